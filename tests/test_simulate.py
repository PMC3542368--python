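"""Tests for the synthetic-cohort generator."""

import dataclasses

import numpy as np
import pytest
import yaml

import somaticsurv as ss


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_patients": 1},
            {"causal_log_hr": float("inf")},
            {"causal_log_hr": float("nan")},
            {"causal_genes": 20, "n_genes": 10},
            {"mutation_freq_range": (0.5, 0.1)},
            {"mutation_freq_range": (0.0, 0.1)},
            {"baseline_hazard": 0.0},
            {"censor_rate": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ss.SimConfig(**kwargs)

    def test_from_yaml_requires_seed(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_patients: 50\nn_genes: 20\n")
        with pytest.raises(ValueError, match="seed"):
            ss.SimConfig.from_file(p)
        p.write_text(
            yaml.safe_dump(
                {"n_patients": 50, "n_genes": 20, "seed": 7,
                 "mutation_freq_range": [0.05, 0.2]}
            )
        )
        cfg = ss.SimConfig.from_file(p)
        assert cfg.seed == 7 and cfg.mutation_freq_range == (0.05, 0.2)


class TestGenerateCohort:
    def test_same_seed_bitwise_identical(self):
        cfg = ss.SimConfig(n_patients=300, n_genes=200, causal_genes=5,
                           causal_log_hr=0.5, seed=1)
        a, b = ss.generate_cohort(cfg), ss.generate_cohort(cfg)
        np.testing.assert_array_equal(a.mutation_matrix.values, b.mutation_matrix.values)
        np.testing.assert_array_equal(a.os_outcome.time, b.os_outcome.time)
        np.testing.assert_array_equal(a.pfs_outcome.event, b.pfs_outcome.event)
        assert a.clinical.equals(b.clinical)
        assert a.truth == b.truth

    def test_null_model_exponential_mean(self):
        cfg = ss.SimConfig(
            n_patients=4000, n_genes=10, causal_genes=0, censor_rate=0.0,
            max_followup=1e12, baseline_hazard=0.02, seed=3,
        )
        coh = ss.generate_cohort(cfg)
        assert coh.os_outcome.event.all()
        mean, target = coh.os_outcome.time.mean(), 1 / 0.02
        se = target / np.sqrt(cfg.n_patients)
        assert abs(mean - target) < 3 * se

    def test_cox_recovers_generating_coefficient(self):
        # single causal gene, no censoring: an established Cox implementation
        # should recover the generating log hazard ratio
        from lifelines import CoxPHFitter
        import pandas as pd

        cfg = ss.SimConfig(
            n_patients=2000, n_genes=1, causal_genes=1, causal_log_hr=0.7,
            mutation_freq_range=(0.3, 0.5), censor_rate=0.0, max_followup=1e12,
            seed=4,
        )
        coh = ss.generate_cohort(cfg)
        df = pd.DataFrame(
            {
                "t": coh.os_outcome.time,
                "e": coh.os_outcome.event,
                "x": coh.mutation_matrix.values[:, 0],
            }
        )
        cph = CoxPHFitter().fit(df, "t", "e")
        assert cph.params_["x"] == pytest.approx(0.7, abs=0.1)

    def test_effect_direction_monotone_in_hazard_ratio(self):
        # stronger causal effects => mutated patients die earlier, on average
        gaps = []
        for beta in (0.0, 0.7, 1.4):
            diffs = []
            for seed in range(5):
                cfg = ss.SimConfig(
                    n_patients=400, n_genes=1, causal_genes=1, causal_log_hr=beta,
                    mutation_freq_range=(0.4, 0.5), censor_rate=0.0, seed=seed,
                )
                coh = ss.generate_cohort(cfg)
                mut = coh.mutation_matrix.values[:, 0] == 1
                diffs.append(
                    np.median(coh.os_outcome.time[~mut])
                    - np.median(coh.os_outcome.time[mut])
                )
            gaps.append(np.mean(diffs))
        assert gaps[0] < gaps[1] < gaps[2]

    def test_null_screening_selects_alpha_fraction(self):
        # with no causal genes the log-rank screen at alpha=0.01 is a pure
        # type-I error machine: ~1% of testable genes selected
        hits = total = 0
        for seed in range(10):
            cfg = ss.SimConfig(n_patients=200, n_genes=300, causal_genes=0, seed=seed)
            coh = ss.generate_cohort(cfg)
            m = ss.filter_rare_genes(coh.mutation_matrix, 5)
            sel = ss.select_genes(m, coh.os_outcome, ss.SelectionConfig(alpha=0.01))
            hits += len(sel)
            total += m.n_genes
        rate = hits / total
        se = np.sqrt(0.01 * 0.99 / total)
        assert abs(rate - 0.01) < 4 * se

    def test_clinical_levels_and_missingness(self):
        coh = ss.generate_cohort(
            ss.SimConfig(n_patients=400, n_genes=10, clinical_missing_rate=0.2, seed=9)
        )
        clin = coh.clinical
        assert set(clin["grade"].dropna().unique()) <= {"2", "3"}
        assert set(clin["platinum"].dropna().unique()) <= {"sensitive", "resistant"}
        frac_missing = clin["residual"].isna().mean()
        assert 0.1 < frac_missing < 0.3


class TestWriteFixture:
    def test_roundtrip_exact(self, tmp_path):
        coh = ss.generate_cohort(ss.SimConfig(n_patients=60, n_genes=25, seed=7))
        paths = ss.write_fixture(coh, tmp_path)
        m2 = ss.read_maf(paths["mutations"])
        orig = coh.mutation_matrix.to_frame()
        back = m2.to_frame()
        # patients with zero mutations cannot appear in a MAF file
        assert set(back.index) <= set(orig.index)
        assert orig.loc[back.index, back.columns].equals(back)
        # genes with zero mutations cannot appear either
        assert (orig.drop(columns=back.columns).sum() == 0).all()

    def test_zero_mutation_patient_survives_via_clinical(self, tmp_path):
        coh = ss.generate_cohort(
            ss.SimConfig(n_patients=40, n_genes=5,
                         mutation_freq_range=(0.02, 0.05), seed=2)
        )
        zero = coh.mutation_matrix.values.sum(axis=1) == 0
        assert zero.any()  # seed chosen so at least one patient has no mutation
        paths = ss.write_fixture(coh, tmp_path)
        clin = ss.read_clinical(paths["clinical"])
        assert set(coh.mutation_matrix.patient_ids) == set(clin.index)

    def test_maf_line_count_is_mutation_count_plus_header(self, tmp_path):
        coh = ss.generate_cohort(ss.SimConfig(n_patients=50, n_genes=20, seed=7))
        paths = ss.write_fixture(coh, tmp_path)
        n_lines = sum(1 for _ in open(paths["mutations"]))
        assert n_lines == int(coh.mutation_matrix.values.sum()) + 1

    def test_clinical_roundtrip_preserves_outcomes(self, tmp_path):
        coh = ss.generate_cohort(ss.SimConfig(n_patients=30, n_genes=10, seed=5))
        paths = ss.write_fixture(coh, tmp_path)
        clin = ss.read_clinical(paths["clinical"])
        np.testing.assert_allclose(
            clin.loc[coh.mutation_matrix.patient_ids, "os_months"].to_numpy(),
            coh.os_outcome.time,
            rtol=1e-9,
        )
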