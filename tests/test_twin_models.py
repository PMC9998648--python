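"""Twin-model statistics: partial correlations, gating, Falconer formulas, Fisher tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from twinconn.io_model import TwinPair, TwinPairManifest, ValidationError
from twinconn.synthetic_data import SimulationConfig, VarianceComponentsSpec, simulate_feature_cohort
from twinconn.twin_models import (
    ZygosityCorrelations,
    ace_decompose,
    ade_decompose,
    bonferroni_adjust,
    classify_scenario,
    compare_correlations,
    fisher_z,
    partial_correlation,
    run_twin_analysis,
    zygosity_correlations,
)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 50))
        assert partial_correlation(x, y) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-12
        )

    def test_single_covariate_matches_textbook_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        z = np.array([1.0, 1, 2, 2, 3])
        r_xy = stats.pearsonr(x, y).statistic
        r_xz = stats.pearsonr(x, z).statistic
        r_yz = stats.pearsonr(y, z).statistic
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert partial_correlation(x, y, z[:, None]) == pytest.approx(expected, abs=1e-12)

    def test_identity_after_residualization(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        cov = rng.standard_normal((30, 2))
        assert partial_correlation(x, x.copy(), cov) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            partial_correlation(np.arange(5.0), np.arange(6.0))

    def test_rank_deficient_covariates_rejected(self):
        x = np.arange(10.0)
        cov = np.ones((10, 2))  # duplicates the intercept twice over
        with pytest.raises(ValidationError, match="rank"):
            partial_correlation(x, x, cov)


def _manifest(n_mz, n_dz, rng, single_sex=False):
    pairs = []
    for i in range(n_mz + n_dz):
        zyg = "MZ" if i < n_mz else "DZ"
        pairs.append(
            TwinPair(
                f"p{i}", zyg, f"s{i}a", f"s{i}b",
                float(rng.uniform(10, 30)),
                "F" if single_sex else ("M" if rng.random() < 0.5 else "F"),
            )
        )
    return TwinPairManifest(tuple(pairs))


class TestZygosityCorrelations:
    def test_duplicated_twin_values_give_unit_correlation(self):
        rng = np.random.default_rng(2)
        manifest = _manifest(8, 8, rng)
        vals = {}
        for p in manifest.pairs:
            v = rng.standard_normal()
            vals[p.twin1_id] = v
            vals[p.twin2_id] = v
        feats = pd.DataFrame({"node:degree:R0": pd.Series(vals)})
        zc = zygosity_correlations(feats, manifest)
        assert zc.loc["node:degree:R0", "rMZ"] == pytest.approx(1.0)
        assert zc.loc["node:degree:R0", "rDZ"] == pytest.approx(1.0)

    def test_recovers_generator_implied_correlations(self):
        spec = VarianceComponentsSpec(a2=0.6, e2=0.4)
        manifest, vals = simulate_feature_cohort(
            spec, SimulationConfig(n_mz=5000, n_dz=5000, seed=3)
        )
        feats = pd.DataFrame({"link:a|b": pd.Series(vals)})
        zc = zygosity_correlations(feats, manifest)
        assert zc.loc["link:a|b", "rMZ"] == pytest.approx(0.6, abs=0.03)
        assert zc.loc["link:a|b", "rDZ"] == pytest.approx(0.3, abs=0.03)
        assert zc.loc["link:a|b", "k"] == 2

    def test_single_sex_cohort_drops_sex_covariate_with_warning(self):
        rng = np.random.default_rng(4)
        manifest = _manifest(8, 8, rng, single_sex=True)
        vals = {s: rng.standard_normal() for s in manifest.subject_ids}
        feats = pd.DataFrame({"net:density": pd.Series(vals)})
        with pytest.warns(UserWarning, match="sex"):
            zc = zygosity_correlations(feats, manifest)
        assert zc.loc["net:density", "k"] == 1

    def test_missing_subject_rejected(self):
        rng = np.random.default_rng(5)
        manifest = _manifest(6, 6, rng)
        feats = pd.DataFrame(
            {"net:density": pd.Series({s: 0.5 for s in manifest.subject_ids[:-1]})}
        )
        with pytest.raises(ValidationError, match="missing"):
            zygosity_correlations(feats, manifest)

    def test_too_few_pairs_rejected(self):
        rng = np.random.default_rng(6)
        manifest = _manifest(3, 8, rng)  # 3 MZ < k + 4
        vals = {s: rng.standard_normal() for s in manifest.subject_ids}
        feats = pd.DataFrame({"net:density": pd.Series(vals)})
        with pytest.raises(ValidationError, match="MZ"):
            zygosity_correlations(feats, manifest)


class TestFisher:
    def test_fixed_point_and_closed_form(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.6) == pytest.approx(np.log(1.6 / 0.4) / 2, abs=1e-12)
        assert fisher_z(0.6) == pytest.approx(0.6931, abs=5e-5)

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=100, derandomize=True)
    def test_odd_symmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5, float("nan")])
    def test_domain_enforced(self, r):
        with pytest.raises(ValidationError):
            fisher_z(r)

    def test_derived_comparison_example(self):
        zc = ZygosityCorrelations("f", 0.8, 0.2, 18, 25, 2)
        fc = compare_correlations(zc)
        expected_z = (np.arctanh(0.8) - np.arctanh(0.2)) / np.sqrt(1 / 13 + 1 / 20)
        assert fc.Z == pytest.approx(expected_z, abs=1e-12)
        assert fc.Z == pytest.approx(2.514, abs=2e-3)
        assert fc.p == pytest.approx(0.0060, abs=2e-4)

    def test_equal_correlations_give_null(self):
        fc = compare_correlations(ZygosityCorrelations("f", 0.4, 0.4, 20, 20, 2))
        assert fc.Z == 0.0
        assert fc.p == 0.5

    def test_antisymmetry_under_group_swap(self):
        a = compare_correlations(ZygosityCorrelations("f", 0.7, 0.3, 18, 25, 2))
        b = compare_correlations(ZygosityCorrelations("f", 0.3, 0.7, 25, 18, 2))
        assert b.Z == pytest.approx(-a.Z, abs=1e-12)
        assert b.p == pytest.approx(1 - a.p, abs=1e-12)

    def test_degenerate_group_size_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            compare_correlations(ZygosityCorrelations("f", 0.5, 0.2, 5, 25, 2))


class TestScenarioGating:
    @pytest.mark.parametrize(
        "r_mz,r_dz,label",
        [
            (0.5, 0.1, "EPISTASIS"),  # rMZ > 4 rDZ > 0
            (0.6, 0.2, "ADE"),  # 2 rDZ < rMZ < 4 rDZ
            (0.35, 0.2, "ACE"),  # rDZ < rMZ < 2 rDZ
            (0.3, 0.4, "UNMODELED"),  # rMZ <= rDZ
            (-0.2, 0.1, "UNMODELED"),
            (0.3, -0.1, "UNMODELED"),
            (0.0, 0.0, "UNMODELED"),
            (float("nan"), 0.2, "UNMODELED"),
        ],
    )
    def test_gating_rules(self, r_mz, r_dz, label):
        assert classify_scenario(r_mz, r_dz) == label

    def test_boundaries_keep_estimates_continuous(self):
        # rMZ = 2 rDZ -> ACE with C = 0; rMZ = 4 rDZ -> ADE with A = 0
        assert classify_scenario(0.4, 0.2) == "ACE"
        dec = ace_decompose(0.4, 0.2)
        assert dec.C == pytest.approx(0.0, abs=1e-15)
        assert classify_scenario(0.8, 0.2) == "ADE"
        dec = ade_decompose(0.8, 0.2)
        assert dec.A == pytest.approx(0.0, abs=1e-15)

    def test_partition_of_admissible_region(self):
        """Each grid point with 0 < rDZ < rMZ gets exactly one non-trivial label."""
        grid = np.linspace(0.01, 0.99, 57)
        for r_mz in grid:
            for r_dz in grid:
                label = classify_scenario(r_mz, r_dz)
                if 0 < r_dz < r_mz:
                    assert label in ("EPISTASIS", "ADE", "ACE")
                else:
                    assert label == "UNMODELED"


class TestFalconerDecomposition:
    def test_ade_reproduces_published_row(self):
        dec = ade_decompose(0.6191, 0.27025)
        assert 100 * dec.A == pytest.approx(46.19, abs=0.005)
        assert 100 * dec.D == pytest.approx(15.72, abs=0.005)
        assert 100 * dec.E == pytest.approx(38.09, abs=0.005)
        assert 100 * dec.H2 == pytest.approx(61.91, abs=0.005)

    def test_ade_direct_evaluation(self):
        dec = ade_decompose(0.6, 0.2)
        assert (dec.A, dec.D, dec.E) == pytest.approx((0.2, 0.4, 0.4), abs=1e-12)
        assert dec.H2 == pytest.approx(0.6)

    def test_ace_reproduces_published_heritability(self):
        dec = ace_decompose(0.3519, 0.18355)
        assert 100 * dec.A == pytest.approx(33.67, abs=0.005)
        assert 100 * dec.C == pytest.approx(1.52, abs=0.005)
        assert 100 * dec.E == pytest.approx(64.81, abs=0.005)
        assert dec.h2 == dec.A

    def test_ace_direct_evaluation(self):
        dec = ace_decompose(0.4, 0.3)
        assert (dec.A, dec.C, dec.E) == pytest.approx((0.2, 0.2, 0.6), abs=1e-12)

    def test_scenario_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="ADE"):
            ade_decompose(0.35, 0.2)  # ACE region
        with pytest.raises(ValidationError, match="ACE"):
            ace_decompose(0.6, 0.2)  # ADE region

    def test_components_nonnegative_and_sum_to_one_on_dense_grid(self):
        grid = np.linspace(0.005, 0.995, 120)
        for r_mz in grid:
            for r_dz in grid:
                label = classify_scenario(r_mz, r_dz)
                if label == "ADE":
                    dec = ade_decompose(r_mz, r_dz)
                    comps = (dec.A, dec.D, dec.E)
                elif label == "ACE":
                    dec = ace_decompose(r_mz, r_dz)
                    comps = (dec.A, dec.C, dec.E)
                else:
                    continue
                assert all(c >= -1e-12 for c in comps)
                assert sum(comps) == pytest.approx(1.0, abs=1e-12)


class TestBonferroni:
    def test_definition_and_cap(self):
        out = bonferroni_adjust(np.array([0.01, 0.2, 0.004]), n_condition=10)
        np.testing.assert_allclose(out["p_bonferroni"], [0.1, 1.0, 0.04])
        assert list(out["significant_bonf"]) == [False, False, True]
        assert list(out["significant_unc"]) == [True, False, True]

    def test_family_size_validation(self):
        with pytest.raises(ValidationError):
            bonferroni_adjust(np.array([0.01]), n_condition=0)
        with pytest.raises(ValidationError, match="smaller"):
            bonferroni_adjust(np.array([0.01, 0.02]), n_condition=1)


class TestRunTwinAnalysis:
    def _feature_frame(self, manifest, values_by_feature):
        return pd.DataFrame(
            {fid: pd.Series(vals) for fid, vals in values_by_feature.items()}
        )

    def test_ace_cohort_recovered(self):
        spec = VarianceComponentsSpec(a2=0.4, c2=0.2, e2=0.4)
        manifest, vals = simulate_feature_cohort(
            spec, SimulationConfig(n_mz=5000, n_dz=5000, seed=17)
        )
        feats = self._feature_frame(manifest, {"link:a|b": vals})
        res = run_twin_analysis(feats, manifest)
        row = res.iloc[0]
        assert row["scenario"] == "ACE"
        assert row["A"] == pytest.approx(0.4, abs=0.03)
        assert row["C"] == pytest.approx(0.2, abs=0.03)
        assert row["E"] == pytest.approx(0.4, abs=0.03)

    def test_null_cohort_mostly_unmodeled_or_insignificant(self):
        fractions = []
        for seed in range(20):
            manifest, vals = simulate_feature_cohort(
                VarianceComponentsSpec(e2=1.0),
                SimulationConfig(n_mz=18, n_dz=25, seed=300 + seed),
            )
            feats = self._feature_frame(manifest, {"link:a|b": vals})
            res = run_twin_analysis(feats, manifest)
            row = res.iloc[0]
            fractions.append(
                row["scenario"] == "UNMODELED" or not row["significant_unc"]
            )
        assert np.mean(fractions) >= 0.95

    def test_bonferroni_families_are_scale_by_scenario(self):
        rng = np.random.default_rng(23)
        manifest = _manifest(10, 10, rng)
        feats = pd.DataFrame(
            rng.standard_normal((40, 6)),
            index=list(manifest.subject_ids),
            columns=[
                "link:a|b", "link:a|c", "link:b|c",
                "node:degree:a", "node:degree:b", "net:density",
            ],
        )
        res = run_twin_analysis(feats, manifest)
        for (_, _), grp in res.groupby(["scale", "scenario"]):
            valid = grp["p"].notna()
            np.testing.assert_allclose(
                grp.loc[valid, "p_bonferroni"],
                np.minimum(1.0, grp.loc[valid, "p"] * valid.sum()),
            )

    def test_require_significant_r_prunes_weak_features(self):
        manifest, vals = simulate_feature_cohort(
            VarianceComponentsSpec(a2=0.3, e2=0.7),
            SimulationConfig(n_mz=8, n_dz=8, seed=31),
        )
        feats = self._feature_frame(manifest, {"link:a|b": vals})
        strict = run_twin_analysis(feats, manifest, require_significant_r=True)
        loose = run_twin_analysis(feats, manifest, require_significant_r=False)
        # the strict filter can only move features toward UNMODELED
        assert (strict["scenario"] == "UNMODELED").sum() >= (
            loose["scenario"] == "UNMODELED"
        ).sum()

    def test_double_entry_is_order_invariant(self):
        rng = np.random.default_rng(37)
        manifest = _manifest(10, 10, rng)
        vals = {s: rng.standard_normal() for s in manifest.subject_ids}
        feats = self._feature_frame(manifest, {"link:a|b": vals})
        res1 = run_twin_analysis(feats, manifest, double_entry=True)
        swapped = TwinPairManifest(
            tuple(
                TwinPair(p.pair_id, p.zygosity, p.twin2_id, p.twin1_id, p.age, p.sex)
                for p in manifest.pairs
            )
        )
        res2 = run_twin_analysis(feats, swapped, double_entry=True)
        assert res1["rMZ"].iloc[0] == pytest.approx(res2["rMZ"].iloc[0], abs=1e-12)
        assert res1["rDZ"].iloc[0] == pytest.approx(res2["rDZ"].iloc[0], abs=1e-12)
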