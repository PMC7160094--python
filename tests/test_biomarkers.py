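"""Robust line fit, tapering formulas, AA ratio, volume normalization."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bronchotaper.biomarkers import (
    _wls,
    aa_ratio,
    branch_mean_diameter,
    compute_branch_biomarkers,
    fit_branch_line,
    inter_branch_tapering,
    intra_branch_tapering,
    rescale_subject,
    subject_biomarkers,
)
from bronchotaper.pairing import pair_trees
from bronchotaper.synthetic_data import GeneratorParams, generate_subject
from bronchotaper.tree_model import Branch, resample_subject

from conftest import straight_branch, two_branch_subject


ARC = np.arange(0.0, 15.5, 0.5)


class TestFitBranchLine:
    def test_constant_profile(self):
        fit = fit_branch_line(ARC, np.full_like(ARC, 4.0))
        assert fit.accepted
        assert fit.slope_m == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept_n == pytest.approx(4.0, abs=1e-12)

    def test_noiseless_line_exact(self):
        fit = fit_branch_line(ARC, 4.0 - 0.08 * ARC)
        assert fit.slope_m == pytest.approx(-0.08, abs=1e-9)
        assert fit.intercept_n == pytest.approx(4.0, abs=1e-9)

    def test_outliers_match_clean_subset_ols(self):
        y = 4.0 - 0.08 * ARC
        contaminated = y.copy()
        rng = np.random.default_rng(1)
        bad = rng.random(len(ARC)) < 0.2
        contaminated[bad] *= 2.0
        fit = fit_branch_line(ARC, contaminated)
        clean_beta = _wls(ARC[~bad], y[~bad], np.ones(np.sum(~bad)))
        assert fit.slope_m == pytest.approx(clean_beta[0], abs=1e-3)
        assert fit.intercept_n == pytest.approx(clean_beta[1], abs=1e-3)

    def test_noiseless_inliers_keep_high_weight(self):
        rng = np.random.default_rng(2)
        y = 4.0 - 0.05 * ARC + rng.normal(0, 0.02, len(ARC))
        bad = np.zeros(len(ARC), dtype=bool)
        bad[[3, 11, 20]] = True
        y[bad] *= 2.0
        fit = fit_branch_line(ARC, y)
        assert fit.accepted and fit.converged
        assert np.all(fit.weights[~bad] >= 0.5)
        assert np.all(fit.weights[bad] < 0.05)

    def test_too_few_samples_rejected(self):
        fit = fit_branch_line(ARC[:5], 4.0 - 0.08 * ARC[:5])
        assert not fit.accepted and "usable samples" in fit.reason
        assert np.isnan(intra_branch_tapering(fit))

    def test_negative_intercept_rejected(self):
        fit = fit_branch_line(ARC, -1.0 + 0.01 * ARC)
        assert not fit.accepted and "intercept" in fit.reason

    @given(
        m=st.floats(-0.1, 0.1),
        n=st.floats(1.0, 8.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_exact_recovery_on_any_line(self, m, n):
        y = n + m * ARC
        if np.any(y <= 0):
            return
        fit = fit_branch_line(ARC, y)
        assert fit.accepted
        assert fit.slope_m == pytest.approx(m, abs=1e-8)
        assert fit.intercept_n == pytest.approx(n, abs=1e-8)


class TestTaperingFormulas:
    @pytest.mark.parametrize(
        "m,n,expected",
        [(-0.08, 4.0, 2.0), (0.0, 5.0, 0.0), (0.04, 4.0, -1.0)],
    )
    def test_intra_branch_tapering(self, m, n, expected):
        from bronchotaper.biomarkers import LineFit

        fit = LineFit(m, n, 31, True, True)
        assert intra_branch_tapering(fit) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "d,dp,expected",
        [(4.0, 5.0, 20.0), (4.0, 4.0, 0.0), (4.4, 4.0, -10.0)],
    )
    def test_inter_branch_tapering(self, d, dp, expected):
        assert inter_branch_tapering(d, dp) == pytest.approx(expected, abs=1e-12)

    def test_inter_requires_positive_means(self):
        with pytest.raises(ValueError):
            inter_branch_tapering(-1.0, 5.0)


class TestAARatio:
    def test_constant_profiles(self):
        aw = straight_branch("a", None, 0, (0, 0, 0), (1, 0, 0), 10.0, 3.0, 4.0)
        art = straight_branch("v", None, 0, (0, 2, 0), (1, 0, 0), 10.0,
                              np.nan, 4.0)
        art.inner = np.full(len(art), np.nan)
        ratio_inner, ratio_outer, _ = aa_ratio(aw, art)
        assert ratio_outer == pytest.approx(1.0, abs=1e-12)
        assert ratio_inner == pytest.approx(0.75, abs=1e-12)

    def test_site_found_where_diameters_most_similar(self):
        def outer(x):
            return np.where((x >= 5.0) & (x <= 7.0), 4.0, 5.0)

        aw = straight_branch("a", None, 0, (0, 0, 0), (1, 0, 0), 12.0,
                             inner=lambda x: outer(x) * 0.75, outer=outer)
        art = straight_branch("v", None, 0, (0, 2, 0), (1, 0, 0), 12.0,
                              np.nan, 4.0)
        art.inner = np.full(len(art), np.nan)
        _, _, site = aa_ratio(aw, art, window_mm=2.0)
        assert site == pytest.approx(6.0, abs=1e-9)

    def test_disjoint_centerlines_excluded(self):
        aw = straight_branch("a", None, 0, (0, 0, 0), (1, 0, 0), 10.0, 3.0, 4.0)
        art = straight_branch("v", None, 0, (0, 50, 0), (1, 0, 0), 10.0,
                              np.nan, 4.0)
        art.inner = np.full(len(art), np.nan)
        assert aa_ratio(aw, art) is None


class TestRescale:
    def test_reference_volume_is_identity(self, minimal_subject):
        out = rescale_subject(minimal_subject)
        b0 = minimal_subject.airway_tree.branches["p"]
        b1 = out.airway_tree.branches["p"]
        assert np.allclose(b0.points, b1.points, atol=1e-12)
        assert out.rescale_factor == pytest.approx(1.0)

    def test_half_litre_scales_by_two(self, minimal_subject):
        minimal_subject.lung_volume = 0.5
        out = rescale_subject(minimal_subject)
        assert out.rescale_factor == pytest.approx(2.0, abs=1e-12)
        assert out.airway_tree.branches["p"].inner[0] == pytest.approx(
            2 * minimal_subject.airway_tree.branches["p"].inner[0]
        )

    def test_missing_volume_passes_through_with_warning(self, minimal_subject):
        minimal_subject.lung_volume = None
        with pytest.warns(UserWarning, match="no lung volume"):
            out = rescale_subject(minimal_subject)
        assert out.rescale_factor == pytest.approx(1.0)

    def test_scale_laws(self):
        """Isotropic rescaling by s leaves interBT and AA ratios
        unchanged and divides intraBT by exactly s."""
        p = GeneratorParams(n_generations=4, seed=13, diameter_noise_sd=0.02,
                            outlier_fraction=0.0, lung_volume_L=(4.0, 0.0))
        subject = resample_subject(generate_subject(p))
        scaled = replace(subject, lung_volume=4.0 / 2.0**3)  # => s = 2
        scaled = rescale_subject(scaled)
        assert scaled.rescale_factor == pytest.approx(2.0)

        # same matched pairs; the AA window is a physical length, so it
        # scales with the subject to keep the measurement site identical
        pairs = pair_trees(subject.airway_tree, subject.artery_tree)
        base = compute_branch_biomarkers(subject, pairs, window_mm=2.0)
        after = compute_branch_biomarkers(scaled, pairs, window_mm=4.0)

        for col in ("interBT_inner", "interBT_outer", "aa_inner", "aa_outer"):
            delta = np.abs(after[col].to_numpy() - base[col].to_numpy())
            assert np.nanmax(delta) < 1e-9, col
        for col in ("intraBT_inner", "intraBT_outer"):
            delta = np.abs(after[col].to_numpy() - base[col].to_numpy() / 2.0)
            assert np.nanmax(delta) < 1e-9, col


class TestBranchBiomarkers:
    def test_noiseless_uniform_ground_truth(self, clean_params):
        subject = generate_subject(clean_params)
        table = subject_biomarkers(subject, pair=False)
        root = subject.airway_tree.root_id
        assert np.allclose(table["intraBT_inner"], 1.0, atol=1e-6)
        non_root = table[table.branch_id != root]
        assert np.allclose(non_root["interBT_inner"], 20.0, atol=1e-6)
        assert np.isnan(table.loc[table.branch_id == root, "interBT_inner"]).all()

    def test_short_branch_missing_intra_present_inter(self, minimal_subject):
        child = minimal_subject.airway_tree.branches["c"]
        keep = slice(0, 3)
        minimal_subject.airway_tree.branches["c"] = Branch(
            "c", "p", 1, child.points[keep], child.inner[keep],
            child.outer[keep], arc=child.arc[keep],
        )
        table = compute_branch_biomarkers(minimal_subject, [])
        row = table[table.branch_id == "c"].iloc[0]
        assert np.isnan(row.intraBT_inner)
        assert row.interBT_inner == pytest.approx(20.0, abs=1e-9)
        assert "usable samples" in row["flags"]

    def test_unpaired_branch_keeps_tapering(self, minimal_subject):
        table = compute_branch_biomarkers(minimal_subject, [])
        assert table["aa_inner"].isna().all()
        assert np.isfinite(table["intraBT_inner"]).all()

    def test_inter_uses_raw_means_not_fit(self, minimal_subject):
        """interBT must equal the ratio of raw sample means, entirely
        independent of the line-fit stage."""
        airway = minimal_subject.airway_tree
        rng = np.random.default_rng(5)
        for b in airway:
            b.inner = b.inner + rng.normal(0, 0.3, len(b))  # wreck linearity
        table = compute_branch_biomarkers(minimal_subject, [])
        d = branch_mean_diameter(airway.branches["c"], "inner")
        dp = branch_mean_diameter(airway.branches["p"], "inner")
        expected = (dp - d) / dp * 100.0
        row = table[table.branch_id == "c"].iloc[0]
        assert row.interBT_inner == pytest.approx(expected, abs=1e-12)
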