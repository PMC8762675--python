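"""Grading rules, z-scores, group maps and ring regressions."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octsf import grading, simulate
from octsf.grading import (
    RegressionFit,
    SeverityClassificationError,
    assign_severity_group,
    classify_mferg,
    classify_patient_toxicity,
    classify_vf_abnormal,
    compute_zscores,
    group_mean_zmaps,
    ols_fit,
    univariate_ring_regression,
)
from octsf.simulate import MfergNormative
from octsf.types import MfergRings


class TestSeverityGroups:
    @pytest.mark.parametrize(
        "extent,island,foveal,expected",
        [
            (50.0, np.inf, False, "1"),
            (100.0, np.inf, False, "1"),
            (500.0, np.inf, False, "2"),
            (1000.0, np.inf, False, "2"),
            (1500.0, 600.0, False, "3"),
            (2000.0, 501.0, False, "3"),
            (2500.0, 0.0, True, "4"),
            (120.0, 0.0, True, "4"),
            (0.0, np.inf, False, "unaffected"),
        ],
    )
    def test_worked_examples(self, extent, island, foveal, expected):
        assert assign_severity_group(extent, island, foveal) == expected

    def test_contradictory_morphometry_raises(self):
        with pytest.raises(SeverityClassificationError):
            assign_severity_group(1500.0, 300.0, False)

    def test_negative_extent_rejected(self):
        with pytest.raises(ValueError):
            assign_severity_group(-1.0)

    @given(
        extent=st.floats(0, 5000),
        island=st.floats(0, 3000),
        foveal=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_partitions_valid_inputs(self, extent, island, foveal):
        """Every consistent input maps to exactly one group."""
        try:
            group = assign_severity_group(extent, island, foveal)
        except SeverityClassificationError:
            assert extent > 1000 and island <= 500 and not foveal
        else:
            assert group in ("unaffected", "1", "2", "3", "4")


class TestVfAbnormality:
    def _flags(self, grid, loci):
        flags = np.zeros(grid.n_loci, dtype=bool)
        for xy in loci:
            idx = np.nonzero((grid.x_deg == xy[0]) & (grid.y_deg == xy[1]))[0]
            flags[idx] = True
        return flags

    def test_three_horizontally_contiguous_points(self, grid):
        flags = self._flags(grid, [(-1, 3), (1, 3), (3, 3)])
        assert classify_vf_abnormal(flags, grid) is True

    def test_two_points_insufficient(self, grid):
        flags = self._flags(grid, [(-1, 3), (1, 3)])
        assert classify_vf_abnormal(flags, grid) is False

    def test_three_scattered_points_insufficient(self, grid):
        flags = self._flags(grid, [(-9, 1), (1, 9), (9, -1)])
        assert classify_vf_abnormal(flags, grid) is False

    def test_diagonal_counts_only_with_8_connectivity(self, grid):
        flags = self._flags(grid, [(1, 1), (3, 3), (5, 5)])
        assert classify_vf_abnormal(flags, grid, connectivity=4) is False
        assert classify_vf_abnormal(flags, grid, connectivity=8) is True

    def test_full_ring_scotoma(self, grid):
        flags = grid.ring == 2
        assert classify_vf_abnormal(flags, grid) is True

    def test_wrong_flag_count_rejected(self, grid):
        with pytest.raises(ValueError):
            classify_vf_abnormal(np.zeros(10, dtype=bool), grid)

    @given(data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_added_flags(self, grid, data):
        flags = np.array(
            data.draw(st.lists(st.booleans(), min_size=68, max_size=68))
        )
        extra = data.draw(st.integers(0, 67))
        more = flags.copy()
        more[extra] = True
        if classify_vf_abnormal(flags, grid):
            assert classify_vf_abnormal(more, grid)


class TestMfergRule:
    LIMITS = MfergNormative(r1_lower_limit=100.0, r1_r2_upper_limit=2.4)

    def test_elevated_ratio_is_positive(self):
        rings = MfergRings(np.array([120.0, 40.0, 40.0, 30.0, 25.0]))  # R1/R2 = 3
        assert classify_mferg(rings, self.LIMITS) is True

    def test_reduced_r1_is_positive(self):
        rings = MfergRings(np.array([80.0, 60.0, 40.0, 30.0, 25.0]))
        assert classify_mferg(rings, self.LIMITS) is True

    def test_normal_eye_is_negative(self):
        rings = MfergRings(np.array([120.0, 60.0, 40.0, 30.0, 25.0]))
        assert classify_mferg(rings, self.LIMITS) is False

    def test_missing_limits_rejected(self):
        rings = MfergRings(np.array([120.0, 60.0, 40.0, 30.0, 25.0]))
        with pytest.raises(ValueError):
            classify_mferg(rings, None)


class TestToxicityPipeline:
    def test_fellow_eye_mild_toxicity(self):
        status = classify_patient_toxicity(
            vf_abnormal={"OD": True, "OS": False},
            mferg_positive={"OD": True, "OS": True},
            oct_evidence={"OD": True, "OS": False},
        )
        assert status == {"OD": "toxic", "OS": "toxic_mild"}

    def test_vf_alone_insufficient(self):
        status = classify_patient_toxicity(
            vf_abnormal={"OD": True, "OS": False},
            mferg_positive={"OD": False, "OS": False},
            oct_evidence={"OD": False, "OS": False},
        )
        assert status == {"OD": "unaffected", "OS": "unaffected"}

    def test_mferg_alone_without_toxic_fellow_is_unaffected(self):
        status = classify_patient_toxicity(
            vf_abnormal={"OD": False, "OS": False},
            mferg_positive={"OD": True, "OS": False},
            oct_evidence={"OD": False, "OS": False},
        )
        assert status == {"OD": "unaffected", "OS": "unaffected"}


def toy_feature_table():
    """3 reference eyes + 1 test eye, 2 loci, one metric of interest."""
    rows = []
    ref_vals = {0: [10.0, 12.0, 14.0], 1: [20.0, 20.0, 26.0]}
    for i, eye in enumerate(["r1", "r2", "r3"]):
        for locus in (0, 1):
            rows.append(
                dict(
                    eye_id=eye, patient_id=eye, severity_group="unaffected",
                    locus_id=locus, ring=1, valid=True,
                    trt_um=ref_vals[locus][i],
                    sensitivity_db=30.0 + i,
                )
            )
    for locus in (0, 1):
        rows.append(
            dict(
                eye_id="t1", patient_id="t1", severity_group="2",
                locus_id=locus, ring=1, valid=True,
                trt_um=[16.0, 22.0][locus],
                sensitivity_db=25.0,
            )
        )
    return pd.DataFrame(rows)


class TestZScores:
    def test_worked_values(self):
        feats = toy_feature_table()
        z, stats = compute_zscores(feats, {"r1", "r2", "r3"}, metrics=["trt_um"])
        t = z[z["eye_id"] == "t1"].set_index("locus_id")
        # locus 0: mu=12, sd=2 -> (16-12)/2 = 2 ; locus 1: mu=22, sd=sqrt(12)
        assert t.loc[0, "trt_um"] == pytest.approx(2.0)
        assert t.loc[1, "trt_um"] == pytest.approx(0.0)

    def test_reference_eyes_standardized(self):
        feats = toy_feature_table()
        z, _ = compute_zscores(feats, {"r1", "r2", "r3"}, metrics=["trt_um"])
        ref = z[z["eye_id"].isin({"r1", "r2", "r3"})]
        for _, sub in ref.groupby("locus_id"):
            assert abs(sub["trt_um"].mean()) < 1e-12
            assert sub["trt_um"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_sd_flagged_nan_with_warning(self):
        feats = toy_feature_table()
        feats.loc[feats["locus_id"] == 0, "trt_um"] = 5.0
        with pytest.warns(UserWarning, match="zero reference SD"):
            z, _ = compute_zscores(feats, {"r1", "r2", "r3"}, metrics=["trt_um"])
        assert z[z["locus_id"] == 0]["trt_um"].isna().all()

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_zscores(toy_feature_table(), set())


class TestGroupMaps:
    def test_reference_group_map_is_zero(self):
        feats = toy_feature_table()
        z, _ = compute_zscores(feats, {"r1", "r2", "r3"}, metrics=["trt_um"])
        maps = group_mean_zmaps(
            z, {"r1": "unaffected", "r2": "unaffected", "r3": "unaffected",
                "t1": "2"},
            metrics=["trt_um"],
        )
        assert np.allclose(maps["unaffected"]["trt_um"], 0.0, atol=1e-12)

    def test_single_eye_group_equals_its_z(self):
        feats = toy_feature_table()
        z, _ = compute_zscores(feats, {"r1", "r2", "r3"}, metrics=["trt_um"])
        maps = group_mean_zmaps(
            z, {"r1": "unaffected", "r2": "unaffected", "r3": "unaffected",
                "t1": "2"},
            metrics=["trt_um"],
        )
        t = z[z["eye_id"] == "t1"].set_index("locus_id")["trt_um"]
        assert np.allclose(maps["2"]["trt_um"], t)

    def test_group3_parafoveal_sensitivity_depressed(
        self, reduced_features
    ):
        """Ring-2 mean sensitivity z is below ring 1 in severe eyes."""
        feats = reduced_features
        ref = feats.loc[
            feats["severity_group"] == "unaffected", "eye_id"
        ].unique()
        z, _ = compute_zscores(feats, set(ref))
        sev = feats.drop_duplicates("eye_id").set_index("eye_id")[
            "severity_group"
        ]
        g3_eyes = sev[sev == "3"].index
        sub = z[z["eye_id"].isin(g3_eyes)]
        ring2 = sub[sub["ring"] == 2]["sensitivity_db"].mean()
        ring1 = sub[sub["ring"] == 1]["sensitivity_db"].mean()
        assert ring2 < ring1 < 0.5


class TestOls:
    def test_exact_line(self):
        df = pd.DataFrame(
            dict(
                eye_id="e", ring=2, valid=True,
                trt_um=np.arange(10.0),
                sensitivity_db=2.0 * np.arange(10.0) + 1.0,
            )
        )
        fit = univariate_ring_regression(df, "trt_um", 2)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.mae_db == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_triangle_has_zero_slope_and_r2(self):
        df = pd.DataFrame(
            dict(
                eye_id="e", ring=1, valid=True,
                trt_um=[0.0, 1.0, 2.0],
                sensitivity_db=[0.0, 1.0, 0.0],
            )
        )
        fit = univariate_ring_regression(df, "trt_um", 1)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_convention(self):
        df = pd.DataFrame(
            dict(
                eye_id="e", ring=1, valid=True,
                trt_um=[0.0, 1.0, 2.0],
                sensitivity_db=[5.0, 5.0, 5.0],
            )
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = univariate_ring_regression(df, "trt_um", 1)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_degenerate_predictor_rejected(self):
        df = pd.DataFrame(
            dict(
                eye_id="e", ring=1, valid=True,
                trt_um=[3.0, 3.0, 3.0],
                sensitivity_db=[1.0, 2.0, 3.0],
            )
        )
        with pytest.raises(ValueError, match="degenerate"):
            univariate_ring_regression(df, "trt_um", 1)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_scipy_linregress(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = 3.0 * x + rng.normal(size=12)
        slope, intercept = ols_fit(x, y)
        from scipy.stats import linregress

        ref = linregress(x, y)
        assert slope == pytest.approx(ref.slope, abs=1e-10)
        assert intercept == pytest.approx(ref.intercept, abs=1e-10)

    def test_too_few_points_rejected(self):
        df = pd.DataFrame(
            dict(eye_id="e", ring=1, valid=True, trt_um=[1.0], sensitivity_db=[1.0])
        )
        with pytest.raises(ValueError, match=">= 3"):
            univariate_ring_regression(df, "trt_um", 1)


class TestSlopeRecovery:
    def test_ring2_ols_recovers_beta_ez_noise_free(self):
        """With beta_ort = 0 and flat eccentricity, the ring-2 OLS slope of
        sensitivity on EZ fraction equals -beta_ez to numerical precision."""
        from octsf import extract

        sf = simulate.GroundTruthSF(ecc_slope=0.0, beta_ort=0.0, noise_sd=0.0)
        cfg = simulate.reduced_config(
            seed=21, render_volumes=False, sf_params=sf,
            n_patients_per_group={"unaffected": 3, "2": 2, "3": 2},
        )
        pats = simulate.generate_cohort(cfg)
        feats = extract.extract_cohort_features(pats, cfg)
        fit = univariate_ring_regression(feats, "ez_frac", 2)
        assert fit.slope == pytest.approx(-sf.beta_ez, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
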