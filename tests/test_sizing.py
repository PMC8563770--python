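"""Sizing-table construction, assignment rules, coverage, and agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from maskfit import sizing, synthetic
from maskfit.errors import InputError, NumericalError

FWHM = sizing.FWHM_FACTOR  # 2 sqrt(2 ln 2)


class TestFitNormal:
    def test_hand_arithmetic(self):
        fit = sizing.fit_normal([1.0, 2.0, 3.0])
        assert fit.mu == pytest.approx(2.0)
        assert fit.sd == pytest.approx(1.0)
        assert fit.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)))

    def test_large_sample_fwhm(self):
        draws = np.random.default_rng(0).standard_normal(1_000_000)
        assert sizing.fit_normal(draws).fwhm == pytest.approx(FWHM, rel=0.01)

    def test_degenerate_inputs(self):
        with pytest.raises(NumericalError, match="identical"):
            sizing.fit_normal([5.0, 5.0, 5.0])
        with pytest.raises(InputError, match="at least 3"):
            sizing.fit_normal([1.0, 2.0])


class TestSizeBrackets:
    def test_catalogue_midpoints(self):
        """Moments back-derived from the published catalogue reproduce its
        midpoints 97.3 / 104.9 / 112.4 mm."""
        rng = np.random.default_rng(1)
        mu, sd = 104.85, 6.37
        draws = mu + sd * rng.standard_normal(400_000)
        # re-standardise so the sample moments are exact
        draws = mu + sd * (draws - draws.mean()) / draws.std(ddof=1)
        brs = sizing.build_size_brackets(draws, half_width=4.5)
        mids = [b.midpoint for b in brs]
        assert mids == pytest.approx(
            [mu - FWHM * sd / 2, mu, mu + FWHM * sd / 2], abs=1e-6
        )
        assert mids == pytest.approx([97.35, 104.85, 112.35], abs=0.01)

    @given(
        hw=st.floats(0.3, 3.7),
        sd=st.floats(1.0, 10.0),
        mu=st.floats(50.0, 150.0),
    )
    def test_interval_algebra(self, hw, sd, mu):
        """Adjacent overlap width is 2*hw - fwhm/2; brackets are disjoint
        when hw < fwhm/4; Small and Large never overlap."""
        rng = np.random.default_rng(7)
        vals = mu + sd * rng.standard_normal(500)
        fit = sizing.fit_normal(vals)
        if 2 * hw >= fit.fwhm:
            with pytest.raises(InputError):
                sizing.build_size_brackets(vals, hw)
            return
        small, medium, large = sizing.build_size_brackets(vals, hw)
        assert small.upper - medium.lower == pytest.approx(
            2 * hw - fit.fwhm / 2, rel=1e-9, abs=1e-9
        )
        assert small.upper < large.lower
        if hw < fit.fwhm / 4:
            assert small.upper < medium.lower and medium.upper < large.lower

    def test_bracket_midpoint_definition(self, ref_table):
        """(lower + upper)/2 reproduces the printed midpoint for every
        bracket of the reference catalogue, e.g. Small (92.8, 101.8) -> 97.3."""
        small = ref_table.shells[0]
        assert (small.lower, small.upper) == (92.8, 101.8)
        assert small.midpoint == pytest.approx(97.3, abs=1e-9)
        for s in ref_table.shells:
            assert s.midpoint == pytest.approx((s.lower + s.upper) / 2)


class TestBuildSizingTable:
    def test_default_cohort_structure(self, default_cohort):
        table = sizing.build_sizing_table(default_cohort)
        assert len(table.shells) == 3
        assert len(list(table.cells())) == 9
        fit = sizing.fit_normal(default_cohort["eye_to_chin_mm"])
        expect = [fit.mu - fit.fwhm / 2, fit.mu, fit.mu + fit.fwhm / 2]
        for shell, mid in zip(table.shells, expect):
            assert shell.midpoint == pytest.approx(mid, abs=0.3)
        # adjacent shells overlap, non-adjacent do not
        assert len(table.overlap_regions) == 2
        assert table.shells[0].upper < table.shells[2].lower

    def test_identical_cohort_degenerate(self):
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(40)],
                "eye_to_chin_mm": 100.0,
                "A_mm": 23.0,
                "sigma_mm": 10.0,
            }
        )
        with pytest.raises(NumericalError):
            sizing.build_sizing_table(df)

    def test_sparse_shell_named_in_failure(self):
        rng = np.random.default_rng(3)
        # all mass at the centre: the Small/Large brackets end up undersampled
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(40)],
                "eye_to_chin_mm": np.concatenate(
                    [np.full(38, 100.0) + rng.normal(0, 0.3, 38), [60.0, 140.0]]
                ),
                "A_mm": rng.normal(23, 1, 40),
                "sigma_mm": rng.normal(10, 0.5, 40),
            }
        )
        with pytest.raises(InputError, match="members"):
            sizing.build_sizing_table(df)

    def test_small_cohort_warns(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(12)],
                "eye_to_chin_mm": rng.normal(105, 6, 12),
                "A_mm": rng.normal(23, 1, 12),
                "sigma_mm": rng.normal(10, 0.7, 12),
            }
        )
        with pytest.warns(UserWarning, match="cohort"):
            try:
                sizing.build_sizing_table(df)
            except InputError:
                pass  # sparse cells are acceptable at n = 12


class TestAssign:
    def test_overlap_resolved_by_sigma(self, ref_table):
        """Eye-to-chin 100.5 mm falls in the Small/Medium overlap; sigma
        11.2 is too large for any Small profile, so Medium (III) wins."""
        res = sizing.assign((100.5, 11.2), ref_table)
        assert (res.route, res.shell, res.profile) == ("SEMI_CUSTOM", "Medium", "III")
        assert res.in_overlap

    def test_single_shell_single_profile(self, ref_table):
        res = sizing.assign((104.9, 10.2), ref_table)
        assert (res.shell, res.profile) == ("Medium", "II")
        assert not res.in_overlap

    def test_out_of_range_eye_to_chin(self, ref_table):
        res = sizing.assign((80.0, 10.2), ref_table)
        assert res.route == "FULLY_CUSTOM"
        assert res.shell is None and res.profile is None

    def test_sigma_outside_all_profiles(self, ref_table):
        res = sizing.assign((104.9, 14.0), ref_table)
        assert res.route == "FULLY_CUSTOM"

    def test_rationale_is_recorded(self, ref_table):
        res = sizing.assign((100.5, 11.2), ref_table)
        assert any("overlap" in line or "Small" in line for line in res.rationale)
        assert any("Medium" in line for line in res.rationale)

    @given(
        e2c=st.floats(50.0, 150.0),
        sig=st.floats(5.0, 15.0),
    )
    def test_total_on_in_range_numerics(self, ref_table, e2c, sig):
        """assign never raises on finite inputs: every pair maps to a valid
        cell or the fully-custom flag."""
        res = sizing.assign((e2c, sig), ref_table)
        assert res.route in ("SEMI_CUSTOM", "FULLY_CUSTOM")
        if res.route == "SEMI_CUSTOM":
            assert res.shell in sizing.SHELL_LABELS
            assert res.profile in sizing.PROFILE_LABELS

    def test_shell_monotone_in_eye_to_chin(self, ref_table):
        """With sigma fixed at a value valid in every shell, growing faces
        never map to smaller shells."""
        order = {"Small": 0, "Medium": 1, "Large": 2}
        sigma = 10.2  # inside a profile range of each shell
        last = -1
        for e2c in np.linspace(93.0, 116.5, 200):
            res = sizing.assign((e2c, sigma), ref_table)
            assert res.route == "SEMI_CUSTOM"
            assert order[res.shell] >= last
            last = order[res.shell]

    def test_cell_centres_map_to_their_cell(self, ref_table):
        """Each cell's (shell midpoint, profile range centre) assigns back
        to that same cell, for all nine cells."""
        for shell, prof in ref_table.cells():
            res = sizing.assign((shell.midpoint, prof.midpoint), ref_table)
            assert (res.shell, res.profile) == (shell.label, prof.label)


class TestCoverage:
    def test_all_inside(self, ref_table):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "eye_to_chin_mm": [104.9, 104.9],
                "A_mm": [24.0, 24.0],
                "sigma_mm": [10.2, 10.2],
            }
        )
        assert sizing.coverage(df, ref_table) == 1.0

    def test_all_outside(self, ref_table):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "eye_to_chin_mm": [80.0, 85.0],
                "A_mm": [24.0, 24.0],
                "sigma_mm": [10.2, 10.2],
            }
        )
        assert sizing.coverage(df, ref_table) == 0.0

    def test_shell_coverage_matches_gaussian_cdf(self):
        """Eye-to-chin-only coverage of an exact-normal cohort agrees with
        the closed-form normal CDF within 0.5 percentage points."""
        cohort = synthetic.synth_cohort(synthetic.CohortSpec(n=100_000, seed=12))
        table = sizing.build_sizing_table(cohort)
        measured = sizing.coverage(cohort, table, mode="shell")
        fit = sizing.fit_normal(cohort["eye_to_chin_mm"])
        analytic = norm.cdf(table.shells[2].upper, fit.mu, fit.sd) - norm.cdf(
            table.shells[0].lower, fit.mu, fit.sd
        )
        assert abs(measured - analytic) < 0.005

    def test_joint_coverage_bounds(self, default_cohort):
        table = sizing.build_sizing_table(default_cohort)
        joint = sizing.coverage(default_cohort.iloc[:2000], table)
        shell_only = sizing.coverage(default_cohort.iloc[:2000], table, mode="shell")
        central = np.mean(
            (default_cohort["eye_to_chin_mm"].iloc[:2000] > table.shells[1].lower)
            & (default_cohort["eye_to_chin_mm"].iloc[:2000] < table.shells[1].upper)
        )
        assert central <= joint <= shell_only


class TestCompareParamSets:
    @staticmethod
    def _cohort(n, seed=0):
        return synthetic.synth_cohort(synthetic.CohortSpec(n=n, seed=seed))

    def test_identity(self):
        a = self._cohort(50)
        out = sizing.compare_param_sets(a, a.copy())
        for s in out.values():
            assert s.mean_diff == 0.0 and s.sd_diff == 0.0

    def test_constant_shift(self):
        a = self._cohort(50)
        b = a.copy()
        b["eye_to_chin_mm"] += 2.4
        s = sizing.compare_param_sets(a, b)["eye_to_chin_mm"]
        assert s.mean_diff == pytest.approx(2.4)
        assert s.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_noise_sd_recovered(self):
        a = self._cohort(10_000)
        b = a.copy()
        rng = np.random.default_rng(9)
        b["eye_to_chin_mm"] += rng.normal(0.0, 2.9, len(b))
        s = sizing.compare_param_sets(a, b)["eye_to_chin_mm"]
        assert s.sd_diff == pytest.approx(2.9, rel=0.05)

    def test_id_mismatch_rejected(self):
        a = self._cohort(10)
        b = self._cohort(10).assign(subject_id=[f"X{i}" for i in range(10)])
        with pytest.raises(InputError, match="subject_id"):
            sizing.compare_param_sets(a, b)


class TestSerialisation:
    def test_json_round_trip(self, default_cohort, tmp_path):
        table = sizing.build_sizing_table(default_cohort)
        p = table.to_json(tmp_path / "table.json")
        back = sizing.SizingTable.from_json(p)
        assert back.to_dict() == table.to_dict()

    def test_frame_shape(self, ref_table):
        df = ref_table.to_frame()
        assert len(df) == 9
        assert set(df["shell"]) == set(sizing.SHELL_LABELS)
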