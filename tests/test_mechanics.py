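"""Geometry, the worm-like-chain closed form, and persistence-length fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import tubemech as tm
from tubemech.mechanics import MechanicsPoint, PersistenceLengthModel


def wlc_msr_integral(L, lp):
    """Independent oracle: numeric evaluation of the tangent-correlation
    double integral ∫∫ exp(-|s-s'|/(2lp)) over [0,L]², reduced by symmetry
    of the integrand to 2∫(L-u)exp(-u/(2lp))du."""
    val, _ = quad(
        lambda u: 2.0 * (L - u) * np.exp(-u / (2.0 * lp)),
        0.0,
        L,
        epsabs=1e-14,
        epsrel=1e-13,
        limit=200,
    )
    return val


class TestGeometry:
    def test_contour_length_examples(self):
        t = tm.FilamentTrace(0, 0, [(0, 0), (1, 0), (2, 0)])
        assert tm.contour_length(t) == pytest.approx(2.0)
        t = tm.FilamentTrace(0, 0, [(0, 0), (1, 0), (1, 1)])
        assert tm.contour_length(t) == pytest.approx(2.0)

    def test_contour_length_matches_bruteforce_resummation(self, rng):
        nodes = rng.normal(size=(1000, 2))
        t = tm.FilamentTrace(0, 0, nodes)
        brute = sum(
            float(np.hypot(*(nodes[i + 1] - nodes[i]))) for i in range(999)
        )
        assert tm.contour_length(t) == pytest.approx(brute, rel=1e-12)

    def test_end_to_end_examples(self):
        straight = tm.FilamentTrace(0, 0, [(0, 0), (3, 0), (5, 0)])
        assert tm.end_to_end(straight) == pytest.approx(tm.contour_length(straight))
        bent = tm.FilamentTrace(0, 0, [(0, 0), (1, 0), (1, 1)])
        assert tm.end_to_end(bent) == pytest.approx(np.sqrt(2.0))
        loop = tm.FilamentTrace(0, 0, [(0, 0), (1, 0), (1, 1), (0, 0)])
        assert tm.end_to_end(loop) == 0.0

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            tm.FilamentTrace(0, 0, [(0, 0)])


class TestMeanSquareR:
    def test_no_fluctuation_straight_rod(self):
        traces = tuple(
            tm.FilamentTrace(7, f, [(0, 0), (2.5, 0), (5, 0)]) for f in range(3)
        )
        with pytest.warns(UserWarning, match="frames"):
            pt = tm.mean_square_R(tm.TrackStack(7, traces))
        assert pt.L == pytest.approx(5.0)
        assert pt.msR == pytest.approx(25.0)

    def test_two_frame_arithmetic(self):
        # equal contour length 5, end-to-end 3 and 4 respectively
        tri1 = tm.FilamentTrace(0, 0, [(0, 0), (1.5, 2.0), (3, 0)])
        tri2 = tm.FilamentTrace(0, 1, [(0, 0), (2.0, 1.5), (4, 0)])
        assert tm.contour_length(tri1) == pytest.approx(
            tm.contour_length(tri2), rel=1e-12
        )
        with pytest.warns(UserWarning):
            pt = tm.mean_square_R(tm.TrackStack(0, (tri1, tri2)))
        assert pt.msR == pytest.approx((9.0 + 16.0) / 2.0)

    def test_simulated_stack_matches_closed_form_within_3se(self, rng):
        n_frames = 150
        traces = tuple(
            tm.sample_wlc_chain(2.0, 8.0, 0.05, rng, frame=f) for f in range(n_frames)
        )
        pt = tm.mean_square_R(tm.TrackStack(0, traces))
        se = pt.sd_R2 / np.sqrt(n_frames)
        assert abs(pt.msR - tm.wlc_msR(pt.L, 2.0)) < 3.0 * se

    def test_pixel_traces_need_pixel_size(self):
        t = tm.FilamentTrace(0, 0, [(0, 0), (10, 0)], unit="px")
        with pytest.raises(ValueError, match="pixel_size"):
            tm.mean_square_R(tm.TrackStack(0, (t,)))


class TestWlcClosedForm:
    def test_zero_length(self):
        assert tm.wlc_msR(0.0, 3.0) == 0.0

    def test_rigid_rod_limit(self):
        # leading correction to the rod limit is exactly -L/(6 lp)
        L, lp = 0.001, 10.0
        assert tm.wlc_msR(L, lp) == pytest.approx(L**2, rel=2 * L / (6 * lp))
        assert tm.wlc_msR(L, lp) == pytest.approx(L**2 * (1 - L / (6 * lp)), rel=1e-9)

    def test_known_value_8_over_e(self):
        assert tm.wlc_msR(2.0, 1.0) == pytest.approx(8.0 / np.e, rel=1e-12)

    def test_matches_double_integral_oracle_on_grid(self):
        # 20 (L, lp) combinations spanning stiff to floppy
        Ls = [0.5, 2.0, 5.0, 8.0, 15.0]
        lps = [0.5, 2.0, 12.5, 19.7]
        for L in Ls:
            for lp in lps:
                assert tm.wlc_msR(L, lp) == pytest.approx(
                    wlc_msr_integral(L, lp), rel=1e-8
                )

    def test_series_branch_is_continuous_and_accurate(self):
        lp = 7.0
        for L in [1e-8, 1e-6 * lp, 1e-5]:
            assert tm.wlc_msR(L, lp) == pytest.approx(
                L**2 - L**3 / (6 * lp), rel=1e-9
            )

    @given(
        L=st.floats(0.01, 50.0),
        lp=st.floats(0.05, 100.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_bounds_and_monotonicity(self, L, lp):
        v = tm.wlc_msR(L, lp)
        assert 0.0 <= v <= L**2 * (1 + 1e-12)
        assert tm.wlc_msR(L * 1.01, lp) > v
        assert tm.wlc_msR(L, lp * 1.01) > v

    def test_floppy_limit_ratio(self):
        lp = 0.01
        L = 100.0
        assert tm.wlc_msR(L, lp) / (4 * lp * L) == pytest.approx(1.0, rel=1e-3)

    def test_invalid_lp(self):
        with pytest.raises(ValueError):
            tm.wlc_msR(1.0, 0.0)


class TestPersistenceLengthFit:
    def test_noiseless_self_consistency(self):
        L = np.linspace(1.0, 15.0, 20)
        pts = [
            MechanicsPoint(i, float(l), float(tm.wlc_msR(l, 5.0)), 150)
            for i, l in enumerate(L)
        ]
        fit = tm.fit_persistence_length(pts)
        assert fit.converged
        assert fit.lp_hat == pytest.approx(5.0, abs=1e-6)

    def test_identical_lengths_rejected(self):
        pts = [MechanicsPoint(i, 5.0, 20.0, 100) for i in range(5)]
        with pytest.raises(ValueError, match="identical"):
            tm.fit_persistence_length(pts)

    def test_msr_above_L_squared_rejected(self):
        with pytest.raises(ValueError, match="msR"):
            PersistenceLengthModel([2.0, 4.0], [3.0, 17.0])

    def test_beyond_support_flag(self):
        # nearly straight short filaments: Lp far above the data support
        L = np.linspace(1.0, 2.0, 10)
        pts = [
            MechanicsPoint(i, float(l), float(tm.wlc_msR(l, 500.0)), 150)
            for i, l in enumerate(L)
        ]
        fit = tm.fit_persistence_length(pts)
        assert fit.beyond_support

    def test_summary_mentions_estimate(self):
        L = np.linspace(1.0, 10.0, 8)
        fit = PersistenceLengthModel(L, tm.wlc_msR(L, 3.0)).fit()
        assert "3.000" in fit.summary()

    def test_weighted_fit_runs(self, rng):
        L = np.linspace(2.0, 12.0, 15)
        msR = tm.wlc_msR(L, 4.0) * (1 + rng.normal(0, 0.01, L.size))
        model = PersistenceLengthModel(L, msR, weights_sd=np.full(L.size, 0.1))
        fit = model.fit(weighted=True)
        assert fit.converged
        assert fit.lp_hat == pytest.approx(4.0, rel=0.1)

    def test_from_dataframe(self):
        import pandas as pd

        L = np.linspace(1, 10, 10)
        df = pd.DataFrame({"L": L, "msR": tm.wlc_msR(L, 2.0)})
        fit = PersistenceLengthModel.from_dataframe(df).fit()
        assert fit.lp_hat == pytest.approx(2.0, abs=1e-6)


class TestParameterRecovery:
    @pytest.mark.parametrize("lp_true", [2.0, 12.5, 19.7])
    def test_median_recovery_within_10pct(self, lp_true):
        """Over seeded replicates of the study-scale ensemble (55 filaments
        x 150 frames, L in [2, 15] µm) the median relative error of the
        fitted Lp stays within 10%."""
        errors = []
        for rep in range(20):
            cfg = tm.SyntheticConfig.uniform_lengths(
                lp_true, 55, (2.0, 15.0), n_frames=150, ds=0.05, rng_seed=1000 + rep
            )
            stacks = tm.sample_ensemble(cfg)
            fit = PersistenceLengthModel.from_stacks(stacks).fit()
            errors.append(abs(fit.lp_hat - lp_true) / lp_true)
        assert np.median(errors) <= 0.10


class TestTangentCorrelation:
    def test_recovers_lp_within_10pct(self, rng):
        traces = tuple(
            tm.sample_wlc_chain(3.0, 10.0, 0.05, rng, frame=f) for f in range(400)
        )
        est = tm.tangent_correlation_lp([tm.TrackStack(0, (t,)) for t in traces])
        assert not est.lower_bound
        assert est.lp_hat == pytest.approx(3.0, rel=0.10)

    def test_straight_traces_flag_lower_bound(self):
        nodes = np.column_stack([np.linspace(0, 10, 50), np.zeros(50)])
        stacks = [
            tm.TrackStack(i, (tm.FilamentTrace(i, 0, nodes),)) for i in range(3)
        ]
        est = tm.tangent_correlation_lp(stacks)
        assert est.lower_bound

    def test_insufficient_nodes_raise(self):
        t = tm.FilamentTrace(0, 0, [(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError, match="insufficient"):
            tm.tangent_correlation_lp([tm.TrackStack(0, (t,))])

    def test_agrees_with_end_to_end_fit(self):
        cfg = tm.SyntheticConfig.uniform_lengths(
            2.0, 30, (2.0, 10.0), n_frames=100, ds=0.05, rng_seed=5
        )
        stacks = tm.sample_ensemble(cfg)
        wlc = PersistenceLengthModel.from_stacks(stacks).fit()
        tc = tm.tangent_correlation_lp(stacks)
        assert abs(wlc.lp_hat - tc.lp_hat) / wlc.lp_hat < 0.15
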