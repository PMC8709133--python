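import numpy as np
import pytest
from scipy.optimize import brentq

from npdosim import (
    NPExposure,
    ProximityCurve,
    QualityParams,
    TDRAModel,
    dalpha_ratio,
    delta_xi,
    estimate_proximity,
    rbe_tdra,
    relative_yield,
    simulate_exposure,
    solve_a,
    xi_from_lq,
    xi_from_proximity,
    zeta,
)
from npdosim.tdra import DistanceModel
from npdosim.tracks import CascadeModel, EventRecord

from conftest import random_tracks

KEV_PER_GCC_UM3_TO_GY = 1.602176634e-16 / 1e-15


def analytic_exponential_curve(A=100.0, b=0.05, x_max=1.5, n_bins=20_000):
    """Fine-binned t(x) = A e^(-x/b) for closed-form cross-checks."""
    edges = np.linspace(1e-7, x_max, n_bins + 1)
    x = np.sqrt(edges[:-1] * edges[1:])
    return ProximityCurve(bin_edges=edges, t_values=A * np.exp(-x / b))


def xi_closed_form(A, b, a, rho=1.0):
    # integral(A e^-x/b e^-x/a dx) = A*a*b/(a+b); denominator 8 pi a^3 rho
    return A * a * b / (a + b) / (8 * np.pi * a**3 * rho) * KEV_PER_GCC_UM3_TO_GY


def _event(positions, energies):
    positions = np.atleast_2d(np.asarray(positions, float))
    energies = np.asarray(energies, float)
    return EventRecord(
        event_id=0, np_position=np.zeros(3),
        positions=positions, energies=energies,
        nucleus_positions=positions, nucleus_energies=energies,
        energy_kev=float(energies.sum()), z_gy=0.0,
    )


def _empty_event():
    return EventRecord(
        event_id=0, np_position=np.zeros(3),
        positions=np.empty((0, 3)), energies=np.empty(0),
        nucleus_positions=np.empty((0, 3)), nucleus_energies=np.empty(0),
        energy_kev=0.0, z_gy=0.0,
    )


class TestDistanceModel:
    def test_exponential_kernel(self):
        g = DistanceModel(a=0.5)
        assert g(0.0) == 1.0
        assert g(0.5) == pytest.approx(np.exp(-1))

    def test_requires_positive_a(self):
        with pytest.raises(ValueError):
            DistanceModel(a=0.0)


class TestXi:
    @pytest.mark.parametrize(
        "alpha, beta, expected",
        [(0.150, 0.041, 3.659), (0.0, 0.05, 0.0), (0.04, 0.05, 0.8)],
    )
    def test_xi_from_lq(self, alpha, beta, expected):
        assert xi_from_lq(alpha, beta) == pytest.approx(expected, abs=5e-4)

    def test_xi_from_lq_rejects_bad_params(self):
        with pytest.raises(ValueError):
            xi_from_lq(0.1, 0.0)
        with pytest.raises(ValueError):
            xi_from_lq(-0.1, 0.05)

    def test_zero_curve_gives_zero_xi(self):
        c = ProximityCurve(bin_edges=np.array([0.0, 1.0]), t_values=np.array([0.0]))
        assert xi_from_proximity(c, a=0.1) == 0.0

    def test_matches_closed_form_exponential(self):
        A, b, a = 100.0, 0.05, 0.1
        curve = analytic_exponential_curve(A, b)
        assert xi_from_proximity(curve, a) == pytest.approx(
            xi_closed_form(A, b, a), rel=2e-4
        )

    def test_monotone_decreasing_in_a_for_short_range_t(self):
        curve = analytic_exponential_curve()
        a_grid = np.geomspace(0.02, 2.0, 12)
        xi_vals = [xi_from_proximity(curve, a) for a in a_grid]
        assert np.all(np.diff(xi_vals) < 0)

    def test_scaling_energies_scales_xi_linearly(self, rng):
        # multiplying all deposit energies by 10 multiplies t, hence xi, by 10
        (pos, en), = random_tracks(rng, 1, 60)
        c1 = estimate_proximity([(pos, en)])
        c10 = estimate_proximity([(pos, 10 * en)])
        xi1 = xi_from_proximity(c1, 0.1)
        xi10 = xi_from_proximity(c10, 0.1)
        assert xi10 == pytest.approx(10 * xi1, rel=1e-12)


class TestSolveA:
    def test_round_trip_through_xi(self):
        curve = analytic_exponential_curve()
        a_true = 0.122
        xi = xi_from_proximity(curve, a_true)
        assert solve_a(curve, xi) == pytest.approx(a_true, abs=1e-4)

    def test_recovers_closed_form_inversion(self):
        A, b = 100.0, 0.05
        curve = analytic_exponential_curve(A, b)
        target_a = 0.07
        a_est = solve_a(curve, xi_closed_form(A, b, target_a))
        assert a_est == pytest.approx(target_a, rel=1e-3)

    def test_unreachable_target_raises_with_range(self):
        curve = analytic_exponential_curve()
        sup = xi_from_proximity(curve, 1e-3)
        with pytest.raises(ValueError, match="achievable xi"):
            solve_a(curve, sup * 10)


class TestDeltaXi:
    def _exposure(self, n=6000.0):
        return NPExposure(n=n, p1Gy=1.95e-2)

    def test_all_misses_give_zero(self, hela):
        events = [_empty_event() for _ in range(5)]
        assert delta_xi(events, self._exposure(), a=0.1, cell=hela) == 0.0

    def test_hand_built_events_match_hand_value(self, hela):
        # event 1: two 1 keV deposits at distance a -> integral 2 e^-1 keV^2
        # event 2: single deposit -> 0; event 3: miss -> 0
        a = 0.1
        events = [
            _event([[0, 0, 0], [0, 0, a]], [1.0, 1.0]),
            _event([[0, 0, 0]], [4.0]),
            _empty_event(),
        ]
        exp = self._exposure()
        mean_integral = 2 * np.exp(-1) / 3
        expected = (
            exp.n * exp.p1Gy * mean_integral
            / (8 * np.pi * a**3 * hela.rho**2 * hela.v_nucleus)
            * KEV_PER_GCC_UM3_TO_GY**2
        )
        assert delta_xi(events, exp, a, hela) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_np_count(self, hela):
        events = [_event([[0, 0, 0], [0, 0, 0.05]], [1.0, 2.0])]
        d1 = delta_xi(events, self._exposure(6000), 0.1, hela)
        d2 = delta_xi(events, self._exposure(12000), 0.1, hela)
        assert d2 == pytest.approx(2 * d1, rel=1e-14)

    def test_requires_events(self, hela):
        with pytest.raises(ValueError):
            delta_xi([], self._exposure(), 0.1, hela)


class TestZetaDer:
    @pytest.mark.parametrize(
        "n, p1gy, z_bar, der_expected",
        [
            (6.06e8, 5.04e-8, 8.2e-4, 1.025),   # AGuIX in SQ20B, whole cell
            (6000.0, 1.95e-2, 2.6e-3, 1.304),   # AuNP in Hela, membrane
            (6000.0, 1.95e-2, 0.0, 1.0),
        ],
    )
    def test_der_from_printed_inputs(self, n, p1gy, z_bar, der_expected):
        z, der = zeta(NPExposure(n=n, p1Gy=p1gy, z_bar=z_bar))
        assert der == pytest.approx(der_expected, abs=5e-4)
        assert z == pytest.approx(der - 1.0, rel=1e-14)

    def test_e_bar_route_equals_z_bar_route(self, hela):
        e_bar = 8.0
        z_bar = e_bar * 1.602176634e-16 / hela.m_nucleus
        z1, _ = zeta(NPExposure(n=100, p1Gy=1e-3, e_bar=e_bar), hela)
        z2, _ = zeta(NPExposure(n=100, p1Gy=1e-3, z_bar=z_bar))
        assert z1 == pytest.approx(z2, rel=1e-14)


class TestYieldAndRbe:
    def test_relative_yield_examples(self):
        q = QualityParams(xi=xi_from_lq(0.150, 0.041), delta_xi=0.93, zeta=0.234)
        assert relative_yield(0.0, q) == 0.0
        assert relative_yield(2.0, q) == pytest.approx(14.113, abs=1e-3)
        base = QualityParams(xi=3.0)
        assert relative_yield(2.0, base) == pytest.approx(3.0 * 2 + 4)

    def test_rbe_collapses_to_one_without_np_terms(self):
        q = QualityParams(xi=2.5)
        for d in (0.1, 1.0, 2.0, 10.0):
            assert rbe_tdra(q, d) == pytest.approx(1.0, rel=1e-14)

    def test_rbe_printed_quality_values(self):
        q = QualityParams(xi=xi_from_lq(0.150, 0.041), delta_xi=0.93, zeta=0.234)
        assert rbe_tdra(q, 2.0) == pytest.approx(1.175, abs=1e-3)

    def test_rbe_matches_equal_effect_root_oracle(self):
        """Closed form vs brute-force root of xi D + D^2 = yield(D_NP)."""
        for xi in (0.8, 2.33, 3.66, 10.0):
            for dxi in (0.0, 0.5, 2.0):
                for zt in (0.0, 0.1, 0.5):
                    for d_np in (0.5, 2.0, 8.0):
                        q = QualityParams(xi=xi, delta_xi=dxi, zeta=zt)
                        target = relative_yield(d_np, q)
                        root = brentq(
                            lambda d: xi * d + d**2 - target, 0, 1e3,
                            xtol=1e-14, rtol=8.9e-16,
                        )
                        assert rbe_tdra(q, d_np) == pytest.approx(
                            root / d_np, rel=1e-9
                        )

    def test_rbe_increasing_in_xi_prime_and_zeta(self):
        xi, d = 3.659, 2.0
        r = [rbe_tdra(QualityParams(xi=xi, delta_xi=dx), d) for dx in np.linspace(0, 3, 7)]
        assert np.all(np.diff(r) > 0)
        r = [rbe_tdra(QualityParams(xi=xi, zeta=z), d) for z in np.linspace(0, 1, 7)]
        assert np.all(np.diff(r) > 0)

    def test_rbe_requires_positive_dose(self):
        with pytest.raises(ValueError):
            rbe_tdra(QualityParams(xi=1.0), 0.0)

    @pytest.mark.parametrize(
        "dxi, xi, expected",
        [(0.93, 0.150 / 0.041, 0.254), (0.027, 0.8, 0.034), (0.0, 1.0, 0.0)],
    )
    def test_dalpha_ratio_printed_values(self, dxi, xi, expected):
        q = QualityParams(xi=xi, delta_xi=dxi)
        assert dalpha_ratio(q) == pytest.approx(expected, abs=5e-4)
        # identical to delta_xi / xi by construction
        assert dalpha_ratio(q) == q.delta_xi / q.xi


class TestModelObject:
    def test_fit_results_are_internally_consistent(self, hela):
        cascade = CascadeModel()
        rng = np.random.default_rng(77)
        events, spectrum = simulate_exposure("whole_cell", hela, 500, cascade, rng)
        exposure = NPExposure(n=6000, p1Gy=1.95e-2, z_bar=spectrum.z_bar_gy)
        model = TDRAModel(events, exposure, hela, alpha=0.150, beta=0.041, a=0.122)
        res = model.fit(doses=(1.0, 2.0))
        assert res.xi_prime == pytest.approx(res.xi + res.delta_xi, rel=1e-14)
        assert res.der == pytest.approx(1.0 + res.zeta_value, rel=1e-14)
        assert res.dalpha_over_alpha == pytest.approx(res.delta_xi / res.xi, rel=1e-14)
        assert res.rbe[2.0] == pytest.approx(rbe_tdra(res.quality, 2.0), rel=1e-14)
        assert res.rbe[2.0] >= 1.0
        text = res.summary()
        for token in ("xi", "delta_xi", "DER", "RBE at 2 Gy"):
            assert token in text

    def test_requires_quality_and_distance_inputs(self, hela):
        exposure = NPExposure(n=10, p1Gy=1e-3, z_bar=1e-4)
        with pytest.raises(ValueError, match="alpha"):
            TDRAModel([], exposure, hela, a=0.1)
        with pytest.raises(ValueError, match="reference"):
            TDRAModel([], exposure, hela, xi=1.0)
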