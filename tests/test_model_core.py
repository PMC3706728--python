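"""Flux-level unit tests: half-activation points, boundary cases and
hand-derived values for every single-cell flux function."""

import numpy as np
import pytest

import astrowave as aw
from astrowave.params import ModelParams, compute_delta

RTOL = 1e-9


@pytest.fixture(scope="module")
def p():
    return ModelParams()


KD_KA = 0.15 / 0.017  # ≈ 8.8235


class TestExtLeak:
    @pytest.mark.parametrize(
        "C, expected",
        [
            (0.0, 1.0e-4),
            (2000.0, 0.0),
            (0.1, 1.0e-4 * (1 - 0.1 / 2000.0)),  # ≈ 9.995e-5
        ],
    )
    def test_values(self, p, C, expected):
        assert aw.flux_ext_leak(C, p) == pytest.approx(expected, rel=RTOL)

    def test_negative_only_above_bath(self, p):
        assert aw.flux_ext_leak(2500.0, p) < 0
        assert aw.flux_ext_leak(1999.0, p) > 0


class TestPCA:
    def test_zero_at_zero(self, p):
        assert aw.flux_pca(0.0, p) == 0.0

    def test_half_max_of_first_term_at_k1(self, p):
        # at C = k1 the low-activity term is exactly V1/2; the high-
        # activity term adds a small positive contribution
        val = aw.flux_pca(p.k1, p)
        second = p.V2 * p.k1 ** 4.4 / (p.k2 ** 4.4 + p.k1 ** 4.4)
        assert val == pytest.approx(p.V1 / 2 + second, rel=RTOL)
        assert second < 0.05

    def test_hand_computed_value(self, p):
        # independent evaluation at C = 0.1 μM
        c17, c44 = 0.1 ** 1.7, 0.1 ** 4.4
        expected = (1.63 * c17 / (0.08 ** 1.7 + c17)
                    + 31.67 * c44 / (0.38 ** 4.4 + c44))
        assert aw.flux_pca(0.1, p) == pytest.approx(expected, rel=RTOL)
        assert expected == pytest.approx(1.056, rel=1e-3)

    def test_monotone_and_bounded(self, p):
        C = np.linspace(0, 10, 300)
        v = aw.flux_pca(C, p)
        assert np.all(np.diff(v) >= 0)
        assert np.all(v < p.V1 + p.V2)


class TestIP3R:
    def test_closed_gate(self, p):
        assert aw.flux_ip3r(0.5, 0.5, 0.0, 400.0, p) == 0.0
        assert aw.flux_ip3r(0.5, 0.0, 0.7, 400.0, p) == 0.0

    def test_zero_driving_force(self, p):
        assert aw.flux_ip3r(400.0, 0.5, 0.7, 400.0, p) == 0.0

    def test_half_activation_product(self, p):
        # C = k_C and I = k_I each contribute a factor 1/2
        got = aw.flux_ip3r(p.k_C, p.k_I, 0.5, 400.0, p)
        expected = 100.0 * (0.5 * 0.5 * 0.5) ** 3 * (1 - 0.06 / 400.0)
        assert got == pytest.approx(expected, rel=RTOL)
        assert got == pytest.approx(0.195, rel=2e-3)

    def test_reverse_flux_sign(self, p):
        assert aw.flux_ip3r(10.0, 0.5, 0.7, 5.0, p) < 0

    def test_empty_store_error(self, p):
        with pytest.raises(ValueError):
            aw.flux_ip3r(0.1, 0.1, 0.5, 0.0, p)


class TestSERCA:
    @pytest.mark.parametrize(
        "C, expected",
        [(0.0, 0.0), (0.25, 2.9), (0.5, 5.8 * 0.25 / (0.25 + 0.0625))],
    )
    def test_values(self, p, C, expected):
        assert aw.flux_serca(C, p) == pytest.approx(expected, rel=RTOL)

    def test_saturates_below_max(self, p):
        assert aw.flux_serca(1e6, p) < p.j_serca_max


class TestERLeak:
    def test_values(self, p):
        assert aw.flux_er_leak(400.0, 400.0, p) == 0.0
        assert aw.flux_er_leak(0.0, 400.0, p) == pytest.approx(6e-4, rel=RTOL)
        assert aw.flux_er_leak(200.0, 400.0, p) == pytest.approx(3e-4,
                                                                 rel=RTOL)

    def test_empty_store_error(self, p):
        with pytest.raises(ValueError):
            aw.flux_er_leak(0.1, 0.0, p)


class TestHGate:
    @pytest.mark.parametrize(
        "C, h", [(0.0, 1.0), (0.1, 0.5), (0.3, 0.25)]
    )
    def test_fixed_points(self, p, C, h):
        # h* = k_on/(C + k_on) is the nullcline
        assert aw.h_gate_deriv(C, h, p) == pytest.approx(0.0, abs=1e-12)

    def test_nullcline_decreases_with_calcium(self, p):
        C = np.linspace(0, 2, 100)
        hstar = p.k_on / (C + p.k_on)
        assert np.all(np.diff(hstar) < 0)
        assert np.all((hstar > 0) & (hstar <= 1))

    def test_relaxation_direction(self, p):
        assert aw.h_gate_deriv(0.1, 0.9, p) < 0
        assert aw.h_gate_deriv(0.1, 0.1, p) > 0


class TestGProtein:
    def test_atp_zero_and_saturation(self, p):
        d = p.delta
        assert aw.gprotein_atp(0.0, p) == pytest.approx(
            d / (KD_KA + d), rel=RTOL)
        limit = (1 + d) / (KD_KA + d + 1)
        assert aw.gprotein_atp(1e9, p) == pytest.approx(limit, rel=1e-6)

    def test_atp_half_occupancy(self, p):
        d = p.delta
        expected = (0.5 + d) / (KD_KA + d + 0.5)
        assert aw.gprotein_atp(p.k_atp, p) == pytest.approx(expected,
                                                            rel=RTOL)

    def test_atp_monotone(self, p):
        A = np.linspace(0, 200, 500)
        G = aw.gprotein_atp(A, p)
        assert np.all(np.diff(G) > 0)
        assert np.all((G > 0) & (G < 1))

    def test_glu_values(self, p):
        assert aw.gprotein_glu(0.0, p) == 0.0
        assert aw.gprotein_glu(5.0, p) == pytest.approx(0.5 / (KD_KA + 0.5),
                                                        rel=RTOL)
        assert aw.gprotein_glu(5.0, p) == pytest.approx(0.0536, rel=1e-3)
        assert aw.gprotein_glu(1e9, p) == pytest.approx(1 / (KD_KA + 1),
                                                        rel=1e-5)
        assert aw.gprotein_glu(1e9, p) == pytest.approx(0.1018, rel=1e-3)


class TestDelta:
    def test_ratio_one_gives_kd_over_ka(self):
        # k_deg*I0 = r_h/2 makes the ratio term exactly 1
        p = ModelParams(gpcr_area=1.0, I0=0.02 / 2 / 0.8)
        assert p.delta == pytest.approx(KD_KA, rel=RTOL)

    def test_vanishes_with_basal_ip3(self):
        p = ModelParams(gpcr_area=1.0, I0=1e-9)
        assert p.delta == pytest.approx(0.0, abs=1e-6)

    def test_nonphysical_raises(self):
        with pytest.raises(ValueError):
            ModelParams(gpcr_area=1.0, I0=0.05)  # k_deg*I0 > r_h

    def test_self_consistency_with_steady_state(self):
        # with δ from the formula, the zero-stimulus IP3 drift vanishes
        # exactly at I = I0
        p = ModelParams()
        G0 = aw.gprotein_atp(0.0, p)
        assert aw.ip3_drift(p.I0, G0, 0.0, p) == pytest.approx(0.0,
                                                               abs=1e-15)


class TestIP3Drift:
    def test_trivial_zeros(self):
        p = ModelParams(gpcr_area=1.0, I0=0.01)
        assert aw.ip3_drift(0.0, 0.0, 0.0, p) == 0.0
        I_ss = p.r_h * 0.1 / p.k_deg
        assert aw.ip3_drift(I_ss, 0.05, 0.05, p) == pytest.approx(0.0,
                                                                  abs=1e-15)

    def test_tabulated_production_rate(self):
        # with unit receptor area the production term is r_h_star*(G sum)
        p = ModelParams(gpcr_area=1.0, I0=0.01)
        assert aw.ip3_drift(0.0, 0.06, 0.04, p) == pytest.approx(0.002,
                                                                 rel=RTOL)


class TestATPRelease:
    def test_threshold_branch(self, p):
        assert aw.atp_release(0.01, p) == 0.0
        assert aw.atp_release(p.C_min, p) == 0.0

    def test_continuity_at_threshold(self, p):
        eps = 1e-10
        assert aw.atp_release(p.C_min + eps, p) < 1e-8

    def test_hand_value(self, p):
        assert aw.atp_release(0.1, p) == pytest.approx(
            p.j_atp_max * 0.08 / 0.18, rel=RTOL)

    def test_bounded(self, p):
        assert aw.atp_release(1e9, p) < p.j_atp_max


class TestCellDerivs:
    def test_matches_flux_composition(self, p):
        # independent recomposition from the flux functions
        rng = np.random.default_rng(42)
        for _ in range(20):
            s = aw.CellState(C=rng.uniform(0, 2), h=rng.uniform(0, 1),
                             C_ER=rng.uniform(1, 500), I=rng.uniform(0, 0.5))
            A, glu = rng.uniform(0, 50), rng.uniform(0, 30)
            dC, dh, dCER, dI = aw.cell_derivs(s, A, glu, p)
            j_i = aw.flux_ip3r(s.C, s.I, s.h, s.C_ER, p)
            j_s = aw.flux_serca(s.C, p)
            j_l = aw.flux_er_leak(s.C, s.C_ER, p)
            j_p = aw.flux_pca(s.C, p)
            j_e = aw.flux_ext_leak(s.C, p)
            assert dC == pytest.approx(
                p.beta * (j_i - j_s + j_l - j_p + j_e), rel=1e-12)
            assert dCER == pytest.approx(p.R_vol * (j_s - j_i - j_l),
                                         rel=1e-12)
            assert dh == pytest.approx(aw.h_gate_deriv(s.C, s.h, p),
                                       rel=1e-12)
            assert dI == pytest.approx(
                aw.ip3_drift(s.I, aw.gprotein_atp(A, p),
                             aw.gprotein_glu(glu, p), p), rel=1e-12)

    def test_er_exchange_conservation(self, p):
        # β⁻¹ dC/dt + R_vol⁻¹ dCER/dt = j_lext − j_PCA for any state
        rng = np.random.default_rng(7)
        for _ in range(50):
            s = aw.CellState(C=rng.uniform(0, 5), h=rng.uniform(0, 1),
                             C_ER=rng.uniform(0.5, 600), I=rng.uniform(0, 1))
            dC, _, dCER, _ = aw.cell_derivs(s, rng.uniform(0, 30), 0.0, p)
            lhs = dC / p.beta + dCER / p.R_vol
            rhs = aw.flux_ext_leak(s.C, p) - aw.flux_pca(s.C, p)
            assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)


class TestParams:
    def test_table_defaults(self):
        p = ModelParams()
        assert (p.beta, p.C_ext, p.j_ip3r_max) == (0.0244, 2000.0, 100.0)
        assert (p.k_C, p.k_I, p.k_off, p.k_on) == (0.06, 0.02, 0.75, 0.1)
        assert (p.j_serca_max, p.k_serca, p.R_vol) == (5.8, 0.25, 5.4)
        assert (p.k_l_ext, p.k_l_er) == (1.0e-4, 6.0e-4)
        assert (p.k1, p.k2, p.V1, p.V2) == (0.08, 0.38, 1.63, 31.67)
        assert (p.k_deg, p.r_h_star, p.k_atp, p.k_glu) == (0.8, 0.02, 15.0,
                                                           5.0)
        assert (p.k_d, p.k_a) == (0.15, 0.017)
        assert (p.D, p.alpha, p.k_rel, p.C_min, p.sigma) == (150.0, 0.35,
                                                             0.08, 0.02,
                                                             0.02)

    def test_delta_recomputed_on_update(self):
        p = ModelParams()
        q = p.with_updates(I0=p.I0 / 2)
        assert q.delta == pytest.approx(compute_delta(q))
        assert q.delta < p.delta

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(k_on=0.0)
        with pytest.raises(ValueError):
            ModelParams(C_min=3000.0)
        with pytest.raises(ValueError):
            ModelParams(beta=-1.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            ModelParams.from_dict({"beta": 0.02, "bogus": 1.0})
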