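"""Pure flux and derivative functions for the single-cell biochemistry.

Every function here is a total, vectorizable function of concentrations and
a :class:`~astrowave.params.ModelParams`; no integration or spatial logic.
Units: concentrations μM, fluxes μM/s.

The cytosolic calcium balance is

    dC/dt   = β (j_IP3R − j_SERCA + j_lER − j_PCA + j_lext)
    dh/dt   = k_off (k_on − (C + k_on) h)
    dCER/dt = R_vol (j_SERCA − j_IP3R − j_lER)
    dI/dt   = r_h (G*_ATP + G*_glu) − k_deg I   (+ noise, applied by the
                                                 integrator)

where the ER exchange terms appear with opposite signs in the cytosol and
ER equations, so β⁻¹·dC/dt + R_vol⁻¹·dCER/dt = j_lext − j_PCA identically.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams

__all__ = [
    "CellState",
    "flux_ext_leak",
    "flux_pca",
    "flux_ip3r",
    "flux_serca",
    "flux_er_leak",
    "h_gate_deriv",
    "gprotein_atp",
    "gprotein_glu",
    "ip3_drift",
    "atp_release",
    "cell_derivs",
]


from dataclasses import dataclass


@dataclass
class CellState:
    """Per-cell dynamical variables (scalars or aligned arrays)."""

    C: np.ndarray | float      # cytosolic calcium, μM
    h: np.ndarray | float      # IP3R gating variable, in [0, 1]
    C_ER: np.ndarray | float   # ER calcium, μM
    I: np.ndarray | float      # IP3, μM

    def clamp(self) -> "CellState":
        """Project onto the physical domain (used after explicit steps)."""
        return CellState(
            C=np.maximum(self.C, 0.0),
            h=np.clip(self.h, 0.0, 1.0),
            C_ER=np.maximum(self.C_ER, 0.0),
            I=np.maximum(self.I, 0.0),
        )


def flux_ext_leak(C, p: ModelParams):
    """Calcium leak from the extracellular space, k_l_ext (1 − C/C_ext)."""
    return p.k_l_ext * (1.0 - C / p.C_ext)


def flux_pca(C, p: ModelParams):
    """Plasmalemmal Ca-ATPase extrusion: dual Hill terms (n = 1.7 and 4.4)
    describing the basal and excited activity modes of the pump."""
    c17 = np.power(C, 1.7)
    c44 = np.power(C, 4.4)
    return (
        p.V1 * c17 / (p.k1 ** 1.7 + c17)
        + p.V2 * c44 / (p.k2 ** 4.4 + c44)
    )


def flux_ip3r(C, I, h, C_ER, p: ModelParams):
    """IP3 receptor-channel flux out of the ER.

    Co-gated by calcium, IP3 and the slow inactivation gate h; the cube
    reflects the three-subunit gating of the channel.  The sign is set by
    the driving term (1 − C/C_ER).
    """
    C_ER = np.asarray(C_ER, dtype=float) if np.ndim(C_ER) else C_ER
    if np.any(np.asarray(C_ER) <= 0.0):
        raise ValueError("flux_ip3r requires C_ER > 0")
    gate = (C / (C + p.k_C)) * (I / (I + p.k_I)) * h
    return p.j_ip3r_max * gate ** 3 * (1.0 - C / C_ER)


def flux_serca(C, p: ModelParams):
    """SERCA pump re-uptake into the ER (Hill coefficient 2)."""
    c2 = C * C
    return p.j_serca_max * c2 / (c2 + p.k_serca ** 2)


def flux_er_leak(C, C_ER, p: ModelParams):
    """Passive calcium leak across the ER membrane, k_l_ER (1 − C/C_ER)."""
    if np.any(np.asarray(C_ER) <= 0.0):
        raise ValueError("flux_er_leak requires C_ER > 0")
    return p.k_l_er * (1.0 - C / C_ER)


def h_gate_deriv(C, h, p: ModelParams):
    """Kinetics of the IP3R inactivation gate.

    dh/dt = k_off (k_on − (C + k_on) h); the nullcline h* = k_on/(C + k_on)
    decreases with calcium (calcium-dependent inactivation).  The
    integrator adds no noise here; stochasticity enters through the IP3
    equation.
    """
    return p.k_off * (p.k_on - (C + p.k_on) * h)


def gprotein_atp(A_local, p: ModelParams):
    """Steady-state free G-protein activity driven by extracellular ATP.

    ρ_ATP = A/(k_ATP + A) is the P2YR occupancy; δ sets the residual
    activity of unbound receptors so that G* > 0 at A = 0.
    """
    rho = A_local / (p.k_atp + A_local)
    return (rho + p.delta) / (p.kd_over_ka + p.delta + rho)


def gprotein_glu(glu_ext, p: ModelParams):
    """Steady-state free G-protein activity driven by bath glutamate.

    The mGluR occupancy uses a Hill coefficient of 0.7 (negative
    cooperativity of glutamate binding across receptor subunits).
    """
    g = np.power(glu_ext, 0.7)
    rho = g / (p.k_glu ** 0.7 + g)
    return rho / (p.kd_over_ka + rho)


def ip3_drift(I, G_atp, G_glu, p: ModelParams):
    """Deterministic part of dI/dt: PLCβ production minus degradation."""
    return p.r_h * (G_atp + G_glu) - p.k_deg * I


def atp_release(C, p: ModelParams):
    """Calcium-dependent ATP release rate (units of j_atp_max).

    Zero below the threshold C_min (no leak at rest), then a saturating
    Hill-type dependence (C − C_min)/(k_rel + C), continuous at C_min.
    """
    rate = p.j_atp_max * (C - p.C_min) / (p.k_rel + C)
    return np.where(C > p.C_min, rate, 0.0)


def cell_derivs(s: CellState, A_local, glu_ext, p: ModelParams):
    """Deterministic derivatives (dC/dt, dh/dt, dCER/dt, dI/dt-drift).

    Composes the individual flux functions; the ER exchange fluxes enter
    the cytosol and ER balances with opposite signs and are not double
    counted.
    """
    j_ip3r = flux_ip3r(s.C, s.I, s.h, s.C_ER, p)
    j_serca = flux_serca(s.C, p)
    j_ler = flux_er_leak(s.C, s.C_ER, p)
    j_pca = flux_pca(s.C, p)
    j_lext = flux_ext_leak(s.C, p)
    dC = p.beta * (j_ip3r - j_serca + j_ler - j_pca + j_lext)
    dh = h_gate_deriv(s.C, s.h, p)
    dCER = p.R_vol * (j_serca - j_ip3r - j_ler)
    G_atp = gprotein_atp(A_local, p)
    G_glu = gprotein_glu(glu_ext, p)
    dI = ip3_drift(s.I, G_atp, G_glu, p)
    return dC, dh, dCER, dI
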