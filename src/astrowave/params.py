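"""Model parameters for the astrocyte calcium / ATP signaling model.

All concentrations are in μM, times in s, lengths in μm.  The dataclass
holds every kinetic constant of the single-cell biochemistry (extracellular
and ER leaks, PCA/SERCA pumps, IP3R channel, GPCR→IP3 cascade), the ATP
release and extracellular diffusion constants, and the stochastic forcing
amplitude of the IP3 equation.

Two derived quantities are computed at construction time:

``delta``
    the ratio of the activities of ligand-bound and unbound GPCRs.  It is
    pinned by requiring that, with no external ATP or glutamate, the IP3
    production/degradation balance rests exactly at the basal IP3 level
    ``I0`` (see :func:`compute_delta`).  It may be overridden explicitly.
``r_h``
    the effective maximal IP3 production rate of the compartment, in μM/s.
    The literature value of the PLCβ kinetic parameter is tabulated per
    unit membrane area (μM·μm⁻²·s⁻¹); multiplying by an effective receptor
    domain area converts it to the single-compartment rate used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

__all__ = ["ModelParams", "compute_delta"]


def compute_delta(p: "ModelParams") -> float:
    """Activity ratio δ of bound vs. unbound G-protein-coupled receptors.

    δ is fixed by self-consistency of the resting state: with no agonist
    the G-protein activity is δ/(k_d/k_a + δ), so requiring the IP3
    balance  r_h · δ/(k_d/k_a + δ) = k_deg · I0  gives

        δ = (k_d/k_a) · k_deg·I0 / (r_h − k_deg·I0)

    Raises
    ------
    ValueError
        if ``r_h ≤ k_deg·I0`` (the basal IP3 level would require a
        G-protein activity ≥ 1, which is non-physical).
    """
    basal_production = p.k_deg * p.I0
    if not (p.r_h > basal_production > 0.0):
        raise ValueError(
            f"need r_h > k_deg*I0 > 0, got r_h={p.r_h}, k_deg*I0={basal_production}"
        )
    return (p.k_d / p.k_a) * basal_production / (p.r_h - basal_production)


@dataclass
class ModelParams:
    # --- calcium subsystem -------------------------------------------------
    beta: float = 0.0244        # cytosolic buffer ratio (dimensionless)
    k_l_ext: float = 1.0e-4     # μM/s, max leak from extracellular space
    C_ext: float = 2000.0       # μM, extracellular calcium
    j_ip3r_max: float = 100.0   # μM/s, max IP3R channel flux
    k_C: float = 0.06           # μM, calcium activation constant of IP3R
    k_I: float = 0.02           # μM, IP3 activation constant of IP3R
    k_off: float = 0.75         # inactivation rate of IP3R by calcium
    k_on: float = 0.1           # μM, reactivation constant of IP3R
    j_serca_max: float = 5.8    # μM/s, max SERCA pump rate
    k_serca: float = 0.25       # μM, SERCA half-activation calcium
    R_vol: float = 5.4          # cytosol:ER volume ratio
    k_l_er: float = 6.0e-4      # μM/s, ER leak constant
    k1: float = 0.08            # μM, PCA pump low-activity threshold
    k2: float = 0.38            # μM, PCA pump high-activity threshold
    V1: float = 1.63            # μM/s, PCA pump low-activity max rate
    V2: float = 31.67           # μM/s, PCA pump high-activity max rate
    # --- IP3 subsystem -----------------------------------------------------
    k_deg: float = 0.8          # 1/s, IP3 degradation rate
    r_h_star: float = 0.02      # μM·μm⁻²·s⁻¹, areal PLCβ production rate
    gpcr_area: float = 9.0      # μm², effective receptor domain area (calibrated)
    k_atp: float = 15.0         # μM, ATP dissociation constant on P2YR
    k_glu: float = 5.0          # μM, glutamate dissociation constant on mGluR
    k_d: float = 0.15           # 1/s, G-protein deactivation rate
    k_a: float = 0.017          # 1/s, G-protein activation rate
    # --- ATP release and diffusion ----------------------------------------
    D: float = 150.0            # μm²/s, ATP diffusivity
    alpha: float = 0.35         # 1/s, ATP degradation magnitude (decay)
    k_rel: float = 0.08         # μM, calcium for half-maximal ATP release
    C_min: float = 0.02         # μM, calcium threshold for ATP release
    j_atp_max: float = 1.0      # areal release strength (μm²/s); fitted knob
    sigma: float = 0.02         # std-dev of the IP3 white-noise forcing
    # --- derived / calibrated ----------------------------------------------
    I0: float = 0.002           # μM, basal (steady-state) IP3 level (calibrated)
    delta: Optional[float] = None  # GPCR activity ratio; computed if None

    def __post_init__(self) -> None:
        self._validate()
        if self.delta is None:
            self.delta = compute_delta(self)

    # δ must be refreshed whenever I0 or the GPCR constants change; use
    # `with_updates` instead of mutating fields in place.
    def with_updates(self, **changes) -> "ModelParams":
        """Return a copy with ``changes`` applied and δ recomputed.

        Pass ``delta=...`` explicitly to pin δ instead of recomputing it.
        """
        if "delta" not in changes:
            changes["delta"] = None
        return replace(self, **changes)

    @property
    def r_h(self) -> float:
        """Effective compartment IP3 production rate, μM/s."""
        return self.r_h_star * self.gpcr_area

    @property
    def kd_over_ka(self) -> float:
        return self.k_d / self.k_a

    def _validate(self) -> None:
        nonneg = (
            "beta k_l_ext C_ext j_ip3r_max k_C k_I k_off j_serca_max k_serca "
            "R_vol k_l_er k1 k2 V1 V2 k_deg r_h_star gpcr_area k_atp k_glu "
            "k_d k_a D alpha k_rel C_min j_atp_max sigma I0"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        if self.k_on <= 0:
            raise ValueError("k_on must be > 0")
        if not self.C_min < self.C_ext:
            raise ValueError("C_min must be below C_ext")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)
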