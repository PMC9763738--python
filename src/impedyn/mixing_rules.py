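"""Dielectric mixing rules: perfusion-driven permittivity change of brain tissue.

Over the cardiac cycle the intracranial blood volume varies by a fractional
amount f = dv_total/V_tissue (well below 0.1%).  Treating perfused tissue as
a two-phase mixture of bulk tissue and blood, the Lichtenecker power law

    eps_eff = eps_tissue^(1-f) * eps_blood^f

gives, to first order in f,

    d_eps1 = eps_tissue * f * ln(eps_blood/eps_tissue),

which is the dielectric perturbation fed into the case-(ii) formula.  The
classical alternatives (Clausius-Mossotti/Maxwell-Garnett, Rayleigh,
Bruggeman) are provided to quantify how little the choice of rule matters
at these volume fractions.

All complex powers and logarithms use the principal branch; biological
permittivities at ~1 MHz lie in the right half-plane (Re > 0, Im <= 0), so
no branch crossing occurs — this is asserted at call time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em_core import ComplexDielectric

__all__ = [
    "PerfusionModel",
    "lichtenecker_eff",
    "perfusion_delta_eps",
    "maxwell_garnett_eff",
    "clausius_mossotti_eff",
    "rayleigh_eff",
    "bruggeman_eff",
    "rule_family_delta",
    "MIXING_RULES",
]


def _value(eps) -> complex:
    v = eps.value if isinstance(eps, ComplexDielectric) else complex(eps)
    if v.real <= 0:
        raise ValueError(
            "complex permittivity must lie in the right half-plane for "
            f"principal-branch stability, got {v}"
        )
    return v


def lichtenecker_eff(eps_tissue, eps_blood, f: float) -> complex:
    """Lichtenecker (logarithmic) mixture permittivity, principal branch."""
    et, eb = _value(eps_tissue), _value(eps_blood)
    return np.exp((1.0 - f) * np.log(et) + f * np.log(eb))


def maxwell_garnett_eff(eps_tissue, eps_blood, f: float) -> complex:
    """Maxwell-Garnett mixture: dilute spherical blood inclusions in tissue."""
    et, eb = _value(eps_tissue), _value(eps_blood)
    beta = (eb - et) / (eb + 2.0 * et)
    return et * (1.0 + 2.0 * f * beta) / (1.0 - f * beta)


def clausius_mossotti_eff(eps_tissue, eps_blood, f: float) -> complex:
    """Clausius-Mossotti relation; identical mixture formula to Maxwell-Garnett."""
    return maxwell_garnett_eff(eps_tissue, eps_blood, f)


def rayleigh_eff(eps_tissue, eps_blood, f: float) -> complex:
    """Rayleigh's cubic-lattice-of-spheres formula (MG plus an O(f^{10/3}) term)."""
    et, eb = _value(eps_tissue), _value(eps_blood)
    num = 3.0 * f
    den = (eb + 2.0 * et) / (eb - et) - f - 1.65 * (eb - et) / (eb + 4.0 / 3.0 * et) * f ** (10.0 / 3.0)
    return et * (1.0 + num / den)


def bruggeman_eff(eps_tissue, eps_blood, f: float) -> complex:
    """Symmetric Bruggeman effective medium; root continuous from eps_tissue at f=0."""
    et, eb = _value(eps_tissue), _value(eps_blood)
    # (1-f)(et - e)/(et + 2e) + f(eb - e)/(eb + 2e) = 0  ->  quadratic in e
    b = (2.0 - 3.0 * f) * et + (3.0 * f - 1.0) * eb
    roots = np.roots([-2.0, b, et * eb])
    # pick the physical root: closest to the dilute-limit MG estimate
    guess = maxwell_garnett_eff(et, eb, f)
    return complex(roots[np.argmin(np.abs(roots - guess))])


MIXING_RULES = {
    "lichtenecker": lichtenecker_eff,
    "maxwell_garnett": maxwell_garnett_eff,
    "clausius_mossotti": clausius_mossotti_eff,
    "rayleigh": rayleigh_eff,
    "bruggeman": bruggeman_eff,
}


@dataclass
class PerfusionModel:
    """Blood-volume-driven dielectric change of a tissue compartment.

    f = dv_total/v_tissue is the fractional blood volume change; ``d_eps1``
    is the linearised Lichtenecker permittivity change used by the
    perturbation formulas.
    """

    eps_tissue: ComplexDielectric
    eps_blood: ComplexDielectric
    dv_total: float
    v_tissue: float

    def __post_init__(self):
        if self.v_tissue <= 0:
            raise ValueError("v_tissue must be positive")
        if abs(self.f) >= 1:
            raise ValueError(f"|f| must be < 1, got {self.f}")

    @property
    def f(self) -> float:
        return self.dv_total / self.v_tissue

    @property
    def d_eps1(self) -> complex:
        return perfusion_delta_eps(self)


def perfusion_delta_eps(model: PerfusionModel) -> complex:
    """Linearised Lichtenecker permittivity change, eps_t * f * ln(eps_b/eps_t)."""
    et, eb = _value(model.eps_tissue), _value(model.eps_blood)
    if model.f == 0:
        return 0j
    return et * model.f * np.log(eb / et)


def rule_family_delta(eps_tissue, eps_blood, f: float) -> dict:
    """d_eps under every implemented mixing rule, plus the spread across rules.

    Returns ``{"delta": {rule: d_eps}, "spread": (max|d|-min|d|)/|mean d|}``;
    the spread is 0 when f == 0.
    """
    deltas = {
        name: rule(eps_tissue, eps_blood, f) - _value(eps_tissue)
        for name, rule in MIXING_RULES.items()
    }
    mags = np.array([abs(v) for v in deltas.values()])
    mean = np.mean([v for v in deltas.values()])
    spread = float((mags.max() - mags.min()) / abs(mean)) if mean != 0 else 0.0
    return {"delta": deltas, "spread": spread}
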