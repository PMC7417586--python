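"""Linear viscoelastic material models for creep compliance.

Two creep-compliance models are supported:

* weak power law, ``J(t) = J0 * (t / t0) ** beta`` — the exponent ``beta``
  (the "fluidity") interpolates between a purely elastic solid (beta = 0)
  and a purely viscous fluid (beta = 1); ``J0`` is the compliance at the
  reference time ``t0`` (fixed at 1 s), so ``1 / J0`` is the stiffness in Pa.
* Kelvin–Voigt, ``J(t) = J0 * (1 - exp(-t / tau))`` — a spring and dashpot
  in parallel with relaxation time ``tau`` (viscosity over elastic modulus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MaterialModel", "power_law_compliance", "kelvin_voigt_compliance"]


def power_law_compliance(t, J0: float, beta: float, t0: float = 1.0):
    """Evaluate J(t) = J0 (t/t0)^beta, zero for t < 0.

    At t = 0 the value is J0 for beta = 0 (elastic step response) and 0 for
    beta > 0.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    nonneg = t >= 0
    with np.errstate(divide="ignore"):
        out[nonneg] = J0 * np.power(t[nonneg] / t0, beta)
    return out if out.ndim else float(out)


def kelvin_voigt_compliance(t, J0: float, tau: float):
    """Evaluate J(t) = J0 (1 - exp(-t/tau)), zero for t < 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    nonneg = t >= 0
    out[nonneg] = J0 * (1.0 - np.exp(-t[nonneg] / tau))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MaterialModel:
    """A creep-compliance model with its parameters.

    Parameters
    ----------
    kind:
        ``"power_law"`` or ``"kelvin_voigt"``.
    J0:
        Compliance prefactor in 1/Pa (> 0).  Its reciprocal is the stiffness.
    beta:
        Power-law exponent (fluidity), required for ``power_law``; must lie
        in [0, 1].
    tau:
        Relaxation time in s, required for ``kelvin_voigt``; must be > 0.
    t0:
        Reference time in s for the power law, 1 s by convention.
    """

    kind: str
    J0: float
    beta: float | None = None
    tau: float | None = None
    t0: float = 1.0

    def __post_init__(self):
        if self.kind not in ("power_law", "kelvin_voigt"):
            raise ValueError(f"unknown material kind {self.kind!r}")
        if not self.J0 > 0:
            raise ValueError("J0 must be positive")
        if not self.t0 > 0:
            raise ValueError("t0 must be positive")
        if self.kind == "power_law":
            if self.beta is None:
                raise ValueError("power_law requires beta")
            if not 0.0 <= self.beta <= 1.0:
                raise ValueError("beta must lie in [0, 1]")
        else:
            if self.tau is None or not self.tau > 0:
                raise ValueError("kelvin_voigt requires tau > 0")

    @property
    def stiffness_pa(self) -> float:
        """Reciprocal of the compliance prefactor, 1/J0, in Pa."""
        return 1.0 / self.J0

    def compliance(self, t):
        """Creep compliance J(t) in 1/Pa; zero before the stress step (t < 0)."""
        if self.kind == "power_law":
            return power_law_compliance(t, self.J0, self.beta, self.t0)
        return kelvin_voigt_compliance(t, self.J0, self.tau)

    def __call__(self, t):
        return self.compliance(t)
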