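"""Parameter containers for the neural mass and hemodynamic forward models.

The neural model is the reduced Wong-Wang excitatory/inhibitory mean field:
each region holds one excitatory (NMDA) and one inhibitory (GABA) population
described by synaptic gating variables. Defaults follow the standard
parameterization of this model family; the handful of knobs that are tuned
per subject (global coupling G) or per region (inhibitory weight J_i) are
exposed separately by the fitting modules.

Units: currents nA, rates Hz, time constants ms, conduction velocity m/s,
tract lengths mm (so lag_ms = D_ij / velocity), integration step dt ms.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Any, Mapping

__all__ = ["DMFParams", "HemodynamicParams"]


@dataclass(frozen=True)
class DMFParams:
    """Reduced Wong-Wang mean field parameters.

    Attributes
    ----------
    G : global coupling, scales all long-range excitatory connections.
    w_plus : recurrent excitatory potential w+.
    J_NMDA : local excitatory coupling, nA.
    sigma : additive noise amplitude on both gating equations.
    velocity : conduction velocity, m/s; with tract lengths in mm the
        inter-region lag is D_ij / velocity milliseconds.
    I0 : overall effective external current, nA; scaled by W_E (excitatory
        pool) and W_I (inhibitory pool).
    a_E, b_E, d_E : excitatory transfer-function constants (1/nC, Hz, s).
    a_I, b_I, d_I : inhibitory transfer-function constants.
    tau_E, tau_I : synaptic time constants, ms.
    gamma : kinetic rate scaling of excitatory gating (dimensionless; the
        Hz -> 1/ms conversion of the firing rates is applied explicitly in
        the integrator).
    dt : integration step, ms.
    """

    G: float = 1.4
    w_plus: float = 1.4
    J_NMDA: float = 0.15
    sigma: float = 0.001
    velocity: float = 6.0
    I0: float = 0.382
    W_E: float = 1.0
    W_I: float = 0.7
    a_E: float = 310.0
    b_E: float = 125.0
    d_E: float = 0.16
    a_I: float = 615.0
    b_I: float = 177.0
    d_I: float = 0.087
    tau_E: float = 100.0
    tau_I: float = 10.0
    gamma: float = 0.641
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.d_E <= 0 or self.d_I <= 0:
            raise ValueError("transfer-function d constants must be positive")
        if self.velocity <= 0:
            raise ValueError("conduction velocity must be positive")
        if self.G < 0 or self.sigma < 0:
            raise ValueError("G and sigma must be nonnegative")

    def with_(self, **kwargs: Any) -> "DMFParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DMFParams":
        return cls(**dict(d))


@dataclass(frozen=True)
class HemodynamicParams:
    """Balloon-Windkessel hemodynamic constants (Friston-style defaults).

    kappa : vasodilatory signal decay rate, 1/s.
    gamma_f : flow-dependent elimination rate, 1/s.
    tau0 : hemodynamic transit time, s.
    alpha : Grubb vessel stiffness exponent.
    E0 : resting oxygen extraction fraction.
    V0 : resting venous blood volume fraction.
    k1, k2, k3 : BOLD observation coefficients.
    """

    kappa: float = 0.65
    gamma_f: float = 0.41
    tau0: float = 0.98
    alpha: float = 0.32
    E0: float = 0.34
    V0: float = 0.02
    k1: float = 7 * 0.34
    k2: float = 2.0
    k3: float = 2 * 0.34 - 0.2

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma_f", "tau0", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.E0 < 1:
            raise ValueError("E0 must lie in (0, 1)")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)
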