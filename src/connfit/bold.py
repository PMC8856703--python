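"""Balloon-Windkessel hemodynamics: synaptic gating to BOLD time series.

Per region, excitatory synaptic gating drives a four-state hemodynamic
cascade (vasodilatory signal s, blood inflow f, venous volume v,
deoxyhemoglobin content q):

    ds/dt = z - kappa*s - gamma_f*(f - 1)
    df/dt = s
    tau0 * dv/dt = f - v^(1/alpha)
    tau0 * dq/dt = f * (1 - (1 - E0)^(1/f)) / E0 - v^(1/alpha) * q / v

with drive z = S^(E) (unit gain). The BOLD observation is

    y = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v)).

The ODE is integrated with explicit Euler at the neural sample interval and
read out by point sampling at multiples of the scanner TR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from numba import njit

from .params import HemodynamicParams
from .simulate import IntegrationDivergedError, NeuralTrajectory

__all__ = [
    "BoldSeries",
    "bold_from_activity",
    "remove_transient",
    "read_bold",
    "write_bold",
]


@dataclass
class BoldSeries:
    """Regions x volumes BOLD array (arbitrary units) sampled every ``tr`` s.

    ``t0`` is the time of the sample preceding the first retained volume
    (0 before transient removal); volume k sits at t0 + (k+1)*tr.
    """

    values: np.ndarray
    tr: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a regions x time matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD series contains non-finite entries")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Covered duration in seconds."""
        return self.n_volumes * self.tr


@njit(cache=True)
def _balloon_kernel(z, dt_s, kappa, gamma_f, tau0, alpha, E0, V0, k1, k2, k3, out, tr_steps):
    n, T = z.shape
    inv_alpha = 1.0 / alpha
    for i in range(n):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        rec = 0
        for t in range(T):
            ds = z[i, t] - kappa * s - gamma_f * (f - 1.0)
            df = s
            fv = v**inv_alpha
            dv = (f - fv) / tau0
            dq = (f * (1.0 - (1.0 - E0) ** (1.0 / f)) / E0 - fv * q / v) / tau0
            s += dt_s * ds
            f += dt_s * df
            v += dt_s * dv
            q += dt_s * dq
            if not (np.isfinite(s) and np.isfinite(f) and np.isfinite(v) and np.isfinite(q)):
                return i, t
            if (t + 1) % tr_steps == 0 and rec < out.shape[1]:
                out[i, rec] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
                rec += 1
    return -1, -1


def bold_steady_state(z: float, hemo: HemodynamicParams) -> float:
    """Closed-form BOLD level for a constant drive ``z``.

    At equilibrium s = 0, f = 1 + z/gamma_f, v = f^alpha and
    q = f^alpha * E(f)/E0 with E(f) = 1 - (1 - E0)^(1/f).
    """
    f = 1.0 + z / hemo.gamma_f
    v = f**hemo.alpha
    q = v * (1.0 - (1.0 - hemo.E0) ** (1.0 / f)) / hemo.E0
    return hemo.V0 * (
        hemo.k1 * (1 - q) + hemo.k2 * (1 - q / v) + hemo.k3 * (1 - v)
    )


def bold_from_activity(
    trajectory: NeuralTrajectory,
    hemo: HemodynamicParams | None = None,
    tr: float = 2.0,
) -> BoldSeries:
    """Generate BOLD from an excitatory-gating trajectory.

    ``trajectory.sample_interval`` must be at most 10 ms for explicit-Euler
    stability of the hemodynamic ODE. Volumes are point samples at
    t = tr, 2*tr, ... up to the trajectory duration.
    """
    if hemo is None:
        hemo = HemodynamicParams()
    si_ms = trajectory.sample_interval
    if si_ms > 10.0 + 1e-9:
        raise ValueError(
            f"sample interval {si_ms} ms too coarse for the hemodynamic ODE "
            "(needs <= 10 ms)"
        )
    dt_s = si_ms / 1000.0
    tr_steps = int(round(tr / dt_s))
    if tr_steps < 1 or abs(tr_steps * dt_s - tr) > 1e-9:
        raise ValueError("tr must be a multiple of the neural sample interval")
    n, T = trajectory.S_E.shape
    n_vol = T // tr_steps
    if n_vol < 1:
        raise ValueError("trajectory shorter than one TR")
    out = np.empty((n, n_vol))
    bad_region, bad_step = _balloon_kernel(
        np.ascontiguousarray(trajectory.S_E),
        dt_s,
        hemo.kappa,
        hemo.gamma_f,
        hemo.tau0,
        hemo.alpha,
        hemo.E0,
        hemo.V0,
        hemo.k1,
        hemo.k2,
        hemo.k3,
        out,
        tr_steps,
    )
    if bad_region >= 0:
        raise IntegrationDivergedError(
            bad_step,
            f"hemodynamic state non-finite in region {bad_region} "
            f"at step {bad_step}",
        )
    return BoldSeries(values=out, tr=tr, t0=0.0)


def remove_transient(series: BoldSeries, cut: float) -> BoldSeries:
    """Drop the first floor(cut/tr) volumes to discard initial transients."""
    if cut < 0:
        raise ValueError("cut must be nonnegative")
    if cut >= series.duration:
        raise ValueError(
            f"cut of {cut} s not shorter than the {series.duration} s series"
        )
    drop = int(np.floor(cut / series.tr))
    return replace(
        series, values=series.values[:, drop:], t0=series.t0 + drop * series.tr
    )


def write_bold(series: BoldSeries, path: str | Path) -> None:
    """Write regions x time values as tab-delimited text; TR on a comment line."""
    path = Path(path)
    header = f"tr_s={series.tr} t0_s={series.t0}"
    np.savetxt(path, series.values, fmt="%.10g", delimiter="\t", header=header)


def read_bold(path: str | Path, tr: float | None = None) -> BoldSeries:
    """Read a regions x time delimited-text BOLD file.

    TR is taken from a ``# tr_s=...`` comment header if present, else from
    the ``tr`` argument.
    """
    path = Path(path)
    t0 = 0.0
    with open(path) as f:
        first = f.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if tok.startswith("tr_s="):
                tr = float(tok.split("=", 1)[1])
            elif tok.startswith("t0_s="):
                t0 = float(tok.split("=", 1)[1])
    if tr is None:
        raise ValueError("TR not found in file header; pass tr explicitly")
    values = np.loadtxt(path, ndmin=2)
    return BoldSeries(values=values, tr=tr, t0=t0)
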