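"""Plug-flow voxel model of the catheter contents.

The catheter internal volume is divided into N voxels of length
gamma = L/N, indexed k = 0 at the tip P up to k = N at the mixing point M.
Each voxel holds a simplex-constrained vector of fluid fractions.  Under
plug flow the contents advance with the cumulative displacement

    lambda_tot(t) = (L / V_cath) * integral_0^t u_cath(t') dt'

so the catheter is a FIFO memory: what enters at M leaves at P one full
displacement L later.  This module provides the displacement curve, delay
times, the push-out flow level, an explicit advection operator for
concentration series, and the entry-deviation sequence a_k^diff that feeds
the Poiseuille stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import CatheterSpec
from .network import FlowTrace

__all__ = [
    "ConcentrationSeries",
    "DisplacementCurve",
    "EntrySequence",
    "displacement",
    "delay_time",
    "poiseuille_tip_delay",
    "pushout_flow",
    "advect",
    "entry_sequence",
    "truncation_horizon",
]


class HorizonError(ValueError):
    """Flow trace does not cover the needed time horizon."""


@dataclass
class ConcentrationSeries:
    """Per-voxel fluid-fraction vectors along the catheter.

    ``fractions`` has shape (N+1, n_fluids); row k is voxel k with k = 0 at
    the tip P and k = N at the mixing point M.  Every row sums to one with
    entries in [0, 1].
    """

    fractions: np.ndarray
    fluids: tuple[str, ...]

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 2 or self.fractions.shape[1] != len(self.fluids):
            raise ValueError("fractions must be (n_voxels+1, n_fluids)")
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        f = self.fractions
        if np.any(f < -atol) or np.any(f > 1 + atol):
            raise ValueError("fractions outside [0, 1]")
        if np.any(np.abs(f.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("voxel fractions must sum to 1")

    @classmethod
    def uniform(cls, n_voxels: int, fractions: dict[str, float]) -> "ConcentrationSeries":
        fluids = tuple(fractions)
        row = np.array([fractions[f] for f in fluids])
        return cls(np.tile(row, (n_voxels + 1, 1)), fluids)


@dataclass
class DisplacementCurve:
    """Cumulative travel distance lambda_tot(t) scaled to catheter length."""

    times: np.ndarray
    lambda_tot: np.ndarray

    def __call__(self, t):
        return np.interp(t, self.times, self.lambda_tot)

    def time_at(self, lam):
        """Inverse: earliest time at which the displacement reaches *lam*."""
        if np.any(np.asarray(lam) > self.lambda_tot[-1]):
            raise HorizonError("displacement horizon too short for requested distance")
        return np.interp(lam, self.lambda_tot, self.times)


def displacement(flow: FlowTrace, catheter: CatheterSpec) -> DisplacementCurve:
    """Trapezoidal cumulative integral of u_cath scaled by L/V_cath."""
    lam = (catheter.length / catheter.volume) * _cumtrapz(flow.u_cath, flow.times)
    return DisplacementCurve(times=flow.times, lambda_tot=lam)


def _cumtrapz(y, x):
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x), out=out[1:])
    return out


def delay_time(flow: FlowTrace, catheter: CatheterSpec) -> float:
    """Smallest t with integral_0^t u_cath = V_cath.

    Found by monotone root bracketing on the cumulative volume.  Reduces to
    V_cath / u_cath for constant flow.
    """
    t = flow.times
    vol = _cumtrapz(flow.u_cath, t)
    if vol[-1] < catheter.volume:
        raise HorizonError(
            f"insufficient horizon: cumulative volume {vol[-1]:.4g} ml "
            f"< V_cath {catheter.volume:.4g} ml"
        )
    idx = int(np.searchsorted(vol, catheter.volume))
    if idx == 0:
        return float(t[0])
    lo, hi = t[idx - 1], t[idx]
    f = lambda tt: np.interp(tt, t, vol) - catheter.volume
    if f(lo) == 0.0:
        return float(lo)
    return float(brentq(f, lo, hi, xtol=1e-12 * max(1.0, hi)))


def poiseuille_tip_delay(t_delay: float) -> float:
    """First-arrival time under the parabolic profile: t_delay / 2.

    The centerline velocity of laminar tube flow is twice the average
    velocity, so the tip of the parabolic front reaches P after half the
    plug-flow delay time.
    """
    if t_delay < 0:
        raise ValueError("negative delay time")
    return 0.5 * t_delay


def pushout_flow(u_unchanged: float, u_old_other: float, u_final_other: float) -> float:
    """Constant push-out deviation of the unchanged fluid (ml/s).

    When the other pump's rate changes from u_old to u_final, the old
    mixture stored in the catheter is expelled at the new total rate, so
    the unchanged fluid temporarily deviates by

        beta_pushout = u_unchanged * (u_final_other - u_old_other)
                       / (u_old_other + u_unchanged)

    valid on 0 < t < t_delay_pois.
    """
    denom = u_old_other + u_unchanged
    if denom <= 0:
        raise ValueError("old total flow must be positive")
    return u_unchanged * (u_final_other - u_old_other) / denom


def advect(
    series: ConcentrationSeries,
    entry_fractions: dict[str, float],
    d_lambda: float,
    gamma: float,
):
    """Shift the catheter contents toward the tip by d_lambda.

    Contents move d_lambda/gamma voxel indices toward P (integer shift plus
    linear fractional carry); vacated voxels at M are filled with
    ``entry_fractions``.  Returns ``(new_series, emitted)`` where *emitted*
    is the volume-averaged fraction vector of the material pushed past the
    tip (volume d_lambda/gamma voxel volumes).

    Raises if d_lambda exceeds one catheter length in a single step.
    """
    if d_lambda < 0:
        raise ValueError("negative displacement step")
    f = series.fractions
    n_cells = f.shape[0]  # voxels k = 0..N as finite-volume cells
    shift = d_lambda / gamma
    if shift > n_cells - 1:
        raise ValueError("displacement step larger than the catheter; split the step")
    if shift == 0.0:
        return ConcentrationSeries(f.copy(), series.fluids), f[0].copy()

    entry = np.array([entry_fractions[fl] for fl in series.fluids], dtype=float)
    # finite-volume shift of a piecewise-constant profile: cell k spans
    # [k, k+1) in index space with the tip at 0; the extended profile has
    # entry fluid beyond the mixing point.  New cell k averages the old
    # profile over [k+shift, k+1+shift): exactly mass-conserving.
    F = np.zeros((n_cells + 1, f.shape[1]))  # cumulative integral at cell edges
    np.cumsum(f, axis=0, out=F[1:])
    edges = np.arange(n_cells + 1, dtype=float)

    def cum_at(pos):
        """Cumulative integral of the extended profile at positions *pos*."""
        pos = np.atleast_1d(np.asarray(pos, dtype=float))
        inside = np.clip(pos, 0.0, n_cells)
        base = np.empty((len(pos), f.shape[1]))
        for j in range(f.shape[1]):
            base[:, j] = np.interp(inside, edges, F[:, j])
        over = np.clip(pos - n_cells, 0.0, None)
        return base + np.outer(over, entry)

    lo = cum_at(edges[:-1] + shift)
    hi = cum_at(edges[1:] + shift)
    new = hi - lo
    emitted = cum_at([shift])[0] / shift
    emitted = np.clip(emitted, 0.0, 1.0)
    new = np.clip(new, 0.0, 1.0)
    return ConcentrationSeries(new, series.fluids), emitted


@dataclass
class EntrySequence:
    """Entering deviation fractions resampled onto the entry-voxel index.

    ``a_diff[j]`` is the deviation fraction u_M_diff/u_cath of the monitored
    fluid in the voxel that entered the catheter when the cumulative
    displacement equalled gamma*j.  ``dt_per_index`` maps one index step to
    tip time using the settled total rate:  dt = gamma V_cath / (L u_final).
    """

    a_diff: np.ndarray
    gamma: float
    length: float
    volume: float
    u_final: float

    @property
    def dt_per_index(self) -> float:
        return self.gamma * self.volume / (self.length * self.u_final)

    @property
    def volume_per_index(self) -> float:
        """Fluid volume represented by one index: gamma V_cath / L (ml)."""
        return self.gamma * self.volume / self.length

    def zeroth_volume(self) -> float:
        """Sum of the sequence scaled to ml; equals the dosing-error volume Q."""
        return float(self.a_diff.sum() * self.volume_per_index)

    def to_dataframe(self) -> pd.DataFrame:
        j = np.arange(len(self.a_diff))
        return pd.DataFrame(
            {"k": j, "tau_s": j * self.dt_per_index, "a_diff": self.a_diff}
        )


def entry_sequence(
    flow: FlowTrace,
    catheter: CatheterSpec,
    u_final: float,
    monitored: str | None = None,
    horizon: float | None = None,
) -> EntrySequence:
    """Resample the monitored deviation onto the entry-voxel index.

    The voxel that entered at time t carries fraction u_M_diff(t)/u_cath(t);
    its index is lambda_tot(t)/gamma.  The time-domain counterpart of the
    z-domain displacement rule z^(-lambda/gamma).
    """
    if monitored is None:
        monitored = list(flow.u_M_diff)[-1]
    t = flow.times
    if horizon is None:
        horizon = t[-1]
    if horizon > t[-1] + 1e-12:
        raise HorizonError("flow trace shorter than requested truncation horizon")
    curve = displacement(flow, catheter)
    lam_max = curve(horizon)
    n_idx = int(np.floor(lam_max / catheter.gamma))
    lam_grid = np.arange(n_idx + 1) * catheter.gamma
    t_entry = curve.time_at(lam_grid)
    ratio = flow.u_M_diff[monitored] / flow.u_cath
    a = np.interp(t_entry, t, ratio)
    return EntrySequence(
        a_diff=a,
        gamma=catheter.gamma,
        length=catheter.length,
        volume=catheter.volume,
        u_final=u_final,
    )


def truncation_horizon(theta_second: float, volume: float, u_final: float) -> float:
    """Default horizon for semi-infinite integrals/sums.

    max(10 theta_second, 3 V_cath/u_final): the two-exponential tail is
    below e^-10 and three full catheter turnovers have passed.
    """
    return max(10.0 * theta_second, 3.0 * volume / u_final)
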