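"""Electric-analog (RC network) model of the infusion set-up.

Each pump branch is a flow source in parallel with the syringe compliance
``C_i`` (a capacitor holding the branch pressure ``p_i``), feeding through
the line resistance ``R_i`` into the common mixing point M; from M the
catheter resistance ``R_cath`` drains to the venous reference pressure
(taken as zero — only pressure differences drive flows).

Two routes are provided:

* closed forms for the canonical two-pump rate-step scenario — the Laplace
  transfer function, the two-exponential time transient with its time
  constants, the dosing-error volume ``Q = C2 R_cath u_downstep`` and the
  syringe-exchange error; and
* :func:`state_space_simulate`, a general linear state-space engine for any
  number of channels, arbitrary piecewise-constant schedules and line
  clamps, integrated segment-wise with a stiff solver.  It shares no
  algebra with the closed forms and serves as their independent check.

Sign convention: ``downstep > 0`` denotes a *decrease* of the changed
(green) pump's rate; the resulting excess outflow of the unchanged (red)
syringe is then positive, as is ``Q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import InfusionSetup, ConfigError

__all__ = [
    "TransientFlow",
    "FlowTrace",
    "laplace_transfer_two_pump",
    "transient_flow",
    "dosing_error_volume",
    "syringe_exchange_error",
    "state_space_simulate",
    "analytic_flow_trace",
    "final_total_rate",
]


class NetworkError(ValueError):
    pass


def _two_pump_coeffs(setup: InfusionSetup) -> tuple[float, float, float]:
    """Quadratic coefficients a, b, c of the characteristic polynomial.

    a = R_cath R1 + R_cath R2 + R1 R2   [resistance^2]
    b = C1 (R_cath + R1) + C2 (R_cath + R2)   [time]
    c = C1 C2   [compliance^2]

    Channel 0 is the changed (green) branch, channel 1 the monitored
    unchanged (red) branch.
    """
    if len(setup.channels) != 2:
        raise NetworkError(
            "closed forms cover exactly two channels; "
            "use state_space_simulate for general set-ups"
        )
    g, r = setup.channels
    rc = setup.catheter.resistance
    a = rc * g.resistance + rc * r.resistance + g.resistance * r.resistance
    b = g.compliance * (rc + g.resistance) + r.compliance * (rc + r.resistance)
    c = g.compliance * r.compliance
    return a, b, c


@dataclass(frozen=True)
class TransientFlow:
    """Two-exponential mixing-point flow deviation of the unchanged syringe.

    u_M_diff(t) = (exp(-t/theta_second) - exp(-t/theta_first))
                  * amplitude_factor / discriminant_root,  t >= 0

    with amplitude_factor = u_downstep * R_cath * C2 (units ml) and
    discriminant_root = sqrt(b^2 - 4ac) (units s).  theta_first <=
    theta_second are the network's relaxation times (Vieta:
    theta_first * theta_second = a*c, theta_first + theta_second = b).
    """

    amplitude_factor: float
    theta_first: float
    theta_second: float
    discriminant_root: float
    coeff_a: float
    coeff_b: float
    coeff_c: float

    def u_diff(self, t):
        """Evaluate the deviation flow (ml/s) at time(s) *t* (0 for t < 0)."""
        t = np.asarray(t, dtype=float)
        if self.amplitude_factor == 0.0 or self.discriminant_root == 0.0:
            return np.zeros_like(t)
        with np.errstate(over="ignore", divide="ignore"):
            e2 = np.exp(-t / self.theta_second) if self.theta_second > 0 else (t == 0.0) * 1.0
            e1 = np.exp(-t / self.theta_first) if self.theta_first > 0 else (t == 0.0) * 1.0
        out = (e2 - e1) * self.amplitude_factor / self.discriminant_root
        return np.where(t < 0, 0.0, out)

    def peak_time(self) -> float:
        """Time of the deviation maximum: ln(th2/th1) * th1 th2 / (th2 - th1)."""
        t1, t2 = self.theta_first, self.theta_second
        if t2 == t1:
            return t1
        return math.log(t2 / t1) * t1 * t2 / (t2 - t1)

    def integral(self, T: float | None = None) -> float:
        """Time integral of the deviation over [0, T] (T=None: to infinity)."""
        t1, t2, s = self.theta_first, self.theta_second, self.discriminant_root
        if self.amplitude_factor == 0.0 or s == 0.0:
            return 0.0
        if T is None:
            return (t2 - t1) * self.amplitude_factor / s
        part = t2 * (1.0 - math.exp(-T / t2)) if t2 > 0 else 0.0
        part -= t1 * (1.0 - math.exp(-T / t1)) if t1 > 0 else 0.0
        return part * self.amplitude_factor / s


def laplace_transfer_two_pump(setup: InfusionSetup, downstep: float) -> dict:
    """Laplace-domain transfer description of the unchanged-branch deviation.

    Returns coefficient arrays of the rational function

        u_M_diff(s) = num[0] / (den[0] s^2 + den[1] s + den[2])

    with num[0] = C2 R_cath u_downstep, den = [a*c, b, 1].
    """
    a, b, c = _two_pump_coeffs(setup)
    c2 = setup.channels[1].compliance
    num = c2 * setup.catheter.resistance * downstep
    return {"num": [num], "den": [a * c, b, 1.0]}


def transient_flow(setup: InfusionSetup, downstep: float) -> TransientFlow:
    """Closed-form two-exponential transient for the two-pump step scenario."""
    a, b, c = _two_pump_coeffs(setup)
    g, r = setup.channels
    if b == 0.0:
        # no compliance anywhere: flows follow the set rates instantly
        return TransientFlow(0.0, 0.0, 0.0, 0.0, a, b, c)
    if b < 0:
        raise NetworkError("non-positive relaxation: need positive compliance/resistance")
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise NetworkError("complex relaxation times: non-physical parameter set")
    root = math.sqrt(disc)
    theta_first = 0.5 * (b - root)
    theta_second = 0.5 * (b + root)
    amplitude = downstep * setup.catheter.resistance * r.compliance
    return TransientFlow(
        amplitude_factor=amplitude,
        theta_first=theta_first,
        theta_second=theta_second,
        discriminant_root=root,
        coeff_a=a,
        coeff_b=b,
        coeff_c=c,
    )


def dosing_error_volume(setup: InfusionSetup, downstep: float) -> float:
    """Total excess volume of the unchanged fluid: Q = C2 R_cath u_downstep (ml)."""
    _two_pump_coeffs(setup)  # validates channel count
    return setup.channels[1].compliance * setup.catheter.resistance * downstep


def syringe_exchange_error(
    setup: InfusionSetup, T_exchange: float, red_pump_on: bool = True
) -> float:
    """Dosing-error volume accumulated while the changed line is clamped.

    During a syringe exchange the green line is clamped for ``T_exchange``
    seconds.  The pressure drop at M lets the red syringe's compliance
    discharge undiluted red fluid into the catheter (the *compliance* term,
    the integral of the two-exponential transient driven by the full old
    green rate); if the red pump keeps running, its set rate adds
    ``u_pump_red * T_exchange`` on top.  The compliance term saturates at
    ``C2 R_cath u_old_green`` for long exchanges.
    """
    if T_exchange < 0:
        raise NetworkError("negative exchange duration")
    u_old_green = setup.channels[0].rate(-1.0)
    tf = transient_flow(setup, downstep=u_old_green)
    err = tf.integral(T_exchange)
    if red_pump_on:
        err += setup.channels[1].rate(0.0) * T_exchange
    return err


def final_total_rate(setup: InfusionSetup, t: float = math.inf) -> float:
    """Sum of set rates after all schedule breakpoints (ml/s)."""
    t_last = max((c.schedule[-1][0] for c in setup.channels), default=0.0)
    return setup.total_set_rate(max(t_last, 0.0) if math.isinf(t) else t)


# ---------------------------------------------------------------------------
# General state-space engine
# ---------------------------------------------------------------------------


@dataclass
class FlowTrace:
    """Time-resolved network flows on a uniform grid.

    Attributes
    ----------
    times : ndarray, s
    u_M_diff : dict label -> ndarray, ml/s
        Deviation of each channel's mixing-point inflow from its set rate.
    u_cath : ndarray, ml/s
        Total flow through the catheter.
    set_rates : dict label -> ndarray, ml/s
    """

    times: np.ndarray
    u_M_diff: dict[str, np.ndarray]
    u_cath: np.ndarray
    set_rates: dict[str, np.ndarray] = field(default_factory=dict)

    def u_M(self, label: str) -> np.ndarray:
        """Actual mixing-point inflow of one channel (set rate + deviation)."""
        return self.set_rates[label] + self.u_M_diff[label]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.times}
        for label, arr in self.u_M_diff.items():
            cols[f"u_M_diff_{label}_ml_per_s"] = arr
        cols["u_cath_ml_per_s"] = self.u_cath
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _mixing_pressure(p, active, R_lines, R_cath):
    """Pressure at M from Kirchhoff's current law over the active branches."""
    num = sum(p[i] / R_lines[i] for i in active)
    den = 1.0 / R_cath + sum(1.0 / R_lines[i] for i in active)
    return num / den


def state_space_simulate(setup: InfusionSetup, t_grid: np.ndarray) -> FlowTrace:
    """Integrate the linear RC network for arbitrary schedules and clamps.

    One pressure state per compliance.  Kirchhoff's laws give, for active
    (unclamped) branch i with line flow q_i = (p_i - p_M)/R_i,

        C_i dp_i/dt = u_i(t) - q_i,
        p_M = (sum_i p_i/R_i) / (1/R_cath + sum_i 1/R_i),

    a clamped branch is an open circuit (q_i = 0, its compliance charges
    from its own source).  Integration is segment-wise between schedule and
    clamp breakpoints with an implicit stiff solver (the two relaxation
    times differ by two orders of magnitude on standard values), then
    sampled onto the caller's grid.

    The initial state is the steady state for the rates at ``t_grid[0]``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise NetworkError("t_grid must be a 1-D array with at least two samples")
    chans = setup.channels
    n = len(chans)
    R_lines = np.array([c.resistance for c in chans])
    C = np.array([c.compliance for c in chans])
    if np.any(C <= 0):
        raise NetworkError("state-space engine requires positive compliances")
    R_cath = setup.catheter.resistance

    t0, t_end = t_grid[0], t_grid[-1]
    breaks = sorted(
        {t0, t_end}
        | {b for c in chans for b in c.breakpoints if t0 < b < t_end}
    )

    def active_at(t):
        return [i for i in range(n) if not chans[i].is_clamped(t)]

    # steady state immediately BEFORE the grid start (a breakpoint may sit
    # exactly at t0; the pre-event rates set the initial condition)
    t_init = t0 - 1e-9 * max(1.0, abs(t0))
    rates0 = np.array([c.rate(t_init) for c in chans])
    act0 = active_at(t_init)
    pM0 = R_cath * sum(rates0[i] for i in act0)
    p = np.empty(n)
    for i in range(n):
        p[i] = pM0 + R_lines[i] * rates0[i] if i in act0 else pM0 + R_lines[i] * rates0[i]

    times_out = [np.array([t0])]
    states_out = [p.reshape(1, -1).copy()]

    for seg_start, seg_end in zip(breaks[:-1], breaks[1:]):
        tm = 0.5 * (seg_start + seg_end)
        rates = np.array([c.rate(tm) for c in chans])
        active = active_at(tm)

        def rhs(t, y, rates=rates, active=active):
            pM = _mixing_pressure(y, active, R_lines, R_cath)
            dy = np.empty_like(y)
            for i in range(n):
                q = (y[i] - pM) / R_lines[i] if i in active else 0.0
                dy[i] = (rates[i] - q) / C[i]
            return dy

        seg_eval = t_grid[(t_grid > seg_start) & (t_grid <= seg_end)]
        seg_eval = np.unique(np.concatenate([seg_eval, [seg_end]]))
        sol = solve_ivp(
            rhs, (seg_start, seg_end), p, method="Radau",
            t_eval=seg_eval, rtol=1e-10, atol=1e-13, dense_output=False,
        )
        if not sol.success:
            raise NetworkError(
                f"stiff integration failed on [{seg_start}, {seg_end}]: "
                f"{sol.message}; try a finer grid or shorter horizon"
            )
        times_out.append(sol.t)
        states_out.append(sol.y.T)
        p = sol.y[:, -1].copy()

    t_all = np.concatenate(times_out)
    y_all = np.vstack(states_out)
    # sample states on the requested grid
    order = np.argsort(t_all, kind="stable")
    t_all, y_all = t_all[order], y_all[order]
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    t_all, y_all = t_all[keep], y_all[keep]
    P = np.vstack([np.interp(t_grid, t_all, y_all[:, i]) for i in range(n)]).T

    u_diff = {c.label: np.empty_like(t_grid) for c in chans}
    set_rates = {c.label: np.array([c.rate(t) for t in t_grid]) for c in chans}
    u_cath = np.empty_like(t_grid)
    for k, t in enumerate(t_grid):
        active = active_at(t)
        pM = _mixing_pressure(P[k], active, R_lines, R_cath)
        total = 0.0
        for i, c in enumerate(chans):
            q = (P[k, i] - pM) / R_lines[i] if i in active else 0.0
            u_diff[c.label][k] = q - set_rates[c.label][k]
            total += q
        u_cath[k] = total
    return FlowTrace(times=t_grid, u_M_diff=u_diff, u_cath=u_cath, set_rates=set_rates)


def _linear_branch_flows(setup: InfusionSetup, downstep: float, t: np.ndarray):
    """Exact branch flow deviations for the two-pump step via eigendecomposition.

    Solves the homogeneous relaxation of the 2-state pressure system from
    the pre-step steady state analytically (matrix eigenvalues/vectors);
    independent of both the two-exponential closed forms and the ODE integrator.
    Returns (delta_green, delta_red) arrays of mixing-point inflow
    deviations from the post-step set rates.
    """
    g, r = setup.channels
    R1, R2, Rc = g.resistance, r.resistance, setup.catheter.resistance
    C1, C2 = g.compliance, r.compliance
    t = np.asarray(t, dtype=float)
    if C1 == 0.0 and C2 == 0.0:
        return np.zeros_like(t), np.zeros_like(t)
    if C1 <= 0.0 or C2 <= 0.0:
        raise NetworkError("mixed zero/non-zero compliances are not supported")
    den = 1.0 / Rc + 1.0 / R1 + 1.0 / R2

    # q_i = (p_i - pM)/R_i is linear in p: q = G p, with pM = (p1/R1+p2/R2)/den
    G = np.array([
        [(1.0 - 1.0 / (R1 * den)) / R1, -1.0 / (R1 * R2 * den)],
        [-1.0 / (R1 * R2 * den), (1.0 - 1.0 / (R2 * den)) / R2],
    ])
    Cinv = np.diag([1.0 / C1, 1.0 / C2])
    A = -Cinv @ G  # dp/dt = A p + Cinv u

    u_new = np.array([g.rate(np.inf), r.rate(np.inf)])
    u_old = np.array([g.rate(-1.0), r.rate(-1.0)])
    p_inf = np.linalg.solve(G, u_new)
    p0 = np.linalg.solve(G, u_old)
    w, V = np.linalg.eig(A)
    coef = np.linalg.solve(V, p0 - p_inf)
    # p(t) - p_inf = V @ (coef * exp(w t)); q deviation = G (p - p_inf)
    E = np.exp(np.outer(np.asarray(t), w))  # (nt, 2)
    dev_p = (E * coef) @ V.T
    dev_q = dev_p @ G.T
    return dev_q[:, 0].real, dev_q[:, 1].real


def analytic_flow_trace(
    setup: InfusionSetup,
    downstep: float,
    t_grid: np.ndarray,
    lambda_convention: str = "total",
) -> FlowTrace:
    """FlowTrace for the two-pump step built from the linear closed solution.

    ``u_M_diff`` of the monitored (red) channel follows the two-exponential
    transient.  The total catheter flow carried by the trace depends on
    ``lambda_convention``:

    * ``"total"`` (default) — physical: settled rate plus the relaxation of
      *both* branches;
    * ``"changed_branch"`` — settled rate plus the changed (green) branch's
      relaxation only.  This is the convention under which the closed-form
      central-time and width expressions are exact (the closed forms neglect
      the unchanged branch's compliance discharge in the displacement
      history); see docs/methods.md.
    """
    if lambda_convention not in ("total", "changed_branch"):
        raise ValueError(f"unknown lambda_convention {lambda_convention!r}")
    t_grid = np.asarray(t_grid, dtype=float)
    g, r = setup.channels
    tf = transient_flow(setup, downstep)
    u_diff_red = tf.u_diff(t_grid)
    dg, dr = _linear_branch_flows(setup, downstep, np.clip(t_grid, 0.0, None))
    dg = np.where(t_grid < 0, 0.0, dg)
    dr = np.where(t_grid < 0, 0.0, dr)
    u_final = final_total_rate(setup)
    if lambda_convention == "total":
        u_cath = u_final + dg + dr
    else:
        u_cath = u_final + dg
    if t_grid[0] < 0:
        u_cath = np.where(t_grid < 0, setup.total_set_rate(-1.0), u_cath)
    set_rates = {c.label: np.array([c.rate(t) for t in t_grid]) for c in setup.channels}
    return FlowTrace(
        times=t_grid,
        u_M_diff={g.label: dg, r.label: u_diff_red},
        u_cath=u_cath,
        set_rates=set_rates,
    )
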