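"""Scenario assembly: patient-facing dosing-error traces and named runs.

The patient-side dosing error of the monitored fluid after a single rate
step at t = 0 is composed of three branches:

    beta(t) = 0                                  t < 0
            = beta_pushout                       0 < t < t_delay_pois
            = psi_patient(tau) * u_final_total   t > t_delay_pois

with tau = t - t_delay_pois: first the old mixture is pushed out at the
new total rate (constant deviation), then the Poiseuille-smeared mixture
history — compliance transient plus old-mixture remnant — reaches the tip.

Named scenarios cover the rate step, the syringe exchange and the
parameter sweeps used for verification plots; :func:`generate_fixtures`
writes a deterministic family of scenario files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import catheter as cath_mod
from . import metrics as metrics_mod
from . import network as net_mod
from . import poiseuille as pois_mod
from .config import (
    CatheterSpec,
    InfusionSetup,
    PumpChannel,
    dump_setup,
    standard_setup,
)

__all__ = [
    "DoseErrorTrace",
    "assemble_trace",
    "run_scenario",
    "generate_fixtures",
    "scenario_grid",
]


@dataclass
class DoseErrorTrace:
    """Patient-side dosing-error flow of one monitored fluid."""

    times: np.ndarray
    beta: np.ndarray  # ml/s
    branch: np.ndarray  # str labels: pre | pushout | compliance
    metrics: metrics_mod.BolusMetrics
    monitored: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "beta_ml_per_s": self.beta, "branch": self.branch}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def integral(self) -> float:
        return float(np.trapezoid(self.beta, self.times))


def _single_step(setup: InfusionSetup) -> tuple[str, float, float]:
    """Identify the single rate-step event: (channel, u_old, u_new)."""
    steps = [
        (c.label, c.schedule[0][1], c.schedule[-1][1])
        for c in setup.channels
        if len(c.schedule) > 1
    ]
    if len(steps) != 1:
        raise ValueError(
            "analytic trace assembly covers exactly one rate-step event; "
            "run general schedules through the streamline oracle"
        )
    label, u_old, u_new = steps[0]
    n_breaks = len(setup.channels[[c.label for c in setup.channels].index(label)].schedule)
    if n_breaks > 2:
        raise ValueError("multiple steps on one channel: use the oracle")
    return label, u_old, u_new


def scenario_grid(setup: InfusionSetup, horizon: float, per_voxel: float = 0.5) -> np.ndarray:
    """Uniform grid resolving one voxel of centerline travel per step."""
    u_max = max(setup.total_set_rate(-1.0), setup.total_set_rate(math.inf))
    dt = per_voxel * setup.catheter.gamma * setup.catheter.volume / (
        2.0 * setup.catheter.length * u_max
    )
    n = int(math.ceil(horizon / dt)) + 1
    return np.linspace(0.0, horizon, n)


def assemble_trace(
    setup: InfusionSetup,
    with_poiseuille: bool = True,
    plug_flow_pushout_window: bool = False,
    lambda_convention: str = "total",
    horizon: float | None = None,
) -> DoseErrorTrace:
    """Compose the three-branch dosing-error trace for a single step event.

    ``plug_flow_pushout_window=True`` extends the push-out branch to the
    full plug-flow delay time t_delay (the cartoon picture without
    Poiseuille lead); the normative composition uses t_delay_pois.
    """
    changed, u_old_ch, u_new_ch = _single_step(setup)
    monitored = next(c.label for c in setup.channels if c.label != changed)
    mon = setup.channel(monitored)
    downstep = u_old_ch - u_new_ch
    u_pump = mon.schedule[0][1]
    u_final = net_mod.final_total_rate(setup)

    tf = net_mod.transient_flow(setup, downstep)
    t_max = cath_mod.truncation_horizon(
        tf.theta_second, setup.catheter.volume, u_final
    )
    if horizon is None:
        horizon = t_max
    grid = scenario_grid(setup, horizon)
    flow = net_mod.analytic_flow_trace(
        setup, downstep, grid, lambda_convention=lambda_convention
    )
    t_delay = cath_mod.delay_time(flow, setup.catheter)
    t_dpois = cath_mod.poiseuille_tip_delay(t_delay)
    # normative composition switches branches at t_delay_pois; the plug-flow
    # composition (and the cartoon variant behind the flag) at t_delay
    t_switch = (
        t_delay if (plug_flow_pushout_window or not with_poiseuille) else t_dpois
    )

    push = cath_mod.pushout_flow(u_pump, u_old_ch, u_new_ch)

    entry = cath_mod.entry_sequence(flow, setup.catheter, u_final, monitored=monitored)
    if with_poiseuille:
        k_max = max(
            int(math.ceil((horizon - t_dpois) / (0.5 * entry.dt_per_index))),
            setup.catheter.n_voxels,
        )
        kern = pois_mod.kernel(setup.catheter, k_max)
        bolus = pois_mod.tip_convolution(entry, kern, u_pump, u_old_ch, u_new_ch)
        tau = bolus.times()
        psi = bolus.psi_patient
        moment_source = lambda: metrics_mod.discrete_moments(bolus, part="pois")
    else:
        # plug flow: the compliance bolus is the entry sequence delivered
        # FIFO after t_delay; the old mixture exits entirely inside the
        # push-out window, so there is no remnant tail.
        tau = np.arange(len(entry.a_diff)) * entry.dt_per_index
        psi = entry.a_diff
        moment_source = lambda: metrics_mod.discrete_moments(entry)

    try:
        m = moment_source()
    except metrics_mod.ZeroMassError:
        # zero-compliance set-up: no compliance bolus, only push-out/remnant
        m = metrics_mod.BolusMetrics(
            Q=0.0, t_central=math.nan, sigma=math.nan, method="discrete"
        )

    t_tail = t_switch + tau
    keep = t_tail <= horizon
    t_tail, psi_tail = t_tail[keep], psi[keep] * u_final

    n_pre = max(int(round(t_switch / (t_tail[1] - t_tail[0]))), 1) if len(t_tail) > 1 else 1
    t_push = np.linspace(0.0, t_switch, n_pre, endpoint=False)
    times = np.concatenate([[-1.0], t_push, t_tail])
    beta = np.concatenate([[0.0], np.full(len(t_push), push), psi_tail])
    branch = np.concatenate(
        [["pre"], np.full(len(t_push), "pushout"), np.full(len(t_tail), "compliance")]
    )
    m.t_delay = t_delay
    m.t_delay_pois = t_dpois
    m.truncation["horizon_s"] = horizon
    m.truncation["with_poiseuille"] = with_poiseuille
    return DoseErrorTrace(
        times=times, beta=beta, branch=branch, metrics=m, monitored=monitored
    )


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------


def _fig8_variants(setup: InfusionSetup) -> list[tuple[str, InfusionSetup]]:
    """Catheter-resistance / red-compliance sweep around the standard values."""
    red = setup.channels[1].label
    rc = setup.catheter.resistance
    c_red = setup.channel(red).compliance
    out = []
    for name, rc_f, c_f in [
        ("Rcath_x3", 3.0, 1.0),
        ("Rcath_x2", 2.0, 1.0),
        ("standard", 1.0, 1.0),
        ("Cred_x0.52", 1.0, 0.52),
        ("Cred_x0.36", 1.0, 0.36),
    ]:
        s = replace(setup, catheter=replace(setup.catheter, resistance=rc * rc_f))
        s = s.with_channel(red, compliance=c_red * c_f)
        out.append((name, s))
    return out


def run_scenario(name: str, setup: InfusionSetup | None = None, **options) -> dict:
    """Run a named scenario and return its output bundle.

    Names: ``downstep`` (single rate step; trace + metrics),
    ``syringe_exchange`` (error volume vs exchange duration; the three
    curves compliance-only / pump-on-only / combined),
    ``fig8_sweep`` (deviation-flow transients for resistance/compliance
    variants), ``fig9_sweep`` (alias of syringe_exchange curves).
    """
    setup = setup if setup is not None else standard_setup()
    if name == "downstep":
        trace = assemble_trace(setup, **options)
        return {"trace": trace, "metrics": trace.metrics}
    if name in ("syringe_exchange", "fig9_sweep"):
        T = options.get("T_exchange", np.linspace(0.0, 600.0, 121))
        T = np.asarray(T, dtype=float)
        compliance = np.array(
            [net_mod.syringe_exchange_error(setup, t, red_pump_on=False) for t in T]
        )
        u_red = setup.channels[1].schedule[0][1]
        pump_on = u_red * T
        return {
            "T_exchange_s": T,
            "compliance_ml": compliance,
            "pump_on_ml": pump_on,
            "combined_ml": compliance + pump_on,
        }
    if name == "fig8_sweep":
        horizon = options.get("horizon", 600.0)
        t = np.linspace(0.0, horizon, options.get("n_samples", 1201))
        out = {}
        for vname, s in _fig8_variants(setup):
            downstep = s.channels[0].schedule[0][1] - s.channels[0].schedule[-1][1]
            tf = net_mod.transient_flow(s, downstep)
            out[vname] = {
                "times_s": t,
                "u_M_diff_ml_per_s": tf.u_diff(t),
                "Q_ml": net_mod.dosing_error_volume(s, downstep),
                "setup": s,
            }
        return out
    raise ValueError(f"unknown scenario {name!r}")


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------


def generate_fixtures(seed: int, out_dir, n_random: int = 20) -> list[Path]:
    """Write a deterministic family of scenario files.

    Table-standard scenario, the five resistance/compliance sweep variants,
    the two syringe-exchange variants (red pump on/off), plus ``n_random``
    randomized draws (log-uniform within a factor 10 of the standard
    values) for property testing.  Same seed, same bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written = []

    std = standard_setup()
    paths = {"standard.yaml": std}
    for vname, s in _fig8_variants(std):
        paths[f"sweep_{vname}.yaml"] = s
    for pump_on in (False, True):
        s = std.with_channel("green", clamps=((0.0, 300.0),))
        tag = "pump_on" if pump_on else "pump_off"
        from .config import Event

        s = replace(
            s,
            events=(Event("syringe_exchange", 0.0, "green", 300.0),),
        )
        paths[f"exchange_{tag}.yaml"] = s

    for i in range(n_random):
        f = lambda: float(10.0 ** rng.uniform(-1.0, 1.0))
        std_v = standard_setup()
        g, r = std_v.channels
        cath = std_v.catheter
        u_old = g.schedule[0][1] * f()
        u_new = u_old * float(rng.uniform(0.1, 0.9))
        green = PumpChannel(
            label="green",
            compliance=g.compliance * f(),
            resistance=g.resistance * f(),
            schedule=((-3600.0, u_old), (0.0, u_new)),
        )
        red = PumpChannel(
            label="red",
            compliance=r.compliance * f(),
            resistance=r.resistance * f(),
            schedule=((-3600.0, r.schedule[0][1] * f()),),
        )
        cspec = CatheterSpec(
            resistance=cath.resistance * f(),
            volume=cath.volume,
            length=cath.length,
            n_voxels=cath.n_voxels,
        )
        paths[f"random_{i:03d}.yaml"] = InfusionSetup(
            channels=(green, red), catheter=cspec
        )

    for fname, s in paths.items():
        p = out_dir / fname
        dump_setup(s, p)
        written.append(p)
    return written
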