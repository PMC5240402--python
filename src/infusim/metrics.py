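"""Moment-based bolus characterization: volume Q, central time, width.

A dosing-error bolus is summarized by its total volume Q (ml), its central
time t_central (first moment of the delivered-volume distribution, s) and
its width parameter sigma (square root of the second central moment, s);
the clinically quoted "duration" of a bolus is 2*sigma.  Both a discrete
route (moments of a simulated bolus, the z -> 1 derivative limit evaluated
as index-weighted sums) and closed forms for the canonical two-pump
rate-step scenario are provided, together with the documented limiting
cases (sigma -> 2 C R_cath, sigma_pois -> 4 C R_cath, sigma_pois ->
V_cath/u_final).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .catheter import EntrySequence, poiseuille_tip_delay
from .config import InfusionSetup
from .network import _two_pump_coeffs
from .poiseuille import TipBolus

__all__ = [
    "BolusMetrics",
    "ZeroMassError",
    "discrete_moments",
    "t_central_closed",
    "sigma_closed",
    "limit_checks",
]


class ZeroMassError(ValueError):
    """Moments are undefined for a bolus with zero total mass."""


@dataclass
class BolusMetrics:
    """Summary of one dosing-error bolus.

    Q in ml; t_central, sigma, delays in s.  ``method`` tags the route
    (``closed_form`` or ``discrete``); ``truncation`` records the horizon
    and index cut-offs used.
    """

    Q: float
    t_central: float
    sigma: float
    t_delay: float | None = None
    t_delay_pois: float | None = None
    method: str = "discrete"
    truncation: dict = field(default_factory=dict)

    @property
    def width(self) -> float:
        """Reported bolus duration: 2 sigma."""
        return 2.0 * self.sigma

    def as_dict(self) -> dict:
        d = {
            "Q_ml": self.Q,
            "t_central_s": self.t_central,
            "sigma_s": self.sigma,
            "width_2sigma_s": self.width,
            "method": self.method,
            "truncation": dict(self.truncation),
        }
        if self.t_delay is not None:
            d["t_delay_s"] = self.t_delay
        if self.t_delay_pois is not None:
            d["t_delay_pois_s"] = self.t_delay_pois
        return d


def _moments_from_mass(mass: np.ndarray, times: np.ndarray) -> tuple[float, float, float]:
    q = float(mass.sum())
    if q == 0.0 or not np.isfinite(q):
        raise ZeroMassError("bolus has zero (or non-finite) total mass")
    t1 = float((times * mass).sum()) / q
    t2 = float((times * times * mass).sum()) / q
    var = max(t2 - t1 * t1, 0.0)
    return q, t1, math.sqrt(var)


def discrete_moments(bolus, part: str = "pois") -> BolusMetrics:
    """Moments of a simulated bolus.

    Accepts an :class:`~infusim.catheter.EntrySequence` (plug-flow bolus on
    the entry-voxel index), a :class:`~infusim.poiseuille.TipBolus`
    (``part`` selects ``"pois"``, ``"remnant"`` or ``"patient"``), or a
    ``(times, flow_deviation)`` pair of arrays (time-domain trace, flow in
    ml/s).  Q is the zeroth sum scaled to ml; t_central the first moment of
    the delivered-volume distribution; sigma the root of the second central
    moment.
    """
    if isinstance(bolus, EntrySequence):
        times = np.arange(len(bolus.a_diff)) * bolus.dt_per_index
        mass = bolus.a_diff * bolus.volume_per_index
        q, tc, sig = _moments_from_mass(mass, times)
        return BolusMetrics(
            Q=q, t_central=tc, sigma=sig, method="discrete",
            truncation={"n_indices": len(mass), "dt_per_index_s": bolus.dt_per_index},
        )
    if isinstance(bolus, TipBolus):
        psi = {
            "pois": bolus.psi_pois,
            "remnant": bolus.psi_remnant,
            "patient": bolus.psi_patient,
        }[part]
        times = bolus.times()
        mass = psi * bolus.u_final * bolus.dt_per_index
        q, tc, sig = _moments_from_mass(mass, times)
        return BolusMetrics(
            Q=q, t_central=tc, sigma=sig, method="discrete",
            truncation={
                "n_indices": len(mass),
                "dt_per_index_s": bolus.dt_per_index,
                "part": part,
                "truncation_index": bolus.truncation_index,
            },
        )
    times, beta = bolus
    times = np.asarray(times, float)
    beta = np.asarray(beta, float)
    dt = np.gradient(times)
    q, tc, sig = _moments_from_mass(beta * dt, times)
    return BolusMetrics(
        Q=q, t_central=tc, sigma=sig, method="discrete",
        truncation={"horizon_s": float(times[-1])},
    )


def _symmetric(setup: InfusionSetup, rtol: float = 1e-9) -> bool:
    g, r = setup.channels
    return (
        math.isclose(g.compliance, r.compliance, rel_tol=rtol)
        and math.isclose(g.resistance, r.resistance, rel_tol=rtol)
    )


def t_central_closed(setup: InfusionSetup, downstep: float, u_final: float) -> float:
    """Closed-form central time of the plug-flow compliance bolus (s).

    General two-pump form

        t_central = b + (u_down / 4 u_final)
                    * (sqrt(b^2-4ac) - 2 C2 R_cath + b + 2 a c / b)

    reducing for C1 = C2 = C, R1 = R2 = R to

        t_central = 2 C (R_cath + R)
                    + C u_down (2 R_cath^2 + 6 R_cath R + 3 R^2)
                      / (4 u_final (R_cath + R)).

    Exact under the displacement convention of the closed forms (settled
    rate plus changed-branch relaxation; see docs/methods.md).
    """
    a, b, c = _two_pump_coeffs(setup)
    g, r = setup.channels
    rc = setup.catheter.resistance
    if _symmetric(setup):
        C, R = r.compliance, r.resistance
        return 2.0 * C * (rc + R) + C * downstep * (
            2.0 * rc * rc + 6.0 * rc * R + 3.0 * R * R
        ) / (4.0 * u_final * (rc + R))
    root = math.sqrt(b * b - 4.0 * a * c)
    return b + downstep / (4.0 * u_final) * (
        root - 2.0 * r.compliance * rc + b + 2.0 * a * c / b
    )


def sigma_closed(
    setup: InfusionSetup,
    downstep: float,
    u_final: float,
    with_poiseuille: bool = False,
    V_cath: float | None = None,
) -> float:
    """Closed-form width parameter sigma (s) for the symmetric regime.

    Requires C1 = C2 = C and R1 = R2 = R (asymmetric set-ups must use the
    discrete route) and assumes R << R_cath (warns above R_cath/10).

    Plug flow:
        sigma = C R_cath / (2 sqrt(3) u_final)
                * sqrt(u_down^2 + 12 u_down u_final + 48 u_final^2)

    With Poiseuille mixing:
        sigma_pois = 1/(sqrt(3) u_final)
                * sqrt(C^2 R_cath^2 (u_down^2 + 12 u_down u_final
                       + 48 u_final^2) + 3 V_cath^2)
    """
    if not _symmetric(setup):
        raise ValueError(
            "closed-form sigma covers the symmetric case (C1=C2, R1=R2) only; "
            "use discrete_moments on a simulated bolus"
        )
    g, r = setup.channels
    C, R = r.compliance, r.resistance
    rc = setup.catheter.resistance
    if R > rc / 10.0:
        warnings.warn(
            "closed-form sigma assumes R << R_cath; "
            f"R/R_cath = {R / rc:.3g} exceeds 0.1",
            stacklevel=2,
        )
    poly = downstep * downstep + 12.0 * downstep * u_final + 48.0 * u_final * u_final
    if not with_poiseuille:
        return C * rc / (2.0 * math.sqrt(3.0) * u_final) * math.sqrt(poly)
    v = setup.catheter.volume if V_cath is None else V_cath
    return math.sqrt(C * C * rc * rc * poly + 3.0 * v * v) / (
        math.sqrt(3.0) * u_final
    )


def limit_checks(setup: InfusionSetup, eps: float = 1e-4) -> dict[str, float]:
    """Evaluate the documented asymptotics; returns achieved ratios (-> 1).

    * ``sigma_over_2CR``: plug-flow sigma at u_down/u_final = eps, divided
      by 2 C R_cath.
    * ``sigma_pois_over_4CR``: Poiseuille sigma at u_down/u_final = eps and
      V_cath scaled to eps * C R_cath u_final, divided by 4 C R_cath.
    * ``sigma_pois_over_V_per_u``: Poiseuille sigma with C R_cath scaled
      down by eps, divided by V_cath/u_final.
    * ``tip_delay_over_half_delay``: t_delay_pois / (t_delay / 2).
    """
    g, r = setup.channels
    C = r.compliance
    rc = setup.catheter.resistance
    u_final = sum(c.rate(math.inf) for c in setup.channels)
    downstep = eps * u_final

    sig = sigma_closed(setup, downstep, u_final, with_poiseuille=False)
    out = {"sigma_over_2CR": sig / (2.0 * C * rc)}

    v_small = eps * C * rc * u_final
    sig_p = sigma_closed(setup, downstep, u_final, with_poiseuille=True, V_cath=v_small)
    out["sigma_pois_over_4CR"] = sig_p / (4.0 * C * rc)

    v = setup.catheter.volume
    small = setup.with_channel(g.label, compliance=C * eps)
    small = small.with_channel(r.label, compliance=C * eps)
    sig_v = sigma_closed(small, downstep, u_final, with_poiseuille=True, V_cath=v)
    out["sigma_pois_over_V_per_u"] = sig_v / (v / u_final)

    t_delay = v / u_final  # constant-flow delay
    out["tip_delay_over_half_delay"] = poiseuille_tip_delay(t_delay) / (0.5 * t_delay)
    return out
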