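"""Scenario configuration model: pump channels, catheter, events.

The central objects are :class:`PumpChannel` (one syringe pump with its
mechanical compliance, feeding-line resistance and piecewise-constant rate
schedule), :class:`CatheterSpec` (the shared catheter whose internal volume
acts as a mixture memory) and :class:`InfusionSetup` (all channels joined at
one mixing point M, draining through the catheter to the tip P).

All numeric fields are stored in canonical units (s, ml, Pa); YAML scenario
files declare clinical units per field and are converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import yaml

from .units import to_internal

#: Table of standard hardware values used throughout (clinical units).
STANDARD_VALUES = {
    "R_cath": (1145.0, "Pa/(ml/h)"),
    "R_green": (23.0, "Pa/(ml/h)"),
    "R_red": (23.0, "Pa/(ml/h)"),
    "C_green": (1.5e-5, "ml/Pa"),
    "C_red": (1.5e-5, "ml/Pa"),
    "u_pump_red": (0.5, "ml/h"),
    "u_old_green": (12.0, "ml/h"),
    "u_downstep_green": (6.0, "ml/h"),
}

#: Fixture defaults for quantities that are scenario-dependent rather than
#: standardized hardware values: catheter internal volume, length and voxel
#: count.  Overridable everywhere.
DEFAULT_V_CATH = 1.0  # ml
DEFAULT_LENGTH = 1.0  # arbitrary length unit
DEFAULT_N_VOXELS = 10_000


class ConfigError(ValueError):
    """Invalid or inconsistent scenario configuration."""


@dataclass(frozen=True)
class Event:
    """A single setting change applied to a running set-up.

    kind is one of ``rate_step`` (channel rate changes to ``value`` at
    ``time``), ``clamp`` / ``unclamp`` (line closed / reopened) or
    ``syringe_exchange`` (channel clamped for ``value`` seconds).
    """

    kind: str
    time: float
    channel: str
    value: float | None = None

    _KINDS = ("rate_step", "clamp", "unclamp", "syringe_exchange")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ConfigError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class PumpChannel:
    """One pump + syringe + feeding line.

    Parameters
    ----------
    label : str
        Channel name (e.g. ``"green"``, ``"red"``).
    compliance : float
        Mechanical compliance of the syringe in ml/Pa (mainly plunger
        compressibility) — the capacitor of the electric analog.
    resistance : float
        Feeding-line resistance in Pa/(ml/s).
    schedule : sequence of (start_time, rate)
        Piecewise-constant set rate in ml/s.  ``rate_i`` applies on
        ``[t_i, t_{i+1})``; the first rate also extends backwards to the
        infinite past (pre-stabilized set-up).
    clamps : sequence of (t_start, t_end)
        Intervals during which the line is clamped shut (open circuit).
    """

    label: str
    compliance: float
    resistance: float
    schedule: tuple[tuple[float, float], ...]
    clamps: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "schedule", tuple((float(t), float(r)) for t, r in self.schedule))
        object.__setattr__(self, "clamps", tuple((float(a), float(b)) for a, b in self.clamps))
        if not self.schedule:
            raise ConfigError(f"channel {self.label!r}: empty schedule")
        times = [t for t, _ in self.schedule]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ConfigError(f"channel {self.label!r}: schedule breakpoints must be strictly increasing")
        if any(r < 0 for _, r in self.schedule):
            raise ConfigError(f"channel {self.label!r}: negative set rate")
        if self.compliance < 0 or self.resistance < 0:
            raise ConfigError(f"channel {self.label!r}: negative compliance/resistance")
        cl = sorted(self.clamps)
        if any(b <= a for a, b in cl):
            raise ConfigError(f"channel {self.label!r}: empty clamp interval")
        if any(b1 > a2 for (_, b1), (a2, _) in zip(cl, cl[1:])):
            raise ConfigError(f"channel {self.label!r}: overlapping clamp intervals")

    def rate(self, t: float) -> float:
        """Set rate at time *t* (ml/s); first scheduled rate before the first breakpoint."""
        r = self.schedule[0][1]
        for ti, ri in self.schedule:
            if t >= ti:
                r = ri
            else:
                break
        return r

    def is_clamped(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.clamps)

    @property
    def breakpoints(self) -> tuple[float, ...]:
        bp = [t for t, _ in self.schedule[1:]]
        for a, b in self.clamps:
            bp.extend((a, b))
        return tuple(sorted(set(bp)))


@dataclass(frozen=True)
class CatheterSpec:
    """Catheter between the mixing point M and the distal tip P.

    resistance in Pa/(ml/s); volume (internal/dead volume) in ml; length in
    an arbitrary length unit; n_voxels is the axial discretization N, with
    voxel length gamma = length/N.
    """

    resistance: float
    volume: float = DEFAULT_V_CATH
    length: float = DEFAULT_LENGTH
    n_voxels: int = DEFAULT_N_VOXELS

    def __post_init__(self):
        if self.volume <= 0:
            raise ConfigError("catheter volume must be positive")
        if self.length <= 0:
            raise ConfigError("catheter length must be positive")
        if self.n_voxels < 100:
            raise ConfigError("catheter discretization requires n_voxels >= 100")
        if self.resistance < 0:
            raise ConfigError("negative catheter resistance")

    @property
    def gamma(self) -> float:
        """Voxel length L/N."""
        return self.length / self.n_voxels


@dataclass(frozen=True)
class InfusionSetup:
    """Complete multi-infusion set-up: >=2 channels joined at M, one catheter."""

    channels: tuple[PumpChannel, ...]
    catheter: CatheterSpec
    events: tuple[Event, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "events", tuple(self.events))
        if len(self.channels) < 2:
            raise ConfigError("a multi-infusion set-up needs at least two channels")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate channel labels")

    def channel(self, label: str) -> PumpChannel:
        for c in self.channels:
            if c.label == label:
                return c
        raise KeyError(label)

    def total_set_rate(self, t: float) -> float:
        return sum(c.rate(t) for c in self.channels)

    def with_channel(self, label: str, **changes) -> "InfusionSetup":
        """Return a copy with one channel's fields replaced."""
        chans = tuple(replace(c, **changes) if c.label == label else c for c in self.channels)
        return replace(self, channels=chans)


def standard_setup(
    *,
    volume: float = DEFAULT_V_CATH,
    length: float = DEFAULT_LENGTH,
    n_voxels: int = DEFAULT_N_VOXELS,
) -> InfusionSetup:
    """Two-channel set-up with the standard hardware values.

    The green (fast) pump runs at u_old = 12 ml/h and steps down by
    6 ml/h at t = 0; the red (monitored) pump runs at 0.5 ml/h throughout.
    Catheter volume/length/discretization are fixture defaults, overridable
    via keyword arguments.
    """
    g = {k: to_internal(*v) for k, v in STANDARD_VALUES.items()}
    u_old = g["u_old_green"]
    u_new = u_old - g["u_downstep_green"]
    green = PumpChannel(
        label="green",
        compliance=g["C_green"],
        resistance=g["R_green"],
        schedule=((-SECONDS_BEFORE, u_old), (0.0, u_new)),
    )
    red = PumpChannel(
        label="red",
        compliance=g["C_red"],
        resistance=g["R_red"],
        schedule=((-SECONDS_BEFORE, g["u_pump_red"]),),
    )
    catheter = CatheterSpec(
        resistance=g["R_cath"], volume=volume, length=length, n_voxels=n_voxels
    )
    events = (Event("rate_step", 0.0, "green", u_new),)
    return InfusionSetup(channels=(green, red), catheter=catheter, events=events)


#: Nominal timestamp for the pre-event schedule entry (one hour before t=0);
#: rates extend backwards from the first entry regardless of this value.
SECONDS_BEFORE = 3600.0


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------

_CHANNEL_KEYS = {"label", "C", "R", "schedule", "clamps"}
_CATHETER_KEYS = {"R_cath", "V_cath", "L", "N"}
_SETUP_KEYS = {"channels", "catheter", "events", "units"}
_EVENT_KEYS = {"kind", "time", "channel", "value"}
_DEFAULT_UNITS = {
    "C": "ml/Pa",
    "R": "Pa/(ml/h)",
    "rate": "ml/h",
    "time": "s",
    "R_cath": "Pa/(ml/h)",
    "V_cath": "ml",
}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_setup(path) -> InfusionSetup:
    """Read an :class:`InfusionSetup` from a YAML scenario file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return setup_from_dict(doc)


def setup_from_dict(doc: dict) -> InfusionSetup:
    if not isinstance(doc, dict) or "setup" not in doc:
        raise ConfigError("scenario file must contain a top-level 'setup' mapping")
    su = doc["setup"]
    _check_keys(su, _SETUP_KEYS, "setup")
    units = dict(_DEFAULT_UNITS)
    units.update(su.get("units") or {})

    channels = []
    for ch in su.get("channels", []):
        _check_keys(ch, _CHANNEL_KEYS, f"channel {ch.get('label')!r}")
        schedule = tuple(
            (to_internal(t, units["time"]), to_internal(r, units["rate"]))
            for t, r in (tuple(p) for p in ch["schedule"])
        )
        clamps = tuple(
            (to_internal(a, units["time"]), to_internal(b, units["time"]))
            for a, b in (tuple(p) for p in ch.get("clamps", []))
        )
        channels.append(
            PumpChannel(
                label=str(ch["label"]),
                compliance=to_internal(ch["C"], units["C"]),
                resistance=to_internal(ch["R"], units["R"]),
                schedule=schedule,
                clamps=clamps,
            )
        )

    cath = su["catheter"]
    _check_keys(cath, _CATHETER_KEYS, "catheter")
    catheter = CatheterSpec(
        resistance=to_internal(cath["R_cath"], units["R_cath"]),
        volume=to_internal(cath.get("V_cath", DEFAULT_V_CATH), units["V_cath"]),
        length=float(cath.get("L", DEFAULT_LENGTH)),
        n_voxels=int(cath.get("N", DEFAULT_N_VOXELS)),
    )

    events = []
    for ev in su.get("events", []):
        _check_keys(ev, _EVENT_KEYS, "event")
        value = ev.get("value")
        if value is not None and ev["kind"] == "rate_step":
            value = to_internal(value, units["rate"])
        elif value is not None:
            value = to_internal(value, units["time"])
        events.append(
            Event(kind=ev["kind"], time=to_internal(ev["time"], units["time"]),
                  channel=str(ev["channel"]), value=value)
        )
    return InfusionSetup(channels=tuple(channels), catheter=catheter, events=tuple(events))


def setup_to_dict(setup: InfusionSetup) -> dict:
    """Serialize in canonical units (unit block written explicitly)."""
    units = {"C": "ml/Pa", "R": "Pa/(ml/s)", "rate": "ml/s", "time": "s",
             "R_cath": "Pa/(ml/s)", "V_cath": "ml"}
    doc = {
        "setup": {
            "units": units,
            "channels": [
                {
                    "label": c.label,
                    "C": c.compliance,
                    "R": c.resistance,
                    "schedule": [[t, r] for t, r in c.schedule],
                    "clamps": [[a, b] for a, b in c.clamps],
                }
                for c in setup.channels
            ],
            "catheter": {
                "R_cath": setup.catheter.resistance,
                "V_cath": setup.catheter.volume,
                "L": setup.catheter.length,
                "N": setup.catheter.n_voxels,
            },
            "events": [
                {"kind": e.kind, "time": e.time, "channel": e.channel,
                 **({"value": e.value} if e.value is not None else {})}
                for e in setup.events
            ],
        }
    }
    return doc


def dump_setup(setup: InfusionSetup, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(setup_to_dict(setup), fh, sort_keys=True)
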