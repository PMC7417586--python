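"""Stepwise force protocols.

A protocol is an ordered list of force-change events ``(time_s, dF_nN)``.
The instantaneous force is the cumulative sum of the changes, and must never
go negative (the tweezer only pulls).  Three canonical protocols are
provided: a single constant-force pulse, a train of identical pulses
separated by zero-force relaxation phases, and a staircase in which the
force is raised by a constant increment after each step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ForceProtocol"]

_TOL = 1e-9


@dataclass(frozen=True)
class ForceProtocol:
    """An ordered sequence of force-change events.

    ``events`` is a tuple of ``(time_s, delta_force_nN)`` with strictly
    increasing times; the running sum of the force changes must be >= 0 at
    all times.
    """

    events: tuple[tuple[float, float], ...]
    kind: str = "custom"
    parameters: dict | None = None

    def __post_init__(self):
        events = tuple((float(t), float(df)) for t, df in self.events)
        object.__setattr__(self, "events", events)
        times = [t for t, _ in events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        running = 0.0
        for _, df in events:
            running += df
            if running < -_TOL:
                raise ValueError("cumulative force must stay non-negative")

    # -- constructors -----------------------------------------------------
    @classmethod
    def single_pulse(cls, amplitude_nN: float, on_s: float, t_start: float = 0.0):
        if amplitude_nN < 0:
            raise ValueError("pulse amplitude must be non-negative")
        ev = ((t_start, amplitude_nN), (t_start + on_s, -amplitude_nN))
        return cls(ev, kind="single_pulse",
                   parameters={"amplitude_nN": amplitude_nN, "on_s": on_s})

    @classmethod
    def pulse_train(cls, amplitude_nN: float, on_s: float, off_s: float,
                    n_cycles: int, t_start: float = 0.0):
        if amplitude_nN < 0:
            raise ValueError("pulse amplitude must be non-negative")
        ev = []
        t = t_start
        for _ in range(int(n_cycles)):
            ev.append((t, amplitude_nN))
            ev.append((t + on_s, -amplitude_nN))
            t += on_s + off_s
        return cls(tuple(ev), kind="pulse_train",
                   parameters={"amplitude_nN": amplitude_nN, "on_s": on_s,
                               "off_s": off_s, "n_cycles": int(n_cycles)})

    @classmethod
    def staircase(cls, start_nN: float = 1.0, step_nN: float = 1.0,
                  max_nN: float = 5.0, step_s: float = 2.0,
                  t_start: float = 0.0, release: bool = True):
        """Force raised by ``step_nN`` every ``step_s`` from ``start_nN`` up
        to ``max_nN``; optionally released to zero after the last step."""
        if start_nN <= 0 or step_nN <= 0:
            raise ValueError("staircase forces must be positive")
        levels = np.arange(start_nN, max_nN + _TOL, step_nN)
        ev = [(t_start, start_nN)]
        for i in range(1, len(levels)):
            ev.append((t_start + i * step_s, step_nN))
        if release:
            ev.append((t_start + len(levels) * step_s, -float(levels[-1])))
        return cls(tuple(ev), kind="staircase",
                   parameters={"start_nN": start_nN, "step_nN": step_nN,
                               "max_nN": max_nN, "step_s": step_s})

    # -- queries ----------------------------------------------------------
    def force_at(self, t):
        """Instantaneous force (nN) at times ``t`` (right-continuous steps)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for tk, df in self.events:
            out = out + np.where(t >= tk - _TOL, df, 0.0)
        out = np.clip(out, 0.0, None)  # guard tiny negative rounding
        return out if out.ndim else float(out)

    @property
    def t_end(self) -> float:
        """Time of the last force-change event."""
        return self.events[-1][0] if self.events else 0.0

    def pulses(self) -> list[tuple[float, float, float]]:
        """Decompose into ``(t_on, t_off, force_nN)`` intervals of constant
        nonzero force (generic for all protocol kinds)."""
        out = []
        level = 0.0
        t_on = None
        for tk, df in self.events:
            new = level + df
            if level <= _TOL < new:
                t_on = tk
            if new <= _TOL < level and t_on is not None:
                out.append((t_on, tk, level))
                t_on = None
            elif abs(new - level) > _TOL and new > _TOL and level > _TOL:
                # force changed within an on-interval: close and reopen
                out.append((t_on, tk, level))
                t_on = tk
            level = new
        if t_on is not None and level > _TOL:
            out.append((t_on, np.inf, level))
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {"kind": self.kind, "parameters": self.parameters,
                "events": [[t, df] for t, df in self.events]}

    @classmethod
    def from_dict(cls, d: dict) -> "ForceProtocol":
        kind = d.get("kind", "custom")
        params = d.get("parameters") or {}
        if "events" in d and d["events"]:
            return cls(tuple((t, df) for t, df in d["events"]),
                       kind=kind, parameters=params or None)
        if kind == "single_pulse":
            return cls.single_pulse(params["amplitude_nN"], params["on_s"])
        if kind == "pulse_train":
            return cls.pulse_train(params["amplitude_nN"], params["on_s"],
                                   params["off_s"], params["n_cycles"])
        if kind == "staircase":
            return cls.staircase(params.get("start_nN", 1.0),
                                 params.get("step_nN", 1.0),
                                 params.get("max_nN", 5.0),
                                 params.get("step_s", 2.0))
        raise ValueError(f"cannot build protocol from {d!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ForceProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))
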