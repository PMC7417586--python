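"""Viscous-drag force calibration of the electromagnetic needle.

The force on a superparamagnetic bead depends on the coil current ``I`` and
the bead–needle distance ``d`` through an empirical power law with a
current-dependent exponent::

    F(I, d) = F0 * d ** c(I),        c(I) = c1 / (1 + c2 * exp(c3 * I))

with ``F0`` in nN for ``d`` in µm (the unit of ``F0`` formally depends on
the exponent; the convention is recorded with every persisted model).  The
parameters are obtained by dragging beads through a fluid of known
viscosity: the drift-corrected bead velocity in each constant-current pulse
gives the force via Stokes drag ``F = 6*pi*eta*R*v``; a per-current
power-law fit of force versus distance yields the exponent ``c(I)``, and a
second, nonlinear fit of the exponents versus current yields
``(c1, c2, c3)``.

Force feedback inverts the law analytically: the current required to hold a
force ``F`` at distance ``d`` is ::

    I(F, d) = (1 / c3) * ln( ((c1 * ln(d) / ln(F / F0)) - 1) / c2 )

which is the exact algebraic inverse of the two equations above.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CalibrationModel", "DragMeasurement", "IntervalVelocity",
    "ForceOutOfRangeError", "CalibrationRangeWarning",
    "stokes_force", "drift_corrected_velocity",
    "fit_force_distance", "fit_exponent_current", "fit_calibration",
    "force_at", "current_for_force", "required_current",
    "kinematic_to_dynamic_viscosity",
]

F0_UNIT_NOTE = "F0 in nN * um^(-c(I)); F in nN for d in um"


class ForceOutOfRangeError(ValueError):
    """Requested force unattainable at this distance within the current range."""


class CalibrationRangeWarning(UserWarning):
    """Evaluation outside the calibrated current/distance range (extrapolation)."""


def kinematic_to_dynamic_viscosity(kinematic_cSt: float,
                                   density_g_cm3: float = 0.97) -> float:
    """Convert a kinematic viscosity in centistokes to dynamic Pa*s.

    PDMS calibration fluids are specified in cSt; the density default is
    0.97 g/cm^3 (typical for high-viscosity PDMS) and configurable.
    """
    return kinematic_cSt * 1e-6 * density_g_cm3 * 1000.0


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted force–distance–current law and its validity ranges."""

    F0: float
    c1: float
    c2: float
    c3: float
    current_range: tuple[float, float] = (0.01, 3.0)
    distance_range: tuple[float, float] = (10.0, 150.0)
    saturation_current: float = 1.0
    f0_units: str = F0_UNIT_NOTE
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.distance_range
        if not (0 < lo < hi):
            raise ValueError("distance_range must be positive and increasing")
        ilo, ihi = self.current_range
        if not ilo < ihi:
            raise ValueError("current_range must be increasing")

    def exponent(self, current_A):
        """Current-dependent power-law exponent c(I)."""
        current_A = np.asarray(current_A, dtype=float)
        denom = 1.0 + self.c2 * np.exp(self.c3 * current_A)
        if np.any(np.abs(denom) < 1e-12):
            raise ValueError("c(I) diverges at this current")
        out = self.c1 / denom
        return out if out.ndim else float(out)

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["current_range"] = list(self.current_range)
        d["distance_range"] = list(self.distance_range)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(F0=d["F0"], c1=d["c1"], c2=d["c2"], c3=d["c3"],
                   current_range=tuple(d.get("current_range", (0.01, 3.0))),
                   distance_range=tuple(d.get("distance_range", (10.0, 150.0))),
                   saturation_current=d.get("saturation_current", 1.0),
                   f0_units=d.get("f0_units", F0_UNIT_NOTE),
                   diagnostics=d.get("diagnostics", {}))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class DragMeasurement:
    """One calibration point: drift-corrected velocity at a known current
    and distance, with the Stokes force it implies."""

    current_A: float
    distance_um: float
    velocity_um_s: float
    viscosity_pa_s: float
    bead_radius_um: float
    force_nN: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if not self.distance_um > 0:
            raise ValueError("distance must be positive")
        f = stokes_force(self.velocity_um_s, self.bead_radius_um, self.viscosity_pa_s)
        if self.force_nN is None:
            object.__setattr__(self, "force_nN", f)
        elif not math.isclose(self.force_nN, f, rel_tol=1e-6, abs_tol=1e-12):
            raise ValueError("force inconsistent with Stokes drag")


@dataclass(frozen=True)
class IntervalVelocity:
    """Drift-corrected velocity for one current-on interval."""

    t_mid_s: float
    distance_um: float
    velocity_um_s: float
    drift_um_s: float
    flags: tuple[str, ...] = ()


def stokes_force(velocity_um_s, bead_radius_um: float, viscosity_pa_s: float):
    """Stokes drag force in nN: F = 6*pi*eta*R*v.

    With R in µm and v in µm/s, F[nN] = 6*pi*eta*R*v*1e-3 exactly (the SI
    evaluation times 1e9).
    """
    if not np.all(np.isfinite(velocity_um_s)):
        raise ValueError("velocity must be finite")
    if not bead_radius_um > 0:
        raise ValueError("bead radius must be positive")
    if viscosity_pa_s < 0:
        raise ValueError("viscosity must be non-negative")
    out = 6.0 * np.pi * viscosity_pa_s * bead_radius_um * np.asarray(velocity_um_s, dtype=float) * 1e-3
    return out if np.ndim(out) else float(out)


def _slope(t: np.ndarray, s: np.ndarray) -> float:
    """Least-squares slope of s versus t."""
    t = t - t.mean()
    return float(t @ (s - s.mean()) / (t @ t))


def drift_corrected_velocity(traj, on_intervals, needle_position_um=(0.0, 0.0),
                             smooth_window: int = 5) -> list[IntervalVelocity]:
    """Per-pulse bead speed toward the needle, minus sedimentation drift.

    The scalar record is the Euclidean bead–needle distance; its slope
    within each current-on interval gives the raw speed, and the mean slope
    of the flanking current-off windows estimates the drift, which is
    subtracted.  Distance is reported at the interval midpoint.

    Parameters
    ----------
    traj:
        :class:`~magrheo.trajectory.BeadTrajectory`.
    on_intervals:
        Sequence of ``(t_on, t_off)`` pairs within the trajectory span.
    smooth_window:
        Odd moving-average window applied to the distance record before
        differentiation (1 disables smoothing).
    """
    t = traj.time_s
    s = traj.distance_to(needle_position_um)
    if smooth_window > 1:
        k = int(smooth_window) | 1
        pad = k // 2
        # odd reflection preserves linear trends at the record edges
        sp = np.pad(s, pad, mode="reflect", reflect_type="odd")
        s = np.convolve(sp, np.ones(k) / k, mode="valid")
    on_intervals = sorted((float(a), float(b)) for a, b in on_intervals)
    for a, b in on_intervals:
        if a < t[0] - 1e-9 or b > t[-1] + 1e-9:
            raise ValueError("schedule interval outside trajectory span")

    # off windows: before first pulse, gaps between pulses, after last pulse
    edges = [t[0]] + [x for ab in on_intervals for x in ab] + [t[-1]]
    off_windows = [(edges[2 * i], edges[2 * i + 1]) for i in range(len(on_intervals) + 1)]

    def window_slope(a, b):
        m = (t >= a - 1e-9) & (t <= b + 1e-9)
        if m.sum() < 2:
            return None
        return _slope(t[m], s[m])

    out = []
    for i, (a, b) in enumerate(on_intervals):
        m = (t >= a - 1e-9) & (t <= b + 1e-9)
        if m.sum() < 2:
            raise ValueError(f"fewer than 2 samples in on-interval {i}")
        raw = _slope(t[m], s[m])
        before = window_slope(*off_windows[i])
        after = window_slope(*off_windows[i + 1])
        flags = []
        drifts = [x for x in (before, after) if x is not None]
        if not drifts:
            drift = 0.0
            flags.append("no_off_phase")
        else:
            if before is None:
                flags.append("following_off_only")
            if after is None:
                flags.append("preceding_off_only")
            drift = float(np.mean(drifts))
        t_mid = 0.5 * (a + b)
        d_mid = float(np.interp(t_mid, t, s))
        # speeds toward the needle are positive (distance decreases)
        out.append(IntervalVelocity(t_mid_s=t_mid, distance_um=d_mid,
                                    velocity_um_s=-(raw - drift),
                                    drift_um_s=-drift, flags=tuple(flags)))
    return out


@dataclass(frozen=True)
class ForceDistanceFit:
    """Per-current power-law fit F = F0_I * d**c_I (log–log regression)."""

    current_A: float
    F0_I: float
    exponent: float
    r_squared: float
    n: int


def fit_force_distance(distances_um, forces_nN, current_A: float = np.nan) -> ForceDistanceFit:
    """Fit ``F = F0_I * d**c_I`` for one current by linear regression in
    log–log space."""
    d = np.asarray(distances_um, dtype=float)
    f = np.asarray(forces_nN, dtype=float)
    if np.any(d <= 0) or np.any(f <= 0):
        raise ValueError("distances and forces must be positive")
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct distances")
    res = stats.linregress(np.log(d), np.log(f))
    if res.slope >= 0:
        warnings.warn("fitted force–distance exponent is non-negative "
                      "(force should decay with distance)", CalibrationRangeWarning,
                      stacklevel=2)
    return ForceDistanceFit(current_A=float(current_A),
                            F0_I=float(np.exp(res.intercept)),
                            exponent=float(res.slope),
                            r_squared=float(res.rvalue ** 2), n=d.size)


@dataclass(frozen=True)
class ExponentCurrentFit:
    c1: float
    c2: float
    c3: float
    r_squared: float
    boundary: bool = False


def _cI(I, c1, c2, c3):
    return c1 / (1.0 + c2 * np.exp(c3 * I))


def fit_exponent_current(currents_A, exponents) -> ExponentCurrentFit:
    """Fit ``c(I) = c1 / (1 + c2 * exp(c3 * I))`` by nonlinear least squares
    with multi-start initialization over sign combinations."""
    I = np.asarray(currents_A, dtype=float)
    c = np.asarray(exponents, dtype=float)
    if np.unique(I).size < 4:
        raise ValueError("need at least 4 distinct currents")
    if np.ptp(c) < 1e-12:
        # degenerate: exponent independent of current
        return ExponentCurrentFit(c1=float(c[0]), c2=0.0, c3=0.0,
                                  r_squared=1.0, boundary=True)
    cbar = float(np.mean(c))
    best = None
    scale = 1.0 / max(np.ptp(I), 1e-6)
    for c1_0 in (2 * cbar, 0.5 * cbar, c[np.argmax(np.abs(c))] * 1.5):
        for c2_0 in (0.5, 2.0, -0.5):
            for c3_0 in (scale, -scale, 3 * scale, -3 * scale):
                try:
                    popt, _ = optimize.curve_fit(_cI, I, c, p0=(c1_0, c2_0, c3_0),
                                                 maxfev=20000)
                except (RuntimeError, ValueError):
                    continue
                resid = c - _cI(I, *popt)
                sse = float(resid @ resid)
                if best is None or sse < best[0]:
                    best = (sse, popt)
    if best is None:
        raise RuntimeError("exponent–current fit failed from all starting points")
    sse, popt = best
    sst = float(np.sum((c - cbar) ** 2))
    return ExponentCurrentFit(c1=float(popt[0]), c2=float(popt[1]), c3=float(popt[2]),
                              r_squared=1.0 - sse / sst if sst > 0 else 1.0)


def fit_calibration(table: pd.DataFrame, viscosity_pa_s: float,
                    bead_radius_um: float,
                    saturation_current: float = 1.0) -> CalibrationModel:
    """Two-stage calibration fit from a drag-measurement table.

    ``table`` needs columns ``current_A``, ``distance_um`` and either
    ``force_nN`` or ``velocity_um_s`` (converted via Stokes drag).  Returns
    a :class:`CalibrationModel` whose global ``F0`` is the geometric mean of
    the per-current prefactors; per-current fits are kept in
    ``diagnostics``.
    """
    df = table.copy()
    if "force_nN" not in df:
        df["force_nN"] = stokes_force(df["velocity_um_s"].to_numpy(),
                                      bead_radius_um, viscosity_pa_s)
    per_current = []
    for current, grp in df.groupby("current_A"):
        per_current.append(fit_force_distance(grp["distance_um"], grp["force_nN"],
                                              current_A=current))
    if len(per_current) < 4:
        raise ValueError("need at least 4 distinct currents")
    currents = np.array([f.current_A for f in per_current])
    exponents = np.array([f.exponent for f in per_current])
    efit = fit_exponent_current(currents, exponents)
    F0 = float(np.exp(np.mean([np.log(f.F0_I) for f in per_current])))
    diagnostics = {
        "per_current": [asdict(f) for f in per_current],
        "exponent_fit_r_squared": efit.r_squared,
        "exponent_fit_boundary": efit.boundary,
        "n_measurements": int(len(df)),
    }
    return CalibrationModel(
        F0=F0, c1=efit.c1, c2=efit.c2, c3=efit.c3,
        current_range=(float(currents.min()), float(currents.max())),
        distance_range=(float(df["distance_um"].min()), float(df["distance_um"].max())),
        saturation_current=saturation_current, diagnostics=diagnostics)


def force_at(cal: CalibrationModel, current_A: float, distance_um: float,
             warn_extrapolation: bool = True) -> float:
    """Force in nN at a given coil current and bead–needle distance.

    Currents above the saturation current are clamped (the core cannot be
    magnetized further) with a warning; evaluation outside the calibrated
    ranges is flagged as extrapolation.
    """
    if not distance_um > 0:
        raise ValueError("distance must be positive")
    I = float(current_A)
    if I > cal.saturation_current:
        warnings.warn(f"current {I} A above saturation "
                      f"({cal.saturation_current} A); clamped",
                      CalibrationRangeWarning, stacklevel=2)
        I = cal.saturation_current
    if warn_extrapolation:
        ilo, ihi = cal.current_range
        dlo, dhi = cal.distance_range
        if not (ilo <= I <= ihi) or not (dlo <= distance_um <= dhi):
            warnings.warn("evaluating calibration outside its fitted range",
                          CalibrationRangeWarning, stacklevel=2)
    return cal.F0 * distance_um ** cal.exponent(I)


def required_current(cal: CalibrationModel, force_nN: float,
                     distance_um: float) -> float:
    """Unclamped current solving the calibration law for a target force.

    Inverts ``F = F0 d^{c(I)}`` and ``c(I) = c1/(1 + c2 exp(c3 I))``
    exactly; raises :class:`ForceOutOfRangeError` when the needed exponent
    lies outside the image of c(I) (log arguments non-positive).
    """
    if not distance_um > 0:
        raise ValueError("distance must be positive")
    if not force_nN > 0:
        raise ValueError("force must be positive")
    if abs(math.log(distance_um)) < 1e-12:
        raise ForceOutOfRangeError("distance of 1 um makes the exponent unidentifiable")
    ratio = math.log(force_nN / cal.F0)
    if abs(ratio) < 1e-15:
        raise ForceOutOfRangeError("requested force needs exponent 0, "
                                   "unreachable for c1 != 0")
    c_needed = ratio / math.log(distance_um)
    arg = (cal.c1 / c_needed - 1.0) / cal.c2 if cal.c2 != 0 else -1.0
    if arg <= 0:
        raise ForceOutOfRangeError(
            f"force {force_nN} nN at {distance_um} um needs exponent {c_needed:.4g}, "
            "outside the attainable range of c(I)")
    return math.log(arg) / cal.c3


def current_for_force(cal: CalibrationModel, force_nN: float,
                      distance_um: float) -> float:
    """Coil current that yields ``force_nN`` at ``distance_um``.

    Exact algebraic inverse of the calibration law; raises
    :class:`ForceOutOfRangeError` when no current in the valid range (and
    below saturation) attains the requested force.
    """
    I = required_current(cal, force_nN, distance_um)
    lo = cal.current_range[0]
    hi = min(cal.current_range[1], cal.saturation_current)
    if not (lo - 1e-9 <= I <= hi + 1e-9):
        raise ForceOutOfRangeError(
            f"required current {I:.4g} A outside [{lo}, {hi}] A")
    return float(I)
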