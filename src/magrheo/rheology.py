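"""Creep-compliance rheology: from bead displacements to material
parameters.

Stress and strain are defined on the bead geometry: the contact area is
approximated by the bead cross-section ``A = pi r^2``, so a force step
``dF`` applies a stress ``sigma = dF / (pi r^2)``; the strain is the bead
displacement over its radius, ``eps = d(t) / r``.  The creep compliance is
their ratio, which reduces to scaling the displacement curve by
``pi r / dF``::

    J(t) [1/Pa] = d(t) * pi * r / dF        (1e-3 * pi * r[um] * d[um] / dF[nN])

Stepwise protocols are analyzed by Boltzmann superposition: for a linear
viscoelastic material the displacement under a sequence of force changes
``dF_k`` at times ``t_k`` is ``d(t) = (1/(pi r)) * sum_k dF_k J(t - t_k)``.
Pulse trains and staircases are fitted per cycle/step on the incremental
response, with the residual creep of earlier events subtracted using the
previously fitted processes ("history-corrected"); relaxation after
force-off is fitted as the superposition of the ongoing creep process and
a new, independent power-law recovery process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .material import MaterialModel, kelvin_voigt_compliance, power_law_compliance
from .protocol import ForceProtocol
from .trajectory import BeadTrajectory

__all__ = [
    "CreepCurve", "CreepFit", "RecoveryFit", "StaircaseResult",
    "displacement_to_compliance", "compliance_to_displacement",
    "fit_power_law", "fit_kelvin_voigt", "superpose",
    "fit_pulse_train", "fit_staircase", "fit_recovery",
]

#: J [1/Pa] per (d [um] * r [um] / dF [nN])
_J_PER_DISP = np.pi * 1e-3


def displacement_to_compliance(times_s, displacement_um, dF_nN: float,
                               bead_radius_um: float) -> "CreepCurve":
    """Scale a displacement curve to creep compliance, J = d * pi * r / dF."""
    if not dF_nN > 0:
        raise ValueError("force step must be positive")
    if not bead_radius_um > 0:
        raise ValueError("bead radius must be positive")
    t = np.asarray(times_s, dtype=float)
    d = np.asarray(displacement_um, dtype=float)
    stress_pa = dF_nN * 1e-9 / (np.pi * (bead_radius_um * 1e-6) ** 2)
    strain = d / bead_radius_um
    return CreepCurve(times_s=t, J=strain / stress_pa, stress_pa=stress_pa,
                      strain=strain, bead_radius_um=bead_radius_um)


def compliance_to_displacement(J, dF_nN: float, bead_radius_um: float):
    """Displacement in µm for a compliance value under a force step."""
    return 1e3 * dF_nN * np.asarray(J, dtype=float) / (np.pi * bead_radius_um)


@dataclass
class CreepCurve:
    """Creep compliance versus time (relative to the stress-step onset)."""

    times_s: np.ndarray
    J: np.ndarray
    stress_pa: float
    strain: np.ndarray | None = None
    bead_radius_um: float | None = None

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.times_s.shape != self.J.shape:
            raise ValueError("times and J must have identical shape")
        if np.any(self.times_s < 0):
            raise ValueError("times must be non-negative")


@dataclass
class CreepFit:
    """Fitted rheological parameters of a creep curve.

    ``stiffness_pa`` is 1/J0, the material stiffness at the 1 s reference
    time for the power law.
    """

    model: str
    J0: float
    beta: float | None = None
    tau: float | None = None
    t0: float = 1.0
    r_squared: float = np.nan
    n_points: int = 0
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.J0 > 0:
            raise ValueError("J0 must be positive")

    @property
    def stiffness_pa(self) -> float:
        return 1.0 / self.J0

    def compliance(self, t):
        if self.model == "power_law":
            return power_law_compliance(t, self.J0, self.beta, self.t0)
        return kelvin_voigt_compliance(t, self.J0, self.tau)


@dataclass
class RecoveryFit:
    """Power-law recovery process fitted to the post-force-off relaxation,
    superposed on the frozen creep process."""

    creep: CreepFit
    recovery_J0: float
    recovery_beta: float
    r_squared: float
    flags: dict = field(default_factory=dict)

    @property
    def recovery_stiffness_pa(self) -> float:
        return 1.0 / self.recovery_J0


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)


def _prepare(curve: CreepCurve, min_points: int):
    m = curve.times_s > 0
    t, J = curve.times_s[m], curve.J[m]
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} samples with t > 0")
    flags = {}
    if np.mean(J) < 0:
        flags["negative_compliance"] = True
        warnings.warn("creep curve is dominated by negative compliance; "
                      "fit returned with a warning flag", stacklevel=3)
    return t, J, flags


def fit_power_law(curve: CreepCurve, min_points: int = 5) -> CreepFit:
    """Fit J(t) = J0 (t/t0)^beta in linear space; t0 = 1 s.

    The t = 0 sample is excluded (the reference-time parameterization has
    singular support there).  Initialization comes from a log–log
    regression where possible.
    """
    t, J, flags = _prepare(curve, min_points)
    pos = J > 0
    if pos.sum() >= 2 and np.ptp(np.log(t[pos])) > 0:
        A = np.polyfit(np.log(t[pos]), np.log(J[pos]), 1)
        beta0 = float(np.clip(A[0], 0.0, 1.5))
        J0_0 = float(np.exp(A[1]))
    else:
        beta0, J0_0 = 0.3, max(float(np.mean(np.abs(J))), 1e-12)

    def f(tt, J0, beta):
        return J0 * np.power(tt, beta)

    popt, _ = optimize.curve_fit(f, t, J, p0=(J0_0, beta0),
                                 bounds=([1e-15, 0.0], [np.inf, 2.0]),
                                 maxfev=20000)
    J0, beta = float(popt[0]), float(popt[1])
    if beta > 1.0:
        flags["beta_above_physical_range"] = True
    return CreepFit(model="power_law", J0=J0, beta=beta,
                    r_squared=_r_squared(J, f(t, *popt)),
                    n_points=t.size, flags=flags)


def fit_kelvin_voigt(curve: CreepCurve, min_points: int = 5) -> CreepFit:
    """Fit the Kelvin–Voigt creep J(t) = J0 (1 - exp(-t/tau))."""
    t, J, flags = _prepare(curve, min_points)
    J0_0 = max(float(np.max(J)), 1e-12)
    tau0 = float(np.median(t))

    def f(tt, J0, tau):
        return J0 * (1.0 - np.exp(-tt / tau))

    popt, pcov = optimize.curve_fit(f, t, J, p0=(J0_0, tau0),
                                    bounds=([1e-15, 1e-9], [np.inf, np.inf]),
                                    maxfev=20000)
    J0, tau = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    # tau is unidentifiable when its std error rivals it, or when every
    # sample sits on the plateau (no data in the exponential rise)
    if (not np.all(np.isfinite(perr))
            or (np.isfinite(perr[1]) and perr[1] > tau)
            or float(t.min()) > 3.0 * tau):
        flags["tau_poorly_constrained"] = True
    return CreepFit(model="kelvin_voigt", J0=J0, tau=tau,
                    r_squared=_r_squared(J, f(t, *popt)),
                    n_points=t.size, flags=flags)


def superpose(compliance, protocol: ForceProtocol, bead_radius_um: float,
              times_s) -> np.ndarray:
    """Predicted displacement (µm) of a protocol on a linear material.

    ``compliance`` is a :class:`MaterialModel`, a :class:`CreepFit`, or a
    callable J(t) (evaluated only at t >= 0).  Exact additivity over
    events; a single event reduces to ``d = J(t) dF / (pi r)``.
    """
    J = compliance.compliance if hasattr(compliance, "compliance") else compliance
    times_s = np.asarray(times_s, dtype=float)
    d = np.zeros_like(times_s)
    scale = 1e3 / (np.pi * bead_radius_um)
    for tk, df in protocol.events:
        m = times_s >= tk
        if np.any(m):
            d[m] += scale * df * np.asarray(J(times_s[m] - tk), dtype=float)
    return d


def _history_background(times_s, fitted, events_done, bead_radius_um):
    """Displacement contributed by already-fitted events at ``times_s``."""
    scale = 1e3 / (np.pi * bead_radius_um)
    bg = np.zeros_like(times_s, dtype=float)
    for (tk, df), fit in zip(events_done, fitted):
        m = times_s >= tk
        if np.any(m):
            bg[m] += scale * df * fit.compliance(times_s[m] - tk)
    return bg


def _joint_superposition_fit(t, disp, segments, windows, bead_radius_um,
                             beta_max: float = 1.5):
    """Fit one power-law process per protocol segment, jointly.

    ``segments`` is a list of ``(t_on, t_off_or_None, dF)``: segment k
    contributes ``dF * J_k(t - t_on)`` and, if ``t_off`` is given,
    ``-dF * J_k(t - t_off)`` (the same process reversed at force-off).
    ``windows`` gives the (lo, hi] sample window each segment is judged on;
    all windows enter one least-squares problem, so early-segment errors
    cannot cascade into later segments the way a sequential
    subtract-and-refit would.

    Returns a list of CreepFit (power law), with per-window R².
    """
    n = len(segments)
    scale = 1e3 / (np.pi * bead_radius_um)
    masks = [(t > lo) & (t <= hi) for lo, hi in windows]
    sel = np.logical_or.reduce(masks) if masks else np.zeros(t.size, bool)
    tt, dd = t[sel], disp[sel]
    sub_masks = [(tt > lo) & (tt <= hi) for lo, hi in windows]

    def model(params, times):
        J0s, betas = params[:n], params[n:]
        out = np.zeros_like(times)
        for (ton, toff, dF), J0, b in zip(segments, J0s, betas):
            mon = times >= ton
            out[mon] += scale * dF * J0 * np.power(times[mon] - ton, b)
            if toff is not None:
                moff = times >= toff
                out[moff] -= scale * dF * J0 * np.power(times[moff] - toff, b)
        return out

    # initialize from independent re-zeroed per-window fits
    J0_0, beta_0 = [], []
    for (lo, hi), mask, (ton, _, dF) in zip(windows, masks, segments):
        inc = disp[mask] - float(np.interp(lo, t, disp))
        try:
            curve = displacement_to_compliance(t[mask] - ton, inc, dF,
                                               bead_radius_um)
            f = fit_power_law(curve, min_points=min(5, int(mask.sum())))
            J0_0.append(f.J0)
            beta_0.append(min(f.beta, beta_max - 1e-6))
        except (RuntimeError, ValueError):
            J0_0.append(max(float(np.mean(np.abs(inc))) * np.pi *
                            bead_radius_um * 1e-3 / dF, 1e-12))
            beta_0.append(0.3)
    x0 = np.array(J0_0 + beta_0)
    lb = np.array([1e-15] * n + [0.0] * n)
    ub = np.array([np.inf] * n + [beta_max] * n)
    res = optimize.least_squares(lambda p: model(p, tt) - dd, x0,
                                 bounds=(lb, ub), max_nfev=20000)
    J0s, betas = res.x[:n], res.x[n:]
    yhat = model(res.x, tt)
    fits = []
    for k, mask in enumerate(sub_masks):
        fits.append(CreepFit(model="power_law", J0=float(J0s[k]),
                             beta=float(betas[k]),
                             r_squared=_r_squared(dd[mask], yhat[mask]),
                             n_points=int(mask.sum())))
    return fits


def fit_pulse_train(traj: BeadTrajectory, protocol: ForceProtocol,
                    bead_radius_um: float | None = None,
                    history_corrected: bool = True,
                    min_points: int = 5) -> list[CreepFit]:
    """Per-cycle power-law fits of a consecutive-pulse protocol.

    Each cycle's on-phase is fitted with its own power-law process.  In the
    default history-corrected mode all cycles are fitted *jointly*: the
    model is the full Boltzmann superposition of every pulse's creep and
    recovery, each with its own (J0, beta), solved in one least-squares
    problem (sequentially subtracting previously fitted processes lets
    early-cycle errors cascade).  The non-corrected mode simply re-zeroes
    the displacement at each pulse onset and fits cycles independently.
    Cycles with too few samples are omitted; ``flags["cycle"]`` keeps the
    original cycle index.
    """
    r = bead_radius_um or traj.bead_radius_um
    t = traj.time_s
    disp = traj.displacement_um()
    pulses = protocol.pulses()
    if not pulses:
        return []
    if history_corrected:
        segments = [(t_on, t_off, force) for t_on, t_off, force in pulses]
        windows = [(t_on, t_off) for t_on, t_off, _ in pulses]
        fits = _joint_superposition_fit(t, disp, segments, windows, r)
        out = []
        for k, fit in enumerate(fits):
            if fit.n_points < min_points:
                continue
            fit.flags["cycle"] = k
            out.append(fit)
        return out
    fits: list[CreepFit] = []
    for k, (t_on, t_off, force) in enumerate(pulses):
        m = (t > t_on) & (t <= t_off)
        if m.sum() < min_points:
            continue
        inc = disp[m] - float(np.interp(t_on, t, disp))
        curve = displacement_to_compliance(t[m] - t_on, inc, force, r)
        try:
            fit = fit_power_law(curve, min_points=min_points)
        except (RuntimeError, ValueError):
            continue
        fit.flags["cycle"] = k
        fits.append(fit)
    return fits


@dataclass
class StaircaseResult:
    fits: list[CreepFit]
    forces_nN: list[float]
    stiffness_fold_change: float
    beta_fold_change: float


def fit_staircase(traj: BeadTrajectory, protocol: ForceProtocol,
                  bead_radius_um: float | None = None,
                  history_corrected: bool = True, min_points: int = 5,
                  incremental_stress: bool = True) -> StaircaseResult:
    """Per-step power-law fits of a staircase protocol and the fold change.

    Each step is fitted on the incremental response to its force increment
    ``dF`` (history handled by superposition of the previously fitted
    processes).  With ``incremental_stress=False`` the absolute force level
    is used instead and no history subtraction is applied (the alternative
    reading of per-step analysis).  Fold changes are last/first ratios of
    stiffness and fluidity across force levels.
    """
    r = bead_radius_um or traj.bead_radius_um
    t = traj.time_s
    disp = traj.displacement_um()
    events = [e for e in protocol.events if e[1] > 0]
    if any(df < 0 for _, df in protocol.events[:-1]):
        raise ValueError("staircase schedule must be non-decreasing until release")
    # end of each step = next event time (release event included) or traj end
    all_times = [tk for tk, _ in protocol.events] + [t[-1]]
    step_windows = []
    levels = []
    level = 0.0
    for k, (tk, df) in enumerate(events):
        level += df
        levels.append(level)
        t_next = min(x for x in all_times if x > tk)
        if np.sum((t > tk) & (t <= t_next)) < min_points:
            raise ValueError(f"step {k} has fewer than {min_points} samples")
        step_windows.append((tk, t_next))
    fits: list[CreepFit] = []
    forces: list[float] = []
    if incremental_stress and history_corrected:
        segments = [(tk, None, df) for tk, df in events]
        fits = _joint_superposition_fit(t, disp, segments, step_windows, r)
        for k, fit in enumerate(fits):
            fit.flags["step"] = k
            fit.flags["force_nN"] = levels[k]
        forces = levels
    else:
        for k, ((tk, df), (lo, hi)) in enumerate(zip(events, step_windows)):
            m = (t > lo) & (t <= hi)
            if incremental_stress:
                inc = disp[m] - float(np.interp(tk, t, disp))
                curve = displacement_to_compliance(t[m] - tk, inc, df, r)
            else:
                curve = displacement_to_compliance(t[m] - tk, disp[m],
                                                   levels[k], r)
            fit = fit_power_law(curve, min_points=min_points)
            fit.flags["step"] = k
            fit.flags["force_nN"] = levels[k]
            fits.append(fit)
            forces.append(levels[k])
    sfc = fits[-1].stiffness_pa / fits[0].stiffness_pa if fits else np.nan
    bfc = (fits[-1].beta / fits[0].beta
           if fits and fits[0].beta not in (None, 0) else np.nan)
    return StaircaseResult(fits=fits, forces_nN=forces,
                           stiffness_fold_change=float(sfc),
                           beta_fold_change=float(bfc))


def fit_recovery(traj: BeadTrajectory, creep_fit: CreepFit, t_off_s: float,
                 dF_nN: float, bead_radius_um: float | None = None,
                 t_on_s: float = 0.0, min_points: int = 5) -> RecoveryFit:
    """Fit the relaxation after force-off as a superposition of the ongoing
    (frozen) creep process and a new power-law recovery process::

        d(t > t_off) = (1/(pi r)) * [dF * J_creep(t - t_on) - dF * J_rec(t - t_off)]

    The recovery stiffness 1/J0_rec and fluidity beta_rec quantify how
    completely the material springs back; J0_rec = J0_creep means full
    recovery of a linear material, a smaller recovery compliance indicates
    plastic (unrecovered) deformation.
    """
    r = bead_radius_um or traj.bead_radius_um
    t = traj.time_s
    disp = traj.displacement_um()
    m = t > t_off_s
    if m.sum() < min_points:
        raise ValueError(f"need at least {min_points} samples after force-off")
    tt = t[m]
    dd = disp[m]
    flags = {}
    tail = dd[tt - t_off_s > 0]
    if tail.size >= 2 and np.polyfit(tt, dd, 1)[0] >= 0:
        flags["no_recovery"] = True
    scale = 1e3 * dF_nN / (np.pi * r)
    ongoing = scale * creep_fit.compliance(tt - t_on_s)

    def f(ts, J0r, betar):
        return ongoing - scale * J0r * np.power(ts - t_off_s, betar)

    # initial guess: the recovery process mirrors the creep process
    p0 = (creep_fit.J0, creep_fit.beta if creep_fit.beta is not None else 0.3)
    popt, _ = optimize.curve_fit(f, tt, dd, p0=p0,
                                 bounds=([1e-15, 0.0], [np.inf, 2.0]),
                                 maxfev=20000)
    return RecoveryFit(creep=creep_fit, recovery_J0=float(popt[0]),
                       recovery_beta=float(popt[1]),
                       r_squared=_r_squared(dd, f(tt, *popt)), flags=flags)
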