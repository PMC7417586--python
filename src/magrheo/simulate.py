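"""Virtual magnetic-tweezer instrument.

Generates every input the analysis pipeline consumes, with known ground
truth: viscous-drag trajectories under a current schedule, viscoelastic
creep displacements under a force protocol, rendered brightfield image
sequences (dark bead and dark conical needle on a bright background),
log-normal/normal per-bead parameter populations, and synthetic 3D fiber
networks with known pore geometry.

The bead moves along the +x axis toward the needle tip at the origin; the
bead–needle distance is simply the bead's x coordinate in drag simulations.
Noise models (the real instrument's noise magnitudes are not specified
anywhere, so these are implementation defaults, documented in the methods
note): additive Gaussian noise on positions; Gaussian read noise and
optional Poisson shot noise on images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import CalibrationModel, force_at
from .images import ImageStack
from .material import MaterialModel
from .protocol import ForceProtocol
from .trajectory import BeadTrajectory

__all__ = [
    "NeedleGeometry", "SimulationConfig", "PopulationSample",
    "simulate_drag_trajectory", "simulate_creep_displacement",
    "render_image_sequence", "sample_population",
    "synth_collagen_volume", "synth_cavity_volume",
    "simulate_calibration_table",
]

STOKES_UM = 1e3 / (6.0 * np.pi)  # v[um/s] = STOKES_UM * F[nN] / (eta * R[um])


@dataclass(frozen=True)
class NeedleGeometry:
    """Conical needle silhouette: a wedge with a rounded tip.

    ``tip_position_um`` is the foremost point of the rounded tip;
    ``orientation`` is a unit vector pointing from the tip into the needle
    body (the direction in which the wedge widens).  Defaults follow the
    instrument: 35 degrees opening angle, 10 µm tip curvature radius.
    """

    tip_position_um: tuple[float, float] = (0.0, 0.0)
    opening_angle_deg: float = 35.0
    tip_curvature_radius_um: float = 10.0
    orientation: tuple[float, float] = (-1.0, 0.0)

    def __post_init__(self):
        if not 0.0 < self.opening_angle_deg < 180.0:
            raise ValueError("opening angle must lie in (0, 180) degrees")
        if not self.tip_curvature_radius_um > 0:
            raise ValueError("tip curvature radius must be positive")
        u = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(u)
        if n == 0:
            raise ValueError("orientation must be a nonzero vector")
        object.__setattr__(self, "orientation", tuple(u / n))

    # Geometry: the rounded wedge is the union of the tangent disk of radius
    # R_t (center C on the axis, front point = tip_position) and the wedge
    # from the virtual apex A truncated behind the tangency line.  With half
    # angle h: |A C| = R_t / sin(h), so A = tip - u * R_t * (1 - sin h)/sin h
    # lies *ahead* of the physical tip.
    @property
    def _half_angle_rad(self) -> float:
        return math.radians(self.opening_angle_deg) / 2.0

    @property
    def _disk_center(self) -> np.ndarray:
        u = np.asarray(self.orientation)
        return np.asarray(self.tip_position_um) + u * self.tip_curvature_radius_um

    @property
    def _apex(self) -> np.ndarray:
        h = self._half_angle_rad
        L = self.tip_curvature_radius_um / math.sin(h)
        return self._disk_center - np.asarray(self.orientation) * L

    def contains(self, points_um: np.ndarray) -> np.ndarray:
        """Boolean inside-test for an (n, 2) array of points (µm)."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        u = np.asarray(self.orientation)
        h = self._half_angle_rad
        C = self._disk_center
        A = self._apex
        L = self.tip_curvature_radius_um / math.sin(h)
        in_disk = np.einsum("ij,ij->i", p - C, p - C) <= self.tip_curvature_radius_um ** 2
        rel = p - A
        ax = rel @ u
        r = np.linalg.norm(rel, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            in_cone = (ax > 0) & (ax >= r * math.cos(h))
        beyond_tangency = ax >= L * math.cos(h) ** 2
        return in_disk | (in_cone & beyond_tangency)

    def surface_distance(self, point_um) -> float:
        """Distance from a point to the needle surface (0 if inside)."""
        p = np.asarray(point_um, dtype=float)
        if self.contains(p[None])[0]:
            return 0.0
        u = np.asarray(self.orientation)
        h = self._half_angle_rad
        C = self._disk_center
        A = self._apex
        L = self.tip_curvature_radius_um / math.sin(h)
        d_disk = np.linalg.norm(p - C) - self.tip_curvature_radius_um
        # flank rays start at the tangency points and run along the flanks
        perp = np.array([-u[1], u[0]])
        dists = [d_disk]
        for sgn in (+1.0, -1.0):
            fdir = u * math.cos(h) + sgn * perp * math.sin(h)
            start = A + fdir * (L * math.cos(h))
            rel = p - start
            tproj = max(rel @ fdir, 0.0)
            dists.append(np.linalg.norm(rel - tproj * fdir))
        return float(min(dists))


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knobs of the virtual instrument.

    Defaults: 40 Hz frame rate (the camera's acquisition rate), 4.5 µm bead
    diameter (M-450 superparamagnetic beads), 0.15 µm/px.
    """

    frame_rate_hz: float = 40.0
    noise_sd_position_um: float = 0.0
    drift_velocity_um_s: float = 0.0
    seed: int = 0
    pixel_size_um: float = 0.15
    bead_diameter_um: float = 4.5

    def __post_init__(self):
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size must be positive")
        if not self.bead_diameter_um > 0:
            raise ValueError("bead diameter must be positive")
        if self.noise_sd_position_um < 0:
            raise ValueError("noise sd must be non-negative")

    @property
    def bead_radius_um(self) -> float:
        return self.bead_diameter_um / 2.0

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


def _schedule_current(schedule, t: float) -> float:
    for start, stop, current in schedule:
        if start <= t < stop:
            return float(current)
    return 0.0


def simulate_drag_trajectory(cal: CalibrationModel, viscosity_pa_s: float,
                             bead_radius_um: float, schedule,
                             start_distance_um: float, cfg: SimulationConfig,
                             duration_s: float | None = None,
                             oversample: int = 50) -> BeadTrajectory:
    """Integrate drag motion of a bead under a piecewise-constant current.

    ``schedule`` is a sequence of ``(start_s, stop_s, current_A)`` pulses
    (zero current elsewhere — zero current means zero force, the field is
    off).  Motion follows ``dx/dt = -F(I, x)/(6 pi eta R) + v_drift``, with
    ``x`` the bead–needle distance, integrated with an explicit midpoint
    scheme at ``oversample`` times the frame rate and sampled down.  If the
    bead reaches the needle (x <= bead radius) the record is truncated and
    flagged.
    """
    if not viscosity_pa_s > 0:
        raise ValueError("viscosity must be positive")
    dlo, dhi = cal.distance_range
    if not (dlo <= start_distance_um <= dhi):
        raise ValueError("start distance outside calibration validity range")
    if duration_s is None:
        duration_s = max(stop for _, stop, _ in schedule) if schedule else 1.0
    dt_frame = 1.0 / cfg.frame_rate_hz
    n_frames = int(round(duration_s / dt_frame)) + 1
    dt = dt_frame / oversample
    mobility = STOKES_UM / (viscosity_pa_s * bead_radius_um)  # um/s per nN

    def speed(x, t):
        I = _schedule_current(schedule, t)
        if I == 0.0 or x <= 0:
            pull = 0.0
        else:
            pull = mobility * force_at(cal, I, x, warn_extrapolation=False)
        return -pull + cfg.drift_velocity_um_s

    times = np.empty(n_frames)
    xs = np.empty(n_frames)
    x = float(start_distance_um)
    t = 0.0
    times[0], xs[0] = t, x
    truncated = False
    n_kept = 1
    for i in range(1, n_frames):
        for _ in range(oversample):
            k1 = speed(x, t)
            k2 = speed(x + 0.5 * dt * k1, t + 0.5 * dt)
            x += dt * k2
            t += dt
            if x <= bead_radius_um:
                truncated = True
                break
        if truncated:
            break
        times[i], xs[i] = i * dt_frame, x
        n_kept = i + 1
    times, xs = times[:n_kept], xs[:n_kept]
    ys = np.zeros_like(xs)
    if cfg.noise_sd_position_um > 0:
        rng = cfg.rng(0)
        xs = xs + rng.normal(0.0, cfg.noise_sd_position_um, xs.shape)
        ys = ys + rng.normal(0.0, cfg.noise_sd_position_um, ys.shape)
    return BeadTrajectory(times, xs, ys, bead_radius_um=bead_radius_um,
                          truncated=truncated,
                          meta={"schedule": list(schedule),
                                "viscosity_pa_s": viscosity_pa_s})


def _superpose_events(events, compliances, times, bead_radius_um):
    """d(t) [µm] = sum_k 1e3 * dF_k[nN] * J_k(t - t_k) / (pi * r[µm])."""
    d = np.zeros_like(times, dtype=float)
    scale = 1e3 / (np.pi * bead_radius_um)
    for (tk, df), J in zip(events, compliances):
        mask = times >= tk
        if np.any(mask):
            d[mask] += scale * df * np.asarray(J(times[mask] - tk), dtype=float)
    return d


def simulate_creep_displacement(mat: MaterialModel, protocol: ForceProtocol,
                                bead_radius_um: float, cfg: SimulationConfig,
                                duration_s: float | None = None,
                                start_position_um=(30.0, 0.0),
                                materials_per_event=None) -> BeadTrajectory:
    """Bead displacement under a stepwise force protocol on a linear
    viscoelastic material, by Boltzmann superposition of the responses to
    every force-change event.

    The bead starts at ``start_position_um`` and is displaced toward the
    needle (i.e. toward -x).  ``materials_per_event`` optionally assigns a
    different material to each event (e.g. programmed stiffening between
    pulses); by default all events share ``mat``.
    """
    if duration_s is None:
        duration_s = protocol.t_end + 2.0
    n = int(round(duration_s * cfg.frame_rate_hz)) + 1
    times = np.arange(n) / cfg.frame_rate_hz
    if materials_per_event is None:
        compliances = [mat.compliance] * len(protocol.events)
    else:
        if len(materials_per_event) != len(protocol.events):
            raise ValueError("one material per protocol event required")
        compliances = [m.compliance for m in materials_per_event]
    d = _superpose_events(protocol.events, compliances, times, bead_radius_um)
    x = np.asarray(start_position_um, dtype=float)[0] - d
    y = np.full_like(x, float(start_position_um[1]))
    if cfg.noise_sd_position_um > 0:
        rng = cfg.rng(1)
        x = x + rng.normal(0.0, cfg.noise_sd_position_um, x.shape)
        y = y + rng.normal(0.0, cfg.noise_sd_position_um, y.shape)
    return BeadTrajectory(times, x, y, bead_radius_um=bead_radius_um,
                          meta={"protocol": protocol.to_dict(),
                                "material": {"kind": mat.kind, "J0": mat.J0,
                                             "beta": mat.beta, "tau": mat.tau}})


def _needle_coverage(needle: NeedleGeometry, shape, pixel_size_um,
                     origin_um, supersample: int = 4) -> np.ndarray:
    """Per-pixel area fraction covered by the needle, by supersampling."""
    H, W = shape
    ss = supersample
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    cov = np.zeros((H, W))
    rows = origin_um[1] + np.arange(H) * pixel_size_um
    cols = origin_um[0] + np.arange(W) * pixel_size_um
    for oy in offs:
        for ox in offs:
            xx, yy = np.meshgrid(cols + ox * pixel_size_um,
                                 rows + oy * pixel_size_um)
            pts = np.column_stack([xx.ravel(), yy.ravel()])
            cov += needle.contains(pts).reshape(H, W)
    return cov / ss ** 2


def render_image_sequence(traj: BeadTrajectory, needle: NeedleGeometry,
                          cfg: SimulationConfig, shape=(96, 128),
                          origin_um=(0.0, 0.0), background: float = 3000.0,
                          contrast: float = 2000.0,
                          read_noise_sd: float = 0.0,
                          shot_noise: bool = False) -> ImageStack:
    """Render brightfield-like frames: bright background with a dark
    anti-aliased bead disk and a dark needle wedge.

    ``origin_um`` is the physical position of the centre of pixel (0, 0);
    x maps to columns, y to rows.  One frame per trajectory sample; an
    empty trajectory yields a single reference frame showing only the
    needle.  SNR is ``contrast / read_noise_sd``.
    """
    if not cfg.pixel_size_um > 0:
        raise ValueError("pixel_size must be positive")
    H, W = shape
    px = cfg.pixel_size_um
    needle_cov = _needle_coverage(needle, shape, px, origin_um)
    r_px = cfg.bead_diameter_um / px / 2.0
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    n = len(traj)
    if n == 0:
        positions = [None]
        timestamps = np.array([0.0])
    else:
        positions = list(traj.positions_um)
        timestamps = traj.time_s
    frames = np.empty((len(positions), H, W), dtype=np.uint16)
    rng = np.random.default_rng(cfg.seed + 7919)
    for i, pos in enumerate(positions):
        cov = needle_cov.copy()
        if pos is not None:
            cx = (pos[0] - origin_um[0]) / px
            cy = (pos[1] - origin_um[1]) / px
            if not (0 <= cx < W and 0 <= cy < H):
                raise ValueError("bead position outside the frame bounds")
            dist = np.hypot(cols - cx, rows - cy)
            bead_cov = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
            cov = np.clip(cov + bead_cov, 0.0, 1.0)
        clean = background - contrast * cov
        if shot_noise:
            clean = rng.poisson(np.clip(clean, 0, None)).astype(float)
        if read_noise_sd > 0:
            clean = clean + rng.normal(0.0, read_noise_sd, clean.shape)
        frames[i] = np.clip(clean, 0, 65535).astype(np.uint16)
    return ImageStack(frames, px, timestamps,
                      meta={"origin_um": tuple(origin_um),
                            "background": background, "contrast": contrast})


@dataclass(frozen=True)
class PopulationSample:
    """Per-bead (stiffness, fluidity) draws with the clipping report."""

    stiffness_pa: np.ndarray
    fluidity: np.ndarray
    n_clipped_low: int
    n_clipped_high: int

    @property
    def pairs(self):
        return list(zip(self.stiffness_pa.tolist(), self.fluidity.tolist()))


# Defaults emulate the measured MDA-MB-231 population: geometric-mean
# stiffness 277 Pa with sd(ln) ~ 1.28, fluidity 0.46 with sd ~ 0.25
# (back-computed from the reported errors of the mean at n = 160).
def sample_population(stiffness_logmean: float = math.log(277.0),
                      stiffness_logsd: float = 1.28,
                      fluidity_mean: float = 0.46,
                      fluidity_sd: float = 0.25,
                      n: int = 100, seed: int = 0) -> PopulationSample:
    """Draw a per-bead population: log-normal stiffness (J0^-1) and normal
    fluidity (beta), the distributions cell populations follow.

    Fluidity draws are clipped to the physical range [0, 1] (beta = 0
    purely elastic, beta = 1 purely viscous) and the clip counts reported.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if stiffness_logsd < 0 or fluidity_sd < 0:
        raise ValueError("spread parameters must be non-negative")
    rng = np.random.default_rng(seed)
    stiff = rng.lognormal(stiffness_logmean, stiffness_logsd, n)
    beta = rng.normal(fluidity_mean, fluidity_sd, n)
    lo = int(np.sum(beta < 0))
    hi = int(np.sum(beta > 1))
    return PopulationSample(stiffness_pa=stiff, fluidity=np.clip(beta, 0.0, 1.0),
                            n_clipped_low=lo, n_clipped_high=hi)


def synth_cavity_volume(shape=(64, 64, 64), cavities=((None, 8.0),),
                        voxel_size_zyx=(1.0, 1.0, 1.0)):
    """Solid fibril block with spherical fluid cavities of known radii.

    ``cavities`` is a sequence of ``(center_vox_zyx or None, radius_vox)``;
    None centres the cavity.  Returns a binary ground-truth volume
    (fibril = True).  Synthetic fixture for pore detection.
    """
    from .pores import LabeledVolume3D
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError("shape must be at least 32 voxels per axis")
    solid = np.ones(shape, dtype=bool)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    for center, radius in cavities:
        if center is None:
            center = tuple(s / 2.0 for s in shape)
        cz, cy, cx = center
        inside = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
        solid[inside] = False
    return LabeledVolume3D(solid, voxel_size_zyx, kind="binary")


def synth_collagen_volume(shape=(64, 64, 64), fiber_count: int = 60,
                          fiber_radius_vox: float = 2.5, seed: int = 0,
                          voxel_size_zyx=(1.0, 1.0, 1.0),
                          background: float = 10.0,
                          fiber_intensity: float = 150.0,
                          blur_sigma_vox: float = 0.6,
                          poisson_noise: bool = True):
    """Random straight-fiber network: returns ``(intensity, ground_truth)``.

    Fibers are line segments with random positions and orientations, drawn
    as tubes of ``fiber_radius_vox``; the intensity volume is the blurred
    bright-fiber image with Poisson-like counting noise.  The ground truth
    is the exact binary tube mask.
    """
    from .pores import LabeledVolume3D
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError("shape must be at least 32 voxels per axis")
    if fiber_radius_vox >= min(shape) / 4:
        raise ValueError("fiber radius too large for the volume")
    rng = np.random.default_rng(seed)
    skeleton = np.zeros(shape, dtype=bool)
    diag = math.sqrt(sum(s ** 2 for s in shape))
    for _ in range(int(fiber_count)):
        p0 = rng.uniform(0, 1, 3) * np.array(shape)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        ts = np.arange(-diag, diag, 0.5)
        pts = p0[None, :] + ts[:, None] * direction[None, :]
        idx = np.round(pts).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        idx = idx[ok]
        skeleton[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if skeleton.any():
        edt = ndimage.distance_transform_edt(~skeleton)
        mask = edt <= fiber_radius_vox
    else:
        mask = skeleton
    clean = background + fiber_intensity * ndimage.gaussian_filter(
        mask.astype(float), blur_sigma_vox)
    if poisson_noise:
        intensity = rng.poisson(clean).astype(np.float32)
    else:
        intensity = clean.astype(np.float32)
    return (LabeledVolume3D(intensity, voxel_size_zyx, kind="intensity"),
            LabeledVolume3D(mask, voxel_size_zyx, kind="binary"))


def simulate_calibration_table(cal: CalibrationModel, currents_A, distances_um,
                               viscosity_pa_s: float, bead_radius_um: float,
                               cfg: SimulationConfig, pulse_s: float = 0.05,
                               off_s: float = 0.4):
    """Run one short drag pulse per (current, distance) grid point and
    reduce each to a drift-corrected (distance, velocity) measurement.

    Returns a DataFrame with columns ``current_A, distance_um,
    velocity_um_s`` — the calibration-table format the fitting stage
    consumes.
    """
    import pandas as pd
    from .calibration import drift_corrected_velocity
    rows = []
    for I in currents_A:
        for d0 in distances_um:
            schedule = [(off_s, off_s + pulse_s, I)]
            traj = simulate_drag_trajectory(
                cal, viscosity_pa_s, bead_radius_um, schedule, d0, cfg,
                duration_s=off_s + pulse_s + off_s)
            if traj.truncated:
                continue
            iv = drift_corrected_velocity(traj, [(off_s, off_s + pulse_s)],
                                          smooth_window=1)[0]
            rows.append({"current_A": I, "distance_um": iv.distance_um,
                         "velocity_um_s": iv.velocity_um_s})
    return pd.DataFrame(rows)
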