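"""Orchestration of the analysis stages into reproducible runs.

Each ``run_*`` function takes a validated :class:`~magrheo.config.RunConfig`
and an output directory, writes CSV/JSON artifacts with fixed numeric
precision (9 significant digits) plus the resolved configuration, and
returns the paths it wrote.  A single seed in the config governs all
stochastic stages; per-stage sub-seeds are derived deterministically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import fit_calibration
from .config import RunConfig, config_hash
from .images import ImageStack
from .material import MaterialModel
from .pores import (LabeledVolume3D, fit_pore_spheres, pore_statistics,
                    rescale_volume, segment_fibrils)
from .protocol import ForceProtocol
from .rheology import displacement_to_compliance, fit_kelvin_voigt, fit_power_law
from .simulate import SimulationConfig, simulate_calibration_table, \
    simulate_creep_displacement
from .stats import SampleSet, compare_groups, summarize_fluidity, \
    summarize_stiffness
from .tracking import track_stack
from .trajectory import BeadTrajectory

log = logging.getLogger("magrheo")

__all__ = ["run_calibrate", "run_simulate", "run_track", "run_analyze",
           "run_pores", "run_stats"]

_FLOAT_FMT = "%.9g"


def _prepare_out(cfg: RunConfig, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = cfg.model_dump()
    resolved["_provenance"] = {"config_hash": config_hash(cfg),
                               "magrheo_version": __version__}
    (out / "resolved_config.json").write_text(
        json.dumps(resolved, indent=2, sort_keys=True, default=str))
    return out


def _subseed(cfg: RunConfig, stream: int) -> int:
    return int(np.random.SeedSequence(cfg.seed).spawn(stream + 1)[stream]
               .generate_state(1)[0] % (2 ** 31))


def run_calibrate(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Fit the force–distance–current law from a drag table (measured CSV
    or virtual-instrument simulation) and persist the model."""
    if cfg.calibrate is None:
        raise ValueError("config has no 'calibrate' block")
    c = cfg.calibrate
    out = _prepare_out(cfg, out_dir)
    if c.simulate:
        from .calibration import CalibrationModel
        truth = CalibrationModel(F0=c.true_F0, c1=c.true_c1, c2=c.true_c2,
                                 c3=c.true_c3,
                                 current_range=(min(c.currents_A), max(c.currents_A)),
                                 distance_range=(min(c.distances_um) - 30,
                                                 max(c.distances_um) + 30),
                                 saturation_current=c.saturation_current_A)
        sim_cfg = SimulationConfig(seed=_subseed(cfg, 0),
                                   drift_velocity_um_s=c.drift_velocity_um_s,
                                   noise_sd_position_um=c.noise_sd_position_um)
        table = simulate_calibration_table(truth, c.currents_A, c.distances_um,
                                           c.viscosity_pa_s, c.bead_radius_um,
                                           sim_cfg)
    else:
        if not c.input_csv:
            raise ValueError("calibrate needs input_csv or simulate: true")
        table = pd.read_csv(c.input_csv)
        if table.empty:
            raise ValueError("no measurements in input CSV")
    model = fit_calibration(table, c.viscosity_pa_s, c.bead_radius_um,
                            saturation_current=c.saturation_current_A)
    model.to_json(out / "calibration_model.json")
    table.to_csv(out / "measurements.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(model.diagnostics["per_current"]).to_csv(
        out / "per_current_fits.csv", index=False, float_format=_FLOAT_FMT)
    return {"model": out / "calibration_model.json",
            "measurements": out / "measurements.csv",
            "per_current_fits": out / "per_current_fits.csv"}


def run_simulate(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Generate synthetic creep trajectories (one CSV per bead) with a
    ground-truth sidecar."""
    if cfg.simulate is None:
        raise ValueError("config has no 'simulate' block")
    s = cfg.simulate
    out = _prepare_out(cfg, out_dir)
    protocol = (ForceProtocol.single_pulse(s.amplitude_nN, s.on_s)
                if s.n_cycles <= 1 else
                ForceProtocol.pulse_train(s.amplitude_nN, s.on_s, s.off_s,
                                          s.n_cycles))
    mat = MaterialModel("power_law", J0=s.J0, beta=s.beta)
    paths = []
    for b in range(s.n_beads):
        sim_cfg = SimulationConfig(frame_rate_hz=s.frame_rate_hz,
                                   noise_sd_position_um=s.noise_sd_position_um,
                                   seed=_subseed(cfg, b))
        traj = simulate_creep_displacement(mat, protocol, s.bead_radius_um,
                                           sim_cfg)
        p = out / f"bead_{b:03d}.csv"
        traj.to_csv(p)
        paths.append(p)
    protocol.to_json(out / "protocol.json")
    (out / "ground_truth.json").write_text(json.dumps(
        {"J0": s.J0, "beta": s.beta, "stiffness_pa": 1.0 / s.J0,
         "bead_radius_um": s.bead_radius_um}, indent=2))
    return {"trajectories": paths, "protocol": out / "protocol.json"}


def run_track(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Track the bead in a TIFF stack and write positions + needle distance."""
    if cfg.track is None:
        raise ValueError("config has no 'track' block")
    t = cfg.track
    out = _prepare_out(cfg, out_dir)
    stack = ImageStack.load(t.input_tiff)
    result = track_stack(stack, expected_diameter_um=t.expected_diameter_um,
                         min_correlation=t.min_correlation)
    result.to_frame().to_csv(out / "track.csv", index=False,
                             float_format=_FLOAT_FMT)
    meta = {"terminated_at": result.terminated_at,
            "termination_reason": result.termination_reason,
            "n_frames": int(len(result.time_s))}
    (out / "track_meta.json").write_text(json.dumps(meta, indent=2))
    return {"track": out / "track.csv", "meta": out / "track_meta.json"}


def _load_protocol(a) -> ForceProtocol:
    if a.protocol_json:
        return ForceProtocol.from_json(a.protocol_json)
    if a.protocol:
        return ForceProtocol.from_dict(a.protocol)
    raise ValueError("analyze needs protocol_json or an inline protocol")


def run_analyze(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Fit per-bead creep curves, summarize populations per group and
    compare groups with Bonferroni correction."""
    if cfg.analyze is None:
        raise ValueError("config has no 'analyze' block")
    a = cfg.analyze
    out = _prepare_out(cfg, out_dir)
    protocol = _load_protocol(a)
    pulses = protocol.pulses()
    if not pulses:
        raise ValueError("protocol applies no force")
    t_on, t_off, force = pulses[0]
    groups = a.groups or {"all": a.trajectories}
    rows = []
    for label, paths in groups.items():
        for p in paths:
            try:
                traj = BeadTrajectory.from_csv(p, bead_radius_um=a.bead_radius_um)
                m = (traj.time_s > t_on) & (traj.time_s <= t_off)
                disp = traj.displacement_um()
                curve = displacement_to_compliance(traj.time_s[m] - t_on,
                                                   disp[m], force,
                                                   a.bead_radius_um)
                fit = (fit_power_law(curve) if a.fit_model == "power_law"
                       else fit_kelvin_voigt(curve))
            except Exception as exc:  # per-file failure: log and continue
                log.error("analysis failed for %s: %s", p, exc)
                rows.append({"group": label, "path": str(p), "error": str(exc)})
                continue
            rows.append({"group": label, "path": str(p), "model": fit.model,
                         "J0_per_pa": fit.J0, "beta": fit.beta, "tau": fit.tau,
                         "stiffness_pa": fit.stiffness_pa,
                         "r_squared": fit.r_squared})
    fits = pd.DataFrame(rows)
    fits.to_csv(out / "fits.csv", index=False, float_format=_FLOAT_FMT)
    ok = fits[fits.get("error").isna()] if "error" in fits else fits
    summaries, comparisons = [], []
    samples = {}
    for label, grp in ok.groupby("group"):
        if len(grp) < 2:
            continue
        ss = SampleSet(label, grp["stiffness_pa"].to_numpy(),
                       grp["beta"].fillna(0.0).to_numpy())
        samples[label] = ss
        st = summarize_stiffness(ss)
        fl = summarize_fluidity(ss)
        summaries.append({"group": label, "n": ss.n,
                          "stiffness_gm_pa": st.geometric_mean_pa,
                          "stiffness_err_pa": st.error_pa,
                          "fluidity_mean": fl.mean, "fluidity_sem": fl.sem})
    labels = sorted(samples)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            for metric in ("stiffness", "fluidity"):
                r = compare_groups(samples[la], samples[lb], metric,
                                   n_comparisons=a.n_comparisons)
                comparisons.append({"a": la, "b": lb, "metric": metric,
                                    "t": r.t_statistic, "df": r.df,
                                    "p_raw": r.p_raw,
                                    "p_bonferroni": r.p_bonferroni,
                                    "stars": r.stars})
    pd.DataFrame(summaries).to_csv(out / "summaries.csv", index=False,
                                   float_format=_FLOAT_FMT)
    pd.DataFrame(comparisons).to_csv(out / "comparisons.csv", index=False,
                                     float_format=_FLOAT_FMT)
    (out / "stars.json").write_text(json.dumps(
        [{"a": c["a"], "b": c["b"], "metric": c["metric"],
          "stars": c["stars"]} for c in comparisons], indent=2))
    return {"fits": out / "fits.csv", "summaries": out / "summaries.csv",
            "comparisons": out / "comparisons.csv"}


def run_pores(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Segment a collagen volume and extract its pore-size distribution."""
    if cfg.pores is None:
        raise ValueError("config has no 'pores' block")
    p = cfg.pores
    out = _prepare_out(cfg, out_dir)
    import tifffile
    voxels = tifffile.imread(p.input_tiff)
    vs = p.voxel_size_zyx_um
    if vs is None:
        sidecar = Path(p.input_tiff).with_suffix(".json")
        if not sidecar.exists():
            raise ValueError("missing voxel-size metadata: pass "
                             "voxel_size_zyx_um or provide a JSON sidecar")
        vs = tuple(json.loads(sidecar.read_text())["voxel_size_zyx_um"])
    kind = "binary" if voxels.dtype == bool or set(np.unique(voxels)) <= {0, 1} \
        else "intensity"
    vol = LabeledVolume3D(voxels, vs, kind=kind)
    if p.rescale_xy != 1.0:
        vol = rescale_volume(vol, p.rescale_xy)
    binary = segment_fibrils(vol, sigma_vox=p.sigma_vox)
    pores = fit_pore_spheres(binary, min_radius_um=p.min_radius_um)
    stats = pore_statistics(pores)
    if stats.empty:
        log.warning("no pores found above the minimum radius")
    pores.to_frame().to_csv(out / "pores.csv", index=False,
                            float_format=_FLOAT_FMT)
    (out / "pore_summary.json").write_text(json.dumps(
        {"count": stats.count, "mean_diameter_um": stats.mean_diameter_um,
         "median_diameter_um": stats.median_diameter_um,
         "mean_radius_um": stats.mean_radius_um,
         "median_radius_um": stats.median_radius_um,
         "voxel_size_zyx_um": list(binary.voxel_size_zyx)},
        indent=2, default=float))
    return {"pores": out / "pores.csv", "summary": out / "pore_summary.json"}


def run_stats(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Group summaries and a pairwise Welch/Bonferroni comparison matrix
    from a per-bead CSV (columns: group, stiffness_pa, fluidity)."""
    if cfg.stats is None:
        raise ValueError("config has no 'stats' block")
    s = cfg.stats
    out = _prepare_out(cfg, out_dir)
    df = pd.read_csv(s.input_csv)
    samples = {label: SampleSet(label, grp["stiffness_pa"].to_numpy(),
                                grp["fluidity"].to_numpy())
               for label, grp in df.groupby("group") if len(grp) >= 2}
    labels = sorted(samples)
    m = s.n_comparisons or max(1, len(labels) * (len(labels) - 1) // 2)
    summaries, comparisons = [], []
    for label in labels:
        ss = samples[label]
        st = summarize_stiffness(ss)
        fl = summarize_fluidity(ss)
        summaries.append({"group": label, "n": ss.n,
                          "stiffness_gm_pa": st.geometric_mean_pa,
                          "stiffness_err_pa": st.error_pa,
                          "fluidity_mean": fl.mean, "fluidity_sem": fl.sem})
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            for metric in ("stiffness", "fluidity"):
                r = compare_groups(samples[la], samples[lb], metric,
                                   n_comparisons=m)
                comparisons.append({"a": la, "b": lb, "metric": metric,
                                    "t": r.t_statistic, "df": r.df,
                                    "p_raw": r.p_raw,
                                    "p_bonferroni": r.p_bonferroni,
                                    "stars": r.stars})
    pd.DataFrame(summaries).to_csv(out / "summaries.csv", index=False,
                                   float_format=_FLOAT_FMT)
    pd.DataFrame(comparisons).to_csv(out / "comparisons.csv", index=False,
                                     float_format=_FLOAT_FMT)
    return {"summaries": out / "summaries.csv",
            "comparisons": out / "comparisons.csv"}
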