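"""Batch orchestration: imaging -> geometry -> mechanics -> reports.

`analyze_frames` turns a loaded frame sequence into a
:class:`~capadh.mechanics.PullSequence`; `run_analysis` drives whole batches
from an :class:`~capadh.config.AnalysisConfig` and writes CSV/JSON reports;
`simulate` renders a synthetic scenario to disk in exactly the format
`run_analysis` reads.  Identical configuration and inputs produce
byte-identical reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging, synthetic
from .config import AnalysisConfig
from .errors import CapadhError, ConfigError, DataError
from .geometry import fit_profile
from .mechanics import (
    BendingSpecimen,
    FluidProperties,
    FrameRecord,
    PullSequence,
    force_elongation_curve,
    analyze_sequence,
)

__all__ = ["analyze_frames", "run_analysis", "simulate", "write_sequence"]


def analyze_frames(frames, *, threshold="auto", residuals: str = "orthogonal",
                   mode: str = "tension", angle_window_px: int = 100,
                   min_flank_points: int = 8) -> PullSequence:
    """Extract and fit every frame, identify the snap-off frame, and return
    the assembled pull sequence.

    The snap-off frame is the last frame with a connected meniscus; later
    frames contribute the relaxed fiber tip position.  In bending mode the
    snap-off frame additionally carries the fiber--surface angle.
    """
    records = []
    snap = -1
    for fr in frames:
        sil = imaging.extract_silhouette(fr, threshold)
        rec = FrameRecord(stage_position=fr.stage_position,
                          timestamp=fr.timestamp)
        loc = imaging.locate_meniscus(sil)
        if loc.connected and len(loc.flank_points) >= min_flank_points:
            fit = fit_profile(
                loc.flank_points, r_tip=loc.r_tip or 0.0,
                residuals=residuals, axis_hint=loc.axis_x,
                pixel_scale=fr.pixel_scale,
            )
            rec.fit = fit
            rec.baseline_y = loc.baseline_y
            rec.tip_position = loc.baseline_y + fit.profile.tip_height
            rec.tip_from_fit = True
            snap = len(records)
            if mode == "bending" and loc.axis_x is not None:
                col = int(loc.axis_x / fr.pixel_scale)
                try:
                    rec.bending_angle = imaging.measure_bending_angle(
                        fr, (col - angle_window_px, col), threshold=threshold
                    )
                except CapadhError:
                    rec.bending_angle = None
        else:
            try:
                rec.tip_position = imaging.locate_fiber_tip(sil)
            except DataError:
                rec.tip_position = None
        records.append(rec)
    if snap < 0:
        raise DataError("no frame with a connected meniscus found")
    return PullSequence(frames=records, snap_index=snap,
                        pixel_scale=frames[0].pixel_scale, mode=mode)


def _sequence_from_manual_points(path, manual, scale, meta, mode):
    """Build a PullSequence from clicked coordinates (the manual escape
    hatch mirroring visual assessment)."""
    # clicked y_px counts down from the top of the frame; physical height is
    # -y_px * scale (only differences enter the analysis)
    records = []
    snap = -1
    for i, fmeta in enumerate(meta["frames"]):
        pts = manual.get(i, {})
        rec = FrameRecord(stage_position=float(fmeta["stage_position_m"]),
                          timestamp=float(fmeta["timestamp_s"]))
        base = pts.get("baseline")
        base_y = -float(np.mean(base[:, 1])) * scale if base is not None else 0.0
        if "flank" in pts and len(pts["flank"]) >= 8:
            xy = np.column_stack([
                pts["flank"][:, 0] * scale,
                -pts["flank"][:, 1] * scale - base_y,
            ])
            r_tip = 0.0
            if "fiber" in pts:  # clicked fiber edges give the contact radius
                r_tip = float(np.ptp(pts["fiber"][:, 0])) / 2 * scale
            fit = fit_profile(xy, pixel_scale=scale, r_tip=r_tip)
            rec.fit = fit
            rec.baseline_y = base_y
            rec.tip_position = base_y + fit.profile.tip_height
            rec.tip_from_fit = True
            snap = i
        elif "tip" in pts:
            rec.tip_position = -float(np.mean(pts["tip"][:, 1])) * scale
        records.append(rec)
    if snap < 0:
        raise DataError(f"manual points for {path} contain no flank frames")
    return PullSequence(frames=records, snap_index=snap, pixel_scale=scale,
                        mode=mode)


def run_analysis(config: AnalysisConfig):
    """Analyze every configured input sequence and write the reports.

    Per-sequence failures are recorded and the batch continues.  Returns a
    list of per-sequence dictionaries (measurement result or error).
    """
    fluid = FluidProperties(surface_tension=config.surface_tension,
                            density=config.density, gravity=config.gravity)
    specimen = None
    if config.mode == "bending":
        specimen = BendingSpecimen(length=config.specimen_length,
                                   diameter=config.specimen_diameter,
                                   tilt=config.specimen_tilt)
    manual = (imaging.read_manual_points(config.manual_points)
              if config.manual_points else None)
    outputs = []
    for inp in config.inputs:
        entry = {"input": str(inp)}
        try:
            # validate calibration before any image is decoded
            meta = _read_sidecar(inp)
            scale = config.pixel_scale or meta.get("pixel_scale_m_per_px")
            if not scale:
                raise ConfigError(
                    f"no pixel_scale for {inp}: set it in the config or the "
                    "sidecar YAML"
                )
            if manual is not None:
                seq = _sequence_from_manual_points(inp, manual, float(scale),
                                                   meta, config.mode)
            else:
                frames, _ = imaging.load_sequence(inp)
                for fr in frames:
                    fr.pixel_scale = float(scale)
                seq = analyze_frames(
                    frames, threshold=config.threshold,
                    residuals=config.residuals, mode=config.mode,
                    angle_window_px=config.angle_window_px,
                )
            res = analyze_sequence(
                seq, fluid, specimen=specimen, stencil=config.stencil,
                angle_form=config.angle_form, n_mc=config.mc_n,
                seed=config.seed,
                angle_window=config.angle_window_px * float(scale),
            )
            try:
                curve = force_elongation_curve(seq, fluid,
                                               stencil=config.stencil)
                curve_d = {
                    "slope_N_per_m": curve.slope,
                    "r_squared": curve.r_squared,
                    "elongation_um": (curve.elongation * 1e6).tolist(),
                    "force_uN": (curve.force * 1e6).tolist(),
                }
            except CapadhError:
                curve_d = None
            entry.update(_result_to_dict(res, curve_d, seq))
        except CapadhError as exc:
            entry["error"] = f"{type(exc).__name__}: {exc}"
        outputs.append(entry)
    _write_reports(outputs, config)
    return outputs


def _read_sidecar(inp) -> dict:
    p = Path(inp)
    sidecar = p / "sidecar.yaml" if p.is_dir() else p.with_suffix(".yaml")
    if not sidecar.exists():
        raise DataError(f"no sidecar YAML for {inp}")
    meta = yaml.safe_load(sidecar.read_text())
    if not isinstance(meta, dict) or "frames" not in meta:
        raise DataError(f"sidecar for {inp} lacks a frames list")
    return meta


def _result_to_dict(res, curve_d, seq) -> dict:
    d = {
        "F_uN": res.adhesion_force * 1e6,
        "F_stat_uN": res.statistical.get("F", 0.0) * 1e6,
        "F_syst_uN": res.systematic.get("F", 0.0) * 1e6,
        "F_syst_mc_uN": res.systematic_mc.get("F", 0.0) * 1e6,
        "FG_uN": res.weight_force * 1e6,
        "snap_index": seq.snap_index,
        "n_frames": len(seq.frames),
        "warnings": list(res.warnings),
    }
    if res.elongation is not None:
        d["dy_um"] = res.elongation * 1e6
        d["dy_syst_um"] = res.systematic.get("dy", 0.0) * 1e6
    if res.spring_constant is not None:
        d["D_N_per_m"] = res.spring_constant
        d["D_stat_N_per_m"] = res.statistical.get("D", 0.0)
        d["D_syst_N_per_m"] = res.systematic.get("D", 0.0)
    if res.youngs_modulus is not None:
        d["E_N_per_cm2"] = res.youngs_modulus / 1e4
        d["E_stat_N_per_cm2"] = res.statistical.get("E_Y", 0.0) / 1e4
        d["E_syst_N_per_cm2"] = res.systematic.get("E_Y", 0.0) / 1e4
    if curve_d is not None:
        d["curve"] = curve_d
    return d


_CSV_COLUMNS = [
    "input", "F_uN", "F_stat_uN", "F_syst_uN", "FG_uN", "dy_um",
    "dy_syst_um", "D_N_per_m", "D_stat_N_per_m", "D_syst_N_per_m",
    "E_N_per_cm2", "E_stat_N_per_cm2", "E_syst_N_per_cm2", "error",
]


def _write_reports(outputs, config: AnalysisConfig):
    if config.out_csv:
        rows = [{k: o.get(k) for k in _CSV_COLUMNS} for o in outputs]
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(config.out_csv,
                                                        index=False)
    if config.out_json:
        cfg = json.loads(config.model_dump_json())
        cfg.pop("out_csv", None)  # output locations are not analysis
        cfg.pop("out_json", None)  # parameters; keep reruns byte-identical
        report = {
            "config": cfg,
            "results": outputs,
        }
        Path(config.out_json).write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )


# ---------------------------------------------------------------------------
# synthetic scenario -> on-disk sequence
# ---------------------------------------------------------------------------


def write_sequence(frames, out_dir, extra_meta: dict | None = None):
    """Write frames as numbered PNGs plus the sidecar YAML."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "pixel_scale_m_per_px": frames[0].pixel_scale,
        "frames": [],
    }
    if extra_meta:
        meta.update(extra_meta)
    for i, fr in enumerate(frames):
        name = f"frame_{i:03d}.png"
        iio.imwrite(out / name, fr.image)
        meta["frames"].append({
            "file": name,
            "timestamp_s": float(fr.timestamp),
            "stage_position_m": float(fr.stage_position),
        })
    (out / "sidecar.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return out


def simulate(scenario, out_dir):
    """Render a synthetic scenario to disk: frames + sidecar + truth JSON.

    ``scenario`` is a mapping (or YAML path) following the scenario schema;
    unknown keys are rejected.  The generated sequence is accepted
    unmodified by :func:`run_analysis`.
    """
    if not isinstance(scenario, dict):
        scenario = yaml.safe_load(Path(scenario).read_text())
        if not isinstance(scenario, dict):
            raise ConfigError("scenario YAML must contain a mapping")
    truth, n_frames = synthetic.truth_from_dict(scenario)
    frames, _seq, rec = synthetic.render_frames(truth, n_frames)
    out = write_sequence(frames, out_dir)
    truth_doc = {
        "truth": truth.to_dict(),
        "n_frames": n_frames,
        "analytic": {
            "snap_force_N": rec.snap_force,
            "snap_elongation_m": rec.snap_elongation,
            "spring_constant_N_per_m": rec.spring_constant,
            "force_N": rec.force.tolist(),
            "tip_height_m": rec.tip_height.tolist(),
            "energy_J": rec.energy.tolist(),
        },
    }
    (out / "truth.json").write_text(
        json.dumps(truth_doc, indent=2, sort_keys=True) + "\n"
    )
    return out
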