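"""End-to-end pipeline: phantom (optional) -> split -> measure -> tensile
-> summarize, driven by a single YAML config with full provenance.

The config mirrors the stages::

    seed: 1
    pipeline: {slab_width: 0.2, station_step: 0.05}   # PipelineConfig fields
    phantom:                                          # generate synthetic inputs
      mesh_resolution: 2.0
      truth: {radius_length: 254.4}                   # PhantomTruth overrides
      curves:                                         # optional TensileTruth list
        - {ligament_id: CB, stiffness_true: 33.09, ...}
    inputs:                                           # ... or measure real files
      radius: radius.stl
      ulna: ulna.stl
      membrane: membrane.stl
      landmarks: landmarks.json
      distal_hints: {radius: [0, 0, -1], ulna: [33, 0, -6]}
      curves: [cb.csv]

Every run writes a ``manifest.json`` (config snapshot, input digests,
package version, seed, timestamps); rerunning with identical inputs
reproduces byte-identical result files apart from the manifest
timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import IomorphError, SchemaError
from .io_core import (
    PipelineConfig,
    read_curve,
    read_landmarks,
    read_mesh,
    write_curve,
    write_landmarks,
    write_mesh,
)
from .morphometry import (
    estimate_bone_axis,
    measure_ligament,
    split_ligament,
    thickness_axial_trend,
)
from .phantom import (
    LigamentSpec,
    PhantomTruth,
    TensileTruth,
    make_phantom,
    make_tensile_curve,
)
from .reference import CADAVER_TENSILE
from .summary import make_table
from .tensile import analyze_curve, trapezoid_csa

log = logging.getLogger(__name__)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def _dump_json(payload, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, cls=_Encoder))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def default_curve_truths(seed: int) -> list[TensileTruth]:
    """One representative per-ligament tensile truth at the magnitudes of
    the bundled cadaveric reference rows."""
    out = []
    for i, lig in enumerate(("CB", "AB", "DOAC", "DOB")):
        row = CADAVER_TENSILE[lig][0]
        out.append(
            TensileTruth(
                stiffness_true=row["stiffness"],
                first_peak_force_true=row["first_peak"],
                ultimate_force_true=row["ultimate"],
                ultimate_strain_true=row["ultimate_strain"],
                seed=(seed + i) % 2**31,
                specimen_id=row["specimen"],
                ligament_id=lig,
            )
        )
    return out


def _phantom_truth_from_config(block: dict) -> PhantomTruth:
    kw = dict(block or {})
    ligs = kw.pop("ligaments", None)
    if ligs is not None:
        kw["ligaments"] = [
            spec if isinstance(spec, LigamentSpec) else LigamentSpec(**spec)
            for spec in ligs
        ]
    return PhantomTruth(**kw)


def run_pipeline(config_path, out_dir, seed: int | None = None) -> int:
    """Execute the full pipeline; returns a process exit status (0 = ok).

    Stage failures are logged with the stage name; outputs produced
    before the failure are preserved under *out_dir*.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "config"
    manifest: dict = {
        "tool": "iomorph",
        "version": __version__,
        "started_unix": time.time(),
        "config_path": str(config_path),
    }
    try:
        raw = yaml.safe_load(Path(config_path).read_text()) or {}
        if seed is None:
            seed = int(raw.get("seed", 0))
        manifest["seed"] = seed
        cfg = PipelineConfig(**(raw.get("pipeline") or {}))
        manifest["pipeline_config"] = dataclasses.asdict(cfg)
        log.info(
            "parameters: slab_width=%g mm station_step=%g mm preload=%g N "
            "failure_stop_fraction=%g linear_fit_min_span=%g first_peak_drop=%g "
            "r2_threshold=%g width_metric=%s sd_convention=population",
            cfg.slab_width, cfg.station_step, cfg.preload,
            cfg.failure_stop_fraction, cfg.linear_fit_min_span,
            cfg.first_peak_drop, cfg.r2_threshold, cfg.width_metric,
        )

        curves = []
        if "phantom" in raw:
            stage = "phantom"
            block = raw["phantom"] or {}
            truth = _phantom_truth_from_config(block.get("truth"))
            resolution = float(block.get("mesh_resolution", 2.0))
            result = make_phantom(truth, mesh_resolution=resolution, seed=seed)
            pdir = out / "phantom"
            write_mesh(result.radius, pdir / "radius.stl")
            write_mesh(result.ulna, pdir / "ulna.stl")
            write_mesh(result.membrane, pdir / "membrane.stl")
            write_landmarks(result.landmarks, pdir / "landmarks.json")
            _dump_json(
                {
                    "expected": result.expected,
                    "analytic_areas": result.analytic_areas,
                    "distal_hints": {k: v.tolist() for k, v in result.distal_hints.items()},
                    "vertex_counts": result.vertex_counts,
                },
                pdir / "truth.json",
            )
            membrane, landmarks = result.membrane, result.landmarks
            radius, ulna = result.radius, result.ulna
            hints = result.distal_hints
            curve_cfgs = block.get("curves")
            truths = (
                [TensileTruth(**c) for c in curve_cfgs]
                if curve_cfgs is not None
                else default_curve_truths(seed)
            )
            for i, tt in enumerate(truths):
                curve = make_tensile_curve(tt)
                write_curve(curve, pdir / "curves" / f"{tt.ligament_id or i}.csv")
                curves.append(curve)
        elif "inputs" in raw:
            stage = "inputs"
            inputs = raw["inputs"]
            digests = {}
            for key in ("radius", "ulna", "membrane", "landmarks"):
                if key not in inputs:
                    raise SchemaError(f"inputs block is missing the {key!r} field")
                p = Path(inputs[key])
                if not p.exists():
                    raise SchemaError(f"inputs.{key}: file not found: {p}")
                digests[key] = _sha256(p)
            radius = read_mesh(inputs["radius"], "radius")
            ulna = read_mesh(inputs["ulna"], "ulna")
            membrane = read_mesh(inputs["membrane"], "membrane")
            landmarks = read_landmarks(inputs["landmarks"])
            hints = {
                k: np.asarray(v, float)
                for k, v in (inputs.get("distal_hints") or {}).items()
            }
            if set(hints) < {"radius", "ulna"}:
                raise SchemaError(
                    "inputs.distal_hints must give points for 'radius' and 'ulna'"
                )
            for path in inputs.get("curves", []):
                digests[str(path)] = _sha256(Path(path))
                curves.append(read_curve(path))
            manifest["input_digests"] = digests
        else:
            raise SchemaError("config needs either a 'phantom' or an 'inputs' block")

        stage = "axes"
        radius_axis = estimate_bone_axis(radius, hints["radius"])
        ulna_axis = estimate_bone_axis(ulna, hints["ulna"])

        stage = "split"
        ligament_meshes = {}
        for lm in landmarks:
            lig = split_ligament(
                membrane, lm, radius_axis, clip_half_width=cfg.doac_clip_half_width
            )
            ligament_meshes[lm.ligament_id] = lig
            write_mesh(lig, out / "splits" / f"{lm.ligament_id}.stl")

        stage = "measure"
        records = []
        for lm in landmarks:
            rec = measure_ligament(
                membrane, lm, radius_axis, ulna_axis, cfg,
                ligament_mesh=ligament_meshes[lm.ligament_id],
            )
            records.append(rec)
            for prof in rec.profiles:
                pdir = out / "profiles"
                pdir.mkdir(parents=True, exist_ok=True)
                lines = ["station_mm,thickness_mm"] + [
                    f"{s!r},{'' if not np.isfinite(t) else repr(t)}"
                    for s, t in zip(prof.stations, prof.thickness)
                ]
                safe_pos = prof.position.replace("@", "_")
                (pdir / f"{rec.ligament_id}_{safe_pos}.csv").write_text(
                    "\n".join(lines) + "\n"
                )
        trend_points = [
            (rec.radial_attachment_pct[pos], rec.mean_thickness)
            for rec in records
            for pos in rec.radial_attachment_pct
        ]
        trend = (
            thickness_axial_trend(trend_points) if len(trend_points) >= 2 else None
        )
        _dump_json(
            {
                "records": [rec.to_dict() for rec in records],
                "radius_axis": {
                    "direction": radius_axis.direction,
                    "distal_point": radius_axis.distal_point,
                    "length": radius_axis.length,
                },
                "ulna_axis": {
                    "direction": ulna_axis.direction,
                    "distal_point": ulna_axis.distal_point,
                    "length": ulna_axis.length,
                },
                "thickness_axial_trend": trend
                and {"slope_mm_per_pct": trend[0], "intercept_mm": trend[1]},
            },
            out / "morphometry.json",
        )
        if records:
            make_table(records).to_csv(out / "summary_morphometry.csv", index=False)

        stage = "tensile"
        results = []
        rec_by_lig = {r.ligament_id: r for r in records}
        for curve in curves:
            rec = rec_by_lig.get(curve.ligament_id)
            csa = None
            if rec is not None and rec.width_radial and rec.width_ulnar:
                csa = trapezoid_csa(rec.width_radial, rec.width_ulnar, rec.mean_thickness)
            results.append(analyze_curve(curve, cfg, csa=csa))
        if curves:
            _dump_json([r.to_dict() for r in results], out / "tensile_results.json")
            make_table(results, decimals_by_quantity={"ultimate_strain": 1}).to_csv(
                out / "summary_tensile.csv", index=False
            )
    except (IomorphError, OSError, KeyError, TypeError, ValueError) as exc:
        log.error("pipeline failed in stage %r: %s", stage, exc)
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest["finished_unix"] = time.time()
        _dump_json(manifest, out / "manifest.json")
        return 1
    manifest["finished_unix"] = time.time()
    _dump_json(manifest, out / "manifest.json")
    return 0
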