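"""End-to-end orchestration: simulate → reconstruct → measure → aggregate → model.

A run is fully described by a :class:`RunConfig` (serialisable to JSON) and
reproducible from it alone: the single run seed fans out into fixed per-stage
substreams, so each stage is individually reproducible and stages do not
share random state. Outputs are plain files (TIFF + JSON sidecar, graph JSON,
CSV, model JSON) plus a manifest recording the package version, the config
hash and a checksum of every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .capmetrics import compute_morphometry
from .cohortstats import CohortDesign, fit_group_model, simulate_cohort
from .fibremorph import analyse_sections, section_summary
from .io import write_metrics_csv, write_tiff_stack
from .phantom import (
    GroundTruth,
    PhantomSpec,
    generate_capillary_network,
    generate_fibre_phantom,
    generate_serial_sections,
    rasterise_network,
)
from .reconstruct import reconstruct_graph

__all__ = ["RunConfig", "run_all", "validate_against_truth", "DEFAULT_TOLERANCES"]

_STAGES = ("simulate", "reconstruct", "metrics", "fibres", "stats")

#: declared relative-error tolerances for phantom parameter recovery
DEFAULT_TOLERANCES = {
    "LVm": 0.10,
    "Br_dens": 0.15,
    "tortuosity": 0.15,
    "MeanCap": 0.15,
    "anisotropy": 0.15,
}


def _stage_seed(seed: int, stage: str) -> int:
    """Name-keyed substream seed (< 2³¹) for one pipeline stage."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([int(seed), 1000 + idx]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    resample_step: float = 5.0
    z_calibration: float = 1.0
    spur_length: float = 5.0
    smoothing_sigma: float = 1.5
    segmentation: str = "otsu"
    min_object_volume: float = 100.0
    fibre_type_probs: dict = field(
        default_factory=lambda: {"1": 0.40, "1/2a": 0.05, "2a": 0.30, "2a/2x": 0.05, "2x": 0.20}
    )
    imcl_by_type: dict = field(
        default_factory=lambda: {"1": 6.0, "1/2a": 5.0, "2a": 4.0, "2a/2x": 3.0, "2x": 2.0}
    )
    stats_outcome: str = "LVf"
    seed: int = 0
    out_dir: str = "run_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            for key in ("field_size", "voxel_size"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            d["phantom"] = PhantomSpec(**ph)
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        """Platform-stable hash of the config, excluding output paths."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run manifest.

    Per-stage failures are recorded in the manifest together with the partial
    outputs produced before the failure; the manifest is always written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir", None)  # paths are not part of the reproducible config
    (out / "config.json").write_text(json.dumps(cfg_dict, indent=1, sort_keys=True))
    manifest["outputs"]["config.json"] = _sha256(out / "config.json")

    state: dict = {}
    try:
        for stage in _STAGES:
            _run_stage(stage, config, out, manifest, state)
            manifest["stages"][stage] = "ok"
    except Exception as exc:  # record the failing stage, keep partial outputs
        manifest["stages"][stage] = f"failed: {type(exc).__name__}: {exc}"
        manifest["error_stage"] = stage
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _run_stage(stage: str, config: RunConfig, out: Path, manifest: dict, state: dict) -> None:
    seed = _stage_seed(config.seed, stage)
    if stage == "simulate":
        spec = dataclasses.replace(config.phantom, seed=seed)
        graph, truth = generate_capillary_network(spec)
        stack = rasterise_network(graph, spec)
        fibre_vol, fibre_model = generate_fibre_phantom(spec)
        write_tiff_stack(stack, out / "stack.tif")
        graph.to_json(out / "truth_graph.json")
        (out / "truth_metrics.json").write_text(json.dumps(truth.as_dict(), indent=1))
        state.update(spec=spec, stack=stack, truth=truth, fibre_model=fibre_model)
        for f in ("stack.tif", "stack.tif.json", "truth_graph.json", "truth_metrics.json"):
            manifest["outputs"][f] = _sha256(out / f)
    elif stage == "reconstruct":
        z_cal = config.z_calibration
        graph = reconstruct_graph(
            state["stack"],
            step=config.resample_step,
            z_calibration=z_cal,
            spur_length=config.spur_length,
            smoothing_sigma=config.smoothing_sigma,
            segmentation=config.segmentation,
            min_object_volume=config.min_object_volume,
        )
        graph.to_json(out / "graph.json")
        graph.to_swc(out / "graph.swc", radius=config.phantom.capillary_radius)
        state["graph"] = graph
        state["reference_volume"] = state["stack"].world_volume * z_cal
        for f in ("graph.json", "graph.swc"):
            manifest["outputs"][f] = _sha256(out / f)
    elif stage == "metrics":
        res = compute_morphometry(
            state["graph"], state["reference_volume"], fibres=state["fibre_model"]
        )
        write_metrics_csv({"field_0": res}, out / "metrics.csv")
        state["metrics"] = res
        manifest["outputs"]["metrics.csv"] = _sha256(out / "metrics.csv")
    elif stage == "fibres":
        spec = dataclasses.replace(config.phantom, seed=_stage_seed(config.seed, "fibres"))
        sections, truth = generate_serial_sections(
            spec, config.fibre_type_probs, config.imcl_by_type
        )
        records = analyse_sections(sections)
        df = pd.DataFrame(
            [
                {
                    "fibre_id": r.fibre_id,
                    "type": r.fibre_type,
                    "min_feret_um": r.min_feret,
                    "area_um2": r.area,
                    "imcl_pct": r.imcl_index,
                    "flags": ";".join(r.flags),
                }
                for r in records
            ]
        )
        df.to_csv(out / "fibres.csv", index=False, float_format="%.6g")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            summary = section_summary(records)
        (out / "fibre_summary.json").write_text(json.dumps(summary, indent=1, default=float))
        truth.to_csv(out / "fibre_truth.csv", index=False, float_format="%.6g")
        for f in ("fibres.csv", "fibre_summary.json", "fibre_truth.csv"):
            manifest["outputs"][f] = _sha256(out / f)
    elif stage == "stats":
        design = CohortDesign(outcome=config.stats_outcome)
        table = simulate_cohort(design, seed=seed)
        table.to_csv(out / "cohort.csv", index=False, float_format="%.6g")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = {
                muscle: fit_group_model(table, config.stats_outcome, muscle).as_dict()
                for muscle in design.muscles
            }
        (out / "models.json").write_text(json.dumps(models, indent=1, sort_keys=True))
        for f in ("cohort.csv", "models.json"):
            manifest["outputs"][f] = _sha256(out / f)


def validate_against_truth(
    metrics, truth: GroundTruth, tolerances: dict | None = None
) -> dict:
    """Per-metric relative errors of a pipeline run against phantom truth.

    ``metrics`` is a :class:`~myocap3d.capmetrics.MorphometryResult`. Returns
    a report with per-metric relative error and pass/fail against the
    declared tolerance table; degenerate fields (zero truth length) are
    flagged rather than scored.
    """
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    mapping = {
        "LVm": ("LVm", truth.true_LVm),
        "Br_dens": ("Br_dens", truth.true_NV),
        "tortuosity": ("tortuosity", truth.true_tortuosity),
        "MeanCap": ("MeanCap", truth.true_MeanCap),
        "anisotropy": ("anisotropy", truth.true_anisotropy),
    }
    report: dict = {"metrics": {}, "all_pass": True, "degenerate": False}
    if truth.true_LVm == 0:
        report["degenerate"] = True
        report["all_pass"] = all(
            getattr(metrics, attr) == 0 for attr in ("LVm", "Br_dens")
        )
        return report
    for name, (attr, true_val) in mapping.items():
        measured = getattr(metrics, attr)
        if true_val == 0 or not np.isfinite(true_val):
            report["metrics"][name] = {"true": true_val, "measured": measured, "skipped": True}
            continue
        rel = abs(measured - true_val) / abs(true_val)
        ok = bool(rel <= tol[name])
        report["metrics"][name] = {
            "true": float(true_val),
            "measured": float(measured),
            "rel_error": float(rel),
            "tolerance": tol[name],
            "pass": ok,
        }
        report["all_pass"] = report["all_pass"] and ok
    return report
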