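"""Stage orchestration: reproducible runs with manifests and structured logs.

A pipeline run executes an ordered list of stages over a shared working
directory.  Valid orders follow the workflow of the source method: simulate
first, at least one refinement before membrane flip correction, local-only
refinement afterwards, and the analysis stages (relax / flex / classify /
radius) after a refinement.  Every stage writes a JSON manifest with
parameter echo, content hashes of its outputs, and the seed it used, so a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import TwoReferenceClassifier, labels_to_frame
from .flexibility import FocusedRefiner
from .flip import MembraneFlipCorrector, decisions_to_frame
from .particles import write_records_tsv, write_truth_tsv
from .radius import erect_and_project, measure_radius, plot_radius_histogram, radius_histogram
from .refine import SubtomogramRefiner, average_with_symmetry
from .relax import SymmetryRelaxer, arc_occupancy, assignments_to_frame
from .simulate import (
    AcquisitionGeometry,
    DatasetSpec,
    PhantomSpec,
    build_phantom,
    connector_radius,
    simulate_dataset,
)
from .volume import Mask, cylinder_mask, write_mrc

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_STAGES = ("simulate", "refine", "flipfix", "relax", "flex", "classify", "radius")


class StageOrderError(ValueError):
    """The configured stage list violates the workflow order rules."""


@dataclass
class PipelineConfig:
    stages: list
    out_dir: str
    seed: int = 0
    box: int = 48
    pixel: float = 5.0
    phantom: dict = field(default_factory=dict)
    dataset: dict = field(default_factory=dict)
    refine: dict = field(default_factory=dict)
    flipfix: dict = field(default_factory=dict)
    relax: dict = field(default_factory=dict)
    flex: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    radius: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_stage_order(self.stages)


def validate_stage_order(stages: list) -> None:
    seen_refine = False
    for s in stages:
        name = s if isinstance(s, str) else s[0]
        if name not in _STAGES:
            raise StageOrderError(f"unknown stage {name!r}")
        if name == "refine":
            seen_refine = True
        elif name in ("flipfix", "relax", "flex", "classify") and not seen_refine:
            raise StageOrderError(f"stage {name!r} requires a refinement before it")


def load_config(path) -> PipelineConfig:
    with open(path) as f:
        raw = yaml.safe_load(f)
    return PipelineConfig(**raw)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


class _RunState:
    """In-memory state threaded between stages of one run."""

    def __init__(self, out: Path, seed: int, box: int, pixel: float):
        self.out = out
        self.seed = seed
        self.box = box
        self.pixel = pixel
        self.vols = None
        self.records = None
        self.truth = None
        self.reference = None
        self.pspec = None
        self.dspec = None
        self.log_path = out / "run_log.jsonl"

    def log(self, stage: str, **fields) -> None:
        entry = {"stage": stage, "time": time.time(), **_jsonable(fields)}
        with open(self.log_path, "a") as f:
            f.write(json.dumps(entry) + "\n")


def _write_manifest(state: _RunState, stage: str, params: dict, files: list[Path]) -> dict:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": state.seed,
        "params": _jsonable(params),
        "outputs": {str(p.relative_to(state.out)): _hash_file(p) for p in files},
    }
    path = state.out / f"manifest_{stage}.json"
    with open(path, "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return manifest


def _stage_simulate(state: _RunState, cfg: PipelineConfig, params: dict) -> list[Path]:
    pspec = PhantomSpec(**{**cfg.phantom, **params.get("phantom", {})})
    dargs = {**cfg.dataset, **params.get("dataset", {})}
    dargs.setdefault("seed", state.seed)
    wedge = dargs.pop("wedge", "default")
    if wedge == "default":
        wedge = AcquisitionGeometry()
    elif wedge in (None, "none"):
        wedge = None
    elif isinstance(wedge, dict):
        wedge = AcquisitionGeometry(**wedge)
    dspec = DatasetSpec(wedge=wedge, **dargs)
    vols, records, truth = simulate_dataset(pspec, dspec, state.box, state.pixel)
    state.vols, state.records, state.truth = vols, records, truth
    state.pspec, state.dspec = pspec, dspec
    files = []
    vol_dir = state.out / "subtomograms"
    vol_dir.mkdir(exist_ok=True)
    for r, v in zip(records, vols):
        p = vol_dir / f"particle_{r.particle_id:05d}.mrc"
        write_mrc(p, v)
        files.append(p)
    rec_path = state.out / "particles.tsv"
    write_records_tsv(rec_path, records)
    truth_path = state.out / "ground_truth.tsv"
    write_truth_tsv(truth_path, truth)
    files += [rec_path, truth_path]
    return files


def _require_data(state: _RunState, stage: str) -> None:
    if state.vols is None or state.records is None:
        raise StageOrderError(f"stage {stage!r} has no simulated data to work on")


def _stage_refine(state: _RunState, cfg: PipelineConfig, params: dict) -> list[Path]:
    _require_data(state, "refine")
    kwargs = {**cfg.refine, **params}
    kwargs.setdefault("seed", state.seed)
    use_phantom_ref = kwargs.pop("phantom_reference", False)
    wedge = kwargs.pop("wedge", "dataset")
    if wedge == "dataset":
        wedge = state.dspec.wedge if state.dspec is not None else None
    refiner = SubtomogramRefiner(wedge=wedge, **kwargs)
    if use_phantom_ref and state.pspec is not None:
        refiner.initial_reference = build_phantom(state.pspec, state.box, state.pixel)
    refiner.fit(state.vols, state.records)
    state.records = refiner.records_
    state.reference = refiner.map_
    map_path = state.out / "refined_map.mrc"
    write_mrc(map_path, refiner.map_)
    rec_path = state.out / "particles_refined.tsv"
    write_records_tsv(rec_path, refiner.records_)
    fsc_path = state.out / "fsc.json"
    with open(fsc_path, "w") as f:
        json.dump(
            {
                "shell_frequency": refiner.fsc_.shell_frequency.tolist(),
                "correlation": refiner.fsc_.correlation.tolist(),
                "resolution": refiner.resolution_,
                "mean_score": refiner.log_["mean_score"],
            },
            f,
            indent=1,
        )
    return [map_path, rec_path, fsc_path]


def _stage_flipfix(state: _RunState, cfg: PipelineConfig, params: dict) -> list[Path]:
    _require_data(state, "flipfix")
    kwargs = {**cfg.flipfix, **params}
    corrector = MembraneFlipCorrector(**kwargs)
    state.records = corrector.fit_transform(state.records)
    rec_path = state.out / "particles_flipfixed.tsv"
    write_records_tsv(rec_path, state.records)
    dec_path = state.out / "flip_decisions.tsv"
    decisions_to_frame(corrector.decisions_).to_csv(dec_path, sep="\t", index=False)
    return [rec_path, dec_path]


def _default_focus_mask(state: _RunState) -> Mask:
    ps = state.pspec if state.pspec is not None else PhantomSpec()
    r0 = connector_radius(ps)
    from .volume import _physical_coords, soft_mask_from_binary

    z, y, x = _physical_coords(state.box, state.pixel)
    r = np.hypot(x, y)
    binary = (
        (r > r0 - 15.0)
        & (r < r0 + 15.0)
        & (z > ps.gate_z - 15.0)
        & (z < ps.gate_z + 25.0)
    )
    return soft_mask_from_binary(
        np.broadcast_to(binary, (state.box,) * 3).copy(), state.pixel, 2.0
    )


def _stage_relax(state: _RunState, cfg: PipelineConfig, params: dict) -> list[Path]:
    _require_data(state, "relax")
    kwargs = {**cfg.relax, **params}
    n_sym = kwargs.pop("n_sym", state.pspec.n_sym if state.pspec else 15)
    threshold = kwargs.pop("occupancy_threshold", 0.5)
    mask = kwargs.pop("focus_mask", None) or _default_focus_mask(state)
    c1_ref = kwargs.pop("c1_reference", None)
    if c1_ref is None and state.pspec is not None:
        c1_ref = build_phantom(state.pspec, state.box, state.pixel)
    relaxer = SymmetryRelaxer(n_sym=n_sym, c1_reference=c1_ref, focus_mask=mask)
    relaxer.fit(state.vols, state.records)
    c1_path = state.out / "c1_map.mrc"
    write_mrc(c1_path, relaxer.c1_map_)
    asn_path = state.out / "unit_assignments.tsv"
    assignments_to_frame(relaxer.assignments_).to_csv(asn_path, sep="\t", index=False)
    ps = state.pspec if state.pspec is not None else PhantomSpec()
    rim = connector_radius(ps)
    zc = int(round((ps.gate_z + 5.0) / state.pixel))
    occ = arc_occupancy(
        relaxer.c1_map_, rim_radius=rim, z_band=(zc - 2, zc + 2), threshold=threshold
    )
    occ_path = state.out / "arc_occupancy.json"
    with open(occ_path, "w") as f:
        json.dump(
            {"occupancy_degrees": occ, "threshold": threshold, "rim_radius": rim}, f, indent=1
        )
    return [c1_path, asn_path, occ_path]


def _default_protein_mask(state: _RunState) -> Mask:
    ps = state.pspec if state.pspec is not None else PhantomSpec()
    return cylinder_mask(
        state.box,
        state.pixel,
        radius=ps.flare_radius + 10.0,
        z_min=ps.gate_z + 20.0,
        z_max=ps.height / 2.0 + 5.0,
        soft_width=2.0,
    )


def _stage_flex(state: _RunState, cfg: PipelineConfig, params: dict) -> list[Path]:
    _require_data(state, "flex")
    kwargs = {**cfg.flex, **params}
    n_intervals = kwargs.pop("n_intervals", 5)
    mask = kwargs.pop("protein_mask", None) or _default_protein_mask(state)
    ref = kwargs.pop("reference", None)
    if ref == "phantom" or (ref is None and state.reference is None):
        ref = build_phantom(state.pspec, state.box, state.pixel)
    elif ref is None:
        ref = state.reference
    wedge = kwargs.pop("wedge", "dataset")
    if wedge == "dataset":
        wedge = state.dspec.wedge if state.dspec is not None else None
    refiner = FocusedRefiner(
        protein_mask=mask, reference=ref, n_intervals=n_intervals, wedge=wedge, **kwargs
    )
    refiner.fit(state.vols, state.records)
    files = []
    tilt_path = state.out / "tilts.tsv"
    refiner.tilt_table(state.records).to_csv(tilt_path, sep="\t", index=False)
    files.append(tilt_path)
    for i, c in enumerate(refiner.classes_):
        if c.class_average is not None:
            p = state.out / f"trajectory_class_{i}.mrc"
            write_mrc(p, c.class_average)
            files.append(p)
    summary = state.out / "trajectory.json"
    with open(summary, "w") as f:
        json.dump(
            {
                "endpoint_separation_degrees": refiner.endpoint_separation_,
                "intervals": [
                    {
                        "tilt_low": c.tilt_low,
                        "tilt_high": c.tilt_high,
                        "n_members": len(c.member_ids),
                    }
                    for c in refiner.classes_
                ],
            },
            f,
            indent=1,
        )
    files.append(summary)
    return files


def _stage_classify(state: _RunState, cfg: PipelineConfig, params: dict) -> list[Path]:
    _require_data(state, "classify")
    kwargs = {**cfg.classify, **params}
    ref = kwargs.pop("reference", None)
    if ref is None:
        ref = state.reference
    if ref is None:
        n_sym = state.pspec.n_sym if state.pspec else 15
        ref = average_with_symmetry(state.vols, state.records, n_sym)
    wedge = kwargs.pop("wedge", "dataset")
    if wedge == "dataset":
        wedge = state.dspec.wedge if state.dspec is not None else None
    clf = TwoReferenceClassifier(reference=ref, wedge=wedge, **kwargs)
    clf.fit(state.vols, state.records)
    path = state.out / "class_labels.tsv"
    labels_to_frame(clf.class_labels_).to_csv(path, sep="\t", index=False)
    summary = state.out / "class_counts.json"
    with open(summary, "w") as f:
        json.dump({"class_0": int(clf.counts_[0]), "class_1": int(clf.counts_[1])}, f)
    return [path, summary]


def _stage_radius(state: _RunState, cfg: PipelineConfig, params: dict) -> list[Path]:
    _require_data(state, "radius")
    kwargs = {**cfg.radius, **params}
    cutoff = kwargs.pop("lowpass_cutoff", 40.0)
    bin_width = kwargs.pop("bin_width", state.pixel)
    rows = []
    for v, r in zip(state.vols, state.records):
        img = erect_and_project(v, r.orientation)
        rows.append((r.particle_id, measure_radius(img, cutoff, state.pixel)))
    import pandas as pd

    tab_path = state.out / "radii.tsv"
    pd.DataFrame(rows, columns=["particle_id", "radius_angstrom"]).to_csv(
        tab_path, sep="\t", index=False
    )
    hist = radius_histogram([r for _, r in rows], bin_width)
    hist_path = state.out / "radius_histogram.tsv"
    import pandas as pd

    pd.DataFrame(
        {
            "bin_low": hist.bin_edges[:-1],
            "bin_high": hist.bin_edges[1:],
            "count": hist.counts,
        }
    ).to_csv(hist_path, sep="\t", index=False)
    peaks_path = state.out / "radius_peaks.json"
    with open(peaks_path, "w") as f:
        json.dump({"peak_radii_angstrom": hist.peak_radii.tolist()}, f)
    plot_path = state.out / "radius_histogram.png"
    plot_radius_histogram(hist, plot_path)
    return [tab_path, hist_path, peaks_path, plot_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "refine": _stage_refine,
    "flipfix": _stage_flipfix,
    "relax": _stage_relax,
    "flex": _stage_flex,
    "classify": _stage_classify,
    "radius": _stage_radius,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    validate_stage_order(config.stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_manifest = {"version": __version__, "seed": config.seed, "stages": []}
    state = _RunState(out, config.seed, config.box, config.pixel)
    counts: dict[str, int] = {}
    for s in config.stages:
        name, params = (s, {}) if isinstance(s, str) else (s[0], s[1] or {})
        counts[name] = counts.get(name, 0) + 1
        t0 = time.time()
        files = _STAGE_FUNCS[name](state, config, params)
        manifest = _write_manifest(state, f"{name}{counts[name]}", params, files)
        state.log(name, elapsed=time.time() - t0, params=params)
        run_manifest["stages"].append(manifest)
    with open(out / "run_manifest.json", "w") as f:
        json.dump(run_manifest, f, indent=1, sort_keys=True)
    return run_manifest
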