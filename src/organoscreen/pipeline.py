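"""Pipeline orchestration: simulate → segment → featurize → normalize →
select → cluster → classify, as a configurable, seeded, resumable flow.

Each stage reads and writes files under the configured output directory and
records a manifest (stage name, parameters, seed, input hashes).  Rerunning
a stage whose manifest still matches its inputs is a no-op, so an
interrupted run resumes from the last valid artifact.  The whole pipeline
is a pure function of (config, seed): rerunning from scratch reproduces
identical tables.

:func:`profile_plate` is the in-memory fast path used by tests and scripts:
it renders, segments and featurizes one well at a time without touching
disk, with the same per-well computations as the staged pipeline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as osio
from .clustering import (NO_EFFECT, assign_dose_labels, build_dose_profiles,
                         fit_cluster_model)
from .features import (extract_feature_battery, feature_definitions,
                       zscore_normalize)
from .segmentation import (NucleusObject, OrganoidObject, SectionMask,
                           SegmentationParams, segment_well)
from .selection import RandomForestConfig, run_accumulative_selection
from .synthetic import (PlateSpec, build_plate_map, default_plate_spec,
                        iterate_plate_wells, two_group_plate_spec)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "profile_plate", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    enabled: bool = True
    preset: Literal["default", "two_group", "demo"] = "default"
    noise_sd: float = 150.0
    geometry: tuple[int, int, int] = (8, 256, 256)
    defocus_sections: tuple[int, ...] = (0,)


class SegmentationConfig(_Strict):
    min_object_area: int = 25
    min_nucleus_area: int = 4
    sharpness_min: float = 0.18
    min_overlap_ratio: float = 0.5
    nucleus_max_dist: float = 6.0


class FeatureConfig(_Strict):
    count_variant: Literal["per_section_sum", "distinct_objects"] = "per_section_sum"


class SelectionConfig(_Strict):
    k: int = 10
    n_bootstrap: int = 30
    n_repetitions: int = 500
    cutoff: float = 0.05
    n_estimators: int = 200


class ClusteringConfig(_Strict):
    k: int | None = None
    k_min: int = 2
    k_max: int = 10
    effect_floor: float = 1.0


class PipelineConfig(_Strict):
    """One source of truth for every stage's parameters."""

    seed: int = 1
    output_dir: str = "pipeline_out"
    input_dir: str | None = None  # existing stacks + plate map when not simulating
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    clustering: ClusteringConfig = Field(default_factory=ClusteringConfig)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json")))


def load_config(path: Path) -> PipelineConfig:
    return PipelineConfig.from_yaml(path)


def _plate_spec(cfg: PipelineConfig) -> PlateSpec:
    if cfg.simulate.preset == "default":
        base = default_plate_spec(cfg.seed)
    elif cfg.simulate.preset == "two_group":
        base = two_group_plate_spec(cfg.seed)
    else:  # demo: a 24-well opposing-template plate for quick runs
        from .synthetic import TreatmentSpec, invasive_template, polarized_template
        base = PlateSpec(
            treatments=(
                TreatmentSpec(name="suppressor", template=polarized_template(),
                              doses=(1.0, 3.0, 30.0), replicates=3),
                TreatmentSpec(name="promoter", template=invasive_template(),
                              doses=(1.0, 3.0, 30.0), replicates=3),
            ),
            seed=cfg.seed,
        )
    return PlateSpec(
        treatments=base.treatments,
        seed=cfg.seed,
        geometry=cfg.simulate.geometry,
        noise_sd=cfg.simulate.noise_sd,
        defocus_sections=cfg.simulate.defocus_sections,
    )


def _seg_params(cfg: PipelineConfig) -> SegmentationParams:
    s = cfg.segmentation
    return SegmentationParams(
        min_object_area=s.min_object_area,
        min_nucleus_area=s.min_nucleus_area,
        sharpness_min=s.sharpness_min,
        min_overlap_ratio=s.min_overlap_ratio,
        nucleus_max_dist=s.nucleus_max_dist,
    )


# ---------------------------------------------------------------------------
# in-memory fast path


def profile_plate(
    spec: PlateSpec,
    seg_params: SegmentationParams | None = None,
    count_variant: str = "per_section_sum",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render, segment and featurize a plate well by well (no disk I/O).

    Returns ``(raw wells × 294 feature table, plate map)``.
    """
    seg_params = seg_params or SegmentationParams()
    rows = {}
    plate_rows = []
    for row, stack, _truth in iterate_plate_wells(spec):
        organoids, nuclei_objects, _ = segment_well(
            stack.actin, stack.nuclei, seg_params)
        rows[row.well] = extract_feature_battery(
            organoids, nuclei_objects,
            stack.actin.astype(float), stack.nuclei.astype(float),
            count_variant,
        )
        plate_rows.append(row)
    table = pd.DataFrame(rows).T
    table.index.name = "well"
    return table, pd.DataFrame(plate_rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# staged, file-based pipeline


def _hash_files(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(map(Path, paths)):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _manifest_path(out: Path, stage: str) -> Path:
    return out / "manifests" / f"{stage}.json"


def _stage_current(out: Path, stage: str, params: dict, input_hash: str) -> bool:
    mp = _manifest_path(out, stage)
    if not mp.exists():
        return False
    try:
        manifest = json.loads(mp.read_text())
    except json.JSONDecodeError:
        return False
    if manifest.get("params") != params or manifest.get("input_hash") != input_hash:
        return False
    return all(Path(p).exists() for p in manifest.get("outputs", []))


def _write_manifest(out: Path, stage: str, params: dict, input_hash: str,
                    outputs: list[Path]) -> None:
    osio.write_json(
        {"stage": stage, "params": params, "input_hash": input_hash,
         "outputs": [str(p) for p in outputs]},
        _manifest_path(out, stage),
    )


def _stage_simulate(cfg: PipelineConfig, out: Path) -> Path:
    params = {**cfg.simulate.model_dump(mode="json"), "seed": cfg.seed}
    stacks_dir = out / "stacks"
    if _stage_current(out, "simulate", params, ""):
        log.info("simulate: up to date")
        return stacks_dir
    spec = _plate_spec(cfg)
    outputs = []
    for row, stack, truth in iterate_plate_wells(spec):
        outputs.extend(osio.write_stack(stack, stacks_dir).values())
        osio.write_ground_truth(truth, out / "truth" / f"{row.well}.json")
    plate_map_path = out / "plate_map.csv"
    osio.write_plate_map(build_plate_map(spec), plate_map_path)
    outputs.append(plate_map_path)
    _write_manifest(out, "simulate", params, "", outputs)
    log.info("simulate: wrote %d wells", spec.n_wells)
    return stacks_dir


def _stage_segment(cfg: PipelineConfig, out: Path) -> None:
    plate_map = osio.read_plate_map(out / "plate_map.csv")
    stack_files = sorted((out / "stacks").glob("*.tif"))
    params = {**cfg.segmentation.model_dump(mode="json")}
    input_hash = _hash_files([out / "plate_map.csv"]) + str(len(stack_files))
    if _stage_current(out, "segment", params, input_hash):
        log.info("segment: up to date")
        return
    seg = _seg_params(cfg)
    outputs = []
    table_rows = []
    for well in plate_map["well"]:
        stack = osio.read_stack(out / "stacks", well)
        organoids, nuclei_objects, _ = segment_well(stack.actin, stack.nuclei, seg)
        payload = {
            "well": well,
            "organoids": [_object_payload(o) for o in organoids],
            "nuclei_objects": [_object_payload(o) for o in nuclei_objects],
        }
        path = out / "objects" / f"{well}.json"
        osio.write_json(payload, path)
        outputs.append(path)
        labels = _label_stack(organoids, stack.actin.shape)
        lp = out / "labels" / f"{well}_actin_labels.tif"
        lp.parent.mkdir(parents=True, exist_ok=True)
        osio.write_label_stack(labels, lp)
        outputs.append(lp)
        for o in organoids:
            for m in o.sections:
                cx, cy = m.centroid
                table_rows.append((well, o.object_id, m.section_index, m.area, cx, cy))
    obj_csv = out / "objects.csv"
    pd.DataFrame(table_rows, columns=["well", "object_id", "section", "area",
                                      "centroid_x", "centroid_y"]).to_csv(
        obj_csv, index=False)
    outputs.append(obj_csv)
    _write_manifest(out, "segment", params, input_hash, outputs)
    log.info("segment: %d wells", len(plate_map))


def _object_payload(o: OrganoidObject) -> dict:
    return {
        "object_id": o.object_id,
        "sections": [
            {"section": m.section_index, "pixels": m.pixels.tolist(),
             "channel": m.channel}
            for m in o.sections
        ],
        "children": [
            {"section": n.section_index, "x": n.mass_center[0],
             "y": n.mass_center[1], "area": n.area}
            for n in o.children
        ],
    }


def _object_from_payload(d: dict) -> OrganoidObject:
    sections = [
        SectionMask(section_index=s["section"], pixels=np.asarray(s["pixels"]),
                    channel=s["channel"])
        for s in d["sections"]
    ]
    children = [
        NucleusObject(section_index=c["section"], mass_center=(c["x"], c["y"]),
                      area=c["area"])
        for c in d["children"]
    ]
    return OrganoidObject(object_id=d["object_id"], sections=sections,
                          children=children)


def _label_stack(organoids: list[OrganoidObject], shape) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int32)
    for o in organoids:
        for m in o.sections:
            labels[m.section_index, m.pixels[:, 1], m.pixels[:, 0]] = o.object_id
    return labels


def _stage_featurize(cfg: PipelineConfig, out: Path) -> None:
    plate_map = osio.read_plate_map(out / "plate_map.csv")
    params = cfg.features.model_dump(mode="json")
    object_files = sorted((out / "objects").glob("*.json"))
    input_hash = _hash_files(object_files[:4]) + str(len(object_files))
    if _stage_current(out, "featurize", params, input_hash):
        log.info("featurize: up to date")
        return
    rows = {}
    for well in plate_map["well"]:
        payload = osio.read_json(out / "objects" / f"{well}.json")
        organoids = [_object_from_payload(d) for d in payload["organoids"]]
        nuclei_objects = [_object_from_payload(d) for d in payload["nuclei_objects"]]
        stack = osio.read_stack(out / "stacks", well)
        rows[well] = extract_feature_battery(
            organoids, nuclei_objects,
            stack.actin.astype(float), stack.nuclei.astype(float),
            cfg.features.count_variant,
        )
    table = pd.DataFrame(rows).T
    table.index.name = "well"
    path = out / "features_raw.csv"
    osio.write_feature_table(table, path, normalized=False)
    osio.write_json(feature_definitions(), out / "feature_definitions.json")
    _write_manifest(out, "featurize", params, input_hash, [path])
    log.info("featurize: %d wells x %d features", *table.shape)


def _stage_normalize(cfg: PipelineConfig, out: Path) -> None:
    params: dict = {}
    input_hash = _hash_files([out / "features_raw.csv"])
    if _stage_current(out, "normalize", params, input_hash):
        log.info("normalize: up to date")
        return
    table, _ = osio.read_feature_table(out / "features_raw.csv")
    plate_map = osio.read_plate_map(out / "plate_map.csv")
    incomplete = table.index[table.isna().any(axis=1)]
    if len(incomplete):
        log.warning("dropping %d wells with missing features: %s",
                    len(incomplete), list(incomplete))
        table = table.drop(index=incomplete)
    normalized, excluded = zscore_normalize(table, plate_map)
    path = out / "features_norm.csv"
    osio.write_feature_table(normalized, path, normalized=True)
    osio.write_json({"excluded": excluded}, out / "excluded_features.json")
    _write_manifest(out, "normalize", params, input_hash, [path])


def _stage_select(cfg: PipelineConfig, out: Path) -> None:
    params = cfg.selection.model_dump(mode="json")
    input_hash = _hash_files([out / "features_norm.csv"])
    if _stage_current(out, "select", params, input_hash):
        log.info("select: up to date")
        return
    normalized, _ = osio.read_feature_table(out / "features_norm.csv")
    plate_map = osio.read_plate_map(out / "plate_map.csv")
    result, _comps = run_accumulative_selection(
        normalized, plate_map,
        k=cfg.selection.k,
        n_bootstrap=cfg.selection.n_bootstrap,
        n_repetitions=cfg.selection.n_repetitions,
        cutoff=cfg.selection.cutoff,
        seed=cfg.seed,
        forest=RandomForestConfig(n_estimators=cfg.selection.n_estimators),
    )
    freq_path = out / "selection_frequencies.csv"
    result.frequency.sort_values(ascending=False).rename("frequency").to_csv(freq_path)
    sel_path = out / "selected_features.json"
    osio.write_json(
        {"selected": result.selected, "cutoff": result.cutoff, "k": result.k,
         "n_repetitions": result.n_repetitions, "n_pairs": result.n_pairs},
        sel_path,
    )
    _write_manifest(out, "select", params, input_hash, [freq_path, sel_path])
    log.info("select: %d features pass the %.0f%% cutoff",
             len(result.selected), 100 * result.cutoff)


def _stage_cluster(cfg: PipelineConfig, out: Path) -> None:
    params = cfg.clustering.model_dump(mode="json")
    input_hash = _hash_files([out / "features_norm.csv", out / "selected_features.json"])
    if _stage_current(out, "cluster", params, input_hash):
        log.info("cluster: up to date")
        return
    normalized, _ = osio.read_feature_table(out / "features_norm.csv")
    plate_map = osio.read_plate_map(out / "plate_map.csv")
    selected = osio.read_json(out / "selected_features.json")["selected"]
    profiles = build_dose_profiles(normalized, plate_map, selected)
    model = fit_cluster_model(
        profiles,
        k=cfg.clustering.k,
        k_range=(cfg.clustering.k_min, cfg.clustering.k_max),
        effect_floor=cfg.clustering.effect_floor,
        stability_seed=cfg.seed,
    )
    model_path = out / "cluster_model.json"
    osio.write_json(
        {
            "k": model.k,
            "features": model.features,
            "stability": model.stability,
            "effect_floor": model.effect_floor,
            "centroids": {c: model.centroids.loc[c].to_dict()
                          for c in model.centroids.index},
            "signatures": {
                c: {"F": f.to_dict(),
                    "percent": (None if pct is None else pct.to_dict())}
                for c, (f, pct) in model.signatures.items()
            },
            "index_curves": model.index_curves.reset_index().to_dict("records"),
        },
        model_path,
    )
    labels_path = out / "cluster_labels.csv"
    model.labels.rename("class").to_csv(labels_path)
    profiles_path = out / "dose_profiles.csv"
    profiles.to_csv(profiles_path)
    _plot_cluster_figures(model, profiles, out)
    _write_manifest(out, "cluster", params, input_hash,
                    [model_path, labels_path, profiles_path])
    log.info("cluster: k=%d, stability=%.2f", model.k, model.stability)


def _plot_cluster_figures(model, profiles, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(model.linkage, labels=[f"{t}@{d:g}" for t, d in profiles.index], ax=ax)
    ax.set_ylabel("Ward distance")
    fig.tight_layout()
    fig.savefig(out / "dendrogram.png", dpi=100)
    plt.close(fig)

    sig = pd.DataFrame({c: pct for c, (f, pct) in model.signatures.items()
                        if pct is not None})
    if not sig.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        vmax = np.nanmax(np.abs(sig.to_numpy()))
        im = ax.imshow(sig.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(sig.shape[1]), sig.columns)
        ax.set_yticks(range(sig.shape[0]), sig.index, fontsize=7)
        fig.colorbar(im, label="partition size %(i)")
        fig.tight_layout()
        fig.savefig(out / "signature_heatmap.png", dpi=100)
        plt.close(fig)


def _stage_classify(cfg: PipelineConfig, out: Path) -> None:
    params = {"effect_floor": cfg.clustering.effect_floor}
    input_hash = _hash_files([out / "cluster_model.json", out / "dose_profiles.csv"])
    if _stage_current(out, "classify", params, input_hash):
        log.info("classify: up to date")
        return
    normalized, _ = osio.read_feature_table(out / "features_norm.csv")
    plate_map = osio.read_plate_map(out / "plate_map.csv")
    model_payload = osio.read_json(out / "cluster_model.json")
    selected = model_payload["features"]
    profiles = build_dose_profiles(normalized, plate_map, selected)
    from .clustering import ClusterModel  # lazy: reconstruct a light model
    centroids = pd.DataFrame(model_payload["centroids"]).T[selected]
    model = ClusterModel(
        k=model_payload["k"], features=selected,
        labels=pd.Series(dtype=object), centroids=centroids, signatures={},
        index_curves=pd.DataFrame(), linkage=np.empty((0, 4)),
        effect_floor=model_payload["effect_floor"],
    )
    rows = []
    for treatment in sorted({t for t, _ in profiles.index}):
        seq = assign_dose_labels(treatment, profiles, model)
        for dose, lab in zip(seq.doses, seq.labels):
            rows.append((treatment, dose, lab, seq.general_class))
    path = out / "class_sequences.csv"
    pd.DataFrame(rows, columns=["treatment", "dose", "class", "general_class"]
                 ).to_csv(path, index=False)
    _write_manifest(out, "classify", params, input_hash, [path])
    log.info("classify: wrote %s", path)


_STAGES = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "featurize": _stage_featurize,
    "normalize": _stage_normalize,
    "select": _stage_select,
    "cluster": _stage_cluster,
    "classify": _stage_classify,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Execute the pipeline stages in order; returns the output directory.

    A stage failure halts the run with the stage named; artifacts of
    completed stages are preserved and reused on the next invocation.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    order = list(_STAGES) if stages is None else stages
    if not cfg.simulate.enabled and "simulate" in order:
        order = [s for s in order if s != "simulate"]
        if cfg.input_dir is None:
            raise ValueError("simulate disabled but no input_dir with a plate map given")
        src = Path(cfg.input_dir)
        if not (src / "plate_map.csv").exists():
            raise FileNotFoundError(f"missing plate map: {src / 'plate_map.csv'}")
    for stage in order:
        try:
            _STAGES[stage](cfg, out)
        except Exception:
            log.error("pipeline halted in stage %r (partial outputs kept in %s)",
                      stage, out)
            raise
    report = {
        "stages": order,
        "seed": cfg.seed,
        "outputs": sorted(str(p.relative_to(out)) for p in out.rglob("*")
                          if p.is_file()),
    }
    osio.write_json(report, out / "report.json")
    return out
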