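"""End-to-end analysis runs driven by a single YAML config.

Three entry points mirror the analysis structure: ``run_verb_epoch`` (verb
topic + verb topic entropy model RDMs), ``run_noun_epoch`` (verb-weighted
noun, noun topic, verb–noun interaction with partialling, verb constraint
error), and ``run_connectivity`` (both directions of an ordered region
pair).  Each writes group results (HDF5), cluster summaries (TSV) and a
provenance record (config hash, master seed, package versions).

A single master seed fans out to stage-specific child seeds so that stages
are reproducible in isolation; two runs with identical configs produce
identical statistical outputs.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connectivity import (ConnectivityGroupResult, RoiDefinition,
                           connectivity_cluster_inference, default_lags_ms,
                           directed_connectivity_map, save_connectivity_stack,
                           select_roi)
from .rdm import RDM, StimulusSet, build_model_rdms
from .ssrsa import (GroupResult, SearchlightSpec, SourceEpochs,
                    group_cluster_inference, model_fit_map,
                    multivariate_normalize, spatial_adjacency)
from .topics import CooccurrenceTable, build_verb_documents, fit_topic_model

log = logging.getLogger(__name__)

VERB_EPOCH_MODELS = ("verb_topic", "verb_topic_entropy")
NOUN_EPOCH_MODELS = ("verb_weighted_noun", "noun_topic",
                     "verb_noun_interaction", "verb_constraint_error")


@dataclass
class RunConfig:
    """Validated analysis configuration; see the YAML keys in the README."""

    seed: int
    paths: dict = field(default_factory=dict)
    topics: dict = field(default_factory=dict)
    rsa: dict = field(default_factory=dict)
    connectivity: dict = field(default_factory=dict)

    _DEFAULTS = {
        "topics": {"K": 10, "alpha": None, "eta": 0.01, "max_iter": 200,
                   "weighting": True},
        "rsa": {"spatial_radius_mm": 10.0, "temporal_radius_ms": 30.0,
                "center_step": 1, "point_alpha": 0.01, "cluster_alpha": 0.05,
                "n_perm": 5000, "normalize": True, "shrinkage": "auto",
                "method": "spearman"},
        "connectivity": {"lags_min_ms": 2.0, "lags_max_ms": 120.0,
                         "n_top": 100, "point_alpha": 0.001,
                         "cluster_alpha": 0.01, "n_perm": 5000,
                         "source_roi": None, "target_roi": None,
                         "group_result": None, "source_mask": None,
                         "target_mask": None},
    }

    def __post_init__(self) -> None:
        for section, defaults in self._DEFAULTS.items():
            merged = dict(defaults)
            merged.update(getattr(self, section) or {})
            setattr(self, section, merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls(seed=int(raw.get("seed", 0)),
                   paths=raw.get("paths", {}),
                   topics=raw.get("topics", {}),
                   rsa=raw.get("rsa", {}),
                   connectivity=raw.get("connectivity", {}))

    def validate(self, require=("cooccurrence", "stimuli", "epochs")) -> None:
        for key in require:
            if key not in self.paths:
                raise ValueError(f"config paths.{key} is missing")
        for key in ("cooccurrence", "stimuli", "mask"):
            if key in require and not Path(self.paths[key]).exists():
                raise ValueError(f"input not found: {self.paths[key]}")
        if "epochs" in require and not self.epoch_paths():
            raise ValueError("no epoch files matched paths.epochs")
        for section in ("rsa", "connectivity"):
            cfg = getattr(self, section)
            for key in ("point_alpha", "cluster_alpha"):
                if not 0.0 < cfg[key] < 1.0:
                    raise ValueError(f"{section}.{key} must lie in (0, 1)")
            if cfg["n_perm"] < 1:
                raise ValueError(f"{section}.n_perm must be >= 1")

    def epoch_paths(self) -> list[str]:
        spec = self.paths.get("epochs")
        if spec is None:
            return []
        if isinstance(spec, str):
            return sorted(glob.glob(spec))
        return [str(p) for p in spec]

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).hexdigest()
        return int(digest[:8], 16) % (2 ** 31)

    def as_dict(self) -> dict:
        return {"seed": self.seed, "paths": self.paths, "topics": self.topics,
                "rsa": self.rsa, "connectivity": self.connectivity}

    def digest(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _read_vertex_list(path) -> np.ndarray:
    with open(path) as f:
        return np.array([int(line) for line in f if line.strip()], dtype=int)


def _write_provenance(outdir: Path, config: RunConfig, stage: str) -> None:
    import scipy
    rec = {"stage": stage, "config": config.as_dict(),
           "config_hash": config.digest(), "seed": config.seed,
           "versions": {"semrsa": __version__,
                        "numpy": np.__version__, "scipy": scipy.__version__}}
    with open(outdir / f"provenance_{stage}.json", "w") as f:
        json.dump(rec, f, indent=2, default=str)


def _fit_models(config: RunConfig) -> dict[str, RDM]:
    cooc = CooccurrenceTable.from_tsv(config.paths["cooccurrence"])
    stimuli = StimulusSet.from_tsv(config.paths["stimuli"])
    docs = build_verb_documents(cooc)
    model = fit_topic_model(docs, K=config.topics["K"],
                            seed=config.stage_seed("topics"),
                            alpha=config.topics["alpha"],
                            eta=config.topics["eta"],
                            max_iter=config.topics["max_iter"])
    return build_model_rdms(model, stimuli,
                            weighting=config.topics["weighting"])


def _searchlight_spec(config: RunConfig) -> SearchlightSpec:
    mask = None
    if config.paths.get("mask"):
        mask = _read_vertex_list(config.paths["mask"])
    return SearchlightSpec(
        spatial_radius_mm=config.rsa["spatial_radius_mm"],
        temporal_radius_ms=config.rsa["temporal_radius_ms"],
        mask=mask, center_step=config.rsa["center_step"])


def _run_epoch_models(config: RunConfig,
                      jobs: list[tuple[str, str, list[str]]],
                      ) -> dict[str, GroupResult]:
    """Shared machinery: fit per-subject maps and run group inference.

    ``jobs`` entries are (output label, model RDM label, control labels).
    """
    config.validate()
    outdir = Path(config.paths.get("output_dir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    rdms = _fit_models(config)
    spec = _searchlight_spec(config)

    fitmaps: dict[str, list] = {label: [] for label, _, _ in jobs}
    coords = None
    for path in config.epoch_paths():
        epochs = SourceEpochs.load(path)
        if coords is None:
            coords = epochs.vertex_coords
        elif not np.allclose(coords, epochs.vertex_coords):
            raise ValueError(f"mesh mismatch in {path}")
        if config.rsa["normalize"]:
            epochs = multivariate_normalize(epochs,
                                            shrinkage=config.rsa["shrinkage"])
        for label, model_label, control_labels in jobs:
            fm = model_fit_map(epochs, rdms[model_label],
                               controls=[rdms[c] for c in control_labels],
                               spec=spec, method=config.rsa["method"])
            fm.model_label = label
            fitmaps[label].append(fm)
        log.info("fitted %s", path)

    mask = spec.mask if spec.mask is not None else np.arange(coords.shape[0])
    adj = spatial_adjacency(coords[mask], spec.spatial_radius_mm)
    results = {}
    for label, _, _ in jobs:
        gr = group_cluster_inference(
            fitmaps[label], adj,
            point_alpha=config.rsa["point_alpha"],
            cluster_alpha=config.rsa["cluster_alpha"],
            n_perm=config.rsa["n_perm"],
            seed=config.stage_seed(f"cluster:{label}"))
        gr.save(outdir / f"{label}_group.h5")
        gr.cluster_table().to_csv(outdir / f"{label}_clusters.tsv",
                                  sep="\t", index=False)
        results[label] = gr
        log.info("model %s: %d clusters, %d significant points",
                 label, len(gr.clusters), int(gr.mask.sum()))
    return results


def run_verb_epoch(config: RunConfig) -> dict[str, GroupResult]:
    """Verb-epoch analysis: verb topic and verb topic entropy model RDMs."""
    jobs = [("verb_topic", "verb_topic", []),
            ("verb_topic_entropy", "verb_topic_entropy", [])]
    results = _run_epoch_models(config, jobs)
    _write_provenance(Path(config.paths.get("output_dir", ".")), config,
                      "verb_epoch")
    return results


def run_noun_epoch(config: RunConfig) -> dict[str, GroupResult]:
    """Noun-epoch analysis: four DO-noun model RDMs.

    The verb–noun interaction is the verb-weighted noun RDM fitted with the
    verb topic and noun topic RDMs partialled out.
    """
    jobs = [("verb_weighted_noun", "verb_weighted_noun", []),
            ("noun_topic", "noun_topic", []),
            ("verb_noun_interaction", "verb_weighted_noun",
             ["verb_topic", "noun_topic"]),
            ("verb_constraint_error", "verb_constraint_error", [])]
    results = _run_epoch_models(config, jobs)
    _write_provenance(Path(config.paths.get("output_dir", ".")), config,
                      "noun_epoch")
    return results


def _resolve_roi(config: RunConfig, which: str) -> RoiDefinition:
    cfg = config.connectivity
    if cfg[f"{which}_roi"]:
        return RoiDefinition(_read_vertex_list(cfg[f"{which}_roi"]),
                             source_label=f"{which}:file")
    if not cfg["group_result"]:
        raise ValueError(f"connectivity.{which}_roi or group_result required")
    group = GroupResult.load(cfg["group_result"])
    mask_path = cfg[f"{which}_mask"]
    if not mask_path:
        raise ValueError(f"connectivity.{which}_mask required for auto selection")
    return select_roi(group, _read_vertex_list(mask_path),
                      n_top=cfg["n_top"], label_mask_id=str(mask_path))


def run_connectivity(config: RunConfig) -> dict[str, ConnectivityGroupResult]:
    """Directed connectivity for both directions of an ordered region pair."""
    config.validate(require=("epochs",))
    outdir = Path(config.paths.get("output_dir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.connectivity
    roi_a = _resolve_roi(config, "source")
    roi_b = _resolve_roi(config, "target")
    if np.intersect1d(roi_a.vertices, roi_b.vertices).size:
        raise ValueError("source and target ROIs overlap")

    paths = config.epoch_paths()
    step = SourceEpochs.load(paths[0]).step_ms
    lags = default_lags_ms(step, cfg["lags_min_ms"], cfg["lags_max_ms"])
    maps = {"A_to_B": [], "B_to_A": []}
    for path in paths:
        epochs = SourceEpochs.load(path)
        maps["A_to_B"].append(directed_connectivity_map(
            epochs, roi_a, roi_b, lags, names=("source", "target")))
        maps["B_to_A"].append(directed_connectivity_map(
            epochs, roi_b, roi_a, lags, names=("target", "source")))
        log.info("connectivity maps for %s", path)

    results = {}
    for direction, stack in maps.items():
        gr = connectivity_cluster_inference(
            stack, point_alpha=cfg["point_alpha"],
            cluster_alpha=cfg["cluster_alpha"], n_perm=cfg["n_perm"],
            seed=config.stage_seed(f"connectivity:{direction}"))
        save_connectivity_stack(outdir / f"connectivity_{direction}.h5",
                                stack, mask=gr.mask)
        gr.cluster_table().to_csv(outdir / f"connectivity_{direction}.tsv",
                                  sep="\t", index=False)
        results[direction] = gr
    _write_provenance(outdir, config, "connectivity")
    return results
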