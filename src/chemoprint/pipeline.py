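"""End-to-end workflows: classification and clustering runs with config,
structured logging and reproducible reports.

``run_classification`` takes labeled centroided spectra through feature
extraction, discriminant training, LOOCV and optional blind-sample
prediction; ``run_clustering`` builds the full-spectrum fingerprint
matrix, exports it in the Cluster-3.0 dialect, and produces an
uncentered-correlation single-linkage dendrogram with Newick output and
(when labels are given) a purity score.

Blind predictions carry a *novel-class flag*: a sample whose distance to
its assigned centroid exceeds the 95th percentile of the training
samples' own within-class centroid distances is marked as possibly
belonging to none of the trained classes.  This is an operational aid for
screening unknowns, not a calibrated statistical test.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import chemometrics, clustering, fingerprint, preprocess
from .chemometrics import KernelSpec, LoocvResult
from .errors import ConfigError, DataError
from .spectra_io import SpectrumCollection

log = logging.getLogger("chemoprint")

#: Quantile of training within-class centroid distances above which a
#: blind sample is flagged as a possible novel class.
NOVELTY_QUANTILE = 0.95


@dataclass
class PipelineConfig:
    """All tunables of a run; round-trips losslessly through YAML."""

    # preprocessing
    calibration_degree: int = preprocess.DEFAULT_CAL_DEGREE
    calibration_match_tol_u: float = preprocess.DEFAULT_MATCH_TOL_U
    grid_width_u: float = 0.005
    # fingerprint
    bin_width_u: float = fingerprint.DEFAULT_BIN_WIDTH_U
    min_rel_abundance_pct: float = fingerprint.DEFAULT_MIN_REL_ABUNDANCE_PCT
    # features
    feature_targets: list[float] = field(default_factory=list)
    feature_tolerance_u: float = fingerprint.DEFAULT_FEATURE_TOL_U
    # classifier
    method: str = "kda"
    kernel_name: str = "rbf"
    kernel_bandwidth: Optional[float] = None
    regularization: Optional[float] = None
    # clustering
    metric: str = "uncentered_correlation"
    linkage: str = "single"
    # misc
    seed: int = 0
    output_dir: str = "chemoprint_run"

    def kernel(self) -> KernelSpec:
        return KernelSpec(self.kernel_name, self.kernel_bandwidth)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


@dataclass
class BlindPrediction:
    sample_id: str
    label: str
    distances: dict[str, float]
    novel_flag: bool


@dataclass
class RunReport:
    """Provenance and results of one pipeline run."""

    parameters: dict
    stages: list[dict]
    loocv: Optional[LoocvResult] = None
    blind_predictions: list[BlindPrediction] = field(default_factory=list)
    novelty_threshold: Optional[float] = None
    dendrogram_path: Optional[str] = None
    newick: Optional[str] = None
    purity: Optional[float] = None
    score_table: Optional[np.ndarray] = None

    def to_json(self) -> str:
        payload = {
            "parameters": self.parameters,
            "stages": self.stages,
        }
        if self.loocv is not None:
            payload["loocv"] = {
                "percent_correct": self.loocv.percent_correct,
                "classes": self.loocv.classes,
                "confusion": self.loocv.confusion.tolist(),
            }
        if self.blind_predictions:
            payload["blind_predictions"] = [
                {"sample_id": b.sample_id, "label": b.label,
                 "novel_flag": b.novel_flag,
                 "distances": {k: float(v) for k, v in b.distances.items()}}
                for b in self.blind_predictions
            ]
            payload["novelty_threshold"] = self.novelty_threshold
        if self.newick is not None:
            payload["newick"] = self.newick
            payload["purity"] = self.purity
        return json.dumps(payload, indent=2, sort_keys=True)


def _hash_collection(spectra: SpectrumCollection) -> str:
    h = hashlib.sha256()
    for s in spectra:
        h.update(np.round(s.mz, 9).tobytes())
        h.update(np.round(s.intensity, 9).tobytes())
    return h.hexdigest()[:16]


def _stage(stages, name, **info):
    entry = {"stage": name, **info}
    log.info("%s: %s", name, info)
    stages.append(entry)


def run_classification(
    config: PipelineConfig,
    data: SpectrumCollection,
    labels: Sequence[str],
    blind: Optional[SpectrumCollection] = None,
) -> RunReport:
    """Feature extraction -> discriminant training -> LOOCV -> blind calls."""
    labels = [str(l) for l in labels]
    if len(set(labels)) < 2:
        raise DataError("classification needs at least 2 classes")
    stages: list[dict] = []
    _stage(stages, "input", n_samples=len(data), n_classes=len(set(labels)),
           input_hash=_hash_collection(data))
    if not config.feature_targets:
        raise ConfigError("config.feature_targets is empty")
    table = fingerprint.extract_features(
        data, config.feature_targets, config.feature_tolerance_u
    )
    _stage(stages, "features", n_targets=len(table.target_mz),
           tolerance_u=config.feature_tolerance_u)
    model = chemometrics.train_discriminant(
        table.values, labels, method=config.method,
        kernel=config.kernel() if config.method == "kda" else None,
        regularization=config.regularization,
    )
    _stage(stages, "train", method=config.method,
           n_directions=model.class_centroids.shape[1])
    result = chemometrics.loocv(
        table.values, labels, method=config.method,
        kernel=config.kernel() if config.method == "kda" else None,
        regularization=config.regularization,
    )
    _stage(stages, "loocv", percent_correct=result.percent_correct)

    report = RunReport(
        parameters=asdict(config), stages=stages, loocv=result,
        score_table=model.transform(table.values),
    )

    if blind is not None and len(blind):
        # novelty threshold calibrated out-of-fold: each training sample's
        # nearest-centroid distance under the model that did not see it
        # (in-sample distances are optimistically tight, especially for KDA)
        self_d = []
        n = table.values.shape[0]
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            fold = chemometrics.train_discriminant(
                table.values[mask],
                [l for j, l in enumerate(labels) if j != i],
                method=config.method,
                kernel=config.kernel() if config.method == "kda" else None,
                regularization=config.regularization,
                _allow_drop_singletons=True,
            )
            _, dist = fold.predict(table.values[i])
            self_d.append(min(dist.values()))
        threshold = float(np.quantile(self_d, NOVELTY_QUANTILE))
        report.novelty_threshold = threshold
        blind_table = fingerprint.extract_features(
            blind, config.feature_targets, config.feature_tolerance_u
        )
        for sid, row in zip(blind_table.sample_ids, blind_table.values):
            label, dist = model.predict(row)
            report.blind_predictions.append(BlindPrediction(
                sample_id=sid, label=label, distances=dist,
                novel_flag=dist[label] > threshold,
            ))
        _stage(stages, "blind", n_blind=len(blind),
               novelty_threshold=threshold)
    return report


def run_clustering(
    config: PipelineConfig,
    data: SpectrumCollection,
    labels: Optional[Sequence[str]] = None,
    output_dir: Optional[Path] = None,
) -> RunReport:
    """Fingerprint matrix -> Cluster export -> single linkage -> Newick."""
    if len(data) < 3:
        raise DataError("clustering needs at least 3 samples")
    if config.linkage != "single":
        raise ConfigError(f"unsupported linkage {config.linkage!r}")
    stages: list[dict] = []
    _stage(stages, "input", n_samples=len(data),
           input_hash=_hash_collection(data))
    matrix = fingerprint.build_fingerprint_matrix(
        data, config.bin_width_u, config.min_rel_abundance_pct
    )
    _stage(stages, "fingerprint", n_bins=matrix.n_bins,
           bin_width_u=config.bin_width_u)
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix_path = out / "heatmap_matrix.txt"
    fingerprint.export_cluster_matrix(matrix, matrix_path)
    d = clustering.distance_matrix(matrix, config.metric)
    tree = clustering.single_linkage(d)
    newick = clustering.to_newick(tree)
    nwk_path = out / "dendrogram.nwk"
    nwk_path.write_text(newick + "\n")
    _stage(stages, "cluster", metric=config.metric, linkage=config.linkage,
           matrix_path=str(matrix_path), newick_path=str(nwk_path))
    purity = None
    if labels is not None:
        labels = [str(l) for l in labels]
        purity = clustering.cluster_purity(tree, labels, len(set(labels)))
        _stage(stages, "purity", k=len(set(labels)), purity=purity)
    return RunReport(
        parameters=asdict(config), stages=stages,
        dendrogram_path=str(nwk_path), newick=newick, purity=purity,
    )
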