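"""End-to-end orchestration: matrix -> SVD -> FLSOM -> U-Matrix -> clusters.

A :class:`PipelineConfig` collects every stage parameter plus input/output
paths.  :func:`run_pipeline` executes the six stages in cascade and, when an
output directory is set, writes the map image, the cluster report, the QE
trace, a re-loadable model dump and a ``manifest.txt`` with every resolved
parameter, so any run can be reproduced bit-for-bit from its manifest.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import io as sio
from .dimred import Fingerprints, SVDResult, project_fingerprints, truncated_svd
from .exceptions import SomscapeError, ValidationError
from .segmentation import (
    CannyParams,
    EdgeMask,
    LabelMap,
    assign_clusters,
    canny_edges,
    region_growing,
    render_labelmap,
)
from .som import (
    FLSOMConfig,
    Lattice,
    TrainedSOM,
    quantization_error,
    suggest_lattice_size,
    train_flsom,
)
from .umatrix import UMatrix, compute_umatrix, render_umatrix, save_image

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "save_manifest",
    "load_manifest",
    "save_model",
    "load_model",
]

_FLOAT_KEYS = {
    "sigma0", "sigma_min", "alpha0", "alpha_min", "decay_fast", "decay_slow",
    "improvement_target", "stop_epsilon", "canny_sigma", "canny_low", "canny_high",
}
_INT_KEYS = {"svd_k", "rows", "cols", "max_epochs", "seed", "canny_radius",
             "min_region_size", "verbosity"}
_BOOL_KEYS = {"center", "invert"}


@dataclass
class PipelineConfig:
    """All user-facing parameters of the six-stage pipeline."""

    # input
    matrix_path: Optional[str] = None
    orientation: str = "features_as_rows"
    delimiter: Optional[str] = None
    names_path: Optional[str] = None
    smiles_path: Optional[str] = None
    # dimensionality reduction
    svd_k: Optional[int] = None
    center: bool = True
    # lattice + training
    rows: Optional[int] = None
    cols: Optional[int] = None
    sigma0: Optional[float] = None
    sigma_min: float = 1.0
    alpha0: float = 1.0
    alpha_min: float = 0.05
    decay_fast: float = 0.90
    decay_slow: float = 0.98
    improvement_target: float = 0.01
    stop_epsilon: float = 1e-4
    max_epochs: int = 200
    seed: int = 0
    # rendering + segmentation
    invert: bool = True
    canny_sigma: float = 1.0
    canny_radius: int = 2
    canny_low: float = 0.1
    canny_high: float = 0.3
    min_region_size: int = 2
    # output
    outdir: Optional[str] = None
    verbosity: int = 0

    def flsom_config(self) -> FLSOMConfig:
        return FLSOMConfig(
            sigma0=self.sigma0,
            sigma_min=self.sigma_min,
            alpha0=self.alpha0,
            alpha_min=self.alpha_min,
            decay_fast=self.decay_fast,
            decay_slow=self.decay_slow,
            improvement_target=self.improvement_target,
            stop_epsilon=self.stop_epsilon,
            max_epochs=self.max_epochs,
            seed=self.seed,
        )

    def canny_params(self) -> CannyParams:
        return CannyParams(
            smooth_sigma=self.canny_sigma,
            kernel_radius=self.canny_radius,
            low_threshold=self.canny_low,
            high_threshold=self.canny_high,
        )


@dataclass
class PipelineResult:
    """In-memory products of a pipeline run plus the artifact paths."""

    svd: SVDResult
    fingerprints: Fingerprints
    trained: TrainedSOM
    umatrix: UMatrix
    edge_mask: Optional[EdgeMask]
    labelmap: Optional[LabelMap]
    report: Optional[sio.ClusterReport]
    artifacts: dict = field(default_factory=dict)


class _Stage:
    """Prefix any stage failure with the stage name."""

    def __init__(self, name: str, verbosity: int = 0):
        self.name = name
        self.verbosity = verbosity

    def __enter__(self):
        if self.verbosity > 0:
            print(f"[{self.name}] ...")
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, Exception):
            raise SomscapeError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def _fmt(x: float) -> str:
    return repr(float(x))


def run_pipeline(
    config: PipelineConfig,
    matrix: Optional[sio.FeatureMatrix] = None,
    segment: bool = True,
) -> PipelineResult:
    """Execute the pipeline and (optionally) write its artifacts.

    ``matrix`` may be passed in-memory; otherwise ``config.matrix_path`` is
    read.  With ``segment=False`` the run stops after the U-Matrix (stages
    1-4), which is the "train" mode of the command-line tool.
    """
    v = config.verbosity
    with _Stage("input", v):
        if matrix is None:
            if config.matrix_path is None:
                raise ValidationError("no input matrix: set matrix_path or pass one in-memory")
            matrix = sio.read_feature_matrix(
                config.matrix_path, orientation=config.orientation, delimiter=config.delimiter
            )
        pattern_ids = list(matrix.pattern_ids)
        if config.names_path is not None:
            ann = sio.read_annotations(config.names_path, config.smiles_path)
            if len(ann.pattern_ids) != len(pattern_ids):
                raise ValidationError(
                    f"annotation list has {len(ann.pattern_ids)} entries for "
                    f"{len(pattern_ids)} matrix columns"
                )
            pattern_ids = list(ann.pattern_ids)

    with _Stage("svd", v):
        svd = truncated_svd(matrix, k=config.svd_k, center=config.center)

    with _Stage("fingerprints", v):
        fps = project_fingerprints(matrix, svd)
        fps = Fingerprints(fps.vectors, pattern_ids, fps.k)

    with _Stage("train", v):
        rows, cols = config.rows, config.cols
        if rows is None or cols is None:
            srows, scols = suggest_lattice_size(fps.n_patterns, svd)
            rows = rows if rows is not None else srows
            cols = cols if cols is not None else scols
        trained = train_flsom(fps, rows, cols, svd, config.flsom_config())
        if v > 0:
            for e, qe in enumerate(trained.qe_trace, start=1):
                print(f"[train] epoch {e}: QE = {qe:.6g}")

    with _Stage("umatrix", v):
        um = compute_umatrix(trained.lattice)
        image = render_umatrix(um, invert=config.invert)

    edge_mask = labelmap = report = None
    if segment:
        with _Stage("edges", v):
            edge_mask = canny_edges(image, config.canny_params())
        with _Stage("regions", v):
            labelmap = region_growing(edge_mask, min_region_size=config.min_region_size)
        with _Stage("clusters", v):
            report = assign_clusters(labelmap, trained, trained.lattice, pattern_ids)

    result = PipelineResult(
        svd=svd, fingerprints=fps, trained=trained, umatrix=um,
        edge_mask=edge_mask, labelmap=labelmap, report=report,
    )

    if config.outdir is not None:
        with _Stage("output", v):
            _write_artifacts(config, result, image, rows, cols)
    return result


def _write_artifacts(config: PipelineConfig, result: PipelineResult,
                     image: np.ndarray, rows: int, cols: int) -> None:
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    art = result.artifacts

    art["map_image"] = os.path.join(outdir, "map.png")
    save_image(image, art["map_image"])

    art["qe_trace"] = os.path.join(outdir, "qe_trace.txt")
    with open(art["qe_trace"], "w", encoding="utf-8") as fh:
        fh.write("".join(_fmt(q) + "\n" for q in result.trained.qe_trace))

    if result.report is not None:
        art["cluster_report"] = os.path.join(outdir, "clusters.txt")
        sio.write_cluster_report(result.report, art["cluster_report"])
    if result.labelmap is not None:
        art["label_image"] = os.path.join(outdir, "labels.png")
        save_image(render_labelmap(result.labelmap), art["label_image"])

    model_dir = os.path.join(outdir, "model")
    art["model"] = model_dir
    save_model(model_dir, result.trained, result.umatrix)

    resolved = dataclasses.replace(
        config,
        rows=rows,
        cols=cols,
        svd_k=result.svd.k,
        sigma0=config.flsom_config().resolved_sigma0(rows, cols),
    )
    art["manifest"] = os.path.join(outdir, "manifest.txt")
    save_manifest(resolved, art["manifest"])


# run-local bookkeeping, not part of the reproducible parameter set
_MANIFEST_SKIP = {"outdir", "verbosity"}


def save_manifest(config: PipelineConfig, path) -> None:
    """Write the configuration as sorted ``key=value`` lines.

    Only the scientific parameters and input paths are recorded; the output
    directory and verbosity are run-local and omitted, so two runs of the
    same analysis produce byte-identical manifests.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for f in sorted(dataclasses.fields(PipelineConfig), key=lambda f: f.name):
            value = getattr(config, f.name)
            if value is None or f.name in _MANIFEST_SKIP:
                continue
            if isinstance(value, bool):
                value = "true" if value else "false"
            elif isinstance(value, float):
                value = _fmt(value)
            fh.write(f"{f.name}={value}\n")


def load_manifest(path) -> PipelineConfig:
    """Read a manifest back into a config; unknown keys are rejected."""
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    kwargs = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, value = line.partition("=")
            key = key.strip()
            if not sep or key not in known:
                raise ValidationError(f"unknown manifest key {key!r} at line {lineno} of {path}")
            value = value.strip()
            if key in _FLOAT_KEYS:
                kwargs[key] = float(value)
            elif key in _INT_KEYS:
                kwargs[key] = int(value)
            elif key in _BOOL_KEYS:
                kwargs[key] = value.lower() in ("true", "1", "yes")
            else:
                kwargs[key] = value
    return PipelineConfig(**kwargs)


def save_model(model_dir, trained: TrainedSOM, um: Optional[UMatrix] = None) -> None:
    """Dump a trained map as delimited text, bit-exact re-loadable.

    ``lattice.tsv`` holds one ``row col w1 ... wk`` line per neuron;
    ``fingerprints.tsv`` and ``bmus.tsv`` hold the per-pattern vectors and
    map positions; ``heights.tsv`` the U-Matrix.  Floats use shortest
    round-trip decimal representation.
    """
    os.makedirs(model_dir, exist_ok=True)
    lat = trained.lattice
    with open(os.path.join(model_dir, "lattice.tsv"), "w", encoding="utf-8") as fh:
        fh.write(f"# rows={lat.rows} cols={lat.cols} k={lat.k} "
                 f"epochs={trained.epochs_run} stopped_by={trained.stopped_by}\n")
        for r in range(lat.rows):
            for c in range(lat.cols):
                ws = "\t".join(_fmt(w) for w in lat.weights[r, c])
                fh.write(f"{r}\t{c}\t{ws}\n")
    with open(os.path.join(model_dir, "qe_trace.txt"), "w", encoding="utf-8") as fh:
        fh.write("".join(_fmt(q) + "\n" for q in trained.qe_trace))
    if trained.fingerprints is not None:
        with open(os.path.join(model_dir, "fingerprints.tsv"), "w", encoding="utf-8") as fh:
            for pid, vec in zip(trained.fingerprints.pattern_ids, trained.fingerprints.vectors):
                fh.write(pid + "\t" + "\t".join(_fmt(x) for x in vec) + "\n")
        with open(os.path.join(model_dir, "bmus.tsv"), "w", encoding="utf-8") as fh:
            for pid, (r, c) in zip(trained.fingerprints.pattern_ids, trained.bmu_of_pattern):
                fh.write(f"{pid}\t{int(r)}\t{int(c)}\n")
    if um is not None:
        with open(os.path.join(model_dir, "heights.tsv"), "w", encoding="utf-8") as fh:
            for r in range(um.rows):
                fh.write("\t".join(_fmt(h) for h in um.heights[r]) + "\n")


def load_model(model_dir) -> TrainedSOM:
    """Reload a model dump written by :func:`save_model`."""
    header = None
    weights = {}
    with open(os.path.join(model_dir, "lattice.tsv"), "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                header = dict(tok.split("=") for tok in line[1:].split())
                continue
            parts = line.split("\t")
            weights[(int(parts[0]), int(parts[1]))] = [float(x) for x in parts[2:]]
    if header is None:
        raise ValidationError(f"lattice dump in {model_dir} is missing its header line")
    rows, cols, k = int(header["rows"]), int(header["cols"]), int(header["k"])
    W = np.zeros((rows, cols, k))
    for (r, c), ws in weights.items():
        W[r, c] = ws
    lattice = Lattice(rows=rows, cols=cols, weights=W, k=k)

    qe_trace = []
    qe_path = os.path.join(model_dir, "qe_trace.txt")
    if os.path.isfile(qe_path):
        with open(qe_path, "r", encoding="utf-8") as fh:
            qe_trace = [float(line) for line in fh if line.strip()]

    pattern_ids, vecs, bmus = [], [], []
    fp_path = os.path.join(model_dir, "fingerprints.tsv")
    if os.path.isfile(fp_path):
        with open(fp_path, "r", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                pattern_ids.append(parts[0])
                vecs.append([float(x) for x in parts[1:]])
        with open(os.path.join(model_dir, "bmus.tsv"), "r", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                bmus.append((int(parts[1]), int(parts[2])))
    fps = Fingerprints(np.array(vecs), pattern_ids, k) if pattern_ids else None
    bmu = np.array(bmus, dtype=int) if bmus else np.zeros((0, 2), dtype=int)
    return TrainedSOM(
        lattice=lattice,
        qe_trace=qe_trace,
        bmu_of_pattern=bmu,
        epochs_run=int(header.get("epochs", len(qe_trace))),
        stopped_by=header.get("stopped_by", "delta_qe"),
        fingerprints=fps,
    )
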