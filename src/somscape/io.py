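"""Reading and writing of the pipeline's external file formats.

The central input is a *features x patterns* table: a delimited text file
(TSV or CSV) whose rows are feature identifiers (e.g. molecular fragments)
and whose columns are pattern identifiers (e.g. compounds).  Side inputs are
an ordered list of pattern names and an optional parallel list of SMILES
strings, both carried opaquely.  The main text output is the cluster report:
one block per cluster listing its member pattern ids.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputFileError, MatrixParseError, OutputError, ValidationError

__all__ = [
    "FeatureMatrix",
    "CompoundAnnotations",
    "ClusterReport",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_annotations",
    "write_cluster_report",
    "read_cluster_report",
]


def _infer_delimiter(path: str, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".csv":
        return ","
    # default to tab (.tsv, .txt, anything else)
    return "\t"


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class FeatureMatrix:
    """Numeric matrix in canonical features x patterns orientation.

    Attributes
    ----------
    values : ndarray, shape (n_features, n_patterns)
        Finite real values; unitless.
    feature_ids : list of str
        Row identifiers, unique, in file order.
    pattern_ids : list of str
        Column identifiers, unique, in file order.
    """

    values: np.ndarray
    feature_ids: list
    pattern_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature matrix must be 2-dimensional")
        if self.values.shape != (len(self.feature_ids), len(self.pattern_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} feature ids x {len(self.pattern_ids)} pattern ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature matrix contains non-finite values")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.pattern_ids, "pattern")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_patterns(self) -> int:
        return self.values.shape[1]

    def transposed(self) -> "FeatureMatrix":
        """Swap the roles of features and patterns."""
        return FeatureMatrix(self.values.T.copy(), list(self.pattern_ids), list(self.feature_ids))


@dataclass
class CompoundAnnotations:
    """Ordered pattern names with an optional parallel list of SMILES strings."""

    pattern_ids: list
    smiles: Optional[list] = None

    def __post_init__(self):
        if self.smiles is not None and len(self.smiles) != len(self.pattern_ids):
            raise ValidationError(
                f"{len(self.pattern_ids)} pattern names but {len(self.smiles)} SMILES strings"
            )


@dataclass
class ClusterReport:
    """Disjoint partition of pattern ids into labelled clusters.

    ``clusters`` maps consecutive integer labels (starting at 1) to ordered
    member lists; ``unassigned`` collects patterns outside every cluster
    (empty under the default boundary-resolution policy).
    """

    clusters: dict
    unassigned: list = field(default_factory=list)

    def __post_init__(self):
        labels = sorted(self.clusters)
        if labels != list(range(1, len(labels) + 1)):
            raise ValidationError(f"cluster labels must be 1..n consecutive, got {labels}")
        seen = set()
        for members in list(self.clusters.values()) + [self.unassigned]:
            for p in members:
                if p in seen:
                    raise ValidationError(f"pattern {p!r} appears in more than one cluster")
                seen.add(p)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def all_patterns(self) -> list:
        out = []
        for label in sorted(self.clusters):
            out.extend(self.clusters[label])
        out.extend(self.unassigned)
        return out


def read_feature_matrix(
    path,
    orientation: str = "features_as_rows",
    delimiter: Optional[str] = None,
) -> FeatureMatrix:
    """Read a delimited matrix with one header row and one header column.

    Parameters
    ----------
    path : str or Path
        TSV or CSV file; the delimiter is inferred from the extension
        (``.csv`` -> comma, otherwise tab) unless ``delimiter`` is given.
    orientation : {"features_as_rows", "patterns_as_rows"}
        File-dialect switch.  The returned matrix is always in canonical
        features x patterns orientation; ``patterns_as_rows`` transposes
        after reading.
    """
    if orientation not in ("features_as_rows", "patterns_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if not os.path.isfile(path):
        raise InputFileError(f"matrix file not found: {path}")
    sep = _infer_delimiter(path, delimiter)
    # pandas silently renames duplicate header columns, so check them first
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n")
    _check_unique(header.split(sep)[1:], "column")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"malformed matrix file {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise MatrixParseError(f"empty matrix file {path}") from exc

    row_ids = [str(r) for r in df.index]
    col_ids = [str(c) for c in df.columns]
    _check_unique(row_ids, "row")
    _check_unique(col_ids, "column")

    raw = df.to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise MatrixParseError(
                    f"non-numeric cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r} in {path}"
                ) from None
            if not np.isfinite(v):
                raise MatrixParseError(
                    f"non-finite cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r} in {path}"
                )
            values[i, j] = v

    fm = FeatureMatrix(values, row_ids, col_ids)
    if orientation == "patterns_as_rows":
        fm = fm.transposed()
    return fm


def write_feature_matrix(matrix: FeatureMatrix, path, delimiter: Optional[str] = None) -> None:
    """Write a feature matrix as delimited text with row and column headers."""
    sep = _infer_delimiter(path, delimiter)
    df = pd.DataFrame(matrix.values, index=matrix.feature_ids, columns=matrix.pattern_ids)
    try:
        df.to_csv(path, sep=sep)
    except OSError as exc:
        raise OutputError(f"cannot write matrix to {path}: {exc}") from exc


def _read_lines(path) -> list:
    if not os.path.isfile(path):
        raise InputFileError(f"file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        return [line.rstrip("\r\n") for line in fh if line.rstrip("\r\n") != ""]


def read_annotations(names_path, smiles_path=None) -> CompoundAnnotations:
    """Read the pattern-name list and, optionally, the parallel SMILES list.

    SMILES strings pass through verbatim; no chemistry validation is done.
    """
    names = _read_lines(names_path)
    smiles = None
    if smiles_path is not None:
        smiles = _read_lines(smiles_path)
        if len(smiles) != len(names):
            raise ValidationError(
                f"{len(names)} names in {names_path} but {len(smiles)} SMILES in {smiles_path}"
            )
    return CompoundAnnotations(names, smiles)


def write_cluster_report(report: ClusterReport, path) -> None:
    """Write a plain-text cluster report.

    One block per cluster: a header line ``cluster <label>\\t<size>`` followed
    by one pattern id per line, then a blank line.  A trailing ``unassigned``
    block is emitted only when nonempty.  Ordering is deterministic: clusters
    by label, members in stored order.
    """
    lines = []
    for label in sorted(report.clusters):
        members = report.clusters[label]
        lines.append(f"cluster {label}\t{len(members)}")
        lines.extend(str(m) for m in members)
        lines.append("")
    if report.unassigned:
        lines.append(f"unassigned\t{len(report.unassigned)}")
        lines.extend(str(m) for m in report.unassigned)
        lines.append("")
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines))
    except OSError as exc:
        raise OutputError(f"cannot write cluster report to {path}: {exc}") from exc


def read_cluster_report(path) -> ClusterReport:
    """Parse a file produced by :func:`write_cluster_report`."""
    if not os.path.isfile(path):
        raise InputFileError(f"cluster report not found: {path}")
    clusters: dict = {}
    unassigned: list = []
    current: Optional[list] = None
    remaining = 0
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if remaining == 0:
                if line == "":
                    continue
                head, _, size = line.partition("\t")
                try:
                    remaining = int(size)
                except ValueError:
                    raise MatrixParseError(f"bad block header {line!r} in {path}") from None
                if head == "unassigned":
                    current = unassigned
                elif head.startswith("cluster "):
                    label = int(head.split(" ", 1)[1])
                    current = clusters.setdefault(label, [])
                else:
                    raise MatrixParseError(f"bad block header {line!r} in {path}")
                if remaining == 0:
                    current = None
            else:
                assert current is not None
                current.append(line)
                remaining -= 1
    return ClusterReport(clusters, unassigned)
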