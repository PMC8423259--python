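"""Tabular I/O, core data containers, run configuration and logging.

Conventions used throughout the package:

* Expression tables are delimited text with a header row and a leading ID
  column.  The delimiter is auto-detected from the extension (``.tsv``/``.txt``
  → tab, ``.csv`` → comma) and can be overridden.
* The in-memory orientation is always samples × features, whatever the on-disk
  layout was.
* Duplicate feature names (repeated probes measuring the same gene are kept as
  distinct columns) are disambiguated at load by suffixing the k-th repeat with
  ``.k`` (``GENE``, ``GENE.2``, ``GENE.3`` ...); the mapping is logged.
* Label files are two-column delimited text (sample id, class) with a header
  row.
* Every source of randomness in the package flows from the single integer seed
  in :class:`RunConfig`, expanded into independent child seeds with
  :func:`derive_seeds` (a ``numpy.random.SeedSequence`` spawn tree).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "LabelVector",
    "RunConfig",
    "get_logger",
    "derive_seeds",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_ranked_features",
    "write_ranked_features",
]

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def get_logger(name: str = "imrf") -> logging.Logger:
    """Package logger writing level-prefixed lines to stderr."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def derive_seeds(root_seed: int, n: int) -> list[int]:
    """Expand one integer seed into ``n`` independent child seeds (< 2**31).

    Children are spawned from ``numpy.random.SeedSequence(root_seed)``, so the
    mapping is deterministic and collision-resistant across levels of the
    sampling/initialization hierarchy.
    """
    ss = np.random.SeedSequence(root_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A samples × features numeric table.

    Attributes
    ----------
    sample_ids : unique sample identifiers (length n)
    feature_names : unique feature identifiers (length m)
    values : float array of shape (n, m), free of NaN
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_names) != m:
            raise ValueError(f"{len(self.feature_names)} feature names for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_names)) != m:
            raise ValueError("duplicate feature names (disambiguate at load)")
        if np.isnan(self.values).any():
            raise ValueError("values contain NaN")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    def select_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = list(indices)
        return ExpressionMatrix(
            [self.sample_ids[i] for i in idx], list(self.feature_names), self.values[idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_names == other.feature_names
            and np.array_equal(self.values, other.values)
        )


@dataclass
class LabelVector:
    """Per-sample class assignment over a finite class set.

    ``labels`` is aligned, element for element, with the paired
    :class:`ExpressionMatrix` sample order.  ``class_set`` is ordered (first
    appearance unless given explicitly) and ``counts`` holds per-class sample
    counts, all ≥ 1.
    """

    labels: np.ndarray
    class_set: list
    counts: dict

    @classmethod
    def from_labels(cls, labels: Iterable, class_set: Optional[Sequence] = None) -> "LabelVector":
        arr = np.asarray(list(labels), dtype=object)
        if class_set is None:
            seen: list = []
            for token in arr:
                if token not in seen:
                    seen.append(token)
            class_set = seen
        else:
            class_set = list(class_set)
            unknown = set(arr) - set(class_set)
            if unknown:
                raise ValueError(f"labels outside class_set: {sorted(map(str, unknown))}")
        counts = {c: int(np.sum(arr == c)) for c in class_set}
        return cls(labels=arr, class_set=class_set, counts=counts)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_min(self) -> int:
        return min(v for v in self.counts.values() if v > 0)

    def indices_of(self, token) -> np.ndarray:
        return np.flatnonzero(self.labels == token)

    def select(self, indices: Sequence[int]) -> "LabelVector":
        return LabelVector.from_labels(self.labels[list(indices)], class_set=self.class_set)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelVector):
            return NotImplemented
        return (
            np.array_equal(self.labels, other.labels)
            and self.class_set == other.class_set
            and self.counts == other.counts
        )


@dataclass
class RunConfig:
    """Hyper-parameters of one integrated-forest run.

    Parameters
    ----------
    L : number of balanced samplings (subsets).
    p : forest initializations per sampling; importances are averaged over them.
    q : subgroups used by the aggregation stage; must divide L.
    d : top features taken per subgroup.
    T : trees per forest.
    seed : root seed; all child randomness is derived from it.
    validation_per_class : held-out test samples per class; ``None`` means
        16 per class when every class can spare 16 and still train, else 20%.
    max_features / max_depth : forest split hyper-parameters (sklearn
        semantics), conventional defaults.
    """

    L: int = 8
    p: int = 2
    q: int = 4
    d: int = 20
    T: int = 200
    seed: int = 0
    validation_per_class: Optional[int] = None
    max_features: object = "sqrt"
    max_depth: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("L", "p", "q", "d", "T"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.L % self.q != 0:
            raise ValueError(f"q={self.q} must divide L={self.L}")
        if self.validation_per_class is not None and self.validation_per_class < 1:
            raise ValueError("validation_per_class must be ≥ 1 or None")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


def _dedupe(names: Sequence[str], what: str) -> list[str]:
    """Suffix the k-th occurrence of a repeated name with '.k' (k ≥ 2)."""
    log = get_logger()
    seen: dict[str, int] = {}
    out = []
    for name in names:
        seen[name] = seen.get(name, 0) + 1
        if seen[name] == 1:
            out.append(name)
        else:
            new = f"{name}.{seen[name]}"
            log.info("duplicate %s name %r renamed to %r", what, name, new)
            out.append(new)
    return out


def read_expression(path, orientation: str = "samples_by_features", delimiter: Optional[str] = None) -> ExpressionMatrix:
    """Read a delimited expression table into samples × features orientation.

    ``orientation`` names the on-disk layout; the returned matrix is always
    samples × features.  Missing or non-numeric cells are hard errors naming
    the offending row and column.  Duplicate sample IDs are rejected; duplicate
    feature names are disambiguated with a logged ``.k`` suffix.
    """
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path, delimiter)

    with open(path) as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    raw_cols = header.split(sep)[1:]  # drop the ID-column header

    df = pd.read_csv(path, sep=sep, header=0, index_col=0, float_precision="round_trip")
    raw_rows = [str(r) for r in df.index]
    df.index = raw_rows
    # pandas mangles duplicate header entries; restore raw names then apply
    # our documented suffix scheme.
    if orientation == "samples_by_features":
        sample_names, feature_source = raw_rows, raw_cols
    else:
        sample_names, feature_source = raw_cols, raw_rows
    if len(set(sample_names)) != len(sample_names):
        dupes = sorted({s for s in sample_names if sample_names.count(s) > 1})
        raise ValueError(f"duplicate sample id(s): {dupes}")
    feature_names = _dedupe([str(c) for c in feature_source], "feature")

    if orientation == "samples_by_features":
        df.columns = feature_names
    else:
        df.columns = sample_names
        df.index = feature_names
        df = df.T

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        row, col = df.index[i], df.columns[j]
        cell = df.iat[i, j]
        if pd.isna(cell):
            raise ValueError(f"missing value at row {row!r}, column {col!r}")
        raise ValueError(f"non-numeric value {cell!r} at row {row!r}, column {col!r}")
    return ExpressionMatrix(list(df.index), list(df.columns), numeric.to_numpy(dtype=float))


def write_expression(matrix: ExpressionMatrix, path, delimiter: Optional[str] = None) -> None:
    sep = _sep_for(path, delimiter)
    matrix.to_frame().to_csv(path, sep=sep, index_label="id", float_format=_FLOAT_FMT)


def read_labels(path, matrix: ExpressionMatrix, delimiter: Optional[str] = None) -> LabelVector:
    """Read a two-column (sample id, class) table, aligned to ``matrix`` order.

    Samples present in the matrix but absent from the file are an error;
    samples unknown to the matrix are dropped with a logged warning.
    """
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"label file must have exactly 2 columns, got {df.shape[1]}")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    log = get_logger()
    unknown = [s for s in df.iloc[:, 0] if s not in set(matrix.sample_ids)]
    for s in unknown:
        log.warning("label file sample %r not in matrix; dropped", s)
    missing = [s for s in matrix.sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"no label for sample(s): {missing}")
    return LabelVector.from_labels([mapping[s] for s in matrix.sample_ids])


def write_labels(labels: LabelVector, sample_ids: Sequence[str], path, delimiter: Optional[str] = None) -> None:
    sep = _sep_for(path, delimiter)
    pd.DataFrame({"sample_id": list(sample_ids), "label": list(labels.labels)}).to_csv(
        path, sep=sep, index=False
    )


def write_ranked_features(ranked, path, delimiter: Optional[str] = None) -> None:
    """Write a ranked feature list as TSV (rank, feature_name, mean_position,
    mean_importance); floats round-trip losslessly."""
    sep = _sep_for(path, delimiter)
    ranked.to_frame().to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def read_ranked_features(path, delimiter: Optional[str] = None):
    from .aggregation import RankedFeatureList

    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")
    expected = ["rank", "feature_name", "mean_position", "mean_importance"]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
    return RankedFeatureList(
        feature_names=[str(x) for x in df["feature_name"]],
        mean_positions=[float(x) for x in df["mean_position"]],
        mean_importances=[float(x) for x in df["mean_importance"]],
    )
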