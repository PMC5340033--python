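"""The Repertoire Dissimilarity Index (RDI).

RDI is a non-parametric distance between the gene-segment usage profiles of
two or more repertoires.  Because raw Euclidean distance between frequency
vectors inflates as sequencing depth drops, RDI first equalizes depth:

1. subsample every repertoire without replacement to a common size
   (by default the smallest repertoire's total count);
2. count features in the subsample;
3. normalize each count vector to a fixed constant (500) and optionally
   apply the inverse hyperbolic sine, which is linear near zero and
   logarithmic for large counts so that rare-gene changes are not drowned
   out by the most prevalent genes;
4. take the Euclidean (or root-mean-square) deviation between every pair;
5. repeat 100 times and average.

RDI values only have a defined meaning relative to other RDI values computed
with the same settings (subsample size, normalization constant, transform),
so :class:`DistanceMatrix` records those settings; :mod:`rdikit.calibrate`
converts RDI into absolute fold-change units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import ConfigurationError, DataError
from .repertoire import FeatureCountTable

Transform = Literal["none", "asinh"]
DistanceMode = Literal["euclidean", "rmsd"]

__all__ = [
    "RDIParameters",
    "DistanceMatrix",
    "subsample_counts",
    "normalize_counts",
    "transform_counts",
    "vector_distance",
    "calc_rdi",
    "cross_rdi",
    "shannon_entropy",
]


@dataclass(frozen=True)
class RDIParameters:
    """Settings of one RDI computation.

    ``subsample_size="auto"`` resolves to the minimum repertoire total at
    computation time.  ``distance_mode="rmsd"`` divides the Euclidean
    distance by sqrt(n_features); the two modes differ only by that constant
    factor, which calibration absorbs.
    """

    subsample_size: int | Literal["auto"] = "auto"
    norm_constant: float = 500.0
    transform: Transform = "asinh"
    n_iterations: int = 100
    distance_mode: DistanceMode = "euclidean"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.subsample_size != "auto" and (
            not isinstance(self.subsample_size, (int, np.integer)) or self.subsample_size < 1
        ):
            raise ConfigurationError("subsample_size must be a positive integer or 'auto'")
        if self.norm_constant <= 0:
            raise ConfigurationError("norm_constant must be positive")
        if self.transform not in ("none", "asinh"):
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.distance_mode not in ("euclidean", "rmsd"):
            raise ConfigurationError(f"unknown distance_mode {self.distance_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RDIParameters":
        return cls(**d)

    def comparable_to(self, other: "RDIParameters") -> bool:
        """True if RDI values under the two settings live on the same scale."""
        return (
            self.norm_constant == other.norm_constant
            and self.transform == other.transform
            and self.distance_mode == other.distance_mode
        )


@dataclass
class DistanceMatrix:
    """Symmetric matrix of averaged RDI values with its provenance."""

    ids: list[str]
    values: np.ndarray
    params: RDIParameters
    resolved_subsample_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DataError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise DataError("distance matrix must be symmetric")
        if np.any(self.values < 0) or np.any(np.diag(self.values) != 0):
            raise DataError("distances must be >= 0 with a zero diagonal")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write a square CSV; optionally a JSON sidecar of the settings."""
        df = self.to_dataframe()
        df.index.name = "repertoire_id"
        df.to_csv(path)
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump(
                    {
                        "params": self.params.to_dict(),
                        "resolved_subsample_size": int(self.resolved_subsample_size),
                    },
                    fh,
                    indent=2,
                )
                fh.write("\n")

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        with open(sidecar) as fh:
            meta = json.load(fh)
        return cls(
            ids=[str(i) for i in df.index],
            values=df.to_numpy(dtype=float),
            params=RDIParameters.from_dict(meta["params"]),
            resolved_subsample_size=int(meta["resolved_subsample_size"]),
        )

    def offdiag(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def subsample_counts(counts: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``m`` elements without replacement from a count vector.

    The pooled elements are exchangeable, so the result is a multivariate
    hypergeometric draw over the bins.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise DataError("counts must be non-negative")
    total = int(counts.sum())
    if m > total:
        raise DataError(f"cannot subsample {m} elements from a total of {total}")
    if m == total:
        return counts.astype(np.int64, copy=True)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), int(m))


def normalize_counts(counts: np.ndarray, constant: float = 500.0) -> np.ndarray:
    """Scale a count vector so it sums to ``constant``."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DataError("cannot normalize an all-zero vector")
    return counts * (constant / total)


def transform_counts(v: np.ndarray, method: Transform = "asinh") -> np.ndarray:
    """Apply the optional variance-compressing transform (identity or asinh)."""
    v = np.asarray(v, dtype=float)
    if method == "none":
        return v
    if method == "asinh":
        return np.arcsinh(v)
    raise ConfigurationError(f"unknown transform {method!r}")


def vector_distance(a: np.ndarray, b: np.ndarray, mode: DistanceMode = "euclidean") -> float:
    """Euclidean distance, or RMSD (= Euclidean / sqrt(length))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise DataError(f"vectors must share one dimension >= 1, got {a.shape} vs {b.shape}")
    d = float(np.linalg.norm(a - b))
    if mode == "rmsd":
        d /= np.sqrt(a.size)
    elif mode != "euclidean":
        raise ConfigurationError(f"unknown distance_mode {mode!r}")
    return d


def _resolve_subsample(table: FeatureCountTable, params: RDIParameters) -> int:
    row_sums = table.row_sums()
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        names = [table.repertoire_ids[i] for i in zero]
        raise DataError(f"repertoire(s) with zero counts: {names}")
    if params.subsample_size == "auto":
        return int(row_sums.min())
    m = int(params.subsample_size)
    if np.any(row_sums < m):
        small = [table.repertoire_ids[i] for i in np.flatnonzero(row_sums < m)]
        raise DataError(
            f"subsample_size {m} exceeds the total count of repertoire(s) {small}"
        )
    return m


def _realize(
    counts: np.ndarray, m: int, params: RDIParameters, rng: np.random.Generator
) -> np.ndarray:
    """One subsample/normalize/transform realization for every row."""
    out = np.empty(counts.shape, dtype=float)
    for i in range(counts.shape[0]):
        sub = subsample_counts(counts[i], m, rng)
        out[i] = transform_counts(
            normalize_counts(sub, params.norm_constant), params.transform
        )
    return out


def calc_rdi(table: FeatureCountTable, params: RDIParameters = RDIParameters()) -> DistanceMatrix:
    """Compute the full RDI distance matrix for a count table.

    In each of ``params.n_iterations`` rounds every repertoire is subsampled
    once (globally, so all pairs of a round share realizations), normalized,
    transformed, and all pairwise distances are taken; the final matrix is
    the elementwise mean over rounds.  Self-distance is 0 by convention.
    Deterministic given ``params.seed``.
    """
    if table.n_repertoires < 2:
        raise DataError("need at least 2 repertoires")
    m = _resolve_subsample(table, params)
    rng = np.random.default_rng(params.seed)
    acc = np.zeros(table.n_repertoires * (table.n_repertoires - 1) // 2)
    for _ in range(params.n_iterations):
        real = _realize(table.counts, m, params, rng)
        acc += pdist(real, metric="euclidean")
    acc /= params.n_iterations
    if params.distance_mode == "rmsd":
        acc /= np.sqrt(table.n_features)
    return DistanceMatrix(
        ids=list(table.repertoire_ids),
        values=squareform(acc),
        params=params,
        resolved_subsample_size=m,
    )


def cross_rdi(
    table: FeatureCountTable,
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    params: RDIParameters = RDIParameters(),
) -> np.ndarray:
    """Mean RDI between two disjoint row sets, as a len(a) x len(b) matrix.

    Identical pipeline to :func:`calc_rdi` but only the cross block is
    evaluated — used by calibration, where thousands of perturbed datasets
    are each compared against a small panel of baseline datasets and the
    full pairwise matrix would be wasted work.
    """
    rows_a = np.asarray(rows_a, dtype=int)
    rows_b = np.asarray(rows_b, dtype=int)
    m = _resolve_subsample(table, params)
    rng = np.random.default_rng(params.seed)
    used = np.concatenate([rows_a, rows_b])
    ia, ib = np.arange(rows_a.size), rows_a.size + np.arange(rows_b.size)
    acc = np.zeros((rows_a.size, rows_b.size))
    for _ in range(params.n_iterations):
        real = _realize(table.counts[used], m, params, rng)
        acc += cdist(real[ia], real[ib], metric="euclidean")
    acc /= params.n_iterations
    if params.distance_mode == "rmsd":
        acc /= np.sqrt(table.n_features)
    return acc


def shannon_entropy(counts: np.ndarray) -> float:
    """Shannon entropy of a count (or frequency) vector, in bits."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DataError("cannot compute entropy of an all-zero vector")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())
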