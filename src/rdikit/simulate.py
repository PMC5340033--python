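"""Synthetic repertoires with exactly known ground-truth deviation.

The simulation framework draws repertoires as multinomial samples from
probability vectors over gene segments.  A baseline vector ``p_base`` is
perturbed on the log2 scale by a random vector ``r``:

    p_fc  ∝  p_base · 2^r        (renormalized to sum to 1)

and the realized "true deviation" of the perturbed vector — the mean
absolute log2 fold change (or percent change) of each gene relative to
baseline, computed after renormalization — is recorded per repertoire.
Because calibration keys on the realized deviation rather than on the
nominal perturbation scale, the distribution chosen for ``r`` (i.i.d.
Normal on the log2 scale here) only affects how the deviation axis is
covered, not the meaning of the calibration.

Also provided: the null-split experiment, which divides one real or
simulated repertoire into two unevenly sized pseudo-repertoires that are
identical by construction, giving an empirical null for the dissimilarity
metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DataError
from .repertoire import FeatureCountTable

DeviationUnits = Literal["log2fc", "pct_change"]

# mean of |N(0, sigma^2)| is sigma * sqrt(2/pi)
_HALF_NORMAL = float(np.sqrt(2.0 / np.pi))

__all__ = [
    "ProbabilityVector",
    "PerturbationVector",
    "SimulatedRepertoireSet",
    "geometric_baseline",
    "baseline_from_counts",
    "sample_perturbation",
    "perturb",
    "true_deviation",
    "perturbation_with_deviation",
    "draw_repertoire",
    "simulate_perturbed_set",
    "null_split",
    "counts_to_airr",
]


@dataclass
class ProbabilityVector:
    """A gene-segment probability vector (entries >= 0, summing to 1)."""

    probs: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or self.probs.size < 1:
            raise DataError("probability vector must be 1-D and non-empty")
        if np.any(self.probs < 0):
            raise DataError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise DataError(f"probabilities sum to {self.probs.sum()}, not 1")
        if self.labels is not None and len(self.labels) != self.probs.size:
            raise DataError("labels length does not match probabilities")

    def __len__(self) -> int:
        return self.probs.size


@dataclass
class PerturbationVector:
    """Log2-scale offsets, one per feature."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 1:
            raise DataError("perturbation vector must be 1-D")
        if not np.all(np.isfinite(self.r)):
            raise DataError("perturbation entries must be finite")


@dataclass
class SimulatedRepertoireSet:
    """A count table plus the ground truth each row embodies."""

    counts: FeatureCountTable
    truth: dict[str, tuple[float, float]]  # id -> (true_log2fc, true_pct_change)
    baseline: ProbabilityVector

    def truth_dataframe(self) -> pd.DataFrame:
        rows = [
            {"repertoire_id": rid, "true_log2fc": l2, "true_pct_change": pct}
            for rid, (l2, pct) in self.truth.items()
        ]
        return pd.DataFrame(rows)

    def truth_to_csv(self, path: str | Path) -> None:
        self.truth_dataframe().to_csv(path, index=False)


def geometric_baseline(n_features: int = 50, decay: float = 0.9) -> ProbabilityVector:
    """Default baseline: probabilities proportional to ``decay**i``.

    A geometric decay over 50 features mimics the steeply uneven gene-segment
    prevalence seen in heavy-chain and TCR repertoires (orders of magnitude
    between the most and least used segments).
    """
    if n_features < 1 or not (0 < decay <= 1):
        raise DataError("need n_features >= 1 and 0 < decay <= 1")
    w = decay ** np.arange(n_features)
    labels = [f"SIMV{i + 1}" for i in range(n_features)]
    return ProbabilityVector(w / w.sum(), labels=labels)


def baseline_from_counts(table: FeatureCountTable) -> ProbabilityVector:
    """Average the per-repertoire frequency vectors, renormalized to sum 1."""
    if table.n_repertoires < 1:
        raise DataError("empty count table")
    totals = table.row_sums()
    if np.any(totals <= 0):
        raise DataError("every repertoire needs a positive total count")
    freqs = table.counts / totals[:, None]
    mean = freqs.mean(axis=0)
    return ProbabilityVector(mean / mean.sum(), labels=list(table.feature_labels))


def sample_perturbation(
    n_features: int, sigma: float, rng: np.random.Generator
) -> PerturbationVector:
    """i.i.d. Normal(0, sigma^2) log2-scale offsets; sigma=0 gives zeros."""
    if n_features < 1:
        raise DataError("n_features must be >= 1")
    if sigma < 0:
        raise DataError("sigma must be >= 0")
    if sigma == 0:
        return PerturbationVector(np.zeros(n_features))
    return PerturbationVector(rng.normal(0.0, sigma, size=n_features))


def perturb(p_base: ProbabilityVector, r: PerturbationVector) -> ProbabilityVector:
    """Apply ``p_base * 2**r`` elementwise and renormalize to sum 1.

    Zero-probability baseline entries stay zero regardless of ``r``.
    Invariant: adding a constant to every entry of ``r`` changes nothing,
    since renormalization absorbs a global factor.
    """
    if len(p_base) != r.r.size:
        raise DataError("perturbation length does not match probability vector")
    if not np.any(r.r):  # exact identity, no renormalization roundoff
        return ProbabilityVector(p_base.probs.copy(), labels=p_base.labels)
    unnorm = p_base.probs * np.exp2(r.r)
    unnorm = np.where(p_base.probs > 0, unnorm, 0.0)
    return ProbabilityVector(unnorm / unnorm.sum(), labels=p_base.labels)


def true_deviation(
    p_fc: ProbabilityVector,
    p_base: ProbabilityVector,
    units: DeviationUnits = "log2fc",
) -> float:
    """Realized average deviation of a perturbed vector from baseline.

    ``log2fc``: mean over features of \\|log2(p_fc / p_base)\\| — the unit the
    ArcSinh-transformed metric tracks.  ``pct_change``: mean of
    100·\\|p_fc − p_base\\| / p_base — the unit the untransformed metric tracks.
    Computed on the renormalized perturbed vector; features with zero
    baseline probability are excluded from the average.
    """
    if len(p_fc) != len(p_base):
        raise DataError("vectors must have equal length")
    base = p_base.probs
    if np.all(base == 0):
        raise DataError("baseline is all zero")
    if np.array_equal(p_fc.probs, base):
        return 0.0
    mask = base > 0
    if np.any(~mask) and np.any(p_fc.probs[~mask] > 0):
        raise DataError("perturbed vector has mass on zero-baseline features")
    fc = p_fc.probs[mask] / base[mask]
    if units == "log2fc":
        if np.any(fc == 0):
            raise DataError("perturbed vector has zeros where baseline is positive")
        return float(np.mean(np.abs(np.log2(fc))))
    if units == "pct_change":
        return float(np.mean(100.0 * np.abs(fc - 1.0)))
    raise DataError(f"unknown units {units!r}")


def perturbation_with_deviation(
    p_base: ProbabilityVector,
    target: float,
    rng: np.random.Generator,
    max_scale: float = 64.0,
) -> tuple[PerturbationVector, ProbabilityVector]:
    """Draw a perturbation whose *realized* log2fc deviation equals ``target``.

    A standard-normal-shaped vector is drawn once, then rescaled by a 1-D
    root find so that the deviation of the renormalized perturbed vector hits
    ``target`` (renormalization makes realized deviation a nonlinear function
    of the scale, so simple proportional scaling is not exact).
    Returns the perturbation and the perturbed vector.
    """
    if target < 0:
        raise DataError("target deviation must be >= 0")
    if target == 0:
        r = PerturbationVector(np.zeros(len(p_base)))
        return r, perturb(p_base, r)
    shape = rng.normal(0.0, 1.0, size=len(p_base))

    def dev_at(scale: float) -> float:
        return true_deviation(
            perturb(p_base, PerturbationVector(shape * scale)), p_base, "log2fc"
        )

    lo, hi = 0.0, target / _HALF_NORMAL
    while dev_at(hi) < target:
        hi *= 2.0
        if hi > max_scale:
            raise DataError(f"cannot reach deviation {target} within scale {max_scale}")
    scale = brentq(lambda s: dev_at(s) - target, lo, hi, xtol=1e-12)
    r = PerturbationVector(shape * scale)
    return r, perturb(p_base, r)


def draw_repertoire(p: ProbabilityVector, n: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial draw of ``n`` sequences from a probability vector."""
    if n < 1:
        raise DataError("n must be >= 1")
    return rng.multinomial(int(n), p.probs)


def simulate_perturbed_set(
    p_base: ProbabilityVector,
    sigmas: Sequence[float],
    n_seq: int,
    n_baseline: int,
    rng: np.random.Generator,
) -> SimulatedRepertoireSet:
    """One perturbed repertoire per sigma plus a panel of baseline repertoires.

    Each perturbed repertoire's realized deviation is recorded in both units;
    baseline repertoires have truth 0 by definition.
    """
    if n_seq < 1 or n_baseline < 1:
        raise DataError("n_seq and n_baseline must be >= 1")
    ids: list[str] = []
    rows: list[np.ndarray] = []
    truth: dict[str, tuple[float, float]] = {}
    for k, sigma in enumerate(sigmas):
        r = sample_perturbation(len(p_base), float(sigma), rng)
        p_fc = perturb(p_base, r)
        rid = f"perturbed_{k + 1}"
        ids.append(rid)
        rows.append(draw_repertoire(p_fc, n_seq, rng))
        truth[rid] = (
            true_deviation(p_fc, p_base, "log2fc"),
            true_deviation(p_fc, p_base, "pct_change"),
        )
    for k in range(n_baseline):
        rid = f"baseline_{k + 1}"
        ids.append(rid)
        rows.append(draw_repertoire(p_base, n_seq, rng))
        truth[rid] = (0.0, 0.0)
    labels = p_base.labels or [f"F{j + 1}" for j in range(len(p_base))]
    table = FeatureCountTable(
        repertoire_ids=ids,
        feature_labels=list(labels),
        counts=np.vstack(rows),
        feature_name="simulated",
    )
    return SimulatedRepertoireSet(counts=table, truth=truth, baseline=p_base)


def null_split(
    counts: np.ndarray, m_small: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split one repertoire into two complementary pseudo-repertoires.

    The first part is a without-replacement subsample of ``m_small``
    elements; the second is the elementwise remainder.  The two repertoires
    are identical in expectation, so their dissimilarity is a draw from the
    metric's null distribution at the smaller size.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if not (0 < m_small < total):
        raise DataError(f"m_small must be in (0, {total}), got {m_small}")
    small = rng.multivariate_hypergeometric(counts, int(m_small))
    return small, counts - small


def counts_to_airr(
    table: FeatureCountTable,
    path: str | Path,
    id_column: str = "repertoire_id",
    feature_column: str = "v_call",
    allele_suffix: str = "*01",
) -> None:
    """Expand a count table into a synthetic AIRR-style rearrangement TSV.

    One row per counted sequence, with gene calls formed from the feature
    labels plus an allele suffix, for end-to-end tests of the TSV pipeline.
    """
    with open(path, "w") as fh:
        fh.write(f"{id_column}\t{feature_column}\n")
        for i, rid in enumerate(table.repertoire_ids):
            for j, label in enumerate(table.feature_labels):
                call = f"{label}{allele_suffix}"
                for _ in range(int(table.counts[i, j])):
                    fh.write(f"{rid}\t{call}\n")
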