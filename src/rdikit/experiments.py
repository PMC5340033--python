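"""Synthetic benchmark experiments for the dissimilarity metric.

Each function reproduces, at configurable scale, one of the simulation
studies that characterize the metric:

* :func:`variance_inflation_experiment` — replicate samples of varying depth
  from one gene pool; naive frequency-space Euclidean distance inflates as
  depth drops while the subsampled metric stays flat.
* :func:`scaling_experiment` — repertoires simulated at known average
  deviations; mean RDI increases with deviation at every repertoire size,
  and even 50-sequence repertoires separate 4-fold differences from null.
* :func:`recovery_experiment` — calibration round trip; repertoires
  simulated at deviation d are converted back to approximately d.
* :func:`null_split_experiment` — random uneven splits of one large
  repertoire (identical by construction) produce RDI values that sit on the
  calibrated deviation-0 reference band.

All experiments are deterministic given their ``rng`` argument.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress, mannwhitneyu, t as t_dist

from .calibrate import (
    CalibrationModel,
    build_calibration,
    ladder_band_overlap,
    make_ladder,
    normal_overlap,
    null_tail_fraction,
    rdi_to_fold,
)
from .rdi import RDIParameters, calc_rdi, cross_rdi
from .repertoire import FeatureCountTable
from .simulate import (
    ProbabilityVector,
    baseline_from_counts,
    draw_repertoire,
    geometric_baseline,
    null_split,
    perturbation_with_deviation,
)

__all__ = [
    "size_slope_test",
    "rdi_vs_baseline",
    "variance_inflation_experiment",
    "scaling_experiment",
    "recovery_experiment",
    "null_split_experiment",
]


def _seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def size_slope_test(sizes: np.ndarray, dmat: np.ndarray) -> tuple[float, float]:
    """Slope (and p-value) of distance against repertoire size.

    Pairwise distances sharing a repertoire are correlated, so a naive
    regression over all pairs is wildly anti-conservative.  Each
    repertoire's mean distance to all others is regressed on its own size
    instead: pair-level noise averages out, the 30 points have essentially
    independent errors, and a heteroskedasticity-robust (HC3) standard
    error gives the slope test close to nominal size.
    """
    sizes = np.asarray(sizes, dtype=float)
    n = sizes.size
    mean_dist = dmat.sum(axis=1) / (n - 1)
    res = linregress(sizes, mean_dist)
    # HC3 robust SE for the slope of a simple linear regression
    xc = sizes - sizes.mean()
    resid = mean_dist - (res.intercept + res.slope * sizes)
    h = 1.0 / n + xc**2 / np.sum(xc**2)
    se = np.sqrt(np.sum((xc * resid / (1.0 - h)) ** 2)) / np.sum(xc**2)
    tstat = res.slope / se
    p = 2.0 * t_dist.sf(abs(tstat), n - 2)
    return float(res.slope), float(p)


def variance_inflation_experiment(
    rng: np.random.Generator,
    n_replicates: int = 30,
    n_features: int = 50,
    size_range: tuple[int, int] = (3000, 12000),
    params: RDIParameters = RDIParameters(),
    baseline: ProbabilityVector | None = None,
) -> dict:
    """Depth-confound check: distance vs original repertoire size.

    Replicate repertoires are drawn from a single pool with depths uniform
    in ``size_range``; all pairwise distances are computed twice, naively on
    frequency vectors and with the subsampled metric, and each is regressed
    on size via :func:`size_slope_test`.
    """
    base = baseline or geometric_baseline(n_features)
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_replicates)
    rows = np.vstack([draw_repertoire(base, int(n), rng) for n in sizes])
    labels = base.labels or [f"F{j}" for j in range(len(base))]
    table = FeatureCountTable(
        [f"rep_{i}" for i in range(n_replicates)], list(labels), rows
    )
    freqs = rows / rows.sum(axis=1, keepdims=True)
    naive = squareform(pdist(freqs))
    matrix = calc_rdi(table, dataclasses.replace(params, seed=_seed(rng)))
    naive_slope, naive_p = size_slope_test(sizes, naive)
    rdi_slope, rdi_p = size_slope_test(sizes, matrix.values)
    return {
        "sizes": sizes,
        "naive_slope": naive_slope,
        "naive_p": naive_p,
        "rdi_slope": rdi_slope,
        "rdi_p": rdi_p,
        "resolved_subsample_size": matrix.resolved_subsample_size,
    }


def rdi_vs_baseline(
    base: ProbabilityVector,
    deviation: float,
    n_seq: int,
    n_replicates: int,
    n_baseline: int,
    params: RDIParameters,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean RDI (vs a baseline panel) of replicates at one realized deviation."""
    rows = []
    for _ in range(n_replicates):
        _, p_fc = perturbation_with_deviation(base, deviation, rng)
        rows.append(draw_repertoire(p_fc, n_seq, rng))
    for _ in range(n_baseline):
        rows.append(draw_repertoire(base, n_seq, rng))
    labels = base.labels or [f"F{j}" for j in range(len(base))]
    table = FeatureCountTable(
        [f"x_{i}" for i in range(len(rows))], list(labels), np.vstack(rows)
    )
    run = dataclasses.replace(params, subsample_size=n_seq, seed=_seed(rng))
    cross = cross_rdi(
        table, np.arange(n_replicates), n_replicates + np.arange(n_baseline), run
    )
    return cross.mean(axis=1)


def scaling_experiment(
    rng: np.random.Generator,
    n_seq_values: tuple[int, ...] = (50, 500, 5000),
    deviations: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0),
    n_replicates: int = 30,
    n_baseline: int = 10,
    n_features: int = 50,
    params: RDIParameters = RDIParameters(),
) -> dict:
    """Mean RDI against realized deviation at several repertoire sizes.

    Returns per-size mean RDI by deviation, whether those means increase
    strictly with deviation, and the rank-separation AUC between the largest
    and the zero deviation (1.0 = perfectly separable).
    """
    base = geometric_baseline(n_features)
    results: dict[int, dict] = {}
    for n_seq in n_seq_values:
        samples = {
            d: rdi_vs_baseline(base, d, n_seq, n_replicates, n_baseline, params, rng)
            for d in deviations
        }
        means = {d: float(s.mean()) for d, s in samples.items()}
        ordered = [means[d] for d in deviations]
        u = mannwhitneyu(
            samples[deviations[-1]], samples[deviations[0]], alternative="greater"
        )
        auc = float(u.statistic) / (n_replicates * n_replicates)
        results[n_seq] = {
            "means": means,
            "samples": samples,
            "monotone": all(a < b for a, b in zip(ordered, ordered[1:])),
            "auc_max_vs_null": auc,
        }
    return results


def recovery_experiment(
    rng: np.random.Generator,
    deviations: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
    n_seq: int = 2000,
    n_features: int = 50,
    n_replicates: int = 50,
    n_baseline: int = 20,
    n_perturb: int = 200,
    params: RDIParameters = RDIParameters(),
    model: CalibrationModel | None = None,
) -> dict:
    """Calibrate, then recover known deviations from fresh simulated data."""
    base = geometric_baseline(n_features)
    if model is None:
        ref = FeatureCountTable(
            ["ref_1", "ref_2"],
            list(base.labels),
            np.vstack(
                [draw_repertoire(base, n_seq, rng), draw_repertoire(base, n_seq, rng)]
            ),
        )
        model = build_calibration(
            ref, params, n_perturb=n_perturb, n_baseline=n_baseline, rng=rng
        )
    out = {}
    for d in deviations:
        mean_rdi = rdi_vs_baseline(
            base, d, n_seq, n_replicates, n_baseline, params, rng
        )
        estimates = np.array([rdi_to_fold(model, float(v)) for v in mean_rdi])
        out[d] = {
            "estimates": estimates,
            "mean_estimate": float(estimates.mean()),
            "bias": float(estimates.mean() - d),
        }
    return {"model": model, "by_deviation": out}


def null_split_experiment(
    rng: np.random.Generator,
    pool_size: int = 100_000,
    split_sizes: tuple[int, ...] = (1000, 2500, 5000, 10_000, 50_000),
    n_splits: int = 40,
    n_features: int = 50,
    n_perturb: int = 500,
    n_baseline: int = 20,
    params: RDIParameters = RDIParameters(),
) -> dict:
    """Uneven random splits of one repertoire versus the deviation-0 band.

    A single pool of ``pool_size`` sequences is split ``n_splits`` times at
    each small-side size; the RDI between the two halves is compared against
    a calibration (matched in size and features) of simulated repertoires:
    the overlap of the split-RDI distribution with the deviation-0 ladder
    band, and the null tail fraction of the median split RDI.
    """
    base = geometric_baseline(n_features)
    pool = draw_repertoire(base, pool_size, rng)
    labels = base.labels or [f"F{j}" for j in range(len(base))]
    results: dict[int, dict] = {}
    for m_small in split_sizes:
        small, rest = null_split(pool, m_small, rng)
        ref = FeatureCountTable(["small", "rest"], list(labels), np.vstack([small, rest]))
        model = build_calibration(
            ref, params, n_perturb=n_perturb, n_baseline=n_baseline, rng=rng
        )
        entry = make_ladder(model, [0.0]).entries[0]
        values = np.empty(n_splits)
        for k in range(n_splits):
            a, b = null_split(pool, m_small, rng)
            pair = FeatureCountTable(["a", "b"], list(labels), np.vstack([a, b]))
            run = dataclasses.replace(params, seed=_seed(rng))
            values[k] = calc_rdi(pair, run).values[0, 1]
        results[m_small] = {
            "split_rdi": values,
            "band_mean": entry.mean_rdi,
            "band_sd": entry.sd_rdi,
            "overlap": ladder_band_overlap(entry, values),
            "tail_fractions": np.array(
                [null_tail_fraction(model, float(v)) for v in values]
            ),
            "median_tail_fraction": null_tail_fraction(model, float(np.median(values))),
        }
    # pooled view across the whole ensemble of splits: each value
    # standardized by its size's band, compared against the unit band
    z = np.concatenate(
        [(r["split_rdi"] - r["band_mean"]) / r["band_sd"] for r in results.values()]
    )
    pooled_overlap = normal_overlap(0.0, 1.0, float(z.mean()), float(z.std(ddof=1)))
    pooled_tail = float(
        np.median(np.concatenate([r["tail_fractions"] for r in results.values()]))
    )
    return {
        "by_size": results,
        "pooled_overlap": pooled_overlap,
        "pooled_median_tail_fraction": pooled_tail,
    }
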