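"""Calibrate raw RDI values into fold-change / percent-change units.

A raw RDI value depends on the subsample size, the number of features, the
normalization constant and the transform, so it can only be compared with
other RDI values computed the same way.  Calibration makes it absolute: for
a given dataset, simulated repertoires are generated with the same number of
features and sequences and with *known* average deviation from a baseline
probability vector.  The mean RDI of each perturbed dataset against a panel
of baseline datasets, plotted against its realized deviation, is fitted with
a smoothing spline (monotonized by isotonic projection); inverting that
curve converts an observed RDI into the average fold change (ArcSinh
transform) or percent change (no transform) it corresponds to.

The "RDI ladder" is the same model read the other way: at pre-specified
deviations it reports the expected RDI and a local standard deviation
estimated from the spline residuals, giving reference distributions an
observed value can be compared against.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import isotonic_regression
from scipy.stats import norm

from .errors import CalibrationError, ConfigurationError, DataError
from .rdi import RDIParameters, calc_rdi, cross_rdi
from .repertoire import FeatureCountTable
from .simulate import (
    DeviationUnits,
    PerturbationVector,
    ProbabilityVector,
    _HALF_NORMAL,
    baseline_from_counts,
    draw_repertoire,
    perturb,
    sample_perturbation,
    true_deviation,
)

__all__ = [
    "CalibrationModel",
    "LadderEntry",
    "RDILadder",
    "build_calibration",
    "rdi_to_fold",
    "make_ladder",
    "ladder_density",
    "null_tail_fraction",
    "normal_overlap",
    "ladder_band_overlap",
]

_GRID_SIZE = 1024


@dataclass
class CalibrationModel:
    """A fitted, monotone deviation -> expected-RDI map with residual spread.

    The forward map is stored as a dense piecewise-linear grid
    (``grid_dev``, ``grid_rdi``); inversion interpolates the same grid with
    the axes swapped, so inverse-of-forward is exact on the fitted interior.
    """

    dev_points: np.ndarray      # realized deviations of the fitted points
    rdi_points: np.ndarray      # mean RDI of each perturbed dataset
    grid_dev: np.ndarray        # dense, strictly increasing deviation grid
    grid_rdi: np.ndarray        # monotone expected RDI on that grid
    resid_dev: np.ndarray       # window centers for the residual-SD model
    resid_sd: np.ndarray        # local SD of residuals at those centers
    units: DeviationUnits
    settings: dict              # n_features, n_seq, transform, ...
    null_sample: np.ndarray     # baseline-vs-baseline RDI values

    def expected_rdi(self, deviation: float | np.ndarray) -> np.ndarray | float:
        """Evaluate the fitted (monotone) spline: deviation -> mean RDI."""
        return np.interp(deviation, self.grid_dev, self.grid_rdi)

    def residual_sd_at(self, deviation: float | np.ndarray) -> np.ndarray | float:
        return np.interp(deviation, self.resid_dev, self.resid_sd)

    @property
    def dev_range(self) -> tuple[float, float]:
        return float(self.grid_dev[0]), float(self.grid_dev[-1])

    def check_settings(
        self,
        params: RDIParameters,
        resolved_subsample_size: int | None = None,
        n_features: int | None = None,
    ) -> None:
        """Raise unless RDI values under ``params`` live on this model's scale."""
        mismatches = []
        for key in ("transform", "norm_constant", "distance_mode", "n_iterations"):
            if getattr(params, key) != self.settings[key]:
                mismatches.append(
                    f"{key}: model={self.settings[key]!r} vs matrix={getattr(params, key)!r}"
                )
        if (
            resolved_subsample_size is not None
            and resolved_subsample_size != self.settings["n_seq"]
        ):
            mismatches.append(
                f"subsample size: model={self.settings['n_seq']} vs "
                f"matrix={resolved_subsample_size}"
            )
        if n_features is not None and n_features != self.settings["n_features"]:
            mismatches.append(
                f"n_features: model={self.settings['n_features']} vs matrix={n_features}"
            )
        if mismatches:
            raise ConfigurationError(
                "calibration model and distance matrix settings differ: "
                + "; ".join(mismatches)
            )

    def to_json(self, path: str | Path) -> None:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = (
            "dev_points",
            "rdi_points",
            "grid_dev",
            "grid_rdi",
            "resid_dev",
            "resid_sd",
            "null_sample",
        )
        for k in arrays:
            payload[k] = np.asarray(payload[k], dtype=float)
        return cls(**payload)


@dataclass(frozen=True)
class LadderEntry:
    deviation: float
    mean_rdi: float
    sd_rdi: float


@dataclass
class RDILadder:
    """Reference (deviation, expected RDI mean, local SD) triples."""

    entries: list[LadderEntry]
    units: DeviationUnits

    def __post_init__(self) -> None:
        devs = [e.deviation for e in self.entries]
        if any(b <= a for a, b in zip(devs, devs[1:])):
            raise DataError("ladder deviations must be strictly increasing")
        if any(e.sd_rdi <= 0 for e in self.entries):
            raise DataError("ladder SDs must be positive")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.deviation, e.mean_rdi, e.sd_rdi) for e in self.entries],
            columns=["deviation", "mean_rdi", "sd_rdi"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_calibration(
    table: FeatureCountTable,
    params: RDIParameters = RDIParameters(),
    n_perturb: int = 2000,
    n_baseline: int = 20,
    max_log2fc: float = 8.0,
    rng: np.random.Generator | int | None = None,
) -> CalibrationModel:
    """Fit a deviation -> RDI calibration matched to a real count table.

    The baseline probability vector is the table's average gene frequency.
    ``n_perturb`` perturbation vectors are generated with nominal deviations
    spread uniformly over [0, ``max_log2fc``] on the log2 scale (the default
    8 corresponds to up to 256-fold average change per gene); each perturbed
    vector yields one simulated dataset whose size matches the table's
    resolved subsample size, and its RDI is averaged over comparisons to
    ``n_baseline`` baseline datasets.  The *realized* deviation of each
    vector (after renormalization) is the x-coordinate of the fit.
    """
    if n_perturb < 10 or n_baseline < 2:
        raise DataError("need n_perturb >= 10 and n_baseline >= 2")
    rng = np.random.default_rng(rng)
    baseline = baseline_from_counts(table)
    n_features = table.n_features
    if params.subsample_size == "auto":
        n_seq = int(table.row_sums().min())
    else:
        n_seq = int(params.subsample_size)
    units: DeviationUnits = "log2fc" if params.transform == "asinh" else "pct_change"

    # one perturbed dataset per vector, realized deviation recorded.
    # Nominal deviations mix a log-spaced and a uniform ladder over
    # (0, max_log2fc]: the response curve bends sharply near zero, so the
    # log-spaced half concentrates points where curvature is largest while
    # the uniform half keeps the upper range well constrained.
    n_log = (n_perturb - 1) // 2
    n_lin = n_perturb - 1 - n_log
    targets = np.concatenate(
        [
            [0.0],
            np.geomspace(max_log2fc / 256.0, max_log2fc, n_log),
            np.linspace(max_log2fc / n_lin, max_log2fc, n_lin),
        ]
    )
    # each simulated dataset matches one of the real repertoires' sizes
    # (cycling through them), so the subsampling machinery sees the same
    # size structure — and hence the same averaging of subsample noise —
    # as the real comparisons the model will be applied to
    real_sizes = table.row_sums()
    devs = np.empty(n_perturb)
    rows = np.empty((n_perturb + n_baseline, n_features), dtype=np.int64)
    for i, target in enumerate(targets):
        r = sample_perturbation(n_features, target / _HALF_NORMAL, rng)
        p_fc = perturb(baseline, r)
        devs[i] = true_deviation(p_fc, baseline, units)
        rows[i] = draw_repertoire(p_fc, int(real_sizes[i % real_sizes.size]), rng)
    for k in range(n_baseline):
        rows[n_perturb + k] = draw_repertoire(
            baseline, int(real_sizes[k % real_sizes.size]), rng
        )

    sim_table = FeatureCountTable(
        repertoire_ids=[f"sim_{i}" for i in range(n_perturb + n_baseline)],
        feature_labels=list(table.feature_labels),
        counts=rows,
        feature_name="calibration",
    )
    sim_params = dataclasses.replace(
        params, subsample_size=n_seq, seed=int(rng.integers(2**31))
    )
    cross = cross_rdi(
        sim_table,
        np.arange(n_perturb),
        n_perturb + np.arange(n_baseline),
        sim_params,
    )
    mean_rdi = cross.mean(axis=1)

    base_params = dataclasses.replace(
        params, subsample_size=n_seq, seed=int(rng.integers(2**31))
    )
    base_table = FeatureCountTable(
        repertoire_ids=[f"base_{k}" for k in range(n_baseline)],
        feature_labels=list(table.feature_labels),
        counts=rows[n_perturb:],
        feature_name="calibration",
    )
    null_sample = calc_rdi(base_table, base_params).offdiag()

    # the baseline-vs-baseline RDI values are measurements at deviation 0:
    # they anchor the left end of the fit and of the residual-spread model
    fit_dev = np.concatenate([np.zeros(null_sample.size), devs])
    fit_rdi = np.concatenate([null_sample, mean_rdi])
    grid_dev, grid_rdi = _fit_monotone_spline(fit_dev, fit_rdi)
    resid_dev, resid_sd = _rolling_residual_sd(fit_dev, fit_rdi, grid_dev, grid_rdi)

    return CalibrationModel(
        dev_points=np.sort(devs),
        rdi_points=mean_rdi[np.argsort(devs)],
        grid_dev=grid_dev,
        grid_rdi=grid_rdi,
        resid_dev=resid_dev,
        resid_sd=resid_sd,
        units=units,
        settings={
            "n_features": n_features,
            "n_seq": n_seq,
            "transform": params.transform,
            "distance_mode": params.distance_mode,
            "norm_constant": params.norm_constant,
            "n_iterations": params.n_iterations,
            "n_perturb": n_perturb,
            "n_baseline": n_baseline,
        },
        null_sample=null_sample,
    )


def _fit_monotone_spline(devs: np.ndarray, rdi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smoothing spline through (deviation, mean RDI), isotonic-projected.

    Returns a dense strictly increasing grid representation of the monotone
    forward map.  A microscopic ramp breaks ties left by the isotonic
    projection so the map is numerically invertible.
    """
    # smoothing splines need strictly increasing x: pool exact duplicates
    # (notably the deviation-0 anchors), weighting each pooled x by its count;
    # rounding first merges floating-noise near-duplicates that would make
    # the penalized system ill-conditioned
    ux, inv = np.unique(np.round(devs, 10), return_inverse=True)
    uw = np.bincount(inv).astype(float)
    uy = np.bincount(inv, weights=rdi) / uw
    if ux.size < 4:
        raise CalibrationError("too few distinct deviations to fit a spline")
    # the expected-RDI curve is even in the deviation (reversing a
    # perturbation leaves the distance distribution unchanged), so its slope
    # at 0 is zero; fitting the spline on data mirrored about 0 enforces
    # that symmetry and removes the boundary bias an asymmetric fit shows
    # (it otherwise anticipates the rise and pivots under the anchor)
    pos = ux > 0
    mx = np.concatenate([-ux[pos][::-1], ux])
    my = np.concatenate([uy[pos][::-1], uy])
    mw = np.concatenate([uw[pos][::-1], uw])
    spline = make_smoothing_spline(mx, my, w=mw)
    grid_dev = np.linspace(ux[0], ux[-1], _GRID_SIZE)
    smoothed = spline(grid_dev)
    mono = isotonic_regression(smoothed, increasing=True).x
    span = mono[-1] - mono[0]
    if span <= 0:
        raise CalibrationError(
            "fitted curve is flat after monotonization; increase n_perturb "
            "or the deviation range"
        )
    eps = span * 1e-7 / _GRID_SIZE
    return grid_dev, mono + eps * np.arange(_GRID_SIZE)


def _rolling_residual_sd(
    devs: np.ndarray,
    rdi: np.ndarray,
    grid_dev: np.ndarray,
    grid_rdi: np.ndarray,
    window_frac: float = 0.10,
    min_window: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Local SD of fit residuals in a sliding window along the deviation axis."""
    order = np.argsort(devs)
    x = np.round(devs[order], 10)
    resid = rdi[order] - np.interp(x, grid_dev, grid_rdi)
    n = x.size
    w = min(n, max(min_window, int(np.ceil(window_frac * n))))
    # windows never split a group of tied x values (e.g. the deviation-0
    # anchors): ties are not in exchangeable order, so a partial tie group
    # would give a biased local SD
    ux, starts = np.unique(x, return_index=True)
    starts = np.append(starts, n)
    centers, sds = [], []
    g = 0
    while g < ux.size:
        end = g
        while end < ux.size and starts[end + 1] - starts[g] < w:
            end += 1
        lo, hi = starts[g], starts[min(end, ux.size - 1) + 1]
        if hi - lo < 2 and centers:  # fold a tail stub into the previous window
            lo = prev_lo
            centers.pop()
            sds.pop()
        centers.append(x[lo:hi].mean())
        sds.append(resid[lo:hi].std(ddof=1))
        prev_lo = lo
        g = end + 1
    sds = np.maximum(np.asarray(sds, dtype=float), 1e-12)
    return np.asarray(centers, dtype=float), sds


def rdi_to_fold(
    model: CalibrationModel,
    rdi_value: float,
    params: RDIParameters | None = None,
    resolved_subsample_size: int | None = None,
    with_flag: bool = False,
):
    """Convert an observed RDI into estimated average deviation.

    Values below the model's expected RDI at deviation 0 clamp to 0 ("no
    change"); values above the fitted range clamp to the maximum fitted
    deviation.  With ``with_flag=True`` returns ``(estimate, flag)`` where
    flag is ``"ok"``, ``"low_clamp"`` or ``"high_clamp"``.
    """
    if rdi_value < 0:
        raise DataError("RDI values are non-negative")
    if params is not None:
        model.check_settings(params, resolved_subsample_size=resolved_subsample_size)
    flag = "ok"
    if rdi_value <= model.grid_rdi[0]:
        est, flag = float(model.grid_dev[0]), "low_clamp"
    elif rdi_value >= model.grid_rdi[-1]:
        est, flag = float(model.grid_dev[-1]), "high_clamp"
    else:
        est = float(np.interp(rdi_value, model.grid_rdi, model.grid_dev))
    return (est, flag) if with_flag else est


def make_ladder(model: CalibrationModel, deviations: Sequence[float]) -> RDILadder:
    """Expected RDI mean and local SD at each requested deviation."""
    deviations = [float(d) for d in deviations]
    lo, hi = model.dev_range
    tol = 1e-9 * max(1.0, hi)
    for d in deviations:
        if not (lo - tol <= d <= hi + tol):
            raise DataError(f"deviation {d} outside fitted range [{lo}, {hi}]")
    entries = [
        LadderEntry(
            deviation=d,
            mean_rdi=float(model.expected_rdi(d)),
            sd_rdi=float(model.residual_sd_at(d)),
        )
        for d in deviations
    ]
    return RDILadder(entries=entries, units=model.units)


def ladder_density(entry: LadderEntry, grid: np.ndarray) -> np.ndarray:
    """Normal(mean_rdi, sd_rdi^2) density of a ladder entry on a grid."""
    if entry.sd_rdi <= 0:
        raise DataError("ladder SD must be positive")
    return norm.pdf(np.asarray(grid, dtype=float), entry.mean_rdi, entry.sd_rdi)


def null_tail_fraction(model: CalibrationModel, observed_rdi: float) -> float:
    """Smoothed fraction of the stored null RDI sample >= the observed value.

    Add-one smoothing keeps the result in (0, 1]; an observation above every
    null value returns 1/(n+1) rather than 0.
    """
    null = model.null_sample
    if null is None or null.size == 0:
        raise DataError("model has no stored null sample")
    return (float(np.sum(null >= observed_rdi)) + 1.0) / (null.size + 1.0)


def normal_overlap(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Overlap coefficient (integral of the pointwise min) of two normals."""
    if sd1 <= 0 or sd2 <= 0:
        raise DataError("standard deviations must be positive")
    lo = min(mean1 - 8 * sd1, mean2 - 8 * sd2)
    hi = max(mean1 + 8 * sd1, mean2 + 8 * sd2)
    grid = np.linspace(lo, hi, 4001)
    dens = np.minimum(norm.pdf(grid, mean1, sd1), norm.pdf(grid, mean2, sd2))
    return float(np.trapezoid(dens, grid))


def ladder_band_overlap(entry: LadderEntry, sample: np.ndarray) -> float:
    """Overlap between a ladder band and a Gaussian summary of a sample.

    The ladder band is Normal by construction, so the sample is summarized
    by a matching Normal (its mean and SD) and the density overlap
    coefficient is returned: 1 means the sample sits exactly on the band,
    values near 0 mean it lies elsewhere.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2:
        raise DataError("need at least 2 sample values")
    return normal_overlap(
        entry.mean_rdi, entry.sd_rdi, float(sample.mean()), float(sample.std(ddof=1))
    )
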