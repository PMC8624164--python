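"""Partial ROC evaluation of a suitability prediction.

Presence-only niche models cannot be scored with an ordinary ROC because
true absences are unknown.  The partial ROC instead sweeps suitability
thresholds and compares, over the domain where the model still finds at
least a fraction ``1 - E`` of the test occurrences (sensitivity >=
1 - E, with E the acceptable omission rate), the area under the curve of
(proportion of the landscape predicted present, sensitivity) against the
area under the 1:1 line — the expectation of a model that ranks cells at
random.  The statistic is the AUC ratio; ratios above 1 mean the model
concentrates occurrences into less area than chance.  Uncertainty comes
from bootstrap resampling of the test occurrences; the p-value is the
fraction of bootstrap ratios <= 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import EnvStack

logger = logging.getLogger(__name__)

__all__ = ["PartialROCResult", "partial_roc", "extract_test_suitability"]


@dataclass
class PartialROCResult:
    mean_auc_ratio: float
    bootstrap_ratios: np.ndarray
    p_value: float
    E: float
    n_boot: int
    resample_frac: float
    seed: int | None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "mean_auc_ratio": float(self.mean_auc_ratio),
            "p_value": float(self.p_value),
            "E": self.E,
            "n_boot": self.n_boot,
            "resample_frac": self.resample_frac,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def extract_test_suitability(
    suitability: np.ndarray, stack: EnvStack, occ_set
) -> np.ndarray:
    """Suitability at the cells of an OccurrenceSet's test records."""
    idx = occ_set.test_index
    vals = []
    for i in idx:
        lon, lat = occ_set.records[i]
        r, c = stack.transform.index(lon, lat)
        vals.append(suitability[r, c])
    return np.asarray(vals, dtype=float)


def _curve_areas(
    sens: np.ndarray, area_prop: np.ndarray, min_sens: float
) -> tuple[float, float]:
    """Trapezoidal model and null areas over the sensitivity>=min_sens domain.

    ``sens`` and ``area_prop`` are aligned over thresholds sorted so that
    ``area_prop`` is increasing.  The null model's sensitivity equals the
    proportion of area predicted, so its area over the same x-domain is
    the area under the 1:1 line.
    """
    keep = sens >= min_sens
    if keep.sum() < 2:
        return math.nan, math.nan
    x = area_prop[keep]
    y = sens[keep]
    if x[-1] - x[0] <= 0:
        return math.nan, math.nan
    auc_model = float(np.trapezoid(y, x))
    auc_null = float((x[-1] ** 2 - x[0] ** 2) / 2.0)
    return auc_model, auc_null


def partial_roc(
    suitability: np.ndarray,
    test_suitability: np.ndarray,
    nodata: float | None = None,
    E: float = 0.05,
    n_boot: int = 1000,
    resample_frac: float = 0.5,
    seed: int | None = 0,
    max_thresholds: int = 200,
) -> PartialROCResult:
    """Bootstrap partial ROC of a suitability grid against test records.

    Parameters
    ----------
    suitability
        2-D predicted suitability; cells equal to ``nodata`` (or NaN) are
        excluded from the landscape.
    test_suitability
        Suitability values already extracted at the test occurrences.
    E
        Acceptable omission rate; the curve is integrated where
        sensitivity >= 1 - E.
    n_boot, resample_frac
        Bootstrap iterations; each resamples ``ceil(resample_frac * n)``
        test points with replacement.
    max_thresholds
        Thresholds are the grid's unique suitability values, thinned to at
        most this many quantile steps.
    """
    grid = np.asarray(suitability, dtype=float).ravel()
    valid = ~np.isnan(grid)
    if nodata is not None:
        valid &= ~np.isclose(grid, nodata)
    grid = grid[valid]
    test = np.asarray(test_suitability, dtype=float)
    test = test[~np.isnan(test)]
    if test.size < 2:
        raise ValueError("need at least 2 test occurrences on valid cells")
    if grid.size == 0:
        raise ValueError("suitability grid has no valid cells")

    thresholds = np.unique(grid)
    if thresholds.size < 2:
        logger.warning("constant suitability grid: partial ROC is degenerate")
        return PartialROCResult(
            mean_auc_ratio=1.0,
            bootstrap_ratios=np.ones(n_boot),
            p_value=1.0,
            E=E, n_boot=n_boot, resample_frac=resample_frac, seed=seed,
            degenerate=True,
        )
    if thresholds.size > max_thresholds:
        qs = np.linspace(0.0, 1.0, max_thresholds)
        thresholds = np.unique(np.quantile(thresholds, qs))

    # descending thresholds => proportion-of-area-predicted increases
    thresholds = thresholds[::-1]
    grid_sorted = np.sort(grid)
    # fraction of landscape with suitability >= t
    area_prop = 1.0 - np.searchsorted(grid_sorted, thresholds, side="left") / grid.size

    m = max(1, math.ceil(resample_frac * test.size))
    rng = np.random.default_rng(seed)
    samples = rng.choice(test, size=(n_boot, m), replace=True)
    samples.sort(axis=1)
    # sens[b, t]: fraction of resampled test points with suitability >= t
    pos = np.stack(
        [np.searchsorted(samples[b], thresholds, side="left") for b in range(n_boot)]
    )
    sens = 1.0 - pos / m

    min_sens = 1.0 - E
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        auc_model, auc_null = _curve_areas(sens[b], area_prop, min_sens)
        ratios[b] = 1.0 if math.isnan(auc_model) else auc_model / auc_null
    p_value = float(np.mean(ratios <= 1.0))
    return PartialROCResult(
        mean_auc_ratio=float(ratios.mean()),
        bootstrap_ratios=ratios,
        p_value=p_value,
        E=E, n_boot=n_boot, resample_frac=resample_frac, seed=seed,
    )
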