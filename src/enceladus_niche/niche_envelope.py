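"""Occurrence preprocessing and the Bioclim envelope model.

Bioclim is the classic envelope species-distribution algorithm: for each
environmental variable it stores the training occurrences' values and
scores a query value by how central it is within that empirical
distribution.  We use the percentile-distance convention

    s_v(x) = 2 * min(F_v(x), 1 - F_v(x)),      clipped to [0, 1],

with F_v the midpoint empirical CDF

    F_v(x) = (#{values < x} + 0.5 * #{values == x}) / n,

and s_v(x) = 0 for x outside the training [min, max].  The score of a cell
is the minimum over variables (weakest-link rule), so the overall
suitability is bounded by every marginal and the classical min–max
envelope is recovered at threshold 0.

Preprocessing follows standard niche-modelling practice: exact duplicate
coordinates are removed so occurrences are independent records, records on
nodata cells are dropped, 75% of the cleaned records train the model and
25% are held out for evaluation, and collinear predictors are removed with
a Pearson pre-filter on 10,000 random cells at |r| >= 0.8.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import EnvStack, OccurrenceTable

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceSet",
    "EnvelopeModel",
    "ResponseCurve",
    "clean_and_split",
    "correlation_filter",
    "fit_bioclim",
    "predict_suitability",
    "response_curve",
]


@dataclass
class OccurrenceSet:
    """Cleaned, partitioned occurrences with their environmental extraction."""

    taxon: str
    records: list[tuple[float, float]]
    partition: np.ndarray            # 'train' / 'test' per record
    extraction: pd.DataFrame         # one column per variable, row per record
    n_raw: int                       # records before cleaning
    n_duplicates_removed: int
    n_nodata_dropped: int
    seed: int | None = None

    @property
    def train_index(self) -> np.ndarray:
        return np.flatnonzero(self.partition == "train")

    @property
    def test_index(self) -> np.ndarray:
        return np.flatnonzero(self.partition == "test")

    def subset_extraction(self, which: str) -> pd.DataFrame:
        idx = self.train_index if which == "train" else self.test_index
        return self.extraction.iloc[idx]

    def counts(self) -> dict[str, int]:
        return {
            "raw": self.n_raw,
            "cleaned": len(self.records),
            "train": int(self.train_index.size),
            "test": int(self.test_index.size),
        }


@dataclass
class EnvelopeModel:
    """Per-variable sorted training values defining the envelope."""

    taxon: str
    training: dict[str, np.ndarray]   # variable -> sorted training values
    units: dict[str, str] = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return list(self.training)

    def limits(self, var: str) -> tuple[float, float]:
        vals = self.training[var]
        return float(vals[0]), float(vals[-1])

    def marginal_score(self, var: str, x: np.ndarray | float) -> np.ndarray:
        """Percentile-distance suitability of value(s) ``x`` for one variable."""
        vals = self.training[var]
        x = np.asarray(x, dtype=float)
        n = vals.size
        lo, hi = vals[0], vals[-1]
        if lo == hi:
            # degenerate envelope: point mass
            score = np.where(x == lo, 1.0, 0.0)
            return score if score.ndim else float(score)
        below = np.searchsorted(vals, x, side="left")
        upto = np.searchsorted(vals, x, side="right")
        f = (below + 0.5 * (upto - below)) / n
        score = 2.0 * np.minimum(f, 1.0 - f)
        score = np.clip(score, 0.0, 1.0)
        score = np.where((x < lo) | (x > hi), 0.0, score)
        return score if score.ndim else float(score)

    def score_frame(self, env: pd.DataFrame) -> np.ndarray:
        """Weakest-link suitability for rows of an extraction table."""
        per_var = np.column_stack(
            [self.marginal_score(v, env[v].to_numpy()) for v in self.variables]
        )
        return per_var.min(axis=1)

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "variables": {
                v: [float(x) for x in vals] for v, vals in self.training.items()
            },
            "units": dict(self.units),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnvelopeModel":
        training = {
            v: np.sort(np.asarray(vals, dtype=float))
            for v, vals in d["variables"].items()
        }
        return cls(taxon=d.get("taxon", ""), training=training,
                   units=dict(d.get("units", {})))


@dataclass
class ResponseCurve:
    """Marginal suitability of one variable over an evaluation grid."""

    variable: str
    values: np.ndarray
    scores: np.ndarray
    suitable_range: tuple[float, float]
    units: str = ""

    def score_at(self, x: float | np.ndarray) -> np.ndarray:
        return np.interp(x, self.values, self.scores)


def clean_and_split(
    raw: OccurrenceTable,
    stack: EnvStack,
    train_frac: float = 0.75,
    seed: int | None = 0,
) -> OccurrenceSet:
    """Deduplicate, extract environments, and partition train/test.

    Exact-coordinate duplicates are removed (first kept, input order
    preserved), records falling on nodata cells or outside the grid are
    dropped with a warning, and the remainder is randomly partitioned with
    ``round(train_frac * n)`` training records.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    seen: set[tuple[float, float]] = set()
    unique: list[tuple[float, float]] = []
    for rec in raw.records:
        if rec in seen:
            continue
        seen.add(rec)
        unique.append(rec)
    n_dup = len(raw.records) - len(unique)

    lons = np.array([r[0] for r in unique])
    lats = np.array([r[1] for r in unique])
    env = stack.extract(lons, lats)
    ok = ~env.isna().any(axis=1).to_numpy()
    n_nodata = int((~ok).sum())
    for i in np.flatnonzero(~ok):
        logger.warning(
            "dropping occurrence (%.6g, %.6g): nodata or outside grid",
            unique[i][0], unique[i][1],
        )
    records = [r for r, keep in zip(unique, ok) if keep]
    env = env.loc[ok].reset_index(drop=True)
    n = len(records)
    if n < 2:
        raise ValueError(f"only {n} record(s) remain after cleaning; need >= 2")

    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    partition = np.empty(n, dtype=object)
    partition[order[:n_train]] = "train"
    partition[order[n_train:]] = "test"
    return OccurrenceSet(
        taxon=raw.taxon,
        records=records,
        partition=partition,
        extraction=env,
        n_raw=len(raw.records),
        n_duplicates_removed=n_dup,
        n_nodata_dropped=n_nodata,
        seed=seed,
    )


def correlation_filter(
    stack: EnvStack,
    n_points: int = 10_000,
    threshold: float = 0.8,
    seed: int | None = 0,
) -> list[str]:
    """Drop collinear layers by pairwise Pearson correlation.

    ``n_points`` random non-nodata cells are sampled (without replacement
    when enough cells exist); for every layer pair with |r| >= threshold
    the later-listed layer is dropped.  Zero-variance layers on the sample
    are dropped with a warning.  Deterministic given seed and layer order.
    """
    names = stack.names
    if not names:
        raise ValueError("stack has no layers")
    valid_idx = np.flatnonzero(stack.valid_mask.ravel())
    if valid_idx.size == 0:
        raise ValueError("stack has no valid cells")
    rng = np.random.default_rng(seed)
    replace = valid_idx.size < n_points
    sample = rng.choice(valid_idx, size=n_points, replace=replace)
    rows, cols = np.divmod(sample, stack.shape[1])
    data = {name: stack.layers[name][rows, cols] for name in names}

    retained = []
    for name in names:
        if np.std(data[name]) == 0:
            logger.warning("layer %r has zero variance on the sample; dropped", name)
        else:
            retained.append(name)
    keep = list(retained)
    for i, a in enumerate(retained):
        if a not in keep:
            continue
        for b in retained[i + 1:]:
            if b not in keep:
                continue
            r = np.corrcoef(data[a], data[b])[0, 1]
            if abs(r) >= threshold:
                logger.info(
                    "dropping %r: |r|=%.3f with %r >= %.2f", b, abs(r), a, threshold
                )
                keep.remove(b)
    return keep


def fit_bioclim(
    occ: OccurrenceSet,
    stack: EnvStack,
    variables: list[str] | None = None,
    trim_percentile: float = 0.0,
) -> EnvelopeModel:
    """Fit the envelope from the training partition's extractions.

    ``trim_percentile`` optionally clips the envelope to the central
    [p, 100-p] percentile band (0 keeps the full min–max envelope).
    """
    if variables is None:
        variables = list(occ.extraction.columns)
    missing = [v for v in variables if v not in stack.layers]
    if missing:
        raise KeyError(f"variables not in stack: {missing}")
    train = occ.subset_extraction("train")
    if train.empty:
        raise ValueError("training partition is empty")
    training: dict[str, np.ndarray] = {}
    for var in variables:
        vals = np.sort(train[var].to_numpy(dtype=float))
        if trim_percentile > 0:
            lo = np.percentile(vals, trim_percentile)
            hi = np.percentile(vals, 100 - trim_percentile)
            vals = vals[(vals >= lo) & (vals <= hi)]
        if vals[0] == vals[-1]:
            logger.warning(
                "variable %r has an all-identical training sample; "
                "envelope degenerates to a point", var,
            )
        training[var] = vals
    units = {v: stack.units.get(v, "") for v in variables}
    return EnvelopeModel(taxon=occ.taxon, training=training, units=units)


def predict_suitability(model: EnvelopeModel, stack: EnvStack) -> np.ndarray:
    """Score every grid cell; nodata cells propagate as the stack's nodata."""
    missing = [v for v in model.variables if v not in stack.layers]
    if missing:
        raise KeyError(f"model variables not in stack: {missing}")
    valid = stack.valid_mask
    out = np.full(stack.shape, stack.nodata, dtype=float)
    score = np.ones(int(valid.sum()), dtype=float)
    for var in model.variables:
        vals = stack.layers[var][valid]
        score = np.minimum(score, model.marginal_score(var, vals))
    out[valid] = score
    return out


def response_curve(
    model: EnvelopeModel, variable: str, n_grid: int = 200
) -> ResponseCurve:
    """Marginal suitability curve over [min - 10% span, max + 10% span]."""
    if variable not in model.training:
        raise KeyError(f"variable {variable!r} not in model")
    lo, hi = model.limits(variable)
    span = hi - lo
    pad = 0.1 * span if span > 0 else max(abs(lo) * 0.1, 1.0)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    # include the exact training values so envelope breakpoints (and the
    # unit score at the median) appear on the curve rather than between
    # evaluation points
    grid = np.union1d(
        grid,
        np.append(model.training[variable], np.median(model.training[variable])),
    )
    scores = np.asarray(model.marginal_score(variable, grid), dtype=float)
    return ResponseCurve(
        variable=variable,
        values=grid,
        scores=scores,
        suitable_range=(lo, hi),
        units=model.units.get(variable, ""),
    )
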