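"""Virtual-species simulation: environmental raster stacks and occurrences.

Real benthic layers (temperature, salinity, current velocity, silicate) and
archived occurrence downloads are large external datasets; this module
generates stand-ins with the two properties the niche model actually
exploits — spatial autocorrelation in the layers and occurrences that
concentrate inside a known environmental envelope — so every downstream
stage can be exercised and checked against a known truth.

Layers are independent white-noise fields smoothed by an isotropic
moving-average kernel and min–max rescaled to a configured range.
Occurrences are drawn from cells whose environment lies inside a
``TrueEnvelope`` with probability ``1 - noise``, and from arbitrary valid
cells with probability ``noise``; records are placed at cell centres so
raster extraction is unambiguous.  Everything is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_formats import DEFAULT_NODATA, EnvStack, GridTransform, OccurrenceTable

__all__ = [
    "TrueEnvelope",
    "SimConfig",
    "DEFAULT_VARIABLES",
    "generate_layers",
    "generate_occurrences",
    "default_true_envelope",
    "true_suitability",
    "morans_i",
]

# The four benthic predictors the niche model uses, with realistic global
# ocean ranges: mean temperature (°C), mean salinity (PSU), mean current
# velocity (m/s), mean silicate concentration (µM).
DEFAULT_VARIABLES: dict[str, tuple[float, float]] = {
    "temperature": (-2.0, 30.0),
    "salinity": (25.0, 41.0),
    "current_velocity": (0.0, 0.5),
    "silicate": (0.0, 200.0),
}

DEFAULT_UNITS: dict[str, str] = {
    "temperature": "degC",
    "salinity": "PSU",
    "current_velocity": "m/s",
    "silicate": "uM",
}


@dataclass(frozen=True)
class TrueEnvelope:
    """Ground-truth per-variable tolerance limits for a virtual species."""

    limits: dict[str, tuple[float, float]]
    optima: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.limits.items():
            if not lo < hi:
                raise ValueError(f"envelope for {var!r}: lower {lo} !< upper {hi}")

    def optimum(self, var: str) -> float:
        lo, hi = self.limits[var]
        return self.optima.get(var, 0.5 * (lo + hi))

    def inside(self, values: dict[str, np.ndarray]) -> np.ndarray:
        """Boolean array: True where every variable is within its limits."""
        first = next(iter(values.values()))
        ok = np.ones(np.shape(first), dtype=bool)
        for var, (lo, hi) in self.limits.items():
            ok &= (values[var] >= lo) & (values[var] <= hi)
        return ok


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic world."""

    shape: tuple[int, int] = (100, 100)
    cell_size: float = 0.1
    variables: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VARIABLES)
    )
    smoothness: int = 5           # moving-average kernel radius, cells
    n_occurrences: int = 200
    noise: float = 0.0            # fraction of records ignoring the envelope
    seed: int = 0
    x_origin: float = -180.0
    y_origin: float = 90.0
    nodata_fraction: float = 0.0  # fraction of cells masked out (land)

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 2 or cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.n_occurrences < 1:
            raise ValueError("n_occurrences must be >= 1")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise rate must lie in [0, 1)")
        for var, (lo, hi) in self.variables.items():
            if lo >= hi:
                raise ValueError(f"degenerate range for {var!r}: [{lo}, {hi}]")


def _smooth_field(rng: np.random.Generator, shape, radius: int) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if radius > 0:
        noise = ndimage.uniform_filter(noise, size=2 * radius + 1, mode="reflect")
    return noise


def generate_layers(config: SimConfig) -> EnvStack:
    """Generate a stack of smoothed random fields, one per variable.

    Each field is rescaled so its min and max hit the configured range
    exactly; the same seed always yields a bit-identical stack.
    """
    rng = np.random.default_rng(config.seed)
    transform = GridTransform(config.x_origin, config.y_origin, config.cell_size)
    mask = np.ones(config.shape, dtype=bool)
    if config.nodata_fraction > 0:
        # contiguous-ish nodata blob built from a thresholded smooth field
        blob = _smooth_field(rng, config.shape, max(config.smoothness, 1))
        cut = np.quantile(blob, config.nodata_fraction)
        mask = blob > cut
    layers: dict[str, np.ndarray] = {}
    for var, (lo, hi) in config.variables.items():
        f = _smooth_field(rng, config.shape, config.smoothness)
        fmin, fmax = f.min(), f.max()
        scaled = lo + (f - fmin) / (fmax - fmin) * (hi - lo)
        scaled[~mask] = DEFAULT_NODATA
        layers[var] = scaled
    return EnvStack(
        layers=layers,
        transform=transform,
        nodata=DEFAULT_NODATA,
        units={v: DEFAULT_UNITS.get(v, "") for v in config.variables},
    )


def default_true_envelope(
    stack: EnvStack, lower_q: float = 0.25, upper_q: float = 0.75
) -> TrueEnvelope:
    """Envelope spanning the central quantile band of each layer.

    A convenient ground truth: wide enough that a joint four-variable
    envelope keeps a workable fraction of cells inside.
    """
    limits = {}
    for name in stack.names:
        vals = stack.layers[name][stack.mask_for(name)]
        limits[name] = (
            float(np.quantile(vals, lower_q)),
            float(np.quantile(vals, upper_q)),
        )
    return TrueEnvelope(limits=limits)


def generate_occurrences(
    stack: EnvStack,
    truth: TrueEnvelope,
    n: int,
    noise: float = 0.0,
    seed: int = 0,
    taxon: str = "virtual_methanogen",
) -> OccurrenceTable:
    """Sample ``n`` occurrence records from the stack.

    Each record comes from a uniformly chosen inside-envelope cell with
    probability ``1 - noise`` and from a uniformly chosen valid cell
    (envelope ignored) with probability ``noise``.  Records sit at cell
    centres; the same (stack, truth, n, noise, seed) always returns the
    same table.
    """
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise rate must lie in [0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    for var in truth.limits:
        if var not in stack.layers:
            raise KeyError(f"envelope variable {var!r} not in stack")
    valid = stack.valid_mask
    values = {v: stack.layers[v] for v in truth.limits}
    inside = truth.inside(values) & valid
    inside_idx = np.flatnonzero(inside.ravel())
    valid_idx = np.flatnonzero(valid.ravel())
    if inside_idx.size == 0:
        raise ValueError("empty niche: no cell satisfies the true envelope")
    rng = np.random.default_rng(seed)
    from_noise = rng.random(n) < noise
    flat = np.where(
        from_noise,
        rng.choice(valid_idx, size=n, replace=True),
        rng.choice(inside_idx, size=n, replace=True),
    )
    ncol = stack.shape[1]
    rows, cols = np.divmod(flat, ncol)
    records = [
        stack.transform.cell_center(int(r), int(c)) for r, c in zip(rows, cols)
    ]
    return OccurrenceTable(taxon=taxon, records=records, source="synthetic")


def true_suitability(stack: EnvStack, truth: TrueEnvelope) -> np.ndarray:
    """Suitability of every cell under the generating envelope.

    Each variable scores 1 at its optimum, falls linearly to 0 at the
    envelope limits and is 0 outside; cells take the weakest variable's
    score (same aggregation rule as the fitted model).  Nodata cells
    propagate the stack's nodata value.  Useful as the known-truth
    reference when evaluating a fitted model.
    """
    valid = stack.valid_mask
    score = np.ones(int(valid.sum()))
    for var, (lo, hi) in truth.limits.items():
        x = stack.layers[var][valid]
        opt = truth.optimum(var)
        up = np.where(opt > lo, (x - lo) / (opt - lo), 1.0)
        down = np.where(hi > opt, (hi - x) / (hi - opt), 1.0)
        s = np.clip(np.minimum(up, down), 0.0, 1.0)
        score = np.minimum(score, s)
    out = np.full(stack.shape, stack.nodata, dtype=float)
    out[valid] = score
    return out


def morans_i(grid: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Moran's I spatial autocorrelation with rook (4-neighbour) adjacency.

    Used to verify that generated layers carry positive spatial structure;
    white noise gives I ≈ -1/(N-1) ≈ 0.
    """
    grid = np.asarray(grid, dtype=float)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    z = np.where(mask, grid - grid[mask].mean(), 0.0)
    m = mask.astype(float)
    num = 0.0
    wsum = 0.0
    # horizontal and vertical neighbour pairs, each counted twice (i->j, j->i)
    num += 2.0 * np.sum(z[:, :-1] * z[:, 1:] * m[:, :-1] * m[:, 1:])
    wsum += 2.0 * np.sum(m[:, :-1] * m[:, 1:])
    num += 2.0 * np.sum(z[:-1, :] * z[1:, :] * m[:-1, :] * m[1:, :])
    wsum += 2.0 * np.sum(m[:-1, :] * m[1:, :])
    n_valid = m.sum()
    denom = np.sum(z[mask] ** 2)
    if denom == 0 or wsum == 0:
        return 0.0
    return float((n_valid / wsum) * (num / denom))
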