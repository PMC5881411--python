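"""Seeded synthetic scenes with the statistical structure the pipeline assumes.

A scene consists of a 3-class truth map with spatial patch structure, a
stratum raster of contiguous bands (standing in for ecozones), K degraded
source maps generated by pushing the truth through per-stratum confusion
matrices (each source with its own alphabet and an optional partial
footprint), and reference/validation point samples with configurable
"not sure" and label-noise rates.

The generator emulates what matters for testing the fusion and validation
machinery — conditionally independent noisy witnesses of a fragmented
landscape, heterogeneous legends, partial coverage, ambiguous labels — and
nothing else: there is no land-cover succession model, no georeferencing
realism, and class semantics are labels only.  Every operation is a pure
function of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .fusion import CLASS_CODES, NOT_SURE, ReferencePoint
from .grid import GridSpec
from .raster import CategoricalRaster, ContinuousRaster
from .validation import ValidationRecord, CLASS_ID_NAMES

TRUTH_NODATA = 0
STRATA_NODATA = 0
SOURCE_NODATA = 0


@dataclass(frozen=True)
class SourceSpec:
    """One simulated source map.

    ``confusion`` maps truth class (row, ordered arable/abandoned/other) to a
    distribution over the source's own classes; either a single (3, m) matrix
    used in every stratum or one matrix per stratum.  ``coverage`` is the
    fraction of the grid inside the source footprint.  Continuous sources
    must have m = 2 (columns: not-cropland-like, cropland-like); they emit a
    noisy percentage instead of a class code.
    """

    name: str
    confusion: tuple  # (3, m) rows or per-stratum tuple of such
    coverage: float = 1.0
    kind: str = "categorical"
    noise_sd: float = 10.0  # percentage-point blur for continuous sources

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError("source kind must be 'categorical' or 'continuous'")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must lie in [0, 1]")

    def matrix_for(self, stratum_index: int, n_strata: int) -> np.ndarray:
        m = np.asarray(self.confusion, dtype=float)
        if m.ndim == 3:
            if m.shape[0] != n_strata:
                raise ValueError(
                    f"source {self.name!r}: {m.shape[0]} confusion matrices "
                    f"for {n_strata} strata"
                )
            m = m[stratum_index]
        if m.ndim != 2 or m.shape[0] != 3:
            raise ValueError(f"source {self.name!r}: confusion must be (3, m)")
        if np.abs(m.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError(f"source {self.name!r}: confusion rows must sum to 1")
        if self.kind == "continuous" and m.shape[1] != 2:
            raise ValueError("continuous sources need a 2-column confusion matrix")
        return m

    @property
    def n_classes(self) -> int:
        m = np.asarray(self.confusion, dtype=float)
        return m.shape[-1]


def _diag_confusion(accuracy: float, n: int = 3) -> tuple:
    """Confusion with ``accuracy`` on the diagonal, errors spread uniformly."""
    off = (1.0 - accuracy) / (n - 1)
    m = np.full((n, n), off)
    np.fill_diagonal(m, accuracy)
    return tuple(tuple(float(x) for x in row) for row in m)


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic scene; see the module docstring."""

    grid: GridSpec = GridSpec(10.0, 30.0, 55.0, 300, 300)
    n_strata: int = 3
    class_proportions: tuple = (0.3, 0.2, 0.5)  # single tuple or per-stratum
    patch_scale: float = 6.0  # autocorrelation length, cells
    sources: tuple[SourceSpec, ...] = (
        SourceSpec("global-lc", _diag_confusion(0.85)),
        SourceSpec("regional-abandonment", _diag_confusion(0.80)),
        SourceSpec("cropland-2010", _diag_confusion(0.75)),
        SourceSpec("epoch-change", _diag_confusion(0.70)),
    )
    n_reference: int = 5000
    n_validation: int = 1500
    not_sure_rate: float = 0.05
    label_noise: float = 0.0
    seed: int = 42

    def proportions_for(self, stratum_index: int) -> np.ndarray:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.ndim == 2:
            p = p[stratum_index]
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must be 3 values summing to 1")
        return p

    def __post_init__(self):
        if self.n_strata < 1:
            raise ValueError("need at least one stratum")
        if not (0.0 <= self.not_sure_rate < 1.0):
            raise ValueError("not_sure_rate must lie in [0, 1)")
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError("label_noise must lie in [0, 1)")
        for i in range(self.n_strata):
            self.proportions_for(i)


@dataclass
class SimScene:
    """A generated scene: truth, strata, sources and point samples."""

    config: SimConfig
    truth: CategoricalRaster
    strata: CategoricalRaster
    sources: list
    reference: list[ReferencePoint]
    validation: list[ValidationRecord]


def _strata_bands(grid: GridSpec, n_strata: int) -> CategoricalRaster:
    """Contiguous vertical bands of near-equal width, codes 1..n_strata."""
    cols = np.arange(grid.n_cols)
    band = np.minimum(n_strata - 1, (cols * n_strata) // grid.n_cols) + 1
    codes = np.broadcast_to(band, grid.shape).astype(np.int64).copy()
    return CategoricalRaster(
        grid, codes, STRATA_NODATA, tuple(range(1, n_strata + 1)), "sim-strata"
    )


def generate_truth(config: SimConfig) -> tuple[CategoricalRaster, CategoricalRaster]:
    """Truth map with patch structure plus the stratum raster.

    Gaussian-smoothed white noise at ``patch_scale`` is quantile-mapped to
    classes within each stratum, so realized per-stratum class proportions
    track the configured ones to within the granularity of the quantiles
    (a fraction of a percentage point on grids of 200x200 and larger).
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    strata = _strata_bands(grid, config.n_strata)
    noise = ndimage.gaussian_filter(
        rng.standard_normal(grid.shape), sigma=config.patch_scale, mode="reflect"
    )
    codes = np.zeros(grid.shape, dtype=np.int64)
    for s in range(config.n_strata):
        sel = strata.codes == s + 1
        p = config.proportions_for(s)
        vals = noise[sel]
        # rank-based assignment: lowest p1 mass -> class 1, next p2 -> class
        # 2, rest -> 3; realized proportions are exact to one cell
        order = np.argsort(vals, kind="stable")
        cut1 = int(round(p[0] * vals.size))
        cut2 = int(round((p[0] + p[1]) * vals.size))
        cls = np.empty(vals.size, dtype=np.int64)
        cls[order[:cut1]] = 1
        cls[order[cut1:cut2]] = 2
        cls[order[cut2:]] = 3
        codes[sel] = cls
    truth = CategoricalRaster(grid, codes, TRUTH_NODATA, CLASS_CODES, "sim-truth")
    return truth, strata


def _footprint(grid: GridSpec, coverage: float, rng: np.random.Generator) -> np.ndarray:
    """Random union of rectangles covering ~``coverage`` of the grid (±5%)."""
    if coverage >= 1.0:
        return np.ones(grid.shape, bool)
    mask = np.zeros(grid.shape, bool)
    if coverage <= 0.0:
        return mask
    # rectangle area ~2% of the grid so the last addition overshoots little
    side_r = max(1, int(np.sqrt(0.02) * grid.n_rows))
    side_c = max(1, int(np.sqrt(0.02) * grid.n_cols))
    target = coverage * grid.n_cells
    for _ in range(100000):
        if mask.sum() >= target:
            break
        r = rng.integers(0, max(1, grid.n_rows - side_r + 1))
        c = rng.integers(0, max(1, grid.n_cols - side_c + 1))
        mask[r : r + side_r, c : c + side_c] = True
    return mask


def degrade(
    truth: CategoricalRaster,
    strata: CategoricalRaster,
    source: SourceSpec,
    seed: int,
):
    """Simulate one source map: per-cell reading drawn from the confusion row
    of the cell's truth class in its stratum, nodata outside the footprint.

    Continuous sources report 100 * (reading is the cropland-like class)
    blurred with Gaussian noise of ``noise_sd`` percentage points, clipped to
    [0, 100].
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    n_strata = len(strata.alphabet)
    m = source.n_classes

    u = rng.random(grid.shape)
    reported = np.zeros(grid.shape, dtype=np.int64)
    for s in range(n_strata):
        conf = source.matrix_for(s, n_strata)
        cum = np.cumsum(conf, axis=1)
        for g in CLASS_CODES:
            sel = (strata.codes == s + 1) & (truth.codes == g)
            if not sel.any():
                continue
            reported[sel] = np.searchsorted(cum[g - 1], u[sel], side="right") + 1
    reported = np.clip(reported, 1, m)

    footprint = _footprint(grid, source.coverage, rng)

    if source.kind == "continuous":
        pct = 100.0 * (reported == 2).astype(float)
        pct += rng.normal(0.0, source.noise_sd, grid.shape)
        pct = np.clip(pct, 0.0, 100.0)
        values = np.where(footprint, pct, -1.0)
        return ContinuousRaster(grid, values, nodata_value=-1.0)

    codes = np.where(footprint, reported, SOURCE_NODATA)
    return CategoricalRaster(
        grid, codes, SOURCE_NODATA, tuple(range(1, m + 1)), source.name
    )


def sample_reference(
    truth: CategoricalRaster,
    n: int,
    not_sure_rate: float = 0.0,
    label_noise: float = 0.0,
    seed: int = 42,
    exclude_cells: np.ndarray | None = None,
) -> list[ReferencePoint]:
    """Simple random sample of cells without replacement, labelled from truth.

    With probability ``not_sure_rate`` a point is labelled NOT_SURE; otherwise
    with probability ``label_noise`` it gets a uniformly chosen wrong class.
    ``exclude_cells`` (flat indices) are never sampled.
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    pool = np.arange(grid.n_cells)
    if exclude_cells is not None:
        pool = np.setdiff1d(pool, exclude_cells, assume_unique=False)
    if n > pool.size:
        raise ValueError(f"requested {n} points from {pool.size} available cells")
    cells = rng.choice(pool, size=n, replace=False)
    rows, cols = np.divmod(cells, grid.n_cols)
    lon, lat = grid.cell_center(rows, cols)
    labels = truth.codes[rows, cols].astype(np.int64)

    u = rng.random(n)
    to_not_sure = u < not_sure_rate
    to_noise = (~to_not_sure) & (u < not_sure_rate + label_noise)
    for i in np.flatnonzero(to_noise):
        others = [c for c in CLASS_CODES if c != labels[i]]
        labels[i] = others[rng.integers(0, len(others))]
    labels[to_not_sure] = NOT_SURE

    return [
        ReferencePoint(id=i, lon=float(lon[i]), lat=float(lat[i]), label=int(labels[i]))
        for i in range(n)
    ]


def _ambiguous_code(true_class: int, other: int) -> int:
    a, b = sorted((true_class, other))
    return a * 10 + b


def sample_validation(
    truth: CategoricalRaster,
    n: int,
    not_sure_rate: float = 0.0,
    label_noise: float = 0.0,
    seed: int = 43,
    exclude_cells: np.ndarray | None = None,
) -> list[ValidationRecord]:
    """Validation records: like reference sampling, but ambiguity is encoded
    as a paired code (12/13/23) combining the true class with a uniformly
    chosen other class, instead of a bare NOT_SURE."""
    rng = np.random.default_rng(seed)
    grid = truth.grid
    pool = np.arange(grid.n_cells)
    if exclude_cells is not None:
        pool = np.setdiff1d(pool, exclude_cells, assume_unique=False)
    if n > pool.size:
        raise ValueError(f"requested {n} points from {pool.size} available cells")
    cells = rng.choice(pool, size=n, replace=False)
    rows, cols = np.divmod(cells, grid.n_cols)
    lon, lat = grid.cell_center(rows, cols)
    labels = truth.codes[rows, cols].astype(np.int64)

    u = rng.random(n)
    records = []
    for i in range(n):
        cls = int(labels[i])
        if u[i] < not_sure_rate:
            others = [c for c in CLASS_CODES if c != cls]
            cls = _ambiguous_code(cls, others[rng.integers(0, len(others))])
        elif u[i] < not_sure_rate + label_noise:
            others = [c for c in CLASS_CODES if c != cls]
            cls = others[rng.integers(0, len(others))]
        records.append(
            ValidationRecord(
                id=i,
                lat=float(lat[i]),
                lon=float(lon[i]),
                class_id=cls,
                class_name=CLASS_ID_NAMES[cls],
            )
        )
    return records


def make_scene(config: SimConfig) -> SimScene:
    """Compose a full scene; reference and validation cells are disjoint."""
    truth, strata = generate_truth(config)
    ss = np.random.SeedSequence(config.seed)
    src_seeds = ss.spawn(len(config.sources))
    sources = [
        degrade(truth, strata, spec, int(s.generate_state(1)[0] % (2**31)))
        for spec, s in zip(config.sources, src_seeds)
    ]
    ref_seed = config.seed + 1_000_003
    val_seed = config.seed + 2_000_003
    reference = sample_reference(
        truth, config.n_reference, config.not_sure_rate, config.label_noise, ref_seed
    )
    ref_cells = np.array(
        [truth.grid.locate(p.lon, p.lat) for p in reference], dtype=np.int64
    )
    ref_flat = ref_cells[:, 0] * truth.grid.n_cols + ref_cells[:, 1]
    validation = sample_validation(
        truth,
        config.n_validation,
        config.not_sure_rate,
        config.label_noise,
        val_seed,
        exclude_cells=ref_flat,
    )
    return SimScene(config, truth, strata, list(sources), reference, validation)


def default_config(**overrides) -> SimConfig:
    """The default study scene: 300x300 grid, 3 strata, 4 conditionally
    independent sources with per-class accuracies 0.70-0.85, 5,000 reference
    points and a 5% "not sure" rate."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()
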