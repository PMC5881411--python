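"""Naive Bayes fusion of harmonized land-cover sources.

The model: let G be the true land use of a cell, one of three classes
(1 arable, 2 abandoned, 3 other), and S_1..S_K the readings of the K source
maps at that cell, each in its own class alphabet.  Assuming the sources are
conditionally independent given the truth,

    Pr(G = g | S_1..S_K) ∝ Pr(g) * Π_k Pr(S_k | G = g),

normalized over g.  Sources with no coverage at a cell simply drop out of
the product: because each conditional row sums to one, omitting a factor is
exactly marginalizing the joint over that source's possible readings.

Conditional tables Pr(S_k = c | G = g) are estimated per stratum (ecozone)
from contingency tables of reference points against each source, because the
land cover that follows abandonment differs across ecozones; sparse strata
fall back to the pooled all-strata table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .grid import GridSpec
from .raster import AlignmentError, CategoricalRaster, MapStack


class LandUseClass(IntEnum):
    """Legend of the fused product."""

    ARABLE = 1
    ABANDONED = 2
    OTHER = 3


CLASS_CODES = tuple(int(c) for c in LandUseClass)
CLASS_NAMES = {1: "arable land", 2: "abandoned land", 3: "other land"}

#: Sentinel label for reference points the interpreter could not classify.
NOT_SURE = 0

#: Sentinel for a missing source reading in ``posterior_cell``.
MISSING = None

FUSED_NODATA = 0


@dataclass(frozen=True)
class ReferencePoint:
    """A visually interpreted training point."""

    id: int
    lon: float
    lat: float
    label: int  # 1, 2, 3 or NOT_SURE

    def __post_init__(self):
        if self.label not in (NOT_SURE, *CLASS_CODES):
            raise ValueError(f"reference label must be 1, 2, 3 or {NOT_SURE} (not sure)")


def uniform_prior() -> np.ndarray:
    """Equal prior over the three classes (exactly 1/3 each)."""
    return np.full(3, 1.0 / 3.0)


def _check_prior(prior: np.ndarray) -> np.ndarray:
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (3,) or (prior < 0).any() or abs(prior.sum() - 1.0) > 1e-12:
        raise ValueError("prior must be 3 non-negative probabilities summing to 1")
    return prior


@dataclass
class ConditionalTable:
    """Pr(source reports c | truth g) for one (stratum, source) pair."""

    alphabet: tuple[int, ...]
    probs: np.ndarray  # shape (3, len(alphabet)); rows sum to 1
    support: np.ndarray  # raw contingency counts, same shape
    pooled_fallback: bool = False

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.support = np.asarray(self.support, dtype=float)
        if self.probs.shape != (3, len(self.alphabet)):
            raise ValueError("conditional table shape must be (3, |alphabet|)")
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise ValueError("conditional probabilities must lie in [0, 1]")
        rows = self.probs.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-9:
            raise ValueError(f"conditional rows must sum to 1, got {rows}")

    def column(self, code: int) -> np.ndarray:
        """Pr(code | g) for each truth class g — one factor of the product."""
        try:
            j = self.alphabet.index(int(code))
        except ValueError:
            raise KeyError(
                f"reading {code} outside source alphabet {self.alphabet}"
            ) from None
        return self.probs[:, j]


@dataclass
class ConditionalTableSet:
    """Per-stratum, per-source conditional tables plus the pooled tables."""

    source_names: list[str]
    alphabets: list[tuple[int, ...]]
    tables: dict[int, list[ConditionalTable]]  # stratum id -> one table per source
    pooled: list[ConditionalTable] = field(default_factory=list)

    def for_stratum(self, stratum: int) -> list[ConditionalTable]:
        try:
            return self.tables[int(stratum)]
        except KeyError:
            raise KeyError(
                f"no conditional tables for stratum {stratum}; known strata: "
                f"{sorted(self.tables)}"
            ) from None

    @property
    def strata(self) -> list[int]:
        return sorted(self.tables)


class EstimationError(ValueError):
    """Conditional tables cannot be estimated from the given reference data."""


def _rows_to_probs(counts: np.ndarray, smoothing: float, n_classes: int,
                   pooled_probs: np.ndarray | None) -> np.ndarray:
    """Normalize contingency rows with additive smoothing.

    A row with zero total at smoothing 0 has no defined distribution; it falls
    back to the pooled row for that truth class, or uniform if that is empty too.
    """
    probs = np.empty((3, n_classes), dtype=float)
    for g in range(3):
        total = counts[g].sum()
        denom = total + smoothing * n_classes
        if denom > 0:
            probs[g] = (counts[g] + smoothing) / denom
        elif pooled_probs is not None:
            probs[g] = pooled_probs[g]
        else:
            probs[g] = 1.0 / n_classes
    return probs


def fit_conditionals(
    stack: MapStack,
    reference: list[ReferencePoint],
    strata: CategoricalRaster,
    smoothing: float = 0.0,
    min_support: int = 30,
) -> ConditionalTableSet:
    """Estimate Pr(S_k = c | G = g) per stratum from reference points.

    Contingency counts cross-tabulate each source's reading against the
    reference label at the reference locations.  "Not sure" points are
    excluded; points where a source has no coverage contribute nothing to
    that source's table.  A (stratum, source) table whose total support falls
    below ``min_support`` is replaced by the pooled all-strata table and
    flagged.

    Probabilities use additive smoothing:
    Pr(c|g) = (n_gc + s) / (n_g. + s*|alphabet|); the default s=0 reproduces
    raw contingency proportions, including exact zeros.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    if not reference:
        raise EstimationError("reference point set is empty")
    if not strata.grid.same_grid(stack.grid):
        raise AlignmentError("stratum raster is not on the stack grid")

    labeled = [p for p in reference if p.label != NOT_SURE]
    if not labeled:
        raise EstimationError("all reference points are 'not sure'")

    lons = np.array([p.lon for p in labeled])
    lats = np.array([p.lat for p in labeled])
    rows, cols = stack.grid.locate(lons, lats)
    inside = (rows >= 0) & (cols >= 0)
    if not inside.all():
        raise EstimationError(
            f"{(~inside).sum()} reference points fall outside the analysis extent"
        )
    g_idx = np.array([p.label for p in labeled]) - 1  # 0..2

    strat_codes = strata.codes[rows, cols]
    strat_valid = strat_codes != strata.nodata_code
    if not strat_valid.any():
        raise EstimationError("no reference point falls in a cell with a stratum id")
    stratum_ids = sorted(int(s) for s in np.unique(strat_codes[strat_valid]))

    alphabets = [layer.alphabet for layer in stack.layers]
    counts: dict[int, list[np.ndarray]] = {
        e: [np.zeros((3, len(a))) for a in alphabets] for e in stratum_ids
    }
    pooled_counts = [np.zeros((3, len(a))) for a in alphabets]

    for k, layer in enumerate(stack.layers):
        readings = layer.codes[rows, cols]
        covered = readings != layer.nodata_code
        code_to_col = {c: j for j, c in enumerate(layer.alphabet)}
        for i in np.flatnonzero(covered & strat_valid):
            j = code_to_col[int(readings[i])]
            counts[int(strat_codes[i])][k][g_idx[i], j] += 1
        for i in np.flatnonzero(covered):
            pooled_counts[k][g_idx[i], code_to_col[int(readings[i])]] += 1

    pooled_tables = []
    for k, a in enumerate(alphabets):
        probs = _rows_to_probs(pooled_counts[k], smoothing, len(a), None)
        pooled_tables.append(ConditionalTable(a, probs, pooled_counts[k]))

    tables: dict[int, list[ConditionalTable]] = {}
    for e in stratum_ids:
        per_source = []
        for k, a in enumerate(alphabets):
            c = counts[e][k]
            if c.sum() < min_support:
                per_source.append(
                    ConditionalTable(
                        a, pooled_tables[k].probs.copy(), c, pooled_fallback=True
                    )
                )
            else:
                probs = _rows_to_probs(c, smoothing, len(a), pooled_tables[k].probs)
                per_source.append(ConditionalTable(a, probs, c))
        tables[e] = per_source

    return ConditionalTableSet(list(stack.names), alphabets, tables, pooled_tables)


def posterior_cell(
    readings: list[int | None],
    tables: list[ConditionalTable],
    prior: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Posterior class probabilities for one cell.

    ``readings[k]`` is source k's class code at the cell, or ``None`` when the
    source has no coverage there (the factor is then omitted).  Returns the
    3-vector of probabilities and a degeneracy flag: when every class gets
    zero likelihood the posterior falls back to the prior and the flag is set.
    """
    prior = uniform_prior() if prior is None else _check_prior(prior)
    if len(readings) != len(tables):
        raise ValueError("one reading (or None) required per source table")
    num = prior.copy()
    for k, (code, table) in enumerate(zip(readings, tables)):
        if code is MISSING:
            continue
        try:
            num = num * table.column(code)
        except KeyError as e:
            raise KeyError(f"source {k}: {e.args[0]}") from None
    denom = num.sum()
    if denom <= 0.0:
        return prior.copy(), True
    return num / denom, False


@dataclass
class PosteriorRaster:
    """Per-cell class probabilities plus a degenerate-cell flag plane."""

    grid: GridSpec
    probs: np.ndarray  # shape (3, n_rows, n_cols); NaN where no stratum
    degenerate: np.ndarray  # bool plane: likelihood was zero, prior used
    valid: np.ndarray  # bool plane: cell has a stratum id

    def __post_init__(self):
        if self.probs.shape != (3, *self.grid.shape):
            raise ValueError("posterior needs 3 probability planes on the grid")


def fuse(
    stack: MapStack,
    tables: ConditionalTableSet,
    prior: np.ndarray | None = None,
    strata: CategoricalRaster | None = None,
) -> PosteriorRaster:
    """Apply the per-stratum Naive Bayes posterior to every cell of the stack.

    Vectorized per (stratum, source): each source contributes a multiplicative
    plane looked up from its conditional table; uncovered cells contribute
    nothing.  Cells without a stratum id are invalid (NaN) in the output.
    """
    prior = uniform_prior() if prior is None else _check_prior(prior)
    if strata is None:
        only = tables.strata
        if len(only) != 1:
            raise ValueError("strata raster required when tables span multiple strata")
        strat_codes = np.full(stack.grid.shape, only[0])
        valid = np.ones(stack.grid.shape, bool)
    else:
        if not strata.grid.same_grid(stack.grid):
            raise AlignmentError("stratum raster is not on the stack grid")
        strat_codes = strata.codes
        valid = strata.mask

    shape = stack.grid.shape
    num = np.zeros((3, *shape))
    num[:] = prior[:, None, None]

    for e in np.unique(strat_codes[valid]):
        e_tables = tables.for_stratum(int(e))  # raises for unknown stratum
        in_e = valid & (strat_codes == e)
        for layer, table in zip(stack.layers, e_tables):
            covered = in_e & layer.mask
            if not covered.any():
                continue
            # lookup Pr(code|g) via a dense LUT over the code range
            codes = layer.codes[covered]
            lut = np.zeros((3, max(layer.alphabet) + 1))
            for j, c in enumerate(layer.alphabet):
                lut[:, c] = table.probs[:, j]
            num[:, covered] *= lut[:, codes]

    denom = num.sum(axis=0)
    degenerate = valid & (denom <= 0.0)
    probs = np.full((3, *shape), np.nan)
    ok = valid & ~degenerate
    probs[:, ok] = num[:, ok] / denom[ok]
    probs[:, degenerate] = prior[:, None]
    return PosteriorRaster(stack.grid, probs, degenerate, valid)


def classify(posterior: PosteriorRaster, nodata_code: int = FUSED_NODATA) -> CategoricalRaster:
    """Argmax land-use map from a posterior; ties break to the smallest code.

    Degenerate and no-stratum cells become nodata.
    """
    codes = np.full(posterior.grid.shape, nodata_code, dtype=np.int64)
    ok = posterior.valid & ~posterior.degenerate
    # np.argmax returns the first maximum -> smallest class code on ties
    codes[ok] = np.argmax(posterior.probs[:, ok], axis=0) + 1
    return CategoricalRaster(
        posterior.grid, codes, nodata_code, CLASS_CODES, legend_id="fused-land-use"
    )
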