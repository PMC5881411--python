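"""Stratified map validation and error-adjusted area estimation.

Implements the good-practice workflow for assessing a thematic map with a
stratified random reference sample: build a confusion matrix between mapped
and reference class, convert it to area-weighted cell proportions
p_ij = W_i * n_ij / n_i., and report overall, user's and producer's accuracy
together with error-adjusted class areas and their standard errors.

Two departures from the textbook integer case, both required by the
reference-label protocol used here:

* ambiguous "not sure between X and Y" reference labels contribute 0.5 to
  each of the two candidate reference columns, so confusion cells are
  real-valued;
* the variance estimators treat those fractional counts as real-valued n_ij
  (the natural plug-in extension; the sampling design is unchanged).

Uncertainty is reported as 95% confidence half-widths (1.96 x SE); raw
standard errors are exposed alongside.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import CLASS_CODES, CLASS_NAMES
from .raster import AlignmentError, CategoricalRaster

logger = logging.getLogger(__name__)

#: Reference Class_id codes: pure classes and "not sure between x and y".
AMBIGUOUS_SPLIT = {12: (1, 2), 13: (1, 3), 23: (2, 3)}
VALID_CLASS_IDS = (1, 2, 3, 12, 13, 23)

CLASS_ID_NAMES = {
    1: "arable land",
    2: "abandoned land",
    3: "other land",
    12: "can be either arable or abandoned land",
    13: "can be either arable or other land",
    23: "can be either abandoned land or other land",
}

Z95 = 1.96


@dataclass(frozen=True)
class ValidationRecord:
    """One visually interpreted validation point (Table-5-style record)."""

    id: int
    lat: float
    lon: float
    class_id: int
    class_name: str = ""

    def __post_init__(self):
        if self.class_id not in VALID_CLASS_IDS:
            raise ValueError(
                f"Class_id must be one of {VALID_CLASS_IDS}, got {self.class_id}"
            )


@dataclass
class FractionalConfusion:
    """Real-valued 3x3 confusion matrix; rows mapped class, columns reference."""

    matrix: np.ndarray
    region: int = 0
    n_discarded: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if (self.matrix < 0).any():
            raise ValueError("confusion cells must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        """Sample count per mapped class, n_i."""
        return self.matrix.sum(axis=1)

    @property
    def total_mass(self) -> float:
        return float(self.matrix.sum())


def allocate_sample(
    fused: CategoricalRaster,
    regions: CategoricalRaster,
    sizes: dict[tuple[int, int], int],
    seed: int = 42,
) -> pd.DataFrame:
    """Two-step stratified random sample of cells: by region, then mapped class.

    ``sizes`` maps (region code, mapped class code) to a sample size; simple
    random sampling without replacement within each stratum.  Returns a frame
    with cell indices, cell-center coordinates and the stratum labels, in a
    deterministic order for a fixed seed.
    """
    if not regions.grid.same_grid(fused.grid):
        raise AlignmentError("region raster is not on the fused map grid")
    rng = np.random.default_rng(seed)
    region_codes = regions.codes.ravel()
    map_codes = fused.codes.ravel()
    out = []
    for (region, cls), n in sorted(sizes.items()):
        if n < 0:
            raise ValueError(f"negative sample size for stratum {(region, cls)}")
        if n == 0:
            continue
        pool = np.flatnonzero((region_codes == region) & (map_codes == cls))
        if n > pool.size:
            raise ValueError(
                f"requested {n} samples from stratum (region={region}, "
                f"class={cls}) with only {pool.size} cells"
            )
        chosen = rng.choice(pool, size=n, replace=False)
        rows, cols = np.divmod(chosen, fused.grid.n_cols)
        lon, lat = fused.grid.cell_center(rows, cols)
        out.append(
            pd.DataFrame(
                {
                    "row": rows,
                    "col": cols,
                    "lat": lat,
                    "lon": lon,
                    "region": region,
                    "mapped_class": cls,
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["row", "col", "lat", "lon", "region", "mapped_class"]
        )
    return pd.concat(out, ignore_index=True)


def build_confusion(
    fused: CategoricalRaster,
    records: list[ValidationRecord],
    regions: CategoricalRaster | None = None,
) -> dict[int, FractionalConfusion]:
    """Fractional confusion matrices from validation records, per region.

    An unambiguous record adds 1.0 at (mapped, reference); a "not sure
    between x and y" record adds 0.5 at (mapped, x) and 0.5 at (mapped, y),
    so total mass always equals the number of scored records.  Records on
    nodata map cells are skipped with a warning and counted in
    ``n_discarded``.
    """
    if regions is not None and not regions.grid.same_grid(fused.grid):
        raise AlignmentError("region raster is not on the fused map grid")
    matrices: dict[int, np.ndarray] = {}
    discarded: dict[int, int] = {}
    for rec in records:
        row, col = fused.grid.locate(rec.lon, rec.lat)
        row, col = int(row), int(col)
        region = 0
        if regions is not None and row >= 0 and col >= 0:
            region = int(regions.codes[row, col])
        m = matrices.setdefault(region, np.zeros((3, 3)))
        if row < 0 or col < 0 or fused.codes[row, col] == fused.nodata_code:
            logger.warning(
                "validation record %s at (%.5f, %.5f) falls on nodata; skipped",
                rec.id, rec.lat, rec.lon,
            )
            discarded[region] = discarded.get(region, 0) + 1
            continue
        i = int(fused.codes[row, col]) - 1
        if rec.class_id in AMBIGUOUS_SPLIT:
            a, b = AMBIGUOUS_SPLIT[rec.class_id]
            m[i, a - 1] += 0.5
            m[i, b - 1] += 0.5
        else:
            m[i, rec.class_id - 1] += 1.0
    return {
        region: FractionalConfusion(m, region, discarded.get(region, 0))
        for region, m in sorted(matrices.items())
    }


def map_class_weights(
    fused: CategoricalRaster, regions: CategoricalRaster | None = None, region: int = 0
) -> np.ndarray:
    """Mapped-class area proportions W_i within a region (nodata excluded)."""
    sel = fused.mask
    if regions is not None:
        sel = sel & (regions.codes == region)
    counts = np.array([(fused.codes[sel] == c).sum() for c in CLASS_CODES], float)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"region {region} contains no mapped cells")
    return counts / total


@dataclass
class AccuracyReport:
    """Overall, user's and producer's accuracy, in percent, with 95% CIs."""

    overall: float
    overall_se: float
    users: np.ndarray
    users_se: np.ndarray
    producers: np.ndarray
    producers_se: np.ndarray
    region: int = 0

    @property
    def overall_ci(self) -> float:
        return Z95 * self.overall_se

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": CLASS_NAMES[c],
                "users_pct": self.users[i],
                "users_ci95": Z95 * self.users_se[i],
                "producers_pct": self.producers[i],
                "producers_ci95": Z95 * self.producers_se[i],
            }
            for i, c in enumerate(CLASS_CODES)
        ]
        return pd.DataFrame(rows)


def _cell_proportions(confusion: FractionalConfusion, weights: np.ndarray):
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (3,) or (weights < 0).any():
        raise ValueError("weights must be 3 non-negative proportions")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {weights.sum()}")
    n = confusion.matrix
    n_i = confusion.row_totals
    p = np.zeros((3, 3))
    nz = n_i > 0
    p[nz] = weights[nz, None] * n[nz] / n_i[nz, None]
    # strata with W>0 but no samples cannot be estimated
    if ((weights > 0) & ~nz).any():
        missing = [CLASS_NAMES[CLASS_CODES[i]] for i in np.flatnonzero((weights > 0) & ~nz)]
        logger.warning("no validation samples for mapped class(es): %s", missing)
    return p, n, n_i


def accuracy_report(
    confusion: FractionalConfusion, weights: np.ndarray
) -> AccuracyReport:
    """Stratified accuracy estimates from a (possibly fractional) confusion.

    With p_ij = W_i n_ij / n_i.:
      overall    OA  = sum_i p_ii
      user's     U_i = n_ii / n_i.
      producer's P_j = p_jj / sum_i p_ij

    Standard errors use the stratified estimators for a sample stratified by
    mapped class, with fractional counts entering as real-valued n_ij:
      V(OA)  = sum_i W_i^2 U_i (1 - U_i) / (n_i. - 1)
      V(U_i) = U_i (1 - U_i) / (n_i. - 1)
      V(P_j) combines the commission variance of stratum j with the omission
      contributions of the other strata.

    Mapped classes with zero samples get NaN user's accuracy and are warned
    about.  All outputs are percentages.
    """
    p, n, n_i = _cell_proportions(confusion, weights)
    weights = np.asarray(weights, dtype=float)

    overall = p.trace()
    users = np.full(3, np.nan)
    users_se = np.full(3, np.nan)
    nz = n_i > 0
    users[nz] = np.diag(n)[nz] / n_i[nz]
    var_u = np.zeros(3)
    df_ok = n_i > 1
    var_u[df_ok] = users[df_ok] * (1 - users[df_ok]) / (n_i[df_ok] - 1)
    users_se[nz] = np.sqrt(var_u[nz])

    var_oa = np.nansum(weights[df_ok] ** 2 * var_u[df_ok])
    overall_se = float(np.sqrt(var_oa))

    p_dot_j = p.sum(axis=0)
    producers = np.full(3, np.nan)
    producers_se = np.full(3, np.nan)
    for j in range(3):
        if p_dot_j[j] <= 0:
            continue
        producers[j] = p[j, j] / p_dot_j[j]
        if not nz[j]:
            continue
        # estimated fraction of the region truly class j
        N_hat_j = p_dot_j[j]
        term_j = 0.0
        if n_i[j] > 1:
            term_j = (
                weights[j] ** 2
                * (1 - producers[j]) ** 2
                * users[j]
                * (1 - users[j])
                / (n_i[j] - 1)
            )
        term_others = 0.0
        for i in range(3):
            if i == j or n_i[i] <= 1:
                continue
            q = n[i, j] / n_i[i]
            term_others += weights[i] ** 2 * q * (1 - q) / (n_i[i] - 1)
        producers_se[j] = np.sqrt(
            (term_j + producers[j] ** 2 * term_others) / N_hat_j**2
        )

    return AccuracyReport(
        overall=100.0 * overall,
        overall_se=100.0 * overall_se,
        users=100.0 * users,
        users_se=100.0 * users_se,
        producers=100.0 * producers,
        producers_se=100.0 * producers_se,
        region=confusion.region,
    )


@dataclass
class AreaEstimate:
    """Mapped vs. error-adjusted class areas with 95% confidence half-widths."""

    mapped_area: np.ndarray
    adjusted_area: np.ndarray
    ci95: np.ndarray
    total_area: float
    region: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": [CLASS_NAMES[c] for c in CLASS_CODES],
                "mapped_area": self.mapped_area,
                "adjusted_area": self.adjusted_area,
                "ci95": self.ci95,
            }
        )


def adjusted_areas(
    confusion: FractionalConfusion,
    weights: np.ndarray,
    total_area: float,
) -> AreaEstimate:
    """Error-adjusted class areas with 95% confidence intervals.

    The adjusted proportion of reference class j is the column total of the
    cell proportions, p_.j = sum_i W_i n_ij / n_i., with standard error

        SE(p_.j) = sqrt( sum_i W_i^2 (n_ij/n_i.)(1 - n_ij/n_i.) / (n_i. - 1) )

    and the adjusted area is total_area * p_.j with half-width
    1.96 * total_area * SE.
    """
    p, n, n_i = _cell_proportions(confusion, weights)
    weights = np.asarray(weights, dtype=float)
    p_dot_j = p.sum(axis=0)

    var = np.zeros(3)
    for j in range(3):
        for i in range(3):
            if n_i[i] <= 1:
                continue
            q = n[i, j] / n_i[i]
            var[j] += weights[i] ** 2 * q * (1 - q) / (n_i[i] - 1)
    se = np.sqrt(var)

    return AreaEstimate(
        mapped_area=total_area * weights,
        adjusted_area=total_area * p_dot_j,
        ci95=Z95 * total_area * se,
        total_area=total_area,
        region=confusion.region,
    )


def change_summary(
    map_t1: CategoricalRaster, map_t2: CategoricalRaster, class_code: int
) -> tuple[float, float]:
    """Two-epoch loss/gain percentages for one class.

    loss = cells holding the class at t1 but not t2; gain = cells holding it
    at t2 but not t1; both as a percentage of the class extent at t1.  When
    the class is absent at t1 the denominator falls back to the total number
    of cells mapped at both epochs (and loss is then 0 by construction).
    """
    if not map_t1.grid.same_grid(map_t2.grid):
        raise AlignmentError("the two epoch maps are not on the same grid")
    both = map_t1.mask & map_t2.mask
    at_t1 = both & (map_t1.codes == class_code)
    at_t2 = both & (map_t2.codes == class_code)
    denom = at_t1.sum()
    if denom == 0:
        denom = both.sum()
        if denom == 0:
            return 0.0, 0.0
    loss = 100.0 * (at_t1 & ~at_t2).sum() / denom
    gain = 100.0 * (at_t2 & ~at_t1).sum() / denom
    return float(loss), float(gain)


def format_report(report: AccuracyReport, areas: AreaEstimate | None = None) -> str:
    """Aligned plain-text accuracy block (overall, then per-class U/P rows)."""
    lines = [
        f"Region {report.region}",
        f"  Overall accuracy %: {report.overall:5.1f} ± {report.overall_ci:.1f}",
    ]
    for i, c in enumerate(CLASS_CODES):
        lines.append(
            f"  {CLASS_NAMES[c]:<15s} user's %: {report.users[i]:5.1f} ± "
            f"{Z95 * report.users_se[i]:.1f}   producer's %: "
            f"{report.producers[i]:5.1f} ± {Z95 * report.producers_se[i]:.1f}"
        )
    if areas is not None:
        for i, c in enumerate(CLASS_CODES):
            lines.append(
                f"  {CLASS_NAMES[c]:<15s} mapped area: {areas.mapped_area[i]:.4g}"
                f"   adjusted: {areas.adjusted_area[i]:.4g} ± {areas.ci95[i]:.4g}"
            )
    return "\n".join(lines)
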