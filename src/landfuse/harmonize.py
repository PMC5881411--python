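"""Bring heterogeneous source rasters onto the common target grid.

The harmonization steps mirror the standard preprocessing for fusing land
cover products that arrive with different legends, resolutions and
footprints: merge legend classes, aggregate finer maps by majority (or mean
for percentage layers), snap everything to the target grid with
nearest-neighbour resampling and optionally threshold percentage layers into
presence/absence.

Conventions (fixed here, used everywhere):

* a source cell contributes to the target cell containing its center
  (center-assignment, no area weighting);
* majority ties break to the smallest class code;
* nodata cells do not vote, and a target cell becomes nodata when more than
  half of its contributors are nodata;
* ``threshold_percent`` uses ``value >= threshold`` for presence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec
from .raster import AlignmentError, CategoricalRaster, ContinuousRaster, LegendError, MapStack

PRESENT = 1
ABSENT = 0


@dataclass
class LegendSimplification:
    """Many-to-one merge of source class codes.

    ``unmapped`` controls codes absent from ``mapping``: ``"strict"`` raises,
    ``"pass-through"`` keeps them, ``"to-nodata"`` masks them.
    """

    mapping: dict[int, int]
    unmapped: str = "strict"

    _POLICIES = ("strict", "pass-through", "to-nodata")

    def __post_init__(self) -> None:
        if self.unmapped not in self._POLICIES:
            raise ValueError(f"unmapped policy must be one of {self._POLICIES}")
        self.mapping = {int(k): int(v) for k, v in self.mapping.items()}


def simplify_legend(
    raster: CategoricalRaster, simplification: LegendSimplification
) -> CategoricalRaster:
    """Merge classes of ``raster`` according to ``simplification``.

    The output alphabet is the image of the mapping (plus passed-through
    codes); nodata cells are preserved and the cell count never changes.
    """
    mapping = simplification.mapping
    unmapped = [a for a in raster.alphabet if a not in mapping]
    if unmapped and simplification.unmapped == "strict":
        raise LegendError(
            f"codes {unmapped} of legend {raster.legend_id!r} have no mapping "
            "and the policy is strict"
        )

    out = raster.codes.copy()
    new_alphabet: set[int] = set()
    for src, dst in mapping.items():
        out[raster.codes == src] = dst
        if src in raster.alphabet:
            new_alphabet.add(dst)
    for code in unmapped:
        if simplification.unmapped == "to-nodata":
            out[raster.codes == code] = raster.nodata_code
        else:  # pass-through
            new_alphabet.add(code)
    return raster.copy_with(
        codes=out,
        alphabet=tuple(sorted(new_alphabet)),
        legend_id=f"{raster.legend_id}:simplified" if raster.legend_id else "simplified",
    )


def _contributor_index(source: GridSpec, target: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Flat target index for every source cell (center-assignment).

    Returns (flat_index, in_extent_mask) over flattened source cells.
    """
    lon, lat = source.cell_centers()
    trow, tcol = target.locate(lon.ravel(), lat.ravel())
    ok = (trow >= 0) & (tcol >= 0)
    return trow * target.n_cols + tcol, ok


def _check_finer(source: GridSpec, target: GridSpec) -> None:
    if source.cell_size >= target.cell_size:
        raise ValueError(
            "aggregation requires a source strictly finer than the target "
            f"(source {source.cell_size}\" vs target {target.cell_size}\"); "
            "use resample_nearest for same-or-coarser sources"
        )


def aggregate_majority(raster: CategoricalRaster, target: GridSpec) -> CategoricalRaster:
    """Aggregate a finer categorical raster by modal class per target cell.

    Nodata contributors are excluded from the vote; the target cell is nodata
    when they exceed half of the contributors (or when nothing contributes).
    Ties break to the smallest class code.
    """
    _check_finer(raster.grid, target)
    idx, ok = _contributor_index(raster.grid, target)
    codes = raster.codes.ravel()
    n_target = target.n_cells

    total = np.bincount(idx[ok], minlength=n_target)
    nodata_ct = np.bincount(idx[ok & (codes == raster.nodata_code)], minlength=n_target)

    alphabet = sorted(raster.alphabet)
    best_count = np.zeros(n_target, dtype=np.int64)
    best_code = np.full(n_target, raster.nodata_code, dtype=np.int64)
    # iterate smallest code first so strict > keeps the smallest on ties
    for code in alphabet:
        ct = np.bincount(idx[ok & (codes == code)], minlength=n_target)
        win = ct > best_count
        best_count[win] = ct[win]
        best_code[win] = code

    out = best_code
    out[(total == 0) | (nodata_ct * 2 > total)] = raster.nodata_code
    return raster.copy_with(grid=target, codes=out.reshape(target.shape))


def aggregate_mean(raster: ContinuousRaster, target: GridSpec) -> ContinuousRaster:
    """Aggregate a finer percentage raster by the mean of non-nodata contributors."""
    _check_finer(raster.grid, target)
    idx, ok = _contributor_index(raster.grid, target)
    valid = ok & raster.mask.ravel()
    n_target = target.n_cells

    sums = np.bincount(idx[valid], weights=raster.values.ravel()[valid], minlength=n_target)
    counts = np.bincount(idx[valid], minlength=n_target)
    out = np.full(n_target, raster.nodata_value, dtype=float)
    has = counts > 0
    out[has] = sums[has] / counts[has]
    return ContinuousRaster(target, out.reshape(target.shape), raster.nodata_value)


def resample_nearest(raster, target: GridSpec):
    """Resample to ``target``: each target cell takes the value of the source
    cell whose center is nearest the target cell center.

    For regular grids this is the source cell containing the target center
    (exact-boundary ties resolve south-east, consistent with half-open cells).
    Target cells outside the source footprint become nodata.
    """
    lon, lat = target.cell_centers()
    srow, scol = raster.grid.locate(lon.ravel(), lat.ravel())
    inside = (srow >= 0) & (scol >= 0)
    if not inside.any():
        raise AlignmentError("source raster does not overlap the target extent")

    if isinstance(raster, CategoricalRaster):
        out = np.full(target.n_cells, raster.nodata_code, dtype=raster.codes.dtype)
        out[inside] = raster.codes[srow[inside], scol[inside]]
        return raster.copy_with(grid=target, codes=out.reshape(target.shape))
    out = np.full(target.n_cells, raster.nodata_value, dtype=float)
    out[inside] = raster.values[srow[inside], scol[inside]]
    return ContinuousRaster(target, out.reshape(target.shape), raster.nodata_value)


def threshold_percent(
    raster: ContinuousRaster,
    threshold: float = 50.0,
    present_code: int = PRESENT,
    absent_code: int = ABSENT,
    nodata_code: int = -1,
    legend_id: str = "presence",
) -> CategoricalRaster:
    """Convert a percentage layer to presence/absence at ``threshold``.

    ``value >= threshold`` maps to ``present_code``; the default threshold of
    50% follows the convention used when converting percentage-cropland
    layers to a categorical reading.
    """
    if not (0.0 < threshold <= 100.0):
        raise ValueError(f"threshold must lie in (0, 100], got {threshold}")
    out = np.where(raster.values >= threshold, present_code, absent_code)
    out = np.where(raster.mask, out, nodata_code).astype(np.int64)
    return CategoricalRaster(
        raster.grid, out, nodata_code, (absent_code, present_code), legend_id
    )


def align_stack(rasters, target: GridSpec, names=None) -> MapStack:
    """Snap every layer to ``target`` (nearest neighbour where needed) and
    stack them in the given, recorded order."""
    names = list(names) if names is not None else [f"source_{i}" for i in range(len(rasters))]
    aligned = []
    for name, r in zip(names, rasters):
        if not isinstance(r, CategoricalRaster):
            raise TypeError(
                f"layer {name!r}: only categorical layers can be stacked; "
                "threshold continuous layers first"
            )
        if r.grid.same_grid(target):
            aligned.append(r)
        else:
            try:
                aligned.append(resample_nearest(r, target))
            except AlignmentError as e:
                raise AlignmentError(f"layer {name!r}: {e}") from e
    return MapStack(target, aligned, names)
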