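"""In-memory raster containers: categorical and continuous single-band layers.

A :class:`CategoricalRaster` carries its own class alphabet (legend); sources
with different legends coexist in a :class:`MapStack` without translation —
the fusion stage consumes each source's readings in its native alphabet.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec


class LegendError(ValueError):
    """A class code outside the declared alphabet."""


class AlignmentError(ValueError):
    """Layers expected on a common grid are not."""


@dataclass
class CategoricalRaster:
    """Integer-coded single-band raster with an explicit class alphabet."""

    grid: GridSpec
    codes: np.ndarray
    nodata_code: int
    alphabet: tuple[int, ...]
    legend_id: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise TypeError("categorical codes must be integers")
        if self.codes.shape != self.grid.shape:
            raise ValueError(
                f"codes shape {self.codes.shape} != grid shape {self.grid.shape}"
            )
        self.alphabet = tuple(int(a) for a in self.alphabet)
        if self.nodata_code in self.alphabet:
            raise LegendError(
                f"nodata code {self.nodata_code} collides with alphabet {self.alphabet}"
            )
        self.validate_codes()

    def validate_codes(self) -> None:
        allowed = set(self.alphabet) | {int(self.nodata_code)}
        present = set(np.unique(self.codes).tolist())
        unknown = present - allowed
        if unknown:
            raise LegendError(
                f"codes {sorted(unknown)} outside alphabet {sorted(self.alphabet)} "
                f"of legend {self.legend_id!r}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the raster has data."""
        return self.codes != self.nodata_code

    def copy_with(self, **kw) -> "CategoricalRaster":
        args = dict(
            grid=self.grid,
            codes=self.codes,
            nodata_code=self.nodata_code,
            alphabet=self.alphabet,
            legend_id=self.legend_id,
        )
        args.update(kw)
        return CategoricalRaster(**args)


@dataclass
class ContinuousRaster:
    """Percentage-valued single-band raster; non-nodata values lie in [0, 100]."""

    grid: GridSpec
    values: np.ndarray
    nodata_value: float = -1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        data = self.values[self.mask]
        if data.size and (data.min() < 0.0 or data.max() > 100.0):
            raise ValueError("continuous raster values must lie in [0, 100]")

    @property
    def mask(self) -> np.ndarray:
        if np.isnan(self.nodata_value):
            return ~np.isnan(self.values)
        return self.values != self.nodata_value


@dataclass
class MapStack:
    """Harmonized source layers sharing one grid, in stable, recorded order."""

    grid: GridSpec
    layers: list[CategoricalRaster] = field(default_factory=list)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.layers):
            self.names = [f"source_{i}" for i in range(len(self.layers))]
        for name, layer in zip(self.names, self.layers):
            if not layer.grid.same_grid(self.grid):
                raise AlignmentError(f"layer {name!r} is not on the stack grid")

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)
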