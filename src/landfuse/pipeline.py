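"""End-to-end pipeline: harmonize -> fit -> fuse -> classify -> validate.

A :class:`PipelineConfig` (usually loaded from YAML) names the input rasters
with their kinds, legend simplifications and thresholds, the stratum raster,
the reference and validation CSVs, the prior and estimation knobs, and the
output directory.  ``run_pipeline`` executes the stages, writes every
artifact plus the fully resolved config next to the outputs, and logs each
stage with its parameters, so a run can be reproduced from the output
directory alone.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import harmonize, io as lio, validation
from .fusion import classify, fit_conditionals, fuse, uniform_prior
from .grid import GridSpec
from .raster import MapStack

logger = logging.getLogger(__name__)


@dataclass
class SourceEntry:
    """One input raster in the pipeline config."""

    path: str
    name: str = ""
    kind: str = "categorical"  # or "continuous"
    alphabet: list[int] = field(default_factory=list)
    nodata: int | float | None = None
    legend_mapping: dict[int, int] | None = None
    unmapped: str = "strict"
    threshold: float = 50.0  # used for continuous sources

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"source {self.name or self.path}: unknown kind {self.kind}")


@dataclass
class PipelineConfig:
    target_grid: GridSpec
    sources: list[SourceEntry]
    strata_path: str
    strata_alphabet: list[int]
    reference_path: str
    validation_path: str | None = None
    regions_path: str | None = None
    regions_alphabet: list[int] = field(default_factory=list)
    prior: list[float] | None = None
    smoothing: float = 0.0
    min_support: int = 30
    total_area: float = 1.0
    seed: int = 42
    out_dir: str = "outputs"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        g = doc.pop("target_grid")
        grid = GridSpec(
            g["cell_size"], g["origin_lon"], g["origin_lat"], g["n_rows"], g["n_cols"]
        )
        sources = [SourceEntry(**s) for s in doc.pop("sources")]
        return cls(target_grid=grid, sources=sources, **doc)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["target_grid"] = dataclasses.asdict(self.target_grid)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _load_and_harmonize(entry: SourceEntry, target: GridSpec):
    """One source: read, simplify legend / threshold, bring to the target grid."""
    if entry.kind == "continuous":
        r = lio.read_continuous(entry.path, nodata_value=entry.nodata)
        if r.grid.cell_size < target.cell_size:
            r = harmonize.aggregate_mean(r, target)
        elif not r.grid.same_grid(target):
            r = harmonize.resample_nearest(r, target)
        return harmonize.threshold_percent(r, entry.threshold, legend_id=entry.name)
    r = lio.read_categorical(
        entry.path, entry.alphabet, legend_id=entry.name, nodata_code=entry.nodata
    )
    if entry.legend_mapping:
        r = harmonize.simplify_legend(
            r, harmonize.LegendSimplification(entry.legend_mapping, entry.unmapped)
        )
    if r.grid.cell_size < target.cell_size:
        r = harmonize.aggregate_majority(r, target)
    elif not r.grid.same_grid(target):
        r = harmonize.resample_nearest(r, target)
    return r


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artifacts under ``config.out_dir``.

    Returns a dict of in-memory results (stack, tables, posterior, fused map,
    and reports when validation inputs are configured).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    target = config.target_grid

    logger.info("harmonize: %d sources -> %s grid", len(config.sources), target.shape)
    layers, names = [], []
    for i, entry in enumerate(config.sources):
        name = entry.name or f"source_{i}"
        layers.append(_load_and_harmonize(entry, target))
        names.append(name)
    stack = harmonize.align_stack(layers, target, names)

    strata = lio.read_categorical(
        config.strata_path, config.strata_alphabet, legend_id="strata"
    )
    if not strata.grid.same_grid(target):
        strata = harmonize.resample_nearest(strata, target)

    reference = lio.read_reference_csv(config.reference_path)
    logger.info(
        "fit: %d reference points, smoothing=%g, min_support=%d",
        len(reference), config.smoothing, config.min_support,
    )
    tables = fit_conditionals(
        stack, reference, strata, config.smoothing, config.min_support
    )
    lio.write_conditional_tables(out / "conditional_tables.yaml", tables)

    prior = uniform_prior() if config.prior is None else np.asarray(config.prior, float)
    logger.info("fuse: prior=%s", prior)
    posterior = fuse(stack, tables, prior, strata)
    lio.write_posterior(out / "posterior.tif", out / "posterior_flags.tif", posterior)

    fused = classify(posterior)
    lio.write_raster(out / "fused_map.tif", fused)

    results = {"stack": stack, "tables": tables, "posterior": posterior, "fused": fused}

    if config.validation_path:
        records = lio.read_validation_csv(config.validation_path)
        regions = None
        if config.regions_path:
            regions = lio.read_categorical(
                config.regions_path, config.regions_alphabet, legend_id="regions"
            )
        logger.info("validate: %d records", len(records))
        confusions = validation.build_confusion(fused, records, regions)
        reports, areas, text_blocks = {}, {}, []
        for region, conf in confusions.items():
            weights = validation.map_class_weights(fused, regions, region)
            rep = validation.accuracy_report(conf, weights)
            ae = validation.adjusted_areas(conf, weights, config.total_area)
            reports[region], areas[region] = rep, ae
            rep.to_frame().to_csv(out / f"accuracy_region{region}.csv", index=False)
            ae.to_frame().to_csv(out / f"areas_region{region}.csv", index=False)
            text_blocks.append(validation.format_report(rep, ae))
        (out / "validation_report.txt").write_text("\n\n".join(text_blocks) + "\n")
        results["accuracy"] = reports
        results["areas"] = areas

    config.to_yaml(out / "resolved_config.yaml")
    logger.info("pipeline complete; outputs in %s", out)
    return results
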