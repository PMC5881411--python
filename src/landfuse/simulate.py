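"""Emit a synthetic scene as a reproducible directory of standard files."""
from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from . import io as lio
from .synthetic import SimConfig, SimScene, make_scene


def write_scene(scene: SimScene, out_dir) -> Path:
    """Write truth/strata/source GeoTIFFs, reference.csv, validation.csv and
    the resolved config (seed included) so the run is reproducible from the
    directory alone."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lio.write_raster(out / "truth.tif", scene.truth)
    lio.write_raster(out / "strata.tif", scene.strata)
    for spec, raster in zip(scene.config.sources, scene.sources):
        lio.write_raster(out / f"source_{spec.name}.tif", raster)
    lio.write_reference_csv(out / "reference.csv", scene.reference)
    lio.write_validation_csv(out / "validation.csv", scene.validation)

    doc = dataclasses.asdict(scene.config)
    doc["grid"] = dataclasses.asdict(scene.config.grid)
    (out / "scene_config.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))
    return out


def simulate(config: SimConfig | None = None, out_dir="scene", **overrides) -> Path:
    """Generate a scene (default study conditions unless overridden) and
    write it to ``out_dir``."""
    if config is None:
        config = SimConfig(**overrides) if overrides else SimConfig()
    return write_scene(make_scene(config), out_dir)
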