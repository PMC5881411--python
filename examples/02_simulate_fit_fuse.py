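"""Generate a synthetic scene, fit conditional tables, fuse, and score.

The default scene is a 300x300 cell landscape in 3 strata observed by four
conditionally independent sources with per-class accuracies 0.70-0.85, plus
5,000 visually-interpreted reference points (5% of them "not sure").
"""
import numpy as np

import landfuse as lf

config = lf.SimConfig()
scene = lf.make_scene(config)
stack = lf.MapStack(config.grid, scene.sources, [s.name for s in config.sources])

tables = lf.fit_conditionals(stack, scene.reference, scene.strata)
posterior = lf.fuse(stack, tables, strata=scene.strata)
fused = lf.classify(posterior)

truth = scene.truth
for src in scene.sources:
    acc = np.mean(src.codes[src.mask] == truth.codes[src.mask])
    print(f"single-source accuracy  {src.legend_id:<22s} {acc:.3f}")
acc = np.mean(fused.codes[fused.mask] == truth.codes[fused.mask])
print(f"fused-map accuracy       {'(all four combined)':<22s} {acc:.3f}")

t = tables.for_stratum(1)[0]
print("\nfitted conditional table, stratum 1, source 1 (rows: truth class):")
print(np.round(t.probs, 3))
print("generating matrix diagonal was 0.85: the fit recovers it to ~0.01-0.03")
print("depending on row support (", t.support.sum(axis=1), "points per row).")
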