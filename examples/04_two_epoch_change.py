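"""Summarize cropland change between two epochs of a categorical map."""
import numpy as np

import landfuse as lf

grid = lf.GridSpec(10.0, 30.0, 55.0, 100, 100)
rng = np.random.default_rng(0)

t1 = rng.choice([1, 3], size=grid.shape, p=[0.4, 0.6])
t2 = t1.copy()
flip_away = (t1 == 1) & (rng.random(grid.shape) < 0.10)   # 10% of cropland lost
flip_to = (t1 == 3) & (rng.random(grid.shape) < 0.05)
t2[flip_away] = 3
t2[flip_to] = 1

map_t1 = lf.CategoricalRaster(grid, t1, 0, (1, 2, 3), "epoch-1992")
map_t2 = lf.CategoricalRaster(grid, t2, 0, (1, 2, 3), "epoch-2012")

loss, gain = lf.change_summary(map_t1, map_t2, class_code=1)
print(f"cropland loss: {loss:.1f}%  gain: {gain:.1f}%  "
      "(percent of the class extent at epoch 1)")
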