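import numpy as np
import pytest

import landfuse as lf


@pytest.fixture
def small_grid():
    return lf.GridSpec(cell_size=10.0, origin_lon=30.0, origin_lat=55.0, n_rows=4, n_cols=4)


@pytest.fixture
def table_a():
    """Three-class source: rows are truth (arable, abandoned, other)."""
    return lf.ConditionalTable(
        (1, 2, 3),
        np.array([[0.8, 0.2, 0.0], [0.1, 0.6, 0.3], [0.1, 0.3, 0.6]]),
        np.zeros((3, 3)),
    )


@pytest.fixture
def table_b():
    """Two-class source."""
    return lf.ConditionalTable(
        (1, 2),
        np.array([[0.6, 0.4], [0.2, 0.8], [0.5, 0.5]]),
        np.zeros((3, 2)),
    )


@pytest.fixture(scope="session")
def default_scene():
    """The default study scene: 300x300, 3 strata, 4 sources, 5000 reference
    points, fixed seed.  Session-scoped because several tests reuse it."""
    return lf.make_scene(lf.SimConfig())


@pytest.fixture(scope="session")
def default_scene_fused(default_scene):
    scene = default_scene
    stack = lf.MapStack(
        scene.config.grid, scene.sources, [s.name for s in scene.config.sources]
    )
    tables = lf.fit_conditionals(stack, scene.reference, scene.strata)
    posterior = lf.fuse(stack, tables, strata=scene.strata)
    fused = lf.classify(posterior)
    return scene, stack, tables, posterior, fused


def brute_force_posterior(readings, tables, prior):
    """Independent oracle: build the full joint Pr(G, S_1..S_K) by explicit
    enumeration and condition on the observed readings."""
    import itertools

    prior = np.asarray(prior, float)
    alphabets = [t.alphabet for t in tables]
    post = np.zeros(3)
    for g in range(3):
        for combo in itertools.product(*alphabets):
            pr = prior[g]
            for t, c in zip(tables, combo):
                pr *= t.probs[g, t.alphabet.index(c)]
            if all(r is None or r == c for r, c in zip(readings, combo)):
                post[g] += pr
    return post / post.sum()
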