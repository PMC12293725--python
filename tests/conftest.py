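import numpy as np
import pytest

from pixelcl import (
    ClassSchema,
    LabelMask,
    ProbMap,
    VESSEL_SCHEMA,
    default_fixture,
)


@pytest.fixture(scope="session")
def schema2():
    return VESSEL_SCHEMA


@pytest.fixture(scope="session")
def schema3():
    return ClassSchema(
        names=("a", "b", "c"),
        palette=((0, 0, 0), (255, 0, 0), (0, 255, 0)),
    )


@pytest.fixture(scope="session")
def toy4(schema2):
    """The 4-pixel two-class worked example: probs, observed labels, thresholds.

    Hand trace with t = (0.95, 0.75): pixel0 (obs 0, p=(0.99,0.01)) confirms
    class 0; pixel1 (obs 0, p=(0.40,0.60)) clears neither threshold ->
    unassigned; pixel2 (obs 1, p=(0.98,0.02)) clears only the class-0
    threshold -> counted (1,0); pixel3 (obs 1, p=(0.10,0.90)) confirms
    class 1.  Expected joint counts[obs][inf] = [[1,0],[1,1]], excluded = 1.
    """
    probs = ProbMap(
        np.array([[[0.99, 0.01], [0.40, 0.60]], [[0.98, 0.02], [0.10, 0.90]]]),
        schema2,
    )
    mask = LabelMask(np.array([[0, 0], [1, 1]]), schema2)
    thresholds = np.array([0.95, 0.75])
    return probs, mask, thresholds


@pytest.fixture(scope="session")
def fixture42():
    """The package's default desk-scale synthetic fixture (seed 42, 5% noise)."""
    return default_fixture(seed=42)


def random_mask(rng, shape, m, schema=None):
    if schema is None:
        names = tuple(f"c{i}" for i in range(m))
        palette = tuple((int(40 * i) % 256, 0, 0) for i in range(m))
        schema = ClassSchema(names=names, palette=palette)
    return LabelMask(rng.integers(0, m, size=shape), schema)


def random_probmap(rng, shape, schema):
    raw = rng.random(shape + (schema.m,)) + 1e-9
    return ProbMap(raw / raw.sum(axis=2, keepdims=True), schema)
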