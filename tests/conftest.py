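import numpy as np
import pytest

from mufrf import ToyWorldSpec, generate_toy_world


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic study world (60 drugs, ~300 triples, 400 pairs)."""
    return generate_toy_world(ToyWorldSpec(seed=0))


@pytest.fixture(scope="session")
def tiny_world():
    """A smaller world for structural / smoke tests."""
    return generate_toy_world(ToyWorldSpec(n_drugs=20, n_pairs=60, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_symmetric_kg(n_entities=40, n_pairs=80, holdout_fraction=0.2, seed=0):
    """Symmetric-relation KG: (a,r,b) for every pair, mirror (b,r,a) for all
    but a held-out fraction.  Returns (train_triples, heldout_mirrors, entities)."""
    rng = np.random.default_rng(seed)
    ents = [f"E{i}" for i in range(n_entities)]
    pairs = set()
    while len(pairs) < n_pairs:
        a, b = rng.choice(n_entities, 2, replace=False)
        if (b, a) not in pairs:
            pairs.add((int(a), int(b)))
    pairs = sorted(pairs)
    n_hold = int(holdout_fraction * len(pairs))
    hold = set(map(tuple, np.array(pairs)[rng.choice(len(pairs), n_hold, replace=False)]))
    train, heldout = [], []
    for a, b in pairs:
        train.append((ents[a], "sym", ents[b]))
        mirror = (ents[b], "sym", ents[a])
        (heldout if (a, b) in hold else train).append(mirror)
    return train, heldout, ents


def make_inverse_kg(n_entities=40, n_edges=80, holdout_fraction=0.2, seed=0):
    rng = np.random.default_rng(seed)
    ents = [f"E{i}" for i in range(n_entities)]
    edges = set()
    while len(edges) < n_edges:
        a, b = rng.choice(n_entities, 2, replace=False)
        edges.add((int(a), int(b)))
    edges = sorted(edges)
    n_hold = int(holdout_fraction * len(edges))
    hold = set(map(tuple, np.array(edges)[rng.choice(len(edges), n_hold, replace=False)]))
    train, heldout = [], []
    for a, b in edges:
        train.append((ents[a], "r1", ents[b]))
        inv = (ents[b], "r2", ents[a])
        (heldout if (a, b) in hold else train).append(inv)
    return train, heldout, ents


def make_composition_kg(n_entities=40, n_triangles=60, holdout_fraction=0.2, seed=0):
    rng = np.random.default_rng(seed)
    ents = [f"E{i}" for i in range(n_entities)]
    triangles = set()
    while len(triangles) < n_triangles:
        a, b, c = rng.choice(n_entities, 3, replace=False)
        triangles.add((int(a), int(b), int(c)))
    triangles = sorted(triangles)
    n_hold = int(holdout_fraction * len(triangles))
    hold = set(map(tuple, np.array(triangles)[rng.choice(len(triangles), n_hold,
                                                         replace=False)]))
    train, heldout = [], []
    for a, b, c in triangles:
        train.append((ents[a], "r1", ents[b]))
        train.append((ents[b], "r2", ents[c]))
        comp = (ents[a], "r3", ents[c])
        (heldout if (a, b, c) in hold else train).append(comp)
    return train, heldout, ents


def corrupted_controls(triples, entities, positives, n, seed=0):
    """Random corrupted versions of ``triples`` avoiding any known positive."""
    rng = np.random.default_rng(seed)
    pos = set(map(tuple, positives))
    out = []
    while len(out) < n:
        h, r, t = triples[rng.integers(len(triples))]
        if rng.random() < 0.5:
            h = entities[rng.integers(len(entities))]
        else:
            t = entities[rng.integers(len(entities))]
        if (h, r, t) in pos:
            continue
        out.append((h, r, t))
    return out
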