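"""Seed-deterministic toy worlds: SMILES drugs, a knowledge graph with
planted relation patterns, and DDI labels from a planted two-view rule.

The world is small enough to train on in seconds yet structured so that
every stage of the pipeline has signal to find:

* Drugs come from a pool of simple valid SMILES, half aromatic and half
  aliphatic — the *structural class* that the graph view can recover.
* Every drug is attached to one of two group hub entities via the
  ``in_group`` relation — the *KG group* that the KG view can recover —
  and relation specs plant additional symmetric / inverse / compositional
  relations for the pattern-recovery tests.
* The planted DDI rule needs both views at once: a pair interacts iff
  the two drugs share their KG hub AND share their structural class, so
  neither view alone suffices (single-view ablations are handicapped by
  construction).  Emitted pairs are sampled label-balanced, giving a
  positive rate near 0.5; the multi-class variant labels each pair by
  the (structure-match, group-match) combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .rotate import KGTriple
from . import io as io_formats

GROUP_HUBS = ("G_A", "G_B")
IN_GROUP_RELATION = "in_group"

PATTERNS = ("generic", "symmetric")  # plus inverse_of:<r> and composition_of:<r1>,<r2>


def _build_smiles_pool() -> list[tuple[str, bool]]:
    """(canonical SMILES, is_aromatic) pool; validated and deduplicated."""
    candidates: list[tuple[str, bool]] = []
    chains = ["", "C", "CC", "CCC", "CCCC", "CCCCC", "O", "CO", "CCO",
              "N", "CN", "CCN", "Cl", "CCl", "C(C)C", "COC", "C(=O)O", "C#N"]
    for core in ("c1ccccc1", "c1ccncc1", "c1ccsc1"):
        for chain in chains:
            candidates.append((core + chain, True))
    for k in range(1, 9):
        for suffix in ["", "O", "N", "Cl", "OC", "(C)CC", "C(=O)O"]:
            candidates.append(("C" * k + suffix, False))
    pool: list[tuple[str, bool]] = []
    seen: set[str] = set()
    for smiles, aromatic in candidates:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        pool.append((smiles, aromatic))
    return pool


SMILES_POOL = _build_smiles_pool()


def _default_relation_specs() -> list[tuple[str, str, float]]:
    return [
        ("targets", "generic", 0.08),
        ("similar_to", "symmetric", 0.015),
        ("affects", "generic", 0.03),
        ("affected_by", "inverse_of:affects", 1.0),
        ("co_targets", "composition_of:similar_to,targets", 0.5),
    ]


@dataclass
class ToyWorldSpec:
    n_drugs: int = 60
    n_extra_entities: int = 20
    relation_specs: list[tuple[str, str, float]] = field(default_factory=_default_relation_specs)
    ddi_rule: str = "shared_hub_and_same_structure"
    n_pairs: int = 400
    n_classes: int = 4
    multiclass: bool = False
    seed: int = 0

    def __post_init__(self):
        names = {IN_GROUP_RELATION}
        for name, pattern, density in self.relation_specs:
            if not 0.0 < density <= 1.0:
                raise ValueError(f"density for {name!r} must lie in (0, 1], got {density}")
            if pattern.startswith("inverse_of:"):
                ref = pattern.split(":", 1)[1]
                if ref not in names:
                    raise ValueError(f"{name!r} inverts unknown relation {ref!r}")
            elif pattern.startswith("composition_of:"):
                refs = pattern.split(":", 1)[1].split(",")
                if len(refs) != 2 or not set(refs) <= names:
                    raise ValueError(f"{name!r} composes unknown relations {refs}")
            elif pattern not in PATTERNS:
                raise ValueError(f"unknown pattern {pattern!r} for relation {name!r}")
            names.add(name)


@dataclass
class ToyWorld:
    smiles_table: dict[str, str]
    triples: list[KGTriple]
    pairs: list[tuple[str, str, int]]
    structure_class: dict[str, int]
    kg_group: dict[str, int]


def generate_toy_world(spec: ToyWorldSpec) -> ToyWorld:
    """Generate one deterministic toy world from a spec (see module docstring)."""
    if spec.n_drugs > len(SMILES_POOL):
        raise ValueError(f"n_drugs={spec.n_drugs} exceeds the template pool "
                         f"({len(SMILES_POOL)} distinct molecules)")
    rng = np.random.default_rng(spec.seed)

    # -- drugs: balanced aromatic/aliphatic draw from the pool ----------
    aromatic = [s for s, a in SMILES_POOL if a]
    aliphatic = [s for s, a in SMILES_POOL if not a]
    n_arom = min(spec.n_drugs // 2, len(aromatic))
    n_alip = spec.n_drugs - n_arom
    if n_alip > len(aliphatic):
        n_alip = len(aliphatic)
        n_arom = spec.n_drugs - n_alip
    chosen = ([(s, 1) for s in rng.choice(aromatic, n_arom, replace=False)]
              + [(s, 0) for s in rng.choice(aliphatic, n_alip, replace=False)])
    rng.shuffle(chosen)
    smiles_table = {f"D{i:03d}": smiles for i, (smiles, _) in enumerate(chosen)}
    structure_class = {f"D{i:03d}": flag for i, (_, flag) in enumerate(chosen)}
    drug_ids = list(smiles_table)

    # -- KG -------------------------------------------------------------
    kg_group = {d: int(rng.random() < 0.5) for d in drug_ids}
    extra = [f"T{i:03d}" for i in range(max(0, spec.n_extra_entities - len(GROUP_HUBS)))]
    triples: list[KGTriple] = [
        KGTriple(d, IN_GROUP_RELATION, GROUP_HUBS[kg_group[d]]) for d in drug_ids
    ]
    by_relation: dict[str, list[KGTriple]] = {IN_GROUP_RELATION: list(triples)}
    for name, pattern, density in spec.relation_specs:
        emitted: list[KGTriple] = []
        if pattern == "generic":
            for d in drug_ids:
                for e in extra:
                    if rng.random() < density:
                        emitted.append(KGTriple(d, name, e))
        elif pattern == "symmetric":
            for i, a in enumerate(drug_ids):
                for b in drug_ids[i + 1:]:
                    if rng.random() < density:
                        emitted.append(KGTriple(a, name, b))
                        emitted.append(KGTriple(b, name, a))  # closure
        elif pattern.startswith("inverse_of:"):
            ref = pattern.split(":", 1)[1]
            for h, _, t in by_relation.get(ref, []):
                if rng.random() < density:
                    emitted.append(KGTriple(t, name, h))
        else:  # composition_of:r1,r2
            r1, r2 = pattern.split(":", 1)[1].split(",")
            heads = {}
            for h, _, t in by_relation.get(r2, []):
                heads.setdefault(h, []).append(t)
            for a, _, b in by_relation.get(r1, []):
                for c in heads.get(b, []):
                    if rng.random() < density:
                        emitted.append(KGTriple(a, name, c))
        by_relation[name] = emitted
        triples.extend(emitted)

    # -- DDI labels from the planted two-view rule ----------------------
    def rule_class(a: str, b: str) -> int:
        same_struct = int(structure_class[a] == structure_class[b])
        same_group = int(kg_group[a] == kg_group[b])
        return 2 * same_struct + same_group  # 3 ⇔ both views match

    candidates = [(a, b) for i, a in enumerate(drug_ids) for b in drug_ids[i + 1:]]
    order = rng.permutation(len(candidates))
    if spec.multiclass:
        per_class: dict[int, list] = {c: [] for c in range(4)}
        for k in order:
            a, b = candidates[k]
            per_class[rule_class(a, b)].append((a, b))
        quota = -(-spec.n_pairs // spec.n_classes)
        pairs = []
        for c in range(4):
            label = c % spec.n_classes
            for a, b in per_class[c][:quota]:
                pairs.append((a, b, label))
        pairs = pairs[:spec.n_pairs]
    else:
        pos = [candidates[k] for k in order if rule_class(*candidates[k]) == 3]
        neg = [candidates[k] for k in order if rule_class(*candidates[k]) != 3]
        half = spec.n_pairs // 2
        if len(pos) < half or len(neg) < spec.n_pairs - half:
            raise ValueError("candidate pair space too small for the requested n_pairs")
        pairs = ([(a, b, 1) for a, b in pos[:half]]
                 + [(a, b, 0) for a, b in neg[:spec.n_pairs - half]])
    pair_order = rng.permutation(len(pairs))
    pairs = [pairs[k] for k in pair_order]

    return ToyWorld(smiles_table, triples, pairs, structure_class, kg_group)


def write_toy_world(world: ToyWorld, out_dir) -> dict[str, Path]:
    """Write the world in the package's standard TSV formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "smiles": out / "drugs.tsv",
        "triples": out / "kg.tsv",
        "pairs": out / "ddi.tsv",
    }
    io_formats.write_smiles_table(world.smiles_table, paths["smiles"])
    io_formats.write_triples(world.triples, paths["triples"])
    io_formats.write_ddi_pairs(world.pairs, paths["pairs"])
    return paths
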