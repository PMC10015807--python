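"""Readers and writers for the three tabular inputs, config files, and
checkpoints.

All tabular formats are UTF-8 TSV with ``#`` comment lines and no header
by default (a header on the DDI table is autodetected when the label
field of the first line is non-numeric):

* SMILES table: ``drug_id<TAB>smiles``
* KG triples:   ``head<TAB>relation<TAB>tail``
* DDI pairs:    ``drug_i<TAB>drug_j<TAB>label``
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .rotate import KGTriple

logger = logging.getLogger(__name__)


@dataclass
class Vocabulary:
    """Ordered bidirectional id ↔ string maps for entities, relations, drugs."""

    entities: dict[str, int] = field(default_factory=dict)
    relations: dict[str, int] = field(default_factory=dict)
    drugs: dict[str, int] = field(default_factory=dict)

    def add_entity(self, name: str) -> int:
        return self.entities.setdefault(name, len(self.entities))

    def add_relation(self, name: str) -> int:
        return self.relations.setdefault(name, len(self.relations))

    def add_drug(self, name: str) -> int:
        return self.drugs.setdefault(name, len(self.drugs))


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_smiles_table(path) -> dict[str, str]:
    """``drug_id<TAB>smiles`` per line → ordered dict."""
    table: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            logger.warning("%s:%d: expected 2 fields, got %d — skipped",
                           path, lineno, len(fields))
            continue
        table[fields[0]] = fields[1]
    return table


def write_smiles_table(table: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for drug_id, smiles in table.items():
            fh.write(f"{drug_id}\t{smiles}\n")


def read_triples(path, max_malformed_fraction: float = 0.1
                 ) -> tuple[list[KGTriple], Vocabulary]:
    """Order-preserving parse of a DRKG-style triple TSV.

    Malformed lines are counted and reported; more than
    ``max_malformed_fraction`` of them aborts the parse.
    """
    triples: list[KGTriple] = []
    vocab = Vocabulary()
    malformed = 0
    total = 0
    for lineno, line in _data_lines(path):
        total += 1
        fields = line.split("\t")
        if len(fields) != 3:
            malformed += 1
            logger.warning("%s:%d: malformed triple line (%d fields)",
                           path, lineno, len(fields))
            continue
        h, r, t = fields
        vocab.add_entity(h)
        vocab.add_relation(r)
        vocab.add_entity(t)
        triples.append(KGTriple(h, r, t))
    if total == 0:
        logger.warning("%s: empty triple file", path)
    elif malformed / total > max_malformed_fraction:
        raise ValueError(f"{path}: {malformed}/{total} lines malformed "
                         f"(> {max_malformed_fraction:.0%} allowed)")
    return triples, vocab


def write_triples(triples, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h, r, t in triples:
            fh.write(f"{h}\t{r}\t{t}\n")


def read_ddi_pairs(path, task: str = "binary", n_classes: int | None = None
                   ) -> list[tuple[str, str, int]]:
    """Parse labeled drug pairs; duplicates keep the first label with a warning."""
    if task not in ("binary", "multiclass"):
        raise ValueError("task must be 'binary' or 'multiclass'")
    pairs: list[tuple[str, str, int]] = []
    seen: dict[tuple[str, str], int] = {}
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        a, b, label_str = fields
        if first:
            first = False
            try:
                int(label_str)
            except ValueError:
                logger.info("%s: header line autodetected and skipped", path)
                continue
        try:
            label = int(label_str)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer label {label_str!r}") from exc
        if task == "binary" and label not in (0, 1):
            raise ValueError(f"{path}:{lineno}: binary label must be 0/1, got {label}")
        if task == "multiclass":
            upper = n_classes if n_classes is not None else float("inf")
            if not 0 <= label < upper:
                raise ValueError(f"{path}:{lineno}: label {label} outside [0, {n_classes})")
        key = (a, b)
        if key in seen:
            logger.warning("%s:%d: duplicate pair %s — first label kept", path, lineno, key)
            continue
        seen[key] = label
        pairs.append((a, b, label))
    return pairs


def write_ddi_pairs(pairs, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, label in pairs:
            fh.write(f"{a}\t{b}\t{label}\n")


def load_config(path) -> dict:
    """YAML config whose keys mirror the train-config dataclass fields."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_metrics_report(report, path) -> None:
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


CHECKPOINT_SCHEMA_VERSION = 1


def save_checkpoint(out_dir, meta: dict, arrays: dict[str, np.ndarray]) -> Path:
    """Versioned checkpoint: JSON metadata + one npz of weight arrays."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = dict(meta, schema_version=CHECKPOINT_SCHEMA_VERSION)
    (out / "meta.json").write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    np.savez(out / "weights.npz", **arrays)
    return out


def load_checkpoint(ckpt_dir) -> tuple[dict, dict[str, np.ndarray]]:
    ckpt = Path(ckpt_dir)
    meta = json.loads((ckpt / "meta.json").read_text(encoding="utf-8"))
    version = meta.get("schema_version")
    if version != CHECKPOINT_SCHEMA_VERSION:
        raise ValueError(f"unsupported checkpoint schema version {version!r}")
    with np.load(ckpt / "weights.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    return meta, arrays
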