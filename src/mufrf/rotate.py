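"""RotatE knowledge-graph embedding: entities in complex space, relations
as elementwise unit-modulus rotations.

A triple (h, r, t) is scored by the distance

    score(h, r, t) = || e_h ∘ e_r − e_t ||

where ∘ is the elementwise complex product and e_r has modulus 1 in every
coordinate (stored as a phase vector θ, realized as cos θ + i sin θ, after
Euler's formula).  Lower scores mean more plausible triples; the minimum 0
is attained exactly when the rotated head coincides with the tail.  The
phase parameterization means the unit-modulus constraint can never be
violated during training.

Rotations compose, commute, and invert, which is why RotatE can represent
symmetric relations (θ ∈ {0, π}), inverse relation pairs (θ₂ = −θ₁) and
compositions (θ₃ = θ₁ + θ₂).

Training minimizes a negative-sampling loss.  Two conventions are
available (``loss_convention``):

``"rotate-standard"`` (default)
    L = −ln σ(γ − s_pos) − (1/k) Σ_i ln σ(s_negᵢ − γ),
    which pushes positive scores below the margin γ and negative scores
    above it, consistent with lower-is-better distances.
``"as-printed"``
    L = −Σ_i ln σ(s_pos − s_negᵢ − γ), a literal transcription of the
    printed loss, kept for fidelity; note it rewards *large* positive
    scores, contradicting the distance semantics, so it is not the
    default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator

from ._autodiff import Tensor, logsigmoid
from ._optim import Adam

logger = logging.getLogger(__name__)

LOSS_CONVENTIONS = ("rotate-standard", "as-printed")


class KGTriple(NamedTuple):
    head: str
    relation: str
    tail: str


@dataclass
class ComplexEmbeddingTable:
    """Entity vectors in C^{d_c} (split into real/imag parts) and relation
    phase vectors in radians.  Flattened entity vectors are real‖imag,
    length 2·d_c (= the shared 100-dim width at the default d_c = 50)."""

    entity_real: np.ndarray      # n_entities × d_c
    entity_imag: np.ndarray      # n_entities × d_c
    relation_phase: np.ndarray   # n_relations × d_c
    entity_vocab: dict[str, int] = field(default_factory=dict)
    relation_vocab: dict[str, int] = field(default_factory=dict)

    @property
    def d_c(self) -> int:
        return self.entity_real.shape[1]

    def relation_complex(self, r: int) -> np.ndarray:
        theta = self.relation_phase[r]
        return np.cos(theta) + 1j * np.sin(theta)

    def entity_complex(self, e: int) -> np.ndarray:
        return self.entity_real[e] + 1j * self.entity_imag[e]


@dataclass
class KGTrainConfig:
    margin: float = 12.0                 # γ₁
    negatives_per_positive: int = 128
    learning_rate: float = 0.05
    epochs: int = 200
    seed: int = 0
    loss_convention: str = "rotate-standard"

    def __post_init__(self):
        if self.negatives_per_positive < 1:
            raise ValueError("negatives_per_positive must be >= 1")
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.loss_convention not in LOSS_CONVENTIONS:
            raise ValueError(f"loss_convention must be one of {LOSS_CONVENTIONS}")


def rotate_score(head_vec: np.ndarray, relation_phase: np.ndarray,
                 tail_vec: np.ndarray) -> float:
    """|| e_h ∘ e_r − e_t || for one triple of complex vectors (lower = better)."""
    head_vec = np.asarray(head_vec, dtype=complex)
    tail_vec = np.asarray(tail_vec, dtype=complex)
    relation_phase = np.asarray(relation_phase, dtype=float)
    if not head_vec.shape == relation_phase.shape == tail_vec.shape:
        raise ValueError("head, relation and tail must share the complex dimension")
    rotation = np.cos(relation_phase) + 1j * np.sin(relation_phase)
    return float(np.linalg.norm(head_vec * rotation - tail_vec))


def sample_negatives(triple: KGTriple, vocab_size: int, k: int, seed: int,
                     positives: set[tuple] | None = None,
                     entity_ids: list | None = None) -> list[KGTriple]:
    """Corrupt head or tail (fair coin) with a uniform random entity.

    Candidates equal to the input triple or to any triple in ``positives``
    are rejected and resampled.  ``entity_ids`` maps indices 0..vocab_size
    to identifiers; integers are used directly when it is omitted.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if vocab_size < 2:
        raise ValueError("cannot corrupt triples with fewer than 2 entities")
    positives = positives or set()
    rng = np.random.default_rng(seed)
    out: list[KGTriple] = []
    while len(out) < k:
        corrupt_head = rng.random() < 0.5
        ent = rng.integers(vocab_size)
        ent_id = entity_ids[ent] if entity_ids is not None else int(ent)
        cand = (KGTriple(ent_id, triple.relation, triple.tail) if corrupt_head
                else KGTriple(triple.head, triple.relation, ent_id))
        if cand == triple or tuple(cand) in positives:
            continue
        out.append(cand)
    return out


def kg_loss(positive: KGTriple, negatives: list[KGTriple],
            table: ComplexEmbeddingTable, config: KGTrainConfig) -> float:
    """Negative-sampling loss for one positive triple (conventions above).

    Triples here carry integer ids (or ids resolvable via the table's
    vocabularies).
    """
    if not negatives:
        raise ValueError("negatives must be nonempty")

    def resolve(t: KGTriple) -> tuple[int, int, int]:
        ev, rv = table.entity_vocab, table.relation_vocab
        h = ev[t.head] if ev and not isinstance(t.head, (int, np.integer)) else int(t.head)
        r = rv[t.relation] if rv and not isinstance(t.relation, (int, np.integer)) else int(t.relation)
        tt = ev[t.tail] if ev and not isinstance(t.tail, (int, np.integer)) else int(t.tail)
        return h, r, tt

    def score(t: KGTriple) -> float:
        h, r, tt = resolve(t)
        return rotate_score(table.entity_complex(h), table.relation_phase[r],
                            table.entity_complex(tt))

    def log_sigmoid(x: float) -> float:
        return float(min(x, 0.0) - np.log1p(np.exp(-abs(x))))

    s_pos = score(positive)
    s_negs = [score(n) for n in negatives]
    gamma = config.margin
    if config.loss_convention == "as-printed":
        return -sum(log_sigmoid(s_pos - s_neg - gamma) for s_neg in s_negs)
    return (-log_sigmoid(gamma - s_pos)
            - sum(log_sigmoid(s - gamma) for s in s_negs) / len(s_negs))


class RotatEEmbedder(BaseEstimator):
    """Learn RotatE embeddings from (head, relation, tail) triples.

    ``embedding_dim`` is the flattened real width of an entity vector;
    the complex dimension is ``embedding_dim // 2`` (default 50 pairs →
    100 reals), so :meth:`transform` emits vectors in the shared fusion
    width directly.
    """

    def __init__(self, embedding_dim: int = 100, negatives_per_positive: int = 128,
                 margin: float = 12.0, learning_rate: float = 0.05, epochs: int = 200,
                 loss_convention: str = "rotate-standard", random_state: int = 0):
        self.embedding_dim = embedding_dim
        self.negatives_per_positive = negatives_per_positive
        self.margin = margin
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.loss_convention = loss_convention
        self.random_state = random_state

    # -- internals ------------------------------------------------------
    def _score_t(self, er: Tensor, ei: Tensor, ph: Tensor,
                 h_idx, r_idx, t_idx) -> Tensor:
        hr, hi = er.gather_rows(h_idx), ei.gather_rows(h_idx)
        tr, ti = er.gather_rows(t_idx), ei.gather_rows(t_idx)
        theta = ph.gather_rows(r_idx)
        c, s = theta.cos(), theta.sin()
        d_re = hr * c - hi * s - tr
        d_im = hr * s + hi * c - ti
        return ((d_re * d_re + d_im * d_im).sum(axis=1) + 1e-12) ** 0.5

    def fit(self, X, y=None):
        """Train on a list of triples (strings or pre-resolved ints)."""
        if self.embedding_dim % 2:
            raise ValueError("embedding_dim must be even (real‖imag pairs)")
        if self.loss_convention not in LOSS_CONVENTIONS:
            raise ValueError(f"loss_convention must be one of {LOSS_CONVENTIONS}")
        triples = [KGTriple(*t) for t in X]
        if not triples:
            raise ValueError("cannot train on an empty triple set")
        ents: dict[str, int] = {}
        rels: dict[str, int] = {}
        for h, r, t in triples:
            ents.setdefault(h, len(ents))
            rels.setdefault(r, len(rels))
            ents.setdefault(t, len(ents))
        self.entity_vocab_, self.relation_vocab_ = ents, rels
        n_e, n_r = len(ents), len(rels)
        if n_e < 2:
            raise ValueError("need at least 2 entities to sample negatives")
        d_c = self.embedding_dim // 2

        rng = np.random.default_rng(self.random_state)
        er = Tensor(rng.normal(0.0, 0.5, size=(n_e, d_c)), requires_grad=True)
        ei = Tensor(rng.normal(0.0, 0.5, size=(n_e, d_c)), requires_grad=True)
        ph = Tensor(rng.uniform(-np.pi, np.pi, size=(n_r, d_c)), requires_grad=True)

        h_idx = np.array([ents[t.head] for t in triples], dtype=np.intp)
        r_idx = np.array([rels[t.relation] for t in triples], dtype=np.intp)
        t_idx = np.array([ents[t.tail] for t in triples], dtype=np.intp)
        positive_set = {(h, r, t) for h, r, t in zip(h_idx, r_idx, t_idx)}
        # encoded positives for vectorized collision filtering
        pos_codes = np.sort((h_idx.astype(np.int64) * n_r + r_idx) * n_e + t_idx)
        n_pos, k = len(triples), self.negatives_per_positive
        gamma = self.margin

        opt = Adam([er, ei, ph], lr=self.learning_rate)
        self.loss_history_ = []
        for epoch in range(self.epochs):
            # fresh filtered uniform negatives each epoch
            neg_h = np.repeat(h_idx, k)
            neg_t = np.repeat(t_idx, k)
            neg_r = np.repeat(r_idx, k)
            corrupt_head = rng.random(n_pos * k) < 0.5
            repl = rng.integers(n_e, size=n_pos * k)
            neg_h = np.where(corrupt_head, repl, neg_h)
            neg_t = np.where(corrupt_head, neg_t, repl)
            # reject candidates that are accidental positives (vectorized)
            for _ in range(50):
                codes = (neg_h.astype(np.int64) * n_r + neg_r) * n_e + neg_t
                bad = np.nonzero(np.isin(codes, pos_codes))[0]
                if bad.size == 0:
                    break
                e = rng.integers(n_e, size=bad.size)
                neg_h[bad] = np.where(corrupt_head[bad], e, neg_h[bad])
                neg_t[bad] = np.where(corrupt_head[bad], neg_t[bad], e)

            opt.zero_grad()
            s_pos = self._score_t(er, ei, ph, h_idx, r_idx, t_idx)
            s_neg = self._score_t(er, ei, ph, neg_h, neg_r, neg_t)
            if self.loss_convention == "as-printed":
                diff = s_pos.gather_rows(np.repeat(np.arange(n_pos), k)) - s_neg
                loss = -logsigmoid(diff - gamma).sum() * (1.0 / n_pos)
            else:
                pos_term = -logsigmoid(Tensor(np.full(n_pos, gamma)) - s_pos).mean()
                neg_term = -logsigmoid(s_neg - gamma).mean()
                loss = pos_term + neg_term
            loss.backward()
            opt.step()
            self.loss_history_.append(float(loss.data))

        self.entity_real_ = er.data
        self.entity_imag_ = ei.data
        self.relation_phase_ = np.mod(ph.data + np.pi, 2 * np.pi) - np.pi
        return self

    # -- fitted-surface helpers -----------------------------------------
    @property
    def table_(self) -> ComplexEmbeddingTable:
        return ComplexEmbeddingTable(self.entity_real_, self.entity_imag_,
                                     self.relation_phase_, self.entity_vocab_,
                                     self.relation_vocab_)

    def entity_vector(self, entity_id) -> np.ndarray:
        """Flattened real‖imag vector (length ``embedding_dim``) for one entity."""
        if entity_id not in self.entity_vocab_:
            raise KeyError(f"unknown entity {entity_id!r}")
        i = self.entity_vocab_[entity_id]
        return np.concatenate([self.entity_real_[i], self.entity_imag_[i]])

    def transform(self, entity_ids) -> np.ndarray:
        return np.vstack([self.entity_vector(e) for e in entity_ids])

    def score_triples(self, triples) -> np.ndarray:
        """Distance scores for string triples under the learned table."""
        tab = self.table_
        out = []
        for h, r, t in triples:
            out.append(rotate_score(tab.entity_complex(self.entity_vocab_[h]),
                                    tab.relation_phase[self.relation_vocab_[r]],
                                    tab.entity_complex(self.entity_vocab_[t])))
        return np.asarray(out)


def entity_vector(table: ComplexEmbeddingTable, entity_id) -> np.ndarray:
    """Flatten one entity's complex embedding to real‖imag (length 2·d_c)."""
    if isinstance(entity_id, (int, np.integer)):
        i = int(entity_id)
    else:
        if entity_id not in table.entity_vocab:
            raise KeyError(f"unknown entity {entity_id!r}")
        i = table.entity_vocab[entity_id]
    if not 0 <= i < table.entity_real.shape[0]:
        raise KeyError(f"entity index {i} out of range")
    return np.concatenate([table.entity_real[i], table.entity_imag[i]])


def train_kg_embeddings(triples, config: KGTrainConfig) -> ComplexEmbeddingTable:
    """Functional wrapper: train a :class:`RotatEEmbedder` per ``config``."""
    emb = RotatEEmbedder(
        negatives_per_positive=config.negatives_per_positive, margin=config.margin,
        learning_rate=config.learning_rate, epochs=config.epochs,
        loss_convention=config.loss_convention, random_state=config.seed,
    ).fit(triples)
    return emb.table_
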