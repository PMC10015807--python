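"""Final drug representations, pair scoring, and task losses.

The representation of drug i is the 300-wide concatenation
d_i = [X_att,i ‖ h_G,i ‖ e_h,i] — the attention-refined fused feature
plus the two raw views as residual context.  A pair (i, j) is scored by
a dense head on [d_i ‖ d_j] (600 → 2048 → 1 or N_c) with a sigmoid for
the binary task and a softmax for the multi-class task.

Binary training minimizes cross-entropy on the predicted probability.
The printed form of the loss wraps the probability in a second sigmoid;
that variant is available behind ``double_sigmoid_fidelity`` but is not
the default, since σ(σ(·)) can never reach log-loss 0.  Multi-class
training uses label-smoothing cross-entropy

    l_m = (1 − ε)·ce(i) + ε · Σ_{j≠i} ce(j)/(N_c − 1),   ce(c) = −ln p_c

with smoothing mass ε (default 0.15) spread over the wrong classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat

PROB_FLOOR = 1e-12
REPR_DIM = 300
TASKS = ("binary", "multiclass")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=(fan_in, fan_out)), requires_grad=True)


@dataclass
class DrugRepresentationMatrix:
    """n_drugs × 300 matrix [X_att ‖ h_G ‖ e_h] plus the drug-id ↔ row map."""

    matrix: np.ndarray
    drug_index: dict[str, int]

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[1] != REPR_DIM:
            raise ValueError(f"representation matrix must be n×{REPR_DIM}, "
                             f"got {self.matrix.shape}")

    def row(self, drug_id) -> np.ndarray:
        if drug_id not in self.drug_index:
            raise KeyError(f"unknown drug {drug_id!r}")
        return self.matrix[self.drug_index[drug_id]]


@dataclass
class PairPrediction:
    drug_i: str
    drug_j: str
    task: str
    output: float | np.ndarray   # probability (binary) or distribution (multiclass)


@dataclass
class LossConfig:
    task: str = "binary"
    smooth_epsilon: float = 0.15
    double_sigmoid_fidelity: bool = False

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if not 0.0 <= self.smooth_epsilon < 1.0:
            raise ValueError("smooth_epsilon must lie in [0, 1)")


@dataclass
class DenseHeadParams:
    """Pair-scoring MLP: 2·REPR_DIM → hidden → n_out."""

    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor

    @classmethod
    def init(cls, n_out: int, rng: np.random.Generator, hidden: int = 2048) -> "DenseHeadParams":
        return cls(w1=_glorot(rng, 2 * REPR_DIM, hidden),
                   b1=Tensor(np.zeros(hidden), requires_grad=True),
                   w2=_glorot(rng, hidden, n_out),
                   b2=Tensor(np.zeros(n_out), requires_grad=True))

    def tensors(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]


def assemble_drug_matrix(x_att: np.ndarray, hG: np.ndarray, eh: np.ndarray,
                         drug_index: dict[str, int] | None = None) -> DrugRepresentationMatrix:
    """Concatenate the three n×100 blocks in the fixed order [X_att ‖ h_G ‖ e_h]."""
    for name, block in (("x_att", x_att), ("hG", hG), ("eh", eh)):
        if block.shape != x_att.shape:
            raise ValueError(f"block {name} has shape {block.shape}, expected {x_att.shape}")
    if drug_index is None:
        drug_index = {str(i): i for i in range(x_att.shape[0])}
    return DrugRepresentationMatrix(np.concatenate([x_att, hG, eh], axis=1), drug_index)


def pair_logits_t(d_matrix: Tensor, i_idx: np.ndarray, j_idx: np.ndarray,
                  params: DenseHeadParams) -> Tensor:
    """Dense-head logits for a batch of ordered pairs (autodiff path)."""
    pairs = concat([d_matrix.gather_rows(i_idx), d_matrix.gather_rows(j_idx)], axis=1)
    hidden = (pairs @ params.w1 + params.b1).relu()
    return hidden @ params.w2 + params.b2


def predict_pair(d: DrugRepresentationMatrix, i, j, head_params: DenseHeadParams,
                 task: str = "binary") -> PairPrediction:
    """Score one ordered drug pair with the dense head."""
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    x = np.concatenate([d.row(i), d.row(j)])[None, :]
    hidden = np.maximum(x @ head_params.w1.data + head_params.b1.data, 0.0)
    logits = (hidden @ head_params.w2.data + head_params.b2.data)[0]
    if task == "binary":
        return PairPrediction(i, j, task, float(1.0 / (1.0 + np.exp(-logits[0]))))
    z = logits - logits.max()
    e = np.exp(z)
    return PairPrediction(i, j, task, e / e.sum())


def binary_loss(prediction: float, label: int,
                double_sigmoid_fidelity: bool = False) -> float:
    """Cross-entropy of a predicted interaction probability against a 0/1 label."""
    if label not in (0, 1):
        raise ValueError(f"binary label must be 0 or 1, got {label!r}")
    p = float(prediction)
    if double_sigmoid_fidelity:
        # literal printed form: σ applied again inside the logs
        sig = lambda x: 1.0 / (1.0 + np.exp(-x))
        return float(-(label * np.log(max(sig(p), PROB_FLOOR))
                       + (1 - label) * np.log(max(sig(1.0 - p), PROB_FLOOR))))
    p = min(max(p, PROB_FLOOR), 1.0 - PROB_FLOOR)
    return float(-(label * np.log(p) + (1 - label) * np.log(1.0 - p)))


def label_smoothing_loss(prob_vector: np.ndarray, true_class: int,
                         epsilon: float = 0.15, n_classes: int | None = None) -> float:
    """Label-smoothing cross-entropy over an explicit probability vector."""
    p = np.asarray(prob_vector, dtype=float)
    n_c = n_classes if n_classes is not None else p.shape[0]
    if p.shape[0] != n_c:
        raise ValueError(f"probability vector has {p.shape[0]} entries, expected {n_c}")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    if not 0 <= true_class < n_c:
        raise ValueError(f"true_class {true_class} out of range for {n_c} classes")
    ce = -np.log(np.maximum(p, PROB_FLOOR))
    wrong = ce.sum() - ce[true_class]
    return float((1.0 - epsilon) * ce[true_class] + epsilon * wrong / (n_c - 1))
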