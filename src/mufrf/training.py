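"""Training orchestration, pair splitting/sampling, and evaluation metrics.

Training runs in three stages:

1. RotatE pretraining on the knowledge graph (``RotatEEmbedder``);
2. molecular-graph encoding of every drug (``GINEncoder``);
3. joint training of the fusion block and the pair classifier on
   minibatches of labeled DDI pairs, with the autoencoder reconstruction
   error added as an auxiliary loss.

Each labeled pair is presented in both orders during training and
predictions average the two orders, so pair ordering introduces no
artifacts.  Both view matrices are column-standardized before fusion.

Metrics follow the macro-averaged convention: per-class one-vs-rest
confusion counts; accuracy is the per-class mean of (TP+TN)/total (for
two classes this equals plain accuracy, which is also reported
separately); precision and recall are macro means of per-class ratios;
F1 is the harmonic mean of the macro precision and macro recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._autodiff import Tensor, concat, log_softmax, logsigmoid
from ._optim import Adam
from .chem import graphs_from_table
from .classifier import DenseHeadParams, assemble_drug_matrix, pair_logits_t
from .fusion import FusionParams, fusion_forward_t
from .gin import GINEncoder
from .rotate import RotatEEmbedder
from . import io as io_formats

logger = logging.getLogger(__name__)

TASK_DEFAULTS = {
    "binary": {"learning_rate": 0.0015, "batch_size": 3072, "n_heads": 2},
    "multiclass": {"learning_rate": 0.001, "batch_size": 1000, "n_heads": 4},
}


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

@dataclass
class MetricsReport:
    n_classes: int
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    acc: float
    precision: float
    recall: float
    f1: float
    plain_accuracy: float

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "tp": self.tp.tolist(), "tn": self.tn.tolist(),
            "fp": self.fp.tolist(), "fn": self.fn.tolist(),
            "acc": self.acc, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "plain_accuracy": self.plain_accuracy,
        }


def _metrics_from_counts(tp, tn, fp, fn) -> MetricsReport:
    n_classes = len(tp)
    total = tp + tn + fp + fn

    def safe_div(num, den, what):
        out = np.zeros(len(num))
        for i in range(len(num)):
            if den[i] == 0:
                logger.warning("%s undefined (0/0) for class %d — reported as 0", what, i)
            else:
                out[i] = num[i] / den[i]
        return out

    acc = float(np.mean((tp + tn) / total))
    precision = float(np.mean(safe_div(tp, tp + fp, "precision")))
    recall = float(np.mean(safe_div(tp, tp + fn, "recall")))
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    plain = float(tp.sum() / total[0]) if total[0] else 0.0
    return MetricsReport(n_classes, tp, tn, fp, fn, acc, precision, recall, f1, plain)


def compute_metrics(y_true, y_pred, n_classes: int | None = None) -> MetricsReport:
    """Macro-averaged Acc / Precision / Recall / F1 from one-vs-rest counts."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if n_classes is None:
        n_classes = max(2, int(max(y_true.max(initial=0), y_pred.max(initial=0))) + 1)
    tp = np.zeros(n_classes)
    tn = np.zeros(n_classes)
    fp = np.zeros(n_classes)
    fn = np.zeros(n_classes)
    for c in range(n_classes):
        is_c_true = y_true == c
        is_c_pred = y_pred == c
        tp[c] = np.sum(is_c_true & is_c_pred)
        fn[c] = np.sum(is_c_true & ~is_c_pred)
        fp[c] = np.sum(~is_c_true & is_c_pred)
        tn[c] = np.sum(~is_c_true & ~is_c_pred)
    return _metrics_from_counts(tp, tn, fp, fn)


# ---------------------------------------------------------------------
# splitting and negative-pair sampling
# ---------------------------------------------------------------------

def split_pairs(pairs, test_fraction: float = 0.2, seed: int = 0,
                stratify: bool = True):
    """Disjoint, exhaustive train/test split of labeled pairs."""
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = [p[2] for p in pairs]
    strat = labels if stratify else None
    try:
        train, test = train_test_split(pairs, test_size=test_fraction,
                                       random_state=seed, stratify=strat)
    except ValueError:
        logger.warning("stratified split impossible (a class has <2 members); "
                       "falling back to unstratified")
        train, test = train_test_split(pairs, test_size=test_fraction,
                                       random_state=seed, stratify=None)
    return train, test


def sample_negative_pairs(positive_pairs, drug_vocab, ratio: float = 1.0,
                          seed: int = 0) -> list[tuple[str, str, int]]:
    """Uniform unordered drug pairs outside the positive set, labeled 0."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    drugs = list(drug_vocab)
    pos_set = {frozenset((a, b)) for a, b, *_ in positive_pairs}
    n_pos = len({frozenset((a, b)) for a, b, *_ in positive_pairs})
    n_neg = int(round(ratio * len(positive_pairs)))
    candidates = [(a, b) for i, a in enumerate(drugs) for b in drugs[i + 1:]
                  if frozenset((a, b)) not in pos_set]
    if n_neg > len(candidates):
        raise ValueError(f"cannot sample {n_neg} negatives: only {len(candidates)} "
                         f"non-positive pairs exist ({n_pos} positives over "
                         f"{len(drugs)} drugs)")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_neg, replace=False)
    return [(candidates[k][0], candidates[k][1], 0) for k in chosen]


# ---------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------

class MuFRF(ClassifierMixin, BaseEstimator):
    """Multi-view DDI classifier: GIN structure view + RotatE KG view,
    multi-level latent fusion with attention, dense pair head.

    ``fit(X, y, smiles=..., kg_triples=...)`` takes an (n_pairs, 2)
    array of drug identifiers plus the side data: a drug_id → SMILES
    mapping and a list of KG triples.  ``learning_rate`` / ``batch_size``
    / ``n_heads`` default per task (binary: 0.0015 / 3072 / 2 heads,
    multi-class: 0.001 / 1000 / 4 heads).

    ``ablate`` disables components structurally: ``"c0"``/``"c1"``
    (conv branches), ``"add"``/``"product"`` (autoencoder branches),
    ``"attn"`` (attention block), ``"kg"``/``"structure"`` (whole views).
    """

    _VIEW_ABLATIONS = {"kg", "structure"}

    def __init__(self, task: str = "binary", learning_rate: float | None = None,
                 batch_size: int | None = None, epochs: int = 200,
                 n_heads: int | None = None, smooth_epsilon: float = 0.15,
                 recon_weight: float = 0.1, hidden_dense: int = 2048,
                 n_classes: int | None = None, ablate: tuple = (),
                 kg_epochs: int = 150, kg_negatives: int = 128,
                 kg_margin: float = 12.0, kg_learning_rate: float = 0.05,
                 gin_hidden_dim: int = 32, gin_layers: int = 5,
                 random_state: int = 0):
        self.task = task
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.n_heads = n_heads
        self.smooth_epsilon = smooth_epsilon
        self.recon_weight = recon_weight
        self.hidden_dense = hidden_dense
        self.n_classes = n_classes
        self.ablate = ablate
        self.kg_epochs = kg_epochs
        self.kg_negatives = kg_negatives
        self.kg_margin = kg_margin
        self.kg_learning_rate = kg_learning_rate
        self.gin_hidden_dim = gin_hidden_dim
        self.gin_layers = gin_layers
        self.random_state = random_state

    # -- helpers --------------------------------------------------------
    def _resolved(self, name):
        value = getattr(self, name)
        return TASK_DEFAULTS[self.task][name] if value is None else value

    def _standardize(self, mat, mean, std):
        return (mat - mean) / std

    def _task_loss(self, logits: Tensor, y: np.ndarray) -> Tensor:
        if self.task == "binary":
            z = logits.reshape(len(y))
            yt = Tensor(y.astype(float))
            return -(yt * logsigmoid(z) + (1.0 - yt) * logsigmoid(-z * 1.0)).mean()
        n_c = self.n_classes_
        eps = self.smooth_epsilon
        onehot = np.zeros((len(y), n_c))
        onehot[np.arange(len(y)), y] = 1.0
        lsm = log_softmax(logits, axis=1)
        ce_true = -(Tensor(onehot) * lsm).sum(axis=1)
        ce_all = -lsm.sum(axis=1)
        per = ce_true * (1.0 - eps) + (ce_all - ce_true) * (eps / (n_c - 1))
        return per.mean()

    # -- fitting --------------------------------------------------------
    def fit(self, X, y, *, smiles: dict[str, str], kg_triples):
        if self.task not in TASK_DEFAULTS:
            raise ValueError(f"task must be one of {tuple(TASK_DEFAULTS)}")
        pairs = [(str(a), str(b)) for a, b in np.asarray(X, dtype=object)]
        y = np.asarray(y, dtype=int)
        if len(pairs) != len(y):
            raise ValueError("X and y disagree in length")
        if len(pairs) == 0:
            raise ValueError("empty DDI training set")
        triples = [tuple(t) for t in kg_triples]
        kg_entities = {t[0] for t in triples} | {t[2] for t in triples}

        # drugs need both views: a parseable SMILES and a KG node
        graphs = graphs_from_table({d: s for d, s in smiles.items()}, on_error="skip")
        requested = sorted({d for p in pairs for d in p})
        drugs = [d for d in requested if d in graphs and d in kg_entities]
        dropped = set(requested) - set(drugs)
        if dropped:
            logger.warning("dropping %d drugs lacking a SMILES graph or KG node: %s",
                           len(dropped), sorted(dropped)[:10])
        keep = [k for k, (a, b) in enumerate(pairs)
                if a not in dropped and b not in dropped]
        pairs = [pairs[k] for k in keep]
        y = y[keep]
        if len(pairs) == 0:
            raise ValueError("no training pairs left after dropping unresolvable drugs")
        self.drug_ids_ = drugs
        self.drug_index_ = {d: i for i, d in enumerate(drugs)}

        self.n_classes_ = (2 if self.task == "binary"
                           else (self.n_classes or int(y.max()) + 1))
        self.classes_ = np.array([0, 1]) if self.task == "binary" else np.arange(self.n_classes_)

        seeds = np.random.SeedSequence(self.random_state).generate_state(4)

        # stage 1: KG pretraining
        self.kg_embedder_ = RotatEEmbedder(
            negatives_per_positive=self.kg_negatives, margin=self.kg_margin,
            learning_rate=self.kg_learning_rate, epochs=self.kg_epochs,
            random_state=int(seeds[0] % (2 ** 31)),
        ).fit(triples)
        eh = self.kg_embedder_.transform(drugs)

        # stage 2: structure encoding
        self.gin_encoder_ = GINEncoder(
            hidden_dim=self.gin_hidden_dim, n_layers=self.gin_layers,
            random_state=int(seeds[1] % (2 ** 31)),
        ).fit([graphs[d] for d in drugs])
        hg = self.gin_encoder_.transform([graphs[d] for d in drugs])

        # standardized (and possibly view-ablated) inputs to fusion
        self.hg_stats_ = (hg.mean(axis=0), hg.std(axis=0) + 1e-8)
        self.eh_stats_ = (eh.mean(axis=0), eh.std(axis=0) + 1e-8)
        hg_std = self._standardize(hg, *self.hg_stats_)
        eh_std = self._standardize(eh, *self.eh_stats_)
        ablate = tuple(self.ablate)
        if "structure" in ablate:
            hg_std = np.zeros_like(hg_std)
        if "kg" in ablate:
            eh_std = np.zeros_like(eh_std)
        self.hg_ = hg_std
        self.eh_ = eh_std

        # stage 3: joint fusion + classifier training
        rng = np.random.default_rng(int(seeds[2] % (2 ** 31)))
        fusion_ablate = tuple(a for a in ablate if a not in self._VIEW_ABLATIONS)
        self.fusion_params_ = FusionParams.init(self._resolved("n_heads"), rng,
                                                disabled=fusion_ablate)
        n_out = 1 if self.task == "binary" else self.n_classes_
        self.head_params_ = DenseHeadParams.init(n_out, rng, hidden=self.hidden_dense)
        params = self.fusion_params_.tensors() + self.head_params_.tensors()
        opt = Adam(params, lr=self._resolved("learning_rate"))

        i_idx = np.array([self.drug_index_[a] for a, b in pairs], dtype=np.intp)
        j_idx = np.array([self.drug_index_[b] for a, b in pairs], dtype=np.intp)
        # each pair in both orders, same label
        ii = np.concatenate([i_idx, j_idx])
        jj = np.concatenate([j_idx, i_idx])
        yy = np.concatenate([y, y])
        batch_size = min(self._resolved("batch_size"), len(yy))

        hg_t, eh_t = Tensor(hg_std), Tensor(eh_std)
        shuffle_rng = np.random.default_rng(int(seeds[3] % (2 ** 31)))
        self.loss_history_ = []
        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(len(yy))
            epoch_losses = []
            for start in range(0, len(yy), batch_size):
                sel = order[start:start + batch_size]
                opt.zero_grad()
                x_att, recon = fusion_forward_t(hg_t, eh_t, self.fusion_params_)
                d_mat = concat([x_att, hg_t, eh_t], axis=1)
                logits = pair_logits_t(d_mat, ii[sel], jj[sel], self.head_params_)
                loss = self._task_loss(logits, yy[sel]) + self.recon_weight * recon
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
            self.loss_history_.append(float(np.mean(epoch_losses)))

        # freeze the full drug representation matrix for inference
        x_att, _ = fusion_forward_t(hg_t, eh_t, self.fusion_params_)
        self.x_att_ = x_att.data
        self.D_ = assemble_drug_matrix(self.x_att_, hg_std, eh_std, self.drug_index_)
        return self

    # -- inference ------------------------------------------------------
    def _pair_indices(self, X):
        idx = []
        for a, b in np.asarray(X, dtype=object):
            a, b = str(a), str(b)
            if a not in self.drug_index_ or b not in self.drug_index_:
                raise KeyError(f"unknown drug in pair ({a!r}, {b!r})")
            idx.append((self.drug_index_[a], self.drug_index_[b]))
        arr = np.asarray(idx, dtype=np.intp)
        return arr[:, 0], arr[:, 1]

    def _logits(self, i_idx, j_idx) -> np.ndarray:
        d = Tensor(self.D_.matrix)
        return pair_logits_t(d, i_idx, j_idx, self.head_params_).data

    def predict_proba(self, X) -> np.ndarray:
        i_idx, j_idx = self._pair_indices(X)
        z_ij = self._logits(i_idx, j_idx)
        z_ji = self._logits(j_idx, i_idx)   # order-averaged prediction
        if self.task == "binary":
            p = 0.5 * (1 / (1 + np.exp(-z_ij[:, 0])) + 1 / (1 + np.exp(-z_ji[:, 0])))
            return np.column_stack([1 - p, p])

        def soft(z):
            e = np.exp(z - z.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)

        return 0.5 * (soft(z_ij) + soft(z_ji))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- persistence ----------------------------------------------------
    def save(self, out_dir):
        """Write an inference checkpoint (drug matrix + pair head + vocab)."""
        arrays = {
            "D": self.D_.matrix,
            "head_w1": self.head_params_.w1.data, "head_b1": self.head_params_.b1.data,
            "head_w2": self.head_params_.w2.data, "head_b2": self.head_params_.b2.data,
            "loss_history": np.asarray(self.loss_history_),
        }
        meta = {
            "task": self.task,
            "n_classes": int(self.n_classes_),
            "drug_ids": self.drug_ids_,
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
        }
        return io_formats.save_checkpoint(out_dir, meta, arrays)

    @classmethod
    def load(cls, ckpt_dir) -> "MuFRF":
        meta, arrays = io_formats.load_checkpoint(ckpt_dir)
        params = dict(meta["params"])
        params["ablate"] = tuple(params.get("ablate", ()))
        model = cls(**params)
        model.task = meta["task"]
        model.n_classes_ = meta["n_classes"]
        model.classes_ = (np.array([0, 1]) if model.task == "binary"
                          else np.arange(model.n_classes_))
        model.drug_ids_ = list(meta["drug_ids"])
        model.drug_index_ = {d: i for i, d in enumerate(model.drug_ids_)}
        model.D_ = assemble_drug_matrix(
            arrays["D"][:, :100], arrays["D"][:, 100:200], arrays["D"][:, 200:],
            model.drug_index_)
        n_out = 1 if model.task == "binary" else model.n_classes_
        head = DenseHeadParams.init(n_out, np.random.default_rng(0),
                                    hidden=arrays["head_w1"].shape[1])
        head.w1.data, head.b1.data = arrays["head_w1"], arrays["head_b1"]
        head.w2.data, head.b2.data = arrays["head_w2"], arrays["head_b2"]
        model.head_params_ = head
        model.loss_history_ = arrays["loss_history"].tolist()
        return model


# ---------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------

@dataclass
class TrainConfig:
    """End-to-end run configuration; ``None`` fields resolve per task."""

    task: str = "binary"
    learning_rate: float | None = None
    batch_size: int | None = None
    epochs: int = 200
    n_heads: int | None = None
    test_fraction: float = 0.2
    negative_pair_ratio: float = 1.0
    seed: int = 0
    optimizer: str = "adam"
    n_classes: int | None = None
    smooth_epsilon: float = 0.15
    recon_weight: float = 0.1
    hidden_dense: int = 2048
    ablate: tuple = ()
    folds: int | None = None
    kg: dict = field(default_factory=dict)
    gin: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def build_model(self) -> MuFRF:
        kg = dict(self.kg)
        gin = dict(self.gin)
        return MuFRF(
            task=self.task, learning_rate=self.learning_rate,
            batch_size=self.batch_size, epochs=self.epochs, n_heads=self.n_heads,
            smooth_epsilon=self.smooth_epsilon, recon_weight=self.recon_weight,
            hidden_dense=self.hidden_dense, n_classes=self.n_classes,
            ablate=tuple(self.ablate),
            kg_epochs=kg.get("epochs", 150),
            kg_negatives=kg.get("negatives_per_positive", 128),
            kg_margin=kg.get("margin", 12.0),
            kg_learning_rate=kg.get("learning_rate", 0.05),
            gin_hidden_dim=gin.get("hidden_dim", 32),
            gin_layers=gin.get("n_layers", 5),
            random_state=self.seed,
        )


def _prepare_pairs(ddi_pairs, config: TrainConfig):
    pairs = [(str(a), str(b), int(c)) for a, b, c in ddi_pairs]
    if config.task == "binary" and all(label == 1 for _, _, label in pairs):
        drugs = sorted({d for a, b, _ in pairs for d in (a, b)})
        negs = sample_negative_pairs(pairs, drugs, ratio=config.negative_pair_ratio,
                                     seed=config.seed)
        logger.info("sampled %d negative pairs (ratio %.2f)", len(negs),
                    config.negative_pair_ratio)
        pairs = pairs + negs
    return pairs


def _fit_and_score(train, test, drugs, kg_triples, config: TrainConfig):
    model = config.build_model().fit(
        [(a, b) for a, b, _ in train], [c for _, _, c in train],
        smiles=drugs, kg_triples=kg_triples)
    y_pred = model.predict([(a, b) for a, b, _ in test])
    y_true = [c for _, _, c in test]
    return model, compute_metrics(y_true, y_pred, n_classes=model.n_classes_)


def train_mufrf(drugs: dict[str, str], kg_triples, ddi_pairs,
                config: TrainConfig | None = None, out_dir=None
                ) -> tuple[MuFRF, MetricsReport]:
    """Full pipeline: negative sampling (binary), split, 3-stage fit, metrics.

    With ``config.folds`` set, runs stratified k-fold cross-validation and
    reports metrics from confusion counts pooled over folds; otherwise a
    single stratified 80/20-style split per ``test_fraction``.
    """
    config = config or TrainConfig()
    pairs = _prepare_pairs(ddi_pairs, config)
    if config.folds:
        labels = np.array([c for _, _, c in pairs])
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                              random_state=config.seed)
        counts = None
        model = None
        for train_ix, test_ix in skf.split(np.zeros(len(pairs)), labels):
            model, rep = _fit_and_score([pairs[k] for k in train_ix],
                                        [pairs[k] for k in test_ix],
                                        drugs, kg_triples, config)
            if counts is None:
                counts = [rep.tp, rep.tn, rep.fp, rep.fn]
            else:
                counts = [c + d for c, d in zip(counts, [rep.tp, rep.tn, rep.fp, rep.fn])]
        report = _metrics_from_counts(*counts)
    else:
        train, test = split_pairs(pairs, test_fraction=config.test_fraction,
                                  seed=config.seed, stratify=True)
        model, report = _fit_and_score(train, test, drugs, kg_triples, config)
    if out_dir is not None:
        path = model.save(out_dir)
        io_formats.write_metrics_report(report, path / "metrics.json")
    return model, report
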