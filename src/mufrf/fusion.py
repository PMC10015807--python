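"""Multi-level latent fusion of the structure view and the KG view.

Both views enter as n_drugs × 100 matrices (h_G from the GIN encoder,
e_h from RotatE).  Five 20-dim latent features are produced per drug:

* LF1 — "row stack": the two 100-vectors stacked into a 2×100 image per
  drug, passed through a 2-D convolution (kernel 2×10, 1→8 channels),
  then a 1-D convolution (kernel 5, 8→1 channels), then 1-D adaptive
  average pooling to length 20.
* LF2 — "column stack": the two vectors concatenated into a 1×200 image,
  same convolution cascade with a 1×10 first kernel.
* LF3 / LF4 — "scalar level": elementwise add / product of the views,
  compressed by a 100→60→20→60→100 autoencoder whose 20-wide middle
  activation is the latent feature (the reconstruction error is used as
  an auxiliary training loss).
* LF5 — the elementwise sum LF1+LF2+LF3+LF4.

X = [LF1‖LF2‖LF3‖LF4‖LF5] (n×100) is refined by one multi-head attention
encoder block — scaled dot-product attention with the drugs as tokens,
residual add + layer normalization, position-wise feed-forward, second
residual + normalization — yielding X_att of the same shape.

Convolutions operate per drug so the 2×10 kernel always spans the two
views of the same drug; channel counts (1→8, 8→1), stride 1 and
no padding are this implementation's choices.  All forward passes are
written over autodiff tensors so the whole block trains jointly with the
classifier; the public functions accept and return plain NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat, layer_norm, softmax

SHARED_DIM = 100
LATENT_DIM = 20
BRANCH_TAGS = ("LF1", "LF2", "LF3", "LF4", "LF5")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def adaptive_avg_pool_matrix(length: int, target: int) -> np.ndarray:
    """L×T matrix M with (x @ M) = 1-D adaptive average pooling of x to T bins.

    Bin i averages positions floor(i·L/T) .. ceil((i+1)·L/T) − 1.
    """
    m = np.zeros((length, target))
    for i in range(target):
        start = (i * length) // target
        end = -(-((i + 1) * length) // target)  # ceil
        m[start:end, i] = 1.0 / (end - start)
    return m


def _window_indices(length: int, kernel: int) -> np.ndarray:
    return np.arange(length - kernel + 1)[:, None] + np.arange(kernel)


@dataclass
class LatentFeature:
    matrix: np.ndarray  # n_drugs × 20
    branch_tag: str

    def __post_init__(self):
        if self.branch_tag not in BRANCH_TAGS:
            raise ValueError(f"branch_tag must be one of {BRANCH_TAGS}")
        if self.matrix.ndim != 2 or self.matrix.shape[1] != LATENT_DIM:
            raise ValueError(f"latent matrix must be n×{LATENT_DIM}, got {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("latent matrix contains non-finite entries")


@dataclass
class FusedMatrix:
    X: np.ndarray                 # n_drugs × 100 (LF1..LF5 blocks)
    X_att: np.ndarray | None = None


@dataclass
class ConvParams:
    """One concatenate-level branch: 2-D conv → 1-D conv → adaptive pool."""

    mode: str                        # "row_stack" | "col_stack"
    w2d: Tensor                      # patch_dim × channels
    b2d: Tensor
    w1d: Tensor                      # (channels·kernel1d) × 1
    b1d: Tensor
    kernel2d: tuple[int, int]
    kernel1d: int = 5
    channels: int = 8
    out_len: int = LATENT_DIM

    @classmethod
    def init(cls, mode: str, rng: np.random.Generator, kernel_width: int = 10,
             kernel1d: int = 5, channels: int = 8) -> "ConvParams":
        if mode not in ("row_stack", "col_stack"):
            raise ValueError("mode must be 'row_stack' or 'col_stack'")
        rows = 2 if mode == "row_stack" else 1
        patch = rows * kernel_width
        return cls(mode=mode,
                   w2d=_glorot(rng, patch, channels), b2d=_zeros(channels),
                   w1d=_glorot(rng, channels * kernel1d, 1), b1d=_zeros(1),
                   kernel2d=(rows, kernel_width), kernel1d=kernel1d, channels=channels)

    def tensors(self) -> list[Tensor]:
        return [self.w2d, self.b2d, self.w1d, self.b1d]


@dataclass
class AutoencoderParams:
    """100 → h1 → 20 → h1 → 100 autoencoder; the 20-wide middle layer is
    the latent feature."""

    w_enc1: Tensor
    b_enc1: Tensor
    w_enc2: Tensor
    b_enc2: Tensor
    w_dec1: Tensor
    b_dec1: Tensor
    w_dec2: Tensor
    b_dec2: Tensor
    widths: tuple[int, ...] = (SHARED_DIM, 60, LATENT_DIM, 60, SHARED_DIM)

    @classmethod
    def init(cls, rng: np.random.Generator, hidden: int = 60) -> "AutoencoderParams":
        d, z = SHARED_DIM, LATENT_DIM
        return cls(
            w_enc1=_glorot(rng, d, hidden), b_enc1=_zeros(hidden),
            w_enc2=_glorot(rng, hidden, z), b_enc2=_zeros(z),
            w_dec1=_glorot(rng, z, hidden), b_dec1=_zeros(hidden),
            w_dec2=_glorot(rng, hidden, d), b_dec2=_zeros(d),
            widths=(d, hidden, z, hidden, d),
        )

    def tensors(self) -> list[Tensor]:
        return [self.w_enc1, self.b_enc1, self.w_enc2, self.b_enc2,
                self.w_dec1, self.b_dec1, self.w_dec2, self.b_dec2]


@dataclass
class AttentionParams:
    """One transformer encoder block over the drug tokens."""

    n_heads: int
    wq: list[Tensor]
    wk: list[Tensor]
    wv: list[Tensor]
    wo: Tensor
    ln1_g: Tensor
    ln1_b: Tensor
    ln2_g: Tensor
    ln2_b: Tensor
    w_ff1: Tensor
    b_ff1: Tensor
    w_ff2: Tensor
    b_ff2: Tensor
    d_in: int = SHARED_DIM

    @classmethod
    def init(cls, n_heads: int, rng: np.random.Generator, d_in: int = SHARED_DIM,
             ffn_dim: int = 200) -> "AttentionParams":
        if d_in % n_heads:
            raise ValueError(f"d_in={d_in} is not divisible by n_heads={n_heads}")
        d_k = d_in // n_heads
        return cls(
            n_heads=n_heads,
            wq=[_glorot(rng, d_in, d_k) for _ in range(n_heads)],
            wk=[_glorot(rng, d_in, d_k) for _ in range(n_heads)],
            wv=[_glorot(rng, d_in, d_k) for _ in range(n_heads)],
            wo=_glorot(rng, n_heads * d_k, d_in),
            ln1_g=Tensor(np.ones(d_in), requires_grad=True), ln1_b=_zeros(d_in),
            ln2_g=Tensor(np.ones(d_in), requires_grad=True), ln2_b=_zeros(d_in),
            w_ff1=_glorot(rng, d_in, ffn_dim), b_ff1=_zeros(ffn_dim),
            w_ff2=_glorot(rng, ffn_dim, d_in), b_ff2=_zeros(d_in),
            d_in=d_in,
        )

    @property
    def d_k(self) -> int:
        return self.d_in // self.n_heads

    def tensors(self) -> list[Tensor]:
        return (self.wq + self.wk + self.wv
                + [self.wo, self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b,
                   self.w_ff1, self.b_ff1, self.w_ff2, self.b_ff2])


# -- tensor-level forward passes ---------------------------------------

def _check_views(hg, eh):
    if hg.shape != eh.shape:
        raise ValueError(f"view shapes differ: {hg.shape} vs {eh.shape}")
    if hg.shape[1] != SHARED_DIM:
        raise ValueError(f"views must be n×{SHARED_DIM}, got {hg.shape}")


def concat_level_t(hg: Tensor, eh: Tensor, params: ConvParams) -> Tensor:
    _check_views(hg.data, eh.data)
    n = hg.shape[0]
    if params.mode == "row_stack":
        img = concat([hg.reshape(n, 1, SHARED_DIM), eh.reshape(n, 1, SHARED_DIM)], axis=1)
        width = SHARED_DIM
    else:
        img = concat([hg, eh], axis=1).reshape(n, 1, 2 * SHARED_DIM)
        width = 2 * SHARED_DIM
    rows, kw = params.kernel2d
    n_pos = width - kw + 1
    # 2-D conv as im2col matmul: (n, n_pos, rows·kw) @ (rows·kw, channels)
    patches = img.take(_window_indices(width, kw), axis=2)      # n × rows × n_pos × kw
    patches = patches.transpose(0, 2, 1, 3).reshape(n, n_pos, rows * kw)
    h1 = (patches @ params.w2d + params.b2d).relu()             # n × n_pos × channels
    # 1-D conv across positions, all channels in
    n_pos2 = n_pos - params.kernel1d + 1
    windows = h1.take(_window_indices(n_pos, params.kernel1d), axis=1)
    windows = windows.reshape(n, n_pos2, params.kernel1d * params.channels)
    h2 = (windows @ params.w1d + params.b1d).relu().reshape(n, n_pos2)
    return h2 @ Tensor(adaptive_avg_pool_matrix(n_pos2, params.out_len))


def ae_encode_t(x: Tensor, params: AutoencoderParams) -> Tensor:
    h = (x @ params.w_enc1 + params.b_enc1).relu()
    return h @ params.w_enc2 + params.b_enc2


def ae_decode_t(z: Tensor, params: AutoencoderParams) -> Tensor:
    h = (z @ params.w_dec1 + params.b_dec1).relu()
    return h @ params.w_dec2 + params.b_dec2


def scalar_level_t(hg: Tensor, eh: Tensor, mode: str, params: AutoencoderParams) -> Tensor:
    _check_views(hg.data, eh.data)
    if mode not in ("add", "product"):
        raise ValueError("mode must be 'add' or 'product'")
    fused = hg + eh if mode == "add" else hg * eh
    return ae_encode_t(fused, params)


def ae_reconstruction_loss_t(fused: Tensor, params: AutoencoderParams) -> Tensor:
    recon = ae_decode_t(ae_encode_t(fused, params), params)
    diff = recon - fused
    return (diff * diff).mean()


def multi_head_attention_t(x: Tensor, params: AttentionParams) -> Tensor:
    if x.shape[1] != params.d_in:
        raise ValueError(f"input width {x.shape[1]} != d_in {params.d_in}")
    scale = 1.0 / np.sqrt(params.d_k)
    heads = []
    for i in range(params.n_heads):
        q = x @ params.wq[i]
        k = x @ params.wk[i]
        v = x @ params.wv[i]
        attn = softmax(q @ k.T * scale, axis=-1)
        heads.append(attn @ v)
    att_out = concat(heads, axis=1) @ params.wo
    y = layer_norm(x + att_out, params.ln1_g, params.ln1_b)
    ffn = (y @ params.w_ff1 + params.b_ff1).relu() @ params.w_ff2 + params.b_ff2
    return layer_norm(y + ffn, params.ln2_g, params.ln2_b)


# -- public NumPy surface ----------------------------------------------

def concat_level(hG_mat: np.ndarray, eh_mat: np.ndarray, mode: str,
                 params: ConvParams) -> LatentFeature:
    """Concatenate-level branch: returns LF1 (row_stack) or LF2 (col_stack)."""
    if params.mode != mode:
        raise ValueError(f"params were initialized for mode {params.mode!r}, got {mode!r}")
    out = concat_level_t(Tensor(hG_mat), Tensor(eh_mat), params)
    return LatentFeature(out.data, "LF1" if mode == "row_stack" else "LF2")


def scalar_level(hG_mat: np.ndarray, eh_mat: np.ndarray, mode: str,
                 params: AutoencoderParams) -> LatentFeature:
    """Scalar-level branch: returns LF3 (add) or LF4 (product)."""
    out = scalar_level_t(Tensor(hG_mat), Tensor(eh_mat), mode, params)
    return LatentFeature(out.data, "LF3" if mode == "add" else "LF4")


def ae_reconstruction_loss(fused: np.ndarray, params: AutoencoderParams) -> float:
    """Mean squared error of the autoencoder's reconstruction of ``fused``."""
    return float(ae_reconstruction_loss_t(Tensor(fused), params).data)


def fuse_latents(lf1: LatentFeature, lf2: LatentFeature, lf3: LatentFeature,
                 lf4: LatentFeature) -> FusedMatrix:
    """LF5 = LF1+LF2+LF3+LF4; X = [LF1‖LF2‖LF3‖LF4‖LF5] (n×100)."""
    mats = [lf1.matrix, lf2.matrix, lf3.matrix, lf4.matrix]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"latent features disagree in shape: {shapes}")
    lf5 = mats[0] + mats[1] + mats[2] + mats[3]
    return FusedMatrix(X=np.concatenate(mats + [lf5], axis=1))


def multi_head_attention(X: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Refine the fused matrix with one attention encoder block (drugs = tokens)."""
    return multi_head_attention_t(Tensor(np.asarray(X, dtype=float)), params).data


def attention_weights(X: np.ndarray, params: AttentionParams) -> list[np.ndarray]:
    """Per-head softmax(QKᵀ/√d_k) matrices (rows sum to 1); diagnostic surface."""
    xt = Tensor(np.asarray(X, dtype=float))
    scale = 1.0 / np.sqrt(params.d_k)
    out = []
    for i in range(params.n_heads):
        q = (xt @ params.wq[i]).data
        k = (xt @ params.wk[i]).data
        logits = q @ k.T * scale
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        out.append(e / e.sum(axis=-1, keepdims=True))
    return out


@dataclass
class FusionParams:
    """All trainable parameters of the fusion block."""

    conv_row: ConvParams
    conv_col: ConvParams
    ae_add: AutoencoderParams
    ae_product: AutoencoderParams
    attention: AttentionParams
    disabled: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def init(cls, n_heads: int, rng: np.random.Generator,
             disabled: tuple[str, ...] = ()) -> "FusionParams":
        known = {"c0", "c1", "add", "product", "attn"}
        if not set(disabled) <= known:
            raise ValueError(f"unknown ablation tags {set(disabled) - known}")
        return cls(conv_row=ConvParams.init("row_stack", rng),
                   conv_col=ConvParams.init("col_stack", rng),
                   ae_add=AutoencoderParams.init(rng),
                   ae_product=AutoencoderParams.init(rng),
                   attention=AttentionParams.init(n_heads, rng),
                   disabled=tuple(disabled))

    def tensors(self) -> list[Tensor]:
        return (self.conv_row.tensors() + self.conv_col.tensors()
                + self.ae_add.tensors() + self.ae_product.tensors()
                + self.attention.tensors())


def fusion_forward_t(hg: Tensor, eh: Tensor, params: FusionParams
                     ) -> tuple[Tensor, Tensor]:
    """Full fusion block over tensors; returns (X_att, reconstruction loss).

    Ablated branches (``params.disabled``) contribute an all-zero latent
    of matching shape; ``"attn"`` ablation passes X through unchanged.
    """
    n = hg.shape[0]
    zero = Tensor(np.zeros((n, LATENT_DIM)))
    dis = params.disabled
    # row stacking (2×100 image) is concatenation along dim 0, column
    # stacking (1×200) along dim 1 — the c0/c1 ablation tags follow that
    lf1 = zero if "c0" in dis else concat_level_t(hg, eh, params.conv_row)
    lf2 = zero if "c1" in dis else concat_level_t(hg, eh, params.conv_col)
    lf3 = zero if "add" in dis else scalar_level_t(hg, eh, "add", params.ae_add)
    lf4 = zero if "product" in dis else scalar_level_t(hg, eh, "product", params.ae_product)
    lf5 = lf1 + lf2 + lf3 + lf4
    x = concat([lf1, lf2, lf3, lf4, lf5], axis=1)
    x_att = x if "attn" in dis else multi_head_attention_t(x, params.attention)

    recon = Tensor(np.zeros(()))
    if "add" not in dis:
        recon = recon + ae_reconstruction_loss_t(hg + eh, params.ae_add)
    if "product" not in dis:
        recon = recon + ae_reconstruction_loss_t(hg * eh, params.ae_product)
    return x_att, recon
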