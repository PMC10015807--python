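# Methods

This note records the model as implemented, the defaults and why, what the
synthetic worlds do and do not emulate, and the numerical choices made where
the design was genuinely open.

## Pipeline

Training proceeds in three stages, each seed-deterministic:

1. **KG pretraining.** RotatE embeddings are learned for all KG entities.
   Entities live in C^50 (real and imaginary parts stored separately, so the
   flattened vector has the shared width 100); relations are phase vectors
   θ ∈ [−π, π)^50 realized as cos θ + i sin θ. Storing phases rather than
   complex numbers makes the unit-modulus constraint structural — it cannot
   drift during optimization. The loss is the margin-based negative-sampling
   form −ln σ(γ − s⁺) − (1/k)Σ ln σ(s⁻ − γ) with uniform corruption of head
   or tail (fair coin), filtered against known positives and resampled per
   epoch. An alternative convention that transcribes the loss literally as
   −Σ ln σ(s⁺ − s⁻ − γ) is selectable (`loss_convention="as-printed"`); it
   rewards *large* positive distances, contradicting the score's
   lower-is-better semantics, so it is retained for fidelity testing only.
2. **Structure encoding.** Each drug's SMILES becomes a hydrogen-suppressed
   bidirectional graph. Atom features are one-hot element (9 common
   organics + "other") plus one-hot heavy degree; bond features are one-hot
   type (single/double/triple/aromatic). A K=5-layer GIN with hidden width
   32 runs sum-aggregated message passing; edge features are linearly
   projected to the node width and added to the source-node message. The
   readout concatenates per-depth node sums ((K+1)·32 = 192 dims) and a
   single linear map projects to 100. The GIN weights are *fixed random*
   (drawn from the run seed, never trained): the encoder is a deterministic
   random-feature structural fingerprint, which preserves the
   sum-aggregation injectivity the architecture is chosen for and is all
   the fusion stage needs at this scale. (Published variants initialize
   from large pretrained checkpoints; reproducing trained weights is out of
   scope here.)
3. **Joint fusion + classifier training.** Both view matrices are
   column-standardized (fit-time statistics), fused into five 20-dim
   latents, refined by one attention block, concatenated with the raw views
   into n×300 representations, and scored pairwise by the dense head. All
   fusion and head parameters train jointly by Adam against the task loss
   plus λ·(autoencoder reconstruction MSE), λ = 0.1. The autoencoders are
   trained jointly rather than pretrained — with a shared loss the latent
   stays predictive *and* reconstructive, and one optimizer loop keeps the
   procedure simple and deterministic.

## Interpretation choices (open design points)

* **Per-drug convolution.** Stacking all drugs into a 2n×k matrix before a
  2×10 convolution would mix rows of unrelated drugs. The convolution is
  therefore applied per drug: a 2×100 image (row stack) or 1×200 image
  (column stack) per drug, so the kernel always spans the two views of the
  same drug. Channels 1→8 (2-D stage) and 8→1 (1-D stage), stride 1, no
  padding; the final 1-D adaptive average pool absorbs length differences
  to exactly 20.
* **Attention tokens are drugs.** Q = XW_Q etc. operate on the n×100 fused
  matrix, so the attention tokens are the drugs of the processed matrix.
  The full drug matrix is used during both training and inference (at desk
  scale every step can attend over all drugs), and it is frozen after
  fitting, making predictions deterministic and independent of query batch
  composition. Head width is d_in/h by construction: 50 at two heads
  (binary default), 25 at four heads (multi-class default). The
  feed-forward sublayer has width 200.
* **Graph-view projection.** The readout-to-100 map is a single linear
  layer; convolutions are reserved for the fusion module, where their
  kernel sizes are specified.
* **Pair ordering.** The head scores ordered concatenations [d_i ‖ d_j], so
  f(i,j) ≠ f(j,i) in general. Training presents every labeled pair in both
  orders with the same label; inference averages the two orders. This
  removes order artifacts without constraining the head.
* **Binary loss.** Standard single-sigmoid cross-entropy on the predicted
  probability. The literal double-sigmoid form (σ reapplied inside the
  logs) is available behind `double_sigmoid_fidelity`; it cannot reach loss
  0 and is not used for training. Probabilities are floored at 1e−12
  inside logarithms.
* **Metrics.** Accuracy is reported in two forms, labeled distinctly: the
  per-class mean of (TP+TN)/total over one-vs-rest confusion counts
  (`acc`, the "mean accuracy" convention; identical to plain accuracy for
  two classes) and plain accuracy (`plain_accuracy`). Precision and recall
  are macro means of per-class ratios with 0/0 reported as 0 (logged); F1
  is the harmonic mean of the macro precision and macro recall.

## Defaults

| parameter | default | note |
|---|---|---|
| shared embedding width | 100 | all fusion contracts assume it |
| complex dimension d_c | 50 | 2·d_c = 100 flattened reals |
| margin γ | 12.0 | unstated in the source convention; common RotatE choice |
| negatives per positive | 128 | selection peak in the reference experiments |
| KG learning rate / epochs | 0.05 / 200 (150 inside the full pipeline) | full-batch Adam at toy scale |
| GIN depth / hidden | 5 / 32 | deep enough for ring-scale motifs |
| learning rate | 0.0015 binary / 0.001 multi-class | task defaults |
| batch size | 3072 binary / 1000 multi-class | ≥ toy dataset ⇒ full batch |
| attention heads | 2 binary / 4 multi-class | d_k = 50 / 25 |
| dense hidden | 2048 | pair head capacity |
| label smoothing ε | 0.15 | multi-class only |
| reconstruction weight λ | 0.1 | auxiliary AE loss |
| epochs | 200 | estimator default; desk-scale studies in the test suite use 60 joint / 100 KG epochs, which already saturate the toy task |
| test fraction | 0.2 | stratified split |
| negative-pair ratio | 1:1 | used only when the binary table has no 0 labels |

## The synthetic worlds

The default world has 60 drugs (SMILES from a validated pool of simple
aromatic and aliphatic molecules, half each), 20 extra KG entities (2 group
hubs + proteins), ≈300 triples and 400 labeled pairs. Each drug belongs to
one of two KG groups (hub edge) and one of two structural classes
(aromatic/aliphatic); planted relation layers add a symmetric relation
(emitted closed under (h,r,t)→(t,r,h)), an inverse pair, and a
compositional relation for the pattern-recovery tests. The DDI rule is the
conjunction "same hub AND same structural class", with pairs sampled
label-balanced (positive rate ≈ 0.5); the multi-class variant labels the
four (structure-match × group-match) combinations. A nearest-neighbor
baseline over the concatenated raw views exceeds 0.7 accuracy, so the rule
is learnable and the end-to-end recovery bound measures the pipeline, not
an impossible task; label-shuffled training drops to chance, so it is not
leakage either.

What the worlds do **not** emulate: real pharmacology (labels are
synthetic); KG scale and relation inventory (DRKG has millions of triples
and ~10⁵ entities); class imbalance and noisy or missing labels; molecule
sizes and chemistry beyond simple organics; distribution shift between
train and test drugs (splits are over pairs, not drugs — a drug seen in
training can appear in a test pair, as in the transductive formulation).
Passing tests therefore demonstrate that the architecture recovers a
planted cross-view signal at toy scale, not benchmark performance on real
DDI corpora.

## Numerical notes

* All tensors are float64; computation is NumPy-only and single-threaded
  deterministic: the same seed reproduces bit-identical checkpoints.
* The triple score adds 1e−12 inside the square root during training so the
  gradient at exact-zero distance is finite.
* Softmax and log-softmax are max-shifted; log σ uses the stable
  min(x,0) − log1p(e^{−|x|}) form.
* Attention layer normalization uses eps 1e−5.
* Degenerate inputs: single-drug batches work through every fusion branch
  (no cross-drug dependence except attention, where a single token receives
  weight 1); molecules without bonds (single heavy atom) encode through the
  empty neighbor sum; a class never predicted yields a logged 0 in the
  macro ratios rather than NaN.
* Unparsable SMILES raise a typed error carrying the drug id; table readers
  can skip-with-warning (default) or abort. Drugs lacking either view are
  dropped with a warning before training.

## Limitations

Desk-scale only: dense full-vocabulary Adam updates and full-matrix
attention are O(n²) in drugs and would not scale to real corpora without
minibatched attention and sparse embedding updates. The GIN is a fixed
random encoder — adequate here, but per-task fine-tuning of the structure
view is unimplemented. Checkpoints store the frozen drug matrix and pair
head (sufficient for inference over the fitted drug vocabulary); embedding
new drugs requires refitting.
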