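# Methods

This note documents the model implemented in `pldiffusion`, the choices
made where the design was genuinely open, and what the desk-scale tests do
and do not establish.

## State space and diffusion process

A protein–ligand complex is represented as an ordered token list — residues
first (one Cα coordinate each), then ligand heavy atoms (one coordinate
each) — with all coordinates in Å. Distributions over coordinates live in
the linear subspace with centroid at the origin: noise is drawn as i.i.d.
standard normal and then mean-centered, which makes every construction
translation-invariant by design. A consequence worth remembering when
checking sample statistics: the per-coordinate marginal variance of a
centered n-token standard Gaussian is (n−1)/n, not 1.

The forward process is variance-preserving (VP): q(z_t|x) = N(α_t x, σ_t²I)
with α_t² + σ_t² = 1. The signal/noise relation admits a second,
literal reading (α_t = 1 − σ_t²); the transition and posterior algebra the
sampler relies on requires the VP form, so VP is what the registered
schedules implement. The literal variant ships as `LiteralAlphaSchedule`
for comparison but is deliberately excluded from the registry, so that
"every registered schedule is VP" is an enforceable invariant.

Two schedules are registered:

* `cosine` (default): α_t = cos(πt/2)(1 − 2ε₀) + ε₀ with ε₀ = 1e−4. The
  offset keeps α strictly positive and pins the endpoints
  (α₀ = 1 − 1e−4, α₁ = 1e−4).
* `linear_logsnr`: log-SNR linear from +10 to −10, α_t² = sigmoid(λ(t)).

Both are monotone and satisfy the VP identity to 1e−12 on a dense grid
(tested). The step count defaults to T = 64, a desk-scale choice that the
oracle-recovery test shows is ample for accurate ancestral reconstruction.

Ancestral sampling uses the noise parameterization. The reverse mean is
computed in its ε̂ form, (1/α_{t|s}) z_t − (σ²_{t|s}/(α_{t|s}σ_t)) ε̂, and
asserted at run time against the posterior mean with x̂ = (z_t − σ_t ε̂)/α_t
substituted; the two are algebraically identical and agree to 1e−10.
During generation the implied x̂ is clipped coordinate-wise to ±50 Å
(configurable, disable with `clip_denoised=None`) before the reverse step.
Near t = 1 the division by α_t amplifies any miscalibration of ε̂
enormously; clipping the denoised estimate is the standard stabilization
and is exactly inactive when the noise model is well calibrated (the
oracle-recovery test passes with clipping active because the oracle's x̂
never exceeds the bound). The final decode takes the mean z₀/α₀; adding
decoder noise is available behind a flag.

The sequence is decoded at the end of sampling (argmax of the final logits
at masked positions). Masked tokens stay masked in featurization
throughout the reverse loop — the simplest consistent reading; per-step
sequence resampling was considered and deferred since nothing downstream
depends on it at desk scale.

## Featurization

Single representation (c_m channels, default 64; 16 in the tiny config):

* residue rows: learned 22-token embedding (20 amino acids + UNKNOWN +
  MASK) plus a LayerNorm-then-linear map of a pluggable per-residue
  embedder's output. The embedder interface is where a protein language
  model plugs in; the shipped `StubEmbedder` is a deterministic hash-seeded
  Gaussian draw keyed by (token, position, seed), which preserves the
  contract (fixed dimension, determinism, prefix stability) without any
  network access. Embeddings are computed on the *masked* sequence to avoid
  leaking masked identities.
* ligand-atom rows: the sum of per-field categorical embeddings over nine
  atom fields (atomic number, chirality, degree, formal charge, attached
  hydrogens, radical electrons, hybridization, aromaticity, ring
  membership). Every field has a trailing out-of-vocabulary bucket.

Pair representation (c_z channels, default 32; 8 tiny) accumulates:

* clipped relative-position encodings on the residue–residue block:
  offset clamped to ±r_max (default 32), one-hot, linear;
* bond-feature embeddings (type, stereochemistry, conjugation) injected
  symmetrically at the two ordered entries of each bonded atom pair — the
  symmetric choice keeps the pair tensor's distance block symmetric;
* Gaussian RBF embeddings of current inter-token distances: 16 centers
  evenly spaced on [0, 20] Å, width equal to the spacing (zeros when no
  coordinates are given);
* a broadcast sinusoidal time embedding with frequency ladder π·2^k, so
  t = 0 maps to (sin, cos) = (0, 1) exactly.

The featurizer is re-run at every reverse step with the current latent and
time, so distance features always describe the state being denoised.
Geometry enters only through distances; this is the root of the model's
SE(3) equivariance.

A masked ligand contributes zero tokens rather than a placeholder token,
which keeps the noise-field sum well defined; a placeholder variant would
be a small featurizer extension if ever needed.

## Trunk

Each of n_blocks (default 4; 1 tiny) blocks applies, residually and in this
order: SRA → OPU → triangle-outgoing → triangle-incoming. Weights are
per-block (the standard choice for Evoformer-style stacks). No dropout.

* **SRA** is gated multi-head attention over tokens with an additive bias
  per head derived from LayerNorm of the pair representation. Head width
  C = 65 and N_head = 4 are the published defaults and are kept even though
  65 is an odd-looking width; both are configurable, and the tiny test
  config uses 8×2.
* **OPU** projects the normalized single representation to two C = 32
  vectors a_i, b_j and maps the flattened outer product a_i ⊗ b_j linearly
  to the pair channels, with no averaging over any axis. The pairwise
  output requires the cross form (a_i with b_j); the i-with-i form does not
  produce a pair tensor.
* **Triangle updates** follow the standard multiplicative form: gated
  linear projections a, b of LayerNorm(z), k-sums a_ik ⊙ b_jk (outgoing)
  or a_ki ⊙ b_kj (incoming), then a gated output projection of
  LayerNorm(u). Hidden width defaults to c_z. One identity worth noting:
  outgoing(z) equals incoming(zᵀ) transposed only when the a/b projections
  are also swapped — the output gate reads the untransposed entry — and the
  test checks that exact form.

The trunk never reads coordinates; its interface takes only the two
representation tensors.

## Equivariant denoiser

The final pair tensor is symmetrized, (z + zᵀ)/2, and an entrywise MLP
(c_z → 32 → 1) produces the weight matrix W, exactly symmetric by
construction. The noise field is the W-weighted sum of unit relative
difference vectors with the j = i term excluded (it is 0/0 otherwise) and a
δ = 1e−6 Å regularizer in the denominator so exactly coincident tokens
contribute a vanishing, finite term. The centroid over **all** tokens
(protein and ligand jointly) is subtracted, keeping the prediction in the
same zero-centroid subspace as the latents. With symmetric W the
pre-centering field already sums to zero — each (i, j) pair contributes
equal and opposite vectors — so centering is a numerical safeguard rather
than a correction.

The sequence head is a single linear map c_m → 20 on residue rows: the
smallest head that serves the losses. Config can deepen it if needed.

## Losses and training

* **L_WS**: per-sample Euclidean norm ‖ε − ε̂‖ over all atoms and
  coordinates. The sum over diffusion times is estimated by one uniform
  t-draw per example per step (standard Monte-Carlo treatment).
* **L_KL**: the sequence forward process mixes the one-hot residue
  distribution toward uniform on the same clock as coordinates,
  q_t = α_t² p + (1 − α_t²)/20. The loss is the mean over residues of
  KL(target_{t−Δ} ‖ pred_{t−Δ}) with Δ = 1/T, weighted by
  β(t) = 1 − α_t²/α_{t−Δ}² — the discrete-time noise increment, which is
  non-negative for a monotone schedule. This is the least-pinned-down
  component of the objective; the weight and the mixing law are package
  choices, documented here, and the KL itself is floored at 1e−8 in the
  predicted probabilities before the log (clipping is logged).
* **L_CE**: mean categorical cross-entropy at the masked positions only
  (an all-positions variant is a one-argument change). An empty mask set —
  which the two-stage masking law produces regularly — contributes 0 and
  logs once.
* Total = unweighted sum; per-component weights exist in code only for
  experimentation and default to 1.

Masking is two-stage: effective ratio ~ Uniform(0, mask_ratio), then
round(ratio·n) positions uniformly without replacement, re-drawn every
training step. The expected masked fraction is therefore mask_ratio/2
(7.5 residues per 100 at the 0.15 default), and training sees every
masking level from 0 up to the ceiling. Whether masked positions should be
fixed per example instead is not determinable from first principles;
re-drawing is the implemented choice and a fixed-mask variant is trivially
obtained by fixing the seed.

Optimization is plain Adam (lr 1e-2 in the desk-scale default config,
β₁ = 0.9, β₂ = 0.999). A 500-step seeded run on one 12-residue toy complex
cuts the total loss by well over half from its step-10 moving average —
the suite's trainability smoke test — and identical seeds reproduce the
loss trace bit-for-bit. Autodiff gradients are verified against central
finite differences to 1e−4 relative on randomly chosen weights.

## Evaluation metrics

All structural metrics act on 1:1-corresponding Cα lists (fixed-length
redesign needs no alignment-based residue mapping).

* **RMSD**: Kabsch superposition — centroid alignment plus SVD with the
  determinant sign correction, so the rotation is always proper. The
  degenerate all-coincident case returns the identity rotation by
  convention. Cross-checked against an independent solver and a
  hierarchical rotation-grid search.
* **TM-score**: d₀ = max(1.24·(N−15)^{1/3} − 1.8, 0.5) (the floor matters
  for tiny N). The maximization over rigid motions runs iteratively
  reweighted superposition (weights from the TM kernel derivative) from a
  Kabsch initialization plus a few seeded random restarts, returning the
  best value; a rotation-grid oracle in the tests lower-bounds the result.
  Fragment-seeding as in full TM-align is omitted — at the equal-length,
  desk-scale regime the IRLS+restarts optimizer already dominates the grid
  oracle.
* **Contact overlap**: Jaccard index of contact sets with strict
  inequality ‖p_i − p_j‖ < r_c, default r_c = 8 Å, i ≠ j (a sequence-
  separation filter is available but off by default). Both-sets-empty is
  defined as 1.0: two structures with no contacts agree vacuously.
* **Diversity**: mean pairwise Levenshtein distance (unit costs), computed
  with edlib and verified against a dynamic-programming oracle.

## Synthetic fixtures

`generate_toy_complex` emulates the *shape* of a training example: a
uniform-random 20-letter sequence, a self-avoiding random-walk Cα trace
with steps of 3.8 ± 0.3 Å and a 2.5 Å non-consecutive exclusion radius,
and ligand heavy atoms placed 1.5–4 Å around a surface residue (chosen
among the third of residues farthest from the centroid), all centered and
fully determined by (n_res, smiles, seed). It does **not** emulate
secondary structure, side chains, realistic ligand geometry, or binding
chemistry. Passing tests on these fixtures therefore establishes the
mathematical properties of the machinery — equivariance, diffusion
identities, loss behavior, metric correctness, trainability — and nothing
about design quality on real proteins, which requires real-scale training
data and compute. The shipped ligand menu (ethanol, benzene, acetic acid,
masked `*`) covers the aromaticity, ring, conjugation and masking branches
of the featurizer.

## Numerical choices

Everything runs in float64 on a compact reverse-mode autodiff engine
written for this package (einsum-based contractions, softmax/log-softmax
primitives, numerically stable sigmoid). LayerNorm uses ε = 1e−5.
Probability floors: 1e−8 in KL. Coincident-point regularizer: δ = 1e−6 Å.
Latent-centroid tolerance: 1e−6. Non-finite intermediates raise
immediately, naming the trunk block or sampler step. All randomness flows
through explicitly passed seeds or `numpy` Generators; two runs with the
same seed are bitwise identical.

## Known limitations

* Desk-scale only: default dimensions train in seconds on a CPU but have
  no capacity for real protein–ligand distributions.
* The stub embedder carries no evolutionary information; results with a
  real protein language model plugged into the embedder interface will
  differ qualitatively.
* The KL component's temporal weighting is a documented package choice
  (see above), not a uniquely determined form.
* No side chains, no ligand internal geometry restraints, no learned
  variances, no accelerated (DDIM-style) samplers.
* PDB support covers the ATOM/HETATM/TER/END subset used by the package's
  own writers; mmCIF and multi-model files are out of scope.
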