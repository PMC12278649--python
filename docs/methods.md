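# Methods

## The model

`pairview` predicts properties of drug pairs — cell-line synergy, xenograft
tumor-volume response, and typed drug-drug interactions (DDI) — by treating
every *modality pair* of the two drugs as an independent training instance.

Eight drug modalities are supported: SMILES string, 2D molecular graph,
target gene set, 3D-augmented view, textual description, ontology position,
27-dimensional side-effect indicator, and 60-dimensional sensitivity profile
(drug response across a reference cell-line panel).  A drug carries any
subset of these; absence is recorded, never imputed.

**Projector.**  Eight modality-specific encoders map payloads into a shared
d_hid-dimensional space, each ending in one linear transformation layer:

- *SMILES*: a transformer encoder over a frozen regex token vocabulary
  (bracket atoms, Cl/Br, ring digits, bond symbols) with a trailing CLS
  token; the CLS-position embedding is the sequence representation.
- *2D graph*: message passing over RDKit-derived molecular graphs (element
  one-hot, degree 0–6, formal charge −2…+2, aromatic flag), followed by one
  transformation of the concatenated mean- and max-pooled node embeddings —
  exactly permutation invariant.
- *Targets*: each target gene is expanded with its k_g strongest PPI
  neighbors (default k_g = 5, ties broken by gene id); the expanded set is
  mean-pooled over a learnable gene-embedding table shared with the
  cell-line context encoder.  Pooling replaces concatenation over a
  variable-size set: it is permutation invariant and set-size independent
  (sum pooling is a config option).
- *3D view*: a pluggable precomputed vector per drug, or a 2D graph encoder
  contrastively aligned to 3D representations with a symmetric InfoNCE loss
  (both matching directions weighted 1/2).
- *Text*: a pluggable precomputed description embedding, with a
  deterministic hashed bag-of-tokens fallback featurizer.
- *Ontology*: random-walk-with-restart (RWR) diffusion profiles on the
  ontology graph, factorized by SVD; node vectors are the top-`dim` right
  singular directions scaled by singular values.  The walk matrix is
  column-stochastic, so profiles are probability vectors at every iteration;
  the SVD sign is fixed by making each right singular vector's
  largest-magnitude entry positive.  Defaults: restart α = 0.5, L1 tolerance
  1e-6, 100 iterations (Mashup-style).
- *Side effects / sensitivity*: one linear transformation of the 27- or
  60-length payload.

**Contexts.**  Cell lines are encoded from expression: the over-expressed
gene set {g : TPM(g) ≥ TH} with TH = 400, expanded one hop on the PPI
network, pooled through the shared gene table.  An empty over-expressed set
yields the transform of the zero pool (logged loudly) rather than an error:
small synthetic panels can legitimately sit below TH.  Xenograft contexts
add a sinusoidal day-index embedding (entry 2i = sin(t/10000^(2i/d_hid)),
entry 2i+1 the cosine; squared norm d_hid/2 for every t) elementwise to the
expression embedding.  DDI contexts are learnable per-type embeddings.

**Augmentor.**  A drug pair with availability sets A and B yields |A|·|B|
views (up to 64).  Each view embedding is Dropout(ReLU(W [z_ma | z_mb | c]))
∈ R^{2 d_hid}.  For DDI the context enters through the head instead, and the
pair transform uses Tanh.

**Heads.**  A single shared two-layer head scores every view (sigmoid for
classification; unsquashed for the regression task).  The DDI head is
bilinear: the type embedding is refined as ĉ = Dropout(Tanh(c + W_c [ẑ|c]))
and scored against Dropout(Tanh(W_z ẑ)).

**Aggregator.**  Per triplet, the view predictions are masked to the top
k = 8 most confident (ties broken by canonical view order), then combined as
y\* = ω_NLLᵀ·masked + mean(top-k), clamped into (ε, 1−ε), ε = 1e-7, for
classification.  The shortcut is interpreted as the mean of the retained
top-k; dividing the sum of all views by k is available as a config option.
When fewer than k views exist, k_eff = #views.

**Objective.**  L = L_SL + λ_InfoNCE·L_InfoNCE + λ_MSE·L_MSE with all λ =
0.01.  L_SL is cross-entropy on y\* plus λ_aux = 0.01 times cross-entropy on
r = 2 view predictions sampled uniformly per batch (squared error replaces
cross-entropy for the regression task).  L_InfoNCE matches each triplet's
first sampled view embedding to its own second one against the batch, on
cosine similarities with temperature 1.  L_MSE pulls each sampled view
prediction toward y\* treated as a detached soft label.  Two printed-form
ambiguities are resolved on substance: the output-consistency term is a
positive mean of squared residuals (its label says mean squared error and
its role is a penalty), and the contrastive terms take −log of the softmax
ratio.  Batch reductions are means, so the uniform-similarity value is
log N.  Training uses Adam (optionally with decoupled weight decay), linear
warmup, then polynomial decay (power 1).

## Autodifferentiation layer

The neural components run on a small reverse-mode autodiff engine written on
numpy (`pairview.nn`) in float64.  Gradient correctness is verified against
central finite differences both per-op and end-to-end through the full loss.
All views in a batch are packed into one gather + matmul (block-diagonal
attention for SMILES batches, block-diagonal adjacency for graph batches),
which is numerically identical to per-item encoding and is what makes CPU
training runs practical.  Determinism: every random draw flows from
`RunConfig.seed` through named `numpy` generator streams, so equal configs
give bitwise-equal loss histories at a fixed thread count.

## Synthetic data

The fixture module generates every input the framework consumes: drugs with
valence-safe SMILES from a tiny closed grammar (linear/branched/ring C/N/O
skeletons, all RDKit-parseable), per-modality payloads dropped i.i.d. at
configurable rates (SMILES never missing), preferential-attachment PPI
networks, random ontology trees, lognormal expression panels (about 30 % of
values clear TH = 400; columns are not forced to sum to 1e6 because a small
gene panel is a subsample of a transcriptome), SDL gene-pair lists, and
exponential-growth xenograft trajectories Vol_t = Vol_0·exp((g−e)t) with
multiplicative lognormal noise on the standard day grid {0,3,7,10,14,17,21}.

Labeled triplets follow a planted two-modality rule: synergy iff drug A's
latent mean sensitivity exceeds the cohort median AND drug B targets a gene
over-expressed in the context, with independent label flips at the noise
rate.  The rule spans two modalities by design, so single-modality ablations
underperform the fused model.  Default study conditions: 12 drugs, 6
contexts, 40 genes, 480 sampled triplets (≈60 % of the ordered space, the
coverage regime of dense combination screens), 10 % payload missingness,
2 % label noise.  The noise rate and coverage were set so that the planted
rule is recoverable by the full pipeline at desk scale — a requirement of
the generator's contract — while an identity-only memorizer measurably
trails a learner that uses the payloads.

What the fixture does *not* emulate: real pharmacology (no dose–response
surfaces, no chemically meaningful targets), correlated missingness between
modalities, batch effects in expression, or class imbalance at the scale of
real screens.  Recovery results on it demonstrate that the pipeline can
extract a planted multi-modal signal end to end; they say nothing about
accuracy on real screens.

## Desk-scale recovery protocol

Recovery experiments (see `pairview.recovery`) use hidden width 16
throughout (two-layer sequence/graph encoders, one attention head), batch
32, 2,000 Adam steps at learning rate 5e-3 with decoupled weight decay 1e-3
and dropout 0.1 — a configuration sized so one training run takes well
under a minute on one CPU.  The auxiliary per-view supervision weight is
raised from the full-scale default 0.01 to 0.25 at desk scale: cumulative
per-view supervision scales with steps × λ_aux, and at 2,000 steps the
full-scale weight leaves most of the 64 views essentially untrained, so the
top-k aggregator ends up selecting confidently wrong views.  Held-out
balanced accuracy is reported on a seeded 60/20/20 triplet split with
best-validation checkpointing (validation balanced accuracy evaluated every
50 steps); the label-shuffled control permutes training *and* validation
labels so neither fitting nor model selection sees label information.
Single-modality ablations restrict both drugs' availability to one
modality, with a learnable placeholder embedding standing in where the
payload is missing (the single-modality-study convention).

A caveat the recovery suite itself demonstrates: at these conditions
(twelve drugs, dense triplet coverage), any always-present modality payload
doubles as a drug identity code, and a single-view model is easier to
optimize than the 64-view aggregation, so single-modality ablations can
match the fused model through memorization rather than through reading the
payload values.  The complementarity advantage of fusing modalities is
therefore not reproduced at desk scale; demonstrating it requires regimes
where identity memorization fails (many drugs, sparse coverage, genuinely
unseen test drugs at larger scale).

## Numerical choices and edge cases

- Top-k ties break toward the earlier canonical view, making masking
  deterministic.
- Classification aggregates are clamped into (1e-7, 1−1e-7) because the
  affine term can leave the unit interval.
- RWR on isolated nodes restarts onto the node itself (profile = basis
  vector).
- Quantile rules in patient stratification use linear-interpolation
  percentiles with strict inequalities at the boundary: highly expressed
  means above the cohort's 70th percentile, inhibited means mutated or below
  the 30th.
- Fisher's exact test defaults to one-sided enrichment; the two-sided
  variant uses the point-probability rule.  Degenerate margins give p = 1
  with a warning.
- DDI class-network filtering keeps an interaction if it makes the per-drug
  confidence cap for at least one of its two drugs; a drug in several
  ontology classes counts in each class pair.
- Decision threshold: p = 0.5 maps to the positive class.
- Three-drug predictions average the three pairwise predictions with each
  pair in canonical order, so the result is invariant to listing order.
- DDI new-drug splits hold out a drug subset sized so the expected test
  fraction matches the requested one (2h(1−h) for one-new, h² for two-new).

## Known limitations

- The SMILES transformer and graph encoder are small, self-contained
  variants; they are not drop-in replacements for large pretrained molecular
  encoders, which enter instead as precomputed-embedding payloads.
- The aggregator's affine term is a single linear layer over masked view
  predictions; no attention-based view weighting is provided.
- Training is single-threaded CPU float64; it is meant for desk-scale
  studies and tests, not large screens.
- Survival analysis is out of scope: patient stratification labels are
  exported for standard survival tooling.
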