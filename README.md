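# pairview

Multi-modal view augmentation for drug-pair prediction: cell-line synergy,
xenograft tumor-volume response, and typed drug-drug interactions.

## The problem

Drug-combination screens are sparse and expensive, and the drugs in them are
described by heterogeneous, partially missing data: a SMILES string here, a
target gene set or a side-effect profile there.  Classical multi-modal
models need every modality for every drug, forcing imputation.  `pairview`
instead treats each *modality pair* as its own training instance: with eight
supported modalities per drug

M = {SMILES, 2D graph, targets, 3D view, text, ontology, side effects,
sensitivity},

a drug pair (d_a, d_b) with availability sets A, B ⊆ M expands into
|A|·|B| ≤ 64 views x[m_a, m_b].  A projector of eight modality-specific
encoders maps every payload into a shared space z ∈ R^{d_hid}; an augmentor
builds each view embedding ẑ = Dropout(ReLU(W [z_{m_a} | z_{m_b} | c])) with
the context embedding c (cell line, xenograft model + day index, or
interaction type); a shared head scores every view, and a noisy-label
aggregator keeps the top k = 8 most confident view predictions:

y\* = ω_NLLᵀ · NLL_k({ŷ[m_a, m_b]}) + mean(top-k),

so low-quality augmented views are excluded instead of averaged in.
Training combines supervised loss on y\* and on r = 2 sampled views with two
consistency terms — an InfoNCE loss tying sampled view embeddings of the
same triplet together and an MSE loss pulling view predictions toward y\* as
a soft label (λ = 0.01 each).

Downstream discovery procedures are included: enumeration of unscreened
candidate triplets, mining of (over-expressed gene, drug-target gene) pairs
from confident predictions filtered through a synthetic-dosage-lethality
(SDL) network, patient pathway-activation labels from expression/mutation
profiles, and a Fisher's-exact drug-class interaction network.

The intended users are computational drug-discovery researchers who want a
self-contained, CPU-friendly reference implementation of this augmentation
scheme with fully synthetic fixtures for method development and testing.

## Worked example

`examples/02_train_synergy.py` generates a synthetic screen with a planted
two-factor rule — a triplet is synergistic iff drug A's sensitivity profile
is high *and* drug B targets a gene over-expressed in the cell line — trains
the full pipeline at desk scale and evaluates the held-out split:

```
$ python examples/02_train_synergy.py
12 drugs, 480 triplets, 153 synergistic
loss: 1.103 -> 0.445 over 400 steps
held-out: {'bacc': 0.829, 'auprc': 0.902, 'f1': 0.787, 'kappa': 0.69}
```

`bacc` is balanced accuracy (mean of sensitivity and specificity at
p ≥ 0.5); 0.5 is chance.  A short 400-step demo run already recovers most of
the planted rule; the full recovery protocol (`pairview.recovery`, 2,000
steps with best-validation checkpointing, exercised by the acceptance
suite) reaches a ten-seed median held-out balanced accuracy above 0.85,
while a label-shuffled control stays at chance.

Other examples cover view-count combinatorics (`01`), RWR ontology
embeddings (`03`), xenograft BestResponse and FPKM→TPM conversion (`04`),
and SDL pathway mining (`05`).  A thin CLI mirrors the library:
`pairview fixtures|augment|train|predict|evaluate|pathway|ddinet`.

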