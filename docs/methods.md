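# Methods

## The problem and the modeling idea

A serine/threonine kinase recognizes its substrates largely through the
residues flanking the phospho-acceptor. Peptide-array screens summarize
this as, per kinase, a percentile score for every candidate 15-mer: the
rank of the peptide's profile score within a reference peptide
population. `phoskin` treats kinase-specific phosphosite prediction as
binary classification of (kinase domain, 15-mer peptide) pairs and asks
two questions that are hard to answer on real data: does a multitask
transformer actually *use* the determinant residues, and does masked-
language-model (MLM) pretraining on kinase domains buy generalization to
kinases never seen as classification examples? Both questions are
answered here on synthetic worlds where the ground truth is planted and
therefore checkable.

## Synthetic world

**Kinases.** A family is a cluster of mutational variants of a random
ancestor domain sequence (default length 250; the bundled studies use
48/40, see *Scales* below). Members differ from the ancestor by an i.i.d.
per-site substitution rate (default 0.05), so within-family identity is
~0.90 and between-family identity is at the random-background level
(~0.05). Families carry group labels (named after kinase-group
conventions: AGC, CAMK, CMGC, ...) purely as annotation for grouped
evaluation.

**Specificity.** Each family has a position-specific scoring matrix of
log-odds weights over flank positions −7..+7 (the central position is
scored only through an S-vs-T preference term). Planted determinants add
weight w to chosen (position, residue-set) cells; the library of default
motifs assigns each family one dominant determinant (w = 3.5, e.g. R at
−3) and one weak secondary (w = 1.0). w = 3.5 corresponds to an e^3.5 ≈
33-fold preference — strong but in the range of real anchor residues such
as the PKA R at P−3. Per-kinase jitter (σ = 0.1) differentiates members.
A *bimodal* kinase carries two strong determinants and its substrates are
sampled in mode-split fashion: each peptide commits to one determinant,
so the positive pool is a genuine mixture of two motifs rather than an
additive blend — this is the ground truth against which motif
decomposition is judged.

**Peptides and percentiles.** Phosphorylatable peptides are drawn
position-wise from background frequencies tilted by a randomly chosen
family profile; never-phosphorylated peptides are drawn from background
and rejected if any profile would rank them above the 80th percentile of
the phosphorylatable population (so "easy negatives" are unambiguous).
The raw score is the additive profile score; the percentile is the rank
percentile (mean rank for ties) of that score within the peptide pool,
computed per kinase. The reference population is the peptide pool per
kinase — percentile scores are a within-kinase ranking, which is the
assumption that makes "> 90 ⇒ positive" meaningful across kinases.

What the generator does **not** emulate: real kinome sequence statistics,
structural constraints on domains, array chemistry, correlated flanking
positions, and the long-tailed redundancy of proteomic phosphosite
collections. Passing tests here show the pipeline is correct and that the
architecture can discover planted determinants; they do not certify
performance on biological data.

## Curation

Tiers follow strict thresholds: percentile > 90 positive, < 50 hard
negative, [50, 90] discarded (the screen convention assigns that band no
label). Kinases are clustered greedily at 70% identity in descending
length order (ties by id), identity being positional matches for
equal-length sequences and match-fraction under a simple global alignment
(match 1 / mismatch 0 / gap −1) otherwise. Peptides are clustered greedily
in input order at Hamming distance ≤ 5 over the 11 central residues,
serine and threonine sites separately; the inclusive cutoff (≤) is the
conventional reading. Greedy partitions depend on processing order, so
the order rule is fixed and recorded in the provenance output. One
uniformly random representative survives per (tier, kinase-cluster,
peptide-cluster) combination; the same filter deduplicates randomly
paired easy negatives. Positives split 60:20:20 (floor; remainder to
train); validation and test take hard and easy negatives 1:1:1 with their
positives; leftover negatives train. Non-overlap is enforced at the
(kinase, peptide) pair level; a stricter cluster-level split is available
(`zero_shot_protocol` implements the kinase-level version) but pair-level
is the default, matching the usual reading of "non-overlapping sets" of
examples.

By default the hard-negative pool is subsampled to the positive count
before splitting (the raw pool is several times larger); this keeps
training balanced at desk scale and is configurable.

## Augmentation

Four training-time augmentations, all configurable and off by default in
the bundled studies except where stated: domain-boundary shifts (uniform
±10 residues, clipped), random masking (p = 0.10), Markov span masking
(two-state chain, enter 0.03 / stay 0.80, hence geometric runs of mean 5
and a stationary masked fraction ≈ 0.13), and multi-level negative
sampling over {same family, same group, random} with configurable
weights. Masked residues are written as `#`, which tokenizes to
`<mask>`. Peptides are never mutated — substrate identity is the label.

## Model and training

Tokenization: `<cls> p₁..p₁₅ <eos> k₁..k_L <eos>`; the phosphosite is
always token 9, which gives every pair a common anchor. The encoder is a
pre-norm transformer (bundled studies: 2 layers, d = 64 or 32, 4 heads,
GELU feed-forward, learned positional embeddings, right-padding excluded
from attention; over-long inputs are rejected, never truncated). The MLM
decoder is a linear map to the vocabulary; corruption selects 15% of
residue positions and replaces them with `<mask>` (the simplest auditable
rule). The classifier separates peptide- and kinase-position embeddings
and runs one multi-head cross-attention layer with peptide positions as
queries and kinase positions as keys/values — the orientation is forced
by the requirement that the output live at the phosphosite position; the
reverse orientation is available behind a flag for comparison, with a
masked mean over kinase positions as its anchor. A pre-norm residual
wraps the attention block. The updated phosphosite vector feeds a binary
linear layer and two-class softmax.

Training draws a Bernoulli task per batch (classification with
probability 0.5 by default). Epochs count passes over the classification
training split; MLM batches are additional steps. The full task sequence
is drawn up front from the seed, making the total step count — and the
shared linear learning-rate decay to zero — deterministic and exactly
reproducible. Optimization is AdamW (weight decay 0.01). `TrainConfig`
defaults to lr 2e-5 and 3 epochs, the fine-tuning regime for a large
pretrained encoder; the bundled from-scratch studies configure lr 1e-3,
appropriate for a small randomly initialized model. Checkpoints include
step 0 (the pre-fine-tuning state) so embedding trajectories start at the
pretrained/random origin.

The network runs on a small reverse-mode autodiff engine written for this
package (`phoskin.nn`); its gradients are validated against central
differences in the test suite. Everything is CPU-only and deterministic
under fixed seeds and thread-stable BLAS.

## Evaluation

AUC ROC is the rank statistic (mid-rank ties), equal to exhaustive
concordant-pair counting; AUC PRC is the step-interpolated
precision-recall summary; accuracy and the easy-negative false-positive
rate use threshold 0.5. Hit@1 ranks all candidate kinases per substrate
(rank-1 ties broken by kinase id and logged), scores a hit when the top
kinase shares the true kinase's family/group label, and macro-averages
per-class accuracies without weighting. The zero-shot protocol holds out
floor(10% · n) kinases with *all* their pairs ("unseen" test set), carves
an equal-sized random slice of the remaining training pool as the "seen"
test set, and trains each initialization variant on the reduced set:
random-init (classification only), pretrained (MLM pretraining, then
classification only), pretrained+multitask (MLM pretraining, then mixed
batches). Classification exposure is identical across variants.

## Interpretability

**Embedding trajectories.** Phosphosite-token embeddings from all
checkpoints are stacked, reduced jointly by UMAP (fixed seed, neighbors
15, min-dist 0.1 — recorded in the run manifest), and unstacked, so all
checkpoints share one 2-D frame.

**Partition Shapley.** The explained quantity is the positive-class
probability (bounded, comparable across pairs; logit mode by flag).
Masking a position replaces its token with `<mask>`; the base value is
the output under full masking. Positions are organized in a partition
tree whose peptide and kinase subtrees are separate, so coalitions
respect the biological segmentation. At every internal node the children
are treated as players in an *exact* Shapley computation given the
inherited context distribution; attribution is therefore the exact Owen
value of the tree, efficiency holds to floating point at every call
(asserted, tolerance 1e-4), and a flat root of singleton leaves
reproduces exact Shapley values — verified against 2^n enumeration in the
tests. Cost grows roughly quadratically in leaf count; kinase positions
may be grouped into contiguous blocks (default 8) whose credit is split
equally within the block, while peptide positions are always singletons.

**Motif decomposition.** For one kinase's true positives, affinity
propagation clusters the peptide-part attribution vectors (similarity =
negative squared Euclidean distance; damping 0.9; preference = median
similarity — the standard defaults, recorded per run). Clustering the
full peptide+kinase vector is available by flag; the peptide part is the
default because the readout is a peptide sequence logo. Per cluster the
member peptides are tabulated into a 15×20 position-frequency matrix;
information content is log₂20 minus column entropy. Non-convergence
falls back to a single cluster with a warning.

## Scales used in the bundled studies

Chosen so a complete study runs in minutes on one CPU; they are the
package's canonical configurations (`phoskin.presets`):

* *Mechanism study*: 8 families × 4 kinases, domain length 48, 2 100
  phosphorylatable peptides (≈ 2 000 curated positives), family 0
  bimodal; encoder 2×64, 3 epochs, 100 MLM pretraining steps.
* *Zero-shot study*: 6 families × 5 kinases (30 kinases; a 10% holdout
  removes 3), domain length 40, 700 peptides; encoder 2×32, 3 epochs,
  300 MLM pretraining steps; five seeds per report.

Domain length 250 (the generator default, matching real kinase domains)
works throughout but multiplies runtime by roughly the sequence-length
ratio squared in attention.

## Numerical choices and degenerate inputs

Percentile ties take the mean rank, so a uniform profile yields one tied
value. The 60:20:20 remainder goes to train. Empty inputs (peptide pools,
reference pools, attribution sets, logos) raise immediately; a negative
pool too small for 1:1:1 raises naming the shortfall; an infeasible
easy-negative rejection ceiling raises after a bounded number of
attempts. NaN training loss aborts with a diagnostic snapshot. Scores are
float32 in the network and float64 in reductions; attribution recursion
accumulates in float64.

## Known limitations

The encoder is orders of magnitude smaller than production protein
language models, and the MLM corpus is the synthetic family universe, so
pretraining gains are demonstrated, not maximized; per-seed zero-shot
orderings are noisy even though the mean ordering is stable. Easy
negatives are pure background, easier than real unphosphorylated sites.
Motif recovery is evaluated against the planted determinants of an
additive profile; real kinases have correlated, structure-dependent
preferences the generator does not model. Affinity propagation can
oversplit a mode into several clusters; the decomposition claim is that
modes are *separated*, not that the cluster count equals the mode count.
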