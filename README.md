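# phoskin

Explainable kinase–substrate specificity prediction at desk scale.

Protein kinases phosphorylate serine/threonine residues on substrate
proteins, and which kinase targets which site is governed largely by the
residues flanking the phospho-acceptor (positions −7..+7 of a 15-mer
peptide). `phoskin` is a self-contained workbench for studying how a
multitask transformer learns this mapping and how its decisions can be
opened up residue by residue. It is aimed at methods researchers who want
a fully controlled, CPU-scale testbed: every experiment runs on a
synthetic kinase universe with *known, planted* specificity motifs, so
claims about what the model learned can be checked against ground truth.

## What is inside

* **Synthetic world** (`phoskin.synthetic`): kinase families as
  mutational clusters around ancestor domain sequences; per-family
  position-specific scoring matrices `W ∈ R^{15×20}` of log-odds weights
  with planted determinants (e.g. basophilic R at P−3, acidophilic D/E at
  P−2); peptide percentile scores as rank percentiles of the additive
  score `s(x) = Σ_{p≠0} W[p, x_p] + c(x_0)` within the peptide pool, and a
  pool of never-phosphorylated S/T sites.
* **Curation** (`phoskin.curation`): percentile > 90 ⇒ positive,
  < 50 ⇒ hard negative, middle band discarded; greedy kinase clustering at
  70% identity; greedy peptide clustering at Hamming ≤ 5 over the 11
  central residues (S and T sites separately); one representative pair per
  unique (tier, kinase-cluster, peptide-cluster) combination; easy
  negatives from random kinase × non-phosphosite pairings; 60:20:20
  positive splits with 1:1:1 tier ratios in validation/test.
* **Model** (`phoskin.model`, `phoskin.nn`): a pair is tokenized as
  `<cls> p₁..p₁₅ <eos> k₁..k_L <eos>`, so the candidate phosphosite is
  always the 9th token. A shared pre-norm transformer encoder feeds either
  a masked-language-model decoder (over a kinase-domain corpus) or a
  classifier in which peptide positions attend to kinase positions through
  a single multi-head cross-attention layer and the updated phosphosite
  vector is mapped to a two-class softmax. The network and AdamW training
  run on an in-repo numpy autodiff engine; no GPU or deep-learning
  framework is required.
* **Trainer** (`phoskin.training`): per-batch random task choice between
  MLM and classification, shared linear learning-rate decay to zero,
  checkpointing from step 0 for trajectory analysis.
* **Evaluation** (`phoskin.evaluation`): AUC ROC / AUC PRC / accuracy on
  1:1 positives vs hard negatives, false-positive rate on easy negatives,
  substrate-centric Hit@1 macro-averaged over families and groups, and a
  zero-shot protocol that holds out ~10% of kinases with all their pairs
  and compares random-init / pretrained / pretrained+multitask variants.
* **Interpretability** (`phoskin.interpret`): checkpoint-aligned joint
  UMAP of phosphosite-token embeddings; an exact partition (Owen-value)
  Shapley explainer over residue positions (mask-token ablation, peptide
  and kinase subtrees kept separate, efficiency
  `base + Σφ = prediction` guaranteed); affinity-propagation decomposition
  of a kinase's attribution vectors into motif clusters with sequence
  logos.

## Worked example

```python
from phoskin import presets
from phoskin.curation import CurationConfig
from phoskin.pipeline import (curate_world, train_world_model,
                              seen_test_metrics, attribution_study)

world = presets.mechanism_world(seed=11)        # 8 families x 4 kinases
examples = curate_world(world, CurationConfig(seed=11))
model, _, _ = train_world_model(
    world, examples,
    presets.mechanism_model_config(seed=11),
    presets.mechanism_train_config(seed=11),
    pretrain_steps=presets.MECHANISM_PRETRAIN_STEPS)

print(seen_test_metrics(model, examples, world))
attrs, recovery = attribution_study(model, examples, world,
                                    peptides_per_kinase=2, seed=5)
print("determinant recovery:", recovery)
```

On one CPU this trains in about two minutes and prints

```
{'auc_roc': 1.0, 'auc_prc': 1.0, 'accuracy': 1.0, 'fpr_easy': 0.0,
 'n_scored': 838, 'n_easy': 419}
determinant recovery: 1.0
```

i.e. the trained model perfectly separates positives from hard negatives
on held-out test pairs of seen kinases, calls no easy negative positive at
threshold 0.5, and for every kinase the flank position with the largest
mean |Shapley attribution| is one of that family's planted determinants —
the model's decisions rest on the residues that actually carry the
specificity signal in this world.

The same pipeline is available from the shell:

```bash
phoskin simulate --out run/        # FASTA + percentile TSV + motif JSON
phoskin curate   --out run/        # dataset manifest TSV
phoskin train    --out run/        # checkpoints + loss history
phoskin evaluate --out run/        # metrics.json
phoskin explain  --out run/        # per-residue attributions TSV
phoskin motifs   --out run/        # affinity-propagation logos
phoskin project  --out run/        # checkpoint-aligned UMAP TSV
phoskin zero-shot --out run/       # held-out-kinase ablation
```

Every run writes a manifest (config snapshot + seeds) sufficient to
reproduce it.

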