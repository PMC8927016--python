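# ignet

A two-channel deep classifier for Alzheimer's-disease (AD) diagnosis from
paired imaging-genetics data, with its SNP pre-selection stage,
single-channel variants, ensembles, evaluation suite, and a synthetic
cohort simulator that makes the entire pipeline testable without access to
restricted clinical data.

## Who this is for

Researchers in imaging genetics who want a small, fully inspectable
reference implementation of multimodal fusion classification: a 3D CNN over
structural brain MRI fused with a Transformer encoder over SNP dosage
sequences. Everything — including backpropagation — is plain numpy, so every
gradient and design choice is readable and unit-tested; no deep-learning
framework is required.

## The model

Given a preprocessed T1 volume **V** (grayscale 0–255, side lengths
divisible by 2⁵) and a dosage sequence **g** ∈ {0,1,2}ᴸ of L−1 selected
SNPs plus the APOE ε4 allele count:

- **Imaging channel** — five stages of (3×3×3 conv, stride 1, "same"
  padding → ReLU → 2×2×2 max-pool, stride 2) with filter counts
  [4, 8, 16, 32, 32], then dense layers [128, 32, 16] →
  embedding **eᵢ** ∈ ℝ¹⁶.
- **Genetic channel** — token + positional embeddings (a separate
  vocabulary for the APOE position), a two-layer four-head pre-norm
  Transformer encoder (model dim 16, FFN 32), mean pooling →
  **e_g** ∈ ℝ¹⁶.
- **Fusion & head** — z = eᵢ ⊙ e_g, an MLP with two 16-unit ReLU layers,
  softmax over K = 2: p(AD | V, g).

SNPs enter the sequence only if a Freeman–Halton (2×3) Fisher exact test
against the diagnosis gives p < 0.01 (no multiple-testing correction);
APOE ε4 is appended unconditionally. Training uses categorical
cross-entropy, AdamW (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸, lr 10⁻³), batch 16,
dropout 0.2 in both channels, and early stopping on validation loss with
patience 3, returning the best snapshot. Restricted variants feed a single
channel's embedding to the same head; two ensembles (probability averaging
and conjunctive voting) combine them. See `docs/methods.md` for every
assumption and default.

## Worked example

```python
import numpy as np
from ignet.synthetic import SimConfig, simulate_cohort
from ignet.snp_selection import select_snps, append_apoe
from ignet.data_io import stratified_split
from ignet.training import TrainingData, train, predict
from ignet.model import ModelConfig
from ignet.evaluation import evaluate

cfg = SimConfig(n_subjects=200, n_ad_target=92, n_snps=100,
                causal_log_odds=1.0, seed=3)
cohort = simulate_cohort(cfg)                      # 89 AD / 111 CN
split = stratified_split(cohort.labels, seed=3)    # 80/10/10, stratified
panel, report = select_snps(cohort.genotypes, cohort.labels,
                            training_ids=split.index[split == "train"])
panel = append_apoe(panel)                         # 4 SNPs kept + APOE = 5 tokens
data = TrainingData.from_cohort(cohort, panel)
mc = ModelConfig(variant="genetic_only", seq_len=len(panel),
                 volume_shape=(32, 32, 32))
model, state = train(data, split, mc, seed=1)      # stops at epoch 6
test = np.flatnonzero(split.loc[data.subject_ids] == "test")
print(evaluate(predict(model, data, test)))
```

printed (exact numbers are seed-reproducible):

```
MetricsReport(accuracy=0.8, precision=0.857, recall=0.667, f1=0.75,
              threshold=0.5, tp=6, fp=1, fn=3, tn=10,
              auc_roc=0.818, auc_prc=0.840)
```

Reading: of 20 held-out subjects the genetic-only variant classifies 16
correctly at the 0.5 threshold; its ranking quality (AUC-ROC 0.82) reflects
the four recovered causal SNPs plus the strong APOE-like locus the
simulator planted.

The same pipeline is available from the shell:

```bash
ignet simulate --seed 3 --out cohort/
ignet split --labels cohort/labels.tsv --seed 3 --out split.tsv
ignet select-snps --genotypes cohort/genotypes.tsv --labels cohort/labels.tsv \
                  --split split.tsv --alpha 0.01 --out panel.tsv
ignet train --cohort cohort/ --panel panel.tsv --split split.tsv \
            --variant full --out run/
ignet evaluate --checkpoint run/checkpoint.npz --cohort cohort/ \
               --panel panel.tsv --split split.tsv --out eval/
```

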