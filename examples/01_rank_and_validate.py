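"""Score a synthetic genome against a training gene set and validate by
leave-one-out cross-validation.

Builds 3 knowledge sources over 1000 genes with a planted signal in 20
training genes, computes omnibus rank-annotation scores (0-100%, genome
median 50% by construction), and runs the LOOCV ROC-style validation.
"""

import numpy as np

from tofrank import SimConfig, TrainingSet, loocv_roc, omnibus_scores, simulate_sources

cfg = SimConfig(n_genes=1000, n_sources=3, n_features_per_source=50,
                enrichment=3.0, noise_sd=1.0, seed=11)
sources = simulate_sources(cfg)
training = TrainingSet("synthetic-TOF", frozenset(cfg.resolved_training_genes()))

ann = omnibus_scores(sources, training)
scores = np.array(list(ann.scores.values()))
print(f"genome-wide median score : {np.median(scores):.1f}%  (50% = chance)")
print(f"training-gene median     : "
      f"{np.median([ann.scores[g] for g in training.genes]):.1f}%")

roc = loocv_roc(sources, training)
loo = list(roc.loo_percentiles.values())
print(f"median LOO percentile    : {np.median(loo):.1f}%")
print(f"AUC above diagonal       : {roc.auc_above_diagonal:.3f}  "
      "(0 = chance, 0.5 = perfect)")
# A high LOO median and positive AUC mean held-out training genes are
# recovered near the top of the genome-wide ranking: the planted disease-gene
# signal is detectable from the knowledge sources alone.
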