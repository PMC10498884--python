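#!/usr/bin/env python
"""Outcome models: elastic-net phenotype prediction and the minimal
prognostic signature.

(1) Elastic-net logistic regression predicting the molecular phenotype
    clusters from plasma-style inflammation biomarkers + clinical features.
(2) NSGA-II + SVM search for the smallest plaque-protein subset predicting
    the cardiovascular endpoint, over signature-tagged candidates.
Writes reports under results/prediction/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from plaqueomics.phenotyping import (build_combined_matrix,
                                     kmeans_phenotypes, pca_embed)
from plaqueomics.prediction import (MoeaConfig, final_signature_model,
                                    fit_elasticnet, moea_select)
from plaqueomics.synthetic import SimulationConfig, simulate_risk_panel, \
    simulate_study

study = simulate_study(SimulationConfig(seed=7))
out = Path("results/prediction")
out.mkdir(parents=True, exist_ok=True)

# --- phenotype clusters from plasma-style biomarkers + clinical features ---
combined = build_combined_matrix(*study.matrices.values())
scores, ev = pca_embed(combined, n_components=6)
model = kmeans_phenotypes(scores, k=4, seed=7, n_components=5,
                          explained_variance=ev)

plasma_panel = ["MMP9", "CATD", "S10A8", "S10A9", "PERM"]
sds = study.matrices["SDS"].imputed()
nacl = study.matrices["NaCl"].imputed()
feats = {}
for p in plasma_panel:
    src = sds if p in sds.index else nacl
    if p in src.index:
        feats[p] = src.loc[p]
meta = study.metadata.table
feats["age"] = meta["age"]
feats["statin"] = meta["statin"].astype(float)
feats["echolucent"] = (meta["ultrasound"] == "echolucent").astype(float)
x = pd.DataFrame(feats).loc[model.labels.index]
enet = fit_elasticnet(x, model.labels.to_numpy(), mixing=0.5, seed=7)
print("elastic net selected:", enet.selected, f"(C={enet.C:.3g})")
enet.coefficients.to_csv(out / "elasticnet_coefficients.tsv", sep="\t")

# --- minimal prognostic signature (planted-truth risk panel) ---------------
features, y, planted = simulate_risk_panel(7)
cfg = MoeaConfig(population=32, generations=40, cv_folds=10, seed=7,
                 early_stop_patience=10)
front = moea_select(features, y, cfg)
report = final_signature_model(front, features, y, folds=10, seed=7)
report.pop("model")
(out / "signature_report.json").write_text(json.dumps(report, indent=1))
print("planted prognostic proteins:", planted)
print("selected signature:", report["members"])
print(f"CV AUC {100 * report['refit_cv_auc_mean']:.1f}% "
      f"(sd {100 * report['refit_cv_auc_sd']:.1f}%)")
print("front (size, AUC):",
      [(s.size, round(s.mean_cv_auc, 3)) for s in front.solutions])
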