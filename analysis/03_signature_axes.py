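#!/usr/bin/env python
"""Signature scoring: the inflammation/calcification anti-correlation.

Scores every sample on the inflammation and calcification signatures (first
principal component of the member proteins) in the soluble (NaCl) and core
(GuHCl) matrisome fractions, reports their correlation, and tests sex-hit
enrichment of the proteoglycan block by Fisher's exact test.
"""

from pathlib import Path

import pandas as pd

from plaqueomics.differential import DesignSpec, differential_abundance
from plaqueomics.io_core import Fraction
from plaqueomics.signatures import (SignatureDefinition, correlate_scores,
                                    fisher_enrichment, score_first_pc)
from plaqueomics.synthetic import ANCHORS, SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=7))
out = Path("results/signatures")
out.mkdir(parents=True, exist_ok=True)

rows = []
for frac in ("NaCl", "GuHCl"):
    m = study.matrices[frac]
    anchors = ANCHORS[Fraction.coerce(frac)]
    infl = score_first_pc(m, SignatureDefinition(
        "inflammation", tuple(anchors["inflammation"])))
    calc = score_first_pc(m, SignatureDefinition(
        "calcification", tuple(anchors["calcification"])))
    r, p = correlate_scores(infl, calc)
    rows.append((frac, r, p, infl.variance_explained,
                 calc.variance_explained))
    scores = pd.DataFrame({"inflammation": infl.scores,
                           "calcification": calc.scores})
    scores.to_csv(out / f"{frac}_axis_scores.tsv", sep="\t",
                  index_label="sample_id")
    print(f"{frac:6s} inflammation~calcification r={r:+.3f} (p={p:.2g})")

pd.DataFrame(rows, columns=["fraction", "r", "p", "ve_inflammation",
                            "ve_calcification"]).to_csv(
    out / "axis_correlations.tsv", sep="\t", index=False)

# proteoglycan block enrichment among sex-differential proteins (GuHCl)
m = study.matrices["GuHCl"]
res = differential_abundance(m, study.metadata,
                             DesignSpec("sex", ["age", "statin"]))
hits = set(res.table.loc[res.table["q"] < 0.05, "protein_id"])
pg = set(ANCHORS[Fraction.GUHCL]["proteoglycan"])
enr = fisher_enrichment(hits, {"proteoglycan_block": pg},
                        set(m.protein_ids))
enr.to_csv(out / "proteoglycan_sex_enrichment.tsv", sep="\t", index=False)
print("proteoglycan block vs sex hits:",
      f"OR={enr['odds_ratio'].iloc[0]:.1f}, q={enr['q'].iloc[0]:.2g}")
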