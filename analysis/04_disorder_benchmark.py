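"""Benchmark the confidence-derived disorder predictor.

Scores every residue of the simulated disorder proteome with
1 - 0.01 x pLDDT and evaluates it against the generator's labels by
ROC/AUC, writing the ROC points.
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from structqa.benchmark import LabelledScores, roc_auc, roc_curve
from structqa.confidence import disorder_score
from structqa.structure_io import ConfidenceProfile

OUT = Path("results")
df = pd.read_csv(OUT / "synthetic" / "disorder_proteome.tsv", sep="\t")

scores, labels = [], []
for row in df.itertuples(index=False):
    profile = ConfidenceProfile(row.protein_id,
                                np.array([float(v) for v in row.plddt.split(",")]))
    scores.append(disorder_score(profile))
    labels.append(np.array([int(c) for c in row.labels]))
data = LabelledScores(np.concatenate(scores), np.concatenate(labels))

auc = roc_auc(data)
roc_curve(data).to_csv(OUT / "disorder_roc.tsv", sep="\t", index=False)
report = {"auc": auc, "n_residues": int(data.labels.size),
          "disorder_fraction": float(data.labels.mean())}
(OUT / "disorder_benchmark.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

print(f"disorder predictor AUC: {auc:.4f} over {data.labels.size} residues "
      f"({data.labels.mean():.1%} disordered)")
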