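"""Structure-metric behaviour under controlled noise.

Measures how lDDT-Cα and TM-score degrade as Gaussian coordinate noise
grows, and the resolvability-weighted aggregate on partially resolved
chains.
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from structqa import synthetic
from structqa.metrics import lddt_ca, tm_score, weighted_aggregate

OUT = Path("results")
truth = json.loads((OUT / "synthetic" / "ground_truth.json").read_text())
SEED = truth["seed"]

rows = []
for sigma in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
    lddts, tms = [], []
    for rep in range(20):
        chain = synthetic.make_chain(30, "random_walk", seed=SEED * 1000 + rep)
        pert = synthetic.perturb(chain, sigma, seed=SEED * 1000 + 500 + rep)
        lddts.append(lddt_ca(chain, pert).global_lddt)
        ref = np.array([r.ca_coord for r in chain.residues])
        mod = np.array([r.ca_coord for r in pert.residues])
        tms.append(tm_score(ref, mod).score)
    rows.append(
        {"sigma": sigma, "median_lddt": float(np.median(lddts)),
         "median_tm": float(np.median(tms))}
    )
table = pd.DataFrame(rows)
table.to_csv(OUT / "metric_vs_noise.tsv", sep="\t", index=False)
assert table["median_lddt"].is_monotonic_decreasing
assert table["median_tm"].is_monotonic_decreasing

# weighted aggregation: downweighting unresolved residues
rng = np.random.default_rng([SEED, 61])
per_residue = rng.uniform(0.2, 1.0, 100)
resolved = (rng.random(100) > 0.3).astype(float)
weighted = weighted_aggregate(per_residue, resolved)
report = {
    "noise_table": rows,
    "weighted_vs_plain_mean": {"weighted": weighted, "plain": float(per_residue.mean())},
}
(OUT / "metric_benchmarks.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

print(table.to_string(index=False))
print(f"resolvability-weighted score {weighted:.4f} vs plain mean {per_residue.mean():.4f}")
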