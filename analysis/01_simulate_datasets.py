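"""Generate the synthetic study datasets used by the downstream analyses.

Writes profile tables, a three-chain complex structure, template-hit and
chain-metadata tables, the toy ontology and the ground-truth record under
results/synthetic/.
"""
import json
import sys
from pathlib import Path

import pandas as pd

from structqa import synthetic
from structqa.structure_io import write_structure

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/synthetic")
OUT.mkdir(parents=True, exist_ok=True)

spec = synthetic.GeneratorSpec(seed=SEED)

profiles, band_truth = synthetic.make_banded_proteome(spec)
pd.DataFrame(
    {
        "protein_id": [p.protein_id for p in profiles],
        "plddt": [",".join(f"{v:.2f}" for v in p.plddt) for p in profiles],
    }
).to_csv(OUT / "band_profiles.tsv", sep="\t", index=False)

disorder_proteins, disorder_truth = synthetic.make_disorder_proteome(spec)
pd.DataFrame(
    {
        "protein_id": [p["protein_id"] for p in disorder_proteins],
        "plddt": [",".join(f"{v:.2f}" for v in p["profile"].plddt) for p in disorder_proteins],
        "labels": ["".join(map(str, p["labels"])) for p in disorder_proteins],
    }
).to_csv(OUT / "disorder_proteome.tsv", sep="\t", index=False)

complex_model, complex_truth = synthetic.make_complex(3, ("1", "1", "2"), seed=SEED)
write_structure(complex_model, OUT / "complex.cif", "mmcif")

hits, hit_truth = synthetic.make_hit_table(seed=SEED)
hits.to_csv(OUT / "template_hits.tsv", sep="\t", index=False)
metadata, metadata_truth = synthetic.recent_pdb_fixture()
metadata.to_csv(OUT / "chain_metadata.tsv", sep="\t", index=False)
(OUT / "toy_ontology.obo").write_text(synthetic.toy_ontology_obo())

truth = {
    "seed": SEED,
    "band": band_truth,
    "disorder": disorder_truth,
    "complex": complex_truth,
    "hits_per_residue_max": hit_truth["per_residue_max"].tolist(),
    "metadata": metadata_truth,
}
(OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")

print(f"seed {SEED}: {len(profiles)} banded profiles ({band_truth['total_residues']} residues), "
      f"{len(disorder_proteins)} disorder proteins "
      f"(realized fraction {disorder_truth['realized_disorder_fraction']:.4f}), "
      f"complex contacts {complex_truth['contact_counts']}")
print(f"wrote {OUT}/")
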