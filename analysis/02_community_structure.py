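#!/usr/bin/env python
"""Community-level structure: ordination and distance-based inference.

Computes Bray-Curtis dissimilarities on species and gene-function
profiles, a PCoA of each, a marginal PERMANOVA battery (age, cognitive
score, maternal education) with BH correction, and a Mantel test
between the two feature spaces. In this synthetic cohort age drives a
strong composition gradient, so expect a large age R^2 and a smaller
but nonzero cognitive-score R^2 (the planted taxon links the two).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from gutbrain.community import bray_curtis, mantel, pcoa, permanova_battery
from gutbrain.core_data import read_metadata, read_gene_profiles, read_taxonomic_profiles

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
parser.add_argument("--out", type=Path, default=Path("results/community"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

taxa = read_taxonomic_profiles(args.cohort / "synthetic_taxa.tsv")
genes = read_gene_profiles(args.cohort / "synthetic_genefamilies.tsv")
meta = {r.sample_id: r for r in read_metadata(args.cohort / "synthetic_metadata.csv")}

d_taxa = bray_curtis(taxa)
d_genes = bray_curtis(genes)

ord_taxa = pcoa(d_taxa, k=2)
print(f"taxa PCoA: axis 1 explains {ord_taxa.variance_explained[0]:.1%}, "
      f"axis 2 {ord_taxa.variance_explained[1]:.1%} "
      f"({ord_taxa.n_negative_eigenvalues} negative eigenvalues dropped)")
coords = pd.DataFrame(ord_taxa.coordinates, columns=["PCo1", "PCo2"])
coords.insert(0, "sample_id", ord_taxa.sample_ids)
coords["age_months"] = [meta[s].age_months for s in ord_taxa.sample_ids]
coords.to_csv(args.out / "pcoa_taxa.csv", index=False, float_format="%.6g")

covariates = {
    "age": np.array([meta[s].age_months for s in taxa.sample_ids]),
    "cognitive_score": np.array([meta[s].cognitive_score for s in taxa.sample_ids]),
    "maternal_education": np.array([float(meta[s].maternal_education) for s in taxa.sample_ids]),
}
battery = permanova_battery(
    {"taxa": d_taxa, "genes": d_genes}, covariates,
    n_permutations=999, seed=args.seed,
)
battery.to_csv(args.out / "permanova.csv", index=False, float_format="%.6g")
print(battery.to_string(index=False))

m = mantel(d_taxa, d_genes, n_permutations=999, seed=args.seed)
print(f"Mantel taxa vs genes: r = {m.statistic:.3f}, p = {m.p_value:.4f}")
pd.DataFrame([{"comparison": "taxa_vs_genes", "r": m.statistic, "p_value": m.p_value,
               "n_permutations": m.n_permutations}]).to_csv(
    args.out / "mantel.csv", index=False, float_format="%.6g")
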