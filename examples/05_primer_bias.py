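"""Primer-binding-site mismatches and allele detection curves.

Counts each allele's Hamming mismatches to a primer pair's binding sites,
compares the mismatch load of alleles a short-amplicon assay would share
with this study against the rest, and bootstraps allele detection curves:
how many alleles one expects to see when n genotypes are resampled, given a
maximum tolerated mismatch count.
"""

from sealmhc import (
    Genotype, PLACEHOLDER_PRIMERS, SimulationConfig, allele_detection_curve,
    Allele, AlleleCatalog, compare_mismatch_groups, mismatch_table,
    simulate_dataset,
)

ds = simulate_dataset(SimulationConfig(seed=8))
catalog = AlleleCatalog(
    [Allele(n, s, 10, 2) for n, s in zip(ds.pool["name"], ds.pool["sequence"])]
)
gts = [
    Genotype(r.individual_id, frozenset({r.allele1, r.allele2}), r.colony)
    for r in ds.genotypes.itertuples()
]

mt = mismatch_table(catalog, PLACEHOLDER_PRIMERS).sort_values("mismatches")
print(mt.drop(columns="clone_count").to_string(index=False))
shared = list(mt["name"][:2])  # stand-in for alleles a short assay detects
res = compare_mismatch_groups(catalog, shared, PLACEHOLDER_PRIMERS)
print(f"mean mismatches: shared {res['mean_shared']:.2f}, "
      f"unique {res['mean_unique']:.2f}")

curve = allele_detection_curve(
    gts, catalog, PLACEHOLDER_PRIMERS, thresholds=range(1, 7), n_rep=499, seed=3
)
piv = curve.pivot(index="n", columns="threshold", values="mean_detected")
print(piv.loc[[1, 5, 13, 30, 56]].round(2).to_string())
print("Rows: resampled individuals; columns: tolerated primer mismatches.")
print("Stricter thresholds plateau at fewer alleles — mimicking how primer-")
print("site variation depresses the diversity a short-amplicon assay finds.")
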