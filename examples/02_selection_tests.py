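"""Codon-partitioned selection tests on an allele catalog.

Generates an allele pool with a five-fold excess of non-synonymous change at
the 24 putative antigen binding site (pABS) codons, then measures what a
selection analysis recovers: variable sites, pairwise amino-acid divergence
per codon region, and modified Nei–Gojobori dN/dS with codon-based Z-tests.
"""

from sealmhc import (
    CodonPartition, SimulationConfig, divergence_region_test, dnds_table,
    generate_allele_pool, mean_pairwise_divergence, translate_alignment,
    variable_sites,
)

pool = generate_allele_pool(SimulationConfig(seed=4))
seqs = list(pool["sequence"])
peptides = translate_alignment(seqs)
part = CodonPartition()

print(f"alleles: {len(seqs)}, variable sites: {variable_sites(seqs)} nt / "
      f"{variable_sites(peptides)} aa")

d_p, se_p, per_p = mean_pairwise_divergence(peptides, part.pabs_codons, seed=1)
d_n, se_n, per_n = mean_pairwise_divergence(peptides, part.non_pabs_codons, seed=1)
t, p = divergence_region_test(per_p, per_n)
print(f"amino-acid divergence  pABS d={d_p:.3f}±{se_p:.3f}  "
      f"non-pABS d={d_n:.3f}±{se_n:.3f}  (paired t={t:.1f}, p={p:.2g})")

print(f"{'region':8s} {'dN':>12s} {'dS':>12s} {'Z(dN>dS)':>9s} {'p':>8s}")
for row in dnds_table(seqs, part, tstv_ratio=1.0, n_boot=999, seed=2):
    print(f"{row.region:8s} {row.dN:6.3f}±{row.se_dN:.3f} {row.dS:6.3f}±{row.se_dS:.3f}"
          f" {row.z_greater:9.2f} {row.p_greater:8.4f}")
print("dN >> dS at the pABS but not elsewhere is the signature of balancing")
print("selection on the peptide binding region.")
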