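"""Reference data for the DQB exon 2 pipeline.

The unit of analysis throughout the package is the 267 bp protein-coding
second exon of the MHC class II DQB locus, which encodes the 89 residues of
the beta-1 domain of the class II peptide binding region.  Codons are
numbered 1..89 from the first exon base.

The putative antigen binding sites (pABS) are the 24 codons homologous to
the human class II beta-chain antigen-contact positions resolved by protein
structure.  Antigen-contact homology across mammals is hypothetical; the
list is plain data and can be overridden wherever a ``pabs_codons`` argument
is accepted.
"""

from __future__ import annotations

EXON_LENGTH = 267
N_CODONS = EXON_LENGTH // 3

#: 1-based codon indices of the 24 putative antigen binding sites (class II
#: beta-chain antigen-contact positions of the human structure).
DEFAULT_PABS_CODONS: frozenset[int] = frozenset(
    {9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57,
     60, 61, 65, 67, 68, 70, 71, 74, 78, 81, 82, 85}
)

#: Synthetic 267 bp founder exon (stop-free in frame 0). This is a synthetic
#: stand-in used by the simulator and the test suite; it is not a real
#: ArGa-DQB allele.
SYNTHETIC_FOUNDER_EXON = (
    "TTTAATTTCAACGAGCGGAAGTACAAATCTAGCTGCATTCGAAAGGTAAAAGAATGTTCC"
    "GTCCACCGCGATTTCTGCAACTCACGCGACCCCCTGCCTATGAGAGGAGGGAGATTGTCT"
    "TGTGCGTTCCAACCTCTAGCGCACTACTGCCGAACCTTGGGGATAAGCTTATCACTAAGC"
    "CATACTAGAGGGAGTCATTTACAATCGCATGGTCCCCTCATAATTACATATTACAATACT"
    "TTCTCTTTTATGCTGGTTAATAGCGTG"
)

#: Synthetic intron flanks used to build full-length amplicons around the
#: exon (the real study amplified a 459 bp product with intronic primers).
SYNTHETIC_INTRON_5P = "GCTGTTGGTTGGGCTGAGCATTCAGGACTTGTTCCAGAGTTGACCCTTGACGTAGGAGACCTCAATGGTCACTTAGGATCTGCAAAGTTCAG"
SYNTHETIC_INTRON_3P = "GTAAGTACCTGGGACCTAGGAACTCTAGGTTCACACGGATCCTAGGTATCAGTTACCAGACTGGACACTGTTCCTGCTGAGGTGGTTTCTGG"


def synthetic_amplicon(exon: str | None = None) -> str:
    """Return a full synthetic amplicon (intron flanks around *exon*)."""
    if exon is None:
        exon = SYNTHETIC_FOUNDER_EXON
    return SYNTHETIC_INTRON_5P + exon + SYNTHETIC_INTRON_3P
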