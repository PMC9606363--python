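"""Exception types raised by the pipeline."""


class SealMHCError(Exception):
    """Base class for all package errors."""


class FastaHeaderError(SealMHCError):
    """A FASTA header does not encode an individual identifier."""


class TrimError(SealMHCError):
    """The reference exon could not be placed inside an amplicon."""


class AlignmentError(TrimError):
    """Placing the reference exon would require internal gaps."""


class SimulationError(SealMHCError):
    """The generator could not satisfy its constraints."""


class BiasError(SimulationError):
    """All amplification weights of an individual's alleles are zero."""


class TranslationError(SealMHCError):
    """A coding sequence contains a premature stop codon."""
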