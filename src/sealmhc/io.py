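"""Reading and writing the formats the pipeline touches.

FASTA for clone and allele sequences (via Biopython), UTF-8 CSV with header
rows for all tables (genotypes, pedigree, microsatellites, colony labels and
result tables), Newick for trees and YAML for run configuration.  All
coordinates in reports are 1-based closed intervals, matching codon
numbering.  Missing microsatellite alleles are encoded as empty cells.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FastaHeaderError, TrimError

logger = logging.getLogger(__name__)

_VALID_BASES = re.compile(r"^[ACGT]+$")


@dataclasses.dataclass(frozen=True)
class CloneRecord:
    """One sequenced clone: an individual identifier plus its insert sequence.

    After :func:`trim_to_reading_frame` the sequence is the 267 bp coding
    exon; straight off the sequencer it may be a longer amplicon.
    """

    clone_id: str
    individual_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise FastaHeaderError(f"clone {self.clone_id!r}: empty individual_id")
        if not _VALID_BASES.match(self.sequence):
            raise ValueError(
                f"clone {self.clone_id!r}: sequence must be over ACGT only "
                "(ambiguity codes are rejected)"
            )


def read_clone_fasta(
    path: str | Path, id_delimiter: str = "|", id_field: int = 0
) -> list[CloneRecord]:
    """Read cloned amplicon sequences from FASTA.

    The individual identifier is taken from the record id split on
    *id_delimiter* (field *id_field*, default: first token).  Order of the
    file is preserved.
    """
    records: list[CloneRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split(id_delimiter)
        if len(fields) <= id_field or not fields[id_field]:
            raise FastaHeaderError(
                f"header {rec.id!r} lacks individual field {id_field} "
                f"(delimiter {id_delimiter!r})"
            )
        records.append(
            CloneRecord(
                clone_id=rec.id,
                individual_id=fields[id_field],
                sequence=str(rec.seq).upper(),
            )
        )
    if not records:
        logger.warning("no FASTA records found in %s", path)
    logger.info("read %d clone records from %s", len(records), path)
    return records


def write_fasta(path: str | Path, entries: Iterable[tuple[str, str]]) -> None:
    """Write ``(name, sequence)`` pairs to FASTA."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    SeqIO.write(recs, str(path), "fasta")


def trim_to_reading_frame(
    sequence: str,
    reference_exon: str,
    max_mismatch_frac: float = 0.1,
    flank_k: int = 15,
) -> str:
    """Extract the coding-exon window of an amplicon.

    Placement is alignment-free when the first and last *flank_k*-mers of the
    reference exon occur exactly and the spacing matches; otherwise the exon
    is placed by banded edit distance (infix alignment).  A placement that
    would introduce internal gaps raises :class:`AlignmentError`; more than
    ``max_mismatch_frac`` substitutions raises :class:`TrimError`.
    """
    sequence = sequence.upper()
    reference_exon = reference_exon.upper()
    n = len(reference_exon)
    if len(sequence) < n:
        raise TrimError(
            f"sequence length {len(sequence)} shorter than reference exon ({n})"
        )
    # fast path: exact flank placement
    start = sequence.find(reference_exon[:flank_k])
    if start != -1:
        end_start = sequence.find(reference_exon[-flank_k:], start)
        if end_start != -1 and end_start + flank_k - start == n:
            window = sequence[start : start + n]
            mism = sum(a != b for a, b in zip(window, reference_exon))
            if mism / n <= max_mismatch_frac:
                logger.debug("trim: exact flank placement at offset %d", start)
                return window
    # fall back to banded infix alignment
    max_ed = int(max_mismatch_frac * n)
    aln = edlib.align(reference_exon, sequence, mode="HW", task="path", k=max_ed)
    if aln["editDistance"] < 0:
        raise TrimError(
            f"reference exon not found within {max_ed} edits of any window"
        )
    if "I" in aln["cigar"] or "D" in aln["cigar"]:
        raise AlignmentError(
            "placing the reference exon requires internal gaps "
            f"(cigar {aln['cigar']})"
        )
    start, end = aln["locations"][0]
    logger.debug("trim: banded placement at offset %d (%d edits)", start, aln["editDistance"])
    return sequence[start : end + 1]


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (primers, pABS codons, thresholds, seeds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"individual_id": str, "mother_id": str, "pup_id": str})


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a mother–pup pedigree CSV (mother_id, pup_id, colony)."""
    ped = read_table(path)
    if (ped["mother_id"] == ped["pup_id"]).any():
        raise ValueError("pedigree contains a row with mother_id == pup_id")
    if ped["pup_id"].duplicated().any():
        raise ValueError("a pup appears more than once in the pedigree")
    return ped


def write_results(
    outdir: str | Path,
    tables: Mapping[str, pd.DataFrame] | None = None,
    trees: Mapping[str, str] | None = None,
    fastas: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    config: Mapping | None = None,
    seeds: Mapping[str, int] | None = None,
) -> Path:
    """Write result tables (CSV), trees (Newick) and FASTA files plus a manifest.

    The manifest records the file list, a hash of the configuration and the
    seeds used, so a run can be reproduced bit for bit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for name, df in (tables or {}).items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p.name)
    for name, newick in (trees or {}).items():
        p = outdir / f"{name}.nwk"
        p.write_text(newick if newick.endswith("\n") else newick + "\n")
        written.append(p.name)
    for name, entries in (fastas or {}).items():
        p = outdir / f"{name}.fasta"
        write_fasta(p, entries)
        written.append(p.name)
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "files": sorted(written),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seeds": dict(seeds or {}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
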