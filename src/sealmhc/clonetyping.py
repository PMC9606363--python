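"""Allele calling from cloned amplicon sequences.

The discovery chain is: tally identical clone sequences, discard putative
PCR/sequencing artifacts (rare variants one or two nucleotides away from a
more common sequence), accept alleles supported by enough independent
individuals, assign per-individual genotypes, and check Mendelian
compatibility of mother–pup pairs.

Artifact rule: a variant is discarded iff its total clone count is at most
``max_artifact_count`` (default 2), a doubleton additionally occurs entirely
within one individual, and it lies within ``max_nt_diff`` substitutions of a
strictly more common retained sequence.  Rare variants with no near
neighbour are retained but flagged — they may be genuine rare alleles.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter, defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CloneRecord

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class VariantTally:
    """All clones sharing one exact sequence."""

    sequence: str
    total_count: int
    per_individual_counts: dict[str, int]
    flagged: bool = False  # low-count variant with no near neighbour

    @property
    def n_individuals(self) -> int:
        return len(self.per_individual_counts)


@dataclasses.dataclass
class Allele:
    name: str
    sequence: str
    clone_count: int
    individual_count: int
    flagged: bool = False


@dataclasses.dataclass
class AlleleCatalog:
    """Validated alleles, named ``ArGa-DQB*01..`` in descending clone support."""

    alleles: list[Allele]

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(self.alleles)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.alleles]

    @property
    def sequences(self) -> dict[str, str]:
        return {a.name: a.sequence for a in self.alleles}

    @property
    def total_clones(self) -> int:
        return sum(a.clone_count for a in self.alleles)

    @property
    def mean_clones_per_allele(self) -> float:
        return self.total_clones / len(self.alleles)

    def name_of(self, sequence: str) -> str | None:
        for a in self.alleles:
            if a.sequence == sequence:
                return a.name
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.name, a.sequence, a.clone_count, a.individual_count, a.flagged)
             for a in self.alleles],
            columns=["name", "sequence", "clone_count", "individual_count", "flagged"],
        )


@dataclasses.dataclass
class Genotype:
    individual_id: str
    allele_names: frozenset[str]
    colony: str | None = None
    status: str = "ok"  # "ok" | "multi_allele_flag"

    @property
    def heterozygous(self) -> bool:
        return len(self.allele_names) > 1


def tally_variants(clones: Sequence[CloneRecord]) -> list[VariantTally]:
    """Group clones by exact sequence; one tally per distinct sequence."""
    lengths = {len(c.sequence) for c in clones}
    if len(lengths) > 1:
        raise ValueError(f"clones are not all the same length: {sorted(lengths)}")
    per_seq: dict[str, Counter] = defaultdict(Counter)
    for c in clones:
        per_seq[c.sequence][c.individual_id] += 1
    tallies = [
        VariantTally(seq, sum(cnt.values()), dict(cnt)) for seq, cnt in per_seq.items()
    ]
    tallies.sort(key=lambda t: (-t.total_count, t.sequence))
    return tallies


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def filter_artifacts(
    tallies: Sequence[VariantTally],
    max_artifact_count: int = 2,
    max_nt_diff: int = 2,
) -> tuple[list[VariantTally], list[VariantTally]]:
    """Partition tallies into (retained, discarded) putative artifacts.

    Iterates from most to least common so that chains of artifacts collapse
    onto true alleles: the neighbour comparison is always against the
    already-retained, strictly more common sequences.
    """
    order = sorted(tallies, key=lambda t: (-t.total_count, t.sequence))
    retained: list[VariantTally] = []
    discarded: list[VariantTally] = []
    for t in order:
        candidate_artifact = t.total_count <= max_artifact_count
        if candidate_artifact and t.total_count == 2 and t.n_individuals > 1:
            # doubletons split across individuals are kept (the study's
            # doubleton artifacts always occurred within one individual)
            candidate_artifact = False
        if candidate_artifact:
            near = any(
                r.total_count > t.total_count
                and hamming(r.sequence, t.sequence) <= max_nt_diff
                for r in retained
            )
            if near:
                discarded.append(t)
                continue
            if t.total_count <= max_artifact_count:
                t.flagged = True  # low-count, no near neighbour: possible rare allele
        retained.append(t)
    assert len(retained) + len(discarded) == len(tallies)
    return retained, discarded


def call_alleles(
    retained: Sequence[VariantTally],
    min_individuals: int = 2,
    min_clones: int = 1,
    name_prefix: str = "ArGa-DQB*",
) -> AlleleCatalog:
    """Accept retained variants as alleles when enough individuals carry them.

    Alleles are named ``<prefix>01..`` in descending clone count, ties broken
    lexicographically by sequence.
    """
    accepted = [
        t
        for t in retained
        if t.n_individuals >= min_individuals and t.total_count >= min_clones
    ]
    accepted.sort(key=lambda t: (-t.total_count, t.sequence))
    alleles = [
        Allele(
            name=f"{name_prefix}{i + 1:02d}",
            sequence=t.sequence,
            clone_count=t.total_count,
            individual_count=t.n_individuals,
            flagged=t.flagged,
        )
        for i, t in enumerate(accepted)
    ]
    if not alleles:
        logger.warning("no variants met the allele-acceptance thresholds")
    else:
        logger.info(
            "called %d alleles, mean %.1f clones per allele",
            len(alleles),
            sum(a.clone_count for a in alleles) / len(alleles),
        )
    return AlleleCatalog(alleles)


def assign_genotypes(
    catalog: AlleleCatalog,
    clones: Sequence[CloneRecord],
    colony_of: dict[str, str] | None = None,
) -> tuple[list[Genotype], list[str]]:
    """Per individual, the set of catalog alleles seen in its clones.

    Individuals whose clones support more than two catalog alleles are kept
    but flagged (``multi_allele_flag``); individuals with no retained catalog
    allele are reported as untyped.  Returns (genotypes, untyped_ids).
    """
    seq_to_name = {a.sequence: a.name for a in catalog.alleles}
    per_ind: dict[str, set[str]] = defaultdict(set)
    all_inds: list[str] = []
    seen = set()
    for c in clones:
        if c.individual_id not in seen:
            seen.add(c.individual_id)
            all_inds.append(c.individual_id)
        name = seq_to_name.get(c.sequence)
        if name is not None:
            per_ind[c.individual_id].add(name)
    genotypes = []
    untyped = []
    for ind in all_inds:
        names = per_ind.get(ind)
        if not names:
            untyped.append(ind)
            continue
        status = "ok" if len(names) <= 2 else "multi_allele_flag"
        genotypes.append(
            Genotype(
                individual_id=ind,
                allele_names=frozenset(names),
                colony=(colony_of or {}).get(ind),
                status=status,
            )
        )
    if untyped:
        logger.warning("%d individuals had no retained catalog allele: %s",
                       len(untyped), untyped)
    return genotypes, untyped


def clones_per_individual(clones: Sequence[CloneRecord]) -> pd.Series:
    """Retained clone count per individual (for dataset summaries)."""
    counts = Counter(c.individual_id for c in clones)
    return pd.Series(counts, name="n_clones").sort_index()


def check_mendelian(
    genotypes: Iterable[Genotype], pedigree: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Mother–pup compatibility: the pair must share at least one allele.

    Pairs with an untyped member are excluded from the summary fraction.
    Returns (per-pair table, compatible fraction).
    """
    by_id = {g.individual_id: g for g in genotypes}
    rows = []
    for r in pedigree.itertuples(index=False):
        m = by_id.get(r.mother_id)
        p = by_id.get(r.pup_id)
        if m is None or p is None:
            logger.warning("pair (%s, %s) excluded: member untyped", r.mother_id, r.pup_id)
            rows.append((r.mother_id, r.pup_id, None))
            continue
        rows.append((r.mother_id, r.pup_id, bool(m.allele_names & p.allele_names)))
    table = pd.DataFrame(rows, columns=["mother_id", "pup_id", "compatible"])
    scored = table.dropna(subset=["compatible"])
    if len(scored) == 0:
        return table, float("nan")
    frac = float(scored["compatible"].sum() / len(scored))
    return table, frac
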