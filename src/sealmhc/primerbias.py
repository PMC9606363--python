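"""Primer-binding-site mismatches and allele detection curves.

Quantifies, per allele, the number of nucleotide mismatches (Hamming
distance) to a primer pair's binding sites within the 267 bp exon, compares
mismatch loads between allele groups (e.g. alleles shared with an earlier
study vs alleles unique to the current one), and computes bootstrap allele
detection curves: the expected number of distinct alleles observed when n
genotyped individuals are resampled with replacement, counting only alleles
whose mismatch load does not exceed a threshold.

The forward primer is compared to the sense strand; the reverse primer (as
synthesized, 5'->3') is reverse-complemented first.  Binding sites can be
fixed by coordinates or located by a minimum-Hamming scan over all windows.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .clonetyping import AlleleCatalog, Genotype, hamming
from .reference import SYNTHETIC_FOUNDER_EXON


@dataclasses.dataclass(frozen=True)
class PrimerSet:
    """A primer pair and (optionally) fixed binding-site coordinates.

    Coordinates are 1-based closed intervals on the exon sense strand; when
    absent the binding site is located at the minimum-Hamming window.
    """

    forward: str
    reverse: str
    forward_site: tuple[int, int] | None = None
    reverse_site: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        for primer, site in ((self.forward, self.forward_site),
                             (self.reverse, self.reverse_site)):
            if site is not None and site[1] - site[0] + 1 != len(primer):
                raise ValueError(f"site {site} does not match primer length {len(primer)}")
        f, r = self.forward_site, self.reverse_site
        if f and r and not (f[1] < r[0] or r[1] < f[0]):
            raise ValueError("primer binding sites overlap")


#: Synthetic stand-in primer pair for tests and examples: the earlier
#: study's internal primer sequences are not published here.  These anneal
#: exactly to the synthetic founder exon and span a 141 bp product.
PLACEHOLDER_PRIMERS = PrimerSet(
    forward=SYNTHETIC_FOUNDER_EXON[30:50],
    reverse=str(Seq(SYNTHETIC_FOUNDER_EXON[151:171]).reverse_complement()),
    forward_site=(31, 50),
    reverse_site=(152, 171),
)


def _site_mismatches(allele: str, probe: str, site: tuple[int, int] | None) -> int:
    if len(probe) > len(allele):
        raise ValueError("primer longer than sequence")
    if site is not None:
        lo, hi = site
        return hamming(allele[lo - 1 : hi], probe)
    return min(
        hamming(allele[i : i + len(probe)], probe)
        for i in range(len(allele) - len(probe) + 1)
    )


def primer_mismatch_count(
    allele: str, primers: PrimerSet, combine: str = "sum"
) -> int:
    """Total primer-binding-site mismatches of one allele.

    ``combine`` is "sum" (forward + reverse, default) or "max" (the worse of
    the two sites).
    """
    fwd = _site_mismatches(allele, primers.forward.upper(), primers.forward_site)
    rev_probe = str(Seq(primers.reverse.upper()).reverse_complement())
    rev = _site_mismatches(allele, rev_probe, primers.reverse_site)
    if combine == "sum":
        return fwd + rev
    if combine == "max":
        return max(fwd, rev)
    raise ValueError(f"unknown combine {combine!r}")


def mismatch_table(
    catalog: AlleleCatalog, primers: PrimerSet, combine: str = "sum"
) -> pd.DataFrame:
    """Per-allele mismatch counts with clone-support annotation."""
    total = catalog.total_clones
    rows = [
        {
            "name": a.name,
            "mismatches": primer_mismatch_count(a.sequence, primers, combine),
            "clone_count": a.clone_count,
            "clone_frequency": a.clone_count / total if total else float("nan"),
        }
        for a in catalog.alleles
    ]
    return pd.DataFrame(rows)


def compare_mismatch_groups(
    catalog: AlleleCatalog,
    shared_allele_names: Iterable[str],
    primers: PrimerSet,
    combine: str = "sum",
) -> dict:
    """Mean mismatches for alleles shared with an earlier study vs unique ones.

    Returns group means, the unique/shared ratio (NaN when the shared mean is
    zero or a group is empty) and the per-allele table.
    """
    shared = set(shared_allele_names)
    unknown = shared - set(catalog.names)
    if unknown:
        raise ValueError(f"shared alleles not in catalog: {sorted(unknown)}")
    tab = mismatch_table(catalog, primers, combine)
    tab["group"] = np.where(tab["name"].isin(shared), "shared", "unique")
    means = tab.groupby("group")["mismatches"].mean()
    mean_shared = float(means.get("shared", np.nan))
    mean_unique = float(means.get("unique", np.nan))
    ratio = (
        mean_unique / mean_shared
        if mean_shared and not np.isnan(mean_shared) and not np.isnan(mean_unique)
        else float("nan")
    )
    return {
        "mean_shared": mean_shared,
        "mean_unique": mean_unique,
        "ratio_unique_over_shared": ratio,
        "table": tab,
    }


def allele_detection_curve(
    genotypes: Sequence[Genotype] | Mapping[str, Iterable[str]],
    catalog: AlleleCatalog,
    primers: PrimerSet,
    thresholds: Iterable[int] = range(1, 7),
    n_range: Iterable[int] | None = None,
    n_rep: int = 999,
    seed: int | None = None,
    combine: str = "sum",
) -> pd.DataFrame:
    """Bootstrap allele detection curves under mismatch thresholds.

    For every (sample size n, threshold t): draw n individuals with
    replacement ``n_rep`` times and count the distinct alleles present in the
    drawn genotypes whose mismatch count is <= t.  The sampling unit is the
    individual genotype (all its alleles enter together; flagged multi-allele
    individuals contribute all of theirs).  Returns a tidy DataFrame with
    columns n, threshold, mean_detected, sd_detected.
    """
    if isinstance(genotypes, Mapping):
        sets = {k: frozenset(v) for k, v in genotypes.items()}
    else:
        sets = {g.individual_id: g.allele_names for g in genotypes}
    if not sets:
        raise ValueError("no genotypes to resample")
    mism = {
        a.name: primer_mismatch_count(a.sequence, primers, combine)
        for a in catalog.alleles
    }
    names = sorted(mism)
    name_idx = {n: i for i, n in enumerate(names)}
    inds = sorted(sets)
    # individual x allele incidence matrix
    inc = np.zeros((len(inds), len(names)), dtype=bool)
    for i, ind in enumerate(inds):
        for a in sets[ind]:
            if a in name_idx:
                inc[i, name_idx[a]] = True
    mvec = np.array([mism[n] for n in names])
    thresholds = sorted(thresholds)
    if n_range is None:
        n_range = range(1, len(inds) + 1)
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_range:
        detected = np.empty((n_rep, len(thresholds)))
        for rep in range(n_rep):
            draw = rng.integers(len(inds), size=n)
            present = inc[draw].any(axis=0)
            for k, t in enumerate(thresholds):
                detected[rep, k] = np.count_nonzero(present & (mvec <= t))
        for k, t in enumerate(thresholds):
            rows.append(
                {
                    "n": int(n),
                    "threshold": int(t),
                    "mean_detected": float(detected[:, k].mean()),
                    "sd_detected": float(detected[:, k].std(ddof=0)),
                }
            )
    return pd.DataFrame(rows)
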