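"""Codon-based selection analyses of the 267 bp exon.

Implements translation and variable-site counts, mean pairwise amino-acid
divergence with a codon-column bootstrap, and synonymous/non-synonymous
substitution rates under the modified Nei–Gojobori method with Jukes–Cantor
correction, partitioned into putative antigen binding site (pABS) codons and
the remaining codons.

Method notes
------------
Potential synonymous/non-synonymous sites per codon are counted with
transition changes weighted by the transition/transversion ratio ``R``
(modified Nei–Gojobori); changes to stop codons count as non-synonymous and
each codon is normalised to 3 sites.  Observed differences between a codon
pair average the synonymous/non-synonymous step counts over all minimal
substitution pathways, weighting pathways equally and excluding pathways
that pass through a stop codon (all-blocked pairs fall back to including
them).  Proportions are Jukes–Cantor corrected, d = -(3/4) ln(1 - 4p/3),
undefined for p >= 3/4.  Variances for the codon-based Z-tests come from
bootstrap resampling of codon columns within the tested region.
"""

from __future__ import annotations

import dataclasses
import itertools
import functools
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from Bio.Data.CodonTable import standard_dna_table

from .errors import TranslationError
from .reference import DEFAULT_PABS_CODONS, N_CODONS

_PURINES = {"A", "G"}
_STOPS = frozenset(standard_dna_table.stop_codons)
_AA = dict(standard_dna_table.forward_table)
_BASES = "ACGT"


@dataclasses.dataclass(frozen=True)
class CodonPartition:
    """Partition of the 89 exon codons into pABS and non-pABS (1-based)."""

    pabs_codons: frozenset[int] = DEFAULT_PABS_CODONS
    n_codons: int = N_CODONS

    def __post_init__(self) -> None:
        if not self.pabs_codons <= set(range(1, self.n_codons + 1)):
            raise ValueError("pABS codons must lie in 1..n_codons")

    @property
    def non_pabs_codons(self) -> frozenset[int]:
        return frozenset(range(1, self.n_codons + 1)) - self.pabs_codons

    def region(self, name: str) -> frozenset[int]:
        if name == "exon":
            return frozenset(range(1, self.n_codons + 1))
        if name == "pabs":
            return self.pabs_codons
        if name == "nonpabs":
            return self.non_pabs_codons
        raise ValueError(f"unknown region {name!r}")


@dataclasses.dataclass
class DnDsResult:
    """Substitution-rate estimates and Z-tests for one codon region."""

    region: str
    dN: float
    dS: float
    se_dN: float
    se_dS: float
    z_neq: float
    p_neq: float
    z_greater: float
    p_greater: float
    undefined: bool = False


def translate_alignment(alignment: Sequence[str]) -> list[str]:
    """Translate in-frame nucleotide sequences; error on internal stops."""
    out = []
    for i, seq in enumerate(alignment):
        if len(seq) % 3:
            raise ValueError(f"sequence {i} length {len(seq)} is not a codon multiple")
        aas = []
        for c in range(len(seq) // 3):
            codon = seq[3 * c : 3 * c + 3]
            if codon in _STOPS:
                raise TranslationError(
                    f"sequence {i}: stop codon {codon} at codon {c + 1}"
                )
            aas.append(_AA[codon])
        out.append("".join(aas))
    return out


def variable_sites(alignment: Sequence[str]) -> int:
    """Number of columns with more than one state (nucleotide or amino acid)."""
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    if len({len(s) for s in alignment}) != 1:
        raise ValueError("alignment is ragged")
    arr = np.array([list(s) for s in alignment])
    return int(sum(len(set(col)) > 1 for col in arr.T))


def _pair_index(n: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(n), 2))


def jukes_cantor(p: float | np.ndarray) -> float | np.ndarray:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3); NaN for p >= 3/4."""
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(p < 0.75, -0.75 * np.log(1.0 - 4.0 * p / 3.0), np.nan)
    return d if d.ndim else float(d)


def mean_pairwise_divergence(
    aa_alignment: Sequence[str],
    codon_subset: Iterable[int],
    correction: str = "none",
    n_boot: int = 999,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Mean over sequence pairs of per-pair amino-acid distance on a codon subset.

    ``correction`` is "none" (p-distance) or "poisson" (d = -ln(1-p)).  The
    standard error is a bootstrap over codon columns of the subset.  Returns
    (d, se, per-pair distances).
    """
    cols = sorted(codon_subset)
    if not cols:
        raise ValueError("codon subset is empty")
    arr = np.array([[s[c - 1] for c in cols] for s in aa_alignment])
    pairs = _pair_index(len(aa_alignment))
    diffs = np.array([(arr[i] != arr[j]) for i, j in pairs], dtype=float)  # P x C

    def summarise(mat: np.ndarray) -> tuple[float, np.ndarray]:
        p = mat.mean(axis=1)
        if correction == "poisson":
            with np.errstate(divide="ignore"):
                d = np.where(p < 1.0, -np.log(1.0 - p), np.nan)
        elif correction == "none":
            d = p
        else:
            raise ValueError(f"unknown correction {correction!r}")
        return float(np.mean(d)), d

    d_hat, per_pair = summarise(diffs)
    rng = np.random.default_rng(seed)
    nc = diffs.shape[1]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(nc, size=nc)
        boots[b], _ = summarise(diffs[:, idx])
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else 0.0
    return d_hat, se, per_pair


# ---------------------------------------------------------------------------
# modified Nei–Gojobori machinery


@functools.lru_cache(maxsize=None)
def _codon_sites(codon: str, R: float) -> tuple[float, float]:
    """Potential (synonymous, non-synonymous) sites of one codon.

    Transitions weighted by R, transversions by 1; stop neighbours count as
    non-synonymous; normalised so s + n = 3.
    """
    s = n = 0.0
    aa = _AA[codon]
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            w = R if (b in _PURINES) == (codon[pos] in _PURINES) else 1.0
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and _AA[alt] == aa:
                s += w
            else:
                n += w
    tot = (s + n) / 3.0
    return s / tot, n / tot


@functools.lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Observed (synonymous, non-synonymous) differences between two codons.

    Averages over all orderings of the differing positions, equally
    weighted, excluding pathways that pass through a stop codon (unless all
    pathways do, in which case all are used).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and nxt != c2:
                return None
            a1 = _AA.get(cur, "*")
            a2 = _AA.get(nxt, "*")
            if a1 == a2:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [walk(o) for o in itertools.permutations(diff)]
    valid = [r for r in results if r is not None]
    if not valid:  # all pathways blocked by stops: fall back to all pathways
        valid = [
            w
            for o in itertools.permutations(diff)
            if (w := _walk_through(c1, c2, o)) is not None
        ]
    sd = float(np.mean([v[0] for v in valid]))
    nd = float(np.mean([v[1] for v in valid]))
    return sd, nd


def _walk_through(c1: str, c2: str, order: tuple[int, ...]) -> tuple[float, float]:
    sd = nd = 0.0
    cur = c1
    for pos in order:
        nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
        if _AA.get(cur, "*") == _AA.get(nxt, "*"):
            sd += 1
        else:
            nd += 1
        cur = nxt
    return sd, nd


def _ng_arrays(
    nt_alignment: Sequence[str], codon_subset: Iterable[int], tstv_ratio: float
) -> dict[str, np.ndarray]:
    """Per-pair, per-codon site and difference arrays for the region."""
    cols = sorted(codon_subset)
    if not cols:
        raise ValueError("codon subset is empty")
    if len({len(s) for s in nt_alignment}) != 1 or len(nt_alignment[0]) % 3:
        raise ValueError("alignment must be equal-length and a codon multiple")
    codons = [[s[3 * (c - 1) : 3 * (c - 1) + 3] for c in cols] for s in nt_alignment]
    nseq, nc = len(codons), len(cols)
    s_site = np.empty((nseq, nc))
    n_site = np.empty((nseq, nc))
    for i in range(nseq):
        for k in range(nc):
            s_site[i, k], n_site[i, k] = _codon_sites(codons[i][k], tstv_ratio)
    pairs = _pair_index(nseq)
    P = len(pairs)
    S = np.empty((P, nc))
    N = np.empty((P, nc))
    Sd = np.empty((P, nc))
    Nd = np.empty((P, nc))
    for p, (i, j) in enumerate(pairs):
        S[p] = (s_site[i] + s_site[j]) / 2.0
        N[p] = (n_site[i] + n_site[j]) / 2.0
        for k in range(nc):
            Sd[p, k], Nd[p, k] = _pathway_counts(codons[i][k], codons[j][k])
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pairs": pairs}


def _dnds_from_arrays(arr: dict[str, np.ndarray], idx: np.ndarray | None = None):
    """Mean-over-pairs JC-corrected dN and dS, optionally on resampled columns."""
    sl = slice(None) if idx is None else idx
    S = arr["S"][:, sl].sum(axis=1)
    N = arr["N"][:, sl].sum(axis=1)
    Sd = arr["Sd"][:, sl].sum(axis=1)
    Nd = arr["Nd"][:, sl].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pS = np.where(S > 0, Sd / S, np.nan)
        pN = np.where(N > 0, Nd / N, np.nan)
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    return float(np.nanmean(dN)), float(np.nanmean(dS))


def nei_gojobori_dnds(
    nt_alignment: Sequence[str],
    codon_subset: Iterable[int],
    tstv_ratio: float = 2.0,
) -> tuple[float, float]:
    """Point estimates (dN, dS) for a codon region (mean over sequence pairs)."""
    arr = _ng_arrays(nt_alignment, codon_subset, tstv_ratio)
    return _dnds_from_arrays(arr)


def codon_z_test(
    nt_alignment: Sequence[str],
    codon_subset: Iterable[int],
    alternative: str = "two_sided",
    tstv_ratio: float = 2.0,
    n_boot: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Codon-based Z-test of dN vs dS with bootstrap variances.

    ``alternative`` is ``two_sided`` (H1: dN != dS) or ``dn_greater``
    (H1: dN > dS, positive selection).  Returns (Z, p).
    """
    arr = _ng_arrays(nt_alignment, codon_subset, tstv_ratio)
    dN, dS = _dnds_from_arrays(arr)
    if np.isnan(dN) or np.isnan(dS):
        return float("nan"), 1.0
    rng = np.random.default_rng(seed)
    nc = arr["S"].shape[1]
    reps = np.empty((n_boot, 2))
    for b in range(n_boot):
        idx = rng.integers(nc, size=nc)
        reps[b] = _dnds_from_arrays(arr, idx)
    reps = reps[~np.isnan(reps).any(axis=1)]
    if len(reps) < 2:
        return float("nan"), 1.0
    var = reps.var(axis=0, ddof=1)
    denom = np.sqrt(var.sum())
    if denom == 0:
        return 0.0, 1.0
    z = (dN - dS) / denom
    if alternative == "two_sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "dn_greater":
        p = float(stats.norm.sf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(p)


def dnds_table(
    nt_alignment: Sequence[str],
    partition: CodonPartition | None = None,
    tstv_ratio: float = 2.0,
    n_boot: int = 999,
    seed: int | None = None,
) -> list[DnDsResult]:
    """dN/dS with both Z-tests for the whole exon, pABS and non-pABS regions."""
    partition = partition or CodonPartition()
    out = []
    for region in ("exon", "pabs", "nonpabs"):
        subset = partition.region(region)
        arr = _ng_arrays(nt_alignment, subset, tstv_ratio)
        dN, dS = _dnds_from_arrays(arr)
        rng = np.random.default_rng(seed)
        nc = arr["S"].shape[1]
        reps = np.empty((n_boot, 2))
        for b in range(n_boot):
            idx = rng.integers(nc, size=nc)
            reps[b] = _dnds_from_arrays(arr, idx)
        good = reps[~np.isnan(reps).any(axis=1)]
        undefined = np.isnan(dN) or np.isnan(dS) or len(good) < 2
        if undefined:
            out.append(
                DnDsResult(region, dN, dS, float("nan"), float("nan"),
                           float("nan"), 1.0, float("nan"), 1.0, True)
            )
            continue
        se_dN, se_dS = good.std(axis=0, ddof=1)
        denom = float(np.sqrt(se_dN**2 + se_dS**2))
        z = (dN - dS) / denom if denom > 0 else 0.0
        p_neq = 2.0 * stats.norm.sf(abs(z)) if denom > 0 else 1.0
        p_gt = float(stats.norm.sf(z)) if denom > 0 else 1.0
        out.append(
            DnDsResult(region, dN, dS, float(se_dN), float(se_dS),
                       float(z), float(p_neq), float(z), float(p_gt))
        )
    return out


def divergence_region_test(
    per_pair_d_region1: np.ndarray, per_pair_d_region2: np.ndarray
) -> tuple[float, float]:
    """Paired t-test over sequence pairs of region-1 vs region-2 divergence."""
    a = np.asarray(per_pair_d_region1, dtype=float)
    b = np.asarray(per_pair_d_region2, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length vectors over >= 2 pairs")
    if np.allclose(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
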