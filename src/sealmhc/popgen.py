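"""Colony-level and individual-level population genetics.

Differentiation between colonies is measured with the Weir–Cockerham (1984)
variance-components estimator of FST (theta), multi-locus values combining
variance components by ratio of sums, with significance from permutation of
individuals' colony labels.  Per-colony diversity covers private alleles,
rarefied allelic richness, observed and unbiased expected heterozygosity and
FIS.  Individual-level statistics are Queller–Goodnight pairwise relatedness
and standardised multilocus heterozygosity (sMLH) from the microsatellites.

Genotype tables are wide DataFrames indexed by individual with two columns
per locus (``<locus>_1``, ``<locus>_2``); missing genotypes are NaN.
Individuals flagged for more than two MHC alleles are excluded from these
diploid statistics by the conversion helper.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .clonetyping import Genotype


def loci_of(table: pd.DataFrame) -> list[str]:
    """Locus names of a wide genotype table (columns ``<locus>_1/_2``)."""
    return sorted({c[:-2] for c in table.columns if c.endswith("_1")})


def mhc_to_table(genotypes: Iterable[Genotype]) -> tuple[pd.DataFrame, pd.Series]:
    """One-locus wide table from called MHC genotypes, excluding flagged ones.

    Homozygotes (a single retained allele) contribute two copies of that
    allele.  Returns (table, colony labels).
    """
    rows, labels = {}, {}
    for g in genotypes:
        if g.status != "ok":
            continue
        names = sorted(g.allele_names)
        a, b = (names[0], names[0]) if len(names) == 1 else names[:2]
        rows[g.individual_id] = {"MHC_1": a, "MHC_2": b}
        labels[g.individual_id] = g.colony
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "individual_id"
    return table, pd.Series(labels, name="colony")


def _encode(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per locus, an (n, 2) integer allele array with -1 for missing."""
    out = {}
    for locus in loci_of(table):
        cols = table[[f"{locus}_1", f"{locus}_2"]]
        cats = pd.unique(cols.values.ravel())
        cats = [c for c in cats if pd.notna(c)]
        mapping = {c: i for i, c in enumerate(cats)}
        arr = cols.apply(lambda s: s.map(mapping)).to_numpy(dtype=float)
        arr = np.where(np.isnan(arr), -1, arr).astype(int)
        arr[(arr == -1).any(axis=1)] = -1  # half-missing treated as missing
        out[locus] = arr
    return out


def _theta_components(arr: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Weir–Cockerham variance components (sum of a, sum of a+b+c) for one locus."""
    ok = arr[:, 0] >= 0
    arr = arr[ok]
    labels = labels[ok]
    pops = np.unique(labels)
    r = len(pops)
    if r < 2 or len(arr) == 0:
        return 0.0, 0.0
    n_i = np.array([(labels == p).sum() for p in pops], dtype=float)
    if (n_i == 0).any():
        keep = n_i > 0
        pops, n_i = pops[keep], n_i[keep]
        r = len(pops)
        if r < 2:
            return 0.0, 0.0
    C = n_i.sum()
    nbar = C / r
    nc = (C - (n_i**2).sum() / C) / (r - 1)
    if nbar <= 1 or nc <= 0:
        return 0.0, 0.0
    alleles = np.unique(arr)
    a_sum = d_sum = 0.0
    for al in alleles:
        p_i = np.array(
            [(arr[labels == p] == al).sum() / (2 * n_i[k]) for k, p in enumerate(pops)]
        )
        h_i = np.array(
            [
                ((arr[labels == p] == al).sum(axis=1) == 1).mean()
                for p in pops
            ]
        )
        pbar = (n_i * p_i).sum() / C
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / C
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        d_sum += a + b + c
    return a_sum, d_sum


def weir_cockerham_fst(table: pd.DataFrame, pop_labels: pd.Series) -> float:
    """Multi-locus Weir–Cockerham theta (ratio of summed variance components).

    NaN when the dataset is monomorphic (no variance components).
    """
    labels = pop_labels.loc[table.index].to_numpy()
    num = den = 0.0
    for arr in _encode(table).values():
        a, d = _theta_components(arr, labels)
        num += a
        den += d
    return num / den if den != 0 else float("nan")


def fst_permutation_test(
    table: pd.DataFrame,
    pop_labels: pd.Series,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation p-value for theta (labels permuted across individuals).

    p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).  Returns (theta, p).
    """
    encoded = list(_encode(table).values())
    labels = pop_labels.loc[table.index].to_numpy()

    def theta(lab: np.ndarray) -> float:
        num = den = 0.0
        for arr in encoded:
            a, d = _theta_components(arr, lab)
            num += a
            den += d
        return num / den if den != 0 else float("nan")

    obs = theta(labels)
    if np.isnan(obs):
        return obs, float("nan")
    rng = np.random.default_rng(seed)
    hits = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        t = theta(lab)
        if not np.isnan(t) and t >= obs:
            hits += 1
    return obs, (1 + hits) / (n_perm + 1)


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def diversity_summary(table: pd.DataFrame, pop_labels: pd.Series) -> pd.DataFrame:
    """Per-population diversity: n, private alleles, rarefied richness, Ho, He, Fis.

    Rarefaction size is the smallest per-population, per-locus gene count;
    He uses Nei's small-sample (unbiased) correction; Fis = 1 - Ho/He.
    """
    labels = pop_labels.loc[table.index]
    pops = sorted(labels.dropna().unique())
    encoded = _encode(table)
    # smallest gene count across pops and loci (typed individuals only)
    g = None
    for arr in encoded.values():
        for p in pops:
            n_typed = int(((labels == p).to_numpy() & (arr[:, 0] >= 0)).sum())
            if n_typed > 0:
                g = 2 * n_typed if g is None else min(g, 2 * n_typed)
    rows = []
    for p in pops:
        mask = (labels == p).to_numpy()
        n_pop = int(mask.sum())
        private = 0
        richness_terms, ho_terms, he_terms = [], [], []
        for arr in encoded.values():
            here = arr[mask & (arr[:, 0] >= 0)]
            there = arr[~mask & (arr[:, 0] >= 0)]
            if len(here) == 0:
                continue
            alleles, counts = np.unique(here, return_counts=True)
            other = set(np.unique(there)) if len(there) else set()
            private += sum(1 for al in alleles if al not in other)
            N = counts.sum()
            if g is not None and g <= N:
                with np.errstate(invalid="ignore"):
                    miss = np.where(
                        N - counts >= g,
                        np.exp(_log_comb(N - counts, g) - _log_comb(np.array(N, dtype=float), g)),
                        0.0,
                    )
                richness_terms.append(float((1 - miss).sum()))
            ho = float((here[:, 0] != here[:, 1]).mean())
            freqs = counts / N
            if N > 1:
                he = N / (N - 1) * (1 - (freqs**2).sum())
            else:
                he = float("nan")
            ho_terms.append(ho)
            he_terms.append(he)
        Ho = float(np.mean(ho_terms)) if ho_terms else float("nan")
        He = float(np.nanmean(he_terms)) if he_terms else float("nan")
        Fis = 1 - Ho / He if He and He > 0 else float("nan")
        rows.append(
            {
                "population": p,
                "n": n_pop,
                "private_alleles": private,
                "allelic_richness": float(np.mean(richness_terms))
                if richness_terms
                else float("nan"),
                "Ho": Ho,
                "He": He,
                "Fis": Fis,
            }
        )
    return pd.DataFrame(rows)


def queller_goodnight_r(
    table: pd.DataFrame, reference: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Symmetric matrix of Queller–Goodnight relatedness from microsatellites.

    Reference allele frequencies are computed over *reference* (default: the
    table itself, focal pair included).  Each ordered estimate sums locus
    numerators and denominators before dividing; the returned r is the mean
    of the two directional estimates.  Pairs with no overlapping typed loci
    are NaN; the diagonal is NaN (self-relatedness undefined here).
    """
    ref = table if reference is None else reference
    inds = list(table.index)
    n = len(inds)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for locus in loci_of(table):
        cols = [f"{locus}_1", f"{locus}_2"]
        vals = table[cols].to_numpy()
        ok = ~pd.isna(vals).any(axis=1)
        refvals = ref[cols].to_numpy()
        refvals = refvals[~pd.isna(refvals).any(axis=1)].ravel()
        if len(refvals) == 0:
            continue
        cats, counts = np.unique(refvals, return_counts=True)
        p = dict(zip(cats, counts / counts.sum()))
        a = vals[:, 0]
        b = vals[:, 1]
        pa = np.array([p.get(x, 0.0) for x in a])
        pb = np.array([p.get(x, 0.0) for x in b])
        eq = lambda u, v: (u[:, None] == v[None, :]).astype(float)  # noqa: E731
        share = 0.5 * (eq(a, a) + eq(a, b) + eq(b, a) + eq(b, b))
        num_l = share - (pa + pb)[:, None]
        den_l = (1.0 + (a == b).astype(float) - pa - pb)[:, None] * np.ones(n)
        m = ok[:, None] & ok[None, :]
        num += np.where(m, num_l, 0.0)
        den += np.where(m, den_l, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_dir = num / den
    r = (r_dir + r_dir.T) / 2.0
    np.fill_diagonal(r, np.nan)
    return pd.DataFrame(r, index=inds, columns=inds)


def smlh(table: pd.DataFrame) -> pd.Series:
    """Standardised multilocus heterozygosity per individual.

    sMLH_i = (proportion of i's typed loci that are heterozygous) divided by
    the mean, over i's typed loci, of the population mean heterozygosity of
    those loci.  With complete data the population mean of sMLH is 1.
    """
    loci = loci_of(table)
    het = pd.DataFrame(index=table.index, columns=loci, dtype=float)
    for locus in loci:
        a = table[f"{locus}_1"]
        b = table[f"{locus}_2"]
        typed = a.notna() & b.notna()
        het[locus] = np.where(typed, (a != b).astype(float), np.nan)
    locus_mean = het.mean(axis=0)
    ind_het = het.mean(axis=1)
    expected = het.notna().mul(locus_mean, axis=1).sum(axis=1) / het.notna().sum(axis=1)
    out = ind_het / expected
    out.name = "sMLH"
    return out


def mhc_heterozygosity(genotypes: Iterable[Genotype]) -> pd.Series:
    """1 if an individual carries two distinct retained alleles, else 0.

    Flagged (>2 allele) individuals are excluded.
    """
    vals = {
        g.individual_id: int(g.heterozygous)
        for g in genotypes
        if g.status == "ok"
    }
    return pd.Series(vals, name="mhc_het")
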