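"""Allele tree, UniFrac distances between individuals, and the two models
linking MHC variation to the microsatellite background.

The allele tree is neighbour-joining (Saitou–Nei) on nucleotide p-distances.
Unweighted UniFrac between two individuals' allele sets A and B follows the
standard rooted definition, evaluated at the tree's (arbitrary) root: with
"below an edge" meaning the leaf set on the far side from the root,

    d(A, B) = (branch length below which exactly one of A, B occurs)
              / (branch length below which A ∪ B occurs),

which is 0 iff the allele sets coincide and 1 for disjoint singleton sets.
Homozygotes contribute singleton sets.  Association models: a linear mixed
model of pairwise
UniFrac on pairwise relatedness with a multi-membership random intercept for
the two individuals of each pair, and a binomial GLM of individual MHC
heterozygosity on sMLH.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .clonetyping import Genotype

logger = logging.getLogger(__name__)


def p_distance_matrix(names: Sequence[str], seqs: Sequence[str]) -> DistanceMatrix:
    arr = np.array([list(s) for s in seqs])
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = (arr[i] != arr[j]).mean()
    return DistanceMatrix(d, ids=list(names))


def build_nj_tree(names: Sequence[str], seqs: Sequence[str]) -> TreeNode:
    """Neighbour-joining tree on nucleotide p-distances.

    Negative branch-length estimates are clamped to zero (logged); duplicate
    sequences simply sit at zero distance.
    """
    if len(names) < 3:
        raise ValueError("need at least three alleles for a tree")
    dm = p_distance_matrix(names, seqs)
    tree = nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.info("clamped %d negative NJ branch lengths to zero", clamped)
    return tree


def _edge_table(tree: TreeNode, unit_lengths: bool) -> list[tuple[frozenset[str], float]]:
    """(leaf set below edge, branch length) for every edge of the tree."""
    edges = []
    for node in tree.traverse(include_self=False):
        leaves = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        length = 1.0 if unit_lengths else float(node.length or 0.0)
        edges.append((leaves, length))
    return edges


def unifrac_pair(
    edges: list[tuple[frozenset[str], float]],
    a: frozenset[str],
    b: frozenset[str],
) -> float:
    if a == b:
        return 0.0
    unique = total = 0.0
    for leaves_below, length in edges:
        in_a = bool(a & leaves_below)
        in_b = bool(b & leaves_below)
        if not (in_a or in_b):
            continue
        total += length
        if in_a != in_b:
            unique += length
    if total == 0:
        logger.warning("zero spanning branch length for pair %s vs %s", set(a), set(b))
        return 0.0
    return unique / total


def unifrac_matrix(
    tree: TreeNode,
    genotypes: Iterable[Genotype] | Mapping[str, frozenset[str]],
    unit_lengths: bool = False,
) -> pd.DataFrame:
    """Pairwise unweighted UniFrac between individuals' allele sets.

    ``unit_lengths=True`` replaces branch lengths by 1 (topological UniFrac).
    Raises if a genotype allele is not a leaf of the tree.
    """
    if isinstance(genotypes, Mapping):
        sets = {k: frozenset(v) for k, v in genotypes.items()}
    else:
        sets = {g.individual_id: g.allele_names for g in genotypes}
    leaves = frozenset(t.name for t in tree.tips())
    for ind, s in sets.items():
        missing = s - leaves
        if missing:
            raise ValueError(f"individual {ind}: alleles not in tree: {sorted(missing)}")
    edges = _edge_table(tree, unit_lengths)
    inds = list(sets)
    n = len(inds)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = unifrac_pair(edges, sets[inds[i]], sets[inds[j]])
    return pd.DataFrame(out, index=inds, columns=inds)


def pair_table(
    unifrac: pd.DataFrame, relatedness: pd.DataFrame
) -> pd.DataFrame:
    """Long table of unordered pairs with both distances defined."""
    common = [i for i in unifrac.index if i in relatedness.index]
    rows = []
    for i in range(len(common)):
        for j in range(i + 1, len(common)):
            u = unifrac.loc[common[i], common[j]]
            r = relatedness.loc[common[i], common[j]]
            if pd.notna(u) and pd.notna(r):
                rows.append((common[i], common[j], float(u), float(r)))
    return pd.DataFrame(rows, columns=["id1", "id2", "unifrac", "relatedness"])


@dataclasses.dataclass
class LmeResult:
    slope: float
    se: float
    F: float
    p: float
    df_num: int
    df_den: int


def fit_unifrac_lme(pairs: pd.DataFrame) -> LmeResult:
    """Mixed model: unifrac ~ relatedness + (1 | member identity).

    Non-independence of pairs sharing an individual is absorbed by one
    multi-membership random intercept spanning both identity columns.  The
    fixed effect is tested with an F-test (F = t^2) on n_pairs - 2
    denominator degrees of freedom.
    """
    if pairs["id1"].nunique() + pairs["id2"].nunique() < 3:
        raise ValueError("need at least three individuals")
    df = pairs.copy()
    if df["unifrac"].nunique() == 1:
        return LmeResult(0.0, 0.0, 0.0, 1.0, 1, len(df) - 2)
    df["grp"] = 1
    md = smf.mixedlm(
        "unifrac ~ relatedness",
        df,
        groups="grp",
        vc_formula={"member": "0 + C(id1) + C(id2)"},
    )
    import warnings
    with warnings.catch_warnings():
        # a member variance hitting the zero boundary is expected when the
        # random effect is weak; the fixed-effect inference is unaffected
        warnings.simplefilter("ignore")
        fit = md.fit(reml=True)
    slope = float(fit.fe_params["relatedness"])
    se = float(fit.bse_fe["relatedness"])
    F = (slope / se) ** 2 if se > 0 else 0.0
    df_den = len(df) - 2
    p = float(stats.f.sf(F, 1, df_den)) if se > 0 else 1.0
    return LmeResult(slope, se, F, p, 1, df_den)


@dataclasses.dataclass
class GlmHetResult:
    slope: float
    lr_chi2: float
    lr_p: float
    deviance: float
    deviance_df: int
    deviance_p: float
    separation: bool = False


def fit_het_glm(mhc_het: pd.Series, smlh_values: pd.Series) -> GlmHetResult:
    """Binomial GLM of MHC heterozygosity (0/1) on sMLH.

    Reports the likelihood-ratio test of the slope and the residual-deviance
    goodness-of-fit statistic (deviance on n - 2 df).  A response that is
    constant (all heterozygous or all homozygous) is flagged; no test then.
    """
    df = pd.concat([mhc_het.rename("het"), smlh_values.rename("smlh")], axis=1).dropna()
    y = df["het"].astype(float)
    if y.nunique() < 2:
        return GlmHetResult(float("nan"), float("nan"), 1.0, float("nan"), 0, 1.0, True)
    if df["smlh"].nunique() < 2:
        return GlmHetResult(float("nan"), float("nan"), 1.0, float("nan"), 0, 1.0, True)
    X = sm.add_constant(df["smlh"])
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
    lr = 2.0 * (fit.llf - null.llf)
    lr_p = float(stats.chi2.sf(lr, 1))
    dev_df = int(fit.df_resid)
    dev_p = float(stats.chi2.sf(fit.deviance, dev_df))
    return GlmHetResult(
        float(fit.params["smlh"]), float(lr), lr_p,
        float(fit.deviance), dev_df, dev_p,
    )
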