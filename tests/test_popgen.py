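import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sealmhc import (
    Genotype,
    SimulationConfig,
    diversity_summary,
    fst_permutation_test,
    mhc_to_table,
    queller_goodnight_r,
    simulate_dataset,
    smlh,
    weir_cockerham_fst,
)


def wide(rows, loci=("L01",)):
    """rows: {ind: [(a, b), ...] per locus}"""
    data = {}
    for ind, gts in rows.items():
        rec = {}
        for locus, (a, b) in zip(loci, gts):
            rec[f"{locus}_1"] = a
            rec[f"{locus}_2"] = b
        data[ind] = rec
    df = pd.DataFrame.from_dict(data, orient="index")
    df.index.name = "individual_id"
    return df


def labels_for(table, mapping):
    return pd.Series({i: mapping(i) for i in table.index}, name="pop")


def test_theta_near_zero_for_duplicated_population():
    """Duplicating a table gives zero among-population variance; the WC84
    point estimator retains only its O(1/n) small-sample term, so theta
    shrinks towards 0 as the sample grows."""
    rng = np.random.default_rng(0)
    prev = None
    for n in (12, 60, 600):
        rows = {f"i{k}": [(rng.integers(4), rng.integers(4)) for _ in range(3)]
                for k in range(n)}
        t = wide(rows, loci=("L01", "L02", "L03"))
        dup = pd.concat([t, t.set_index(t.index + "_copy")])
        lab = labels_for(dup, lambda i: "B" if i.endswith("_copy") else "A")
        theta = weir_cockerham_fst(dup, lab)
        assert theta <= 0  # no spurious among-colony signal
        assert abs(theta) < 1.2 / n
        if prev is not None:
            assert abs(theta) < abs(prev)
        prev = theta


def test_theta_one_for_fixed_populations():
    rows = {f"a{k}": [(0, 0)] for k in range(10)}
    rows.update({f"b{k}": [(1, 1)] for k in range(10)})
    t = wide(rows)
    lab = labels_for(t, lambda i: i[0])
    assert weir_cockerham_fst(t, lab) == pytest.approx(1.0)


def test_theta_matches_hand_worked_example():
    """2 populations, 1 biallelic locus, computed from the Weir–Cockerham
    variance-component formulas by hand in this test."""
    # pop A: 4 individuals: AA, AA, AB, BB ; pop B: 4 individuals: AB, BB, BB, BB
    rows = {
        "a1": [(0, 0)], "a2": [(0, 0)], "a3": [(0, 1)], "a4": [(1, 1)],
        "b1": [(0, 1)], "b2": [(1, 1)], "b3": [(1, 1)], "b4": [(1, 1)],
    }
    t = wide(rows)
    lab = labels_for(t, lambda i: i[0])

    # hand computation (both alleles contribute symmetrically)
    n1 = n2 = 4.0
    r = 2.0
    C = n1 + n2
    nbar = C / r
    nc = (C - (n1**2 + n2**2) / C) / (r - 1)
    num = den = 0.0
    for p1, p2, h1, h2 in [(5 / 8, 1 / 8, 1 / 4, 1 / 4), (3 / 8, 7 / 8, 1 / 4, 1 / 4)]:
        pbar = (n1 * p1 + n2 * p2) / C
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / C
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    assert weir_cockerham_fst(t, lab) == pytest.approx(num / den)


def test_monomorphic_gives_nan():
    rows = {f"i{k}": [(0, 0)] for k in range(8)}
    t = wide(rows)
    lab = labels_for(t, lambda i: "A" if int(i[1:]) < 4 else "B")
    assert math.isnan(weir_cockerham_fst(t, lab))


def test_permutation_p_extreme_for_perfect_differentiation():
    rows = {f"a{k}": [(0, 0)] for k in range(10)}
    rows.update({f"b{k}": [(1, 1)] for k in range(10)})
    t = wide(rows)
    lab = labels_for(t, lambda i: i[0])
    theta, p = fst_permutation_test(t, lab, n_perm=199, seed=1)
    assert theta == pytest.approx(1.0)
    assert p == pytest.approx(1 / 200)


def test_diversity_summary_degenerate_and_het_cases():
    rows = {"i1": [(0, 0)], "i2": [(0, 0)], "j1": [(0, 0)], "j2": [(0, 0)]}
    t = wide(rows)
    lab = labels_for(t, lambda i: i[0])
    d = diversity_summary(t, lab).set_index("population")
    assert (d["He"] == 0).all()
    assert d["Fis"].isna().all()

    rows = {"i1": [(0, 1)], "i2": [(0, 1)]}
    t = wide(rows)
    lab = labels_for(t, lambda i: "one")
    d = diversity_summary(t, lab)
    assert d.loc[0, "Ho"] == 1.0


def test_rarefied_richness_matches_exhaustive_enumeration():
    """Analytic rarefaction equals the brute-force mean over all gene-copy
    subsamples of size g."""
    rows = {
        "a1": [(0, 0)], "a2": [(0, 1)], "a3": [(1, 2)],
        "b1": [(0, 0)], "b2": [(0, 0)],
    }
    t = wide(rows)
    lab = labels_for(t, lambda i: i[0])
    g = 4  # smallest population has 2 individuals = 4 gene copies
    copies = [0, 0, 0, 1, 1, 2]  # pop a gene copies
    vals = [
        len(set(sub)) for sub in itertools.combinations(copies, g)
    ]
    expect_a = np.mean(vals)
    d = diversity_summary(t, lab).set_index("population")
    assert d.loc["a", "allelic_richness"] == pytest.approx(expect_a)
    assert d.loc["b", "allelic_richness"] == pytest.approx(1.0)
    assert d.loc["a", "private_alleles"] == 2  # alleles 1 and 2
    assert d.loc["b", "private_alleles"] == 0


def test_qg_anchors():
    rng = np.random.default_rng(2)
    loci = [f"L{k:02d}" for k in range(20)]
    rows = {}
    for i in range(40):  # background population
        rows[f"bg{i}"] = [(rng.integers(8), rng.integers(8)) for _ in loci]
    # identical homozygotes
    rows["t1"] = [(0, 0) for _ in loci]
    rows["t2"] = [(0, 0) for _ in loci]
    # two individuals sharing no alleles
    rows["u1"] = [(1, 2) for _ in loci]
    rows["u2"] = [(3, 4) for _ in loci]
    t = wide(rows, loci=loci)
    r = queller_goodnight_r(t)
    assert r.loc["t1", "t2"] > 0.8
    assert r.loc["u1", "u2"] < 0.0
    assert np.isnan(r.loc["t1", "t1"])
    vals = r.to_numpy()
    assert np.allclose(vals, vals.T, equal_nan=True)


def test_qg_parent_offspring_half():
    """Mother–pup pairs share one allele per locus by construction: mean
    Queller–Goodnight r should be close to 1/2 (the estimator carries a
    small ~ -2/N bias from in-sample allele frequencies)."""
    cfg = SimulationConfig(seed=17, n_mothers_per_colony=40, n_microsat_loci=20,
                           clones_per_individual=(1, 1))
    ds = simulate_dataset(cfg)
    r = queller_goodnight_r(ds.microsats)
    vals = [
        r.loc[m, p]
        for m, p in zip(ds.pedigree["mother_id"], ds.pedigree["pup_id"])
    ]
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - 0.5) <= 2 * se + 2.0 / len(ds.microsats)


def test_smlh_properties():
    rows = {
        "het": [(0, 1), (0, 1), (2, 3)],
        "hom": [(0, 0), (1, 1), (2, 2)],
        "mix": [(0, 1), (1, 1), (2, 3)],
    }
    t = wide(rows, loci=("L01", "L02", "L03"))
    s = smlh(t)
    assert s["hom"] == 0.0
    assert s.mean() == pytest.approx(1.0)  # exact with complete data


def test_smlh_population_mean_one_on_simulated_data(small_dataset):
    s = smlh(small_dataset.microsats)
    assert s.mean() == pytest.approx(1.0, abs=1e-12)


def test_mhc_to_table_excludes_flagged():
    gts = [
        Genotype("a", frozenset({"X"}), "SSB"),
        Genotype("b", frozenset({"X", "Y"}), "FWB"),
        Genotype("c", frozenset({"X", "Y", "Z"}), "FWB", status="multi_allele_flag"),
    ]
    t, lab = mhc_to_table(gts)
    assert list(t.index) == ["a", "b"]
    assert t.loc["a", "MHC_1"] == t.loc["a", "MHC_2"] == "X"


def test_null_colonies_theta_near_zero():
    """Colonies drawn from one allele-frequency law: theta should hover
    around zero and the permutation test should rarely reject."""
    rejections = 0
    thetas = []
    for seed in range(25):
        cfg = SimulationConfig(seed=seed, n_mothers_per_colony=12, n_microsat_loci=8,
                               clones_per_individual=(1, 1))
        ds = simulate_dataset(cfg)
        mums = ds.genotypes[ds.genotypes["role"] == "mother"]
        table = pd.DataFrame(
            {"MHC_1": mums["allele1"].to_numpy(), "MHC_2": mums["allele2"].to_numpy()},
            index=mums["individual_id"],
        )
        lab = pd.Series(mums["colony"].to_numpy(), index=mums["individual_id"])
        theta, p = fst_permutation_test(table, lab, n_perm=99, seed=seed)
        thetas.append(theta)
        rejections += p <= 0.05
    assert abs(np.mean(thetas)) < 0.02
    assert rejections <= 3
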