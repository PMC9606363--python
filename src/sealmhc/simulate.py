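"""Synthetic data generator for the DQB genotyping pipeline.

Generates everything the downstream analyses consume, with the statistical
structure the analyses assume:

* an allele pool of distinct 267 bp coding sequences (no internal stops, no
  frameshifts) whose substitutions favour non-synonymous changes at the
  putative antigen binding sites (pABS) by a configurable factor;
* Hardy–Weinberg genotypes for mothers in two colonies drawn from one shared
  allele-frequency law (the null of no population structure), with each pup
  inheriting one uniformly chosen maternal allele and one paternal allele
  drawn from the population frequencies;
* clone libraries with a per-clone PCR artifact process (1–2 random point
  substitutions) and, optionally, per-allele amplification weights decaying
  exponentially with the number of primer-binding-site mismatches;
* diploid microsatellite genotypes at unlinked loci, transmitted from mother
  to pup, for the relatedness and heterozygosity analyses.

Allele diversity follows a site model: a fixed number of variable nucleotide
sites is placed on the founder exon (at most one per codon, both states
stop-free) and every allele draws one of the two states independently at
each site with probability one half, mimicking ancient balanced
polymorphisms at intermediate frequency rather than a star genealogy.

Determinism: one master RNG is seeded from ``config.seed``; clone libraries
use a sub-stream per individual derived from the seed and the individual's
index, so identical configurations yield byte-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import BiasError, SimulationError
from .io import CloneRecord
from .reference import DEFAULT_PABS_CODONS, EXON_LENGTH, SYNTHETIC_FOUNDER_EXON

_BASES = "ACGT"


@dataclasses.dataclass
class SimulationConfig:
    """Tunable parameters of the generator (defaults follow the study design)."""

    seed: int
    n_alleles: int = 19
    allele_freqs: Sequence[float] | None = None  # None -> equifrequent
    n_mothers_per_colony: int = 14
    colonies: tuple[str, str] = ("SSB", "FWB")
    pabs_nonsyn_multiplier: float = 5.0
    n_variable_sites: int = 34
    clones_per_individual: tuple[int, int] = (7, 32)
    artifact_rate: float = 0.1
    bias_beta: float = 0.0
    n_microsat_loci: int = 41
    microsat_alleles_range: tuple[int, int] = (4, 10)
    founder: str = SYNTHETIC_FOUNDER_EXON
    pabs_codons: frozenset[int] = DEFAULT_PABS_CODONS

    def __post_init__(self) -> None:
        lo, hi = self.clones_per_individual
        if not (1 <= lo <= hi):
            raise SimulationError("clones_per_individual must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise SimulationError("artifact_rate must lie in [0, 1]")
        if self.bias_beta < 0:
            raise SimulationError("bias_beta must be >= 0")
        if self.pabs_nonsyn_multiplier < 1:
            raise SimulationError("pabs_nonsyn_multiplier must be >= 1")
        if self.n_alleles < 1:
            raise SimulationError("n_alleles must be >= 1")
        if len(self.founder) != EXON_LENGTH:
            raise SimulationError(f"founder must be {EXON_LENGTH} bp")
        if self.allele_freqs is not None:
            freqs = np.asarray(self.allele_freqs, dtype=float)
            if len(freqs) != self.n_alleles:
                raise SimulationError("allele_freqs length must equal n_alleles")
            if abs(freqs.sum() - 1.0) > 1e-12:
                raise SimulationError("allele_freqs must sum to 1 within 1e-12")

    @property
    def freqs(self) -> np.ndarray:
        if self.allele_freqs is None:
            return np.full(self.n_alleles, 1.0 / self.n_alleles)
        return np.asarray(self.allele_freqs, dtype=float)


@dataclasses.dataclass
class TruthSet:
    """Ground truth of one simulated dataset."""

    pool: pd.DataFrame          # allele name, sequence
    genotypes: pd.DataFrame     # individual_id, colony, role, allele1, allele2
    pedigree: pd.DataFrame      # mother_id, pup_id, colony
    clones: pd.DataFrame | None = None    # clone_id, individual_id, template_allele, is_artifact
    microsats: pd.DataFrame | None = None
    clone_records: list | None = None     # the CloneRecord objects themselves

    def allele_set(self, individual_id: str) -> frozenset[str]:
        row = self.genotypes.set_index("individual_id").loc[individual_id]
        return frozenset({row["allele1"], row["allele2"]})

    @property
    def sampled_allele_sequences(self) -> frozenset[str]:
        """Sequences of pool alleles carried by at least one individual."""
        carried = set(self.genotypes["allele1"]) | set(self.genotypes["allele2"])
        seqs = self.pool.set_index("name")["sequence"]
        return frozenset(seqs[a] for a in carried)

    def callable_allele_sequences(self, min_individuals: int = 2) -> frozenset[str]:
        """Sequences carried by at least *min_individuals* individuals."""
        g = self.genotypes
        carriers: dict[str, set[str]] = {}
        for _, row in g.iterrows():
            for a in {row["allele1"], row["allele2"]}:
                carriers.setdefault(a, set()).add(row["individual_id"])
        seqs = self.pool.set_index("name")["sequence"]
        return frozenset(
            seqs[a] for a, inds in carriers.items() if len(inds) >= min_individuals
        )


def _translate(seq: str) -> str:
    return str(Seq(seq).translate())


def generate_allele_pool(config: SimulationConfig) -> pd.DataFrame:
    """Generate ``n_alleles`` distinct 267 bp coding alleles.

    ``n_variable_sites`` biallelic sites are placed on the founder exon.
    Codons are proposed uniformly and accepted with probability 1 for pABS
    codons and ``1/pabs_nonsyn_multiplier`` otherwise; at an accepted pABS
    codon the alternative base is forced to be non-synonymous with
    probability ``1 - 1/pabs_nonsyn_multiplier``, while at non-pABS codons it
    is forced to be synonymous with the same probability (purifying
    constraint outside the binding sites).  A multiplier of 1 is therefore
    exactly uniform, stop-free placement — the neutral null.  A codon may
    carry several variable sites; every combination of site states within a
    codon is checked to be stop-free, so any allele translates.  Each allele
    then draws one of the two states independently per site with probability
    1/2, mimicking ancient balanced polymorphisms at intermediate frequency.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    founder = config.founder.upper()
    if "*" in _translate(founder):
        raise SimulationError("founder exon contains an internal stop codon")
    n_codons = EXON_LENGTH // 3
    if config.n_variable_sites > 2 * n_codons:
        raise SimulationError("n_variable_sites too large for the exon")

    # codon idx (0-based) -> {pos in codon: alt base}
    sites: dict[int, dict[int, str]] = {}

    def combos_stop_free(c: int, cand: dict[int, str]) -> bool:
        codon = founder[3 * c : 3 * c + 3]
        positions = sorted(cand)
        for mask in range(2 ** len(positions)):
            trial = list(codon)
            for b, pos in enumerate(positions):
                if mask >> b & 1:
                    trial[pos] = cand[pos]
            if _translate("".join(trial)) == "*":
                return False
        return True

    placed = 0
    tries = 0
    m = config.pabs_nonsyn_multiplier
    while placed < config.n_variable_sites:
        tries += 1
        if tries > 500_000:
            raise SimulationError("could not place the requested diversity")
        c = int(rng.integers(n_codons))
        is_pabs = (c + 1) in config.pabs_codons
        if not is_pabs and rng.random() >= 1.0 / m:
            continue
        used = sites.get(c, {})
        free = [p for p in range(3) if p not in used]
        if not free:
            continue
        pos = free[int(rng.integers(len(free)))]
        codon = founder[3 * c : 3 * c + 3]
        force = rng.random() < 1.0 - 1.0 / m
        alts = [b for b in _BASES if b != codon[pos]]
        alt = alts[int(rng.integers(3))]
        alt_codon = codon[:pos] + alt + codon[pos + 1 :]
        if _translate(alt_codon) == "*":
            continue
        nonsyn = _translate(alt_codon) != _translate(codon)
        if force and (nonsyn != is_pabs):
            continue
        cand = dict(used)
        cand[pos] = alt
        if not combos_stop_free(c, cand):
            continue
        sites[c] = cand
        placed += 1

    site_list = [
        (c, pos, alt) for c in sorted(sites) for pos, alt in sorted(sites[c].items())
    ]
    seqs: list[str] = []
    seen = set()
    guard = 0
    while len(seqs) < config.n_alleles:
        guard += 1
        if guard > 100_000:
            raise SimulationError("could not generate enough distinct alleles")
        s = list(founder)
        if seqs:  # first allele is the founder itself
            for c, pos, alt in site_list:
                if rng.random() < 0.5:
                    s[3 * c + pos] = alt
        seq = "".join(s)
        if seq in seen:
            continue
        seen.add(seq)
        seqs.append(seq)
    pool = pd.DataFrame(
        {"name": [f"SIM*{i + 1:02d}" for i in range(len(seqs))], "sequence": seqs}
    )
    return pool


def simulate_population(
    pool: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw mother genotypes under HWE and transmit one allele to each pup.

    Both colonies share the same allele-frequency law (no structure).  Each
    mother has one pup; fathers are represented only by an independent draw
    from the population frequencies.  Returns (genotypes, pedigree).
    """
    if len(pool) == 0:
        raise SimulationError("allele pool is empty")
    rng = np.random.default_rng([int(config.seed), 2])
    freqs = config.freqs
    names = list(pool["name"])
    rows = []
    ped = []
    for colony in config.colonies:
        for i in range(config.n_mothers_per_colony):
            mid = f"{colony}_M{i + 1:02d}"
            pid = f"{colony}_P{i + 1:02d}"
            m1, m2 = rng.choice(len(names), size=2, p=freqs)
            transmitted = m1 if rng.random() < 0.5 else m2
            pat = rng.choice(len(names), p=freqs)
            rows.append((mid, colony, "mother", names[m1], names[m2]))
            rows.append((pid, colony, "pup", names[transmitted], names[pat]))
            ped.append((mid, pid, colony))
    genotypes = pd.DataFrame(
        rows, columns=["individual_id", "colony", "role", "allele1", "allele2"]
    )
    pedigree = pd.DataFrame(ped, columns=["mother_id", "pup_id", "colony"])
    return genotypes, pedigree


def _mismatch_count(seq: str, primers) -> int:
    # local import to avoid a cycle at module load
    from .primerbias import primer_mismatch_count

    return primer_mismatch_count(seq, primers)


def simulate_clone_library(
    genotypes: pd.DataFrame,
    pool: pd.DataFrame,
    config: SimulationConfig,
    primers=None,
) -> tuple[list[CloneRecord], pd.DataFrame]:
    """Simulate cloned amplicon sequences per individual.

    The clone count is uniform on ``clones_per_individual``.  Each clone's
    template is one of the individual's two alleles, drawn with weight
    ``exp(-bias_beta * mismatches(allele, primers))`` (uniform when *primers*
    is None or ``bias_beta`` is 0).  With probability ``artifact_rate`` the
    clone acquires 1–2 substitutions at uniform positions with uniform
    (Jukes–Cantor-like) base choice.  Returns clone records plus a truth
    table labelling each clone.
    """
    seqs = pool.set_index("name")["sequence"]
    lo, hi = config.clones_per_individual
    weight_cache: dict[str, float] = {}

    def weight(allele: str) -> float:
        if allele not in weight_cache:
            if primers is None or config.bias_beta == 0.0:
                weight_cache[allele] = 1.0
            else:
                m = _mismatch_count(seqs[allele], primers)
                w = math.exp(-config.bias_beta * m) if m > 0 else 1.0
                weight_cache[allele] = w
        return weight_cache[allele]

    clones: list[CloneRecord] = []
    truth_rows = []
    for idx, row in enumerate(genotypes.itertuples(index=False)):
        rng = np.random.default_rng([int(config.seed), 3, idx])
        alleles = [row.allele1, row.allele2]
        w = np.array([weight(a) for a in alleles])
        if w.sum() == 0:
            raise BiasError(
                f"all amplification weights are zero for {row.individual_id}"
            )
        p = w / w.sum()
        n_clones = int(rng.integers(lo, hi + 1))
        for j in range(n_clones):
            template = alleles[int(rng.choice(2, p=p))]
            seq = seqs[template]
            is_artifact = bool(rng.random() < config.artifact_rate)
            if is_artifact:
                k = int(rng.integers(1, 3))
                positions = rng.choice(len(seq), size=k, replace=False)
                s = list(seq)
                for posn in positions:
                    alts = [b for b in _BASES if b != s[posn]]
                    s[posn] = alts[int(rng.integers(3))]
                seq = "".join(s)
            cid = f"{row.individual_id}|c{j + 1:03d}"
            clones.append(CloneRecord(cid, row.individual_id, seq))
            truth_rows.append((cid, row.individual_id, template, is_artifact))
    truth = pd.DataFrame(
        truth_rows, columns=["clone_id", "individual_id", "template_allele", "is_artifact"]
    )
    return clones, truth


def simulate_microsatellites(
    genotypes: pd.DataFrame, pedigree: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate diploid genotypes at unlinked microsatellite loci.

    Founders (mothers, and the paternal contribution) are i.i.d. multinomial
    draws from per-locus Dirichlet(1) frequencies shared by both colonies;
    each pup inherits one allele from its mother per locus.  Returned as a
    wide DataFrame indexed by individual with columns ``L01_1, L01_2, ...``
    (integer allele labels).
    """
    rng = np.random.default_rng([int(config.seed), 4])
    inds = list(genotypes["individual_id"])
    mother_of = dict(zip(pedigree["pup_id"], pedigree["mother_id"]))
    data: dict[str, np.ndarray] = {}
    lo, hi = config.microsat_alleles_range
    n = len(inds)
    ind_pos = {ind: i for i, ind in enumerate(inds)}
    for locus in range(config.n_microsat_loci):
        k = int(rng.integers(lo, hi + 1))
        freqs = rng.dirichlet(np.ones(k))
        a = np.zeros((n, 2), dtype=int)
        # mothers / unpaired individuals first
        for i, ind in enumerate(inds):
            if ind not in mother_of:
                a[i] = rng.choice(k, size=2, p=freqs)
        for i, ind in enumerate(inds):
            if ind in mother_of:
                mrow = a[ind_pos[mother_of[ind]]]
                a[i, 0] = mrow[int(rng.integers(2))]
                a[i, 1] = rng.choice(k, p=freqs)
        name = f"L{locus + 1:02d}"
        data[f"{name}_1"] = a[:, 0]
        data[f"{name}_2"] = a[:, 1]
    return pd.DataFrame(data, index=pd.Index(inds, name="individual_id"))


def simulate_dataset(config: SimulationConfig, primers=None) -> TruthSet:
    """Run the full generator: pool, population, clone library, microsatellites."""
    pool = generate_allele_pool(config)
    genotypes, pedigree = simulate_population(pool, config)
    clones, clone_truth = simulate_clone_library(genotypes, pool, config, primers)
    micro = simulate_microsatellites(genotypes, pedigree, config)
    return TruthSet(
        pool=pool,
        genotypes=genotypes,
        pedigree=pedigree,
        clones=clone_truth,
        microsats=micro,
        clone_records=clones,
    )
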