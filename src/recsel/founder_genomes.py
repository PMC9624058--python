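"""Founder genomes, meiosis, crossing, doubled haploids, and IBD tracking.

The simulated species is an outbred, diploid, hermaphroditic plant. Each
individual carries ``n_chromosomes`` chromosome pairs with
``sites_per_chromosome`` biallelic segregating sites. Alongside the 0/1
allele of every site, each haplotype carries an integer identity-by-descent
(IBD) label recording which founder haplotype copy the allele descends from;
labels are propagated through every meiosis, so coancestry and inbreeding
are computed exactly from descent rather than estimated from markers.

Founder haplotypes are built as Markov mosaics of a small panel of ancestral
haplotypes (allele frequencies Beta(0.5, 0.5), segment switching at a rate
of one per Morgan), which induces realistic linkage disequilibrium without
running a coalescent; any generator producing the same ``FounderPopulation``
container can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

N_ANCESTRAL_HAPLOTYPES = 20
_SEGREGATION_RETRIES = 20


@dataclass(frozen=True)
class GenomeSpec:
    """Genome layout shared by every individual in a simulation.

    Defaults follow the simulated species used throughout: 10 chromosomes of
    1000 segregating sites, a 1 Morgan genetic map per chromosome with
    uniform site spacing, 100 QTL and 50 chip sites per chromosome.
    """

    n_chromosomes: int = 10
    sites_per_chromosome: int = 1000
    map_length: float = 1.0
    qtl_per_chromosome: int = 100
    chip_sites_per_chromosome: int = 50

    def __post_init__(self) -> None:
        counts = (self.n_chromosomes, self.sites_per_chromosome,
                  self.qtl_per_chromosome, self.chip_sites_per_chromosome)
        if any(c <= 0 for c in counts):
            raise ValueError("all genome counts must be positive")
        if self.map_length < 0:
            raise ValueError("map length must be non-negative")
        if (self.qtl_per_chromosome + self.chip_sites_per_chromosome
                > self.sites_per_chromosome):
            raise ValueError(
                "QTL + chip sites per chromosome exceed available sites "
                "(they are sampled disjointly)")

    @property
    def n_sites(self) -> int:
        return self.n_chromosomes * self.sites_per_chromosome

    def positions(self) -> np.ndarray:
        """Genetic-map positions (Morgans) of the sites of one chromosome."""
        m = self.sites_per_chromosome
        return (np.arange(m) + 0.5) * (self.map_length / m)


@dataclass
class Individual:
    """A diploid individual: alleles plus per-site founder-origin labels.

    ``haplotypes`` and ``ibd`` both have shape
    ``(n_chromosomes, 2, sites_per_chromosome)``.
    """

    id: int
    haplotypes: np.ndarray
    ibd: np.ndarray
    birth_cycle: int = 0
    meta: str = ""
    mother_id: int | None = None
    father_id: int | None = None

    def __post_init__(self) -> None:
        if self.haplotypes.shape != self.ibd.shape:
            raise ValueError("IBD label array must match haplotype shape")

    def dosages(self) -> np.ndarray:
        """Allele dosage (0/1/2) at every site, flattened chromosome-major."""
        return self.haplotypes.sum(axis=1).reshape(-1)

    def is_doubled_haploid(self) -> bool:
        return bool(np.array_equal(self.haplotypes[:, 0], self.haplotypes[:, 1]))


@dataclass
class FounderPopulation:
    individuals: list[Individual]
    spec: GenomeSpec
    site_positions: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.site_positions is None:
            self.site_positions = self.spec.positions()

    def __len__(self) -> int:
        return len(self.individuals)


def generate_founders(spec: GenomeSpec, n_individuals: int,
                      seed: int) -> FounderPopulation:
    """Simulate an outbred diploid founder population.

    Every site segregates among the ``2 * n_individuals`` founder haplotypes
    (monomorphic sites are resampled), and every founder haplotype carries a
    unique IBD label per chromosome. Identical seeds give bit-identical
    populations.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    m = spec.sites_per_chromosome
    d = spec.map_length / m  # inter-site map distance
    switch_p = 1.0 - np.exp(-d)  # mosaic switch rate: 1 per Morgan

    chrom_alleles = []
    for _ in range(spec.n_chromosomes):
        freqs = rng.beta(0.5, 0.5, size=m)
        ancestral = (rng.random((N_ANCESTRAL_HAPLOTYPES, m)) < freqs).astype(np.uint8)
        # Markov mosaic: per-haplotype ancestral-origin index along the map.
        switches = rng.random((n_hap, m - 1)) < switch_p
        seg_id = np.zeros((n_hap, m), dtype=np.int64)
        seg_id[:, 1:] = np.cumsum(switches, axis=1)
        seg_draws = rng.integers(0, N_ANCESTRAL_HAPLOTYPES, size=(n_hap, m))
        origins = seg_draws[np.arange(n_hap)[:, None], seg_id]
        alleles = ancestral[origins, np.arange(m)[None, :]]

        # Resample non-segregating sites: redraw the ancestral column (the
        # mosaic origins stay fixed) until both alleles are present.
        counts = alleles.sum(axis=0)
        bad = np.flatnonzero((counts == 0) | (counts == n_hap))
        for s in bad:
            logger.debug("resampling non-segregating site %d", s)
            for _ in range(_SEGREGATION_RETRIES):
                col = (rng.random(N_ANCESTRAL_HAPLOTYPES)
                       < rng.beta(0.5, 0.5)).astype(np.uint8)
                cand = col[origins[:, s]]
                if 0 < cand.sum() < n_hap:
                    alleles[:, s] = cand
                    break
            else:
                # All founders trace to one ancestor here; flip one haplotype.
                alleles[:, s] = alleles[0, s]
                alleles[rng.integers(n_hap), s] ^= 1
        chrom_alleles.append(alleles)

    individuals = []
    for i in range(n_individuals):
        haps = np.empty((spec.n_chromosomes, 2, m), dtype=np.uint8)
        ibd = np.empty((spec.n_chromosomes, 2, m), dtype=np.int32)
        for c in range(spec.n_chromosomes):
            for h in range(2):
                haps[c, h] = chrom_alleles[c][2 * i + h]
                ibd[c, h] = (2 * i + h) * spec.n_chromosomes + c
        individuals.append(Individual(id=i, haplotypes=haps, ibd=ibd,
                                      birth_cycle=0, meta="founder"))
    return FounderPopulation(individuals=individuals, spec=spec)


def meiosis(parent: Individual, spec: GenomeSpec,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis: a recombinant gamete (alleles, IBD labels).

    Per chromosome the crossover count is Poisson(map length) with
    breakpoints uniform on the map and no interference; a map length of 0
    transmits one intact parental haplotype per chromosome.
    """
    n_chr, _, m = parent.haplotypes.shape
    positions = spec.positions()
    gamete = np.empty((n_chr, m), dtype=np.uint8)
    labels = np.empty((n_chr, m), dtype=np.int32)
    for c in range(n_chr):
        k = rng.poisson(spec.map_length)
        start = rng.integers(2)
        if k == 0:
            src = np.full(m, start)
        else:
            breaks = np.sort(rng.uniform(0.0, spec.map_length, size=k))
            src = (start + np.searchsorted(breaks, positions)) % 2
        sites = np.arange(m)
        gamete[c] = parent.haplotypes[c][src, sites]
        labels[c] = parent.ibd[c][src, sites]
    return gamete, labels


def make_cross(mother: Individual, father: Individual, n_progeny: int,
               birth_cycle: int, rng: np.random.Generator, spec: GenomeSpec,
               first_id: int = 0, allow_selfing: bool = False) -> list[Individual]:
    """Cross two parents; each progeny gets one meiosis from each parent."""
    if mother.id == father.id and not allow_selfing:
        raise ValueError("selfing is disabled: mother and father are the same")
    progeny = []
    for j in range(n_progeny):
        mg, ml = meiosis(mother, spec, rng)
        fg, fl = meiosis(father, spec, rng)
        haps = np.stack([mg, fg], axis=1)
        ibd = np.stack([ml, fl], axis=1)
        progeny.append(Individual(id=first_id + j, haplotypes=haps, ibd=ibd,
                                  birth_cycle=birth_cycle,
                                  mother_id=mother.id, father_id=father.id))
    return progeny


def make_dh(source: Individual, birth_cycle: int, rng: np.random.Generator,
            spec: GenomeSpec, new_id: int) -> Individual:
    """Doubled haploid: one gamete duplicated onto both haplotypes."""
    gamete, labels = meiosis(source, spec, rng)
    haps = np.stack([gamete, gamete], axis=1)
    ibd = np.stack([labels, labels], axis=1)
    return Individual(id=new_id, haplotypes=haps, ibd=ibd,
                      birth_cycle=birth_cycle, meta="DH",
                      mother_id=source.id, father_id=source.id)


def _label_matrix(individuals: list[Individual]) -> tuple[np.ndarray, np.ndarray]:
    """Stack IBD labels to two (n, total_sites) arrays, one per haplotype."""
    l0 = np.stack([ind.ibd[:, 0, :].reshape(-1) for ind in individuals])
    l1 = np.stack([ind.ibd[:, 1, :].reshape(-1) for ind in individuals])
    return l0, l1


def coancestry(a: Individual, b: Individual) -> float:
    """Kinship of two individuals from IBD labels.

    The probability that one allele drawn at random from each individual, at
    a site drawn at random, descends from the same founder haplotype. For
    ``a is b`` this is the self-kinship (1 + F)/2.
    """
    la = a.ibd.reshape(a.ibd.shape[0], 2, -1)
    lb = b.ibd.reshape(b.ibd.shape[0], 2, -1)
    match = sum(
        np.mean(la[:, i, :] == lb[:, j, :]) for i in range(2) for j in range(2))
    return float(match) / 4.0


def ibd_inbreeding(individuals: list[Individual]) -> float:
    """Mean pairwise IBD coancestry over all unordered pairs of individuals.

    This is the population's genomic inbreeding measure: the average
    probability that alleles drawn from two distinct individuals are
    identical by descent, using every segregating site.
    """
    n = len(individuals)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    l0, l1 = _label_matrix(individuals)
    total = 0.0
    for i in range(n - 1):
        m = ((l0[i] == l0[i + 1:]).mean(axis=1)
             + (l0[i] == l1[i + 1:]).mean(axis=1)
             + (l1[i] == l0[i + 1:]).mean(axis=1)
             + (l1[i] == l1[i + 1:]).mean(axis=1))
        total += float(m.sum()) / 4.0
    return total / (n * (n - 1) / 2)


def kinship_matrix(individuals: list[Individual]) -> np.ndarray:
    """Full pairwise coancestry matrix (diagonal = self-kinship (1+F)/2)."""
    n = len(individuals)
    l0, l1 = _label_matrix(individuals)
    K = np.empty((n, n))
    for i in range(n):
        m = ((l0[i] == l0[i:]).mean(axis=1)
             + (l0[i] == l1[i:]).mean(axis=1)
             + (l1[i] == l0[i:]).mean(axis=1)
             + (l1[i] == l1[i:]).mean(axis=1)) / 4.0
        K[i, i:] = m
        K[i:, i] = m
    return K


def founder_label_set(population: FounderPopulation) -> set[int]:
    return set(
        int(x) for ind in population.individuals for x in np.unique(ind.ibd))


def export_ped_map(individuals: list[Individual], spec: GenomeSpec,
                   ped_path, map_path) -> None:
    """Write a cohort as PLINK .ped/.map text files (alleles coded 1/2)."""
    positions = spec.positions()
    with open(map_path, "w") as fh:
        for c in range(spec.n_chromosomes):
            for s in range(spec.sites_per_chromosome):
                bp = int(round(positions[s] * 1_000_000)) + 1
                fh.write(f"{c + 1}\tsnp_{c + 1}_{s + 1}\t{positions[s]:.6f}\t{bp}\n")
    with open(ped_path, "w") as fh:
        for ind in individuals:
            fields = ["FAM", str(ind.id), "0", "0", "0", "-9"]
            for c in range(spec.n_chromosomes):
                for s in range(spec.sites_per_chromosome):
                    a1 = ind.haplotypes[c, 0, s] + 1
                    a2 = ind.haplotypes[c, 1, s] + 1
                    fields.append(f"{a1} {a2}")
            fh.write(" ".join(fields) + "\n")


def pedigree_kinship(pedigree: dict[int, tuple[int | None, int | None]]) -> dict:
    """Exact kinship from a pedigree (tabular method); independent oracle.

    ``pedigree`` maps id -> (mother_id, father_id); founders have (None, None).
    Returns a dict keyed by frozenset pairs / single ids for self-kinship.
    Ids must be topologically ordered (parents before offspring).
    """
    ids = list(pedigree)
    idx = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    K = np.zeros((n, n))
    for i, v in enumerate(ids):
        mo, fa = pedigree[v]
        if mo is None:
            K[i, i] = 0.5
        else:
            K[i, i] = 0.5 + 0.5 * K[idx[mo], idx[fa]]
        for j in range(i):
            w = ids[j]
            if mo is None:
                K[i, j] = K[j, i] = 0.0
            else:
                K[i, j] = K[j, i] = 0.5 * (K[j, idx[mo]] + K[j, idx[fa]])
    out = {}
    for i, v in enumerate(ids):
        out[(v, v)] = K[i, i]
        for j in range(i):
            out[frozenset((v, ids[j]))] = K[i, j]
    return out
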