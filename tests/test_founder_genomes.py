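"""Founder generation, meiosis, crossing, doubled haploids and IBD tracking."""

import numpy as np
import pytest

from recsel.founder_genomes import (GenomeSpec, Individual, coancestry,
                                    founder_label_set, generate_founders,
                                    ibd_inbreeding, kinship_matrix, make_cross,
                                    make_dh, meiosis, pedigree_kinship)


def _uniform_parent(spec, hap_values=(0, 1), labels=(0, 1)):
    """A parent whose two haplotypes are constant-valued (crossovers visible)."""
    m = spec.sites_per_chromosome
    haps = np.stack([np.full((spec.n_chromosomes, m), v, dtype=np.uint8)
                     for v in hap_values], axis=1)
    ibd = np.stack([np.full((spec.n_chromosomes, m), v, dtype=np.int32)
                    for v in labels], axis=1)
    return Individual(id=0, haplotypes=haps, ibd=ibd)


class TestGenerateFounders:
    def test_study_population_layout(self, full_founders, full_spec):
        assert len(full_founders) == 100
        ind = full_founders.individuals[0]
        assert ind.haplotypes.shape == (10, 2, 1000)
        # every site segregates among the 200 founder haplotypes
        alleles = np.stack([i.haplotypes for i in full_founders.individuals])
        counts = alleles.sum(axis=(0, 2))  # (n_chr, m)
        assert counts.min() >= 1 and counts.max() <= 199
        # unique IBD label per founder haplotype per chromosome
        labels = founder_label_set(full_founders)
        assert labels == set(range(2 * 100 * 10))

    def test_determinism(self, small_spec):
        a = generate_founders(small_spec, 10, seed=3)
        b = generate_founders(small_spec, 10, seed=3)
        for x, y in zip(a.individuals, b.individuals):
            assert np.array_equal(x.haplotypes, y.haplotypes)
            assert np.array_equal(x.ibd, y.ibd)

    def test_tiny_population_segregates(self):
        spec = GenomeSpec(n_chromosomes=1, sites_per_chromosome=4,
                          qtl_per_chromosome=1, chip_sites_per_chromosome=1)
        pop = generate_founders(spec, 2, seed=0)
        alleles = np.stack([i.haplotypes for i in pop.individuals])
        counts = alleles.sum(axis=(0, 2)).ravel()
        assert np.all(counts >= 1) and np.all(counts <= 3)

    def test_rejects_invalid_inputs(self, small_spec):
        with pytest.raises(ValueError):
            generate_founders(small_spec, 1, seed=0)
        with pytest.raises(ValueError):
            GenomeSpec(n_chromosomes=0)
        with pytest.raises(ValueError):
            GenomeSpec(sites_per_chromosome=100, qtl_per_chromosome=80,
                       chip_sites_per_chromosome=30)


class TestMeiosis:
    def test_zero_map_transmits_intact_haplotype(self, rng):
        spec = GenomeSpec(n_chromosomes=2, sites_per_chromosome=20,
                          map_length=0.0, qtl_per_chromosome=2,
                          chip_sites_per_chromosome=2)
        parent = generate_founders(spec, 2, seed=1).individuals[0]
        gamete, labels = meiosis(parent, spec, rng)
        for c in range(2):
            matches = [np.array_equal(gamete[c], parent.haplotypes[c, h])
                       and np.array_equal(labels[c], parent.ibd[c, h])
                       for h in range(2)]
            assert any(matches)

    def test_homozygous_parent_gamete(self, rng):
        spec = GenomeSpec(n_chromosomes=1, sites_per_chromosome=30,
                          qtl_per_chromosome=2, chip_sites_per_chromosome=2)
        parent = _uniform_parent(spec, hap_values=(1, 1))
        gamete, _ = meiosis(parent, spec, rng)
        assert np.all(gamete == 1)

    def test_gamete_allele_always_parental(self, small_spec, small_founders,
                                           rng):
        parent = small_founders.individuals[3]
        gamete, labels = meiosis(parent, small_spec, rng)
        for c in range(small_spec.n_chromosomes):
            ok = ((gamete[c] == parent.haplotypes[c, 0])
                  | (gamete[c] == parent.haplotypes[c, 1]))
            assert ok.all()
            lab_ok = ((labels[c] == parent.ibd[c, 0])
                      | (labels[c] == parent.ibd[c, 1]))
            assert lab_ok.all()

    def test_poisson_crossover_rate(self):
        # Label switches along the gamete count crossovers; their mean over
        # many meioses must match the 1.0 Morgan map length.
        spec = GenomeSpec(n_chromosomes=1, sites_per_chromosome=500,
                          map_length=1.0, qtl_per_chromosome=1,
                          chip_sites_per_chromosome=1)
        parent = _uniform_parent(spec)
        rng = np.random.default_rng(42)
        n = 10_000
        switches = np.empty(n)
        for i in range(n):
            _, labels = meiosis(parent, spec, rng)
            switches[i] = np.count_nonzero(np.diff(labels[0]))
        se = switches.std(ddof=1) / np.sqrt(n)
        assert abs(switches.mean() - 1.0) < 3 * se + 0.01


class TestCrossingAndDh:
    def test_progeny_labels_inherited(self, small_spec, small_founders, rng):
        mo, fa = small_founders.individuals[:2]
        child = make_cross(mo, fa, 1, 1, rng, small_spec, first_id=100)[0]
        parental = set(np.unique(mo.ibd)) | set(np.unique(fa.ibd))
        assert set(np.unique(child.ibd)) <= parental
        assert child.birth_cycle == 1 and child.id == 100
        assert (child.mother_id, child.father_id) == (mo.id, fa.id)

    def test_progeny_count(self, small_spec, small_founders, rng):
        mo, fa = small_founders.individuals[:2]
        assert len(make_cross(mo, fa, 97, 0, rng, small_spec)) == 97

    def test_selfing_rejected(self, small_spec, small_founders, rng):
        mo = small_founders.individuals[0]
        with pytest.raises(ValueError, match="selfing"):
            make_cross(mo, mo, 1, 0, rng, small_spec)

    def test_clone_parents_give_inbred_progeny(self, small_spec,
                                               small_founders, rng):
        # Crossing two clones: progeny inbreeding F equals the clones'
        # self-coancestry 1/2 in expectation (pedigree F = parental kinship).
        src = small_founders.individuals[0]
        twin = Individual(id=999, haplotypes=src.haplotypes.copy(),
                          ibd=src.ibd.copy())
        progeny = make_cross(src, twin, 400, 1, rng, small_spec)
        f = np.mean([np.mean(p.ibd[:, 0] == p.ibd[:, 1]) for p in progeny])
        assert f > 0
        assert abs(f - 0.5) < 0.05

    def test_dh_homozygous_everywhere(self, small_spec, small_founders, rng):
        dh = make_dh(small_founders.individuals[5], 2, rng, small_spec, 500)
        assert dh.is_doubled_haploid()
        assert np.array_equal(dh.haplotypes[:, 0], dh.haplotypes[:, 1])
        # each site's allele is one of the source's two
        src = small_founders.individuals[5]
        ok = ((dh.haplotypes[:, 0] == src.haplotypes[:, 0])
              | (dh.haplotypes[:, 0] == src.haplotypes[:, 1]))
        assert ok.all()

    def test_dh_of_inbred_source_is_source(self, small_spec, rng):
        inbred = _uniform_parent(small_spec, hap_values=(1, 1), labels=(3, 3))
        dh = make_dh(inbred, 0, rng, small_spec, 1)
        assert np.array_equal(dh.haplotypes, inbred.haplotypes)


class TestIbdInbreeding:
    def test_founders_unrelated(self, small_founders):
        assert ibd_inbreeding(small_founders.individuals) == 0.0

    def test_copies_of_one_gamete_fully_ibd(self, small_spec, small_founders,
                                            rng):
        dh = make_dh(small_founders.individuals[0], 0, rng, small_spec, 1)
        clones = [Individual(id=k, haplotypes=dh.haplotypes.copy(),
                             ibd=dh.ibd.copy()) for k in range(4)]
        assert ibd_inbreeding(clones) == 1.0

    def test_requires_two_individuals(self, small_founders):
        with pytest.raises(ValueError):
            ibd_inbreeding(small_founders.individuals[:1])

    def test_full_sibs_quarter_coancestry(self, small_spec, small_founders,
                                          rng):
        # Pedigree oracle: full sibs of unrelated non-inbred parents have
        # kinship 1/4; the IBD-tracked value must agree within MC error.
        ped = {0: (None, None), 1: (None, None), 2: (0, 1), 3: (0, 1)}
        assert pedigree_kinship(ped)[frozenset((2, 3))] == pytest.approx(0.25)
        mo, fa = small_founders.individuals[:2]
        sibs = make_cross(mo, fa, 300, 1, rng, small_spec)
        vals = [coancestry(sibs[2 * k], sibs[2 * k + 1]) for k in range(150)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.25) < 3 * se + 0.005

    def test_invariant_to_orderings(self, small_spec, small_founders, rng):
        mo, fa = small_founders.individuals[:2]
        group = make_cross(mo, fa, 6, 1, rng, small_spec)
        base = ibd_inbreeding(group)
        assert ibd_inbreeding(group[::-1]) == pytest.approx(base, abs=1e-15)
        flipped = [Individual(id=g.id, haplotypes=g.haplotypes[::-1].copy(),
                              ibd=g.ibd[::-1].copy()) for g in group]
        assert ibd_inbreeding(flipped) == pytest.approx(base, abs=1e-15)

    def test_kinship_matrix_diagonal_and_symmetry(self, small_founders):
        K = kinship_matrix(small_founders.individuals[:8])
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 0.5)  # non-inbred self-kinship

    def test_random_mating_inbreeding_trend(self, small_spec):
        # In a closed population of size N, drift accumulates IBD: the
        # coancestry trend over 20 generations must be increasing.
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pop = generate_founders(small_spec, 10, seed=seed).individuals
            series = []
            nid = 100
            for gen in range(1, 21):
                new = []
                for _ in range(10):
                    i, j = rng.choice(10, size=2, replace=False)
                    new.extend(make_cross(pop[i], pop[j], 1, gen, rng,
                                          small_spec, first_id=nid))
                    nid += 1
                pop = new
                series.append(ibd_inbreeding(pop))
            slope = np.polyfit(np.arange(20), series, 1)[0]
            assert slope > 0
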