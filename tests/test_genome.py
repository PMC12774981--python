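"""Genome engine: founders, meiosis, crossing, selfing, dosages, VCF I/O."""

import numpy as np
import pytest

from elitepool import (
    DemographyModel,
    GenomeSpec,
    advance_selfing,
    cross,
    cross_pairs,
    dosage_matrix,
    export_vcf,
    heterozygosity,
    import_vcf,
    make_family,
    meiosis,
    self_panel,
    simulate_founders,
)
from elitepool.genome import gametes_batch

from conftest import build_panel


class TestSimulateFounders:
    def test_panel_shape_and_polymorphism(self, tiny_spec, constant_demography):
        panel = simulate_founders(tiny_spec, constant_demography, 20, seed=3)
        assert panel.haplotypes.shape == (20, 2, 100)
        freqs = dosage_matrix(panel).sum(axis=0)
        assert ((freqs > 0) & (freqs < 40)).all(), "every retained site segregates"
        # positions strictly increasing within each chromosome
        for c in (1, 2):
            pos = panel.sites.query("chrom == @c")["pos"].to_numpy()
            assert (np.diff(pos) > 0).all()

    def test_minimal_single_site(self, constant_demography):
        spec = GenomeSpec(n_chromosomes=1, sites_per_chromosome=1, physical_length=1e6)
        panel = simulate_founders(spec, constant_demography, 2, seed=5)
        assert panel.haplotypes.shape == (2, 2, 1)
        assert 0 < panel.haplotypes.sum() < 4

    def test_deterministic_given_seed(self, tiny_spec, constant_demography):
        a = simulate_founders(tiny_spec, constant_demography, 10, seed=11)
        b = simulate_founders(tiny_spec, constant_demography, 10, seed=11)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert (a.sites["pos"] == b.sites["pos"]).all()

    def test_too_few_segregating_sites_names_chromosome(self, constant_demography):
        spec = GenomeSpec(
            n_chromosomes=1, sites_per_chromosome=5000, physical_length=1e4,
            mutation_rate=1e-9,
        )
        with pytest.raises(ValueError, match="chromosome 1"):
            simulate_founders(spec, constant_demography, 5, seed=1)

    def test_pairwise_coalescence_time_matches_discrete_oracle(self, constant_demography):
        """Mean TMRCA of two lineages under constant Ne matches a brute-force
        per-generation coalescent simulation."""
        rng = np.random.default_rng(0)
        ne = constant_demography.epochs[0][1]
        oracle = rng.geometric(1.0 / (2 * ne), size=20000)  # discrete-time pair coalescence
        import msprime

        times = []
        for s in range(300):
            ts = msprime.sim_ancestry(
                samples=1, ploidy=2, demography=constant_demography.to_msprime(),
                random_seed=s + 1,
            )
            times.append(ts.first().tmrca(0, 1))
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(np.mean(times) - np.mean(oracle)) < 3 * se + 3 * np.std(oracle) / np.sqrt(len(oracle))


class TestMeiosis:
    def test_homozygous_parent_transmits_shared_haplotype(self, homozygous_pair_panel):
        panel = homozygous_pair_panel
        rng = np.random.default_rng(1)
        gam = meiosis(panel.haplotypes[1], panel, rng)
        assert np.array_equal(gam.alleles, panel.haplotypes[1, 0])

    def test_crossover_count_is_poisson_with_map_length_mean(self, random_panel):
        rng = np.random.default_rng(2)
        counts = [len(meiosis(random_panel.haplotypes[0], random_panel, rng).crossovers[0])
                  for _ in range(10000)]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / 100
        assert abs(mean - random_panel.spec.genetic_length) < 3 * se

    def test_recombination_fraction_matches_haldane(self):
        """Realized recombination between loci 0.5 M apart ~ (1-e^-1)/2."""
        haps = np.zeros((1, 2, 2), dtype=np.int8)
        haps[0, 0] = [0, 0]
        haps[0, 1] = [1, 1]
        spec = GenomeSpec(n_chromosomes=1, sites_per_chromosome=2, physical_length=1e6)
        panel = build_panel(haps, spec)
        # place the two sites 0.5 Morgans apart
        panel.sites.loc[0, "gpos"] = 0.25
        panel.sites.loc[1, "gpos"] = 0.75
        rng = np.random.default_rng(3)
        n = 10000
        gams = gametes_batch(np.repeat(haps, n, axis=0), panel.site_index(), rng)
        recomb = (gams[:, 0] != gams[:, 1]).mean()
        expected = 0.5 * (1 - np.exp(-2 * 0.5))  # Haldane map function at d=0.5
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(recomb - expected) < 3 * se

    def test_gamete_segments_match_parental_haplotypes(self, random_panel):
        rng = np.random.default_rng(4)
        parent = random_panel.haplotypes[3]
        gam = meiosis(parent, random_panel, rng)
        matches = (gam.alleles == parent[0]) | (gam.alleles == parent[1])
        assert matches.all()


class TestCrossAndSelfing:
    def test_f1_of_homozygous_parents_heterozygous_at_differing_sites(self, homozygous_pair_panel):
        panel = homozygous_pair_panel
        rng = np.random.default_rng(5)
        f1 = cross(panel, 0, 1, rng)
        differing = (panel.haplotypes[0, 0] != panel.haplotypes[1, 0])
        het = f1.haplotypes[0, 0] != f1.haplotypes[0, 1]
        assert np.array_equal(het, differing)

    def test_self_cross_of_homozygote_is_identity(self, homozygous_pair_panel):
        panel = homozygous_pair_panel
        rng = np.random.default_rng(6)
        child = cross(panel, 1, 1, rng)
        assert np.array_equal(np.sort(child.haplotypes[0], axis=0),
                              np.sort(panel.haplotypes[1], axis=0))

    def test_offspring_dosage_expectation_is_midparent(self, random_panel):
        """Mendelian sampling: mean offspring dosage equals the parental mean."""
        rng = np.random.default_rng(7)
        pairs = np.repeat([[2, 7]], 4000, axis=0)
        offspring = cross_pairs(random_panel, pairs, rng)
        mean_dos = dosage_matrix(offspring).mean(axis=0)
        midparent = dosage_matrix(random_panel)[[2, 7]].mean(axis=0)
        # binomial SE per site is at most 0.5/sqrt(n) per haplotype draw
        assert np.abs(mean_dos - midparent).max() < 3 * 1.0 / np.sqrt(4000) + 0.02

    def test_selfing_zero_generations_is_identity(self, random_panel):
        rng = np.random.default_rng(8)
        out = advance_selfing(random_panel, 0, rng)
        assert out is random_panel

    @pytest.mark.parametrize("g", [1, 2, 4, 6])
    def test_heterozygosity_halves_each_selfing_generation(self, g):
        """Fully heterozygous start: expected residual heterozygosity (1/2)^g."""
        n = 400
        haps = np.zeros((n, 2, 40), dtype=np.int8)
        haps[:, 1, :] = 1
        panel = build_panel(haps)
        rng = np.random.default_rng(g)
        out = self_panel(panel, g, rng)
        het = heterozygosity(out).mean()
        expected = 0.5**g
        se = np.sqrt(expected * (1 - expected) / (n * 40 / 10))  # sites are linked: deflate n
        assert abs(het - expected) < 4 * se

    def test_residual_heterozygosity_matches_markov_oracle(self):
        """Per-site heterozygosity after g selfing generations follows the
        2-state Markov chain het->het w.p. 1/2 (10-site genome)."""
        g = 3
        oracle = 1.0
        for _ in range(g):
            oracle *= 0.5
        n = 2000
        haps = np.zeros((n, 2, 10), dtype=np.int8)
        haps[:, 1, :] = 1
        panel = build_panel(haps)
        out = self_panel(panel, g, np.random.default_rng(9))
        per_site = (out.haplotypes[:, 0, :] != out.haplotypes[:, 1, :]).mean(axis=0)
        se = np.sqrt(oracle * (1 - oracle) / n)
        assert np.abs(per_site - oracle).max() < 4 * se


class TestFamilies:
    def test_f2_family_shares_single_f1_parent(self, homozygous_pair_panel):
        fam = make_family(homozygous_pair_panel, 0, 1, "F2", 30, np.random.default_rng(10))
        assert fam.n_individuals == 30
        assert fam.pedigree["parent_a"].nunique() == 1

    def test_identical_homozygous_parents_give_identical_progeny(self):
        haps = np.zeros((2, 2, 20), dtype=np.int8)
        haps[:, :, ::2] = 1
        panel = build_panel(haps)
        fam = make_family(panel, 0, 1, "F2", 25, np.random.default_rng(11))
        assert (fam.haplotypes == haps[0, 0][None, None, :]).all()

    def test_f2_genotype_frequencies_one_quarter_half_quarter(self):
        haps = np.zeros((2, 2, 1), dtype=np.int8)
        haps[1] = 1
        panel = build_panel(haps)
        fam = make_family(panel, 0, 1, "F2", 10000, np.random.default_rng(12))
        dos = dosage_matrix(fam)[:, 0]
        freqs = np.bincount(dos, minlength=3) / len(dos)
        assert np.abs(freqs - [0.25, 0.5, 0.25]).max() < 3 * np.sqrt(0.25 / 10000) + 0.01

    def test_unknown_generation_label_raises(self, random_panel):
        with pytest.raises(ValueError, match="generation label"):
            make_family(random_panel, 0, 1, "BC1", 5, np.random.default_rng(0))


class TestDosageAndVcf:
    def test_dosage_codes(self, homozygous_pair_panel):
        d = dosage_matrix(homozygous_pair_panel)
        assert set(np.unique(d)) <= {0, 1, 2}
        assert (d[1, ::3] == 2).all()

    def test_row_sums_equal_haplotype_counts(self, random_panel):
        d = dosage_matrix(random_panel)
        direct = random_panel.haplotypes.sum(axis=(1, 2))
        assert np.array_equal(d.sum(axis=1), direct)

    def test_unknown_site_subset_raises(self, random_panel):
        with pytest.raises(ValueError, match="unknown site"):
            dosage_matrix(random_panel, site_subset=[10_000])

    def test_vcf_round_trip_preserves_dosage_and_phase(self, random_panel, tmp_path):
        path = tmp_path / "panel.vcf"
        export_vcf(random_panel, path)
        text = path.read_text()
        assert text.count("\n") >= random_panel.n_sites
        back = import_vcf(path)
        assert back.ids == random_panel.ids
        assert np.array_equal(dosage_matrix(back), dosage_matrix(random_panel))
        # phase: haplotype-by-haplotype identity, not just dosage
        assert np.array_equal(back.haplotypes, random_panel.haplotypes)

    def test_vcf_shape_small(self, homozygous_pair_panel, tmp_path):
        path = tmp_path / "two.vcf"
        export_vcf(homozygous_pair_panel, path)
        data_lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(data_lines) == homozygous_pair_panel.n_sites
        assert all(len(l.split("\t")) == 11 for l in data_lines)  # 9 fixed + 2 samples


class TestNeutralInvariants:
    def test_allele_frequency_drift_is_unbiased(self):
        """Random mating without selection: mean per-site frequency change 0,
        variance ~ p(1-p)/2N."""
        rng = np.random.default_rng(13)
        n = 60
        haps = rng.integers(0, 2, size=(n, 2, 30)).astype(np.int8)
        panel = build_panel(haps)
        p0 = dosage_matrix(panel).mean(axis=0) / 2
        deltas = []
        for rep in range(400):
            r = np.random.default_rng(rep)
            a = r.integers(0, n, size=n)
            b = r.integers(0, n, size=n)
            child = cross_pairs(panel, np.column_stack([a, b]), r)
            deltas.append(dosage_matrix(child).mean(axis=0) / 2 - p0)
        deltas = np.asarray(deltas)
        assert np.abs(deltas.mean(axis=0)).max() < 0.03
        expected_var = (p0 * (1 - p0) / (2 * n)).mean()
        assert abs(deltas.var() - expected_var) < 0.5 * expected_var

    def test_pipeline_determinism(self, tiny_spec, constant_demography):
        def run(seed):
            panel = simulate_founders(tiny_spec, constant_demography, 12, seed=seed)
            rng = np.random.default_rng(seed)
            fam = make_family(panel, 0, 1, "F5", 10, rng)
            return fam.haplotypes
        assert np.array_equal(run(21), run(21))
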