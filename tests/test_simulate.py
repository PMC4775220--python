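import numpy as np
import pandas as pd
import pytest

import ripcall as rc
from ripcall.simulate import DEFAULT_REGION_MIX, CapacityError


class TestMakeGenomeModel:
    def test_single_gene_has_all_region_classes(self):
        model = rc.make_genome_model(1, 10_000, seed=1)
        assert len(model.genes) == 1
        runs = model.genes[0].transcripts[0].region_runs()
        assert {cls for _, _, cls in runs} == set(rc.genome.CODING_CLASSES)

    def test_seed_determinism(self):
        a = rc.make_genome_model(5, 100_000, seed=7)
        b = rc.make_genome_model(5, 100_000, seed=7)
        assert [g.transcripts[0].exons for g in a.genes] == [
            g.transcripts[0].exons for g in b.genes
        ]
        assert [g.strand for g in a.genes] == [g.strand for g in b.genes]

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            rc.make_genome_model(50, 10_000, seed=0)

    def test_genes_pairwise_disjoint(self, toy_model):
        spans = sorted(g.span for g in toy_model.genes)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            assert s2 >= e1


class TestPlantSites:
    def test_degenerate_mix_all_intronic(self, toy_model):
        sites = rc.plant_sites(toy_model, 3, region_mix={"intron": 1.0}, seed=1)
        assert len(sites) == 3
        assert all(s.host_region_class == "intron" for s in sites)

    def test_zero_sites(self, toy_model):
        assert rc.plant_sites(toy_model, 0, seed=1) == []

    def test_sites_lie_within_their_region_class(self, toy_model):
        sites = rc.plant_sites(toy_model, 8, width=400, seed=3)
        for site in sites:
            hosted = False
            for gene in toy_model.genes:
                for s, e, cls in gene.transcripts[0].region_runs():
                    if s <= site.start and site.end <= e:
                        assert cls == site.host_region_class
                        hosted = True
            assert hosted

    def test_separation(self, toy_model):
        width = 300
        sites = rc.plant_sites(toy_model, 6, width=width, seed=5)
        ivs = sorted((s.start, s.end) for s in sites)
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            assert s2 - e1 >= 4 * width

    def test_class_frequencies_match_mix(self):
        """Drawn class frequencies are binomial around the mix probabilities."""
        model = rc.make_genome_model(500, 4_600_000, seed=11)
        n = 1000
        sites = rc.plant_sites(model, n, width=100, seed=13)
        freqs = pd.Series([s.host_region_class for s in sites]).value_counts() / n
        for cls, p in DEFAULT_REGION_MIX.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freqs.get(cls, 0.0) - p) <= 3 * se + 1e-12

    def test_impossible_mix_raises(self, toy_model):
        # a site wider than any 5'UTR cannot be hosted
        with pytest.raises(CapacityError):
            rc.plant_sites(toy_model, 1, region_mix={"5'UTR": 1.0}, width=5000)


class TestSimulateFragments:
    def test_seed_determinism(self, toy_model):
        sites = rc.plant_sites(toy_model, 2, seed=1)
        a = rc.simulate_fragments(toy_model, sites, seed=9)
        b = rc.simulate_fragments(toy_model, sites, seed=9)
        for fa, fb in zip(a, b):
            assert fa.sample_id == fb.sample_id
            pd.testing.assert_frame_equal(fa.fragments, fb.fragments)

    def test_null_conditions_indistinguishable(self, toy_model):
        """Without planted sites, RIP and IgG window counts match in law."""
        from scipy.stats import mannwhitneyu

        fragsets = rc.simulate_fragments(toy_model, [], seed=4)
        rip = next(f for f in fragsets if f.condition == "RIP")
        ctl = next(f for f in fragsets if f.condition == "control")
        edges = np.linspace(0, 100_000, 201)
        c_rip = np.histogram(rip.midpoints("chr1"), bins=edges)[0]
        c_ctl = np.histogram(ctl.midpoints("chr1"), bins=edges)[0]
        assert mannwhitneyu(c_rip, c_ctl).pvalue > 0.01

    def test_planted_enrichment_ratio(self):
        """Mean RIP midpoint count in a planted site is ~8x the control mean."""
        model = rc.make_genome_model(3, 40_000, seed=2)
        sites = rc.plant_sites(model, 1, region_mix={"intron": 1.0}, width=600,
                               enrichment=8.0, seed=2)
        site = sites[0]
        rip_counts, ctl_counts = [], []
        for seed in range(100):
            for fs in rc.simulate_fragments(model, sites, seed=seed):
                mids = fs.midpoints(site.chrom)
                n = int(((mids >= site.start) & (mids < site.end)).sum())
                (rip_counts if fs.condition == "RIP" else ctl_counts).append(n)
        mean_rip, mean_ctl = np.mean(rip_counts), np.mean(ctl_counts)
        # ratio of means: delta-method s.e. over 200 replicates per arm
        ratio = mean_rip / mean_ctl
        se = ratio * np.sqrt(
            np.var(rip_counts) / (len(rip_counts) * mean_rip**2)
            + np.var(ctl_counts) / (len(ctl_counts) * mean_ctl**2)
        )
        assert abs(ratio - 8.0) <= 3 * se

    def test_zero_dispersion_is_poisson(self):
        """alpha=0 gives window counts with index of dispersion ~1."""
        model = rc.make_genome_model(10, 200_000, seed=3)
        fragsets = rc.simulate_fragments(model, [], nb_dispersion=0.0, seed=5)
        mids = fragsets[0].midpoints("chr1")
        counts = []
        for gene in model.genes:  # windows wholly inside gene spans
            lo, hi = gene.span
            edges = np.arange(lo, hi, 200)
            counts.extend(np.histogram(mids, bins=edges)[0])
        counts = np.asarray(counts, dtype=float)
        iod = counts.var(ddof=1) / counts.mean()
        assert abs(iod - 1.0) < 3 * np.sqrt(2 / len(counts))

    def test_nb_moments_calibration(self):
        """Window counts match NB mean/variance for alpha > 0."""
        alpha, rate, window = 0.2, 0.2, 200
        model = rc.make_genome_model(40, 600_000, seed=6)
        fragsets = rc.simulate_fragments(
            model, [], background_rate=rate, nb_dispersion=alpha, seed=8
        )
        mids = fragsets[0].midpoints("chr1")
        counts = []
        for gene in model.genes:
            lo, hi = gene.span
            edges = np.arange(lo, hi, window)
            counts.extend(np.histogram(mids, bins=edges)[0])
        counts = np.asarray(counts, dtype=float)
        mu = rate * window
        var_expected = mu + alpha * mu**2
        assert abs(counts.mean() - mu) < 0.1 * mu
        assert abs(counts.var(ddof=1) - var_expected) < 0.25 * var_expected

    def test_parameter_validation(self, toy_model):
        with pytest.raises(ValueError):
            rc.simulate_fragments(toy_model, [], background_rate=0.0)
        with pytest.raises(ValueError):
            rc.simulate_fragments(toy_model, [], nb_dispersion=-1.0)


def test_fragments_bed_round_trip(toy_model, tmp_path):
    fragsets = rc.simulate_fragments(toy_model, [], seed=1)
    path = tmp_path / "frags.bed"
    rc.simulate.write_fragments_bed(fragsets[0], str(path))
    back = rc.simulate.read_fragments_bed(str(path), "RIP_1", "RIP", 1)
    pd.testing.assert_frame_equal(back.fragments, fragsets[0].fragments)
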