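import dataclasses

import numpy as np
import pytest
from scipy import stats

from chiprx.simdata import (
    ReferenceGenome,
    SimulationConfig,
    build_toy_genomes,
    reverse_complement,
    simulate_chiprx_experiment,
)


def small_cfg(**kw):
    defaults = dict(
        seed=5,
        target_genome_bp=50_000,
        spikein_genome_bp=20_000,
        n_marked_loci_target=12,
        n_marked_loci_spikein=4,
        depth=10_000,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestReferenceGenome:
    def test_rejects_empty_chromosome(self):
        with pytest.raises(ValueError):
            ReferenceGenome("target", {"chr1": ""})

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            ReferenceGenome("target", {"chr1": "ACGN"})

    def test_rejects_bad_label(self):
        with pytest.raises(ValueError):
            ReferenceGenome("human", {"chr1": "ACGT"})


class TestConfigValidation:
    def test_fold_change_positive(self):
        with pytest.raises(ValueError):
            small_cfg(fold_change=0)

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            small_cfg(pulldown_efficiency=1.5)

    def test_fragment_mean_at_least_read_length(self):
        with pytest.raises(ValueError):
            small_cfg(fragment_length_mean=50, read_length=83)

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            SimulationConfig.from_dict({"seed": 1, "bogus": 2})


class TestBuildToyGenomes:
    def test_same_seed_identical(self):
        cfg = small_cfg()
        g1 = build_toy_genomes(cfg)
        g2 = build_toy_genomes(cfg)
        for a, b in zip(g1, g2):
            assert a.chromosomes == b.chromosomes
            assert a.marked_loci == b.marked_loci

    def test_gc_fraction_near_half(self):
        # i.i.d. uniform bases: direct-count oracle, binomial bound p=0.5
        cfg = small_cfg(seed=1, target_genome_bp=100_000)
        target, _ = build_toy_genomes(cfg)
        seq = target.chromosomes["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_no_loci_gives_empty_truth(self):
        cfg = small_cfg(n_marked_loci_target=0)
        target, _ = build_toy_genomes(cfg)
        assert target.marked_loci == []

    def test_loci_disjoint_and_in_bounds(self):
        cfg = small_cfg()
        target, spikein = build_toy_genomes(cfg)
        for genome, n in ((target, 12), (spikein, 4)):
            loci = sorted(genome.marked_loci, key=lambda l: l.start)
            assert len(loci) == n
            size = len(genome.chromosomes["chr1"])
            for prev, cur in zip(loci, loci[1:]):
                assert prev.end <= cur.start
            assert all(0 <= l.start < l.end <= size for l in loci)

    def test_genome_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            build_toy_genomes(small_cfg(target_genome_bp=5_000, locus_width=1_000))


class TestSimulateExperiment:
    def test_four_libraries(self):
        cfg = small_cfg(depth=500)
        libs = simulate_chiprx_experiment(cfg, build_toy_genomes(cfg))
        assert [(l.role, l.condition) for l in libs] == [
            ("pulldown", "treated"),
            ("input", "treated"),
            ("pulldown", "vehicle"),
            ("input", "vehicle"),
        ]
        assert all(len(l) == 500 for l in libs)

    def test_determinism_byte_identical(self):
        cfg = small_cfg(depth=2_000)
        libs1 = simulate_chiprx_experiment(cfg, build_toy_genomes(cfg))
        libs2 = simulate_chiprx_experiment(cfg, build_toy_genomes(cfg))
        for a, b in zip(libs1, libs2):
            assert [dataclasses.astuple(r) for r in a.reads] == [
                dataclasses.astuple(r) for r in b.reads
            ]

    def test_read_length_and_truth_tags(self):
        cfg = small_cfg(depth=1_000)
        genomes = build_toy_genomes(cfg)
        libs = simulate_chiprx_experiment(cfg, genomes)
        by_label = {g.label: g for g in genomes}
        for lib in libs:
            for read in lib.reads[:100]:
                assert len(read.sequence) == cfg.read_length
                chrom_seq = by_label[read.truth_genome].chromosomes[read.truth_chrom]
                span = chrom_seq[read.truth_position : read.truth_position + cfg.read_length]
                if read.truth_strand == "+":
                    assert read.sequence == span
                else:
                    assert read.sequence == reverse_complement(span)

    def test_depth_zero_warns_and_empty(self):
        cfg = small_cfg(depth=0)
        with pytest.warns(UserWarning, match="depth=0"):
            libs = simulate_chiprx_experiment(cfg, build_toy_genomes(cfg))
        assert all(len(l) == 0 for l in libs)

    def test_input_spikein_fraction_matches_mixture_expectation(self):
        # equal genome lengths, 1e7 vs 3e6 cells -> analytic fraction 3/13
        cfg = SimulationConfig(
            seed=3,
            target_genome_bp=40_000,
            spikein_genome_bp=40_000,
            n_marked_loci_target=10,
            n_marked_loci_spikein=10,
            depth=100_000,
        )
        libs = simulate_chiprx_experiment(cfg, build_toy_genomes(cfg))
        inp = next(l for l in libs if l.sample_id == "vehicle_input")
        frac = sum(r.truth_genome == "spikein" for r in inp.reads) / len(inp)
        expected = 3e6 / (1e7 + 3e6)
        sigma = np.sqrt(expected * (1 - expected) / len(inp))
        assert abs(frac - expected) <= 3 * sigma

    def test_fold_change_one_is_symmetric(self):
        cfg = small_cfg(fold_change=1.0, depth=20_000)
        genomes = build_toy_genomes(cfg)
        libs = {l.sample_id: l for l in simulate_chiprx_experiment(cfg, genomes)}
        loci = genomes[0].marked_loci

        def marked_mass(lib):
            n = 0
            for r in lib.reads:
                if r.truth_genome != "target":
                    continue
                s, e = r.truth_position, r.truth_position + cfg.read_length
                if any(l.start < e and s < l.end for l in loci):
                    n += 1
            return n

        ratio = marked_mass(libs["treated_pulldown"]) / marked_mass(libs["vehicle_pulldown"])
        assert 0.95 <= ratio <= 1.05

    def test_flat_pulldown_indistinguishable_from_input(self):
        # capture probability identical for marked and unmarked fragments
        cfg = small_cfg(
            base_occupancy=1.0, pulldown_efficiency=0.3, background_capture=0.3, depth=20_000
        )
        genomes = build_toy_genomes(cfg)
        libs = {l.sample_id: l for l in simulate_chiprx_experiment(cfg, genomes)}
        loci = genomes[0].marked_loci

        def locus_split(lib):
            marked = unmarked = 0
            for r in lib.reads:
                if r.truth_genome != "target":
                    continue
                s, e = r.truth_position, r.truth_position + cfg.read_length
                if any(l.start < e and s < l.end for l in loci):
                    marked += 1
                else:
                    unmarked += 1
            return marked, unmarked

        table = [locus_split(libs["vehicle_pulldown"]), locus_split(libs["vehicle_input"])]
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_condition_isolation_spikein_unchanged(self):
        # spike-in read rates must be statistically identical across conditions
        cfg = small_cfg(depth=20_000)
        libs = {l.sample_id: l for l in simulate_chiprx_experiment(cfg, build_toy_genomes(cfg))}
        table = []
        for cond in ("treated", "vehicle"):
            inp = libs[f"{cond}_input"]
            n_spike = sum(r.truth_genome == "spikein" for r in inp.reads)
            table.append([n_spike, len(inp) - n_spike])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_paired_mode_emits_mates(self):
        cfg = small_cfg(depth=200, paired=True)
        genomes = build_toy_genomes(cfg)
        libs = simulate_chiprx_experiment(cfg, genomes)
        by_label = {g.label: g for g in genomes}
        for read in libs[0].reads[:50]:
            assert read.mate is not None and len(read.mate) == cfg.read_length
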