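"""Simulator: genome synthesis, mutation layers, emission, determinism."""

import pandas as pd
import pytest

from chimeraems.config import SimulationConfig, SpectrumConfig, SUBSTITUTION_TYPES
from chimeraems.errors import ConfigurationError, SimulationError
from chimeraems.simdata import (
    CLASS_EMS1,
    CLASS_EMS2_GREEN,
    CLASS_EMS2_YELLOW,
    emit_pileup,
    emit_sample_calls,
    generate_genome,
    plant_causal_genes,
    sample_layout,
    simulate_two_round_mutagenesis,
)
from chimeraems.spectrum import complement_type, empirical_spectrum
from chimeraems.caller import _strip_read_bases


def _cfg(**kw) -> SimulationConfig:
    base = dict(
        genome_length=10_000, n_genes=5, gene_length=500, background_snv_rate=0.0,
        ems1_count=0, ems2_count=0, n_causal_genes=0, seed=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateGenome:
    def test_genes_fit_within_bounds_and_do_not_overlap(self):
        genome = generate_genome(_cfg())
        genes = sorted(genome.genes, key=lambda g: (g.chrom, g.start))
        assert len(genes) == 5
        for g in genes:
            assert 1 <= g.start <= g.end <= 10_000
            assert g.end - g.start + 1 == 500
        for a, b in zip(genes, genes[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start

    def test_same_seed_byte_identical(self):
        g1 = generate_genome(_cfg())
        g2 = generate_genome(_cfg())
        assert g1.sequences == g2.sequences
        assert g1.genes == g2.genes

    def test_different_seed_differs(self):
        assert generate_genome(_cfg()).sequences != generate_genome(
            _cfg(seed=4)
        ).sequences

    def test_impossible_packing_raises(self):
        with pytest.raises(ConfigurationError, match="pack"):
            generate_genome(_cfg(n_genes=30))

    def test_base_composition_roughly_uniform(self):
        genome = generate_genome(_cfg(genome_length=100_000))
        seq = genome.sequences["chr1"]
        for b in "ACGT":
            assert 0.23 < seq.count(b) / len(seq) < 0.27


class TestMutagenesis:
    def test_leak_off_yields_no_green_records(self):
        cfg = _cfg(ems2_count=50, green_leak_fraction=0.0)
        truth = simulate_two_round_mutagenesis(cfg, generate_genome(cfg))
        assert (truth.variants["true_class"] == CLASS_EMS2_GREEN).sum() == 0

    def test_degenerate_spectrum_fixes_ref_and_alt(self):
        spec = SpectrumConfig(
            {t: (1.0 if t == "G/A" else 0.0) for t in SUBSTITUTION_TYPES}
        )
        cfg = _cfg(ems1_count=30, ems2_count=30, spectrum=spec)
        truth = simulate_two_round_mutagenesis(cfg, generate_genome(cfg))
        assert (truth.variants["ref"] == "G").all()
        assert (truth.variants["alt"] == "A").all()

    def test_ems1_counts_per_line_and_disjoint_positions(self):
        cfg = _cfg(ems1_count=100, genome_length=100_000, n_genes=0)
        truth = simulate_two_round_mutagenesis(cfg, generate_genome(cfg))
        e1 = truth.variants[truth.variants["true_class"] == CLASS_EMS1]
        sets = {}
        for line, sub in e1.groupby("line"):
            assert len(sub) == 100
            sets[line] = set(zip(sub["chrom"], sub["pos"]))
        assert sets["GY1"] & sets["GY2"] == set()
        # no collisions anywhere in the table
        assert not truth.variants.duplicated(["chrom", "pos"]).any()

    def test_variants_drawn_on_matching_reference_bases(self):
        cfg = _cfg(ems1_count=50, background_snv_rate=1e-3)
        genome = generate_genome(cfg)
        truth = simulate_two_round_mutagenesis(cfg, genome)
        for rec in truth.variants.itertuples():
            assert genome.base(rec.chrom, rec.pos) == rec.ref

    def test_base_exhaustion_names_the_type(self):
        spec = SpectrumConfig(
            {t: (1.0 if t == "C/T" else 0.0) for t in SUBSTITUTION_TYPES}
        )
        cfg = _cfg(genome_length=100, n_genes=0, ems1_count=90, spectrum=spec)
        with pytest.raises(SimulationError, match="C/T"):
            simulate_two_round_mutagenesis(cfg, generate_genome(cfg))

    def test_every_ems_record_heterozygous(self):
        cfg = _cfg(ems1_count=20, ems2_count=20, background_snv_rate=1e-3)
        truth = simulate_two_round_mutagenesis(cfg, generate_genome(cfg))
        ems = truth.variants[truth.variants["true_class"] != "BACKGROUND"]
        assert (ems["zygosity"] == "het").all()

    def test_complement_symmetry(self):
        """Simulating on the reverse-complemented genome with the
        complement-swapped spectrum gives the complement-swapped
        empirical spectrum (within sampling noise)."""
        cfg = _cfg(genome_length=500_000, n_genes=0, ems2_count=20_000)
        genome = generate_genome(cfg)
        fwd = empirical_spectrum(
            simulate_two_round_mutagenesis(cfg, genome).variants
        )
        cfg_rc = _cfg(
            genome_length=500_000, n_genes=0, ems2_count=20_000,
            spectrum=cfg.spectrum.complement_swapped(),
        )
        rev = empirical_spectrum(
            simulate_two_round_mutagenesis(cfg_rc, genome.reverse_complemented()).variants
        )
        for t in SUBSTITUTION_TYPES:
            assert fwd[t] == pytest.approx(rev[complement_type(t)], abs=0.02)


class TestPlantCausalGenes:
    def test_counts_and_pair_satisfies_rule_by_rescan(self):
        cfg = _cfg(ems1_count=10, ems2_count=10, n_causal_genes=3)
        genome = generate_genome(cfg)
        truth = plant_causal_genes(
            cfg, genome, simulate_two_round_mutagenesis(cfg, genome)
        )
        assert len(truth.causal_genes) == 3
        genes = {g.gene_id: g for g in genome.genes}
        for rec in truth.causal_genes.itertuples():
            g = genes[rec.gene_id]
            inside = truth.variants[
                (truth.variants["chrom"] == g.chrom)
                & (truth.variants["pos"] >= g.start)
                & (truth.variants["pos"] <= g.end)
                & (truth.variants["line"] == rec.line)
            ]
            second = inside[inside["true_class"] == CLASS_EMS2_YELLOW]
            induced = inside[
                inside["true_class"].isin([CLASS_EMS1, CLASS_EMS2_YELLOW])
            ]
            assert len(second) >= 1
            assert induced["pos"].nunique() >= 2

    def test_zero_causal_genes_is_identity(self):
        cfg = _cfg(ems1_count=10)
        genome = generate_genome(cfg)
        truth = simulate_two_round_mutagenesis(cfg, genome)
        planted = plant_causal_genes(cfg, genome, truth)
        pd.testing.assert_frame_equal(planted.variants, truth.variants)
        assert planted.causal_genes.empty

    def test_gene_too_short_error_names_gene(self):
        cfg = _cfg(gene_length=1, n_genes=3, n_causal_genes=1)
        genome = generate_genome(cfg)
        truth = simulate_two_round_mutagenesis(cfg, genome)
        with pytest.raises(SimulationError, match="gene0000"):
            plant_causal_genes(cfg, genome, truth)


class TestEmitCalls:
    def test_zero_noise_positions_equal_visible_truth(self, tiny_config):
        genome = generate_genome(tiny_config)
        truth = simulate_two_round_mutagenesis(tiny_config, genome)
        calls, masks = emit_sample_calls(truth, tiny_config, genome)
        for sample, line, sector in sample_layout(tiny_config):
            vis = truth.visible_to(line, sector)
            assert set(zip(calls[sample]["chrom"], calls[sample]["pos"])) == set(
                zip(vis["chrom"], vis["pos"])
            )

    def test_ems1_visible_in_both_own_line_samples_only(self, tiny_config):
        genome = generate_genome(tiny_config)
        truth = simulate_two_round_mutagenesis(tiny_config, genome)
        calls, _ = emit_sample_calls(truth, tiny_config, genome)
        e1 = truth.variants[
            (truth.variants["true_class"] == CLASS_EMS1)
            & (truth.variants["line"] == "GY1")
        ].iloc[0]
        key = (e1["chrom"], e1["pos"])
        for sample in ("GY1Y", "GY1G"):
            assert key in set(zip(calls[sample]["chrom"], calls[sample]["pos"]))
        for sample in ("GY2Y", "GY2G"):
            assert key not in set(zip(calls[sample]["chrom"], calls[sample]["pos"]))

    def test_het_alt_read_fraction_is_half_at_full_purity(self):
        cfg = _cfg(
            genome_length=200_000, n_genes=0, ems1_count=600,
            coverage_mean=100.0, sector_purity=1.0,
        )
        genome = generate_genome(cfg)
        truth = simulate_two_round_mutagenesis(cfg, genome)
        calls, _ = emit_sample_calls(truth, cfg, genome)
        het = pd.concat(
            [c[c["zygosity"] == "het"] for c in calls.values()], ignore_index=True
        )
        assert len(het) >= 1000
        frac = (het["alt_reads"] / het["depth"]).mean()
        assert 0.45 <= frac <= 0.55

    def test_sector_purity_dilutes_alt_fraction(self):
        cfg = _cfg(
            genome_length=200_000, n_genes=0, ems1_count=500,
            coverage_mean=100.0, sector_purity=0.5,
        )
        genome = generate_genome(cfg)
        truth = simulate_two_round_mutagenesis(cfg, genome)
        calls, _ = emit_sample_calls(truth, cfg, genome)
        het = pd.concat(list(calls.values()), ignore_index=True)
        assert (het["alt_reads"] / het["depth"]).mean() == pytest.approx(0.25, abs=0.03)

    def test_emission_deterministic(self, tiny_config):
        genome = generate_genome(tiny_config)
        truth = simulate_two_round_mutagenesis(tiny_config, genome)
        c1, m1 = emit_sample_calls(truth, tiny_config, genome)
        c2, m2 = emit_sample_calls(truth, tiny_config, genome)
        for s in c1:
            pd.testing.assert_frame_equal(c1[s], c2[s])
            pd.testing.assert_frame_equal(m1[s], m2[s])


class TestEmitPileup:
    def test_depth_matches_read_string_and_symbols(self, tiny_config):
        genome = generate_genome(tiny_config)
        truth = simulate_two_round_mutagenesis(tiny_config, genome)
        piles = emit_pileup(truth, tiny_config, genome)
        vis = truth.visible_to("GY1", "yellow")
        vis_map = dict(
            (((c, p)), a) for c, p, a in zip(vis["chrom"], vis["pos"], vis["alt"])
        )
        for raw in piles["GY1Y"].splitlines():
            chrom, pos, ref, depth, bases, quals = raw.split("\t")
            stripped = _strip_read_bases(bases, 0)
            assert len(stripped) == int(depth) == len(quals)
            allowed = {"."}
            alt = vis_map.get((chrom, int(pos)))
            if alt is not None:
                allowed.add(alt)
            assert set(stripped) <= allowed  # zero-error emission

    def test_pileup_deterministic(self, tiny_config):
        genome = generate_genome(tiny_config)
        truth = simulate_two_round_mutagenesis(tiny_config, genome)
        assert emit_pileup(truth, tiny_config, genome) == emit_pileup(
            truth, tiny_config, genome
        )
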