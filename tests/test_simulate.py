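"""Synthetic-data generators: determinism, planted-truth recovery."""

import numpy as np
import pytest

from breakscape.core import GenomicInterval
from breakscape.damid import OccupancyTable, count_reads_to_fragments, gatc_fragment_map
from breakscape.motifs import scan_g_quadruplexes, scan_iupac_motifs
from breakscape.shm import assign_transcriptional_strand, select_cytidine_mutations
from breakscape.simulate import (
    PlantedG4,
    PlantedMotif,
    SynthConfig,
    generate_breakpoints,
    generate_contact_matrix,
    generate_damid_reads,
    generate_genome,
    generate_snvs_from_signatures,
    generate_transcription_units,
    random_catalog,
)


def small_config(seed=1):
    cfg = SynthConfig(seed=seed)
    cfg.genome.n_chroms = 2
    cfg.genome.chrom_length = 100_000
    cfg.transcription.n_units = 8
    cfg.transcription.max_length = 8_000
    cfg.breakpoints.n_pairs = 20
    cfg.snv.n = 300
    cfg.damid.reads_per_sample = 50_000
    cfg.damid.n_enriched_fragments = 40
    cfg.contact.n_bins = 80
    cfg.contact.box_rows = (10, 15)
    cfg.contact.box_cols = (50, 55)
    return cfg


def two_sig_config(seed=1):
    cfg = small_config(seed)
    cfg.snv.mixture_weights = (0.7, 0.3)
    return cfg


class TestGenome:
    def test_gc_fraction_matches_config(self):
        cfg = small_config()
        cfg.genome.gc_fraction = 0.5
        genome, _ = generate_genome(cfg)
        s = "".join(genome.seq.values())
        gc = (s.count("G") + s.count("C")) / len(s)
        assert gc == pytest.approx(0.5, abs=0.01)

    def test_planted_motifs_recovered_by_scanner(self):
        cfg = small_config()
        cfg.genome.motif_clusters = [PlantedMotif("GAGCT", 25)]
        genome, truth = generate_genome(cfg)
        matches = scan_iupac_motifs(genome, "GAGCT", strands="+")
        starts = {(m.chrom, m.start) for m in matches}
        for planted in truth["motif:GAGCT"]:
            assert (planted.chrom, planted.start) in starts

    def test_planted_g4s_recovered_by_scanner(self):
        cfg = small_config()
        cfg.genome.g4s = PlantedG4(count=10)
        genome, truth = generate_genome(cfg)
        spans = scan_g_quadruplexes(genome)
        assert len(truth["g4"]) == 10
        for planted in truth["g4"]:
            assert any(
                m.chrom == planted.chrom and m.start <= planted.start and m.end >= planted.end
                for m in spans
            )

    def test_seed_determinism_byte_identical(self):
        g1, t1 = generate_genome(small_config(seed=9))
        g2, t2 = generate_genome(small_config(seed=9))
        g3, _ = generate_genome(small_config(seed=10))
        assert g1.seq == g2.seq and t1 == t2
        assert g1.seq != g3.seq

    def test_overcrowded_planting_is_error(self):
        cfg = small_config()
        cfg.genome.chrom_length = 200
        cfg.genome.motif_clusters = [PlantedMotif("GGGGW", 500)]
        with pytest.raises(RuntimeError):
            generate_genome(cfg)


class TestTranscriptionUnits:
    def test_units_nonoverlapping_and_stranded(self):
        cfg = small_config()
        units = generate_transcription_units(cfg, {"c1": 200_000})
        assert all(u.strand in "+-" for u in units)
        us = sorted(units, key=lambda u: u.start)
        assert all(a.end <= b.start for a, b in zip(us, us[1:]))


class TestBreakpoints:
    def test_biased_mode_places_near_features(self):
        cfg = small_config()
        cfg.breakpoints.n_pairs = 100
        sizes = {"c1": 10_000_000}
        feats = [GenomicInterval("c1", p, p + 1_000) for p in range(100_000, 9_000_000, 500_000)]
        pairs, truth = generate_breakpoints(cfg, sizes, feats)
        from breakscape.breakpoints import distance_to_nearest, pairs_to_intervals

        a_ends = [GenomicInterval(p.breakend_a.chrom, p.breakend_a.pos, p.breakend_a.pos + 1) for p in pairs]
        med = np.median(distance_to_nearest(a_ends, feats))
        assert med <= 2_000  # half-normal sigma=1 kb places most within 2 kb

    def test_null_mode_truth_is_nan(self):
        cfg = small_config()
        cfg.breakpoints.biased = False
        pairs, truth = generate_breakpoints(cfg, {"c1": 1_000_000})
        assert len(pairs) == 20 and all(np.isnan(t) for t in truth)

    def test_zero_pairs(self):
        cfg = small_config()
        cfg.breakpoints.n_pairs = 0
        pairs, truth = generate_breakpoints(cfg, {"c1": 1_000_000}, [GenomicInterval("c1", 0, 10)])
        assert pairs == [] and truth == []


class TestSnvGenerator:
    def test_refs_match_genome_and_truth_recorded(self):
        cfg = small_config()
        genome, _ = generate_genome(cfg)
        genes = generate_transcription_units(cfg, genome)
        cat = random_catalog(3, cfg.seed)
        per_sample, truth = generate_snvs_from_signatures(cfg, genome, cat, genes)
        vs = [v for lst in per_sample.values() for v in lst]
        assert len(vs) == cfg.snv.n
        assert all(genome.seq[v.chrom][v.pos0] == v.ref for v in vs)
        assert len(truth.class_of) == cfg.snv.n

    def test_planted_strand_bias_recovered(self):
        cfg = two_sig_config(seed=21)
        cfg.snv.n = 1_500
        cfg.snv.p_nontemplate = 0.7
        genome, _ = generate_genome(cfg)
        genes = generate_transcription_units(cfg, genome)
        cat = random_catalog(2, cfg.seed)
        per_sample, _ = generate_snvs_from_signatures(cfg, genome, cat, genes)
        vs = [v for lst in per_sample.values() for v in lst]
        res = assign_transcriptional_strand(select_cytidine_mutations(vs), genes)
        assert res.bias == pytest.approx(0.7, abs=0.06)

    def test_shared_variants_removed_by_somatic_filter(self):
        from breakscape.shm import filter_somatic_variants

        cfg = two_sig_config(seed=5)
        cfg.snv.n_samples = 3
        cfg.snv.n_shared = 10
        cfg.snv.n = 90
        genome, _ = generate_genome(cfg)
        cat = random_catalog(2, cfg.seed)
        per_sample, _ = generate_snvs_from_signatures(cfg, genome, cat, None)
        somatic = filter_somatic_variants(per_sample)
        assert sum(len(v) for v in per_sample.values()) == 90 + 3 * 10
        assert sum(len(v) for v in somatic.values()) == 90

    def test_determinism(self):
        cfg = two_sig_config(seed=33)
        genome, _ = generate_genome(cfg)
        cat = random_catalog(2, cfg.seed)
        a, _ = generate_snvs_from_signatures(cfg, genome, cat, None)
        b, _ = generate_snvs_from_signatures(cfg, genome, cat, None)
        assert a == b


class TestDamidGenerator:
    def test_read_totals_and_enrichment_direction(self):
        cfg = small_config(seed=13)
        genome, _ = generate_genome(cfg)
        fm = gatc_fragment_map(genome)
        reads, roles, enriched = generate_damid_reads(cfg, fm, as_arrays=True)
        raw, samples, _ = count_reads_to_fragments(reads, fm)
        assert (raw.sum(axis=0) == cfg.damid.reads_per_sample).all()
        table = OccupancyTable(fm, samples, roles, raw)
        corr = table.corrected_for("fusion1")
        assert (corr[enriched] > 0).mean() > 0.9

    def test_fold_one_indistinguishable(self):
        cfg = small_config(seed=14)
        cfg.damid.fold = 1.0
        genome, _ = generate_genome(cfg)
        fm = gatc_fragment_map(genome)
        reads, roles, enriched = generate_damid_reads(cfg, fm, as_arrays=True)
        raw, samples, _ = count_reads_to_fragments(reads, fm)
        table = OccupancyTable(fm, samples, roles, raw)
        corr = table.corrected_for("fusion1")
        # positive rate on "enriched" fragments near chance
        assert abs((corr[enriched] > 0).mean() - 0.5) < 0.2

    def test_interval_output_mode(self):
        cfg = small_config(seed=15)
        cfg.damid.reads_per_sample = 500
        genome, _ = generate_genome(cfg)
        fm = gatc_fragment_map(genome)
        reads, roles, _ = generate_damid_reads(cfg, fm, as_arrays=False)
        sample = next(iter(reads))
        assert all(isinstance(r, GenomicInterval) for r in reads[sample])
        assert len(reads[sample]) == 500


class TestContactGenerator:
    def test_symmetric_and_deterministic(self):
        cfg = small_config(seed=17)
        m1, box1 = generate_contact_matrix(cfg)
        m2, _ = generate_contact_matrix(cfg)
        assert np.allclose(m1.M, m1.M.T)
        assert np.array_equal(m1.M, m2.M)

    def test_decay_with_distance(self):
        cfg = small_config(seed=18)
        cfg.contact.fold = 1.0
        m, _ = generate_contact_matrix(cfg)
        d1 = np.mean(np.diag(m.M, k=1))
        d20 = np.mean(np.diag(m.M, k=20))
        assert d1 > d20

    def test_planted_box_enriched_over_fold1(self):
        cfg = small_config(seed=19)
        m, (rows, cols) = generate_contact_matrix(cfg)
        cfg0 = small_config(seed=19)
        cfg0.contact.fold = 1.0
        m0, _ = generate_contact_matrix(cfg0)
        assert m.M[np.ix_(rows, cols)].mean() > 2 * m0.M[np.ix_(rows, cols)].mean()
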