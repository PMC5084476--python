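"""Generators: construction invariants, determinism, planted ground truth."""

import numpy as np
import pytest

from grasskit import aci, synthetic as syn
from grasskit._seq import circular_slice, revcomp
from grasskit.errors import InvalidSpecError


class TestGeneratePlastome:
    def test_quadripartite_construction(self):
        spec = syn.PlastomeSpec(lsc_len=1000, ssc_len=300, ir_len=200, seed=0)
        seq, part = syn.generate_plastome(spec)
        assert len(seq) == 1700
        # IRb occupies bases 1001-1200 (1-based), IRa 1501-1700
        assert seq[1000:1200] == revcomp(seq[1500:1700])
        assert part.total == 1700
        assert part.lsc_len + part.ssc_len + 2 * part.irb_len == len(seq)

    def test_table_geometry_total(self):
        spec = syn.PlastomeSpec(lsc_len=82_090, ssc_len=12_572, ir_len=22_719)
        assert spec.total == 140_100

    def test_deterministic(self):
        spec = syn.PlastomeSpec(lsc_len=1000, ssc_len=300, ir_len=200, seed=7)
        assert syn.generate_plastome(spec)[0] == syn.generate_plastome(spec)[0]

    def test_too_small_rejected(self):
        with pytest.raises(InvalidSpecError):
            syn.PlastomeSpec(lsc_len=50, ssc_len=300, ir_len=200)


class TestShredReads:
    def test_read_count(self, small_plastome):
        _, genome, _ = small_plastome
        sim = syn.ReadSimSpec(read_len=100, coverage=50.0, seed=0)
        spec = syn.PlastomeSpec(lsc_len=1000, ssc_len=300, ir_len=200, seed=0)
        g, _ = syn.generate_plastome(spec)
        assert len(syn.shred_reads(g, sim)) == 850  # ceil(50*1700/100)

    def test_error_free_reads_are_genome_substrings(self):
        spec = syn.PlastomeSpec(lsc_len=1000, ssc_len=300, ir_len=200, seed=3)
        g, _ = syn.generate_plastome(spec)
        doubled = g + g
        rc_doubled = revcomp(g) + revcomp(g)
        reads = syn.shred_reads(g, syn.ReadSimSpec(read_len=80, coverage=5, seed=4))
        for r in reads:
            assert r in doubled or r in rc_doubled

    def test_error_rate_binomial(self):
        spec = syn.PlastomeSpec(lsc_len=1000, ssc_len=300, ir_len=200, seed=5)
        g, _ = syn.generate_plastome(spec)
        sim = syn.ReadSimSpec(read_len=100, coverage=60, error_rate=0.01, seed=6)
        reads = syn.shred_reads(g, sim)
        clean = syn.shred_reads(g, syn.ReadSimSpec(
            read_len=100, coverage=60, error_rate=0.0, seed=6))
        n_bases = sum(len(r) for r in reads)
        mism = sum(
            a != b for r, c in zip(reads, clean) for a, b in zip(r, c)
        )
        p = mism / n_bases
        sd = (0.01 * 0.99 / n_bases) ** 0.5
        assert n_bases > 1e5
        assert abs(p - 0.01) < 3 * sd

    def test_read_longer_than_genome_rejected(self):
        with pytest.raises(InvalidSpecError):
            syn.shred_reads("ACGT" * 10, syn.ReadSimSpec(read_len=100, coverage=2))


class TestSeedContigs:
    def test_contigs_cover_genome_minus_gaps(self, small_plastome):
        _, genome, _ = small_plastome
        contigs, truth = syn.seed_contigs(genome, n_gaps=2, min_gap=150, seed=3)
        assert len(contigs) == 2
        gap_total = sum(
            (e - s) % len(genome) for s, e in truth["gaps"]
        )
        assert sum(len(c) for c in contigs) == len(genome) - gap_total
        assert gap_total >= 2 * 150

    def test_no_slop_contigs_exact_substrings(self, small_plastome):
        _, genome, _ = small_plastome
        contigs, truth = syn.seed_contigs(genome, n_gaps=3, min_gap=150,
                                          end_slop=0, seed=9)
        doubled = genome + genome
        for c in contigs:
            assert c.sequence in doubled

    def test_truth_gap_coordinates_match(self, small_plastome):
        _, genome, _ = small_plastome
        contigs, truth = syn.seed_contigs(genome, n_gaps=2, min_gap=150,
                                          end_slop=0, seed=4)
        n = truth["genome_length"]
        for (c_start, _), contig in zip(truth["contigs"], contigs):
            assert circular_slice(genome, c_start, len(contig)) == contig.sequence

    def test_impossible_gaps_rejected(self):
        with pytest.raises(InvalidSpecError):
            syn.seed_contigs("ACGT" * 300, n_gaps=5, min_gap=400, seed=0)


class TestGenerateGradient:
    def test_deterministic(self):
        d = syn.GradientDesign(n_genes=50, n_tf=10, seed=5)
        a = syn.generate_gradient(d)
        b = syn.generate_gradient(d)
        for sp in a.datasets:
            assert a.datasets[sp].data.equals(b.datasets[sp].data)

    def test_planted_fold_exact_without_noise(self):
        planted = (syn.PlantedTF(0, frozenset({"Zm", "Sb"}), 4.0, (3, 4)),)
        d = syn.GradientDesign(n_genes=30, n_tf=5, planted=planted,
                               noise_cv=0.0, seed=1)
        res = syn.generate_gradient(d)
        zm = res.datasets["Zm"].segment_means().loc["TF0000"]
        do = res.datasets["Do"].segment_means().loc["TF0000"]
        assert np.allclose(zm[[3, 4]] / do[[3, 4]], 4.0)
        assert np.allclose(zm[[1, 2]], do[[1, 2]])

    def test_background_shared_across_species(self):
        d = syn.GradientDesign(n_genes=30, n_tf=5, noise_cv=0.0, seed=2)
        res = syn.generate_gradient(d)
        assert res.datasets["Zm"].segment_means().equals(
            res.datasets["Os"].segment_means()
        )

    def test_replicate_minimum_enforced(self):
        with pytest.raises(InvalidSpecError):
            syn.GradientDesign(n_replicates=1)

    def test_planted_pattern_validation(self):
        with pytest.raises(InvalidSpecError):
            syn.GradientDesign(
                planted=(syn.PlantedTF(0, frozenset({"Do"}), 4.0),)
            )

    def test_ortholog_dropout_recorded_as_na(self):
        d = syn.GradientDesign(n_genes=50, n_tf=20, ortholog_dropout=0.5, seed=3)
        res = syn.generate_gradient(d)
        dropped = res.ortholog_map["Sb"].isna()
        assert dropped.any()
        assert res.ortholog_map["Zm"].notna().all()  # reference keeps all


class TestKmerGenome:
    def test_length_arithmetic(self):
        seq, truth = syn.generate_kmer_genome(
            syn.KmerGenomeSpec(unique_bp=10_000, duplicated_bp=2_000, seed=0)
        )
        assert len(seq) == 14_000 == truth["total_bp"]

    def test_duplicated_block_occurs_twice(self):
        seq, truth = syn.generate_kmer_genome(
            syn.KmerGenomeSpec(unique_bp=10_000, duplicated_bp=2_000, seed=1)
        )
        (a, b), _ = truth["dup_intervals"]
        block = seq[a:b]
        assert seq.count(block) == 2

    def test_gc_binomial(self):
        seq, _ = syn.generate_kmer_genome(
            syn.KmerGenomeSpec(unique_bp=100_000, duplicated_bp=10_000, seed=2)
        )
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        sd = (0.25 / len(seq)) ** 0.5
        assert abs(gc - 0.5) < 3 * sd


class TestGenerateAlignment:
    def test_planting_substitutes_reference_column(self):
        aln = syn.synthetic_protein_alignment(n_seqs=4, length=800, seed=0)
        aln = syn.generate_alignment(aln, [("REF", 780, "A"), ("seq1", 780, "S")])
        assert aln["REF"][779] == "A"
        assert aln["seq1"][779] == "S"

    def test_empty_plant_list_is_identity(self):
        aln = syn.synthetic_protein_alignment(n_seqs=3, length=100, seed=1)
        assert syn.generate_alignment(aln, []) == aln

    def test_alignment_length_preserved(self):
        aln = syn.synthetic_protein_alignment(n_seqs=3, length=100,
                                              gap_columns=10, seed=2)
        out = syn.generate_alignment(aln, [("seq1", 50, "W")])
        assert {len(s) for s in out.values()} == {len(aln["REF"])}

    def test_position_out_of_range(self):
        aln = syn.synthetic_protein_alignment(n_seqs=3, length=100, seed=3)
        with pytest.raises(InvalidSpecError):
            syn.generate_alignment(aln, [("seq1", 101, "S")])


class TestSimulateAci:
    def test_zero_noise_equals_model_curve(self):
        p = aci.c3_defaults()
        obs = syn.simulate_aci(p, noise_sd=0.0, seed=0)
        curve = aci.model_curve(obs["ci_ubar"].to_numpy(), p)
        assert np.allclose(obs["a_umol"], curve.a)

    def test_default_grid_matches_measurement_pressures(self):
        grid = syn.default_ci_grid()
        assert set(np.round(grid, 1)) == {
            round(pa * 10, 1) for pa in aci.MEASUREMENT_PA
        }

    def test_seeded_noise_reproducible(self):
        p = aci.c4_defaults()
        a = syn.simulate_aci(p, noise_sd=0.5, seed=42)
        b = syn.simulate_aci(p, noise_sd=0.5, seed=42)
        assert a.equals(b)
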