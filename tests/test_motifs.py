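"""TTS-anchored window extraction, positional motif profiles, k-mer rankings."""

import numpy as np
import pytest

from oligou import synthetic as syn
from oligou.motifs import (
    Feature,
    FeatureSet,
    OrientedWindow,
    Window,
    extract_windows,
    filter_nonoverlapping,
    normalize_motif,
    positional_profile,
    rank_kmers,
    read_bed6,
    read_fasta,
    reverse_complement,
    smooth_profile,
    write_bed6,
    write_fasta,
)


def brute_force_nonoverlap(features):
    feats = features.features
    keep = []
    for i, f in enumerate(feats):
        clash = any(
            j != i and g.chrom == f.chrom
            and f.start < g.end and g.start < f.end
            for j, g in enumerate(feats)
        )
        if not clash:
            keep.append(f)
    return keep


def brute_force_scan(windows, motif):
    """Naive per-position occurrence scan, independent of the profile code."""
    hits = {}
    for w in windows:
        for idx in range(len(w.seq) - len(motif) + 1):
            if w.seq[idx:idx + len(motif)] == motif:
                pos = w.first_position + idx
                hits[pos] = hits.get(pos, 0) + 1
    return hits


class TestFilterNonoverlapping:
    def test_disjoint_kept(self):
        fs = FeatureSet([Feature("c", 100, 200, "+", "a"),
                         Feature("c", 300, 400, "-", "b")])
        assert len(filter_nonoverlapping(fs)) == 2

    def test_overlapping_pair_both_removed(self):
        fs = FeatureSet([Feature("c", 100, 200, "+", "a"),
                         Feature("c", 150, 250, "+", "b")])
        assert len(filter_nonoverlapping(fs)) == 0

    def test_different_chromosomes_never_overlap(self):
        fs = FeatureSet([Feature("c1", 100, 200, "+", "a"),
                         Feature("c2", 100, 200, "-", "b")])
        assert len(filter_nonoverlapping(fs)) == 2

    def test_matches_all_pairs_oracle_on_random_set(self):
        rng = np.random.default_rng(17)
        feats = []
        for i in range(50):
            start = int(rng.integers(0, 2000))
            feats.append(Feature(
                chrom=f"c{int(rng.integers(1, 4))}", start=start,
                end=start + int(rng.integers(10, 200)),
                strand="+" if rng.random() < 0.5 else "-", name=f"f{i}"))
        fs = FeatureSet(feats)
        got = [f.name for f in filter_nonoverlapping(fs)]
        want = [f.name for f in brute_force_nonoverlap(fs)]
        assert got == want


class TestExtractWindows:
    genome = {"chr1": "ACGTACGTAC" * 120}  # 1200 nt

    def test_plus_strand_coordinates(self):
        feats = [Feature("chr1", 900, 1000, "+", "f")]
        (w,) = extract_windows(self.genome, feats, Window(2, 3))
        assert w.seq == self.genome["chr1"][998:1003]
        assert list(w.positions) == [-2, -1, 0, 1, 2]
        assert not w.clipped

    def test_minus_strand_is_revcomp(self):
        feats = [Feature("chr1", 1000, 1100, "-", "f")]
        (w,) = extract_windows(self.genome, feats, Window(2, 3))
        assert w.seq == reverse_complement(self.genome["chr1"][997:1002])
        assert w.first_position == -2

    def test_clipping_at_chromosome_end(self):
        feats = [Feature("chr1", 1000, 1150, "+", "f")]  # 50 nt of room
        (w,) = extract_windows(self.genome, feats, Window(20, 600))
        assert w.clipped
        assert len(w.seq) == 50 + 20
        assert w.first_position == -20

    def test_clipping_minus_strand_at_left_end(self):
        feats = [Feature("chr1", 30, 100, "-", "f")]
        (w,) = extract_windows(self.genome, feats, Window(10, 600))
        assert w.clipped
        assert len(w.seq) == 30 + 10  # downstream clipped to 30 nt
        assert w.first_position == -10

    def test_missing_chromosome_names_feature(self):
        with pytest.raises(KeyError, match="lost"):
            extract_windows(self.genome, [Feature("chrX", 0, 10, "+", "lost")])


class TestPositionalProfile:
    def test_absent_motif_all_zero(self):
        wins = [OrientedWindow("w", "ACGCACGC", -2)]
        prof = positional_profile(wins, "TTTTT", Window(2, 8))
        assert prof.counts.sum() == 0

    def test_planted_motif_exact_by_construction(self):
        fasta, feats = syn.gen_genome(5, 50000, motif="TTTTT", offset_nt=10,
                                      strand_mix=0.4, seed=7)
        genome = {"chr1": "".join(fasta.splitlines()[1:])}
        wins = extract_windows(genome, feats)
        prof = positional_profile(wins, "UUUUU")
        peak = prof.positions[np.argmax(prof.counts)]
        assert peak == 10
        assert prof.counts.max() == 5
        assert prof.counts.sum() == 5  # no accidental background copies

    def test_all_minus_strand_plants_revcomp_in_fasta(self):
        fasta, feats = syn.gen_genome(4, 40000, motif="TTTTT", offset_nt=10,
                                      strand_mix=1.0, seed=3)
        seq = "".join(fasta.splitlines()[1:])
        for f in feats:
            assert f.strand == "-"
            g0 = f.start - 10 - 5
            assert seq[g0:g0 + 5] == "AAAAA"  # revcomp of TTTTT, downstream-left

    def test_overlapping_occurrences_counted_at_every_start(self):
        wins = [OrientedWindow("w", "TTTTTTT", 0)]
        prof = positional_profile(wins, "TTTTT", Window(0, 7))
        assert list(prof.counts) == [1, 1, 1]
        assert list(prof.positions) == [0, 1, 2]

    def test_oracle_equivalence_on_random_windows(self):
        rng = np.random.default_rng(23)
        wins = []
        for i in range(30):
            n = int(rng.integers(20, 80))
            seq = "".join(rng.choice(list("ACGT"), n))
            wins.append(OrientedWindow(f"w{i}", seq, -10))
        window = Window(10, 80)
        for motif in ("TT", "ACG", "TTTT"):
            prof = positional_profile(wins, motif, window)
            oracle = brute_force_scan(wins, motif)
            for pos, cnt in zip(prof.positions, prof.counts):
                assert cnt == oracle.get(pos, 0)
            assert prof.counts.sum() == sum(oracle.values())

    def test_coverage_normalizes_clipping(self):
        wins = [OrientedWindow("full", "A" * 20, -5),
                OrientedWindow("clip", "A" * 10, -5, clipped=True)]
        prof = positional_profile(wins, "AA", Window(5, 15))
        # positions covered by both windows have coverage 2, the rest 1
        cov = dict(zip(prof.positions, prof.coverage))
        assert cov[-5] == 2 and cov[3] == 2
        assert cov[4] == 1 and cov[13] == 1
        assert all(d == 1.0 for d in prof.density[prof.coverage > 0])

    def test_background_pentamer_rate_binomial(self):
        # background-only genome: expected count per position across
        # features is n * (1/4)^5; totalled over all window positions
        fasta, feats = syn.gen_genome(12, 80000, motif=None, seed=29,
                                      window=Window(50, 150))
        genome = {"chr1": "".join(fasta.splitlines()[1:])}
        wins = extract_windows(genome, feats, Window(50, 150))
        prof = positional_profile(wins, "CTAGA", Window(50, 150))
        n_slots = prof.coverage.sum()
        expected = n_slots * 0.25**5
        # Poisson-ish sampling band: mean +/- 4 sd
        assert abs(prof.counts.sum() - expected) < 4 * np.sqrt(expected) + 4


class TestRankKmers:
    def test_single_window_trivial(self):
        r = rank_kmers([OrientedWindow("w", "AAAA", 0)], 4)
        assert r.table == [("AAAA", 1)]
        assert r.rank("AAAA") == 1

    def test_planted_second_rank(self):
        wins = (
            [OrientedWindow(f"a{i}", "AAAAA", 0) for i in range(10)]
            + [OrientedWindow(f"t{i}", "TTTTT", 0) for i in range(6)]
            + [OrientedWindow("bg", "ACGTCAGTCGA", 0)]
        )
        r = rank_kmers(wins, 5)
        assert r.rank("AAAAA") == 1
        assert r.rank("UUUUU") == 2
        assert r.count_rank("TTTTT") == 2

    def test_count_conservation(self):
        rng = np.random.default_rng(31)
        wins = [
            OrientedWindow(f"w{i}", "".join(rng.choice(list("ACGT"), 50)), 0)
            for i in range(10)
        ]
        r = rank_kmers(wins, 5)
        assert sum(c for _, c in r.table) == 10 * (50 - 5 + 1)

    def test_non_acgt_kmers_skipped(self):
        r = rank_kmers([OrientedWindow("w", "AANTT", 0)], 2)
        assert dict(r.table) == {"AA": 1, "TT": 1}

    def test_ties_broken_lexicographically(self):
        r = rank_kmers([OrientedWindow("w", "ACGT", 0)], 2)
        assert [k for k, _ in r.table] == ["AC", "CG", "GT"]
        assert r.count_rank("GT") == 1  # all counts tie at 1

    def test_profile_counts_match_ranking_entry(self):
        fasta, feats = syn.gen_genome(6, 60000, motif="TTTTT", offset_nt=20,
                                      seed=5)
        genome = {"chr1": "".join(fasta.splitlines()[1:])}
        wins = extract_windows(genome, feats)
        prof = positional_profile(wins, "TTTTT")
        rank = rank_kmers(wins, 5)
        # ranking scans whole windows including the last k-1 tail positions
        # beyond the profile's start-position range; planted copies are inside
        assert rank.count("TTTTT") >= prof.counts.sum() == 6


class TestStrandSymmetry:
    def test_revcomp_genome_with_flipped_strands_is_invariant(self):
        fasta, feats = syn.gen_genome(6, 60000, motif="TTTTT", offset_nt=15,
                                      strand_mix=0.5, seed=19)
        seq = "".join(fasta.splitlines()[1:])
        genome = {"chr1": seq}
        n = len(seq)
        flipped_genome = {"chr1": reverse_complement(seq)}
        flipped = FeatureSet([
            Feature("chr1", n - f.end, n - f.start,
                    "-" if f.strand == "+" else "+", f.name)
            for f in feats
        ])
        w = Window(50, 100)
        p1 = positional_profile(extract_windows(genome, feats, w), "TTTTT", w)
        p2 = positional_profile(extract_windows(flipped_genome, flipped, w),
                                "TTTTT", w)
        assert np.array_equal(p1.counts, p2.counts)
        r1 = rank_kmers(extract_windows(genome, feats, w), 4)
        r2 = rank_kmers(extract_windows(flipped_genome, flipped, w), 4)
        assert r1.table == r2.table


class TestSmoothProfile:
    def _delta_profile(self):
        wins = [OrientedWindow("w", "GGTGG", 0)]
        return positional_profile(wins, "T", Window(0, 5))

    def test_width_one_identity(self):
        prof = self._delta_profile()
        sm = smooth_profile(prof, 1)
        assert np.allclose(sm.density, prof.density)

    def test_constant_profile_unchanged(self):
        wins = [OrientedWindow("w", "TTTTT", 0)]
        prof = positional_profile(wins, "T", Window(0, 5))
        sm = smooth_profile(prof, 3)
        assert np.allclose(sm.density, 1.0)

    def test_delta_spreads_third_mass(self):
        prof = self._delta_profile()
        sm = smooth_profile(prof, 3)
        d = dict(zip(sm.positions, sm.density))
        assert d[1] == pytest.approx(1 / 3)
        assert d[2] == pytest.approx(1 / 3)
        assert d[3] == pytest.approx(1 / 3)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(self._delta_profile(), 4)


class TestMotifNormalization:
    def test_u_maps_to_t(self):
        assert normalize_motif("UUUUU") == "TTTTT"
        assert normalize_motif("acgu") == "ACGT"

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError):
            normalize_motif("UUXUU")


def test_fasta_bed_roundtrip(tmp_path):
    fasta, feats = syn.gen_genome(3, 30000, motif="TTTT", offset_nt=5, seed=2)
    fa = tmp_path / "g.fa"
    fa.write_text(fasta)
    genome = read_fasta(fa)
    assert len(genome["chr1"]) == 30000
    assert max(len(l) for l in fasta.splitlines()[1:]) == 60
    bed = tmp_path / "f.bed"
    write_bed6(feats, bed)
    back = read_bed6(bed)
    assert [(f.chrom, f.start, f.end, f.strand, f.name) for f in back] == \
           [(f.chrom, f.start, f.end, f.strand, f.name) for f in feats]
    fa2 = tmp_path / "h.fa"
    write_fasta(genome, fa2)
    assert read_fasta(fa2) == genome
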