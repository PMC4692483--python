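"""The three background randomizers, flank GC profiling, site pooling and
the exact composition-correction step."""

from collections import Counter

import numpy as np
import pytest

from glicluster import _seq
from glicluster.background import (
    CompositionError,
    BackgroundEnsemble,
    bg_flip_gc_at,
    bg_random,
    bg_shuffle3mer,
    build_site_pool,
    gc_context_profile,
    native_composition,
    reconstruct_backgrounds,
)
from glicluster.genome import scan_sites, GenomeAssembly


def random_seq(rng, n, gc=0.5):
    is_gc = rng.random(n) < gc
    half = rng.integers(0, 2, size=n)
    return _seq.decode(np.where(is_gc, 1 + half, np.where(half == 0, 0, 3)))


class TestRandomizers:
    def test_n_preserved_everywhere(self, rng):
        for fn in (bg_random, bg_shuffle3mer, bg_flip_gc_at):
            assert fn("NNNN", rng) == "NNNN"
            out = fn("ACGNNTGC", rng)
            assert [c == "N" for c in out] == [c == "N" for c in "ACGNNTGC"]

    def test_random_uniform_within_binomial_bound(self, rng):
        n = 10_000
        out = bg_random("A" * n, rng)
        sd = (n * 0.25 * 0.75) ** 0.5
        for b in "ACGT":
            assert abs(out.count(b) - n * 0.25) < 5 * sd

    def test_determinism(self):
        seq = random_seq(np.random.default_rng(0), 3000)
        for fn in (bg_random, bg_shuffle3mer, bg_flip_gc_at):
            a = fn(seq, np.random.default_rng(42))
            b = fn(seq, np.random.default_rng(42))
            assert a == b

    def test_shuffle3mer_block_multiset_preserved(self, rng):
        seq = random_seq(rng, 9_999)
        out = bg_shuffle3mer(seq, rng)
        blocks = lambda s: Counter(s[i : i + 3] for i in range(0, len(s) - 2, 3))
        assert blocks(out) == blocks(seq)
        assert Counter(out) == Counter(seq)

    @pytest.mark.parametrize("n", [3001, 3002])
    def test_shuffle3mer_remainder_in_place(self, rng, n):
        seq = random_seq(rng, n)
        out = bg_shuffle3mer(seq, rng)
        assert out[3000:] == seq[3000:]

    def test_shuffle3mer_identical_blocks_fixed_point(self, rng):
        assert bg_shuffle3mer("AAAAAA", rng) == "AAAAAA"

    def test_flip_stays_within_complement_pair(self, rng):
        assert set(bg_flip_gc_at("GGCC" * 25, rng)) <= set("GC")
        assert set(bg_flip_gc_at("ATAT" * 25, rng)) <= set("AT")

    def test_flip_preserves_every_window_gc_exactly(self, rng):
        seq = random_seq(rng, 20_000, gc=0.37)
        out = bg_flip_gc_at(seq, rng)
        gc_in = np.frombuffer(seq.encode(), dtype=np.uint8)
        gc_out = np.frombuffer(out.encode(), dtype=np.uint8)
        is_gc = lambda a: (a == ord("G")) | (a == ord("C"))
        assert np.array_equal(is_gc(gc_in), is_gc(gc_out))  # per-base, hence per-window

    def test_flip_per_base_is_input_or_complement(self, rng):
        seq = random_seq(rng, 5_000)
        out = bg_flip_gc_at(seq, rng)
        comp = _seq.reverse_complement(seq)[::-1]
        assert all(o in (i, c) for o, i, c in zip(out, seq, comp))


class TestGCProfile:
    def test_all_g_flanks(self):
        seq = "G" * 50 + "AAAAAAAAA" + "G" * 50
        prof = gc_context_profile(np.array([50]), seq, width=9)
        assert prof.fractions[0] == pytest.approx(1.0)

    def test_all_a_flanks(self):
        seq = "A" * 109
        prof = gc_context_profile(np.array([50]), seq, width=9)
        assert prof.fractions[0] == pytest.approx(0.0)

    def test_site_bases_excluded(self):
        # GC-free flanks around an all-GC site
        seq = "A" * 50 + "G" * 9 + "A" * 50
        prof = gc_context_profile(np.array([50]), seq, width=9)
        assert prof.fractions[0] == pytest.approx(0.0)

    def test_incomplete_flanks_excluded_and_counted(self):
        seq = "A" * 70
        prof = gc_context_profile(np.array([3, 30]), seq, width=9)
        assert prof.n_excluded == 2
        assert len(prof.fractions) == 0

    def test_flip_background_preserves_profile_exactly(self, rng):
        seq = random_seq(rng, 10_000, gc=0.6)
        starts = np.sort(rng.choice(9_000, size=40, replace=False)) + 100
        native = gc_context_profile(starts, seq, width=9)
        flipped = gc_context_profile(starts, bg_flip_gc_at(seq, rng), width=9)
        assert np.array_equal(native.fractions, flipped.fractions)

    def test_random_background_homogenizes_to_half(self, rng):
        seq = random_seq(rng, 50_000, gc=0.7)
        starts = np.sort(rng.choice(48_000, size=200, replace=False)) + 100
        prof = gc_context_profile(starts, bg_random(seq, rng), width=9)
        assert abs(prof.mean - 0.5) < 3 * prof.sem + 1e-9


class TestSitePool:
    def test_pool_size_equals_sum_of_replicate_counts(self, vocab, fixture_genome, rng):
        genome, _ = fixture_genome
        seq = genome.codes("chrS")[:10_000]
        pool = build_site_pool(seq, vocab, "random", rng, n_raw=10)
        assert pool.total == int(pool.replicate_totals.sum())

    def test_empty_pool_when_no_kmer_can_occur(self, vocab, rng):
        # all-A sequence under the flip model can only produce A/T bases,
        # but every vocabulary k-mer contains G or C (concordance rule)
        pool = build_site_pool("A" * 5_000, vocab, "flip_gc_at", rng, n_raw=5)
        assert pool.total == 0

    def test_flip_replicates_undercount_gc_clustered_native(self, vocab, rng):
        """Raw flip backgrounds carry consistently fewer sites than a native
        chromosome whose sites sit in GC-favourable sequence."""
        from glicluster.synthetic import FixtureSpec, PlantedCluster, make_genome

        spec = FixtureSpec(
            seed=5,
            gc_segments={"c": [(30_000, 0.45)]},
            planted_clusters=[PlantedCluster("c", 5_000 + 6_000 * i, 4, 900) for i in range(4)],
            scrub_decoys=False,
        )
        genome, _ = make_genome(spec, vocab)
        native_count = len(scan_sites(genome, vocab))
        pool = build_site_pool(genome.codes("c"), vocab, "flip_gc_at", rng, n_raw=20)
        assert np.mean(pool.replicate_totals) < native_count


class TestReconstruction:
    def _pool_and_native(self, vocab, fixture_genome, rng, n_raw=30):
        genome, truth = fixture_genome
        comp = native_composition(truth.sites, "chrS")
        pool = build_site_pool(genome.codes("chrS"), vocab, "flip_gc_at", rng, n_raw=n_raw, chrom="chrS")
        return pool, comp

    def test_every_replicate_matches_native_composition_exactly(self, vocab, fixture_genome, rng):
        pool, comp = self._pool_and_native(vocab, fixture_genome, rng)
        ens = reconstruct_backgrounds(pool, comp, rng, n=100)
        for codes in ens.replicate_codes:
            assert dict(Counter(codes.tolist())) == comp
        for starts in ens.replicate_starts:
            assert len(np.unique(starts)) == len(starts)  # no duplicate intervals

    def test_counts_in_region(self, vocab, fixture_genome, rng):
        pool, comp = self._pool_and_native(vocab, fixture_genome, rng)
        ens = reconstruct_backgrounds(pool, comp, rng, n=10)
        counts = ens.counts_in(0, 100_000)
        assert np.all(counts == sum(comp.values()))
        # brute-force containment oracle on a smaller window
        lo, hi = 20_000, 60_000
        brute = [int(sum(1 for s in st if lo <= s and s + 9 <= hi)) for st in ens.replicate_starts]
        assert ens.counts_in(lo, hi).tolist() == brute

    def test_native_kmer_absent_from_pool_errors(self, vocab, rng):
        from glicluster.background import SitePool

        pool = SitePool(
            chrom="c", width=9, model="flip_gc_at", n_raw=5,
            positions={0: np.arange(10) * 20}, replicate_totals=np.zeros(5, dtype=np.int64),
            mss_by_code={0: 0.8},
        )
        with pytest.raises(CompositionError, match="increase the raw replicate count"):
            reconstruct_backgrounds(pool, {1: 3}, rng, n=2)

    def test_mss_class_fallback(self, rng, caplog):
        """A k-mer with too few pooled positions borrows from its MSS class."""
        from glicluster.background import SitePool

        pool = SitePool(
            chrom="c", width=9, model="flip_gc_at", n_raw=5,
            positions={0: np.array([100]), 1: np.arange(50) * 30 + 1000},
            replicate_totals=np.zeros(5, dtype=np.int64),
            mss_by_code={0: 0.801, 1: 0.799},  # same class at 0.01 rounding
        )
        ens = reconstruct_backgrounds(pool, {0: 3}, rng, n=4)
        for starts in ens.replicate_starts:
            assert len(starts) == 3 and len(set(starts.tolist())) == 3

    def test_expected_count_arithmetic(self):
        counts = [0, 1, 2, 1, 0, 1, 3, 0, 1, 1]
        starts = [np.arange(c) * 20 + 100 for c in counts]
        ens = BackgroundEnsemble(
            chrom="c", width=9, n_replicates=10,
            replicate_starts=starts,
            replicate_codes=[np.zeros(len(s), dtype=np.int64) for s in starts],
            native_composition={},
        )
        assert ens.expected_count(0, 1000) == pytest.approx(1.0)


class TestEnsembleIO:
    def test_tsv_round_trip(self, tmp_path, vocab, fixture_genome, rng):
        from glicluster.background import read_ensemble_tsv

        genome, truth = fixture_genome
        comp = native_composition(truth.sites, "chrS")
        pool = build_site_pool(genome.codes("chrS"), vocab, "flip_gc_at", rng, n_raw=20, chrom="chrS")
        ens = reconstruct_backgrounds(pool, comp, rng, n=5)
        p = tmp_path / "ens.tsv"
        ens.write_tsv(p)
        back = read_ensemble_tsv(p)
        assert back.chrom == "chrS" and back.n_replicates == 5
        for a, b in zip(ens.replicate_starts, back.replicate_starts):
            assert sorted(a.tolist()) == sorted(b.tolist())
        assert back.expected_count(0, 100_000) == ens.expected_count(0, 100_000)

    def test_gc_profile_tsv(self, tmp_path, rng):
        seq = random_seq(rng, 2_000, gc=0.5)
        prof = gc_context_profile(np.array([500, 900]), seq, width=9)
        p = tmp_path / "prof.tsv"
        prof.write_tsv(p)
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "record\tgc_fraction"
        assert lines[-1].startswith("n_excluded")


def test_dedupe_pool_collapses_duplicate_coordinates(vocab, fixture_genome, rng):
    genome, _ = fixture_genome
    seq = genome.codes("chrS")[:20_000]
    raw = build_site_pool(seq, vocab, "random", np.random.default_rng(3), n_raw=40)
    deduped = build_site_pool(seq, vocab, "random", np.random.default_rng(3), n_raw=40, dedupe_positions=True)
    assert deduped.total <= raw.total
    for c, v in deduped.positions.items():
        assert len(np.unique(v)) == len(v)


def test_null_calibration_reported_not_thresholded(vocab, rng, capsys):
    """On a genome whose 'native' sites were themselves drawn from the
    background model, few windows reach CC >= 4, and the fraction shrinks
    with more replicates (reported as a tendency)."""
    from glicluster.clusters import ClusterConfig, enumerate_windows, score_clusters
    from glicluster.genome import BindingSite, scan_codes
    from glicluster.synthetic import FixtureSpec, make_genome

    spec = FixtureSpec(seed=77, gc_segments={"c": [(60_000, 0.52)]}, scrub_decoys=False)
    genome, _ = make_genome(spec, vocab)
    codes = genome.codes("c")
    # 'native' = one flip replicate of the fixture
    null_seq = bg_flip_gc_at(codes, rng)
    starts, sense_codes, mss, plus = scan_codes(null_seq, vocab)
    sites = [
        BindingSite("c", int(s), int(s) + 9, "+" if p else "-", _seq.index_to_kmer(int(c), 9), float(m))
        for s, c, m, p in zip(starts, sense_codes, mss, plus)
    ]
    fractions = {}
    for n_rep in (5, 40):
        pool = build_site_pool(null_seq, vocab, "flip_gc_at", rng, n_raw=40, chrom="c")
        ens = reconstruct_backgrounds(pool, native_composition(sites, "c"), rng, n=n_rep)
        cfg = ClusterConfig()
        wins = enumerate_windows(sites, cfg)
        if not wins:
            pytest.skip("null fixture produced no candidate windows")
        score_clusters(wins, ens, cfg)
        fractions[n_rep] = sum(1 for w in wins if w.cc >= cfg.cc_min) / len(wins)
    print(f"null CC>=4 window fraction: {fractions}")
    assert fractions[40] <= fractions[5] + 0.05
    assert fractions[40] < 0.5


class TestRandomizerProperties:
    """Hypothesis property tests over arbitrary sequences and seeds."""

    dna = __import__("hypothesis").strategies.text(alphabet="ACGTN", min_size=0, max_size=200)
    seeds = __import__("hypothesis").strategies.integers(0, 2**31 - 1)

    from hypothesis import given, settings

    @given(dna, seeds)
    @settings(derandomize=True, max_examples=60)
    def test_flip_output_is_base_or_complement_everywhere(self, seq, seed):
        out = bg_flip_gc_at(seq, np.random.default_rng(seed))
        comp = dict(zip("ACGTN", "TGCAN"))
        assert len(out) == len(seq)
        assert all(o in (i, comp[i]) for o, i in zip(out, seq))

    @given(dna, seeds)
    @settings(derandomize=True, max_examples=60)
    def test_shuffle3mer_preserves_composition(self, seq, seed):
        out = bg_shuffle3mer(seq, np.random.default_rng(seed))
        assert Counter(out) == Counter(seq)

    @given(dna, seeds)
    @settings(derandomize=True, max_examples=60)
    def test_random_preserves_length_and_n_layout(self, seq, seed):
        out = bg_random(seq, np.random.default_rng(seed))
        assert len(out) == len(seq)
        assert [c == "N" for c in out] == [c == "N" for c in seq]
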