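import numpy as np
import pytest

from insulome import insulation, synthetic
from insulome.insulation import ContactMatrix
from insulome.io import ContactRecord, GenomicInterval, SignalTrack,  \
    ValidationError


def brute_force_profile(counts, w, psi):
    """Literal double loop over all bin pairs: the insulation oracle."""
    B = counts.shape[0]
    scores = np.full(B, np.nan)
    for i in range(B):
        if i - w < 0 or i + w >= B:
            continue
        up = sum(counts[j, i] for j in range(B) if 1 <= i - j <= w)
        down = sum(counts[i, j] for j in range(B) if 1 <= j - i <= w)
        scores[i] = np.log2((up + psi) / (down + psi))
    return scores


def symmetric_random(rng, B, scale=20):
    m = rng.integers(0, scale, size=(B, B)).astype(float)
    return np.triu(m) + np.triu(m, 1).T


class TestBinContacts:
    def test_same_bin_and_symmetry(self):
        recs = [ContactRecord("chr1", 0, 100, "chr1", 200, 300),
                ContactRecord("chr1", 0, 100, "chr1", 80_500, 80_600),
                ContactRecord("chr1", 80_500, 80_600, "chr1", 0, 100)]
        mats = insulation.bin_contacts(recs, 40_000, {"chr1": 200_000})
        m = mats["chr1"].counts
        assert m[0, 0] == 1
        assert m[0, 2] == 2 == m[2, 0]

    def test_interchromosomal_excluded_with_warning(self):
        recs = [ContactRecord("chr1", 0, 100, "chr2", 0, 100)]
        with pytest.warns(UserWarning, match="interchromosomal"):
            mats = insulation.bin_contacts(recs, 40_000,
                                           {"chr1": 80_000, "chr2": 80_000})
        assert mats["chr1"].counts.sum() == 0

    def test_anchor_beyond_chrom_rejected(self):
        recs = [ContactRecord("chr1", 0, 100, "chr1", 90_000, 90_100)]
        with pytest.raises(ValidationError):
            insulation.bin_contacts(recs, 40_000, {"chr1": 80_000})


class TestInsulationProfile:
    def test_uniform_matrix_scores_zero(self):
        mat = ContactMatrix("chr1", 40_000, np.full((11, 11), 7.0))
        prof = insulation.insulation_profile(mat, window_bp=120_000)
        w = 3
        defined = prof.scores[w:-w]
        np.testing.assert_allclose(defined, 0.0, atol=1e-12)
        assert np.isnan(prof.scores[:w]).all()

    def test_log2_ratio_worked_example(self):
        # bin 1 of a 3-bin matrix, w=1: up = 8, down = 2, psi = 0 -> log2(4)
        counts = np.array([[0, 8, 0], [8, 0, 2], [0, 2, 0]], dtype=float)
        mat = ContactMatrix("chr1", 40_000, counts)
        prof = insulation.insulation_profile(mat, window_bp=40_000,
                                             pseudocount=0.0)
        assert prof.scores[1] == pytest.approx(2.0)

    @pytest.mark.parametrize("B,w", [(7, 1), (10, 2), (10, 4)])
    def test_equals_brute_force_oracle(self, B, w):
        rng = np.random.default_rng(B * 10 + w)
        counts = symmetric_random(rng, B)
        mat = ContactMatrix("chr1", 40_000, counts)
        prof = insulation.insulation_profile(mat, window_bp=w * 40_000,
                                             pseudocount=1.0)
        expected = brute_force_profile(counts, w, 1.0)
        np.testing.assert_allclose(prof.scores, expected, equal_nan=True)

    def test_mirror_antisymmetry(self):
        """Mirroring the matrix left-right negates every defined score."""
        rng = np.random.default_rng(5)
        counts = symmetric_random(rng, 15)
        mat = ContactMatrix("chr1", 40_000, counts)
        mirrored = ContactMatrix("chr1", 40_000, counts[::-1, ::-1])
        a = insulation.insulation_profile(mat, window_bp=120_000).scores
        b = insulation.insulation_profile(mirrored, window_bp=120_000).scores
        np.testing.assert_allclose(a, -b[::-1], equal_nan=True)

    def test_constant_shift_shrinks_scores(self):
        """Adding c > 0 everywhere moves scores toward 0, never across sign."""
        rng = np.random.default_rng(6)
        counts = symmetric_random(rng, 12) + 1.0
        base = insulation.insulation_profile(
            ContactMatrix("chr1", 40_000, counts), window_bp=80_000,
            pseudocount=0.0).scores
        shifted = insulation.insulation_profile(
            ContactMatrix("chr1", 40_000, counts + 50.0), window_bp=80_000,
            pseudocount=0.0).scores
        ok = ~np.isnan(base)
        assert np.all(np.abs(shifted[ok]) <= np.abs(base[ok]) + 1e-12)
        assert np.all(np.sign(shifted[ok]) * np.sign(base[ok]) >= 0)

    def test_too_small_matrix_all_undefined(self):
        mat = ContactMatrix("chr1", 40_000, np.ones((5, 5)))
        with pytest.warns(UserWarning):
            prof = insulation.insulation_profile(mat, window_bp=400_000)
        assert np.isnan(prof.scores).all()

    def test_planted_boundary_is_argmax(self):
        tb = synthetic.synth_contact_map(11, 40, boundaries=[20],
                                         p_intra=1.0, p_inter=0.2,
                                         base_count=200)
        mats = insulation.bin_contacts(tb.artifact, 40_000,
                                       tb.truth["chrom_sizes"])
        prof = insulation.insulation_profile(mats["chr1"])
        # the score is extreme on a flank of the boundary ...
        assert int(np.nanargmax(np.abs(prof.scores))) in (19, 20)
        # ... and the sign-aware caller resolves the boundary bin itself
        assert insulation.call_boundary(prof) == 20


class TestLoopRatio:
    def _matrix(self, B=12):
        return np.zeros((B, B))

    def test_all_inside(self):
        counts = self._matrix()
        counts[4, 5] = counts[5, 4] = 10
        mat = ContactMatrix("chr1", 40_000, counts)
        left = GenomicInterval("chr1", 2 * 40_000, 3 * 40_000)
        right = GenomicInterval("chr1", 8 * 40_000, 9 * 40_000)
        r = insulation.loop_within_across_ratio(mat, left, right,
                                                pseudocount=1.0)
        assert r == pytest.approx(11.0)

    def test_balanced_mass_near_one(self):
        counts = self._matrix()
        counts[4, 5] = counts[5, 4] = 10   # inside
        counts[4, 10] = counts[10, 4] = 10  # crossing
        mat = ContactMatrix("chr1", 40_000, counts)
        left = GenomicInterval("chr1", 80_000, 120_000)
        right = GenomicInterval("chr1", 320_000, 360_000)
        r = insulation.loop_within_across_ratio(mat, left, right)
        assert r == pytest.approx(1.0)

    def test_zero_width_loop_rejected(self):
        mat = ContactMatrix("chr1", 40_000, self._matrix())
        left = GenomicInterval("chr1", 80_000, 120_000)
        with pytest.raises(ValidationError):
            insulation.loop_within_across_ratio(mat, left, left)

    def test_block_match_beats_straddle(self):
        """A loop matching a planted block retains more contact mass than
        one straddling the boundary."""
        tb = synthetic.synth_contact_map(3, 30, boundaries=[15],
                                         p_intra=1.0, p_inter=0.1,
                                         base_count=300)
        mats = insulation.bin_contacts(tb.artifact, 40_000,
                                       tb.truth["chrom_sizes"])
        mat = mats["chr1"]

        def loop(a, b):
            return (GenomicInterval("chr1", a * 40_000, (a + 1) * 40_000),
                    GenomicInterval("chr1", b * 40_000, (b + 1) * 40_000))

        matched = insulation.loop_within_across_ratio(mat, *loop(2, 13))
        straddling = insulation.loop_within_across_ratio(mat, *loop(9, 20))
        assert matched > straddling


class TestRanking:
    def test_descending_scores_split_into_pairs(self):
        anchors = [GenomicInterval("chr1", i * 40_000, i * 40_000 + 100)
                   for i in range(10)]
        scores = np.arange(10, 0, -1, dtype=float)
        g = insulation.group_by_score(anchors, scores, k=5)
        assert list(g.group) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_ties_keep_input_order_and_near_equal_sizes(self):
        anchors = [GenomicInterval("chr1", i, i + 10) for i in range(7)]
        g = insulation.group_by_score(anchors, np.ones(7), k=5)
        sizes = np.bincount(g.group)[1:]
        assert sizes.max() - sizes.min() <= 1
        assert list(g.group) == sorted(g.group)

    def test_rank_from_profile_drops_undefined(self):
        counts = np.ones((11, 11))
        mat = ContactMatrix("chr1", 40_000, counts)
        prof = insulation.insulation_profile(mat, window_bp=120_000)
        anchors = [GenomicInterval("chr1", 0, 100),           # undefined bin
                   GenomicInterval("chr1", 200_000, 200_100)]
        with pytest.warns(UserWarning, match="dropped"):
            g = insulation.rank_anchors(anchors, prof, k=1)
        assert len(g.anchors) == 1 and g.n_dropped == 1

    def test_recovered_groups_track_truth_ranks(self):
        tb = synthetic.synth_anchor_cohort(8, 200, coupling_slope=1.0,
                                           noise_sd=0.0)
        anchors, _ = tb.artifact
        g = insulation.group_by_score(anchors, tb.truth["u"], k=5)
        # group number must be a non-increasing function of u
        order = np.argsort(-tb.truth["u"])
        assert list(g.group[order]) == sorted(g.group)


class TestGroupSummary:
    def test_constant_track_equal_means(self):
        anchors = [GenomicInterval("chr1", i * 1000, i * 1000 + 100)
                   for i in range(10)]
        g = insulation.group_by_score(anchors, np.arange(10.0), k=5)
        track = SignalTrack([("chr1", 0, 100_000, 3.0)])
        summary = insulation.group_signal_summary(g, track)
        assert all(summary[k]["mean"] == pytest.approx(3.0) for k in summary)

    def test_single_anchor_groups(self):
        anchors = [GenomicInterval("chr1", 0, 100),
                   GenomicInterval("chr1", 1000, 1100)]
        g = insulation.group_by_score(anchors, np.array([2.0, 1.0]), k=2)
        track = SignalTrack([("chr1", 0, 100, 5.0), ("chr1", 1000, 1100, 9.0)])
        summary = insulation.group_signal_summary(g, track)
        assert summary[1]["mean"] == pytest.approx(5.0)
        assert summary[2]["mean"] == pytest.approx(9.0)

    def test_coupled_cohort_means_decrease(self):
        tb = synthetic.synth_anchor_cohort(9, 500, coupling_slope=1.0,
                                           noise_sd=0.2)
        anchors, track = tb.artifact
        g = insulation.group_by_score(anchors, tb.truth["u"], k=5)
        summary = insulation.group_signal_summary(g, track)
        means = [summary[k]["mean"] for k in range(1, 6)]
        assert all(a >= b for a, b in zip(means, means[1:]))
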