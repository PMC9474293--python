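import numpy as np
import pytest

from insulome import io, synthetic
from insulome.io import ValidationError


class TestDeterminism:
    def test_same_seed_identical_artifacts(self, ctcf_pfm):
        a = synthetic.synth_genome_with_arrays(7, 1, 10_000, ctcf_pfm, [2], 5)
        b = synthetic.synth_genome_with_arrays(7, 1, 10_000, ctcf_pfm, [2], 5)
        assert a.artifact == b.artifact
        c = synthetic.synth_contact_map(9, 20, boundaries=[10])
        d = synthetic.synth_contact_map(9, 20, boundaries=[10])
        assert c.artifact == d.artifact

    def test_different_seeds_differ(self, ctcf_pfm):
        a = synthetic.synth_genome_with_arrays(1, 1, 10_000, ctcf_pfm, [1], 5)
        b = synthetic.synth_genome_with_arrays(2, 1, 10_000, ctcf_pfm, [1], 5)
        assert a.artifact != b.artifact

    def test_streams_are_independent(self):
        """Drawing from one generator does not perturb another's output."""
        before = synthetic.synth_frap_trace(11, noise_sd=0.02).artifact[1]
        synthetic.synth_contact_map(11, 15)   # interleaved draw, same seed
        after = synthetic.synth_frap_trace(11, noise_sd=0.02).artifact[1]
        np.testing.assert_array_equal(before, after)


class TestGenomeArrays:
    def test_single_motif_sites_count(self, ctcf_pfm):
        tb = synthetic.synth_genome_with_arrays(0, 2, 20_000, ctcf_pfm,
                                                [1], 10)
        assert len(tb.truth["hits"]) == 10
        assert len(tb.truth["sites"]) == 10

    def test_array_sites_contain_k_instances(self, ctcf_pfm):
        tb = synthetic.synth_genome_with_arrays(0, 1, 50_000, ctcf_pfm,
                                                [3], 8)
        for site in tb.truth["sites"]:
            inside = [h for h in tb.truth["hits"]
                      if h.chrom == site.chrom and site.start <= h.start
                      and h.end <= site.end]
            assert len(inside) == 3

    def test_capacity_error_when_genome_too_small(self, ctcf_pfm):
        with pytest.raises(synthetic.CapacityError):
            synthetic.synth_genome_with_arrays(0, 1, 600, ctcf_pfm, [2], 50)

    def test_planted_sequences_match_truth_strand(self, ctcf_pfm):
        tb = synthetic.synth_genome_with_arrays(3, 1, 20_000, ctcf_pfm, [1], 5)
        genome = tb.artifact
        probs = ctcf_pfm.counts / ctcf_pfm.counts.sum(axis=1, keepdims=True)
        consensus_cols = probs.max(axis=1)
        for h in tb.truth["hits"]:
            seq = genome[h.chrom][h.start:h.end]
            # planted instances must look motif-like: strong-consensus
            # positions (p > 0.9) agree on the recorded strand
            from insulome.motifs import reverse_complement
            oriented = seq if h.strand == "+" else reverse_complement(seq)
            strong = [i for i, p in enumerate(consensus_cols) if p > 0.9]
            agree = sum(oriented[i] == "ACGT"[probs[i].argmax()]
                        for i in strong)
            assert agree >= len(strong) - 1


class TestContactMap:
    def test_no_boundaries_expectation_depends_on_distance_only(self):
        tb = synthetic.synth_contact_map(0, 20, boundaries=[])
        exp = tb.truth["expected"]
        for d in (1, 3, 7):
            diag = np.diagonal(exp, offset=d)
            np.testing.assert_allclose(diag, diag[0])

    def test_equal_probabilities_match_boundaryless_expectation(self):
        a = synthetic.synth_contact_map(1, 20, boundaries=[10], p_intra=0.5,
                                        p_inter=0.5)
        b = synthetic.synth_contact_map(1, 20, boundaries=[], p_intra=0.5,
                                        p_inter=0.5)
        np.testing.assert_allclose(a.truth["expected"], b.truth["expected"])

    def test_validation(self):
        with pytest.raises(ValidationError):
            synthetic.synth_contact_map(0, 2)
        with pytest.raises(ValidationError):
            synthetic.synth_contact_map(0, 10, p_intra=0.1, p_inter=0.5)
        with pytest.raises(ValidationError):
            synthetic.synth_contact_map(0, 10, boundaries=[0])


class TestAnchorCohort:
    def test_zero_slope_gives_unit_signal_without_noise(self):
        tb = synthetic.synth_anchor_cohort(0, 50, coupling_slope=0.0,
                                           noise_sd=0.0)
        _, track = tb.artifact
        values = np.array([v for _, _, _, v in track])
        np.testing.assert_allclose(values, 1.0)

    def test_positive_slope_monotone_without_noise(self):
        tb = synthetic.synth_anchor_cohort(1, 100, coupling_slope=1.0,
                                           noise_sd=0.0)
        u = tb.truth["u"]
        s = tb.truth["signal"]
        order = np.argsort(u)
        assert np.all(np.diff(s[order]) > 0)

    def test_spearman_correlation_at_moderate_noise(self):
        from scipy.stats import spearmanr

        tb = synthetic.synth_anchor_cohort(2, 500, coupling_slope=1.0,
                                           noise_sd=0.2)
        rho = spearmanr(tb.truth["u"], tb.truth["signal"]).statistic
        assert rho > 0.8

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.synth_anchor_cohort(0, 50, 1.0, -0.1)


class TestVariantCatalog:
    def test_pure_spectrum(self):
        tb = synthetic.synth_variant_catalog(0, {"CTCF": 727}, 100,
                                             {"R>H": 1.0})
        assert all(h.startswith("p.R") and h.endswith("H")
                   for _, h, _ in tb.artifact)

    def test_unknown_hotspot_gene_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.synth_variant_catalog(0, {"CTCF": 727}, 10,
                                            {"R>H": 1.0},
                                            hotspot=("TP53", 175, 10))

    def test_bad_spectrum_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.synth_variant_catalog(0, {"CTCF": 727}, 10,
                                            {"R>H": 0.7})

    def test_tsv_round_trip(self, tmp_path):
        tb = synthetic.synth_variant_catalog(0, {"CTCF": 727}, 20,
                                             {"R>H": 0.5, "A>T": 0.5})
        p = tmp_path / "v.tsv"
        synthetic.write_variant_tsv(tb.artifact, p)
        from insulome import mutations
        records, rejected = mutations.read_variants(p)
        assert len(records) == 20 and len(rejected) == 0


class TestFrapAndKymo:
    def test_frap_plateau_closed_form(self):
        tb = synthetic.synth_frap_trace(0, Ipre=1.0, Io=0.2, Mf=0.8,
                                        tau_s=2.0, noise_sd=0.0,
                                        n_points=200)
        t, y = tb.artifact
        assert y[-1] == pytest.approx(0.2 + 0.8 * 0.8, abs=1e-6)
        assert tb.truth["Ie"] == pytest.approx(0.84)

    def test_frap_immobile_flat(self):
        tb = synthetic.synth_frap_trace(1, Mf=0.0, Io=0.3, noise_sd=0.0)
        t, y = tb.artifact
        np.testing.assert_allclose(y[t >= 0], 0.3, atol=1e-12)

    def test_kymo_zero_rate_constant_end(self):
        tb = synthetic.synth_kymograph(0, rate_nm_s=0.0, noise_sd=0.0)
        assert np.ptp(tb.truth["end_px"]) == 0

    def test_kymo_planted_retreat_per_frame(self):
        tb = synthetic.synth_kymograph(0, rate_nm_s=871.0, pixel_nm=100.0,
                                       dt_s=1.0, noise_sd=0.0)
        steps = -np.diff(tb.truth["end_px"])
        np.testing.assert_allclose(steps, 8.71)

    def test_kymo_rate_too_high_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.synth_kymograph(0, n_frames=100, n_pix=50,
                                      rate_nm_s=871.0)


class TestNucleusStack:
    def test_focus_margins_and_separation(self):
        tb = synthetic.synth_nucleus_stack(0, n_foci=4)
        sigma = tb.truth["sigma_vox"]
        cents = np.array(tb.truth["centroids"])
        shape = np.array(tb.artifact.shape)
        assert np.all(cents >= 2 * sigma - 1e-9)
        assert np.all(cents <= shape - 2 * sigma + 1e-9)
        for i in range(len(cents)):
            for j in range(i + 1, len(cents)):
                assert np.linalg.norm(cents[i] - cents[j]) >= 4 * sigma

    def test_overcrowding_raises_capacity_error(self):
        with pytest.raises(synthetic.CapacityError):
            synthetic.synth_nucleus_stack(0, shape=(8, 16, 16), n_foci=40)

    def test_poisson_noise_model(self):
        tb = synthetic.synth_nucleus_stack(1, n_foci=1, noise_model="poisson")
        assert np.all(tb.artifact.data == tb.artifact.data.astype(int))
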