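"""Generator contracts: expected-count laws, determinism, planted structure."""

import numpy as np
import pytest

from tadbound.synthetic import (
    BoundarySpec,
    DecayModel,
    FishCondition,
    TadLayout,
    evenly_spaced_layout,
    expected_matrix,
    gen_contact_matrix,
    gen_depletion_pair,
    gen_expression,
    gen_fish_sample,
    gen_peaks,
    gen_spikein_pair,
    gene_id,
    render_stack,
    spot_table,
)


class TestDecayAndExpectedMatrix:
    def test_pure_decay_formula(self):
        layout = TadLayout(chrom="c", bin_size=1000, n_bins=30, boundaries=())
        exp = expected_matrix(layout, DecayModel(amplitude=100.0, alpha=1.0,
                                                 diagonal_level=2.0))
        for d in (1, 2, 5, 10):
            assert exp.counts[0, d] == pytest.approx(100.0 / d)
        assert exp.counts[3, 3] == pytest.approx(200.0)

    def test_single_boundary_halves_cross_counts(self):
        layout = TadLayout(chrom="c", bin_size=1000, n_bins=40,
                           boundaries=(BoundarySpec(bin=20, strength=0.5),))
        exp = expected_matrix(layout, DecayModel(amplitude=100.0, alpha=1.0))
        d = 6
        intra = exp.counts[5, 5 + d]       # both sides left of the boundary
        cross = exp.counts[17, 17 + d]     # 17 < 20 <= 23: crosses once
        assert cross == pytest.approx(0.5 * intra)

    def test_attenuation_composes_across_boundaries(self):
        layout = TadLayout(chrom="c", bin_size=1000, n_bins=40,
                           boundaries=(BoundarySpec(bin=15, strength=0.5),
                                       BoundarySpec(bin=20, strength=0.2)))
        exp = expected_matrix(layout, DecayModel(amplitude=100.0, alpha=1.0))
        d = 10
        assert exp.counts[12, 22] == pytest.approx(100.0 / d * 0.5 * 0.8)

    def test_expected_counts_non_increasing_with_distance(self):
        layout = TadLayout(chrom="c", bin_size=1000, n_bins=50)
        exp = expected_matrix(layout, DecayModel())
        row = exp.counts[0, 1:]
        assert np.all(np.diff(row) <= 1e-9)

    def test_layout_validation(self):
        with pytest.raises(ValueError):
            TadLayout(n_bins=3)
        with pytest.raises(ValueError):
            TadLayout(n_bins=50, boundaries=(BoundarySpec(bin=0, strength=0.5),))
        with pytest.raises(ValueError):
            TadLayout(n_bins=50, boundaries=(BoundarySpec(bin=10, strength=0.5),
                                             BoundarySpec(bin=10, strength=0.5)))
        with pytest.raises(ValueError):
            BoundarySpec(bin=5, strength=1.0)

    def test_tads_tile_the_chromosome(self):
        layout = evenly_spaced_layout(n_boundaries=7, n_bins=200)
        tads = layout.tad_bins
        assert tads[0][0] == 0 and tads[-1][1] == 200
        assert all(a[1] == b[0] for a, b in zip(tads, tads[1:]))


class TestContactMatrixGeneration:
    def test_seed_determinism(self):
        layout = evenly_spaced_layout(n_boundaries=3, n_bins=100)
        a = gen_contact_matrix(layout, DecayModel(), seed=7)
        b = gen_contact_matrix(layout, DecayModel(), seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = gen_contact_matrix(layout, DecayModel(), seed=8)
        assert not np.array_equal(a.counts, c.counts)

    def test_matrix_is_one_draw_per_unordered_pair(self):
        layout = TadLayout(chrom="c", bin_size=1000, n_bins=20)
        m = gen_contact_matrix(layout, DecayModel(), seed=1)
        np.testing.assert_array_equal(m.counts, m.counts.T)

    def test_empirical_mean_matches_expected_law(self):
        layout = TadLayout(chrom="c", bin_size=1000, n_bins=30,
                           boundaries=(BoundarySpec(bin=15, strength=0.6),))
        decay = DecayModel(amplitude=50.0, alpha=0.8)
        lam = expected_matrix(layout, decay).counts
        draws = np.stack([gen_contact_matrix(layout, decay, seed=s).counts
                          for s in range(100)])
        mean = draws.mean(axis=0)
        se = np.sqrt(lam / 100)
        checks = [(0, 1), (5, 10), (10, 20), (14, 16), (3, 3)]
        for i, j in checks:
            assert abs(mean[i, j] - lam[i, j]) <= 3 * se[i, j] + 1e-9

    def test_depletion_pair_weakening_limit(self):
        layout = TadLayout(chrom="c", bin_size=1000, n_bins=40,
                           boundaries=(BoundarySpec(bin=20, strength=0.7,
                                                    weakening=1.0),))
        dep = expected_matrix(layout, DecayModel(), depleted=True)
        flat = expected_matrix(TadLayout(chrom="c", bin_size=1000, n_bins=40),
                               DecayModel())
        np.testing.assert_allclose(dep.counts, flat.counts)

    def test_exchangeable_pair_warns(self):
        layout = evenly_spaced_layout(n_boundaries=2, n_bins=100)
        with pytest.warns(UserWarning, match="exchangeable"):
            gen_depletion_pair(layout, DecayModel(), seed=0)

    def test_pair_is_deterministic_given_seed(self):
        layout = evenly_spaced_layout(n_boundaries=2, n_bins=100,
                                      weakened={0: 0.5})
        wt1, dep1 = gen_depletion_pair(layout, DecayModel(), seed=3)
        wt2, dep2 = gen_depletion_pair(layout, DecayModel(), seed=3)
        np.testing.assert_array_equal(wt1.counts, wt2.counts)
        np.testing.assert_array_equal(dep1.counts, dep2.counts)
        assert not np.array_equal(wt1.counts, dep1.counts)


class TestPeakGeneration:
    def test_no_background_single_factor_peaks_sit_at_boundaries(self):
        layout = evenly_spaced_layout(n_boundaries=4, n_bins=400)
        assignment = {int(b): {"CTCF"} for b in layout.boundary_bins}
        sets = gen_peaks(layout, assignment, jitter_sd=0.0, n_background=0, seed=0)
        assert sorted(sets["CTCF"].summit_positions().tolist()) == \
            sorted(layout.boundary_positions.tolist())
        for factor in ("BEAF-32", "Su(Hw)", "CP190"):
            assert len(sets[factor]) == 0

    def test_determinism_and_background_count(self):
        layout = evenly_spaced_layout(n_boundaries=3, n_bins=300)
        assignment = {int(b): {"CTCF", "CP190"} for b in layout.boundary_bins}
        a = gen_peaks(layout, assignment, jitter_sd=500, n_background=10, seed=5)
        b = gen_peaks(layout, assignment, jitter_sd=500, n_background=10, seed=5)
        for f in a:
            assert [p.summit_pos for p in a[f]] == [p.summit_pos for p in b[f]]
        assert len(a["CTCF"]) == 3 + 10
        assert len(a["Su(Hw)"]) == 10

    def test_invalid_inputs_rejected(self):
        layout = evenly_spaced_layout(n_boundaries=2, n_bins=100)
        good = {int(layout.boundary_bins[0]): {"CTCF"}}
        with pytest.raises(ValueError, match="jitter"):
            gen_peaks(layout, good, jitter_sd=-1.0)
        with pytest.raises(ValueError, match="unknown factors"):
            gen_peaks(layout, {int(layout.boundary_bins[0]): {"NotAFactor"}})
        with pytest.raises(ValueError, match="boundary bin"):
            gen_peaks(layout, {7: {"CTCF"}})


class TestExpressionGeneration:
    def test_noiseless_planted_effect_is_exact(self):
        layout = evenly_spaced_layout(n_boundaries=4, n_bins=400)
        b = int(layout.boundary_bins[1])
        genes = gen_expression(layout, genes_per_tad=2,
                               hijack_plan=[(gene_id(2, 0), b, 2.0)],
                               noise_sd=0.0, maternal_fraction=0.0, seed=0)
        planted = genes.loc[genes["gene_id"] == gene_id(2, 0)]
        assert planted["log2fc"].iloc[0] == 2.0
        assert (genes.loc[genes["gene_id"] != gene_id(2, 0), "log2fc"] == 0).all()

    def test_all_maternal_empties_the_zygotic_set(self):
        layout = evenly_spaced_layout(n_boundaries=3, n_bins=300)
        genes = gen_expression(layout, maternal_fraction=1.0, seed=0)
        assert genes["maternal"].all()

    def test_non_adjacent_hijack_gene_rejected(self):
        layout = evenly_spaced_layout(n_boundaries=4, n_bins=400)
        b = int(layout.boundary_bins[0])  # flanks are TADs 0 and 1
        with pytest.raises(ValueError, match="adjacent"):
            gen_expression(layout, hijack_plan=[(gene_id(3, 0), b, 1.0)], seed=0)

    def test_tss_lies_within_the_gene_tad(self):
        layout = evenly_spaced_layout(n_boundaries=5, n_bins=500)
        genes = gen_expression(layout, genes_per_tad=3, seed=2)
        for _, g in genes.iterrows():
            t = int(g["gene_id"][1:4])
            a, b = layout.tads[t]
            assert a <= g["tss"] < b

    def test_null_pvalues_are_uniformish_with_noise(self):
        layout = evenly_spaced_layout(n_boundaries=3, n_bins=300)
        genes = gen_expression(layout, genes_per_tad=60, noise_sd=0.3,
                               maternal_fraction=0.0, seed=3)
        p = genes["pvalue"]
        assert 0.35 < p.mean() < 0.65  # uniform mean is 0.5


class TestFishGeneration:
    def test_degenerate_contact_condition(self):
        cond = FishCondition(contact_prob=1.0, mu_contact=100.0,
                             sigma_contact=1e-6, mu_open=700.0, sigma_open=100.0)
        sample = gen_fish_sample(cond, 50, seed=0)
        np.testing.assert_allclose(sample.distances, 100.0, atol=1e-4)

    def test_mixture_fraction_matches_analytic_cdf(self):
        cond = FishCondition(contact_prob=0.3)
        sample = gen_fish_sample(cond, 1000, seed=1)
        frac = np.mean(sample.distances < 250.0)
        assert abs(frac - cond.fraction_below(250.0)) <= 0.03

    def test_validation(self):
        with pytest.raises(ValueError):
            FishCondition(contact_prob=1.2)
        with pytest.raises(ValueError):
            FishCondition(mu_contact=700.0, mu_open=600.0)
        cond = FishCondition()
        with pytest.raises(ValueError):
            gen_fish_sample(cond, 0)

    def test_render_stack_is_deterministic(self):
        spots = spot_table(np.array([[2000.0, 3000.0, 3000.0]]), ["ch0"])
        a = render_stack(spots, shape=(12, 40, 40), seed=9)
        b = render_stack(spots, shape=(12, 40, 40), seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_render_rejects_bad_voxels(self):
        spots = spot_table(np.array([[0.0, 0.0, 0.0]]), ["ch0"])
        with pytest.raises(ValueError):
            render_stack(spots, voxel_size_nm=(0.0, 60.0, 60.0))


class TestSpikeinGeneration:
    def test_pair_is_deterministic_and_depth_scales_spike(self):
        layout = evenly_spaced_layout(n_boundaries=2, n_bins=100)
        assignment = {int(b): {"CP190"} for b in layout.boundary_bins}
        peaks = gen_peaks(layout, assignment, jitter_sd=0, n_background=0,
                          seed=0)["CP190"]
        t1 = gen_spikein_pair(peaks, "chrS", layout.chrom_length, seed=4)
        t2 = gen_spikein_pair(peaks, "chrS", layout.chrom_length, seed=4)
        np.testing.assert_array_equal(t1["wt"].values, t2["wt"].values)
        assert t1["spike_wt"] == t2["spike_wt"]
        deep = gen_spikein_pair(peaks, "chrS", layout.chrom_length,
                                depth_dep=2.0, seed=4)
        assert deep["spike_dep"] > 1.5 * deep["spike_wt"]
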