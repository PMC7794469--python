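import numpy as np
import pytest

import chromoseed as cs
from chromoseed.chain_model import Conformation, Ensemble, PhysicalParams
from chromoseed.structure_analysis import (
    boundary_probability,
    boundary_strength,
    call_boundaries,
    call_tad_like,
    cluster_conformations,
    compactness,
    distance_map,
    multibody_fraction,
    peak_enrichment,
    virtual_4c,
)


def _rod(n, spacing=25.0):
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return coords


def _two_globules(n=40, gap=300.0, rng_seed=0):
    """Two tight clusters of n/2 beads each, far apart (distances within a
    cluster ~ tens of nm, across ~ gap)."""
    rng = np.random.default_rng(rng_seed)
    half = n // 2
    a = rng.normal(scale=15.0, size=(half, 3))
    b = rng.normal(scale=15.0, size=(n - half, 3)) + [gap, 0.0, 0.0]
    return np.vstack([a, b])


class TestDistanceMap:
    def test_two_beads(self):
        d = distance_map(Conformation(coords=[[0, 0, 0], [25, 0, 0]]))
        np.testing.assert_allclose(d, [[0, 25], [25, 0]])

    def test_collinear_chain(self):
        d = distance_map(Conformation(coords=_rod(3)))
        assert d[0, 2] == pytest.approx(50.0)

    def test_metric_properties(self):
        rng = np.random.default_rng(4)
        d = distance_map(Conformation(coords=rng.normal(size=(12, 3)) * 50))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for i in range(12):
            for j in range(12):
                assert (d[i] <= d[i, j] + d[j] + 1e-9).all()


class TestCompactness:
    def test_two_beads(self):
        st = compactness(Conformation(coords=[[0, 0, 0], [30, 0, 0]]))
        assert st.rg == pytest.approx(15.0)
        assert st.end_to_end == pytest.approx(30.0)

    def test_coincident_beads(self):
        st = compactness(Conformation(coords=np.zeros((5, 3))))
        assert st.rg == 0.0

    def test_ring_radius_closed_form(self):
        m, R = 24, 80.0
        theta = 2 * np.pi * np.arange(m) / m
        ring = np.stack([R * np.cos(theta), R * np.sin(theta),
                         np.zeros(m)], axis=1)
        st = compactness(Conformation(coords=ring))
        assert st.rg == pytest.approx(R)


class TestClustering:
    def test_duplicated_conformations_split_perfectly(self, sphere_params):
        rng = np.random.default_rng(1)
        compact = rng.normal(scale=20.0, size=(15, 3))
        extended = _rod(15, spacing=40.0)
        confs = [Conformation(coords=c)
                 for c in (compact, compact + 0.1, extended, extended + 0.1)]
        ens = Ensemble(conformations=confs, params=sphere_params)
        res = cluster_conformations(ens, k=2)
        assert res.assignments[0] == res.assignments[1]
        assert res.assignments[2] == res.assignments[3]
        assert res.assignments[0] != res.assignments[2]
        # cluster 1 is the compact one
        assert res.assignments[0] == 1
        assert res.mean_rg[0] < res.mean_rg[1]

    def test_proportions_sum_and_map_recombination(self, sphere_params):
        ens, _ = cs.generate_labeled_conformations("mixture", n=60, seed=3,
                                                   n_beads=30)
        res = cluster_conformations(ens, k=3)
        assert res.proportions.sum() == pytest.approx(1.0)
        full = cs.contact_probability(ens).p_null
        recombined = sum(p * m for p, m in zip(res.proportions,
                                               res.contact_maps))
        iu, ju = np.triu_indices(30, 1)
        np.testing.assert_allclose(recombined[iu, ju], full[iu, ju],
                                   atol=1e-12)

    def test_k_larger_than_ensemble_rejected(self, sphere_params):
        ens = Ensemble(conformations=[Conformation(coords=_rod(5))],
                       params=sphere_params)
        with pytest.raises(ValueError):
            cluster_conformations(ens, k=2)


class TestBoundaryStrength:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(30, 3)) * 60
        dmap = distance_map(Conformation(coords=pts))
        w = 5
        s = boundary_strength(dmap, w=w)
        for i in range(w, 30 - w + 1):
            inter = np.mean([dmap[a, b] for a in range(i - w, i)
                             for b in range(i, i + w)])
            intra_l = np.mean([dmap[a, b] for a in range(i - w, i)
                               for b in range(i - w, i) if a < b])
            intra_r = np.mean([dmap[a, b] for a in range(i, i + w)
                               for b in range(i, i + w) if a < b])
            expected = inter / (0.5 * (intra_l + intra_r))
            assert s[i] == pytest.approx(expected)

    def test_two_distant_globules_peak_at_junction(self):
        dmap = distance_map(Conformation(coords=_two_globules(40)))
        s = boundary_strength(dmap, w=10)
        assert s[20] > 2.2
        assert s[20] == s.max()

    def test_rod_strength_is_flat_near_three(self):
        dmap = distance_map(Conformation(coords=_rod(40)))
        s = boundary_strength(dmap, w=10)
        interior = s[10:31]
        assert np.allclose(interior, interior[0], rtol=1e-9)
        assert 2.2 < interior[0] < 3.2

    def test_single_globule_no_interior_peak(self):
        rng = np.random.default_rng(9)
        dmap = distance_map(
            Conformation(coords=rng.normal(scale=20.0, size=(40, 3))))
        s = boundary_strength(dmap, w=10)
        assert s[10:31].max() < 2.2

    def test_ends_padded_with_one(self):
        dmap = distance_map(Conformation(coords=_rod(30)))
        s = boundary_strength(dmap, w=10)
        assert (s[:10] == 1.0).all() and (s[-9:] == 1.0).all()


class TestCallBoundaries:
    def test_flat_curve_no_boundaries(self):
        assert call_boundaries(np.ones(50), 2.2, 5) == []

    def test_single_spike(self):
        s = np.ones(100)
        s[50] = 3.0
        assert call_boundaries(s, 2.2, 10) == [50]

    def test_close_spikes_keep_taller(self):
        s = np.ones(40)
        s[20] = 3.0
        s[23] = 2.8
        assert call_boundaries(s, 2.2, min_sep=5) == [20]

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            call_boundaries(np.ones(10), 0.5, 2)


class TestCallTadLike:
    def test_two_globules_give_two_domains(self):
        dmap = distance_map(Conformation(coords=_two_globules(40)))
        s = boundary_strength(dmap, w=10)
        b = call_boundaries(s, 2.2, 10)
        calls = call_tad_like(dmap, b)
        assert calls.n_domains == 2
        assert all(q < 0.05 for q in calls.q_values)

    def test_no_boundaries_no_domains(self):
        dmap = distance_map(Conformation(coords=_rod(30)))
        assert call_tad_like(dmap, []).n_domains == 0

    def test_rod_boundaries_not_significant(self):
        """A featureless rod has uniform decay-normalized distances, so an
        arbitrary candidate boundary yields no significant domain."""
        dmap = distance_map(Conformation(coords=_rod(40)))
        calls = call_tad_like(dmap, [20])
        assert calls.n_domains == 0

    def test_short_intervals_skipped(self):
        dmap = distance_map(Conformation(coords=_two_globules(40)))
        calls = call_tad_like(dmap, [1, 39])
        # the 1-bin and 1..39 split leaves only the middle interval testable
        assert all(b - a >= 3 for a, b in calls.intervals)


class TestBoundaryProbability:
    def _ensemble_of(self, coords_list, params):
        return Ensemble(conformations=[Conformation(coords=c)
                                       for c in coords_list], params=params)

    def test_identical_conformations_concentrate(self, sphere_params):
        coords = _two_globules(40)
        ens = self._ensemble_of([coords] * 20, sphere_params)
        stats = boundary_probability(ens, sample_size=20, seed=1, w=10)
        assert stats.probability[20] == pytest.approx(1.0)
        assert stats.probability.sum() == pytest.approx(1.0)

    def test_uniform_boundary_sites(self, sphere_params):
        """Boundary site uniform over 4 locations -> ~0.25 each."""
        rng = np.random.default_rng(5)
        sites = [15, 25, 35, 45]
        coords_list = []
        for k in range(400):
            site = sites[k % 4]
            half1 = rng.normal(scale=12.0, size=(site, 3))
            half2 = rng.normal(scale=12.0, size=(60 - site, 3)) + [320, 0, 0]
            coords_list.append(np.vstack([half1, half2]))
        ens = self._ensemble_of(coords_list, sphere_params)
        stats = boundary_probability(ens, sample_size=400, seed=2, w=10)
        for site in sites:
            window = stats.probability[site - 2: site + 3].sum()
            assert window == pytest.approx(0.25, abs=0.05)

    def test_histogram_sums_to_one(self, sphere_params):
        ens, _ = cs.generate_labeled_conformations("globule-pair", n=30,
                                                   seed=5)
        stats = boundary_probability(ens, sample_size=30, seed=3, w=10)
        assert stats.domain_counts.sum() == pytest.approx(1.0)
        assert 0.0 <= stats.frac_with_domain <= 1.0
        assert ((stats.probability >= 0) & (stats.probability <= 1)).all()

    def test_sample_size_bounded(self, sphere_params):
        ens = self._ensemble_of([_two_globules(40)] * 5, sphere_params)
        with pytest.raises(ValueError):
            boundary_probability(ens, sample_size=50, seed=1)


class TestPeakEnrichment:
    def _binning(self, n=60):
        return cs.GenomicBinning(chrom="chrT", start=0, resolution=2000,
                                 n_bins=n)

    def test_uniform_profile_flat_curve(self):
        binning = self._binning()
        peaks = cs.generate_peaks([10, 30, 50], 0, binning, seed=1)
        curve = peak_enrichment(np.full(60, 0.2), peaks, binning, flank=10000)
        np.testing.assert_allclose(curve[np.isfinite(curve)], 1.0)

    def test_delta_profile_peaks_at_center(self):
        binning = self._binning()
        profile = np.zeros(60)
        profile[[10, 30, 50]] = 1.0
        peaks = cs.generate_peaks([10, 30, 50], 0, binning, seed=1)
        curve = peak_enrichment(profile, peaks, binning, flank=10000)
        center = curve.size // 2
        assert curve[center] == curve[np.isfinite(curve)].max()
        assert curve[center] > 2.0

    def test_no_usable_peaks_rejected(self):
        binning = self._binning()
        peaks = cs.generate_peaks([], 0, binning, seed=1)
        with pytest.raises(ValueError, match="peaks"):
            peak_enrichment(np.ones(60), peaks, binning)


class TestVirtual4C:
    def test_single_anchor_row(self):
        rng = np.random.default_rng(6)
        m = rng.uniform(size=(20, 20))
        m = (m + m.T) / 2
        np.testing.assert_array_equal(virtual_4c(m, 7), m[7])

    def test_interval_anchor_mean(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(size=(20, 20))
        m = (m + m.T) / 2
        np.testing.assert_allclose(virtual_4c(m, (3, 5)), m[3:5].mean(axis=0))

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(size=(15, 15))
        m = (m + m.T) / 2
        assert virtual_4c(m, 2)[9] == virtual_4c(m, 9)[2]

    def test_anchor_outside_region_rejected(self):
        with pytest.raises(ValueError):
            virtual_4c(np.ones((10, 10)), 12)


class TestMultibody:
    def test_all_within_threshold(self, sphere_params):
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10) * 25.0
        ens = Ensemble(conformations=[Conformation(coords=coords)] * 3,
                       params=sphere_params)
        res = multibody_fraction(ens, [0, 1, 2], d_c=80.0)
        assert res.fraction == pytest.approx(1.0)

    def test_conditional_never_met(self, sphere_params):
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10) * 25.0
        ens = Ensemble(conformations=[Conformation(coords=coords)] * 2,
                       params=sphere_params)
        res = multibody_fraction(ens, [0, 5, 9], d_c=80.0, condition=(0, 2))
        assert not res.conditional_valid
        assert np.isnan(res.fraction)

    def test_pair_fraction_equals_contact_map(self, sphere_params):
        ens = cs.build_null_ensemble(
            cs.GrowthConfig(n_beads=15, n_chains=200, master_seed=12),
            sphere_params)
        res = multibody_fraction(ens, [2, 11], d_c=80.0)
        p = cs.simulate_contact_map(ens)
        assert res.fraction == pytest.approx(p[2, 11], abs=1e-12)

    def test_needs_two_loci(self, sphere_params):
        ens = Ensemble(conformations=[Conformation(coords=np.zeros((5, 3)))],
                       params=sphere_params)
        with pytest.raises(ValueError):
            multibody_fraction(ens, [1])
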