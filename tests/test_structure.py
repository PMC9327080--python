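"""RDFs, pyramidalization, LIIC paths, exponential fitting."""

import numpy as np
import pytest

from sehop import structure as ST
from sehop import synth


class TestRDF:
    def test_uniform_sphere_is_flat(self, rng):
        # points uniform in a sphere around a central particle: g ~ 1 mid-range
        n, r_sphere = 4000, 10.0
        u = rng.random(n)
        r = r_sphere * u ** (1 / 3)
        prof = ST.rdf_from_distances(r, bin_width=0.3, r_max=9.0, n_frames=1,
                                     reference_shell=(5.0, 8.5))
        mid = (prof.r_centers > 3.0) & (prof.r_centers < 8.5)
        counts = prof.counts[mid]
        se = np.sqrt(np.maximum(counts, 1.0)) / np.maximum(counts, 1.0)
        assert np.all(np.abs(prof.g[mid] - 1.0) <= 3 * se + 0.05)

    def test_two_fixed_particles_single_bin(self):
        frames = [np.array([[0.0, 0, 0], [2.5, 0, 0]])]
        prof = ST.rdf(frames, ([0], [1]), bin_width=0.3, r_max=5.0)
        nz = np.nonzero(prof.g)[0]
        assert len(nz) == 1
        lo, hi = prof.r_bins[nz[0]], prof.r_bins[nz[0] + 1]
        assert lo <= 2.5 < hi

    def test_shell_peak_area_gives_coordination_number(self, rng):
        """Coordination number from the peak integral matches the constructed
        shell population."""
        n_frames, n_shell, n_bulk = 200, 6, 120
        r_shell, rmax = 2.5, 10.0
        dists = []
        for _ in range(n_frames):
            shell = rng.normal(r_shell, 0.08, n_shell)
            u = rng.random(n_bulk)
            bulk = (4.0**3 + u * (rmax**3 - 4.0**3)) ** (1 / 3)
            dists.append(np.concatenate([shell, bulk]))
        prof = ST.rdf_from_distances(np.concatenate(dists), bin_width=0.3,
                                     r_max=rmax, n_frames=n_frames,
                                     reference_shell=(5.0, 9.5))
        centers = prof.r_centers
        peak = centers < 3.5
        coord = np.sum(prof.g[peak] * 4 * np.pi * centers[peak] ** 2
                       * prof.rho_bulk * 0.3)
        assert coord == pytest.approx(n_shell, rel=0.02)

    def test_difference_map_is_plain_subtraction(self, rng):
        g_t = rng.random((5, 20))
        ground = ST.RDFProfile(r_bins=np.arange(21) * 0.3, g=rng.random(20),
                               n_frames=1)
        diff = ST.rdf_difference_map(g_t, ground)
        assert np.allclose(diff, g_t - ground.g[None, :], atol=1e-12)

    def test_difference_map_bin_mismatch_raises(self):
        ground = ST.RDFProfile(r_bins=np.arange(11) * 0.3, g=np.ones(10),
                               n_frames=1)
        with pytest.raises(ST.StructureError):
            ST.rdf_difference_map(np.ones((3, 20)), ground)

    def test_null_contrast_map_near_zero(self):
        ens_g = synth.gen_solvent_trajectories(tau_shell=np.inf, n_traj=150,
                                               seed=3, t_max=300.0)
        ground = ST.rdf_from_distances(
            ens_g.distances[0], bin_width=0.3, r_max=8.0,
            n_frames=ens_g.distances.shape[1])
        edges, G = ST.time_resolved_rdf(
            [ens_g.distances[i] for i in range(0, ens_g.t.size, 10)],
            bin_width=0.3, r_max=8.0)
        diff = ST.rdf_difference_map(G, ground)
        # frozen shell: no systematic depletion anywhere
        assert np.max(np.abs(diff.mean(axis=0))) < 0.35

    def test_depletion_map_signs(self):
        """First-shell loss shows up negative near 2.5 Å and positive near
        4 Å in the difference map."""
        ens_g = synth.gen_solvent_trajectories(tau_shell=np.inf, n_traj=300, seed=5)
        ens_x = synth.gen_solvent_trajectories(tau_shell=100.0, n_traj=300, seed=5)
        ground = ST.rdf_from_distances(ens_g.distances[0], bin_width=0.3,
                                       r_max=8.0, n_frames=300)
        edges, G = ST.time_resolved_rdf(list(ens_x.distances), bin_width=0.3,
                                        r_max=8.0)
        diff = ST.rdf_difference_map(G, ground)
        centers = 0.5 * (edges[:-1] + edges[1:])
        late = diff[-5:].mean(axis=0)
        j25 = np.argmin(np.abs(centers - 2.5))
        j40 = np.argmin(np.abs(centers - 4.0))
        assert late[j25] < 0 and late[j40] > 0


class TestSliceFit:
    def test_noiseless_slice_recovery(self):
        t = np.linspace(0, 1000, 101)
        sl = -1.8 * np.exp(-t / 129.0)
        diff = np.zeros((101, 10))
        diff[:, 4] = sl
        edges = np.arange(11) * 0.3 + 1.2  # bin 4 covers 2.40-2.70
        tau, fit = ST.rdf_slice_fit(diff, t, edges, r_slice=2.5)
        assert tau == pytest.approx(129.0, rel=0.01)

    def test_constant_slice_flagged(self):
        t = np.linspace(0, 100, 30)
        diff = np.zeros((30, 10))
        edges = np.arange(11) * 0.3 + 1.2
        with pytest.warns(UserWarning):
            tau, fit = ST.rdf_slice_fit(diff, t, edges)
        assert np.isnan(tau)

    def test_noisy_slice_recovery_within_15_percent(self):
        taus = []
        for rep in range(50):
            rng = np.random.default_rng(900 + rep)
            t = np.linspace(0, 1000, 101)
            y = -1.5 * np.exp(-t / 129.0) + rng.normal(0, 0.15, t.size)
            diff = np.zeros((101, 10))
            diff[:, 4] = y
            edges = np.arange(11) * 0.3 + 1.2
            tau, _ = ST.rdf_slice_fit(diff, t, edges)
            taus.append(tau)
        assert np.median(np.abs(np.array(taus) - 129.0) / 129.0) < 0.15


class TestPyramidalization:
    def planar(self):
        return np.array([[1.5, 0, 0],      # apex
                         [0.0, 0, 0],      # central
                         [-1.0, 1.0, 0],   # sub1
                         [-1.0, -1.0, 0]]) # sub2

    def test_planar_is_zero(self):
        assert ST.pyramidalization(self.planar(), (0, 1, 2, 3)) == pytest.approx(0.0)

    def test_constructed_40_degree_geometry(self):
        geo = self.planar()
        r = np.linalg.norm(geo[0] - geo[1])
        ang = np.radians(40.0)
        geo[0] = [ -r * np.cos(ang) * -1.0, 0.0, r * np.sin(ang)]
        val = ST.pyramidalization(geo, (0, 1, 2, 3))
        assert abs(val) == pytest.approx(40.0, abs=1e-6)

    def test_sign_flips_under_reflection(self, rng):
        geo = self.planar()
        geo[0, 2] = 0.8  # out of plane
        mirror = geo.copy()
        mirror[:, 2] *= -1
        a = ST.pyramidalization(geo, (0, 1, 2, 3))
        b = ST.pyramidalization(mirror, (0, 1, 2, 3))
        assert a == pytest.approx(-b) and abs(a) > 1.0

    def test_collinear_plane_atoms_rejected(self):
        geo = np.array([[1.0, 0, 1.0], [0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(ST.StructureError):
            ST.pyramidalization(geo, (0, 1, 2, 3))


class TestLIIC:
    def test_identity_path_flat(self):
        geo = np.random.default_rng(0).normal(0, 1, (4, 3))
        path = ST.liic(geo, geo, n_points=5,
                       provider=lambda x: np.array([float(np.sum(x**2))]))
        assert path.barrier == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(path.frames[0], geo) and np.allclose(path.frames[-1], geo)

    def test_harmonic_1d_barriers_match_dense_scan(self):
        provider = lambda q: np.array([0.5 * 0.1 * float(q[0]) ** 2])
        # symmetric straddle of the minimum: no rise above the start
        path = ST.liic(np.array([-1.0]), np.array([1.0]), n_points=51,
                       provider=provider)
        assert path.barrier == pytest.approx(0.0, abs=1e-12)
        # same wall: barrier equals endpoint difference
        path2 = ST.liic(np.array([0.5]), np.array([2.0]), n_points=50,
                        provider=provider)
        dense = 0.5 * 0.1 * np.linspace(0.5, 2.0, 5000) ** 2
        assert path2.barrier == pytest.approx(dense.max() - dense[0], rel=1e-6)

    def test_bond_interpolation_linear_in_index(self):
        # C=Se-like stretch from 1.82 to 2.0 Å over 10 frames
        a = np.array([[0.0, 0, 0], [1.82, 0, 0], [2.5, 1.0, 0.0]])
        b = np.array([[0.0, 0, 0], [2.00, 0, 0], [2.5, 1.0, 0.0]])
        spec = [("bond", 0, 1), ("bond", 0, 2), ("angle", 1, 0, 2)]
        path = ST.liic(a, b, n_points=10, internal_spec=spec)
        bonds = [ST.bond_length(f[0], f[1]) for f in path.frames]
        assert np.allclose(bonds, np.linspace(1.82, 2.0, 10), atol=1e-7)

    def test_endpoint_reversal_symmetric_barrier(self):
        provider = lambda q: np.array([np.sin(float(q[0])) + 0.2 * float(q[0])])
        fwd = ST.liic(np.array([0.0]), np.array([4.0]), n_points=80,
                      provider=provider)
        rev = ST.liic(np.array([4.0]), np.array([0.0]), n_points=80,
                      provider=provider)
        e = fwd.energies[:, 0]
        # barrier referenced to each start; reversal only shifts the reference
        assert fwd.barrier == pytest.approx(e.max() - e[0], abs=1e-12)
        assert rev.barrier == pytest.approx(e.max() - e[-1], abs=1e-12)


class TestFitExponentials:
    def test_pure_monoexponential_exact(self):
        t = np.linspace(0, 800, 400)
        fit = ST.fit_exponentials(t, np.exp(-t / 100.0), n_components=1)
        assert fit["tau"][0] == pytest.approx(100.0, rel=1e-6)

    def test_biexponential_noiseless_recovery(self):
        t = np.linspace(0, 600, 1200)
        y = 0.5 * np.exp(-t / 14.0) + 0.5 * np.exp(-t / 123.0)
        fit = ST.fit_exponentials(t, y, n_components=2)
        assert fit["tau"][0] == pytest.approx(14.0, rel=0.01)
        assert fit["tau"][1] == pytest.approx(123.0, rel=0.01)

    def test_multistart_converges_to_sorted_pair(self):
        t = np.linspace(0, 600, 600)
        y = 0.3 * np.exp(-t / 20.0) + 0.7 * np.exp(-t / 200.0) + 0.1
        f1 = ST.fit_exponentials(t, y, n_components=2, n_starts=2)
        f2 = ST.fit_exponentials(t, y, n_components=2, n_starts=6)
        assert np.allclose(f1["tau"], f2["tau"], rtol=1e-4)
        assert f1["tau"] == sorted(f1["tau"])

    def test_flat_series_zero_amplitude(self):
        t = np.linspace(0, 100, 50)
        fit = ST.fit_exponentials(t, np.full(50, 0.7), n_components=1)
        assert fit["status"] == "zero-amplitude"

    def test_too_short_series_rejected(self):
        with pytest.raises(ST.StructureError):
            ST.fit_exponentials(np.arange(3.0), np.arange(3.0), n_components=1)
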