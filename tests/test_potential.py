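"""Training machinery: accumulators, DFIRE term, KDE, correction, build."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import i0 as bessel_i0

from rotas.fixtures import build_chain, FixtureSpec, helix, planted_training_set
from rotas.geometry import local_frame, pair_geometry, residue_frames
from rotas.potential import (
    POOLED,
    AngularSamples,
    BuilderConfig,
    DistanceCounts,
    PotentialFormatError,
    accumulate_angular,
    accumulate_distance,
    build,
    corrected_density,
    deviation_profile,
    dfire_energy,
    expected_angular_density,
    kappa_from_sigma,
    kde_density,
    load,
    save,
)
from rotas.structure import Atom, Residue, StructureModel, atom_type_of


def two_atom_model(d, same_residue=False):
    """Minimal model: ALA CB and GLY CA separated by d along x."""
    model = StructureModel("pair")
    r1 = Residue("ALA", "A", 1)
    r1.atoms["CB"] = Atom("ALA", "CB", np.zeros(3))
    if same_residue:
        r1.atoms["CA"] = Atom("ALA", "CA", np.array([d, 0.0, 0.0]))
        model.chains["A"] = [r1]
    else:
        r2 = Residue("GLY", "B", 1)
        r2.atoms["CA"] = Atom("GLY", "CA", np.array([d, 0.0, 0.0]))
        model.chains["A"] = [r1]
        model.chains["B"] = [r2]
    return model


class TestAccumulateDistance:
    def test_single_pair_lands_in_its_bin(self):
        counts = DistanceCounts(BuilderConfig())
        accumulate_distance(two_atom_model(3.1), counts)
        assert counts.total == 1
        ti = atom_type_of("ALA", "CB")
        tj = atom_type_of("GLY", "CA")
        assert counts.symmetric()[ti, tj, 6] == 1  # bin [3.0, 3.5)

    def test_same_residue_pairs_excluded(self):
        counts = DistanceCounts(BuilderConfig())
        accumulate_distance(two_atom_model(3.1, same_residue=True), counts)
        assert counts.total == 0

    def test_matches_bruteforce_enumeration(self):
        model = helix("ASKLDEVFRM")  # ~50 heavy atoms
        counts = DistanceCounts(BuilderConfig())
        accumulate_distance(model, counts)
        atoms = [(ri, a.position) for ri, res in enumerate(model.residues())
                 for a in res.atoms.values()]
        expected = sum(
            1
            for k in range(len(atoms)) for l in range(k + 1, len(atoms))
            if atoms[k][0] != atoms[l][0]
            and np.linalg.norm(atoms[k][1] - atoms[l][1]) < 15.0
        )
        assert counts.total == expected


class TestDfireEnergy:
    def test_powerlaw_counts_give_zero_energy(self):
        cfg = BuilderConfig()
        counts = DistanceCounts(cfg)
        ti, tj = 0, 5
        # observed counts exactly proportional to d^alpha, including the
        # cutoff bin (fractional counts are fine for the ratio formula)
        counts.counts = counts.counts.astype(float)
        counts.counts[ti, tj, :] = 1000.0 * cfg.bin_centers ** cfg.alpha
        energy, usable = dfire_energy(counts, cfg)
        assert usable[ti, tj]
        np.testing.assert_allclose(energy[ti, tj], 0.0, atol=1e-9)

    def test_cutoff_bin_is_exactly_zero(self, small_tables):
        usable = small_tables.dist_usable
        assert np.all(small_tables.e_dist[usable, -1] == 0.0)

    def test_single_bin_closed_form(self):
        cfg = BuilderConfig()
        counts = DistanceCounts(cfg)
        ti, tj = 2, 7
        counts.counts[ti, tj, -1] = 100   # cutoff bin, center 14.75
        counts.counts[ti, tj, 9] = 50     # bin [4.5, 5.0), center 4.75
        energy, usable = dfire_energy(counts, cfg)
        expected = -math.log(50.0 / ((4.75 / 14.75) ** 1.61 * 100.0))
        assert usable[ti, tj]
        assert energy[ti, tj, 9] == pytest.approx(expected, abs=1e-12)
        # unobserved bins of a usable pair get the finite repulsive cap
        assert energy[ti, tj, 0] == cfg.zero_count_energy

    def test_pair_without_cutoff_counts_flagged_unusable(self):
        cfg = BuilderConfig()
        counts = DistanceCounts(cfg)
        counts.counts[3, 4, 5] = 10  # no counts at the cutoff bin
        with pytest.warns(UserWarning):
            energy, usable = dfire_energy(counts, cfg)
        assert not usable[3, 4]
        np.testing.assert_array_equal(energy[3, 4], 0.0)


class TestKde:
    cfg = BuilderConfig()

    def test_single_sample_mode_and_symmetry(self):
        grid = self.cfg.theta_grid
        dens = kde_density([0.3], self.cfg.kappa, grid)
        assert grid[np.argmax(dens)] == pytest.approx(np.pi / 9, abs=1e-12)

    def test_normalization_contract(self, rng):
        for domain_grid in (self.cfg.theta_grid, self.cfg.phi_grid):
            for n in (1, 10, 500):
                lo, hi = domain_grid[0], domain_grid[-1]
                samples = rng.uniform(lo, hi, size=n)
                dens = kde_density(samples, self.cfg.kappa, domain_grid)
                assert np.trapezoid(dens, domain_grid) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_samples_give_flat_density(self, rng):
        samples = rng.uniform(-np.pi, np.pi, size=100_000)
        dens = kde_density(samples, self.cfg.kappa, self.cfg.theta_grid)
        assert dens.max() / dens.min() < 1.05

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError):
            kde_density([], self.cfg.kappa, self.cfg.theta_grid)


class TestCorrectedDensity:
    def test_equal_weights_at_n_equals_inverse_sigma(self):
        p_state = np.array([1.0, 0.0])
        p_pool = np.array([0.0, 1.0])
        mixed = corrected_density(p_state, p_pool, 100, 0.01)
        np.testing.assert_allclose(mixed, [0.5, 0.5])

    def test_zero_observations_returns_pooled(self):
        p_state = np.array([1.0, 0.0])
        p_pool = np.array([0.25, 0.75])
        np.testing.assert_array_equal(
            corrected_density(p_state, p_pool, 0, 0.01), p_pool)

    def test_large_n_converges_to_state(self):
        p_state = np.array([0.9, 0.1])
        p_pool = np.array([0.5, 0.5])
        mixed = corrected_density(p_state, p_pool, 10**6, 0.01)
        np.testing.assert_allclose(mixed, p_state, atol=1e-4)


class TestExpectedDensity:
    cfg = BuilderConfig()

    def test_theta_and_omega_uniform(self):
        for domain in ("theta", "omega"):
            dens = expected_angular_density(domain, self.cfg.kappa,
                                            self.cfg.theta_grid)
            np.testing.assert_allclose(dens, 1.0 / (2 * np.pi))

    def test_phi_matches_quadrature_oracle(self):
        """Independent oracle: adaptive quadrature of the smoothed cosine."""
        grid = self.cfg.phi_grid
        kappa = self.cfg.kappa
        dens = expected_angular_density("phi", kappa, grid)

        def smoothed(g):
            val, _ = integrate.quad(
                lambda t: math.exp(kappa * math.cos(g - t)) * math.cos(t) / 2,
                -np.pi / 2, np.pi / 2)
            return val / (2 * np.pi * bessel_i0(kappa))

        oracle = np.array([smoothed(g) for g in grid])
        oracle /= np.trapezoid(oracle, grid)
        np.testing.assert_allclose(dens, oracle, atol=1e-6)
        # the even-count grid straddles 0, so the maximum sits at the two
        # central points
        assert abs(grid[np.argmax(dens)]) == pytest.approx(np.pi / 18)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(dens, dens[::-1], atol=1e-9)  # symmetric

    def test_kappa_sigma_correspondence(self):
        assert round(kappa_from_sigma(np.pi / 9), 2) == self.cfg.kappa


class TestAccumulateAngular:
    def test_sequence_separation_threshold(self):
        cfg = BuilderConfig()
        # helix: residues 6 apart are ~9 A apart, inside the angular range
        model = helix("G" * 12)
        chain = model.chains["A"]
        samples = AngularSamples(cfg)
        accumulate_angular(model, samples)
        d06 = np.linalg.norm(chain[0].coords("CA") - chain[6].coords("CA"))
        assert 2.0 <= d06 < 15.0  # the threshold pairs are in range
        recorded = samples.n_samples
        oracle = self._bruteforce_count(model, cfg)
        assert recorded == oracle > 0
        # a 7-residue helix has no pair at separation >= 6
        short = AngularSamples(cfg)
        accumulate_angular(helix("G" * 6), short)
        assert short.n_samples == 0

    @staticmethod
    def _bruteforce_count(model, cfg):
        residues = list(model.residues())
        atoms = [(ri, res, name) for ri, res in enumerate(residues)
                 for name in res.atoms]
        count = 0
        for k in range(len(atoms)):
            for l in range(k + 1, len(atoms)):
                ri, res_i, name_i = atoms[k]
                rj, res_j, name_j = atoms[l]
                if ri == rj or abs(ri - rj) < cfg.min_seq_sep:
                    continue  # single unbroken chain fixtures only
                try:
                    fi = local_frame(res_i, name_i)
                    fj = local_frame(res_j, name_j)
                except Exception:
                    continue
                d = np.linalg.norm(fi.origin - fj.origin)
                if cfg.angular_min <= d < cfg.distance_max:
                    count += 2  # both ordered directions
        return count

    def test_cross_chain_pairs_always_eligible(self):
        cfg = BuilderConfig()
        samples = AngularSamples(cfg)
        accumulate_angular(planted_training_set(n_structures=1, seed=0)[0],
                           samples)
        assert samples.n_samples > 0

    def test_pooled_equals_sum_over_states(self):
        cfg = BuilderConfig()
        samples = AngularSamples(cfg)
        for m in planted_training_set(n_structures=12, seed=1):
            accumulate_angular(m, samples)
        for key, per_state in samples.entries.items():
            pooled = samples.pooled(key)
            assert pooled["n"] == sum(r["n"] for r in per_state.values())
            np.testing.assert_allclose(
                pooled["theta"],
                sum(r["theta"] for r in per_state.values()))


class TestBuild:
    def test_smoke_energies_finite_with_metadata(self, small_tables):
        assert np.all(np.isfinite(small_tables.e_dist))
        for per_state in small_tables.angular.values():
            for grids in per_state.values():
                for arr in grids.values():
                    assert np.all(np.isfinite(arr))
        assert small_tables.metadata["n_structures"] == 6
        assert small_tables.config.kappa == 8.21

    def test_duplication_invariance(self, helix_models, small_tables):
        doubled = build(helix_models * 2)
        np.testing.assert_allclose(doubled.e_dist, small_tables.e_dist,
                                   atol=1e-12)
        assert set(doubled.angular) == set(small_tables.angular)
        for key in list(small_tables.angular)[:50]:
            a, b = small_tables.angular[key], doubled.angular[key]
            assert set(a) == set(b)
            # doubling the counts moves the sparse-state correction weight,
            # so only the pooled densities are exactly invariant
            np.testing.assert_allclose(a[POOLED]["theta"], b[POOLED]["theta"],
                                       atol=1e-9)

    def test_order_invariance(self, helix_models, small_tables):
        reordered = build(helix_models[::-1])
        np.testing.assert_allclose(reordered.e_dist, small_tables.e_dist)

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError):
            build([])

    def test_planted_modes_recovered_as_energy_minima(self):
        structs = planted_training_set(
            modes={"g+": 1.0, "t": -1.0},
            state_chis={"g+": (60.0,), "t": (180.0,)},
            n_structures=90, seed=3)
        tables = build(structs)
        ti = atom_type_of("SER", "CB")
        tj = atom_type_of("GLY", "N")
        entry = tables.angular[(ti, tj, 10)]  # bin [5.0, 5.5)
        grid = tables.config.theta_grid
        for state, mode in ((0, 1.0), (2, -1.0)):  # g+ = 0, t = 2
            argmin = grid[np.argmin(entry[state]["theta"])]
            nearest = grid[np.argmin(np.abs(grid - mode))]
            assert argmin == pytest.approx(nearest)

    def test_single_state_matches_pooled(self):
        """With one rotameric state the corrected state density equals the
        pooled one, so conditioning is a no-op (the orientation-only limit)."""
        structs = planted_training_set(
            modes={"g+": 0.5}, state_chis={"g+": (60.0,)},
            n_structures=40, seed=7)
        tables = build(structs)
        ti = atom_type_of("SER", "CB")
        tj = atom_type_of("GLY", "N")
        entry = tables.angular[(ti, tj, 10)]
        np.testing.assert_allclose(entry[0]["theta"], entry[POOLED]["theta"],
                                   atol=1e-9)


class TestDeviationProfile:
    @staticmethod
    def _stream(rng, cfg, planted_bin=None, n_per_bin=300):
        samples = AngularSamples(cfg)
        for b in range(cfg.first_angular_bin, cfg.n_bins):
            for _ in range(n_per_bin):
                if b == planted_bin:
                    theta = rng.normal(0.5, 0.05)
                else:
                    theta = rng.uniform(-np.pi, np.pi)
                phi = np.arcsin(rng.uniform(-1, 1))
                omega = rng.uniform(-np.pi, np.pi)
                samples.add(3, 7, b, 0, theta, phi, omega)
        return samples

    def test_shape_contract(self, rng):
        cfg = BuilderConfig()
        profile = deviation_profile(self._stream(rng, cfg, n_per_bin=5))
        per_bin = profile.groupby("bin").size()
        assert (per_bin == 3).all()  # one row per angle per distance bin
        assert len(per_bin) == cfg.n_bins - cfg.first_angular_bin

    def test_planted_bin_stands_out(self, rng):
        cfg = BuilderConfig()
        profile = deviation_profile(self._stream(rng, cfg, planted_bin=10))
        theta = profile[profile.angle == "theta"].set_index("bin")
        assert theta.loc[10, "rms"] == theta["rms"].max()
        assert theta.loc[10, "rms"] > 3 * theta.drop(10)["rms"].max()

    def test_uniform_geometry_gives_small_rms(self, rng):
        cfg = BuilderConfig()
        profile = deviation_profile(self._stream(rng, cfg))
        # sampling noise only: far below the planted-signal level (~0.2)
        assert profile["rms"].max() < 0.05


class TestPersistence:
    def test_roundtrip_is_exact(self, small_tables, tmp_path):
        path = tmp_path / "pot.npz"
        save(small_tables, path)
        loaded = load(path)
        np.testing.assert_array_equal(loaded.e_dist, small_tables.e_dist)
        assert loaded.config == small_tables.config
        assert set(loaded.angular) == set(small_tables.angular)
        for key, per_state in small_tables.angular.items():
            assert set(loaded.angular[key]) == set(per_state)
            for state, grids in per_state.items():
                for term, arr in grids.items():
                    np.testing.assert_array_equal(
                        loaded.angular[key][state][term], arr)

    def test_checksum_mismatch_rejected(self, small_tables, tmp_path):
        path = tmp_path / "pot.npz"
        bad = small_tables
        bad.metadata["typing_checksum"] = "deadbeef"
        try:
            save(bad, path)
            with pytest.raises(PotentialFormatError):
                load(path)
        finally:
            from rotas.structure import default_type_table
            bad.metadata["typing_checksum"] = default_type_table().checksum()

    def test_truncated_file_rejected(self, small_tables, tmp_path):
        path = tmp_path / "pot.npz"
        save(small_tables, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(PotentialFormatError):
            load(path)
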