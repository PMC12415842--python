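import numpy as np
import pytest

from condensekit.core.model import DomainMap, TrajectoryFrameSet
from condensekit.metrics import (
    autocorrelation,
    dimension_series,
    end_to_end,
    hull_rh_single,
    hullrad_rh,
    integrated_act,
    kabsch_rmsd,
    radius_of_gyration,
    rmsf,
    stability_report,
    suggest_equilibration,
    unwrapped_chain_coords,
)
from condensekit.synthetic import SyntheticSpec, generate_chain
from condensekit.synthetic.groups import random_rotation

from conftest import hull_rh_oracle, make_model


class TestRg:
    def test_two_equal_masses(self):
        assert radius_of_gyration(np.array([[0.0, 0, 0], [4.0, 0, 0]])) == 2.0

    def test_coincident_atoms(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_direct_formula(self, rng):
        x = rng.normal(size=(40, 3)) * 6
        m = rng.uniform(1, 16, size=40)
        com = (x * m[:, None]).sum(0) / m.sum()
        expected = np.sqrt((m * ((x - com) ** 2).sum(1)).sum() / m.sum())
        assert radius_of_gyration(x, m) == pytest.approx(expected, abs=1e-12)

    def test_unweighted(self, rng):
        x = rng.normal(size=(10, 3))
        a = radius_of_gyration(x, mass_weighted=False)
        b = radius_of_gyration(x, np.ones(10))
        assert a == pytest.approx(b)

    def test_needs_two_atoms(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((1, 3)))


class TestEndToEnd:
    def test_straight_ten_bead_chain(self):
        m = generate_chain(SyntheticSpec(seed=1, chain_length=10, frames=1))
        top = m.topology
        coords = m.trajectory.coords.copy()
        for r in range(10):
            ca = top.find_atom(r, "CA")
            shift = np.array([3.8 * r, 0.0, 0.0]) - coords[0, ca]
            coords[0, top.residue_atoms(r)] += shift
        m2 = m.with_trajectory(TrajectoryFrameSet(coords))
        assert end_to_end(m2, 0, "A") == pytest.approx(34.2)

    def test_ring_closed_chain(self):
        m = generate_chain(SyntheticSpec(seed=1, chain_length=12, frames=1))
        top = m.topology
        coords = m.trajectory.coords.copy()
        for r in range(12):
            ang = 2 * np.pi * r / 12
            radius = 3.8 / (2 * np.sin(np.pi / 12))
            ca = top.find_atom(r, "CA")
            target = np.array([radius * np.cos(ang), radius * np.sin(ang), 0])
            coords[0, top.residue_atoms(r)] += target - coords[0, ca]
        m2 = m.with_trajectory(TrajectoryFrameSet(coords))
        assert end_to_end(m2, 0, "A") == pytest.approx(3.8, abs=1e-9)

    def test_matches_manual_measurement(self):
        m = generate_chain(SyntheticSpec(seed=6, chain_length=20, frames=1))
        top = m.topology
        X = m.trajectory.frame(0)
        manual = np.linalg.norm(
            X[top.find_atom(19, "CA")] - X[top.find_atom(0, "CA")]
        )
        assert end_to_end(m, 0, "A") == pytest.approx(manual)


class TestAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        acf = autocorrelation(rng.normal(size=100), 10)
        assert acf[0] == pytest.approx(1.0)

    def test_white_noise_null(self):
        rng = np.random.default_rng(77)
        acf = autocorrelation(rng.normal(size=100_000), 50)
        assert np.abs(acf[1:]).max() < 0.02

    def test_ar1_act_closed_form(self):
        rng = np.random.default_rng(42)
        phi, n = 0.9, 200_000
        e = rng.normal(size=n)
        s = np.empty(n)
        s[0] = e[0]
        for i in range(1, n):
            s[i] = phi * s[i - 1] + e[i]
        act = integrated_act(s)
        assert act == pytest.approx((1 + phi) / (1 - phi), rel=0.2)

    def test_constant_series_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            acf = autocorrelation(np.ones(50), 5)
        assert acf[0] == 1.0
        assert np.all(acf[1:] == 0)

    def test_max_lag_validation(self):
        with pytest.raises(ValueError):
            autocorrelation(np.arange(5.0), 10)

    def test_equilibration_suggestion_drifting_prefix(self):
        rng = np.random.default_rng(3)
        drift = np.linspace(10, 0, 200)
        stable = rng.normal(size=800)
        cut = suggest_equilibration(np.concatenate([drift, stable]))
        assert cut >= 100


class TestKabsch:
    def test_rigid_transform_zero(self, rng):
        P = rng.normal(size=(20, 3))
        rot = random_rotation(rng)
        Q = P @ rot.T + [3.0, -1.0, 7.0]
        assert kabsch_rmsd(Q, P) < 1e-9

    def test_mirror_rejected(self, rng):
        P = rng.normal(size=(20, 3))
        M = P.copy()
        M[:, 0] *= -1
        assert kabsch_rmsd(M, P) > 0.1

    def test_single_atom_displacement_analytic(self):
        # displace one atom by delta after fitting on the others:
        # RMSD over all N = sqrt(delta^2 / N)
        rng = np.random.default_rng(8)
        N = 10
        P = rng.normal(size=(N, 3))
        Q = P.copy()
        Q[0] += [1.0, 0, 0]
        fit = np.arange(1, N)
        rmsd = kabsch_rmsd(Q, P, fit_idx=fit, measure_idx=np.arange(N))
        assert rmsd == pytest.approx(np.sqrt(1.0 / N), abs=1e-12)

    def test_too_few_fit_atoms(self, rng):
        P = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            kabsch_rmsd(P, P, fit_idx=np.array([0, 1]))


class TestRmsf:
    def test_static_trajectory_zero(self, rng):
        frame = rng.normal(size=(12, 3))
        m = make_model(["GLY"] * 3, np.stack([frame] * 5))
        assert np.allclose(rmsf(m, np.arange(12)), 0.0)

    def test_oscillating_atom_closed_form(self):
        # atom 0 oscillates +/- a along x, others fixed; fitting on the
        # others leaves RMSF(atom0) = a
        base = np.array(
            [[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10], [10, 10, 0],
             [10, 0, 10], [0, 10, 10], [10, 10, 10]]
        )
        a = 0.7
        frames = []
        for sign in (1, -1, 1, -1):
            f = base.copy()
            f[0, 0] += sign * a
            frames.append(f)
        m = make_model(["GLY", "GLY"], np.stack(frames))
        vals = rmsf(m, np.arange(8), fit_idx=np.arange(1, 8))
        assert vals[0] == pytest.approx(a, abs=1e-9)
        assert vals[1:].max() < 1e-9

    def test_frame_permutation_invariance(self, rng):
        base = rng.normal(size=(8, 3)) * 5
        coords = base[None] + rng.normal(scale=0.1, size=(6, 8, 3))
        m1 = make_model(["GLY", "GLY"], coords)
        m2 = make_model(["GLY", "GLY"], coords[rng.permutation(6)])
        np.testing.assert_allclose(
            rmsf(m1, np.arange(8)), rmsf(m2, np.arange(8)), atol=1e-6
        )

    def test_needs_two_frames(self, rng):
        m = make_model(["GLY"], rng.normal(size=(1, 4, 3)))
        with pytest.raises(ValueError):
            rmsf(m, np.arange(4))

    def test_rigid_domain_rmsf_near_zero(self):
        dm = DomainMap([("CORE", 5, 20)])
        m = generate_chain(SyntheticSpec(seed=4, chain_length=30, frames=6,
                                         domain_map=dm, folded_domains=("CORE",)))
        top = m.topology
        ca = np.array([top.find_atom(r, "CA") for r in range(4, 20)])
        assert rmsf(m, ca).max() < 1e-6


class TestHullRad:
    def test_rigid_invariance(self, rng):
        P = rng.normal(size=(60, 3)) * 8
        rot = random_rotation(rng)
        rh1, _, _ = hull_rh_single(P)
        rh2, _, _ = hull_rh_single(P @ rot.T + 11.0)
        assert rh2 == pytest.approx(rh1, abs=1e-9)

    def test_volume_homogeneity(self, rng):
        P = rng.normal(size=(60, 3)) * 8
        _, v1, _ = hull_rh_single(P)
        _, v8, _ = hull_rh_single(P * 2)
        assert v8 == pytest.approx(8 * v1, rel=1e-12)

    def test_rh_exceeds_anhydrous_radius(self, rng):
        P = rng.normal(size=(60, 3)) * 8
        rh, v_hull, _ = hull_rh_single(P)
        assert rh > (3 * v_hull / (4 * np.pi)) ** (1 / 3)

    def test_degenerate_coplanar(self):
        P = np.zeros((10, 3))
        P[:, :2] = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="degenerate|coplanar"):
            hull_rh_single(P)

    @pytest.mark.parametrize("seed", range(5))
    def test_reference_oracle_within_1_percent(self, seed):
        m = generate_chain(SyntheticSpec(seed=seed, chain_length=100, frames=1))
        res = hullrad_rh(m)
        heavy = m.component_atoms("protein")
        coords = m.trajectory.frame(0)[heavy]
        expected = hull_rh_oracle(coords)
        assert res.rh[0] == pytest.approx(expected, rel=0.01)

    def test_trajectory_wide(self):
        m = generate_chain(SyntheticSpec(seed=2, chain_length=40, frames=3))
        res = hullrad_rh(m)
        assert res.rh.shape == (3,)
        assert np.all(res.rh > 0)
        assert "hydration_shell_A" in res.metadata


class TestDimensionSeries:
    def test_summary_fields(self):
        m = generate_chain(SyntheticSpec(seed=2, chain_length=25, frames=12))
        ds = dimension_series(m)
        s = ds.summary()
        assert s["rg_mean"] > 0
        assert ds.acf_rg[0] == pytest.approx(1.0)

    def test_unwrap_across_boundary(self):
        # a two-residue chain straddling the periodic boundary must not be
        # split by Rg computations
        m = generate_chain(SyntheticSpec(seed=3, chain_length=5, frames=1))
        top = m.topology
        coords = m.trajectory.coords.copy()
        # place CA walk crossing z-boundary of a 20 A box
        for r in range(5):
            ca = top.find_atom(r, "CA")
            target = np.array([5.0, 5.0, 16.0 + 2.5 * r])
            coords[0, top.residue_atoms(r)] += target - coords[0, ca]
        coords[0] = np.mod(coords[0], 20.0)
        m2 = m.with_trajectory(
            TrajectoryFrameSet(coords, box=np.tile([20.0, 20.0, 20.0], (1, 1)))
        )
        unwrapped, _ = unwrapped_chain_coords(m2, 0, "A")
        span = unwrapped[:, 2].max() - unwrapped[:, 2].min()
        assert span == pytest.approx(10.0, abs=3.0)  # not ~16 (wrapped split)


def test_stability_report_rigid_core():
    dm = DomainMap([("CORE", 8, 22)])
    m = generate_chain(SyntheticSpec(seed=9, chain_length=30, frames=5,
                                     domain_map=dm, folded_domains=("CORE",)))
    top = m.topology
    ca = np.array([top.find_atom(r, "CA") for r in range(7, 22)])
    rep = stability_report(m, fit_idx=ca)
    assert rep.rmsd.max() < 1e-9
    assert rep.rmsf.max() < 1e-6
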