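"""Electrostatic coupling: exact Coulomb, multipoles, ESPF, hybrid scans."""

import numpy as np
import pytest
from scipy.special import eval_legendre

from mpakit.coupling import (
    ChargeCloud,
    CouplingConfig,
    convergence_scan,
    espf_fit,
    espf_grid,
    exact_interaction,
    expand_multipoles,
    hybrid_interaction,
    multipole_potential,
)
from mpakit.synthetic import make_charge_cloud


def exact_potential(cloud, points):
    return np.array(
        [
            np.sum(cloud.charges / np.linalg.norm(p - cloud.positions, axis=1))
            for p in np.atleast_2d(points)
        ]
    )


def legendre_expansion_potential(cloud, points, order):
    """Independent per-charge Legendre-addition-theorem oracle."""
    out = np.zeros(len(points))
    cen = cloud.centroid
    for q, a in zip(cloud.charges, cloud.positions - cen):
        an = np.linalg.norm(a)
        for i, pt in enumerate(points):
            rv = pt - cen
            rn = np.linalg.norm(rv)
            cosg = float(np.dot(a, rv) / (an * rn)) if an > 0 else 1.0
            for n in range(order + 1):
                out[i] += q * an**n / rn ** (n + 1) * eval_legendre(n, cosg)
    return out


class TestExactInteraction:
    def test_two_unit_charges_one_bohr(self):
        cloud = ChargeCloud(positions=[[0.0, 0, 0]], charges=[1.0])
        res = exact_interaction(cloud, np.array([[0.0, 0, 1.0]]), np.array([1.0]))
        assert res["energy"] == pytest.approx(1.0)
        assert np.linalg.norm(res["forces"][0]) == pytest.approx(1.0)
        assert res["forces"][0][2] > 0  # repulsive, pushes the env charge away

    def test_symmetric_under_role_swap(self, rng):
        a = rng.normal(size=(4, 3))
        qa = rng.normal(size=4)
        b = rng.normal(size=(3, 3)) + 5.0
        qb = rng.normal(size=3)
        e1 = exact_interaction(ChargeCloud(a, qa), b, qb)["energy"]
        e2 = exact_interaction(ChargeCloud(b, qb), a, qa)["energy"]
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        cloud, _ = make_charge_cloud(20, seed=5)
        env = rng.normal(size=(9, 3)) * 8.0 + 15.0
        qenv = rng.normal(size=9)
        res = exact_interaction(cloud, env, qenv)
        energy = 0.0
        forces = np.zeros_like(env)
        for j in range(20):
            for k in range(9):
                rv = env[k] - cloud.positions[j]
                r = np.linalg.norm(rv)
                energy += cloud.charges[j] * qenv[k] / r
                forces[k] += qenv[k] * cloud.charges[j] * rv / r**3
        assert res["energy"] == pytest.approx(energy, abs=1e-12)
        np.testing.assert_allclose(res["forces"], forces, atol=1e-12)

    def test_coincident_points_rejected(self):
        cloud = ChargeCloud(positions=[[0.0, 0, 0]], charges=[1.0])
        with pytest.raises(ValueError, match="coincident"):
            exact_interaction(cloud, np.array([[0.0, 0, 0]]), np.array([1.0]))


class TestExpandMultipoles:
    def test_point_dipole(self):
        d = 0.6
        cloud = ChargeCloud(
            positions=[[0, 0, d / 2], [0, 0, -d / 2]], charges=[1.0, -1.0]
        )
        exp = expand_multipoles(cloud, 1)
        assert exp.moments[0][(0, 0, 0)] == pytest.approx(0.0, abs=1e-14)
        assert exp.moments[1][(0, 0, 1)] == pytest.approx(d)
        assert exp.moments[1][(1, 0, 0)] == pytest.approx(0.0, abs=1e-14)

    def test_single_central_charge_is_monopole_only(self):
        cloud = ChargeCloud(positions=[[0.0, 0, 0]], charges=[2.5])
        exp = expand_multipoles(cloud, 4)
        assert exp.moments[0][(0, 0, 0)] == pytest.approx(2.5)
        for n in range(1, 5):
            assert max(abs(v) for v in exp.moments[n].values()) < 1e-14

    def test_moments_are_traceless(self):
        cloud, _ = make_charge_cloud(15, seed=8)
        exp = expand_multipoles(cloud, 8)
        scale = max(max(abs(v) for v in m.values()) for m in exp.moments[2:])
        for n in range(2, 9):
            assert exp.trace_norm(n) < 1e-10 * max(scale, 1.0)

    def test_matches_legendre_oracle_per_order(self, rng):
        cloud, _ = make_charge_cloud(10, extent=2.0, net_charge=0.3, seed=2)
        pts = rng.normal(size=(5, 3))
        pts = 9.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True) + cloud.centroid
        for order in (0, 1, 2, 3, 5, 8):
            exp = expand_multipoles(cloud, order)
            np.testing.assert_allclose(
                multipole_potential(exp, pts),
                legendre_expansion_potential(cloud, pts, order),
                atol=1e-12,
            )

    def test_far_field_error_within_truncation_tail_bound(self):
        # |P_n| <= 1 bounds the order-p remainder by
        # sum_j |q_j| (a_j/r)^(p+1) / (r - a_j); the truncated expansion must
        # respect that bound at 10x the cloud radius.
        cloud, _ = make_charge_cloud(10, extent=2.0, seed=3)
        r = 10.0 * cloud.radius
        pt = cloud.centroid + np.array([0.0, 0.0, r])
        ref = exact_potential(cloud, pt)[0]
        for p in (2, 4, 6):
            err = abs(multipole_potential(expand_multipoles(cloud, p), pt)[0] - ref)
            aj = np.linalg.norm(cloud.positions - cloud.centroid, axis=1)
            bound = np.sum(np.abs(cloud.charges) * (aj / r) ** (p + 1) / (r - aj))
            assert err <= bound * 1.000001

    def test_order_above_max_rejected(self):
        cloud, _ = make_charge_cloud(3, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            expand_multipoles(cloud, 9)


class TestEspf:
    def test_single_charge_recovered(self):
        cloud = ChargeCloud(positions=[[0.1, -0.2, 0.3]], charges=[0.73])
        q = espf_fit(cloud)
        assert q[0] == pytest.approx(0.73, abs=1e-10)

    def test_symmetric_dimer_equal_charges(self):
        cloud = ChargeCloud(
            positions=[[0, 0, 1.0], [0, 0, -1.0]], charges=[0.4, 0.4]
        )
        q = espf_fit(cloud)
        assert q[0] == pytest.approx(q[1], abs=1e-9)
        assert q.sum() == pytest.approx(0.8, abs=1e-12)

    def test_total_charge_constraint_exact(self):
        cloud, _ = make_charge_cloud(10, net_charge=-1.0, seed=6)
        centers = cloud.positions[:4]
        q = espf_fit(cloud, fit_positions=centers)
        assert q.sum() == pytest.approx(-1.0, abs=1e-10)

    def test_beats_single_center_monopole(self):
        # Charges standing in for a density, fitted onto fewer centers: the
        # atom-centered fit must reproduce the ESP better than collapsing
        # everything into the centroid monopole.
        cloud, _ = make_charge_cloud(10, extent=3.0, net_charge=0.5, seed=7)
        centers = cloud.positions[:5]
        grid = espf_grid(cloud)
        fitted = espf_fit(cloud, grid=grid, fit_positions=centers)
        phi_ref = exact_potential(cloud, grid)
        phi_fit = np.array(
            [np.sum(fitted / np.linalg.norm(g - centers, axis=1)) for g in grid]
        )
        phi_mono = multipole_potential(expand_multipoles(cloud, 0), grid)
        rms_fit = np.sqrt(np.mean((phi_fit - phi_ref) ** 2))
        rms_mono = np.sqrt(np.mean((phi_mono - phi_ref) ** 2))
        assert rms_fit < rms_mono

    def test_higher_order_not_implemented(self):
        cloud, _ = make_charge_cloud(4, seed=1)
        with pytest.raises(NotImplementedError):
            espf_fit(cloud, order=1)


class TestHybrid:
    def test_full_extent_cutoff_equals_exact(self, rng):
        cloud, _ = make_charge_cloud(12, seed=4)
        env = rng.normal(size=(10, 3)) * 10 + 20.0
        qenv = rng.normal(size=10)
        ref = exact_interaction(cloud, env, qenv)
        res = hybrid_interaction(
            cloud, env, qenv, CouplingConfig(r_exact=1e4, order=2)
        )
        assert res["energy"] == pytest.approx(ref["energy"], abs=1e-12)
        np.testing.assert_allclose(res["forces"], ref["forces"], atol=1e-12)
        assert res["exact_mask"].all()

    def test_partition_is_disjoint_cover(self, rng):
        cloud, _ = make_charge_cloud(12, seed=4)
        env = rng.normal(size=(30, 3)) * 12
        qenv = rng.normal(size=30)
        res = hybrid_interaction(cloud, env, qenv, CouplingConfig(r_exact=8.0))
        dist = np.linalg.norm(env - cloud.centroid, axis=1)
        np.testing.assert_array_equal(res["exact_mask"], dist <= 8.0)

    def test_pure_multipole_error_decreases_with_order(self, rng):
        cloud, _ = make_charge_cloud(15, extent=3.0, seed=9)
        env = rng.normal(size=(12, 3))
        env = 18.0 * env / np.linalg.norm(env, axis=1, keepdims=True)
        qenv = rng.normal(size=12)
        ref = exact_interaction(cloud, env, qenv)["energy"]
        errs = [
            abs(
                hybrid_interaction(
                    cloud, env, qenv, CouplingConfig(r_exact=0.0, order=p)
                )["energy"]
                - ref
            )
            for p in (0, 2, 4, 6, 8)
        ]
        assert errs[-1] < errs[0]
        assert all(np.diff(np.log10(np.array(errs) + 1e-300)) < 1.0)

    def test_espf_scheme_runs(self, rng):
        cloud, _ = make_charge_cloud(6, seed=10)
        env = rng.normal(size=(5, 3)) * 5 + 15
        qenv = rng.normal(size=5)
        res = hybrid_interaction(
            cloud, env, qenv, CouplingConfig(r_exact=0.0, scheme="espf")
        )
        ref = exact_interaction(cloud, env, qenv)["energy"]
        # for a point-charge cloud fitted onto its own positions the ESPF
        # surrogate is the cloud itself
        assert res["energy"] == pytest.approx(ref, rel=1e-8)


class TestConvergenceScan:
    def test_row_count_and_zero_at_full_extent(self, rng):
        cloud, _ = make_charge_cloud(10, seed=11)
        env = rng.normal(size=(8, 3)) * 10 + 25
        qenv = rng.normal(size=8)
        scan = convergence_scan(cloud, env, qenv, [0.0, 1e4], [0, 2])
        assert len(scan) == 4
        full = scan[scan.r_exact == 1e4]
        assert np.all(full.abs_dE < 1e-12)
        assert np.all(full.abs_dFmax < 1e-12)

    def test_median_monotone_in_order(self):
        rows = []
        for seed in range(10):
            cloud, _ = make_charge_cloud(10, extent=3.0, seed=100 + seed)
            env, _ = make_charge_cloud(20, extent=50.0, seed=200 + seed)
            keep = np.linalg.norm(env.positions - cloud.centroid, axis=1) > 10.0
            scan = convergence_scan(
                cloud, env.positions[keep], env.charges[keep], [0.0], [1, 6]
            )
            rows.append(scan.set_index("order").abs_dE)
        p1 = np.median([r[1] for r in rows])
        p6 = np.median([r[6] for r in rows])
        assert p6 <= p1

    def test_empty_scan_rejected(self):
        cloud, _ = make_charge_cloud(3, seed=0)
        with pytest.raises(ValueError):
            convergence_scan(cloud, np.zeros((1, 3)) + 5, np.ones(1), [], [0])


def test_neutral_cloud_dipole_dominates_far_field():
    """With zero net charge the far potential falls off as r^-2 (dipole)."""
    rng = np.random.default_rng(21)
    pos = rng.normal(size=(8, 3))
    q = rng.normal(size=8)
    q -= q.mean()  # exactly neutral
    cloud = ChargeCloud(pos, q)
    direction = np.array([0.3, -0.5, 0.81])
    direction /= np.linalg.norm(direction)
    radii = np.array([20.0, 40.0, 80.0, 160.0])
    pts = cloud.centroid + radii[:, None] * direction
    assert abs(multipole_potential(expand_multipoles(cloud, 0), pts)[0]) < 1e-14
    phi = np.abs(exact_potential(cloud, pts))
    slope = np.polyfit(np.log(radii), np.log(phi), 1)[0]
    assert slope == pytest.approx(-2.0, abs=0.1)
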