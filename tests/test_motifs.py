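import numpy as np
import pytest
from scipy.integrate import solve_ivp

from metapatterns.motifs import (
    DEFAULT_SAMPLING_RANGES,
    EquilibriumConfig,
    LocalParameters,
    MotifTopology,
    build_motif,
    dynamics_jacobian,
    find_equilibrium,
    local_jacobian,
    local_rhs,
    permute_parameters,
    sample_feasible_parameters,
    sample_local_parameters,
)


def two_species_chain(d=0.1, r=1.0, K=1.0, A=1.0, B=1.0, e=0.5):
    motif = MotifTopology(
        name="chain2", links=((0, 1),), roles=("producer", "top_consumer")
    )
    return LocalParameters(
        motif=motif,
        r=np.array([r, 0.0]),
        K=np.array([K, np.nan]),
        d=np.array([0.0, d]),
        A={(0, 1): A},
        B={(0, 1): B},
        e={(0, 1): e},
    )


class TestTopology:
    @pytest.mark.parametrize(
        "name,n_links",
        [
            ("food_chain", 2),
            ("apparent_competition", 2),
            ("resource_competition", 2),
            ("intraguild_predation", 3),
        ],
    )
    def test_link_counts(self, name, n_links):
        assert len(build_motif(name).links) == n_links

    def test_food_chain_roles_and_links(self):
        m = build_motif("food_chain")
        assert m.links == ((0, 1), (1, 2))
        assert m.roles == ("producer", "intermediate_consumer", "top_consumer")

    def test_intraguild_predation_links(self):
        m = build_motif("intraguild_predation")
        assert m.links == ((0, 1), (0, 2), (1, 2))

    def test_species_zero_is_producer(self, motif):
        assert motif.roles[0] == "producer"

    def test_producers_never_predate_consumers_eat(self, motif):
        predators = {c for _, c in motif.links}
        for i in motif.producers:
            assert i not in predators
        for i in motif.consumers:
            assert len(motif.prey_of(i)) >= 1

    def test_unknown_name_lists_options(self):
        with pytest.raises(ValueError, match="food_chain.*intraguild_predation"):
            build_motif("foodchain ")

    def test_disconnected_topology_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            MotifTopology(
                name="bad",
                links=((0, 1), (2, 3)),
                roles=("producer", "top_consumer", "producer", "top_consumer"),
            )


class TestRhs:
    def test_hand_evaluated_chain(self):
        # producer: x*(r(1-x/K) - A y/(B+x)) = 0.5*(0.5 - 0.5/1.5)
        params = two_species_chain()
        f = local_rhs(params, [0.5, 0.5])
        assert f[0] == pytest.approx(0.5 * (0.5 - 0.5 / 1.5), abs=1e-12)
        # consumer: y*(e A x/(B+x) - d y) = 0.5*(0.5*0.5/1.5 - 0.05)
        assert f[1] == pytest.approx(0.5 * (0.5 * 0.5 / 1.5 - 0.05), abs=1e-12)

    def test_isolated_producer_fixed_point(self, motif, rng):
        params = sample_local_parameters(motif, rng)
        x = np.zeros(motif.n_species)
        x[0] = params.K[0]
        assert np.allclose(local_rhs(params, x), 0.0)

    def test_extinction_state_is_fixed_point(self, motif, rng):
        params = sample_local_parameters(motif, rng)
        assert np.all(local_rhs(params, np.zeros(motif.n_species)) == 0.0)

    def test_negative_density_rejected(self, rng):
        params = sample_local_parameters(build_motif("food_chain"), rng)
        with pytest.raises(ValueError, match="non-negative"):
            local_rhs(params, [-0.1, 1.0, 1.0])


class TestEquilibrium:
    def test_feasible_equilibria_have_tiny_residual(self, small_ensembles):
        for name, ens in small_ensembles.items():
            for params, eq in zip(ens.params, ens.equilibria):
                assert eq.feasible and np.all(eq.x_star > 1e-6)
                assert np.max(np.abs(local_rhs(params, eq.x_star))) < 1e-9

    def test_apparent_competition_exclusion_infeasible(self):
        # the heavily attacked producer cannot persist alongside a predator
        # sustained by the other producer, so no coexistence state exists
        motif = build_motif("apparent_competition")
        params = LocalParameters(
            motif=motif,
            r=np.array([2.0, 0.5, 0.0]),
            K=np.array([10.0, 1.0, np.nan]),
            d=np.array([0.0, 0.0, 0.05]),
            A={(0, 2): 1.0, (1, 2): 5.0},
            B={(0, 2): 1.0, (1, 2): 0.5},
            e={(0, 2): 1.0, (1, 2): 1.0},
        )
        eq = find_equilibrium(params)
        assert not eq.feasible
        # oracle: time-stepping drives producer 1 to the boundary
        sol = solve_ivp(
            lambda t, x: local_rhs(params, np.maximum(x, 0.0)),
            (0.0, 2000.0),
            [1.0, 0.5, 0.5],
            rtol=1e-8,
            atol=1e-12,
        )
        assert sol.y[1, -1] < 1e-6

    def test_consumer_with_prey_always_invades(self):
        # density-dependent mortality vanishes per-capita at low density, so
        # even a heavily harvested two-species chain keeps a coexistence state
        eq = find_equilibrium(two_species_chain(d=50.0))
        assert eq.feasible and eq.x_star[1] > 0

    def test_coexisting_chain_found(self):
        params = two_species_chain(d=0.1)
        eq = find_equilibrium(params)
        assert eq.feasible
        assert np.max(np.abs(local_rhs(params, eq.x_star))) < 1e-9


class TestJacobian:
    def test_logistic_producer_slope(self, rng):
        # with consumers absent, d f_0/d x_0 at x_0 = K is -r
        params = sample_local_parameters(build_motif("food_chain"), rng)
        x = np.array([params.K[0], 0.0, 0.0])
        J = dynamics_jacobian(params, x)
        assert J[0, 0] == pytest.approx(-params.r[0], rel=1e-12)

    def test_matches_central_finite_differences(self, small_ensembles):
        h = 1e-6
        for ens in small_ensembles.values():
            for params, eq in list(zip(ens.params, ens.equilibria))[:10]:
                x = eq.x_star
                J = dynamics_jacobian(params, x)
                n = len(x)
                J_fd = np.empty((n, n))
                for j in range(n):
                    dx = np.zeros(n)
                    dx[j] = h * max(1.0, abs(x[j]))
                    J_fd[:, j] = (local_rhs(params, x + dx) - local_rhs(params, x - dx)) / (
                        2 * dx[j]
                    )
                assert np.allclose(J, J_fd, rtol=1e-6, atol=1e-8)

    def test_sign_pattern_at_feasible_equilibria(self, small_ensembles):
        for ens in small_ensembles.values():
            for params, P in zip(ens.params, ens.P_stack):
                for p, c in params.motif.links:
                    assert P[c, p] > 0, "consumer gains from its resource"
                    assert P[p, c] < 0, "resource suffers from its consumer"

    def test_infeasible_equilibrium_rejected(self):
        from metapatterns.motifs import Equilibrium

        params = two_species_chain()
        eq = Equilibrium(np.array([1.0, -0.1]), False, np.inf)
        with pytest.raises(ValueError, match="feasible"):
            local_jacobian(params, eq)

    def test_permutation_equivariance(self, motif, rng):
        params, eq, _ = sample_feasible_parameters(motif, rng)
        P = local_jacobian(params, eq).P
        perm = [2, 0, 1]
        params_p = permute_parameters(params, perm)
        eq_p = find_equilibrium(params_p)
        assert eq_p.feasible
        Pi = np.zeros((3, 3))
        for old, new in enumerate(perm):
            Pi[new, old] = 1.0
        assert np.allclose(Pi @ P @ Pi.T, local_jacobian(params_p, eq_p).P, atol=1e-7)


class TestSampler:
    def test_values_within_bounds(self, motif, rng):
        for _ in range(50):
            params = sample_local_parameters(motif, rng)
            for i in motif.producers:
                assert DEFAULT_SAMPLING_RANGES["r"][0] <= params.r[i] <= DEFAULT_SAMPLING_RANGES["r"][1]
                assert DEFAULT_SAMPLING_RANGES["K"][0] <= params.K[i] <= DEFAULT_SAMPLING_RANGES["K"][1]
            for i in motif.consumers:
                assert DEFAULT_SAMPLING_RANGES["d"][0] <= params.d[i] <= DEFAULT_SAMPLING_RANGES["d"][1]
            for link in motif.links:
                for cls in ("A", "B", "e"):
                    lo, hi = DEFAULT_SAMPLING_RANGES[cls]
                    assert lo <= getattr(params, cls)[link] <= hi

    def test_same_seed_identical_draw(self, motif):
        a = sample_local_parameters(motif, np.random.default_rng(7))
        b = sample_local_parameters(motif, np.random.default_rng(7))
        assert np.array_equal(a.r, b.r) and np.array_equal(a.d, b.d)
        assert a.A == b.A and a.B == b.B and a.e == b.e

    def test_invalid_bounds_rejected(self, motif, rng):
        with pytest.raises(ValueError, match="lower >= upper"):
            sample_local_parameters(motif, rng, {"e": (1.0, 0.1)})

    def test_efficiency_mean_matches_uniform(self):
        rng = np.random.default_rng(2024)
        m = build_motif("food_chain")
        draws = np.array(
            [sample_local_parameters(m, rng).e[(0, 1)] for _ in range(10_000)]
        )
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.55) < 3 * se
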