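import numpy as np
import pytest

from metapatterns.motifs import build_motif
from metapatterns.robustness import (
    RobustnessGrid,
    average_over_subsets,
    build_grid,
    draw_local_ensemble,
    exclude_unstable,
    local_robustness_distribution,
    moments,
    scan_motif,
    spatial_robustness_distribution,
    total_robustness,
)
from metapatterns.stability import LABEL_CODES, PATTERN_FORMING, STABLE, UNSTABLE, classify

ST, US, PF = (LABEL_CODES[k] for k in (STABLE, UNSTABLE, PATTERN_FORMING))


def make_grid(labels):
    return RobustnessGrid(
        labels=np.asarray(labels, dtype=np.uint8),
        motif=build_motif("food_chain"),
        subset=(),
        constrained=False,
    )


class TestCounting:
    def test_two_by_two_example(self):
        grid = make_grid([[ST, PF], [ST, ST]])
        s = total_robustness(grid)
        assert (s.omega_st, s.omega_pf, s.omega_us) == (0.75, 0.25, 0.0)
        # column means of the stable indicator
        assert local_robustness_distribution(grid, STABLE).tolist() == [1.0, 0.5]
        assert spatial_robustness_distribution(grid, STABLE).tolist() == [0.5, 1.0]

    def test_all_stable(self):
        assert total_robustness(make_grid([[ST, ST], [ST, ST]])).omega_st == 1.0

    def test_fractions_partition_grid(self, rng):
        labels = rng.integers(0, 3, size=(13, 7))
        s = total_robustness(make_grid(labels))
        assert s.omega_st + s.omega_us + s.omega_pf == 1.0

    def test_distribution_means_equal_total(self, rng):
        grid = make_grid(rng.integers(0, 3, size=(20, 30)))
        s = total_robustness(grid)
        assert local_robustness_distribution(grid, PATTERN_FORMING).mean() == pytest.approx(s.omega_pf)
        assert spatial_robustness_distribution(grid, PATTERN_FORMING).mean() == pytest.approx(s.omega_pf)


class TestMoments:
    def test_constant_distribution(self):
        m = moments(np.full(5, 0.3), np.full(7, 0.3))
        assert m.variance_local == 0.0 and m.skew_local == 0.0

    def test_symmetric_two_point(self):
        m = moments(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert m.variance_local == pytest.approx(0.25)
        assert m.skew_local == pytest.approx(0.0, abs=1e-12)

    def test_skewed_three_point(self):
        m = moments(np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, 1.0]))
        assert m.shared_mean == pytest.approx(1 / 3)
        assert m.variance_local == pytest.approx(2 / 9)
        assert m.skew_local == pytest.approx(1 / np.sqrt(2))

    def test_mismatched_means_rejected(self):
        with pytest.raises(ValueError, match="share a mean"):
            moments(np.array([0.0, 1.0]), np.array([1.0, 1.0]))


class TestExcludeUnstable:
    def test_drops_unstable_rows(self):
        grid = make_grid([[US, US], [ST, PF]])
        sub = exclude_unstable(grid)
        assert sub.labels.shape == (1, 2)
        s = total_robustness(sub)
        assert s.omega_pf + s.omega_st == 1.0

    def test_all_unstable_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            exclude_unstable(make_grid([[US], [US]]))


class TestBuildGrid:
    def test_degenerate_grid_matches_classify(self, small_ensembles):
        ens = small_ensembles["food_chain"]
        sub_ens = type(ens)(
            motif=ens.motif,
            params=ens.params[:1],
            equilibria=ens.equilibria[:1],
            P_stack=ens.P_stack[:1],
            lam0=ens.lam0[:1],
            n_discarded=0,
        )
        rng = np.random.default_rng(3)
        grid = build_grid(
            ens.motif, ((0, 1), (1, 0)), False, 1, 1, rng, local_ensemble=sub_ens
        )
        # rebuild the same connectivity draw and compare against classify
        from metapatterns.dispersal import sample_connectivity, sign_pattern

        C = sample_connectivity(
            sign_pattern(ens.motif), ((0, 1), (1, 0)), False, np.random.default_rng(3)
        ).C
        expected = classify(ens.P_stack[0], C).label
        assert grid.labels[0, 0] == LABEL_CODES[expected]

    def test_unstable_rows_broadcast(self, small_ensembles):
        ens = small_ensembles["apparent_competition"]
        rng = np.random.default_rng(5)
        grid = build_grid(
            ens.motif, ((0, 2), (2, 0)), False, 40, 20, rng, local_ensemble=ens
        )
        for i, lam0 in enumerate(ens.lam0):
            if lam0 > 1e-9:
                assert np.all(grid.labels[i] == US)
            else:
                assert np.all(grid.labels[i] != US)

    def test_same_seed_identical_grids(self, small_ensembles):
        ens = small_ensembles["food_chain"]
        grids = [
            build_grid(
                ens.motif,
                ((0, 1),),
                True,
                40,
                15,
                np.random.default_rng(11),
                local_ensemble=ens,
            )
            for _ in range(2)
        ]
        assert np.array_equal(grids[0].labels, grids[1].labels)

    def test_shared_mean_identity_on_real_grid(self, small_ensembles):
        ens = small_ensembles["intraguild_predation"]
        grid = build_grid(
            ens.motif,
            ((0, 1), (1, 0), (1, 2)),
            False,
            40,
            25,
            np.random.default_rng(2),
            local_ensemble=ens,
        )
        s = total_robustness(grid)
        for label, omega in ((STABLE, s.omega_st), (PATTERN_FORMING, s.omega_pf)):
            assert local_robustness_distribution(grid, label).mean() == pytest.approx(omega)
            assert spatial_robustness_distribution(grid, label).mean() == pytest.approx(omega)


class TestScanMotif:
    def test_row_layout_and_subset_counts(self):
        df, info = scan_motif("food_chain", False, n_P=10, n_C=8, seed=21)
        # one row per subset: sum_k C(4, k) = 16
        assert len(df) == 16
        assert set(df["n_cross"]) == {0, 1, 2, 3, 4}
        assert len(df[df.n_cross == 0]) == 1 and len(df[df.n_cross == 4]) == 1
        avg = average_over_subsets(df)
        assert len(avg) == 5  # motif maximum + 1

    def test_unstable_fraction_matched_across_flags(self):
        a, _ = scan_motif("food_chain", False, n_P=15, n_C=10, seed=8)
        b, _ = scan_motif("food_chain", True, n_P=15, n_C=10, seed=8)
        assert np.array_equal(a["omega_us"].values, b["omega_us"].values)
        assert a["omega_us"].nunique() == 1  # depends only on P

    def test_monte_carlo_consistency_under_doubling(self):
        kw = dict(n_cross_values=[4], seed=31)
        small, _ = scan_motif("food_chain", False, n_P=60, n_C=60, **kw)
        big, _ = scan_motif("food_chain", False, n_P=120, n_C=120, **kw)
        p1, p2 = small["omega_pf"].iloc[0], big["omega_pf"].iloc[0]
        se = np.sqrt(max(p1, p2) * (1 - max(p1, p2)) / (60 * 60))
        assert abs(p1 - p2) < 3 * se
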