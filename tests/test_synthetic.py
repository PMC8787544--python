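import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import vfarch
from vfarch.archetypes import ArchetypeModel, FitOptions, decompose_matrix, fit_archetypes
from vfarch.grids import GRID_24_2, GRID_30_2
from vfarch.pipeline import td_matrix
from vfarch.synthetic import (
    CohortConfig,
    default_normative_map,
    make_pattern_library,
    simulate_controls,
    simulate_mixture,
    simulate_on_cohort,
)
from vfarch.vf_core import normalize_record


def model_from_library(lib):
    """Use the library patterns themselves as a fixed archetype basis."""
    P = lib.patterns
    return ArchetypeModel(
        k=P.shape[0],
        archetype_td=P,
        rw_percent=np.full(P.shape[0], 100.0 / P.shape[0]),
        avg_td=P.mean(axis=1),
        order=np.arange(P.shape[0]),
        fit_rss=0.0,
    )


class TestPatternLibrary:
    def test_normal_pattern_is_flat_zero(self, lib):
        assert np.array_equal(lib.pattern("normal"), np.zeros(52))
        assert lib.avg_td("normal") > -2.0

    def test_diffuse_depth(self, lib):
        assert lib.avg_td("diffuse-severe") == pytest.approx(-30.0)

    def test_superior_altitudinal_respects_hemifield(self, lib):
        xy = np.asarray(GRID_24_2.analysis_locations)
        pat = lib.pattern("superior-altitudinal")
        sup, inf = pat[xy[:, 1] > 0], pat[xy[:, 1] < 0]
        assert sup.mean() <= inf.mean() - 10.0
        assert np.all(pat[xy[:, 1] < 0] == 0)

    def test_mask_depth_configurable(self):
        lib = make_pattern_library(depth=-15.0)
        xy = np.asarray(GRID_24_2.analysis_locations)
        pat = lib.pattern("superior-altitudinal")
        assert np.all(pat[xy[:, 1] > 0] == -15.0)

    def test_all_patterns_finite_and_regional(self, lib):
        assert np.all(np.isfinite(lib.patterns))
        xy = np.asarray(GRID_24_2.analysis_locations)
        x, y = xy[:, 0], xy[:, 1]
        pairs = [
            ("inferior-altitudinal", y < 0, y > 0),
            ("nasal-hemianopia", x < 0, x > 0),
            ("temporal-hemianopia", x > 0, x < 0),
        ]
        for name, inside, outside in pairs:
            pat = lib.pattern(name)
            assert pat[inside].mean() <= pat[outside].mean() - 10.0, name

    def test_unknown_name_and_wrong_grid_rejected(self, lib):
        with pytest.raises(ValueError):
            lib.pattern("spiral")
        with pytest.raises(ValueError):
            make_pattern_library(GRID_30_2)


class TestONCohort:
    def test_pure_normal_noise_free_is_fixed_at_zero(self, lib):
        cfg = CohortConfig(
            n_eyes=1, noise_sigma=0.0, alpha={"normal": 1.0},
            projected_fraction=0.0, unreliable_fraction=0.0, seed=0,
        )
        recs, truth = simulate_on_cohort(lib, cfg)
        for r in recs:
            assert np.allclose(normalize_record(r).td, 0.0)
            assert r.md == 0.0

    def test_pure_diffuse_without_recovery_is_constant(self, lib):
        cfg = CohortConfig(
            n_eyes=1, noise_sigma=0.0, alpha={"diffuse-severe": 1.0},
            tau_median=np.inf, tau_sigma=0.0,
            projected_fraction=0.0, unreliable_fraction=0.0, seed=0,
        )
        recs, truth = simulate_on_cohort(lib, cfg)
        tds = np.vstack([normalize_record(r).td for r in recs])
        assert np.allclose(tds, tds[0])
        assert np.allclose(tds[0], lib.pattern("diffuse-severe"))

    def test_baseline_md_matches_generator_law(self, lib):
        cfg = CohortConfig(seed=0)
        recs, _ = simulate_on_cohort(lib, cfg)
        md = [r.md for r in recs if r.visit_day == 0]
        assert abs(np.mean(md) - cfg.expected_baseline_md(lib)) < 3.0
        assert abs(np.mean(md) - cfg.target_baseline_md) < 3.0

    def test_ground_truth_on_simplex_every_visit(self, lib):
        cfg = CohortConfig(n_eyes=25, seed=1)
        _, truth = simulate_on_cohort(lib, cfg)
        for W in truth.weights.values():
            assert np.all(W >= 0)
            assert np.allclose(W.sum(axis=1), 1.0, atol=1e-9)

    def test_recovery_moves_weight_to_normal_pattern(self, lib):
        cfg = CohortConfig(n_eyes=30, seed=2)
        _, truth = simulate_on_cohort(lib, cfg)
        i_norm = lib.index("normal")
        for W in truth.weights.values():
            assert W[-1, i_norm] >= W[0, i_norm] - 1e-12

    def test_slower_recovery_leaves_worse_late_fields(self, lib):
        def late_md(tau, seed):
            cfg = CohortConfig(
                n_eyes=40, tau_median=tau, tau_sigma=0.0, noise_sigma=0.0,
                projected_fraction=0.0, unreliable_fraction=0.0, seed=seed,
            )
            recs, _ = simulate_on_cohort(lib, cfg)
            return np.mean([r.md for r in recs if r.visit_day == 365])

        # slower recovery (larger tau) leaves a larger deficit at one year
        assert all(late_md(300.0, s) < late_md(30.0, s) for s in range(3))

    def test_left_eye_records_mirror_consistently(self, lib):
        # an x-asymmetric pure pattern survives the native-layout round trip
        cfg = CohortConfig(
            n_eyes=2, noise_sigma=0.0, alpha={"nasal-step": 1.0},
            tau_median=np.inf, tau_sigma=0.0,
            projected_fraction=0.0, unreliable_fraction=0.0, seed=3,
        )
        recs, _ = simulate_on_cohort(lib, cfg)
        lateralities = {r.laterality for r in recs}
        assert lateralities == {"left", "right"}
        for r in recs:
            assert np.allclose(normalize_record(r).td, lib.pattern("nasal-step"))

    def test_projected_baselines_are_all_zero_sensitivity(self, lib):
        cfg = CohortConfig(n_eyes=40, projected_fraction=0.25, seed=4)
        recs, _ = simulate_on_cohort(lib, cfg)
        proj = [r for r in recs if r.projected_baseline]
        assert proj
        norm = default_normative_map(lib.grid)
        for r in proj:
            assert r.visit_day == 0
            assert np.all(r.sensitivity == 0.0)
            assert np.allclose(normalize_record(r).td, -norm.normal_sensitivity)

    def test_seeding_contract(self, lib):
        cfg = CohortConfig(n_eyes=5, seed=7)
        a, _ = simulate_on_cohort(lib, cfg)
        b, _ = simulate_on_cohort(lib, cfg)
        c, _ = simulate_on_cohort(lib, CohortConfig(n_eyes=5, seed=8))
        assert all(np.array_equal(x.td, y.td) for x, y in zip(a, b))
        assert any(not np.array_equal(x.td, y.td) for x, y in zip(a, c))


class TestControls:
    def test_zero_jitter_zero_noise_is_exactly_normal(self, lib):
        recs, _ = simulate_controls(lib, n_eyes=3, n_visits=3, jitter_scale=0.0,
                                    noise_sigma=0.0, seed=0)
        model = model_from_library(lib)
        for r in recs:
            td = normalize_record(r).td
            assert np.allclose(td, 0.0)
            w = vfarch.decompose(td, model)
            assert w[lib.index("normal")] == pytest.approx(100.0, abs=1e-8)

    def test_default_controls_rarely_show_severe_loss_weights(self, lib, on_model16):
        recs, _ = simulate_controls(lib, seed=0)
        W = decompose_matrix(td_matrix(recs), on_model16)
        severe = np.flatnonzero(on_model16.avg_td < -15.0)
        frac = np.mean((W[:, severe] < 7.0).all(axis=1))
        assert frac >= 0.95

    def test_reliability_always_passes_control_policy(self, lib):
        from vfarch.vf_core import CONTROL_RELIABILITY_POLICY, reliability_pass

        recs, _ = simulate_controls(lib, n_eyes=10, seed=1)
        assert all(reliability_pass(r, CONTROL_RELIABILITY_POLICY) for r in recs)

    def test_seeding_contract(self, lib):
        a, _ = simulate_controls(lib, n_eyes=4, seed=0)
        b, _ = simulate_controls(lib, n_eyes=4, seed=0)
        c, _ = simulate_controls(lib, n_eyes=4, seed=1)
        assert all(np.array_equal(x.td, y.td) for x, y in zip(a, b))
        assert any(not np.array_equal(x.td, y.td) for x, y in zip(a, c))


class TestEndToEndRecovery:
    def test_benchmark_patterns_are_hull_vertices(self, lib):
        from vfarch.archetypes import simplex_ls
        from vfarch.synthetic import DEFAULT_MIXTURE_PATTERNS

        P = np.vstack([lib.pattern(n) for n in DEFAULT_MIXTURE_PATTERNS])
        for j in range(P.shape[0]):
            others = np.delete(P, j, axis=0)
            w = simplex_ls(P[j], others)
            # no pattern is a convex combination of the others
            assert np.linalg.norm(w @ others - P[j]) > 1.0

    def test_independent_patterns_are_affinely_independent(self, lib):
        from vfarch.synthetic import INDEPENDENT_MIXTURE_PATTERNS

        P = np.vstack([lib.pattern(n) for n in INDEPENDENT_MIXTURE_PATTERNS])
        assert np.linalg.matrix_rank(P - P[0]) == P.shape[0] - 1

    def test_noise_free_cohort_recovers_true_weights(self, lib):
        from vfarch.synthetic import INDEPENDENT_MIXTURE_PATTERNS

        X, W_true, P = simulate_mixture(
            lib,
            pattern_names=INDEPENDENT_MIXTURE_PATTERNS,
            n=400,
            noise_sigma=0.0,
            seed=3,
            include_pure=True,
        )
        model = fit_archetypes(X, P.shape[0], FitOptions(n_restarts=5, seed=3))
        D = np.abs(model.archetype_td[:, None, :] - P[None]).mean(-1)
        r, c = linear_sum_assignment(D)
        W_est = decompose_matrix(X, model) / 100.0
        aligned = np.zeros_like(W_est)
        for mi, pi in zip(r, c):
            aligned[:, pi] = W_est[:, mi]
        assert np.abs(aligned - W_true).mean() < 0.01
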