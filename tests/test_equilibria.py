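"""Fixed-point catalogues, stability, Hopf thresholds, parameter regions."""

import numpy as np
import pytest

from riskcoev import (CoupledSystem, FeedbackSpec, GameParams,
                      classify_region, classify_stability,
                      enumerate_fixed_points, find_threshold_roots,
                      first_lyapunov_coefficient, gamma, hopf_threshold,
                      hopf_threshold_numeric, interior_fixed_point,
                      system_rhs)
from riskcoev.presets import get_preset


class TestThresholdRoots:
    def test_tangency_at_the_mode(self):
        params = GameParams(N=6, M=3, b=1.0, c=0.3456)
        roots = find_threshold_roots(params)
        assert roots == (0.4, 0.4)

    def test_two_roots_bracket_the_mode(self, game):
        x1, x2 = find_threshold_roots(game)
        assert x1 < game.gamma_mode < x2
        assert gamma(x1, game) == pytest.approx(game.c / game.b, abs=1e-12)
        assert gamma(x2, game) == pytest.approx(game.c / game.b, abs=1e-12)

    def test_no_roots_above_the_peak(self):
        assert find_threshold_roots(GameParams(N=6, M=3, b=1.0, c=0.5)) == ()


class TestFixedPointCatalogue:
    @pytest.mark.parametrize("preset, expected_count", [
        ("fig4-top", 7), ("fig4-hopf", 7), ("fig4-low", 7),
        ("fig4-boundary", 6),
        ("fig6-top", 7), ("fig6-hopf", 7), ("fig6-low", 7),
        ("fig6-boundary", 6),
    ])
    def test_counts_match_regime(self, preset, expected_count):
        assert len(enumerate_fixed_points(get_preset(preset))) == expected_count

    def test_four_corners_always_present(self, system_I_bistable):
        fps = enumerate_fixed_points(system_I_bistable)
        corners = {(fp.x, fp.r) for fp in fps if fp.kind == "corner"}
        assert corners == {(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)}

    @pytest.mark.parametrize("preset", [
        "fig4-top", "fig4-hopf", "fig4-low", "fig4-boundary",
        "fig6-top", "fig6-hopf", "fig6-low", "fig6-boundary"])
    def test_every_point_annihilates_the_field(self, preset):
        system = get_preset(preset)
        for fp in enumerate_fixed_points(system):
            dx, dr = system_rhs(fp.x, fp.r, system)
            assert np.hypot(dx, dr) < 1e-10

    def test_interior_point_requires_strict_risk_below_one(self, game):
        # u=4 puts the balance point at x=0.8 where Gamma = 0.0512 < c/b
        fb = FeedbackSpec(variant="linear", u=4.0)
        assert interior_fixed_point(game, fb) is None
        # at u=2 the interior risk is 0.6075 < 1
        fb = FeedbackSpec(variant="linear", u=2.0)
        assert interior_fixed_point(game, fb) == pytest.approx(
            (2 / 3, 0.6075))

    def test_custom_feedback_unsupported(self, game):
        fb = FeedbackSpec(variant="custom", func=lambda x, r: 0.0)
        with pytest.raises(ValueError):
            enumerate_fixed_points(CoupledSystem(game=game, feedback=fb))


class TestStability:
    def test_interior_stable_above_threshold(self, system_I_bistable):
        fps = enumerate_fixed_points(system_I_bistable)
        interior = next(fp for fp in fps if fp.kind == "interior")
        assert interior.stability == "stable"
        stable = {(fp.x, fp.r) for fp in fps if fp.stability == "stable"}
        assert stable == {(0.0, 1.0), (interior.x, interior.r)}

    def test_interior_unstable_below_threshold(self, game):
        system = get_preset("fig4-low")
        interior = next(fp for fp in enumerate_fixed_points(system)
                        if fp.kind == "interior")
        assert interior.stability == "unstable"

    def test_boundary_root_stable_without_interior(self):
        system = get_preset("fig4-boundary")
        fps = enumerate_fixed_points(system)
        x2 = max(fp.x for fp in fps if fp.kind == "boundary_root")
        stable = {(fp.x, fp.r) for fp in fps if fp.stability == "stable"}
        assert stable == {(0.0, 1.0), (x2, 1.0)}
        assert x2 < 4.0 / 5.0  # x2* below the risk balance point u/(1+u)

    def test_interior_center_at_hopf(self, system_I_hopf, system_II_hopf):
        for system in (system_I_hopf, system_II_hopf):
            interior = next(fp for fp in enumerate_fixed_points(system)
                            if fp.kind == "interior")
            assert interior.stability == "center_hopf"
            eigs = np.array(interior.eigenvalues)
            assert np.max(np.abs(eigs.real)) < 1e-9
            assert np.all(np.abs(eigs.imag) > 1e-3)

    def test_tragedy_corner_always_stable(self):
        """(0,1) is evolutionarily stable for every sampled regime."""
        rng = np.random.default_rng(82954)
        for _ in range(500):
            N = int(rng.integers(3, 13))
            M = int(rng.integers(2, N))
            b = float(rng.uniform(0.5, 3.0))
            c = float(rng.uniform(0.02, 0.98)) * b
            game = GameParams(N=N, M=M, b=b, c=c)
            if rng.random() < 0.5:
                fb = FeedbackSpec(variant="linear",
                                  u=float(rng.uniform(0.05, 6.0)))
            else:
                fb = FeedbackSpec(variant="exponential",
                                  T=float(rng.uniform(0.05, 0.95)),
                                  beta=float(rng.uniform(0.5, 40.0)))
            eps = float(rng.choice([0.01, 0.1, 1.0]))
            system = CoupledSystem(game=game, feedback=fb, eps=eps)
            assert classify_stability(system, (0.0, 1.0)) == "stable"
            labels = {fp.stability for fp in enumerate_fixed_points(system)}
            assert labels <= {"stable", "unstable", "saddle", "center_hopf",
                              "marginal_degenerate"}

    @pytest.mark.parametrize("eps", [0.01, 0.1, 1.0])
    def test_labels_invariant_to_feedback_speed(self, game, eps):
        for fb in (FeedbackSpec(variant="linear", u=2.0),
                   FeedbackSpec(variant="exponential", T=0.5, beta=10.0)):
            ref = [fp.stability for fp in enumerate_fixed_points(
                CoupledSystem(game=game, feedback=fb, eps=0.1))]
            got = [fp.stability for fp in enumerate_fixed_points(
                CoupledSystem(game=game, feedback=fb, eps=eps))]
            assert got == ref


class TestHopfThreshold:
    def test_reference_values(self, game):
        assert hopf_threshold("linear", game) == pytest.approx(2 / 3)
        assert hopf_threshold("exponential", game) == pytest.approx(0.4)
        assert hopf_threshold("exponential",
                              GameParams(N=10, M=5)) == pytest.approx(4 / 9)

    def test_numeric_trace_zero_agrees_with_closed_form(self):
        for N in range(4, 14):
            for M in range(3, N):
                game = GameParams(N=N, M=M, b=1.0, c=0.05)
                for family in ("linear", "exponential"):
                    analytic = hopf_threshold(family, game)
                    numeric = hopf_threshold_numeric(family, game)
                    assert abs(analytic - numeric) < 1e-10

    @pytest.mark.parametrize("eps", [0.01, 0.1, 1.0])
    def test_threshold_independent_of_eps(self, game, eps):
        for family in ("linear", "exponential"):
            assert hopf_threshold_numeric(family, game, eps=eps) == \
                pytest.approx(hopf_threshold(family, game), abs=1e-10)


class TestFirstLyapunovCoefficient:
    def test_negative_at_both_hopf_points(self, system_I_hopf,
                                          system_II_hopf):
        """Both bifurcations are supercritical: a stable cycle is born."""
        assert first_lyapunov_coefficient(system_I_hopf) < 0
        assert first_lyapunov_coefficient(system_II_hopf) < 0

    def test_rejected_off_threshold(self, system_I_bistable):
        with pytest.raises(ValueError):
            first_lyapunov_coefficient(system_I_bistable)

    def test_rejected_without_interior_point(self):
        with pytest.raises(ValueError):
            first_lyapunov_coefficient(get_preset("fig4-boundary"))


class TestRegionClassifier:
    @pytest.mark.parametrize("fb, expected", [
        (FeedbackSpec(variant="linear", u=2.0), "bistable_interior"),
        (FeedbackSpec(variant="linear", u=0.5), "defection_only"),
        (FeedbackSpec(variant="linear", u=2 / 3), "hopf_line"),
        (FeedbackSpec(variant="linear", u=4.0), "bistable_boundary"),
        (FeedbackSpec(variant="exponential", T=0.5, beta=10.0),
         "bistable_interior"),
        (FeedbackSpec(variant="exponential", T=0.2, beta=10.0),
         "defection_only"),
        (FeedbackSpec(variant="exponential", T=0.4, beta=10.0), "hopf_line"),
        (FeedbackSpec(variant="exponential", T=0.8, beta=10.0),
         "bistable_boundary"),
    ])
    def test_reference_regions(self, game, fb, expected):
        region = classify_region(game, fb)
        assert region.label == expected
        # the tragedy corner is in every stable set
        assert any(fp.is_at(0.0, 1.0) for fp in region.stable_set)
        if expected == "defection_only":
            assert len(region.stable_set) == 1
        if expected == "hopf_line":
            assert region.limit_cycle

    def test_sweep_produces_all_four_labels(self, game):
        labels = set()
        for u in np.linspace(0.1, 5.0, 15):
            for cb in np.linspace(0.02, 0.4, 12):
                g = GameParams(N=6, M=3, b=1.0, c=float(cb))
                fb = FeedbackSpec(variant="linear", u=float(u))
                labels.add(classify_region(g, fb).label)
        labels.add(classify_region(
            game, FeedbackSpec(variant="linear", u=2 / 3)).label)
        assert labels == {"bistable_interior", "hopf_line", "defection_only",
                          "bistable_boundary"}
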