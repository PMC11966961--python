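"""1-D tissue simulators, pattern segmentation and metrics."""

import numpy as np
import pytest

from morphogrn import (
    ConfigurationError,
    EnhancerPerturbation,
    EnhancerSwitchSpec,
    GradientSpec,
    SizeMismatchError,
    SpaceTimeField,
    Tissue1D,
    gradient_value,
    mismatch_score,
    run_additive_stripe_enhancers,
    run_enhancer_switching,
    run_french_flag_thresholds,
    run_nested_feedforward,
    run_speed_regulation,
    run_two_gradient_model,
    segment_domains,
    wave_trajectory,
)


def _field_from(values, genes=("G",)):
    """Tiny synthetic field: values indexed (time, cell, gene)."""
    values = np.asarray(values, dtype=float)
    times = np.linspace(0, 1, values.shape[0])
    return SpaceTimeField(times, tuple(genes), values)


class TestFrenchFlag:
    def test_steady_state_is_half_max_where_m_crosses_k(
        self, tissue100, falling_gradient
    ):
        field = run_french_flag_thresholds(tissue100, falling_gradient, t_end=30.0)
        M = gradient_value(falling_gradient, tissue100.positions)
        snap = field.slice_at(field.times[-1])
        # the activated gene G1 (K=0.1) passes 1/(2 lam) where M = K
        cell = int(np.argmin(np.abs(M - 0.1)))
        assert snap[cell, 0] == pytest.approx(0.5, abs=0.06)

    def test_strong_repression_silences_high_m_cells(self, tissue100, falling_gradient):
        field = run_french_flag_thresholds(tissue100, falling_gradient, t_end=30.0)
        snap = field.slice_at(field.times[-1])
        assert snap[0, 2] < 1e-3  # G3 strongly repressed where M ~ 1

    def test_threshold_ordering_sets_boundary_ordering(
        self, tissue100, falling_gradient
    ):
        field = run_french_flag_thresholds(tissue100, falling_gradient, t_end=30.0)
        snap = field.slice_at(field.times[-1])
        # boundary = where each activated gene falls below half its max
        b = [int(np.argmin(np.abs(snap[:, g] - 0.5 * snap[:, g].max()))) for g in (0, 1)]
        assert b[0] > b[1]  # stronger activation (lower K) reaches further down-gradient

    def test_violated_ordering_warns_but_runs(self, tissue100, falling_gradient):
        with pytest.warns(UserWarning):
            run_french_flag_thresholds(
                tissue100, falling_gradient, K=(0.5, 0.1, 0.1, 0.5), t_end=1.0
            )


class TestTwoGradient:
    def test_domains_are_interior_and_mirror_symmetric(self, tissue100):
        field = run_two_gradient_model(tissue100)
        summary = segment_domains(field, threshold_mode="half_max")
        doms = {g: [d for d in summary.domains if d[0] == g] for g in ("G1", "G2")}
        for g in ("G1", "G2"):
            assert len(doms[g]) == 1
            _, start, end = doms[g][0]
            assert start > 0 and end < 99
        snap = field.slice_at(field.times[-1])
        np.testing.assert_allclose(snap[:, 0], snap[::-1, 1], atol=1e-6)

    def test_double_repression_silences_shared_high_cells(self, tissue100):
        m1 = GradientSpec(form="static_sigmoid", k=-0.2, x0=35.0)
        field = run_two_gradient_model(tissue100, m1=m1)
        snap = field.slice_at(field.times[-1])
        # at x=0, M1 ~ 1 strongly represses G1
        assert snap[0, 0] < 1e-3


class TestNestedFeedforward:
    def test_five_ordered_abutting_domains(self, tissue100, falling_gradient):
        field = run_nested_feedforward(tissue100, falling_gradient)
        summary = segment_domains(field, threshold_mode="argmax")
        genes = [d[0] for d in summary.domains]
        assert genes == ["G5", "G4", "G3", "G2", "G1"]  # high-M to low-M end
        # tiling without overlap
        edges = [(d[1], d[2]) for d in summary.domains]
        assert edges[0][0] == 0 and edges[-1][1] == 99
        for (_, e), (s, _) in zip(edges[:-1], edges[1:]):
            assert s == e + 1

    def test_top_gene_is_unrepressed_above_its_threshold(
        self, tissue100, falling_gradient
    ):
        field = run_nested_feedforward(tissue100, falling_gradient, t_end=40.0)
        M = gradient_value(falling_gradient, tissue100.positions)
        snap = field.slice_at(field.times[-1])
        above = M > 0.5 * 1.5  # comfortably above K_5 = 0.5
        assert np.all(snap[above, 4] > 0.5)

    def test_zero_gradient_silences_everything(self, tissue100):
        flat = GradientSpec(form="static_sigmoid", k=-1.0, x0=-1e4)  # M ~ 0 everywhere
        field = run_nested_feedforward(tissue100, flat, t_end=10.0)
        assert field.expression.max() < 1e-6

    def test_too_few_genes_rejected(self, tissue100, falling_gradient):
        with pytest.raises(ConfigurationError):
            run_nested_feedforward(tissue100, falling_gradient, N=2)


class TestAdditiveStripes:
    def test_two_disjoint_domains(self, tissue100):
        field = run_additive_stripe_enhancers(tissue100)
        summary = segment_domains(field, threshold_mode="half_max")
        g_domains = [d for d in summary.domains if d[0] == "G"]
        assert len(g_domains) == 2
        (_, s1, e1), (_, s2, e2) = sorted(g_domains, key=lambda d: d[1])
        assert e1 < s2  # disjoint stripes

    def test_gene_settles_at_summed_enhancer_activity(self, tissue100):
        lam = 0.8
        field = run_additive_stripe_enhancers(tissue100, lam=lam, t_end=40.0)
        snap = field.slice_at(field.times[-1])
        G, E1, E2 = snap[:, 0], snap[:, 1], snap[:, 2]
        np.testing.assert_allclose(G, (E1 + E2) / lam, rtol=1e-4, atol=1e-8)

    def test_silent_cells_where_both_enhancers_off(self, tissue100):
        field = run_additive_stripe_enhancers(tissue100, t_end=40.0)
        snap = field.slice_at(field.times[-1])
        mid = 50  # both morphogens ~ 0.5 there: strong repression on both enhancers
        assert snap[mid, 0] < 0.1
        assert snap[mid, 0] < 0.3 * snap[:, 0].max()


class TestSpeedRegulation:
    def test_zero_morphogen_freezes_cells_entirely(self):
        tissue = Tissue1D(5)
        off = GradientSpec(form="static_sigmoid", k=-1.0, x0=-1e4)  # M ~ 0
        field = run_speed_regulation(tissue, off, t_end=50.0, speed_scope="full_rhs")
        # every cell stays pinned at the initial state (gene 1 high)
        np.testing.assert_allclose(
            field.expression[-1], field.expression[0], atol=1e-9
        )

    def test_higher_morphogen_progresses_sooner(self, falling_gradient):
        tissue = Tissue1D.at_positions([10.0, 80.0])  # high-M and low-M cells
        field = run_speed_regulation(tissue, falling_gradient, t_end=120.0)
        g2 = field.expression[:, :, 1]
        g1 = field.expression[:, :, 0]
        overtake = [
            np.argmax(g2[:, c] > g1[:, c]) if np.any(g2[:, c] > g1[:, c]) else np.inf
            for c in (0, 1)
        ]
        assert overtake[0] < overtake[1]

    def test_waves_drift_toward_low_m_end(self, tissue100, falling_gradient):
        field = run_speed_regulation(tissue100, falling_gradient, t_end=120.0)
        for gene in ("G2", "G3", "G4"):
            pos = wave_trajectory(field, gene)
            steps = np.diff(pos[~np.isnan(pos)])
            assert np.all(steps >= 0)  # low-M end is at large x

    def test_mirrored_gradient_mirrors_drift(self, tissue100):
        rising = GradientSpec(form="static_sigmoid", k=0.1, x0=50.0)
        field = run_speed_regulation(tissue100, rising, t_end=120.0)
        pos = wave_trajectory(field, "G3")
        steps = np.diff(pos[~np.isnan(pos)])
        assert np.all(steps <= 0)

    def test_cells_are_autonomous(self, tissue100, falling_gradient):
        full = run_speed_regulation(tissue100, falling_gradient, t_end=60.0)
        keep = [5, 33, 71]
        sub = run_speed_regulation(
            Tissue1D.at_positions([float(c) for c in keep]),
            falling_gradient,
            t_end=60.0,
        )
        for j, c in enumerate(keep):
            np.testing.assert_allclose(
                sub.expression[:, j, :], full.expression[:, c, :], atol=1e-4
            )

    def test_retracting_front_freezes_an_ordered_pattern(self, tissue100):
        front = GradientSpec(form="retracting_sigmoid", k=-0.2, x0=99.0, v=-1.0)
        field = run_speed_regulation(tissue100, front, t_end=130.0)
        summary = segment_domains(field, threshold_mode="argmax")
        genes = [int(d[0][1:]) for d in summary.domains]
        assert len(genes) >= 3
        assert genes == sorted(genes, reverse=True)  # later fates where exposed longer

    def test_unknown_speed_scope_rejected(self, tissue100, falling_gradient):
        with pytest.raises(ConfigurationError):
            run_speed_regulation(
                tissue100, falling_gradient, speed_scope="half_rhs", t_end=1.0
            )


class TestEnhancerSwitching:
    def test_zero_morphogen_silences_dynamic_enhancers(self):
        tissue = Tissue1D(4)
        off = GradientSpec(form="static_sigmoid", k=-1.0, x0=-1e4)  # M ~ 0
        spec = EnhancerSwitchSpec(k_ts=1e-9)  # static contribution negligible
        field = run_enhancer_switching(tissue, off, spec, t_end=30.0)
        # with dynamics gated off, gene 1 only decays and nothing else rises
        assert np.all(np.diff(field.expression[:, :, 0], axis=0) <= 1e-9)
        assert field.expression[-1, :, 1:].max() < 1e-6

    def test_competitive_production_is_promoter_bounded(self):
        # even a grossly overactive enhancer cannot push the per-gene
        # production rate above k_t: levels stay below k_t / lam
        tissue = Tissue1D(10)
        grad = GradientSpec(form="static_sigmoid", k=-0.2, x0=5.0)
        pert = EnhancerPerturbation(gene_index=1, enhancer="dynamic", factor=1e4)
        spec = EnhancerSwitchSpec(integration="competitive", perturbation=pert)
        field = run_enhancer_switching(tissue, grad, spec, t_end=40.0)
        assert field.expression.max() <= spec.k_t / spec.lam + 1e-6

    def test_saturated_enhancers_reach_promoter_rate(self):
        # both weights huge: production -> k_t, level -> k_t / lam
        tissue = Tissue1D(2)
        grad = GradientSpec(form="static_sigmoid", k=-0.2, x0=50.0)  # M ~ 1
        spec = EnhancerSwitchSpec(
            integration="competitive", k_ed=1e6, k_es=1e6, theta_s=1e6, theta_w=1e6
        )
        field = run_enhancer_switching(tissue, grad, spec, t_end=40.0)
        assert field.expression[-1].max() == pytest.approx(
            spec.k_t / spec.lam, rel=1e-3
        )

    def test_additive_pattern_is_ordered_along_the_gradient(self, tissue100):
        grad = GradientSpec(form="static_sigmoid", k=-0.2, x0=50.0)
        field = run_enhancer_switching(tissue100, grad, EnhancerSwitchSpec(), t_end=120.0)
        summary = segment_domains(field, threshold_mode="argmax")
        genes = [int(d[0][1:]) for d in summary.domains]
        assert len(genes) >= 2
        assert genes == sorted(genes, reverse=True)  # later genes at higher M

    def test_invalid_rates_rejected(self):
        with pytest.raises(Exception):
            EnhancerSwitchSpec(k_td=0.0)
        with pytest.raises(Exception):
            EnhancerPerturbation(gene_index=1, factor=0.0)


class TestPatternMetrics:
    def test_single_bump_yields_one_domain(self):
        vals = np.zeros((3, 30, 1))
        vals[:, 10:21, 0] = 1.0
        summary = segment_domains(_field_from(vals), threshold_mode="half_max")
        assert summary.domains == (("G", 10, 20),)

    def test_two_gene_mirror_pattern_tiles_the_tissue(self):
        vals = np.zeros((2, 10, 2))
        vals[:, :5, 0] = 1.0
        vals[:, 5:, 1] = 1.0
        summary = segment_domains(_field_from(vals, ("A", "B")), threshold_mode="argmax")
        assert summary.domains == (("A", 0, 4), ("B", 5, 9))
        assert summary.boundaries == (5,)

    def test_all_zero_field_gives_empty_summary(self):
        summary = segment_domains(_field_from(np.zeros((2, 8, 1))))
        assert summary.domains == ()
        assert np.all(summary.identity == -1)

    def test_mismatch_identity_and_symmetry(self):
        vals_a = np.zeros((2, 10, 2))
        vals_a[:, :5, 0] = 1.0
        vals_a[:, 5:, 1] = 1.0
        vals_b = vals_a.copy()
        vals_b[:, 5:8, :] = vals_b[:, 5:8, ::-1]  # shift boundary by 3 cells
        a = segment_domains(_field_from(vals_a, ("A", "B")))
        b = segment_domains(_field_from(vals_b, ("A", "B")))
        assert mismatch_score(a, a) == 0.0
        assert mismatch_score(a, b) == mismatch_score(b, a) == pytest.approx(0.3)

    def test_completely_different_patterns_score_one(self):
        vals_a = np.zeros((1, 6, 2))
        vals_a[..., 0] = 1.0
        vals_b = np.zeros((1, 6, 2))
        vals_b[..., 1] = 1.0
        a = segment_domains(_field_from(vals_a, ("A", "B")))
        b = segment_domains(_field_from(vals_b, ("A", "B")))
        assert mismatch_score(a, b) == 1.0

    def test_size_mismatch_rejected(self):
        a = segment_domains(_field_from(np.ones((1, 5, 1))))
        b = segment_domains(_field_from(np.ones((1, 6, 1))))
        with pytest.raises(SizeMismatchError):
            mismatch_score(a, b)

    def test_static_bump_has_constant_wave_position(self):
        vals = np.zeros((5, 20, 1))
        vals[:, 7, 0] = 1.0
        pos = wave_trajectory(_field_from(vals), "G")
        np.testing.assert_array_equal(pos, 7.0)

    def test_flat_profile_position_is_undefined(self):
        pos = wave_trajectory(_field_from(np.zeros((4, 10, 1))), "G")
        assert np.all(np.isnan(pos))

    def test_long_format_export_round_trips(self, tmp_path):
        import pandas as pd

        vals = np.arange(12, dtype=float).reshape(2, 3, 2)
        field = _field_from(vals, ("A", "B"))
        path = tmp_path / "field.csv"
        field.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "cell", "gene", "value"]
        assert len(df) == 12
        back = df.pivot_table(index=["time", "cell"], columns="gene", values="value")
        np.testing.assert_allclose(back.to_numpy().reshape(vals.shape), vals)
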