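"""Mechanism decomposition: pooled OLS, correlations, compound joins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colloidquant.mechanism import (
    PAIRING_EFFICIENCY,
    PAIRING_INTERCEPT,
    CompoundSummary,
    MechanismFit,
    build_compound_summary,
    correlate_mechanism,
    fit_mechanism,
    fit_mechanism_panel,
)
from colloidquant.synthetic import (
    CompoundParams,
    PanelSpec,
    generate_mechanism_panel,
    latent_driver_compounds,
)


def _wells(x, y, compound="c"):
    return pd.DataFrame({"compound": compound, "puncta_per_cell": x,
                         "foci_per_cell": y})


def normal_equation_ols(x, y):
    """Closed-form (X'X)^-1 X'y — the independent regression oracle."""
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y))
    return beta[1], beta[0]


class TestFitMechanism:
    def test_exact_line_recovered(self):
        x = np.arange(6.0)
        fit = fit_mechanism(_wells(x, 2 * x + 1))
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            n = rng.integers(3, 21)
            x = rng.uniform(0, 10, n)
            x[0] = 0.0  # blocker anchor
            y = 0.4 * x + 1.2 + rng.normal(0, 0.3, n)
            fit = fit_mechanism(_wells(x, y))
            slope, intercept = normal_equation_ols(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_generator_roundtrip_within_2se(self):
        spec = PanelSpec(
            compounds=[CompoundParams("c1", 6.0, 0.3, 1.5, 1.0)],
            wells_per_compound=15, noise_sd=0.1, seed=12,
        )
        fit = fit_mechanism(generate_mechanism_panel(spec))
        assert abs(fit.slope - 0.3) <= 2 * fit.slope_se
        assert abs(fit.intercept - 1.5) <= 2 * fit.intercept_se

    def test_all_blocker_design_degenerate(self):
        with pytest.raises(ValueError, match="degenerate design"):
            fit_mechanism(_wells(np.zeros(6), np.ones(6)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_mechanism(_wells([0.0, 1.0], [1.0, 2.0]))

    def test_mixed_compounds_rejected(self):
        df = pd.concat([_wells(np.arange(3.0), np.arange(3.0), "a"),
                        _wells(np.arange(3.0), np.arange(3.0), "b")])
        with pytest.raises(ValueError, match="one compound"):
            fit_mechanism(df)

    def test_blocker_anchors_reduce_intercept_se(self):
        """x = 0 anchor wells tighten the intercept estimate."""
        wins = 0
        for seed in range(20):
            spec = PanelSpec(
                compounds=[CompoundParams("c", 6.0, 0.3, 1.5, 1.0)],
                wells_per_compound=15, noise_sd=0.1, seed=seed,
            )
            panel = generate_mechanism_panel(spec)
            pooled = fit_mechanism(panel)
            unanchored = fit_mechanism(panel[~panel["blocker"]])
            wins += pooled.intercept_se < unanchored.intercept_se
        assert wins >= 18


def _summaries(est, ves, which="slope"):
    out = []
    for i, (e, v) in enumerate(zip(est, ves)):
        kw = dict(slope=0.1, intercept=0.1)
        kw[which if which != "efficiency" else "slope"] = float(e)
        out.append(CompoundSummary(compound=f"c{i}", pka=6.0,
                                   vesicles_per_cell=float(v), **kw))
    return out


class TestCorrelate:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-10.0, 10.0),
        sign=st.sampled_from([1.0, -1.0]),
    )
    def test_affine_maps_give_unit_correlation(self, scale, shift, sign):
        base = np.array([0.5, 1.0, 1.7, 2.2, 3.1])
        s = _summaries(sign * scale * base + shift, base, "intercept")
        res = correlate_mechanism(s, PAIRING_INTERCEPT)
        assert res.r == pytest.approx(sign, abs=1e-9)

    def test_affine_invariance_of_r(self):
        rng = np.random.default_rng(3)
        est, ves = rng.normal(size=(2, 8))
        r1 = correlate_mechanism(_summaries(est, ves, "slope"),
                                 PAIRING_EFFICIENCY).r
        r2 = correlate_mechanism(_summaries(3 * est + 1, 0.5 * ves - 2,
                                            "slope"),
                                 PAIRING_EFFICIENCY).r
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_zero_variance_rejected(self):
        s = _summaries([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], "slope")
        with pytest.raises(ValueError, match="zero variance"):
            correlate_mechanism(s, PAIRING_EFFICIENCY)

    def test_latent_driver_panel_reproduces_dual_pattern(self):
        """Free-drug intercepts track phospholipidosis; colloid
        efficiencies do not — mirroring the strong/poor correlation
        split between the two disruption mechanisms."""
        compounds = latent_driver_compounds(15, seed=1)
        spec = PanelSpec(compounds=compounds, wells_per_compound=15,
                         noise_sd=0.1, seed=1)
        panel = generate_mechanism_panel(spec)
        fits = fit_mechanism_panel(panel)
        ves = panel.groupby("compound")["vesicles_per_cell"].mean().to_dict()
        pka = {c.compound_id: c.pka for c in compounds}
        join = build_compound_summary(fits, pka, ves)
        r_int = correlate_mechanism(join.summaries, PAIRING_INTERCEPT).r
        r_eff = correlate_mechanism(join.summaries, PAIRING_EFFICIENCY).r
        assert r_int > 0.9
        assert abs(r_eff) < 0.3


class TestBuildSummary:
    def _fit(self, cid):
        return MechanismFit(compound=cid, slope=0.2, slope_se=0.01,
                            intercept=1.0, intercept_se=0.05,
                            r_squared=0.9, n_points=15)

    def test_single_complete_compound_joins(self):
        join = build_compound_summary([self._fit("a")], {"a": 6.2},
                                      {"a": 1.4})
        assert len(join.summaries) == 1
        assert join.summaries[0].pka == 6.2
        assert all(not v for v in join.missing.values())

    def test_disjoint_ids_reported_not_dropped(self):
        join = build_compound_summary([self._fit("a")], {"b": 6.0},
                                      {"c": 1.0})
        assert join.summaries == []
        assert join.missing["mechanism"] == ["b", "c"]
        assert join.missing["pka"] == ["a", "c"]
        assert join.missing["phospholipidosis"] == ["a", "b"]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_compound_summary([self._fit("a"), self._fit("a")],
                                   {"a": 6.0}, {"a": 1.0})

    def test_full_panel_one_row_per_compound(self):
        compounds = latent_driver_compounds(15, seed=0)
        spec = PanelSpec(compounds=compounds, seed=0)
        panel = generate_mechanism_panel(spec)
        fits = fit_mechanism_panel(panel)
        ves = panel.groupby("compound")["vesicles_per_cell"].mean().to_dict()
        pka = {c.compound_id: c.pka for c in compounds}
        join = build_compound_summary(fits, pka, ves)
        assert len(join.summaries) == 15
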