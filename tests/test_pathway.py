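"""Forward labeling model and pool-fraction inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c1trace import (
    FORMATE_TRACER,
    SER_TRACER,
    TRP_TRACER,
    MetaboliteDef,
    OneCarbonParams,
    estimate_pool_fractions,
    labeling_distribution,
    one_carbon_pool_fraction,
    pool_labeled_fractions,
    simulate_labeling,
)
from c1trace.isotopes import ConfigurationError


def make_params(**kw):
    base = dict(f_trp=0.0, f_ser=0.0, f_exo_formate=0.0, f_other=1.0)
    base.update(kw)
    total = base["f_trp"] + base["f_ser"] + base["f_exo_formate"]
    base["f_other"] = 1.0 - total
    return OneCarbonParams(**base)


# random valid parameter draws for property tests
valid_params = st.builds(
    lambda shares, q, trp, ido1: OneCarbonParams(
        f_trp=shares[0] / sum(shares),
        f_ser=shares[1] / sum(shares),
        f_exo_formate=shares[2] / sum(shares),
        f_other=1.0
        - (shares[0] + shares[1] + shares[2]) / sum(shares),
        q_gly=q,
        trp_intracellular_labeled=trp,
        ido1_active=ido1,
    ),
    st.tuples(*[st.floats(0.001, 1.0)] * 4),
    st.floats(0.0, 1.0),
    st.floats(0.0, 1.0),
    st.booleans(),
)


class TestOneCarbonPoolFraction:
    def test_single_fully_labeled_source(self):
        params = make_params(f_trp=1.0)
        tracer = TRP_TRACER.__class__("trp", "tryptophan", 11, 1.0, 0.08)
        assert one_carbon_pool_fraction(params, tracer) == 1.0

    def test_zero_purity_tracer_gives_zero(self):
        params = make_params(f_trp=0.5, f_ser=0.5)
        tracer = TRP_TRACER.__class__("trp", "tryptophan", 11, 0.0, 0.08)
        assert one_carbon_pool_fraction(params, tracer) == 0.0

    def test_purity_weighted_mixture(self):
        params = make_params(f_trp=0.5, f_ser=0.5)
        assert one_carbon_pool_fraction(params, TRP_TRACER) == pytest.approx(
            0.495
        )

    def test_only_matching_source_contributes(self):
        params = make_params(f_trp=0.3, f_ser=0.5, f_exo_formate=0.2)
        assert one_carbon_pool_fraction(params, SER_TRACER) == pytest.approx(
            0.5 * 0.99
        )
        assert one_carbon_pool_fraction(params, FORMATE_TRACER) == pytest.approx(
            0.2 * 0.99
        )

    def test_ido1_inhibition_silences_trp_contribution(self):
        params = make_params(f_trp=0.8, f_ser=0.2, ido1_active=False)
        assert one_carbon_pool_fraction(params, TRP_TRACER) == 0.0
        # the serine route is unaffected
        assert one_carbon_pool_fraction(params, SER_TRACER) == pytest.approx(
            0.2 * 0.99
        )

    def test_invalid_source_fractions_rejected(self):
        with pytest.raises(ValueError):
            OneCarbonParams(f_trp=0.5, f_ser=0.5, f_other=0.5)


class TestSimulateLabeling:
    def test_unlabeled_pools_give_point_mass_at_m0(self, defs):
        mids = simulate_labeling(OneCarbonParams(), TRP_TRACER, defs)
        for mid in mids.values():
            assert mid.fractions[0] == pytest.approx(1.0)

    def test_kynurenine_inherits_ten_tryptophan_carbons(self, defs):
        # 11 tracer carbons minus the formyl carbon released as formate
        params = make_params(f_trp=1.0, trp_intracellular_labeled=1.0)
        mids = simulate_labeling(params, TRP_TRACER, defs)
        kyn = mids["kynurenine"].fractions
        assert kyn.size == 11
        assert kyn[10] == pytest.approx(1.0)
        assert mids["tryptophan"].fractions[11] == pytest.approx(1.0)

    def test_purine_labeling_is_binomial_over_one_carbon_positions(self, defs):
        pools = {"one_carbon": 0.5, "methyl": 0.5, "glycine": 0.0,
                 "trp_intact": 0.0}
        amp = labeling_distribution(defs["AMP"], pools)
        np.testing.assert_allclose(amp.fractions[:3], [0.25, 0.5, 0.25])
        np.testing.assert_allclose(amp.fractions[3:], 0.0)

    def test_glycine_pool_inert_under_tryptophan_tracer(self, defs):
        # the one-carbon unit sits on serine C3, which glycine does not keep
        params = make_params(f_trp=1.0, q_gly=0.9)
        pools = pool_labeled_fractions(params, TRP_TRACER)
        assert pools["glycine"] == 0.0
        pools_ser = pool_labeled_fractions(
            make_params(f_ser=1.0, q_gly=0.9), SER_TRACER
        )
        assert pools_ser["glycine"] == 0.9

    def test_epacadostat_condition_erases_all_labeling(self, defs):
        # ido1_active=False under the Trp tracer: purines, serine and
        # methionine revert to m+0
        params = make_params(
            f_trp=0.9, q_gly=0.8, trp_intracellular_labeled=0.0,
            ido1_active=False,
        )
        mids = simulate_labeling(params, TRP_TRACER, defs)
        for name in ("AMP", "ATP", "GMP", "serine", "methionine"):
            assert mids[name].fractions[0] == pytest.approx(1.0)

    def test_unknown_pool_rejected(self):
        bad = MetaboliteDef("bad", 3, slots=(("mystery_pool", 2),))
        with pytest.raises(ConfigurationError):
            labeling_distribution(bad, {"one_carbon": 0.5})

    @given(valid_params)
    @settings(derandomize=True, max_examples=200)
    def test_simulated_vectors_are_distributions(self, defs, params):
        for mid in simulate_labeling(params, TRP_TRACER, defs).values():
            assert np.all(mid.fractions >= 0.0)
            assert mid.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_purine_labeled_fraction_monotone_in_p(self, defs, p1, p2, q):
        lo, hi = sorted((p1, p2))
        mk = lambda p: labeling_distribution(
            defs["AMP"],
            {"one_carbon": p, "methyl": p, "glycine": q, "trp_intact": 0.0},
        ).labeled_fraction()
        assert mk(lo) <= mk(hi) + 1e-12

    def test_slot_order_irrelevant(self, defs):
        pools = {"one_carbon": 0.35, "methyl": 0.35, "glycine": 0.6,
                 "trp_intact": 0.0}
        forward = MetaboliteDef("x", 10, slots=(("one_carbon", 2), ("glycine", 2)))
        swapped = MetaboliteDef("x", 10, slots=(("glycine", 2), ("one_carbon", 2)))
        np.testing.assert_allclose(
            labeling_distribution(forward, pools).fractions,
            labeling_distribution(swapped, pools).fractions,
        )


class TestEstimatePoolFractions:
    def fit(self, defs, p, q):
        pools = {"one_carbon": p, "methyl": p, "glycine": q, "trp_intact": 0.0}
        pur = labeling_distribution(defs["AMP"], pools)
        ser = labeling_distribution(defs["serine"], pools)
        return estimate_pool_fractions(pur, ser, defs["AMP"], defs["serine"])

    @pytest.mark.parametrize("p,q", [(0.3, 0.1), (0.05, 0.8), (0.7, 0.7)])
    def test_noiseless_roundtrip(self, defs, p, q):
        fit = self.fit(defs, p, q)
        assert fit.p == pytest.approx(p, abs=1e-6)
        assert fit.q_gly == pytest.approx(q, abs=1e-6)
        assert fit.residual == pytest.approx(0.0, abs=1e-10)
        assert not fit.uninformative

    def test_all_m0_input_flagged_uninformative(self, defs):
        fit = self.fit(defs, 0.0, 0.0)
        assert (fit.p, fit.q_gly) == (0.0, 0.0)
        assert fit.residual == 0.0
        assert fit.uninformative

    def test_agrees_with_grid_search_oracle(self, defs):
        # closed-form SSE surface over a 0.001-step grid of (p, q)
        p_true, q_true = 0.3, 0.1
        fit = self.fit(defs, p_true, q_true)
        grid = np.arange(0.0, 1.0005, 0.001)
        P, Q = np.meshgrid(grid, grid, indexing="ij")
        b = [(1 - P) ** 2, 2 * P * (1 - P), P**2]
        g = [(1 - Q) ** 2, 2 * Q * (1 - Q), Q**2]
        pur = [
            b[0] * g[0],
            b[1] * g[0] + b[0] * g[1],
            b[2] * g[0] + b[1] * g[1] + b[0] * g[2],
            b[2] * g[1] + b[1] * g[2],
            b[2] * g[2],
        ]
        ser = [(1 - P) * g[0], P * g[0] + (1 - P) * g[1],
               P * g[1] + (1 - P) * g[2], P * g[2]]
        pools = {"one_carbon": p_true, "methyl": p_true, "glycine": q_true,
                 "trp_intact": 0.0}
        obs_pur = labeling_distribution(defs["AMP"], pools).fractions
        obs_ser = labeling_distribution(defs["serine"], pools).fractions
        sse = sum((m - o) ** 2 for m, o in zip(pur, obs_pur)) + sum(
            (m - o) ** 2 for m, o in zip(ser, obs_ser)
        )
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.p == pytest.approx(grid[i], abs=1e-3)
        assert fit.q_gly == pytest.approx(grid[j], abs=1e-3)
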