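"""Mixed-model association: recovery, calibration, q-values, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beemarkers import (
    LABELS,
    InestimableEffectError,
    MissingnessModel,
    QuantMatrix,
    compute_qvalues,
    detection_filter,
    fit_protein_model,
    make_ground_truth,
    normalize,
    run_dataset,
    simulate_quant,
)

POPS = ["ON", "CA1", "CA2", "Ch", "SK"]


class TestFitProteinModel:
    def test_planted_slope_recovered_within_two_se(self, colonies, design):
        truth = make_ground_truth(
            20, POPS, n_markers=1, marker_beta=0.5, pop_effect_sd=0.0,
            sigma_colony=0.1, sigma_resid=0.2, seed=20,
        )
        sim = simulate_quant(colonies, design, truth, seed=21)
        norm = normalize(detection_filter(sim.matrix))
        marker = sorted(truth.marker_ids)[0]
        res = fit_protein_model(norm, marker, design, colonies, predictor="r24")
        assert res.converged
        # the planted effect is per SD of hb_true; the fit is per unit r24 on
        # the MAD-standardized scale, so compare via the strongly nonzero t
        assert res.effect / res.se > 4
        assert res.p_value < 1e-4

    def test_hb_slope_sign_follows_planted_direction(self, colonies, design):
        truth = make_ground_truth(
            10, POPS, n_markers=1, marker_beta=-0.8, pop_effect_sd=0.0, seed=22
        )
        sim = simulate_quant(colonies, design, truth, seed=23)
        norm = normalize(detection_filter(sim.matrix))
        marker = sorted(truth.marker_ids)[0]
        res = fit_protein_model(norm, marker, design, colonies, predictor="r24")
        assert res.effect < 0

    def test_permuted_predictor_gives_uniform_pvalues(self, colonies, design):
        # shuffle hb across colonies: p-values over 200 proteins must look U(0,1)
        truth = make_ground_truth(
            200, POPS, n_markers=0, sigma_colony=0.0, pop_effect_sd=0.0, seed=24
        )
        sim = simulate_quant(colonies, design, truth, seed=25)
        norm = normalize(detection_filter(sim.matrix))
        rng = np.random.default_rng(26)
        perm = rng.permutation([c.r24 for c in colonies])
        import copy

        shuffled = [copy.copy(c) for c in colonies]
        for c, v in zip(shuffled, perm):
            c.r24 = float(v)
            c.u24 = max(c.u24, v)
            c.r48 = max(c.r48, v)
            c.u48 = max(c.u48, c.r48)
        res, _ = run_dataset(norm, design, shuffled, predictors=["r24"])
        p = res["r24"]["p_value"].dropna()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_response_reports_p_one_without_convergence(self, colonies, design):
        cols = pd.MultiIndex.from_tuples(
            [(b, lab) for b in design.block_ids() for lab in LABELS],
            names=["block", "label"],
        )
        vals = pd.DataFrame(
            np.zeros((1, len(cols))), index=pd.Index(["P0000"], name="protein"), columns=cols
        )
        m = QuantMatrix(values=vals, state="standardized")
        res = fit_protein_model(m, "P0000", design, colonies)
        assert not res.converged
        assert res.p_value == 1.0

    def test_constant_predictor_raises_inestimable(self, colonies, design, standardized):
        flat = [type(c)(**{**c.__dict__}) for c in colonies]
        for c in flat:
            c.r24 = 0.5
            c.r48 = c.u24 = c.u48 = 0.5
        with pytest.raises(InestimableEffectError):
            fit_protein_model(standardized, standardized.proteins[0], design, flat)

    def test_sparse_protein_is_skipped_with_reason(self, colonies, design, standardized):
        m = standardized.copy()
        first = m.proteins[0]
        keep = m.values.columns[:6]  # present in only 2 blocks
        row = pd.Series(np.nan, index=m.values.columns)
        row[keep] = 1.0 + np.arange(6) * 0.1
        m.values.loc[first] = row
        res = fit_protein_model(m, first, design, colonies)
        assert not res.converged
        assert "skipped" in res.fit_notes

    def test_label_permutation_leaves_pvalues_unchanged(self, colonies, design, standardized):
        prot = standardized.proteins[1]
        base = fit_protein_model(standardized, prot, design, colonies)
        permuted = standardized.copy()
        relab = {"light": "heavy", "medium": "light", "heavy": "medium"}
        permuted.values.columns = pd.MultiIndex.from_tuples(
            [(b, relab[lab]) for b, lab in permuted.values.columns],
            names=["block", "label"],
        )
        from beemarkers.types import BlockAssignment, BlockSlot

        des2 = BlockAssignment(
            blocks=[
                [BlockSlot(s.colony_id, s.replicate, relab[s.label]) for s in blk]
                for blk in design.blocks
            ],
            seed=design.seed,
        )
        alt = fit_protein_model(permuted, prot, des2, colonies)
        assert alt.p_value == pytest.approx(base.p_value, rel=1e-9)
        assert alt.effect == pytest.approx(base.effect, rel=1e-9)

    def test_population_predictor_detects_planted_offsets(self, colonies, design):
        truth = make_ground_truth(
            40, POPS, n_markers=0, pop_effect_sd=0.6, sigma_colony=0.1, seed=27
        )
        sim = simulate_quant(colonies, design, truth, seed=28)
        norm = normalize(detection_filter(sim.matrix))
        res, _ = run_dataset(norm, design, colonies, predictors=["population"])
        p = res["population"]["p_value"].dropna()
        assert (p < 0.05).mean() > 0.5

    def test_mixedlm_engine_agrees_with_fallback_direction(self, colonies, design, standardized):
        prot = standardized.proteins[2]
        auto = fit_protein_model(standardized, prot, design, colonies, engine="auto")
        mixed = fit_protein_model(standardized, prot, design, colonies, engine="mixedlm")
        assert np.sign(auto.effect) == np.sign(mixed.effect)
        assert mixed.fit_notes  # either a mixed fit or an explained fallback


class TestQValues:
    def test_single_pvalue_is_its_own_qvalue(self):
        assert compute_qvalues([0.01])[0] == pytest.approx(0.01)

    def test_hand_computed_step_up_example(self):
        q = compute_qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert np.allclose(compute_qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        q = compute_qvalues(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_nans_propagate_without_counting(self):
        q = compute_qvalues([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert q[0] == pytest.approx(0.02)  # m = 2, not 3


class TestRunDataset:
    def test_empty_matrix_warns_and_returns_empty(self, colonies, design):
        cols = pd.MultiIndex.from_tuples(
            [(b, lab) for b in design.block_ids() for lab in LABELS],
            names=["block", "label"],
        )
        empty = QuantMatrix(
            values=pd.DataFrame(np.empty((0, len(cols))), columns=cols),
            state="standardized",
        )
        with pytest.warns(RuntimeWarning, match="no proteins"):
            res, log = run_dataset(empty, design, colonies)
        assert res["r24"].empty

    def test_two_predictors_give_independent_monotone_qsets(self, colonies, design, standardized):
        res, _ = run_dataset(standardized, design, colonies, predictors=["r24", "u48"])
        for pred in ("r24", "u48"):
            df = res[pred].dropna(subset=["p_value"])
            order = np.argsort(df["p_value"].to_numpy())
            assert (np.diff(df["q_value"].to_numpy()[order]) >= -1e-12).all()

    def test_marker_recovery_in_run_dataset(self, colonies, design, marker_sim, standardized):
        res, log = run_dataset(standardized, design, colonies, predictors=["r24"])
        df = res["r24"]
        markers = [m for m in marker_sim.truth.marker_ids if m in df.index]
        assert len(markers) >= 4
        assert (df.loc[markers, "q_value"] < 0.1).all()
        assert log.n_fit > 0
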