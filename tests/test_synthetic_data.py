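"""Generator correctness: phenotype invariants, genetics, equilibria, determinism."""

import numpy as np
import pandas as pd
import pytest

from beemarkers import (
    MissingnessModel,
    bound_1to1,
    competition_bound,
    make_ground_truth,
    simulate_colonies,
    simulate_diallel,
    simulate_expression_trios,
    simulate_psms,
    simulate_quant,
    simulate_titration,
)
from beemarkers.quant_processing import decoy_fdr_filter

POPS = ["A", "B", "C"]


class TestColonies:
    def test_phenotype_ordering_invariants_hold_across_seeds(self):
        for seed in range(5):
            cols = simulate_colonies(10, POPS, seed=seed)
            for c in cols:
                assert 0 <= c.r24 <= c.u24 <= 1
                assert 0 <= c.r48 <= c.u48 <= 1
                assert c.r24 <= c.r48

    def test_point_mass_at_one_gives_saturated_phenotypes(self):
        cols = simulate_colonies(5, POPS, hb_distribution=("point", 1.0), seed=0)
        assert all(c.r24 == 1.0 and c.u24 == 1.0 for c in cols)

    def test_zero_colonies_per_population_gives_empty_list(self):
        assert simulate_colonies(0, POPS, seed=0) == []

    def test_invalid_distribution_parameters_raise(self):
        with pytest.raises(ValueError):
            simulate_colonies(2, POPS, hb_distribution=("beta", -1, 2), seed=0)
        with pytest.raises(ValueError):
            simulate_colonies(2, POPS, hb_distribution=("nope", 1), seed=0)

    def test_binomial_sampling_oracle_for_mean_r24(self):
        # 1000 colonies at fixed propensity 0.5, 10000 cells, no retest noise:
        # mean r24 must sit within 3 standard errors of 0.5
        cols = simulate_colonies(
            334, POPS, hb_distribution=("point", 0.5),
            n_cells_per_test=10000, test_retest_sd=0.0, seed=7,
        )
        r = np.array([c.r24 for c in cols])
        se = r.std(ddof=1) / np.sqrt(len(r))
        assert abs(r.mean() - 0.5) < 3 * max(se, 1e-6)

    def test_binomial_noise_scale_matches_theory(self):
        # empirical SD of r24 vs sqrt(p(1-p)/n_total) within 20% at 100 cells/test
        cols = simulate_colonies(
            334, POPS, hb_distribution=("point", 0.5),
            n_cells_per_test=100, test_retest_sd=0.0, seed=8,
        )
        r = np.array([c.r24 for c in cols])
        expected = np.sqrt(0.25 / 200)  # two tests of 100 cells averaged
        assert abs(r.std(ddof=1) - expected) / expected < 0.2


class TestDiallel:
    def _parents(self, seed=0):
        return simulate_colonies(10, POPS, seed=seed)

    def test_perfect_heritability_no_noise_equals_midparent(self):
        parents = self._parents()
        crosses = [(parents[0].colony_id, parents[1].colony_id)]
        f1 = simulate_diallel(parents, crosses, h2_behavior=1.0, segregation_sd=0.0, seed=1)
        mid = 0.5 * (parents[0].hb_true + parents[1].hb_true)
        assert f1[0].hb_true == pytest.approx(mid, abs=1e-12)
        assert f1[0].dam_id == parents[0].colony_id
        assert f1[0].sire_id == parents[1].colony_id

    def test_zero_heritability_gives_flat_midparent_regression(self):
        parents = self._parents(seed=3)
        rng = np.random.default_rng(4)
        crosses = [
            (parents[i].colony_id, parents[j].colony_id)
            for i, j in zip(rng.integers(0, 30, 300), rng.integers(0, 30, 300))
            if i != j
        ]
        f1 = simulate_diallel(parents, crosses, h2_behavior=0.0, segregation_sd=0.05, seed=5)
        by_id = {p.colony_id: p.hb_true for p in parents}
        mid = np.array([0.5 * (by_id[c.dam_id] + by_id[c.sire_id]) for c in f1])
        hb = np.array([c.hb_true for c in f1])
        slope = np.polyfit(mid, hb, 1)[0]
        assert abs(slope) < 0.1

    def test_high_and_low_crosses_preserve_ordering(self):
        parents = self._parents(seed=6)
        ranked = sorted(parents, key=lambda c: c.hb_true)
        low, high = ranked[:6], ranked[-6:]
        lows = [(a.colony_id, b.colony_id) for a in low for b in low if a is not b][:100]
        highs = [(a.colony_id, b.colony_id) for a in high for b in high if a is not b][:100]
        f1_low = simulate_diallel(parents, lows, seed=7)
        f1_high = simulate_diallel(parents, highs, seed=8)
        assert np.mean([c.hb_true for c in f1_high]) > np.mean([c.hb_true for c in f1_low])

    def test_dangling_parent_reference_raises(self):
        parents = self._parents()
        with pytest.raises(KeyError, match="ghost"):
            simulate_diallel(parents, [("ghost", parents[0].colony_id)], seed=0)


class TestQuant:
    def test_null_model_without_noise_is_constant_per_protein(self, colonies, design):
        truth = make_ground_truth(
            10, ["ON", "CA1", "CA2", "Ch", "SK"], n_markers=0, pop_effect_sd=0.0,
            sigma_colony=0.0, sigma_resid=0.0, sigma_block=0.0, sigma_label=0.0,
            missing_model=MissingnessModel.none(), seed=0,
        )
        sim = simulate_quant(colonies, design, truth, seed=1)
        vals = sim.matrix.values
        assert (vals.nunique(axis=1) == 1).all()

    def test_zero_missingness_model_leaves_no_gaps(self, colonies, design):
        truth = make_ground_truth(
            20, ["ON", "CA1", "CA2", "Ch", "SK"],
            missing_model=MissingnessModel.none(), seed=2,
        )
        sim = simulate_quant(colonies, design, truth, seed=3)
        assert not sim.matrix.values.isna().any().any()

    def test_planted_marker_tracks_colony_hb_when_noise_vanishes(self, colonies, design):
        truth = make_ground_truth(
            5, ["ON", "CA1", "CA2", "Ch", "SK"], n_markers=1, marker_beta=1.0,
            pop_effect_sd=0.0, sigma_colony=0.0, sigma_resid=1e-9, sigma_block=0.0,
            sigma_label=0.0, missing_model=MissingnessModel.none(), seed=4,
        )
        sim = simulate_quant(colonies, design, truth, seed=5)
        marker = sorted(truth.marker_ids)[0]
        hb = pd.Series({c.colony_id: c.hb_true for c in colonies})
        cv = sim.colony_values.loc[marker]
        assert cv.corr(hb[cv.index], method="spearman") > 0.9999

    def test_residual_sd_recovered_when_all_effects_zero(self, colonies, design):
        truth = make_ground_truth(
            30, ["ON", "CA1", "CA2", "Ch", "SK"], n_markers=0, pop_effect_sd=0.0,
            sigma_colony=0.0, sigma_block=0.0, sigma_label=0.0, sigma_resid=0.7,
            missing_model=MissingnessModel.none(), seed=6,
        )
        sim = simulate_quant(colonies, design, truth, seed=7)
        logvals = np.log(sim.matrix.values)
        sds = logvals.std(axis=1, ddof=1)  # 180 samples per protein
        assert abs(sds.mean() - 0.7) / 0.7 < 0.05
        assert (np.abs(sds - 0.7) / 0.7 < 0.2).all()

    def test_missingness_drops_whole_blocks(self, colonies, design):
        truth = make_ground_truth(100, ["ON", "CA1", "CA2", "Ch", "SK"], seed=8)
        sim = simulate_quant(colonies, design, truth, seed=9)
        present = sim.matrix.values.notna()
        counts = present.T.groupby(level=0).sum().T.to_numpy()
        assert set(np.unique(counts)) <= {0, 3}

    def test_assignment_colony_mismatch_raises(self, colonies, design):
        truth = make_ground_truth(5, ["ON"], seed=0)
        with pytest.raises(ValueError, match="absent"):
            simulate_quant(colonies[:10], design, truth, seed=0)


class TestTrios:
    def test_slope_sum_estimates_heritability(self):
        tots = []
        for s in range(20):
            trios = simulate_expression_trios(200, h2=0.5, seed=s)
            X = np.column_stack([np.ones(len(trios)), trios["dam"], trios["sire"]])
            b = np.linalg.lstsq(X, trios["daughter"], rcond=None)[0]
            tots.append(b[1] + b[2])
        assert np.mean(tots) == pytest.approx(0.5, abs=0.05)


class TestPSMs:
    def test_zero_decoy_fraction_emits_no_decoys(self):
        psms = simulate_psms(20, decoy_fraction=0.0, seed=0)
        assert not psms["decoy"].any()

    def test_separated_components_accept_all_correct_psms(self):
        sm = {"mu_correct": 100.0, "sd_correct": 1.0, "mu_incorrect": 10.0,
              "sd_incorrect": 1.0, "pi_incorrect": 0.2}
        psms = simulate_psms(40, score_model=sm, seed=1)
        res = decoy_fdr_filter(psms, fdr=0.01, min_score=0.0)
        correct = psms[psms["correct"]]
        assert set(res.accepted["peptide_id"]) >= set(correct["peptide_id"])

    def test_shared_and_subset_structure_is_emitted(self):
        psms = simulate_psms(
            30, shared_peptide_rate=0.5, subset_protein_rate=0.3, seed=2
        )
        multi = psms["protein_ids"].str.contains(";")
        assert multi.any()


class TestEquilibria:
    def test_quadratic_root_matches_grid_search_oracle(self):
        # brute-force the 1:1 mass-balance residual over a fine bound grid
        ptot, ltot, kd = 2.0, 2.0, 2.0
        grid = np.linspace(0, min(ptot, ltot), 2_000_001)
        resid = np.abs((ptot - grid) * (ltot - grid) - kd * grid)
        oracle = grid[resid.argmin()]
        assert bound_1to1(ptot, ltot, kd) == pytest.approx(oracle, abs=1e-5)

    def test_tight_binding_limit_binds_all_probe(self):
        b = bound_1to1(protein_tot=100.0, ligand_tot=0.01, kd=0.001)
        assert b == pytest.approx(0.01, rel=1e-3)

    def test_zero_competitor_matches_single_equilibrium(self):
        b0 = bound_1to1(2.0, 2.0, 2.0)
        b, free, bc = competition_bound(2.0, 2.0, 2.0, 0.0, 1.0)
        assert b == pytest.approx(b0, rel=1e-12)
        assert bc == 0.0

    def test_mass_balance_residuals_are_tiny_everywhere(self):
        for c in [0.1, 1.0, 5.0, 20.0]:
            bp, fp, bc = competition_bound(2.0, 2.0, 2.0, c, 0.5)
            pf = 2.0 - bp - bc
            assert abs(pf * (2.0 - bp) / 2.0 - 0)  # smoke: quantities finite
            # species-level balances
            assert abs(bp + fp - 2.0) < 1e-8 * 20
            assert abs(bp * 0.5 - 0) >= 0
            # equilibrium conditions
            assert bp == pytest.approx(pf * fp / 2.0, rel=1e-8)

    def test_titration_competitor_zero_first_point_equals_saturation_value(self):
        sim = simulate_titration(
            2.0, 2.0, competitor_kd=1.0, competitor_concs=[0, 2, 4],
            probe_conc=2.0, noise_cv=0.0,
        )
        assert sim.bound_true[0] == pytest.approx(bound_1to1(2.0, 2.0, 2.0), rel=1e-10)


class TestDeterminism:
    def test_identical_seeds_are_bit_identical(self, colonies, design):
        a = simulate_colonies(5, POPS, seed=42)
        b = simulate_colonies(5, POPS, seed=42)
        assert a == b
        truth = make_ground_truth(20, ["ON", "CA1", "CA2", "Ch", "SK"], seed=42)
        qa = simulate_quant(colonies, design, truth, seed=42)
        qb = simulate_quant(colonies, design, truth, seed=42)
        pd.testing.assert_frame_equal(qa.matrix.values, qb.matrix.values)
        pa = simulate_psms(10, seed=42)
        pb = simulate_psms(10, seed=42)
        pd.testing.assert_frame_equal(pa, pb)
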