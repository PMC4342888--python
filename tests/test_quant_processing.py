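"""FDR thresholding, parsimony inference, detection filter and normalization."""

import numpy as np
import pandas as pd
import pytest

from beemarkers import (
    LABELS,
    QuantMatrix,
    block_center,
    decoy_fdr_filter,
    detection_filter,
    label_standardize,
    log_transform,
    normalize,
    parsimony_group,
    simulate_psms,
)
from beemarkers.quant_processing import (
    DegenerateScaleError,
    MAD_SCALE,
    exhaustive_min_cover,
    _peptide_map,
)
from beemarkers.types import QuantMatrixError


def _psm_frame(rows):
    df = pd.DataFrame(rows, columns=["peptide_id", "protein_ids", "score", "decoy"])
    df["block"] = "B000"
    for lab in LABELS:
        df[f"intensity_{lab}"] = 100.0
    return df


def _brute_force_threshold(scores, decoys, fdr):
    """Independent oracle: scan every unique score as a candidate threshold."""
    best = None
    s = np.asarray(scores, float)
    d = np.asarray(decoys, bool)
    for t in sorted(set(s)):
        sel = s >= t
        nt = (~d & sel).sum()
        nd = (d & sel).sum()
        if nt > 0 and nd / nt <= fdr:
            best = t if best is None else min(best, t)
    return best


class TestDecoyFDR:
    def test_zero_decoys_threshold_is_min_score(self):
        rows = [(f"p{i}", f"T{i}", 30.0 + i, False) for i in range(10)]
        res = decoy_fdr_filter(_psm_frame(rows), fdr=0.01, min_score=25.0)
        assert res.thresholds["B000"] == 25.0
        assert len(res.accepted) == 10

    def test_decoy_dominated_block_rejects_everything_with_warning(self):
        rows = [(f"p{i}", f"T{i}", 30.0 + i, False) for i in range(10)]
        rows.append(("d0", "DECOY_0", 50.0, True))
        with pytest.warns(RuntimeWarning, match="no score threshold"):
            res = decoy_fdr_filter(_psm_frame(rows), fdr=0.01)
        assert res.accepted.empty
        assert res.thresholds["B000"] == np.inf

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        decoy = rng.random(n) < 0.3
        scores = np.where(decoy, rng.normal(15, 6, n), rng.normal(30, 10, n))
        rows = [
            (f"p{i}", ("DECOY_%d" % i) if decoy[i] else f"T{i}", float(scores[i]), bool(decoy[i]))
            for i in range(n)
        ]
        res = decoy_fdr_filter(_psm_frame(rows), fdr=0.05, min_score=0.0)
        oracle = _brute_force_threshold(scores, decoy, 0.05)
        if oracle is None:
            assert res.accepted.empty
        else:
            assert res.thresholds["B000"] == pytest.approx(oracle)

    def test_realized_fdp_stays_near_nominal(self):
        # known correctness labels: average realized FDP <= 2x nominal 1%
        fdps = []
        for s in range(30):
            psms = simulate_psms(60, peptides_per_protein=5, seed=s)
            res = decoy_fdr_filter(psms, fdr=0.01, min_score=0.0)
            if len(res.accepted) == 0:
                continue
            fdps.append(1.0 - res.accepted["correct"].mean())
        assert np.mean(fdps) <= 0.02

    def test_min_score_gate_drops_low_scoring_targets(self):
        rows = [("p0", "T0", 20.0, False), ("p1", "T1", 30.0, False)]
        res = decoy_fdr_filter(_psm_frame(rows), fdr=0.01, min_score=25.0)
        assert list(res.accepted["peptide_id"]) == ["p1"]


class TestParsimony:
    def _frame(self, mapping, score=40.0):
        rows = [(pep, ";".join(sorted(prots)), score, False) for pep, prots in mapping]
        return _psm_frame(rows)

    def test_subset_protein_absorbed_into_superset(self):
        df = self._frame([("p1", {"A"}), ("p2", {"A", "B"})])
        res = parsimony_group(df)
        assert len(res.groups) == 1
        g = res.groups[0]
        assert g.group_id == "A"
        assert set(g.members) == {"A", "B"}

    def test_disjoint_proteins_stay_separate(self):
        df = self._frame([("p1", {"A"}), ("p2", {"B"})])
        res = parsimony_group(df)
        assert sorted(g.group_id for g in res.groups) == ["A", "B"]

    def test_identical_peptide_sets_merge_into_one_group(self):
        df = self._frame([("p1", {"A", "B"}), ("p2", {"A", "B"})])
        res = parsimony_group(df)
        assert len(res.groups) == 1
        assert set(res.groups[0].members) == {"A", "B"}

    def test_every_peptide_is_covered(self):
        psms = simulate_psms(40, shared_peptide_rate=0.4, subset_protein_rate=0.2, seed=3)
        targets = psms[~psms["decoy"]]
        res = parsimony_group(targets)
        covered = set().union(*(g.peptides for g in res.groups))
        assert covered == set(targets["peptide_id"])

    @pytest.mark.parametrize("seed", range(8))
    def test_group_count_matches_exact_set_cover(self, seed):
        rng = np.random.default_rng(seed)
        n_prot, n_pep = 10, 25
        rows = []
        for i in range(n_pep):
            owners = {f"T{j:02d}" for j in rng.choice(n_prot, rng.integers(1, 4), replace=False)}
            rows.append((f"p{i}", owners))
        df = self._frame(rows)
        res = parsimony_group(df)
        pep_sets = _peptide_map(df)
        optimum = exhaustive_min_cover(pep_sets, set(df["peptide_id"]))
        assert len(res.groups) == optimum

    def test_invariant_to_input_row_order(self):
        psms = simulate_psms(25, shared_peptide_rate=0.3, seed=4)
        targets = psms[~psms["decoy"]]
        a = parsimony_group(targets)
        b = parsimony_group(targets.sample(frac=1.0, random_state=0))
        assert [g.group_id for g in a.groups] == [g.group_id for g in b.groups]

    def test_log_ratios_are_peptide_means(self):
        rows = [("p1", "A", 40.0, False), ("p2", "A", 40.0, False)]
        df = _psm_frame(rows)
        df.loc[0, "intensity_light"] = 100.0
        df.loc[0, "intensity_medium"] = 200.0
        df.loc[1, "intensity_light"] = 100.0
        df.loc[1, "intensity_medium"] = 800.0
        res = parsimony_group(df)
        row = res.ratios.set_index(["group_id", "block"]).loc[("A", "B000")]
        assert row["log2_medium_light"] == pytest.approx((1 + 3) / 2)


def _matrix(values, n_blocks, state="raw"):
    cols = pd.MultiIndex.from_tuples(
        [(f"B{b:03d}", lab) for b in range(n_blocks) for lab in LABELS],
        names=["block", "label"],
    )
    df = pd.DataFrame(values, columns=cols)
    df.index = pd.Index([f"P{i:04d}" for i in range(len(df))], name="protein")
    return QuantMatrix(values=df, state=state)


class TestDetectionFilter:
    def test_boundary_at_quarter_of_38_blocks(self):
        n_blocks = 38
        vals = np.full((2, 3 * n_blocks), np.nan)
        vals[0, : 3 * 10] = 5.0  # in 10 blocks -> retained
        vals[1, : 3 * 9] = 5.0  # in 9 blocks -> dropped
        out = detection_filter(_matrix(vals, n_blocks), 0.25)
        assert list(out.proteins) == ["P0000"]

    def test_protein_in_all_blocks_retained_and_zero_threshold_identity(self):
        vals = np.abs(np.random.default_rng(0).normal(5, 1, (4, 12)))
        m = _matrix(vals, 4)
        assert list(detection_filter(m, 0.25).proteins) == list(m.proteins)
        assert list(detection_filter(m, 0.0).proteins) == list(m.proteins)

    def test_monotone_in_threshold(self, marker_sim):
        m = marker_sim.matrix
        prev = set(detection_filter(m, 0.0).proteins)
        for frac in (0.25, 0.5, 0.75, 1.0):
            cur = set(detection_filter(m, frac).proteins)
            assert cur <= prev
            prev = cur


class TestNormalize:
    def test_block_centering_arithmetic_example(self):
        vals = np.array([[np.e, np.e**2, np.e**3]])
        m = _matrix(vals, 1)
        centered = block_center(log_transform(m))
        assert np.allclose(centered.values.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_block_centering_is_idempotent(self, marker_sim):
        logm = log_transform(marker_sim.matrix)
        once = block_center(logm)
        again = once.copy()
        again.state = "log"  # re-run the centering step on centered data
        twice = block_center(again)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_full_pipeline_yields_exact_label_median_and_mad(self, standardized):
        vals = standardized.values
        for lab in LABELS:
            cols = vals.columns[vals.columns.get_level_values(1) == lab]
            x = vals[cols].to_numpy().ravel()
            x = x[~np.isnan(x)]
            assert abs(np.median(x)) < 1e-9
            assert abs(MAD_SCALE * np.median(np.abs(x - np.median(x))) - 1) < 1e-9

    def test_center_scale_is_idempotent_given_unit_statistics(self, standardized):
        again = standardized.copy()
        again.state = "block_centered"
        out = label_standardize(again)
        pd.testing.assert_frame_equal(out.values, standardized.values)

    def test_nonpositive_intensity_identifies_the_cell(self):
        vals = np.abs(np.random.default_rng(1).normal(5, 1, (2, 6)))
        vals[1, 2] = 0.0
        with pytest.raises(ValueError, match="P0001"):
            log_transform(_matrix(vals, 2))

    def test_zero_mad_label_raises_degenerate_scale(self):
        vals = np.ones((3, 6)) * 7.0
        with pytest.raises(DegenerateScaleError):
            normalize(_matrix(vals, 2))

    def test_state_machine_refuses_backward_transitions(self, standardized):
        with pytest.raises(QuantMatrixError):
            log_transform(standardized)
        with pytest.raises(QuantMatrixError):
            standardized.advance_state("raw")

    def test_missing_cells_stay_missing(self, marker_sim, standardized):
        before = marker_sim.matrix.values.loc[standardized.proteins].isna()
        after = standardized.values.isna()
        pd.testing.assert_frame_equal(before, after)
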