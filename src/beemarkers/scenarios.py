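"""Reference study scenarios: the emulated two-site, three-year experiment.

Builds the synthetic counterpart of the breeding-and-proteomics study
structure: two apiary sites, three years each (founders in year 1, partial
diallel F1 colonies in years 2 and 3, with the site-1 year-3 diallel
carrying the pedigree used for heritability), a shared protein panel with
planted hygienic-behavior markers, ~25% block-level missingness, and the
full analysis chain (detection filter, normalization, per-protein
association, heritability regression, marker ranking and selection).

These scenario builders exist so that validation scripts and tests
exercise one and the same study definition instead of re-declaring sample
sizes ad hoc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import run_dataset
from .block_design import build_design
from .marker_ranking import (
    SelectionRules,
    fit_midparent_regression,
    rank_markers,
    select_markers,
)
from .quant_processing import colony_means, detection_filter, normalize
from .synthetic_data import (
    GroundTruth,
    MissingnessModel,
    make_ground_truth,
    simulate_colonies,
    simulate_diallel,
    simulate_quant,
)
from .types import HB_VARIABLES, BlockAssignment, ColonyRecord, QuantMatrix

POPULATIONS = ["ON", "CA1", "CA2", "Ch", "SK"]

#: block-level missingness tuned to ~25% of (protein, block) triples overall
STUDY_MISSINGNESS = MissingnessModel(mnar_intercept=-2.0, mnar_slope=1.0, mcar_rate=0.08)


@dataclass
class StudyFrame:
    """Colonies and block designs of the six datasets (fixed per study)."""

    datasets: dict[str, tuple[list[ColonyRecord], BlockAssignment]]
    diallel_dataset: str  # dataset whose colonies carry dam/sire pedigree


@dataclass
class StudyData:
    """One simulated realization of the study's quantitative proteomics."""

    frame: StudyFrame
    truth: GroundTruth
    matrices: dict[str, QuantMatrix]  # standardized, detection-filtered


def _diallel_crosses(parents: list[ColonyRecord], n_crosses: int, rng) -> list[tuple[str, str]]:
    ranked = sorted(parents, key=lambda c: c.hb_true)
    k = max(3, len(ranked) // 3)
    low, high = ranked[:k], ranked[-k:]
    pools = [(high, high), (low, low), (high, low)]
    crosses = []
    for i in range(n_crosses):
        dams, sires = pools[i % 3]
        dam = dams[int(rng.integers(len(dams)))]
        sire = sires[int(rng.integers(len(sires)))]
        while sire.colony_id == dam.colony_id:
            sire = sires[int(rng.integers(len(sires)))]
        crosses.append((dam.colony_id, sire.colony_id))
    return crosses


def build_study_frame(
    seed: int,
    n_founders_per_pop: int = 7,
    n_f1: int = 24,
    n_restarts: int = 2,
) -> StudyFrame:
    """Two sites x three years of colonies with their optimized block designs.

    Year 1 holds founders from the five populations; years 2 and 3 hold
    partial-diallel F1 colonies bred from the site's year-1 stock.  The
    site-1 year-3 dataset includes its year-1 parents alongside the F1s so
    daughter and parent expression are measured on a shared scale for the
    heritability regression.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(16)]
    rng = np.random.default_rng(seeds[0])
    datasets: dict[str, tuple[list[ColonyRecord], BlockAssignment]] = {}
    for si, site in enumerate(("BL", "GF")):
        founders = simulate_colonies(
            n_founders_per_pop, POPULATIONS, seed=seeds[1 + si], site=site,
            year="Y1", id_prefix=f"{site}1-",
        )
        datasets[f"{site}-Y1"] = (
            founders,
            build_design(founders, n_restarts=n_restarts, seed=seeds[3 + si]),
        )
        for year, s_off in (("Y2", 5), ("Y3", 7)):
            crosses = _diallel_crosses(founders, n_f1, rng)
            f1 = simulate_diallel(
                founders, crosses, seed=seeds[s_off + si], site=site, year=year,
                id_prefix=f"{site}{year[-1]}-",
            )
            if site == "BL" and year == "Y3":
                # parents measured alongside daughters for the heritability fit
                parent_ids = sorted({c.dam_id for c in f1} | {c.sire_id for c in f1})
                parents = [c for c in founders if c.colony_id in parent_ids]
                cols = parents + f1
            else:
                cols = f1
            datasets[f"{site}-{year}"] = (
                cols,
                build_design(cols, n_restarts=n_restarts, seed=seeds[11 + 2 * si]),
            )
    return StudyFrame(datasets=datasets, diallel_dataset="BL-Y3")


def simulate_study(
    frame: StudyFrame,
    seed: int,
    n_proteins: int = 500,
    n_markers: int = 5,
    marker_beta: float = 0.6,
) -> StudyData:
    """Simulate, filter and normalize all six quantification datasets."""
    truth = make_ground_truth(
        n_proteins,
        POPULATIONS,
        n_markers=n_markers,
        marker_beta=marker_beta,
        missing_model=STUDY_MISSINGNESS,
        seed=seed,
    )
    ss = np.random.SeedSequence(seed + 1)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(frame.datasets))]
    matrices = {}
    for s, (name, (cols, des)) in zip(seeds, sorted(frame.datasets.items())):
        sim = simulate_quant(cols, des, truth, seed=s)
        matrices[name] = normalize(detection_filter(sim.matrix))
    return StudyData(frame=frame, truth=truth, matrices=matrices)


def heritability_fits_from_dataset(
    study: StudyData, dataset: str | None = None
) -> dict:
    """Per-protein midparent regressions from the diallel dataset's colony means."""
    name = dataset or study.frame.diallel_dataset
    cols, des = study.frame.datasets[name]
    levels = colony_means(study.matrices[name], des)
    by_id = {c.colony_id: c for c in cols}
    trios = [
        (c.colony_id, c.dam_id, c.sire_id)
        for c in cols
        if c.dam_id in by_id and c.sire_id in by_id
        and c.dam_id in levels.columns and c.sire_id in levels.columns
        and c.colony_id in levels.columns
    ]
    fits = {}
    for prot in levels.index:
        d = levels.loc[prot, [t[0] for t in trios]].to_numpy(float)
        dam = levels.loc[prot, [t[1] for t in trios]].to_numpy(float)
        sire = levels.loc[prot, [t[2] for t in trios]].to_numpy(float)
        ok = ~(np.isnan(d) | np.isnan(dam) | np.isnan(sire))
        if ok.sum() < 3:
            continue
        try:
            fits[prot] = fit_midparent_regression(d[ok], dam[ok], sire[ok], protein_id=prot)
        except ValueError:
            continue
    return fits


@dataclass
class StudyAnalysis:
    hb_results: dict[str, pd.DataFrame]  # per dataset, headline HB predictor
    site_results: dict[str, dict[str, pd.DataFrame]]  # Y1 pair, all field params
    ranked: pd.DataFrame
    selected: pd.DataFrame


def analyze_study(
    study: StudyData,
    predictor: str = "r24",
    top_k: int = 10,
) -> StudyAnalysis:
    """Full marker-discovery analysis over the six simulated datasets.

    The site-1 year-1 dataset is analyzed adjusting for population of
    origin (it mixes the five source populations); the year-1 pair is
    additionally fit for all four field parameters to drive the two-site
    selection route.
    """
    hb_results = {}
    for name, (cols, des) in sorted(study.frame.datasets.items()):
        res, _ = run_dataset(
            study.matrices[name], des, cols, predictors=[predictor],
            adjust_population=(name == "BL-Y1"),
        )
        hb_results[name] = res[predictor]
    site_results: dict[str, dict[str, pd.DataFrame]] = {}
    for name in ("BL-Y1", "GF-Y1"):
        cols, des = study.frame.datasets[name]
        res, _ = run_dataset(
            study.matrices[name], des, cols, predictors=list(HB_VARIABLES),
            adjust_population=(name == "BL-Y1"),
        )
        site_results[name] = res
    fits = heritability_fits_from_dataset(study)
    ranked = rank_markers(hb_results, fits)
    rules = SelectionRules(
        reference_dataset="BL-Y1",
        two_site_datasets=("BL-Y1", "GF-Y1"),
        top_k=top_k,
    )
    selected = select_markers(ranked, site_results, rules)
    return StudyAnalysis(hb_results, site_results, ranked, selected)


def marker_recovery(study: StudyData, analysis: StudyAnalysis) -> dict:
    """Recovery metrics for the planted markers of one study realization."""
    markers = study.truth.marker_ids
    union = set(analysis.selected.index)
    ranked = analysis.ranked
    n_top = max(1, int(np.ceil(0.1 * len(ranked))))
    top_decile = set(ranked.index[:n_top])
    return {
        "n_markers": len(markers),
        "in_union": len(markers & union),
        "in_top_decile": len(markers & top_decile),
        "n_scored": len(ranked),
    }
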