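"""Synthetic data emulating the hygienic-behavior proteomics study design.

Generates every input the pipeline consumes, with known ground truth:

* colonies with latent hygienic propensity and freeze-killed-brood
  phenotypes (removed/uncapped proportions at 24/48 h, two field tests a
  week apart, averaged);
* partial-diallel F1 colonies whose propensity regresses to the midparent;
* block-structured protein quantification matrices with planted marker
  proteins, population offsets, heritable colony effects, block/label
  offsets, and abundance-dependent plus completely-at-random missingness
  of whole (protein, block) triples;
* peptide-spectrum-match tables with a correct/incorrect score mixture and
  reversed-database decoys;
* fluorescence titration curves from exact 1:1 and competitive binding
  equilibria.

All randomness flows from one integer seed through numpy SeedSequence
spawning: each sub-simulation draws from its own child stream, so outputs
are bit-reproducible and adding one simulation never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .types import (
    LABELS,
    BlockAssignment,
    ColonyRecord,
    QuantMatrix,
    TitrationCurve,
)

__all__ = [
    "GroundTruth",
    "MissingnessModel",
    "QuantSim",
    "TitrationSim",
    "simulate_colonies",
    "simulate_diallel",
    "make_ground_truth",
    "simulate_quant",
    "simulate_expression_trios",
    "simulate_psms",
    "simulate_titration",
    "bound_1to1",
    "competition_bound",
]


# ---------------------------------------------------------------------------
# colonies and phenotypes
# ---------------------------------------------------------------------------


def _draw_hb(
    hb_distribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw latent hygienic propensities in [0, 1].

    ``hb_distribution`` is ``("beta", a, b)``, ``("uniform", lo, hi)``,
    ``("point", v)`` or a callable ``f(rng, n) -> array``.
    """
    if callable(hb_distribution):
        vals = np.asarray(hb_distribution(rng, n), dtype=float)
    else:
        kind, *params = hb_distribution
        if kind == "beta":
            a, b = params
            if a <= 0 or b <= 0:
                raise ValueError(f"beta parameters must be positive, got {a}, {b}")
            vals = rng.beta(a, b, size=n)
        elif kind == "uniform":
            lo, hi = params
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"uniform range [{lo}, {hi}] outside [0, 1]")
            vals = rng.uniform(lo, hi, size=n)
        elif kind == "point":
            (v,) = params
            if not 0 <= v <= 1:
                raise ValueError(f"point mass {v} outside [0, 1]")
            vals = np.full(n, float(v))
        else:
            raise ValueError(f"unknown hb distribution {kind!r}")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("hb distribution produced values outside [0, 1]")
    return vals


def _one_test_counts(
    p: float,
    n_cells: int,
    rng: np.random.Generator,
    uncap_margin: float,
    progress: float,
) -> tuple[int, int, int, int]:
    """Counts (r24, r48, u24, u48) for one freeze-killed-brood test.

    Cells are uncapped before pupae are removed and both processes only
    accumulate between 24 and 48 h, so r24 <= u24, r24 <= r48 <= u48 and
    u24 <= u48 hold for every draw.  ``p`` is the removal-at-24h propensity;
    ``uncap_margin`` is the extra fraction of cells uncapped but not yet
    cleared at 24 h; ``progress`` is the fraction of the remaining work
    completed between 24 and 48 h.
    """
    pu24 = p + (1.0 - p) * uncap_margin
    n_u24 = int(rng.binomial(n_cells, pu24))
    n_r24 = int(rng.binomial(n_u24, p / pu24)) if pu24 > 0 else 0
    n_u48 = n_u24 + int(rng.binomial(n_cells - n_u24, progress))
    p48 = p + (1.0 - p) * progress
    pu48 = pu24 + (1.0 - pu24) * progress
    q48 = (p48 - p) / (pu48 - p) if pu48 > p else 0.0
    n_r48 = n_r24 + int(rng.binomial(n_u48 - n_r24, min(1.0, q48)))
    return n_r24, n_r48, n_u24, n_u48


def _phenotype(
    hb: float,
    n_cells: int,
    rng: np.random.Generator,
    test_retest_sd: float,
    uncap_margin: float,
    progress: float,
) -> tuple[float, float, float, float]:
    """Average the four phenotype proportions over two field tests.

    Each test perturbs the latent propensity on the logit scale
    (independent logit-normal noise per test, the tests being a week apart)
    and scores ``n_cells`` brood cells.
    """
    totals = np.zeros(4)
    for _ in range(2):
        if hb <= 0.0:
            p = 0.0
        elif hb >= 1.0:
            p = 1.0
        elif test_retest_sd > 0:
            p = float(expit(logit(hb) + rng.normal(0.0, test_retest_sd)))
        else:
            p = hb
        totals += np.array(_one_test_counts(p, n_cells, rng, uncap_margin, progress))
    r24, r48, u24, u48 = totals / (2 * n_cells)
    return r24, r48, u24, u48


def simulate_colonies(
    n_per_population: int,
    populations: Sequence[str],
    hb_distribution=("beta", 1.5, 1.5),
    n_cells_per_test: int = 100,
    seed: int = 0,
    site: str = "S1",
    year: str = "Y1",
    test_retest_sd: float = 0.3,
    uncap_margin: float = 0.15,
    progress: float = 0.5,
    id_prefix: str = "C",
) -> list[ColonyRecord]:
    """Simulate founder colonies spanning a wide range of hygienic behavior.

    Each colony draws ``hb_true`` from ``hb_distribution`` (default a wide
    Beta(1.5, 1.5)) and is scored by two freeze-killed-brood tests of
    ``n_cells_per_test`` cells each, averaged.
    """
    if n_per_population < 0:
        raise ValueError("n_per_population must be >= 0")
    if n_cells_per_test < 1:
        raise ValueError("n_cells_per_test must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    colonies: list[ColonyRecord] = []
    k = 0
    for pop in populations:
        hbs = _draw_hb(hb_distribution, n_per_population, rng)
        for hb in hbs:
            r24, r48, u24, u48 = _phenotype(
                float(hb), n_cells_per_test, rng, test_retest_sd, uncap_margin, progress
            )
            rec = ColonyRecord(
                colony_id=f"{id_prefix}{k:04d}",
                site=site,
                year=year,
                population=pop,
                hb_true=float(hb),
                r24=r24,
                r48=r48,
                u24=u24,
                u48=u48,
            )
            rec.validate()
            colonies.append(rec)
            k += 1
    return colonies


def simulate_diallel(
    parents: Sequence[ColonyRecord],
    crosses: Sequence[tuple[str, str]],
    h2_behavior: float = 0.6,
    seed: int = 0,
    segregation_sd: float = 0.08,
    n_cells_per_test: int = 100,
    site: Optional[str] = None,
    year: str = "Y3",
    test_retest_sd: float = 0.3,
    uncap_margin: float = 0.15,
    progress: float = 0.5,
    id_prefix: str = "F1-",
) -> list[ColonyRecord]:
    """Simulate F1 colonies from a partial diallel cross of the parents.

    Each cross is a ``(dam_id, sire_id)`` pair.  The F1 latent propensity is
    the parental population mean plus ``h2_behavior`` times the midparent
    deviation, plus Gaussian segregation noise, truncated to [0, 1]; at
    ``h2_behavior = 1`` and zero noise the F1 equals the midparent exactly.
    """
    if not 0 <= h2_behavior <= 1:
        raise ValueError("h2_behavior must lie in [0, 1]")
    by_id = {p.colony_id: p for p in parents}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pop_mean = float(np.mean([p.hb_true for p in parents])) if parents else 0.5
    out: list[ColonyRecord] = []
    for k, (dam_id, sire_id) in enumerate(crosses):
        if dam_id not in by_id or sire_id not in by_id:
            missing = dam_id if dam_id not in by_id else sire_id
            raise KeyError(f"cross references unknown parent colony {missing!r}")
        dam, sire = by_id[dam_id], by_id[sire_id]
        midparent = 0.5 * (dam.hb_true + sire.hb_true)
        hb = pop_mean + h2_behavior * (midparent - pop_mean)
        if segregation_sd > 0:
            hb += rng.normal(0.0, segregation_sd)
        hb = float(np.clip(hb, 0.0, 1.0))
        r24, r48, u24, u48 = _phenotype(
            hb, n_cells_per_test, rng, test_retest_sd, uncap_margin, progress
        )
        rec = ColonyRecord(
            colony_id=f"{id_prefix}{k:04d}",
            site=site if site is not None else dam.site,
            year=year,
            population=f"{dam.population}x{sire.population}",
            hb_true=hb,
            r24=r24,
            r48=r48,
            u24=u24,
            u48=u48,
            dam_id=dam_id,
            sire_id=sire_id,
        )
        rec.validate()
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# quantification matrices with planted markers
# ---------------------------------------------------------------------------


@dataclass
class MissingnessModel:
    """Block-level missingness: abundance-dependent plus flat MCAR.

    A whole (protein, block) triple goes missing with probability
    ``expit(mnar_intercept - mnar_slope * (baseline - median baseline))``
    (low-abundance proteins drop out more, mimicking data-dependent
    acquisition) combined with an independent completely-at-random rate.
    """

    mnar_intercept: float = -1.7
    mnar_slope: float = 1.0
    mcar_rate: float = 0.1

    def missing_probability(self, baselines: np.ndarray) -> np.ndarray:
        centered = baselines - np.median(baselines)
        p_mnar = expit(self.mnar_intercept - self.mnar_slope * centered)
        return p_mnar + self.mcar_rate - p_mnar * self.mcar_rate

    @classmethod
    def none(cls) -> "MissingnessModel":
        return cls(mnar_intercept=-np.inf, mnar_slope=0.0, mcar_rate=0.0)


@dataclass
class GroundTruth:
    """Known generative parameters of a simulated quantification experiment.

    ``beta`` holds the standardized effect of hygienic propensity on
    log-expression per protein (nonzero only for planted markers); ``h2``
    the narrow-sense heritability of each protein's colony-level expression
    (fraction of colony-level variance that is additive genetic);
    ``sigma_colony`` the total colony-level SD; ``sigma_resid`` the
    within-colony residual SD per sample.
    """

    protein_ids: list[str]
    marker_ids: set[str]
    beta: dict[str, float]
    h2: dict[str, float]
    baselines: dict[str, float]
    pop_effects: dict[tuple[str, str], float]
    sigma_colony: float
    sigma_resid: float
    sigma_block: float
    sigma_label: float
    missing_model: MissingnessModel = field(default_factory=MissingnessModel)

    def __post_init__(self) -> None:
        if not self.marker_ids <= set(self.protein_ids):
            raise ValueError("marker_ids must be a subset of protein_ids")
        for p, h in self.h2.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"h2[{p}]={h} outside [0, 1]")
        for name in ("sigma_colony", "sigma_resid", "sigma_block", "sigma_label"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_ground_truth(
    n_proteins: int,
    populations: Sequence[str],
    n_markers: int = 5,
    marker_beta: float = 0.6,
    h2: float = 0.4,
    marker_h2: Optional[float] = None,
    baseline_mean: float = 14.0,
    baseline_sd: float = 1.5,
    pop_effect_sd: float = 0.2,
    sigma_colony: float = 0.5,
    sigma_resid: float = 0.5,
    sigma_block: float = 0.3,
    sigma_label: float = 0.2,
    missing_model: Optional[MissingnessModel] = None,
    seed: int = 0,
) -> GroundTruth:
    """Build a GroundTruth with ``n_markers`` planted markers of effect ``marker_beta``.

    Baselines are natural-log intensities around ``baseline_mean``; marker
    proteins are chosen uniformly at random.  ``pop_effect_sd`` sets the
    scale of per-(protein, population) expression offsets.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ids = [f"P{i:04d}" for i in range(n_proteins)]
    markers = set(
        np.array(ids)[rng.choice(n_proteins, size=n_markers, replace=False)]
    ) if n_markers else set()
    beta = {p: (marker_beta if p in markers else 0.0) for p in ids}
    h2_map = {
        p: (marker_h2 if (marker_h2 is not None and p in markers) else h2) for p in ids
    }
    baselines = {p: float(v) for p, v in zip(ids, rng.normal(baseline_mean, baseline_sd, n_proteins))}
    pops = list(populations)
    pop_eff = {
        (p, q): float(v)
        for p in ids
        for q, v in zip(pops, rng.normal(0.0, pop_effect_sd, len(pops)))
    }
    return GroundTruth(
        protein_ids=ids,
        marker_ids={str(m) for m in markers},
        beta=beta,
        h2=h2_map,
        baselines=baselines,
        pop_effects=pop_eff,
        sigma_colony=sigma_colony,
        sigma_resid=sigma_resid,
        sigma_block=sigma_block,
        sigma_label=sigma_label,
        missing_model=missing_model if missing_model is not None else MissingnessModel(),
    )


def _colony_genetic_values(
    colonies: Sequence[ColonyRecord],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> np.ndarray:
    """Additive genetic values g[protein, colony], transmitted through pedigrees.

    Founders draw g ~ N(0, h2 * sigma_colony^2); an F1 colony receives the
    midparent mean plus Mendelian segregation noise of half the founder
    genetic variance, so relatives covary as expected under an additive model.
    """
    n_p = len(truth.protein_ids)
    idx = {c.colony_id: j for j, c in enumerate(colonies)}
    sg = np.sqrt(np.array([truth.h2[p] for p in truth.protein_ids])) * truth.sigma_colony
    g = np.zeros((n_p, len(colonies)))
    for j, c in enumerate(colonies):
        if c.dam_id in idx and c.sire_id in idx:
            mid = 0.5 * (g[:, idx[c.dam_id]] + g[:, idx[c.sire_id]])
            g[:, j] = mid + rng.normal(0.0, 1.0, n_p) * sg * math.sqrt(0.5)
        else:
            g[:, j] = rng.normal(0.0, 1.0, n_p) * sg
    return g


@dataclass
class QuantSim:
    """A simulated quantification experiment plus its per-level truth."""

    matrix: QuantMatrix
    truth: GroundTruth
    colony_values: pd.DataFrame  # protein x colony expected log-expression
    block_offsets: pd.Series
    label_offsets: pd.Series


def simulate_quant(
    colonies: Sequence[ColonyRecord],
    assignment: BlockAssignment,
    truth: GroundTruth,
    seed: int = 0,
) -> QuantSim:
    """Simulate a raw protein x (block, label) intensity matrix.

    Log-intensity of protein p in the sample of colony c placed at
    (block b, label l) is::

        baseline_p + pop_effect[p, pop(c)] + beta_p * z(hb_c)
        + colony_effect[p, c] + block_offset[b] + label_offset[l] + resid

    where z() standardizes ``hb_true`` over the supplied colonies and the
    colony effect splits into a heritable genetic part (variance
    ``h2 * sigma_colony^2``, transmitted through the pedigree) and an
    environmental part.  Entire (protein, block) triples go missing under
    ``truth.missing_model``.  Stored intensities are exp(log-intensity).
    """
    ids = {c.colony_id for c in colonies}
    for block in assignment.blocks:
        for slot in block:
            if slot.colony_id not in ids:
                raise ValueError(
                    f"assignment references colony {slot.colony_id!r} absent "
                    "from the colony list"
                )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    proteins = truth.protein_ids
    n_p = len(proteins)
    hb = np.array([c.hb_true for c in colonies])
    sd = hb.std()
    z = (hb - hb.mean()) / sd if sd > 0 else np.zeros_like(hb)
    zmap = {c.colony_id: z[j] for j, c in enumerate(colonies)}
    popmap = {c.colony_id: c.population for c in colonies}

    g = _colony_genetic_values(colonies, truth, rng)
    se = np.sqrt(1.0 - np.array([truth.h2[p] for p in proteins])) * truth.sigma_colony
    env = rng.normal(0.0, 1.0, g.shape) * se[:, None]
    colony_effect = g + env

    base = np.array([truth.baselines[p] for p in proteins])
    beta = np.array([truth.beta[p] for p in proteins])
    cid_idx = {c.colony_id: j for j, c in enumerate(colonies)}
    colony_values = pd.DataFrame(
        base[:, None]
        + np.array(
            [
                [truth.pop_effects.get((p, popmap[c.colony_id]), 0.0) for c in colonies]
                for p in proteins
            ]
        )
        + beta[:, None] * np.array([zmap[c.colony_id] for c in colonies])[None, :]
        + colony_effect,
        index=pd.Index(proteins, name="protein"),
        columns=[c.colony_id for c in colonies],
    )

    block_ids = assignment.block_ids()
    block_off = pd.Series(
        rng.normal(0.0, truth.sigma_block, len(block_ids)), index=block_ids
    )
    label_off = pd.Series(rng.normal(0.0, truth.sigma_label, 3), index=list(LABELS))

    columns = pd.MultiIndex.from_tuples(
        [(b, lab) for b in block_ids for lab in LABELS], names=["block", "label"]
    )
    vals = np.empty((n_p, len(columns)))
    col_colonies = []
    for bi, b in enumerate(block_ids):
        for lab in LABELS:
            col_colonies.append(assignment.colony_of(b, lab))
    for k, (b, lab) in enumerate(columns):
        j = cid_idx[col_colonies[k]]
        vals[:, k] = (
            colony_values.iloc[:, j].to_numpy()
            + block_off[b]
            + label_off[lab]
            + rng.normal(0.0, truth.sigma_resid, n_p)
        )

    # block-level missingness: whole triples drop out together
    p_miss = truth.missing_model.missing_probability(base)
    miss = rng.random((n_p, len(block_ids))) < p_miss[:, None]
    for bi, b in enumerate(block_ids):
        cols = [3 * bi, 3 * bi + 1, 3 * bi + 2]
        vals[np.ix_(miss[:, bi], cols)] = np.nan

    matrix = QuantMatrix(
        values=pd.DataFrame(np.exp(vals), index=pd.Index(proteins, name="protein"), columns=columns),
        state="raw",
        provenance=[f"simulate_quant(seed={seed}, n_proteins={n_p}, n_blocks={len(block_ids)})"],
    )
    return QuantSim(matrix, truth, colony_values, block_off, label_off)


def simulate_expression_trios(
    n_trios: int,
    h2: float = 0.6,
    sigma_total: float = 1.0,
    measurement_sd: float = 0.0,
    n_daughters: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Colony-level expression for dam/sire/daughter trios under additive genetics.

    Founder dams and sires carry genetic value ~ N(0, h2 * sigma_total^2)
    and environment ~ N(0, (1-h2) * sigma_total^2); each cross produces
    ``n_daughters`` daughter colonies (sister queens inseminated with the
    same sire's drones) receiving the midparent genetic value plus
    independent segregation noise of half the genetic variance, and the
    reported daughter level is their mean.  Optional measurement noise is
    added to every observed level.  The expected joint-regression slope sum
    (daughter on dam and sire) equals h2 regardless of ``n_daughters``;
    averaging daughters only sharpens the estimate by averaging away
    environmental and segregation noise.
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must lie in [0, 1]")
    if n_daughters < 1:
        raise ValueError("n_daughters must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sg = math.sqrt(h2) * sigma_total
    senv = math.sqrt(1 - h2) * sigma_total
    g_dam = rng.normal(0, sg, n_trios)
    g_sire = rng.normal(0, sg, n_trios)
    mid = 0.5 * (g_dam + g_sire)
    daughters = np.zeros(n_trios)
    for _ in range(n_daughters):
        g_child = mid + rng.normal(0, sg * math.sqrt(0.5), n_trios)
        obs_child = (
            g_child
            + rng.normal(0, senv, n_trios)
            + rng.normal(0, measurement_sd, n_trios)
        )
        daughters += obs_child
    obs = {
        "dam": g_dam + rng.normal(0, senv, n_trios) + rng.normal(0, measurement_sd, n_trios),
        "sire": g_sire + rng.normal(0, senv, n_trios) + rng.normal(0, measurement_sd, n_trios),
        "daughter": daughters / n_daughters,
    }
    return pd.DataFrame(obs)


# ---------------------------------------------------------------------------
# PSM score mixtures with decoys
# ---------------------------------------------------------------------------


def simulate_psms(
    n_target_proteins: int,
    peptides_per_protein: int = 5,
    decoy_fraction: float = 0.5,
    score_model: Optional[dict] = None,
    shared_peptide_rate: float = 0.0,
    subset_protein_rate: float = 0.0,
    seed: int = 0,
    block: str = "B000",
) -> pd.DataFrame:
    """Simulate a PSM table with a two-component score mixture and decoys.

    Every target peptide yields one PSM whose score comes from the correct
    component with probability ``1 - pi_incorrect`` and from the incorrect
    component otherwise.  Incorrect spectra additionally match the reversed
    (decoy) database: for each incorrect target PSM, a matching decoy PSM is
    emitted with odds ``decoy_fraction : (1 - decoy_fraction)`` (0.5 models
    equal-size target and decoy databases, making the decoy count an
    unbiased estimate of incorrect target hits).  ``shared_peptide_rate``
    makes a peptide map to a second protein; ``subset_protein_rate`` makes a
    protein's peptides a strict subset of another protein's.

    Columns: peptide_id, protein_ids (semicolon-joined), score, decoy,
    correct (ground truth), block, intensity_light/medium/heavy.
    """
    for name, v in (("decoy_fraction", decoy_fraction), ("shared_peptide_rate", shared_peptide_rate), ("subset_protein_rate", subset_protein_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    sm = {
        "mu_correct": 45.0,
        "sd_correct": 8.0,
        "mu_incorrect": 15.0,
        "sd_incorrect": 7.0,
        "pi_incorrect": 0.1,
    }
    if score_model:
        sm.update(score_model)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    proteins = [f"T{i:04d}" for i in range(n_target_proteins)]
    rows = []
    pep_counter = 0
    subset_of: dict[str, str] = {}
    for i, prot in enumerate(proteins):
        if i > 0 and rng.random() < subset_protein_rate:
            subset_of[prot] = proteins[int(rng.integers(i))]
    peptide_owner: dict[str, list[str]] = {}
    for prot in proteins:
        if prot in subset_of:
            continue
        peps = []
        for _ in range(peptides_per_protein):
            pid = f"pep{pep_counter:06d}"
            pep_counter += 1
            owners = [prot]
            if shared_peptide_rate > 0 and rng.random() < shared_peptide_rate and len(proteins) > 1:
                other = proteins[int(rng.integers(len(proteins)))]
                if other != prot and other not in subset_of:
                    owners.append(other)
            peptide_owner[pid] = owners
            peps.append(pid)
    for prot, parent in subset_of.items():
        parent_peps = [p for p, o in peptide_owner.items() if parent in o]
        if len(parent_peps) >= 2:
            take = rng.choice(parent_peps, size=max(1, len(parent_peps) // 2), replace=False)
            for p in take:
                peptide_owner[p].append(prot)

    decoy_counter = 0
    for pid, owners in peptide_owner.items():
        correct = rng.random() >= sm["pi_incorrect"]
        if correct:
            score = rng.normal(sm["mu_correct"], sm["sd_correct"])
        else:
            score = rng.normal(sm["mu_incorrect"], sm["sd_incorrect"])
        inten = np.exp(rng.normal(10.0, 1.0, 3))
        rows.append(
            {
                "peptide_id": pid,
                "protein_ids": ";".join(sorted(set(owners))),
                "score": float(score),
                "decoy": False,
                "correct": bool(correct),
                "block": block,
                "intensity_light": inten[0],
                "intensity_medium": inten[1],
                "intensity_heavy": inten[2],
            }
        )
        if not correct and decoy_fraction > 0:
            odds = decoy_fraction / (1.0 - decoy_fraction) if decoy_fraction < 1 else np.inf
            n_decoy = rng.poisson(odds) if np.isfinite(odds) else 1
            for _ in range(int(n_decoy)):
                inten_d = np.exp(rng.normal(10.0, 1.0, 3))
                rows.append(
                    {
                        "peptide_id": f"decoypep{decoy_counter:06d}",
                        "protein_ids": f"DECOY_{decoy_counter:05d}",
                        "score": float(rng.normal(sm["mu_incorrect"], sm["sd_incorrect"])),
                        "decoy": True,
                        "correct": False,
                        "block": block,
                        "intensity_light": inten_d[0],
                        "intensity_medium": inten_d[1],
                        "intensity_heavy": inten_d[2],
                    }
                )
                decoy_counter += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binding equilibria and titrations
# ---------------------------------------------------------------------------


def bound_1to1(protein_tot: float, ligand_tot: float, kd: float) -> float:
    """Bound complex concentration for exact 1:1 binding (quadratic root).

    Solves ``B^2 - (P + L + Kd) B + P L = 0`` for the physical root,
    accounting for ligand and protein depletion.
    """
    if protein_tot < 0 or ligand_tot < 0 or kd <= 0:
        raise ValueError("concentrations must be >= 0 and kd > 0")
    s = protein_tot + ligand_tot + kd
    disc = s * s - 4.0 * protein_tot * ligand_tot
    return 0.5 * (s - math.sqrt(max(disc, 0.0)))


def competition_bound(
    protein_tot: float,
    probe_tot: float,
    probe_kd: float,
    comp_tot: float,
    comp_kd: float,
    tol: float = 1e-10,
) -> tuple[float, float, float]:
    """Coupled competitive 1:1 equilibria, solved for free protein by bisection.

    Returns ``(bound_probe, free_probe, bound_competitor)``.  The protein
    mass balance ``Pf (1 + Lt/(KL+Pf) + Ct/(KC+Pf)) = Pt`` is monotone in
    free protein, so Brent's method on [0, Pt] converges; residuals are
    verified against ``tol`` relative to total concentrations.
    """
    if min(protein_tot, probe_tot) < 0 or comp_tot < 0 or probe_kd <= 0 or comp_kd <= 0:
        raise ValueError("invalid concentrations or dissociation constants")
    if comp_tot == 0:
        b = bound_1to1(protein_tot, probe_tot, probe_kd)
        return b, probe_tot - b, 0.0

    def balance(pf: float) -> float:
        return (
            pf * (1.0 + probe_tot / (probe_kd + pf) + comp_tot / (comp_kd + pf))
            - protein_tot
        )

    pf = brentq(balance, 0.0, protein_tot, xtol=1e-16, rtol=8.881784197001252e-16)
    bound_probe = probe_tot * pf / (probe_kd + pf)
    bound_comp = comp_tot * pf / (comp_kd + pf)
    resid = abs(pf + bound_probe + bound_comp - protein_tot)
    if resid > tol * max(protein_tot, probe_tot, comp_tot, 1.0):
        raise RuntimeError(
            f"equilibrium solve did not converge: mass-balance residual {resid:.3e}"
        )
    return bound_probe, probe_tot - bound_probe, bound_comp


@dataclass
class TitrationSim:
    """A simulated titration curve plus its generative truth."""

    curve: TitrationCurve
    true_probe_kd: float
    true_competitor_kd: Optional[float]
    fluorescence_scale: float
    baseline: float
    bound_true: list[float]


def simulate_titration(
    protein_conc: float,
    probe_kd: float,
    probe_concs: Optional[Sequence[float]] = None,
    competitor_kd: Optional[float] = None,
    competitor_concs: Optional[Sequence[float]] = None,
    probe_conc: Optional[float] = None,
    noise_cv: float = 0.02,
    seed: int = 0,
    fluorescence_scale: float = 1000.0,
    baseline: float = 0.0,
    micelle_cmc: Optional[float] = None,
    micelle_slope: float = 0.0,
    ligand_name: str = "",
) -> TitrationSim:
    """Simulate a fluorescence titration from exact binding equilibria.

    Saturation mode (``probe_concs`` given): the probe itself is titrated
    and fluorescence tracks the bound probe from the exact 1:1 quadratic.
    Competition mode (``competitor_kd``/``competitor_concs``/``probe_conc``
    given): probe and competitor equilibria are solved jointly at each
    competitor concentration.  Fluorescence is
    ``(scale * bound + baseline) * lognormal(cv)``; an optional micelle
    artifact adds signal above ``micelle_cmc``.
    """
    if protein_conc <= 0 or probe_kd <= 0:
        raise ValueError("protein_conc and probe_kd must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if competitor_kd is not None:
        if competitor_concs is None or probe_conc is None:
            raise ValueError("competition mode needs competitor_concs and probe_conc")
        concs = list(competitor_concs)
        if any(c < 0 for c in concs):
            raise ValueError("competitor concentrations must be >= 0")
        bound = [
            competition_bound(protein_conc, probe_conc, probe_kd, c, competitor_kd)[0]
            for c in concs
        ]
        mode = "competition"
    else:
        if probe_concs is None:
            raise ValueError("saturation mode needs probe_concs")
        concs = list(probe_concs)
        if any(c <= 0 for c in concs):
            raise ValueError("probe concentrations must be > 0")
        bound = [bound_1to1(protein_conc, c, probe_kd) for c in concs]
        mode = "saturation"
    fl = fluorescence_scale * np.array(bound) + baseline
    if micelle_cmc is not None and micelle_slope > 0:
        over = np.maximum(np.array(concs) - micelle_cmc, 0.0)
        fl = fl + micelle_slope * over
    if noise_cv > 0:
        sigma = math.sqrt(math.log1p(noise_cv**2))
        fl = fl * rng.lognormal(-0.5 * sigma**2, sigma, len(fl))
    curve = TitrationCurve(
        protein_conc=protein_conc,
        points=list(zip([float(c) for c in concs], [float(f) for f in fl])),
        mode=mode,
        probe_conc=float(probe_conc) if probe_conc is not None else float("nan"),
        ligand_name=ligand_name,
    )
    return TitrationSim(
        curve=curve,
        true_probe_kd=probe_kd,
        true_competitor_kd=competitor_kd,
        fluorescence_scale=fluorescence_scale,
        baseline=baseline,
        bound_true=[float(b) for b in bound],
    )
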