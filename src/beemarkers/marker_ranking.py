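"""Cross-dataset marker ranking and selection.

Combines per-dataset association results into an overall hygienic-behavior
(HB) correlation score:

    correlation_score = mean(HB factor over datasets where quantified)
                        + heritability factor

The per-dataset HB factor multiplies a statistical factor (capped
-log10 p) by a biological factor derived from the standardized effect
magnitude, signed by whether the dataset's effect direction agrees with
the protein's cross-dataset majority direction.  The heritability factor
rewards proteins whose expression is transmitted from dam and sire to F1
daughter colonies, from a joint midparent regression.  These factor
formulas are this package's declared interpretation of "combining a
biological and statistical factor": they are unitless, reward directional
consistency, and are configurable; nothing downstream depends on their
exact shape.

Selection applies three routes, each tagged in the output: (a) low
q-value in a designated reference dataset; (b) p < 0.05 for all four
field parameters in both first-year site datasets; (c) top-k by
correlation score among proteins quantified in enough datasets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import HB_VARIABLES, AssociationResult, HeritabilityFit, MarkerScore

__all__ = [
    "FactorConfig",
    "SelectionRules",
    "dataset_hb_factor",
    "majority_direction",
    "fit_midparent_regression",
    "heritability_factor",
    "overall_score",
    "rank_markers",
    "select_markers",
]


@dataclass
class FactorConfig:
    """Tunable caps and weights of the HB and heritability factors."""

    stat_cap: float = 10.0  # cap on -log10(p)
    bio_cap: float = 2.0  # cap on |standardized effect|
    h2_weight_significant: float = 1.0  # joint_p < 0.05
    h2_weight_suggestive: float = 0.5  # joint_p < 0.5
    h2_weight_weak: float = 0.25  # otherwise


def dataset_hb_factor(
    result: AssociationResult,
    direction_reference: float,
    config: Optional[FactorConfig] = None,
) -> float:
    """Signed HB factor of one dataset's association result.

    statistical factor ``s = min(-log10 p, cap)`` (p = 0 uses the cap);
    biological factor ``b = min(|effect|, cap)`` (the effect is already in
    pooled-SD units on the standardized matrix); the factor is
    ``sign * s * (1 + b) / 2`` with sign +1 when the effect direction
    matches ``direction_reference`` (ties count as agreement) and -1
    otherwise.  Undefined (NaN) inputs yield NaN, excluding the dataset
    from the protein's average.
    """
    cfg = config or FactorConfig()
    if not np.isfinite(result.effect) or np.isnan(result.p_value):
        return float("nan")
    p = result.p_value
    s = cfg.stat_cap if p <= 0 else min(-math.log10(p), cfg.stat_cap)
    b = min(abs(result.effect), cfg.bio_cap)
    agree = result.effect * direction_reference >= 0
    return (1.0 if agree else -1.0) * s * (1.0 + b) / 2.0


def majority_direction(effects: Sequence[float]) -> float:
    """Majority sign of a protein's effects across datasets; ties are positive."""
    signs = [math.copysign(1.0, e) for e in effects if np.isfinite(e) and e != 0]
    if not signs:
        return 1.0
    return 1.0 if sum(signs) >= 0 else -1.0


def fit_midparent_regression(
    daughter: Sequence[float],
    dam: Sequence[float],
    sire: Sequence[float],
    protein_id: str = "",
) -> HeritabilityFit:
    """Joint regression of F1 daughter expression on dam and sire levels.

    Under an additive model the expected slope sum approximates the
    narrow-sense heritability of the expression level.  ``joint_p`` is the
    F-test of both slopes being zero.
    """
    y = np.asarray(daughter, float)
    X = np.column_stack([np.ones(len(y)), np.asarray(dam, float), np.asarray(sire, float)])
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete trios, got {n}")
    res = sm.OLS(y[ok], X[ok]).fit()
    return HeritabilityFit(
        protein_id=protein_id,
        slope_dam=float(res.params[1]),
        slope_sire=float(res.params[2]),
        joint_p=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0,
        n_trios=n,
    )


def heritability_factor(
    fit: Optional[HeritabilityFit],
    config: Optional[FactorConfig] = None,
) -> float:
    """Nonnegative heritability factor from a midparent regression fit.

    ``max(0, slope_dam + slope_sire)`` weighted by the joint p-value
    (1 if p < 0.05, 0.5 if p < 0.5, 0.25 otherwise).  Absent pedigree data
    or fewer than three trios give 0.
    """
    cfg = config or FactorConfig()
    if fit is None or fit.n_trios < 3:
        return 0.0
    total = fit.slope_dam + fit.slope_sire
    if not np.isfinite(total):
        return 0.0
    if fit.joint_p < 0.05:
        w = cfg.h2_weight_significant
    elif fit.joint_p < 0.5:
        w = cfg.h2_weight_suggestive
    else:
        w = cfg.h2_weight_weak
    return max(0.0, total) * w


def overall_score(
    per_dataset: Mapping[str, float],
    heritability: float,
    protein_id: str = "",
    min_datasets: int = 4,
    total_datasets: Optional[int] = None,
) -> MarkerScore:
    """Overall HB correlation score: mean dataset factor plus heritability.

    Proteins quantified in fewer than ``min_datasets`` datasets keep their
    score but are flagged ineligible for the ranked list.
    """
    finite = {d: f for d, f in per_dataset.items() if np.isfinite(f)}
    if not finite:
        raise ValueError(f"{protein_id}: no dataset factor available")
    n_q = len(finite)
    if total_datasets is not None and n_q > total_datasets:
        raise ValueError("more dataset factors than datasets")
    score = float(np.mean(list(finite.values()))) + heritability
    return MarkerScore(
        protein_id=protein_id,
        per_dataset_factor=dict(finite),
        n_datasets_quantified=n_q,
        heritability_factor=heritability,
        correlation_score=score,
        selection_rules_hit=(["eligible"] if n_q >= min_datasets else ["ineligible"]),
    )


def rank_markers(
    hb_results: Mapping[str, pd.DataFrame],
    heritability_fits: Optional[Mapping[str, HeritabilityFit]] = None,
    config: Optional[FactorConfig] = None,
    min_datasets: int = 4,
) -> pd.DataFrame:
    """Score every protein over the datasets' HB association results.

    ``hb_results`` maps dataset name to a run_dataset frame (indexed by
    protein with effect/p_value columns).  Returns a frame sorted by
    descending correlation score with per-dataset factors, the heritability
    factor, and an eligibility flag; insensitive to dataset or protein
    input order.
    """
    cfg = config or FactorConfig()
    datasets = sorted(hb_results)
    proteins = sorted(set().union(*(set(hb_results[d].index) for d in datasets)))
    fits = heritability_fits or {}
    rows = []
    for prot in proteins:
        effects = []
        per_ds: dict[str, AssociationResult] = {}
        for d in datasets:
            df = hb_results[d]
            if prot not in df.index or np.isnan(df.loc[prot, "p_value"]):
                continue
            r = AssociationResult(
                protein_id=prot,
                predictor="hb",
                effect=float(df.loc[prot, "effect"]),
                se=float(df.loc[prot, "se"]),
                p_value=float(df.loc[prot, "p_value"]),
            )
            per_ds[d] = r
            effects.append(r.effect)
        if not per_ds:
            continue
        direction = majority_direction(effects)
        factors = {d: dataset_hb_factor(r, direction, cfg) for d, r in per_ds.items()}
        h = heritability_factor(fits.get(prot), cfg)
        ms = overall_score(factors, h, prot, min_datasets, total_datasets=len(datasets))
        row = {
            "protein": prot,
            "correlation_score": ms.correlation_score,
            "heritability_factor": h,
            "n_datasets_quantified": ms.n_datasets_quantified,
            "eligible": ms.n_datasets_quantified >= min_datasets,
        }
        for d in datasets:
            row[f"factor_{d}"] = factors.get(d, np.nan)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("protein")
    return out.sort_values("correlation_score", ascending=False)


@dataclass
class SelectionRules:
    """Thresholds of the three marker-selection routes (study defaults)."""

    reference_dataset: Optional[str] = None  # route (a) dataset
    q_threshold: float = 0.1
    strong_p: float = 0.0005  # stricter tag within route (a)
    two_site_datasets: tuple[str, str] | None = None  # route (b) Y1 site pair
    two_site_p: float = 0.05
    field_parameters: tuple[str, ...] = HB_VARIABLES
    top_k: int = 10  # route (c)
    min_datasets: int = 4


def select_markers(
    scores: pd.DataFrame,
    site_results: Mapping[str, Mapping[str, pd.DataFrame]],
    rules: Optional[SelectionRules] = None,
) -> pd.DataFrame:
    """Union of the three selection routes with per-protein rule tags.

    ``scores`` is the rank_markers output; ``site_results`` maps dataset ->
    predictor -> results frame.  Route tags: ``reference_q`` (q below
    threshold in the reference dataset), ``reference_strong`` (additionally
    p below the strict cutoff), ``two_site`` (p < threshold for every field
    parameter in both designated site datasets), ``top_ranked`` (top-k
    correlation score among eligible proteins).
    """
    rules = rules or SelectionRules()
    tags: dict[str, list[str]] = {}

    def add(prot: str, tag: str) -> None:
        tags.setdefault(prot, []).append(tag)

    if rules.reference_dataset is not None:
        if rules.reference_dataset not in site_results:
            warnings.warn(
                f"reference dataset {rules.reference_dataset!r} missing; "
                "route (a) skipped",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            preds = site_results[rules.reference_dataset]
            for pred, df in preds.items():
                if pred not in rules.field_parameters:
                    continue
                hit = df.index[df["q_value"] < rules.q_threshold]
                for prot in hit:
                    add(prot, "reference_q")
                strong = df.index[
                    (df["q_value"] < rules.q_threshold)
                    & (df["p_value"] < rules.strong_p)
                ]
                for prot in strong:
                    add(prot, "reference_strong")

    if rules.two_site_datasets is not None:
        d1, d2 = rules.two_site_datasets
        if d1 in site_results and d2 in site_results:
            candidates: Optional[set[str]] = None
            for d in (d1, d2):
                for pred in rules.field_parameters:
                    df = site_results[d].get(pred)
                    if df is None:
                        candidates = set()
                        break
                    ok = set(df.index[df["p_value"] < rules.two_site_p])
                    candidates = ok if candidates is None else candidates & ok
                if candidates == set():
                    break
            for prot in sorted(candidates or set()):
                add(prot, "two_site")
        else:
            warnings.warn(
                "two-site datasets missing; route (b) skipped",
                RuntimeWarning,
                stacklevel=2,
            )

    eligible = scores[scores["eligible"]].sort_values(
        "correlation_score", ascending=False
    )
    for prot in eligible.index[: rules.top_k]:
        add(prot, "top_ranked")

    rows = [
        {
            "protein": prot,
            "rules_hit": ",".join(sorted(set(tg))),
            "correlation_score": (
                float(scores.loc[prot, "correlation_score"])
                if prot in scores.index
                else np.nan
            ),
        }
        for prot, tg in sorted(tags.items())
    ]
    out = pd.DataFrame(rows, columns=["protein", "rules_hit", "correlation_score"])
    return out.set_index("protein").sort_values("correlation_score", ascending=False)
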