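"""PSM filtering, parsimony protein inference, and matrix normalization.

Turns peptide-spectrum-match evidence into a filtered, normalized protein
x (block, label) matrix the association stage can consume:

1. per-block target-decoy FDR thresholding (1% default) with an ions-score
   quantification gate (>= 25 default);
2. greedy parsimony (Occam's razor) protein grouping with per-(group,
   block) averaging of peptide log-ratios;
3. a detection filter keeping proteins seen in at least a quarter of
   blocks;
4. the normalization chain: log, per-(protein, block) mean subtraction,
   then median/MAD standardization within each isotopic label across all
   proteins and blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .types import LABELS, QuantMatrix, QuantMatrixError

#: Normal-consistency factor: MAD * 1.4826 estimates the SD of a Gaussian.
MAD_SCALE = 1.4826


class DegenerateScaleError(ValueError):
    """A label's MAD is zero; standardization is undefined."""


# ---------------------------------------------------------------------------
# decoy FDR filtering
# ---------------------------------------------------------------------------


@dataclass
class FDRFilterResult:
    accepted: pd.DataFrame
    thresholds: dict[str, float]  # block -> score threshold
    warnings: list[str] = field(default_factory=list)


def _block_threshold(scores: np.ndarray, decoy: np.ndarray, fdr: float) -> Optional[float]:
    """Smallest score t with (#decoys >= t) / (#targets >= t) <= fdr.

    Scans all unique observed scores (exhaustive: the FDP curve is a step
    function changing only at observed scores).  Returns None when no
    threshold achieves the target FDR.
    """
    order = np.argsort(scores)[::-1]
    s = scores[order]
    d = decoy[order]
    n_decoy = np.cumsum(d)
    n_target = np.cumsum(~d)
    best: Optional[float] = None
    for i in range(len(s) - 1, -1, -1):
        if i + 1 < len(s) and s[i] == s[i + 1]:
            continue  # evaluate each unique score once, at its last occurrence
        if n_target[i] == 0:
            continue
        if n_decoy[i] / n_target[i] <= fdr:
            best = float(s[i])
            break  # scores sorted descending: this is the smallest passing t
    return best


def decoy_fdr_filter(
    psms: pd.DataFrame,
    fdr: float = 0.01,
    min_score: float = 25.0,
) -> FDRFilterResult:
    """Per-block target-decoy FDR thresholding plus the quantification gate.

    For each block the smallest score threshold t is chosen such that the
    decoy/target count ratio at scores >= t does not exceed ``fdr`` (the
    plain ratio estimator, no +1 correction).  Accepted PSMs are the target
    PSMs with ``score >= max(t, min_score)``.  Blocks where decoys dominate
    at every threshold yield an empty accepted set with a warning.
    """
    if psms.empty:
        raise ValueError("psms is empty")
    if not 0.0 < fdr < 1.0:
        raise ValueError(f"fdr={fdr} outside (0, 1)")
    blocks = psms["block"] if "block" in psms.columns else pd.Series("", index=psms.index)
    thresholds: dict[str, float] = {}
    warns: list[str] = []
    keep_masks = []
    for block, sub in psms.groupby(blocks, sort=True):
        t = _block_threshold(
            sub["score"].to_numpy(float), sub["decoy"].to_numpy(bool), fdr
        )
        if t is None:
            thresholds[str(block)] = float("inf")
            warns.append(
                f"block {block!r}: no score threshold achieves {fdr:.0%} FDR; "
                "all PSMs rejected"
            )
            continue
        if t <= float(sub["score"].min()):
            eff = min_score  # whole block passes: only the score gate applies
        else:
            eff = max(t, min_score)
        thresholds[str(block)] = eff
        keep_masks.append(sub.index[(~sub["decoy"]) & (sub["score"] >= eff)])
    for w in warns:
        warnings.warn(w, RuntimeWarning, stacklevel=2)
    keep = psms.index[:0] if not keep_masks else keep_masks[0].append(keep_masks[1:])
    return FDRFilterResult(
        accepted=psms.loc[keep].copy(), thresholds=thresholds, warnings=warns
    )


# ---------------------------------------------------------------------------
# parsimony protein inference
# ---------------------------------------------------------------------------


@dataclass
class ProteinGroup:
    group_id: str  # lead accession (lexicographically first of the leads)
    members: list[str]  # all accessions merged or absorbed into the group
    peptides: set[str]


@dataclass
class ParsimonyResult:
    groups: list[ProteinGroup]
    ratios: pd.DataFrame  # (group, block) x log2-ratio columns


def _peptide_map(accepted: pd.DataFrame) -> dict[str, set[str]]:
    """protein accession -> set of peptide ids mapped to it."""
    out: dict[str, set[str]] = {}
    for pep, prots in zip(accepted["peptide_id"], accepted["protein_ids"]):
        for prot in str(prots).split(";"):
            out.setdefault(prot, set()).add(pep)
    return out


def _greedy_cover(pep_sets: dict[str, set[str]], universe: set[str]) -> list[str]:
    """Greedy set cover: repeatedly take the protein explaining the most
    unexplained peptides, ties broken by accession order."""
    uncovered = set(universe)
    remaining = dict(pep_sets)
    chosen: list[str] = []
    while uncovered:
        best = max(sorted(remaining), key=lambda p: len(remaining[p] & uncovered))
        if not pep_sets[best] & uncovered:
            break
        chosen.append(best)
        uncovered -= pep_sets[best]
        remaining.pop(best)
    return chosen


def _exact_cover(
    pep_sets: dict[str, set[str]], universe: set[str], cap: int
) -> list[str]:
    """Smallest set cover by combination search up to size ``cap`` (the
    greedy solution size); first hit in combination order is the
    lexicographically smallest minimum cover."""
    prots = sorted(pep_sets)
    for k in range(1, cap):
        for combo in combinations(prots, k):
            if set().union(*(pep_sets[p] for p in combo)) >= universe:
                return list(combo)
    return []  # greedy size is already minimal


def parsimony_group(accepted: pd.DataFrame, exact_max_proteins: int = 16) -> ParsimonyResult:
    """Minimal-set-cover protein inference with per-block ratio averages.

    Instances with at most ``exact_max_proteins`` candidate proteins are
    solved to the exact minimum (combination search, capped by the greedy
    solution); larger instances use the greedy heuristic of repeatedly
    selecting the protein explaining the most unexplained peptides (ties
    by accession order).  Proteins with identical peptide sets merge into
    one group; proteins whose peptide sets are subsets of a selected
    protein's set are absorbed into its group.  Every accepted peptide ends
    up covered.  Per group and block, each label-pair log2 ratio is the
    arithmetic mean of its peptides' log2 ratios (geometric mean of raw
    ratios, symmetric in label order).
    """
    if accepted.empty:
        raise ValueError("no accepted PSMs")
    pep_sets = _peptide_map(accepted)
    universe = set(accepted["peptide_id"])

    chosen = _greedy_cover(pep_sets, universe)
    if len(pep_sets) <= exact_max_proteins and len(chosen) > 1:
        exact = _exact_cover(pep_sets, universe, cap=len(chosen))
        if exact:
            chosen = exact

    # report groups in coverage order (greedy order within the chosen cover)
    uncovered = set(universe)
    remaining = set(chosen)
    ordered: list[str] = []
    while remaining:
        best = max(sorted(remaining), key=lambda p: len(pep_sets[p] & uncovered))
        ordered.append(best)
        uncovered -= pep_sets[best]
        remaining.discard(best)

    unassigned = {p for p in pep_sets if p not in chosen}
    groups: list[ProteinGroup] = []
    for lead in ordered:
        same = sorted(p for p in unassigned if pep_sets[p] == pep_sets[lead])
        subsets = sorted(
            p
            for p in unassigned
            if pep_sets[p] != pep_sets[lead] and pep_sets[p] <= pep_sets[lead]
        )
        unassigned -= set(same) | set(subsets)
        groups.append(
            ProteinGroup(
                group_id=min([lead] + same),
                members=sorted([lead] + same + subsets),
                peptides=set(pep_sets[lead]),
            )
        )
    groups.sort(key=lambda g: g.group_id)

    # per-(group, block) mean peptide log2 ratios
    pep_to_groups: dict[str, list[str]] = {}
    for g in groups:
        for pep in g.peptides:
            pep_to_groups.setdefault(pep, []).append(g.group_id)
    rows = []
    inten_cols = [f"intensity_{lab}" for lab in LABELS]
    have_inten = all(c in accepted.columns for c in inten_cols)
    if have_inten:
        for _, row in accepted.iterrows():
            for gid in pep_to_groups.get(row["peptide_id"], []):
                entry = {"group_id": gid, "block": row.get("block", "")}
                for a, b in combinations(LABELS, 2):
                    ia, ib = row[f"intensity_{a}"], row[f"intensity_{b}"]
                    entry[f"log2_{b}_{a}"] = (
                        np.log2(ib / ia) if ia > 0 and ib > 0 else np.nan
                    )
                rows.append(entry)
    if rows:
        ratios = (
            pd.DataFrame(rows)
            .groupby(["group_id", "block"], sort=True)
            .mean()
            .reset_index()
        )
    else:
        ratios = pd.DataFrame(columns=["group_id", "block"])
    return ParsimonyResult(groups=groups, ratios=ratios)


def exhaustive_min_cover(pep_sets: dict[str, set[str]], universe: set[str]) -> int:
    """Exact minimal set-cover size by exhaustive subset search (small instances)."""
    prots = sorted(pep_sets)
    for k in range(1, len(prots) + 1):
        for combo in combinations(prots, k):
            if set().union(*(pep_sets[p] for p in combo)) >= universe:
                return k
    raise ValueError("universe not coverable")


# ---------------------------------------------------------------------------
# detection filter and normalization
# ---------------------------------------------------------------------------


def detection_filter(matrix: QuantMatrix, min_block_fraction: float = 0.25) -> QuantMatrix:
    """Keep proteins detected (any label) in >= ceil(fraction * n_blocks) blocks.

    The ceiling convention matches requiring 10 of 38 blocks at 25%
    (ceil(9.5) = 10).  A fraction of 0 is the identity on the protein set.
    """
    if matrix.state not in ("raw", "log"):
        raise QuantMatrixError("detection filter expects a raw or log matrix")
    n_blocks = len(matrix.blocks)
    need = int(np.ceil(min_block_fraction * n_blocks))
    counts = matrix.presence_by_block().sum(axis=1)
    keep = counts.index[counts >= need]
    out = matrix.copy()
    out.values = out.values.loc[keep]
    out.provenance.append(
        f"detection_filter(min_block_fraction={min_block_fraction}): "
        f"kept {len(keep)}/{len(matrix.proteins)} proteins (>= {need} of {n_blocks} blocks)"
    )
    return out


def log_transform(matrix: QuantMatrix) -> QuantMatrix:
    """Natural-log transform of raw intensities; nonpositive values are errors."""
    if matrix.state != "raw":
        raise QuantMatrixError("log_transform expects a raw matrix")
    bad = matrix.values.le(0.0)
    if bad.any().any():
        prot = bad.any(axis=1).idxmax()
        col = bad.loc[prot].idxmax()
        raise ValueError(f"nonpositive intensity at protein {prot!r}, cell {col}")
    out = matrix.copy()
    out.values = np.log(out.values)
    out.advance_state("log")
    out.provenance.append("log_transform: natural log")
    return out


def block_center(matrix: QuantMatrix, drop_partial: bool = False) -> QuantMatrix:
    """Subtract each protein's per-block mean over present values.

    Partial blocks (one or two labels present) are centered by the mean of
    the present values by default, or dropped when ``drop_partial``.
    """
    if matrix.state != "log":
        raise QuantMatrixError("block_center expects a log matrix")
    out = matrix.copy()
    vals = out.values
    if drop_partial:
        present = vals.notna().T.groupby(level=0).sum().T
        for block in out.blocks:
            partial = present[block].between(1, 2)
            vals.loc[partial, block] = np.nan
    means = vals.T.groupby(level=0).mean().T  # protein x block means over present
    broadcast = means.reindex(columns=vals.columns.get_level_values(0)).to_numpy()
    out.values = vals - broadcast
    out.advance_state("block_centered")
    out.provenance.append(
        f"block_center(drop_partial={drop_partial}): per-(protein, block) mean subtracted"
    )
    return out


def _scaled_mad(x: np.ndarray) -> float:
    med = np.median(x)
    return MAD_SCALE * float(np.median(np.abs(x - med)))


def label_standardize(matrix: QuantMatrix) -> QuantMatrix:
    """Center and scale within each label by median and (normal-consistent) MAD.

    The value set of each label across all proteins and blocks ends up with
    median 0 and scaled MAD 1.  A zero MAD for any label raises
    :class:`DegenerateScaleError`.
    """
    if matrix.state != "block_centered":
        raise QuantMatrixError("label_standardize expects a block-centered matrix")
    out = matrix.copy()
    vals = out.values
    for lab in LABELS:
        cols = vals.columns[vals.columns.get_level_values(1) == lab]
        if len(cols) == 0:
            continue
        x = vals[cols].to_numpy().ravel()
        x = x[~np.isnan(x)]
        if x.size == 0:
            continue
        med = float(np.median(x))
        mad = _scaled_mad(x)
        if mad <= 0:
            raise DegenerateScaleError(f"label {lab!r} has zero MAD")
        vals[cols] = (vals[cols] - med) / mad
    out.values = vals
    out.advance_state("standardized")
    out.provenance.append(
        f"label_standardize: per-label median/MAD (x{MAD_SCALE}) standardization"
    )
    return out


def normalize(matrix: QuantMatrix, drop_partial: bool = False) -> QuantMatrix:
    """Full normalization chain: log -> block centering -> label standardization."""
    return label_standardize(block_center(log_transform(matrix), drop_partial))


def colony_means(matrix: QuantMatrix, assignment) -> pd.DataFrame:
    """Per-protein mean expression per colony (protein x colony table).

    Averages a colony's present cells across its three (block, label) slots;
    intended for standardized matrices (heritability regressions).
    """
    col_colony = {
        (b, lab): assignment.colony_of(b, lab)
        for b in assignment.block_ids()
        for lab in LABELS
        if (b, lab) in matrix.values.columns
    }
    colonies = pd.Index([col_colony[c] for c in matrix.values.columns], name="colony")
    return matrix.values.T.groupby(colonies).mean().T


def ratios_to_matrix(ratios: pd.DataFrame, reference_label: str = "light") -> QuantMatrix:
    """Assemble a QuantMatrix of relative intensities from parsimony ratios.

    The reference label gets intensity 1 and the other labels their
    2**log2-ratio against it; useful for pushing PSM-level simulations
    through the matrix pipeline.
    """
    rows = {}
    for _, r in ratios.iterrows():
        for lab in LABELS:
            if lab == reference_label:
                v = 1.0
            else:
                key = f"log2_{lab}_{reference_label}"
                alt = f"log2_{reference_label}_{lab}"
                if key in r and pd.notna(r.get(key)):
                    v = float(2.0 ** r[key])
                elif alt in r and pd.notna(r.get(alt)):
                    v = float(2.0 ** (-r[alt]))
                else:
                    v = np.nan
            rows.setdefault(r["group_id"], {})[(r["block"], lab)] = v
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["block", "label"])
    df = df.sort_index(axis=1)
    df.index.name = "protein"
    return QuantMatrix(values=df, state="raw", provenance=["ratios_to_matrix"])
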