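"""Per-protein association of expression with colony-level predictors.

For each protein the standardized expression over its present (block,
label) cells is regressed on a colony-level predictor (a hygienic-behavior
field score, or population), adjusting for block and label.  The declared
model is a linear mixed-effects fit with a block random intercept and
fixed label (and optionally population) effects; because block centering
during normalization removes within-block means, the block variance
component typically collapses to the boundary, in which case the fit
falls back to fixed-effects least squares with an exact t-test.  The
default engine checks a moment estimate of the between-block variance and
only pays for the iterative mixed fit when that estimate is positive.

Multiple testing over proteins is controlled per predictor with
Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    LABELS,
    AssociationResult,
    BlockAssignment,
    ColonyRecord,
    QuantMatrix,
)


class InestimableEffectError(ValueError):
    """The predictor is constant over the contributing colonies."""


# ---------------------------------------------------------------------------
# design-matrix plumbing
# ---------------------------------------------------------------------------


@dataclass
class _DatasetContext:
    """Per-(block, label) covariates aligned with the matrix columns."""

    predictor: np.ndarray  # colony-level predictor per column
    label_codes: np.ndarray  # 0/1/2 per column
    block_codes: np.ndarray  # integer block index per column
    pop_codes: Optional[np.ndarray]  # integer population index, or None
    n_blocks: int
    min_block_fraction: float = 0.25
    categorical: bool = False  # predictor is population (ANOVA F-test)


def _build_context(
    matrix: QuantMatrix,
    assignment: BlockAssignment,
    colonies: Sequence[ColonyRecord],
    predictor: str,
    adjust_population: bool,
    min_block_fraction: float = 0.25,
) -> _DatasetContext:
    by_id = {c.colony_id: c for c in colonies}
    cols = list(matrix.values.columns)
    blocks = sorted({b for b, _ in cols})
    bidx = {b: i for i, b in enumerate(blocks)}
    lidx = {lab: i for i, lab in enumerate(LABELS)}
    pred = np.empty(len(cols))
    labc = np.empty(len(cols), dtype=int)
    blkc = np.empty(len(cols), dtype=int)
    pops = []
    for k, (b, lab) in enumerate(cols):
        cid = assignment.colony_of(b, lab)
        col = by_id[cid]
        if predictor == "population":
            pred[k] = np.nan  # categorical predictor handled separately
        else:
            pred[k] = getattr(col, predictor)
        labc[k] = lidx[lab]
        blkc[k] = bidx[b]
        pops.append(col.population)
    pop_levels = sorted(set(pops))
    categorical = predictor == "population"
    popc = (
        np.array([pop_levels.index(p) for p in pops])
        if (adjust_population and not categorical)
        else None
    )
    if categorical:
        # categorical predictor: codes, tested by an ANOVA F-test in _fit_one
        pred = np.array([pop_levels.index(p) for p in pops], dtype=float)
    return _DatasetContext(
        predictor=pred,
        label_codes=labc,
        block_codes=blkc,
        pop_codes=popc,
        n_blocks=len(blocks),
        min_block_fraction=min_block_fraction,
        categorical=categorical,
    )


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded indicator columns for levels 1..n-1."""
    out = np.zeros((len(codes), max(n_levels - 1, 0)))
    for lv in range(1, n_levels):
        out[codes == lv, lv - 1] = 1.0
    return out


def _between_block_variance(resid: np.ndarray, blocks: np.ndarray) -> float:
    """ANOVA moment estimate of a block variance component from residuals."""
    df = pd.DataFrame({"r": resid, "b": blocks})
    grp = df.groupby("b")["r"]
    sizes = grp.size().to_numpy(float)
    if (sizes <= 1).all() or len(sizes) < 2:
        return 0.0
    means = grp.mean().to_numpy()
    msw_num = ((df["r"] - df["b"].map(grp.mean())) ** 2).sum()
    msw = msw_num / max(len(resid) - len(sizes), 1)
    msb = float(np.sum(sizes * (means - resid.mean()) ** 2) / max(len(sizes) - 1, 1))
    nbar = (len(resid) - np.sum(sizes**2) / len(resid)) / max(len(sizes) - 1, 1)
    return max(0.0, (msb - msw) / max(nbar, 1.0))


def _absorb_blocks(
    yy: np.ndarray, X: np.ndarray, blocks: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Within-block demeaning of response and covariates (Frisch-Waugh).

    Equivalent to including one fixed intercept per present block; the
    caller must charge one residual degree of freedom per present block.
    """
    _, inv = np.unique(blocks, return_inverse=True)
    nb = int(inv.max()) + 1
    counts = np.bincount(inv, minlength=nb).astype(float)
    ym = np.bincount(inv, weights=yy, minlength=nb) / counts
    yt = yy - ym[inv]
    Xt = np.empty_like(X)
    for j in range(X.shape[1]):
        cm = np.bincount(inv, weights=X[:, j], minlength=nb) / counts
        Xt[:, j] = X[:, j] - cm[inv]
    return yt, Xt, nb


def _fixed_effects_fit(
    yy: np.ndarray,
    X: np.ndarray,
    blocks: np.ndarray,
    n: int,
) -> tuple[float, float, float, int, bool, str] | None:
    """Block-absorbing least squares with an exact t-test on the slope.

    Block effects enter as fixed intercepts (absorbed by demeaning); the
    residual degrees of freedom charge one per present block so the
    t-test stays exact even though normalization already removed block
    means.  Returns None when too few degrees of freedom remain.
    """
    yt, Xt, nb = _absorb_blocks(yy, X, blocks)
    keep = [0] + [j for j in range(1, Xt.shape[1]) if np.ptp(Xt[:, j]) > 1e-12]
    Xt = Xt[:, keep]
    k = Xt.shape[1]
    df = n - nb - k
    if df < 1 or np.ptp(Xt[:, 0]) <= 1e-12:
        return None
    ols = sm.OLS(yt, Xt).fit()
    eff = float(ols.params[0])
    rss = float((ols.resid**2).sum())
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(Xt.T @ Xt)
    se = math.sqrt(sigma2 * xtx_inv[0, 0])
    if not se > 0:
        return 0.0, float("nan"), 1.0, n, False, "zero residual variance"
    tstat = eff / se
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return eff, se, float(p), n, True, ""


def _fit_one(
    y: np.ndarray,
    ctx: _DatasetContext,
    mask: np.ndarray,
    engine: str = "auto",
) -> tuple[float, float, float, int, bool, str]:
    """Fit one protein; returns (effect, se, p, n_obs, converged, notes)."""
    yy = y[mask]
    x = ctx.predictor[mask]
    n = len(yy)
    if np.ptp(x) == 0:
        raise InestimableEffectError("predictor constant over contributing colonies")
    if np.ptp(yy) == 0:
        return 0.0, float("nan"), 1.0, n, False, "zero response variance"

    blocks = ctx.block_codes[mask]
    if ctx.categorical:
        return _fit_categorical(yy, x, ctx.label_codes[mask], blocks, n)

    Xparts = [x[:, None], _dummies(ctx.label_codes[mask], 3)]
    if ctx.pop_codes is not None:
        npop = int(ctx.pop_codes.max()) + 1
        Xparts.append(_dummies(ctx.pop_codes[mask], npop))
    X = np.hstack(Xparts)  # slope first; block and grand intercepts absorbed

    notes = ""
    use_mixed = False
    if engine == "mixedlm":
        use_mixed = True
    elif engine == "auto":
        # cheap moment screen: between-block variance of the residuals of a
        # no-block fit; only a materially positive component justifies the
        # iterative mixed fit (after block centering it sits at the boundary)
        X1 = np.hstack([np.ones((n, 1)), X])
        keep1 = [j for j in range(X1.shape[1]) if j < 2 or np.ptp(X1[:, j]) > 0]
        beta1, *_ = np.linalg.lstsq(X1[:, keep1], yy, rcond=None)
        resid1 = yy - X1[:, keep1] @ beta1
        sigma_b2 = _between_block_variance(resid1, blocks)
        sigma_e2 = float(np.var(resid1)) - sigma_b2
        use_mixed = sigma_b2 > 0.05 * max(sigma_e2, 1e-12)
        if not use_mixed:
            fe = _fixed_effects_fit(yy, X, blocks, n)
            if fe is None:
                return float("nan"), float("nan"), float("nan"), n, False, "too few observations"
            eff, se, p, n_, conv, _ = fe
            return eff, se, p, n_, conv, "block fixed effects (variance component at boundary)"
    elif engine == "ols":
        fe = _fixed_effects_fit(yy, X, blocks, n)
        if fe is None:
            return float("nan"), float("nan"), float("nan"), n, False, "too few observations"
        eff, se, p, n_, conv, _ = fe
        return eff, se, p, n_, conv, "block fixed effects (requested)"
    else:
        raise ValueError(f"unknown engine {engine!r}")

    if use_mixed:
        Xm = np.hstack([np.ones((n, 1)), X])
        keep = [0, 1] + [j for j in range(2, Xm.shape[1]) if np.ptp(Xm[:, j]) > 0]
        Xm = Xm[:, keep]
        if n <= Xm.shape[1]:
            return float("nan"), float("nan"), float("nan"), n, False, "too few observations"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(yy, Xm, groups=blocks)
                mr = md.fit(reml=True, method="lbfgs", maxiter=200)
            if np.isfinite(mr.bse[1]) and mr.bse[1] > 0:
                eff = float(mr.params[1])
                se = float(mr.bse[1])
                pz = 2.0 * stats.norm.sf(abs(eff / se))  # Wald, normal approx
                return eff, se, float(pz), n, bool(mr.converged), "mixed fit (block random intercept)"
            notes = "mixed fit degenerate; fixed-effects fallback"
        except Exception as exc:  # singular/boundary fits fall back
            notes = f"mixed fit failed ({type(exc).__name__}); fixed-effects fallback"
        fe = _fixed_effects_fit(yy, X, blocks, n)
        if fe is None:
            return float("nan"), float("nan"), float("nan"), n, False, "too few observations"
        eff, se, p, n_, conv, _ = fe
        return eff, se, p, n_, conv, notes

    raise AssertionError("unreachable")


def _fit_categorical(
    yy: np.ndarray,
    codes: np.ndarray,
    label_codes: np.ndarray,
    blocks: np.ndarray,
    n: int,
) -> tuple[float, float, float, int, bool, str]:
    """Population effect as an ANOVA F-test, block and label absorbed."""
    levels = np.unique(codes)
    if len(levels) < 2:
        raise InestimableEffectError("single population among contributing colonies")
    remap = {lv: i for i, lv in enumerate(levels)}
    cc = np.array([remap[v] for v in codes])
    lab = _dummies(label_codes, 3)
    pop = _dummies(cc, len(levels))
    X1 = np.hstack([lab, pop])
    yt, X1t, nb = _absorb_blocks(yy, X1, blocks)
    nlab = lab.shape[1]
    keep_lab = [j for j in range(nlab) if np.ptp(X1t[:, j]) > 1e-12]
    keep_pop = [j for j in range(nlab, X1t.shape[1]) if np.ptp(X1t[:, j]) > 1e-12]
    if not keep_pop:
        raise InestimableEffectError("population confounded with blocks")
    X0t = X1t[:, keep_lab] if keep_lab else np.zeros((n, 0))
    X1k = X1t[:, keep_lab + keep_pop]
    df1 = n - nb - X1k.shape[1]
    if df1 < 1:
        return float("nan"), float("nan"), float("nan"), n, False, "too few observations"

    def rss(M: np.ndarray) -> float:
        if M.shape[1] == 0:
            return float((yt**2).sum())
        b, *_ = np.linalg.lstsq(M, yt, rcond=None)
        return float(((yt - M @ b) ** 2).sum())

    rss0, rss1 = rss(X0t), rss(X1k)
    q = len(keep_pop)
    fstat = ((rss0 - rss1) / q) / (rss1 / df1)
    pval = float(stats.f.sf(max(fstat, 0.0), q, df1))
    # effect reported as the between-population SD of raw population means
    eff = float(np.std([yy[cc == i].mean() for i in range(len(levels))]))
    return eff, float("nan"), pval, n, True, "population ANOVA F-test (block, label absorbed)"


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def fit_protein_model(
    matrix: QuantMatrix,
    protein_id: str,
    assignment: BlockAssignment,
    colonies: Sequence[ColonyRecord],
    predictor: str = "r24",
    adjust_population: bool = False,
    engine: str = "auto",
    min_block_fraction: float = 0.25,
) -> AssociationResult:
    """Association of one protein's standardized expression with a predictor.

    Fits ``expression ~ intercept + predictor + label [+ population] +
    block random intercept`` and reports the Wald slope test; when the block
    variance component sits at the boundary (the usual case after block
    centering) or the mixed fit fails, an exact-t fixed-effects fit is used
    and the fallback is noted.
    """
    ctx = _build_context(
        matrix, assignment, colonies, predictor, adjust_population, min_block_fraction
    )
    y = matrix.values.loc[protein_id].to_numpy(float)
    mask = ~np.isnan(y)
    present_blocks = len(np.unique(ctx.block_codes[mask]))
    need = int(np.ceil(min_block_fraction * ctx.n_blocks))
    if present_blocks < need:
        return AssociationResult(
            protein_id=protein_id,
            predictor=predictor,
            effect=float("nan"),
            se=float("nan"),
            p_value=float("nan"),
            n_obs=int(mask.sum()),
            converged=False,
            fit_notes=f"skipped: present in {present_blocks} < {need} blocks",
        )
    eff, se, p, n, conv, notes = _fit_one(y, ctx, mask, engine)
    res = AssociationResult(
        protein_id=protein_id,
        predictor=predictor,
        effect=eff,
        se=se,
        p_value=p,
        n_obs=n,
        converged=conv,
        fit_notes=notes,
    )
    res.validate()
    return res


def compute_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input.

    NaN p-values (skipped proteins) propagate as NaN and do not count
    toward the number of tests.
    """
    p = np.asarray(list(p_values), dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return q
    _, qv, _, _ = multipletests(p[ok], method="fdr_bh")
    q[ok] = qv
    return q


@dataclass
class DatasetRunLog:
    n_proteins: int = 0
    n_fit: int = 0
    n_fallback: int = 0
    n_skipped: int = 0
    messages: list[str] = field(default_factory=list)


def run_dataset(
    matrix: QuantMatrix,
    assignment: BlockAssignment,
    colonies: Sequence[ColonyRecord],
    predictors: Sequence[str] = ("r24",),
    adjust_population: bool = False,
    engine: str = "auto",
    min_block_fraction: float = 0.25,
) -> tuple[dict[str, pd.DataFrame], DatasetRunLog]:
    """Fit every retained protein for every predictor; attach q-values.

    Returns ``{predictor: results frame}`` (indexed by protein, columns
    effect/se/p_value/q_value/n_obs/converged/fit_notes, protein order
    preserved) plus a run log.  Per-protein failures are recorded, never
    propagated.
    """
    log = DatasetRunLog(n_proteins=len(matrix.proteins))
    out: dict[str, pd.DataFrame] = {}
    if len(matrix.proteins) == 0:
        warnings.warn("no proteins retained in matrix", RuntimeWarning, stacklevel=2)
        for pred in predictors:
            out[pred] = pd.DataFrame(
                columns=["effect", "se", "p_value", "q_value", "n_obs", "converged", "fit_notes"]
            )
        return out, log
    vals = matrix.values.to_numpy(float)
    need = int(np.ceil(min_block_fraction * len(matrix.blocks)))
    for pred in predictors:
        ctx = _build_context(
            matrix, assignment, colonies, pred, adjust_population, min_block_fraction
        )
        rows = []
        for i, prot in enumerate(matrix.proteins):
            y = vals[i]
            mask = ~np.isnan(y)
            present_blocks = len(np.unique(ctx.block_codes[mask]))
            if present_blocks < need:
                log.n_skipped += 1
                rows.append((np.nan, np.nan, np.nan, int(mask.sum()), False,
                             f"skipped: present in {present_blocks} < {need} blocks"))
                continue
            try:
                eff, se, p, n, conv, notes = _fit_one(y, ctx, mask, engine)
            except InestimableEffectError as exc:
                log.n_skipped += 1
                log.messages.append(f"{prot}/{pred}: {exc}")
                rows.append((np.nan, np.nan, np.nan, int(mask.sum()), False, str(exc)))
                continue
            log.n_fit += 1
            if "fallback" in notes or "fixed effects" in notes:
                log.n_fallback += 1
            rows.append((eff, se, p, n, conv, notes))
        df = pd.DataFrame(
            rows,
            index=pd.Index(matrix.proteins, name="protein"),
            columns=["effect", "se", "p_value", "n_obs", "converged", "fit_notes"],
        )
        df.insert(3, "q_value", compute_qvalues(df["p_value"]))
        out[pred] = df
    return out, log
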