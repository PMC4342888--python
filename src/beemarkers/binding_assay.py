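"""Binding-constant estimation from fluorescence titration curves.

The probe (1-NPN) dissociation constant comes from a saturation titration:
fluorescence is converted to bound-probe concentration under the 1:1,
100%-active stoichiometry assumption, free probe is total minus bound
(protein at ~2 uM and K_d of 1-5 uM make depletion non-negligible), and a
Scatchard regression (bound/free vs bound, slope -1/K_d) is iterated with
the plateau estimate to a fixed point.  A direct nonlinear least-squares
fit of the exact quadratic isotherm is provided as a cross-check.

Competitor affinities come from the IC50 (competitor concentration
halving the initial probe fluorescence, log-linearly interpolated between
bracketing points) converted through

    K_D = IC50 / (1 + [1-NPN] / K_1-NPN)

with [1-NPN] the free probe concentration (estimated at half
displacement by default; total concentration is available as an option).
"""

from __future__ import annotations

import math
import warnings
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .synthetic_data import bound_1to1
from .types import BindingResult, TitrationCurve


class NoBindingError(ValueError):
    """The titration shows no saturable binding (flat or rising Scatchard)."""


class DataInconsistencyError(ValueError):
    """Implied bound exceeds total ligand (negative free concentration)."""


# ---------------------------------------------------------------------------
# saturation fit (probe K_d)
# ---------------------------------------------------------------------------


def fit_saturation(
    curve: TitrationCurve,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> BindingResult:
    """Probe dissociation constant by iterated Scatchard linearization.

    Given a plateau fluorescence guess F_sat, bound = (F / F_sat) * [P]_tot
    (1:1, 100% active), free = total - bound, and the Scatchard line
    bound/free vs bound has slope -1/K_d and intercept B_max/K_d.  The
    implied B_max recalibrates F_sat until the relative change drops below
    ``tol`` (at most ``max_iter`` iterations).
    """
    if curve.mode != "saturation":
        raise ValueError("fit_saturation expects a saturation-mode curve")
    total = curve.concentrations
    fl = curve.fluorescence
    if len(total) < 4:
        raise ValueError("need at least 4 titration points")
    if np.any(np.diff(fl) < 0):
        warnings.warn(
            "fluorescence is not monotone increasing; check for artifacts",
            RuntimeWarning,
            stacklevel=2,
        )
    if float(np.ptp(fl)) <= 0 or np.allclose(fl, fl[0], rtol=1e-12):
        raise NoBindingError("fluorescence constant across titration points")
    ptot = curve.protein_conc

    f_sat = 2.0 * float(fl.max())  # start above the data; refined by iteration
    kd = float("nan")
    r2 = float("nan")
    for _ in range(max_iter):
        bound = fl / f_sat * ptot
        free = total - bound
        if np.any(free <= 0):
            raise DataInconsistencyError(
                "implied bound exceeds total ligand at some points"
            )
        slope, intercept, r, _, _ = stats.linregress(bound, bound / free)
        if slope >= 0:
            raise NoBindingError("Scatchard slope >= 0: no saturable binding")
        kd = -1.0 / slope
        bmax = -intercept / slope
        r2 = r * r
        f_sat_new = f_sat * (bmax / ptot)
        if f_sat_new <= 0:
            raise NoBindingError("implied saturation fluorescence <= 0")
        if abs(f_sat_new - f_sat) / f_sat < tol:
            f_sat = f_sat_new
            break
        f_sat = f_sat_new
    return BindingResult(
        k_probe=float(kd),
        fit_r2=float(r2),
        method_notes=f"Scatchard fixed point (F_sat={f_sat:.4g})",
    )


def fit_saturation_nls(curve: TitrationCurve) -> BindingResult:
    """Direct nonlinear least-squares fit of the exact 1:1 isotherm.

    Fits F = scale * bound(P_tot, L_tot, K_d); serves as the cross-check
    for the Scatchard route (the two agree closely on clean data).
    """
    if curve.mode != "saturation":
        raise ValueError("fit_saturation_nls expects a saturation-mode curve")
    total = curve.concentrations
    fl = curve.fluorescence
    ptot = curve.protein_conc

    def model(lt, kd, scale):
        return scale * np.array([bound_1to1(ptot, l, kd) for l in lt])

    kd0 = max(float(np.median(total)), 1e-3)
    scale0 = float(fl.max()) / max(bound_1to1(ptot, float(total.max()), kd0), 1e-12)
    popt, _ = optimize.curve_fit(
        model, total, fl, p0=[kd0, scale0], bounds=([1e-9, 1e-12], [1e6, np.inf]),
        maxfev=10000,
    )
    resid = fl - model(total, *popt)
    ss_tot = float(((fl - fl.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return BindingResult(
        k_probe=float(popt[0]), fit_r2=r2, method_notes="nonlinear least squares"
    )


# ---------------------------------------------------------------------------
# competition: IC50 and K_D
# ---------------------------------------------------------------------------


def find_ic50(curve: TitrationCurve) -> BindingResult:
    """Competitor concentration halving the initial probe fluorescence.

    The first point (competitor 0 recommended) defines F0; the crossing of
    F0/2 is log-linearly interpolated between the bracketing measured
    points (linearly when the lower bracket is concentration 0).  When the
    fluorescence never falls below F0/2 within the tested range the result
    is censored and the maximum tested concentration is reported as a lower
    bound.
    """
    if curve.mode != "competition":
        raise ValueError("find_ic50 expects a competition-mode curve")
    conc = curve.concentrations
    fl = curve.fluorescence
    f0 = float(fl[0])
    if f0 <= 0:
        raise ValueError("initial fluorescence must be positive")
    target = f0 / 2.0
    below = fl <= target
    crossings = np.flatnonzero(below[1:] & ~below[:-1])
    if not below.any():
        return BindingResult(
            ic50=float(conc[-1]),
            censored=True,
            method_notes="fluorescence never fell below F0/2; lower bound reported",
        )
    i = int(crossings[0]) if crossings.size else 0
    if crossings.size > 1 or (below.any() and not below[-1]):
        warnings.warn(
            "multiple F0/2 crossings; first crossing used",
            RuntimeWarning,
            stacklevel=2,
        )
    lo, hi = i, i + 1
    c_lo, c_hi = float(conc[lo]), float(conc[hi])
    f_lo, f_hi = float(fl[lo]), float(fl[hi])
    if f_hi == f_lo:
        ic50 = c_hi
    elif c_lo <= 0:
        ic50 = c_lo + (c_hi - c_lo) * (f_lo - target) / (f_lo - f_hi)
    else:
        t = (f_lo - target) / (f_lo - f_hi)
        ic50 = math.exp(math.log(c_lo) + t * (math.log(c_hi) - math.log(c_lo)))
    return BindingResult(ic50=float(ic50), censored=False, method_notes="log-linear interpolation")


def kd_from_ic50(ic50: float, probe_free_conc: float, k_probe: float) -> float:
    """Competitor K_D from its IC50: ``IC50 / (1 + [probe]_free / K_probe)``.

    The conventional (Cheng-Prusoff-style) conversion; it treats the IC50
    as the free competitor concentration, so it overestimates K_D when the
    protein concentration is comparable to the competitor K_D and a large
    fraction of the competitor is bound.
    """
    if ic50 <= 0 or probe_free_conc < 0 or k_probe <= 0:
        raise ValueError("ic50 and k_probe must be > 0, probe concentration >= 0")
    return ic50 / (1.0 + probe_free_conc / k_probe)


def kd_from_ic50_mass_balance(
    ic50: float, protein_tot: float, probe_tot: float, k_probe: float
) -> float:
    """Exact K_D from the IC50 via species mass balance at half displacement.

    At the IC50 the bound probe is half its initial value L_b0/2 (initial
    value from the exact 1:1 probe equilibrium), so every species follows
    from known quantities::

        L_b = L_b0 / 2          L_f = L_tot - L_b
        P_f = K_probe * L_b / L_f
        C_b = P_tot - P_f - L_b  (protein mass balance)
        C_f = IC50 - C_b         (competitor mass balance)
        K_D = C_f * P_f / C_b

    Exact for 1:1 competitive binding, including probe and competitor
    depletion.  Degenerate mass balances (C_b <= 0 or C_f <= 0, possible
    under heavy noise) fall back to the conventional free-probe formula
    with a warning.
    """
    if min(ic50, protein_tot, probe_tot, k_probe) <= 0:
        raise ValueError("all concentrations and constants must be > 0")
    l_b = 0.5 * bound_1to1(protein_tot, probe_tot, k_probe)
    l_f = probe_tot - l_b
    p_f = k_probe * l_b / l_f
    c_b = protein_tot - p_f - l_b
    c_f = ic50 - c_b
    if c_b <= 0 or c_f <= 0:
        warnings.warn(
            "degenerate mass balance at IC50; falling back to the "
            "conventional free-probe conversion",
            RuntimeWarning,
            stacklevel=2,
        )
        return kd_from_ic50(ic50, l_f, k_probe)
    return c_f * p_f / c_b


def fit_competition(
    curve: TitrationCurve,
    k_probe: float,
    method: str = "mass_balance",
    probe_mode: str = "free",
) -> BindingResult:
    """Full competitor pipeline: IC50 then K_D conversion.

    ``method="mass_balance"`` (default) uses the exact depletion-corrected
    conversion (:func:`kd_from_ic50_mass_balance`); ``method="formula"``
    uses the conventional expression with ``probe_mode="free"`` (free probe
    at half displacement) or ``probe_mode="total"``.
    """
    res = find_ic50(curve)
    if math.isnan(curve.probe_conc):
        raise ValueError("competition curve lacks probe_conc")
    if method == "mass_balance":
        kd = kd_from_ic50_mass_balance(
            res.ic50, curve.protein_conc, curve.probe_conc, k_probe
        )
        note = "mass-balance conversion"
    elif method == "formula":
        if probe_mode == "total":
            probe = curve.probe_conc
        elif probe_mode == "free":
            bound0 = bound_1to1(curve.protein_conc, curve.probe_conc, k_probe)
            probe = curve.probe_conc - 0.5 * bound0
        else:
            raise ValueError(f"unknown probe_mode {probe_mode!r}")
        kd = kd_from_ic50(res.ic50, probe, k_probe)
        note = f"conventional conversion, probe_mode={probe_mode}"
    else:
        raise ValueError(f"unknown method {method!r}")
    return BindingResult(
        k_probe=k_probe,
        ic50=res.ic50,
        k_d=float(kd),
        censored=res.censored,
        method_notes=res.method_notes + "; " + note,
    )
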