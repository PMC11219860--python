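"""Four-parameter logistic titration fitting and the allosteric EC50-shift model.

A positive allosteric modulator (PAM) bound at its own site changes the
apparent affinity of the orthosteric ligand without changing maximal
efficacy.  For a sensor with baseline midpoint ``EC50``, modulator affinity
constant ``Kb`` and cooperativity factor ``alpha``, the apparent midpoint at
modulator concentration ``B`` follows the ternary-complex shift

    EC50*(B) = EC50 * (1 + B/Kb) / (1 + alpha * B/Kb)

so that EC50*(0) = EC50 and EC50*(inf) = EC50/alpha.  ``alpha > 1`` means
potentiation (leftward shift).  A family of titrations at several modulator
concentrations is fitted globally: top, bottom, Hill slope, EC50, Kb and
alpha are shared, and each curve's midpoint is constrained to EC50*(B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    FitConvergenceError,
    InsufficientFamilyError,
    NoDynamicRangeError,
    NonPositiveBaselineError,
)

__all__ = [
    "TitrationCurve",
    "TitrationFamily",
    "FourPLParams",
    "AllostericParams",
    "compute_dff_trace",
    "four_pl",
    "fit_four_pl",
    "predict_shifted_ec50",
    "fit_allosteric_shift",
    "max_fold_shift",
    "ec50_fold_change",
]


@dataclass(frozen=True)
class TitrationCurve:
    """One concentration-response titration at a fixed modulator concentration.

    Parameters
    ----------
    concentrations : array-like of float
        Orthosteric ligand concentrations in molar, strictly increasing.
        A leading zero is allowed (evaluated directly, not via a log placeholder).
    responses : array-like of float
        Normalized sensor responses (ΔF/F0, percent).
    modulator_conc : float
        Allosteric modulator concentration in molar (>= 0).
    """

    concentrations: np.ndarray
    responses: np.ndarray
    modulator_conc: float = 0.0

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.ndim != 1 or r.shape != c.shape:
            raise ValueError("concentrations and responses must be equal-length 1-D")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.diff(c) > 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")
        if self.modulator_conc < 0:
            raise ValueError("modulator_conc must be >= 0")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)


@dataclass(frozen=True)
class TitrationFamily:
    """A set of titration curves indexed by modulator concentration."""

    curves: tuple[TitrationCurve, ...]

    def __post_init__(self):
        object.__setattr__(self, "curves", tuple(self.curves))

    @property
    def modulator_concs(self) -> np.ndarray:
        return np.array([c.modulator_conc for c in self.curves])


@dataclass(frozen=True)
class FourPLParams:
    """Four-parameter logistic fit (bottom, top in percent; ec50 molar; Hill)."""

    bottom: float
    top: float
    ec50: float
    hill: float
    residual_norm: float = 0.0

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")


@dataclass(frozen=True)
class AllostericParams:
    """Globally fitted ternary-complex parameters.

    ``ec50`` is the baseline orthosteric apparent affinity (molar), ``kb``
    the modulator affinity constant (molar), and ``alpha`` the cooperativity
    factor (alpha > 1 = positive modulation).
    """

    ec50: float
    kb: float
    alpha: float
    top: float = 100.0
    bottom: float = 0.0
    hill: float = 1.0
    residual_norm: float = 0.0
    stderr: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ec50 <= 0 or self.kb <= 0 or self.alpha <= 0:
            raise ValueError("ec50, kb and alpha must all be > 0")


def compute_dff_trace(raw_trace, addition_index: int, baseline_n: int = 10) -> np.ndarray:
    """ΔF/F0 (percent) of a fluorescence trace relative to a pre-ligand baseline.

    F0 is the mean of the ``baseline_n`` samples immediately before the
    ligand-addition index; the whole trace is returned as
    ``(F(t) - F0)/F0 * 100``.
    """
    f = np.asarray(raw_trace, dtype=float)
    if baseline_n < 1 or baseline_n > addition_index or addition_index > f.size:
        raise ValueError("need 1 <= baseline_n <= addition_index <= len(trace)")
    f0 = f[addition_index - baseline_n : addition_index].mean()
    if f0 <= 0:
        raise NonPositiveBaselineError(f"non-positive baseline (F0 = {f0:g})")
    return (f - f0) / f0 * 100.0


def four_pl(conc, bottom, top, ec50, hill):
    """Four-parameter logistic response at concentration(s) ``conc`` (molar).

    Evaluated in log10-concentration space; zero concentrations map to the
    lower asymptote directly.
    """
    c = np.asarray(conc, dtype=float)
    out = np.full(c.shape, float(bottom))
    pos = c > 0
    with np.errstate(over="ignore"):
        out[pos] = bottom + (top - bottom) / (
            1.0 + 10.0 ** ((math.log10(ec50) - np.log10(c[pos])) * hill)
        )
    return out


def _curve_to_log(curve: TitrationCurve):
    c = curve.concentrations
    pos = c > 0
    return c, pos


def fit_four_pl(curve: TitrationCurve, *, max_nfev: int = 2000) -> FourPLParams:
    """Least-squares 4PL fit of a single titration (log(agonist) vs. response).

    Raises
    ------
    NoDynamicRangeError
        If the responses are (numerically) flat.
    FitConvergenceError
        If the solver does not converge; carries the last iterate.
    """
    if curve.concentrations.size < 5:
        raise ValueError("need >= 5 points for a 4PL fit")
    r = curve.responses
    span = r.max() - r.min()
    if span <= 1e-12 * max(1.0, abs(r).max()):
        raise NoDynamicRangeError("responses are flat; no dynamic range to fit")

    c = curve.concentrations
    pos = c > 0
    logc = np.log10(c[pos])
    # init: asymptotes from the data range, midpoint from the half-rise crossing
    b0, t0 = float(r.min()), float(r.max())
    half = (b0 + t0) / 2.0
    idx = int(np.argmin(np.abs(r[pos] - half)))
    x0 = np.array([b0, t0, logc[idx], 1.0])

    def resid(p):
        bottom, top, logec50, hill = p
        return four_pl(c, bottom, top, 10.0**logec50, hill) - r

    lo = [-np.inf, -np.inf, logc.min() - 4, 1e-3]
    hi = [np.inf, np.inf, logc.max() + 4, 20.0]
    x0 = np.clip(x0, lo, hi)
    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14,
                        gtol=1e-14, max_nfev=max_nfev)
    if not sol.success:
        raise FitConvergenceError("4PL fit did not converge", last_params=sol.x)
    bottom, top, logec50, hill = sol.x
    if top <= bottom:  # mirror a fitted descending curve into the canonical form
        bottom, top = top, bottom
        hill = abs(hill)
    return FourPLParams(bottom=float(bottom), top=float(top), ec50=float(10.0**logec50),
                        hill=float(hill), residual_norm=float(np.linalg.norm(sol.fun)))


def predict_shifted_ec50(params: AllostericParams, modulator_conc: float) -> float:
    """Apparent EC50* at modulator concentration ``B`` (molar).

    ``B = 0`` returns the baseline EC50; ``B = inf`` returns the saturating
    limit EC50/alpha.
    """
    if modulator_conc < 0:
        raise ValueError("modulator_conc must be >= 0")
    if math.isinf(modulator_conc):
        return params.ec50 / params.alpha
    ratio = modulator_conc / params.kb
    return params.ec50 * (1.0 + ratio) / (1.0 + params.alpha * ratio)


def max_fold_shift(params: AllostericParams) -> float:
    """Saturating fold-decrease in EC50 (= the cooperativity factor alpha)."""
    return params.ec50 / predict_shifted_ec50(params, math.inf)


def ec50_fold_change(ec50_reference: float, ec50_shifted: float) -> float:
    """Fold change in apparent affinity between two conditions.

    Works on any pair of half-maximal measures on the same scale (molar
    EC50s, iontophoresis ejection-current EC50s, modulator Kb values).
    """
    if ec50_reference <= 0 or ec50_shifted <= 0:
        raise ValueError("EC50 values must be > 0")
    return ec50_reference / ec50_shifted


def _family_resid(theta, family: TitrationFamily):
    bottom, top, logec50, hill, logkb, logalpha = theta
    ec50, kb, alpha = 10.0**logec50, 10.0**logkb, 10.0**logalpha
    out = []
    for curve in family.curves:
        ratio = curve.modulator_conc / kb
        ec50_star = ec50 * (1.0 + ratio) / (1.0 + alpha * ratio)
        out.append(four_pl(curve.concentrations, bottom, top, ec50_star, hill)
                   - curve.responses)
    return np.concatenate(out)


def fit_allosteric_shift(family: TitrationFamily, *, seed: int = 0,
                         n_starts: int = 3, max_nfev: int = 5000) -> AllostericParams:
    """Global ternary-complex fit of a titration family.

    Shares bottom/top/Hill/EC50/Kb/alpha across curves with each curve's
    midpoint constrained to ``predict_shifted_ec50``.  Initialization comes
    from per-curve 4PL fits (EC50 from the B=0 curve, alpha from the maximal
    observed shift, Kb from the modulator level giving half-maximal shift);
    on solver failure up to ``n_starts`` seeded, jittered restarts are tried.
    """
    mods = family.modulator_concs
    if len(set(mods.tolist())) < 3 or 0.0 not in mods:
        raise InsufficientFamilyError(
            "need >= 3 distinct modulator concentrations including 0")

    per_curve = {}
    for curve in family.curves:
        try:
            per_curve[curve.modulator_conc] = fit_four_pl(curve)
        except (NoDynamicRangeError, FitConvergenceError):
            continue
    if 0.0 not in per_curve:
        raise FitConvergenceError("baseline (B=0) curve could not be fitted")

    base = per_curve[0.0]
    ec50_0 = base.ec50
    folds = {b: ec50_0 / p.ec50 for b, p in per_curve.items() if b > 0}
    alpha0 = max(1.05, max(folds.values(), default=1.05))
    # B giving half-maximal shift: fold closest to (1 + alpha)/2
    if folds:
        half_target = (1.0 + alpha0) / 2.0
        kb0 = min(folds, key=lambda b: abs(folds[b] - half_target))
    else:
        kb0 = ec50_0
    x0 = np.array([base.bottom, base.top, math.log10(ec50_0), base.hill,
                   math.log10(kb0), math.log10(alpha0)])

    lo = [-np.inf, -np.inf, -15.0, 1e-3, -15.0, -3.0]
    hi = [np.inf, np.inf, 3.0, 20.0, 3.0, 3.0]
    x0 = np.clip(x0, lo, hi)

    rng = np.random.default_rng(seed)
    last = None
    start = x0
    for attempt in range(max(1, n_starts)):
        sol = least_squares(_family_resid, start, args=(family,), bounds=(lo, hi),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_nfev)
        last = sol
        if sol.success:
            break
        start = np.clip(x0 + rng.normal(0, 0.1, size=x0.size), lo, hi)
    if last is None or not last.success:
        raise FitConvergenceError("allosteric shift fit did not converge",
                                  last_params=None if last is None else last.x)

    bottom, top, logec50, hill, logkb, logalpha = last.x
    return AllostericParams(
        ec50=float(10.0**logec50), kb=float(10.0**logkb), alpha=float(10.0**logalpha),
        top=float(top), bottom=float(bottom), hill=float(hill),
        residual_norm=float(np.linalg.norm(last.fun)),
    )
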