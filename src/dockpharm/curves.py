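"""In vitro pharmacology mathematics.

Four-parameter logistic (4PL) concentration-response fitting on log10
concentration, normalization of raw signals to a reference agonist's fitted
span, the Cheng-Prusoff IC50 -> Ki conversion, the percent-activity equation
used by enzyme-fragment-complementation recruitment assays, and affinity
fold-change reporting.

The 4PL model, with x = log10([ligand] / M):

    y(x) = bottom + (top - bottom) / (1 + 10^((log10 EC50 - x) * hill))

An agonist curve that rises with concentration has hill > 0.  Fits are
unweighted least squares on replicate-level points; parameter uncertainty is
asymptotic (Wald) from the Jacobian, with 95% confidence intervals from the
t distribution on the residual degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponseCurve",
    "CurveFit",
    "BindingResult",
    "four_pl",
    "fit_4pl",
    "normalize_to_reference",
    "cheng_prusoff",
    "percent_activity",
    "fold_change",
]

_PARAM_NAMES = ("bottom", "top", "pec50", "hill")


class InsufficientDataError(ValueError):
    """Raised when a curve has too few distinct concentrations to fit."""


@dataclass(frozen=True)
class DoseResponseCurve:
    """Replicate-level concentration-response data for one compound.

    ``concentrations`` are molar and must be positive; ``responses`` is a
    flat vector aligned with ``concentrations`` (replicates appear as
    repeated concentration entries).
    """

    compound_id: str
    concentrations: np.ndarray
    responses: np.ndarray
    pathway: str | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise ValueError("concentrations and responses must be equal-length 1-D")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive (molar)")

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.concentrations))


@dataclass(frozen=True)
class CurveFit:
    compound_id: str
    bottom: float
    top: float
    pec50: float
    hill: float
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    converged: bool
    residual_sd: float
    message: str = ""
    pathway: str | None = None

    @property
    def ec50(self) -> float:
        return 10.0 ** (-self.pec50)

    @property
    def emax(self) -> float:
        """Fitted maximal response (the top plateau)."""
        return self.top


@dataclass(frozen=True)
class BindingResult:
    ic50: float
    ki: float
    radioligand_conc: float
    radioligand_kd: float


def four_pl(x: np.ndarray, bottom: float, top: float, pec50: float, hill: float) -> np.ndarray:
    """4PL response at x = log10(concentration / M)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((-pec50 - x) * hill))


def _failed_fit(curve: DoseResponseCurve, message: str) -> CurveFit:
    nan = float("nan")
    return CurveFit(
        compound_id=curve.compound_id,
        bottom=nan,
        top=nan,
        pec50=nan,
        hill=nan,
        se={k: nan for k in _PARAM_NAMES},
        ci95={k: (nan, nan) for k in _PARAM_NAMES},
        converged=False,
        residual_sd=nan,
        message=message,
        pathway=curve.pathway,
    )


def fit_4pl(
    curve: DoseResponseCurve,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
) -> CurveFit:
    """Least-squares 4PL fit of a concentration-response curve.

    Initialization: bottom/top from the response extremes, pEC50 from the
    concentration nearest the half-maximal response, hill = 1.  A curve
    whose responses are essentially flat (span below 1e-6 of the absolute
    response scale, or a singular fit) is reported with
    ``converged=False`` and a diagnostic message rather than an exception.
    """
    if curve.n_distinct < 4:
        raise InsufficientDataError(
            f"{curve.compound_id}: need >= 4 distinct concentrations, "
            f"got {curve.n_distinct}"
        )
    x = np.log10(curve.concentrations)
    y = curve.responses
    span = float(y.max() - y.min())
    scale = max(abs(float(y.max())), abs(float(y.min())), 1.0)
    if span <= 1e-6 * scale:
        return _failed_fit(curve, "flat curve: no response span to fit")

    # half-maximal crossing for the pEC50 start
    half = (y.max() + y.min()) / 2.0
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    crossing = xs[np.argmin(np.abs(ys - half))]
    p0 = (float(y.min()), float(y.max()), -float(crossing), 1.0)

    kwargs: dict = {"p0": p0, "maxfev": 20000}
    if bounds is not None:
        kwargs["bounds"] = bounds
        kwargs["p0"] = np.clip(p0, bounds[0], bounds[1])
    try:
        popt, pcov = optimize.curve_fit(four_pl, x, y, **kwargs)
    except (RuntimeError, ValueError) as exc:
        return _failed_fit(curve, f"optimizer failure: {exc}")

    resid = y - four_pl(x, *popt)
    dof = max(len(y) - 4, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))
    with np.errstate(invalid="ignore"):
        se_vec = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(se_vec)):
        # singular Jacobian, e.g. hill ~ 0: parameters unidentifiable
        fit = _failed_fit(curve, "singular covariance: parameters unidentifiable")
        return replace(
            fit,
            bottom=float(popt[0]),
            top=float(popt[1]),
            pec50=float(popt[2]),
            hill=float(popt[3]),
            residual_sd=residual_sd,
        )
    tcrit = stats.t.ppf(0.975, dof)
    se = {name: float(s) for name, s in zip(_PARAM_NAMES, se_vec)}
    ci95 = {
        name: (float(p - tcrit * s), float(p + tcrit * s))
        for name, p, s in zip(_PARAM_NAMES, popt, se_vec)
    }
    return CurveFit(
        compound_id=curve.compound_id,
        bottom=float(popt[0]),
        top=float(popt[1]),
        pec50=float(popt[2]),
        hill=float(popt[3]),
        se=se,
        ci95=ci95,
        converged=True,
        residual_sd=residual_sd,
        pathway=curve.pathway,
    )


def normalize_to_reference(
    curves: Sequence[DoseResponseCurve],
    reference_fit: CurveFit,
    span_tol: float = 1e-9,
) -> tuple[list[DoseResponseCurve], bool]:
    """Rescale raw responses so the reference fit spans 0-100%.

    Returns ``(curves, normalized)``.  If the reference did not converge or
    is flat (top == bottom within ``span_tol``), the data pass through
    unchanged with ``normalized=False`` — mirroring the convention of
    leaving data unnormalized when the reference agonist shows no response.
    """
    span = reference_fit.top - reference_fit.bottom
    if not reference_fit.converged or not math.isfinite(span) or abs(span) <= span_tol:
        return list(curves), False
    out = [
        replace(c, responses=100.0 * (c.responses - reference_fit.bottom) / span)
        for c in curves
    ]
    return out, True


def cheng_prusoff(ic50: float, radioligand_conc: float, radioligand_kd: float) -> BindingResult:
    """Ki = IC50 / (1 + [L]/Kd) for competition binding against a radioligand."""
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    if radioligand_kd <= 0:
        raise ValueError("radioligand Kd must be positive")
    if radioligand_conc < 0:
        raise ValueError("radioligand concentration cannot be negative")
    ki = ic50 / (1.0 + radioligand_conc / radioligand_kd)
    return BindingResult(
        ic50=ic50, ki=ki, radioligand_conc=radioligand_conc, radioligand_kd=radioligand_kd
    )


def percent_activity(
    mean_rlu_test: float,
    mean_rlu_vehicle: float,
    mean_rlu_ref_max: float,
    mean_rlu_ref_baseline: float,
) -> float:
    """Percent of reference-agonist activity from raw luminescence means.

    100 x (test - vehicle) / (reference max - reference baseline).  The
    denominator is the reference compound's span, so the reference itself
    scores 100%.
    """
    denom = mean_rlu_ref_max - mean_rlu_ref_baseline
    if denom == 0:
        raise ZeroDivisionError("reference span is zero: percent activity undefined")
    return 100.0 * (mean_rlu_test - mean_rlu_vehicle) / denom


def fold_change(ki_parent: float, ki_analog: float) -> tuple[float, int]:
    """Affinity improvement of an analog over its parent.

    Returns the exact ratio ki_parent / ki_analog and the integer-rounded
    value used in prose (e.g. 700 nM -> 44 nM is 15.9, reported 16-fold).
    """
    if ki_parent <= 0 or ki_analog <= 0:
        raise ValueError("Ki values must be positive")
    fold = ki_parent / ki_analog
    return fold, round(fold)
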