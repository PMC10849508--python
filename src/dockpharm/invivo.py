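"""In vivo summary metrics.

Noncompartmental pharmacokinetic analysis (NCA) of concentration-time
profiles with explicit lower-limit-of-quantitation (LLOQ) handling,
therapeutic windows from dose-wise behavioral significance tables,
conditioned-place-preference scores, and the thermodynamic conversion
between affinity fold-changes and binding free-energy differences.

LLOQ convention: concentrations below the limit are "designated as zero"
for concentration summaries before the first quantifiable point, but are
treated as missing (excluded) when fitting the terminal slope, so an
unreliable tail cannot corrupt the half-life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ConcentrationTimeProfile",
    "NCAResult",
    "DoseOutcomeTable",
    "TherapeuticWindow",
    "nca",
    "therapeutic_window",
    "cpp_score",
    "ng_per_ml_to_nm",
    "fold_to_ddg",
    "ddg_to_fold",
]

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.987e-3


class InsufficientDataError(ValueError):
    """Raised when a profile has too few quantifiable points for NCA."""


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One compartment's concentration-time course.

    Units: minutes, and ng/mL (plasma/CSF) or ng/g (brain).  Points at or
    below ``lloq`` are flagged below-limit.
    """

    compartment: str
    times: np.ndarray
    concentrations: np.ndarray
    lloq: float = 0.0
    compound_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.lloq < 0:
            raise ValueError("LLOQ cannot be negative")

    @property
    def below_limit(self) -> np.ndarray:
        return self.concentrations < self.lloq

    @property
    def n_quantifiable(self) -> int:
        return int((~self.below_limit).sum())


@dataclass(frozen=True)
class NCAResult:
    compound_id: str
    compartment: str
    cmax: float
    tmax: float
    lambda_z: float
    t_half: float
    auc_last: float
    auc_inf: float
    n_lambda_points: int
    extrapolated_fraction: float
    lambda_z_adj_r2: float
    message: str = ""


@dataclass(frozen=True)
class DoseOutcomeTable:
    """Dose-wise significance flags for one behavioral endpoint.

    The flags come from the caller's own statistics (ANOVA post-hoc tests);
    this module only reads them.
    """

    compound_id: str
    endpoint: str
    doses: tuple[float, ...]  # mg/kg
    significant: tuple[bool, ...]
    highest_tested_dose: float

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.significant):
            raise ValueError("doses and significance flags disagree in length")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if len(set(self.doses)) != len(self.doses):
            raise ValueError("doses must be unique per endpoint")
        if self.highest_tested_dose < max(self.doses, default=0.0):
            raise ValueError("highest tested dose below a listed dose")

    def onset_dose(self) -> float | None:
        """Smallest tested dose with a significant effect, or None."""
        sig = [d for d, s in zip(self.doses, self.significant) if s]
        return min(sig) if sig else None


@dataclass(frozen=True)
class TherapeuticWindow:
    compound_id: str
    analgesia_endpoint: str
    side_effect_endpoint: str
    analgesia_onset_dose: float
    side_effect_onset_dose: float | None  # None: no dose significant
    window_fold: float
    lower_bound_only: bool


def _terminal_fit(times: np.ndarray, log_conc: np.ndarray) -> tuple[float, float, float]:
    """Log-linear regression; returns (slope, intercept, adjusted R^2)."""
    n = len(times)
    slope, intercept = np.polyfit(times, log_conc, 1)
    pred = slope * times + intercept
    ss_res = float(((log_conc - pred) ** 2).sum())
    ss_tot = float(((log_conc - log_conc.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return float(slope), float(intercept), float(adj)


def nca(
    profile: ConcentrationTimeProfile,
    model: Literal["extravascular", "bolus"] = "extravascular",
    lambda_z_points: int | None = None,
) -> NCAResult:
    """Noncompartmental analysis of one concentration-time profile.

    Cmax/Tmax come from the maximum observed quantifiable concentration.
    The terminal slope lambda_z is fit by log-linear regression over
    candidate windows of the last k >= 3 quantifiable points strictly
    after Tmax, choosing the window with the best adjusted R² (or exactly
    ``lambda_z_points`` if given).  AUC_last uses the linear trapezoid over
    the quantifiable span, with below-limit values before the first
    quantifiable point set to zero; AUC_inf adds C_last/lambda_z.
    """
    if model not in ("extravascular", "bolus"):
        raise ValueError("model must be 'extravascular' or 'bolus'")
    quant = ~profile.below_limit
    if quant.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 quantifiable points, got {int(quant.sum())}"
        )
    t_all, c_all = profile.times, profile.concentrations

    first_q = int(np.argmax(quant))
    last_q = len(quant) - 1 - int(np.argmax(quant[::-1]))
    # Below-limit values before the first quantifiable point count as zero;
    # below-limit values after it are missing and dropped entirely.
    keep = quant.copy()
    keep[:first_q] = True
    conc = np.where(quant, c_all, 0.0)[: last_q + 1][keep[: last_q + 1]]
    times = t_all[: last_q + 1][keep[: last_q + 1]]

    i_max = int(np.argmax(conc))
    cmax, tmax = float(conc[i_max]), float(times[i_max])

    # terminal-phase fit on quantifiable points strictly after Tmax
    tq = profile.times[quant]
    cq = profile.concentrations[quant]
    term_mask = tq > tmax
    t_term, c_term = tq[term_mask], cq[term_mask]
    lambda_z = float("nan")
    adj_best = float("nan")
    n_pts = 0
    message = ""
    if len(t_term) < 3:
        message = "fewer than 3 terminal points: lambda_z undefined"
    else:
        logc = np.log(c_term)
        candidates = (
            [lambda_z_points]
            if lambda_z_points is not None
            else range(3, len(t_term) + 1)
        )
        best = None
        for k in candidates:
            if k is None or k < 3 or k > len(t_term):
                continue
            slope, _, adj = _terminal_fit(t_term[-k:], logc[-k:])
            if best is None or adj > best[2]:
                best = (slope, k, adj)
        if best is None:
            message = "no valid terminal window"
        else:
            slope, n_pts, adj_best = best
            if slope >= 0:
                message = "non-positive terminal slope: t_half undefined"
            else:
                lambda_z = -slope

    auc_last = float(np.trapezoid(conc, times))
    c_last = float(conc[-1])
    if math.isfinite(lambda_z) and lambda_z > 0:
        auc_inf = auc_last + c_last / lambda_z
        t_half = math.log(2) / lambda_z
        extrap = (auc_inf - auc_last) / auc_inf if auc_inf > 0 else 0.0
    else:
        auc_inf = float("nan")
        t_half = float("nan")
        extrap = float("nan")
    return NCAResult(
        compound_id=profile.compound_id,
        compartment=profile.compartment,
        cmax=cmax,
        tmax=tmax,
        lambda_z=lambda_z,
        t_half=t_half,
        auc_last=auc_last,
        auc_inf=auc_inf,
        n_lambda_points=n_pts,
        extrapolated_fraction=extrap,
        lambda_z_adj_r2=adj_best,
        message=message,
    )


def therapeutic_window(
    analgesia: DoseOutcomeTable, side_effect: DoseOutcomeTable
) -> TherapeuticWindow:
    """Therapeutic window between an analgesic and a side-effect endpoint.

    The window is the ratio of the minimum significant side-effect dose to
    the minimum significant analgesic dose.  When no side-effect dose was
    significant, the highest tested side-effect dose is used instead and the
    window is flagged as a lower bound.
    """
    onset_analgesia = analgesia.onset_dose()
    if onset_analgesia is None:
        raise ValueError(
            f"{analgesia.endpoint}: no significant analgesic dose, window undefined"
        )
    onset_side = side_effect.onset_dose()
    if onset_side is None:
        fold = side_effect.highest_tested_dose / onset_analgesia
        lower_bound = True
    else:
        fold = onset_side / onset_analgesia
        lower_bound = False
    return TherapeuticWindow(
        compound_id=analgesia.compound_id,
        analgesia_endpoint=analgesia.endpoint,
        side_effect_endpoint=side_effect.endpoint,
        analgesia_onset_dose=onset_analgesia,
        side_effect_onset_dose=onset_side,
        window_fold=fold,
        lower_bound_only=lower_bound,
    )


def cpp_score(
    time_in_chamber_test: dict[str, float], time_pretest: dict[str, float]
) -> dict[str, float]:
    """Conditioned-place-preference score per chamber: test minus pretest (s)."""
    if set(time_in_chamber_test) != set(time_pretest):
        raise ValueError(
            f"chamber labels differ: {sorted(time_in_chamber_test)} vs {sorted(time_pretest)}"
        )
    return {k: time_in_chamber_test[k] - time_pretest[k] for k in time_in_chamber_test}


def ng_per_ml_to_nm(conc_ng_per_ml: float, mw_g_per_mol: float) -> float:
    """Convert a mass concentration (ng/mL) to nM given the molecular weight.

    The molecular weight is a required caller input; nothing in a
    concentration-time table determines it.
    """
    if mw_g_per_mol <= 0:
        raise ValueError("molecular weight must be positive")
    return conc_ng_per_ml / mw_g_per_mol * 1e3


def fold_to_ddg(fold: float, temperature_k: float = 298.15) -> float:
    """Binding free-energy difference for an affinity fold-change.

    ΔΔG = −RT ln(fold) in kcal/mol; an affinity gain (fold > 1) is negative.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return -R_KCAL * temperature_k * math.log(fold)


def ddg_to_fold(ddg: float, temperature_k: float = 298.15) -> float:
    """Inverse of :func:`fold_to_ddg`."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(-ddg / (R_KCAL * temperature_k))
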