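"""BRET signaling-signature statistics.

Biosensor panels report, per compound and per pathway (Gi1, Gi2, GoB, Gz,
G13, Gq, G15, Gs, β-arrestin-2), an Emax and EC50.  Compounds are compared
to a reference agonist through the log-ratio

    Δlog(Emax/EC50) = log10(Emax/EC50)_compound − log10(Emax/EC50)_reference

whose antilog, RE = 10^Δ, is the per-pathway relative efficacy plotted on
radar charts.  Uncertainty propagates as SEM_Δ = sqrt(SEM₁² + SEM₂²) and
pairwise comparisons use a two-tailed unpaired Student t-test on the
per-experiment log(Emax/EC50) values.

Emax is conventionally in percent of the reference response and EC50 in
molar; the absolute log-ratio depends on that choice but Δlog(Emax/EC50)
does not, and Δ is the reported quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathwayActivity",
    "RelativeEfficacy",
    "ubret",
    "log_r",
    "sem_of_mean",
    "relative_efficacy",
    "holm_adjust",
    "radar_table",
]


class DegenerateControlsError(ValueError):
    """Raised when BRET positive and negative controls coincide."""


@dataclass(frozen=True)
class PathwayActivity:
    """Per-pathway Emax/EC50 summary for one compound.

    ``emax``/``ec50`` are the across-experiment means; ``sd_log_r`` is the
    standard deviation of log10(Emax/EC50) over the ``n_experiments``
    independent experiments.
    """

    compound_id: str
    pathway: str
    emax: float
    ec50: float
    n_experiments: int
    sd_log_r: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")
        if self.n_experiments < 1:
            raise ValueError("need at least one experiment")
        if self.sd_log_r < 0:
            raise ValueError("standard deviation cannot be negative")

    @property
    def mean_log_r(self) -> float:
        return log_r(self.emax, self.ec50)

    @property
    def sem_log_r(self) -> float:
        return sem_of_mean(self.sd_log_r, self.n_experiments)


@dataclass(frozen=True)
class RelativeEfficacy:
    compound_id: str
    reference_id: str
    pathway: str
    delta_log_r: float
    sem_delta: float
    re: float
    p_value: float | None


def ubret(bret_ratio: float, a_negative_control: float, b_positive_control: float) -> float:
    """Universal BRET standardization.

    Maps the negative-control ratio A to 0 and the positive-control ratio B
    to 10,000: uBRET = (ratio − A)/(B − A) × 10,000.
    """
    if a_negative_control == b_positive_control:
        raise DegenerateControlsError("negative and positive control ratios coincide")
    return (bret_ratio - a_negative_control) / (b_positive_control - a_negative_control) * 10_000.0


def log_r(emax: float, ec50: float) -> float:
    """log10(Emax/EC50), the activity log-ratio for one pathway."""
    if emax <= 0 or ec50 <= 0:
        raise ValueError("Emax and EC50 must be positive")
    return math.log10(emax / ec50)


def sem_of_mean(sd: float, n: int) -> float:
    """Standard error of the mean, σ/√n."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if sd < 0:
        raise ValueError("standard deviation cannot be negative")
    return sd / math.sqrt(n)


def relative_efficacy(
    compound: PathwayActivity,
    reference: PathwayActivity,
    welch: bool = False,
) -> RelativeEfficacy:
    """Δlog(Emax/EC50) of a compound versus a reference on one pathway.

    The p-value is a two-tailed unpaired t-test (Student by default, Welch
    optional) built from the per-experiment log-ratio summaries.  With
    fewer than two experiments in either group the test is undefined and
    ``p_value`` is None; point estimates are still returned.
    """
    if compound.pathway != reference.pathway:
        raise ValueError(
            f"pathway mismatch: {compound.pathway!r} vs {reference.pathway!r}"
        )
    delta = compound.mean_log_r - reference.mean_log_r
    sem_delta = math.sqrt(compound.sem_log_r**2 + reference.sem_log_r**2)
    if compound.n_experiments < 2 or reference.n_experiments < 2:
        p_value = None
    else:
        _, p = stats.ttest_ind_from_stats(
            mean1=compound.mean_log_r,
            std1=compound.sd_log_r,
            nobs1=compound.n_experiments,
            mean2=reference.mean_log_r,
            std2=reference.sd_log_r,
            nobs2=reference.n_experiments,
            equal_var=not welch,
        )
        p_value = float(p)
    return RelativeEfficacy(
        compound_id=compound.compound_id,
        reference_id=reference.compound_id,
        pathway=compound.pathway,
        delta_log_r=delta,
        sem_delta=sem_delta,
        re=10.0**delta,
        p_value=p_value,
    )


def holm_adjust(re_list: Sequence[RelativeEfficacy]) -> list[RelativeEfficacy]:
    """Holm step-down adjustment of the per-pathway p-values.

    Off by default in the pipeline (per-pathway pairwise tests are
    reported uncorrected); apply when a family-wise error rate across
    pathways is wanted.  Entries with undefined p-values pass through.
    """
    import dataclasses

    defined = [(i, r.p_value) for i, r in enumerate(re_list) if r.p_value is not None]
    m = len(defined)
    order = sorted(range(m), key=lambda k: defined[k][1])
    adjusted = [None] * m
    running = 0.0
    for rank, k in enumerate(order):
        running = max(running, (m - rank) * defined[k][1])
        adjusted[k] = min(1.0, running)
    out = list(re_list)
    for (i, _), p_adj in zip(defined, adjusted):
        out[i] = dataclasses.replace(out[i], p_value=p_adj)
    return out


def radar_table(re_list: Sequence[RelativeEfficacy]) -> pd.DataFrame:
    """Wide compound x pathway table of relative efficacies for radar plots.

    The reference compound appears as a row of exactly 1.0 across all
    pathways.  Duplicate (compound, pathway) entries are an error.
    """
    if not re_list:
        raise ValueError("no relative efficacies supplied")
    refs = {r.reference_id for r in re_list}
    if len(refs) > 1:
        raise ValueError(f"mixed reference compounds: {sorted(refs)}")
    reference_id = refs.pop()
    seen = set()
    for r in re_list:
        key = (r.compound_id, r.pathway)
        if key in seen:
            raise ValueError(f"duplicate pathway entry: {key}")
        seen.add(key)
    pathways = list(dict.fromkeys(r.pathway for r in re_list))
    rows = {reference_id: {p: 1.0 for p in pathways}}
    for r in re_list:
        rows.setdefault(r.compound_id, {})[r.pathway] = r.re
    table = pd.DataFrame.from_dict(rows, orient="index", columns=pathways)
    table.index.name = "compound_id"
    return table
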