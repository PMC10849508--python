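"""Seeded synthetic-data generators.

Every pipeline stage in this package can be exercised without external
downloads: these generators produce inputs with the statistical structure
each stage assumes — a score-ranked library organised into chemotype
families, pose pairs whose optimal-assignment RMSD is known by
construction, 4PL concentration-response curves with replicate noise,
per-pathway Emax/EC50 panels with a planted log-ratio shift, and
one-compartment extravascular PK time courses with a quantitation limit.

All randomness flows through one `numpy.random.default_rng` per call,
seeded explicitly; the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curves import DoseResponseCurve, four_pl
from .invivo import ConcentrationTimeProfile
from .poses import Pose, symmetry_rmsd
from .signaling import PathwayActivity
from .triage import LigandRecord

__all__ = [
    "GeneratorConfig",
    "PKParams",
    "FAMILY_SCAFFOLDS",
    "SUBSTITUENTS",
    "gen_library",
    "planted_family",
    "gen_pose_pair",
    "gen_dose_response",
    "SyntheticDoseResponse",
    "gen_pk_profile",
    "SyntheticPKProfile",
    "gen_pathway_panel",
]

#: Family scaffolds: diverse drug-like cores whose pairwise ECFP4 Tanimoto
#: similarity stays well below the 0.38 novelty threshold, each written so
#: the string ends at an aliphatic attachment point that substituents extend.
FAMILY_SCAFFOLDS: tuple[str, ...] = (
    "c1ccc2c(c1)oc(n2)CCNC(=O)C",
    "c1ccc2c(c1)sc(n2)NC(=O)CC",
    "c1ccc2c(c1)[nH]c(n2)CSCC",
    "c1ccc2c(c1)cc([nH]2)CCC(=O)OC",
    "c1ccc2c(c1)ccc(n2)NS(=O)(=O)CC",
    "c1ccc2c(c1)cncc2CN(C)CC",
    "c1ccc(cc1)C(=O)N1CCOC(C1)CC",
    "c1ccc(cc1)S(=O)(=O)N1CCCC1CC",
    "CCOc1ccccc1-c1cc(no1)C",
    "O=C(c1ccco1)Nc1nnc(s1)C",
    "c1ccc(nc1)NC(=O)Cn1cc(cn1)C",
    "C1CCC(CC1)NC(=O)c1ccnc(c1)OCC",
    "O=C1C=CC(=NN1c1ccc(cc1)OC)CC",
    "O=C(c1cccs1)N1CCN(CC1)C",
    "c1csc(c1)c1nc(no1)CCOC",
    "C1CCN(CC1)S(=O)(=O)c1ccc(cc1)OC",
    "c1cc2cccnc2nc1NCC(=O)N",
    "C1Oc2ccccc2OC1C(=O)NCC",
    "c1cc(cnc1)C#Cc1ccccc1CN",
    "C1CC2(C1)CCN(C2)C(=O)COc1ccccc1",
    "c1cc(ccc1F)C(c1ncccn1)OCC",
    "C1CCC2(CC1)OCCN2C(=O)c1ccc(cc1)C",
    "c1ccc(cc1)c1cc(sc1)CN1C(=O)NC(=O)C1C",
    "c1ccc(cc1)CCN1CCC(CC1)Oc1ccncc1",
)

#: Small substituents appended at the attachment point; varying them keeps
#: intra-family Tc comfortably above the 0.5 clustering threshold.
SUBSTITUENTS: tuple[str, ...] = (
    "", "C", "CC", "CCC", "O", "CO", "CCO", "N", "CN", "C(C)C", "OC", "CCN",
)

#: Default pose-pair element pattern, cycled to the requested atom count.
_ELEMENT_POOL: tuple[str, ...] = ("C", "O", "C", "N", "O", "C")


@dataclass(frozen=True)
class PKParams:
    """One-compartment extravascular PK parameters.

    Defaults emulate a low (0.2 mg/kg i.p.) dose in a 30 g mouse with a
    terminal half-life near two hours and a Cmax in the mid-teens of
    ng/mL, so the standard nine-point schedule leaves a quantifiable
    terminal phase above a 2 ng/mL LLOQ while still censoring the 24 h
    point.  ``volume_ml`` is the apparent volume of distribution V/F.
    """

    dose_mg_per_kg: float = 0.2
    ka_per_min: float = 0.05
    ke_per_min: float = math.log(2) / 114.0
    volume_ml: float = 300.0
    lloq_ng_per_ml: float = 2.0
    body_mass_kg: float = 0.030
    bioavailability: float = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    n_molecules: int = 500
    n_families: int = 20
    mw_range: tuple[float, float] = (350.0, 500.0)
    clogp_range: tuple[float, float] = (3.0, 5.0)
    score_noise_sd: float = 2.0
    curve_noise_sd: float = 0.05
    n_substituents: int = len(SUBSTITUENTS)
    pk_params: PKParams = field(default_factory=PKParams)

    def __post_init__(self) -> None:
        if self.n_molecules <= 0 or self.n_families <= 0:
            raise ValueError("molecule and family counts must be positive")
        if self.n_families > len(FAMILY_SCAFFOLDS):
            raise ValueError(
                f"at most {len(FAMILY_SCAFFOLDS)} families available"
            )
        if not (1 <= self.n_substituents <= len(SUBSTITUENTS)):
            raise ValueError("n_substituents out of range")
        for lo, hi, name in (
            (*self.mw_range, "mw_range"),
            (*self.clogp_range, "clogp_range"),
        ):
            if lo > hi:
                raise ValueError(f"{name} lower bound exceeds upper bound")
        if self.score_noise_sd < 0 or self.curve_noise_sd < 0:
            raise ValueError("noise levels cannot be negative")
        pk = self.pk_params
        if min(pk.ka_per_min, pk.ke_per_min, pk.volume_ml) <= 0:
            raise ValueError("PK rate constants and volume must be positive")


def planted_family(record_id: str) -> int:
    """Recover the planted family index encoded in a generated record id."""
    return int(record_id.split("-")[0].removeprefix("FAM"))


def gen_library(config: GeneratorConfig) -> list[LigandRecord]:
    """Score-ranked synthetic library of chemotype families.

    Molecules are drawn as ``n_families`` structural families — a shared
    scaffold with a varied small substituent — so that intra-family
    fingerprint Tc is typically >= 0.5 and inter-family Tc < 0.38.  Each
    record gets MW and cLogP sampled uniformly in the configured closed
    ranges and a docking-like score = family base score + Gaussian noise.
    Records come back sorted best score (lowest) first with ranks assigned;
    ids encode the planted family (``FAM<k>-<i>``) for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    scaffolds = [
        FAMILY_SCAFFOLDS[i]
        for i in rng.permutation(len(FAMILY_SCAFFOLDS))[: config.n_families]
    ]
    subs = SUBSTITUENTS[: config.n_substituents]
    base_scores = rng.normal(-38.0, 4.0, size=config.n_families)
    families = np.arange(config.n_molecules) % config.n_families
    records = []
    for i, fam in enumerate(families):
        smiles = scaffolds[fam] + subs[rng.integers(len(subs))]
        records.append(
            LigandRecord(
                id=f"FAM{fam:02d}-{i:04d}",
                smiles=smiles,
                mw=float(rng.uniform(*config.mw_range)),
                clogp=float(rng.uniform(*config.clogp_range)),
                score=float(base_scores[fam] + rng.normal(0.0, config.score_noise_sd)),
                rank=0,
            )
        )
    records.sort(key=lambda r: (r.score, r.id))
    return [
        LigandRecord(
            id=r.id, smiles=r.smiles, mw=r.mw, clogp=r.clogp, score=r.score, rank=k + 1
        )
        for k, r in enumerate(records)
    ]


def _spread_points(rng: np.random.Generator, n: int, min_sep: float = 3.0) -> np.ndarray:
    """Random points with a minimum pairwise separation (rejection sampling)."""
    side = max(min_sep * 2.0, min_sep * n ** (1.0 / 3.0) * 2.0)
    points: list[np.ndarray] = []
    while len(points) < n:
        cand = rng.uniform(0.0, side, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in points):
            points.append(cand)
    return np.array(points)


def gen_pose_pair(
    n_atoms: int,
    permuted_elements: Sequence[str],
    rmsd_target: float,
    seed: int,
) -> tuple[Pose, Pose, float]:
    """Pose pair whose optimal-assignment RMSD is ``rmsd_target`` by construction.

    The second pose is the first with a random permutation applied within
    each listed element class plus an isotropic Gaussian displacement scaled
    so that the symmetry-corrected RMSD equals ``rmsd_target`` within 1e-6.
    Returns ``(pose_a, pose_b, true_rmsd)``.
    """
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    if rmsd_target < 0:
        raise ValueError("RMSD target cannot be negative")
    rng = np.random.default_rng(seed)
    elements = tuple(_ELEMENT_POOL[i % len(_ELEMENT_POOL)] for i in range(n_atoms))
    coords_a = _spread_points(rng, n_atoms)
    pose_a = Pose(ligand_id="synthetic-pair", elements=elements, coords=coords_a)

    perm = np.arange(n_atoms)
    for element in permuted_elements:
        idx = [i for i, el in enumerate(elements) if el == element]
        perm[idx] = rng.permutation(idx)
    coords_b = coords_a[perm].copy()

    true_rmsd = 0.0
    if rmsd_target > 0:
        disp = rng.normal(size=(n_atoms, 3))

        def rmsd_at(s: float) -> float:
            b = Pose(
                ligand_id="synthetic-pair",
                elements=elements,
                coords=coords_b + s * disp,
            )
            return symmetry_rmsd(pose_a, b)

        # the map s -> RMSD is essentially linear while the optimal
        # assignment is stable; a short fixed-point iteration converges fast
        s = rmsd_target / rmsd_at(1.0)
        for _ in range(100):
            r = rmsd_at(s)
            if abs(r - rmsd_target) <= 1e-9:
                break
            s *= rmsd_target / r
        true_rmsd = rmsd_at(s)
        coords_b = coords_b + s * disp
    pose_b = Pose(ligand_id="synthetic-pair", elements=elements, coords=coords_b)
    return pose_a, pose_b, float(true_rmsd)


@dataclass(frozen=True)
class SyntheticDoseResponse:
    """A generated curve together with the parameters that produced it."""

    curve: DoseResponseCurve
    true_bottom: float
    true_top: float
    true_pec50: float
    true_hill: float


def gen_dose_response(
    true_params: tuple[float, float, float, float],
    concentrations: Sequence[float],
    replicates: int,
    noise_sd: float,
    seed: int,
    compound_id: str = "synthetic",
) -> SyntheticDoseResponse:
    """4PL responses with Gaussian replicate noise.

    ``true_params`` is (bottom, top, pEC50, hill); ``noise_sd`` is a
    fraction of the curve span.  Concentrations (molar) must include at
    least four distinct values spanning at least two log units.
    """
    conc = np.asarray(concentrations, dtype=float)
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    span_log = math.log10(conc.max() / conc.min())
    if span_log < 2.0:
        raise ValueError("concentrations must span at least 2 log units")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    bottom, top, pec50, hill = true_params
    rng = np.random.default_rng(seed)
    conc_rep = np.tile(conc, replicates)
    clean = four_pl(np.log10(conc_rep), bottom, top, pec50, hill)
    noise = rng.normal(0.0, noise_sd * abs(top - bottom), size=clean.shape)
    curve = DoseResponseCurve(
        compound_id=compound_id, concentrations=conc_rep, responses=clean + noise
    )
    return SyntheticDoseResponse(
        curve=curve,
        true_bottom=bottom,
        true_top=top,
        true_pec50=pec50,
        true_hill=hill,
    )


@dataclass(frozen=True)
class SyntheticPKProfile:
    """A generated PK time course together with its true rate constants."""

    profile: ConcentrationTimeProfile
    true_ka: float
    true_ke: float

    @property
    def true_t_half(self) -> float:
        return math.log(2) / self.true_ke

    @property
    def usable(self) -> bool:
        """At least three quantifiable points — enough for NCA."""
        return self.profile.n_quantifiable >= 3


def one_compartment_conc(t: np.ndarray, pk: PKParams) -> np.ndarray:
    """Extravascular one-compartment concentration (ng/mL) at times t (min)."""
    if pk.ka_per_min == pk.ke_per_min:
        raise ValueError("ka equal to ke: one-compartment model degenerate")
    dose_ng = pk.dose_mg_per_kg * pk.body_mass_kg * 1e6 * pk.bioavailability
    coeff = dose_ng * pk.ka_per_min / (pk.volume_ml * (pk.ka_per_min - pk.ke_per_min))
    return coeff * (np.exp(-pk.ke_per_min * t) - np.exp(-pk.ka_per_min * t))


def gen_pk_profile(
    config: GeneratorConfig,
    times: Sequence[float],
    compartment: str = "plasma",
    noise_cv: float = 0.0,
    compound_id: str = "synthetic",
) -> SyntheticPKProfile:
    """One-compartment extravascular concentration-time profile.

    C(t) = (F·Dose·ka / (V·(ka − ke))) · (e^(−ke·t) − e^(−ka·t)), optionally
    with proportional Gaussian noise of coefficient of variation
    ``noise_cv``.  Values below the configured LLOQ are flagged below-limit
    by the profile itself.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(np.diff(t) <= 0) or np.any(t < 0):
        raise ValueError("times must be non-negative and strictly increasing")
    pk = config.pk_params
    conc = one_compartment_conc(t, pk)
    if noise_cv > 0:
        rng = np.random.default_rng(config.seed)
        conc = np.clip(conc * (1.0 + rng.normal(0.0, noise_cv, size=conc.shape)), 0.0, None)
    profile = ConcentrationTimeProfile(
        compartment=compartment,
        times=t,
        concentrations=conc,
        lloq=pk.lloq_ng_per_ml,
        compound_id=compound_id,
    )
    return SyntheticPKProfile(profile=profile, true_ka=pk.ka_per_min, true_ke=pk.ke_per_min)


def gen_pathway_panel(
    pathways: Sequence[str],
    delta_log_r: float,
    n_experiments: int,
    sigma: float,
    seed: int,
    reference_log_r: float = 7.0,
    compound_id: str = "test-compound",
    reference_id: str = "reference",
) -> list[tuple[PathwayActivity, PathwayActivity]]:
    """Per-pathway (compound, reference) activity pairs with a planted shift.

    Per-experiment log10(Emax/EC50) values are drawn Normal(mu, sigma) with
    the compound mean shifted by ``delta_log_r``; summaries (mean and SD of
    the log-ratio) are what downstream relative-efficacy statistics consume.
    Emax is fixed at 100% so the EC50 carries the log-ratio.
    """
    if n_experiments < 1:
        raise ValueError("need at least one experiment per pathway")
    rng = np.random.default_rng(seed)
    panel = []
    for pathway in pathways:
        ref_draws = rng.normal(reference_log_r, sigma, size=n_experiments)
        cmp_draws = rng.normal(reference_log_r + delta_log_r, sigma, size=n_experiments)
        ddof = 1 if n_experiments > 1 else 0
        compound = PathwayActivity(
            compound_id=compound_id,
            pathway=pathway,
            emax=100.0,
            ec50=10.0 ** (math.log10(100.0) - float(cmp_draws.mean())),
            n_experiments=n_experiments,
            sd_log_r=float(cmp_draws.std(ddof=ddof)),
        )
        reference = PathwayActivity(
            compound_id=reference_id,
            pathway=pathway,
            emax=100.0,
            ec50=10.0 ** (math.log10(100.0) - float(ref_draws.mean())),
            n_experiments=n_experiments,
            sd_log_r=float(ref_draws.std(ddof=ddof)),
        )
        panel.append((compound, reference))
    return panel
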