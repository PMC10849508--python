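"""Post-docking hit triage.

The screening funnel this module implements takes a score-ranked library of
docked molecules and reduces it to a short list of novel, diverse candidates:

1. physical-property windows (molecular weight and cLogP),
2. circular-fingerprint similarity (ECFP4-style, radius 2, 2048 bits),
3. greedy leader clustering of the ranked list at a Tanimoto threshold,
4. rejection of candidates too similar to already-known ligands,
5. analog retrieval around confirmed hits,
6. campaign bookkeeping (sampled pose counts, hit rates).

Similarity thresholds are always applied with this package's own
fingerprinter so the cascade is self-consistent; bit-exact agreement with
other toolkits is not promised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors, Crippen
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "LigandRecord",
    "Fingerprint",
    "ClusterAssignment",
    "NoveltyReport",
    "CampaignSummary",
    "fingerprint",
    "tanimoto",
    "property_filter",
    "leader_cluster",
    "novelty_filter",
    "analog_search",
    "campaign_summary",
    "hit_rate",
    "percent_fulfilment",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class MissingFingerprintError(KeyError):
    """Raised when a record has no fingerprint in the supplied mapping."""


@dataclass(frozen=True)
class LigandRecord:
    """One library molecule with its docking score.

    Scores are docking-energy-like: lower is better.  ``mw`` is the molecular
    weight in amu and ``clogp`` the calculated octanol-water logP.
    """

    id: str
    smiles: str
    mw: float
    clogp: float
    score: float
    rank: int = 0


@dataclass(frozen=True)
class Fingerprint:
    """Folded circular fingerprint: a set of on-bit indices."""

    bits: frozenset[int]
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.n_bits for b in self.bits):
            raise ValueError("bit index outside folded length")


@dataclass
class ClusterAssignment:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class NoveltyReport:
    candidate_id: str
    max_tc: float
    nearest_reference_id: str | None
    kept: bool


@dataclass(frozen=True)
class CampaignSummary:
    n_input: int
    n_fit: int
    mean_orientations: float
    mean_conformations: float
    mean_poses_per_molecule: float
    total_complexes: float

    @property
    def poses_per_molecule_millions(self) -> float:
        """Mean poses per molecule in millions, to three significant figures."""
        millions = self.mean_poses_per_molecule / 1e6
        if millions == 0:
            return 0.0
        return float(f"{millions:.3g}")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


_FP_GENERATORS: dict[tuple[int, int], object] = {}


def fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Hashed circular fingerprint (ECFP4 equivalent at the default radius 2).

    Deterministic for a given canonical structure: "CCO" and "OCC" give
    identical bit sets.
    """
    mol = _mol_from_smiles(smiles)
    key = (radius, n_bits)
    gen = _FP_GENERATORS.get(key)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        _FP_GENERATORS[key] = gen
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), radius=radius, n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b| in [0, 1].

    Two empty fingerprints are defined to have similarity 0.0 (with a
    warning): nothing is shared, and 1.0 would make every featureless
    molecule a duplicate of every other.
    """
    if a.radius != b.radius or a.n_bits != b.n_bits:
        raise ValueError("fingerprints have incompatible radius or length")
    if not a.bits and not b.bits:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0.0", stacklevel=2)
        return 0.0
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


def compute_properties(smiles: str) -> tuple[float, float]:
    """Molecular weight (amu) and Crippen cLogP computed from the structure."""
    mol = _mol_from_smiles(smiles)
    return Descriptors.MolWt(mol), Crippen.MolLogP(mol)


def property_filter(
    records: Iterable[LigandRecord],
    mw_low: float = 350.0,
    mw_high: float = 500.0,
    clogp_low: float = 3.0,
    clogp_high: float = 5.0,
) -> list[LigandRecord]:
    """Keep records inside the closed MW and cLogP windows, order preserved.

    Defaults are the lead-like window used for the screened library subset
    (350–500 amu, cLogP 3–5); boundary values are kept.
    """
    for low, high, name in ((mw_low, mw_high, "mw"), (clogp_low, clogp_high, "clogp")):
        if not (math.isfinite(low) and math.isfinite(high)):
            raise ValueError(f"{name} bounds must be finite")
        if low > high:
            raise ValueError(f"{name} lower bound exceeds upper bound")
    return [
        r
        for r in records
        if mw_low <= r.mw <= mw_high and clogp_low <= r.clogp <= clogp_high
    ]


def leader_cluster(
    ranked: Sequence[LigandRecord],
    fps: Mapping[str, Fingerprint],
    tc_threshold: float = 0.5,
) -> list[ClusterAssignment]:
    """Greedy leader clustering of a best-score-first ranked list.

    Walking down the ranking, each record joins the first existing cluster
    whose leader it matches at Tc >= ``tc_threshold``, otherwise it founds a
    new cluster.  Because the list is score-sorted, every leader is the
    best-scoring member of its cluster.
    """
    order = [r.score for r in ranked]
    if any(b < a for a, b in zip(order, order[1:])):
        raise ValueError("records must be sorted best score (lowest) first")
    clusters: list[ClusterAssignment] = []
    leader_fps: list[Fingerprint] = []
    for rec in ranked:
        try:
            fp = fps[rec.id]
        except KeyError as exc:
            raise MissingFingerprintError(f"no fingerprint for record {rec.id!r}") from exc
        for assignment, lfp in zip(clusters, leader_fps):
            if tanimoto(fp, lfp) >= tc_threshold:
                assignment.member_ids.append(rec.id)
                break
        else:
            clusters.append(ClusterAssignment(representative_id=rec.id, member_ids=[rec.id]))
            leader_fps.append(fp)
    return clusters


def novelty_filter(
    candidates: Sequence[LigandRecord],
    reference_smiles: Sequence[str],
    tc_threshold: float = 0.38,
    radius: int = 2,
    n_bits: int = 2048,
) -> list[NoveltyReport]:
    """Reject candidates resembling known ligands.

    A candidate with maximum Tc >= ``tc_threshold`` to any reference is not
    pursued (rejection threshold inclusive); an empty reference set keeps
    everything with max_tc = 0.
    """
    ref_fps = [fingerprint(s, radius, n_bits) for s in reference_smiles]
    reports = []
    for cand in candidates:
        fp = fingerprint(cand.smiles, radius, n_bits)
        max_tc = 0.0
        nearest: str | None = None
        for ref_smi, ref_fp in zip(reference_smiles, ref_fps):
            tc = tanimoto(fp, ref_fp)
            if tc > max_tc:
                max_tc, nearest = tc, ref_smi
        reports.append(
            NoveltyReport(
                candidate_id=cand.id,
                max_tc=max_tc,
                nearest_reference_id=nearest,
                kept=max_tc < tc_threshold,
            )
        )
    return reports


def analog_search(
    hit: LigandRecord,
    pool: Sequence[LigandRecord],
    tc_min: float = 0.5,
    radius: int = 2,
    n_bits: int = 2048,
) -> list[LigandRecord]:
    """Pool members with Tc(hit, member) >= tc_min, most similar first.

    Ties in similarity are broken by ascending id so the ordering is total.
    """
    hit_fp = fingerprint(hit.smiles, radius, n_bits)
    scored = []
    for rec in pool:
        tc = tanimoto(hit_fp, fingerprint(rec.smiles, radius, n_bits))
        if tc >= tc_min:
            scored.append((tc, rec))
    scored.sort(key=lambda pair: (-pair[0], pair[1].id))
    return [rec for _, rec in scored]


def campaign_summary(
    n_input: int,
    n_fit: int,
    mean_orientations: float,
    mean_conformations: float,
) -> CampaignSummary:
    """Docking-campaign sampling bookkeeping.

    Poses per molecule is the product of mean orientations and mean
    conformations per orientation; total complexes multiplies that by the
    number of molecules successfully fit in the site.
    """
    if min(n_input, n_fit, mean_orientations, mean_conformations) < 0:
        raise ValueError("counts must be non-negative")
    if n_fit > n_input:
        raise ValueError("cannot fit more molecules than were input")
    poses = mean_orientations * mean_conformations
    return CampaignSummary(
        n_input=n_input,
        n_fit=n_fit,
        mean_orientations=mean_orientations,
        mean_conformations=mean_conformations,
        mean_poses_per_molecule=poses,
        total_complexes=n_fit * poses,
    )


def hit_rate(displacements: Sequence[float], threshold: float = 50.0) -> tuple[int, float, int]:
    """Single-point screening hit rate.

    A hit displaces strictly more than ``threshold`` percent of the
    radioligand.  Returns ``(n_hits, rate_percent, rate_percent_rounded)``;
    over-displacement above 100% is clipped to 100 before counting.
    """
    if len(displacements) == 0:
        raise ValueError("hit rate undefined for an empty displacement list")
    clipped = [min(d, 100.0) for d in displacements]
    n_hits = sum(1 for d in clipped if d > threshold)
    rate = 100.0 * n_hits / len(clipped)
    return n_hits, rate, round(rate)


def percent_fulfilment(n_made: int, n_ordered: int) -> tuple[float, int]:
    """Synthesis fulfilment as a percentage (exact, and rounded for reporting)."""
    if n_ordered <= 0:
        raise ValueError("no molecules ordered")
    if n_made < 0 or n_made > n_ordered:
        raise ValueError("molecules made must lie in [0, ordered]")
    rate = 100.0 * n_made / n_ordered
    return rate, round(rate)
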