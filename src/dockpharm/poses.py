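"""Geometric evaluation of docked ligand poses.

Two operations: a polar-contact filter that asks whether any polar ligand
atom sits within hydrogen-bonding distance of named receptor probe atoms,
and a symmetry-corrected RMSD in which chemically equivalent atoms (same
element) are matched by optimal assignment before the deviation is
computed.  Poses are compared in a common (receptor) frame; no
re-superposition is performed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "Pose",
    "SiteProbe",
    "SiteDefinition",
    "ContactReport",
    "polar_contact_filter",
    "symmetry_rmsd",
    "naive_rmsd",
]

#: Heavy atoms counted as polar by default.  Sulfur is deliberately excluded:
#: thioethers are poor hydrogen-bond partners at heavy-atom distance cutoffs.
DEFAULT_POLAR_ELEMENTS = frozenset({"N", "O"})


class IncompatiblePoseError(ValueError):
    """Raised when two poses do not describe the same multiset of atoms."""


@dataclass(frozen=True)
class Pose:
    """Element-labelled 3-D coordinates of one ligand conformation (Å)."""

    ligand_id: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3)
    polar_flags: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (n_atoms, 3) array")
        if len(self.elements) != coords.shape[0]:
            raise ValueError("element list and coordinates disagree in length")
        if coords.shape[0] < 1:
            raise ValueError("a pose needs at least one atom")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if self.polar_flags is not None and len(self.polar_flags) != len(self.elements):
            raise ValueError("polar flags and elements disagree in length")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def polar_indices(self) -> list[int]:
        if self.polar_flags is not None:
            return [i for i, f in enumerate(self.polar_flags) if f]
        return [i for i, el in enumerate(self.elements) if el in DEFAULT_POLAR_ELEMENTS]


@dataclass(frozen=True)
class SiteProbe:
    """One named polar receptor atom, e.g. residue "S383", atom "OG"."""

    residue: str
    atom: str
    position: tuple[float, float, float]
    role: Literal["donor", "acceptor", "either"] = "either"

    @property
    def label(self) -> str:
        return f"{self.residue}:{self.atom}"


@dataclass(frozen=True)
class SiteDefinition:
    probes: tuple[SiteProbe, ...]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.probes]
        dup = [l for l, c in Counter(labels).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate site probes: {dup}")


@dataclass(frozen=True)
class ContactReport:
    ligand_id: str
    distances: dict[str, float]  # probe label -> min heavy-atom distance (Å)
    closest_atoms: dict[str, int]  # probe label -> ligand atom index
    passed: bool
    rule: str
    reason: str | None = None


def polar_contact_filter(
    pose: Pose,
    site: SiteDefinition,
    cutoff: float = 3.5,
    require: Literal["any", "all"] = "any",
) -> ContactReport:
    """Polar-proximity pose filter.

    For each probe, find the minimum distance from any polar ligand heavy
    atom (N/O by default, or explicit flags).  The pose passes when the
    required combination of probes ("any" or "all") lies within ``cutoff``
    (inclusive).  Poses with no polar atoms fail with a reason rather than
    raising.
    """
    if require not in ("any", "all"):
        raise ValueError("require must be 'any' or 'all'")
    rule = f"{require} probe <= {cutoff:g} Å"
    polar_idx = pose.polar_indices()
    if not polar_idx:
        return ContactReport(
            ligand_id=pose.ligand_id,
            distances={},
            closest_atoms={},
            passed=False,
            rule=rule,
            reason="no polar atoms",
        )
    polar_xyz = pose.coords[polar_idx]
    probe_xyz = np.array([p.position for p in site.probes], dtype=float)
    dists = cdist(probe_xyz, polar_xyz)  # (n_probes, n_polar)
    min_per_probe = dists.min(axis=1)
    argmin_per_probe = dists.argmin(axis=1)
    distances = {p.label: float(d) for p, d in zip(site.probes, min_per_probe)}
    closest = {
        p.label: int(polar_idx[i]) for p, i in zip(site.probes, argmin_per_probe)
    }
    hits = min_per_probe <= cutoff
    passed = bool(hits.any()) if require == "any" else bool(hits.all())
    return ContactReport(
        ligand_id=pose.ligand_id,
        distances=distances,
        closest_atoms=closest,
        passed=passed,
        rule=rule,
    )


def _check_same_elements(a: Pose, b: Pose) -> None:
    ca, cb = Counter(a.elements), Counter(b.elements)
    if ca != cb:
        diff = {el: (ca.get(el, 0), cb.get(el, 0)) for el in set(ca) | set(cb) if ca.get(el, 0) != cb.get(el, 0)}
        raise IncompatiblePoseError(f"element multisets differ (a_count, b_count): {diff}")


def _kabsch_superpose(a: Pose, b: Pose) -> Pose:
    """Least-squares superposition of b onto a using the index matching."""
    if a.n_atoms != b.n_atoms:
        raise IncompatiblePoseError("alignment requires index-matched poses")
    from scipy.spatial.transform import Rotation

    ca, cb = a.coords - a.coords.mean(0), b.coords - b.coords.mean(0)
    rot, _ = Rotation.align_vectors(ca, cb)
    return Pose(
        ligand_id=b.ligand_id,
        elements=b.elements,
        coords=rot.apply(cb) + a.coords.mean(0),
        polar_flags=b.polar_flags,
    )


def symmetry_rmsd(a: Pose, b: Pose, align: bool = False) -> float:
    """Symmetry-corrected RMSD between two poses of the same ligand (Å).

    Within each element class the atom correspondence is chosen by solving
    the optimal assignment problem (Hungarian algorithm) on the squared
    inter-atom distance matrix, so that topologically equivalent atoms —
    e.g. the two oxygens of an ester written in either order — do not
    inflate the deviation.  Poses are compared in a common frame by
    default; ``align=True`` first superposes b onto a by index-matched
    least squares (for poses that do not already share a receptor frame).
    """
    _check_same_elements(a, b)
    if align:
        b = _kabsch_superpose(a, b)
    total_sq = 0.0
    for element in set(a.elements):
        ia = [i for i, el in enumerate(a.elements) if el == element]
        ib = [i for i, el in enumerate(b.elements) if el == element]
        cost = cdist(a.coords[ia], b.coords[ib], metric="sqeuclidean")
        rows, cols = linear_sum_assignment(cost)
        total_sq += float(cost[rows, cols].sum())
    return float(np.sqrt(total_sq / a.n_atoms))


def naive_rmsd(a: Pose, b: Pose) -> float:
    """Index-matched RMSD, the uncorrected baseline (Å)."""
    if a.n_atoms != b.n_atoms:
        raise IncompatiblePoseError(
            f"atom counts differ: {a.n_atoms} vs {b.n_atoms}"
        )
    delta = a.coords - b.coords
    return float(np.sqrt((delta * delta).sum() / a.n_atoms))
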