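"""File-format helpers.

Plain-text exchange formats only: SMILES (.smi, tab-separated), CSV tables
via pandas, SD-format pose files via RDKit, site probes from YAML or a
PDB-format subset via gemmi.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from .curves import DoseResponseCurve
from .invivo import ConcentrationTimeProfile, DoseOutcomeTable, NCAResult
from .poses import Pose, SiteDefinition, SiteProbe
from .triage import (
    CampaignSummary,
    ClusterAssignment,
    LigandRecord,
    NoveltyReport,
    compute_properties,
)

__all__ = [
    "write_smi",
    "read_smi",
    "write_library_csv",
    "read_library_csv",
    "write_poses_sdf",
    "read_poses_sdf",
    "read_site_yaml",
    "read_site_pdb",
    "write_cluster_csv",
    "write_novelty_csv",
    "write_campaign_json",
    "write_curves_csv",
    "read_curves_csv",
    "write_pk_csv",
    "read_pk_csv",
    "read_dose_outcome_csv",
    "nca_result_frame",
]


# ---------------------------------------------------------------- libraries

def write_smi(records: Iterable[LigandRecord], path: str | Path) -> None:
    """SMILES<TAB>id, one molecule per line."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles}\t{r.id}\n")


def read_smi(path: str | Path) -> list[tuple[str, str]]:
    """Return (smiles, id) pairs; a missing id falls back to the line number."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        parts = line.split()
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
        out.append((smiles, mol_id))
    return out


def write_library_csv(records: Iterable[LigandRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.id,
                "smiles": r.smiles,
                "score": r.score,
                "mw": r.mw,
                "clogp": r.clogp,
                "rank": r.rank,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_library_csv(path: str | Path) -> list[LigandRecord]:
    """Read id,smiles,score[,mw,clogp]; missing properties computed from structure."""
    df = pd.read_csv(path)
    for col in ("id", "smiles", "score"):
        if col not in df.columns:
            raise ValueError(f"library CSV missing required column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        mw = getattr(row, "mw", None)
        clogp = getattr(row, "clogp", None)
        if mw is None or clogp is None or pd.isna(mw) or pd.isna(clogp):
            mw_c, clogp_c = compute_properties(row.smiles)
            mw = mw_c if mw is None or pd.isna(mw) else mw
            clogp = clogp_c if clogp is None or pd.isna(clogp) else clogp
        rank = int(getattr(row, "rank", i + 1))
        records.append(
            LigandRecord(
                id=str(row.id),
                smiles=row.smiles,
                mw=float(mw),
                clogp=float(clogp),
                score=float(row.score),
                rank=rank,
            )
        )
    return records


# -------------------------------------------------------------------- poses

def write_poses_sdf(poses: Iterable[Pose], path: str | Path) -> None:
    """Write poses as SD records (atoms + 3-D coordinates, no bonds)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for pose in poses:
        mol = Chem.RWMol()
        for el in pose.elements:
            atom = Chem.Atom(el)
            atom.SetNoImplicit(True)
            mol.AddAtom(atom)
        conf = Chem.Conformer(pose.n_atoms)
        for i, xyz in enumerate(pose.coords):
            conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        mol.AddConformer(conf)
        mol.SetProp("_Name", pose.ligand_id)
        writer.write(mol)
    writer.close()


def read_poses_sdf(path: str | Path) -> list[Pose]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    poses = []
    for mol in supplier:
        if mol is None:
            raise ValueError(f"unreadable SD record in {path}")
        if mol.GetNumConformers() == 0:
            raise ValueError("SD record lacks coordinates")
        conf = mol.GetConformer()
        elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
        coords = np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
             for i in range(mol.GetNumAtoms())]
        )
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else "pose"
        poses.append(Pose(ligand_id=name, elements=elements, coords=coords))
    return poses


# ----------------------------------------------------------------- site probes

def read_site_yaml(path: str | Path) -> SiteDefinition:
    """Probe list: [{residue, atom, x, y, z, role?}, ...] or {probes: [...]}"""
    data = yaml.safe_load(Path(path).read_text())
    entries = data["probes"] if isinstance(data, dict) else data
    probes = tuple(
        SiteProbe(
            residue=str(e["residue"]),
            atom=str(e["atom"]),
            position=(float(e["x"]), float(e["y"]), float(e["z"])),
            role=e.get("role", "either"),
        )
        for e in entries
    )
    return SiteDefinition(probes=probes)


def read_site_pdb(
    path: str | Path, selections: Sequence[tuple[str, str]]
) -> SiteDefinition:
    """Extract named probe atoms from a PDB-format subset file.

    ``selections`` are (residue label, atom name) pairs where the residue
    label is one-letter code + sequence number, e.g. ("S383", "OG").
    """
    structure = gemmi.read_pdb(str(path))
    wanted = {(res.upper(), atom.upper()) for res, atom in selections}
    found: dict[tuple[str, str], SiteProbe] = {}
    for model in structure:
        for chain in model:
            for residue in chain:
                one = gemmi.find_tabulated_residue(residue.name)
                code = one.one_letter_code.upper() if one else "X"
                label = f"{code}{residue.seqid.num}"
                for atom in residue:
                    key = (label, atom.name.upper())
                    if key in wanted and key not in found:
                        found[key] = SiteProbe(
                            residue=label,
                            atom=atom.name,
                            position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        )
    missing = wanted - set(found)
    if missing:
        raise ValueError(f"probe atoms not found in PDB subset: {sorted(missing)}")
    return SiteDefinition(probes=tuple(found[k] for k in sorted(found)))


# ------------------------------------------------------------------- reports

def write_cluster_csv(clusters: Sequence[ClusterAssignment], path: str | Path) -> None:
    rows = [
        {
            "cluster": k,
            "representative_id": c.representative_id,
            "member_id": member,
            "n_members": len(c.member_ids),
        }
        for k, c in enumerate(clusters)
        for member in c.member_ids
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_novelty_csv(reports: Sequence[NoveltyReport], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "candidate_id": r.candidate_id,
                "max_tc": r.max_tc,
                "nearest_reference_id": r.nearest_reference_id,
                "kept": r.kept,
            }
            for r in reports
        ]
    ).to_csv(path, index=False)


def write_campaign_json(summary: CampaignSummary, path: str | Path) -> None:
    payload = {
        "n_input": summary.n_input,
        "n_fit": summary.n_fit,
        "mean_orientations": summary.mean_orientations,
        "mean_conformations": summary.mean_conformations,
        "mean_poses_per_molecule": summary.mean_poses_per_molecule,
        "poses_per_molecule_millions": summary.poses_per_molecule_millions,
        "total_complexes": summary.total_complexes,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# -------------------------------------------------------------------- curves

def write_curves_csv(curves: Sequence[DoseResponseCurve], path: str | Path) -> None:
    rows = []
    for curve in curves:
        for conc, resp in zip(curve.concentrations, curve.responses):
            rows.append(
                {
                    "compound_id": curve.compound_id,
                    "pathway": curve.pathway or "",
                    "concentration_M": conc,
                    "response": resp,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves_csv(path: str | Path) -> list[DoseResponseCurve]:
    df = pd.read_csv(path)
    curves = []
    pathway_col = "pathway" if "pathway" in df.columns else None
    keys = ["compound_id"] + ([pathway_col] if pathway_col else [])
    for key, group in df.groupby(keys, dropna=False, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        pathway = None
        if pathway_col:
            raw = key[1]
            pathway = None if pd.isna(raw) or raw == "" else str(raw)
        curves.append(
            DoseResponseCurve(
                compound_id=str(key[0]),
                concentrations=group["concentration_M"].to_numpy(),
                responses=group["response"].to_numpy(),
                pathway=pathway,
            )
        )
    return curves


# ------------------------------------------------------------------------ PK

def write_pk_csv(profile: ConcentrationTimeProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "compartment": profile.compartment,
            "time_min": profile.times,
            "concentration": profile.concentrations,
            "lloq": profile.lloq,
        }
    ).to_csv(path, index=False)


def read_pk_csv(path: str | Path) -> list[ConcentrationTimeProfile]:
    df = pd.read_csv(path)
    profiles = []
    for compartment, group in df.groupby("compartment", sort=False):
        profiles.append(
            ConcentrationTimeProfile(
                compartment=str(compartment),
                times=group["time_min"].to_numpy(),
                concentrations=group["concentration"].to_numpy(),
                lloq=float(group["lloq"].iloc[0]),
            )
        )
    return profiles


def read_dose_outcome_csv(path: str | Path) -> list[DoseOutcomeTable]:
    """CSV columns: compound, endpoint, dose_mg_per_kg, significant, highest_tested."""
    df = pd.read_csv(path)
    tables = []
    for (compound, endpoint), group in df.groupby(["compound", "endpoint"], sort=False):
        tables.append(
            DoseOutcomeTable(
                compound_id=str(compound),
                endpoint=str(endpoint),
                doses=tuple(float(d) for d in group["dose_mg_per_kg"]),
                significant=tuple(bool(int(s)) for s in group["significant"]),
                highest_tested_dose=float(group["highest_tested"].iloc[0]),
            )
        )
    return tables


def nca_result_frame(results: Sequence[NCAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "compartment": r.compartment,
                "cmax": r.cmax,
                "tmax_min": r.tmax,
                "lambda_z_per_min": r.lambda_z,
                "t_half_min": r.t_half,
                "auc_last": r.auc_last,
                "auc_inf": r.auc_inf,
                "n_lambda_points": r.n_lambda_points,
                "extrapolated_fraction": r.extrapolated_fraction,
            }
            for r in results
        ]
    )
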