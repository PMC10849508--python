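#!/usr/bin/env python
"""Stage 2 — pose geometry: symmetry-corrected RMSD and polar contacts.

Generates pose pairs with known optimal-assignment RMSD, contrasts the
symmetry-corrected value with the naive index-matched RMSD, and runs the
polar-contact filter against a three-probe site definition.  Writes an
RMSD comparison table and a contact report under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from dockpharm import io
from dockpharm.poses import (
    SiteDefinition,
    SiteProbe,
    naive_rmsd,
    polar_contact_filter,
    symmetry_rmsd,
)
from dockpharm.synth import gen_pose_pair

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    rows = []
    for k, target in enumerate((0.5, 1.0, 1.5, 2.0)):
        a, b, true_rmsd = gen_pose_pair(8, ["O", "N"], target, seed=args.seed + k)
        rows.append(
            {
                "target_rmsd_A": target,
                "true_rmsd_A": true_rmsd,
                "symmetry_rmsd_A": symmetry_rmsd(a, b),
                "naive_rmsd_A": naive_rmsd(a, b),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "rmsd_comparison.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print("naive RMSD overstates the deviation whenever equivalent atoms are swapped;")
    print("the optimal-assignment value recovers the constructed target exactly.")

    # polar-contact filter: serine and histidine probes placed within
    # hydrogen-bonding range of the pose's first polar atom, a threonine
    # probe far outside it — "any" passes, "all" would not
    pose, _, _ = gen_pose_pair(8, [], 0.0, seed=args.seed)
    o_xyz = pose.coords[pose.polar_indices()[0]]
    site = SiteDefinition(
        probes=(
            SiteProbe("S383", "OG", tuple(o_xyz + [2.8, 0.0, 0.0])),
            SiteProbe("H178", "NE2", tuple(o_xyz + [0.0, 3.3, 0.0])),
            SiteProbe("T201", "OG1", tuple(o_xyz + [0.0, 0.0, 12.0])),
        )
    )
    report = polar_contact_filter(pose, site, cutoff=3.5, require="any")
    io.write_poses_sdf([pose], RESULTS / "pose.sdf")
    pd.DataFrame(
        [{"probe": k, "min_distance_A": v} for k, v in report.distances.items()]
    ).to_csv(RESULTS / "contacts.csv", index=False)
    print(f"polar-contact filter ({report.rule}): pass={report.passed}")
    for label, dist in report.distances.items():
        print(f"  {label}: {dist:.2f} Å")


if __name__ == "__main__":
    main()
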