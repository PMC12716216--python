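"""Full pipeline on a miniature structural ensemble.

Writes a four-frame XYZ trajectory and two transition-charge tables,
loads them back through the standard readers, and evaluates the per-frame
coupling records — Coulomb term, polarizable-environment term, screening
factor, κ², center distance and the point-dipole coupling — exactly as
the `trespfret couple` command does.
"""

import tempfile
from pathlib import Path

from trespfret import couple_ensemble, load_charge_table, load_ensemble
from trespfret.coupling import records_to_frame

workdir = Path(tempfile.mkdtemp())

(workdir / "donor.txt").write_text(
    "# chromophore_id: Trp-like donor\n"
    "C 0.0 0.0 0.5 0.1\nC 0.0 0.0 -0.5 -0.1\n"
)
(workdir / "acceptor.txt").write_text(
    "# chromophore_id: ligand acceptor\n"
    "C 0.0 0.0 0.5 0.12\nC 0.0 0.0 -0.5 -0.12\n"
)
frames_txt = []
for i in range(4):
    ax = 20.0 + i  # the acceptor drifts 1 Å per 50 ps frame
    frames_txt += [
        "6", f"frame {i}",
        "C 0.0 0.0 0.5", "C 0.0 0.0 -0.5",
        f"C {ax} 0.0 0.5", f"C {ax} 0.0 -0.5",
        "O 10.0 3.0 0.0", "O 10.0 -3.0 0.0",
    ]
(workdir / "traj.xyz").write_text("\n".join(frames_txt) + "\n")

donor = load_charge_table(workdir / "donor.txt")
acceptor = load_charge_table(workdir / "acceptor.txt")
frames = load_ensemble(workdir / "traj.xyz", donor_indices=[0, 1],
                       acceptor_indices=[2, 3], stride_ps=50.0)
records = couple_ensemble(donor, acceptor, frames, cutoff=15.0)

df = records_to_frame(records)
cols = ["frame_time_ps", "r_angstrom", "v_coul_cm1", "v_total_cm1", "s", "kappa2"]
print(df[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nPer frame: the exact Coulomb coupling, the environment-screened "
    "total (s < 1 here:\nthe two polarizable oxygens between the "
    "chromophores attenuate the interaction),\nand the κ² orientation "
    "factor from the instantaneous transition dipoles."
)
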