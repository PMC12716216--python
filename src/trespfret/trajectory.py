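"""Structural ensembles: per-frame donor/acceptor/environment geometries.

Multi-frame coordinates are read with MDAnalysis (multi-frame XYZ or
multi-model PDB; the frame index is the model/record order).  Atom
selection for the two chromophores is by 0-based index lists, matching the
atom order of the corresponding transition-charge tables; everything else
is environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["GeometryFrame", "load_ensemble"]


@dataclass(frozen=True)
class GeometryFrame:
    """One time-stamped snapshot of the donor/acceptor/environment split."""

    time_ps: float
    donor_coords: np.ndarray  # (n_d, 3) Å
    acceptor_coords: np.ndarray  # (n_a, 3) Å
    env_coords: np.ndarray  # (n_e, 3) Å
    env_types: tuple[str, ...]
    replica_id: str = "r0"

    def __post_init__(self) -> None:
        for name in ("donor_coords", "acceptor_coords", "env_coords"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1, 3)
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "env_types", tuple(self.env_types))
        if len(self.env_types) != self.env_coords.shape[0]:
            raise ValueError("environment types and coordinates differ in length")


def load_ensemble(
    path: str | Path,
    donor_indices: Sequence[int],
    acceptor_indices: Sequence[int],
    stride_ps: float = 50.0,
    replica_id: str = "r0",
) -> list[GeometryFrame]:
    """Read a multi-frame XYZ or multi-model PDB file into GeometryFrames.

    ``donor_indices`` and ``acceptor_indices`` are 0-based atom indices in
    file order; they must be disjoint.  Atoms in neither list form the
    environment.  Frame times are assigned as frame_index·stride_ps.
    """
    import MDAnalysis as mda

    d_idx = np.asarray(donor_indices, dtype=int)
    a_idx = np.asarray(acceptor_indices, dtype=int)
    if np.intersect1d(d_idx, a_idx).size:
        raise ValueError("donor and acceptor atom selections overlap")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # guessed masses/elements are harmless here
        u = mda.Universe(str(path))
    n = len(u.atoms)
    for name, idx in (("donor", d_idx), ("acceptor", a_idx)):
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise IndexError(f"{name} indices out of range for {n} atoms")
    env_mask = np.ones(n, dtype=bool)
    env_mask[d_idx] = False
    env_mask[a_idx] = False
    env_idx = np.flatnonzero(env_mask)
    names = [getattr(a, "element", "") or a.name[:1] for a in u.atoms]
    env_types = tuple(names[i] for i in env_idx)
    frames = []
    for i, _ts in enumerate(u.trajectory):
        pos = u.atoms.positions.astype(float)
        frames.append(
            GeometryFrame(
                time_ps=i * stride_ps,
                donor_coords=pos[d_idx],
                acceptor_coords=pos[a_idx],
                env_coords=pos[env_idx],
                env_types=env_types,
                replica_id=replica_id,
            )
        )
    if not frames:
        raise ValueError(f"{path}: trajectory contains no frames")
    return frames
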