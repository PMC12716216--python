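"""End-to-end per-frame evaluation: charges → fields → dipoles → couplings.

This is the glue the command-line interface and examples use: given the
two transition-charge sets, a structural ensemble and a polarizability
assignment, it produces one CouplingRecord per frame with the Coulomb
term, the environment term from the induced-dipole solver, the screening
factor, κ², the center distance and the unscreened point-dipole coupling.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .chromophore import TransitionChargeSet, position_charges, transition_dipole
from .coupling import (
    FLAG_NEAR_ZERO_COULOMB,
    NEAR_ZERO_COULOMB,
    CouplingRecord,
    coulomb_coupling,
    kappa_squared,
    pda_coupling,
)
from .mmpol import (
    DEFAULT_CUTOFF,
    env_coupling,
    field_at_sites,
    select_environment,
    solve_induced_dipoles,
)
from .trajectory import GeometryFrame

__all__ = ["couple_frame", "couple_ensemble"]


def couple_frame(
    donor_cs: TransitionChargeSet,
    acceptor_cs: TransitionChargeSet,
    frame: GeometryFrame,
    *,
    cutoff: float = DEFAULT_CUTOFF,
    polarizabilities: dict[str, float] | None = None,
    thole_factor: float = 0.0,
    solver: str = "direct",
) -> CouplingRecord:
    """Evaluate all coupling quantities for one frame.

    Induced dipoles are driven by the acceptor's transition charges and
    contracted with the donor's field; with an empty environment the
    record reduces to the vacuum Coulomb result (s = 1).
    """
    donor = position_charges(donor_cs, frame.donor_coords)
    acceptor = position_charges(acceptor_cs, frame.acceptor_coords)
    v_coul = coulomb_coupling(donor, acceptor)
    sites = select_environment(
        frame.env_coords,
        frame.env_types,
        frame.donor_coords,
        frame.acceptor_coords,
        cutoff=cutoff,
        polarizabilities=polarizabilities,
        thole_factor=thole_factor,
    )
    if sites:
        e_a = field_at_sites(acceptor, sites)
        sol = solve_induced_dipoles(sites, e_a, method=solver)
        v_env = env_coupling(donor, sites, sol)
    else:
        v_env = 0.0
    mu_d = transition_dipole(donor)
    mu_a = transition_dipole(acceptor)
    rvec = acceptor.center - donor.center
    k2 = kappa_squared(mu_d.components, mu_a.components, rvec)
    v_pda = pda_coupling(mu_d, mu_a, donor.center, acceptor.center, screening=1.0)
    flags = set()
    if abs(v_coul) < NEAR_ZERO_COULOMB:
        flags.add(FLAG_NEAR_ZERO_COULOMB)
    return CouplingRecord(
        frame_time=frame.time_ps,
        replica_id=frame.replica_id,
        v_coul=v_coul,
        v_env=v_env,
        r=float(np.linalg.norm(rvec)),
        kappa2=k2,
        v_pda_unscreened=v_pda,
        flags=frozenset(flags),
    )


def couple_ensemble(
    donor_cs: TransitionChargeSet,
    acceptor_cs: TransitionChargeSet,
    frames: Sequence[GeometryFrame],
    **kwargs,
) -> list[CouplingRecord]:
    """Evaluate couplings over a whole ensemble (see ``couple_frame``)."""
    if len(frames) == 0:
        raise ValueError("empty ensemble")
    return [couple_frame(donor_cs, acceptor_cs, f, **kwargs) for f in frames]
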