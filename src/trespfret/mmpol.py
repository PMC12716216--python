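"""Polarizable (induced-dipole) environment and screening of the coupling.

Environment atoms within a cutoff of the chromophores carry isotropic
polarizabilities α and respond to the field of the acceptor's transition
charges with mutually coupled induced point dipoles,

    μₗ = αₗ ( Eₗ + Σ_{m≠l} T_lm μ_m ),

with T the dipole–dipole interaction tensor.  The environment-mediated
contribution to the donor–acceptor coupling is the contraction of those
dipoles with the donor's transition field,

    V_env = − Σₗ E_D(rₗ) · μₗ ,

which for a single site with no mutual coupling reduces to the closed form
−α (E_D · E_A).  The screening factor s = (V_Coul + V_env)/V_Coul can be
compared with the 1/n² factor Förster theory assumes.

All electrostatics here are in atomic units (bohr, e, Hartree).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .chromophore import PositionedCharges
from .coupling import (
    FLAG_NEAR_ZERO_COULOMB,
    NEAR_ZERO_COULOMB,
    CouplingRecord,
    StericClashError,
    binned_profile,
)
from .units import ANG3_TO_BOHR3, ANGSTROM_TO_BOHR

__all__ = [
    "PolarizableSite",
    "InducedDipoleSolution",
    "select_environment",
    "field_at_sites",
    "interaction_tensor",
    "solve_induced_dipoles",
    "env_coupling",
    "screening_factor",
    "screening_profile",
    "load_polarizability_table",
    "DEFAULT_POLARIZABILITIES",
]

MIN_SITE_DISTANCE = 0.1  # Å, charge–site clash threshold
DEFAULT_CUTOFF = 15.0  # Å, any-atom distance from either chromophore

# Element-based isotropic polarizabilities in Å³ (Thole/van Duijnen-style
# values), used when no explicit per-type table is supplied.  Real
# applications should provide force-field-specific assignments.
DEFAULT_POLARIZABILITIES = {
    "H": 0.514,
    "C": 1.405,
    "N": 1.105,
    "O": 0.862,
    "S": 2.926,
    "P": 1.743,
}


@dataclass(frozen=True)
class PolarizableSite:
    """One environment atom carrying an isotropic polarizability.

    ``alpha`` is in bohr³; ``thole_factor`` enables linear Thole damping of
    short-range interactions (0 disables damping, the default).
    """

    coordinate: np.ndarray  # (3,) Å
    alpha: float
    thole_factor: float = 0.0
    source_atom_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinate, dtype=float).ravel()
        if c.shape != (3,):
            raise ValueError("site coordinate must be a 3-vector")
        object.__setattr__(self, "coordinate", c)
        if self.alpha < 0:
            raise ValueError(f"polarizability must be ≥ 0, got {self.alpha}")


@dataclass(frozen=True)
class InducedDipoleSolution:
    """Converged induced dipoles (e·bohr) for a set of sites."""

    dipoles: np.ndarray  # (n, 3)
    residual_norm: float
    iterations: int
    method: str  # "direct" | "iterative"

    def __post_init__(self) -> None:
        d = np.asarray(self.dipoles, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "dipoles", d)


def load_polarizability_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (atom-type, α) table; returns α in bohr³.

    A comment line ``# units: angstrom^3`` (default) or ``# units: bohr^3``
    fixes the unit of the α column.
    """
    path = Path(path)
    units = "angstrom^3"
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip().lower()
                if body.startswith("units"):
                    units = body.split(":", 1)[1].strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'atom-type alpha'")
            table[parts[0]] = float(parts[1])
    if units in ("angstrom^3", "a^3", "ang^3"):
        table = {k: v * ANG3_TO_BOHR3 for k, v in table.items()}
    elif units not in ("bohr^3", "au"):
        raise ValueError(f"{path}: unknown polarizability units '{units}'")
    return table


def select_environment(
    env_coords: np.ndarray,
    env_types: Sequence[str],
    donor_coords: np.ndarray,
    acceptor_coords: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    polarizabilities: dict[str, float] | None = None,
    thole_factor: float = 0.0,
) -> list[PolarizableSite]:
    """Select environment atoms within ``cutoff`` Å of either chromophore.

    Inclusion is atom-based: an environment atom is kept when its distance
    to ANY donor or acceptor atom is ≤ cutoff (closed interval).  The
    chromophore atoms themselves are assumed already excluded from
    ``env_coords``.  Polarizabilities are attached from the ``polarizabilities``
    map (bohr³ keyed by atom type); element-based defaults are used when no
    map is given.

    Raises
    ------
    KeyError
        Listing the atom types that have no polarizability assignment.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    env_coords = np.asarray(env_coords, dtype=float).reshape(-1, 3)
    if env_coords.shape[0] == 0:
        return []
    if polarizabilities is None:
        polarizabilities = {
            el: a * ANG3_TO_BOHR3 for el, a in DEFAULT_POLARIZABILITIES.items()
        }
    missing = sorted({t for t in env_types if t not in polarizabilities})
    if missing:
        raise KeyError(
            f"no polarizability assignment for atom types: {', '.join(missing)}"
        )
    chrom = np.vstack(
        [
            np.asarray(donor_coords, float).reshape(-1, 3),
            np.asarray(acceptor_coords, float).reshape(-1, 3),
        ]
    )
    dmin = cdist(env_coords, chrom).min(axis=1)
    sites = []
    for i in np.flatnonzero(dmin <= cutoff):
        t = env_types[i]
        sites.append(
            PolarizableSite(
                coordinate=env_coords[i],
                alpha=polarizabilities[t],
                thole_factor=thole_factor,
                source_atom_id=f"{t}:{i}",
            )
        )
    return sites


def _site_coords_bohr(sites: Sequence[PolarizableSite]) -> np.ndarray:
    return np.array([s.coordinate for s in sites], float).reshape(-1, 3) * ANGSTROM_TO_BOHR


def field_at_sites(
    charges: PositionedCharges, sites: Sequence[PolarizableSite]
) -> np.ndarray:
    """Electric field of transition charges at each site, in atomic units.

    Eₗ = Σⱼ qⱼ (rₗ − rⱼ)/|rₗ − rⱼ|³.  When a site's ``thole_factor`` is
    positive, the charge–dipole interaction is damped with the linear Thole
    scheme (scaled distance u = r / (a·αₗ^{1/3}); field factor 4u³ − 3u⁴
    inside the damping radius).
    """
    sites = list(sites)
    if not sites:
        return np.zeros((0, 3))
    rl = _site_coords_bohr(sites)
    rj = charges.coordinates * ANGSTROM_TO_BOHR
    q = charges.charges
    dvec = rl[:, None, :] - rj[None, :, :]  # (L, J, 3)
    dist = np.linalg.norm(dvec, axis=2)
    if dist.size and dist.min() < MIN_SITE_DISTANCE * ANGSTROM_TO_BOHR:
        raise StericClashError("polarizable site within 0.1 Å of a transition charge")
    damp = np.ones_like(dist)
    for l, site in enumerate(sites):
        if site.thole_factor > 0 and site.alpha > 0:
            r_damp = site.thole_factor * site.alpha ** (1.0 / 3.0)
            u = dist[l] / r_damp
            inside = u < 1.0
            damp[l, inside] = 4.0 * u[inside] ** 3 - 3.0 * u[inside] ** 4
    w = q[None, :] * damp / dist**3
    return (w[:, :, None] * dvec).sum(axis=1)


def interaction_tensor(sites: Sequence[PolarizableSite]) -> np.ndarray:
    """Dense 3N×3N dipole–dipole interaction tensor T (atomic units).

    Block (l, m) is (3 r̂r̂ᵀ − I)/r³ for l ≠ m, zero on the diagonal.
    With positive Thole factors the short-range blocks are damped with the
    linear scheme: scaled distance u = r / (a·(αₗα_m)^{1/6}), screening
    functions λ₃ = 4u³ − 3u⁴ and λ₅ = u⁴ inside the damping radius.
    """
    sites = list(sites)
    n = len(sites)
    T = np.zeros((3 * n, 3 * n))
    if n < 2:
        return T
    coords = _site_coords_bohr(sites)
    for l in range(n):
        for m in range(l + 1, n):
            d = coords[m] - coords[l]
            r = np.linalg.norm(d)
            if r < MIN_SITE_DISTANCE * ANGSTROM_TO_BOHR:
                raise StericClashError("coincident polarizable sites")
            rh = d / r
            lam3 = lam5 = 1.0
            a = min(sites[l].thole_factor, sites[m].thole_factor)
            if a > 0 and sites[l].alpha > 0 and sites[m].alpha > 0:
                r_damp = a * (sites[l].alpha * sites[m].alpha) ** (1.0 / 6.0)
                u = r / r_damp
                if u < 1.0:
                    lam3 = 4.0 * u**3 - 3.0 * u**4
                    lam5 = u**4
            block = (3.0 * lam5 * np.outer(rh, rh) - lam3 * np.eye(3)) / r**3
            T[3 * l : 3 * l + 3, 3 * m : 3 * m + 3] = block
            T[3 * m : 3 * m + 3, 3 * l : 3 * l + 3] = block
    return T


def solve_induced_dipoles(
    sites: Sequence[PolarizableSite],
    field: np.ndarray,
    *,
    method: str = "direct",
    tolerance: float = 1e-8,
    max_iter: int = 500,
    mixing: float = 0.5,
) -> InducedDipoleSolution:
    """Solve μₗ = αₗ(Eₗ + Σ_{m≠l} T_lm μ_m) for all sites.

    ``method="direct"`` assembles the 3N×3N system (I − diag(α)T) μ = αE
    and solves it densely; ``method="iterative"`` runs Jacobi fixed-point
    iteration with linear mixing until the largest component change drops
    below ``tolerance``.

    Raises
    ------
    RuntimeError
        On non-convergence (with the residual history) or a singular
        direct system.
    """
    sites = list(sites)
    n = len(sites)
    field = np.asarray(field, dtype=float).reshape(-1, 3)
    if field.shape[0] != n:
        raise ValueError(f"{field.shape[0]} field vectors for {n} sites")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if n == 0:
        return InducedDipoleSolution(np.zeros((0, 3)), 0.0, 0, method)
    alpha = np.repeat([s.alpha for s in sites], 3)
    E = field.ravel()
    T = interaction_tensor(sites)
    if method == "direct":
        A = np.eye(3 * n) - alpha[:, None] * T
        try:
            mu = np.linalg.solve(A, alpha * E)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular induced-dipole system: {exc}") from None
        residual = float(np.abs(mu - alpha * (E + T @ mu)).max())
        return InducedDipoleSolution(mu.reshape(n, 3), residual, 1, "direct")
    if method == "iterative":
        mu = alpha * E
        history = []
        for it in range(1, max_iter + 1):
            mu_new = alpha * (E + T @ mu)
            change = float(np.abs(mu_new - mu).max())
            history.append(change)
            mu = (1.0 - mixing) * mu + mixing * mu_new
            if change < tolerance:
                return InducedDipoleSolution(mu.reshape(n, 3), change, it, "iterative")
        raise RuntimeError(
            f"induced dipoles not converged in {max_iter} iterations; "
            f"last residuals: {['%.2e' % h for h in history[-5:]]}"
        )
    raise ValueError(f"unknown method '{method}' (use 'direct' or 'iterative')")


def env_coupling(
    donor: PositionedCharges,
    sites: Sequence[PolarizableSite],
    solution: InducedDipoleSolution,
) -> float:
    """Environment-mediated coupling V_env = −Σₗ E_D(rₗ)·μₗ, in Hartree.

    ``solution`` holds dipoles induced by the acceptor's transition
    charges; contracting them with the donor's transition field gives the
    polarization pathway between the two transition densities.  By linear
    response the opposite convention (induce with the donor, contract with
    the acceptor) yields the same value.
    """
    sites = list(sites)
    if not sites:
        return 0.0
    e_d = field_at_sites(donor, sites)
    return float(-(e_d * solution.dipoles).sum())


def screening_factor(v_coul: float, v_env: float) -> float:
    """Screening factor s = (V_Coul + V_env)/V_Coul.

    Raises
    ------
    ValueError
        When |V_Coul| is below the near-zero threshold; such frames carry
        the near-zero-coulomb flag and are excluded from statistics.
    """
    if abs(v_coul) < NEAR_ZERO_COULOMB:
        raise ValueError(
            f"|V_Coul| = {abs(v_coul):.2e} Hartree below the near-zero "
            "threshold; screening undefined for this frame"
        )
    return (v_coul + v_env) / v_coul


def screening_profile(
    records: Sequence[CouplingRecord], bin_width: float = 1.0
) -> pd.DataFrame:
    """Distance-binned statistics of the screening factor s.

    Flagged frames are excluded and counted in ``attrs["n_flagged"]``.
    """
    if len(records) == 0:
        raise ValueError("no coupling records provided")
    clean = [rec for rec in records if FLAG_NEAR_ZERO_COULOMB not in rec.flags]
    n_flagged = len(records) - len(clean)
    if not clean:
        raise ValueError("all records flagged near-zero-coulomb; no screening defined")
    r = np.array([rec.r for rec in clean])
    s = np.array([rec.s for rec in clean])
    out = binned_profile(r, s, bin_width)
    out.attrs["n_flagged"] = n_flagged
    return out
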