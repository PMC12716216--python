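"""Donor–acceptor electronic couplings and orientation-factor statistics.

Two levels of theory are provided for the Coulomb part of the coupling:

* the transition-charge (TrESP) sum  V_Coul = Σᵢⱼ q_D,i q_A,j / |rᵢ − rⱼ|,
  evaluated in atomic units over all donor/acceptor atom pairs, and
* the point-dipole approximation (PDA)  V_PDA = s κ |μ_D||μ_A| / R³,
  where κ = μ̂_D·μ̂_A − 3(μ̂_D·r̂)(μ̂_A·r̂) is the orientation factor and s a
  dielectric screening factor (Förster theory takes s = 1/n²).

The ratio V_PDA/V_TrESP as a function of the center-to-center distance R
quantifies where the dipole approximation breaks down; both quantities are
unscreened in that ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .chromophore import PositionedCharges, TransitionDipoleVector, transition_dipole
from .units import ANGSTROM_TO_BOHR, HARTREE_TO_CM

__all__ = [
    "CouplingRecord",
    "StericClashError",
    "coulomb_coupling",
    "kappa",
    "kappa_squared",
    "pda_coupling",
    "pda_ratio_profile",
    "binned_profile",
    "records_to_frame",
]

MIN_PAIR_DISTANCE = 0.1  # Å; closer contacts are treated as steric clashes
NEAR_ZERO_COULOMB = 1e-9  # Hartree; below this, ratios to V_coul are undefined

FLAG_NEAR_ZERO_COULOMB = "near-zero-coulomb"


class StericClashError(ValueError):
    """Raised when two point charges sit closer than the clash threshold."""


@dataclass(frozen=True)
class CouplingRecord:
    """All coupling-related quantities for one trajectory frame.

    Energies are in Hartree.  ``v_total = v_coul + v_env`` by construction;
    ``s = v_total / v_coul`` unless the frame is flagged near-zero-coulomb,
    in which case ``s`` is NaN and the frame is excluded from screening and
    ratio statistics (but kept in raw output).
    """

    frame_time: float  # ps
    replica_id: str
    v_coul: float
    v_env: float
    r: float  # Å, center-to-center
    kappa2: float
    v_pda_unscreened: float
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"center-to-center distance must be positive, got {self.r}")
        if not 0.0 <= self.kappa2 <= 4.0 + 1e-12:
            raise ValueError(f"kappa² out of [0, 4]: {self.kappa2}")

    @property
    def v_total(self) -> float:
        return self.v_coul + self.v_env

    @property
    def s(self) -> float:
        """Screening factor (v_coul + v_env)/v_coul; NaN when flagged."""
        if FLAG_NEAR_ZERO_COULOMB in self.flags:
            return float("nan")
        return self.v_total / self.v_coul

    @property
    def pda_ratio(self) -> float:
        """Unscreened V_PDA / V_TrESP; NaN when flagged."""
        if FLAG_NEAR_ZERO_COULOMB in self.flags:
            return float("nan")
        return self.v_pda_unscreened / self.v_coul


def coulomb_coupling(donor: PositionedCharges, acceptor: PositionedCharges) -> float:
    """TrESP Coulomb coupling Σᵢⱼ q_D,i q_A,j / |rᵢ − rⱼ|, in Hartree.

    Coordinates (Å) are converted to bohr so the bare Coulomb sum over
    elementary charges is directly in Hartree.

    Raises
    ------
    StericClashError
        If any donor–acceptor atom pair is closer than 0.1 Å; such frames
        are unphysical and should be excluded upstream.
    """
    d = cdist(donor.coordinates, acceptor.coordinates)
    dmin = d.min() if d.size else np.inf
    if dmin < MIN_PAIR_DISTANCE:
        raise StericClashError(
            f"donor/acceptor atoms within {dmin:.3f} Å (< {MIN_PAIR_DISTANCE} Å)"
        )
    qq = np.outer(donor.charges, acceptor.charges)
    return float((qq / (d * ANGSTROM_TO_BOHR)).sum())


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    n = np.linalg.norm(v)
    if n < 1e-8:
        raise ValueError(f"{name} has near-zero norm ({n:.2e}); direction undefined")
    return v / n


def kappa(mu_d_hat: np.ndarray, mu_a_hat: np.ndarray, r_hat: np.ndarray) -> float:
    """Signed orientation factor κ = μ̂_D·μ̂_A − 3(μ̂_D·r̂)(μ̂_A·r̂).

    Inputs are renormalized internally; a vector with norm below 1e-8 is an
    error.  κ ranges over [−2, 2]: collinear head-to-tail dipoles give −2,
    parallel dipoles perpendicular to the separation axis give ±1.
    """
    d = _unit(mu_d_hat, "donor dipole")
    a = _unit(mu_a_hat, "acceptor dipole")
    r = _unit(r_hat, "separation axis")
    return float(d @ a - 3.0 * (d @ r) * (a @ r))


def kappa_squared(mu_d_hat: np.ndarray, mu_a_hat: np.ndarray, r_hat: np.ndarray) -> float:
    """Orientation factor κ² ∈ [0, 4]; isotropic average 2/3."""
    return kappa(mu_d_hat, mu_a_hat, r_hat) ** 2


def pda_coupling(
    mu_d: TransitionDipoleVector,
    mu_a: TransitionDipoleVector,
    center_d: np.ndarray,
    center_a: np.ndarray,
    screening: float = 1.0,
) -> float:
    """Point-dipole coupling s κ |μ_D||μ_A| / R³, in Hartree.

    Centers are in Å (converted to bohr), dipoles in e·bohr.  With
    ``screening=1`` this is the unscreened PDA coupling used in ratio
    analyses; Förster theory corresponds to ``screening = 1/n²``.
    """
    rvec = np.asarray(center_a, float) - np.asarray(center_d, float)
    r_ang = float(np.linalg.norm(rvec))
    if r_ang < 1e-9:
        raise ValueError("donor and acceptor centers coincide")
    k = kappa(mu_d.components, mu_a.components, rvec)
    r_bohr = r_ang * ANGSTROM_TO_BOHR
    return screening * k * mu_d.magnitude * mu_a.magnitude / r_bohr**3


def binned_profile(
    r: np.ndarray, values: np.ndarray, bin_width: float = 1.0
) -> pd.DataFrame:
    """Bin ``values`` over distance ``r`` (Å) into fixed-width bins.

    Returns a DataFrame with columns ``bin_center, mean, sd, n``; empty
    bins are omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    r = np.asarray(r, float)
    values = np.asarray(values, float)
    if r.size == 0:
        raise ValueError("no records to bin")
    idx = np.floor(r / bin_width).astype(int)
    df = pd.DataFrame({"idx": idx, "value": values})
    g = df.groupby("idx")["value"]
    out = pd.DataFrame(
        {
            "bin_center": (g.mean().index + 0.5) * bin_width,
            "mean": g.mean().to_numpy(),
            "sd": g.std(ddof=1).fillna(0.0).to_numpy(),
            "n": g.size().to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def pda_ratio_profile(
    records: Sequence[CouplingRecord], bin_width: float = 1.0
) -> pd.DataFrame:
    """Distance-binned statistics of the PDA/TrESP coupling ratio.

    Frames flagged near-zero-coulomb (the ratio's denominator vanishes)
    are excluded from the statistics; their count is reported in the
    DataFrame's ``attrs["n_flagged"]``.
    """
    if len(records) == 0:
        raise ValueError("no coupling records provided")
    clean = [rec for rec in records if FLAG_NEAR_ZERO_COULOMB not in rec.flags]
    n_flagged = len(records) - len(clean)
    if not clean:
        raise ValueError("all records flagged near-zero-coulomb; no ratio defined")
    r = np.array([rec.r for rec in clean])
    ratio = np.array([rec.pda_ratio for rec in clean])
    out = binned_profile(r, ratio, bin_width)
    out.attrs["n_flagged"] = n_flagged
    return out


def records_to_frame(records: Iterable[CouplingRecord]) -> pd.DataFrame:
    """Flatten coupling records into a DataFrame (energies also in cm⁻¹)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "frame_time_ps": rec.frame_time,
                "replica_id": rec.replica_id,
                "v_coul_hartree": rec.v_coul,
                "v_env_hartree": rec.v_env,
                "v_total_hartree": rec.v_total,
                "v_coul_cm1": rec.v_coul * HARTREE_TO_CM,
                "v_total_cm1": rec.v_total * HARTREE_TO_CM,
                "s": rec.s,
                "r_angstrom": rec.r,
                "kappa2": rec.kappa2,
                "v_pda_unscreened_hartree": rec.v_pda_unscreened,
                "pda_ratio": rec.pda_ratio,
                "flags": ";".join(sorted(rec.flags)),
            }
        )
    return pd.DataFrame(rows)


def make_record(
    donor: PositionedCharges,
    acceptor: PositionedCharges,
    *,
    v_env: float = 0.0,
    frame_time: float = 0.0,
    replica_id: str = "r0",
) -> CouplingRecord:
    """Assemble a CouplingRecord from positioned charge sets.

    Computes the TrESP Coulomb coupling, per-frame κ² from the
    instantaneous transition dipoles and center axis, and the unscreened
    PDA coupling.  ``v_env`` is supplied by the polarizable-environment
    solver (0 for vacuum).
    """
    v_coul = coulomb_coupling(donor, acceptor)
    mu_d = transition_dipole(donor)
    mu_a = transition_dipole(acceptor)
    rvec = acceptor.center - donor.center
    r = float(np.linalg.norm(rvec))
    k2 = kappa_squared(mu_d.components, mu_a.components, rvec)
    v_pda = pda_coupling(mu_d, mu_a, donor.center, acceptor.center, screening=1.0)
    flags = set()
    if abs(v_coul) < NEAR_ZERO_COULOMB:
        flags.add(FLAG_NEAR_ZERO_COULOMB)
    return CouplingRecord(
        frame_time=frame_time,
        replica_id=replica_id,
        v_coul=v_coul,
        v_env=v_env,
        r=r,
        kappa2=k2,
        v_pda_unscreened=v_pda,
        flags=frozenset(flags),
    )
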