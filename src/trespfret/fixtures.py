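"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed (identical
inputs give bit-identical outputs) and ships the analytic quantities the
fixture encodes alongside the data, so downstream code can be tested
without recomputing the truth with the code under test.  The fixtures
emulate the study conditions of a tryptophan/ligand FRET experiment:
coupling trajectories sampled every 50 ps, titrations at a handful of
micromolar ligand concentrations, and environments of polarizable atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chromophore import PositionedCharges, TransitionChargeSet
from .mmpol import PolarizableSite
from .observables import PhotophysicsParams
from .titration import TitrationSeries
from .units import ANGSTROM_TO_BOHR

__all__ = [
    "FixtureSpec",
    "make_dipole_pair",
    "make_orientation_samples",
    "make_two_timescale_trajectory",
    "make_titration",
    "make_polarizable_shell",
    "make_charge_set",
]

DEFAULT_STRIDE_PS = 50.0  # coupling sampling stride emulated by trajectories


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic fixture.

    ``kind`` selects the generator; ``parameters`` are its keyword
    arguments.  ``build()`` dispatches and returns whatever the generator
    returns (data plus ground truth).
    """

    seed: int
    kind: str
    parameters: dict = field(default_factory=dict)

    _GENERATORS = {
        "dipole_pair": "make_dipole_pair",
        "orientation_sweep": "make_orientation_samples",
        "two_timescale_trajectory": "make_two_timescale_trajectory",
        "titration": "make_titration",
        "polarizable_shell": "make_polarizable_shell",
    }

    def build(self):
        if self.kind not in self._GENERATORS:
            raise ValueError(
                f"unknown fixture kind '{self.kind}'; "
                f"choose from {sorted(self._GENERATORS)}"
            )
        fn = globals()[self._GENERATORS[self.kind]]
        kwargs = dict(self.parameters)
        if self.kind != "dipole_pair":  # deterministic generator, no seed arg
            kwargs.setdefault("seed", self.seed)
        return fn(**kwargs)


def make_dipole_pair(
    mu_mag: float,
    sep: float,
    r: float,
    d_hat: Sequence[float] = (0.0, 0.0, 1.0),
    a_hat: Sequence[float] = (0.0, 0.0, 1.0),
    axis: Sequence[float] = (0.0, 0.0, 1.0),
) -> dict:
    """Two ±q charge pairs emulating point dipoles at finite separation.

    Each chromophore is a pair of charges ±q at distance ``sep`` (Å) along
    its dipole direction, with q chosen so the dipole magnitude is
    ``mu_mag`` (e·bohr); centers are ``r`` Å apart along ``axis``.  The
    ground truth holds the exact 4-term Coulomb sum and the exact
    point-dipole coupling, evaluated here by direct arithmetic.
    """
    if r <= sep:
        raise ValueError(f"center distance r={r} Å must exceed the internal "
                         f"separation sep={sep} Å")
    d_hat = np.asarray(d_hat, float) / np.linalg.norm(d_hat)
    a_hat = np.asarray(a_hat, float) / np.linalg.norm(a_hat)
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    q = mu_mag / (sep * ANGSTROM_TO_BOHR)  # e, so that q·sep = mu_mag
    c_d = np.zeros(3)
    c_a = r * axis
    donor = PositionedCharges(
        coordinates=np.array([c_d + 0.5 * sep * d_hat, c_d - 0.5 * sep * d_hat]),
        charges=np.array([q, -q]),
    )
    acceptor = PositionedCharges(
        coordinates=np.array([c_a + 0.5 * sep * a_hat, c_a - 0.5 * sep * a_hat]),
        charges=np.array([q, -q]),
    )
    # exact 4-term Coulomb sum, written out independently of the engine
    v_coul = 0.0
    for ri, qi in zip(donor.coordinates, donor.charges):
        for rj, qj in zip(acceptor.coordinates, acceptor.charges):
            v_coul += qi * qj / (np.linalg.norm(ri - rj) * ANGSTROM_TO_BOHR)
    k = float(d_hat @ a_hat - 3.0 * (d_hat @ axis) * (a_hat @ axis))
    v_pda = k * mu_mag**2 / (r * ANGSTROM_TO_BOHR) ** 3
    return {
        "donor": donor,
        "acceptor": acceptor,
        "ground_truth": {
            "v_coul": v_coul,
            "v_pda": v_pda,
            "kappa": k,
            "kappa2": k * k,
            "mu_mag": mu_mag,
            "r": r,
        },
    }


def make_orientation_samples(count: int, seed: int = 0) -> np.ndarray:
    """Isotropic (μ̂_D, μ̂_A, r̂) triples: shape (count, 3, 3), unit rows.

    Directions are independent and uniform on the sphere (normalized
    Gaussian vectors); the κ² sample mean converges to the isotropic
    limit 2/3.
    """
    if count <= 0:
        raise ValueError("count must be positive")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(count, 3, 3))
    return v / np.linalg.norm(v, axis=2, keepdims=True)


def make_two_timescale_trajectory(
    slow_couplings: Sequence[float],
    windows_per_state: Sequence[int],
    params: PhotophysicsParams,
    frames_per_window: int = 20,
    fast_sigma: float = 0.0,
    stride_ps: float = DEFAULT_STRIDE_PS,
    seed: int = 0,
) -> dict:
    """Coupling time series with slow states plus fast Gaussian noise.

    The slow component is piecewise constant: state ``i`` (coupling value
    ``slow_couplings[i]``, Hartree) persists for ``windows_per_state[i]``
    windows of ``frames_per_window`` frames each, so slow blocks align
    with the averaging windows downstream.  Zero-mean Gaussian noise of
    standard deviation ``fast_sigma`` (Hartree) is added per frame.

    The ground-truth efficiency is analytic: noise on the coupling adds
    its variance to the fast-averaged squared coupling, ⟨V²⟩ = V_s² + σ²,
    so state ``s`` contributes E_s = τ⟨k_s⟩/(1 + τ⟨k_s⟩) with weight
    proportional to its window count.
    """
    slow = np.asarray(slow_couplings, float)
    wins = np.asarray(windows_per_state, int)
    if slow.size == 0:
        raise ValueError("need at least one slow state")
    if slow.size != wins.size or np.any(wins <= 0):
        raise ValueError("windows_per_state must be positive, one per state")
    if fast_sigma < 0:
        raise ValueError("fast_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    series = np.repeat(slow, wins * frames_per_window)
    if fast_sigma > 0:
        series = series + rng.normal(0.0, fast_sigma, size=series.size)
    from .observables import instantaneous_rate  # deferred to avoid cycle

    c = instantaneous_rate(1.0, params)  # rate per unit V², ns⁻¹/Hartree²
    k_states = c * (slow**2 + fast_sigma**2)
    e_states = params.tau_d * k_states / (1.0 + params.tau_d * k_states)
    e_truth = float(np.sum(wins * e_states) / wins.sum())
    return {
        "series": series,
        "stride_ps": stride_ps,
        "frames_per_window": frames_per_window,
        "fast_window_ns": frames_per_window * stride_ps / 1000.0,
        "ground_truth": {
            "efficiency": e_truth,
            "state_efficiencies": e_states,
            "state_rates": k_states,
        },
    }


def make_titration(
    kd_um: float,
    n_hill: float,
    e_true: float,
    i_d: float = 1000.0,
    concs_um: Sequence[float] = (10.0, 50.0, 100.0),
    noise_sigma: float = 0.0,
    abs_ex_per_um: float = 0.0,
    abs_em_per_um: float = 0.0,
    ligand_id: str = "synthetic",
    protein_conc: float = 5.0,
    seed: int = 0,
) -> dict:
    """Synthetic fluorescence titration with known binding ground truth.

    Intensities follow I_DA([L]) = I_D·(1 − e_true·f([L])) with the Hill
    isotherm f = [L]ⁿ/(K_dⁿ + [L]ⁿ); with ``e_true = 1`` this is exactly
    the double-log binding law the fit assumes.  Absorbances grow linearly
    with [L] and the stored intensities are attenuated by
    10^−((Abs_ex+Abs_em)/2), so the inner-filter correction is exercised
    end-to-end.  ``noise_sigma`` applies multiplicative log-normal noise
    (σ on the log scale) to the intensities.
    """
    if not 0 < e_true <= 1:
        raise ValueError("e_true must lie in (0, 1]")
    if kd_um <= 0 or n_hill <= 0 or i_d <= 0:
        raise ValueError("kd_um, n_hill and i_d must be positive")
    concs = np.asarray(concs_um, float)
    rng = np.random.default_rng(seed)
    f = concs**n_hill / (kd_um**n_hill + concs**n_hill)
    i_true = i_d * (1.0 - e_true * f)
    abs_ex = abs_ex_per_um * concs
    abs_em = abs_em_per_um * concs
    i_meas = i_true * 10.0 ** (-(abs_ex + abs_em) / 2.0)
    if noise_sigma > 0:
        i_meas = i_meas * np.exp(rng.normal(0.0, noise_sigma, size=i_meas.size))
    series = TitrationSeries(
        ligand_id=ligand_id,
        protein_conc=protein_conc,
        ligand_concs=concs,
        i_d=i_d,
        i_da=i_meas,
        abs_ex=abs_ex,
        abs_em=abs_em,
    )
    return {
        "series": series,
        "ground_truth": {
            "kd_um": kd_um,
            "n_hill": n_hill,
            "e_true": e_true,
            "fraction_bound": f,
            "i_da_true": i_true,
        },
    }


def make_polarizable_shell(
    n_sites: int,
    radius: float,
    alpha: float,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    thole_factor: float = 0.0,
    seed: int = 0,
) -> list[PolarizableSite]:
    """Polarizable sites scattered uniformly on a sphere (radius in Å).

    Typically centered on the donor–acceptor midpoint to emulate an
    attenuating environment; α is in bohr³ and shared by all sites.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    if n_sites == 0:
        return []
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_sites, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    center = np.asarray(center, float)
    return [
        PolarizableSite(
            coordinate=center + radius * v[i],
            alpha=alpha,
            thole_factor=thole_factor,
            source_atom_id=f"shell:{i}",
        )
        for i in range(n_sites)
    ]


def make_random_sites(
    n_sites: int,
    box: float = 20.0,
    min_dist: float = 2.5,
    alpha_range: tuple[float, float] = (0.5, 3.0),
    thole_factor: float = 0.0,
    seed: int = 0,
) -> list[PolarizableSite]:
    """Random polarizable sites with a minimum pairwise separation.

    Rejection-sampled positions in a cube of side ``box`` Å keep every
    pair at least ``min_dist`` Å apart (overlapping polarizable atoms are
    unphysical and destabilize the mutual-induction equations); α values
    are uniform in ``alpha_range`` (bohr³).
    """
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    attempts = 0
    while len(coords) < n_sites:
        c = rng.uniform(-box / 2, box / 2, size=3)
        if all(np.linalg.norm(c - p) >= min_dist for p in coords):
            coords.append(c)
        attempts += 1
        if attempts > 1000 * max(1, n_sites):
            raise RuntimeError(
                f"could not place {n_sites} sites with min_dist={min_dist} Å "
                f"in a {box} Å box"
            )
    alphas = rng.uniform(*alpha_range, size=n_sites)
    return [
        PolarizableSite(
            coordinate=coords[i],
            alpha=float(alphas[i]),
            thole_factor=thole_factor,
            source_atom_id=f"rand:{i}",
        )
        for i in range(n_sites)
    ]


def make_charge_set(
    n_atoms: int = 16,
    extent: float = 3.0,
    seed: int = 0,
    chromophore_id: str = "synthetic",
    state_label: str = "pi-pi*",
) -> TransitionChargeSet:
    """Random neutral transition-charge set on a compact random geometry.

    Charges are drawn and then shifted to exact neutrality; useful for
    round-trip and invariance tests of the charge-table machinery.
    """
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-extent, extent, size=(n_atoms, 3))
    q = rng.uniform(-0.2, 0.2, size=n_atoms)
    q -= q.mean()  # exact neutrality
    elements = tuple(rng.choice(["C", "N", "O", "H"], size=n_atoms))
    return TransitionChargeSet(
        chromophore_id=chromophore_id,
        state_label=state_label,
        elements=elements,
        template_coords=coords,
        charges=q,
    )
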