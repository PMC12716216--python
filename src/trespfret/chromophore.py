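"""Transition-charge representations of chromophores.

A chromophore's electronic transition is represented by atom-centered
transition charges (TrESP charges) fitted externally to reproduce the
electrostatic potential of a quantum-mechanical transition density.  This
module loads and validates such charge sets, maps them onto per-frame
geometries from a structural ensemble, and derives the transition dipole
μ = Σᵢ qᵢ rᵢ used by the point-dipole approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .units import EANG_TO_EBOHR

__all__ = [
    "TransitionChargeSet",
    "PositionedCharges",
    "TransitionDipoleVector",
    "ChargeTableError",
    "load_charge_table",
    "write_charge_table",
    "transition_dipole",
    "rescale_to_dipole",
    "position_charges",
]

DEFAULT_NET_CHARGE_TOL = 1e-3  # |Σq| allowed for an ESP-fitted set, in e


class ChargeTableError(ValueError):
    """Raised for malformed or physically invalid transition-charge tables."""


@dataclass(frozen=True)
class TransitionChargeSet:
    """Atom-anchored transition charges for one chromophore excitation.

    Parameters
    ----------
    chromophore_id : str
        Label for the chromophore (e.g. ``"Trp214"``).
    state_label : str
        Label for the excited state the charges describe (e.g. ``"La"``).
    elements : sequence of str
        Element symbol per atom.
    template_coords : (n, 3) array
        Template geometry in Å (the geometry the charges were fitted on).
    charges : (n,) array
        Transition charges in elementary-charge units, before scaling.
    scale : float
        Dimensionless factor applied to all charges (default 1).
    net_charge_tol : float
        Allowed magnitude of the summed charge, in e.
    """

    chromophore_id: str
    state_label: str
    elements: tuple[str, ...]
    template_coords: np.ndarray
    charges: np.ndarray
    scale: float = 1.0
    net_charge_tol: float = DEFAULT_NET_CHARGE_TOL

    def __post_init__(self) -> None:
        coords = np.asarray(self.template_coords, dtype=float).reshape(-1, 3)
        charges = np.asarray(self.charges, dtype=float).ravel()
        object.__setattr__(self, "template_coords", coords)
        object.__setattr__(self, "charges", charges)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) != coords.shape[0]:
            raise ChargeTableError(
                f"{len(self.elements)} elements but {coords.shape[0]} coordinates"
            )
        if charges.shape[0] != coords.shape[0]:
            raise ChargeTableError(
                f"{charges.shape[0]} charges but {coords.shape[0]} atoms"
            )
        if not self.scale > 0:
            raise ChargeTableError(f"scale must be positive, got {self.scale}")
        net = abs(float(np.sum(self.effective_charges)))
        if net > self.net_charge_tol:
            raise ChargeTableError(
                f"net transition charge |Σq| = {net:.3e} e exceeds tolerance "
                f"{self.net_charge_tol:.1e} e for {self.chromophore_id}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def effective_charges(self) -> np.ndarray:
        """Charges with the scale factor applied, in e."""
        return self.scale * self.charges


@dataclass(frozen=True)
class PositionedCharges:
    """Transition charges carried onto one frame's coordinates.

    ``center`` is the geometric centroid of the charge-bearing atoms; it is
    the point used for center-to-center distances and as the dipole anchor
    in the point-dipole approximation.
    """

    coordinates: np.ndarray  # (n, 3) Å
    charges: np.ndarray  # (n,) e
    center: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        charges = np.asarray(self.charges, dtype=float).ravel()
        if coords.shape[0] != charges.shape[0]:
            raise ValueError(
                f"{coords.shape[0]} coordinates but {charges.shape[0]} charges"
            )
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "charges", charges)
        center = self.center
        if center is None:
            center = coords.mean(axis=0)
        center = np.asarray(center, dtype=float).ravel()
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        if np.any(center < lo - 1e-9) or np.any(center > hi + 1e-9):
            raise ValueError("center lies outside the bounding box of the atoms")
        object.__setattr__(self, "center", center)

    @property
    def n_atoms(self) -> int:
        return self.charges.shape[0]


@dataclass(frozen=True)
class TransitionDipoleVector:
    """Transition dipole in atomic units (e·bohr)."""

    components: np.ndarray  # (3,) e·bohr

    def __post_init__(self) -> None:
        c = np.asarray(self.components, dtype=float).ravel()
        if c.shape != (3,):
            raise ValueError("dipole needs exactly three components")
        object.__setattr__(self, "components", c)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.components))

    @property
    def unit(self) -> np.ndarray:
        m = self.magnitude
        if m < 1e-14:
            raise ValueError("cannot normalize a zero transition dipole")
        return self.components / m


def load_charge_table(
    path: str | Path,
    *,
    chromophore_id: str | None = None,
    state_label: str = "",
    net_charge_tol: float = DEFAULT_NET_CHARGE_TOL,
) -> TransitionChargeSet:
    """Read a transition-charge table.

    The format is a plain-text table with columns ``element x y z q``
    (coordinates in Å, charges in e), separated by whitespace or commas.
    Lines starting with ``#`` are comments; a comment of the form
    ``# key: value`` may carry ``chromophore_id`` / ``state_label`` metadata.

    Raises
    ------
    ChargeTableError
        On a malformed row (with its line number) or when the summed charge
        exceeds ``net_charge_tol`` — an over-threshold net charge is an
        input defect and is never silently corrected.
    """
    path = Path(path)
    elements: list[str] = []
    coords: list[list[float]] = []
    charges: list[float] = []
    meta: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip().lower()] = value.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 5:
                raise ChargeTableError(
                    f"{path}:{lineno}: expected 5 columns (element x y z q), "
                    f"found {len(parts)}"
                )
            try:
                xyz = [float(v) for v in parts[1:4]]
                q = float(parts[4])
            except ValueError as exc:
                raise ChargeTableError(f"{path}:{lineno}: {exc}") from None
            elements.append(parts[0])
            coords.append(xyz)
            charges.append(q)
    if not elements:
        raise ChargeTableError(f"{path}: no data rows")
    return TransitionChargeSet(
        chromophore_id=chromophore_id or meta.get("chromophore_id", path.stem),
        state_label=state_label or meta.get("state_label", ""),
        elements=elements,
        template_coords=np.array(coords),
        charges=np.array(charges),
        net_charge_tol=net_charge_tol,
    )


def write_charge_table(cs: TransitionChargeSet, path: str | Path) -> None:
    """Write a charge set in the same dialect ``load_charge_table`` reads."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# chromophore_id: {cs.chromophore_id}\n")
        if cs.state_label:
            fh.write(f"# state_label: {cs.state_label}\n")
        fh.write("# element x[A] y[A] z[A] q[e]\n")
        for el, (x, y, z), q in zip(cs.elements, cs.template_coords, cs.charges):
            # float repr round-trips exactly, keeping write→read bit-identical
            fh.write(f"{el} {float(x)!r} {float(y)!r} {float(z)!r} "
                     f"{float(q * cs.scale)!r}\n")


def transition_dipole(pc: PositionedCharges) -> TransitionDipoleVector:
    """Transition dipole μ = Σᵢ qᵢ rᵢ of a positioned charge set, in e·bohr.

    For a zero-net-charge set the result is origin-independent.  A
    non-neutral set (within reason — validation happens upstream) triggers
    a warning and the dipole is referenced to the charge-weighted center,
    making the reported value well defined.
    """
    q = pc.charges
    r = pc.coordinates
    net = float(np.sum(q))
    if abs(net) > 1e-6:
        warnings.warn(
            f"non-neutral charge set (Σq = {net:.3e} e); dipole referenced to "
            "the charge-weighted center",
            stacklevel=2,
        )
        origin = (np.abs(q)[:, None] * r).sum(axis=0) / np.abs(q).sum()
        r = r - origin
    mu_eang = (q[:, None] * r).sum(axis=0)
    return TransitionDipoleVector(mu_eang * EANG_TO_EBOHR)


def rescale_to_dipole(
    cs: TransitionChargeSet,
    target_magnitude: float,
    template_coords: np.ndarray | None = None,
) -> TransitionChargeSet:
    """Rescale all charges so the dipole magnitude matches a reference value.

    TrESP charges are commonly rescaled so that Σ qᵢ rᵢ on the template
    geometry reproduces the transition dipole of the underlying QM
    calculation.  ``target_magnitude`` is in e·bohr.

    Raises
    ------
    ValueError
        If the current dipole magnitude is zero (direction undefined) or
        the target is not positive.
    """
    if target_magnitude <= 0:
        raise ValueError("target dipole magnitude must be positive")
    coords = cs.template_coords if template_coords is None else np.asarray(template_coords, float)
    current = transition_dipole(
        PositionedCharges(coords, cs.effective_charges)
    ).magnitude
    if current < 1e-14:
        raise ValueError("current transition dipole is zero; cannot rescale")
    return replace(cs, scale=cs.scale * target_magnitude / current)


def position_charges(
    cs: TransitionChargeSet, frame_coords: np.ndarray
) -> PositionedCharges:
    """Carry a charge set onto one frame's coordinates (Å).

    The frame selection must contain exactly the charge set's atoms, in
    matching order; only the atom count is checkable and is enforced.
    """
    coords = np.asarray(frame_coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] != cs.n_atoms:
        raise ValueError(
            f"frame selection has {coords.shape[0]} atoms, charge set "
            f"'{cs.chromophore_id}' expects {cs.n_atoms}"
        )
    return PositionedCharges(coords, cs.effective_charges)
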