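"""Fluorescence-titration processing: binding constants and FRET efficiencies.

A protein at fixed concentration is titrated with a quenching ligand; the
donor (tryptophan) intensity I_DA at each ligand concentration [L] is first
corrected for inner-filter effects,

    I_corr = I · 10^((Abs_ex + Abs_em)/2),

then the association constant K_b and Hill coefficient n are obtained from
the double-log binding plot

    log₁₀((I_D − I_DA)/I_DA) = log₁₀ K_b + n log₁₀ [L],

with [L] in molar.  Raw efficiencies E = 1 − I_DA/I_D are corrected by the
fraction of protein actually bound, f([L]) = [L]ⁿ/(K_dⁿ + [L]ⁿ), and the
corrected values are averaged over concentrations.  The double-log plot is
exact when the complex quenches the donor completely; for partial quenching
it is the standard field approximation and the fitted parameters absorb
part of the unquenched fraction (the fraction-bound correction is exact
whenever K_d and n themselves are accurate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "ife_correct",
    "efficiency_from_intensities",
    "hill_fit",
    "fraction_bound",
    "corrected_efficiency",
    "compare_to_simulation",
    "load_titration_csv",
]

logger = logging.getLogger(__name__)

RULE_OUT_THRESHOLD = 0.25  # |E_exp − E_site| above which a binding model is ruled out
MIN_FRACTION_BOUND = 1e-3  # below this the fraction-bound correction is unstable


@dataclass(frozen=True)
class TitrationSeries:
    """One ligand titration at fixed protein concentration.

    ``i_d`` is the donor-only intensity (the [L] = 0 anchor point, never
    fitted); ``i_da``, ``abs_ex`` and ``abs_em`` are per-concentration
    intensities and absorbances at the excitation and emission wavelengths.
    Concentrations are in µM.
    """

    ligand_id: str
    protein_conc: float
    ligand_concs: np.ndarray
    i_d: float
    i_da: np.ndarray
    abs_ex: np.ndarray
    abs_em: np.ndarray
    excitation_nm: float = 295.0
    emission_nm: float = 340.0

    def __post_init__(self) -> None:
        concs = np.asarray(self.ligand_concs, dtype=float).ravel()
        i_da = np.asarray(self.i_da, dtype=float).ravel()
        a_ex = np.asarray(self.abs_ex, dtype=float).ravel()
        a_em = np.asarray(self.abs_em, dtype=float).ravel()
        if not (concs.size == i_da.size == a_ex.size == a_em.size):
            raise ValueError("concentration/intensity/absorbance lengths differ")
        if np.any(concs <= 0):
            raise ValueError("ligand concentrations must be positive (the [L]=0 "
                             "point enters only as i_d)")
        if np.any(np.diff(concs) <= 0):
            raise ValueError("ligand concentrations must be strictly increasing")
        if not self.i_d > 0 or np.any(i_da <= 0):
            raise ValueError("intensities must be positive")
        if np.any(a_ex < 0) or np.any(a_em < 0):
            raise ValueError("absorbances must be non-negative")
        object.__setattr__(self, "ligand_concs", concs)
        object.__setattr__(self, "i_da", i_da)
        object.__setattr__(self, "abs_ex", a_ex)
        object.__setattr__(self, "abs_em", a_em)


@dataclass(frozen=True)
class BindingFit:
    """Result of the double-log binding fit, plus corrected efficiencies."""

    ligand_id: str
    log_kb: float  # log10 of K_b in M⁻¹
    n_hill: float
    kd_um: float
    r_squared: float
    per_conc: pd.DataFrame = field(default_factory=pd.DataFrame)
    e_final: float = float("nan")
    n_clipped: int = 0
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "ligand_id": self.ligand_id,
            "log_kb": self.log_kb,
            "n_hill": self.n_hill,
            "kd_uM": self.kd_um,
            "r_squared": self.r_squared,
            "e_final": self.e_final,
            "n_clipped": self.n_clipped,
            "n_excluded": self.n_excluded,
            "per_conc": self.per_conc.to_dict(orient="records"),
        }


def ife_correct(
    intensity: float | np.ndarray,
    abs_ex: float | np.ndarray,
    abs_em: float | np.ndarray,
):
    """Inner-filter correction I·10^((Abs_ex + Abs_em)/2)."""
    a_ex = np.asarray(abs_ex, dtype=float)
    a_em = np.asarray(abs_em, dtype=float)
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise ValueError("absorbances must be non-negative")
    out = np.asarray(intensity, dtype=float) * 10.0 ** ((a_ex + a_em) / 2.0)
    return out if out.ndim else float(out)


def efficiency_from_intensities(i_da: float, i_d: float) -> float:
    """Quenching efficiency E = 1 − I_DA/I_D.

    A negative value (I_DA > I_D, fluorescence enhancement rather than
    quenching) is returned as-is with a warning so the caller can see it.
    """
    if i_d <= 0:
        raise ValueError("donor-only intensity must be positive")
    e = 1.0 - i_da / i_d
    if e < 0:
        logger.warning(
            "I_DA (%.4g) exceeds I_D (%.4g): enhancement, not quenching", i_da, i_d
        )
    return e


def hill_fit(series: TitrationSeries, apply_ife: bool = True) -> BindingFit:
    """Fit log₁₀((I_D − I_DA)/I_DA) = log₁₀K_b + n·log₁₀[L] by OLS.

    Intensities are inner-filter corrected first (unless ``apply_ife`` is
    False, for pre-corrected data).  Points with I_DA ≥ I_D carry no
    quenching signal and are excluded with a warning; at least two usable
    points are required.  [L] enters the fit in molar; K_d is reported in
    µM as the half-saturation concentration K_b^(−1/n) of the fitted
    isotherm (equal to 1/K_b when n = 1).
    """
    i_da = series.i_da
    if apply_ife:
        i_da = ife_correct(i_da, series.abs_ex, series.abs_em)
    usable = i_da < series.i_d
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.warning(
            "%s: excluding %d point(s) with I_DA >= I_D from the binding fit",
            series.ligand_id, n_excluded,
        )
    if usable.sum() < 2:
        raise ValueError(
            f"{series.ligand_id}: need at least 2 concentrations with "
            f"I_DA < I_D, have {int(usable.sum())}"
        )
    conc_m = series.ligand_concs[usable] * 1e-6
    y = np.log10((series.i_d - i_da[usable]) / i_da[usable])
    x = np.log10(conc_m)
    res = stats.linregress(x, y)
    # K_d is reported as the half-saturation concentration of the fitted
    # Hill isotherm, K_d = K_b^(−1/n) (identical to 1/K_b when n = 1, and
    # the quantity the fraction-bound correction actually needs).
    kd_um = 10.0 ** (-res.intercept / res.slope) * 1e6
    raw_e = 1.0 - i_da / series.i_d
    per_conc = pd.DataFrame(
        {
            "ligand_conc_uM": series.ligand_concs,
            "i_da_corrected": i_da,
            "e_raw": raw_e,
            "used_in_fit": usable,
        }
    )
    return BindingFit(
        ligand_id=series.ligand_id,
        log_kb=float(res.intercept),
        n_hill=float(res.slope),
        kd_um=float(kd_um),
        r_squared=float(res.rvalue**2),
        per_conc=per_conc,
        n_excluded=n_excluded,
    )


def fraction_bound(conc_um: float | np.ndarray, kd_um: float, n_hill: float = 1.0):
    """Hill isotherm f([L]) = [L]ⁿ / (K_dⁿ + [L]ⁿ), free ligand ≈ total."""
    c = np.asarray(conc_um, dtype=float)
    f = c**n_hill / (kd_um**n_hill + c**n_hill)
    return f if f.ndim else float(f)


def fraction_bound_depletion(
    conc_um: float, kd_um: float, protein_um: float
) -> float:
    """Exact 1:1 bound fraction with ligand depletion (n = 1 only).

    Solves [PL] from the quadratic mass-balance for total concentrations
    and returns [PL]/[P]_total.
    """
    p, l, kd = protein_um, conc_um, kd_um
    b = p + l + kd
    pl = (b - np.sqrt(b**2 - 4 * p * l)) / 2.0
    return float(pl / p)


def corrected_efficiency(
    series: TitrationSeries,
    fit: BindingFit,
    *,
    apply_ife: bool = True,
    langmuir: bool = False,
) -> BindingFit:
    """Complete a BindingFit with fraction-bound-corrected efficiencies.

    The raw per-concentration efficiency E_raw = 1 − I_DA/I_D reflects only
    the fraction f([L]) of protein in the complex; the site efficiency is
    E_raw/f.  Corrected values are clipped to [0, 1] (each clip logged and
    counted — over-correction at low f is possible and must stay visible),
    concentrations with f < 1e-3 are excluded as unstable, and ``e_final``
    is the mean of the corrected values over the remaining concentrations.
    ``langmuir=True`` forces n = 1 in the isotherm regardless of the fit.
    """
    i_da = series.i_da
    if apply_ife:
        i_da = ife_correct(i_da, series.abs_ex, series.abs_em)
    raw_e = 1.0 - i_da / series.i_d
    n_iso = 1.0 if langmuir else fit.n_hill
    f = fraction_bound(series.ligand_concs, fit.kd_um, n_iso)
    stable = f >= MIN_FRACTION_BOUND
    if not stable.any():
        raise ValueError(
            f"{series.ligand_id}: fraction bound < {MIN_FRACTION_BOUND} at all "
            "concentrations; correction unstable"
        )
    corrected = np.where(stable, raw_e / np.where(stable, f, 1.0), np.nan)
    clipped = np.clip(corrected, 0.0, 1.0)
    # tolerate float round-off; count only genuine over/under-corrections
    overshoot = np.abs(corrected - clipped) > 1e-9
    n_clipped = int(np.nansum(overshoot & stable))
    if n_clipped:
        logger.warning(
            "%s: clipped %d corrected efficiency value(s) into [0, 1]",
            series.ligand_id, n_clipped,
        )
    e_final = float(np.nanmean(clipped[stable]))
    per_conc = pd.DataFrame(
        {
            "ligand_conc_uM": series.ligand_concs,
            "i_da_corrected": i_da,
            "e_raw": raw_e,
            "fraction_bound": f,
            "e_corrected": clipped,
        }
    )
    return BindingFit(
        ligand_id=fit.ligand_id,
        log_kb=fit.log_kb,
        n_hill=fit.n_hill,
        kd_um=fit.kd_um,
        r_squared=fit.r_squared,
        per_conc=per_conc,
        e_final=e_final,
        n_clipped=n_clipped,
        n_excluded=fit.n_excluded,
    )


def compare_to_simulation(
    e_exp: float,
    site_means: dict[str, float],
    threshold: float = RULE_OUT_THRESHOLD,
) -> pd.DataFrame:
    """Rank candidate binding sites by |E_exp − E_site|.

    Sites whose simulated mean efficiency deviates from the experimental
    value by more than ``threshold`` are flagged ruled out — deviations of
    that size are incompatible with the site being the dominant binding
    model (secondary binding to another site remains a caveat).  Ties are
    broken alphabetically by site name for stable output.
    """
    if not np.isfinite(e_exp):
        raise ValueError("experimental efficiency is not a finite number")
    if not site_means:
        raise ValueError("no simulated site efficiencies to compare against")
    rows = [
        {
            "site": site,
            "e_site": e_site,
            "deviation": abs(e_exp - e_site),
            "ruled_out": abs(e_exp - e_site) > threshold,
        }
        for site, e_site in site_means.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["deviation", "site"], kind="stable", ignore_index=True
    )
    df.attrs["e_exp"] = e_exp
    df.attrs["threshold"] = threshold
    return df


def load_titration_csv(
    path: str | Path,
    ligand_id: str | None = None,
    protein_conc: float = 5.0,
    **kwargs,
) -> TitrationSeries:
    """Read a titration CSV with columns ligand_conc_uM, intensity, abs_ex, abs_em.

    The row with ligand_conc_uM == 0 provides the donor-only intensity I_D.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"ligand_conc_uM", "intensity", "abs_ex", "abs_em"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    zero = df[df.ligand_conc_uM == 0]
    if len(zero) != 1:
        raise ValueError(f"{path}: need exactly one ligand_conc_uM == 0 row for I_D")
    rest = df[df.ligand_conc_uM > 0].sort_values("ligand_conc_uM")
    return TitrationSeries(
        ligand_id=ligand_id or path.stem,
        protein_conc=protein_conc,
        ligand_concs=rest.ligand_conc_uM.to_numpy(),
        i_d=float(zero.intensity.iloc[0]),
        i_da=rest.intensity.to_numpy(),
        abs_ex=rest.abs_ex.to_numpy(),
        abs_em=rest.abs_em.to_numpy(),
        **kwargs,
    )
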