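# Methods

## Model

The package treats donor-to-acceptor excitation transfer in the weak
(Förster) coupling limit, where the transfer rate is proportional to the
squared electronic coupling times the spectral overlap. Three levels of
description of the coupling are implemented:

1. **Point-dipole (PDA).** V = s·κ·μ_D μ_A / R³ with
   κ = μ̂_D·μ̂_A − 3(μ̂_D·R̂)(μ̂_A·R̂), the transition dipoles at the
   chromophore centers, and a scalar screening s (1/n² in Förster
   theory). κ ∈ [−2, 2], κ² ∈ [0, 4], isotropic average ⟨κ²⟩ = 2/3.
2. **Transition charges (TrESP).** The Coulomb sum
   V_Coul = Σ_ij q_D,i q_A,j/|r_i − r_j| over atom-centered transition
   charges, which retains the shape of the transition densities. The
   charges are consumed as input (they are fitted externally to QM
   transition densities); an optional rescaling reproduces a reference
   dipole magnitude, since Σ_i q_i r_i defines the transition dipole.
3. **TrESP + polarizable environment.** Environment atoms within a
   cutoff of either chromophore (default 15 Å, any-atom distance, closed
   interval) carry isotropic polarizabilities and acquire mutually
   coupled induced dipoles in the field of the acceptor's transition
   charges, μ_l = α_l(E_l + Σ_{m≠l} T_lm μ_m). The environment-mediated
   coupling is V_env = −Σ_l E_D(r_l)·μ_l, the polarization cross term of
   the two transition fields (for one site without mutual coupling it is
   exactly −α E_D·E_A). V = V_Coul + V_env, and s = V/V_Coul defines the
   atomistic screening factor. By linear response the roles of donor and
   acceptor are interchangeable; the implementation asserts this
   reciprocity rather than assuming it.

Units are atomic internally (bohr, e, Hartree; couplings also exported in
cm⁻¹); coordinates cross the API in Å, lifetimes in ns, Förster radii in
Å, spectral overlaps in M⁻¹cm⁻¹nm⁴.

### Rates and disorder averaging

Instantaneous rates follow
k(t) = V(t)²·3n⁴R₀⁶/(2 τ_D μ_D² μ_A²), which is constructed so that
inserting the screened PDA coupling with κ² = 2/3 and s = 1/n² recovers
the textbook (R₀/R)⁶/τ_D exactly (this identity is a test). Efficiencies
are averaged in the intermediate regime: each replica's rate series is
cut into non-overlapping windows of duration equal to the donor lifetime
by default (the timescale separating "fast" from "slow" fluctuations);
rates are averaged arithmetically within a window; each window
contributes E_w = 1/(1 + 1/(τ_D⟨k⟩)); the distribution over windows and
replicas carries the static disorder. Window length is configurable and
recorded in output; partial trailing windows are dropped; windows weigh
equally across replicas (no length weighting). The two limits — one
window per trajectory (fully dynamic) and one frame per window (fully
static) — bracket the intermediate result for the two-state fixtures
used in testing.

### Distance bias

Inverting E = 1/(1 + (R/R₀)⁶) maps an efficiency distribution to an
apparent distance distribution. The comparison with the directly sampled
distances aligns the two distributions by equal quantiles (sorted,
linearly interpolated to a common grid), which is exact when the
efficiencies derive frame-by-frame from the distances, and reports mean
signed error, mean unsigned error and maximum deviation. Efficiencies of
exactly 0 or 1 cannot be inverted and are excluded with a reported count.

### Titrations

Intensities are inner-filter corrected as I·10^((A_ex+A_em)/2). The
binding fit is ordinary least squares on
log₁₀((I_D − I_DA)/I_DA) = log₁₀K_b + n log₁₀[L] with [L] in molar and
the total ligand concentration standing in for the free one (protein at
5 µM against ligand ≥ 10 µM makes depletion modest; an exact 1:1
depletion solver is available for n = 1). K_d is reported as the
half-saturation concentration K_b^(−1/n) of the fitted Hill isotherm —
identical to 1/K_b at n = 1 and the quantity the fraction-bound
correction consumes. Raw efficiencies are divided by
f([L]) = [L]ⁿ/(K_dⁿ + [L]ⁿ), clipped to [0, 1] with a logged count
(over-correction at small f must remain visible), concentrations with
f < 10⁻³ are excluded, and the corrected values are averaged over
concentrations.

**Identifiability.** The double-log plot is exact only when the complex
quenches the donor completely. For partial quenching
(I_DA = I_D(1 − e·f)), the quantity the fit linearizes is e·f/(1 − e·f),
and at the fitted points the implied isotherm equals e·f — the fit
estimates the *quenched* fraction, not the bound fraction. Consequently,
correcting efficiencies with the self-fitted isotherm drives E toward 1
regardless of the true site efficiency (verified numerically; it is a
property of the analysis, not a bug). Recovering a partial-quenching
efficiency requires binding parameters known independently of the same
titration; the tests exercise both regimes explicitly, and the
fitted-parameter behaviour is itself asserted as documented behaviour.

## Synthetic data

The fixture generators are pure functions of (parameters, seed) and ship
their analytic ground truths:

- **Dipole pairs** — ±q charge pairs with q·sep equal to a target dipole;
  exact 4-term Coulomb sums and PDA values written out independently of
  the engine. They probe the PDA breakdown: deviations scale as
  (sep/R)², <1% beyond ~50× the internal separation.
- **Orientation samples** — independent uniform directions on the sphere
  for κ² statistics.
- **Two-timescale trajectories** — piecewise-constant slow coupling
  states aligned with the averaging windows plus per-frame Gaussian
  noise on the *coupling* (rates are quadratic in V, so Gaussian noise
  contributes its variance exactly: ⟨V²⟩ = V_s² + σ², keeping the
  ground-truth efficiency analytic). Default stride 50 ps.
- **Titrations** — I_DA = I_D(1 − e·f([L])) with Hill f, linear-in-[L]
  absorbances and optional multiplicative log-normal noise; stored
  intensities are pre-attenuated so the inner-filter correction is
  exercised end to end. Default concentrations 10/50/100 µM at 5 µM
  protein.
- **Polarizable shells and random site clouds** — for screening and
  solver tests; random clouds enforce a 2.5 Å minimum separation because
  near-contact undamped polarizable pairs have no convergent mutual
  induction (polarization catastrophe).

What the fixtures do **not** emulate: real force-field geometries,
conformational kinetics, anisotropic polarizabilities, spectral shapes of
real chromophores, or instrument noise structure. Passing tests therefore
validate the numerics and the averaging machinery, not the accuracy of
any particular force field or charge set on a real complex.

## Numerical choices

- Induced dipoles: the direct method solves the dense
  (I − diag(α)T)μ = αE system; the iterative method is Jacobi fixed
  point with 0.5 linear mixing, tolerance 1e-8 on the maximum component
  change (tightened in equivalence tests), maximum 500 iterations, with
  the residual history reported on failure. Optional linear Thole
  damping (pair radius a·(α_l α_m)^(1/6)) is off by default.
- Clash thresholds: donor/acceptor atom pairs or charge–site pairs
  closer than 0.1 Å are errors (frames should be excluded upstream).
- Near-zero Coulomb couplings (|V_Coul| < 1e-9 Hartree) make the
  screening factor and PDA/TrESP ratio ill-defined; such frames are
  flagged, excluded from those statistics, and retained in raw output.
- Chromophore "center" is the geometric centroid of the charge-bearing
  atoms (recorded in output; the center convention matters only through
  R and κ²).
- Transition-dipole sign is arbitrary; distribution statistics use
  squared or ratio-safe quantities, raw signed values are retained.
- Net transition charge must vanish within 1e-3 e (configurable); the
  dipole of a neutral set is origin-independent, and a non-neutral set
  falls back to the charge-weighted center with a warning.
- Binned distance profiles use fixed-width bins (default 1 Å) with mean,
  sample standard deviation and count per bin; efficiency histograms use
  50 bins on [0, 1] by default.

## Scope and limitations

Docking, MD propagation, QM transition-density calculations and charge
fitting are out of scope; charges, ensembles and polarizabilities are
inputs. Only isotropic polarizabilities and the induced-dipole
environment term are implemented (no permanent-charge site-energy
shifts, no charge transfer, no periodic boundaries). The donor is a
two-state emitter: no photon statistics, no lifetime fitting, no
multi-site global binding models. Test problem sizes (10⁶ orientation
samples, ≤100 polarizable sites, 2.5·10⁴-frame trajectories, 200-seed
titration ensembles) were chosen so the full suite runs in seconds while
keeping Monte-Carlo errors well below the tolerances being asserted.
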