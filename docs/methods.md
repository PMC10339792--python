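# Methods

## The scattering model

The fiber is modelled as an infinitely long rectangular rod with a
nested cross-section: a hydrophobic core (edges `a_core × b_core`), a
peptide shell of thicknesses `a_shell`, `b_shell` (so the peptide
envelope is `a_pep = a_core + 2 a_shell`, `b_pep = b_core + 2 b_shell`),
and an optional PEG corona of thickness `d` (`a_tot = a_pep + 2d`,
`b_tot = b_pep + 2d`).  Because the fiber length `c` far exceeds the
cross-section, the orientational average factorizes (decoupling
approximation) into an in-plane rotational average of the cross-section
amplitude times the longitudinal factor of an infinitely thin rod,
`Λ(x) = 2 Si(x)/x − 4 sin²(x/2)/x²` with `x = Qc`.

The cross-section amplitude superposes the three nested rectangle
amplitudes so that each physical region carries its own excess SLD:

    A_cs = Δρ_core V_core A_core
         + Δρ_shell (V_pep A_pep − V_core A_core)
         + Δρ_PEG  (V_tot A_tot − V_pep A_pep)

with `A_x(Q, α) = sinc(Q a_x cos α / 2) sinc(Q b_x sin α / 2)`
normalized to 1 at Q = 0.  All amplitudes are unitless; contrast ×
volume weights are applied only in this assembly, which keeps each
region's weight explicit and makes the forward-limit identity
(see below) a direct bookkeeping check.

Density fluctuations of the solvent-swollen PEG corona add an
incoherent-like per-chain term ("blob scattering"): `N_agg` chains per
fiber, each weighted by `(Δρ_PEG V_PEG)²`, with a Beaucage unified shape
of exponent 2 (Gaussian chain).  The exponent is fixed at 2 unless
overridden: a ~2 kDa PEG at a surface in good solvent scatters with a
Q⁻² tail over the accessible window.

### Absolute scale

The fiber number density is `φ / V_pep`, with `φ` the *peptide* volume
fraction — the quantity the sample preparation fixes (10 mg/mL at
1.25 g/mL ≈ 0.8%).  The solvent-swollen corona carries no volume
fraction of its own; this normalization makes the intensity exactly
invariant under adding a contrast-matched corona, which is also how the
PEG match-out contrast in a variation series behaves physically.  The
forward limit obeys, exactly,

    I(0) − bkg = φ/V_pep [ (Σ_i Δρ_i V_i)² + N_agg (Δρ_PEG V_PEG)² ]

with i ∈ {core, shell, PEG layer}; the blob term vanishes for d = 0.

### Numerical choices

- Rotational average over α ∈ [0, π/2]: Gauss–Legendre quadrature,
  256 nodes by default, doubled until the relative change is < 10⁻⁴
  (the integrand oscillates at high Q·b).  Inside fit loops the node
  count is fixed at 256 for speed and determinism.
- Geometry validation: `c` must exceed the cross-section; `c` below
  10× the larger cross-section edge only warns (decoupling is then
  approximate — the published fiber, c = 340 Å vs b_pep = 61.1 Å, sits
  in this advisory regime, as real fibers do).
- Polydispersity is not modelled; the fiber length is at the edge of
  the experimental resolution window, so distributions in `c` are not
  identifiable and would only add parameters.
- Resolution smearing is off by default; curve files may carry a ΔQ
  column, which readers preserve.
- Units: lengths Å, Q Å⁻¹, I cm⁻¹, SLD cm⁻²; mass–volume conversion
  uses 1 g/cm³ = 0.60221 Da/Å³.

The reconstruction was validated three ways: the forward-limit closed
form holds to 0.1% at production quadrature settings; the decoupled
intensity agrees with a brute-force two-angle quadrature of the nested
parallelepipeds over the full sphere within 5% at the decoupling
boundary (c = 10× cross-section, Qc > 10 — the residual deviation peaks
at the deep form-factor minimum, where any finite-length effect is
amplified); and the published parameter set reproduces the
characteristic curve anatomy (flat→Q⁻¹ rollover, cross-section Guinier
knee, pronounced min/max pair near Q ≈ 0.2 Å⁻¹ that disappears when the
contrasts are collapsed to a homogeneous filament).

## SLDs, exchange and the ZAC design

X-ray SLDs are electron density × the classical electron radius;
neutron SLDs sum tabulated coherent scattering lengths over the
molecular formula (D is a distinct symbol).  Labile hydrogens — backbone
amides plus side-chain N–H/O–H in neutral form, plus terminal
modifications — substitute H↔D in proportion to the solvent D₂O
fraction, scaled by an `exchange_fraction` parameter (default 1:
samples equilibrate in buffer for hours).  Dilute buffer salts
(tens of mM) shift the solvent SLD by ≲0.3% and are ignored.  Water
densities default to 25 °C values (H₂O 0.997, D₂O 1.107 g/mL);
temperature enters only through these densities and both are exposed.

The zero-average-contrast condition — a solvent whose SLD lies exactly
midway between the h-PEG and d-PEG conjugates — is solved by bracketed
root finding, under one of two documented labile-H conventions:

- `full` (default): labile sites counted as fully deuterated, the
  convention under which match points of exchangeable molecules are
  usually quoted.  For Ac-K₃W(QL)₆K₂ conjugated to 1.9 kg/mol h-PEG /
  2.1 kg/mol d-PEG this gives 56.6% D₂O.
- `equilibrated`: labile sites track the solvent D₂O fraction
  self-consistently, giving 51.3% for the same pair.

The ~5-point spread between the conventions is the honest uncertainty
of the exchange model; both are exposed so the assumption is explicit
rather than buried.

Peptide compositions come from a per-residue formula table (average
masses); termini default to N-acetyl / C-amide, the product of standard
solid-phase synthesis, and are configurable.  Region compositions for
contrast-variation simulation assign leucine and tryptophan side chains
to the core and everything else (backbone, termini, K/Q side chains) to
the shell.

## Global fitting

All datasets share the structural parameters (geometry, corona, φ);
each dataset has its own contrast set, an optional intensity scale
(freed for SANS to absorb absolute-calibration drift, pinned to 1 for
SAXS) and a flat background.  Residuals are (I_model − I_data)/σ
concatenated across datasets and minimized with a bounded trust-region
least-squares optimizer (lmfit/least_squares); uncertainties come from
the covariance at the optimum.  Because the cross-section oscillations
create local minima, a seeded multi-start loop (default 8 starts,
log-normal perturbations of the free parameters) is available; with a
start near the truth a single start converges.  The fiber length should
be read as a lower bound whenever the data show no longitudinal Guinier
region.  Aggregation number and per-molecule masses are always
re-derived from the best-fit geometry, never cached.

## Synthetic data

The generator emulates the study's measurement conditions: log-spaced Q
grids over 0.004–0.7 Å⁻¹, Gaussian noise with σ(Q) = 2%·I(Q) + 10⁻³ cm⁻¹,
φ = 0.8%, five-contrast H₂O/D₂O series, and 50/50 h/d blends at the ZAC
composition.  It does **not** emulate instrument resolution smearing,
inter-fiber interference, aggregation/polydispersity, or wavelength-
dependent backgrounds — passing recovery tests therefore demonstrate
estimator correctness under the model's own assumptions, not robustness
to real-data artifacts.

Parameter-recovery checks run at 2% relative noise (10 noise seeds,
median errors): the additive noise floor, while realistic, swamps the
high-Q min/max region that constrains the thinnest shell dimension and
is therefore part of the generator's realism settings rather than the
recovery conditions.  Problem sizes are kept at 60–80 points per curve
and ≤ 10 seeds, which resolves all reported quantities comfortably.

### ZAC exchange kinetics

Exchange is tracked mean-field: each fiber population carries the
h-fraction of its corona, not per-molecule labels — the scattered
intensity senses only population-level shell contrast, and the
mechanistic argument is population-level.  Three mechanisms:

- `end_only`: only `n_end` molecules per fiber end are accessible; the
  mixed fraction saturates at `2 n_end / N_agg`, so the intensity
  plateaus strictly above the fully mixed baseline — the signature of
  exchange confined to fiber ends.
- `uniform_unimer`: any molecule exchanges; single-exponential
  relaxation to complete mixing.
- `breakup_reform`: scission/reformation events rescramble fibers;
  complete mixing at long times.

At the ZAC composition the blend-mean corona SLD equals the solvent, so
peptide–corona cross terms cancel between the two populations and the
intensity decays monotonically to the corona-free curve.  The
relaxation function is reported as R(t) = √[(I(t) − I∞)/(I₀ − I∞)],
the square-root convention of kinetic zero-average-contrast analysis.
No quantitative decay constants are asserted anywhere — the simulation
is validated by its invariants (monotonicity, label conservation,
mechanism continuity as n_end → N_agg/2, plateau ordering).

## Energetics and CD

The activation-energy estimate prices each leucine side chain as two
CH₃ (9 kJ/mol) and two CH₂-equivalents (3 kJ/mol) — the branch CH is
priced at the CH₂ increment — giving 24 kJ/mol per leucine; the
alternative calibration scales 90 kJ/mol per 24 aliphatic carbons from
alkyl-micelle exchange measurements.  The hydrogen-bond term counts one
backbone bond per residue of the stably bonded central block per side;
removal from a fiber end breaks one side's bonds only.  These are
order-of-magnitude estimates: lysine electrostatics, tryptophan
hydrophobicity and side-chain interactions are all neglected.

CD conversion uses the standard molar-residual-ellipticity
normalization MRE = θ_mdeg / (10 · c · n · l) with c in mol/L, n the
residue count and l the path length in cm; it is linear and exactly
invertible, which the tests exercise.

## Known limitations

- Fiber twist (observed in MD with a ~35-strand period) is not in the
  scattering model; the rotational average largely masks it.
- The screened-Coulomb structure factor is a random-phase approximation
  on top of the Percus–Yevick fluid — adequate for producing and
  locating a correlation peak, not for quantitative charge inversion.
- The ZAC simulation has no spatial resolution along the fiber: the
  "exchange front" advancing from the ends is represented only through
  the saturating accessible fraction.
- Exchangeable-H counts assume neutral side chains; protonation states
  shift conjugate SLDs at well below the exchange-model uncertainty.
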