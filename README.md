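# fibersas

Small-angle scattering analysis of self-assembling beta-sheet peptide
nanofibers.

Multidomain peptides of the K<sub>x</sub>W(QL)<sub>y</sub>K<sub>z</sub>
family assemble into long fibers built from two stacked antiparallel
beta-sheets: a hydrophobic leucine/tryptophan core wrapped by the peptide
backbone and hydrophilic residues, optionally surrounded by a
solvent-swollen PEG corona when the peptide is PEGylated.  `fibersas`
implements the quantitative analysis of SAXS/SANS data from such fibers
for scattering practitioners and peptide-materials researchers:

- **Form factor** — a rectangular core–shell(–shell) cross-section model
  on an absolute intensity scale.  The cross-section amplitude is a
  contrast-weighted superposition of nested rectangle amplitudes
  A(Q, α) = sinc(Qa cos α/2) · sinc(Qb sin α/2), rotationally averaged
  over α, multiplied by the longitudinal factor of an infinitely thin
  rod Λ(Qc) = 2 Si(Qc)/(Qc) − 4 sin²(Qc/2)/(Qc)², plus a Beaucage "blob"
  term for density fluctuations in the PEG corona:

      I(Q) = φ/V_pep · [ ⟨|A_cs(Q,α)|²⟩_α Λ(Qc) + N_agg (Δρ_PEG V_PEG)² B(Q R_g) ] + bkg

- **SLDs and contrast** — X-ray and neutron scattering length densities
  from chemical composition, mass density and exchangeable-hydrogen
  bookkeeping, including H₂O/D₂O contrast variation and the
  zero-average-contrast (ZAC) blend design for exchange kinetics.
- **Global fitting** — simultaneous weighted least-squares refinement of
  one structural parameter set against several datasets (SAXS + SANS, or
  a multi-contrast SANS series), with per-dataset scales/backgrounds and
  derived quantities (aggregation number, per-molecule masses).
- **Companion models** — Beaucage unified fits for dissolved chains,
  Percus–Yevick / screened-Coulomb structure factors for charged
  unimers, and the legacy homogeneous-filament model.
- **Synthetic data** — a generator for noisy curves, contrast series and
  time-resolved ZAC decay under competing exchange mechanisms (end-only,
  uniform unimer, fiber break-up/reform), so the whole pipeline is
  testable without beamline data.
- **Energetics and CD** — the empirical activation-energy estimate for
  molecular exchange (Tanford group increments or alkyl-micelle
  calibration plus backbone hydrogen bonds) and conversion of raw CD
  ellipticity to molar residual ellipticity.

## Worked example

The empirical binding-energy decomposition for the Ac-K₃W(QL)₆K₂
peptide (`fibersas energetics KKKWQLQLQLQLQLQLKK`):

```
aliphatic carbons        : 24
hydrophobic (Tanford)    : 144 kJ/mol
hydrophobic (alkyl calib): 90 kJ/mol
H-bonds per side         : 14
H-bond term              : 112 kJ/mol
activation estimate      : 202 kJ/mol (lower bound)
```

The six leucine side chains contribute 24 aliphatic carbons; priced with
Tanford transfer increments (2 CH₃ at 9 kJ/mol + 2 CH₂-equivalents at
3 kJ/mol per leucine) they give 144 kJ/mol, or 90 kJ/mol when scaled from
the measured exchange barrier of 24-carbon alkyl micelles.  The 14
backbone hydrogen bonds of the central KW(QL)₆ block add 112 kJ/mol for
pulling one molecule off a fiber end, so the exchange barrier is at least
~200 kJ/mol — the reason thermally activated exchange between fibers is
essentially frozen.

The ZAC blend design and a solvent SLD
(`fibersas zac-match`, `fibersas sld --formula D2O --density 1.107`):

```
ZAC solvent composition: 56.6% D2O (full exchange)
xray SLD   : 9.3801e+10 cm^-2
neutron SLD: 6.3728e+10 cm^-2
```

In a 57/43 D₂O/H₂O buffer the solvent SLD sits midway between the h-PEG
and d-PEG peptide conjugates, so a 50/50 blend of the two species starts
with equal and opposite corona contrast and molecular exchange shows up
as a decay of the excess scattering.

A model curve can be simulated and refit from the command line
(`fibersas synth` → `fibersas fit`); with the true parameters as the
starting point the reduced chi-square comes back at ≈ 1, and the fit
report includes the derived aggregation number (≈ 178 molecules per
fiber for the published geometry and densities).

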