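"""Back-of-envelope binding energetics and CD unit conversion.

The activation energy for pulling one molecule off a fiber end is
estimated from two additive contributions: the hydrophobic transfer
energy of the leucine side chains (either Tanford group increments or a
calibration against n-alkyl micelle exchange kinetics) and the backbone
hydrogen bonds of the central beta-sheet block, one bond per residue per
side.  The numbers are order-of-magnitude bookkeeping, not a free-energy
calculation — electrostatic repulsion of the lysines, tryptophan
hydrophobicity and glutamine side-chain interactions are all neglected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class EnergeticsConfig:
    """Group increments (kJ/mol) for the empirical binding estimate.

    Tanford transfer energies per aliphatic group; ``e_hbond`` per
    backbone hydrogen bond; ``alkyl_calibration`` is the activation
    energy measured for n-alkyl amphiphile exchange, quoted per
    ``alkyl_calibration_carbons`` aliphatic carbons.
    """

    e_ch3: float = 9.0
    e_ch2: float = 3.0
    e_hbond: float = 8.0
    alkyl_calibration: float = 90.0
    alkyl_calibration_carbons: int = 24

    def __post_init__(self) -> None:
        if min(self.e_ch3, self.e_ch2, self.e_hbond, self.alkyl_calibration) < 0:
            raise ValueError("energies must be >= 0")
        if self.alkyl_calibration_carbons <= 0:
            raise ValueError("alkyl_calibration_carbons must be positive")


#: aliphatic side-chain carbons counted per residue.  Only leucine is
#: priced by default: its side chain contributes 4 carbons (2 CH3, one
#: CH2, one branch CH).  The table is configurable for other conventions.
ALIPHATIC_CARBONS: dict[str, int] = {"L": 4}

#: aliphatic group breakdown per residue as (n_CH3, n_CH2_equivalent);
#: leucine's branch CH is priced at the CH2 increment so that one leucine
#: contributes 2*9 + 2*3 = 24 kJ/mol.
ALIPHATIC_GROUPS: dict[str, tuple[int, int]] = {"L": (2, 2)}

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - _AA_LETTERS
    if bad:
        raise ValueError(f"unknown amino-acid letters {sorted(bad)}")


def count_aliphatic_carbons(
    sequence: str, table: dict[str, int] | None = None
) -> int:
    """Aliphatic side-chain carbons in a sequence (leucine-only default)."""
    _check_sequence(sequence)
    table = ALIPHATIC_CARBONS if table is None else table
    return sum(table.get(ch, 0) for ch in sequence)


def tanford_hydrophobic_energy(
    sequence: str, config: EnergeticsConfig = EnergeticsConfig()
) -> float:
    """Hydrophobic transfer energy (kJ/mol) via Tanford group increments."""
    _check_sequence(sequence)
    total = 0.0
    for ch in sequence:
        n_ch3, n_ch2 = ALIPHATIC_GROUPS.get(ch, (0, 0))
        total += n_ch3 * config.e_ch3 + n_ch2 * config.e_ch2
    return total


def hbond_block_count(sequence: str, block: str) -> int:
    """Backbone hydrogen bonds per side of one molecule: one per residue
    of the stably bonded ``block`` motif, which must occur in the
    sequence (the empty block counts zero)."""
    _check_sequence(sequence)
    if block == "":
        return 0
    _check_sequence(block)
    if block not in sequence:
        raise ValueError(f"block {block!r} not found in sequence")
    return len(block)


def exchange_activation_estimate(
    sequence: str,
    config: EnergeticsConfig = EnergeticsConfig(),
    mode: str = "alkyl_calibration",
    block: str | None = None,
) -> dict[str, float]:
    """Lower-bound activation energy of molecular exchange, kJ/mol.

    Hydrophobic term per ``mode`` ("tanford" increments or
    "alkyl_calibration" scaling by aliphatic carbon count) plus the
    one-sided hydrogen-bond term (removing a molecule from a fiber end
    breaks the bonds on one side only).  ``block`` defaults to the
    longest central stretch bonded on both sides; pass it explicitly for
    sequences other than the K3W(QL)6K2 family.

    Returns a dict with the two terms and their ``total``.
    """
    if mode not in ("tanford", "alkyl_calibration"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_sequence(sequence)
    if block is None:
        block = _default_hbond_block(sequence)
    if mode == "tanford":
        hydrophobic = tanford_hydrophobic_energy(sequence, config)
    else:
        n_c = count_aliphatic_carbons(sequence)
        hydrophobic = config.alkyl_calibration * n_c / config.alkyl_calibration_carbons
    n_bonds = hbond_block_count(sequence, block) if block else 0
    hbond = n_bonds * config.e_hbond
    return {
        "hydrophobic": hydrophobic,
        "hbond": float(hbond),
        "n_hbonds_per_side": float(n_bonds),
        "total": hydrophobic + hbond,
    }


def _default_hbond_block(sequence: str) -> str:
    """Strip the charged lysine caps; what remains is the bonded core."""
    core = sequence.strip("K")
    if not core:
        return ""
    # keep one inner lysine adjacent to the core on the N side if present
    start = sequence.index(core)
    if start > 0:
        core = sequence[start - 1] + core
    return core


# ---------------------------------------------------------------------------
# circular dichroism
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CDSpectrum:
    """Raw CD data: wavelengths (nm), ellipticity (mdeg), and the sample
    description needed for normalization (molar concentration, residues
    per molecule, path length in mm)."""

    wavelength_nm: np.ndarray
    ellipticity_mdeg: np.ndarray
    concentration_m: float
    n_residues: int
    path_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelength_nm", np.asarray(self.wavelength_nm, float))
        object.__setattr__(self, "ellipticity_mdeg", np.asarray(self.ellipticity_mdeg, float))
        if self.wavelength_nm.size != self.ellipticity_mdeg.size:
            raise ValueError("wavelength and ellipticity lengths differ")
        if self.concentration_m <= 0 or self.path_mm <= 0:
            raise ValueError("concentration and path length must be positive")
        if self.n_residues < 1:
            raise ValueError("need at least one residue")


def mre_convert(spectrum: CDSpectrum) -> np.ndarray:
    """Molar residual ellipticity, deg cm^2/dmol.

        MRE(lambda) = theta_mdeg(lambda) / (10 * c * n * l)

    with c in mol/L, n the residue count and l the path length in cm.
    Linear in the raw signal and exactly invertible given (c, n, l).
    """
    l_cm = spectrum.path_mm / 10.0
    return spectrum.ellipticity_mdeg / (
        10.0 * spectrum.concentration_m * spectrum.n_residues * l_cm
    )


def mre_invert(mre, concentration_m: float, n_residues: int, path_mm: float) -> np.ndarray:
    """Raw ellipticity (mdeg) back from molar residual ellipticity."""
    l_cm = path_mm / 10.0
    return np.asarray(mre, float) * 10.0 * concentration_m * n_residues * l_cm
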