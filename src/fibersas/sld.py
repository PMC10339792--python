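"""Scattering length densities, peptide compositions and derived fiber mass.

X-ray SLDs are electron density times the classical electron radius;
neutron SLDs sum tabulated coherent scattering lengths over the molecular
formula.  Labile (exchangeable) hydrogens substitute H for D in proportion
to the solvent D2O fraction, which makes conjugate SLDs themselves depend
on the solvent — the zero-average-contrast (ZAC) solvent composition is
therefore found by 1-D root finding.

Small element tables are maintained here (coherent b in fm, average
atomic weight in Da, electron count); the deuteron is a distinct symbol
``D``.  Buffer salts at the tens-of-mM level shift the solvent SLD by
well under a percent and are ignored.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .formfactor import GCM3_TO_DA_A3, NanofiberGeometry

#: classical electron radius, cm
R_ELECTRON_CM = 2.8179403262e-13

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

# coherent neutron scattering length (fm), average atomic weight (Da),
# electron count -- the elements occurring in peptides, PEG and buffers
_ELEMENTS: dict[str, tuple[float, float, int]] = {
    "H": (-3.7406, 1.008, 1),
    "D": (6.671, 2.0141, 1),
    "C": (6.6460, 12.011, 6),
    "N": (9.36, 14.007, 7),
    "O": (5.803, 15.999, 8),
    "S": (2.847, 32.06, 16),
    "P": (5.13, 30.974, 15),
    "Na": (3.63, 22.990, 11),
    "Cl": (9.577, 35.45, 17),
    "K": (3.67, 39.098, 19),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: solvent densities at 25 C, g/mL
D2O_DENSITY = 1.107
H2O_DENSITY = 0.997


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``'C2H4O'``-style formulas into an element->count map.

    ``D`` is treated as its own symbol.  Raises on unknown symbols or
    leftover characters.
    """
    counts: Counter[str] = Counter()
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in _ELEMENTS:
            raise ValueError(f"unknown element symbol {sym!r} in {formula!r}")
        counts[sym] += int(num) if num else 1
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return dict(counts)


@dataclass(frozen=True)
class MaterialComposition:
    """A material defined by formula, mass density and labile-H count."""

    formula: dict[str, int]
    mass_density: float  # g/mL
    n_exchangeable_h: int = 0

    def __post_init__(self) -> None:
        if self.mass_density <= 0:
            raise ValueError("mass_density must be positive")
        if any(v < 0 for v in self.formula.values()):
            raise ValueError("negative element count")
        if self.n_exchangeable_h > self.formula.get("H", 0):
            raise ValueError("n_exchangeable_h exceeds the H count")
        for sym in self.formula:
            if sym not in _ELEMENTS:
                raise ValueError(f"unknown element {sym!r}")

    @classmethod
    def from_formula(
        cls, formula: str, mass_density: float, n_exchangeable_h: int = 0
    ) -> "MaterialComposition":
        return cls(parse_formula(formula), mass_density, n_exchangeable_h)

    @property
    def molar_mass(self) -> float:
        """Average molar mass in Da."""
        return sum(n * _ELEMENTS[s][1] for s, n in self.formula.items())

    @property
    def molecular_volume_a3(self) -> float:
        """Molecular volume in A^3 from molar mass and density."""
        return self.molar_mass / (self.mass_density * GCM3_TO_DA_A3)

    def combine(self, other: "MaterialComposition") -> "MaterialComposition":
        """Volume-additive combination (e.g. peptide + PEG conjugate)."""
        formula = dict(Counter(self.formula) + Counter(other.formula))
        mass = self.molar_mass + other.molar_mass
        vol = self.molecular_volume_a3 + other.molecular_volume_a3
        density = mass / (vol * GCM3_TO_DA_A3)
        return MaterialComposition(
            formula, density, self.n_exchangeable_h + other.n_exchangeable_h
        )


@dataclass(frozen=True)
class SolventSpec:
    """H2O/D2O mixture; dilute buffer salts are ignored for the SLD."""

    f_d2o: float = 0.0
    description: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_d2o <= 1.0:
            raise ValueError("f_d2o must lie in [0, 1]")


WATER_H = MaterialComposition.from_formula("H2O", H2O_DENSITY)
WATER_D = MaterialComposition.from_formula("D2O", D2O_DENSITY)


def xray_sld(comp: MaterialComposition) -> float:
    """X-ray scattering length density, 1/cm^2.

    Electron number density times the classical electron radius; isotopes
    share the electron count, so H/D substitution leaves it unchanged.
    """
    n_el = sum(n * _ELEMENTS[s][2] for s, n in comp.formula.items())
    if n_el == 0:
        return 0.0
    v_cm3 = comp.molecular_volume_a3 * 1e-24
    return R_ELECTRON_CM * n_el / v_cm3


def neutron_sld(
    comp: MaterialComposition,
    solvent: SolventSpec | None = None,
    exchange_fraction: float = 1.0,
) -> float:
    """Neutron scattering length density, 1/cm^2.

    Sums coherent scattering lengths over the formula.  Labile hydrogens
    (``comp.n_exchangeable_h``) are replaced by deuterium in proportion
    ``exchange_fraction * solvent.f_d2o``; the molecular volume is taken
    as isotope-independent.
    """
    if not 0.0 <= exchange_fraction <= 1.0:
        raise ValueError("exchange_fraction must lie in [0, 1]")
    if sum(comp.formula.values()) == 0:
        return 0.0
    b_fm = sum(n * _ELEMENTS[s][0] for s, n in comp.formula.items())
    if solvent is not None and comp.n_exchangeable_h > 0:
        swap = exchange_fraction * solvent.f_d2o * comp.n_exchangeable_h
        b_fm += swap * (_ELEMENTS["D"][0] - _ELEMENTS["H"][0])
    v_cm3 = comp.molecular_volume_a3 * 1e-24
    return b_fm * 1e-13 / v_cm3


def solvent_sld(f_d2o: float, radiation: str = "neutron") -> float:
    """Solvent SLD at D2O volume fraction ``f_d2o`` (linear mixing)."""
    if radiation == "neutron":
        lo, hi = neutron_sld(WATER_H), neutron_sld(WATER_D)
    elif radiation == "xray":
        lo, hi = xray_sld(WATER_H), xray_sld(WATER_D)
    else:
        raise ValueError(f"unknown radiation {radiation!r}")
    return (1.0 - f_d2o) * lo + f_d2o * hi


def solvent_sld_curve(f_d2o_grid, radiation: str = "neutron") -> np.ndarray:
    """Solvent SLD over a grid of D2O fractions."""
    grid = np.asarray(f_d2o_grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("f_d2o values must lie in [0, 1]")
    return np.array([solvent_sld(f, radiation) for f in grid])


def contrast_match_point(
    comp: MaterialComposition,
    exchange_fraction: float = 1.0,
    exchange_model: str = "full",
) -> float:
    """D2O fraction at which the solvent SLD equals the material's own.

    ``exchange_model`` follows :func:`zac_match_point`: ``"full"`` counts
    labile hydrogens as deuterated, ``"equilibrated"`` lets them track
    the solvent D2O fraction.
    """
    if exchange_model not in ("full", "equilibrated"):
        raise ValueError(f"unknown exchange_model {exchange_model!r}")

    def gap(f: float) -> float:
        if exchange_model == "full":
            own = _neutron_sld_labile(comp, exchange_fraction)
        else:
            own = neutron_sld(comp, SolventSpec(f), exchange_fraction)
        return solvent_sld(f) - own

    if gap(0.0) * gap(1.0) > 0:
        raise ValueError("no contrast match point in [0, 1]")
    return brentq(gap, 0.0, 1.0, xtol=1e-10)


def _neutron_sld_labile(comp: MaterialComposition, d_fraction: float) -> float:
    """Neutron SLD with the labile hydrogens deuterated to ``d_fraction``."""
    if sum(comp.formula.values()) == 0:
        return 0.0
    b_fm = sum(n * _ELEMENTS[s][0] for s, n in comp.formula.items())
    b_fm += d_fraction * comp.n_exchangeable_h * (_ELEMENTS["D"][0] - _ELEMENTS["H"][0])
    return b_fm * 1e-13 / (comp.molecular_volume_a3 * 1e-24)


def zac_match_point(
    conj_h: MaterialComposition,
    conj_d: MaterialComposition,
    exchange_fraction: float = 1.0,
    exchange_model: str = "full",
) -> float:
    """Zero-average-contrast solvent composition for an h/d conjugate pair.

    Returns the D2O volume fraction at which the solvent neutron SLD sits
    exactly midway between the two conjugates' volume-averaged SLDs, so
    that the two labelled species carry equal and opposite contrast.

    Two exchange models are available for the labile hydrogens:

    - ``"full"`` (default): labile sites are counted as fully deuterated
      (scaled by ``exchange_fraction``), the convention in which match
      points of exchangeable molecules are usually quoted;
    - ``"equilibrated"``: labile sites carry D in proportion to the
      solvent D2O fraction itself, making the conjugate SLDs f-dependent.

    Either way the residual is monotone in ``f_d2o`` (the solvent SLD
    grows faster than any exchange term), so the root found by bracketing
    is unique when it exists.
    """
    if exchange_model not in ("full", "equilibrated"):
        raise ValueError(f"unknown exchange_model {exchange_model!r}")

    def gap(f: float) -> float:
        if exchange_model == "full":
            mean = 0.5 * (
                _neutron_sld_labile(conj_h, exchange_fraction)
                + _neutron_sld_labile(conj_d, exchange_fraction)
            )
        else:
            sol = SolventSpec(f)
            mean = 0.5 * (
                neutron_sld(conj_h, sol, exchange_fraction)
                + neutron_sld(conj_d, sol, exchange_fraction)
            )
        return solvent_sld(f) - mean

    if gap(0.0) * gap(1.0) > 0:
        raise ValueError("no zero-average-contrast composition in [0, 1] D2O")
    return brentq(gap, 0.0, 1.0, xtol=1e-10)


# ---------------------------------------------------------------------------
# peptide sequences
# ---------------------------------------------------------------------------

# average-mass residue formulas (residue = amino acid - H2O)
_RESIDUES: dict[str, dict[str, int]] = {
    "G": parse_formula("C2H3NO"),
    "A": parse_formula("C3H5NO"),
    "S": parse_formula("C3H5NO2"),
    "P": parse_formula("C5H7NO"),
    "V": parse_formula("C5H9NO"),
    "T": parse_formula("C4H7NO2"),
    "C": parse_formula("C3H5NOS"),
    "L": parse_formula("C6H11NO"),
    "I": parse_formula("C6H11NO"),
    "N": parse_formula("C4H6N2O2"),
    "D": parse_formula("C4H5NO3"),
    "Q": parse_formula("C5H8N2O2"),
    "K": parse_formula("C6H12N2O"),
    "E": parse_formula("C5H7NO3"),
    "M": parse_formula("C5H9NOS"),
    "H": parse_formula("C6H7N3O"),
    "F": parse_formula("C9H9NO"),
    "R": parse_formula("C6H12N4O"),
    "Y": parse_formula("C9H9NO2"),
    "W": parse_formula("C11H10N2O"),
}

# labile hydrogens per residue: one backbone amide N-H (except proline)
# plus side-chain N-H/O-H in the neutral form
_RESIDUE_LABILE_H: dict[str, int] = {
    "G": 1, "A": 1, "S": 2, "P": 0, "V": 1, "T": 2, "C": 2, "L": 1,
    "I": 1, "N": 3, "D": 2, "Q": 3, "K": 3, "E": 2, "M": 1, "H": 2,
    "F": 1, "R": 5, "Y": 2, "W": 2,
}

# backbone unit N-H-C(alpha)H-C=O shared by every residue; the side chain
# is the residue formula minus this
_BACKBONE = parse_formula("C2H2NO")

# terminal modifications as formula deltas relative to the bare chain
# (chain = sum of residues + H2O); labile-H delta alongside
_TERMINAL_MODS: dict[str, tuple[dict[str, int], int]] = {
    # N-terminus
    "free_amine": ({}, 1),  # NH2 already has 2 H counted via chain H2O split; +1 labile
    "acetyl": ({"C": 2, "H": 2, "O": 1}, 0),  # -H +COCH3 on the amine
    # C-terminus
    "free_acid": ({}, 1),
    "amide": ({"N": 1, "H": 1, "O": -1}, 2),  # -OH +NH2
}


def _check_sequence(sequence: str) -> None:
    for ch in sequence:
        if ch not in _RESIDUES:
            raise ValueError(f"unknown amino-acid letter {ch!r}")


def sequence_composition(
    sequence: str,
    n_term: str = "acetyl",
    c_term: str = "amide",
    mass_density: float = 1.25,
) -> MaterialComposition:
    """Composition of a peptide given as a one-letter sequence.

    Defaults match solid-phase synthesis products: acetylated N-terminus
    and C-terminal amide.  The labile-hydrogen count collects backbone
    amides plus side-chain N-H/O-H.
    """
    _check_sequence(sequence)
    if n_term not in ("acetyl", "free_amine"):
        raise ValueError(f"unknown N-terminal modification {n_term!r}")
    if c_term not in ("amide", "free_acid"):
        raise ValueError(f"unknown C-terminal modification {c_term!r}")
    formula: Counter[str] = Counter({"H": 2, "O": 1})  # chain-terminating water
    labile = 0
    for ch in sequence:
        formula.update(_RESIDUES[ch])
        labile += _RESIDUE_LABILE_H[ch]
    for mod in (n_term, c_term):
        delta, dl = _TERMINAL_MODS[mod]
        formula.update(delta)
        labile += dl
    if sequence and sequence[0] == "P" and n_term == "free_amine":
        labile -= 1  # proline has no backbone N-H to start with
    formula = Counter({k: v for k, v in formula.items() if v != 0})
    return MaterialComposition(dict(formula), mass_density, labile)


def sequence_mass(sequence: str, n_term: str = "acetyl", c_term: str = "amide") -> float:
    """Average molar mass (Da) of a peptide from its one-letter sequence."""
    return sequence_composition(sequence, n_term, c_term).molar_mass


def side_chain_formula(letter: str) -> dict[str, int]:
    """Side-chain formula of one residue (residue minus the backbone unit)."""
    _check_sequence(letter)
    out = Counter(_RESIDUES[letter])
    out.subtract(_BACKBONE)
    if any(v < 0 for v in out.values()):
        raise ValueError(f"residue {letter!r} smaller than the backbone unit")
    return {k: v for k, v in out.items() if v > 0}


# ---------------------------------------------------------------------------
# derived fiber quantities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DerivedFiberQuantities:
    """Per-fiber and per-molecule mass/volume bookkeeping."""

    n_agg: float
    m_core: float  # Da per molecule
    m_shell: float
    m_pep: float
    v_core: float  # A^3 per fiber
    v_shell: float
    v_pep: float


def derive_fiber_quantities(
    geom: NanofiberGeometry, d_core: float, d_shell: float, m_pep: float
) -> DerivedFiberQuantities:
    """Aggregation number and per-molecule masses from geometry + densities.

    The fiber masses follow from region volumes and mass densities
    (1 g/cm^3 = 0.60221 Da/A^3); dividing the total by the molecular mass
    gives the number of molecules per fiber, and per-molecule core/shell
    masses follow by division.
    """
    if d_core <= 0 or d_shell <= 0:
        raise ValueError("densities must be positive")
    if m_pep <= 0:
        raise ValueError("m_pep must be positive")
    v_core, v_shell, v_pep = geom.v_core, geom.v_shell, geom.v_pep
    if v_shell < 0:
        raise ValueError("negative shell volume")
    mass_core = v_core * d_core * GCM3_TO_DA_A3
    mass_shell = v_shell * d_shell * GCM3_TO_DA_A3
    n_agg = (mass_core + mass_shell) / m_pep
    if n_agg == 0:
        return DerivedFiberQuantities(0.0, 0.0, 0.0, m_pep, v_core, v_shell, v_pep)
    return DerivedFiberQuantities(
        n_agg=n_agg,
        m_core=mass_core / n_agg,
        m_shell=mass_shell / n_agg,
        m_pep=m_pep,
        v_core=v_core,
        v_shell=v_shell,
        v_pep=v_pep,
    )


# ---------------------------------------------------------------------------
# reference materials for the K3W(QL)6K2 system
# ---------------------------------------------------------------------------

#: hydrogenous PEG repeat density, g/mL (amorphous PEG ~2 kDa)
PEG_H_DENSITY = 1.13

SEQ_K3WQL6K2 = "KKKW" + "QL" * 6 + "KK"


def peg_composition(molar_mass: float, deuterated: bool = False) -> MaterialComposition:
    """PEG chain of given molar mass as repeat units (C2H4O / C2D4O).

    The repeat count is ``molar_mass`` over the repeat mass (end groups
    are neglected at the 2 kDa scale); the deuterated chain density is
    the hydrogenous one scaled by the repeat-mass ratio (equal chain
    volume).
    """
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    unit = parse_formula("C2D4O" if deuterated else "C2H4O")
    unit_mass = sum(n * _ELEMENTS[s][1] for s, n in unit.items())
    n_rep = max(1, round(molar_mass / unit_mass))
    h_unit_mass = sum(n * _ELEMENTS[s][1] for s, n in parse_formula("C2H4O").items())
    density = PEG_H_DENSITY * unit_mass / h_unit_mass
    return MaterialComposition({s: n * n_rep for s, n in unit.items()}, density, 0)


def k3wql6k2_conjugates() -> tuple[MaterialComposition, MaterialComposition]:
    """(hPEG, dPEG) conjugates of Ac-K3W(QL)6K2: 1.9 / 2.1 kg/mol PEG."""
    pep = sequence_composition(SEQ_K3WQL6K2)
    return (
        pep.combine(peg_composition(1900.0, deuterated=False)),
        pep.combine(peg_composition(2100.0, deuterated=True)),
    )


def region_compositions(
    sequence: str = SEQ_K3WQL6K2,
    core_residues: str = "LW",
    d_core: float = 0.95,
    d_shell: float = 1.36,
) -> tuple[MaterialComposition, MaterialComposition]:
    """(core, shell) compositions of the fiber cross-section.

    The hydrophobic core collects the side chains of ``core_residues``
    (leucine and tryptophan by default); the shell takes the backbone,
    termini and the remaining side chains.
    """
    _check_sequence(sequence)
    full = sequence_composition(sequence)
    core: Counter[str] = Counter()
    core_labile = 0
    for ch in sequence:
        if ch in core_residues:
            core.update(side_chain_formula(ch))
            # side-chain labile H only (backbone amide sits in the shell)
            core_labile += max(0, _RESIDUE_LABILE_H[ch] - 1)
    shell = Counter(full.formula)
    shell.subtract(core)
    if any(v < 0 for v in shell.values()):
        raise ValueError("core formula exceeds the full peptide")
    core_comp = MaterialComposition(dict(core), d_core, core_labile)
    shell_comp = MaterialComposition(
        {k: v for k, v in shell.items() if v > 0},
        d_shell,
        full.n_exchangeable_h - core_labile,
    )
    return core_comp, shell_comp
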