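"""Rectangular core-shell(-shell) nanofiber form factor.

The scattering model describes long fibers of stacked antiparallel
beta-sheets: a hydrophobic core (leucine/tryptophan side chains) of
cross-section ``a_core x b_core``, wrapped by a peptide shell (backbone +
hydrophilic residues) of thicknesses ``a_shell``/``b_shell``, optionally
wrapped by a solvent-swollen PEG layer of thickness ``d``.  The fiber
length ``c`` greatly exceeds the cross-section, so the intensity
factorizes (decoupling approximation) into a rotationally averaged
cross-section term times the longitudinal factor of an infinitely thin
rod.  Density fluctuations inside the PEG corona add an incoherent-like
"blob" term with a Beaucage form.

Units: lengths in Angstrom, Q in 1/Angstrom, SLD in 1/cm^2, intensity in
1/cm.  Amplitudes are dimensionless (1 at Q = 0); all contrast x volume
weights are applied when the cross-section amplitude is assembled, so
every region's weight stays explicit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf, sici

logger = logging.getLogger(__name__)

#: conversion of one cubic Angstrom to cm^3
A3_TO_CM3 = 1e-24

#: 1 g/cm^3 expressed in Da per cubic Angstrom
GCM3_TO_DA_A3 = 0.60221

# rotational average: Gauss-Legendre on [0, pi/2]; node count doubles
# until the relative change of the average drops below this tolerance
QUAD_NODES_DEFAULT = 256
QUAD_RTOL = 1e-4
QUAD_NODES_MAX = 2048

_gauss_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights mapped to [0, pi/2], cached."""
    if n not in _gauss_cache:
        x, w = np.polynomial.legendre.leggauss(n)
        half = np.pi / 4.0
        _gauss_cache[n] = (half * (x + 1.0), half * w)
    return _gauss_cache[n]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NanofiberGeometry:
    """Cross-section and length of the rectangular nanofiber.

    ``a_core``/``b_core`` are the full core edges, ``a_shell``/``b_shell``
    the peptide-shell thicknesses (added on both sides), ``c`` the fiber
    length and ``d`` the PEG-layer thickness (0 for non-PEGylated fibers).
    """

    a_core: float
    a_shell: float
    b_core: float
    b_shell: float
    c: float
    d: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a_core", "a_shell", "b_core", "b_shell", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.c <= max(self.a_tot, self.b_tot):
            raise ValueError(
                "fiber length c must exceed the cross-section "
                f"(c={self.c}, a_tot={self.a_tot}, b_tot={self.b_tot})"
            )
        if self.c < 10.0 * max(self.a_tot, self.b_tot):
            # flagged, not rejected: the decoupling approximation is only
            # approximate here (default warning filter shows this once)
            warnings.warn(
                f"c = {self.c:.3g} < 10 x max cross-section: decoupling "
                "approximation is only approximate in this regime",
                stacklevel=2,
            )

    @property
    def a_pep(self) -> float:
        return self.a_core + 2.0 * self.a_shell

    @property
    def b_pep(self) -> float:
        return self.b_core + 2.0 * self.b_shell

    @property
    def a_tot(self) -> float:
        return self.a_pep + 2.0 * self.d

    @property
    def b_tot(self) -> float:
        return self.b_pep + 2.0 * self.d

    # region volumes (A^3), shell/PEG as differences of nested boxes
    @property
    def v_core(self) -> float:
        return self.a_core * self.b_core * self.c

    @property
    def v_pep(self) -> float:
        return self.a_pep * self.b_pep * self.c

    @property
    def v_shell(self) -> float:
        return self.v_pep - self.v_core

    @property
    def v_tot(self) -> float:
        return self.a_tot * self.b_tot * self.c

    @property
    def v_peg_layer(self) -> float:
        return self.v_tot - self.v_pep


@dataclass(frozen=True)
class ContrastSet:
    """Scattering length densities of the three regions and the solvent.

    All SLDs in 1/cm^2.  ``radiation`` is ``"xray"`` or ``"neutron"``;
    X-ray SLDs must be non-negative (electron densities are).
    """

    rho_core: float
    rho_shell: float
    rho_peg: float
    rho_solv: float
    radiation: str = "xray"

    def __post_init__(self) -> None:
        if self.radiation not in ("xray", "neutron"):
            raise ValueError(f"radiation must be 'xray' or 'neutron', got {self.radiation!r}")
        if self.radiation == "xray":
            for name in ("rho_core", "rho_shell", "rho_peg", "rho_solv"):
                if getattr(self, name) < 0:
                    raise ValueError(f"X-ray SLD {name} must be >= 0")

    @property
    def drho_core(self) -> float:
        return self.rho_core - self.rho_solv

    @property
    def drho_shell(self) -> float:
        return self.rho_shell - self.rho_solv

    @property
    def drho_peg(self) -> float:
        return self.rho_peg - self.rho_solv


@dataclass(frozen=True)
class NanofiberModel:
    """Full parameter set of the nanofiber scattering model.

    ``n_agg`` is the number of peptide molecules per fiber, ``v_peg`` the
    molecular volume of one PEG chain (A^3), ``rg_blob`` the radius of
    gyration of the PEG blobs, ``phi`` the fiber volume fraction and
    ``background`` the flat incoherent background (1/cm).
    """

    geometry: NanofiberGeometry
    contrasts: ContrastSet
    n_agg: float = 180.0
    v_peg: float = 2790.0
    rg_blob: float = 15.0
    phi: float = 0.008
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.n_agg < 1:
            raise ValueError("n_agg must be >= 1")
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (0, 1)")
        if self.background < 0:
            raise ValueError("background must be >= 0")

    def with_contrasts(self, contrasts: ContrastSet) -> "NanofiberModel":
        return replace(self, contrasts=contrasts)


# ---------------------------------------------------------------------------
# amplitudes
# ---------------------------------------------------------------------------


def rect_amplitude(q, alpha, a: float, b: float):
    """Normalized scattering amplitude of a rectangular cross-section.

    The product of cardinal sines of the two edge projections,

        A(Q, alpha) = sinc(Q a cos(alpha) / 2) * sinc(Q b sin(alpha) / 2),

    with sinc(x) = sin(x)/x.  Equals 1 at Q = 0 and is symmetric under
    swapping (a, b) together with alpha -> pi/2 - alpha.

    Parameters
    ----------
    q : float or array
        Scattering vector magnitude, 1/A.
    alpha : float or array
        In-plane rotation angle, radians.
    a, b : float
        Edge lengths, A; must be positive.
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"edge lengths must be positive, got a={a}, b={b}")
    q = np.asarray(q, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    return np.sinc(q * a * np.cos(alpha) / (2.0 * np.pi)) * np.sinc(
        q * b * np.sin(alpha) / (2.0 * np.pi)
    )


def cross_section_amplitude(q, alpha, model: NanofiberModel):
    """Contrast- and volume-weighted cross-section amplitude.

    Superposition of the three nested rectangle amplitudes in which each
    physical region (core; shell = peptide envelope minus core; PEG layer
    = total minus peptide envelope) carries its own excess SLD:

        A(Q, a) = drho_core V_core A_core
                + drho_shell (V_pep A_pep - V_core A_core)
                + drho_peg  (V_tot A_tot - V_pep A_pep)

    Volumes in A^3, SLDs in 1/cm^2.  For ``d = 0`` the PEG term vanishes
    identically and the expression reduces to the two-region model.
    """
    g, con = model.geometry, model.contrasts
    a_core = g.v_core * rect_amplitude(q, alpha, g.a_core, g.b_core) if g.v_core > 0 else 0.0
    a_pep = g.v_pep * rect_amplitude(q, alpha, g.a_pep, g.b_pep)
    out = con.drho_core * a_core + con.drho_shell * (a_pep - a_core)
    if g.d > 0:
        a_tot = g.v_tot * rect_amplitude(q, alpha, g.a_tot, g.b_tot)
        out = out + con.drho_peg * (a_tot - a_pep)
    return out


def rod_factor(q, c: float):
    """Longitudinal factor of an infinitely thin rod of length ``c``.

        L(Q) = 2 Si(Qc)/(Qc) - 4 sin^2(Qc/2)/(Qc)^2

    with Si the sine integral.  Equals 1 at Q = 0 and decays as
    pi/(Qc) for Qc >> 1.
    """
    if c <= 0:
        raise ValueError("rod length c must be positive")
    scalar = np.isscalar(q) or np.ndim(q) == 0
    x = np.atleast_1d(np.asarray(q, dtype=float)) * c
    out = np.ones_like(x)
    nz = x > 0
    si = sici(x[nz])[0]
    out[nz] = 2.0 * si / x[nz] - 4.0 * np.sin(x[nz] / 2.0) ** 2 / x[nz] ** 2
    return float(out[0]) if scalar else out


def blob_scattering(q, rg: float, n_agg: float, v_peg: float, drho_peg: float):
    """Blob scattering of the PEG corona, per fiber.

    ``n_agg`` Gaussian-coil blobs added incoherently, each weighted by
    (drho_peg * v_peg)^2, with a simple Beaucage form of exponent 2:

        I_blob(Q) = n_agg (drho v)^2 [exp(-x^2/3) + (2/Rg^2) (erf(x/sqrt 6)^3 / Q)^2]

    where x = Q Rg.  Returned in units of (cm^-2 A^3)^2 like the squared
    cross-section amplitude, so it enters the absolute-scale assembly on
    the same footing.
    """
    if rg <= 0:
        raise ValueError("rg must be positive")
    q = np.asarray(q, dtype=float)
    x = q * rg
    guinier = np.exp(-x * x / 3.0)
    # power-law branch: B = 2 G / Rg^2 for a Gaussian chain (df = 2)
    qstar = np.where(q > 0, erf(x / np.sqrt(6.0)) ** 3 / np.where(q > 0, q, 1.0), 0.0)
    powerlaw = (2.0 / rg**2) * qstar**2
    shape = guinier + powerlaw
    return n_agg * (drho_peg * v_peg) ** 2 * shape


# ---------------------------------------------------------------------------
# intensity assembly
# ---------------------------------------------------------------------------


def cross_section_average(q_grid, model: NanofiberModel, n_nodes: int | None = None):
    """Rotational average <|A(Q, alpha)|^2> over alpha in [0, pi/2].

    Gauss-Legendre quadrature; when ``n_nodes`` is None the node count
    starts at 256 and doubles until the relative change is below 1e-4
    (the integrand oscillates at high Q*b).
    """
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))

    def average(n: int) -> np.ndarray:
        nodes, weights = _gauss_nodes(n)
        amp = cross_section_amplitude(q[:, None], nodes[None, :], model)
        return (amp**2 * weights[None, :]).sum(axis=1) * (2.0 / np.pi)

    if n_nodes is not None:
        return average(n_nodes)
    n = QUAD_NODES_DEFAULT
    prev = average(n)
    while n < QUAD_NODES_MAX:
        n *= 2
        cur = average(n)
        scale = np.max(np.abs(cur)) or 1.0
        if np.max(np.abs(cur - prev)) <= QUAD_RTOL * scale:
            return cur
        prev = cur
    logger.warning("rotational average not converged at %d nodes", QUAD_NODES_MAX)
    return prev


def nanofiber_intensity(q_grid, model: NanofiberModel, n_nodes: int | None = None):
    """Absolute-scale scattered intensity of the nanofiber model, 1/cm.

        I(Q) = phi / V_pep * [ <|A(Q,alpha)|^2> L(Q; c) + I_blob(Q) ] + bkg

    ``phi`` is the peptide volume fraction (what the sample concentration
    fixes), so the fiber number density is phi / V_pep; the solvent-
    swollen PEG corona carries no volume fraction of its own, which makes
    the intensity invariant under adding a contrast-matched corona.  The
    forward limit obeys, exactly,

        I(0) - bkg = phi/V_pep * [ (sum_i drho_i V_i)^2 + n_agg (drho_peg v_peg)^2 ]

    where the second term is absent for d = 0 (no PEG corona) and
    V_pep = V_tot there.

    Parameters
    ----------
    q_grid : array
        Scattering vectors, 1/A; must be non-negative and non-empty.
    model : NanofiberModel
    n_nodes : int, optional
        Fixed quadrature node count (skips adaptive doubling); useful
        inside fit loops.
    """
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    if q.size == 0:
        raise ValueError("empty Q grid")
    if np.any(q < 0):
        raise ValueError("negative Q values")
    g = model.geometry
    coherent = cross_section_average(q, model, n_nodes=n_nodes) * rod_factor(q, g.c)
    total = coherent
    if g.d > 0 and model.contrasts.drho_peg != 0.0:
        total = total + blob_scattering(
            q, model.rg_blob, model.n_agg, model.v_peg, model.contrasts.drho_peg
        )
    # (cm^-2 A^3)^2 / A^3 -> cm^-1 requires one A^3 -> cm^3 conversion
    return model.phi / g.v_pep * A3_TO_CM3 * total + model.background


def forward_intensity(model: NanofiberModel) -> float:
    """Closed-form I(0) - background (coherent + blob terms)."""
    g, con = model.geometry, model.contrasts
    coh = con.drho_core * g.v_core + con.drho_shell * g.v_shell
    blob = 0.0
    if g.d > 0:
        coh += con.drho_peg * g.v_peg_layer
        blob = model.n_agg * (con.drho_peg * model.v_peg) ** 2
    return model.phi / g.v_pep * A3_TO_CM3 * (coh**2 + blob)
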