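"""Companion scattering models for dissolved or partially assembled peptides.

When electrostatic repulsion wins over hydrogen bonding and hydrophobic
attraction (extra lysines, low pH) the fibers fall apart and the curves
are those of dissolved random chains: the Beaucage unified model, with an
optional inter-particle structure factor when the charged unimers repel
strongly enough to produce a correlation peak.  A homogeneous-filament
model (the contrast-collapsed limit of the core-shell fiber) is kept for
comparison with older analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .formfactor import (
    A3_TO_CM3,
    GCM3_TO_DA_A3,
    ContrastSet,
    NanofiberGeometry,
    NanofiberModel,
    nanofiber_intensity,
)
from .sld import N_AVOGADRO

# ---------------------------------------------------------------------------
# Beaucage unified model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeaucageParams:
    """Unified Guinier/power-law parameters.

    ``g`` is the forward intensity (1/cm), ``rg`` the radius of gyration
    (A), ``b`` the power-law prefactor and ``df`` the power-law exponent
    (2 for a Gaussian chain).  ``b = None`` selects the Gaussian-chain
    consistency value df*g*Gamma(df/2)/rg^df.
    """

    g: float
    rg: float
    b: float | None = None
    df: float = 2.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.g <= 0 or self.rg <= 0:
            raise ValueError("g and rg must be positive")
        if not 1.0 <= self.df <= 4.0:
            raise ValueError("df must lie in [1, 4]")

    @property
    def b_effective(self) -> float:
        from math import gamma

        if self.b is not None:
            return self.b
        return self.df * self.g * gamma(self.df / 2.0) / self.rg**self.df


def beaucage_intensity(q_grid, params: BeaucageParams) -> np.ndarray:
    """Beaucage unified intensity, 1/cm.

        I(Q) = G exp(-Q^2 Rg^2/3) + B (erf(Q Rg / sqrt 6)^3 / Q)^df + bkg

    Forward value G + bkg; high-Q slope -df on log-log axes.
    """
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    x = q * params.rg
    guinier = params.g * np.exp(-x * x / 3.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        qstar = np.where(q > 0, erf(x / np.sqrt(6.0)) ** 3 / np.where(q > 0, q, 1.0), 0.0)
    return guinier + params.b_effective * qstar**params.df + params.background


def mw_from_forward(g: float, conc_g_ml: float, drho: float, vbar_ml_g: float) -> float:
    """Molar mass (g/mol) from the forward intensity of a dilute solution.

    Uses I(0) = c M (drho vbar)^2 / N_A with c in g/cm^3, drho in 1/cm^2
    and the partial specific volume vbar in cm^3/g (1/d_pep).
    """
    if conc_g_ml <= 0 or drho == 0 or vbar_ml_g <= 0:
        raise ValueError("need positive concentration and vbar, nonzero contrast")
    return g * N_AVOGADRO / (conc_g_ml * (drho * vbar_ml_g) ** 2)


# ---------------------------------------------------------------------------
# structure factors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureFactorParams:
    """Inter-particle correlation parameters.

    ``volume_fraction`` and ``effective_radius`` define the hard-sphere
    reference (Percus-Yevick closure); ``coupling``/``screening_length``
    switch on a screened-Coulomb repulsion treated in the random-phase
    approximation on top of the hard-sphere fluid.
    """

    volume_fraction: float
    effective_radius: float
    coupling: float = 0.0  # dimensionless repulsion strength
    screening_length: float = 0.0  # A

    def __post_init__(self) -> None:
        if not 0.0 <= self.volume_fraction < 0.74:
            raise ValueError("volume_fraction must lie in [0, 0.74)")
        if self.effective_radius <= 0:
            raise ValueError("effective_radius must be positive")
        if self.coupling < 0 or self.screening_length < 0:
            raise ValueError("repulsion parameters must be >= 0")


def percus_yevick_sq(q_grid, volume_fraction: float, radius: float) -> np.ndarray:
    """Analytic Percus-Yevick hard-sphere structure factor.

    S(Q) = 1 / (1 + 24 eta G(2QR)/(2QR)) with the standard Ashcroft-
    Lekner G built from the PY direct correlation function.
    """
    eta = volume_fraction
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    if eta == 0.0:
        return np.ones_like(q)
    x = 2.0 * q * radius  # Q * sigma with sigma the hard-sphere diameter
    alpha = (1.0 + 2.0 * eta) ** 2 / (1.0 - eta) ** 4
    beta = -6.0 * eta * (1.0 + eta / 2.0) ** 2 / (1.0 - eta) ** 4
    gamma = eta * alpha / 2.0
    out = np.empty_like(x)
    small = x < 1e-4
    xs = x[~small]
    sin, cos = np.sin(xs), np.cos(xs)
    g = (
        alpha * (sin - xs * cos) / xs**2
        + beta * (2.0 * xs * sin + (2.0 - xs**2) * cos - 2.0) / xs**3
        + gamma
        * (-(xs**4) * cos + 4.0 * ((3.0 * xs**2 - 6.0) * cos + (xs**3 - 6.0 * xs) * sin + 6.0))
        / xs**5
    )
    out[~small] = 1.0 / (1.0 + 24.0 * eta * g / xs)
    # Q -> 0 limit: isothermal compressibility of the PY fluid
    out[small] = (1.0 - eta) ** 4 / (1.0 + 2.0 * eta) ** 2
    return out


def screened_coulomb_sq(q_grid, params: StructureFactorParams) -> np.ndarray:
    """Hard-sphere + screened-Coulomb structure factor (RPA).

    1/S(Q) = 1/S_PY(Q) + coupling / (1 + (Q lambda)^2), a random-phase
    treatment of a repulsive Yukawa tail over the Percus-Yevick fluid.
    Approximate but captures the correlation peak of charged unimers.
    """
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    s_hs = percus_yevick_sq(q, params.volume_fraction, params.effective_radius)
    inv = 1.0 / s_hs + params.coupling / (1.0 + (q * params.screening_length) ** 2)
    return 1.0 / inv


def structure_factor(q_grid, params: StructureFactorParams) -> np.ndarray:
    """S(Q) for the given parameters; pure PY when the coupling is zero."""
    if params.coupling > 0:
        return screened_coulomb_sq(q_grid, params)
    return percus_yevick_sq(q_grid, params.volume_fraction, params.effective_radius)


def apply_structure_factor(intensity, q_grid, params: StructureFactorParams) -> np.ndarray:
    """Element-wise P(Q) S(Q) under the decoupling approximation."""
    p = np.atleast_1d(np.asarray(intensity, dtype=float))
    s = structure_factor(q_grid, params)
    if p.shape != s.shape:
        raise ValueError("intensity and Q grid shapes differ")
    return p * s


# ---------------------------------------------------------------------------
# uniform filament
# ---------------------------------------------------------------------------


def uniform_filament_intensity(
    q_grid, a: float, b: float, c: float, drho: float, phi: float, background: float = 0.0
) -> np.ndarray:
    """Homogeneous rectangular filament, 1/cm.

    The contrast-collapsed limit of the core-shell fiber: a single box of
    edges a < b << c with uniform excess SLD ``drho``.  The ordering
    a < b < c is conventional; violations only warn via the geometry's
    decoupling check.
    """
    geom = NanofiberGeometry(a_core=a, a_shell=0.0, b_core=b, b_shell=0.0, c=c)
    contrasts = ContrastSet(
        rho_core=drho, rho_shell=drho, rho_peg=0.0, rho_solv=0.0, radiation="neutron"
    )
    model = NanofiberModel(
        geometry=geom, contrasts=contrasts, phi=phi, background=background
    )
    return nanofiber_intensity(q_grid, model)


def uniform_filament_forward(a: float, b: float, c: float, drho: float, phi: float) -> float:
    """Closed-form forward intensity phi V drho^2 of the uniform filament."""
    return phi * a * b * c * A3_TO_CM3 * drho**2
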