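"""Synthetic beamline data: noisy curves, contrast series, ZAC decays.

Every input the analysis pipeline expects can be generated here from a
known ground truth, so parameter-recovery and kinetics logic are testable
end to end.  Defaults mirror the measurement conditions of the nanofiber
study this package models: Q grids of 0.004-0.7 1/A, 2% relative noise
with a 1e-3 1/cm floor, 10 mg/mL samples (phi ~ 0.8%), five-contrast
H2O/D2O series, and 50/50 h/d-labelled blends at the zero-average-
contrast solvent composition.

The exchange-kinetics simulation is mean-field: each fiber population is
tracked by the h-fraction of its PEG corona rather than per-molecule
labels, which is sufficient because the scattered intensity senses only
the population-level shell contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import sld
from .formfactor import ContrastSet, NanofiberModel, nanofiber_intensity
from .io import ScatteringCurve

#: default noise model, matching good synchrotron/reactor data quality
NOISE_RELATIVE = 0.02
NOISE_FLOOR = 1e-3  # 1/cm


@dataclass(frozen=True)
class QGridSpec:
    """Q-grid specification: bounds (1/A), point count, spacing."""

    q_min: float = 0.004
    q_max: float = 0.7
    n_points: int = 100
    spacing: str = "log"

    def __post_init__(self) -> None:
        if not 0 < self.q_min < self.q_max:
            raise ValueError("need 0 < q_min < q_max")
        if self.n_points < 2:
            raise ValueError("need at least 2 points")
        if self.spacing not in ("log", "linear"):
            raise ValueError("spacing must be 'log' or 'linear'")

    def build(self) -> np.ndarray:
        if self.spacing == "log":
            return np.logspace(np.log10(self.q_min), np.log10(self.q_max), self.n_points)
        return np.linspace(self.q_min, self.q_max, self.n_points)


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground truth + grid + noise + seed for one synthetic measurement."""

    model: NanofiberModel
    grid: QGridSpec = QGridSpec()
    noise_relative: float = NOISE_RELATIVE
    noise_floor: float = NOISE_FLOOR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_relative < 0 or self.noise_floor < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class ExchangeMechanism:
    """How molecules move between fibers in the ZAC blend.

    ``end_only``: only the ``n_end`` molecules at each fiber end are
    accessible; the mixed fraction saturates at 2 n_end / n_agg and the
    intensity plateaus above the fully mixed baseline.  ``uniform_unimer``:
    any molecule can leave, single-exponential relaxation to complete
    mixing.  ``breakup_reform``: fiber scission events rescramble whole
    fibers, also relaxing to complete mixing.  ``rate`` is the relaxation
    rate in inverse time units of the supplied time grid.
    """

    kind: str = "end_only"
    rate: float = 1.0
    n_end: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("end_only", "uniform_unimer", "breakup_reform"):
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.n_end < 0:
            raise ValueError("n_end must be >= 0")

    def accessible_fraction(self, n_agg: float) -> float:
        if self.kind == "end_only":
            if self.n_end > n_agg / 2.0:
                raise ValueError("n_end exceeds n_agg/2")
            return 2.0 * self.n_end / n_agg
        return 1.0

    def mixed_fraction(self, t: float, n_agg: float) -> float:
        """Fraction of each shell's initial excess label lost by time t."""
        f_acc = self.accessible_fraction(n_agg)
        return f_acc * (1.0 - np.exp(-self.rate * t))


def simulate_curve(scenario: SyntheticScenario) -> ScatteringCurve:
    """Noisy realization of the ground-truth model.

    sigma(Q) = rel * I_true(Q) + floor, stored in the sigma column and
    used to draw independent Gaussian noise; the seed fixes the bytes.
    """
    q = scenario.grid.build()
    i_true = nanofiber_intensity(q, scenario.model)
    sigma = scenario.noise_relative * np.abs(i_true) + scenario.noise_floor
    rng = np.random.default_rng(scenario.seed)
    if scenario.noise_relative == 0 and scenario.noise_floor == 0:
        noisy, sigma_out = i_true, np.full_like(q, 1e-12)
    else:
        noisy = i_true + rng.normal(0.0, sigma)
        sigma_out = sigma
    return ScatteringCurve(
        q,
        noisy,
        sigma_out,
        metadata={
            "radiation": scenario.model.contrasts.radiation,
            "seed": scenario.seed,
            "label": "synthetic",
        },
    )


def contrast_set_at(
    f_d2o: float,
    core: sld.MaterialComposition,
    shell: sld.MaterialComposition,
    peg: sld.MaterialComposition | None = None,
    exchange_fraction: float = 1.0,
) -> ContrastSet:
    """Neutron contrasts of the fiber regions at one D2O fraction."""
    sol = sld.SolventSpec(f_d2o)
    rho_peg = sld.neutron_sld(peg, sol, exchange_fraction) if peg is not None else 0.0
    return ContrastSet(
        rho_core=sld.neutron_sld(core, sol, exchange_fraction),
        rho_shell=sld.neutron_sld(shell, sol, exchange_fraction),
        rho_peg=rho_peg,
        rho_solv=sld.solvent_sld(f_d2o),
        radiation="neutron",
    )


def simulate_contrast_series(
    scenario: SyntheticScenario,
    f_d2o_list,
    core: sld.MaterialComposition,
    shell: sld.MaterialComposition,
    peg: sld.MaterialComposition | None = None,
    exchange_fraction: float = 1.0,
) -> list[ScatteringCurve]:
    """One noisy curve per H2O/D2O contrast, shared geometry and truth.

    Region SLDs are recomputed per contrast from the compositions, so at
    the PEG match point the corona (layer and blob terms alike)
    contributes nothing.  Curve ``i`` uses seed ``scenario.seed + i``.
    """
    curves = []
    for i, f in enumerate(f_d2o_list):
        contrasts = contrast_set_at(f, core, shell, peg, exchange_fraction)
        model = scenario.model.with_contrasts(contrasts)
        sub = replace(scenario, model=model, seed=scenario.seed + i)
        curve = simulate_curve(sub)
        curve.metadata["f_d2o"] = float(f)
        curves.append(curve)
    return curves


def zac_blend_intensity(
    q,
    model: NanofiberModel,
    rho_peg_h: float,
    rho_peg_d: float,
    mixed_fraction: float,
) -> np.ndarray:
    """Intensity of a 50/50 h/d blend after partial shell mixing.

    Population A starts with an all-h corona, B with all-d.  After a
    mixed fraction m each corona SLD has relaxed toward the blend mean
    rho_bar = (rho_h + rho_d)/2:

        rho_A = rho_bar - (1-m) (rho_bar - rho_h),   rho_B symmetric.

    The blend intensity is the population average of the two model
    curves; peptide-PEG cross terms carry opposite signs in the two
    populations and cancel, so the intensity decays monotonically as the
    corona contrast relaxes.
    """
    rho_bar = 0.5 * (rho_peg_h + rho_peg_d)
    delta = (1.0 - mixed_fraction) * 0.5 * (rho_peg_d - rho_peg_h)
    con = model.contrasts
    m_a = model.with_contrasts(replace(con, rho_peg=rho_bar - delta))
    m_b = model.with_contrasts(replace(con, rho_peg=rho_bar + delta))
    return 0.5 * (nanofiber_intensity(q, m_a) + nanofiber_intensity(q, m_b))


def simulate_zac_decay(
    scenario: SyntheticScenario,
    mechanism: ExchangeMechanism,
    times,
    rho_peg_h: float,
    rho_peg_d: float,
) -> list[ScatteringCurve]:
    """Time series of ZAC blend curves under one exchange mechanism.

    The blend starts fully unmixed (maximal corona contrast of either
    sign) and relaxes per the mechanism; molecule counts are conserved —
    only labels redistribute.  Curve ``j`` uses seed ``scenario.seed + j``.
    At the ZAC solvent composition the blend-mean corona SLD equals the
    solvent SLD, so the fully mixed limit has zero corona contrast.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    q = scenario.grid.build()
    model = scenario.model
    curves = []
    for j, t in enumerate(times):
        m = mechanism.mixed_fraction(float(t), model.n_agg)
        i_true = zac_blend_intensity(q, model, rho_peg_h, rho_peg_d, m)
        sigma = scenario.noise_relative * np.abs(i_true) + scenario.noise_floor
        rng = np.random.default_rng(scenario.seed + j)
        if scenario.noise_relative == 0 and scenario.noise_floor == 0:
            noisy, sigma_out = i_true, np.full_like(q, 1e-12)
        else:
            noisy = i_true + rng.normal(0.0, sigma)
            sigma_out = sigma
        curve = ScatteringCurve(
            q, noisy, sigma_out, metadata={"time": float(t), "mechanism": mechanism.kind}
        )
        curves.append(curve)
    return curves


def relaxation_function(i_t, i_0, i_inf) -> np.ndarray:
    """R(t) = sqrt((I(t) - I_inf) / (I_0 - I_inf)), the normalized
    contrast relaxation used in kinetic zero-average-contrast analysis."""
    i_t = np.asarray(i_t, dtype=float)
    denom = i_0 - i_inf
    if np.any(np.asarray(denom) <= 0):
        raise ValueError("need I_0 > I_inf")
    return np.sqrt(np.clip((i_t - i_inf) / denom, 0.0, None))
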