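"""Simultaneous refinement of one scattering model against many datasets.

SAXS and SANS curves (or a whole contrast series) share one set of
structural parameters; each dataset carries its own contrasts, an
optional nuisance intensity scale (absolute-calibration drift, typically
freed for SANS and pinned to 1 for SAXS) and its own flat background.
The residuals are sigma-weighted and concatenated across datasets, and
minimized with a bounded trust-region least-squares optimizer.  Because
the cross-section oscillations create local minima, an optional seeded
multi-start loop perturbs the starting point and keeps the best optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .formfactor import ContrastSet, NanofiberGeometry, NanofiberModel, nanofiber_intensity
from .io import ScatteringCurve
from .sld import DerivedFiberQuantities, derive_fiber_quantities

logger = logging.getLogger(__name__)

#: quadrature nodes used inside fit loops (fixed for speed/determinism)
FIT_QUAD_NODES = 256

# geometry parameters shared across datasets in a fiber fit
_GEOMETRY_NAMES = ("a_core", "a_shell", "b_core", "b_shell", "c", "d")
_MODEL_NAMES = _GEOMETRY_NAMES + ("rg_blob", "phi", "n_agg", "v_peg")


@dataclass
class FitProblem:
    """Datasets + model + parameter map for a simultaneous fit.

    ``params`` is an :class:`lmfit.Parameters` holding shared structural
    parameters by name plus per-dataset ``scale_i`` / ``background_i``.
    ``contrasts[i]`` supplies the SLDs the model uses for dataset ``i``.
    ``mass_spec = (d_core, d_shell, m_pep)`` lets the fit re-derive the
    aggregation number from the current geometry and report derived mass
    quantities with the result.
    """

    datasets: list[ScatteringCurve]
    contrasts: list[ContrastSet]
    params: lmfit.Parameters
    mass_spec: tuple[float, float, float] | None = None
    rg_blob: float = 15.0
    v_peg: float = 2790.0

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("need at least one dataset")
        if len(self.contrasts) != len(self.datasets):
            raise ValueError("one ContrastSet per dataset required")

    # -- model evaluation ---------------------------------------------------

    def _model_for(self, values: dict, i: int) -> NanofiberModel:
        geom = NanofiberGeometry(
            a_core=values["a_core"],
            a_shell=values["a_shell"],
            b_core=values["b_core"],
            b_shell=values["b_shell"],
            c=values["c"],
            d=values.get("d", 0.0),
        )
        n_agg = values.get("n_agg", 1.0)
        if self.mass_spec is not None:
            d_core, d_shell, m_pep = self.mass_spec
            n_agg = derive_fiber_quantities(geom, d_core, d_shell, m_pep).n_agg
        return NanofiberModel(
            geometry=geom,
            contrasts=self.contrasts[i],
            n_agg=max(n_agg, 1.0),
            v_peg=values.get("v_peg", self.v_peg),
            rg_blob=values.get("rg_blob", self.rg_blob),
            phi=values["phi"],
            background=values.get(f"background_{i}", 0.0),
        )

    def evaluate(self, values: dict, i: int) -> np.ndarray:
        """Model intensity for dataset ``i`` at the given parameter values."""
        model = self._model_for(values, i)
        scale = values.get(f"scale_{i}", 1.0)
        return scale * nanofiber_intensity(self.datasets[i].q, model, n_nodes=FIT_QUAD_NODES)

    def derived(self, values: dict) -> DerivedFiberQuantities | None:
        if self.mass_spec is None:
            return None
        geom = NanofiberGeometry(
            a_core=values["a_core"],
            a_shell=values["a_shell"],
            b_core=values["b_core"],
            b_shell=values["b_shell"],
            c=values["c"],
            d=values.get("d", 0.0),
        )
        d_core, d_shell, m_pep = self.mass_spec
        return derive_fiber_quantities(geom, d_core, d_shell, m_pep)


@dataclass
class FitResult:
    """Best-fit values, uncertainties and goodness-of-fit diagnostics."""

    values: dict
    stderr: dict
    chi2_per_dataset: list[float]
    redchi_global: float
    n_points: int
    n_free: int
    success: bool
    message: str
    derived: DerivedFiberQuantities | None = None
    n_starts: int = 1
    residuals: np.ndarray | None = None

    @property
    def chi2_global(self) -> float:
        return float(sum(self.chi2_per_dataset))


def objective(problem: FitProblem, params: lmfit.Parameters) -> np.ndarray:
    """Concatenated sigma-weighted residuals across all datasets."""
    values = params.valuesdict() if isinstance(params, lmfit.Parameters) else dict(params)
    chunks = []
    for i, data in enumerate(problem.datasets):
        try:
            model = problem.evaluate(values, i)
        except Exception as exc:
            raise RuntimeError(f"model evaluation failed on dataset {i}: {exc}") from exc
        chunks.append((model - data.intensity) / data.sigma)
    return np.concatenate(chunks)


def _chi2_per_dataset(problem: FitProblem, values: dict) -> list[float]:
    out = []
    for i, data in enumerate(problem.datasets):
        resid = (problem.evaluate(values, i) - data.intensity) / data.sigma
        out.append(float(np.sum(resid**2)))
    return out


def fit(
    problem: FitProblem,
    seed: int | None = None,
    n_starts: int = 8,
    perturbation: float = 0.1,
) -> FitResult:
    """Bounded trust-region least squares, optionally multi-start.

    Start ``1`` uses the parameter values as given; further starts
    perturb every free parameter log-normally (relative scale
    ``perturbation``), clipped to its bounds, with randomness fixed by
    ``seed``.  The best optimum by global chi-square wins.  With zero
    free parameters the input is returned with its evaluation chi-square.
    """
    free_names = [n for n, p in problem.params.items() if p.vary]
    n_points = sum(len(d) for d in problem.datasets)

    if not free_names:
        values = dict(problem.params.valuesdict())
        chi2 = _chi2_per_dataset(problem, values)
        total = sum(chi2)
        return FitResult(
            values=values,
            stderr={},
            chi2_per_dataset=chi2,
            redchi_global=total / n_points,
            n_points=n_points,
            n_free=0,
            success=True,
            message="no free parameters; evaluation only",
            derived=problem.derived(values),
        )

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        params = problem.params.copy()
        if start > 0:
            for name in free_names:
                p = params[name]
                val = p.value * float(rng.lognormal(0.0, perturbation))
                lo = p.min if np.isfinite(p.min) else -np.inf
                hi = p.max if np.isfinite(p.max) else np.inf
                p.value = float(np.clip(val, lo, hi))
        try:
            res = lmfit.minimize(
                lambda pars: objective(problem, pars),
                params,
                method="least_squares",
                nan_policy="raise",
            )
        except Exception as exc:
            logger.warning("start %d failed: %s", start, exc)
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all optimization starts failed")

    values = dict(best.params.valuesdict())
    stderr = {
        n: (best.params[n].stderr if best.params[n].stderr is not None else float("nan"))
        for n in free_names
    }
    chi2 = _chi2_per_dataset(problem, values)
    dof = max(n_points - len(free_names), 1)
    if not best.success:
        logger.warning("fit did not converge: %s", best.message)
    return FitResult(
        values=values,
        stderr=stderr,
        chi2_per_dataset=chi2,
        redchi_global=sum(chi2) / dof,
        n_points=n_points,
        n_free=len(free_names),
        success=bool(best.success),
        message=str(best.message),
        derived=problem.derived(values),
        n_starts=max(1, n_starts),
        residuals=np.asarray(best.residual),
    )


# ---------------------------------------------------------------------------
# problem builders
# ---------------------------------------------------------------------------


def fiber_problem(
    datasets: list[ScatteringCurve],
    contrasts: list[ContrastSet],
    start: NanofiberModel,
    free: tuple[str, ...] = ("a_core", "a_shell", "b_core", "b_shell", "c"),
    bounds: dict[str, tuple[float, float]] | None = None,
    mass_spec: tuple[float, float, float] | None = None,
    free_scales: tuple[int, ...] = (),
    free_backgrounds: bool = True,
) -> FitProblem:
    """Build a simultaneous fiber-fit problem from a starting model.

    ``free`` names the structural parameters to vary; the rest stay
    fixed at the starting model's values.  ``free_scales`` lists dataset
    indices whose intensity scale floats (SANS calibration drift);
    others are pinned to 1.  Default bounds are a factor 4 around the
    start, overridable per parameter via ``bounds``.
    """
    bounds = bounds or {}
    g = start.geometry
    start_values = {
        "a_core": g.a_core,
        "a_shell": g.a_shell,
        "b_core": g.b_core,
        "b_shell": g.b_shell,
        "c": g.c,
        "d": g.d,
        "rg_blob": start.rg_blob,
        "phi": start.phi,
        "n_agg": start.n_agg,
        "v_peg": start.v_peg,
    }
    unknown = set(free) - set(_MODEL_NAMES)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    params = lmfit.Parameters()
    for name, value in start_values.items():
        vary = name in free
        if name in bounds:
            lo, hi = bounds[name]
        elif vary:
            lo, hi = value / 4.0 if value > 0 else 0.0, value * 4.0 if value > 0 else 1.0
        else:
            lo, hi = -np.inf, np.inf
        params.add(name, value=value, vary=vary, min=lo, max=hi)
    for i in range(len(datasets)):
        params.add(f"scale_{i}", value=1.0, vary=i in free_scales, min=0.1, max=10.0)
        params.add(
            f"background_{i}",
            value=start.background,
            vary=free_backgrounds,
            min=0.0,
            max=max(10.0 * start.background, 1.0),
        )
    return FitProblem(
        datasets=list(datasets),
        contrasts=list(contrasts),
        params=params,
        mass_spec=mass_spec,
        rg_blob=start.rg_blob,
        v_peg=start.v_peg,
    )
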