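"""Two-state sequential kinetic decomposition of ΔI(q, t).

The time-resolved difference data are modelled as a linear combination
of two time-independent basis spectra whose weights follow sequential
monoexponential kinetics: an intermediate state rises with time constant
τ1 and converts to a final state with time constant τ2,

    C1(t) = τ2/(τ1−τ2) (e^{−t/τ1} − e^{−t/τ2})
    C2(t) = 1 + (τ2 e^{−t/τ2} − τ1 e^{−t/τ1})/(τ1−τ2),

so C1 + C2 = 1 − e^{−t/τ1} exactly.  Fitting uses variable projection:
for a trial (τ1, τ2) the basis spectra are the row-wise linear
least-squares solution, and the residual — weighted by q, i.e. on
q·ΔI — is minimized over (τ1, τ2) on a log grid followed by Nelder–Mead
refinement.  Note the per-q linear solve is independent of any positive
per-row weight (the rows decouple), so the q weight affects only the
(τ1, τ2) objective; basis spectra are stored in ΔI units.

The photoexcitation turnover fraction is absorbed into the basis
spectra: it is not separately identifiable from difference data alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import chebyshev
from scipy import optimize

from .models import DifferenceDataset, ScatteringCurve

__all__ = [
    "SequentialKineticModel",
    "SpectralDecomposition",
    "MonoExpFit",
    "sequential_concentrations",
    "smooth_polynomial",
    "fit_decomposition",
    "reconstruct",
    "fit_monoexponential",
]


@dataclass
class SequentialKineticModel:
    """Rise times (s) of the intermediate (τ1) and final (τ2) states."""

    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if not 0 < self.tau1 < self.tau2:
            if self.tau1 == self.tau2:
                raise ValueError(
                    "tau1 == tau2 is a degenerate denominator; the analytic "
                    "tau1 -> tau2 limit is not implemented — perturb one of "
                    "the time constants"
                )
            raise ValueError("require 0 < tau1 < tau2")


@dataclass
class SpectralDecomposition:
    """Result of the two-state fit.

    ``basis_int``/``basis_fin`` are the basis spectra in ΔI units on the
    data grid; ``coefficients`` is the 2 × n_t concentration matrix at
    the fitted delays; ``residual_norm`` is the q-weighted Frobenius
    residual ‖diag(q)(ΔI − BS·C)‖; ``converged`` is False when the
    optimizer ended on the τ bounds.
    """

    model: SequentialKineticModel
    basis_int: ScatteringCurve
    basis_fin: ScatteringCurve
    coefficients: np.ndarray
    residual_norm: float
    converged: bool = True


def sequential_concentrations(
    model: SequentialKineticModel, times: np.ndarray
) -> np.ndarray:
    """Concentration matrix [2, n_t] of the sequential two-state scheme.

    Both rows lie in [0, 1] for all t > 0 when τ1 < τ2.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("delay times must be positive")
    t1, t2 = model.tau1, model.tau2
    e1 = np.exp(-times / t1)
    e2 = np.exp(-times / t2)
    c1 = t2 / (t1 - t2) * (e1 - e2)
    c2 = 1.0 + (t2 * e2 - t1 * e1) / (t1 - t2)
    return np.vstack([c1, c2])


def smooth_polynomial(dataset: DifferenceDataset, degree: int = 40) -> DifferenceDataset:
    """Replace each delay's curve by its least-squares polynomial fit in q.

    A Chebyshev basis on the q range mapped to [−1, 1] keeps the
    high-degree fit well conditioned.  With ``degree`` well below n_q
    this low-pass filters detector noise while following the real
    oscillations of the difference signal.
    """
    if degree >= dataset.n_q:
        raise ValueError(
            f"polynomial degree {degree} must be < n_q = {dataset.n_q}"
        )
    smoothed = np.empty_like(dataset.dI)
    for j in range(dataset.n_t):
        coef = chebyshev.chebfit(dataset.q, dataset.dI[:, j], degree)
        smoothed[:, j] = chebyshev.chebval(dataset.q, coef)
    return DifferenceDataset(
        dataset.q.copy(), dataset.times.copy(), smoothed, dataset.sigma
    )


def _projected_residual(
    log_tau: np.ndarray,
    dataset: DifferenceDataset,
    weights: np.ndarray,
    bounds: tuple[tuple[float, float], tuple[float, float]],
) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    """Residual of the variable-projection fit for log10 τ parameters.

    Returns (residual, basis matrix n_q×2, C matrix 2×n_t); the latter
    two are None for infeasible parameters (penalty branch).
    """
    (lo1, hi1), (lo2, hi2) = bounds
    tau1, tau2 = 10.0 ** log_tau
    if not (lo1 <= tau1 <= hi1 and lo2 <= tau2 <= hi2 and tau1 < tau2):
        return np.inf, None, None
    conc = sequential_concentrations(SequentialKineticModel(tau1, tau2), dataset.times)
    gram = conc @ conc.T
    try:
        basis = dataset.dI @ conc.T @ np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    resid = weights[:, None] * (dataset.dI - basis @ conc)
    return float(np.linalg.norm(resid)), basis, conc


def fit_decomposition(
    dataset: DifferenceDataset,
    tau_bounds: tuple[tuple[float, float], tuple[float, float]] = (
        (1e-7, 1e-3),
        (1e-3, 10.0),
    ),
    n_grid: int = 25,
    seed: int | None = None,
) -> SpectralDecomposition:
    """Fit the two-state sequential model by variable projection.

    (τ1, τ2) are searched on a log10 scale: an ``n_grid`` × ``n_grid``
    coarse grid over ``tau_bounds`` followed by Nelder–Mead refinement.
    The procedure is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic stages and is unused.
    """
    if dataset.n_t < 4:
        raise ValueError("need at least 4 delay times to constrain two rises")
    (lo1, hi1), (lo2, hi2) = tau_bounds
    if min(lo1, hi1, lo2, hi2) <= 0:
        raise ValueError("tau bounds must be positive")

    weights = dataset.q.copy()  # the fit is carried out on q*dI
    grid1 = np.linspace(np.log10(lo1), np.log10(hi1), n_grid)
    grid2 = np.linspace(np.log10(lo2), np.log10(hi2), n_grid)

    best = (np.inf, None)
    for g1 in grid1:
        for g2 in grid2:
            r, _, _ = _projected_residual(
                np.array([g1, g2]), dataset, weights, tau_bounds
            )
            if r < best[0]:
                best = (r, (g1, g2))
    if best[1] is None:
        raise ValueError("no feasible (tau1, tau2) found on the coarse grid")

    result = optimize.minimize(
        lambda p: _projected_residual(p, dataset, weights, tau_bounds)[0],
        x0=np.array(best[1]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000},
    )
    x = result.x if result.fun <= best[0] else np.array(best[1])
    resid, basis, conc = _projected_residual(x, dataset, weights, tau_bounds)
    tau1, tau2 = 10.0 ** x

    rel = 1e-6
    on_bound1 = tau1 <= lo1 * (1 + rel) or tau1 >= hi1 * (1 - rel)
    on_bound2 = tau2 <= lo2 * (1 + rel) or tau2 >= hi2 * (1 - rel)
    converged = not (on_bound1 and on_bound2)

    return SpectralDecomposition(
        model=SequentialKineticModel(float(tau1), float(tau2)),
        basis_int=ScatteringCurve(dataset.q.copy(), basis[:, 0]),
        basis_fin=ScatteringCurve(dataset.q.copy(), basis[:, 1]),
        coefficients=conc,
        residual_norm=resid,
        converged=converged,
    )


def reconstruct(
    decomp: SpectralDecomposition, times: np.ndarray
) -> DifferenceDataset:
    """Reconstruct ΔI(q, t) = BS·C(t) at arbitrary delays."""
    conc = sequential_concentrations(decomp.model, np.asarray(times, float))
    basis = np.column_stack([decomp.basis_int.I, decomp.basis_fin.I])
    return DifferenceDataset(
        decomp.basis_int.q.copy(), np.asarray(times, float), basis @ conc
    )


@dataclass
class MonoExpFit:
    """Result of a monoexponential decay fit A e^{−t/τ} + B."""

    tau: float
    amplitude: float
    offset: float
    tau_stderr: float
    converged: bool


def fit_monoexponential(times: np.ndarray, values: np.ndarray) -> MonoExpFit:
    """Least-squares fit of A e^{−t/τ} + B to a flash-photolysis trace.

    Reports τ with its asymptotic standard error.  Traces that do not
    decay (fitted τ pinned at a bound, or vanishing amplitude) are
    flagged ``converged=False``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 5:
        raise ValueError("need at least 5 points")
    if np.any(times <= 0):
        raise ValueError("times must be positive")

    span = times.max() - times.min()
    tau_lo, tau_hi = span * 1e-6, span * 1e6
    scale = np.ptp(values)
    if scale == 0.0:
        return MonoExpFit(np.nan, 0.0, float(values[0]), np.nan, False)

    def model(t, amp, tau, off):
        return amp * np.exp(-t / tau) + off

    p0 = (values[0] - values[-1], max(span / 3.0, times.min()), values[-1])
    try:
        popt, pcov = optimize.curve_fit(
            model,
            times,
            values,
            p0=p0,
            bounds=([-np.inf, tau_lo, -np.inf], [np.inf, tau_hi, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return MonoExpFit(np.nan, np.nan, np.nan, np.nan, False)
    amp, tau, off = popt
    stderr = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    at_bound = tau <= tau_lo * (1 + 1e-6) or tau >= tau_hi * (1 - 1e-6)
    tiny_amp = abs(amp) < 1e-10 * scale
    return MonoExpFit(
        float(tau), float(amp), float(off), stderr, not (at_bound or tiny_amp)
    )
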