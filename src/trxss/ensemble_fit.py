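"""Ensemble pair fitting of candidate structures against difference data.

Every dark × light candidate pair is turned into a theoretical
difference curve (trim flexible termini → Debye intensity → difference ×
turnover → optional polychromatic smearing → restriction to the fit q
range) and scored against the experimental curve with the bounded-scale
R factor

    R = Σ_q |ΔI_exp − c ΔI_theory| / Σ_q |ΔI_exp| ,   0.35 ≤ c ≤ 1.6.

R(c) is piecewise linear and convex in c, so the constrained minimizer
is found exactly: the lower weighted median of the breakpoints
ΔI_exp/ΔI_theory with weights |ΔI_theory|, clipped to the bounds.  The
100 lowest-R pairs are accepted as good fits.  An L2 variant of the
score is available for comparison but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import scattering_calc
from .models import BeamSpectrum, ScatteringCurve
from .scattering_calc import FormFactorTable, QGridSpec
from .synthetic_data import ConformerEnsemble

__all__ = [
    "PairFit",
    "FitConfig",
    "r_factor",
    "initial_scale",
    "compute_member_curves",
    "pair_search",
    "select_top",
]


@dataclass
class PairFit:
    """One scored (dark, light) candidate pair."""

    dark_index: int
    light_index: int
    c: float
    R: float
    rank: int = -1


@dataclass
class FitConfig:
    """Scoring configuration: scale bounds, retention count, fit range."""

    c_bounds: tuple[float, float] = (0.35, 1.6)
    n_keep: int = 100
    q_fit_range: tuple[float, float] = (0.06, 1.0)
    turnover: float = 0.7
    metric: str = "l1"

    def __post_init__(self) -> None:
        lo, hi = self.c_bounds
        if not 0 < lo < hi:
            raise ValueError("c bounds must be positive and ordered")
        if self.n_keep < 1:
            raise ValueError("n_keep must be >= 1")
        qlo, qhi = self.q_fit_range
        if not qlo < qhi:
            raise ValueError("q fit range must be ordered")
        if self.metric not in ("l1", "l2"):
            raise ValueError("metric must be 'l1' or 'l2'")


def _r_factor_arrays(
    exp: np.ndarray,
    theory: np.ndarray,
    c_bounds: tuple[float, float],
    metric: str = "l1",
) -> tuple[float, float]:
    denom = float(np.sum(np.abs(exp)))
    if denom == 0.0:
        raise ValueError("experimental curve is identically zero")
    lo, hi = c_bounds
    nz = theory != 0.0
    if metric == "l2":
        tt = float(theory @ theory)
        c = float(np.clip((exp @ theory) / tt, lo, hi)) if tt > 0 else lo
        resid = exp - c * theory
        return float(np.sqrt(resid @ resid) / np.sqrt(exp @ exp)), c
    if not nz.any():
        c = float(np.clip(1.0, lo, hi))
        return 1.0, c
    ratios = exp[nz] / theory[nz]
    weights = np.abs(theory[nz])
    order = np.argsort(ratios)
    ratios = ratios[order]
    cum = np.cumsum(weights[order])
    # smallest global minimizer of the convex piecewise-linear objective
    idx = int(np.searchsorted(cum, 0.5 * cum[-1], side="left"))
    c = float(np.clip(ratios[idx], lo, hi))
    r = float(np.sum(np.abs(exp - c * theory)) / denom)
    return r, c


def r_factor(
    exp: ScatteringCurve,
    theory: ScatteringCurve,
    c_bounds: tuple[float, float] = (0.35, 1.6),
    metric: str = "l1",
) -> tuple[float, float]:
    """Bounded-scale R factor between experimental and theoretical curves.

    Returns (R, c) with c the exact constrained minimizer.  When the
    minimizing set is an interval, its smallest element is returned
    (deterministic tie-break).
    """
    if not np.array_equal(exp.q, theory.q):
        raise ValueError("curves must share one q grid")
    return _r_factor_arrays(exp.I, theory.I, c_bounds, metric)


def initial_scale(exp_abs: ScatteringCurve, theory_abs: ScatteringCurve) -> float:
    """Least-squares scale between absolute scattering curves.

    Returns s minimizing ‖I_exp − s I_theory‖², i.e. Σ I_exp I_theory /
    Σ I_theory².  Used to pre-scale the experimental data so the Eq.-3
    scale c is a bounded correction around 1.
    """
    if not np.array_equal(exp_abs.q, theory_abs.q):
        raise ValueError("curves must share one q grid")
    tt = float(theory_abs.I @ theory_abs.I)
    if tt == 0.0:
        raise ValueError("theoretical curve is identically zero")
    return float(exp_abs.I @ theory_abs.I) / tt


def compute_member_curves(
    ensemble: ConformerEnsemble,
    grid: QGridSpec | None = None,
    ff: FormFactorTable | None = None,
    spectrum: BeamSpectrum | None = None,
    trim: bool = True,
) -> list[ScatteringCurve]:
    """Absolute Debye curves of all ensemble members (trimmed, optionally smeared).

    Each member's intensity is computed once; pair differences reuse
    them, so a |dark| × |light| search costs |dark| + |light| Debye
    evaluations.
    """
    curves = []
    for member in ensemble.members:
        structure = scattering_calc.trim_flexible(member) if trim else member
        curve = scattering_calc.debye_intensity(structure, grid, ff)
        if spectrum is not None:
            curve = scattering_calc.polychromatic_smear(curve, spectrum)
        curves.append(curve)
    return curves


def pair_search(
    dark: ConformerEnsemble,
    light: ConformerEnsemble,
    exp: ScatteringCurve,
    spectrum: BeamSpectrum | None = None,
    cfg: FitConfig | None = None,
    grid: QGridSpec | None = None,
    ff: FormFactorTable | None = None,
    dark_curves: list[ScatteringCurve] | None = None,
    light_curves: list[ScatteringCurve] | None = None,
) -> list[PairFit]:
    """Score every dark × light pair against an experimental difference curve.

    Returns all |dark| × |light| fits sorted ascending by R, ties broken
    by (dark_index, light_index).  Precomputed member curves (from
    :func:`compute_member_curves`, matching ``grid``/``spectrum``) may be
    passed to amortize the Debye sums across searches against several
    target curves.  Peak memory is bounded by the member curves, not by
    the number of pairs.
    """
    cfg = cfg or FitConfig()
    if dark.members[0].site_keys() != light.members[0].site_keys():
        raise ValueError("dark and light ensembles must share one residue set")
    if dark_curves is None:
        dark_curves = compute_member_curves(dark, grid, ff, spectrum)
    if light_curves is None:
        light_curves = compute_member_curves(light, grid, ff, spectrum)

    qlo, qhi = cfg.q_fit_range
    exp_r = exp.restrict(qlo, qhi)
    theory_grid = dark_curves[0].q
    fit_mask = (theory_grid >= qlo) & (theory_grid <= qhi)
    if not np.array_equal(theory_grid[fit_mask], exp_r.q):
        raise ValueError(
            "experimental curve grid does not match the evaluation grid on "
            "the fit range"
        )
    exp_I = exp_r.I
    dark_I = np.array([c.I[fit_mask] for c in dark_curves])
    light_I = np.array([c.I[fit_mask] for c in light_curves])

    fits: list[PairFit] = []
    for i in range(len(dark_I)):
        diffs = cfg.turnover * (light_I - dark_I[i])
        for j in range(len(light_I)):
            r, c = _r_factor_arrays(exp_I, diffs[j], cfg.c_bounds, cfg.metric)
            fits.append(PairFit(i, j, c, r))
    fits.sort(key=lambda p: (p.R, p.dark_index, p.light_index))
    for rank, fit in enumerate(fits):
        fit.rank = rank
    return fits


def select_top(pairs: list[PairFit], n_keep: int = 100) -> list[PairFit]:
    """First ``n_keep`` pairs of a ranked list (the accepted good fits)."""
    if n_keep > len(pairs):
        raise ValueError(f"n_keep={n_keep} exceeds {len(pairs)} available pairs")
    return pairs[:n_keep]
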