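"""Coarse-grained solution-scattering calculator.

Theoretical intensities are computed with the Debye equation over
one-site-per-residue models,

    I(q) = Σ_i Σ_j f_i(q) f_j(q) sin(q r_ij) / (q r_ij),

with the i = j and q = 0 limits equal to 1.  The double sum is evaluated
exactly (no spherical-harmonic expansion).  Form factors are effective
per-residue amplitudes with an optional single-Gaussian q decay; the
default is a uniform constant amplitude, which is all the internal
consistency between synthetic-data generation and ensemble fitting
requires.  Hydration-shell and excluded-volume terms are deliberately
out of scope.

Polychromatic (pink-beam) smearing convolves a monochromatic curve with
a beam spectrum: at fixed scattering angle q scales linearly with photon
energy, so I_poly(q) = Σ_k w_k I_mono(q E_k / E_nominal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import BeamSpectrum, ScatteringCurve, StructureModel

__all__ = [
    "FormFactorTable",
    "QGridSpec",
    "debye_intensity",
    "difference_curve",
    "polychromatic_smear",
    "trim_flexible",
]

#: E [keV] * lambda [Å] conversion constant
HC_KEV_ANGSTROM = 12.398

# pair-chunk size bounding the (n_q, chunk) work arrays to a few tens of MB
_PAIR_CHUNK = 2_000_000


@dataclass
class FormFactorTable:
    """Effective per-class scattering amplitudes.

    ``entries`` maps a form-factor class name to ``(f0, width)`` where
    ``f0`` is the amplitude at q = 0 and ``width`` (Å) sets a
    single-Gaussian decay f(q) = f0 exp(-(width q)² / 2); width 0 means
    a q-independent amplitude.
    """

    entries: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CA": (1.0, 0.0)}
    )

    def __post_init__(self) -> None:
        for name, (f0, width) in self.entries.items():
            if f0 <= 0:
                raise ValueError(f"form-factor amplitude for {name!r} must be > 0")
            if width < 0:
                raise ValueError(f"form-factor width for {name!r} must be >= 0")

    def lookup(self, classes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (f0, width) arrays for an array of class names."""
        f0 = np.empty(len(classes))
        width = np.empty(len(classes))
        for i, name in enumerate(classes):
            key = str(name)
            if key not in self.entries:
                raise ValueError(f"unknown form-factor class {key!r}")
            f0[i], width[i] = self.entries[key]
        return f0, width


@dataclass
class QGridSpec:
    """Evaluation grid for theoretical curves (default 101 points, 0–1 Å⁻¹)."""

    n_points: int = 101
    q_min: float = 0.0
    q_max: float = 1.0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("q grid needs at least 2 points")
        if not self.q_min < self.q_max:
            raise ValueError("require q_min < q_max")

    def make(self) -> np.ndarray:
        return np.linspace(self.q_min, self.q_max, self.n_points)


def debye_intensity(
    structure: StructureModel,
    grid: QGridSpec | np.ndarray | None = None,
    ff: FormFactorTable | None = None,
) -> ScatteringCurve:
    """Exact Debye-sum intensity of a coarse-grained structure.

    ``grid`` may be a :class:`QGridSpec` or an explicit q array; the
    default is 101 points on 0–1 Å⁻¹.  The q = 0 endpoint is included
    with the sinc limit handled analytically, so I(0) = (Σ f_i(0))².
    """
    if len(structure) == 0:
        raise ValueError("structure is empty")
    if grid is None:
        grid = QGridSpec()
    q = grid.make() if isinstance(grid, QGridSpec) else np.asarray(grid, float)
    ff = ff or FormFactorTable()
    f0, width = ff.lookup(structure.ff_class)

    coords = structure.coords
    n = len(coords)
    q_col = q[:, None]
    uniform_f = bool(np.all(width == 0.0))

    if uniform_f:
        f_site = np.broadcast_to(f0, (len(q), n))
    else:
        f_site = f0[None, :] * np.exp(-0.5 * (width[None, :] * q_col) ** 2)
    self_term = np.sum(f_site**2, axis=1)
    if n == 1:
        return ScatteringCurve(q, self_term)

    iu, ju = np.triu_indices(n, k=1)
    diff = coords[iu] - coords[ju]
    dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))

    intensity = self_term.copy()
    chunk = max(1, _PAIR_CHUNK // len(q))
    for start in range(0, len(dist), chunk):
        sl = slice(start, start + chunk)
        # np.sinc(x/pi) = sin(x)/x with the x = 0 limit handled
        sinc = np.sinc(q_col * dist[None, sl] / np.pi)
        if uniform_f:
            fw = f0[iu[sl]] * f0[ju[sl]]
            intensity += 2.0 * sinc @ fw
        else:
            fw = f_site[:, iu[sl]] * f_site[:, ju[sl]]
            intensity += 2.0 * np.sum(fw * sinc, axis=1)
    return ScatteringCurve(q, intensity)


def difference_curve(
    light: ScatteringCurve, dark: ScatteringCurve, turnover: float = 1.0
) -> ScatteringCurve:
    """ΔI = turnover × (I_light − I_dark) on the shared grid."""
    if not 0 < turnover <= 1:
        raise ValueError("turnover must lie in (0, 1]")
    if len(light) != len(dark) or not np.array_equal(light.q, dark.q):
        raise ValueError("light and dark curves must share one q grid")
    return ScatteringCurve(light.q, turnover * (light.I - dark.I))


def polychromatic_smear(
    curve: ScatteringCurve,
    spectrum: BeamSpectrum,
    nominal_energy: float | None = None,
) -> ScatteringCurve:
    """Convolve a monochromatic curve with an undulator spectrum.

    I_poly(q) = Σ_k w_k I_mono(q E_k / E_nominal), with linear
    interpolation on the monochromatic grid and constant extrapolation
    at the grid ends.  ``nominal_energy`` defaults to the spectrum's
    weight maximum.
    """
    spec = spectrum.normalized()
    if nominal_energy is None:
        nominal_energy = spec.nominal_energy
    if nominal_energy <= 0:
        raise ValueError("nominal energy must be positive")
    out = np.zeros_like(curve.I)
    for energy, weight in zip(spec.energy, spec.weight):
        if weight == 0.0:
            continue
        out += weight * np.interp(curve.q * (energy / nominal_energy), curve.q, curve.I)
    return ScatteringCurve(curve.q, out)


def default_trim_ranges(structure: StructureModel) -> list[tuple[str, int, int]]:
    """Residues 1–10 on every chain (flexible N-terminus)."""
    return [(chain, 1, 10) for chain in structure.chains]


def trim_flexible(
    structure: StructureModel,
    drop_ranges: Sequence[tuple[str, int, int]] | None = None,
    drop_resnames: Sequence[str] = (),
) -> StructureModel:
    """Remove flexible residues before computing scattering.

    By default residues 1–10 of every chain are dropped (disordered
    N-terminus); ``drop_resnames`` removes e.g. purification-tag
    residues by name.  Ranges that match nothing are ignored (trimming
    is idempotent); order of the remaining sites is preserved.
    """
    if len(structure) == 0:
        raise ValueError("structure is empty")
    if drop_ranges is None:
        drop_ranges = default_trim_ranges(structure)
    drop = np.zeros(len(structure), dtype=bool)
    for chain_id, first, last in drop_ranges:
        drop |= (
            (structure.chain == chain_id)
            & (structure.resnum >= first)
            & (structure.resnum <= last)
        )
    for name in drop_resnames:
        drop |= structure.resname == name
    if drop.all():
        raise ValueError("trimming would remove all sites")
    return structure.select(~drop)
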