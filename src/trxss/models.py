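"""Core in-memory containers shared across the pipeline.

A time-resolved solution scattering experiment produces difference
intensities ΔI(q, t) on a grid of scattering-vector moduli q (Å⁻¹) and
pump-probe delay times t (s).  Structural modelling works on Cα-level
coordinate sets.  These containers validate the invariants every module
relies on (strictly increasing grids, consistent shapes, unique residue
keys) at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ScatteringCurve",
    "DifferenceDataset",
    "StructureModel",
    "BeamSpectrum",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class ScatteringCurve:
    """Intensity (or difference intensity) sampled on a q grid.

    Parameters
    ----------
    q : array
        Scattering-vector moduli in Å⁻¹, strictly increasing.
    I : array
        Intensity per q point, arbitrary units.  May be a difference
        intensity ΔI (negative values allowed).
    sigma : array, optional
        Per-point 1σ uncertainty, same units as ``I``; all entries > 0.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = _as_float_array(self.q, "q")
        self.I = _as_float_array(self.I, "I")
        if len(self.q) != len(self.I):
            raise ValueError(
                f"q and I must have equal length ({len(self.q)} != {len(self.I)})"
            )
        if len(self.q) and np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if self.sigma is not None:
            self.sigma = _as_float_array(self.sigma, "sigma")
            if len(self.sigma) != len(self.q):
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma entries must all be > 0")

    def __len__(self) -> int:
        return len(self.q)

    def restrict(self, q_min: float, q_max: float) -> "ScatteringCurve":
        """Return the sub-curve with q_min <= q <= q_max."""
        mask = (self.q >= q_min) & (self.q <= q_max)
        if not mask.any():
            raise ValueError(f"no grid points in [{q_min}, {q_max}]")
        sigma = self.sigma[mask] if self.sigma is not None else None
        return ScatteringCurve(self.q[mask], self.I[mask], sigma)

    def copy(self) -> "ScatteringCurve":
        return ScatteringCurve(
            self.q.copy(),
            self.I.copy(),
            None if self.sigma is None else self.sigma.copy(),
        )


@dataclass
class DifferenceDataset:
    """Matrix of difference intensities ΔI(q, t).

    ``dI`` has shape (n_q, n_t); ``replicates`` optionally holds, per
    delay, the stack of individual difference curves (n_rep, n_q) that
    were averaged.
    """

    q: np.ndarray
    times: np.ndarray
    dI: np.ndarray
    sigma: np.ndarray | None = None
    replicates: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.q = _as_float_array(self.q, "q")
        self.times = _as_float_array(self.times, "times")
        self.dI = np.asarray(self.dI, dtype=float)
        if len(self.q) and np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("delay times must be strictly increasing")
        if np.any(self.times <= 0):
            raise ValueError("delay times must be positive")
        if self.dI.shape != (len(self.q), len(self.times)):
            raise ValueError(
                f"dI shape {self.dI.shape} inconsistent with "
                f"(n_q={len(self.q)}, n_t={len(self.times)})"
            )
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.dI.shape:
                raise ValueError("sigma must match dI in shape")
        if self.replicates is not None:
            if len(self.replicates) != len(self.times):
                raise ValueError("one replicate stack per delay required")
            for k, stack in enumerate(self.replicates):
                stack = np.asarray(stack, dtype=float)
                if stack.ndim != 2 or stack.shape[1] != len(self.q):
                    raise ValueError(
                        f"replicate stack {k} has shape {stack.shape}, "
                        f"expected (n_rep, {len(self.q)})"
                    )
                self.replicates[k] = stack

    @property
    def n_q(self) -> int:
        return len(self.q)

    @property
    def n_t(self) -> int:
        return len(self.times)

    def column(self, index: int) -> ScatteringCurve:
        """The difference curve at one delay."""
        sigma = None
        if self.sigma is not None:
            sigma = self.sigma[:, index]
            if np.any(sigma <= 0):
                sigma = None
        return ScatteringCurve(self.q, self.dI[:, index], sigma)

    def copy(self) -> "DifferenceDataset":
        return DifferenceDataset(
            self.q.copy(),
            self.times.copy(),
            self.dI.copy(),
            None if self.sigma is None else self.sigma.copy(),
            None
            if self.replicates is None
            else [s.copy() for s in self.replicates],
        )


@dataclass
class StructureModel:
    """Cα-level labelled coordinate set.

    Sites are ordered records of (chain id, residue number, insertion
    code, residue name, xyz position in Å, form-factor class).  The key
    (chain, residue number, insertion code) is unique per site.
    """

    chain: np.ndarray
    resnum: np.ndarray
    resname: np.ndarray
    coords: np.ndarray
    icode: np.ndarray | None = None
    ff_class: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chain = np.asarray(self.chain, dtype="U4")
        self.resnum = np.asarray(self.resnum, dtype=int)
        self.resname = np.asarray(self.resname, dtype="U5")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.chain)
        if self.icode is None:
            self.icode = np.full(n, "", dtype="U1")
        else:
            self.icode = np.asarray(self.icode, dtype="U1")
        if self.ff_class is None:
            self.ff_class = np.full(n, "CA", dtype="U8")
        else:
            self.ff_class = np.asarray(self.ff_class, dtype="U8")
        if not (
            len(self.resnum) == len(self.resname) == len(self.icode)
            == len(self.ff_class) == n
        ):
            raise ValueError("site annotation arrays must share one length")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords must have shape ({n}, 3), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        keys = list(zip(self.chain, self.resnum, self.icode))
        if len(set(keys)) != n:
            seen: set = set()
            for key in keys:
                if key in seen:
                    raise ValueError(
                        f"duplicate site for chain {key[0]!r} residue "
                        f"{key[1]}{key[2]!r}"
                    )
                seen.add(key)

    def __len__(self) -> int:
        return len(self.chain)

    @property
    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(str(c), None)
        return list(seen)

    def site_keys(self) -> list[tuple[str, int, str]]:
        return list(
            zip((str(c) for c in self.chain), self.resnum.tolist(), self.icode)
        )

    def select(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.chain[mask],
            self.resnum[mask],
            self.resname[mask],
            self.coords[mask],
            self.icode[mask],
            self.ff_class[mask],
            dict(self.metadata),
        )

    def range_mask(
        self, ranges: Sequence[tuple[str, int, int]]
    ) -> np.ndarray:
        """Boolean mask selecting residues within (chain, first, last) triples."""
        mask = np.zeros(len(self), dtype=bool)
        for chain_id, first, last in ranges:
            if first > last:
                raise ValueError(
                    f"range ({chain_id}, {first}, {last}) is not well-ordered"
                )
            hit = (self.chain == chain_id) & (self.resnum >= first) & (
                self.resnum <= last
            )
            if not hit.any():
                raise ValueError(
                    f"selection ({chain_id}, {first}-{last}) matches no residues"
                )
            mask |= hit
        return mask

    def with_coords(self, coords: np.ndarray, **metadata) -> "StructureModel":
        meta = dict(self.metadata)
        meta.update(metadata)
        return StructureModel(
            self.chain.copy(),
            self.resnum.copy(),
            self.resname.copy(),
            np.asarray(coords, dtype=float).copy(),
            self.icode.copy(),
            self.ff_class.copy(),
            meta,
        )

    def copy(self) -> "StructureModel":
        return self.with_coords(self.coords)

    def same_sites(self, other: "StructureModel") -> bool:
        return len(self) == len(other) and self.site_keys() == other.site_keys()


@dataclass
class BeamSpectrum:
    """Relative spectral weight of a polychromatic (pink) X-ray beam.

    ``energy`` may be photon energies in keV or wavelengths in Å — the
    smearing operation only uses ratios, which coincide for energies
    (q scales linearly with E at fixed angle).
    """

    energy: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.energy = _as_float_array(self.energy, "energy")
        self.weight = _as_float_array(self.weight, "weight")
        if len(self.energy) != len(self.weight):
            raise ValueError("energy and weight must have equal length")
        if len(self.energy) < 1:
            raise ValueError("spectrum must contain at least one row")
        if len(self.energy) > 1 and np.any(np.diff(self.energy) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.weight < 0):
            raise ValueError("spectral weights must be non-negative")
        total = self.weight.sum()
        if total <= 0:
            raise ValueError("at least one spectral weight must be positive")

    def normalized(self) -> "BeamSpectrum":
        return BeamSpectrum(self.energy.copy(), self.weight / self.weight.sum())

    @property
    def nominal_energy(self) -> float:
        """Energy of maximum weight (default reference for smearing)."""
        return float(self.energy[int(np.argmax(self.weight))])
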