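"""Geometric descriptors of the light-induced conformational change.

The sensor histidine kinase dimer is described at Cα level.  Two scalar
descriptors quantify how the kinase effector module moves relative to
the LOV sensor module:

* χ — the bend angle at the centre of mass of the hinge region
  (residues 146–156) subtended by the LOV core (11–127) and the linker/
  DHp helices (170–200); straightening of the protein decreases |180°−χ|.
* ψ — the dihedral of the four centres of mass (LOV of chain A, LOV of
  chain B, CA domain of chain A, CA domain of chain B; CA-domain range
  224–377).  A positive change in ψ corresponds to a left-handed
  rotation (supercoiling) of the kinase module as seen from the sensor
  side; the convention is fixed by the constructed-rotation tests.

Rigid-body superposition uses the proper (det +1) Kabsch solution;
distance-difference and double-difference matrices quantify internal
rearrangement between photoproduct states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .models import StructureModel

__all__ = [
    "ResidueRanges",
    "RigidTransform",
    "DisplacementField",
    "superpose",
    "mean_displacement",
    "chi_angle",
    "psi_dihedral",
    "distance_matrix",
    "double_difference",
]

Ranges = Sequence[tuple[str, int, int]]


@dataclass
class ResidueRanges:
    """Named residue selections used by the descriptors.

    Defaults follow the domain boundaries of the dimer: LOV core
    11–127, hinge 146–156, linker/DHp 170–200, kinase CA domain
    224–377, on both chains.
    """

    selections: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    @classmethod
    def defaults(cls, chains: Sequence[str] = ("A", "B")) -> "ResidueRanges":
        a, b = chains
        return cls(
            {
                "lov": [(a, 11, 127), (b, 11, 127)],
                "hinge": [(a, 146, 156), (b, 146, 156)],
                "dhp": [(a, 170, 200), (b, 170, 200)],
                "kinase_ca": [(a, 224, 377), (b, 224, 377)],
                "lov_a": [(a, 11, 127)],
                "lov_b": [(b, 11, 127)],
                "ca_a": [(a, 224, 377)],
                "ca_b": [(b, 224, 377)],
            }
        )

    def get(self, name: str) -> list[tuple[str, int, int]]:
        if name not in self.selections:
            raise KeyError(f"no selection named {name!r}")
        return self.selections[name]


def _centroid(structure: StructureModel, ranges: Ranges) -> np.ndarray:
    """Unweighted Cα centroid over a selection (equal masses assumed)."""
    mask = structure.range_mask(ranges)
    return structure.coords[mask].mean(axis=0)


@dataclass
class RigidTransform:
    """Proper rigid-body map x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    selection: Ranges | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Only a proper rotation (determinant +1) plus translation is allowed;
    mirror images therefore keep a positive residual.  The RMSD over the
    selection after applying the transform is returned alongside it.
    """
    if selection is None:
        if not mobile.same_sites(reference):
            raise ValueError("structures differ in sites; pass an explicit selection")
        x = mobile.coords
        y = reference.coords
    else:
        x = mobile.coords[mobile.range_mask(selection)]
        y = reference.coords[reference.range_mask(selection)]
        if len(x) != len(y):
            raise ValueError("selection resolves to different site counts")
    if len(x) < 3:
        raise ValueError("superposition needs at least 3 sites")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    if np.linalg.matrix_rank(x0, tol=1e-9) < 2:
        raise ValueError("selection is collinear; superposition is degenerate")
    rot, _ = Rotation.align_vectors(y0, x0)  # proper rotation by construction
    matrix = rot.as_matrix()
    transform = RigidTransform(matrix, yc - matrix @ xc)
    moved = transform.apply(x)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return transform, rmsd


@dataclass
class DisplacementField:
    """Per-residue mean displacement across accepted structure pairs.

    ``mean_vector`` averages the per-pair displacement vectors (after
    alignment on the reference selection); ``magnitude`` is the length
    of that mean vector, and ``mean_magnitude`` the secondary
    mean-of-lengths statistic.
    """

    chain: np.ndarray
    resnum: np.ndarray
    mean_vector: np.ndarray
    magnitude: np.ndarray
    mean_magnitude: np.ndarray


def mean_displacement(
    pairs: Sequence[tuple[StructureModel, StructureModel]],
    align_selection: Ranges | None = None,
    ranges: ResidueRanges | None = None,
) -> DisplacementField:
    """Mean Cα displacement field over accepted (dark, light) pairs.

    Each light structure is superposed onto its dark partner over
    ``align_selection`` (default: the LOV core of both chains); the
    per-residue displacement is moved-light minus dark, averaged over
    pairs.
    """
    if not pairs:
        raise ValueError("need at least one (dark, light) pair")
    first_dark = pairs[0][0]
    if align_selection is None:
        ranges = ranges or ResidueRanges.defaults(first_dark.chains[:2])
        align_selection = ranges.get("lov")
    keys = first_dark.site_keys()
    acc = np.zeros((len(first_dark), 3))
    acc_mag = np.zeros(len(first_dark))
    for dark, light in pairs:
        if dark.site_keys() != keys or light.site_keys() != keys:
            raise ValueError("all pairs must share one residue set, in order")
        transform, _ = superpose(light, dark, align_selection)
        disp = transform.apply(light.coords) - dark.coords
        acc += disp
        acc_mag += np.linalg.norm(disp, axis=1)
    n = len(pairs)
    mean_vec = acc / n
    return DisplacementField(
        chain=first_dark.chain.copy(),
        resnum=first_dark.resnum.copy(),
        mean_vector=mean_vec,
        magnitude=np.linalg.norm(mean_vec, axis=1),
        mean_magnitude=acc_mag / n,
    )


def chi_angle(
    structure: StructureModel, ranges: ResidueRanges | None = None
) -> float:
    """Bend angle χ in degrees, in [0, 180].

    The angle at the hinge centroid (146–156) subtended by the LOV
    (11–127) and linker/DHp (170–200) centroids; each centroid pools the
    Cα of both chains.
    """
    ranges = ranges or ResidueRanges.defaults(structure.chains[:2])
    p_outer1 = _centroid(structure, ranges.get("lov"))
    p_mid = _centroid(structure, ranges.get("hinge"))
    p_outer2 = _centroid(structure, ranges.get("dhp"))
    v1 = p_outer1 - p_mid
    v2 = p_outer2 - p_mid
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("coincident centres of mass; chi undefined")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _dihedral(p0, p1, p2, p3) -> float:
    """Standard signed dihedral of four points, degrees in (−180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise ValueError("degenerate dihedral axis")
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("collinear centre triplet; dihedral undefined")
    m1 = np.cross(n1, b1 / nb1)
    angle = np.degrees(np.arctan2(m1 @ n2, n1 @ n2))
    # map -180 to +180 so the range is (-180, 180]
    return float(angle) if angle != -180.0 else 180.0


def psi_dihedral(
    structure: StructureModel, ranges: ResidueRanges | None = None
) -> float:
    """Supercoiling dihedral ψ in degrees, signed, in (−180, 180].

    Dihedral of the centres of mass, in order: LOV of chain A, LOV of
    chain B, CA domain of chain A, CA domain of chain B.  Positive Δψ =
    left-handed rotation of the CA pair viewed from the LOV side.
    """
    ranges = ranges or ResidueRanges.defaults(structure.chains[:2])
    points = [
        _centroid(structure, ranges.get(name))
        for name in ("lov_a", "lov_b", "ca_a", "ca_b")
    ]
    return _dihedral(*points)


def distance_matrix(
    structure: StructureModel, selection: Ranges | None = None
) -> np.ndarray:
    """Symmetric pairwise Cα distance matrix (Å) over a selection.

    Rows/columns are ordered by (chain, residue number).
    """
    if selection is not None:
        structure = structure.select(structure.range_mask(selection))
    if len(structure) < 2:
        raise ValueError("selection must resolve to at least 2 sites")
    order = np.lexsort((structure.resnum, structure.chain))
    coords = structure.coords[order]
    return squareform(pdist(coords))


def double_difference(
    dark: StructureModel,
    state_a: StructureModel,
    state_b: StructureModel,
    selection: Ranges | None = None,
) -> np.ndarray:
    """Cα double distance difference matrix between two photoproduct states.

    [D(state_b) − D(dark)] − [D(state_a) − D(dark)] = D(state_b) − D(state_a):
    the dark term cancels algebraically, but the dark structure is still
    required to share the residue set, keeping the call signature of the
    experimental analysis.  Negative entries mean two regions move closer
    going from state_a to state_b.
    """
    for other in (state_a, state_b):
        if not dark.same_sites(other):
            raise ValueError("structures must share one residue set")
    d_a = distance_matrix(state_a, selection)
    d_b = distance_matrix(state_b, selection)
    return d_b - d_a
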