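"""Synthetic stand-ins for the experiment: structures, ensembles, datasets.

The generator emulates, at desk scale, everything the beamline and the
restrained MD simulations produced:

* a toy two-chain Cα dimer with the sensor-linker-kinase architecture
  of a LOV histidine kinase (C2 symmetric about z by construction);
* dark/light conformer ensembles obtained by rigid-body supercoiling
  rotations of the kinase module (light centred on the ~11° left-handed
  rotation of the photoproduct states) plus Gaussian jitter;
* two basis difference curves produced by the same coarse-grained Debye
  forward model used for fitting, mixed by sequential two-state kinetics
  (τ1 = 2 μs, τ2 = 250 ms), ~70% photoexcitation turnover, additive
  Gaussian noise, and a solvent-heating contribution confined to
  q > 1.4 Å⁻¹ where solvent scattering dominates.

Because generator and fitter share one forward model, pair-recovery and
parameter-recovery tests are exactly well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import geometry, kinetics, scattering_calc
from .models import DifferenceDataset, ScatteringCurve, StructureModel

__all__ = [
    "ConformerEnsemble",
    "SyntheticTruth",
    "make_toy_dimer",
    "perturb_conformer",
    "make_ensembles",
    "generate_dataset",
    "make_truth",
    "heating_reference",
]

DEFAULT_SPLITS = (127, 200, 223)


@dataclass
class ConformerEnsemble:
    """A pool of candidate conformers sharing one residue set."""

    members: list[StructureModel]
    label: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("dark", "light"):
            raise ValueError("ensemble label must be 'dark' or 'light'")
        if not self.members:
            raise ValueError("ensemble must have at least one member")
        keys = self.members[0].site_keys()
        for k, member in enumerate(self.members[1:], start=1):
            if member.site_keys() != keys:
                raise ValueError(f"member {k} differs in residue set")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind a synthetic dataset."""

    tau1: float
    tau2: float
    turnover: float
    basis_int: ScatteringCurve
    basis_fin: ScatteringCurve
    heating_ref: ScatteringCurve
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.tau1 < self.tau2:
            raise ValueError("require 0 < tau1 < tau2")
        if not 0 < self.turnover <= 1:
            raise ValueError("turnover must lie in (0, 1]")
        for curve in (self.basis_fin, self.heating_ref):
            if not np.array_equal(curve.q, self.basis_int.q):
                raise ValueError("truth curves must share one q grid")


def _ball_points(rng, n, radius, center):
    """Uniform points in a ball — a globular domain at scattering resolution."""
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return center + direction * r[:, None]


def make_toy_dimer(
    n_res_per_chain: int = 385,
    helix_rise: float = 1.5,
    helix_radius: float = 2.3,
    splits: tuple[int, int, int] = DEFAULT_SPLITS,
    seed: int = 0,
    sensor_radius: float = 12.0,
    sensor_offset: float = 14.0,
    coiled_offset: float = 5.0,
    ca_radius: float = 11.0,
    ca_offset: float = 16.0,
    ca_azimuth: float = 60.0,
) -> StructureModel:
    """Two-chain Cα toy dimer with sensor / coiled linker / kinase layout.

    Chain A comprises an N-terminal globular sensor blob (residues
    1..splits[0]), an ascending helix winding about an axis offset from
    z (splits[0]+1..splits[1]), a descending return helix
    (splits[1]+1..splits[2]), and a C-terminal globular CA-domain blob.
    Chain B is chain A rotated by 180° about z, so the dimer centroid
    lies exactly on the z axis.  Deterministic given ``seed``.
    """
    if not (splits[0] < splits[1] < splits[2]):
        raise ValueError("domain split points must be strictly increasing")
    if n_res_per_chain < splits[2]:
        raise ValueError("n_res_per_chain must be >= the largest split point")
    rng = np.random.default_rng(seed)
    s1, s2, s3 = splits
    twist = np.radians(100.0)  # per-residue helical twist

    coords = np.empty((n_res_per_chain, 3))
    # sensor blob below the coiled coil
    coords[:s1] = _ball_points(
        rng, s1, sensor_radius, np.array([sensor_offset, 0.0, -sensor_radius - 6.0])
    )
    # ascending linker/DHp helix
    n_up = s2 - s1
    i = np.arange(n_up)
    coords[s1:s2] = np.column_stack(
        [
            coiled_offset + helix_radius * np.cos(twist * i),
            helix_radius * np.sin(twist * i),
            helix_rise * i,
        ]
    )
    top = helix_rise * (n_up - 1)
    # descending return helix, laterally offset hairpin partner
    n_down = s3 - s2
    j = np.arange(n_down)
    coords[s2:s3] = np.column_stack(
        [
            coiled_offset + 6.0 + helix_radius * np.cos(twist * j + np.pi),
            helix_radius * np.sin(twist * j + np.pi),
            top - helix_rise * j,
        ]
    )
    # CA-domain blob hanging off the returned helix; the azimuthal offset
    # keeps the supercoiling dihedral well away from the ±180° branch cut
    n_ca = n_res_per_chain - s3
    z_ca = top - helix_rise * (n_down - 1) - 4.0
    phi = np.radians(ca_azimuth)
    coords[s3:] = _ball_points(
        rng,
        n_ca,
        ca_radius,
        np.array([ca_offset * np.cos(phi), ca_offset * np.sin(phi), z_ca]),
    )

    rot180 = np.diag([-1.0, -1.0, 1.0])
    full = np.vstack([coords, coords @ rot180.T])
    resnum = np.tile(np.arange(1, n_res_per_chain + 1), 2)
    chain = np.repeat(["A", "B"], n_res_per_chain)
    return StructureModel(
        chain=chain,
        resnum=resnum,
        resname=np.full(2 * n_res_per_chain, "ALA"),
        coords=full,
        metadata={"source": "toy_dimer", "seed": seed, "splits": splits},
    )


def _rotate_about_z(coords: np.ndarray, degrees: float) -> np.ndarray:
    t = np.radians(degrees)
    rot = np.array(
        [[np.cos(t), -np.sin(t), 0.0], [np.sin(t), np.cos(t), 0.0], [0.0, 0.0, 1.0]]
    )
    return coords @ rot.T


def _default_mobile(base: StructureModel) -> list[tuple[str, int, int]]:
    """Everything C-terminal of the sensor module, both chains."""
    first = int(base.metadata.get("splits", DEFAULT_SPLITS)[0]) + 1
    last = int(base.resnum.max())
    return [(chain, first, last) for chain in base.chains]


def perturb_conformer(
    base: StructureModel,
    d_psi: float = 0.0,
    d_chi: float = 0.0,
    jitter_sigma: float = 0.0,
    mobile: list[tuple[str, int, int]] | None = None,
    seed: int = 0,
    ranges: geometry.ResidueRanges | None = None,
) -> StructureModel:
    """Supercoil/bend the mobile module of a conformer, then add jitter.

    The mobile sites (default: everything past the sensor domain on both
    chains) are rotated rigidly about the dimer z axis so that the ψ
    descriptor changes by exactly ``d_psi`` (positive = left-handed as
    seen from the sensor; the underlying z rotation angle is solved by
    bisection because the four-point dihedral is not identical to the
    rotation angle), then tilted by ``d_chi`` about a hinge axis through
    the mobile selection's boundary centroid.  Finally i.i.d. Gaussian
    jitter of scale ``jitter_sigma`` (Å) is added to *all* sites.
    Non-mobile sites are unchanged before jitter.
    """
    mobile = mobile if mobile is not None else _default_mobile(base)
    mask = base.range_mask(mobile)
    if (~mask).sum() < 4:
        raise ValueError("need at least 4 sites outside the mobile selection")
    coords = base.coords.copy()

    if d_psi != 0.0:
        ranges = ranges or geometry.ResidueRanges.defaults(base.chains[:2])
        psi0 = geometry.psi_dihedral(base, ranges)

        # The four ψ centroids respond linearly to the rotation: splitting
        # each range into its static and mobile coordinate sums lets the
        # bracket/bisection loop evaluate ψ(β) from 4 points only.
        parts = []
        for name in ("lov_a", "lov_b", "ca_a", "ca_b"):
            rmask = base.range_mask(ranges.get(name))
            static_sum = coords[rmask & ~mask].sum(axis=0)
            mobile_sum = coords[rmask & mask].sum(axis=0)
            parts.append((static_sum, mobile_sum, int(rmask.sum())))

        def delta_psi(beta: float) -> float:
            centroids = [
                (static + _rotate_about_z(mobile[None, :], beta)[0]) / n_sites
                for static, mobile, n_sites in parts
            ]
            psi = geometry._dihedral(*centroids)
            return (psi - psi0 + 180.0) % 360.0 - 180.0 - d_psi

        # bracket the monotone branch around zero rotation
        lo, hi = -3.0 * abs(d_psi) - 5.0, 3.0 * abs(d_psi) + 5.0
        grid = np.linspace(lo, hi, 101)
        vals = np.array([delta_psi(b) for b in grid])
        sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if len(sign_change) == 0:
            raise ValueError(f"could not bracket a z rotation realizing d_psi={d_psi}")
        k = sign_change[np.argmin(np.abs(grid[sign_change]))]
        beta = optimize.brentq(delta_psi, grid[k], grid[k + 1], xtol=1e-12)
        coords[mask] = _rotate_about_z(coords[mask], beta)

    if d_chi != 0.0:
        boundary_res = min(first for _, first, _ in mobile)
        boundary = (base.resnum[mask] == boundary_res) | (
            base.resnum[mask] == base.resnum[mask].min()
        )
        pivot = coords[mask][boundary].mean(axis=0)
        t = np.radians(d_chi)
        rot = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, np.cos(t), -np.sin(t)],
                [0.0, np.sin(t), np.cos(t)],
            ]
        )  # tilt about the x axis through the hinge point
        coords[mask] = (coords[mask] - pivot) @ rot.T + pivot

    if jitter_sigma > 0.0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, jitter_sigma, coords.shape)

    return base.with_coords(
        coords, perturbation={"d_psi": d_psi, "d_chi": d_chi, "jitter": jitter_sigma}
    )


def make_ensembles(
    base: StructureModel,
    n_dark: int = 200,
    n_light: int = 200,
    light_dpsi_mean: float = 11.0,
    spread: float = 1.5,
    jitter: float = 0.3,
    seed: int = 0,
) -> tuple[ConformerEnsemble, ConformerEnsemble]:
    """Draw dark and light conformer pools around the base structure.

    Dark members carry supercoiling rotations d_psi ~ N(0, spread²),
    light members d_psi ~ N(light_dpsi_mean, spread²) (degrees), each
    followed by coordinate jitter.  Mirrors the two restrained MD pools
    of the experimental analysis at reduced scale.  Reproducible from
    ``seed``.
    """
    if n_dark < 1 or n_light < 1:
        raise ValueError("ensemble counts must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    member_seeds = [
        int(child.generate_state(1)[0] % (2**31))
        for child in ss.spawn(n_dark + n_light)
    ]

    def draw(n, mean, label, seeds):
        dpsis = rng.normal(mean, spread, n)
        members = [
            perturb_conformer(base, d_psi=float(dp), jitter_sigma=jitter, seed=s)
            for dp, s in zip(dpsis, seeds)
        ]
        return ConformerEnsemble(
            members,
            label,
            provenance={
                "seed": seed,
                "dpsi_mean": mean,
                "spread": spread,
                "jitter": jitter,
                "applied_dpsi": dpsis.tolist(),
            },
        )

    dark = draw(n_dark, 0.0, "dark", member_seeds[:n_dark])
    light = draw(n_light, light_dpsi_mean, "light", member_seeds[n_dark:])
    return dark, light


def heating_reference(q: np.ndarray) -> ScatteringCurve:
    """Solvent-heating difference signature on a q grid.

    A smooth bump supported on 1.4–2.4 Å⁻¹ (peak at 1.9 Å⁻¹), exactly
    zero below 1.4 Å⁻¹ — solvent heating dominates the water-structure
    band and contributes nothing at protein q.
    """
    q = np.asarray(q, dtype=float)
    h = np.zeros_like(q)
    inside = (q >= 1.4) & (q <= 2.4)
    h[inside] = np.sin(np.pi * (q[inside] - 1.4) / 1.0) ** 2
    return ScatteringCurve(q, h)


def _highq_window(q: np.ndarray) -> np.ndarray:
    """Smooth window forcing protein difference signal to zero above ~1.4 Å⁻¹.

    cos² roll-off on 1.3–1.45 Å⁻¹.  Encodes the empirical scale
    separation the heating subtraction relies on: at q > 1.5 Å⁻¹ the
    measured difference signal is essentially all solvent.
    """
    w = np.ones_like(q)
    ramp = (q > 1.3) & (q < 1.45)
    w[ramp] = np.cos(np.pi / 2 * (q[ramp] - 1.3) / 0.15) ** 2
    w[q >= 1.45] = 0.0
    return w


def generate_dataset(
    truth: SyntheticTruth,
    times: np.ndarray,
    noise_sigma: float = 0.02,
    heating_amp: float = 0.0,
    seed: int = 0,
) -> DifferenceDataset:
    """Forward-model a time-resolved difference dataset.

    Each delay column is

        ΔI(:, t) = turnover [C1(t) basis_int + C2(t) basis_fin]
                   + heating_amp h(t) heating_ref + noise,

    with C1, C2 from the sequential two-state kinetics, the heating time
    profile h(t) = 1 − e^{−t/τ1} (heat deposited with the
    photochemistry), and i.i.d. Gaussian noise of standard deviation
    ``noise_sigma`` × max |protein signal|.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("delay times must be positive")
    model = kinetics.SequentialKineticModel(truth.tau1, truth.tau2)
    conc = kinetics.sequential_concentrations(model, times)
    basis = np.column_stack([truth.basis_int.I, truth.basis_fin.I])
    signal = truth.turnover * (basis @ conc)
    h_t = 1.0 - np.exp(-times / truth.tau1)
    data = signal + heating_amp * truth.heating_ref.I[:, None] * h_t[None, :]
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        scale = noise_sigma * np.max(np.abs(signal))
        data = data + rng.normal(0.0, scale, data.shape)
    return DifferenceDataset(truth.basis_int.q.copy(), times, data)


def make_truth(
    seed: int = 0,
    grid: scattering_calc.QGridSpec | None = None,
    tau1: float = 2e-6,
    tau2: float = 0.25,
    turnover: float = 0.7,
    dpsi_int: float = 11.0,
    dpsi_fin: float = 12.0,
    dchi: float = 2.0,
    internal_dchi: float = 8.0,
    n_res_per_chain: int = 385,
) -> tuple[SyntheticTruth, StructureModel, StructureModel, StructureModel]:
    """Build ground truth mirroring the photocycle's study conditions.

    The intermediate state carries an 11° left-handed supercoiling
    rotation plus a 2° bend; the final state a 12° rotation, the same
    bend, and an internal rearrangement of one CA domain
    (``internal_dchi`` tilt of chain A's CA blob) that distinguishes its
    basis curve shape, mirroring the internal kinase rearrangement of
    the slow step.  Basis difference curves come from the trimmed Debye
    forward model; when the grid extends past ~1.3 Å⁻¹ they are windowed
    to zero so the solvent-heating band contains no protein signal.

    Returns (truth, dark, light_int, light_fin).
    """
    grid = grid or scattering_calc.QGridSpec()
    base = make_toy_dimer(n_res_per_chain=n_res_per_chain, seed=seed)
    light_int = perturb_conformer(base, d_psi=dpsi_int, d_chi=dchi, seed=seed + 1)
    light_fin = perturb_conformer(base, d_psi=dpsi_fin, d_chi=dchi, seed=seed + 2)
    if internal_dchi != 0.0:
        # internal rearrangement of one CA domain: reorientation about its
        # own centroid, so the two basis curves differ in shape while
        # keeping comparable amplitudes (no net domain translation)
        splits = base.metadata.get("splits", DEFAULT_SPLITS)
        ca_sel = [("A", int(splits[2]) + 1, int(base.resnum.max()))]
        mask = light_fin.range_mask(ca_sel)
        coords = light_fin.coords.copy()
        pivot = coords[mask].mean(axis=0)
        t = np.radians(internal_dchi)
        rot = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, np.cos(t), -np.sin(t)],
                [0.0, np.sin(t), np.cos(t)],
            ]
        )
        coords[mask] = (coords[mask] - pivot) @ rot.T + pivot
        light_fin = light_fin.with_coords(coords)

    def basis_from(light: StructureModel) -> ScatteringCurve:
        dark_curve = scattering_calc.debye_intensity(
            scattering_calc.trim_flexible(base), grid
        )
        light_curve = scattering_calc.debye_intensity(
            scattering_calc.trim_flexible(light), grid
        )
        diff = scattering_calc.difference_curve(light_curve, dark_curve, 1.0)
        return ScatteringCurve(diff.q, diff.I * _highq_window(diff.q))

    basis_int = basis_from(light_int)
    basis_fin = basis_from(light_fin)
    truth = SyntheticTruth(
        tau1=tau1,
        tau2=tau2,
        turnover=turnover,
        basis_int=basis_int,
        basis_fin=basis_fin,
        heating_ref=heating_reference(basis_int.q),
        seed=seed,
    )
    return truth, base, light_int, light_fin
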