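"""Readers and writers for the formats the pipeline touches.

PDB structures (via biotite), delimited ΔI(q, t) tables, and two-column
beam-spectrum tables.  All readers validate the container invariants on
entry; all writers produce files that round-trip bit-exactly (tables) or
to PDB coordinate precision (structures).
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .models import BeamSpectrum, DifferenceDataset, StructureModel

__all__ = [
    "read_structure",
    "write_structure",
    "read_curve_table",
    "write_curve_table",
    "read_spectrum",
    "write_spectrum",
]


def read_structure(path: str | os.PathLike, ca_only: bool = True) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Sites appear in file order.  Only the first model of a multi-model
    file is used; for alternate locations the first altloc is kept.
    With ``ca_only`` (default) only CA ATOM records are retained and
    HETATM records (cofactors, ions, waters) are ignored.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file contains no ATOM records, or duplicate
        (chain, residue number, insertion code) CA sites.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such PDB file: {path}")
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    if atoms.array_length() == 0 or bool(np.all(atoms.hetero)):
        raise ValueError(f"{path}: no ATOM records found")
    if ca_only:
        mask = (~atoms.hetero) & (atoms.atom_name == "CA")
        if not mask.any():
            raise ValueError(f"{path}: no CA ATOM records found")
        atoms = atoms[mask]
    model = StructureModel(
        chain=atoms.chain_id,
        resnum=atoms.res_id,
        resname=atoms.res_name,
        coords=atoms.coord,
        icode=atoms.ins_code,
        metadata={"source": str(path)},
    )
    return model


def write_structure(structure: StructureModel, path: str | os.PathLike) -> None:
    """Write a Cα-level structure as a PDB file (one CA atom per site)."""
    n = len(structure)
    atoms = bst.AtomArray(n)
    atoms.chain_id = structure.chain
    atoms.res_id = structure.resnum
    atoms.ins_code = structure.icode
    atoms.res_name = structure.resname
    atoms.atom_name = np.full(n, "CA", dtype="U6")
    atoms.element = np.full(n, "C", dtype="U2")
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.coord = structure.coords
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_curve_table(path: str | os.PathLike) -> DifferenceDataset:
    """Read a delimited ΔI(q, t) table.

    Expected layout: lines starting with ``#`` are comments; the first
    non-comment row is a header whose first cell labels the q column and
    whose remaining cells are delay times in seconds (scientific
    notation accepted); each following row is ``q  ΔI(t1)  ΔI(t2) ...``.
    Tab, comma, and whitespace delimiters are accepted.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such table: {path}")
    frame = None
    try:
        # exact (round-trip) float parsing for tab and comma delimiters;
        # generic whitespace as a fallback
        for sep in ("\t", ","):
            candidate = pd.read_csv(
                path, sep=sep, comment="#", float_precision="round_trip"
            )
            if candidate.shape[1] > 1:
                frame = candidate
                break
        if frame is None:
            frame = pd.read_csv(path, sep=r"\s+", comment="#", engine="python")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed table ({err})") from err
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need a q column plus at least one delay column")
    try:
        times = np.array([float(c) for c in frame.columns[1:]])
    except ValueError as err:
        raise ValueError(
            f"{path}: header cells after the first must be delay times in "
            f"seconds, got {list(frame.columns[1:])}"
        ) from err
    values = frame.to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-numeric cell in table body") from err
    if np.any(~np.isfinite(values)):
        raise ValueError(f"{path}: non-numeric or missing cell in table body")
    return DifferenceDataset(q=values[:, 0], times=times, dI=values[:, 1:])


def write_curve_table(dataset: DifferenceDataset, path: str | os.PathLike) -> None:
    """Write a ΔI(q, t) table readable by :func:`read_curve_table`.

    Values are printed with 17 significant digits so the round trip is
    bit-exact for doubles.
    """
    with open(path, "w") as fh:
        fh.write("# difference scattering dI(q, t); q in 1/A, delays in s\n")
        fh.write("q\t" + "\t".join(f"{t:.17g}" for t in dataset.times) + "\n")
        for i in range(dataset.n_q):
            row = "\t".join(f"{v:.17g}" for v in dataset.dI[i])
            fh.write(f"{dataset.q[i]:.17g}\t{row}\n")


def read_spectrum(path: str | os.PathLike) -> BeamSpectrum:
    """Read a two-column (energy, weight) table and renormalize weights to 1."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such spectrum table: {path}")
    data = np.atleast_2d(np.loadtxt(path, comments="#", ndmin=2))
    if data.size == 0:
        raise ValueError(f"{path}: spectrum table is empty")
    if data.shape[1] != 2:
        raise ValueError(
            f"{path}: expected two columns (energy, weight), got {data.shape[1]}"
        )
    return BeamSpectrum(energy=data[:, 0], weight=data[:, 1]).normalized()


def write_spectrum(spectrum: BeamSpectrum, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# beam spectrum: energy (keV)\tweight\n")
        for e, w in zip(spectrum.energy, spectrum.weight):
            fh.write(f"{e:.17g}\t{w:.17g}\n")
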