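"""Molecule I/O and conformer generation.

Molecules are thin wrappers around RDKit molecules carrying a stable id and a
permutation-invariant structure key.  SDF is read in V2000/V3000 and written
in V2000; SMILES tables are tab-separated ``smiles<TAB>id``.  Conformer
ensembles come from seeded distance-geometry embedding (ETKDG) so that a
fixed seed reproduces coordinates bitwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rdkit parse noise is re-reported via logging


class ChemIOError(RuntimeError):
    pass


class ConformerError(ChemIOError):
    """Molecule could not be embedded in 3D."""


@dataclass
class Molecule:
    """A small molecule with zero or more 3D conformers (coordinates in Å)."""

    id: str
    rdmol: Chem.Mol
    name: str | None = None

    @property
    def atoms(self) -> list[tuple[str, int, bool]]:
        """(element symbol, formal charge, aromatic flag) per atom."""
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
            for a in self.rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[tuple[int, int], float]]:
        return [
            ((b.GetBeginAtomIdx(), b.GetEndAtomIdx()), b.GetBondTypeAsDouble())
            for b in self.rdmol.GetBonds()
        ]

    @property
    def num_conformers(self) -> int:
        return self.rdmol.GetNumConformers()

    @property
    def conformers(self) -> list[np.ndarray]:
        return [
            np.array(self.rdmol.GetConformer(i).GetPositions())
            for i in range(self.rdmol.GetNumConformers())
        ]

    def conformer(self, index: int) -> np.ndarray:
        if index >= self.rdmol.GetNumConformers():
            raise IndexError(
                f"molecule {self.id!r} has {self.rdmol.GetNumConformers()} "
                f"conformer(s), no index {index}"
            )
        return np.array(self.rdmol.GetConformer(index).GetPositions())

    def heavy_atom_coords(self, conformer_index: int) -> np.ndarray:
        coords = self.conformer(conformer_index)
        heavy = [a.GetIdx() for a in self.rdmol.GetAtoms() if a.GetAtomicNum() > 1]
        return coords[heavy]

    @property
    def structure_key(self) -> str:
        """Canonical hashed structure identifier (InChIKey).

        Identical for identical connectivity and stereochemistry regardless
        of atom ordering; used for cross-referencing against identifier lists.
        """
        mol = Chem.RemoveHs(self.rdmol)
        key = Chem.MolToInchiKey(mol)
        if key:
            return key
        # very exotic species can fail InChI; canonical SMILES is still stable
        return "SMI-" + Chem.MolToSmiles(mol)


@dataclass
class LibraryRecord:
    molecule: Molecule
    source: str
    record_index: int


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------


def read_sdf(path: str | Path, strict: bool = False) -> list[LibraryRecord]:
    """Read an SDF (V2000/V3000) into library records.

    3D coordinates are preserved as written; records whose molfile is flagged
    2D carry zero conformers.  Malformed records are skipped with a logged
    warning unless ``strict`` is set, in which case they abort the read.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"cannot read {path}: no such file")
    if path.stat().st_size == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    records: list[LibraryRecord] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            msg = f"{path}: record {i + 1} is malformed"
            if strict:
                raise ChemIOError(msg)
            log.warning("%s; skipped", msg)
            continue
        if mol.GetNumConformers() and not mol.GetConformer().Is3D():
            mol.RemoveAllConformers()
        mol_id = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not mol_id:
            mol_id = f"{path.stem}-{i + 1}"
        records.append(
            LibraryRecord(Molecule(mol_id, mol, name=mol_id), str(path), len(records))
        )
    return records


def write_sdf(records: Iterable[LibraryRecord], path: str | Path) -> None:
    """Write records as V2000 SDF, one record per conformer.

    Multi-conformer molecules are emitted as consecutive records sharing the
    same id.  Round-trips preserve atom/bond counts and coordinates at the
    4-decimal molfile precision.
    """
    try:
        writer = Chem.SDWriter(str(path))
    except OSError as exc:
        raise ChemIOError(f"cannot write {path}: {exc}") from exc
    writer.SetForceV3000(False)
    for rec in records:
        mol = Chem.Mol(rec.molecule.rdmol)
        mol.SetProp("_Name", rec.molecule.id)
        if mol.GetNumConformers() == 0:
            writer.write(mol)
        else:
            for ci in range(mol.GetNumConformers()):
                writer.write(mol, confId=mol.GetConformer(ci).GetId())
    writer.close()


# ---------------------------------------------------------------------------
# SMILES tables
# ---------------------------------------------------------------------------


def read_smiles_table(path: str | Path) -> list[LibraryRecord]:
    """Read a tab-separated ``smiles<TAB>id`` table (optional header line).

    Molecules carry zero conformers; stereo descriptors are retained in the
    structure key.  Unparsable lines are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"cannot read {path}: no such file")
    records: list[LibraryRecord] = []
    seen_ids: set[str] = set()
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            if lineno == 1 and smiles.lower() in ("smiles", "canonical_smiles"):
                continue  # header
            mol_id = parts[1] if len(parts) > 1 else f"{path.stem}-{lineno}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                n_bad += 1
                log.warning("%s:%d: unparsable SMILES %r; skipped", path, lineno, smiles)
                continue
            if mol_id in seen_ids:
                log.warning("%s:%d: duplicate id %r kept", path, lineno, mol_id)
            seen_ids.add(mol_id)
            records.append(
                LibraryRecord(Molecule(mol_id, mol, name=mol_id), str(path), len(records))
            )
    if n_bad:
        log.warning("%s: %d unparsable line(s) skipped", path, n_bad)
    return records


# ---------------------------------------------------------------------------
# Conformer generation
# ---------------------------------------------------------------------------


def generate_conformers(
    molecule: Molecule,
    max_conformers: int = 200,
    seed: int = 42,
    prune_rms: float = 0.25,
) -> Molecule:
    """Generate up to ``max_conformers`` 3D conformers by seeded ETKDG embedding.

    Hydrogens are made explicit before embedding and kept on the returned
    molecule.  The same seed yields bitwise-identical coordinates (embedding
    runs single-threaded).  ``prune_rms`` (Å) is the RMSD threshold used to
    drop near-duplicate conformers; it is a configuration knob, not a fidelity
    claim about any particular ensemble generator.
    """
    if max_conformers < 1:
        raise ValueError("max_conformers must be >= 1")
    mol = Chem.AddHs(Chem.Mol(molecule.rdmol))
    mol.RemoveAllConformers()
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.numThreads = 1
    params.pruneRmsThresh = float(prune_rms)
    params.useRandomCoords = False
    try:
        conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=int(max_conformers), params=params)
    except ValueError as exc:
        raise ConformerError(f"molecule {molecule.id!r} could not be embedded in 3D: {exc}") from exc
    if len(conf_ids) == 0:
        raise ConformerError(f"molecule {molecule.id!r} could not be embedded in 3D")
    return Molecule(molecule.id, mol, name=molecule.name)
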