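"""Typed pharmacophoric feature perception on a single conformer.

Four feature classes are perceived:

* **HBD** — hydrogen-bond donor, placed on the donor heavy atom (one feature
  per heavy atom, not per hydrogen); direction along the mean N/O→H vector
  when explicit hydrogens with coordinates exist.
* **HBA** — hydrogen-bond acceptor, placed on the acceptor heavy atom;
  direction approximates the lone-pair bisector (pointing away from the mean
  of the bonded neighbours).
* **AI** — aromatic interaction, at the centroid of each 5- or 6-membered
  aromatic ring, with the unit normal of the ring least-squares plane.
* **HC** — hydrophobic contact, at the centroid of each maximal connected
  cluster of at least three contiguous low-polarity atoms (C, S, halogens,
  excluding carbons bonded to N or O).

The default SMARTS rule table follows common pharmacophore-tool semantics:
N–H and O–H as donors; pyridine-type aromatic N, amine/imine N and most O as
acceptors, excluding amide N, nitro O and pyrrole-type aromatic N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from pharmscreen.chem_io import Molecule
from pharmscreen.model import FeatureKind

_KIND_ORDER = {k: i for i, k in enumerate(FeatureKind)}


@dataclass(frozen=True)
class LigandFeature:
    """One perceived feature on one conformer: a typed point, optional direction."""

    kind: FeatureKind
    position: np.ndarray
    direction: np.ndarray | None = None
    atom_indices: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "kind", FeatureKind(self.kind))
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"feature position must be 3D, got shape {pos.shape}")
        object.__setattr__(self, "position", pos)
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            n = np.linalg.norm(d)
            if abs(n - 1.0) > 1e-9:
                if n == 0:
                    raise ValueError("zero feature direction")
                d = d / n
            object.__setattr__(self, "direction", d)
        object.__setattr__(self, "atom_indices", tuple(self.atom_indices))
        if not self.atom_indices:
            raise ValueError("atom_indices must be non-empty")


@dataclass
class FeatureSet:
    """All perceived features of one conformer of one molecule."""

    molecule_id: str
    conformer_index: int
    features: list[LigandFeature] = field(default_factory=list)

    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features]).reshape(-1, 3)

    def of_kind(self, kind: FeatureKind) -> list[LigandFeature]:
        return [f for f in self.features if f.kind == kind]


@dataclass(frozen=True)
class PerceptionRules:
    """SMARTS rule table driving feature perception."""

    hbd_smarts: tuple[str, ...]
    hba_smarts: tuple[str, ...]
    aromatic_ring_sizes: tuple[int, ...] = (5, 6)
    hc_min_cluster: int = 3

    def __post_init__(self):
        if not self.hbd_smarts and not self.hba_smarts:
            raise ValueError("empty rule table")
        for patt in (*self.hbd_smarts, *self.hba_smarts):
            if Chem.MolFromSmarts(patt) is None:
                raise ValueError(f"invalid SMARTS pattern {patt!r}")


DEFAULT_RULES = PerceptionRules(
    hbd_smarts=(
        "[#7;!H0;+0,+1]",  # N-H (aliphatic or aromatic, neutral or cationic)
        "[#8;!H0;+0]",  # O-H
    ),
    hba_smarts=(
        "[n;X2;+0]",  # pyridine-type aromatic N (pyrrole nH is X3)
        "[N;X2;+0;!$(N=O)]",  # imine / sp2 N
        "[N;X3;+0;!$([N]C=[O,S,N]);!$([N]S=O);!$([N][N]=O);!a]",  # amine, not amide
        "[O;X2;+0;!$([O][N+])]",  # hydroxyl / ether O
        "[O;X1;+0;$([O]=[C,S,P]);!$([O]=[C,S,P][O-])]",  # carbonyl-type O
    ),
)


def perceive_features(
    molecule: Molecule,
    conformer_index: int = 0,
    rules: PerceptionRules = DEFAULT_RULES,
) -> FeatureSet:
    """Perceive typed features on one conformer.

    Output order is deterministic: by kind (HBD, HBA, HC, AI), then by lowest
    supporting atom index.
    """
    mol = molecule.rdmol
    coords = molecule.conformer(conformer_index)  # raises IndexError if missing

    feats: list[LigandFeature] = []
    feats.extend(_donors(mol, coords, rules))
    feats.extend(_acceptors(mol, coords, rules))
    feats.extend(_hydrophobic(mol, coords, rules))
    feats.extend(_aromatic(mol, coords, rules))
    feats.sort(key=lambda f: (_KIND_ORDER[f.kind], min(f.atom_indices)))
    return FeatureSet(molecule.id, conformer_index, feats)


def _match_atoms(mol: Chem.Mol, patterns: tuple[str, ...]) -> list[int]:
    hits: set[int] = set()
    for patt in patterns:
        q = Chem.MolFromSmarts(patt)
        for match in mol.GetSubstructMatches(q):
            hits.add(match[0])
    return sorted(hits)


def _donors(mol, coords, rules) -> list[LigandFeature]:
    out = []
    for idx in _match_atoms(mol, rules.hbd_smarts):
        atom = mol.GetAtomWithIdx(idx)
        h_idx = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]
        direction = None
        if h_idx:
            # mean heavy-atom -> H vector; collapses multiple H to one feature
            vecs = coords[h_idx] - coords[idx]
            mean = vecs.mean(axis=0)
            if np.linalg.norm(mean) > 1e-9:
                direction = mean / np.linalg.norm(mean)
        out.append(LigandFeature(FeatureKind.HBD, coords[idx], direction, (idx,)))
    return out


def _acceptors(mol, coords, rules) -> list[LigandFeature]:
    out = []
    for idx in _match_atoms(mol, rules.hba_smarts):
        atom = mol.GetAtomWithIdx(idx)
        nbrs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
        direction = None
        if nbrs:
            # lone-pair bisector approximation: away from bonded neighbours
            away = coords[idx] - coords[nbrs].mean(axis=0)
            if np.linalg.norm(away) > 1e-9:
                direction = away / np.linalg.norm(away)
        out.append(LigandFeature(FeatureKind.HBA, coords[idx], direction, (idx,)))
    return out


_HC_ELEMENTS = {6, 9, 16, 17, 35, 53}  # C, F, S, Cl, Br, I


def _is_lipophilic(atom: Chem.Atom) -> bool:
    if atom.GetAtomicNum() not in _HC_ELEMENTS:
        return False
    return not any(n.GetAtomicNum() in (7, 8) for n in atom.GetNeighbors())


def _hydrophobic(mol, coords, rules) -> list[LigandFeature]:
    lipo = {a.GetIdx() for a in mol.GetAtoms() if _is_lipophilic(a)}
    # connected components of the lipophilic-atom subgraph
    seen: set[int] = set()
    out = []
    for start in sorted(lipo):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for n in mol.GetAtomWithIdx(i).GetNeighbors():
                j = n.GetIdx()
                if j in lipo and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(comp) >= rules.hc_min_cluster:
            comp = sorted(comp)
            out.append(
                LigandFeature(FeatureKind.HC, coords[comp].mean(axis=0), None, tuple(comp))
            )
    return out


def _aromatic(mol, coords, rules) -> list[LigandFeature]:
    out = []
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) not in rules.aromatic_ring_sizes:
            continue
        if not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        pts = coords[list(ring)]
        centroid = pts.mean(axis=0)
        normal = ring_plane_normal(pts)
        out.append(
            LigandFeature(FeatureKind.AI, centroid, normal, tuple(sorted(ring)))
        )
    return out


def ring_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through ``points``.

    The sign is fixed deterministically (first non-zero component positive);
    ring normals are intrinsically sign-ambiguous and matching treats them as
    axes.
    """
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    for c in normal:
        if abs(c) > 1e-12:
            if c < 0:
                normal = -normal
            break
    return normal / np.linalg.norm(normal)
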