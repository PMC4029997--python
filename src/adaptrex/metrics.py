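"""Structural comparison metrics: fraction of native contacts and bead RMSD.

Native contacts are all residue pairs (i, j), j > i, whose side-chain-center
distance is strictly below a 6.5 A cutoff in the reference structure; the
fraction of native contacts of a decoy is the share of those pairs still
within the cutoff.  RMSD is the Kabsch rigid-body minimum over proper
rotations and translations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .errors import (
    InvalidArgumentError,
    InvalidStructureError,
    UndefinedMetricError,
)
from .models import BeadStructure

__all__ = [
    "ContactSet",
    "side_chain_centers",
    "side_chain_centers_from_pdb",
    "native_contacts",
    "fraction_native_contacts",
    "kabsch_rmsd",
]

DEFAULT_CONTACT_CUTOFF = 6.5  # A

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class ContactSet:
    """Residue index pairs (i, j) with j > i, plus the defining cutoff."""

    pairs: frozenset
    cutoff: float

    def __post_init__(self):
        for i, j in self.pairs:
            if j <= i:
                raise InvalidArgumentError(f"contact pair ({i}, {j}) must have j > i")

    def __len__(self) -> int:
        return len(self.pairs)


def side_chain_centers(residues) -> BeadStructure:
    """Mass-weighted side-chain center per residue.

    ``residues`` is an iterable of ``(coords, masses)`` with coords of shape
    (n_atoms, 3).  Use :func:`side_chain_centers_from_pdb` for all-atom PDB
    input, where backbone atoms are stripped first (glycine keeps its CA).
    """
    centers = []
    for idx, (coords, masses) in enumerate(residues):
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        masses = np.asarray(masses, dtype=float).reshape(-1)
        if coords.shape[0] == 0:
            raise InvalidStructureError(f"residue {idx} has no atoms")
        if coords.shape[0] != masses.shape[0]:
            raise InvalidStructureError(f"residue {idx}: coords/masses mismatch")
        centers.append(masses @ coords / masses.sum())
    return BeadStructure(np.asarray(centers))


def side_chain_centers_from_pdb(path, model_index: int = 0) -> BeadStructure:
    """Side-chain centers of mass from an all-atom PDB file.

    Backbone atoms (N, CA, C, O, OXT) and hydrogens are excluded; residues
    with no side-chain atoms (glycine) fall back to their CA position.
    """
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("s", path)
    model = list(structure)[model_index]
    groups = []
    labels = []
    for chain in model:
        for residue in chain:
            if residue.id[0].strip():
                continue  # skip heteroatoms / waters
            side = [
                a for a in residue
                if a.get_name() not in _BACKBONE_ATOMS and a.element != "H"
            ]
            if not side:
                if "CA" not in residue:
                    raise InvalidStructureError(
                        f"residue {residue.id[1]} has no side chain and no CA"
                    )
                side = [residue["CA"]]
            groups.append(
                (np.array([a.coord for a in side]), np.array([a.mass for a in side]))
            )
            labels.append(str(residue.id[1]))
    bead = side_chain_centers(groups)
    return BeadStructure(bead.coords, tuple(labels))


def _pair_distances(structure: BeadStructure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = structure.n_res
    ii, jj = np.triu_indices(n, k=1)
    return ii, jj, pdist(structure.coords)


def native_contacts(
    native: BeadStructure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_separation: int = 0,
) -> ContactSet:
    """All pairs j > i strictly closer than ``cutoff`` in the native structure.

    ``min_separation`` optionally requires j - i > min_separation (default 0,
    i.e. every j > i pair counts, including chain neighbors).
    """
    if cutoff <= 0.0:
        raise InvalidArgumentError("cutoff must be positive")
    ii, jj, d = _pair_distances(native)
    keep = (d < cutoff) & (jj - ii > min_separation)
    pairs = frozenset((int(i), int(j)) for i, j in zip(ii[keep], jj[keep]))
    return ContactSet(pairs=pairs, cutoff=float(cutoff))


def fraction_native_contacts(
    decoy: BeadStructure,
    native: BeadStructure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_separation: int = 0,
) -> float:
    """Share of native contacts preserved (distance < cutoff) in the decoy."""
    if decoy.n_res != native.n_res:
        raise InvalidArgumentError(
            f"residue counts differ: decoy {decoy.n_res} vs native {native.n_res}"
        )
    contacts = native_contacts(native, cutoff, min_separation)
    if len(contacts) == 0:
        raise UndefinedMetricError("native structure has no contacts under cutoff")
    idx = np.array(sorted(contacts.pairs))
    d = np.linalg.norm(decoy.coords[idx[:, 0]] - decoy.coords[idx[:, 1]], axis=1)
    return float(np.count_nonzero(d < cutoff) / len(contacts))


def _as_coords(s) -> np.ndarray:
    return s.coords if isinstance(s, BeadStructure) else np.asarray(s, dtype=float)


def kabsch_rmsd(a, b) -> float:
    """Minimum RMSD between paired point sets over proper rigid motions.

    Reflections are disallowed (determinant-corrected rotation).  Accepts
    BeadStructures or plain (n, 3) arrays.
    """
    pa = _as_coords(a)
    pb = _as_coords(b)
    if pa.shape != pb.shape:
        raise InvalidArgumentError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    if pa.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 points")
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(pa.shape[0]))
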