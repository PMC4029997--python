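"""Synthetic energy models, bead structures and decoy generation.

Desk-scale stand-ins for an all-atom refinement landscape: an analytic
harmonic well, a quartic double well with a sharp barrier between two basins,
and a structure-based (Go-type) bead model whose global minimum sits at a
reference native conformation.  Decoy ensembles are produced by controlled
Gaussian perturbation of the native beads.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, InvalidStructureError

__all__ = [
    "EnergyModel",
    "BeadStructure",
    "DecoySet",
    "HarmonicModel",
    "DoubleWellModel",
    "GoBeadModel",
    "harmonic_model",
    "double_well_model",
    "go_bead_model",
    "generate_decoys",
    "ideal_helix",
]


class EnergyModel(abc.ABC):
    """Potential energy + gradient contract for any sampled system."""

    dim: int
    metadata: dict

    @abc.abstractmethod
    def energy(self, x: np.ndarray) -> float:
        """Potential energy of one configuration of shape (dim,)."""

    @abc.abstractmethod
    def gradient(self, x: np.ndarray) -> np.ndarray:
        """dE/dx for one configuration of shape (dim,)."""

    def energy_batch(self, xs: np.ndarray) -> np.ndarray:
        """Energies for a stack of configurations of shape (n, dim)."""
        return np.array([self.energy(x) for x in xs])

    def gradient_batch(self, xs: np.ndarray) -> np.ndarray:
        return np.stack([self.gradient(x) for x in xs])


class HarmonicModel(EnergyModel):
    """Isotropic harmonic well E = k |x|^2 / 2."""

    def __init__(self, k: float, dim: int):
        if k <= 0.0:
            raise InvalidArgumentError("stiffness must be positive")
        if dim < 1:
            raise InvalidArgumentError("dim must be >= 1")
        self.k = float(k)
        self.dim = int(dim)
        self.metadata = {"kind": "harmonic", "k": self.k, "dim": self.dim}

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return float(0.5 * self.k * np.dot(x, x))

    def gradient(self, x):
        return self.k * np.asarray(x, dtype=float)

    def energy_batch(self, xs):
        xs = np.asarray(xs, dtype=float)
        return 0.5 * self.k * np.einsum("ij,ij->i", xs, xs)

    def gradient_batch(self, xs):
        return self.k * np.asarray(xs, dtype=float)


class DoubleWellModel(EnergyModel):
    """1D quartic double well E(x) = barrier * ((x/x0)^2 - 1)^2.

    Minima at x = +-x0 with E = 0; barrier height E(0) = barrier.
    """

    dim = 1

    def __init__(self, barrier: float, x0: float):
        if barrier <= 0.0 or x0 <= 0.0:
            raise InvalidArgumentError("barrier and x0 must be positive")
        self.barrier = float(barrier)
        self.x0 = float(x0)
        self.metadata = {"kind": "double_well", "barrier": self.barrier, "x0": self.x0}

    def energy(self, x):
        s = float(np.asarray(x).reshape(-1)[0])
        u = (s / self.x0) ** 2 - 1.0
        return float(self.barrier * u * u)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        u = (x / self.x0) ** 2 - 1.0
        return 4.0 * self.barrier * x * u / self.x0 ** 2

    def energy_batch(self, xs):
        xs = np.asarray(xs, dtype=float)
        u = (xs[:, 0] / self.x0) ** 2 - 1.0
        return self.barrier * u * u

    def gradient_batch(self, xs):
        xs = np.asarray(xs, dtype=float)
        u = (xs / self.x0) ** 2 - 1.0
        return 4.0 * self.barrier * xs * u / self.x0 ** 2


@dataclass(frozen=True)
class BeadStructure:
    """One bead per residue, treated as that residue's side-chain center (A)."""

    coords: np.ndarray
    labels: tuple = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InvalidStructureError("coords must have shape (n_res, 3)")
        if coords.shape[0] < 3:
            raise InvalidStructureError("need at least 3 residues")
        if not np.all(np.isfinite(coords)):
            raise InvalidStructureError("coordinates must be finite")
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(str(i + 1) for i in range(coords.shape[0]))
            )
        elif len(self.labels) != coords.shape[0]:
            raise InvalidStructureError("labels length must match residue count")

    @property
    def n_res(self) -> int:
        return int(self.coords.shape[0])

    # ---- I/O: CA-only PDB and XYZ -------------------------------------

    def to_pdb(self, path, model_sets=None) -> None:
        """Write as CA-only PDB; ``model_sets`` adds extra MODEL entries."""
        frames = [self.coords] + ([] if model_sets is None else list(model_sets))
        with open(path, "w") as fh:
            fh.write(_pdb_text(frames))

    def to_xyz(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_res}\nbead structure\n")
            for c in self.coords:
                fh.write(f"CA {c[0]:12.5f} {c[1]:12.5f} {c[2]:12.5f}\n")

    @classmethod
    def from_xyz(cls, path) -> "BeadStructure":
        with open(path) as fh:
            lines = fh.read().splitlines()
        n = int(lines[0].split()[0])
        coords = [
            [float(v) for v in ln.split()[1:4]] for ln in lines[2 : 2 + n]
        ]
        return cls(np.asarray(coords))

    @classmethod
    def from_pdb(cls, path, model_index: int = 0) -> "BeadStructure":
        frames, labels = read_bead_pdb(path)
        return cls(frames[model_index], labels)


def _pdb_text(frames) -> str:
    multi = len(frames) > 1
    out = []
    for mi, coords in enumerate(frames):
        if multi:
            out.append(f"MODEL     {mi + 1:4d}")
        for i, c in enumerate(np.asarray(coords, dtype=float)):
            out.append(
                f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
                f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}  1.00  0.00           C"
            )
        if multi:
            out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"


def read_bead_pdb(path):
    """Read CA records of a (possibly multi-model) PDB into coordinate frames."""
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("bead", path)
    frames = []
    labels = None
    for model in structure:
        coords = []
        labs = []
        for chain in model:
            for residue in chain:
                if "CA" in residue:
                    coords.append(residue["CA"].coord)
                    labs.append(str(residue.id[1]))
        frames.append(np.asarray(coords, dtype=float))
        labels = tuple(labs)
    if not frames or frames[0].shape[0] == 0:
        raise InvalidStructureError(f"no CA records found in {path}")
    return frames, labels


@dataclass(frozen=True)
class DecoySet:
    """Native reference plus perturbed decoys and their provenance."""

    native: BeadStructure
    decoys: tuple
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for d in self.decoys:
            if d.n_res != self.native.n_res:
                raise InvalidStructureError("decoy residue count must match native")

    def to_pdb(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(_pdb_text([d.coords for d in self.decoys]))


class GoBeadModel(EnergyModel):
    """Structure-based bead potential with its minimum at the native fold.

    Terms: harmonic chain bonds at native lengths, a 12-10 attraction at the
    native separation for each native-contact pair (sequence separation >= 2),
    and a purely repulsive r^-12 wall for the remaining nonbonded pairs.
    All terms depend on pair distances only, so the energy is invariant under
    rigid motion.
    """

    def __init__(
        self,
        native: BeadStructure,
        contact_cutoff: float = 6.5,
        eps: float = 1.0,
        bond_k: float = 100.0,
        repulsion_sigma: float = 4.0,
    ):
        if contact_cutoff <= 0.0:
            raise InvalidArgumentError("contact cutoff must be positive")
        coords = native.coords
        n = native.n_res
        self.native = native
        self.dim = 3 * n
        self.n_res = n
        self.eps = float(eps)
        self.bond_k = float(bond_k)
        self.repulsion_sigma = float(repulsion_sigma)

        ii, jj = np.triu_indices(n, k=1)
        d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
        if np.any(d < 1e-6):
            raise InvalidStructureError("native has coincident beads")

        bonded = jj - ii == 1
        self.bond_i, self.bond_j = ii[bonded], jj[bonded]
        self.bond_r0 = d[bonded]

        contact = (~bonded) & (d < contact_cutoff)
        self.con_i, self.con_j = ii[contact], jj[contact]
        self.con_r0 = d[contact]

        rep = (~bonded) & ~contact
        self.rep_i, self.rep_j = ii[rep], jj[rep]

        self.metadata = {
            "kind": "go_bead",
            "n_res": n,
            "contact_cutoff": float(contact_cutoff),
            "eps": self.eps,
            "bond_k": self.bond_k,
            "repulsion_sigma": self.repulsion_sigma,
            "n_contacts": int(contact.sum()),
        }

    def _pair_terms(self, xyz):
        """Distances per term group for a (n_res, 3) configuration."""
        db = np.linalg.norm(xyz[self.bond_i] - xyz[self.bond_j], axis=1)
        dc = np.linalg.norm(xyz[self.con_i] - xyz[self.con_j], axis=1)
        dr = np.linalg.norm(xyz[self.rep_i] - xyz[self.rep_j], axis=1)
        return db, dc, dr

    def energy(self, x):
        xyz = np.asarray(x, dtype=float).reshape(self.n_res, 3)
        db, dc, dr = self._pair_terms(xyz)
        e = 0.5 * self.bond_k * np.sum((db - self.bond_r0) ** 2)
        s = self.con_r0 / dc
        e += self.eps * np.sum(5.0 * s**12 - 6.0 * s**10)
        e += self.eps * np.sum((self.repulsion_sigma / dr) ** 12)
        return float(e)

    def gradient(self, x):
        xyz = np.asarray(x, dtype=float).reshape(self.n_res, 3)
        grad = np.zeros_like(xyz)

        def add(i_idx, j_idx, dEdd):
            rij = xyz[i_idx] - xyz[j_idx]
            d = np.linalg.norm(rij, axis=1)
            g = (dEdd / d)[:, None] * rij
            np.add.at(grad, i_idx, g)
            np.add.at(grad, j_idx, -g)

        db, dc, dr = self._pair_terms(xyz)
        add(self.bond_i, self.bond_j, self.bond_k * (db - self.bond_r0))
        s = self.con_r0 / dc
        add(self.con_i, self.con_j, (60.0 * self.eps / dc) * (s**10 - s**12))
        add(self.rep_i, self.rep_j,
            -12.0 * self.eps * (self.repulsion_sigma / dr) ** 12 / dr)
        return grad.reshape(-1)


def harmonic_model(k: float, dim: int) -> HarmonicModel:
    """Analytic test system E = k |x|^2 / 2."""
    return HarmonicModel(k, dim)


def double_well_model(barrier: float, x0: float) -> DoubleWellModel:
    """Two basins at +-x0 separated by a barrier of the given height."""
    return DoubleWellModel(barrier, x0)


def go_bead_model(
    native: BeadStructure,
    contact_cutoff: float = 6.5,
    eps: float = 1.0,
    bond_k: float = 100.0,
    repulsion_sigma: float = 4.0,
) -> GoBeadModel:
    return GoBeadModel(native, contact_cutoff, eps, bond_k, repulsion_sigma)


def generate_decoys(
    native: BeadStructure, n: int, sigma: float, seed: int
) -> DecoySet:
    """Perturb the native beads with isotropic Gaussian noise of scale sigma (A)."""
    if n < 1:
        raise InvalidArgumentError("need at least one decoy")
    if sigma < 0.0:
        raise InvalidArgumentError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(n, native.n_res, 3)) if sigma > 0 else np.zeros((n, native.n_res, 3))
    decoys = tuple(
        BeadStructure(native.coords + noise[i], native.labels) for i in range(n)
    )
    return DecoySet(
        native=native,
        decoys=decoys,
        provenance={"sigma": float(sigma), "seed": int(seed), "n": int(n)},
    )


def ideal_helix(n_res: int, rise: float = 1.5, radius: float = 2.3,
                twist_deg: float = 100.0) -> BeadStructure:
    """Idealized alpha-helical CA trace; a convenient compact synthetic native."""
    if n_res < 3:
        raise InvalidArgumentError("need at least 3 residues")
    t = np.arange(n_res) * np.deg2rad(twist_deg)
    coords = np.stack(
        [radius * np.cos(t), radius * np.sin(t), rise * np.arange(n_res)], axis=1
    )
    return BeadStructure(coords)
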