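"""Chromophore structural descriptors along a trajectory.

For a conjugated (retinal-like) backbone described by five single (sigma)
and five double (pi) bonds the descriptors are:

* bond-length alternation ``BLA = (sum sigma_i - sum pi_i) / 5`` in Å,
* the ten backbone dihedrals around those bonds (degrees, IUPAC sign
  convention, range (-180, 180]),
* planarity ``P = sum_i (| |theta_i| - 90 |) / 90`` in [0, 10]:
  P = 10 when every dihedral is planar (0 or 180 deg), P = 0 when every
  dihedral is fully twisted (+-90 deg).

Conventions used in every file this module reads or writes: 0-based atom
indices, coordinates in Å, dihedrals in degrees in (-180, 180].  The
absolute value of theta is taken before the planarity map, so P is
continuous across the +-180 deg wrap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConjugationTopology",
    "Trajectory",
    "StructuralTimeline",
    "bond_length",
    "bla",
    "dihedral",
    "planarity",
    "timeline",
    "freedman_diaconis_bins",
]


@dataclass(frozen=True)
class ConjugationTopology:
    """Atom-index map of the conjugated backbone.

    Exactly five sigma bonds, five pi bonds, and one dihedral quadruple per
    bond (ten total); each quadruple's central pair must be its bond.
    Indices are 0-based into the frame's atom list.
    """

    sigma_bonds: tuple[tuple[int, int], ...]
    pi_bonds: tuple[tuple[int, int], ...]
    dihedrals: tuple[tuple[int, int, int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma_bonds", tuple(map(tuple, self.sigma_bonds)))
        object.__setattr__(self, "pi_bonds", tuple(map(tuple, self.pi_bonds)))
        object.__setattr__(self, "dihedrals", tuple(map(tuple, self.dihedrals)))
        if len(self.sigma_bonds) != 5 or len(self.pi_bonds) != 5:
            raise ValueError("need exactly 5 sigma and 5 pi bonds")
        if len(self.dihedrals) != 10:
            raise ValueError("need exactly 10 dihedrals (one per bond)")
        bonds = set(self.sigma_bonds) | set(self.pi_bonds)
        for quad in self.dihedrals:
            central = (quad[1], quad[2])
            if central not in bonds and central[::-1] not in bonds:
                raise ValueError(
                    f"dihedral {quad} central pair {central} is not a listed bond"
                )

    @property
    def bonds(self) -> tuple[tuple[int, int], ...]:
        return self.sigma_bonds + self.pi_bonds

    def validate_against(self, n_atoms: int) -> None:
        indices = [i for b in self.bonds for i in b] + [
            i for q in self.dihedrals for i in q
        ]
        if min(indices) < 0 or max(indices) >= n_atoms:
            raise ValueError(
                f"topology indexes atoms outside 0..{n_atoms - 1}"
            )

    @classmethod
    def from_json(cls, path) -> "ConjugationTopology":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            sigma_bonds=tuple(map(tuple, data["sigma_bonds"])),
            pi_bonds=tuple(map(tuple, data["pi_bonds"])),
            dihedrals=tuple(map(tuple, data["dihedrals"])),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "sigma_bonds": [list(b) for b in self.sigma_bonds],
                    "pi_bonds": [list(b) for b in self.pi_bonds],
                    "dihedrals": [list(q) for q in self.dihedrals],
                },
                fh,
                indent=1,
            )


@dataclass
class Trajectory:
    """Multi-frame coordinate set: elements, (n_frames, n_atoms, 3) Å, fs."""

    elements: tuple[str, ...]
    coordinates: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != len(self.elements):
            raise ValueError("atom count mismatch between elements and coordinates")
        if self.times.size != self.coordinates.shape[0]:
            raise ValueError("one time per frame required")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]


@dataclass
class StructuralTimeline:
    """Per-frame descriptors; dihedrals in degrees, lengths in Å."""

    times: np.ndarray
    bla: np.ndarray
    sigma_lengths: np.ndarray     # (n_frames, 5)
    pi_lengths: np.ndarray        # (n_frames, 5)
    dihedrals: np.ndarray         # (n_frames, 10), (-180, 180]
    planarity: np.ndarray         # [0, 10]

    def summaries(self) -> dict[str, dict[str, float]]:
        out = {}
        for name, arr in (("bla", self.bla), ("planarity", self.planarity)):
            out[name] = {
                "mean": float(np.mean(arr)),
                "sd": float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0,
            }
        return out


def bond_length(frame: np.ndarray, pair: Sequence[int]) -> float:
    """Euclidean distance in Å between two atoms of one frame."""
    i, j = pair
    if i == j:
        raise ValueError("bond between identical atoms")
    d = np.asarray(frame[i], dtype=float) - np.asarray(frame[j], dtype=float)
    return float(np.linalg.norm(d))


def bla(frame: np.ndarray, topo: ConjugationTopology) -> float:
    """Bond-length alternation (Å): mean single minus mean double bond length."""
    s = sum(bond_length(frame, b) for b in topo.sigma_bonds)
    p = sum(bond_length(frame, b) for b in topo.pi_bonds)
    return (s - p) / 5.0


def dihedral(frame: np.ndarray, quadruple: Sequence[int]) -> float:
    """Signed dihedral angle (degrees) of four atoms, IUPAC convention.

    Range (-180, 180]; positive when, looking along the central bond from
    atom 2 to atom 3, the far bond is rotated clockwise from the near bond.
    Raises for collinear triples, where the dihedral is undefined.
    """
    p = np.asarray(frame, dtype=float)[list(quadruple)]
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or b2n < 1e-10:
        raise ValueError(f"dihedral undefined: collinear atoms in {tuple(quadruple)}")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def planarity(frame: np.ndarray, topo: ConjugationTopology) -> float:
    """Planarity P = sum over the ten dihedrals of (| |theta| - 90 |)/90."""
    total = 0.0
    for quad in topo.dihedrals:
        theta = dihedral(frame, quad)
        total += abs(abs(theta) - 90.0) / 90.0
    return total


def planarity_from_angles(thetas_deg: np.ndarray) -> np.ndarray:
    """Planarity from dihedral values directly (wrap- and sign-invariant)."""
    t = np.abs((np.asarray(thetas_deg, dtype=float) + 180.0) % 360.0 - 180.0)
    return np.sum(np.abs(t - 90.0) / 90.0, axis=-1)


def freedman_diaconis_bins(x: np.ndarray) -> np.ndarray:
    """Histogram bin edges by the Freedman–Diaconis rule (descriptive only)."""
    x = np.asarray(x, dtype=float)
    q75, q25 = np.percentile(x, [75, 25])
    width = 2.0 * (q75 - q25) / np.cbrt(x.size)
    if width <= 0:
        return np.linspace(x.min() - 0.5, x.max() + 0.5, 2)
    n = max(1, int(np.ceil((x.max() - x.min()) / width)))
    return np.linspace(x.min(), x.max(), n + 1)


def timeline(traj: Trajectory, topo: ConjugationTopology) -> StructuralTimeline:
    """Evaluate all descriptors on every frame of a trajectory."""
    topo.validate_against(traj.n_atoms)
    nf = traj.n_frames
    sig = np.empty((nf, 5))
    pi_ = np.empty((nf, 5))
    dih = np.empty((nf, 10))
    for f in range(nf):
        frame = traj.frame(f)
        sig[f] = [bond_length(frame, b) for b in topo.sigma_bonds]
        pi_[f] = [bond_length(frame, b) for b in topo.pi_bonds]
        dih[f] = [dihedral(frame, q) for q in topo.dihedrals]
    return StructuralTimeline(
        times=traj.times.copy(),
        bla=(sig.sum(axis=1) - pi_.sum(axis=1)) / 5.0,
        sigma_lengths=sig,
        pi_lengths=pi_,
        dihedrals=dih,
        planarity=planarity_from_angles(dih),
    )
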