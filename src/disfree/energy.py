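"""Pairwise residue interaction energies with an attractive/repulsive split.

The free-energy model only requires a pairwise-decomposable interaction
energy E_ij between residues; here this is supplied by a 12-6 potential on
per-residue interaction centers,

    E_ij = eps * [ (sigma_ij / r_ij)^12 - 2 (sigma_ij / r_ij)^6 ],

with sigma_ij the sum of the two residue sphere radii, so the minimum
-eps is at r = sigma_ij.  The positive part of each pair term is the
repulsive channel (capped at ``rep_cap`` to bound the r -> 0 singularity),
the negative part the attractive channel.  Externally computed pair
energies can be injected through :func:`load_interaction_matrix`.

The repulsive-only treatment of residues designated disordered in advance
is implemented by :func:`masked_energy` (drop the attractive channel of
every pair touching the mask) and :func:`masked_energy_reduced` (the same,
after additionally reducing masked residues to glycine-like minimal-radius
centers placed on the Cα).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import StructureModel

__all__ = [
    "InteractionMatrix",
    "EnergyBackendParams",
    "DEFAULT_RADII",
    "compute_interaction_matrix",
    "load_interaction_matrix",
    "masked_energy",
    "masked_energy_reduced",
]

# Per-residue interaction-sphere radii (Å), ordered by side-chain bulk and
# scaled so GLY = 2.0 and TRP = 3.4.
DEFAULT_RADII: dict[str, float] = {
    "G": 2.0, "A": 2.3, "S": 2.4, "C": 2.5, "D": 2.6, "P": 2.6, "T": 2.6,
    "N": 2.7, "V": 2.7, "E": 2.8, "I": 2.9, "L": 2.9, "Q": 2.9, "M": 3.0,
    "H": 3.0, "K": 3.1, "F": 3.2, "R": 3.3, "Y": 3.3, "W": 3.4, "X": 2.7,
}


@dataclass
class EnergyBackendParams:
    """Parameters of the 12-6 interaction backend."""

    radius_by_aa: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    well_depth: float = 1.0
    rep_cap: float = 10.0
    cutoff: float = 12.0

    def __post_init__(self) -> None:
        if not self.radius_by_aa:
            raise ValueError("radius_by_aa must not be empty")
        if any(r <= 0 for r in self.radius_by_aa.values()):
            raise ValueError("all radii must be positive")
        if self.cutoff <= 2 * max(self.radius_by_aa.values()):
            raise ValueError("cutoff must exceed twice the largest radius")
        if self.well_depth <= 0 or self.rep_cap <= 0:
            raise ValueError("well_depth and rep_cap must be positive")

    @property
    def min_radius(self) -> float:
        """Smallest radius in the set; used for masked (reduced) residues."""
        return min(self.radius_by_aa.values())

    def radii(self, aa: Iterable[str]) -> np.ndarray:
        fallback = self.radius_by_aa.get("X", self.min_radius)
        return np.array([self.radius_by_aa.get(a, fallback) for a in aa])


@dataclass
class InteractionMatrix:
    """Symmetric per-residue-pair energies for one model.

    ``e_attr`` is elementwise <= 0, ``e_rep`` >= 0; the diagonal and the
    bonded band |i - j| <= 1 are zero.  The pair total is their sum.
    """

    n: int
    e_attr: np.ndarray
    e_rep: np.ndarray

    def __post_init__(self) -> None:
        self.e_attr = np.asarray(self.e_attr, dtype=float)
        self.e_rep = np.asarray(self.e_rep, dtype=float)
        for name, m in (("e_attr", self.e_attr), ("e_rep", self.e_rep)):
            if m.shape != (self.n, self.n):
                raise ValueError(f"{name} must be {self.n}x{self.n}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
        if (self.e_attr > 0).any():
            raise ValueError("e_attr must be <= 0 elementwise")
        if (self.e_rep < 0).any():
            raise ValueError("e_rep must be >= 0 elementwise")
        band = np.abs(np.subtract.outer(np.arange(self.n), np.arange(self.n))) <= 1
        if self.e_attr[band].any() or self.e_rep[band].any():
            raise ValueError("diagonal and bonded band |i-j| <= 1 must be zero")

    @property
    def total(self) -> np.ndarray:
        return self.e_attr + self.e_rep


def _pair_terms(
    centers: np.ndarray, radii: np.ndarray, params: EnergyBackendParams
) -> tuple[np.ndarray, np.ndarray]:
    """12-6 pair terms split into (attractive, repulsive) matrices."""
    n = len(radii)
    r = cdist(centers, centers)
    sigma = np.add.outer(radii, radii)
    with np.errstate(divide="ignore", over="ignore"):
        s6 = (sigma / np.where(r > 0, r, np.inf)) ** 6
        term = params.well_depth * (s6 * s6 - 2.0 * s6)
    term[r == 0] = params.rep_cap
    excl = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) <= 1
    term[excl] = 0.0
    term[r > params.cutoff] = 0.0
    e_rep = np.clip(term, 0.0, params.rep_cap)
    e_attr = np.minimum(term, 0.0)
    return e_attr, e_rep


def compute_interaction_matrix(
    model: StructureModel, params: EnergyBackendParams | None = None
) -> InteractionMatrix:
    """Pairwise 12-6 energies on the model's interaction centers."""
    params = params or EnergyBackendParams()
    e_attr, e_rep = _pair_terms(model.center, params.radii(model.aa), params)
    return InteractionMatrix(n=model.n, e_attr=e_attr, e_rep=e_rep)


def load_interaction_matrix(path: str | Path, n: int) -> InteractionMatrix:
    """Load externally computed pair energies from a plain-text table.

    Each line is ``i j e_attr e_rep`` (1-based indices, whitespace
    delimited, ``#`` comments allowed).  Missing pairs are zero; entries
    are mirrored to keep the matrix symmetric.
    """
    e_attr = np.zeros((n, n))
    e_rep = np.zeros((n, n))
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'i j e_attr e_rep'")
        i, j = int(parts[0]), int(parts[1])
        ea, er = float(parts[2]), float(parts[3])
        if not (1 <= i <= n and 1 <= j <= n):
            raise ValueError(f"{path}:{lineno}: index out of range 1..{n}")
        if ea > 0:
            raise ValueError(f"{path}:{lineno}: attractive term must be <= 0")
        if er < 0:
            raise ValueError(f"{path}:{lineno}: repulsive term must be >= 0")
        if abs(i - j) <= 1:
            raise ValueError(f"{path}:{lineno}: bonded pair |i-j| <= 1 must be zero")
        e_attr[i - 1, j - 1] = e_attr[j - 1, i - 1] = ea
        e_rep[i - 1, j - 1] = e_rep[j - 1, i - 1] = er
    return InteractionMatrix(n=n, e_attr=e_attr, e_rep=e_rep)


def _check_mask(mask: Iterable[int], n: int) -> np.ndarray:
    idx = np.asarray(sorted(set(mask)), dtype=int)
    if idx.size and (idx.min() < 1 or idx.max() > n):
        raise ValueError(f"mask indices must lie in 1..{n}")
    flag = np.zeros(n, dtype=bool)
    flag[idx - 1] = True
    return flag


def masked_energy(matrix: InteractionMatrix, mask: Iterable[int]) -> float:
    """Total energy with pairs touching ``mask`` contributing repulsion only.

    Pairs with neither endpoint masked contribute their full (attractive +
    repulsive) energy; every pair with at least one masked endpoint —
    including masked-masked pairs — contributes only its repulsive part.
    ``mask`` holds 1-based residue indices.
    """
    flag = _check_mask(mask, matrix.n)
    untouched = np.outer(~flag, ~flag)
    return 0.5 * float(np.sum(matrix.e_rep) + np.sum(matrix.e_attr * untouched))


def masked_energy_reduced(
    model: StructureModel,
    mask: Iterable[int],
    params: EnergyBackendParams | None = None,
) -> float:
    """Repulsive-only score with masked residues reduced to minimal spheres.

    Masked residues take interaction center = Cα and radius =
    ``params.min_radius`` (glycine-like reduction) before pair terms are
    computed; pairs among unmasked residues are unchanged.  Pairs touching
    the mask then contribute only their repulsive part, so for clash-free
    masked conformations the score depends only on the unmasked residues.
    """
    params = params or EnergyBackendParams()
    flag = _check_mask(mask, model.n)
    centers = np.where(flag[:, None], model.ca, model.center)
    radii = np.where(flag, params.min_radius, params.radii(model.aa))
    e_attr, e_rep = _pair_terms(centers, radii, params)
    untouched = np.outer(~flag, ~flag)
    return 0.5 * float(np.sum(e_rep) + np.sum(e_attr * untouched))
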