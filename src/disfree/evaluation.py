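"""Scoring disorder predictions and comparing models to a native structure.

Reference disorder is derived from NMR-style ensembles: models are
superposed on the medoid model over all Cα and residues whose root-mean-
square deviation from the per-residue mean position exceeds a threshold
(default 2 Å) are labeled disordered.  Predictions (disorder-frequency
profiles) are scored by the per-residue agreement

    score = (1/N) * sum_i P_i,

where P_i is the predicted frequency of the reference state of residue i,
so a perfect prediction scores 1.0.  The baseline is the all-ordered null
model, whose score is simply the fraction of ordered reference residues.

Structure similarity over the ordered core is measured by core Cα RMSD
(optimal rigid superposition) and core GDT-TS (mean over 1/2/4/8 Å cutoffs
of the largest fraction of core residues simultaneously superposable
within the cutoff, found by a seeded fit-and-extend search).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .energy import EnergyBackendParams
from .free_energy import (
    DisorderAssignment,
    DisorderProfile,
    FreeEnergyParams,
    profile_ensemble,
)
from .structure_io import Ensemble, StructureModel

__all__ = [
    "ReferenceDisorder",
    "Eq2Score",
    "reference_from_ensemble",
    "eq2_score",
    "null_model_score",
    "tail_length_accuracy",
    "core_rmsd",
    "core_gdt_ts",
    "scan_parameters",
    "read_mask",
    "write_mask",
]

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
_SEED_LENGTHS = (3, 5, 7)


@dataclass
class ReferenceDisorder:
    """Ground-truth ordered/disordered labels for one sequence."""

    disordered: np.ndarray
    source: Literal["ensemble-deviation", "mask-file", "synthetic"]
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.disordered = np.asarray(self.disordered, dtype=bool)

    @property
    def n(self) -> int:
        return self.disordered.size

    @classmethod
    def from_mask(cls, indices: Iterable[int], n: int,
                  source: str = "mask-file") -> "ReferenceDisorder":
        dis = np.zeros(n, dtype=bool)
        for i in indices:
            if not 1 <= i <= n:
                raise ValueError(f"mask index {i} out of range 1..{n}")
            dis[i - 1] = True
        return cls(disordered=dis, source=source)  # type: ignore[arg-type]


@dataclass
class Eq2Score:
    """Mean per-residue agreement between prediction and reference."""

    score: float
    per_residue_P: np.ndarray
    N: int


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the transformed mobile coordinates and the RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - tc, mobile - mc)
    moved = rot.apply(mobile - mc) + tc
    return moved, float(rssd / math.sqrt(len(mobile)))


def _pairwise_rmsd(coords: list[np.ndarray]) -> np.ndarray:
    m = len(coords)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            _, r = superpose(coords[i], coords[j])
            d[i, j] = d[j, i] = r
    return d


def reference_from_ensemble(
    ensemble: Ensemble, threshold: float = 2.0
) -> ReferenceDisorder:
    """Label residues disordered from per-residue ensemble deviations.

    All models are superposed on the medoid model (minimum summed all-Cα
    RMSD to the others) and the per-residue deviation is the RMS Cα
    distance from the per-residue mean position; residues with deviation
    greater than ``threshold`` Å are disordered.
    """
    if ensemble.n_models < 2:
        raise ValueError("need at least 2 models to estimate deviations")
    coords = [m.ca for m in ensemble.models]
    medoid = int(np.argmin(_pairwise_rmsd(coords).sum(axis=0)))
    aligned = [
        coords[medoid] if k == medoid else superpose(c, coords[medoid])[0]
        for k, c in enumerate(coords)
    ]
    stack = np.stack(aligned)                       # (M, N, 3)
    mean = stack.mean(axis=0)
    dev = np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0))
    return ReferenceDisorder(
        disordered=dev > threshold, source="ensemble-deviation",
        threshold=threshold,
    )


def eq2_score(profile: DisorderProfile, reference: ReferenceDisorder) -> Eq2Score:
    """Score a disorder-frequency profile against reference labels."""
    if profile.n != reference.n:
        raise ValueError(
            f"profile length {profile.n} != reference length {reference.n}"
        )
    p = np.where(
        reference.disordered, profile.freq_disordered, 1.0 - profile.freq_disordered
    )
    return Eq2Score(score=float(p.mean()), per_residue_P=p, N=profile.n)


def null_model_score(reference: ReferenceDisorder) -> Eq2Score:
    """Score of the baseline declaring every residue ordered."""
    profile = DisorderProfile(
        freq_disordered=np.zeros(reference.n), n_models=1
    )
    return eq2_score(profile, reference)


def tail_length_accuracy(
    predicted: DisorderAssignment, true_n_tail: int, true_c_tail: int
) -> tuple[int, int]:
    """Signed length differences (predicted - true) of the two tails."""
    return predicted.n_tail - true_n_tail, predicted.c_tail - true_c_tail


def _core_coords(
    model: StructureModel, native: StructureModel, core: Iterable[int]
) -> tuple[np.ndarray, np.ndarray]:
    idx = sorted(set(core))
    for i in idx:
        if not (1 <= i <= model.n and 1 <= i <= native.n):
            raise ValueError(f"core index {i} out of range")
    sel = np.asarray(idx, dtype=int) - 1
    return model.ca[sel], native.ca[sel]


def core_rmsd(
    model: StructureModel, native: StructureModel, core: Iterable[int]
) -> float:
    """Cα RMSD over the core after optimal rigid superposition on the core."""
    mc, nc = _core_coords(model, native, core)
    if len(mc) < 3:
        raise ValueError("core_rmsd needs at least 3 core residues")
    return superpose(mc, nc)[1]


def _gdt_fraction(model: np.ndarray, native: np.ndarray, cutoff: float) -> float:
    """Largest fraction of residues superposable within ``cutoff``.

    Seeds from every contiguous fragment of lengths 3/5/7, then iterates
    include-within-cutoff / re-fit until the included set converges.
    """
    k = len(model)
    best = 0
    for length in _SEED_LENGTHS:
        if length > k:
            continue
        for start in range(k - length + 1):
            included = np.zeros(k, dtype=bool)
            included[start:start + length] = True
            for _ in range(32):
                mc = model[included].mean(axis=0)
                nc = native[included].mean(axis=0)
                rot, _ = Rotation.align_vectors(
                    native[included] - nc, model[included] - mc
                )
                moved = rot.apply(model - mc) + nc
                d = np.linalg.norm(moved - native, axis=1)
                new = d <= cutoff
                if new.sum() < 3:
                    break
                if (new == included).all():
                    best = max(best, int(new.sum()))
                    break
                included = new
    return best / k


def core_gdt_ts(
    model: StructureModel, native: StructureModel, core: Iterable[int]
) -> float:
    """GDT-TS over the core: mean superposable fraction at 1, 2, 4, 8 Å."""
    mc, nc = _core_coords(model, native, core)
    if len(mc) < 4:
        raise ValueError("core_gdt_ts needs at least 4 core residues")
    return float(np.mean([_gdt_fraction(mc, nc, c) for c in GDT_CUTOFFS]))


def gdt_fraction_exhaustive(
    model: np.ndarray, native: np.ndarray, cutoff: float
) -> float:
    """Exact maximum superposable fraction by subset enumeration (small k).

    Reference oracle for the seeded heuristic: tries every subset of size
    >= 3, fits on the subset and keeps it only if all its members land
    within the cutoff.
    """
    k = len(model)
    if k > 14:
        raise ValueError("exhaustive GDT is limited to k <= 14")
    best = 0
    indices = range(k)
    for size in range(k, 2, -1):
        if size <= best:
            break
        for subset in itertools.combinations(indices, size):
            sel = np.asarray(subset)
            mc = model[sel].mean(axis=0)
            nc = native[sel].mean(axis=0)
            rot, _ = Rotation.align_vectors(native[sel] - nc, model[sel] - mc)
            moved = rot.apply(model[sel] - mc) + nc
            if (np.linalg.norm(moved - native[sel], axis=1) <= cutoff).all():
                best = size
                break
    return best / k


def scan_parameters(
    benchmark: Sequence[tuple[Ensemble, ReferenceDisorder]],
    grid: dict[str, Sequence[float]],
    mode: Literal["terminal", "internal"] = "internal",
    backend: EnergyBackendParams | None = None,
    base_params: FreeEnergyParams | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Grid scan of free-energy parameters over a benchmark.

    ``grid`` maps any of ``e_d``, ``beta``, ``l0`` to candidate values; the
    Cartesian product is scanned.  In ``internal`` mode each point is
    scored by the mean per-residue agreement with the reference; in
    ``terminal`` mode by the fraction of models whose predicted tail
    lengths both match the reference tails exactly.  Returns the table and
    the best grid point (first in grid order on ties).
    """
    if not benchmark or not grid:
        raise ValueError("benchmark and grid must be nonempty")
    base = base_params or FreeEnergyParams()
    backend = backend or EnergyBackendParams()
    keys = list(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in keys)):
        point = dict(zip(keys, values))
        params = FreeEnergyParams(
            e_d=point.get("e_d", base.e_d),
            beta=point.get("beta", base.beta),
            l0=point.get("l0", base.l0),
            min_loop_len=base.min_loop_len,
            block=base.block,
        )
        scores = []
        for ensemble, reference in benchmark:
            if mode == "internal":
                profile = profile_ensemble(
                    ensemble, params, backend, mode="internal"
                )
                scores.append(eq2_score(profile, reference).score)
            else:
                runs_true = reference.disordered
                true_n = int(np.argmax(~runs_true)) if (~runs_true).any() else 0
                true_c = (
                    int(np.argmax(~runs_true[::-1])) if (~runs_true).any() else 0
                )
                _, assignments = profile_ensemble(
                    ensemble, params, backend, mode="terminal",
                    return_assignments=True,
                )
                exact = [
                    tail_length_accuracy(a, true_n, true_c) == (0, 0)
                    for a in assignments
                ]
                scores.append(float(np.mean(exact)))
        rows.append({**point, "mean_score": float(np.mean(scores))})
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_score"].idxmax()].to_dict()
    return table, best


def read_mask(path: str | Path) -> set[int]:
    """Read 1-based residue indices from a mask file (``a`` or ``a-b`` lines)."""
    out: set[int] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "-" in line:
            a, b = line.split("-", 1)
            lo, hi = int(a), int(b)
            if lo > hi:
                raise ValueError(f"{path}:{lineno}: empty range {line!r}")
            out.update(range(lo, hi + 1))
        else:
            out.add(int(line))
    if out and min(out) < 1:
        raise ValueError(f"{path}: mask indices must be >= 1")
    return out


def write_mask(indices: Iterable[int], path: str | Path) -> None:
    """Write 1-based residue indices as inclusive ranges, one per line."""
    idx = sorted(set(indices))
    lines = []
    i = 0
    while i < len(idx):
        j = i
        while j + 1 < len(idx) and idx[j + 1] == idx[j] + 1:
            j += 1
        lines.append(str(idx[i]) if i == j else f"{idx[i]}-{idx[j]}")
        i = j + 1
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
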