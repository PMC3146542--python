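"""Order/disorder free-energy assignment and its search procedures.

Every residue is either fully ordered or fully disordered.  An ordered
residue contributes its pair interactions with all other ordered residues
and no entropy; a disordered terminal residue (part of a run touching the
first or last position, a *tail*) earns a per-residue entropy credit E_d;
a disordered internal run of length L (a *loop*) earns a per-loop credit
beta * ln(L / L_0).  With T absorbed into E_d and beta, the free energy of
an assignment is

    F = E - sum_tails E_d * n_tail_residues - sum_loops beta * ln(L / L_0)

and the preferred assignment is the one of lowest F: residues are called
disordered when the entropy gained outweighs the attractive interactions
lost.

Two searches are provided.  :func:`enumerate_terminal` enumerates all
N-tail/C-tail length pairs (the at-most-two-stretch regime, where
exhaustive enumeration is cheap).  :func:`greedy_internal` starts from the
all-ordered state and repeatedly flips the best block of consecutive
ordered residues to disordered until F can no longer be lowered, which
also discovers internal loops.  :func:`exhaustive_search` is the exact
small-n reference for both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .energy import EnergyBackendParams, InteractionMatrix, compute_interaction_matrix
from .structure_io import Ensemble

__all__ = [
    "FreeEnergyParams",
    "FreeEnergyBreakdown",
    "DisorderAssignment",
    "DisorderProfile",
    "free_energy",
    "enumerate_terminal",
    "greedy_internal",
    "exhaustive_search",
    "profile_ensemble",
    "compensation_curve",
]


@dataclass(frozen=True)
class FreeEnergyParams:
    """Parameters of the free-energy function and its searches.

    e_d : per-residue entropy credit of disordered terminal residues
        (energy units; fitted default 2.0).
    beta, l0 : scale and reference length of the per-loop entropy
        beta * ln(L / l0) (fitted defaults 1.5 and 0.3).
    min_loop_len : minimum length of an internal disordered run (4).
    block : number of consecutive residues flipped per greedy move (4).
    max_stretches : maximum disordered stretches in the terminal
        enumeration (2: one tail per terminus).
    """

    e_d: float = 2.0
    beta: float = 1.5
    l0: float = 0.3
    min_loop_len: int = 4
    block: int = 4
    max_stretches: int = 2

    def __post_init__(self) -> None:
        if self.e_d <= 0 or self.beta <= 0 or self.l0 <= 0:
            raise ValueError("e_d, beta and l0 must be positive")
        if self.min_loop_len < 1:
            raise ValueError("min_loop_len must be >= 1")
        if self.min_loop_len / self.l0 <= 1:
            raise ValueError("min_loop_len / l0 must exceed 1 (loop credit > 0)")
        if self.block < 1:
            raise ValueError("block must be >= 1")
        if self.max_stretches != 2:
            raise ValueError("terminal enumeration supports exactly two stretches")


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """Additive decomposition of the assignment free energy."""

    E: float
    tail_term: float
    loop_term: float
    F: float


@dataclass
class DisorderAssignment:
    """A per-residue ordered/disordered labeling with its free energy."""

    ordered: np.ndarray
    breakdown: FreeEnergyBreakdown

    def __post_init__(self) -> None:
        self.ordered = np.asarray(self.ordered, dtype=bool)

    @property
    def n(self) -> int:
        return self.ordered.size

    @property
    def n_disordered(self) -> int:
        return int((~self.ordered).sum())

    @property
    def n_tail(self) -> int:
        """Length of the disordered run at the N terminus (0 if none)."""
        o = self.ordered
        return int(np.argmax(o)) if o.any() else self.n

    @property
    def c_tail(self) -> int:
        """Length of the disordered run at the C terminus (0 if none)."""
        o = self.ordered[::-1]
        return int(np.argmax(o)) if o.any() else self.n

    @property
    def disordered_indices(self) -> list[int]:
        """1-based indices of disordered residues."""
        return [int(i) + 1 for i in np.flatnonzero(~self.ordered)]


@dataclass
class DisorderProfile:
    """Per-residue frequency of the disordered label across an ensemble."""

    freq_disordered: np.ndarray
    n_models: int

    def __post_init__(self) -> None:
        self.freq_disordered = np.asarray(self.freq_disordered, dtype=float)
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if ((self.freq_disordered < 0) | (self.freq_disordered > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.freq_disordered.size


def disorder_runs(ordered: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal disordered runs as ``(start, stop, is_tail)`` half-open 0-based.

    A run touching position 0 or N-1 is a tail; all others are loops.
    """
    o = np.asarray(ordered, dtype=bool)
    n = o.size
    runs: list[tuple[int, int, bool]] = []
    i = 0
    while i < n:
        if not o[i]:
            j = i
            while j < n and not o[j]:
                j += 1
            runs.append((i, j, i == 0 or j == n))
            i = j
        else:
            i += 1
    return runs


def _entropy_terms(
    ordered: np.ndarray, params: FreeEnergyParams, validate: bool = True
) -> tuple[float, float]:
    tail = 0.0
    loop = 0.0
    for start, stop, is_tail in disorder_runs(ordered):
        length = stop - start
        if is_tail:
            tail += params.e_d * length
        else:
            if validate and length < params.min_loop_len:
                raise ValueError(
                    f"internal disordered run [{start + 1}, {stop}] has length "
                    f"{length} < min_loop_len {params.min_loop_len}"
                )
            loop += params.beta * math.log(length / params.l0)
    return tail, loop


def _ordered_energy(matrix: InteractionMatrix, ordered: np.ndarray) -> float:
    o = ordered.astype(float)
    return 0.5 * float(o @ matrix.total @ o)


def free_energy(
    matrix: InteractionMatrix,
    ordered: Sequence[bool] | np.ndarray,
    params: FreeEnergyParams | None = None,
) -> DisorderAssignment:
    """Score one ordered/disordered assignment.

    E sums pair energies over pairs with both residues ordered; disordered
    residues contribute entropy only.  Internal disordered runs shorter
    than ``min_loop_len`` are rejected.
    """
    params = params or FreeEnergyParams()
    o = np.asarray(ordered, dtype=bool)
    if o.size != matrix.n:
        raise ValueError(f"assignment length {o.size} != matrix size {matrix.n}")
    tail, loop = _entropy_terms(o, params)
    e = _ordered_energy(matrix, o)
    return DisorderAssignment(
        ordered=o,
        breakdown=FreeEnergyBreakdown(E=e, tail_term=tail, loop_term=loop,
                                      F=e - tail - loop),
    )


# ---------------------------------------------------------------------------
# Terminal enumeration
# ---------------------------------------------------------------------------

def enumerate_terminal(
    matrix: InteractionMatrix, params: FreeEnergyParams | None = None
) -> DisorderAssignment:
    """Lowest-F assignment among all N-tail/C-tail length pairs.

    Enumerates every (a, b) with a + b < n (at least one ordered residue;
    two disordered stretches at most, one per terminus).  Ties are broken
    toward fewer disordered residues, then toward the smaller N tail.
    """
    params = params or FreeEnergyParams()
    n = matrix.n
    if n < 2:
        raise ValueError("terminal enumeration needs n >= 2")
    # Integral image of the pair-total matrix: the ordered-block energy for
    # tails (a, b) is half the sum of M over the block [a, n-b).
    cum = np.zeros((n + 1, n + 1))
    cum[1:, 1:] = np.cumsum(np.cumsum(matrix.total, axis=0), axis=1)

    def block_energy(lo: int, hi: int) -> float:
        return 0.5 * float(cum[hi, hi] - cum[lo, hi] - cum[hi, lo] + cum[lo, lo])

    best: tuple[float, int, int] | None = None
    best_ab: tuple[int, int] = (0, 0)
    for a in range(n):
        for b in range(n - a):
            e = block_energy(a, n - b)
            f = e - params.e_d * (a + b)
            key = (f, a + b, a)
            if best is None or key < best:
                best = key
                best_ab = (a, b)
    a, b = best_ab
    ordered = np.ones(n, dtype=bool)
    ordered[:a] = False
    if b:
        ordered[n - b:] = False
    return free_energy(matrix, ordered, params)


# ---------------------------------------------------------------------------
# Greedy internal search
# ---------------------------------------------------------------------------

def _candidate_windows(ordered: np.ndarray, params: FreeEnergyParams) -> Iterator[int]:
    """Offsets of all-ordered windows of length ``block`` (every offset)."""
    n = ordered.size
    b = params.block
    for start in range(n - b + 1):
        if ordered[start:start + b].all():
            yield start


def greedy_internal(
    matrix: InteractionMatrix,
    params: FreeEnergyParams | None = None,
    return_trajectory: bool = False,
) -> DisorderAssignment | tuple[DisorderAssignment, list[DisorderAssignment]]:
    """Greedy block-flip search for the lowest-F assignment.

    Starts all-ordered; each round evaluates flipping every all-ordered
    window of ``block`` consecutive residues to disordered (windows merge
    with adjacent disordered runs, which are then re-classified as tails
    or loops by position) and commits the single flip that lowers F the
    most, breaking ties toward the leftmost window.  Stops when no flip
    lowers F.  Only order -> disorder flips are made, and the all-disordered
    state is never entered.
    """
    params = params or FreeEnergyParams()
    n = matrix.n
    if n < params.block:
        raise ValueError(f"greedy search needs n >= block ({params.block})")
    ordered = np.ones(n, dtype=bool)
    current = free_energy(matrix, ordered, params)
    trajectory = [current]
    while True:
        best_f = current.breakdown.F
        best_assignment: DisorderAssignment | None = None
        for start in _candidate_windows(ordered, params):
            trial = ordered.copy()
            trial[start:start + params.block] = False
            if not trial.any():
                continue
            # Merged internal runs are always >= block >= min_loop_len for
            # the defaults; guard for nonstandard parameter combinations.
            try:
                cand = free_energy(matrix, trial, params)
            except ValueError:
                continue
            if cand.breakdown.F < best_f:
                best_f = cand.breakdown.F
                best_assignment = cand
        if best_assignment is None:
            break
        current = best_assignment
        ordered = current.ordered
        trajectory.append(current)
    if return_trajectory:
        return current, trajectory
    return current


# ---------------------------------------------------------------------------
# Exhaustive small-n reference search
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _admissible_assignments(n: int, min_loop_len: int) -> tuple[np.ndarray, ...]:
    """All admissible masks for chain length n, as stacked arrays.

    Admissible: >= 1 ordered residue; internal disordered runs have length
    >= min_loop_len; tails may have any length.  Returns (ordered_masks
    [K, n] bool, n_disordered [K], n_tail [K], sum_ln_loop_len [K],
    n_loops [K]).
    """
    masks: list[np.ndarray] = []
    n_dis: list[int] = []
    n_tailv: list[int] = []
    sum_ln: list[float] = []
    n_loops: list[int] = []

    def emit(runs: list[tuple[int, int]]) -> None:
        o = np.ones(n, dtype=bool)
        tail_ct = 0
        s_ln = 0.0
        loops = 0
        for start, stop in runs:
            o[start:stop] = False
            if start == 0 or stop == n:
                tail_ct += stop - start
            else:
                s_ln += math.log(stop - start)
                loops += 1
        masks.append(o)
        n_dis.append(int((~o).sum()))
        n_tailv.append(int(np.argmax(o)))
        sum_ln.append(s_ln)
        n_loops.append(loops)

    def extend(pos: int, runs: list[tuple[int, int]], seen_ordered: bool) -> None:
        # pos: next free position; the residue at pos-1 (if any) is ordered
        # unless a run just ended there.
        if pos == n:
            if seen_ordered:
                emit(runs)
            return
        # ordered block of length o >= 1
        for o_len in range(1, n - pos + 1):
            nxt = pos + o_len
            if nxt == n:
                emit(runs)
            else:
                # disordered run after the ordered block: tail if it reaches
                # the end (any length), else internal (>= min_loop_len)
                for d_len in range(1, n - nxt + 1):
                    if nxt + d_len == n or d_len >= min_loop_len:
                        extend(nxt + d_len, runs + [(nxt, nxt + d_len)], True)

    # optional leading tail of length a >= 0
    for a in range(n):
        extend(a, [(0, a)] if a else [], False)

    order = np.arange(len(masks))
    return (
        np.array(masks)[order],
        np.array(n_dis)[order],
        np.array(n_tailv)[order],
        np.array(sum_ln)[order],
        np.array(n_loops)[order],
    )


def exhaustive_search(
    matrix: InteractionMatrix,
    params: FreeEnergyParams | None = None,
    max_n: int = 24,
) -> DisorderAssignment:
    """Globally optimal assignment by enumeration (small n only).

    Enumerates every admissible mask (internal runs >= min_loop_len, at
    least one ordered residue), with the same tie rules as the other
    searches: lowest F, then fewest disordered residues, then smallest
    N tail, then lexicographically first mask.
    """
    params = params or FreeEnergyParams()
    n = matrix.n
    if n > max_n:
        raise ValueError(f"exhaustive search refused for n = {n} > max_n = {max_n}")
    masks, n_dis, n_tail, sum_ln, n_loops = _admissible_assignments(
        n, params.min_loop_len
    )
    o = masks.astype(float)
    e = 0.5 * np.einsum("ki,ij,kj->k", o, matrix.total, o)
    tail_term = params.e_d * _terminal_run_lengths(masks)
    loop_term = params.beta * (sum_ln - n_loops * math.log(params.l0))
    f = e - tail_term - loop_term
    fmin = f.min()
    tied = np.flatnonzero(f == fmin)
    key = min(
        tied,
        key=lambda k: (n_dis[k], n_tail[k], tuple((~masks[k]).astype(int))),
    )
    return free_energy(matrix, masks[key], params)


def _terminal_run_lengths(masks: np.ndarray) -> np.ndarray:
    """Total residues in disordered runs touching either end, per mask row."""
    k, n = masks.shape
    lead = np.where(masks.any(axis=1), masks.argmax(axis=1), n)
    rev = masks[:, ::-1]
    trail = np.where(masks.any(axis=1), rev.argmax(axis=1), 0)
    # fully disordered rows never occur (>= 1 ordered residue is enforced)
    return lead + trail


# ---------------------------------------------------------------------------
# Ensemble aggregation
# ---------------------------------------------------------------------------

def profile_ensemble(
    ensemble: Ensemble,
    params: FreeEnergyParams | None = None,
    backend: EnergyBackendParams | None = None,
    mode: Literal["terminal", "internal"] = "terminal",
    return_assignments: bool = False,
) -> DisorderProfile | tuple[DisorderProfile, list[DisorderAssignment]]:
    """Per-residue disorder frequency over each model's optimal assignment."""
    if ensemble.n_models < 1:
        raise ValueError("ensemble must contain at least one model")
    params = params or FreeEnergyParams()
    backend = backend or EnergyBackendParams()
    search = {"terminal": enumerate_terminal, "internal": greedy_internal}[mode]
    assignments: list[DisorderAssignment] = []
    for model in ensemble.models:
        matrix = compute_interaction_matrix(model, backend)
        assignments.append(search(matrix, params))
    freq = np.mean([~a.ordered for a in assignments], axis=0)
    profile = DisorderProfile(freq_disordered=freq, n_models=ensemble.n_models)
    if return_assignments:
        return profile, assignments
    return profile


def compensation_curve(
    matrix: InteractionMatrix,
    params: FreeEnergyParams | None = None,
    assignments: Iterable[DisorderAssignment] = (),
) -> pd.DataFrame:
    """Entropy-enthalpy compensation table along a set of assignments.

    Re-scores each assignment and tabulates (n_disordered, E,
    entropy_term, F) sorted by n_disordered: as more residues are labeled
    disordered the retained interaction energy E rises (fewer interacting
    pairs) while the entropy credit grows, leaving F comparatively flat.
    """
    params = params or FreeEnergyParams()
    rows = []
    for a in assignments:
        scored = free_energy(matrix, a.ordered, params)
        b = scored.breakdown
        rows.append(
            {
                "n_disordered": scored.n_disordered,
                "E": b.E,
                "entropy_term": b.tail_term + b.loop_term,
                "F": b.F,
            }
        )
    return (
        pd.DataFrame(rows, columns=["n_disordered", "E", "entropy_term", "F"])
        .sort_values("n_disordered", kind="stable")
        .reset_index(drop=True)
    )
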