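"""Synthetic decoy ensembles with planted order/disorder ground truth.

The generator emulates the three situations the method is exercised on:

* a compact rigid core plus flexible terminal tails, re-sampled per model
  so that tail residues scatter widely while the core barely moves;
* NMR-style ensembles with internal disordered loops whose per-residue
  deviations far exceed the 2 Å disorder threshold while core deviations
  stay well below it;
* "collapsed-tail" decoys in which the disordered segments pack against
  the core, making spurious attractive contacts (and some steric
  overlap) — the pathology the repulsive-only re-scoring removes.

Chains are coarse virtual-bond models: one site per residue, 3.8 Å
between consecutive Cα, self-avoiding placement with hard-sphere
rejection.  No Ramachandran statistics are attempted; only the contact
and deviation statistics matter to the methods under test.  Sequences are
poly-A for ordered residues and poly-G for disordered ones unless a
sequence is supplied; the energy backend keys only on radii.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .energy import InteractionMatrix
from .structure_io import Ensemble, StructureModel

__all__ = [
    "SyntheticSpec",
    "GenerationError",
    "generate_ensemble",
    "generate_pair_matrix",
]

BOND = 3.8          # virtual Cα-Cα bond length, Å
CORE_MIN_SEP = 4.2  # minimum non-bonded separation inside the core, Å
TAIL_CLEARANCE = 5.5  # minimum detached tail/loop distance from the core, Å
VOLUME_PER_RESIDUE = 95.0  # Å^3, protein-like packing of the core globule


class GenerationError(RuntimeError):
    """Geometry construction failed after bounded retries."""


@dataclass
class SyntheticSpec:
    """Recipe for one planted-ground-truth ensemble.

    ``loops`` are (start, length) in 1-based full-chain coordinates; they
    must be internal (not touching either terminus through tails).
    ``collapse_fraction`` of the models have their disordered segments
    steered into contact with the core instead of pointing away from it.
    """

    n_core: int = 40
    n_tail_n: int = 0
    n_tail_c: int = 0
    loops: Sequence[tuple[int, int]] = field(default_factory=tuple)
    n_models: int = 10
    core_noise: float = 0.2
    tail_amplitude: float = 8.0
    collapse_fraction: float = 0.0
    seed: int | None = None
    min_loop_len: int = 4

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducible generation")
        if self.n_core < 8:
            raise ValueError("n_core must be >= 8")
        if self.n_models < 1 or min(self.n_tail_n, self.n_tail_c) < 0:
            raise ValueError("invalid counts")
        if not 0.0 <= self.collapse_fraction <= 1.0:
            raise ValueError("collapse_fraction must lie in [0, 1]")
        n = self.n_total
        prev_end = self.n_tail_n + 1  # first ordered position
        for start, length in sorted(self.loops):
            if length < self.min_loop_len:
                raise ValueError(
                    f"loop at {start} shorter than min_loop_len {self.min_loop_len}"
                )
            if start <= prev_end or start + length - 1 >= n - self.n_tail_c:
                raise ValueError(
                    f"loop at {start} must be internal with ordered flanks"
                )
            prev_end = start + length

    @property
    def n_total(self) -> int:
        return self.n_tail_n + self.n_core + sum(l for _, l in self.loops) \
            + self.n_tail_c

    @property
    def disordered_truth(self) -> np.ndarray:
        """Planted ground truth: True where the residue is disordered."""
        dis = np.zeros(self.n_total, dtype=bool)
        dis[: self.n_tail_n] = True
        if self.n_tail_c:
            dis[-self.n_tail_c:] = True
        for start, length in self.loops:
            dis[start - 1: start - 1 + length] = True
        return dis


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


CONTACT_SHELL = 5.6  # Å; non-bonded pairs inside this shell count as contacts


def _compact_walk(
    n: int,
    rng: np.random.Generator,
    surface: frozenset[int] | set[int] = frozenset(),
) -> np.ndarray:
    """Compact self-avoiding chain of n sites with protein-like contacts.

    The chain grows from the middle outward (both arms alternately), each
    new site chosen from random trial directions by a contact-seeking
    score: most non-bonded neighbours in the [CORE_MIN_SEP, CONTACT_SHELL]
    shell, mild centripetal tie-break, and at least three contacts once
    the globule is large enough.  Growing the ends last leaves both chain
    termini surface-exposed, so terminal tails can detach cleanly.
    When ``surface`` is nonempty (residues that must anchor a disordered
    loop), the whole globule is grown in the half-space z <= 0 and the
    surface residues seek the z = 0 plane, so the upper half-space stays
    free for loop excursions and the anchors are never buried.
    """
    mid = n // 2
    half_space = bool(surface)
    for _ in range(120):  # whole-walk restarts
        coords = np.zeros((n, 3))
        coords[mid] = np.array([0.0, 0.0, -4.5 if half_space else 0.0])
        step0 = _random_unit(rng)
        if half_space:
            step0[2] = -abs(step0[2])
            step0 /= np.linalg.norm(step0)
        coords[mid + 1] = coords[mid] + BOND * step0
        placed_idx = [mid, mid + 1]
        lo, hi = mid - 1, mid + 2
        ok = True
        while lo >= 0 or hi < n:
            grow_lo = lo >= 0 and (hi >= n or (mid - lo) <= (hi - mid - 1))
            idx = lo if grow_lo else hi
            anchor = coords[lo + 1] if grow_lo else coords[hi - 1]
            others = coords[placed_idx]
            centroid = others.mean(axis=0)
            seek_plane = idx in surface
            best = None
            best_score = -np.inf
            contact_floor = (
                (0,) if seek_plane or len(placed_idx) < 8 else (3, 0)
            )
            for need_contacts in contact_floor:
                for _ in range(150):
                    cand = anchor + BOND * _random_unit(rng)
                    # loop anchors may poke up to the z = 0 plane; the rest
                    # of the globule stays below it, leaving the anchors
                    # proud of the surface
                    if half_space and cand[2] > (0.0 if seek_plane else -2.8):
                        continue
                    dist = np.linalg.norm(others - cand, axis=1)
                    # all placed sites except the bonded anchor keep apart
                    if np.partition(dist, 1)[1] < CORE_MIN_SEP:
                        continue
                    contacts = int(
                        ((dist >= CORE_MIN_SEP) & (dist <= CONTACT_SHELL)).sum()
                    )
                    if contacts < need_contacts:
                        continue
                    if seek_plane:
                        score = cand[2] + rng.uniform(0.0, 0.5)
                    else:
                        score = (contacts + rng.uniform(0.0, 0.8)
                                 - 0.02 * np.linalg.norm(cand - centroid))
                    if score > best_score:
                        best_score = score
                        best = cand
                if best is not None:
                    break
            if best is None:
                ok = False
                break
            coords[idx] = best
            placed_idx.append(idx)
            if grow_lo:
                lo -= 1
            else:
                hi += 1
        if ok:
            return coords - coords.mean(axis=0)
    raise GenerationError(f"could not build a compact {n}-residue core")


def _grow_segment(
    anchor: np.ndarray,
    neighbor: np.ndarray,
    length: int,
    obstacles: np.ndarray,
    rng: np.random.Generator,
    away_from: np.ndarray,
    collapse: bool,
) -> np.ndarray:
    """Grow a disordered segment of ``length`` sites starting bonded to anchor.

    ``obstacles`` must exclude the anchor itself (the first segment site is
    bonded to it at BOND distance) and the anchor's bonded chain
    ``neighbor``, which sits one bond away and is held only at normal
    non-bonded separation from the first tail sites.  Detached segments
    keep TAIL_CLEARANCE from every obstacle and drift away from
    ``away_from`` (the core centroid); collapsed segments are steered
    toward it and may approach obstacles down to ~3.2 Å, creating
    attractive contacts and occasional steric overlap.
    """
    min_clear = 3.2 if collapse else TAIL_CLEARANCE
    for attempt in range(800):
        # meandering tails can dead-end against the core; later attempts
        # head outward more directly, which always has room
        wander_bias = 0.35 if attempt < 400 else 1.2
        pts: list[np.ndarray] = []
        prev = anchor
        ok = True
        for k in range(length):
            placed = False
            # collapsed sites aim for a target distance from the core
            # surface: every fourth site presses into mild steric overlap,
            # the others sit in the attractive shell
            target = (3.6 if k % 3 == 1 else 4.5) if collapse else None
            best_cand = None
            best_err = np.inf
            for _ in range(240):
                direction = _random_unit(rng)
                out = prev - away_from
                norm = np.linalg.norm(out) + 1e-9
                # detached tails leave the core firmly, then meander so the
                # ensemble spreads well beyond the disorder threshold
                bias = (-1.1 if collapse else (1.4 if k == 0 else wander_bias)) \
                    * out / norm
                if collapse and norm < 9.0:
                    bias = 0.15 * out / norm  # hover near the core surface
                step = direction + bias
                step /= np.linalg.norm(step)
                cand = prev + BOND * step
                dmin = np.inf
                if obstacles.size:
                    dmin = float(np.linalg.norm(obstacles - cand, axis=1).min())
                    if dmin < (3.5 if collapse else min_clear):
                        continue
                if k > 0 and np.linalg.norm(cand - anchor) < (
                    3.5 if collapse else CORE_MIN_SEP
                ):
                    continue
                if collapse:
                    nb_clear = 3.5
                else:
                    nb_clear = (CORE_MIN_SEP, 5.0)[min(k, 1)] \
                        if k < 2 else min_clear
                if np.linalg.norm(cand - neighbor) < nb_clear:
                    continue
                if pts:
                    d_self = np.linalg.norm(np.array(pts) - cand, axis=1)
                    if (d_self < 3.6).any():
                        continue
                if collapse:
                    err = abs(dmin - target)
                    if err < best_err:
                        best_err = err
                        best_cand = cand
                    placed = True
                    if best_err < 0.15:
                        break
                    continue
                pts.append(cand)
                prev = cand
                placed = True
                break
            if collapse and placed:
                pts.append(best_cand)
                prev = best_cand
            if not placed:
                ok = False
                break
        if ok:
            seg = np.array(pts)
            if collapse and obstacles.size:
                # a collapsed segment must actually pack against the core:
                # many spurious attractive contacts plus a little genuine
                # (mild) steric overlap, so it wins under full scoring but
                # loses under repulsive-only scoring
                d = np.linalg.norm(
                    obstacles[None, :, :] - seg[:, None, :], axis=2
                )
                n_clash = int((d.min(axis=1) < 3.8).sum())
                n_attr = int(((d >= 3.9) & (d <= 5.6)).sum())
                if n_clash < 3 or n_attr < max(8, 2 * length):
                    continue
            return seg
    raise GenerationError(f"could not grow a {length}-residue disordered segment")


def _loop_bridge(
    left: np.ndarray,
    right: np.ndarray,
    length: int,
    core: np.ndarray,
    centroid: np.ndarray,
    rng: np.random.Generator,
    amplitude: float,
    collapse: bool,
) -> np.ndarray:
    """Internal loop of ``length`` sites bridging two anchors.

    The loop is sampled on a circular major arc between the anchors with
    segment spacing inside the (2, 5) Å band by construction; ``core``
    must exclude the two anchors themselves (they are bonded neighbours
    of the loop ends).  Detached loops bulge outward from the core with
    clearance; collapsed loops hug it.
    """
    mid = 0.5 * (left + right)
    d = np.linalg.norm(right - left)
    if 0.95 * BOND * (length + 1) <= d + 2.0:
        raise GenerationError("loop too short to bridge its anchors")
    axis = (right - left) / (d + 1e-9)
    out = mid - centroid
    out = out / (np.linalg.norm(out) + 1e-9)
    # graded clearance: loop ends hug their anchors, the middle swings free
    if collapse:
        clear = np.full(length, 3.0)
    else:
        clear = np.full(length, 4.6)
        for k in (0, length - 1):
            clear[k] = 4.2
        for k in (1, length - 2):
            if 0 <= k < length:
                clear[k] = min(clear[k], 4.4)
    # per-point jitter grows toward mid-loop so models genuinely differ;
    # it is smoothed along the loop so adjacent spacings survive
    kk = np.arange(length, dtype=float)
    jitter_scale = np.minimum(0.3 + 0.3 * np.minimum(kk + 1, length - kk), 1.5)
    for _ in range(900):
        # vary the contour actually used so the apex height differs by model
        total = rng.uniform(0.68, 0.92) * BOND * (length + 1)
        if total <= d + 2.0:
            continue
        # circle radius whose major arc over chord d has length `total`
        r_lo, r_hi = 0.5 * d + 1e-6, 0.5 * total
        for _ in range(50):
            r = 0.5 * (r_lo + r_hi)
            arc_len = r * (2 * math.pi - 2 * math.asin(min(1.0, d / (2 * r))))
            if arc_len > total:
                r_hi = r
            else:
                r_lo = r
        radius = 0.5 * (r_lo + r_hi)
        m = math.sqrt(max(radius ** 2 - (d / 2) ** 2, 0.0))
        half = math.pi - math.atan2(d / 2, m)
        theta = np.linspace(-half, half, length + 2)[1:-1]
        # mild skew slides the apex along the arc between models
        theta = theta + rng.uniform(-0.22, 0.22) * np.sin(theta)
        u = _random_unit(rng)
        u = u - (u @ axis) * axis
        u /= np.linalg.norm(u) + 1e-9
        if collapse:
            direction = 0.8 * u - 0.5 * out
        else:
            direction = rng.uniform(0.6, 1.6) * u + rng.uniform(0.1, 0.9) * out
        w = direction - (direction @ axis) * axis
        w /= np.linalg.norm(w) + 1e-9
        center = mid + m * w
        raw = gaussian_filter1d(
            rng.normal(size=(length, 3)), sigma=1.5, axis=0, mode="nearest"
        )
        raw /= raw.std() + 1e-9
        pts_arr = (
            center[None, :]
            + radius * (np.cos(theta)[:, None] * w[None, :]
                        + np.sin(theta)[:, None] * axis[None, :])
            + raw * jitter_scale[:, None]
        )
        chain = np.vstack([left, pts_arr, right])
        step = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        if step.min() <= 2.1 or step.max() >= 4.9:
            continue
        if core.size:
            dmin = np.min(
                np.linalg.norm(core[None, :, :] - pts_arr[:, None, :], axis=2),
                axis=1,
            )
            if (dmin < clear).any():
                continue
        return pts_arr
    raise GenerationError(f"could not bridge a {length}-residue loop")


def _repair_overlaps(
    xyz: np.ndarray,
    min_sep: float = 4.15,
    bond: float = BOND,
    bond_tol: float = 0.25,
    max_iter: int = 60,
) -> np.ndarray:
    """Project jittered core coordinates back onto the steric constraints.

    Gauss-Seidel sweeps: non-bonded pairs (|i-j| >= 2) closer than
    ``min_sep`` are pushed apart symmetrically; virtual bonds drifting
    more than ``bond_tol`` from ``bond`` are corrected.  Keeps the jitter
    character while preventing spurious steric repulsion in the core.
    """
    p = xyz.copy()
    n = len(p)
    for _ in range(max_iter):
        moved = False
        diff = p[:, None, :] - p[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        iu, ju = np.triu_indices(n, k=2)
        bad = dist[iu, ju] < min_sep
        for i, j in zip(iu[bad], ju[bad]):
            d = dist[i, j]
            axis = (p[i] - p[j]) / (d + 1e-12)
            shift = 0.5 * (min_sep - d + 0.02)
            p[i] += shift * axis
            p[j] -= shift * axis
            moved = True
        for i in range(n - 1):
            d = np.linalg.norm(p[i + 1] - p[i])
            if abs(d - bond) > bond_tol:
                axis = (p[i + 1] - p[i]) / (d + 1e-12)
                corr = 0.5 * (d - bond)
                p[i] += corr * axis
                p[i + 1] -= corr * axis
                moved = True
        if not moved:
            break
    return p


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------

def _assemble_sequence(spec: SyntheticSpec) -> str:
    seq = np.full(spec.n_total, "A", dtype="<U1")
    seq[spec.disordered_truth] = "G"
    return "".join(seq)


def generate_ensemble(
    spec: SyntheticSpec,
) -> tuple[Ensemble, np.ndarray, StructureModel]:
    """Generate (ensemble, ground_truth, native) for a planted recipe.

    The ordered scaffold is one compact self-avoiding chain shared by all
    models up to ``core_noise`` jitter; each disordered segment is
    re-sampled per model.  The first ``ceil(collapse_fraction * n_models)``
    models are collapsed.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    truth = spec.disordered_truth
    n = spec.n_total
    ordered_pos = np.flatnonzero(~truth)        # 0-based chain positions
    # loop anchors must sit on the core surface for the loop to bulge out
    flanks = set()
    for start, length in spec.loops:
        for pos in (start - 2, start - 1 + length):
            flanks.add(int(np.searchsorted(ordered_pos, pos)))
    scaffold = _compact_walk(len(ordered_pos), rng, surface=frozenset(flanks))
    centroid = scaffold.mean(axis=0)
    seq = _assemble_sequence(spec)
    n_collapsed = math.ceil(spec.collapse_fraction * spec.n_models)

    def build_model(model_id: str, collapse: bool, noise: float,
                    mrng: np.random.Generator) -> StructureModel:
        coords = np.zeros((n, 3))
        if noise > 0:
            # chain-correlated jitter keeps virtual bond lengths intact
            white = mrng.normal(size=scaffold.shape)
            smooth = gaussian_filter1d(white, sigma=2.0, axis=0, mode="nearest")
            smooth *= noise / (smooth.std() + 1e-12)
            core_xyz = _repair_overlaps(scaffold + smooth)
        else:
            core_xyz = scaffold.copy()
        coords[ordered_pos] = core_xyz
        # N tail, grown backwards from the first ordered residue
        if spec.n_tail_n:
            seg = _grow_segment(core_xyz[0], core_xyz[1], spec.n_tail_n,
                                core_xyz[2:], mrng, centroid, collapse)
            coords[spec.n_tail_n - 1:: -1] = seg
        if spec.n_tail_c:
            seg = _grow_segment(core_xyz[-1], core_xyz[-2], spec.n_tail_c,
                                core_xyz[:-2], mrng, centroid, collapse)
            coords[n - spec.n_tail_c:] = seg
        for start, length in spec.loops:
            left = coords[start - 2]
            right = coords[start - 1 + length]
            fl = int(np.searchsorted(ordered_pos, start - 2))
            fr = int(np.searchsorted(ordered_pos, start - 1 + length))
            core_wo_anchors = np.delete(core_xyz, [fl, fr], axis=0)
            coords[start - 1: start - 1 + length] = _loop_bridge(
                left, right, length, core_wo_anchors, centroid, mrng,
                spec.tail_amplitude, collapse,
            )
        return StructureModel(model_id=model_id, aa=list(seq), ca=coords,
                              center=coords.copy())

    def build_checked(model_id: str, collapse: bool, noise: float):
        # bounded per-model retries; the retry seeds come from the parent
        # generator, so the whole ensemble stays deterministic in spec.seed
        last: GenerationError | None = None
        for _ in range(8):
            mrng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            try:
                model = build_model(model_id, collapse, noise, mrng)
            except GenerationError as exc:
                last = exc
                continue
            # generated-structure invariant: consecutive Cα in (2, 5) Å
            d = np.linalg.norm(np.diff(model.ca, axis=0), axis=1)
            if d.min() <= 2.0 or d.max() >= 5.0:
                last = GenerationError(
                    f"model {model_id}: bond length outside (2, 5) Å"
                )
                continue
            return model
        raise last if last is not None else GenerationError(model_id)

    models = [
        build_checked(str(k + 1), k < n_collapsed, spec.core_noise)
        for k in range(spec.n_models)
    ]
    native = build_checked("native", False, 0.0)
    return Ensemble(sequence=seq, models=models), truth, native


def generate_pair_matrix(
    n: int,
    planted_disordered: Sequence[int] | set[int],
    attr_core: float = -5.0,
    attr_disordered: float = 0.0,
    seed: int | None = None,
    jitter: float = 0.05,
) -> InteractionMatrix:
    """Coordinate-free planted interaction matrix for search unit tests.

    Pairs with both residues in the ordered complement get ``attr_core``;
    pairs touching ``planted_disordered`` (1-based) get
    ``attr_disordered``; a small negative jitter breaks ties.  Both
    attraction values must be <= 0.
    """
    if attr_core > 0 or attr_disordered > 0:
        raise ValueError("attraction values must be <= 0")
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    planted = np.zeros(n, dtype=bool)
    for i in planted_disordered:
        if not 1 <= i <= n:
            raise ValueError(f"planted index {i} out of range 1..{n}")
        planted[i - 1] = True
    e_attr = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 2, n):
            if planted[i] or planted[j]:
                val = attr_disordered
            else:
                val = attr_core - (jitter * rng.uniform() if jitter > 0 else 0.0)
            e_attr[i, j] = e_attr[j, i] = val
    return InteractionMatrix(n=n, e_attr=e_attr, e_rep=np.zeros((n, n)))
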