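"""Pairwise structural comparison with a Qscore objective.

The aligner works on Cα traces only.  It proceeds in three stages, in
the style of secondary-structure-matching aligners:

1. *SSE assignment* — helices and strands are detected from Cα-distance
   patterns (d(i,i+2), d(i,i+3), d(i,i+4) windows) and each element gets
   a least-squares axis.
2. *Seeding* — pairs of same-kind SSE pairs with compatible inter-axis
   angles and midpoint separations propose rigid transforms (Kabsch on
   axis endpoints); chains with fewer than two SSEs fall back to gapless
   sliding-window seeding.
3. *Refinement* — each seed is refined by alternating an order-preserving
   dynamic-programming correspondence (score 1/(1+(d/r0)^2), zero gap
   penalty, distance cutoff) with a Kabsch re-fit, keeping the iterate of
   highest Qscore.

The similarity score is

    Qscore = Nalign^2 / ((1 + (RMSD/R0)^2) * N1 * N2)

where Nalign is the number of corresponding residue pairs, RMSD their
Cα RMSD after superposition, N1 and N2 the resolved residue counts of
the two chains, and R0 a distance scale (default 3.0 Å).  Qscore is 1
for identical structures and near 0 for unrelated ones.  When no
correspondence of at least ``min_aligned`` residues is found, the result
carries the NO_SIMILARITY status, conventionally tabulated as -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from strucphy.structure_io import ChainRecord

NO_SIMILARITY_SENTINEL = -1.0

# Cα-distance windows (Å) marking residue i as a candidate, after P-SEA
HELIX_D13 = (4.5, 6.0)   # d(i, i+3)
HELIX_D14 = (5.7, 7.0)   # d(i, i+4)
STRAND_D12 = (6.2, 7.2)  # d(i, i+2)
STRAND_D13 = (9.3, 10.8) # d(i, i+3)
MIN_RUN = {"helix": 5, "strand": 3}
# residues past the last candidate still covered by the detection window
RUN_TAIL = {"helix": 4, "strand": 3}


class Status(Enum):
    OK = "OK"
    NO_SIMILARITY = "NO_SIMILARITY"


@dataclass
class SSE:
    """A secondary-structure element with its fitted axis.

    ``start``/``end`` are 0-based inclusive resolved-residue indices.
    ``axis_origin`` is the axis point at the element's first residue and
    ``axis_direction`` the unit vector towards its last residue.
    """

    kind: str
    start: int
    end: int
    axis_origin: np.ndarray
    axis_direction: np.ndarray

    @property
    def n_res(self) -> int:
        return self.end - self.start + 1

    @property
    def length(self) -> float:
        return (self.n_res - 1) * self._rise()

    def _rise(self) -> float:
        return 1.5 if self.kind == "helix" else 3.3

    @property
    def midpoint(self) -> np.ndarray:
        return self.axis_origin + 0.5 * self.length * self.axis_direction

    @property
    def endpoints(self) -> np.ndarray:
        return np.vstack(
            [self.axis_origin, self.axis_origin + self.length * self.axis_direction]
        )


@dataclass
class Superposition:
    """Rigid transform ``x -> rotation @ x + translation`` with its RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "Superposition":
        rt = self.rotation.T
        return Superposition(rt, -rt @ self.translation, self.rmsd)

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(np.eye(3), np.zeros(3), 0.0)


@dataclass
class AlignParams:
    """Tunable parameters of the structural aligner.

    r0 : Qscore distance scale (Å).
    d_cut : residue pairs farther apart than this after superposition are
        dropped during refinement (Å).
    min_aligned : smallest correspondence accepted as structural similarity.
    max_iter : refinement iteration cap per seed.
    max_seeds : number of seed transforms refined, best-first.
    seed_angle_tol / seed_dist_tol : SSE-pair compatibility windows
        (degrees, Å).
    window : sliding-window length for the few-SSE seeding fallback.
    sse_anchor_min : an alignment counts as structural similarity only if
        at least this many corresponding pairs lie inside detected SSEs
        of both chains; the aligner matches secondary structure, so a
        correspondence built purely from irregular regions is treated as
        coincidental and reported as NO_SIMILARITY.
    early_stop_q : refinement of further seeds stops once this Qscore is
        reached (a self-comparison hits 1.0 on its first seed).
    """

    r0: float = 3.0
    d_cut: float = 5.0
    min_aligned: int = 10
    max_iter: int = 50
    max_seeds: int = 100
    seed_angle_tol: float = 30.0
    seed_dist_tol: float = 5.0
    window: int = 15
    sse_anchor_min: int = 3
    early_stop_q: float = 0.999


@dataclass
class AlignmentResult:
    """Outcome of a pairwise structural comparison.

    ``correspondence`` holds (index in A, index in B) pairs, strictly
    increasing in both components.  ``qscore`` is in [0, 1] for OK
    results and -1 (sentinel) when no similarity was detected.
    """

    correspondence: list[tuple[int, int]]
    n_aligned: int
    n1: int
    n2: int
    rmsd: float
    qscore: float
    transform: Superposition
    status: Status = Status.OK

    @classmethod
    def no_similarity(cls, n1: int, n2: int) -> "AlignmentResult":
        return cls(
            correspondence=[],
            n_aligned=0,
            n1=n1,
            n2=n2,
            rmsd=float("nan"),
            qscore=NO_SIMILARITY_SENTINEL,
            transform=Superposition.identity(),
            status=Status.NO_SIMILARITY,
        )

    def swapped(self) -> "AlignmentResult":
        """The same alignment viewed with the chains exchanged."""
        return AlignmentResult(
            correspondence=[(j, i) for i, j in self.correspondence],
            n_aligned=self.n_aligned,
            n1=self.n2,
            n2=self.n1,
            rmsd=self.rmsd,
            qscore=self.qscore,
            transform=self.transform.inverse(),
            status=self.status,
        )


# ---------------------------------------------------------------------------
# Secondary-structure assignment


def _candidate_mask(coords: np.ndarray, kind: str) -> np.ndarray:
    n = len(coords)
    mask = np.zeros(n, dtype=bool)

    def d(k: int) -> np.ndarray:
        return np.linalg.norm(coords[k:] - coords[:-k], axis=1)

    if kind == "helix" and n >= 5:
        d13, d14 = d(3), d(4)
        m = (
            (d13[: n - 4] >= HELIX_D13[0]) & (d13[: n - 4] <= HELIX_D13[1])
            & (d14 >= HELIX_D14[0]) & (d14 <= HELIX_D14[1])
        )
        mask[: n - 4] = m
    elif kind == "strand" and n >= 4:
        d12, d13 = d(2), d(3)
        m = (
            (d12[: n - 3] >= STRAND_D12[0]) & (d12[: n - 3] <= STRAND_D12[1])
            & (d13 >= STRAND_D13[0]) & (d13 <= STRAND_D13[1])
        )
        mask[: n - 3] = m
    return mask


def _fit_axis(coords: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares axis through the segment's smoothed Cα trace."""
    if kind == "helix" and len(coords) >= 4:
        # running 4-residue centroids cancel the helical wobble
        trace = np.array([coords[i : i + 4].mean(axis=0) for i in range(len(coords) - 3)])
    else:
        trace = coords
    center = trace.mean(axis=0)
    if len(trace) < 2:
        return center, np.array([0.0, 0.0, 1.0])
    _, _, vt = np.linalg.svd(trace - center)
    direction = vt[0]
    if np.dot(direction, coords[-1] - coords[0]) < 0:
        direction = -direction
    # origin: axis point closest to the first residue
    origin = center + np.dot(coords[0] - center, direction) * direction
    return origin, direction


def assign_sse(chain: ChainRecord | np.ndarray) -> list[SSE]:
    """Detect helices and strands from Cα geometry.

    Residue *i* is a helix candidate when d(i,i+3) ∈ [4.5, 6.0] Å and
    d(i,i+4) ∈ [5.7, 7.0] Å, and a strand candidate when
    d(i,i+2) ∈ [6.2, 7.2] Å and d(i,i+3) ∈ [9.3, 10.8] Å.  Runs of ≥ 5
    (helix) / ≥ 3 (strand) consecutive candidates become elements, the
    window tail included.  Helix assignments take precedence on overlap.
    Returns an empty list for chains shorter than 5 residues.
    """
    coords = chain.ca_coords if isinstance(chain, ChainRecord) else np.asarray(chain)
    n = len(coords)
    if n < 5:
        return []

    taken = np.zeros(n, dtype=bool)
    sses: list[SSE] = []
    for kind in ("helix", "strand"):
        mask = _candidate_mask(coords, kind) & ~taken
        i = 0
        while i < n:
            if not mask[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if j - i + 1 >= MIN_RUN[kind]:
                end = min(j + RUN_TAIL[kind], n - 1)
                if not taken[i : end + 1].any():
                    seg = coords[i : end + 1]
                    origin, direction = _fit_axis(seg, kind)
                    sses.append(SSE(kind, i, end, origin, direction))
                    taken[i : end + 1] = True
            i = j + 1
    sses.sort(key=lambda s: s.start)
    return sses


# ---------------------------------------------------------------------------
# Rigid superposition


def kabsch(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Optimal rigid superposition of point set Q onto P.

    Returns the proper rotation R and translation t minimising the RMSD
    of ``R @ q + t`` against P (Kabsch algorithm; reflections are
    corrected to proper rotations).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("at least 3 point pairs are required")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(P - cp, Q - cq)
    r = rot.as_matrix()
    t = cp - r @ cq
    diff = P - (Q @ r.T + t)
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return Superposition(r, t, rmsd)


def qscore(n_aligned: int, rmsd: float, n1: int, n2: int, r0: float = 3.0) -> float:
    """Superposition quality score in [0, 1].

    ``Nalign^2 / ((1 + (RMSD/R0)^2) * N1 * N2)``: 1 for identical
    structures, approaching 0 as fewer residues superpose or the RMSD
    grows relative to the scale R0.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must be >= 1")
    if not 0 <= n_aligned <= min(n1, n2):
        raise ValueError("n_aligned must be in [0, min(n1, n2)]")
    if rmsd < 0 or not np.isfinite(rmsd):
        raise ValueError("rmsd must be finite and >= 0")
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    return n_aligned**2 / ((1.0 + (rmsd / r0) ** 2) * n1 * n2)


# ---------------------------------------------------------------------------
# Seeding


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    c = abs(float(np.dot(u, v)))  # axis direction sign is arbitrary
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _sliding_window_seeds(
    coordsA: np.ndarray, coordsB: np.ndarray, window: int, max_offsets: int = 80
) -> list[Superposition]:
    """Gapless seeding: one Kabsch fit per relative sequence offset.

    The fit uses the full gapless overlap at each offset (at least
    ``window`` residues); offsets are strided down to ``max_offsets``.
    """
    nA, nB = len(coordsA), len(coordsB)
    w = min(window, nA, nB)
    if w < 3:
        return []
    offsets = list(range(-(nB - w), nA - w + 1))
    stride = max(1, -(-len(offsets) // max_offsets))
    if stride > 1:  # keep the zero offset in the strided set
        offsets = [k for k in offsets if k % stride == 0]
    seeds = []
    for k in offsets:
        a0, b0 = max(k, 0), max(-k, 0)
        m = min(nA - a0, nB - b0)
        seeds.append(kabsch(coordsA[a0 : a0 + m], coordsB[b0 : b0 + m]))
    return seeds


def _dedupe_seeds(seeds: list[Superposition]) -> list[Superposition]:
    """Drop transforms nearly identical to an earlier one (order kept)."""
    kept: list[Superposition] = []
    for s in seeds:
        dup = False
        for k in kept:
            if (
                np.linalg.norm(s.rotation - k.rotation) < 0.05
                and np.linalg.norm(s.translation - k.translation) < 0.5
            ):
                dup = True
                break
        if not dup:
            kept.append(s)
    return kept


def seed_transforms(
    ssesA: Sequence[SSE],
    ssesB: Sequence[SSE],
    coordsA: np.ndarray,
    coordsB: np.ndarray,
    params: AlignParams | None = None,
) -> list[Superposition]:
    """Propose rigid transforms from compatible SSE pairs.

    For every ordered pair of distinct SSEs (a1, a2) in A and (b1, b2)
    in B with matching kinds, compatible inter-axis angles (within
    ``seed_angle_tol``) and midpoint separations (within
    ``seed_dist_tol``), a transform is fitted by Kabsch on the four axis
    endpoints.  Gapless sliding-window seeds supplement the SSE seeds
    (they are all a chain with fewer than two SSEs gets, and they rescue
    cases where perturbed SSE boundaries shift the endpoint fit into a
    wrong register).  Near-duplicate transforms are dropped and seeds
    are returned best-first by a preliminary agreement count (residues
    of A within d_cut of a transformed residue of B).
    """
    params = params or AlignParams()
    seeds: list[Superposition] = []
    if len(ssesA) >= 2 and len(ssesB) >= 2:
        pairsA = [(x, y) for i, x in enumerate(ssesA) for j, y in enumerate(ssesA) if i != j]
        pairsB = [(x, y) for i, x in enumerate(ssesB) for j, y in enumerate(ssesB) if i != j]
        for a1, a2 in pairsA:
            angA = _angle_between(a1.axis_direction, a2.axis_direction)
            sepA = float(np.linalg.norm(a1.midpoint - a2.midpoint))
            for b1, b2 in pairsB:
                if a1.kind != b1.kind or a2.kind != b2.kind:
                    continue
                angB = _angle_between(b1.axis_direction, b2.axis_direction)
                if abs(angA - angB) > params.seed_angle_tol:
                    continue
                sepB = float(np.linalg.norm(b1.midpoint - b2.midpoint))
                if abs(sepA - sepB) > params.seed_dist_tol:
                    continue
                pa = np.vstack([a1.endpoints, a2.endpoints])
                pb = np.vstack([b1.endpoints, b2.endpoints])
                seeds.append(kabsch(pa, pb))
    seeds.extend(_sliding_window_seeds(coordsA, coordsB, params.window))
    seeds = _dedupe_seeds(seeds)
    if not seeds:
        return []

    tree = cKDTree(coordsA)
    scored = []
    for s in seeds:
        moved = s.apply(coordsB)
        d, _ = tree.query(moved, k=1, distance_upper_bound=params.d_cut)
        scored.append((int(np.isfinite(d).sum()), s))
    scored.sort(key=lambda x: -x[0])
    return [s for _, s in scored]


# ---------------------------------------------------------------------------
# Refinement


def _dp_correspondence(score: np.ndarray) -> list[tuple[int, int]]:
    """Order-preserving correspondence maximising the summed pair score.

    Needleman–Wunsch with zero gap penalty over a positive score matrix;
    ties prefer the diagonal (pairing) move.
    """
    n1, n2 = score.shape
    H = np.zeros((n1 + 1, n2 + 1))
    for i in range(1, n1 + 1):
        tmp = np.maximum(H[i - 1, :-1] + score[i - 1], H[i - 1, 1:])
        H[i, 1:] = np.maximum.accumulate(np.maximum(tmp, H[i, 0]))
    pairs: list[tuple[int, int]] = []
    i, j = n1, n2
    while i > 0 and j > 0:
        if H[i, j] == H[i - 1, j - 1] + score[i - 1, j - 1] and score[i - 1, j - 1] > 0:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def refine_alignment(
    coordsA: np.ndarray,
    coordsB: np.ndarray,
    seed: Superposition,
    params: AlignParams | None = None,
) -> AlignmentResult:
    """Iteratively refine a seed transform to maximise Qscore.

    Each iteration (1) builds the order-preserving correspondence under
    the current transform by dynamic programming with pair score
    1/(1+(d/r0)^2) and zero gap penalty, (2) drops pairs farther apart
    than ``d_cut``, (3) re-fits the transform by Kabsch on the surviving
    pairs.  Iteration stops when a correspondence set repeats or after
    ``max_iter`` rounds; the iterate of highest Qscore is returned.  If
    fewer than 3 pairs ever survive, the best iterate so far (or
    NO_SIMILARITY) is returned.
    """
    params = params or AlignParams()
    coordsA = np.asarray(coordsA, dtype=float)
    coordsB = np.asarray(coordsB, dtype=float)
    n1, n2 = len(coordsA), len(coordsB)
    best: AlignmentResult | None = None
    seen: set[tuple[tuple[int, int], ...]] = set()
    transform = seed

    for _ in range(params.max_iter):
        moved = transform.apply(coordsB)
        d2 = ((coordsA[:, None, :] - moved[None, :, :]) ** 2).sum(axis=2)
        score = 1.0 / (1.0 + d2 / params.r0**2)
        pairs = _dp_correspondence(score)
        if pairs:
            ia = np.array([p[0] for p in pairs])
            ib = np.array([p[1] for p in pairs])
            keep = d2[ia, ib] <= params.d_cut**2
            pairs = [p for p, k in zip(pairs, keep) if k]
        if len(pairs) < 3:
            break
        key = tuple(pairs)
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        transform = kabsch(coordsA[ia], coordsB[ib])
        q = qscore(len(pairs), transform.rmsd, n1, n2, params.r0)
        cand = AlignmentResult(
            correspondence=pairs,
            n_aligned=len(pairs),
            n1=n1,
            n2=n2,
            rmsd=transform.rmsd,
            qscore=q,
            transform=transform,
            status=Status.OK,
        )
        if best is None or cand.qscore > best.qscore:
            best = cand
        if key in seen:
            break
        seen.add(key)

    if best is None or best.n_aligned < params.min_aligned:
        return AlignmentResult.no_similarity(n1, n2)
    return best


# ---------------------------------------------------------------------------
# Top-level comparison


def _sse_mask(sses: Sequence[SSE], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s in sses:
        mask[s.start : s.end + 1] = True
    return mask


def _align_ordered(
    coordsA: np.ndarray, coordsB: np.ndarray, params: AlignParams
) -> AlignmentResult:
    ssesA = assign_sse(coordsA)
    ssesB = assign_sse(coordsB)
    no_sim = AlignmentResult.no_similarity(len(coordsA), len(coordsB))
    # an SSE-matching aligner has nothing to anchor on in a chain with no
    # recognisable secondary structure
    if not ssesA or not ssesB:
        return no_sim
    maskA = _sse_mask(ssesA, len(coordsA))
    maskB = _sse_mask(ssesB, len(coordsB))
    seeds = seed_transforms(ssesA, ssesB, coordsA, coordsB, params)[: params.max_seeds]
    best = no_sim
    for seed in seeds:
        res = refine_alignment(coordsA, coordsB, seed, params)
        if res.status is not Status.OK:
            continue
        anchored = sum(1 for i, j in res.correspondence if maskA[i] and maskB[j])
        if anchored < params.sse_anchor_min:
            continue
        if best.status is not Status.OK or res.qscore > best.qscore:
            best = res
        if best.qscore >= params.early_stop_q:
            break
    return best


def align_structures(
    chainA: ChainRecord,
    chainB: ChainRecord,
    params: AlignParams | None = None,
) -> AlignmentResult:
    """Compare two chains structurally and return the best Qscore alignment.

    The computation is carried out with the chains in canonical
    lexicographic order by (entry_id, chain_id) and the result inverted
    if the caller passed them the other way round, so that the score is
    exactly symmetric.  Returns NO_SIMILARITY (qscore sentinel -1) when
    no seed yields at least ``min_aligned`` corresponding residues.
    """
    params = params or AlignParams()
    if chainA.n_resolved < 3 or chainB.n_resolved < 3:
        return AlignmentResult.no_similarity(chainA.n_resolved, chainB.n_resolved)
    swap = (chainA.entry_id, chainA.chain_id) > (chainB.entry_id, chainB.chain_id)
    first, second = (chainB, chainA) if swap else (chainA, chainB)
    res = _align_ordered(first.ca_coords, second.ca_coords, params)
    return res.swapped() if swap else res


def self_check(chain: ChainRecord, params: AlignParams | None = None) -> bool:
    """Vet a chain: can the aligner make sense of its secondary structure?

    Passes iff at least one SSE is detected and the chain aligned with
    itself yields an OK result with Qscore ≥ 0.99.  Chains failing this
    cannot serve as cluster centroids.
    """
    params = params or AlignParams()
    if chain.n_resolved < 5:
        return False
    if not assign_sse(chain):
        return False
    res = align_structures(chain, chain, params)
    return res.status is Status.OK and res.qscore >= 0.99
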