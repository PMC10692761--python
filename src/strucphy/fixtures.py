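"""Synthetic protein chains with controllable secondary-structure content.

The generators build Cα-only chains from ideal geometric templates —
α-helical traces (1.5 Å rise, 100° twist per residue, 2.3 Å radius),
extended β-strand zig-zags, and random-walk coils — plus mutation and
coordinate-noise operators.  Every stage of the pipeline is thereby
testable without downloading real structures.  All stochastic operations
take explicit seeds and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from strucphy.structure_io import ChainRecord, write_chain_pdb

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

CA_STEP = 3.8  # canonical consecutive Cα–Cα distance, Å

# Ideal α-helix Cα parameters
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3

# Ideal extended-strand parameters: 3.3 Å rise with an alternating
# perpendicular offset sized so consecutive Cα–Cα distances equal 3.8 Å.
STRAND_RISE = 3.3
STRAND_OFFSET = float(np.sqrt(CA_STEP**2 - STRAND_RISE**2) / 2.0)


@dataclass
class ChainSpec:
    """Recipe for a synthetic chain.

    ``segments`` is an ordered list of ``(kind, n_residues)`` with kind in
    ``{"helix", "strand", "coil"}``.  ``sequence_mode`` is either
    ``"random"`` or a fixed sequence string whose length must equal the
    total residue count.
    """

    segments: list[tuple[str, int]]
    sequence_mode: str = "random"
    seed: int = 0
    entry_id: str = "synt"
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not self.segments or sum(n for _, n in self.segments) < 1:
            raise ValueError("spec must contain at least one residue")
        for kind, n in self.segments:
            if kind not in ("helix", "strand", "coil"):
                raise ValueError(f"unknown segment kind {kind!r}")
            if n < 1:
                raise ValueError("segment length must be >= 1")

    @property
    def n_res(self) -> int:
        return sum(n for _, n in self.segments)


def make_ideal_sse(kind: str, n_res: int) -> np.ndarray:
    """Cα trace of an ideal helix or strand, ``(n_res, 3)`` in Å.

    The helix runs along +z; the strand along +x with its zig-zag in the
    xy-plane.  Geometry is chosen to satisfy the Cα-distance criteria of
    the secondary-structure detector.
    """
    if n_res < 4:
        raise ValueError("an ideal SSE needs at least 4 residues")
    if kind == "helix":
        i = np.arange(n_res)
        theta = np.deg2rad(HELIX_TWIST_DEG) * i
        return np.column_stack(
            [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
        )
    if kind == "strand":
        i = np.arange(n_res)
        y = np.where(i % 2 == 0, STRAND_OFFSET, -STRAND_OFFSET)
        return np.column_stack([STRAND_RISE * i, y, np.zeros(n_res)])
    raise ValueError(f"unknown SSE kind {kind!r}")


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _coil_walk(n: int, rng: np.random.Generator, start: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Smooth random walk with fixed 3.8 Å steps: irregular, detector-blind."""
    pts = [start]
    d = direction / np.linalg.norm(direction)
    for _ in range(n - 1):
        d = d + 0.9 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + CA_STEP * d)
    return np.asarray(pts)


def synth_chain(spec: ChainSpec, pdb_path: str | Path | None = None) -> ChainRecord:
    """Build a synthetic chain from a :class:`ChainSpec`.

    Segment geometries are concatenated with 3.8 Å linker steps; each
    regular segment is laid along the current growth direction, which is
    rotated between segments so the chain does not self-overlap.  The
    deposited sequence equals the resolved sequence.  Deterministic for
    a given spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    coords: list[np.ndarray] = []
    pos = np.zeros(3)
    direction = np.array([1.0, 0.0, 0.0])
    seg_axes = {"helix": np.array([0.0, 0.0, 1.0]), "strand": np.array([1.0, 0.0, 0.0])}

    for si, (kind, n) in enumerate(spec.segments):
        if coords:
            pos = coords[-1][-1] + CA_STEP * direction
        if kind == "coil":
            seg = _coil_walk(n, rng, pos, direction)
        else:
            local = make_ideal_sse(kind, max(n, 4))[:n]
            rot = _rotation_between(seg_axes[kind], direction)
            seg = (local - local[0]) @ rot.T + pos
        coords.append(seg)
        # turn the growth direction between segments (deterministic spiral)
        ang = np.deg2rad(75.0 + 17.0 * si)
        c, s = np.cos(ang), np.sin(ang)
        turn = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        direction = turn @ direction
        if kind != "coil":
            end_dir = seg[-1] - seg[max(len(seg) - 4, 0)]
            nrm = np.linalg.norm(end_dir)
            if nrm > 1e-9:
                direction = 0.5 * direction + 0.5 * end_dir / nrm
                direction /= np.linalg.norm(direction)

    ca = np.vstack(coords)
    n_total = len(ca)
    if spec.sequence_mode == "random":
        seq = "".join(rng.choice(list(AA_ALPHABET), size=n_total))
    else:
        if len(spec.sequence_mode) != n_total:
            raise ValueError("fixed sequence length must match total residue count")
        seq = spec.sequence_mode
    rec = ChainRecord(
        entry_id=spec.entry_id,
        chain_id=spec.chain_id,
        deposited_seq=seq,
        resolved_seq=seq,
        ca_coords=ca,
    )
    if pdb_path is not None:
        write_chain_pdb(rec, pdb_path)
    return rec


def perturb_chain(chain: ChainRecord, sigma: float, seed: int = 0) -> ChainRecord:
    """Add i.i.d. Gaussian noise (std ``sigma`` Å per coordinate) to each Cα."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=chain.ca_coords.shape) if sigma > 0 else 0.0
    return chain.with_coords(chain.ca_coords + noise)


def mutate_seq(seq: str, rate: float, seed: int = 0) -> str:
    """Substitute each position with probability ``rate`` by a different residue."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for aa in seq:
        if rng.random() < rate:
            choices = [c for c in AA_ALPHABET if c != aa]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


# ---------------------------------------------------------------------------
# Presets used by the CLI and the end-to-end tests


def two_helix_chain(seed: int = 1, entry_id: str = "twhx", chain_id: str = "A") -> ChainRecord:
    """45-residue helix–coil–helix chain; passes the centroid self-check."""
    return synth_chain(
        ChainSpec(
            segments=[("helix", 20), ("coil", 5), ("helix", 20)],
            seed=seed,
            entry_id=entry_id,
            chain_id=chain_id,
        )
    )


def coil_chain(n: int = 60, seed: int = 7, entry_id: str = "coil", chain_id: str = "A") -> ChainRecord:
    """Pure random-walk coil; fails the centroid self-check (no SSEs)."""
    return synth_chain(
        ChainSpec(segments=[("coil", n)], seed=seed, entry_id=entry_id, chain_id=chain_id)
    )


def histone_like_chain(seed: int = 3, entry_id: str = "hist", chain_id: str = "A") -> ChainRecord:
    """Helix-rich chain echoing the short–long–short helix histone fold."""
    return synth_chain(
        ChainSpec(
            segments=[
                ("coil", 8), ("helix", 10), ("coil", 4),
                ("helix", 28), ("coil", 4), ("helix", 10), ("coil", 6),
            ],
            seed=seed,
            entry_id=entry_id,
            chain_id=chain_id,
        )
    )


def strand_sheet_chain(seed: int = 5, entry_id: str = "shee", chain_id: str = "A") -> ChainRecord:
    """55-residue five-strand chain; the all-β counterpart of the presets."""
    return synth_chain(
        ChainSpec(
            segments=[("strand", 8), ("coil", 3)] * 5,
            seed=seed,
            entry_id=entry_id,
            chain_id=chain_id,
        )
    )


def _copies(
    founder: ChainRecord,
    prefix: str,
    n: int,
    mutation_rate: float,
    noise_sigma: float,
    base_seed: int,
) -> list[ChainRecord]:
    out = []
    for mi in range(n):
        seed = base_seed + mi
        seq = mutate_seq(founder.deposited_seq, mutation_rate, seed=seed)
        member = ChainRecord(
            entry_id=f"{prefix}{mi:02d}",
            chain_id="A",
            deposited_seq=seq,
            resolved_seq=seq,
            ca_coords=founder.ca_coords,
        )
        out.append(perturb_chain(member, noise_sigma, seed=seed))
    return out


def family_set(
    out_dir: str | Path | None = None,
    base_seed: int = 11,
) -> dict[str, list[ChainRecord]]:
    """Fixture set for end-to-end tests, ~30 chains in two structural
    families of opposite secondary-structure class plus one coil.

    Each family has a *cluster* of near-identical members (2% mutations,
    0.3 Å coordinate noise — redundancy the identity clustering must
    collapse) and sequence-diverged *relatives* of the same fold (50%
    mutations — below any identity threshold, so each founds its own
    cluster, yet structurally nearly identical to the family centroid:
    the neighbours a structural search must recover).  The helix family
    carries only helices and the strand family only strands, so an
    SSE-matching aligner finds no similarity across families.  The
    coil-only singleton has no secondary structure and is removed during
    centroid vetting.
    """
    # founders are ~100 residues: realistic single-domain size, and large
    # enough that coincidental cross-fold matches fall below Qscore 0.1
    helix_founder = synth_chain(
        ChainSpec(
            segments=[("helix", 30), ("coil", 6), ("helix", 30), ("coil", 6), ("helix", 30)],
            seed=base_seed,
            entry_id="ha00",
        )
    )
    strand_founder = synth_chain(
        ChainSpec(
            segments=[("strand", 10), ("coil", 3)] * 8,
            seed=base_seed + 1,
            entry_id="sb00",
        )
    )
    out: dict[str, list[ChainRecord]] = {
        "helix_cluster": [helix_founder]
        + _copies(helix_founder, "ha", 8, 0.02, 0.2, base_seed + 100)[1:],
        "helix_relatives": _copies(helix_founder, "hr", 5, 0.50, 0.2, base_seed + 200),
        "strand_cluster": [strand_founder]
        + _copies(strand_founder, "sb", 8, 0.02, 0.2, base_seed + 300)[1:],
        "strand_relatives": _copies(strand_founder, "sr", 5, 0.50, 0.2, base_seed + 400),
        "coil_singleton": [coil_chain(n=60, seed=7, entry_id="lone")],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for members in out.values():
            for rec in members:
                write_chain_pdb(rec, out_dir / f"{rec.entry_id}.pdb")
    return out
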