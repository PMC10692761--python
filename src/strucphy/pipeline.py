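"""End-to-end database build and query modes.

The build runs the full funnel: read and split structures into chains,
filter on deposited size (≥ 50 aa by default), cluster at 90% sequence
identity, vet cluster centroids with the structural self-check
(replacing or removing clusters whose centroid the aligner cannot make
sense of), then compute all centroid-pair structure and sequence scores.
The result is persisted as a plain directory of TSV tables plus
per-chain PDB files, so a build is inspectable and diff-able, and
rebuilding from the same input is byte-identical.

Two query modes are served over a built database: *neighbours* (ranked
structural neighbourhood of the query's cluster centroid, reported at
Qscore ≥ 0.1 — the structural analogue of the sequence twilight zone)
and *cluster view* (membership and per-member superposition against the
centroid).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from strucphy.clustering import Cluster, flag_confidence, greedy_cluster
from strucphy.seq_compare import local_align_stats
from strucphy.struct_align import (
    AlignParams,
    AlignmentResult,
    Status,
    align_structures,
    self_check,
)
from strucphy.structure_io import (
    ChainRecord,
    StructureParseError,
    chain_size,
    filter_chains,
    read_chains,
    write_chain_pdb,
)

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "id1", "id2", "qscore", "rmsd", "n_aligned", "n1", "n2",
    "identity_pct", "similarity_pct", "bit_score", "evalue",
]


def to_distance(q: float) -> float:
    """Convert a Qscore (or the -1 sentinel) to a distance in [0, 1].

    Distance is ``1 − Qscore``; the NO_SIMILARITY sentinel is treated as
    similarity zero, i.e. distance 1.0.
    """
    if q == -1.0:
        return 1.0
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"qscore must be in [0, 1] or the -1 sentinel, got {q}")
    return 1.0 - q


def canonical_pair(id1: str, id2: str) -> tuple[str, str]:
    return (id1, id2) if id1 <= id2 else (id2, id1)


@dataclass
class HitList:
    """Ranked structural neighbourhood of a query centroid."""

    query_centroid_id: str
    hits: list[dict] = field(default_factory=list)

    def taxa(self, include_query: bool = True) -> list[str]:
        out = [self.query_centroid_id] if include_query else []
        return out + [h["centroid_id"] for h in self.hits]

    def to_frame(self) -> pd.DataFrame:
        cols = ["centroid_id", "qscore", "distance", "rmsd", "n_aligned",
                "identity_pct", "similarity_pct", "bit_score", "evalue",
                "scop", "cath", "description"]
        return pd.DataFrame(self.hits, columns=cols)


def vet_centroids(
    clusters: Sequence[Cluster],
    chains: Mapping[str, ChainRecord],
    params: AlignParams | None = None,
) -> tuple[list[Cluster], list[str], list[dict]]:
    """Vet every cluster centroid with the structural self-check.

    A centroid that fails is replaced by the largest member that passes;
    clusters in which no member passes (including failing singletons)
    are removed.  Returns the vetted clusters, the removed cluster ids,
    and a log of every replacement/removal.
    """
    params = params or AlignParams()
    vetted: list[Cluster] = []
    removed: list[str] = []
    log: list[dict] = []
    for cluster in clusters:
        candidates = sorted(
            cluster.member_ids,
            key=lambda mid: (-chain_size(chains[mid]), mid),
        )
        # try the designated centroid first, then members by size
        ordered = [cluster.centroid_id] + [m for m in candidates if m != cluster.centroid_id]
        new_centroid = None
        for mid in ordered:
            if self_check(chains[mid], params):
                new_centroid = mid
                break
        if new_centroid is None:
            removed.append(cluster.cluster_id)
            log.append({"cluster_id": cluster.cluster_id, "action": "removed",
                        "old_centroid": cluster.centroid_id, "new_centroid": ""})
            continue
        if new_centroid != cluster.centroid_id:
            log.append({"cluster_id": cluster.cluster_id, "action": "replaced",
                        "old_centroid": cluster.centroid_id, "new_centroid": new_centroid})
            cluster = Cluster(
                cluster_id=cluster.cluster_id,
                centroid_id=new_centroid,
                member_ids=list(cluster.member_ids),
                confidence=dict(cluster.confidence),
            )
        vetted.append(cluster)
    return vetted, removed, log


def _score_row(a: ChainRecord, b: ChainRecord, params: AlignParams) -> dict:
    id1, id2 = canonical_pair(a.key, b.key)
    if id1 != a.key:
        a, b = b, a
    res = align_structures(a, b, params)
    seq = local_align_stats(a.deposited_seq, b.deposited_seq)
    ok = res.status is Status.OK
    return {
        "id1": id1,
        "id2": id2,
        "qscore": round(res.qscore, 6) if ok else -1.0,
        "rmsd": round(res.rmsd, 4) if ok else -1.0,
        "n_aligned": res.n_aligned if ok else -1,
        "n1": res.n1,
        "n2": res.n2,
        "identity_pct": round(seq.identity_pct, 2),
        "similarity_pct": round(seq.similarity_pct, 2),
        "bit_score": round(seq.bit_score, 2),
        "evalue": float(f"{seq.evalue:.6g}") if seq.status is Status.OK else -1.0,
    }


def all_pairs_scores(
    centroids: Sequence[ChainRecord],
    params: AlignParams | None = None,
) -> pd.DataFrame:
    """Structure and sequence scores for every unordered centroid pair.

    One row per pair, keyed by the lexicographically ordered id pair;
    NO_SIMILARITY outcomes are encoded as -1.  The result is independent
    of input order.
    """
    if len(centroids) < 2:
        raise ValueError("need at least 2 vetted centroids")
    params = params or AlignParams()
    by_key = sorted(centroids, key=lambda c: c.key)
    rows = []
    for i in range(len(by_key)):
        for j in range(i + 1, len(by_key)):
            rows.append(_score_row(by_key[i], by_key[j], params))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# Persistence


@dataclass
class Database:
    """A built structural-phylogenetics database.

    Directory layout: ``chains.tsv`` (one row per retained chain),
    ``clusters.tsv`` (one row per cluster member), ``scores.tsv`` (one
    row per centroid pair), ``vetting.tsv`` (replacement/removal log),
    ``meta.json`` (build parameters), and ``chains/<id>.pdb`` Cα files.
    """

    root: Path
    chains: dict[str, ChainRecord]
    clusters: list[Cluster]
    scores: pd.DataFrame
    params: AlignParams = field(default_factory=AlignParams)
    annotations: pd.DataFrame | None = None

    # -- lookups ----------------------------------------------------------

    def cluster_of(self, query: str) -> Cluster:
        for cluster in self.clusters:
            if query in cluster.member_ids:
                return cluster
        raise KeyError(f"query id {query!r} not found in any cluster")

    def centroid_ids(self) -> list[str]:
        return [c.centroid_id for c in self.clusters]

    def pair_qscore(self, id1: str, id2: str) -> float:
        """Qscore for a centroid pair (1.0 on the diagonal), computed on
        demand if the pair is missing from the score table."""
        if id1 == id2:
            return 1.0
        a, b = canonical_pair(id1, id2)
        hit = self.scores[(self.scores.id1 == a) & (self.scores.id2 == b)]
        if len(hit):
            return float(hit.iloc[0].qscore)
        res = align_structures(self.chains[a], self.chains[b], self.params)
        return res.qscore if res.status is Status.OK else -1.0

    def annotation_for(self, centroid_id: str) -> dict[str, str]:
        out = {"scop": "N/A", "cath": "N/A", "description": "N/A"}
        if self.annotations is not None:
            hit = self.annotations[self.annotations.member_id == centroid_id]
            if len(hit):
                row = hit.iloc[0]
                for k in out:
                    if k in row and pd.notna(row[k]) and str(row[k]):
                        out[k] = str(row[k])
        return out

    # -- persistence ------------------------------------------------------

    def save(self) -> None:
        self.root.mkdir(parents=True, exist_ok=True)
        chain_rows = []
        for key in sorted(self.chains):
            c = self.chains[key]
            chain_rows.append({
                "member_id": key,
                "entry_id": c.entry_id,
                "chain_id": c.chain_id,
                "size": chain_size(c),
                "n_resolved": c.n_resolved,
                "deposited_seq": c.deposited_seq,
                "resolved_seq": c.resolved_seq,
                "author_numbers": ",".join(c.author_numbers),
            })
        pd.DataFrame(chain_rows).to_csv(self.root / "chains.tsv", sep="\t", index=False)

        cluster_rows = []
        for cl in self.clusters:
            for mid in cl.member_ids:
                cluster_rows.append({
                    "cluster_id": cl.cluster_id,
                    "centroid_id": cl.centroid_id,
                    "member_id": mid,
                    "member_size": chain_size(self.chains[mid]),
                    "confidence": cl.confidence.get(mid, "high"),
                })
        pd.DataFrame(cluster_rows).to_csv(self.root / "clusters.tsv", sep="\t", index=False)
        self.scores.to_csv(self.root / "scores.tsv", sep="\t", index=False)

        pdb_dir = self.root / "chains"
        pdb_dir.mkdir(exist_ok=True)
        for key in sorted(self.chains):
            write_chain_pdb(self.chains[key], pdb_dir / f"{key}.pdb")
        meta = {
            "r0": self.params.r0,
            "d_cut": self.params.d_cut,
            "min_aligned": self.params.min_aligned,
            "max_iter": self.params.max_iter,
            "max_seeds": self.params.max_seeds,
        }
        (self.root / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, root: str | Path) -> "Database":
        root = Path(root)
        chains_df = pd.read_csv(root / "chains.tsv", sep="\t", dtype=str)
        chains: dict[str, ChainRecord] = {}
        pdb_dir = root / "chains"
        for _, row in chains_df.iterrows():
            recs = read_chains(pdb_dir / f"{row.member_id}.pdb")
            rec = recs[0]
            chains[row.member_id] = ChainRecord(
                entry_id=row.entry_id,
                chain_id=row.chain_id,
                deposited_seq=row.deposited_seq,
                resolved_seq=rec.resolved_seq,
                ca_coords=rec.ca_coords,
                author_numbers=str(row.author_numbers).split(","),
            )
        clusters_df = pd.read_csv(root / "clusters.tsv", sep="\t", dtype=str)
        clusters = []
        for cid, grp in clusters_df.groupby("cluster_id", sort=True):
            cluster = Cluster(
                cluster_id=str(cid),
                centroid_id=grp.iloc[0].centroid_id,
                member_ids=list(grp.member_id),
                confidence={r.member_id: r.confidence for r in grp.itertuples()},
            )
            clusters.append(cluster)
        scores = pd.read_csv(root / "scores.tsv", sep="\t")
        meta = json.loads((root / "meta.json").read_text())
        params = AlignParams(
            r0=meta["r0"], d_cut=meta["d_cut"], min_aligned=meta["min_aligned"],
            max_iter=meta["max_iter"], max_seeds=meta["max_seeds"],
        )
        return cls(root=root, chains=chains, clusters=clusters, scores=scores, params=params)


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read a user-supplied annotation table (TSV keyed by ``member_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "member_id" not in df.columns:
        raise ValueError("annotation table needs a 'member_id' column")
    return df


# ---------------------------------------------------------------------------
# Build


def build_database(
    input_dir: str | Path,
    out_db: str | Path,
    min_length: int = 50,
    identity: float = 0.90,
    fasta: str | Path | None = None,
    params: AlignParams | None = None,
    annotations: str | Path | None = None,
) -> Database:
    """Run the full funnel over a directory of structure files.

    Stages (counts for each are logged to stderr): read & split into
    chains → deposited-size filter (≥ ``min_length``) → greedy identity
    clustering (≥ ``identity`` to the centroid) → confidence flagging →
    centroid vetting (self-check, replacement, removal) → all-pairs
    centroid scores.  The persisted database directory is returned
    loaded.  Unparseable files are logged and discarded.
    """
    params = params or AlignParams()
    input_dir = Path(input_dir)
    files = sorted(p for p in input_dir.iterdir() if p.suffix.lower() in (".pdb", ".ent", ".cif"))
    all_chains: list[ChainRecord] = []
    for f in files:
        try:
            all_chains.extend(read_chains(f, fasta=fasta))
        except StructureParseError as exc:
            logger.warning("discarding %s: %s", f.name, exc)
    logger.info("chains read: %d (from %d files)", len(all_chains), len(files))

    kept = filter_chains(all_chains, min_length)
    logger.info("chains ≥ %d aa: %d", min_length, len(kept))
    if len(kept) < 2:
        raise ValueError("fewer than two chains pass the size filter")

    chains = {c.key: c for c in kept}
    clusters = greedy_cluster(kept, threshold=identity)
    logger.info("clusters: %d", len(clusters))
    for cl in clusters:
        flag_confidence(cl, [chain_size(chains[m]) for m in cl.member_ids])

    vetted, removed, vet_log = vet_centroids(clusters, chains, params)
    logger.info("vetted clusters: %d (removed %d)", len(vetted), len(removed))

    centroids = [chains[c.centroid_id] for c in vetted]
    scores = all_pairs_scores(centroids, params)
    logger.info("centroid pairs scored: %d", len(scores))

    db = Database(
        root=Path(out_db),
        chains=chains,
        clusters=vetted,
        scores=scores,
        params=params,
        annotations=load_annotations(annotations) if annotations else None,
    )
    db.save()
    pd.DataFrame(vet_log, columns=["cluster_id", "action", "old_centroid", "new_centroid"]).to_csv(
        db.root / "vetting.tsv", sep="\t", index=False
    )
    return db


# ---------------------------------------------------------------------------
# Query modes


def neighbours(
    db: Database,
    query: str,
    min_qscore: float = 0.1,
    top_n: int | None = 50,
    include_self: bool = False,
) -> HitList:
    """Ranked structural neighbourhood of the query's cluster centroid.

    The query may be any cluster member; its centroid is the comparison
    anchor.  Hits are centroids with Qscore ≥ ``min_qscore`` (default
    0.1, below which structural similarity enters the twilight zone),
    sorted by Qscore descending and truncated to ``top_n``.  The query
    centroid itself is excluded from the hit rows unless
    ``include_self``; it is always available as the first taxon for
    matrix/tree export (:meth:`HitList.taxa`).
    """
    centroid_id = db.cluster_of(query).centroid_id
    rows = []
    if include_self:
        ann = db.annotation_for(centroid_id)
        rows.append({
            "centroid_id": centroid_id, "qscore": 1.0, "distance": 0.0,
            "rmsd": 0.0, "n_aligned": db.chains[centroid_id].n_resolved,
            "identity_pct": 100.0, "similarity_pct": 100.0,
            "bit_score": float("nan"), "evalue": float("nan"), **ann,
        })
    sub = db.scores[(db.scores.id1 == centroid_id) | (db.scores.id2 == centroid_id)]
    for row in sub.itertuples():
        q = float(row.qscore)
        if q == -1.0 or q < min_qscore:
            continue
        other = row.id2 if row.id1 == centroid_id else row.id1
        ann = db.annotation_for(other)
        rows.append({
            "centroid_id": other,
            "qscore": q,
            "distance": to_distance(q),
            "rmsd": float(row.rmsd),
            "n_aligned": int(row.n_aligned),
            "identity_pct": float(row.identity_pct),
            "similarity_pct": float(row.similarity_pct),
            "bit_score": float(row.bit_score),
            "evalue": float(row.evalue),
            **ann,
        })
    rows.sort(key=lambda r: (-r["qscore"], r["centroid_id"]))
    if top_n is not None:
        keep = top_n + (1 if include_self else 0)
        rows = rows[:keep]
    return HitList(query_centroid_id=centroid_id, hits=rows)


def cluster_view(db: Database, query: str) -> pd.DataFrame:
    """Members of the query's cluster with their alignment to the centroid.

    One row per member: id, deposited size, confidence flag, and the
    Qscore of the member's structure against the cluster centroid (1.0
    for the centroid itself).
    """
    cluster = db.cluster_of(query)
    centroid = db.chains[cluster.centroid_id]
    rows = []
    for mid in cluster.member_ids:
        member = db.chains[mid]
        if mid == cluster.centroid_id:
            q, rmsd, nal = 1.0, 0.0, member.n_resolved
        else:
            res = align_structures(member, centroid, db.params)
            ok = res.status is Status.OK
            q = res.qscore if ok else -1.0
            rmsd = res.rmsd if ok else float("nan")
            nal = res.n_aligned
        rows.append({
            "cluster_id": cluster.cluster_id,
            "member_id": mid,
            "size": chain_size(member),
            "confidence": cluster.confidence.get(mid, "high"),
            "qscore_vs_centroid": round(q, 6),
            "rmsd": round(rmsd, 4) if np.isfinite(rmsd) else rmsd,
            "n_aligned": nal,
        })
    return pd.DataFrame(rows)
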