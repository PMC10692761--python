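"""Greedy sequence-identity clustering and per-member confidence flags.

Chains are processed in decreasing deposited-size order and each joins
the first existing cluster whose centroid it matches at or above the
identity threshold (semi-global identity), otherwise it founds a new
cluster with itself as centroid — the greedy centroid-linkage scheme of
UCLUST-style tools.  Clustering removes the redundancy caused by
repeated depositions, homo-multimers and point-mutant series.

Because the identity is semi-global, members of one cluster are expected
to have near-identical sizes; members whose size deviates from the
cluster median by more than one standard deviation are flagged as
low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from strucphy.seq_compare import semi_global_identity
from strucphy.structure_io import ChainRecord, chain_size


@dataclass
class Cluster:
    """An identity-based cluster with its centroid and member flags."""

    cluster_id: str
    centroid_id: str
    member_ids: list[str]
    confidence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.centroid_id not in self.member_ids:
            raise ValueError("centroid must be a member of its own cluster")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("member ids must be unique")


def greedy_cluster(
    chains: Sequence[ChainRecord],
    threshold: float = 0.90,
    best_hit: bool = False,
) -> list[Cluster]:
    """Cluster chains at a sequence-identity threshold (default 90%).

    Chains are visited in decreasing :func:`chain_size` order (ties
    broken lexicographically by id) so that centroids are the longest
    sequences.  With ``best_hit=False`` (default, matching the greedy
    first-hit semantics of the reference clustering tools) a chain joins
    the first centroid at identity ≥ threshold, in cluster-founding
    order; with ``best_hit=True`` it joins the best-matching centroid.
    Cluster ids are zero-padded 5-digit ordinals in founding order.
    """
    if not chains:
        raise ValueError("no chains to cluster")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(chains, key=lambda c: (-chain_size(c), c.key))
    centroids: list[ChainRecord] = []
    members: list[list[str]] = []
    for chain in order:
        hit = None
        best_ident = -1.0
        for ci, centroid in enumerate(centroids):
            ident = semi_global_identity(chain.deposited_seq, centroid.deposited_seq)
            if ident >= threshold:
                if not best_hit:
                    hit = ci
                    break
                if ident > best_ident:
                    best_ident = ident
                    hit = ci
        if hit is None:
            centroids.append(chain)
            members.append([chain.key])
        else:
            members[hit].append(chain.key)
    return [
        Cluster(
            cluster_id=f"{i + 1:05d}",
            centroid_id=centroids[i].key,
            member_ids=members[i],
        )
        for i in range(len(centroids))
    ]


def flag_confidence(cluster: Cluster, sizes: Sequence[int]) -> dict[str, str]:
    """Flag members whose size deviates from the cluster median by > 1 SD.

    ``sizes`` aligns with ``cluster.member_ids``.  The spread is the
    population standard deviation of the member sizes; a member is
    ``"low"`` iff ``|size − median| > SD`` and ``"high"`` otherwise.
    With zero SD (all sizes equal) any nonzero deviation flags low.
    The flags are also stored on the cluster.
    """
    if len(sizes) != len(cluster.member_ids):
        raise ValueError("sizes must align with member_ids")
    arr = np.asarray(sizes, dtype=float)
    median = float(np.median(arr))
    sd = float(arr.std())  # population SD
    flags = {
        mid: ("low" if abs(s - median) > sd else "high")
        for mid, s in zip(cluster.member_ids, arr)
    }
    cluster.confidence = flags
    return flags
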