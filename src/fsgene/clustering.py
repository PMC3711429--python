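"""Constrained homology clustering of fs-proteins.

Two fs-proteins are joined by an edge when the best stringent hit between
them (E <= 1e-50) satisfies three criteria: (i) both frameshift positions
lie inside the pairwise alignment block, at least 10 aa from its borders;
(ii) both frameshifts have the same direction; (iii) the two frameshift
positions are separated by at most 50 aa measured in alignment columns.
Connected components of two or more nodes are clusters; the rest are
singletons.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .homology import AlignmentHit
from .model import FsProtein

logger = logging.getLogger(__name__)

MIN_BORDER_AA = 10
MAX_FS_SEPARATION_AA = 50


@dataclass(frozen=True)
class Cluster:
    """A connected component of fs-genes sharing a frameshift context."""

    id: str
    members: tuple[str, ...]
    direction: int
    genera: frozenset[str] = frozenset()
    name: str = ""

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_genera(self) -> int:
        return len(self.genera)


def edge_satisfied(
    hit: AlignmentHit,
    fs_a: int,
    fs_b: int,
    dir_a: int,
    dir_b: int,
    min_border: int = MIN_BORDER_AA,
    max_sep: int = MAX_FS_SEPARATION_AA,
) -> bool:
    """Evaluate the three edge criteria on one hit (query=a, target=b)."""
    if dir_a != dir_b:
        return False
    if not (
        hit.query_start + min_border <= fs_a < hit.query_end - min_border + 1
        and hit.target_start + min_border <= fs_b < hit.target_end - min_border + 1
    ):
        return False
    col_a = hit.project_query(fs_a)
    col_b = hit.project_target(fs_b)
    return abs(col_a - col_b) <= max_sep


def _best_hit_per_pair(hits: list[AlignmentHit]) -> dict[tuple[str, str], AlignmentHit]:
    """Lowest-E hit per unordered pair; ties by higher score then ids."""
    best: dict[tuple[str, str], AlignmentHit] = {}
    for hit in hits:
        key = tuple(sorted((hit.query, hit.target)))
        prev = best.get(key)
        if (
            prev is None
            or hit.evalue < prev.evalue
            or (hit.evalue == prev.evalue and hit.score > prev.score)
        ):
            best[key] = hit
    return best


def build_fs_graph(
    fs_proteins: dict[str, FsProtein],
    hits: list[AlignmentHit],
    min_border: int = MIN_BORDER_AA,
    max_sep: int = MAX_FS_SEPARATION_AA,
) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(sorted(fs_proteins))
    for (a, b), hit in sorted(_best_hit_per_pair(hits).items()):
        if a not in fs_proteins or b not in fs_proteins:
            logger.warning("hit %s-%s references unknown fs-protein; skipped", a, b)
            continue
        if not hit.query_blocks:
            logger.warning("hit %s-%s has no interval data; skipped", a, b)
            continue
        pa, pb = fs_proteins[a], fs_proteins[b]
        # orient the hit: query side may be either member of the sorted pair
        if hit.query == a:
            ok = edge_satisfied(hit, pa.fs_aa, pb.fs_aa, pa.direction, pb.direction,
                                min_border, max_sep)
        else:
            ok = edge_satisfied(hit, pb.fs_aa, pa.fs_aa, pb.direction, pa.direction,
                                min_border, max_sep)
        if ok:
            graph.add_edge(a, b)
    return graph


def find_clusters(
    graph: nx.Graph, fs_proteins: dict[str, FsProtein] | None = None
) -> tuple[list[Cluster], list[str]]:
    """Partition nodes into clusters (size >= 2) and singletons.

    Cluster ids are assigned deterministically by the smallest member id.
    The same-direction invariant (guaranteed by the edge rule) is asserted
    post hoc when fs-proteins are supplied.
    """
    clusters = []
    singletons = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    for idx, comp in enumerate(c for c in components if len(c) >= 2):
        direction = 0
        if fs_proteins is not None:
            directions = {fs_proteins[m].direction for m in comp}
            assert len(directions) == 1, f"mixed directions in component {comp}"
            direction = directions.pop()
        clusters.append(Cluster(id=f"C{idx + 1:04d}", members=tuple(comp),
                                direction=direction))
    for comp in components:
        if len(comp) == 1:
            singletons.append(comp[0])
    return clusters, sorted(singletons)


def name_cluster(
    cluster: Cluster,
    domains: dict[str, list[tuple[str, int, int, float]]],
    reference_hits: dict[str, str] | None = None,
) -> str:
    """Name a cluster from the domains shared by a majority of its members.

    A domain present in more than 50% of member fs-proteins contributes its
    name; multi-domain clusters join names with '/', more frequent domains
    first.  Falls back to reference-hit function transfer (majority target
    of member reference hits), then to the cluster id.
    """
    counts: Counter[str] = Counter()
    for member in cluster.members:
        for name in {d[0] for d in domains.get(member, [])}:
            counts[name] += 1
    majority = [
        (n, c) for n, c in counts.items() if c > 0.5 * cluster.size
    ]
    if majority:
        majority.sort(key=lambda nc: (-nc[1], nc[0]))
        return "/".join(n for n, _ in majority)
    if reference_hits:
        targets = Counter(
            reference_hits[m] for m in cluster.members if m in reference_hits
        )
        if targets and targets.most_common(1)[0][1] > 0.5 * cluster.size:
            return targets.most_common(1)[0][0]
    return cluster.id
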