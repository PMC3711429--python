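"""Edge criteria, connected components vs an independent oracle, naming."""

import numpy as np
import pytest

from fsgene.clustering import (
    Cluster,
    build_fs_graph,
    edge_satisfied,
    find_clusters,
    name_cluster,
)
from fsgene.homology import AlignmentHit
from fsgene.model import FsProtein


def ungapped_hit(a, b, qs, qe, ts, te, evalue=1e-60):
    assert qe - qs == te - ts
    return AlignmentHit(a, b, qs, qe, ts, te, 500.0, evalue, 95.0,
                        ((qs, qe),), ((ts, te),))


def protein(pid, fs_aa, direction, n=200):
    return FsProtein(pid, "", "K" * n, fs_aa, direction)


class TestEdgeCriteria:
    def test_same_position_same_direction_inside_block(self):
        hit = ungapped_hit("a", "b", 0, 200, 0, 200)
        assert edge_satisfied(hit, 80, 80, +1, +1)

    def test_opposite_directions_never_join(self):
        hit = ungapped_hit("a", "b", 0, 200, 0, 200)
        assert not edge_satisfied(hit, 80, 80, +1, -1)

    def test_separation_over_50_columns_rejected(self):
        hit = ungapped_hit("a", "b", 0, 200, 0, 200)
        assert not edge_satisfied(hit, 60, 115, +1, +1)  # delta 55
        assert edge_satisfied(hit, 60, 110, +1, +1)      # delta 50

    def test_border_margin_10aa(self):
        hit = ungapped_hit("a", "b", 50, 150, 50, 150)
        assert not edge_satisfied(hit, 55, 60, +1, +1)   # 5 aa from border
        assert edge_satisfied(hit, 60, 60, +1, +1)

    def test_gapped_hit_distance_in_alignment_columns(self):
        # block with a 10-column gap on the query side between segments
        hit = AlignmentHit(
            "a", "b", 0, 100, 0, 110, 500.0, 1e-60, 90.0,
            ((0, 50), (50, 100)), ((0, 50), (60, 110)),
        )
        # fs_a=45 -> col 45; fs_b=100 -> col 50 + 10 + 40 = 100: delta 55
        assert not edge_satisfied(hit, 45, 100, +1, +1)
        # fs_b=95 -> col 95: delta 50
        assert edge_satisfied(hit, 45, 95, +1, +1)


class TestComponents:
    def test_chain_is_transitive(self):
        proteins = {p: protein(p, 80, +1) for p in "abc"}
        hits = [
            ungapped_hit("a", "b", 0, 200, 0, 200),
            ungapped_hit("b", "c", 0, 200, 0, 200),
        ]
        clusters, singles = find_clusters(build_fs_graph(proteins, hits), proteins)
        assert len(clusters) == 1 and clusters[0].members == ("a", "b", "c")
        assert singles == []

    def test_no_edges_all_singletons(self):
        proteins = {f"p{i}": protein(f"p{i}", 80, +1) for i in range(5)}
        clusters, singles = find_clusters(build_fs_graph(proteins, {}), proteins)
        assert clusters == [] and len(singles) == 5

    @staticmethod
    def _bfs_components(nodes, edges):
        adjacency = {n: set() for n in nodes}
        for a, b in edges:
            adjacency[a].add(b)
            adjacency[b].add(a)
        seen, components = set(), []
        for start in nodes:
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                node = stack.pop()
                if node in comp:
                    continue
                comp.add(node)
                stack.extend(adjacency[node] - comp)
            seen |= comp
            components.append(frozenset(comp))
        return {c for c in components}

    def test_random_instances_match_bfs_oracle(self):
        """Components equal an independent BFS oracle on random hit sets."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            proteins = {
                f"p{i:03d}": protein(
                    f"p{i:03d}",
                    int(rng.integers(20, 180)),
                    int(rng.choice([-1, 1])),
                )
                for i in range(n)
            }
            ids = sorted(proteins)
            hits = []
            for _ in range(int(rng.integers(n, 4 * n))):
                a, b = rng.choice(n, size=2, replace=False)
                hits.append(ungapped_hit(ids[a], ids[b], 0, 200, 0, 200))
            graph = build_fs_graph(proteins, hits)
            clusters, singles = find_clusters(graph, proteins)
            # independent edge recomputation + BFS
            edges = set()
            for h in hits:
                pa, pb = proteins[h.query], proteins[h.target]
                if (
                    pa.direction == pb.direction
                    and 10 <= pa.fs_aa <= 190
                    and 10 <= pb.fs_aa <= 190
                    and abs(pa.fs_aa - pb.fs_aa) <= 50
                ):
                    edges.add((h.query, h.target))
            expected = self._bfs_components(ids, edges)
            got = {frozenset(c.members) for c in clusters} | {
                frozenset({s}) for s in singles
            }
            assert got == expected

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        proteins = {f"p{i}": protein(f"p{i}", 80, +1) for i in range(12)}
        hits = [
            ungapped_hit(f"p{a}", f"p{b}", 0, 200, 0, 200)
            for a, b in [(0, 3), (3, 7), (2, 5), (8, 9)]
        ]
        base, _ = find_clusters(build_fs_graph(proteins, hits), proteins)
        order = list(proteins)
        rng.shuffle(order)
        shuffled = {k: proteins[k] for k in order}
        permuted, _ = find_clusters(
            build_fs_graph(shuffled, hits[::-1]), shuffled
        )
        assert [c.members for c in base] == [c.members for c in permuted]

    def test_direction_uniformity_asserted(self, small_bundle):
        """Criterion (ii) makes every component direction-pure."""
        from fsgene.homology import all_against_all
        from fsgene.io import predictions_to_fs_genes
        from fsgene.model import build_fs_protein

        genes = predictions_to_fs_genes(small_bundle.predictions)
        proteins = {
            g.id: build_fs_protein(small_bundle.genomes[g.genome_id], g)
            for g in genes.values()
        }
        hits = all_against_all({k: p.aa for k, p in proteins.items()})
        clusters, _ = find_clusters(build_fs_graph(proteins, hits), proteins)
        assert clusters  # planted families must cluster
        for cluster in clusters:
            assert len({proteins[m].direction for m in cluster.members}) == 1


class TestNaming:
    def make_cluster(self, n=6):
        return Cluster("C1", tuple(f"m{i}" for i in range(n)), +1)

    def test_majority_domain_names_cluster(self):
        domains = {f"m{i}": [("HTH_Tnp_1", 0, 50, 1e-6)] for i in range(4)}
        assert name_cluster(self.make_cluster(), domains) == "HTH_Tnp_1"

    def test_exactly_half_is_not_a_majority(self):
        domains = {f"m{i}": [("Dom", 0, 50, 1e-6)] for i in range(3)}
        assert name_cluster(self.make_cluster(), domains) == "C1"

    def test_multidomain_names_ordered_by_frequency(self):
        domains = {}
        for i in range(6):
            entries = [("B", 0, 50, 1e-6)] if i < 4 else []
            if i < 5:
                entries.append(("A", 60, 100, 1e-6))
            domains[f"m{i}"] = entries
        # A in 5/6, B in 4/6 -> "A/B"
        assert name_cluster(self.make_cluster(), domains) == "A/B"

    def test_reference_transfer_fallback(self):
        refs = {f"m{i}": "dnaX_homolog" for i in range(5)}
        assert name_cluster(self.make_cluster(), {}, refs) == "dnaX_homolog"
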