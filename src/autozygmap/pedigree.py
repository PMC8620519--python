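"""Pedigree ancestry analysis on the sire/dam graph.

A pedigree is a directed acyclic graph with an edge from each individual to
its (at most one) sire and dam.  Three questions matter for recessive-trait
mapping: which ancestors are shared by all cases, at how many generations'
distance (a generation = one parent edge, so a parent sits at depth 1), and
how much loop structure (inbreeding) the case families carry.  Multiple
paths through inbreeding loops yield multiple path lengths to the same
ancestor; depth *sets* are therefore tracked, not single numbers.

Unknown parents truncate paths silently — real pedigrees are ragged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import networkx as nx


@dataclass
class Individual:
    id: str
    sire: str | None = None
    dam: str | None = None
    phenotype: str = "unknown"


@dataclass(frozen=True)
class AncestorHit:
    """A common ancestor of a case set with its generation-distance range."""

    ancestor: str
    per_case_depths: dict
    gen_min: int
    gen_max: int


class Pedigree:
    """Directed sire/dam graph with depth and loop queries."""

    def __init__(self):
        self._ind: dict[str, Individual] = {}
        self._cache_token = 0

    # -- construction -------------------------------------------------------
    def add(self, iid: str, sire: str | None = None, dam: str | None = None,
            phenotype: str = "unknown") -> None:
        if iid in self._ind:
            raise ValueError(f"duplicate individual {iid}")
        self._ind[iid] = Individual(iid, sire, dam, phenotype)
        self._cache_token += 1

    def validate(self) -> None:
        """Check acyclicity; implicit parents get founder stubs."""
        for ind in list(self._ind.values()):
            for p in (ind.sire, ind.dam):
                if p is not None and p not in self._ind:
                    self._ind[p] = Individual(p)
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValueError(f"pedigree contains a cycle: {cyc}")

    def graph(self) -> nx.DiGraph:
        """child → parent edge graph."""
        g = nx.DiGraph()
        g.add_nodes_from(self._ind)
        for ind in self._ind.values():
            for p in (ind.sire, ind.dam):
                if p is not None:
                    g.add_edge(ind.id, p)
        return g

    def __contains__(self, iid: str) -> bool:
        return iid in self._ind

    def __getitem__(self, iid: str) -> Individual:
        return self._ind[iid]

    def individuals(self) -> list[str]:
        return list(self._ind)

    def parents(self, iid: str) -> list[str]:
        ind = self._ind[iid]
        return [p for p in (ind.sire, ind.dam) if p is not None]

    def affected(self) -> list[str]:
        return [i for i, ind in self._ind.items() if ind.phenotype == "affected"]

    # -- ancestry -----------------------------------------------------------
    def ancestors_with_depths(self, iid: str) -> dict[str, frozenset[int]]:
        """Every ancestor of ``iid`` with the set of distinct path lengths.

        Computed by dynamic programming over the parent DAG: the depth set to
        an ancestor A through parent P is 1 + each depth from P to A, plus
        {1} when A is a parent itself.
        """
        if iid not in self._ind:
            raise KeyError(f"unknown individual {iid}")
        memo: dict[str, dict[str, set[int]]] = {}
        for node in self._topo_order():
            depths: dict[str, set[int]] = {}
            for p in self.parents(node):
                depths.setdefault(p, set()).add(1)
                for anc, dset in memo[p].items():
                    depths.setdefault(anc, set()).update(d + 1 for d in dset)
            memo[node] = depths
        return {a: frozenset(d) for a, d in memo[iid].items()}

    def _topo_order(self) -> list[str]:
        # parents before children
        return list(reversed(list(nx.topological_sort(self.graph()))))

    def path_counts(self, iid: str) -> dict[str, int]:
        """Number of distinct parent paths from ``iid`` to each ancestor."""
        if iid not in self._ind:
            raise KeyError(f"unknown individual {iid}")
        memo: dict[str, dict[str, int]] = {}
        for node in self._topo_order():
            counts: dict[str, int] = {}
            for p in self.parents(node):
                counts[p] = counts.get(p, 0) + 1
                for anc, n in memo[p].items():
                    counts[anc] = counts.get(anc, 0) + n
            memo[node] = counts
        return memo[iid]

    def common_ancestors(self, case_ids: Sequence[str]) -> list[AncestorHit]:
        """Ancestors shared by every case, with the generation range taken
        over all paths of all cases; sorted by (max depth, min depth, id)."""
        if len(case_ids) < 2:
            raise ValueError("need at least 2 cases")
        per_case = {c: self.ancestors_with_depths(c) for c in case_ids}
        shared = set.intersection(*(set(d) for d in per_case.values()))
        hits = []
        for anc in shared:
            depths = {c: per_case[c][anc] for c in case_ids}
            alldepths = [d for ds in depths.values() for d in ds]
            hits.append(AncestorHit(ancestor=anc, per_case_depths=depths,
                                    gen_min=min(alldepths), gen_max=max(alldepths)))
        return sorted(hits, key=lambda h: (h.gen_max, h.gen_min, h.ancestor))

    def inbreeding_loops(self, iid: str) -> int:
        """Number of ancestors reachable from ``iid`` by ≥ 2 distinct paths."""
        return sum(1 for n in self.path_counts(iid).values() if n >= 2)

    def kinship(self, a: str, b: str) -> float:
        """Pedigree kinship coefficient (recursive tabular method)."""
        order = {iid: i for i, iid in enumerate(self._topo_order())}

        @lru_cache(maxsize=None)
        def f(x: str, y: str) -> float:
            if order[x] > order[y]:
                x, y = y, x
            if x == y:
                s, d = self._ind[x].sire, self._ind[x].dam
                return 0.5 * (1 + (f(s, d) if s and d else 0.0))
            # y is not an ancestor-ordered-before x; recurse through y's parents
            s, d = self._ind[y].sire, self._ind[y].dam
            return 0.5 * ((f(x, s) if s else 0.0) + (f(x, d) if d else 0.0))

        return f(a, b)

    def inbreeding_coefficient(self, iid: str) -> float:
        """Wright's F: kinship of the parents (0 for unknown parents)."""
        ind = self._ind[iid]
        if ind.sire is None or ind.dam is None:
            return 0.0
        return self.kinship(ind.sire, ind.dam)

    # -- export -------------------------------------------------------------
    def to_dot(self, case_ids: Iterable[str] | None = None) -> str:
        """DOT text of the ancestry subgraph of the given cases (or all)."""
        if case_ids:
            keep = set(case_ids)
            for c in case_ids:
                keep.update(self.ancestors_with_depths(c))
        else:
            keep = set(self._ind)
        lines = ["digraph pedigree {", "  rankdir=BT;"]
        for iid in sorted(keep):
            shape = "box" if self._ind[iid].phenotype == "affected" else "ellipse"
            lines.append(f'  "{iid}" [shape={shape}];')
        for iid in sorted(keep):
            for p in self.parents(iid):
                if p in keep:
                    lines.append(f'  "{iid}" -> "{p}";')
        lines.append("}")
        return "\n".join(lines)
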