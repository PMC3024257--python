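"""Subset hierarchy of modules.

Modules are organized into a DAG whose edges are the transitive reduction of
the strict-subset relation on gene membership; modules with identical gene
sets collapse into a single node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .isa_core import TranscriptionModule


@dataclass
class HierarchyDAG:
    """``graph`` nodes are canonical node keys with attributes
    ``module_ids`` (modules sharing that gene set) and ``size`` (gene count);
    edges point from strict subsets to strict supersets and form the
    transitive reduction."""

    graph: nx.DiGraph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def module_count(self, node) -> int:
        return len(self.graph.nodes[node]["module_ids"])

    def to_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("subset\tsuperset\tsubset_size\tsuperset_size\n")
            for a, b in sorted(self.graph.edges):
                fh.write(
                    f"{a}\t{b}\t{self.graph.nodes[a]['size']}\t"
                    f"{self.graph.nodes[b]['size']}\n"
                )

    def to_dot(
        self, path: str | Path, annotations: Mapping[str, Mapping[str, bool]] | None = None
    ) -> None:
        """DOT export; ``annotations`` optionally maps node -> flag dict
        (e.g. contains-hemizygous, replicated, extracellular-enriched)."""
        lines = ["digraph hierarchy {", "  rankdir=BT;"]
        for node, data in sorted(self.graph.nodes(data=True)):
            label = f"{'+'.join(data['module_ids'])}\\n{data['size']} genes"
            if annotations and node in annotations:
                flags = ",".join(k for k, v in annotations[node].items() if v)
                if flags:
                    label += f"\\n[{flags}]"
            lines.append(f'  "{node}" [label="{label}"];')
        for a, b in sorted(self.graph.edges):
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")


def build_hierarchy(modules: Sequence[TranscriptionModule]) -> HierarchyDAG:
    """Build the subset-relation DAG over module gene sets (nonzero scores).

    Modules with identical gene sets are merged into one node; the stored
    edge set is the unique transitive reduction of the strict-subset
    relation."""
    by_set: dict[frozenset, list[str]] = {}
    for module in modules:
        genes = module.gene_set
        if not genes:
            raise ValueError(f"module {module.id} has an empty gene set")
        by_set.setdefault(genes, []).append(module.id)

    graph = nx.DiGraph()
    node_keys = {}
    for genes, ids in by_set.items():
        key = sorted(ids)[0]
        node_keys[genes] = key
        graph.add_node(key, module_ids=tuple(sorted(ids)), size=len(genes))
    sets = list(by_set)
    for a in sets:
        for b in sets:
            if a is not b and a < b:
                graph.add_edge(node_keys[a], node_keys[b])
    reduced = nx.transitive_reduction(graph)
    for node in reduced.nodes:
        reduced.nodes[node].update(graph.nodes[node])
    return HierarchyDAG(reduced)


def components(dag: HierarchyDAG, min_size: int = 2) -> list[tuple[str, int]]:
    """Weakly connected components with at least ``min_size`` modules,
    returned as (component id, module count) sorted by count descending.

    The component id is its lexicographically smallest node key."""
    out = []
    for comp in nx.weakly_connected_components(dag.graph):
        count = sum(dag.module_count(node) for node in comp)
        if count >= min_size:
            out.append((min(comp), count))
    return sorted(out, key=lambda item: (-item[1], item[0]))
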