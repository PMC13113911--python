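"""Per-residue chirality field and the residue graph export.

The field attaches a local chirality vector [LTA_i, AES_i] to every
residue along the backbone (the fiber-bundle view of distributed
chirality); the residue graph carries those vectors as node weights with
edges from C-alpha proximity and chain adjacency.  Both are export
surfaces — spectral or topological analysis of the graph is out of scope.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .atomic_chirality import per_residue_field
from .structure_io import Structure


@dataclass
class ChiralityField:
    """Ordered per-residue entries (chain_id, residue_index, lta_i, aes_i).

    Residues without qualifying tetrahedra carry NaN for lta_i.
    """

    entries: list

    def __len__(self):
        return len(self.entries)

    def aes_gradient(self) -> list:
        """Forward finite difference of AES_i along the sequence (last
        entry gets NaN)."""
        grads = []
        for k in range(len(self.entries)):
            if (k + 1 < len(self.entries)
                    and self.entries[k][0] == self.entries[k + 1][0]):
                grads.append(self.entries[k + 1][3] - self.entries[k][3])
            else:
                grads.append(float("nan"))
        return grads

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["chain", "residue_index", "lta_i", "aes_i"])
            for chain, idx, lta, aes in self.entries:
                w.writerow([chain, idx, lta, aes])


@dataclass
class ResidueGraph:
    nodes: list        # (chain_id, residue_index, lta_i, aes_i)
    edges: list        # ((chain_a, res_a), (chain_b, res_b), distance)

    def to_files(self, node_path, edge_path) -> None:
        with open(node_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["chain", "residue_index", "lta_i", "aes_i"])
            w.writerows(self.nodes)
        with open(edge_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["res_a", "res_b", "distance"])
            for a, b, d in self.edges:
                w.writerow([f"{a[0]}:{a[1]}", f"{b[0]}:{b[1]}", d])


def build_field(structure: Structure, **kwargs) -> ChiralityField:
    """Per-residue [LTA_i, AES_i] field (one entry per residue, in
    chain/residue order)."""
    return ChiralityField(per_residue_field(structure, **kwargs))


def build_graph(structure: Structure, field: ChiralityField | None = None,
                edge_cutoff: float = 8.0) -> ResidueGraph:
    """Residue graph with chirality node weights.

    Edge iff the two residues' C-alpha atoms lie within ``edge_cutoff``
    (by default 8 A) or the residues are chain-adjacent; undirected, no
    self-edges.  Residues without a C-alpha only get adjacency edges.
    """
    if field is None:
        field = build_field(structure)
    nodes = list(field.entries)
    node_keys = [(chain, idx) for chain, idx, _, _ in nodes]
    key_set = set(node_keys)

    ca = {}
    for atom in structure.atoms:
        if atom.name.strip() == "CA" and atom.element == "C":
            ca.setdefault((atom.chain_id, atom.residue_index), atom.coords)

    edges = {}
    keys_with_ca = [k for k in node_keys if k in ca]
    for i, ka in enumerate(keys_with_ca):
        for kb in keys_with_ca[i + 1:]:
            if ka[0] != kb[0] and edge_cutoff <= 0:
                continue
            d = float(np.linalg.norm(ca[ka] - ca[kb]))
            if d <= edge_cutoff:
                edges[(ka, kb)] = d
    # chain adjacency always connects sequence neighbors
    for chain, idx in node_keys:
        nxt = (chain, idx + 1)
        if nxt in key_set:
            key = ((chain, idx), nxt)
            if key not in edges:
                if (chain, idx) in ca and nxt in ca:
                    d = float(np.linalg.norm(ca[(chain, idx)] - ca[nxt]))
                else:
                    d = math.nan
                edges[key] = d
    edge_list = [(a, b, d) for (a, b), d in sorted(edges.items())]
    return ResidueGraph(nodes, edge_list)
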