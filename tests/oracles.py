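"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's own code paths: alignment
scores are found by exhaustive enumeration of alignment columns, and
substructure/MCS results by networkx monomorphism search over element
graphs.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import networkx as nx
from networkx.algorithms import isomorphism
from rdkit import Chem


def exhaustive_local_alignment(
    a: Sequence[str],
    b: Sequence[str],
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -2,
    gap_extend: int = -1,
) -> int:
    """Best local-alignment score by exhaustive enumeration of all column
    sequences (match/mismatch, gap-in-a, gap-in-b) from every start pair."""

    def best_from(i: int, j: int, prev: str) -> int:
        options = [0]
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best_from(i + 1, j + 1, "M"))
        if i < len(a):
            g = gap_extend if prev == "X" else gap_open
            options.append(g + best_from(i + 1, j, "X"))
        if j < len(b):
            g = gap_extend if prev == "Y" else gap_open
            options.append(g + best_from(i, j + 1, "Y"))
        return max(options)

    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, best_from(i, j, "start"))
    return best


def mol_to_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            element=atom.GetSymbol(),
            aromatic=atom.GetIsAromatic(),
        )
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            order=str(bond.GetBondType()),
        )
    return g


def _node_match(n1, n2):
    return n1["element"] == n2["element"] and n1["aromatic"] == n2["aromatic"]


def _edge_match(e1, e2):
    return e1["order"] == e2["order"]


def count_substructure_matches(target_smiles: str, pattern_smiles: str) -> int:
    """Distinct atom sets of the target matched by the pattern (element +
    bond-order monomorphism)."""
    target = mol_to_graph(Chem.MolFromSmiles(target_smiles))
    pattern = mol_to_graph(Chem.MolFromSmiles(pattern_smiles))
    gm = isomorphism.GraphMatcher(
        target, pattern, node_match=_node_match, edge_match=_edge_match
    )
    return len({frozenset(m.keys()) for m in gm.subgraph_monomorphisms_iter()})


def exhaustive_mcs(query_smiles: str, target_smiles: str) -> tuple[int, int]:
    """(atoms, bonds) of the maximum connected common subgraph, by exhaustive
    enumeration of connected query-atom subsets.  Intended for small acyclic
    molecules, where a connected node subset determines its edge set."""
    qmol = Chem.MolFromSmiles(query_smiles)
    query = mol_to_graph(qmol)
    target = mol_to_graph(Chem.MolFromSmiles(target_smiles))
    best = (0, 0)
    nodes = list(query.nodes)
    for size in range(len(nodes), 0, -1):
        if size + (size - 1) <= sum(best):
            break
        for subset in combinations(nodes, size):
            sub = query.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            gm = isomorphism.GraphMatcher(
                target, sub, node_match=_node_match, edge_match=_edge_match
            )
            if any(True for _ in gm.subgraph_monomorphisms_iter()):
                score = (sub.number_of_nodes(), sub.number_of_edges())
                if sum(score) > sum(best):
                    best = score
    return best


def confusion_matrix_metrics(y_true, y_pred, labels):
    """Per-label precision/recall/F1 tallied directly from raw counts."""
    out = {}
    for lab in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p == lab)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != lab and p == lab)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p != lab)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[lab] = {"precision": prec, "recall": rec, "f1": f1,
                    "support": sum(1 for t in y_true if t == lab)}
    return out
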