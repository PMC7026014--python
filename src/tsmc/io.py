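"""Readers, writers and run reporting.

Interchange formats: CSV (one observation per row for mixture data; bridge
diagnostics), strict FASTA (equal-length A/C/G/T sequences), Newick (trees
with branch lengths in coalescent units; consensus supports as internal node
labels) and JSON (per-model evidence, configuration echo).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import dendropy

from .coalescent import Alignment, CoalescentState
from .smc_core import BridgeReport

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_mixture_csv",
    "write_mixture_csv",
    "write_newick",
    "newick_string",
    "read_newick",
    "write_diagnostics_csv",
    "write_run_json",
]


def read_fasta(path, mask_n: bool = False) -> Alignment:
    """Strict FASTA reader: equal lengths, A/C/G/T only, unique labels.

    ``mask_n=True`` replaces N/ambiguity symbols by 'A' instead of rejecting
    them (a crude mask; positions are noted nowhere, so use sparingly).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    labels = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    if mask_n:
        allowed = set("ACGT")
        seqs = ["".join(c if c in allowed else "A" for c in s) for s in seqs]
    return Alignment(seqs, labels)


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=lab, description="")
        for lab, s in zip(alignment.labels, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_mixture_csv(path) -> np.ndarray:
    """One observation per row; a single non-numeric header row is allowed."""
    first = pd.read_csv(path, header=None, nrows=1)
    try:
        float(first.iloc[0, 0])
        header = None
    except (TypeError, ValueError):
        header = 0
    frame = pd.read_csv(path, header=header)
    y = pd.to_numeric(frame.iloc[:, 0], errors="raise").to_numpy(dtype=float)
    if y.size == 0:
        raise ValueError(f"no observations in {path}")
    return y


def write_mixture_csv(y: np.ndarray, path) -> None:
    pd.DataFrame({"value": np.asarray(y, dtype=float)}).to_csv(path, index=False)


def newick_string(state: CoalescentState) -> str:
    """Newick with branch lengths in coalescent time units.

    theta is not part of the tree and is reported separately.
    """
    n = state.n_leaves
    if n == 1:
        return f"{state.labels[0]}:0.0;"

    def render(node: int, parent_height: float) -> str:
        h = state.node_height(node)
        branch = parent_height - h
        if node < n:
            return f"{state.labels[node]}:{branch:.12g}"
        a, b = (int(c) for c in state.children[node - n])
        return f"({render(a, h)},{render(b, h)}):{branch:.12g}"

    root = state.root
    rh = state.node_height(root)
    a, b = (int(c) for c in state.children[root - n])
    return f"({render(a, rh)},{render(b, rh)});"


def write_newick(state: CoalescentState, path) -> None:
    Path(path).write_text(newick_string(state) + "\n")


def read_newick(path_or_string, theta: float = 1.0) -> CoalescentState:
    """Parse a rooted ultrametric Newick tree into a genealogy state."""
    s = str(path_or_string)
    if "(" in s and ";" in s:
        tree = dendropy.Tree.get(data=s, schema="newick")
    else:
        tree = dendropy.Tree.get(path=s, schema="newick")
    # node depths from the root, then heights = max depth - depth
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    leaves = [n for n in tree.leaf_node_iter()]
    max_depth = max(depth[n] for n in leaves)
    labels = [n.taxon.label.replace(" ", "_") for n in leaves]
    leaf_id = {id(n): i for i, n in enumerate(leaves)}
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    n = len(labels)
    children = np.zeros((n - 1, 2), dtype=int)
    heights = np.zeros(n - 1)
    internal_id = {id(node): n + r for r, node in enumerate(internals)}
    for r, node in enumerate(internals):
        ch = node.child_nodes()
        if len(ch) != 2:
            raise ValueError("genealogies must be strictly binary")
        ids = [
            leaf_id[id(c)] if c.is_leaf() else internal_id[id(c)] for c in ch
        ]
        children[r] = ids
        heights[r] = max_depth - depth[node]
    return CoalescentState(labels, children, heights, theta)


def write_diagnostics_csv(reports: Sequence[BridgeReport], path, log_z0: float = 0.0) -> None:
    """Per-annealing-step diagnostics for a whole run, one CSV row per step."""
    rows: list[dict] = []
    cum = log_z0
    for rep in reports:
        rows.extend(rep.rows(cumulative_offset=cum))
        cum += rep.log_evidence_ratio
    pd.DataFrame(
        rows,
        columns=[
            "model_index",
            "step",
            "gamma",
            "ess",
            "cess",
            "resampled",
            "mean_acceptance",
            "cumulative_log_evidence",
        ],
    ).to_csv(path, index=False)


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, float) and (math.isnan(value) or math.isinf(value)):
        return str(value)
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def write_run_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
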