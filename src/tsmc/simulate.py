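"""Synthetic-data generators: Kingman genealogies, Jukes-Cantor sequence
evolution along them, and Gaussian-mixture draws.

These generators emulate exactly the models the samplers target, so every
pipeline stage can be exercised offline: coalescent trees with Exp(C(a,2))
inter-coalescence times and uniform pair merges, sequences evolved site-wise
with the exact JC transition matrix (theta/2 expected substitutions per site
per unit branch time), and i.i.d. mixture observations.
"""

from __future__ import annotations

import numpy as np

from .coalescent import Alignment, CoalescentState
from .mixture import MixtureDataset, MixtureParams

__all__ = [
    "simulate_coalescent_tree",
    "evolve_sequences",
    "simulate_mixture_data",
]

_BASES = "ACGT"


def simulate_coalescent_tree(
    n: int,
    rng: np.random.Generator,
    theta: float = 1.0,
    labels: list[str] | None = None,
) -> CoalescentState:
    """Simulate a Kingman coalescent genealogy over n labelled leaves.

    While a lineages remain, the next coalescence happens after an
    Exp(C(a,2)) waiting time and merges a uniformly chosen pair.
    """
    if n < 2:
        raise ValueError("need at least two leaves")
    if labels is None:
        labels = [f"seq{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("need one label per leaf")
    lineages = list(range(n))
    children = np.zeros((n - 1, 2), dtype=int)
    heights = np.zeros(n - 1)
    height = 0.0
    for r in range(n - 1):
        a = len(lineages)
        height += rng.exponential(1.0 / (a * (a - 1) / 2.0))
        i, j = rng.choice(a, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        children[r] = [lineages[i], lineages[j]]
        heights[r] = height
        lineages[i] = n + r
        lineages.pop(j)
    return CoalescentState(list(labels), children, heights, theta)


def evolve_sequences(
    tree: CoalescentState,
    theta: float,
    n_sites: int,
    rng: np.random.Generator,
) -> Alignment:
    """Evolve an alignment down a genealogy under Jukes-Cantor.

    The root sequence is uniform on {A,C,G,T}; on a branch of duration l a
    site keeps its state with probability exp(-4 d / 3) (d = theta l / 2
    expected substitutions) and otherwise redraws uniformly, which reproduces
    the JC transition matrix exactly.
    """
    if theta <= 0 or n_sites < 1:
        raise ValueError("theta must be positive and n_sites >= 1")
    n = tree.n_leaves
    seqs: dict[int, np.ndarray] = {}
    root = tree.root
    seqs[root] = rng.integers(0, 4, size=n_sites)
    order = np.argsort(tree.heights)[::-1]  # root first, then downwards
    for r in order:
        parent_seq = seqs[n + r]
        for c in tree.children[r]:
            c = int(c)
            dur = tree.heights[r] - tree.node_height(c)
            d = 0.5 * theta * dur
            keep = rng.uniform(size=n_sites) < np.exp(-4.0 * d / 3.0)
            child_seq = np.where(keep, parent_seq, rng.integers(0, 4, size=n_sites))
            seqs[c] = child_seq
    sequences = ["".join(_BASES[b] for b in seqs[i]) for i in range(n)]
    return Alignment(sequences, list(tree.labels))


def simulate_mixture_data(
    params: MixtureParams, n: int, rng: np.random.Generator
) -> MixtureDataset:
    """Draw n i.i.d. observations from a Gaussian mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    comp = rng.choice(params.n_components, size=n, p=params.weights / params.weights.sum())
    y = rng.normal(params.means[comp], 1.0 / np.sqrt(params.precisions[comp]))
    return MixtureDataset.from_observations(y)
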