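"""Online Bayesian inference of coalescent genealogies from DNA sequences.

The model: a Kingman coalescent prior on the genealogy of t sampled
sequences (while a lineages remain they coalesce at rate C(a,2); time is in
coalescent units), a Jukes-Cantor substitution model for the alignment
(theta/2 expected substitutions per site per unit time on each branch,
uniform root frequencies), and a Gamma(1, 5) prior on the scaled mutation
parameter theta.

Sequences are introduced one at a time.  The transformation that carries a
particle from the t-leaf posterior to the (t+1)-leaf posterior attaches the
new leaf to a proposed lineage (probability guided by the SNP distance
between the new sequence and each existing leaf) at a proposed height (a
Laplace approximation of the pairwise likelihood on log-height, or a plain
Exp(1)).  The proposal density in the weight update is marginalised over
every lineage whose choice could have produced the realised attachment (the
inverse image of the transformation), which is the set of leaves descending
from the new leaf's sibling subtree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .smc_core import AnnealConfig, BridgeReport, ModelBridge, ParticleSystem, run_bridge

__all__ = [
    "Alignment",
    "CoalescentState",
    "InvalidTreeError",
    "coalescent_log_prior",
    "log_theta_prior",
    "jc_log_likelihood",
    "lineage_proposal",
    "height_proposal",
    "HeightProposal",
    "add_leaf",
    "remove_leaf",
    "inverse_image_lineages",
    "LeafAdditionBridge",
    "leaf_addition_bridge",
    "make_coalescent_kernel",
    "sequence_ordering",
    "majority_consensus",
    "ConsensusTree",
    "snp_distance_matrix",
    "weighted_quantile",
    "CoalescentRunResult",
    "tsmc_coalescent_evidences",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class InvalidTreeError(ValueError):
    """Raised for trees that violate the ultrametric height ordering."""


def _small_lse(values) -> float:
    """log-sum-exp of a small python list (hot path, avoids array overhead)."""
    m = max(values)
    if m == -np.inf:
        return -np.inf
    return m + math.log(sum(math.exp(v - m) for v in values))


# ---------------------------------------------------------------------------
# alignment


class Alignment:
    """t equal-length DNA sequences over {A, C, G, T} with labels."""

    def __init__(self, sequences: Sequence[str], labels: Sequence[str]) -> None:
        sequences = [s.upper() for s in sequences]
        labels = list(labels)
        if len(sequences) != len(labels):
            raise ValueError("one label per sequence required")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate sequence labels")
        if sequences:
            n = len(sequences[0])
            for lab, s in zip(labels, sequences):
                if len(s) != n:
                    raise ValueError(
                        f"sequence {lab!r} has length {len(s)}, expected {n} "
                        f"(like {labels[0]!r})"
                    )
                bad = set(s) - set(_BASES)
                if bad:
                    raise ValueError(f"sequence {lab!r} contains non-ACGT symbols {sorted(bad)}")
        self.sequences = sequences
        self.labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}
        self._encoded = (
            np.array([[_BASE_INDEX[c] for c in s] for s in sequences], dtype=np.int8)
            if sequences
            else np.zeros((0, 0), dtype=np.int8)
        )
        self._pattern_cache: dict[tuple[str, ...], tuple[np.ndarray, np.ndarray]] = {}

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_sites(self) -> int:
        return self._encoded.shape[1]

    def encoded(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Integer-coded matrix (rows in the given label order)."""
        if labels is None:
            return self._encoded
        rows = [self._index[lab] for lab in labels]
        return self._encoded[rows]

    def site_patterns(self, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Unique site columns and their counts for a subset of sequences.

        Cached per label subset: pattern compression leaves the likelihood
        bit-identical while collapsing repeated columns.
        """
        key = tuple(labels)
        hit = self._pattern_cache.get(key)
        if hit is None:
            enc = self.encoded(labels)
            patterns, counts = np.unique(enc, axis=1, return_counts=True)
            hit = (patterns, counts.astype(float))
            self._pattern_cache[key] = hit
        return hit

    def snp_distance(self, label_a: str, label_b: str) -> int:
        a = self._encoded[self._index[label_a]]
        b = self._encoded[self._index[label_b]]
        return int(np.sum(a != b))

    def subset(self, labels: Sequence[str]) -> "Alignment":
        return Alignment([self.sequences[self._index[lab]] for lab in labels], list(labels))


def snp_distance_matrix(alignment: Alignment) -> np.ndarray:
    enc = alignment.encoded()
    return np.sum(enc[:, None, :] != enc[None, :, :], axis=2).astype(int)


# ---------------------------------------------------------------------------
# genealogy state


@dataclass
class CoalescentState:
    """Rooted ultrametric genealogy over labelled leaves, plus theta.

    Leaves are node ids 0..n-1 (in ``labels`` order, all at height 0);
    internal node ``n + r`` is described by row r of ``children`` and
    ``heights[r]``.  Heights must be distinct and every parent higher than
    its children; the root is the highest node (its height is the TMRCA).
    """

    labels: list[str]
    children: np.ndarray
    heights: np.ndarray
    theta: float = 1.0

    def __post_init__(self) -> None:
        self.children = np.asarray(self.children, dtype=int).reshape(-1, 2)
        self.heights = np.asarray(self.heights, dtype=float).ravel()
        n = len(self.labels)
        if self.children.shape[0] != max(n - 1, 0) or len(self.heights) != max(n - 1, 0):
            raise ValueError("a binary tree over n leaves has exactly n-1 internal nodes")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.n_leaves + int(np.argmax(self.heights))

    def node_height(self, node: int) -> float:
        return 0.0 if node < self.n_leaves else float(self.heights[node - self.n_leaves])

    def parent_map(self) -> dict[int, int]:
        parents: dict[int, int] = {}
        n = self.n_leaves
        for r in range(self.children.shape[0]):
            for c in self.children[r]:
                parents[int(c)] = n + r
        return parents

    def leaves_under(self, node: int) -> list[str]:
        n = self.n_leaves
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(self.labels[v])
            else:
                stack.extend(int(c) for c in self.children[v - n])
        return out

    def sorted_heights(self) -> np.ndarray:
        """Coalescence heights in increasing order (last one is the TMRCA)."""
        return np.sort(self.heights)

    def is_valid(self) -> bool:
        n = self.n_leaves
        if n == 1:
            return True
        if np.any(self.heights <= 0) or len(np.unique(self.heights)) != n - 1:
            return False
        for r in range(n - 1):
            for c in self.children[r]:
                if self.node_height(int(c)) >= self.heights[r]:
                    return False
        # exactly one root: every node but one has a parent
        return len(self.parent_map()) == 2 * n - 2

    def copy(self) -> "CoalescentState":
        return CoalescentState(
            list(self.labels), self.children.copy(), self.heights.copy(), self.theta
        )


def _to_links(state: CoalescentState) -> tuple[dict[int, tuple[int, int]], dict[int, float]]:
    n = state.n_leaves
    children_of = {
        n + r: (int(state.children[r, 0]), int(state.children[r, 1]))
        for r in range(state.children.shape[0])
    }
    height_of = {v: state.node_height(v) for v in range(2 * n - 1)} if n >= 1 else {}
    return children_of, height_of


def _from_links(
    labels: list[str],
    children_of: dict,
    height_of: dict,
    theta: float,
    leaf_key: dict,
) -> CoalescentState:
    """Re-encode a linked tree (arbitrary node keys) into array form."""
    n = len(labels)
    internal_keys = list(children_of.keys())
    new_id = {leaf_key[lab]: i for i, lab in enumerate(labels)}
    for r, key in enumerate(internal_keys):
        new_id[key] = n + r
    children = np.zeros((n - 1, 2), dtype=int)
    heights = np.zeros(n - 1)
    for key in internal_keys:
        r = new_id[key] - n
        children[r] = [new_id[c] for c in children_of[key]]
        heights[r] = height_of[key]
    return CoalescentState(labels, children, heights, theta)


# ---------------------------------------------------------------------------
# prior and likelihood


def log_theta_prior(theta: float, shape: float = 1.0, rate: float = 5.0) -> float:
    """Gamma prior on the scaled mutation parameter (default Gamma(1, 5))."""
    if theta <= 0:
        return -np.inf
    return float(
        shape * math.log(rate)
        - math.lgamma(shape)
        + (shape - 1.0) * math.log(theta)
        - rate * theta
    )


def coalescent_log_posterior(
    state: CoalescentState,
    alignment: Alignment,
    theta_prior: tuple[float, float] = (1.0, 5.0),
) -> float:
    """Unnormalised log posterior: theta prior x coalescent prior x JC
    likelihood (-inf for invalid genealogies)."""
    lp = log_theta_prior(state.theta, *theta_prior)
    if lp == -np.inf or not _tree_ok(state):
        return -np.inf
    try:
        prior = coalescent_log_prior(state)
    except InvalidTreeError:
        return -np.inf
    return lp + prior + jc_log_likelihood(state, alignment)


def coalescent_log_prior(state: CoalescentState) -> float:
    """Kingman coalescent log density of the genealogy.

    With a lineages extant for a duration l^(a), the density of
    (topology, heights) under the uniform-pair-merge convention is
    exp(-sum_a C(a,2) l^(a)); the per-merge combinatorial factors cancel the
    exponential rates.  Returns 0 for a single leaf.
    """
    t = state.n_leaves
    if t == 1:
        return 0.0
    hs = state.sorted_heights()
    if hs[0] <= 0 or np.any(np.diff(hs) <= 0) or not _tree_ok(state):
        raise InvalidTreeError("coalescence heights must be positive and strictly ordered")
    total = 0.0
    prev = 0.0
    for k, h in enumerate(hs):
        a = t - k  # lineages extant during this interval
        total -= (a * (a - 1) / 2.0) * (h - prev)
        prev = h
    return total


def _jc_probs(expected_subs: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Jukes-Cantor (p_same, p_diff) at the given expected substitutions."""
    e = np.exp(-4.0 * np.asarray(expected_subs, dtype=float) / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def _tree_ok(state: CoalescentState) -> bool:
    """Cheap structural check: positive heights, every parent above its
    children (root uniqueness is preserved by all tree operations)."""
    n = state.n_leaves
    if n == 1:
        return True
    hs = state.heights
    if hs.min() <= 0:
        return False
    ch = state.children
    child_h = np.where(ch < n, 0.0, hs[np.maximum(ch - n, 0)])
    return bool(np.all(child_h < hs[:, None]))


def jc_log_likelihood(state: CoalescentState, alignment: Alignment) -> float:
    """Felsenstein pruning log likelihood under Jukes-Cantor.

    A branch of duration l carries (theta/2) * l expected substitutions per
    site; root frequencies are uniform.  Site patterns are compressed before
    pruning (bit-identical result).
    """
    if set(state.labels) - set(alignment.labels):
        raise ValueError("tree leaves missing from the alignment")
    n = state.n_leaves
    n_sites = alignment.n_sites
    if n == 1:
        return n_sites * math.log(0.25)
    if not _tree_ok(state):
        raise InvalidTreeError("invalid genealogy")
    patterns, counts = alignment.site_patterns(state.labels)
    p = patterns.shape[1]
    heights = state.heights
    children = state.children
    theta = state.theta
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(p)
    rows = np.arange(p)
    for r in np.argsort(heights):
        node_h = heights[r]
        part = None
        for c in children[r]:
            c = int(c)
            dur = node_h if c < n else node_h - heights[c - n]
            e = math.exp(-2.0 * theta * dur / 3.0)  # exp(-4d/3), d = theta*dur/2
            p_same, p_diff = 0.25 + 0.75 * e, 0.25 - 0.25 * e
            if c < n:
                res = np.full((p, 4), p_diff)
                res[rows, patterns[c]] = p_same
            else:
                child = partials.pop(c)
                tot = child.sum(axis=1, keepdims=True)
                res = p_diff * tot + (p_same - p_diff) * child
            part = res if part is None else part * res
        peak = part.max(axis=1)
        log_scale += np.log(peak)
        partials[n + r] = part / peak[:, None]
    root_part = partials[state.root]
    site_log_lik = np.log(0.25 * root_part.sum(axis=1)) + log_scale
    return float(counts @ site_log_lik)


# ---------------------------------------------------------------------------
# leaf attachment proposals


def lineage_proposal(
    alignment: Alignment,
    new_sequence: str,
    theta: float,
    power: float = 1.0,
) -> dict[str, float]:
    """SNP-guided lineage-choice probabilities for attaching a new sequence.

    The probability of choosing the lineage of leaf s is proportional to
    [(N theta / (t + N theta)) ^ M_s] ^ power, with M_s the SNP distance
    between the new sequence and leaf s; power 0 gives a uniform choice.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    t, n_sites = alignment.n_sequences, alignment.n_sites
    if len(new_sequence) != n_sites:
        raise ValueError("new sequence length does not match the alignment")
    new_enc = np.array([_BASE_INDEX[c] for c in new_sequence.upper()], dtype=np.int8)
    m = np.array([np.sum(alignment.encoded()[i] != new_enc) for i in range(t)], dtype=float)
    base = math.log(n_sites * theta) - math.log(t + n_sites * theta)
    logits = power * m * base
    probs = np.exp(logits - logsumexp(logits))
    probs /= probs.sum()
    return dict(zip(alignment.labels, probs))


@dataclass
class HeightProposal:
    """Attachment-height distribution: Exp(1) or a log-normal from a Laplace
    approximation of the pairwise Jukes-Cantor likelihood on log-height."""

    kind: str  # "exp1" | "laplace"
    log_mode: float = 0.0
    sigma: float = 1.0

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "exp1":
            return float(rng.exponential())
        return float(np.exp(self.log_mode + self.sigma * rng.standard_normal()))

    def log_density(self, h: float) -> float:
        if h <= 0:
            return -np.inf
        if self.kind == "exp1":
            return -h
        z = (math.log(h) - self.log_mode) / self.sigma
        return -0.5 * z**2 - math.log(h) - math.log(self.sigma) - 0.5 * math.log(2 * math.pi)

    @property
    def mode(self) -> float:
        if self.kind == "exp1":
            return 0.0
        return math.exp(self.log_mode)


def _pairwise_jc_loglik(m: int, n_sites: int, d: np.ndarray) -> np.ndarray:
    """Pairwise JC log likelihood of m mismatches in n sites at distance d
    (expected substitutions separating the pair)."""
    p_same, p_diff = _jc_probs(np.asarray(d, dtype=float))
    with np.errstate(divide="ignore"):
        return m * np.log(0.25 * p_diff * 4) + (n_sites - m) * np.log(p_same) + n_sites * math.log(
            0.25
        )


def laplace_height_params(m: int, n_sites: int, theta: float) -> tuple[float, float] | None:
    """(log-mode, sigma) of the log-normal Laplace fit, or None when the fit
    degenerates (no mismatches, or saturation at >= 3/4 mismatch fraction).

    Two sequences joined at height h are separated by expected substitutions
    d = theta * h, so the pairwise mismatch MLE d_hat = -(3/4) log(1 - 4p/3)
    gives the mode h_hat = d_hat / theta; the curvature on log-height is
    found by central differences at the mode.
    """
    if m <= 0 or m >= 0.75 * n_sites:
        return None
    p_hat = m / n_sites
    d_hat = -0.75 * math.log1p(-4.0 * p_hat / 3.0)
    log_mode = math.log(d_hat / theta)

    def obj(x: float) -> float:
        return float(_pairwise_jc_loglik(m, n_sites, theta * math.exp(x)))

    eps = 1e-4
    curv = (obj(log_mode + eps) - 2.0 * obj(log_mode) + obj(log_mode - eps)) / eps**2
    if curv >= 0:
        return None
    return log_mode, math.sqrt(-1.0 / curv)


def height_proposal(
    alignment: Alignment,
    new_sequence: str,
    chosen_leaf: str,
    theta: float,
    state: CoalescentState | None = None,
    kind: str = "laplace",
) -> HeightProposal:
    """Attachment-height proposal for joining the new sequence to a lineage.

    ``kind='exp1'`` returns Exp(1); ``kind='laplace'`` fits a log-normal by
    Laplace approximation of the pairwise JC likelihood of (chosen leaf, new
    sequence) as a function of log height, falling back to Exp(1) when the
    curvature is non-positive (e.g. identical sequences).
    """
    if kind == "exp1":
        return HeightProposal("exp1")
    if kind != "laplace":
        raise ValueError("kind must be 'laplace' or 'exp1'")
    new_enc = np.array([_BASE_INDEX[c] for c in new_sequence.upper()], dtype=np.int8)
    leaf_enc = alignment.encoded([chosen_leaf])[0]
    m = int(np.sum(leaf_enc != new_enc))
    # the pairwise likelihood depends on theta*h only, so the fit is done at
    # unit theta and the mode shifted (sigma on log-height is theta-free)
    params = laplace_height_params(m, alignment.n_sites, 1.0)
    if params is None:
        return HeightProposal("exp1")
    return HeightProposal("laplace", log_mode=params[0] - math.log(theta), sigma=params[1])


# ---------------------------------------------------------------------------
# leaf addition / removal


def add_leaf(
    state: CoalescentState, leaf_label: str, chosen_leaf: str, new_height: float
) -> CoalescentState:
    """Attach a new leaf to the chosen leaf's lineage at the given height.

    The new branch joins the lineage of ``chosen_leaf`` (its root-ward path)
    at ``new_height``; above the current root the new node becomes the root.
    An exact collision with an existing node height is perturbed by machine
    epsilon.
    """
    if new_height <= 0:
        raise ValueError("attachment height must be positive")
    if leaf_label in state.labels:
        raise ValueError(f"label {leaf_label!r} already in the tree")
    while np.any(np.isclose(state.heights, new_height, rtol=1e-15, atol=0.0)):
        new_height *= 1.0 + 1e-13
    children_of, height_of = _to_links(state)
    leaf_key = {lab: i for i, lab in enumerate(state.labels)}
    parents = state.parent_map()

    node = leaf_key[chosen_leaf]
    while node in parents and height_of[parents[node]] < new_height:
        node = parents[node]
    new_leaf = "NEW_LEAF"
    new_internal = "NEW_NODE"
    leaf_key = dict(leaf_key)
    leaf_key[leaf_label] = new_leaf
    height_of = dict(height_of)
    height_of[new_leaf] = 0.0
    height_of[new_internal] = new_height
    children_of = dict(children_of)
    if node in parents:
        par = parents[node]
        a, b = children_of[par]
        children_of[par] = (new_internal, b) if a == node else (a, new_internal)
    children_of[new_internal] = (node, new_leaf)
    return _from_links(
        state.labels + [leaf_label], children_of, height_of, state.theta, leaf_key
    )


def remove_leaf(state: CoalescentState, leaf_label: str) -> tuple[CoalescentState, float]:
    """Inverse of :func:`add_leaf`: detach a leaf and splice out its parent.

    Returns the reduced genealogy (label order preserved) and the height at
    which the removed branch joined the tree.
    """
    if state.n_leaves < 2:
        raise ValueError("cannot remove a leaf from a single-leaf tree")
    leaf = state.labels.index(leaf_label)
    parents = state.parent_map()
    children_of, height_of = _to_links(state)
    par = parents[leaf]
    attach_height = height_of[par]
    a, b = children_of[par]
    sibling = b if a == leaf else a
    children_of = {k: v for k, v in children_of.items() if k != par}
    if par in parents:
        gpar = parents[par]
        ga, gb = children_of[gpar]
        children_of[gpar] = (sibling, gb) if ga == par else (ga, sibling)
    new_labels = [lab for lab in state.labels if lab != leaf_label]
    leaf_key = {lab: i for i, lab in enumerate(state.labels) if lab != leaf_label}
    if not children_of:  # two-leaf tree collapses to a single leaf
        return (
            CoalescentState(new_labels, np.zeros((0, 2), dtype=int), np.zeros(0), state.theta),
            attach_height,
        )
    return _from_links(new_labels, children_of, height_of, state.theta, leaf_key), attach_height


def inverse_image_lineages(state_after: CoalescentState, new_leaf: str) -> set[str]:
    """Leaves whose lineage choice could have produced the realised branch.

    These are exactly the leaves of the sibling subtree of the new leaf:
    every lineage through the subdivided edge passes that subtree (all old
    leaves, when the attachment is above the old root).
    """
    leaf = state_after.labels.index(new_leaf)
    parents = state_after.parent_map()
    par = parents[leaf]
    a, b = state_after.children[par - state_after.n_leaves]
    sibling = int(b) if int(a) == leaf else int(a)
    return set(state_after.leaves_under(sibling))


# ---------------------------------------------------------------------------
# the leaf-addition bridge


class LeafAdditionBridge(ModelBridge):
    """Transition from t to t+1 sequences by attaching one new leaf.

    The proposal draws a lineage (SNP-guided, Eq.-style geometric weights
    raised to ``lineage_power``) and an attachment height; the proposal
    density at any (t+1)-leaf state marginalises the lineage over the inverse
    image set, so the weight update is

        pi_{t+1}(T', theta | y_{1:t+1})
        / [ pi_t(T, theta | y_{1:t}) * sum_{s in Lambda} chi_g(s) chi_h(h | s) ].

    The attachment is measure-preserving on existing coordinates (no
    Jacobian).  Both chi_g and chi_h depend on the particle's theta and are
    re-evaluated as MCMC moves theta during annealing.
    """

    route_mode = "marginal"

    def __init__(
        self,
        alignment: Alignment,
        current_labels: Sequence[str],
        new_label: str,
        lineage_power: float = 1.0,
        height_kind: str = "laplace",
        theta_prior: tuple[float, float] = (1.0, 5.0),
    ) -> None:
        self.alignment = alignment
        self.current_labels = list(current_labels)
        self.new_label = new_label
        self.lineage_power = float(lineage_power)
        self.height_kind = height_kind
        self.theta_prior = theta_prior
        self.n_sites = alignment.n_sites
        self.t = len(self.current_labels)
        new_enc = alignment.encoded([new_label])[0]
        cur_enc = alignment.encoded(self.current_labels)
        self.snp = {
            lab: int(np.sum(cur_enc[i] != new_enc)) for i, lab in enumerate(self.current_labels)
        }
        # Laplace parameters factorise as log-mode = log d_hat - log theta with
        # a theta-free sigma, so they are precomputed per candidate leaf.
        self._laplace: dict[str, tuple[float, float] | None] = {}
        if height_kind == "laplace":
            for lab in self.current_labels:
                self._laplace[lab] = laplace_height_params(self.snp[lab], self.n_sites, 1.0)

    # --- proposal pieces -------------------------------------------------

    def _log_chi_g(self, theta: float) -> dict[str, float]:
        base = math.log(self.n_sites * theta) - math.log(self.t + self.n_sites * theta)
        logits = [self.lineage_power * self.snp[lab] * base for lab in self.current_labels]
        logz = _small_lse(logits)
        return {lab: l - logz for lab, l in zip(self.current_labels, logits)}

    def _height_proposal(self, leaf: str, theta: float) -> HeightProposal:
        if self.height_kind == "exp1":
            return HeightProposal("exp1")
        params = self._laplace[leaf]
        if params is None:
            return HeightProposal("exp1")
        log_mode_unit, sigma = params
        return HeightProposal("laplace", log_mode=log_mode_unit - math.log(theta), sigma=sigma)

    # --- targets ----------------------------------------------------------

    def _log_pi(self, state: CoalescentState) -> float:
        lp = log_theta_prior(state.theta, *self.theta_prior)
        if lp == -np.inf or not _tree_ok(state):
            return -np.inf
        try:
            prior = coalescent_log_prior(state)
        except InvalidTreeError:
            return -np.inf
        return lp + prior + jc_log_likelihood(state, self.alignment)

    # --- ModelBridge interface -------------------------------------------

    def sample_transform(self, state: CoalescentState, rng: np.random.Generator):
        theta = state.theta
        log_g = self._log_chi_g(theta)
        labs = self.current_labels
        probs = np.exp([log_g[lab] for lab in labs])
        probs /= probs.sum()
        chosen = labs[int(rng.choice(self.t, p=probs))]
        h = self._height_proposal(chosen, theta).sample(rng)
        return add_leaf(state, self.new_label, chosen, h), chosen

    def log_target(self, state: CoalescentState, tag) -> float:
        return self._log_pi(state)

    def log_proposal(self, state: CoalescentState, tag) -> float:
        reduced, h_new = remove_leaf(state, self.new_label)
        lam = inverse_image_lineages(state, self.new_label)
        if not lam:
            raise AssertionError("inverse image of a leaf attachment cannot be empty")
        theta = state.theta
        log_g = self._log_chi_g(theta)
        terms = [
            log_g[s] + self._height_proposal(s, theta).log_density(h_new) for s in lam
        ]
        return self._log_pi(reduced) + _small_lse(terms)


def leaf_addition_bridge(
    t: int,
    alignment: Alignment,
    ordered_labels: Sequence[str] | None = None,
    lineage_power: float = 1.0,
    height_kind: str = "laplace",
    theta_prior: tuple[float, float] = (1.0, 5.0),
) -> LeafAdditionBridge:
    """Bridge adding sequence t+1 (1-based position in the given ordering)."""
    labels = list(ordered_labels) if ordered_labels is not None else list(alignment.labels)
    if not 1 <= t < len(labels):
        raise ValueError("t must satisfy 1 <= t < number of sequences")
    return LeafAdditionBridge(
        alignment,
        labels[:t],
        labels[t],
        lineage_power=lineage_power,
        height_kind=height_kind,
        theta_prior=theta_prior,
    )


# ---------------------------------------------------------------------------
# MCMC kernel


def make_coalescent_kernel(
    values: list[CoalescentState],
    weights: np.ndarray,
    enable_topology: bool = True,
) -> Callable:
    """One Metropolis sweep over a genealogy particle.

    Moves: (i) Gaussian random walk on each non-root coalescence height,
    truncated to (max child height, parent height); (ii) log-scale random
    walk on the root height (TMRCA); (iii) a nearest-neighbour interchange
    that swaps a child of a non-root internal node with that node's sibling,
    keeping all heights (skipped when topology moves are disabled);
    (iv) log-scale random walk on theta.  Proposal scales are adapted from
    the weighted particle population.
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    roots = np.array([v.sorted_heights()[-1] if v.n_leaves > 1 else 1.0 for v in values])
    log_thetas = np.log([v.theta for v in values])

    def _wstd(x: np.ndarray, floor: float) -> float:
        mean = float(np.sum(w * x))
        var = float(np.sum(w * (x - mean) ** 2))
        return max(math.sqrt(max(var, 0.0)), floor)

    mean_root = float(np.sum(w * roots))
    scale_h = max(0.5 * _wstd(roots, 0.0), 0.05 * max(mean_root, 1e-6), 1e-6)
    scale_root = max(2.38 * _wstd(np.log(np.maximum(roots, 1e-12)), 0.0), 0.05)
    scale_theta = max(2.38 * _wstd(log_thetas, 0.0), 0.05)

    def kernel(state: CoalescentState, gamma: float, log_density, rng: np.random.Generator):
        n_acc, n_prop = 0, 0
        cur = log_density(state)
        n = state.n_leaves
        if n >= 2:
            parents = state.parent_map()
            root_row = int(np.argmax(state.heights))
            for r in range(n - 1):
                n_prop += 1
                old = state.heights[r]
                child_max = max(state.node_height(int(c)) for c in state.children[r])
                if r == root_row:
                    delta = scale_root * rng.standard_normal()
                    new = old * math.exp(delta)
                    hastings = delta
                else:
                    par = parents[n + r]
                    upper = state.node_height(par)
                    new = old + scale_h * rng.standard_normal()
                    hastings = 0.0
                    if not child_max < new < upper:
                        continue
                if new <= child_max:
                    continue
                state.heights[r] = new
                prop = log_density(state)
                if math.log(rng.uniform()) < prop - cur + hastings:
                    cur = prop
                    n_acc += 1
                else:
                    state.heights[r] = old
        if enable_topology and n >= 3:
            n_prop += 1
            parents = state.parent_map()
            candidates = [
                r for r in range(n - 1) if (n + r) in parents
            ]  # non-root internal nodes
            r = candidates[int(rng.integers(len(candidates)))]
            pr = parents[n + r] - n
            a, b = (int(c) for c in state.children[pr])
            sibling = b if a == n + r else a
            side = int(rng.integers(2))
            child = int(state.children[r, side])
            # swap a child of this node with the node's sibling (NNI); the
            # sibling must fit below this node's height
            if state.node_height(sibling) < state.heights[r]:
                old_r = state.children[r].copy()
                old_p = state.children[pr].copy()
                sib_idx = 0 if int(old_p[0]) == sibling else 1
                state.children[r, side] = sibling
                state.children[pr, sib_idx] = child
                prop = log_density(state)
                if math.log(rng.uniform()) < prop - cur:
                    cur = prop
                    n_acc += 1
                else:
                    state.children[r] = old_r
                    state.children[pr] = old_p
        # theta
        n_prop += 1
        old_theta = state.theta
        delta = scale_theta * rng.standard_normal()
        state.theta = old_theta * math.exp(delta)
        prop = log_density(state)
        if math.log(rng.uniform()) < prop - cur + delta:
            cur = prop
            n_acc += 1
        else:
            state.theta = old_theta
        # joint ridge move: heights x c, theta / c (the likelihood depends on
        # theta x duration products, so this traverses the height-theta ridge)
        if n >= 2:
            n_prop += 1
            delta = 0.4 * rng.standard_normal()
            c = math.exp(delta)
            old_heights = state.heights.copy()
            old_theta = state.theta
            state.heights = state.heights * c
            state.theta = old_theta / c
            prop = log_density(state)
            if math.log(rng.uniform()) < prop - cur + (n - 2) * delta:
                cur = prop
                n_acc += 1
            else:
                state.heights = old_heights
                state.theta = old_theta
        return state, n_acc / n_prop

    return kernel


# ---------------------------------------------------------------------------
# orderings and consensus


def sequence_ordering(alignment: Alignment, mode: str = "furthest") -> list[str]:
    """Greedy sequence ordering by pairwise SNP distance.

    ``nearest`` starts from the closest pair and repeatedly appends the
    remaining sequence with the smallest SNP distance to any already-selected
    sequence; ``furthest`` is the mirror image; ``given`` keeps input order.
    Ties break in input order.
    """
    labels = list(alignment.labels)
    if mode == "given":
        return labels
    if mode not in ("nearest", "furthest"):
        raise ValueError("mode must be 'nearest', 'furthest' or 'given'")
    t = len(labels)
    if t < 2:
        return labels
    d = snp_distance_matrix(alignment)
    best = None
    for i in range(t):
        for j in range(i + 1, t):
            if (
                best is None
                or (mode == "nearest" and d[i, j] < best[0])
                or (mode == "furthest" and d[i, j] > best[0])
            ):
                best = (d[i, j], i, j)
    selected = [best[1], best[2]]
    remaining = [i for i in range(t) if i not in selected]
    while remaining:
        scores = []
        for c in remaining:
            to_sel = d[c, selected]
            scores.append(to_sel.min() if mode == "nearest" else to_sel.max())
        if mode == "nearest":
            pick = remaining[int(np.argmin(scores))]
        else:
            pick = remaining[int(np.argmax(scores))]
        selected.append(pick)
        remaining.remove(pick)
    return [labels[i] for i in selected]


@dataclass
class ConsensusTree:
    """Majority-rule consensus: clades with weighted support > 1/2."""

    labels: list[str]
    clade_support: dict[frozenset, float] = field(default_factory=dict)

    def newick(self) -> str:
        kept = sorted(self.clade_support, key=len, reverse=True)
        # nest each clade under the smallest kept clade strictly containing it
        children: dict[frozenset, list] = {c: [] for c in kept}
        root = frozenset(self.labels)
        for c in kept:
            if c == root:
                continue
            parent = min(
                (p for p in kept if len(p) > len(c) and c < p),
                key=len,
            )
            children[parent].append(c)

        def render(clade: frozenset) -> str:
            subs = children[clade]
            covered = set().union(*subs) if subs else set()
            parts = [render(c) for c in sorted(subs, key=lambda c: min(c))]
            parts += sorted(clade - covered)
            inner = ",".join(parts)
            if clade == root:
                return f"({inner})"
            return f"({inner}){self.clade_support[clade]:.3f}"

        return render(root) + ";"


def majority_consensus(
    trees: Iterable[CoalescentState], weights: Sequence[float] | None = None
) -> ConsensusTree:
    """Weighted majority-rule consensus over sampled genealogies.

    Keeps every non-trivial clade whose weighted support exceeds 1/2 (strict
    majority clades are pairwise compatible, so they nest into a valid,
    possibly multifurcating topology).
    """
    trees = list(trees)
    if not trees:
        raise ValueError("no trees given")
    label_set = frozenset(trees[0].labels)
    if weights is None:
        w = np.full(len(trees), 1.0 / len(trees))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    support: dict[frozenset, float] = {}
    for tree, wt in zip(trees, w):
        if frozenset(tree.labels) != label_set:
            raise ValueError("consensus requires identical leaf sets")
        n = tree.n_leaves
        for r in range(n - 1):
            clade = frozenset(tree.leaves_under(n + r))
            support[clade] = support.get(clade, 0.0) + float(wt)
    kept = {c: s for c, s in support.items() if s > 0.5 and len(c) < len(label_set)}
    kept[label_set] = support.get(label_set, 1.0)
    return ConsensusTree(labels=sorted(label_set), clade_support=kept)


# ---------------------------------------------------------------------------
# full online run


def weighted_quantile(x: Sequence[float], weights: Sequence[float], q) -> np.ndarray:
    """Quantiles of a weighted sample (inverse of the weighted ECDF)."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(x)
    x, w = x[order], w[order]
    cdf = np.cumsum(w) / w.sum()
    return np.interp(np.atleast_1d(q), cdf, x)


@dataclass
class CoalescentRunResult:
    """Per-step evidence, diagnostics and posterior summaries of one run."""

    ordered_labels: list[str]
    log_evidences: dict[int, float]
    reports: list[BridgeReport] = field(default_factory=list)
    theta_summary: dict[str, float] = field(default_factory=dict)
    step_consensus: dict[int, "ConsensusTree"] = field(default_factory=dict)
    final_system: ParticleSystem | None = None

    @property
    def total_distributions(self) -> int:
        return int(sum(r.n_steps for r in self.reports))

    def consensus(self) -> ConsensusTree:
        system = self.final_system
        return majority_consensus(system.values, system.normalized_weights())


def tsmc_coalescent_evidences(
    alignment: Alignment,
    config: AnnealConfig,
    rng: np.random.Generator,
    n_particles: int = 250,
    ordering: str | Sequence[str] = "furthest",
    lineage_power: float = 1.0,
    height_kind: str = "laplace",
    topology_moves: bool = True,
    theta_prior: tuple[float, float] = (1.0, 5.0),
    max_sequences: int | None = None,
    final_rejuvenation: int = 5,
) -> CoalescentRunResult:
    """Online coalescent inference: add sequences one at a time.

    The single-sequence posterior is the theta prior with the constant
    (1/4)^N likelihood, so the initial particle set is an exact prior draw
    and Z_1 = (1/4)^N is known exactly; each subsequent sequence is absorbed
    by one leaf-addition bridge.  ``final_rejuvenation`` extra MCMC sweeps at
    the full posterior sharpen the particle approximation (quantiles,
    consensus) after the last bridge; they leave the evidence untouched.
    Returns per-step log evidence, bridge diagnostics, the final particle
    system and a theta posterior summary.
    """
    if isinstance(ordering, str):
        labels = sequence_ordering(alignment, ordering)
    else:
        labels = list(ordering)
    t_max = min(max_sequences or len(labels), len(labels))
    if t_max < 1:
        raise ValueError("need at least one sequence")
    shape, rate = theta_prior
    values = [
        CoalescentState(
            [labels[0]],
            np.zeros((0, 2), dtype=int),
            np.zeros(0),
            theta=float(rng.gamma(shape, 1.0 / rate)),
        )
        for _ in range(n_particles)
    ]
    log_z1 = alignment.n_sites * math.log(0.25)
    system = ParticleSystem.from_initial_draws(values, model_index=1, log_z0=log_z1)
    result = CoalescentRunResult(ordered_labels=labels[:t_max], log_evidences={1: log_z1})
    log_z = log_z1
    for t in range(1, t_max):
        bridge = leaf_addition_bridge(
            t,
            alignment,
            labels,
            lineage_power=lineage_power,
            height_kind=height_kind,
            theta_prior=theta_prior,
        )
        system, report = run_bridge(
            system,
            bridge,
            None,
            config,
            rng,
            kernel_factory=lambda v, w: make_coalescent_kernel(
                v, w, enable_topology=topology_moves
            ),
        )
        log_z += report.log_evidence_ratio
        result.log_evidences[t + 1] = log_z
        result.reports.append(report)
        if t + 1 >= 3:
            result.step_consensus[t + 1] = majority_consensus(
                system.values, system.normalized_weights()
            )
    if final_rejuvenation > 0 and t_max > 1:
        kernel = make_coalescent_kernel(
            system.values, system.normalized_weights(), enable_topology=topology_moves
        )
        log_post = lambda s: coalescent_log_posterior(s, alignment, theta_prior)
        for i in range(system.n_particles):
            if np.isneginf(system.log_weights[i]):
                continue
            state = system.values[i]
            for _ in range(final_rejuvenation):
                state, _ = kernel(state, 1.0, log_post, rng)
            system.values[i] = state
    w = system.normalized_weights()
    thetas = np.array([v.theta for v in system.values])
    q05, q50, q95 = weighted_quantile(thetas, w, [0.05, 0.5, 0.95])
    result.theta_summary = {
        "mean": float(np.sum(w * thetas)),
        "q05": float(q05),
        "median": float(q50),
        "q95": float(q95),
    }
    result.final_system = system
    return result
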