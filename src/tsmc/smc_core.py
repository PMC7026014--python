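"""Generic transformation-SMC engine.

A transformation SMC (TSMC) sampler moves a weighted particle population
through a sequence of target distributions that may live on spaces of
different dimension.  Each transition ``t -> t+1`` is described by a
:class:`ModelBridge`: a deterministic transformation (possibly chosen among
several "routes") carries each particle into the new space, and geometric
annealing with an adaptive schedule bridges the gap between the pushed-forward
proposal density and the new target.  Along the way the sampler accumulates
an unbiased estimate of the ratio of normalising constants (the Bayes factor
between successive models), so a full run yields marginal-likelihood
estimates for every model in the sequence.

All weight arithmetic is carried out in the log domain.  The "fill in"
variables that formally pad every target to a common maximal dimension are
never instantiated: their densities cancel analytically in every weight
update, so particle states only ever carry the current parameters and the
auxiliary draws of the transition in progress.
"""

from __future__ import annotations

import abc
import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidWeightsError",
    "ParticleDegeneracyError",
    "ParticleSystem",
    "AnnealConfig",
    "BridgeReport",
    "ModelBridge",
    "Route",
    "RouteBridge",
    "IdentityBridge",
    "ess",
    "cess",
    "log_cess",
    "adapt_gamma",
    "reweight_geometric",
    "stratified_resample",
    "transform_step",
    "log_proposal_density",
    "run_bridge",
    "log_evidence",
]


class InvalidWeightsError(ValueError):
    """Raised when particle weights are degenerate (all zero, or NaN)."""


class ParticleDegeneracyError(RuntimeError):
    """Raised when every particle has zero weight after a reweighting step."""


def _copy_state(state: Any) -> Any:
    copier = getattr(state, "copy", None)
    if callable(copier):
        return copier()
    return copy.deepcopy(state)


# ---------------------------------------------------------------------------
# particle bookkeeping


@dataclass
class ParticleSystem:
    """A population of P weighted particles.

    ``values`` holds model-specific states (opaque to the engine),
    ``log_weights`` the unnormalised log weights.  ``log_evidence_increments``
    accumulates one log-mean incremental weight per completed reweighting
    step; together with ``log_z0`` (the known normalising constant of the
    initial distribution) these yield the running evidence estimate.
    """

    values: list
    log_weights: np.ndarray
    model_index: int = 0
    anneal_fraction: float = 0.0
    log_evidence_increments: list = field(default_factory=list)
    log_z0: float = 0.0
    route_tags: list | None = None

    def __post_init__(self) -> None:
        self.log_weights = np.asarray(self.log_weights, dtype=float)
        if len(self.values) < 1:
            raise ValueError("a particle system needs at least one particle")
        if self.log_weights.shape != (len(self.values),):
            raise ValueError("log_weights must have one entry per particle")

    @property
    def n_particles(self) -> int:
        return len(self.values)

    def normalized_weights(self) -> np.ndarray:
        lw = self.log_weights
        if np.all(np.isneginf(lw)) or np.any(np.isnan(lw)):
            raise InvalidWeightsError("all-zero or NaN particle weights")
        w = np.exp(lw - logsumexp(lw))
        return w / w.sum()

    def ess(self) -> float:
        return ess(self.normalized_weights())

    @classmethod
    def from_initial_draws(
        cls, values: Sequence, model_index: int = 0, log_z0: float = 0.0
    ) -> "ParticleSystem":
        """Equally weighted system from exact draws of the initial target."""
        values = list(values)
        return cls(
            values=values,
            log_weights=np.zeros(len(values)),
            model_index=model_index,
            log_z0=log_z0,
        )


@dataclass
class AnnealConfig:
    """Tuning knobs of the adaptive annealing schedule.

    ``cess_fraction`` (beta) is the conditional-ESS target as a fraction of P
    used to place the next intermediate distribution; ``resample_fraction``
    (alpha) the ESS fraction below which stratified resampling is triggered.
    """

    cess_fraction: float = 0.99
    resample_fraction: float = 0.5
    max_bisection_iters: int = 60
    min_gamma_step: float = 1e-6
    gamma_tol: float = 1e-8
    mcmc_iters_per_distribution: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.resample_fraction < 1.0):
            raise ValueError("resample_fraction must lie in (0, 1)")
        if not (0.0 < self.cess_fraction < 1.0):
            raise ValueError("cess_fraction must lie in (0, 1)")
        if self.min_gamma_step <= 0:
            raise ValueError("min_gamma_step must be positive")


@dataclass
class BridgeReport:
    """Diagnostics for one model transition."""

    model_index: int
    gammas: list = field(default_factory=list)
    ess: list = field(default_factory=list)
    cess: list = field(default_factory=list)
    resampled: list = field(default_factory=list)
    acceptance_rates: list = field(default_factory=list)
    log_increments: list = field(default_factory=list)
    n_killed: int = 0

    @property
    def n_steps(self) -> int:
        return len(self.gammas)

    @property
    def log_evidence_ratio(self) -> float:
        return float(sum(self.log_increments))

    def rows(self, cumulative_offset: float = 0.0) -> list[dict]:
        """One dict per annealing step, suitable for CSV serialisation."""
        out = []
        cum = cumulative_offset
        for k in range(self.n_steps):
            cum += self.log_increments[k]
            out.append(
                {
                    "model_index": self.model_index,
                    "step": k,
                    "gamma": self.gammas[k],
                    "ess": self.ess[k],
                    "cess": self.cess[k],
                    "resampled": int(self.resampled[k]),
                    "mean_acceptance": self.acceptance_rates[k],
                    "cumulative_log_evidence": cum,
                }
            )
        return out


# ---------------------------------------------------------------------------
# effective sample sizes


def ess(normalized_weights: np.ndarray) -> float:
    """Effective sample size 1 / sum(w^2) of normalised weights."""
    w = np.asarray(normalized_weights, dtype=float)
    if np.any(np.isnan(w)) or np.all(w == 0):
        raise InvalidWeightsError("all-zero or NaN weights")
    if np.any(w < 0):
        raise InvalidWeightsError("negative weights")
    return float(1.0 / np.sum(w**2))

def cess(normalized_weights: np.ndarray, incremental_weights: np.ndarray) -> float:
    """Conditional ESS:  P (sum w*omega)^2 / sum w*omega^2.

    Measures the discrepancy a single incremental reweight ``omega`` would
    introduce, relative to the current normalised weights ``w``.  Equals P
    when the increments are constant across particles.
    """
    w = np.asarray(normalized_weights, dtype=float)
    om = np.asarray(incremental_weights, dtype=float)
    if np.any(np.isnan(om)) or not np.any(om > 0):
        raise InvalidWeightsError("incremental weights all zero or NaN")
    if np.any(om < 0):
        raise InvalidWeightsError("negative incremental weights")
    num = len(w) * np.sum(w * om) ** 2
    den = np.sum(w * om**2)
    return float(num / den)


def log_cess(log_norm_weights: np.ndarray, log_incremental: np.ndarray) -> float:
    """CESS computed stably from log weights and log incremental weights."""
    lw = np.asarray(log_norm_weights, dtype=float)
    li = np.asarray(log_incremental, dtype=float)
    alive = np.isfinite(lw)
    if not np.any(alive):
        raise InvalidWeightsError("no particles with positive weight")
    lw, li = lw[alive], li[alive]
    if np.any(np.isnan(li)):
        raise InvalidWeightsError("NaN incremental weights")
    p = len(log_norm_weights)
    log_num = math.log(p) + 2.0 * logsumexp(lw + li)
    log_den = logsumexp(lw + 2.0 * li)
    if not np.isfinite(log_num - log_den):
        raise InvalidWeightsError("incremental weights all zero")
    return float(np.exp(log_num - log_den))


# ---------------------------------------------------------------------------
# adaptive schedule


def adapt_gamma(
    system: ParticleSystem,
    log_increment_at: Callable[[float], np.ndarray],
    current_gamma: float,
    config: AnnealConfig,
) -> float:
    """Choose the next annealing fraction by bisection on CESS(gamma) = beta P.

    ``log_increment_at(g)`` must return the per-particle log incremental
    weights for tempering from ``current_gamma`` to ``g``.  Returns 1.0 when
    even the full step keeps the CESS above the target.
    """
    if current_gamma >= 1.0:
        raise ValueError("current_gamma must be < 1")
    p = system.n_particles
    target = config.cess_fraction * p
    lw_norm = system.log_weights - logsumexp(system.log_weights)

    def cess_at(g: float) -> float:
        return log_cess(lw_norm, log_increment_at(g))

    try:
        if cess_at(1.0) >= target:
            return 1.0
    except InvalidWeightsError:
        pass  # full step degenerate; bisect below

    lo, hi = current_gamma, 1.0
    try:
        for _ in range(config.max_bisection_iters):
            mid = 0.5 * (lo + hi)
            if cess_at(mid) >= target:
                lo = mid
            else:
                hi = mid
            if hi - lo < config.gamma_tol:
                break
        gamma_new = lo if lo > current_gamma else hi
        if not np.isfinite(cess_at(gamma_new)):
            raise InvalidWeightsError("non-finite CESS at bisection output")
    except (InvalidWeightsError, FloatingPointError):
        logger.warning(
            "CESS bisection failed between %.4g and 1; falling back to the "
            "minimum step",
            current_gamma,
        )
        gamma_new = current_gamma + config.min_gamma_step
    gamma_new = max(gamma_new, current_gamma + config.min_gamma_step)
    return min(gamma_new, 1.0)


# ---------------------------------------------------------------------------
# reweighting and resampling


def reweight_geometric(
    system: ParticleSystem,
    log_from: np.ndarray,
    log_to: np.ndarray,
    gamma_old: float,
    gamma_new: float,
) -> ParticleSystem:
    """Geometric-annealing reweight from gamma_old to gamma_new.

    Each log weight is incremented by ``(gamma_new - gamma_old) *
    (log_to - log_from)`` and the log-mean incremental weight (under the
    current normalised weights) is appended to the evidence increments.
    Particles with a non-finite bridging density are given zero weight.
    """
    if gamma_new <= gamma_old:
        raise ValueError("gamma_new must exceed gamma_old")
    log_from = np.asarray(log_from, dtype=float)
    log_to = np.asarray(log_to, dtype=float)
    step = gamma_new - gamma_old

    delta = np.full(system.n_particles, -np.inf)
    # log_to = -inf is a legal "out of support" value (delta -> -inf); any
    # other non-finite density kills the particle outright.
    usable = np.isfinite(log_from) & (np.isfinite(log_to) | np.isneginf(log_to))
    delta[usable] = step * (log_to[usable] - log_from[usable])
    n_bad = int(np.sum(~usable))
    if n_bad:
        logger.warning("%d particle(s) had non-finite densities; weight zeroed", n_bad)

    lw = system.log_weights
    alive = np.isfinite(lw)
    if not np.any(alive & np.isfinite(delta)):
        raise ParticleDegeneracyError("all particles lost weight in reweight")
    lw_norm = lw - logsumexp(lw[alive])
    with np.errstate(invalid="ignore"):
        contrib = np.where(alive, lw_norm + delta, -np.inf)
    increment = float(logsumexp(contrib[alive]))
    system.log_evidence_increments.append(increment)
    system.log_weights = np.where(alive, lw + delta, -np.inf)
    system.anneal_fraction = gamma_new
    return system


def stratified_resample(system: ParticleSystem, rng: np.random.Generator) -> ParticleSystem:
    """Stratified resampling: one uniform per stratum ((i-1)/P, i/P]."""
    p = system.n_particles
    w = system.normalized_weights()
    positions = (np.arange(p) + rng.uniform(size=p)) / p
    ancestors = np.searchsorted(np.cumsum(w), positions, side="left")
    ancestors = np.minimum(ancestors, p - 1)
    system.values = [_copy_state(system.values[a]) for a in ancestors]
    if system.route_tags is not None:
        system.route_tags = [system.route_tags[a] for a in ancestors]
    system.log_weights = np.zeros(p)
    system._last_ancestors = ancestors  # exposed for diagnostics/tests
    return system


# ---------------------------------------------------------------------------
# model bridges


class ModelBridge(abc.ABC):
    """Contract for one model transition t -> t+1.

    ``sample_transform`` draws fresh auxiliary variables (and a route, where
    several transformations are available), applies the deterministic map and
    returns the new state together with a route tag.  ``log_target`` is the
    log unnormalised extended target at t+1 (including any retained-route
    mass in conditional mode); ``log_proposal`` is the log density of the
    pushed-forward proposal, evaluated through the inverse image of the
    transformation(s), Jacobian-corrected.
    """

    route_mode: str = "marginal"

    @abc.abstractmethod
    def sample_transform(self, state: Any, rng: np.random.Generator) -> tuple[Any, Any]:
        ...

    @abc.abstractmethod
    def log_target(self, state: Any, tag: Any) -> float:
        ...

    @abc.abstractmethod
    def log_proposal(self, state: Any, tag: Any) -> float:
        ...


@dataclass
class Route:
    """One bijective transformation route with its auxiliary proposal.

    ``forward(state, u)`` and ``inverse(state')`` must be mutually inverse;
    ``inverse`` returns ``None`` outside the route's image.
    ``log_jac_forward`` is log |det J| of the forward map.
    """

    sample_u: Callable[[Any, np.random.Generator], Any]
    log_psi: Callable[[Any, Any], float]
    forward: Callable[[Any, Any], Any]
    inverse: Callable[[Any], tuple[Any, Any] | None]
    log_jac_forward: Callable[[Any, Any], float]
    prob: float = 1.0


class RouteBridge(ModelBridge):
    """Generic bridge built from a list of bijective routes.

    In ``conditional`` mode the sampled route index is retained with the
    particle and the proposal density is evaluated through that route alone;
    in ``marginal`` mode the route is summed out (Rao-Blackwellised), each
    in-support route contributing its prior mass times the Jacobian-corrected
    inverse-image density.
    """

    def __init__(
        self,
        log_target_from: Callable[[Any], float],
        log_target_to: Callable[[Any], float],
        routes: Sequence[Route],
        route_mode: str = "marginal",
    ) -> None:
        if route_mode not in ("conditional", "marginal"):
            raise ValueError("route_mode must be 'conditional' or 'marginal'")
        probs = np.array([r.prob for r in routes], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("route prior masses must sum to 1")
        self.log_target_from = log_target_from
        self.log_target_to = log_target_to
        self.routes = list(routes)
        self.route_mode = route_mode
        self._log_probs = np.log(probs)

    def sample_transform(self, state, rng):
        m = int(rng.choice(len(self.routes), p=np.exp(self._log_probs)))
        route = self.routes[m]
        u = route.sample_u(state, rng)
        return route.forward(state, u), m

    def _route_term(self, state, m: int, with_prior: bool) -> float:
        route = self.routes[m]
        pre = route.inverse(state)
        if pre is None:
            return -np.inf
        s, u = pre
        extra = self._log_probs[m] if with_prior else 0.0
        return (
            self.log_target_from(s)
            + route.log_psi(s, u)
            + extra
            - route.log_jac_forward(s, u)
        )

    def log_proposal(self, state, tag):
        # conditional mode: the retained route's prior mass appears in both
        # the extended target and the proposal, so it cancels and is omitted
        # from both (bijective routes cover the full target support)
        if self.route_mode == "conditional":
            return self._route_term(state, tag, with_prior=False)
        terms = [self._route_term(state, m, with_prior=True) for m in range(len(self.routes))]
        return float(logsumexp(terms))

    def log_target(self, state, tag):
        return self.log_target_to(state)


class IdentityBridge(ModelBridge):
    """Bridge between two targets on the same space (no transformation).

    This is the sampler that anneals from a tractable initial distribution to
    a posterior on the same space ("SMC2" in the model-comparison setting).
    """

    def __init__(self, log_target_from, log_target_to):
        self.log_target_from = log_target_from
        self.log_target_to = log_target_to

    def sample_transform(self, state, rng):
        return state, None

    def log_target(self, state, tag):
        return self.log_target_to(state)

    def log_proposal(self, state, tag):
        return self.log_target_from(state)


def log_proposal_density(bridge: ModelBridge, transformed_state: Any, route: Any = None) -> float:
    """Log density of the transformed-state proposal.

    With an integer ``route`` the density is evaluated conditionally through
    that route's inverse image; with ``route=None`` the route variable is
    marginalised (summed over all routes whose inverse image contains the
    state).  With a single route the two coincide.
    """
    return bridge.log_proposal(transformed_state, route)


# ---------------------------------------------------------------------------
# main loop


def transform_step(
    system: ParticleSystem, bridge: ModelBridge, rng: np.random.Generator
) -> ParticleSystem:
    """Apply the bridge's transformation to every particle.

    Draws fresh auxiliary variables (and routes), maps each particle into the
    new space and stores the route tags.  Weights are unchanged except that
    particles landing outside the support of the new target are zeroed.
    """
    new_values, tags = [], []
    for v in system.values:
        nv, tag = bridge.sample_transform(v, rng)
        new_values.append(nv)
        tags.append(tag)
    system.values = new_values
    system.route_tags = tags
    for i, (v, tag) in enumerate(zip(new_values, tags)):
        if np.isfinite(system.log_weights[i]) and np.isneginf(bridge.log_target(v, tag)):
            system.log_weights[i] = -np.inf
    system.anneal_fraction = 0.0
    return system


MCMCKernel = Callable[[Any, float, Callable[[Any], float], np.random.Generator], tuple[Any, float]]


def run_bridge(
    system: ParticleSystem,
    bridge: ModelBridge,
    mcmc_kernel: MCMCKernel | None,
    config: AnnealConfig,
    rng: np.random.Generator,
    kernel_factory: Callable[[list, np.ndarray], MCMCKernel] | None = None,
) -> tuple[ParticleSystem, BridgeReport]:
    """Carry the population across one model transition.

    Transform, then repeat (adapt gamma -> reweight -> resample if ESS < alpha P
    -> MCMC sweeps at the bridged density) until gamma reaches 1.  The MCMC
    kernel has signature ``kernel(state, gamma, log_density, rng) ->
    (state, acceptance_rate)`` and must be invariant for ``log_density``.
    ``kernel_factory(values, normalized_weights)``, when given, rebuilds the
    kernel from the current population before each move step (population-based
    proposal-scale adaptation).
    """
    report = BridgeReport(model_index=system.model_index)
    transform_step(system, bridge, rng)
    tags = system.route_tags

    def densities() -> tuple[np.ndarray, np.ndarray]:
        l_to = np.empty(system.n_particles)
        l_from = np.empty(system.n_particles)
        for i, (v, tag) in enumerate(zip(system.values, tags)):
            if np.isneginf(system.log_weights[i]):
                l_to[i] = l_from[i] = -np.inf
                continue
            l_to[i] = bridge.log_target(v, tag)
            l_from[i] = bridge.log_proposal(v, tag)
        return l_to, l_from

    l_to, l_from = densities()
    n_killed = int(np.sum(np.isfinite(system.log_weights) & ~np.isfinite(l_from)))
    report.n_killed = n_killed

    gamma = 0.0
    while gamma < 1.0:
        alive = np.isfinite(system.log_weights) & np.isfinite(l_from)
        with np.errstate(invalid="ignore"):
            delta = np.where(alive, l_to - l_from, -np.inf)
        delta = np.where(np.isnan(delta), -np.inf, delta)

        def log_inc(g: float, _d=delta, _g0=gamma) -> np.ndarray:
            return (g - _g0) * _d

        gamma_new = adapt_gamma(system, log_inc, gamma, config)
        lw_before = system.log_weights - logsumexp(
            system.log_weights[np.isfinite(system.log_weights)]
        )
        step_cess = log_cess(lw_before, log_inc(gamma_new))
        reweight_geometric(system, l_from, l_to, gamma, gamma_new)
        w = system.normalized_weights()
        step_ess = ess(w)
        resampled = step_ess < config.resample_fraction * system.n_particles
        if resampled:
            stratified_resample(system, rng)
            tags = system.route_tags
            w = system.normalized_weights()
        gamma = gamma_new

        kernel = kernel_factory(system.values, w) if kernel_factory else mcmc_kernel
        acc_rates = []
        if kernel is not None:
            for i in range(system.n_particles):
                if np.isneginf(system.log_weights[i]):
                    continue
                tag = tags[i]
                if gamma >= 1.0:
                    log_density = lambda s, _t=tag: bridge.log_target(s, _t)
                else:
                    log_density = lambda s, _t=tag, _g=gamma: (
                        _g * bridge.log_target(s, _t)
                        + (1.0 - _g) * bridge.log_proposal(s, _t)
                    )
                state = system.values[i]
                for _ in range(config.mcmc_iters_per_distribution):
                    state, acc = kernel(state, gamma, log_density, rng)
                    acc_rates.append(acc)
                system.values[i] = state
        if gamma < 1.0:
            l_to, l_from = densities()

        report.gammas.append(gamma)
        report.ess.append(step_ess)
        report.cess.append(step_cess)
        report.resampled.append(resampled)
        report.acceptance_rates.append(float(np.mean(acc_rates)) if acc_rates else float("nan"))
        report.log_increments.append(system.log_evidence_increments[-1])

    system.model_index += 1
    system.anneal_fraction = 0.0
    system.route_tags = None
    return system, report


def log_evidence(system: ParticleSystem) -> float:
    """Running log normalising-constant estimate (log Z0 + all increments)."""
    return float(system.log_z0 + sum(system.log_evidence_increments))
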