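"""Bayesian comparison of univariate Gaussian mixture models.

The model with t components has means mu_1..mu_t, precisions tau_1..tau_t and
weights nu_1..nu_t (summing to one); the likelihood is the usual
"without completion" mixture (no latent allocation variables):

    f_t(y | theta_t) = prod_i sum_s nu_s N(y_i | mu_s, 1/tau_s).

Priors are data-calibrated: mu ~ N(m, S^2), tau ~ Gamma(2, 2 S^2 / 100)
(shape/rate), nu ~ Dirichlet(1, ..., 1), with m the mean and S the range of
the observations, and an ordering constraint mu_1 < ... < mu_t for
identifiability.

Two trans-dimensional transformations move a particle population from the
t-component posterior to the (t+1)-component posterior:

* **birth** — a new component is drawn from the prior, its weight from a
  stick-breaking Beta(1, t), existing weights rescaled by (1 - nu_new);
* **split** — one component is split in two by the classical moment-matching
  construction (children preserve the parent's weight, mean and variance;
  auxiliary draws u1, u2 ~ Beta(2,2), u3 ~ Uniform).

Both transformations re-sort components by mean, so the insertion rank of the
new component(s) acts as the "route" variable: it can be retained per
particle (conditional weight update) or summed out (marginalised,
Rao-Blackwellised weight update, lower variance).  Per-model evidence can
also be computed by annealing each model from its prior to its posterior
("SMC2"), the baseline that transformation SMC is compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import gammaln

from .smc_core import (
    AnnealConfig,
    BridgeReport,
    IdentityBridge,
    ModelBridge,
    ParticleSystem,
    run_bridge,
)

__all__ = [
    "MixtureParams",
    "MixtureDataset",
    "MixturePriorSpec",
    "log_likelihood",
    "log_posterior",
    "birth_route",
    "birth_inverse",
    "split_route",
    "merge_route",
    "BirthBridge",
    "SplitBridge",
    "bridge_for_transition",
    "make_mixture_kernel",
    "sample_ordered_prior",
    "smc2_evidence",
    "smc2_mixture_evidences",
    "tsmc_mixture_evidences",
    "gauss_evals",
]


class _EvalCounter:
    """Running count of scalar Gaussian density evaluations."""

    def __init__(self) -> None:
        self.count = 0

    def add(self, n: int) -> None:
        self.count += int(n)

    def reset(self) -> None:
        self.count = 0


#: incremented by ``log_likelihood`` (N * t per call); reset freely.
gauss_evals = _EvalCounter()


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MixtureParams:
    """Parameters of a t-component mixture, components sorted by mean."""

    means: np.ndarray
    precisions: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.precisions = np.atleast_1d(np.asarray(self.precisions, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if not (len(self.means) == len(self.precisions) == len(self.weights)):
            raise ValueError("means, precisions and weights must have equal length")

    @property
    def n_components(self) -> int:
        return len(self.means)

    def is_valid(self) -> bool:
        """Ordering constraint, positive precisions, weights on the simplex."""
        return bool(
            np.all(np.diff(self.means) > 0)
            and np.all(self.precisions > 0)
            and np.all(self.weights > 0)
            and abs(self.weights.sum() - 1.0) <= 1e-12 * max(1, self.n_components)
        )

    def copy(self) -> "MixtureParams":
        return MixtureParams(self.means.copy(), self.precisions.copy(), self.weights.copy())


@dataclass
class MixtureDataset:
    """Observations plus the data summaries the priors are calibrated on."""

    observations: np.ndarray
    data_mean: float
    data_range: float

    @classmethod
    def from_observations(cls, y) -> "MixtureDataset":
        y = np.asarray(y, dtype=float).ravel()
        if y.size < 1:
            raise ValueError("need at least one observation")
        rng_ = float(y.max() - y.min())
        if y.size >= 2 and rng_ <= 0:
            raise ValueError("observations must not all be equal")
        return cls(observations=y, data_mean=float(y.mean()), data_range=rng_)

    @property
    def n(self) -> int:
        return self.observations.size


@dataclass
class MixturePriorSpec:
    """Data-calibrated priors: mu ~ N(m, S^2), tau ~ Gamma(2, 2 S^2/100),
    nu ~ Dirichlet(1,...,1), model index uniform on 1..max_components."""

    mean_loc: float
    mean_scale: float
    prec_shape: float
    prec_rate: float
    max_components: int = 8

    @classmethod
    def from_data(cls, data: MixtureDataset, max_components: int = 8) -> "MixturePriorSpec":
        s = data.data_range
        if s <= 0:
            s = max(abs(data.data_mean), 1.0)  # single-observation degenerate case
        return cls(
            mean_loc=data.data_mean,
            mean_scale=s,
            prec_shape=2.0,
            prec_rate=2.0 * s**2 / 100.0,
            max_components=max_components,
        )

    @property
    def _mean_const(self) -> float:
        return -math.log(self.mean_scale) - 0.5 * math.log(2 * math.pi)

    @property
    def _prec_const(self) -> float:
        return self.prec_shape * math.log(self.prec_rate) - math.lgamma(self.prec_shape)

    def log_mean_prior(self, mu) -> np.ndarray:
        z = (np.asarray(mu) - self.mean_loc) / self.mean_scale
        return -0.5 * z**2 + self._mean_const

    def log_prec_prior(self, tau) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        a = self.prec_shape
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                tau > 0, self._prec_const + (a - 1) * np.log(np.abs(tau)) - self.prec_rate * tau,
                -np.inf,
            )
        return out

    def sample_mean(self, rng: np.random.Generator, size=None):
        return rng.normal(self.mean_loc, self.mean_scale, size=size)

    def sample_prec(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.prec_shape, 1.0 / self.prec_rate, size=size)


# ---------------------------------------------------------------------------
# densities


def _lse(values: list[float]) -> float:
    """log-sum-exp of a small python list (cheap path for route sums)."""
    m = max(values)
    if m == -np.inf:
        return -np.inf
    return m + math.log(sum(math.exp(v - m) for v in values))


def log_likelihood(params: MixtureParams, data: MixtureDataset) -> float:
    """Mixture log likelihood  sum_i log sum_s nu_s N(y_i | mu_s, 1/tau_s)."""
    y = data.observations[:, None]
    tau = params.precisions[None, :]
    comp = (
        np.log(params.weights[None, :])
        + 0.5 * np.log(tau)
        - 0.5 * math.log(2 * math.pi)
        - 0.5 * tau * (y - params.means[None, :]) ** 2
    )
    gauss_evals.add(data.n * params.n_components)
    peak = comp.max(axis=1)
    return float(np.sum(peak + np.log(np.exp(comp - peak[:, None]).sum(axis=1))))


def log_prior(params: MixtureParams, priors: MixturePriorSpec) -> float:
    """Log prior with the ordering-constraint indicator (Dirichlet weights
    contribute their (t-1)! normalising constant).

    Scalar arithmetic on purpose: this sits inside every bridged-density
    evaluation of the MCMC sweeps.
    """
    t = params.n_components
    means, precs, wts = params.means, params.precisions, params.weights
    loc, scale = priors.mean_loc, priors.mean_scale
    a, b = priors.prec_shape, priors.prec_rate
    total = t * (priors._mean_const + priors._prec_const) + math.lgamma(t)
    prev = -math.inf
    weight_sum = 0.0
    for s in range(t):
        mu = means[s]
        tau = precs[s]
        w = wts[s]
        if mu <= prev or tau <= 0 or w <= 0:
            return -np.inf
        prev = mu
        weight_sum += w
        z = (mu - loc) / scale
        total += -0.5 * z * z + (a - 1.0) * math.log(tau) - b * tau
    if abs(weight_sum - 1.0) > 1e-12 * t:
        return -np.inf
    return float(total)


def log_posterior(params: MixtureParams, data: MixtureDataset, priors: MixturePriorSpec) -> float:
    """Unnormalised log posterior (prior x likelihood, -inf off the ordering
    constraint).  Its normalising constant is the model evidence Z_t."""
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(params, data)


# ---------------------------------------------------------------------------
# birth transformation


def _insert_sorted(params: MixtureParams, new_comps: list[tuple[float, float, float]],
                   drop: tuple[int, ...] = ()) -> tuple[MixtureParams, list[int]]:
    """Drop components, insert new (mu, tau, nu) triples, re-sort by mean.

    Returns the sorted parameters and the positions of the inserted triples.
    """
    keep = [s for s in range(params.n_components) if s not in drop]
    triples = [(params.means[s], params.precisions[s], params.weights[s], -1) for s in keep]
    triples += [(mu, tau, nu, k) for k, (mu, tau, nu) in enumerate(new_comps)]
    triples.sort(key=lambda c: c[0])
    means = np.array([c[0] for c in triples])
    precs = np.array([c[1] for c in triples])
    wts = np.array([c[2] for c in triples])
    positions = [next(i for i, c in enumerate(triples) if c[3] == k) for k in range(len(new_comps))]
    return MixtureParams(means, precs, wts), positions


def birth_route(
    params_t: MixtureParams, u: tuple[float, float, float]
) -> tuple[MixtureParams, int, float]:
    """Birth: insert a prior-drawn component with stick-breaking weight.

    ``u = (mu_new, tau_new, nu_new)`` with nu_new ~ Beta(1, t).  Existing
    weights are rescaled by (1 - nu_new) and components re-sorted by mean.
    Returns (params_{t+1}, insertion rank, log |J_forward|) with
    log |J| = (t - 1) log(1 - nu_new) from the weight rescaling.
    """
    mu_new, tau_new, nu_new = u
    t = params_t.n_components
    scaled = params_t.copy()
    scaled.weights = params_t.weights * (1.0 - nu_new)
    out, (pos,) = _insert_sorted(scaled, [(mu_new, tau_new, nu_new)])
    return out, pos, (t - 1) * math.log1p(-nu_new)


def birth_inverse(
    params_t1: MixtureParams, new_index: int
) -> tuple[MixtureParams, tuple[float, float, float], float]:
    """Inverse of :func:`birth_route`: delete component ``new_index``.

    Returns (params_t, u, log |J_forward| at the preimage).
    """
    t1 = params_t1.n_components
    nu_new = float(params_t1.weights[new_index])
    u = (float(params_t1.means[new_index]), float(params_t1.precisions[new_index]), nu_new)
    keep = [s for s in range(t1) if s != new_index]
    params_t = MixtureParams(
        params_t1.means[keep],
        params_t1.precisions[keep],
        params_t1.weights[keep] / (1.0 - nu_new),
    )
    return params_t, u, (t1 - 2) * math.log1p(-nu_new)


def _log_beta_pdf(x: float, a: float, b: float) -> float:
    if not 0.0 < x < 1.0:
        return -np.inf
    return float(
        gammaln(a + b) - gammaln(a) - gammaln(b) + (a - 1) * math.log(x) + (b - 1) * math.log1p(-x)
    )


# ---------------------------------------------------------------------------
# split transformation (moment matching)


def split_route(
    params_t: MixtureParams, component: int, u: tuple[float, float, float]
) -> tuple[MixtureParams, tuple[int, int], float]:
    """Moment-matching split of one component into two.

    With parent (nu, mu, sigma^2 = 1/tau) and aux draws u1, u2 ~ Beta(2,2),
    u3 ~ Uniform(0,1), the children are

        nu1 = nu u1                      nu2 = nu (1 - u1)
        mu1 = mu - u2 sigma sqrt(nu2/nu1)  mu2 = mu + u2 sigma sqrt(nu1/nu2)
        sigma1^2 = u3 (1-u2^2) sigma^2 nu/nu1
        sigma2^2 = (1-u3)(1-u2^2) sigma^2 nu/nu2

    which preserve the parent's weight and its first two moments.  Components
    are re-sorted by mean.  Returns (params_{t+1}, (i, j) child positions,
    log |J_forward|) where the Jacobian, expressed in the precision
    parameterisation, is

        log|J| = log nu + log(mu2 - mu1) - log u2 - log(1-u2^2)
                 - log u3 - log(1-u3) - log tau + log tau1 + log tau2.
    """
    u1, u2, u3 = u
    nu = float(params_t.weights[component])
    mu = float(params_t.means[component])
    tau = float(params_t.precisions[component])
    var = 1.0 / tau
    nu1, nu2 = nu * u1, nu * (1.0 - u1)
    sd = math.sqrt(var)
    mu1 = mu - u2 * sd * math.sqrt(nu2 / nu1)
    mu2 = mu + u2 * sd * math.sqrt(nu1 / nu2)
    var1 = u3 * (1.0 - u2**2) * var * nu / nu1
    var2 = (1.0 - u3) * (1.0 - u2**2) * var * nu / nu2
    tau1, tau2 = 1.0 / var1, 1.0 / var2
    out, (i, j) = _insert_sorted(
        params_t, [(mu1, tau1, nu1), (mu2, tau2, nu2)], drop=(component,)
    )
    log_jac = (
        math.log(nu)
        + math.log(mu2 - mu1)
        - math.log(u2)
        - math.log1p(-u2**2)
        - math.log(u3)
        - math.log1p(-u3)
        - math.log(tau)
        + math.log(tau1)
        + math.log(tau2)
    )
    return out, (i, j), log_jac


def merge_route(
    params_t1: MixtureParams, i: int, j: int
) -> tuple[MixtureParams, int, tuple[float, float, float], float] | None:
    """Inverse of :func:`split_route`: merge components i < j by moment
    matching.

    Returns (params_t, merged rank, u, log |J_forward| at the preimage).
    The moment-matching inverse always exists: the merged variance is the
    within-plus-between decomposition, so the recovered u2, u3 always fall in
    (0, 1).  Returns None only for numerically degenerate inputs.
    """
    if i > j:
        i, j = j, i
    nu_i, nu_j = float(params_t1.weights[i]), float(params_t1.weights[j])
    mu_i, mu_j = float(params_t1.means[i]), float(params_t1.means[j])
    var_i = 1.0 / float(params_t1.precisions[i])
    var_j = 1.0 / float(params_t1.precisions[j])
    nu = nu_i + nu_j
    mu = (nu_i * mu_i + nu_j * mu_j) / nu
    var = (nu_i * (mu_i**2 + var_i) + nu_j * (mu_j**2 + var_j)) / nu - mu**2
    if var <= 0:
        return None
    u1 = nu_i / nu
    u2 = (mu - mu_i) / math.sqrt(var * nu_j / nu_i)
    if not (0.0 < u2 < 1.0):
        return None
    u3 = var_i * nu_i / ((1.0 - u2**2) * var * nu)
    if not (0.0 < u3 < 1.0):
        return None
    params_t, (pos,) = _insert_sorted(params_t1, [(mu, 1.0 / var, nu)], drop=(i, j))
    log_jac = (
        math.log(nu)
        + math.log(mu_j - mu_i)
        - math.log(u2)
        - math.log1p(-u2**2)
        - math.log(u3)
        - math.log1p(-u3)
        + math.log(var)  # -log tau
        + math.log(params_t1.precisions[i])
        + math.log(params_t1.precisions[j])
    )
    return params_t, pos, (u1, u2, u3), log_jac


# ---------------------------------------------------------------------------
# bridges


class BirthBridge(ModelBridge):
    """Transition t -> t+1 components via a prior birth (a single route).

    There is no free route choice in a birth: the insertion rank of the new
    component is determined by the sort, so the exact density of the
    transformed state is the sum over all t+1 candidate ranks of the
    Jacobian-corrected inverse-image terms.  Conditional and marginal modes
    therefore coincide (the single-route degeneracy); ``route_mode`` is
    accepted for interface symmetry with the split bridge.
    """

    def __init__(self, t: int, data: MixtureDataset, priors: MixturePriorSpec,
                 route_mode: str = "marginal") -> None:
        if route_mode not in ("conditional", "marginal"):
            raise ValueError("route_mode must be 'conditional' or 'marginal'")
        self.t = t
        self.data = data
        self.priors = priors
        self.route_mode = route_mode

    def _log_pi(self, params: MixtureParams) -> float:
        return log_posterior(params, self.data, self.priors)

    def _log_psi(self, u: tuple[float, float, float]) -> float:
        mu_new, tau_new, nu_new = u
        return float(
            self.priors.log_mean_prior(mu_new)
            + self.priors.log_prec_prior(tau_new)
            + _log_beta_pdf(nu_new, 1.0, self.t)
        )

    def sample_transform(self, state: MixtureParams, rng: np.random.Generator):
        u = (
            float(self.priors.sample_mean(rng)),
            float(self.priors.sample_prec(rng)),
            float(rng.beta(1.0, self.t)),
        )
        out, pos, _ = birth_route(state, u)
        return out, pos

    def _rank_term(self, state: MixtureParams, rank: int) -> float:
        params_t, u, log_jac = birth_inverse(state, rank)
        lp = self._log_pi(params_t)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self._log_psi(u) - log_jac

    def log_proposal(self, state: MixtureParams, tag) -> float:
        # exact pushforward density of the sorted birth: one term per
        # candidate insertion rank (tag unused; single-route transition)
        terms = [self._rank_term(state, r) for r in range(state.n_components)]
        return _lse(terms)

    def log_target(self, state: MixtureParams, tag) -> float:
        return self._log_pi(state)


class SplitBridge(ModelBridge):
    """Transition t -> t+1 components via a moment-matching split.

    The route prior is uniform over the t components (rho = 1/t).  Because
    components are re-sorted, the pair of child positions identifies the
    route uniquely even after MCMC moves, so the conditional tag stores the
    child pair; the retained pair carries uniform mass 1/C(t+1, 2) in the
    extended target.  The marginal denominator sums over every component
    pair, whose moment-matching merge inverse always exists.
    """

    def __init__(self, t: int, data: MixtureDataset, priors: MixturePriorSpec,
                 route_mode: str = "marginal") -> None:
        if route_mode not in ("conditional", "marginal"):
            raise ValueError("route_mode must be 'conditional' or 'marginal'")
        if t < 1:
            raise ValueError("need at least one component to split")
        self.t = t
        self.data = data
        self.priors = priors
        self.route_mode = route_mode

    def _log_pi(self, params: MixtureParams) -> float:
        return log_posterior(params, self.data, self.priors)

    @staticmethod
    def _log_psi(u: tuple[float, float, float]) -> float:
        u1, u2, u3 = u
        if not 0.0 < u3 < 1.0:
            return -np.inf
        return _log_beta_pdf(u1, 2.0, 2.0) + _log_beta_pdf(u2, 2.0, 2.0)

    def sample_transform(self, state: MixtureParams, rng: np.random.Generator):
        component = int(rng.integers(self.t))
        u = (float(rng.beta(2, 2)), float(rng.beta(2, 2)), float(rng.uniform()))
        out, pair, _ = split_route(state, component, u)
        return out, pair

    def _pair_term(self, state: MixtureParams, i: int, j: int) -> float:
        inv = merge_route(state, i, j)
        if inv is None:
            return -np.inf
        params_t, _, u, log_jac = inv
        lp = self._log_pi(params_t)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self._log_psi(u) - math.log(self.t) - log_jac

    def log_proposal(self, state: MixtureParams, tag) -> float:
        if self.route_mode == "conditional":
            i, j = tag
            return self._pair_term(state, i, j)
        t1 = state.n_components
        terms = [
            self._pair_term(state, i, j) for i in range(t1) for j in range(i + 1, t1)
        ]
        return _lse(terms)

    def log_target(self, state: MixtureParams, tag) -> float:
        if self.route_mode == "conditional":
            n_pairs = (self.t + 1) * self.t // 2
            extra = -math.log(n_pairs)
        else:
            extra = 0.0
        return self._log_pi(state) + extra


def bridge_for_transition(
    t: int,
    move: str,
    mode: str,
    priors: MixturePriorSpec,
    data: MixtureDataset,
) -> ModelBridge:
    """Bridge for the t -> t+1 component transition (move: birth|split)."""
    if not 1 <= t < priors.max_components:
        raise ValueError("t must satisfy 1 <= t < max_components")
    if move == "birth":
        return BirthBridge(t, data, priors, route_mode=mode)
    if move == "split":
        return SplitBridge(t, data, priors, route_mode=mode)
    raise ValueError(f"unknown move {move!r}")


# ---------------------------------------------------------------------------
# MCMC kernel


def _alr(weights: np.ndarray) -> np.ndarray:
    return np.log(weights[:-1]) - math.log(weights[-1])


def _weighted_std(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    mean = np.average(x, axis=0, weights=w)
    var = np.average((x - mean) ** 2, axis=0, weights=w)
    return np.sqrt(np.maximum(var, 0.0))


def make_mixture_kernel(
    values: list[MixtureParams], weights: np.ndarray
) -> Callable:
    """Metropolis-within-Gibbs sweep with population-adapted proposal scales.

    One sweep: Gaussian random walk on each mean (rejected outright when it
    breaks the ordering), log-scale random walk on each precision, and a
    joint random walk on the additive log-ratio transform of the weights.
    Scales are 2.38 x the weighted particle standard deviation per coordinate.
    """
    t = values[0].n_components
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    means = np.array([v.means for v in values])
    ltaus = np.log([v.precisions for v in values])
    scale_mu = np.maximum(2.38 * _weighted_std(means, w), 1e-8)
    scale_ltau = np.maximum(2.38 * _weighted_std(ltaus, w), 1e-8)
    if t > 1:
        zs = np.array([_alr(v.weights) for v in values])
        scale_z = np.maximum(2.38 * _weighted_std(zs, w), 1e-8)
    else:
        scale_z = None

    def kernel(state: MixtureParams, gamma: float, log_density, rng: np.random.Generator):
        n_acc, n_prop = 0, 0
        cur = log_density(state)
        # means
        for s in range(t):
            n_prop += 1
            old = state.means[s]
            new = old + scale_mu[s] * rng.standard_normal()
            state.means[s] = new
            if not np.all(np.diff(state.means) > 0):
                state.means[s] = old
                continue
            prop = log_density(state)
            if math.log(rng.uniform()) < prop - cur:
                cur = prop
                n_acc += 1
            else:
                state.means[s] = old
        # precisions (log scale)
        for s in range(t):
            n_prop += 1
            old = state.precisions[s]
            delta = scale_ltau[s] * rng.standard_normal()
            state.precisions[s] = old * math.exp(delta)
            prop = log_density(state)
            if math.log(rng.uniform()) < prop - cur + delta:
                cur = prop
                n_acc += 1
            else:
                state.precisions[s] = old
        # weights (joint ALR random walk)
        if t > 1:
            n_prop += 1
            old_w = state.weights.copy()
            z = _alr(old_w) + scale_z * rng.standard_normal(t - 1)
            expz = np.exp(np.concatenate([z, [0.0]]) - max(np.max(z), 0.0))
            new_w = expz / expz.sum()
            if np.all(new_w > 0):
                state.weights = new_w
                prop = log_density(state)
                log_jac = float(np.sum(np.log(new_w)) - np.sum(np.log(old_w)))
                if math.log(rng.uniform()) < prop - cur + log_jac:
                    cur = prop
                    n_acc += 1
                else:
                    state.weights = old_w
        return state, n_acc / n_prop

    return kernel


# ---------------------------------------------------------------------------
# SMC2 and full TSMC runs


def log_ordered_prior(params: MixtureParams, priors: MixturePriorSpec) -> float:
    """Normalised log density of the sorted prior draw (t! x iid prior on the
    ordered region)."""
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return -np.inf
    return lp + float(gammaln(params.n_components + 1))


def sample_ordered_prior(
    t: int, priors: MixturePriorSpec, rng: np.random.Generator
) -> MixtureParams:
    """Exact draw from the prior restricted to ordered means (sort whole
    component triples by mean)."""
    mu = priors.sample_mean(rng, size=t)
    tau = priors.sample_prec(rng, size=t)
    nu = rng.dirichlet(np.ones(t))
    order = np.argsort(mu)
    return MixtureParams(mu[order], tau[order], nu[order])


def smc2_evidence(
    t: int,
    data: MixtureDataset,
    priors: MixturePriorSpec,
    config: AnnealConfig,
    rng: np.random.Generator,
    n_particles: int = 500,
    return_system: bool = False,
):
    """Log evidence of the t-component model by prior-to-posterior annealing.

    Anneals from the ordered prior (sampled exactly) to the posterior with the
    same adaptive CESS placement machinery used by the trans-dimensional
    bridges, an identity transformation, and the standard mixture MCMC
    kernel.  Returns the log-evidence estimate (plus the final particle
    system and the bridge report when ``return_system``).
    """
    values = [sample_ordered_prior(t, priors, rng) for _ in range(n_particles)]
    system = ParticleSystem.from_initial_draws(values, model_index=t)
    bridge = IdentityBridge(
        log_target_from=lambda p: log_ordered_prior(p, priors),
        log_target_to=lambda p: log_posterior(p, data, priors),
    )
    system, report = run_bridge(
        system, bridge, None, config, rng, kernel_factory=make_mixture_kernel
    )
    log_z = report.log_evidence_ratio
    if return_system:
        return log_z, system, report
    return log_z


@dataclass
class MixtureRunResult:
    """Per-model evidence estimates and diagnostics from one sampler run."""

    log_evidences: dict[int, float]
    reports: list[BridgeReport] = field(default_factory=list)
    n_gauss_evals: int = 0
    final_system: ParticleSystem | None = None


def tsmc_mixture_evidences(
    data: MixtureDataset,
    priors: MixturePriorSpec,
    config: AnnealConfig,
    rng: np.random.Generator,
    max_components: int | None = None,
    move: str = "split",
    mode: str = "marginal",
    n_particles: int = 500,
) -> MixtureRunResult:
    """Evidence for models 1..T by transformation SMC.

    Model 1 is annealed prior-to-posterior (its own SMC2 run); each further
    model is reached by one trans-dimensional bridge, so the sampler reports
    Z_1 and the chain of Bayes factors Z_{t+1}/Z_t.
    """
    t_max = max_components or priors.max_components
    evals0 = gauss_evals.count
    log_z1, system, rep1 = smc2_evidence(
        1, data, priors, config, rng, n_particles=n_particles, return_system=True
    )
    result = MixtureRunResult(log_evidences={1: log_z1}, reports=[rep1])
    log_z = log_z1
    for t in range(1, t_max):
        bridge = bridge_for_transition(t, move, mode, priors, data)
        system, report = run_bridge(
            system, bridge, None, config, rng, kernel_factory=make_mixture_kernel
        )
        log_z += report.log_evidence_ratio
        result.log_evidences[t + 1] = log_z
        result.reports.append(report)
    result.n_gauss_evals = gauss_evals.count - evals0
    result.final_system = system
    return result


def smc2_mixture_evidences(
    data: MixtureDataset,
    priors: MixturePriorSpec,
    config: AnnealConfig,
    rng: np.random.Generator,
    max_components: int | None = None,
    n_particles: int = 500,
) -> MixtureRunResult:
    """Evidence for models 1..T, each by its own prior-to-posterior run."""
    t_max = max_components or priors.max_components
    evals0 = gauss_evals.count
    result = MixtureRunResult(log_evidences={})
    for t in range(1, t_max + 1):
        log_z, _, report = smc2_evidence(
            t, data, priors, config, rng, n_particles=n_particles, return_system=True
        )
        result.log_evidences[t] = log_z
        result.reports.append(report)
    result.n_gauss_evals = gauss_evals.count - evals0
    return result
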