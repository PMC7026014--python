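"""Independent brute-force oracles used by the tests.

Everything here is written from the model definitions directly (enumeration,
quadrature, Monte Carlo from the priors) and deliberately avoids the package's
own pruning/likelihood/weight code paths.
"""

import itertools
import math

import numpy as np
from numpy.polynomial.laguerre import laggauss
from scipy.special import gammaln, logsumexp


# ---------------------------------------------------------------------------
# mixtures


def mixture_loglik_brute(means, precs, weights, y):
    """Per-point linear-domain mixture likelihood, summed in logs."""
    total = 0.0
    for yi in y:
        s = 0.0
        for mu, tau, nu in zip(means, precs, weights):
            s += nu * math.sqrt(tau / (2 * math.pi)) * math.exp(-0.5 * tau * (yi - mu) ** 2)
        total += math.log(s)
    return total


def mixture_logZ_prior_is(y, priors, t, n_samples, seed):
    """Ordered-model evidence by importance sampling from the (unordered)
    prior: Z_t = E_prior[f] / t!.  Returns (logZ, relative standard error)."""
    r = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    mu = r.normal(priors.mean_loc, priors.mean_scale, (n_samples, t))
    tau = r.gamma(priors.prec_shape, 1.0 / priors.prec_rate, (n_samples, t))
    nu = r.dirichlet(np.ones(t), n_samples)
    comp = (
        np.log(nu)[:, None, :]
        + 0.5 * np.log(tau)[:, None, :]
        - 0.5 * math.log(2 * math.pi)
        - 0.5 * tau[:, None, :] * (y[None, :, None] - mu[:, None, :]) ** 2
    )
    ll = logsumexp(comp, axis=2).sum(axis=1)
    log_z = logsumexp(ll) - math.log(n_samples) - gammaln(t + 1)
    scaled = np.exp(ll - ll.max())
    rel_se = scaled.std(ddof=1) / math.sqrt(n_samples) / scaled.mean()
    return float(log_z), float(rel_se)


def mixture_logZ1_quadrature(y, priors, n_tau=20000, log_tau_span=(-12.0, 8.0)):
    """One-component evidence: conjugate closed form in mu, dense 1-D
    quadrature in tau.

    For fixed tau the mu-integral is Gaussian-Gaussian:

        prod_i N(y_i | mu, 1/tau) = (tau/2pi)^(N/2) e^(-tau SS/2)
                                     sqrt(2pi/(N tau)) N(mu; ybar, 1/(N tau))
        int N(mu; m, S^2) N(mu; ybar, 1/(N tau)) dmu
                                   = N(ybar; m, S^2 + 1/(N tau)),

    leaving int Gamma(tau; 2, rate) Z(tau) dtau, evaluated by trapezoid on a
    dense log-tau grid.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    ybar = y.mean()
    ss = float(np.sum((y - ybar) ** 2))
    log_tau = np.linspace(*log_tau_span, n_tau)
    tau = np.exp(log_tau)
    var_pred = priors.mean_scale**2 + 1.0 / (n * tau)
    log_z_tau = (
        0.5 * n * (np.log(tau) - math.log(2 * math.pi))
        - 0.5 * tau * ss
        + 0.5 * (math.log(2 * math.pi) - np.log(n * tau))
        - 0.5 * np.log(2 * math.pi * var_pred)
        - 0.5 * (ybar - priors.mean_loc) ** 2 / var_pred
    )
    b = priors.prec_rate
    log_prior_tau = 2.0 * math.log(b) - gammaln(2.0) + np.log(tau) - b * tau
    # trapezoid in log tau (extra +log tau Jacobian)
    integrand = log_prior_tau + log_z_tau + log_tau
    peak = integrand.max()
    z = np.trapezoid(np.exp(integrand - peak), log_tau)
    return float(math.log(z) + peak)


# ---------------------------------------------------------------------------
# coalescent


def _jc_p_trans(d, same):
    e = math.exp(-4.0 * d / 3.0)
    return 0.25 + 0.75 * e if same else 0.25 - 0.25 * e


def jc_loglik_enumeration(state, alignment):
    """Small-taxon JC likelihood by summing over all internal-node base
    assignments on the rooted genealogy."""
    n = state.n_leaves
    enc = alignment.encoded(state.labels)
    parents = state.parent_map()
    total = 0.0
    for site in range(alignment.n_sites):
        site_p = 0.0
        for assign in itertools.product(range(4), repeat=n - 1):
            base = {i: int(enc[i][site]) for i in range(n)}
            for r in range(n - 1):
                base[n + r] = assign[r]
            p = 0.25
            for node, par in parents.items():
                d = 0.5 * state.theta * (state.node_height(par) - state.node_height(node))
                p *= _jc_p_trans(d, base[node] == base[par])
            site_p += p
        total += math.log(site_p)
    return total


def jc_loglik_unrooted_enumeration(state, alignment):
    """JC likelihood evaluated on the *unrooted* tree obtained by suppressing
    the root node (its two edges fuse into one).

    Under a reversible model with uniform frequencies the likelihood depends
    only on this unrooted weighted tree, not on where along the fused edge the
    root sits — agreement with the rooted pruning value is exactly the
    re-rooting invariance.
    """
    n = state.n_leaves
    enc = alignment.encoded(state.labels)
    parents = state.parent_map()
    root = state.root

    def dist(node, par):
        return 0.5 * state.theta * (state.node_height(par) - state.node_height(node))

    ra, rb = (int(c) for c in state.children[root - n])
    edges = [(node, par, dist(node, par)) for node, par in parents.items() if par != root]
    edges.append((ra, rb, dist(ra, root) + dist(rb, root)))  # fused root edge
    free = [v for v in range(n, 2 * n - 1) if v != root]
    total = 0.0
    for site in range(alignment.n_sites):
        site_p = 0.0
        for assign in itertools.product(range(4), repeat=len(free)):
            base = {i: int(enc[i][site]) for i in range(n)}
            base.update(dict(zip(free, assign)))
            p = 0.25
            for a, b, d in edges:
                p *= _jc_p_trans(d, base[a] == base[b])
            site_p += p
        total += math.log(site_p)
    return total


def coalescent_logZ3_quadrature(alignment, nodes=48, theta_shape=1.0, theta_rate=5.0):
    """Three-leaf evidence by 3-topology x 3-D Gauss-Laguerre quadrature.

    Z_3 = sum_topologies int Gamma(theta) e^{-3 l3 - l2} f(y | T, theta),
    with the JC likelihood written out directly (no pruning code shared with
    the package).  Substitutions x = 3 l3, x = l2, x = rate * theta turn all
    three integrals into plain Gauss-Laguerre sums; the Gamma(1, rate) density
    cancels into the e^{-x} weight.
    """
    if alignment.n_sequences != 3 or theta_shape != 1.0:
        raise ValueError("oracle covers 3 sequences and a shape-1 theta prior")
    enc = alignment.encoded()
    pat, cnt = np.unique(enc, axis=1, return_counts=True)
    x, w = laggauss(nodes)
    l3g, l2g, thg = np.meshgrid(x / 3.0, x, x / theta_rate, indexing="ij")
    wg = (w[:, None, None] * w[None, :, None] * w[None, None, :]).ravel()
    l3, l2, th = l3g.ravel(), l2g.ravel(), thg.ravel()

    def ptrans(d):
        e = np.exp(-4.0 * d / 3.0)
        return 0.25 + 0.75 * e, 0.25 - 0.25 * e

    per_topology = []
    for ia, ib, ic in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
        ps_l, pd_l = ptrans(0.5 * th * l3)
        ps_m, pd_m = ptrans(0.5 * th * l2)
        ps_c, pd_c = ptrans(0.5 * th * (l3 + l2))
        loglik = np.zeros_like(l3)
        for k in range(pat.shape[1]):
            xa, xb, xc = pat[ia, k], pat[ib, k], pat[ic, k]
            site = np.zeros_like(l3)
            for u in range(4):
                pa = ps_l if u == xa else pd_l
                pb = ps_l if u == xb else pd_l
                for v in range(4):
                    pm = ps_m if v == u else pd_m
                    pc = ps_c if v == xc else pd_c
                    site += 0.25 * pa * pb * pm * pc
            loglik += cnt[k] * np.log(site)
        peak = loglik.max()
        per_topology.append(math.log(np.sum(wg * np.exp(loglik - peak))) + peak)
    m = max(per_topology)
    # the 1/3 is the Jacobian of x = 3 l3 in the first substitution
    return m + math.log(sum(math.exp(v - m) for v in per_topology)) - math.log(3.0)


def pairwise_jc_loglik(m, n_sites, d):
    """Closed-form pairwise JC log likelihood at separation d (expected
    substitutions between the two sequences)."""
    e = math.exp(-4.0 * d / 3.0)
    p_same = 0.25 + 0.75 * e
    p_diff = 0.25 - 0.25 * e
    return m * math.log(0.25 * p_diff) + (n_sites - m) * math.log(0.25 * p_same)
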