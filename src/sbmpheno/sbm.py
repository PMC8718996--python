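"""Bayesian stochastic block model: Gibbs inference, model selection, summaries.

The stochastic block model (SBM) is a generative model for an undirected
binary network on ``n`` nodes.  Each node ``i`` carries a latent community
label ``z_i`` in ``{1..K}``; conditional on the labels, edges are independent
Bernoulli draws

    A_ij | z, Theta ~ Bernoulli(theta_{z_i z_j}),   i < j,

where ``Theta`` is a symmetric K x K matrix of block connectivity
probabilities.  Nodes in the same community are stochastically equivalent.
The fully Bayesian formulation used here places conjugate priors on all
parameters:

* ``z_i ~ Categorical(pi)`` with ``pi ~ Dirichlet(alpha_1 .. alpha_K)``,
* ``theta_rs ~ Beta(beta1, beta2)`` independently for ``r <= s``,

with the weakly informative defaults ``alpha_k = 1`` and
``beta1 = beta2 = 1``.  Conjugacy makes every full conditional a standard
distribution, so the posterior is explored by plain Gibbs sampling.  Label
switching is handled by projecting every stored sample onto the canonical
subspace in which community 1 appears first in ``z``, community 2 second,
and so on.  The point estimate of the partition is the stored sample
maximizing the collapsed posterior ``p(z | A)`` (``pi`` and ``Theta``
integrated out), and the number of communities is compared across fits via
BIC.

Typical use::

    model = StochasticBlockModel(network, k=3)
    res = model.fit(n_iter=10_000, n_burn=1_000, seed=42)
    print(res.summary())
    res.z_map, res.theta_mean, res.bic
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

from . import _engine
from .network import SimilarityNetwork

__all__ = [
    "SBMConfig",
    "PosteriorSamples",
    "StochasticBlockModel",
    "SBMResults",
    "log_likelihood",
    "gibbs_update_pi",
    "gibbs_update_theta",
    "gibbs_update_z",
    "canonical_relabel",
    "collapsed_log_posterior",
    "fit_sbm",
    "bic",
    "select_k",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration and sample containers
# ---------------------------------------------------------------------------

@dataclass
class SBMConfig:
    """Hyperparameters and MCMC settings for one SBM fit.

    Defaults are the weakly informative choices alpha = 1, beta1 = beta2 = 1
    with 10,000 iterations and 1,000 burn-in.
    """

    k: int
    alpha: np.ndarray | float = 1.0
    beta1: float = 1.0
    beta2: float = 1.0
    n_iter: int = 10_000
    n_burn: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        self.alpha = np.broadcast_to(
            np.asarray(self.alpha, dtype=float), (self.k,)).copy()
        if (self.alpha <= 0).any() or self.beta1 <= 0 or self.beta2 <= 0:
            raise ValueError("prior parameters must be positive")
        if not 0 <= self.n_burn < self.n_iter:
            raise ValueError("require 0 <= n_burn < n_iter")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alpha"] = [float(a) for a in self.alpha]
        return d


@dataclass
class PosteriorSamples:
    """Post-burn-in Gibbs draws, all in canonical label form.

    ``z`` is S x n with entries in {1..K}; ``pi`` is S x K; ``theta`` is
    S x K x K with each draw symmetric.  ``log_post`` holds the collapsed
    log posterior of every stored labeling (up to a constant).
    """

    z: np.ndarray
    pi: np.ndarray
    theta: np.ndarray
    log_post: np.ndarray

    @property
    def S(self) -> int:
        return self.z.shape[0]

    @property
    def n(self) -> int:
        return self.z.shape[1]

    @property
    def K(self) -> int:
        return self.pi.shape[1]

    def occupancy(self) -> np.ndarray:
        """n x K matrix: fraction of samples assigning each node to each label."""
        occ = np.empty((self.n, self.K))
        for k in range(self.K):
            occ[:, k] = (self.z == k + 1).mean(axis=0)
        return occ


# ---------------------------------------------------------------------------
# single-step reference operations (pure NumPy)
# ---------------------------------------------------------------------------

def _as_adjacency(A) -> np.ndarray:
    if isinstance(A, SimilarityNetwork):
        return A.A
    A = np.asarray(A)
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    return A


def log_likelihood(A, z, theta) -> float:
    """Bernoulli log likelihood sum over dyads i < j at labels z, matrix theta.

    Returns -inf (and logs a warning) when a degenerate theta entry of exactly
    0 or 1 contradicts an observed dyad.
    """
    A = _as_adjacency(A)
    z = np.asarray(z, dtype=int) - 1
    theta = np.asarray(theta, dtype=float)
    if z.min() < 0 or z.max() >= theta.shape[0]:
        raise ValueError("labels must lie in {1..K}")
    iu, ju = np.triu_indices(len(z), 1)
    p = theta[z[iu], z[ju]]
    a = A[iu, ju]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(a == 1, np.log(p), np.log1p(-p))
    if np.isnan(terms).any() or np.isneginf(terms).any():
        logger.warning("degenerate theta entry contradicts an observed dyad")
        return float("-inf")
    return float(terms.sum())


def gibbs_update_pi(z, alpha, rng, k: int | None = None) -> np.ndarray:
    """Draw pi ~ Dirichlet(alpha_1 + n_1, ..., alpha_K + n_K)."""
    alpha = np.asarray(alpha, dtype=float)
    if (alpha <= 0).any():
        raise ValueError("alpha entries must be positive")
    K = k or len(alpha)
    counts = np.bincount(np.asarray(z, dtype=int) - 1, minlength=K)
    return rng.dirichlet(alpha + counts)


def _block_counts(A, z, K) -> tuple[np.ndarray, np.ndarray]:
    """Edge counts m_rs and dyad counts M_rs for unordered block pairs."""
    z = np.asarray(z, dtype=int) - 1
    nk = np.bincount(z, minlength=K).astype(float)
    iu, ju = np.nonzero(np.triu(_as_adjacency(A), 1))
    m = np.zeros((K, K))
    np.add.at(m, (np.minimum(z[iu], z[ju]), np.maximum(z[iu], z[ju])), 1)
    M = np.outer(nk, nk)
    np.fill_diagonal(M, nk * (nk - 1) / 2)
    return np.triu(m), np.triu(M)


def gibbs_update_theta(A, z, beta1, beta2, rng, k: int | None = None) -> np.ndarray:
    """Draw each theta_rs ~ Beta(beta1 + m_rs, beta2 + M_rs - m_rs), r <= s.

    Block pairs with no possible dyads (M_rs = 0) are drawn from the prior.
    """
    A = _as_adjacency(A)
    K = k or int(np.max(z))
    m, M = _block_counts(A, z, K)
    theta = np.zeros((K, K))
    for r in range(K):
        for s in range(r, K):
            theta[r, s] = theta[s, r] = rng.beta(
                beta1 + m[r, s], beta2 + M[r, s] - m[r, s])
    return theta


def gibbs_update_z(A, z, pi, theta, rng) -> np.ndarray:
    """One systematic sweep i = 1..n of the label full conditionals.

    For each node the conditional is p(z_i = k | .) proportional to
    pi_k * prod_{j != i} theta_{k z_j}^{A_ij} (1 - theta_{k z_j})^{1 - A_ij},
    evaluated in log space.
    """
    A = _as_adjacency(A)
    z = np.asarray(z, dtype=int).copy()
    pi = np.asarray(pi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    K = len(pi)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        lt = np.log(theta)
        l1t = np.log1p(-theta)
    n = len(z)
    for i in range(n):
        zi0 = z - 1
        nbr = A[i].astype(bool).copy()
        nbr[i] = False
        e = np.bincount(zi0[nbr], minlength=K).astype(float)
        tot = np.bincount(zi0, minlength=K).astype(float)
        tot[zi0[i]] -= 1  # exclude node i itself
        logw = log_pi + lt @ e + l1t @ (tot - e)
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        z[i] = rng.choice(K, p=w) + 1
    return z


def canonical_relabel(z) -> np.ndarray:
    """Map labels to first-occurrence order: the first subject gets label 1,
    the first subject in a different community gets label 2, and so on.

    The partition is unchanged; only the naming of communities is fixed,
    which removes label switching across MCMC samples.
    """
    z = np.asarray(z, dtype=int)
    mapping: dict[int, int] = {}
    out = np.empty_like(z)
    for i, lab in enumerate(z):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def collapsed_log_posterior(A, z, config: SBMConfig) -> float:
    """log p(z | A) up to an additive constant, with pi and Theta integrated out.

    The Dirichlet-multinomial term covers the community counts and a
    Beta-function ratio covers each unordered block pair:

        log DM(n_1..n_K; alpha)
        + sum_{r <= s} [ log B(beta1 + m_rs, beta2 + M_rs - m_rs)
                         - log B(beta1, beta2) ].
    """
    A = _as_adjacency(A)
    z = np.asarray(z, dtype=int)
    K = config.k
    alpha = config.alpha
    nk = np.bincount(z - 1, minlength=K).astype(float)
    lp = gammaln(alpha.sum()) - gammaln(alpha.sum() + len(z))
    lp += (gammaln(alpha + nk) - gammaln(alpha)).sum()
    m, M = _block_counts(A, z, K)
    r, s = np.triu_indices(K)
    lp += (betaln(config.beta1 + m[r, s],
                  config.beta2 + M[r, s] - m[r, s])
           - betaln(config.beta1, config.beta2)).sum()
    return float(lp)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class StochasticBlockModel:
    """Bayesian SBM for an undirected binary network.

    Parameters
    ----------
    network : SimilarityNetwork or ndarray
        Symmetric 0/1 adjacency with zero diagonal.
    k : int
        Number of communities K (an upper bound: clusters may empty out
        during sampling).
    alpha : float or array, default 1
        Dirichlet concentration for the community weights.
    beta : (float, float), default (1, 1)
        Beta prior for every connectivity entry.
    """

    def __init__(self, network, k: int, alpha=1.0, beta=(1.0, 1.0)):
        if not isinstance(network, SimilarityNetwork):
            network = SimilarityNetwork(A=np.asarray(network))
        if k > network.n:
            raise ValueError(f"k={k} exceeds the number of nodes n={network.n}")
        self.network = network
        self.k = int(k)
        self.alpha = alpha
        self.beta1, self.beta2 = float(beta[0]), float(beta[1])

    def loglike(self, z, theta) -> float:
        return log_likelihood(self.network, z, theta)

    def fit(self, n_iter: int = 10_000, n_burn: int = 1_000,
            seed: int = 0) -> "SBMResults":
        """Run the Gibbs sampler and summarize the posterior.

        The chain starts from uniformly random labels, alternates the pi,
        Theta and z full-conditional updates, and stores every post-burn
        sample in canonical label form.  The returned results carry the
        MAP partition (collapsed-posterior argmax over stored samples,
        earliest iteration on ties), posterior means and equal-tailed 95%
        credible intervals for Theta, the log likelihood at the point
        estimates, and BIC.
        """
        config = SBMConfig(k=self.k, alpha=self.alpha, beta1=self.beta1,
                           beta2=self.beta2, n_iter=n_iter, n_burn=n_burn,
                           seed=seed)
        net = self.network
        ei, ej = net.edges()
        # CSR adjacency for the kernel
        deg = net.degrees
        indptr = np.zeros(net.n + 1, dtype=np.int64)
        np.cumsum(deg, out=indptr[1:])
        indices = np.nonzero(net.A)[1].astype(np.int64)
        logger.info("fitting SBM: n=%d K=%d iter=%d burn=%d seed=%d",
                    net.n, config.k, n_iter, n_burn, seed)
        z_s, pi_s, th_s, lp_s = _engine.run_chain(
            indptr, indices, ei, ej, net.n, config.k,
            config.alpha.astype(np.float64), float(self.beta1),
            float(self.beta2), int(n_iter), int(n_burn),
            int(seed) % (2 ** 31))
        samples = PosteriorSamples(z=z_s.astype(np.int32) + 1, pi=pi_s,
                                   theta=th_s, log_post=lp_s)
        return SBMResults(model=self, config=config, samples=samples)


class SBMResults:
    """Posterior summaries of a fitted stochastic block model.

    Attributes
    ----------
    z_map : (n,) int array
        Canonical MAP community labels (1-based).
    theta_mean : (K, K) array
        Posterior mean connectivity matrix.
    theta_ci_low, theta_ci_high : (K, K) arrays
        Equal-tailed 2.5% / 97.5% posterior quantiles.
    log_lik_at_map : float
        Bernoulli log likelihood at (z_map, theta_mean).
    bic : float
        -2 logL + p log M with p = K(K+1)/2 + (K-1) free parameters and
        M = n(n-1)/2 dyads.
    """

    def __init__(self, model: StochasticBlockModel, config: SBMConfig,
                 samples: PosteriorSamples):
        self.model = model
        self.config = config
        self.samples = samples
        best = int(np.argmax(samples.log_post))  # argmax -> earliest on ties
        self.map_index = best
        self.z_map = samples.z[best].astype(int)
        self.theta_mean = samples.theta.mean(axis=0)
        self.theta_ci_low = np.quantile(samples.theta, 0.025, axis=0)
        self.theta_ci_high = np.quantile(samples.theta, 0.975, axis=0)
        self.log_lik_at_map = log_likelihood(
            model.network, self.z_map, self.theta_mean)
        self.bic = bic(model.network, self, config.k)

    @property
    def k(self) -> int:
        return self.config.k

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.z_map - 1, minlength=self.k)

    # phenotyping conveniences delegate to the phenotype module
    def uncertainty(self) -> np.ndarray:
        from .phenotype import uncertainty

        return uncertainty(self.samples, self.z_map)

    def vulnerability(self, k_v: int) -> np.ndarray:
        from .phenotype import vulnerability_score

        return vulnerability_score(self.samples, k_v)

    def connectivity_summary(self):
        from .phenotype import connectivity_summary

        return connectivity_summary(self.samples)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = []
        n, K = self.samples.n, self.k
        lines.append("Bayesian stochastic block model (Gibbs)")
        lines.append("=" * 46)
        lines.append(f"nodes: {n}   edges: {self.model.network.n_edges}   K: {K}")
        lines.append(
            f"iterations: {self.config.n_iter} (burn-in {self.config.n_burn},"
            f" {self.samples.S} kept)   seed: {self.config.seed}")
        lines.append(f"log-likelihood (MAP): {self.log_lik_at_map:.2f}"
                     f"   BIC: {self.bic:.2f}")
        lines.append("cluster sizes: " + ", ".join(
            f"{k + 1}: {c}" for k, c in enumerate(self.cluster_sizes)))
        lines.append("")
        lines.append("connectivity Theta (posterior mean [95% CI]):")
        for r in range(K):
            for s in range(r, K):
                lines.append(
                    f"  theta[{r + 1},{s + 1}] = {self.theta_mean[r, s]:.4f} "
                    f"[{self.theta_ci_low[r, s]:.4f}, "
                    f"{self.theta_ci_high[r, s]:.4f}]")
        return "\n".join(lines)

    def plot_connectivity(self, ax=None):
        """Heatmap of the posterior mean connectivity matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.theta_mean, vmin=0, cmap="viridis")
        ax.set_xlabel("community")
        ax.set_ylabel("community")
        ax.set_xticks(range(self.k), [str(k + 1) for k in range(self.k)])
        ax.set_yticks(range(self.k), [str(k + 1) for k in range(self.k)])
        ax.figure.colorbar(im, ax=ax, label=r"posterior mean $\theta_{rs}$")
        return ax

    def to_json(self, path) -> None:
        out = {
            "z_map": self.z_map.tolist(),
            "theta_mean": self.theta_mean.tolist(),
            "theta_ci_low": self.theta_ci_low.tolist(),
            "theta_ci_high": self.theta_ci_high.tolist(),
            "log_lik_at_map": self.log_lik_at_map,
            "bic": self.bic,
            "config": self.config.to_dict(),
            "notes": {
                "bic": "p = K(K+1)/2 + (K-1) parameters; M = n(n-1)/2 dyads; "
                       "likelihood at (z_map, theta_mean)",
                "credible_interval": "equal-tailed sample quantiles, linear "
                                     "interpolation between order statistics",
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(out, fh, indent=2)


# ---------------------------------------------------------------------------
# functional interface and model selection
# ---------------------------------------------------------------------------

def fit_sbm(network, config: SBMConfig) -> tuple[SBMResults, PosteriorSamples]:
    """Fit the SBM under ``config`` and return (results, posterior samples)."""
    model = StochasticBlockModel(network, k=config.k, alpha=config.alpha,
                                 beta=(config.beta1, config.beta2))
    res = model.fit(n_iter=config.n_iter, n_burn=config.n_burn,
                    seed=config.seed)
    return res, res.samples


def bic(network, fit, k: int) -> float:
    """BIC = -2 logL(z_map, theta_mean) + p log M.

    Free parameters p = K(K+1)/2 connectivity entries + (K-1) community
    weights; effective sample size M = n(n-1)/2 observed dyads.
    """
    if isinstance(fit, SBMResults):
        ll = fit.log_lik_at_map
        n = fit.samples.n
    else:  # (z_map, theta_mean) pair
        z_map, theta_mean = fit
        ll = log_likelihood(network, z_map, theta_mean)
        n = len(np.asarray(z_map))
    p = k * (k + 1) / 2 + (k - 1)
    M = n * (n - 1) / 2
    return float(-2.0 * ll + p * np.log(M))


def select_k(network, k_range, config: SBMConfig | None = None,
             **fit_kw) -> pd.DataFrame:
    """Fit the SBM for each K in ``k_range`` and tabulate BIC.

    Each K gets an independent chain with seed ``config.seed + K`` so sweeps
    are reproducible without seed collisions.  Returns a DataFrame sorted by
    K with columns ``K``, ``bic``, ``log_lik``, ``fit`` (the SBMResults) and
    a boolean ``best`` flagging the BIC argmin.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    base = config or SBMConfig(k=max(k_range), **fit_kw)
    rows = []
    for k in k_range:
        if not 1 <= k <= (network.n if hasattr(network, "n") else len(network)):
            raise ValueError(f"K={k} outside [1, n]")
        seed_k = (base.seed + k) % (2 ** 31)
        logger.info("select_k: fitting K=%d with seed %d", k, seed_k)
        cfg = SBMConfig(k=k, alpha=float(np.asarray(base.alpha).flat[0]),
                        beta1=base.beta1, beta2=base.beta2,
                        n_iter=base.n_iter, n_burn=base.n_burn, seed=seed_k)
        res, _ = fit_sbm(network, cfg)
        rows.append({"K": k, "bic": res.bic, "log_lik": res.log_lik_at_map,
                     "fit": res})
    tab = pd.DataFrame(rows).sort_values("K", ignore_index=True)
    tab["best"] = tab["bic"] == tab["bic"].min()
    return tab
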