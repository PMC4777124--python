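"""Bayesian estimation of per-population divergence from ancestral allele
frequencies (the drift parameter "c") by Metropolis-within-Gibbs MCMC.

Model: for locus j and population i, the latent population frequency is a
censored normal around the ancestral frequency,

    p_ij = clip(y_ij, 0, 1),   y_ij ~ Normal(pi_j, c_i * pi_j * (1 - pi_j))

with observed haploid allele counts x_ij ~ Binomial(n_ij, p_ij). Tail mass of
y below 0 / above 1 supplies the point masses at fixed frequencies. Priors are
uniform on (0, 1) for both pi_j and c_i.

Each sweep updates every y_ij (normal random walk), every pi_j (Dirichlet-
style Beta proposal with concentration m centered on the current value), and
every c_i (log-scale random walk, scale adapted during burn-in only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .genodata import HOM_ALT, HOM_REF, GenotypeMatrix

__all__ = ["NicholsonCounts", "CPosterior", "nicholson_counts", "fit_nicholson_c", "c_density_summary", "moment_drift_estimate"]


class NicholsonError(ValueError):
    pass


@dataclass
class NicholsonCounts:
    """Observed haploid allele counts x and sample sizes n, loci x populations."""

    populations: list[str]
    x: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.x.shape != self.n.shape:
            raise NicholsonError("x and n shapes differ")
        if np.any(self.x > self.n) or np.any(self.x < 0):
            raise NicholsonError("allele counts must satisfy 0 <= x <= n")


@dataclass
class CPosterior:
    """Retained MCMC samples of c per population, with summaries and diagnostics."""

    populations: list[str]
    samples: np.ndarray  # (run_length, K)
    burn_in: int
    seed: int
    acceptance: dict[str, float]

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    @property
    def median(self) -> np.ndarray:
        return np.median(self.samples, axis=0)

    def interval(self, level: float = 0.95) -> np.ndarray:
        lo = (1 - level) / 2
        return np.quantile(self.samples, [lo, 1 - lo], axis=0).T

    def summary(self) -> pd.DataFrame:
        ci = self.interval()
        return pd.DataFrame(
            {
                "population": self.populations,
                "mean": self.mean,
                "median": self.median,
                "q2.5": ci[:, 0],
                "q97.5": ci[:, 1],
            }
        )


def nicholson_counts(g: GenotypeMatrix, groups: dict[str, list[str]]) -> NicholsonCounts:
    """Haploid allele counts per population, dropping loci monomorphic in the pooled
    group or untyped in any population."""
    names = sorted(groups)
    xs, ns = [], []
    for name in names:
        rows = g.accession_index(groups[name])
        sub = g.calls[rows]
        ref = np.sum(sub == HOM_REF, axis=0).astype(float)
        alt = np.sum(sub == HOM_ALT, axis=0).astype(float)
        xs.append(ref)
        ns.append(ref + alt)
    x = np.stack(xs, axis=1)
    n = np.stack(ns, axis=1)
    tot_x, tot_n = x.sum(axis=1), n.sum(axis=1)
    keep = (n.min(axis=1) > 0) & (tot_x > 0) & (tot_x < tot_n)
    return NicholsonCounts(populations=names, x=x[keep], n=n[keep])


def _binom_loglik(x, n, p):
    return xlogy(x, p) + xlogy(n - x, 1.0 - p)


def _normal_logpdf(y, mu, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (y - mu) ** 2 / var)


def _beta_logpdf(z, a, b):
    return gammaln(a + b) - gammaln(a) - gammaln(b) + xlogy(a - 1.0, z) + xlogy(b - 1.0, 1.0 - z)


def fit_nicholson_c(
    counts: NicholsonCounts,
    burn_in: int = 1000,
    run_length: int = 10000,
    m: float = 10.0,
    seed: int = 0,
    min_loci: int = 50,
) -> CPosterior:
    """Run the MCMC and return the posterior over c for every population.

    Deterministic for a fixed seed. Proposal scales for the frequency and
    drift random walks adapt every 100 sweeps during burn-in and are frozen
    afterwards so the retained chain is Markovian.
    """
    x, n = counts.x, counts.n
    L, K = x.shape
    if K < 2:
        raise NicholsonError("need >= 2 populations")
    if L < min_loci:
        raise NicholsonError(f"need >= {min_loci} polymorphic loci, got {L}")

    rng = np.random.default_rng(seed)
    eps = 1e-6

    # moment initialization
    pi = np.clip(x.sum(axis=1) / n.sum(axis=1), eps, 1 - eps)
    p_obs = x / n
    with np.errstate(invalid="ignore"):
        c = np.clip(
            np.nanmean((p_obs - pi[:, None]) ** 2 / (pi * (1 - pi))[:, None], axis=0),
            1e-3,
            0.9,
        )
    y = p_obs.copy()

    scale_y = np.full(K, 0.05)
    scale_c = np.full(K, 0.3)

    def prior_y_ll(y_, pi_, c_):
        var = c_[None, :] * (pi_ * (1 - pi_))[:, None]
        return _normal_logpdf(y_, pi_[:, None], var)

    lik = _binom_loglik(x, n, np.clip(y, 0.0, 1.0))
    pri = prior_y_ll(y, pi, c)
    if not np.all(np.isfinite(lik + pri)):
        # re-initialize from pure moment estimates nudged into support
        y = np.clip(p_obs, eps, 1 - eps)
        lik = _binom_loglik(x, n, y)
        pri = prior_y_ll(y, pi, c)

    total = burn_in + run_length
    samples = np.empty((run_length, K))
    acc_y = np.zeros(K)
    acc_pi = 0.0
    acc_c = np.zeros(K)
    adapt_y = np.zeros(K)
    adapt_c = np.zeros(K)
    n_since_adapt = 0

    for it in range(total):
        # --- update latent frequencies y_ij (elementwise MH) ---
        prop = y + rng.standard_normal((L, K)) * scale_y[None, :]
        lik_p = _binom_loglik(x, n, np.clip(prop, 0.0, 1.0))
        pri_p = prior_y_ll(prop, pi, c)
        log_a = (lik_p + pri_p) - (lik + pri)
        accept = np.log(rng.random((L, K))) < log_a
        y = np.where(accept, prop, y)
        lik = np.where(accept, lik_p, lik)
        pri = np.where(accept, pri_p, pri)
        frac = accept.mean(axis=0)
        acc_y += frac
        adapt_y += frac

        # --- update ancestral frequencies pi_j (Beta proposal, concentration m) ---
        pi_p = np.clip(rng.beta(m * pi, m * (1.0 - pi)), eps, 1 - eps)
        pri_p = prior_y_ll(y, pi_p, c)
        # proposal density ratio q(pi | pi') / q(pi' | pi)
        log_q_fwd = _beta_logpdf(pi_p, m * pi, m * (1.0 - pi))
        log_q_rev = _beta_logpdf(pi, m * pi_p, m * (1.0 - pi_p))
        log_a = (pri_p - pri).sum(axis=1) + log_q_rev - log_q_fwd
        accept_pi = np.log(rng.random(L)) < log_a
        pi = np.where(accept_pi, pi_p, pi)
        pri = np.where(accept_pi[:, None], pri_p, pri)
        acc_pi += accept_pi.mean()

        # --- update drift parameters c_i (log random walk, uniform(0,1) prior) ---
        c_p = c * np.exp(rng.standard_normal(K) * scale_c)
        pri_p = prior_y_ll(y, pi, c_p)
        log_a = (pri_p - pri).sum(axis=0) + np.log(c_p / c)
        log_a[c_p >= 1.0] = -np.inf
        accept_c = np.log(rng.random(K)) < log_a
        c = np.where(accept_c, c_p, c)
        pri = np.where(accept_c[None, :], pri_p, pri)
        acc_c += accept_c
        adapt_c += accept_c

        # --- adapt proposal scales during burn-in only ---
        n_since_adapt += 1
        if it < burn_in and n_since_adapt == 100:
            ra = adapt_y / n_since_adapt
            scale_y *= np.where(ra < 0.2, 0.7, np.where(ra > 0.5, 1.4, 1.0))
            rc = adapt_c / n_since_adapt
            scale_c *= np.where(rc < 0.15, 0.7, np.where(rc > 0.5, 1.4, 1.0))
            adapt_y[:] = 0.0
            adapt_c[:] = 0.0
            n_since_adapt = 0
        elif it == burn_in - 1:
            n_since_adapt = 0

        if it >= burn_in:
            samples[it - burn_in] = c

    acceptance = {
        "y": float(np.mean(acc_y) / total),
        "pi": float(acc_pi / total),
        "c": float(np.mean(acc_c) / total),
    }
    return CPosterior(
        populations=list(counts.populations),
        samples=samples,
        burn_in=burn_in,
        seed=seed,
        acceptance=acceptance,
    )


def c_density_summary(post: CPosterior, n_bins: int = 50) -> pd.DataFrame:
    """Histogram density of the c posterior per population on a fixed bin grid."""
    rows = []
    for k, pop in enumerate(post.populations):
        s = post.samples[:, k]
        lo, hi = float(s.min()), float(s.max())
        if lo == hi:  # degenerate chain: point mass
            rows.append({"population": pop, "bin_mid": lo, "density_mass": 1.0})
            continue
        hist, edges = np.histogram(s, bins=n_bins, range=(lo, hi))
        mass = hist / hist.sum()
        mids = 0.5 * (edges[:-1] + edges[1:])
        for bm, ms in zip(mids, mass):
            rows.append({"population": pop, "bin_mid": float(bm), "density_mass": float(ms)})
    return pd.DataFrame(rows)


def gelman_rubin(chains: list[CPosterior]) -> np.ndarray:
    """Split-free multi-chain R-hat per population from independent seeded runs."""
    if len(chains) < 2:
        raise NicholsonError("R-hat needs >= 2 chains")
    s = np.stack([c.samples for c in chains])  # (m, n, K)
    m, n, _ = s.shape
    chain_means = s.mean(axis=1)
    w = s.var(axis=1, ddof=1).mean(axis=0)
    b = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return np.sqrt(var_hat / w)


def moment_drift_estimate(p: np.ndarray, pi: np.ndarray) -> float:
    """Independent moment oracle: mean over loci of (p - pi)^2 / (pi (1 - pi))."""
    pi = np.asarray(pi, dtype=float)
    p = np.asarray(p, dtype=float)
    return float(np.mean((p - pi) ** 2 / (pi * (1 - pi))))
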