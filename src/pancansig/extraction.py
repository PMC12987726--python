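"""De novo signature extraction: KL-NMF with multi-restart stability and AIC.

Catalogues are factorized as X ~ Poisson(S A) with S channels x k
column-stochastic and A k x samples non-negative, by multiplicative updates
minimizing the generalized Kullback-Leibler divergence (the Poisson deviance
up to constants). One consensus solution per candidate k is formed from the
best-likelihood restart; the remaining restarts are matched to it by greedy
maximum-cosine pairing, giving the stability score and the per-channel
across-restart variance that the pan-cancer combiner consumes as inverse
weights.

Model selection offers the AIC rule used for SV signatures,

    AIC = 2 K (n + M) - 2 * sum(X * log(lambda) - lambda),  lambda = S A,

(Poisson log-likelihood without the log-factorial constant; K signatures,
n samples, M mutation channels) and a stability rule (largest k that is
stable and significantly improves per-sample reconstruction error over k-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_EPS = np.finfo(float).tiny


@dataclass
class NmfSolution:
    """One factorization at a fixed signature count k."""

    k: int
    S: np.ndarray                # channels x k, column-stochastic
    A: np.ndarray                # k x samples, non-negative
    loglik: float                # constant-free Poisson log-likelihood
    stability: float = 1.0      # mean matched cosine across restarts
    channel_variance: np.ndarray | None = None  # channels x k across restarts
    sample_errors: np.ndarray | None = None     # per-sample KL reconstruction error
    channels: list | None = None
    samples: list | None = None

    def signatures_frame(self, prefix: str = "S") -> pd.DataFrame:
        index = self.channels if self.channels is not None else range(self.S.shape[0])
        return pd.DataFrame(self.S, index=index,
                            columns=[f"{prefix}{i + 1}" for i in range(self.k)])

    def activities_frame(self, prefix: str = "S") -> pd.DataFrame:
        cols = self.samples if self.samples is not None else range(self.A.shape[1])
        return pd.DataFrame(self.A.T, index=cols,
                            columns=[f"{prefix}{i + 1}" for i in range(self.k)])


def poisson_loglik(X: np.ndarray, rates: np.ndarray) -> float:
    """sum(X * log(lambda) - lambda), with 0*log(0) = 0."""
    rates = np.maximum(rates, _EPS)
    return float(np.sum(X * np.log(rates) - rates))


def kl_divergence(X: np.ndarray, rates: np.ndarray) -> float:
    """Generalized KL divergence D(X || lambda) >= 0."""
    rates = np.maximum(rates, _EPS)
    Xp = np.maximum(X, _EPS)
    return float(np.sum(X * np.log(Xp / rates) - X + rates))


def nmf_kl(X, k: int, seed: int = 0, max_iter: int = 10_000,
           tol: float = 1e-8) -> NmfSolution:
    """Multiplicative-update KL-NMF of a samples x channels catalogue.

    The objective (generalized KL divergence) is non-increasing across
    updates; this is asserted every 100 iterations. Convergence is declared
    when the relative objective decrease over 10 iterations falls below
    ``tol``. S is rescaled column-stochastic with a compensating rescale of A.
    """
    channels = samples = None
    if isinstance(X, pd.DataFrame):
        channels, samples = list(X.columns), list(X.index)
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("catalogue must be non-negative")
    if X.sum() == 0:
        raise ValueError("catalogue is identically zero")
    V = X.T  # channels x samples
    n_channels, n_samples = V.shape
    if not 1 <= k <= min(n_channels, n_samples):
        raise ValueError(f"k must lie in [1, {min(n_channels, n_samples)}]")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(0.1, 1.0, (n_channels, k)) * scale
    H = rng.uniform(0.1, 1.0, (k, n_samples)) * scale

    prev_obj = kl_divergence(V, W @ H)
    check_obj = prev_obj
    for iteration in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
        WH = np.maximum(W @ H, _EPS)
        H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0), _EPS)[:, None]
        if iteration % 10 == 0:
            obj = kl_divergence(V, W @ H)
            if iteration % 100 == 0:
                assert obj <= check_obj + 1e-6 * max(1.0, abs(check_obj)), \
                    "KL objective increased"
                check_obj = obj
            if prev_obj - obj <= tol * max(1.0, abs(prev_obj)):
                break
            prev_obj = obj

    col_sums = np.maximum(W.sum(axis=0), _EPS)
    S = W / col_sums
    A = H * col_sums[:, None]
    rates = S @ A
    sample_errors = np.array([
        kl_divergence(V[:, j], rates[:, j]) for j in range(n_samples)
    ])
    return NmfSolution(k=k, S=S, A=A, loglik=poisson_loglik(V, rates),
                       sample_errors=sample_errors,
                       channels=channels, samples=samples)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def greedy_match(reference: np.ndarray, candidate: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy maximum-cosine bipartite pairing of columns.

    Returns (reference column, candidate column, cosine) triples; each column
    is used at most once, pairs taken in decreasing cosine order.
    """
    k_ref, k_cand = reference.shape[1], candidate.shape[1]
    sims = np.array([[cosine_similarity(reference[:, i], candidate[:, j])
                      for j in range(k_cand)] for i in range(k_ref)])
    order = np.dstack(np.unravel_index(np.argsort(sims, axis=None)[::-1],
                                       sims.shape))[0]
    used_ref: set[int] = set()
    used_cand: set[int] = set()
    pairs = []
    for i, j in order:
        if i in used_ref or j in used_cand:
            continue
        pairs.append((int(i), int(j), float(sims[i, j])))
        used_ref.add(int(i))
        used_cand.add(int(j))
        if len(pairs) == min(k_ref, k_cand):
            break
    return pairs


def extract(X, k_range, n_restarts: int = 10, seed: int = 0,
            max_iter: int = 10_000, tol: float = 1e-8) -> list[NmfSolution]:
    """One consensus NmfSolution per k, with restart stability and variance.

    Restart r uses seed ``seed + r``; the best-log-likelihood restart is the
    consensus and the others are matched to it by greedy cosine pairing.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k range")
    if n_restarts < 2:
        raise ValueError("need at least 2 restarts for stability")
    solutions = []
    for k in ks:
        restarts = [nmf_kl(X, k, seed=seed + r, max_iter=max_iter, tol=tol)
                    for r in range(n_restarts)]
        best = max(restarts, key=lambda s: s.loglik)
        matched_cols = [[] for _ in range(k)]
        cosines = []
        for restart in restarts:
            if restart is best:
                continue
            for i, j, sim in greedy_match(best.S, restart.S):
                cosines.append(sim)
                matched_cols[i].append(restart.S[:, j])
        best.stability = float(np.mean(cosines)) if cosines else 1.0
        variance = np.zeros_like(best.S)
        for i in range(k):
            stack = np.column_stack([best.S[:, i]] + matched_cols[i])
            variance[:, i] = stack.var(axis=1)
        best.channel_variance = variance
        solutions.append(best)
    return solutions


def aic(solution: NmfSolution) -> float:
    """2 K (n + M) - 2 * (constant-free Poisson log-likelihood)."""
    n_channels, _ = solution.S.shape
    _, n_samples = solution.A.shape
    return 2.0 * solution.k * (n_samples + n_channels) - 2.0 * solution.loglik


def select_k_aic(solutions: list[NmfSolution]) -> NmfSolution:
    """Minimum-AIC candidate; ties broken toward smaller k."""
    if not solutions:
        raise ValueError("no candidate solutions")
    return min(solutions, key=lambda s: (aic(s), s.k))


def select_k_stability(solutions: list[NmfSolution],
                       min_stability: float = 0.8,
                       alpha: float = 0.05) -> NmfSolution:
    """Largest k that is stable and significantly improves reconstruction.

    A candidate k qualifies when its stability >= ``min_stability`` and its
    per-sample reconstruction errors improve over the k-1 candidate (one-sided
    Wilcoxon rank-sum p < alpha). Falls back to the smallest k when none
    qualifies.
    """
    if not solutions:
        raise ValueError("no candidate solutions")
    by_k = {s.k: s for s in solutions}
    ordered = sorted(by_k)
    selected = by_k[ordered[0]]
    for k in ordered:
        sol = by_k[k]
        if sol.stability < min_stability:
            continue
        prev = by_k.get(k - 1)
        if prev is not None:
            p = stats.ranksums(sol.sample_errors, prev.sample_errors,
                               alternative="less").pvalue
            if p >= alpha:
                continue
        selected = sol
    return selected
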