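"""Clonal/subclonal attribution of mutations to signatures and timing tests.

Individual mutations cannot be assigned deterministically to a signature when
several active signatures can produce the same mutation class; instead each
(class, sample) cell's clonal and subclonal counts are shared among signatures
in proportion to the expected fraction

    rho_ckp = S_ck A_kp / sum_k' S_ck' A_k'p,

giving per-signature timed counts N_kpt = sum_c rho_ckp M_cpt and per-sample
subclonal fractions f_kp = N_kp1 / (N_kp0 + N_kp1). Within a cohort, each
signature's f values are ranked against those of all other signatures: a mean
rank below 0.5 marks a relatively early (clonal) signature, above 0.5 a
relatively late one; significance is a two-sided Mann-Whitney U test. The same
operations serve the early-/late-clonal split by relabeling the two timing
classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TimingResult:
    """Attributed timed counts and subclonal fractions.

    ``n_clonal``/``n_subclonal`` are signatures x samples; ``subclonal_fraction``
    holds f_kp (NaN where a signature has no attributed mutations).
    """

    n_clonal: pd.DataFrame
    n_subclonal: pd.DataFrame
    subclonal_fraction: pd.DataFrame


def attribution_fractions(signatures: pd.DataFrame, activities: pd.DataFrame
                          ) -> np.ndarray:
    """rho_ckp tensor (channels x signatures x samples).

    Cells with zero denominator (no active signature covers the channel) are
    NaN and must not coincide with nonzero mutation counts downstream.
    """
    S = signatures.to_numpy(dtype=float)        # channels x k
    A = activities.to_numpy(dtype=float).T      # k x samples
    if np.any(S < 0) or np.any(A < 0):
        raise ValueError("signatures and activities must be non-negative")
    if S.shape[1] != A.shape[0]:
        raise ValueError("signature count mismatch between S and A")
    weighted = S[:, :, None] * A[None, :, :]    # c x k x p
    denom = weighted.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = weighted / denom
    rho[np.broadcast_to(denom == 0, rho.shape)] = np.nan
    return rho


def signature_timing(rho: np.ndarray, timing: "object") -> TimingResult:
    """Weight clonal/subclonal counts by rho to attribute them to signatures.

    ``timing`` is a TimingCounts (clonal/subclonal samples x channels frames).
    Additivity holds exactly: sum_k N_kpt = sum_c M_cpt per sample and class.
    """
    clonal = timing.clonal
    subclonal = timing.subclonal
    M = np.stack([clonal.to_numpy(dtype=float).T,
                  subclonal.to_numpy(dtype=float).T])  # t x c x p
    undefined = np.isnan(rho[:, 0, :])
    if np.any((M.sum(axis=0) > 0) & undefined):
        raise ValueError("attribution fractions undefined at nonzero counts")
    rho_filled = np.nan_to_num(rho)
    # N_kpt = sum_c rho_ckp * M_cpt
    N = np.einsum("ckp,tcp->tkp", rho_filled, M)
    samples = clonal.index
    n_sig = rho.shape[1]
    sig_names = [f"S{i + 1}" for i in range(n_sig)]
    n_clonal = pd.DataFrame(N[0], index=sig_names, columns=samples)
    n_subclonal = pd.DataFrame(N[1], index=sig_names, columns=samples)
    total = N[0] + N[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, N[1] / total, np.nan)
    return TimingResult(n_clonal=n_clonal, n_subclonal=n_subclonal,
                        subclonal_fraction=pd.DataFrame(f, index=sig_names,
                                                        columns=samples))


def timing_test(f_matrix: pd.DataFrame, signature: str,
                min_subclonal: int = 0,
                n_subclonal: pd.DataFrame | None = None
                ) -> tuple[float, float]:
    """Rank one signature's subclonal fractions against all other signatures.

    Returns (two-sided Mann-Whitney U p-value, mean rank scaled to (0, 1)).
    Samples with fewer than ``min_subclonal`` subclonal mutations attributed
    to the signature are excluded from the test (they remain attributed).
    Ties take midranks.
    """
    if signature not in f_matrix.index:
        raise ValueError(f"unknown signature {signature!r}")
    own = f_matrix.loc[signature].to_numpy(dtype=float)
    if min_subclonal and n_subclonal is not None:
        own = own[n_subclonal.loc[signature].to_numpy() >= min_subclonal]
    own = own[~np.isnan(own)]
    others = f_matrix.drop(index=signature).to_numpy(dtype=float).ravel()
    others = others[~np.isnan(others)]
    if own.size == 0 or others.size == 0:
        raise ValueError("no defined subclonal fractions to compare")
    pooled = np.concatenate([own, others])
    ranks = stats.rankdata(pooled)  # midranks
    mean_rank = float(ranks[:own.size].mean() / pooled.size)
    method = "exact" if (own.size <= 20 and others.size <= 20
                         and np.unique(pooled).size == pooled.size) else "asymptotic"
    mwu = stats.mannwhitneyu(own, others, alternative="two-sided", method=method)
    return float(mwu.pvalue), mean_rank


def cohort_timing_table(result: TimingResult, min_subclonal: int = 20
                        ) -> pd.DataFrame:
    """Per-signature cohort summary: n_samples, median f, mean rank, MWU p."""
    f = result.subclonal_fraction
    rows = []
    for sig in f.index:
        defined = f.loc[sig].dropna()
        try:
            p, mean_rank = timing_test(f, sig, min_subclonal=min_subclonal,
                                       n_subclonal=result.n_subclonal)
        except ValueError:
            p, mean_rank = np.nan, np.nan
        rows.append((sig, len(defined), float(defined.median()) if len(defined) else np.nan,
                     mean_rank, p))
    return pd.DataFrame(rows, columns=["signature", "n_samples", "median_f",
                                       "mean_rank", "mwu_p"]).set_index("signature")
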