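"""Cross-cohort aggregation of association evidence into pan-cancer z-scores.

Cohort-level p-values are converted to 1-df chi-square z-scores, summed across
tumor groups into a chi-square statistic with as many degrees of freedom as
groups, converted back to an aggregate p and a single-df z carrying the common
effect direction. Evidence sets whose significant members disagree in sign are
not aggregated, a min-p binomial correction accounts for multiple tests per
cohort, and a factor-of-20 confound filter discards targets far less
significant than the best target for the same signature. Also provides the
homologous-recombination-deficiency indicator (nonzero activity in at least
two of SBS3, ID6 and CN17).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class CohortEvidence:
    """One cohort's contribution to a (signature, target) evidence set."""

    cohort: str
    p: float
    direction: int               # +1 or -1
    significant: bool = False    # study-wide significant in this cohort
    n_tests: int = 1             # tests considered (min-p binomial correction)

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


@dataclass
class AggregateResult:
    z: float                     # signed single-df z (0 when not kept)
    p: float
    statistic: float             # sum of squared cohort z-scores
    df: int
    kept: bool
    reason: str = ""


def p_to_z(p: float) -> float:
    """z = sqrt(inverse survival of chi-square(1) at p); z >= 0."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    return float(np.sqrt(stats.chi2.isf(p, df=1)))


def min_p_binomial(p_min: float, n_tests: int) -> float:
    """P(at least one of n_tests tests attains a p below p_min) = 1-(1-p)^T."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 <= p_min <= 1.0:
        raise ValueError("p_min must lie in [0, 1]")
    return float(1.0 - (1.0 - p_min) ** n_tests)


def combine_groups(evidence: list[CohortEvidence],
                   positive_only: bool = False) -> AggregateResult:
    """Aggregate cohort evidence for one (signature, target) pair.

    Cohort p-values (min-p corrected where several tests were considered) are
    squared-z summed into a chi-square statistic with df = number of cohorts.
    Sets whose significant members disagree in direction are returned with
    kept=False; with ``positive_only`` (DNA-repair-gene targets) negative
    evidence sets are likewise dropped.
    """
    if not evidence:
        raise ValueError("empty evidence set")
    signif_dirs = {e.direction for e in evidence if e.significant}
    if len(signif_dirs) > 1:
        return AggregateResult(z=0.0, p=1.0, statistic=np.nan, df=len(evidence),
                               kept=False, reason="discordant directions")
    sign = signif_dirs.pop() if signif_dirs else max(
        (e for e in evidence), key=lambda e: p_to_z(e.p)).direction
    if positive_only and sign < 0:
        return AggregateResult(z=0.0, p=1.0, statistic=np.nan, df=len(evidence),
                               kept=False, reason="negative direction excluded")
    stat = 0.0
    for e in evidence:
        p = min_p_binomial(e.p, e.n_tests) if e.n_tests > 1 else e.p
        stat += p_to_z(p) ** 2
    df = len(evidence)
    p_agg = float(stats.chi2.sf(stat, df=df))
    z = sign * p_to_z(max(p_agg, np.nextafter(0, 1)))
    return AggregateResult(z=z, p=p_agg, statistic=stat, df=df, kept=True)


def confound_filter(results: dict[str, float], factor: float = 20.0
                    ) -> dict[str, float]:
    """Keep targets whose aggregate p is within ``factor`` of the family minimum.

    ``results`` maps target -> aggregate p within one association family for
    one signature; correlated targets (for example inactivation of co-mutated
    genes) far less significant than the best target are discarded.
    """
    if not results:
        raise ValueError("empty result family")
    p_min = min(results.values())
    return {target: p for target, p in results.items() if p <= factor * p_min}


def hrd_flag(sbs3: float, id6: float, cn17: float) -> bool:
    """HRD indicator: nonzero activity in at least two of SBS3, ID6, CN17."""
    return sum(a > 0 for a in (sbs3, id6, cn17)) >= 2
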