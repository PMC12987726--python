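"""Copy-number profile QC from SNV VAF distributions.

Given a tumor's copy-number segmentation restricted to the five simple clonal
states (1:1, 1:0, 2:2, 2:1, 2:0), the VAF of a clonal SNV of multiplicity m in
a state of total ploidy psi at sample purity rho concentrates at

    VAF(rho, m, psi) = rho * m / (2 * (1 - rho) + rho * psi).

Observed VAF-density peaks are matched to these expectations; each matched
peak inverts to a peak-wise purity estimate, and the SNV-weighted discrepancy
eta between those estimates and the input purity scores profile quality. A
failing profile is re-attempted (at most three times) with the re-estimated
purity and the correspondingly rescaled ploidy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import argrelextrema

_ALLOWED_STATES = {(1, 1), (1, 0), (2, 2), (2, 1), (2, 0)}

#: QC criteria, in the order they are evaluated.
CRITERIA = (
    "vaf_peaks_at_expected_locations",   # eta < 5%
    "clonal_cluster_present",            # CCF in [0.9, 1.1] holding >= 5% of SNVs
    "no_superclonal_cluster",            # no CCF > 1.1 cluster with >= 5% of SNVs
    "tetraploid_mult1_peak",             # 2:2-dominated genomes show an m=1 peak
    "no_large_homozygous_deletion",      # no homozygous deletion > 10 Mb
)


class InsufficientDataError(ValueError):
    """Raised when too few VAFs exist to detect peaks; maps to a QC fail."""


@dataclass(frozen=True)
class CNState:
    """One of the five considered clonal copy-number states."""

    major: int
    minor: int
    n_snvs: int = 0

    def __post_init__(self) -> None:
        if (self.major, self.minor) not in _ALLOWED_STATES:
            raise ValueError(
                f"state {self.major}:{self.minor} not in the considered set "
                "{1:1, 1:0, 2:2, 2:1, 2:0}"
            )
        if self.n_snvs < 0:
            raise ValueError("n_snvs must be non-negative")

    @property
    def state_ploidy(self) -> int:
        return self.major + self.minor

    @property
    def legal_multiplicities(self) -> tuple[int, ...]:
        # multiplicity 2 requires two copies of one parental allele
        return (1, 2) if self.major >= 2 else (1,)

    @property
    def q(self) -> int:
        """Number of considered multiplicities for the state."""
        return len(self.legal_multiplicities)


@dataclass
class VAFDataset:
    """Per-SNV VAF table plus the sample's purity/ploidy estimates.

    ``snvs`` columns: major, minor, alt_reads, total_reads, vaf (and, for
    synthetic data, the true multiplicity). ``true_purity`` is carried by the
    generator for recovery tests and never consulted by the QC itself.
    """

    snvs: "object"  # pandas DataFrame
    purity_estimate: float
    ploidy_estimate: float
    true_purity: float | None = None
    homdel_max_len: float = 0.0
    tetraploid: bool | None = None

    @property
    def n_all(self) -> int:
        return len(self.snvs)


@dataclass
class QCResult:
    rho_new: float | None
    psi_new: float | None
    eta: float | None
    criteria: dict[str, bool]
    passed: bool
    attempts: int = 1
    excluded: bool = False


# ---------------------------------------------------------------------------
# Stage II formulas

def expected_peak_vafs(rho: float, state: CNState) -> list[tuple[int, float]]:
    """Expected VAF peak per legal multiplicity: rho*m / (2(1-rho) + rho*psi_v)."""
    if not 0.0 < rho <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    psi_v = state.state_ploidy
    denom = 2.0 * (1.0 - rho) + rho * psi_v
    return [(m, rho * m / denom) for m in state.legal_multiplicities]


def purity_from_peak(omega: float, m: int, psi_s: float) -> float:
    """Invert the peak-location formula: rho_i = 2*omega / (m + omega*(2 - psi_s)).

    Exact algebraic inverse of :func:`expected_peak_vafs`; the result is
    clamped to (0, 1].
    """
    if not 0.0 < omega <= 1.0:
        raise ValueError("observed peak VAF must lie in (0, 1]")
    denom = m + omega * (2.0 - psi_s)
    if denom <= 0:
        raise ValueError("invalid peak: non-positive denominator in purity inversion")
    rho = 2.0 * omega / denom
    return min(rho, 1.0)


def detect_vaf_peaks(vafs: np.ndarray, density_threshold: float = 0.3,
                     grid_size: int = 512) -> list[float]:
    """Local maxima of a Gaussian KDE of the VAFs (Silverman bandwidth).

    Peaks with absolute density below ``density_threshold`` are excluded.
    Requires >= 10 values in (0, 1).
    """
    vafs = np.asarray(vafs, dtype=float)
    vafs = vafs[(vafs > 0) & (vafs < 1)]
    if vafs.size < 10:
        raise InsufficientDataError(
            f"need >= 10 VAF values in (0,1) to detect peaks, got {vafs.size}"
        )
    if np.ptp(vafs) < 1e-6:  # degenerate spike: KDE is singular
        return [float(vafs.mean())]
    kde = stats.gaussian_kde(vafs, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, grid_size)
    density = kde(grid)
    idx = argrelextrema(density, np.greater)[0]
    peaks = [float(grid[i]) for i in idx if density[i] >= density_threshold]
    return sorted(peaks)


@dataclass
class MatchedPeak:
    state: CNState
    multiplicity: int
    expected_vaf: float
    observed_vaf: float

    @property
    def delta(self) -> float:
        return abs(self.expected_vaf - self.observed_vaf)


def match_peaks(expected: list[tuple[int, float]], observed: list[float],
                state: CNState) -> list[MatchedPeak]:
    """Match expected peaks of one state to observed KDE peaks.

    The greatest-multiplicity expected peak is matched to the greatest observed
    VAF; remaining expected peaks are matched to their nearest observed peak.
    The global worst-pair discard is applied later across all states.
    """
    if not observed:
        raise InsufficientDataError("no observed VAF peaks to match")
    observed = sorted(observed)
    expected = sorted(expected)  # ascending multiplicity
    pairs = [MatchedPeak(state, expected[-1][0], expected[-1][1], observed[-1])]
    for m, exp_vaf in expected[:-1]:
        nearest = min(observed, key=lambda obs: abs(obs - exp_vaf))
        pairs.append(MatchedPeak(state, m, exp_vaf, nearest))
    return pairs


def discard_worst_peak(pairs: list[MatchedPeak]) -> list[MatchedPeak]:
    """Drop the expected peak furthest (in VAF) from its matched observed peak.

    Applied per sample across all considered states, and only when more than
    one expected peak was considered (tumor heterogeneity can inhibit peak
    detection, so the single worst match is distrusted).
    """
    if len(pairs) <= 1:
        return list(pairs)
    # ties in |delta| resolve toward the lower expected peak, which carries
    # the least information about high-multiplicity structure
    worst = max(range(len(pairs)),
                key=lambda i: (pairs[i].delta, -pairs[i].expected_vaf))
    return [p for i, p in enumerate(pairs) if i != worst]


def profile_concordance(pairs: list[MatchedPeak], rho_reference: float,
                        n_all: int) -> tuple[float, float]:
    """Weighted purity re-estimate and concordance metric.

    rho_new = sum_i n_i * rho_i / (n_all * q_i);
    eta     = sum_i n_i * |rho_i - rho_reference| / (n_all * q_i),
    summing over all remaining matched peaks of all considered states.
    """
    if n_all <= 0:
        raise ValueError("n_all must be positive")
    if not pairs:
        raise ValueError("no matched peaks remain")
    rho_new = 0.0
    eta = 0.0
    weight_total = 0.0
    for p in pairs:
        rho_i = purity_from_peak(p.observed_vaf, p.multiplicity, p.state.state_ploidy)
        w = p.state.n_snvs / (n_all * p.state.q)
        rho_new += w * rho_i
        eta += w * abs(rho_i - rho_reference)
        weight_total += w
    # rho_new is a sub-convex combination of the rho_i: weights sum to <= 1
    assert weight_total <= 1.0 + 1e-9, "peak weights exceed 1"
    return rho_new, eta


def reestimate_ploidy(rho_old: float, psi_old: float, rho_new: float) -> float:
    """psi_new = (rho_old * (psi_old - 2) + 2 * rho_new) / rho_new."""
    if rho_new <= 0:
        raise ValueError("rho_new must be positive")
    return (rho_old * (psi_old - 2.0) + 2.0 * rho_new) / rho_new


# ---------------------------------------------------------------------------
# Stage III criteria

def assess_profile(eta: float, ccf_clusters: list[tuple[float, float]],
                   tetraploid: bool, mult1_peak_in_22: bool,
                   homdel_max_len: float) -> QCResult:
    """Evaluate the five profile-quality criteria.

    ``ccf_clusters`` are (CCF, fraction-of-SNVs) summaries. The tetraploid
    multiplicity-1 criterion only binds when the genome is 2:2-dominated.
    """
    for _, frac in ccf_clusters:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("cluster SNV fractions must lie in [0,1]")
    criteria = {
        CRITERIA[0]: eta < 0.05,
        CRITERIA[1]: any(0.9 <= ccf <= 1.1 and frac >= 0.05
                         for ccf, frac in ccf_clusters),
        CRITERIA[2]: not any(ccf > 1.1 and frac >= 0.05
                             for ccf, frac in ccf_clusters),
        CRITERIA[3]: (mult1_peak_in_22 if tetraploid else True),
        CRITERIA[4]: homdel_max_len <= 10e6,
    }
    return QCResult(rho_new=None, psi_new=None, eta=eta, criteria=criteria,
                    passed=all(criteria.values()))


# ---------------------------------------------------------------------------
# Stage IV loop

def _ccf_clusters(snvs, rho: float, min_fraction: float = 0.01
                  ) -> list[tuple[float, float]]:
    """Summarize CCF clusters by 1-D KDE mode-finding (DPClust stand-in).

    Each SNV's CCF is computed from its VAF after assigning it to the nearest
    expected-multiplicity peak of its copy-number state at purity rho.
    """
    ccfs = []
    for (major, minor), group in snvs.groupby(["major", "minor"], sort=True):
        state = CNState(int(major), int(minor))
        expected = expected_peak_vafs(rho, state)
        vafs = group["vaf"].to_numpy()
        exp_vafs = np.array([v for _, v in expected])
        nearest = np.argmin(np.abs(vafs[:, None] - exp_vafs[None, :]), axis=1)
        denom = exp_vafs[nearest]
        ccfs.append(np.divide(vafs, denom, out=np.zeros_like(vafs), where=denom > 0))
    ccf = np.concatenate(ccfs)
    ccf = ccf[ccf > 0]
    if ccf.size < 10 or np.ptp(ccf) < 1e-6:
        return [(float(np.mean(ccf)), 1.0)] if ccf.size else []
    kde = stats.gaussian_kde(ccf, bw_method="silverman")
    grid = np.linspace(0.0, max(2.0, ccf.max()), 512)
    density = kde(grid)
    modes = argrelextrema(density, np.greater)[0]
    if modes.size == 0:
        modes = np.array([int(np.argmax(density))])
    # assign each SNV to its nearest mode to estimate cluster fractions
    mode_ccfs = grid[modes]
    assignment = np.argmin(np.abs(ccf[:, None] - mode_ccfs[None, :]), axis=1)
    clusters = []
    for j, mode in enumerate(mode_ccfs):
        frac = float(np.mean(assignment == j))
        if frac >= min_fraction:
            clusters.append((float(mode), frac))
    return clusters


def run_qc_loop(dataset: VAFDataset, max_attempts: int = 3,
                min_state_fraction: float = 0.05,
                density_threshold: float = 0.3) -> QCResult:
    """Iterate detect -> match -> concordance -> assess, reprofiling on failure.

    On each failed attempt the working purity is replaced by rho_new and the
    ploidy rescaled accordingly; after ``max_attempts`` failures the sample is
    marked excluded. States holding < 5% of all SNVs are not considered.
    """
    snvs = dataset.snvs
    n_all = len(snvs)
    rho = dataset.purity_estimate
    psi = dataset.ploidy_estimate
    last: QCResult | None = None

    for attempt in range(1, max_attempts + 1):
        try:
            pairs: list[MatchedPeak] = []
            considered = 0
            snvs_22 = 0
            for (major, minor), group in snvs.groupby(["major", "minor"], sort=True):
                if len(group) < min_state_fraction * n_all:
                    continue
                considered += len(group)
                state = CNState(int(major), int(minor), n_snvs=len(group))
                observed = detect_vaf_peaks(group["vaf"].to_numpy(),
                                            density_threshold=density_threshold)
                expected = expected_peak_vafs(rho, state)
                if (major, minor) == (2, 2):
                    snvs_22 = len(group)
                pairs.extend(match_peaks(expected, observed, state))
            if not pairs:
                raise InsufficientDataError("no considered states produced peaks")
            if len(pairs) > 1:
                pairs = discard_worst_peak(pairs)
            # an m=1 peak "observed" in 2:2 regions = a surviving match whose
            # observed peak lies near the expected multiplicity-1 location
            mult1_peak_in_22 = any(
                p.multiplicity == 1 and (p.state.major, p.state.minor) == (2, 2)
                and p.delta < 0.05
                for p in pairs
            )
            rho_new, eta = profile_concordance(pairs, rho, considered)
            tetraploid = snvs_22 > 0.5 * considered
            result = assess_profile(eta, _ccf_clusters(snvs, rho), tetraploid,
                                    mult1_peak_in_22, dataset.homdel_max_len)
            result.rho_new = rho_new
            result.psi_new = reestimate_ploidy(rho, psi, rho_new)
            result.attempts = attempt
            last = result
            if result.passed:
                return result
            rho, psi = result.rho_new, result.psi_new
        except InsufficientDataError:
            last = QCResult(rho_new=None, psi_new=None, eta=None,
                            criteria={name: False for name in CRITERIA},
                            passed=False, attempts=attempt)
            break  # no peaks detectable; retrying with the same data cannot help

    assert last is not None
    last.excluded = True
    return last
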