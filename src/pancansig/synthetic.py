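"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generators emulate the inputs of the downstream stages: Poisson mutation
catalogues driven by signature x activity products, negative-binomial
activities with covariate effects, composite gene-inactivation variables,
clonal/subclonal mutation splits, read-sampled VAF distributions at known
purity/ploidy, and toy rearrangement clusters constructed to satisfy or
violate the chromothripsis/chromoplexy criteria.

All generators are deterministic under a fixed seed (numpy PCG64 streams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogue import SVRecord
from .cna_qc import CNState, VAFDataset, expected_peak_vafs
from .sv_events import SVCluster, Footprint

COVARIATE_NAMES = ("log_age", "sex", "pc1", "pc2", "pc3")


@dataclass
class CohortSpec:
    """Parameters of one simulated cohort.

    ``covariate_effects`` maps signature index -> length-5 vector of
    per-covariate log-rate coefficients (order: log(age), sex, PC1-3).
    ``dispersion`` is the negative-binomial size theta (variance mu + mu^2/theta).
    ``baseline_log_activity`` sets the intercept of each signature's log mean
    activity (default log(200) mutations, a mid-range burden).
    """

    n_samples: int
    n_channels: int
    n_signatures: int
    covariate_effects: dict[int, np.ndarray] = field(default_factory=dict)
    dispersion: float = 1.0
    subclonal_fractions: dict[int, float] = field(default_factory=dict)
    baseline_log_activity: float = float(np.log(200.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_channels, self.n_signatures) < 1:
            raise ValueError("n_samples, n_channels, n_signatures must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion (NB size theta) must be > 0")
        for k, frac in self.subclonal_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"subclonal fraction for signature {k} outside [0,1]")
        for k, eff in list(self.covariate_effects.items()):
            eff = np.asarray(eff, dtype=float)
            if eff.shape != (len(COVARIATE_NAMES),):
                raise ValueError(
                    f"covariate_effects[{k}] must have length {len(COVARIATE_NAMES)}"
                )
            self.covariate_effects[k] = eff


@dataclass(frozen=True)
class InactivationParams:
    """Component rates of the composite gene-inactivation variable."""

    p_germline: float
    p_loh: float
    mu_somatic: float

    def __post_init__(self) -> None:
        for p in (self.p_germline, self.p_loh):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        if self.mu_somatic < 0:
            raise ValueError("mu_somatic must be non-negative")


def gen_reference_signatures(n_channels: int, k: int, concentration: float = 0.1,
                             seed: int = 0, prefix: str = "S") -> pd.DataFrame:
    """Draw k column-stochastic signature profiles from a symmetric Dirichlet.

    Small concentration (default 0.1) yields sparse, mutually distinguishable
    profiles, standing in for a reference catalogue in tests and simulations.
    """
    if n_channels < 2 or k < 1:
        raise ValueError("need n_channels >= 2 and k >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(n_channels, concentration), size=k).T
    return pd.DataFrame(
        profiles,
        index=[f"ch{c}" for c in range(n_channels)],
        columns=[f"{prefix}{i + 1}" for i in range(k)],
    )


def gen_covariates(n_samples: int, seed: int = 0) -> pd.DataFrame:
    """Sample the five-covariate design: log(age), sex, three germline PCs.

    Age ~ Normal(60, 10) truncated at 20; sex ~ Bernoulli(0.5); PCs standard
    normal. All columns are standardized to zero mean, unit variance after
    sampling, mirroring how the association models consume them.
    """
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(60.0, 10.0, n_samples), 20.0, None)
    sex = rng.integers(0, 2, n_samples).astype(float)
    pcs = rng.standard_normal((n_samples, 3))
    raw = np.column_stack([np.log(age), sex, pcs])
    std = raw.std(axis=0)
    std[std == 0] = 1.0
    design = (raw - raw.mean(axis=0)) / std
    return pd.DataFrame(design, columns=list(COVARIATE_NAMES),
                        index=[f"sample{i}" for i in range(n_samples)])


def gen_cohort(spec: CohortSpec, signatures: pd.DataFrame
               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (covariates, activities, catalogue) for one cohort.

    Activities A_kp ~ NB(mean = exp(b + Q p . alpha_k), size = theta); counts
    X_cp ~ Poisson((S A)_cp). Returns covariates (samples x 5), activities
    (samples x signatures) and the catalogue (samples x channels).
    """
    if signatures.shape != (spec.n_channels, spec.n_signatures):
        raise ValueError(
            f"signature matrix shape {signatures.shape} does not match spec "
            f"({spec.n_channels}, {spec.n_signatures})"
        )
    rng = np.random.default_rng(spec.seed)
    covariates = gen_covariates(spec.n_samples, seed=rng.integers(2**31))
    Q = covariates.to_numpy()

    theta = spec.dispersion
    activities = np.zeros((spec.n_samples, spec.n_signatures), dtype=np.int64)
    for k in range(spec.n_signatures):
        eta = np.full(spec.n_samples, spec.baseline_log_activity)
        if k in spec.covariate_effects:
            eta = eta + Q @ spec.covariate_effects[k]
        mu = np.exp(eta)
        activities[:, k] = rng.negative_binomial(theta, theta / (theta + mu))

    S = signatures.to_numpy(dtype=float)
    rates = activities @ S.T  # samples x channels
    counts = rng.poisson(rates)

    samples = covariates.index
    activity_df = pd.DataFrame(activities, index=samples, columns=signatures.columns)
    catalogue = pd.DataFrame(counts, index=samples, columns=signatures.index)
    return covariates, activity_df, catalogue


@dataclass
class TimingCounts:
    """Clonal/subclonal split of a catalogue (both samples x channels)."""

    clonal: pd.DataFrame
    subclonal: pd.DataFrame

    def total(self) -> pd.DataFrame:
        return self.clonal + self.subclonal


def gen_clonality(catalogue: pd.DataFrame, signatures: pd.DataFrame,
                  activities: pd.DataFrame, subclonal_fractions: dict,
                  seed: int = 0) -> TimingCounts:
    """Split catalogue counts into clonal and subclonal per cell.

    Each mutation is first assigned a signature of origin multinomially using
    the channel-wise signature shares rho_ck = S_ck A_k / sum_k S_ck A_k, then
    thinned into the subclonal class with its signature's fraction. Totals are
    conserved exactly.
    """
    fracs = {}
    for key, value in subclonal_fractions.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"subclonal fraction for {key} outside [0,1]")
        fracs[key if isinstance(key, str) else signatures.columns[key]] = float(value)
    frac_vec = np.array([fracs.get(name, 0.0) for name in signatures.columns])

    rng = np.random.default_rng(seed)
    S = signatures.to_numpy(dtype=float)  # channels x k
    X = catalogue.to_numpy()
    A = activities.to_numpy()  # samples x k
    n_samples, n_channels = X.shape
    k = S.shape[1]

    subclonal = np.zeros_like(X)
    for p in range(n_samples):
        weights = S * A[p]  # channels x k
        denom = weights.sum(axis=1, keepdims=True)
        probs = np.divide(weights, denom, out=np.full_like(weights, 1.0 / k),
                          where=denom > 0)
        for c in range(n_channels):
            if X[p, c] == 0:
                continue
            by_sig = rng.multinomial(X[p, c], probs[c])
            subclonal[p, c] = rng.binomial(by_sig, frac_vec).sum()
    sub = pd.DataFrame(subclonal, index=catalogue.index, columns=catalogue.columns)
    return TimingCounts(clonal=catalogue - sub, subclonal=sub)


_ENUM_TAIL = 64  # Poisson support truncation for exact enumeration


def inactivation_pmf(params: InactivationParams) -> np.ndarray:
    """Exact pmf of min(2, Bern + Bern + Pois) over {0, 1, 2} by enumeration."""
    from scipy import stats

    pmf = np.zeros(3)
    pois = stats.poisson.pmf(np.arange(_ENUM_TAIL + 1), params.mu_somatic)
    for g in (0, 1):
        pg = params.p_germline if g else 1 - params.p_germline
        for l in (0, 1):
            pl = params.p_loh if l else 1 - params.p_loh
            for s in range(_ENUM_TAIL + 1):
                pmf[min(2, g + l + s)] += pg * pl * pois[s]
    pmf[2] += 1.0 - pmf.sum()  # Poisson tail mass beyond truncation caps at 2
    return pmf


def gen_inactivation(n: int, params: InactivationParams, seed: int = 0) -> np.ndarray:
    """Composite inactivation variable X = min(2, Bern(p_g) + Bern(p_loh) + Pois(mu))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    germline = rng.binomial(1, params.p_germline, n)
    loh = rng.binomial(1, params.p_loh, n)
    somatic = rng.poisson(params.mu_somatic, n)
    return np.minimum(2, germline + loh + somatic)


def gen_vaf_dataset(purity: float, segments: list[dict], depth: int = 80,
                    seed: int = 0, purity_estimate: float | None = None,
                    ploidy_estimate: float | None = None) -> VAFDataset:
    """Simulate per-SNV VAFs at known purity over a set of copy-number states.

    ``segments`` is a list of dicts with keys ``major``, ``minor``, ``n_snvs``
    and optional ``multiplicity_probs`` (mapping multiplicity -> weight over
    the state's legal multiplicities; default: uniform). Each SNV's alt-read
    count is Binomial(depth, expected VAF at its true multiplicity).
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    if depth < 1:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for seg in segments:
        state = CNState(major=int(seg["major"]), minor=int(seg["minor"]),
                        n_snvs=int(seg["n_snvs"]))
        legal = state.legal_multiplicities
        probs_map = seg.get("multiplicity_probs")
        if probs_map is None:
            probs = np.full(len(legal), 1.0 / len(legal))
        else:
            illegal = set(probs_map) - set(legal)
            if illegal:
                raise ValueError(
                    f"multiplicity {sorted(illegal)} illegal for state "
                    f"{state.major}:{state.minor}"
                )
            probs = np.array([probs_map.get(m, 0.0) for m in legal], dtype=float)
            probs = probs / probs.sum()
        expected = dict(expected_peak_vafs(purity, state))
        mults = rng.choice(legal, size=state.n_snvs, p=probs)
        alt = rng.binomial(depth, [expected[m] for m in mults])
        for m, a in zip(mults, alt):
            rows.append((state.major, state.minor, int(m), int(a), depth, a / depth))
    df = pd.DataFrame(rows, columns=["major", "minor", "multiplicity",
                                     "alt_reads", "total_reads", "vaf"])
    mean_state_ploidy = float(np.average(df["major"] + df["minor"]))
    return VAFDataset(
        snvs=df,
        purity_estimate=purity if purity_estimate is None else purity_estimate,
        ploidy_estimate=mean_state_ploidy if ploidy_estimate is None else ploidy_estimate,
        true_purity=purity,
    )


def gen_sv_fixture(kind: str, seed: int = 0) -> SVCluster:
    """Construct a toy rearrangement cluster for the event callers.

    kinds: ``simple`` (<=2 rearrangements, negative for both calls),
    ``chromothripsis_like`` (8 interleaved intrachromosomal SVs, balanced
    orientations, CN oscillating between two states),
    ``chromoplexy_like`` (balanced translocation chain over 3 chromosomes),
    ``boundary_fail`` (chromothripsis-like but with only 5 interleaved
    rearrangements; fails exactly the interleaving criterion).
    """
    rng = np.random.default_rng(seed)
    offset = int(rng.integers(1_000_000, 2_000_000))

    def interleaved(n: int) -> list[SVRecord]:
        # staggered overlapping, non-nested intervals; orientations cycle over
        # the four join categories so the multinomial test sees equal quarters
        types = [("del", None), ("tds", None), ("inv", "h2h"), ("inv", "t2t")]
        records = []
        for i in range(n):
            sv_type, orient = types[i % 4]
            start = offset + i * 10_000
            records.append(SVRecord("chr5", start, "chr5", start + 15_000,
                                    sv_type, cluster_id="ct", clustered=True,
                                    orientation=orient))
        return records

    if kind == "simple":
        records = [
            SVRecord("chr1", offset, "chr1", offset + 5_000, "del",
                     cluster_id="simple", clustered=False),
            SVRecord("chr1", offset + 200_000, "chr1", offset + 260_000, "tds",
                     cluster_id="simple", clustered=False),
        ]
        return SVCluster(cluster_id="simple", rearrangements=records,
                         segments=[("chr1", offset - 10_000, offset + 300_000, 2)],
                         footprints=[])

    if kind in ("chromothripsis_like", "boundary_fail"):
        n = 8 if kind == "chromothripsis_like" else 5
        records = interleaved(n)
        span = offset + n * 10_000 + 15_000
        # total CN oscillates 2,1,2,1,2 -> a run of four segments on two states
        bounds = np.linspace(offset - 5_000, span + 5_000, 6).astype(int)
        cn = [2, 1, 2, 1, 2]
        segments = [("chr5", int(bounds[i]), int(bounds[i + 1]), cn[i])
                    for i in range(5)]
        cluster = SVCluster(cluster_id=kind, rearrangements=records,
                            segments=segments, footprints=[])
        if kind == "boundary_fail":
            cluster.expected_failure = "interleaved_rearrangements"
        return cluster

    if kind == "chromoplexy_like":
        chroms = ("chr1", "chr2", "chr3")
        anchors = {c: offset + i * 3_000_000 for i, c in enumerate(chroms)}
        records = []
        footprints = []
        for i, c in enumerate(chroms):
            nxt = chroms[(i + 1) % 3]
            # translocation from chrom i to chrom i+1; partner breakpoints on a
            # chromosome sit within 10 kb of each other -> 1 Mb graph links
            records.append(SVRecord(c, anchors[c], nxt, anchors[nxt] + 10_000,
                                    "trans", cluster_id="cp", clustered=True))
            footprints.append(Footprint(chrom=c, positions=(anchors[c], anchors[c] + 10_000),
                                        balanced=True))
        return SVCluster(cluster_id="cp", rearrangements=records,
                         segments=[(c, anchors[c] - 50_000, anchors[c] + 60_000, 2)
                                   for c in chroms],
                         footprints=footprints)

    raise ValueError(f"unknown fixture kind {kind!r}")
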