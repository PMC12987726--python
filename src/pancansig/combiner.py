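"""Iterative pan-cancer signature combining.

Cohort-level de novo signatures are decomposed against a reference catalogue
by non-negative least squares; a signature is *decomposable* when the cosine
similarity between its profile and its normalized reconstruction exceeds 0.8.
Non-decomposable signatures from different cohorts are grouped into sets of
mutually similar profiles, each set is merged into a consensus by
inverse-variance weighting of its members per channel, and the consensus
whose set is least similar to the current reference (smallest maximum cosine
to any reference signature) is admitted. Decomposition and set formation then
repeat against the enlarged reference until every extracted signature is
decomposable.

A leave-one-out audit reports which reference signatures are themselves
linear combinations of the others (cosine > 0.8), quantifying the linear
dependence the one-at-a-time admission rule cannot prevent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .extraction import cosine_similarity

COSINE_THRESHOLD = 0.8
VARIANCE_FLOOR = 1e-6


@dataclass
class ExtractedSignature:
    """A cohort-level signature with its across-restart channel variances."""

    name: str
    cohort: str
    profile: np.ndarray
    channel_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        total = self.profile.sum()
        if total <= 0:
            raise ValueError(f"signature {self.name} has non-positive mass")
        self.profile = self.profile / total
        if self.channel_variance is None:
            self.channel_variance = np.full_like(self.profile, VARIANCE_FLOOR)
        else:
            self.channel_variance = np.asarray(self.channel_variance, dtype=float)
            if self.channel_variance.shape != self.profile.shape:
                raise ValueError("variance vector length mismatch")


@dataclass
class ReferenceSet:
    """Named reference profiles with provenance (cosmic | new)."""

    signatures: "pd.DataFrame"  # channels x names, column-stochastic
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = self.signatures.to_numpy(dtype=float)
        sums = cols.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError("reference profiles must have positive mass")
        self.signatures = self.signatures / sums
        for name in self.signatures.columns:
            self.provenance.setdefault(name, "cosmic")

    @property
    def names(self) -> list[str]:
        return list(self.signatures.columns)

    def __len__(self) -> int:
        return self.signatures.shape[1]

    def matrix(self) -> np.ndarray:
        return self.signatures.to_numpy(dtype=float)

    def with_signature(self, name: str, profile: np.ndarray,
                       provenance: str = "new") -> "ReferenceSet":
        if name in self.signatures.columns:
            raise ValueError(f"duplicate reference name {name}")
        df = self.signatures.copy()
        df[name] = profile / profile.sum()
        prov = dict(self.provenance)
        prov[name] = provenance
        return ReferenceSet(df, prov)


@dataclass
class Decomposition:
    weights: dict[str, float]
    reconstruction: np.ndarray | None
    cosine: float

    @property
    def decomposable(self) -> bool:
        return self.cosine > COSINE_THRESHOLD


def decompose(profile: np.ndarray, reference: ReferenceSet) -> Decomposition:
    """Non-negative least-squares reconstruction from the reference profiles."""
    profile = np.asarray(profile, dtype=float)
    profile = profile / profile.sum()
    if len(reference) == 0:
        return Decomposition(weights={}, reconstruction=None, cosine=0.0)
    R = reference.matrix()
    weights, _ = nnls(R, profile)
    recon = R @ weights
    if recon.sum() <= 0:
        return Decomposition(weights=dict(zip(reference.names, weights)),
                             reconstruction=None, cosine=0.0)
    recon = recon / recon.sum()
    return Decomposition(
        weights=dict(zip(reference.names, weights)),
        reconstruction=recon,
        cosine=cosine_similarity(profile, recon),
    )


def build_sets(unexplained: list[ExtractedSignature]) -> list[list[ExtractedSignature]]:
    """Group non-decomposable signatures into cross-cohort similarity sets.

    Pairs are scanned in descending cosine order (ties broken by (cohort,
    name) for determinism). A pair with cosine > 0.8 from different cohorts
    opens a new set when neither member is assigned; a signature joins an
    existing set only if its cosine with every member exceeds 0.8 and its
    cohort is absent from the set.
    """
    n = len(unexplained)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            sim = cosine_similarity(unexplained[i].profile, unexplained[j].profile)
            pairs.append((sim, i, j))
    key = lambda t: (-t[0],
                     (unexplained[t[1]].cohort, unexplained[t[1]].name),
                     (unexplained[t[2]].cohort, unexplained[t[2]].name))
    pairs.sort(key=key)

    assignment: dict[int, int] = {}
    sets: list[list[int]] = []

    def can_join(idx: int, members: list[int]) -> bool:
        sig = unexplained[idx]
        if any(unexplained[m].cohort == sig.cohort for m in members):
            return False
        return all(
            cosine_similarity(sig.profile, unexplained[m].profile) > COSINE_THRESHOLD
            for m in members
        )

    for sim, i, j in pairs:
        if sim <= COSINE_THRESHOLD:
            break
        in_i, in_j = i in assignment, j in assignment
        if not in_i and not in_j:
            if unexplained[i].cohort != unexplained[j].cohort:
                assignment[i] = assignment[j] = len(sets)
                sets.append([i, j])
        elif in_i != in_j:
            assigned, free = (i, j) if in_i else (j, i)
            set_id = assignment[assigned]
            if can_join(free, sets[set_id]):
                assignment[free] = set_id
                sets[set_id].append(free)
    return [[unexplained[i] for i in members] for members in sets]


def combine_set(members: list[ExtractedSignature],
                variance_floor: float = VARIANCE_FLOOR) -> np.ndarray:
    """Inverse-variance weighted per-channel mean of the set, renormalized."""
    if not members:
        raise ValueError("empty signature set")
    profiles = np.column_stack([m.profile for m in members])
    variances = np.column_stack([m.channel_variance for m in members])
    weights = 1.0 / np.maximum(variances, variance_floor)
    consensus = (weights * profiles).sum(axis=1) / weights.sum(axis=1)
    return consensus / consensus.sum()


def max_cosine_to_reference(profile: np.ndarray, reference: ReferenceSet) -> float:
    if len(reference) == 0:
        return 0.0
    R = reference.matrix()
    return max(cosine_similarity(profile, R[:, j]) for j in range(R.shape[1]))


def admit_next(sets: list[list[ExtractedSignature]], reference: ReferenceSet,
               name: str) -> ReferenceSet:
    """Admit the consensus of the set least similar to the current reference."""
    if not sets:
        raise ValueError("no candidate sets")
    consensuses = [combine_set(members) for members in sets]
    scores = [max_cosine_to_reference(c, reference) for c in consensuses]
    chosen = int(np.argmin(scores))
    return reference.with_signature(name, consensuses[chosen])


@dataclass
class CombineResult:
    reference: ReferenceSet
    decompositions: dict[str, Decomposition]  # per "cohort/name"
    admitted: list[str]
    iterations: int


def combine_all(cohort_signatures: dict[str, list[ExtractedSignature]],
                initial_reference: ReferenceSet,
                name_prefix: str = "NEW") -> CombineResult:
    """Run the iterative combine loop to convergence.

    Singleton non-decomposable signatures that can join no cross-cohort set
    are admitted directly (smallest max-cosine to the reference first) so the
    loop always terminates; each iteration admits exactly one signature.
    """
    extracted: list[ExtractedSignature] = []
    for cohort, sigs in sorted(cohort_signatures.items()):
        for sig in sigs:
            if sig.cohort != cohort:
                raise ValueError(f"signature {sig.name} labeled {sig.cohort}, "
                                 f"listed under {cohort}")
            extracted.append(sig)

    reference = initial_reference
    admitted: list[str] = []
    iterations = 0
    max_iterations = len(extracted) + 1
    while True:
        iterations += 1
        decompositions = {
            f"{sig.cohort}/{sig.name}": decompose(sig.profile, reference)
            for sig in extracted
        }
        unexplained = [sig for sig in extracted
                       if not decompositions[f"{sig.cohort}/{sig.name}"].decomposable]
        if not unexplained:
            return CombineResult(reference=reference,
                                 decompositions=decompositions,
                                 admitted=admitted, iterations=iterations)
        if iterations > max_iterations:  # pragma: no cover - loop safety bound
            raise RuntimeError("combine_all failed to terminate")
        name = f"{name_prefix}{len(admitted) + 1}"
        sets = build_sets(unexplained)
        if sets:
            reference = admit_next(sets, reference, name)
        else:
            # no cross-cohort pair exists: admit the least-similar singleton
            scores = [max_cosine_to_reference(sig.profile, reference)
                      for sig in unexplained]
            loner = unexplained[int(np.argmin(scores))]
            reference = reference.with_signature(name, loner.profile)
        admitted.append(name)


def composability_audit(reference: ReferenceSet) -> pd.DataFrame:
    """Leave-one-out linear-dependence audit of a reference catalogue.

    For each signature, reconstruct it by NNLS from all the others; it is
    *composable* when the cosine of the normalized reconstruction exceeds
    0.8. Returns a DataFrame (signature, cosine, composable).
    """
    if len(reference) < 2:
        raise ValueError("audit requires at least 2 reference signatures")
    rows = []
    for name in reference.names:
        others = ReferenceSet(reference.signatures.drop(columns=[name]),
                              dict(reference.provenance))
        dec = decompose(reference.signatures[name].to_numpy(), others)
        rows.append((name, dec.cosine, dec.decomposable))
    return pd.DataFrame(rows, columns=["signature", "cosine", "composable"]
                        ).set_index("signature")
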