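"""Rule-based chromothripsis and chromoplexy calling on rearrangement clusters.

Cluster membership (ClusterSV-style) is an input. A cluster is called as:

chromothripsis when (1) it holds at least six interleaved intrachromosomal
rearrangements, (2) its total-copy-number segments contain a contiguous run of
four segments oscillating between two states or five segments oscillating
between three states, and (3) the distribution of its intrachromosomal join
orientations (duplication-like, deletion-like, head-to-head inversion,
tail-to-tail inversion) is consistent with equal quarters after
Benjamini-Hochberg control at FDR 0.2 across all clusters under evaluation;

chromoplexy when it (1) comprises 3-30 rearrangements, (2) contains a chain of
rearrangements spanning at least three chromosomes in the breakpoint graph
(nodes = breakpoints, proximity edges within 1 Mb between different
rearrangements, plus the join of each rearrangement itself), and (3) at least
half of its footprints are balanced translocations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalogue import SVRecord

ORIENTATION_CATEGORIES = ("dup_like", "del_like", "inv_h2h", "inv_t2t")

CHROMOTHRIPSIS_CRITERIA = (
    "interleaved_rearrangements",  # >= 6 interleaved intrachromosomal
    "cn_oscillation",              # 4 segments / 2 states or 5 segments / 3 states
    "orientation_uniformity",      # equal-quarters test not rejected at FDR 0.2
)

CHROMOPLEXY_CRITERIA = (
    "size_3_to_30",
    "chain_spans_3_chromosomes",
    "balanced_footprints",         # >= 50% balanced translocation footprints
)


@dataclass(frozen=True)
class Footprint:
    """A group of positionally associated breakpoints with balance annotation."""

    chrom: str
    positions: tuple[int, ...]
    balanced: bool  # balanced translocation: deletion bridge or no CN change


@dataclass
class SVCluster:
    """A rearrangement cluster plus the CN segments on its chromosomes.

    ``segments`` are (chrom, start, end, total_cn) tuples, ordered and
    non-overlapping per chromosome.
    """

    cluster_id: str
    rearrangements: list[SVRecord]
    segments: list[tuple[str, int, int, int]] = field(default_factory=list)
    footprints: list[Footprint] = field(default_factory=list)
    expected_failure: str | None = None  # set by boundary fixtures

    def intrachromosomal(self) -> list[SVRecord]:
        return [r for r in self.rearrangements if r.sv_type != "trans"]


@dataclass
class EventCall:
    kind: str  # "chromothripsis" | "chromoplexy" | "none"
    criteria: dict[str, bool]
    orientation_pvalue: float | None = None
    orientation_pvalue_adjusted: float | None = None
    indeterminate: bool = False


# ---------------------------------------------------------------------------
# chromothripsis

def _interleaved(a: SVRecord, b: SVRecord) -> bool:
    """Breakpoint intervals overlap but neither contains the other."""
    if a.chrom1 != b.chrom1:
        return False
    lo_a, hi_a = a.pos1, a.pos2
    lo_b, hi_b = b.pos1, b.pos2
    overlap = lo_a < hi_b and lo_b < hi_a
    nested = (lo_a <= lo_b and hi_b <= hi_a) or (lo_b <= lo_a and hi_a <= hi_b)
    return overlap and not nested


def count_interleaved(cluster: SVCluster) -> int:
    """Intrachromosomal rearrangements interleaved with >= 1 cluster member."""
    intra = cluster.intrachromosomal()
    return sum(
        any(_interleaved(r, other) for other in intra if other is not r)
        for r in intra
    )


def has_cn_oscillation(segments: list[tuple[str, int, int, int]]) -> bool:
    """A contiguous run of 4 segments on 2 CN states, or 5 on 3 states.

    Runs are maximal stretches with no two adjacent segments at equal total
    CN, scanned per chromosome in genomic order.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, _end, cn in segments:
        by_chrom.setdefault(chrom, []).append((start, cn))
    for entries in by_chrom.values():
        values = [cn for _start, cn in sorted(entries)]
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] == values[i - 1]:
                run = values[run_start:i]
                for width, max_states in ((4, 2), (5, 3)):
                    for j in range(len(run) - width + 1):
                        if len(set(run[j:j + width])) <= max_states:
                            return True
                run_start = i
    return False


def orientation_counts(cluster: SVCluster) -> np.ndarray:
    """Counts of the four intrachromosomal join-orientation categories."""
    counts = dict.fromkeys(ORIENTATION_CATEGORIES, 0)
    for r in cluster.intrachromosomal():
        if r.sv_type == "tds":
            counts["dup_like"] += 1
        elif r.sv_type == "del":
            counts["del_like"] += 1
        elif r.sv_type == "inv":
            key = "inv_h2h" if r.orientation in (None, "h2h") else "inv_t2t"
            counts[key] += 1
    return np.array([counts[c] for c in ORIENTATION_CATEGORIES])


def orientation_pvalue(cluster: SVCluster) -> float:
    """Chi-square goodness of fit against equal quarters (3 df)."""
    counts = orientation_counts(cluster)
    if counts.sum() == 0:
        return 1.0
    return float(stats.chisquare(counts).pvalue)


def call_chromothripsis(cluster: SVCluster,
                        orientation_rejected: bool | None = None) -> EventCall:
    """Evaluate the three chromothripsis criteria for one cluster.

    ``orientation_rejected`` carries the FDR-level decision across all
    clusters (see :func:`call_events`); when None, the raw p-value is compared
    to 0.2 directly (single-cluster evaluation).
    """
    if not cluster.rearrangements:
        raise ValueError("empty cluster")
    p_orient = orientation_pvalue(cluster)
    criteria = {
        CHROMOTHRIPSIS_CRITERIA[0]: count_interleaved(cluster) >= 6,
        CHROMOTHRIPSIS_CRITERIA[2]: (not orientation_rejected
                                     if orientation_rejected is not None
                                     else p_orient >= 0.2),
    }
    indeterminate = False
    if cluster.segments:
        criteria[CHROMOTHRIPSIS_CRITERIA[1]] = has_cn_oscillation(cluster.segments)
    else:
        criteria[CHROMOTHRIPSIS_CRITERIA[1]] = False
        indeterminate = criteria[CHROMOTHRIPSIS_CRITERIA[0]]
    kind = "chromothripsis" if all(criteria.values()) else "none"
    return EventCall(kind=kind, criteria=criteria, orientation_pvalue=p_orient,
                     indeterminate=indeterminate)


# ---------------------------------------------------------------------------
# chromoplexy

def breakpoint_graph(cluster: SVCluster, max_distance: int = 1_000_000) -> nx.Graph:
    """Nodes = breakpoints; edges join breakpoints within 1 Mb on the same
    chromosome from different rearrangements, plus each rearrangement's own
    two breakpoints (the join itself), so chains traverse translocations."""
    graph = nx.Graph()
    breakpoints = []
    for i, r in enumerate(cluster.rearrangements):
        for node, chrom, pos in ((2 * i, r.chrom1, r.pos1), (2 * i + 1, r.chrom2, r.pos2)):
            graph.add_node(node, chrom=chrom, pos=pos, rearrangement=i)
            breakpoints.append((node, chrom, pos, i))
        graph.add_edge(2 * i, 2 * i + 1, kind="rearrangement")
    for a, chrom_a, pos_a, ra in breakpoints:
        for b, chrom_b, pos_b, rb in breakpoints:
            if b <= a or ra == rb or chrom_a != chrom_b:
                continue
            if abs(pos_a - pos_b) <= max_distance:
                graph.add_edge(a, b, kind="proximity")
    return graph


def chain_chromosome_span(cluster: SVCluster) -> int:
    """Chromosome count of the largest connected chain in the breakpoint graph."""
    graph = breakpoint_graph(cluster)
    best = 0
    for component in nx.connected_components(graph):
        chroms = {graph.nodes[n]["chrom"] for n in component}
        best = max(best, len(chroms))
    return best


def call_chromoplexy(cluster: SVCluster) -> EventCall:
    """Evaluate the three chromoplexy criteria for one cluster."""
    if not cluster.rearrangements:
        raise ValueError("empty cluster")
    n = len(cluster.rearrangements)
    balanced_frac = (
        np.mean([f.balanced for f in cluster.footprints])
        if cluster.footprints else 0.0
    )
    criteria = {
        CHROMOPLEXY_CRITERIA[0]: 3 <= n <= 30,
        CHROMOPLEXY_CRITERIA[1]: chain_chromosome_span(cluster) >= 3,
        CHROMOPLEXY_CRITERIA[2]: balanced_frac >= 0.5,
    }
    kind = "chromoplexy" if all(criteria.values()) else "none"
    return EventCall(kind=kind, criteria=criteria)


# ---------------------------------------------------------------------------
# cohort-level evaluation

def call_events(clusters: list[SVCluster], fdr: float = 0.2
                ) -> dict[str, EventCall]:
    """Call chromothripsis/chromoplexy for a set of clusters.

    The orientation equal-quarters test is corrected across all clusters by
    Benjamini-Hochberg at the given FDR; chromothripsis takes precedence when
    a cluster satisfies both rule sets (it is the more specific event).
    """
    if not clusters:
        return {}
    pvals = np.array([orientation_pvalue(c) for c in clusters])
    rejected, p_adjusted, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    calls: dict[str, EventCall] = {}
    for cluster, rej, p_adj in zip(clusters, rejected, p_adjusted):
        ct = call_chromothripsis(cluster, orientation_rejected=bool(rej))
        ct.orientation_pvalue_adjusted = float(p_adj)
        if ct.kind == "chromothripsis":
            calls[cluster.cluster_id] = ct
            continue
        cp = call_chromoplexy(cluster)
        if cp.kind == "chromoplexy":
            cp.orientation_pvalue = ct.orientation_pvalue
            cp.orientation_pvalue_adjusted = float(p_adj)
            calls[cluster.cluster_id] = cp
        else:
            ct.criteria.update(cp.criteria)
            calls[cluster.cluster_id] = ct
    return calls
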