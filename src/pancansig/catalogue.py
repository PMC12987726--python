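"""Catalogue / signature matrix containers, COSMIC-layout I/O and SV32 classification.

A *catalogue* is a samples x channels matrix of non-negative integer mutation
counts under a named channel scheme. A *signature matrix* is channels x
signatures, each column a probability distribution over channels. On disk both
use the COSMIC layout: first column holds the channel label, remaining columns
one sample (catalogue) or one signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schemas import SV_SIZE_BINS, SV_SIZE_EDGES, ChannelSchema, get_schema

_SV_TYPE_ALIASES = {
    "deletion": "del",
    "del": "del",
    "tandem_duplication": "tds",
    "tds": "tds",
    "dup": "tds",
    "inversion": "inv",
    "inv": "inv",
    "translocation": "trans",
    "trans": "trans",
    "tra": "trans",
}


@dataclass(frozen=True)
class SVRecord:
    """One somatic rearrangement (1-based inclusive coordinates).

    ``orientation`` distinguishes head-to-head from tail-to-tail inversions and
    is only consulted by the event callers, not by the 32-class scheme.
    """

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    sample: str = "sample"
    cluster_id: str | None = None
    clustered: bool = False
    orientation: str | None = None  # "h2h" | "t2t" for inversions

    def __post_init__(self) -> None:
        sv_type = _SV_TYPE_ALIASES.get(self.sv_type)
        if sv_type is None:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        object.__setattr__(self, "sv_type", sv_type)
        if sv_type == "trans":
            if self.chrom1 == self.chrom2:
                raise ValueError("translocation breakpoints must lie on different chromosomes")
        else:
            if self.chrom1 != self.chrom2:
                raise ValueError(f"{sv_type} breakpoints must lie on one chromosome")
            if self.pos2 <= self.pos1:
                raise ValueError("intrachromosomal records require pos2 > pos1")

    @property
    def size(self) -> int | None:
        """Breakpoint distance; undefined for translocations."""
        if self.sv_type == "trans":
            return None
        return self.pos2 - self.pos1


def sv_size_bin(size: int) -> str:
    """Size bin label for an intrachromosomal SV; half-open [lower, upper) bins,
    everything below the first edge goes to the smallest bin."""
    if size <= 0:
        raise ValueError("SV size must be positive")
    for edge, label in zip(SV_SIZE_EDGES, SV_SIZE_BINS):
        if size < edge:
            return label
    return SV_SIZE_BINS[-1]


def classify_sv(record: SVRecord) -> str:
    """Assign a rearrangement to one of the 32 SV channels.

    Channels are {clustered, non-clustered} x ({del, tds, inv} x five size
    bins, plus translocation). Size is breakpoint distance.
    """
    clust = "clustered" if record.clustered else "non-clustered"
    if record.sv_type == "trans":
        return f"{clust}:trans"
    return f"{clust}:{record.sv_type}:{sv_size_bin(record.size)}"


def build_catalogue(records: list[SVRecord]) -> pd.DataFrame:
    """Count records per sample per SV32 channel.

    Returns a samples x 32 integer DataFrame whose total equals len(records).
    """
    schema = get_schema("SV32")
    samples = sorted({r.sample for r in records})
    counts = pd.DataFrame(
        np.zeros((len(samples), len(schema)), dtype=np.int64),
        index=pd.Index(samples, name="sample"),
        columns=list(schema.labels),
    )
    for record in records:
        counts.loc[record.sample, classify_sv(record)] += 1
    return counts


def validate_catalogue(df: pd.DataFrame, scheme: str | None = None) -> pd.DataFrame:
    """Check a samples x channels count matrix; returns it with columns ordered
    to the schema when a scheme name is given."""
    values = df.to_numpy()
    if np.any(values < 0):
        raise ValueError("catalogue contains negative counts")
    if not np.all(np.isfinite(values)):
        raise ValueError("catalogue contains non-finite values")
    if scheme is not None:
        schema = get_schema(scheme)
        missing = set(schema.labels) - set(df.columns)
        if missing:
            raise ValueError(f"catalogue is missing {len(missing)} {scheme} channels")
        df = df.loc[:, list(schema.labels)]
    return df


def validate_signatures(df: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Check a channels x signatures matrix: non-negative, columns sum to 1."""
    values = df.to_numpy(dtype=float)
    if np.any(values < -atol):
        raise ValueError("signature matrix has negative entries")
    sums = values.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=max(atol, 1e-6)):
        bad = df.columns[~np.isclose(sums, 1.0, atol=max(atol, 1e-6))]
        raise ValueError(f"signature columns do not sum to 1: {list(bad)}")
    return df


# ---------------------------------------------------------------------------
# COSMIC-layout TSV I/O

def write_cosmic_tsv(df: pd.DataFrame, path: str | Path, label: str = "MutationType",
                     transpose: bool = False) -> None:
    """Write a matrix in COSMIC layout (channel-label column + one column per
    signature/sample). Pass ``transpose=True`` for samples x channels catalogues."""
    out = df.T if transpose else df
    out = out.copy()
    out.insert(0, label, out.index)
    out.to_csv(path, sep="\t", index=False)


def read_cosmic_tsv(path: str | Path, transpose: bool = False) -> pd.DataFrame:
    """Read a COSMIC-layout TSV; first column is the channel label."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = None
    return df.T if transpose else df


def write_catalogue(df: pd.DataFrame, path: str | Path) -> None:
    write_cosmic_tsv(df, path, transpose=True)


def read_catalogue(path: str | Path, scheme: str | None = None) -> pd.DataFrame:
    df = read_cosmic_tsv(path, transpose=True).astype(np.int64)
    df.index.name = "sample"
    return validate_catalogue(df, scheme)


def write_signatures(df: pd.DataFrame, path: str | Path) -> None:
    write_cosmic_tsv(df, path, transpose=False)


def read_signatures(path: str | Path) -> pd.DataFrame:
    return validate_signatures(read_cosmic_tsv(path, transpose=False))


# ---------------------------------------------------------------------------
# BEDPE-like SV records

_BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "type", "cluster_id",
]


def read_bedpe(path: str | Path) -> list[SVRecord]:
    """Read SV records from a BEDPE-like tab-separated file.

    Columns: chrom1, start1, end1, chrom2, start2, end2, name (sample),
    type, cluster_id (empty / "." = unclustered). Breakpoints are taken as the
    start coordinates, converted from BED half-open to 1-based.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_BEDPE_COLUMNS,
                     comment="#", dtype={"chrom1": str, "chrom2": str})
    records = []
    for row in df.itertuples(index=False):
        cluster = None if pd.isna(row.cluster_id) or row.cluster_id in (".", "") else str(row.cluster_id)
        records.append(SVRecord(
            chrom1=row.chrom1, pos1=int(row.start1) + 1,
            chrom2=row.chrom2, pos2=int(row.start2) + 1,
            sv_type=row.type, sample=str(row.name),
            cluster_id=cluster, clustered=cluster is not None,
        ))
    return records


def write_bedpe(records: list[SVRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append((r.chrom1, r.pos1 - 1, r.pos1, r.chrom2, r.pos2 - 1, r.pos2,
                     r.sample, r.sv_type, r.cluster_id or "."))
    pd.DataFrame(rows, columns=_BEDPE_COLUMNS).to_csv(path, sep="\t", index=False, header=False)
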