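"""Mutation channel schemas.

Each scheme is a fixed, ordered set of channel labels. SBS96/SBS288, DBS78,
ID83 and CN48 follow the COSMIC channel layouts; SV32 is the rearrangement
scheme used for structural-variant signatures (type x size x clustering).
Label sets are generated programmatically so the package ships no data files.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

BASES = ("A", "C", "G", "T")
PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SV_TYPES = ("del", "tds", "inv")
SV_SIZE_BINS = ("1-10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb")
# upper edges (bp) of the size bins; bottom bin is closed at 50 bp, top bin open
SV_SIZE_EDGES = (10_000, 100_000, 1_000_000, 10_000_000)

SCHEME_SIZES = {
    "SBS96": 96,
    "SBS288": 288,
    "DBS78": 78,
    "ID83": 83,
    "CN48": 48,
    "SV32": 32,
}


@dataclass(frozen=True)
class ChannelSchema:
    """An ordered, named set of mutation-channel labels."""

    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.name not in SCHEME_SIZES:
            raise ValueError(f"unknown channel scheme {self.name!r}")
        expected = SCHEME_SIZES[self.name]
        if len(self.labels) != expected:
            raise ValueError(
                f"{self.name} requires {expected} channels, got {len(self.labels)}"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"{self.name} labels are not unique")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def _sbs96_labels() -> list[str]:
    return [
        f"{five}[{sub}]{three}"
        for sub in PYRIMIDINE_SUBS
        for five in BASES
        for three in BASES
    ]


def _sbs288_labels() -> list[str]:
    # T = transcribed, U = untranscribed, N = nontranscribed strand
    return [f"{strand}:{chan}" for strand in ("T", "U", "N") for chan in _sbs96_labels()]


def _dbs78_labels() -> list[str]:
    refs = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    labels: list[str] = []
    for ref in refs:
        palindromic = ref == comp[ref[1]] + comp[ref[0]]
        seen: set[str] = set()
        for a in BASES:
            for b in BASES:
                alt = a + b
                if a == ref[0] or b == ref[1]:
                    continue
                if palindromic:
                    rc = comp[alt[1]] + comp[alt[0]]
                    if rc in seen:
                        continue
                seen.add(alt)
                labels.append(f"{ref}>{alt}")
    return labels


def _id83_labels() -> list[str]:
    labels: list[str] = []
    # 1-bp deletions / insertions in homopolymer context
    for kind in ("Del", "Ins"):
        for base in ("C", "T"):
            lens = ("1", "2", "3", "4", "5", "6+") if kind == "Del" else ("0", "1", "2", "3", "4", "5+")
            for n in lens:
                labels.append(f"1:{kind}:{base}:{n}")
    # >=2bp repeat-mediated deletions / insertions
    for kind in ("Del", "Ins"):
        for size in ("2", "3", "4", "5+"):
            lens = ("1", "2", "3", "4", "5", "6+") if kind == "Del" else ("0", "1", "2", "3", "4", "5+")
            for n in lens:
                labels.append(f"{size}:{kind}:R:{n}")
    # microhomology-mediated deletions
    for size, mhs in (("2", ("1",)), ("3", ("1", "2")), ("4", ("1", "2", "3")),
                      ("5+", ("1", "2", "3", "4", "5+"))):
        for mh in mhs:
            labels.append(f"{size}:Del:M:{mh}")
    return labels


def _cn48_labels() -> list[str]:
    labels = [f"0:homdel:{size}" for size in ("0-100kb", "100kb-1Mb", ">1Mb")]
    sizes = ("0-100kb", "100kb-1Mb", "1Mb-10Mb", "10Mb-40Mb", ">40Mb")
    for tcn in ("1", "2", "3-4", "5-8", "9+"):
        for size in sizes:
            labels.append(f"{tcn}:LOH:{size}")
    for tcn in ("2", "3-4", "5-8", "9+"):
        for size in sizes:
            labels.append(f"{tcn}:het:{size}")
    return labels


def _sv32_labels() -> list[str]:
    labels: list[str] = []
    for clust in ("clustered", "non-clustered"):
        for sv_type in SV_TYPES:
            for size in SV_SIZE_BINS:
                labels.append(f"{clust}:{sv_type}:{size}")
        labels.append(f"{clust}:trans")
    return labels


_BUILDERS = {
    "SBS96": _sbs96_labels,
    "SBS288": _sbs288_labels,
    "DBS78": _dbs78_labels,
    "ID83": _id83_labels,
    "CN48": _cn48_labels,
    "SV32": _sv32_labels,
}


@lru_cache(maxsize=None)
def get_schema(name: str) -> ChannelSchema:
    """Return the ChannelSchema for one of the six supported schemes."""
    if name not in _BUILDERS:
        raise ValueError(
            f"unknown channel scheme {name!r}; expected one of {sorted(_BUILDERS)}"
        )
    return ChannelSchema(name, tuple(_BUILDERS[name]()))
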