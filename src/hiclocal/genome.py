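"""In-silico restriction digestion and per-bin normalization covariates.

Kilobase-resolution Hi-C maps are built on a restriction digest of the
genome (DpnII ``GATC`` for 2-kb maps, HindIII ``AAGCTT`` for coarser ones).
The digest drives two things downstream: the self-ligation filter on read
pairs (is there a cut site between the mates?) and the per-bin covariates of
the Poisson bias regression — effective fragment length, GC content of
fragment ends, fragment-end count, and mappability.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeSequence",
    "RestrictionFragment",
    "BinFeatures",
    "ENZYMES",
    "ARABIDOPSIS_CENTROMERES",
    "digest",
    "cut_positions",
    "bin_features",
    "centromere_mask",
]

#: Recognition site and cut offset within the site for the enzymes used for
#: kilobase-scale Hi-C in A. thaliana.  DpnII cuts ^GATC (offset 0), HindIII
#: cuts A^AGCTT (offset 1).  Both sites are palindromic at the cut, so
#: forward-strand scanning finds every cut.
ENZYMES: dict[str, tuple[str, int]] = {
    "DpnII": ("GATC", 0),
    "HindIII": ("AAGCTT", 1),
}

#: Pericentromeric spans excluded from Hi-C pattern analysis (bp, 0-based
#: half-open), for the five A. thaliana chromosomes.
ARABIDOPSIS_CENTROMERES: dict[str, tuple[int, int]] = {
    "Chr1": (13_700_000, 15_900_000),
    "Chr2": (2_450_000, 5_500_000),
    "Chr3": (11_300_000, 14_300_000),
    "Chr4": (1_800_000, 5_150_000),
    "Chr5": (11_000_000, 13_350_000),
}

_VALID_MOTIF = re.compile(r"^[ACGT]+$")


@dataclass
class GenomeSequence:
    """Ordered chromosome names and their DNA sequences (A/C/G/T/N)."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        for name in self.chrom_names:
            if len(self.sequences[name]) == 0:
                raise ValueError(f"chromosome {name!r} is empty")

    def lengths(self) -> dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.chrom_names}


@dataclass(frozen=True)
class RestrictionFragment:
    """One restriction fragment, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BinFeatures:
    """Per-bin covariates feeding the Hi-C bias regression, one chromosome.

    ``eff_len`` is the fraction of the bin lying within ``eff_flank`` bp of a
    cut site (only sequence near fragment ends can produce Hi-C reads),
    ``gc_ends`` the GC fraction of the flanking windows around the bin's cut
    sites, ``end_count`` the number of fragment ends in the bin, and
    ``mappability`` an externally supplied fraction (1.0 if unknown).
    """

    chrom: str
    bin_size: int
    eff_len: np.ndarray
    gc_ends: np.ndarray
    end_count: np.ndarray
    mappability: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.end_count)


def cut_positions(sequence: str, site: str, cut_offset: int | None = None) -> np.ndarray:
    """Cut positions (bp) from forward-strand motif occurrences.

    Overlapping occurrences count (``GATCGATC`` has cuts at 0 and 4 for
    DpnII, and ``AAAA`` would yield cuts at 0,1 for motif ``AAA``).
    """
    if not _VALID_MOTIF.match(site):
        raise ValueError(f"restriction site must be A/C/G/T only, got {site!r}")
    if cut_offset is None:
        cut_offset = next((off for s, off in ENZYMES.values() if s == site), 0)
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset must lie within the recognition site")
    upper = sequence.upper()
    hits = []
    start = upper.find(site)
    while start != -1:
        hits.append(start + cut_offset)
        start = upper.find(site, start + 1)
    return np.asarray(hits, dtype=np.int64)


def digest(
    genome: GenomeSequence, site: str = "GATC", cut_offset: int | None = None
) -> list[RestrictionFragment]:
    """Complete in-silico digestion of a genome.

    Fragments span successive cut positions plus the chromosome ends;
    zero-length fragments (a cut at position 0) are dropped, so the surviving
    fragments tile each chromosome exactly.
    """
    if len(site) < 4:
        raise ValueError("recognition site must be at least 4 bp")
    fragments: list[RestrictionFragment] = []
    for chrom in genome.chrom_names:
        seq = genome.sequences[chrom]
        cuts = cut_positions(seq, site, cut_offset)
        bounds = np.concatenate([[0], cuts, [len(seq)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b > a:
                fragments.append(RestrictionFragment(chrom, int(a), int(b)))
    return fragments


def _union_coverage(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open intervals into a disjoint sorted union."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def bin_features(
    fragments: Sequence[RestrictionFragment],
    genome: GenomeSequence,
    chrom: str,
    bin_size: int = 2000,
    end_flank: int = 200,
    eff_flank: int = 500,
    mappability: np.ndarray | None = None,
) -> BinFeatures:
    """Per-bin normalization covariates for one chromosome.

    end_count counts interior cut positions (fragment boundaries) in the bin;
    gc_ends is the GC fraction of the union of ``end_flank``-bp windows on
    both sides of each such cut; eff_len is the fraction of the bin within
    ``eff_flank`` bp of any cut on the chromosome.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if end_flank <= 0 or eff_flank <= 0:
        raise ValueError("flank sizes must be positive")
    seq = genome.sequences[chrom].upper()
    n = len(seq)
    n_bins = -(-n // bin_size)

    # interior cut positions = shared boundaries of successive fragments
    frags = sorted(
        (f for f in fragments if f.chrom == chrom), key=lambda f: f.start
    )
    cuts = np.asarray(
        [f.start for f in frags if f.start > 0], dtype=np.int64
    )

    end_count = np.zeros(n_bins, dtype=np.int64)
    gc_ends = np.zeros(n_bins, dtype=float)
    eff_len = np.zeros(n_bins, dtype=float)

    if len(cuts):
        np.add.at(end_count, cuts // bin_size, 1)

    gc_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (gc_arr == ord("G")) | (gc_arr == ord("C"))
    gc_cum = np.concatenate([[0], np.cumsum(is_gc)])

    def gc_of_union(windows: list[tuple[int, int]]) -> float:
        merged = _union_coverage([(max(0, a), min(n, b)) for a, b in windows])
        tot = sum(b - a for a, b in merged)
        if tot == 0:
            return 0.0
        gc = sum(gc_cum[b] - gc_cum[a] for a, b in merged)
        return gc / tot

    for b in range(n_bins):
        lo, hi = b * bin_size, min((b + 1) * bin_size, n)
        a0, a1 = np.searchsorted(cuts, [lo, hi])
        in_bin = cuts[a0:a1]
        if len(in_bin):
            gc_ends[b] = gc_of_union(
                [(int(c) - end_flank, int(c) + end_flank) for c in in_bin]
            )
        b0 = np.searchsorted(cuts, lo - eff_flank, side="right")
        b1 = np.searchsorted(cuts, hi + eff_flank, side="left")
        near = _union_coverage(
            [
                (max(lo, int(c) - eff_flank), min(hi, int(c) + eff_flank))
                for c in cuts[b0:b1]
            ]
        )
        eff_len[b] = sum(e - s for s, e in near) / (hi - lo)

    if mappability is None:
        mapp = np.ones(n_bins, dtype=float)
    else:
        mapp = np.asarray(mappability, dtype=float)
        if len(mapp) != n_bins:
            raise ValueError("mappability track length does not match bin count")
    return BinFeatures(chrom, bin_size, eff_len, gc_ends, end_count, mapp)


def centromere_mask(
    spans: Mapping[str, tuple[int, int]] | str,
    bin_size: int,
) -> dict[str, set[int]]:
    """Bin indices overlapping centromeric spans, per chromosome.

    ``spans`` is either an explicit {chrom: (start_bp, end_bp)} mapping or the
    assembly name ``"TAIR10"`` for the built-in A. thaliana spans.
    """
    if isinstance(spans, str):
        if spans != "TAIR10":
            raise ValueError(f"unknown assembly {spans!r}; pass explicit spans")
        spans = ARABIDOPSIS_CENTROMERES
    out: dict[str, set[int]] = {}
    for chrom, (start, end) in spans.items():
        if start >= end:
            raise ValueError(f"bad centromere span for {chrom}: {start}-{end}")
        first = start // bin_size
        last = -(-end // bin_size)  # ceil; half-open bin range
        out[chrom] = set(range(first, last))
    return out
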