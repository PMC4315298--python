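"""Classification and filtering of mapped Hi-C read pairs.

A Hi-C library contains, besides genuine proximity-ligation products,
self-ligated fragments, undigested loops, and ordinary genomic inserts that
slipped through size selection.  Mapped pairs are sorted into classes using
the geometry of the two reads relative to the restriction digest:

* interchromosomal pairs are valid only if the mapped lengths plus each
  read's distance to its first downstream cut site fit in the library insert
  (< 600 bp) — otherwise the two reads cannot come from one ligation product;
* intrachromosomal forward/reverse (FR, paired-end mode) pairs are valid if
  the apparent insert exceeds 600 bp (shorter ones are ordinary inserts);
* reverse/forward (RF, mate-pair mode) pairs are self-ligation products if
  no cut site lies between the reads, and are discarded as likely
  incomplete-digestion artifacts if the mapped loci are closer than 1500 bp.

FF/RR pairs cannot arise from self-ligation or an undigested linear
fragment, so they are kept as valid with no distance filter; the census
reports them so the choice is auditable.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PairRecord",
    "PAIR_CLASSES",
    "orient",
    "classify_pair",
    "dedup",
    "filter_pairs",
]

PAIR_CLASSES = (
    "valid_intra",
    "valid_inter",
    "short_insert",
    "self_ligation",
    "too_close",
)


@dataclass(frozen=True)
class PairRecord:
    """One uniquely mapped read pair (0-based leftmost positions)."""

    chrom1: str
    pos1: int
    strand1: str
    len1: int
    chrom2: str
    pos2: int
    strand2: str
    len2: int

    def canonical(self) -> "PairRecord":
        """Order sides so (chrom1,pos1) <= (chrom2,pos2)."""
        if (self.chrom1, self.pos1) <= (self.chrom2, self.pos2):
            return self
        return PairRecord(
            self.chrom2, self.pos2, self.strand2, self.len2,
            self.chrom1, self.pos1, self.strand1, self.len1,
        )


def orient(pair: PairRecord) -> str:
    """Orientation mode FR/RF/FF/RR of a canonically ordered pair."""
    s1, s2 = pair.strand1, pair.strand2
    if s1 == "+" and s2 == "-":
        return "FR"
    if s1 == "-" and s2 == "+":
        return "RF"
    return "FF" if s1 == "+" else "RR"


def _dist_to_downstream_cut(
    pos: int, length: int, strand: str, cuts: Sequence[int], chrom_len: int
) -> int:
    """Distance from a read's 3' end to the first cut site in its 5'->3'
    direction; reads mapping past the last cut get the distance to the
    chromosome end (or start, for minus-strand reads)."""
    if strand == "+":
        three_prime = pos + length
        i = bisect_left(cuts, three_prime)
        return (cuts[i] if i < len(cuts) else chrom_len) - three_prime
    three_prime = pos
    i = bisect_right(cuts, three_prime) - 1
    return three_prime - (cuts[i] if i >= 0 else 0)


def classify_pair(
    pair: PairRecord,
    cut_index: Mapping[str, Sequence[int]],
    chrom_lengths: Mapping[str, int],
    insert_max: int = 600,
    min_rf_distance: int = 1500,
) -> str:
    """Assign a single filter class to a mapped pair.

    ``cut_index`` maps chromosome name to an ascending array of cut
    positions (bp).  Raises ``KeyError`` for a chromosome without cuts
    indexed, since the self-ligation and insert criteria are undefined then.
    """
    for chrom in (pair.chrom1, pair.chrom2):
        if chrom not in cut_index:
            raise KeyError(f"chromosome {chrom!r} missing from the cut index")

    if pair.chrom1 != pair.chrom2:
        d1 = _dist_to_downstream_cut(
            pair.pos1, pair.len1, pair.strand1,
            cut_index[pair.chrom1], chrom_lengths[pair.chrom1],
        )
        d2 = _dist_to_downstream_cut(
            pair.pos2, pair.len2, pair.strand2,
            cut_index[pair.chrom2], chrom_lengths[pair.chrom2],
        )
        if pair.len1 + pair.len2 + d1 + d2 < insert_max:
            return "valid_inter"
        return "short_insert"

    p = pair.canonical()
    mode = orient(p)
    cuts = cut_index[p.chrom1]
    if mode == "FR":
        apparent_insert = p.pos2 + p.len2 - p.pos1
        return "valid_intra" if apparent_insert > insert_max else "short_insert"
    if mode == "RF":
        # cut "between mapped reads": in [inner end of left read, start of right)
        lo, hi = p.pos1 + p.len1, p.pos2
        i = bisect_left(cuts, lo)
        has_cut_between = i < len(cuts) and cuts[i] < hi
        if not has_cut_between:
            return "self_ligation"
        if abs(p.pos2 - p.pos1) < min_rf_distance:
            return "too_close"
        return "valid_intra"
    return "valid_intra"  # FF/RR: no self-ligation geometry possible


def dedup(pairs: Iterable[PairRecord]) -> list[PairRecord]:
    """Drop PCR duplicates: keep the first pair per canonical
    (chrom1,pos1,strand1,chrom2,pos2,strand2) key."""
    seen: set[tuple] = set()
    out: list[PairRecord] = []
    for pair in pairs:
        p = pair.canonical()
        key = (p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2)
        if key not in seen:
            seen.add(key)
            out.append(pair)
    return out


def filter_pairs(
    pairs: Iterable[PairRecord],
    cut_index: Mapping[str, Sequence[int]],
    chrom_lengths: Mapping[str, int],
    insert_max: int = 600,
    min_rf_distance: int = 1500,
) -> tuple[list[PairRecord], Counter]:
    """Deduplicate, classify, and keep valid contacts.

    Returns the valid (intra + inter) pairs in input order and a census of
    every class over the deduplicated input.
    """
    unique = dedup(pairs)
    census: Counter = Counter()
    valid: list[PairRecord] = []
    for pair in unique:
        label = classify_pair(
            pair, cut_index, chrom_lengths, insert_max, min_rf_distance
        )
        census[label] += 1
        if label in ("valid_intra", "valid_inter"):
            valid.append(pair)
    return valid, census
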