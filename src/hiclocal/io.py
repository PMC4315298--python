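"""Readers and writers for the pipeline's plain-text formats.

Everything is 0-based half-open internally and on disk: BED and bedGraph
natively are; the pairs TSV and contact coordinate lists are written that
way by convention.  Each written file carries a provenance comment header
("#" lines) with the producing stage and parameters.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeSequence, RestrictionFragment
from .matrix import ContactMatrix
from .pairs import PairRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_bed",
    "write_bedgraph",
    "write_pairs",
    "read_pairs",
    "write_contacts",
    "read_contacts",
]


def read_fasta(path) -> GenomeSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    names = [r.id for r in records]
    return GenomeSequence(names, {r.id: str(r.seq).upper() for r in records})


def write_fasta(genome: GenomeSequence, path) -> None:
    records = [
        SeqRecord(Seq(genome.sequences[c]), id=c, description="")
        for c in genome.chrom_names
    ]
    SeqIO.write(records, str(path), "fasta")


def _header(lines: Sequence[str]) -> str:
    return "".join(f"# {l}\n" for l in lines)


def write_bed(
    rows: Iterable[tuple],
    path,
    provenance: Sequence[str] = (),
) -> None:
    """Write (chrom, start, end[, name[, score]]) rows as BED."""
    with open(path, "w") as fh:
        fh.write(_header(provenance))
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(
    chrom: str,
    values: np.ndarray,
    bin_size: int,
    path,
    provenance: Sequence[str] = (),
) -> None:
    """Per-bin track as bedGraph; NaN (undefined) bins are omitted."""
    with open(path, "w") as fh:
        fh.write(_header(provenance))
        for i, v in enumerate(values):
            if isinstance(v, float) and np.isnan(v):
                continue
            fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v}\n")


PAIRS_COLUMNS = (
    "chrom1", "pos1", "strand1", "len1", "chrom2", "pos2", "strand2", "len2"
)


def write_pairs(pairs: Iterable[PairRecord], path, provenance: Sequence[str] = ()) -> None:
    """Tab-delimited pairs records, 0-based positions, strands +/-."""
    with open(path, "w") as fh:
        fh.write(_header(provenance))
        fh.write("#" + "\t".join(PAIRS_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.chrom1}\t{p.pos1}\t{p.strand1}\t{p.len1}\t"
                f"{p.chrom2}\t{p.pos2}\t{p.strand2}\t{p.len2}\n"
            )


def read_pairs(path) -> list[PairRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c1, p1, s1, l1, c2, p2, s2, l2 = line.rstrip("\n").split("\t")
            out.append(
                PairRecord(c1, int(p1), s1, int(l1), c2, int(p2), s2, int(l2))
            )
    return out


def write_contacts(mat: ContactMatrix, path, provenance: Sequence[str] = ()) -> None:
    """Upper-triangle coordinate list (bin_i, bin_j, value), 0-based bins;
    zero cells are omitted."""
    with open(path, "w") as fh:
        fh.write(_header(
            list(provenance)
            + [f"chrom={mat.chrom} bin_size={mat.bin_size} "
               f"n_bins={mat.n_bins} kind={mat.kind}"]
        ))
        i, j = np.triu_indices(mat.n_bins)
        vals = mat.values[i, j]
        nz = vals != 0
        for a, b, v in zip(i[nz], j[nz], vals[nz]):
            fh.write(f"{a}\t{b}\t{v:.10g}\n")


def read_contacts(path) -> ContactMatrix:
    chrom, bin_size, n_bins, kind = "chr", 1, None, "raw"
    triplets = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k == "chrom":
                            chrom = v
                        elif k == "bin_size":
                            bin_size = int(v)
                        elif k == "n_bins":
                            n_bins = int(v)
                        elif k == "kind":
                            kind = v
                continue
            if line.strip():
                a, b, v = line.split("\t")
                triplets.append((int(a), int(b), float(v)))
    if n_bins is None:
        n_bins = 1 + max(max(a, b) for a, b, _ in triplets) if triplets else 0
    M = np.zeros((n_bins, n_bins))
    for a, b, v in triplets:
        M[a, b] = v
        M[b, a] = v
    return ContactMatrix(chrom, bin_size, M, np.ones(n_bins, dtype=bool), kind)
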