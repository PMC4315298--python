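"""Synthetic genomes, contact maps, epigenomes, and read-pair populations.

Every downstream stage is exercised against data with known ground truth:

* ``gen_genome`` — random chromosomes with a restriction motif injected at a
  controlled per-bp rate, so in-silico digestion yields realistic fragment
  sizes (a 4-cutter at ~1/250 bp gives a median fragment around 170 bp).
* ``gen_contact_map`` — Poisson contact counts with a power-law distance
  decay, multiplicative per-bin biases, planted high-contact strip bins
  (boosted within 50 kb), and planted blocks of upstream/downstream
  interaction bias confined to the 60-kb DI window, with insulator points
  at up->down block junctions.
* ``gen_epigenome`` — per-bin coverage fractions for the 16-mark panel
  conditioned on six latent chromatin states.
* ``gen_read_pairs`` — labelled pair populations (valid intra/inter,
  self-ligation, undigested loop, short insert) whose geometry realizes
  each class by construction.

Counts are Poisson throughout, matching the distribution the bias
regression assumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeSequence
from .matrix import ContactMatrix
from .pairs import PairRecord
from .states import MARK_NAMES

__all__ = [
    "SyntheticTruth",
    "gen_genome",
    "gen_contact_map",
    "gen_epigenome",
    "gen_read_pairs",
    "DEFAULT_EMISSIONS",
]

PAIR_CLASS_NAMES = (
    "valid_intra",
    "valid_inter",
    "self_ligation",
    "undigested_loop",
    "short_insert",
)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators.

    ``bias_block_spans`` are half-open (start_bin, end_bin, direction)
    spans; ``insulator_bins`` mark up->down junctions between adjacent
    blocks; ``pair_labels`` parallel the generated pair list.
    """

    strip_bins: set[int] = field(default_factory=set)
    bias_block_spans: list[tuple[int, int, str]] = field(default_factory=list)
    insulator_bins: set[int] = field(default_factory=set)
    state_labels: np.ndarray | None = None
    pair_labels: list[str] = field(default_factory=list)
    bin_bias: np.ndarray | None = None


def gen_genome(
    n_chrom: int,
    lengths: list[int],
    gc: float = 0.36,
    site: str = "GATC",
    site_rate: float = 1 / 250,
    seed: int = 0,
) -> GenomeSequence:
    """Random chromosomes with a restriction motif injected at ``site_rate``.

    The background composition has the requested GC; motif copies are then
    written over the background at Bernoulli(site_rate) start positions
    (non-overlapping), so digestion produces approximately geometric
    fragment lengths with mean ~1/site_rate.
    """
    if n_chrom <= 0 or len(lengths) != n_chrom:
        raise ValueError("lengths must list one length per chromosome")
    if any(l < 10_000 for l in lengths):
        raise ValueError("chromosome lengths must be at least 10 kb")
    if not 0 <= gc < 1:
        raise ValueError("gc must be a fraction in [0, 1)")
    if site_rate < 0:
        raise ValueError("site_rate must be nonnegative")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs: dict[str, str] = {}
    motif = np.array(list(site))
    for name, L in zip(names, lengths):
        arr = rng.choice(bases, size=L, p=probs)
        if site_rate > 0:
            # scrub chance occurrences so the digest density is set by
            # site_rate alone, then inject at Bernoulli(site_rate)
            text = "".join(arr)
            for _ in range(5):
                hits = [m.start() for m in re.finditer(f"(?={site})", text)]
                if not hits:
                    break
                for h in hits:
                    k = h + len(site) // 2
                    alt = [b for b in "ACGT" if b != site[len(site) // 2]]
                    arr[k] = alt[rng.integers(len(alt))]
                text = "".join(arr)
            starts = np.flatnonzero(
                rng.random(L - len(site)) < site_rate
            )
            last_end = -1
            for s in starts:
                if s >= last_end:
                    arr[s : s + len(site)] = motif
                    last_end = s + len(site)
        seqs[name] = "".join(arr)
    return GenomeSequence(names, seqs)


def gen_contact_map(
    n_bins: int,
    bin_size: int = 2000,
    decay_exponent: float = -1.0,
    base_count: float = 50.0,
    truth: SyntheticTruth | None = None,
    strip_boost: float = 3.0,
    di_block_strength: float = 2.0,
    seed: int = 0,
    chrom: str = "chr1",
    strip_reach_bins: int = 25,
    di_window_bins: int = 30,
) -> tuple[ContactMatrix, SyntheticTruth]:
    """Poisson contact map with planted strips and directionality blocks.

    Expected count for bins i < j:

        lam_ij = base_count * (j - i)^decay_exponent * bias_i * bias_j
                 * strip_boost^[i or j is a strip bin and j-i <= 25 bins]
                 * di_block_strength^[the pair realizes a planted
                                      directional preference within 60 kb]

    The strip boost is symmetric (both the row and the column of a strip
    bin light up), mirroring how strips appear on a Hi-C map.  Directional
    blocks multiply only the contacts of a block bin with bins on its
    preferred side within the DI window, the minimal structure the DI
    statistic detects.  The diagonal uses distance 1 for the decay term.
    """
    if n_bins < 60:
        raise ValueError("need at least 60 bins to support a 60-kb DI window")
    if decay_exponent >= 0:
        raise ValueError("decay_exponent must be negative")
    if strip_boost <= 1 or di_block_strength < 1:
        raise ValueError("boost factors must exceed 1")
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = SyntheticTruth()
    if truth.bin_bias is None:
        truth.bin_bias = np.ones(n_bins)
    bias = np.asarray(truth.bin_bias, dtype=float)
    if (bias <= 0).any():
        raise ValueError("bin biases must be strictly positive")
    for s, e, direction in truth.bias_block_spans:
        if not (0 <= s < e <= n_bins) or direction not in ("up", "down"):
            raise ValueError(f"bad bias block ({s}, {e}, {direction})")

    i, j = np.triu_indices(n_bins)
    dist = np.maximum(j - i, 1)
    lam = base_count * dist.astype(float) ** decay_exponent * bias[i] * bias[j]

    if truth.strip_bins:
        strip = np.zeros(n_bins, dtype=bool)
        strip[list(truth.strip_bins)] = True
        touching = (strip[i] | strip[j]) & (j - i <= strip_reach_bins) & (j > i)
        lam[touching] *= strip_boost

    if truth.bias_block_spans and di_block_strength > 1:
        in_down = np.zeros(n_bins, dtype=bool)
        in_up = np.zeros(n_bins, dtype=bool)
        for s, e, direction in truth.bias_block_spans:
            (in_down if direction == "down" else in_up)[s:e] = True
        w = j - i
        # bin i prefers downstream partners; bin j prefers upstream ones
        boosted = (w >= 1) & (w <= di_window_bins) & (in_down[i] | in_up[j])
        lam[boosted] *= di_block_strength

    counts = rng.poisson(lam).astype(float)
    M = np.zeros((n_bins, n_bins))
    M[i, j] = counts
    M[j, i] = counts
    mat = ContactMatrix(chrom, bin_size, M, np.ones(n_bins, dtype=bool), "raw")
    return mat, truth


#: Default state-conditional enrichment probabilities: each latent state is
#: strongly enriched (0.8) for a disjoint group of marks, over a low
#: spurious-peak background (0.05) shared by all marks — real ChIP tracks
#: always carry some genome-wide background enrichment.
DEFAULT_EMISSIONS: np.ndarray = np.full((6, len(MARK_NAMES)), 0.05)
for _s, _marks in enumerate(
    [
        ("H3K4me2", "H3K4me3", "H3K9ac", "H3K18ac"),  # active chromatin
        ("H3K27me3", "H3.1", "H3.3"),                 # Polycomb-like
        ("H3K9me2", "H3K27me1", "mCG"),               # heterochromatin
        ("H4K20me1",),                                # weakly marked
        ("H3K36me2", "H3K36me3", "H2Bub"),            # transcribed bodies
        ("mCHG", "mCHH"),                             # non-CG methylation
    ]
):
    for _m in _marks:
        DEFAULT_EMISSIONS[_s, MARK_NAMES.index(_m)] = 0.8


def gen_epigenome(
    n_bins: int,
    state_labels: np.ndarray,
    emission_table: np.ndarray = DEFAULT_EMISSIONS,
    seed: int = 0,
) -> np.ndarray:
    """Per-bin per-mark coverage fractions conditioned on latent states.

    For a bin in state s and mark m with probability p = emission[s-1, m],
    coverage is drawn Uniform(max(0, 2p-1), min(1, 2p)) — mean exactly p —
    or is exactly 0 when p = 0, so all-zero emission rows produce fully
    "unclear" bins.
    """
    state_labels = np.asarray(state_labels)
    if len(state_labels) != n_bins:
        raise ValueError("state_labels must have one entry per bin")
    if state_labels.min() < 1 or state_labels.max() > emission_table.shape[0]:
        raise ValueError("state labels must be in 1..6")
    emission_table = np.asarray(emission_table, dtype=float)
    if ((emission_table < 0) | (emission_table > 1)).any():
        raise ValueError("emission probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = emission_table[state_labels - 1]  # (n_bins, n_marks)
    lo = np.maximum(0.0, 2 * p - 1)
    hi = np.minimum(1.0, 2 * p)
    cov = lo + rng.random(p.shape) * (hi - lo)
    cov[p == 0] = 0.0
    return cov


def _pick_fragment(rng, cuts: np.ndarray, chrom_len: int, min_len: int) -> tuple[int, int]:
    """A random restriction fragment (between successive cuts) of at least
    ``min_len`` bp."""
    bounds = np.concatenate([[0], cuts, [chrom_len]])
    lens = np.diff(bounds)
    ok = np.flatnonzero(lens >= min_len)
    if len(ok) == 0:
        raise ValueError("no restriction fragment long enough for this class")
    k = ok[rng.integers(len(ok))]
    return int(bounds[k]), int(bounds[k + 1])


def gen_read_pairs(
    genome: GenomeSequence,
    cut_index: dict[str, np.ndarray],
    n_pairs: int,
    class_mix: dict[str, float] | None = None,
    read_len: int = 50,
    insert_max: int = 600,
    min_rf_distance: int = 1500,
    seed: int = 0,
) -> tuple[list[PairRecord], SyntheticTruth]:
    """Labelled read-pair populations realizing each filter class.

    Geometry by construction (0-based leftmost positions, reads never
    placed on exact thresholds):

    * valid_intra — FR with apparent insert > 600 bp, or RF with a cut
      site between the reads and distance >= 1500 bp;
    * self_ligation — RF with both reads inside one restriction fragment
      (no cut site between them);
    * undigested_loop — RF with a cut between reads but distance < 1500 bp
      (removed downstream as "too_close");
    * short_insert — FR with apparent insert <= 600 bp;
    * valid_inter — reads on two chromosomes, each a short distance
      upstream of a cut site so the inferred insert is < 600 bp.
    """
    if class_mix is None:
        class_mix = {
            "valid_intra": 0.5,
            "self_ligation": 0.2,
            "undigested_loop": 0.2,
            "short_insert": 0.1,
        }
    unknown = set(class_mix) - set(PAIR_CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown pair classes in mix: {sorted(unknown)}")
    mix = np.array([class_mix.get(c, 0.0) for c in PAIR_CLASS_NAMES])
    if not np.isclose(mix.sum(), 1.0):
        raise ValueError("class_mix must sum to 1")
    rng = np.random.default_rng(seed)
    chroms = genome.chrom_names
    lengths = genome.lengths()
    for c in chroms:
        if (mix[0] > 0 or mix[2] > 0) and len(cut_index.get(c, ())) == 0:
            raise ValueError(
                f"cut index for {c} is empty; cannot construct pairs that "
                "need a cut site between reads"
            )
    if mix[1] > 0 and len(chroms) < 2:
        raise ValueError("valid_inter pairs need at least two chromosomes")

    pairs: list[PairRecord] = []
    labels: list[str] = []
    draws = rng.choice(len(PAIR_CLASS_NAMES), size=n_pairs, p=mix)
    L = read_len
    for d in draws:
        cls = PAIR_CLASS_NAMES[d]
        chrom = chroms[rng.integers(len(chroms))]
        clen = lengths[chrom]
        cuts = np.asarray(cut_index[chrom])
        if cls == "valid_intra":
            if rng.random() < 0.5 or len(cuts) == 0:
                # FR, apparent insert well above the threshold
                insert = int(rng.integers(insert_max + 50, 60_000))
                pos1 = int(rng.integers(0, max(1, clen - insert - 1)))
                pair = PairRecord(chrom, pos1, "+", L, chrom, pos1 + insert - L, "-", L)
            else:
                # RF spanning a cut, distance above the threshold
                usable = cuts[(cuts > L + 300) & (cuts < clen - 8000)]
                c = int(usable[rng.integers(len(usable))])
                gap = int(rng.integers(min_rf_distance + 50, min_rf_distance + 5000))
                pos1 = c - L - int(rng.integers(10, 200))
                pos2 = pos1 + gap
                pair = PairRecord(chrom, pos1, "-", L, chrom, pos2, "+", L)
        elif cls == "self_ligation":
            fs, fe = _pick_fragment(rng, cuts, clen, 2 * L + 20)
            pos1 = fs + int(rng.integers(0, fe - fs - 2 * L - 10))
            pos2 = int(rng.integers(pos1 + L, fe - L)) if fe - L > pos1 + L else pos1 + L
            pair = PairRecord(chrom, pos1, "-", L, chrom, pos2, "+", L)
        elif cls == "undigested_loop":
            usable = cuts[(cuts > L + 300) & (cuts < clen - 1500)]
            c = int(usable[rng.integers(len(usable))])
            pos1 = c - L - int(rng.integers(10, 200))
            pos2 = c + 1 + int(rng.integers(10, min_rf_distance - (c - pos1) - 60))
            pair = PairRecord(chrom, pos1, "-", L, chrom, pos2, "+", L)
        elif cls == "short_insert":
            insert = int(rng.integers(2 * L + 1, insert_max))
            pos1 = int(rng.integers(0, clen - insert - 1))
            pair = PairRecord(chrom, pos1, "+", L, chrom, pos1 + insert - L, "-", L)
        else:  # valid_inter
            c1, c2 = rng.choice(len(chroms), size=2, replace=False)
            sides = []
            for cn in (chroms[c1], chroms[c2]):
                ccuts = np.asarray(cut_index[cn])
                usable = ccuts[(ccuts > L + 50) & (ccuts < lengths[cn] - 50)]
                cut = int(usable[rng.integers(len(usable))])
                d_down = int(rng.integers(0, (insert_max - 2 * L) // 2 - 10))
                sides.append((cn, cut - L - d_down, "+"))
            pair = PairRecord(
                sides[0][0], sides[0][1], "+", L,
                sides[1][0], sides[1][1], "+", L,
            )
        pairs.append(pair)
        labels.append(cls)
    truth = SyntheticTruth(pair_labels=labels)
    return pairs, truth
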