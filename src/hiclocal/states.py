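"""Epigenetic-mark scoring, chromatin-state segmentation, and profiles.

Sixteen epigenetic marks (histone modifications, histone variants, and DNA
methylation contexts) are summarized per 400-bp (or 2-kb) bin as the
fraction of the bin covered by the mark's enriched intervals.  Per mark,
covered bins get an integer quintile score 0-4; bins scoring 0 for all 16
marks are "unclear" and excluded from clustering.  k-means (Euclidean,
k = 6) on the 16-dimensional score vectors defines chromatin states
CS1-CS6, named by matching centroids to canonical profiles:

* CS1 — active euchromatin (H3K4me2/3, H3K9ac, H3K36me3, H2Bub);
* CS2 — Polycomb chromatin (H3K27me3, H3.1, H3.3);
* CS3 — classical heterochromatin (H3K9me2, H3K27me1, DNA methylation);
* CS4 — no particular enrichment;
* CS5 — CS1-like with stronger H3K36me2, H2Bub, H3.3;
* CS6 — CS3-like with weaker H3K9me2 / H3K27me1.

The module also carries RPKM expression normalization, nine-way expression
grouping, and aggregation of any per-bin annotation around called regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "MARK_NAMES",
    "CANONICAL_STATE_PROFILES",
    "MarkScoreMatrix",
    "ChromatinStateAssignment",
    "mark_coverage",
    "quintile_scores",
    "classify_states",
    "name_states",
    "pca_project",
    "rpkm",
    "expression_groups",
    "profile_around",
]

#: The 16-mark panel: histone methylations/acetylations, ubiquitination,
#: histone variants, and the three DNA-methylation contexts.
MARK_NAMES = (
    "H3K4me2", "H3K4me3", "H3K9ac", "H3K18ac",
    "H3K36me2", "H3K36me3", "H2Bub", "H3K9me2",
    "H3K27me1", "H3K27me3", "H4K20me1", "H3.1",
    "H3.3", "mCG", "mCHG", "mCHH",
)

#: Editable canonical profiles (relative enrichment per mark, one row per
#: state) used to name k-means centroids.  Magnitudes are nominal; naming
#: uses cosine similarity, so only the pattern matters.
CANONICAL_STATE_PROFILES: dict[str, dict[str, float]] = {
    "CS1": {"H3K4me2": 3, "H3K4me3": 3, "H3K9ac": 3, "H3K18ac": 3,
            "H3K36me2": 2, "H3K36me3": 3, "H2Bub": 2, "H3.3": 1},
    "CS2": {"H3K27me3": 4, "H3.1": 3, "H3.3": 3, "H3K4me2": 1},
    "CS3": {"H3K9me2": 4, "H3K27me1": 3, "H4K20me1": 2, "H3.1": 2,
            "mCG": 3, "mCHG": 3, "mCHH": 3},
    "CS4": {},
    "CS5": {"H3K4me2": 2, "H3K4me3": 2, "H3K9ac": 2, "H3K18ac": 2,
            "H3K36me2": 4, "H3K36me3": 3, "H2Bub": 4, "H3.3": 3},
    "CS6": {"H3K9me2": 1, "H3K27me1": 1, "H4K20me1": 2, "H3.1": 3,
            "mCG": 3, "mCHG": 2, "mCHH": 2},
}


@dataclass
class MarkScoreMatrix:
    """Integer quintile scores (bins x 16 marks) with an unclear flag."""

    scores: np.ndarray
    unclear: np.ndarray
    marks: tuple[str, ...] = MARK_NAMES


@dataclass
class ChromatinStateAssignment:
    """Per-bin state label (CS1..CS6 or 'unclear') and named centroids."""

    labels: np.ndarray  # dtype=object / str
    centroids: dict[str, np.ndarray]


def mark_coverage(
    intervals: Mapping[str, Sequence[tuple[int, int]]],
    chrom_length: int,
    bin_size: int,
) -> np.ndarray:
    """Fraction of each bin covered by each mark's enriched intervals.

    ``intervals`` maps mark name -> list of (start, end) bp spans on one
    chromosome (0-based half-open); overlapping spans are unioned, so the
    fraction never exceeds 1.
    """
    n_bins = -(-chrom_length // bin_size)
    out = np.zeros((n_bins, len(MARK_NAMES)), dtype=float)
    for m, mark in enumerate(MARK_NAMES):
        spans = sorted(intervals.get(mark, []))
        for a, b in spans:
            if a >= b:
                raise ValueError(f"malformed interval ({a}, {b}) for {mark}")
        merged: list[list[int]] = []
        for a, b in spans:
            a, b = max(0, a), min(chrom_length, b)
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        for a, b in merged:
            first, last = a // bin_size, (b - 1) // bin_size
            for k in range(first, last + 1):
                lo, hi = k * bin_size, min((k + 1) * bin_size, chrom_length)
                out[k, m] += (min(b, hi) - max(a, lo)) / (hi - lo)
    return out


def _midrank_percentiles(values: np.ndarray) -> np.ndarray:
    """Midrank percentile of each value within the array, in [0, 100).

    Equals 100 * (count_less + count_equal/2) / n, via average ranks.
    """
    v = np.asarray(values, dtype=float)
    return 100.0 * (rankdata(v, method="average") - 0.5) / len(v)


def quintile_scores(coverage: np.ndarray) -> MarkScoreMatrix:
    """Integer quintile scores 0-4 per bin and mark.

    Bins with zero coverage for a mark score 0; among covered bins, the
    midrank percentile p assigns quintile q where p is in [20q, 20(q+1)).
    Bins scoring 0 for all marks are flagged unclear.  Invariant under any
    strictly monotone transform of the coverage values.
    """
    coverage = np.asarray(coverage, dtype=float)
    n_bins, n_marks = coverage.shape
    scores = np.zeros((n_bins, n_marks), dtype=int)
    for m in range(n_marks):
        pos = coverage[:, m] > 0
        if pos.any():
            p = _midrank_percentiles(coverage[pos, m])
            q = np.minimum((p // 20).astype(int), 4)
            scores[pos, m] = q
    unclear = (scores == 0).all(axis=1)
    return MarkScoreMatrix(scores, unclear)


def classify_states(
    score_matrix: MarkScoreMatrix,
    k: int = 6,
    seed: int = 0,
    restarts: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means (Euclidean) over non-unclear score vectors.

    Returns (cluster labels with -1 for unclear bins, k x n_marks centroid
    matrix).  The best of ``restarts`` initializations by within-cluster
    sum of squares is kept.
    """
    X = score_matrix.scores[~score_matrix.unclear].astype(float)
    if len(X) < k:
        raise ValueError(f"need at least k={k} non-unclear bins, got {len(X)}")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("fewer than k distinct score vectors")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    fit_labels = km.fit_predict(X)
    labels = np.full(len(score_matrix.scores), -1, dtype=int)
    labels[~score_matrix.unclear] = fit_labels
    return labels, km.cluster_centers_


def name_states(
    centroids: np.ndarray,
    canonical_profiles: Mapping[str, Mapping[str, float]] | None = None,
    marks: Sequence[str] = MARK_NAMES,
) -> list[str]:
    """Name centroids CS1..CS6 by optimal one-to-one cosine matching to the
    canonical profiles.

    The near-zero canonical CS4 profile is represented as a small uniform
    vector so that a featureless centroid matches it.
    """
    if canonical_profiles is None:
        canonical_profiles = CANONICAL_STATE_PROFILES
    names = list(canonical_profiles)
    ref = np.array(
        [
            [canonical_profiles[s].get(m, 0.0) for m in marks]
            for s in names
        ]
    )
    ref[np.linalg.norm(ref, axis=1) == 0] = 0.1  # flat reference for CS4
    C = np.asarray(centroids, dtype=float)
    if C.shape[0] != len(names):
        raise ValueError("number of centroids must match canonical profiles")
    Cn = C / np.maximum(np.linalg.norm(C, axis=1, keepdims=True), 1e-12)
    Rn = ref / np.linalg.norm(ref, axis=1, keepdims=True)
    sim = Cn @ Rn.T
    rows, cols = linear_sum_assignment(-sim)
    out = [""] * len(names)
    for r, c in zip(rows, cols):
        out[r] = names[c]
    return out


def pca_project(score_matrix: MarkScoreMatrix, n_components: int = 3) -> np.ndarray:
    """First principal components of the (non-unclear) score vectors.

    Component signs are fixed by making the largest-magnitude loading of
    each component positive; unclear bins get NaN coordinates.
    """
    X = score_matrix.scores[~score_matrix.unclear].astype(float)
    if len(X) < 4:
        raise ValueError("need at least 4 bins for a PCA projection")
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components)
    Y = pca.fit_transform(X)
    for c in range(n_components):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            Y[:, c] = -Y[:, c]
    out = np.full((len(score_matrix.scores), n_components), np.nan)
    out[~score_matrix.unclear] = Y
    return out


def rpkm(counts, lengths, total_reads: float) -> np.ndarray:
    """Reads per kilobase of transcript per million mapped reads."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if total_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return 1e9 * counts / (total_reads * lengths)


def expression_groups(rpkm_values, n_groups: int = 9) -> np.ndarray:
    """Expression-level groups 1..n_groups.

    Group 1 holds undetected genes (RPKM 0); positive RPKMs are split into
    the remaining groups by midrank percentile (octiles for the default
    nine groups).  Monotone: a higher RPKM never lands in a lower group.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    v = np.asarray(rpkm_values, dtype=float)
    groups = np.ones(len(v), dtype=int)
    pos = v > 0
    if pos.any():
        p = _midrank_percentiles(v[pos])
        width = 100.0 / (n_groups - 1)
        g = np.minimum((p // width).astype(int), n_groups - 2)
        groups[pos] = g + 2
    return groups


def profile_around(
    regions: Sequence,
    track: np.ndarray,
    flank_bins: int,
    categories: Sequence | None = None,
) -> np.ndarray:
    """Average a per-bin track around region anchors (the start bin).

    For a numeric track, returns a (2*flank_bins + 1,) mean profile; for a
    categorical track, pass ``categories`` to get per-position frequencies
    with shape (positions, categories).  Positions beyond the track are
    skipped from the means; an empty region list yields an all-NaN profile.
    """
    n_pos = 2 * flank_bins + 1
    n = len(track)
    anchors = [r.start_bin for r in regions]
    if categories is None:
        sums = np.zeros(n_pos)
        counts = np.zeros(n_pos)
        for a in anchors:
            for k, rel in enumerate(range(-flank_bins, flank_bins + 1)):
                pos = a + rel
                if 0 <= pos < n and not (
                    isinstance(track[pos], float) and np.isnan(track[pos])
                ):
                    sums[k] += track[pos]
                    counts[k] += 1
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    cat_idx = {c: i for i, c in enumerate(categories)}
    freq = np.zeros((n_pos, len(categories)))
    counts = np.zeros(n_pos)
    for a in anchors:
        for k, rel in enumerate(range(-flank_bins, flank_bins + 1)):
            pos = a + rel
            if 0 <= pos < n and track[pos] in cat_idx:
                freq[k, cat_idx[track[pos]]] += 1
                counts[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = freq / counts[:, None]
    out[counts == 0] = np.nan
    return out
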