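"""Contact binning, Poisson bias regression, and local contact strength.

The pair count u_ij between two bins of one chromosome is modelled as
Poisson with

    log lambda_ij = b0 + b_len*log(L_i L_j) + b_gc*log(G_i G_j)
                       + b_end*log(F_i F_j) + log(M_i M_j)

where L is effective fragment length, G the GC content of fragment ends,
F the fragment-end count, and M mappability entering as a fixed offset.
The regression is fitted per chromosome over all unmasked off-diagonal
pairs; the residual matrix (Pearson residuals by default) is the
normalized Hi-C map.  Genomic distance is deliberately not a covariate:
downstream statistics (strip index, directionality index) compare
same-offset values, which neutralizes the distance decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .genome import BinFeatures
from .pairs import PairRecord

__all__ = [
    "ContactMatrix",
    "RegressionFit",
    "bin_contacts",
    "exclusion_mask",
    "normalize",
    "contact_strength",
]


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome contact matrix with a validity mask.

    ``mask`` is True for valid (analysis-included) bins.  Masked bins carry
    zero in every cell.  ``kind`` is "raw" (counts) or "normalized"
    (regression residuals).
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    mask: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != n:
            raise ValueError("mask length must match matrix size")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def zero_masked(self) -> None:
        bad = ~self.mask
        self.values[bad, :] = 0.0
        self.values[:, bad] = 0.0


@dataclass
class RegressionFit:
    """Fitted bias-regression coefficients for one chromosome."""

    intercept: float
    beta_len: float
    beta_gc: float
    beta_end: float
    deviance: float
    n_pairs_fit: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.intercept, self.beta_len, self.beta_gc, self.beta_end]
        )


def bin_contacts(
    contacts: Iterable[PairRecord],
    bin_size: int,
    chrom_lengths: Mapping[str, int],
) -> tuple[dict[str, ContactMatrix], dict[tuple[str, str], int]]:
    """Accumulate valid pairs into per-chromosome raw matrices.

    Returns the intrachromosomal matrices plus a table of interchromosomal
    pair counts per chromosome pair (kept raw; the bias regression indexes a
    single chromosome).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = {c: -(-l // bin_size) for c, l in chrom_lengths.items()}
    mats = {
        c: np.zeros((n, n), dtype=float) for c, n in n_bins.items()
    }
    inter: dict[tuple[str, str], int] = {}
    for p in contacts:
        for chrom, pos in ((p.chrom1, p.pos1), (p.chrom2, p.pos2)):
            if pos >= chrom_lengths[chrom]:
                raise ValueError(
                    f"position {pos} beyond end of {chrom} "
                    f"({chrom_lengths[chrom]} bp)"
                )
        if p.chrom1 == p.chrom2:
            i, j = p.pos1 // bin_size, p.pos2 // bin_size
            m = mats[p.chrom1]
            m[i, j] += 1
            if i != j:
                m[j, i] += 1
        else:
            key = tuple(sorted((p.chrom1, p.chrom2)))
            inter[key] = inter.get(key, 0) + 1
    out = {
        c: ContactMatrix(c, bin_size, m, np.ones(n_bins[c], dtype=bool), "raw")
        for c, m in mats.items()
    }
    return out, inter


def exclusion_mask(
    features: BinFeatures,
    centromere_bins: set[int] | None = None,
    map_min: float = 0.5,
    efflen_min: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-level bin exclusion for one chromosome.

    Returns ``(norm_ok, analysis_ok)`` boolean arrays: bins with mappability
    below ``map_min`` or effective fragment length below ``efflen_min`` are
    excluded from the regression and everything downstream; centromeric bins
    stay in the regression but are excluded from pattern analysis.
    """
    if not (0 <= map_min <= 1 and 0 <= efflen_min <= 1):
        raise ValueError("thresholds must be fractions in [0, 1]")
    norm_ok = (features.mappability >= map_min) & (features.eff_len >= efflen_min)
    analysis_ok = norm_ok.copy()
    if centromere_bins:
        idx = [b for b in centromere_bins if b < len(analysis_ok)]
        analysis_ok[idx] = False
    return norm_ok, analysis_ok


def _design(features: BinFeatures, ok: np.ndarray):
    """Log-product covariates for all unmasked off-diagonal pairs (i<j)."""
    idx = np.flatnonzero(ok)
    ii, jj = np.triu_indices(len(idx), k=1)
    i, j = idx[ii], idx[jj]
    L = features.eff_len
    G = features.gc_ends
    F = features.end_count.astype(float)
    M = features.mappability
    X = np.column_stack(
        [
            np.log(L[i] * L[j]),
            np.log(G[i] * G[j]),
            np.log(F[i] * F[j]),
        ]
    )
    offset = np.log(M[i] * M[j])
    return i, j, X, offset


def normalize(
    raw: ContactMatrix,
    features: BinFeatures,
    norm_ok: np.ndarray | None = None,
    analysis_ok: np.ndarray | None = None,
    residual: str = "pearson",
    max_iter: int = 100,
) -> tuple[ContactMatrix, RegressionFit]:
    """Fit the Poisson bias regression and return the residual matrix.

    Bins whose covariates contain a zero (no fragment end in the bin) have
    an undefined log-covariate and are auto-masked with a warning.  The
    mappability product enters as a fixed offset, i.e. with coefficient 1.
    ``residual`` selects Pearson ``(u - lam)/sqrt(lam)`` (default;
    variance-stabilized and comparable across the distance decay) or
    ``raw`` ``u - lam``.
    """
    if raw.kind != "raw":
        raise ValueError("normalize expects a raw count matrix")
    if residual not in ("pearson", "raw"):
        raise ValueError("residual must be 'pearson' or 'raw'")
    n = raw.n_bins
    if norm_ok is None:
        norm_ok = np.ones(n, dtype=bool)
    norm_ok = np.asarray(norm_ok, dtype=bool).copy()

    degenerate = (
        (features.eff_len <= 0)
        | (features.gc_ends <= 0)
        | (features.end_count <= 0)
        | (features.mappability <= 0)
    )
    auto = norm_ok & degenerate
    if auto.any():
        warnings.warn(
            f"{auto.sum()} bin(s) with a zero covariate auto-masked "
            f"on {raw.chrom}",
            stacklevel=2,
        )
        norm_ok &= ~degenerate
    m = int(norm_ok.sum())
    if m * (m - 1) // 2 <= 4:
        raise ValueError(
            "too few unmasked bins: the regression needs more off-diagonal "
            "pairs than coefficients"
        )

    i, j, X, offset = _design(features, norm_ok)
    u = raw.values[i, j]
    # a constant covariate is unidentifiable from the intercept; drop it
    # from the design (slope reported as 0)
    keep = np.ptp(X, axis=0) > 0
    design = np.column_stack([np.ones(len(u)), X[:, keep]])
    model = sm.GLM(
        u, design, family=sm.families.Poisson(), offset=offset
    )
    res = model.fit(maxiter=max_iter)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(
            f"bias regression did not converge on {raw.chrom}; "
            f"deviance {res.deviance}"
        )
    lam = res.mu
    slopes = np.zeros(3)
    slopes[keep] = res.params[1:]

    values = np.zeros((n, n), dtype=float)
    if residual == "pearson":
        r = (u - lam) / np.sqrt(lam)
    else:
        r = u - lam
    values[i, j] = r
    values[j, i] = r

    mask = norm_ok if analysis_ok is None else (norm_ok & analysis_ok)
    out = ContactMatrix(raw.chrom, raw.bin_size, values, mask, "normalized")
    out.zero_masked()
    fit = RegressionFit(
        intercept=float(res.params[0]),
        beta_len=float(slopes[0]),
        beta_gc=float(slopes[1]),
        beta_end=float(slopes[2]),
        deviance=float(res.deviance),
        n_pairs_fit=len(u),
    )
    return out, fit


def contact_strength(norm: ContactMatrix, window_bins: int = 5) -> np.ndarray:
    """Sum of a bin's normalized contacts with its neighbors within
    ``window_bins`` bins on each side (10 kb at 2-kb bins).

    Out-of-range and masked neighbors are skipped; masked focal bins get
    NaN.
    """
    if norm.kind != "normalized":
        raise ValueError("contact_strength expects a normalized matrix")
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    n = norm.n_bins
    out = np.full(n, np.nan)
    v, ok = norm.values, norm.mask
    for i in range(n):
        if not ok[i]:
            continue
        total = 0.0
        for o in range(1, window_bins + 1):
            if i - o >= 0 and ok[i - o]:
                total += v[i, i - o]
            if i + o < n and ok[i + o]:
                total += v[i, i + o]
        out[i] = total
    return out
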