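"""Directionality index, 3-state HMM decoding, and region grammars.

The directionality index (DI) of bin i contrasts its summed normalized
contacts with the 30 upstream bins (A) and 30 downstream bins (B) within
60 kb:

    E = (A + B) / 2
    DI = sign(B - A) * [ (A - E)^2 / E + (B - E)^2 / E ]

Positive DI means downstream-biased interactions.  A three-state Gaussian
HMM on the DI track labels each bin U (upstream-biased; most negative
emission mean), D (downstream-biased; most positive), or N (no bias).
Excluded bins (failed normalization or centromeric) split the state string
into independent segments; no pattern may span a gap.

Region grammars over the decoded states, matched with a sliding window:

* insulator-like: cores UUDD / UUNDD / UUNNDD (types A/B/C) with at least
  two flanking states on each side; the called region is the central
  UD / UND / UNND.
* TAD-boundary-like: UUUUU(D/N)(D/N)X and X(U/N)(U/N)DDDDD; the called
  region is the U->(D/N) junction or the (U/N)->D junction (2 bins).
* TAD-interior-like: the mirror patterns X(D/N)(D/N)UUUUU and
  DDDDD(U/N)(U/N)X, calling the (D/N)->U and D->(U/N) junctions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .matrix import ContactMatrix

__all__ = [
    "StateTrack",
    "RegionCall",
    "directionality_index",
    "fit_hmm",
    "extract_insulators",
    "extract_boundaries",
    "extract_interiors",
]


@dataclass
class StateTrack:
    """Per-bin DI and decoded HMM state for one chromosome.

    ``states`` holds one character per bin: U, D, N, or "." for excluded
    bins (NaN DI), which break the chain into independent segments.
    """

    chrom: str
    di: np.ndarray
    states: str


@dataclass(frozen=True)
class RegionCall:
    """A called region (bin units, half-open) with its grammar type."""

    chrom: str
    start_bin: int
    end_bin: int
    type: str
    matched_states: str


def directionality_index(norm: ContactMatrix, window_bp: int = 60_000) -> np.ndarray:
    """Per-bin DI within ``window_bp`` (30 bins each side at 2-kb bins).

    Masked and out-of-range neighbors are skipped from the sums; masked
    focal bins get NaN.  DI is 0 where A == B or E <= 0.
    """
    if norm.kind != "normalized":
        raise ValueError("directionality_index expects a normalized matrix")
    if window_bp % norm.bin_size != 0:
        raise ValueError("window must be a multiple of the bin size")
    w = window_bp // norm.bin_size
    n = norm.n_bins
    M, ok = norm.values, norm.mask
    di = np.full(n, np.nan)
    for i in range(n):
        if not ok[i]:
            continue
        up = [M[i, j] for j in range(max(0, i - w), i) if ok[j]]
        down = [M[i, j] for j in range(i + 1, min(n, i + w + 1)) if ok[j]]
        A, B = float(np.sum(up)), float(np.sum(down))
        E = (A + B) / 2.0
        if A == B or E <= 0:
            di[i] = 0.0
        else:
            di[i] = np.sign(B - A) * ((A - E) ** 2 / E + (B - E) ** 2 / E)
    return di


def _segments(defined: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of defined bins as half-open (start, end) spans."""
    segs = []
    i, n = 0, len(defined)
    while i < n:
        if defined[i]:
            j = i
            while j + 1 < n and defined[j + 1]:
                j += 1
            segs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return segs


def fit_hmm(
    di: np.ndarray,
    chrom: str = "",
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> StateTrack:
    """Decode U/D/N states from a DI track with a 3-state Gaussian HMM.

    The DI is a signed chi-square statistic with heavy tails; emissions are
    therefore modelled on its signed square root, (B - A)/sqrt(A + B) -- a
    z-score-scale quantity -- with one Gaussian per state and a covariance
    tied across states, so the three states decompose the track by
    direction (location) rather than by magnitude.  Emission means are
    initialized from terciles, parameters fitted by EM, and the most-likely
    state path decoded per defined segment.  States are named by
    emission-mean rank: most negative -> U, most positive -> D, middle ->
    N.  A (near-)constant DI track decodes as all N.
    """
    di = np.asarray(di, dtype=float)
    defined = ~np.isnan(di)
    segs = _segments(defined)
    chars = np.full(len(di), ".", dtype="U1")
    vals = di[defined]
    vals = np.sign(vals) * np.sqrt(np.abs(vals))
    if len(vals) == 0:
        return StateTrack(chrom, di, "".join(chars))
    if np.std(vals) < 1e-12:
        for s, e in segs:
            chars[s:e] = "N"
        return StateTrack(chrom, di, "".join(chars))

    X = vals.reshape(-1, 1)
    lengths = [e - s for s, e in segs]
    # tied covariance: states must differ by emission mean (direction), not
    # by scale -- free variances would fit the heavy DI tails instead
    model = GaussianHMM(
        n_components=3,
        covariance_type="tied",
        n_iter=max_iter,
        tol=tol,
        init_params="c",  # means/startprob/transmat set explicitly
        params="stmc",
        random_state=seed,
    )
    terciles = np.quantile(vals, [1 / 6, 3 / 6, 5 / 6])
    model.means_ = terciles.reshape(-1, 1)
    model.startprob_ = np.full(3, 1 / 3)
    model.transmat_ = np.full((3, 3), 0.1) + 0.7 * np.eye(3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, lengths)
    if not model.monitor_.converged:
        warnings.warn(
            f"HMM EM did not converge on {chrom or 'track'}; "
            "using best-so-far parameters",
            stacklevel=2,
        )
    order = np.argsort(model.means_.ravel())
    name = {order[0]: "U", order[1]: "N", order[2]: "D"}
    path = model.predict(X, lengths)
    pos = 0
    flat = np.concatenate([np.arange(s, e) for s, e in segs])
    for idx, st in zip(flat, path):
        chars[idx] = name[st]
    return StateTrack(chrom, di, "".join(chars))


def _match_core(
    track: StateTrack,
    core_sets: list[set[str]],
    region_rel: tuple[int, int],
    flank_left: int,
    flank_right: int,
    type_name: str,
) -> list[RegionCall]:
    """Slide a per-position character-class pattern over each defined
    segment; flanks only require that a (non-excluded) state exists there."""
    calls: dict[tuple[int, int], RegionCall] = {}
    s = track.states
    for seg_start, seg_end in _segments(np.array([c != "." for c in s])):
        text = s[seg_start:seg_end]
        L = len(core_sets)
        for off in range(flank_left, len(text) - L - flank_right + 1):
            if all(text[off + k] in core_sets[k] for k in range(L)):
                a = seg_start + off + region_rel[0]
                b = seg_start + off + region_rel[1]
                key = (a, b)
                if key not in calls:
                    calls[key] = RegionCall(
                        track.chrom, a, b, type_name, s[a:b]
                    )
    return list(calls.values())


_U, _D, _N = {"U"}, {"D"}, {"N"}
_DN, _UN = {"D", "N"}, {"U", "N"}
_ANY = {"U", "D", "N"}


def extract_insulators(track: StateTrack) -> list[RegionCall]:
    """Insulator-like regions: UD (type A), UND (type B), UNND (type C)
    junctions flanked by UU and DD runs, with two flanking states required
    on each side."""
    calls: list[RegionCall] = []
    grammars = [
        ("insulatorA", [_U, _U, _D, _D], (1, 3)),
        ("insulatorB", [_U, _U, _N, _D, _D], (1, 4)),
        ("insulatorC", [_U, _U, _N, _N, _D, _D], (1, 5)),
    ]
    for name, core, rel in grammars:
        calls.extend(_match_core(track, core, rel, 2, 2, name))
    calls.sort(key=lambda c: (c.start_bin, c.type))
    return calls


def extract_boundaries(track: StateTrack) -> list[RegionCall]:
    """TAD-boundary-like regions: end of a U run (U(D/N)) or start of a D
    run ((U/N)D).  The two subtypes may overlap each other and
    insulator-like calls."""
    calls: list[RegionCall] = []
    calls.extend(
        _match_core(
            track,
            [_U, _U, _U, _U, _U, _DN, _DN, _ANY],
            (4, 6),
            0,
            0,
            "boundary_UD",
        )
    )
    calls.extend(
        _match_core(
            track,
            [_ANY, _UN, _UN, _D, _D, _D, _D, _D],
            (2, 4),
            0,
            0,
            "boundary_UND_end",
        )
    )
    calls.sort(key=lambda c: (c.start_bin, c.type))
    return calls


def extract_interiors(track: StateTrack) -> list[RegionCall]:
    """TAD-interior-like regions: start of a U run ((D/N)U) or end of a D
    run (D(U/N)), the mirror of the boundary grammars."""
    calls: list[RegionCall] = []
    calls.extend(
        _match_core(
            track,
            [_ANY, _DN, _DN, _U, _U, _U, _U, _U],
            (2, 4),
            0,
            0,
            "interior_DU",
        )
    )
    calls.extend(
        _match_core(
            track,
            [_D, _D, _D, _D, _D, _UN, _UN, _ANY],
            (4, 6),
            0,
            0,
            "interior_DUN_end",
        )
    )
    calls.sort(key=lambda c: (c.start_bin, c.type))
    return calls
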