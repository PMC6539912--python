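"""G4Hunter scoring and putative quadruplex sequence (PQS) calling.

The G4Hunter score of a nucleotide window is the mean of per-base scores:
every base inside a run of n consecutive guanines scores +min(n, 4), every
base inside a run of n cytosines scores -min(n, 4), and all other bases
score 0.  A positive window mean indicates G4-forming potential on the
given strand; a negative mean indicates the complementary strand (where
the C runs read as G runs).  Windows whose mean magnitude reaches the
detection threshold are merged into maximal putative quadruplex sequences
(PQS), each re-scored over its full extent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 25
DEFAULT_THRESHOLD = 1.2
#: Half-open score-magnitude intervals used for the census; the last bin
#: is unbounded above.
DEFAULT_BINS: tuple[tuple[float, float], ...] = (
    (1.2, 1.4),
    (1.4, 1.6),
    (1.6, 1.8),
    (1.8, 2.0),
    (2.0, float("inf")),
)

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def reverse_complement(sequence: str) -> str:
    """Reverse complement, mapping U to A and leaving other symbols as-is."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _fmt_bound(x: float) -> str:
    return f"{x:.1f}" if float(x) == round(x, 1) else f"{x:g}"


def _bin_label(lo: float, hi: float) -> str:
    if np.isinf(hi):
        return f"{_fmt_bound(lo)}–more"
    return f"{_fmt_bound(lo)}–{_fmt_bound(hi)}"


@dataclass(frozen=True)
class ScanParams:
    """Parameters of a G4Hunter scan.

    window_size : sliding-window width in bp (>= 2).
    threshold   : minimum |window mean| for a window to qualify (> 0).
    score_bins  : ordered, disjoint half-open [lo, hi) intervals starting
                  at the threshold; the last interval may be unbounded.
    """

    window_size: int = DEFAULT_WINDOW
    threshold: float = DEFAULT_THRESHOLD
    score_bins: tuple[tuple[float, float], ...] = DEFAULT_BINS

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError(f"window_size must be >= 2, got {self.window_size}")
        if not self.threshold > 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        bins = tuple((float(a), float(b)) for a, b in self.score_bins)
        if not bins:
            raise ValueError("score_bins must be non-empty")
        if bins[0][0] != self.threshold:
            raise ValueError("first score bin must start at the threshold")
        for (a1, b1), (a2, _) in zip(bins, bins[1:]):
            if not (a1 < b1 and b1 == a2):
                raise ValueError("score_bins must be sorted, disjoint and contiguous")
        if bins[-1][0] >= bins[-1][1]:
            raise ValueError("last score bin is empty")
        object.__setattr__(self, "score_bins", bins)

    @property
    def bin_labels(self) -> tuple[str, ...]:
        return tuple(_bin_label(lo, hi) for lo, hi in self.score_bins)


@dataclass(frozen=True)
class BaseScoreTrack:
    """Per-base G4Hunter scores for one sequence (integers in [-4, 4])."""

    seq_id: str
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class PQSRegion:
    """One called putative quadruplex sequence.

    Coordinates are 0-based half-open.  ``score`` is the mean per-base
    score over [start, end); its sign records the strand (+ for G-rich,
    - for C-rich, i.e. G-rich on the complementary strand).
    """

    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    sequence: str = field(repr=False, default="")

    @property
    def length(self) -> int:
        return self.end - self.start


def base_scores(sequence: str, seq_id: str = "") -> BaseScoreTrack:
    """Per-base G4Hunter scores with the run-capping rule.

    Bases in a G run of length n all score +min(n, 4); bases in a C run
    score -min(n, 4); everything else (including non-ACGT symbols, which
    also break runs) scores 0.  Case-insensitive; U is treated as T.
    """
    if not sequence:
        raise ValueError("empty sequence")
    arr = np.frombuffer(sequence.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    is_g = arr == ord("G")
    is_c = arr == ord("C")
    scores = np.zeros(len(arr), dtype=np.int8)
    for mask, sign in ((is_g, 1), (is_c, -1)):
        if not mask.any():
            continue
        # run-length encode the mask
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.view(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        for s, e in zip(starts, ends):
            scores[s:e] = sign * min(e - s, 4)
    return BaseScoreTrack(seq_id=seq_id, scores=scores)


def window_scores(track: BaseScoreTrack, params: ScanParams) -> np.ndarray:
    """Means of every length-W window; L - W + 1 values.

    A track shorter than the window yields an empty array (with a warning)
    so short plasmids aggregate as zero-PQS contributions rather than
    failing the run.
    """
    w = params.window_size
    n = len(track)
    if n < w:
        warnings.warn(
            f"sequence {track.seq_id!r} shorter than window ({n} < {w}); no windows scored",
            stacklevel=2,
        )
        return np.empty(0, dtype=float)
    csum = np.concatenate(([0], np.cumsum(track.scores, dtype=np.int64)))
    return (csum[w:] - csum[:-w]) / w


def _merge_starts(starts: np.ndarray, w: int) -> list[tuple[int, int]]:
    """Union of intervals [k, k+w) for qualifying window starts.

    Overlapping or touching intervals merge: since starts are sorted, a gap
    of more than w between consecutive starts begins a new region.
    """
    regions: list[tuple[int, int]] = []
    if len(starts) == 0:
        return regions
    lo = prev = int(starts[0])
    for k in starts[1:]:
        k = int(k)
        if k - prev > w:  # disjoint and non-adjacent
            regions.append((lo, prev + w))
            lo = k
        prev = k
    regions.append((lo, prev + w))
    return regions


def call_pqs(sequence: str, params: ScanParams | None = None, seq_id: str = "") -> list[PQSRegion]:
    """Scan one sequence and return merged PQS regions sorted by start.

    Qualifying windows (mean >= threshold, or <= -threshold) of the same
    sign that overlap or touch are merged into one maximal region, which
    is then re-scored as the mean base score over its full extent.
    Opposite-sign regions never merge.
    """
    params = params or ScanParams()
    track = base_scores(sequence, seq_id=seq_id)
    means = window_scores(track, params)
    if means.size == 0:
        return []
    w = params.window_size
    csum = np.concatenate(([0], np.cumsum(track.scores, dtype=np.int64)))
    regions: list[PQSRegion] = []
    for sign, starts in (
        ("+", np.flatnonzero(means >= params.threshold)),
        ("-", np.flatnonzero(means <= -params.threshold)),
    ):
        for lo, hi in _merge_starts(starts, w):
            score = (csum[hi] - csum[lo]) / (hi - lo)
            regions.append(
                PQSRegion(
                    seq_id=seq_id,
                    start=lo,
                    end=hi,
                    strand=sign,
                    score=float(score),
                    sequence=sequence[lo:hi].upper(),
                )
            )
    regions.sort(key=lambda r: (r.seq_id, r.start, r.strand))
    return regions


def bin_score(score: float, params: ScanParams | None = None) -> str:
    """Score-bin label for a PQS score; binning is by magnitude.

    Intervals are left-closed, right-open; the last bin is unbounded.
    Raises ValueError below the threshold.
    """
    params = params or ScanParams()
    mag = abs(score)
    if mag < params.threshold:
        raise ValueError(f"|score| {mag:.4f} below threshold {params.threshold}")
    for (lo, hi), label in zip(params.score_bins, params.bin_labels):
        if lo <= mag < hi:
            return label
    raise ValueError(f"score {score} not covered by bins {params.score_bins}")


def bin_score_clamped(score: float, params: ScanParams | None = None) -> str:
    """Like :func:`bin_score` but merged regions whose re-scored magnitude
    drifted marginally below the threshold are counted in the lowest bin,
    so census bin counts always sum to the PQS total."""
    params = params or ScanParams()
    if abs(score) < params.threshold:
        return params.bin_labels[0]
    return bin_score(score, params)
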