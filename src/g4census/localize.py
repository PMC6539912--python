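"""PQS localization relative to annotated features.

Each feature defines three zones: the feature interval itself ("inside")
and flanking windows of up to ``flank`` bp on either side ("before" on the
5' side, "after" on the 3' side).  By default orientation is strand-aware:
for a minus-strand feature the genomic-right flank is "before".  A PQS is
assigned to every zone it overlaps by at least 1 bp, at most once per
individual zone interval; frequencies are PQS per 1000 bp of summed
(truncated) zone length.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .g4core import PQSRegion
from .genome_io import Feature

logger = logging.getLogger(__name__)

ZONES = ("before", "inside", "after")
DEFAULT_FLANK = 100


@dataclass(frozen=True)
class ZoneInterval:
    """One zone of one feature; empty intervals (start == end) carry length 0."""

    feature: Feature
    zone: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def zone_intervals(
    feature: Feature,
    flank: int,
    seq_length: int,
    strand_aware: bool = True,
) -> tuple[ZoneInterval, ZoneInterval, ZoneInterval]:
    """(before, inside, after) zones of a feature, truncated to [0, seq_length).

    With ``strand_aware`` (default), "before" is the feature's 5' flank:
    genomic left for '+' (and unknown) strand, genomic right for '-'.
    With strand_aware=False, "before" is always the genomic-left flank.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    left = (max(0, feature.start - flank), feature.start)
    right = (feature.end, min(seq_length, feature.end + flank))
    if strand_aware and feature.strand == "-":
        before, after = right, left
    else:
        before, after = left, right
    return (
        ZoneInterval(feature, "before", *before),
        ZoneInterval(feature, "inside", feature.start, feature.end),
        ZoneInterval(feature, "after", *after),
    )


def assign_pqs(pqs: PQSRegion, zones: Iterable[ZoneInterval]) -> set[str]:
    """Zone labels whose intervals the PQS overlaps by >= 1 bp."""
    labels = set()
    for z in zones:
        if z.feature.seq_id == pqs.seq_id and pqs.start < z.end and pqs.end > z.start:
            labels.add(z.zone)
    return labels


def zone_frequency_table(
    pqs_regions: Sequence[PQSRegion],
    features: Sequence[Feature],
    seq_lengths: Mapping[str, int],
    flank: int = DEFAULT_FLANK,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Aggregate PQS counts and densities per (feature_class, zone).

    Columns: feature_class, zone, n_features, pqs_count, total_length_bp,
    freq_per_kbp.  A PQS may contribute to several cells (one per zone
    interval it overlaps) but at most once per individual zone interval.
    Rows with zero total zone length are omitted.
    """
    if not features:
        warnings.warn("no features supplied; zone table is empty", stacklevel=2)
        return pd.DataFrame(
            columns=["feature_class", "zone", "n_features", "pqs_count", "total_length_bp", "freq_per_kbp"]
        )
    # index PQS per seq_id, sorted by start, for windowed candidate lookup
    by_seq: dict[str, list[PQSRegion]] = {}
    for r in sorted(pqs_regions, key=lambda r: (r.seq_id, r.start)):
        by_seq.setdefault(r.seq_id, []).append(r)
    starts = {sid: [r.start for r in lst] for sid, lst in by_seq.items()}
    max_len = {sid: max((r.length for r in lst), default=0) for sid, lst in by_seq.items()}

    counts: dict[tuple[str, str], int] = {}
    lengths: dict[tuple[str, str], int] = {}
    n_feat: dict[str, int] = {}
    classes_order: list[str] = []
    for feat in features:
        if feat.feature_class not in n_feat:
            classes_order.append(feat.feature_class)
            n_feat[feat.feature_class] = 0
        n_feat[feat.feature_class] += 1
        seq_len = seq_lengths.get(feat.seq_id)
        if seq_len is None:
            logger.warning("feature on unknown sequence %r skipped", feat.seq_id)
            continue
        zones = zone_intervals(feat, flank, seq_len, strand_aware=strand_aware)
        cand = by_seq.get(feat.seq_id, [])
        pos = starts.get(feat.seq_id, [])
        for z in zones:
            key = (feat.feature_class, z.zone)
            lengths[key] = lengths.get(key, 0) + z.length
            if z.length == 0 or not cand:
                continue
            # candidates: start in [z.start - max_len, z.end)
            lo = bisect_left(pos, z.start - max_len[feat.seq_id])
            hi = bisect_left(pos, z.end)
            n = sum(1 for r in cand[lo:hi] if r.end > z.start)
            counts[key] = counts.get(key, 0) + n

    rows = []
    for cls in classes_order:
        for zone in ZONES:
            key = (cls, zone)
            total = lengths.get(key, 0)
            if total <= 0:
                continue
            n = counts.get(key, 0)
            rows.append({
                "feature_class": cls,
                "zone": zone,
                "n_features": n_feat[cls],
                "pqs_count": n,
                "total_length_bp": total,
                "freq_per_kbp": 1000.0 * n / total,
            })
    return pd.DataFrame(rows)
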