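"""Per-genome and cohort-level PQS statistics.

Densities are expressed as PQS per 1000 bp: f = 1000 * count / length.
Group comparison uses the Kruskal-Wallis rank test (tie-corrected H,
chi-square approximation, alpha = 0.05), restricted to groups with at
least ``min_group_size`` genomes.  Per-bin frequency vectors can be
max-normalized with outliers flagged at normalized value > 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .g4core import PQSRegion, ScanParams, bin_score_clamped
from .genome_io import GenomeRecord, gc_content

logger = logging.getLogger(__name__)

ALPHA = 0.05
MIN_GROUP_SIZE = 10


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    group: str
    subgroup: str
    total_length: int
    gc_percent: float
    pqs_total: int
    bin_counts: tuple[int, ...]
    bin_labels: tuple[str, ...]

    @property
    def freq_per_kbp(self) -> float:
        return 1000.0 * self.pqs_total / self.total_length

    def bin_freqs_per_kbp(self) -> tuple[float, ...]:
        return tuple(1000.0 * c / self.total_length for c in self.bin_counts)


@dataclass(frozen=True)
class GroupSummary:
    """Cohort aggregate in the layout of the per-group census table."""

    group: str
    n_genomes: int
    median_length: float
    shortest: int
    longest: int
    mean_gc: float
    pqs_total: int
    mean_freq: float
    min_freq: float
    max_freq: float


@dataclass(frozen=True)
class KWResult:
    level: str
    k_groups: int
    n_total: int
    h_statistic: float
    df: int
    p_value: float
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def summarize_genome(
    record: GenomeRecord,
    regions: Sequence[PQSRegion],
    params: ScanParams | None = None,
    group: str = "",
    subgroup: str = "",
) -> GenomeSummary:
    """Per-genome census: length, GC%, PQS total and per-score-bin counts."""
    params = params or ScanParams()
    if record.total_length == 0:
        raise ValueError(f"genome {record.genome_id!r} has zero length")
    labels = params.bin_labels
    counts = dict.fromkeys(labels, 0)
    for r in regions:
        counts[bin_score_clamped(r.score, params)] += 1
    return GenomeSummary(
        genome_id=record.genome_id,
        group=group,
        subgroup=subgroup,
        total_length=record.total_length,
        gc_percent=gc_content(record),
        pqs_total=len(regions),
        bin_counts=tuple(counts[l] for l in labels),
        bin_labels=labels,
    )


def genome_summary_frame(summaries: Sequence[GenomeSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "genome_id": s.genome_id,
            "group": s.group,
            "subgroup": s.subgroup,
            "total_length_bp": s.total_length,
            "gc_percent": s.gc_percent,
            "pqs_total": s.pqs_total,
            "freq_per_kbp": s.freq_per_kbp,
        }
        for label, c, f in zip(s.bin_labels, s.bin_counts, s.bin_freqs_per_kbp()):
            row[f"n[{label}]"] = c
            row[f"f[{label}]"] = f
        rows.append(row)
    return pd.DataFrame(rows)


def score_bin_census(summaries: Sequence[GenomeSummary]) -> pd.DataFrame:
    """Pooled per-bin census: counts summed over genomes, frequency = pooled
    count / pooled length * 1000 (the whole-dataset census formula)."""
    if not summaries:
        raise ValueError("no genome summaries")
    labels = summaries[0].bin_labels
    total_len = sum(s.total_length for s in summaries)
    rows = []
    for i, label in enumerate(labels):
        n = sum(s.bin_counts[i] for s in summaries)
        rows.append({
            "score_interval": label,
            "pqs_count": n,
            "freq_per_kbp": 1000.0 * n / total_len,
        })
    return pd.DataFrame(rows)


def summarize_group(
    summaries: Sequence[GenomeSummary],
    level: str = "group",
    pooled_mean: bool = False,
) -> list[GroupSummary]:
    """Aggregate genome summaries at the group or subgroup level.

    Mean frequency is by default the unweighted mean of per-genome
    frequencies (matching the per-genome min/max columns); with
    ``pooled_mean`` it becomes pooled counts / pooled length * 1000.
    Groups keep first-appearance order; empty groups are skipped.
    """
    if level not in ("group", "subgroup"):
        raise ValueError(f"level must be 'group' or 'subgroup', got {level!r}")
    order: list[str] = []
    members: dict[str, list[GenomeSummary]] = {}
    for s in summaries:
        name = s.group if level == "group" else s.subgroup
        if name not in members:
            order.append(name)
            members[name] = []
        members[name].append(s)
    out = []
    for name in order:
        group = members[name]
        if not group:
            warnings.warn(f"group {name!r} is empty; skipped", stacklevel=2)
            continue
        lengths = np.array([s.total_length for s in group])
        freqs = np.array([s.freq_per_kbp for s in group])
        if pooled_mean:
            mean_f = 1000.0 * sum(s.pqs_total for s in group) / lengths.sum()
        else:
            mean_f = float(freqs.mean())
        out.append(
            GroupSummary(
                group=name,
                n_genomes=len(group),
                median_length=float(np.median(lengths)),
                shortest=int(lengths.min()),
                longest=int(lengths.max()),
                mean_gc=float(np.mean([s.gc_percent for s in group])),
                pqs_total=sum(s.pqs_total for s in group),
                mean_freq=mean_f,
                min_freq=float(freqs.min()),
                max_freq=float(freqs.max()),
            )
        )
    return out


def group_summary_frame(groups: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "group": g.group,
            "n_genomes": g.n_genomes,
            "median_length_bp": g.median_length,
            "shortest_bp": g.shortest,
            "longest_bp": g.longest,
            "mean_gc_percent": g.mean_gc,
            "pqs_total": g.pqs_total,
            "mean_f": g.mean_freq,
            "min_f": g.min_freq,
            "max_f": g.max_freq,
        }
        for g in groups
    ])


def kruskal_wallis(
    frequencies_by_group: Mapping[str, Sequence[float]],
    min_group_size: int = MIN_GROUP_SIZE,
    level: str = "group",
    alpha: float = ALPHA,
) -> KWResult:
    """Tie-corrected Kruskal-Wallis H test across groups.

    Groups smaller than ``min_group_size`` are excluded before ranking.
    All-identical data (tie correction degenerate) is reported as
    H = 0, p = 1.  Fewer than two eligible groups is an error.
    """
    eligible = {
        name: np.asarray(vals, dtype=float)
        for name, vals in frequencies_by_group.items()
        if len(vals) >= min_group_size
    }
    if len(eligible) < 2:
        raise ValueError(
            f"need >= 2 groups with >= {min_group_size} genomes; "
            f"only {len(eligible)} eligible"
        )
    samples = list(eligible.values())
    n_total = sum(len(s) for s in samples)
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    return KWResult(
        level=level,
        k_groups=len(eligible),
        n_total=n_total,
        h_statistic=float(h),
        df=len(eligible) - 1,
        p_value=float(p),
        alpha=alpha,
    )


def normalize_and_flag(frequencies: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Divide per-genome frequencies by their maximum and flag values
    strictly above 0.5 of the maximum (an all-zero bin yields no flags)."""
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency vector")
    if (freqs < 0).any():
        raise ValueError("frequencies must be non-negative")
    top = freqs.max()
    if top == 0:
        return np.zeros_like(freqs), np.zeros(freqs.shape, dtype=bool)
    normalized = freqs / top
    return normalized, normalized > 0.5
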