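"""Orchestration of the scan -> localize -> cohort stages over a manifest.

Genomes are processed independently (results are order-invariant); a
genome that fails to read is recorded and skipped so one bad file does not
abort a cohort run.  All outputs are deterministic tab-delimited tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort_stats, genome_io, localize
from .g4core import PQSRegion, ScanParams, call_pqs

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    manifest_path: Path
    out_dir: Path
    params: ScanParams = field(default_factory=ScanParams)
    flank: int = localize.DEFAULT_FLANK
    level: str = "group"
    min_group_size: int = cohort_stats.MIN_GROUP_SIZE
    alpha: float = cohort_stats.ALPHA
    strand_aware: bool = True


@dataclass
class ScanResult:
    summaries: list[cohort_stats.GenomeSummary]
    pqs_paths: dict[str, Path]
    failures: list[tuple[str, str]]  # (genome_id, reason)


def scan_genome(record: genome_io.GenomeRecord, params: ScanParams) -> list[PQSRegion]:
    """Call PQS on every sequence of one genome."""
    regions: list[PQSRegion] = []
    for seq_id, seq in record.sequences:
        regions.extend(call_pqs(seq, params, seq_id=seq_id))
    return regions


def run_scan(config: RunConfig) -> ScanResult:
    """Scan every manifest genome; write one PQS table per genome and a
    per-genome summary table."""
    manifest = genome_io.read_manifest(config.manifest_path)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    summaries = []
    pqs_paths: dict[str, Path] = {}
    failures: list[tuple[str, str]] = []
    for row in manifest.itertuples(index=False):
        try:
            record = genome_io.read_fasta(row.fasta_path, genome_id=row.genome_id)
        except (OSError, ValueError) as exc:
            logger.error("genome %s unreadable: %s", row.genome_id, exc)
            failures.append((row.genome_id, str(exc)))
            continue
        regions = scan_genome(record, config.params)
        out = config.out_dir / f"{row.genome_id}.pqs.tsv"
        genome_io.write_pqs_table(regions, out, config.params)
        pqs_paths[row.genome_id] = out
        summaries.append(
            cohort_stats.summarize_genome(
                record, regions, config.params, group=row.group, subgroup=row.subgroup
            )
        )
    cohort_stats.genome_summary_frame(summaries).to_csv(
        config.out_dir / "genome_summary.tsv", sep="\t", index=False
    )
    return ScanResult(summaries=summaries, pqs_paths=pqs_paths, failures=failures)


def run_localize(config: RunConfig, scan: ScanResult) -> pd.DataFrame:
    """Zone-frequency table pooled over the cohort (plus per-genome tables).

    Genomes without a feature table are skipped from localization and
    logged; they still count in the scan summaries."""
    manifest = genome_io.read_manifest(config.manifest_path)
    all_pqs: list[PQSRegion] = []
    all_features: list[genome_io.Feature] = []
    seq_lengths: dict[str, int] = {}
    for row in manifest.itertuples(index=False):
        if row.genome_id not in scan.pqs_paths:
            continue
        try:
            features = genome_io.read_feature_table(row.feature_table_path)
        except (OSError, ValueError) as exc:
            logger.warning("no feature table for %s (%s); skipped from localization",
                           row.genome_id, exc)
            continue
        record = genome_io.read_fasta(row.fasta_path, genome_id=row.genome_id)
        pqs = genome_io.read_pqs_table(scan.pqs_paths[row.genome_id])
        table = localize.zone_frequency_table(
            pqs, features, record.seq_lengths(),
            flank=config.flank, strand_aware=config.strand_aware,
        )
        table.to_csv(config.out_dir / f"{row.genome_id}.zones.tsv", sep="\t", index=False)
        all_pqs.extend(pqs)
        all_features.extend(features)
        seq_lengths.update(record.seq_lengths())
    pooled = localize.zone_frequency_table(
        all_pqs, all_features, seq_lengths,
        flank=config.flank, strand_aware=config.strand_aware,
    )
    pooled.to_csv(config.out_dir / "zone_frequency.tsv", sep="\t", index=False)
    return pooled


def run_cohort(config: RunConfig, scan: ScanResult) -> dict[str, pd.DataFrame]:
    """Score-bin census, group summaries and the Kruskal-Wallis report."""
    if not scan.summaries:
        raise ValueError("no genome summaries; nothing to aggregate")
    census = cohort_stats.score_bin_census(scan.summaries)
    census.to_csv(config.out_dir / "score_bin_census.tsv", sep="\t", index=False)
    groups = cohort_stats.summarize_group(scan.summaries, level=config.level)
    group_df = cohort_stats.group_summary_frame(groups)
    group_df.to_csv(config.out_dir / f"{config.level}_summary.tsv", sep="\t", index=False)

    freqs: dict[str, list[float]] = {}
    for s in scan.summaries:
        name = s.group if config.level == "group" else s.subgroup
        freqs.setdefault(name, []).append(s.freq_per_kbp)
    kw_rows = []
    try:
        kw = cohort_stats.kruskal_wallis(
            freqs, min_group_size=config.min_group_size,
            level=config.level, alpha=config.alpha,
        )
        kw_rows.append({
            "level": kw.level, "k_groups": kw.k_groups, "n_total": kw.n_total,
            "H": kw.h_statistic, "df": kw.df, "p_value": kw.p_value,
            "significant": kw.significant,
        })
    except ValueError as exc:
        logger.warning("Kruskal-Wallis not applicable: %s", exc)
    kw_df = pd.DataFrame(kw_rows)
    kw_df.to_csv(config.out_dir / "kruskal_wallis.tsv", sep="\t", index=False)
    return {"census": census, "groups": group_df, "kw": kw_df}
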