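"""Genome FASTA and NCBI feature-table I/O, plus tabular output writers.

External coordinates (FASTA-derived feature tables, written PQS tables) are
1-based inclusive, the NCBI convention; everything internal is 0-based
half-open.  Conversion happens only here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .g4core import PQSRegion, ScanParams, bin_score_clamped

logger = logging.getLogger(__name__)

PQS_COLUMNS = ["seq_id", "start", "end", "length", "strand", "score", "bin", "sequence"]
FEATURE_TABLE_COLUMNS = [
    "# feature", "class", "assembly", "assembly_unit", "seq_type", "chromosome",
    "genomic_accession", "start", "end", "strand", "product_accession",
    "non-redundant_refseq", "related_accession", "name", "symbol", "GeneID",
    "locus_tag", "feature_interval_length", "product_length", "attributes",
]


@dataclass(frozen=True)
class GenomeRecord:
    """One assembly: ordered (seq_id, residues) pairs, residues upper-case."""

    genome_id: str
    sequences: tuple[tuple[str, str], ...]

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.sequences)

    def seq_lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.sequences}


@dataclass(frozen=True)
class Feature:
    """One annotated interval; coordinates 0-based half-open, start < end.

    ``strand`` is '+', '-' or '?' (unknown).  ``feature_class`` is the
    verbatim value of the feature-table "feature" column (gene, tRNA,
    rRNA, tmRNA, ncRNA, regulatory, repeat_region, misc_feature, STS, ...).
    """

    seq_id: str
    feature_class: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.feature_class:
            raise ValueError("feature_class must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"feature interval empty: [{self.start}, {self.end})")


def read_fasta(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Read a (possibly multi-record) FASTA file into a GenomeRecord."""
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return GenomeRecord(genome_id=genome_id or path.stem, sequences=tuple(records))


def write_fasta(record: GenomeRecord, path: str | Path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in record.sequences:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_feature_table(path: str | Path) -> list[Feature]:
    """Parse an NCBI tab-delimited ``*_feature_table.txt``.

    Requires a header line starting with ``# feature`` and the columns
    feature, genomic_accession, start, end, strand.  1-based inclusive
    coordinates become 0-based half-open; rows whose coordinates do not
    parse are skipped and counted in a log message.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("# feature"):
        raise ValueError(f"{path}: not an NCBI feature table (header must start with '# feature')")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.rename(columns={"# feature": "feature"})
    required = {"feature", "genomic_accession", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    features: list[Feature] = []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            start = int(row.start)
            end = int(row.end)
        except (TypeError, ValueError):
            skipped += 1
            continue
        if start > end:  # some minus-strand dialects list coordinates reversed
            start, end = end, start
        strand = row.strand if row.strand in ("+", "-") else "?"
        features.append(
            Feature(
                seq_id=row.genomic_accession,
                feature_class=row.feature,
                start=start - 1,
                end=end,
                strand=strand,
            )
        )
    if skipped:
        logger.warning("%s: skipped %d rows with unparsable coordinates", path, skipped)
    return features


def write_feature_table(features: Sequence[Feature], path: str | Path, assembly: str = "synthetic") -> None:
    """Write features in the NCBI feature-table dialect (1-based inclusive)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FEATURE_TABLE_COLUMNS)
        for f in features:
            row = dict.fromkeys(FEATURE_TABLE_COLUMNS, "")
            row.update({
                "# feature": f.feature_class,
                "class": "",
                "assembly": assembly,
                "genomic_accession": f.seq_id,
                "start": str(f.start + 1),
                "end": str(f.end),
                "strand": f.strand if f.strand in ("+", "-") else "?",
                "feature_interval_length": str(f.end - f.start),
            })
            writer.writerow(row[c] for c in FEATURE_TABLE_COLUMNS)


def gc_content(record: GenomeRecord) -> float:
    """GC percentage over all sequences; non-ACGT bases stay in the denominator."""
    total = record.total_length
    if total == 0:
        raise ValueError(f"genome {record.genome_id!r} has zero length")
    gc = sum(s.count("G") + s.count("C") for _, s in record.sequences)
    return 100.0 * gc / total


def write_pqs_table(regions: Iterable[PQSRegion], path: str | Path, params: ScanParams | None = None) -> None:
    """Tab-delimited PQS table, 1-based inclusive output coordinates."""
    params = params or ScanParams()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PQS_COLUMNS)
        for r in regions:
            writer.writerow([
                r.seq_id, r.start + 1, r.end, r.length, r.strand,
                f"{r.score:.4f}", bin_score_clamped(r.score, params), r.sequence,
            ])


def read_pqs_table(path: str | Path) -> list[PQSRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "sequence": str})
    return [
        PQSRegion(
            seq_id=row.seq_id,
            start=int(row.start) - 1,
            end=int(row.end),
            strand=row.strand,
            score=float(row.score),
            sequence="" if pd.isna(row.sequence) else str(row.sequence),
        )
        for row in df.itertuples(index=False)
    ]


MANIFEST_COLUMNS = ["genome_id", "fasta_path", "feature_table_path", "group", "subgroup"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Cohort manifest: genome_id, fasta_path, feature_table_path, group, subgroup."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: manifest is empty")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)
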