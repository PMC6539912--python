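"""Synthetic genomes, feature tables, and cohorts with known ground truth.

Backgrounds are i.i.d. nucleotides with P(G) = P(C) = gc/2 and
P(A) = P(T) = (1-gc)/2, spanning the GC range observed across bacteria
(roughly 20-75%).  G-rich tracts such as (GGGGTGT)_n — the canonical
high-scoring repeat — are overwritten onto the background at known
positions, so the scanner's output can be checked against an exact plant
ledger.  Each genome in a cohort gets its own random stream derived from
(cohort seed, genome index), making generation reproducible and
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import Feature, GenomeRecord, write_fasta, write_feature_table, write_manifest
from .g4core import reverse_complement

#: high-scoring repeat unit; a long tract scores 17/7 ~ 2.43 per base
G_TRACT_UNIT = "GGGGTGT"

FEATURE_CLASSES = (
    "gene", "tRNA", "rRNA", "tmRNA", "ncRNA",
    "regulatory", "repeat_region", "misc_feature", "STS",
)


@dataclass(frozen=True)
class MotifPlant:
    """A motif to plant: ``copies`` at random positions, or explicit
    ``positions`` (0-based starts); minus-strand plants insert the
    reverse complement."""

    motif: str
    copies: int = 0
    positions: tuple[int, ...] | None = None
    strand: str = "+"


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    length: int
    gc_fraction: float
    seed: int
    plants: tuple[MotifPlant, ...] = ()
    min_spacing: int = 100
    seq_id: str = "chr1"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.min_spacing < 0:
            raise ValueError("min_spacing must be >= 0")


@dataclass(frozen=True)
class PlantRecord:
    """Ground-truth position of one planted motif (0-based half-open)."""

    seq_id: str
    start: int
    end: int
    strand: str
    motif: str


def _draw_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(bases, size=length, p=probs)


def _place_randomly(
    rng: np.random.Generator,
    length: int,
    sizes: Sequence[int],
    occupied: list[tuple[int, int]],
    min_spacing: int,
    max_tries: int = 1000,
) -> list[int]:
    """Uniform-random non-overlapping starts with min_spacing between items.

    The batch is placed by the gap method (sorted uniform offsets plus
    cumulative item widths), which succeeds whenever the items fit; a
    placement colliding with pre-existing ``occupied`` intervals is redrawn.
    """
    if not sizes:
        return []
    slack = length - sum(sizes) - min_spacing * (len(sizes) - 1)
    if slack < 0:
        raise ValueError(
            f"{len(sizes)} items totalling {sum(sizes)} bp with spacing {min_spacing} "
            f"do not fit in {length} bp"
        )
    for _ in range(max_tries):
        offsets = np.sort(rng.integers(0, slack + 1, size=len(sizes)))
        starts = []
        pos = 0
        for off, size in zip(offsets, sizes):
            s = int(off) + pos
            starts.append(s)
            pos += size + min_spacing
        if all(
            s + size + min_spacing <= a or b + min_spacing <= s
            for s, size in zip(starts, sizes)
            for a, b in occupied
        ):
            occupied.extend((s, s + size) for s, size in zip(starts, sizes))
            return starts
    raise ValueError(
        f"could not place {len(sizes)} items with spacing {min_spacing} in {length} bp "
        f"around {len(occupied)} reserved intervals after {max_tries} tries"
    )


def generate_genome(spec: SyntheticGenomeSpec) -> tuple[GenomeRecord, list[PlantRecord]]:
    """Background genome with motifs overwritten at known positions.

    Returns the GenomeRecord and the exact plant ledger.  Deterministic for
    a fixed spec (same seed => byte-identical sequence).
    """
    rng = np.random.default_rng(spec.seed)
    arr = _draw_background(rng, spec.length, spec.gc_fraction)
    occupied: list[tuple[int, int]] = []
    ledger: list[PlantRecord] = []
    for plant in spec.plants:
        inserted = plant.motif if plant.strand == "+" else reverse_complement(plant.motif)
        size = len(inserted)
        if plant.positions is not None:
            starts = list(plant.positions)
            for s in starts:
                if not 0 <= s <= spec.length - size:
                    raise ValueError(f"explicit plant position {s} out of range")
                if not all(s + size + spec.min_spacing <= a or b + spec.min_spacing <= s
                           for a, b in occupied):
                    raise ValueError(f"explicit plant at {s} violates spacing constraint")
                occupied.append((s, s + size))
        else:
            starts = _place_randomly(rng, spec.length, [size] * plant.copies,
                                     occupied, spec.min_spacing)
        motif_bytes = np.frombuffer(inserted.encode(), dtype=np.uint8)
        for s in starts:
            arr[s : s + size] = motif_bytes
            ledger.append(PlantRecord(spec.seq_id, s, s + size, plant.strand, plant.motif))
    ledger.sort(key=lambda p: p.start)
    record = GenomeRecord(genome_id=spec.seq_id, sequences=((spec.seq_id, arr.tobytes().decode()),))
    return record, ledger


@dataclass(frozen=True)
class FeaturePlan:
    """How many features of each class to scatter, and their strand."""

    feature_class: str
    count: int
    length: int = 300
    strand: str = "+"


def generate_feature_table(
    record: GenomeRecord,
    plans: Sequence[FeaturePlan],
    seed: int,
    min_spacing: int = 250,
    path: str | Path | None = None,
    explicit: Sequence[Feature] = (),
) -> list[Feature]:
    """Scatter non-overlapping features over the genome; optionally write
    the NCBI feature-table file.  ``explicit`` features are kept verbatim
    and reserved before random placement."""
    rng = np.random.default_rng(seed)
    seq_id, seq = record.sequences[0]
    length = len(seq)
    occupied: list[tuple[int, int]] = [(f.start, f.end) for f in explicit]
    features: list[Feature] = list(explicit)
    for plan in plans:
        starts = _place_randomly(rng, length, [plan.length] * plan.count, occupied, min_spacing)
        for s in starts:
            features.append(Feature(seq_id, plan.feature_class, s, s + plan.length, plan.strand))
    features.sort(key=lambda f: (f.seq_id, f.start))
    if path is not None:
        write_feature_table(features, path, assembly=record.genome_id)
    return features


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: genome count, length distribution (uniform between
    the two bounds), GC fraction, and planted PQS density per kbp realized
    as Poisson-distributed counts of (GGGGTGT)_8 tracts."""

    name: str
    n_genomes: int
    length_range: tuple[int, int]
    gc_fraction: float
    plant_density_per_kbp: float
    subgroup: str = ""

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.plant_density_per_kbp < 0:
            raise ValueError("plant density must be >= 0")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int
    motif: str = G_TRACT_UNIT * 8
    min_spacing: int = 100


def generate_cohort(spec: SyntheticCohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write FASTA + feature table per genome and a cohort manifest.

    Plant counts per genome are Poisson with mean density * length / 1000.
    Each genome's stream is seeded by (cohort seed, global genome index).
    Returns the manifest DataFrame (also written to ``manifest.tsv``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    index = 0
    for group in spec.groups:
        for g in range(group.n_genomes):
            child = np.random.default_rng([spec.seed, index])
            length = int(child.integers(group.length_range[0], group.length_range[1] + 1))
            n_plants = int(child.poisson(group.plant_density_per_kbp * length / 1000.0))
            genome_id = f"{group.name}_g{g:03d}"
            gspec = SyntheticGenomeSpec(
                length=length,
                gc_fraction=group.gc_fraction,
                seed=int(child.integers(0, 2**31)),
                plants=(MotifPlant(spec.motif, copies=n_plants),) if n_plants else (),
                min_spacing=spec.min_spacing,
                seq_id=genome_id,
            )
            record, _ = generate_genome(gspec)
            fasta = out_dir / f"{genome_id}.fna"
            ftable = out_dir / f"{genome_id}_feature_table.txt"
            write_fasta(record, fasta)
            generate_feature_table(
                record,
                [FeaturePlan("gene", max(1, length // 20_000)), FeaturePlan("tRNA", 3)],
                seed=int(child.integers(0, 2**31)),
                path=ftable,
            )
            rows.append({
                "genome_id": genome_id,
                "fasta_path": str(fasta),
                "feature_table_path": str(ftable),
                "group": group.name,
                "subgroup": group.subgroup or group.name,
            })
            index += 1
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.tsv")
    return manifest
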