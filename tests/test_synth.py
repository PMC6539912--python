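"""Synthetic genome / feature-table / cohort generators and their ground truth."""

import numpy as np
import pytest

from g4census import (
    FeaturePlan,
    GroupSpec,
    MotifPlant,
    ScanParams,
    SyntheticCohortSpec,
    SyntheticGenomeSpec,
    call_pqs,
    gc_content,
    generate_cohort,
    generate_feature_table,
    generate_genome,
    kruskal_wallis,
    read_fasta,
    read_feature_table,
    read_manifest,
    zone_frequency_table,
)
from g4census.synth import G_TRACT_UNIT


class TestGenerateGenome:
    def test_gc_zero_is_at_only(self):
        rec, _ = generate_genome(SyntheticGenomeSpec(length=10_000, gc_fraction=0.0, seed=1))
        assert set(rec.sequences[0][1]) <= {"A", "T"}

    def test_deterministic_for_fixed_seed(self):
        spec = SyntheticGenomeSpec(
            length=50_000, gc_fraction=0.4, seed=7,
            plants=(MotifPlant(G_TRACT_UNIT * 8, copies=3),),
        )
        r1, l1 = generate_genome(spec)
        r2, l2 = generate_genome(spec)
        assert r1.sequences == r2.sequences and l1 == l2

    def test_realized_gc_close_to_requested(self):
        rec, _ = generate_genome(SyntheticGenomeSpec(length=200_000, gc_fraction=0.66, seed=3))
        assert gc_content(rec) == pytest.approx(66.0, abs=1.0)

    def test_every_planted_tract_recovered(self):
        """All 5 (GGGGTGT)_8 plants on a gc=0.30 background are covered by a
        plus-strand call (the background contributes its own G-rich calls at
        this GC, as real low-GC genomes do)."""
        spec = SyntheticGenomeSpec(
            length=1_000_000, gc_fraction=0.30, seed=11,
            plants=(MotifPlant(G_TRACT_UNIT * 8, copies=5),), min_spacing=200,
        )
        rec, ledger = generate_genome(spec)
        regions = call_pqs(rec.sequences[0][1], ScanParams(), seq_id=rec.genome_id)
        assert len(ledger) == 5
        for p in ledger:
            cover = [r for r in regions if r.start <= p.start and r.end >= p.end]
            assert len(cover) == 1 and cover[0].strand == "+"

    def test_plant_list_exactly_recovered_on_clean_background(self):
        """At gc=0.15 the background yields no qualifying windows, so the
        called PQS are exactly the 5 plants."""
        spec = SyntheticGenomeSpec(
            length=1_000_000, gc_fraction=0.15, seed=11,
            plants=(MotifPlant(G_TRACT_UNIT * 8, copies=5),), min_spacing=200,
        )
        rec, ledger = generate_genome(spec)
        regions = call_pqs(rec.sequences[0][1], ScanParams(), seq_id=rec.genome_id)
        assert len(regions) == 5 == len(ledger)
        for r, p in zip(sorted(regions, key=lambda r: r.start), ledger):
            assert r.start <= p.start and r.end >= p.end
            assert r.strand == "+"

    def test_minus_strand_plant_inserts_revcomp(self):
        spec = SyntheticGenomeSpec(
            length=2_000, gc_fraction=0.0, seed=5,
            plants=(MotifPlant(G_TRACT_UNIT * 4, copies=1, strand="-"),),
        )
        rec, (plant,) = generate_genome(spec)
        regions = call_pqs(rec.sequences[0][1], ScanParams())
        assert len(regions) == 1 and regions[0].strand == "-" and regions[0].score < 0

    def test_explicit_positions_honored(self):
        spec = SyntheticGenomeSpec(
            length=5_000, gc_fraction=0.0, seed=5,
            plants=(MotifPlant("GGGG", positions=(100, 400)),),
        )
        rec, ledger = generate_genome(spec)
        assert [p.start for p in ledger] == [100, 400]
        assert rec.sequences[0][1][100:104] == "GGGG"

    def test_infeasible_placement_rejected(self):
        spec = SyntheticGenomeSpec(
            length=100, gc_fraction=0.0, seed=1,
            plants=(MotifPlant("G" * 40, copies=5),), min_spacing=50,
        )
        with pytest.raises(ValueError, match="do not fit"):
            generate_genome(spec)


class TestGenerateFeatureTable:
    def test_round_trip_through_ncbi_dialect(self, tmp_path):
        rec, _ = generate_genome(SyntheticGenomeSpec(length=100_000, gc_fraction=0.4, seed=2))
        path = tmp_path / "ft.txt"
        feats = generate_feature_table(rec, [FeaturePlan("tRNA", 10, length=80)], seed=3, path=path)
        assert len(feats) == 10
        assert read_feature_table(path) == feats

    def test_upstream_plants_localize_to_trna_before(self, tmp_path):
        """Plants 50 bp upstream of every tRNA all land in (tRNA, before)."""
        from g4census.genome_io import Feature

        length = 200_000
        trnas = [Feature("g", "tRNA", 10_000 + i * 18_000, 10_000 + i * 18_000 + 80, "+")
                 for i in range(10)]
        motif = G_TRACT_UNIT * 8  # 56 bp
        plant_starts = tuple(f.start - 50 - len(motif) for f in trnas)
        spec = SyntheticGenomeSpec(
            length=length, gc_fraction=0.15, seed=13,
            plants=(MotifPlant(motif, positions=plant_starts),), seq_id="g",
        )
        rec, ledger = generate_genome(spec)
        feats = generate_feature_table(rec, [FeaturePlan("gene", 5, length=2000)],
                                       seed=4, explicit=trnas)
        regions = call_pqs(rec.sequences[0][1], ScanParams(), seq_id="g")
        assert len(regions) == 10
        df = zone_frequency_table(regions, feats, {"g": length}, flank=100)
        cell = df.set_index(["feature_class", "zone"])
        assert cell.loc[("tRNA", "before"), "pqs_count"] == 10
        best = cell.loc[("tRNA", "before"), "freq_per_kbp"]
        others = df[~((df.feature_class == "tRNA") & (df.zone == "before"))]
        assert (others.freq_per_kbp < best).all()


class TestGenerateCohort:
    def _spec(self, seed=0, densities=(0.5, 5.0)):
        return SyntheticCohortSpec(
            groups=tuple(
                GroupSpec(name=f"grp{i}", n_genomes=10, length_range=(40_000, 60_000),
                          gc_fraction=0.15, plant_density_per_kbp=d)
                for i, d in enumerate(densities)
            ),
            seed=seed,
        )

    def test_manifest_and_files_written(self, tmp_path):
        manifest = generate_cohort(self._spec(), tmp_path)
        assert len(manifest) == 20
        back = read_manifest(tmp_path / "manifest.tsv")
        assert list(back.genome_id) == list(manifest.genome_id)
        rec = read_fasta(manifest.fasta_path[0])
        assert 40_000 <= rec.total_length <= 60_000

    def test_byte_identical_across_runs(self, tmp_path):
        m1 = generate_cohort(self._spec(seed=3), tmp_path / "a")
        m2 = generate_cohort(self._spec(seed=3), tmp_path / "b")
        for f1, f2 in zip(m1.fasta_path, m2.fasta_path):
            assert open(f1).read() == open(f2).read()

    def test_density_contrast_detected_by_kw(self, tmp_path):
        manifest = generate_cohort(self._spec(seed=1), tmp_path)
        freqs: dict[str, list[float]] = {}
        for row in manifest.itertuples(index=False):
            rec = read_fasta(row.fasta_path, genome_id=row.genome_id)
            n = sum(len(call_pqs(s, ScanParams())) for _, s in rec.sequences)
            freqs.setdefault(row.group, []).append(1000 * n / rec.total_length)
        res = kruskal_wallis(freqs, min_group_size=10)
        assert res.significant

    def test_realized_density_near_requested(self, tmp_path):
        """Poisson plant counts: realized density within 15% at ~1 Mbp scale."""
        spec = SyntheticCohortSpec(
            groups=(GroupSpec("g", 1, (1_000_000, 1_000_000), 0.15, 0.5),),
            seed=8,
        )
        manifest = generate_cohort(spec, tmp_path)
        rec = read_fasta(manifest.fasta_path[0], genome_id="g")
        n = sum(len(call_pqs(s, ScanParams())) for _, s in rec.sequences)
        assert 1000 * n / rec.total_length == pytest.approx(0.5, rel=0.15)

    def test_zero_density_cohort_all_zero(self, tmp_path):
        spec = SyntheticCohortSpec(
            groups=(GroupSpec("a", 3, (30_000, 30_000), 0.15, 0.0),
                    GroupSpec("b", 3, (30_000, 30_000), 0.15, 0.0)),
            seed=4,
        )
        manifest = generate_cohort(spec, tmp_path)
        freqs: dict[str, list[float]] = {}
        for row in manifest.itertuples(index=False):
            rec = read_fasta(row.fasta_path, genome_id=row.genome_id)
            n = sum(len(call_pqs(s, ScanParams())) for _, s in rec.sequences)
            freqs.setdefault(row.group, []).append(1000 * n / rec.total_length)
        assert all(v == 0 for vals in freqs.values() for v in vals)
        res = kruskal_wallis(freqs, min_group_size=3)
        assert res.h_statistic == 0.0 and res.p_value == 1.0
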