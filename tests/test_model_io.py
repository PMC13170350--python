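"""Domain-type invariants and file round-trips."""
import os

import numpy as np
import pandas as pd
import pytest

import lohscan.io as lio
from lohscan.model import (
    Chromosome, EventCall, GenomeMap, IsolateProfile, RateEstimate, paper_design,
)


class TestModelInvariants:
    def test_centromere_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            Chromosome("chrA", 1000, 900, 1100)

    def test_snp_position_zero_rejected(self, toy_genome):
        snps = toy_genome.snps.copy()
        snps.loc[0, "pos"] = 0
        with pytest.raises(ValueError, match="outside|1-based|position"):
            GenomeMap(toy_genome.chromosomes, snps)

    def test_duplicate_snp_position_rejected(self, toy_genome):
        snps = toy_genome.snps.copy()
        snps.loc[1, "pos"] = snps.loc[0, "pos"]
        with pytest.raises(ValueError, match="duplicate|unsorted"):
            GenomeMap(toy_genome.chromosomes, snps)

    def test_feature_outside_chromosome_rejected(self, toy_genome):
        feats = pd.DataFrame([{"track": "repeat", "chrom": "chrB",
                               "start": 1, "end": 70_000, "label": "Ty1"}])
        with pytest.raises(ValueError, match="outside"):
            GenomeMap(toy_genome.chromosomes, toy_genome.snps, feats)

    def test_negative_depth_rejected(self, toy_genome):
        df = toy_genome.snps[["chrom", "pos"]].copy()
        df["depth_P1"] = 5
        df["depth_P2"] = -1
        with pytest.raises(ValueError, match="negative"):
            IsolateProfile("x", 8, df)

    def test_rate_estimate_ci_ordering_enforced(self):
        with pytest.raises(ValueError):
            RateEstimate("x", 5, 100.0, 0.05, 0.06, 0.10)

    def test_event_size_is_inclusive_span(self):
        e = EventCall("i", "I_LOH", "chrA", 1000, 5000, bp_left=(900, 1000),
                      bp_right=(5000, 5100))
        assert e.size == 4001


class TestDesign:
    def test_study_design_divisions(self):
        d = paper_design()
        assert len(d.isolates) == 46
        assert sum(1 for _, c in d.isolates if c == 8) == 38
        assert sum(1 for _, c in d.isolates if c == 20) == 8
        assert d.total_divisions == 10858.0
        # without the stated override, cycles x divisions/cycle lands there too
        from lohscan.model import ExperimentDesign
        d2 = ExperimentDesign(d.isolates, divisions_per_cycle=23.4)
        assert d2.total_divisions == pytest.approx(10858, abs=1)


class TestGenomeMapIO:
    def test_round_trip(self, toy_genome, tmp_path):
        lio.write_genome_map(toy_genome, str(tmp_path))
        g2 = lio.read_genome_map(str(tmp_path / "genome.yaml"))
        pd.testing.assert_frame_equal(toy_genome.snps, g2.snps)
        assert [c.name for c in g2.chromosomes] == toy_genome.chrom_names
        assert g2.arrays == toy_genome.arrays
        pd.testing.assert_frame_equal(
            toy_genome.features.sort_values(["chrom", "start"]).reset_index(drop=True),
            g2.features.sort_values(["chrom", "start"]).reset_index(drop=True))

    def test_bed_zero_based_conversion(self, tmp_path):
        bed = tmp_path / "f.bed"
        bed.write_text("chrI\t99\t200\tTy1\n")
        df = lio.read_feature_bed(str(bed))
        assert (df.loc[0, "start"], df.loc[0, "end"]) == (100, 200)
        out = tmp_path / "g.bed"
        lio.write_feature_bed(df, str(out))
        assert out.read_text() == "chrI\t99\t200\tTy1\n"


class TestProfileIO:
    def _table(self, toy_genome, n_iso=3):
        frames = []
        for i in range(n_iso):
            df = toy_genome.snps[["chrom", "pos"]].copy()
            df.insert(0, "isolate", f"iso{i}")
            df["depth_P1"] = 18
            df["depth_P2"] = 21
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_tsv_round_trip(self, toy_genome, tmp_path):
        path = tmp_path / "profiles.tsv"
        self._table(toy_genome).to_csv(path, sep="\t", index=False)
        profiles = lio.read_profiles(str(path), toy_genome)
        assert len(profiles) == 3
        assert all(len(p.depths) == toy_genome.n_snps() for p in profiles)

    def test_missing_snps_filled_with_zero(self, toy_genome, tmp_path, caplog):
        tbl = self._table(toy_genome, n_iso=1).iloc[:-5]
        path = tmp_path / "profiles.tsv"
        tbl.to_csv(path, sep="\t", index=False)
        with caplog.at_level("WARNING"):
            (p,) = lio.read_profiles(str(path), toy_genome)
        assert (p.depths.tail(5)[["depth_P1", "depth_P2"]] == 0).all().all()
        assert "absent" in caplog.text

    def test_unknown_position_rejected(self, toy_genome, tmp_path):
        tbl = self._table(toy_genome, n_iso=1)
        tbl.loc[0, "pos"] = 123
        path = tmp_path / "profiles.tsv"
        tbl.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="not in genome map"):
            lio.read_profiles(str(path), toy_genome)

    def test_vcf_allele_depths_mapped_to_parents(self, toy_genome, tmp_path):
        # P1 allele is A, P2 is G at every marker; first record has AD 18,21
        vcf = tmp_path / "x.vcf"
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            '##contig=<ID=chrA,length=100000>',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tiso0",
            "chrA\t500\t.\tA\tG\t.\t.\t.\tAD\t18,21",
            "chrA\t1500\t.\tG\tA\t.\t.\t.\tAD\t7,9",
        ]
        vcf.write_text("\n".join(lines) + "\n")
        (p,) = lio.read_profiles(str(vcf), toy_genome)
        row0 = p.depths[(p.depths["chrom"] == "chrA") & (p.depths["pos"] == 500)]
        assert (int(row0["depth_P1"].iloc[0]), int(row0["depth_P2"].iloc[0])) == (18, 21)
        # second record swaps REF/ALT relative to the parents
        row1 = p.depths[(p.depths["chrom"] == "chrA") & (p.depths["pos"] == 1500)]
        assert (int(row1["depth_P1"].iloc[0]), int(row1["depth_P2"].iloc[0])) == (9, 7)


class TestEventIO:
    def _events(self):
        return [
            EventCall("i1", "I_LOH", "chrII", 1000, 5000, bp_left=(900, 1000),
                      bp_right=(5000, 5100), retained_parent="P1",
                      n_transitions=2, n_snps=12, event_id="e1", state=(2, 0)),
            EventCall("i1", "T_DEL", "chrVII", 561_000, 1_090_000,
                      bp_left=(560_000, 561_000), retained_parent="P2",
                      n_transitions=1, n_snps=2000, large=True,
                      junction_repeat_family="Ty1", event_id="e2", state=(0, 1)),
        ]

    def test_bed_coordinate_convention(self, tmp_path):
        tsv, bed = lio.write_events(self._events(), str(tmp_path / "ev"))
        first = open(bed).readline().rstrip("\n").split("\t")
        assert first == ["chrII", "999", "5000", "I_LOH"]

    def test_tsv_round_trip_lossless(self, tmp_path):
        events = self._events()
        tsv, _ = lio.write_events(events, str(tmp_path / "ev"))
        back = lio.read_events(tsv)
        assert back == events

    def test_empty_event_list_writes_header_only(self, tmp_path):
        tsv, bed = lio.write_events([], str(tmp_path / "ev"))
        assert lio.read_events(tsv) == []
        assert open(bed).read() == ""
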