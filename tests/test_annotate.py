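import re

import numpy as np
import pytest

from d4z4kit import annotate_assembly, annotate_read, scan_motifs
from d4z4kit.annotate import (FULL, PARTIAL_DISTAL, TRUNCATED_INTERNAL,
                              detect_features, detect_units, read_fastx,
                              segment_arrays, write_jsonl)
from d4z4kit.annotate import annotation_to_dict, annotation_from_dict, read_jsonl
from d4z4kit._align import IUPAC, revcomp
from d4z4kit.simulate import AlleleSpec, build_allele_sequence, simulate_reads
from d4z4kit import MotifSet


def spanning_read(bundle, rng, err=(0, 0, 0), **spec_kwargs):
    spec = AlleleSpec(**spec_kwargs)
    allele = build_allele_sequence(spec, bundle, rng)
    read = simulate_reads([allele], 1, rng, error_rates=err, all_spanning=True)[0]
    return allele, read


class TestDetectUnits:
    def test_exact_three_unit_read(self, bundle, params):
        read = bundle.p13e11_seq + bundle.unit_seq * 3 + bundle.plam_seq
        hits = detect_units(read, bundle, params)
        fulls = [h for h in hits if h.completeness == FULL]
        assert len(fulls) == 3
        # boundaries snapped to the KpnI anchor of each copy
        starts = [h.read_start for h in fulls]
        assert starts == [len(bundle.p13e11_seq) + i * bundle.unit_len for i in range(3)]
        for h in fulls:
            assert read[h.read_start:h.read_start + 6] == "GGTACC"

    def test_truncated_internal_unit_is_counted(self, bundle, params, rng):
        # analogue of a ~1.2 kb internally deleted unit inside a 5RU array
        _, read = spanning_read(bundle, rng, name="tr", chrom="10q", ab="A",
                                subtype="AS", structure=(5,),
                                truncated_internal=(2, 1200))
        ann = annotate_read(read.seq, bundle, params, "tr")
        assert ann.structure == (5,)
        kinds = [u.completeness for seg in ann.main_segments for u in seg.units]
        assert TRUNCATED_INTERNAL in kinds

    def test_error_injected_count_matches_truth(self, bundle, params, rng):
        _, read = spanning_read(bundle, rng, err=(0.015, 0.0075, 0.0075),
                                name="e", chrom="4q", ab="A", subtype="AL",
                                structure=(12,))
        ann = annotate_read(read.seq, bundle, params, "e")
        assert ann.structure == (12,)

    def test_short_read_gives_empty_result(self, bundle, params):
        assert detect_units("ACGT", bundle, params) == []

    def test_reverse_complement_involution(self, bundle, params, rng):
        _, read = spanning_read(bundle, rng, name="rc", chrom="4q", ab="A",
                                subtype="AS", structure=(3,))
        fwd = detect_units(read.seq, bundle, params)
        rev = detect_units(revcomp(read.seq), bundle, params)
        L = len(read.seq)
        mirrored = sorted((L - h.read_end, L - h.read_start) for h in rev)
        assert mirrored == sorted((h.read_start, h.read_end) for h in fwd)
        assert {h.strand for h in fwd} == {"-" if s == "+" else "+" for s in
                                           {h.strand for h in rev}}
        n_counted = sum(1 for h in fwd if h.completeness in (FULL, TRUNCATED_INTERNAL))
        n_counted_rev = sum(1 for h in rev if h.completeness in (FULL, TRUNCATED_INTERNAL))
        assert n_counted == n_counted_rev


class TestSegmentArrays:
    def test_triplication_splits_into_three_segments(self, bundle, params, rng):
        _, read = spanning_read(bundle, rng, name="trip", chrom="10q", ab="A",
                                subtype="AS", structure=(15, 2, 5),
                                spacers=(20000, 20000),
                                segment_proximal_partials=(1500, 1500))
        ann = annotate_read(read.seq, bundle, params, "trip")
        assert ann.structure == (15, 2, 5)

    def test_duplication_with_short_spacer(self, bundle, params, rng):
        _, read = spanning_read(bundle, rng, name="dup", chrom="10q", ab="A",
                                subtype="AS", structure=(26, 1), spacers=(6500,),
                                segment_proximal_partials=(300,))
        ann = annotate_read(read.seq, bundle, params, "dup")
        assert ann.structure == (26, 1)

    def test_single_contiguous_array_one_segment(self, bundle, params, rng):
        _, read = spanning_read(bundle, rng, name="one", chrom="4q", ab="A",
                                subtype="AS", structure=(4,))
        ann = annotate_read(read.seq, bundle, params, "one")
        assert len(ann.main_segments) == 1

    def test_strand_flip_starts_new_segment(self, bundle, params):
        read = (bundle.flank4q_up + revcomp(bundle.unit_seq * 2) + "T" * 500
                + bundle.p13e11_seq + bundle.unit_seq * 3 + bundle.plam_seq)
        units = detect_units(read, bundle, params)
        segs = segment_arrays(units, params)
        strands = [s.strand for s in segs]
        assert "+" in strands and "-" in strands
        minus = [s for s in segs if s.strand == "-"][0]
        assert minus.full_unit_count == 2


class TestScanMotifs:
    def test_blni_direct_match(self):
        sites = scan_motifs("AACCTAGGTT", MotifSet())
        assert (3, "+") in sites["blni"]

    def test_xapi_iupac_expansion(self):
        sites = scan_motifs("GGAATTCC", MotifSet())
        assert (2, "+") in sites["xapi"]  # GAATTC matches RAATTY (R=G, Y=C)

    def test_brute_force_oracle_equivalence(self, rng):
        # independent oracle: sliding window with per-base IUPAC sets
        def naive(seq, motif):
            out = []
            for i in range(len(seq) - len(motif) + 1):
                if all(seq[i + j] in IUPAC[m] for j, m in enumerate(motif)):
                    out.append(i + 1)
            return out

        seq = "".join(rng.choice(list("ACGT"), size=10000))
        ms = MotifSet()
        sites = scan_motifs(seq, ms)
        for name, motif in ms.named.__call__().items():
            fwd = [p for p, s in sites[name] if s == "+"]
            assert fwd == naive(seq, motif.upper()), name
            rc = revcomp(motif.upper())
            if rc != motif.upper():
                rev = [p for p, s in sites[name] if s == "-"]
                assert rev == naive(seq, rc), name

    def test_mirrored_on_reverse_complement(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        ms = MotifSet()
        fwd = scan_motifs(seq, ms)
        rev = scan_motifs(revcomp(seq), ms)
        L = len(seq)
        for name, motif in ms.named().items():
            mirrored = sorted(L - (p - 1 + len(motif)) + 1 for p, _ in rev[name])
            assert mirrored == sorted(p for p, _ in fwd[name]), name


class TestDetectFeatures:
    def test_exact_plam_hit(self, bundle, params):
        read = "A" * 2000 + bundle.plam_seq + "C" * 2000
        hits = [f for f in detect_features(read, bundle, params) if f.feature == "pLAM"]
        assert len(hits) == 1
        assert hits[0].identity == 1.0
        assert hits[0].read_start == 2000

    def test_featureless_read_is_empty(self, rng, bundle, params):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        assert detect_features(seq, bundle, params) == []

    def test_simulated_spanning_read_has_both_anchors(self, bundle, params, rng):
        _, read = spanning_read(bundle, rng, err=(0.015, 0.0075, 0.0075),
                                name="f", chrom="4q", ab="A", subtype="AS",
                                structure=(2,))
        names = {f.feature for f in detect_features(read.seq, bundle, params)}
        assert {"p13E-11", "pLAM"} <= names

    def test_telomere_run_flagged(self, bundle, params):
        read = "A" * 1500 + "TTAGGG" * 10 + "C" * 1500
        hits = [f for f in detect_features(read, bundle, params)
                if f.feature == "telomere"]
        assert len(hits) == 1 and hits[0].read_end - hits[0].read_start == 60


class TestAnnotateRead:
    def test_spanning_rule(self, bundle, params):
        spanning = bundle.p13e11_seq + bundle.unit_seq * 2 + bundle.plam_seq
        assert annotate_read(spanning, bundle, params).spanning
        no_p13 = bundle.unit_seq * 2 + bundle.plam_seq
        assert not annotate_read(no_p13, bundle, params).spanning
        qb_span = bundle.p13e11_seq + bundle.unit_seq * 2 + bundle.qb_distal_seq
        ann = annotate_read(qb_span, bundle, params)
        assert ann.spanning and ann.feature("qB") is not None

    def test_upstream_inverted_array_flagged(self, bundle, params, rng):
        _, read = spanning_read(bundle, rng, name="inv", chrom="4q", ab="B",
                                structure=(14,), upstream_inverted=(1600, 3300, 3300))
        ann = annotate_read(read.seq, bundle, params, "inv")
        assert ann.inverted_upstream is not None
        assert ann.inverted_upstream.strand != ann.main_segments[0].strand
        assert ann.structure == (14,)

    def test_d4s2463_feature_becomes_inverted_flag(self, bundle, params, rng):
        _, read = spanning_read(bundle, rng, name="d4s", chrom="4q", ab="A",
                                subtype="AS", structure=(5,),
                                upstream_inverted="d4s2463")
        ann = annotate_read(read.seq, bundle, params, "d4s")
        assert ann.has_upstream_d4s2463

    def test_distal_partial_lengths(self, bundle, params, rng):
        for subtype, expect in (("AS", 300), ("AM", 600), ("AL", 1900)):
            _, read = spanning_read(bundle, rng, name=subtype, chrom="4q",
                                    ab="A", subtype=subtype, structure=(3,))
            ann = annotate_read(read.seq, bundle, params, subtype)
            assert ann.distal_partial_len == expect


class TestAssemblyAndIO:
    def test_perfect_assembly_round_trip(self, bundle, params, rng):
        spec = AlleleSpec(name="asm", chrom="4q", ab="A", subtype="AM", structure=(6,))
        allele = build_allele_sequence(spec, bundle, rng)
        anns = annotate_assembly({"contig1": allele.seq}, bundle, params)
        assert anns["contig1"].structure == (6,)
        assert not anns["contig1"].edge_truncated

    def test_split_contig_flagged(self, bundle, params, rng):
        spec = AlleleSpec(name="sp", chrom="4q", ab="A", subtype="AS", structure=(6,))
        allele = build_allele_sequence(spec, bundle, rng)
        units = allele.unit_intervals
        cut = units[3][0] + 1000  # mid-array
        anns = annotate_assembly({"left": allele.seq[:cut]}, bundle, params)
        assert anns["left"].edge_truncated
        assert anns["left"].total_full_units == 3

    def test_jsonl_round_trip(self, bundle, params, rng, tmp_path):
        _, read = spanning_read(bundle, rng, name="io", chrom="10q", ab="A",
                                subtype="AS", structure=(3,))
        ann = annotate_read(read.seq, bundle, params, "io")
        path = tmp_path / "ann.jsonl"
        write_jsonl([ann], path)
        back = read_jsonl(path)[0]
        assert back.structure == ann.structure
        assert back.spanning == ann.spanning
        assert back.distal_partial_len == ann.distal_partial_len

    def test_fastx_gzip_transparency(self, tmp_path):
        import gzip
        (tmp_path / "r.fasta").write_text(">a\nACGT\n")
        with gzip.open(tmp_path / "r.fasta.gz", "wt") as fh:
            fh.write(">a\nACGT\n")
        assert read_fastx(tmp_path / "r.fasta") == read_fastx(tmp_path / "r.fasta.gz")
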