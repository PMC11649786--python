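import numpy as np
import pytest

from _oracles import brute_project_bin
from epimeta.annotation import (
    AnnotationParseError,
    TranscriptModel,
    build_metagene_model,
    parse_annotation,
    project_to_metagene,
    select_representative_transcripts,
)


def gtf_line(chrom, feature, start1, end1, strand, gene, tx):
    return (f"{chrom}\tsrc\t{feature}\t{start1}\t{end1}\t.\t{strand}\t.\t"
            f'gene_id "{gene}"; transcript_id "{tx}";')


class TestParseAnnotation:
    def test_single_exon_plus(self):
        models = parse_annotation(gtf_line("chr1", "exon", 101, 200, "+", "G", "T"))
        assert len(models) == 1
        m = models[0]
        assert m.exons == [(100, 200)]
        assert m.tss == 100

    def test_single_exon_minus_tss(self):
        (m,) = parse_annotation(gtf_line("chr1", "exon", 101, 200, "-", "G", "T"))
        assert m.tss == 199

    def test_three_exon_utr_cds_partition(self):
        # hand-enumerated structure: exons 101-200, 301-400, 501-600 (1-based)
        lines = [
            gtf_line("chr1", "exon", 101, 200, "+", "G", "T"),
            gtf_line("chr1", "exon", 301, 400, "+", "G", "T"),
            gtf_line("chr1", "exon", 501, 600, "+", "G", "T"),
            gtf_line("chr1", "five_prime_utr", 101, 150, "+", "G", "T"),
            gtf_line("chr1", "CDS", 151, 200, "+", "G", "T"),
            gtf_line("chr1", "CDS", 301, 400, "+", "G", "T"),
            gtf_line("chr1", "CDS", 501, 550, "+", "G", "T"),
            gtf_line("chr1", "three_prime_utr", 551, 600, "+", "G", "T"),
        ]
        (m,) = parse_annotation("\n".join(lines))
        assert m.exons == [(100, 200), (300, 400), (500, 600)]
        assert m.utr5 == [(100, 150)]
        assert m.cds == [(150, 200), (300, 400), (500, 550)]
        assert m.utr3 == [(550, 600)]
        assert m.region_lengths() == (50, 200, 50)

    def test_generic_utr_feature_sides(self):
        lines = [
            gtf_line("chr1", "exon", 101, 400, "-", "G", "T"),
            gtf_line("chr1", "CDS", 151, 350, "-", "G", "T"),
            gtf_line("chr1", "UTR", 351, 400, "-", "G", "T"),
            gtf_line("chr1", "UTR", 101, 150, "-", "G", "T"),
        ]
        (m,) = parse_annotation("\n".join(lines))
        # minus strand: right-hand UTR is 5'
        assert m.utr5 == [(350, 400)]
        assert m.utr3 == [(100, 150)]

    def test_malformed_line_reports_line_number(self):
        text = gtf_line("chr1", "exon", 101, 200, "+", "G", "T") + "\nchr1\tonly_two"
        with pytest.raises(AnnotationParseError, match="line 2"):
            parse_annotation(text)

    def test_non_integer_coordinate(self):
        with pytest.raises(AnnotationParseError, match="line 1"):
            parse_annotation(gtf_line("chr1", "exon", "x", 200, "+", "G", "T"))

    def test_unknown_strand_rejected_with_warning(self):
        text = "\n".join([
            gtf_line("chr1", "exon", 101, 200, "*", "G1", "T1"),
            gtf_line("chr1", "exon", 101, 200, "+", "G2", "T2"),
        ])
        with pytest.warns(UserWarning, match="rejected 1"):
            models = parse_annotation(text)
        assert [m.transcript_id for m in models] == ["T2"]

    def test_records_without_transcript_id_ignored(self):
        text = "\n".join([
            'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "G";',
            gtf_line("chr1", "exon", 101, 200, "+", "G", "T"),
        ])
        assert len(parse_annotation(text)) == 1


class TestRepresentativeSelection:
    def _tx(self, gene, tid, length, start=0):
        return TranscriptModel(gene, tid, "chr1", "+",
                               exons=[(start, start + length)])

    def test_longest_wins(self):
        reps = select_representative_transcripts(
            [self._tx("G", "a", 900), self._tx("G", "b", 1200)])
        assert reps["G"].transcript_id == "b"

    def test_tie_breaks_lexicographically(self):
        reps = select_representative_transcripts(
            [self._tx("G", "tB", 1000), self._tx("G", "tA", 1000)])
        assert reps["G"].transcript_id == "tA"

    def test_empty_input(self):
        assert select_representative_transcripts([]) == {}

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(5)
        models = []
        for gi in range(50):
            for ti in range(int(rng.integers(1, 5))):
                models.append(self._tx(f"G{gi}", f"G{gi}.t{ti}",
                                       int(rng.integers(100, 2000))))
        reps = select_representative_transcripts(models)
        for gene in {m.gene_id for m in models}:
            iso = [m for m in models if m.gene_id == gene]
            expect = min(iso, key=lambda m: (-m.exon_length, m.transcript_id))
            assert reps[gene].transcript_id == expect.transcript_id

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(6)
        models = [self._tx(f"G{i % 10}", f"t{i}", int(rng.integers(100, 500)))
                  for i in range(40)]
        reps1 = select_representative_transcripts(models)
        shuffled = list(models)
        rng.shuffle(shuffled)
        reps2 = select_representative_transcripts(shuffled)
        assert {g: m.transcript_id for g, m in reps1.items()} == \
               {g: m.transcript_id for g, m in reps2.items()}


class TestMetageneModel:
    def test_defaults_total_400(self):
        mg = build_metagene_model()
        assert (mg.bins_flank5, mg.bins_utr5, mg.bins_cds, mg.bins_utr3,
                mg.bins_flank3) == (50, 100, 100, 100, 50)
        assert mg.total_bins == 400

    def test_zero_flank(self):
        mg = build_metagene_model(flank_bp=0)
        assert mg.bins_flank5 == mg.bins_flank3 == 0
        assert mg.total_bins == 300

    def test_custom_five_tuple_boundaries(self):
        mg = build_metagene_model((10, 10, 10, 10, 10), flank_bp=1000)
        assert mg.region_boundaries == (10, 20, 30, 40, 50)

    @pytest.mark.parametrize("bad", [(0, 100, 100), (100, -1, 100)])
    def test_invalid_bin_counts(self, bad):
        with pytest.raises(ValueError):
            build_metagene_model(bad)


class TestProjection:
    def test_tss_maps_to_first_utr5_bin(self, toy_plus, mg_default):
        c = project_to_metagene(toy_plus.tss, toy_plus, mg_default)
        assert c == mg_default.bins_flank5  # start of the utr5 band
        assert mg_default.region_of(c) == "utr5"

    def test_cds_midpoint_linear_scaling(self, mg_default):
        # single-exon transcript with a 300 nt CDS flanked by 300 nt UTRs
        m = TranscriptModel("G", "T", "chr1", "+", exons=[(1000, 1900)],
                            utr5=[(1000, 1300)], cds=[(1300, 1600)],
                            utr3=[(1600, 1900)])
        c = project_to_metagene(1450, m, mg_default)  # CDS offset 150 of 300
        assert c == mg_default.bins_flank5 + mg_default.bins_utr5 + 50

    def test_intron_returns_none(self, toy_plus, mg_default):
        assert project_to_metagene(1300, toy_plus, mg_default) is None

    def test_beyond_flank_returns_none(self, toy_plus, mg_default):
        assert project_to_metagene(toy_plus.tss - 1001, toy_plus,
                                   mg_default) is None
        assert project_to_metagene(3400, toy_plus, mg_default) is None

    def test_no_utr_transcript_projects_cds(self, mg_default):
        m = TranscriptModel("G", "T", "chr1", "+", exons=[(1000, 1500)],
                            cds=[(1000, 1500)])
        c = project_to_metagene(1250, m, mg_default)
        assert mg_default.region_of(c) == "cds"

    def test_noncoding_transcript_projects_as_body(self, mg_default):
        m = TranscriptModel("G", "T", "chr1", "+", exons=[(1000, 1500)])
        c = project_to_metagene(1250, m, mg_default)
        assert mg_default.region_of(c) == "cds"

    @pytest.mark.parametrize("fixture", ["toy_plus", "toy_minus"])
    def test_brute_force_oracle(self, fixture, mg_default, request):
        model = request.getfixturevalue(fixture)
        rng = np.random.default_rng(42)
        s0, s1 = model.span
        positions = rng.integers(s0 - 1500, s1 + 1500, size=1000)
        for pos in positions:
            got = project_to_metagene(int(pos), model, mg_default)
            expect = brute_project_bin(int(pos), model, mg_default)
            if expect is None:
                assert got is None, pos
            else:
                assert got is not None and int(np.floor(got)) == expect, pos

    @pytest.mark.parametrize("fixture", ["toy_plus", "toy_minus"])
    def test_order_preserving(self, fixture, mg_default, request):
        model = request.getfixturevalue(fixture)
        s0, s1 = model.span
        sweep = range(s0 - 1000, s1 + 1000)
        if model.strand == "-":
            sweep = reversed(list(sweep))
        coords = [project_to_metagene(p, model, mg_default) for p in sweep]
        seen = [c for c in coords if c is not None]
        assert all(a <= b for a, b in zip(seen, seen[1:]))

    def test_mirror_property(self, toy_plus, mg_default):
        reflect = 5000
        mirrored = TranscriptModel(
            "G1m", "G1m.t1", "chr1", "-",
            exons=[(reflect - e, reflect - s) for s, e in reversed(toy_plus.exons)],
            utr5=[(reflect - e, reflect - s) for s, e in reversed(toy_plus.utr5)],
            cds=[(reflect - e, reflect - s) for s, e in reversed(toy_plus.cds)],
            utr3=[(reflect - e, reflect - s) for s, e in reversed(toy_plus.utr3)],
        )
        for pos in range(toy_plus.span[0] - 1000, toy_plus.span[1] + 1000):
            a = project_to_metagene(pos, toy_plus, mg_default)
            b = project_to_metagene(reflect - 1 - pos, mirrored, mg_default)
            if a is None:
                assert b is None
            else:
                assert b == pytest.approx(a)

    def test_bin_midpoints_round_trip(self, toy_plus, mg_default):
        # genomic bases of each bin via the brute-force walk; the midpoint
        # base of every populated bin must project back into that bin
        s0, s1 = toy_plus.span
        per_bin: dict[int, list[int]] = {}
        for pos in range(s0 - 1000, s1 + 1000):
            b = brute_project_bin(pos, toy_plus, mg_default)
            if b is not None:
                per_bin.setdefault(b, []).append(pos)
        assert per_bin
        for b, bases in per_bin.items():
            mid = bases[len(bases) // 2]
            c = project_to_metagene(mid, toy_plus, mg_default)
            assert int(np.floor(c)) == b
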