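"""Feature-table parsing, spacer arithmetic and validation audits."""

from __future__ import annotations

import io

import pytest
from hypothesis import given, settings, strategies as st

from mitocomparator.genome_model import (Feature, FeatureTable,
                                         FeatureTableError,
                                         coding_length_summary,
                                         parse_feature_table_tsv, spacer_table,
                                         validate_table, write_feature_table)

GENE_POOL = ["cox1", "cox2", "cox3", "nad1", "nad2", "nad3", "nad4", "nad4L",
             "nad5", "nad6", "atp6", "atp8", "cytb", "rrnS", "rrnL",
             "trnA", "trnK", "trnV", "trnD", "trnL1", "trnS2"]


def make_table(rows, topology="linear", total=None):
    feats = tuple(Feature(*r) for r in rows)
    total = total or (feats[-1].end + 5 if feats else 100)
    return FeatureTable(feats, topology, total)


class TestParsing:
    def test_published_fixture_round_trips_byte_identical(self, calanus_table):
        text = write_feature_table(calanus_table)
        again = parse_feature_table_tsv(io.StringIO(text))
        assert again == calanus_table
        assert write_feature_table(again) == text

    def test_empty_table_is_valid(self):
        t = parse_feature_table_tsv(io.StringIO(
            "# topology: linear\n# total_length: 100\n"
            "name\tkind\tstrand\tstart\tend\tstart_codon\tstop_codon\n"))
        assert len(t) == 0 and t.total_length == 100

    @pytest.mark.parametrize("row, message", [
        ("cox1\tPCG\tL\t5207\t3660\tATA\tTAA", "end"),        # end < start
        ("cox9\tPCG\tH\t1\t9\tATA\tTAA", "unknown gene"),     # bad name
        ("cox1\tXXX\tH\t1\t9\tATA\tTAA", "kind"),             # bad kind
        ("cox1\tPCG\tZ\t1\t9\tATA\tTAA", "strand"),           # bad strand
        ("cox1\tPCG\tH\tx\t9\tATA\tTAA", "coordinates"),      # non-numeric
    ])
    def test_malformed_rows_rejected(self, row, message):
        text = ("# topology: linear\n# total_length: 9000\n"
                "name\tkind\tstrand\tstart\tend\tstart_codon\tstop_codon\n"
                + row + "\n")
        with pytest.raises(FeatureTableError, match=message):
            parse_feature_table_tsv(io.StringIO(text))

    def test_duplicate_names_rejected(self):
        with pytest.raises(FeatureTableError, match="duplicate"):
            make_table([("cox1", "PCG", "H", 1, 9, "ATA", "TAA"),
                        ("cox1", "PCG", "H", 20, 28, "ATA", "TAA")])

    def test_plus_minus_strands_normalised(self):
        f = Feature("cox1", "PCG", "-", 1, 9, "ATA", "TAA")
        assert f.strand == "L"

    def test_non_pcg_cannot_carry_codons(self):
        with pytest.raises(FeatureTableError, match="start/stop"):
            Feature("trnA", "tRNA", "H", 1, 65, "ATA", None)


class TestSpacers:
    def test_published_spacers_and_overlaps(self, calanus_table):
        records = {(r.upstream, r.downstream): r for r in spacer_table(calanus_table)}
        assert records[("trnH", "trnA")].spacer_nt == 1770
        assert records[("trnH", "trnA")].lnr_label == "LNR3"
        assert records[("trnY", "trnE")].spacer_nt == -5
        overlaps = [r for r in records.values() if r.is_overlap]
        assert len(overlaps) == 3
        assert min(r.spacer_nt for r in overlaps) == -5

    def test_lnr_labels_follow_genome_order(self, calanus_table):
        labels = {r.lnr_label: (r.upstream, r.downstream)
                  for r in spacer_table(calanus_table) if r.lnr_label}
        assert labels == {
            "LNR1": ("atp6", "rrnL"),   # open wrap region (head + tail)
            "LNR2": ("cox1", "nad4L"),
            "LNR3": ("trnH", "trnA"),
            "LNR4": ("nad3", "cox3"),
            "LNR5": ("cox3", "nad4"),
            "LNR6": ("nad2", "atp8"),
        }

    def test_linear_wrap_record_flagged_open(self, calanus_table):
        wrap = spacer_table(calanus_table)[-1]
        assert wrap.open and wrap.spacer_nt == 2243 + 716

    def test_abutting_features_have_zero_spacer(self):
        t = make_table([("cox1", "PCG", "H", 1, 9, "ATA", "TAA"),
                        ("cox2", "PCG", "H", 10, 18, "ATA", "TAA")])
        assert spacer_table(t)[0].spacer_nt == 0

    def test_single_feature_yields_no_records(self):
        t = make_table([("cox1", "PCG", "H", 1, 9, "ATA", "TAA")])
        assert spacer_table(t) == []

    def test_circular_lengths_plus_spacers_tile_the_genome(self):
        t = make_table([("cox1", "PCG", "H", 11, 19, "ATA", "TAA"),
                        ("trnA", "tRNA", "H", 25, 40),
                        ("rrnS", "rRNA", "L", 61, 90)],
                       topology="circular", total=120)
        total = sum(f.length for f in t.features) + \
            sum(r.spacer_nt for r in spacer_table(t))
        assert total == t.total_length


class TestSummaries:
    def test_published_kind_totals(self, calanus_table):
        s = coding_length_summary(calanus_table)
        assert s["PCG"].count == 13
        assert s["PCG"].total_nt == 11137
        assert s["rRNA"].lengths == {"rrnS": 654, "rrnL": 1139}
        assert s["tRNA"].count == 20

    def test_empty_table_all_zero(self):
        t = FeatureTable((), "linear", 50)
        assert all(v.total_nt == 0 and v.count == 0
                   for v in coding_length_summary(t).values())


class TestValidation:
    def test_declared_audit_flags_only_known_discrepancies(self, calanus_table,
                                                           declared_claims):
        issues = validate_table(calanus_table, declared_claims)
        flagged = {(i.row, i.field) for i in issues}
        # the two intergenic "3"s are inconsistent with the printed
        # coordinates; every other declared length and spacer verifies
        assert flagged == {("trnV", "intergenic"), ("trnG", "intergenic")}

    def test_length_mismatch_flagged(self):
        t = make_table([("cox1", "PCG", "H", 1, 10, "ATA", "TAA"),
                        ("cox2", "PCG", "H", 20, 28, "ATA", "TAA")])
        issues = validate_table(t, {"cox1": {"length": 11}})
        assert [(i.row, i.field, i.declared, i.computed) for i in issues] == \
            [("cox1", "length", 11, 10)]

    def test_prose_spacer_claim_against_coordinates(self, calanus_table):
        # the text's "762 bp" for the cox3..nad4 region vs the computed 771
        issues = validate_table(calanus_table, {"nad4": {"intergenic": 762}})
        assert len(issues) == 1 and issues[0].computed == 771

    def test_consistent_declarations_produce_empty_report(self, calanus_table):
        issues = validate_table(calanus_table,
                                {"trnV": {"length": 65}, "rrnS": {"length": 654}})
        assert issues == []


def test_genbank_and_tsv_dialects_agree(tmp_path):
    """The same annotation content parses identically from both dialects."""
    from mitocomparator.genome_model import parse_feature_table

    seq = ("ATA" + "GGA" * 3 + "TAA" +          # cox1, H strand, 1..15
           "ACGTACGTAC" +                        # spacer 16..25
           "GCGCATTGCAGCATA")                    # trnA 26..40 (L strand)
    gb = tmp_path / "toy.gb"
    gb.write_text(f"""LOCUS       toy                       40 bp    DNA     linear   INV 01-JAN-2000
DEFINITION  toy record.
FEATURES             Location/Qualifiers
     CDS             1..15
                     /gene="cox1"
     tRNA            complement(26..40)
                     /gene="trnA"
ORIGIN
        1 {seq[:40].lower()}
//
""")
    t_gb = parse_feature_table(gb)
    tsv = tmp_path / "toy.tsv"
    tsv.write_text("# topology: linear\n# total_length: 40\n"
                   "name\tkind\tstrand\tstart\tend\tstart_codon\tstop_codon\n"
                   "cox1\tPCG\tH\t1\t15\tATA\tTAA\n"
                   "trnA\ttRNA\tL\t26\t40\t.\t.\n")
    t_tsv = parse_feature_table(tsv)
    assert [(f.name, f.kind, f.strand, f.start, f.end) for f in t_gb.features] == \
        [(f.name, f.kind, f.strand, f.start, f.end) for f in t_tsv.features]
    assert t_gb["cox1"].start_codon == "ATA" and t_gb["cox1"].stop_codon == "TAA"
    assert t_gb.total_length == t_tsv.total_length == 40


@st.composite
def random_tables(draw):
    n = draw(st.integers(min_value=0, max_value=8))
    names = draw(st.permutations(GENE_POOL))[:n]
    feats = []
    pos = 1
    from mitocomparator.genome_model import GENE_VOCABULARY
    for name in names:
        pos += draw(st.integers(min_value=0, max_value=30))
        length = draw(st.integers(min_value=3, max_value=120))
        kind = GENE_VOCABULARY[name]
        strand = draw(st.sampled_from("HL"))
        feats.append(Feature(name, kind, strand, pos, pos + length - 1))
        pos += length
    topology = draw(st.sampled_from(["linear", "circular"]))
    return FeatureTable(tuple(feats), topology, pos + draw(st.integers(0, 50)))


@settings(max_examples=60, deadline=None)
@given(random_tables())
def test_serialisation_round_trip_is_identity(t):
    assert parse_feature_table_tsv(io.StringIO(write_feature_table(t))) == t


@settings(max_examples=60, deadline=None)
@given(random_tables())
def test_spacer_identity_and_overlap_count(t):
    records = spacer_table(t)
    by_pair = {(r.upstream, r.downstream): r for r in records}
    names = t.names()
    for prev, nxt in zip(t.features, t.features[1:]):
        assert by_pair[(prev.name, nxt.name)].spacer_nt == \
            nxt.start - prev.end - 1
    assert sum(1 for r in records if r.is_overlap) == \
        sum(1 for r in records if r.spacer_nt < 0)
    if t.topology == "circular" and len(t) >= 2:
        assert sum(f.length for f in t.features) + \
            sum(r.spacer_nt for r in records) == t.total_length
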