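"""Variable-site calling, window scans, hotspots, microsatellites, motifs."""

from __future__ import annotations

import numpy as np
import pytest

from mitocomparator.popscan import (HaplotypeAlignment, HotspotRegion,
                                    call_and_classify_variable_sites,
                                    find_microsatellites_and_alleles,
                                    hotspot_regions, scan_cr_motifs,
                                    sliding_window_scan)


def aln(*rows, taxa=None, annotation=None):
    taxa = taxa or tuple(f"h{i}" for i in range(len(rows)))
    return HaplotypeAlignment(tuple(taxa), tuple(rows), annotation)


class TestSiteClassification:
    def test_identical_rows_have_no_variable_sites(self):
        sites, summary = call_and_classify_variable_sites(aln("ACGT", "ACGT"))
        assert sites == [] and summary.n_variable == 0

    def test_column_state_classification(self):
        sites, summary = call_and_classify_variable_sites(
            aln("AAAA", "GCA-"))
        kinds = {s.column: (s.kind, s.transition) for s in sites}
        assert kinds[1] == ("substitution", True)    # A/G
        assert kinds[2] == ("substitution", False)   # A/C
        assert kinds[4] == ("indel", None)           # A/-
        assert summary.n_substitution == 2 and summary.n_indel == 1

    def test_multiallelic_column_counts_per_state_pair(self):
        _, summary = call_and_classify_variable_sites(
            aln("A", "G", "C"))
        # pairs {A,G} ts, {A,C} tv, {G,C} tv
        assert summary.ts_pairs == 1 and summary.tv_pairs == 2

    def test_parsimony_informative_needs_two_pairs(self):
        sites, _ = call_and_classify_variable_sites(
            aln("AC", "AC", "GC", "GA"))
        by_col = {s.column: s.parsimony_informative for s in sites}
        assert by_col[1] is True     # A,A vs G,G
        assert by_col[2] is False    # singleton A
        _, summary = call_and_classify_variable_sites(aln("A", "A", "G"))
        assert summary.n_parsimony_informative == 0

    def test_effect_classification_with_annotation(self):
        from mitocomparator.genome_model import Feature, FeatureTable
        t = FeatureTable((Feature("cox1", "PCG", "H", 1, 9, "ATA", "TAA"),),
                         "linear", 9)
        # ATA GGA TAA; third row changes G->A at codon-2 position 2
        # (nonsynonymous Gly->Glu), second row changes A->G at codon-2
        # position 3 (synonymous GGA->GGG)
        rows = ["ATAGGATAA", "ATAGGGTAA", "ATAGAATAA"]
        sites, summary = call_and_classify_variable_sites(
            aln(*rows, annotation=t))
        by_col = {s.column: s for s in sites}
        assert by_col[6].effect == "synonymous"
        assert by_col[6].codon_position == 3
        assert by_col[5].effect == "nonsynonymous"
        assert by_col[5].codon_position == 2
        assert summary.codon_position_counts == {1: 0, 2: 1, 3: 1}

    def test_l_strand_gene_effect_uses_sense_codons(self):
        from mitocomparator.genome_model import Feature, FeatureTable, \
            reverse_complement
        sense = "ATAGGATAA"
        ref = reverse_complement(sense)            # gene on L strand
        t = FeatureTable((Feature("cox1", "PCG", "L", 1, 9, "ATA", "TAA"),),
                         "linear", 9)
        # mutate the reference-strand base pairing with sense position 6
        # (GGA -> GGG, synonymous): sense pos 6 is reference pos 4
        mutated = ref[:3] + "C" + ref[4:]
        sites, _ = call_and_classify_variable_sites(aln(ref, mutated,
                                                        annotation=t))
        assert sites[0].effect == "synonymous"
        assert sites[0].gene == "cox1"

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            call_and_classify_variable_sites(aln("ACGT"))


class TestWindowScan:
    def test_hand_counted_window_frequencies(self):
        # 400 columns, single variable column at 250
        scan = sliding_window_scan([250], window=200, step=2,
                                   alignment_length=400)
        freqs = dict(zip(scan.starts.tolist(), scan.frequencies.tolist()))
        assert freqs[51] == pytest.approx(0.005)    # covers 51..250
        assert freqs[53] == pytest.approx(0.005)
        assert freqs[49] == 0.0                     # covers 49..248? no: 49..248 includes 250? no
        assert freqs[1] == 0.0
        assert all(f == pytest.approx(0.005) for s, f in freqs.items()
                   if s <= 250 <= s + 199)

    def test_zero_variability(self):
        scan = sliding_window_scan([], window=200, step=2, alignment_length=500)
        assert scan.mean_frequency == 0
        assert np.all(scan.frequencies == 0)

    def test_partial_trailing_window_dropped(self):
        scan = sliding_window_scan([10], window=100, step=30,
                                   alignment_length=205)
        assert scan.starts.tolist() == [1, 31, 61, 91]

    def test_mean_frequency_identity(self):
        rng = np.random.default_rng(2)
        pos = sorted(rng.choice(np.arange(1, 1001), size=37, replace=False))
        scan = sliding_window_scan([int(p) for p in pos], window=200, step=2,
                                   alignment_length=1000)
        assert scan.mean_frequency * scan.alignment_length == pytest.approx(37)

    def test_published_mean_variable_site_frequency(self):
        """397 variable sites over the 16,670-column alignment give the
        reported mean frequency of ~0.024."""
        scan = sliding_window_scan(list(range(1, 398)), window=200, step=2,
                                   alignment_length=16670)
        assert round(scan.mean_frequency, 3) == 0.024

    def test_window_larger_than_alignment_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_scan([1], window=300, alignment_length=200)

    def test_scan_reverses_with_the_alignment(self):
        L = 600
        pos = [3, 100, 101, 340]
        fwd = sliding_window_scan(pos, window=100, step=1, alignment_length=L)
        rev = sliding_window_scan([L + 1 - p for p in pos], window=100,
                                  step=1, alignment_length=L)
        assert np.allclose(fwd.frequencies, rev.frequencies[::-1])


class TestHotspots:
    def test_published_hotspot_densities(self):
        """The reported hotspot spans and counts give 1-in-4.6 and
        1-in-17.6 bases per variable site."""
        assert round(HotspotRegion(11216, 12260, 226).bases_per_site, 1) == 4.6
        assert round(HotspotRegion(1848, 2235, 22).bases_per_site, 1) == 17.6
        assert round(HotspotRegion(649, 862, 10).bases_per_site, 1) == 21.4

    def test_clustered_sites_emerge_as_one_region(self):
        pos = list(range(480, 530)) + [50, 900]
        scan = sliding_window_scan(pos, window=100, step=2,
                                   alignment_length=1000)
        regions = hotspot_regions(scan, pos, threshold_quantile=0.9)
        assert len(regions) >= 1
        top = regions[0]
        assert top.start <= 480 and top.end >= 529
        assert top.n_sites >= 50

    def test_uniform_variability_yields_no_hotspots(self):
        pos = list(range(10, 1000, 10))
        scan = sliding_window_scan(pos, window=100, step=2,
                                   alignment_length=1000)
        # every window sees the same density: nothing exceeds the quantile
        assert hotspot_regions(scan, pos, threshold_quantile=0.95) == []


class TestMicrosatellites:
    def test_simple_tcc_array(self):
        loci = find_microsatellites_and_alleles(
            aln("AATCCTCCTCCTCCAA", "AATCCTCCTCCTCCAA"))
        assert len(loci) == 1
        locus = loci[0]
        assert locus.motif == "TCC"
        assert set(locus.repeat_counts.values()) == {4}
        assert locus.n_alleles == 1

    def test_repeat_number_variation_creates_alleles(self):
        a = "G" + "AT" * 14 + "-" * 28 + "G"
        b = "G" + "AT" * 28 + "G"
        c = "G" + "AT" * 14 + "-" * 28 + "G"
        loci = find_microsatellites_and_alleles(aln(a, b, c))
        assert len(loci) == 1
        assert loci[0].n_alleles == 2
        assert sorted(loci[0].repeat_counts.values()) == [14, 14, 28]

    def test_internal_variant_creates_extra_allele(self):
        a = "C" + "TA" * 10 + "C"
        b = "C" + "TA" * 5 + "TG" + "TA" * 4 + "C"   # broken array
        loci = find_microsatellites_and_alleles(aln(a, b))
        spans = [l for l in loci if l.motif in ("TA", "AT")]
        assert spans  # the intact array is found
        assert all(l.n_alleles >= 1 for l in loci)

    def test_programmed_loci_recovered(self, population_bundle):
        alignment, truth = population_bundle
        loci = find_microsatellites_and_alleles(alignment)
        for spec in truth["microsatellites"]:
            hits = [l for l in loci
                    if min(s[0] for s in l.spans.values()) == spec["start"]]
            assert len(hits) == 1, spec
            locus = hits[0]
            assert locus.n_alleles == spec["n_alleles"]
            assert sorted(locus.repeat_counts.values()) == \
                sorted(spec["repeat_counts"])


class TestCrMotifs:
    def test_poly_t_run_detection(self):
        rep = scan_cr_motifs("AAAA" + "T" * 10 + "CCC", min_poly_t=8)
        assert rep.poly_t_runs == [(5, 14)]

    def test_short_runs_ignored(self):
        rep = scan_cr_motifs("TTTTTTT", min_poly_t=8)
        assert rep.poly_t_runs == []

    def test_constructed_hairpin_found(self):
        stem = "GCGCGCGC"
        seq = "AACCA" + stem + "AAAA" + "GCGCGCGC" + "ACCAA"
        rep = scan_cr_motifs(seq, min_stem=8)
        assert len(rep.hairpins) == 1
        h = rep.hairpins[0]
        assert h.stem_length == 8 and h.loop_length == 4
        assert h.stem_start == 6

    def test_hairpin_count_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        min_stem, min_loop, max_loop = 5, 3, 30
        rep = scan_cr_motifs(seq, min_stem=min_stem, min_loop=min_loop,
                             max_loop=max_loop)
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        n = len(seq)

        def valid(i, m, loop):
            j = i + m + loop
            if i < 0 or j + m > n:
                return False
            return all(comp[seq[i + x]] == seq[j + m - 1 - x]
                       for x in range(m))

        oracle = set()
        for i in range(n):
            for loop in range(min_loop, max_loop + 1):
                for m in range(min_stem, (n - i - loop) // 2 + 1):
                    if not valid(i, m, loop):
                        continue
                    outward = valid(i - 1, m + 1, loop)
                    inward = loop - 2 >= min_loop and valid(i, m + 1, loop - 2)
                    if not outward and not inward:
                        oracle.add((i + 1, m, loop))
        found = {(h.stem_start, h.stem_length, h.loop_length)
                 for h in rep.hairpins}
        assert found == oracle

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan_cr_motifs("")
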