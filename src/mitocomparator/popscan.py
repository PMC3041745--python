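"""Intraspecific polymorphism scan over a multi-haplotype alignment.

Given a gapped alignment of mitogenome haplotypes (optionally annotated with
a feature table so columns can be assigned to genes and codon positions),
this module calls and classifies variable sites, draws a sliding-window
variable-site frequency track, ranks hotspot regions, types microsatellite
alleles and scans control-region motifs (poly-T stretches, hairpins).

Site classification:

* a column is *variable* iff it shows ≥2 distinct states, a gap counting as a
  state;
* a variable column is an *indel* site iff a gap participates, otherwise a
  *substitution*;
* transition/transversion status is assessed per distinct unordered base
  pair, so a multi-allelic column contributes one tally per observed pair;
* *parsimony informative*: ≥2 states each carried by ≥2 haplotypes;
* synonymous/nonsynonymous effect is decided from the observed haplotype
  codons (not hypothetical mutants) under the invertebrate mitochondrial
  code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import INVERTEBRATE_MITO, GeneticCode
from .genome_model import FeatureTable, reverse_complement

__all__ = [
    "HaplotypeAlignment",
    "VariableSite",
    "SiteSummary",
    "WindowScan",
    "HotspotRegion",
    "MicrosatelliteLocus",
    "call_and_classify_variable_sites",
    "sliding_window_scan",
    "hotspot_regions",
    "find_microsatellites_and_alleles",
    "scan_cr_motifs",
]

_BASES = set("ACGT")
_PURINES = set("AG")
_PYRIMIDINES = set("CT")
GAP = "-"


@dataclass(frozen=True)
class HaplotypeAlignment:
    """n haplotypes × L aligned columns, with optional genome annotation.

    ``annotation`` coordinates refer to the *reference* haplotype
    (``reference_row``, default the first): alignment column c maps to the
    reference genome position equal to the count of non-gap reference
    characters in columns 1..c.
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]
    annotation: FeatureTable | None = None
    reference_row: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("ragged alignment")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, c: int) -> str:
        """1-based column."""
        return "".join(r[c - 1] for r in self.rows)

    def column_to_genome(self) -> np.ndarray:
        """1-based genome coordinate of every alignment column (0 where the
        reference itself has a gap, i.e. an insertion column)."""
        ref = self.rows[self.reference_row]
        coords = np.zeros(len(ref), dtype=int)
        pos = 0
        for i, ch in enumerate(ref):
            if ch != GAP:
                pos += 1
                coords[i] = pos
        return coords

    @classmethod
    def from_fasta(cls, path, annotation: FeatureTable | None = None
                   ) -> "HaplotypeAlignment":
        from Bio import SeqIO
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(tuple(taxa), tuple(rows), annotation)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, r in zip(self.taxa, self.rows):
                fh.write(f">{t}\n{r}\n")


@dataclass(frozen=True)
class VariableSite:
    column: int                      # 1-based alignment column
    kind: str                        # "substitution" | "indel"
    states: tuple[str, ...]
    transition: bool | None          # biallelic substitutions only
    parsimony_informative: bool
    gene: str | None = None
    codon_position: int | None = None
    effect: str | None = None        # "synonymous" | "nonsynonymous"


@dataclass
class SiteSummary:
    n_variable: int = 0
    n_substitution: int = 0
    n_indel: int = 0
    ts_pairs: int = 0
    tv_pairs: int = 0
    n_parsimony_informative: int = 0
    codon_position_counts: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    n_synonymous: int = 0
    n_nonsynonymous: int = 0

    @property
    def transition_fraction(self) -> float | None:
        pairs = self.ts_pairs + self.tv_pairs
        return None if pairs == 0 else self.ts_pairs / pairs

    @property
    def parsimony_informative_fraction(self) -> float | None:
        return (None if self.n_substitution == 0
                else self.n_parsimony_informative / self.n_substitution)


def _pair_is_transition(a: str, b: str) -> bool:
    pair = {a, b}
    return pair <= _PURINES or pair <= _PYRIMIDINES


def _site_effect(a: HaplotypeAlignment, coords: np.ndarray, col: int,
                 code: GeneticCode) -> tuple[str | None, int | None, str | None]:
    """(gene, codon_position, effect) of an alignment column, via annotation."""
    t = a.annotation
    if t is None:
        return None, None, None
    g = coords[col - 1]
    if g == 0:
        return None, None, None
    feature = None
    for f in t.features:
        if f.start <= g <= f.end:
            feature = f
            if f.kind == "PCG":
                break  # overlapping annotations resolve to the PCG
    if feature is None:
        return None, None, None
    if feature.kind != "PCG":
        return feature.name, None, None
    # position within the sense-strand CDS
    if feature.strand == "H":
        cds_off = g - feature.start
    else:
        cds_off = feature.end - g
    codon_pos = cds_off % 3 + 1
    codon_idx = cds_off // 3
    # genome coordinates of the codon, reference strand
    if feature.strand == "H":
        gstart = feature.start + 3 * codon_idx
        gcoords = (gstart, gstart + 1, gstart + 2)
    else:
        gend = feature.end - 3 * codon_idx
        gcoords = (gend, gend - 1, gend - 2)  # sense order
    # map genome coords back to alignment columns (identity away from
    # insertion columns)
    colmap = {}
    for i, gc in enumerate(coords):
        if gc:
            colmap[int(gc)] = i  # 0-based column
    codons = []
    for row in a.rows:
        try:
            codon = "".join(row[colmap[gc]] for gc in gcoords)
        except KeyError:
            return feature.name, codon_pos, None
        if feature.strand == "L":
            # positions were already read in sense order; complement only
            codon = reverse_complement(codon)[::-1]
        if all(b in _BASES for b in codon):
            codons.append(codon)
    if not codons:
        return feature.name, codon_pos, None
    # judge the focal site from observed codon pairs differing only there,
    # so a second variable position in the same codon cannot confound it
    focal = codon_pos - 1
    uniq = sorted(set(codons))
    isolating = [(c1, c2) for i, c1 in enumerate(uniq) for c2 in uniq[i + 1:]
                 if c1[focal] != c2[focal] and
                 all(c1[k] == c2[k] for k in range(3) if k != focal)]
    if isolating:
        changed = any(code.codons.get(c1, "X") != code.codons.get(c2, "X")
                      for c1, c2 in isolating)
    else:
        changed = len({code.codons.get(c, "X") for c in uniq}) > 1
    effect = "nonsynonymous" if changed else "synonymous"
    return feature.name, codon_pos, effect


def call_and_classify_variable_sites(a: HaplotypeAlignment,
                                     code: GeneticCode = INVERTEBRATE_MITO
                                     ) -> tuple[list[VariableSite], SiteSummary]:
    """Scan every column; return variable sites and exact summary counts."""
    if a.n < 2:
        raise ValueError("need at least two haplotypes")
    coords = a.column_to_genome()
    sites: list[VariableSite] = []
    summary = SiteSummary()
    for c in range(1, a.length + 1):
        col = a.column(c)
        states = Counter(ch for ch in col if ch in _BASES or ch == GAP)
        if len(states) < 2:
            continue
        summary.n_variable += 1
        is_indel = GAP in states
        kind = "indel" if is_indel else "substitution"
        pi = sum(1 for n in states.values() if n >= 2) >= 2
        transition: bool | None = None
        gene = codon_pos = effect = None
        if not is_indel:
            summary.n_substitution += 1
            bases = sorted(states)
            if len(bases) == 2:
                transition = _pair_is_transition(*bases)
            for i in range(len(bases)):
                for j in range(i + 1, len(bases)):
                    if _pair_is_transition(bases[i], bases[j]):
                        summary.ts_pairs += 1
                    else:
                        summary.tv_pairs += 1
            if pi:
                summary.n_parsimony_informative += 1
            gene, codon_pos, effect = _site_effect(a, coords, c, code)
            if codon_pos is not None:
                summary.codon_position_counts[codon_pos] += 1
            if effect == "synonymous":
                summary.n_synonymous += 1
            elif effect == "nonsynonymous":
                summary.n_nonsynonymous += 1
        else:
            summary.n_indel += 1
            gene, codon_pos, _ = _site_effect(a, coords, c, code)
        sites.append(VariableSite(column=c, kind=kind,
                                  states=tuple(sorted(states)),
                                  transition=transition,
                                  parsimony_informative=pi,
                                  gene=gene, codon_position=codon_pos,
                                  effect=effect))
    return sites, summary


@dataclass(frozen=True)
class WindowScan:
    window_length: int
    step: int
    starts: np.ndarray          # 1-based window start columns
    frequencies: np.ndarray     # variable-column fraction per window
    mean_frequency: float       # total variable sites / alignment length
    n_variable: int
    alignment_length: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start": self.starts,
                             "end": self.starts + self.window_length - 1,
                             "frequency": self.frequencies})


def sliding_window_scan(a: HaplotypeAlignment | Sequence[int],
                        window: int = 200, step: int = 2,
                        alignment_length: int | None = None) -> WindowScan:
    """Variable-site frequency in windows of ``window`` columns slid by
    ``step``.  The trailing partial window is dropped.  Accepts either an
    alignment (sites are called first) or a precomputed list of 1-based
    variable-column positions plus ``alignment_length``."""
    if isinstance(a, HaplotypeAlignment):
        sites, _ = call_and_classify_variable_sites(a)
        positions = [s.column for s in sites]
        L = a.length
    else:
        positions = sorted(a)
        if alignment_length is None:
            raise ValueError("alignment_length required with a position list")
        L = alignment_length
    if window > L:
        raise ValueError(f"window {window} exceeds alignment length {L}")
    mask = np.zeros(L + 1, dtype=np.int64)
    for p in positions:
        mask[p] = 1
    csum = np.cumsum(mask)
    starts = np.arange(1, L - window + 2, step)
    freqs = (csum[starts + window - 1] - csum[starts - 1]) / window
    return WindowScan(window, step, starts, freqs,
                      mean_frequency=len(positions) / L,
                      n_variable=len(positions), alignment_length=L)


@dataclass(frozen=True)
class HotspotRegion:
    start: int
    end: int
    n_sites: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def bases_per_site(self) -> float:
        return self.span / self.n_sites

    @property
    def density(self) -> float:
        return self.n_sites / self.span


def hotspot_regions(scan: WindowScan,
                    site_positions: Sequence[int],
                    threshold_quantile: float = 0.95) -> list[HotspotRegion]:
    """Merge windows above the frequency quantile into regions, ranked by
    variable-site density.  ``site_positions`` are the 1-based variable
    columns used to count sites per merged region.  The quantile rule is this
    implementation's explicit hotspot definition."""
    if len(scan.frequencies) == 0:
        return []
    cut = float(np.quantile(scan.frequencies, threshold_quantile))
    if cut <= 0:
        return []
    hot = [(int(s), int(s + scan.window_length - 1))
           for s, f in zip(scan.starts, scan.frequencies) if f > cut]
    if not hot:
        return []
    merged: list[list[int]] = [list(hot[0])]
    for s, e in hot[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    pos = sorted(site_positions)
    regions = []
    for s, e in merged:
        n = sum(1 for p in pos if s <= p <= e)
        if n:
            regions.append(HotspotRegion(s, e, n))
    return sorted(regions, key=lambda r: r.density, reverse=True)


# ---------------------------------------------------------------------------
# Microsatellites
# ---------------------------------------------------------------------------

#: minimum repeat count per motif length for a tandem array to qualify
DEFAULT_MIN_REPEATS = {1: 8, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class MicrosatelliteLocus:
    motif: str                               # canonical core repeat
    spans: dict[str, tuple[int, int]]        # per-haplotype 1-based spans
    repeat_counts: dict[str, int]
    alleles: tuple[str, ...]                 # distinct full locus strings

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


def _canonical_motif(motif: str) -> str:
    """Smallest rotation; collapses phase so TCC/CCT/CTC merge."""
    rots = [motif[i:] + motif[:i] for i in range(len(motif))]
    return min(rots)


def _is_primitive(motif: str) -> bool:
    for k in range(1, len(motif)):
        if len(motif) % k == 0 and motif == motif[:k] * (len(motif) // k):
            return False
    return True


def _scan_tandem_repeats(seq: str, motif_lengths: Iterable[int],
                         min_repeats: Mapping[int, int]
                         ) -> list[tuple[str, int, int, int]]:
    """Maximal perfect tandem repeats: (canonical_motif, start, end, count),
    1-based inclusive coordinates.  Gap characters break repeats."""
    found: list[tuple[str, int, int, int]] = []
    occupied: list[tuple[int, int]] = []
    for k in sorted(motif_lengths):
        need = min_repeats.get(k, 3)
        i = 0
        L = len(seq)
        while i + k <= L:
            motif = seq[i:i + k]
            if not _is_primitive(motif) or any(c not in "ACGT" for c in motif):
                i += 1
                continue
            j = i + k
            while j + k <= L and seq[j:j + k] == motif:
                j += k
            count = (j - i) // k
            if count >= need:
                span = (i + 1, i + count * k)
                # skip arrays already covered by a shorter-motif array
                if not any(s <= span[0] and span[1] <= e for s, e in occupied):
                    found.append((motif, span[0], span[1], count))
                    occupied.append(span)
                i = i + count * k
            else:
                i += 1
    return sorted(found, key=lambda r: r[1])


def find_microsatellites_and_alleles(a: HaplotypeAlignment,
                                     motif_lengths: Iterable[int] = range(1, 7),
                                     min_repeats: Mapping[int, int] | None = None
                                     ) -> list[MicrosatelliteLocus]:
    """Per-haplotype perfect tandem-repeat scan, merged into loci.

    Arrays from different haplotypes are merged into one locus when their
    alignment spans overlap and share the canonical motif.  A locus's alleles
    are the distinct gap-free locus strings over the merged span union, so
    both repeat-number differences and internal substitutions create alleles.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    per_hap: list[tuple[str, str, int, int, int]] = []
    for taxon, row in zip(a.taxa, a.rows):
        # coordinates on the gapped row = alignment columns
        for motif, s, e, count in _scan_tandem_repeats(row, motif_lengths, min_repeats):
            per_hap.append((taxon, motif, s, e, count))
    # merge by (canonical motif, overlapping span); report the first
    # observed phase of the repeat unit
    loci: list[dict] = []
    for taxon, motif, s, e, count in sorted(per_hap, key=lambda r: r[2]):
        canon = _canonical_motif(motif)
        merged = False
        for locus in loci:
            if locus["canon"] == canon and s <= locus["end"] and e >= locus["start"]:
                locus["start"] = min(locus["start"], s)
                locus["end"] = max(locus["end"], e)
                locus["members"][taxon] = (s, e, count)
                merged = True
                break
        if not merged:
            loci.append({"motif": motif, "canon": canon, "start": s, "end": e,
                         "members": {taxon: (s, e, count)}})
    out: list[MicrosatelliteLocus] = []
    for locus in loci:
        s, e = locus["start"], locus["end"]
        alleles = sorted({row[s - 1:e].replace(GAP, "")
                          for taxon, row in zip(a.taxa, a.rows)
                          if taxon in locus["members"]})
        out.append(MicrosatelliteLocus(
            motif=locus["motif"],
            spans={t: (m[0], m[1]) for t, m in locus["members"].items()},
            repeat_counts={t: m[2] for t, m in locus["members"].items()},
            alleles=tuple(alleles)))
    return out


# ---------------------------------------------------------------------------
# Control-region motif scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hairpin:
    stem_start: int      # 1-based start of 5' stem arm
    stem_length: int
    loop_length: int

    @property
    def end(self) -> int:
        return self.stem_start + 2 * self.stem_length + self.loop_length - 1


@dataclass(frozen=True)
class CrMotifReport:
    poly_t_runs: list[tuple[int, int]]           # 1-based inclusive spans
    hairpins: list[Hairpin]
    microsatellites: list[tuple[str, int, int, int]]


def _find_hairpins(seq: str, min_stem: int = 8,
                   min_loop: int = 3, max_loop: int = 30) -> list[Hairpin]:
    """Inverted repeats (Watson–Crick pairs only) folding into stem-loops.

    A stem pairs position p with position q = s − p for a fixed centre-sum s,
    so each hairpin is a maximal run of nested complementary pairs around one
    centre whose innermost pair encloses a loop of ``min_loop``..``max_loop``
    unpaired nucleotides and whose run length (stem) is ≥ ``min_stem``.
    """
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    n = len(seq)
    out: list[Hairpin] = []
    for s in range(2 * min_stem + min_loop - 1, 2 * n - 2 * min_stem - min_loop + 1):
        # p runs outward (decreasing); gap of pair (p, s-p) is s - 2p - 1
        p_inner = (s - min_loop - 1) // 2          # innermost allowed pair
        p_outer = max(0, s - n + 1)                # q = s-p must be < n
        run_len = 0
        run_inner = None
        for p in range(p_inner, p_outer - 1, -1):
            q = s - p
            paired = (q < n and p >= 0 and p < q and
                      comp.get(seq[p]) == seq[q])
            if paired:
                if run_len == 0:
                    run_inner = p
                run_len += 1
            if not paired or p == p_outer:
                if run_len >= min_stem:
                    loop = s - 2 * run_inner - 1
                    if min_loop <= loop <= max_loop:
                        start = run_inner - (run_len - 1)
                        out.append(Hairpin(start + 1, run_len, loop))
                run_len = 0
                run_inner = None
    return sorted(out, key=lambda h: (h.stem_start, h.loop_length))


def scan_cr_motifs(seq: str, *, min_poly_t: int = 8, min_stem: int = 8,
                   min_loop: int = 3, max_loop: int = 30,
                   min_repeats: Mapping[int, int] | None = None
                   ) -> CrMotifReport:
    """Scan a (control-region) sequence for replication/transcription motifs:
    poly-T runs, stem-loop hairpins and microsatellite arrays."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper().replace("U", "T")
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(seq):
        if seq[i] == "T":
            j = i
            while j < len(seq) and seq[j] == "T":
                j += 1
            if j - i >= min_poly_t:
                runs.append((i + 1, j))
            i = j
        else:
            i += 1
    hairpins = _find_hairpins(seq, min_stem, min_loop, max_loop)
    msats = _scan_tandem_repeats(seq, range(1, 7),
                                 min_repeats or DEFAULT_MIN_REPEATS)
    return CrMotifReport(runs, hairpins, msats)
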