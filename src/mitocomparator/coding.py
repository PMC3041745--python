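"""Invertebrate mitochondrial genetic code and CDS conventions.

Translation, start/stop-codon annotation (including the 1–2 nt truncated stop
codons completed in vivo by post-transcriptional polyadenylation), and
fourfold-degenerate third-position site classification.  The code table is
seeded from the standard invertebrate mitochondrial table (NCBI translation
table 5) but is carried around as plain data so tests can inject toy codes.

Start codons are fixed to the ATD set {ATA, ATT, ATG}: atypical initiators
are out of scope.  Mutations that create a stop codon are classified as
nonsynonymous by downstream dN/dS counting (explicit policy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable as _BioCodonTable

from .genome_model import Feature, FeatureTable, reverse_complement

__all__ = [
    "GeneticCode",
    "INVERTEBRATE_MITO",
    "CdsAnnotation",
    "translate_cds",
    "annotate_start_stop",
    "fourfold_degenerate_sites",
]

STOP = "*"
_BASES = "ACGT"


@dataclass(frozen=True)
class GeneticCode:
    """A codon->amino-acid map with declared start and stop sets."""

    code_id: str
    codons: dict[str, str]  # 64 entries; stops map to "*"
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codons) != 64:
            raise ValueError(f"code table must map 64 codons, got {len(self.codons)}")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codons.items() if aa == STOP)

    def translate(self, codon: str) -> str:
        return self.codons[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return self.codons.get(codon.upper()) == STOP

    def to_mapping(self) -> dict:
        return {"code_id": self.code_id, "codons": dict(self.codons),
                "start_codons": sorted(self.start_codons)}

    @classmethod
    def from_mapping(cls, data: dict) -> "GeneticCode":
        return cls(data["code_id"], dict(data["codons"]),
                   frozenset(data["start_codons"]))


def _build_invertebrate_mito() -> GeneticCode:
    table = _BioCodonTable.unambiguous_dna_by_id[5]
    codons = dict(table.forward_table)
    for stop in table.stop_codons:
        codons[stop] = STOP
    return GeneticCode("invertebrate_mitochondrial", codons,
                       frozenset({"ATA", "ATT", "ATG"}))


INVERTEBRATE_MITO = _build_invertebrate_mito()


class CodingError(ValueError):
    pass


def translate_cds(seq: str, code: GeneticCode = INVERTEBRATE_MITO, *,
                  truncated: bool = False,
                  allow_internal_stops: bool = False) -> str:
    """Translate an in-frame CDS; the terminal stop codon is consumed.

    A trailing 1–2 nt remainder is accepted only with ``truncated=True`` and
    is treated as an incomplete stop.  Internal stop codons raise by default
    (pseudogene guard).
    """
    seq = seq.upper().replace("U", "T")
    tail = len(seq) % 3
    if tail and not truncated:
        raise CodingError(f"CDS length {len(seq)} not divisible by 3 "
                          "(pass truncated=True for an incomplete stop)")
    aas = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i:3 * i + 3]
        try:
            aa = code.translate(codon)
        except KeyError as exc:
            raise CodingError(f"unrecognised codon {codon!r} at position {i}") from exc
        if aa == STOP:
            if i == n_codons - 1:
                return "".join(aas)  # terminal stop consumed
            if not allow_internal_stops:
                raise CodingError(f"internal stop codon {codon} at codon {i + 1}")
        aas.append(aa)
    return "".join(aas)


@dataclass(frozen=True)
class CdsAnnotation:
    gene: str
    start_codon: str
    stop_codon: str
    truncated: bool
    completed_stop_policy: str = "polyadenylation completes truncated TA/T to TAA"

    def __post_init__(self) -> None:
        assert self.truncated == (len(self.stop_codon) < 3)


def _sense_neighbours(t: FeatureTable, gene: str) -> tuple[Feature | None, Feature | None]:
    """(5'-neighbour, 3'-neighbour) of a gene in its own reading direction."""
    idx = t.names().index(gene)
    f = t.features[idx]
    before = t.features[idx - 1] if idx > 0 else None
    after = t.features[idx + 1] if idx + 1 < len(t.features) else None
    if f.strand == "H":
        return before, after
    return after, before


def annotate_start_stop(t: FeatureTable, gene: str,
                        code: GeneticCode = INVERTEBRATE_MITO,
                        search_window: int = 9) -> CdsAnnotation:
    """Identify start/stop codons of an annotated protein-coding gene.

    Start: among in-frame ATD candidates within ``search_window`` nt of the
    annotated 5' boundary, pick the one minimising overlap with the upstream
    feature; ties go to the longer reading frame (the more 5' candidate).
    Stop: a terminal TAA/TAG, else a trailing TA/T abutting the downstream
    feature, annotated as truncated.
    """
    f = t[gene]
    if f.kind != "PCG":
        raise CodingError(f"{gene} is not a protein-coding gene")
    sense = t.feature_sequence(gene)
    upstream, downstream = _sense_neighbours(t, gene)

    # --- start codon -------------------------------------------------------
    # offset is relative to the annotated 5' end, in sense-strand nt;
    # negative offsets extend the gene 5'-ward (more overlap with upstream).
    candidates: list[tuple[int, int]] = []  # (overlap_nt, offset)
    for offset in range(-search_window, search_window + 1, 3):
        if f.strand == "H":
            pos0 = f.start - 1 + offset          # 0-based on reference
            if pos0 < 0 or pos0 + 3 > t.total_length:
                continue
            codon = t.sequence[pos0:pos0 + 3]
            new_start = pos0 + 1
            overlap = 0 if upstream is None else max(0, upstream.end - new_start + 1)
        else:
            pos_end = f.end - offset             # 1-based 3'..; codon occupies [pos_end-2, pos_end] rc'd
            if pos_end > t.total_length or pos_end - 3 < 0:
                continue
            codon = reverse_complement(t.sequence[pos_end - 3:pos_end])
            overlap = 0 if upstream is None else max(0, pos_end - upstream.start + 1)
        if codon in code.start_codons:
            candidates.append((overlap, offset))
    if not candidates:
        raise CodingError(f"{gene}: no ATD start candidate within "
                          f"±{search_window} nt of the annotated boundary")
    candidates.sort(key=lambda c: (c[0], c[1]))  # min overlap, then most 5'
    start_codon = None
    best_offset = candidates[0][1]
    if f.strand == "H":
        pos0 = f.start - 1 + best_offset
        start_codon = t.sequence[pos0:pos0 + 3]
    else:
        pos_end = f.end - best_offset
        start_codon = reverse_complement(t.sequence[pos_end - 3:pos_end])

    # --- stop codon --------------------------------------------------------
    tail = len(sense) % 3
    if tail == 0 and sense[-3:] in code.stop_codons:
        return CdsAnnotation(gene, start_codon, sense[-3:], truncated=False)
    if tail:
        remnant = sense[-tail:]
        abuts = downstream is not None and (
            (f.strand == "H" and downstream.start == f.end + 1) or
            (f.strand == "L" and downstream.end == f.start - 1))
        if remnant in ("TA", "T") and abuts:
            return CdsAnnotation(gene, start_codon, remnant, truncated=True)
        raise CodingError(f"{gene}: trailing {remnant!r} is not a truncated stop "
                          "adjacent to a downstream feature")
    raise CodingError(f"{gene}: no stop or truncated stop found "
                      f"(terminal codon {sense[-3:]!r})")


def fourfold_degenerate_sites(cds: str, code: GeneticCode = INVERTEBRATE_MITO
                              ) -> tuple[list[int], dict[str, int]]:
    """Third-codon positions where all four bases are synonymous.

    Returns (0-based nucleotide positions within the CDS, base counts at
    those positions).  A site counts as fourfold degenerate only if every
    substitution keeps the amino acid — families touching a stop codon are
    excluded automatically because "*" differs from any amino acid.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise CodingError(f"CDS length {len(cds)} not divisible by 3")
    positions: list[int] = []
    counts = {b: 0 for b in _BASES}
    for i in range(len(cds) // 3):
        codon = cds[3 * i:3 * i + 3]
        if any(b not in _BASES for b in codon):
            continue
        family = {code.translate(codon[:2] + b) for b in _BASES}
        if len(family) == 1 and STOP not in family:
            pos = 3 * i + 2
            positions.append(pos)
            counts[codon[2]] += 1
    return positions, counts
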