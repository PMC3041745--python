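"""Base composition, strand skews, codon usage and AT-content correlation.

Strand compositional asymmetry is measured by the classical skew pair

    AT-skew = (A − T) / (A + T)        GC-skew = (G − C) / (G + C)

computed over unambiguous bases only.  Per-gene profiles are computed on each
gene's sense (reading) strand — light-strand genes are reverse-complemented
before counting — which is what makes anti-A skew comparable across genes
regardless of the strand encoding them.  Protein-coding genes can additionally
be partitioned into 1st+2nd versus 3rd codon positions, the 3rd being the
least constrained and quickest to accumulate skew.

A zero denominator (no A/T or no G/C bases) leaves the corresponding skew
*undefined*, reported as ``None`` — never as 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .genome_model import FeatureTable, reverse_complement

__all__ = [
    "SkewStats",
    "CodonUsageTable",
    "CorrelationResult",
    "base_composition_and_skew",
    "skew_from_percentages",
    "per_gene_skew_profiles",
    "codon_usage",
    "at_synonymous_correlation",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SkewStats:
    """Base fractions and strand skews of one sequence slice."""

    frac_a: float
    frac_c: float
    frac_g: float
    frac_t: float
    n_bases: int
    n_excluded: int = 0  # ambiguity codes / gaps left out of all denominators

    @property
    def at_content(self) -> float:
        return self.frac_a + self.frac_t

    @property
    def at_skew(self) -> float | None:
        at = self.frac_a + self.frac_t
        return None if at == 0 else (self.frac_a - self.frac_t) / at

    @property
    def gc_skew(self) -> float | None:
        gc = self.frac_g + self.frac_c
        return None if gc == 0 else (self.frac_g - self.frac_c) / gc


def base_composition_and_skew(seq: str) -> SkewStats:
    """Composition and skews of a nucleotide string (IUPAC codes tolerated)."""
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper().replace("U", "T"))
    n = sum(counts[b] for b in _BASES)
    excluded = sum(counts.values()) - n
    if n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return SkewStats(counts["A"] / n, counts["C"] / n,
                     counts["G"] / n, counts["T"] / n, n, excluded)


def skew_from_percentages(a: float, c: float, g: float, t: float) -> SkewStats:
    """Build SkewStats from pre-tabulated percentages (e.g. published values).

    Values are taken at face value (divided by 100, not renormalised):
    published compositions carry rounding error, and renormalising would
    change the printed A+T content while leaving the scale-free skews
    untouched."""
    if a + c + g + t <= 0:
        raise ValueError("percentages must sum to a positive total")
    return SkewStats(a / 100, c / 100, g / 100, t / 100, n_bases=0)


def per_gene_skew_profiles(t: FeatureTable, *, by_codon_position: bool = False
                           ) -> pd.DataFrame:
    """Sense-strand composition/skew table, one row per feature.

    With ``by_codon_position=True``, protein-coding genes get two extra rows
    partitioning the CDS into 1st+2nd and 3rd codon positions.  Truncated
    stop codons (CDS length not divisible by 3) contribute only their complete
    codons to the positional partition.
    """
    if t.sequence is None:
        raise ValueError("feature table carries no sequence")
    rows = []

    def add(feature: str, kind: str, strand: str, partition: str, seq: str) -> None:
        s = base_composition_and_skew(seq)
        rows.append({"feature": feature, "kind": kind, "strand": strand,
                     "partition": partition, "n_bases": s.n_bases,
                     "frac_a": s.frac_a, "frac_c": s.frac_c,
                     "frac_g": s.frac_g, "frac_t": s.frac_t,
                     "at_content": s.at_content,
                     "at_skew": s.at_skew, "gc_skew": s.gc_skew})

    for f in t.features:
        sense = t.feature_sequence(f.name)
        add(f.name, f.kind, f.strand, "all", sense)
        if by_codon_position and f.kind == "PCG":
            full = sense[:len(sense) - len(sense) % 3]
            pos12 = "".join(full[i] for i in range(len(full)) if i % 3 != 2)
            pos3 = full[2::3]
            add(f.name, f.kind, f.strand, "pos12", pos12)
            add(f.name, f.kind, f.strand, "pos3", pos3)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CodonUsageTable:
    """Pooled codon counts over a set of coding sequences.

    Stop codons are tallied separately (``stop_counts``) and excluded from
    the per-thousand normalisation by default, matching the usual codon-usage
    table convention where n counts sense codons only.
    """

    counts: dict[str, int]
    stop_counts: dict[str, int]
    total_codons: int

    @property
    def per_thousand(self) -> dict[str, float]:
        if self.total_codons == 0:
            return {c: 0.0 for c in self.counts}
        return {c: 1000.0 * n / self.total_codons for c, n in self.counts.items()}

    def per_thousand_rounded(self, decimals: int = 3) -> dict[str, float]:
        return {c: round(v, decimals) for c, v in self.per_thousand.items()}

    def to_frame(self) -> pd.DataFrame:
        pt = self.per_thousand
        return pd.DataFrame(
            [{"codon": c, "count": n, "per_thousand": round(pt[c], 3)}
             for c, n in sorted(self.counts.items())])


def codon_usage(cds_set: Iterable[str], *, stop_codons: frozenset[str] | None = None
                ) -> CodonUsageTable:
    """Pool codon counts over in-frame CDSs (64 DNA codons).

    Each CDS must consist of complete codons; trailing truncated stops must be
    completed or trimmed by the caller first.
    """
    from .coding import INVERTEBRATE_MITO

    if stop_codons is None:
        stop_codons = INVERTEBRATE_MITO.stop_codons
    codons = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
    counts = {c: 0 for c in codons if c not in stop_codons}
    stops = {c: 0 for c in stop_codons}
    for cds in cds_set:
        cds = cds.upper().replace("U", "T")
        if len(cds) % 3:
            raise ValueError(f"CDS length {len(cds)} not divisible by 3")
        for i in range(0, len(cds), 3):
            codon = cds[i:i + 3]
            if codon in stops:
                stops[codon] += 1
            elif codon in counts:
                counts[codon] += 1
            # codons with ambiguity codes are skipped
    total = sum(counts.values())
    return CodonUsageTable(counts, stops, total)


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    n_taxa: int
    slope: float
    intercept: float
    degenerate_fit: bool = False  # two points: fit is exact by construction


def at_synonymous_correlation(taxa: Mapping[str, tuple[float, float]] |
                              Sequence[tuple[float, float]]) -> CorrelationResult:
    """OLS of fourfold-degenerate-site A+T% on whole-genome A+T% across taxa.

    ``taxa`` supplies (overall_at, degenerate_site_at) pairs.  Two taxa are
    allowed but flagged (a line through two points explains everything).
    """
    pairs = list(taxa.values()) if isinstance(taxa, Mapping) else list(taxa)
    if len(pairs) < 2:
        raise ValueError("need at least two taxa")
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    if len(set(x)) == 1:
        raise ValueError("zero variance in overall A+T content: fit undefined")
    fit = stats.linregress(x, y)
    return CorrelationResult(r_squared=fit.rvalue ** 2, n_taxa=len(pairs),
                             slope=fit.slope, intercept=fit.intercept,
                             degenerate_fit=(len(pairs) == 2))
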