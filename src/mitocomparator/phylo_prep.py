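"""Phylogenomic dataset construction: masking, strand-bias and rate filters.

Builds concatenated amino-acid supermatrices from per-gene alignments the way
mitogenome phylogenetics pipelines do before tree inference:

* column-confidence masking — each alignment column carries a 0–9 integer
  confidence score (e.g. alignment posterior probabilities); only columns
  scoring above a threshold (default 5) are concatenated ("Original"-style
  dataset);
* strand-bias gene exclusion — genes whose nucleotide composition at
  fourfold-degenerate sites is significantly G/C-skewed in most taxa are
  dropped ("Balanced"-style dataset); the concrete rule here is a two-sided
  exact binomial test of G vs C counts per taxon, excluding a gene when
  p < alpha in more than half of the taxa;
* slow–fast moderate-rate filtering — per-site rates are estimated as the
  summed within-group parsimony-step lower bound (distinct non-gap states
  minus one, summed over user-declared groups), sites are ranked into
  quartiles and only the two internal quartiles retained, with boundary ties
  kept on the side of inclusion;
* nucleotide-composition PCA — a centred PCA on per-taxon A,C,G,T
  proportions, used to choose compositionally homogeneous taxon samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .coding import INVERTEBRATE_MITO, GeneticCode

__all__ = [
    "ConcatDataset",
    "SiteRateVector",
    "PcaResult",
    "StrandBiasDecision",
    "build_concat_dataset",
    "strand_bias_filter",
    "slowfast_filter",
    "composition_pca",
]

_GAPLIKE = set("-.?X")


@dataclass(frozen=True)
class ConcatDataset:
    """Concatenated alignment with per-gene column partitions."""

    taxa: tuple[str, ...]
    matrix: tuple[str, ...]                       # one row per taxon
    gene_partitions: dict[str, tuple[int, int]]   # 1-based inclusive ranges
    column_scores: tuple[int, ...] | None = None
    padded_taxa: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = self.n_columns
        if any(len(r) != L for r in self.matrix):
            raise ValueError("ragged concatenated matrix")
        ranges = sorted(self.gene_partitions.values())
        expect = 1
        for lo, hi in ranges:
            if lo != expect or hi < lo - 1:
                raise ValueError("partitions must tile the matrix without overlap")
            expect = hi + 1
        if ranges and expect != L + 1:
            raise ValueError("partitions do not cover the matrix")
        if self.column_scores is not None and len(self.column_scores) != L:
            raise ValueError("column_scores must cover all columns")

    @property
    def n_columns(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0

    def row(self, taxon: str) -> str:
        return self.matrix[self.taxa.index(taxon)]

    def select_columns(self, keep: Sequence[int]) -> "ConcatDataset":
        """Restrict to 0-based column indices, rebuilding partitions."""
        keep = sorted(keep)
        matrix = tuple("".join(r[i] for i in keep) for r in self.matrix)
        parts: dict[str, tuple[int, int]] = {}
        cursor = 1
        for gene, (lo, hi) in sorted(self.gene_partitions.items(),
                                     key=lambda kv: kv[1][0]):
            width = sum(1 for i in keep if lo - 1 <= i <= hi - 1)
            parts[gene] = (cursor, cursor + width - 1)
            cursor += width
        scores = (tuple(self.column_scores[i] for i in keep)
                  if self.column_scores is not None else None)
        return ConcatDataset(self.taxa, matrix, parts, scores, self.padded_taxa)


def build_concat_dataset(gene_alignments: Mapping[str, Mapping[str, str]],
                         column_scores: Mapping[str, Sequence[int] | str] | None = None,
                         score_threshold: int = 5,
                         exclude_genes: Iterable[str] = ("atp8",)
                         ) -> ConcatDataset:
    """Concatenate per-gene amino-acid alignments with confidence masking.

    ``column_scores[gene]`` is a 0–9 integer sequence (or digit string), one
    per column; columns scoring > ``score_threshold`` are retained.  Genes in
    ``exclude_genes`` (default: atp8, routinely missing from sampled taxa)
    are skipped.  Taxa missing from a gene are padded with gaps and recorded.
    """
    genes = [g for g in gene_alignments if g not in set(exclude_genes)]
    if not genes:
        raise ValueError("no genes left to concatenate")
    taxa = tuple(sorted({t for g in genes for t in gene_alignments[g]}))
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    kept_scores: list[int] = []
    cursor = 1
    padded: dict[str, list[str]] = {}
    for gene in genes:
        aln = gene_alignments[gene]
        L = len(next(iter(aln.values())))
        if any(len(s) != L for s in aln.values()):
            raise ValueError(f"{gene}: ragged alignment")
        if column_scores is not None:
            raw = column_scores[gene]
            scores = [int(c) for c in raw]
            if len(scores) != L:
                raise ValueError(f"{gene}: {len(scores)} scores for {L} columns")
            if any(not 0 <= s <= 9 for s in scores):
                raise ValueError(f"{gene}: scores must be integers 0-9")
            keep = [i for i, s in enumerate(scores) if s > score_threshold]
        else:
            scores = [9] * L
            keep = list(range(L))
        for t in taxa:
            row = aln.get(t)
            if row is None:
                padded.setdefault(gene, []).append(t)
                row = "-" * L
            pieces[t].append("".join(row[i] for i in keep))
        kept_scores += [scores[i] for i in keep]
        partitions[gene] = (cursor, cursor + len(keep) - 1)
        cursor += len(keep)
    matrix = tuple("".join(pieces[t]) for t in taxa)
    if not matrix or not matrix[0]:
        raise ValueError("masking removed every column")
    return ConcatDataset(taxa, matrix, partitions, tuple(kept_scores),
                         {g: tuple(ts) for g, ts in padded.items()})


@dataclass(frozen=True)
class StrandBiasDecision:
    gene: str
    n_taxa: int
    n_biased: int
    excluded: bool
    p_values: dict[str, float | None]
    flagged_no_degenerate_sites: bool = False


def strand_bias_filter(d: ConcatDataset,
                       nucleotide_cds: Mapping[str, Mapping[str, str]],
                       alpha: float = 0.05,
                       code: GeneticCode = INVERTEBRATE_MITO
                       ) -> tuple[ConcatDataset, list[StrandBiasDecision]]:
    """Drop genes whose fourfold-degenerate sites are G/C strand-biased.

    For each gene and taxon, G and C are counted at fourfold-degenerate third
    positions of that taxon's (ungapped) CDS and tested against a symmetric
    binomial; the gene is excluded when p < alpha in more than half of the
    taxa with testable sites.  Genes without degenerate sites are flagged and
    retained.  Returns the filtered dataset plus the full decision table.
    """
    from .coding import fourfold_degenerate_sites

    decisions: list[StrandBiasDecision] = []
    drop: list[str] = []
    for gene in d.gene_partitions:
        cds_by_taxon = nucleotide_cds.get(gene, {})
        pvals: dict[str, float | None] = {}
        n_biased = n_tested = 0
        for taxon, cds in cds_by_taxon.items():
            clean = "".join(c for c in cds.upper() if c not in _GAPLIKE)
            clean = clean[:len(clean) - len(clean) % 3]
            if not clean:
                pvals[taxon] = None
                continue
            _, counts = fourfold_degenerate_sites(clean, code)
            g, c = counts["G"], counts["C"]
            if g + c == 0:
                pvals[taxon] = None
                continue
            p = _stats.binomtest(g, g + c, 0.5).pvalue
            pvals[taxon] = p
            n_tested += 1
            if p < alpha:
                n_biased += 1
        no_sites = n_tested == 0
        excluded = (not no_sites) and n_biased * 2 > n_tested
        decisions.append(StrandBiasDecision(gene, n_tested, n_biased, excluded,
                                            pvals, flagged_no_degenerate_sites=no_sites))
        if excluded:
            drop.append(gene)
    keep_cols = [i for gene, (lo, hi) in d.gene_partitions.items()
                 if gene not in drop for i in range(lo - 1, hi)]
    filtered = d.select_columns(sorted(keep_cols))
    filtered = replace(filtered, gene_partitions={
        g: rng for g, rng in filtered.gene_partitions.items() if g not in drop})
    return filtered, decisions


@dataclass(frozen=True)
class SiteRateVector:
    rates: tuple[int, ...]
    quartile_labels: tuple[str, ...]  # "Q1".."Q4" per site

    def retained_mask(self) -> list[bool]:
        return [q in ("Q2", "Q3") for q in self.quartile_labels]


def site_rates(d: ConcatDataset, groups: Mapping[str, str]) -> tuple[int, ...]:
    """Summed within-group parsimony-step lower bound per column."""
    group_rows: dict[str, list[str]] = {}
    for taxon in d.taxa:
        g = groups.get(taxon)
        if g is None:
            raise ValueError(f"taxon {taxon!r} missing from the group map")
        group_rows.setdefault(g, []).append(d.row(taxon))
    for g, rows in group_rows.items():
        if len(rows) < 2:
            raise ValueError(f"group {g!r} has fewer than two taxa")
    rates = []
    for c in range(d.n_columns):
        r = 0
        for rows in group_rows.values():
            states = {row[c] for row in rows} - _GAPLIKE
            if states:
                r += len(states) - 1
        rates.append(r)
    return tuple(rates)


def slowfast_filter(d: ConcatDataset, groups: Mapping[str, str]
                    ) -> tuple[ConcatDataset, SiteRateVector]:
    """Retain only moderate-rate sites (internal quartiles Q2 and Q3).

    Sites are ranked by rate and split into four equal-count quartiles;
    sites tied with a boundary rate are all retained (inclusion-biased,
    deterministic).
    """
    rates = site_rates(d, groups)
    n = len(rates)
    q = n // 4
    sorted_rates = sorted(rates)
    # boundary rate values; ties at either boundary fall inside
    r_lo = sorted_rates[q] if q < n else sorted_rates[-1]
    hi_idx = max(0, -(-3 * n // 4) - 1)  # ceil(3n/4) - 1
    r_hi = sorted_rates[hi_idx]
    labels = []
    for r in rates:
        if r < r_lo:
            labels.append("Q1")
        elif r > r_hi:
            labels.append("Q4")
        elif r <= sorted_rates[max(0, (n - 1) // 2)]:
            labels.append("Q2")
        else:
            labels.append("Q3")
    vec = SiteRateVector(rates, tuple(labels))
    keep = [i for i, ok in enumerate(vec.retained_mask()) if ok]
    if not keep:
        raise ValueError("rate filter removed every column")
    return d.select_columns(keep), vec


@dataclass(frozen=True)
class PcaResult:
    loadings: np.ndarray            # components × variables
    scores: np.ndarray              # taxa × components
    variance_explained: np.ndarray  # fraction per component
    taxa: tuple[str, ...]
    degenerate: bool = False        # zero total variance


def composition_pca(taxa_compositions: Mapping[str, Sequence[float]]
                    ) -> PcaResult:
    """Centred PCA on per-taxon (A, C, G, T) proportions.

    Intended as taxon-sampling guidance: taxa far from the main cloud carry
    deviant nucleotide compositions and risk compositional attraction
    artefacts in tree inference.
    """
    from sklearn.decomposition import PCA

    taxa = tuple(sorted(taxa_compositions))
    if len(taxa) < 3:
        raise ValueError("need at least three taxa")
    X = np.array([taxa_compositions[t] for t in taxa], dtype=float)
    if X.shape[1] != 4:
        raise ValueError("compositions must have four variables (A, C, G, T)")
    if np.allclose(X.var(axis=0), 0):
        return PcaResult(np.zeros((0, 4)), np.zeros((len(taxa), 0)),
                         np.zeros(0), taxa, degenerate=True)
    k = min(len(taxa), 4)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    return PcaResult(pca.components_, scores, pca.explained_variance_ratio_, taxa)
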