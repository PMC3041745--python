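"""Pairwise/group divergence and Nei–Gojobori (NG86) dN/dS.

Divergence is the uncorrected p-distance (differences / compared positions,
gap columns excluded pairwise).  Selection is quantified by the NG86 counting
method: per-codon synonymous-site fractions averaged over both sequences,
observed differences split into synonymous and nonsynonymous by averaging
over all shortest substitution pathways between differing codons with equal
weights, and a Jukes–Cantor multiple-hit correction applied to the resulting
proportions.  omega = dN/dS, undefined (``None``) when dS = 0.

Group summaries follow the between/within design used for comparing a set of
species against a within-species haplotype sample: DW is the mean nucleotide
p-distance over within-group pairs, DB the mean between-group distance
(amino acids for protein-coding genes, nucleotides for RNA genes), and
omegaW / omegaB are NG86 estimates pooled over the corresponding pair sets.

Mutations to stop codons count as nonsynonymous, and pathways passing through
a stop codon are retained under that policy rather than discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .coding import INVERTEBRATE_MITO, GeneticCode
from .genome_model import GENE_VOCABULARY

__all__ = [
    "NGResult",
    "GroupDivergenceRow",
    "pairwise_divergence",
    "ng86",
    "group_divergence_summary",
    "omega_ratio_summary",
]

_BASES = "ACGT"
_GAPLIKE = set("-.?")


def pairwise_divergence(a: str, b: str, mode: str = "nt") -> tuple[float, int]:
    """Uncorrected p-distance between two aligned sequences.

    Returns (p, n_compared).  Columns where either sequence has a gap or an
    ambiguous/unknown residue are excluded pairwise.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    valid = set(_BASES) if mode == "nt" else set("ACDEFGHIKLMNPQRSTVWY")
    diffs = compared = 0
    for x, y in zip(a, b):
        if x not in valid or y not in valid:
            continue
        compared += 1
        diffs += x != y
    if compared == 0:
        raise ValueError("no comparable positions")
    return diffs / compared, compared


@dataclass(frozen=True)
class NGResult:
    """NG86 site and difference counts for one sequence pair."""

    N: float           # nonsynonymous sites (pair average)
    S: float           # synonymous sites
    Nd: float          # observed nonsynonymous differences
    Sd: float          # synonymous differences
    n_codons: int      # gap-free codon columns compared
    defined: bool      # False when the JC correction is out of range

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N else 0.0

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S else 0.0

    @property
    def dN(self) -> float | None:
        return _jukes_cantor(self.pN)

    @property
    def dS(self) -> float | None:
        return _jukes_cantor(self.pS)

    @property
    def omega(self) -> float | None:
        dn, ds = self.dN, self.dS
        if dn is None or ds is None or ds == 0:
            return None
        return dn / ds


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _syn_site_fraction(code: GeneticCode, codon: str) -> float:
    """Number of synonymous sites in a codon (0..3), NG86 convention."""
    aa = code.translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if code.translate(mutant) == aa:  # change to stop is nonsynonymous
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def _codon_pair_diffs(code_id: str, c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaged with equal
    weight over all shortest substitution pathways."""
    code = _CODE_REGISTRY[code_id]
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_s = total_n = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = c1
        s = n = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.translate(nxt) == code.translate(cur) and \
               not code.is_stop(nxt) and not code.is_stop(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        total_s += s
        total_n += n
        n_paths += 1
    return total_s / n_paths, total_n / n_paths


_CODE_REGISTRY: dict[str, GeneticCode] = {INVERTEBRATE_MITO.code_id: INVERTEBRATE_MITO}


def _register(code: GeneticCode) -> None:
    _CODE_REGISTRY.setdefault(code.code_id, code)


def ng86(a: str, b: str, code: GeneticCode = INVERTEBRATE_MITO) -> NGResult:
    """NG86 counting between two equal-length in-frame coding sequences.

    Codon columns containing gaps, ambiguity codes or stop codons in either
    sequence are dropped pairwise.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError(f"alignment length {len(a)} not divisible by 3")
    _register(code)
    a, b = a.upper().replace("U", "T"), b.upper().replace("U", "T")
    S_a = S_b = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(x not in _BASES for x in ca + cb):
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        n_codons += 1
        S_a += _syn_site_fraction(code, ca)
        S_b += _syn_site_fraction(code, cb)
        s, n = _codon_pair_diffs(code.code_id, ca, cb)
        Sd += s
        Nd += n
    if n_codons == 0:
        raise ValueError("no comparable codons")
    S = (S_a + S_b) / 2.0
    N = 3.0 * n_codons - S
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    defined = pS < 0.75 and pN < 0.75
    return NGResult(N=N, S=S, Nd=Nd, Sd=Sd, n_codons=n_codons, defined=defined)


def _pooled_ng86(pairs: Iterable[tuple[str, str]],
                 code: GeneticCode) -> NGResult | None:
    """NG86 with site and difference counts pooled over a set of pairs."""
    N = S = Nd = Sd = 0.0
    n_codons = 0
    any_pair = False
    for a, b in pairs:
        r = ng86(a, b, code)
        any_pair = True
        N += r.N
        S += r.S
        Nd += r.Nd
        Sd += r.Sd
        n_codons += r.n_codons
    if not any_pair:
        return None
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    return NGResult(N=N, S=S, Nd=Nd, Sd=Sd, n_codons=n_codons,
                    defined=pS < 0.75 and pN < 0.75)


@dataclass(frozen=True)
class GroupDivergenceRow:
    """Per-gene between/within divergence and selection summary."""

    gene: str
    DB: float | None          # mean between-group divergence
    omegaB: float | None      # between-group NG86 dN/dS
    DW: float | None          # mean within-group divergence
    omegaW: float | None      # within-group NG86 dN/dS
    n_between_pairs: int = 0
    n_within_pairs: int = 0


def _gene_kind(gene: str) -> str:
    return GENE_VOCABULARY.get(gene, "NCR")


def _pairs_by_side(taxa: Sequence[str], groups: Mapping[str, str]
                   ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    within, between = [], []
    for t1, t2 in combinations(taxa, 2):
        (within if groups[t1] == groups[t2] else between).append((t1, t2))
    return within, between


def group_divergence_summary(alignments: Mapping[str, Mapping[str, str]],
                             groups: Mapping[str, str],
                             code: GeneticCode = INVERTEBRATE_MITO,
                             overall_label: str = "overall"
                             ) -> list[GroupDivergenceRow]:
    """Between/within divergence table over per-gene nucleotide alignments.

    ``alignments`` maps gene -> {taxon: aligned sequence}; protein-coding
    genes must be codon alignments (length divisible by 3).  DB for
    protein-coding genes is computed on translated amino acids, DW always on
    nucleotides; omegas only exist for protein-coding genes.  A group with a
    single member yields an undefined (``None``) within-group value, and an
    ``overall`` row pools pairs across all genes.
    """
    rows: list[GroupDivergenceRow] = []
    # accumulators for the overall row
    all_within_nt: list[float] = []
    all_between_div: list[float] = []
    omega_pairs_w: list[tuple[str, str]] = []
    omega_pairs_b: list[tuple[str, str]] = []

    for gene, seqs in alignments.items():
        kind = _gene_kind(gene)
        taxa = sorted(seqs)
        within, between = _pairs_by_side(taxa, groups)

        dw_vals = [pairwise_divergence(seqs[x], seqs[y], "nt")[0]
                   for x, y in within]
        if kind == "PCG":
            # column-wise translation keeps amino acids aligned even when
            # the codon alignment carries gaps
            aa = {t: _translate_aligned(seqs[t], code) for t in taxa}
            db_vals = [pairwise_divergence(aa[x], aa[y], "aa")[0]
                       for x, y in between]
            w_cds = [(seqs[x], seqs[y]) for x, y in within]
            b_cds = [(seqs[x], seqs[y]) for x, y in between]
            ng_w = _pooled_ng86(w_cds, code) if w_cds else None
            ng_b = _pooled_ng86(b_cds, code) if b_cds else None
            omega_w = ng_w.omega if ng_w and ng_w.defined else None
            omega_b = ng_b.omega if ng_b and ng_b.defined else None
            omega_pairs_w += w_cds
            omega_pairs_b += b_cds
        else:
            db_vals = [pairwise_divergence(seqs[x], seqs[y], "nt")[0]
                       for x, y in between]
            omega_w = omega_b = None
        rows.append(GroupDivergenceRow(
            gene=gene,
            DB=sum(db_vals) / len(db_vals) if db_vals else None,
            omegaB=omega_b,
            DW=sum(dw_vals) / len(dw_vals) if dw_vals else None,
            omegaW=omega_w,
            n_between_pairs=len(between),
            n_within_pairs=len(within)))
        all_within_nt += dw_vals
        all_between_div += db_vals

    ng_w = _pooled_ng86(omega_pairs_w, code) if omega_pairs_w else None
    ng_b = _pooled_ng86(omega_pairs_b, code) if omega_pairs_b else None
    rows.append(GroupDivergenceRow(
        gene=overall_label,
        DB=sum(all_between_div) / len(all_between_div) if all_between_div else None,
        omegaB=ng_b.omega if ng_b and ng_b.defined else None,
        DW=sum(all_within_nt) / len(all_within_nt) if all_within_nt else None,
        omegaW=ng_w.omega if ng_w and ng_w.defined else None,
        n_between_pairs=sum(r.n_between_pairs for r in rows),
        n_within_pairs=sum(r.n_within_pairs for r in rows)))
    return rows


def _translate_aligned(cds: str, code: GeneticCode) -> str:
    """Codon-wise translation of an aligned CDS; gap codons become '-'."""
    out = []
    cds = cds.upper().replace("U", "T")
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        if any(b not in _BASES for b in codon):
            out.append("-")
        elif code.is_stop(codon):
            out.append("-")
        else:
            out.append(code.translate(codon))
    return "".join(out)


@dataclass(frozen=True)
class OmegaRatioSummary:
    overall_ratio: float | None
    per_gene: dict[str, float | None]


def omega_ratio_summary(rows: Sequence[GroupDivergenceRow],
                        overall_label: str = "overall") -> OmegaRatioSummary:
    """omegaW / omegaB ratios; undefined flags propagate as ``None``."""
    per_gene: dict[str, float | None] = {}
    overall = None
    for r in rows:
        ratio = None
        if r.omegaW is not None and r.omegaB not in (None, 0):
            ratio = r.omegaW / r.omegaB
        if r.gene == overall_label:
            overall = ratio
        else:
            per_gene[r.gene] = ratio
    return OmegaRatioSummary(overall_ratio=overall, per_gene=per_gene)


def rows_to_frame(rows: Sequence[GroupDivergenceRow]) -> pd.DataFrame:
    return pd.DataFrame([{"gene": r.gene, "DB": r.DB, "omegaB": r.omegaB,
                          "DW": r.DW, "omegaW": r.omegaW} for r in rows])
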