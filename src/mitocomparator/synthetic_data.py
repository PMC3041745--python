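"""Seeded synthetic-data generators with machine-readable ground truth.

Every generator is a pure function of (config, seed): identical inputs give
bit-identical outputs (the PRNG is numpy's PCG64, platform-stable).  Counts —
substitution columns, indel columns, transition/transversion split,
microsatellite repeat numbers — are *placed deterministically* to hit the
configured totals exactly, rather than drawn per site, so downstream
recovery tests can assert equality instead of statistical closeness.

The default configurations emulate the study system: a ~20 kb annotated
mitogenome contig with 35 features, 13 protein-coding genes and six long
non-coding regions; an 11-haplotype population alignment with 191
substitution columns, 104 indel columns (non-coding only) and 87%
transitions; and codon pair sets evolved at a specified dN/dS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coding import INVERTEBRATE_MITO, GeneticCode
from .genome_model import Feature, FeatureTable, reverse_complement
from .popscan import HaplotypeAlignment

__all__ = [
    "FeatureTemplate",
    "GenomeConfig",
    "MicrosatelliteSpec",
    "PopulationConfig",
    "CodonPairConfig",
    "RateClassConfig",
    "SimConfig",
    "calanus_like_template",
    "gen_annotated_genome",
    "gen_population_alignment",
    "gen_codon_pair_set",
    "gen_rate_class_alignment",
]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FeatureTemplate:
    """Shape of one feature: identity plus upstream spacer."""
    name: str
    kind: str
    strand: str
    length: int
    upstream_spacer: int  # nt between previous feature and this one
    start_codon: str | None = None
    stop_codon: str | None = None


@dataclass(frozen=True)
class GenomeConfig:
    """Annotated-genome template; defaults mirror the study contig."""
    genome_length: int = 20460
    head_spacer: int = 2243          # unannotated contig head (open LNR)
    template: tuple[FeatureTemplate, ...] = ()
    composition: tuple[float, float, float, float] = (0.321, 0.191, 0.193, 0.296)
    topology: str = "linear"


@dataclass(frozen=True)
class MicrosatelliteSpec:
    """One programmed tandem-repeat locus inside a non-coding region."""
    motif: str
    repeat_counts: tuple[int, ...]   # one per haplotype
    region_index: int = 0            # which eligible NCR span hosts the locus

    @property
    def capacity(self) -> int:
        return max(self.repeat_counts) * len(self.motif)

    @property
    def expected_alleles(self) -> int:
        return len(set(self.repeat_counts))

    @property
    def expected_gap_columns(self) -> int:
        return (max(self.repeat_counts) - min(self.repeat_counts)) * len(self.motif)


@dataclass(frozen=True)
class PopulationConfig:
    """Haplotype-sample structure; defaults mirror the 11-genome sample:
    191 substitution columns with 87% transitions, 104 indel columns
    confined to non-coding regions, and an AT microsatellite with 14-28
    repeats plus a TCC locus."""
    n_haplotypes: int = 11
    n_substitutions: int = 191
    n_indel_columns: int = 104
    transition_fraction: float = 0.87
    # three control-region loci: a TCC array, a hypervariable TA array with
    # repeat numbers 10-56 falling into seven distinct alleles, and a short
    # TA array
    microsatellites: tuple[MicrosatelliteSpec, ...] = (
        MicrosatelliteSpec("TCC", (4, 4, 5, 4, 4, 5, 4, 5, 4, 4, 4),
                           region_index=1),
        MicrosatelliteSpec("TA", (28, 10, 56, 28, 14, 33, 10, 20, 28, 47, 14),
                           region_index=1),
        MicrosatelliteSpec("TA", (15, 15, 14, 15, 15, 13, 15, 14, 15, 15, 15),
                           region_index=1),
    )

    @property
    def ts_count(self) -> int:
        return round(self.transition_fraction * self.n_substitutions)


@dataclass(frozen=True)
class CodonPairConfig:
    """Codon pair sets evolved at a target dN/dS (omega)."""
    omega: float = 0.2
    n_codons: int = 500
    target_divergence: float = 0.05   # substitutions per site before selection
    n_pairs: int = 200


@dataclass(frozen=True)
class RateClassConfig:
    """Amino-acid alignment with exactly known per-site rate classes."""
    group_sizes: tuple[int, ...] = (3, 3)
    class_rates: tuple[int, ...] = (0, 1, 2, 3)
    sites_per_class: int = 25


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    codon_pairs: CodonPairConfig = field(default_factory=CodonPairConfig)
    rate_classes: RateClassConfig = field(default_factory=RateClassConfig)


def calanus_like_template() -> GenomeConfig:
    """Genome template copying the study contig's feature shapes: 35
    features (13 PCGs, 2 rRNAs, 20 tRNAs), spacers including six long
    non-coding regions, truncated stops on nad1/nad5."""
    from .datasets import calanus_feature_table
    from .genome_model import spacer_table

    t = calanus_feature_table()
    spacers = {r.downstream: r.spacer_nt for r in spacer_table(t)
               if not r.open}
    feats = []
    prev_end = None
    for f in t.features:
        up = f.start - 1 - prev_end if prev_end is not None else 0
        feats.append(FeatureTemplate(f.name, f.kind, f.strand, f.length, up,
                                     f.start_codon, f.stop_codon))
        prev_end = f.end
    head = t.features[0].start - 1
    return GenomeConfig(genome_length=t.total_length, head_spacer=head,
                        template=tuple(feats), topology=t.topology)


def _draw_bases(rng: np.random.Generator, n: int,
                probs: Sequence[float]) -> str:
    if n <= 0:
        return ""
    idx = rng.choice(4, size=n, p=np.asarray(probs) / np.sum(probs))
    return "".join(_BASES[i] for i in idx)


def _draw_cds(rng: np.random.Generator, length: int, probs: Sequence[float],
              start_codon: str, stop_codon: str,
              code: GeneticCode) -> str:
    """Sense-strand CDS of exactly ``length`` nt: declared start codon,
    stop-free internal codons, declared (possibly truncated) stop."""
    body_len = length - 3 - len(stop_codon)
    if body_len < 0 or body_len % 3:
        raise ValueError(f"CDS template infeasible: length {length}, "
                         f"stop {stop_codon!r}")
    codons = []
    while len(codons) * 3 < body_len:
        c = _draw_bases(rng, 3, probs)
        if not code.is_stop(c):
            codons.append(c)
    return start_codon + "".join(codons) + stop_codon


def gen_annotated_genome(cfg: GenomeConfig | None = None, seed: int = 0,
                         code: GeneticCode = INVERTEBRATE_MITO) -> FeatureTable:
    """Generate an annotated genome with sequence from a feature template.

    Composition targets apply genome-wide; protein-coding genes get valid
    declared start codons, stop-free reading frames and declared
    (possibly truncated) stops.  The result passes ``validate_table``
    against its own template by construction.
    """
    if cfg is None:
        cfg = calanus_like_template()
    if not cfg.template:
        raise ValueError("empty feature template")
    rng = np.random.default_rng(seed)
    probs = cfg.composition
    seq: list[str] = [_draw_bases(rng, cfg.head_spacer, probs)]
    pos = cfg.head_spacer
    feats: list[Feature] = []
    for idx, ft in enumerate(cfg.template):
        if idx:
            # overlapping templates (negative spacers) are clipped to
            # abutting genes: the assembled sequence cannot share bases
            up = max(0, ft.upstream_spacer)
            seq.append(_draw_bases(rng, up, probs))
            pos += up
        start = pos + 1
        end = pos + ft.length
        if ft.kind == "PCG":
            sense = _draw_cds(rng, ft.length, probs, ft.start_codon or "ATG",
                              ft.stop_codon or "TAA", code)
            piece = reverse_complement(sense) if ft.strand == "L" else sense
        else:
            piece = _draw_bases(rng, ft.length, probs)
        seq.append(piece)
        pos = end
        feats.append(Feature(ft.name, ft.kind, ft.strand, start, end,
                             ft.start_codon if ft.kind == "PCG" else None,
                             ft.stop_codon if ft.kind == "PCG" else None))
    tail = cfg.genome_length - pos
    if tail < 0:
        raise ValueError("template exceeds genome length")
    seq.append(_draw_bases(rng, tail, probs))
    return FeatureTable(tuple(feats), cfg.topology, cfg.genome_length,
                        "".join(seq))


# ---------------------------------------------------------------------------
# population alignment
# ---------------------------------------------------------------------------

def _noncoding_spans(t: FeatureTable) -> list[tuple[int, int]]:
    """1-based inclusive unannotated spans (spacers, head, tail), largest
    first."""
    spans = []
    prev_end = 0
    for f in t.features:
        if f.start - prev_end > 1:
            spans.append((prev_end + 1, f.start - 1))
        prev_end = max(prev_end, f.end)
    if t.total_length > prev_end:
        spans.append((prev_end + 1, t.total_length))
    return sorted(spans, key=lambda s: s[0] - s[1])


def gen_population_alignment(cfg: PopulationConfig | None = None,
                             reference: FeatureTable | None = None,
                             seed: int = 0
                             ) -> tuple[HaplotypeAlignment, dict]:
    """Haplotype alignment with exactly configured polymorphism counts.

    Returns (alignment, truth).  The truth record lists every programmed
    substitution column (with its transition/transversion status), every
    indel column, and per-locus microsatellite bookkeeping including the gap
    columns introduced by repeat-number differences.
    """
    if cfg is None:
        cfg = PopulationConfig()
    if reference is None:
        reference = gen_annotated_genome(seed=seed)
    if reference.sequence is None:
        raise ValueError("reference carries no sequence")
    rng = np.random.default_rng(seed)
    n = cfg.n_haplotypes
    if n < 2:
        raise ValueError("need at least two haplotypes")
    L = reference.total_length
    rows = [list(reference.sequence) for _ in range(n)]

    ncr = _noncoding_spans(reference)
    if not ncr and (cfg.n_indel_columns or cfg.microsatellites):
        raise ValueError("no non-coding spans available for indels")

    # --- microsatellite loci ----------------------------------------------
    msat_truth = []
    msat_cols: set[int] = set()
    for spec in cfg.microsatellites:
        if len(spec.repeat_counts) != n:
            raise ValueError(f"locus {spec.motif}: need {n} repeat counts")
        span = ncr[spec.region_index % len(ncr)]
        cap = spec.capacity
        # place after previously used columns within the span
        free_start = span[0]
        while any(c in msat_cols for c in range(free_start, free_start + cap)):
            free_start += cap
        if free_start + cap - 1 > span[1]:
            raise ValueError(f"locus {spec.motif} does not fit in region {span}")
        for h in range(n):
            allele = spec.motif * spec.repeat_counts[h]
            padded = allele + "-" * (cap - len(allele))
            rows[h][free_start - 1:free_start - 1 + cap] = list(padded)
        cols = set(range(free_start, free_start + cap))
        # break the motif at both flanks in every haplotype so the arrays
        # cannot extend into (or merge with) flanking sequence
        left, right = free_start - 1, free_start + cap
        if left >= 1:
            b = next(x for x in "GCAT" if x != spec.motif[-1])
            for h in range(n):
                rows[h][left - 1] = b
            cols.add(left)
        if right <= L:
            b = next(x for x in "GCAT" if x != spec.motif[0])
            for h in range(n):
                rows[h][right - 1] = b
            cols.add(right)
        msat_cols |= cols
        msat_truth.append({
            "motif": spec.motif, "start": free_start,
            "end": free_start + cap - 1,
            "repeat_counts": list(spec.repeat_counts),
            "n_alleles": spec.expected_alleles,
            "gap_columns": spec.expected_gap_columns,
        })

    # --- indel columns (non-coding only) -----------------------------------
    ncr_columns = [c for s, e in ncr for c in range(s, e + 1)
                   if c not in msat_cols]
    if cfg.n_indel_columns > len(ncr_columns):
        raise ValueError("not enough non-coding columns for the requested indels")
    indel_cols = sorted(rng.choice(len(ncr_columns), size=cfg.n_indel_columns,
                                   replace=False))
    indel_cols = [ncr_columns[i] for i in indel_cols]
    for c in indel_cols:
        k = int(rng.integers(1, n))           # 1..n-1 haplotypes get the gap
        carriers = rng.choice(n - 1, size=k, replace=False) + 1  # never the ref
        for h in carriers:
            rows[h][c - 1] = "-"

    # --- substitution columns ----------------------------------------------
    used = msat_cols | set(indel_cols)
    candidates = np.array([c for c in range(1, L + 1) if c not in used])
    if cfg.n_substitutions > len(candidates):
        raise ValueError("not enough columns for the requested substitutions")
    picked = rng.choice(len(candidates), size=cfg.n_substitutions, replace=False)
    sub_cols = [int(candidates[i]) for i in picked]
    ts_count = cfg.ts_count
    sub_truth = []
    for rank, c in enumerate(sub_cols):
        ref_base = rows[0][c - 1]
        is_ts = rank < ts_count
        if is_ts:
            alt = _TRANSITION[ref_base]
        else:
            alt = _TRANSVERSIONS[ref_base][int(rng.integers(2))]
        k = int(rng.integers(1, n))
        carriers = rng.choice(n - 1, size=k, replace=False) + 1
        for h in carriers:
            rows[h][c - 1] = alt
        sub_truth.append({"column": c, "ref": ref_base, "alt": alt,
                          "transition": bool(is_ts),
                          "n_carriers": int(k)})

    taxa = tuple(["ref"] + [f"hap{i:02d}" for i in range(1, n)])
    aln = HaplotypeAlignment(taxa, tuple("".join(r) for r in rows),
                             annotation=reference)
    truth = {
        "n_haplotypes": n,
        "substitution_columns": sorted(s["column"] for s in sub_truth),
        "substitutions": sorted(sub_truth, key=lambda s: s["column"]),
        "n_substitutions": cfg.n_substitutions,
        "ts_count": ts_count,
        "tv_count": cfg.n_substitutions - ts_count,
        "indel_columns": sorted(indel_cols),
        "n_indel_columns": cfg.n_indel_columns,
        "microsatellites": msat_truth,
        "msat_gap_columns": sum(m["gap_columns"] for m in msat_truth),
    }
    return aln, truth


# ---------------------------------------------------------------------------
# codon pairs under a target omega
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int,
                code: GeneticCode) -> list[str]:
    codons = []
    while len(codons) < n_codons:
        c = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if not code.is_stop(c):
            codons.append(c)
    return codons


def gen_codon_pair_set(cfg: CodonPairConfig | None = None, seed: int = 0,
                       code: GeneticCode = INVERTEBRATE_MITO
                       ) -> tuple[list[tuple[str, str]], dict]:
    """Pairs of in-frame CDSs whose substitutions were accepted/rejected so
    the realised nonsynonymous:synonymous rate ratio targets omega.

    Proposal: uniform single-base changes (stop-creating changes rejected);
    acceptance: synonymous changes accepted with probability min(1, 1/omega),
    nonsynonymous with min(1, omega).  Multiple hits per codon are allowed.
    Returns (pairs, truth) where truth logs per-pair accepted synonymous and
    nonsynonymous substitution events.
    """
    if cfg is None:
        cfg = CodonPairConfig()
    if cfg.omega < 0:
        raise ValueError("omega must be non-negative")
    rng = np.random.default_rng(seed)
    n_mut = max(1, round(cfg.target_divergence * 3 * cfg.n_codons))
    p_syn = min(1.0, 1.0 / cfg.omega) if cfg.omega > 0 else 1.0
    p_non = min(1.0, cfg.omega)
    pairs: list[tuple[str, str]] = []
    log = []
    for _ in range(cfg.n_pairs):
        anc = _random_cds(rng, cfg.n_codons, code)
        der = list(anc)
        syn = non = 0
        guard = 0
        while syn + non < n_mut:
            guard += 1
            if guard > 200000:
                raise RuntimeError("infeasible omega target: no accepted changes")
            i = int(rng.integers(cfg.n_codons))
            pos = int(rng.integers(3))
            new = _BASES[int(rng.integers(4))]
            codon = der[i]
            if new == codon[pos]:
                continue
            mutant = codon[:pos] + new + codon[pos + 1:]
            if code.is_stop(mutant):
                continue
            synonymous = code.translate(mutant) == code.translate(codon)
            p = p_syn if synonymous else p_non
            if p < 1.0 and rng.random() >= p:
                continue
            der[i] = mutant
            if synonymous:
                syn += 1
            else:
                non += 1
        pairs.append(("".join(anc), "".join(der)))
        log.append({"syn_events": syn, "nonsyn_events": non})
    truth = {"omega_target": cfg.omega, "n_mutations_per_pair": n_mut,
             "pairs": log}
    return pairs, truth


# ---------------------------------------------------------------------------
# rate-class alignment for the slow-fast filter
# ---------------------------------------------------------------------------

def gen_rate_class_alignment(cfg: RateClassConfig | None = None, seed: int = 0
                             ) -> tuple[dict[str, str], dict[str, str], dict]:
    """Amino-acid alignment whose per-site summed within-group state counts
    are programmed exactly.

    Returns (alignment, groups, truth): ``alignment`` maps taxon -> row,
    ``groups`` maps taxon -> group label, and ``truth`` carries the per-site
    rate class.  A site of rate r distributes r extra states over the groups
    round-robin, so the slow-fast rate estimator recovers r exactly.
    """
    if cfg is None:
        cfg = RateClassConfig()
    if len(cfg.group_sizes) < 2 or any(s < 2 for s in cfg.group_sizes):
        raise ValueError("need >=2 groups with >=2 taxa each")
    max_steps = sum(s - 1 for s in cfg.group_sizes)
    if max(cfg.class_rates) > max_steps:
        raise ValueError("a rate class exceeds the achievable parsimony steps")
    rng = np.random.default_rng(seed)
    taxa: list[str] = []
    groups: dict[str, str] = {}
    for gi, size in enumerate(cfg.group_sizes):
        label = f"G{gi + 1}"
        for m in range(size):
            t = f"{label}_t{m + 1}"
            taxa.append(t)
            groups[t] = label
    columns: list[str] = []
    site_classes: list[int] = []
    for rate in cfg.class_rates:
        for _ in range(cfg.sites_per_class):
            base = _AA20[int(rng.integers(len(_AA20)))]
            col = {t: base for t in taxa}
            # hand out `rate` extra states, cycling over groups
            steps_per_group = [0] * len(cfg.group_sizes)
            gi = 0
            for _ in range(rate):
                while steps_per_group[gi] >= cfg.group_sizes[gi] - 1:
                    gi = (gi + 1) % len(cfg.group_sizes)
                steps_per_group[gi] += 1
                member = steps_per_group[gi]  # 1-based member index
                label = f"G{gi + 1}"
                variant = _AA20[(_AA20.index(base) + member) % len(_AA20)]
                col[f"{label}_t{member + 1}"] = variant
                gi = (gi + 1) % len(cfg.group_sizes)
            columns.append("".join(col[t] for t in taxa))
            site_classes.append(rate)
    order = rng.permutation(len(columns))
    matrix = {t: "".join(columns[i][j] for i in order)
              for j, t in enumerate(taxa)}
    truth = {"site_classes": [site_classes[i] for i in order],
             "class_rates": list(cfg.class_rates)}
    return matrix, groups, truth
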