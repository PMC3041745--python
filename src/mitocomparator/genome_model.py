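"""Annotated mitogenome feature tables and coordinate arithmetic.

The central container is :class:`FeatureTable`: an ordered list of annotated
features (protein-coding genes, tRNAs, rRNAs, named non-coding regions) on a
linear or circular molecule, with 1-based inclusive coordinates on the
reference (heavy, H) strand.  All downstream stages — composition profiling,
divergence, gene-order comparison, the polymorphism scan — consume this model.

Coordinates stay 1-based inclusive internally; conversion to other conventions
happens only at I/O boundaries.  Spacer arithmetic follows
``spacer = start(next) − end(prev) − 1``, negative values marking gene
overlaps.  Long non-coding regions (LNRs) are spacers exceeding a configurable
threshold (default 100 nt, the conventional cut-off for "large" mitochondrial
intergenic regions) and are labelled in genome order.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Feature",
    "FeatureTable",
    "SpacerRecord",
    "ValidationIssue",
    "KINDS",
    "GENE_VOCABULARY",
    "parse_feature_table",
    "parse_feature_table_tsv",
    "parse_feature_table_genbank",
    "write_feature_table",
    "spacer_table",
    "coding_length_summary",
    "validate_table",
]

KINDS = ("PCG", "tRNA", "rRNA", "NCR")

_AA_LETTERS = "ACDEFGHIKMNPQRSTVWY"  # L and S appear only as L1/L2, S1/S2

#: Controlled gene-name vocabulary.  tRNA-Leu and tRNA-Ser are disambiguated
#: by codon family: trnL1 = CUN, trnL2 = UUR, trnS1 = AGN, trnS2 = UCN.
GENE_VOCABULARY: dict[str, str] = {}
for _g in ("cox1", "cox2", "cox3", "nad1", "nad2", "nad3", "nad4", "nad4L",
           "nad5", "nad6", "atp6", "atp8", "cytb"):
    GENE_VOCABULARY[_g] = "PCG"
for _g in ("rrnS", "rrnL"):
    GENE_VOCABULARY[_g] = "rRNA"
for _x in _AA_LETTERS:
    GENE_VOCABULARY[f"trn{_x}"] = "tRNA"
for _x in ("L1", "L2", "S1", "S2"):
    GENE_VOCABULARY[f"trn{_x}"] = "tRNA"

_NCR_NAME = re.compile(r"^(NCR|LNR|CR)[\w.-]*$")


class FeatureTableError(ValueError):
    """Malformed feature-table input."""


def _check_name(name: str, kind: str) -> None:
    if kind == "NCR":
        if not _NCR_NAME.match(name):
            raise FeatureTableError(f"invalid non-coding region label {name!r}")
        return
    expected = GENE_VOCABULARY.get(name)
    if expected is None:
        raise FeatureTableError(f"unknown gene name {name!r}")
    if expected != kind:
        raise FeatureTableError(
            f"gene {name!r} declared as {kind}, vocabulary says {expected}")


@dataclass(frozen=True)
class Feature:
    """One annotated feature on the reference strand.

    ``start``/``end`` are 1-based inclusive; ``end >= start`` always (features
    spanning a circular origin are not represented as single rows).  ``strand``
    is 'H' (heavy) or 'L' (light); '+'/'-' are normalised on input.
    """

    name: str
    kind: str
    strand: str
    start: int
    end: int
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise FeatureTableError(f"unknown feature kind {self.kind!r}")
        _check_name(self.name, self.kind)
        strand = {"+": "H", "-": "L"}.get(self.strand, self.strand)
        object.__setattr__(self, "strand", strand)
        if strand not in ("H", "L"):
            raise FeatureTableError(f"strand must be H or L, got {self.strand!r}")
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise FeatureTableError("coordinates must be integers")
        if self.start < 1:
            raise FeatureTableError(f"{self.name}: start {self.start} < 1")
        if self.end < self.start:
            raise FeatureTableError(
                f"{self.name}: end {self.end} < start {self.start}")
        if self.kind == "PCG":
            if self.start_codon is not None and len(self.start_codon) != 3:
                raise FeatureTableError(f"{self.name}: start codon must be a 3-mer")
            if self.stop_codon is not None and not 1 <= len(self.stop_codon) <= 3:
                raise FeatureTableError(
                    f"{self.name}: stop codon must be 1-3 nt (truncated allowed)")
        elif self.start_codon or self.stop_codon:
            raise FeatureTableError(
                f"{self.name}: only protein-coding genes carry start/stop codons")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FeatureTable:
    """Ordered features of one mitogenome (linear contig or circle)."""

    features: tuple[Feature, ...]
    topology: str  # "linear" | "circular"
    total_length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        if self.topology not in ("linear", "circular"):
            raise FeatureTableError(f"topology must be linear/circular, got {self.topology!r}")
        if self.total_length < 1:
            raise FeatureTableError("total_length must be positive")
        seen: set[str] = set()
        prev_start = 0
        for f in self.features:
            if f.name in seen:
                raise FeatureTableError(f"duplicate feature name {f.name!r}")
            seen.add(f.name)
            if f.end > self.total_length:
                raise FeatureTableError(
                    f"{f.name}: end {f.end} beyond total length {self.total_length}")
            if f.start <= prev_start:
                raise FeatureTableError(
                    f"{f.name}: features must be strictly ordered by start")
            prev_start = f.start
        if self.sequence is not None:
            seq = self.sequence.upper()
            object.__setattr__(self, "sequence", seq)
            if len(seq) != self.total_length:
                raise FeatureTableError(
                    f"sequence length {len(seq)} != total_length {self.total_length}")

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def feature_sequence(self, name: str) -> str:
        """Sense-strand (reading-direction) sequence of a feature."""
        if self.sequence is None:
            raise FeatureTableError("feature table carries no sequence")
        f = self[name]
        s = self.sequence[f.start - 1:f.end]
        return reverse_complement(s) if f.strand == "L" else s

    def with_sequence(self, sequence: str) -> "FeatureTable":
        return replace(self, sequence=sequence)


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpacerRecord:
    """Intergenic spacer between two consecutive features.

    ``spacer_nt`` is negative for overlapping genes.  On a linear table the
    wrap-around record (last feature back to the first) is flagged ``open``:
    its length is the sum of the unannotated contig head and tail and must not
    be read as a plain internal spacer.
    """

    upstream: str
    downstream: str
    spacer_nt: int
    open: bool = False
    lnr_label: str | None = None

    @property
    def is_overlap(self) -> bool:
        return self.spacer_nt < 0


def spacer_table(t: FeatureTable, lnr_threshold: int = 100) -> list[SpacerRecord]:
    """Spacer/overlap records for every consecutive feature pair.

    Includes the wrap pair (circular: a plain record; linear: an ``open``
    record covering head + tail).  Records whose spacer exceeds
    ``lnr_threshold`` are labelled LNR1, LNR2, ... in genome order, the wrap
    region ordering at the genome head.
    """
    fs = t.features
    if len(fs) < 2:
        return []
    records: list[SpacerRecord] = []
    # region start position used only to order LNR labels along the genome
    positions: list[int] = []
    for prev, nxt in zip(fs, fs[1:]):
        records.append(SpacerRecord(prev.name, nxt.name,
                                    nxt.start - prev.end - 1))
        positions.append(prev.end + 1)
    head = fs[0].start - 1
    tail = t.total_length - fs[-1].end
    records.append(SpacerRecord(fs[-1].name, fs[0].name, head + tail,
                                open=(t.topology == "linear")))
    positions.append(1 if head > 0 else fs[-1].end + 1)
    order = sorted(range(len(records)), key=lambda i: positions[i])
    label = 0
    labelled = list(records)
    for i in order:
        if records[i].spacer_nt > lnr_threshold:
            label += 1
            labelled[i] = replace(records[i], lnr_label=f"LNR{label}")
    return labelled


@dataclass
class KindSummary:
    kind: str
    count: int
    total_nt: int
    lengths: dict[str, int] = field(default_factory=dict)


def coding_length_summary(t: FeatureTable) -> dict[str, KindSummary]:
    """Per-kind feature counts and summed lengths (end − start + 1)."""
    out = {k: KindSummary(k, 0, 0) for k in KINDS}
    for f in t.features:
        s = out[f.kind]
        s.count += 1
        s.total_nt += f.length
        s.lengths[f.name] = f.length
    return out


@dataclass(frozen=True)
class ValidationIssue:
    row: str
    field: str
    declared: object
    computed: object

    def __str__(self) -> str:
        return (f"{self.row}: declared {self.field} {self.declared!r} "
                f"!= computed {self.computed!r}")


def validate_table(t: FeatureTable,
                   declared: Mapping[str, Mapping[str, object]] | None = None,
                   lnr_threshold: int = 100) -> list[ValidationIssue]:
    """Audit a table against independently declared lengths and spacers.

    ``declared`` maps feature name -> {"length": int, "intergenic": int}
    where "intergenic" is the spacer immediately upstream of the feature.
    Everything is reported, nothing raises: an empty list means the table is
    fully consistent with its declarations.
    """
    issues: list[ValidationIssue] = []
    for f in t.features:
        if f.end > t.total_length or f.start < 1:
            issues.append(ValidationIssue(f.name, "coordinates",
                                          (f.start, f.end),
                                          f"within [1, {t.total_length}]"))
    if not declared:
        return issues
    spacers = {r.downstream: r for r in spacer_table(t, lnr_threshold)}
    for name, claims in declared.items():
        try:
            f = t[name]
        except KeyError:
            issues.append(ValidationIssue(name, "presence", "declared", "absent"))
            continue
        if "length" in claims and claims["length"] != f.length:
            issues.append(ValidationIssue(name, "length", claims["length"], f.length))
        if "intergenic" in claims:
            rec = spacers.get(name)
            computed = None if rec is None else rec.spacer_nt
            if rec is not None and rec.open:
                computed = f"open:{rec.spacer_nt}"
            if str(claims["intergenic"]) != str(computed):
                issues.append(ValidationIssue(name, "intergenic",
                                              claims["intergenic"], computed))
    return issues


# ---------------------------------------------------------------------------
# I/O: TSV dialect and GenBank flat files
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["name", "kind", "strand", "start", "end", "start_codon", "stop_codon"]


def parse_feature_table_tsv(source: str | Path | io.TextIOBase) -> FeatureTable:
    """Read the tab-separated feature-table dialect.

    Two header directives are required before the column header::

        # topology: linear|circular
        # total_length: <nt>
        name  kind  strand  start  end  start_codon  stop_codon

    '.' or an empty field means "no codon".  Other '#' lines are comments.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    topology = None
    total_length = None
    rows: list[Feature] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(topology|total_length)\s*:\s*(\S+)", line)
            if m:
                if m.group(1) == "topology":
                    topology = m.group(2)
                else:
                    total_length = int(m.group(2))
            continue
        parts = line.split("\t")
        if not header_seen:
            if [p.strip() for p in parts] != _TSV_COLUMNS:
                raise FeatureTableError(
                    f"line {lineno}: expected header {' '.join(_TSV_COLUMNS)}")
            header_seen = True
            continue
        if len(parts) != len(_TSV_COLUMNS):
            raise FeatureTableError(f"line {lineno}: expected "
                                    f"{len(_TSV_COLUMNS)} columns, got {len(parts)}")
        name, kind, strand, start, end, sc, tc = (p.strip() for p in parts)
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise FeatureTableError(f"line {lineno}: malformed coordinates") from exc
        rows.append(Feature(name, kind, strand, start_i, end_i,
                            None if sc in (".", "") else sc,
                            None if tc in (".", "") else tc))
    if topology is None or total_length is None:
        raise FeatureTableError("missing '# topology:' or '# total_length:' directive")
    return FeatureTable(tuple(rows), topology, total_length)


def write_feature_table(t: FeatureTable, path: str | Path | None = None) -> str:
    """Serialise to the TSV dialect; inverse of :func:`parse_feature_table_tsv`."""
    lines = [f"# topology: {t.topology}",
             f"# total_length: {t.total_length}",
             "\t".join(_TSV_COLUMNS)]
    for f in t.features:
        lines.append("\t".join([f.name, f.kind, f.strand, str(f.start), str(f.end),
                                f.start_codon or ".", f.stop_codon or "."]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


_GB_KIND = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
            "misc_feature": "NCR", "D-loop": "NCR"}


def parse_feature_table_genbank(source: str | Path) -> FeatureTable:
    """Read an annotated GenBank flat file (CDS/tRNA/rRNA features).

    LOCUS topology is honoured; gene names are taken from ``gene`` qualifiers
    and must match the controlled vocabulary.  Start/stop codons of CDS
    features are derived from the record sequence when present.
    """
    from Bio import SeqIO

    record = SeqIO.read(str(source), "genbank")
    topology = record.annotations.get("topology", "linear")
    seq = str(record.seq).upper() if len(record.seq) else None
    feats: list[Feature] = []
    for gf in record.features:
        kind = _GB_KIND.get(gf.type)
        if kind is None:
            continue
        quals = gf.qualifiers
        name = (quals.get("gene") or quals.get("label") or quals.get("product") or [None])[0]
        if name is None:
            raise FeatureTableError(f"{gf.type} feature without a gene qualifier")
        start = int(gf.location.start) + 1  # Biopython is 0-based half-open
        end = int(gf.location.end)
        strand = "L" if gf.location.strand == -1 else "H"
        sc = tc = None
        if kind == "PCG" and seq is not None:
            sense = seq[start - 1:end]
            if strand == "L":
                sense = reverse_complement(sense)
            sc = sense[:3]
            tail = len(sense) % 3 or 3
            tc = sense[-tail:]
        feats.append(Feature(name, kind, strand, start, end, sc, tc))
    feats.sort(key=lambda f: f.start)
    return FeatureTable(tuple(feats), topology, len(record.seq), seq)


def parse_feature_table(source: str | Path) -> FeatureTable:
    """Dispatch on file content: GenBank flat file or the TSV dialect."""
    path = Path(source)
    head = path.read_text()[:2048]
    if head.lstrip().startswith("LOCUS"):
        return parse_feature_table_genbank(path)
    return parse_feature_table_tsv(path)
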