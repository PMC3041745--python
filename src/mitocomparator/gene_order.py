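"""Signed gene orders: adjacency retention, inversions, common intervals.

A mitochondrial gene arrangement is modelled as a circular (or linear)
permutation of oriented genes.  Three comparisons are provided:

* adjacency retention — which unordered neighbouring gene pairs survive
  between an arrangement and a reference ground pattern;
* strand-inversion census — which genes changed transcriptional polarity,
  after anchoring both arrangements on a common gene and orientation;
* common intervals — the number of gene sets of size 2..n−1 that are
  contiguous (in any internal order, orientations ignored) in both
  arrangements; a synteny-conservation measure that drops to 0 for heavily
  reshuffled genomes.

Common intervals are counted on orders linearised at a shared anchor gene
(cox1, oriented forward, by default).  The straightforward O(n^2) window scan
is used: mitogenome orders have at most a few dozen genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .genome_model import FeatureTable

__all__ = [
    "SignedGeneOrder",
    "OrderComparison",
    "CommonIntervalResult",
    "order_from_features",
    "compare_to_ground_pattern",
    "common_intervals",
    "parse_gene_orders",
    "read_gene_orders",
    "write_gene_orders",
    "builtin_orders",
    "arthropod_ground_pattern",
]


@dataclass(frozen=True)
class SignedGeneOrder:
    """Cyclic sequence of (gene, orientation) pairs; orientation is '+'/'-'."""

    genes: tuple[tuple[str, str], ...]
    topology: str = "circular"
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple((g, s) for g, s in self.genes))
        names = [g for g, _ in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique within an order")
        for _, s in self.genes:
            if s not in ("+", "-"):
                raise ValueError(f"orientation must be +/-, got {s!r}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def names(self) -> list[str]:
        return [g for g, _ in self.genes]

    def orientation(self, gene: str) -> str:
        for g, s in self.genes:
            if g == gene:
                return s
        raise KeyError(gene)

    def restrict(self, keep: Iterable[str]) -> "SignedGeneOrder":
        keep = set(keep)
        return replace(self, genes=tuple((g, s) for g, s in self.genes if g in keep))

    def reversed(self) -> "SignedGeneOrder":
        flip = {"+": "-", "-": "+"}
        return replace(self, genes=tuple((g, flip[s]) for g, s in reversed(self.genes)))

    def linearised(self, anchor: str, orientation: str = "+") -> "SignedGeneOrder":
        """Rotate (and if needed reflect) so ``anchor`` comes first with the
        requested orientation.  Reflection is only available on circles."""
        order = self
        if order.orientation(anchor) != orientation:
            order = order.reversed()
        idx = order.names().index(anchor)
        if idx and order.topology == "linear":
            raise ValueError("cannot rotate a linear order to a new anchor")
        genes = order.genes[idx:] + order.genes[:idx]
        return SignedGeneOrder(genes, "linear", order.name)

    def adjacencies(self) -> set[frozenset[str]]:
        """Unordered neighbouring pairs (wrap pair included on circles)."""
        names = self.names()
        pairs = [frozenset({a, b}) for a, b in zip(names, names[1:])]
        if self.topology == "circular" and len(names) > 2:
            pairs.append(frozenset({names[-1], names[0]}))
        return {p for p in pairs if len(p) == 2}


def order_from_features(t: FeatureTable,
                        include: Iterable[str] | None = None) -> SignedGeneOrder:
    """Extract the signed gene order of a feature table, genomic order,
    '+' for H-strand genes.  ``include`` filters by kind, e.g. {"PCG", "rRNA"}
    to drop tRNAs and non-coding regions for order comparisons."""
    kinds = set(include) if include is not None else None
    genes = tuple((f.name, "+" if f.strand == "H" else "-")
                  for f in t.features if kinds is None or f.kind in kinds)
    if not genes:
        raise ValueError("feature filter selected no genes")
    return SignedGeneOrder(genes, "circular" if t.topology == "circular" else "linear")


@dataclass(frozen=True)
class OrderComparison:
    retained_adjacencies: list[frozenset[str]]
    retained_count: int
    inverted_genes: list[str]
    inverted_fraction: float
    common_interval_count: int
    shared_genes: int
    only_in_first: list[str]
    only_in_second: list[str]


@dataclass(frozen=True)
class CommonIntervalResult:
    count: int
    intervals: list[frozenset[str]]


def common_intervals(p: SignedGeneOrder, q: SignedGeneOrder,
                     anchor: str | None = None) -> CommonIntervalResult:
    """Unsigned common intervals of size 2..n−1 between two orders over the
    same gene set.  Circular orders are linearised at ``anchor`` (default:
    cox1 if present, else the first gene of ``p``); intervals spanning the
    linearisation cut are not counted, matching a cut-then-compare workflow.
    """
    if set(p.names()) != set(q.names()):
        raise ValueError("gene sets differ; restrict to the intersection first")
    n = len(p)
    if n < 3:
        return CommonIntervalResult(0, [])
    if anchor is None:
        anchor = "cox1" if "cox1" in p.names() else p.names()[0]
    pl = p.linearised(anchor) if p.topology == "circular" else p
    ql = q.linearised(anchor) if q.topology == "circular" else q
    pos = {g: i for i, g in enumerate(ql.names())}
    seq = [pos[g] for g in pl.names()]
    intervals: list[frozenset[str]] = []
    names = pl.names()
    for i in range(n - 1):
        lo = hi = seq[i]
        for j in range(i + 1, n):
            lo = min(lo, seq[j])
            hi = max(hi, seq[j])
            k = j - i + 1
            if k == n:
                continue  # the full set is a trivial interval
            if hi - lo == j - i:
                intervals.append(frozenset(names[i:j + 1]))
    return CommonIntervalResult(len(intervals), intervals)


def compare_to_ground_pattern(o: SignedGeneOrder, ref: SignedGeneOrder,
                              anchor: str | None = None) -> OrderComparison:
    """Compare an arrangement against a reference ground pattern.

    Both orders are restricted to their shared gene set; adjacencies are
    compared as unordered pairs on the circle, inversions after anchoring
    both orders on the same gene with the same orientation.
    """
    shared = set(o.names()) & set(ref.names())
    if not shared:
        raise ValueError("no shared genes to compare")
    only_o = [g for g in o.names() if g not in shared]
    only_r = [g for g in ref.names() if g not in shared]
    ro = o.restrict(shared)
    rr = ref.restrict(shared)
    retained = sorted(ro.adjacencies() & rr.adjacencies(),
                      key=lambda p: sorted(p))
    if anchor is None:
        anchor = "cox1" if "cox1" in shared else sorted(shared)[0]
    lo = ro.linearised(anchor) if ro.topology == "circular" else (
        ro if ro.orientation(anchor) == "+" else ro.reversed())
    lr = rr.linearised(anchor) if rr.topology == "circular" else (
        rr if rr.orientation(anchor) == "+" else rr.reversed())
    inverted = sorted(g for g in shared if lo.orientation(g) != lr.orientation(g))
    ci = common_intervals(ro, rr, anchor=anchor)
    return OrderComparison(
        retained_adjacencies=retained,
        retained_count=len(retained),
        inverted_genes=inverted,
        inverted_fraction=len(inverted) / len(shared),
        common_interval_count=ci.count,
        shared_genes=len(shared),
        only_in_first=only_o,
        only_in_second=only_r)


# ---------------------------------------------------------------------------
# gene-order text format: "name: gene1 -gene2 gene3 ..."
# ---------------------------------------------------------------------------

def parse_gene_orders(text: str, topology: str = "circular"
                      ) -> dict[str, SignedGeneOrder]:
    orders: dict[str, SignedGeneOrder] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, body = line.partition(":")
        if not body:
            raise ValueError(f"malformed gene-order line: {line!r}")
        genes = []
        for tok in body.split():
            if tok.startswith("-"):
                genes.append((tok[1:], "-"))
            else:
                genes.append((tok, "+"))
        orders[name.strip()] = SignedGeneOrder(tuple(genes), topology, name.strip())
    return orders


def read_gene_orders(path: str | Path, topology: str = "circular"
                     ) -> dict[str, SignedGeneOrder]:
    return parse_gene_orders(Path(path).read_text(), topology)


def write_gene_orders(orders: Iterable[SignedGeneOrder],
                      path: str | Path | None = None) -> str:
    lines = []
    for o in orders:
        body = " ".join(g if s == "+" else f"-{g}" for g, s in o.genes)
        lines.append(f"{o.name or 'order'}: {body}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def builtin_orders() -> dict[str, SignedGeneOrder]:
    """Gene orders shipped with the package (arthropod ground pattern)."""
    data = resources.files("mitocomparator.data").joinpath("gene_orders.txt")
    return parse_gene_orders(data.read_text())


def arthropod_ground_pattern(include_trna: bool = True) -> SignedGeneOrder:
    """The putative ancestral arthropod arrangement, with or without tRNAs."""
    key = "arthropod_ground" if include_trna else "arthropod_ground_major"
    return builtin_orders()[key]
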