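"""Packaged reference data: printed annotation, divergence and gene orders.

These loaders expose the published summary data used throughout the test and
acceptance suites: the annotated feature table of the *Calanus sinicus*
mitogenome contig, its per-row declared lengths/spacers/composition, the
per-gene between/within divergence table, and named gene orders including
the putative arthropod ground pattern.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .genome_model import FeatureTable, parse_feature_table_tsv

__all__ = [
    "calanus_feature_table",
    "calanus_declared_table",
    "copepod_divergence_table",
    "calanus_gene_order",
]


def _data(name: str) -> str:
    return resources.files("mitocomparator.data").joinpath(name).read_text()


def calanus_feature_table() -> FeatureTable:
    """The 35-feature annotated *C. sinicus* mitogenome contig (20,460 nt,
    linear: the molecule is circular but was not sequenced through LNR1)."""
    return parse_feature_table_tsv(io.StringIO(_data("calanus_sinicus_mito.tsv")))


def calanus_declared_table() -> pd.DataFrame:
    """Published per-row declared values (length, upstream intergenic spacer,
    LNR label, AT%, skews) for auditing against computed coordinates."""
    df = pd.read_csv(io.StringIO(_data("calanus_declared_values.tsv")),
                     sep="\t", comment="#", na_values=["."])
    return df.set_index("name")


def calanus_declared_claims() -> dict[str, dict[str, object]]:
    """Declared values in the mapping shape ``validate_table`` consumes."""
    df = calanus_declared_table()
    claims: dict[str, dict[str, object]] = {}
    for name, row in df.iterrows():
        intergenic = row["intergenic"]
        if isinstance(intergenic, str) and intergenic.startswith("open:"):
            pass  # keep the open-region string as-is
        else:
            intergenic = int(intergenic)
        claims[name] = {"length": int(row["length"]), "intergenic": intergenic}
    return claims


def copepod_divergence_table() -> pd.DataFrame:
    """Published per-gene divergence/selection summary: DB and omega_B
    between five copepod species, DW and omega_W within 11 conspecific
    individuals; NA cells are genuinely undefined."""
    return pd.read_csv(io.StringIO(_data("copepod_divergence.tsv")),
                       sep="\t", comment="#", na_values=["NA"]).set_index("gene")


def calanus_gene_order(include_trna: bool = False):
    """Signed gene order of the contig (PCG+rRNA by default, as used for
    rearrangement comparisons)."""
    from .gene_order import order_from_features

    include = None if include_trna else {"PCG", "rRNA"}
    return order_from_features(calanus_feature_table(), include)
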