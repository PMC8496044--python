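"""Packaged default gene-set resources.

The DDR collection covers 27 DNA damage response and repair pathways spanning
the five canonical repair mechanisms (mismatch, base-excision, nucleotide-
excision repair, homologous recombination, non-homologous end joining) plus
double-strand-break sub-processes, damage checkpoints and replication-coupled
repair, curated in the style of the KEGG and Reactome pathway collections.
The immune pathway collection and immune-specific gene list are curated
stand-ins for hallmark-style immune signatures and a literature infiltration
marker list; both are replaceable by user-supplied files.
"""

from __future__ import annotations

from importlib import resources

from .io import GeneSetCollection, read_gene_list, read_gmt

__all__ = ["load_ddr_collection", "load_immune_collection", "load_immune_genes"]

_DATA = resources.files("ddrimmune.data")


def _data_path(name: str):
    return resources.as_file(_DATA / name)


def load_ddr_collection() -> GeneSetCollection:
    """The packaged 27-pathway DNA damage response/repair collection."""
    with _data_path("ddr_pathways.gmt") as p:
        coll = read_gmt(p)
    return GeneSetCollection(coll.sets, source_label="ddrimmune:ddr_pathways")


def load_immune_collection() -> GeneSetCollection:
    """Packaged immune pathway gene sets (hallmark-style stand-ins)."""
    with _data_path("immune_pathways.gmt") as p:
        coll = read_gmt(p)
    return GeneSetCollection(coll.sets, source_label="ddrimmune:immune_pathways")


def load_immune_genes() -> list[str]:
    """Packaged immune-specific marker gene list for the content score."""
    with _data_path("immune_genes.txt") as p:
        return read_gene_list(p)
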