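"""Drug-gene interaction lookup against a local two-column TSV table.

The packaged default table is a DGIdb-style export (gene_symbol,
drug_name).  Lookups are case-insensitive on gene symbols and composite
node names ("SYNGAP1, ZBTB9") are split on commas with each symbol
queried separately.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

__all__ = ["DrugGeneTable", "load_default_table", "map_genes_to_drugs"]


@dataclass
class DrugGeneTable:
    """Uppercase-normalized gene -> sorted unique drug names."""

    interactions: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs) -> "DrugGeneTable":
        seen: dict[str, set[str]] = {}
        for gene, drug in pairs:
            seen.setdefault(str(gene).strip().upper(), set()).add(
                str(drug).strip().upper()
            )
        return cls({g: sorted(ds) for g, ds in seen.items()})

    @classmethod
    def from_tsv(cls, path) -> "DrugGeneTable":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            rows = [r for r in reader if r and not r[0].startswith("#")]
        if rows and rows[0][0].lower() in ("gene", "gene_symbol"):
            rows = rows[1:]
        return cls.from_pairs((r[0], r[1]) for r in rows if len(r) >= 2)

    def drugs_for(self, gene: str) -> list[str]:
        return list(self.interactions.get(str(gene).strip().upper(), []))


def load_default_table() -> DrugGeneTable:
    """The packaged DGIdb-style fixture table."""
    text = resources.files("rewirekit.data").joinpath("dgidb_interactions.tsv").read_text()
    rows = [
        line.split("\t") for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if rows and rows[0][0].lower() in ("gene", "gene_symbol"):
        rows = rows[1:]
    return DrugGeneTable.from_pairs((r[0], r[1]) for r in rows if len(r) >= 2)


def map_genes_to_drugs(genes, table: DrugGeneTable) -> dict[str, list[str]]:
    """Map gene (or composite) names to candidate drugs.

    Composite names are split on commas and the union of per-symbol hits
    returned.  Genes without any interaction map to an empty list
    (rendered "NA" by the CLI).
    """
    out: dict[str, list[str]] = {}
    for name in genes:
        hits: set[str] = set()
        for symbol in str(name).split(","):
            hits.update(table.drugs_for(symbol))
        out[str(name)] = sorted(hits)
    return out
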