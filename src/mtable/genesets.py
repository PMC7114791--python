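"""Gene-set bookkeeping: batch queries, Venn partitions, persistence.

A :class:`GeneSet` is a named, deduplicated collection of gene ids with an
append-only provenance log recording how it was produced (operation,
parameters, input sets, timestamp), so an analysis trail survives
save/load round-trips.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Optional, Sequence

from .errors import FormatError, ValidationError

VENN_MIN_SETS = 2
VENN_MAX_SETS = 4


@dataclass
class GeneSet:
    name: str
    genes: set = field(default_factory=set)
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        self.log = list(self.log)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def add_log_entry(self, operation: str, parameters: Optional[dict] = None,
                      inputs: Optional[Sequence[str]] = None) -> None:
        """Append one provenance entry; the log is never rewritten."""
        self.log.append({
            "operation": operation,
            "parameters": dict(parameters or {}),
            "inputs": list(inputs or []),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        })


def batch_query(
    identifiers: Iterable[str],
    annotation=None,
    table=None,
    name: str = "batch_query",
) -> tuple[GeneSet, list[str]]:
    """Resolve identifiers to gene ids, case-insensitively.

    Each identifier is matched against gene ids first, then against gene
    symbols from the annotation (an id match wins when one string is both
    an id and another gene's symbol). Gene ids come from the annotation
    and/or an mtable. Unmatched identifiers are returned verbatim, in
    input order.
    """
    identifiers = list(identifiers)
    id_lookup: dict[str, str] = {}
    symbol_lookup: dict[str, str] = {}
    if annotation is not None:
        for gene in annotation:
            id_lookup[gene.gene_id.lower()] = gene.gene_id
            if gene.symbol:
                symbol_lookup.setdefault(gene.symbol.lower(), gene.gene_id)
    if table is not None:
        for gene_id in table.gene_ids:
            id_lookup.setdefault(gene_id.lower(), gene_id)

    matched: set = set()
    unmatched: list[str] = []
    for ident in identifiers:
        key = ident.lower()
        if key in id_lookup:
            matched.add(id_lookup[key])
        elif key in symbol_lookup:
            matched.add(symbol_lookup[key])
        else:
            unmatched.append(ident)
    result = GeneSet(name, matched)
    result.add_log_entry("batch_query", {"n_identifiers": len(identifiers),
                                         "n_unmatched": len(unmatched)})
    return result, unmatched


def venn(sets: Sequence[GeneSet]) -> dict[tuple[str, ...], list[str]]:
    """Partition the union of 2–4 gene sets into exclusive Venn regions.

    Returns a mapping from each non-empty membership pattern — the tuple
    of set names, in input order, that exactly contain a region's genes —
    to the sorted list of genes exclusive to that region. Regions are
    disjoint and jointly cover the union of the inputs.
    """
    if not VENN_MIN_SETS <= len(sets) <= VENN_MAX_SETS:
        raise ValidationError(
            f"Venn analysis accepts {VENN_MIN_SETS} to {VENN_MAX_SETS} gene "
            f"sets, got {len(sets)}"
        )
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValidationError(f"gene set names must be unique: {names}")
    regions: dict[tuple[str, ...], list[str]] = {}
    union = set().union(*(s.genes for s in sets))
    for gene in union:
        pattern = tuple(s.name for s in sets if gene in s.genes)
        regions.setdefault(pattern, []).append(gene)
    for genes in regions.values():
        genes.sort()
    return regions


def save_geneset(geneset: GeneSet, path) -> None:
    """Persist as JSON: name, sorted gene list, full provenance log."""
    document = {
        "name": geneset.name,
        "genes": sorted(geneset.genes),
        "log": geneset.log,
    }
    with open(path, "wt") as fh:
        json.dump(document, fh, indent=2, sort_keys=False)
        fh.write("\n")


def load_geneset(path) -> GeneSet:
    with open(path, "rt") as fh:
        try:
            document = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: malformed gene-set JSON: {exc}") from exc
    try:
        name = document["name"]
        genes = list(document["genes"])
        log = list(document.get("log", []))
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: gene-set JSON missing fields: {exc}") from exc
    if len(set(genes)) != len(genes):
        warnings.warn(f"{path}: duplicate genes deduplicated on load")
    return GeneSet(name, set(genes), log)


def read_gene_list(path, name: Optional[str] = None) -> GeneSet:
    """Read a plain one-gene-per-line text file."""
    with open(path, "rt") as fh:
        genes = {line.strip() for line in fh if line.strip()}
    geneset = GeneSet(name or str(path), genes)
    geneset.add_log_entry("read_gene_list", {"path": str(path)})
    return geneset


def write_gene_list(geneset: GeneSet, path) -> None:
    with open(path, "wt") as fh:
        for gene in sorted(geneset.genes):
            fh.write(gene + "\n")
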