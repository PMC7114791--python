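"""GO-term / KEGG-pathway over-representation by hypergeometric test.

For a query of n annotated genes drawn from a universe of N genes of which
K carry a term, the enrichment p-value is the upper tail P[X >= k] of the
hypergeometric distribution — the probability that a random size-n draw
contains at least the observed k term members. Benjamini–Hochberg step-up
adjustment controls the FDR over all tested terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import FormatError, ValidationError
from .genesets import GeneSet

DEFAULT_MIN_TERM_SIZE = 2


@dataclass
class TermMapping:
    """term id -> gene set, with optional readable names."""

    term_to_genes: dict
    term_names: dict
    namespace: str = "custom"

    def __post_init__(self) -> None:
        empty = [t for t, genes in self.term_to_genes.items() if not genes]
        if empty:
            raise ValidationError(f"terms with empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.term_to_genes)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query genes carrying the term
    n: int  # query size within the universe
    K: int  # term size within the universe
    N: int  # universe size
    p_value: float
    q_value: float


def read_term_mapping(path, namespace: str = "custom") -> TermMapping:
    """Read a 2- or 3-column TSV: gene_id, term_id[, term_name].

    Duplicate (gene, term) rows are deduplicated; genes with no term are
    simply absent.
    """
    term_to_genes: dict = {}
    term_names: dict = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(
                    f"{path}: line {lineno}: expected gene_id<TAB>term_id"
                    f"[<TAB>term_name]"
                )
            gene_id, term_id = fields[0], fields[1]
            term_to_genes.setdefault(term_id, set()).add(gene_id)
            if len(fields) >= 3 and fields[2]:
                term_names[term_id] = fields[2]
    return TermMapping(term_to_genes, term_names, namespace)


def _as_gene_ids(genes) -> set:
    if isinstance(genes, GeneSet):
        return set(genes.genes)
    return set(genes)


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k]."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query,
    universe,
    mapping: TermMapping,
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
) -> list[EnrichmentResult]:
    """Over-representation of each term in the query gene set.

    Query genes outside the universe are dropped with a warning; term gene
    sets are intersected with the universe before testing, and terms
    smaller than ``min_term_size`` (after intersection) are skipped.
    Results are sorted by (p-value, term id); q-values are BH-adjusted over
    all tested terms.
    """
    universe_genes = _as_gene_ids(universe)
    if not universe_genes:
        raise ValidationError("universe must be non-empty")
    query_genes = _as_gene_ids(query)
    outside = query_genes - universe_genes
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped"
        )
        query_genes = query_genes & universe_genes

    N = len(universe_genes)
    n = len(query_genes)
    tested: list[tuple] = []
    for term_id in sorted(mapping.term_to_genes):
        term_genes = mapping.term_to_genes[term_id] & universe_genes
        K = len(term_genes)
        if K < min_term_size:
            continue
        k = len(term_genes & query_genes)
        p = hypergeom_pvalue(k, N, K, n)
        tested.append((term_id, k, K, p))
    if not tested:
        return []
    q_values = adjust_pvalues_bh([t[3] for t in tested])
    results = [
        EnrichmentResult(
            term_id,
            mapping.term_names.get(term_id, ""),
            k, n, K, N, p, float(q),
        )
        for (term_id, k, K, p), q in zip(tested, q_values)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def adjust_pvalues_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at
    1. Raises for p-values outside (0, 1].
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def write_enrichment_tsv(results: Iterable[EnrichmentResult], path) -> None:
    with open(path, "wt") as fh:
        fh.write("term_id\tname\tk\tn\tK\tN\tp_value\tq_value\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.p_value:.6g}\t{r.q_value:.6g}\n"
            )
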