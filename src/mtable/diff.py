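"""Differentially methylated genes by simple level arithmetic.

A gene is called differentially methylated when the absolute difference of
its methylation levels between two conditions reaches a threshold — a
deliberate plain-arithmetic caller with no test statistic, operating on one
(region kind, context) score column at a time. A background-subtraction
variant adjusts a target table by the mean of a panel of background tables.
Genes missing a score in either condition are skipped, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genesets import GeneSet
from .table import MTable

DEFAULT_DELTA_THRESHOLD = 0.2


@dataclass(frozen=True)
class DmgCall:
    gene_id: str
    context: str
    region_kind: str
    level_a: float
    level_b: float
    delta: float  # level_a - level_b
    direction: str  # "hyper" if delta > 0 else "hypo"


@dataclass
class DmgResult:
    """Calls plus bookkeeping of how many genes were tested or skipped."""

    calls: list[DmgCall]
    n_tested: int
    n_skipped: int
    parameters: dict

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.gene_id, c.context, c.region_kind, c.level_a, c.level_b,
                 c.delta, c.direction)
                for c in self.calls
            ],
            columns=["gene_id", "context", "region", "level_a", "level_b",
                     "delta", "direction"],
        )


def call_dmgs_pairwise(
    table_a: MTable,
    table_b: MTable,
    context: str,
    region_kind: str,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> DmgResult:
    """Pairwise DMG calls: |level_a − level_b| >= delta_threshold.

    Only genes with a present score in both tables are tested; the rest are
    counted in ``n_skipped``. Calls are ordered by gene id.
    """
    if not 0.0 < delta_threshold <= 1.0:
        raise ValidationError(
            f"delta_threshold must be in (0, 1], got {delta_threshold}"
        )
    a = table_a.column(region_kind, context)
    b = table_b.column(region_kind, context)
    genes = sorted(set(a.index) | set(b.index))
    calls: list[DmgCall] = []
    n_tested = 0
    n_skipped = 0
    for gene in genes:
        va = a.get(gene, np.nan)
        vb = b.get(gene, np.nan)
        if np.isnan(va) or np.isnan(vb):
            n_skipped += 1
            continue
        n_tested += 1
        delta = float(va) - float(vb)
        if abs(delta) >= delta_threshold:
            calls.append(
                DmgCall(gene, context, region_kind, float(va), float(vb),
                        delta, "hyper" if delta > 0 else "hypo")
            )
    return DmgResult(
        calls,
        n_tested,
        n_skipped,
        {"context": context, "region": region_kind,
         "delta_threshold": delta_threshold,
         "sample_a": table_a.sample, "sample_b": table_b.sample},
    )


def subtract_background(
    targets: Sequence[MTable],
    background: Sequence[MTable],
    context: str,
    region_kind: str,
) -> pd.DataFrame:
    """Target levels minus the per-gene mean of background levels.

    Returns a gene × target DataFrame of adjusted scores in [−1, 1]. A
    cell is NaN when the target score is missing or no background table
    has a score for that gene (missing background tables are averaged over
    the ones that do have a value).
    """
    targets = list(targets)
    background = list(background)
    if not targets:
        raise ValidationError("need at least one target table")
    if not background:
        raise ValidationError("need at least one background table")
    genes: list[str] = []
    seen: set[str] = set()
    for t in targets:
        for g in t.gene_ids:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    bg = pd.DataFrame(
        {i: t.column(region_kind, context).reindex(genes)
         for i, t in enumerate(background)}
    )
    bg_mean = bg.mean(axis=1, skipna=True)  # NaN where no background value
    out = {}
    for i, t in enumerate(targets):
        name = t.sample or f"target{i + 1}"
        adjusted = t.column(region_kind, context).reindex(genes) - bg_mean
        out[name] = adjusted.clip(-1.0, 1.0)
    return pd.DataFrame(out, index=pd.Index(genes, name="gene_id"))


def select_genes_by_level(
    table: MTable,
    context: str,
    region_kind: str,
    min_level: float = 0.0,
    max_level: float = 1.0,
    name: str = "level_selection",
) -> GeneSet:
    """Genes whose score is present and within [min_level, max_level]."""
    if not (0.0 <= min_level <= max_level <= 1.0):
        raise ValidationError(
            f"need 0 <= min_level <= max_level <= 1, got "
            f"[{min_level}, {max_level}]"
        )
    column = table.column(region_kind, context)
    selected = set(column[(column >= min_level) & (column <= max_level)].index)
    geneset = GeneSet(name, selected)
    geneset.add_log_entry(
        "select_genes_by_level",
        {"context": context, "region": region_kind,
         "min_level": min_level, "max_level": max_level,
         "sample": table.sample},
    )
    return geneset
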