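"""The mtable: gene-based methylation levels per region and context.

An mtable row holds six scores per gene — the weighted methylation level
(sum of methylated read counts over sum of total read counts) of the
promoter and gene-body regions in each of the CG, CHG and CHH contexts.
On disk it is a 7-column TSV: gene id followed by the six scores in the
fixed order promoter_CG, promoter_CHG, promoter_CHH, body_CG, body_CHG,
body_CHH. Missing scores (no covered cytosine of that context in the
region) are the literal ``NA``.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import Region
from .errors import FormatError, ValidationError
from .methio import CONTEXTS, CytosineRecord

SCORE_COLUMNS = (
    "promoter_CG",
    "promoter_CHG",
    "promoter_CHH",
    "body_CG",
    "body_CHG",
    "body_CHH",
)


class MTable:
    """Gene × {promoter, body} × {CG, CHG, CHH} methylation-level table.

    Wraps a DataFrame indexed by gene id with the six score columns
    (float in [0, 1], NaN for missing) plus run metadata (sample name and
    the parameters the scores were computed with).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        sample: Optional[str] = None,
        metadata: Optional[dict] = None,
    ) -> None:
        missing_cols = [c for c in SCORE_COLUMNS if c not in data.columns]
        if missing_cols:
            raise ValidationError(f"mtable data lacks columns {missing_cols}")
        data = data.loc[:, list(SCORE_COLUMNS)].astype(float)
        values = data.to_numpy()
        present = ~np.isnan(values)
        if ((values[present] < 0) | (values[present] > 1)).any():
            raise ValidationError("methylation levels must lie in [0, 1]")
        self.data = data
        self.sample = sample
        self.metadata = dict(metadata or {})

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def score(self, gene_id: str, region_kind: str, context: str) -> float:
        return float(self.data.at[gene_id, f"{region_kind}_{context}"])

    def column(self, region_kind: str, context: str) -> pd.Series:
        """One score column as a Series indexed by gene id."""
        name = f"{region_kind}_{context}"
        if name not in SCORE_COLUMNS:
            raise ValidationError(f"no such score column {name!r}")
        return self.data[name]

    def equals(self, other: "MTable") -> bool:
        return self.data.equals(other.data) and self.sample == other.sample


def score_methylation(
    records: Iterable[CytosineRecord],
    regions: Iterable[Region],
    min_coverage: int = 1,
    sample: Optional[str] = None,
    site_mean: bool = False,
) -> MTable:
    """Aggregate cytosine records into an mtable.

    For each gene, region kind and context, the default score is the
    coverage-weighted level Σ meth / Σ (meth + unmeth) over records of
    that context falling inside the region (half-open: start <= pos < end)
    with coverage >= ``min_coverage``; it is order- and
    partition-invariant. ``site_mean=True`` instead averages per-site
    fractions meth/(meth+unmeth), for comparison with tools that report
    the mean site level. A score with empty denominator is missing (NaN).
    """
    regions = list(regions)
    if not regions:
        raise ValidationError("empty region set")
    trees: dict[str, IntervalTree] = {}
    gene_order: list[str] = []
    seen_genes: set[str] = set()
    for region in regions:
        if region.gene_id not in seen_genes:
            seen_genes.add(region.gene_id)
            gene_order.append(region.gene_id)
        if region.end > region.start:  # empty intervals cannot be indexed
            trees.setdefault(region.chrom, IntervalTree()).addi(
                region.start, region.end, (region.gene_id, region.kind)
            )

    # numerator/denominator accumulators keyed by (gene, kind, context)
    num: dict[tuple, float] = {}
    den: dict[tuple, float] = {}
    for r in records:
        if r.coverage < min_coverage or r.coverage == 0:
            continue
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for hit in tree.at(r.pos):
            gene_id, kind = hit.data
            key = (gene_id, kind, r.context)
            if site_mean:
                num[key] = num.get(key, 0.0) + r.meth / r.coverage
                den[key] = den.get(key, 0.0) + 1.0
            else:
                num[key] = num.get(key, 0.0) + r.meth
                den[key] = den.get(key, 0.0) + r.coverage

    values = np.full((len(gene_order), len(SCORE_COLUMNS)), np.nan)
    gene_index = {g: i for i, g in enumerate(gene_order)}
    col_index = {c: j for j, c in enumerate(SCORE_COLUMNS)}
    for key, d in den.items():
        gene_id, kind, context = key
        if d > 0:
            values[gene_index[gene_id], col_index[f"{kind}_{context}"]] = (
                num[key] / d
            )
    data = pd.DataFrame(values, index=pd.Index(gene_order, name="gene_id"),
                        columns=list(SCORE_COLUMNS))
    metadata = {"min_coverage": min_coverage,
                "estimator": "site_mean" if site_mean else "weighted"}
    return MTable(data, sample=sample, metadata=metadata)


def write_mtable(table: MTable, path) -> None:
    """Write the 7-column TSV with a ``#``-prefixed header line.

    Scores are fixed 6-decimal; missing scores are ``NA``. The header
    carries the sample name and scoring parameters so a run is
    self-describing; headerless consumers can skip ``#`` lines.
    """
    meta = ";".join(f"{k}={v}" for k, v in sorted(table.metadata.items()))
    header = f"#gene_id\t" + "\t".join(SCORE_COLUMNS)
    if table.sample or meta:
        header = f"#sample={table.sample or ''};{meta}\n" + header
    with open(path, "wt") as fh:
        fh.write(header + "\n")
        for gene_id, row in table.data.iterrows():
            cells = [
                "NA" if np.isnan(v) else f"{v:.6f}" for v in row.to_numpy()
            ]
            fh.write(gene_id + "\t" + "\t".join(cells) + "\n")


def read_mtable(path, sample: Optional[str] = None) -> MTable:
    """Read a 7-column mtable TSV (``#`` header lines optional)."""
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    metadata: dict = {}
    file_sample = None
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line and "\t" not in line:
                    for part in line[1:].split(";"):
                        key, _, value = part.partition("=")
                        if key == "sample":
                            file_sample = value or None
                        elif key:
                            metadata[key] = value
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(
                    f"{path}: line {lineno}: expected 7 tab-separated fields, "
                    f"got {len(fields)}"
                )
            scores = []
            for cell in fields[1:]:
                if cell == "NA":
                    scores.append(np.nan)
                    continue
                try:
                    v = float(cell)
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from exc
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(
                        f"{path}: line {lineno}: score {v} outside [0, 1]"
                    )
                scores.append(v)
            gene_ids.append(fields[0])
            rows.append(scores)
    data = pd.DataFrame(
        rows, index=pd.Index(gene_ids, name="gene_id"), columns=list(SCORE_COLUMNS)
    )
    return MTable(data, sample=sample or file_sample, metadata=metadata)


def to_matrix(
    tables: list[MTable], context: str, region_kind: str
) -> pd.DataFrame:
    """Gene × sample matrix of one score column across tables.

    Rows cover the union of gene ids (first-seen order); missing scores
    propagate as NaN. Suitable for export to clustering/heatmap viewers.
    """
    if not tables:
        raise ValidationError("need at least one mtable")
    if context not in CONTEXTS:
        raise ValidationError(f"context {context!r} not one of {CONTEXTS}")
    names = [t.sample or f"sample{i + 1}" for i, t in enumerate(tables)]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate sample names: {names}")
    genes: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for g in t.gene_ids:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    columns = {
        name: t.column(region_kind, context).reindex(genes)
        for name, t in zip(names, tables)
    }
    matrix = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    return matrix
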