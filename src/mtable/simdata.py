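"""Synthetic annotations and cytosine reports with known methylation truth.

The generative model is deliberately minimal: cytosine sites are placed
uniformly within each promoter/body region, per-site read coverage is
shifted-Poisson (1 + Poisson(mean − 1), so every emitted site has at least
one read) and the methylated read count is Binomial(coverage, p) with p
the region's true level per context. Under this model the coverage-
weighted level is the maximum-likelihood estimate of p, so scored levels
converge to the truth as coverage grows. An optional conversion-error rate
epsilon flips each read's call with probability epsilon. Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .annotation import (
    DEFAULT_PROMOTER_LENGTH,
    GeneModel,
    Region,
    derive_all_regions,
)
from .errors import ValidationError
from .methio import CONTEXTS, CytosineRecord, write_cx_report

DEFAULT_SITES_PER_REGION = 10
DEFAULT_COVERAGE_MEAN = 20.0


@dataclass
class SimulationTruth:
    """True methylation level per (gene_id, region kind, context)."""

    levels: dict  # (gene_id, kind, context) -> p in [0, 1]
    seed: int
    effect_genes: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for key, p in self.levels.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"true level {p} for {key} outside [0, 1]")

    def level(self, gene_id: str, kind: str, context: str) -> float:
        return self.levels[(gene_id, kind, context)]


def simulate_annotation(
    n_genes: int,
    chrom_length: int = 1_000_000,
    gene_length_range: tuple[int, int] = (1000, 3000),
    promoter_gap: int = 2 * DEFAULT_PROMOTER_LENGTH + 1000,
    seed: int = 0,
    chrom: str = "chrSim",
) -> list[GeneModel]:
    """Non-overlapping genes with alternating strands on one chromosome.

    Genes are laid out left to right with ``promoter_gap`` bases between
    consecutive genes. Because a − strand gene's promoter extends downstream
    and the next + strand gene's promoter extends upstream into the same
    gap, the gap must be at least twice the promoter length used in
    scoring for all derived regions to stay disjoint; the default leaves
    1 kb of slack over twice the default promoter length. Raises when the
    requested genes do not fit.
    """
    rng = np.random.default_rng(seed)
    lo, hi = gene_length_range
    models: list[GeneModel] = []
    pos = promoter_gap
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        start = pos
        end = start + length
        if end + promoter_gap > chrom_length:
            raise ValidationError(
                f"cannot pack {n_genes} genes of length <= {hi} with gap "
                f"{promoter_gap} into chromosome of length {chrom_length}"
            )
        strand = "+" if i % 2 == 0 else "-"
        models.append(
            GeneModel(f"simg{i + 1:04d}", chrom, start, end, strand,
                      symbol=f"SYM{i + 1}")
        )
        pos = end + promoter_gap
    return models


def write_gff3(models: Iterable[GeneModel], path) -> None:
    """Write gene models as GFF3 (1-based inclusive on disk)."""
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.gene_id}"
            if m.symbol:
                attrs += f";Name={m.symbol}"
            fh.write(
                f"{m.chrom}\tsimdata\tgene\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )


def simulate_truth(
    models: Sequence[GeneModel],
    seed: int = 0,
    level_range: tuple[float, float] = (0.05, 0.95),
) -> SimulationTruth:
    """Draw one true level per gene × region kind × context, uniformly."""
    rng = np.random.default_rng(seed)
    lo, hi = level_range
    levels = {
        (m.gene_id, kind, context): float(rng.uniform(lo, hi))
        for m in models
        for kind in ("promoter", "body")
        for context in CONTEXTS
    }
    return SimulationTruth(levels, seed)


def shift_truth(
    truth: SimulationTruth,
    effect_genes: Iterable[str],
    delta: float,
    context: str = "CG",
    region_kind: str = "body",
) -> SimulationTruth:
    """A copy of ``truth`` with effect genes shifted by delta in one score."""
    effect_genes = set(effect_genes)
    levels = dict(truth.levels)
    for gene in effect_genes:
        key = (gene, region_kind, context)
        if key not in levels:
            raise ValidationError(f"effect gene {gene!r} not in the truth")
        shifted = levels[key] + delta
        if not 0.0 <= shifted <= 1.0:
            raise ValidationError(
                f"shifted level {shifted:.3f} for {gene} outside [0, 1]"
            )
        levels[key] = shifted
    return SimulationTruth(levels, truth.seed, effect_genes)


def simulate_records(
    models: Sequence[GeneModel],
    truth: SimulationTruth,
    sites_per_region_per_context: int = DEFAULT_SITES_PER_REGION,
    coverage_mean: float = DEFAULT_COVERAGE_MEAN,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
    seed: int = 0,
    epsilon: float = 0.0,
) -> list[CytosineRecord]:
    """Sample cytosine records for every region of every gene.

    Returns records sorted by position (one chromosome assumed per the
    annotation simulator, but sorting is (chrom, pos) anyway).
    """
    if coverage_mean < 1:
        raise ValidationError("coverage_mean must be >= 1")
    rng = np.random.default_rng(seed)
    regions = derive_all_regions(models, promoter_length)
    records: list[CytosineRecord] = []
    for region in regions:
        width = region.end - region.start
        if width <= 0:
            continue
        for context in CONTEXTS:
            p = truth.level(region.gene_id, region.kind, context)
            n_sites = min(sites_per_region_per_context, width)
            offsets = rng.choice(width, size=n_sites, replace=False)
            coverages = 1 + rng.poisson(coverage_mean - 1.0, size=n_sites)
            meths = rng.binomial(coverages, p)
            if epsilon > 0:
                # each read's call flips with probability epsilon
                unmeths = coverages - meths
                flipped_to_unmeth = rng.binomial(meths, epsilon)
                flipped_to_meth = rng.binomial(unmeths, epsilon)
                meths = meths - flipped_to_unmeth + flipped_to_meth
            strands = rng.integers(0, 2, size=n_sites)
            for off, cov, meth, s in zip(offsets, coverages, meths, strands):
                records.append(
                    CytosineRecord(
                        region.chrom,
                        int(region.start + off),
                        "+" if s == 0 else "-",
                        int(meth),
                        int(cov - meth),
                        context,
                    )
                )
    records.sort(key=lambda r: (r.chrom, r.pos, r.context, r.strand))
    return records


def simulate_condition_pair(
    models: Sequence[GeneModel],
    base_truth: SimulationTruth,
    effect_genes: Iterable[str],
    delta: float,
    context: str = "CG",
    region_kind: str = "body",
    sites_per_region_per_context: int = DEFAULT_SITES_PER_REGION,
    coverage_mean: float = DEFAULT_COVERAGE_MEAN,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
    seed: int = 0,
) -> tuple[list[CytosineRecord], list[CytosineRecord], set]:
    """Two record sets: condition A from the base truth, B with the shift.

    Returns (records_a, records_b, labels) where labels is the set of true
    differentially methylated genes (empty when delta == 0).
    """
    truth_b = shift_truth(base_truth, effect_genes, delta, context, region_kind)
    records_a = simulate_records(
        models, base_truth, sites_per_region_per_context, coverage_mean,
        promoter_length, seed=seed,
    )
    records_b = simulate_records(
        models, truth_b, sites_per_region_per_context, coverage_mean,
        promoter_length, seed=seed + 1,
    )
    labels = set(effect_genes) if delta != 0 else set()
    return records_a, records_b, labels


def write_truth_tsv(truth: SimulationTruth, path) -> None:
    with open(path, "wt") as fh:
        fh.write("gene_id\tregion\tcontext\ttrue_level\n")
        for (gene_id, kind, context), p in sorted(truth.levels.items()):
            fh.write(f"{gene_id}\t{kind}\t{context}\t{p:.6f}\n")


def simulate_dataset(
    outdir,
    n_genes: int = 20,
    seed: int = 0,
    sites_per_region_per_context: int = DEFAULT_SITES_PER_REGION,
    coverage_mean: float = DEFAULT_COVERAGE_MEAN,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
    effect_genes: int = 0,
    delta: float = 0.0,
    context: str = "CG",
    region_kind: str = "body",
) -> dict:
    """Write a complete synthetic study to ``outdir``.

    Emits annotation.gff3, truth.tsv and either a single conditionA.cx
    report or, when ``effect_genes``/``delta`` request a contrast, a
    condition pair plus a labels.tsv of true DMGs. Returns the file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = simulate_annotation(n_genes, seed=seed)
    truth = simulate_truth(models, seed=seed + 1)
    paths = {
        "annotation": outdir / "annotation.gff3",
        "truth": outdir / "truth.tsv",
        "condition_a": outdir / "conditionA.cx.tsv",
    }
    write_gff3(models, paths["annotation"])
    write_truth_tsv(truth, paths["truth"])
    if effect_genes > 0 and delta != 0.0:
        chosen = [m.gene_id for m in models[:effect_genes]]
        # keep the shifted level inside [0, 1]: rescale each effect gene's
        # base level into the feasible band, preserving its relative rank
        lo = max(0.05, 0.05 - delta)
        hi = min(0.95, 0.95 - delta)
        if hi <= lo:
            raise ValidationError(f"delta {delta} leaves no feasible level band")
        for gene in chosen:
            key = (gene, region_kind, context)
            p = truth.levels[key]
            truth.levels[key] = lo + (p - 0.05) / 0.9 * (hi - lo)
        records_a, records_b, labels = simulate_condition_pair(
            models, truth, chosen, delta, context, region_kind,
            sites_per_region_per_context, coverage_mean, promoter_length,
            seed=seed + 2,
        )
        paths["condition_b"] = outdir / "conditionB.cx.tsv"
        paths["labels"] = outdir / "labels.tsv"
        write_cx_report(records_a, paths["condition_a"])
        write_cx_report(records_b, paths["condition_b"])
        with open(paths["labels"], "wt") as fh:
            for gene in sorted(labels):
                fh.write(gene + "\n")
    else:
        records = simulate_records(
            models, truth, sites_per_region_per_context, coverage_mean,
            promoter_length, seed=seed + 2,
        )
        write_cx_report(records, paths["condition_a"])
    return {k: str(v) for k, v in paths.items()}
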