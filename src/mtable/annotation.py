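"""Gene annotations and the promoter / gene-body regions derived from them.

Internal coordinates are always 0-based half-open. GFF3/GTF files are read
as 1-based inclusive and converted on input; BED12 is already 0-based
half-open. The promoter is a fixed-length window immediately upstream of
the transcription start site (strand-aware), clipped at the chromosome
edges; the gene body is the full annotated gene extent.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .errors import FormatError, ValidationError

STRANDS = ("+", "-")
DEFAULT_PROMOTER_LENGTH = 2000

REGION_KINDS = ("promoter", "body")


@dataclass(frozen=True)
class GeneModel:
    """A gene feature: id, location and strand (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} must exceed start {self.start}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: strand {self.strand!r} not one of {STRANDS}"
            )


@dataclass(frozen=True)
class Region:
    """A half-open genomic interval tied to a gene, promoter or body."""

    chrom: str
    start: int
    end: int
    kind: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValidationError(f"region kind {self.kind!r} not in {REGION_KINDS}")
        if self.start < 0 or self.end < self.start:
            raise ValidationError(
                f"region {self.gene_id}|{self.kind}: invalid interval "
                f"[{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_gff_attributes(field: str) -> dict:
    """Parse `key=value;...` (GFF3) attribute strings."""
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def _parse_gtf_attributes(field: str) -> dict:
    """Parse `key "value"; ...` (GTF) attribute strings."""
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key.strip()] = value.strip().strip('"')
    return attrs


def _detect_format(path) -> str:
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".gff", ".gff3")):
        return "gff3"
    if name.endswith(".gtf"):
        return "gtf"
    if name.endswith(".bed"):
        return "bed12"
    raise FormatError(
        f"cannot infer annotation format from file name {name!r}; "
        "pass format='gff3', 'gtf' or 'bed12'"
    )


def read_gene_models(path, format: Optional[str] = None) -> list[GeneModel]:
    """Read gene features from a GFF3, GTF or BED12 file.

    Only features of type ``gene`` are considered in GFF3/GTF; every BED12
    row is taken to be a gene. Coordinates are converted to the internal
    0-based half-open convention. Duplicate gene ids raise
    :class:`ValidationError`.
    """
    fmt = format or _detect_format(path)
    if fmt not in ("gff3", "gtf", "bed12"):
        raise FormatError(f"unknown annotation format {fmt!r}")

    models: list[GeneModel] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed12":
                    model = _gene_from_bed12(fields)
                else:
                    model = _gene_from_gff_like(fields, fmt)
            except ValidationError:
                raise
            except (FormatError, ValueError, IndexError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if model is None:
                continue
            if model.gene_id in seen:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate gene id {model.gene_id!r}"
                )
            seen.add(model.gene_id)
            models.append(model)
    return models


def _gene_from_gff_like(fields: list[str], fmt: str) -> Optional[GeneModel]:
    if len(fields) != 9:
        raise FormatError(f"expected 9 tab-separated fields, got {len(fields)}")
    chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
    if feature != "gene":
        return None
    if strand not in STRANDS:
        raise FormatError(f"unknown strand symbol {strand!r}")
    start1 = int(start)
    end1 = int(end)
    if fmt == "gff3":
        attrs = _parse_gff_attributes(attr)
        gene_id = attrs.get("ID") or attrs.get("gene_id")
        symbol = attrs.get("Name") or attrs.get("gene_name")
    else:
        attrs = _parse_gtf_attributes(attr)
        gene_id = attrs.get("gene_id")
        symbol = attrs.get("gene_name")
    if not gene_id:
        raise FormatError("gene feature without an ID/gene_id attribute")
    # 1-based inclusive -> 0-based half-open
    return GeneModel(gene_id, chrom, start1 - 1, end1, strand, symbol)


def _gene_from_bed12(fields: list[str]) -> GeneModel:
    if len(fields) < 6:
        raise FormatError(f"expected >=6 BED fields, got {len(fields)}")
    chrom, start, end, name, _score, strand = fields[:6]
    if strand not in STRANDS:
        raise FormatError(f"unknown strand symbol {strand!r}")
    return GeneModel(name, chrom, int(start), int(end), strand)


def derive_regions(
    gene: GeneModel,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
    chrom_length: Optional[int] = None,
) -> tuple[Region, Region]:
    """Derive the (promoter, body) region pair for one gene.

    The body is the gene's [start, end). The promoter is the
    ``promoter_length`` bases immediately upstream of the TSS: upstream of
    ``start`` on the + strand, downstream of ``end`` on the − strand,
    clipped at position 0 and at ``chrom_length`` when given. Clipping can
    yield an empty promoter; that is not an error.
    """
    if promoter_length <= 0:
        raise ValidationError(f"promoter_length must be > 0, got {promoter_length}")
    body = Region(gene.chrom, gene.start, gene.end, "body", gene.gene_id)
    if gene.strand == "+":
        p_start = max(0, gene.start - promoter_length)
        p_end = gene.start
    else:
        p_start = gene.end
        p_end = gene.end + promoter_length
        if chrom_length is not None:
            p_end = min(p_end, chrom_length)
    if p_end < p_start:  # fully clipped
        p_end = p_start
    promoter = Region(gene.chrom, p_start, p_end, "promoter", gene.gene_id)
    return promoter, body


def derive_all_regions(
    genes: Iterable[GeneModel],
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
    chrom_lengths: Optional[dict] = None,
) -> list[Region]:
    """Promoter and body regions for every gene, in gene order."""
    regions: list[Region] = []
    for gene in genes:
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        promoter, body = derive_regions(gene, promoter_length, clen)
        regions.append(promoter)
        regions.append(body)
    return regions


def write_regions_bed(regions: Iterable[Region], path) -> None:
    """Write regions as BED6 (name = gene_id|kind, strand left as '.')."""
    with open(path, "wt") as fh:
        for region in regions:
            fh.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t"
                f"{region.gene_id}|{region.kind}\t0\t.\n"
            )
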