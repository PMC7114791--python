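"""Per-cytosine methylation call I/O (Bismark cytosine/CX report dialect).

The on-disk format is a headerless 7-field TSV: chromosome, 1-based
position, strand, count methylated, count unmethylated, sequence context
(CG/CHG/CHH) and the trinucleotide. Positions are converted to 0-based
internally and back to 1-based on write. Readers are generators so memory
use is independent of file length.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .errors import FormatError

CONTEXTS = ("CG", "CHG", "CHH")
_STRANDS = ("+", "-")

# placeholder trinucleotides consistent with each context (H = A/C/T)
_DEFAULT_TRINUC = {"CG": "CGG", "CHG": "CAG", "CHH": "CAT"}


@dataclass(frozen=True)
class CytosineRecord:
    """Methylation evidence at one cytosine (pos is 0-based internally)."""

    chrom: str
    pos: int
    strand: str
    meth: int
    unmeth: int
    context: str

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_cx_report(path) -> Iterator[CytosineRecord]:
    """Stream cytosine records from a (possibly gzipped) CX report.

    Raises :class:`FormatError` naming the offending line on malformed
    input: wrong field count, non-integer counts, unknown strand or a
    context outside CG/CHG/CHH.
    """
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(
                    f"{path}: line {lineno}: expected 7 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, pos, strand, meth, unmeth, context, _trinuc = fields
            if strand not in _STRANDS:
                raise FormatError(
                    f"{path}: line {lineno}: unknown strand {strand!r}"
                )
            if context not in CONTEXTS:
                raise FormatError(
                    f"{path}: line {lineno}: context {context!r} not one of "
                    f"{CONTEXTS}"
                )
            try:
                pos1 = int(pos)
                meth_n = int(meth)
                unmeth_n = int(unmeth)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if pos1 < 1 or meth_n < 0 or unmeth_n < 0:
                raise FormatError(
                    f"{path}: line {lineno}: position must be >=1 and counts >=0"
                )
            yield CytosineRecord(chrom, pos1 - 1, strand, meth_n, unmeth_n, context)


def write_cx_report(records: Iterable[CytosineRecord], path) -> None:
    """Write records back to the 7-field CX dialect (1-based positions)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.strand}\t{r.meth}\t{r.unmeth}\t"
                f"{r.context}\t{_DEFAULT_TRINUC[r.context]}\n"
            )


def filter_records(
    records: Iterable[CytosineRecord], min_coverage: int = 1
) -> Iterator[CytosineRecord]:
    """Drop records with fewer than ``min_coverage`` total reads.

    ``min_coverage=0`` is the identity.
    """
    for r in records:
        if r.coverage >= min_coverage:
            yield r


def destrand_cg(records: Iterable[CytosineRecord]) -> Iterator[CytosineRecord]:
    """Merge symmetric CG pairs (+ at p with − at p+1) into one + record.

    Non-CG records pass through unchanged. Input is expected in file order
    (sorted by chromosome, then position), which is how CX reports are
    produced; an unpaired − CG record is emitted as-is.
    """
    pending: CytosineRecord | None = None
    for r in records:
        if r.context != "CG":
            if pending is not None:
                yield pending
                pending = None
            yield r
            continue
        if (
            pending is not None
            and pending.strand == "+"
            and r.strand == "-"
            and r.chrom == pending.chrom
            and r.pos == pending.pos + 1
        ):
            yield CytosineRecord(
                pending.chrom,
                pending.pos,
                "+",
                pending.meth + r.meth,
                pending.unmeth + r.unmeth,
                "CG",
            )
            pending = None
            continue
        if pending is not None:
            yield pending
        pending = r if r.strand == "+" else None
        if r.strand == "-":
            yield r
    if pending is not None:
        yield pending
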