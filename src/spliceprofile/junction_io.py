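"""Tab-separated input/output for splice-junction counts and exon coverage.

Junction counts use the STAR ``SJ.out.tab`` dialect: nine tab-separated
columns (chromosome, intron start, intron end, strand code, motif,
annotated flag, uniquely-mapping reads, multi-mapping reads, max overhang),
intron coordinates 1-based inclusive on the first/last intronic base.
Strand codes 0/1/2 decode to undefined/+/-.

Exon coverage tables are three-column TSVs (gene, exon_index, mean_depth)
with one row per (gene, exon); exons missing from the table are treated as
depth 0 downstream.

Only uniquely-mapping reads feed quantification; multi-mapped counts are
carried through unchanged but never used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionRecord",
    "ExonCoverageRecord",
    "read_junctions",
    "write_junctions",
    "read_exon_coverage",
    "write_exon_coverage",
]

_STRAND_DECODE = {"0": "undefined", "1": "+", "2": "-"}
_STRAND_ENCODE = {"undefined": "0", "+": "1", "-": "2"}


@dataclass(frozen=True)
class JunctionRecord:
    """One observed splice junction (an excised intron) with read support."""

    chromosome: str
    intron_start: int  # 1-based, first intronic base
    intron_end: int  # 1-based, last intronic base
    strand: str  # '+', '-' or 'undefined'
    unique_reads: int
    multimapped_reads: int = 0
    motif: int = 0
    annotated: int = 0
    max_overhang: int = 0

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.unique_reads < 0 or self.multimapped_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.strand not in _STRAND_ENCODE:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chromosome, self.intron_start, self.intron_end, self.strand)


@dataclass(frozen=True)
class ExonCoverageRecord:
    """Mean read depth over one exon of one panel gene."""

    gene_symbol: str
    exon_index: int
    mean_depth: float

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")


def read_junctions(path: str) -> list[JunctionRecord]:
    """Parse an SJ.out.tab-style file; rows are preserved in file order.

    Lines starting with ``#`` are skipped as headers. Malformed rows raise
    with the offending line number; an empty file yields an empty list.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom, start, end, strand_code, motif, annot, uniq, multi, ovh = fields
                rec = JunctionRecord(
                    chromosome=chrom,
                    intron_start=int(start),
                    intron_end=int(end),
                    strand=_STRAND_DECODE[strand_code],
                    unique_reads=int(uniq),
                    multimapped_reads=int(multi),
                    motif=int(motif),
                    annotated=int(annot),
                    max_overhang=int(ovh),
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            records.append(rec)
    return records


def write_junctions(records: list[JunctionRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.chromosome,
                        r.intron_start,
                        r.intron_end,
                        _STRAND_ENCODE[r.strand],
                        r.motif,
                        r.annotated,
                        r.unique_reads,
                        r.multimapped_reads,
                        r.max_overhang,
                    )
                )
                + "\n"
            )


def read_exon_coverage(path: str) -> list[ExonCoverageRecord]:
    """Read a per-exon mean-coverage TSV (columns gene, exon_index, mean_depth).

    A duplicated (gene, exon) pair is an error; missing exons are allowed
    (treated as depth 0 by coverage QC).
    """
    records = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene":  # header
                continue
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            gene, idx_s, depth_s = fields
            try:
                rec = ExonCoverageRecord(gene, int(idx_s), float(depth_s))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            k = (rec.gene_symbol, rec.exon_index)
            if k in seen:
                raise ValueError(f"{path}:{lineno}: duplicate (gene, exon) {k}")
            seen.add(k)
            records.append(rec)
    return records


def write_exon_coverage(records: list[ExonCoverageRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\texon_index\tmean_depth\n")
        for r in records:
            fh.write(f"{r.gene_symbol}\t{r.exon_index}\t{r.mean_depth:g}\n")
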