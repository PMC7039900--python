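"""Reference gene models for a targeted gene panel.

Each panel gene is represented by a single designated reference isoform
(the transcript against which all splicing events are defined). The model
carries the ordered exon structure, strand, and a possibly-empty set of
excluded exons — exons kept in the model for coordinate arithmetic but
whose events are dropped from quantification (e.g. regions confounded by a
highly homologous pseudogene).

Coordinates: exon intervals are stored 1-based inclusive, the GTF/STAR
convention. Cumulative (transcript) coordinate arithmetic is carried out on
derived 0-based half-open arrays so that length and offset computations
never need ``+1`` corrections.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "PanelGene",
    "PanelConfig",
    "TranscriptPosition",
    "load_gene_models",
    "genomic_to_transcript",
    "transcript_to_genomic",
]


@dataclass(frozen=True)
class PanelGene:
    """One gene of the panel: symbol, designated reference transcript, and
    exon indices (1-based, in reference-isoform order) excluded from event
    quantification."""

    gene_symbol: str
    transcript_id: str
    excluded_exon_indices: frozenset[int] = frozenset()


@dataclass(frozen=True)
class PanelConfig:
    """Panel definition plus the coverage-QC thresholds.

    A sample passes coverage QC when at least ``min_exon_fraction`` of the
    panel's non-excluded exons have mean depth >= ``min_exon_depth``.
    """

    genes: tuple[PanelGene, ...]
    min_exon_depth: float = 50.0
    min_exon_fraction: float = 0.85

    def __post_init__(self) -> None:
        if not self.min_exon_depth > 0:
            raise ValueError("min_exon_depth must be strictly positive")
        if not (0.0 < self.min_exon_fraction <= 1.0):
            raise ValueError("min_exon_fraction must be in (0, 1]")
        symbols = [g.gene_symbol for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate gene symbols in panel")

    @classmethod
    def from_json(cls, path: str) -> "PanelConfig":
        with open(path) as fh:
            raw = json.load(fh)
        genes = tuple(
            PanelGene(
                gene_symbol=g["gene_symbol"],
                transcript_id=g["transcript_id"],
                excluded_exon_indices=frozenset(g.get("excluded_exon_indices", [])),
            )
            for g in raw["genes"]
        )
        qc = raw.get("coverage_qc", {})
        return cls(
            genes=genes,
            min_exon_depth=qc.get("min_exon_depth", 50.0),
            min_exon_fraction=qc.get("min_exon_fraction", 0.85),
        )

    def to_json(self, path: str) -> None:
        raw = {
            "genes": [
                {
                    "gene_symbol": g.gene_symbol,
                    "transcript_id": g.transcript_id,
                    "excluded_exon_indices": sorted(g.excluded_exon_indices),
                }
                for g in self.genes
            ],
            "coverage_qc": {
                "min_exon_depth": self.min_exon_depth,
                "min_exon_fraction": self.min_exon_fraction,
            },
        }
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2)
            fh.write("\n")


@dataclass(frozen=True)
class GeneModel:
    """A single reference isoform.

    ``exons`` are (start, end) genomic intervals, 1-based inclusive, ordered
    5'->3' in *transcript* orientation: exon 1 of a minus-strand gene is the
    interval with the highest genomic coordinates.
    """

    gene_symbol: str
    chromosome: str
    strand: str
    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    coding_start_exon_index: int = 1
    excluded_exon_indices: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"exon interval ({s}, {e}) has end < start")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1 + 1:  # overlap or zero-length intron
                raise ValueError(
                    f"{self.gene_symbol}: exons ({s1},{e1}) and ({s2},{e2}) "
                    "overlap or leave no intron"
                )
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"{self.gene_symbol}: exons not ordered in transcript orientation"
            )
        bad = self.excluded_exon_indices - set(range(1, self.n_exons + 1))
        if bad:
            raise ValueError(
                f"{self.gene_symbol}: excluded exon indices {sorted(bad)} out of range"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> np.ndarray:
        return np.array([e - s + 1 for s, e in self.exons], dtype=int)

    @property
    def transcript_length(self) -> int:
        return int(self.exon_lengths.sum())

    @property
    def gene_span(self) -> tuple[int, int]:
        """Genomic (min, max) over all exons, 1-based inclusive."""
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    def exon_transcript_span(self, exon_index: int) -> tuple[int, int]:
        """Transcript coordinates (1-based inclusive) occupied by an exon."""
        if not 1 <= exon_index <= self.n_exons:
            raise ValueError(f"exon index {exon_index} out of range")
        cum = np.concatenate([[0], np.cumsum(self.exon_lengths)])
        return int(cum[exon_index - 1] + 1), int(cum[exon_index])

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals (1-based inclusive), in transcript order.

        Intron k lies between exon k and exon k+1.
        """
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out


@dataclass(frozen=True)
class TranscriptPosition:
    """A transcript-space position in r.-style notation.

    Exonic positions have ``offset == 0`` and render as the plain cumulative
    coordinate; intronic positions are anchored to the nearest exon boundary
    and render as ``anchor+offset`` (downstream of a donor) or
    ``anchor-offset`` (upstream of an acceptor).
    """

    anchor: int
    offset: int = 0

    @property
    def is_exonic(self) -> bool:
        return self.offset == 0

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.anchor)
        sign = "+" if self.offset > 0 else "-"
        return f"{self.anchor}{sign}{abs(self.offset)}"


def load_gene_models(annotation_path: str, panel: PanelConfig) -> list[GeneModel]:
    """Load one :class:`GeneModel` per panel gene from a GTF annotation.

    The annotation must contain every ``transcript_id`` named in the panel;
    a missing transcript is a hard error naming the gene. Transcripts with
    fewer than two exons load with a warning (junction analysis is
    degenerate for them).
    """
    db = gffutils.create_db(
        annotation_path,
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons_by_tx: dict[str, list] = {}
    for ex in db.features_of_type("exon"):
        for tx in ex.attributes.get("transcript_id", []):
            exons_by_tx.setdefault(tx, []).append(ex)

    models = []
    for gene in panel.genes:
        feats = exons_by_tx.get(gene.transcript_id)
        if not feats:
            raise ValueError(
                f"transcript {gene.transcript_id!r} for gene "
                f"{gene.gene_symbol!r} not found in {annotation_path}"
            )
        strand = feats[0].strand
        chrom = feats[0].seqid
        intervals = sorted((f.start, f.end) for f in feats)
        if strand == "-":
            intervals = intervals[::-1]
        if len(intervals) < 2:
            warnings.warn(
                f"{gene.gene_symbol}: reference isoform has "
                f"{len(intervals)} exon(s); junction analysis is degenerate"
            )
        models.append(
            GeneModel(
                gene_symbol=gene.gene_symbol,
                chromosome=chrom,
                strand=strand,
                transcript_id=gene.transcript_id,
                exons=tuple(intervals),
                excluded_exon_indices=gene.excluded_exon_indices,
            )
        )
    return models


def _exon_arrays(model: GeneModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """0-based half-open exon bounds plus cumulative transcript offsets."""
    starts0 = np.array([s - 1 for s, _ in model.exons], dtype=int)
    ends0 = np.array([e for _, e in model.exons], dtype=int)
    cum = np.concatenate([[0], np.cumsum(ends0 - starts0)])
    return starts0, ends0, cum


def genomic_to_transcript(model: GeneModel, genomic_pos: int) -> TranscriptPosition:
    """Map a genomic position (1-based) to transcript coordinates.

    Exonic bases map to the cumulative transcript position (the first base
    of exon 1 is position 1). Intronic bases map to nearest-boundary offset
    notation: ``n+k`` for the k-th base downstream of the donor whose exon
    ends at transcript position n, ``n-k`` for the k-th base upstream of
    the acceptor whose exon starts at transcript position n. Ties at the
    intron midpoint anchor to the donor side.
    """
    lo, hi = model.gene_span
    if not lo <= genomic_pos <= hi:
        raise ValueError(
            f"position {genomic_pos} outside span of {model.gene_symbol} [{lo}, {hi}]"
        )
    starts0, ends0, cum = _exon_arrays(model)
    pos0 = genomic_pos - 1
    for i in range(model.n_exons):
        if starts0[i] <= pos0 < ends0[i]:
            if model.strand == "+":
                return TranscriptPosition(int(cum[i] + (pos0 - starts0[i]) + 1))
            return TranscriptPosition(int(cum[i] + (ends0[i] - 1 - pos0) + 1))
    # intronic: locate the intron in transcript order
    for k, (istart, iend) in enumerate(model.introns(), start=1):
        if istart <= genomic_pos <= iend:
            if model.strand == "+":
                from_donor = genomic_pos - istart + 1
                from_acceptor = iend - genomic_pos + 1
            else:
                from_donor = iend - genomic_pos + 1
                from_acceptor = genomic_pos - istart + 1
            donor_t = model.exon_transcript_span(k)[1]
            acceptor_t = model.exon_transcript_span(k + 1)[0]
            if from_donor <= from_acceptor:
                return TranscriptPosition(donor_t, from_donor)
            return TranscriptPosition(acceptor_t, -from_acceptor)
    raise ValueError(
        f"position {genomic_pos} in {model.gene_symbol} span but in no exon or intron"
    )


def transcript_to_genomic(model: GeneModel, tpos: TranscriptPosition | int) -> int:
    """Inverse of :func:`genomic_to_transcript`; exact for all positions."""
    if isinstance(tpos, int):
        tpos = TranscriptPosition(tpos)
    if not 1 <= tpos.anchor <= model.transcript_length:
        raise ValueError(f"transcript position {tpos.anchor} out of range")
    starts0, ends0, cum = _exon_arrays(model)
    i = int(np.searchsorted(cum, tpos.anchor, side="left")) - 1
    within = tpos.anchor - cum[i] - 1  # 0-based offset inside exon i
    if model.strand == "+":
        genomic = int(starts0[i] + within + 1 + tpos.offset)
    else:
        genomic = int(ends0[i] - within - tpos.offset)
    lo, hi = model.gene_span
    if not lo <= genomic <= hi:
        raise ValueError(f"{tpos} maps outside the gene span")
    return genomic
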