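"""Percent-spliced-in (PSI) quantification of classified events.

PSI of an event in a sample is the percentage of reads in the event's
region that support the alternative (non-canonical) outcome:

    PSI = 100 * alt_reads / region_reads

``region_reads`` is the alternative read count plus the canonical support,
taken as the rounded mean of uniquely-mapping read counts over the
canonical junctions the event replaces — one junction for an alternative
donor/acceptor (ESP) or intronic extension (IP), the k+1 junctions spanned
by a k-exon skip (ESF), and the host intron's canonical junction for a
cryptic exon (IC). Averaging over the replaced junctions avoids counting a
single canonical molecule several times when the event spans more than one
junction, and reduces to alt/(alt + canonical) in the single-junction case.

For IC events (two supporting junctions, one per cryptic-exon flank) the
alternative count is likewise the rounded mean of the two flank junctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .event_engine import SpliceEvent
from .junction_io import JunctionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "EventQuantification",
    "junction_counts",
    "region_reads",
    "compute_psi",
    "quantify_events",
]


@dataclass(frozen=True)
class EventQuantification:
    """Read support and PSI for one event in one sample.

    ``psi`` is a percentage in [0, 100]; when ``region_reads == 0`` the
    value is not assessable and ``assessable`` is False (psi reported 0).
    """

    sample_id: str
    event_key: tuple[str, str]  # (gene_symbol, event name)
    alt_reads: int
    region_reads: int
    psi: float
    assessable: bool = True

    def __post_init__(self) -> None:
        if self.alt_reads < 0 or self.region_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.region_reads:
            raise ValueError("alt_reads cannot exceed region_reads")
        if self.assessable and not 0.0 <= self.psi <= 100.0:
            raise ValueError("psi must lie in [0, 100]")


def junction_counts(junctions: list[JunctionRecord]) -> dict[tuple[str, int, int], int]:
    """Uniquely-mapping read counts keyed by (chrom, intron_start, intron_end).

    Strand is dropped from the key: strand compatibility was already
    enforced during classification, and STAR emits undefined-strand rows
    for non-canonical motifs. Duplicate coordinates are summed.
    """
    counts: dict[tuple[str, int, int], int] = {}
    for j in junctions:
        k = (j.chromosome, j.intron_start, j.intron_end)
        counts[k] = counts.get(k, 0) + j.unique_reads
    return counts


def _rounded_mean(values: list[int]) -> int:
    if not values:
        return 0
    return int(sum(values) / len(values) + 0.5)


def _alt_reads(e: SpliceEvent, counts) -> int:
    support = [counts.get(k[:3], 0) for k in e.supporting_junctions]
    if e.event_type == "IC":
        return _rounded_mean(support)
    return support[0]


def region_reads(e: SpliceEvent, junctions: list[JunctionRecord]) -> int:
    """Total reads in the event's region: alternative + canonical support.

    Canonical support is the rounded mean of unique read counts over the
    event's denominator (canonical) junctions; absent junctions count 0.
    """
    counts = junction_counts(junctions)
    alt = _alt_reads(e, counts)
    canon = _rounded_mean([counts.get(k[:3], 0) for k in e.denominator_junctions])
    return alt + canon


def compute_psi(
    e: SpliceEvent, junctions: list[JunctionRecord], sample_id: str = ""
) -> EventQuantification:
    """Quantify one event in one sample.

    PSI is stored unrounded (round only for display); a region with zero
    reads yields a flagged, non-assessable quantification.
    """
    counts = junction_counts(junctions)
    alt = _alt_reads(e, counts)
    canon = _rounded_mean([counts.get(k[:3], 0) for k in e.denominator_junctions])
    region = alt + canon
    if region == 0:
        return EventQuantification(
            sample_id=sample_id, event_key=e.key, alt_reads=0,
            region_reads=0, psi=0.0, assessable=False,
        )
    return EventQuantification(
        sample_id=sample_id,
        event_key=e.key,
        alt_reads=alt,
        region_reads=region,
        psi=100.0 * alt / region,
    )


def quantify_events(
    events: list[SpliceEvent], junctions: list[JunctionRecord], sample_id: str = ""
) -> list[EventQuantification]:
    """Quantify every event of a sample; events without a single supporting
    unique read are not emitted (PSI 0 is equivalent to absent)."""
    counts = junction_counts(junctions)
    out = []
    for e in events:
        if _alt_reads(e, counts) < 1:
            continue
        out.append(compute_psi(e, junctions, sample_id=sample_id))
    return out
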