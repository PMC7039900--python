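"""Classification of observed splice junctions against a reference isoform.

Every junction is an excised genomic interval. Comparing its two attachment
points (the exonic bases flanking the excision) with the reference exon
boundaries yields the event taxonomy:

* ``ESF`` — full exon skipping: both ends at canonical boundaries of
  non-adjacent exons; every exon in between is skipped entirely.
* ``ESP`` — partial exon skipping (alternative donor/acceptor inside an
  exon): one end canonical, the other strictly inside an exon.
* ``ES``  — reporting aggregate combining the full and partial skipping
  events of the same exon(s).
* ``IP``  — partial intronic insertion: one end canonical, the other
  strictly inside the adjoining intron, extending the neighbouring exon
  into the intron.
* ``IC``  — cryptic exon: two intron-anchored junctions delimiting a
  non-empty intronic segment that is spliced in as a novel exon.

A junction whose far end lies inside the adjoining intron is inherently
ambiguous between IP and one flank of a cryptic exon; junction counts alone
cannot distinguish a retained stretch from a re-spliced one. The pairing
pass therefore upgrades donor-anchored + acceptor-anchored candidates
within the same intron to a single IC when their implied cryptic interval
is non-empty, and leaves unpaired candidates as IP.

Frame status is a pure function of the net length change:
in-frame iff (inserted_length - deleted_length) mod 3 == 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .gene_models import GeneModel, genomic_to_transcript
from .junction_io import JunctionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SpliceEvent",
    "EsAggregate",
    "ClassifiedJunction",
    "frame_status",
    "canonical_junctions",
    "classify_junction",
    "pair_cryptic_exons",
    "merge_es",
    "name_event",
    "detect_events",
    "intersects_excluded",
]

JunctionKey = tuple[str, int, int, str]


def frame_status(inserted_length: int, deleted_length: int) -> str:
    return "in-frame" if (inserted_length - deleted_length) % 3 == 0 else "frameshift"


@dataclass(frozen=True)
class SpliceEvent:
    """A classified non-canonical splicing event on one reference isoform.

    ``skipped_exon_indices`` lists every affected exon in transcript order:
    fully skipped exons for ESF, fully skipped plus the truncated exon for
    ESP, empty for intronic insertions (IP/IC).
    """

    gene_symbol: str
    event_type: str  # ESF, ESP, IC, IP
    skipped_exon_indices: tuple[int, ...]
    affected_genomic_span: tuple[int, int]
    inserted_length: int
    deleted_length: int
    frame_status: str
    name: str
    denominator_junctions: tuple[JunctionKey, ...]
    supporting_junctions: tuple[JunctionKey, ...]

    def __post_init__(self) -> None:
        if self.event_type not in ("ESF", "ESP", "IC", "IP"):
            raise ValueError(f"invalid event_type {self.event_type!r}")
        if self.event_type == "IC" and len(self.supporting_junctions) != 2:
            raise ValueError("IC events need exactly 2 supporting junctions")
        if self.event_type != "IC" and len(self.supporting_junctions) != 1:
            raise ValueError(
                f"{self.event_type} events need exactly 1 supporting junction"
            )
        expect = frame_status(self.inserted_length, self.deleted_length)
        if self.frame_status != expect:
            raise ValueError("frame_status inconsistent with length change")

    @property
    def key(self) -> tuple[str, str]:
        """Stable identity used across samples: (gene, deterministic name)."""
        return (self.gene_symbol, self.name)


@dataclass(frozen=True)
class EsAggregate:
    """Reporting aggregate: full + partial skipping events of the same exon(s)."""

    gene_symbol: str
    exon_indices: tuple[int, ...]
    components: tuple[SpliceEvent, ...]

    @property
    def name(self) -> str:
        exons = ",".join(str(i) for i in self.exon_indices)
        return f"ES:{self.gene_symbol}:exon{exons}"


@dataclass(frozen=True)
class ClassifiedJunction:
    """Outcome of classifying one junction: canonical, an event, or unassigned."""

    junction: JunctionRecord
    kind: str  # 'canonical' | 'event' | 'unassigned'
    event: SpliceEvent | None = None
    reason: str = ""


def canonical_junctions(model: GeneModel) -> set[JunctionKey]:
    """Junction keys of all n-1 canonical introns of the reference isoform."""
    return {(model.chromosome, s, e, model.strand) for s, e in model.introns()}


# ---------------------------------------------------------------------------
# geometry helpers (genomic-sorted exon indices, 0-based)

def _genomic_exons(model: GeneModel) -> list[tuple[int, int]]:
    return sorted(model.exons)


def _g_to_t(model: GeneModel, g: int) -> int:
    """Genomic-sorted exon index (0-based) -> transcript exon index (1-based)."""
    return g + 1 if model.strand == "+" else model.n_exons - g


def _intron_key(model: GeneModel, g_intron: int) -> JunctionKey:
    """Canonical junction key for the intron between genomic-sorted exons
    ``g_intron`` and ``g_intron + 1`` (0-based)."""
    gex = _genomic_exons(model)
    return (
        model.chromosome,
        gex[g_intron][1] + 1,
        gex[g_intron + 1][0] - 1,
        model.strand,
    )


def _locate_end(model: GeneModel, attach: int, side: str) -> tuple[str, int]:
    """Categorize one attachment point (the base flanking the excision).

    ``side`` is 'left' (attach = intron_start - 1) or 'right'
    (attach = intron_end + 1). Returns ('canonical'|'exon'|'intron'|'outside',
    genomic-sorted index). Coinciding with a canonical boundary always wins
    over an interior interpretation.
    """
    gex = _genomic_exons(model)
    for g, (es, ee) in enumerate(gex):
        if side == "left" and attach == ee:
            return ("canonical", g)
        if side == "right" and attach == es:
            return ("canonical", g)
        if es <= attach <= ee:
            return ("exon", g)
    for k in range(len(gex) - 1):
        if gex[k][1] < attach < gex[k + 1][0]:
            return ("intron", k)
    return ("outside", -1)


# ---------------------------------------------------------------------------
# per-junction classification

def classify_junction(j: JunctionRecord, model: GeneModel) -> ClassifiedJunction:
    """Classify one observed junction against the reference isoform.

    Returns a canonical match, a classified event (ESF/ESP/IP), or an
    unassigned junction with a reason. Intron-interior candidates classify
    provisionally as IP; :func:`pair_cryptic_exons` may upgrade them to IC.
    """
    if j.chromosome != model.chromosome:
        return ClassifiedJunction(j, "unassigned", reason="different chromosome")
    if j.strand not in ("undefined", model.strand):
        return ClassifiedJunction(j, "unassigned", reason="wrong strand")
    lo, hi = model.gene_span
    if j.intron_end < lo or j.intron_start > hi:
        return ClassifiedJunction(j, "unassigned", reason="outside gene span")

    gex = _genomic_exons(model)
    jkey: JunctionKey = (model.chromosome, j.intron_start, j.intron_end, model.strand)
    left = _locate_end(model, j.intron_start - 1, "left")
    right = _locate_end(model, j.intron_end + 1, "right")

    if left[0] == "outside" or right[0] == "outside":
        return ClassifiedJunction(j, "unassigned", reason="end outside gene span")

    if left[0] == "canonical" and right[0] == "canonical":
        a, b = left[1], right[1]
        if b == a + 1:
            return ClassifiedJunction(j, "canonical")
        skipped_g = list(range(a + 1, b))
        skipped_t = sorted(_g_to_t(model, g) for g in skipped_g)
        deleted = sum(gex[g][1] - gex[g][0] + 1 for g in skipped_g)
        event = SpliceEvent(
            gene_symbol=model.gene_symbol,
            event_type="ESF",
            skipped_exon_indices=tuple(skipped_t),
            affected_genomic_span=(gex[a + 1][0], gex[b - 1][1]),
            inserted_length=0,
            deleted_length=deleted,
            frame_status=frame_status(0, deleted),
            name="",
            denominator_junctions=tuple(_intron_key(model, k) for k in range(a, b)),
            supporting_junctions=(jkey,),
        )
        return ClassifiedJunction(j, "event", event=_named(event, model))

    if left[0] == "canonical" and right[0] == "exon":
        a, b = left[1], right[1]
        if b <= a:
            return ClassifiedJunction(j, "unassigned", reason="inconsistent geometry")
        partial_span = (gex[b][0], j.intron_end)  # truncated exonic bases
        return _esp(j, model, jkey, list(range(a + 1, b)), b, partial_span,
                    list(range(a, b)))

    if left[0] == "exon" and right[0] == "canonical":
        a, b = left[1], right[1]
        if b <= a:
            return ClassifiedJunction(j, "unassigned", reason="inconsistent geometry")
        partial_span = (j.intron_start, gex[a][1])
        return _esp(j, model, jkey, list(range(a + 1, b)), a, partial_span,
                    list(range(a, b)))

    if left[0] == "canonical" and right[0] == "intron":
        a, k = left[1], right[1]
        if k != a:
            return ClassifiedJunction(
                j, "unassigned", reason="far end in non-adjacent intron"
            )
        retained = (j.intron_end + 1, gex[a + 1][0] - 1)
        return _ip(j, model, jkey, k, retained)

    if left[0] == "intron" and right[0] == "canonical":
        k, b = left[1], right[1]
        if k != b - 1:
            return ClassifiedJunction(
                j, "unassigned", reason="far end in non-adjacent intron"
            )
        retained = (gex[b - 1][1] + 1, j.intron_start - 1)
        return _ip(j, model, jkey, k, retained)

    if left[0] == "exon" and right[0] == "exon":
        return ClassifiedJunction(
            j, "unassigned", reason="both ends inside exons (exitron-like)"
        )
    return ClassifiedJunction(j, "unassigned", reason="no canonical anchor")


def _esp(j, model, jkey, skipped_g, partial_g, partial_span, introns):
    gex = _genomic_exons(model)
    deleted_partial = partial_span[1] - partial_span[0] + 1
    deleted = deleted_partial + sum(gex[g][1] - gex[g][0] + 1 for g in skipped_g)
    affected_t = sorted(_g_to_t(model, g) for g in skipped_g + [partial_g])
    event = SpliceEvent(
        gene_symbol=model.gene_symbol,
        event_type="ESP",
        skipped_exon_indices=tuple(affected_t),
        affected_genomic_span=(j.intron_start, j.intron_end),
        inserted_length=0,
        deleted_length=deleted,
        frame_status=frame_status(0, deleted),
        name="",
        denominator_junctions=tuple(_intron_key(model, k) for k in introns),
        supporting_junctions=(jkey,),
    )
    return ClassifiedJunction(
        j, "event",
        event=_named(event, model, esp_partial=(partial_g, partial_span)),
    )


def _ip(j, model, jkey, host_intron, retained):
    inserted = retained[1] - retained[0] + 1
    if inserted < 1:
        return ClassifiedJunction(j, "unassigned", reason="empty intronic retention")
    event = SpliceEvent(
        gene_symbol=model.gene_symbol,
        event_type="IP",
        skipped_exon_indices=(),
        affected_genomic_span=retained,
        inserted_length=inserted,
        deleted_length=0,
        frame_status=frame_status(inserted, 0),
        name="",
        denominator_junctions=(_intron_key(model, host_intron),),
        supporting_junctions=(jkey,),
    )
    return ClassifiedJunction(j, "event", event=_named(event, model))


def pair_cryptic_exons(
    unassigned: list[JunctionRecord], model: GeneModel
) -> list[SpliceEvent]:
    """Pair intron-anchored junctions into cryptic-exon (IC) events.

    A junction ending inside intron k (anchored at the genomically upstream
    exon's canonical boundary) pairs with a junction starting inside intron
    k (anchored at the downstream boundary); the implied cryptic exon is
    the intronic interval strictly between them and must be non-empty.
    Every compatible pair yields one IC; unpaired candidates are untouched.
    """
    left_anchored: dict[int, list[JunctionRecord]] = {}
    right_anchored: dict[int, list[JunctionRecord]] = {}
    for j in unassigned:
        if j.chromosome != model.chromosome:
            continue
        if j.strand not in ("undefined", model.strand):
            continue
        left = _locate_end(model, j.intron_start - 1, "left")
        right = _locate_end(model, j.intron_end + 1, "right")
        if left[0] == "canonical" and right[0] == "intron" and right[1] == left[1]:
            left_anchored.setdefault(left[1], []).append(j)
        elif right[0] == "canonical" and left[0] == "intron" and left[1] == right[1] - 1:
            right_anchored.setdefault(left[1], []).append(j)

    events = []
    for k in sorted(set(left_anchored) & set(right_anchored)):
        for ja in sorted(left_anchored[k], key=lambda j: j.intron_end):
            for jb in sorted(right_anchored[k], key=lambda j: j.intron_start):
                c_start, c_end = ja.intron_end + 1, jb.intron_start - 1
                if c_end < c_start:
                    continue  # empty implied interval
                inserted = c_end - c_start + 1
                event = SpliceEvent(
                    gene_symbol=model.gene_symbol,
                    event_type="IC",
                    skipped_exon_indices=(),
                    affected_genomic_span=(c_start, c_end),
                    inserted_length=inserted,
                    deleted_length=0,
                    frame_status=frame_status(inserted, 0),
                    name="",
                    denominator_junctions=(_intron_key(model, k),),
                    supporting_junctions=(
                        (model.chromosome, ja.intron_start, ja.intron_end, model.strand),
                        (model.chromosome, jb.intron_start, jb.intron_end, model.strand),
                    ),
                )
                events.append(_named(event, model))
    return events


def merge_es(events: list[SpliceEvent]) -> list[EsAggregate]:
    """Combine ESF and ESP events affecting the same exon(s) into ES rows."""
    groups: dict[tuple[str, tuple[int, ...]], list[SpliceEvent]] = {}
    for e in events:
        if e.event_type not in ("ESF", "ESP"):
            continue
        key = (e.gene_symbol, tuple(sorted(set(e.skipped_exon_indices))))
        groups.setdefault(key, []).append(e)
    return [
        EsAggregate(gene_symbol=g, exon_indices=x, components=tuple(evts))
        for (g, x), evts in sorted(groups.items())
    ]


def intersects_excluded(e: SpliceEvent, model: GeneModel) -> bool:
    """True when the event's span or skipped exons touch an excluded exon."""
    if not model.excluded_exon_indices:
        return False
    if set(e.skipped_exon_indices) & model.excluded_exon_indices:
        return True
    s, en = e.affected_genomic_span
    for idx in model.excluded_exon_indices:
        es, ee = model.exons[idx - 1]
        if s <= ee and es <= en:
            return True
    return False


# ---------------------------------------------------------------------------
# deterministic r.-style naming

def name_event(e: SpliceEvent, model: GeneModel) -> str:
    """Deterministic r.-style label in transcript coordinates.

    Deletions render as ``r.<first>_<last>del``; intronic insertions as
    ``r.<left>_<right>ins<start>_<end>`` with the inserted interval's ends
    in nearest-boundary offset notation. Events touching excluded exons are
    an error (they should have been filtered upstream).
    """
    if intersects_excluded(e, model):
        raise ValueError(
            f"{e.gene_symbol}: event touches excluded exon(s) "
            f"{sorted(model.excluded_exon_indices)}"
        )
    return _name(e, model)


def _name(e: SpliceEvent, model: GeneModel, esp_partial=None) -> str:
    if e.event_type in ("ESF", "ESP"):
        first, last = _deleted_transcript_range(e, model, esp_partial)
        return f"r.{first}_{last}del"
    # IP / IC: inserted intronic interval, ends in transcript orientation
    a, b = e.affected_genomic_span
    ta, tb = genomic_to_transcript(model, a), genomic_to_transcript(model, b)
    if model.strand == "-":
        ta, tb = tb, ta
    # the insertion sits between adjacent exonic transcript positions n, n+1
    left_flank = min(p.anchor if p.offset > 0 else p.anchor - 1 for p in (ta, tb))
    return f"r.{left_flank}_{left_flank + 1}ins{ta}_{tb}"


def _deleted_transcript_range(e, model, esp_partial=None):
    """Transcript-coordinate extent of the deleted bases of a skip event."""
    if e.event_type == "ESP" and esp_partial is None:
        esp_partial = _esp_partial_from_span(e, model)
    positions: list[int] = []
    full_exons = set(e.skipped_exon_indices)
    if esp_partial is not None:
        partial_g, partial_span = esp_partial
        full_exons -= {_g_to_t(model, partial_g)}
        for g in partial_span:
            tp = genomic_to_transcript(model, g)
            if not tp.is_exonic:
                raise ValueError("partial-skip endpoint not exonic")
            positions.append(tp.anchor)
    for t in full_exons:
        a, b = model.exon_transcript_span(t)
        positions.extend((a, b))
    return min(positions), max(positions)


def _esp_partial_from_span(e: SpliceEvent, model: GeneModel):
    """Recover (genomic exon index, truncated exonic interval) of a partial skip."""
    s, en = e.affected_genomic_span
    gex = _genomic_exons(model)
    for g, (es, ee) in enumerate(gex):
        if es <= s <= ee:
            return g, (s, min(en, ee))
        if es <= en <= ee:
            return g, (max(s, es), en)
    raise ValueError("partial-skip span touches no exon")


def _named(event: SpliceEvent, model: GeneModel, esp_partial=None) -> SpliceEvent:
    return replace(event, name=_name(event, model, esp_partial))


# ---------------------------------------------------------------------------
# orchestration

def detect_events(
    junctions: list[JunctionRecord], model: GeneModel, drop_excluded: bool = True
) -> tuple[list[SpliceEvent], list[ClassifiedJunction]]:
    """Full per-gene classification pass.

    Classifies every junction, pairs cryptic exons (consuming the
    provisional IP interpretation of paired junctions), and optionally
    drops events touching excluded exons. Returns the event list and the
    per-junction classification audit trail.
    """
    classified = [classify_junction(j, model) for j in junctions]
    ip_candidates = [
        c.junction
        for c in classified
        if c.kind == "event" and c.event.event_type == "IP"
    ]
    ics = pair_cryptic_exons(ip_candidates, model)
    consumed = {k for ic in ics for k in ic.supporting_junctions}

    events: list[SpliceEvent] = []
    for c in classified:
        if c.kind != "event":
            continue
        if c.event.event_type == "IP" and c.event.supporting_junctions[0] in consumed:
            continue  # explained by a cryptic exon
        events.append(c.event)
    events.extend(ics)

    if drop_excluded:
        kept = []
        for e in events:
            if intersects_excluded(e, model):
                logger.debug("dropping %s (touches excluded exon)", e.name)
                continue
            kept.append(e)
        events = kept
    return events, classified
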