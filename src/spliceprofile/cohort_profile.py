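"""Sample QC and the healthy-control reference splicing profile.

A control cohort quantified over the panel yields, per event, two parallel
summaries used downstream:

* detected-only median and interquartile range (what a reviewer sees in a
  reference table: the typical PSI among carriers of the event), and
* mean and SD over *all* QC-passing controls with PSI 0 assigned to
  samples in which the event was not detected (the vector the one-sample
  t-test runs against).

Coverage QC follows the panel thresholds: a sample passes when at least
``min_exon_fraction`` (default 85%) of the panel's non-excluded exons have
mean depth >= ``min_exon_depth`` (default 50x), both thresholds inclusive.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gene_models import GeneModel, PanelConfig
from .junction_io import ExonCoverageRecord
from .quantify import EventQuantification

logger = logging.getLogger(__name__)

__all__ = [
    "SampleQC",
    "SeqMetrics",
    "EventStats",
    "ControlProfile",
    "coverage_qc",
    "build_profile",
    "common_events",
    "per_sample_event_count",
    "per_gene_median_event_count",
    "exon_count_correlation",
    "group_event_count_tests",
]


@dataclass(frozen=True)
class SeqMetrics:
    """Sequencing-level QC metrics, precomputed upstream of this package."""

    q30_fraction: float
    mean_base_quality: float
    perfect_index_fraction: float

    def passes(self) -> bool:
        return (
            self.q30_fraction > 0.75
            and self.mean_base_quality > 30
            and self.perfect_index_fraction > 0.85
        )


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    fraction_exons_at_depth: float
    passed: bool
    seq_metrics: SeqMetrics | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_exons_at_depth <= 1.0:
            raise ValueError("fraction_exons_at_depth must be in [0, 1]")


def coverage_qc(
    cov: list[ExonCoverageRecord],
    panel: PanelConfig,
    models: list[GeneModel],
    sample_id: str = "",
    seq_metrics: SeqMetrics | None = None,
) -> SampleQC:
    """Coverage QC over the panel's non-excluded exons.

    Exons missing from the coverage table count as depth 0. The sample
    passes iff the fraction of exons at or above ``min_exon_depth`` is at
    least ``min_exon_fraction`` (inclusive), and, when sequencing metrics
    are supplied, those pass as well.
    """
    depth = {(r.gene_symbol, r.exon_index): r.mean_depth for r in cov}
    n_total = 0
    n_ok = 0
    for m in models:
        for idx in range(1, m.n_exons + 1):
            if idx in m.excluded_exon_indices:
                continue
            n_total += 1
            if depth.get((m.gene_symbol, idx), 0.0) >= panel.min_exon_depth:
                n_ok += 1
    frac = n_ok / n_total if n_total else 0.0
    passed = frac >= panel.min_exon_fraction
    if seq_metrics is not None:
        passed = passed and seq_metrics.passes()
    return SampleQC(
        sample_id=sample_id,
        fraction_exons_at_depth=frac,
        passed=passed,
        seq_metrics=seq_metrics,
    )


@dataclass(frozen=True)
class EventStats:
    """Per-event summary across the control cohort."""

    event_key: tuple[str, str]
    n_controls_total: int
    n_detected: int
    detection_frequency: float
    median_psi: float  # over detected controls only
    iqr_low: float
    iqr_high: float
    mean_psi: float  # over all controls, zeros assigned
    sd_psi: float
    psi_vector: tuple[float, ...]  # zero-assigned, length n_controls_total


@dataclass(frozen=True)
class ControlProfile:
    """Reference splicing profile: one :class:`EventStats` per event seen in
    at least one control; events seen in no control are absent (patients may
    still present novel events, tested against an all-zero vector)."""

    sample_ids: tuple[str, ...]
    events: dict[tuple[str, str], EventStats] = field(default_factory=dict)

    @property
    def n_controls(self) -> int:
        return len(self.sample_ids)

    def psi_matrix(self) -> pd.DataFrame:
        """Events x samples PSI matrix with zeros assigned (for export)."""
        return pd.DataFrame(
            {
                "|".join(k): list(st.psi_vector)
                for k, st in sorted(self.events.items())
            },
            index=list(self.sample_ids),
        ).T

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (gene, name), st in sorted(self.events.items()):
            rows.append(
                {
                    "gene": gene,
                    "event": name,
                    "n_controls_total": st.n_controls_total,
                    "n_detected": st.n_detected,
                    "detection_frequency": st.detection_frequency,
                    "median_psi": st.median_psi,
                    "iqr_low": st.iqr_low,
                    "iqr_high": st.iqr_high,
                    "mean_psi": st.mean_psi,
                    "sd_psi": st.sd_psi,
                }
            )
        return pd.DataFrame(rows)


def build_profile(
    quants: dict[str, list[EventQuantification]]
) -> ControlProfile:
    """Build the reference profile from per-control quantifications.

    ``quants`` maps sample id -> that control's event quantifications (all
    contributing samples are expected to have passed QC). Detected means
    PSI > 0 in that control. Fewer than two controls is an error: the
    downstream test needs a variance.
    """
    sample_ids = tuple(quants.keys())
    n = len(sample_ids)
    if n < 2:
        raise ValueError(f"need >=2 QC-passing controls, got {n}")

    by_event: dict[tuple[str, str], dict[str, float]] = {}
    for sid, qlist in quants.items():
        for q in qlist:
            if not q.assessable:
                continue
            by_event.setdefault(q.event_key, {})[sid] = q.psi

    events = {}
    for key, per_sample in by_event.items():
        vec = np.array([per_sample.get(sid, 0.0) for sid in sample_ids])
        detected = vec[vec > 0]
        if detected.size == 0:
            continue  # observed in zero controls: absent from profile
        q1, med, q3 = np.percentile(detected, [25, 50, 75])
        events[key] = EventStats(
            event_key=key,
            n_controls_total=n,
            n_detected=int(detected.size),
            detection_frequency=detected.size / n,
            median_psi=float(med),
            iqr_low=float(q1),
            iqr_high=float(q3),
            mean_psi=float(vec.mean()),
            sd_psi=float(vec.std(ddof=1)),
            psi_vector=tuple(float(x) for x in vec),
        )
    return ControlProfile(sample_ids=sample_ids, events=events)


def common_events(
    profile: ControlProfile, psi_min: float = 5.0, freq_min: float = 0.05,
    strict: bool = False,
) -> list[tuple[str, str]]:
    """Events common to the healthy population.

    An event is retained iff the number of controls with PSI >= ``psi_min``
    reaches the count threshold floor(freq_min * n_controls) — with
    n = 345 and freq_min = 0.05 that threshold is 17. ``strict=True``
    instead requires the exact fraction (ceil), i.e. 18 of 345.
    """
    n = profile.n_controls
    thr = int(np.ceil(freq_min * n)) if strict else int(np.floor(freq_min * n))
    out = []
    for key, st in sorted(profile.events.items()):
        n_at = sum(1 for p in st.psi_vector if p >= psi_min)
        if n_at >= thr:
            out.append(key)
    return out


def per_sample_event_count(
    quants: list[EventQuantification],
    psi_min: float = 5.0,
    min_region_reads: int = 50,
) -> int:
    """Number of events detected in one sample at PSI >= ``psi_min`` with
    region coverage >= ``min_region_reads``."""
    return sum(
        1
        for q in quants
        if q.assessable and q.psi >= psi_min and q.region_reads >= min_region_reads
    )


def per_gene_median_event_count(
    quants_by_sample: dict[str, list[EventQuantification]],
    psi_min: float = 5.0,
    min_region_reads: int = 50,
) -> dict[str, float]:
    """Median (across samples) of the per-sample detected-event count, per
    gene, at the detection gates used throughout (PSI and region coverage)."""
    genes = sorted({q.event_key[0] for ql in quants_by_sample.values() for q in ql})
    out = {}
    for g in genes:
        counts = [
            per_sample_event_count(
                [q for q in ql if q.event_key[0] == g],
                psi_min=psi_min, min_region_reads=min_region_reads,
            )
            for ql in quants_by_sample.values()
        ]
        out[g] = float(np.median(counts))
    return out


def exon_count_correlation(
    per_gene_median_count: dict[str, float], models: list[GeneModel]
) -> tuple[float, float]:
    """Pearson correlation between per-gene median event count and exon count.

    Returns (r, two-sided p from the t transform). Requires >=3 genes; a
    zero-variance vector makes the coefficient undefined (NaN, NaN, with a
    warning).
    """
    genes = [m.gene_symbol for m in models if m.gene_symbol in per_gene_median_count]
    if len(genes) < 3:
        raise ValueError("need >=3 genes for a correlation")
    x = np.array([per_gene_median_count[g] for g in genes], dtype=float)
    y = np.array(
        [float(m.n_exons) for m in models if m.gene_symbol in per_gene_median_count],
        dtype=float,
    )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: Pearson correlation undefined")
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def group_event_count_tests(
    counts_by_group: dict[str, list[float]]
) -> dict[tuple[str, str], float]:
    """Two-sample two-sided t-tests of event counts between all group pairs
    (e.g. metadata strata such as ethnicity). Groups with fewer than two
    samples are skipped with a warning."""
    usable = {}
    for g, vals in counts_by_group.items():
        if len(vals) < 2:
            warnings.warn(f"group {g!r} has <2 samples; skipped")
            continue
        usable[g] = np.asarray(vals, dtype=float)
    out = {}
    for g1, g2 in itertools.combinations(sorted(usable), 2):
        res = stats.ttest_ind(usable[g1], usable[g2])
        out[(g1, g2)] = float(res.pvalue)
    return out
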