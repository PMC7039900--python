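"""Cohort-level pipeline orchestration and diagnostic-yield reporting.

``run_pipeline`` wires the stages end to end from one JSON configuration:
sample QC -> per-sample event detection and PSI quantification -> control
reference profile -> per-patient aberrant calls, writing TSV outputs plus
a per-sample summary JSON. Given identical inputs the outputs are
byte-identical; every gate decision (sample failed QC, event failed a
coverage or direction gate) is logged.

``diagnostic_yield`` performs the cohort arithmetic for the added value of
RNA evidence: with n_before patients positive on DNA panel testing alone
and n_after positive once RNA evidence is incorporated, the relative
increase is 100 * (n_after - n_before) / n_before percent.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aberrant_calling import call_aberrant
from .cohort_profile import (
    ControlProfile,
    EventStats,
    build_profile,
    common_events,
    coverage_qc,
    per_sample_event_count,
)
from .event_engine import detect_events, merge_es
from .gene_models import PanelConfig, load_gene_models
from .junction_io import read_exon_coverage, read_junctions
from .quantify import quantify_events

logger = logging.getLogger(__name__)

__all__ = ["CohortYield", "diagnostic_yield", "run_pipeline", "profile_from_psi_matrix"]

DEFAULT_THRESHOLDS = {
    "psi_min": 5.0,
    "freq_min": 0.05,
    "min_region_reads": 50,
    "alpha": 0.05,
}


@dataclass(frozen=True)
class CohortYield:
    n_positive_before: int
    n_positive_after: int
    n_rna_attributable: int
    relative_increase_percent: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive_before <= self.n_positive_after:
            raise ValueError("need n_positive_after >= n_positive_before >= 0")
        if self.n_rna_attributable != self.n_positive_after - self.n_positive_before:
            raise ValueError("n_rna_attributable inconsistent")


def diagnostic_yield(n_before: int, n_after: int) -> CohortYield:
    """Relative increase in diagnostic rate from adding RNA evidence,
    reported to one decimal. ``n_before`` must be at least 1."""
    if n_before < 1:
        raise ValueError("n_before must be >= 1 (relative increase undefined)")
    if n_after < n_before:
        raise ValueError("n_after must be >= n_before")
    rel = round(100.0 * (n_after - n_before) / n_before, 1)
    return CohortYield(
        n_positive_before=n_before,
        n_positive_after=n_after,
        n_rna_attributable=n_after - n_before,
        relative_increase_percent=rel,
    )


# ---------------------------------------------------------------------------
# pipeline

def _detect_and_quantify(models, junctions, sample_id):
    quants = []
    events_by_key = {}
    for m in models:
        events, _ = detect_events(junctions, m)
        quants.extend(quantify_events(events, junctions, sample_id=sample_id))
        events_by_key.update({e.key: e for e in events})
    return quants, events_by_key


def _quantify_sample(models, junctions, sample_id):
    return _detect_and_quantify(models, junctions, sample_id)[0]


def _write_event_catalog(events_by_key, path):
    rows = []
    for (gene, name), e in sorted(events_by_key.items()):
        rows.append(
            {
                "gene": gene,
                "event": name,
                "type": e.event_type,
                "frame": e.frame_status,
                "skipped_exons": ",".join(map(str, e.skipped_exon_indices)),
                "span_start": e.affected_genomic_span[0],
                "span_end": e.affected_genomic_span[1],
                "inserted_nt": e.inserted_length,
                "deleted_nt": e.deleted_length,
                "supporting_junctions": ";".join(
                    f"{c}:{s}-{en}:{st}" for c, s, en, st in e.supporting_junctions
                ),
            }
        )
    agg = merge_es(list(events_by_key.values()))
    for a in agg:
        rows.append(
            {
                "gene": a.gene_symbol,
                "event": a.name,
                "type": "ES",
                "frame": "",
                "skipped_exons": ",".join(map(str, a.exon_indices)),
                "span_start": "", "span_end": "",
                "inserted_nt": "", "deleted_nt": "",
                "supporting_junctions": ";".join(c.name for c in a.components),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def profile_from_psi_matrix(path: str) -> ControlProfile:
    """Reconstruct a control profile from an exported zero-assigned PSI
    matrix TSV (rows ``gene|event``, columns samples)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    sample_ids = tuple(mat.columns)
    events = {}
    for row_key, row in mat.iterrows():
        gene, name = str(row_key).split("|", 1)
        vec = row.to_numpy(dtype=float)
        detected = vec[vec > 0]
        if detected.size == 0:
            continue
        q1, med, q3 = np.percentile(detected, [25, 50, 75])
        events[(gene, name)] = EventStats(
            event_key=(gene, name),
            n_controls_total=vec.size,
            n_detected=int(detected.size),
            detection_frequency=detected.size / vec.size,
            median_psi=float(med),
            iqr_low=float(q1),
            iqr_high=float(q3),
            mean_psi=float(vec.mean()),
            sd_psi=float(vec.std(ddof=1)),
            psi_vector=tuple(float(x) for x in vec),
        )
    return ControlProfile(sample_ids=sample_ids, events=events)


def run_pipeline(config: str | dict, stage: str = "all") -> str:
    """Execute QC -> quantify -> profile -> call from a JSON config.

    ``config`` is a path to a JSON file or an equivalent dict with keys
    ``gtf``, ``panel``, ``metadata``, ``junctions_dir``, ``coverage_dir``,
    ``output_dir`` and optional ``thresholds``. ``stage='profile'`` stops
    after the reference profile (no patients required). Returns the output
    directory. Missing input files raise before any output is written.
    """
    if isinstance(config, str):
        with open(config) as fh:
            cfg = json.load(fh)
    else:
        cfg = dict(config)
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}

    meta = pd.read_csv(cfg["metadata"], sep="\t", dtype={"sample_id": str})
    required = [cfg["gtf"], cfg["panel"]]
    sample_files = {}
    for sid in meta["sample_id"]:
        jpath = os.path.join(cfg["junctions_dir"], f"{sid}.SJ.out.tab")
        cpath = os.path.join(cfg["coverage_dir"], f"{sid}.coverage.tsv")
        sample_files[sid] = (jpath, cpath)
        required.extend((jpath, cpath))
    missing = [p for p in required if not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing[:5]}")

    panel = PanelConfig.from_json(cfg["panel"])
    models = load_gene_models(cfg["gtf"], panel)
    outdir = cfg["output_dir"]
    os.makedirs(outdir, exist_ok=True)

    # QC
    qc_rows = []
    passing: dict[str, str] = {}  # sample -> role
    for _, row in meta.iterrows():
        sid = str(row["sample_id"])
        cov = read_exon_coverage(sample_files[sid][1])
        qc = coverage_qc(cov, panel, models, sample_id=sid)
        qc_rows.append(
            {
                "sample_id": sid,
                "role": row["role"],
                "fraction_exons_at_depth": round(qc.fraction_exons_at_depth, 4),
                "pass": qc.passed,
            }
        )
        if qc.passed:
            passing[sid] = str(row["role"])
        else:
            logger.info("sample %s failed coverage QC (%.3f)",
                        sid, qc.fraction_exons_at_depth)
    pd.DataFrame(qc_rows).to_csv(
        os.path.join(outdir, "qc_report.tsv"), sep="\t", index=False
    )
    if not passing:
        raise RuntimeError("all samples failed QC")

    # quantification
    quants_by_sample = {}
    all_events = {}
    for sid in sorted(passing):
        junctions = read_junctions(sample_files[sid][0])
        quants_by_sample[sid], events = _detect_and_quantify(models, junctions, sid)
        all_events.update(events)
    _write_event_catalog(all_events, os.path.join(outdir, "event_catalog.tsv"))

    controls = {s: q for s, q in quants_by_sample.items() if passing[s] == "control"}
    patients = {s: q for s, q in quants_by_sample.items() if passing[s] == "patient"}
    logger.info("QC passed: %d controls, %d patients", len(controls), len(patients))

    profile = build_profile(controls)
    profile.to_frame().to_csv(
        os.path.join(outdir, "control_profile.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )
    mat = profile.psi_matrix()
    mat.to_csv(os.path.join(outdir, "psi_matrix.tsv"), sep="\t", float_format="%.6g")
    common = common_events(
        profile, psi_min=thresholds["psi_min"], freq_min=thresholds["freq_min"]
    )
    with open(os.path.join(outdir, "common_events.tsv"), "w") as fh:
        fh.write("gene\tevent\n")
        for gene, name in common:
            fh.write(f"{gene}\t{name}\n")

    counts = {
        sid: per_sample_event_count(
            q, psi_min=thresholds["psi_min"],
            min_region_reads=thresholds["min_region_reads"],
        )
        for sid, q in controls.items()
    }
    pd.DataFrame(
        {"sample_id": list(counts), "n_events": list(counts.values())}
    ).to_csv(os.path.join(outdir, "control_event_counts.tsv"), sep="\t", index=False)

    if stage == "profile" or not patients:
        return outdir

    # aberrant calling
    call_rows = []
    summary = {}
    for sid, quants in sorted(patients.items()):
        calls = call_aberrant(
            quants, profile,
            alpha=thresholds["alpha"],
            psi_min=thresholds["psi_min"],
            min_region_reads=thresholds["min_region_reads"],
        )
        summary[sid] = {
            "tested": sum(c.tested for c in calls),
            "significant": sum(c.significant for c in calls),
            "novel": sum(c.novel_in_patient for c in calls),
        }
        for c in calls:
            call_rows.append(
                {
                    "sample_id": c.sample_id,
                    "gene": c.event_key[0],
                    "event": c.event_key[1],
                    "patient_psi": round(c.patient_psi, 2),
                    "region_reads": c.patient_region_reads,
                    "control_mean_psi": round(c.control_mean_psi, 4),
                    "control_sd_psi": round(c.control_sd_psi, 4),
                    "n_controls": c.n_controls,
                    "t": round(c.t_statistic, 4) if np.isfinite(c.t_statistic) else c.t_statistic,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "significant": c.significant,
                    "novel_in_patient": c.novel_in_patient,
                    "degenerate": c.degenerate,
                    "tested": c.tested,
                }
            )
    pd.DataFrame(call_rows).to_csv(
        os.path.join(outdir, "aberrant_calls.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
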