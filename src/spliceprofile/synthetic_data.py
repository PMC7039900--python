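"""Seed-reproducible synthetic cohorts with known splicing truth.

The generator emulates the structure of a targeted capture RNA-seq study
of a tumor-suppressor gene panel in whole blood:

* a panel of gene models (one reference isoform each) with realistic exon
  counts and lengths;
* a catalog of *background* alternative-splicing events common in the
  healthy population — each with a population frequency and a Beta-
  distributed per-carrier PSI, mostly low-PSI, plus one ubiquitous
  in-frame partial skip at PSI around 38% emulating the strongest
  constitutive alternative event seen in blood;
* *spike-in* events carried by designated patient samples at elevated PSI
  (20-60%), the signature of a heterozygous splice-disrupting variant;
* junction read counts: per event region a canonical depth D is drawn
  from a negative binomial (overdispersed capture depth), alternative
  reads ~ Binomial(D, PSI/100), and the replaced canonical junctions
  receive D - alt so that the estimated PSI is unbiased for the truth;
* per-exon mean-coverage tables consistent with the junction depths, with
  optional QC-failing samples whose zeroed exons exceed the 85%/50x gate.

Random streams are split per sample and per event from the master seed
(``numpy.random.SeedSequence`` keyed on (seed, purpose, sample, event)),
so adding samples or events never perturbs existing draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .event_engine import detect_events
from .gene_models import GeneModel, PanelConfig, PanelGene
from .junction_io import (
    ExonCoverageRecord,
    JunctionRecord,
    write_exon_coverage,
    write_junctions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "EventTemplate",
    "TruthRecord",
    "Cohort",
    "simulate_models",
    "write_models_gtf",
    "panel_from_models",
    "default_event_catalog",
    "default_spikein_templates",
    "simulate_sample",
    "simulate_cohort",
]

# metadata category frequencies of the emulated control cohort
_ETHNICITIES = (("Caucasian", 0.54), ("Hispanic", 0.13), ("Asian", 0.12),
                ("AfricanAmerican", 0.08), ("Other", 0.13))
_AGE_RANGES = (("30-40", 0.56), ("20-30", 0.20), ("40-50", 0.15), ("50+", 0.09))
_GENDERS = (("F", 0.61), ("M", 0.39))
_N_BATCHES = 12


@dataclass(frozen=True)
class EventTemplate:
    """A concrete simulatable event: its alternative junction(s), the
    canonical junctions it replaces, and its population PSI model."""

    gene_symbol: str
    chromosome: str
    strand: str
    event_type: str
    alt_junctions: tuple[tuple[int, int], ...]
    denominator_introns: tuple[tuple[int, int], ...]
    population_frequency: float
    beta_a: float
    beta_b: float
    event_key: tuple[str, str]  # (gene, deterministic event name)

    def __post_init__(self) -> None:
        if not 0.0 <= self.population_frequency <= 1.0:
            raise ValueError("population_frequency must be in [0, 1]")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta shapes must be positive")

    @property
    def mean_psi(self) -> float:
        return 100.0 * self.beta_a / (self.beta_a + self.beta_b)


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    event_key: tuple[str, str]
    true_psi: float
    is_spikein: bool


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults emulate the emulated study: an 18-gene panel profiled in 345
    healthy controls by deep targeted capture (mean junction depth 500x,
    negative-binomial size 10, i.e. ~32% depth CV across samples).
    """

    seed: int = 0
    n_genes: int = 18
    exon_count_range: tuple[int, int] = (8, 45)
    exon_length_range: tuple[int, int] = (60, 250)
    intron_length_range: tuple[int, int] = (300, 3000)
    n_controls: int = 345
    n_patients: int = 10
    coverage_mean: float = 500.0
    coverage_dispersion: float = 10.0  # NB size; variance = m + m^2/size
    qc_fail_fraction: float = 0.0
    spikein_psi_range: tuple[float, float] = (20.0, 60.0)
    n_spikein_templates: int = 4

    def __post_init__(self) -> None:
        for lo, hi in (self.exon_count_range, self.exon_length_range,
                       self.intron_length_range):
            if lo < 1 or hi < lo:
                raise ValueError("degenerate simulation range")
        if self.exon_count_range[0] < 2:
            raise ValueError("genes need >=2 exons for junction analysis")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage model parameters must be positive")
        if not 0.0 <= self.qc_fail_fraction <= 1.0:
            raise ValueError("qc_fail_fraction must be in [0, 1]")


def _rng(cfg: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed,) + key))


# ---------------------------------------------------------------------------
# gene models

def simulate_models(cfg: SimulationConfig) -> list[GeneModel]:
    """Simulate the panel's reference isoforms, one gene per chromosome,
    alternating strands; deterministic under a fixed seed."""
    rng = _rng(cfg, 0)
    models = []
    for i in range(cfg.n_genes):
        n_ex = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        ex_lens = rng.integers(
            cfg.exon_length_range[0], cfg.exon_length_range[1] + 1, size=n_ex
        )
        in_lens = rng.integers(
            cfg.intron_length_range[0], cfg.intron_length_range[1] + 1, size=n_ex - 1
        )
        pos = 10_000
        intervals = []
        for k in range(n_ex):
            intervals.append((pos, pos + int(ex_lens[k]) - 1))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        strand = "+" if i % 2 == 0 else "-"
        if strand == "-":
            intervals = intervals[::-1]
        models.append(
            GeneModel(
                gene_symbol=f"GENE{i + 1:02d}",
                chromosome=f"chr{i + 1}",
                strand=strand,
                transcript_id=f"TX{i + 1:04d}.1",
                exons=tuple(intervals),
            )
        )
    return models


def write_models_gtf(models: list[GeneModel], path: str) -> None:
    """Emit the models as a GTF that round-trips through the loader."""
    with open(path, "w") as fh:
        for m in models:
            lo, hi = m.gene_span
            attrs = (
                f'gene_id "{m.gene_symbol}"; transcript_id "{m.transcript_id}"; '
                f'gene_name "{m.gene_symbol}";'
            )
            fh.write(
                f"{m.chromosome}\tsim\ttranscript\t{lo}\t{hi}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.chromosome}\tsim\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def panel_from_models(
    models: list[GeneModel],
    min_exon_depth: float = 50.0,
    min_exon_fraction: float = 0.85,
) -> PanelConfig:
    return PanelConfig(
        genes=tuple(
            PanelGene(m.gene_symbol, m.transcript_id, m.excluded_exon_indices)
            for m in models
        ),
        min_exon_depth=min_exon_depth,
        min_exon_fraction=min_exon_fraction,
    )


# ---------------------------------------------------------------------------
# event templates

def _gex(model: GeneModel) -> list[tuple[int, int]]:
    return sorted(model.exons)


def _intron(model: GeneModel, k: int) -> tuple[int, int]:
    gex = _gex(model)
    return (gex[k][1] + 1, gex[k + 1][0] - 1)


def _template(model, event_type, alt_junctions, denominator_introns,
              frequency, beta_a, beta_b) -> EventTemplate:
    """Assemble a template and derive its canonical event key by running
    the classification engine on the materialized junctions."""
    jrecs = [
        JunctionRecord(model.chromosome, s, e, model.strand, unique_reads=1)
        for s, e in alt_junctions
    ]
    events, _ = detect_events(jrecs, model, drop_excluded=False)
    if len(events) != 1 or events[0].event_type != event_type:
        raise ValueError(
            f"template junctions classify as "
            f"{[e.event_type for e in events]}, expected one {event_type}"
        )
    return EventTemplate(
        gene_symbol=model.gene_symbol,
        chromosome=model.chromosome,
        strand=model.strand,
        event_type=event_type,
        alt_junctions=tuple(alt_junctions),
        denominator_introns=tuple(denominator_introns),
        population_frequency=frequency,
        beta_a=beta_a,
        beta_b=beta_b,
        event_key=events[0].key,
    )


def template_esf(model, g_exon: int, frequency, beta_a, beta_b) -> EventTemplate:
    """Full skip of the genomic-sorted exon ``g_exon`` (0-based interior)."""
    gex = _gex(model)
    alt = (gex[g_exon - 1][1] + 1, gex[g_exon + 1][0] - 1)
    return _template(
        model, "ESF", [alt],
        [_intron(model, g_exon - 1), _intron(model, g_exon)],
        frequency, beta_a, beta_b,
    )


def template_esp(model, g_exon: int, trunc_len: int, frequency,
                 beta_a, beta_b) -> EventTemplate:
    """Truncate the genomically left ``trunc_len`` bases of exon ``g_exon``."""
    gex = _gex(model)
    es, ee = gex[g_exon]
    if trunc_len >= ee - es + 1:
        raise ValueError("truncation swallows the whole exon")
    alt = (gex[g_exon - 1][1] + 1, es + trunc_len - 1)
    return _template(
        model, "ESP", [alt], [_intron(model, g_exon - 1)],
        frequency, beta_a, beta_b,
    )


def template_ip(model, g_intron: int, retained_len: int, frequency,
                beta_a, beta_b) -> EventTemplate:
    """Retain the genomically last ``retained_len`` bases of intron ``g_intron``."""
    istart, iend = _intron(model, g_intron)
    if retained_len >= iend - istart + 1:
        raise ValueError("retention swallows the whole intron")
    alt = (istart, iend - retained_len)
    return _template(
        model, "IP", [alt], [(istart, iend)], frequency, beta_a, beta_b,
    )


def template_ic(model, g_intron: int, offset: int, length: int, frequency,
                beta_a, beta_b) -> EventTemplate:
    """Cryptic exon of ``length`` nt starting ``offset`` nt into intron
    ``g_intron`` (both junction flanks canonical-anchored)."""
    istart, iend = _intron(model, g_intron)
    c_start = istart + offset
    c_end = c_start + length - 1
    if c_end >= iend:
        raise ValueError("cryptic exon exceeds intron")
    alt = [(istart, c_start - 1), (c_end + 1, iend)]
    return _template(
        model, "IC", alt, [(istart, iend)], frequency, beta_a, beta_b,
    )


def default_event_catalog(
    models: list[GeneModel], cfg: SimulationConfig
) -> list[EventTemplate]:
    """Background events of the healthy population.

    Per gene, roughly one event per five exons (so that the per-gene event
    count tracks exon count), cycling through the four event shapes, with
    population frequencies drawn in [0.15, 0.95] and low per-carrier PSI
    (Beta(2, 30), mean ~6%). The very first event of the panel is made
    ubiquitous and in-frame at Beta(15, 24) (mean PSI ~38%), emulating the
    constitutive partial-skip event seen in every control.
    """
    rng = _rng(cfg, 1)
    catalog: list[EventTemplate] = []
    first = True
    for m in models:
        n_events = max(1, m.n_exons // 5)
        free_introns = list(range(m.n_exons - 1))
        types = ["ESF", "ESP", "IP", "IC"]
        for ei in range(n_events):
            etype = types[ei % 4]
            freq, a, b = float(rng.uniform(0.15, 0.95)), 2.0, 30.0
            if first:
                etype, freq, a, b = "ESP", 1.0, 15.0, 24.0
            try:
                if etype in ("ESF", "ESP"):
                    # interior exon whose two flanking introns are free
                    g = None
                    for cand in range(1, m.n_exons - 1):
                        if cand - 1 in free_introns and cand in free_introns:
                            g = cand
                            break
                    if g is None:
                        break
                    if etype == "ESF":
                        t = template_esf(m, g, freq, a, b)
                        free_introns.remove(g - 1)
                        free_introns.remove(g)
                    else:
                        gex = _gex(m)
                        exlen = gex[g][1] - gex[g][0] + 1
                        trunc = int(rng.integers(10, max(11, min(61, exlen))))
                        if first:
                            trunc = 42  # in-frame partial skip
                        t = template_esp(m, g, trunc, freq, a, b)
                        free_introns.remove(g - 1)
                else:
                    if not free_introns:
                        break
                    k = free_introns.pop(0)
                    istart, iend = _intron(m, k)
                    ilen = iend - istart + 1
                    if etype == "IP":
                        t = template_ip(m, k, int(rng.integers(5, 31)), freq, a, b)
                    else:
                        length = int(rng.integers(40, 121))
                        offset = int(rng.integers(30, max(31, ilen - length - 30)))
                        t = template_ic(m, k, offset, length, freq, a, b)
            except ValueError:
                continue  # geometry did not fit; skip this slot
            catalog.append(t)
            first = False
    return catalog


def default_spikein_templates(
    models: list[GeneModel], cfg: SimulationConfig,
    catalog: list[EventTemplate],
) -> list[EventTemplate]:
    """Variant-driven events for patient carriers: full or partial skips on
    introns unused by the background catalog, population frequency 0."""
    used: dict[str, set[tuple[int, int]]] = {}
    for t in catalog:
        used.setdefault(t.gene_symbol, set()).update(t.denominator_introns)
    spikes: list[EventTemplate] = []
    rng = _rng(cfg, 4)
    for m in models:
        if len(spikes) >= cfg.n_spikein_templates:
            break
        taken = used.setdefault(m.gene_symbol, set())
        for g in range(1, m.n_exons - 1):
            if len(spikes) >= cfg.n_spikein_templates:
                break
            flanks = {_intron(m, g - 1), _intron(m, g)}
            if flanks & taken:
                continue
            if rng.random() < 0.5:
                t = template_esf(m, g, 0.0, 1.0, 1.0)
            else:
                gex = _gex(m)
                exlen = gex[g][1] - gex[g][0] + 1
                t = template_esp(m, g, min(17, exlen - 5), 0.0, 1.0, 1.0)
            taken.update(flanks)
            spikes.append(t)
    return spikes


# ---------------------------------------------------------------------------
# sample simulation

def _nb_depth(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    r = cfg.coverage_dispersion
    p = r / (r + cfg.coverage_mean)
    return int(rng.negative_binomial(r, p))


def simulate_sample(
    models: list[GeneModel],
    templates: list[EventTemplate],
    cfg: SimulationConfig,
    sample_index: int,
    sample_id: str,
    spikein_psi: dict[tuple[str, str], float] | None = None,
    qc_fail: bool = False,
) -> tuple[list[JunctionRecord], list[ExonCoverageRecord], list[TruthRecord]]:
    """Simulate one sample's junction table, exon coverage, and truth.

    For each template: carrier status ~ Bernoulli(frequency), per-carrier
    true PSI ~ Beta * 100 (or the supplied spike-in PSI); region depth
    D ~ NB(mean, dispersion); alt ~ Binomial(D, PSI/100); each replaced
    canonical junction receives D - alt reads. Canonical junctions not
    touched by any template get independent NB depths. Exon coverage is
    the mean of the adjacent canonical junction depths; QC-failing samples
    have 20% of exons zeroed out, exceeding the 85% x 50x gate.
    """
    spikein_psi = spikein_psi or {}
    models_by_gene = {m.gene_symbol: m for m in models}

    canon_counts: dict[tuple[str, int, int], int] = {}
    alt_counts: dict[tuple[str, tuple[int, int]], int] = {}
    truths: list[TruthRecord] = []

    for ei, t in enumerate(templates):
        erng = np.random.default_rng(
            np.random.SeedSequence((cfg.seed, 3, sample_index, ei))
        )
        if t.event_key in spikein_psi:
            psi = spikein_psi[t.event_key]
            is_spike = True
        else:
            carrier = erng.random() < t.population_frequency
            psi = 100.0 * float(erng.beta(t.beta_a, t.beta_b)) if carrier else 0.0
            is_spike = False
        depth = _nb_depth(erng, cfg)
        alt = int(erng.binomial(depth, psi / 100.0)) if depth > 0 else 0
        for j in t.alt_junctions:
            alt_counts[(t.gene_symbol, j)] = alt_counts.get((t.gene_symbol, j), 0) + alt
        for intr in t.denominator_introns:
            key = (t.chromosome, intr[0], intr[1])
            canon_counts[key] = canon_counts.get(key, 0) + (depth - alt)
        if psi > 0 or is_spike:
            truths.append(TruthRecord(sample_id, t.event_key, psi, is_spike))

    srng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2, sample_index)))
    for m in models:
        for istart, iend in m.introns():
            key = (m.chromosome, istart, iend)
            if key not in canon_counts:
                canon_counts[key] = _nb_depth(srng, cfg)

    junctions: list[JunctionRecord] = []
    for m in models:
        for istart, iend in m.introns():
            junctions.append(
                JunctionRecord(
                    m.chromosome, istart, iend, m.strand,
                    unique_reads=canon_counts[(m.chromosome, istart, iend)],
                    annotated=1, max_overhang=50,
                )
            )
    for (gene, (s, e)), count in alt_counts.items():
        if count < 1:
            continue
        m = models_by_gene[gene]
        junctions.append(
            JunctionRecord(m.chromosome, s, e, m.strand,
                           unique_reads=count, annotated=0, max_overhang=50)
        )
    junctions.sort(key=lambda j: (j.chromosome, j.intron_start, j.intron_end))

    coverage: list[ExonCoverageRecord] = []
    for m in models:
        introns = m.introns()
        for t_idx in range(1, m.n_exons + 1):
            adjacent = []
            if t_idx >= 2:
                adjacent.append(introns[t_idx - 2])
            if t_idx <= m.n_exons - 1:
                adjacent.append(introns[t_idx - 1])
            depths = [canon_counts[(m.chromosome, a, b)] for a, b in adjacent]
            coverage.append(
                ExonCoverageRecord(m.gene_symbol, t_idx, float(np.mean(depths)))
            )
    if qc_fail:
        n_zero = int(np.ceil(0.20 * len(coverage)))
        zero_idx = set(srng.choice(len(coverage), size=n_zero, replace=False).tolist())
        coverage = [
            replace(c, mean_depth=0.0) if i in zero_idx else c
            for i, c in enumerate(coverage)
        ]
    return junctions, coverage, truths


# ---------------------------------------------------------------------------
# cohort orchestration

def _draw_category(rng, table) -> str:
    names = [n for n, _ in table]
    probs = np.array([p for _, p in table])
    return str(rng.choice(names, p=probs / probs.sum()))


@dataclass
class Cohort:
    """A fully materialized synthetic cohort."""

    config: SimulationConfig
    models: list[GeneModel]
    panel: PanelConfig
    catalog: list[EventTemplate]
    spike_templates: list[EventTemplate]
    samples: dict[str, tuple[list[JunctionRecord], list[ExonCoverageRecord]]]
    truth: list[TruthRecord]
    metadata: pd.DataFrame


def simulate_cohort(cfg: SimulationConfig, outdir: str | None = None) -> Cohort:
    """Materialize a full cohort: controls, patients with one spike-in each,
    metadata, and truth. With ``outdir`` set, writes the exact pipeline
    input dialects (GTF, panel JSON, SJ tables, coverage TSVs, metadata and
    truth TSVs) into that directory.
    """
    models = simulate_models(cfg)
    panel = panel_from_models(models)
    catalog = default_event_catalog(models, cfg)
    spikes = default_spikein_templates(models, cfg, catalog)
    templates = catalog + spikes

    mrng = _rng(cfg, 5)
    n_fail = int(round(cfg.qc_fail_fraction * cfg.n_controls))
    fail_ids = set(
        mrng.choice(cfg.n_controls, size=n_fail, replace=False).tolist()
    ) if n_fail else set()

    samples = {}
    truth: list[TruthRecord] = []
    meta_rows = []
    for i in range(cfg.n_controls):
        sid = f"CTRL{i + 1:04d}"
        j, c, tr = simulate_sample(
            models, templates, cfg, sample_index=i, sample_id=sid,
            qc_fail=i in fail_ids,
        )
        samples[sid] = (j, c)
        truth.extend(tr)
        meta_rows.append(_meta_row(cfg, sid, "control", i))
    for k in range(cfg.n_patients):
        i = cfg.n_controls + k
        sid = f"PAT{k + 1:04d}"
        assigned = {}
        if spikes:
            tmpl = spikes[k % len(spikes)]
            prng = _rng(cfg, 6, k)
            assigned[tmpl.event_key] = float(
                prng.uniform(*cfg.spikein_psi_range)
            )
        j, c, tr = simulate_sample(
            models, templates, cfg, sample_index=i, sample_id=sid,
            spikein_psi=assigned,
        )
        samples[sid] = (j, c)
        truth.extend(tr)
        meta_rows.append(_meta_row(cfg, sid, "patient", i))

    metadata = pd.DataFrame(meta_rows)
    cohort = Cohort(
        config=cfg, models=models, panel=panel, catalog=catalog,
        spike_templates=spikes, samples=samples, truth=truth, metadata=metadata,
    )
    if outdir is not None:
        _write_cohort(cohort, outdir)
    return cohort


def _meta_row(cfg, sid, role, i):
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7, i)))
    return {
        "sample_id": sid,
        "role": role,
        "age_range": _draw_category(rng, _AGE_RANGES),
        "gender": _draw_category(rng, _GENDERS),
        "ethnicity": _draw_category(rng, _ETHNICITIES),
        "batch": int(rng.integers(1, _N_BATCHES + 1)),
    }


def _write_cohort(cohort: Cohort, outdir: str) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    write_models_gtf(cohort.models, os.path.join(outdir, "models.gtf"))
    cohort.panel.to_json(os.path.join(outdir, "panel.json"))
    jdir = os.path.join(outdir, "junctions")
    cdir = os.path.join(outdir, "coverage")
    os.makedirs(jdir, exist_ok=True)
    os.makedirs(cdir, exist_ok=True)
    for sid, (junc, cov) in cohort.samples.items():
        write_junctions(junc, os.path.join(jdir, f"{sid}.SJ.out.tab"))
        write_exon_coverage(cov, os.path.join(cdir, f"{sid}.coverage.tsv"))
    cohort.metadata.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write("sample_id\tgene\tevent\ttrue_psi\tis_spikein\n")
        for t in cohort.truth:
            fh.write(
                f"{t.sample_id}\t{t.event_key[0]}\t{t.event_key[1]}\t"
                f"{t.true_psi:.6g}\t{int(t.is_spikein)}\n"
            )
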