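"""Statistical calling of aberrant splicing in one patient sample.

For every quantified patient event, the patient PSI is compared against
the zero-assigned control PSI vector with a one-sample two-sided t-test:

    t = (mean(controls) - patient_psi) / (sd(controls) / sqrt(n))

with n - 1 degrees of freedom. p-values are adjusted within one patient
sample by the Holm–Sidak step-down procedure over the family of
direction-passing, gate-eligible events. An event is called significant
when all four criteria hold: patient PSI >= 5, patient PSI greater than
the control mean, adjusted p < 0.05, and region coverage >= 50 reads.
Events with patient PSI at or below the control mean are never considered.

Events absent from every control (novel in the patient) are tested against
an all-zero control vector; this is the degenerate zero-variance branch,
which reports p = 0 with an explicit flag rather than NaN — mirroring the
treatment of control-absent events as maximally significant findings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_profile import ControlProfile
from .quantify import EventQuantification

logger = logging.getLogger(__name__)

__all__ = ["AberrantCall", "one_sample_t", "holm_sidak", "call_aberrant"]


@dataclass(frozen=True)
class AberrantCall:
    sample_id: str
    event_key: tuple[str, str]
    patient_psi: float
    patient_region_reads: int
    control_mean_psi: float
    control_sd_psi: float
    n_controls: int
    t_statistic: float
    p_raw: float
    p_adjusted: float  # NaN when the event was outside the tested family
    significant: bool
    novel_in_patient: bool  # event absent from all controls
    degenerate: bool = False  # zero control variance
    tested: bool = True  # member of the adjusted family

    def __post_init__(self) -> None:
        if self.significant:
            assert self.patient_psi >= 5.0
            assert self.patient_psi > self.control_mean_psi
            assert self.p_adjusted < 0.05
            assert self.patient_region_reads >= 50


def one_sample_t(
    control_psis: np.ndarray | list[float], patient_psi: float
) -> tuple[float, float, bool]:
    """One-sample two-sided t-test of the patient PSI against the controls.

    Returns (t, raw two-sided p, degenerate flag). With zero control
    variance the t distribution is undefined: p is reported as 0 when the
    patient differs from the constant control value (and 1 on equality),
    with the degenerate flag set.
    """
    x = np.asarray(control_psis, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need >=2 control values, got {n}")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        if patient_psi == mean:
            return 0.0, 1.0, True
        t = float("-inf") if patient_psi > mean else float("inf")
        return t, 0.0, True
    t = (mean - patient_psi) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(min(p, 1.0)), False


def holm_sidak(p_raw: np.ndarray | list[float]) -> np.ndarray:
    """Holm–Sidak step-down adjustment.

    Sort ascending; the i-th smallest of m p-values becomes
    1 - (1 - p_(i))^(m - i + 1); monotonicity is enforced by a running
    maximum, values are capped at 1, and the input order is restored.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_raw must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    exponents = m - np.arange(m)  # m, m-1, ..., 1
    # -expm1(k*log1p(-p)) == 1-(1-p)^k without underflow at tiny p,
    # preserving adjusted >= raw even below double epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        adj_sorted = -np.expm1(exponents * np.log1p(-p[order]))
    adj_sorted = np.where(p[order] == 1.0, 1.0, adj_sorted)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def call_aberrant(
    patient_quants: list[EventQuantification],
    profile: ControlProfile,
    alpha: float = 0.05,
    psi_min: float = 5.0,
    min_region_reads: int = 50,
) -> list[AberrantCall]:
    """Test one patient's events against the control profile.

    The multiple-testing family is the set of this patient's events that
    pass the direction filter (patient PSI above the control mean) and both
    gates (PSI >= ``psi_min``, region reads >= ``min_region_reads``); other
    events are reported untested with raw statistics only. Novel events
    (absent from all controls) use an all-zero control vector.
    """
    if not profile.events:
        raise ValueError("control profile is empty")
    n = profile.n_controls
    zero_vec = np.zeros(n)

    rows = []
    for q in patient_quants:
        if not q.assessable:
            continue
        st = profile.events.get(q.event_key)
        if st is not None:
            vec = np.asarray(st.psi_vector)
            novel = False
        else:
            vec = zero_vec
            novel = True
        t, p, degen = one_sample_t(vec, q.psi)
        mean, sd = float(vec.mean()), float(vec.std(ddof=1))
        in_family = (
            q.psi > mean and q.psi >= psi_min and q.region_reads >= min_region_reads
        )
        rows.append(
            dict(
                q=q, t=t, p=p, degen=degen, mean=mean, sd=sd,
                novel=novel, in_family=in_family,
            )
        )

    family = [r for r in rows if r["in_family"]]
    if family:
        adj = holm_sidak([r["p"] for r in family])
        for r, a in zip(family, adj):
            r["p_adj"] = float(a)

    calls = []
    for r in rows:
        q = r["q"]
        p_adj = r.get("p_adj", float("nan"))
        significant = bool(r["in_family"] and p_adj < alpha)
        if not r["in_family"]:
            logger.debug(
                "%s %s outside tested family (psi=%.2f, mean=%.2f, region=%d)",
                q.sample_id, q.event_key, q.psi, r["mean"], q.region_reads,
            )
        calls.append(
            AberrantCall(
                sample_id=q.sample_id,
                event_key=q.event_key,
                patient_psi=q.psi,
                patient_region_reads=q.region_reads,
                control_mean_psi=r["mean"],
                control_sd_psi=r["sd"],
                n_controls=n,
                t_statistic=r["t"],
                p_raw=r["p"],
                p_adjusted=p_adj,
                significant=significant,
                novel_in_patient=r["novel"],
                degenerate=r["degen"],
                tested=r["in_family"],
            )
        )
    return calls
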