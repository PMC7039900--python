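"""Coverage QC and control-profile statistics."""

import numpy as np
import pytest

from spliceprofile.cohort_profile import (
    SeqMetrics,
    build_profile,
    common_events,
    coverage_qc,
    exon_count_correlation,
    group_event_count_tests,
    per_sample_event_count,
)
from spliceprofile.gene_models import PanelConfig, PanelGene
from spliceprofile.junction_io import ExonCoverageRecord
from spliceprofile.quantify import EventQuantification

from conftest import make_model


def quant(sid, psi, key=("G", "ev"), region=100):
    alt = int(round(psi / 100 * region))
    return EventQuantification(sid, key, alt_reads=alt, region_reads=region,
                               psi=psi)


@pytest.fixture
def twenty_exon_setup():
    model = make_model([100] * 20, [500] * 19, gene="G20")
    panel = PanelConfig(genes=(PanelGene("G20", "G20_tx"),))
    return model, panel


class TestCoverageQC:
    @pytest.mark.parametrize("n_covered,expected", [(17, True), (16, False)])
    def test_85_percent_threshold_inclusive(self, twenty_exon_setup,
                                            n_covered, expected):
        model, panel = twenty_exon_setup
        cov = [ExonCoverageRecord("G20", i + 1, 50.0 if i < n_covered else 10.0)
               for i in range(20)]
        qc = coverage_qc(cov, panel, [model])
        assert qc.passed is expected
        assert qc.fraction_exons_at_depth == pytest.approx(n_covered / 20)

    def test_all_zero_depth(self, twenty_exon_setup):
        model, panel = twenty_exon_setup
        qc = coverage_qc([], panel, [model])
        assert not qc.passed
        assert qc.fraction_exons_at_depth == 0.0

    def test_excluded_exons_not_counted(self):
        model = make_model([100] * 10, [500] * 9, gene="G",
                           excluded={9, 10})
        panel = PanelConfig(genes=(PanelGene("G", "G_tx", frozenset({9, 10})),))
        cov = [ExonCoverageRecord("G", i, 60.0) for i in range(1, 9)]
        qc = coverage_qc(cov, panel, [model])  # 8/8 non-excluded covered
        assert qc.passed and qc.fraction_exons_at_depth == 1.0

    def test_seq_metrics_gate(self, twenty_exon_setup):
        model, panel = twenty_exon_setup
        cov = [ExonCoverageRecord("G20", i + 1, 60.0) for i in range(20)]
        bad = SeqMetrics(q30_fraction=0.70, mean_base_quality=35,
                         perfect_index_fraction=0.9)
        assert not coverage_qc(cov, panel, [model], seq_metrics=bad).passed
        good = SeqMetrics(q30_fraction=0.80, mean_base_quality=35,
                          perfect_index_fraction=0.9)
        assert coverage_qc(cov, panel, [model], seq_metrics=good).passed


class TestBuildProfile:
    def test_detected_only_vs_zero_assigned(self):
        quants = {
            "c1": [quant("c1", 10.0)],
            "c2": [quant("c2", 20.0)],
            "c3": [quant("c3", 30.0)],
            "c4": [],
        }
        profile = build_profile(quants)
        st = profile.events[("G", "ev")]
        assert st.n_detected == 3
        assert st.detection_frequency == pytest.approx(0.75)
        assert st.median_psi == pytest.approx(20.0)  # detected only
        assert st.mean_psi == pytest.approx(15.0)  # zeros assigned
        assert st.psi_vector == (10.0, 20.0, 30.0, 0.0)
        assert st.mean_psi <= np.mean([10, 20, 30])

    def test_constant_vector(self):
        quants = {f"c{i}": [quant(f"c{i}", 38.69)] for i in range(5)}
        st = build_profile(quants).events[("G", "ev")]
        assert st.median_psi == pytest.approx(38.69)
        assert st.iqr_high - st.iqr_low == pytest.approx(0.0)
        assert st.sd_psi == pytest.approx(0.0)

    def test_undetected_event_absent(self):
        quants = {"c1": [], "c2": []}
        assert build_profile(quants).events == {}

    def test_fewer_than_two_controls_errors(self):
        with pytest.raises(ValueError, match=">=2"):
            build_profile({"c1": [quant("c1", 10.0)]})

    def test_bruteforce_recompute_agrees(self, small_cohort):
        from spliceprofile.cohort_profile import coverage_qc as cq
        from spliceprofile.report import _quantify_sample

        co = small_cohort
        controls = {}
        for sid, (j, c) in co.samples.items():
            if not sid.startswith("CTRL"):
                continue
            controls[sid] = _quantify_sample(co.models, j, sid)
        profile = build_profile(controls)
        # independent brute-force pass over the raw quantifications
        sids = list(controls)
        for key, st in profile.events.items():
            vec = []
            for sid in sids:
                vals = [q.psi for q in controls[sid] if q.event_key == key]
                vec.append(vals[0] if vals else 0.0)
            vec = np.array(vec)
            det = vec[vec > 0]
            assert st.n_detected == det.size
            assert st.mean_psi == pytest.approx(vec.mean())
            assert st.sd_psi == pytest.approx(vec.std(ddof=1))
            assert st.median_psi == pytest.approx(np.median(det))


class TestCommonEvents:
    def make_profile(self, n, counts_at_5):
        """Profile with one event per entry of counts_at_5: that many
        controls at PSI 10, the rest at PSI 1."""
        quants = {f"c{i}": [] for i in range(n)}
        for ev, k in enumerate(counts_at_5):
            key = ("G", f"ev{ev}")
            for i in range(n):
                psi = 10.0 if i < k else 1.0
                quants[f"c{i}"].append(quant(f"c{i}", psi, key=key))
        return build_profile(quants)

    def test_threshold_17_of_345(self):
        profile = self.make_profile(345, [17, 16])
        kept = common_events(profile, psi_min=5, freq_min=0.05)
        assert kept == [("G", "ev0")]  # 16/345 excluded, 17/345 kept

    def test_threshold_floor_at_100(self):
        profile = self.make_profile(100, [5, 4])
        assert common_events(profile) == [("G", "ev0")]

    def test_strict_reading(self):
        profile = self.make_profile(345, [17, 18])
        assert common_events(profile, strict=True) == [("G", "ev1")]

    def test_monotone_in_thresholds(self):
        profile = self.make_profile(50, [30, 10, 3])
        base = set(common_events(profile, psi_min=5, freq_min=0.05))
        for psi_min, freq_min in [(5, 0.2), (11, 0.05), (11, 0.4)]:
            tighter = set(common_events(profile, psi_min=psi_min,
                                        freq_min=freq_min))
            assert tighter <= base


class TestEventCounts:
    def test_gates(self):
        quants = [
            quant("s", 6.0, key=("G", "a"), region=60),
            quant("s", 4.0, key=("G", "b"), region=60),
            quant("s", 80.0, key=("G", "c"), region=40),
        ]
        assert per_sample_event_count(quants) == 1
        assert per_sample_event_count([]) == 0
        all_pass = [quant("s", 50.0, key=("G", str(i)), region=60)
                    for i in range(4)]
        assert per_sample_event_count(all_pass) == 4


class TestCorrelation:
    def test_perfect_correlation(self):
        models = [make_model([50] * n, [100] * (n - 1), gene=f"G{n}")
                  for n in (3, 5, 9)]
        medians = {f"G{n}": float(n) for n in (3, 5, 9)}
        r, p = exon_count_correlation(medians, models)
        assert r == pytest.approx(1.0)

    def test_three_point_half(self):
        models = [make_model([50] * n, [100] * (n - 1), gene=g)
                  for g, n in [("A", 2), ("B", 1), ("C", 3)]]
        medians = {"A": 1.0, "B": 2.0, "C": 3.0}
        r, p = exon_count_correlation(medians, models)
        assert r == pytest.approx(0.5)

    def test_constant_medians_undefined(self):
        models = [make_model([50] * n, [100] * (n - 1), gene=f"G{n}")
                  for n in (3, 5, 9)]
        medians = {f"G{n}": 2.0 for n in (3, 5, 9)}
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = exon_count_correlation(medians, models)
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_genes(self):
        models = [make_model([50, 50], [100], gene="A")]
        with pytest.raises(ValueError):
            exon_count_correlation({"A": 1.0}, models)


class TestGroupTests:
    def test_identical_groups(self):
        p = group_event_count_tests({"a": [5, 6, 7], "b": [5, 6, 7]})
        assert p[("a", "b")] == pytest.approx(1.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        groups = {
            "lo": list(rng.normal(10, 1, 50)),
            "hi": list(rng.normal(20, 1, 50)),
        }
        assert group_event_count_tests(groups)[("hi", "lo")] < 1e-6

    def test_three_groups_three_pairs(self):
        groups = {g: [1.0, 2.0, 3.0] for g in "abc"}
        assert len(group_event_count_tests(groups)) == 3

    def test_small_group_skipped(self):
        with pytest.warns(UserWarning, match="skipped"):
            p = group_event_count_tests({"a": [1, 2, 3], "b": [9]})
        assert p == {}
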