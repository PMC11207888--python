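import json

import numpy as np
import pytest

from plidrift.connectivity import PLINetworkStack
from plidrift.group import (band_report, gn_average, gn_significant,
                            in_gn_overlap, prevalence, shared_edges,
                            slope_tally)
from plidrift.montage import MontageSpec
from plidrift.trend import EdgeSet, ThresholdConfig


def edge_set(band, entries):
    es = EdgeSet(band=band)
    for edge, slope in entries.items():
        es.edges.add(edge)
        es.slopes[edge] = slope
    return es


class TestPrevalence:
    def test_fractions(self):
        sets = {f"s{i}": edge_set("alpha", {("C3", "C4"): 0.01}) for i in range(21)}
        for i in range(10, 21):  # only 10 subjects keep a second edge
            pass
        for i in range(10):
            sets[f"s{i}"].edges.add(("C3", "P3"))
            sets[f"s{i}"].slopes[("C3", "P3")] = -0.02
        prev = prevalence(sets, 21)
        assert prev.fraction(("C3", "C4")) == 1.0
        assert prev.fraction(("C3", "P3")) == pytest.approx(10 / 21)
        assert prev.max_shared_fraction() == 1.0

    def test_disjoint_sets(self):
        sets = {f"s{i}": edge_set("alpha", {(f"C{2*i+1}", f"P{2*i+1}"): 0.1})
                for i in range(4)}
        prev = prevalence(sets, 4)
        assert all(c == 1 for c in prev.counts.values())

    def test_subject_order_invariance(self):
        entries = {f"s{i}": edge_set("alpha", {("C3", "C4"): 0.01 * (i + 1)})
                   for i in range(5)}
        a = prevalence(dict(sorted(entries.items())), 5)
        b = prevalence(dict(sorted(entries.items(), reverse=True)), 5)
        assert a.counts == b.counts


class TestSharedEdges:
    def _prev(self, counts_and_slopes, n_subjects=21):
        sets = {}
        for edge, (count, slope) in counts_and_slopes.items():
            for i in range(count):
                sets.setdefault(f"s{i}", edge_set("alpha", {}))
                sets[f"s{i}"].edges.add(edge)
                sets[f"s{i}"].slopes[edge] = slope
        for i in range(n_subjects):
            sets.setdefault(f"s{i}", edge_set("alpha", {}))
        return prevalence(sets, n_subjects)

    def test_minimum_count_at_40_percent_of_21(self):
        prev = self._prev({("C3", "C4"): (9, 0.1), ("C3", "P3"): (8, 0.1)})
        shared = shared_edges(prev, 0.40)
        assert ("C3", "C4") in shared.edges      # 9/21 ~ 0.4286 >= 0.40
        assert ("C3", "P3") not in shared.edges  # 8/21 ~ 0.381 < 0.40

    def test_threshold_one_keeps_universal_only(self):
        prev = self._prev({("C3", "C4"): (21, 0.1), ("C3", "P3"): (20, 0.1)})
        shared = shared_edges(prev, 1.0)
        assert shared.edges == {("C3", "C4")}

    def test_consensus_sign_is_mean_slope_sign(self):
        sets = {}
        for i, slope in enumerate([0.01, 0.02, -0.005]):
            sets[f"s{i}"] = edge_set("alpha", {("C3", "C4"): slope})
        shared = shared_edges(prevalence(sets, 3), 0.4)
        assert shared.consensus_signs[("C3", "C4")] == 1

    def test_exact_tie_flagged_zero(self):
        sets = {
            "s0": edge_set("alpha", {("C3", "C4"): 0.01}),
            "s1": edge_set("alpha", {("C3", "C4"): -0.01}),
        }
        shared = shared_edges(prevalence(sets, 2), 0.4)
        assert shared.consensus_signs[("C3", "C4")] == 0
        assert slope_tally(shared) == (0, 0)

    def test_nested_in_threshold(self):
        prev = self._prev({("C3", "C4"): (15, 0.1), ("C3", "P3"): (9, 0.1),
                           ("C4", "P4"): (5, -0.1)})
        assert shared_edges(prev, 0.6).edges <= shared_edges(prev, 0.4).edges

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            shared_edges(self._prev({}), 0.0)


class TestSlopeTally:
    def test_alpha_band_style_tally(self):
        sets = {}
        for s in range(21):
            sets[f"s{s}"] = edge_set("alpha", {})
        edges = [(f"C{i}", f"P{i}") for i in range(1, 34)]
        for j, e in enumerate(edges):
            slope = 0.01 if j < 24 else -0.01
            for s in range(9):
                sets[f"s{s}"].edges.add(e)
                sets[f"s{s}"].slopes[e] = slope
        shared = shared_edges(prevalence(sets, 21), 0.40)
        assert len(shared) == 33
        assert slope_tally(shared) == (24, 9)

    def test_empty(self):
        shared = shared_edges(prevalence({"s0": edge_set("alpha", {})}, 1), 0.4)
        assert slope_tally(shared) == (0, 0)


class TestGlobalNetwork:
    def _stack(self, sid, weights, m):
        return PLINetworkStack(subject_id=sid, band="alpha",
                               epoch_indices=np.arange(weights.shape[0]),
                               weights=weights, montage=m)

    def test_identical_subjects_average_to_any(self, rng):
        m = MontageSpec(labels=("C3", "C4", "Cz"))
        w = rng.uniform(0, 1, (5, 3))
        gn = gn_average([self._stack("a", w, m), self._stack("b", w.copy(), m)])
        assert np.allclose(gn.weights, w)

    def test_two_subject_mean(self):
        m = MontageSpec(labels=("C3", "C4"))
        gn = gn_average([
            self._stack("a", np.full((4, 1), 0.2), m),
            self._stack("b", np.full((4, 1), 0.4), m),
        ])
        assert np.allclose(gn.weights, 0.3)

    def test_averaging_is_linear(self, rng):
        m = MontageSpec(labels=("C3", "C4", "Cz"))
        ws = [rng.uniform(0, 1, (5, 3)) for _ in range(3)]
        gn1 = gn_average([self._stack(f"s{i}", w, m) for i, w in enumerate(ws)])
        gn2 = gn_average([self._stack(f"s{i}", 0.5 * w, m) for i, w in enumerate(ws)])
        assert np.allclose(gn2.weights, 0.5 * gn1.weights)
        assert np.all((gn1.weights >= 0) & (gn1.weights <= 1))

    def test_grid_mismatch_rejected(self, rng):
        m = MontageSpec(labels=("C3", "C4"))
        a = self._stack("a", rng.uniform(0, 1, (4, 1)), m)
        b = PLINetworkStack(subject_id="b", band="alpha",
                            epoch_indices=np.array([0, 1, 2, 4]),
                            weights=rng.uniform(0, 1, (4, 1)), montage=m)
        with pytest.raises(ValueError, match="not aligned"):
            gn_average([a, b])

    def test_gn_trend_gate(self, rng):
        m = MontageSpec(labels=("C3", "C4", "Cz"))
        w = rng.uniform(0.29, 0.31, (20, 3))
        w[:, 1] = np.linspace(0.2, 0.6, 20)  # one strongly trending average edge
        gn = gn_average([self._stack("a", w, m)])
        out = gn_significant(gn, ThresholdConfig())
        assert ("C3", "Cz") in out.edges


class TestOverlap:
    def test_superset_and_disjoint(self):
        gn = edge_set("alpha", {("C3", "C4"): 0.1, ("C3", "P3"): 0.1})
        ins = {
            "s0": edge_set("alpha", {("C3", "C4"): 0.1, ("C3", "P3"): 0.1,
                                     ("C4", "P4"): 0.1}),
            "s1": edge_set("alpha", {("C4", "P4"): 0.1}),
        }
        ov = in_gn_overlap(ins, gn)
        assert ov.per_subject["s0"] == 100.0
        assert ov.per_subject["s1"] == 0.0
        assert ov.mean == 50.0 and ov.min == 0.0 and ov.max == 100.0
        assert ov.sd == 50.0  # population convention

    def test_table_style_arithmetic(self):
        """92 of 287 shared GN edges gives 32.06% (printed precision)."""
        gn_edges = {(f"C{i}", f"P{i}"): 0.1 for i in range(287)}
        gn = edge_set("theta", gn_edges)
        subset = dict(list(gn_edges.items())[:92])
        ov = in_gn_overlap({"s0": edge_set("theta", subset)}, gn)
        assert ov.per_subject["s0"] == pytest.approx(32.06, abs=0.005)

    def test_percentages_are_integer_counts(self, rng):
        gn_edges = {(f"C{i}", f"P{i}"): 0.1 for i in range(17)}
        gn = edge_set("alpha", gn_edges)
        ins = {}
        for s in range(6):
            k = int(rng.integers(0, 18))
            ins[f"s{s}"] = edge_set("alpha", dict(list(gn_edges.items())[:k]))
        ov = in_gn_overlap(ins, gn)
        for pct in ov.per_subject.values():
            count = pct * ov.gn_size / 100.0
            assert abs(count - round(count)) < 1e-9

    def test_empty_gn_reported_missing(self):
        gn = edge_set("gamma", {})
        with pytest.warns(UserWarning, match="no significant"):
            ov = in_gn_overlap({"s0": edge_set("gamma", {("C3", "C4"): 0.1})}, gn)
        assert ov.mean is None and ov.per_subject["s0"] is None


class TestBandReport:
    def test_report_is_json_serializable_and_consistent(self):
        ins = {
            "s0": edge_set("alpha", {("C3", "C4"): 0.1, ("Fz", "Cz"): 0.2}),
            "s1": edge_set("alpha", {("C3", "C4"): 0.3}),
        }
        gn = edge_set("alpha", {("C3", "C4"): 0.1})
        shared = shared_edges(prevalence(ins, 2), 0.4)
        ov = in_gn_overlap(ins, gn)
        rep = band_report("alpha", ins, 2, gn, ov, shared)
        text = json.dumps(rep)
        assert "alpha" in text
        sh = rep["shared_edges"]
        assert sh["count"] == sh["n_positive"] + sh["n_negative"] + sh["n_tied"]
        classes = {e["topography"] for e in sh["edges"]}
        assert classes <= {"intra-left", "intra-right", "interhemispheric",
                           "midline-involving"}
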