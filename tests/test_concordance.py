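"""Region-instance construction, cross-classification, the six metrics, and
stratified reporting. Cohen's kappa is cross-checked against scikit-learn's
implementation as an independent oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zmapsoz.concordance import (
    ConfusionCounts,
    RegionInstance,
    build_region_instances,
    compute_metrics,
    cross_classify,
    stratify_and_report,
)


def kappa_oracle(c: ConfusionCounts) -> float:
    """Independent kappa via sklearn on expanded label vectors."""
    from sklearn.metrics import cohen_kappa_score

    truth = [1] * c.tp + [0] * c.fp + [1] * c.fn + [0] * c.tn
    pred = [1] * c.tp + [1] * c.fp + [0] * c.fn + [0] * c.tn
    return cohen_kappa_score(truth, pred, labels=[0, 1])


def report_df(rows):
    return pd.DataFrame(
        rows, columns=["contact_id", "region_id", "region", "hemisphere",
                       "majority_fraction", "verified"]
    )


class TestBuildInstances:
    def test_single_soz_contact(self, parcellation):
        hemi, name = parcellation.key_of(2)
        report = report_df([("c1", 2, name, hemi, 1.0, True)])
        inst = build_region_instances(report, {"c1": True}, parcellation)
        assert len(inst) == 1
        assert inst[0].is_soz and inst[0].region == name and inst[0].hemisphere == hemi

    def test_any_contact_rule(self, parcellation):
        hemi, name = parcellation.key_of(2)
        report = report_df(
            [("c1", 2, name, hemi, 1.0, True), ("c2", 2, name, hemi, 0.9, True)]
        )
        inst = build_region_instances(report, {"c1": False, "c2": True}, parcellation)
        assert len(inst) == 1 and inst[0].is_soz

    def test_homologous_regions_distinct(self, parcellation):
        lh, lname = parcellation.key_of(1)
        rh, rname = parcellation.key_of(13)
        report = report_df(
            [("c1", 1, lname, lh, 1.0, True), ("c2", 13, rname, rh, 1.0, True)]
        )
        inst = build_region_instances(report, {"c1": True, "c2": False}, parcellation)
        assert len(inst) == 2
        assert {i.hemisphere for i in inst} == {"left", "right"}

    def test_unverified_contacts_excluded(self, parcellation):
        hemi, name = parcellation.key_of(2)
        report = report_df(
            [("c1", 2, name, hemi, 1.0, True), ("c2", 0, "", "", 0.3, False)]
        )
        inst = build_region_instances(report, {"c1": False, "c2": True}, parcellation)
        assert len(inst) == 1 and not inst[0].is_soz

    def test_missing_soz_flag_rejected(self, parcellation):
        hemi, name = parcellation.key_of(2)
        report = report_df([("c1", 2, name, hemi, 1.0, True)])
        with pytest.raises(KeyError):
            build_region_instances(report, {}, parcellation)


def _instance(pid, hemi, region, lobe, soz):
    return RegionInstance(pid, hemi, region, lobe, soz)


class TestCrossClassify:
    def test_all_positive(self):
        inst = [_instance("p", "left", f"r{i}", "frontal", True) for i in range(5)]
        hypo = {("left", f"r{i}") for i in range(5)}
        counts, _ = cross_classify(inst, hypo)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (5, 0, 0, 0)

    def test_empty_hypometabolic_set(self):
        inst = [_instance("p", "left", f"r{i}", "frontal", i < 2) for i in range(6)]
        counts, _ = cross_classify(inst, set())
        assert counts.tp == 0 and counts.fp == 0
        assert counts.fn == 2 and counts.tn == 4

    def test_matches_brute_force_on_random_fixture(self, rng):
        inst = []
        hypo = set()
        for i in range(100):
            hemi = "left" if rng.random() < 0.5 else "right"
            region = f"r{i}"
            soz = bool(rng.random() < 0.3)
            if rng.random() < 0.4:
                hypo.add((hemi, region))
            inst.append(_instance("p", hemi, region, "frontal", soz))
        counts, labeled = cross_classify(inst, hypo)
        # brute-force enumeration
        tp = sum(1 for x in inst if x.is_soz and (x.hemisphere, x.region) in hypo)
        fp = sum(1 for x in inst if not x.is_soz and (x.hemisphere, x.region) in hypo)
        fn = sum(1 for x in inst if x.is_soz and (x.hemisphere, x.region) not in hypo)
        tn = len(inst) - tp - fp - fn
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (tp, fp, fn, tn)
        assert counts.n == len(inst)

    def test_per_patient_hypometabolic_sets(self):
        inst = [
            _instance("p1", "left", "r1", "frontal", True),
            _instance("p2", "left", "r1", "frontal", True),
        ]
        counts, _ = cross_classify(inst, {"p1": {("left", "r1")}, "p2": set()})
        assert counts.tp == 1 and counts.fn == 1


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=90))
        assert (m.tpr, m.tnr, m.ppv, m.npv, m.acc, m.kappa) == (1, 1, 1, 1, 1, 1)

    def test_all_negative_predictor(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=10, tn=90))
        assert m.tpr == 0 and m.tnr == 1 and m.acc == pytest.approx(0.9)
        assert m.kappa == 0
        assert math.isnan(m.ppv) and "PPV" in m.undefined

    def test_direct_formula_example(self):
        m = compute_metrics(ConfusionCounts(tp=170, fp=59, fn=106, tn=925))
        assert m.acc == pytest.approx(0.869, abs=5e-4)
        assert m.kappa == pytest.approx(0.592, abs=5e-4)
        assert m.kappa == pytest.approx(
            kappa_oracle(ConfusionCounts(tp=170, fp=59, fn=106, tn=925)), abs=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        tp=st.integers(1, 200), fp=st.integers(1, 200),
        fn=st.integers(1, 200), tn=st.integers(1, 200),
    )
    def test_kappa_matches_sklearn_oracle(self, tp, fp, fn, tn):
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        assert compute_metrics(c).kappa == pytest.approx(kappa_oracle(c), abs=1e-12)

    def test_kappa_near_zero_for_independent_labels(self, rng):
        truth = rng.random(10_000) < 0.3
        pred = rng.random(10_000) < 0.4
        c = ConfusionCounts(
            tp=int((truth & pred).sum()), fp=int((~truth & pred).sum()),
            fn=int((truth & ~pred).sum()), tn=int((~truth & ~pred).sum()),
        )
        assert abs(compute_metrics(c).kappa) < 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts())


class TestStratify:
    def _cohort(self, rng, n=200):
        lobes = ["frontal", "parietal", "temporal", "occipital", "insular"]
        inst, hypo = [], set()
        for i in range(n):
            hemi = "left" if rng.random() < 0.5 else "right"
            lobe = lobes[int(rng.integers(0, 5))]
            region = f"r{i}"
            soz = bool(rng.random() < 0.25)
            if (soz and rng.random() < 0.7) or (not soz and rng.random() < 0.05):
                hypo.add((hemi, region))
            inst.append(_instance("p", hemi, region, lobe, soz))
        return inst, hypo

    def test_table_layout_and_conservation(self, rng):
        inst, hypo = self._cohort(rng)
        table, raw = stratify_and_report(inst, hypo, stratum_floor=1)
        assert list(table["Category"]) == [
            "Total", "Frontal lobe", "Parietal lobe", "Temporal lobe",
            "Occipital lobe", "Insular lobe", "Left hemisphere", "Right hemisphere",
        ]
        lobe_n = table.set_index("Category")["N"]
        assert (
            lobe_n[["Frontal lobe", "Parietal lobe", "Temporal lobe",
                    "Occipital lobe", "Insular lobe"]].sum() == lobe_n["Total"]
        )
        assert lobe_n[["Left hemisphere", "Right hemisphere"]].sum() == lobe_n["Total"]

    def test_small_stratum_flagged_not_numeric(self, rng):
        inst, hypo = self._cohort(rng, n=40)
        table, _ = stratify_and_report(inst, hypo, stratum_floor=30)
        flagged = table[table["Flag"] == "insufficient"]
        assert len(flagged) >= 1
        assert flagged[["TPR", "TNR", "PPV", "NPV", "ACC", "Kappa"]].isna().all().all()

    def test_single_lobe_cohort_matches_total(self, rng):
        inst = [
            _instance("p", "left", f"r{i}", "frontal", bool(rng.random() < 0.4))
            for i in range(60)
        ]
        hypo = {("left", f"r{i}") for i in range(0, 60, 3)}
        table, _ = stratify_and_report(inst, hypo, stratum_floor=1)
        total = table[table["Category"] == "Total"].iloc[0]
        frontal = table[table["Category"] == "Frontal lobe"].iloc[0]
        for m in ("TPR", "TNR", "PPV", "NPV", "ACC", "Kappa"):
            assert total[m] == frontal[m] or (math.isnan(total[m]) and math.isnan(frontal[m]))

    def test_order_and_patient_relabeling_invariance(self, rng):
        inst, hypo = self._cohort(rng)
        table1, _ = stratify_and_report(inst, hypo, stratum_floor=1)
        shuffled = [inst[i] for i in rng.permutation(len(inst))]
        renamed = [
            RegionInstance("q", x.hemisphere, x.region, x.lobe, x.is_soz)
            for x in shuffled
        ]
        table2, _ = stratify_and_report(renamed, hypo, stratum_floor=1)
        pd.testing.assert_frame_equal(table1, table2)
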