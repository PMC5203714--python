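"""Prevalence curves, per-sample fractions, confidence filters, concordance."""

import numpy as np
import pytest
import scipy.sparse as sp

from junctionscope.aggregate import (
    confident_junctions,
    cross_cohort_membership,
    per_sample_profiles,
    prevalence_curve,
    set_concordance,
)
from junctionscope.classify import EvidenceCategory, classify_table
from junctionscope.model import Junction, JunctionTable, SampleMeta

from conftest import random_table


def _novel_categories(t):
    return {j.key: EvidenceCategory.NOVEL for j in t.junctions}


class TestPrevalenceCurve:
    def test_threshold_one_counts_everything(self, small_cohort):
        _, ann, table, meta = small_cohort
        cats, _ = classify_table(table, ann.index)
        curve = prevalence_curve(table, cats, thresholds=[1])
        assert curve.loc[1, "total"] == table.n_junctions

    def test_project_prevalence_counts_projects_once(self):
        t = JunctionTable(
            [Junction("chr1", 10, 90, "+")], ["s1", "s2"],
            sp.csr_matrix(np.array([[5, 7]])),
        )
        meta = [SampleMeta("s1", "p1"), SampleMeta("s2", "p1")]
        cats = _novel_categories(t)
        curve = prevalence_curve(t, cats, unit="project", meta=meta,
                                 thresholds=[1, 2])
        assert curve.loc[1, "total"] == 1
        assert curve.loc[2, "total"] == 0

    def test_missing_sample_metadata_rejected(self):
        t = JunctionTable(
            [Junction("chr1", 10, 90, "+")], ["s1"], sp.csr_matrix(np.array([[5]]))
        )
        with pytest.raises(ValueError, match="missing"):
            prevalence_curve(t, _novel_categories(t), unit="project",
                             meta=[SampleMeta("other", "p1")], thresholds=[1])

    def test_matches_bruteforce_and_is_monotone(self, small_cohort):
        _, ann, table, meta = small_cohort
        cats, _ = classify_table(table, ann.index)
        thresholds = [1, 2, 5, 10, 20, 40]
        for unit in ("sample", "project"):
            curve = prevalence_curve(table, cats, unit=unit, meta=meta,
                                     thresholds=thresholds)
            # brute force: recount per junction from raw counts
            if unit == "sample":
                prev = [
                    sum(1 for v in table.sample_counts(i).values() if v >= 1)
                    for i in range(table.n_junctions)
                ]
            else:
                proj = {m.sample_id: m.project_id for m in meta}
                prev = [
                    len({proj[s] for s in table.sample_counts(i)})
                    for i in range(table.n_junctions)
                ]
            for s in thresholds:
                expected = sum(1 for p in prev if p >= s)
                assert curve.loc[s, "total"] == expected
                assert (
                    sum(
                        curve.loc[s, c.label]
                        for c in EvidenceCategory
                    )
                    == expected
                )
            for col in curve.columns:
                assert (np.diff(curve[col].to_numpy()) <= 0).all()

    def test_project_prevalence_never_exceeds_sample_prevalence(self, small_cohort):
        _, _, table, meta = small_cohort
        assert (table.project_prevalence(meta) <= table.sample_prevalence()).all()


class TestPerSampleProfiles:
    def test_all_annotated_sample_has_unit_fractions(self):
        t = JunctionTable(
            [Junction("chr1", 10, 90, "+")], ["s1"], sp.csr_matrix(np.array([[4]]))
        )
        cats = {t.junctions[0].key: EvidenceCategory.FULLY_ANNOTATED}
        (p,) = per_sample_profiles(t, cats, min_junctions=0)
        assert p.frac_overlaps_annotated == 1.0
        assert p.frac_junctions_annotated == 1.0

    def test_overlap_vs_junction_fraction_arithmetic(self):
        j1 = Junction("chr1", 10, 90, "+")
        j2 = Junction("chr1", 200, 290, "+")
        t = JunctionTable([j1, j2], ["s1"], sp.csr_matrix(np.array([[99], [1]])))
        cats = {j1.key: EvidenceCategory.FULLY_ANNOTATED,
                j2.key: EvidenceCategory.NOVEL}
        (p,) = per_sample_profiles(t, cats, min_junctions=0)
        assert p.frac_overlaps_annotated == pytest.approx(0.99)
        assert p.frac_junctions_annotated == pytest.approx(0.5)
        assert p.n_overlaps == 100 and p.n_junctions == 2

    def test_min_junctions_filter_and_bruteforce(self, small_cohort):
        _, ann, table, _ = small_cohort
        cats, _ = classify_table(table, ann.index)
        min_j = 50
        profiles = {p.sample_id: p for p in
                    per_sample_profiles(table, cats, min_junctions=min_j)}
        csc = table.counts.tocsc()
        for col, sid in enumerate(table.sample_ids):
            rows = csc[:, col].nonzero()[0]
            if len(rows) < min_j:
                assert sid not in profiles
                continue
            ann_rows = [
                i for i in rows
                if cats[table.junctions[i].key] is EvidenceCategory.FULLY_ANNOTATED
            ]
            vals = {i: int(csc[i, col]) for i in rows}
            p = profiles[sid]
            assert p.n_junctions == len(rows)
            assert p.n_overlaps == sum(vals.values()) >= p.n_junctions
            assert p.frac_junctions_annotated == pytest.approx(
                len(ann_rows) / len(rows)
            )
            assert p.frac_overlaps_annotated == pytest.approx(
                sum(vals[i] for i in ann_rows) / sum(vals.values())
            )
            assert 0 <= p.frac_overlaps_annotated <= 1


class TestConfidentJunctions:
    def test_threshold_one_keeps_all(self, small_cohort):
        _, _, table, _ = small_cohort
        assert confident_junctions(table, 1) == set(table.junctions)

    def test_boundary_inclusive(self):
        t = JunctionTable(
            [Junction("chr1", 10, 90, "+")], ["s1", "s2"],
            sp.csr_matrix(np.array([[3, 17]])),
        )
        assert len(confident_junctions(t, 20)) == 1
        assert len(confident_junctions(t, 21)) == 0

    def test_nested_across_thresholds(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, n_junctions=80, n_samples=10)
        sets = [confident_junctions(t, thr) for thr in (20, 40, 80, 160)]
        for lower, higher in zip(sets, sets[1:]):
            assert higher <= lower


class TestSetConcordance:
    def test_self_concordance_is_total(self, small_cohort):
        _, _, table, _ = small_cohort
        df = set_concordance(table, [set(table.junctions)], thresholds=[1, 5])
        assert (df["frac_ge_1"] == 1.0).all()

    def test_disjoint_set_is_zero(self, small_cohort):
        _, _, table, _ = small_cohort
        other = {Junction("chrQ", 10, 90, "+")}
        df = set_concordance(table, [other], thresholds=[1])
        assert (df["frac_ge_1"] == 0.0).all()

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(13)
        t = random_table(rng, n_junctions=60, n_samples=9)
        others = [
            set(rng.choice(t.junctions, size=30)),
            set(rng.choice(t.junctions, size=20)),
        ]
        df = set_concordance(t, others, thresholds=[1, 3, 5])
        prev = t.sample_prevalence()
        for s in (1, 3, 5):
            eligible = [j for j, p in zip(t.junctions, prev) if p >= s]
            for k in (1, 2):
                expected = sum(
                    1 for j in eligible
                    if sum(j in o for o in others) >= k
                )
                assert df.loc[s, f"found_ge_{k}"] == expected

    def test_empty_comparison_rejected(self, small_cohort):
        _, _, table, _ = small_cohort
        with pytest.raises(ValueError):
            set_concordance(table, [], thresholds=[1])


class TestCrossCohortMembership:
    def test_query_subset_fully_found_at_threshold_one(self, small_cohort):
        _, ann, table, _ = small_cohort
        cats, _ = classify_table(table, ann.index)
        query = set(table.junctions[:25])
        df = cross_cohort_membership(query, table, [1], cats)
        assert df.loc[1, "n_query_found"] == 25

    def test_disjoint_query_finds_nothing(self, small_cohort):
        _, ann, table, _ = small_cohort
        cats, _ = classify_table(table, ann.index)
        query = {Junction("chrQ", 5, 50, "+")}
        df = cross_cohort_membership(query, table, [1, 2], cats)
        assert (df["n_query_found"] == 0).all()

    def test_breakdown_matches_generator_truth(self, small_cohort):
        _, ann, table, _ = small_cohort
        cats, _ = classify_table(table, ann.index)
        rng = np.random.default_rng(3)
        query = set(rng.choice(table.junctions, size=100, replace=False))
        thr = 5
        df = cross_cohort_membership(query, table, [thr], cats)
        prev = {j.key: p for j, p in zip(table.junctions, table.sample_prevalence())}
        found = [q for q in query if prev[q.key] >= thr]
        assert df.loc[thr, "n_query_found"] == len(found)
        for c in EvidenceCategory:
            expected = sum(1 for q in found if ann.truth[q.key] is c)
            assert df.loc[thr, f"n_{c.label}"] == expected
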