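"""Mitotype-specific sequence detection against synthetic panels."""

import numpy as np
import pytest

from mitoscreen import (Genome, MssParams, annotate_overlaps,
                        coverage_profile, detect_mss, find_duplicates,
                        find_orfs)
from mitoscreen.simulate import MssSpec, gen_panel, random_seq


class TestCoverageProfile:
    def test_self_coverage_all_true(self, rng):
        g = Genome("g", random_seq(rng, 5000))
        assert coverage_profile(g, g).all()

    def test_unrelated_sequence_mostly_uncovered(self, rng):
        q = Genome("q", random_seq(rng, 5000))
        s = Genome("s", random_seq(rng, 5000))
        assert coverage_profile(q, s).mean() < 0.05

    def test_foreign_insertion_uncovered(self, rng):
        backbone = random_seq(rng, 20000)
        ins = random_seq(rng, 500)
        q = Genome("q", backbone[:10000] + ins + backbone[10000:])
        prof = coverage_profile(q, Genome("s", backbone))
        uncovered = np.flatnonzero(~prof)
        assert len(uncovered) > 0
        # uncovered run matches the insertion within a small boundary slack
        assert abs(uncovered.min() - 10000) <= 50
        assert abs(uncovered.max() - (10499)) <= 50


class TestDetectMss:
    def test_identical_panel_no_mss(self, rng):
        g = Genome("q", random_seq(rng, 10000), circular=True)
        twin = Genome("p", g.seq, circular=True)
        records, matrix = detect_mss(g, [twin])
        assert records == [] and matrix.empty

    def test_planted_segments_recovered(self, rich_panel):
        records, matrix = detect_mss(rich_panel.query, rich_panel.panel)
        truth = sorted(rich_panel.truth["mss"], key=lambda t: t["start"])
        assert len(records) == len(truth)
        for rec, t in zip(records, truth):
            assert abs(rec.location.start - t["start"]) <= 50
            assert abs(rec.location.end - t["end"]) <= 50
            absent = {g for g, present in rec.presence.items() if not present}
            assert absent == set(t["absent_from"])

    def test_ids_in_coordinate_order(self, rich_panel):
        records, _ = detect_mss(rich_panel.query, rich_panel.panel)
        assert [r.id for r in records] == [f"M{i+1}" for i in range(len(records))]
        starts = [r.location.start for r in records]
        assert starts == sorted(starts)

    def test_presence_matrix_invariants(self, rich_panel):
        records, matrix = detect_mss(rich_panel.query, rich_panel.panel)
        assert matrix[rich_panel.query.id].all()       # query column all true
        assert not matrix.all(axis=1).any()            # no all-true row

    def test_mss_intervals_disjoint(self, rich_panel):
        records, _ = detect_mss(rich_panel.query, rich_panel.panel)
        spans = sorted((r.location.start, r.location.end) for r in records)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_absent_genomes_self_consistent(self, rich_panel):
        """Re-aligning an MSS against a genome marked absent yields no
        qualifying coverage of >= presence_frac of its length."""
        p = MssParams()
        records, _ = detect_mss(rich_panel.query, rich_panel.panel, p)
        L = len(rich_panel.query.seq)
        by_id = {g.id: g for g in rich_panel.panel}
        for rec in records[:3]:
            probe = Genome("probe", rich_panel.query.fetch(rec.location))
            for gid, present in rec.presence.items():
                if present or gid not in by_id:
                    continue
                prof = coverage_profile(probe, by_id[gid], p)
                assert prof.mean() < p.presence_frac


class TestDuplicates:
    def test_no_repeats_no_duplicates(self, small_panel):
        records, _ = detect_mss(small_panel.query, small_panel.panel)
        assert all(r.copies == 1 for r in records)

    def test_duplicated_segment_counted(self, rich_panel):
        records, _ = detect_mss(rich_panel.query, rich_panel.panel)
        truth_dup_starts = {t["start"] for t in rich_panel.truth["mss"]
                            if any(u["duplicate_copy"] and u["index"] == t["index"]
                                   for u in rich_panel.truth["mss"])}
        dup = [r for r in records if r.copies >= 2]
        # both copies of the duplicated insertion are separate MSS loci,
        # each with copies == 2
        assert len(dup) == 2
        assert all(r.copies == 2 for r in dup)


class TestAnnotateOverlaps:
    def test_orf_inside_mss_annotated(self, rich_panel):
        records, _ = detect_mss(rich_panel.query, rich_panel.panel)
        orfs = find_orfs(rich_panel.query, min_codons=85)
        overlaps = annotate_overlaps(orfs, records, len(rich_panel.query.seq))
        t = rich_panel.truth["orfs"][0]
        planted = [o for o in orfs if o.location.start == t["start"]]
        assert planted and overlaps[planted[0]] != []

    def test_disjoint_orf_unannotated(self, rich_panel):
        records, _ = detect_mss(rich_panel.query, rich_panel.panel)
        orfs = find_orfs(rich_panel.query, min_codons=25)
        overlaps = annotate_overlaps(orfs, records, len(rich_panel.query.seq))
        spans = [(r.location.start, r.location.end) for r in records]
        for orf, ids in overlaps.items():
            if ids:
                continue
            a, b = orf.location.start, orf.location.end
            if not orf.location.wraps:
                assert all(b < s or a > e for s, e in spans)
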