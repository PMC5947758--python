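"""Database preprocessing, hit filtering, alignment extraction, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrprep import (MultipleAlignment, SearchHit, SequenceRecord, SpanError,
                    cluster_domains, extract_pairwise, filter_hits, hit_span,
                    preprocess_sequence_db, reduce_redundancy,
                    sequence_identity)

from oracles import gotoh_identity, seeded_clusters, transitive_closure_clusters

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seq(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def _mutate(rng, seq, p_sub=0.2):
    return "".join(c if rng.random() > p_sub else rng.choice(list(AA))
                   for c in seq)


class TestPreprocess:
    def test_his_tag_stripped(self):
        core = "MKVLITGGAGFIGSNFVHYVYNNHPDAHVTVLDKLTYAGN"
        (rec,) = preprocess_sequence_db([SequenceRecord("x", "HHHHHH" + core)])
        assert rec.sequence == core

    def test_short_fragments_removed(self):
        assert preprocess_sequence_db([SequenceRecord("short", "MKVLITGG")]) == []

    def test_tag_free_sequence_unchanged(self):
        seq = _random_seq(np.random.default_rng(0), 100)
        (rec,) = preprocess_sequence_db([SequenceRecord("y", seq)])
        assert rec.sequence == seq

    def test_three_his_run_is_not_a_tag(self):
        seq = "HHH" + "MKVLITGGAGFI"
        (rec,) = preprocess_sequence_db([SequenceRecord("z", seq)])
        assert rec.sequence == seq

    def test_c_terminal_tag_and_cascade_removal(self):
        # after the 5xH tag falls off only 8 residues remain -> dropped
        assert preprocess_sequence_db([SequenceRecord("w", "MKVLITGG" + "H" * 5)]) == []


class TestSequenceIdentity:
    def test_identical(self):
        assert sequence_identity("MKVLITGG", "MKVLITGG") == 1.0

    def test_single_mismatch(self):
        assert sequence_identity("AAAA", "AAAT") == pytest.approx(0.75)

    def test_fragment_scores_full_identity(self):
        assert sequence_identity("VLITG", "MKVLITGGAGFI") == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sequence_identity("", "MKV")

    def test_matches_gotoh_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = _random_seq(rng, int(rng.integers(15, 40)))
            b = _mutate(rng, a)
            if rng.random() < 0.5:   # sometimes compare a fragment
                b = b[3:-3] or b
            assert sequence_identity(a, b) == pytest.approx(
                gotoh_identity(a, b), abs=1e-12)


class TestReduceRedundancy:
    def _family(self, rng, n, length=40, p_sub=0.02):
        base = _random_seq(rng, length)
        return [SequenceRecord(f"s{i}", _mutate(rng, base, p_sub),
                               resolution=round(float(rng.uniform(1.0, 3.0)), 2))
                for i in range(n)]

    def test_level_100_is_identity(self):
        rng = np.random.default_rng(1)
        records = self._family(rng, 5)
        assert reduce_redundancy(records, 100) == records

    def test_best_resolution_preferred(self):
        seq = _random_seq(np.random.default_rng(2), 50)
        records = [SequenceRecord("worse", seq, resolution=2.0),
                   SequenceRecord("better", seq, resolution=1.5)]
        out = reduce_redundancy(records, 95)
        assert [r.id for r in out] == ["better"]

    def test_r_value_breaks_resolution_ties(self):
        seq = _random_seq(np.random.default_rng(3), 50)
        records = [SequenceRecord("hi_r", seq, resolution=1.5, r_value=0.25),
                   SequenceRecord("lo_r", seq, resolution=1.5, r_value=0.18)]
        assert [r.id for r in reduce_redundancy(records, 95)] == ["lo_r"]

    def test_similar_collapse_dissimilar_survive(self):
        rng = np.random.default_rng(4)
        near = self._family(rng, 3, p_sub=0.02)       # pairwise ~96%+
        far = [SequenceRecord(f"f{i}", _random_seq(rng, 40)) for i in range(3)]
        assert len(reduce_redundancy(near, 95)) == 1
        assert len(reduce_redundancy(near, 50)) == 1
        assert len(reduce_redundancy(far, 95)) == 3

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(7)
        records = self._family(rng, 8, p_sub=0.08) + \
            [SequenceRecord(f"u{i}", _random_seq(rng, 40)) for i in range(4)]
        for level in (95, 90, 70, 50):
            matrix = np.array([[sequence_identity(a.sequence, b.sequence)
                                for b in records] for a in records])
            clusters = transitive_closure_clusters(matrix, level / 100.0)
            expected = len(clusters)
            assert len(reduce_redundancy(records, level)) == expected

    def test_size_non_increasing_with_level(self):
        rng = np.random.default_rng(8)
        records = self._family(rng, 6, p_sub=0.15)
        sizes = [len(reduce_redundancy(records, lvl)) for lvl in (100, 95, 90, 70, 50)]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            reduce_redundancy([], 80)


class TestFilterHits:
    def test_boundary_inclusive(self):
        hits = [SearchHit("lo", 19.99), SearchHit("at", 20.0), SearchHit("hi", 25.0)]
        assert [h.id for h in filter_hits(hits)] == ["hi", "at"]

    def test_empty(self):
        assert filter_hits([]) == []

    @given(st.lists(st.floats(0, 100, allow_nan=False), max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_sorted(self, scores):
        hits = [SearchHit(f"h{i}", s) for i, s in enumerate(scores)]
        once = filter_hits(hits)
        assert filter_hits(once) == once
        assert all(a.score >= b.score for a, b in zip(once, once[1:]))


class TestExtractPairwise:
    MSA = MultipleAlignment({
        "target": "MKV-LITG",
        "hitA":   "MKRWLIT-",
        "hitB":   "---W----",
    })

    def test_both_gap_column_dropped(self):
        aln = extract_pairwise(self.MSA, "target", "hitB")
        assert len(aln.target_row) == 8 - 0  # no column gapped in both here
        aln2 = extract_pairwise(MultipleAlignment(
            {"t": "MK-V", "h": "MA-V"}), "t", "h")
        assert aln2.target_row == "MKV" and aln2.hit_row == "MAV"

    def test_self_alignment(self):
        aln = extract_pairwise(self.MSA, "target", "target")
        assert aln.identity == 1.0
        assert aln.mapping == tuple((i, i) for i in range(1, 8))

    def test_missing_id(self):
        with pytest.raises(LookupError):
            extract_pairwise(self.MSA, "target", "nope")

    def test_mapping_matches_column_scan_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            cols = int(rng.integers(5, 25))
            def row():
                return "".join(rng.choice(list("A-"), p=[0.7, 0.3]) for _ in range(cols))
            t, h = row(), row()
            msa = MultipleAlignment({"t": t, "h": h})
            aln = extract_pairwise(msa, "t", "h")
            # oracle: direct column walk
            expected, tp, hp = [], 0, 0
            for tc, hc in zip(t, h):
                tp += tc != "-"
                hp += hc != "-"
                if tc != "-" and hc != "-":
                    expected.append((tp, hp))
            assert list(aln.mapping) == expected


class TestHitSpan:
    def test_contiguous_block(self):
        msa = MultipleAlignment({"t": "A" * 120, "h": "-" * 9 + "A" * 100 + "-" * 11})
        mid, ext = hit_span(extract_pairwise(msa, "t", "h"))
        assert (mid, ext) == (60, 100)  # midpoint of 10..109 rounds half-up

    def test_single_column(self):
        msa = MultipleAlignment({"t": "A" * 80, "h": "-" * 41 + "A" + "-" * 38})
        assert hit_span(extract_pairwise(msa, "t", "h")) == (42, 1)

    def test_no_match_columns(self):
        from mrprep import PairwiseAlignment
        with pytest.raises(SpanError):
            hit_span(PairwiseAlignment("AB--", "--CD", 0.0, ()))

    def test_random_spans_match_recomputation(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = 150
            first = int(rng.integers(1, 100))
            last = int(rng.integers(first, n))
            h = "-" * (first - 1) + "A" * (last - first + 1) + "-" * (n - last)
            aln = extract_pairwise(MultipleAlignment({"t": "A" * n, "h": h}), "t", "h")
            mid, ext = hit_span(aln)
            assert ext == last - first + 1
            assert mid == int(np.floor((first + last) / 2 + 0.5))


class TestClusterDomains:
    def _hits(self, specs):
        return [SearchHit(i, s, midpoint=m, extent=e)
                for i, s, m, e in specs]

    def test_one_tight_group(self):
        hits = self._hits([("a", 50, 100, 200), ("b", 45, 105, 210), ("c", 40, 108, 190)])
        clusters = cluster_domains(hits)
        assert len(clusters) == 1
        assert clusters[0].seed_id == "a"
        assert {h.id for h in clusters[0].members} == {"a", "b", "c"}

    def test_two_separated_groups(self):
        hits = self._hits([("a", 50, 100, 120), ("b", 45, 300, 120),
                           ("c", 40, 102, 118), ("d", 35, 305, 125)])
        clusters = cluster_domains(hits)
        assert len(clusters) == 2
        assert clusters[0].number == 1 and clusters[1].number == 2
        assert all(h.domain is not None for h in hits)

    def test_seed_is_top_scorer_and_partition(self):
        rng = np.random.default_rng(7)
        hits = self._hits([(f"h{i}", float(rng.uniform(20, 60)),
                            int(rng.integers(20, 300)), int(rng.integers(30, 150)))
                           for i in range(50)])
        clusters = cluster_domains(hits)
        assert sum(len(c.members) for c in clusters) == 50
        for c in clusters:
            top = max(c.members, key=lambda h: (h.score, h.id))
            assert c.seed_id == top.id or c.members[0].score == top.score

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        specs = [(f"h{i}", round(float(rng.uniform(20, 60)), 3),
                  int(rng.integers(20, 300)), int(rng.integers(30, 150)))
                 for i in range(50)]
        clusters = cluster_domains(self._hits(specs))
        expected = seeded_clusters(specs, mid_tol=10, ext_tol=25)
        got = [frozenset(h.id for h in c.members) for c in clusters]
        assert got == expected


def test_extract_identity_tracks_global_identity(tiered_family):
    """MSA-extracted identity stays close to alignment-based identity."""
    _target, _models, seqs, _sd = tiered_family
    target_seq = seqs[0]
    agree = 0
    for rec in seqs[1:]:
        msa = MultipleAlignment({"t": target_seq.sequence, "h": rec.sequence})
        aln = extract_pairwise(msa, "t", "h")
        full = sequence_identity(target_seq.sequence, rec.sequence)
        agree += abs(aln.identity - full) < 0.1
    assert agree >= 0.9 * (len(seqs) - 1)
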