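import pytest

from foldpool.msa import Msa, depth, pairwise_identity
from foldpool.structsearch import (
    DEFAULT_HIT_COLUMNS,
    HitFormatError,
    StructureHit,
    TemplateRecord,
    augment_msa,
    curate_templates,
    hit_to_msa_row,
    parse_hits,
    select_templates,
    template_identity,
    write_hits,
)


def hit(**kw):
    base = dict(
        query_id="q", hit_id="h", evalue=1e-5, tm=0.8,
        qstart=1, qend=3, tstart=1, tend=3, qaln="ACD", taln="AKD",
    )
    base.update(kw)
    return StructureHit(**base)


class TestStructureHitInvariants:
    def test_residue_count_must_match_interval(self):
        with pytest.raises(HitFormatError):
            hit(qend=4)

    def test_double_gap_column_rejected(self):
        with pytest.raises(HitFormatError):
            hit(qaln="A-D", taln="A-D", qend=2, tend=2)

    def test_unequal_alignment_lengths_rejected(self):
        with pytest.raises(HitFormatError):
            hit(taln="AKDE")


class TestParseHits:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("")
        assert parse_hits(p) == []

    def test_well_formed_row_positional_mapping(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q\thitA\t1e-8\t0.91\t2\t4\t1\t3\tACD\tAKD\n")
        [h] = parse_hits(p)
        assert (h.query_id, h.hit_id) == ("q", "hitA")
        assert h.evalue == pytest.approx(1e-8)
        assert (h.qstart, h.qend, h.tstart, h.tend) == (2, 4, 1, 3)

    def test_invalid_row_rejected_with_report(self, tmp_path, caplog):
        p = tmp_path / "h.tsv"
        good = "q\tok\t1e-8\t0.91\t2\t4\t1\t3\tACD\tAKD"
        bad = "q\tbad\t1e-8\t0.91\t2\t5\t1\t3\tACD\tAKD"  # count mismatch
        p.write_text(good + "\n" + bad + "\n")
        with caplog.at_level("WARNING"):
            hits = parse_hits(p)
        assert [h.hit_id for h in hits] == ["ok"]
        assert any("line 2" in r.message for r in caplog.records)

    def test_unknown_dialect_key_rejected(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("")
        with pytest.raises(KeyError):
            parse_hits(p, dialect={"nonsense": 0})

    def test_round_trip_through_writer(self, tmp_path):
        hits = [hit(), hit(hit_id="i2", tm=None, evalue=2.5)]
        p = tmp_path / "rt.tsv"
        write_hits(hits, p)
        back = parse_hits(p)
        assert [h.hit_id for h in back] == ["h", "i2"]
        assert back[1].tm is None


class TestHitToMsaRow:
    def test_interior_alignment_padded_with_gaps(self):
        h = hit(qstart=2, qend=4, tstart=1, tend=3)
        rid, row = hit_to_msa_row(h, query_length=5)
        assert row == "-AKD-"

    def test_insertion_lowercased(self):
        h = hit(qaln="A-C", taln="AWC", qstart=1, qend=2, tstart=1, tend=3)
        _, row = hit_to_msa_row(h, query_length=3)
        # hit residue opposite the query gap becomes a lowercase
        # insertion; the uncovered query column 3 becomes '-'
        assert row == "AwC-"

    def test_match_column_count_always_query_length(self):
        from foldpool.msa import match_state_count

        h = hit(qaln="AC-D", taln="A-WD", qstart=3, qend=5, tstart=1, tend=3)
        _, row = hit_to_msa_row(h, query_length=9)
        assert match_state_count(row) == 9

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hit_to_msa_row(hit(), query_length=2)


class TestAugmentMsa:
    def _msa(self):
        return Msa(query_id="q", rows=(("q", "ACDEF"),))

    def test_zero_hits_unchanged(self):
        m = self._msa()
        assert augment_msa(m, []) == m

    def test_query_identical_hit_filtered(self):
        h = hit(qaln="ACDEF", taln="ACDEF", qend=5, tend=5)
        out = augment_msa(self._msa(), [h])
        assert depth(out) == 1

    def test_novel_hits_increase_depth(self):
        hits = [
            hit(hit_id="a", qaln="ACDEF", taln="GGGGG", qend=5, tend=5, evalue=1e-9),
            hit(hit_id="b", qaln="ACDEF", taln="HHHHH", qend=5, tend=5, evalue=1e-8),
            hit(hit_id="c", qaln="ACDEF", taln="IIIII", qend=5, tend=5, evalue=1e-7),
        ]
        out = augment_msa(self._msa(), hits)
        assert depth(out) == 4

    def test_no_overthreshold_pair_after_augmentation(self):
        hits = [
            hit(hit_id="a", qaln="ACDEF", taln="GGGGG", qend=5, tend=5, evalue=1e-9),
            hit(hit_id="dup", qaln="ACDEF", taln="GGGGG", qend=5, tend=5, evalue=1e-6),
            hit(hit_id="b", qaln="ACDEF", taln="GGGGH", qend=5, tend=5, evalue=1e-5),
        ]
        out = augment_msa(self._msa(), hits, id_threshold=0.7)
        seqs = [s for _, s in out.rows[1:]]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert pairwise_identity(seqs[i], seqs[j]) <= 0.7


class TestSelectTemplates:
    def test_fewer_than_k_returned_in_order(self):
        hits = [hit(hit_id="b", evalue=1e-3), hit(hit_id="a", evalue=1e-9)]
        assert [h.hit_id for h in select_templates(hits, k=4)] == ["a", "b"]

    def test_tie_broken_by_tm_then_id(self):
        hits = [
            hit(hit_id="low", evalue=1e-5, tm=0.7),
            hit(hit_id="high", evalue=1e-5, tm=0.9),
        ]
        assert [h.hit_id for h in select_templates(hits, k=2)] == ["high", "low"]

    def test_empty(self):
        assert select_templates([], k=4) == []


class TestCurateTemplates:
    def test_printed_filters_applied_exactly(self):
        seq60 = "ACDEFGHIKLMNPQRSTVWY" * 3
        records = [
            TemplateRecord("keep1", seq60, 2.0, 60),
            TemplateRecord("badres", seq60[::-1], 9.0, 60),      # resolution > 8
            TemplateRecord("short", "WAWCWDWEWFWGWHWIWKWLWMWNWPWQW", 1.5, 29),  # < 30
            TemplateRecord("len30", "WAWCWDWEWFWGWHWIWKWLWMWNWPWQWR", 1.5, 30),
            TemplateRecord("na_res", seq60.lower().upper(), None, 60, "predicted"),
        ]
        kept = {r.template_id for r in curate_templates(records)}
        assert "badres" not in kept
        assert "short" not in kept
        assert "len30" in kept          # exactly 30 residues survives
        assert "keep1" in kept
        # NA resolution passes the resolution filter but is redundant
        # with keep1 (identical sequence), so the greedy pass removes it
        assert "na_res" not in kept

    def test_redundancy_boundary_strict(self):
        s = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"  # 40 residues
        # 36/40 identity = 0.9 exactly -> kept; 38/40 = 0.95 -> removed
        s_90 = s[:36] + "GGGG"
        s_95 = s[:38] + "GG"
        kept = curate_templates([
            TemplateRecord("first", s, 2.0, 40),
            TemplateRecord("exact90", s_90, 2.0, 40),
            TemplateRecord("at95", s_95, 2.0, 40),
        ])
        ids = {r.template_id for r in kept}
        assert "first" in ids and "exact90" in ids and "at95" not in ids

    def test_curated_set_passes_independent_audit(self):
        import numpy as np

        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        records = []
        base = "".join(rng.choice(aas, size=50))
        for i in range(10):
            seq = "".join(
                c if rng.random() > 0.2 else str(rng.choice(aas)) for c in base
            )
            res = float(rng.uniform(1, 10))
            records.append(TemplateRecord(f"t{i}", seq, res, len(seq)))
        kept = curate_templates(records)
        for r in kept:
            assert r.resolution is None or r.resolution <= 8.0
            assert r.length >= 30
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert template_identity(kept[i].sequence, kept[j].sequence) <= 0.90
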