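"""Six-frame translation, longest ORFs and consensus TM calling."""

import itertools

import pytest

from estmap.io import SequenceRecord
from estmap.orf import (KYTE_DOOLITTLE, TMPrediction, annotation_tally,
                        builtin_hydropathy_predict, consensus_and_dedupe,
                        longest_orf, mask_signal_peptide, parse_predictions,
                        run_builtin_panel, six_frame_translate)
from estmap.simulate import SimConfig, emit_tm_fixtures, random_dna, simulate

# independent verbatim standard genetic code (codon -> amino acid)
_CODE_SPEC = """
TTT F TTC F TTA L TTG L CTT L CTC L CTA L CTG L
ATT I ATC I ATA I ATG M GTT V GTC V GTA V GTG V
TCT S TCC S TCA S TCG S CCT P CCC P CCA P CCG P
ACT T ACC T ACA T ACG T GCT A GCC A GCA A GCG A
TAT Y TAC Y TAA * TAG * CAT H CAC H CAA Q CAG Q
AAT N AAC N AAA K AAG K GAT D GAC D GAA E GAG E
TGT C TGC C TGA * TGG W CGT R CGC R CGA R CGG R
AGT S AGC S AGA R AGG R GGT G GGC G GGA G GGG G
"""
_CODON_TABLE = dict(zip(*[iter(_CODE_SPEC.split())] * 2))
_COMP = str.maketrans("ACGT", "TGCA")


def _oracle_translate(nt, frame):
    if frame.startswith("-"):
        nt = nt.translate(_COMP)[::-1]
    off = int(frame[1]) - 1
    sub = nt[off:]
    return "".join(_CODON_TABLE.get(sub[i:i + 3], "X")
                   for i in range(0, len(sub) - len(sub) % 3, 3))


class TestSixFrame:
    def test_standard_code(self):
        assert six_frame_translate("ATGAAATAG")["+1"] == "MK*"

    def test_minus_one_equals_revcomp_translation(self):
        frames = six_frame_translate("ATGAAATAG")
        assert frames["-1"] == six_frame_translate("CTATTTCAT")["+1"]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            six_frame_translate("AT")

    def test_all_frames_match_codon_table_oracle(self, rng):
        for _ in range(100):
            nt = random_dna(rng, int(rng.integers(3, 120)), 0.5)
            frames = six_frame_translate(nt)
            for frame in ("+1", "+2", "+3", "-1", "-2", "-3"):
                assert frames[frame] == _oracle_translate(nt, frame), frame


def _oracle_longest(frames):
    best = ("", None, -1)
    for frame in ("+1", "+2", "+3", "-1", "-2", "-3"):
        pos = 0
        for seg in frames[frame].split("*"):
            if len(seg) > len(best[0]):
                best = (seg, frame, pos)
            pos += len(seg) + 1
    return best


class TestLongestOrf:
    def test_longest_stop_free_segment_wins(self):
        frames = {f: "" for f in ("+1", "+2", "+3", "-1", "-2", "-3")}
        frames["+1"] = "AAA*BB"
        frames["+2"] = "CCCCCC"
        orf = longest_orf(frames, min_orf_aa=1)
        assert orf.aa_seq == "CCCCCC" and orf.frame == "+2"

    def test_tie_breaks_by_frame_order(self):
        frames = {f: "" for f in ("+1", "+2", "+3", "-1", "-2", "-3")}
        frames["+1"] = "AAAA"
        frames["-2"] = "CCCC"
        assert longest_orf(frames, min_orf_aa=1).frame == "+1"

    def test_below_minimum_returns_none(self):
        frames = {f: "AA*AA" for f in ("+1", "+2", "+3", "-1", "-2", "-3")}
        assert longest_orf(frames, min_orf_aa=30) is None

    def test_start_codon_mode_trims_to_methionine(self):
        frames = {f: "" for f in ("+1", "+2", "+3", "-1", "-2", "-3")}
        frames["+1"] = "KKMAAAA"
        orf = longest_orf(frames, min_orf_aa=1, require_start=True)
        assert orf.aa_seq == "MAAAA"

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            nt = random_dna(rng, int(rng.integers(30, 300)), 0.5)
            frames = six_frame_translate(nt)
            orf = longest_orf(frames, min_orf_aa=1)
            seg, frame, pos = _oracle_longest(frames)
            assert orf.aa_seq == seg and orf.frame == frame
            assert orf.aa_start == pos
            assert "*" not in orf.aa_seq


class TestParsePredictions:
    def test_phobius_dialect(self, tmp_path):
        p = tmp_path / "phobius.txt"
        p.write_text("p1\t2\tY:20\t-\np2\t0\t0\t-\n")
        preds = parse_predictions(p, "phobius")
        assert preds[0].n_tm == 2 and preds[0].sp_interval == (0, 20)
        assert preds[1].n_tm == 0 and preds[1].sp_interval is None

    def test_tmhmm_dialect(self, tmp_path):
        p = tmp_path / "tmhmm.txt"
        p.write_text("p1\tlen=120\tExpAA=0.1\tPredHel=0\tTopology=o\n")
        (pred,) = parse_predictions(p, "tmhmm")
        assert pred.n_tm == 0

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("p1\tnot_a_number\n")
        with pytest.raises(ValueError, match=":1"):
            parse_predictions(p, "sosui")

    def test_fixture_files_round_trip_truth(self, tmp_path, planted_result):
        paths = emit_tm_fixtures(planted_result, tmp_path, disagreement=0.0)
        for dialect, path in paths.items():
            preds = {p.protein_id: p.n_tm
                     for p in parse_predictions(path, dialect)}
            for pid, t in planted_result.truth.tm.items():
                assert preds[pid] == t["n_tm"]


class TestMaskSignalPeptide:
    def test_prefix_truncation(self):
        assert len(mask_signal_peptide("A" * 120, (0, 22))) == 98

    def test_no_interval_is_identity(self):
        assert mask_signal_peptide("MKT", None) == "MKT"

    def test_non_prefix_interval_rejected(self):
        with pytest.raises(ValueError):
            mask_signal_peptide("A" * 50, (5, 20))


class TestBuiltinHydropathy:
    def test_polyleucine_island_counts_one_segment(self):
        seq = "D" * 30 + "L" * 25 + "D" * 30
        assert builtin_hydropathy_predict(seq).n_tm == 1

    def test_all_aspartate_is_soluble(self):
        assert builtin_hydropathy_predict("D" * 60).n_tm == 0

    def test_short_sequence_flagged(self):
        pred = builtin_hydropathy_predict("LLL")
        assert pred.n_tm == 0 and pred.topology == "too_short"

    def test_window_mean_from_published_scale(self):
        # 19 leucines: mean KD = 3.8 > 1.6 exactly one window
        assert KYTE_DOOLITTLE["L"] == 3.8
        assert builtin_hydropathy_predict("L" * 19).n_tm == 1

    def test_planted_two_tm_protein_counted(self, planted_result):
        res = planted_result
        for rec in res.proteins:
            t = res.truth.tm[rec.id]
            masked = mask_signal_peptide(rec.seq, t["sp"])
            assert builtin_hydropathy_predict(masked).n_tm == t["n_tm"]


class TestConsensus:
    def _preds(self, votes):
        return {name: TMPrediction(name, "p", n)
                for name, n in zip(("phobius", "tmhmm", "sosui"), votes)}

    @pytest.mark.parametrize("votes,accepted", [
        ((1, 0, 2), True), ((1, 0, 0), False), ((0, 0, 0), False),
        ((2, 2, 2), True),
    ])
    def test_vote_rule_examples(self, votes, accepted):
        (rec,) = consensus_and_dedupe({"p": self._preds(votes)},
                                      {"p": "A" * 50})
        assert rec.accepted is accepted

    def test_exhaustive_vote_patterns(self):
        """All 3^3 vote patterns follow the >=2-predictors-with->=1-TM rule."""
        for votes in itertools.product((0, 1, 2), repeat=3):
            (rec,) = consensus_and_dedupe({"p": self._preds(votes)},
                                          {"p": "A" * 50})
            assert rec.accepted == (sum(1 for v in votes if v >= 1) >= 2)

    def test_vote_monotonicity(self):
        """Adding a positive vote never flips accepted -> rejected."""
        for votes in itertools.product((0, 1), repeat=3):
            (base,) = consensus_and_dedupe({"p": self._preds(votes)},
                                           {"p": "A" * 50})
            for k in range(3):
                boosted = list(votes)
                boosted[k] += 1
                (more,) = consensus_and_dedupe({"p": self._preds(boosted)},
                                               {"p": "A" * 50})
                assert not (base.accepted and not more.accepted)

    def test_fewer_than_two_predictions_excluded(self):
        preds = {"p": {"phobius": TMPrediction("phobius", "p", 2)}}
        assert consensus_and_dedupe(preds, {"p": "A" * 50}) == []

    def test_identical_sequences_deduped(self):
        preds = {pid: self._preds((1, 1, 1)) for pid in ("a", "b")}
        db = {"a": "MKTLLILAVVLLSAQAMKTLLILAV", "b": "MKTLLILAVVLLSAQAMKTLLILAV"}
        recs = consensus_and_dedupe(preds, db)
        by_id = {r.protein_id: r for r in recs}
        assert by_id["a"].redundant_of is None
        assert by_id["b"].redundant_of == "a"

    def test_dedupe_idempotent(self, planted_result):
        res = planted_result
        db = {p.id: p.seq for p in res.proteins}
        sp = {pid: t["sp"] for pid, t in res.truth.tm.items() if t["sp"]}
        panel = run_builtin_panel(db, phobius_sp=sp)
        first = consensus_and_dedupe(panel, db)
        reps = [r.protein_id for r in first
                if r.accepted and r.redundant_of is None]
        second = consensus_and_dedupe({p: panel[p] for p in reps},
                                      {p: db[p] for p in reps})
        assert all(r.redundant_of is None for r in second)
        assert [r.protein_id for r in second if r.accepted] == sorted(reps)

    def test_accepted_set_equals_planted_tm_truth(self, planted_result):
        res = planted_result
        db = {p.id: p.seq for p in res.proteins}
        sp = {pid: t["sp"] for pid, t in res.truth.tm.items() if t["sp"]}
        panel = run_builtin_panel(db, phobius_sp=sp)
        recs = consensus_and_dedupe(panel, db)
        accepted = {r.protein_id for r in recs if r.accepted}
        want = {pid for pid, t in res.truth.tm.items() if t["n_tm"] >= 1}
        assert accepted == want

    def test_one_disagreeing_predictor_cannot_flip_consensus(self, tmp_path,
                                                             planted_result):
        res = planted_result
        paths = emit_tm_fixtures(res, tmp_path, disagreement=1.0,
                                 disagree_predictor="sosui")
        panel = {}
        for dialect, path in paths.items():
            for p in parse_predictions(path, dialect):
                panel.setdefault(p.protein_id, {})[dialect] = p
        db = {p.id: p.seq for p in res.proteins}
        recs = consensus_and_dedupe(panel, db)
        accepted = {r.protein_id for r in recs if r.accepted}
        want = {pid for pid, t in res.truth.tm.items() if t["n_tm"] >= 1}
        assert accepted == want


class TestAnnotationTally:
    def test_shared_annotation_counted_once_per_protein(self):
        table = {f"p{i}": ["PF1"] for i in range(10)}
        df = annotation_tally(table.keys(), table)
        assert len(df) == 1 and df.iloc[0]["count"] == 10

    def test_empty_table(self):
        assert annotation_tally([], {}).empty

    def test_matches_counting_oracle(self, rng):
        anns = [f"PF{i}" for i in range(8)]
        table = {f"p{i}": list(rng.choice(anns,
                                          size=int(rng.integers(1, 4)),
                                          replace=False))
                 for i in range(50)}
        df = annotation_tally(table.keys(), table, top_k=100)
        oracle = {}
        for pid, vals in table.items():
            for a in set(vals):
                oracle[a] = oracle.get(a, 0) + 1
        assert dict(zip(df.annotation, df["count"])) == oracle
        assert df.iloc[-1]["cum_fraction"] == pytest.approx(1.0)
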