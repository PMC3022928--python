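"""HSP filtering, collinear chaining, A-J classification and coverage."""

import numpy as np
import pandas as pd
import pytest

from estmap.io import HSP, Chain, flip_hsp_target, interval_union_len
from estmap.reconcile import (FilterParams, KnownGeneCutoffs, chain_collinear,
                              chain_score, classify, coverage, filter_hsps,
                              join_graph, known_gene_coverage,
                              one_to_one_select)
from estmap.simulate import SimConfig, simulate


def _hsp(q="q", t="t", qs=0, qe=100, ts=0, te=100, strand="+",
         identity=99.0, length=None, evalue=None):
    return HSP(q, t, qs, qe, ts, te, strand, identity_pct=identity,
               aln_len=length or (qe - qs), evalue=evalue)


class TestFilterHsps:
    def test_passing_both_thresholds_kept(self, default_params):
        assert filter_hsps([_hsp(identity=95, length=60)], default_params)

    def test_exact_identity_boundary_dropped(self, default_params):
        assert filter_hsps([_hsp(identity=90.0, length=60)],
                           default_params) == []

    def test_exact_length_boundary_dropped(self, default_params):
        h = _hsp(qe=50, identity=99, length=50)
        assert filter_hsps([h], default_params) == []

    def test_round2_drops_singleton_queries(self, default_params):
        hs = [_hsp(q="contig1"), _hsp(q="sgl1")]
        kept = filter_hsps(hs, default_params, singleton_ids={"sgl1"})
        assert [h.query_id for h in kept] == ["contig1"]

    def test_matches_brute_force_predicate(self, rng, default_params):
        hs = []
        for i in range(300):
            length = int(rng.integers(10, 120))
            hs.append(_hsp(q=f"q{i}", qs=0, qe=length,
                           identity=float(rng.uniform(70, 100)),
                           length=length))
        kept = filter_hsps(hs, default_params)
        oracle = [h for h in hs if h.identity_pct > 90 and h.aln_len > 50]
        assert kept == oracle


# --------------------------------------------------------------------------
# chaining
# --------------------------------------------------------------------------

def _pair_ok(a, b, strand, tol):
    """Independent adjacency predicate (query earlier HSP a, later b)."""
    q_ok = b.q_start >= a.q_start and b.q_end > a.q_end and \
        a.q_end - b.q_start <= tol
    if strand == "+":
        t_ok = b.t_start >= a.t_start and b.t_end > a.t_end and \
            a.t_end - b.t_start <= tol
    else:
        t_ok = b.t_start < a.t_start and b.t_end <= a.t_end and \
            b.t_end - a.t_start <= tol
    return q_ok and t_ok


def _brute_best_chain_cov(group, strand, tol=10):
    hs = sorted(group, key=lambda h: (h.q_start, h.q_end, h.t_start))
    best = 0
    n = len(hs)
    for mask in range(1, 1 << n):
        sub = [hs[i] for i in range(n) if mask >> i & 1]
        if all(_pair_ok(a, b, strand, tol) for a, b in zip(sub, sub[1:])):
            best = max(best, interval_union_len(
                [(h.q_start, h.q_end) for h in sub]))
    return best


class TestChaining:
    def test_monotone_pair_forms_one_chain(self):
        hs = [_hsp(qs=0, qe=50, ts=0, te=50),
              _hsp(qs=60, qe=100, ts=300, te=340)]
        chains = chain_collinear(hs)
        assert len(chains) == 1 and len(chains[0]) == 2
        assert chains[0].covered_qbp == 90

    def test_inverted_target_order_breaks_chain(self):
        hs = [_hsp(qs=0, qe=50, ts=300, te=350),
              _hsp(qs=60, qe=100, ts=0, te=40)]
        chains = chain_collinear(hs)
        assert sorted(len(c) for c in chains) == [1, 1]

    def test_minus_strand_requires_decreasing_target(self):
        hs = [_hsp(qs=0, qe=50, ts=300, te=350, strand="-"),
              _hsp(qs=60, qe=100, ts=0, te=40, strand="-")]
        chains = chain_collinear(hs)
        assert len(chains) == 1 and len(chains[0]) == 2

    def test_partition_conserves_all_hsps(self, rng):
        hs = []
        for i in range(30):
            qs, ts = int(rng.integers(0, 300)), int(rng.integers(0, 300))
            hs.append(_hsp(qs=qs, qe=qs + int(rng.integers(10, 80)),
                           ts=ts, te=ts + int(rng.integers(10, 80))))
        chains = chain_collinear(hs)
        assert sum(len(c) for c in chains) == len(hs)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_best_chain_score_matches_exhaustive_search(self, rng, strand):
        for _ in range(60):
            n = int(rng.integers(2, 11))
            group = []
            for _ in range(n):
                qs = int(rng.integers(0, 200))
                ql = int(rng.integers(10, 60))
                ts = int(rng.integers(0, 200))
                tl = int(rng.integers(10, 60))
                group.append(_hsp(qs=qs, qe=qs + ql, ts=ts, te=ts + tl,
                                  strand=strand))
            assert chain_score(group) == _brute_best_chain_cov(group, strand)


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

class TestClassify:
    def _run(self, hsps, glens, tlens, params=None):
        params = params or FilterParams()
        chains = chain_collinear(hsps, overlap_tol=params.overlap_tol)
        return classify(chains, glens, tlens, params)

    def test_genomic_gap_with_query_continuity_is_intron(self):
        hs = [_hsp(qs=0, qe=100, ts=0 + 50, te=150),
              _hsp(qs=100, qe=200, ts=300, te=400)]
        feats, counts = self._run(hs, {"t": 800}, {"q": 200})
        e = [f for f in feats if f.category == "E"]
        assert len(e) == 1 and e[0].derived_len == 150

    def test_left_overhang_at_contig_edge_is_c(self):
        hs = [_hsp(qs=80, qe=200, ts=0, te=120)]
        feats, _ = self._run(hs, {"t": 500}, {"q": 200})
        c = [f for f in feats if f.category == "C"]
        assert len(c) == 1 and c[0].derived_len == 80

    def test_interior_unaligned_prefix_is_not_c(self):
        hs = [_hsp(qs=80, qe=200, ts=100, te=220)]
        feats, _ = self._run(hs, {"t": 500}, {"q": 200})
        assert not [f for f in feats if f.category in "CJ"]

    def test_missing_length_rejected(self):
        hs = [_hsp()]
        with pytest.raises(KeyError):
            self._run(hs, {}, {"q": 100})

    def test_planted_scenarios_recovered_exactly(self, planted_result,
                                                 default_params):
        res = planted_result
        kept = filter_hsps(res.hsps, default_params)
        chains = chain_collinear(kept)
        _, counts = classify(chains, res.genome_lens, res.transcript_lens,
                             default_params)
        got = dict(zip(counts.category, counts["count"]))
        assert got == res.truth.category_counts()

    def test_planted_intron_lengths_recovered(self, planted_result,
                                              default_params):
        res = planted_result
        chains = chain_collinear(filter_hsps(res.hsps, default_params))
        feats, _ = classify(chains, res.genome_lens, res.transcript_lens,
                            default_params)
        got = sorted((f.query_id, f.derived_len)
                     for f in feats if f.category == "E")
        want = sorted((r["transcript"], r["t_end"] - r["t_start"])
                      for r in res.truth.introns)
        assert got == want

    def test_target_revcomp_leaves_counts_invariant(self, planted_result,
                                                    default_params):
        res = planted_result
        kept = filter_hsps(res.hsps, default_params)
        flipped = [flip_hsp_target(h, res.genome_lens[h.target_id])
                   for h in kept]
        _, base = classify(chain_collinear(kept), res.genome_lens,
                           res.transcript_lens, default_params)
        _, flip = classify(chain_collinear(flipped), res.genome_lens,
                           res.transcript_lens, default_params)
        assert base.equals(flip)


# --------------------------------------------------------------------------
# coverage
# --------------------------------------------------------------------------

class TestCoverage:
    def test_union_arithmetic(self):
        hs = [_hsp(ts=0, te=50), _hsp(ts=25, te=75)]
        rep = coverage(hs, {"t": 100}, "target_set")
        assert rep.pct == pytest.approx(75.0)

    def test_no_hsps_gives_zero(self):
        assert coverage([], {"t": 100}, "target_set").pct == 0.0

    def test_interval_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            coverage([_hsp(ts=0, te=200)], {"t": 100}, "target_set")

    def test_matches_per_base_mask_oracle(self, rng):
        lens = {f"s{i}": int(rng.integers(50, 300)) for i in range(100)}
        hs = []
        for sid, L in lens.items():
            for _ in range(int(rng.integers(0, 5))):
                s = int(rng.integers(0, L - 10))
                e = int(rng.integers(s + 1, L + 1))
                hs.append(_hsp(t=sid, ts=s, te=e))
        rep = coverage(hs, lens, "target_set")
        masks = {sid: np.zeros(L, bool) for sid, L in lens.items()}
        for h in hs:
            masks[h.target_id][h.t_start:h.t_end] = True
        assert rep.covered_bp == sum(int(m.sum()) for m in masks.values())
        assert rep.total_bp == sum(lens.values())

    def test_tightening_thresholds_never_raises_coverage(self, rng):
        hs = []
        for i in range(200):
            L = int(rng.integers(20, 150))
            hs.append(_hsp(q=f"q{i % 20}", qs=0, qe=L,
                           identity=float(rng.uniform(80, 100)), length=L))
        lens = {f"q{i}": 200 for i in range(20)}
        last = 101.0
        for ident in (80, 85, 90, 95):
            params = FilterParams(round1_min_identity_pct=ident)
            pct = coverage(filter_hsps(hs, params), lens, "query_set").pct
            assert pct <= last
            last = pct


# --------------------------------------------------------------------------
# 1-to-1 selection, joins, known genes
# --------------------------------------------------------------------------

class TestOneToOne:
    def test_single_hsp_chain_rejected(self, default_params):
        ch = Chain("q", "t", "+", [_hsp(qs=0, qe=500)])
        assert one_to_one_select([ch], default_params) == []

    def test_qualifying_chain_accepted(self, default_params):
        ch = Chain("q", "t", "+", [_hsp(qs=0, qe=60, ts=0, te=60, identity=95),
                                   _hsp(qs=60, qe=120, ts=200, te=260,
                                        identity=96)])
        assert one_to_one_select([ch], default_params) == [("q", "t")]

    def test_two_target_query_excluded(self, default_params):
        mk = lambda t: Chain("q", t, "+", [
            _hsp(t=t, qs=0, qe=60, ts=0, te=60, identity=95),
            _hsp(t=t, qs=60, qe=120, ts=200, te=260, identity=96)])
        assert one_to_one_select([mk("t1"), mk("t2")], default_params) == []

    def test_covered_exactly_100_rejected(self, default_params):
        ch = Chain("q", "t", "+", [_hsp(qs=0, qe=51, ts=0, te=51, identity=95),
                                   _hsp(qs=51, qe=100, ts=200, te=249,
                                        identity=95, length=51)])
        assert ch.covered_qbp == 100
        assert one_to_one_select([ch], default_params) == []


class TestJoinGraph:
    def test_planted_joins_form_edges(self, planted_result, default_params):
        res = planted_result
        chains = chain_collinear(filter_hsps(res.hsps, default_params))
        feats, _ = classify(chains, res.genome_lens, res.transcript_lens,
                            default_params)
        g, report = join_graph([f for f in feats if f.category == "I"])
        assert report["n_edges"] == len(res.truth.joins)
        for t1, t2, _ in res.truth.joins:
            assert g.has_edge(t1, t2)

    def test_shared_edge_accumulates_support(self):
        from estmap.reconcile import ClassifiedFeature
        f1 = ClassifiedFeature("I", "q1", "A", target_id2="B")
        f2 = ClassifiedFeature("I", "q2", "A", target_id2="B")
        g, report = join_graph([f1, f2])
        assert report["n_edges"] == 1
        assert g.edges["A", "B"]["support"] == {"q1", "q2"}

    def test_transitive_joins_form_one_component(self):
        from estmap.reconcile import ClassifiedFeature
        feats = [ClassifiedFeature("I", "q1", "A", target_id2="B"),
                 ClassifiedFeature("I", "q2", "B", target_id2="C")]
        _, report = join_graph(feats)
        assert report["component_sizes"] == [3]


class TestKnownGeneCoverage:
    def test_printed_formula(self):
        hs = [_hsp(q="tr1", t="gene", qs=0, qe=200, ts=0, te=200,
                   identity=95, evalue=1e-30),
              _hsp(q="tr2", t="gene", qs=0, qe=200, ts=300, te=500,
                   identity=95, evalue=1e-30)]
        df = known_gene_coverage(hs, {"gene": 500})
        row = df.iloc[0]
        assert row.coverage_pct == pytest.approx(80.0)
        assert row.n_seqs == 2
        assert row.avg_cov_pct == pytest.approx(40.0)

    def test_evalue_cutoff_applied(self):
        hs = [_hsp(q="tr", t="gene", qs=0, qe=200, ts=0, te=200,
                   identity=95, evalue=0.01)]
        df = known_gene_coverage(hs, {"gene": 500})
        assert df.iloc[0].coverage_pct == 0.0

    def test_gene_without_hits_reported_with_zeros(self):
        df = known_gene_coverage([], {"lonely": 300})
        row = df.iloc[0]
        assert (row.n_seqs, row.coverage_pct, row.avg_cov_pct) == (0, 0.0, 0.0)

    def test_matches_per_base_oracle_on_collinear_fixtures(self, rng):
        cutoffs = KnownGeneCutoffs()
        for _ in range(100):
            glen = int(rng.integers(300, 800))
            hs = []
            for q in range(int(rng.integers(1, 4))):
                pos = 0
                qpos = 0
                for _ in range(int(rng.integers(1, 4))):
                    pos += int(rng.integers(1, 60))
                    length = int(rng.integers(30, 120))
                    if pos + length > glen:
                        break
                    hs.append(_hsp(q=f"tr{q}", t="g", qs=qpos,
                                   qe=qpos + length, ts=pos, te=pos + length,
                                   identity=float(rng.uniform(70, 100)),
                                   evalue=float(10 ** -rng.uniform(0, 40))))
                    pos += length
                    qpos += length + 5
            df = known_gene_coverage(hs, {"g": glen}, cutoffs)
            passing = [h for h in hs if h.evalue <= 0.001
                       and h.identity_pct > 80 and h.aln_len > 50]
            mask = np.zeros(glen, bool)
            for h in passing:
                mask[h.t_start:h.t_end] = True
            row = df.iloc[0]
            assert row.coverage_pct == pytest.approx(100 * mask.sum() / glen)
            assert row.n_seqs == len({h.query_id for h in passing})
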