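"""End-to-end pipeline driver over a synthetic dataset.

Runs every stage in order — simulate, filter, chain, classify, coverage,
1-to-1 selection, intron inference, PWMs, TM consensus, census and GO
rollup — and writes the standard report files.  All stages are seeded from
the one configuration, so two runs with the same config produce
byte-identical reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import census, gorollup, orf, reconcile, simulate, splice
from .io import write_fasta, write_gff3_introns, write_hsp_table


def run_pipeline(cfg: simulate.SimConfig, out_dir: str | Path,
                 params: reconcile.FilterParams | None = None) -> dict:
    """Run the full analysis on a freshly simulated dataset.

    Returns a summary dict of headline numbers; reports land in
    ``out_dir``.
    """
    params = params or reconcile.FilterParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = simulate.simulate(cfg)
    result.write(out / "inputs")

    kept = reconcile.filter_hsps(result.hsps, params)
    chains = reconcile.chain_collinear(kept, overlap_tol=params.overlap_tol)
    features, counts = reconcile.classify(chains, result.genome_lens,
                                          result.transcript_lens, params)
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    reconcile.features_table(features).to_csv(out / "features.tsv", sep="\t",
                                              index=False)

    cov_q = reconcile.coverage(kept, result.transcript_lens, "query_set")
    cov_t = reconcile.coverage(kept, result.genome_lens, "target_set")
    pd.DataFrame([
        {"side": cov_q.side, "covered_bp": cov_q.covered_bp,
         "total_bp": cov_q.total_bp, "pct": round(cov_q.pct, 4)},
        {"side": cov_t.side, "covered_bp": cov_t.covered_bp,
         "total_bp": cov_t.total_bp, "pct": round(cov_t.pct, 4)},
    ]).to_csv(out / "coverage.tsv", sep="\t", index=False)

    pairs = reconcile.one_to_one_select(chains, params)
    pd.DataFrame(pairs, columns=["transcript", "genome_contig"]).to_csv(
        out / "one2one.tsv", sep="\t", index=False)

    i_features = [f for f in features if f.category == "I"]
    _, join_report = reconcile.join_graph(i_features) if i_features \
        else (None, {"n_edges": 0, "n_supporting_queries": 0,
                     "component_sizes": []})
    pd.DataFrame([{"contig1": f.target_id, "contig2": f.target_id2,
                   "transcript": f.query_id} for f in i_features]).to_csv(
        out / "joins.tsv", sep="\t", index=False)

    # splice analysis on univocal pairs
    genome_seqs = result.genome_seqs
    chain_by_pair = {}
    for ch in chains:
        key = (ch.query_id, ch.target_id)
        if key not in chain_by_pair or ch.covered_qbp > \
                chain_by_pair[key].covered_qbp:
            chain_by_pair[key] = ch
    introns = []
    for q, t in pairs:
        ch = chain_by_pair.get((q, t))
        if ch is None:
            continue
        introns.extend(splice.refine_boundaries(ch, genome_seqs[t],
                                                params=params))
    introns.sort(key=lambda i: (i.source_query_id, i.intron_index))
    write_gff3_introns(introns, out / "introns.gff3")
    splice.sites_table(introns, genome_seqs).to_csv(out / "sites.tsv",
                                                    sep="\t", index=False)
    stats = splice.intron_stats(introns)
    donor_ic = []
    if any(i.cls == "U2" for i in introns):
        donor_pwm, acceptor_pwm = splice.donor_acceptor_pwms(
            introns, genome_seqs, classes=("U2",))
        donor_pwm.to_frame().to_csv(out / "pwm_u2_donor.tsv", sep="\t",
                                    index=False)
        acceptor_pwm.to_frame().to_csv(out / "pwm_u2_acceptor.tsv", sep="\t",
                                       index=False)
        donor_ic = [round(float(x), 6) for x in donor_pwm.ic]

    # TM consensus on the simulated protein set (built-in hydropathy panel)
    aa_db = {p.id: p.seq for p in result.proteins}
    sp_map = {pid: t["sp"] for pid, t in result.truth.tm.items() if t["sp"]}
    panel = orf.run_builtin_panel(aa_db, phobius_sp=sp_map)
    consensus = orf.consensus_and_dedupe(panel, aa_db)
    orf.consensus_table(consensus, aa_db).to_csv(out / "consensus.tsv",
                                                 sep="\t", index=False)

    # census on a membership fixture drawn from the same seed
    rng = np.random.default_rng(cfg.seed + 104729)
    membership = simulate.simulate_membership(rng)
    venn = census.venn3(membership, ("a90", "a98", "a90e"))
    venn.to_csv(out / "venn.tsv", sep="\t", index=False)
    seq_stats = census.set_stats(result.genome)
    pd.DataFrame([vars(seq_stats)]).to_csv(out / "stats.tsv", sep="\t",
                                           index=False)

    # GO rollup on a seeded annotation fixture over a toy ontology
    obo_text = simulate.random_ontology_obo(rng, n_terms=12)
    obo_path = out / "toy_ontology.obo"
    obo_path.write_text(obo_text)
    graph = gorollup.load_ontology(obo_path)
    terms = sorted(graph.nodes)
    ann_hsps, protein2go = simulate.random_annotation_fixture(rng, 50, terms)
    passing = gorollup.filter_annotation_hsps(ann_hsps)
    assignments = gorollup.assign_terms(passing, protein2go)
    tables = gorollup.rollup(assignments, graph, level=2,
                             n_queries_total=50)
    for ns, table in tables.items():
        table.rows.to_csv(out / f"go_{ns}.tsv", sep="\t", index=False)

    accepted = [r.protein_id for r in consensus if r.accepted]
    nonredundant = [r.protein_id for r in consensus
                    if r.accepted and r.redundant_of is None]
    summary = {
        "category_counts": dict(zip(counts["category"], counts["count"].astype(int))),
        "coverage_query_pct": round(cov_q.pct, 4),
        "coverage_target_pct": round(cov_t.pct, 4),
        "n_one_to_one": len(pairs),
        "n_introns": stats["n_introns"],
        "donor_ic": donor_ic,
        "join_edges": join_report["n_edges"],
        "tm_accepted": len(accepted),
        "tm_nonredundant": len(nonredundant),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True) + "\n")
    return summary
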