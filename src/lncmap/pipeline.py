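"""End-to-end run on a synthetic dataset with a planted-truth report.

``run_all`` generates a dataset, writes it to disk, reads it back through
the format layer, and runs discovery filtering, expression metrics,
specificity, conservation, stage-pair differential expression,
neighbor-gene correlation, the co-expression network and
guilt-by-association. The returned report compares every stage against the
planted truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import conservation as cons
from . import diffexpr as de
from . import expression as ex
from . import filters as fl
from . import io as lio
from . import network as nw
from . import simulate as sim
from . import specificity as sp
from .simulate import MUSCLE_SAMPLES, SimulationConfig, SyntheticTruth


def _filter_report(verdicts, truth: SyntheticTruth) -> dict:
    by_id = {v.transcript_id: v for v in verdicts}
    planted = set(truth.lncrna_category)
    retained = {v.transcript_id for v in verdicts if v.fate == "retained"}
    tp = len(retained & planted)
    precision = tp / len(retained) if retained else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    category_correct = sum(
        1 for tid in planted
        if tid in by_id and by_id[tid].fate == "retained"
        and by_id[tid].category == truth.lncrna_category[tid]
    )
    decoy_step_correct = sum(
        1 for tid, step in truth.decoy_step.items()
        if tid in by_id and by_id[tid].fate == "removed" and by_id[tid].step == step
    )
    novel_correct = sum(
        1 for tid, novel in truth.lncrna_novel.items()
        if tid in by_id and by_id[tid].fate == "retained" and by_id[tid].novel == novel
    )
    return {
        "n_input": len(verdicts),
        "n_retained": len(retained),
        "precision": precision,
        "recall": recall,
        "category_accuracy": category_correct / len(planted),
        "decoy_step_accuracy": decoy_step_correct / len(truth.decoy_step),
        "novel_flag_accuracy": novel_correct / len(truth.lncrna_novel),
        "pass": precision == 1.0 and recall == 1.0
        and category_correct == len(planted)
        and decoy_step_correct == len(truth.decoy_step),
    }


def _specificity_report(expr: ex.ExpressionMatrix, truth: SyntheticTruth, lnc_ids) -> dict:
    rpkm = expr.rpkm.loc[[t for t in lnc_ids if t in expr.rpkm.index]]
    scores = sp.js_specificity_matrix(rpkm)
    assoc = sp.tissue_association(rpkm, muscle_samples=MUSCLE_SAMPLES)
    planted_specific = {t for t in rpkm.index if truth.specificity.get(t, "") != "ubiquitous"}
    planted_flat = set(rpkm.index) - planted_specific
    organ_specific = {
        t for t in planted_specific if truth.specificity[t] != sp.DEFAULT_MUSCLE_LABEL
    }

    assoc_recall = (
        sum(1 for t in planted_specific if truth.specificity[t] in assoc[t])
        / len(planted_specific)
        if planted_specific else float("nan")
    )

    def _best_ok(t: str) -> bool:
        best = scores.loc[t, "best_tissue"]
        if truth.specificity[t] == sp.DEFAULT_MUSCLE_LABEL:
            return best in MUSCLE_SAMPLES
        return best == truth.specificity[t]

    best_correct = (
        sum(1 for t in planted_specific if _best_ok(t)) / len(planted_specific)
        if planted_specific else float("nan")
    )
    min_js_organ = float(scores.loc[sorted(organ_specific), "js_score"].min())
    mean_js_flat = float(scores.loc[sorted(planted_flat), "js_score"].mean())
    flat_fpr = (
        sum(1 for t in planted_flat if assoc[t]) / len(planted_flat)
        if planted_flat else float("nan")
    )
    report = sp.specificity_report(assoc)
    return {
        "planted_specific_fraction": len(planted_specific) / len(rpkm),
        "association_recall": assoc_recall,
        "best_tissue_accuracy": best_correct,
        "min_js_organ_specific": min_js_organ,
        "mean_js_ubiquitous": mean_js_flat,
        "flat_profile_association_rate": flat_fpr,
        "z_rule_report": report,
        "pass": assoc_recall == 1.0
        and best_correct == 1.0
        and min_js_organ >= 0.8
        and mean_js_flat <= 0.5,
    }


def _conservation_report(calls, truth: SyntheticTruth) -> dict:
    class_errors = 0
    frac_err = 0.0
    hom_errors = 0
    for call in calls:
        tid = call.transcript_id
        if tid not in truth.conservation_class:
            continue
        if call.genome_class != truth.conservation_class[tid]:
            class_errors += 1
        fa, fb = truth.conservation_fractions[tid]
        frac_err = max(
            frac_err,
            abs(call.covered_fraction_a - fa),
            abs(call.covered_fraction_b - fb),
        )
        ha, hb = truth.transcript_homology[tid]
        if call.transcript_homology_a != ha or call.transcript_homology_b != hb:
            hom_errors += 1
    return {
        "n_calls": len(calls),
        "class_errors": class_errors,
        "max_fraction_error": frac_err,
        "homology_errors": hom_errors,
        "pass": class_errors == 0 and hom_errors == 0 and frac_err <= 1e-9,
    }


def _de_report(counts: lio.CountMatrix, truth: SyntheticTruth, lnc_ids) -> dict:
    lnc_in = [t for t in lnc_ids if t in counts.counts.index]
    sub = lio.CountMatrix(counts.counts.loc[lnc_in], counts.library_sizes)
    result = de.call_de(sub, MUSCLE_SAMPLES)
    union = set(result["union"])
    planted = {
        t for t, pairs in truth.de_log2fc.items()
        if any(abs(v) > 0 for v in pairs.values()) and t in counts.counts.index
    }
    tp = len(union & planted)
    recall = tp / len(planted) if planted else float("nan")
    precision = tp / len(union) if union else float("nan")
    return {
        "n_de_called": len(union),
        "n_planted": len(planted),
        "recall": recall,
        "precision": precision,
        "per_pair": {f"{a}|{b}": len(v) for (a, b), v in result["significant_per_pair"].items()},
        "pass": recall >= 0.9,
    }


def _network_report(
    net_counts: lio.CountMatrix,
    trait: pd.Series,
    truth: SyntheticTruth,
    transcripts,
    annotation,
    go_map,
) -> dict:
    lengths = {t.transcript_id: t.exonic_length for t in transcripts}
    for t in annotation:
        lengths.setdefault(t.gene_id, t.exonic_length)
    expr = ex.compute_rpkm(net_counts, lengths)
    log_rpkm = np.log2(expr.rpkm + 1.0)
    net = nw.build_network(
        log_rpkm, beta=6, min_module_size=30, trait_vector=trait.to_numpy()
    )
    module_ids = [g for g in log_rpkm.index if g in truth.module_label]
    planted_labels = [truth.module_label[g] for g in module_ids]
    detected_labels = net.module_labels.loc[module_ids].tolist()
    ari = adjusted_rand_score(planted_labels, detected_labels)

    # which detected module carries the planted trait-linked genes?
    trait_planted = truth.trait_linked_modules[0] if truth.trait_linked_modules else None
    trait_top = False
    gba_term_enriched = False
    if trait_planted is not None and net.module_trait is not None:
        members = [g for g in module_ids if truth.module_label[g] == trait_planted]
        detected = pd.Series(net.module_labels.loc[members]).mode()
        if len(detected):
            trait_top = net.module_trait.index[0] == detected.iloc[0]
        # guilt-by-association for a planted lncRNA member of the trait module
        lnc_members = [g for g in members if g in truth.lncrna_category]
        pcg_in_net = [g for g in truth.pcg_gene_ids if g in log_rpkm.index]
        if lnc_members:
            gba = nw.guilt_by_association(lnc_members[0], log_rpkm, pcg_in_net, go_map)
            hallmark = truth.module_go_term[trait_planted]
            gba_term_enriched = gba.assessed and any(
                r.term_id == hallmark and r.q < 0.05 for r in gba.enriched_terms
            )
    n_hubs = int(net.hubs.sum()) if net.hubs is not None else 0
    return {
        "n_genes": int(log_rpkm.shape[0]),
        "n_modules": len(set(net.module_labels) - {nw.UNASSIGNED}),
        "module_ari": float(ari),
        "trait_module_top": bool(trait_top),
        "n_hubs": n_hubs,
        "gba_hallmark_enriched": bool(gba_term_enriched),
        "pass": ari >= 0.95 and trait_top and gba_term_enriched,
    }


def run_all(seed: int = 42, outdir: str | Path = "lncmap_run", config: SimulationConfig | None = None) -> dict:
    """Generate, write, re-read and analyze a full synthetic dataset.

    Returns the truth-comparison report (also written to
    ``<outdir>/report.json``).
    """
    outdir = Path(outdir)
    if config is None:
        config = SimulationConfig(seed=seed)
    truth = sim.emit_dataset(config, outdir)

    # everything below goes through the files, exercising the format layer
    annotation = lio.read_gtf(outdir / "annotation.gtf")
    transcripts = lio.read_gtf(outdir / "transcripts.gtf")
    coding = lio.read_coding_table(outdir / "coding.tsv")
    ncrna = lio.read_ncrna_table(outdir / "ncrna.tsv")
    counts = lio.read_counts(outdir / "counts.tsv")
    net_counts = lio.read_counts(outdir / "network_counts.tsv")
    trait = pd.read_csv(outdir / "muscle_vector.tsv", sep="\t", index_col=0)["muscle"]
    chains_a = lio.read_chain(outdir / "pig2human.chain")
    chains_b = lio.read_chain(outdir / "pig2mouse.chain")
    hits_a = lio.read_hits(outdir / "hits_human.tsv")
    hits_b = lio.read_hits(outdir / "hits_mouse.tsv")
    go_map = lio.read_go(outdir / "go_map.tsv")

    verdicts = fl.run_filter_pipeline(transcripts, annotation, coding, ncrna)
    by_id = {v.transcript_id: v for v in verdicts}
    lnc_ids = [v.transcript_id for v in verdicts if v.fate == "retained"]

    lengths = {t.transcript_id: t.exonic_length for t in transcripts}
    for t in annotation:
        lengths.setdefault(t.gene_id, t.exonic_length)
    expr = ex.compute_rpkm(counts, lengths)

    tx_by_id = {t.transcript_id: t for t in transcripts}
    lnc_models = [tx_by_id[t] for t in lnc_ids]
    calls = cons.call_conservation(lnc_models, chains_a, chains_b, hits_a, hits_b)

    neighbor = de.neighbor_correlation(
        lnc_models, annotation, expr, {v.transcript_id: v for v in verdicts}
    )

    # sample tree: the muscle stages should form a clade before any
    # non-muscle sample joins them
    tree = ex.cluster_samples(expr, subset=[t for t in lnc_ids if t in expr.rpkm.index])
    muscle_set = set(MUSCLE_SAMPLES)
    i_clade = i_mixed = None
    for i, (a, b, _h) in enumerate(tree.merge_order()):
        merged = a | b
        if i_clade is None and merged == muscle_set:
            i_clade = i
        if i_mixed is None and merged & muscle_set and merged - muscle_set:
            i_mixed = i
    muscle_clade = i_clade is not None and (i_mixed is None or i_clade < i_mixed)

    report = {
        "seed": seed,
        "filter": _filter_report(verdicts, truth),
        "specificity": _specificity_report(expr, truth, lnc_ids),
        "conservation": _conservation_report(calls, truth),
        "differential_expression": _de_report(counts, truth, lnc_ids),
        "neighbor_correlation": {
            "mean_r_intergenic": neighbor["nearest_intergenic"]["mean_r"],
            "fraction_positive": neighbor["nearest_intergenic"]["fraction_positive"],
            "pass": bool(neighbor["nearest_intergenic"]["mean_r"] > 0.2),
        },
        "sample_tree": {
            "muscle_stages_form_clade": bool(muscle_clade),
            "pass": bool(muscle_clade),
        },
        "network": _network_report(net_counts, trait, truth, transcripts, annotation, go_map),
    }
    report["all_pass"] = all(
        section["pass"] for section in report.values() if isinstance(section, dict) and "pass" in section
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
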