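"""Discovery filter: step order, positional classification, and agreement
with per-base brute-force oracles."""

import numpy as np
import pytest

from conftest import make_tx
from lncmap.filters import (
    classify_position,
    interval_overlap_fraction,
    run_filter_pipeline,
)
from lncmap.intervals import covered_mask
from lncmap.io import GenomicInterval

NONCODING = {"CNCI": "noncoding", "CPC": "noncoding"}


@pytest.fixture(scope="module")
def annotation():
    # one protein-coding gene: exons [1000,1300) and [2000,2300), span 1300 nt
    return [make_tx("g1.t1", [(1000, 1300), (2000, 2300)], strand="+",
                    gene_id="g1", biotype="protein_coding")]


def _run(transcripts, annotation, coding=None, ncrna=None, **kw):
    coding = coding or {t.transcript_id: NONCODING for t in transcripts}
    return run_filter_pipeline(transcripts, annotation, coding, ncrna or {}, **kw)


class TestFilterSteps:
    def test_mono_exonic_removed_first_even_if_long(self, annotation):
        t = make_tx("t", [(10_000, 15_000)])
        (v,) = _run([t], annotation)
        assert (v.fate, v.step) == ("removed", "multi_exon")

    def test_short_multi_exon_removed_at_length(self, annotation):
        t = make_tx("t", [(10_000, 10_100), (10_200, 10_250)])
        (v,) = _run([t], annotation)
        assert (v.fate, v.step) == ("removed", "length")

    def test_same_strand_exon_overlap_removed(self, annotation):
        t = make_tx("t", [(1200, 1400), (1500, 1700)], strand="+")
        (v,) = _run([t], annotation)
        assert (v.fate, v.step) == ("removed", "annotated_overlap")

    def test_opposite_strand_overlap_survives_as_antisense(self, annotation):
        t = make_tx("t", [(1200, 1400), (1500, 1700)], strand="-")
        (v,) = _run([t], annotation)
        assert (v.fate, v.category) == ("retained", "antisense")

    def test_any_caller_coding_removes(self, annotation):
        t = make_tx("t", [(10_000, 10_300), (10_500, 10_800)])
        (v,) = _run([t], annotation, coding={"t": {"CNCI": "coding", "CPC": "noncoding"}})
        assert (v.fate, v.step) == ("removed", "coding_potential")

    def test_structural_ncrna_homology_removes(self, annotation):
        t = make_tx("t", [(10_000, 10_300), (10_500, 10_800)])
        (v,) = _run([t], annotation, ncrna={"t": {"tRNA"}})
        assert (v.fate, v.step) == ("removed", "ncrna_homology")

    def test_lncrna_model_only_match_is_retained(self, annotation):
        t = make_tx("t", [(10_000, 10_300), (10_500, 10_800)])
        (v,) = _run([t], annotation, ncrna={"t": {"lncRNA_model"}})
        assert v.fate == "retained"

    def test_annotated_lncrna_bypasses_overlap_and_is_not_novel(self, annotation):
        known = make_tx("k", [(10_000, 10_300), (10_500, 10_800)], biotype="annotated_lncRNA")
        (v,) = _run([known], annotation + [known])
        assert (v.fate, v.novel) == ("retained", False)

    def test_missing_coding_verdict_configurable(self, annotation):
        t = make_tx("t", [(10_000, 10_300), (10_500, 10_800)])
        with pytest.raises(KeyError):
            run_filter_pipeline([t], annotation, {}, {})
        (v,) = run_filter_pipeline([t], annotation, {}, {}, missing_coding="noncoding")
        assert v.fate == "retained"


def test_verdicts_partition_input_and_ignore_order(dataset):
    coding = {t.transcript_id: NONCODING for t in dataset.transcripts}
    for tid, step in dataset.truth.decoy_step.items():
        if step == "coding_potential":
            coding[tid] = {"CNCI": "coding", "CPC": "noncoding"}
    for tid in dataset.truth.pcg_transcript_ids:
        coding[tid] = {"CNCI": "coding", "CPC": "coding"}
    verdicts = run_filter_pipeline(dataset.transcripts, dataset.annotation, coding, {})
    assert len(verdicts) == len(dataset.transcripts)
    removed = [v for v in verdicts if v.fate == "removed"]
    retained = [v for v in verdicts if v.fate == "retained"]
    assert len(removed) + len(retained) == len(verdicts)

    rng = np.random.default_rng(0)
    shuffled = [dataset.transcripts[i] for i in rng.permutation(len(dataset.transcripts))]
    verdicts2 = run_filter_pipeline(shuffled, dataset.annotation, coding, {})
    assert {(v.transcript_id, v.fate, v.step, v.category) for v in verdicts} == {
        (v.transcript_id, v.fate, v.step, v.category) for v in verdicts2
    }


class TestClassifyPosition:
    def test_far_transcript_is_intergenic(self, annotation):
        t = make_tx("t", [(7500, 7700), (7900, 8200)])
        assert classify_position(t, annotation) == "intergenic"

    def test_opposite_strand_exon_overlap_is_antisense(self, annotation):
        t = make_tx("t", [(1250, 1450), (1600, 1800)], strand="-")
        assert classify_position(t, annotation) == "antisense"

    def test_inside_intron_same_strand_is_intronic(self, annotation):
        t = make_tx("t", [(1400, 1500), (1600, 1900)], strand="+")
        assert classify_position(t, annotation) == "intronic"

    def test_within_2kb_upstream_is_cis_regulatory(self, annotation):
        # ends 500 bp before the gene span starts
        t = make_tx("t", [(200, 300), (400, 500)])
        assert classify_position(t, annotation) == "cis_regulatory"

    def test_agrees_with_per_base_oracle_on_random_transcripts(self):
        """1,000 random transcripts against a brute-force per-base rule set."""
        rng = np.random.default_rng(11)
        genes = [
            make_tx(
                f"g{k}.t1",
                [(s, s + 300), (s + 800, s + 1100), (s + 1600, s + 2000)],
                strand="+" if k % 2 == 0 else "-",
                gene_id=f"g{k}",
                biotype="protein_coding",
            )
            for k, s in enumerate(range(1000, 61_000, 6000))
        ]
        L = 70_000
        gene_exon_mask = {"+": np.zeros(L, bool), "-": np.zeros(L, bool)}
        span_list = []
        for g in genes:
            for e in g.exons:
                gene_exon_mask[g.strand][e.start:e.end] = True
            span_list.append((g.interval.start, g.interval.end, g.exons))
        for _ in range(1000):
            s = int(rng.integers(0, L - 3000))
            l1, gap, l2 = rng.integers(100, 400, size=3)
            strand = "+" if rng.random() < 0.5 else "-"
            t = make_tx("t", [(s, s + l1), (s + l1 + gap, s + l1 + gap + l2)], strand=strand)
            mask = covered_mask([(e.start, e.end) for e in t.exons], 0, L)
            opp = "-" if strand == "+" else "+"
            if (mask & gene_exon_mask[opp]).any():
                expected = "antisense"
            elif any(
                a <= t.interval.start and t.interval.end <= b
                and not any(
                    max(e.start, x.start) < min(e.end, x.end)
                    for e in exons for x in t.exons
                )
                for a, b, exons in span_list
            ):
                expected = "intronic"
            elif min(
                max(a, t.interval.start) - min(b, t.interval.end) for a, b, _ in span_list
            ) < 2000:
                expected = "cis_regulatory"
            else:
                expected = "intergenic"
            assert classify_position(t, genes) == expected


class TestOverlapFraction:
    def test_identity_and_disjoint(self):
        t = make_tx("t", [(0, 100), (200, 300)])
        assert interval_overlap_fraction(t, [GenomicInterval("chr1", 0, 100),
                                             GenomicInterval("chr1", 200, 300)]) == 1.0
        assert interval_overlap_fraction(t, [GenomicInterval("chr1", 500, 600)]) == 0.0

    def test_partial_overlap_half(self):
        t = make_tx("t", [(0, 100), (200, 300)])
        assert interval_overlap_fraction(t, [GenomicInterval("chr1", 50, 250)]) == 0.5

    def test_matches_per_base_count_on_random_cases(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            a = int(rng.integers(0, 500))
            exons = [(a, a + int(rng.integers(50, 200)))]
            b = exons[0][1] + int(rng.integers(10, 100))
            exons.append((b, b + int(rng.integers(50, 200))))
            t = make_tx("t", exons)
            feats = []
            for _ in range(int(rng.integers(0, 5))):
                s = int(rng.integers(0, 900))
                feats.append(GenomicInterval("chr1", s, s + int(rng.integers(5, 150))))
            got = interval_overlap_fraction(t, feats)
            exon_mask = covered_mask(exons, 0, 1200)
            feat_mask = covered_mask([(f.start, f.end) for f in feats], 0, 1200)
            assert got == pytest.approx((exon_mask & feat_mask).sum() / exon_mask.sum())


def test_planted_truth_recovery(dataset):
    """Every planted lncRNA retained with its category; every decoy removed
    at its planted step (noiseless synthetic data)."""
    from lncmap.simulate import generate_coding_table, generate_ncrna_table

    coding = generate_coding_table(dataset.transcripts, dataset.truth)
    ncrna = generate_ncrna_table(dataset.truth)
    verdicts = run_filter_pipeline(dataset.transcripts, dataset.annotation, coding, ncrna)
    by_id = {v.transcript_id: v for v in verdicts}
    for tid, category in dataset.truth.lncrna_category.items():
        assert by_id[tid].fate == "retained"
        assert by_id[tid].category == category
        assert by_id[tid].novel == dataset.truth.lncrna_novel[tid]
    for tid, step in dataset.truth.decoy_step.items():
        assert (by_id[tid].fate, by_id[tid].step) == ("removed", step)
    retained = {v.transcript_id for v in verdicts if v.fate == "retained"}
    assert retained == set(dataset.truth.lncrna_category)
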