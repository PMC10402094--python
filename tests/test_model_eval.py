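import math

import numpy as np
import pandas as pd
import pytest

from isobench import (
    Annotation,
    SimConfig,
    SupportTrack,
    TranscriptModel,
    TruthSet,
    build_barcodes,
    build_reference_index,
    classify_set,
    classify_transcript,
    end_support,
    evaluate_detection,
    frequently_detected,
    junction_support,
    pairwise_overlap,
    simulate_annotation,
    ujc_key,
)
from isobench.models import ValidationError

from _oracles import brute_detection_counts


def sirv_fixture():
    """10 single-isoform 'rSIRV' genes plus a crafted submission:
    6 RM copies, 2 FSMs with 200-nt end extensions (non-RM), 1 NNC,
    1 antisense model."""
    cfg = SimConfig(seed=3, n_genes=10, isoforms_per_gene=1)
    ann = simulate_annotation(cfg)
    tids = ann.transcript_ids
    models = [ann[tid] for tid in tids[:6]]
    for tid in tids[6:8]:
        t = ann[tid]
        ex = list(t.exons)
        ex[0] = (ex[0][0] - 200, ex[0][1])
        ex[-1] = (ex[-1][0], ex[-1][1] + 200)
        models.append(
            TranscriptModel(t.transcript_id + "_ext", t.gene_id, t.chrom,
                            t.strand, tuple(ex))
        )
    t = ann[tids[8]]
    ex = list(t.exons)
    j = len(ex) // 2 - 1
    s, e = ex[j]
    ex[j] = (s, e + 6)
    models.append(TranscriptModel("nnc1", t.gene_id, t.chrom, t.strand, tuple(ex)))
    t = ann[tids[9]]
    st = "-" if t.strand == "+" else "+"
    models.append(
        TranscriptModel(
            "as1", "novel", t.chrom, st,
            ((t.start + 40, t.start + 240), (t.start + 640, t.start + 840)),
        )
    )
    return ann, models


class TestDetection:
    def test_sirv_hand_counted_rates(self):
        """The worked 10-rSIRV fixture reproduces the printed-formula rates."""
        ann, models = sirv_fixture()
        classified, _ = classify_set(models, build_reference_index(ann))
        perf = evaluate_detection(classified, TruthSet(mode="sirv", transcripts=ann))
        assert (perf.TP, perf.PTP, perf.FN, perf.FP) == (6, 2, 2, 2)
        assert perf.sensitivity == pytest.approx(0.6)
        assert perf.precision == pytest.approx(0.6)
        assert perf.positive_detection_rate == pytest.approx(0.8)
        assert perf.false_discovery_rate == pytest.approx(0.4)
        assert perf.false_detection_rate == pytest.approx(0.2)
        assert perf.redundancy == pytest.approx(1.0)

    def test_perfect_submission(self, sim_bundle):
        ann = sim_bundle.annotation
        classified, _ = classify_set(list(ann), build_reference_index(ann))
        perf = evaluate_detection(classified, TruthSet(mode="sirv", transcripts=ann))
        assert perf.sensitivity == 1.0
        assert perf.precision == 1.0
        assert perf.positive_detection_rate == 1.0
        assert perf.false_discovery_rate == 0.0
        assert perf.redundancy == 1.0

    def test_duplicate_rm_counts_once_but_redundancy_two(self):
        cfg = SimConfig(seed=4, n_genes=1, isoforms_per_gene=1)
        ann = simulate_annotation(cfg)
        t = next(iter(ann))
        dup = TranscriptModel("copy", t.gene_id, t.chrom, t.strand, t.exons)
        classified, _ = classify_set([t, dup], build_reference_index(ann))
        perf = evaluate_detection(classified, TruthSet(mode="sirv", transcripts=ann))
        assert perf.TP == 1
        assert perf.redundancy == pytest.approx(2.0)

    def test_conservation_and_brute_force_agreement(self, sim_bundle):
        ann = sim_bundle.annotation
        classified, _ = classify_set(sim_bundle.submission, build_reference_index(ann))
        perf = evaluate_detection(classified, TruthSet(mode="sirv", transcripts=ann))
        assert perf.TP + perf.PTP + perf.FN == perf.n_truth
        tp, ptp, fn, fp = brute_detection_counts(classified, ann.transcript_ids)
        assert (perf.TP, perf.PTP, perf.FN, perf.FP) == (tp, ptp, fn, fp)

    def test_pure_fp_leaves_sensitivity_weakly_decreases_precision(self):
        ann, models = sirv_fixture()
        idx = build_reference_index(ann)
        base, _ = classify_set(models, idx)
        t = ann[ann.transcript_ids[0]]
        ex = list(t.exons)
        s, e = ex[1]
        ex[1] = (s, e + 9)  # novel donor -> NNC
        extra, _ = classify_set(
            models + [TranscriptModel("fp", t.gene_id, t.chrom, t.strand, tuple(ex))],
            idx,
        )
        truth = TruthSet(mode="sirv", transcripts=ann)
        p0, p1 = evaluate_detection(base, truth), evaluate_detection(extra, truth)
        assert p1.sensitivity == p0.sensitivity
        assert p1.precision < p0.precision
        assert p1.nr_precision < p0.nr_precision

    def test_simulated_mode_known_novel_split(self):
        ann, models = sirv_fixture()
        tids = ann.transcript_ids
        truth = TruthSet(
            mode="simulated",
            transcripts=ann,
            known_ids=frozenset(tids[:8]),
            novel_ids=frozenset(tids[8:]),
        )
        classified, _ = classify_set(models, build_reference_index(ann))
        perf = evaluate_detection(classified, truth)
        # all 6 RMs hit known truths; the novel pair got no RM
        assert perf.sens_ref == pytest.approx(6 / 8)
        assert perf.sens_novel == 0.0
        calls = perf.TP + perf.PTP + perf.FP
        assert perf.precision == pytest.approx(perf.TP / calls)
        assert perf.false_discovery_rate == pytest.approx((perf.FP + perf.PTP) / calls)

    def test_empty_truth_rejected_and_empty_submission_is_nan(self):
        ann, _ = sirv_fixture()
        with pytest.raises(ValidationError):
            evaluate_detection([], TruthSet(mode="sirv", transcripts=Annotation([])))
        perf = evaluate_detection([], TruthSet(mode="sirv", transcripts=ann))
        assert perf.sensitivity == 0.0
        assert math.isnan(perf.precision)
        assert math.isnan(perf.redundancy)


class TestSupport:
    def make_classified(self, ann, models):
        classified, _ = classify_set(models, build_reference_index(ann))
        return classified

    def test_fsm_with_exact_ends_is_srtm_via_reference(self, tiny_annotation):
        ref = tiny_annotation["GA.T1"]
        cl = self.make_classified(tiny_annotation, [ref])
        table = end_support(cl, tiny_annotation)
        row = table.iloc[0]
        assert row.ref_supported_5 and row.ref_supported_3 and row.SRTM

    def test_51nt_offset_is_unsupported(self, tiny_annotation):
        ref = tiny_annotation["GA.T3"]  # TSS 2000; GA.T2 acceptor at 2050
        ex = list(ref.exons)
        ex[0] = (ex[0][0] + 51, ex[0][1])
        q = TranscriptModel("q", "GA", "chr1", "+", tuple(ex))
        cl = self.make_classified(tiny_annotation, [q])
        table = end_support(cl, tiny_annotation)
        assert not table.iloc[0].ref_supported_5
        assert not table.iloc[0].supported_5

    def test_sntm_requires_peaks_and_novel_junction_reads(self, tiny_annotation):
        # exon-skip NIC of GA.T1 with exact terminal ends
        q = TranscriptModel(
            "q", "GA", "chr1", "+", ((1000, 1200), (2000, 2200), (2500, 2700))
        )
        cl = self.make_classified(tiny_annotation, [q])
        peaks5 = SupportTrack(
            "five_prime", pd.DataFrame({"chrom": ["chr1"], "start": [990], "end": [1010]})
        )
        peaks3 = SupportTrack(
            "three_prime", pd.DataFrame({"chrom": ["chr1"], "start": [2690], "end": [2710]})
        )
        covered = SupportTrack(
            "junction",
            pd.DataFrame(
                {"chrom": ["chr1"], "strand": ["+"], "donor": [1200],
                 "acceptor": [2000], "count": [3]}
            ),
        )
        table = end_support(cl, tiny_annotation, peaks5, peaks3, covered)
        assert bool(table.iloc[0].SNTM)
        uncovered = SupportTrack(
            "junction",
            pd.DataFrame(
                {"chrom": ["chr1"], "strand": ["+"], "donor": [1200],
                 "acceptor": [2000], "count": [0]}
            ),
        )
        table2 = end_support(cl, tiny_annotation, peaks5, peaks3, uncovered)
        assert not bool(table2.iloc[0].SNTM)

    def test_junction_support_fraction_and_summary(self, tiny_annotation):
        ref = tiny_annotation["GA.T1"]  # 3 junctions
        ref2 = tiny_annotation["GA.T2"]
        cl = self.make_classified(tiny_annotation, [ref, ref2])
        chain = [(1200, 1500), (1700, 2000)]  # 2 of T1's 3 junctions
        track = SupportTrack(
            "junction",
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "strand": "+",
                    "donor": [d for d, a in chain],
                    "acceptor": [a for d, a in chain],
                    "count": 5,
                }
            ),
        )
        per_model, summary = junction_support(cl, track)
        t1 = per_model.set_index("transcript_id").loc["GA.T1"]
        assert t1.frac_supported == pytest.approx(2 / 3)
        assert not t1.fully_supported
        fsm = summary.set_index("category").loc["FSM"]
        assert fsm.n_models == 2
        assert fsm.pct_fully_supported == 0.0

    def test_mono_exon_excluded_from_junction_support(self, tiny_annotation):
        cl = self.make_classified(tiny_annotation, [tiny_annotation["GC.T1"]])
        per_model, _ = junction_support(
            cl,
            SupportTrack(
                "junction",
                pd.DataFrame(
                    {"chrom": [], "strand": [], "donor": [], "acceptor": [], "count": []}
                ),
            ),
        )
        assert per_model.empty


class TestAgreement:
    def classified_subs(self, tiny_annotation):
        idx = build_reference_index(tiny_annotation)
        t1 = tiny_annotation["GA.T1"]
        t2 = tiny_annotation["GB.T1"]
        t3 = tiny_annotation["GA.T2"]
        a, _ = classify_set([t1, t2, t3], idx)
        b, _ = classify_set([t1, t2], idx)
        c, _ = classify_set([t1], idx)
        return {"p1": a, "p2": b, "p3": c}

    def test_barcode_counts(self, tiny_annotation):
        subs = self.classified_subs(tiny_annotation)
        barcodes = build_barcodes(subs)
        by_ujc = {bc.ujc: bc for bc in barcodes}
        assert len(barcodes) == 3  # distinct chains across the union
        assert by_ujc[ujc_key(tiny_annotation["GA.T1"])].n_pipelines_detecting == 3
        assert by_ujc[ujc_key(tiny_annotation["GA.T2"])].n_pipelines_detecting == 1
        with pytest.raises(ValidationError):
            build_barcodes({})

    def test_overlap_identical_and_subset(self, tiny_annotation):
        subs = self.classified_subs(tiny_annotation)
        m = pairwise_overlap({"a": subs["p1"], "b": subs["p1"]}, feature="ujc")
        assert (m.to_numpy() == 1.0).all()
        m2 = pairwise_overlap({"A": subs["p3"], "B": subs["p1"]}, feature="ujc")
        assert m2.loc["A", "B"] == 1.0          # A subset of B
        assert m2.loc["B", "A"] == pytest.approx(1 / 3)
        assert m2.loc["A", "A"] == 1.0 and m2.loc["B", "B"] == 1.0

    def test_overlap_disjoint_is_identity_pattern(self, tiny_annotation):
        idx = build_reference_index(tiny_annotation)
        a, _ = classify_set([tiny_annotation["GA.T1"]], idx)
        b, _ = classify_set([tiny_annotation["GB.T1"]], idx)
        m = pairwise_overlap({"a": a, "b": b}, feature="ujc")
        assert m.to_numpy().tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_dominant_ujc_requires_majority_share(self, tiny_annotation):
        idx = build_reference_index(tiny_annotation)
        models = [tiny_annotation["GA.T1"], tiny_annotation["GA.T2"]]
        cl, _ = classify_set(models, idx)
        ab = {"p": pd.Series({"GA.T1": 90.0, "GA.T2": 10.0})}
        m = pairwise_overlap({"p": cl, "q": cl}, feature="dominant_ujc",
                             abundances={"p": ab["p"], "q": ab["p"]})
        assert m.loc["p", "q"] == 1.0  # only the dominant chain remains

    def test_frequently_detected_thresholds(self, tiny_annotation):
        idx = build_reference_index(tiny_annotation)
        chain_x, _ = classify_set([tiny_annotation["GA.T1"]], idx)
        chain_y, _ = classify_set([tiny_annotation["GB.T1"]], idx)
        subs = {}
        # chain X: 3 datasets x 3 tools; chain Y: one pipeline only
        for ds in ("d1", "d2", "d3"):
            for tool in ("t1", "t2", "t3"):
                subs[f"{ds}/{tool}"] = chain_x
        subs["d1/t1"] = chain_x + chain_y
        barcodes = build_barcodes(subs)
        fdt, enrich = frequently_detected(barcodes, min_pipelines=3, min_datasets=3)
        kept = {bc.ujc for bc in fdt}
        assert ujc_key(tiny_annotation["GA.T1"]) in kept
        assert ujc_key(tiny_annotation["GB.T1"]) not in kept
        with pytest.raises(ValueError):
            frequently_detected(barcodes, min_pipelines=0)

    def test_all_fsm_enrichment_is_one(self, tiny_annotation):
        idx = build_reference_index(tiny_annotation)
        cl, _ = classify_set([tiny_annotation["GA.T1"]], idx)
        subs = {f"d{i}/t{i}": cl for i in range(1, 4)}
        barcodes = build_barcodes(subs)
        _, enrich = frequently_detected(barcodes, min_pipelines=3, min_datasets=3)
        fsm = enrich.set_index("category").loc["FSM"]
        assert fsm.fold_enrichment == pytest.approx(1.0)
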