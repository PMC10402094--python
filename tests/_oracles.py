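"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written by direct enumeration over reference
transcripts and replicate loops — deliberately naive and structurally
unrelated to the package's indexed/vectorized code paths.
"""

from __future__ import annotations

import math
import statistics

import numpy as np

from isobench.models import Annotation, TranscriptModel


def introns_of(t: TranscriptModel) -> list[tuple[int, int]]:
    return [(t.exons[i][1], t.exons[i + 1][0]) for i in range(len(t.exons) - 1)]


def brute_classify(model: TranscriptModel, annotation: Annotation, window: int = 50) -> str:
    """Exhaustive classifier: tests every reference transcript and every
    contiguous sub-chain directly."""
    q_introns = introns_of(model)
    same = [
        t for t in annotation if t.chrom == model.chrom and t.strand == model.strand
    ]
    anti = [
        t for t in annotation if t.chrom == model.chrom and t.strand != model.strand
    ]

    if q_introns:
        # FSM: any ref with an identical chain
        for t in same:
            if introns_of(t) == q_introns:
                return "FSM"
        # ISM: contiguous proper sub-chain of any ref chain
        for t in same:
            ri = introns_of(t)
            for i in range(len(ri)):
                for j in range(i + 1, len(ri) + 1):
                    if ri[i:j] == q_introns and len(q_introns) < len(ri):
                        return "ISM"
        # gene overlap by gene spans
        genes = {}
        for t in same:
            s, e = genes.get(t.gene_id, (t.start, t.end))
            genes[t.gene_id] = (min(s, t.start), max(e, t.end))
        overlapping = [
            g for g, (s, e) in genes.items() if s < model.end and model.start < e
        ]
        if not overlapping:
            for t in anti:
                if t.start < model.end and model.start < t.end:
                    return "ANTISENSE"
            return "INTERGENIC"
        # genes whose exons (or retained introns) the query touches
        def touches(gid):
            for t in same:
                if t.gene_id != gid:
                    continue
                for s, e in t.exons:
                    for qs, qe in model.exons:
                        if s < qe and qs < e:
                            return True
                for s, e in introns_of(t):
                    for qs, qe in model.exons:
                        if qs < s and qe > e:
                            return True
            return False

        exonic = [g for g in overlapping if touches(g)]
        if len(exonic) > 1:
            return "FUSION"
        gid = exonic[0] if exonic else overlapping[0]
        exon_hit = any(
            s < qe and qs < e
            for t in same
            if t.gene_id == gid
            for s, e in t.exons
            for qs, qe in model.exons
        )
        retention = any(
            qs < s and qe > e
            for t in same
            if t.gene_id == gid
            for s, e in introns_of(t)
            for qs, qe in model.exons
        )
        if not exon_hit and not retention:
            return "GENIC_INTRON"
        donors, acceptors = set(), set()
        for t in same:
            if t.gene_id != gid:
                continue
            for s, e in introns_of(t):
                d, a = (s, e) if t.strand == "+" else (e, s)
                donors.add(d)
                acceptors.add(a)
        ok = True
        for s, e in q_introns:
            d, a = (s, e) if model.strand == "+" else (e, s)
            ok = ok and d in donors and a in acceptors
        return "NIC" if ok else "NNC"

    # mono-exon
    qs, qe = model.exons[0]
    genes = {}
    for t in same:
        s, e = genes.get(t.gene_id, (t.start, t.end))
        genes[t.gene_id] = (min(s, t.start), max(e, t.end))
    overlapping = [g for g, (s, e) in genes.items() if s < qe and qs < e]
    if not overlapping:
        for t in anti:
            if t.start < qe and qs < t.end:
                return "ANTISENSE"
        return "INTERGENIC"
    fsm = ism = exonic = False
    for t in same:
        if t.gene_id not in overlapping:
            continue
        for s, e in t.exons:
            if s <= qs and qe <= e:
                if len(t.exons) == 1:
                    fsm = True
                else:
                    ism = True
            if s < qe and qs < e:
                exonic = True
    if fsm:
        return "FSM"
    if ism:
        return "ISM"
    return "GENIC_GENOMIC" if exonic else "GENIC_INTRON"


def brute_spearman(x, y) -> float:
    """Rank (average ties) then Pearson, by hand."""

    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx, my = statistics.mean(rx), statistics.mean(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def brute_im(matrix_values) -> float:
    """IM by explicit loops: matrix_values is the (group, replicate)
    MultiIndex DataFrame of an AbundanceMatrix."""
    groups = matrix_values.columns.get_level_values(0).unique()
    terms = []
    for tid in matrix_values.index:
        for g in groups:
            logs = [math.log(v + 1.0) for v in matrix_values.loc[tid, g]]
            u = statistics.mean(logs)
            if u == 0:
                continue
            s = statistics.stdev(logs)
            terms.append((s / u) ** 2)
    return statistics.mean(terms) if terms else float("nan")


def brute_nrmse(truth, est) -> float:
    diffs = [(t - e) ** 2 for t, e in zip(truth, est)]
    rmse = math.sqrt(statistics.mean(diffs))
    return rmse / statistics.stdev(truth)


def brute_detection_counts(classified, truth_ids):
    """Loop over truth x submission pairs, assigning each truth its best
    single status (RM > FSM/ISM)."""
    best = {}
    for tid in truth_ids:
        for c in classified:
            if c.ref_transcript_id != tid:
                continue
            if c.category.value == "FSM" and c.is_RM:
                best[tid] = "RM"
            elif c.category.value in ("FSM", "ISM") and best.get(tid) != "RM":
                best[tid] = "PARTIAL"
    tp = sum(1 for v in best.values() if v == "RM")
    ptp = sum(1 for v in best.values() if v == "PARTIAL")
    fn = len(truth_ids) - tp - ptp
    fp = sum(
        1 for c in classified
        if c.category.value in ("NIC", "NNC", "ANTISENSE", "FUSION")
    )
    return tp, ptp, fn, fp
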