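"""Detection performance and cross-pipeline agreement.

Detection metrics score a classified submission against a truth set of
transcript models (spike-in SIRV-style, simulated with a known/novel
split, or a curated subset of the annotation):

* a truth transcript with at least one Reference-Match model is a TP;
* one detected only at ISM/non-RM-FSM level is a partial TP (PTP);
* one with neither FSM nor ISM is an FN;
* submitted NIC/NNC/antisense/fusion models are FPs.

Each truth transcript is assigned its single best status (RM beats
FSM/ISM), so TP + PTP + FN = n_truth and the positive detection rate is
provably ≤ 1. Ratios with an empty denominator are reported as NaN,
never 0.

Cross-pipeline agreement compares submissions at the level of unique
junction chains (UJCs): a barcode per distinct chain records which
pipelines detected it, and pairwise overlap matrices give the fraction
of one submission's features recovered by another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import (
    Category,
    ClassifiedTranscript,
    NOVEL_CATEGORIES,
    ujc_key,
)
from .models import AbundanceMatrix, Annotation, SupportTrack, ValidationError


@dataclass
class TruthSet:
    """Ground-truth transcript models for detection evaluation.

    ``mode`` is one of {"sirv", "simulated", "curated"}. In simulated
    mode the truth ids are partitioned into known (annotation-derived)
    and novel transcripts; the annotation is expected to contain only
    transcripts for which reads were actually simulated, so the known
    set doubles as the sensitivity denominator.
    """

    mode: str
    transcripts: Annotation
    known_ids: frozenset[str] = frozenset()
    novel_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.mode not in ("sirv", "simulated", "curated"):
            raise ValidationError(f"unknown truth mode {self.mode!r}")
        if self.known_ids & self.novel_ids:
            raise ValidationError("known and novel truth ids must be disjoint")
        if self.mode == "simulated":
            ids = set(self.transcripts.transcript_ids)
            if (self.known_ids | self.novel_ids) - ids:
                raise ValidationError("known/novel ids not present in truth annotation")

    @property
    def n_truth(self) -> int:
        return len(self.transcripts)


def _nan_div(num: float, den: float) -> float:
    return num / den if den else float("nan")


@dataclass
class PerformanceReport:
    """Detection counts and derived rates for one submission."""

    mode: str
    n_truth: int
    n_submitted: int
    TP: int
    PTP: int
    FN: int
    FP: int
    n_rm_models: int
    n_fsm_models: int
    n_ism_models: int
    sensitivity: float
    precision: float
    nr_precision: float
    positive_detection_rate: float
    false_discovery_rate: float
    false_detection_rate: float
    redundancy: float
    sens_ref: Optional[float] = None
    sens_novel: Optional[float] = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if v is not None}
        return d


def evaluate_detection(
    classified: Sequence[ClassifiedTranscript], truth: TruthSet
) -> PerformanceReport:
    """Score a classified submission against a truth set.

    The submission must have been classified with ``truth.transcripts``
    as the reference. Spike-in and curated modes use submission-size
    denominators for precision-type rates; simulated mode uses the
    detection-call denominator TP + PTP + FP and splits sensitivity into
    known (sens_ref) and novel (sens_novel) components.
    """
    n_truth = truth.n_truth
    if n_truth == 0:
        raise ValidationError("empty truth set")
    n_sub = len(classified)

    truth_status: dict[str, str] = {}  # truth id -> "RM" | "PARTIAL"
    for c in classified:
        if c.category is Category.FSM and c.is_RM:
            truth_status[c.ref_transcript_id] = "RM"
        elif c.category in (Category.FSM, Category.ISM):
            truth_status.setdefault(c.ref_transcript_id, "PARTIAL")

    tp_ids = {t for t, s in truth_status.items() if s == "RM"}
    ptp_ids = {t for t, s in truth_status.items() if s == "PARTIAL"}
    TP, PTP = len(tp_ids), len(ptp_ids)
    FN = n_truth - TP - PTP
    FP = sum(1 for c in classified if c.category in NOVEL_CATEGORIES)
    n_rm = sum(1 for c in classified if c.is_RM)
    n_fsm = sum(1 for c in classified if c.category is Category.FSM)
    n_ism = sum(1 for c in classified if c.category is Category.ISM)
    detected = TP + PTP  # distinct truth transcripts detected at any level

    sens_ref = sens_novel = None
    if truth.mode == "simulated":
        tp_ref = len(tp_ids & truth.known_ids)
        tp_nov = len(tp_ids & truth.novel_ids)
        sens_ref = _nan_div(tp_ref, len(truth.known_ids))
        sens_novel = _nan_div(tp_nov, len(truth.novel_ids))
        calls = TP + PTP + FP
        precision = _nan_div(TP, calls)
        fdr = _nan_div(FP + PTP, calls)
        false_detection = _nan_div(FP, calls)
    else:
        precision = _nan_div(n_rm, n_sub)
        fdr = _nan_div(n_sub - n_rm, n_sub)
        false_detection = _nan_div(FP, n_sub)

    return PerformanceReport(
        mode=truth.mode,
        n_truth=n_truth,
        n_submitted=n_sub,
        TP=TP,
        PTP=PTP,
        FN=FN,
        FP=FP,
        n_rm_models=n_rm,
        n_fsm_models=n_fsm,
        n_ism_models=n_ism,
        sensitivity=_nan_div(TP, n_truth),
        precision=precision,
        nr_precision=_nan_div(TP, n_sub),
        positive_detection_rate=_nan_div(detected, n_truth),
        false_discovery_rate=fdr,
        false_detection_rate=false_detection,
        redundancy=_nan_div(n_fsm + n_ism, detected),
        sens_ref=sens_ref,
        sens_novel=sens_novel,
    )


# ---------------------------------------------------------------------------
# End and junction support
# ---------------------------------------------------------------------------

def _peak_supported(track: SupportTrack, chrom: str, pos: int, window: int) -> bool:
    df = track.records
    hit = df[
        (df["chrom"] == chrom)
        & (df["start"] - window <= pos)
        & (pos < df["end"] + window)
    ]
    return len(hit) > 0


def end_support(
    classified: Sequence[ClassifiedTranscript],
    reference: Annotation,
    five_prime: Optional[SupportTrack] = None,
    three_prime: Optional[SupportTrack] = None,
    junctions: Optional[SupportTrack] = None,
    window: int = 50,
    min_junction_count: int = 1,
) -> pd.DataFrame:
    """Per-transcript 5'/3' support flags and SRTM/SNTM calls.

    An end is *reference-supported* when it lies within ``window`` nt of
    any same-gene reference TSS (5') or TTS (3'), and *peak-supported*
    when it falls inside an orthogonal-evidence peak extended by the
    window. A supported reference transcript model (SRTM) is an FSM/ISM
    with both ends supported by either source; a supported novel
    transcript model (SNTM) is an NIC/NNC with both ends supported and
    every novel junction covered by the short-read junction track.

    Missing tracks leave their flags as NA (pandas missing); SRTM/SNTM
    are computed from the evidence that is available.
    """
    ref_index: dict[str, tuple[set[int], set[int]]] = {}
    for gid in reference.gene_ids:
        ref_index[gid] = reference.gene_tss_tts(gid)
    all_tss: dict[str, set[int]] = {}
    all_tts: dict[str, set[int]] = {}
    for t in reference:
        all_tss.setdefault((t.chrom, t.strand), set()).add(t.tss)
        all_tts.setdefault((t.chrom, t.strand), set()).add(t.tts)

    jc = junctions.junction_counts() if junctions is not None else None

    rows = []
    for c in classified:
        m = c.model
        tss_set = all_tss.get((m.chrom, m.strand), set())
        tts_set = all_tts.get((m.chrom, m.strand), set())
        ref5 = any(abs(m.tss - p) <= window for p in tss_set)
        ref3 = any(abs(m.tts - p) <= window for p in tts_set)
        peak5 = (
            _peak_supported(five_prime, m.chrom, m.tss, window)
            if five_prime is not None
            else pd.NA
        )
        peak3 = (
            _peak_supported(three_prime, m.chrom, m.tts, window)
            if three_prime is not None
            else pd.NA
        )
        sup5 = ref5 or (peak5 is True)
        sup3 = ref3 or (peak3 is True)

        srtm = c.category in (Category.FSM, Category.ISM) and sup5 and sup3
        sntm = False
        if c.category in (Category.NIC, Category.NNC) and sup5 and sup3:
            if jc is None:
                sntm = pd.NA  # junction clause unverifiable
            else:
                from .classify import extract_intron_chain

                chain = extract_intron_chain(m)
                ref_junctions = {
                    (s, e)
                    for t in reference
                    if t.chrom == m.chrom and t.strand == m.strand
                    for s, e in zip(
                        (x[1] for x in t.exons[:-1]), (x[0] for x in t.exons[1:])
                    )
                }
                novel = [j for j in chain.introns if j not in ref_junctions]
                sntm = all(
                    jc.get((m.chrom, m.strand, s, e), 0) >= min_junction_count
                    for s, e in novel
                )
        rows.append(
            {
                "transcript_id": m.transcript_id,
                "category": c.category.value,
                "ref_supported_5": ref5,
                "ref_supported_3": ref3,
                "peak_supported_5": peak5,
                "peak_supported_3": peak3,
                "supported_5": sup5,
                "supported_3": sup3,
                "SRTM": srtm,
                "SNTM": sntm,
            }
        )
    return pd.DataFrame(rows)


def junction_support(
    classified: Sequence[ClassifiedTranscript],
    junctions: SupportTrack,
    min_count: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Short-read support of each model's splice junctions.

    Returns a per-model table (fraction of junctions supported at
    ``min_count`` reads, full-support flag) and a per-category summary
    (mean % supported, % of models with all junctions supported).
    Mono-exon models have no junctions and are excluded.
    """
    from .classify import extract_intron_chain

    jc = junctions.junction_counts()
    rows = []
    for c in classified:
        m = c.model
        chain = extract_intron_chain(m).introns
        if not chain:
            continue
        n_sup = sum(
            1 for s, e in chain if jc.get((m.chrom, m.strand, s, e), 0) >= min_count
        )
        rows.append(
            {
                "transcript_id": m.transcript_id,
                "category": c.category.value,
                "n_junctions": len(chain),
                "frac_supported": n_sup / len(chain),
                "fully_supported": n_sup == len(chain),
            }
        )
    per_model = pd.DataFrame(rows)
    if per_model.empty:
        return per_model, pd.DataFrame()
    summary = per_model.groupby("category").agg(
        n_models=("transcript_id", "size"),
        pct_junctions_supported=("frac_supported", lambda s: 100 * s.mean()),
        pct_fully_supported=("fully_supported", lambda s: 100 * s.mean()),
    )
    return per_model, summary.reset_index()


# ---------------------------------------------------------------------------
# Cross-pipeline agreement
# ---------------------------------------------------------------------------

@dataclass
class UJCBarcode:
    """One distinct junction chain and the pipelines that detected it."""

    ujc: str
    category: Category
    flags: dict[str, bool]
    length: int
    exon_count: int

    @property
    def n_pipelines_detecting(self) -> int:
        return sum(self.flags.values())


def build_barcodes(
    submissions: Mapping[str, Sequence[ClassifiedTranscript]],
) -> list[UJCBarcode]:
    """One barcode per distinct UJC across all submissions.

    All submissions must have been classified against the same
    reference; the barcode's category is taken from the first
    classification of the chain encountered (chain-identical models share
    their category up to end effects).
    """
    if not submissions:
        raise ValidationError("empty submission map")
    info: dict[str, tuple[Category, int, int]] = {}
    detected: dict[str, dict[str, bool]] = {}
    pipelines = list(submissions)
    for pipe, classified in submissions.items():
        for c in classified:
            key = ujc_key(c.model)
            if key not in info:
                info[key] = (c.category, c.model.length, c.model.exon_count)
                detected[key] = {p: False for p in pipelines}
            detected[key][pipe] = True
    return [
        UJCBarcode(
            ujc=key,
            category=info[key][0],
            flags=detected[key],
            length=info[key][1],
            exon_count=info[key][2],
        )
        for key in info
    ]


def _feature_set(
    classified: Sequence[ClassifiedTranscript],
    feature: str,
    abundance: Optional[pd.Series] = None,
) -> set:
    from .classify import extract_intron_chain

    if feature == "gene":
        return {
            c.ref_gene_id if c.ref_gene_id is not None else c.model.gene_id
            for c in classified
        }
    if feature == "junction":
        out = set()
        for c in classified:
            m = c.model
            for j in extract_intron_chain(m).introns:
                out.add((m.chrom, m.strand, *j))
        return out
    if feature == "ujc":
        return {ujc_key(c.model) for c in classified}
    if feature == "dominant_ujc":
        if abundance is None:
            raise ValueError("dominant_ujc requires per-transcript abundance")
        gene_expr: dict[str, float] = {}
        chain_expr: dict[tuple[str, str], float] = {}
        for c in classified:
            g = c.ref_gene_id if c.ref_gene_id is not None else c.model.gene_id
            a = float(abundance.get(c.model.transcript_id, 0.0))
            gene_expr[g] = gene_expr.get(g, 0.0) + a
            k = (g, ujc_key(c.model))
            chain_expr[k] = chain_expr.get(k, 0.0) + a
        return {
            key
            for (g, key), a in chain_expr.items()
            if gene_expr[g] > 0 and a / gene_expr[g] > 0.5
        }
    raise ValueError(f"unknown feature {feature!r}")


def pairwise_overlap(
    submissions: Mapping[str, Sequence[ClassifiedTranscript]],
    feature: str = "ujc",
    abundances: Optional[Mapping[str, pd.Series]] = None,
) -> pd.DataFrame:
    """Pairwise relative overlap of detected features between pipelines.

    ``M[row, col] = |F_row ∩ F_col| / |F_row|`` — the fraction of the row
    pipeline's features also reported by the column pipeline. Diagonal is
    1 by construction; an empty row set yields a NaN row. The
    ``dominant_ujc`` feature restricts each submission to chains carrying
    more than half of their gene's expression and requires per-pipeline
    abundance series.
    """
    if len(submissions) < 2:
        raise ValidationError("pairwise_overlap needs at least 2 submissions")
    sets = {
        p: _feature_set(
            cl, feature, abundances.get(p) if abundances is not None else None
        )
        for p, cl in submissions.items()
    }
    names = list(submissions)
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            denom = len(sets[a])
            mat.loc[a, b] = (
                len(sets[a] & sets[b]) / denom if denom else float("nan")
            )
    return mat


def frequently_detected(
    barcodes: Sequence[UJCBarcode],
    min_pipelines: int = 3,
    min_datasets: int = 3,
    pipeline_key=lambda name: tuple(name.split("/", 1)),
) -> tuple[list[UJCBarcode], pd.DataFrame]:
    """Frequently-detected transcripts and per-category enrichment.

    A chain qualifies when it was detected in at least ``min_datasets``
    distinct datasets and by at least ``min_pipelines`` distinct analysis
    tools. Pipeline names carry both dimensions; by default they are
    parsed as ``"dataset/tool"``. Enrichment is each category's share in
    the FDT subset divided by its share overall.
    """
    if min_pipelines < 1 or min_datasets < 1:
        raise ValueError("thresholds must be >= 1")
    fdt = []
    for bc in barcodes:
        hits = [p for p, flag in bc.flags.items() if flag]
        datasets = {pipeline_key(p)[0] for p in hits}
        tools = {pipeline_key(p)[-1] for p in hits}
        if len(datasets) >= min_datasets and len(tools) >= min_pipelines:
            fdt.append(bc)

    def shares(items: Sequence[UJCBarcode]) -> pd.Series:
        s = pd.Series([b.category.value for b in items], dtype=str)
        return s.value_counts(normalize=True)

    overall = shares(barcodes)
    subset = shares(fdt) if fdt else pd.Series(dtype=float)
    cats = overall.index
    enrich = pd.DataFrame(
        {
            "share_overall": overall,
            "share_fdt": subset.reindex(cats).fillna(0.0),
        }
    )
    enrich["fold_enrichment"] = enrich["share_fdt"] / enrich["share_overall"]
    return fdt, enrich.reset_index(names="category")
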