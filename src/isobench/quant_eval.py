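"""Transcript-quantification evaluation metrics.

Two families of statistics over transcript-level TPM estimates:

* **truth-based** — Spearman correlation (SCC), median relative
  difference (MRD), normalized root-mean-square error (NRMSE) and the
  percentage of expressed transcripts recovered (PET), comparing an
  estimate vector against a known ground truth;
* **truth-free** — replicate-based statistics: the irreproducibility
  measure IM (mean squared coefficient of variation of log abundance
  across replicates) with its area-under-curve companion ACVC, the
  consistency measure C(α) with its area ACC, and the resolution entropy
  RE of the estimate histogram.

A cell-mixing design (two samples combined at a known fraction w) turns
the truth-based metrics into a real-data evaluation: the expected mixture
abundance is the w-weighted combination of the two individually
quantified samples.

The K-value — the condition number of a gene's binary exon-isoform
matrix — summarizes how hard a gene's isoforms are to deconvolve from
coverage alone.

All log transforms are natural-log ``log(x + 1)`` unless stated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .models import AbundanceMatrix, Annotation, GroundTruth, TranscriptModel

VectorLike = Union[pd.Series, np.ndarray, Sequence[float]]


def _align(truth: GroundTruth, est: VectorLike) -> tuple[np.ndarray, np.ndarray]:
    """Pair truth and estimate values by transcript id.

    An id-indexed Series is matched on ids (transcripts missing from the
    estimate count as 0 TPM); a bare array must already be in truth
    order.
    """
    t = truth.abundance
    if isinstance(est, pd.Series):
        e = est.reindex(t.index).fillna(0.0)
    else:
        e = pd.Series(np.asarray(est, dtype=float), index=t.index)
    return t.to_numpy(dtype=float), e.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Truth-based metrics
# ---------------------------------------------------------------------------

def scc(truth: GroundTruth, est: VectorLike) -> float:
    """Spearman rank correlation between truth and estimate.

    Ties get average ranks. Returns NaN if either vector has zero rank
    variance (fewer than 3 pairs are rejected).
    """
    t, e = _align(truth, est)
    if t.size < 3:
        raise ValueError("SCC requires at least 3 paired transcripts")
    if np.unique(t).size == 1 or np.unique(e).size == 1:
        return float("nan")
    rho, _ = stats.spearmanr(t, e)
    return float(rho)


def mrd(truth: GroundTruth, est: VectorLike) -> float:
    """Median relative difference |θ - θ̂| / θ over expressed transcripts.

    Restricted to transcripts with true abundance θ > 0 (the relative
    difference is undefined at θ = 0).
    """
    t, e = _align(truth, est)
    mask = t > 0
    if not mask.any():
        raise ValueError("MRD requires at least one expressed truth transcript")
    rel = np.abs(t[mask] - e[mask]) / t[mask]
    return float(np.median(rel))


def nrmse(truth: GroundTruth, est: VectorLike) -> float:
    """Root-mean-square error normalized by the truth's sample std.

    ``sqrt(mean((θ - θ̂)^2)) / s(Θ)`` with s(Θ) the I−1-denominator
    standard deviation. NaN when the truth vector is constant.
    """
    t, e = _align(truth, est)
    if t.size < 2:
        raise ValueError("NRMSE requires at least 2 transcripts")
    s = float(np.std(t, ddof=1))
    if s == 0:
        return float("nan")
    rmse = math.sqrt(float(np.mean((t - e) ** 2)))
    return rmse / s


def pet(truth: GroundTruth, est: VectorLike, threshold: float = 0.0) -> float:
    """Percentage of truly expressed transcripts with estimate > threshold."""
    t, e = _align(truth, est)
    expressed = t > 0
    if not expressed.any():
        raise ValueError("PET requires at least one expressed truth transcript")
    return 100.0 * float(np.sum(expressed & (e > threshold))) / float(np.sum(expressed))


# ---------------------------------------------------------------------------
# Replicate-based (truth-free) metrics
# ---------------------------------------------------------------------------

@dataclass
class CVProfile:
    """Per (transcript, group) coefficient of variation of log1p TPM.

    Entries with zero mean log abundance (all-zero replicates) are
    excluded: CV is undefined at zero mean.
    """

    u: pd.DataFrame          # mean of log(TPM+1) per (transcript, group)
    s: pd.DataFrame          # sample std (ddof=1) of the same
    cv: pd.DataFrame         # s / u where included, NaN elsewhere
    included: pd.DataFrame   # boolean mask


def cv_profile(matrix: AbundanceMatrix) -> CVProfile:
    """Compute the log1p coefficient-of-variation profile of a matrix.

    Requires at least two replicates per group.
    """
    if matrix.n_replicates < 2:
        raise ValueError("cv_profile requires >= 2 replicates per group")
    logv = np.log1p(matrix.values)
    u = logv.T.groupby(level="group").mean().T
    s = logv.T.groupby(level="group").std(ddof=1).T
    included = u > 0
    cv = (s / u).where(included)
    return CVProfile(u=u, s=s, cv=cv, included=included)


def im(profile: CVProfile) -> float:
    """Irreproducibility measure: mean of CV² over included entries."""
    cv2 = (profile.cv ** 2).to_numpy()
    vals = cv2[~np.isnan(cv2)]
    if vals.size == 0:
        return float("nan")
    return float(np.mean(vals))


def acvc(profile: CVProfile, bins: int = 50) -> float:
    """Area under the CV-vs-mean-abundance curve.

    The included (u, CV) pairs are pooled across groups, partitioned into
    equal-count bins of u, summarized by the median CV per bin, and
    integrated by the trapezoid rule over the observed u range. With all
    CVs zero the area is 0.
    """
    mask = profile.included.to_numpy()
    u = profile.u.to_numpy()[mask]
    cv = profile.cv.to_numpy()[mask]
    if u.size == 0:
        return float("nan")
    order = np.argsort(u)
    u, cv = u[order], cv[order]
    nbins = min(bins, u.size)
    edges = np.array_split(np.arange(u.size), nbins)
    xs = np.array([np.mean(u[idx]) for idx in edges if idx.size])
    ys = np.array([np.median(cv[idx]) for idx in edges if idx.size])
    if xs.size < 2:
        return 0.0
    return float(np.trapezoid(ys, xs))


@dataclass
class ConsistencyCurve:
    """C(α) over a grid of expression thresholds α (on log1p TPM).

    CM is the scalar C(α₀); ACC is the trapezoidal area under the curve
    over the grid span.
    """

    alphas: np.ndarray
    values: np.ndarray
    alpha0: float
    cm: float
    acc: float


def consistency_curve(
    matrix: AbundanceMatrix,
    alphas: Optional[Sequence[float]] = None,
    alpha0: float = math.log(2.0),
) -> ConsistencyCurve:
    """Fraction of replicate pairs agreeing on expressed-vs-not at α.

    For every transcript i, group g and replicate pair r1 < r2, the pair
    agrees at threshold α when both log1p values are below α or both are
    at/above it. C(0) = 1 (log1p ≥ 0 everywhere) and C(α) = 1 for α above
    the data maximum.

    The default grid runs from 0 to just past the maximum log1p value in
    steps of 0.1; the default α₀ = ln 2 corresponds to a 1-TPM
    expression threshold.
    """
    if matrix.n_replicates < 2:
        raise ValueError("consistency_curve requires >= 2 replicates per group")
    logv = np.log1p(matrix.values)
    if alphas is None:
        top = float(logv.to_numpy().max()) + 0.1
        alphas = np.arange(0.0, top + 0.1, 0.1)
    alphas = np.asarray(list(alphas), dtype=float)
    if alphas.size == 0 or np.any(np.diff(alphas) <= 0):
        raise ValueError("alphas must be a non-empty ascending grid")

    values = np.empty(alphas.size)
    blocks = [logv[g].to_numpy() for g in matrix.groups]  # each I x R
    R = matrix.n_replicates
    pairs = [(r1, r2) for r1 in range(R) for r2 in range(r1 + 1, R)]
    for k, a in enumerate(alphas):
        agree = total = 0
        for block in blocks:
            below = block < a
            for r1, r2 in pairs:
                agree += int(np.sum(below[:, r1] == below[:, r2]))
                total += block.shape[0]
        values[k] = agree / total
    cm = float(np.interp(alpha0, alphas, values))
    acc = float(np.trapezoid(values, alphas))
    return ConsistencyCurve(alphas=alphas, values=values, alpha0=alpha0, cm=cm, acc=acc)


def resolution_entropy(est: VectorLike, M: int = 100) -> float:
    """Entropy (nats) of the abundance histogram at bin width max/M.

    Estimates are binned into M equal-width bins over [0, max]; the
    entropy −Σ P_m ln P_m runs over occupied bins. A constant vector
    (including all-zero) gives exactly 0; values spread one-per-bin give
    ln M.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    x = np.asarray(est, dtype=float) if not isinstance(est, pd.Series) else est.to_numpy(dtype=float)
    if x.size == 0:
        return float("nan")
    top = float(x.max())
    if top <= 0:
        return 0.0
    width = top / M
    idx = np.minimum((x / width).astype(int), M - 1)
    counts = np.bincount(idx, minlength=M).astype(float)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p))) + 0.0


def resolution_entropy_matrix(matrix: AbundanceMatrix, M: int = 100) -> float:
    """Mean per-replicate resolution entropy of an abundance matrix."""
    vals = [
        resolution_entropy(matrix.values[col].to_numpy(), M=M)
        for col in matrix.values.columns
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Cell-mixing design
# ---------------------------------------------------------------------------

def mixing_expected(a: pd.Series, b: pd.Series, w: float) -> pd.Series:
    """Expected mixture abundance w·a + (1−w)·b on a common TPM scale.

    TPM is compositional, so the two inputs are first rescaled to the
    mean of their totals (a no-op when they already share a total) before
    weighting; the result then sums to that common total.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("mixing weight w must be in [0, 1]")
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("mixing inputs must share transcript ids")
        b = b.reindex(a.index)
    ta, tb = float(a.sum()), float(b.sum())
    if ta <= 0 or tb <= 0:
        raise ValueError("mixing inputs must have positive totals")
    target = (ta + tb) / 2.0
    return w * a * (target / ta) + (1.0 - w) * b * (target / tb)


def evaluate_mixing(mix_est: pd.Series, expected: pd.Series) -> dict[str, float]:
    """Score a mixture quantification against its expected abundance.

    The expected vector plays the role of ground truth for SCC, MRD and
    NRMSE.
    """
    truth = GroundTruth(expected)
    return {
        "SCC": scc(truth, mix_est),
        "MRD": mrd(truth, mix_est),
        "NRMSE": nrmse(truth, mix_est),
    }


def recover_mixing_weight(mix_est: pd.Series, a: pd.Series, b: pd.Series) -> float:
    """Least-squares estimate of the mixing fraction w from a mixture.

    Solves min_w ||mix − (w·a' + (1−w)·b')||² over the common-scale
    inputs; the closed form is the projection of (mix − b') onto
    (a' − b').
    """
    a2 = mixing_expected(a, b, 1.0)
    b2 = mixing_expected(a, b, 0.0)
    m = mix_est.reindex(a2.index).fillna(0.0).to_numpy(dtype=float)
    d = (a2 - b2).to_numpy(dtype=float)
    denom = float(np.dot(d, d))
    if denom == 0:
        raise ValueError("samples are identical; mixing weight unidentifiable")
    return float(np.dot(m - b2.to_numpy(dtype=float), d) / denom)


# ---------------------------------------------------------------------------
# K-value
# ---------------------------------------------------------------------------

@dataclass
class ExonIsoformMatrix:
    """Binary isoform x exonic-segment matrix of one gene.

    Columns are the disjoint exonic segments obtained by cutting the
    union of the gene's exons at every exon boundary; a_ie = 1 iff
    isoform i covers segment e.
    """

    gene_id: str
    isoform_ids: list[str]
    segments: list[tuple[int, int]]
    A: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape


def exon_isoform_matrix(gene: Sequence[TranscriptModel]) -> ExonIsoformMatrix:
    """Build a gene's binary exon-isoform matrix.

    Overlapping exons across isoforms are resolved into disjoint segments
    at all boundaries, so 'exon e' is well defined even when isoforms
    share only part of an exon.
    """
    if not gene:
        raise ValueError("need at least one isoform")
    gene_id = gene[0].gene_id
    boundaries = sorted({c for t in gene for s, e in t.exons for c in (s, e)})
    candidate = [
        (boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)
    ]
    # keep segments covered by at least one isoform
    def covers(t: TranscriptModel, seg: tuple[int, int]) -> bool:
        return any(s <= seg[0] and seg[1] <= e for s, e in t.exons)

    segments = [seg for seg in candidate if any(covers(t, seg) for t in gene)]
    A = np.array(
        [[1 if covers(t, seg) else 0 for seg in segments] for t in gene],
        dtype=float,
    )
    return ExonIsoformMatrix(
        gene_id=gene_id,
        isoform_ids=[t.transcript_id for t in gene],
        segments=segments,
        A=A,
    )


def k_value(matrix: ExonIsoformMatrix, rank_tol: float = 1e-10) -> float:
    """Condition number σ_max/σ_min of the exon-isoform matrix.

    Rank-deficient matrices (σ_min below ``rank_tol``·σ_max, e.g. a
    duplicated isoform) return +inf: such genes cannot be deconvolved
    from coverage at all.
    """
    sv = np.linalg.svd(matrix.A, compute_uv=False)
    smax, smin = float(sv[0]), float(sv[-1])
    if matrix.A.shape[0] > matrix.A.shape[1]:
        smin = 0.0  # more isoforms than segments: necessarily rank deficient
    if smin <= rank_tol * smax:
        return float("inf")
    return smax / smin


def k_values(annotation: Annotation) -> pd.Series:
    """K-value per gene of an annotation."""
    out = {}
    for gid, transcripts in annotation.genes():
        out[gid] = k_value(exon_isoform_matrix(transcripts))
    return pd.Series(out, name="k_value")


# ---------------------------------------------------------------------------
# Feature-stratified evaluation
# ---------------------------------------------------------------------------

@dataclass
class StrataConfig:
    """Bin edges for the feature-stratified evaluation."""

    abundance_edges: tuple = (0.0, 1.0, 5.0, 20.0, 100.0, float("inf"))
    isoform_count_edges: tuple = (0, 1, 3, 5, 10, float("inf"))
    exon_count_edges: tuple = (0, 1, 3, 5, 10, 15, float("inf"))
    length_edges: tuple = (0, 500, 1000, 2000, 5000, float("inf"))
    k_value_edges: tuple = (0.0, 1.5, 2.5, 5.0, float("inf"))
    min_n: int = 3


def transcript_features(
    truth: GroundTruth, annotation: Annotation
) -> pd.DataFrame:
    """Per-transcript features used for stratified evaluation.

    Columns: abundance (true TPM), isoform_count (of the parent gene),
    exon_count, length (spliced nt), k_value (of the parent gene).
    Transcripts absent from the annotation are dropped.
    """
    kv = k_values(annotation)
    rows = {}
    for t in annotation:
        if t.transcript_id not in truth.abundance.index:
            continue
        n_iso = len(annotation.gene_transcripts(t.gene_id))
        rows[t.transcript_id] = {
            "abundance": float(truth.abundance[t.transcript_id]),
            "isoform_count": n_iso,
            "exon_count": t.exon_count,
            "length": t.length,
            "k_value": float(kv[t.gene_id]),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def stratified_report(
    truth: GroundTruth,
    est: pd.Series,
    annotation: Annotation,
    config: StrataConfig = StrataConfig(),
) -> pd.DataFrame:
    """Per-stratum MRD for each transcript feature, min-max normalized.

    For every feature the evaluated transcripts are binned by the
    configured edges; the MRD is computed per stratum and normalized to
    [0, 1] across that feature's strata (a single stratum normalizes to
    0). Strata smaller than ``min_n`` report NaN with a note.
    """
    feats = transcript_features(truth, annotation)
    edge_map = {
        "abundance": config.abundance_edges,
        "isoform_count": config.isoform_count_edges,
        "exon_count": config.exon_count_edges,
        "length": config.length_edges,
        "k_value": config.k_value_edges,
    }
    rows = []
    for feature, edges in edge_map.items():
        binned = pd.cut(feats[feature], bins=list(edges), include_lowest=True)
        raw = {}
        for stratum, idx in feats.groupby(binned, observed=True).groups.items():
            ids = [i for i in idx if truth.abundance[i] > 0]
            if len(ids) < config.min_n:
                raw[stratum] = (float("nan"), len(ids), "below min_n")
                continue
            sub_truth = GroundTruth(truth.abundance.loc[ids])
            raw[stratum] = (mrd(sub_truth, est), len(ids), "")
        vals = np.array([v[0] for v in raw.values()], dtype=float)
        finite = vals[~np.isnan(vals)]
        lo = float(finite.min()) if finite.size else float("nan")
        hi = float(finite.max()) if finite.size else float("nan")
        for stratum, (v, n, note) in raw.items():
            if np.isnan(v):
                norm = float("nan")
            elif hi == lo:
                norm = 0.0
            else:
                norm = (v - lo) / (hi - lo)
            rows.append(
                {
                    "feature": feature,
                    "stratum": str(stratum),
                    "n": n,
                    "mrd": v,
                    "normalized_mrd": norm,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)
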