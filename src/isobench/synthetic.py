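"""Synthetic fixtures with known ground truth.

Generates (i) multi-isoform gene annotations with shared and variant
junctions, (ii) submissions containing a controlled mix of structural
categories planted by construction (exact FSM copies with end jitter,
5'-truncated ISMs, exon-skipping NICs, splice-site-shifted NNCs,
antisense and intergenic models), (iii) replicate TPM matrices with
multiplicative log-normal noise around a log-normal ground truth, and
(iv) two-sample mixtures at a known fraction.

Everything is deterministic given ``SimConfig.seed``: every operation
draws from ``numpy.random.default_rng`` seeded by (seed, salt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .models import AbundanceMatrix, Annotation, GroundTruth, TranscriptModel
from .quant_eval import mixing_expected

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Structural perturbation rates are per reference transcript and
    mutually exclusive (sampled in the order drop, truncate, exon-skip,
    site-shift; the remainder are emitted as jittered FSM copies).
    ``end_jitter`` (nt, default 25) keeps planted FSMs inside the 50-nt
    Reference-Match window; ``site_shift_nt`` (default +6) creates a
    novel donor clear of annotated sites and of the end window.
    """

    seed: int = 0
    # annotation geometry
    n_genes: int = 20
    isoforms_per_gene: int = 3
    exons_per_transcript: tuple[int, int] = (5, 9)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (300, 2000)
    gene_gap: tuple[int, int] = (6000, 12000)
    chrom: str = "chrS"
    variant_acceptor_shift: int = 12
    # submission perturbations
    p_drop: float = 0.0
    p_truncate: float = 0.0
    p_exon_skip: float = 0.0
    p_site_shift: float = 0.0
    end_jitter: int = 25
    site_shift_nt: int = 6
    n_antisense: int = 0
    n_intergenic: int = 0
    # abundance model
    lognormal_mu: float = 3.0
    lognormal_sigma: float = 1.5
    replicate_sigma: float = 0.1
    n_replicates: int = 3
    groups: tuple[str, ...] = ("sample",)
    # mixing
    mixing_weight: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_drop", "p_truncate", "p_exon_skip", "p_site_shift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_truncate + self.p_exon_skip + self.p_site_shift > 1.0:
            raise ValueError("perturbation rates must sum to <= 1")
        if self.exons_per_transcript[0] < 4:
            raise ValueError(
                "need >= 4 exons per transcript so truncation and exon "
                "skipping are always feasible"
            )
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError("mixing_weight must be in [0, 1]")


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, salt])


def simulate_annotation(config: SimConfig) -> Annotation:
    """Generate non-overlapping multi-isoform genes on one chromosome.

    Each gene has a base isoform using every exon of its skeleton;
    additional isoforms use an alternative acceptor (internal exon start
    shifted by ``variant_acceptor_shift``), so isoforms have distinct
    intron chains while sharing most junctions.
    """
    rng = _rng(config, 1)
    lo_e, hi_e = config.exons_per_transcript
    transcripts = []
    pos = 10_000
    for g in range(config.n_genes):
        gid = f"G{g:04d}"
        strand = "+" if g % 2 == 0 else "-"
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        lengths = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_exons)
        gaps = rng.integers(config.intron_length[0], config.intron_length[1] + 1, n_exons - 1)
        exons = []
        cur = pos
        for i, L in enumerate(lengths):
            exons.append((cur, cur + int(L)))
            if i < n_exons - 1:
                cur = cur + int(L) + int(gaps[i])
        base = tuple(exons)
        if config.variant_acceptor_shift >= config.exon_length[0]:
            raise ValueError("variant_acceptor_shift must be smaller than min exon length")
        for k in range(config.isoforms_per_gene):
            tid = f"{gid}.T{k}"
            if k == 0:
                ex = base
            else:
                # shift the start (acceptor) of one internal exon
                idx = 1 + (k - 1) % (n_exons - 2)
                shift = config.variant_acceptor_shift * k
                if shift >= base[idx][1] - base[idx][0]:
                    shift = config.variant_acceptor_shift
                ex = tuple(
                    (s + shift, e) if i == idx else (s, e)
                    for i, (s, e) in enumerate(base)
                )
            transcripts.append(
                TranscriptModel(tid, gid, config.chrom, strand, ex)
            )
        gene_span = base[-1][1] - base[0][0]
        pos += gene_span + int(rng.integers(config.gene_gap[0], config.gene_gap[1] + 1))
    return Annotation(transcripts)


def _jitter_ends(exons, jitter5: int, jitter3: int):
    ex = list(exons)
    s0, e0 = ex[0]
    ex[0] = (s0 + jitter5, e0)
    s1, e1 = ex[-1]
    ex[-1] = (s1, e1 + jitter3)
    return tuple(ex)


def perturb_submission(
    annotation: Annotation, config: SimConfig
) -> tuple[Annotation, pd.Series]:
    """Build a submission with planted structural categories.

    Returns the submission annotation and a Series mapping each emitted
    model id to its intended category label (FSM / ISM / NIC / NNC /
    ANTISENSE / INTERGENIC). Genes too simple for a drawn perturbation
    fall back to an FSM copy with a logged note (the default geometry
    makes this unreachable).
    """
    rng = _rng(config, 2)
    models: list[TranscriptModel] = []
    labels: dict[str, str] = {}
    n = 0

    for t in annotation:
        u = rng.random()
        if u < config.p_drop:
            continue
        v = rng.random()
        n += 1
        sid = f"S{n:05d}"
        exons = t.exons
        if v < config.p_truncate and len(exons) >= 3:
            # drop the first junction (5' truncation) -> ISM
            new = exons[1:]
            models.append(TranscriptModel(f"{sid}_ISM", t.gene_id, t.chrom, t.strand, new))
            labels[f"{sid}_ISM"] = "ISM"
        elif v < config.p_truncate + config.p_exon_skip and len(exons) >= 4:
            # skip an internal exon, reconnecting annotated donor/acceptor -> NIC
            idx = len(exons) // 2
            new = exons[:idx] + exons[idx + 1:]
            models.append(TranscriptModel(f"{sid}_NIC", t.gene_id, t.chrom, t.strand, new))
            labels[f"{sid}_NIC"] = "NIC"
        elif v < config.p_truncate + config.p_exon_skip + config.p_site_shift:
            # extend one internal exon end into the intron -> novel site -> NNC
            j = len(exons) // 2 - 1
            s, e = exons[j]
            new = exons[:j] + ((s, e + config.site_shift_nt),) + exons[j + 1:]
            models.append(TranscriptModel(f"{sid}_NNC", t.gene_id, t.chrom, t.strand, new))
            labels[f"{sid}_NNC"] = "NNC"
        else:
            j5 = int(rng.integers(-config.end_jitter, config.end_jitter + 1))
            j3 = int(rng.integers(-config.end_jitter, config.end_jitter + 1))
            # keep the first/last exon non-degenerate
            j5 = min(j5, exons[0][1] - exons[0][0] - 1)
            j3 = max(j3, -(exons[-1][1] - exons[-1][0] - 1))
            new = _jitter_ends(exons, j5, j3)
            models.append(TranscriptModel(f"{sid}_FSM", t.gene_id, t.chrom, t.strand, new))
            labels[f"{sid}_FSM"] = "FSM"

    # antisense models: opposite strand inside a gene span
    gene_ids = annotation.gene_ids
    for k in range(config.n_antisense):
        gid = gene_ids[k % len(gene_ids)]
        gts = annotation.gene_transcripts(gid)
        gs = min(t.start for t in gts)
        strand = "-" if gts[0].strand == "+" else "+"
        ex = ((gs + 40 + k, gs + 240 + k), (gs + 640 + k, gs + 840 + k))
        tid = f"AS{k:04d}"
        models.append(TranscriptModel(tid, f"novel_{tid}", gts[0].chrom, strand, ex))
        labels[tid] = "ANTISENSE"

    # intergenic models: centred in inter-gene gaps, clear of every span
    spans = sorted(
        (min(t.start for t in ts), max(t.end for t in ts))
        for _, ts in annotation.genes()
    )
    gaps = [
        (spans[i][1], spans[i + 1][0])
        for i in range(len(spans) - 1)
        if spans[i + 1][0] - spans[i][1] > 3000
    ]
    for k in range(config.n_intergenic):
        if not gaps:
            logger.warning("no inter-gene gap wide enough for intergenic model %d", k)
            break
        lo, hi = gaps[k % len(gaps)]
        mid = (lo + hi) // 2
        ex = ((mid - 500 + k, mid - 300 + k), (mid + 100 + k, mid + 300 + k))
        tid = f"IG{k:04d}"
        models.append(TranscriptModel(tid, f"novel_{tid}", config.chrom, "+", ex))
        labels[tid] = "INTERGENIC"

    sub = Annotation(models)
    return sub, pd.Series(labels, name="planted_category")


def simulate_abundances(
    annotation: Annotation, config: SimConfig, salt: int = 3
) -> tuple[GroundTruth, AbundanceMatrix]:
    """Log-normal ground-truth TPM plus noisy replicate estimates.

    True abundances are log-normal draws normalized to 1e6 (TPM).
    Replicate r multiplies each truth value by exp(eps), eps ~
    Normal(0, replicate_sigma^2), then renormalizes its column back to
    1e6, emulating abundance estimation noise on a compositional scale.
    """
    rng = _rng(config, salt)
    ids = annotation.transcript_ids
    raw = rng.lognormal(mean=config.lognormal_mu, sigma=config.lognormal_sigma, size=len(ids))
    tpm = raw / raw.sum() * 1e6
    truth = GroundTruth(pd.Series(tpm, index=ids))

    cols = []
    data = []
    for g in config.groups:
        for r in range(1, config.n_replicates + 1):
            eps = rng.normal(0.0, config.replicate_sigma, size=len(ids))
            col = tpm * np.exp(eps)
            col = col / col.sum() * 1e6
            cols.append((g, f"rep{r}"))
            data.append(col)
    mat = pd.DataFrame(
        np.column_stack(data),
        index=ids,
        columns=pd.MultiIndex.from_tuples(cols, names=["group", "replicate"]),
    )
    return truth, AbundanceMatrix(mat)


def simulate_mixing(
    truth_a: GroundTruth,
    truth_b: GroundTruth,
    w: float,
    config: SimConfig,
    salt: int = 4,
) -> tuple[AbundanceMatrix, pd.Series]:
    """Mixture replicates at fraction w plus the expected-abundance vector.

    The mixture ground truth is the common-scale weighted combination of
    the two sample truths; replicates add the same multiplicative noise
    model as :func:`simulate_abundances`.
    """
    if set(truth_a.transcript_ids) != set(truth_b.transcript_ids):
        raise ValueError("mixing inputs must share transcript ids")
    rng = _rng(config, salt)
    expected = mixing_expected(truth_a.abundance, truth_b.abundance, w)
    ids = list(expected.index)
    data, cols = [], []
    for r in range(1, config.n_replicates + 1):
        eps = rng.normal(0.0, config.replicate_sigma, size=len(ids))
        col = expected.to_numpy() * np.exp(eps)
        col = col / col.sum() * float(expected.sum())
        data.append(col)
        cols.append(("mix", f"rep{r}"))
    mat = pd.DataFrame(
        np.column_stack(data),
        index=ids,
        columns=pd.MultiIndex.from_tuples(cols, names=["group", "replicate"]),
    )
    return AbundanceMatrix(mat), expected


@dataclass
class SimTruthBundle:
    """Everything one simulated study produces."""

    config: SimConfig
    annotation: Annotation
    submission: Annotation
    planted_labels: pd.Series
    truth: GroundTruth
    matrix: AbundanceMatrix


def simulate(config: SimConfig) -> SimTruthBundle:
    """Run the full generator: annotation, submission, abundances."""
    ann = simulate_annotation(config)
    sub, labels = perturb_submission(ann, config)
    truth, mat = simulate_abundances(ann, config)
    return SimTruthBundle(
        config=config,
        annotation=ann,
        submission=sub,
        planted_labels=labels,
        truth=truth,
        matrix=mat,
    )
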