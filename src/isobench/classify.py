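"""SQANTI-style structural classification of transcript models.

Every submitted transcript model is assigned exactly one structural
category against a reference annotation:

* **FSM** — intron chain identical to a reference transcript's chain;
* **ISM** — chain is a contiguous *proper* sub-chain of a reference chain
  (a 5'/3' truncation);
* **NIC** — novel combination of annotated junctions, a novel junction
  built from annotated donor/acceptor sites, or unannotated intron
  retention;
* **NNC** — uses at least one unannotated donor or acceptor site;
* **FUSION** — the model spans more than one same-strand reference gene;
* **ANTISENSE** — overlaps a reference gene only on the opposite strand;
* **GENIC_GENOMIC / GENIC_INTRON** — overlaps a gene in a mixture of
  exonic and intronic sequence / lies entirely within a reference intron;
* **INTERGENIC** — no reference gene overlap at all.

An FSM whose 5' and 3' ends both lie within ``window`` (default 50 nt) of
the matched reference transcript's TSS/TTS is additionally flagged as a
Reference Match (RM).

Mono-exon models do not have an intron chain; they are handled by
containment rules (see :func:`classify_transcript`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .models import Annotation, IntronChain, TranscriptModel, ValidationError


class Category(str, enum.Enum):
    FSM = "FSM"
    ISM = "ISM"
    NIC = "NIC"
    NNC = "NNC"
    ANTISENSE = "ANTISENSE"
    FUSION = "FUSION"
    INTERGENIC = "INTERGENIC"
    GENIC_GENOMIC = "GENIC_GENOMIC"
    GENIC_INTRON = "GENIC_INTRON"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Categories whose models count as false positives in detection metrics.
NOVEL_CATEGORIES = (Category.NIC, Category.NNC, Category.ANTISENSE, Category.FUSION)

CATEGORY_ORDER = [c.value for c in Category]


@dataclass(frozen=True)
class ClassifiedTranscript:
    """A transcript model together with its structural classification."""

    model: TranscriptModel
    category: Category
    ref_transcript_id: Optional[str] = None
    ref_gene_id: Optional[str] = None
    dist_tss: Optional[int] = None
    dist_tts: Optional[int] = None
    is_RM: bool = False
    novel_junction_count: int = 0
    has_intron_retention: bool = False

    def __post_init__(self) -> None:
        in_catalog = self.category in (Category.FSM, Category.ISM)
        if (self.ref_transcript_id is not None) != in_catalog:
            raise ValidationError(
                "ref_transcript_id must be present iff category is FSM/ISM"
            )
        if self.is_RM and self.category is not Category.FSM:
            raise ValidationError("only FSM transcripts can be Reference Matches")


def extract_intron_chain(model: TranscriptModel) -> IntronChain:
    """The ordered introns of a model: gaps between consecutive exons.

    Mono-exon models yield an empty chain.
    """
    introns = tuple(
        (model.exons[i][1], model.exons[i + 1][0]) for i in range(len(model.exons) - 1)
    )
    return IntronChain(chrom=model.chrom, strand=model.strand, introns=introns)


def _donor_acceptor(strand: str, intron: tuple[int, int]) -> tuple[int, int]:
    """Strand-aware (donor, acceptor) sites of one genomic intron.

    The donor is the 5' intron boundary in transcription direction: the
    genomic start for '+' genes, the genomic end for '-' genes.
    """
    s, e = intron
    return (s, e) if strand == "+" else (e, s)


class _GeneIndex:
    """Per-gene site/junction/exon lookup tables."""

    __slots__ = ("gene_id", "chrom", "strand", "span", "donors", "acceptors",
                 "junctions", "introns", "exon_tree", "transcripts")

    def __init__(self, gene_id: str, transcripts: list[TranscriptModel]):
        self.gene_id = gene_id
        self.chrom = transcripts[0].chrom
        self.strand = transcripts[0].strand
        self.span = (min(t.start for t in transcripts), max(t.end for t in transcripts))
        self.donors: set[int] = set()
        self.acceptors: set[int] = set()
        self.junctions: set[tuple[int, int]] = set()
        self.introns: set[tuple[int, int]] = set()
        self.exon_tree = IntervalTree()
        self.transcripts = transcripts
        for t in transcripts:
            for s, e in t.exons:
                self.exon_tree[s:e] = t.transcript_id
            chain = extract_intron_chain(t)
            for intron in chain.introns:
                self.introns.add(intron)
                self.junctions.add(intron)
                d, a = _donor_acceptor(self.strand, intron)
                self.donors.add(d)
                self.acceptors.add(a)


class RefIndex:
    """Lookup structures over a reference annotation.

    Indexes full intron chains, per-gene junction/donor/acceptor sites,
    genome-wide site sets, and gene spans (strand-aware interval trees).
    """

    def __init__(self, annotation: Annotation):
        self.annotation = annotation
        self.chains: dict[tuple[str, str, tuple], list[str]] = {}
        self.genes: dict[str, _GeneIndex] = {}
        self.global_donors: set[tuple[str, str, int]] = set()
        self.global_acceptors: set[tuple[str, str, int]] = set()
        self.global_junctions: set[tuple[str, str, int, int]] = set()
        # gene span trees: (chrom, strand) -> IntervalTree of gene_ids
        self._gene_trees: dict[tuple[str, str], IntervalTree] = {}

        for gid, transcripts in annotation.genes():
            gidx = _GeneIndex(gid, transcripts)
            self.genes[gid] = gidx
            key = (gidx.chrom, gidx.strand)
            tree = self._gene_trees.setdefault(key, IntervalTree())
            tree[gidx.span[0]: gidx.span[1]] = gid
            for intron in gidx.introns:
                self.global_junctions.add((gidx.chrom, gidx.strand, *intron))
                d, a = _donor_acceptor(gidx.strand, intron)
                self.global_donors.add((gidx.chrom, gidx.strand, d))
                self.global_acceptors.add((gidx.chrom, gidx.strand, a))

        for t in annotation:
            chain = extract_intron_chain(t)
            if chain.introns:
                key = (t.chrom, t.strand, chain.introns)
                self.chains.setdefault(key, []).append(t.transcript_id)

    @property
    def n_junctions(self) -> int:
        return len(self.global_junctions)

    def overlapping_genes(self, chrom: str, strand: str, start: int, end: int) -> list[str]:
        tree = self._gene_trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted(iv.data for iv in tree[start:end])


def build_reference_index(annotation: Annotation) -> RefIndex:
    """Index a reference annotation for classification queries."""
    return RefIndex(annotation)


def _end_distances(model: TranscriptModel, ref: TranscriptModel) -> tuple[int, int]:
    """Signed TSS/TTS distances in transcription direction.

    Positive means the query end lies downstream (inside) of the
    reference end; negative means it extends upstream/beyond.
    """
    if model.strand == "+":
        return model.start - ref.start, model.end - ref.end
    return ref.end - model.end, ref.start - model.start


def _best_match(model: TranscriptModel, candidates: Sequence[TranscriptModel]):
    """Associate to the candidate minimizing |dist_tss| + |dist_tts|,
    breaking ties by lexicographic transcript id."""
    best = min(
        candidates,
        key=lambda r: (
            sum(map(abs, _end_distances(model, r))),
            r.transcript_id,
        ),
    )
    return best, _end_distances(model, best)


def _is_contiguous_proper_subchain(query: tuple, ref: tuple) -> bool:
    nq, nr = len(query), len(ref)
    if nq == 0 or nq >= nr:
        return False
    return any(ref[i: i + nq] == query for i in range(nr - nq + 1))


def classify_transcript(
    model: TranscriptModel,
    index: RefIndex,
    window: int = 50,
    site_scope: str = "gene",
) -> ClassifiedTranscript:
    """Classify one transcript model against the reference index.

    Parameters
    ----------
    model, index
        Must share the same coordinate system (0-based half-open).
    window : int
        End-distance window (nt) for the Reference Match flag.
    site_scope : {"gene", "global"}
        Whether the NIC/NNC donor-acceptor annotation check consults only
        the overlapping gene's sites (default) or the genome-wide site
        sets.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if site_scope not in ("gene", "global"):
        raise ValueError(f"unknown site_scope {site_scope!r}")

    chain = extract_intron_chain(model)

    if chain.introns:
        return _classify_multi_exon(model, chain, index, window, site_scope)
    return _classify_mono_exon(model, index, window)


def _novel_junction_count(model, chain, index, gene_ids) -> int:
    if gene_ids:
        annotated = set()
        for gid in gene_ids:
            annotated |= index.genes[gid].junctions
    else:
        annotated = {
            (s, e)
            for (c, st, s, e) in index.global_junctions
            if c == model.chrom and st == model.strand
        }
    return sum(1 for intron in chain.introns if intron not in annotated)


def _intron_retention(model, index, gene_ids) -> bool:
    """A query exon fully spanning a reference intron of an overlapping
    same-strand gene."""
    for gid in gene_ids:
        for intron in index.genes[gid].introns:
            s, e = intron
            for qs, qe in model.exons:
                if qs < s and qe > e:
                    return True
    return False


def _classify_multi_exon(model, chain, index, window, site_scope):
    # 1) FSM: exact chain match
    key = (model.chrom, model.strand, chain.introns)
    if key in index.chains:
        candidates = [index.annotation[tid] for tid in index.chains[key]]
        ref, (dtss, dtts) = _best_match(model, candidates)
        return ClassifiedTranscript(
            model=model,
            category=Category.FSM,
            ref_transcript_id=ref.transcript_id,
            ref_gene_id=ref.gene_id,
            dist_tss=dtss,
            dist_tts=dtts,
            is_RM=abs(dtss) <= window and abs(dtts) <= window,
        )

    gene_ids = index.overlapping_genes(model.chrom, model.strand, model.start, model.end)

    # 2) ISM: contiguous proper sub-chain of a reference chain
    ism_candidates = []
    seen = set()
    for gid in gene_ids:
        for ref in index.genes[gid].transcripts:
            if ref.transcript_id in seen:
                continue
            seen.add(ref.transcript_id)
            ref_chain = extract_intron_chain(ref).introns
            if _is_contiguous_proper_subchain(chain.introns, ref_chain):
                ism_candidates.append(ref)
    if ism_candidates:
        ref, (dtss, dtts) = _best_match(model, ism_candidates)
        return ClassifiedTranscript(
            model=model,
            category=Category.ISM,
            ref_transcript_id=ref.transcript_id,
            ref_gene_id=ref.gene_id,
            dist_tss=dtss,
            dist_tts=dtts,
        )

    retention = _intron_retention(model, index, gene_ids)
    novel_junctions = _novel_junction_count(model, chain, index, gene_ids)

    if not gene_ids:
        anti = index.overlapping_genes(
            model.chrom, "-" if model.strand == "+" else "+", model.start, model.end
        )
        if anti:
            return ClassifiedTranscript(
                model=model, category=Category.ANTISENSE,
                novel_junction_count=novel_junctions,
            )
        return ClassifiedTranscript(
            model=model, category=Category.INTERGENIC,
            novel_junction_count=novel_junctions,
        )

    # genes with exonic overlap of the query (not just span overlap)
    exonic_genes = [
        gid
        for gid in gene_ids
        if any(index.genes[gid].exon_tree[qs:qe] for qs, qe in model.exons)
        or any(
            qs < s and qe > e
            for s, e in index.genes[gid].introns
            for qs, qe in model.exons
        )
    ]
    if len(exonic_genes) > 1:
        return ClassifiedTranscript(
            model=model,
            category=Category.FUSION,
            novel_junction_count=novel_junctions,
            has_intron_retention=retention,
        )

    gid = exonic_genes[0] if exonic_genes else gene_ids[0]
    gidx = index.genes[gid]

    # entirely intronic within the gene: no exonic overlap at all
    has_exonic_overlap = any(gidx.exon_tree[qs:qe] for qs, qe in model.exons)
    if not has_exonic_overlap and not retention:
        return ClassifiedTranscript(
            model=model, category=Category.GENIC_INTRON,
            novel_junction_count=novel_junctions,
        )

    if site_scope == "gene":
        donors_ok = acceptors_ok = True
        for intron in chain.introns:
            d, a = _donor_acceptor(model.strand, intron)
            donors_ok &= d in gidx.donors
            acceptors_ok &= a in gidx.acceptors
        all_sites_annotated = donors_ok and acceptors_ok
    else:
        all_sites_annotated = all(
            (model.chrom, model.strand, _donor_acceptor(model.strand, i)[0])
            in index.global_donors
            and (model.chrom, model.strand, _donor_acceptor(model.strand, i)[1])
            in index.global_acceptors
            for i in chain.introns
        )

    if all_sites_annotated:
        return ClassifiedTranscript(
            model=model,
            category=Category.NIC,
            novel_junction_count=novel_junctions,
            has_intron_retention=retention,
        )
    return ClassifiedTranscript(
        model=model,
        category=Category.NNC,
        novel_junction_count=novel_junctions,
        has_intron_retention=retention,
    )


def _classify_mono_exon(model, index, window):
    qs, qe = model.exons[0]
    gene_ids = index.overlapping_genes(model.chrom, model.strand, qs, qe)

    if not gene_ids:
        anti = index.overlapping_genes(
            model.chrom, "-" if model.strand == "+" else "+", qs, qe
        )
        cat = Category.ANTISENSE if anti else Category.INTERGENIC
        return ClassifiedTranscript(model=model, category=cat)

    fsm_candidates, ism_candidates = [], []
    any_exonic = False
    for gid in gene_ids:
        gidx = index.genes[gid]
        if gidx.exon_tree[qs:qe]:
            any_exonic = True
        for ref in gidx.transcripts:
            if any(rs <= qs and qe <= re for rs, re in ref.exons):
                if ref.is_mono_exon:
                    fsm_candidates.append(ref)
                else:
                    ism_candidates.append(ref)

    if fsm_candidates:
        ref, (dtss, dtts) = _best_match(model, fsm_candidates)
        return ClassifiedTranscript(
            model=model,
            category=Category.FSM,
            ref_transcript_id=ref.transcript_id,
            ref_gene_id=ref.gene_id,
            dist_tss=dtss,
            dist_tts=dtts,
            is_RM=abs(dtss) <= window and abs(dtts) <= window,
        )
    if ism_candidates:
        ref, (dtss, dtts) = _best_match(model, ism_candidates)
        return ClassifiedTranscript(
            model=model,
            category=Category.ISM,
            ref_transcript_id=ref.transcript_id,
            ref_gene_id=ref.gene_id,
            dist_tss=dtss,
            dist_tts=dtts,
        )
    if any_exonic:
        return ClassifiedTranscript(model=model, category=Category.GENIC_GENOMIC)
    return ClassifiedTranscript(model=model, category=Category.GENIC_INTRON)


def classify_set(
    models: Iterable[TranscriptModel],
    index: RefIndex,
    window: int = 50,
    site_scope: str = "gene",
) -> tuple[list[ClassifiedTranscript], pd.Series]:
    """Classify a submission; return per-model results and category counts.

    The summary is a Series over all categories (zero-filled), in the
    fixed category order, summing to the number of models.
    """
    classified = [
        classify_transcript(m, index, window=window, site_scope=site_scope)
        for m in models
    ]
    counts = pd.Series(0, index=CATEGORY_ORDER, dtype=int)
    for c in classified:
        counts[c.category.value] += 1
    return classified, counts


def ujc_key(model: TranscriptModel, mono_exon_bin: int = 0) -> str:
    """Canonical unique-junction-chain key of a model.

    Multi-exon models map to ``chrom:strand:donor-acceptor:...`` over the
    genomic intron coordinates, so any two models with identical intron
    chains share a key irrespective of their 5'/3' ends. Mono-exon models
    have no junctions; they are keyed by their exon span, optionally
    quantized to ``mono_exon_bin``-nt bins (0 = exact span).
    """
    chain = extract_intron_chain(model)
    if chain.introns:
        parts = ":".join(f"{s}-{e}" for s, e in chain.introns)
        return f"{model.chrom}:{model.strand}:{parts}"
    s, e = model.exons[0]
    if mono_exon_bin > 0:
        s = (s // mono_exon_bin) * mono_exon_bin
        e = (e // mono_exon_bin) * mono_exon_bin
    return f"{model.chrom}:{model.strand}:mono:{s}-{e}"


def classification_table(classified: Sequence[ClassifiedTranscript]) -> pd.DataFrame:
    """Flatten classification results to one row per model."""
    rows = []
    for c in classified:
        rows.append(
            {
                "transcript_id": c.model.transcript_id,
                "gene_id": c.model.gene_id,
                "chrom": c.model.chrom,
                "strand": c.model.strand,
                "exons": c.model.exon_count,
                "length": c.model.length,
                "category": c.category.value,
                "ref_transcript_id": c.ref_transcript_id,
                "ref_gene_id": c.ref_gene_id,
                "dist_tss": c.dist_tss,
                "dist_tts": c.dist_tts,
                "is_RM": c.is_RM,
                "novel_junction_count": c.novel_junction_count,
                "has_intron_retention": c.has_intron_retention,
                "ujc": ujc_key(c.model),
            }
        )
    return pd.DataFrame(rows)
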