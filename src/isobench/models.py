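"""Core domain types for transcript-model benchmarking.

Coordinate convention: all genomic intervals are 0-based, half-open
``[start, end)``. GTF/BED I/O converts at the boundary (GTF is 1-based,
fully closed; BED already matches the internal convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript model: the unit of structural classification.

    Exons are 0-based half-open intervals, strictly increasing and
    non-overlapping, with at least a 1-bp gap (the intron) between
    consecutive exons. Exons are stored in genomic order regardless of
    strand; transcription direction is given by ``strand``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: at least one exon required")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s >= e:
                raise ValidationError(
                    f"{self.transcript_id}: exon start {s} >= end {e}"
                )
            if prev_end is not None and s < prev_end + 1:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or touch at {prev_end}/{s}"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        """Spliced (mature) length in nt."""
        return sum(e - s for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def is_mono_exon(self) -> bool:
        return len(self.exons) == 1

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware genomic coordinate)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Transcription termination position (strand-aware)."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class IntronChain:
    """Ordered introns of a transcript; the identity of a splice isoform.

    Empty for mono-exon transcripts. Each intron is ``(donor_end,
    acceptor_start)`` in genomic order, i.e. the half-open gap between
    consecutive exons.
    """

    chrom: str
    strand: str
    introns: tuple[Interval, ...]

    def __post_init__(self) -> None:
        prev = None
        for s, e in self.introns:
            if s >= e:
                raise ValidationError(f"intron start {s} >= end {e}")
            if prev is not None and s < prev:
                raise ValidationError("introns not strictly increasing")
            prev = e

    @property
    def is_empty(self) -> bool:
        return not self.introns

    def __len__(self) -> int:
        return len(self.introns)


class Annotation:
    """A set of transcript models grouped by gene.

    Transcript ids are unique; every transcript belongs to exactly one
    gene; a gene's transcripts share chromosome and strand.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._transcripts: dict[str, TranscriptModel] = {}
        self._genes: dict[str, list[str]] = {}
        for t in transcripts:
            if t.transcript_id in self._transcripts:
                raise ValidationError(f"duplicate transcript_id {t.transcript_id!r}")
            self._transcripts[t.transcript_id] = t
            self._genes.setdefault(t.gene_id, []).append(t.transcript_id)
        for gid, tids in self._genes.items():
            chroms = {self._transcripts[t].chrom for t in tids}
            strands = {self._transcripts[t].strand for t in tids}
            if len(chroms) > 1 or len(strands) > 1:
                raise ValidationError(
                    f"gene {gid!r}: transcripts span multiple chroms/strands"
                )

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self._transcripts)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    @property
    def n_genes(self) -> int:
        return len(self._genes)

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self._transcripts[t] for t in self._genes[gene_id]]

    def genes(self) -> Iterator[tuple[str, list[TranscriptModel]]]:
        for gid in self._genes:
            yield gid, self.gene_transcripts(gid)

    def gene_tss_tts(self, gene_id: str) -> tuple[set[int], set[int]]:
        """Reference TSS and TTS coordinate sets for one gene."""
        tss = {t.tss for t in self.gene_transcripts(gene_id)}
        tts = {t.tts for t in self.gene_transcripts(gene_id)}
        return tss, tts


@dataclass
class GroundTruth:
    """True transcript abundances in TPM; a transcript is 'expressed' iff
    its true abundance is strictly positive."""

    abundance: "pd.Series"  # index: transcript_id, values: TPM

    def __post_init__(self) -> None:
        ab = pd.Series(self.abundance, dtype=float)
        if ab.index.has_duplicates:
            raise ValidationError("duplicate transcript ids in ground truth")
        if (ab < 0).any() or not np.isfinite(ab.to_numpy()).all():
            raise ValidationError("ground-truth abundances must be finite and >= 0")
        self.abundance = ab

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def expressed_ids(self) -> list[str]:
        return list(self.abundance.index[self.abundance > 0])

    def __len__(self) -> int:
        return len(self.abundance)


class AbundanceMatrix:
    """Transcripts x (group x replicate) TPM estimates.

    Values are non-negative and finite; the replicate count R is the same
    for every group within one matrix. Columns are pandas MultiIndex
    (group, replicate).
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values.columns, pd.MultiIndex) or values.columns.nlevels != 2:
            raise ValidationError(
                "AbundanceMatrix requires (group, replicate) MultiIndex columns"
            )
        if values.index.has_duplicates:
            raise ValidationError("duplicate transcript ids")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("abundance values must be finite")
        if (arr < 0).any():
            raise ValidationError("abundance values must be >= 0")
        reps_per_group = {
            g: len(values.columns[values.columns.get_level_values(0) == g])
            for g in values.columns.get_level_values(0).unique()
        }
        if len(set(reps_per_group.values())) > 1:
            raise ValidationError(
                f"unequal replicate counts across groups: {reps_per_group}"
            )
        self.values = values.astype(float)

    @classmethod
    def from_arrays(
        cls,
        transcript_ids: Sequence[str],
        groups: Sequence[str],
        replicates: Sequence[str],
        data: np.ndarray,
    ) -> "AbundanceMatrix":
        """Build from an (I, G*R) array laid out group-major."""
        cols = pd.MultiIndex.from_tuples(
            [(g, r) for g in groups for r in replicates], names=["group", "replicate"]
        )
        return cls(pd.DataFrame(np.asarray(data, dtype=float), index=list(transcript_ids), columns=cols))

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def groups(self) -> list[str]:
        return list(self.values.columns.get_level_values(0).unique())

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        g0 = self.groups[0]
        return self.values[g0].shape[1]

    def group(self, group: str) -> pd.DataFrame:
        """The I x R block of one group."""
        return self.values[group]

    def sample(self, group: str, replicate: str) -> pd.Series:
        return self.values[(group, replicate)]

    def __repr__(self) -> str:
        return (
            f"AbundanceMatrix({self.n_transcripts} transcripts, "
            f"{len(self.groups)} group(s) x {self.n_replicates} replicate(s))"
        )


@dataclass
class SupportTrack:
    """Orthogonal-evidence track: 5'/3' end peaks (intervals) or
    short-read splice-junction counts.

    ``kind`` is one of {"five_prime", "three_prime", "junction"}.
    Interval kinds carry a DataFrame with columns chrom/start/end[/strand];
    the junction kind carries columns chrom/strand/donor/acceptor/count
    with donor/acceptor the intron's genomic boundaries (0-based half-open
    intron [donor, acceptor)).
    """

    kind: str
    records: pd.DataFrame
    window: int = 50

    KINDS = ("five_prime", "three_prime", "junction")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown track kind {self.kind!r}")
        df = self.records
        if self.kind == "junction":
            required = {"chrom", "strand", "donor", "acceptor", "count"}
            if not required.issubset(df.columns):
                raise ValidationError(f"junction track needs columns {sorted(required)}")
            if (df["count"] < 0).any():
                raise ValidationError("junction counts must be >= 0")
        else:
            required = {"chrom", "start", "end"}
            if not required.issubset(df.columns):
                raise ValidationError(f"interval track needs columns {sorted(required)}")
            if (df["start"] >= df["end"]).any():
                raise ValidationError("invalid intervals in support track")

    def junction_counts(self) -> Mapping[tuple[str, str, int, int], float]:
        assert self.kind == "junction"
        return {
            (row.chrom, row.strand, int(row.donor), int(row.acceptor)): float(row.count)
            for row in self.records.itertuples()
        }
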