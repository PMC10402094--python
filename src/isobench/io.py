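"""Readers and writers for GTF, BED and TSV abundance tables.

GTF is 1-based fully-closed; BED and the internal representation are
0-based half-open. Conversion happens here and only here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .models import (
    AbundanceMatrix,
    Annotation,
    GroundTruth,
    SupportTrack,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class GTFParseError(ValueError):
    """A malformed GTF line, reported with its line number."""


def read_gtf(path: PathLike, dialect: str = "gencode") -> Annotation:
    """Read transcript models from a GTF file.

    Only ``exon`` features are used to build transcript structures;
    ``gene``/``transcript`` rows are accepted and ignored. Exons are
    grouped by ``transcript_id``, sorted by coordinate and converted to
    0-based half-open intervals. Rows without a strand are rejected:
    donor/acceptor identity depends on it.

    Parameters
    ----------
    path : str or Path
    dialect : {"gencode", "generic"}
        Retained for interface symmetry; both are parsed identically via
        gffutils' attribute parser, which handles GENCODE-style quoted
        attributes as well as unquoted ones.
    """
    if dialect not in ("gencode", "generic"):
        raise ValueError(f"unknown GTF dialect {dialect!r}")
    exons: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    n_anon = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise GTFParseError(
                    f"{path}:{lineno}: expected 9 tab-separated GTF fields, "
                    f"got {line.count(chr(9)) + 1}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GTFParseError(f"{path}:{lineno}: cannot parse GTF line: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs:
                raise GTFParseError(
                    f"{path}:{lineno}: exon feature lacks transcript_id attribute"
                )
            tid = attrs["transcript_id"][0]
            if "gene_id" in attrs and attrs["gene_id"]:
                gid = attrs["gene_id"][0]
            else:
                n_anon += 1
                gid = f"gene_of_{tid}"
            if feat.strand not in ("+", "-"):
                raise GTFParseError(
                    f"{path}:{lineno}: exon of {tid!r} has no strand; "
                    "stranded annotation is required"
                )
            # GTF 1-based inclusive -> 0-based half-open
            exons.setdefault(tid, []).append((feat.start - 1, feat.end))
            prev = meta.get(tid)
            if prev is not None and prev != (gid, feat.seqid, feat.strand):
                raise ValidationError(
                    f"{path}:{lineno}: transcript {tid!r} has inconsistent "
                    "gene/chrom/strand across exon rows"
                )
            meta[tid] = (gid, feat.seqid, feat.strand)
    if n_anon:
        logger.warning("%d transcripts lacked gene_id; synthesized gene ids", n_anon)
    transcripts = []
    for tid, ivs in exons.items():
        gid, chrom, strand = meta[tid]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(ivs)),
            )
        )
    return Annotation(transcripts)


def write_gtf(annotation: Annotation, path: PathLike, source: str = "isobench") -> None:
    """Write an Annotation as GENCODE-style GTF (transcript + exon rows).

    Ordering is deterministic: by chrom, start, transcript_id. Internal
    0-based half-open intervals are emitted 1-based inclusive.
    """
    models = sorted(annotation, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with open(path, "w") as fh:
        for t in models:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def read_abundance(path: PathLike) -> AbundanceMatrix:
    """Read a transcript x replicate TPM table.

    Expected TSV schema: a ``transcript_id`` column (or first column) and
    one numeric column per replicate, headers ``group:replicate`` (a
    header without ':' becomes group "sample"). Missing cells are set to
    0 TPM with a logged warning; the count is recorded on the returned
    matrix as ``load_report``.
    """
    df = pd.read_csv(path, sep="\t")
    id_col = "transcript_id" if "transcript_id" in df.columns else df.columns[0]
    if df[id_col].duplicated().any():
        dups = df[id_col][df[id_col].duplicated()].tolist()
        raise ValidationError(f"duplicate transcript_id(s) in {path}: {dups[:5]}")
    df = df.set_index(id_col)
    n_na = int(df.isna().to_numpy().sum())
    if n_na:
        logger.warning("%s: %d missing abundance cells set to 0 TPM", path, n_na)
        df = df.fillna(0.0)
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValidationError(f"negative abundance value in {path}")
    cols = []
    for c in df.columns:
        if ":" in str(c):
            g, r = str(c).split(":", 1)
        else:
            g, r = "sample", str(c)
        cols.append((g, r))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["group", "replicate"])
    mat = AbundanceMatrix(df)
    mat.load_report = {"path": str(path), "n_na_filled": n_na}
    return mat


def write_abundance(matrix: AbundanceMatrix, path: PathLike) -> None:
    """Write an AbundanceMatrix as TSV with ``group:replicate`` headers."""
    df = matrix.values.copy()
    df.columns = [f"{g}:{r}" for g, r in df.columns]
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_ground_truth(path: PathLike) -> GroundTruth:
    """Read a two-column TSV (transcript_id, TPM) as ground truth."""
    df = pd.read_csv(path, sep="\t")
    id_col = "transcript_id" if "transcript_id" in df.columns else df.columns[0]
    val_col = [c for c in df.columns if c != id_col][0]
    return GroundTruth(pd.Series(df[val_col].to_numpy(dtype=float), index=df[id_col]))


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    df = truth.abundance.rename("tpm").to_frame()
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_bed_track(path: PathLike, kind: str, window: int = 50) -> SupportTrack:
    """Read a BED(6) file of end-support peaks as a SupportTrack.

    BED coordinates are already 0-based half-open. Columns beyond the
    first six are ignored; strand defaults to '.' when absent.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}: BED line with <3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) >= 6 else "."
            rows.append((chrom, start, end, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return SupportTrack(kind=kind, records=df, window=window)


def read_junction_track(path: PathLike) -> SupportTrack:
    """Read a short-read splice-junction count TSV.

    Columns: chrom, strand, donor, acceptor, count — donor/acceptor are
    the 0-based half-open intron boundaries.
    """
    df = pd.read_csv(path, sep="\t")
    return SupportTrack(kind="junction", records=df)


def write_junction_track(track: SupportTrack, path: PathLike) -> None:
    track.records.to_csv(path, sep="\t", index=False)
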