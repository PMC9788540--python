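"""Reading, writing and normalization of the standard formats the pipeline touches.

All genomic coordinates are 1-based inclusive (GFF3 convention); conversions to
0-based happen only at file boundaries and array indexing. Coverage tracks hold
one strand of one library type (TEX-treated dRNA-seq, untreated dRNA-seq, or
fragmented strand-specific RNA-seq) for one condition and replicate.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_LIBRARIES = ("TEXplus", "TEXminus", "SS")
VALID_TRACK_KINDS = ("five_prime_ends", "full_coverage")
VALID_STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A single replicon: id plus an uppercase DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(
                f"genome {self.id!r}: invalid characters {sorted(bad)} in sequence"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature with 1-based inclusive coordinates."""

    gene_id: str
    feature_type: str  # CDS, rRNA, tRNA or other
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"feature {self.gene_id!r}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"feature {self.gene_id!r}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CoverageTrack:
    """Strand-specific per-position signal for one library/condition/replicate.

    ``values[i]`` is the signal at 1-based genome position ``i + 1``.
    """

    library: str
    track_kind: str
    condition: str
    replicate: int
    strand: str
    values: np.ndarray
    normalization: str = "raw"  # raw | per_million
    total_aligned_reads: float | None = None

    def __post_init__(self) -> None:
        if self.library not in VALID_LIBRARIES:
            raise ValueError(f"unknown library {self.library!r}")
        if self.track_kind not in VALID_TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.track_kind!r}")
        if self.strand not in VALID_STRANDS:
            raise ValueError("strand must be + or -")
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    @property
    def genome_length(self) -> int:
        return len(self.values)

    def value_at(self, position: int) -> float:
        """Signal at a 1-based genome position."""
        return float(self.values[position - 1])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA into GenomeRecords.

    Sequences are uppercased and U is converted to T so downstream code works
    on a single DNA alphabet.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3

_GFF_KNOWN_TYPES = {"CDS", "rRNA", "tRNA"}


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read CDS/rRNA/tRNA (and other) features from a GFF3 file.

    Coordinates are kept 1-based inclusive; feature types outside
    {CDS, rRNA, tRNA} are mapped to "other".
    """
    annotations: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            _, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            attrs = _parse_gff_attributes(attrs_s)
            gene_id = attrs.get("ID") or attrs.get("locus_tag") or f"feature_{lineno}"
            annotations.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    feature_type=ftype if ftype in _GFF_KNOWN_TYPES else "other",
                    start=start,
                    end=end,
                    strand=strand if strand in VALID_STRANDS else "+",
                    product=attrs.get("product", ""),
                )
            )
    return annotations


def write_gff3(
    annotations: Iterable[GeneAnnotation],
    path: str | Path,
    seqid: str = "chr",
    source: str = "srnascape",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            attrs = f"ID={ann.gene_id}"
            if ann.product:
                attrs += f";product={ann.product}"
            fh.write(
                f"{seqid}\t{source}\t{ann.feature_type}\t{ann.start}\t{ann.end}"
                f"\t.\t{ann.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Wiggle / bedGraph


def _track_metadata(track_line: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for token in track_line.split()[1:]:
        key, _, value = token.partition("=")
        meta[key] = value.strip('"')
    return meta


def read_wiggle(
    path: str | Path,
    genome_length: int,
    *,
    library: str = "SS",
    track_kind: str = "full_coverage",
    condition: str = "na",
    replicate: int = 1,
    strand: str = "+",
) -> CoverageTrack:
    """Read a fixedStep or variableStep wiggle file into a CoverageTrack.

    Missing positions are filled with zero. Track metadata (library, strand,
    etc.) is taken from the ``track`` line keys when present, else from the
    keyword arguments.
    """
    values = np.zeros(genome_length, dtype=float)
    mode = None
    pos = step = 1
    meta: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("track"):
                meta = _track_metadata(line)
                continue
            if line.startswith("variableStep"):
                mode = "variable"
                continue
            if line.startswith("fixedStep"):
                mode = "fixed"
                params = _track_metadata(line)
                pos = int(params.get("start", 1))
                step = int(params.get("step", 1))
                continue
            if mode is None:
                raise FormatError(f"{path}:{lineno}: data before step declaration")
            parts = line.split()
            if mode == "variable":
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: expected 'position value'")
                p, v = int(parts[0]), float(parts[1])
            else:
                p, v = pos, float(parts[0])
                pos += step
            if p < 1 or p > genome_length:
                raise FormatError(
                    f"{path}:{lineno}: position {p} outside genome of length {genome_length}"
                )
            values[p - 1] = abs(v)  # minus-strand wiggles often carry negative values
    return CoverageTrack(
        library=meta.get("library", library),
        track_kind=meta.get("track_kind", track_kind),
        condition=meta.get("condition", condition),
        replicate=int(meta.get("replicate", replicate)),
        strand=meta.get("strand", strand),
        values=values,
        normalization=meta.get("normalization", "per_million"),
    )


def write_wiggle(track: CoverageTrack, path: str | Path, chrom: str = "chr") -> None:
    """Write a track as variableStep wiggle, omitting zero positions."""
    buf = _io.StringIO()
    buf.write(
        'track type=wiggle_0 name="{}_{}_{}_rep{}_{}" library={} track_kind={} '
        "condition={} replicate={} strand={} normalization={}\n".format(
            track.library, track.condition, track.track_kind, track.replicate,
            track.strand, track.library, track.track_kind, track.condition,
            track.replicate, track.strand, track.normalization,
        )
    )
    buf.write(f"variableStep chrom={chrom}\n")
    nonzero = np.nonzero(track.values)[0]
    for i in nonzero:
        v = track.values[i]
        buf.write(f"{i + 1} {v:.6g}\n")
    Path(path).write_text(buf.getvalue())


def read_bedgraph(
    path: str | Path,
    genome_length: int,
    **track_kwargs,
) -> CoverageTrack:
    """Read a bedGraph (0-based half-open) file, converting to 1-based values."""
    values = np.zeros(genome_length, dtype=float)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            if start < 0 or end > genome_length:
                raise FormatError(f"{path}:{lineno}: interval outside genome")
            values[start:end] = abs(value)
    defaults = dict(
        library="SS", track_kind="full_coverage", condition="na",
        replicate=1, strand="+",
    )
    defaults.update(track_kwargs)
    return CoverageTrack(values=values, **defaults)


# ---------------------------------------------------------------------------
# Normalization


def normalize_coverage(track: CoverageTrack, total_aligned_reads: float) -> CoverageTrack:
    """Scale a raw track to reads-per-million of the library's aligned total."""
    if track.normalization != "raw":
        raise ValueError("track is already normalized")
    if total_aligned_reads <= 0:
        raise ValueError("total_aligned_reads must be positive")
    return replace(
        track,
        values=track.values / total_aligned_reads * 1e6,
        normalization="per_million",
        total_aligned_reads=float(total_aligned_reads),
    )


def average_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Mean of replicate tracks sharing library/kind/condition/strand/normalization."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if (t.library, t.track_kind, t.condition, t.strand, t.normalization) != (
            first.library, first.track_kind, first.condition, first.strand,
            first.normalization,
        ):
            raise ValueError("cannot average tracks with differing metadata")
    values = np.mean([t.values for t in tracks], axis=0)
    return replace(first, values=values, replicate=0)


def write_tsv(df, path: str | Path, schema_comment: str | None = None) -> None:
    """Write a DataFrame as TSV with an optional leading schema comment line."""
    with open(path, "w") as fh:
        if schema_comment:
            fh.write(f"# {schema_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
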