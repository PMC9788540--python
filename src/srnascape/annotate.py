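"""sRNA candidate detection, 5'-origin and genomic-location classification.

An sRNA candidate must satisfy three criteria: (i) signal in both the dRNA-seq
and the fragmented strand-specific RNA-seq libraries, (ii) mean per-million
ssRNA-seq coverage of at least 10 in at least one growth condition, and
(iii) a clean architecture — a TSS or PSS at the 5'-end and a terminator, PSS
or sharp coverage decrease at the 3'-end. Candidates are then classified along
two independent axes: 5'-end origin (ts = own transcription start, ps =
processing product) and location relative to annotated gene transcripts
(intergenic, antisense, intragenic with subtype, or both).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .io import CoverageTrack, GeneAnnotation, GenomeRecord, reverse_complement
from .sites import (
    SharpDecreaseParams,
    SiteCall,
    TranscriptInterval,
    find_sharp_decrease,
)

LOCATION_CLASSES = ("inter", "as", "intra", "intra_as")
INTRA_SUBTYPES = ("5UTR", "5CDS", "mCDS", "3CDS", "3UTR", "3rRNA", "2CDSs", "none")


@dataclass
class DetectionParams:
    min_len: int = 50
    max_len: int = 500
    min_abundance: float = 10.0     # mean per-million ssRNA-seq coverage, best condition
    site_tolerance: int = 1         # nt slack for 5'-end / site coincidence
    transcript_slack: int = 3       # nt slack for containment in a detected transcript
    sharp_decrease: SharpDecreaseParams = field(default_factory=SharpDecreaseParams)


@dataclass
class LocationParams:
    default_utr5: int = 50  # nt of 5'UTR assumed when no transcript evidence exists
    default_utr3: int = 80


@dataclass(frozen=True)
class GeneExtent:
    """A gene's transcript footprint: CDS plus UTR allowances (or measured extent)."""

    gene_id: str
    feature_type: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int


@dataclass
class SRnaCandidate:
    id: str
    start: int
    end: int
    strand: str
    origin_class: str            # ts | ps
    anchor_site: SiteCall
    end_evidence: str            # terminator | PSS | sharp_decrease
    location_class: str = "inter"
    location_subtype: str = "none"
    sequence: str = ""
    overlapping_gene_ids: tuple[str, ...] = ()
    same_strand_gene_ids: tuple[str, ...] = ()
    antisense_gene_ids: tuple[str, ...] = ()
    abundance: Mapping[str, float] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


def name_srna(five_prime: int, strand: str, taken: set[str] | None = None) -> str:
    """Name an sRNA after its strand-aware 5'-end genomic position.

    Two sRNAs starting at the same position on opposite strands are
    disambiguated by an "m" suffix on the minus-strand one.
    """
    name = f"sRNA{five_prime}"
    if taken is not None and name in taken:
        name = name + "m" if strand == "-" else name
    return name


def classify_origin(candidate: SRnaCandidate) -> str:
    """ts if the 5'-anchor is a TSS, ps if it is a PSS."""
    if candidate.anchor_site is None:
        raise ValueError(f"{candidate.id}: candidate has no anchor site")
    return "ts" if candidate.anchor_site.kind == "TSS" else "ps"


# ---------------------------------------------------------------------------
# Location classification


def build_gene_extents(
    annotations: Sequence[GeneAnnotation],
    transcripts: Sequence[TranscriptInterval] = (),
    params: LocationParams | None = None,
) -> list[GeneExtent]:
    """Associate every gene with a transcript footprint.

    For CDS features the footprint is the detected ssRNA-seq transcript when a
    unique same-strand transcript covers the CDS and no other CDS; otherwise
    the CDS extended by default UTR allowances, truncated where the extension
    would run into a neighboring same-strand CDS. rRNA/tRNA footprints are
    their annotated coordinates.
    """
    params = params or LocationParams()
    extents: list[GeneExtent] = []
    cds = [a for a in annotations if a.feature_type == "CDS"]

    def covering_transcript(ann: GeneAnnotation) -> TranscriptInterval | None:
        hits = [
            t for t in transcripts
            if t.strand == ann.strand and t.start <= ann.start and t.end >= ann.end
        ]
        if len(hits) != 1:
            return None
        t = hits[0]
        others = [
            o for o in cds
            if o is not ann and o.strand == ann.strand
            and min(t.end, o.end) >= max(t.start, o.start)
        ]
        return None if others else t

    for ann in annotations:
        if ann.feature_type == "CDS":
            t = covering_transcript(ann)
            if t is not None:
                lo, hi = t.start, t.end
            else:
                if ann.strand == "+":
                    lo = ann.start - params.default_utr5
                    hi = ann.end + params.default_utr3
                else:
                    lo = ann.start - params.default_utr3
                    hi = ann.end + params.default_utr5
                for o in cds:
                    if o is ann or o.strand != ann.strand:
                        continue
                    if o.end < ann.start:
                        lo = max(lo, o.end + 1)
                    elif o.start > ann.end:
                        hi = min(hi, o.start - 1)
                lo = max(lo, 1)
        else:
            lo, hi = ann.start, ann.end
        extents.append(
            GeneExtent(
                gene_id=ann.gene_id,
                feature_type=ann.feature_type,
                strand=ann.strand,
                tx_start=lo,
                tx_end=hi,
                cds_start=ann.start,
                cds_end=ann.end,
            )
        )
    return extents


def _overlaps(s: int, e: int, lo: int, hi: int) -> bool:
    return min(e, hi) >= max(s, lo)


def classify_interval(
    start: int,
    end: int,
    strand: str,
    extents: Sequence[GeneExtent],
) -> tuple[str, str, tuple[str, ...], tuple[str, ...]]:
    """Classify an interval against gene transcript footprints.

    Decision order: no overlap -> inter; opposite-strand only -> as;
    same-strand only -> intra with subtype; both -> intra_as with subtype.
    Overlap means at least one shared nucleotide. Returns
    (location_class, subtype, same-strand gene ids, opposite-strand gene ids).
    """
    same = [g for g in extents if g.strand == strand and _overlaps(start, end, g.tx_start, g.tx_end)]
    opposite = [g for g in extents if g.strand != strand and _overlaps(start, end, g.tx_start, g.tx_end)]
    same_ids = tuple(g.gene_id for g in same)
    opp_ids = tuple(g.gene_id for g in opposite)
    if not same and not opposite:
        return "inter", "none", (), ()
    if not same:
        return "as", "none", (), opp_ids
    subtype = _intra_subtype(start, end, strand, same)
    location = "intra" if not opposite else "intra_as"
    return location, subtype, same_ids, opp_ids


def _intra_subtype(start: int, end: int, strand: str, same: Sequence[GeneExtent]) -> str:
    """Subtype by which part of the same-strand parental transcript is overlapped.

    Rules are evaluated in a fixed order and the first match wins, so e.g. an
    interval crossing the CDS start from inside the 5'UTR is 5CDS, not 5UTR.
    """
    same = sorted(same, key=lambda g: (g.tx_start, g.gene_id))
    for g in same:
        if g.feature_type != "rRNA":
            continue
        three_prime_end = g.cds_end if g.strand == "+" else g.cds_start
        if _overlaps(start, end, three_prime_end, three_prime_end):
            return "3rRNA"
    body_overlapped = [
        g for g in same if _overlaps(start, end, g.cds_start, g.cds_end)
    ]
    if len([g for g in body_overlapped if g.feature_type == "CDS"]) >= 2:
        return "2CDSs"
    host = body_overlapped[0] if body_overlapped else same[0]
    body_touched = bool(body_overlapped)
    if host.strand == "+":
        utr5_lo, utr5_hi = host.tx_start, host.cds_start - 1
        utr3_lo, utr3_hi = host.cds_end + 1, host.tx_end
        body_start, body_end = host.cds_start, host.cds_end
    else:
        utr5_lo, utr5_hi = host.cds_end + 1, host.tx_end
        utr3_lo, utr3_hi = host.tx_start, host.cds_start - 1
        body_start, body_end = host.cds_end, host.cds_start
    if not body_touched and utr5_hi >= utr5_lo and _overlaps(start, end, utr5_lo, utr5_hi):
        return "5UTR"
    if _overlaps(start, end, body_start, body_start):
        return "5CDS"
    if start > min(host.cds_start, host.cds_end) and end < max(host.cds_start, host.cds_end):
        return "mCDS"
    if _overlaps(start, end, body_end, body_end):
        return "3CDS"
    if not body_touched and utr3_hi >= utr3_lo and _overlaps(start, end, utr3_lo, utr3_hi):
        return "3UTR"
    return "none"


def classify_location(
    candidate: SRnaCandidate,
    annotations: Sequence[GeneAnnotation],
    transcripts: Sequence[TranscriptInterval] = (),
    params: LocationParams | None = None,
) -> tuple[str, str]:
    extents = build_gene_extents(annotations, transcripts, params)
    location, subtype, same_ids, opp_ids = classify_interval(
        candidate.start, candidate.end, candidate.strand, extents
    )
    candidate.location_class = location
    candidate.location_subtype = subtype
    candidate.same_strand_gene_ids = same_ids
    candidate.antisense_gene_ids = opp_ids
    candidate.overlapping_gene_ids = same_ids + opp_ids
    return location, subtype


# ---------------------------------------------------------------------------
# Candidate detection


def _interval_from_anchor(anchor: SiteCall, three_prime: int) -> tuple[int, int]:
    if anchor.strand == "+":
        return anchor.position, three_prime
    return three_prime, anchor.position


def detect_srnas(
    transcripts_by_condition: Mapping[str, Sequence[TranscriptInterval]],
    sites: Sequence[SiteCall],
    ss_tracks_by_condition: Mapping[str, Sequence[CoverageTrack]],
    drna_tracks: Sequence[CoverageTrack],
    genome: GenomeRecord | None = None,
    params: DetectionParams | None = None,
) -> list[SRnaCandidate]:
    """Emit sRNA candidates anchored on called 5'-end sites.

    ``ss_tracks_by_condition`` maps condition label to the per-strand averaged
    ssRNA-seq coverage tracks; ``drna_tracks`` holds the averaged TEX+/TEX-
    5'-end tracks used only for the presence check of criterion (i). For every
    site the nearest downstream 3'-end giving a length within bounds is chosen
    among downstream PSS calls and sharp coverage decreases, PSS preferred on a
    tie. Output order is independent of input ordering.
    """
    params = params or DetectionParams()
    sites = sorted(sites, key=SiteCall.sort_key)
    pss_by_strand: dict[str, np.ndarray] = {
        st: np.array(
            sorted(s.position for s in sites if s.strand == st and s.kind == "PSS"),
            dtype=int,
        )
        for st in ("+", "-")
    }
    ss_by_cond_strand = {
        (cond, t.strand): t
        for cond, tracks in ss_tracks_by_condition.items()
        for t in tracks
    }
    drna_by_strand: dict[str, np.ndarray] = {}
    for t in drna_tracks:
        cur = drna_by_strand.get(t.strand)
        drna_by_strand[t.strand] = t.values if cur is None else cur + t.values

    candidates: dict[tuple[int, str], SRnaCandidate] = {}
    for anchor in sites:
        cand = _candidate_for_anchor(
            anchor, pss_by_strand, transcripts_by_condition,
            ss_by_cond_strand, drna_by_strand, params,
        )
        if cand is not None:
            candidates[(cand.five_prime, cand.strand)] = cand

    out = sorted(candidates.values(), key=lambda cand: (cand.strand, cand.start))
    taken: set[str] = set()
    for cand in out:
        cand.id = name_srna(cand.five_prime, cand.strand, taken)
        taken.add(cand.id)
        if genome is not None:
            seq = genome.sequence[cand.start - 1 : cand.end]
            if cand.strand == "-":
                seq = reverse_complement(seq)
            cand.sequence = seq.replace("T", "U")
    return out


def _candidate_for_anchor(
    anchor: SiteCall,
    pss_by_strand: Mapping[str, np.ndarray],
    transcripts_by_condition: Mapping[str, Sequence[TranscriptInterval]],
    ss_by_cond_strand: Mapping[tuple[str, str], CoverageTrack],
    drna_by_strand: Mapping[str, np.ndarray],
    params: DetectionParams,
) -> SRnaCandidate | None:
    direction = 1 if anchor.strand == "+" else -1
    ends: list[tuple[int, int, str]] = []  # (length, 3' position, evidence)

    pss_positions = pss_by_strand.get(anchor.strand, np.array([], dtype=int))
    if anchor.strand == "+":
        downstream = pss_positions[pss_positions > anchor.position]
        for p in downstream[: 20]:
            ends.append((int(p) - 1 - anchor.position + 1, int(p) - 1, "PSS"))
    else:
        downstream = pss_positions[pss_positions < anchor.position][::-1]
        for p in downstream[: 20]:
            ends.append((anchor.position - (int(p) + 1) + 1, int(p) + 1, "PSS"))

    for (cond, strand), track in ss_by_cond_strand.items():
        if strand != anchor.strand:
            continue
        pos = find_sharp_decrease(track, anchor.position + direction * params.min_len,
                                  anchor.strand, params.sharp_decrease)
        if pos is not None:
            ends.append((abs(pos - anchor.position) + 1, pos, "sharp_decrease"))

    # shortest in-bounds extension wins; PSS preferred on equal length
    valid = sorted(
        (e for e in ends if params.min_len <= e[0] <= params.max_len),
        key=lambda e: (e[0], e[2] != "PSS"),
    )
    for length, three_prime, evidence in valid:
        start, end = _interval_from_anchor(anchor, three_prime)
        abundance = _interval_abundance(start, end, anchor.strand, ss_by_cond_strand)
        if max(abundance.values(), default=0.0) < params.min_abundance:
            continue
        if not _covered_by_transcript(start, end, anchor.strand,
                                      transcripts_by_condition, params):
            continue
        drna = drna_by_strand.get(anchor.strand)
        if drna is None or drna[start - 1 : end].max() <= 0:
            continue
        return SRnaCandidate(
            id="",
            start=start,
            end=end,
            strand=anchor.strand,
            origin_class="ts" if anchor.kind == "TSS" else "ps",
            anchor_site=anchor,
            end_evidence=evidence,
            abundance=abundance,
        )
    return None


def _interval_abundance(
    start: int, end: int, strand: str,
    ss_by_cond_strand: Mapping[tuple[str, str], CoverageTrack],
) -> dict[str, float]:
    out: dict[str, float] = {}
    for (cond, st), track in ss_by_cond_strand.items():
        if st != strand:
            continue
        out[cond] = float(track.values[start - 1 : end].mean())
    return out


def _covered_by_transcript(
    start: int, end: int, strand: str,
    transcripts_by_condition: Mapping[str, Sequence[TranscriptInterval]],
    params: DetectionParams,
) -> bool:
    slack = params.transcript_slack
    for transcripts in transcripts_by_condition.values():
        for t in transcripts:
            if t.strand == strand and t.start - slack <= start and t.end + slack >= end:
                return True
    return False


# ---------------------------------------------------------------------------
# Redundancy clustering


def _local_identity(a: str, b: str, aligner: Align.PairwiseAligner) -> tuple[float, float]:
    """(identity over alignment columns, aligned fraction of the shorter sequence)."""
    alignments = aligner.align(a, b)
    if len(alignments) == 0:
        return 0.0, 0.0
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    if columns == 0:
        return 0.0, 0.0
    identity = counts.identities / columns
    aligned_short = counts.identities + counts.mismatches
    coverage = aligned_short / min(len(a), len(b))
    return identity, coverage


def cluster_redundant(
    sequences: Mapping[str, str] | Sequence[SRnaCandidate],
    identity: float = 0.70,
    short_coverage: float = 0.90,
) -> list[list[str]]:
    """Greedy longest-first redundancy clustering (CD-HIT-style thresholds).

    A sequence joins the first cluster whose representative it matches with
    local-alignment identity >= ``identity`` over >= ``short_coverage`` of the
    shorter sequence; otherwise it founds a new cluster. Returns clusters of
    ids, each led by its representative.
    """
    if not isinstance(sequences, Mapping):
        sequences = {c.id: c.sequence for c in sequences}
    if not sequences:
        raise ValueError("cluster_redundant requires at least one sequence")
    aligner = Align.PairwiseAligner(
        mode="local", match_score=1.0, mismatch_score=-1.0,
        open_gap_score=-2.0, extend_gap_score=-1.0,
    )
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    clusters: list[list[str]] = []
    for sid in order:
        seq = sequences[sid].upper().replace("U", "T")
        for cluster in clusters:
            rep = sequences[cluster[0]].upper().replace("U", "T")
            ident, cov = _local_identity(rep, seq, aligner)
            if ident >= identity and cov >= short_coverage:
                cluster.append(sid)
                break
        else:
            clusters.append([sid])
    return clusters
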