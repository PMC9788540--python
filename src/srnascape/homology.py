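"""sRNA homolog search across reference genomes and conservation summaries.

The search is a seed-and-extend local aligner in the BLASTN mold: exact k-mer
seeds on both strands, then gapped local alignment of the seeded neighborhood.
Identity is matches over alignment columns (gap columns included) and query
coverage is the aligned fraction of the query, both in percent, so the
standard identity/coverage threshold profiles (strict 75/75, loose 60/50,
known-family 50/50) apply directly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .io import GenomeRecord, reverse_complement

THRESHOLD_PROFILES = {
    "strict": (75.0, 75.0),
    "loose": (60.0, 50.0),
    "rfam": (50.0, 50.0),
}


@dataclass(frozen=True)
class HomologHit:
    srna_id: str
    genome_id: str
    identity: float        # percent of alignment columns matching
    query_coverage: float  # percent of query length aligned
    subject_start: int     # 1-based inclusive on the reference genome
    subject_end: int
    strand: str            # strand of the reference genome matched
    copy_index: int = 1
    score: float = 0.0


@dataclass
class SearchParams:
    k: int = 11
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    band_margin: int = 30     # subject window slack around the seeded diagonal span
    diagonal_band: int = 20   # seeds within this diagonal distance cluster together


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=params.match,
        mismatch_score=params.mismatch,
        # first gap position pays open + extend, as in BLAST-style affine costs
        open_gap_score=params.gap_open + params.gap_extend,
        extend_gap_score=params.gap_extend,
    )


def _kmer_index(sequence: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(sequence) - k + 1):
        index[sequence[i : i + k]].append(i)
    return index


def _seed_clusters(
    query: str, index: Mapping[str, list[int]], k: int, band: int
) -> list[tuple[int, int]]:
    """Cluster seed hits by diagonal; return (subject_lo, subject_hi) 0-based spans."""
    by_diag: dict[int, list[int]] = defaultdict(list)
    for qpos in range(len(query) - k + 1):
        for spos in index.get(query[qpos : qpos + k], ()):
            by_diag[spos - qpos].append(spos)
    if not by_diag:
        return []
    clusters: list[list[int]] = []
    for diag in sorted(by_diag):
        if clusters and diag - clusters[-1][0] <= band:
            clusters[-1][1] = min(clusters[-1][1], min(by_diag[diag]))
            clusters[-1][2] = max(clusters[-1][2], max(by_diag[diag]))
        else:
            clusters.append([diag, min(by_diag[diag]), max(by_diag[diag])])
        clusters[-1][0] = diag
    return [(c[1], c[2] + k) for c in clusters]


def homology_search(
    srna_sequence: str,
    reference_genome: GenomeRecord,
    min_identity: float = 75.0,
    min_coverage: float = 75.0,
    srna_id: str = "query",
    params: SearchParams | None = None,
    index: Mapping[str, list[int]] | None = None,
) -> list[HomologHit]:
    """Find local matches of an sRNA in a reference genome.

    Non-overlapping hits passing both percent thresholds are returned sorted
    by identity descending, with copy indices assigned in that order. A
    pre-built k-mer ``index`` of the reference may be passed to amortize
    repeated searches.
    """
    if not 0 < min_identity <= 100 or not 0 < min_coverage <= 100:
        raise ValueError("thresholds must be in (0, 100]")
    params = params or SearchParams()
    query = srna_sequence.upper().replace("U", "T")
    if len(query) < params.k:
        return []
    subject = reference_genome.sequence
    if index is None:
        index = _kmer_index(subject, params.k)
    aligner = _make_aligner(params)

    raw: list[HomologHit] = []
    for strand, oriented in (("+", query), ("-", reverse_complement(query))):
        for lo, hi in _seed_clusters(oriented, index, params.k, params.diagonal_band):
            wlo = max(0, lo - len(oriented) - params.band_margin)
            whi = min(len(subject), hi + len(oriented) + params.band_margin)
            window = subject[wlo:whi]
            alignments = aligner.align(window, oriented)
            if len(alignments) == 0 or alignments.score <= 0:
                continue
            aln = alignments[0]
            counts = aln.counts()
            columns = counts.gaps + counts.identities + counts.mismatches
            if columns == 0:
                continue
            identity = 100.0 * counts.identities / columns
            q_blocks = aln.aligned[1]
            aligned_q = int(sum(e - s for s, e in q_blocks))
            coverage = 100.0 * aligned_q / len(query)
            s_blocks = aln.aligned[0]
            s_start = wlo + int(s_blocks[0][0]) + 1
            s_end = wlo + int(s_blocks[-1][1])
            if identity >= min_identity and coverage >= min_coverage:
                raw.append(
                    HomologHit(
                        srna_id=srna_id, genome_id=reference_genome.id,
                        identity=identity, query_coverage=coverage,
                        subject_start=s_start, subject_end=s_end,
                        strand=strand, score=float(alignments.score),
                    )
                )
    return _collapse_hits(raw)


def _collapse_hits(hits: list[HomologHit]) -> list[HomologHit]:
    """Drop subject-overlapping hits keeping the best; re-index copies."""
    hits = sorted(hits, key=lambda h: (-h.score, -h.identity, h.subject_start))
    kept: list[HomologHit] = []
    for h in hits:
        if any(
            min(h.subject_end, k.subject_end) >= max(h.subject_start, k.subject_start)
            for k in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (-h.identity, h.subject_start))
    return [
        HomologHit(**{**h.__dict__, "copy_index": i + 1}) for i, h in enumerate(kept)
    ]


def search_all(
    sequences: Mapping[str, str],
    genomes: Sequence[GenomeRecord],
    profile: str = "strict",
    params: SearchParams | None = None,
) -> list[HomologHit]:
    """Search every sRNA against every reference genome at a named profile."""
    if profile not in THRESHOLD_PROFILES:
        raise ValueError(f"unknown threshold profile {profile!r}")
    min_id, min_cov = THRESHOLD_PROFILES[profile]
    params = params or SearchParams()
    hits: list[HomologHit] = []
    for genome in genomes:
        index = _kmer_index(genome.sequence, params.k)
        for sid in sorted(sequences):
            hits.extend(
                homology_search(
                    sequences[sid], genome, min_id, min_cov,
                    srna_id=sid, params=params, index=index,
                )
            )
    return hits


@dataclass
class ConservationMatrix:
    identity: pd.DataFrame      # rows sRNAs, columns genomes; NaN = absent
    species_count: pd.Series
    category: pd.Series         # specific | local | broad
    multi_copy: pd.Series       # True where any genome holds >= 2 copies
    profile: str


def build_conservation_matrix(
    hits: Sequence[HomologHit],
    srna_ids: Sequence[str],
    genome_ids: Sequence[str],
    profile: str = "strict",
    broad_min: int | None = None,
) -> ConservationMatrix:
    """Presence/identity matrix and conservation categories.

    species_count is the number of reference genomes holding at least one
    passing hit. Categories: specific = present in no reference genome (only
    the genome of origin), broad = present in at least ``broad_min`` genomes
    (default: all of them), local = in between.
    """
    broad_min = broad_min if broad_min is not None else len(genome_ids)
    identity = pd.DataFrame(np.nan, index=list(srna_ids), columns=list(genome_ids))
    copies = pd.DataFrame(0, index=list(srna_ids), columns=list(genome_ids))
    for h in hits:
        if h.srna_id not in identity.index or h.genome_id not in identity.columns:
            raise ValueError(f"hit references unknown ids: {h.srna_id}/{h.genome_id}")
        prev = identity.at[h.srna_id, h.genome_id]
        if pd.isna(prev) or h.identity > prev:
            identity.at[h.srna_id, h.genome_id] = h.identity
        copies.at[h.srna_id, h.genome_id] += 1
    species_count = identity.notna().sum(axis=1)
    category = pd.Series(
        np.where(species_count == 0, "specific",
                 np.where(species_count >= broad_min, "broad", "local")),
        index=identity.index,
    )
    return ConservationMatrix(
        identity=identity,
        species_count=species_count,
        category=category,
        multi_copy=(copies >= 2).any(axis=1),
        profile=profile,
    )


def correlate_identity_phylogeny(
    identity_row: Mapping[str, float] | pd.Series,
    distances: Mapping[str, float] | pd.Series,
) -> tuple[float, float] | None:
    """Spearman correlation of homolog identity with phylogenetic similarity.

    Similarity is the negated patristic distance, so vertically inherited
    sRNAs give positive rho. Returns None when fewer than 4 genomes have both
    values, or when either vector is constant (rank correlation undefined).
    """
    identity_row = pd.Series(identity_row).dropna()
    distances = pd.Series(distances).dropna()
    shared = identity_row.index.intersection(distances.index)
    if len(shared) < 4:
        return None
    ident = identity_row[shared].to_numpy(dtype=float)
    sim = -distances[shared].to_numpy(dtype=float)
    if np.allclose(ident, ident[0]) or np.allclose(sim, sim[0]):
        return None
    rho, p = stats.spearmanr(ident, sim)
    return float(rho), float(p)


def read_distance_matrix(path) -> pd.DataFrame:
    """Square patristic distance matrix from TSV with matching genome ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix rows and columns must match")
    return df
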