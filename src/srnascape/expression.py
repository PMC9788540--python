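"""Expression quantification, differential classification and target scanning.

Expression is summarized as TPM; differential expression between two growth
conditions uses median-of-ratios library-size normalization, a two-sided Welch
t-test on log2(normalized + 0.5) and Benjamini–Hochberg adjustment, with the
conventional call thresholds padj < 0.05 and |log2FC| >= 1. Post-
transcriptional candidates come from two scans: ANGGA motifs around the
ribosome binding region (CsrA-repressed targets) and an antisense
seed-and-extend duplex score between sRNAs and mRNA translation-initiation
windows (trans-acting targets).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneAnnotation, GenomeRecord, reverse_complement

PADJ_THRESHOLD = 0.05
LOG2FC_THRESHOLD = 1.0


# ---------------------------------------------------------------------------
# TPM and differential expression


def compute_tpm(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Transcripts per million: length-normalized rates scaled to sum 1e6."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    rate = counts / lengths
    total = rate.sum()
    if total <= 0:
        raise ValueError("all counts are zero")
    return rate / total * 1e6


def tpm_table(
    counts: pd.DataFrame, lengths: Mapping[str, float] | pd.Series
) -> pd.DataFrame:
    lengths = pd.Series(lengths).loc[counts.index]
    return counts.apply(lambda col: compute_tpm(col.to_numpy(), lengths.to_numpy()))


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """Library size factors from the median ratio to the geometric-mean sample."""
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    usable = np.isfinite(log_counts).all(axis=1)
    if not usable.any():
        raise ValueError("no feature has positive counts in every sample")
    log_geo = log_counts[usable].mean(axis=1, keepdims=True)
    return np.exp(np.median(log_counts[usable] - log_geo, axis=0))


def differential_expression(
    counts: pd.DataFrame,
    condition_labels: Sequence[str],
) -> pd.DataFrame:
    """Per-feature fold change, Welch p, BH-adjusted p and up/down/ns status.

    ``counts`` has features as rows and samples as columns; labels give each
    column's condition (exactly two distinct values, first-seen = numerator).
    Features with zero counts everywhere get p = 1 and status ns.
    """
    labels = list(condition_labels)
    if len(labels) != counts.shape[1]:
        raise ValueError("one condition label per sample column is required")
    conds = list(dict.fromkeys(labels))
    if len(conds) != 2:
        raise ValueError("exactly two conditions are required")
    idx_a = [i for i, c in enumerate(labels) if c == conds[0]]
    idx_b = [i for i, c in enumerate(labels) if c == conds[1]]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("at least two replicates per condition are required")

    mat = counts.to_numpy(dtype=float)
    factors = median_of_ratios_size_factors(mat)
    norm = mat / factors
    log_norm = np.log2(norm + 0.5)
    a, b = log_norm[:, idx_a], log_norm[:, idx_b]
    log2fc = np.log2((norm[:, idx_a].mean(axis=1) + 0.5)
                     / (norm[:, idx_b].mean(axis=1) + 0.5))
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvalues = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvalues = np.asarray(pvalues, dtype=float)
    all_zero = (mat == 0).all(axis=1)
    pvalues[~np.isfinite(pvalues)] = 1.0
    pvalues[all_zero] = 1.0
    log2fc[all_zero] = 0.0
    _, padj, _, _ = multipletests(pvalues, method="fdr_bh")
    status = np.where(
        (padj < PADJ_THRESHOLD) & (log2fc >= LOG2FC_THRESHOLD), "up",
        np.where((padj < PADJ_THRESHOLD) & (log2fc <= -LOG2FC_THRESHOLD), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalues,
            "padj": padj,
            "status": status,
        },
        index=counts.index,
    )


def top_expressed(
    tpm: pd.DataFrame,
    condition_labels: Sequence[str],
    n: int = 50,
) -> dict:
    """Per-condition top-n features by mean TPM, and their overlap.

    Ties at the cutoff break deterministically by feature id, so the sets are
    invariant to input row order.
    """
    labels = list(condition_labels)
    conds = list(dict.fromkeys(labels))
    tops: dict[str, list[str]] = {}
    for cond in conds:
        cols = [c for c, l in zip(tpm.columns, labels) if l == cond]
        means = tpm[cols].mean(axis=1)
        ranked = means.sort_index().sort_values(ascending=False, kind="stable")
        tops[cond] = list(ranked.index[:n])
    overlap = set(tops[conds[0]])
    for cond in conds[1:]:
        overlap &= set(tops[cond])
    share = {
        cond: float(tpm[[c for c, l in zip(tpm.columns, labels) if l == cond]]
                    .mean(axis=1).loc[tops[cond]].sum()
                    / tpm[[c for c, l in zip(tpm.columns, labels) if l == cond]]
                    .mean(axis=1).sum())
        for cond in conds
    }
    return {"top": tops, "overlap": sorted(overlap), "overlap_size": len(overlap),
            "top_share_of_total": share}


# ---------------------------------------------------------------------------
# CsrA target scan

_ANGGA = re.compile("(?=A[ACGT]GGA)")


def scan_csra_targets(
    annotations: Sequence[GeneAnnotation],
    genome: GenomeRecord,
    window: tuple[int, int] = (-25, 10),
) -> pd.DataFrame:
    """Rank genes by ANGGA occurrences around the ribosome binding region.

    For each CDS the strand-aware window ``window`` (relative to the first
    base of the start codon, truncated at contig edges) is scanned for the
    CsrA binding motif ANGGA. Genes with at least one occurrence are candidate
    targets, ranked by (count desc, distance of the nearest motif to the start
    codon asc, gene id).
    """
    rows = []
    n = genome.length
    for ann in annotations:
        if ann.feature_type != "CDS":
            continue
        if ann.strand == "+":
            anchor = ann.start
            lo, hi = max(1, anchor + window[0]), min(n, anchor + window[1])
            seq = genome.sequence[lo - 1 : hi]
            offset0 = lo - anchor
        else:
            anchor = ann.end
            lo, hi = max(1, anchor - window[1]), min(n, anchor - window[0])
            seq = reverse_complement(genome.sequence[lo - 1 : hi])
            offset0 = anchor - hi
        positions = [m.start() + offset0 for m in _ANGGA.finditer(seq)]
        if not positions:
            continue
        rows.append({
            "gene_id": ann.gene_id,
            "motif_count": len(positions),
            "nearest_offset": min(positions, key=lambda p: (abs(p), p)),
            "offsets": ",".join(str(p) for p in positions),
        })
    df = pd.DataFrame(rows, columns=["gene_id", "motif_count", "nearest_offset", "offsets"])
    if df.empty:
        return df
    df["abs_nearest"] = df["nearest_offset"].abs()
    df = df.sort_values(
        ["motif_count", "abs_nearest", "gene_id"], ascending=[False, True, True]
    ).drop(columns="abs_nearest").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# Trans-acting target prediction

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}
_PAIR_SCORE = {**{p: 2.0 for p in (("A", "U"), ("U", "A"))},
               **{p: 3.0 for p in (("G", "C"), ("C", "G"))},
               **{p: 1.0 for p in (("G", "U"), ("U", "G"))}}


@dataclass(frozen=True)
class InteractionPrediction:
    srna_id: str
    target_gene_id: str
    duplex_score: float
    srna_interval: tuple[int, int]    # 0-based [start, end] on the sRNA
    target_interval: tuple[int, int]  # 0-based [start, end] on the window
    rank: int = 0


@dataclass
class TargetParams:
    seed_min: int = 7
    allow_gu: bool = True            # GU wobble accepted in seeds
    window: tuple[int, int] = (-150, 100)  # around the start codon


def duplex_score(
    srna: str, window: str, params: TargetParams | None = None
) -> tuple[float, tuple[int, int], tuple[int, int]] | None:
    """Best gap-free antisense duplex between an sRNA and a target window.

    Both sequences are 5'->3'. A duplex pairs srna[i + t] with window[j - t];
    a mismatch terminates the extension, so scored duplexes are exactly the
    maximal all-paired runs. A run qualifies only if it contains
    ``seed_min`` consecutive Watson–Crick (optionally wobble) pairs. Scoring:
    GC +3, AU +2, GU +1. Returns (score, sRNA interval, window interval) of
    the best duplex or None.
    """
    params = params or TargetParams()
    s = srna.upper().replace("T", "U")
    w = window.upper().replace("T", "U")
    ns, nw = len(s), len(w)
    if ns == 0 or nw == 0:
        return None
    best: tuple[float, tuple[int, int], tuple[int, int]] | None = None
    # along each anti-diagonal i + j = const, runs of valid pairs are maximal duplexes
    for c in range(ns + nw - 1):
        i0 = max(0, c - nw + 1)
        i1 = min(ns - 1, c)
        run_start = None
        run_score = 0.0
        wc_run = 0
        best_wc = 0
        for i in range(i0, i1 + 2):
            j = c - i
            pair = (s[i], w[j]) if i <= i1 else None
            valid = pair in _PAIR_SCORE if pair is not None else False
            if valid:
                if run_start is None:
                    run_start = i
                    run_score = 0.0
                    best_wc = 0
                    wc_run = 0
                run_score += _PAIR_SCORE[pair]
                if pair in _WC or (params.allow_gu and pair in _GU):
                    wc_run += 1
                else:
                    wc_run = 0
                best_wc = max(best_wc, wc_run)
            if not valid and run_start is not None:
                end_i = i - 1
                if best_wc >= params.seed_min:
                    cand = (run_score, (run_start, end_i), (c - end_i, c - run_start))
                    if best is None or cand[0] > best[0]:
                        best = cand
                run_start = None
    return best


def predict_trans_targets(
    srna_sequence: str,
    gene_windows: Mapping[str, str],
    srna_id: str = "query",
    params: TargetParams | None = None,
) -> list[InteractionPrediction]:
    """Rank genes by the best antisense duplex with the sRNA.

    ``gene_windows`` maps gene id to the mRNA-sense target window sequence
    (typically around the start codon). Genes without any qualifying seed are
    omitted. Ranks are dense starting at 1; ties break by gene id.
    """
    params = params or TargetParams()
    rows = []
    for gid in sorted(gene_windows):
        hit = duplex_score(srna_sequence, gene_windows[gid], params)
        if hit is None:
            continue
        score, s_iv, w_iv = hit
        rows.append((score, gid, s_iv, w_iv))
    rows.sort(key=lambda r: (-r[0], r[1]))
    return [
        InteractionPrediction(
            srna_id=srna_id, target_gene_id=gid, duplex_score=score,
            srna_interval=s_iv, target_interval=w_iv, rank=i + 1,
        )
        for i, (score, gid, s_iv, w_iv) in enumerate(rows)
    ]


def extract_gene_windows(
    annotations: Sequence[GeneAnnotation],
    genome: GenomeRecord,
    window: tuple[int, int] = (-150, 100),
) -> dict[str, str]:
    """mRNA-sense sequence windows around every CDS start codon."""
    out: dict[str, str] = {}
    n = genome.length
    for ann in annotations:
        if ann.feature_type != "CDS":
            continue
        if ann.strand == "+":
            lo = max(1, ann.start + window[0])
            hi = min(n, ann.start + window[1])
            seq = genome.sequence[lo - 1 : hi]
        else:
            lo = max(1, ann.end - window[1])
            hi = min(n, ann.end - window[0])
            seq = reverse_complement(genome.sequence[lo - 1 : hi])
        out[ann.gene_id] = seq.replace("T", "U")
    return out


# ---------------------------------------------------------------------------
# Direct-relation classifier


@dataclass(frozen=True)
class DirectRelationCall:
    srna_id: str
    key_gene_id: str
    criteria: tuple[str, ...]  # subset of ("i", "ii", "iii")


def classify_direct_relations(
    srnas: Sequence,
    key_gene_ids: Sequence[str],
    interactions: Mapping[str, Sequence[InteractionPrediction]],
    known_gene_ids: Sequence[str] | None = None,
    top_k: int = 10,
) -> list[DirectRelationCall]:
    """sRNAs directly related to key genes by origin, antisense overlap or targeting.

    Criterion i: an intragenic sRNA whose parental gene is a key gene.
    Criterion ii: an antisense (or mixed) sRNA overlapping a key gene on the
    opposite strand. Criterion iii: an intragenic or intergenic sRNA whose
    predicted targets place the key gene within the top ``top_k`` ranks.
    One call is emitted per (sRNA, key gene) with every met criterion.
    """
    if known_gene_ids is not None:
        unknown = [g for g in key_gene_ids if g not in set(known_gene_ids)]
        if unknown:
            raise ValueError(f"unknown key gene ids: {', '.join(unknown)}")
    calls = []
    for srna in srnas:
        same = set(getattr(srna, "same_strand_gene_ids", ()))
        opposite = set(getattr(srna, "antisense_gene_ids", ()))
        preds = interactions.get(srna.id, ())
        top_targets = {p.target_gene_id for p in preds if p.rank <= top_k}
        for gene in key_gene_ids:
            met = []
            if srna.location_class in ("intra", "intra_as") and gene in same:
                met.append("i")
            if srna.location_class in ("as", "intra_as") and gene in opposite:
                met.append("ii")
            if srna.location_class in ("intra", "inter") and gene in top_targets:
                met.append("iii")
            if met:
                calls.append(DirectRelationCall(srna.id, gene, tuple(met)))
    return calls
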