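"""Per-sRNA sequence/structure features, motif profiles, sORFs and GGA counts.

Structure stability is summarized as the normalized minimum free energy
(NMFE): the folding energy of the sequence divided by its length, in
(kcal/mol)/nt. Two folding backends are provided: a thermodynamic one
delegating to ViennaRNA where available, and a built-in maximum base-pairing
(Nussinov) proxy whose score is the negated pair count — exactly testable
against exhaustive enumeration, and adequate wherever only relative stability
across groups is compared.
"""

from __future__ import annotations

import itertools
import math
import re
import shutil
import subprocess
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomeRecord, reverse_complement
from .sites import SiteCall

MIN_LOOP = 3  # minimum unpaired nucleotides enclosed by a base pair

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

_IUPAC2 = {
    frozenset("AG"): "R", frozenset("CU"): "Y", frozenset("AU"): "W",
    frozenset("CG"): "S", frozenset("GU"): "K", frozenset("AC"): "M",
}

_STOPS = ("UAA", "UAG", "UGA")


def _as_rna(sequence: str) -> str:
    return sequence.upper().replace("T", "U")


@dataclass(frozen=True)
class FeatureRecord:
    srna_id: str
    length: int
    gc: float
    mfe: float

    @property
    def nmfe(self) -> float:
        return self.mfe / self.length


@dataclass
class MotifProfile:
    anchor: str                  # TSS | PSS
    offsets: list[int]           # relative offsets; anchor base is +1, no zero
    frequencies: pd.DataFrame    # rows = offsets, columns = A/C/G/U
    information: np.ndarray      # bits per position
    consensus: str
    n_sites: int

    def consensus_between(self, lo: int, hi: int) -> str:
        picked = [i for i, off in enumerate(self.offsets) if lo <= off <= hi]
        return "".join(self.consensus[i] for i in picked)


@dataclass(frozen=True)
class SmallORF:
    srna_id: str
    frame: int
    start_offset: int  # 0-based within the sRNA
    end_offset: int    # 0-based, inclusive of the stop codon's last nt
    aa_length: int     # amino acids, stop excluded


def gc_content(sequence: str) -> float:
    """(#G + #C) / length; ambiguous bases count as non-GC."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# Folding

try:  # ViennaRNA python bindings, if present in the environment
    import RNA as _vienna  # type: ignore
except Exception:  # pragma: no cover
    _vienna = None


def _numba_nussinov():
    from numba import njit

    @njit(cache=False)
    def kernel(codes):  # codes: int8 array, A=0 C=1 G=2 U=3
        n = codes.shape[0]
        M = np.zeros((n, n), dtype=np.int32)
        for span in range(MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = M[i, j - 1]
                cj = codes[j]
                for k in range(i, j - MIN_LOOP):
                    ck = codes[k]
                    ok = ((ck == 0 and cj == 3) or (ck == 3 and cj == 0)
                          or (ck == 2 and cj == 1) or (ck == 1 and cj == 2)
                          or (ck == 2 and cj == 3) or (ck == 3 and cj == 2))
                    if ok:
                        left = M[i, k - 1] if k > i else 0
                        inner = M[k + 1, j - 1] if k + 1 <= j - 1 else 0
                        cand = left + 1 + inner
                        if cand > best:
                            best = cand
                M[i, j] = best
        return M[0, n - 1] if n > 0 else 0

    return kernel


_nussinov_kernel = None


def _max_pairing(sequence: str) -> int:
    """Maximum number of AU/GC/GU pairs in a nested structure (min loop 3)."""
    global _nussinov_kernel
    seq = _as_rna(sequence)
    if len(seq) <= MIN_LOOP + 1:
        return 0
    code_map = {"A": 0, "C": 1, "G": 2, "U": 3}
    codes = np.array([code_map.get(ch, 4) for ch in seq], dtype=np.int8)
    if _nussinov_kernel is None:
        _nussinov_kernel = _numba_nussinov()
    return int(_nussinov_kernel(codes))


def fold_mfe(sequence: str, backend: str = "basepair_proxy") -> float:
    """Folding score of an RNA sequence, always <= 0.

    backend "thermodynamic": ViennaRNA minimum free energy in kcal/mol
    (python bindings or the RNAfold executable). backend "basepair_proxy":
    negated Nussinov maximum pair count — only relative comparisons are
    meaningful, never absolute kcal/mol.
    """
    seq = _as_rna(sequence)
    if backend == "basepair_proxy":
        return -float(_max_pairing(seq))
    if backend == "thermodynamic":
        if _vienna is not None:
            return float(_vienna.fold(seq)[1])
        if shutil.which("RNAfold"):
            out = subprocess.run(
                ["RNAfold", "--noPS"], input=seq + "\n", text=True,
                capture_output=True, check=True,
            ).stdout
            match = re.search(r"\(\s*(-?\d+\.?\d*)\)\s*$", out.strip().splitlines()[-1])
            return float(match.group(1))
        raise RuntimeError("no thermodynamic folding engine available")
    raise ValueError(f"unknown folding backend {backend!r}")


def nmfe(mfe: float, length: int) -> float:
    """Length-normalized folding energy, (kcal/mol)/nt."""
    if length <= 0:
        raise ValueError("length must be positive")
    return mfe / length


def feature_table(
    sequences: Mapping[str, str], backend: str = "basepair_proxy"
) -> pd.DataFrame:
    rows = []
    for sid, seq in sequences.items():
        mfe = fold_mfe(seq, backend)
        rows.append({
            "srna_id": sid, "length": len(seq), "gc": gc_content(seq),
            "mfe": mfe, "nmfe": nmfe(mfe, len(seq)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group statistics


def compare_feature_groups(
    groups: Mapping[str, pd.DataFrame],
    features: Sequence[str] = ("length", "gc", "nmfe"),
    min_n: int = 3,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum p for every group pair on every feature.

    Groups smaller than ``min_n`` are excluded (with a warning column rather
    than an exception, so one thin class never aborts a run).
    """
    import warnings

    usable = {}
    for name, df in groups.items():
        if len(df) < min_n:
            warnings.warn(f"group {name!r} has n={len(df)} < {min_n}; excluded")
            continue
        usable[name] = df
    if len(usable) < 2:
        raise ValueError("need at least two groups of sufficient size")
    rows = []
    for (a, da), (b, db) in itertools.combinations(sorted(usable.items()), 2):
        for feat in features:
            stat, p = stats.ranksums(da[feat], db[feat])
            rows.append({"group_a": a, "group_b": b, "feature": feat,
                         "n_a": len(da), "n_b": len(db),
                         "statistic": float(stat), "pvalue": float(p)})
    return pd.DataFrame(rows)


def correlate_gc_nmfe(gc_means: Sequence[float], nmfe_means: Sequence[float]):
    """Spearman correlation between per-group mean GC and mean NMFE."""
    if len(gc_means) != len(nmfe_means) or len(gc_means) < 4:
        raise ValueError("need at least 4 paired group means")
    rho, p = stats.spearmanr(gc_means, nmfe_means)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Motif profiling


def extract_site_windows(
    sites: Sequence[SiteCall],
    genome: GenomeRecord,
    upstream: int,
    downstream: int,
) -> tuple[list[str], list[int]]:
    """Strand-aware sequence windows around sites, as RNA.

    Window covers ``upstream`` nt before the site and ``downstream`` nt from
    the site on (the site base included); minus-strand windows are
    reverse-complemented. Sites too close to the genome edge are skipped.
    Returns (windows, offsets) with offsets labeled ...,-2,-1,+1,+2,...
    and the site base at +1.
    """
    import warnings

    windows = []
    n = genome.length
    for site in sites:
        if site.strand == "+":
            lo, hi = site.position - upstream, site.position + downstream - 1
            if lo < 1 or hi > n:
                warnings.warn(f"site {site.position}{site.strand} too close to edge; skipped")
                continue
            seq = genome.sequence[lo - 1 : hi]
        else:
            lo, hi = site.position - downstream + 1, site.position + upstream
            if lo < 1 or hi > n:
                warnings.warn(f"site {site.position}{site.strand} too close to edge; skipped")
                continue
            seq = reverse_complement(genome.sequence[lo - 1 : hi])
        windows.append(_as_rna(seq))
    offsets = list(range(-upstream, 0)) + list(range(1, downstream + 1))
    return windows, offsets


def _consensus_base(freqs: Mapping[str, float]) -> str:
    """Degenerate consensus: dominant base, two-letter IUPAC code, or N."""
    ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    (b1, f1), (b2, f2) = ranked[0], ranked[1]
    if f1 >= 0.5 and f1 >= 2 * f2:
        return b1
    if f1 + f2 >= 0.75 and f1 >= 0.25 and f2 >= 0.25:
        return _IUPAC2[frozenset((b1, b2))]
    return "N"


def motif_profile(
    sites: Sequence[SiteCall],
    genome: GenomeRecord,
    anchor_kind: str,
    window: tuple[int, int] = (-10, 10),
) -> MotifProfile:
    """Position frequency matrix, information content and consensus around sites.

    ``window`` is (lowest, highest) offset with the anchor base at +1 and no
    position zero; the TSS default in promoter work is (-50, 1), the
    processing-site default (-10, 10).
    """
    use = [s for s in sites if s.kind == anchor_kind]
    if len(use) < 10:
        raise ValueError(f"need at least 10 {anchor_kind} sites, got {len(use)}")
    upstream = max(0, -window[0])
    downstream = max(0, window[1])
    windows, offsets = extract_site_windows(use, genome, upstream, downstream)
    keep = [i for i, off in enumerate(offsets) if window[0] <= off <= window[1]]
    offsets = [offsets[i] for i in keep]
    mat = np.array([[w[i] for i in keep] for w in windows])
    bases = ["A", "C", "G", "U"]
    counts = np.stack([(mat == b).sum(axis=0) for b in bases], axis=1).astype(float)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    information = 2.0 + plogp.sum(axis=1)
    consensus = "".join(
        _consensus_base(dict(zip(bases, row))) for row in freqs
    )
    return MotifProfile(
        anchor=anchor_kind,
        offsets=offsets,
        frequencies=pd.DataFrame(freqs, index=offsets, columns=bases),
        information=information,
        consensus=consensus,
        n_sites=len(windows),
    )


def strongest_hexamer(
    sites: Sequence[SiteCall],
    genome: GenomeRecord,
    anchor_kind: str,
    window: tuple[int, int],
) -> tuple[str, int]:
    """Most frequent hexamer in a strand-aware offset window (promoter boxes).

    Returns (hexamer, occurrence count) over all usable sites; a deterministic
    stand-in for de novo motif discovery in the -10/-35 regions.
    """
    use = [s for s in sites if s.kind == anchor_kind]
    upstream = max(0, -window[0])
    windows, offsets = extract_site_windows(use, genome, upstream, max(0, window[1]))
    keep = [i for i, off in enumerate(offsets) if window[0] <= off <= window[1]]
    counts: dict[str, int] = {}
    for w in windows:
        sub = "".join(w[i] for i in keep)
        for i in range(len(sub) - 5):
            hexamer = sub[i : i + 6]
            counts[hexamer] = counts.get(hexamer, 0) + 1
    if not counts:
        raise ValueError("no sequence available in the requested window")
    best = max(sorted(counts), key=lambda k: counts[k])
    return best, counts[best]


# ---------------------------------------------------------------------------
# Small ORFs


def find_sorfs(sequence: str, min_aa: int = 20, srna_id: str = "") -> list[SmallORF]:
    """AUG-initiated, stop-terminated reading frames of >= ``min_aa`` amino acids.

    All three frames of the given strand are scanned; nested AUGs sharing a
    stop within one frame are reported once, keeping the longest (earliest
    start).
    """
    seq = _as_rna(sequence)
    out: list[SmallORF] = []
    for frame in range(3):
        seen_stops: set[int] = set()
        i = frame
        while i + 2 < len(seq):
            if seq[i : i + 3] == "AUG":
                j = i + 3
                while j + 3 <= len(seq):
                    codon = seq[j : j + 3]
                    if codon in _STOPS:
                        if j not in seen_stops:
                            aa = (j - i) // 3
                            if aa >= min_aa:
                                out.append(
                                    SmallORF(
                                        srna_id=srna_id, frame=frame,
                                        start_offset=i, end_offset=j + 2,
                                        aa_length=aa,
                                    )
                                )
                            seen_stops.add(j)
                        break
                    j += 3
            i += 3
    out.sort(key=lambda o: (o.start_offset, o.frame))
    return out


# ---------------------------------------------------------------------------
# GGA motifs against a secondary structure


def count_gga_motifs(sequence: str, dot_bracket: str) -> dict[str, int]:
    """Classify every (possibly overlapping) GGA occurrence by pairing state.

    All three positions unpaired -> unpaired; one or two unpaired ->
    partially_paired; none unpaired -> paired.
    """
    seq = _as_rna(sequence)
    if len(seq) != len(dot_bracket):
        raise ValueError("structure length must equal sequence length")
    depth = 0
    for ch in dot_bracket:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError("unbalanced dot-bracket structure")
        elif ch != ".":
            raise ValueError(f"unexpected structure character {ch!r}")
    if depth != 0:
        raise ValueError("unbalanced dot-bracket structure")
    counts = {"unpaired": 0, "partially_paired": 0, "paired": 0}
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "GGA":
            continue
        unpaired = sum(1 for k in range(i, i + 3) if dot_bracket[k] == ".")
        if unpaired == 3:
            counts["unpaired"] += 1
        elif unpaired == 0:
            counts["paired"] += 1
        else:
            counts["partially_paired"] += 1
    return counts
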