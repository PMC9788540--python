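"""TSS/PSS calling from TEX+/TEX- 5'-end tracks and coverage-based transcript detection.

Differential RNA-seq pairs a TEX-treated library (5'P-dependent exonuclease
degrades processed transcripts, enriching primary 5'-triphosphate ends) with an
untreated one. A 5'-end position whose TEX+/TEX- signal ratio exceeds an
enrichment factor is called a transcription start site (TSS); a position with a
clear 5'-end peak but no enrichment is a processing site (PSS), typically an
RNase E cleavage product.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import CoverageTrack


@dataclass
class SiteCallingParams:
    min_height: float = 5.0       # per-million 5'-end signal floor for a candidate
    pseudocount: float = 1.0      # stabilizes the enrichment ratio near zero
    enrichment_factor: float = 2.0  # TEX+/TEX- ratio at or above which a site is a TSS
    cluster_window: int = 3       # nt; nearby calls merged keeping the highest


@dataclass
class TranscriptParams:
    min_coverage: float = 2.0  # per-million coverage defining "transcribed"
    max_gap: int = 5           # nt allowed below threshold inside a run
    min_length: int = 20       # nt; shorter runs discarded


@dataclass
class SharpDecreaseParams:
    window: int = 5      # nt averaged on each side of the candidate step
    drop_factor: float = 0.5  # downstream/upstream mean ratio at or below which a step fires
    max_scan: int = 600  # nt scanned downstream of the start position


@dataclass(frozen=True)
class SiteCall:
    """A TSS or PSS at single-nucleotide resolution."""

    position: int  # 1-based
    strand: str
    kind: str  # TSS | PSS
    height: float  # defining-track 5'-end signal (TEX+ for TSS, TEX- for PSS)
    enrichment: float
    conditions: tuple[str, ...] = ()

    def sort_key(self):
        return (self.strand, self.position, self.kind)


@dataclass(frozen=True)
class TranscriptInterval:
    start: int
    end: int
    strand: str
    mean_coverage: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _check_pair(texplus: CoverageTrack, texminus: CoverageTrack) -> None:
    if texplus.library != "TEXplus" or texminus.library != "TEXminus":
        raise ValueError("call_sites expects a (TEXplus, TEXminus) track pair")
    for t in (texplus, texminus):
        if t.track_kind != "five_prime_ends":
            raise ValueError("site calling requires five_prime_ends tracks")
        if t.normalization != "per_million":
            raise ValueError("site calling requires per_million normalized tracks")
    if texplus.strand != texminus.strand:
        raise ValueError("TEX+ and TEX- tracks are on different strands")
    if texplus.condition != texminus.condition:
        raise ValueError("TEX+ and TEX- tracks are from different conditions")
    if texplus.genome_length != texminus.genome_length:
        raise ValueError("track lengths differ")


def call_sites(
    texplus: CoverageTrack,
    texminus: CoverageTrack,
    params: SiteCallingParams | None = None,
) -> list[SiteCall]:
    """Call TSSs and PSSs on one strand of one condition.

    Candidate positions are those where either library's 5'-end signal reaches
    ``min_height``. The TEX enrichment ``(TEX+ + c) / (TEX- + c)`` then decides
    the kind: at or above ``enrichment_factor`` the position is a TSS, below it
    a PSS. A PSS additionally requires the untreated library itself to reach
    ``min_height`` (a TEX+-only spike without enrichment is discarded as noise).
    Calls within ``cluster_window`` nt are merged keeping the highest peak.
    """
    params = params or SiteCallingParams()
    _check_pair(texplus, texminus)
    p, m = texplus.values, texminus.values
    c = params.pseudocount
    candidates = np.nonzero(np.maximum(p, m) >= params.min_height)[0]
    calls: list[SiteCall] = []
    for i in candidates:
        enrich = (p[i] + c) / (m[i] + c)
        if enrich >= params.enrichment_factor:
            kind, height = "TSS", p[i]
        else:
            if m[i] < params.min_height:
                continue  # unenriched spike visible only in TEX+: noise
            kind, height = "PSS", m[i]
        calls.append(
            SiteCall(
                position=int(i) + 1,
                strand=texplus.strand,
                kind=kind,
                height=float(height),
                enrichment=float(enrich),
                conditions=(texplus.condition,),
            )
        )
    return _cluster_calls(calls, params.cluster_window)


def _cluster_calls(calls: list[SiteCall], window: int) -> list[SiteCall]:
    """Greedy peak clustering: highest peak wins, neighbors within the window drop."""
    kept: list[SiteCall] = []
    suppressed: set[int] = set()
    # height descending, position ascending for deterministic ties
    for call in sorted(calls, key=lambda s: (-s.height, s.position)):
        if call.position in suppressed:
            continue
        kept.append(call)
        for offset in range(-window, window + 1):
            suppressed.add(call.position + offset)
    kept.sort(key=SiteCall.sort_key)
    return kept


def merge_condition_sites(per_condition: list[list[SiteCall]]) -> list[SiteCall]:
    """Union of site calls across conditions with per-condition provenance.

    Sites at the same (position, strand) are merged keeping the maximum height.
    If one condition supports a TSS and another a PSS at the same position, the
    TSS wins (a genuine initiation event explains both observations) and both
    condition labels are retained.
    """
    merged: dict[tuple[int, str], SiteCall] = {}
    for calls in per_condition:
        for call in calls:
            key = (call.position, call.strand)
            prev = merged.get(key)
            if prev is None:
                merged[key] = call
                continue
            kind = "TSS" if "TSS" in (prev.kind, call.kind) else "PSS"
            best = prev if prev.height >= call.height else call
            merged[key] = replace(
                best,
                kind=kind,
                conditions=tuple(sorted(set(prev.conditions) | set(call.conditions))),
            )
    return sorted(merged.values(), key=SiteCall.sort_key)


def detect_transcripts(
    ss: CoverageTrack,
    params: TranscriptParams | None = None,
) -> list[TranscriptInterval]:
    """Detect transcribed intervals as maximal above-threshold coverage runs.

    Runs of coverage >= ``min_coverage`` are merged across below-threshold gaps
    of at most ``max_gap`` nt; runs shorter than ``min_length`` are discarded.
    """
    params = params or TranscriptParams()
    if ss.track_kind != "full_coverage":
        raise ValueError("transcript detection requires a full_coverage track")
    if ss.normalization != "per_million":
        raise ValueError("transcript detection requires a per_million track")
    above = ss.values >= params.min_coverage
    if not above.any():
        return []
    # run-length encode the boolean profile
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges, len(above) - 1]
    runs = [(int(s), int(e)) for s, e, a in zip(starts, ends, above[starts]) if a]
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= params.max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if e - s + 1 < params.min_length:
            continue
        out.append(
            TranscriptInterval(
                start=s + 1,
                end=e + 1,
                strand=ss.strand,
                mean_coverage=float(ss.values[s : e + 1].mean()),
            )
        )
    return out


def find_sharp_decrease(
    ss: CoverageTrack,
    start_from: int,
    strand: str,
    params: SharpDecreaseParams | None = None,
) -> int | None:
    """Locate the first sharp coverage drop downstream of ``start_from``.

    Scans 5'->3' on the given strand for the first position ``p`` where the
    mean coverage over the next ``window`` nt falls to at most ``drop_factor``
    times the mean over the previous ``window`` nt, then refines to the local
    minimum of that ratio so a clean step is reported exactly at its last
    high-coverage position. Returns the 1-based genome position of the
    transcript 3'-end, or None.
    """
    params = params or SharpDecreaseParams()
    values = ss.values
    n = len(values)
    w = params.window

    if strand == "+":
        def prev_mean(p):  # positions p-w+1 .. p (1-based), needs p >= w
            return values[p - w : p].mean()

        def next_mean(p):
            return values[p : p + w].mean()

        scan = range(max(start_from, w), min(start_from + params.max_scan, n - w) + 1)
        step = 1
    else:
        def prev_mean(p):  # on minus strand "previous" is the higher coordinates
            return values[p - 1 : p - 1 + w].mean()

        def next_mean(p):
            return values[p - 1 - w : p - 1].mean()

        scan = range(min(start_from, n - w + 1), max(start_from - params.max_scan, w + 1) - 1, -1)
        step = -1

    def ratio(p):
        pm = prev_mean(p)
        if pm <= 0:
            return np.inf
        return next_mean(p) / pm

    for p in scan:
        r = ratio(p)
        if r <= params.drop_factor:
            # walk downstream while the ratio keeps strictly decreasing
            q = p
            while True:
                nxt = q + step
                if strand == "+" and not (w <= nxt <= n - w):
                    break
                if strand == "-" and not (w + 1 <= nxt <= n - w + 1):
                    break
                if ratio(nxt) < ratio(q):
                    q = nxt
                else:
                    break
            return q
    return None
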