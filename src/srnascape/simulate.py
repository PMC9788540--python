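"""Synthetic genome, annotation and coverage generator with full ground truth.

The generator emulates the statistical structure a differential-RNA-seq sRNA
study rests on: a GC-rich single-replicon bacterial genome; protein-coding
genes with fixed UTR allowances; planted sRNAs realizing every location class
(intergenic, antisense, intragenic subtypes, and both); transcription start
sites carrying -10/-35 promoter boxes and a +1 purine; processing sites
carrying the RNase E-style RN^WUU cleavage motif; TEX+/TEX- 5'-end tracks with
configurable enrichment (TSS) and depletion (PSS) factors; strand-specific
full coverage proportional to expression sampled log-uniformly over several
orders of magnitude, with condition-specific fold changes; and per-replicate
Poisson noise. Everything planted is reported in a machine-checkable truth
object so recovery rates can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotate
from .io import (
    CoverageTrack,
    GeneAnnotation,
    GenomeRecord,
    write_fasta,
    write_gff3,
    write_tsv,
    write_wiggle,
)

_PURINES = ("A", "G")
_WEAK = ("A", "T")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class GenerationError(RuntimeError):
    pass


@dataclass
class SyntheticConfig:
    genome_length: int = 200_000
    gc_content: float = 0.616            # marine alkane-degrader GC level
    n_cds: int = 150
    n_rrna: int = 2
    n_trna: int = 8
    n_srna_per_class: Mapping[str, int] = field(
        # 60 sRNAs at roughly the observed class proportions
        # (intragenic ~2/3, antisense ~1/5, intergenic and mixed the rest)
        default_factory=lambda: {"intra": 40, "as": 12, "inter": 4, "intra_as": 4}
    )
    tss_fraction: float = 0.634          # fraction of sRNAs with their own TSS
    expression_range: tuple[float, float] = (10.0, 1e6)
    gene_expression_range: tuple[float, float] = (5.0, 1e4)
    de_fraction_up: float = 0.23
    de_fraction_down: float = 0.22
    fold_change_range: tuple[float, float] = (1.0, 4.0)  # |log2 FC| of DE sRNAs
    noise: float = 0.2                   # Poisson background mean, per-million units
    tex_enrichment_true: float = 10.0    # TEX+/TEX- at a primary 5'-end
    tex_depletion_true: float = 0.2      # TEX+/TEX- at a processed 5'-end
    replicates: int = 3
    conditions: tuple[str, str] = ("alkane", "acetate")
    utr5: int = 50
    utr3: int = 80
    min_srna_len: int = 50
    max_srna_len: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tss_fraction", "de_fraction_up", "de_fraction_down", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.expression_range[0] <= 0 or self.expression_range[1] <= 0:
            raise ValueError("expression_range must be positive")

    @property
    def n_srnas(self) -> int:
        return sum(self.n_srna_per_class.values())


@dataclass
class PlantedGene:
    gene_id: str
    feature_type: str
    cds_start: int
    cds_end: int
    strand: str
    tx_start: int
    tx_end: int
    tss: int
    expression: dict[str, float] = field(default_factory=dict)


@dataclass
class PlantedSRna:
    srna_id: str
    start: int
    end: int
    strand: str
    origin_class: str       # ts | ps
    location_class: str
    location_subtype: str
    five_prime_site: int    # genomic position of the 5'-end TSS/PSS
    three_prime_pss: int | None  # planted 3'-end processing site, if any
    host_gene_ids: tuple[str, ...]
    expression: dict[str, float]
    log2fc: float           # first condition vs second condition

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PlantedSite:
    position: int
    strand: str
    kind: str       # TSS | PSS
    source: str     # gene | srna_5p | srna_3p
    parent_id: str


@dataclass
class SyntheticTruth:
    config: SyntheticConfig
    genes: list[PlantedGene]
    srnas: list[PlantedSRna]
    sites: list[PlantedSite]

    def sites_by_key(self) -> dict[tuple[int, str], PlantedSite]:
        return {(s.position, s.strand): s for s in self.sites}

    def srnas_by_five_prime(self) -> dict[tuple[int, str], PlantedSRna]:
        return {(s.five_prime_site, s.strand): s for s in self.srnas}


@dataclass
class SyntheticDataset:
    genome: GenomeRecord
    annotations: list[GeneAnnotation]
    tracks: list[CoverageTrack]
    truth: SyntheticTruth

    def tracks_for(self, library: str, condition: str | None = None,
                   strand: str | None = None) -> list[CoverageTrack]:
        out = []
        for t in self.tracks:
            if t.library != library:
                continue
            if condition is not None and t.condition != condition:
                continue
            if strand is not None and t.strand != strand:
                continue
            out.append(t)
        return out


# ---------------------------------------------------------------------------
# Cassette layout (relative coordinates, then mirrored for minus-strand hosts)


@dataclass
class _Cassette:
    span: int
    genes: list[dict] = field(default_factory=list)   # relative coords
    srna: dict | None = None

    def mirror(self) -> "_Cassette":
        """Flip the cassette to the opposite strand within its own span."""
        def flip(d: dict) -> dict:
            out = dict(d)
            for key in ("cds", "tx", "iv"):
                if key in d:
                    lo, hi = d[key]
                    out[key] = (self.span - hi + 1, self.span - lo + 1)
            if "strand" in d:
                out["strand"] = "+" if d["strand"] == "-" else "-"
            return out

        return _Cassette(
            span=self.span,
            genes=[flip(g) for g in self.genes],
            srna=flip(self.srna) if self.srna else None,
        )


def _plain_gene(rng, ftype: str, cfg: SyntheticConfig) -> _Cassette:
    if ftype == "CDS":
        cds_len = int(rng.integers(100, 500)) * 3
        span = cfg.utr5 + cds_len + cfg.utr3
        return _Cassette(
            span=span,
            genes=[{"type": "CDS", "strand": "+",
                    "cds": (cfg.utr5 + 1, cfg.utr5 + cds_len),
                    "tx": (1, span)}],
        )
    length = 1500 if ftype == "rRNA" else 80
    return _Cassette(
        span=length,
        genes=[{"type": ftype, "strand": "+", "cds": (1, length), "tx": (1, length)}],
    )


def _intra_cassette(rng, subtype: str, cfg: SyntheticConfig) -> _Cassette:
    if subtype == "3UTR":
        srna_len = int(rng.integers(cfg.min_srna_len, cfg.utr3 - 5))
    else:
        srna_len = int(rng.integers(120, 261))
    cds_len = ((srna_len + 220) // 3) * 3
    c1 = cfg.utr5 + 1
    c2 = c1 + cds_len - 1
    span = cfg.utr5 + cds_len + cfg.utr3
    if subtype == "mCDS":
        s = c1 + 30
        e = s + srna_len - 1
    elif subtype == "5CDS":
        s = c1 - 20
        e = s + srna_len - 1
    elif subtype == "3CDS":
        e = c2 + 20
        s = e - srna_len + 1
    elif subtype == "3UTR":
        s = c2 + 3
        e = s + srna_len - 1
    else:
        raise ValueError(f"unsupported planted intra subtype {subtype!r}")
    return _Cassette(
        span=span,
        genes=[{"type": "CDS", "strand": "+", "cds": (c1, c2), "tx": (1, span)}],
        srna={"strand": "+", "iv": (s, e), "class": "intra", "subtype": subtype,
              "pss3": True},
    )


def _as_cassette(rng, cfg: SyntheticConfig) -> _Cassette:
    srna_len = int(rng.integers(120, 261))
    cds_len = ((srna_len + 220) // 3) * 3
    c1 = cfg.utr5 + 1
    c2 = c1 + cds_len - 1
    span = cfg.utr5 + cds_len + cfg.utr3
    s = c1 + 40
    e = s + srna_len - 1
    return _Cassette(
        span=span,
        genes=[{"type": "CDS", "strand": "+", "cds": (c1, c2), "tx": (1, span)}],
        srna={"strand": "-", "iv": (s, e), "class": "as", "subtype": "none",
              "pss3": False},
    )


def _inter_cassette(rng, cfg: SyntheticConfig) -> _Cassette:
    srna_len = int(rng.integers(100, 261))
    pad = 150
    return _Cassette(
        span=srna_len + 2 * pad,
        genes=[],
        srna={"strand": "+", "iv": (pad + 1, pad + srna_len), "class": "inter",
              "subtype": "none", "pss3": False},
    )


def _intra_as_cassette(rng, cfg: SyntheticConfig) -> _Cassette:
    len_a = int(rng.integers(220, 300)) * 3
    len_b = int(rng.integers(220, 300)) * 3
    a1 = cfg.utr5 + 1
    a2 = a1 + len_a - 1
    b1 = a2 + 41            # CDS gap 40 nt: the two 3'UTR allowances overlap
    b2 = b1 + len_b - 1
    span = b2 + cfg.utr5
    e = a2 + int(rng.integers(10, 31))
    srna_len = int(rng.integers(120, 221))
    s = e - srna_len + 1
    return _Cassette(
        span=span,
        genes=[
            {"type": "CDS", "strand": "+", "cds": (a1, a2), "tx": (1, a2 + cfg.utr3)},
            {"type": "CDS", "strand": "-", "cds": (b1, b2),
             "tx": (b1 - cfg.utr3, span)},
        ],
        srna={"strand": "+", "iv": (s, e), "class": "intra_as", "subtype": "3CDS",
              "pss3": True},
    )


# ---------------------------------------------------------------------------
# Generator


def _loguniform(rng, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _strand_pos(anchor: int, offset: int, strand: str) -> int:
    return anchor + offset if strand == "+" else anchor - offset


def _set_base(seq: list[str], position: int, base: str, strand: str) -> None:
    if not 1 <= position <= len(seq):
        return
    seq[position - 1] = base if strand == "+" else _COMPLEMENT[base]


def _plant_promoter(seq: list[str], rng, tss: int, strand: str) -> None:
    for i, ch in enumerate("TTGACA"):
        _set_base(seq, _strand_pos(tss, -35 + i, strand), ch, strand)
    for i, ch in enumerate("TATAAT"):
        _set_base(seq, _strand_pos(tss, -12 + i, strand), ch, strand)
    _set_base(seq, tss, _PURINES[rng.integers(2)], strand)


def _plant_cleavage_motif(seq: list[str], rng, pss: int, strand: str) -> None:
    """RN^WUU around a processing site; the site itself is the +1 (W) base."""
    _set_base(seq, _strand_pos(pss, -2, strand), _PURINES[rng.integers(2)], strand)
    _set_base(seq, _strand_pos(pss, -1, strand), _BASES[rng.integers(4)], strand)
    _set_base(seq, _strand_pos(pss, 0, strand), _WEAK[rng.integers(2)], strand)
    _set_base(seq, _strand_pos(pss, 1, strand), "T", strand)
    _set_base(seq, _strand_pos(pss, 2, strand), "T", strand)


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic landscape with ground truth.

    The same seed always yields the identical dataset, byte for byte, when
    written out.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    cassettes: list[tuple[str, _Cassette]] = []
    intra_subtypes = ["mCDS", "5CDS", "3CDS", "3UTR"]
    for cls, count in sorted(cfg.n_srna_per_class.items()):
        for i in range(count):
            if cls == "intra":
                cas = _intra_cassette(rng, intra_subtypes[i % 4], cfg)
            elif cls == "as":
                cas = _as_cassette(rng, cfg)
            elif cls == "inter":
                cas = _inter_cassette(rng, cfg)
            elif cls == "intra_as":
                cas = _intra_as_cassette(rng, cfg)
            else:
                raise ValueError(f"unknown location class {cls!r}")
            cassettes.append(("srna", cas))
    hosts_used = sum(len(c.genes) for _, c in cassettes)
    n_plain = cfg.n_cds - hosts_used
    if n_plain < 0:
        raise GenerationError(
            "n_cds is smaller than the number of host genes required by "
            "n_srna_per_class; increase n_cds"
        )
    for _ in range(n_plain):
        cassettes.append(("gene", _plain_gene(rng, "CDS", cfg)))
    for _ in range(cfg.n_rrna):
        cassettes.append(("gene", _plain_gene(rng, "rRNA", cfg)))
    for _ in range(cfg.n_trna):
        cassettes.append(("gene", _plain_gene(rng, "tRNA", cfg)))

    order = rng.permutation(len(cassettes))
    cassettes = [cassettes[i] for i in order]
    # mirror ~half of the cassettes onto the minus strand
    cassettes = [
        (tag, cas.mirror() if rng.random() < 0.5 else cas) for tag, cas in cassettes
    ]

    total_span = sum(c.span for _, c in cassettes)
    margin = 400
    budget = cfg.genome_length - total_span - 2 * margin
    n_gaps = len(cassettes) - 1
    if budget < n_gaps * 120:
        raise GenerationError(
            f"cassettes need {total_span + n_gaps * 120 + 2 * margin} nt but the "
            f"genome is only {cfg.genome_length} nt; increase genome_length"
        )
    # 120 nt minimum gap; the rest of the budget split randomly so cassettes
    # spread over the whole genome without ever overshooting it
    extra = budget - n_gaps * 120
    weights = rng.random(max(n_gaps, 1))
    gaps = (120 + np.floor(extra * weights / weights.sum())).astype(int)

    # lay out left to right
    genes: list[PlantedGene] = []
    srna_specs: list[dict] = []
    offset = margin
    gene_counter = {"CDS": 0, "rRNA": 0, "tRNA": 0}
    for idx, (tag, cas) in enumerate(cassettes):
        for g in cas.genes:
            gene_counter[g["type"]] += 1
            prefix = {"CDS": "g", "rRNA": "r", "tRNA": "t"}[g["type"]]
            gid = f"{prefix}{gene_counter[g['type']]:04d}"
            cds = (offset + g["cds"][0], offset + g["cds"][1])
            tx = (offset + g["tx"][0], offset + g["tx"][1])
            tss = tx[0] if g["strand"] == "+" else tx[1]
            genes.append(
                PlantedGene(
                    gene_id=gid, feature_type=g["type"], cds_start=cds[0],
                    cds_end=cds[1], strand=g["strand"], tx_start=tx[0],
                    tx_end=tx[1], tss=tss,
                )
            )
        if cas.srna is not None:
            d = dict(cas.srna)
            d["iv"] = (offset + d["iv"][0], offset + d["iv"][1])
            d["host_ids"] = tuple(
                genes[-len(cas.genes) + i].gene_id for i in range(len(cas.genes))
            )
            srna_specs.append(d)
        offset += cas.span + (int(gaps[idx]) if idx < n_gaps else 0)

    # 5'-origin assignment: exactly round(tss_fraction * n) sRNAs are ts
    n = len(srna_specs)
    n_ts = int(round(cfg.tss_fraction * n))
    origins = np.array(["ts"] * n_ts + ["ps"] * (n - n_ts))
    rng.shuffle(origins)

    # expression and fold changes
    base_expr = _loguniform(rng, *cfg.expression_range, size=n)
    n_up = int(round(cfg.de_fraction_up * n))
    n_down = int(round(cfg.de_fraction_down * n))
    de_sign = np.array([1] * n_up + [-1] * n_down + [0] * (n - n_up - n_down))
    rng.shuffle(de_sign)
    lfc = de_sign * rng.uniform(*cfg.fold_change_range, size=n)
    cond_a, cond_b = cfg.conditions

    srnas: list[PlantedSRna] = []
    sites: list[PlantedSite] = []
    for g in genes:
        sites.append(PlantedSite(g.tss, g.strand, "TSS", "gene", g.gene_id))
        expr = float(_loguniform(rng, *cfg.gene_expression_range))
        g.expression = {c: expr for c in cfg.conditions}
    for i, spec in enumerate(srna_specs):
        s, e = spec["iv"]
        strand = spec["strand"]
        five = s if strand == "+" else e
        kind = "TSS" if origins[i] == "ts" else "PSS"
        srna_id = f"sRNA{five}" + ("m" if strand == "-" and
                                   any(x.five_prime_site == five for x in srnas) else "")
        pss3 = None
        if spec["pss3"]:
            pss3 = e + 1 if strand == "+" else s - 1
        expr = {cond_a: float(base_expr[i] * 2.0 ** lfc[i]),
                cond_b: float(base_expr[i])}
        srnas.append(
            PlantedSRna(
                srna_id=srna_id, start=s, end=e, strand=strand,
                origin_class=str(origins[i]), location_class=spec["class"],
                location_subtype=spec["subtype"], five_prime_site=five,
                three_prime_pss=pss3, host_gene_ids=spec["host_ids"],
                expression=expr, log2fc=float(lfc[i]),
            )
        )
        sites.append(PlantedSite(five, strand, kind, "srna_5p", srna_id))
        if pss3 is not None:
            sites.append(PlantedSite(pss3, strand, "PSS", "srna_3p", srna_id))

    truth = SyntheticTruth(config=cfg, genes=genes, srnas=srnas, sites=sites)
    _check_geometry(truth)

    # genome sequence with motifs planted at every site
    p_base = np.array([
        (1 - cfg.gc_content) / 2, cfg.gc_content / 2,
        cfg.gc_content / 2, (1 - cfg.gc_content) / 2,
    ])
    seq = list("".join(rng.choice(_BASES, size=cfg.genome_length, p=p_base)))
    for site in sorted(sites, key=lambda x: (x.position, x.strand, x.kind)):
        if site.kind == "TSS":
            _plant_promoter(seq, rng, site.position, site.strand)
        else:
            _plant_cleavage_motif(seq, rng, site.position, site.strand)
    genome = GenomeRecord(id="synthetic_chr", sequence="".join(seq))

    annotations = [
        GeneAnnotation(
            gene_id=g.gene_id, feature_type=g.feature_type, start=g.cds_start,
            end=g.cds_end, strand=g.strand,
            product=f"synthetic {g.feature_type}",
        )
        for g in genes
    ]

    tracks = _simulate_tracks(cfg, rng, truth)
    return SyntheticDataset(genome=genome, annotations=annotations,
                            tracks=tracks, truth=truth)


def _check_geometry(truth: SyntheticTruth) -> None:
    """Self-consistency: re-derive each planted class with the location rules."""
    extents = [
        annotate.GeneExtent(
            gene_id=g.gene_id, feature_type=g.feature_type, strand=g.strand,
            tx_start=g.tx_start, tx_end=g.tx_end,
            cds_start=g.cds_start, cds_end=g.cds_end,
        )
        for g in truth.genes
    ]
    for srna in truth.srnas:
        loc, subtype, _, _ = annotate.classify_interval(
            srna.start, srna.end, srna.strand, extents
        )
        if (loc, subtype) != (srna.location_class, srna.location_subtype):
            raise GenerationError(
                f"{srna.srna_id}: planted as {srna.location_class}/{srna.location_subtype} "
                f"but geometry reads as {loc}/{subtype}"
            )
        if not truth.config.min_srna_len <= srna.length <= truth.config.max_srna_len:
            raise GenerationError(f"{srna.srna_id}: length {srna.length} out of bounds")


def _site_strength(expression: float) -> float:
    # 5'-end peak tied to transcript abundance, floored so every planted site
    # clears the default calling threshold even after replicate noise
    return max(10.0, 0.5 * expression)


def _simulate_tracks(cfg: SyntheticConfig, rng, truth: SyntheticTruth) -> list[CoverageTrack]:
    n = cfg.genome_length
    tracks: list[CoverageTrack] = []
    for condition in cfg.conditions:
        signal = {
            ("SS", "+"): np.zeros(n), ("SS", "-"): np.zeros(n),
            ("TEXplus", "+"): np.zeros(n), ("TEXplus", "-"): np.zeros(n),
            ("TEXminus", "+"): np.zeros(n), ("TEXminus", "-"): np.zeros(n),
        }
        for g in truth.genes:
            expr = g.expression[condition]
            signal[("SS", g.strand)][g.tx_start - 1 : g.tx_end] += expr
            strength = _site_strength(expr)
            signal[("TEXplus", g.strand)][g.tss - 1] += strength
            signal[("TEXminus", g.strand)][g.tss - 1] += strength / cfg.tex_enrichment_true
        for srna in truth.srnas:
            expr = srna.expression[condition]
            signal[("SS", srna.strand)][srna.start - 1 : srna.end] += expr
            strength = _site_strength(expr)
            if srna.origin_class == "ts":
                plus, minus = strength, strength / cfg.tex_enrichment_true
            else:
                plus, minus = strength * cfg.tex_depletion_true, strength
            signal[("TEXplus", srna.strand)][srna.five_prime_site - 1] += plus
            signal[("TEXminus", srna.strand)][srna.five_prime_site - 1] += minus
            if srna.three_prime_pss is not None:
                signal[("TEXplus", srna.strand)][srna.three_prime_pss - 1] += (
                    strength * cfg.tex_depletion_true
                )
                signal[("TEXminus", srna.strand)][srna.three_prime_pss - 1] += strength

        for replicate in range(1, cfg.replicates + 1):
            for (library, strand), lam in sorted(signal.items()):
                if cfg.noise > 0:
                    values = rng.poisson(lam + cfg.noise).astype(float)
                else:
                    values = lam.copy()
                tracks.append(
                    CoverageTrack(
                        library=library,
                        track_kind="full_coverage" if library == "SS" else "five_prime_ends",
                        condition=condition,
                        replicate=replicate,
                        strand=strand,
                        values=values,
                        normalization="per_million",
                    )
                )
    return tracks


# ---------------------------------------------------------------------------
# Homolog genomes


def mutate_genome(
    genome: GenomeRecord,
    substitution_rate: float,
    deleted_srna_ids: Sequence[str] = (),
    seed: int = 0,
    *,
    srna_loci: Mapping[str, tuple[int, int]] | None = None,
    genome_id: str | None = None,
    gc_content: float = 0.616,
) -> GenomeRecord:
    """Derive a homolog genome by i.i.d. substitutions.

    Every substitution changes the base, so the expected identity of a
    surviving locus is 1 - rate. Loci listed in ``deleted_srna_ids`` (resolved
    through ``srna_loci``) are replaced by random sequence, i.e. the homolog is
    absent from that genome.
    """
    if not 0 <= substitution_rate < 0.5:
        raise ValueError("substitution_rate must be in [0, 0.5)")
    if deleted_srna_ids and srna_loci is None:
        raise ValueError("srna_loci mapping required to resolve deleted_srna_ids")
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1").copy()
    if substitution_rate > 0:
        hits = np.nonzero(rng.random(len(seq)) < substitution_rate)[0]
        for i in hits:
            current = seq[i].decode()
            choices = [b for b in _BASES if b != current]
            seq[i] = choices[rng.integers(3)].encode()
    p_base = np.array([(1 - gc_content) / 2, gc_content / 2,
                       gc_content / 2, (1 - gc_content) / 2])
    for sid in deleted_srna_ids:
        lo, hi = srna_loci[sid]
        repl = rng.choice(_BASES, size=hi - lo + 1, p=p_base)
        seq[lo - 1 : hi] = np.array([b.encode() for b in repl])
    return GenomeRecord(
        id=genome_id or f"{genome.id}_mut{substitution_rate:g}",
        sequence=seq.tobytes().decode(),
    )


def generate_reference_set(
    dataset: SyntheticDataset,
    rates: Sequence[float],
    deletions: Sequence[Sequence[str]] | None = None,
    seed: int = 0,
) -> list[GenomeRecord]:
    """Mutated reference genomes for conservation analysis, one per rate."""
    loci = {s.srna_id: (s.start, s.end) for s in dataset.truth.srnas}
    deletions = deletions or [[] for _ in rates]
    genomes = []
    for i, (rate, dels) in enumerate(zip(rates, deletions)):
        genomes.append(
            mutate_genome(
                dataset.genome, rate, dels, seed=seed + i + 1,
                srna_loci=loci, genome_id=f"ref{i + 1:02d}",
                gc_content=dataset.truth.config.gc_content,
            )
        )
    return genomes


# ---------------------------------------------------------------------------
# Count-matrix simulation (for differential-expression calibration)


def simulate_counts(
    n_features: int,
    n_replicates: int = 3,
    mean_range: tuple[float, float] = (50.0, 2000.0),
    dispersion: float = 0.05,
    log2fc: float | np.ndarray = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Negative-binomial count matrix for two conditions.

    Returns (counts with shape (n_features, 2 * n_replicates), labels).
    ``log2fc`` is applied to the first condition's mean.
    """
    rng = np.random.default_rng(seed)
    base = _loguniform(rng, *mean_range, size=n_features)
    lfc = np.broadcast_to(np.asarray(log2fc, dtype=float), (n_features,))
    means = np.empty((n_features, 2 * n_replicates))
    means[:, :n_replicates] = (base * 2.0 ** lfc)[:, None]
    means[:, n_replicates:] = base[:, None]
    # NB via gamma-Poisson mixture: var = mu + dispersion * mu^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means / shape)
    counts = rng.poisson(lam)
    labels = ["A"] * n_replicates + ["B"] * n_replicates
    return counts.astype(float), labels


# ---------------------------------------------------------------------------
# Serialization


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write FASTA, GFF3, per-track wiggle files and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([dataset.genome], outdir / "genome.fa")
    write_gff3(dataset.annotations, outdir / "annotation.gff3",
               seqid=dataset.genome.id)
    for t in dataset.tracks:
        name = (f"{t.library}_{t.condition}_rep{t.replicate}_"
                f"{'fwd' if t.strand == '+' else 'rev'}_{t.track_kind}.wig")
        write_wiggle(t, outdir / name, chrom=dataset.genome.id)
    truth = dataset.truth
    write_tsv(
        pd.DataFrame([
            {"srna_id": s.srna_id, "start": s.start, "end": s.end,
             "strand": s.strand, "origin_class": s.origin_class,
             "location_class": s.location_class,
             "location_subtype": s.location_subtype,
             "five_prime_site": s.five_prime_site,
             "three_prime_pss": s.three_prime_pss if s.three_prime_pss else "",
             "host_gene_ids": ",".join(s.host_gene_ids),
             **{f"expr_{c}": v for c, v in s.expression.items()},
             "log2fc": s.log2fc}
            for s in truth.srnas
        ]),
        outdir / "truth_srnas.tsv",
        "planted sRNAs: interval, strand, classes, anchor sites, expression",
    )
    write_tsv(
        pd.DataFrame([
            {"position": s.position, "strand": s.strand, "kind": s.kind,
             "source": s.source, "parent_id": s.parent_id}
            for s in truth.sites
        ]),
        outdir / "truth_sites.tsv",
        "planted TSS/PSS positions",
    )
    write_tsv(
        pd.DataFrame([
            {"gene_id": g.gene_id, "feature_type": g.feature_type,
             "cds_start": g.cds_start, "cds_end": g.cds_end, "strand": g.strand,
             "tx_start": g.tx_start, "tx_end": g.tx_end, "tss": g.tss,
             **{f"expr_{c}": v for c, v in g.expression.items()}}
            for g in truth.genes
        ]),
        outdir / "truth_genes.tsv",
        "planted genes with transcript extents",
    )
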