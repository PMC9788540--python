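"""End-to-end orchestration: simulate or load data, run every stage, summarize.

The pipeline consumes a genome, an annotation and per-million coverage tracks
(TEX+/TEX- 5'-end and strand-specific full coverage, per condition and
replicate), calls 5'-end sites, detects and classifies sRNA candidates,
computes their sequence features and expression response, and writes every
stage's tables. When the input is a synthetic dataset the planted truth is
carried along and a recovery report is produced.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate, expression, features, homology, simulate, sites
from .io import (
    CoverageTrack,
    GenomeRecord,
    average_replicates,
    write_fasta,
    write_gff3,
    write_tsv,
)

logger = logging.getLogger("srnascape")


def percent(k: int, n: int, decimals: int = 1) -> float:
    """Percentage k/n rounded half away from zero to ``decimals`` places."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    value = 100.0 * k / n
    scale = 10 ** decimals
    return math.floor(abs(value) * scale + 0.5) / scale * (1 if value >= 0 else -1)


def summarize_classes(srnas: Sequence[annotate.SRnaCandidate]) -> pd.DataFrame:
    """Counts and percentages per origin class and per location class/subtype."""
    total = len(srnas)
    rows = []

    def block(axis: str, values: Sequence[str], key):
        for v in values:
            k = sum(1 for s in srnas if key(s) == v)
            rows.append({
                "axis": axis, "class": v, "count": k,
                "percent": percent(k, total) if total else 0.0,
            })

    block("origin", ("ts", "ps"), lambda s: s.origin_class)
    block("location", annotate.LOCATION_CLASSES, lambda s: s.location_class)
    subtypes = sorted({s.location_subtype for s in srnas} - {"none"})
    block("subtype", subtypes, lambda s: s.location_subtype)
    df = pd.DataFrame(rows, columns=["axis", "class", "count", "percent"])
    for axis in ("origin", "location"):
        sub = df[df.axis == axis]
        assert sub["count"].sum() == total, "class counts must partition the total"
    return df


@dataclass
class PipelineConfig:
    simdata: simulate.SyntheticConfig = field(default_factory=simulate.SyntheticConfig)
    site_params: sites.SiteCallingParams = field(default_factory=sites.SiteCallingParams)
    transcript_params: sites.TranscriptParams = field(default_factory=sites.TranscriptParams)
    detection_params: annotate.DetectionParams = field(default_factory=annotate.DetectionParams)
    location_params: annotate.LocationParams = field(default_factory=annotate.LocationParams)
    target_params: expression.TargetParams = field(default_factory=expression.TargetParams)
    fold_backend: str = "basepair_proxy"
    top_n: int = 50
    seed: int = 0
    outdir: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(_dataclass_to_dict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return _dataclass_from_dict(cls, data)


def _dataclass_to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _dataclass_to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_dataclass_to_dict(v) for v in obj]
    if isinstance(obj, Mapping):
        return {k: _dataclass_to_dict(v) for k, v in obj.items()}
    return obj


def _dataclass_from_dict(cls, data):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type if isinstance(f.type, type) else None) and isinstance(value, Mapping):
            value = _dataclass_from_dict(f.type, value)
        else:
            hint = f.default_factory() if f.default_factory is not dataclasses.MISSING else None
            if dataclasses.is_dataclass(hint) and isinstance(value, Mapping):
                value = _dataclass_from_dict(type(hint), value)
            elif isinstance(hint, tuple) and isinstance(value, list):
                value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class PipelineResult:
    genome: GenomeRecord
    annotations: list
    site_calls: list[sites.SiteCall]
    transcripts_by_condition: dict[str, list[sites.TranscriptInterval]]
    srnas: list[annotate.SRnaCandidate]
    feature_table: pd.DataFrame
    expression_table: pd.DataFrame
    de_table: pd.DataFrame
    class_summary: pd.DataFrame
    recovery: dict | None = None


def _group_tracks(tracks: Sequence[CoverageTrack]):
    """Average replicates into one track per (library, condition, strand)."""
    groups: dict[tuple[str, str, str], list[CoverageTrack]] = {}
    for t in tracks:
        groups.setdefault((t.library, t.condition, t.strand), []).append(t)
    return {key: average_replicates(ts) for key, ts in groups.items()}


def run_pipeline(
    config: PipelineConfig | None = None,
    dataset: simulate.SyntheticDataset | None = None,
    genome: GenomeRecord | None = None,
    annotations=None,
    tracks: Sequence[CoverageTrack] | None = None,
) -> PipelineResult:
    """Run every stage on a synthetic dataset or user-provided inputs."""
    config = config or PipelineConfig()
    truth = None
    if dataset is None and tracks is None:
        cfg = dataclasses.replace(config.simdata, seed=config.seed)
        dataset = simulate.generate_dataset(cfg)
    if dataset is not None:
        genome, annotations, tracks = dataset.genome, dataset.annotations, dataset.tracks
        truth = dataset.truth
    if genome is None or annotations is None or tracks is None:
        raise ValueError("either a dataset or genome+annotations+tracks are required")

    averaged = _group_tracks(tracks)
    conditions = sorted({t.condition for t in tracks})
    for cond in conditions:
        for strand in ("+", "-"):
            for lib in ("TEXplus", "TEXminus", "SS"):
                if (lib, cond, strand) not in averaged:
                    raise ValueError(f"missing {lib} track for condition {cond!r} strand {strand}")

    logger.info("calling sites on %d conditions", len(conditions))
    per_condition_calls = []
    for cond in conditions:
        for strand in ("+", "-"):
            per_condition_calls.append(
                sites.call_sites(
                    averaged[("TEXplus", cond, strand)],
                    averaged[("TEXminus", cond, strand)],
                    config.site_params,
                )
            )
    site_calls = sites.merge_condition_sites(per_condition_calls)
    logger.info("stage=site_calling n_sites=%d", len(site_calls))

    transcripts_by_condition = {
        cond: [
            t
            for strand in ("+", "-")
            for t in sites.detect_transcripts(
                averaged[("SS", cond, strand)], config.transcript_params
            )
        ]
        for cond in conditions
    }
    ss_by_condition = {
        cond: [averaged[("SS", cond, "+")], averaged[("SS", cond, "-")]]
        for cond in conditions
    }
    drna_tracks = [v for (lib, _, _), v in averaged.items() if lib != "SS"]

    srnas = annotate.detect_srnas(
        transcripts_by_condition, site_calls, ss_by_condition, drna_tracks,
        genome=genome, params=config.detection_params,
    )
    all_transcripts = [t for ts in transcripts_by_condition.values() for t in ts]
    for cand in srnas:
        cand.origin_class = annotate.classify_origin(cand)
        annotate.classify_location(cand, annotations, all_transcripts,
                                   config.location_params)
    logger.info("stage=srna_annotation n_candidates=%d", len(srnas))

    feats = features.feature_table(
        {c.id: c.sequence for c in srnas}, backend=config.fold_backend
    ) if srnas else pd.DataFrame(columns=["srna_id", "length", "gc", "mfe", "nmfe"])

    # expression: per-replicate interval quantification from the SS tracks
    by_rep: dict[tuple[str, int, str], CoverageTrack] = {
        (t.condition, t.replicate, t.strand): t
        for t in tracks if t.library == "SS"
    }
    # numerator condition for fold changes: the generator's declared order
    # (treatment first) when known, else alphabetical
    cond_order = list(truth.config.conditions) if truth else conditions
    cond_rank = {c: i for i, c in enumerate(cond_order)}
    sample_keys = sorted({(c, r) for (c, r, _) in by_rep},
                         key=lambda x: (cond_rank.get(x[0], len(cond_rank)), x[1]))
    counts = pd.DataFrame(
        {
            f"{cond}_rep{rep}": [
                float(by_rep[(cond, rep, s.strand)].values[s.start - 1 : s.end].sum())
                for s in srnas
            ]
            for cond, rep in sample_keys
        },
        index=[s.id for s in srnas],
    )
    labels = [cond for cond, _ in sample_keys]
    if len(srnas) >= 2 and len(conditions) == 2:
        de = expression.differential_expression(counts, labels)
        tpm = expression.tpm_table(counts, pd.Series({s.id: s.length for s in srnas}))
    else:
        de = pd.DataFrame(columns=["log2fc", "pvalue", "padj", "status"])
        tpm = counts
    class_summary = summarize_classes(srnas)

    recovery = _recovery_report(truth, site_calls, srnas) if truth else None
    result = PipelineResult(
        genome=genome, annotations=list(annotations), site_calls=site_calls,
        transcripts_by_condition=transcripts_by_condition, srnas=srnas,
        feature_table=feats, expression_table=tpm, de_table=de,
        class_summary=class_summary, recovery=recovery,
    )
    if config.outdir:
        write_outputs(result, config)
    return result


def _recovery_report(
    truth: simulate.SyntheticTruth,
    site_calls: Sequence[sites.SiteCall],
    srnas: Sequence[annotate.SRnaCandidate],
) -> dict:
    """Planted-truth recovery: site recall/precision, sRNA recall, class accuracy."""
    planted = truth.sites_by_key()
    called = {(s.position, s.strand): s for s in site_calls}
    site_hits = sum(
        1 for key, site in planted.items()
        if key in called and called[key].kind == site.kind
    )
    site_recall = site_hits / len(planted) if planted else float("nan")
    site_precision = (
        sum(1 for key, c in called.items()
            if key in planted and planted[key].kind == c.kind) / len(called)
        if called else float("nan")
    )

    planted_srnas = truth.srnas_by_five_prime()
    recovered = {}
    for cand in srnas:
        key = (cand.five_prime, cand.strand)
        if key in planted_srnas:
            recovered[key] = cand
    srna_recall = len(recovered) / len(planted_srnas) if planted_srnas else float("nan")
    origin_ok = sum(
        1 for key, cand in recovered.items()
        if cand.origin_class == planted_srnas[key].origin_class
    )
    location_ok = sum(
        1 for key, cand in recovered.items()
        if (cand.location_class, cand.location_subtype)
        == (planted_srnas[key].location_class, planted_srnas[key].location_subtype)
    )
    n_rec = len(recovered) or 1
    end_errors = [
        abs((cand.end if cand.strand == "+" else cand.start)
            - (planted_srnas[key].end if cand.strand == "+" else planted_srnas[key].start))
        for key, cand in recovered.items()
    ]
    return {
        "site_recall": site_recall,
        "site_precision": site_precision,
        "srna_recall": srna_recall,
        "n_planted_sites": len(planted),
        "n_called_sites": len(called),
        "n_planted_srnas": len(planted_srnas),
        "n_recovered_srnas": len(recovered),
        "origin_accuracy": origin_ok / n_rec,
        "location_accuracy": location_ok / n_rec,
        "three_prime_within_5nt": (
            sum(1 for e in end_errors if e <= 5) / n_rec if end_errors else float("nan")
        ),
    }


def write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.yaml").write_text(config.to_yaml())

    write_tsv(
        pd.DataFrame([
            {"position": s.position, "strand": s.strand, "kind": s.kind,
             "height": s.height, "enrichment": s.enrichment,
             "conditions": ",".join(s.conditions)}
            for s in result.site_calls
        ]),
        outdir / "sites.tsv",
        "TSS/PSS calls: position strand kind height enrichment conditions",
    )
    from .io import GeneAnnotation
    write_gff3(
        [GeneAnnotation(gene_id=f"site_{s.position}{'' if s.strand == '+' else 'm'}",
                        feature_type="other", start=s.position, end=s.position,
                        strand=s.strand, product=s.kind)
         for s in result.site_calls],
        outdir / "sites.gff3", seqid=result.genome.id,
    )
    write_tsv(
        pd.DataFrame([
            {"srna_id": c.id, "start": c.start, "end": c.end, "strand": c.strand,
             "origin_class": c.origin_class, "location_class": c.location_class,
             "location_subtype": c.location_subtype,
             "end_evidence": c.end_evidence,
             "overlapping_genes": ",".join(c.overlapping_gene_ids),
             **{f"abundance_{k}": v for k, v in sorted(c.abundance.items())}}
            for c in result.srnas
        ]),
        outdir / "srnas.tsv",
        "sRNA candidates with origin/location classes and abundances",
    )
    write_fasta(
        [GenomeRecord(id=c.id, sequence=c.sequence.replace("U", "T"))
         for c in result.srnas],
        outdir / "srnas.fa",
    )
    write_tsv(result.feature_table, outdir / "features.tsv",
              "per-sRNA length, GC fraction, folding score, NMFE")
    write_tsv(result.de_table.reset_index(names="srna_id"), outdir / "expression_de.tsv",
              "differential expression: log2fc, Welch p, BH padj, status")
    write_tsv(result.class_summary, outdir / "class_summary.tsv",
              "class counts and percentages per axis")
    if result.recovery:
        write_tsv(pd.DataFrame([result.recovery]), outdir / "recovery.tsv",
                  "planted-truth recovery metrics")
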