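"""End-to-end orchestration of the analysis stages.

Each ``run_*`` function consumes a :class:`PipelineConfig`, executes one
stage (simulate | shared | motifs | switch) and writes its artifacts under
the configured output directory.  One structured log line per stage records
the event funnel (input -> FDR-filtered -> shared -> concordant) so the
analysis can be reconstructed from the log alone.  Identical config + seed
produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import simulate as sim
from .errors import ConfigError
from .events import EVENT_TYPES, SpliceEvent, event_key
from .io import (
    GeneAnnotation,
    GenomeSequence,
    read_de_table,
    read_fasta,
    read_gtf,
    read_isoform_table,
    read_rmats_table,
    write_fasta,
    write_gtf,
    write_rmats_table,
)
from .motifs import MotifResult, motif_pipeline
from .shared import (
    ConcordanceSummary,
    collapse_duplicate_keys,
    concordance_summary,
    filter_events,
    match_shared_events,
    top_genes_by_event_count,
    venn_counts,
)
from .switch import de_filter, dif_expression_correlation, isoform_fractions

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    ``contrast_tables`` maps contrast label -> event type -> table path.
    All thresholds are strict inequalities, mirroring the upstream callers'
    conventions."""

    out_dir: str = "run"
    seed: int = 0
    contrast_tables: dict[str, dict[str, str]] = field(default_factory=dict)
    genome_fasta: Optional[str] = None
    annotation_gtf: Optional[str] = None
    de_table: Optional[str] = None
    isoform_table: Optional[str] = None
    event_fdr: float = 0.05
    junction_fdr: float = 0.1
    de_q: float = 0.05
    de_lfc: float = 0.6
    flank: int = 25
    pseudocount: float = 0.5
    simulate: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_thresholds(self) -> None:
        for name in ("event_fdr", "junction_fdr", "de_q"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name} {v} outside (0, 1]")
        if self.de_lfc < 0:
            raise ConfigError("de_lfc must be non-negative")
        if self.flank < 1:
            raise ConfigError("flank must be >= 1")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be non-negative")


def _json_dump(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_contrast_events(
    config: PipelineConfig, label: str
) -> list[SpliceEvent]:
    events: list[SpliceEvent] = []
    for etype, path in config.contrast_tables[label].items():
        if not Path(path).exists():
            raise ConfigError(f"input table missing: {path}")
        events.extend(read_rmats_table(path, etype, label))
    return events


# ---------------------------------------------------------------------------
# simulate


def run_simulate(config: PipelineConfig) -> dict:
    """Generate the full fixture set and a manifest under out_dir/fixtures."""
    out = Path(config.out_dir) / "fixtures"
    out.mkdir(parents=True, exist_ok=True)
    params = dict(config.simulate)
    labels = params.pop("contrasts", ["kd1_vs_ctrl", "kd2_vs_ctrl"])
    params.setdefault("seed", config.seed)
    params.setdefault("n_contrasts", len(labels))
    syn = sim.SyntheticConfig(**params)

    genome, annotation = sim.generate_genome_annotation(syn)
    tables, truth = sim.generate_event_tables(syn, genome, annotation, labels)
    de_records, iso_df, expr_truth = sim.generate_expression_tables(syn, annotation)

    files: dict[str, str] = {}
    fasta = out / "genome.fa"
    gtf = out / "annotation.gtf"
    write_fasta(genome, fasta)
    write_gtf(annotation, gtf)
    files["genome_fasta"] = str(fasta)
    files["annotation_gtf"] = str(gtf)

    contrast_tables: dict[str, dict[str, str]] = {}
    for label in labels:
        contrast_tables[label] = {}
        for etype in EVENT_TYPES:
            path = out / f"{label}.{etype}.MATS.JC.txt"
            write_rmats_table(tables[label][etype], path, etype)
            contrast_tables[label][etype] = str(path)

    de_path = out / "de.tsv"
    with open(de_path, "w") as fh:
        fh.write("gene_id\tlog2FC\tqvalue\n")
        for r in de_records:
            fh.write(f"{r.gene_id}\t{r.log2fc}\t{r.qvalue}\n")
    iso_path = out / "isoforms.tsv"
    iso_df.to_csv(iso_path, sep="\t", index=False)
    files["de_table"] = str(de_path)
    files["isoform_table"] = str(iso_path)

    truth_obj = {
        "n_shared_planted": truth.n_shared_planted,
        "planted_correlation": truth.planted_correlation,
        "concordance_rate": truth.concordance_rate,
        "n_concordant_planted": int(sum(truth.concordance_flags)),
        "five_ss_consensus": truth.five_ss_consensus,
        "three_ss_consensus": truth.three_ss_consensus,
        "n_de_pass_planted": int(sum(expr_truth.passes_de_filter.values())),
    }
    truth_path = out / "truth.json"
    _json_dump(truth_obj, truth_path)
    files["truth"] = str(truth_path)

    manifest = {
        "seed": syn.seed,
        "contrasts": list(labels),
        "files": files,
        "contrast_tables": contrast_tables,
    }
    _json_dump(manifest, out / "manifest.json")
    logger.info(
        "simulate: %d contrasts, %d shared events planted, files under %s",
        len(labels), truth.n_shared_planted, out,
    )
    return manifest


def config_from_manifest(manifest: dict, base: PipelineConfig) -> PipelineConfig:
    """Point a config's input paths at a simulated fixture set."""
    cfg = dataclasses.replace(base)
    cfg.contrast_tables = manifest["contrast_tables"]
    cfg.genome_fasta = manifest["files"]["genome_fasta"]
    cfg.annotation_gtf = manifest["files"]["annotation_gtf"]
    cfg.de_table = manifest["files"]["de_table"]
    cfg.isoform_table = manifest["files"]["isoform_table"]
    return cfg


# ---------------------------------------------------------------------------
# shared events


def run_shared(config: PipelineConfig) -> ConcordanceSummary:
    """Filter -> match -> concordance -> correlation -> Venn -> top genes."""
    config.validate_thresholds()
    labels = list(config.contrast_tables)
    if len(labels) < 2:
        raise ConfigError("shared-event analysis needs at least 2 contrasts")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    per_contrast: dict[str, list[SpliceEvent]] = {}
    for label in labels:
        raw = _load_contrast_events(config, label)
        kept = collapse_duplicate_keys(filter_events(raw, config.event_fdr))
        logger.info(
            "shared[%s]: %d events read, %d at FDR < %g after key collapsing",
            label, len(raw), len(kept), config.event_fdr,
        )
        per_contrast[label] = kept

    label_a, label_b = labels[0], labels[1]
    pairs = match_shared_events(per_contrast[label_a], per_contrast[label_b])
    summary = concordance_summary(pairs)
    logger.info(
        "shared: %d shared events (%d genes), %d concordant (%.1f%%), R=%s",
        summary.n_shared_events, summary.n_genes, summary.n_concordant,
        summary.concordance_percent or 0.0,
        "NA" if summary.pearson_r is None else f"{summary.pearson_r:.3f}",
    )

    with open(out / "shared_events.tsv", "w") as fh:
        fh.write(
            "event_type\tcontig\tstrand\tgene_id\tgene_symbol\t"
            "delta_psi_a\tdelta_psi_b\tconcordant\n"
        )
        for p in pairs:
            fh.write(
                f"{p.key.event_type}\t{p.key.contig}\t{p.key.strand}\t"
                f"{p.event_a.gene_id}\t{p.event_a.gene_symbol}\t"
                f"{p.event_a.delta_psi}\t{p.event_b.delta_psi}\t"
                f"{int(p.concordant)}\n"
            )

    event_sets = {
        label: {str(event_key(ev)) for ev in evs}
        for label, evs in per_contrast.items()
    }
    gene_sets = {
        label: {ev.gene_id for ev in evs} for label, evs in per_contrast.items()
    }
    with open(out / "venn.tsv", "w") as fh:
        fh.write("kind\tregion\tcount\n")
        for kind, sets in (("events", event_sets), ("genes", gene_sets)):
            for region, count in sorted(
                venn_counts(sets).items(), key=lambda kv: sorted(kv[0])
            ):
                fh.write(f"{kind}\t{'&'.join(sorted(region))}\t{count}\n")

    top = top_genes_by_event_count(pairs, 10)
    report = {
        "contrast_a": label_a,
        "contrast_b": label_b,
        "event_fdr_threshold": config.event_fdr,
        "n_shared_events": summary.n_shared_events,
        "n_concordant": summary.n_concordant,
        "concordance_fraction": summary.concordance_fraction,
        "concordance_percent": summary.concordance_percent,
        "n_genes": summary.n_genes,
        "per_type_counts": summary.per_type_counts,
        "pearson_r": summary.pearson_r,
        "correlation_p": summary.correlation_p,
        "top_genes": [{"gene_symbol": g, "n_events": c} for g, c in top],
    }
    _json_dump(report, out / "summary.json")
    return summary


# ---------------------------------------------------------------------------
# motifs


def _write_matrix_tsv(pwm, path: Path, attr: str) -> None:
    mat = getattr(pwm, attr)
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\n")
        for i, row in enumerate(mat):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def _write_meme(pwms: dict[str, "object"], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for name, pwm in pwms.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm.probs)} "
                f"nsites= {pwm.n_sequences} E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def run_motifs(config: PipelineConfig) -> MotifResult:
    """Junction-window extraction and PWM construction over all contrasts."""
    config.validate_thresholds()
    if config.genome_fasta is None:
        raise ConfigError("motif analysis requires genome_fasta")
    genome = read_fasta(config.genome_fasta)
    events: list[SpliceEvent] = []
    for label in config.contrast_tables:
        events.extend(_load_contrast_events(config, label))
    for ev in events:
        if ev.contig not in genome.contigs:
            raise ConfigError(f"contig {ev.contig!r} absent from genome")

    result = motif_pipeline(
        events,
        genome,
        fdr_threshold=config.junction_fdr,
        flank=config.flank,
        pseudocount=config.pseudocount,
    )
    out = Path(config.out_dir) / "motifs"
    out.mkdir(parents=True, exist_ok=True)

    with open(Path(config.out_dir) / "windows.fa", "w") as fh:
        for side, windows in result.windows.items():
            for w in windows:
                fh.write(
                    f">{w.source_event_id}|{w.side}|{w.strand}|{w.cut_point}\n"
                    f"{w.sequence}\n"
                )
    for side, pwm in result.pooled.items():
        _write_matrix_tsv(pwm, out / f"{side}.ppm.tsv", "probs")
        _write_matrix_tsv(pwm, out / f"{side}.pwm.tsv", "log_odds")
        with open(out / f"{side}.consensus.tsv", "w") as fh:
            fh.write("position\tconsensus\tinfo_bits\n")
            for i, (b, ic) in enumerate(zip(pwm.consensus, pwm.info_content)):
                fh.write(f"{i}\t{b}\t{ic:.6f}\n")
    with open(out / "composition.tsv", "w") as fh:
        fh.write("side\tn_sequences\texonic_gc\tintronic_ct\n")
        for side, prof in result.composition.items():
            fh.write(
                f"{side}\t{prof.n_sequences}\t{prof.exonic_gc:.6f}\t"
                f"{prof.intronic_ct:.6f}\n"
            )
    _write_meme(
        {f"{etype}_{side}": pwm for (etype, side), pwm in result.per_group.items()}
        | {f"pooled_{side}": pwm for side, pwm in result.pooled.items()},
        out / "motifs.meme",
    )
    logger.info(
        "motifs: %d 5'ss + %d 3'ss windows, %d skipped (out of bounds)",
        len(result.windows["5ss"]), len(result.windows["3ss"]), result.n_skipped,
    )
    return result


# ---------------------------------------------------------------------------
# isoform switch


def run_switch(config: PipelineConfig) -> dict:
    """dIF computation and the dIF-vs-log2FC correlation report."""
    config.validate_thresholds()
    if config.de_table is None or config.isoform_table is None:
        raise ConfigError("switch analysis requires de_table and isoform_table")
    for path in (config.de_table, config.isoform_table):
        if not Path(path).exists():
            raise ConfigError(f"input table missing: {path}")
    de = de_filter(
        read_de_table(config.de_table), q_threshold=config.de_q,
        lfc_threshold=config.de_lfc,
    )
    isoforms = isoform_fractions(read_isoform_table(config.isoform_table))
    r, p, n = dif_expression_correlation(isoforms, de)

    sig_genes = {rec.gene_id for rec in de if rec.significant}
    report = {
        "pearson_r": r,
        "correlation_p": p,
        "n_joined": n,
        "n_de_significant": len(sig_genes),
        "de_q_threshold": config.de_q,
        "de_lfc_threshold": config.de_lfc,
    }
    try:
        sig_iso = [i for i in isoforms if i.gene_id in sig_genes]
        r_sig, p_sig, n_sig = dif_expression_correlation(sig_iso, de)
        report.update(
            {"pearson_r_significant": r_sig, "correlation_p_significant": p_sig,
             "n_joined_significant": n_sig}
        )
    except ValueError:
        pass

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "dif.tsv", "w") as fh:
        fh.write("isoform_id\tgene_id\tif_ctrl\tif_kd\tdif\n")
        for iso in isoforms:
            def fmt(v):
                return "NA" if v is None else f"{v:.6f}"
            fh.write(
                f"{iso.isoform_id}\t{iso.gene_id}\t{fmt(iso.if_ctrl)}\t"
                f"{fmt(iso.if_kd)}\t{fmt(iso.dif)}\n"
            )
    _json_dump(report, out / "switch_correlation.json")
    logger.info(
        "switch: %d isoforms joined, R=%.4f (p=%.3g), %d DE-significant genes",
        n, r, p, len(sig_genes),
    )
    return report


def run_all(config: PipelineConfig) -> dict:
    """simulate -> shared -> motifs -> switch on the simulated fixtures."""
    manifest = run_simulate(config)
    cfg = config_from_manifest(manifest, config)
    summary = run_shared(cfg)
    run_motifs(cfg)
    switch_report = run_switch(cfg)
    return {
        "manifest": manifest,
        "n_shared_events": summary.n_shared_events,
        "concordance_percent": summary.concordance_percent,
        "pearson_r": summary.pearson_r,
        "switch": switch_report,
    }
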