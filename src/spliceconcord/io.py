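"""Readers and writers for the external formats the pipeline touches.

Tables use the rMATS v4 junction-count dialect (one TSV per event type with
``*_0base`` start columns); sequence data use FASTA and GTF.  All coordinate
conversion happens here: the rMATS ``*_0base`` starts are kept as-is and the
1-based inclusive end columns are identical to 0-based exclusive ends, so no
arithmetic is needed; GTF starts are decremented by one.  Everything past
this module speaks 0-based half-open intervals only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, RowError
from .events import Interval, SpliceEvent

# ---------------------------------------------------------------------------
# sequence containers


@dataclass
class GenomeSequence:
    """In-memory genome: contig name -> uppercase nucleotide string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if len(seq) == 0:
                raise ValueError(f"contig {name!r} is empty")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Substring [start, end) of a contig; bounds are checked."""
        if contig not in self.contigs:
            raise KeyError(f"contig {contig!r} not in genome")
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"fetch [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]


@dataclass
class Gene:
    gene_id: str
    symbol: str
    contig: str
    strand: str
    exons: list[Interval] = field(default_factory=list)


@dataclass
class GeneAnnotation:
    """Gene models: gene_id -> (symbol, contig, strand, sorted exon list)."""

    genes: dict[str, Gene]

    def symbol_of(self, gene_id: str) -> str:
        return self.genes[gene_id].symbol


# ---------------------------------------------------------------------------
# rMATS dialect

_COMMON_PRE = ["ID", "GeneID", "geneSymbol", "chr", "strand"]
_COMMON_POST = [
    "IJC_SAMPLE_1",
    "SJC_SAMPLE_1",
    "IJC_SAMPLE_2",
    "SJC_SAMPLE_2",
    "IncFormLen",
    "SkipFormLen",
    "PValue",
    "FDR",
    "IncLevel1",
    "IncLevel2",
    "IncLevelDifference",
]

#: type-specific coordinate columns, in file order
TYPE_COORD_COLUMNS: dict[str, list[str]] = {
    "SE": [
        "exonStart_0base", "exonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ],
    "RI": [
        "riExonStart_0base", "riExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ],
    "MXE": [
        "1stExonStart_0base", "1stExonEnd",
        "2ndExonStart_0base", "2ndExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ],
    "A3SS": [
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ],
    "A5SS": [
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ],
}


def rmats_columns(event_type: str) -> list[str]:
    if event_type not in TYPE_COORD_COLUMNS:
        raise ValueError(f"unknown event type {event_type!r}")
    return _COMMON_PRE + TYPE_COORD_COLUMNS[event_type] + _COMMON_POST


def _parse_psi_list(text: str, row_index: int) -> tuple[Optional[float], ...]:
    out: list[Optional[float]] = []
    for tok in str(text).split(","):
        tok = tok.strip()
        if tok in ("NA", "", "nan"):
            out.append(None)
            continue
        try:
            v = float(tok)
        except ValueError:
            raise RowError(f"non-numeric PSI value {tok!r}", row_index) from None
        if not (0.0 <= v <= 1.0):
            raise RowError(f"PSI value {v} outside [0, 1]", row_index)
        out.append(v)
    return tuple(out)


def _parse_count_list(text: str, row_index: int) -> tuple[int, ...]:
    out = []
    for tok in str(text).split(","):
        tok = tok.strip()
        try:
            v = int(tok)
        except ValueError:
            raise RowError(f"non-integer count {tok!r}", row_index) from None
        if v < 0:
            raise RowError(f"negative junction count {v}", row_index)
        out.append(v)
    return tuple(out)


def _parse_float(text, name: str, row_index: int) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise RowError(f"non-numeric {name} value {text!r}", row_index) from None


def _parse_int(text, name: str, row_index: int) -> int:
    try:
        return int(text)
    except (TypeError, ValueError):
        raise RowError(f"non-integer {name} value {text!r}", row_index) from None


def _coords_from_row(event_type: str, strand: str, get) -> dict[str, Interval]:
    """Map the dialect's coordinate columns onto named internal intervals."""
    if event_type == "SE":
        return {
            "target": (get("exonStart_0base"), get("exonEnd")),
            "upstream": (get("upstreamES"), get("upstreamEE")),
            "downstream": (get("downstreamES"), get("downstreamEE")),
        }
    if event_type == "RI":
        up = (get("upstreamES"), get("upstreamEE"))
        down = (get("downstreamES"), get("downstreamEE"))
        # retained intron spans the gap between the flanking exons; on the
        # minus strand the transcript-upstream exon is genomically rightmost
        intron = (up[1], down[0]) if strand == "+" else (down[1], up[0])
        return {"upstream": up, "downstream": down, "intron": intron}
    if event_type == "MXE":
        return {
            "exon1": (get("1stExonStart_0base"), get("1stExonEnd")),
            "exon2": (get("2ndExonStart_0base"), get("2ndExonEnd")),
            "upstream": (get("upstreamES"), get("upstreamEE")),
            "downstream": (get("downstreamES"), get("downstreamEE")),
        }
    # A3SS / A5SS
    return {
        "long": (get("longExonStart_0base"), get("longExonEnd")),
        "short": (get("shortES"), get("shortEE")),
        "flanking": (get("flankingES"), get("flankingEE")),
    }


def read_rmats_table(
    path: str | Path, event_type: str, contrast_label: str
) -> list[SpliceEvent]:
    """Read one per-type differential-splicing TSV into SpliceEvent records.

    ``contrast_label`` identifies the knockdown-vs-control comparison the
    file belongs to; it is carried on every record and never inferred from
    the filename.
    """
    required = rmats_columns(event_type)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing required column {col!r} for {event_type}"
            )
    events: list[SpliceEvent] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        strand = rec["strand"]
        if strand not in ("+", "-"):
            raise RowError(f"unknown strand symbol {strand!r}", i)

        def geti(col: str, _rec=rec, _i=i) -> int:
            return _parse_int(_rec[col], col, _i)

        coords = _coords_from_row(event_type, strand, geti)
        delta_text = rec["IncLevelDifference"]
        delta = (
            None
            if delta_text in ("NA", "")
            else _parse_float(delta_text, "IncLevelDifference", i)
        )
        try:
            ev = SpliceEvent(
                event_id=str(rec["ID"]),
                event_type=event_type,
                gene_id=rec["GeneID"],
                gene_symbol=rec["geneSymbol"],
                contig=rec["chr"],
                strand=strand,
                coords=coords,
                psi_group1=_parse_psi_list(rec["IncLevel1"], i),
                psi_group2=_parse_psi_list(rec["IncLevel2"], i),
                delta_psi=delta,
                pvalue=_parse_float(rec["PValue"], "PValue", i),
                fdr=_parse_float(rec["FDR"], "FDR", i),
                ijc_group1=_parse_count_list(rec["IJC_SAMPLE_1"], i),
                sjc_group1=_parse_count_list(rec["SJC_SAMPLE_1"], i),
                ijc_group2=_parse_count_list(rec["IJC_SAMPLE_2"], i),
                sjc_group2=_parse_count_list(rec["SJC_SAMPLE_2"], i),
                inc_len=geti("IncFormLen"),
                skip_len=geti("SkipFormLen"),
                contrast_label=contrast_label,
            )
        except ValueError as exc:
            raise RowError(str(exc), i) from None
        events.append(ev)
    return events


def _coord_row_values(event: SpliceEvent) -> list[int]:
    c = event.coords
    t = event.event_type
    if t == "SE":
        ivals = [c["target"], c["upstream"], c["downstream"]]
    elif t == "RI":
        # riExon spans the whole retained region across both flanking exons
        lo = min(c["upstream"][0], c["downstream"][0])
        hi = max(c["upstream"][1], c["downstream"][1])
        ivals = [(lo, hi), c["upstream"], c["downstream"]]
    elif t == "MXE":
        ivals = [c["exon1"], c["exon2"], c["upstream"], c["downstream"]]
    else:
        ivals = [c["long"], c["short"], c["flanking"]]
    return [x for iv in ivals for x in iv]


def _format_psi_list(values: Sequence[Optional[float]]) -> str:
    return ",".join("NA" if v is None else repr(round(v, 10)) for v in values)


def write_rmats_table(
    events: Sequence[SpliceEvent], path: str | Path, event_type: str
) -> None:
    """Write events of one type back to the rMATS dialect (round-trip safe)."""
    cols = rmats_columns(event_type)
    rows = []
    for ev in events:
        if ev.event_type != event_type:
            raise ValueError(
                f"event {ev.event_id!r} has type {ev.event_type}, "
                f"expected {event_type}"
            )
        row = [ev.event_id, ev.gene_id, ev.gene_symbol, ev.contig, ev.strand]
        row += _coord_row_values(ev)
        row += [
            ",".join(map(str, ev.ijc_group1)),
            ",".join(map(str, ev.sjc_group1)),
            ",".join(map(str, ev.ijc_group2)),
            ",".join(map(str, ev.sjc_group2)),
            ev.inc_len,
            ev.skip_len,
            repr(ev.pvalue),
            repr(ev.fdr),
            _format_psi_list(ev.psi_group1),
            _format_psi_list(ev.psi_group2),
            "NA" if ev.delta_psi is None else repr(ev.delta_psi),
        ]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file; contig names must be unique, sequence upper-cased."""
    try:
        records = SeqIO.to_dict(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # SeqIO.to_dict raises on duplicate ids
        raise FormatError(f"{path}: {exc}") from None
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSequence(
        {name: str(rec.seq).upper() for name, rec in records.items()}
    )


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path) -> GeneAnnotation:
    """Read exon features from a GTF into per-gene sorted interval lists.

    Only ``exon`` features are used.  1-based inclusive coordinates become
    0-based half-open.  ``gene_name`` falls back to ``gene_id`` when absent.
    """
    genes: dict[str, Gene] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise RowError(
                    f"expected 9 tab-separated columns, got {len(fields)}", i
                )
            contig, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            start = _parse_int(start_s, "start", i)
            end = _parse_int(end_s, "end", i)
            if start > end:
                raise RowError(f"start {start} > end {end}", i)
            if strand not in ("+", "-"):
                raise RowError(f"unknown strand symbol {strand!r}", i)
            attr_map = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr_map:
                raise RowError(
                    f"malformed attribute field (no gene_id): {attrs!r}", i
                )
            gid = attr_map["gene_id"]
            symbol = attr_map.get("gene_name", gid)
            gene = genes.setdefault(gid, Gene(gid, symbol, contig, strand))
            gene.exons.append((start - 1, end))
    for gene in genes.values():
        gene.exons.sort()
    return GeneAnnotation(genes)


def write_gtf(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write exon features, one transcript per gene, 1-based inclusive."""
    with open(path, "w") as fh:
        for gene in annotation.genes.values():
            for start, end in gene.exons:
                attrs = (
                    f'gene_id "{gene.gene_id}"; '
                    f'transcript_id "{gene.gene_id}.1"; '
                    f'gene_name "{gene.symbol}";'
                )
                fh.write(
                    f"{gene.contig}\tsynthetic\texon\t{start + 1}\t{end}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# expression tables


def read_de_table(path: str | Path):
    """Read a differential-expression TSV (gene_id, log2FC, qvalue)."""
    from .switch import DERecord

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_id", "log2FC", "qvalue"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        lfc = _parse_float(rec["log2FC"], "log2FC", i)
        q = _parse_float(rec["qvalue"], "qvalue", i)
        if not (0.0 <= q <= 1.0):
            raise RowError(f"qvalue {q} outside [0, 1]", i)
        records.append(DERecord(gene_id=rec["gene_id"], log2fc=lfc, qvalue=q))
    return records


def read_isoform_table(path: str | Path) -> pd.DataFrame:
    """Read an isoform expression TSV (isoform_id, gene_id, one col/sample)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("isoform_id", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("isoform_id", "gene_id")]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    if (df[sample_cols] < 0).any().any():
        raise FormatError(f"{path}: negative expression values")
    return df
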