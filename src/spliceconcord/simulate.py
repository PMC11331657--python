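"""Synthetic fixture generator: toy genome, annotation, splicing tables,
expression tables, and a truth record for recovery tests.

The generator emulates the statistical structure of a two-knockdown
comparison: a planted fraction of events carries identical matching keys in
both contrasts; for those shared pairs the two ΔPSI values are drawn from a
bivariate (generally equicorrelated multivariate) normal with a configurable
correlation; an optional per-pair Bernoulli draw forces a configured
direction-concordance rate; and FDRs are drawn so that the strict
significance filters behave unambiguously.  Planted shared events are
significant in both contrasts by construction — they model the shared
members of the two significant sets, which is what the downstream matching
stage counts — while background (contrast-unique) events are significant
with a configurable probability.

The toy genome plants splice-site sequence structure at every exon–intron
boundary: introns open with a donor consensus (default ``GTAAG``), close
with a pyrimidine-rich tract followed by an acceptor consensus (default
``CAG``), and the exonic 25 nt upstream of each donor is G/C-enriched.  For
alternative-site events the same structure is planted at both the long and
short splice sites.  Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .events import EVENT_TYPES, EventKey, Interval, SpliceEvent, compute_psi, event_key
from .io import Gene, GeneAnnotation, GenomeSequence, reverse_complement

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: plausible junction-count effective lengths per event type (bases)
_FORM_LENGTHS = {
    "SE": (198, 99),
    "RI": (297, 99),
    "MXE": (396, 99),
    "A3SS": (198, 99),
    "A5SS": (198, 99),
}


@dataclass(frozen=True)
class FlankMotif:
    """Planted sequence structure on one side of a splice site.

    ``exonic_weights`` are A,C,G,T sampling weights for the exonic flank;
    ``intronic_consensus`` is the fixed intronic string at the cut point;
    ``tract_weights`` (optional) generate the intron-terminal tract that
    precedes a 3'ss consensus."""

    exonic_weights: tuple[float, float, float, float]
    intronic_consensus: str
    tract_weights: Optional[tuple[float, float, float, float]] = None


_DEFAULT_MOTIFS = (
    # G/C-enriched exonic flank, canonical donor consensus
    ("5ss", FlankMotif((0.15, 0.35, 0.35, 0.15), "GTAAG")),
    # uniform exonic flank; C/T-rich polypyrimidine tract ending in CAG
    ("3ss", FlankMotif((0.25, 0.25, 0.25, 0.25), "CAG", (0.08, 0.42, 0.08, 0.42))),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the emulated two-knockdown comparison.

    Defaults mirror the analysed dataset: 819 shared significant events over
    301 genes across two contrasts with two replicates each, an 82.7 %
    direction-concordance rate and a cross-contrast ΔPSI correlation of
    0.89 with ΔPSI spread 0.15."""

    seed: int
    n_events_per_type: int = 250
    shared_fraction: float = 0.655
    n_shared_total: Optional[int] = 819
    concordance_rate: Optional[float] = 0.827
    delta_psi_correlation: float = 0.89
    delta_psi_sd: float = 0.15
    fdr_significant_fraction: float = 0.8
    de_significant_fraction: float = 0.3
    dif_coupling: float = 0.0
    flank_motifs: tuple[tuple[str, FlankMotif], ...] = _DEFAULT_MOTIFS
    n_genes: int = 301
    contig: str = "chrS"
    contig_length: Optional[int] = None
    n_replicates: int = 2
    n_contrasts: int = 2
    isoforms_per_gene: int = 3

    def __post_init__(self) -> None:
        for name in (
            "shared_fraction",
            "fdr_significant_fraction",
            "de_significant_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} {v} outside [0, 1]")
        if self.concordance_rate is not None and not (
            0.0 <= self.concordance_rate <= 1.0
        ):
            raise ConfigError(f"concordance_rate {self.concordance_rate} outside [0, 1]")
        if not (-1.0 <= self.delta_psi_correlation <= 1.0):
            raise ConfigError("delta_psi_correlation outside [-1, 1]")
        if self.delta_psi_sd <= 0:
            raise ConfigError("delta_psi_sd must be positive")
        if self.n_genes < 1 or self.n_events_per_type < 0:
            raise ConfigError("n_genes and n_events_per_type must be positive")
        if self.n_replicates < 1 or self.n_contrasts < 1:
            raise ConfigError("n_replicates and n_contrasts must be >= 1")

    @property
    def motifs(self) -> dict[str, FlankMotif]:
        return dict(self.flank_motifs)


@dataclass
class EventSlot:
    """One planned event locus: its type, sharing status and genome coords."""

    index: int
    event_type: str
    shared: bool
    contrast_index: Optional[int]  # None for shared slots
    gene_id: str = ""
    gene_symbol: str = ""
    strand: str = "+"
    coords: dict[str, Interval] = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    """Planted parameters, for recovery tests against the pipeline output."""

    shared_keys: list[EventKey]
    concordance_flags: list[bool]
    planted_deltas: np.ndarray  # (n_shared, n_contrasts) as emitted (3 dp)
    planted_correlation: float
    concordance_rate: Optional[float]
    n_shared_planted: int
    five_ss_consensus: str
    three_ss_consensus: str


@dataclass
class ExpressionTruth:
    log2fc: dict[str, float]
    qvalue: dict[str, float]
    passes_de_filter: dict[str, bool]
    difs: dict[str, tuple[float, ...]]
    coupling: float


def _shared_counts(config: SyntheticConfig) -> list[int]:
    if config.n_shared_total is not None:
        base, rem = divmod(config.n_shared_total, len(EVENT_TYPES))
        counts = [base + (1 if i < rem else 0) for i in range(len(EVENT_TYPES))]
    else:
        counts = [
            int(round(config.shared_fraction * config.n_events_per_type))
        ] * len(EVENT_TYPES)
    for c in counts:
        if c > config.n_events_per_type:
            raise ConfigError(
                f"shared count {c} exceeds n_events_per_type "
                f"{config.n_events_per_type}"
            )
    return counts


# ---------------------------------------------------------------------------
# sequence building (all in transcript orientation, mapped to genome later)


def _rand_dna(rng: np.random.Generator, n: int, weights=None) -> str:
    if n <= 0:
        return ""
    if weights is None:
        idx = rng.integers(0, 4, n)
    else:
        idx = rng.choice(4, size=n, p=np.asarray(weights) / np.sum(weights))
    return _BASE_BYTES[idx].tobytes().decode()


def _exon_seq(rng, length: int, motifs: dict[str, FlankMotif]) -> str:
    """Exon body; the last <=25 nt (donor-proximal) follow the configured
    exonic composition of the 5'ss motif."""
    tail = min(25, max(0, length - 10))
    body = _rand_dna(rng, length - tail)
    gc = _rand_dna(rng, tail, motifs["5ss"].exonic_weights)
    return body + gc


def _acceptor_tail(rng, length: int, motifs: dict[str, FlankMotif]) -> str:
    """Intron-terminal tract + acceptor consensus, ``length`` bases total."""
    cons = motifs["3ss"].intronic_consensus
    tract_w = motifs["3ss"].tract_weights or (0.08, 0.42, 0.08, 0.42)
    tract_len = max(0, length - len(cons))
    return _rand_dna(rng, tract_len, tract_w) + cons


def _intron_seq(rng, length: int, motifs: dict[str, FlankMotif]) -> str:
    cons5 = motifs["5ss"].intronic_consensus
    tail_len = min(25, length - len(cons5) - 5)
    mid = _rand_dna(rng, length - len(cons5) - tail_len)
    return cons5 + mid + _acceptor_tail(rng, tail_len, motifs)


def _ilen(rng) -> int:
    return int(rng.integers(60, 140))


def _elen(rng) -> int:
    return int(rng.integers(60, 140))


def _block_for_type(rng, etype: str, motifs) -> tuple[str, list[Interval], dict]:
    """Sequence block hosting one event; returns (seq, exon intervals local,
    named event coords local)."""

    def E():
        return _exon_seq(rng, _elen(rng), motifs)

    def I():
        return _intron_seq(rng, _ilen(rng), motifs)

    if etype == "SE":
        parts = [E(), I(), E(), I(), E()]
        segs = _offsets(parts)
        exons = [segs[0], segs[2], segs[4]]
        coords = {"upstream": segs[0], "target": segs[2], "downstream": segs[4]}
    elif etype == "RI":
        parts = [E(), I(), E()]
        segs = _offsets(parts)
        exons = [segs[0], segs[2]]
        coords = {"upstream": segs[0], "downstream": segs[2], "intron": segs[1]}
    elif etype == "MXE":
        parts = [E(), I(), E(), I(), E(), I(), E()]
        segs = _offsets(parts)
        exons = [segs[0], segs[2], segs[4], segs[6]]
        coords = {
            "upstream": segs[0],
            "exon1": segs[2],
            "exon2": segs[4],
            "downstream": segs[6],
        }
    elif etype == "A5SS":
        # long exon = short part + planted internal donor site + extension
        short_part = _exon_seq(rng, int(rng.integers(40, 90)), motifs)
        cons5 = motifs["5ss"].intronic_consensus
        ext = _exon_seq(rng, int(rng.integers(30, 60)), motifs)
        long_exon = short_part + cons5 + ext
        parts = [long_exon, I(), E()]
        segs = _offsets(parts)
        exons = [segs[0], segs[2]]
        coords = {
            "long": segs[0],
            "short": (segs[0][0], segs[0][0] + len(short_part)),
            "flanking": segs[2],
        }
    elif etype == "A3SS":
        # extension between the two acceptors: tract + planted acceptor
        flank_exon = E()
        intron = I()
        ext = _acceptor_tail(rng, int(rng.integers(20, 45)), motifs)
        body = _exon_seq(rng, int(rng.integers(50, 110)), motifs)
        long_exon = ext + body
        parts = [flank_exon, intron, long_exon]
        segs = _offsets(parts)
        exons = [segs[0], segs[2]]
        coords = {
            "long": segs[2],
            "short": (segs[2][0] + len(ext), segs[2][1]),
            "flanking": segs[0],
        }
    else:  # filler gene without an event
        parts = [E(), I(), E()]
        segs = _offsets(parts)
        exons = [segs[0], segs[2]]
        coords = {}
    return "".join(parts), exons, coords


def _offsets(parts: list[str]) -> list[Interval]:
    out, pos = [], 0
    for p in parts:
        out.append((pos, pos + len(p)))
        pos += len(p)
    return out


@dataclass
class _Built:
    genome: GenomeSequence
    annotation: GeneAnnotation
    slots: list[EventSlot]


@lru_cache(maxsize=8)
def _build(config: SyntheticConfig) -> _Built:
    """Deterministically build genome, annotation and event-slot plan."""
    ss = np.random.SeedSequence(config.seed)
    genome_ss, _, _ = ss.spawn(3)
    rng = np.random.default_rng(genome_ss)

    shared = _shared_counts(config)
    slots: list[EventSlot] = []
    idx = 0
    for t, s_count in zip(EVENT_TYPES, shared):
        for _ in range(s_count):
            slots.append(EventSlot(idx, t, True, None))
            idx += 1
        for ci in range(config.n_contrasts):
            for _ in range(config.n_events_per_type - s_count):
                slots.append(EventSlot(idx, t, False, ci))
                idx += 1

    # round-robin slots over genes so genes mix event types
    gene_slots: list[list[EventSlot]] = [[] for _ in range(config.n_genes)]
    for i, slot in enumerate(slots):
        gene_slots[i % config.n_genes].append(slot)

    chunks: list[str] = []
    genes: dict[str, Gene] = {}
    cursor = 0
    motifs = config.motifs
    for g, my_slots in enumerate(gene_slots):
        gid = f"SYNG{g:05d}"
        symbol = f"Sg{g}"
        strand = "+" if rng.random() < 0.5 else "-"
        gap = _rand_dna(rng, int(rng.integers(60, 150)))
        chunks.append(gap)
        cursor += len(gap)

        # assemble the gene in transcript orientation
        parts: list[str] = []
        exons_local: list[Interval] = []
        slot_coords_local: list[dict] = []
        pos = 0
        block_types = [s.event_type for s in my_slots] or ["filler"]
        for bi, btype in enumerate(block_types):
            if bi > 0:
                spacer = _intron_seq(rng, _ilen(rng), motifs)
                parts.append(spacer)
                pos += len(spacer)
            seq, bex, bcoords = _block_for_type(rng, btype, motifs)
            parts.append(seq)
            exons_local.extend((s + pos, e + pos) for s, e in bex)
            slot_coords_local.append(
                {k: (s + pos, e + pos) for k, (s, e) in bcoords.items()}
            )
            pos += len(seq)
        local_seq = "".join(parts)
        L = len(local_seq)

        if strand == "+":
            chunks.append(local_seq)
            def gmap(iv: Interval, _c=cursor) -> Interval:
                return (_c + iv[0], _c + iv[1])
        else:
            chunks.append(reverse_complement(local_seq))
            def gmap(iv: Interval, _c=cursor, _L=L) -> Interval:
                return (_c + _L - iv[1], _c + _L - iv[0])

        genes[gid] = Gene(
            gid, symbol, config.contig, strand,
            sorted(gmap(iv) for iv in exons_local),
        )
        for slot, coords in zip(my_slots, slot_coords_local):
            slot.gene_id = gid
            slot.gene_symbol = symbol
            slot.strand = strand
            slot.coords = {k: gmap(iv) for k, iv in coords.items()}
        cursor += L

    sequence = "".join(chunks)
    if config.contig_length is not None:
        if len(sequence) > config.contig_length:
            raise ConfigError(
                f"genes do not fit on contig: need {len(sequence)} bases, "
                f"contig_length is {config.contig_length}"
            )
        sequence += _rand_dna(rng, config.contig_length - len(sequence))
    genome = GenomeSequence({config.contig: sequence})
    return _Built(genome, GeneAnnotation(genes), slots)


def generate_genome_annotation(
    config: SyntheticConfig,
) -> tuple[GenomeSequence, GeneAnnotation]:
    """Toy genome and annotation with planted splice-site structure."""
    built = _build(config)
    return built.genome, built.annotation


# ---------------------------------------------------------------------------
# event tables


def _replicate_psis(rng, base: float, n: int) -> list[float]:
    """Replicate PSI values with mean exactly ``base`` (pairwise jitter)."""
    out = [base] * n
    for i in range(0, n - 1, 2):
        eps = rng.uniform(0.005, 0.02)
        out[i] += eps
        out[i + 1] -= eps
    return out


def _counts_for_psi(rng, psi: float, inc_len: int, skip_len: int) -> tuple[int, int]:
    depth = int(rng.integers(80, 300))
    kappa = depth / (inc_len + skip_len)
    return (
        int(round(psi * kappa * inc_len)),
        int(round((1 - psi) * kappa * skip_len)),
    )


def _make_event(
    rng,
    slot: EventSlot,
    config: SyntheticConfig,
    event_id: str,
    contrast_label: str,
    delta: float,
    fdr: float,
) -> SpliceEvent:
    inc_len, skip_len = _FORM_LENGTHS[slot.event_type]
    d = round(float(delta), 3)
    lo = max(0.05, d + 0.05)
    hi = min(0.95, 1 + d - 0.05)
    p1 = rng.uniform(lo, hi)
    p2 = p1 - d
    groups = []
    for base in (p1, p2):
        psis = []
        for rep_psi in _replicate_psis(rng, base, config.n_replicates):
            i, s = _counts_for_psi(rng, rep_psi, inc_len, skip_len)
            psis.append((i, s, round(compute_psi(i, s, inc_len, skip_len), 3)))
        groups.append(psis)
    pvalue = round(float(fdr * rng.uniform(0.05, 1.0)), 8)
    return SpliceEvent(
        event_id=event_id,
        event_type=slot.event_type,
        gene_id=slot.gene_id,
        gene_symbol=slot.gene_symbol,
        contig=config.contig,
        strand=slot.strand,
        coords=dict(slot.coords),
        psi_group1=tuple(p for _, _, p in groups[0]),
        psi_group2=tuple(p for _, _, p in groups[1]),
        delta_psi=d,
        pvalue=pvalue,
        fdr=round(float(fdr), 8),
        ijc_group1=tuple(i for i, _, _ in groups[0]),
        sjc_group1=tuple(s for _, s, _ in groups[0]),
        ijc_group2=tuple(i for i, _, _ in groups[1]),
        sjc_group2=tuple(s for _, s, _ in groups[1]),
        inc_len=inc_len,
        skip_len=skip_len,
        contrast_label=contrast_label,
    )


def generate_event_tables(
    config: SyntheticConfig,
    genome: GenomeSequence,
    annotation: GeneAnnotation,
    contrasts: Sequence[str],
) -> tuple[dict[str, dict[str, list[SpliceEvent]]], SyntheticTruth]:
    """Per-contrast, per-type splicing tables with planted structure.

    Shared slots appear with identical keys in every contrast and are
    significant (FDR < 0.05) in all of them; contrast-unique slots appear in
    one table and are significant with probability
    ``fdr_significant_fraction``.  ΔPSI vectors of shared slots follow an
    equicorrelated normal with the configured correlation; when
    ``concordance_rate`` is set, signs of the non-first contrasts are
    adjusted per pair to hit that rate in expectation."""
    if len(contrasts) != config.n_contrasts:
        raise ConfigError(
            f"{len(contrasts)} contrast labels given but config.n_contrasts "
            f"is {config.n_contrasts}"
        )
    if config.n_contrasts < 2 and any(_shared_counts(config)):
        raise ConfigError("shared events require at least 2 contrasts")

    built = _build(config)
    ss = np.random.SeedSequence(config.seed)
    _, events_ss, _ = ss.spawn(3)
    rng = np.random.default_rng(events_ss)

    k = config.n_contrasts
    sd, rho = config.delta_psi_sd, config.delta_psi_correlation
    cov = sd * sd * ((1 - rho) * np.eye(k) + rho * np.ones((k, k)))

    tables: dict[str, dict[str, list[SpliceEvent]]] = {
        c: {t: [] for t in EVENT_TYPES} for c in contrasts
    }
    counters = {c: {t: 0 for t in EVENT_TYPES} for c in contrasts}
    shared_keys: list[EventKey] = []
    flags: list[bool] = []
    planted: list[list[float]] = []

    for slot in built.slots:
        if slot.shared:
            deltas = rng.multivariate_normal(np.zeros(k), cov, method="cholesky")
            deltas = np.clip(deltas, -0.9, 0.9)
            if config.concordance_rate is not None:
                concordant = bool(rng.random() < config.concordance_rate)
                s0 = 1.0 if deltas[0] >= 0 else -1.0
                for j in range(1, k):
                    mag = abs(deltas[j])
                    deltas[j] = s0 * mag if concordant else -s0 * mag
            deltas = np.round(deltas, 3)
            emitted = []
            key = None
            for ci, label in enumerate(contrasts):
                counters[label][slot.event_type] += 1
                ev = _make_event(
                    rng,
                    slot,
                    config,
                    str(counters[label][slot.event_type]),
                    label,
                    float(deltas[ci]),
                    rng.uniform(1e-6, 0.049),
                )
                tables[label][slot.event_type].append(ev)
                emitted.append(ev)
                if key is None:
                    key = event_key(ev)
            shared_keys.append(key)
            flags.append(bool(deltas[0] * deltas[1] > 0) if k >= 2 else True)
            planted.append([float(d) for d in deltas])
        else:
            label = contrasts[slot.contrast_index]
            delta = float(np.clip(rng.normal(0.0, sd), -0.9, 0.9))
            significant = rng.random() < config.fdr_significant_fraction
            fdr = (
                rng.uniform(1e-6, 0.049)
                if significant
                else rng.uniform(0.05, 1.0)
            )
            counters[label][slot.event_type] += 1
            tables[label][slot.event_type].append(
                _make_event(
                    rng,
                    slot,
                    config,
                    str(counters[label][slot.event_type]),
                    label,
                    delta,
                    fdr,
                )
            )

    motifs = config.motifs
    truth = SyntheticTruth(
        shared_keys=shared_keys,
        concordance_flags=flags,
        planted_deltas=np.array(planted) if planted else np.zeros((0, k)),
        planted_correlation=rho,
        concordance_rate=config.concordance_rate,
        n_shared_planted=len(shared_keys),
        five_ss_consensus=motifs["5ss"].intronic_consensus,
        three_ss_consensus=motifs["3ss"].intronic_consensus,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# expression tables


def generate_expression_tables(
    config: SyntheticConfig,
    annotation: Optional[GeneAnnotation] = None,
) -> tuple[list, pd.DataFrame, ExpressionTruth]:
    """Differential-expression and isoform-expression tables.

    Per-gene log2FC ~ Normal(0, 1.5); a configured fraction of genes is
    drawn to pass the q < 0.05, |log2FC| > 0.6 filter.  Isoform fractions
    per condition follow Dirichlet draws; with ``dif_coupling`` 0 the
    knockdown fractions are independent of log2FC, so dIF ⟂ log2FC by
    construction."""
    from .switch import DERecord

    ss = np.random.SeedSequence(config.seed)
    _, _, expr_ss = ss.spawn(3)
    rng = np.random.default_rng(expr_ss)

    if annotation is not None:
        gene_ids = list(annotation.genes)
    else:
        gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]

    de_records: list[DERecord] = []
    iso_rows = []
    log2fc: dict[str, float] = {}
    qvals: dict[str, float] = {}
    passes: dict[str, bool] = {}
    difs: dict[str, tuple[float, ...]] = {}
    k_iso = config.isoforms_per_gene
    for gid in gene_ids:
        is_pass = bool(rng.random() < config.de_significant_fraction)
        if is_pass:
            q = float(rng.uniform(1e-6, 0.049))
            lfc = float(rng.choice([-1, 1]) * (0.61 + rng.exponential(0.8)))
        else:
            q = float(rng.uniform(0.051, 1.0))
            lfc = float(rng.normal(0.0, 1.5))
        lfc, q = round(lfc, 4), round(q, 6)
        log2fc[gid], qvals[gid], passes[gid] = lfc, q, is_pass
        de_records.append(DERecord(gene_id=gid, log2fc=lfc, qvalue=q))

        base = float(rng.lognormal(np.log(50), 1.0))
        f_ctrl = rng.dirichlet([2.0] * k_iso)
        if config.dif_coupling == 0.0:
            f_kd = rng.dirichlet([2.0] * k_iso)
        else:
            tilt = np.ones(k_iso)
            tilt[0] = np.exp(config.dif_coupling * lfc)
            f_kd = f_ctrl * tilt
            f_kd = f_kd / f_kd.sum()
        base_kd = base * 2.0**lfc
        difs[gid] = tuple(float(round(b - a, 6)) for a, b in zip(f_ctrl, f_kd))
        for j in range(k_iso):
            iso_rows.append(
                {
                    "isoform_id": f"{gid}.iso{j + 1}",
                    "gene_id": gid,
                    "ctrl": round(base * f_ctrl[j], 4),
                    "kd": round(base_kd * f_kd[j], 4),
                }
            )
    iso_df = pd.DataFrame(iso_rows, columns=["isoform_id", "gene_id", "ctrl", "kd"])
    truth = ExpressionTruth(
        log2fc=log2fc,
        qvalue=qvals,
        passes_de_filter=passes,
        difs=difs,
        coupling=config.dif_coupling,
    )
    return de_records, iso_df, truth
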