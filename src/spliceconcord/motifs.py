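"""Strand-aware splice-junction windows and position weight matrices.

For each FDR-significant event the exon–intron junction cut points are
derived per event type (donor = 5'ss, acceptor = 3'ss, always in transcript
orientation), a window of ``flank`` bases on each side of the cut point is
extracted from the genome (reverse-complemented for minus-strand events so
the sequence reads 5'→3' on the transcript), and per-position base
probability matrices are built with a Laplace-style pseudocount.  The PWM is
the log2-odds of the probabilities against a background model; information
content is 2 + Σ p·log2 p bits per position (uniform background).

Window layout (length 2×flank):
  5'ss: [exonic flank][intronic flank]
  3'ss: [intronic flank][exonic flank]
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

from .errors import NoWindowsError, WindowBoundsError
from .events import Interval, SpliceEvent
from .io import GenomeSequence, reverse_complement
from .shared import filter_events

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class Junction(NamedTuple):
    side: str  # "5ss" | "3ss"
    contig: str
    strand: str
    cut_point: int  # 0-based inter-base coordinate


@dataclass
class JunctionWindow:
    contig: str
    strand: str
    cut_point: int
    side: str
    sequence: str
    source_event_id: str = ""

    @property
    def flank(self) -> int:
        return len(self.sequence) // 2


@dataclass
class PWMatrix:
    """Per-position base probabilities with derived log-odds and consensus."""

    probs: np.ndarray  # (positions, 4) in A,C,G,T order
    pseudocount: float
    background: np.ndarray  # (4,)
    log_odds: np.ndarray
    info_content: np.ndarray  # bits per position
    consensus: str
    n_sequences: int


@dataclass
class CompositionProfile:
    side: str
    flank: int
    per_position: np.ndarray  # (positions, 4) base fractions
    exonic_gc: float
    intronic_ct: float
    n_sequences: int


def _donor(interval: Interval, strand: str) -> int:
    """Transcript-end boundary of an exon (the 5' splice site cut point)."""
    return interval[1] if strand == "+" else interval[0]


def _acceptor(interval: Interval, strand: str) -> int:
    """Transcript-start boundary of an exon (the 3' splice site cut point)."""
    return interval[0] if strand == "+" else interval[1]


def derive_junctions(event: SpliceEvent) -> list[Junction]:
    """Exon–intron junction cut points of an event, strand-aware.

    SE: acceptor and donor of the cassette exon.  RI: donor of the upstream
    exon and acceptor of the downstream exon (the retained intron's ends).
    MXE: acceptor and donor of each mutually exclusive exon.  A5SS: the two
    alternative donors (long- and short-exon ends in transcript orientation).
    A3SS: the two alternative acceptors.
    """
    c = event.coords
    strand = event.strand
    contig = event.contig
    t = event.event_type

    def j(side: str, cut: int) -> Junction:
        return Junction(side, contig, strand, cut)

    if t == "SE":
        return [
            j("3ss", _acceptor(c["target"], strand)),
            j("5ss", _donor(c["target"], strand)),
        ]
    if t == "RI":
        return [
            j("5ss", _donor(c["upstream"], strand)),
            j("3ss", _acceptor(c["downstream"], strand)),
        ]
    if t == "MXE":
        out = []
        for name in ("exon1", "exon2"):
            out.append(j("3ss", _acceptor(c[name], strand)))
            out.append(j("5ss", _donor(c[name], strand)))
        return out
    if t == "A5SS":
        return [
            j("5ss", _donor(c["long"], strand)),
            j("5ss", _donor(c["short"], strand)),
        ]
    if t == "A3SS":
        return [
            j("3ss", _acceptor(c["long"], strand)),
            j("3ss", _acceptor(c["short"], strand)),
        ]
    raise ValueError(f"unknown event type {t!r}")


def extract_window(
    genome: GenomeSequence,
    junction: Junction,
    flank: int = 25,
    source_event_id: str = "",
) -> JunctionWindow:
    """Sequence of 2×flank bases centred on the cut point, 5'→3' on the
    transcript strand (minus strand: reverse complement of the genomic
    substring)."""
    side, contig, strand, cut = junction
    length = genome.lengths.get(contig)
    if length is None:
        raise WindowBoundsError(f"contig {contig!r} absent from genome")
    start, end = cut - flank, cut + flank
    if start < 0 or end > length:
        raise WindowBoundsError(
            f"window [{start}, {end}) at {contig}:{cut} exceeds contig "
            f"bounds [0, {length})"
        )
    seq = genome.fetch(contig, start, end)
    if strand == "-":
        seq = reverse_complement(seq)
    return JunctionWindow(contig, strand, cut, side, seq, source_event_id)


def _sequences(windows: Sequence) -> list[str]:
    return [w.sequence if isinstance(w, JunctionWindow) else str(w) for w in windows]


def build_pwm(
    windows: Sequence,
    pseudocount: float = 0.5,
    background: Optional[Sequence[float]] = None,
) -> PWMatrix:
    """Position probability matrix over aligned windows, plus log-odds.

    probs[i][b] = (count_b(i) + pc) / (n_effective(i) + 4·pc) with N bases
    excluded from both the count and n_effective.  Consensus ties break in
    A < C < G < T order.
    """
    seqs = _sequences(windows)
    if not seqs:
        raise ValueError("cannot build a PWM from zero windows")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    length = lengths.pop()
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background must be 4 probabilities summing to 1")

    counts = np.zeros((length, 4))
    for s in seqs:
        for i, base in enumerate(s.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                counts[i, idx] += 1
    n_eff = counts.sum(axis=1, keepdims=True)
    denom = n_eff + 4 * pseudocount
    if np.any(denom == 0):
        raise ValueError("a position has no informative bases and zero pseudocount")
    probs = (counts + pseudocount) / denom

    with np.errstate(divide="ignore"):
        log_odds = np.where(probs > 0, np.log2(np.maximum(probs, 1e-300) / bg), -np.inf)
        plogp = np.where(probs > 0, probs * np.log2(np.maximum(probs, 1e-300)), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    consensus = "".join(BASES[i] for i in probs.argmax(axis=1))
    return PWMatrix(
        probs=probs,
        pseudocount=pseudocount,
        background=bg,
        log_odds=log_odds,
        info_content=info,
        consensus=consensus,
        n_sequences=len(seqs),
    )


def composition_profile(windows: Sequence[JunctionWindow]) -> CompositionProfile:
    """Per-position base fractions plus the aggregate exonic G+C and
    intronic C+T fractions, halves assigned by the windows' side label."""
    if not windows:
        raise ValueError("cannot profile zero windows")
    sides = {w.side for w in windows}
    if len(sides) != 1:
        raise ValueError(f"mixed side labels: {sorted(sides)}")
    side = sides.pop()
    seqs = _sequences(windows)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    length = lengths.pop()
    flank = length // 2

    counts = np.zeros((length, 4))
    for s in seqs:
        for i, base in enumerate(s.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                counts[i, idx] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        per_position = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)

    # transcript orientation: 5'ss windows are exon-then-intron, 3'ss the reverse
    if side == "5ss":
        exonic, intronic = counts[:flank], counts[flank:]
    else:
        intronic, exonic = counts[:flank], counts[flank:]

    def _agg(block: np.ndarray, bases: str) -> float:
        total = block.sum()
        if total == 0:
            return 0.0
        return float(sum(block[:, _BASE_INDEX[b]].sum() for b in bases) / total)

    return CompositionProfile(
        side=side,
        flank=flank,
        per_position=per_position,
        exonic_gc=_agg(exonic, "GC"),
        intronic_ct=_agg(intronic, "CT"),
        n_sequences=len(seqs),
    )


@dataclass
class MotifResult:
    per_group: dict[tuple[str, str], PWMatrix]  # (event_type, side) -> PWM
    pooled: dict[str, PWMatrix]  # side -> PWM over all types
    composition: dict[str, CompositionProfile]  # side -> profile
    windows: dict[str, list[JunctionWindow]] = field(default_factory=dict)
    n_skipped: int = 0


def motif_pipeline(
    events: Sequence[SpliceEvent],
    genome: GenomeSequence,
    fdr_threshold: float = 0.1,
    flank: int = 25,
    pseudocount: float = 0.5,
) -> MotifResult:
    """Filter events (FDR strictly below threshold), derive junctions,
    extract windows (out-of-bounds windows are skipped and counted), and
    build per-(type, side) and pooled per-side matrices plus composition
    profiles."""
    kept = filter_events(list(events), fdr_threshold)
    group_windows: dict[tuple[str, str], list[JunctionWindow]] = {}
    side_windows: dict[str, list[JunctionWindow]] = {"5ss": [], "3ss": []}
    n_skipped = 0
    for ev in kept:
        for junction in derive_junctions(ev):
            try:
                w = extract_window(genome, junction, flank, ev.event_id)
            except WindowBoundsError:
                n_skipped += 1
                continue
            group_windows.setdefault((ev.event_type, junction.side), []).append(w)
            side_windows[junction.side].append(w)
    if n_skipped:
        logger.info("motif_pipeline: skipped %d out-of-bounds windows", n_skipped)
    for side, ws in side_windows.items():
        if not ws:
            raise NoWindowsError(
                f"no junction windows survived filtering for side {side!r}"
            )
    per_group = {
        g: build_pwm(ws, pseudocount=pseudocount) for g, ws in group_windows.items()
    }
    pooled = {
        side: build_pwm(ws, pseudocount=pseudocount)
        for side, ws in side_windows.items()
    }
    composition = {side: composition_profile(ws) for side, ws in side_windows.items()}
    return MotifResult(
        per_group=per_group,
        pooled=pooled,
        composition=composition,
        windows=side_windows,
        n_skipped=n_skipped,
    )
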