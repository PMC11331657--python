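"""Splicing-event data model, PSI arithmetic and matching-key construction.

The central object is :class:`SpliceEvent`, one differential-splicing record
in the dialect emitted by junction-count based splicing callers: an event of
one of the five canonical classes (SE, RI, MXE, A3SS, A5SS) with type-specific
exon coordinates, per-replicate inclusion levels (PSI) for the two sample
groups of a contrast, the group difference ΔPSI, and event-level p/FDR.

All coordinates are 0-based half-open genome intervals.  ``upstream`` and
``downstream`` are in transcript orientation: for a minus-strand event the
transcript-upstream exon has the larger genomic coordinates.

Shared events across two contrasts are found by exact key equality
(:func:`event_key`).  The key composition is type specific: A3SS/A5SS events
match on gene identity plus long/short/flanking exon intervals, while
SE/RI/MXE events match on the upstream/downstream exon boundaries plus the
target exon(s) or retained intron.  Contig and strand enter every key so that
events on different chromosomes can never collide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from .errors import MissingCoordinateError, RowError

EVENT_TYPES = ("SE", "RI", "MXE", "A3SS", "A5SS")

#: coordinate components each event type must carry
REQUIRED_COORDS: dict[str, tuple[str, ...]] = {
    "SE": ("target", "upstream", "downstream"),
    "RI": ("upstream", "downstream", "intron"),
    "MXE": ("exon1", "exon2", "upstream", "downstream"),
    "A3SS": ("long", "short", "flanking"),
    "A5SS": ("long", "short", "flanking"),
}

Interval = Tuple[int, int]


@dataclass
class SpliceEvent:
    """One differential alternative-splicing record of a single contrast.

    ``psi_group1``/``psi_group2`` are per-replicate inclusion levels with
    ``None`` for missing replicates.  ``delta_psi`` is the group difference
    (group1 − group2) as reported by the caller, not recomputed from the
    replicate means.
    """

    event_id: str
    event_type: str
    gene_id: str
    gene_symbol: str
    contig: str
    strand: str
    coords: dict[str, Interval]
    psi_group1: tuple[Optional[float], ...]
    psi_group2: tuple[Optional[float], ...]
    delta_psi: Optional[float]
    pvalue: float
    fdr: float
    ijc_group1: tuple[int, ...] = ()
    sjc_group1: tuple[int, ...] = ()
    ijc_group2: tuple[int, ...] = ()
    sjc_group2: tuple[int, ...] = ()
    inc_len: int = 1
    skip_len: int = 1
    contrast_label: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"pvalue {self.pvalue} outside [0, 1]")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"FDR {self.fdr} outside [0, 1]")
        if self.delta_psi is not None and not (-1.0 <= self.delta_psi <= 1.0):
            raise ValueError(f"delta_psi {self.delta_psi} outside [-1, 1]")
        for name, (start, end) in self.coords.items():
            if start >= end:
                raise ValueError(
                    f"coordinate {name!r} has start {start} >= end {end}"
                )
        if self.inc_len <= 0 or self.skip_len <= 0:
            raise ValueError("effective lengths must be positive")


@dataclass(frozen=True)
class EventKey:
    """Hashable identity of a splicing event for cross-contrast matching.

    ``components`` holds the type-specific tuple described in the module
    docstring; keys of different ``event_type`` never compare equal because
    the type is part of the key.
    """

    event_type: str
    contig: str
    strand: str
    components: tuple


def compute_psi(
    inc_count: int, skip_count: int, inc_len: int, skip_len: int
) -> Optional[float]:
    """Length-normalized inclusion level for one replicate.

    PSI = (I/lI) / (I/lI + S/lS); ``None`` when both junction counts are zero
    (the ratio is undefined).
    """
    if inc_count < 0 or skip_count < 0:
        raise ValueError("junction counts must be non-negative")
    if inc_len <= 0 or skip_len <= 0:
        raise ValueError("effective lengths must be positive")
    if inc_count == 0 and skip_count == 0:
        return None
    inc_norm = inc_count / inc_len
    skip_norm = skip_count / skip_len
    return inc_norm / (inc_norm + skip_norm)


def mean_psi(replicates: Iterable[Optional[float]]) -> Optional[float]:
    """Arithmetic mean over non-missing replicate PSI values."""
    values = []
    for v in replicates:
        if v is None:
            continue
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"PSI value {v} outside [0, 1]")
        values.append(v)
    if not values:
        return None
    return sum(values) / len(values)


def _coord(event: SpliceEvent, name: str) -> Interval:
    try:
        return event.coords[name]
    except KeyError:
        raise MissingCoordinateError(
            f"event {event.event_id!r} ({event.event_type}) lacks "
            f"coordinate component {name!r}"
        ) from None


def event_key(event: SpliceEvent) -> EventKey:
    """Build the type-specific matching key of an event.

    A3SS/A5SS: (gene_id, gene_symbol, long, short, flanking exon).
    SE:        (upstream start/end, downstream start/end, target exon).
    RI:        (upstream start/end, downstream start/end, retained intron).
    MXE:       (upstream start/end, downstream start/end, both exons).
    Contig and strand are part of every key.
    """
    etype = event.event_type
    if etype in ("A3SS", "A5SS"):
        components = (
            event.gene_id,
            event.gene_symbol,
            _coord(event, "long"),
            _coord(event, "short"),
            _coord(event, "flanking"),
        )
    else:
        up = _coord(event, "upstream")
        down = _coord(event, "downstream")
        if etype == "SE":
            targets: tuple = (_coord(event, "target"),)
        elif etype == "RI":
            targets = (_coord(event, "intron"),)
        else:  # MXE
            targets = (_coord(event, "exon1"), _coord(event, "exon2"))
        components = (up[0], up[1], down[0], down[1]) + targets
    return EventKey(etype, event.contig, event.strand, components)


def first_coordinate(event: SpliceEvent) -> int:
    """Smallest genomic start among an event's coordinate components."""
    return min(start for start, _ in event.coords.values())
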