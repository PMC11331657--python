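"""Shared-event identification and direction-concordance statistics.

Given the FDR-significant event sets of two knockdown contrasts, this module
finds events present in both (exact key equality, see
:mod:`spliceconcord.events`), classifies whether the two knockdowns shift
each event in the same direction (sign of ΔPSI), and summarises: counts,
concordant fraction, distinct-gene tally, per-type composition, and the
Pearson correlation of ΔPSI across contrasts.  Venn-region counting for
set-overlap figures lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Optional, Sequence

from scipy import stats

from .errors import DuplicateKeyError
from .events import EventKey, SpliceEvent, event_key, first_coordinate


@dataclass
class MatchedEventPair:
    """A splicing event shared by two contrasts, with its concordance call."""

    key: EventKey
    event_a: SpliceEvent
    event_b: SpliceEvent
    concordant: bool


@dataclass
class ConcordanceSummary:
    n_shared_events: int
    n_concordant: int
    concordance_fraction: Optional[float]
    concordance_percent: Optional[float]  # one decimal, half-up
    n_genes: int
    per_type_counts: dict[str, int] = field(default_factory=dict)
    pearson_r: Optional[float] = None
    correlation_p: Optional[float] = None


def filter_events(
    events: Sequence[SpliceEvent], fdr_threshold: float
) -> list[SpliceEvent]:
    """Keep events with FDR strictly below the threshold, order preserved."""
    if not (0.0 < fdr_threshold <= 1.0):
        raise ValueError(f"FDR threshold {fdr_threshold} outside (0, 1]")
    return [ev for ev in events if ev.fdr < fdr_threshold]


def collapse_duplicate_keys(events: Sequence[SpliceEvent]) -> list[SpliceEvent]:
    """Resolve duplicate keys within one contrast before matching.

    Keeps the record with the smallest FDR, tie-broken by smallest p-value
    then by event_id, so that matching is guaranteed one-to-one.
    """
    best: dict[EventKey, SpliceEvent] = {}
    order: list[EventKey] = []
    for ev in events:
        k = event_key(ev)
        if k not in best:
            best[k] = ev
            order.append(k)
        else:
            cur = best[k]
            if (ev.fdr, ev.pvalue, ev.event_id) < (cur.fdr, cur.pvalue, cur.event_id):
                best[k] = ev
    return [best[k] for k in order]


def classify_concordance(
    delta_psi_a: Optional[float], delta_psi_b: Optional[float]
) -> bool:
    """True iff both ΔPSI values have the same (non-zero) sign."""
    if delta_psi_a is None or delta_psi_b is None:
        raise ValueError("cannot classify concordance with missing ΔPSI")
    return delta_psi_a * delta_psi_b > 0


def match_shared_events(
    events_a: Sequence[SpliceEvent], events_b: Sequence[SpliceEvent]
) -> list[MatchedEventPair]:
    """Pair events whose type-specific keys are present in both contrasts.

    Inputs must already be FDR-filtered and free of within-contrast
    duplicate keys (see :func:`collapse_duplicate_keys`).  Pairs come back
    sorted by (event_type, contig, first coordinate).
    """
    index_a: dict[EventKey, SpliceEvent] = {}
    for ev in events_a:
        k = event_key(ev)
        if k in index_a:
            raise DuplicateKeyError(f"duplicate key within contrast A: {k}")
        index_a[k] = ev
    seen_b: set[EventKey] = set()
    pairs: list[MatchedEventPair] = []
    for ev in events_b:
        k = event_key(ev)
        if k in seen_b:
            raise DuplicateKeyError(f"duplicate key within contrast B: {k}")
        seen_b.add(k)
        if k in index_a:
            a = index_a[k]
            pairs.append(
                MatchedEventPair(
                    key=k,
                    event_a=a,
                    event_b=ev,
                    concordant=classify_concordance(a.delta_psi, ev.delta_psi),
                )
            )
    pairs.sort(
        key=lambda p: (p.key.event_type, p.key.contig, first_coordinate(p.event_a))
    )
    return pairs


def _percent_one_decimal(fraction: float) -> float:
    """Fraction -> percentage rounded half-up to one decimal (82.7 style)."""
    return float(
        (Decimal(str(fraction)) * 100).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


def concordance_summary(pairs: Sequence[MatchedEventPair]) -> ConcordanceSummary:
    """Counts, concordant fraction/percentage, gene tally and per-type split.

    The ΔPSI Pearson correlation is attached when computable (≥3 pairs with
    non-constant ΔPSI on both axes), otherwise left as None.
    """
    n = len(pairs)
    n_conc = sum(1 for p in pairs if p.concordant)
    fraction = n_conc / n if n else None
    percent = _percent_one_decimal(fraction) if fraction is not None else None
    genes = {p.event_a.gene_id for p in pairs}
    per_type: dict[str, int] = {}
    for p in pairs:
        per_type[p.key.event_type] = per_type.get(p.key.event_type, 0) + 1
    r: Optional[float] = None
    pval: Optional[float] = None
    try:
        r, pval = delta_psi_correlation(pairs)
    except ValueError:
        pass
    return ConcordanceSummary(
        n_shared_events=n,
        n_concordant=n_conc,
        concordance_fraction=fraction,
        concordance_percent=percent,
        n_genes=len(genes),
        per_type_counts=per_type,
        pearson_r=r,
        correlation_p=pval,
    )


def delta_psi_correlation(
    pairs: Sequence[MatchedEventPair],
) -> tuple[float, float]:
    """Pearson correlation of (ΔPSI_a, ΔPSI_b) with two-sided p-value."""
    xs = [p.event_a.delta_psi for p in pairs]
    ys = [p.event_b.delta_psi for p in pairs]
    if any(v is None for v in xs + ys):
        raise ValueError("missing ΔPSI among matched pairs")
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched pairs for a correlation")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("ΔPSI vector is constant; correlation undefined")
    result = stats.pearsonr(xs, ys)
    return float(result.statistic), float(result.pvalue)


def venn_counts(labelled_sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exclusive-region counts for 2–5 labelled sets.

    Returns a mapping from the frozenset of labels defining a region to the
    number of identifiers found in exactly those sets; all 2^k − 1 regions
    are present (empty regions count 0).
    """
    labels = list(labelled_sets)
    if not (2 <= len(labels) <= 5):
        raise ValueError("venn_counts requires between 2 and 5 sets")
    regions: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            regions[frozenset(combo)] = 0
    universe = set().union(*labelled_sets.values())
    for item in universe:
        membership = frozenset(l for l in labels if item in labelled_sets[l])
        regions[membership] += 1
    return regions


def top_genes_by_event_count(
    pairs: Sequence[MatchedEventPair], n: int
) -> list[tuple[str, int]]:
    """Genes ranked by number of shared events (desc), ties lexicographic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    counts: dict[str, int] = {}
    for p in pairs:
        sym = p.event_a.gene_symbol
        counts[sym] = counts.get(sym, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]
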