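"""Three-tier enumeration of conversion events and pairing opportunities.

Tier 1 counts every detected fragment as an independent event.  Tier 2
collapses "duplicates" — fragments with identical (start, end) borders in the
same segment and group-pair category, the signature of a single transfer that
predates lineage divergence in the recipient group — into one event.  Tier 3
counts at most one event per (segment, group-pair) cell, since overlapping
fragments in one cell rarely represent independent transfers.

The opportunity table holds the null-model weights: how many strain pairs of
each category a panel offers.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Iterable, Mapping

from .conversion_detect import ConversionFragment, is_inter, pair_category

CellKey = tuple[str, str]  # (segment_id, category)


@dataclasses.dataclass(frozen=True)
class TierEventSet:
    """Event counts at one stringency tier.

    counts maps (segment_id, category) to the event tally; provenance maps a
    stable event id to the indices (into the input fragment list) of the
    fragments it absorbs.
    """

    tier: int
    counts: Mapping[CellKey, int]
    provenance: Mapping[str, tuple[int, ...]]

    def total(self, inter_only: bool = False) -> int:
        return sum(
            n
            for (seg, cat), n in self.counts.items()
            if not inter_only or is_inter(cat)
        )

    def by_category(self, inter_only: bool = False) -> dict[str, int]:
        """Counts summed over segments, keyed by category."""
        out: dict[str, int] = {}
        for (_, cat), n in self.counts.items():
            if inter_only and not is_inter(cat):
                continue
            out[cat] = out.get(cat, 0) + n
        return out

    def segment_totals(self, inter_only: bool = False) -> dict[str, int]:
        """Per-segment event totals T_s."""
        out: dict[str, int] = {}
        for (seg, cat), n in self.counts.items():
            if inter_only and not is_inter(cat):
                continue
            out[seg] = out.get(seg, 0) + n
        return out


@dataclasses.dataclass(frozen=True)
class OpportunityTable:
    """Strain-pairing opportunities per category for each panel.

    For a panel with group sizes n_g: n(intra:g) = C(n_g, 2) and
    n(inter:g1|g2) = n_g1 * n_g2; total opportunities are C(sum n_g, 2).
    ``segment_panel`` says which panel each segment was sequenced in.
    """

    group_sizes: Mapping[str, Mapping[str, int]]  # panel -> group -> size
    pair_counts: Mapping[str, Mapping[str, int]]  # panel -> category -> count
    segment_panel: Mapping[str, str]

    def n_intra(self, panel: str) -> int:
        return sum(
            n for cat, n in self.pair_counts[panel].items() if not is_inter(cat)
        )

    def n_inter(self, panel: str) -> int:
        return sum(n for cat, n in self.pair_counts[panel].items() if is_inter(cat))

    def categories(self, inter_only: bool = True) -> list[str]:
        cats: set[str] = set()
        for panel_counts in self.pair_counts.values():
            for cat in panel_counts:
                if not inter_only or is_inter(cat):
                    cats.add(cat)
        return sorted(cats)

    def panel_for(self, segment_id: str) -> str:
        return self.segment_panel[segment_id]


def opportunities(
    panel_groups: Mapping[str, Mapping[str, int]],
    segment_panel: Mapping[str, str],
) -> OpportunityTable:
    """Exact combinatorial pairing counts per category for each panel.

    panel_groups: panel id -> {group label: strain count}.
    segment_panel: segment id -> panel id.
    """
    pair_counts: dict[str, dict[str, int]] = {}
    for panel, sizes in panel_groups.items():
        if not sizes or all(n == 0 for n in sizes.values()):
            raise ValueError(f"panel {panel!r} has no strains")
        counts: dict[str, int] = {}
        for g, n in sizes.items():
            counts[pair_category(g, g)] = n * (n - 1) // 2
        for g1, g2 in combinations(sorted(sizes), 2):
            counts[pair_category(g1, g2)] = sizes[g1] * sizes[g2]
        pair_counts[panel] = counts
    unknown = set(segment_panel.values()) - set(panel_groups)
    if unknown:
        raise ValueError(f"segments reference unknown panels: {sorted(unknown)}")
    return OpportunityTable(
        group_sizes={p: dict(s) for p, s in panel_groups.items()},
        pair_counts=pair_counts,
        segment_panel=dict(segment_panel),
    )


def _tally(
    fragments: Iterable[ConversionFragment],
    tier: int,
    event_key,
) -> TierEventSet:
    groups: dict[tuple, list[int]] = {}
    for idx, frag in enumerate(fragments):
        groups.setdefault(event_key(idx, frag), []).append(idx)
    counts: dict[CellKey, int] = {}
    provenance: dict[str, tuple[int, ...]] = {}
    for key, members in sorted(groups.items(), key=lambda kv: repr(kv[0])):
        seg, cat = key[0], key[1]
        counts[(seg, cat)] = counts.get((seg, cat), 0) + 1
        event_id = f"t{tier}:" + ":".join(str(k) for k in key)
        provenance[event_id] = tuple(members)
    return TierEventSet(tier=tier, counts=counts, provenance=provenance)


def tier1_events(fragments: list[ConversionFragment]) -> TierEventSet:
    """Every fragment is an independent event."""
    return _tally(fragments, 1, lambda i, f: (f.segment_id, f.category, i))


def tier2_events(fragments: list[ConversionFragment]) -> TierEventSet:
    """Fragments with identical (start, end) borders in the same segment and
    category collapse to a single event, regardless of which strains carry
    them."""
    return _tally(
        fragments, 2, lambda i, f: (f.segment_id, f.category, f.start, f.end)
    )


def tier3_events(fragments: list[ConversionFragment]) -> TierEventSet:
    """At most one event per (segment, category) cell."""
    return _tally(fragments, 3, lambda i, f: (f.segment_id, f.category))


def tier_events(fragments: list[ConversionFragment], tier: int) -> TierEventSet:
    if tier == 1:
        return tier1_events(fragments)
    if tier == 2:
        return tier2_events(fragments)
    if tier == 3:
        return tier3_events(fragments)
    raise ValueError(f"tier must be 1, 2 or 3, got {tier}")
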