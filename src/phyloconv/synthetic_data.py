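"""Synthetic grouped alignments with known planted conversion structure.

The generator emulates the study design the pipeline targets: a handful of
deeply separated phylogroups, several strains per group, a few ~23-kb
chromosome segments, and between-group gene-conversion tracts planted with
known borders.  Evolution is deliberately simple — a star phylogeny within
and between groups with independent per-site substitutions under a
K2P-compatible transition bias — which creates the group-block polymorphism
structure the detector needs while keeping the ground truth exact.

Planted events come in two timings: "ancestral" copies the donor-group
founder sequence into the recipient-group founder *before* strain
derivation, so every descendant of the recipient group carries a tract with
identical borders (the duplicate mechanism that tier-2 counting collapses);
"terminal" copies a donor strain's derived sequence into named recipient
strains after derivation.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np

from .alignment_io import GroupedAlignment
from .conversion_detect import ConversionFragment, pair_category, project_polymorphic

_BASES = "ACGT"
_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.int8)  # A<->G, C<->T
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)

DEFAULT_GROUPS = {"A": 4, "B1": 4, "B2": 4, "D": 4, "E": 4}
OUTGROUP_ID = "OUT"
OUTGROUP_LABEL = "O"


@dataclasses.dataclass(frozen=True)
class PlantedEvent:
    """One conversion tract to plant: donor group -> recipient group."""

    segment: int  # 0-based segment index
    donor_group: str
    recipient_group: str
    start: int
    end: int
    timing: str = "ancestral"  # or "terminal"
    recipient_strains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.timing not in {"ancestral", "terminal"}:
            raise ValueError(f"unknown timing {self.timing!r}")
        if self.donor_group == self.recipient_group:
            raise ValueError("donor and recipient group must differ")
        if not 0 <= self.start < self.end:
            raise ValueError("invalid tract interval")


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for one synthetic panel.

    Defaults mirror the target study's scale: 5 phylogroups of 4 strains,
    4 segments of 23 kb, deep between-group divergence (2% per founder
    branch) and shallow within-group divergence (0.2% per strain branch),
    transition:transversion ratio 2, outgroup at 3x the founder divergence.
    """

    groups: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    n_segments: int = 4
    segment_length: int = 23_000
    inter_group_divergence: float = 0.02
    intra_group_divergence: float = 0.002
    ts_tv_ratio: float = 2.0
    planted_events: tuple[PlantedEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.inter_group_divergence, self.intra_group_divergence):
            if not 0.0 <= p < 1.0:
                raise ValueError("divergence probabilities must be in [0, 1)")
        if self.segment_length < 1 or self.n_segments < 1:
            raise ValueError("need >= 1 segment of >= 1 bp")
        for ev in self.planted_events:
            if ev.end > self.segment_length:
                raise ValueError(
                    f"planted tract [{ev.start}, {ev.end}) outside segment of "
                    f"length {self.segment_length}"
                )
            if not 0 <= ev.segment < self.n_segments:
                raise ValueError(f"planted event references segment {ev.segment}")
            for g in (ev.donor_group, ev.recipient_group):
                if g not in self.groups:
                    raise ValueError(f"planted event references unknown group {g!r}")

    def strain_names(self, group: str) -> list[str]:
        return [f"{group}_{i + 1:02d}" for i in range(self.groups[group])]


@dataclasses.dataclass(frozen=True)
class RealizedEvent:
    """A planted event with its realized carriers and detectability info."""

    segment_id: str
    donor_group: str
    recipient_group: str
    start: int
    end: int
    timing: str
    donor_strain: str
    carrier_strains: tuple[str, ...]
    category: str
    psite_start: int  # polymorphic-site interval inside the tract; -1 if none
    psite_end: int
    n_polymorphic_in_tract: int


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    events: tuple[RealizedEvent, ...]
    polymorphic_sites: Mapping[str, int]  # segment_id -> count
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "polymorphic_sites": dict(self.polymorphic_sites),
                "events": [dataclasses.asdict(e) for e in self.events],
            },
            indent=2,
        )


def _mutate(seq: np.ndarray, p: float, ts_tv_ratio: float, rng) -> np.ndarray:
    """Independent per-site substitution with transition bias.

    Each site mutates with probability p; a mutation is a transition with
    probability R/(R+1) for ts_tv_ratio R, otherwise one of the two
    transversions uniformly.
    """
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < p)
    if hit.size == 0:
        return out
    p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0)
    is_ts = rng.random(hit.size) < p_ts
    cur = out[hit]
    new = np.where(
        is_ts,
        _TS_PARTNER[cur],
        _TV_PARTNERS[cur, rng.integers(0, 2, size=hit.size)],
    )
    out[hit] = new.astype(np.int8)
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[c] for c in seq)


def generate_panel(
    cfg: GeneratorConfig,
) -> tuple[list[GroupedAlignment], SyntheticTruth]:
    """Generate one panel of segment alignments plus its ground truth.

    Per segment: a random ancestral sequence; one founder per group mutated
    at the inter-group rate; strains mutated from founders at the
    intra-group rate; planted tracts copied donor -> recipient (ancestral
    events into the founder, terminal events into named strains); an
    outgroup mutated at 3x the inter-group rate.  The same seed always
    yields byte-identical panels.
    """
    rng = np.random.default_rng(cfg.seed)
    group_labels = sorted(cfg.groups)
    alignments: list[GroupedAlignment] = []
    events: list[RealizedEvent] = []
    poly_counts: dict[str, int] = {}

    for seg_idx in range(cfg.n_segments):
        segment_id = f"seg{seg_idx + 1}"
        L = cfg.segment_length
        ancestor = rng.integers(0, 4, size=L, dtype=np.int8)
        founders = {
            g: _mutate(ancestor, cfg.inter_group_divergence, cfg.ts_tv_ratio, rng)
            for g in group_labels
        }
        seg_events = [e for e in cfg.planted_events if e.segment == seg_idx]
        for ev in seg_events:
            if ev.timing == "ancestral":
                founders[ev.recipient_group][ev.start : ev.end] = founders[
                    ev.donor_group
                ][ev.start : ev.end]
        strains: dict[str, np.ndarray] = {}
        groups_map: dict[str, str] = {}
        for g in group_labels:
            for name in cfg.strain_names(g):
                strains[name] = _mutate(
                    founders[g], cfg.intra_group_divergence, cfg.ts_tv_ratio, rng
                )
                groups_map[name] = g
        for ev in seg_events:
            donor_strain = cfg.strain_names(ev.donor_group)[0]
            if ev.timing == "terminal":
                recipients = ev.recipient_strains or (
                    cfg.strain_names(ev.recipient_group)[0],
                )
                for r in recipients:
                    if groups_map.get(r) != ev.recipient_group:
                        raise ValueError(
                            f"recipient strain {r!r} not in group "
                            f"{ev.recipient_group!r}"
                        )
                    strains[r][ev.start : ev.end] = strains[donor_strain][
                        ev.start : ev.end
                    ]
                carriers = tuple(recipients)
            else:
                carriers = tuple(cfg.strain_names(ev.recipient_group))
            events.append(
                (segment_id, ev, donor_strain, carriers)  # resolved below
            )
        outgroup_seq = _mutate(
            ancestor, 3.0 * cfg.inter_group_divergence, cfg.ts_tv_ratio, rng
        )
        strains[OUTGROUP_ID] = outgroup_seq
        groups_map[OUTGROUP_ID] = OUTGROUP_LABEL
        aln = GroupedAlignment(
            segment_id=segment_id,
            sequences={s: _decode(seq) for s, seq in strains.items()},
            groups=groups_map,
            outgroup=OUTGROUP_ID,
            panel_id="panel1",
        )
        alignments.append(aln)

    # resolve detectability info against the realized polymorphic projections
    realized: list[RealizedEvent] = []
    proj_by_seg = {}
    for aln in alignments:
        proj = project_polymorphic(aln)
        proj_by_seg[aln.segment_id] = proj
        poly_counts[aln.segment_id] = proj.n_sites
    for segment_id, ev, donor_strain, carriers in events:
        cols = proj_by_seg[segment_id].site_columns
        lo = int(np.searchsorted(cols, ev.start, side="left"))
        hi = int(np.searchsorted(cols, ev.end - 1, side="right"))
        n_in = hi - lo
        realized.append(
            RealizedEvent(
                segment_id=segment_id,
                donor_group=ev.donor_group,
                recipient_group=ev.recipient_group,
                start=ev.start,
                end=ev.end,
                timing=ev.timing,
                donor_strain=donor_strain,
                carrier_strains=carriers,
                category=pair_category(ev.donor_group, ev.recipient_group),
                psite_start=lo if n_in > 0 else -1,
                psite_end=hi if n_in > 0 else -1,
                n_polymorphic_in_tract=n_in,
            )
        )
    truth = SyntheticTruth(
        events=tuple(realized), polymorphic_sites=poly_counts, seed=cfg.seed
    )
    return alignments, truth


def truth_to_fragments(truth: SyntheticTruth) -> list[ConversionFragment]:
    """Oracle fragments from the planted truth (p_global = 0).

    Each event yields one fragment per (donor strain, carrier strain) pair
    with the planted borders; an ancestral event inherited by d descendants
    therefore yields d identical-border fragments — the tier-2 duplicate
    signature.  Events whose tract contains no polymorphic site are
    undetectable in principle and yield no fragment.
    """
    out: list[ConversionFragment] = []
    for ev in truth.events:
        if ev.n_polymorphic_in_tract <= 0:
            continue
        for carrier in ev.carrier_strains:
            out.append(
                ConversionFragment(
                    segment_id=ev.segment_id,
                    pair=tuple(sorted((ev.donor_strain, carrier))),
                    start=ev.start,
                    end=ev.end,
                    psite_start=ev.psite_start,
                    psite_end=ev.psite_end,
                    score=ev.n_polymorphic_in_tract,
                    p_global=0.0,
                    category=ev.category,
                )
            )
    return out


def panel_metadata(cfg: GeneratorConfig):
    """Strain metadata rows (strain_id, group, panel_id, is_outgroup) for a panel."""
    import pandas as pd

    rows = []
    for g in sorted(cfg.groups):
        for name in cfg.strain_names(g):
            rows.append((name, g, "panel1", False))
    rows.append((OUTGROUP_ID, OUTGROUP_LABEL, "panel1", True))
    return pd.DataFrame(
        rows, columns=["strain_id", "group", "panel_id", "is_outgroup"]
    )


def sample_planted_events(
    cfg_groups: Mapping[str, int],
    n_segments: int,
    segment_length: int,
    total_events: int,
    rng: np.random.Generator,
    enrichment: Mapping[tuple[str, str], float] | None = None,
    tract_length: int = 2000,
) -> tuple[PlantedEvent, ...]:
    """Random terminal inter-group events at opportunity-proportional rates.

    Category probabilities are proportional to n_g1 * n_g2, optionally
    multiplied by an enrichment factor per (sorted) group pair — the planted
    analogue of non-random exchange.  Used by calibration and power
    experiments.
    """
    labels = sorted(cfg_groups)
    cats: list[tuple[str, str]] = []
    weights: list[float] = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1 :]:
            w = cfg_groups[g1] * cfg_groups[g2]
            if enrichment:
                w *= enrichment.get((g1, g2), 1.0)
            cats.append((g1, g2))
            weights.append(float(w))
    probs = np.array(weights) / sum(weights)
    events: list[PlantedEvent] = []
    for _ in range(total_events):
        g1, g2 = cats[int(rng.choice(len(cats), p=probs))]
        if rng.random() < 0.5:
            g1, g2 = g2, g1
        seg = int(rng.integers(0, n_segments))
        start = int(rng.integers(0, max(1, segment_length - tract_length)))
        rec_strains = [f"{g2}_{i + 1:02d}" for i in range(cfg_groups[g2])]
        recipient = rec_strains[int(rng.integers(0, len(rec_strains)))]
        events.append(
            PlantedEvent(
                segment=seg,
                donor_group=g1,
                recipient_group=g2,
                start=start,
                end=start + tract_length,
                timing="terminal",
                recipient_strains=(recipient,),
            )
        )
    return tuple(events)
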