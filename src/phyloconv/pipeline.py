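"""End-to-end pipeline: detect -> tiers -> exchange test -> inter/intra -> trees.

Artifacts are written to a run directory with a provenance manifest (seed,
config hash, package version).  Reruns with identical config and seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .alignment_io import mask_fragments, read_grouped_alignment, read_metadata, write_grouped_alignment
from .conversion_detect import (
    ConversionFragment,
    DetectorConfig,
    category_groups,
    detect_fragments,
    fragments_to_rows,
    is_inter,
    project_polymorphic,
)
from .exchange_test import simulate_null
from .inter_intra_test import inter_vs_intra
from .phylo_congruence import bootstrap_support, write_tree
from .tier_enum import OpportunityTable, opportunities, tier_events

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs.

    fastas maps segment id -> aligned multi-FASTA path; all strains must be
    listed in the metadata TSV.  Tree building runs on the masked
    alignments (converted tracts gapped out), matching the intent that
    converted signal should not shape the trees.
    """

    fastas: Mapping[str, str]
    metadata: str
    outdir: str
    gscale: float = 1.0
    alpha: float = 0.05
    n_permutations: int = 10_000
    n_sims: int = 1_000_000
    rounding: str = "paper-compat"
    exclude_groups: tuple[str, ...] = ()
    seed: int = 0
    build_trees: bool = False
    bootstrap_reps: int = 1000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fastas"] = dict(self.fastas)
        d["exclude_groups"] = list(self.exclude_groups)
        return d


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _opportunity_table(meta: pd.DataFrame, segments: Sequence[str]) -> OpportunityTable:
    """Pairing opportunities from metadata; ingroup strains only.

    With a single panel every segment maps to it; otherwise segment ids must
    be suffix-matched to panel ids via a `segment_panel` column, which the
    synthetic generator always writes a single panel for.
    """
    ingroup = meta[~meta["is_outgroup"]]
    panel_groups = {
        panel: sub.groupby("group").size().to_dict()
        for panel, sub in ingroup.groupby("panel_id")
    }
    panels = sorted(panel_groups)
    if len(panels) == 1:
        segment_panel = {s: panels[0] for s in segments}
    else:
        raise ValueError(
            "multiple panels in metadata; per-segment panel assignment is "
            "only supported via per-segment metadata subsets"
        )
    return opportunities(panel_groups, segment_panel)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = read_metadata(cfg.metadata)
    report: dict = {"seed": cfg.seed, "segments": sorted(cfg.fastas)}

    # stage 1: detection per segment
    fragments: list[ConversionFragment] = []
    alignments = {}
    for seg in sorted(cfg.fastas):
        try:
            aln = read_grouped_alignment(cfg.fastas[seg], meta, seg)
            alignments[seg] = aln
            proj = project_polymorphic(aln)
            det_cfg = DetectorConfig(
                gscale=cfg.gscale,
                n_permutations=cfg.n_permutations,
                alpha=cfg.alpha,
                seed=cfg.seed,
            )
            fragments.extend(detect_fragments(proj, aln.groups, det_cfg))
        except Exception as exc:
            raise RuntimeError(f"stage detect failed on segment {seg}: {exc}") from exc
    frag_df = pd.DataFrame(
        fragments_to_rows(fragments),
        columns=[
            "segment_id",
            "start",
            "end",
            "pair",
            "score",
            "p_global",
            "psite_start",
            "psite_end",
            "category",
        ],
    )
    frag_df.to_csv(outdir / "fragments.tsv", sep="\t", index=False)
    report["n_fragments"] = len(fragments)

    opp = _opportunity_table(meta, sorted(cfg.fastas))

    # stages 2-4 per tier: enumeration, exchange test, inter/intra comparison
    report["tiers"] = {}
    for tier in (1, 2, 3):
        ev = tier_events(fragments, tier)
        rows = [
            {"segment_id": seg, "category": cat, "count": n}
            for (seg, cat), n in sorted(ev.counts.items())
        ]
        pd.DataFrame(rows, columns=["segment_id", "category", "count"]).to_csv(
            outdir / f"tier{tier}_counts.tsv", sep="\t", index=False
        )
        _write_json(
            outdir / f"tier{tier}_provenance.json",
            {k: list(v) for k, v in ev.provenance.items()},
        )
        tier_report: dict = {
            "total": ev.total(),
            "total_inter": ev.total(inter_only=True),
        }
        try:
            if ev.total(inter_only=True) > 0:
                ex = simulate_null(
                    ev,
                    opp,
                    n_sims=cfg.n_sims,
                    seed=cfg.seed,
                    exclude_groups=cfg.exclude_groups,
                )
                _write_json(outdir / f"exchange_tier{tier}.json", ex.to_dict())
                tier_report["exchange"] = ex.to_dict()
        except Exception as exc:
            raise RuntimeError(f"stage exchange-test failed at tier {tier}: {exc}") from exc
        # inter vs intra with opportunities summed over segments
        o_by_cat = ev.by_category()
        o_inter = sum(n for c, n in o_by_cat.items() if is_inter(c))
        o_intra = ev.total() - o_inter
        excl = set(cfg.exclude_groups)
        n_intra = n_inter = 0
        for seg in sorted(cfg.fastas):
            panel = opp.panel_for(seg)
            for cat, n in opp.pair_counts[panel].items():
                if set(category_groups(cat)) & excl:
                    continue
                if is_inter(cat):
                    n_inter += n
                else:
                    n_intra += n
        if o_intra + o_inter > 0:
            try:
                ii = inter_vs_intra(
                    o_intra, o_inter, n_intra, n_inter, rounding=cfg.rounding
                )
                _write_json(outdir / f"intra_inter_tier{tier}.json", ii.to_dict())
                tier_report["inter_vs_intra"] = ii.to_dict()
            except ValueError as exc:
                logger.warning("inter/intra test skipped at tier %d: %s", tier, exc)
        report["tiers"][str(tier)] = tier_report

    # stage 5 (optional): masked alignments and bootstrapped NJ trees
    if cfg.build_trees:
        for seg, aln in alignments.items():
            try:
                seg_frags = [f for f in fragments if f.segment_id == seg]
                masked = mask_fragments(aln, seg_frags)
                write_grouped_alignment(masked, outdir / f"masked_{seg}.fasta")
                tree = bootstrap_support(
                    masked,
                    outgroup=aln.outgroup,
                    n_reps=cfg.bootstrap_reps,
                    seed=cfg.seed,
                    cap_saturated=True,
                )
                write_tree(tree, outdir / f"tree_{seg}.nwk")
            except Exception as exc:
                raise RuntimeError(f"stage tree failed on segment {seg}: {exc}") from exc
        report["trees"] = [f"tree_{seg}.nwk" for seg in sorted(alignments)]

    # outdir is implied by the manifest's own location; leaving it out keeps
    # reruns into different directories byte-identical
    cfg_dict = {k: v for k, v in cfg.to_dict().items() if k != "outdir"}
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "phyloconv_version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    _write_json(outdir / "manifest.json", manifest)
    _write_json(outdir / "report.json", report)
    return report
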