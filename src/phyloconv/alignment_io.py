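"""Grouped segment alignments: reading, validation, and masking of converted regions.

A *grouped alignment* is one aligned chromosome segment with one sequence per
strain, where every strain carries a phylogroup label (A, B1, B2, D, E, ...)
and at most one strain per panel is flagged as the outgroup used for tree
rooting.  Coordinates throughout the package are 0-based half-open on
alignment columns.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .conversion_detect import ConversionFragment

VALID_RESIDUES = frozenset("ACGT-N")

METADATA_COLUMNS = ("strain_id", "group", "panel_id", "is_outgroup")


@dataclasses.dataclass(frozen=True)
class GroupedAlignment:
    """One aligned segment with per-strain phylogroup labels.

    Parameters
    ----------
    segment_id
        Identifier of the chromosome segment this alignment covers.
    sequences
        Mapping strain id -> aligned residue string over ``A C G T - N``.
    groups
        Mapping strain id -> phylogroup label; must cover every strain.
    outgroup
        Strain id of the rooting outgroup, or ``None``.  The outgroup is
        excluded from polymorphism calling and conversion scanning.
    panel_id
        Identifier of the strain panel the segment was sequenced in (segments
        sequenced in different strain panels have different pairing
        opportunity counts).
    """

    segment_id: str
    sequences: Mapping[str, str]
    groups: Mapping[str, str]
    outgroup: str | None = None
    panel_id: str = "panel1"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"segment {self.segment_id}: empty alignment")
        lengths = {s: len(seq) for s, seq in self.sequences.items()}
        ref_len = next(iter(lengths.values()))
        if ref_len < 1:
            raise ValueError(f"segment {self.segment_id}: zero-length alignment")
        for strain, n in lengths.items():
            if n != ref_len:
                raise ValueError(
                    f"segment {self.segment_id}: strain {strain!r} has length "
                    f"{n}, expected {ref_len}"
                )
        for strain, seq in self.sequences.items():
            bad = set(seq) - VALID_RESIDUES
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValueError(
                    f"segment {self.segment_id}: strain {strain!r} has unknown "
                    f"residue {seq[pos]!r} at column {pos}"
                )
        missing = set(self.sequences) - set(self.groups)
        if missing:
            raise ValueError(
                f"segment {self.segment_id}: strains without group label: "
                f"{sorted(missing)}"
            )
        if self.outgroup is not None and self.outgroup not in self.sequences:
            raise ValueError(
                f"segment {self.segment_id}: outgroup {self.outgroup!r} not in alignment"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def ingroup_strains(self) -> list[str]:
        """Strain ids excluding the outgroup, in sorted order."""
        return sorted(s for s in self.sequences if s != self.outgroup)

    def group_sizes(self, include_outgroup: bool = False) -> dict[str, int]:
        """Number of strains per group label."""
        sizes: dict[str, int] = {}
        for strain in self.sequences:
            if strain == self.outgroup and not include_outgroup:
                continue
            g = self.groups[strain]
            sizes[g] = sizes.get(g, 0) + 1
        return sizes


def read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    """Read the strain metadata TSV (strain_id, group, panel_id, is_outgroup).

    Enforces unique strain ids, nonempty group labels and at most one
    outgroup per panel.
    """
    df = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = set(METADATA_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    if df["strain_id"].duplicated().any():
        dup = df.loc[df["strain_id"].duplicated(), "strain_id"].iloc[0]
        raise ValueError(f"duplicate strain_id in metadata: {dup!r}")
    if df["group"].isna().any() or (df["group"].str.len() == 0).any():
        raise ValueError("metadata contains empty group labels")
    df["is_outgroup"] = df["is_outgroup"].str.lower().isin({"1", "true", "yes"})
    for panel, sub in df.groupby("panel_id"):
        if int(sub["is_outgroup"].sum()) > 1:
            raise ValueError(f"panel {panel!r} has more than one outgroup")
    return df


def read_grouped_alignment(
    fasta_path: str | Path,
    metadata_path: str | Path | pd.DataFrame,
    segment_id: str,
    panel_id: str | None = None,
) -> GroupedAlignment:
    """Read one segment's aligned multi-FASTA plus strain metadata.

    FASTA record ids must match metadata ``strain_id`` values; strains listed
    in the metadata but absent from the FASTA are dropped (the panels differ
    between segments in real data).  A FASTA record without metadata is a
    hard error, as is any length mismatch or unknown residue.
    """
    meta = (
        metadata_path
        if isinstance(metadata_path, pd.DataFrame)
        else read_metadata(metadata_path)
    )
    if panel_id is not None:
        meta = meta[meta["panel_id"] == panel_id]
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records")
    known = set(meta["strain_id"])
    unknown = set(records) - known
    if unknown:
        raise ValueError(
            f"segment {segment_id}: strains in FASTA but not metadata: {sorted(unknown)}"
        )
    meta_present = meta[meta["strain_id"].isin(records)]
    groups = dict(zip(meta_present["strain_id"], meta_present["group"]))
    out_rows = meta_present.loc[meta_present["is_outgroup"], "strain_id"]
    outgroup = out_rows.iloc[0] if len(out_rows) else None
    panels = meta_present["panel_id"].unique()
    if len(panels) != 1:
        raise ValueError(
            f"segment {segment_id}: strains span multiple panels {sorted(panels)}; "
            "pass panel_id explicitly"
        )
    return GroupedAlignment(
        segment_id=segment_id,
        sequences=records,
        groups=groups,
        outgroup=outgroup,
        panel_id=str(panels[0]),
    )


def write_grouped_alignment(aln: GroupedAlignment, fasta_path: str | Path) -> None:
    """Write the alignment as multi-FASTA, strains in sorted order."""
    recs = [
        SeqRecord(Seq(aln.sequences[s]), id=s, description="")
        for s in sorted(aln.sequences)
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")


def mask_fragments(
    aln: GroupedAlignment, fragments: Iterable["ConversionFragment"]
) -> GroupedAlignment:
    """Replace converted tracts with gap characters in both strains of each pair.

    For every fragment, residues of both implicated strains over
    ``[start, end)`` become ``'-'``; downstream complete-deletion distance
    computation then drops those columns, removing the converted signal from
    trees.  Returns a new alignment; the input is not modified.
    """
    masked = {s: list(seq) for s, seq in aln.sequences.items()}
    for frag in fragments:
        if frag.segment_id != aln.segment_id:
            raise ValueError(
                f"fragment segment {frag.segment_id!r} != alignment "
                f"{aln.segment_id!r}"
            )
        if not (0 <= frag.start < frag.end <= aln.length):
            raise ValueError(
                f"fragment interval [{frag.start}, {frag.end}) outside "
                f"alignment of length {aln.length}"
            )
        for strain in frag.pair:
            if strain not in masked:
                raise ValueError(f"fragment strain {strain!r} not in alignment")
            seq = masked[strain]
            for col in range(frag.start, frag.end):
                seq[col] = "-"
    return dataclasses.replace(
        aln, sequences={s: "".join(chars) for s, chars in masked.items()}
    )
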