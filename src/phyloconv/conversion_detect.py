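"""GENECONV-style detection of gene-conversion fragments between strain pairs.

The detector works on the polymorphic columns of a grouped alignment.  For
every unordered pair of ingroup strains it builds a match/mismatch profile
over those columns, scores runs of agreement (+1 per matching site, an
integer penalty per mismatching site scaled by the ``gscale`` parameter g),
and extracts all maximal scoring subsequences in the Ruzzo–Tompa sense.
Unusually long runs of agreement between two diverged strains are the
signature of a converted (recombined) tract.

Significance is assessed globally by column permutation: each replicate
shuffles the order of the polymorphic columns jointly for all strains
(preserving the site-frequency spectrum), and the maximum fragment score
over *all* pairs is recorded.  A fragment's p-value is the (pseudocounted)
fraction of replicates whose maximum score reaches its observed score, which
corrects for the number of pairs scanned.

This is a faithful-in-spirit reimplementation of the published GENECONV
approach (global fragments, gscale mismatch penalties, permutation nulls),
not a bit-compatible clone of the original binary, whose exact internal
penalty function is not public in closed form.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numba
import numpy as np

from .alignment_io import GroupedAlignment

logger = logging.getLogger(__name__)

# profile codes
MATCH: int = 1
MISMATCH: int = 0
SKIP: int = -1

_RESIDUE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": -1, "N": -1}


def pair_category(g1: str, g2: str) -> str:
    """Category label for a strain pair: ``intra:<g>`` or ``inter:<g1>|<g2>``."""
    if g1 == g2:
        return f"intra:{g1}"
    a, b = sorted((g1, g2))
    return f"inter:{a}|{b}"


def is_inter(category: str) -> bool:
    return category.startswith("inter:")


def category_groups(category: str) -> tuple[str, ...]:
    """The group label(s) a category refers to."""
    kind, _, rest = category.partition(":")
    return tuple(rest.split("|")) if kind == "inter" else (rest,)


@dataclasses.dataclass(frozen=True)
class PolymorphicProjection:
    """Ingroup alignment condensed to its polymorphic columns.

    ``site_columns[j]`` is the alignment column of polymorphic site ``j``;
    ``site_matrix[i, j]`` the residue code of strain ``strains[i]`` there
    (0..3 for A/C/G/T, -1 for gap or N).
    """

    segment_id: str
    strains: tuple[str, ...]
    site_columns: np.ndarray  # (n_sites,) int64, strictly increasing
    site_matrix: np.ndarray  # (n_strains, n_sites) int8

    @property
    def n_sites(self) -> int:
        return int(self.site_columns.size)

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"strain {strain!r} not in projection") from None


@dataclasses.dataclass(frozen=True)
class ConversionFragment:
    """A detected converted tract between one strain pair in one segment.

    ``start``/``end`` are 0-based half-open alignment columns; ``psite_*``
    the corresponding half-open interval in polymorphic-site index space.
    ``category`` is ``intra:<g>`` when both strains share a group label,
    ``inter:<g1>|<g2>`` otherwise.
    """

    segment_id: str
    pair: tuple[str, str]  # sorted
    start: int
    end: int
    psite_start: int
    psite_end: int
    score: int
    p_global: float
    category: str

    def __post_init__(self) -> None:
        if self.pair != tuple(sorted(self.pair)):
            object.__setattr__(self, "pair", tuple(sorted(self.pair)))
        if not (self.start < self.end and self.psite_start < self.psite_end):
            raise ValueError("fragment intervals must be nonempty")
        if self.score <= 0:
            raise ValueError("fragment score must be positive")
        if not 0.0 <= self.p_global <= 1.0:
            raise ValueError("p_global outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class DetectorConfig:
    """Detector settings.

    gscale
        Mismatch-penalty scale g >= 0; g = 0 forbids mismatches inside
        fragments.  The published analyses use g = 1.
    n_permutations
        Column-permutation replicates for the global null (default 10,000).
    alpha
        Significance level on the global permutation p-value.
    seed
        RNG seed for the permutation null.
    """

    gscale: float = 1.0
    n_permutations: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gscale < 0:
            raise ValueError("gscale must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def encode_sequences(aln: GroupedAlignment, strains: Sequence[str]) -> np.ndarray:
    """Residues of the given strains as an int8 matrix (gap/N -> -1)."""
    lut = np.full(128, -1, dtype=np.int8)
    for res, code in _RESIDUE_CODE.items():
        lut[ord(res)] = code
    rows = [
        lut[np.frombuffer(aln.sequences[s].encode("ascii"), dtype=np.uint8)]
        for s in strains
    ]
    return np.vstack(rows)


def project_polymorphic(aln: GroupedAlignment) -> PolymorphicProjection:
    """Condense an alignment to columns polymorphic among ingroup strains.

    A column is polymorphic when it carries >= 2 distinct non-gap residues
    among the ingroup; the outgroup is ignored, serving only tree rooting.
    """
    strains = tuple(aln.ingroup_strains)
    if len(strains) < 2:
        raise ValueError("need >= 2 ingroup strains to call polymorphisms")
    mat = encode_sequences(aln, strains)
    # distinct non-gap states per column
    n_states = np.zeros(mat.shape[1], dtype=np.int8)
    for code in range(4):
        n_states += (mat == code).any(axis=0)
    keep = np.flatnonzero(n_states >= 2)
    return PolymorphicProjection(
        segment_id=aln.segment_id,
        strains=strains,
        site_columns=keep.astype(np.int64),
        site_matrix=np.ascontiguousarray(mat[:, keep]),
    )


def pair_profile(proj: PolymorphicProjection, s_i: str, s_j: str) -> np.ndarray:
    """Match/mismatch/skip codes for one strain pair over polymorphic sites.

    Returns an int8 vector of length ``proj.n_sites`` with values MATCH (1)
    where both residues are non-gap and equal, MISMATCH (0) where non-gap and
    unequal, SKIP (-1) where either is gap/N.  Downstream scoring drops SKIP
    entries; ``np.flatnonzero(profile != SKIP)`` is the retained map back to
    polymorphic-site indices.
    """
    a = proj.site_matrix[proj.strain_index(s_i)]
    b = proj.site_matrix[proj.strain_index(s_j)]
    return _profile_from_rows(a, b)


def _profile_from_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.where(a == b, MATCH, MISMATCH).astype(np.int8)
    out[(a < 0) | (b < 0)] = SKIP
    return out


def mismatch_penalty(g: float, k: int, m: int) -> int | None:
    """Per-mismatch penalty B = ceil(g*k/m); None means mismatches forbidden.

    k and m are the pair's total match and mismatch counts.  The ceiling
    guarantees the expected per-site score drift under column shuffling is
    <= 0, so maximal segments do not grow without bound.
    """
    if m == 0 or g == 0:
        return None
    return math.ceil(g * k / m)


def _score_values(profile: np.ndarray, g: float) -> tuple[np.ndarray, np.ndarray]:
    """(unskipped site-index map, integer score per unskipped entry)."""
    kept = np.flatnonzero(profile != SKIP)
    sub = profile[kept]
    k = int((sub == MATCH).sum())
    m = int(sub.size - k)
    B = mismatch_penalty(g, k, m)
    if B is None:
        B = k + 1  # exceeds any achievable run: acts as a terminator
    scores = np.where(sub == MATCH, 1, -B).astype(np.int64)
    return kept, scores


def ruzzo_tompa(scores: Sequence[float]) -> list[tuple[int, int, float]]:
    """All maximal scoring subsequences of a score sequence.

    Returns disjoint half-open intervals ``(start, end, score)`` in input
    order, each with positive score, none extendable or subdividable to a
    higher score.
    """
    stack: list[list[float]] = []  # [start, end, cum_left, cum_right]
    cum = 0.0
    for i, s in enumerate(scores):
        left = cum
        cum += s
        if s <= 0:
            continue
        k = [i, i + 1, left, cum]
        while True:
            j = None
            for idx in range(len(stack) - 1, -1, -1):
                if stack[idx][2] < k[2]:
                    j = idx
                    break
            if j is None or stack[j][3] >= k[3]:
                stack.append(k)
                break
            k = [stack[j][0], k[1], stack[j][2], k[3]]
            del stack[j:]
    return [(int(a), int(b), r - l) for a, b, l, r in stack]


def max_scoring_fragments(
    profile: np.ndarray, g: float
) -> list[tuple[int, int, int]]:
    """Maximal-scoring fragments of one pair profile.

    Each fragment is ``(start, end, score)`` with the half-open interval in
    the index space of the *unskipped* profile (SKIP entries removed).  With
    k total matches and m mismatches the per-mismatch penalty is
    ``ceil(g*k/m)``; when g = 0 or m = 0 mismatches terminate fragments.
    """
    if profile.size == 0:
        raise ValueError("empty profile")
    _, scores = _score_values(np.asarray(profile, dtype=np.int8), g)
    return [(a, b, int(s)) for a, b, s in ruzzo_tompa(scores.tolist())]


@numba.njit(cache=True)
def _null_pair_max_scores(score_matrix, n_reps, seed):  # pragma: no cover - jitted
    """Per-pair max fragment score for each column-permutation replicate.

    Each replicate applies one Fisher-Yates shuffle of the site order,
    shared by all pairs; the max fragment score per pair is the max-subarray
    score of its permuted score vector (SKIP sites score 0, which leaves
    subarray maxima unchanged).
    """
    n_pairs, n_sites = score_matrix.shape
    out = np.zeros((n_reps, n_pairs), dtype=np.int64)
    order = np.arange(n_sites)
    np.random.seed(seed)
    for r in range(n_reps):
        for t in range(n_sites - 1, 0, -1):
            u = np.random.randint(0, t + 1)
            tmp = order[t]
            order[t] = order[u]
            order[u] = tmp
        for p in range(n_pairs):
            cur = np.int64(0)
            best = np.int64(0)
            for t in range(n_sites):
                cur += score_matrix[p, order[t]]
                if cur < 0:
                    cur = 0
                elif cur > best:
                    best = cur
            out[r, p] = best
    return out


def detect_fragments(
    proj: PolymorphicProjection,
    groups: Mapping[str, str],
    cfg: DetectorConfig,
) -> list[ConversionFragment]:
    """Detect significant conversion fragments among all ingroup pairs.

    For each unordered pair the maximal fragments are computed.  The null is
    built from ``cfg.n_permutations`` joint column shuffles; because pairs of
    different divergence have incomparable raw score scales (a near-identical
    pair's null maxima dwarf a diverged pair's strongest real signal), each
    pair's max score is standardized by its own permutation-null mean and sd,
    and the global null statistic is the max *standardized* score over all
    pairs.  A fragment is reported when
    ``p_global = (1 + #{null max-z >= fragment z}) / (n_permutations + 1)``
    is at most ``cfg.alpha``.  Fragment intervals are mapped back to
    alignment columns as [column of first site, column of last site + 1).
    """
    if proj.n_sites == 0:
        logger.info(
            "segment %s: no polymorphic sites, nothing to detect", proj.segment_id
        )
        return []
    strains = proj.strains
    pairs = [
        (strains[i], strains[j])
        for i in range(len(strains))
        for j in range(i + 1, len(strains))
    ]
    # per-pair score vectors over the full site axis; SKIP scored 0, which is
    # neutral for maximum-subarray scores, so the shared column permutation
    # can be applied to all pairs at once
    score_matrix = np.zeros((len(pairs), proj.n_sites), dtype=np.int64)
    observed: list[tuple[int, tuple[str, str], list[tuple[int, int, int]], np.ndarray]] = []
    for p_idx, (si, sj) in enumerate(pairs):
        profile = pair_profile(proj, si, sj)
        kept, scores = _score_values(profile, cfg.gscale)
        score_matrix[p_idx, kept] = scores
        frags = [(a, b, int(s)) for a, b, s in ruzzo_tompa(scores.tolist())]
        observed.append((p_idx, (si, sj), frags, kept))

    pair_max = _null_pair_max_scores(
        score_matrix, cfg.n_permutations, np.uint32(cfg.seed)
    )  # (n_reps, n_pairs)
    mu = pair_max.mean(axis=0)
    # sd floor of 1 score unit: degenerate pairs (constant null max) would
    # otherwise blow up the standardization
    sd = np.maximum(pair_max.std(axis=0), 1.0)
    null_max_z = np.sort(((pair_max - mu) / sd).max(axis=1))

    results: list[ConversionFragment] = []
    denom = cfg.n_permutations + 1
    for p_idx, (si, sj), frags, kept in observed:
        for a, b, score in frags:
            z = (score - mu[p_idx]) / sd[p_idx]
            n_ge = cfg.n_permutations - int(
                np.searchsorted(null_max_z, z, side="left")
            )
            p = (1 + n_ge) / denom
            if p > cfg.alpha:
                continue
            ps_start = int(kept[a])
            ps_end = int(kept[b - 1]) + 1
            results.append(
                ConversionFragment(
                    segment_id=proj.segment_id,
                    pair=tuple(sorted((si, sj))),
                    start=int(proj.site_columns[ps_start]),
                    end=int(proj.site_columns[ps_end - 1]) + 1,
                    psite_start=ps_start,
                    psite_end=ps_end,
                    score=score,
                    p_global=p,
                    category=pair_category(groups[si], groups[sj]),
                )
            )
    results.sort(key=lambda f: (f.segment_id, f.pair, f.start, f.end))
    return results


def fragments_to_rows(fragments: Iterable[ConversionFragment]) -> list[dict]:
    """Fragments as flat dicts for a BED-like TSV (0-based half-open)."""
    return [
        {
            "segment_id": f.segment_id,
            "start": f.start,
            "end": f.end,
            "pair": f"{f.pair[0]},{f.pair[1]}",
            "score": f.score,
            "p_global": f.p_global,
            "psite_start": f.psite_start,
            "psite_end": f.psite_end,
            "category": f.category,
        }
        for f in fragments
    ]


def read_fragments_tsv(path) -> list[ConversionFragment]:
    """Read fragments back from the BED-like TSV written by the pipeline."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"segment_id": str})
    out = []
    for row in df.itertuples(index=False):
        pair = tuple(sorted(str(row.pair).split(",")))
        out.append(
            ConversionFragment(
                segment_id=row.segment_id,
                pair=pair,  # type: ignore[arg-type]
                start=int(row.start),
                end=int(row.end),
                psite_start=int(row.psite_start),
                psite_end=int(row.psite_end),
                score=int(row.score),
                p_global=float(row.p_global),
                category=str(row.category),
            )
        )
    return out
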