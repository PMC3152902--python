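import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyloconv import (
    DetectorConfig,
    GeneratorConfig,
    GroupedAlignment,
    PlantedEvent,
    detect_fragments,
    generate_panel,
    max_scoring_fragments,
    pair_profile,
    project_polymorphic,
    ruzzo_tompa,
)
from phyloconv.conversion_detect import MATCH, MISMATCH, SKIP, mismatch_penalty

from conftest import brute_force_mss


def aln_from_columns(cols, groups=None, **kw):
    """Build an alignment from per-column residue strings (one char per strain)."""
    n = len(cols[0])
    seqs = {f"s{i+1}": "".join(col[i] for col in cols) for i in range(n)}
    groups = groups or {s: "A" for s in seqs}
    return GroupedAlignment(segment_id="seg1", sequences=seqs, groups=groups, **kw)


class TestProjection:
    def test_monomorphic_alignment_has_no_sites(self):
        aln = aln_from_columns(["AAA", "CCC", "TTT"])
        assert project_polymorphic(aln).n_sites == 0

    def test_single_non_gap_state_column_excluded(self):
        # columns: AAA (mono), ACA (poly), GG- (one non-gap state), TTT (mono)
        aln = aln_from_columns(["AAA", "ACA", "GG-", "TTT"])
        proj = project_polymorphic(aln)
        assert proj.site_columns.tolist() == [1]

    def test_outgroup_excluded_from_polymorphism_call(self):
        # only the outgroup differs at column 0
        aln = aln_from_columns(
            ["AAG", "ACC"],
            groups={"s1": "A", "s2": "A", "s3": "O"},
            outgroup="s3",
        )
        proj = project_polymorphic(aln)
        assert proj.site_columns.tolist() == [1]
        assert proj.strains == ("s1", "s2")

    def test_matches_per_column_recount(self, small_panel):
        alignments, _ = small_panel
        aln = alignments[0]
        proj = project_polymorphic(aln)
        ingroup = [s for s in sorted(aln.sequences) if s != aln.outgroup]
        expected = []
        for col in range(aln.length):
            residues = {aln.sequences[s][col] for s in ingroup} - {"-", "N"}
            if len(residues) >= 2:
                expected.append(col)
        assert proj.site_columns.tolist() == expected


class TestPairProfile:
    def test_identical_strains_all_match(self):
        aln = aln_from_columns(["AC", "CA", "GG", "TA"])
        proj = project_polymorphic(aln)
        prof = pair_profile(proj, "s1", "s1")
        assert (prof == MATCH).all()

    def test_match_mismatch_skip_codes(self):
        # 4 polymorphic columns; s1=ACGT, s2=AC-A over them
        aln = aln_from_columns(["AAC", "CCA", "G-C", "TAG"])
        proj = project_polymorphic(aln)
        assert proj.n_sites == 4
        prof = pair_profile(proj, "s1", "s2")
        assert prof.tolist() == [MATCH, MATCH, SKIP, MISMATCH]

    def test_symmetry_and_conservation(self, small_panel):
        alignments, _ = small_panel
        proj = project_polymorphic(alignments[0])
        prof_ij = pair_profile(proj, "A_01", "B1_02")
        prof_ji = pair_profile(proj, "B1_02", "A_01")
        assert (prof_ij == prof_ji).all()
        n_match = int((prof_ij == MATCH).sum())
        n_mismatch = int((prof_ij == MISMATCH).sum())
        n_skip = int((prof_ij == SKIP).sum())
        assert n_match + n_mismatch + n_skip == proj.n_sites

    def test_unknown_strain_raises(self, small_panel):
        alignments, _ = small_panel
        proj = project_polymorphic(alignments[0])
        with pytest.raises(KeyError):
            pair_profile(proj, "A_01", "nope")


class TestRuzzoTompa:
    def test_all_match_single_fragment(self):
        prof = np.full(7, MATCH, dtype=np.int8)
        assert max_scoring_fragments(prof, 1.0) == [(0, 7, 7)]

    def test_gzero_mismatch_terminates(self):
        prof = np.array([MATCH, MATCH, MISMATCH, MATCH, MATCH], dtype=np.int8)
        assert max_scoring_fragments(prof, 0.0) == [(0, 2, 2), (3, 5, 2)]

    def test_penalty_formula(self):
        assert mismatch_penalty(1.0, 10, 3) == 4  # ceil(10/3)
        assert mismatch_penalty(1.0, 9, 3) == 3
        assert mismatch_penalty(0.0, 10, 3) is None
        assert mismatch_penalty(1.0, 10, 0) is None

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.sampled_from([1, 1, 1, -1, -2, -3]), min_size=1, max_size=20))
    def test_matches_brute_force_on_random_scores(self, scores):
        got = ruzzo_tompa(scores)
        want = brute_force_mss(scores)
        assert [(a, b, float(s)) for a, b, s in got] == want

    def test_fragment_endpoints_are_matches(self, small_panel_fragments, small_panel):
        alignments, _ = small_panel
        proj = project_polymorphic(alignments[0])
        for f in small_panel_fragments:
            prof = pair_profile(proj, *f.pair)
            assert prof[f.psite_start] == MATCH
            assert prof[f.psite_end - 1] == MATCH


class TestDetection:
    def test_no_polymorphism_empty(self):
        aln = aln_from_columns(["AA", "CC", "GG"])
        proj = project_polymorphic(aln)
        assert detect_fragments(proj, {"s1": "A", "s2": "A"}, DetectorConfig()) == []

    def test_planted_tract_recovered(self, small_panel, small_panel_fragments):
        _, truth = small_panel
        ev = truth.events[0]
        hits = [
            f
            for f in small_panel_fragments
            if f.category == "inter:A|B1" and f.start < ev.end and f.end > ev.start
        ]
        assert hits, "planted conversion not detected"
        assert all(f.p_global <= 0.05 for f in hits)

    def test_detection_symmetric_in_pair_order(self, small_panel_fragments):
        for f in small_panel_fragments:
            assert f.pair == tuple(sorted(f.pair))

    def test_determinism(self, small_panel, small_panel_fragments):
        alignments, _ = small_panel
        aln = alignments[0]
        proj = project_polymorphic(aln)
        again = detect_fragments(proj, aln.groups, DetectorConfig(n_permutations=300, seed=7))
        assert again == small_panel_fragments

    def test_single_permutation_tie_gives_p_one(self):
        # two identical strains: every permutation reproduces the observed
        # all-match maximum, so p = (1+1)/(1+1) = 1 and nothing is reported
        aln = aln_from_columns(
            ["AAC", "CCA", "GGT"], groups={"s1": "A", "s2": "A", "s3": "B1"}
        )
        proj = project_polymorphic(aln)
        cfg = DetectorConfig(n_permutations=1, alpha=0.999, seed=3)
        frags = detect_fragments(proj, aln.groups, cfg)
        pair_ps = {f.pair: f.p_global for f in frags}
        assert pair_ps.get(("s1", "s2"), 1.0) == 1.0

    def test_null_panels_rarely_yield_fragments(self):
        """Global correction keeps the panel-wise false-positive rate near alpha."""
        n_panels, hits = 50, 0
        for seed in range(n_panels):
            cfg = GeneratorConfig(
                groups={"A": 3, "B1": 3},
                n_segments=1,
                segment_length=4000,
                seed=1000 + seed,
            )
            alignments, _ = generate_panel(cfg)
            aln = alignments[0]
            proj = project_polymorphic(aln)
            frags = detect_fragments(
                proj, aln.groups, DetectorConfig(n_permutations=200, seed=seed)
            )
            hits += bool(frags)
        assert hits <= 7  # alpha=0.05 plus Monte-Carlo slack at n=50
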