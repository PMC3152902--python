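# Methods

`phyloconv` asks whether homologous recombination (gene conversion) between
bacterial phylogroups is random with respect to which groups exchange DNA.
Its model system is a panel of *E. coli*-like strains from a few deeply
separated phylogroups (A, B1, B2, D, E), each sequenced over a handful of
~23-kb backbone chromosome segments, with *E. albertii*-like material as an
outgroup. This note records the statistical model, the numerical choices,
and what the synthetic experiments do and do not demonstrate.

## Conversion fragment detection

Detection follows the classic polymorphism-run paradigm (as implemented in
tools such as GENECONV): only columns that are polymorphic among ingroup
strains carry information, so each segment alignment is condensed to its
polymorphic columns (≥ 2 distinct non-gap residues; the outgroup is
excluded from polymorphism calling and scanning). For every unordered strain
pair a profile over those sites is built — match, mismatch, or skip (either
residue a gap/N; skipped sites are removed from that pair's profile but a
map back to alignment columns is retained).

With k total matches and m mismatches for a pair, each match scores +1 and
each mismatch −B with

    B = ceil(g · k / m),

where g is the mismatch-penalty scale (`gscale`, default 1; g = 0 or m = 0
makes mismatches fragment-terminating). The ceiling guarantees the expected
per-site score drift under column shuffling is ≤ 0. All maximal scoring
subsequences in the Ruzzo–Tompa sense (disjoint, positive score, neither
extendable nor subdividable to a higher score) are the candidate fragments;
reported intervals span [column of first site, column of last site + 1), so
fragment endpoints are always matching sites.

**Null model and multiplicity.** Each of R permutation replicates (default
10,000) shuffles the *order* of the polymorphic columns once, jointly for
all strains, preserving the site-frequency spectrum; each pair's maximum
fragment score is recorded. Raw maxima are not comparable between pairs: a
near-identical intra-group pair (k/m ≈ 30) performs a near-driftless score
walk whose null maxima reach many hundreds, while a diverged cross-group
pair with a genuine 2-kb converted tract peaks around 250. Comparing every
fragment against the raw max-over-pairs null therefore has essentially no
power — this failure mode was observed directly on default synthetic panels
(0% recovery of planted 2–2.5 kb tracts). Each pair's scores are therefore
standardized by that pair's own null mean and standard deviation (sd floored
at 1 score unit to protect degenerate pairs), and the global null statistic
is the maximum standardized score over all pairs. A fragment with
standardized score z gets

    p_global = (1 + #{replicates with max-z ≥ z}) / (R + 1),

which retains the family-wide correction over all pairs scanned (the
analogue of a "global" fragment listing) and a pseudocount that avoids
p = 0. Fragments with p_global ≤ α (default 0.05) are reported. This
detector is faithful to the published approach in its inputs, penalty scale,
permutation null, and global correction, but it is not a bit-compatible
clone of the original binary, whose internal scoring is not public in
closed form; fragment lists may differ in detail.

A conversion event in one strain also creates clustered derived polymorphism
among the *other* strains of its group, which can surface as secondary
fragments in neighbouring pairs; this artefact is shared with the original
tool and is one reason the tiered counting below exists.

## Tiered event enumeration

Fragments are tallied per (segment, category), where a category is
`intra:g` or `inter:g1|g2` from the pair's group labels:

* **Tier 1** — every fragment is an independent event.
* **Tier 2** — fragments with identical (start, end) borders within one
  segment and category collapse to a single event, regardless of which
  strains carry them. Identical borders across strain pairs are the
  signature of one transfer into a common ancestor of the recipient group.
* **Tier 3** — at most one event per (segment, category) cell, the most
  conservative reading when overlapping fragments cannot be resolved into
  independent transfers.

Tier 1 ≥ tier 2 ≥ tier 3 holds cell-wise by construction and is
property-tested.

## Exchange test (proportional-opportunity null)

Under the null, every inter-group strain pairing of a segment's panel is
equally likely to host a conversion, so the expected count for category c is

    E_c = Σ_s T_s · w_s(c),   w_s(c) = n_c(panel(s)) / N_inter(panel(s)),

with T_s the segment's observed inter-group event total, n_c = n_g1·n_g2
the category's pairings, and N_inter the panel's total inter-group
pairings. Departure is measured by the Pearson score
X² = Σ_c (O_c − E_c)²/E_c (categories with E = 0 and O = 0 are skipped;
E = 0 with O > 0 is flagged and handled by the simulated tails only).
Because most cells are empty at these sample sizes, the asymptotic χ²
distribution is not used; instead each of n_sims replicates (default 10⁶)
redraws every segment's T_s events from a multinomial with probabilities
w_s(·), sums across segments, and recomputes X². The global p-value is the
plain proportion of replicates with simulated X² ≥ observed (minimum
reportable value 1/n_sims); per-category one-sided tails (p_over, p_under)
flag over/under-represented group pairs. Whether those per-pair tails should
be two-sided or multiplicity-corrected is left to the user; the reported
quantities are the raw one-sided simulated tails. A configurable group
exclusion list supports dropping sparsely sampled groups.

## Inter- vs intra-group comparison

The two-cell test splits T = O_intra + O_inter in proportion to the intra-
and inter-group pairing opportunities and computes a df = 1 chi-square with
a two-tailed upper-tail p-value. Two rounding modes exist because the
original analysis evidently rounded expected counts to integers before the
statistic — its printed chi-squares (1.415, 4.719, 6.786 from observed
40/95, 26/47, 10/9 against opportunities 258/772) are reproducible only
that way. `paper-compat` (default) rounds half-away-from-zero;
`none` keeps exact expecteds (giving 1.509, 4.342, 7.700) and is the
statistically preferable mode. The published opportunity totals (258, 772)
are taken as given inputs; in pipeline runs on new data the totals are the
panel pairing counts summed over segments.

## Trees and congruence

Distances are Kimura 2-parameter, d = −½·ln((1−2P−Q)·√(1−2Q)), with
complete deletion (every column containing any gap/N in any strain is
dropped — including masked conversion tracts, which is the point of
masking both members of each significant pair). Saturated pairs are a hard
error by default; an opt-in cap (d = 5.0) exists because silent capping
distorts trees. Neighbor joining uses the Saitou–Nei Q-criterion with
deterministic lexicographic tie-breaking on the smallest strain id per
cluster, so topology never depends on input order; trees are rooted at the
midpoint of the outgroup branch. Bootstrap support resamples
post-complete-deletion columns with replacement (default 1,000 replicates)
and reports, per internal node, the fraction of replicate trees containing
its bipartition.

Group-level congruence collapses every maximal monophyletic same-group
clade to a single leaf; groups failing monophyly are flagged paraphyletic
and contribute one leaf per maximal clade. Two collapsed topologies are
congruent iff their canonical forms (children sorted recursively) are
identical — equivalent to rooted Robinson–Foulds distance 0 over matched
leaf multisets. This is a precise surrogate for by-eye judgments of whether
"major branch points" coincide.

## Synthetic data generator

The generator emulates the study design, not bacterial population genetics:
a star phylogeny within and between groups. Per segment, a uniform-random
ancestral sequence spawns one founder per group by independent per-site
substitution at the inter-group rate; strains derive from founders at the
intra-group rate; the outgroup derives from the ancestor at 3× the
inter-group rate (a deeper split without a free parameter). Substitutions
are transitions with probability R/(R+1) for transition:transversion ratio
R, otherwise a uniform transversion — K2P-compatible, so distance estimates
are checkable against configured branch lengths.

Defaults (the study-scale conditions used throughout the tests): 5 groups
of 4 strains, 4 segments of 23,000 nt, inter-group divergence 0.02/site,
intra-group divergence 0.002/site, R = 2, one panel. Divergences were
chosen so that between-group distance (~4%) and within-group distance
(~0.4%) bracket typical *E. coli* backbone values; R = 2 is a standard
bacterial transition bias.

Planted conversions copy the donor-side tract over the recipient's:
`ancestral` timing edits the recipient founder before strain derivation
(all descendants inherit identical borders — the tier-2 duplicate
mechanism), `terminal` timing edits named strains after derivation. Ground
truth records realized borders, carriers, and the polymorphic sites inside
each tract; `truth_to_fragments` converts truth to oracle fragments so the
tier and exchange machinery can be tested independently of the detector.

What passing synthetic tests do **not** show: robustness to coalescent
within-group structure, indels, rate heterogeneity along the chromosome,
selection, or mobile-element turnover. The generator's block-like group
structure is deliberately favourable for detection; recovery rates on real
data will be lower at comparable tract lengths.

## Problem sizes used by the shipped experiments

Test-suite and acceptance-script experiment sizes are chosen to give stable
Monte-Carlo estimates at interactive runtimes: detector permutations R = 200–300
in experiments (CLI default 10,000), exchange simulations 10⁴ in experiments
(CLI default 10⁶), 25 panels × 4 planted tracts for recovery, 200 (tests) /
100 (script) panels for enrichment power, 500 null runs for calibration, and
50 small null panels for the detector's panel-wise false-positive rate. The
minimum reportable detector p at R = 300 is 1/301 ≈ 0.0033, comfortably
below α = 0.05.

## Known limitations

* The detector's fragment lists are not guaranteed to match the original
  binary's output on the same input; only the statistical behaviour
  (calibration, recovery under planted truth) is validated.
* Donor/recipient direction is not inferred; both members of a significant
  pair are masked before tree building.
* Expected-count rounding in `paper-compat` mode can make Σ E_c differ
  slightly from Σ O_c; it exists purely to reproduce the published
  statistics.
* Multi-panel metadata (different strain sets per segment) is supported in
  the data model, but the one-shot pipeline requires a single panel;
  per-segment runs cover the general case.
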