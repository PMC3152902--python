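"""Reference inputs from the published E. coli phylogroup exchange analysis.

These are the printed observed event counts and pairing-opportunity totals
of the original four-segment study, kept here so the statistics can be
recomputed from them directly (the underlying alignments are not publicly
accessioned).
"""

# (intra-group, inter-group) observed recombination events per tier
TIER_OBSERVED: dict[int, tuple[int, int]] = {
    1: (40, 95),
    2: (26, 47),
    3: (10, 9),
}

# strain-to-strain pairing opportunities: (intra-group, inter-group)
OPPORTUNITIES: tuple[int, int] = (258, 772)

# total inter-group pairings of the two strain panels (segments 1-2, 3-4)
PANEL_INTER_PAIRINGS: dict[str, int] = {"panelA": 166, "panelB": 292}
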