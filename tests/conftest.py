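import numpy as np
import pytest

from phyloconv import (
    DetectorConfig,
    GeneratorConfig,
    PlantedEvent,
    detect_fragments,
    generate_panel,
    project_polymorphic,
)


@pytest.fixture(scope="session")
def small_panel():
    """One 6-kb segment, two groups of three strains, one planted terminal
    A->B1 conversion of 2 kb."""
    cfg = GeneratorConfig(
        groups={"A": 3, "B1": 3},
        n_segments=1,
        segment_length=6000,
        planted_events=(
            PlantedEvent(0, "A", "B1", 2000, 4000, "terminal", ("B1_01",)),
        ),
        seed=42,
    )
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def small_panel_fragments(small_panel):
    alignments, _ = small_panel
    aln = alignments[0]
    proj = project_polymorphic(aln)
    cfg = DetectorConfig(n_permutations=300, seed=7)
    return detect_fragments(proj, aln.groups, cfg)


def brute_force_mss(scores):
    """Independent enumeration oracle for maximal scoring subsequences.

    A half-open interval [i, j) qualifies when its cumulative-sum walk has a
    unique minimum at i and a unique maximum at j (every proper prefix and
    suffix scores strictly positive); the maximal ones are those not properly
    contained in another qualifying interval.
    """
    n = len(scores)
    c = np.concatenate([[0.0], np.cumsum(scores)])
    cands = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            if c[j] - c[i] <= 0:
                continue
            if all(c[k] > c[i] for k in range(i + 1, j + 1)) and all(
                c[k] < c[j] for k in range(i, j)
            ):
                cands.append((i, j, float(c[j] - c[i])))
    return [
        x
        for x in cands
        if not any(
            a <= x[0] and x[1] <= b and (a, b) != (x[0], x[1])
            for a, b, _ in cands
        )
    ]
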