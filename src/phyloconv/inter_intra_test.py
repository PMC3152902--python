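"""Two-cell chi-square comparison of inter- vs intra-group recombination.

Observed intra- and inter-group event counts are compared against expected
counts proportional to the pairing opportunities (how many intra-group vs
inter-group strain pairs the panels offer), with a 1-df chi-square
approximate two-tailed p-value.

Two rounding modes are provided.  The original analysis evidently rounded the
expected counts to integers before computing the statistic — its printed
chi-squares are only reproducible that way — so "paper-compat" (the default)
does the same; "none" keeps the expecteds exact, which is statistically
preferable and also reported.
"""

from __future__ import annotations

import dataclasses

from scipy import stats


@dataclasses.dataclass(frozen=True)
class ChiSquareResult:
    observed: tuple[int, int]  # (intra, inter)
    expected: tuple[float, float]
    chi_square: float
    df: int
    p_two_tailed: float
    rounding: str

    def to_dict(self) -> dict:
        return {
            "observed_intra": self.observed[0],
            "observed_inter": self.observed[1],
            "expected_intra": self.expected[0],
            "expected_inter": self.expected[1],
            "chi_square": self.chi_square,
            "df": self.df,
            "p_two_tailed": self.p_two_tailed,
            "rounding": self.rounding,
        }


def inter_vs_intra(
    o_intra: int,
    o_inter: int,
    n_intra_opportunities: int,
    n_inter_opportunities: int,
    rounding: str = "paper-compat",
) -> ChiSquareResult:
    """Chi-square (df=1) test of inter- vs intra-group exchange frequency.

    With T = o_intra + o_inter total events, the expecteds split T in
    proportion to the opportunity counts: E_intra = T * n_intra / (n_intra +
    n_inter), E_inter = T - E_intra.  In paper-compat mode both expecteds are
    rounded to the nearest integer (half away from zero) before the
    statistic.  The p-value is the upper chi-square(1) tail at X^2.
    """
    if rounding not in {"none", "paper-compat"}:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    if min(o_intra, o_inter) < 0:
        raise ValueError("observed counts must be non-negative")
    if n_intra_opportunities <= 0 or n_inter_opportunities <= 0:
        raise ValueError("opportunity counts must be positive")
    total = o_intra + o_inter
    if total == 0:
        raise ValueError("no observed events")
    n_opp = n_intra_opportunities + n_inter_opportunities
    e_intra = total * n_intra_opportunities / n_opp
    e_inter = total - e_intra
    if rounding == "paper-compat":
        e_intra = float(int(e_intra + 0.5))
        e_inter = float(int(e_inter + 0.5))
        if e_intra == 0 or e_inter == 0:
            raise ValueError(
                "rounded expected count of 0; rerun with rounding='none'"
            )
    x2 = (o_intra - e_intra) ** 2 / e_intra + (o_inter - e_inter) ** 2 / e_inter
    p = float(stats.chi2.sf(x2, df=1))
    return ChiSquareResult(
        observed=(o_intra, o_inter),
        expected=(e_intra, e_inter),
        chi_square=float(x2),
        df=1,
        p_two_tailed=p,
        rounding=rounding,
    )
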