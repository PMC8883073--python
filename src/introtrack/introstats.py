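"""Segregation expectations and distortion tests for introgression populations.

For a single unlinked locus, the genotype distribution over {A, H, B}
(donor homozygote, heterozygote, recipient homozygote) follows exactly from
the crossing scheme: the F1 is pure H, a backcross to the recipient maps
each gamete against a recipient gamete, and a selfing applies the Mendelian
transition A -> A, H -> 1/4 A + 1/2 H + 1/4 B, B -> B.  For the standard
BC1S1 scheme this gives A:B:H = 1:5:2 and a donor-allele (Ar genotype)
frequency of 25%.

Observed matrices are compared to these expectations with a Pearson
chi-square over genotype classes, and per-marker distortion is flagged with
an exact binomial test on donor-allele counts, Bonferroni-corrected.
Missing calls are excluded from every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MarkerGenotypeMatrix
from .simulate import CrossSpec

__all__ = [
    "GenotypeCounts",
    "SegregationExpectation",
    "expected_segregation",
    "ar_frequency",
    "segregation_test",
    "donor_coverage",
    "donor_coverage_by_line",
    "flag_distorted_markers",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype-class counts in some scope (whole matrix, one marker, one line)."""

    n_A: int
    n_B: int
    n_H: int
    n_D: int = 0
    scope: str = "matrix"

    def __post_init__(self):
        if min(self.n_A, self.n_B, self.n_H, self.n_D) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_called(self) -> int:
        return self.n_A + self.n_B + self.n_H

    @property
    def total(self) -> int:
        return self.n_called + self.n_D

    @classmethod
    def from_matrix(cls, matrix: MarkerGenotypeMatrix) -> "GenotypeCounts":
        c = matrix.counts()
        return cls(c["A"], c["B"], c["H"], c["D"], scope="matrix")

    def proportions(self) -> dict[str, float]:
        """Proportions of A, B, H over non-missing calls."""
        if self.n_called == 0:
            raise ValueError("no non-missing calls in scope")
        return {k: getattr(self, f"n_{k}") / self.n_called for k in ("A", "B", "H")}


@dataclass(frozen=True)
class SegregationExpectation:
    """Exact single-locus genotype probabilities under a crossing scheme."""

    p_A: Fraction
    p_B: Fraction
    p_H: Fraction

    def __post_init__(self):
        if self.p_A + self.p_B + self.p_H != 1:
            raise ValueError("genotype probabilities must sum to 1")

    @property
    def f_star(self) -> Fraction:
        """Theoretical donor-genotype (Ar) frequency: p_A + p_H / 2."""
        return self.p_A + self.p_H / 2


def expected_segregation(spec: CrossSpec | Iterable[str]) -> SegregationExpectation:
    """Propagate a genotype probability vector through the crossing steps.

    Returns exact rationals.  Rejects specs with selection entries: the
    expectation here is the neutral (selection-free) baseline that observed
    matrices are tested against.
    """
    if isinstance(spec, CrossSpec):
        if spec.selection:
            raise ValueError("expected_segregation is the neutral baseline; "
                             "remove selection entries")
        steps = spec.steps
    else:
        steps = tuple(spec)
    if not steps or steps[0] != "make_f1":
        raise ValueError("first step must be make_f1")
    p_A, p_H, p_B = Fraction(0), Fraction(0), Fraction(0)
    for step in steps:
        if step == "make_f1":
            p_A, p_H, p_B = Fraction(0), Fraction(1), Fraction(0)
        elif step == "backcross_to_recipient":
            # gametes: A -> donor allele; H -> 1/2 each; B -> recipient allele
            p_A, p_H, p_B = Fraction(0), p_A + p_H / 2, p_B + p_H / 2
        elif step == "self":
            p_A, p_H, p_B = p_A + p_H / 4, p_H / 2, p_B + p_H / 4
        else:
            raise ValueError(f"unknown step {step!r}")
    return SegregationExpectation(p_A=p_A, p_B=p_B, p_H=p_H)


def _as_counts(counts) -> GenotypeCounts:
    if isinstance(counts, GenotypeCounts):
        return counts
    if isinstance(counts, MarkerGenotypeMatrix):
        return GenotypeCounts.from_matrix(counts)
    n_A, n_B, n_H = counts[:3]
    n_D = counts[3] if len(counts) > 3 else 0
    return GenotypeCounts(n_A, n_B, n_H, n_D)


def ar_frequency(counts) -> float:
    """Observed donor-genotype (Ar) frequency: (2 n_A + n_H) / (2 (n_A+n_B+n_H)).

    This is the donor allele frequency over the non-missing calls in scope;
    missing calls never enter the denominator.
    """
    c = _as_counts(counts)
    if c.n_called == 0:
        raise ValueError("Ar frequency undefined: no non-missing calls")
    return (2 * c.n_A + c.n_H) / (2 * c.n_called)


@dataclass(frozen=True)
class SegregationTestResult:
    statistic: float
    df: int
    pvalue: float
    warning: str | None = None


def segregation_test(counts, exp: SegregationExpectation) -> SegregationTestResult:
    """Pearson chi-square of observed A/B/H counts against scheme expectations.

    df = 2; expected counts below 5 trigger a warning field, below 1 a
    rejection (the asymptotic is meaningless there).
    """
    c = _as_counts(counts)
    n = c.n_called
    if n == 0:
        raise ValueError("segregation test undefined: no non-missing calls")
    probs = np.array([float(exp.p_A), float(exp.p_B), float(exp.p_H)])
    expected = n * probs
    if (expected < 1).any():
        raise ValueError("an expected class count is below 1; test not applicable")
    warning = "expected class count below 5" if (expected < 5).any() else None
    observed = np.array([c.n_A, c.n_B, c.n_H], dtype=float)
    stat, p = stats.chisquare(observed, f_exp=expected)
    return SegregationTestResult(float(stat), 2, float(p), warning)


def donor_coverage(counts) -> float:
    """Fraction of non-missing loci carrying at least one donor allele."""
    c = _as_counts(counts)
    if c.n_called == 0:
        raise ValueError("donor coverage undefined: no non-missing calls")
    return (c.n_A + c.n_H) / c.n_called


def donor_coverage_by_line(matrix: MarkerGenotypeMatrix) -> pd.DataFrame:
    """Per-line donor coverage plus the overall and per-recipient means.

    Returns a frame indexed by line id with ``coverage`` and ``recipient``;
    the across-line mean is ``result["coverage"].mean()`` and group means are
    ``result.groupby("recipient")["coverage"].mean()``.
    """
    arr = matrix.calls.to_numpy()
    n_donor = ((arr == "A") | (arr == "H")).sum(axis=1)
    n_called = (arr != "D").sum(axis=1)
    with np.errstate(invalid="ignore"):
        cov = np.where(n_called > 0, n_donor / np.where(n_called > 0, n_called, 1), np.nan)
    return pd.DataFrame({"coverage": cov, "n_called": n_called,
                         "recipient": matrix.recipients}, index=matrix.calls.index)


def flag_distorted_markers(matrix: MarkerGenotypeMatrix, exp: SegregationExpectation,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-marker donor-genotype frequency, direction and distortion test.

    For each marker the observed Ar frequency is compared with the
    theoretical ``f* = p_A + p_H/2``: a two-sided exact binomial test on the
    2N donor-allele draws, Bonferroni-corrected across markers.  Columns:
    counts, ``f``, ``direction`` (above/below/at f*), ``p_raw``, ``p_adj``,
    ``significant``.  The attached ``attrs['summary']`` reports the share of
    positively selected markers (f > f*) and the count significantly below.
    """
    f_star = float(exp.f_star)
    rows = []
    m = len(matrix.marker_ids)
    for mk in matrix.marker_ids:
        col = matrix.calls[mk].to_numpy()
        n_A = int((col == "A").sum())
        n_B = int((col == "B").sum())
        n_H = int((col == "H").sum())
        n_D = int((col == "D").sum())
        n = n_A + n_B + n_H
        if n == 0:
            raise ValueError(f"marker {mk}: no non-missing calls")
        k = 2 * n_A + n_H
        f = k / (2 * n)
        p_raw = stats.binomtest(k, 2 * n, f_star, alternative="two-sided").pvalue
        rows.append({"marker_id": mk,
                     "chrom": matrix.markers.loc[mk, "chrom"],
                     "bp": matrix.markers.loc[mk, "bp"],
                     "n_A": n_A, "n_B": n_B, "n_H": n_H, "n_D": n_D,
                     "f": f,
                     "direction": "above" if f > f_star else ("below" if f < f_star else "at"),
                     "p_raw": p_raw,
                     "p_adj": min(1.0, p_raw * m)})
    out = pd.DataFrame(rows).set_index("marker_id")
    out["significant"] = out["p_adj"] < alpha
    n_above = int((out["direction"] == "above").sum())
    out.attrs["summary"] = {
        "f_star": f_star,
        "n_markers": m,
        "n_above": n_above,
        "pct_above": 100.0 * n_above / m,
        "n_significant_below": int(((out["direction"] == "below") & out["significant"]).sum()),
        "alpha": alpha,
    }
    return out
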