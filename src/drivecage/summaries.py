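"""Summary statistics for drive cross, resistance, and fecundity tables.

These operate on tabulated counts only (vial-level DsRed-positive /
total offspring, allele-class counts, per-female daily egg counts) and
reproduce the standard readouts of a homing-drive characterisation:
inheritance rates (per-vial, vial-averaged, and count-pooled), Fisher exact
tests against the Mendelian 50% expectation, drive conversion rates derived
from inheritance, resistance-allele fractions, and group fecundity means
with unpaired t-tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import Sex

__all__ = [
    "CrossRecord",
    "FecundityRecord",
    "AlleleClassCounts",
    "InheritanceSummary",
    "inheritance_summary",
    "fisher_exact_vs_mendelian",
    "drive_conversion_from_inheritance",
    "resistance_fraction",
    "fecundity_summary",
]

RESISTANCE_CLASSES = frozenset(
    {"resistance-functional-candidate", "resistance-nonfunctional"}
)
ALLELE_CLASSES = frozenset(
    {"wild-type", "drive"} | RESISTANCE_CLASSES | {"other"}
)


@dataclass
class CrossRecord:
    """Offspring phenotype counts from one cross vial."""

    vial_id: str
    drive_parent_sex: Sex
    n_dsred_pos: int
    n_total: int
    variant_class: str | None = None  # pass-through polymorphism label

    def __post_init__(self) -> None:
        if not 0 <= self.n_dsred_pos <= self.n_total:
            raise ValueError(
                f"vial {self.vial_id}: need 0 <= n_dsred_pos <= n_total"
            )


@dataclass
class FecundityRecord:
    """One female's egg count on one day."""

    female_id: str
    genotype_label: str  # WT | heterozygote | homozygote
    octopamine: bool
    day: int
    eggs: int

    def __post_init__(self) -> None:
        if self.eggs < 0:
            raise ValueError("egg counts must be non-negative")


@dataclass
class AlleleClassCounts:
    """Target-site allele class counts with an explicit denominator convention."""

    counts: dict[str, int]
    denominator: int
    denominator_convention: str  # "progeny" or "alleles"

    def __post_init__(self) -> None:
        if self.denominator_convention not in ("progeny", "alleles"):
            raise ValueError(
                f"unknown denominator convention {self.denominator_convention!r}"
            )
        unknown = set(self.counts) - ALLELE_CLASSES
        if unknown:
            raise ValueError(f"unknown allele classes: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("class counts must be non-negative")
        if sum(self.counts.values()) > self.denominator:
            raise ValueError("class counts exceed the denominator")


@dataclass
class InheritanceSummary:
    """Per-vial and aggregate DsRed inheritance rates."""

    per_vial: pd.DataFrame  # vial_id, n_dsred_pos, n_total, rate
    mean_rate: float  # unweighted average of per-vial rates
    pooled_rate: float  # sum(pos) / sum(total)
    n_vials: int
    n_excluded: int = 0


def inheritance_summary(records: list[CrossRecord]) -> InheritanceSummary:
    """Per-vial rates plus vial-averaged and count-pooled inheritance.

    Both aggregates are reported because vial-averaging and pooling answer
    different questions (small vials count equally vs. proportionally).
    Empty vials are excluded with a warning.
    """
    kept = [r for r in records if r.n_total > 0]
    n_excluded = len(records) - len(kept)
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} vial(s) with zero offspring")
    if not kept:
        raise ValueError("no vials with offspring")
    df = pd.DataFrame(
        {
            "vial_id": [r.vial_id for r in kept],
            "n_dsred_pos": [r.n_dsred_pos for r in kept],
            "n_total": [r.n_total for r in kept],
        }
    )
    df["rate"] = df["n_dsred_pos"] / df["n_total"]
    return InheritanceSummary(
        per_vial=df,
        mean_rate=float(df["rate"].mean()),
        pooled_rate=float(df["n_dsred_pos"].sum() / df["n_total"].sum()),
        n_vials=len(kept),
        n_excluded=n_excluded,
    )


def fisher_exact_vs_mendelian(n_pos: int, n_total: int) -> float:
    """Two-sided Fisher exact test of an observed split against Mendelian 50:50.

    The comparison table is the expected half/half split of the same total,
    with an odd total resolved by rounding the expected positive count half
    up.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise ValueError("need 0 <= n_pos <= n_total")
    exp_pos = math.floor(n_total / 2 + 0.5)  # round half up
    table = [[n_pos, n_total - n_pos], [exp_pos, n_total - exp_pos]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def drive_conversion_from_inheritance(p: float) -> tuple[float, bool]:
    """Drive conversion rate implied by an inheritance proportion.

    Under the model, heterozygote-cross inheritance is (1 + c)/2, so
    c = 2p - 1.  Returns ``(c, clamped)``: proportions below 0.5 clamp to
    c = 0 with ``clamped=True`` (sampling noise, not negative conversion).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("inheritance proportion must lie in [0, 1]")
    c = 2.0 * p - 1.0
    if c < 0.0:
        return 0.0, True
    return c, False


def resistance_fraction(counts: AlleleClassCounts) -> tuple[float, str]:
    """Fraction of resistance alleles, with its denominator convention label."""
    if counts.denominator <= 0:
        raise ValueError("denominator must be positive")
    n_res = sum(counts.counts.get(k, 0) for k in RESISTANCE_CLASSES)
    return n_res / counts.denominator, counts.denominator_convention


@dataclass
class FecundityGroup:
    label: tuple
    n_females: int
    mean_eggs_per_day: float
    sd_between_females: float
    female_means: pd.Series = field(repr=False, default=None)


@dataclass
class FecunditySummary:
    groups: pd.DataFrame  # one row per group: n_females, mean, sd
    tests: pd.DataFrame  # pairwise t-tests on per-female means
    female_means: pd.DataFrame


def fecundity_summary(
    records: list[FecundityRecord],
    group_by: tuple[str, ...] = ("genotype_label", "octopamine"),
    equal_var: bool = True,
) -> FecunditySummary:
    """Group mean eggs/female/day with pairwise unpaired two-tailed t-tests.

    The unit of analysis is the female: daily counts are averaged per
    female first, then group means and Student t-tests (Welch optional via
    ``equal_var=False``) are computed on the female means.  Groups with
    fewer than two females report a mean but suppress tests (flagged in the
    test table).
    """
    if not records:
        raise ValueError("no fecundity records")
    df = pd.DataFrame(
        {
            "female_id": [r.female_id for r in records],
            "genotype_label": [r.genotype_label for r in records],
            "octopamine": [r.octopamine for r in records],
            "day": [r.day for r in records],
            "eggs": [r.eggs for r in records],
        }
    )
    fm = (
        df.groupby(["female_id", *group_by], sort=True)["eggs"]
        .mean()
        .rename("mean_eggs_per_day")
        .reset_index()
    )
    grouped = fm.groupby(list(group_by), sort=True)["mean_eggs_per_day"]
    groups = grouped.agg(n_females="count", mean="mean", sd="std").reset_index()

    rows = []
    keys = [tuple(k) if len(group_by) > 1 else (k,) for k in grouped.groups.keys()]
    series = {k: grouped.get_group(k if len(k) > 1 else k[0]) for k in keys}
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = series[keys[i]], series[keys[j]]
            suppressed = len(a) < 2 or len(b) < 2
            if suppressed:
                t = p = dof = np.nan
            else:
                t, p = stats.ttest_ind(a, b, equal_var=equal_var)
                if equal_var:
                    dof = len(a) + len(b) - 2
                else:  # Welch-Satterthwaite
                    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
                    dof = (va + vb) ** 2 / (
                        va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
                    )
            rows.append(
                {
                    "group_a": keys[i],
                    "group_b": keys[j],
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "t": float(t) if not suppressed else np.nan,
                    "dof": float(dof) if not suppressed else np.nan,
                    "p_value": float(p) if not suppressed else np.nan,
                    "test_suppressed": suppressed,
                }
            )
    return FecunditySummary(
        groups=groups, tests=pd.DataFrame(rows), female_means=fm
    )
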