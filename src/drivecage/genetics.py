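"""Allele-level model of a single-locus homing suppression gene drive.

The locus carries three allele classes: wild-type (``W``), the drive
construct (``D``, scored phenotypically by its DsRed marker), and
nonfunctional resistance (``R``, an end-joining repair product that the
drive can no longer cut and that also disrupts the target gene).

The target gene is a haplosufficient female-fertility gene: one wild-type
copy gives a normal female, so heterozygous females are fertile while
females carrying no wild-type allele (D/D, D/R, R/R) are sterile.  Drive
conversion (homing) and resistance formation happen only in the germline of
drive/wild-type heterozygotes, at sex-specific rates.  Maternal Cas9
carryover cutting paternal alleles in the early embryo is carried as a
parameter but is zero in the default model.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

__all__ = [
    "Allele",
    "Sex",
    "Genotype",
    "GENOTYPES",
    "DriveParams",
    "gamete_distribution",
    "offspring_genotype_distribution",
    "is_sterile_female",
    "fecundity_weight",
    "phenotype",
    "SterileMotherError",
]


class Allele(str, enum.Enum):
    """One of the three allele classes segregating at the drive locus."""

    W = "W"  #: wild-type
    D = "D"  #: drive construct (DsRed-marked)
    R = "R"  #: nonfunctional resistance (end-joining product)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of alleles; ``Genotype(D, W) == Genotype(W, D)``."""

    a1: Allele
    a2: Allele

    def __post_init__(self) -> None:
        # canonical order (W < D < R by enum definition order) so that
        # frozen-dataclass equality/hashing is order-insensitive
        order = {Allele.W: 0, Allele.D: 1, Allele.R: 2}
        if order[self.a1] > order[self.a2]:
            lo, hi = self.a2, self.a1
            object.__setattr__(self, "a1", lo)
            object.__setattr__(self, "a2", hi)

    @property
    def alleles(self) -> tuple[Allele, Allele]:
        return (self.a1, self.a2)

    def count(self, allele: Allele) -> int:
        return (self.a1 == allele) + (self.a2 == allele)

    def carries(self, allele: Allele) -> bool:
        return allele in (self.a1, self.a2)

    @classmethod
    def from_string(cls, s: str) -> "Genotype":
        """Parse ``'D/W'``-style labels (order-insensitive)."""
        left, _, right = s.partition("/")
        return cls(Allele(left.strip()), Allele(right.strip()))

    def __str__(self) -> str:
        return f"{self.a1.value}/{self.a2.value}"


#: The six distinct unordered genotypes, in canonical order.
GENOTYPES: tuple[Genotype, ...] = tuple(
    Genotype(a, b)
    for a, b in itertools.combinations_with_replacement(
        (Allele.W, Allele.D, Allele.R), 2
    )
)

WW = Genotype(Allele.W, Allele.W)
DW = Genotype(Allele.D, Allele.W)
WR = Genotype(Allele.W, Allele.R)
DD = Genotype(Allele.D, Allele.D)
DR = Genotype(Allele.D, Allele.R)
RR = Genotype(Allele.R, Allele.R)


class SterileMotherError(ValueError):
    """Raised when an offspring distribution is requested for a sterile mother."""


@dataclass
class DriveParams:
    """All fixed rates of the drive-inheritance model.

    Parameters
    ----------
    c_f, c_m
        Germline drive-conversion (homing) probability in female / male
        drive-heterozygote germlines, on [0, 1].  Study estimates: 0.076
        (females) and 0.146 (males).
    r_f, r_m
        Germline resistance-allele formation probability per sex; set to
        half the conversion rate in the study model.
    f_het
        Relative fecundity of drive/wild-type heterozygous females
        (wild-type = 1; cost = 1 - f_het).  This is the one free parameter
        of the cage likelihood.
    embryo_cut_rate
        Probability that maternally deposited Cas9 converts each wild-type
        allele of an offspring of a drive-carrying mother to resistance.
        Zero in the default model (germline cut rates were low).
    """

    c_f: float = 0.076
    c_m: float = 0.146
    r_f: float = field(default=None)  # type: ignore[assignment]
    r_m: float = field(default=None)  # type: ignore[assignment]
    f_het: float = 1.0
    embryo_cut_rate: float = 0.0

    def __post_init__(self) -> None:
        # resistance formation defaults to half the conversion rate per sex
        if self.r_f is None:
            self.r_f = self.c_f / 2.0
        if self.r_m is None:
            self.r_m = self.c_m / 2.0
        self.validate()

    def validate(self) -> None:
        for sex, c, r in (("female", self.c_f, self.r_f), ("male", self.c_m, self.r_m)):
            if not (0.0 <= c <= 1.0 and 0.0 <= r <= 1.0):
                raise ValueError(f"{sex} conversion/resistance rates must lie in [0, 1]")
            if c + r > 1.0 + 1e-12:
                raise ValueError(
                    f"{sex} conversion + resistance rate exceeds 1 (c={c}, r={r})"
                )
        if self.f_het < 0.0:
            raise ValueError("f_het must be non-negative")
        if not (0.0 <= self.embryo_cut_rate <= 1.0):
            raise ValueError("embryo_cut_rate must lie in [0, 1]")

    def conversion(self, sex: Sex) -> float:
        return self.c_f if sex is Sex.FEMALE else self.c_m

    def resistance(self, sex: Sex) -> float:
        return self.r_f if sex is Sex.FEMALE else self.r_m

    def replace(self, **kwargs) -> "DriveParams":
        d = dict(
            c_f=self.c_f,
            c_m=self.c_m,
            r_f=self.r_f,
            r_m=self.r_m,
            f_het=self.f_het,
            embryo_cut_rate=self.embryo_cut_rate,
        )
        d.update(kwargs)
        return DriveParams(**d)


def gamete_distribution(
    genotype: Genotype, sex: Sex, params: DriveParams
) -> dict[Allele, float]:
    """Allele transmission probabilities for one parent.

    In drive/wild-type heterozygotes the wild-type allele is cut in the
    germline and either converted to drive (homing, probability ``c``),
    repaired to nonfunctional resistance (probability ``r``), or left
    wild-type, giving P(D) = (1+c)/2, P(R) = r/2, P(W) = (1-c-r)/2.  Every
    other genotype has no drive/wild-type pair to act on and transmits each
    carried allele with probability 1/2.
    """
    if genotype == DW:
        c = params.conversion(sex)
        r = params.resistance(sex)
        dist = {
            Allele.D: (1.0 + c) / 2.0,
            Allele.W: (1.0 - c - r) / 2.0,
            Allele.R: r / 2.0,
        }
        return {a: p for a, p in dist.items() if p > 0.0}
    dist: dict[Allele, float] = {}
    for allele in genotype.alleles:
        dist[allele] = dist.get(allele, 0.0) + 0.5
    return dist


def is_sterile_female(genotype: Genotype) -> bool:
    """True iff a female of this genotype is sterile (no wild-type allele)."""
    return not genotype.carries(Allele.W)


def fecundity_weight(genotype: Genotype, sex: Sex, params: DriveParams) -> float:
    """Relative expected offspring contribution of an individual.

    Males always weigh 1 (the model has no male costs).  Sterile females
    weigh 0; drive/wild-type heterozygous females weigh ``f_het``; all
    other fertile females weigh 1.
    """
    if sex is Sex.MALE:
        return 1.0
    if is_sterile_female(genotype):
        return 0.0
    if genotype == DW:
        return params.f_het
    return 1.0


def phenotype(genotype: Genotype) -> str:
    """DsRed fluorescence phenotype: positive iff at least one drive allele."""
    return "DsRed-positive" if genotype.carries(Allele.D) else "DsRed-negative"


def is_dsred_positive(genotype: Genotype) -> bool:
    return genotype.carries(Allele.D)


def _apply_embryo_cutting(
    offspring: dict[Genotype, float], rate: float
) -> dict[Genotype, float]:
    """Convert each W allele to R with probability ``rate`` (maternal carryover)."""
    if rate == 0.0:
        return offspring
    out: dict[Genotype, float] = {}
    for geno, p in offspring.items():
        # each W allele independently converts W -> R
        branches = [(geno.a1, geno.a2, 1.0)]
        for idx in (0, 1):
            new_branches = []
            for a1, a2, bp in branches:
                a = (a1, a2)[idx]
                if a is Allele.W:
                    cut = list((a1, a2))
                    cut[idx] = Allele.R
                    new_branches.append((cut[0], cut[1], bp * rate))
                    new_branches.append((a1, a2, bp * (1.0 - rate)))
                else:
                    new_branches.append((a1, a2, bp))
            branches = new_branches
        for a1, a2, bp in branches:
            g = Genotype(a1, a2)
            out[g] = out.get(g, 0.0) + p * bp
    return out


def offspring_genotype_distribution(
    mother: Genotype, father: Genotype, params: DriveParams
) -> dict[Genotype, float]:
    """Offspring genotype distribution for one mated pair.

    Outer product of the maternal (female-rate) and paternal (male-rate)
    gamete distributions, collapsed to unordered genotypes.  If the mother
    carries a drive allele and ``embryo_cut_rate`` > 0, each wild-type
    allele of the zygote is additionally converted to resistance with that
    probability (maternal Cas9 carryover).

    Raises
    ------
    SterileMotherError
        If the mother is sterile under the model; callers must exclude
        sterile females before asking for offspring.
    """
    if is_sterile_female(mother):
        raise SterileMotherError(f"mother {mother} is sterile; no offspring defined")
    m = gamete_distribution(mother, Sex.FEMALE, params)
    f = gamete_distribution(father, Sex.MALE, params)
    out: dict[Genotype, float] = {}
    for am, pm in m.items():
        for af, pf in f.items():
            g = Genotype(am, af)
            out[g] = out.get(g, 0.0) + pm * pf
    if mother.carries(Allele.D):
        out = _apply_embryo_cutting(out, params.embryo_cut_rate)
    return out
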