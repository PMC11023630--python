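"""Synthetic cross, cage, and fecundity datasets under the drive model.

Every generator draws from the same stochastic structure the analysis
assumes — binomial offspring phenotypes at inheritance rate (1 + c)/2,
full genotype-resolved cage simulation, negative-binomial daily egg counts
around group means — and records the generating truth, so each downstream
summary and fit can be checked against a known answer without external
data.

Defaults mirror the study conditions: sex-specific conversion rates 7.6%
(female) / 14.6% (male) with resistance formation at half the conversion
rate, 26 cross vials, cages seeded with 15 + 15 drive-heterozygous and
45 + 45 wild-type flies (census 120, 12 generations, 3 replicates), and
fecundity group means of 24.46 (wild-type), 23.57 (heterozygote), 5.40
(homozygote) and 26.76 (homozygote on octopamine) eggs/female/day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import DriveParams, Sex
from .simulate import CageConfig, CageTrajectory, seed_cage, simulate_cage
from .summaries import CrossRecord, FecundityRecord

__all__ = [
    "SyntheticSpec",
    "generate_cross_data",
    "generate_cage_data",
    "generate_fecundity_data",
]


def _default_fecundity_means() -> dict[tuple[str, bool], float]:
    # octopamine restores homozygote oviposition; normal females unchanged
    return {
        ("WT", False): 24.46,
        ("heterozygote", False): 23.57,
        ("homozygote", False): 5.40,
        ("WT", True): 24.46,
        ("heterozygote", True): 23.57,
        ("homozygote", True): 26.76,
    }


@dataclass
class SyntheticSpec:
    """Conditions for the synthetic generators (defaults = study conditions)."""

    params: DriveParams = field(default_factory=DriveParams)
    # cross experiment
    n_vials: int = 26
    offspring_per_vial: int | None = None  # fixed size; None -> Poisson
    offspring_poisson_mean: float = 100.0
    # cage experiment
    n_cages: int = 3
    census: int = 120
    n_generations: int = 12
    n_het_males: int = 15
    n_het_females: int = 15
    n_wt_males: int = 45
    n_wt_females: int = 45
    # fecundity experiment
    fecundity_means: dict[tuple[str, bool], float] = field(
        default_factory=_default_fecundity_means
    )
    fecundity_dispersion: float = 5.0  # negative-binomial size parameter
    n_females_per_group: int = 6
    n_days: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_vials", "n_cages", "census", "n_generations",
                     "n_females_per_group", "n_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(m < 0 for m in self.fecundity_means.values()):
            raise ValueError("fecundity means must be non-negative")
        if self.fecundity_dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_cross_data(
    spec: SyntheticSpec,
    drive_parent_sex: Sex = Sex.MALE,
    rng: np.random.Generator | None = None,
) -> tuple[list[CrossRecord], dict]:
    """Per-vial offspring phenotype counts from heterozygote x wild-type crosses.

    Each vial's offspring count is fixed or Poisson per the spec; the
    DsRed-positive count is Binomial(n, (1 + c)/2) with the conversion rate
    of the drive parent's sex.  Returns the records and a truth dict with
    the generating conversion rate and expected inheritance.
    """
    if rng is None:
        rng = spec.rng()
    c = spec.params.conversion(drive_parent_sex)
    p = (1.0 + c) / 2.0
    records = []
    for i in range(spec.n_vials):
        if spec.offspring_per_vial is not None:
            n = spec.offspring_per_vial
        else:
            n = int(rng.poisson(spec.offspring_poisson_mean))
        k = int(rng.binomial(n, p)) if n > 0 else 0
        records.append(
            CrossRecord(
                vial_id=f"vial_{i + 1:03d}",
                drive_parent_sex=drive_parent_sex,
                n_dsred_pos=k,
                n_total=n,
            )
        )
    truth = {
        "conversion_rate": c,
        "expected_inheritance": p,
        "drive_parent_sex": drive_parent_sex.value,
    }
    return records, truth


def generate_cage_data(
    spec: SyntheticSpec,
    f_het_true: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[CageTrajectory], dict]:
    """Replicate cage trajectories with genotype truth counts attached."""
    if rng is None:
        rng = spec.rng()
    params = spec.params.replace(f_het=f_het_true)
    trajs = []
    for i in range(spec.n_cages):
        config = CageConfig(
            census=spec.census,
            n_generations=spec.n_generations,
            initial=seed_cage(
                spec.n_het_males,
                spec.n_het_females,
                spec.n_wt_males,
                spec.n_wt_females,
            ),
            cage_id=f"cage_{i + 1}",
        )
        trajs.append(simulate_cage(config, params, rng=rng, record_truth=True))
    truth = {"f_het": f_het_true, "cost": 1.0 - f_het_true}
    return trajs, truth


def generate_fecundity_data(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> list[FecundityRecord]:
    """Per-female daily egg counts, negative binomial around group means.

    Daily counts for a female in group g are NB(size = dispersion,
    mean = group mean); the Poisson limit is recovered as dispersion grows.
    A zero group mean yields all-zero counts.
    """
    if rng is None:
        rng = spec.rng()
    k = spec.fecundity_dispersion
    records = []
    fid = 0
    for (label, octo), mean in sorted(spec.fecundity_means.items()):
        for _ in range(spec.n_females_per_group):
            fid += 1
            for day in range(1, spec.n_days + 1):
                if mean == 0.0:
                    eggs = 0
                else:
                    eggs = int(rng.negative_binomial(k, k / (k + mean)))
                records.append(
                    FecundityRecord(
                        female_id=f"f{fid:04d}",
                        genotype_label=label,
                        octopamine=octo,
                        day=day,
                        eggs=eggs,
                    )
                )
    return records
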