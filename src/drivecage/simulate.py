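"""Discrete-generation stochastic simulation of gene-drive cage trials.

Cages are closed populations of fixed census size.  Each generation, every
fertile female picks one male uniformly at random (males may mate
multiply), her expected share of the next generation is proportional to her
fecundity weight, and the next census is drawn multinomially from the
mixture of the mated pairs' offspring genotype distributions.  Offspring
sex is assigned independently 50/50 (the drive locus is autosomal).

The deterministic infinite-population counterpart of the same generation
cycle, :func:`expected_phenotype_trajectory`, is the mean-field recursion
used by the likelihood in :mod:`drivecage.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetics import (
    GENOTYPES,
    Allele,
    DriveParams,
    Genotype,
    Sex,
    fecundity_weight,
    is_sterile_female,
    offspring_genotype_distribution,
)

__all__ = [
    "Population",
    "CageConfig",
    "CageTrajectory",
    "seed_cage",
    "advance_generation",
    "simulate_cage",
    "expected_phenotype_trajectory",
    "DegenerateStateError",
]

_GIDX = {g: i for i, g in enumerate(GENOTYPES)}
_N_GENO = len(GENOTYPES)
_CARRIER = np.array([g.carries(Allele.D) for g in GENOTYPES])
_STERILE_F = np.array([is_sterile_female(g) for g in GENOTYPES])

_ALLELES = (Allele.W, Allele.D, Allele.R)
_AIDX = {a: i for i, a in enumerate(_ALLELES)}


class DegenerateStateError(ValueError):
    """All females sterile (or a sex missing): the generation cycle is undefined."""


class ModelArrays:
    """Vectorized transmission tables for one parameter set.

    Precomputes the per-genotype gamete distributions for each sex, the
    female fecundity weights, and the 6x6 table of per-pair offspring
    genotype distributions, so that both the stochastic simulator and the
    likelihood recursion run on small numpy arrays.
    """

    def __init__(self, params: DriveParams):
        self.params = params
        from .genetics import gamete_distribution

        self.gamete_f = np.zeros((_N_GENO, 3))
        self.gamete_m = np.zeros((_N_GENO, 3))
        for g, i in _GIDX.items():
            for a, p in gamete_distribution(g, Sex.FEMALE, params).items():
                self.gamete_f[i, _AIDX[a]] = p
            for a, p in gamete_distribution(g, Sex.MALE, params).items():
                self.gamete_m[i, _AIDX[a]] = p
        self.fec = np.array(
            [fecundity_weight(g, Sex.FEMALE, params) for g in GENOTYPES]
        )
        # offspring[m, f, :] = offspring genotype distribution of mother m x father f
        self.offspring = np.zeros((_N_GENO, _N_GENO, _N_GENO))
        for gm, im in _GIDX.items():
            if is_sterile_female(gm):
                continue
            for gf, jf in _GIDX.items():
                dist = offspring_genotype_distribution(gm, gf, params)
                for g, p in dist.items():
                    self.offspring[im, jf, _GIDX[g]] = p

    def with_f_het(self, f_het: float) -> "ModelArrays":
        """Cheap copy with a different heterozygous-female fecundity.

        Only the female fecundity weights depend on ``f_het``; the gamete
        and offspring tables are shared, which keeps profile-likelihood
        scans over ``f_het`` fast.
        """
        import copy

        new = copy.copy(self)
        new.params = self.params.replace(f_het=f_het)
        new.fec = np.array(
            [fecundity_weight(g, Sex.FEMALE, new.params) for g in GENOTYPES]
        )
        return new

    def step(self, freq_f: np.ndarray, freq_m: np.ndarray) -> np.ndarray:
        """One deterministic generation: genotype frequencies of the offspring.

        ``freq_f``/``freq_m`` are genotype frequencies among females/males
        (each summing to 1).  Mothers are weighted by fecundity; fathers are
        drawn uniformly from the male pool.  Raises
        :class:`DegenerateStateError` if no fertile female mass remains.
        """
        w = freq_f * self.fec
        tot = w.sum()
        if tot <= 0.0 or freq_m.sum() <= 0.0:
            raise DegenerateStateError("no fertile females (or no males) in state")
        mother = w / tot
        father = freq_m / freq_m.sum()
        # sum over mother genotypes keeps maternal-carryover effects exact
        out = np.einsum("m,f,mfg->g", mother, father, self.offspring)
        return out / out.sum()


@dataclass
class Population:
    """Genotype-by-sex census of one cage generation (integer counts)."""

    counts: np.ndarray  # shape (6 genotypes, 2 sexes), columns: female, male

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (_N_GENO, 2):
            raise ValueError(f"counts must have shape ({_N_GENO}, 2)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def empty(cls) -> "Population":
        return cls(np.zeros((_N_GENO, 2), dtype=np.int64))

    @classmethod
    def from_dict(cls, d: dict[tuple[Genotype, Sex], int]) -> "Population":
        arr = np.zeros((_N_GENO, 2), dtype=np.int64)
        for (g, s), n in d.items():
            arr[_GIDX[g], 0 if s is Sex.FEMALE else 1] += n
        return cls(arr)

    def count(self, genotype: Genotype, sex: Sex) -> int:
        return int(self.counts[_GIDX[genotype], 0 if sex is Sex.FEMALE else 1])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_dsred_positive(self) -> int:
        return int(self.counts[_CARRIER].sum())

    def genotype_totals(self) -> dict[Genotype, int]:
        return {g: int(self.counts[i].sum()) for g, i in _GIDX.items()}


@dataclass
class CageConfig:
    """Simulation settings for one cage run."""

    census: int = 120
    n_generations: int = 12
    initial: Population | None = None
    seed: int | None = None
    cage_id: str = "sim"

    def __post_init__(self) -> None:
        if self.census <= 0:
            raise ValueError("census must be positive")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.initial is None:
            self.initial = seed_cage(15, 15, 45, 45)


@dataclass
class CageTrajectory:
    """Per-generation DsRed phenotype counts for one cage (observed or simulated).

    ``generation`` 0 is the founding census.  ``truth`` optionally carries the
    per-generation genotype counts (synthetic data only).
    """

    cage_id: str
    n_dsred_pos: list[int]
    n_total: list[int]
    truth: list[dict[Genotype, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.n_dsred_pos) != len(self.n_total):
            raise ValueError("phenotype count lists must have equal length")
        for k, (p, t) in enumerate(zip(self.n_dsred_pos, self.n_total)):
            if not (0 <= p <= t):
                raise ValueError(
                    f"generation {k}: need 0 <= n_dsred_pos <= n_total, got {p}/{t}"
                )

    @property
    def n_generations(self) -> int:
        return len(self.n_total)

    @property
    def carrier_frequency(self) -> np.ndarray:
        tot = np.asarray(self.n_total, dtype=float)
        pos = np.asarray(self.n_dsred_pos, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, pos / tot, np.nan)

    def to_frame(self):
        import pandas as pd

        data = {
            "cage_id": self.cage_id,
            "generation": np.arange(len(self.n_total)),
            "n_dsred_pos": self.n_dsred_pos,
            "n_total": self.n_total,
        }
        df = pd.DataFrame(data)
        if self.truth is not None:
            for g in GENOTYPES:
                df[f"truth_{g.a1.value}{g.a2.value}"] = [t.get(g, 0) for t in self.truth]
        return df


def seed_cage(
    n_het_males: int, n_het_females: int, n_wt_males: int, n_wt_females: int
) -> Population:
    """Founding census: D/W heterozygotes (paternally inherited drive) plus wild-type.

    The study seeding is 15 heterozygous males, 15 heterozygous females,
    45 wild-type males and 45 wild-type females (25% carriers of 120).
    """
    for n in (n_het_males, n_het_females, n_wt_males, n_wt_females):
        if n < 0:
            raise ValueError("founder counts must be non-negative")
    from .genetics import DW, WW

    return Population.from_dict(
        {
            (DW, Sex.MALE): n_het_males,
            (DW, Sex.FEMALE): n_het_females,
            (WW, Sex.MALE): n_wt_males,
            (WW, Sex.FEMALE): n_wt_females,
        }
    )


def advance_generation(
    pop: Population,
    params: DriveParams,
    census: int,
    rng: np.random.Generator,
    arrays: ModelArrays | None = None,
) -> Population:
    """Draw the next generation of exactly ``census`` individuals.

    Returns an empty population (extinction) when no fertile female or no
    male is present, or when total fecundity weight is zero.
    """
    if arrays is None or arrays.params is not params:
        arrays = ModelArrays(params)
    females = pop.counts[:, 0].astype(np.int64)
    males = pop.counts[:, 1].astype(np.int64)
    fertile = females.copy()
    fertile[_STERILE_F] = 0
    n_males = males.sum()
    if fertile.sum() == 0 or n_males == 0:
        return Population.empty()
    male_probs = males / n_males
    # pair counts: each fertile female of genotype g draws a male genotype
    mix = np.zeros(_N_GENO)
    total_w = 0.0
    for i in np.nonzero(fertile)[0]:
        pair_counts = rng.multinomial(int(fertile[i]), male_probs)
        w = arrays.fec[i]
        if w <= 0.0:
            continue
        mix += w * pair_counts @ arrays.offspring[i]
        total_w += w * pair_counts.sum()
    if total_w <= 0.0:
        return Population.empty()
    mix /= mix.sum()
    geno_counts = rng.multinomial(census, mix)
    n_female = rng.binomial(geno_counts, 0.5)
    out = np.stack([n_female, geno_counts - n_female], axis=1)
    return Population(out)


def simulate_cage(
    config: CageConfig,
    params: DriveParams,
    rng: np.random.Generator | None = None,
    record_truth: bool = True,
) -> CageTrajectory:
    """Simulate one cage for ``config.n_generations`` generations past the founders.

    Generation 0 records the seed composition; each later generation is one
    :func:`advance_generation` draw at the configured census.  Fully
    reproducible for a fixed ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    arrays = ModelArrays(params)
    pop = config.initial
    pos = [pop.n_dsred_positive]
    tot = [pop.total]
    truth = [pop.genotype_totals()]
    for _ in range(config.n_generations):
        pop = advance_generation(pop, params, config.census, rng, arrays)
        pos.append(pop.n_dsred_positive)
        tot.append(pop.total)
        truth.append(pop.genotype_totals())
    return CageTrajectory(
        cage_id=config.cage_id,
        n_dsred_pos=pos,
        n_total=tot,
        truth=truth if record_truth else None,
    )


def _freq_vector(freqs: dict[Genotype, float] | np.ndarray) -> np.ndarray:
    if isinstance(freqs, dict):
        v = np.zeros(_N_GENO)
        for g, p in freqs.items():
            v[_GIDX[g]] = p
    else:
        v = np.asarray(freqs, dtype=float)
    if v.shape != (_N_GENO,) or (v < -1e-12).any():
        raise ValueError("genotype frequencies must be a non-negative 6-vector")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("genotype frequencies must sum to 1")
    return np.clip(v, 0.0, None)


def expected_phenotype_trajectory(
    initial_f: dict[Genotype, float] | np.ndarray,
    params: DriveParams,
    n_generations: int,
    initial_m: dict[Genotype, float] | np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic infinite-population genotype-frequency recursion.

    Returns an array of shape ``(n_generations + 1, 6)`` of genotype
    frequencies (row 0 = the initial female frequencies; after one cycle
    both sexes share the offspring frequencies because sex is assigned
    independently of genotype).  The DsRed-positive frequency of row ``t``
    is ``row[t][carrier genotypes].sum()``.

    Raises :class:`DegenerateStateError` if at any generation every female
    is sterile.
    """
    arrays = ModelArrays(params)
    f = _freq_vector(initial_f)
    m = _freq_vector(initial_m) if initial_m is not None else f.copy()
    traj = np.empty((n_generations + 1, _N_GENO))
    traj[0] = f
    for t in range(1, n_generations + 1):
        nxt = arrays.step(f, m)
        traj[t] = nxt
        f = nxt
        m = nxt
    return traj


def carrier_frequency(traj: np.ndarray) -> np.ndarray:
    """DsRed-positive frequency per generation of a recursion trajectory."""
    return np.asarray(traj)[:, _CARRIER].sum(axis=1)
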