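"""Forward-time Wright–Fisher simulation of karyotype sorting.

A hybrid population founded by fully heterozygous F1 individuals sorts its
fusion/fission heterozygosity by random segregation and drift: every site
behaves like a neutral biallelic locus at initial frequency 1/2, so each
fixes either the fused or the unfused allele, and after roughly 4N
generations (N = effective population size, here the harmonic mean of the
census sizes) most sites are homozygous.  Because sites fix independently,
the fixed karyotype is almost never parental once more than a few sites
segregate — the simulational counterpart of r = 1 - 2/2^n.

Generations are discrete and non-overlapping; individuals are monoecious
with self-pairing excluded.  Selection against chromosomal heterozygotes
(the hybrids' observed 42% relative fitness) can be switched on as a
fecundity weight, either flat per individual or compounding per
heterozygous site.

Internally a population is an ``(N, F)`` int8 array counting fused alleles
per site (0, 1, 2); the object layer of :mod:`karyosort.architecture`
wraps it at the API boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .architecture import (
    DiploidGenotype,
    FusionArchitecture,
    GameteHaplotype,
    RaceKaryotype,
    default_races,
    from_document,
)

__all__ = [
    "FitnessModel",
    "SimulationConfig",
    "PopulationState",
    "SimulationResult",
    "sample_gamete",
    "next_generation",
    "run_simulation",
    "harmonic_mean_Ne",
    "neutral_fixation_expectation",
    "diffusion_fixation_time",
    "simulation_config_from_document",
]

NEUTRAL = "neutral"
FLAT_HYBRID = "flat_hybrid"
PER_SITE = "per_site"
RANDOM_MATING = "random_mating"
MONOGAMOUS_PAIRS = "monogamous_pairs"

PARENTAL_P1 = "parental_P1"
PARENTAL_P2 = "parental_P2"
NOVEL = "novel"
UNFIXED = "unfixed"


@dataclass(frozen=True)
class FitnessModel:
    """Fecundity weights for chromosomal heterozygotes.

    ``neutral``: every individual weighs 1.  ``flat_hybrid``: any
    individual with at least one heterozygous site weighs ``w`` (default
    0.42, the hybrids' observed relative fitness).  ``per_site``: weight
    ``w ** h`` so fitness compounds across heterozygous sites; use
    :meth:`per_site_from_aggregate` to choose ``w`` so that a fully
    heterozygous F1 lands on a target aggregate fitness.
    """

    mode: str = NEUTRAL
    w: float = 0.42

    def __post_init__(self) -> None:
        if self.mode not in (NEUTRAL, FLAT_HYBRID, PER_SITE):
            raise ValueError(f"unknown fitness mode {self.mode!r}")
        if not 0.0 < self.w <= 1.0:
            raise ValueError("w must be in (0, 1]")

    @classmethod
    def per_site_from_aggregate(
        cls, aggregate_w: float = 0.42, n_sites: int = 24
    ) -> "FitnessModel":
        return cls(mode=PER_SITE, w=aggregate_w ** (1.0 / n_sites))

    def weights(self, het_counts: np.ndarray) -> np.ndarray:
        h = np.asarray(het_counts)
        if self.mode == NEUTRAL:
            return np.ones(h.shape)
        if self.mode == FLAT_HYBRID:
            return np.where(h > 0, self.w, 1.0)
        return self.w ** h.astype(float)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything a sorting run needs; fully reproducible from ``seed``.

    ``sizes`` lists per-generation census sizes and is recycled when the
    horizon is longer (generation t uses ``sizes[t % len(sizes)]``; the
    founder uses ``sizes[0]``).  ``founder_mix`` optionally founds the
    population as a (P1, P2, F1) mixture instead of pure F1.
    """

    architecture: FusionArchitecture
    race_a: RaceKaryotype
    race_b: RaceKaryotype
    sizes: tuple[int, ...] = (15,)
    generations: int = 60
    replicates: int = 1
    fitness: FitnessModel = field(default_factory=FitnessModel)
    seed: int = 0
    mating: str = RANDOM_MATING
    founder_mix: tuple[float, float, float] | None = None
    keep_populations: bool = False

    def __post_init__(self) -> None:
        if not self.sizes or any(n < 2 for n in self.sizes):
            raise ValueError("all population sizes must be >= 2")
        if self.generations < 1:
            raise ValueError("horizon must be >= 1 generation")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mating not in (RANDOM_MATING, MONOGAMOUS_PAIRS):
            raise ValueError(f"unknown mating mode {self.mating!r}")
        for race in (self.race_a, self.race_b):
            if race.architecture != self.architecture:
                raise ValueError("race architecture differs from the config's")
        if self.founder_mix is not None:
            mix = tuple(float(p) for p in self.founder_mix)
            if len(mix) != 3 or any(p < 0 for p in mix) or not math.isclose(sum(mix), 1.0):
                raise ValueError("founder_mix must be 3 non-negative proportions summing to 1")
            object.__setattr__(self, "founder_mix", mix)

    def size_at(self, t: int) -> int:
        return self.sizes[t % len(self.sizes)]


@dataclass(frozen=True)
class PopulationState:
    """A generation snapshot at the object layer."""

    generation: int
    individuals: tuple[DiploidGenotype, ...]


# ---------------------------------------------------------------------------
# array core
# ---------------------------------------------------------------------------


def _genotype_to_row(genotype: DiploidGenotype) -> np.ndarray:
    return np.array([a + b for a, b in genotype.alleles], dtype=np.int8)


def _row_to_genotype(arch: FusionArchitecture, row: np.ndarray) -> DiploidGenotype:
    pairs = tuple({0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(v)] for v in row)
    return DiploidGenotype(arch, pairs)


def _race_row(race: RaceKaryotype) -> np.ndarray:
    row = np.zeros(race.architecture.n_sites, dtype=np.int8)
    for i in race.fused_sites:
        row[i] = 2
    return row


def _draw_gametes(rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One balanced gamete per row: heterozygous sites coin-flip."""
    return ((rows == 2) + ((rows == 1) & (rng.random(rows.shape) < 0.5))).astype(np.int8)


def _step(
    G: np.ndarray,
    n_next: int,
    fitness: FitnessModel,
    mating: str,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(G)
    if n < 2:
        raise ValueError("cannot breed a population of size < 2")
    if mating == RANDOM_MATING:
        w = fitness.weights((G == 1).sum(axis=1))
        p = w / w.sum()
        pa = rng.choice(n, size=n_next, p=p)
        pb = rng.choice(n, size=n_next, p=p)
        clash = pa == pb  # self-pairing excluded: redraw the second parent
        while clash.any():
            pb[clash] = rng.choice(n, size=int(clash.sum()), p=p)
            clash = pa == pb
    else:  # monogamous_pairs: fixed random pairs, offspring equiprobable
        order = rng.permutation(n)
        n_pairs = n // 2
        pick = rng.integers(0, n_pairs, size=n_next)
        pa = order[2 * pick]
        pb = order[2 * pick + 1]
    return _draw_gametes(G[pa], rng) + _draw_gametes(G[pb], rng)


def _stats(G: np.ndarray, invariant_units: int) -> tuple[float, float, float]:
    h = (G == 1).sum(axis=1)
    fused_hom = (G == 2).sum(axis=1)
    unfused_hom = (G == 0).sum(axis=1)
    x = invariant_units + fused_hom + 2 * unfused_hom
    m = 2 * x + 3 * h
    prop = 100.0 * 2 * x / m
    fixed = ((G == 0).all(axis=0) | (G == 2).all(axis=0)).mean() if G.shape[1] else 1.0
    return float(h.mean()), float(prop.mean()), float(fixed)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def sample_gamete(genotype: DiploidGenotype, rng: np.random.Generator) -> GameteHaplotype:
    """Draw one balanced gamete: each trivalent segregates 50:50."""
    row = _genotype_to_row(genotype)
    alleles = _draw_gametes(row[None, :], rng)[0]
    return GameteHaplotype(genotype.architecture, tuple(int(a) for a in alleles))


def next_generation(
    state: PopulationState,
    n_next: int,
    fitness: FitnessModel | None = None,
    mating: str = RANDOM_MATING,
    rng: np.random.Generator | None = None,
) -> PopulationState:
    """Breed one Wright–Fisher generation of ``n_next`` offspring.

    Parents are sampled with probability proportional to fecundity weight
    (random mating; self-pairing excluded), one balanced gamete per parent.
    """
    if not state.individuals:
        raise ValueError("empty population")
    arch = state.individuals[0].architecture
    G = np.stack([_genotype_to_row(g) for g in state.individuals])
    rng = rng if rng is not None else np.random.default_rng()
    G2 = _step(G, n_next, fitness or FitnessModel(), mating, rng)
    return PopulationState(
        generation=state.generation + 1,
        individuals=tuple(_row_to_genotype(arch, row) for row in G2),
    )


@dataclass(frozen=True)
class SimulationResult:
    """Trajectories and fixation outcomes of a sorting run.

    Arrays are (replicates, generations + 1); column ``t`` is generation
    ``t`` (0 = F1 founders).  ``fixation_generation`` is -1 for replicates
    not fully fixed within the horizon.
    """

    config: SimulationConfig
    mean_h: np.ndarray
    mean_prop_hom: np.ndarray
    frac_sites_fixed: np.ndarray
    fixation_generation: np.ndarray
    final_class: tuple[str, ...]
    populations: tuple[tuple[np.ndarray, ...], ...] | None = None

    def trajectory_frame(self) -> pd.DataFrame:
        reps, horizon = self.mean_h.shape
        rep, t = np.divmod(np.arange(reps * horizon), horizon)
        return pd.DataFrame(
            {
                "replicate": rep,
                "t": t,
                "mean_h": self.mean_h.ravel(),
                "mean_prop_hom": self.mean_prop_hom.ravel(),
                "frac_sites_fixed": self.frac_sites_fixed.ravel(),
            }
        )

    def outcome_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self.final_class)),
                "fixation_generation": self.fixation_generation,
                "final_class": list(self.final_class),
            }
        )

    def genotypes_at(self, replicate: int, t: int) -> tuple[DiploidGenotype, ...]:
        if self.populations is None:
            raise ValueError("run with keep_populations=True to retain genotypes")
        arch = self.config.architecture
        return tuple(
            _row_to_genotype(arch, row) for row in self.populations[replicate][t]
        )

    def summary(self) -> str:
        fixed = self.fixation_generation[self.fixation_generation >= 0]
        lines = [
            f"replicates: {len(self.final_class)}",
            f"fully fixed within horizon: {len(fixed)}",
        ]
        if len(fixed):
            lines.append(f"median fixation generation: {float(np.median(fixed)):.1f}")
        for label in (PARENTAL_P1, PARENTAL_P2, NOVEL, UNFIXED):
            k = sum(c == label for c in self.final_class)
            if k:
                lines.append(f"{label}: {k}")
        n_eff = harmonic_mean_Ne(self.config.sizes)
        lines.append(
            f"harmonic-mean N = {n_eff:.2f}; 4N horizon (upper bound) = "
            f"{neutral_fixation_expectation(round(n_eff))} generations; "
            f"diffusion mean from p=1/2 ≈ {diffusion_fixation_time(n_eff):.1f}"
        )
        return "\n".join(lines)


def _founder(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    ra, rb = _race_row(config.race_a), _race_row(config.race_b)
    f1 = ((ra + rb) // 2).astype(np.int8)
    n0 = config.size_at(0)
    if config.founder_mix is None:
        return np.tile(f1, (n0, 1))
    kinds = rng.choice(3, size=n0, p=np.asarray(config.founder_mix))
    rows = {0: ra, 1: rb, 2: f1}
    return np.stack([rows[int(k)] for k in kinds]).astype(np.int8)


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the configured replicates and record sorting trajectories.

    Each replicate draws from its own RNG stream derived from the root seed
    and the replicate index, so runs are reproducible and replicates
    independent.  A replicate stops evolving once every site is fixed
    population-wide (the population is then a single homozygous karyotype);
    its trajectory is padded constant to the horizon.
    """
    arch = config.architecture
    inv = arch.invariant_unit_count
    horizon = config.generations
    reps = config.replicates
    shape = (reps, horizon + 1)
    mean_h = np.zeros(shape)
    mean_prop = np.zeros(shape)
    frac_fixed = np.zeros(shape)
    fix_gen = np.full(reps, -1, dtype=int)
    final: list[str] = []
    pops: list[tuple[np.ndarray, ...]] = []
    ra, rb = _race_row(config.race_a), _race_row(config.race_b)

    for r in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, r)))
        G = _founder(config, rng)
        kept = [G.copy()] if config.keep_populations else None
        mean_h[r, 0], mean_prop[r, 0], frac_fixed[r, 0] = _stats(G, inv)
        fixed_at = -1
        if frac_fixed[r, 0] == 1.0:
            fixed_at = 0
        t = 0
        while t < horizon and fixed_at < 0:
            t += 1
            G = _step(G, config.size_at(t), config.fitness, config.mating, rng)
            if kept is not None:
                kept.append(G.copy())
            mean_h[r, t], mean_prop[r, t], frac_fixed[r, t] = _stats(G, inv)
            if frac_fixed[r, t] == 1.0:
                fixed_at = t
        if t < horizon:  # pad the absorbed trajectory
            mean_h[r, t + 1 :] = mean_h[r, t]
            mean_prop[r, t + 1 :] = mean_prop[r, t]
            frac_fixed[r, t + 1 :] = frac_fixed[r, t]
            if kept is not None:
                kept.extend(G.copy() for _ in range(horizon - t))
        fix_gen[r] = fixed_at
        if fixed_at < 0:
            final.append(UNFIXED)
        else:
            karyo = G[0]
            if np.array_equal(karyo, ra):
                final.append(PARENTAL_P1)
            elif np.array_equal(karyo, rb):
                final.append(PARENTAL_P2)
            else:
                final.append(NOVEL)
        if kept is not None:
            pops.append(tuple(kept))

    return SimulationResult(
        config=config,
        mean_h=mean_h,
        mean_prop_hom=mean_prop,
        frac_sites_fixed=frac_fixed,
        fixation_generation=fix_gen,
        final_class=tuple(final),
        populations=tuple(pops) if config.keep_populations else None,
    )


# ---------------------------------------------------------------------------
# drift arithmetic
# ---------------------------------------------------------------------------


def harmonic_mean_Ne(sizes: Sequence[int]) -> float:
    """Effective size of fluctuating censuses: k / sum(1/N_i).

    The experimental breeding sizes (8, 12, 24, 40) give 14.55, i.e. N = 15.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("need at least one population size")
    if any(n <= 0 for n in sizes):
        raise ValueError("population sizes must be positive")
    return len(sizes) / sum(1.0 / n for n in sizes)


def neutral_fixation_expectation(n_eff: float) -> float:
    """4N: the classical upper-bound horizon for neutral-allele fixation."""
    if n_eff < 1:
        raise ValueError("effective size must be >= 1")
    return 4.0 * n_eff


def diffusion_fixation_time(n_eff: float, p0: float = 0.5) -> float:
    """Diffusion mean absorption time from frequency p0: -4N (p ln p + q ln q).

    At p0 = 1/2 this is 4N ln 2 ≈ 2.77N — the 4N figure is an upper bound.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be strictly between 0 and 1")
    q0 = 1.0 - p0
    return -4.0 * n_eff * (p0 * math.log(p0) + q0 * math.log(q0))


# ---------------------------------------------------------------------------
# JSON configuration
# ---------------------------------------------------------------------------


def simulation_config_from_document(doc: Mapping, seed: int | None = None) -> SimulationConfig:
    """Build a config from a JSON document.

    Keys: optional architecture (``U``, ``sites``, ``races``; defaults to
    the 53-unit / 25-site frame with its spanish/swedish presets),
    ``race_a``/``race_b`` (race names), ``sizes``, ``generations``,
    ``replicates``, ``fitness`` ({mode, w}), ``mating``, ``founder_mix``,
    ``keep_populations``, ``seed`` (overridden by the ``seed`` argument).
    """
    if "U" in doc or "sites" in doc:
        arch, races = from_document(doc)
    else:
        races = default_races()
        arch = next(iter(races.values())).architecture
    if not races:
        races = default_races()

    def _race(key: str, fallback: str) -> RaceKaryotype:
        name = str(doc.get(key, fallback))
        if name not in races:
            raise ValueError(f"{key}={name!r} not among races {sorted(races)}")
        return races[name]

    fit_doc = dict(doc.get("fitness", {}))
    fitness = FitnessModel(
        mode=str(fit_doc.get("mode", NEUTRAL)), w=float(fit_doc.get("w", 0.42))
    )
    mix = doc.get("founder_mix")
    return SimulationConfig(
        architecture=arch,
        race_a=_race("race_a", "spanish"),
        race_b=_race("race_b", "swedish"),
        sizes=tuple(int(n) for n in doc.get("sizes", (15,))),
        generations=int(doc.get("generations", 60)),
        replicates=int(doc.get("replicates", 1)),
        fitness=fitness,
        seed=int(seed if seed is not None else doc.get("seed", 0)),
        mating=str(doc.get("mating", RANDOM_MATING)),
        founder_mix=tuple(mix) if mix is not None else None,
        keep_populations=bool(doc.get("keep_populations", False)),
    )
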