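"""Forward-time simulation of a single random-mating diploid population.

The model is a two-sex Wright–Fisher scheme with non-overlapping
generations: constant population size, an exactly balanced 1:1 sex ratio,
promiscuous random mating (each offspring draws its mother uniformly from
the females and its father uniformly from the males, with replacement),
free recombination (each locus inherits one uniformly chosen copy from
each parent, independently across loci), and a mixed mutation model in
which each transmitted copy mutates with a fixed per-copy probability,
the event being K-allele (jump to any of the K-1 other states, uniformly)
with probability ``p_kam`` and stepwise (one state up or down, reflecting
inward at the boundaries) otherwise.

Two presets emulate common marker types:

* ``ssr``: 10 loci, 20 allelic states, mutation rate 1e-4 — microsatellites.
* ``snp``: 2500 loci, 2 allelic states, mutation rate 1e-7 — biallelic SNPs.

Both run 600 diploids for 10 generations from a maximally variable initial
population (every allele copy uniform over the K states).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genotype_io import GenotypeMatrix


class SimulationError(RuntimeError):
    """The population cannot produce a next generation."""


@dataclass
class SimulationParams:
    """Forward-simulation settings (one population, two sexes, 1:1 ratio)."""

    n_loci: int
    mutation_rate: float
    n_allelic_states: int
    n_individuals: int = 600
    p_kam: float = 0.5
    n_generations: int = 10
    seed: int | None = None
    marker_label: str = ""

    def validate(self) -> "SimulationParams":
        if self.n_individuals < 2 or self.n_individuals % 2 != 0:
            raise ValueError("n_individuals must be an even integer >= 2 (1:1 sex ratio)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_allelic_states < 1:
            raise ValueError("n_allelic_states must be >= 1")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not (0.0 <= self.p_kam <= 1.0):
            raise ValueError("p_kam must lie in [0, 1]")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        return self

    def replace(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs).validate()


def ssr_params(**overrides) -> SimulationParams:
    """Microsatellite preset: 10 loci, K=20 states, mutation rate 1e-4."""
    return SimulationParams(
        n_loci=10, mutation_rate=1e-4, n_allelic_states=20, marker_label="SSR"
    ).replace(**overrides)


def snp_params(**overrides) -> SimulationParams:
    """SNP preset: 2500 biallelic loci, mutation rate 1e-7."""
    return SimulationParams(
        n_loci=2500, mutation_rate=1e-7, n_allelic_states=2, marker_label="SNP"
    ).replace(**overrides)


PRESETS = {"ssr": ssr_params, "snp": snp_params}


def _balanced_sexes(n: int) -> np.ndarray:
    """Exactly n/2 females (0) followed by n/2 males (1)."""
    return np.repeat(np.array([0, 1], dtype=np.int8), n // 2)


def init_population(P: SimulationParams, rng: np.random.Generator) -> GenotypeMatrix:
    """Maximally variable founding population: every allele copy i.i.d.
    uniform over the K allelic states; sexes split exactly 1:1."""
    P.validate()
    n, L, K = P.n_individuals, P.n_loci, P.n_allelic_states
    alleles = rng.integers(1, K + 1, size=(n, L, 2), dtype=np.int64)
    return GenotypeMatrix(
        individual_ids=[f"ind_{i + 1}" for i in range(n)],
        locus_ids=[f"L{j + 1}" for j in range(L)],
        alleles=alleles,
        missing_code=0,
        marker_label=P.marker_label,
        sexes=_balanced_sexes(n),
    )


def _mutate_states(
    states: np.ndarray, K: int, p_kam: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized mixed SSM/KAM mutation of allelic states in 1..K."""
    states = np.asarray(states, dtype=np.int64)
    if K == 1 or states.size == 0:
        return states.copy()
    is_kam = rng.random(states.shape) < p_kam
    # KAM: uniform over the K-1 other states
    draw = rng.integers(1, K, size=states.shape, dtype=np.int64)
    kam_new = draw + (draw >= states)
    # SSM: one step up/down, reflecting inward at 1 and K
    step = rng.integers(0, 2, size=states.shape, dtype=np.int64) * 2 - 1
    ssm_new = states + step
    ssm_new = np.where(states == 1, 2, ssm_new)
    ssm_new = np.where(states == K, K - 1, ssm_new)
    return np.where(is_kam, kam_new, ssm_new)


def mutate_allele(state: int, P: SimulationParams, rng: np.random.Generator) -> int:
    """Mutate one allelic state under the mixed SSM/KAM model."""
    K = P.n_allelic_states
    if not (1 <= state <= K):
        raise ValueError(f"allelic state {state} outside 1..{K}")
    return int(_mutate_states(np.array([state]), K, P.p_kam, rng)[0])


def next_generation(
    G: GenotypeMatrix, P: SimulationParams, rng: np.random.Generator
) -> GenotypeMatrix:
    """One generation of random mating with Mendelian transmission.

    Parents are redrawn per offspring (promiscuity); every locus segregates
    independently (free recombination); each transmitted copy mutates with
    probability ``mutation_rate``.  Offspring sexes are assigned exactly
    n/2 and n/2.
    """
    if G.sexes is None:
        raise SimulationError("population lacks sex assignments")
    females = np.flatnonzero(G.sexes == 0)
    males = np.flatnonzero(G.sexes == 1)
    if females.size == 0 or males.size == 0:
        raise SimulationError("both sexes are required to breed")
    n, L = G.n_individuals, G.n_loci
    mothers = rng.choice(females, size=n, replace=True)
    fathers = rng.choice(males, size=n, replace=True)
    cols = np.arange(L)[None, :]
    mat_copy = rng.integers(0, 2, size=(n, L))
    pat_copy = rng.integers(0, 2, size=(n, L))
    maternal = G.alleles[mothers[:, None], cols, mat_copy]
    paternal = G.alleles[fathers[:, None], cols, pat_copy]
    offspring = np.stack([maternal, paternal], axis=2)
    if P.mutation_rate > 0.0:
        hits = rng.random(offspring.shape) < P.mutation_rate
        if hits.any():
            offspring[hits] = _mutate_states(
                offspring[hits], P.n_allelic_states, P.p_kam, rng
            )
    return GenotypeMatrix(
        individual_ids=list(G.individual_ids),
        locus_ids=list(G.locus_ids),
        alleles=offspring,
        missing_code=G.missing_code,
        marker_label=G.marker_label,
        sexes=_balanced_sexes(n),
    )


def simulate(P: SimulationParams) -> GenotypeMatrix:
    """Found a population and advance it ``n_generations`` generations."""
    P.validate()
    ss = np.random.SeedSequence(P.seed)
    streams = ss.spawn(P.n_generations + 1)
    G = init_population(P, np.random.default_rng(streams[0]))
    for g in range(P.n_generations):
        G = next_generation(G, P, np.random.default_rng(streams[g + 1]))
    return G
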