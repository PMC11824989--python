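from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rarepop.genotype_io import Config, GenotypeMatrix
from rarepop.popgen_stats import AlleleFrequencyTable
from rarepop.rarefaction import STAT_COLUMNS, RarefactionResult


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """3 individuals x 2 loci, no missing data."""
    alleles = np.array(
        [
            [[1, 1], [3, 4]],
            [[1, 2], [3, 3]],
            [[2, 2], [4, 4]],
        ]
    )
    return GenotypeMatrix(["a", "b", "c"], ["L1", "L2"], alleles, missing_code=0)


@pytest.fixture
def matrix_with_missing() -> GenotypeMatrix:
    """4 individuals x 2 loci with both full and half-missing genotypes."""
    alleles = np.array(
        [
            [[1, 2], [5, 5]],
            [[0, 0], [5, 6]],
            [[2, 2], [0, 6]],
            [[1, 0], [6, 6]],
        ]
    )
    return GenotypeMatrix(["a", "b", "c", "d"], ["L1", "L2"], alleles, missing_code=0)


def random_matrix(rng: np.random.Generator, missing_code: int = 0) -> GenotypeMatrix:
    """Random 6-individual, 3-locus matrix with ~15% missing copies."""
    alleles = rng.integers(1, 5, size=(6, 3, 2))
    mask = rng.random((6, 3, 2)) < 0.15
    alleles[mask] = missing_code
    return GenotypeMatrix(
        [f"i{k}" for k in range(6)], ["L1", "L2", "L3"], alleles, missing_code=missing_code
    )


def make_aft(*locus_freqs: dict[int, float], counts=None) -> AlleleFrequencyTable:
    """Build a frequency table directly from per-locus dicts."""
    n = len(locus_freqs)
    counts = np.asarray(counts if counts is not None else [10] * n)
    return AlleleFrequencyTable([f"L{j + 1}" for j in range(n)], list(locus_freqs), counts)


def make_result(mean_by_stat: dict[str, dict[int, float]], sizes: list[int],
                pass_rule: str = "persistent") -> RarefactionResult:
    """Minimal RarefactionResult carrying only aggregate means, for testing
    the minimum-sample-size decision rule in isolation."""
    rows = []
    for size in sizes:
        for col in STAT_COLUMNS:
            mean = mean_by_stat.get(col, {}).get(size, 0.0)
            rows.append({"size": size, "statistic": col, "mean": mean,
                         "sd": 0.0, "min": mean, "max": mean, "n": 1})
    return RarefactionResult(
        sizes=sizes,
        n_resamples=1,
        full=None,  # type: ignore[arg-type]
        replicates=pd.DataFrame(),
        per_locus=pd.DataFrame(),
        aggregates=pd.DataFrame(rows),
        master_seed=0,
        config=Config(input_path="x", pass_rule=pass_rule),
    )
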