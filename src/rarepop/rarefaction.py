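"""Subsampling ladder, replicate statistics, aggregation, and the
minimum-sample-size decision rule.

The engine draws, for each size on a ladder (multiples of the smallest
subsample size up to the dataset size), a fixed number of random subsamples
without replacement, computes every statistic against the *full* dataset,
and aggregates mean/sd/min/max per size.  A criterion's minimum sample
size is the smallest ladder size whose aggregate mean meets the threshold
and keeps meeting it at every larger size ("persistent" rule — the curve
has reached its plateau); the overall minimum is the most conservative
(largest) of the per-criterion minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import Config, ConfigError, GenotypeMatrix
from . import popgen_stats as ps

#: Replicate-level statistic columns aggregated per subsample size.
STAT_COLUMNS = [
    "frac_common_detected",
    "frac_all_detected",
    "frac_rare_detected",
    "mean_freq_diff",
    "mean_ho",
    "mean_he",
    "mean_ho_diff",
    "mean_he_diff",
    "fst",
    "nei_d",
    "rogers_d",
    "most_common_freq",
    "least_common_freq",
]

#: criterion name -> (replicate column, threshold, direction)
DEFAULT_THRESHOLDS: dict[str, tuple[str, float, str]] = {
    "common_alleles": ("frac_common_detected", 0.95, "ge"),
    "allele_freq": ("mean_freq_diff", 0.01, "le"),
    "fst": ("fst", 0.05, "le"),
    "he_diff": ("mean_he_diff", 0.05, "le"),
}


@dataclass
class FullDatasetStats:
    """Statistics of the complete input, the baseline for every replicate."""

    frequencies: ps.AlleleFrequencyTable
    het: ps.HetEstimates
    classification: ps.AlleleClassification
    all_alleles: set[tuple[int, int]]


@dataclass
class RarefactionResult:
    """Replicate-level and aggregated rarefaction statistics.

    ``replicates`` holds one row per (size, replicate) with the columns in
    :data:`STAT_COLUMNS`; ``per_locus`` holds per-locus Ho/He per replicate
    (feeding the per-locus outputs); ``aggregates`` holds mean/sd/min/max
    per size and statistic (sd is the sample standard deviation, 0 for a
    single replicate).
    """

    sizes: list[int]
    n_resamples: int
    full: FullDatasetStats
    replicates: pd.DataFrame
    per_locus: pd.DataFrame
    aggregates: pd.DataFrame
    master_seed: int
    config: Config

    def aggregate_mean(self, column: str) -> pd.Series:
        """Per-size mean of one replicate statistic, indexed by size."""
        sub = self.aggregates[self.aggregates["statistic"] == column]
        return sub.set_index("size")["mean"]


@dataclass
class CriterionResult:
    statistic: str
    threshold: float
    direction: str  # "ge" or "le"
    min_size: int | None  # None = not reached


@dataclass
class MinSampleSizeReport:
    """Per-criterion and overall minimum sample sizes.

    ``overall`` is the maximum of the four per-criterion minima, or None
    ("not reached") as soon as any criterion never passes.
    """

    criteria: dict[str, CriterionResult]
    overall: int | None
    rule: str

    def as_row(self) -> dict[str, object]:
        def fmt(v: int | None) -> object:
            return "not reached" if v is None else v

        return {
            "Common alleles": fmt(self.criteria["common_alleles"].min_size),
            "Allele freq.": fmt(self.criteria["allele_freq"].min_size),
            "F_ST": fmt(self.criteria["fst"].min_size),
            "H_E": fmt(self.criteria["he_diff"].min_size),
            "Overall": fmt(self.overall),
        }


def subsample_sizes(n_individuals: int, step: int, cap: int | None = None) -> list[int]:
    """Ladder of subsample sizes: multiples of ``step`` strictly below
    ``N = min(n_individuals, cap)``, plus ``N`` itself.

    The smallest subsample size doubles as the spacing, e.g. 50 individuals
    with step 5 give 5, 10, ..., 45, 50.
    """
    if step < 2:
        raise ConfigError("smallest subsample size must be >= 2")
    if step > n_individuals:
        raise ConfigError(
            f"smallest subsample size {step} exceeds dataset size {n_individuals}"
        )
    N = n_individuals if cap is None else min(n_individuals, cap)
    sizes = list(range(step, N, step))
    sizes.append(N)
    return sizes


def replicate_rng(master_seed: int, size: int, replicate: int) -> np.random.Generator:
    """Independent substream for one (size, replicate) draw.

    Keyed by counter rather than sequentially, so adding or removing ladder
    sizes never shifts the draws of other sizes.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(size, replicate))
    return np.random.default_rng(ss)


def draw_subsample(G: GenotypeMatrix, n: int, rng: np.random.Generator) -> GenotypeMatrix:
    """Random subsample of ``n`` distinct individuals, all loci retained."""
    if not (2 <= n <= G.n_individuals):
        raise ValueError(f"subsample size {n} out of range [2, {G.n_individuals}]")
    idx = np.sort(rng.choice(G.n_individuals, size=n, replace=False))
    return G.subset(idx)


def full_dataset_stats(G: GenotypeMatrix, min_allele_freq: float) -> FullDatasetStats:
    F = ps.allele_frequencies(G)
    het = ps.het_estimates(G, F)
    classification = ps.classify_alleles(F, min_allele_freq)
    return FullDatasetStats(
        frequencies=F,
        het=het,
        classification=classification,
        all_alleles=F.allele_set(),
    )


def replicate_stats(
    sub: GenotypeMatrix, full: FullDatasetStats
) -> tuple[dict[str, float], np.ndarray, np.ndarray]:
    """All comparison statistics of one subsample against the full dataset.

    Returns the scalar statistics plus the per-locus Ho and He arrays.
    """
    F_sub = ps.allele_frequencies(sub)
    het = ps.het_estimates(sub, F_sub)
    cls = full.classification
    diffs = ps.mean_freq_difference(F_sub, full.frequencies)

    ho_diff = np.abs(het.ho - full.het.ho)
    he_diff = np.abs(het.he - full.het.he)
    ml, mc, _ = cls.most_common
    ll, lc, _ = cls.least_common
    stats = {
        "frac_common_detected": ps.detected_fraction(cls.common, F_sub)
        if cls.common
        else np.nan,
        "frac_all_detected": ps.detected_fraction(full.all_alleles, F_sub),
        "frac_rare_detected": ps.detected_fraction(cls.rare, F_sub)
        if cls.rare
        else np.nan,
        "mean_freq_diff": diffs.mean,
        "mean_ho": het.mean_ho,
        "mean_he": het.mean_he,
        "mean_ho_diff": float(np.nanmean(ho_diff)) if np.any(~np.isnan(ho_diff)) else np.nan,
        "mean_he_diff": float(np.nanmean(he_diff)) if np.any(~np.isnan(he_diff)) else np.nan,
        "fst": ps.fst_pair(F_sub, full.frequencies),
        "nei_d": ps.nei_distance(F_sub, full.frequencies),
        "rogers_d": ps.rogers_distance(F_sub, full.frequencies),
        "most_common_freq": F_sub.freq(ml, mc),
        "least_common_freq": F_sub.freq(ll, lc),
    }
    return stats, het.ho, het.he


def run_rarefaction(G: GenotypeMatrix, config: Config) -> RarefactionResult:
    """Full rarefaction run: ladder, replicates, statistics, aggregates."""
    config.validate()
    if config.smallest_subsample > G.n_individuals:
        raise ConfigError(
            f"smallest_subsample {config.smallest_subsample} exceeds the "
            f"{G.n_individuals}-individual dataset"
        )
    sizes = subsample_sizes(G.n_individuals, config.smallest_subsample, config.max_sample_size)
    master_seed = (
        config.seed
        if config.seed is not None
        else int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    )
    full = full_dataset_stats(G, config.min_allele_freq)

    rep_rows: list[dict[str, float]] = []
    locus_rows: list[pd.DataFrame] = []
    for size in sizes:
        for rep in range(config.n_resamples):
            rng = replicate_rng(master_seed, size, rep)
            sub = draw_subsample(G, size, rng)
            stats, ho, he = replicate_stats(sub, full)
            rep_rows.append({"size": size, "replicate": rep, **stats})
            locus_rows.append(
                pd.DataFrame(
                    {
                        "size": size,
                        "replicate": rep,
                        "locus": G.locus_ids,
                        "ho": ho,
                        "he": he,
                    }
                )
            )
    replicates = pd.DataFrame(rep_rows)
    per_locus = pd.concat(locus_rows, ignore_index=True)
    aggregates = _aggregate(replicates)
    return RarefactionResult(
        sizes=sizes,
        n_resamples=config.n_resamples,
        full=full,
        replicates=replicates,
        per_locus=per_locus,
        aggregates=aggregates,
        master_seed=master_seed,
        config=config,
    )


def _aggregate(replicates: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-size mean/sd/min/max for every statistic (NaNs skipped)."""
    rows = []
    for size, grp in replicates.groupby("size", sort=True):
        for col in STAT_COLUMNS:
            vals = grp[col].to_numpy(dtype=float)
            finite_or_inf = vals[~np.isnan(vals)]
            if finite_or_inf.size == 0:
                mean = sd = vmin = vmax = np.nan
            else:
                mean = float(np.mean(finite_or_inf))
                sd = float(np.std(finite_or_inf, ddof=1)) if finite_or_inf.size > 1 else 0.0
                vmin = float(np.min(finite_or_inf))
                vmax = float(np.max(finite_or_inf))
            rows.append(
                {
                    "size": size,
                    "statistic": col,
                    "mean": mean,
                    "sd": sd,
                    "min": vmin,
                    "max": vmax,
                    "n": int(finite_or_inf.size),
                }
            )
    return pd.DataFrame(rows)


def _passes(mean: float, threshold: float, direction: str) -> bool:
    if np.isnan(mean):
        return False
    return mean >= threshold if direction == "ge" else mean <= threshold


def minimum_sample_size(
    R: RarefactionResult,
    thresholds: dict[str, tuple[str, float, str]] | None = None,
    rule: str | None = None,
) -> MinSampleSizeReport:
    """Apply the per-criterion pass rule and the conservative overall rule.

    A size passes a criterion when the aggregate *mean* at that size meets
    the threshold.  Under the default "persistent" rule the criterion's
    minimum is the smallest ladder size from which every larger ladder size
    also passes; under "first" it is simply the first passing size.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    rule = rule or R.config.pass_rule
    if rule not in ("persistent", "first"):
        raise ValueError("rule must be 'persistent' or 'first'")
    criteria: dict[str, CriterionResult] = {}
    for name, (col, thr, direction) in thresholds.items():
        means = R.aggregate_mean(col).reindex(R.sizes)
        passes = [_passes(float(m), thr, direction) for m in means]
        min_size: int | None = None
        if rule == "persistent":
            for i, size in enumerate(R.sizes):
                if all(passes[i:]):
                    min_size = size
                    break
        else:
            for size, ok in zip(R.sizes, passes):
                if ok:
                    min_size = size
                    break
        criteria[name] = CriterionResult(col, thr, direction, min_size)
    if any(c.min_size is None for c in criteria.values()):
        overall = None
    else:
        overall = max(c.min_size for c in criteria.values())  # type: ignore[type-var]
    return MinSampleSizeReport(criteria=criteria, overall=overall, rule=rule)
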