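"""Per-dataset and pairwise population-genetic statistics.

All statistics are built on per-locus allele frequencies computed over
non-missing allele copies.  Pairwise statistics always compare a subsample
against its source (full) dataset over the same locus set; alleles absent
from one side enter with frequency zero.

Formulas
--------
* He (gene diversity): ``1 - sum_a p_a^2`` per locus, no small-sample
  correction, so an identity subsample reproduces the full-dataset value
  exactly.
* FST: per locus ``(Ht - Hs) / Ht`` with ``Ht = 1 - sum_a pbar_a^2``
  (``pbar`` the unweighted mean of the two pools) and ``Hs`` the mean of
  the two pools' He; averaged over loci with ``Ht > 0`` (mean of ratios).
* Nei's standard distance: ``-ln(Jxy / sqrt(Jx * Jy))`` with the J's
  averaged over loci; ``+inf`` when the pools share no alleles.
* Rogers' distance: mean over loci of ``sqrt(0.5 * sum_a (p_a - q_a)^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies over non-missing copies.

    ``freqs[l]`` maps allele code -> fraction of the ``copy_counts[l]``
    non-missing copies at locus ``l``; a locus with no scored copies has
    an empty map and a copy count of 0.
    """

    locus_ids: list[str]
    freqs: list[dict[int, float]]
    copy_counts: np.ndarray

    @property
    def n_loci(self) -> int:
        return len(self.freqs)

    def freq(self, locus: int, code: int) -> float:
        return self.freqs[locus].get(code, 0.0)

    def allele_set(self) -> set[tuple[int, int]]:
        """All observed (locus index, allele code) pairs."""
        return {(l, a) for l, f in enumerate(self.freqs) for a in f}


@dataclass
class HetEstimates:
    """Observed and expected heterozygosity per locus and averaged.

    Per-locus values are NaN when undefined (Ho: no individual with two
    scored copies; He: no scored copies); means skip undefined loci.
    """

    ho: np.ndarray
    he: np.ndarray
    mean_ho: float
    mean_he: float


@dataclass
class AlleleClassification:
    """Common/rare split of the full dataset's alleles plus global extremes.

    ``common``/``rare`` hold (locus index, allele code) pairs partitioned
    by the minimum-frequency threshold; ``most_common``/``least_common``
    are (locus index, code, frequency) global extrema, ties broken by
    (locus index, allele code) order.
    """

    common: set[tuple[int, int]]
    rare: set[tuple[int, int]]
    most_common: tuple[int, int, float]
    least_common: tuple[int, int, float]
    min_freq: float


@dataclass
class FreqDifferences:
    """Absolute subsample-vs-full allele frequency differences."""

    per_allele: dict[tuple[int, int], float]
    mean: float


def allele_frequencies(G: GenotypeMatrix) -> AlleleFrequencyTable:
    """Count allele copies per locus, excluding the missing code.

    A genotype with exactly one missing copy still contributes its scored
    copy, so frequencies use all available information.
    """
    freqs: list[dict[int, float]] = []
    counts = np.zeros(G.n_loci, dtype=np.int64)
    for l in range(G.n_loci):
        copies = G.alleles[:, l, :].reshape(-1)
        copies = copies[copies != G.missing_code]
        counts[l] = copies.size
        if copies.size == 0:
            freqs.append({})
            continue
        codes, ncopies = np.unique(copies, return_counts=True)
        total = copies.size
        freqs.append({int(c): int(k) / total for c, k in zip(codes, ncopies)})
    return AlleleFrequencyTable(list(G.locus_ids), freqs, counts)


def observed_heterozygosity(G: GenotypeMatrix) -> np.ndarray:
    """Per-locus fraction of heterozygotes among fully scored individuals.

    Individuals with any missing copy at the locus are excluded; a locus
    with no fully scored individual is NaN.
    """
    complete = ~G.missing_mask().any(axis=2)  # (n, loci)
    hetero = (G.alleles[:, :, 0] != G.alleles[:, :, 1]) & complete
    denom = complete.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(denom > 0, hetero.sum(axis=0) / denom, np.nan)
    return ho


def expected_heterozygosity(F: AlleleFrequencyTable) -> np.ndarray:
    """Nei gene diversity ``1 - sum p^2`` per locus (NaN where no copies)."""
    he = np.full(F.n_loci, np.nan)
    for l, f in enumerate(F.freqs):
        if f:
            he[l] = 1.0 - sum(p * p for p in f.values())
    return he


def het_estimates(G: GenotypeMatrix, F: AlleleFrequencyTable | None = None) -> HetEstimates:
    """Bundle Ho and He with their means over defined loci."""
    if F is None:
        F = allele_frequencies(G)
    ho = observed_heterozygosity(G)
    he = expected_heterozygosity(F)
    mean_ho = float(np.nanmean(ho)) if np.any(~np.isnan(ho)) else float("nan")
    mean_he = float(np.nanmean(he)) if np.any(~np.isnan(he)) else float("nan")
    return HetEstimates(ho=ho, he=he, mean_ho=mean_ho, mean_he=mean_he)


def _check_same_loci(F_a: AlleleFrequencyTable, F_b: AlleleFrequencyTable) -> None:
    if F_a.locus_ids != F_b.locus_ids:
        raise ValueError("frequency tables cover different locus sets")


def fst_pair(F_sub: AlleleFrequencyTable, F_full: AlleleFrequencyTable) -> float:
    """Nei-style FST between two allele-frequency pools.

    Per locus, ``Ht = 1 - sum pbar^2`` over the pooled mean frequencies and
    ``Hs`` is the mean of the two within-pool gene diversities; loci with
    ``Ht = 0`` (jointly monomorphic) are excluded and the remaining
    per-locus ratios are averaged.  Returns 0 when no locus is polymorphic.
    """
    _check_same_loci(F_sub, F_full)
    ratios = []
    for l in range(F_full.n_loci):
        fs, ff = F_sub.freqs[l], F_full.freqs[l]
        if not fs or not ff:
            continue
        codes = set(fs) | set(ff)
        pbar2 = sum(((fs.get(a, 0.0) + ff.get(a, 0.0)) / 2.0) ** 2 for a in codes)
        ht = 1.0 - pbar2
        if ht <= 0.0:
            continue
        he_s = 1.0 - sum(p * p for p in fs.values())
        he_f = 1.0 - sum(p * p for p in ff.values())
        hs = (he_s + he_f) / 2.0
        ratios.append((ht - hs) / ht)
    return float(np.mean(ratios)) if ratios else 0.0


def nei_distance(F_a: AlleleFrequencyTable, F_b: AlleleFrequencyTable) -> float:
    """Nei's (1972) standard genetic distance between two pools.

    ``D = -ln(Jxy / sqrt(Jx * Jy))`` with Jx, Jy, Jxy the mean over loci of
    within- and between-pool allelic identities.  Loci lacking scored
    copies in either pool are skipped; ``+inf`` when the pools share no
    allele (Jxy = 0).
    """
    _check_same_loci(F_a, F_b)
    jx, jy, jxy = [], [], []
    for l in range(F_a.n_loci):
        fa, fb = F_a.freqs[l], F_b.freqs[l]
        if not fa or not fb:
            continue
        jx.append(sum(p * p for p in fa.values()))
        jy.append(sum(q * q for q in fb.values()))
        jxy.append(sum(p * fb.get(a, 0.0) for a, p in fa.items()))
    if not jx:
        raise ValueError("no locus with scored copies in both pools")
    mjxy = float(np.mean(jxy))
    if mjxy == 0.0:
        return float("inf")
    return float(-math.log(mjxy / math.sqrt(np.mean(jx) * np.mean(jy))))


def rogers_distance(F_a: AlleleFrequencyTable, F_b: AlleleFrequencyTable) -> float:
    """Rogers' (1972) distance: mean over loci of the per-locus Euclidean
    frequency distance ``sqrt(0.5 * sum (p - q)^2)``; bounded in [0, 1]."""
    _check_same_loci(F_a, F_b)
    per_locus = []
    for l in range(F_a.n_loci):
        fa, fb = F_a.freqs[l], F_b.freqs[l]
        if not fa and not fb:
            continue
        codes = set(fa) | set(fb)
        ss = sum((fa.get(a, 0.0) - fb.get(a, 0.0)) ** 2 for a in codes)
        per_locus.append(math.sqrt(0.5 * ss))
    return float(np.mean(per_locus)) if per_locus else 0.0


def classify_alleles(F_full: AlleleFrequencyTable, min_freq: float) -> AlleleClassification:
    """Partition alleles into common (frequency >= ``min_freq``) and rare,
    and locate the globally most and least common alleles over all loci."""
    if not any(F_full.freqs):
        raise ValueError("cannot classify alleles of an empty frequency table")
    common: set[tuple[int, int]] = set()
    rare: set[tuple[int, int]] = set()
    most: tuple[int, int, float] | None = None
    least: tuple[int, int, float] | None = None
    for l, f in enumerate(F_full.freqs):
        for code in sorted(f):
            p = f[code]
            (common if p >= min_freq else rare).add((l, code))
            if most is None or p > most[2]:
                most = (l, code, p)
            if least is None or p < least[2]:
                least = (l, code, p)
    assert most is not None and least is not None
    return AlleleClassification(common, rare, most, least, min_freq)


def detected_fraction(
    allele_set: set[tuple[int, int]], F_sub: AlleleFrequencyTable
) -> float:
    """Fraction of the given (locus, code) alleles present in the subsample."""
    if not allele_set:
        raise ValueError("allele_set must be non-empty")
    found = sum(1 for (l, a) in allele_set if F_sub.freq(l, a) > 0.0)
    return found / len(allele_set)


def mean_freq_difference(
    F_sub: AlleleFrequencyTable, F_full: AlleleFrequencyTable
) -> FreqDifferences:
    """|p_sub - p_full| for every allele observed in the full dataset.

    Alleles missing from the subsample count with frequency 0; the mean is
    unweighted over all full-dataset alleles.
    """
    _check_same_loci(F_sub, F_full)
    per_allele: dict[tuple[int, int], float] = {}
    for l, ff in enumerate(F_full.freqs):
        fs = F_sub.freqs[l]
        for a, p in ff.items():
            per_allele[(l, a)] = abs(fs.get(a, 0.0) - p)
    mean = float(np.mean(list(per_allele.values()))) if per_allele else 0.0
    return FreqDifferences(per_allele=per_allele, mean=mean)
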