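"""Result tables, plots, the minimum-size summary, and the group test.

A rarefaction run is rendered as 14 numbered table/plot pairs.  Boxplot
outputs show the replicate distribution per subsample size with a red
threshold line where one applies (0.95 for common-allele detection, 0.01
for the mean allele-frequency difference, 0.05 for the heterozygosity
differences and for FST); mean/sd outputs show the mean with an sd box and
a min-max whisker; the distance outputs show the per-size mean curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import write_table
from .rarefaction import (
    DEFAULT_THRESHOLDS,
    MinSampleSizeReport,
    RarefactionResult,
    minimum_sample_size,
)

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be fixed first)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutputSpec:
    number: int
    slug: str
    kind: str  # "box" | "meansd" | "line"
    columns: tuple[str, ...]  # replicate statistic column(s)
    threshold: float | None
    title: str
    per_locus: bool = False


#: The 14 output pairs, in fixed order.
CATALOGUE: tuple[OutputSpec, ...] = (
    OutputSpec(1, "common_alleles", "box", ("frac_common_detected",), 0.95,
               "Fraction of common alleles detected"),
    OutputSpec(2, "all_alleles", "box", ("frac_all_detected",), None,
               "Fraction of all alleles detected"),
    OutputSpec(3, "rare_alleles", "box", ("frac_rare_detected",), None,
               "Fraction of rare alleles detected"),
    OutputSpec(4, "allele_freq_diff", "box", ("mean_freq_diff",), 0.01,
               "Mean |allele frequency difference| vs full dataset"),
    OutputSpec(5, "extreme_allele_freqs", "meansd",
               ("most_common_freq", "least_common_freq"), None,
               "Frequencies of the globally most/least common alleles"),
    OutputSpec(6, "he_per_locus", "box", ("he",), None,
               "Expected heterozygosity per locus", per_locus=True),
    OutputSpec(7, "he_mean", "meansd", ("mean_he",), None,
               "Expected heterozygosity over loci"),
    OutputSpec(8, "ho_per_locus", "box", ("ho",), None,
               "Observed heterozygosity per locus", per_locus=True),
    OutputSpec(9, "ho_mean", "meansd", ("mean_ho",), None,
               "Observed heterozygosity over loci"),
    OutputSpec(10, "ho_diff", "box", ("mean_ho_diff",), 0.05,
               "Mean |Ho difference| vs full dataset"),
    OutputSpec(11, "he_diff", "box", ("mean_he_diff",), 0.05,
               "Mean |He difference| vs full dataset"),
    OutputSpec(12, "fst", "line", ("fst",), 0.05,
               "Mean pairwise FST, subsample vs full dataset"),
    OutputSpec(13, "nei_distance", "line", ("nei_d",), None,
               "Nei's standard distance, subsample vs full dataset"),
    OutputSpec(14, "rogers_distance", "line", ("rogers_d",), None,
               "Rogers' distance, subsample vs full dataset"),
)

THRESHOLD_LINE_COLOR = "red"


def _table_for(spec: OutputSpec, R: RarefactionResult) -> pd.DataFrame:
    """Aggregate table for one output: keyed by size (and locus for the
    per-locus outputs), with mean/sd/min/max columns per statistic."""
    if spec.per_locus:
        col = spec.columns[0]
        grp = R.per_locus.groupby(["size", "locus"], sort=True)[col]
        out = grp.agg(mean="mean", sd="std", min="min", max="max").reset_index()
        out["sd"] = out["sd"].fillna(0.0)
        return out
    frames = []
    for col in spec.columns:
        sub = R.aggregates[R.aggregates["statistic"] == col]
        sub = sub[["size", "mean", "sd", "min", "max"]].copy()
        if len(spec.columns) > 1:
            sub.columns = ["size"] + [f"{col}_{c}" for c in ("mean", "sd", "min", "max")]
        frames.append(sub.set_index("size"))
    return pd.concat(frames, axis=1).reset_index()


def _plot_for(spec: OutputSpec, R: RarefactionResult, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    sizes = R.sizes
    if spec.kind == "box":
        source = R.per_locus if spec.per_locus else R.replicates
        col = spec.columns[0]
        data = [
            source.loc[source["size"] == s, col].dropna().to_numpy() for s in sizes
        ]
        ax.boxplot(data, tick_labels=[str(s) for s in sizes])
    elif spec.kind == "meansd":
        positions = np.arange(1, len(sizes) + 1)
        for offset, col in zip(
            np.linspace(-0.15, 0.15, len(spec.columns)), spec.columns
        ):
            agg = R.aggregates[R.aggregates["statistic"] == col].set_index("size")
            agg = agg.reindex(sizes)
            x = positions + (offset if len(spec.columns) > 1 else 0.0)
            ax.vlines(x, agg["min"], agg["max"], color="grey", lw=1)
            ax.bar(
                x,
                2 * agg["sd"],
                bottom=agg["mean"] - agg["sd"],
                width=0.25,
                alpha=0.4,
                label=col,
            )
            ax.plot(x, agg["mean"], "k_", markersize=12)
        if len(spec.columns) > 1:
            ax.legend(fontsize=8)
        ax.set_xticks(positions, [str(s) for s in sizes])
    else:  # line
        agg = R.aggregates[R.aggregates["statistic"] == spec.columns[0]]
        agg = agg.set_index("size").reindex(sizes)
        ax.plot(sizes, agg["mean"], "o-")
        ax.set_xticks(sizes, [str(s) for s in sizes])
    if spec.threshold is not None:
        ax.axhline(spec.threshold, color=THRESHOLD_LINE_COLOR, lw=1.2)
    ax.set_xlabel("subsample size")
    ax.set_title(spec.title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def build_outputs(
    R: RarefactionResult, out_dir: str | Path, image_format: str = "png"
) -> list[tuple[Path, Path | None]]:
    """Write the 14 table/plot pairs; returns them in catalogue order.

    When the dataset has no rare allele, output 3's table is written with
    an empty body and its plot is skipped with a logged notice.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs: list[tuple[Path, Path | None]] = []
    no_rare = len(R.full.classification.rare) == 0
    for spec in CATALOGUE:
        table_path = out_dir / f"output_{spec.number:02d}_{spec.slug}.csv"
        plot_path = out_dir / f"output_{spec.number:02d}_{spec.slug}.{image_format}"
        table = _table_for(spec, R)
        if spec.number == 3 and no_rare:
            write_table(table.iloc[0:0], table_path)
            logger.info(
                "output 3: the full dataset has no rare allele below the "
                "%.3g threshold; empty table written, plot skipped",
                R.full.classification.min_freq,
            )
            pairs.append((table_path, None))
            continue
        write_table(table, table_path)
        _plot_for(spec, R, plot_path)
        pairs.append((table_path, plot_path))
    return pairs


def summarize_minimum(
    R: RarefactionResult,
    out_dir: str | Path | None = None,
    thresholds: dict[str, tuple[str, float, str]] | None = None,
) -> tuple[MinSampleSizeReport, pd.DataFrame]:
    """Minimum-sample-size report plus its one-row summary table.

    The row mirrors the conventional presentation: one column per criterion
    (common alleles, allele frequency, FST, He difference) and the
    conservative overall minimum (their maximum).
    """
    report = minimum_sample_size(R, thresholds=thresholds)
    row = pd.DataFrame([report.as_row()])
    if out_dir is not None:
        write_table(row, Path(out_dir) / "minimum_sample_size.csv")
    return report, row


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``W`` is the rank-sum statistic of ``x``: sum of the midranks of ``x``
    in the pooled ranking minus ``n_x (n_x + 1) / 2``.  The p-value uses
    the exact null distribution when there are no ties, and the normal
    approximation with tie correction and continuity correction otherwise
    (matching the conventional default of R's ``wilcox.test``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    W = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "asymptotic" if has_ties else "exact"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return W, float(res.pvalue)


def compare_groups(
    table: pd.DataFrame, group_column: str, value_column: str
) -> tuple[str, str, float, float]:
    """Rank-sum comparison of a two-group column; returns the group labels
    (in first-appearance order) with W computed for the first group."""
    groups = list(dict.fromkeys(table[group_column]))
    if len(groups) != 2:
        raise ValueError(
            f"column {group_column!r} must contain exactly 2 groups, found {len(groups)}"
        )
    ga, gb = groups
    x = table.loc[table[group_column] == ga, value_column]
    y = table.loc[table[group_column] == gb, value_column]
    W, p = wilcoxon_rank_sum(x, y)
    return str(ga), str(gb), W, p
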