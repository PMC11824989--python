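"""Input/output for Structure-format genotype data and run configuration.

A dataset is a diploid multilocus genotype matrix: individuals in rows,
loci in columns, two integer allele codes per locus.  Two row dialects are
supported, mirroring the two layouts accepted by the Structure program:

* ``one_row_per_individual`` — each individual occupies one row; the two
  allele copies of a locus sit in two consecutive columns.
* ``two_rows_per_individual`` — each individual occupies two consecutive
  rows; each locus is one column and the two rows carry the two copies.

Missing data are coded ``0`` or ``-9``.  Files are plain CSV; any preamble
(header lines) before the first individual is skipped.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ONE_ROW = "one_row_per_individual"
TWO_ROW = "two_rows_per_individual"

_LAYOUT_ALIASES = {
    ONE_ROW: ONE_ROW,
    TWO_ROW: TWO_ROW,
    "one_row": ONE_ROW,
    "two_rows": TWO_ROW,
    "one": ONE_ROW,
    "two": TWO_ROW,
    "1": ONE_ROW,
    "2": TWO_ROW,
}

VALID_MISSING_CODES = (0, -9)


class ConfigError(ValueError):
    """A configuration file or Config object is invalid."""


class ParseError(ValueError):
    """A genotype file could not be parsed."""


class LayoutError(ParseError):
    """A genotype file is inconsistent with the declared row dialect."""


@dataclass
class Config:
    """Run configuration: file layout plus analysis settings.

    ``smallest_subsample`` doubles as the spacing of the subsample-size
    ladder; ``min_allele_freq`` is the full-dataset frequency above which
    an allele counts as "common"; ``max_sample_size`` optionally caps the
    ladder (the comparison baseline stays the full dataset).
    """

    input_path: str = ""
    layout: str = ONE_ROW
    missing_code: int = 0
    first_individual_line: int = 1
    n_prefix_columns: int = 1
    smallest_subsample: int = 5
    n_resamples: int = 50
    min_allele_freq: float = 0.05
    max_sample_size: int | None = None
    seed: int | None = None
    output_dir: str = "rarepop_out"
    pass_rule: str = "persistent"  # or "first": minimum-size decision rule
    marker_label: str = ""

    def validate(self) -> "Config":
        if self.layout not in (ONE_ROW, TWO_ROW):
            raise ConfigError(f"layout must be {ONE_ROW!r} or {TWO_ROW!r}, got {self.layout!r}")
        if self.missing_code not in VALID_MISSING_CODES:
            raise ConfigError(
                f"missing_code must be 0 or -9, got {self.missing_code}"
            )
        if self.first_individual_line < 1:
            raise ConfigError("first_individual_line must be a positive 1-based line number")
        if self.n_prefix_columns < 0:
            raise ConfigError("n_prefix_columns must be >= 0")
        if self.smallest_subsample < 2:
            raise ConfigError("smallest_subsample must be >= 2")
        if self.n_resamples < 1:
            raise ConfigError("n_resamples must be >= 1")
        if not (0.0 < self.min_allele_freq < 1.0):
            raise ConfigError("min_allele_freq must lie strictly between 0 and 1")
        if self.max_sample_size is not None and self.max_sample_size < 2:
            raise ConfigError("max_sample_size must be >= 2 when set")
        if self.seed is not None and not (0 <= self.seed < 2**63):
            raise ConfigError("seed must be a non-negative integer")
        if self.pass_rule not in ("persistent", "first"):
            raise ConfigError("pass_rule must be 'persistent' or 'first'")
        return self

    def replace(self, **kwargs) -> "Config":
        return replace(self, **kwargs).validate()


_REQUIRED_KEYS = ("input_path", "layout")
_INT_KEYS = {
    "missing_code",
    "first_individual_line",
    "n_prefix_columns",
    "smallest_subsample",
    "n_resamples",
    "max_sample_size",
    "seed",
}
_FLOAT_KEYS = {"min_allele_freq"}
_STR_KEYS = {"input_path", "layout", "output_dir", "pass_rule", "marker_label"}
CONFIG_KEYS = _INT_KEYS | _FLOAT_KEYS | _STR_KEYS


def read_config(path: str | Path) -> Config:
    """Parse a ``key = value`` plain-text configuration file.

    One entry per line; ``#`` starts a comment; blank lines are ignored.
    Omitted analysis settings fall back to the defaults (smallest subsample
    5, 50 resamples per size, minimum allele frequency 0.05).
    """
    text = Path(path).read_text(encoding="utf-8")
    values: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in CONFIG_KEYS:
            raise ConfigError(
                f"line {lineno}: unknown setting {key!r} (valid: {', '.join(sorted(CONFIG_KEYS))})"
            )
        if key in _INT_KEYS:
            try:
                values[key] = int(val)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: setting {key!r} requires an integer, got {val!r}"
                ) from None
        elif key in _FLOAT_KEYS:
            try:
                values[key] = float(val)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: setting {key!r} requires a number, got {val!r}"
                ) from None
        else:
            values[key] = val
    missing = [k for k in _REQUIRED_KEYS if k not in values]
    if missing:
        raise ConfigError(f"missing required setting(s): {', '.join(missing)}")
    layout = _LAYOUT_ALIASES.get(str(values["layout"]).strip().lower())
    if layout is None:
        raise ConfigError(f"layout must be {ONE_ROW!r} or {TWO_ROW!r}, got {values['layout']!r}")
    values["layout"] = layout
    return Config(**values).validate()  # type: ignore[arg-type]


def write_config(config: Config, path: str | Path) -> None:
    """Write a Config back as the plain-text ``key = value`` format."""
    lines = []
    for f in fields(config):
        value = getattr(config, f.name)
        if value is None:
            continue
        lines.append(f"{f.name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class GenotypeMatrix:
    """Diploid multilocus genotypes for one population.

    ``alleles`` has shape (n_individuals, n_loci, 2) with integer codes;
    entries equal to ``missing_code`` are missing allele copies.  Allele
    codes are opaque labels to every analysis stage; only the forward
    simulator assigns them an order (for stepwise mutation).
    """

    individual_ids: list[str]
    locus_ids: list[str]
    alleles: np.ndarray
    missing_code: int = 0
    marker_label: str = ""
    sexes: np.ndarray | None = None  # 0 = female, 1 = male; used by forward_sim only

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError(f"alleles must have shape (n, loci, 2), got {self.alleles.shape}")
        n, L, _ = self.alleles.shape
        if n < 2:
            raise ValueError("a genotype matrix needs at least 2 individuals")
        if L < 1:
            raise ValueError("a genotype matrix needs at least 1 locus")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match allele array")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length does not match allele array")
        if self.missing_code not in VALID_MISSING_CODES:
            raise ValueError("missing_code must be 0 or -9")
        nonmissing = self.alleles[self.alleles != self.missing_code]
        if self.missing_code == 0 and nonmissing.size and nonmissing.min() <= 0:
            raise ValueError("non-missing allele codes must be > 0 when missing_code is 0")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, loci, 2) mask of missing allele copies."""
        return self.alleles == self.missing_code

    def subset(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """New matrix restricted to the given individuals (all loci kept)."""
        idx = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in idx],
            locus_ids=list(self.locus_ids),
            alleles=self.alleles[idx].copy(),
            missing_code=self.missing_code,
            marker_label=self.marker_label,
            sexes=None if self.sexes is None else self.sexes[idx].copy(),
        )


def _parse_int(token: str, row: int, col: int) -> int:
    try:
        return int(token.strip())
    except ValueError:
        raise ParseError(
            f"row {row}, column {col}: allele token {token.strip()!r} is not an integer"
        ) from None


def read_structure(path: str | Path, config: Config) -> GenotypeMatrix:
    """Read a Structure-format CSV file into a :class:`GenotypeMatrix`.

    The first ``first_individual_line - 1`` lines are preamble and skipped
    (the last preamble line is reused for locus names when its shape
    matches).  ``n_prefix_columns`` leading columns are non-genotype
    metadata; the first of them, when present, is the individual label.
    In the two-row dialect consecutive row pairs are one individual and
    their labels, if present, must agree.
    """
    config.validate()
    with open(path, newline="", encoding="utf-8") as fh:
        raw_rows = list(csv.reader(fh))
    preamble = raw_rows[: config.first_individual_line - 1]
    data_rows = [
        (i + config.first_individual_line, row)
        for i, row in enumerate(raw_rows[config.first_individual_line - 1 :])
        if any(tok.strip() for tok in row)
    ]
    if not data_rows:
        raise ParseError(f"{path}: no genotype rows found from line {config.first_individual_line}")

    widths = {len(row) for _, row in data_rows}
    if len(widths) > 1:
        bad = next((n, row) for n, row in data_rows if len(row) != len(data_rows[0][1]))
        raise ParseError(
            f"row {bad[0]}: ragged row with {len(bad[1])} columns "
            f"(expected {len(data_rows[0][1])})"
        )
    ncols = widths.pop()
    npre = config.n_prefix_columns
    ngeno = ncols - npre
    if ngeno < 1:
        raise LayoutError(f"only {ncols} columns but {npre} prefix columns configured")

    if config.layout == ONE_ROW:
        if ngeno % 2 != 0:
            raise LayoutError(
                f"one-row dialect needs an even number of genotype columns, got {ngeno}"
            )
        n_loci = ngeno // 2
        n_ind = len(data_rows)
        alleles = np.empty((n_ind, n_loci, 2), dtype=np.int64)
        ids = []
        for i, (rowno, row) in enumerate(data_rows):
            ids.append(row[0].strip() if npre >= 1 else f"ind_{i + 1}")
            for j in range(ngeno):
                alleles[i, j // 2, j % 2] = _parse_int(row[npre + j], rowno, npre + j + 1)
    else:
        if len(data_rows) % 2 != 0:
            raise LayoutError(
                f"two-row dialect needs an even number of data rows, got {len(data_rows)}"
            )
        n_loci = ngeno
        n_ind = len(data_rows) // 2
        alleles = np.empty((n_ind, n_loci, 2), dtype=np.int64)
        ids = []
        for i in range(n_ind):
            (rn1, r1), (rn2, r2) = data_rows[2 * i], data_rows[2 * i + 1]
            if npre >= 1:
                lab1, lab2 = r1[0].strip(), r2[0].strip()
                if lab1 != lab2:
                    raise LayoutError(
                        f"rows {rn1}/{rn2}: paired rows carry different labels "
                        f"({lab1!r} vs {lab2!r})"
                    )
                ids.append(lab1)
            else:
                ids.append(f"ind_{i + 1}")
            for j in range(n_loci):
                alleles[i, j, 0] = _parse_int(r1[npre + j], rn1, npre + j + 1)
                alleles[i, j, 1] = _parse_int(r2[npre + j], rn2, npre + j + 1)

    locus_ids = _locus_names_from_preamble(preamble, config, n_loci) or [
        f"L{j + 1}" for j in range(n_loci)
    ]
    return GenotypeMatrix(
        individual_ids=ids,
        locus_ids=locus_ids,
        alleles=alleles,
        missing_code=config.missing_code,
        marker_label=config.marker_label,
    )


def _locus_names_from_preamble(
    preamble: list[list[str]], config: Config, n_loci: int
) -> list[str] | None:
    """Recover locus names from the last preamble line when its shape fits."""
    if not preamble:
        return None
    header = [tok.strip() for tok in preamble[-1]]
    npre = config.n_prefix_columns
    body = header[npre:]
    if config.layout == ONE_ROW and len(body) == 2 * n_loci:
        names = body[0::2]
        if names == body[1::2]:  # duplicated per allele column
            return names
        return None
    if config.layout == TWO_ROW and len(body) == n_loci:
        return body
    return None


def write_structure(
    G: GenotypeMatrix, path: str | Path, layout: str = ONE_ROW, header: bool = True
) -> Config:
    """Serialize a matrix as Structure-format CSV; returns a matching Config.

    The emitted file has one header line with locus names (when ``header``)
    and an individual-label first column, so the returned Config has
    ``first_individual_line = 2`` and ``n_prefix_columns = 1``.
    """
    if layout not in (ONE_ROW, TWO_ROW):
        raise ValueError(f"unknown layout {layout!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if header:
            if layout == ONE_ROW:
                writer.writerow(["id"] + [name for name in G.locus_ids for _ in range(2)])
            else:
                writer.writerow(["id"] + list(G.locus_ids))
        for i, ind in enumerate(G.individual_ids):
            if layout == ONE_ROW:
                writer.writerow([ind] + list(G.alleles[i].reshape(-1)))
            else:
                writer.writerow([ind] + list(G.alleles[i, :, 0]))
                writer.writerow([ind] + list(G.alleles[i, :, 1]))
    return Config(
        input_path=str(path),
        layout=layout,
        missing_code=G.missing_code,
        first_individual_line=2 if header else 1,
        n_prefix_columns=1,
        marker_label=G.marker_label,
    )


def write_table(rows: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write tabular data as CSV (header row, full precision, UTF-8).

    Non-finite cells are rendered as explicit ``Inf`` / ``-Inf`` / ``NaN``
    tokens so that nothing is silently dropped; :func:`read_table` maps
    them back.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_render_float)
    out.to_csv(path, index=False, na_rep="NaN", encoding="utf-8")


def _render_float(x: float) -> str:
    if isinstance(x, float):
        if math.isnan(x):
            return "NaN"
        if math.isinf(x):
            return "Inf" if x > 0 else "-Inf"
    return repr(float(x))


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, na_values=["NaN"], keep_default_na=False)
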