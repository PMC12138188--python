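"""Feature-table I/O, abundance filtering, pair enumeration, output matrices.

The feature table is a tab-separated genome-by-feature matrix of 0/1
presence calls: rows are genomes (first column holds the genome ID), the
header row holds feature names.  Feature names may carry prefixes such as
``plasmid_`` that group them into functional subsets; the comparison plan
selects which unordered feature pairs are fit, either exhaustively or
restricted by prefix (``compare_from`` / ``compare_to``).

Results are written as two symmetric TSV matrices (Z-scores, P-values) over
the full retained feature set, with ``NA`` marking the diagonal, untested
pairs and invalid fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FeatureTableError, ParameterError


@dataclass(frozen=True)
class FeatureTable:
    """Genome-by-feature 0/1 presence matrix."""

    data: pd.DataFrame  # int8 values, index = genome IDs, columns = features

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = sorted(self.data.index[self.data.index.duplicated()])
            raise FeatureTableError(f"duplicate genome IDs: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = sorted(self.data.columns[self.data.columns.duplicated()])
            raise FeatureTableError(f"duplicate feature names: {dupes}")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def presence_counts(self) -> pd.Series:
        return self.data.sum(axis=0)

    def column(self, name: str) -> pd.Series:
        return self.data[name]

    def write(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "genome"
        out.to_csv(path, sep="\t")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Parse and validate a tab-separated 0/1 feature table.

    Every cell must be exactly ``0`` or ``1``; offending cells are reported
    with their genome/feature coordinates.
    """
    with open(path) as handle:  # pandas renames duplicate columns silently
        header = handle.readline().rstrip("\n").split("\t")[1:]
    dupes = sorted({name for name in header if header.count(name) > 1})
    if dupes:
        raise FeatureTableError(f"duplicate feature names: {dupes}")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    raw.index = raw.index.astype(str)
    bad = []
    for col in raw.columns:
        stripped = raw[col].str.strip()
        mask = ~stripped.isin(("0", "1"))
        for genome in raw.index[mask]:
            bad.append((genome, col, raw.at[genome, col]))
    if bad:
        g, c, v = bad[0]
        raise FeatureTableError(
            f"cell (genome={g!r}, feature={c!r}) has value {v!r}; "
            f"every cell must be 0 or 1 ({len(bad)} offending cell(s))"
        )
    data = raw.apply(lambda s: s.str.strip()).astype(np.int8)
    return FeatureTable(data)


@dataclass(frozen=True)
class FilterReport:
    """Names and presence counts of features removed by the abundance filter."""

    removed: tuple[tuple[str, int], ...]
    min_count: int
    max_count: int

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def abundance_filter(
    table: FeatureTable, min_count: int, max_count: int
) -> tuple[FeatureTable, FilterReport]:
    """Drop features whose presence count falls outside [min_count, max_count].

    Bounds are absolute presence counts and inclusive at both ends; features
    present in almost no or almost all genomes carry no usable signal for a
    pairwise association test.
    """
    n_genomes = table.shape[0]
    if not 0 <= min_count <= max_count <= n_genomes:
        raise ParameterError(
            f"need 0 <= min_count <= max_count <= {n_genomes}, "
            f"got min={min_count} max={max_count}"
        )
    counts = table.presence_counts()
    keep = (counts >= min_count) & (counts <= max_count)
    removed = tuple(
        (name, int(counts[name])) for name in table.feature_names if not keep[name]
    )
    filtered = FeatureTable(table.data.loc[:, keep[keep].index])
    return filtered, FilterReport(removed, min_count, max_count)


@dataclass(frozen=True)
class ComparisonPlan:
    """The unordered feature pairs selected for fitting."""

    pairs: tuple[tuple[str, str], ...]
    from_prefixes: tuple[str, ...]
    to_prefixes: tuple[str, ...]
    warnings: tuple[str, ...] = field(default=())

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _match_prefixes(
    features: Sequence[str], prefixes: Sequence[str]
) -> tuple[set[str], list[str]]:
    if not prefixes:
        return set(features), []
    selected: set[str] = set()
    warnings = []
    for prefix in prefixes:
        hits = {f for f in features if f.startswith(prefix)}
        if not hits:
            warnings.append(f"prefix {prefix!r} matches no feature")
        selected |= hits
    return selected, warnings


def enumerate_pairs(
    features: Sequence[str],
    from_prefixes: Sequence[str] = (),
    to_prefixes: Sequence[str] = (),
) -> ComparisonPlan:
    """Build the comparison plan from literal name-prefix subsets.

    A pair {a, b} is included when one member matches a ``from`` prefix and
    the other a ``to`` prefix (in either orientation); an empty prefix list
    selects the full feature set.  Each qualifying pair appears exactly once,
    ordered by position in ``features``.
    """
    from_set, warn_f = _match_prefixes(features, from_prefixes)
    to_set, warn_t = _match_prefixes(features, to_prefixes)
    pairs = []
    for i, a in enumerate(features):
        for b in features[i + 1 :]:
            if (a in from_set and b in to_set) or (a in to_set and b in from_set):
                pairs.append((a, b))
    return ComparisonPlan(
        pairs=tuple(pairs),
        from_prefixes=tuple(from_prefixes),
        to_prefixes=tuple(to_prefixes),
        warnings=tuple(warn_f + warn_t),
    )


def build_matrices(
    results: Mapping[tuple[str, str], tuple[float, float] | None],
    features: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric Z and P DataFrames over ``features``; untested cells NaN."""
    z = pd.DataFrame(np.nan, index=list(features), columns=list(features))
    p = z.copy()
    for (a, b), value in results.items():
        if a == b:
            raise ParameterError(f"self-pair ({a!r}, {a!r}) is not a comparison")
        if value is None:
            continue
        zval, pval = value
        z.loc[a, b] = z.loc[b, a] = zval
        p.loc[a, b] = p.loc[b, a] = pval
    return z, p


def write_matrices(
    results: Mapping[tuple[str, str], tuple[float, float] | None],
    features: Sequence[str],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write the Z and P matrices as TSV with ``NA`` for absent values.

    Returns the two paths (``<prefix>.zscores.tsv``, ``<prefix>.pvalues.tsv``).
    Values are serialised with ``repr`` precision so a re-parse reproduces
    them bit-for-bit.
    """
    z, p = build_matrices(results, features)
    z_path = Path(f"{out_prefix}.zscores.tsv")
    p_path = Path(f"{out_prefix}.pvalues.tsv")
    for frame, path in ((z, z_path), (p, p_path)):
        frame.to_csv(
            path,
            sep="\t",
            na_rep="NA",
            index_label="feature",
            float_format=lambda v: format(float(v), ".17g"),
        )
    return z_path, p_path


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Re-parse a Z or P matrix written by :func:`write_matrices`."""
    frame = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=["NA"],
        keep_default_na=False,
        float_precision="round_trip",
    )
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame
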