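"""Abundance data and species frequency counts.

The sufficient statistic for every richness estimator in this package is the
frequency-count spectrum: ``f_k`` is the number of species observed exactly
``k`` times in a sample of individuals.  Species never observed contribute
``f_0``, which is the estimand and is never stored here.

Two plain-text input formats are supported:

* *abundance* — one record per observed species, ``label,count`` or a bare
  ``count`` per line; and
* *frequency* — ``k,f_k`` records.

Both accept ``#`` comment lines, an optional header row, and comma or tab
delimiters (auto-sniffed).
"""

from __future__ import annotations

import csv
import io
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from numbers import Integral, Real
from pathlib import Path

__all__ = [
    "AbundanceVector",
    "FrequencyCounts",
    "freq_counts_from_abundances",
    "read_counts",
]


@dataclass(frozen=True)
class AbundanceVector:
    """Per-species individual counts ``X_i`` for the observed species.

    Species absent from the sample are by definition not listed; every count
    must therefore be a positive integer.
    """

    counts: tuple[int, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = tuple(self.counts)
        for i, x in enumerate(counts):
            if not isinstance(x, Integral) or isinstance(x, bool):
                name = self._name(i)
                raise ValueError(
                    f"abundance for {name} is {x!r}; counts must be integers"
                )
            if x <= 0:
                name = self._name(i)
                raise ValueError(
                    f"abundance for {name} is {x}; observed species must have "
                    "count >= 1 (unobserved species are not listed)"
                )
        object.__setattr__(self, "counts", tuple(int(x) for x in counts))
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != len(counts):
                raise ValueError(
                    f"{len(labels)} labels for {len(counts)} counts"
                )
            object.__setattr__(self, "labels", labels)

    def _name(self, i: int) -> str:
        if self.labels is not None and i < len(self.labels):
            return f"species {self.labels[i]!r} (entry {i})"
        return f"entry {i}"

    @property
    def n(self) -> int:
        """Total number of individuals in the sample."""
        return sum(self.counts)

    @property
    def s_obs(self) -> int:
        """Number of observed species."""
        return len(self.counts)


@dataclass(frozen=True)
class FrequencyCounts:
    """Sparse frequency-count spectrum ``{k: f_k}`` with derived totals.

    Values are stored as floats so that *expected* spectra ``E[f_k]`` (used
    for moment identities and estimator oracles) share the same container as
    observed integer tallies.  Keys are strictly positive multiplicities.
    """

    f: Mapping[int, float]

    def __post_init__(self) -> None:
        clean: dict[int, float] = {}
        for k, v in self.f.items():
            if not isinstance(k, Integral) or isinstance(k, bool) or k < 1:
                raise ValueError(f"multiplicity {k!r} must be an integer >= 1")
            if not isinstance(v, Real) or v < 0:
                raise ValueError(f"f_{k} = {v!r} must be a non-negative real")
            clean[int(k)] = float(v)
        object.__setattr__(self, "f", clean)

    def __getitem__(self, k: int) -> float:
        return self.f.get(k, 0.0)

    @property
    def n(self) -> float:
        """Total individuals, ``sum k * f_k``."""
        return sum(k * v for k, v in self.f.items())

    @property
    def s_obs(self) -> float:
        """Observed richness, ``sum f_k``."""
        return sum(self.f.values())

    @property
    def sum_sq(self) -> float:
        """``sum k^2 * f_k``, i.e. ``sum X_i^2`` over observed species."""
        return sum(k * k * v for k, v in self.f.items())

    @property
    def is_integral(self) -> bool:
        return all(v == int(v) for v in self.f.values())

    def nonzero(self) -> dict[int, float]:
        """The spectrum restricted to strictly positive counts."""
        return {k: v for k, v in sorted(self.f.items()) if v > 0}

    def summary(self) -> str:
        return (
            f"S_obs={self.s_obs:g}, n={self.n:g}, "
            f"f1={self[1]:g}, f2={self[2]:g}, f3={self[3]:g}"
        )


def freq_counts_from_abundances(
    abundances: AbundanceVector | Iterable[int],
) -> FrequencyCounts:
    """Tally per-species counts into a frequency spectrum.

    ``f_k = #{i : X_i = k}``; the derived totals satisfy
    ``n = sum X_i`` and ``S_obs = len(X)``.
    """
    if not isinstance(abundances, AbundanceVector):
        abundances = AbundanceVector(tuple(abundances))
    f: dict[int, float] = {}
    for x in abundances.counts:
        f[x] = f.get(x, 0.0) + 1.0
    return FrequencyCounts(f)


def _sniff_rows(path: Path) -> list[list[str]]:
    text = path.read_text(encoding="utf-8")
    lines = [
        ln for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: no data rows")
    sample = "\n".join(lines[:20])
    try:
        dialect = csv.Sniffer().sniff(sample, delimiters=",\t;")
        delim = dialect.delimiter
    except csv.Error:
        delim = "\t" if "\t" in lines[0] else ","
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter=delim)
    rows = [[c.strip() for c in row] for row in reader]

    def numeric(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    # drop a header row: first row whose last cell is non-numeric
    if rows and not numeric(rows[0][-1]):
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no data rows after header")
    return rows


def _int_cell(cell: str, where: str) -> int:
    try:
        v = float(cell)
    except ValueError:
        raise ValueError(f"{where}: {cell!r} is not a number") from None
    if v != int(v):
        raise ValueError(f"{where}: {cell!r} is not an integer")
    return int(v)


def read_counts(
    path: str | Path,
    format: str = "abundance",
    delimiter: str | None = None,
) -> FrequencyCounts:
    """Read a frequency spectrum from a plain-text file.

    Parameters
    ----------
    path:
        File to read; UTF-8, ``#`` comments allowed, optional header row.
    format:
        ``"abundance"`` (one count per observed species, optional leading
        label column) or ``"frequency"`` (``k,f_k`` pairs; explicit zero
        ``f_k`` rows are kept, duplicate ``k`` rejected).
    delimiter:
        Override the sniffed delimiter.
    """
    path = Path(path)
    if format not in ("abundance", "frequency"):
        raise ValueError(f"unknown format {format!r}")
    rows = _sniff_rows(path)
    if delimiter is not None:
        text = path.read_text(encoding="utf-8")
        lines = [
            ln for ln in text.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        rows = [
            [c.strip() for c in ln.split(delimiter)] for ln in lines
        ]
        if rows and any(not _is_number(c) for c in rows[0][-1:]):
            rows = rows[1:]

    if format == "frequency":
        f: dict[int, float] = {}
        for i, row in enumerate(rows):
            if len(row) != 2:
                raise ValueError(
                    f"{path} row {i + 1}: expected two columns (k, f_k), "
                    f"got {len(row)}"
                )
            k = _int_cell(row[0], f"{path} row {i + 1} (k)")
            v = _int_cell(row[1], f"{path} row {i + 1} (f_k)")
            if k < 1:
                raise ValueError(f"{path} row {i + 1}: k = {k} must be >= 1")
            if v < 0:
                raise ValueError(f"{path} row {i + 1}: f_{k} = {v} is negative")
            if k in f:
                raise ValueError(f"{path} row {i + 1}: duplicate multiplicity k={k}")
            f[k] = float(v)
        return FrequencyCounts(f)

    counts: list[int] = []
    labels: list[str] = []
    for i, row in enumerate(rows):
        if len(row) == 1:
            labels.append(f"row{i + 1}")
            cell = row[0]
        elif len(row) == 2:
            labels.append(row[0])
            cell = row[1]
        else:
            raise ValueError(
                f"{path} row {i + 1}: expected 'count' or 'label,count', "
                f"got {len(row)} columns"
            )
        x = _int_cell(cell, f"{path} row {i + 1}")
        if x <= 0:
            raise ValueError(
                f"{path} row {i + 1} ({labels[-1]}): count {x} must be >= 1"
            )
        counts.append(x)
    return freq_counts_from_abundances(
        AbundanceVector(tuple(counts), tuple(labels))
    )


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False
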