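"""Packaged survey fixtures.

Three published abundance-frequency rows ship with the package and serve as
worked examples and as empirical "true assemblages" for resampling studies:

* ``vascular`` — vascular plants, southern Appalachians (188 species,
  1,008 individuals);
* ``butterfly`` — the classic Malayan butterfly light-trap survey
  (620 species, 9,031 individuals);
* ``invertebrate`` — ground-dwelling invertebrates, northwest Tasmania
  (the printed row sums to 85 species over 2,050 individuals; the survey
  total is reported as 84 — the row ships verbatim).

Each file lists f_k for k = 1..14 plus an aggregated ``15+`` tail (species
seen at least 15 times).  The loader keeps the tail separate: the rare
counts f1..f3 that drive every estimator are exact, while reconstructing
per-species tail abundances (needed only for empirical resampling) uses a
documented deterministic allocation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .assemblages import Assemblage, empirical_assemblage
from .frequency import FrequencyCounts

__all__ = ["FIXTURE_NAMES", "Fixture", "load_fixture", "write_fixture"]

FIXTURE_NAMES = ("vascular", "butterfly", "invertebrate")

_TAIL_K_MIN = 15


@dataclass(frozen=True)
class Fixture:
    """A packaged frequency row with its aggregated tail."""

    name: str
    head: FrequencyCounts  # exact counts for k = 1..14
    tail_species: int  # species observed >= 15 times
    total_species: int
    total_individuals: int

    @property
    def tail_total(self) -> int:
        """Individuals in the aggregated tail, by subtraction."""
        return self.total_individuals - int(self.head.n)

    @property
    def s_obs(self) -> int:
        return int(self.head.s_obs) + self.tail_species

    def frequency_counts(self) -> FrequencyCounts:
        """Full spectrum with the tail expanded into concrete abundances.

        The rare counts f1..f3 are exact; multiplicities >= 15 depend on the
        deterministic tail allocation.
        """
        from .frequency import freq_counts_from_abundances
        from .assemblages import geometric_tail_allocation

        counts: list[int] = []
        for k, v in self.head.nonzero().items():
            counts.extend([int(k)] * int(v))
        counts.extend(
            geometric_tail_allocation(self.tail_species, self.tail_total, _TAIL_K_MIN)
        )
        return freq_counts_from_abundances(counts)

    def assemblage(self) -> Assemblage:
        """Empirical true assemblage with the tail expanded."""
        return empirical_assemblage(
            self.head,
            tail_species=self.tail_species,
            tail_total=self.tail_total,
            tail_k_min=_TAIL_K_MIN,
            model_id=f"empirical:{self.name}",
        )


def _fixture_text(name: str) -> str:
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return (
        resources.files("gprich.data").joinpath(f"{name}.csv").read_text("utf-8")
    )


def load_fixture(name: str) -> Fixture:
    """Load a packaged frequency row by name."""
    text = _fixture_text(name)
    meta: dict[str, int] = {}
    f: dict[int, float] = {}
    tail_species = 0
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                val = val.strip()
                if key.strip() in ("total_species", "total_individuals"):
                    meta[key.strip()] = int(val)
            continue
        k_cell, _, v_cell = line.partition(",")
        if k_cell == "k":
            continue
        if k_cell.endswith("+"):
            tail_species = int(v_cell)
            continue
        f[int(k_cell)] = float(v_cell)
    return Fixture(
        name,
        FrequencyCounts(f),
        tail_species,
        meta["total_species"],
        meta["total_individuals"],
    )


def write_fixture(name: str, dest: str | Path) -> Path:
    """Copy a packaged fixture file to ``dest`` (file or directory)."""
    text = _fixture_text(name)
    dest = Path(dest)
    if dest.is_dir():
        dest = dest / f"{name}.csv"
    dest.write_text(text, encoding="utf-8")
    return dest
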