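"""Longitudinal census records and their reduction to transition tallies.

The sufficient statistics of the transition model are, per species x size
class x observation-interval length, the counts of stems present at the
start of an interval (``n_all``) and of those found one interval later in
the same class (``n_st``), one class up (``n_pr``) or one class down
(``n_rt``); the shortfall against ``n_all`` is deaths.  Survey years are
treated as replicates, so tallies are pooled over calendar time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .scheme import SizeClassScheme

ALLOWED_INTERVALS = (1, 2, 4)

TALLY_COLUMNS = ["species", "class", "interval", "n_all", "n_st", "n_pr", "n_rt"]
RECORD_COLUMNS = ["individual_id", "species", "year", "status", "class_label"]


@dataclass(frozen=True)
class Observation:
    year: int
    alive: bool
    class_index: int | None  # None iff dead

    def __post_init__(self) -> None:
        if self.alive and self.class_index is None:
            raise ValueError("live observation requires a class index")
        if not self.alive and self.class_index is not None:
            raise ValueError("dead observation must not carry a class index")


@dataclass(frozen=True)
class IndividualHistory:
    """One stem's ordered survey record."""

    individual_id: str
    species: str
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        years = [o.year for o in obs]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError(
                f"individual {self.individual_id!r}: survey years must strictly increase"
            )
        seen_dead = False
        for o in obs:
            if seen_dead and o.alive:
                raise ValueError(
                    f"individual {self.individual_id!r}: alive after recorded death"
                )
            seen_dead = seen_dead or not o.alive


@dataclass(frozen=True)
class TransitionTally:
    """Counts for one species x class x interval cell."""

    species: str
    class_index: int
    interval_years: int
    n_all: int
    n_st: int
    n_pr: int
    n_rt: int

    def __post_init__(self) -> None:
        if self.interval_years not in ALLOWED_INTERVALS:
            raise ValueError(
                f"interval {self.interval_years} not supported (use 1, 2 or 4)"
            )
        counts = (self.n_all, self.n_st, self.n_pr, self.n_rt)
        if any(c < 0 for c in counts):
            raise ValueError("tally counts must be non-negative")
        if self.n_st + self.n_pr + self.n_rt > self.n_all:
            raise ValueError(
                f"{self.species} class {self.class_index} interval "
                f"{self.interval_years}: survivors exceed starters"
            )

    @property
    def n_survivors(self) -> int:
        return self.n_st + self.n_pr + self.n_rt

    @property
    def n_dead(self) -> int:
        return self.n_all - self.n_survivors

    def validate_against(self, scheme: SizeClassScheme, species_max: bool = True) -> None:
        if not 1 <= self.class_index <= scheme.n_classes:
            raise ValueError(f"class index {self.class_index} outside scheme")
        if self.n_rt and self.class_index not in scheme.retro_classes:
            raise ValueError(
                f"retrogression tallied at class {self.class_index}, which is "
                f"not retrogression-capable"
            )
        if species_max and self.n_pr and self.class_index >= scheme.max_class(self.species):
            raise ValueError(
                f"progression tallied at or above the maximum class of "
                f"{self.species}"
            )


def tally_transitions(
    histories: Iterable[IndividualHistory],
    scheme: SizeClassScheme,
) -> list[TransitionTally]:
    """Reduce survey histories to pooled transition tallies.

    Every consecutive pair of observations whose first member is alive
    contributes one count to exactly one (species, class, interval) cell;
    years are pooled.  Intervals other than 1, 2 or 4 years and class jumps
    of more than one step are rejected with a diagnostic naming the
    individual.
    """
    cells: dict[tuple[str, int, int], list[int]] = {}
    for h in histories:
        for a, b in zip(h.observations, h.observations[1:]):
            if not a.alive:
                continue
            dt = b.year - a.year
            if dt not in ALLOWED_INTERVALS:
                raise ValueError(
                    f"individual {h.individual_id!r}: observation interval "
                    f"{a.year}->{b.year} is {dt} years; only 1, 2 or 4 supported"
                )
            i = a.class_index
            assert i is not None
            key = (h.species, i, dt)
            cell = cells.setdefault(key, [0, 0, 0, 0])
            cell[0] += 1
            if not b.alive:
                continue
            step = b.class_index - i
            if abs(step) > 1:
                raise ValueError(
                    f"individual {h.individual_id!r}: class jump of {step} between "
                    f"{a.year} and {b.year}; transitions are limited to one class"
                )
            if step == 0:
                cell[1] += 1
            elif step == 1:
                cell[2] += 1
            else:
                if i not in scheme.retro_classes:
                    raise ValueError(
                        f"individual {h.individual_id!r}: retrogression from class "
                        f"{i}, which is not retrogression-capable"
                    )
                cell[3] += 1
    tallies = [
        TransitionTally(sp, i, dt, *counts)
        for (sp, i, dt), counts in sorted(cells.items())
    ]
    for t in tallies:
        t.validate_against(scheme)
    return tallies


# ---------------------------------------------------------------------------
# delimited-text IO


def tallies_to_frame(tallies: Iterable[TransitionTally]) -> pd.DataFrame:
    rows = [
        (t.species, t.class_index, t.interval_years, t.n_all, t.n_st, t.n_pr, t.n_rt)
        for t in tallies
    ]
    return pd.DataFrame(rows, columns=TALLY_COLUMNS)


def write_tally_table(tallies: Iterable[TransitionTally], path: str | Path, sep: str = "\t") -> None:
    tallies_to_frame(tallies).to_csv(path, sep=sep, index=False)


def read_tally_table(path: str | Path | io.IOBase, sep: str | None = None) -> list[TransitionTally]:
    """Read a delimited tally table (tab or comma separated, sniffed)."""
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in TALLY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tally table missing columns: {missing}")
    out = []
    for pos in range(len(df)):
        row = df.iloc[pos]
        line = pos + 2  # header is line 1
        try:
            out.append(
                TransitionTally(
                    species=str(row["species"]),
                    class_index=int(row["class"]),
                    interval_years=int(row["interval"]),
                    n_all=int(row["n_all"]),
                    n_st=int(row["n_st"]),
                    n_pr=int(row["n_pr"]),
                    n_rt=int(row["n_rt"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return out


def histories_to_frame(histories: Iterable[IndividualHistory], scheme: SizeClassScheme) -> pd.DataFrame:
    rows = []
    for h in histories:
        for o in h.observations:
            rows.append(
                (
                    h.individual_id,
                    h.species,
                    o.year,
                    "alive" if o.alive else "dead",
                    scheme.label_of(o.class_index) if o.alive else "",
                )
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(histories: Iterable[IndividualHistory], scheme: SizeClassScheme, path: str | Path, sep: str = "\t") -> None:
    histories_to_frame(histories, scheme).to_csv(path, sep=sep, index=False)


def read_records(path: str | Path, scheme: SizeClassScheme, sep: str | None = None) -> list[IndividualHistory]:
    df = pd.read_csv(path, sep=sep, engine="python", keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")
    out = []
    for (ind, sp), grp in df.groupby(["individual_id", "species"], sort=True):
        grp = grp.sort_values("year")
        obs = []
        for line, row in grp.iterrows():
            alive = str(row["status"]).lower() == "alive"
            cls = scheme.index_of(str(row["class_label"])) if alive else None
            obs.append(Observation(int(row["year"]), alive, cls))
        out.append(IndividualHistory(str(ind), str(sp), tuple(obs)))
    return out
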