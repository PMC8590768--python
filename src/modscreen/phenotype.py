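"""Hatching-rate and population assays with right-censored survival curves.

The hatching assay counts eggs laid and embryos hatched per plate over four
daily transfers; the hatching rate is total hatched / total laid (progeny of
worms that died or were lost stay in the denominator). The population assay
follows each plate daily for three events — 50 viable worms, 50 L4-or-older
worms, population death — with the experiment terminated at 30 days.

Event-time distributions are summarised with the Kaplan–Meier product-limit
estimator (via lifelines); reports use the 1 − S(t) orientation ("% of
plates to reach the metric by day t"). A plate that dies before reaching a
population metric is censored for that metric at its death day; ties between
events and censorings at one day count the events first (the standard
product-limit convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import FormatError, ModelError

POPULATION_THRESHOLD = 50
HORIZON_DAYS = 30

METRICS = ("reach_viable_50", "reach_l4_50", "death")


@dataclass(frozen=True)
class HatchPlate:
    """Daily (eggs laid, hatched) counts for one plate, up to 4 days."""

    strain_id: str
    plate_id: str
    days: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.days) > 4:
            raise ModelError(f"plate {self.plate_id}: more than 4 hatch-assay days")
        for laid, hatched in self.days:
            if laid < 0 or hatched < 0:
                raise ModelError(f"plate {self.plate_id}: negative counts")
        if self.total_hatched > self.total_laid:
            raise ModelError(f"plate {self.plate_id}: hatched exceeds eggs laid")

    @property
    def total_laid(self) -> int:
        return sum(laid for laid, _ in self.days)

    @property
    def total_hatched(self) -> int:
        return sum(hatched for _, hatched in self.days)


@dataclass(frozen=True)
class PopulationPlate:
    """Daily population counts for one plate: (day, viable, L4-or-older)."""

    strain_id: str
    plate_id: str
    daily: tuple[tuple[int, int, int], ...]
    death_day: Optional[int] = None
    horizon: int = HORIZON_DAYS

    def __post_init__(self) -> None:
        for day, viable, l4plus in self.daily:
            if l4plus > viable:
                raise ModelError(
                    f"plate {self.plate_id} day {day}: L4+ count exceeds viable count"
                )
            if self.death_day is not None and day >= self.death_day and viable > 0:
                raise ModelError(
                    f"plate {self.plate_id}: viable > 0 on/after death day"
                )


@dataclass(frozen=True)
class EventRecord:
    """One plate's outcome for one metric: day plus observed/censored flag."""

    day: int
    observed: bool


@dataclass
class SurvivalCurve:
    """Product-limit estimates at the observed event/censoring times."""

    event_times: list[int]
    estimates: list[float]
    n_events: list[int]
    n_censored: list[int]
    at_risk: list[int]

    def survival_at(self, day: float) -> float:
        s = 1.0
        for t, est in zip(self.event_times, self.estimates):
            if t <= day:
                s = est
            else:
                break
        return s

    def cumulative_incidence_at(self, day: float) -> float:
        """1 − S(t): fraction of plates having reached the metric by `day`."""
        return 1.0 - self.survival_at(day)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def hatching_rate(plate: HatchPlate) -> Optional[float]:
    """Percentage of eggs that hatched, to 2 decimals; None for zero eggs."""
    if plate.total_laid == 0:
        return None
    return round(100.0 * plate.total_hatched / plate.total_laid, 2)


def population_events(
    plate: PopulationPlate, threshold: int = POPULATION_THRESHOLD
) -> dict[str, EventRecord]:
    """Event day (or censoring) for each of the three population metrics."""
    days = [d for d, _, _ in plate.daily]
    if days != sorted(days):
        raise FormatError(f"plate {plate.plate_id}: daily records not sorted by day")
    last_day = min(days[-1], plate.horizon) if days else plate.horizon
    censor_day = plate.death_day if plate.death_day is not None else last_day

    records: dict[str, EventRecord] = {}
    for metric, column in (("reach_viable_50", 1), ("reach_l4_50", 2)):
        hit = next(
            (d for d, *counts in plate.daily if counts[column - 1] >= threshold), None
        )
        if hit is not None and (plate.death_day is None or hit <= plate.death_day):
            records[metric] = EventRecord(day=hit, observed=True)
        else:
            records[metric] = EventRecord(day=censor_day, observed=False)
    if plate.death_day is not None and plate.death_day <= plate.horizon:
        records["death"] = EventRecord(day=plate.death_day, observed=True)
    else:
        records["death"] = EventRecord(day=last_day, observed=False)
    return records


def km_curve(event_records: Sequence[EventRecord]) -> SurvivalCurve:
    """Kaplan–Meier product-limit curve over plates for one metric."""
    if not event_records:
        raise ModelError("km_curve requires at least one event record")
    durations = [r.day for r in event_records]
    observed = [r.observed for r in event_records]
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table
    sf = kmf.survival_function_[kmf.survival_function_.columns[0]]
    times, estimates, n_events, n_censored, at_risk = [], [], [], [], []
    for t, row in table.iterrows():
        if t == 0 and row["observed"] == 0 and row["censored"] == 0:
            continue
        times.append(int(t))
        estimates.append(float(sf.loc[t]))
        n_events.append(int(row["observed"]))
        n_censored.append(int(row["censored"]))
        at_risk.append(int(row["at_risk"]))
    return SurvivalCurve(
        event_times=times,
        estimates=estimates,
        n_events=n_events,
        n_censored=n_censored,
        at_risk=at_risk,
    )


def strain_summary(
    hatch_plates: Sequence[HatchPlate],
    population_plates: Sequence[PopulationPlate],
    threshold: int = POPULATION_THRESHOLD,
) -> pd.DataFrame:
    """Per-strain summary table: brood size, pooled hatching rate, metric rates.

    The hatching rate is pooled (total hatched / total laid across plates),
    not a mean of per-plate rates.
    """
    strains = sorted(
        {p.strain_id for p in hatch_plates} | {p.strain_id for p in population_plates}
    )
    rows = []
    for strain in strains:
        hp = [p for p in hatch_plates if p.strain_id == strain]
        pp = [p for p in population_plates if p.strain_id == strain]
        laid = sum(p.total_laid for p in hp)
        hatched = sum(p.total_hatched for p in hp)
        events = [population_events(p, threshold) for p in pp]
        n_pop = len(events)
        row = {
            "strain_id": strain,
            "n_hatch_plates": len(hp),
            "mean_eggs_laid": round(laid / len(hp), 2) if hp else None,
            "hatching_rate_pct": round(100.0 * hatched / laid, 2) if laid else None,
            "n_population_plates": n_pop,
        }
        for metric in METRICS:
            hit = sum(1 for e in events if e[metric].observed)
            row[f"pct_{metric}"] = round(100.0 * hit / n_pop, 2) if n_pop else None
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plate TSV I/O (formats emitted by the synthetic screen)
# ---------------------------------------------------------------------------


def read_hatch_tsv(path) -> list[HatchPlate]:
    df = pd.read_csv(path, sep="\t", comment="#")
    plates = []
    for (strain, plate), grp in df.groupby(["strain", "plate"], sort=True):
        grp = grp.sort_values("day")
        plates.append(
            HatchPlate(
                strain_id=str(strain),
                plate_id=str(plate),
                days=tuple(
                    (int(r.laid), int(r.hatched)) for r in grp.itertuples()
                ),
            )
        )
    return plates


def read_population_tsv(path, horizon: int = HORIZON_DAYS) -> list[PopulationPlate]:
    df = pd.read_csv(path, sep="\t", comment="#")
    plates = []
    for (strain, plate), grp in df.groupby(["strain", "plate"], sort=True):
        grp = grp.sort_values("day")
        dead_rows = grp[grp["dead_flag"] == 1]
        death_day = int(dead_rows["day"].iloc[0]) if len(dead_rows) else None
        plates.append(
            PopulationPlate(
                strain_id=str(strain),
                plate_id=str(plate),
                daily=tuple(
                    (int(r.day), int(r.viable), int(r.l4plus)) for r in grp.itertuples()
                ),
                death_day=death_day,
                horizon=horizon,
            )
        )
    return plates


def write_hatch_tsv(plates: Sequence[HatchPlate], path, header_comment=None) -> None:
    rows = [
        {"strain": p.strain_id, "plate": p.plate_id, "day": day, "laid": laid,
         "hatched": hatched}
        for p in plates
        for day, (laid, hatched) in enumerate(p.days, start=1)
    ]
    _write_tsv(pd.DataFrame(rows, columns=["strain", "plate", "day", "laid", "hatched"]),
               path, header_comment)


def write_population_tsv(plates: Sequence[PopulationPlate], path, header_comment=None) -> None:
    rows = [
        {"strain": p.strain_id, "plate": p.plate_id, "day": day, "viable": viable,
         "l4plus": l4plus,
         "dead_flag": int(p.death_day is not None and day >= p.death_day)}
        for p in plates
        for day, viable, l4plus in p.daily
    ]
    _write_tsv(
        pd.DataFrame(rows, columns=["strain", "plate", "day", "viable", "l4plus", "dead_flag"]),
        path, header_comment,
    )


def _write_tsv(df: pd.DataFrame, path, header_comment=None) -> None:
    with open(path, "w") as handle:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        df.to_csv(handle, sep="\t", index=False)
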