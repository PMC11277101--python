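"""Individual-level rearing records for a predator cohort experiment.

A cohort starts as a batch of eggs laid on day 0 of the cohort clock.
Each individual is followed daily: hatching, larval molts (exuviae),
adult emergence, sex and fresh weight at emergence, and death.  Paired
females additionally carry a daily reproduction ledger whose clutches
are inspected four days after laying to split eggs into hatched larvae,
embryonated eggs (fertile but failed to hatch) and infertile eggs.

The on-disk form is a long CSV: one *base* row per individual with the
life-history fields, optional *stage* rows (columns ``stage`` and
``stage_day``) and optional *reproduction* rows (columns ``rep_day``,
``eggs_laid``, ``hatched``, ``embryonated``, ``infertile``).  Empty
string means missing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "ClutchRecord",
    "IndividualRecord",
    "CohortDataset",
    "ValidationError",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "observed_sex_counts",
]

FEMALE = "female"
MALE = "male"
UNKNOWN = "unknown"

CSV_COLUMNS = [
    "individual_id", "diet", "day_laid", "day_hatched", "day_emerged_adult",
    "sex", "adult_weight_mg", "day_died", "censored", "stage", "stage_day",
    "rep_day", "eggs_laid", "hatched", "embryonated", "infertile",
]


class ValidationError(ValueError):
    """A record violates a dataset invariant; the message names the individual."""


class SchemaError(ValueError):
    """The CSV does not conform to the cohort data dictionary."""


@dataclass
class ClutchRecord:
    """One day's egg clutch for one female.

    ``day_observed`` is on the cohort clock (days since the female's own
    egg was laid).  Egg fates may be pending (``None``) when the female
    died before the four-day inspection; fates never exceed the clutch
    size.
    """

    day_observed: int
    eggs_laid: int
    hatched: Optional[int] = None
    embryonated: Optional[int] = None
    infertile: Optional[int] = None

    def fates_known(self) -> bool:
        return not (self.hatched is None and self.embryonated is None
                    and self.infertile is None)

    def n_fertile(self) -> int:
        """Fertile eggs = hatched + embryonated (unknown fates count 0)."""
        return (self.hatched or 0) + (self.embryonated or 0)

    def validate(self, owner: str) -> None:
        if self.day_observed < 0:
            raise ValidationError(f"{owner}: clutch day {self.day_observed} < 0")
        counts = [self.eggs_laid, self.hatched, self.embryonated, self.infertile]
        for c in counts:
            if c is not None and c < 0:
                raise ValidationError(f"{owner}: negative clutch count on day "
                                      f"{self.day_observed}")
        fated = sum(c for c in counts[1:] if c is not None)
        if fated > self.eggs_laid:
            raise ValidationError(
                f"{owner}: egg fates ({fated}) exceed eggs laid "
                f"({self.eggs_laid}) on day {self.day_observed}")


@dataclass
class IndividualRecord:
    """One reared insect, from egg (day_laid, cohort day 0) to death."""

    individual_id: str
    diet: str
    day_laid: int = 0
    day_hatched: Optional[int] = None
    day_emerged_adult: Optional[int] = None
    sex: str = UNKNOWN
    adult_weight_mg: Optional[float] = None
    day_died: Optional[int] = None
    censored: bool = False
    stage_transitions: list[tuple[str, int]] = field(default_factory=list)
    reproduction: list[ClutchRecord] = field(default_factory=list)

    # -- derived conveniences -------------------------------------------------
    @property
    def is_fertile_female(self) -> bool:
        """Female with at least one recorded clutch (the jackknife unit)."""
        return self.sex == FEMALE and len(self.reproduction) > 0

    def total_eggs(self) -> int:
        return sum(c.eggs_laid for c in self.reproduction)

    def total_fertile_eggs(self) -> int:
        return sum(c.n_fertile() for c in self.reproduction)

    def total_hatched(self) -> int:
        return sum(c.hatched or 0 for c in self.reproduction)

    def oviposition_days(self) -> list[int]:
        return sorted(c.day_observed for c in self.reproduction if c.eggs_laid > 0)

    def alive_at(self, day: int) -> bool:
        """Alive on day ``day``: not yet dead (death day itself counts dead)."""
        if self.day_died is None:
            return True
        return day < self.day_died

    def validate(self) -> None:
        iid = self.individual_id
        days = [("day_laid", self.day_laid), ("day_hatched", self.day_hatched),
                ("day_emerged_adult", self.day_emerged_adult),
                ("day_died", self.day_died)]
        present = [(n, d) for n, d in days if d is not None]
        for (na, da), (nb, db) in zip(present, present[1:]):
            if da > db:
                raise ValidationError(f"{iid}: {na} ({da}) > {nb} ({db})")
        if self.reproduction and self.sex != FEMALE:
            raise ValidationError(f"{iid}: reproduction recorded for sex "
                                  f"'{self.sex}'")
        if self.censored and self.day_died is not None:
            raise ValidationError(f"{iid}: censored record has a death day")
        if self.sex not in (FEMALE, MALE, UNKNOWN):
            raise ValidationError(f"{iid}: unrecognized sex '{self.sex}'")
        for clutch in self.reproduction:
            clutch.validate(iid)


@dataclass
class CohortDataset:
    """All individuals of one diet treatment plus the parental sex ratio.

    Following the study protocol, offspring sex ratios are not observed
    (progeny are not reared to adulthood); the proportion of females used
    to thin the maternity schedule comes from the parental population.
    """

    diet: str
    records: list[IndividualRecord] = field(default_factory=list)
    parental_sex_ratio: float = 0.5
    sex_ratio_source: str = "unspecified"

    def validate(self) -> None:
        if not 0.0 < self.parental_sex_ratio < 1.0:
            raise ValidationError(
                f"parental_sex_ratio {self.parental_sex_ratio} not in (0,1)")
        for rec in self.records:
            if rec.diet != self.diet:
                raise ValidationError(
                    f"{rec.individual_id}: diet '{rec.diet}' differs from "
                    f"cohort diet '{self.diet}'")
            rec.validate()

    # -- selectors ------------------------------------------------------------
    def fertile_females(self) -> list[IndividualRecord]:
        return [r for r in self.records if r.is_fertile_female]

    def drop_individual(self, individual_id: str) -> "CohortDataset":
        """Leave-one-out copy (the jackknife resampling step)."""
        kept = [r for r in self.records if r.individual_id != individual_id]
        if len(kept) == len(self.records):
            raise KeyError(f"no individual '{individual_id}' in cohort")
        return CohortDataset(self.diet, kept, self.parental_sex_ratio,
                             self.sex_ratio_source)


# ---------------------------------------------------------------------------
# CSV I/O

def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_int(text: str, what: str, row: int) -> Optional[int]:
    if text == "":
        return None
    try:
        return int(text)
    except ValueError:
        raise SchemaError(f"row {row}: cannot parse {what} '{text}' as integer")


def _parse_float(text: str) -> Optional[float]:
    return None if text == "" else float(text)


def write_cohort(dataset: CohortDataset, path) -> None:
    """Serialize a cohort to the long-format CSV dialect."""
    dataset.validate()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in dataset.records:
            writer.writerow([
                rec.individual_id, rec.diet, _fmt(rec.day_laid),
                _fmt(rec.day_hatched), _fmt(rec.day_emerged_adult), rec.sex,
                _fmt(rec.adult_weight_mg), _fmt(rec.day_died),
                _fmt(rec.censored), "", "", "", "", "", "", ""])
            for stage, day in rec.stage_transitions:
                writer.writerow([rec.individual_id, rec.diet] + [""] * 7 +
                                [stage, _fmt(day)] + [""] * 5)
            for c in rec.reproduction:
                writer.writerow([rec.individual_id, rec.diet] + [""] * 9 +
                                [_fmt(c.day_observed), _fmt(c.eggs_laid),
                                 _fmt(c.hatched), _fmt(c.embryonated),
                                 _fmt(c.infertile)])


def read_cohort(path, diet: str, parental_sex_ratio: Optional[float] = None,
                sex_ratio_source: str = "parental population") -> CohortDataset:
    """Load and validate a cohort CSV for one diet.

    Rows whose ``diet`` column differs from ``diet`` are rejected.  When
    ``parental_sex_ratio`` is None it is taken from the observed adult
    sex counts of the file itself (the parental-population convention).
    """
    records: dict[str, IndividualRecord] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        missing = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing required columns "
                              f"{sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            iid = row["individual_id"]
            if not iid:
                raise SchemaError(f"row {i}: empty individual_id")
            if row["diet"] != diet:
                raise ValidationError(
                    f"{iid}: diet '{row['diet']}' differs from requested "
                    f"'{diet}'")
            if row["rep_day"] != "":
                rec = records.get(iid)
                if rec is None:
                    raise SchemaError(f"row {i}: reproduction row for "
                                      f"'{iid}' precedes its base row")
                rec.reproduction.append(ClutchRecord(
                    day_observed=_parse_int(row["rep_day"], "rep_day", i),
                    eggs_laid=_parse_int(row["eggs_laid"], "eggs_laid", i) or 0,
                    hatched=_parse_int(row["hatched"], "hatched", i),
                    embryonated=_parse_int(row["embryonated"], "embryonated", i),
                    infertile=_parse_int(row["infertile"], "infertile", i)))
            elif row["stage"] != "":
                rec = records.get(iid)
                if rec is None:
                    raise SchemaError(f"row {i}: stage row for '{iid}' "
                                      f"precedes its base row")
                rec.stage_transitions.append(
                    (row["stage"], _parse_int(row["stage_day"], "stage_day", i)))
            else:
                if iid in records:
                    raise SchemaError(f"row {i}: duplicate base row for '{iid}'")
                day_laid = _parse_int(row["day_laid"], "day_laid", i)
                if day_laid is None:
                    raise SchemaError(f"row {i}: day_laid is required")
                records[iid] = IndividualRecord(
                    individual_id=iid, diet=diet, day_laid=day_laid,
                    day_hatched=_parse_int(row["day_hatched"], "day_hatched", i),
                    day_emerged_adult=_parse_int(row["day_emerged_adult"],
                                                 "day_emerged_adult", i),
                    sex=row["sex"] or UNKNOWN,
                    adult_weight_mg=_parse_float(row["adult_weight_mg"]),
                    day_died=_parse_int(row["day_died"], "day_died", i),
                    censored=row["censored"] in ("1", "true", "True"))
    dataset = CohortDataset(diet=diet, records=list(records.values()))
    if parental_sex_ratio is None:
        nf, nm = observed_sex_counts(dataset)
        if nf + nm == 0 or nf == 0 or nm == 0:
            dataset.parental_sex_ratio = 0.5
            dataset.sex_ratio_source = "default 0.5 (degenerate observed counts)"
        else:
            dataset.parental_sex_ratio = nf / (nf + nm)
            dataset.sex_ratio_source = "observed adult sex counts of this file"
    else:
        dataset.parental_sex_ratio = parental_sex_ratio
        dataset.sex_ratio_source = sex_ratio_source
    dataset.validate()
    return dataset


def observed_sex_counts(dataset: CohortDataset) -> tuple[int, int]:
    """Counts of emerged adults of known sex, (n_female, n_male).

    Unknown-sex adults are excluded; individuals that never emerged do
    not contribute.
    """
    n_f = sum(1 for r in dataset.records
              if r.day_emerged_adult is not None and r.sex == FEMALE)
    n_m = sum(1 for r in dataset.records
              if r.day_emerged_adult is not None and r.sex == MALE)
    return n_f, n_m
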