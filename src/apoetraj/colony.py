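"""Colony table loading and the exclusion rules producing the analysis cohort.

The input is a long-format table with one row per weight measurement, the
layout colony records are usually exported in: mouse id, sex, APOE genotype, birth
date, optional death date/cause, breeder flag, measurement date, weight in
grams.  Loading groups rows into per-mouse series sorted by age; malformed
rows are collected into the report rather than silently dropped.

Preprocessing applies the exclusion rules in a fixed, documented order:

1. breeders excluded (diet change confounds weight),
2. record-level date sanity (measurement before birth or after death),
3. records before 5 months of age dropped,
4. mice with monthly-normalized weight loss > 20% between consecutive
   retained measurements excluded,
5. mice with fewer than 3 remaining measurements excluded.

Record-level sanitation runs before mouse-level counting so the >=3-point
rule applies to clean records.  "Monthly" loss between measurements Delta
days apart is the observed fractional loss scaled by 30.44/Delta when
Delta >= 15 days; closer-spaced pairs are not rate-tested (short-gap
fluctuations would otherwise extrapolate to implausible monthly rates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ahmm import GENOTYPE_LEVELS, ObservationSequence, SEX_LEVELS

DAYS_PER_MONTH = 30.44

REQUIRED_COLUMNS = ("mouse_id", "sex", "genotype", "birth_date",
                    "measurement_date", "weight_g")
OPTIONAL_COLUMNS = ("death_date", "death_cause", "is_breeder")
_SYNONYMS = {
    "mouse_id": {"mouse_id", "mouseid", "id", "animal_id", "mouse"},
    "sex": {"sex"},
    "genotype": {"genotype", "apoe", "apoe_genotype"},
    "birth_date": {"birth_date", "dob", "date_of_birth", "birthdate"},
    "death_date": {"death_date", "dod", "date_of_death", "deathdate"},
    "death_cause": {"death_cause", "cause_of_death", "cod"},
    "is_breeder": {"is_breeder", "breeder"},
    "measurement_date": {"measurement_date", "date", "weigh_date", "collection_date"},
    "weight_g": {"weight_g", "weight", "weight_grams", "body_weight"},
}


class SchemaError(ValueError):
    """Required columns missing from the input table."""


class PreprocessError(ValueError):
    pass


@dataclass
class WeightRecord:
    measurement_date: pd.Timestamp
    age_months: float
    weight_g: float


@dataclass
class MouseSeries:
    """One mouse: static covariates plus its age-ordered weight records."""

    mouse_id: str
    sex: str
    genotype: str
    birth_date: pd.Timestamp
    death_date: pd.Timestamp | None = None
    death_cause: str | None = None
    is_breeder: bool = False
    records: list = field(default_factory=list)

    @property
    def ages(self) -> np.ndarray:
        return np.array([r.age_months for r in self.records])

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.weight_g for r in self.records])

    def to_observation(self) -> ObservationSequence:
        return ObservationSequence(
            mouse_id=self.mouse_id,
            sex=SEX_LEVELS.index(self.sex),
            genotype=GENOTYPE_LEVELS.index(self.genotype),
            ages=self.ages,
            weights=self.weights,
        )


@dataclass
class PreprocessConfig:
    min_age_months: float = 5.0
    min_points: int = 3
    max_monthly_loss: float = 0.20
    exclude_breeders: bool = True
    min_gap_days_for_rate: float = 15.0

    def validate(self) -> None:
        if self.min_age_months < 0 or self.min_points < 1 \
                or not 0 < self.max_monthly_loss < 1:
            raise PreprocessError("preprocess thresholds out of range")


@dataclass
class ExclusionReport:
    """Auditable record of what was excluded and why."""

    mouse_reasons: dict = field(default_factory=dict)    # mouse_id -> [reasons]
    record_reasons: list = field(default_factory=list)   # (mouse_id, date, reason)
    malformed_rows: list = field(default_factory=list)   # (row_index, message)
    counts: dict = field(default_factory=dict)           # stage -> counts

    def add_mouse(self, mouse_id: str, reason: str) -> None:
        self.mouse_reasons.setdefault(mouse_id, []).append(reason)

    @property
    def n_excluded_mice(self) -> int:
        return len(self.mouse_reasons)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"mouse_id": m, "reason": r}
                for m, reasons in sorted(self.mouse_reasons.items())
                for r in reasons]
        return pd.DataFrame(rows, columns=["mouse_id", "reason"])

    def to_json(self, path) -> None:
        payload = {
            "mouse_reasons": self.mouse_reasons,
            "record_reasons": [[m, str(d), r] for m, d, r in self.record_reasons],
            "malformed_rows": [[int(i), msg] for i, msg in self.malformed_rows],
            "counts": self.counts,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _canonical_columns(df: pd.DataFrame) -> pd.DataFrame:
    lower = {c.lower().strip().replace(" ", "_"): c for c in df.columns}
    mapping = {}
    for canon, names in _SYNONYMS.items():
        for name in names:
            if name in lower:
                mapping[lower[name]] = canon
                break
    df = df.rename(columns=mapping)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    for c in OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = None if c != "is_breeder" else False
    return df


def _norm_sex(v) -> str | None:
    s = str(v).strip().lower()
    if s in {"f", "female"}:
        return "female"
    if s in {"m", "male"}:
        return "male"
    return None


def _norm_genotype(v) -> str | None:
    s = str(v).strip().upper().replace("APOE", "").replace("HAPOE", "")
    s = s.strip("- ")
    table = {"E3/3": "E3/3", "3/3": "E3/3", "33": "E3/3",
             "E3/4": "E3/4", "3/4": "E3/4", "34": "E3/4",
             "E4/4": "E4/4", "4/4": "E4/4", "44": "E4/4"}
    return table.get(s)


def load_colony_table(
    path, format_dialect: str | None = None
) -> tuple[list[MouseSeries], ExclusionReport]:
    """Read a colony table (CSV or XLSX) into per-mouse series.

    Returns the series list (records sorted by age) and a report collecting
    malformed rows.  ``format_dialect`` overrides the suffix-based format
    guess ('csv' or 'xlsx').
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_dialect or ("xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv")
    df = pd.read_excel(path) if fmt == "xlsx" else pd.read_csv(path)
    report = ExclusionReport()
    if df.empty:
        _canonical_columns(df)  # still enforce the schema
        return [], report
    df = _canonical_columns(df)

    mice: dict[str, MouseSeries] = {}
    for idx, row in df.iterrows():
        mid = str(row["mouse_id"]).strip()
        sex = _norm_sex(row["sex"])
        geno = _norm_genotype(row["genotype"])
        birth = pd.to_datetime(row["birth_date"], errors="coerce")
        mdate = pd.to_datetime(row["measurement_date"], errors="coerce")
        weight = pd.to_numeric(row["weight_g"], errors="coerce")
        problems = []
        if not mid or mid.lower() == "nan":
            problems.append("missing mouse_id")
        if sex is None:
            problems.append(f"unrecognized sex {row['sex']!r}")
        if geno is None:
            problems.append(f"unrecognized genotype {row['genotype']!r}")
        if pd.isna(birth):
            problems.append("unparseable birth_date")
        if pd.isna(mdate):
            problems.append("unparseable measurement_date")
        if pd.isna(weight) or weight <= 0:
            problems.append(f"invalid weight {row['weight_g']!r}")
        if problems:
            report.malformed_rows.append((idx, "; ".join(problems)))
            continue
        if mid not in mice:
            death = pd.to_datetime(row.get("death_date"), errors="coerce")
            cause = row.get("death_cause")
            cause = None if pd.isna(cause) or str(cause).strip() == "" else str(cause).strip().lower()
            breeder = bool(row.get("is_breeder")) and str(row.get("is_breeder")).lower() not in {"false", "0", "no", "nan"}
            mice[mid] = MouseSeries(
                mouse_id=mid, sex=sex, genotype=geno, birth_date=birth,
                death_date=None if pd.isna(death) else death,
                death_cause=cause, is_breeder=breeder,
            )
        age = (mdate - mice[mid].birth_date).days / DAYS_PER_MONTH
        mice[mid].records.append(WeightRecord(mdate, float(age), float(weight)))

    out = []
    for series in mice.values():
        series.records.sort(key=lambda r: r.age_months)
        out.append(series)
    out.sort(key=lambda s: s.mouse_id)
    report.counts["loaded"] = {"n_rows": int(len(df)), "n_mice": len(out),
                              "n_malformed_rows": len(report.malformed_rows)}
    return out, report


def monthly_loss_rate(w_prev: float, w_curr: float, delta_days: float,
                      min_gap_days: float = 15.0) -> float | None:
    """Fractional weight loss normalized to a 30.44-day month.

    None when the gap is shorter than ``min_gap_days`` (rate not assessed).
    Positive values are losses.
    """
    if delta_days < min_gap_days:
        return None
    return (w_prev - w_curr) / w_prev * (DAYS_PER_MONTH / delta_days)


def apply_exclusions(
    mice: list[MouseSeries],
    rules: PreprocessConfig | None = None,
    report: ExclusionReport | None = None,
) -> tuple[list[MouseSeries], ExclusionReport]:
    """Apply the exclusion rules in order; returns (retained, report).

    The report reconciles: every input mouse is either retained or carries at
    least one exclusion reason.  The operation is idempotent and insensitive
    to input ordering.
    """
    rules = rules or PreprocessConfig()
    rules.validate()
    report = report or ExclusionReport()
    n_in = len(mice)

    stage = {"input_mice": n_in}
    survivors: list[MouseSeries] = []
    for mouse in sorted(mice, key=lambda s: s.mouse_id):
        if rules.exclude_breeders and mouse.is_breeder:
            report.add_mouse(mouse.mouse_id, "breeder")
            continue
        survivors.append(mouse)
    stage["after_breeders"] = len(survivors)

    cleaned: list[MouseSeries] = []
    for mouse in survivors:
        kept = []
        for rec in mouse.records:
            bad = rec.measurement_date < mouse.birth_date or (
                mouse.death_date is not None and rec.measurement_date > mouse.death_date)
            if bad:
                report.record_reasons.append(
                    (mouse.mouse_id, rec.measurement_date, "date_error"))
            elif rec.age_months < rules.min_age_months:
                report.record_reasons.append(
                    (mouse.mouse_id, rec.measurement_date, "under_age"))
            else:
                kept.append(rec)
        cleaned.append(MouseSeries(
            mouse_id=mouse.mouse_id, sex=mouse.sex, genotype=mouse.genotype,
            birth_date=mouse.birth_date, death_date=mouse.death_date,
            death_cause=mouse.death_cause, is_breeder=mouse.is_breeder,
            records=kept,
        ))
    stage["records_dropped"] = len(report.record_reasons)

    retained: list[MouseSeries] = []
    for mouse in cleaned:
        rates = []
        recs = mouse.records
        for prev, curr in zip(recs, recs[1:]):
            delta_days = (curr.measurement_date - prev.measurement_date).days
            rate = monthly_loss_rate(prev.weight_g, curr.weight_g, delta_days,
                                     rules.min_gap_days_for_rate)
            if rate is not None:
                rates.append(rate)
        if rates and max(rates) > rules.max_monthly_loss:
            report.add_mouse(mouse.mouse_id, "rapid_loss")
            continue
        if len(recs) < rules.min_points:
            report.add_mouse(mouse.mouse_id, "too_few_points")
            continue
        retained.append(mouse)
    stage["retained_mice"] = len(retained)
    stage["excluded_mice"] = n_in - len(retained)
    report.counts["exclusions"] = stage
    return retained, report


@dataclass
class CohortSummary:
    n_mice: int
    n_datapoints: int
    sex_pct: dict
    genotype_pct: dict
    n_more_than_5: int
    n_more_than_10: int
    weight_by_age: pd.DataFrame        # age_bin, n, mean, sd
    weight_by_age_sex: pd.DataFrame    # sex, age_bin, n, mean, sd


def summarize_cohort(mice: list[MouseSeries]) -> CohortSummary:
    """Cohort composition and mean weight-by-age curves (overall and by sex)."""
    if not mice:
        raise PreprocessError("cannot summarize an empty cohort")
    n = len(mice)
    rows = [{"sex": m.sex, "age_bin": round(r.age_months), "weight": r.weight_g}
            for m in mice for r in m.records]
    df = pd.DataFrame(rows)
    sex_counts = pd.Series([m.sex for m in mice]).value_counts()
    geno_counts = pd.Series([m.genotype for m in mice]).value_counts()
    by_age = (df.groupby("age_bin")["weight"]
              .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
              .reset_index())
    by_age_sex = (df.groupby(["sex", "age_bin"])["weight"]
                  .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
                  .reset_index())
    return CohortSummary(
        n_mice=n,
        n_datapoints=int(len(df)),
        sex_pct={s: 100.0 * sex_counts.get(s, 0) / n for s in SEX_LEVELS},
        genotype_pct={g: 100.0 * geno_counts.get(g, 0) / n for g in GENOTYPE_LEVELS},
        n_more_than_5=sum(len(m.records) > 5 for m in mice),
        n_more_than_10=sum(len(m.records) > 10 for m in mice),
        weight_by_age=by_age,
        weight_by_age_sex=by_age_sex,
    )


def to_observations(mice: list[MouseSeries]) -> list[ObservationSequence]:
    return [m.to_observation() for m in mice]
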