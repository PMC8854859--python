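"""Reading of longitudinal ejaculate records and study quality control.

A record table holds one row per semen collection with the trait values
VOL (ml), MOT (%), CON (1e8 cells/ml) and ABN (%), plus derived columns:
``age_weeks``, ``interval_days`` (days since the boar's previous
collection; undefined for its first), the combined fixed-effect class
``aiys`` (AI center x year x month) and ``interval_class`` (1-30, one
level per day).

Quality control applies, in order: (e) per-trait range filters, (a) the
age window, (b) removal of undefined or out-of-range collection
intervals (a boar's chronologically first record has an undefined
interval, so it is removed here), (c) a minimum number of ejaculates per
boar, and (d) a minimum number of records per fixed-effect level; (c)
and (d) are re-applied alternately until a fixed point. Each removed row
is attributed to the first criterion that removed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

TRAITS = ("vol", "mot", "con", "abn")

#: canonical column names understood by the pipeline
COLUMNS = ("boar", "date", "age_weeks", "center", "interval_days") + TRAITS


class SchemaError(ValueError):
    pass


class RecordParseError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("malformed rows:\n" + "\n".join(errors))


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCConfig:
    """Quality-control bounds (defaults = the study criteria (a)-(e))."""

    age_min: float = 33.0
    age_max: float = 150.0
    interval_min: int = 1
    interval_max: int = 30
    min_ejaculates_per_boar: int = 6
    min_records_per_fixed_level: int = 10
    trait_ranges: dict = field(
        default_factory=lambda: {
            "vol": (100.0, 600.0),
            "mot": (10.0, 100.0),
            "con": (0.1, 8.0),
            "abn": (0.01, 100.0),
        }
    )

    def __post_init__(self):
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be < age_max")
        if not self.interval_min <= self.interval_max:
            raise ValueError("interval_min must be <= interval_max")
        if min(self.min_ejaculates_per_boar, self.min_records_per_fixed_level) < 1:
            raise ValueError("count thresholds must be >= 1")
        for t, (lo, hi) in self.trait_ranges.items():
            if not lo < hi:
                raise ValueError(f"trait range for {t} has min >= max")


@dataclass
class QCReport:
    """Per-criterion removal counts; removals + survivors = input rows."""

    input_records: int = 0
    removed: dict = field(default_factory=dict)
    surviving_records: int = 0
    surviving_boars: int = 0
    passes: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        lines = [f"input records: {self.input_records}"]
        lines += [f"removed by {k}: {v}" for k, v in self.removed.items()]
        lines += [
            f"surviving records: {self.surviving_records}",
            f"surviving boars: {self.surviving_boars}",
            f"fixed-point passes: {self.passes}",
        ]
        return "\n".join(lines)


def parse_records(path, schema: dict | None = None) -> pd.DataFrame:
    """Read a delimited records file into the canonical column layout.

    ``schema`` maps canonical names (see :data:`COLUMNS`) to file column
    names; canonical names present in the file are picked up
    automatically. Exactly one of ``date`` / ``age_weeks`` must be
    provided (dataset-wide). Separator is chosen by extension
    (.tsv -> tab, otherwise comma). Malformed values raise
    :class:`RecordParseError` naming each offending row and column.
    """
    sep = "\t" if str(path).endswith(".tsv") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    schema = dict(schema or {})
    colmap = {canon: schema.get(canon, canon) for canon in COLUMNS}
    present = {canon: col for canon, col in colmap.items() if col in raw.columns}

    for required in ("boar", "center"):
        if required not in present:
            raise SchemaError(f"required column {colmap[required]!r} missing from {path}")
    if ("date" in present) == ("age_weeks" in present):
        raise SchemaError("exactly one of 'date' or 'age_weeks' must be present")
    if not any(t in present for t in TRAITS):
        raise SchemaError(f"no trait column among {TRAITS} found")

    out = pd.DataFrame(index=raw.index)
    errors: list[str] = []
    out["boar"] = raw[present["boar"]].astype(str)
    if (out["boar"].str.strip() == "").any():
        errors.append("empty boar id in rows "
                      f"{list(out.index[out['boar'].str.strip() == ''])}")
    out["center"] = raw[present["center"]].astype(str)

    if "date" in present:
        dates = pd.to_datetime(raw[present["date"]], errors="coerce", format="ISO8601")
        for i in out.index[dates.isna()]:
            errors.append(f"row {i}: unparseable date {raw.loc[i, present['date']]!r}")
        out["date"] = dates
    for num_col in ("age_weeks", "interval_days") + TRAITS:
        if num_col not in present:
            continue
        vals = pd.to_numeric(raw[present[num_col]].replace("", np.nan), errors="coerce")
        bad = vals.isna() & (raw[present[num_col]].str.strip() != "")
        for i in out.index[bad]:
            errors.append(
                f"row {i}: column {present[num_col]!r} value "
                f"{raw.loc[i, present[num_col]]!r} is not numeric"
            )
        out[num_col] = vals
    if errors:
        raise RecordParseError(errors)
    return out.reset_index(drop=True)


def derive_columns(rt: pd.DataFrame, birthdates: dict | None = None) -> pd.DataFrame:
    """Derive interval, age and fixed-effect class columns.

    Rows are sorted within boar by date (when dates exist).
    ``interval_days`` is the date difference to the boar's previous
    record; a supplied ``interval_days`` column is kept when dates are
    absent. ``age_weeks`` = floor((date - birthdate)/7) when birthdates
    are given. ``aiys`` = center|year|month from the date, or the center
    alone for date-less data.
    """
    rt = rt.copy()
    has_date = "date" in rt.columns and rt["date"].notna().any()
    if has_date:
        dup = rt.duplicated(subset=["boar", "date"], keep=False)
        if dup.any():
            pairs = rt.loc[dup, ["boar", "date"]].drop_duplicates()
            raise QCError(f"duplicate (boar, date) pairs:\n{pairs.to_string(index=False)}")
        rt = rt.sort_values(["boar", "date"], kind="stable").reset_index(drop=True)
        delta = rt.groupby("boar", sort=False)["date"].diff()
        rt["interval_days"] = delta.dt.days.astype("Float64")
        if (rt["interval_days"].dropna() <= 0).any():
            raise QCError("non-positive collection interval (out-of-order data)")
        if birthdates is not None:
            birth = rt["boar"].map(lambda b: pd.Timestamp(birthdates[b]))
            rt["age_weeks"] = ((rt["date"] - birth).dt.days // 7).astype(float)
        rt["aiys"] = (
            rt["center"].astype(str)
            + "|" + rt["date"].dt.year.astype(str)
            + "|" + rt["date"].dt.month.astype(str)
        )
    else:
        if "age_weeks" not in rt.columns:
            raise QCError("need either dates or an age_weeks column")
        rt = rt.sort_values(["boar", "age_weeks"], kind="stable").reset_index(drop=True)
        if "interval_days" not in rt.columns:
            rt["interval_days"] = np.nan
        rt["interval_days"] = pd.array(rt["interval_days"], dtype="Float64")
        if (pd.Series(rt["interval_days"]).dropna() <= 0).any():
            raise QCError("non-positive collection interval")
        rt["aiys"] = rt["center"].astype(str)
    if "age_weeks" not in rt.columns:
        rt["age_weeks"] = np.nan  # underivable without birthdates; QC's age
        # window then rejects every record, with an explicit report
    iv = pd.Series(rt["interval_days"], dtype="Float64")
    rt["interval_class"] = iv.round().astype("Int64")
    return rt


def apply_qc(
    rt: pd.DataFrame, cfg: QCConfig | None = None, trait: str | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the five QC criteria; returns the filtered table and report.

    ``trait`` restricts criterion (e) to one trait (traits are analyzed
    separately, so a row failing only another trait's range stays
    usable); ``None`` applies every configured trait range.
    """
    cfg = cfg or QCConfig()
    report = QCReport(input_records=len(rt))
    df = rt.copy()

    def drop(mask: pd.Series, label: str) -> None:
        nonlocal df
        report.removed[label] = report.removed.get(label, 0) + int(mask.sum())
        df = df[~mask]

    traits = [trait.lower()] if trait else [t for t in TRAITS if t in df.columns]
    for t in traits:
        if t not in df.columns:
            raise QCError(f"trait column {t!r} missing")
        lo, hi = cfg.trait_ranges[t]
        bad = ~df[t].between(lo, hi)  # closed interval; NaN fails
        drop(bad, f"trait_range_{t}")
    drop(~df["age_weeks"].between(cfg.age_min, cfg.age_max), "age_window")
    iv = df["interval_days"].astype("Float64")
    in_range = iv.notna() & (iv >= cfg.interval_min) & (iv <= cfg.interval_max)
    drop(~in_range.astype(bool), "first_record_or_interval")

    passes = 0
    while True:
        passes += 1
        removed_this_pass = 0
        boar_counts = df.groupby("boar")["boar"].transform("size")
        small_boar = boar_counts < cfg.min_ejaculates_per_boar
        removed_this_pass += int(small_boar.sum())
        drop(small_boar, "min_ejaculates_per_boar")
        for factor in ("aiys", "interval_class"):
            counts = df.groupby(factor)[factor].transform("size")
            thin = counts < cfg.min_records_per_fixed_level
            removed_this_pass += int(thin.sum())
            drop(thin, f"fixed_level_count_{factor}")
        if removed_this_pass == 0:
            break
        if len(df) == 0:
            break
    report.passes = passes
    report.surviving_records = len(df)
    report.surviving_boars = df["boar"].nunique()
    if len(df) == 0:
        raise QCError("all records filtered out:\n" + report.to_text())
    return df.reset_index(drop=True), report
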