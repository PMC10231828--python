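"""Known-origin baseline preparation for contingent classification.

The classification baseline consists of known-origin juvenile fish whose
otolith carbonate was milled from the first annulus, so their stable-isotope
values (δ¹⁸O, δ¹³C, both ‰ VPDB) reflect the natal nursery. Because the two
contingents are sampled unevenly across cohorts, the baseline is balanced by
random oversampling within each year-class before any model is fitted, and
both isotope predictors are standardized to z-scores on the balanced
baseline. The stored transform is later applied verbatim to unknown-origin
adults — it is never refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTINGENTS = ("northern", "southern")
PREDICTORS = ("d18o", "d13c")

REQUIRED_COLUMNS = ("fish_id", "d18o", "d13c", "year_class", "age", "contingent")
OPTIONAL_COLUMNS = ("subregion", "collection_year")

#: Default maximum age (in years) for baseline eligibility, per contingent.
#: Juveniles are assumed to still reside in their natal region at these ages;
#: the northern baseline admits age-2 fish because immigration of southern
#: fish into northern waters is rare.
DEFAULT_MAX_BASELINE_AGE = {"southern": 1, "northern": 2}


class BaselineError(ValueError):
    """Raised when baseline records violate a structural requirement."""


@dataclass
class Standardization:
    """Per-predictor mean/SD computed on the balanced baseline."""

    mean: dict[str, float]
    sd: dict[str, float]

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        """Return a copy of *df* with predictor columns z-scored."""
        out = df.copy()
        for col in PREDICTORS:
            out[col] = (out[col] - self.mean[col]) / self.sd[col]
        return out

    def to_dict(self) -> dict:
        return {"mean": dict(self.mean), "sd": dict(self.sd)}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardization":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]))


@dataclass
class BaselineDataset:
    """A balanced, optionally standardized, known-origin baseline.

    ``records`` holds one row per fish (duplicated rows are genuine
    oversampling replicates). ``standardization`` is present once
    :func:`standardize` has run; its transform — not a refit — is what
    unknown adults receive.
    """

    records: pd.DataFrame
    seed: int
    standardization: Standardization | None = None
    meta: dict = field(default_factory=dict)

    @property
    def year_classes(self) -> list[int]:
        return sorted(self.records["year_class"].unique().tolist())

    def predictor_matrix(self) -> np.ndarray:
        return self.records[list(PREDICTORS)].to_numpy(dtype=float)


def read_otolith_csv(path) -> pd.DataFrame:
    """Read an otolith record table, validating required columns.

    Required columns: fish_id, d18o, d13c, year_class, age, contingent.
    Optional: subregion, collection_year. Missing values in required
    columns are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise BaselineError(f"missing required columns: {missing}")
    if df[list(REQUIRED_COLUMNS)].isna().any().any():
        bad = df.columns[df[list(REQUIRED_COLUMNS)].isna().any()].tolist()
        raise BaselineError(f"missing values in required columns: {bad}")
    return validate_records(df)


def write_otolith_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check record-level invariants; returns the frame unchanged on success."""
    for col in ("d18o", "d13c"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            raise BaselineError(f"non-finite values in column {col!r}")
    if (df["age"] < 0).any():
        raise BaselineError("negative age")
    ok = df["contingent"].isin(CONTINGENTS + ("unknown",))
    if not ok.all():
        bad = sorted(df.loc[~ok, "contingent"].unique().tolist())
        raise BaselineError(f"unrecognized contingent labels: {bad}")
    if "collection_year" in df.columns:
        both = df["collection_year"].notna()
        mism = both & (df["collection_year"] - df["age"] != df["year_class"])
        if mism.any():
            ids = df.loc[mism, "fish_id"].tolist()
            raise BaselineError(
                f"year_class != collection_year - age for fish: {ids[:5]}"
            )
    return df


def filter_baseline(
    df: pd.DataFrame,
    max_baseline_age: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Keep baseline-eligible records: known contingent and young enough.

    ``max_baseline_age`` maps contingent -> maximum age admitted to the
    baseline (defaults: southern 1, northern 2).
    """
    ages = dict(DEFAULT_MAX_BASELINE_AGE)
    if max_baseline_age:
        ages.update(max_baseline_age)
    known = df[df["contingent"].isin(CONTINGENTS)]
    keep = known["age"] <= known["contingent"].map(ages)
    return known[keep].reset_index(drop=True)


def oversample_balance(
    records: pd.DataFrame,
    seed: int,
    equalize_year_classes: bool = False,
) -> BaselineDataset:
    """Balance contingent counts within each year-class by oversampling.

    Within every year-class the minority contingent is resampled with
    replacement (seeded) until its count matches the majority contingent.
    All original records are retained; only duplicates are added, so no
    isotope value is invented. With ``equalize_year_classes=True`` each
    year-class is additionally inflated to the size of the largest one.
    """
    records = validate_records(records)
    if not records["contingent"].isin(CONTINGENTS).all():
        raise BaselineError("baseline records must have known contingent")
    rng = np.random.default_rng(seed)
    parts: list[pd.DataFrame] = []
    for yc, grp in records.groupby("year_class", sort=True):
        counts = grp["contingent"].value_counts()
        present = [c for c in CONTINGENTS if c in counts.index]
        if len(present) < 2:
            raise BaselineError(
                f"year-class {yc} has records for only one contingent "
                f"({present[0] if present else 'none'})"
            )
        target = int(counts.max())
        for cont in CONTINGENTS:
            sub = grp[grp["contingent"] == cont]
            parts.append(sub)
            deficit = target - len(sub)
            if deficit > 0:
                idx = rng.integers(0, len(sub), size=deficit)
                parts.append(sub.iloc[idx])
    balanced = pd.concat(parts, ignore_index=True)

    if equalize_year_classes:
        sizes = balanced.groupby("year_class").size()
        top = int(sizes.max())
        extra: list[pd.DataFrame] = [balanced]
        for yc, grp in balanced.groupby("year_class", sort=True):
            deficit = top - len(grp)
            # keep contingents balanced: draw deficit/2 from each
            if deficit > 0:
                for cont in CONTINGENTS:
                    sub = grp[grp["contingent"] == cont]
                    k = deficit // 2
                    if k > 0:
                        idx = rng.integers(0, len(sub), size=k)
                        extra.append(sub.iloc[idx])
        balanced = pd.concat(extra, ignore_index=True)

    return BaselineDataset(records=balanced, seed=seed)


def standardize(ds: BaselineDataset) -> BaselineDataset:
    """Z-score both isotope predictors on the balanced baseline.

    Stores the per-predictor mean/SD so the identical transform can be
    applied to unknown adults. A zero-variance predictor is an error.
    """
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for col in PREDICTORS:
        vals = ds.records[col].to_numpy(dtype=float)
        if np.unique(vals).size < 2:
            raise BaselineError(f"predictor {col!r} has zero variance")
        mean[col] = float(vals.mean())
        sd[col] = float(vals.std(ddof=0))
        if sd[col] <= 0:
            raise BaselineError(f"predictor {col!r} has zero variance")
    std = Standardization(mean=mean, sd=sd)
    return BaselineDataset(
        records=std.apply(ds.records),
        seed=ds.seed,
        standardization=std,
        meta=dict(ds.meta),
    )


def prepare_adults(
    adults: pd.DataFrame,
    baseline: BaselineDataset,
    strict: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize unknown adults and resolve their year-class.

    Year-class is taken as ``collection_year - age`` when absent. Adults
    whose year-class never appears in the baseline cannot be classified by
    year-class-aware members; in strict mode (default) they are split off
    and returned separately for the caller to report.

    Returns ``(usable, excluded)`` frames, both carrying z-scored
    predictors.
    """
    if baseline.standardization is None:
        raise BaselineError("baseline must be standardized first")
    df = adults.copy()
    if "year_class" not in df.columns or df["year_class"].isna().any():
        if "collection_year" not in df.columns:
            raise BaselineError(
                "adults need year_class or collection_year + age"
            )
        df["year_class"] = df["collection_year"] - df["age"]
    df = baseline.standardization.apply(df)
    known = set(baseline.year_classes)
    mask = df["year_class"].isin(known)
    if strict:
        return df[mask].reset_index(drop=True), df[~mask].reset_index(drop=True)
    return df.reset_index(drop=True), df.iloc[0:0]
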