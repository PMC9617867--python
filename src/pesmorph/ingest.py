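"""Ingest of repeated calliper measurements on skeletal elements.

Osteometric protocols measure each dimension several times (three repeats by
the same operator is the reference design) to control intra-operator error.
This module aggregates long-format repeat tables into wide per-specimen
tables, quantifies measurement reliability via intraclass correlation, and
restricts tables to analysis measurement subsets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

ELEMENTS = ("astragalus", "calcaneus", "metatarsal4")

#: Columns of a long-format repeat-measurement table.
REPEAT_COLUMNS = ("specimen_id", "element", "measurement_name", "replicate_index", "value_mm")

#: Per-specimen label columns carried through the pipeline.
METADATA_COLUMNS = (
    "specimen_id", "genus", "species", "element",
    "age_class", "sex", "provenance", "stratum",
)

AGE_CLASSES = ("juvenile", "subadult", "adult", "unknown")
ICC_VARIANTS = ("icc1", "icc1k", "icc2", "icc2k", "icc3", "icc3k")


def measurement_columns(table: pd.DataFrame) -> list[str]:
    """Names of the measurement columns of a wide specimen table."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def validate_repeat_table(repeats: pd.DataFrame, min_replicates: int = 2) -> None:
    """Check structural invariants of a long repeat table.

    Raises :class:`ValidationError` naming the offending specimens when values
    are non-positive, replicate indices collide, or a (specimen, measurement)
    pair has fewer than ``min_replicates`` replicates.
    """
    missing = [c for c in REPEAT_COLUMNS if c not in repeats.columns]
    if missing:
        raise ValidationError(f"repeat table missing required columns: {missing}")
    values = pd.to_numeric(repeats["value_mm"], errors="coerce")
    bad = repeats[~(values > 0)]
    if len(bad):
        ids = bad[["specimen_id", "measurement_name"]].drop_duplicates()
        raise ValidationError(
            "non-positive or non-numeric measurement values for: "
            + "; ".join(f"{r.specimen_id}/{r.measurement_name}" for r in ids.itertuples())
        )
    keys = ["specimen_id", "element", "measurement_name"]
    dup = repeats.duplicated(subset=keys + ["replicate_index"], keep=False)
    if dup.any():
        ids = repeats.loc[dup, keys].drop_duplicates()
        raise ValidationError(
            "duplicate replicate indices for: "
            + "; ".join(f"{r.specimen_id}/{r.measurement_name}" for r in ids.itertuples())
        )
    counts = repeats.groupby(keys, sort=False).size()
    short = counts[counts < min_replicates]
    if len(short):
        raise ValidationError(
            f"fewer than {min_replicates} replicates for: "
            + "; ".join("/".join(map(str, k)) for k in short.index[:20])
        )


def read_repeat_table(path, min_replicates: int = 2) -> pd.DataFrame:
    """Read and validate a long-format repeat CSV (UTF-8, '.' decimal)."""
    repeats = pd.read_csv(path)
    validate_repeat_table(repeats, min_replicates=min_replicates)
    return repeats


def read_metadata(path) -> pd.DataFrame:
    """Read a specimen metadata CSV, checking required columns and label values."""
    meta = pd.read_csv(path, dtype={"stratum": "string"})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns and c != "stratum"]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    if "stratum" not in meta.columns:
        meta["stratum"] = pd.NA
    validate_metadata(meta)
    return meta


def validate_metadata(meta: pd.DataFrame) -> None:
    bad_elem = set(meta["element"].dropna()) - set(ELEMENTS)
    if bad_elem:
        raise ValidationError(f"unknown skeletal elements {sorted(bad_elem)}; expected one of {ELEMENTS}")
    bad_age = set(meta["age_class"].dropna()) - set(AGE_CLASSES)
    if bad_age:
        raise ValidationError(f"unknown age classes {sorted(bad_age)}; expected one of {AGE_CLASSES}")
    modern = meta[meta["provenance"] == "modern"]
    anon = modern[modern["genus"].isna() | (modern["genus"].astype(str).str.strip() == "")]
    if len(anon):
        raise ValidationError(
            "modern specimens must carry a genus label; missing for: "
            + ", ".join(map(str, anon["specimen_id"].tolist()[:20]))
        )


def aggregate_repeats(repeats: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicate measurements to a wide specimen table.

    Each measurement cell is the arithmetic mean of its replicates; specimen
    labels are joined by ``specimen_id`` + ``element``.  Specimens present in
    the repeat table but absent from the metadata raise an error listing the
    offending ids.
    """
    validate_repeat_table(repeats, min_replicates=1)
    validate_metadata(metadata)
    known = set(zip(metadata["specimen_id"], metadata["element"]))
    seen = set(zip(repeats["specimen_id"], repeats["element"]))
    orphans = sorted(seen - known)
    if orphans:
        raise ValidationError(
            "specimens in repeat table without metadata: "
            + ", ".join(f"{s}({e})" for s, e in orphans[:20])
        )
    means = (
        repeats.groupby(["specimen_id", "element", "measurement_name"], sort=False)["value_mm"]
        .mean()
        .reset_index()
    )
    order = list(dict.fromkeys(repeats["measurement_name"]))
    wide = means.pivot(index=["specimen_id", "element"], columns="measurement_name", values="value_mm")
    wide = wide.reindex(columns=order).reset_index()
    wide.columns.name = None
    meta_cols = [c for c in METADATA_COLUMNS if c in metadata.columns]
    table = metadata[meta_cols].merge(wide, on=["specimen_id", "element"], how="inner")
    dup = table.duplicated(subset=["specimen_id", "element"], keep=False)
    if dup.any():
        raise ValidationError(
            "duplicate specimen rows after aggregation: "
            + ", ".join(map(str, table.loc[dup, "specimen_id"].unique()[:20]))
        )
    return table


def icc_from_matrix(ratings: np.ndarray, variant: str = "icc3") -> float:
    """Intraclass correlation from an n-specimen x k-replicate rating matrix.

    Computed from explicit two-way ANOVA mean squares.  ``icc3``/``icc3k`` are
    the two-way mixed-effects consistency forms (single rating / mean of k
    ratings), appropriate when one fixed operator measures every specimen;
    ``icc2``/``icc2k`` are the absolute-agreement random-rater forms, and
    ``icc1``/``icc1k`` the one-way forms.
    """
    if variant not in ICC_VARIANTS:
        raise ValidationError(f"unknown ICC variant {variant!r}; expected one of {ICC_VARIANTS}")
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("ICC requires at least 2 specimens and 2 replicates")
    if np.isnan(x).any():
        raise ValidationError("ICC rating matrix must be complete (no missing cells)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    msb = ss_rows / (n - 1)                       # between specimens
    msw = (ss_total - ss_rows) / (n * (k - 1))    # within specimens (one-way)
    msc = ss_cols / (k - 1)                       # between replicates
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if variant == "icc1":
        denom = msb + (k - 1) * msw
        return float((msb - msw) / denom) if denom > 0 else 1.0
    if variant == "icc1k":
        return float((msb - msw) / msb) if msb > 0 else 1.0
    if variant == "icc2":
        denom = msb + (k - 1) * mse + k * (msc - mse) / n
        return float((msb - mse) / denom) if denom > 0 else 1.0
    if variant == "icc2k":
        denom = msb + (msc - mse) / n
        return float((msb - mse) / denom) if denom > 0 else 1.0
    if variant == "icc3":
        denom = msb + (k - 1) * mse
        return float((msb - mse) / denom) if denom > 0 else 1.0
    return float((msb - mse) / msb) if msb > 0 else 1.0  # icc3k


@dataclass
class ReliabilityReport:
    """Per-measurement repeatability summary.

    ``table`` has one row per measurement with columns ``n_specimens``,
    ``n_replicates``, ``icc``, ``mean_repeat_sd_mm``, ``repeat_sd_proportion``
    and ``flagged`` (ICC below the reliability floor).
    """

    table: pd.DataFrame
    icc_variant: str = "icc3"
    icc_threshold: float = 0.9
    warnings: list = field(default_factory=list)

    @property
    def flagged_measurements(self) -> list[str]:
        t = self.table
        return t.loc[t["flagged"].fillna(False), "measurement_name"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def repeat_reliability(
    repeats: pd.DataFrame,
    icc_variant: str = "icc3",
    icc_threshold: float = 0.9,
) -> ReliabilityReport:
    """Quantify intra-operator measurement error per measurement.

    Returns per-measurement ICC (default two-way mixed consistency, single
    rating), the mean within-specimen repeat SD in mm, and that SD as a
    proportion of the specimen mean — small bones tend to show proportionally
    larger repeat error.  Measurements with ICC below ``icc_threshold`` are
    flagged; a measurement observed on a single specimen gets a missing ICC
    and a warning.
    """
    validate_repeat_table(repeats, min_replicates=2)
    rows = []
    notes: list[str] = []
    for name, sub in repeats.groupby("measurement_name", sort=False):
        pivot = sub.pivot_table(
            index=["specimen_id", "element"], columns="replicate_index", values="value_mm"
        )
        complete = pivot.dropna()
        if len(complete) < len(pivot):
            notes.append(
                f"{name}: {len(pivot) - len(complete)} specimen(s) with unbalanced "
                "replicates excluded from the ICC"
            )
        per_spec_sd = pivot.std(axis=1, ddof=1)
        per_spec_mean = pivot.mean(axis=1)
        if len(complete) >= 2:
            icc = icc_from_matrix(complete.to_numpy(), variant=icc_variant)
            flagged = bool(icc < icc_threshold)
        else:
            icc, flagged = np.nan, np.nan
            notes.append(f"{name}: ICC undefined with a single specimen")
        rows.append(
            {
                "measurement_name": name,
                "n_specimens": int(len(pivot)),
                "n_replicates": int(pivot.notna().sum(axis=1).max()),
                "icc": icc,
                "mean_repeat_sd_mm": float(per_spec_sd.mean()),
                "repeat_sd_proportion": float((per_spec_sd / per_spec_mean).mean()),
                "flagged": flagged,
            }
        )
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return ReliabilityReport(
        table=pd.DataFrame(rows), icc_variant=icc_variant,
        icc_threshold=icc_threshold, warnings=notes,
    )


def select_measurement_subset(table: pd.DataFrame, keep: list[str]) -> pd.DataFrame:
    """Restrict a wide specimen table to the named measurements.

    Label columns are untouched.  Unknown names raise an error listing them.
    """
    if not len(keep):
        raise ValidationError("measurement subset is empty")
    present = measurement_columns(table)
    unknown = [k for k in keep if k not in present]
    if unknown:
        raise ValidationError(f"measurements not in table: {unknown}")
    meta = [c for c in table.columns if c in METADATA_COLUMNS]
    return table[meta + list(keep)]


def complete_cases(table: pd.DataFrame, required: list[str] | None = None) -> pd.DataFrame:
    """Drop specimens missing any required measurement, with a logged warning.

    Fragmentary-specimen modelling is out of scope; incomplete rows simply
    leave the pipeline for their element.
    """
    required = required if required is not None else measurement_columns(table)
    ok = table[required].notna().all(axis=1)
    if (~ok).any():
        dropped = table.loc[~ok, "specimen_id"].tolist()
        warnings.warn(
            f"excluding {len(dropped)} specimen(s) with incomplete measurements: "
            + ", ".join(map(str, dropped[:20])),
            stacklevel=2,
        )
    return table.loc[ok].reset_index(drop=True)
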