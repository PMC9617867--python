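"""Bone size and size-free shape variables.

Size is summarised by the geometric mean (GM) of a specimen's linear
measurements, which is less sensitive to allometric distortion than any
single measurement or ratio.  Shape is expressed as Mosimann log-shape
ratios, log10(measurement / GM): uniform rescaling of a specimen cancels
out, so the variables are size-free while retaining allometric signal.
Species are then binned into ordered size groups (small/medium/large by
default) on the GM scale; taxa whose size range straddles a boundary belong
to both neighbouring groups.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ValidationError
from .ingest import METADATA_COLUMNS, measurement_columns

DEFAULT_GROUP_LABELS = ("small", "medium", "large")


def _check_positive(values: np.ndarray) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValidationError("empty measurement vector")
    if not np.all(np.isfinite(a)) or np.any(a <= 0):
        raise ValidationError("measurements must be finite and strictly positive")
    return a


def geometric_mean(values) -> float:
    """Geometric mean of positive measurements: the p-th root of their product."""
    a = np.atleast_1d(_check_positive(values))
    return float(np.exp(np.mean(np.log(a))))


def log_shape_ratios(values) -> np.ndarray:
    """Mosimann log-shape ratios log10(x_i / GM(x)); components sum to zero."""
    a = np.atleast_1d(_check_positive(values))
    logs = np.log10(a)
    return logs - logs.mean()


def shape_matrix(table: pd.DataFrame, measurements: list[str] | None = None) -> pd.DataFrame:
    """Per-specimen log-shape-ratio matrix from a wide specimen table.

    Rows are indexed by specimen_id when available.  Every row sums to zero
    (to numerical precision) and is invariant to uniform rescaling of that
    specimen's measurements.
    """
    cols = measurements if measurements is not None else measurement_columns(table)
    if len(cols) < 2:
        raise ValidationError("shape requires at least 2 measurements")
    m = table[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise ValidationError("shape matrix requires complete, positive measurements")
    logs = np.log10(m)
    shape = logs - logs.mean(axis=1, keepdims=True)
    index = table["specimen_id"] if "specimen_id" in table.columns else table.index
    return pd.DataFrame(shape, index=pd.Index(index, name="specimen_id"), columns=cols)


@dataclass
class SizeProfile:
    """GM size summaries: one row per specimen and one per species.

    ``per_species`` carries min/median/max GM plus the central-interval
    bounds (``gm_lo``/``gm_hi``) used for size-group assignment.
    """

    per_specimen: pd.DataFrame
    per_species: pd.DataFrame
    central_interval: float = 0.95


def size_profile(
    table: pd.DataFrame,
    measurements: list[str] | None = None,
    central_interval: float = 0.95,
) -> SizeProfile:
    """Compute per-specimen GM and per-species GM distribution summaries."""
    if not 0 < central_interval <= 1:
        raise ValidationError("central_interval must lie in (0, 1]")
    cols = measurements if measurements is not None else measurement_columns(table)
    m = table[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise ValidationError("size profile requires complete, positive measurements")
    gm = np.exp(np.mean(np.log(m), axis=1))
    per_specimen = pd.DataFrame(
        {
            "specimen_id": table.get("specimen_id", pd.Series(table.index)).to_numpy(),
            "genus": table.get("genus", pd.Series([None] * len(table))).to_numpy(),
            "species": table.get("species", pd.Series([None] * len(table))).to_numpy(),
            "gm": gm,
        }
    )
    lo_q, hi_q = (1 - central_interval) / 2, 1 - (1 - central_interval) / 2
    grp = per_specimen.dropna(subset=["genus", "species"]).groupby(
        ["genus", "species"], sort=True
    )["gm"]
    per_species = grp.agg(
        n="size", gm_min="min", gm_median="median", gm_max="max",
        gm_lo=lambda s: s.quantile(lo_q), gm_hi=lambda s: s.quantile(hi_q),
    ).reset_index()
    return SizeProfile(per_specimen=per_specimen, per_species=per_species,
                       central_interval=central_interval)


@dataclass
class SizeGrouping:
    """Ordered GM size groups with species memberships.

    ``intervals`` maps each label to its [lo, hi] GM interval; the intervals
    partition the observed training GM range.  ``species_groups`` maps
    (genus, species) to the tuple of groups whose interval its central GM
    interval intersects — a straddling species belongs to both neighbours.
    """

    labels: tuple[str, ...]
    boundaries: tuple[float, ...]
    intervals: dict[str, tuple[float, float]]
    species_groups: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def members(self, label: str) -> list[tuple[str, str]]:
        return [sp for sp, groups in self.species_groups.items() if label in groups]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"genus": g, "species": s, "groups": "|".join(groups)}
            for (g, s), groups in sorted(self.species_groups.items())
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "boundaries": [float(b) for b in self.boundaries],
            "intervals": {k: [float(v[0]), float(v[1])] for k, v in self.intervals.items()},
            "species_groups": {f"{g} {s}": list(v) for (g, s), v in self.species_groups.items()},
        }


def _kmeans_boundaries(medians: np.ndarray, k: int) -> list[float]:
    """1-D k-means on species median GM; boundaries at midpoints between
    the edges of adjacent clusters."""
    km = KMeans(n_clusters=k, n_init=10, random_state=0)
    labels = km.fit_predict(medians.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    clusters = [np.sort(medians[labels == lab]) for lab in order]
    return [
        float((clusters[i][-1] + clusters[i + 1][0]) / 2)
        for i in range(k - 1)
    ]


def assign_size_groups(
    profile: SizeProfile,
    boundaries: list[float] | None = None,
    labels: tuple[str, ...] = DEFAULT_GROUP_LABELS,
) -> SizeGrouping:
    """Assign species to ordered size groups on the GM scale.

    With explicit ``boundaries`` (len(labels) - 1 increasing GM cut-points)
    the split is fully user-controlled, replicating any visual grouping.
    Without them, 1-D k-means on species median GM derives the cut-points.
    A species joins every group whose interval intersects its central GM
    interval, so size-straddling taxa are analysed in both groups.
    """
    sp = profile.per_species
    if sp is None or not len(sp):
        raise ValidationError("size profile contains no labelled species")
    gm_all = profile.per_specimen["gm"].to_numpy()
    lo_all, hi_all = float(gm_all.min()), float(gm_all.max())
    k = len(labels)
    if boundaries is None:
        if len(sp) < k:
            raise ValidationError(
                f"{len(sp)} species cannot be clustered into {k} size groups; "
                "supply explicit boundaries"
            )
        boundaries = _kmeans_boundaries(sp["gm_median"].to_numpy(dtype=float), k)
    boundaries = [float(b) for b in boundaries]
    if len(boundaries) != k - 1:
        raise ValidationError(f"expected {k - 1} boundaries for {k} groups, got {len(boundaries)}")
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise ValidationError("size-group boundaries must be strictly increasing")
    edges = [min(lo_all, boundaries[0])] + boundaries + [max(hi_all, boundaries[-1])]
    intervals = {lab: (edges[i], edges[i + 1]) for i, lab in enumerate(labels)}
    species_groups = {}
    for row in sp.itertuples():
        lo, hi = float(row.gm_lo), float(row.gm_hi)
        member = tuple(
            lab for lab in labels
            if lo <= intervals[lab][1] and hi >= intervals[lab][0]
        )
        species_groups[(row.genus, row.species)] = member
    return SizeGrouping(
        labels=tuple(labels), boundaries=tuple(boundaries),
        intervals=intervals, species_groups=species_groups,
    )


@dataclass
class UnknownPlacement:
    """Size-group placement of an unknown specimen's GM."""

    groups: tuple[str, ...]
    flag: str | None = None  # below_training_range / above_training_range


def place_unknown_in_groups(
    gm: float, grouping: SizeGrouping, pad_fraction: float = 0.025
) -> UnknownPlacement:
    """Place an unknown specimen's GM into size groups.

    Each group interval is padded by ``pad_fraction`` of its width so that
    boundary-adjacent unknowns are analysed in both neighbouring groups.
    A GM outside the whole training range is assigned to the nearest group
    and flagged rather than rejected.
    """
    if not np.isfinite(gm) or gm <= 0:
        raise ValidationError("unknown GM must be positive and finite")
    hits = []
    for lab in grouping.labels:
        lo, hi = grouping.intervals[lab]
        pad = pad_fraction * (hi - lo)
        if lo - pad <= gm <= hi + pad:
            hits.append(lab)
    if hits:
        return UnknownPlacement(groups=tuple(hits))
    overall_lo = grouping.intervals[grouping.labels[0]][0]
    overall_hi = grouping.intervals[grouping.labels[-1]][1]
    if gm < overall_lo:
        return UnknownPlacement(groups=(grouping.labels[0],), flag="below_training_range")
    if gm > overall_hi:
        return UnknownPlacement(groups=(grouping.labels[-1],), flag="above_training_range")
    # numerically possible only at exact internal boundaries with zero padding
    nearest = min(
        grouping.labels,
        key=lambda lab: min(abs(gm - grouping.intervals[lab][0]), abs(gm - grouping.intervals[lab][1])),
    )
    return UnknownPlacement(groups=(nearest,))
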