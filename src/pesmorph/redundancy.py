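"""Stepwise measurement-redundancy reduction.

Calliper protocols on compact tarsals are highly redundant: several
measurements carry nearly the same shape information.  To meet the
within-group sample-size requirements of discriminant analysis, measurements
are dropped greedily as long as the ordination of inter-specimen shape
distances is preserved.  Congruence between the full and reduced measurement
sets is the Pearson correlation between the upper triangles of their
Euclidean inter-specimen distance matrices, computed on log-shape ratios
(a Mantel-style statistic).  Measurements that rarely survive in
archaeological material (e.g. epiphysis-dependent ones) can be force-dropped
up front, and anchor measurements force-kept.

Log-shape ratios of a measurement subset are obtained by re-centring the
full-set rows over the retained columns: dropping a column changes the
geometric mean, and downstream analyses must use shapes computed from the
retained set only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import ValidationError


def _subset_shape(shape: pd.DataFrame, columns: list[str]) -> np.ndarray:
    sub = shape[list(columns)].to_numpy(dtype=float)
    return sub - sub.mean(axis=1, keepdims=True)


def distance_congruence(shape: pd.DataFrame, reference: list[str], reduced: list[str]) -> float:
    """Correlation between inter-specimen shape distances of two measurement sets.

    Both sets are re-centred (shape recomputed on their own geometric means)
    before Euclidean distances are taken.  Returns 1.0 for identical sets.
    """
    d_ref = pdist(_subset_shape(shape, reference))
    d_red = pdist(_subset_shape(shape, reduced))
    sd_ref, sd_red = d_ref.std(), d_red.std()
    if sd_ref == 0 or sd_red == 0:
        return 1.0 if np.allclose(d_ref, d_red) else 0.0
    return float(np.corrcoef(d_ref, d_red)[0, 1])


@dataclass
class RedundancyResult:
    """Outcome of the stepwise redundancy test.

    ``dropped`` records (step, measurement, congruence) in drop order; forced
    exclusions come first with step 0.  ``retained`` and the dropped names
    partition the input measurement set.
    """

    retained: list[str]
    dropped: list[tuple[int, str, float]] = field(default_factory=list)
    congruence_threshold: float = 0.99
    min_keep: int = 2

    @property
    def dropped_names(self) -> list[str]:
        return [name for _, name, _ in self.dropped]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["step", "dropped", "congruence"])


def stepwise_redundancy(
    shape: pd.DataFrame,
    force_exclude: list[str] | None = None,
    force_keep: list[str] | None = None,
    congruence_threshold: float = 0.99,
    min_keep: int = 2,
) -> RedundancyResult:
    """Greedy backward elimination of redundant measurements.

    ``force_exclude`` is dropped unconditionally first (archaeological
    preservation rule).  Then, while more than ``min_keep`` measurements
    remain, the candidate whose removal yields the highest congruence with
    the post-exclusion reference set is dropped, provided that congruence
    stays >= ``congruence_threshold``.  Ties are broken by dropping the
    lexicographically last name, making the drop sequence deterministic.
    """
    force_exclude = list(force_exclude or [])
    force_keep = list(force_keep or [])
    cols = list(shape.columns)
    if len(shape) < 3:
        raise ValidationError("redundancy test requires at least 3 specimens")
    if not 0 < congruence_threshold <= 1:
        raise ValidationError("congruence_threshold must lie in (0, 1]")
    if min_keep < 2:
        raise ValidationError("min_keep must be at least 2")
    unknown = [c for c in force_exclude + force_keep if c not in cols]
    if unknown:
        raise ValidationError(f"unknown measurements in force lists: {unknown}")
    overlap = set(force_exclude) & set(force_keep)
    if overlap:
        raise ValidationError(f"measurements both force-kept and force-excluded: {sorted(overlap)}")
    retained = [c for c in cols if c not in force_exclude]
    if len(retained) < min_keep:
        raise ValidationError(
            f"min_keep={min_keep} exceeds the {len(retained)} measurements left "
            "after forced exclusions"
        )
    dropped: list[tuple[int, str, float]] = []
    for name in force_exclude:
        score = distance_congruence(shape, cols, retained)
        dropped.append((0, name, score))
    reference = list(retained)
    step = 0
    while len(retained) > min_keep:
        candidates = [c for c in retained if c not in force_keep]
        if not candidates:
            break
        scores = {
            c: distance_congruence(shape, reference, [r for r in retained if r != c])
            for c in candidates
        }
        best_score = max(scores.values())
        if not best_score >= congruence_threshold:
            break
        # scores equal up to float noise are ties; drop the last name
        best = max(c for c, s in scores.items() if best_score - s <= 1e-12)
        retained.remove(best)
        step += 1
        dropped.append((step, best, best_score))
    return RedundancyResult(
        retained=retained, dropped=dropped,
        congruence_threshold=congruence_threshold, min_keep=min_keep,
    )
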