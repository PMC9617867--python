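"""Ordination of size-free shape and multivariate tests on it.

PCA summarises the main axes of log-shape-ratio variation within each
element x size group; archaeological unknowns are projected into the
training morphospace for visual comparison.  MANOVA tests shape against
size (allometry), age class and sex.  Because log-shape-ratio rows sum to
zero, the shape covariance is singular along the unit vector; multivariate
tests are computed on the leading full-rank subspace, to which Wilks'
lambda is invariant.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.manova import MANOVA

from .errors import ComputationError, ValidationError

_RANK_TOL = 1e-9


@dataclass
class OrdinationResult:
    """Covariance PCA of a shape matrix.

    ``loadings`` columns are orthonormal; each column's largest-magnitude
    entry is oriented positive so score signs are reproducible across runs.
    ``explained_ratio`` is over the retained (full-rank) components and sums
    to 1.
    """

    center: pd.Series
    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance: np.ndarray
    explained_ratio: np.ndarray


def fit_pca(shape: pd.DataFrame, n_components: int | None = None) -> OrdinationResult:
    """Principal components of centred shape rows, ordered by variance."""
    X = shape.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValidationError("PCA requires at least 3 specimens and 2 measurements")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 0 or not np.isfinite(s[0]):
        raise ValidationError("shape matrix has no variance; PCA is undefined")
    rank = int(np.sum(s > s[0] * _RANK_TOL))
    r = rank if n_components is None else min(n_components, rank)
    V = Vt[:rank].T
    # deterministic sign: largest-|loading| entry positive per component
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(rank)])
    V = V * flip
    scores = Xc @ V
    var = s[:rank] ** 2 / (n - 1)
    comps = [f"PC{i + 1}" for i in range(rank)]
    return OrdinationResult(
        center=pd.Series(center, index=shape.columns),
        loadings=pd.DataFrame(V[:, :r], index=shape.columns, columns=comps[:r]),
        scores=pd.DataFrame(scores[:, :r], index=shape.index, columns=comps[:r]),
        explained_variance=var[:r],
        explained_ratio=(var / var.sum())[:r],
    )


def project(result: OrdinationResult, rows: pd.DataFrame) -> pd.DataFrame:
    """Project new shape rows into a fitted morphospace: (row - center) @ loadings."""
    missing = [c for c in result.center.index if c not in rows.columns]
    if missing:
        raise ValidationError(f"projection rows missing measurements: {missing}")
    X = rows[result.center.index].to_numpy(dtype=float)
    scores = (X - result.center.to_numpy()) @ result.loadings.to_numpy()
    return pd.DataFrame(scores, index=rows.index, columns=result.loadings.columns)


@dataclass
class ManovaResult:
    """One multivariate test of shape against a predictor."""

    predictor: str
    statistic_name: str
    statistic: float
    f_value: float
    df_num: float
    df_den: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "statistic_name": self.statistic_name,
            "statistic": float(self.statistic),
            "f_value": float(self.f_value),
            "df_num": float(self.df_num),
            "df_den": float(self.df_den),
            "p_value": float(self.p_value),
        }


_STAT_ROWS = {"wilks": "Wilks' lambda", "pillai": "Pillai's trace"}


def _design_matrix(predictor: pd.Series, kind: str) -> np.ndarray:
    if kind == "categorical":
        levels = pd.Categorical(predictor.astype(str))
        if len(levels.categories) < 2:
            raise ValidationError(
                f"categorical predictor {predictor.name!r} has fewer than 2 levels"
            )
        dummies = pd.get_dummies(levels, drop_first=True, dtype=float).to_numpy()
        return np.column_stack([np.ones(len(predictor)), dummies])
    if kind == "continuous":
        v = predictor.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValidationError("continuous predictor contains non-finite values")
        if v.std() == 0:
            raise ValidationError(f"continuous predictor {predictor.name!r} is constant")
        return np.column_stack([np.ones(len(v)), v])
    raise ValidationError(f"unknown predictor kind {kind!r}")


def _full_rank_basis(Y: np.ndarray) -> np.ndarray:
    Yc = Y - Y.mean(axis=0)
    _, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    if s[0] <= 0:
        raise ValidationError("response matrix is constant; MANOVA undefined")
    rank = int(np.sum(s > s[0] * _RANK_TOL))
    return Vt[:rank].T


def _manova_fit(Y: np.ndarray, X: np.ndarray, stat_row: str) -> tuple[float, float, float, float, float]:
    n, q = X.shape
    if Y.shape[1] == 1:
        # one response: Wilks reduces to the ordinary F test of the regression
        from scipy.stats import f as f_dist
        y = Y[:, 0]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse_full = float(((y - X @ beta) ** 2).sum())
        sse_null = float(((y - y.mean()) ** 2).sum())
        df1, df2 = q - 1, n - q
        lam = sse_full / sse_null if sse_null > 0 else 1.0
        f_value = ((sse_null - sse_full) / df1) / (sse_full / df2)
        p = float(f_dist.sf(f_value, df1, df2))
        value = lam if stat_row == "Wilks' lambda" else 1.0 - lam
        return value, float(f_value), float(df1), float(df2), p
    L = np.hstack([np.zeros((q - 1, 1)), np.eye(q - 1)])
    res = MANOVA(endog=Y, exog=X).mv_test(hypotheses=[("predictor", L, None)])
    stat = res.results["predictor"]["stat"].loc[stat_row]
    return (
        float(stat["Value"]), float(stat["F Value"]),
        float(stat["Num DF"]), float(stat["Den DF"]), float(stat["Pr > F"]),
    )


def manova_shape(
    shape: pd.DataFrame,
    predictor: pd.Series,
    kind: str = "categorical",
    statistic: str = "wilks",
    n_permutations: int | None = None,
    seed: int | None = None,
) -> ManovaResult:
    """MANOVA of shape on a single predictor.

    Reports Wilks' lambda (default, with Rao's F approximation) or Pillai's
    trace.  The shape matrix is first rotated onto its leading full-rank
    subspace (dropping the sum-to-zero null direction), to which both
    statistics are invariant.  With ``n_permutations`` the p-value is
    replaced by a permutation p-value (predictor rows shuffled); the
    parametric statistic and F are still reported.
    """
    if statistic not in _STAT_ROWS:
        raise ValidationError(f"statistic must be one of {sorted(_STAT_ROWS)}")
    if len(predictor) != len(shape):
        raise ValidationError("predictor length does not match shape matrix")
    if not isinstance(predictor, pd.Series):
        predictor = pd.Series(predictor, index=shape.index, name="predictor")
    X = _design_matrix(predictor, kind)
    B = _full_rank_basis(shape.to_numpy(dtype=float))
    Y = shape.to_numpy(dtype=float) @ B
    n, r = Y.shape
    q = X.shape[1]
    if n - q < r:
        raise ComputationError(
            f"insufficient residual degrees of freedom (n={n}, predictors={q}, "
            f"shape rank={r}); reduce the number of measurements first"
        )
    stat_row = _STAT_ROWS[statistic]
    value, f_value, df1, df2, p = _manova_fit(Y, X, stat_row)
    name = predictor.name if predictor.name is not None else "predictor"
    if n_permutations:
        rng = np.random.default_rng(seed)
        obs = value
        more_extreme = 0
        for _ in range(int(n_permutations)):
            perm = predictor.sample(frac=1, random_state=rng).reset_index(drop=True)
            perm.index = predictor.index
            Xp = _design_matrix(perm, kind)
            v, *_ = _manova_fit(Y, Xp, stat_row)
            extreme = v <= obs if statistic == "wilks" else v >= obs
            more_extreme += int(extreme)
        p = (1 + more_extreme) / (1 + int(n_permutations))
    return ManovaResult(
        predictor=str(name), statistic_name=statistic, statistic=value,
        f_value=f_value, df_num=df1, df_den=df2, p_value=p,
    )


def manova_by_species(
    shape: pd.DataFrame,
    table: pd.DataFrame,
    predictor_col: str,
    kind: str = "categorical",
    min_n: int = 8,
    statistic: str = "wilks",
) -> list[dict]:
    """Run a shape-vs-predictor MANOVA separately per species.

    Species with fewer than ``min_n`` specimens, or without predictor
    variation, are reported as skipped rather than tested — intraspecific
    age/sex tests are only meaningful where sample size permits.
    """
    out: list[dict] = []
    table = table.reset_index(drop=True)
    for (genus, species), idx in table.groupby(["genus", "species"], sort=True).groups.items():
        sub_shape = shape.iloc[list(idx)]
        pred = table.loc[list(idx), predictor_col]
        pred.index = sub_shape.index
        label = f"{genus} {species}"
        if len(idx) < min_n:
            out.append({"species": label, "predictor": predictor_col,
                        "skipped": f"n={len(idx)} < {min_n}"})
            continue
        try:
            res = manova_shape(sub_shape, pred.rename(predictor_col), kind=kind,
                               statistic=statistic)
        except (ValidationError, ComputationError) as exc:
            out.append({"species": label, "predictor": predictor_col, "skipped": str(exc)})
            continue
        out.append({"species": label, **res.to_dict()})
    return out
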