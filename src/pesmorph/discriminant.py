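"""Linear discriminant classification of bone form with chance-corrected evaluation.

Within each element x size group, genera are modelled as Gaussians with a
shared (pooled) covariance in *form* space: the log10 of every retained
measurement.  Form = size + shape — a specimen's log measurements decompose
exactly into log10 GM times the unit vector plus its log-shape ratios — and
LDA is invariant to that change of basis, so classifying logged measurements
is equivalent to classifying [size, shape] coordinates.

Cross-validated hit ratios are judged against chance-corrected criteria:
the maximum chance criterion Cmax = max(n_i)/N, the proportional chance
criterion Cpro = sum((n_i/N)^2), both scaled by 1.25 to form pass
thresholds, and Press's Q = (N - nK)^2 / (N(K-1)) referred to chi-square(1)
at p = 0.1.  Archaeological unknowns receive Gaussian posterior
probabilities per genus plus a typicality probability (chi-square tail of
the squared Mahalanobis distance); specimens atypical of every training
genus are flagged as potential novel taxa but still given a nearest-genus
call.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

from .errors import ComputationError, ValidationError

FAILED_FOLD = "__failed__"


def build_form(table: pd.DataFrame, retained: list[str]) -> pd.DataFrame:
    """Form matrix: log10 of each retained measurement, one row per specimen.

    Uniform size change moves a row along the unit vector; shape differences
    move it within the sum-to-zero complement.
    """
    if not retained:
        raise ValidationError("retained measurement list is empty")
    missing = [c for c in retained if c not in table.columns]
    if missing:
        raise ValidationError(f"measurements not in table: {missing}")
    m = table[list(retained)].to_numpy(dtype=float)
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise ValidationError("form matrix requires complete, positive measurements")
    index = table["specimen_id"] if "specimen_id" in table.columns else table.index
    return pd.DataFrame(np.log10(m), index=pd.Index(index, name="specimen_id"),
                        columns=list(retained))


@dataclass
class DiscriminantModel:
    """Gaussian LDA model: group means, pooled covariance, priors, LD axes.

    ``scalings`` holds up to min(K-1, p) canonical discriminant axes a,
    normalised so that a' W a = 1 (unit pooled within-group variance along
    each axis).
    """

    classes: tuple[str, ...]
    means: pd.DataFrame
    pooled_cov: pd.DataFrame
    priors: pd.Series
    scalings: pd.DataFrame
    counts: pd.Series
    element: str | None = None
    size_group: str | None = None
    _cho: tuple = field(default=None, repr=False, compare=False)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def _cho_factor(self):
        if self._cho is None:
            object.__setattr__(self, "_cho", linalg.cho_factor(self.pooled_cov.to_numpy()))
        return self._cho


def _resolve_priors(priors, classes, counts) -> pd.Series:
    if isinstance(priors, str):
        if priors == "proportional":
            p = counts / counts.sum()
        elif priors == "equal":
            p = pd.Series(1.0 / len(classes), index=list(classes))
        else:
            raise ValidationError("priors must be 'proportional', 'equal', or explicit values")
    else:
        p = pd.Series(priors, dtype=float)
        missing = [c for c in classes if c not in p.index]
        if missing:
            raise ValidationError(f"explicit priors missing classes: {missing}")
        p = p[list(classes)]
        if (p < 0).any() or p.sum() <= 0:
            raise ValidationError("priors must be non-negative with positive sum")
        p = p / p.sum()
    return p.astype(float)


def fit_lda(
    form: pd.DataFrame,
    labels,
    priors="proportional",
    element: str | None = None,
    size_group: str | None = None,
) -> DiscriminantModel:
    """Fit a pooled-covariance Gaussian discriminant model.

    Requires >= 2 classes and an invertible pooled within-group covariance;
    groups smaller than p + 1 specimens trigger a warning (estimates become
    unstable).  The fit is deterministic and invariant to specimen order.
    """
    X = form.to_numpy(dtype=float)
    y = pd.Series(labels).astype(str).to_numpy()
    if len(y) != len(X):
        raise ValidationError("labels length does not match form matrix")
    classes = tuple(sorted(pd.unique(y)))
    if len(classes) < 2:
        raise ValidationError("LDA requires at least 2 groups (genera)")
    n, p = X.shape
    K = len(classes)
    if n - K < p:
        raise ComputationError(
            f"pooled covariance is rank-deficient with n={n}, K={K}, p={p}; "
            "reduce the measurement set"
        )
    counts = pd.Series({c: int((y == c).sum()) for c in classes})
    small = counts[counts < p + 1]
    if len(small):
        warnings.warn(
            "groups smaller than p + 1 specimens: "
            + ", ".join(f"{c} (n={v})" for c, v in small.items()),
            stacklevel=2,
        )
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    W = np.zeros((p, p))
    for i, c in enumerate(classes):
        d = X[y == c] - means[i]
        W += d.T @ d
    W /= n - K
    evals_w = np.linalg.eigvalsh(W)
    if evals_w[0] <= evals_w[-1] * 1e-12:
        raise ComputationError(
            "singular pooled within-group covariance; drop redundant measurements"
        )
    grand = (counts.to_numpy()[:, None] * means).sum(axis=0) / n
    B = np.zeros((p, p))
    for i, c in enumerate(classes):
        d = (means[i] - grand)[:, None]
        B += counts.iloc[i] * (d @ d.T)
    B /= max(K - 1, 1)
    evals, evecs = linalg.eigh(B, W)
    order = np.argsort(evals)[::-1][: min(K - 1, p)]
    A = evecs[:, order]
    # normalise a' W a = 1 and fix signs (largest-|entry| positive)
    for j in range(A.shape[1]):
        a = A[:, j]
        a = a / np.sqrt(a @ W @ a)
        if a[np.abs(a).argmax()] < 0:
            a = -a
        A[:, j] = a
    cols = list(form.columns)
    return DiscriminantModel(
        classes=classes,
        means=pd.DataFrame(means, index=list(classes), columns=cols),
        pooled_cov=pd.DataFrame(W, index=cols, columns=cols),
        priors=_resolve_priors(priors, classes, counts),
        scalings=pd.DataFrame(A, index=cols, columns=[f"LD{j + 1}" for j in range(A.shape[1])]),
        counts=counts, element=element, size_group=size_group,
    )


def _align(model: DiscriminantModel, rows: pd.DataFrame) -> np.ndarray:
    cols = list(model.means.columns)
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise ValidationError(f"rows missing measurements required by the model: {missing}")
    X = rows[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("rows contain missing or non-finite values")
    return X


def mahalanobis_sq(model: DiscriminantModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Squared Mahalanobis distance to each group mean under the pooled covariance."""
    X = _align(model, rows)
    cho = model._cho_factor()
    out = np.empty((len(X), len(model.classes)))
    for i, c in enumerate(model.classes):
        d = X - model.means.loc[c].to_numpy()
        out[:, i] = np.sum(d * linalg.cho_solve(cho, d.T).T, axis=1)
    return pd.DataFrame(out, index=rows.index, columns=list(model.classes))


def posterior_probs(model: DiscriminantModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Gaussian-Bayes posterior probability of each group; rows sum to 1."""
    d2 = mahalanobis_sq(model, rows).to_numpy()
    log_post = -0.5 * d2 + np.log(model.priors.to_numpy())
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    return pd.DataFrame(post, index=rows.index, columns=list(model.classes))


def predict(model: DiscriminantModel, rows: pd.DataFrame) -> pd.Series:
    post = posterior_probs(model, rows)
    return post.idxmax(axis=1)


def discriminant_scores(model: DiscriminantModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Canonical discriminant scores (centred on the weighted grand mean)."""
    X = _align(model, rows)
    grand = (model.counts.to_numpy()[:, None] * model.means.to_numpy()).sum(axis=0) / model.counts.sum()
    return pd.DataFrame((X - grand) @ model.scalings.to_numpy(),
                        index=rows.index, columns=list(model.scalings.columns))


def typicality_probs(model: DiscriminantModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Chi-square tail probability of each row's distance to each group mean.

    Low typicality for *every* group indicates the specimen lies outside the
    training distribution (a potential novel taxon).
    """
    d2 = mahalanobis_sq(model, rows)
    return pd.DataFrame(chi2.sf(d2.to_numpy(), df=model.n_features),
                        index=rows.index, columns=list(model.classes))


@dataclass
class ClassificationResult:
    """Posterior classification of unknown specimens by one model.

    ``table`` mirrors a classification matrix: per-genus posteriors,
    predicted genus (argmax), max typicality and the atypical flag.
    ``skipped`` lists specimens with incomplete measurements.
    """

    table: pd.DataFrame
    posteriors: pd.DataFrame
    typicality: pd.DataFrame
    scores: pd.DataFrame
    typicality_alpha: float
    element: str | None = None
    size_group: str | None = None
    skipped: list = field(default_factory=list)


def classify_unknowns(
    model: DiscriminantModel,
    rows: pd.DataFrame,
    typicality_alpha: float = 0.01,
) -> ClassificationResult:
    """Classify unknown form rows, flagging specimens atypical of all groups.

    Rows with missing measurements are skipped with a warning (fragmentary
    material is out of scope).  Atypical specimens keep their nearest-genus
    call — the flag qualifies, not replaces, the classification.
    """
    if not 0 < typicality_alpha < 1:
        raise ValidationError("typicality_alpha must lie in (0, 1)")
    cols = list(model.means.columns)
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise ValidationError(f"unknowns missing measurements: {missing}")
    ok = rows[cols].notna().all(axis=1) & np.isfinite(rows[cols]).all(axis=1)
    skipped = list(rows.index[~ok])
    if skipped:
        warnings.warn(
            f"skipping {len(skipped)} unknown(s) with incomplete measurements: "
            + ", ".join(map(str, skipped[:20])),
            stacklevel=2,
        )
    use = rows.loc[ok]
    post = posterior_probs(model, use)
    typ = typicality_probs(model, use)
    scores = discriminant_scores(model, use)
    table = post.copy()
    table["predicted_genus"] = post.idxmax(axis=1)
    table["max_posterior"] = post.max(axis=1)
    table["max_typicality"] = typ.max(axis=1)
    table["atypical"] = typ.max(axis=1) < typicality_alpha
    return ClassificationResult(
        table=table, posteriors=post, typicality=typ, scores=scores,
        typicality_alpha=typicality_alpha,
        element=model.element, size_group=model.size_group, skipped=skipped,
    )


@dataclass
class ChanceCriteria:
    """Chance-corrected accuracy benchmarks for a group composition."""

    cmax: float
    cpro: float
    cmax_threshold: float
    cpro_threshold: float


def chance_criteria(counts) -> ChanceCriteria:
    """Cmax = max(n_i)/N, Cpro = sum((n_i/N)^2); thresholds are 1.25x each."""
    n = np.asarray(pd.Series(counts), dtype=float)
    if n.size == 0:
        raise ValidationError("empty group counts")
    if np.any(n <= 0) or not np.all(np.isfinite(n)):
        raise ValidationError("group counts must be positive")
    props = n / n.sum()
    cmax = float(props.max())
    cpro = float((props ** 2).sum())
    return ChanceCriteria(cmax=cmax, cpro=cpro,
                          cmax_threshold=1.25 * cmax, cpro_threshold=1.25 * cpro)


#: chi-square(1) upper 0.1 quantile — the Press Q significance cut-off.
PRESS_Q_ALPHA = 0.1


def press_q(n_correct: float, n_total: int, k_groups: int) -> tuple[float, bool]:
    """Press's Q statistic and its significance at p = 0.1 against chi-square(1)."""
    if k_groups < 2:
        raise ValidationError("Press Q requires at least 2 groups")
    if not 0 <= n_correct <= n_total:
        raise ValidationError("n_correct must lie in [0, N]")
    q = (n_total - n_correct * k_groups) ** 2 / (n_total * (k_groups - 1))
    cutoff = chi2.ppf(1 - PRESS_Q_ALPHA, df=1)
    return float(q), bool(q > cutoff)


@dataclass
class CrossValidationReport:
    """Machine form of a cross-validated hit-ratio table row.

    ``confusion`` is a true-genus x predicted-genus count table (plus a
    ``__failed__`` column when degenerate folds occurred); its trace over N
    is the hit ratio.
    """

    scheme: str
    hit_ratio: float
    n_correct: float
    confusion: pd.DataFrame
    n: int
    k: int
    cmax: float
    cpro: float
    cmax_threshold: float
    cpro_threshold: float
    press_q: float
    press_q_significant: bool
    seed: int | None = None
    repetitions: int | None = None
    degenerate_folds: list = field(default_factory=list)
    beats_cmax: bool = False
    beats_cpro: bool = False
    overall_pass: bool = False

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme, "seed": self.seed, "repetitions": self.repetitions,
            "n": self.n, "k": self.k,
            "hit_ratio": float(self.hit_ratio), "n_correct": float(self.n_correct),
            "cmax": self.cmax, "cpro": self.cpro,
            "cmax_threshold": self.cmax_threshold, "cpro_threshold": self.cpro_threshold,
            "press_q": self.press_q, "press_q_significant": self.press_q_significant,
            "beats_cmax": self.beats_cmax, "beats_cpro": self.beats_cpro,
            "overall_pass": self.overall_pass,
            "degenerate_folds": [str(f) for f in self.degenerate_folds],
            "confusion": {t: {c: int(v) for c, v in row.items()}
                          for t, row in self.confusion.to_dict(orient="index").items()},
        }


def evaluate_hit_ratio(report: CrossValidationReport) -> dict:
    """Pass verdicts: hit ratio strictly above both 1.25x thresholds and
    Press Q significant; ``overall_pass`` is their conjunction."""
    beats_cmax = report.hit_ratio > report.cmax_threshold
    beats_cpro = report.hit_ratio > report.cpro_threshold
    overall = bool(beats_cmax and beats_cpro and report.press_q_significant)
    report.beats_cmax = bool(beats_cmax)
    report.beats_cpro = bool(beats_cpro)
    report.overall_pass = overall
    return {
        "beats_cmax": report.beats_cmax, "beats_cpro": report.beats_cpro,
        "press_q_significant": report.press_q_significant, "overall_pass": overall,
    }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: tuple[str, ...]) -> pd.DataFrame:
    pred_levels = list(classes) + ([FAILED_FOLD] if FAILED_FOLD in y_pred else [])
    conf = pd.DataFrame(0, index=list(classes), columns=pred_levels, dtype=int)
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    return conf


def cross_validate(
    form: pd.DataFrame,
    labels,
    scheme: str = "loocv",
    repetitions: int = 1000,
    holdout_fraction: float = 0.2,
    seed: int | None = None,
    priors="proportional",
) -> CrossValidationReport:
    """Cross-validated reclassification of the training set.

    ``loocv`` (default) refits the model with each specimen held out in turn
    — exhaustive and deterministic.  ``monte_carlo`` repeats a stratified
    random holdout ``repetitions`` times and averages the hit ratio.  Folds
    whose reduced training set loses a genus or a full-rank covariance are
    counted as misclassified and recorded in ``degenerate_folds``.
    """
    y = pd.Series(labels).astype(str).to_numpy()
    X = form.to_numpy(dtype=float)
    if len(y) != len(X):
        raise ValidationError("labels length does not match form matrix")
    classes = tuple(sorted(pd.unique(y)))
    if len(classes) < 2:
        raise ValidationError("cross-validation requires at least 2 groups")
    counts = pd.Series({c: int((y == c).sum()) for c in classes})
    chance = chance_criteria(counts)
    N, K = len(y), len(classes)
    degenerate: list = []

    def _fold_predict(train_idx, test_idx):
        try:
            model = fit_lda(form.iloc[train_idx], y[train_idx], priors=priors)
            return predict(model, form.iloc[test_idx]).to_numpy()
        except (ValidationError, ComputationError) as exc:
            degenerate.append((list(form.index[test_idx]), str(exc)))
            return np.array([FAILED_FOLD] * len(test_idx))

    if scheme == "loocv":
        preds = np.empty(N, dtype=object)
        all_idx = np.arange(N)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(N):
                preds[i] = _fold_predict(np.delete(all_idx, i), np.array([i]))[0]
        n_correct = float((preds == y).sum())
        hit = n_correct / N
        conf = _confusion(y, preds, classes)
        reps = None
    elif scheme == "monte_carlo":
        if repetitions < 1:
            raise ValidationError("repetitions must be >= 1 for monte_carlo CV")
        rng = np.random.default_rng(seed)
        class_idx = {c: np.flatnonzero(y == c) for c in classes}
        total_correct = 0
        total_tested = 0
        conf = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(int(repetitions)):
                test = np.concatenate([
                    rng.permutation(idx)[: max(1, int(round(holdout_fraction * len(idx))))]
                    for idx in class_idx.values()
                ])
                train = np.setdiff1d(np.arange(N), test)
                p = _fold_predict(train, test)
                total_correct += int((p == y[test]).sum())
                total_tested += len(test)
                for t, pr in zip(y[test], p):
                    if pr in conf.columns:
                        conf.loc[t, pr] += 1
                    else:
                        conf[pr] = 0
                        conf.loc[t, pr] += 1
        hit = total_correct / total_tested
        n_correct = hit * N
        reps = int(repetitions)
    else:
        raise ValidationError("scheme must be 'loocv' or 'monte_carlo'")

    q, sig = press_q(n_correct, N, K)
    report = CrossValidationReport(
        scheme=scheme, hit_ratio=float(hit), n_correct=n_correct, confusion=conf,
        n=N, k=K, cmax=chance.cmax, cpro=chance.cpro,
        cmax_threshold=chance.cmax_threshold, cpro_threshold=chance.cpro_threshold,
        press_q=q, press_q_significant=sig, seed=seed, repetitions=reps,
        degenerate_folds=degenerate,
    )
    evaluate_hit_ratio(report)
    return report
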