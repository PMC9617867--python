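"""End-to-end orchestration: ingest -> reliability -> redundancy -> size/shape
-> ordination/MANOVA -> cross-validated LDA -> unknown classification.

The pipeline consumes the CSV dialects defined in :mod:`pesmorph.ingest`,
runs every stage per skeletal element and size group, writes plain-CSV
outputs plus a JSON run report, and is deterministic for a fixed config and
seed.  Stages that cannot run (e.g. a size group with a single genus)
report a skip reason instead of failing the run.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .discriminant import (
    build_form, classify_unknowns, cross_validate, fit_lda,
)
from .errors import ComputationError, ValidationError
from .ingest import (
    aggregate_repeats, complete_cases, measurement_columns,
    read_metadata, read_repeat_table, repeat_reliability, select_measurement_subset,
)
from .ordination import fit_pca, manova_by_species, manova_shape, project
from .redundancy import stepwise_redundancy
from .size_shape import (
    DEFAULT_GROUP_LABELS, assign_size_groups, place_unknown_in_groups,
    shape_matrix, size_profile,
)

#: element-specific retained-measurement floors for the redundancy step
DEFAULT_MIN_KEEP = {"astragalus": 7, "metatarsal4": 7, "calcaneus": 9}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    repeats_csv: str
    metadata_csv: str
    elements: list[str] | None = None
    keep_measurements: list[str] | None = None
    force_exclude: list[str] = field(default_factory=list)
    force_keep: list[str] = field(default_factory=list)
    congruence_threshold: float = 0.99
    min_keep: dict | int | None = None
    boundaries: list[float] | None = None
    group_labels: list[str] = field(default_factory=lambda: list(DEFAULT_GROUP_LABELS))
    central_interval: float = 0.95
    pad_fraction: float = 0.025
    icc_variant: str = "icc3"
    icc_threshold: float = 0.9
    manova_min_n: int = 8
    cv_scheme: str = "loocv"
    cv_repetitions: int = 1000
    priors: str = "proportional"
    typicality_alpha: float = 0.01
    seed: int = 0
    outdir: str = "pesmorph_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "repeats_csv" not in raw or "metadata_csv" not in raw:
            raise ValidationError("config must set repeats_csv and metadata_csv")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("repeats_csv", "metadata_csv"):
            path = getattr(self, key)
            if not Path(path).exists():
                raise ValidationError(f"{key} points at a missing file: {path}")
        if not 0 < self.congruence_threshold <= 1:
            raise ValidationError("congruence_threshold must lie in (0, 1]")
        if not 0 < self.central_interval <= 1:
            raise ValidationError("central_interval must lie in (0, 1]")
        if not 0 < self.typicality_alpha < 1:
            raise ValidationError("typicality_alpha must lie in (0, 1)")
        if self.cv_scheme not in ("loocv", "monte_carlo"):
            raise ValidationError("cv_scheme must be 'loocv' or 'monte_carlo'")

    def min_keep_for(self, element: str, n_measurements: int) -> int:
        if isinstance(self.min_keep, int):
            return self.min_keep
        table = self.min_keep if isinstance(self.min_keep, dict) else DEFAULT_MIN_KEEP
        return int(table.get(element, min(7, n_measurements)))

    def config_hash(self) -> str:
        """Hash of the analytic settings (output location excluded)."""
        settings = {k: v for k, v in asdict(self).items() if k != "outdir"}
        payload = json.dumps(settings, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_to_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, allow_nan=True))


def load_report(path) -> dict:
    return json.loads(Path(path).read_text())


def strip_timestamps(report: dict) -> dict:
    """Copy of a run report without timing provenance (for determinism checks)."""
    out = json.loads(json.dumps(_jsonable(report)))
    prov = out.get("provenance", {})
    prov.pop("started", None)
    prov.pop("finished", None)
    return out


def summarize_by_stratum(classification: pd.DataFrame, strata: pd.Series) -> pd.DataFrame:
    """Cross-tabulate predicted genus by stratum; atypical specimens counted
    separately under ``(atypical)``."""
    if classification.empty:
        return pd.DataFrame()
    pred = classification["predicted_genus"].where(~classification["atypical"], "(atypical)")
    strata = strata.reindex(classification.index).fillna("(none)")
    return pd.crosstab(pred.rename("genus"), strata.rename("stratum"))


def _best_classification(per_group: list[tuple[str, pd.Series]]) -> pd.Series | None:
    """Among group-level calls for one unknown, keep the most confident."""
    if not per_group:
        return None
    return max(per_group, key=lambda gr: gr[1]["max_posterior"])[1]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to disk).

    Outputs (all plain CSV plus ``run_report.json``) land in
    ``config.outdir``; the report lists every file written.  Identical
    config + seed produce identical reports up to timestamps.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    outputs: list[str] = []

    def write(df: pd.DataFrame, name: str, index=False):
        path = outdir / name
        df.to_csv(path, index=index)
        outputs.append(name)

    repeats = read_repeat_table(config.repeats_csv)
    metadata = read_metadata(config.metadata_csv)
    table_all = aggregate_repeats(repeats, metadata)
    write(table_all, "specimen_table.csv")

    elements = config.elements or sorted(table_all["element"].dropna().unique())
    report: dict = {"elements": {}}
    crossval_rows = []

    for element in elements:
        el_report: dict = {}
        report["elements"][element] = el_report
        sub_repeats = repeats[repeats["element"] == element]
        table = table_all[table_all["element"] == element].reset_index(drop=True)
        if table.empty:
            el_report["skipped"] = "no specimens for this element"
            continue

        rel = repeat_reliability(sub_repeats, icc_variant=config.icc_variant,
                                 icc_threshold=config.icc_threshold)
        write(rel.table, f"reliability_{element}.csv")
        el_report["reliability"] = {
            "icc_variant": rel.icc_variant,
            "icc_min": float(rel.table["icc"].min()),
            "flagged": rel.flagged_measurements,
        }

        if config.keep_measurements:
            keep = [m for m in config.keep_measurements if m in measurement_columns(table)]
            table = select_measurement_subset(table, keep)
        table = complete_cases(table)
        is_arch = table["provenance"] == "archaeological"
        training = table[~is_arch].reset_index(drop=True)
        unknowns = table[is_arch].reset_index(drop=True)
        el_report["n_training"] = int(len(training))
        el_report["n_unknowns"] = int(len(unknowns))
        if len(training) < 10:
            el_report["skipped"] = "fewer than 10 training specimens"
            continue

        meas = measurement_columns(training)
        train_shape = shape_matrix(training)
        min_keep = config.min_keep_for(element, len(meas))
        if len(meas) > min_keep:
            red = stepwise_redundancy(
                train_shape, force_exclude=config.force_exclude,
                force_keep=config.force_keep,
                congruence_threshold=config.congruence_threshold,
                min_keep=min_keep,
            )
            retained = red.retained
            write(red.to_frame(), f"redundancy_{element}.csv")
            el_report["redundancy"] = {
                "retained": retained, "dropped": red.dropped_names,
                "threshold": red.congruence_threshold,
            }
        else:
            retained = [m for m in meas if m not in config.force_exclude]
            el_report["redundancy"] = {"retained": retained, "dropped": [],
                                       "threshold": config.congruence_threshold}

        training_r = select_measurement_subset(training, retained)
        unknowns_r = select_measurement_subset(unknowns, retained) if len(unknowns) else unknowns
        profile = size_profile(training_r, central_interval=config.central_interval)
        grouping = assign_size_groups(profile, boundaries=config.boundaries,
                                      labels=tuple(config.group_labels))
        write(profile.per_species, f"size_profile_{element}.csv")
        write(grouping.to_frame(), f"size_groups_{element}.csv")
        el_report["size_grouping"] = grouping.to_dict()

        unknown_placements = {}
        if len(unknowns_r):
            gm_unknown = unknowns_r[retained].apply(
                lambda r: float(np.exp(np.mean(np.log(r.to_numpy(dtype=float))))), axis=1
            )
            for sid, gm in zip(unknowns_r["specimen_id"], gm_unknown):
                unknown_placements[sid] = place_unknown_in_groups(
                    gm, grouping, pad_fraction=config.pad_fraction
                )
            el_report["unknown_placement"] = {
                sid: {"groups": list(pl.groups), "flag": pl.flag}
                for sid, pl in unknown_placements.items()
            }

        el_report["groups"] = {}
        unknown_calls: dict[str, list] = {}
        for label in grouping.labels:
            members = grouping.members(label)
            grp_report: dict = {"species": [f"{g} {s}" for g, s in members]}
            el_report["groups"][label] = grp_report
            mask = training_r.apply(
                lambda r: (r["genus"], r["species"]) in members, axis=1
            ) if members else pd.Series(False, index=training_r.index)
            grp_train = training_r[mask].reset_index(drop=True)
            grp_report["n"] = int(len(grp_train))
            grp_report["genus_counts"] = grp_train["genus"].value_counts().to_dict()
            if len(grp_train) < 3:
                grp_report["skipped"] = "fewer than 3 training specimens in group"
                continue

            grp_shape = shape_matrix(grp_train)
            grp_unknown_ids = [sid for sid, pl in unknown_placements.items()
                               if label in pl.groups]
            try:
                pca = fit_pca(grp_shape)
                write(pca.scores.reset_index(), f"pca_scores_{element}_{label}.csv")
                write(pca.loadings.reset_index(names="measurement"),
                      f"pca_loadings_{element}_{label}.csv")
                grp_report["pca"] = {
                    "explained_ratio": [float(v) for v in pca.explained_ratio[:5]],
                }
                if grp_unknown_ids:
                    rows = unknowns_r[unknowns_r["specimen_id"].isin(grp_unknown_ids)]
                    unk_scores = project(pca, shape_matrix(rows))
                    write(unk_scores.reset_index(),
                          f"pca_scores_unknowns_{element}_{label}.csv")
            except (ValidationError, ComputationError) as exc:
                grp_report["pca"] = {"skipped": str(exc)}
                pca = None

            manova_rows = []
            log_gm = np.log10(grp_train[retained].to_numpy(dtype=float)).mean(axis=1)
            try:
                res = manova_shape(grp_shape, pd.Series(log_gm, index=grp_shape.index,
                                                        name="size"), kind="continuous")
                manova_rows.append({"species": "(all)", **res.to_dict()})
            except (ValidationError, ComputationError) as exc:
                manova_rows.append({"species": "(all)", "predictor": "size", "skipped": str(exc)})
            for pred in ("age_class", "sex"):
                manova_rows += manova_by_species(
                    grp_shape, grp_train, pred, kind="categorical",
                    min_n=config.manova_min_n,
                )
            grp_report["manova"] = manova_rows
            write(pd.DataFrame(manova_rows), f"manova_{element}_{label}.csv")

            if grp_train["genus"].nunique() < 2:
                grp_report["crossval"] = {"skipped": "single genus in size group"}
                continue
            form = build_form(grp_train, retained)
            try:
                cv = cross_validate(
                    form, grp_train["genus"], scheme=config.cv_scheme,
                    repetitions=config.cv_repetitions, seed=config.seed,
                    priors=config.priors,
                )
            except (ValidationError, ComputationError) as exc:
                grp_report["crossval"] = {"skipped": str(exc)}
                continue
            grp_report["crossval"] = cv.to_dict()
            write(cv.confusion.reset_index(names="true_genus"),
                  f"confusion_{element}_{label}.csv")
            crossval_rows.append({
                "element": element, "size_group": label, "n": cv.n, "k": cv.k,
                "hit_ratio": cv.hit_ratio, "cmax_threshold": cv.cmax_threshold,
                "cpro_threshold": cv.cpro_threshold, "press_q": cv.press_q,
                "press_q_significant": cv.press_q_significant,
                "overall_pass": cv.overall_pass,
            })

            model = fit_lda(form, grp_train["genus"], priors=config.priors,
                            element=element, size_group=label)
            if grp_unknown_ids:
                rows = unknowns_r[unknowns_r["specimen_id"].isin(grp_unknown_ids)]
                uform = build_form(rows, retained)
                result = classify_unknowns(model, uform,
                                           typicality_alpha=config.typicality_alpha)
                tab = result.table.copy()
                tab.insert(0, "size_group", label)
                grp_report["classification"] = _jsonable(
                    tab.reset_index().to_dict(orient="records")
                )
                for sid, row in tab.iterrows():
                    unknown_calls.setdefault(sid, []).append((label, row))

        if unknown_calls:
            best_rows = []
            for sid, calls in unknown_calls.items():
                best = _best_classification(calls)
                rec = best.to_dict()
                rec["specimen_id"] = sid
                rec["groups_analysed"] = "|".join(lab for lab, _ in calls)
                rec["range_flag"] = unknown_placements[sid].flag
                best_rows.append(rec)
            class_df = pd.DataFrame(best_rows).set_index("specimen_id")
            lead = ["size_group", "groups_analysed", "predicted_genus",
                    "max_posterior", "max_typicality", "atypical", "range_flag"]
            class_df = class_df[lead + [c for c in class_df.columns if c not in lead]]
            write(class_df.reset_index(), f"classification_{element}.csv")
            el_report["classification"] = _jsonable(
                class_df.reset_index().to_dict(orient="records"))
            strata = unknowns_r.set_index("specimen_id")["stratum"]
            strat = summarize_by_stratum(class_df, strata)
            if not strat.empty:
                write(strat.reset_index(), f"stratum_summary_{element}.csv")
                el_report["stratum_summary"] = {
                    g: {str(s): int(v) for s, v in row.items()}
                    for g, row in strat.to_dict(orient="index").items()
                }

    if crossval_rows:
        write(pd.DataFrame(crossval_rows), "crossval_summary.csv")
    report["provenance"] = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "cv_scheme": config.cv_scheme,
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
    }
    report["outputs"] = outputs + ["run_report.json"]
    report_to_json(report, outdir / "run_report.json")
    return report
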