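"""End-to-end study orchestration.

``run_study`` takes a cohort (a directory of RR files or the synthetic
generator), applies the reliability filter, extracts the 13 features per
record, and writes the report bundle:

* ``features.csv`` — one row per record
* ``session_stats.csv`` — per-session descriptives of every feature
* ``differences.csv`` — stress-minus-rest descriptives + Wilcoxon p
* ``classification.csv`` — single-feature and best-subset CV results with
  human-readable rule text
* ``rules.json`` — rule weights/intercepts
* ``run_log.txt`` and ``config.json`` — provenance

Both statistics tables and the classification table are computed from the
same in-memory feature frame (no recomputation drift).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, stats
from .errors import HRVError, PairingError, ValidationError
from .features import FEATURE_NAMES, RadiusMode, extract_all_features
from .rr_io import NNSeries, RRSeries, read_rr, reliability_check, to_nn
from .synth import SyntheticParams, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    input_dir: str | None = None        # directory of RR CSV files
    synthetic: SyntheticParams | None = None
    unit: str = "s"                     # input unit for file-based cohorts
    reliability_threshold: float = 0.90
    entropy_m: int = 2
    d2_m: int = 10
    rp_m: int = 10
    rp_tau: int = 1
    rp_radius_mode: RadiusMode = "sqrt_m"
    cv_folds: int = 10
    cv_seed: int = 0
    full_search: bool = True            # exhaustive subset search for the best rule
    skip_invalid: bool = False
    output_dir: str = "study_out"

    def resolved(self) -> dict:
        out = asdict(self)
        if self.synthetic is not None:
            out["synthetic"] = asdict(self.synthetic)
        return out


def load_cohort(config: StudyConfig) -> list[RRSeries]:
    """Read or synthesize the raw RR records."""
    if (config.input_dir is None) == (config.synthetic is None):
        raise ValidationError(
            "exactly one of input_dir and synthetic must be set")
    if config.synthetic is not None:
        return generate_cohort(config.synthetic)
    records = []
    paths = sorted(Path(config.input_dir).glob("*.csv"))
    if not paths:
        raise ValidationError(f"no .csv records under {config.input_dir}")
    for path in paths:
        # file name convention: <subject>_<session>.csv
        stem = path.stem
        if "_" not in stem:
            raise ValidationError(
                f"{path.name}: expected <subject>_<session>.csv")
        subject_id, session = stem.rsplit("_", 1)
        if session not in ("rest", "stress"):
            raise ValidationError(f"{path.name}: unknown session {session!r}")
        records.append(read_rr(path, subject_id=subject_id, session=session,
                               unit=config.unit))
    return records


def preprocess(records: list[RRSeries], config: StudyConfig
               ) -> tuple[list[NNSeries], list[str]]:
    """Filter to NN series and apply the reliability criterion.

    Returns the retained series and the ids of excluded records.
    """
    kept, excluded = [], []
    for record in records:
        tag = f"{record.subject_id}/{record.session}"
        try:
            nn = to_nn(record)
        except HRVError:
            if not config.skip_invalid:
                raise
            excluded.append(tag)
            continue
        if reliability_check(nn, config.reliability_threshold):
            kept.append(nn)
        else:
            excluded.append(tag)
    return kept, excluded


def extract_features(series: list[NNSeries], config: StudyConfig) -> pd.DataFrame:
    rows = []
    for nn in series:
        vector = extract_all_features(
            nn, entropy_m=config.entropy_m, d2_m=config.d2_m,
            rp_m=config.rp_m, rp_tau=config.rp_tau,
            rp_radius_mode=config.rp_radius_mode)
        row = {"subject_id": nn.subject_id, "session": nn.session}
        row.update(vector.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "session", *FEATURE_NAMES])


def session_stats_table(dataset: classify.PairedDataset) -> pd.DataFrame:
    """Per-session descriptives of every feature (one row per feature)."""
    rows = []
    frame = dataset.frame
    for feature in dataset.feature_names:
        row = {"feature": feature}
        for session in ("rest", "stress"):
            summary = stats.describe(
                frame.loc[frame["session"] == session, feature])
            row.update({
                f"{session}_mean": summary.mean, f"{session}_sd": summary.sd,
                f"{session}_median": summary.median,
                f"{session}_q25": summary.q25, f"{session}_q75": summary.q75,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def differences_table(dataset: classify.PairedDataset) -> pd.DataFrame:
    """Stress-minus-rest descriptives plus the Wilcoxon signed-rank p."""
    rows = []
    for feature in dataset.feature_names:
        diffs, summary = stats.paired_differences(dataset, feature)
        test = stats.wilcoxon_signed_rank(diffs)
        rows.append({
            "feature": feature, "mean": summary.mean, "sd": summary.sd,
            "median": summary.median, "q25": summary.q25, "q75": summary.q75,
            "p_value": test.p_value, "p_display": stats.format_p(test.p_value),
            "n_effective": test.n_effective, "exact": test.exact,
        })
    return pd.DataFrame(rows)


def classification_table(dataset: classify.PairedDataset,
                         config: StudyConfig
                         ) -> tuple[pd.DataFrame, dict]:
    """Single-feature rows plus the best subset, with refit rule text."""
    if config.cv_folds > dataset.n_subjects:
        raise ValidationError(
            f"cv_folds = {config.cv_folds} exceeds the "
            f"{dataset.n_subjects} subjects")
    folds = classify.make_subject_folds(dataset, k=config.cv_folds,
                                        seed=config.cv_seed)
    rows, rules = [], {}

    def _add(subset, report):
        rule = classify.final_rule(dataset, list(subset))
        key = ",".join(subset)
        rules[key] = {
            "features": list(subset),
            "weights": [float(w) for w in rule.weights],
            "intercept": float(rule.intercept),
            "text": rule.text(),
        }
        rows.append({
            "features": key, "n_features": len(subset),
            "ACC": report.acc, "SEN": report.sen, "SPE": report.spe,
            "PPV": report.ppv, "NPV": report.npv, "rule": rule.text(),
        })

    single_reports = []
    for feature in dataset.feature_names:
        report = classify.cross_validate(dataset, [feature], folds)
        single_reports.append(((feature,), report))
        _add((feature,), report)

    if config.full_search:
        ranking, n_enumerated = classify.exhaustive_search(dataset, folds)
        best_subset, best_report = ranking[0]
        search_info = {"n_enumerated": n_enumerated,
                       "n_evaluated": len(ranking),
                       "best_subset": list(best_subset),
                       "best_acc": best_report.acc}
    else:
        best_subset, best_report = max(
            single_reports, key=lambda item: item[1].acc)
        search_info = {"n_enumerated": None, "n_evaluated": len(single_reports),
                       "best_subset": list(best_subset),
                       "best_acc": best_report.acc}
    if len(best_subset) > 1 or not config.full_search:
        _add(best_subset, best_report)
    table = pd.DataFrame(rows).sort_values(
        ["ACC", "n_features"], ascending=[False, True]).reset_index(drop=True)
    return table, {"rules": rules, "search": search_info}


def run_study(config: StudyConfig) -> dict:
    """Execute the full pipeline and write the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config: {json.dumps(config.resolved(), sort_keys=True)}"]

    records = load_cohort(config)
    kept, excluded = preprocess(records, config)
    log_lines.append(f"records: {len(records)} read, {len(kept)} retained, "
                     f"{len(excluded)} excluded {excluded}")
    if not kept:
        raise ValidationError("empty cohort after reliability filtering")

    features = extract_features(kept, config)
    try:
        dataset = classify.PairedDataset(features)
    except PairingError:
        raise
    stats_table = session_stats_table(dataset)
    diff_table = differences_table(dataset)
    clf_table, clf_meta = classification_table(dataset, config)

    features.to_csv(out / "features.csv", index=False)
    stats_table.to_csv(out / "session_stats.csv", index=False)
    diff_table.to_csv(out / "differences.csv", index=False)
    clf_table.to_csv(out / "classification.csv", index=False)
    (out / "rules.json").write_text(json.dumps(clf_meta, indent=2) + "\n")
    (out / "config.json").write_text(
        json.dumps(config.resolved(), indent=2, sort_keys=True) + "\n")
    log_lines.append(f"rp_radius_mode: {config.rp_radius_mode}")
    log_lines.append(f"search: {json.dumps(clf_meta['search'])}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return {
        "features": features,
        "session_stats": stats_table,
        "differences": diff_table,
        "classification": clf_table,
        "rules": clf_meta["rules"],
        "search": clf_meta["search"],
        "excluded": excluded,
        "output_dir": str(out),
    }
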