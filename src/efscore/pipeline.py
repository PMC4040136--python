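"""End-to-end pipeline: score images, compare groups, emit a report bundle.

The bundle contains per-image scores, per-patient aggregates, an
upper-vs-lower-lobe paired comparison, group comparisons for every cohort
variable (continuous -> pooled t, categorical -> Fisher/chi-square routing),
an inter-rater kappa table when two-rater data are supplied, Kaplan-Meier /
log-rank survival output, and a machine-readable JSON that is the source of
truth for every number in the human-readable tables.  Identical config and
inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from efscore import cohortstats
from efscore._version import __version__ as _version
from efscore.config import default_grayscale_weights
from efscore.efquant import PatientAggregate, ThresholdConfig, score_manifest
from efscore.semiquant import RaterPair, weighted_kappa

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

P_DECIMALS = 3
PCT_DECIMALS = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and knobs for one reproducible pipeline run."""

    out_dir: Path
    image_dir: Path | None = None
    manifest_csv: Path | None = None
    cohort_csv: Path | None = None
    survival_csv: Path | None = None
    ratings_csv: Path | None = None
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    grayscale_weights: tuple[float, float, float] | None = None
    kappa_weighting: Literal["linear", "quadratic"] = "linear"
    group_column: str = "group"
    seed: int = 0

    @property
    def has_images(self) -> bool:
        return self.image_dir is not None and self.manifest_csv is not None


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML or JSON file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    thr = raw.pop("threshold", None)
    threshold = ThresholdConfig(**thr) if thr else ThresholdConfig()
    paths = {
        k: Path(raw.pop(k))
        for k in ("image_dir", "manifest_csv", "cohort_csv", "survival_csv", "ratings_csv")
        if raw.get(k)
    }
    gw = raw.pop("grayscale_weights", None)
    return PipelineConfig(
        out_dir=Path(raw.pop("out_dir")),
        threshold=threshold,
        grayscale_weights=tuple(gw) if gw else None,
        **paths,
        **raw,
    )


def _config_hash(config: PipelineConfig) -> str:
    # out_dir only says where the bundle lands, not what is computed
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)
    blob = json.dumps(payload, default=str, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _round(x: float, nd: int) -> float:
    return float(np.round(x, nd))


def _lobe_paired_comparison(aggregates: Sequence[PatientAggregate]) -> dict | None:
    """Paired t of upper- vs lower-lobe means within patients having both."""
    upper, lower = [], []
    for agg in aggregates:
        if "upper" in agg.lobe_scores and "lower" in agg.lobe_scores:
            upper.append(agg.lobe_scores["upper"])
            lower.append(agg.lobe_scores["lower"])
    if len(upper) < 2:
        logger.warning("fewer than two patients with both lobes; paired lobe comparison skipped")
        return None
    res = cohortstats.t_test_raw(upper, lower, paired=True)
    return {
        "n_patients": len(upper),
        "mean_upper_pct": _round(float(np.mean(upper)), PCT_DECIMALS),
        "mean_lower_pct": _round(float(np.mean(lower)), PCT_DECIMALS),
        "method": res.method,
        "statistic": res.statistic,
        "p_two_sided": res.p_two_sided,
    }


def _group_comparisons(cohort: pd.DataFrame, group_col: str) -> list[dict]:
    groups = list(pd.unique(cohort[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    a, b = groups
    out = []
    for col in cohort.columns:
        if col in (group_col, "patient_id"):
            continue
        xa = cohort.loc[cohort[group_col] == a, col]
        xb = cohort.loc[cohort[group_col] == b, col]
        if pd.api.types.is_numeric_dtype(cohort[col]):
            sa = cohortstats.summarize_continuous(xa)
            sb = cohortstats.summarize_continuous(xb)
            res = cohortstats.t_test_from_summary(sa, sb)
            out.append(
                {
                    "variable": col,
                    "kind": "continuous",
                    "group_a": {"mean": sa.mean, "sd": sa.sd, "n": sa.n},
                    "group_b": {"mean": sb.mean, "sd": sb.sd, "n": sb.n},
                    "method": res.method,
                    "statistic": res.statistic,
                    "p_two_sided": res.p_two_sided,
                }
            )
        else:
            crosstab = pd.crosstab(cohort[group_col], cohort[col]).reindex([a, b])
            if crosstab.shape[1] < 2:
                logger.warning("variable %s has a single category; skipped", col)
                continue
            table = cohortstats.ContingencyTable.from_counts(
                crosstab.to_numpy().tolist(),
                row_labels=tuple(str(g) for g in crosstab.index),
                col_labels=tuple(str(c) for c in crosstab.columns),
            )
            res = cohortstats.choose_categorical_test(table)
            out.append(
                {
                    "variable": col,
                    "kind": "categorical",
                    "categories": list(map(str, crosstab.columns)),
                    "counts_a": [int(v) for v in crosstab.iloc[0]],
                    "counts_b": [int(v) for v in crosstab.iloc[1]],
                    "method": res.method,
                    "statistic": res.statistic,
                    "p_two_sided": res.p_two_sided,
                }
            )
    return out


def _kappa_table(ratings: pd.DataFrame, weighting: str) -> list[dict]:
    """Weighted kappa per item from a long table (item, rater_a, rater_b)."""
    out = []
    for item, sub in ratings.groupby("item", sort=True):
        a = tuple(int(v) for v in sub["rater_a"])
        b = tuple(int(v) for v in sub["rater_b"])
        k = int(max(max(a), max(b))) + 1
        try:
            pair = RaterPair(a, b, max(k, 2))
            res = weighted_kappa(pair, weighting)  # type: ignore[arg-type]
        except ValueError as exc:
            logger.warning("kappa undefined for item %s: %s", item, exc)
            continue
        out.append({"item": str(item), "weighting": res.weighting, "kappa": res.kappa})
    return out


def _survival_section(survival: pd.DataFrame, group_col: str) -> dict:
    groups = list(pd.unique(survival[group_col]))
    if len(groups) != 2:
        raise ValueError("survival table must contain exactly two groups")
    a, b = groups
    sub_a = survival[survival[group_col] == a]
    sub_b = survival[survival[group_col] == b]
    curves = {}
    for label, sub in ((a, sub_a), (b, sub_b)):
        curve = cohortstats.km_estimate(sub["time_months"], sub["event"])
        curves[str(label)] = {
            "times": curve.times.tolist(),
            "survival": curve.survival.tolist(),
            "n": len(sub),
            "events": int(sub["event"].sum()),
        }
    section: dict = {"kaplan_meier": curves}
    try:
        res = cohortstats.logrank(
            sub_a["time_months"], sub_a["event"], sub_b["time_months"], sub_b["event"]
        )
        section["logrank"] = {
            "statistic": res.statistic,
            "df": res.df,
            "p_two_sided": res.p_two_sided,
        }
    except ValueError as exc:
        logger.warning("log-rank skipped: %s", exc)
    return section


def _render_markdown(report: dict) -> str:
    lines = ["# Cohort analysis report", ""]
    lines.append(f"Run: version {report['meta']['version']}, seed {report['meta']['seed']}, config {report['meta']['config_hash']}")
    lines.append("")
    lines.append("No multiple-testing correction is applied; p-values are per-row nominal, two-sided.")
    if "patients" in report:
        lines += ["", "## EF scores (percent)", "", "| patient | score | per-lobe |", "|---|---|---|"]
        for p in report["patients"]:
            lobes = "; ".join(f"{k}: {round(v, PCT_DECIMALS)}" for k, v in p["lobe_scores"].items())
            lines.append(f"| {p['patient_id']} | {round(p['patient_ef_score'], PCT_DECIMALS)} | {lobes} |")
    if report.get("lobe_comparison"):
        lc = report["lobe_comparison"]
        lines += [
            "",
            "## Upper vs lower lobe (paired)",
            "",
            f"Upper {lc['mean_upper_pct']}% vs lower {lc['mean_lower_pct']}% "
            f"in {lc['n_patients']} patients; paired t p = {round(lc['p_two_sided'], P_DECIMALS)}.",
        ]
    if report.get("group_comparisons"):
        lines += ["", "## Group comparisons", "", "| variable | method | p |", "|---|---|---|"]
        for row in report["group_comparisons"]:
            lines.append(
                f"| {row['variable']} | {row['method']} | {round(row['p_two_sided'], P_DECIMALS)} |"
            )
    if report.get("kappa"):
        lines += ["", "## Inter-rater agreement", "", "| item | weighting | kappa |", "|---|---|---|"]
        for row in report["kappa"]:
            lines.append(f"| {row['item']} | {row['weighting']} | {round(row['kappa'], 2)} |")
    if report.get("survival") and "logrank" in report["survival"]:
        lr = report["survival"]["logrank"]
        lines += [
            "",
            "## Survival",
            "",
            f"Log-rank chi-square = {round(lr['statistic'], 3)} (df 1), p = {round(lr['p_two_sided'], P_DECIMALS)}.",
        ]
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Stages without inputs are skipped (a cohort-only config yields a
    statistics-only report).  Writes ``scores.csv``, ``patients.csv``,
    ``report.json`` and ``report.md`` into ``config.out_dir`` and returns the
    report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "meta": {
            "version": _version,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "alpha": cohortstats.ALPHA,
            "multiple_testing_correction": "none",
        }
    }

    if config.has_images:
        manifest = pd.read_csv(config.manifest_csv)
        weights = config.grayscale_weights or default_grayscale_weights()
        scores, aggregates = score_manifest(
            config.image_dir, manifest, config.threshold, weights
        )
        scores.to_csv(out / "scores.csv", index=False)
        patients = pd.DataFrame(
            {
                "patient_id": [a.patient_id for a in aggregates],
                "ef_score_percent": [a.patient_ef_score for a in aggregates],
            }
        )
        patients.to_csv(out / "patients.csv", index=False)
        report["patients"] = [
            {
                "patient_id": a.patient_id,
                "patient_ef_score": a.patient_ef_score,
                "lobe_scores": a.lobe_scores,
                "n_images": len(a.images),
            }
            for a in aggregates
        ]
        report["lobe_comparison"] = _lobe_paired_comparison(aggregates)
    else:
        logger.info("no image manifest configured; image stage skipped")

    if config.cohort_csv is not None:
        cohort = pd.read_csv(config.cohort_csv)
        report["group_comparisons"] = _group_comparisons(cohort, config.group_column)

    if config.ratings_csv is not None:
        ratings = pd.read_csv(config.ratings_csv)
        report["kappa"] = _kappa_table(ratings, config.kappa_weighting)

    if config.survival_csv is not None:
        survival = pd.read_csv(config.survival_csv)
        report["survival"] = _survival_section(survival, config.group_column)

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "report.md").write_text(_render_markdown(report))
    logger.info("report bundle written to %s (config %s)", out, report["meta"]["config_hash"])
    return report
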