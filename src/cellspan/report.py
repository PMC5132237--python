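"""End-to-end analysis pipeline and machine-readable report.

``run_full_analysis`` executes the whole chain — validation, spline
fitting, SEP detection, per-age correlation screens, the early-life
median split with Kaplan-Meier / log-rank comparison, time-to-age
rank-sum, and (when a reporter channel is present) the fluorescence
analyses — and returns a JSON-serializable report in which every number
names the operation that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lifehistory import LifeHistoryDataset, dataset_summary
from .stats import (
    concentration_size_relation,
    conditional_age_correlation,
    feature_concentration,
    feature_fold_increase,
    km_estimate,
    logrank_test,
    median_split_at_age,
    pearson_r,
    per_age_lifespan_correlation,
    percent_median_difference,
    ranksum_test,
    sep_ages_for,
    total_fluorescence,
)
from .trajectories import fit_cell, sep_for_cell, time_to_age

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    """Pipeline settings; defaults reproduce the standard analysis."""

    spar: float = 0.5
    split_age: int = 5
    min_n: int = 10
    sep_epsilon: float = 0.02
    conditional_min_rls: tuple[int, ...] = (8, 12, 16, 18)
    representative_ages: tuple[int, ...] = (7, 13)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["conditional_min_rls"] = list(self.conditional_min_rls)
        d["representative_ages"] = list(self.representative_ages)
        return d


def _corr_records(series) -> list[dict]:
    return [
        {"age": int(a), "n": int(n), "r": float(r)}
        for a, n, r in zip(series.ages, series.n, series.r)
    ]


def _dataset_hash(dataset: LifeHistoryDataset) -> str:
    h = hashlib.sha256()
    for c in dataset.cells:
        h.update(c.cell_id.encode())
        h.update(np.ascontiguousarray(c.sizes).tobytes())
        h.update(np.ascontiguousarray(c.times).tobytes())
        if c.avg_fluor is not None:
            h.update(np.ascontiguousarray(c.avg_fluor).tobytes())
    return h.hexdigest()[:16]


def run_full_analysis(
    dataset: LifeHistoryDataset, config: AnalysisConfig | None = None
) -> dict:
    """Run the complete lifespan analysis on one dataset.

    Stages: summary -> raw start/end-size correlations -> spline fit +
    fold-increase -> SEP detection and SEP-size correlation -> per-age
    correlation screen (all data and pre-SEP only) -> median split at the
    configured age with KM/log-rank and time-to-age rank-sum ->
    fluorescence analyses when the channel is present.
    """
    cfg = config or AnalysisConfig()
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": cfg.to_dict(),
        "provenance": {
            "dataset_name": dataset.name,
            "dataset_source": dataset.source,
            "dataset_hash": _dataset_hash(dataset),
        },
        "warnings": [],
    }

    # --- cohort summary (operation: dataset_summary)
    report["summary"] = dataset_summary(dataset)

    rls = dataset.lifespans().astype(float)

    # --- raw-size correlations, computed before any smoothing
    starts = np.array([c.sizes[0] for c in dataset.cells])
    ends = np.array([c.sizes[-1] for c in dataset.cells])
    report["size_correlations"] = {
        "source": "pearson_r on raw sizes",
        "start_size_vs_rls": pearson_r(starts, rls),
        "end_size_vs_rls": pearson_r(ends, rls),
    }

    # --- trajectories and SEP
    fold = feature_fold_increase(dataset, spar=cfg.spar)
    seps = {c.cell_id: sep_for_cell(c, epsilon=cfg.sep_epsilon) for c in dataset.cells}
    sep_ages = {cid: s.sep_age for cid, s in seps.items()}
    with_sep = [c for c in dataset.cells if sep_ages[c.cell_id] is not None]
    report["sep"] = {
        "source": "detect_sep on raw division durations",
        "n_with_sep": len(with_sep),
        "n_without_sep": len(dataset) - len(with_sep),
    }
    if len(with_sep) >= 3:
        sep_sizes = [
            fit_cell(c, spar=cfg.spar).values[sep_ages[c.cell_id] - 1] for c in with_sep
        ]
        sep_age_vals = [sep_ages[c.cell_id] for c in with_sep]
        report["sep"]["sep_size_vs_sep_age_r"] = pearson_r(sep_sizes, sep_age_vals)
        report["sep"]["median_sep_age"] = float(np.median(sep_age_vals))

    # --- per-age correlation screen: fold increase vs lifespan
    corr_all = per_age_lifespan_correlation(
        dataset, fold, min_n=cfg.min_n, feature_name="fold_increase"
    )
    corr_pre = per_age_lifespan_correlation(
        dataset, fold, min_n=cfg.min_n, exclude_post_sep=True,
        sep_ages=sep_ages, feature_name="fold_increase|pre-SEP",
    )
    report["fold_increase_correlations"] = {
        "source": "per_age_lifespan_correlation on fold_increase",
        "all_data": _corr_records(corr_all),
        "pre_sep_only": _corr_records(corr_pre),
    }

    # --- median split at the configured age, survival comparison
    split_age = cfg.split_age
    split = median_split_at_age(dataset, split_age, fold)
    below = [dataset[cid] for cid in split.below_ids]
    above = [dataset[cid] for cid in split.above_ids]
    km_below = km_estimate([c.rls for c in below], [c.death_observed for c in below])
    km_above = km_estimate([c.rls for c in above], [c.death_observed for c in above])
    lr = logrank_test(
        [c.rls for c in below], [c.rls for c in above],
        [c.death_observed for c in below], [c.death_observed for c in above],
    )
    median_fold = split.threshold
    report["median_split"] = {
        "source": "median_split_at_age + km_estimate + logrank_test",
        "split_age": split_age,
        "feature": "fold_increase",
        "threshold_fold": median_fold,
        "n_below": len(below),
        "n_above": len(above),
        "km_median_below": km_below.median,
        "km_median_above": km_above.median,
        "logrank_statistic": lr.statistic,
        "logrank_p": lr.p_value,
        "percent_median_difference": percent_median_difference(
            km_below.median, km_above.median
        ),
    }

    # --- time to reach the split age, compared between the two groups
    tta_below = [time_to_age(c, split_age) for c in below]
    tta_above = [time_to_age(c, split_age) for c in above]
    rs = ranksum_test(tta_below, tta_above)
    report["time_to_age"] = {
        "source": "time_to_age + ranksum_test",
        "age": split_age,
        "median_hours_below": float(np.median(tta_below)),
        "median_hours_above": float(np.median(tta_above)),
        "statistic": rs.statistic,
        "p": rs.p_value,
        "method": rs.method,
    }

    # --- fluorescence analyses
    if dataset.has_fluor:
        conc = feature_concentration(dataset, spar=cfg.spar)
        # population fold of total amount and of concentration, per age
        max_age = int(rls.max())
        tot_folds, conc_folds, ages_out = [], [], []
        fitted_sizes = {c.cell_id: fit_cell(c, spar=cfg.spar).values for c in dataset.cells}
        for a in range(1, max_age + 1):
            tf, cf = [], []
            for c in dataset.cells:
                if c.rls < a:
                    continue
                tot = total_fluorescence(conc[c.cell_id], fitted_sizes[c.cell_id])
                tf.append(tot[a - 1] / tot[0])
                cf.append(conc[c.cell_id][a - 1] / conc[c.cell_id][0])
            if len(tf) >= cfg.min_n:
                ages_out.append(a)
                tot_folds.append(float(np.median(tf)))
                conc_folds.append(float(np.median(cf)))
        report["fluorescence"] = {
            "source": "total_fluorescence + feature_concentration",
            "ages": ages_out,
            "median_total_fold": tot_folds,
            "median_concentration_fold": conc_folds,
        }

        corr_conc = per_age_lifespan_correlation(
            dataset, conc, min_n=cfg.min_n, feature_name="concentration"
        )
        report["concentration_correlations"] = {
            "source": "per_age_lifespan_correlation on concentration",
            "all_data": _corr_records(corr_conc),
        }

        relations = {}
        for a in cfg.representative_ages:
            try:
                r, slope, n = concentration_size_relation(
                    dataset, a, spar=cfg.spar, min_n=cfg.min_n
                )
                relations[str(a)] = {"r": r, "slope": slope, "n": n}
            except ValueError as err:
                report["warnings"].append(f"concentration_size_relation age {a}: {err}")
        report["concentration_size"] = {
            "source": "concentration_size_relation",
            "by_age": relations,
        }

        conditional = {}
        for m in cfg.conditional_min_rls:
            try:
                series = conditional_age_correlation(
                    dataset, conc, m, min_n=cfg.min_n, feature_name=f"concentration|rls>={m}"
                )
                conditional[str(m)] = _corr_records(series)
            except ValueError as err:
                report["warnings"].append(f"conditional_age_correlation min_rls {m}: {err}")
        report["conditional_concentration_correlations"] = {
            "source": "conditional_age_correlation on concentration",
            "by_min_rls": conditional,
        }
    else:
        report["warnings"].append("no fluorescence channel: reporter analyses skipped")

    return report


def write_report(report: dict, out_dir) -> dict[str, Path]:
    """Write report.json plus flat CSV tables (correlations, survival, SEP)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"report": out / "report.json"}
    paths["report"].write_text(json.dumps(report, indent=1, sort_keys=True))

    rows = []
    for key, block in (
        ("fold_increase_all", report.get("fold_increase_correlations", {}).get("all_data")),
        ("fold_increase_pre_sep", report.get("fold_increase_correlations", {}).get("pre_sep_only")),
        ("concentration", report.get("concentration_correlations", {}).get("all_data")),
    ):
        for rec in block or []:
            rows.append({"series": key, **rec})
    if rows:
        p = out / "corr_by_age.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths["correlations"] = p
    return paths
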