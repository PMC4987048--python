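"""End-to-end study analysis and machine-readable reports.

``run_analysis`` drives the full agreement analysis for a study: filter
cases to those annotated by all required observers, then for every
observer pair compute pooled and per-case Dice (with case-bootstrap
CIs), score confusion matrices with quadratic-weighted kappa, and
Bland-Altman statistics on log-transformed counts; optionally a size
comparison of poor- vs good-agreement consensus objects when length
measurements are supplied.  ``emit_report`` writes the result as
delimited-text tables plus one structured summary file, with provenance
(config, seed, version) embedded so every number is recomputable.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotations import StudyDataset, filter_cases, read_annotations
from .counts import (
    bland_altman_log,
    confusion,
    mitotic_score,
    normalized_count,
    quadratic_weighted_kappa,
    two_point_discrepancies,
)
from .dice import BootstrapSpec, bootstrap_ci, case_match_triples, dice_from_counts
from .matching import DEFAULT_TOLERANCE_PX, build_consensus
from .sizes import assign_agreement_groups, compare_sizes

logger = logging.getLogger("mitoagree")

__all__ = ["AnalysisConfig", "StudyReport", "run_analysis", "emit_report"]


@dataclass
class AnalysisConfig:
    """Settings for a full-study analysis run."""

    annotations: str | Path | StudyDataset
    metadata: str | Path | None = None
    observers: Sequence[str] = ()
    automatic: str | None = None
    tolerance_px: float = DEFAULT_TOLERANCE_PX
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    min_mean_count: float | None = None
    sizes: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.tolerance_px <= 0:
            raise ValueError("tolerance_px must be > 0")

    def all_observers(self) -> list[str]:
        ids = list(self.observers)
        if self.automatic and self.automatic not in ids:
            ids.append(self.automatic)
        return ids


@dataclass
class StudyReport:
    """All study-level agreement tables, as tidy DataFrames."""

    dice_table: pd.DataFrame
    per_case_dice_table: pd.DataFrame
    confusion_tables: dict[tuple[str, str], pd.DataFrame]
    kappa_table: pd.DataFrame
    bland_altman_table: pd.DataFrame
    size_comparison: pd.DataFrame | None
    provenance: dict

    @property
    def n_cases(self) -> int:
        return int(self.provenance["n_cases"])


def _load_dataset(config: AnalysisConfig) -> StudyDataset:
    if isinstance(config.annotations, StudyDataset):
        return config.annotations
    return read_annotations(config.annotations, metadata=config.metadata)


def run_analysis(config: AnalysisConfig) -> StudyReport:
    """Run the complete agreement analysis for one study."""
    dataset = _load_dataset(config)
    observers = list(config.observers) or [
        o for o in dataset.observers if o != config.automatic
    ]
    all_ids = list(observers)
    if config.automatic:
        all_ids.append(config.automatic)
    if len(all_ids) < 2:
        raise ValueError("analysis requires at least 2 observers")

    dataset = filter_cases(dataset, all_ids, min_mean_count=config.min_mean_count)
    case_ids = dataset.case_ids()
    logger.info("analysis over %d cases, observers %s", len(case_ids), all_ids)

    tol = config.tolerance_px
    boot = config.bootstrap
    pairs = list(itertools.combinations(all_ids, 2))

    dice_rows, per_case_rows, kappa_rows, ba_rows = [], [], [], []
    confusion_tables: dict[tuple[str, str], pd.DataFrame] = {}

    scores = {}
    counts = {}
    for obs in all_ids:
        per_case = []
        for cid in case_ids:
            ann = dataset.get(cid, obs)
            per_case.append(
                (cid, ann.count, normalized_count(ann.count, ann.region_area_mm2))
            )
        counts[obs] = {cid: c for cid, c, _ in per_case}
        scores[obs] = {cid: mitotic_score(nc) for cid, _, nc in per_case}

    for obs_a, obs_b in pairs:
        triples = case_match_triples(dataset, obs_a, obs_b, tol)
        count_triples = [(na, nb, ns) for _, na, nb, ns in triples]
        n_a = sum(t[0] for t in count_triples)
        n_b = sum(t[1] for t in count_triples)
        n_shared = sum(t[2] for t in count_triples)
        pooled = dice_from_counts(n_a, n_b, n_shared)
        pooled_ci = bootstrap_ci(count_triples, "pooled_dice", boot)
        case_values = [dice_from_counts(*t) for t in count_triples]
        median_ci = bootstrap_ci(count_triples, "median_case_dice", boot)
        dice_rows.append(
            {
                "observer_a": obs_a,
                "observer_b": obs_b,
                "count_a": n_a,
                "count_b": n_b,
                "n_shared": n_shared,
                "dice": pooled,
                "dice_ci_low": pooled_ci[0],
                "dice_ci_high": pooled_ci[1],
                "median_case_dice": float(pd.Series(case_values).median()),
                "median_ci_low": median_ci[0],
                "median_ci_high": median_ci[1],
            }
        )
        for (cid, na, nb, ns), d in zip(triples, case_values):
            per_case_rows.append(
                {
                    "case_id": cid,
                    "observer_a": obs_a,
                    "observer_b": obs_b,
                    "count_a": na,
                    "count_b": nb,
                    "n_shared": ns,
                    "dice": d,
                }
            )

        sa = [scores[obs_a][cid] for cid in case_ids]
        sb = [scores[obs_b][cid] for cid in case_ids]
        conf = confusion(sa, sb, row_observer=obs_a, col_observer=obs_b)
        confusion_tables[(obs_a, obs_b)] = pd.DataFrame(
            conf.matrix,
            index=[f"{obs_a}_score{i}" for i in (1, 2, 3)],
            columns=[f"{obs_b}_score{i}" for i in (1, 2, 3)],
        )
        kr = quadratic_weighted_kappa(conf, ci_spec=boot)
        kappa_rows.append(
            {
                "observer_a": obs_a,
                "observer_b": obs_b,
                "kappa": kr.kappa,
                "kappa_ci_low": kr.ci[0] if kr.ci else float("nan"),
                "kappa_ci_high": kr.ci[1] if kr.ci else float("nan"),
                "undefined": kr.undefined,
                "two_point_discrepancies": two_point_discrepancies(conf),
                "n_cases": conf.total,
            }
        )

        ca = [counts[obs_a][cid] for cid in case_ids]
        cb = [counts[obs_b][cid] for cid in case_ids]
        ba = bland_altman_log(ca, cb)
        ba_rows.append(
            {
                "observer_a": obs_a,
                "observer_b": obs_b,
                "mean_difference": ba.mean_difference,
                "la_low": ba.la_low,
                "la_high": ba.la_high,
                "n": ba.n,
                "transform": ba.transform,
            }
        )

    size_comparison = None
    if config.sizes is not None:
        human_sets = {
            obs: {
                cid: dataset.get(cid, obs).coords() for cid in case_ids
            }
            for obs in all_ids
        }
        auto_ids = {config.automatic} if config.automatic else set()
        poor_all, good_all = [], []
        offset = 0
        for cid in case_ids:
            per_case_ann = {obs: human_sets[obs][cid] for obs in all_ids}
            objs = build_consensus(per_case_ann, tol)
            # global ids: sizes mapping is keyed by (running) object index
            sized = {
                obj.object_id + offset: config.sizes.get(obj.object_id + offset)
                for obj in objs
            }
            remapped = [
                type(obj)(
                    object_id=obj.object_id + offset,
                    member_points=obj.member_points,
                    centroid=obj.centroid,
                )
                for obj in objs
            ]
            offset += len(objs)
            known = {k: v for k, v in sized.items() if v is not None}
            usable = [o for o in remapped if o.object_id in known]
            p, g = assign_agreement_groups(
                usable, known, len(observers), automatic_ids=auto_ids
            )
            poor_all.extend(p)
            good_all.extend(g)
        if len(poor_all) >= 2 and len(good_all) >= 2:
            sc = compare_sizes(poor_all, good_all)
            size_comparison = pd.DataFrame(
                [
                    {
                        "mean_poor_um": sc.mean_poor,
                        "mean_good_um": sc.mean_good,
                        "t_statistic": sc.t_statistic,
                        "p_value": sc.p_value,
                        "n_poor": sc.n_poor,
                        "n_good": sc.n_good,
                    }
                ]
            )

    from . import __version__

    provenance = {
        "version": __version__,
        "tolerance_px": tol,
        "bootstrap_n": boot.n_boot,
        "bootstrap_level": boot.level,
        "seed": boot.seed,
        "observers": observers,
        "automatic": config.automatic,
        "min_mean_count": config.min_mean_count,
        "n_cases": len(case_ids),
    }
    return StudyReport(
        dice_table=pd.DataFrame(dice_rows),
        per_case_dice_table=pd.DataFrame(per_case_rows),
        confusion_tables=confusion_tables,
        kappa_table=pd.DataFrame(kappa_rows),
        bland_altman_table=pd.DataFrame(ba_rows),
        size_comparison=size_comparison,
        provenance=provenance,
    )


def emit_report(report: StudyReport, outdir: str | Path) -> list[Path]:
    """Write the report tables as CSVs plus a JSON summary; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    tables = {
        "dice.csv": report.dice_table,
        "per_case_dice.csv": report.per_case_dice_table,
        "kappa.csv": report.kappa_table,
        "bland_altman.csv": report.bland_altman_table,
    }
    if report.size_comparison is not None:
        tables["size_comparison.csv"] = report.size_comparison
    for name, df in tables.items():
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)
    for (obs_a, obs_b), df in report.confusion_tables.items():
        path = outdir / f"confusion_{obs_a}_vs_{obs_b}.csv"
        df.to_csv(path)
        written.append(path)

    summary = {
        "provenance": report.provenance,
        "dice": report.dice_table.to_dict(orient="records"),
        "kappa": report.kappa_table.to_dict(orient="records"),
        "bland_altman": report.bland_altman_table.to_dict(orient="records"),
    }
    if report.size_comparison is not None:
        summary["size_comparison"] = report.size_comparison.to_dict(orient="records")
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(summary_path)
    logger.info("wrote %d report files to %s", len(written), outdir)
    return written
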