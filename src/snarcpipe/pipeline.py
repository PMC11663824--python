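"""End-to-end orchestration: simulate/load -> filter -> slopes -> inference
-> bootstrap prevalence -> questionnaire analyses, with CSV/JSON reports.

Every number in the report bundle is produced by one of the stage operations;
this layer only arranges inputs and writes tables. All randomness derives
from ``master_seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from snarcpipe import io
from snarcpipe._rng import derive_seed
from snarcpipe.bootstrap import chi_square_independence, h0_bootstrap, prevalence_table
from snarcpipe.cdpq import item_contingency, records_from_frame, score_slope_correlation, total_score_trend
from snarcpipe.inference import (
    jonckheere_terpstra,
    one_sample_t,
    paired_t,
    pearson_cor,
    welch_t,
)
from snarcpipe.preprocess import exclude_participants, filter_trials
from snarcpipe.simulate import GroupConfig, TASKS, simulate_study
from snarcpipe.slopes import estimate_participant

logger = logging.getLogger("snarcpipe")

_CONFIG_DEFAULTS = dict(
    n_boot=5000,
    n_perm=2000,
    alpha=0.05,
    rscale=0.707,
    cor_width=1.0 / 3.0,
    sd_multiplier=3.0,
    rt_window=(200.0, 1500.0),
    retention_threshold=0.75,
    bootstrap_set_size=20,
)


@dataclass
class RunConfig:
    master_seed: int
    out_dir: str
    groups: list[GroupConfig] = field(default_factory=list)
    trials_path: str | None = None
    cdpq_path: str | None = None
    group_order: list[str] | None = None  # hypothesized increasing slope order
    n_boot: int = 5000
    n_perm: int = 2000
    alpha: float = 0.05
    rscale: float = 0.707
    cor_width: float = 1.0 / 3.0
    sd_multiplier: float = 3.0
    rt_window: tuple[float, float] = (200.0, 1500.0)
    retention_threshold: float = 0.75
    bootstrap_set_size: int = 20

    def __post_init__(self) -> None:
        self.rt_window = tuple(float(v) for v in self.rt_window)
        self.validate()

    def validate(self) -> None:
        if not self.groups and self.trials_path is None:
            raise ValueError("groups/trials_path: provide simulation configs or an input file")
        for c in self.groups:
            c.validate()
        if self.n_boot < 1:
            raise ValueError("n_boot: must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm: must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha: must lie in (0, 1)")
        if self.rscale <= 0:
            raise ValueError("rscale: must be positive")
        if self.cor_width <= 0:
            raise ValueError("cor_width: must be positive")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier: must be positive")
        lo, hi = self.rt_window
        if not lo < hi:
            raise ValueError("rt_window: lower bound must be below upper bound")
        if not 0.0 <= self.retention_threshold <= 1.0:
            raise ValueError("retention_threshold: must lie in [0, 1]")
        if self.bootstrap_set_size < 1:
            raise ValueError("bootstrap_set_size: must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        groups = [
            g if isinstance(g, GroupConfig) else GroupConfig(**g)
            for g in data.pop("groups", [])
        ]
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(groups=groups, **data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


def _result_row(res, **labels) -> dict:
    row = dict(labels)
    row.update(
        statistic=res.statistic,
        df=res.df,
        p_value=res.p_value,
        sidedness=res.sidedness,
        bf10=res.bf10,
        n=str(res.n),
    )
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the report bundle to ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"master_seed": config.master_seed}

    # ---- stage 1: data ----------------------------------------------------
    if config.trials_path is not None:
        trials = io.read_trials(config.trials_path)
        cdpq = io.read_cdpq(config.cdpq_path) if config.cdpq_path else None
        logger.info("loaded %d trials from %s", len(trials), config.trials_path)
    else:
        trials, cdpq = simulate_study(config.groups, config.master_seed)
        io.write_trials(trials, out / "trials.csv")
        io.write_cdpq(cdpq, out / "cdpq.csv")
        logger.info("simulated %d trials for %d groups", len(trials), len(config.groups))

    group_of = dict(
        trials[["participant_id", "group"]].drop_duplicates().itertuples(index=False)
    )
    group_order = config.group_order or [c.group_label for c in config.groups] or sorted(
        set(group_of.values())
    )

    # ---- stage 2: filtering and exclusion ---------------------------------
    reports = {}
    retained_parts = []
    report_rows = []
    for (pid, task), sub in trials.groupby(["participant_id", "task"], sort=True):
        kept, rep = filter_trials(
            sub, rt_window=config.rt_window, sd_multiplier=config.sd_multiplier
        )
        reports[(pid, task)] = rep
        retained_parts.append(kept)
        report_rows.append(
            dict(participant_id=pid, task=task, **rep.__dict__)
        )
    retained = pd.concat(retained_parts, ignore_index=True)
    pd.DataFrame(report_rows).to_csv(out / "filter_reports.csv", index=False)
    logger.info(
        "filtering retained %d of %d trials", len(retained), len(trials)
    )

    decisions = exclude_participants(
        retained, reports, retention_threshold=config.retention_threshold
    )
    pd.DataFrame([d.__dict__ for d in decisions]).to_csv(
        out / "exclusions.csv", index=False
    )
    kept_ids = {d.participant_id for d in decisions if not d.excluded}
    summary["n_participants_retained"] = len(kept_ids)
    summary["n_participants_excluded"] = len(decisions) - len(kept_ids)
    logger.info("%d participants retained, %d excluded",
                len(kept_ids), len(decisions) - len(kept_ids))
    analysis = retained[retained["participant_id"].isin(kept_ids)]

    # ---- stage 3: slopes --------------------------------------------------
    slope_rows = []
    estimates: dict[str, dict] = {}
    for pid in sorted(kept_ids):
        sub = analysis[analysis["participant_id"] == pid]
        est = estimate_participant(
            sub[sub["task"] == "PJ"], sub[sub["task"] == "MC"]
        )
        estimates[pid] = est
        for model, e in est.items():
            slope_rows.append(
                dict(
                    participant_id=pid,
                    group=group_of[pid],
                    task=e.task,
                    model=model,
                    b_mag=e.b_mag,
                    b_par=e.b_par,
                    z_mag=e.z_mag,
                    z_par=e.z_par,
                    intercept=e.intercept,
                )
            )
    slopes_df = pd.DataFrame(slope_rows)
    slopes_df.to_csv(out / "slopes.csv", index=False)

    def series(model: str, column: str) -> pd.DataFrame:
        sub = slopes_df[slopes_df["model"] == model][["participant_id", "group", column]]
        return sub.rename(columns={column: "value"})

    measures = [
        ("SNARC_PJ", series("pj_linear", "b_mag")),
        ("standardized_SNARC_PJ", series("pj_linear", "z_mag")),
        ("MARC_PJ", series("pj_linear", "b_par")),
        ("standardized_MARC_PJ", series("pj_linear", "z_par")),
        ("SNARC_MC", series("mc_categorical", "b_mag")),
        ("standardized_SNARC_MC", series("mc_categorical", "z_mag")),
        ("SNARC_MC_continuous", series("mc_continuous", "b_mag")),
    ]

    # ---- stage 4: group inference ----------------------------------------
    test_rows = []
    for measure, data in measures:
        for g in group_order:
            vals = data.loc[data["group"] == g, "value"].to_numpy()
            if len(vals) < 2:
                continue
            res = one_sample_t(vals, rscale=config.rscale)
            row = _result_row(res, measure=measure, group=g)
            row.update(mean=float(np.mean(vals)), sd=float(np.std(vals, ddof=1)))
            test_rows.append(row)
    pd.DataFrame(test_rows).to_csv(out / "group_tests.csv", index=False)

    welch_rows = []
    for measure in ("SNARC_PJ", "SNARC_MC"):
        data = dict(measures)[measure]
        for g1, g2 in zip(group_order[:-1], group_order[1:]):
            a = data.loc[data["group"] == g1, "value"].to_numpy()
            b = data.loc[data["group"] == g2, "value"].to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            res = welch_t(a, b, sidedness="less", rscale=config.rscale)
            welch_rows.append(_result_row(res, measure=measure, pair=f"{g1}-{g2}"))
    pd.DataFrame(welch_rows).to_csv(out / "welch_tests.csv", index=False)

    trend_rows = []
    for measure in ("SNARC_PJ", "SNARC_MC"):
        data = dict(measures)[measure]
        groups_vals = [
            data.loc[data["group"] == g, "value"].to_numpy() for g in group_order
        ]
        if len(groups_vals) >= 3 and all(len(v) >= 1 for v in groups_vals):
            res = jonckheere_terpstra(
                groups_vals,
                n_perm=config.n_perm,
                seed=derive_seed(config.master_seed, "jt", measure),
            )
            trend_rows.append(
                dict(measure=measure, t_jt=res.t_jt, p_value=res.p_value,
                     n_permutations=res.n_permutations)
            )

    # paired PJ vs MC (continuous) and cross-task correlation, per group
    paired_rows = []
    cor_rows = []
    pj = series("pj_linear", "b_mag").set_index("participant_id")
    mc_cont = series("mc_continuous", "b_mag").set_index("participant_id")
    mc_cat = series("mc_categorical", "b_mag").set_index("participant_id")
    for g in group_order:
        ids = sorted(set(pj.index[pj["group"] == g]) & set(mc_cont.index))
        if len(ids) >= 3:
            a = pj.loc[ids, "value"].to_numpy()
            b = mc_cont.loc[ids, "value"].to_numpy()
            res = paired_t(a, b, rscale=config.rscale)
            paired_rows.append(_result_row(res, measure="PJ_vs_MC_continuous", group=g))
            b_cat = mc_cat.loc[ids, "value"].to_numpy()
            try:
                res = pearson_cor(a, b_cat, width=config.cor_width)
                cor_rows.append(_result_row(res, measure="PJ_vs_MC_slope_correlation", group=g))
            except ValueError:
                pass
    pd.DataFrame(paired_rows).to_csv(out / "paired_tests.csv", index=False)

    # ---- stage 5: bootstrap prevalence ------------------------------------
    class_rows = []
    classifications = {"PJ_SNARC": [], "PJ_MARC": [], "MC_SNARC": []}
    for pid in sorted(kept_ids):
        for task in TASKS:
            sub = analysis[
                (analysis["participant_id"] == pid) & (analysis["task"] == task)
            ]
            results = h0_bootstrap(
                sub,
                n_iter=config.n_boot,
                set_size=config.bootstrap_set_size,
                seed=derive_seed(config.master_seed, "boot", pid, task),
            )
            for c in results:
                classifications[f"{task}_{c.effect}"].append(c)
                class_rows.append(dict(group=group_of[pid], **c.__dict__))
    pd.DataFrame(class_rows).to_csv(out / "bootstrap_classifications.csv", index=False)

    contingency_rows = []
    for key, cls_list in classifications.items():
        table = prevalence_table(cls_list, group_of, group_order)
        merged = table.counts.copy()
        for col in table.counts.columns:
            merged[f"{col}_pct"] = table.percentages[col].round(2)
        merged.to_csv(out / f"prevalence_{key.lower()}.csv")
        counts = table.counts.to_numpy()
        counts = counts[:, counts.sum(axis=0) > 0]  # a label nobody got is uninformative
        if counts.shape[1] >= 2:
            res = chi_square_independence(counts)
            contingency_rows.append(_result_row(res, prevalence=key))
            summary[f"prevalence_{key}_chi2"] = res.statistic
            summary[f"prevalence_{key}_p"] = res.p_value
    pd.DataFrame(contingency_rows).to_csv(out / "prevalence_tests.csv", index=False)

    # ---- stage 6: questionnaire -------------------------------------------
    if cdpq is not None and len(cdpq):
        records = [
            r for r in records_from_frame(cdpq) if r.participant_id in kept_ids
        ]
        pd.DataFrame(
            [
                dict(participant_id=r.participant_id, group=r.group_label,
                     sum_score=r.sum_score)
                for r in records
            ]
        ).to_csv(out / "cdpq_scores.csv", index=False)

        item_rows = []
        for item in range(1, 8):
            result = item_contingency(
                records, item, group_order,
                seed=derive_seed(config.master_seed, "cdpq_item", item),
            )
            omni = result["omnibus"]
            item_rows.append(_result_row(omni, item=item, test=omni.test_kind))
            for ph in result["posthoc"]:
                item_rows.append(
                    dict(item=item, test=f"posthoc_{ph['pair'][0]}-{ph['pair'][1]}",
                         statistic=ph["result"].statistic, df=ph["result"].df,
                         p_value=ph["p_bonferroni"], sidedness="two",
                         bf10=None, n=str(ph["result"].n))
                )
        pd.DataFrame(item_rows).to_csv(out / "cdpq_item_tests.csv", index=False)

        if len(group_order) >= 3:
            res = total_score_trend(
                records, group_order, n_perm=config.n_perm,
                seed=derive_seed(config.master_seed, "jt", "cdpq"),
            )
            trend_rows.append(
                dict(measure="CDPQ_total", t_jt=res.t_jt, p_value=res.p_value,
                     n_permutations=res.n_permutations)
            )
            summary["cdpq_trend_p"] = res.p_value

        slope_map = {
            "PJ": dict(zip(pj.index, pj["value"])),
            "MC": dict(zip(mc_cat.index, mc_cat["value"])),
        }
        for task, smap in slope_map.items():
            for g in group_order:
                try:
                    res = score_slope_correlation(records, smap, group=g)
                except ValueError:
                    continue
                cor_rows.append(
                    _result_row(res, measure=f"CDPQ_vs_{task}_slope", group=g)
                )

    pd.DataFrame(trend_rows).to_csv(out / "trend_tests.csv", index=False)
    pd.DataFrame(cor_rows).to_csv(out / "correlations.csv", index=False)

    for row in trend_rows:
        summary[f"trend_{row['measure']}_p"] = row["p_value"]
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    logger.info("report bundle written to %s", out)
    return summary
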