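"""Scoring and group analyses of the 7-item directional-preference questionnaire.

Each item response is coded LR = -1, NONE = 0 (mixed order / no preference),
RL = +1; the sum score spans -7 (strong left-to-right preference) to +7
(strong right-to-left preference). Items 1-2 record an ordering of several
elements: the ordering reduces to LR/RL only when it is strictly monotone in
that direction, anything else counts as NONE.

Group comparisons: per item a group x {LR, NONE, RL} contingency test
(Pearson chi-square, switching to Fisher's exact test whenever any expected
cell frequency is below 5), with Bonferroni-corrected pairwise post-hoc
tests; the total score is compared across ordered groups with the
permutation Jonckheere-Terpstra trend test and correlated with individual
slopes per group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from snarcpipe.bootstrap import chi_square_independence, fisher_exact_rxc
from snarcpipe.inference import (
    TestResult,
    TrendTestResult,
    jonckheere_terpstra,
    pearson_cor,
)

N_ITEMS = 7
ITEM_CODES = ("LR", "NONE", "RL")
SCORES = {"LR": -1, "NONE": 0, "RL": 1}

#: raw tokens accepted per item, normalized to the three canonical codes
_ALIASES = {
    "LR": "LR",
    "RL": "RL",
    "NONE": "NONE",
    "NP": "NONE",
    "MIXED": "NONE",
    "NO_PREFERENCE": "NONE",
}

EXPECTED_CELL_THRESHOLD = 5.0


@dataclass
class CdpqRecord:
    participant_id: str
    group_label: str
    item_codes: tuple
    sum_score: int

    def __post_init__(self) -> None:
        if len(self.item_codes) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} item codes")
        if any(c not in ITEM_CODES for c in self.item_codes):
            raise ValueError(f"item codes must be in {ITEM_CODES}")
        if self.sum_score != sum(SCORES[c] for c in self.item_codes):
            raise ValueError("sum_score inconsistent with item codes")


def normalize_token(token: str) -> str:
    key = str(token).strip().upper().replace(" ", "_")
    if key not in _ALIASES:
        raise ValueError(f"unknown response token: {token!r}")
    return _ALIASES[key]


def reduce_ordering(observed: Sequence, canonical_lr: Sequence) -> str:
    """Reduce an element ordering to LR / RL / NONE.

    ``canonical_lr`` is the left-to-right spatial order of the elements;
    ``observed`` is the order in which the participant listed them. Only a
    strictly monotone match (identical or fully reversed) counts as a
    directional response.
    """
    obs = list(observed)
    ref = list(canonical_lr)
    if sorted(map(str, obs)) != sorted(map(str, ref)):
        raise ValueError("observed ordering does not match the canonical element set")
    if obs == ref:
        return "LR"
    if obs == ref[::-1]:
        return "RL"
    return "NONE"


def score_record(
    participant_id: str, group_label: str, responses: Sequence[str]
) -> CdpqRecord:
    """Score 7 raw item responses into a questionnaire record."""
    if len(responses) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} responses, got {len(responses)}")
    codes = tuple(normalize_token(r) for r in responses)
    return CdpqRecord(
        participant_id=participant_id,
        group_label=group_label,
        item_codes=codes,
        sum_score=sum(SCORES[c] for c in codes),
    )


def records_from_frame(cdpq: pd.DataFrame) -> list[CdpqRecord]:
    item_cols = [f"item{i}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in item_cols + ["participant_id", "group"] if c not in cdpq.columns]
    if missing:
        raise ValueError(f"questionnaire table is missing columns: {missing}")
    return [
        score_record(row["participant_id"], row["group"], [row[c] for c in item_cols])
        for _, row in cdpq.iterrows()
    ]


def _item_table(
    records: Sequence[CdpqRecord], item_index: int, group_order: Sequence[str]
) -> pd.DataFrame:
    rows = [(r.group_label, r.item_codes[item_index - 1]) for r in records]
    df = pd.DataFrame(rows, columns=["group", "code"])
    table = (
        df.groupby(["group", "code"]).size().unstack(fill_value=0)
        .reindex(index=list(group_order), columns=list(ITEM_CODES), fill_value=0)
    )
    return table.fillna(0).astype(int)


def _contingency_auto(
    table: pd.DataFrame, n_mc: int = 100_000, seed: int | None = None
) -> TestResult:
    """Chi-square, or Fisher's exact when any expected cell frequency < 5.

    Columns with zero total are dropped first (a response never given by any
    group carries no information and would make expected counts degenerate).
    """
    obs = np.asarray(table, dtype=float)
    obs = obs[:, obs.sum(axis=0) > 0]
    obs = obs[obs.sum(axis=1) > 0, :]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table collapsed below 2x2")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if expected.min() < EXPECTED_CELL_THRESHOLD:
        return fisher_exact_rxc(obs, n_mc=n_mc, seed=seed)
    return chi_square_independence(obs)


def item_contingency(
    records: Sequence[CdpqRecord],
    item_index: int,
    group_order: Sequence[str] | None = None,
    posthoc: bool = True,
    seed: int | None = None,
) -> dict:
    """Group x directionality test for one item, with pairwise post-hocs.

    Returns a dict with the omnibus ``TestResult``, the counts table, and a
    list of Bonferroni-corrected pairwise group comparisons.
    """
    if not 1 <= item_index <= N_ITEMS:
        raise ValueError(f"item_index must be 1..{N_ITEMS}")
    groups = group_order or sorted({r.group_label for r in records})
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    table = _item_table(records, item_index, groups)
    if table.to_numpy().sum() == 0:
        raise ValueError(f"item {item_index} has no responses")
    omnibus = _contingency_auto(table, seed=seed)
    result = {"item": item_index, "table": table, "omnibus": omnibus, "posthoc": []}
    if posthoc:
        pairs = list(itertools.combinations(groups, 2))
        for g1, g2 in pairs:
            sub = table.loc[[g1, g2]]
            res = _contingency_auto(sub, seed=seed)
            adj_p = min(1.0, res.p_value * len(pairs))
            result["posthoc"].append(
                {"pair": (g1, g2), "result": res, "p_bonferroni": adj_p}
            )
    return result


def total_score_trend(
    records: Sequence[CdpqRecord],
    ordered_groups: Sequence[str],
    n_perm: int = 2000,
    seed: int | None = None,
) -> TrendTestResult:
    """One-sided permutation JT trend test on sum scores across ordered groups."""
    if len(ordered_groups) < 3:
        raise ValueError("need at least 3 ordered groups")
    by_group = {g: [] for g in ordered_groups}
    for r in records:
        if r.group_label in by_group:
            by_group[r.group_label].append(r.sum_score)
    groups = [np.asarray(by_group[g], dtype=float) for g in ordered_groups]
    return jonckheere_terpstra(groups, n_perm=n_perm, seed=seed)


def score_slope_correlation(
    records: Sequence[CdpqRecord],
    slopes: Mapping[str, float],
    group: str | None = None,
) -> TestResult:
    """Pearson correlation of sum scores with per-participant slopes.

    ``slopes`` maps participant id to an unstandardized slope. When ``group``
    is given only that group's records enter.
    """
    xs, ys = [], []
    for r in records:
        if group is not None and r.group_label != group:
            continue
        if r.participant_id in slopes:
            xs.append(float(r.sum_score))
            ys.append(float(slopes[r.participant_id]))
    if len(xs) < 3:
        raise ValueError("fewer than 3 matched participants")
    return pearson_cor(xs, ys)
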