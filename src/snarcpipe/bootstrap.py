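"""H0 bootstrapping of individual slopes and prevalence contingency tests.

For each participant and task, every bootstrap iteration draws, per digit,
two independent sets of 20 RTs with replacement from that digit's pooled
retained RTs (both hands together); one set plays left-hand responses, the
other right-hand. The resulting dRT profile is fitted with the same model as
the empirical slope (PJ: magnitude + parity, giving one null distribution
per coefficient from a single resampling pass; MC: categorical). The
empirical slope is classified against the 5th/95th percentiles of the 5000
bootstrap slopes:

- reliable           empirical slope < q05
- reliable_reverse   empirical slope > q95
- unreliable         otherwise (boundary equality included)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from snarcpipe.simulate import DIGITS
from snarcpipe.slopes import (
    MAGNITUDE,
    PARITY_CONTRAST,
    compute_drt,
    fit_mc_models,
    fit_pj_model,
)
from snarcpipe.inference import TestResult

LABELS = ("reliable", "reliable_reverse", "unreliable")

_ENUMERATION_LIMIT = 1_000_000


@dataclass
class BootstrapClassification:
    participant_id: str
    task: str
    effect: str  # {"SNARC", "MARC"}
    empirical_slope: float
    q05: float
    q95: float
    n_iterations: int
    label: str

    def __post_init__(self) -> None:
        if self.q05 > self.q95:
            raise ValueError("q05 must not exceed q95")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")


@dataclass
class PrevalenceTable:
    groups: tuple
    counts: pd.DataFrame  # index: group, columns: LABELS
    percentages: pd.DataFrame


def classify(empirical: float, q05: float, q95: float) -> str:
    if empirical < q05:
        return "reliable"
    if empirical > q95:
        return "reliable_reverse"
    return "unreliable"


def h0_bootstrap(
    trials: pd.DataFrame,
    n_iter: int = 5000,
    set_size: int = 20,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[BootstrapClassification]:
    """Null-bootstrap classification for one participant in one task.

    Returns one classification per effect: SNARC and MARC for the PJ task
    (both coefficients from the same resamples), SNARC only for MC (using
    the categorical model, matching the empirical MC slope being classified).
    """
    if len(trials) == 0:
        raise ValueError("no retained trials")
    if trials["participant_id"].nunique() > 1 or trials["task"].nunique() > 1:
        raise ValueError("h0_bootstrap expects one participant and one task")
    task = str(trials["task"].iloc[0])
    pid = str(trials["participant_id"].iloc[0])
    if rng is None:
        rng = np.random.default_rng(seed)

    drt = np.empty((n_iter, len(DIGITS)))
    for k, d in enumerate(DIGITS):
        pool = trials.loc[trials["digit"] == d, "rt_ms"].to_numpy(dtype=float)
        if pool.size == 0:
            raise ValueError(f"digit {d} has no retained trials")
        idx = rng.integers(0, pool.size, size=(n_iter, 2, set_size))
        means = pool[idx].mean(axis=2)  # (n_iter, 2): [left, right]
        drt[:, k] = means[:, 1] - means[:, 0]

    profile = compute_drt(trials)
    out = []
    if task == "PJ":
        X = np.column_stack([np.ones(len(DIGITS)), MAGNITUDE, PARITY_CONTRAST])
        pinv = np.linalg.pinv(X)
        mag_slopes = drt @ pinv[1]
        par_slopes = drt @ pinv[2]
        est = fit_pj_model(profile)
        empirical = {"SNARC": est.b_mag, "MARC": est.b_par}
        null_slopes = {"SNARC": mag_slopes, "MARC": par_slopes}
    else:
        small = MAGNITUDE < 5
        cat_slopes = drt[:, ~small].mean(axis=1) - drt[:, small].mean(axis=1)
        cat, _ = fit_mc_models(profile)
        empirical = {"SNARC": cat.b_mag}
        null_slopes = {"SNARC": cat_slopes}

    for effect, emp in empirical.items():
        slopes = null_slopes[effect]
        q05, q95 = np.percentile(slopes, [5.0, 95.0])
        out.append(
            BootstrapClassification(
                participant_id=pid,
                task=task,
                effect=effect,
                empirical_slope=float(emp),
                q05=float(q05),
                q95=float(q95),
                n_iterations=n_iter,
                label=classify(float(emp), float(q05), float(q95)),
            )
        )
    return out


def prevalence_table(
    classifications: Sequence[BootstrapClassification],
    groups: Mapping[str, str],
    group_order: Sequence[str] | None = None,
) -> PrevalenceTable:
    """Counts and percentages of labels per group for one task x effect set."""
    if not classifications:
        raise ValueError("no classifications")
    rows = []
    for c in classifications:
        if c.participant_id not in groups:
            raise ValueError(f"participant {c.participant_id} is in no group")
        rows.append((groups[c.participant_id], c.label))
    df = pd.DataFrame(rows, columns=["group", "label"])
    order = list(group_order) if group_order is not None else sorted(df["group"].unique())
    counts = (
        df.groupby(["group", "label"]).size().unstack(fill_value=0)
        .reindex(index=order, columns=list(LABELS), fill_value=0)
    )
    if counts.isna().any().any() or (counts.sum(axis=1) == 0).any():
        empty = counts.index[counts.fillna(0).sum(axis=1) == 0].tolist()
        raise ValueError(f"empty group rows: {empty}")
    counts = counts.astype(int)
    percentages = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return PrevalenceTable(groups=tuple(order), counts=counts, percentages=percentages)


def chi_square_independence(table: np.ndarray | pd.DataFrame) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("all row and column sums must be positive")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    return TestResult(
        "chi_square", float(chi2), float(p), df=float(df),
        n=int(obs.sum()), extra={"expected": expected},
    )


def _log_table_prob(table: np.ndarray, logfact_margins: float, logfact_n: float) -> float:
    return logfact_margins - logfact_n - special.gammaln(table + 1.0).sum()


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    n_rows = len(row_sums)

    def rec(row_idx: int, remaining_cols: np.ndarray, built: list):
        if row_idx == n_rows - 1:
            yield built + [remaining_cols.copy()]
            return
        target = row_sums[row_idx]
        n_cols = len(remaining_cols)

        def row_rec(col_idx: int, left: int, row: list):
            if col_idx == n_cols - 1:
                if left <= remaining_cols[col_idx]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                yield from row_rec(col_idx + 1, left - v, row + [v])

        for row in row_rec(0, target, []):
            row_arr = np.array(row)
            yield from rec(row_idx + 1, remaining_cols - row_arr, built + [row_arr])

    yield from rec(0, np.asarray(col_sums, dtype=int).copy(), [])


def fisher_exact_rxc(
    table: np.ndarray | pd.DataFrame,
    method: str = "auto",
    n_mc: int = 100_000,
    seed: int | None = None,
) -> TestResult:
    """Fisher's exact test for an r x c contingency table.

    Exact enumeration of all tables with the observed margins when the state
    space is small enough (probability-ordering rule: the p-value sums the
    hypergeometric probabilities of tables no more probable than the observed
    one); otherwise Monte-Carlo sampling from the conditional null via label
    permutation, with the add-one estimator.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0) or np.any(obs != np.round(obs)):
        raise ValueError("table must be a 2-D array of non-negative integers")
    obs = obs.astype(int)
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise ValueError("degenerate margins: zero row or column sum")
    n = int(obs.sum())
    logfact_margins = (
        special.gammaln(row_sums + 1.0).sum() + special.gammaln(col_sums + 1.0).sum()
    )
    logfact_n = float(special.gammaln(n + 1.0))
    log_p_obs = _log_table_prob(obs, logfact_margins, logfact_n)
    tol = 1e-7  # guards against round-off when comparing table probabilities

    if method not in ("auto", "enumeration", "monte_carlo"):
        raise ValueError("method must be auto, enumeration, or monte_carlo")

    use_enum = method == "enumeration"
    if method == "auto":
        # loose upper bound on the number of tables: product over free cells
        bound = 1.0
        for r in row_sums[:-1]:
            for c in col_sums[:-1]:
                bound *= min(r, c) + 1
                if bound > _ENUMERATION_LIMIT:
                    break
        use_enum = bound <= _ENUMERATION_LIMIT

    if use_enum:
        p = 0.0
        count = 0
        for rows in _enumerate_tables(row_sums, col_sums):
            count += 1
            if count > _ENUMERATION_LIMIT:
                if method == "enumeration":
                    raise RuntimeError("state space too large for enumeration")
                use_enum = False
                break
            t = np.vstack(rows)
            lp = _log_table_prob(t, logfact_margins, logfact_n)
            if lp <= log_p_obs + tol:
                p += math.exp(lp)
        if use_enum:
            return TestResult(
                "fisher_exact", float(math.exp(log_p_obs)), min(1.0, float(p)),
                n=n, extra={"method": "enumeration"},
            )

    rng = np.random.default_rng(seed)
    col_labels = np.repeat(np.arange(len(col_sums)), col_sums)
    row_starts = np.concatenate([[0], np.cumsum(row_sums)])
    count = 0
    n_cols = len(col_sums)
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        t = np.empty_like(obs)
        for i in range(len(row_sums)):
            seg = perm[row_starts[i]:row_starts[i + 1]]
            t[i] = np.bincount(seg, minlength=n_cols)
        lp = _log_table_prob(t, logfact_margins, logfact_n)
        if lp <= log_p_obs + tol:
            count += 1
    p = (1 + count) / (n_mc + 1)
    return TestResult(
        "fisher_exact", float(math.exp(log_p_obs)), float(p),
        n=n, extra={"method": "monte_carlo", "n_mc": n_mc},
    )
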