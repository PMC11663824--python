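"""Synthetic trial-level RT data and questionnaire responses.

The generator mirrors the two-task binary-response design: per task,
2 blocks x 8 digits x 20 repetitions = 320 trials. Each participant draws a
magnitude slope, a parity (MARC) slope, and a baseline RT from group-level
distributions; the expected right-minus-left RT difference (dRT) for digit
``d`` is ``a + b*d`` (plus ``m * parity_contrast`` in the parity-judgment
task), implemented symmetrically: half the effect is added to right-side
responses and subtracted from left-side responses. Within-trial noise is
ex-Gaussian (Gaussian component plus exponential tail), the standard choice
for RT data; the generating model is otherwise deliberately minimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from snarcpipe._rng import rng_for

DIGITS: tuple[int, ...] = (1, 2, 3, 4, 6, 7, 8, 9)
TASKS: tuple[str, str] = ("PJ", "MC")
N_REPS_PER_BLOCK = 20
RT_WINDOW = (200.0, 1500.0)

#: parity contrast: -0.5 for odd digits, +0.5 for even digits
PARITY = {d: (0.5 if d % 2 == 0 else -0.5) for d in DIGITS}

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "task",
    "block",
    "trial_index",
    "digit",
    "response_side",
    "correct",
    "rt_ms",
]

_UNIFORM_TRIPLE = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
CDPQ_CODES = ("LR", "NONE", "RL")


@dataclass
class GroupConfig:
    """Generative parameters for one cultural group.

    ``slope_mean``/``slope_sd`` govern the per-participant linear dRT slope
    (ms per digit unit) in the parity-judgment task; ``mc_slope_mean``/``_sd``
    the analogous linear slope for the magnitude-classification task (falling
    back to the PJ values when None). ``marc_mean``/``marc_sd`` govern the
    parity-contrast effect, present in PJ only. ``cdpq_item_probs`` holds, for
    each of the 7 questionnaire items, the (LR, NONE, RL) response
    probabilities.
    """

    group_label: str
    n_participants: int
    slope_mean: float
    slope_sd: float
    marc_mean: float = 0.0
    marc_sd: float = 0.0
    mc_slope_mean: float | None = None
    mc_slope_sd: float | None = None
    base_rt_mean: float = 600.0
    base_rt_sd_between: float = 80.0
    noise_sd_within: float = 100.0
    tau_within: float = 60.0
    error_rate: float = 0.045
    lapse_rate: float = 0.01
    drt_intercept_mean: float = 0.0
    drt_intercept_sd: float = 0.0
    block_effect: float = 0.0
    cdpq_item_probs: tuple = tuple(_UNIFORM_TRIPLE for _ in range(7))
    start_hand_probs: tuple | None = None  # (left, right, none, no_answer)
    stability_probs: tuple | None = None  # (always, usually, none, no_answer)

    def validate(self) -> None:
        if not self.group_label:
            raise ValueError("group_label: must be a non-empty string")
        if int(self.n_participants) < 1:
            raise ValueError("n_participants: must be >= 1")
        for name in ("slope_sd", "marc_sd", "base_rt_sd_between",
                     "noise_sd_within", "tau_within", "drt_intercept_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if self.mc_slope_sd is not None and self.mc_slope_sd < 0:
            raise ValueError("mc_slope_sd: must be >= 0")
        for name in ("error_rate", "lapse_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}: must be a probability in [0, 1]")
        if self.base_rt_mean <= 0:
            raise ValueError("base_rt_mean: must be > 0")
        probs = tuple(self.cdpq_item_probs)
        if len(probs) != 7:
            raise ValueError("cdpq_item_probs: must hold 7 item triples")
        for i, triple in enumerate(probs, start=1):
            t = tuple(float(x) for x in triple)
            if len(t) != 3 or any(x < 0 or x > 1 for x in t):
                raise ValueError(
                    f"cdpq_item_probs: item {i} must be a triple of probabilities"
                )
            if abs(sum(t) - 1.0) > 1e-9:
                raise ValueError(f"cdpq_item_probs: item {i} triple must sum to 1")
        for name in ("start_hand_probs", "stability_probs"):
            p = getattr(self, name)
            if p is None:
                continue
            t = tuple(float(x) for x in p)
            if len(t) != 4 or any(x < 0 for x in t) or abs(sum(t) - 1.0) > 1e-9:
                raise ValueError(f"{name}: must be 4 probabilities summing to 1")


def _correct_side(task: str, digit: int, block: int) -> str:
    """Required response side under the block's response-to-key mapping.

    Block 1 is the compatible mapping (odd-left/even-right in PJ,
    small-left/large-right in MC); block 2 reverses it.
    """
    if task == "PJ":
        base = "left" if digit % 2 == 1 else "right"
    else:
        base = "left" if digit < 5 else "right"
    if block == 2:
        base = "right" if base == "left" else "left"
    return base


def simulate_participant(
    config: GroupConfig, participant_id: str, seed: int
) -> pd.DataFrame:
    """Simulate both tasks (320 trials each) for one participant.

    Deterministic given ``(config, participant_id, seed)``. Error trials are
    flagged (``correct=False``) but keep an RT drawn from the same
    distribution; lapse trials get an RT outside the 200-1500 ms window.
    Removal of either is the preprocessing stage's job.
    """
    config.validate()
    rng = rng_for(seed, "participant", participant_id)

    b_pj = rng.normal(config.slope_mean, config.slope_sd)
    mc_mean = config.mc_slope_mean if config.mc_slope_mean is not None else config.slope_mean
    mc_sd = config.mc_slope_sd if config.mc_slope_sd is not None else config.slope_sd
    b_mc = rng.normal(mc_mean, mc_sd)
    m_par = rng.normal(config.marc_mean, config.marc_sd)
    base_rt = rng.normal(config.base_rt_mean, config.base_rt_sd_between)
    a_drt = rng.normal(config.drt_intercept_mean, config.drt_intercept_sd)

    frames = []
    for task in TASKS:
        b = b_pj if task == "PJ" else b_mc
        digits_parts = []
        blocks_parts = []
        for block in (1, 2):
            block_digits = np.repeat(np.array(DIGITS), N_REPS_PER_BLOCK)
            rng.shuffle(block_digits)
            digits_parts.append(block_digits)
            blocks_parts.append(np.full(block_digits.size, block))
        digits = np.concatenate(digits_parts)
        blocks = np.concatenate(blocks_parts)
        n = digits.size

        req_sides = np.array(
            [_correct_side(task, d, blk) for d, blk in zip(digits, blocks)]
        )
        errors = rng.random(n) < config.error_rate
        sides = np.where(
            errors, np.where(req_sides == "left", "right", "left"), req_sides
        )

        parity = np.array([PARITY[d] for d in digits])
        effect = a_drt + b * digits
        if task == "PJ":
            effect = effect + m_par * parity
        side_sign = np.where(sides == "right", 0.5, -0.5)

        rt = (
            base_rt
            + config.block_effect * (blocks - 1)
            + side_sign * effect
            + rng.normal(0.0, config.noise_sd_within, size=n)
        )
        if config.tau_within > 0:
            rt = rt + rng.exponential(config.tau_within, size=n)

        lapses = rng.random(n) < config.lapse_rate
        if lapses.any():
            k = int(lapses.sum())
            slow = rng.random(k) < 0.8  # most lapses are slow responses
            lapse_rt = np.where(
                slow,
                rng.uniform(RT_WINDOW[1] + 1.0, 3000.0, size=k),
                rng.uniform(50.0, RT_WINDOW[0] - 1.0, size=k),
            )
            rt[lapses] = lapse_rt
        rt = np.maximum(rt, 1.0)

        frames.append(
            pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "group": config.group_label,
                    "task": task,
                    "block": blocks,
                    "trial_index": np.arange(n),
                    "digit": digits,
                    "response_side": sides,
                    "correct": ~errors,
                    "rt_ms": rt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def _simulate_cdpq(
    config: GroupConfig, participant_id: str, seed: int
) -> dict:
    rng = rng_for(seed, "cdpq", participant_id)
    rec: dict = {"participant_id": participant_id, "group": config.group_label}
    for i, triple in enumerate(config.cdpq_item_probs, start=1):
        rec[f"item{i}"] = CDPQ_CODES[rng.choice(3, p=np.asarray(triple, dtype=float))]
    if config.start_hand_probs is not None:
        opts = ("left", "right", "none", "no_answer")
        rec["start_hand"] = opts[rng.choice(4, p=np.asarray(config.start_hand_probs, dtype=float))]
    if config.stability_probs is not None:
        opts = ("always", "usually", "none", "no_answer")
        rec["stability"] = opts[rng.choice(4, p=np.asarray(config.stability_probs, dtype=float))]
    return rec


def simulate_study(
    configs: Sequence[GroupConfig] | Iterable[GroupConfig], seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full multi-group study.

    Returns ``(trials, cdpq)`` data frames. Per-participant randomness is
    derived from the master seed and the participant id, so individual
    participants are reproducible in isolation.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("configs: at least one group is required")
    labels = [c.group_label for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError("group_label: duplicate group labels")
    for c in configs:
        c.validate()

    trial_frames = []
    cdpq_rows = []
    for config in configs:
        for i in range(int(config.n_participants)):
            pid = f"{config.group_label}_{i + 1:03d}"
            trial_frames.append(simulate_participant(config, pid, seed))
            cdpq_rows.append(_simulate_cdpq(config, pid, seed))
    trials = pd.concat(trial_frames, ignore_index=True)
    cdpq = pd.DataFrame(cdpq_rows)
    return trials, cdpq
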