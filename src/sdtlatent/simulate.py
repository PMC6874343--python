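"""Seeded synthetic m-AFC response generation.

Two generative modes are provided.  ``model`` mode draws each score as
Bernoulli with p = L_m(theta + effect - b).  ``mechanistic`` mode draws the
internal responses themselves — x_C ~ N(theta + effect - b, 1) and m-1
independent x_I ~ N(0, 1), scoring correct iff x_C exceeds every x_I — and
therefore serves as an independent Monte-Carlo oracle for the psychometric
function: the two modes are equal in distribution.

The default study design mirrors a two-condition forced-choice experiment:
50 subjects each counted as two "persons" (one per condition), 192 items in
8 blocks, each subject randomly assigned either the odd or the even blocks
to the treated condition, so disjoint person groups respond to disjoint item
blocks.  A third of the items are 2-AFC and the rest 3-AFC.  The condition
effect is an additive shift on person ability in d' units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psychometric import pc_from_dprime

__all__ = [
    "SimulationTruth",
    "make_truth",
    "simulate_responses",
    "mc_pc",
]

#: Default generating distributions: theta ~ N(0, 0.8), b ~ N(-1, 1).
#: Items sit mostly below (easier than) the average person, as is typical
#: for clinical forced-choice batteries designed to be doable.
THETA_SD = 0.8
B_MEAN = -1.0
B_SD = 1.0


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters behind a synthetic response table.

    ``person_truth`` maps person_id -> (theta, condition); ``item_truth``
    maps item_id -> (b, m, block).  ``condition_effect`` is added to theta
    for every person whose condition is "treated".  With the blocked design
    each person responds only to the blocks of matching parity, emulating a
    randomized within-subject two-condition layout; the complete design has
    every person answer every item.
    """

    person_truth: dict[str, tuple[float, str]]
    item_truth: dict[str, tuple[float, int, int]]
    condition_effect: float
    design: str  # "complete" | "blocked"
    seed: int
    n_blocks: int = 8
    #: person_id -> parity (0 or 1) of the blocks this person responds to
    person_blocks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in ("complete", "blocked"):
            raise ValueError(f"design must be 'complete' or 'blocked', got {self.design!r}")
        for item, (_, m, _) in self.item_truth.items():
            if m < 2:
                raise ValueError(f"item {item!r} has m < 2")
        if self.design == "blocked" and set(self.person_blocks) != set(self.person_truth):
            raise ValueError("blocked design requires a block parity for every person")


def make_truth(seed: int, n_subjects: int = 50, n_items: int = 192,
               design: str = "blocked", condition_effect: float = 0.0,
               paired: bool = True, theta_sd: float = THETA_SD,
               b_mean: float = B_MEAN, b_sd: float = B_SD,
               n_blocks: int = 8, frac_2afc: float = 1.0 / 3.0) -> SimulationTruth:
    """Draw a ground truth emulating the two-condition study design.

    With ``paired=True`` each subject contributes two persons sharing the
    same latent theta — "<subj>:ctl" (untreated) and "<subj>:trt" (treated,
    ability shifted by ``condition_effect``).  With ``paired=False`` each
    subject is a single untreated person.  Items are split into ``n_blocks``
    contiguous blocks; in the blocked design each subject is randomly
    assigned odd or even blocks to the treated condition and the two
    persons of a subject respond to disjoint block sets.
    """
    rng = np.random.default_rng(seed)
    thetas = rng.normal(0.0, theta_sd, n_subjects)
    bs = rng.normal(b_mean, b_sd, n_items)
    n2 = int(round(frac_2afc * n_items))
    ms = np.array([2] * n2 + [3] * (n_items - n2))
    rng.shuffle(ms)
    width = len(str(n_items))
    item_truth = {
        f"i{idx:0{width}d}": (float(bs[idx]), int(ms[idx]), idx * n_blocks // n_items)
        for idx in range(n_items)
    }
    person_truth: dict[str, tuple[float, str]] = {}
    person_blocks: dict[str, int] = {}
    parities = rng.integers(0, 2, n_subjects)
    swidth = len(str(n_subjects))
    for s in range(n_subjects):
        subj = f"s{s:0{swidth}d}"
        if paired:
            person_truth[f"{subj}:ctl"] = (float(thetas[s]), "control")
            person_truth[f"{subj}:trt"] = (float(thetas[s]), "treated")
            person_blocks[f"{subj}:trt"] = int(parities[s])
            person_blocks[f"{subj}:ctl"] = 1 - int(parities[s])
        else:
            person_truth[subj] = (float(thetas[s]), "control")
            person_blocks[subj] = int(parities[s])
    if design == "complete":
        person_blocks = {}
    return SimulationTruth(
        person_truth=person_truth, item_truth=item_truth,
        condition_effect=float(condition_effect), design=design,
        seed=int(seed), n_blocks=n_blocks, person_blocks=person_blocks,
    )


def _effective_theta(truth: SimulationTruth, person_id: str) -> float:
    theta, condition = truth.person_truth[person_id]
    if condition == "treated":
        theta += truth.condition_effect
    return theta


def simulate_responses(truth: SimulationTruth, mode: str = "model",
                       seed: int | None = None) -> pd.DataFrame:
    """Generate the response table implied by a ground truth.

    ``mode="model"`` draws scores through the psychometric function;
    ``mode="mechanistic"`` simulates the internal responses directly
    (largest internal response wins).  The same (truth, mode, seed) always
    yields a bit-identical table.  ``seed`` defaults to ``truth.seed``.
    """
    if mode not in ("model", "mechanistic"):
        raise ValueError(f"mode must be 'model' or 'mechanistic', got {mode!r}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows: list[tuple[str, str, int, int]] = []
    items = sorted(truth.item_truth.items())
    for person_id in sorted(truth.person_truth):
        theta = _effective_theta(truth, person_id)
        if truth.design == "blocked":
            parity = truth.person_blocks[person_id]
            my_items = [(i, v) for i, v in items if v[2] % 2 == parity]
        else:
            my_items = items
        for item_id, (b, m, _block) in my_items:
            d = theta - b
            if mode == "model":
                score = int(rng.random() < pc_from_dprime(d, m))
            else:
                x_c = rng.normal(d, 1.0)
                x_i = rng.normal(0.0, 1.0, m - 1)
                score = int(np.all(x_c > x_i))
            rows.append((person_id, item_id, m, score))
    return pd.DataFrame(rows, columns=["person_id", "item_id", "m", "score"])


def truth_frames(truth: SimulationTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The ground truth as (persons, items) DataFrames, for export."""
    persons = pd.DataFrame(
        [(pid, th, cond) for pid, (th, cond) in sorted(truth.person_truth.items())],
        columns=["person_id", "theta_true", "condition"],
    )
    items = pd.DataFrame(
        [(iid, b, m, blk) for iid, (b, m, blk) in sorted(truth.item_truth.items())],
        columns=["item_id", "b_true", "m", "block"],
    )
    return persons, items


def mc_pc(dprime: float, m: int, n: int, seed: int) -> float:
    """Monte-Carlo probability correct from n mechanistic draws.

    The independent oracle for ``pc_from_dprime``: draws x_C ~ N(d', 1) and
    m-1 standard normals per trial and scores the fraction of trials where
    the correct choice produced the largest internal response.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if m < 2:
        raise ValueError("m must be >= 2")
    rng = np.random.default_rng(seed)
    # chunked to bound memory at large n
    correct = 0
    remaining = n
    while remaining > 0:
        k = min(remaining, 1_000_000)
        x_c = rng.normal(dprime, 1.0, k)
        x_i_max = rng.normal(0.0, 1.0, (k, m - 1)).max(axis=1)
        correct += int(np.sum(x_c > x_i_max))
        remaining -= k
    return correct / n
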