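"""Dichotomous Rasch model (JMLE) and the SDT-vs-Rasch item comparison.

The dichotomous Rasch model puts P(correct) = logistic(theta - b) with
theta, b in logits.  It is fit here by joint maximum likelihood —
alternating Newton updates of person and item parameters — with the mean
item measure anchored at 0, the usual Rasch convention.  Persons and items
with extreme raw scores (all correct / all incorrect) have no finite MLE
and are excluded from estimation.

Because the Rasch model is itself a special case of the m-AFC signal
detection model (point-mass correct-choice density, logistic noise CDF),
item measures from the two models are linearly related within any fixed m;
``compare_rasch_sdt`` fits those per-m lines by OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import linregress

from .estimation import ItemEstimate, validate_responses

__all__ = ["RaschFit", "LineFit", "rasch_probability", "fit_rasch", "compare_rasch_sdt"]


@dataclass
class RaschFit:
    """JMLE Rasch estimates in logits, mean item measure anchored at 0."""

    item_measures: dict[str, float]
    person_measures: dict[str, float]
    converged: bool
    n_iterations: int
    excluded_persons: list[str] = field(default_factory=list)
    excluded_items: list[str] = field(default_factory=list)
    anchoring: str = "mean-item-zero"


@dataclass(frozen=True)
class LineFit:
    """OLS line relating Rasch logits to SDT d' item measures within one m."""

    m: int
    slope: float
    intercept: float
    r2: float
    n_items: int


def rasch_probability(theta: float, b: float, score: int) -> float:
    """P(R = score) under the dichotomous Rasch model, theta and b in logits."""
    if not (np.isfinite(theta) and np.isfinite(b)):
        raise ValueError("theta and b must be finite")
    if score not in (0, 1):
        raise ValueError(f"score must be 0 or 1, got {score!r}")
    p1 = float(expit(theta - b))
    return p1 if score == 1 else 1.0 - p1


def fit_rasch(responses: pd.DataFrame, tol: float = 1e-5,
              max_iter: int = 500) -> RaschFit:
    """Joint maximum-likelihood Rasch fit of a scored response table.

    Persons and items with extreme raw scores are iteratively removed (a
    removal can create new extremes), then person and item parameters are
    updated by damped Newton steps on the logistic log-likelihood until the
    largest change falls below ``tol`` logits.  After every cycle item
    measures are re-centered to mean 0.
    """
    df = validate_responses(responses)
    df = df.copy()
    df["person_id"] = df["person_id"].astype(str)
    df["item_id"] = df["item_id"].astype(str)

    excluded_persons: list[str] = []
    excluded_items: list[str] = []
    while True:
        pr = df.groupby("person_id")["score"].agg(["sum", "count"])
        bad_p = pr.index[(pr["sum"] == 0) | (pr["sum"] == pr["count"])]
        ir = df.groupby("item_id")["score"].agg(["sum", "count"])
        bad_i = ir.index[(ir["sum"] == 0) | (ir["sum"] == ir["count"])]
        if len(bad_p) == 0 and len(bad_i) == 0:
            break
        excluded_persons += list(bad_p)
        excluded_items += list(bad_i)
        df = df[~df["person_id"].isin(bad_p) & ~df["item_id"].isin(bad_i)]
        if df.empty:
            raise ValueError("no estimable responses remain after removing extreme scores")

    persons = np.array(sorted(df["person_id"].unique()))
    items = np.array(sorted(df["item_id"].unique()))
    p_idx = {p: i for i, p in enumerate(persons)}
    i_idx = {h: i for i, h in enumerate(items)}
    rows = df["person_id"].map(p_idx).to_numpy()
    cols = df["item_id"].map(i_idx).to_numpy()
    x = df["score"].to_numpy().astype(float)

    # logit of the raw proportions as starting values
    pr = df.groupby("person_id")["score"].mean().reindex(persons).to_numpy()
    ir = df.groupby("item_id")["score"].mean().reindex(items).to_numpy()
    theta = np.log(pr / (1 - pr))
    b = -np.log(ir / (1 - ir))
    b -= b.mean()

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(theta[rows] - b[cols])
        resid = x - p
        info = p * (1 - p)
        # person Newton step
        g_p = np.bincount(rows, weights=resid, minlength=len(persons))
        h_p = np.bincount(rows, weights=info, minlength=len(persons))
        d_theta = np.clip(g_p / h_p, -1.0, 1.0)
        theta = theta + d_theta
        # item Newton step with updated thetas
        p = expit(theta[rows] - b[cols])
        resid = x - p
        info = p * (1 - p)
        g_i = np.bincount(cols, weights=resid, minlength=len(items))
        h_i = np.bincount(cols, weights=info, minlength=len(items))
        d_b = np.clip(-g_i / h_i, -1.0, 1.0)
        b = b + d_b
        shift = b.mean()
        b -= shift
        theta -= shift
        if max(np.max(np.abs(d_theta)), np.max(np.abs(d_b))) < tol:
            converged = True
            break

    return RaschFit(
        item_measures={h: float(v) for h, v in zip(items, b)},
        person_measures={pid: float(v) for pid, v in zip(persons, theta)},
        converged=converged, n_iterations=it,
        excluded_persons=sorted(excluded_persons),
        excluded_items=sorted(excluded_items),
    )


def compare_rasch_sdt(sdt_items: list[ItemEstimate], rasch: RaschFit) -> list[LineFit]:
    """OLS regression of Rasch logits on SDT d' item measures, per m group.

    SDT anchors chance at b = 0 for every m while the Rasch logit scale
    anchors the mean item at 0, so the per-m lines share (approximately)
    a slope but differ in intercept when m is mixed.  Groups with fewer
    than 3 shared items are skipped with a warning record (not returned).
    """
    shared = [it for it in sdt_items if it.item_id in rasch.item_measures]
    fits: list[LineFit] = []
    by_m: dict[int, list[ItemEstimate]] = {}
    for it in shared:
        by_m.setdefault(it.m, []).append(it)
    for m in sorted(by_m):
        group = by_m[m]
        if len(group) < 3:
            import logging
            logging.getLogger(__name__).warning(
                "skipping m=%d line fit: only %d shared items", m, len(group))
            continue
        xs = np.array([it.b for it in group])
        ys = np.array([rasch.item_measures[it.item_id] for it in group])
        res = linregress(xs, ys)
        fits.append(LineFit(m=m, slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(res.rvalue) ** 2, n_items=len(group)))
    return fits
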