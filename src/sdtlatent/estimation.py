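"""Item and person measure estimation on the d' axis.

Estimation proceeds in two stages.  Items are first calibrated against a
single "average" person anchored at theta = 0: each item's observed
proportion correct p_h is inverted through the m-AFC psychometric function,
b_h = -L_m^{-1}(p_h), with Wilson binomial confidence intervals mapped into
d' units the same way (the order of the endpoints flips because b = -d').
Person measures are then independent one-parameter maximum-likelihood
estimates given the item measures, with standard errors from the observed
information.  An alternating "local MLE" refinement (here called EM, after
its expectation-maximization-like structure) re-estimates items given
persons and persons given items until parameter changes fall below a
threshold, re-anchoring the mean person measure to 0 after every cycle —
the likelihood depends only on differences theta - b, so an explicit
anchoring constraint is required for identifiability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .psychometric import dprime_from_pc, pc_from_dprime

__all__ = [
    "ItemEstimate",
    "PersonEstimate",
    "FitResult",
    "PairedEffect",
    "validate_responses",
    "wilson_ci",
    "calibrate_items",
    "fit_person",
    "fit_all_persons",
    "fit_em",
    "summarize_paired_effect",
]

logger = logging.getLogger(__name__)

#: 1-D search interval for person and item measures, in d' units.
SEARCH_BOUND = 10.0
#: Absolute tolerance of the 1-D golden/Brent refinement.
_XATOL = 1e-6
#: Step for the central second difference behind the observed-information SE.
_SE_STEP = 1e-3


@dataclass(frozen=True)
class ItemEstimate:
    """An item's location b on the d' axis (negative = easier, 0 = chance)."""

    item_id: str
    b: float
    ci_low: float
    ci_high: float
    n_correct: int
    n_total: int
    m: int
    degenerate_flag: bool = False


@dataclass(frozen=True)
class PersonEstimate:
    """A person's ability theta on the d' axis, with its MLE standard error."""

    person_id: str
    theta: float
    se: float
    n_items: int
    degenerate_flag: bool = False


@dataclass
class FitResult:
    """Paired item/person estimates plus method metadata and trace.

    ``trace`` rows are (iteration, max_abs_parameter_change, total_log_likelihood);
    for ``method="em"`` the log-likelihood is non-decreasing along the trace.
    """

    items: list[ItemEstimate]
    persons: list[PersonEstimate]
    method: str
    n_iterations: int
    converged: bool
    trace: list[tuple[int, float, float]] = field(default_factory=list)


@dataclass(frozen=True)
class PairedEffect:
    """Mean paired difference in person measures with a normal-theory CI."""

    mean_diff: float
    ci_low: float
    ci_high: float
    n: int
    conf: float


def validate_responses(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format response table.

    Required columns: person_id, item_id, m (int >= 2), score (0/1).
    Each (person, item) pair may appear at most once, and all rows of an
    item must share one m.
    """
    required = ["person_id", "item_id", "m", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")
    df = df.copy()
    df["m"] = pd.to_numeric(df["m"], errors="raise").astype(int)
    df["score"] = pd.to_numeric(df["score"], errors="raise").astype(int)
    if (df["m"] < 2).any():
        bad = df.loc[df["m"] < 2].index[0]
        raise ValueError(f"m must be >= 2 (row {bad})")
    if ~df["score"].isin([0, 1]).all():
        bad = df.loc[~df["score"].isin([0, 1])].index[0]
        raise ValueError(f"score must be 0 or 1 (row {bad})")
    dup = df.duplicated(subset=["person_id", "item_id"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate response for pair ({row['person_id']!r}, {row['item_id']!r})"
        )
    m_per_item = df.groupby("item_id")["m"].nunique()
    if (m_per_item > 1).any():
        item = m_per_item[m_per_item > 1].index[0]
        raise ValueError(f"item {item!r} has inconsistent m across rows")
    return df


def wilson_ci(n_correct: int, n_total: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Endpoints are kept strictly inside (0, 1): at degenerate counts the raw
    Wilson interval touches 0 or 1 exactly, so endpoints are pulled in by a
    quarter-count, 1/(4(n+2)).
    """
    if not (0 <= n_correct <= n_total) or n_total < 1:
        raise ValueError(f"invalid counts n_correct={n_correct}, n_total={n_total}")
    if not (0.0 < conf < 1.0):
        raise ValueError(f"conf must be in (0, 1), got {conf}")
    lo, hi = proportion_confint(n_correct, n_total, alpha=1.0 - conf, method="wilson")
    eps = 1.0 / (4.0 * (n_total + 2))
    if n_correct == 0:
        lo = eps
    if n_correct == n_total:
        hi = 1.0 - eps
    return (float(lo), float(hi))


def _adjusted_p(n_correct: int, n_total: int) -> tuple[float, bool]:
    """Observed proportion with the degenerate-score adjustment.

    Perfect (or zero) scores have no finite d' inverse; substitute
    (x + 0.5)/(n + 1), which keeps the estimate finite and ordinal with
    its neighbours, and flag the item.
    """
    if n_correct == 0 or n_correct == n_total:
        return (n_correct + 0.5) / (n_total + 1.0), True
    return n_correct / n_total, False


def calibrate_items(responses: pd.DataFrame, conf: float = 0.95) -> list[ItemEstimate]:
    """Calibrate every item against the average person (theta = 0).

    For item h with n_correct of n_total correct: b_h = -L_m^{-1}(p_h), and
    the Wilson interval endpoints map through the same inverse with the
    order flipped (higher probability correct = easier item = lower b).
    """
    responses = validate_responses(responses)
    out: list[ItemEstimate] = []
    grouped = responses.groupby("item_id", sort=True)
    for item_id, grp in grouped:
        n_total = len(grp)
        n_correct = int(grp["score"].sum())
        m = int(grp["m"].iloc[0])
        p_hat, degenerate = _adjusted_p(n_correct, n_total)
        b = -dprime_from_pc(p_hat, m)
        lo, hi = wilson_ci(n_correct, n_total, conf)
        ci_low = -dprime_from_pc(hi, m)
        ci_high = -dprime_from_pc(lo, m)
        out.append(
            ItemEstimate(
                item_id=str(item_id), b=b, ci_low=ci_low, ci_high=ci_high,
                n_correct=n_correct, n_total=n_total, m=m,
                degenerate_flag=degenerate,
            )
        )
    return out


def _group_by_m(pairs: Iterable[tuple[float, int]]) -> dict[int, np.ndarray]:
    by_m: dict[int, list[float]] = {}
    for b, m in pairs:
        by_m.setdefault(int(m), []).append(float(b))
    # sorted so summation order (hence the float result) is independent of
    # the order responses arrived in
    return {m: np.sort(np.asarray(v)) for m, v in by_m.items()}


def _make_loglik(correct: Iterable[tuple[float, int]],
                 incorrect: Iterable[tuple[float, int]]):
    """Log-likelihood of one latent location given (b, m) response sets.

    Used symmetrically: for a person, the sets hold item measures and the
    function is evaluated at theta; for an item, the sets hold person
    measures and the function of b is ll(-b) with signs flipped by the
    caller (L_m depends only on theta - b).
    """
    cor = _group_by_m(correct)
    inc = _group_by_m(incorrect)

    def loglik(x: float) -> float:
        total = 0.0
        for m in sorted(cor):
            p = pc_from_dprime(x - cor[m], m)
            total += float(np.sum(np.log(p)))
        for m in sorted(inc):
            p = pc_from_dprime(x - inc[m], m)
            total += float(np.sum(np.log1p(-p)))
        return total

    return loglik


def _maximize_1d(loglik) -> tuple[float, bool]:
    """Maximize a unimodal log-likelihood on [-SEARCH_BOUND, SEARCH_BOUND].

    Returns (argmax, hit_bound).  A monotone likelihood (degenerate response
    pattern) drives the optimum to the bound, which is then returned exactly.
    """
    res = minimize_scalar(
        lambda x: -loglik(x),
        bounds=(-SEARCH_BOUND, SEARCH_BOUND),
        method="bounded",
        options={"xatol": _XATOL},
    )
    x = float(res.x)
    if x >= SEARCH_BOUND - 1e-4 and loglik(SEARCH_BOUND) >= loglik(x):
        return SEARCH_BOUND, True
    if x <= -SEARCH_BOUND + 1e-4 and loglik(-SEARCH_BOUND) >= loglik(x):
        return -SEARCH_BOUND, True
    return x, False


def _information_se(loglik, x: float) -> float:
    """SE from the observed information: (-d2 loglik / dx2)^(-1/2)."""
    d2 = (loglik(x + _SE_STEP) - 2.0 * loglik(x) + loglik(x - _SE_STEP)) / _SE_STEP**2
    if d2 >= 0:
        return float("nan")
    return float(1.0 / np.sqrt(-d2))


def fit_person(correct_items: Sequence[tuple[float, int]],
               incorrect_items: Sequence[tuple[float, int]],
               person_id: str = "") -> PersonEstimate:
    """One-parameter MLE of a person measure given item measures.

    ``correct_items`` / ``incorrect_items`` are (b, m) pairs for the items
    the person answered correctly / incorrectly.  A person with no
    incorrect (or no correct) responses has a monotone likelihood and no
    finite MLE; theta is clamped to the search bound and flagged, with the
    SE left undefined (NaN).
    """
    correct_items = list(correct_items)
    incorrect_items = list(incorrect_items)
    n_items = len(correct_items) + len(incorrect_items)
    if n_items == 0:
        raise ValueError("fit_person requires at least one response")
    loglik = _make_loglik(correct_items, incorrect_items)
    if not correct_items:
        return PersonEstimate(person_id, -SEARCH_BOUND, float("nan"), n_items, True)
    if not incorrect_items:
        return PersonEstimate(person_id, SEARCH_BOUND, float("nan"), n_items, True)
    theta, hit_bound = _maximize_1d(loglik)
    se = float("nan") if hit_bound else _information_se(loglik, theta)
    return PersonEstimate(person_id, theta, se, n_items, hit_bound)


def fit_all_persons(responses: pd.DataFrame,
                    items: Sequence[ItemEstimate]) -> list[PersonEstimate]:
    """Independent person MLEs for every person in the table."""
    responses = validate_responses(responses)
    b_by_item = {it.item_id: (it.b, it.m) for it in items}
    unknown = set(responses["item_id"].astype(str)) - set(b_by_item)
    if unknown:
        raise KeyError(f"responses reference items with no estimate: {sorted(unknown)[:5]}")
    out: list[PersonEstimate] = []
    for person_id, grp in responses.groupby("person_id", sort=True):
        cor = [b_by_item[str(i)] for i in grp.loc[grp["score"] == 1, "item_id"]]
        inc = [b_by_item[str(i)] for i in grp.loc[grp["score"] == 0, "item_id"]]
        out.append(fit_person(cor, inc, person_id=str(person_id)))
    return out


def _refit_item(thetas_correct: Sequence[tuple[float, int]],
                thetas_incorrect: Sequence[tuple[float, int]],
                template: ItemEstimate) -> ItemEstimate:
    """Item-step MLE of b given person measures (the EM item update).

    The likelihood depends on theta - b, so the person-measure log-likelihood
    machinery is reused with the sign flipped: maximizing over b equals
    maximizing ll(-b) with the roles of theta and b exchanged.
    """
    # ll(b) = sum log L_m(theta - b): substitute u = -b so theta - b = u - (-theta);
    # reuse the person machinery by negating the stored person measures.
    neg = _make_loglik(
        [(-t, m) for t, m in thetas_correct],
        [(-t, m) for t, m in thetas_incorrect],
    )
    u, hit_bound = _maximize_1d(neg)
    b_new = -u
    shift = b_new - template.b
    return ItemEstimate(
        item_id=template.item_id, b=b_new,
        ci_low=template.ci_low + shift, ci_high=template.ci_high + shift,
        n_correct=template.n_correct, n_total=template.n_total, m=template.m,
        degenerate_flag=template.degenerate_flag or hit_bound,
    )


def total_log_likelihood(responses: pd.DataFrame,
                         items: Sequence[ItemEstimate],
                         persons: Sequence[PersonEstimate]) -> float:
    """Joint log-likelihood of the table under given item/person measures."""
    b = {it.item_id: it.b for it in items}
    m_of = {it.item_id: it.m for it in items}
    th = {p.person_id: p.theta for p in persons}
    d = np.array([th[str(r.person_id)] - b[str(r.item_id)] for r in responses.itertuples()])
    ms = np.array([m_of[str(r.item_id)] for r in responses.itertuples()])
    scores = responses["score"].to_numpy()
    ll = 0.0
    for m in np.unique(ms):
        sel = ms == m
        p = pc_from_dprime(d[sel], int(m))
        s = scores[sel]
        ll += float(np.sum(np.log(np.where(s == 1, p, 1.0 - p))))
    return ll


def fit_em(responses: pd.DataFrame, conf: float = 0.95, tol: float = 1e-4,
           max_iter: int = 100) -> FitResult:
    """Alternating local-MLE refinement of item and person measures.

    Initializes with the average-person calibration and independent person
    MLEs, then alternates the item step (per-item 1-D MLE of b given the
    current person measures) and the person step, re-anchoring the mean
    person measure to 0 after each full cycle (subtracting the same constant
    from every theta and every b, which leaves all theta - b and hence the
    likelihood unchanged).  Stops when the maximum absolute parameter change
    drops below ``tol`` or at ``max_iter``; non-convergence is reported via
    the ``converged`` flag, not an exception.

    Score-degenerate items (0 or all correct) and persons (all responses
    correct or all incorrect) have no finite MLE: they keep their stage-1
    estimates, stay flagged, and their responses are excluded from the
    refinement likelihood — the same convention Rasch practice uses for
    extreme scores.  The anchoring mean and the trace log-likelihood are
    taken over the estimable (non-degenerate) part of the table.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    responses = validate_responses(responses)
    items = calibrate_items(responses, conf)
    persons = fit_all_persons(responses, items)

    frozen_items = {it.item_id for it in items if it.n_correct in (0, it.n_total)}
    frozen_persons = {p.person_id for p in persons if p.degenerate_flag}
    # closure: dropping an extreme item can make a person extreme on what
    # remains (and vice versa), so iterate until stable
    while True:
        estimable = responses[
            ~responses["item_id"].astype(str).isin(frozen_items)
            & ~responses["person_id"].astype(str).isin(frozen_persons)
        ]
        if estimable.empty:
            raise ValueError("no estimable responses: every item or person is score-degenerate")
        pr = estimable.groupby("person_id")["score"].agg(["sum", "count"])
        new_p = set(pr.index[(pr["sum"] == 0) | (pr["sum"] == pr["count"])].astype(str))
        ir = estimable.groupby("item_id")["score"].agg(["sum", "count"])
        new_i = set(ir.index[(ir["sum"] == 0) | (ir["sum"] == ir["count"])].astype(str))
        if new_p <= frozen_persons and new_i <= frozen_items:
            break
        frozen_persons |= new_p
        frozen_items |= new_i
    free_items = [it for it in items if it.item_id not in frozen_items]
    free_persons = [p for p in persons if p.person_id not in frozen_persons]

    trace: list[tuple[int, float, float]] = [
        (0, float("inf"), total_log_likelihood(estimable, free_items, free_persons))
    ]
    by_person = {str(p): g for p, g in estimable.groupby("person_id", sort=True)}
    by_item = {str(i): g for i, g in estimable.groupby("item_id", sort=True)}

    converged = False
    it_count = 0
    for iteration in range(1, max_iter + 1):
        it_count = iteration
        theta_of = {p.person_id: p.theta for p in free_persons}
        # item step (per-item 1-D MLE): b_h given current thetas
        new_items = []
        for it in free_items:
            grp = by_item[it.item_id]
            cor = [(theta_of[str(p)], it.m) for p in grp.loc[grp["score"] == 1, "person_id"]]
            inc = [(theta_of[str(p)], it.m) for p in grp.loc[grp["score"] == 0, "person_id"]]
            new_items.append(_refit_item(cor, inc, it))
        b_of = {it.item_id: (it.b, it.m) for it in new_items}
        # person step: theta_i given new item measures
        new_persons = []
        for p in free_persons:
            grp = by_person[p.person_id]
            cor = [b_of[str(i)] for i in grp.loc[grp["score"] == 1, "item_id"]]
            inc = [b_of[str(i)] for i in grp.loc[grp["score"] == 0, "item_id"]]
            new_persons.append(fit_person(cor, inc, person_id=p.person_id))
        # re-anchor: average (estimable) person back to theta = 0
        shift = float(np.mean([p.theta for p in new_persons]))
        new_persons = [
            PersonEstimate(p.person_id, p.theta - shift, p.se, p.n_items, p.degenerate_flag)
            for p in new_persons
        ]
        new_items = [
            ItemEstimate(i.item_id, i.b - shift, i.ci_low - shift, i.ci_high - shift,
                         i.n_correct, i.n_total, i.m, i.degenerate_flag)
            for i in new_items
        ]
        old = np.array([p.theta for p in free_persons] + [i.b for i in free_items])
        new = np.array([p.theta for p in new_persons] + [i.b for i in new_items])
        max_change = float(np.max(np.abs(new - old)))
        free_items, free_persons = new_items, new_persons
        trace.append((iteration, max_change,
                      total_log_likelihood(estimable, free_items, free_persons)))
        logger.debug("em iter %d: max change %.3g, ll %.6f", iteration, max_change, trace[-1][2])
        if max_change < tol:
            converged = True
            break

    # merge frozen stage-1 estimates back (flagged), preserving calibration order
    items_out = {
        it.item_id: replace(it, degenerate_flag=True) if it.item_id in frozen_items else it
        for it in items
    }
    items_out.update({it.item_id: it for it in free_items})
    persons_out = {
        p.person_id: replace(p, degenerate_flag=True) if p.person_id in frozen_persons else p
        for p in persons
    }
    persons_out.update({p.person_id: p for p in free_persons})
    return FitResult(items=[items_out[it.item_id] for it in items],
                     persons=[persons_out[p.person_id] for p in persons],
                     method="em", n_iterations=it_count, converged=converged,
                     trace=trace)


def summarize_paired_effect(persons_a: Sequence[PersonEstimate],
                            persons_b: Sequence[PersonEstimate],
                            conf: float = 0.95) -> PairedEffect:
    """Mean matched difference theta_b - theta_a with a normal-theory CI.

    The two sets must cover identical person ids; differences are matched
    by id.  Positive values mean condition b improved ability.
    """
    a = {p.person_id: p.theta for p in persons_a}
    b = {p.person_id: p.theta for p in persons_b}
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))[:3]
        only_b = sorted(set(b) - set(a))[:3]
        raise KeyError(f"person id sets differ (e.g. only in a: {only_a}, only in b: {only_b})")
    ids = sorted(a)
    diffs = np.array([b[i] - a[i] for i in ids])
    n = len(diffs)
    mean = float(np.mean(diffs))
    if n > 1:
        sem = float(np.std(diffs, ddof=1) / np.sqrt(n))
    else:
        sem = 0.0
    z = norm.ppf(0.5 + conf / 2.0)
    return PairedEffect(mean, mean - z * sem, mean + z * sem, n, conf)
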