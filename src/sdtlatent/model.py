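"""Model/Results façade over the estimation layer.

``MAFCModel`` holds a validated long-format response table; ``fit`` runs
either the two-stage average-person approximation or the alternating
local-MLE refinement and returns an ``MAFCResults`` carrying the item and
person measure tables, the convergence trace and a printable summary —
the same shape statsmodels users expect from a fitted model.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import estimation
from .estimation import (
    FitResult,
    ItemEstimate,
    PersonEstimate,
    calibrate_items,
    fit_all_persons,
    fit_em,
    validate_responses,
)

__all__ = ["MAFCModel", "MAFCResults"]


def _items_frame(items: Sequence[ItemEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(i.item_id, i.m, i.n_correct, i.n_total, i.b, i.ci_low, i.ci_high,
          i.degenerate_flag) for i in items],
        columns=["item_id", "m", "n_correct", "n_total", "b", "ci_low",
                 "ci_high", "degenerate_flag"],
    )


def _persons_frame(persons: Sequence[PersonEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.person_id, p.n_items, p.theta, p.se, p.degenerate_flag) for p in persons],
        columns=["person_id", "n_items", "theta", "se", "degenerate_flag"],
    )


class MAFCModel:
    """Latent-variable SDT model for m-alternative forced-choice scores.

    Parameters
    ----------
    data : DataFrame
        Long-format scored trials with columns person_id, item_id, m, score
        (one row per trial; at most one trial per person x item pair; a
        single m per item).

    Examples
    --------
    >>> model = MAFCModel(responses)
    >>> res = model.fit(method="two_stage")
    >>> res.items[["item_id", "b", "ci_low", "ci_high"]]
    """

    def __init__(self, data: pd.DataFrame):
        self.data = validate_responses(data)

    @classmethod
    def from_csv(cls, path) -> "MAFCModel":
        from .io import read_responses
        return cls(read_responses(path))

    @property
    def n_persons(self) -> int:
        return self.data["person_id"].nunique()

    @property
    def n_items(self) -> int:
        return self.data["item_id"].nunique()

    def fit(self, method: str = "two_stage", conf: float = 0.95,
            tol: float = 1e-4, max_iter: int = 100) -> "MAFCResults":
        """Estimate item and person measures.

        method="two_stage": items calibrated against the average person
        (theta = 0) by inverting observed proportions, then independent
        person MLEs.  method="em": the two-stage fit refined by alternating
        item/person maximization with mean-person re-anchoring.
        """
        if method in ("two_stage", "approx"):
            items = calibrate_items(self.data, conf=conf)
            persons = fit_all_persons(self.data, items)
            ll = estimation.total_log_likelihood(self.data, items, persons)
            fr = FitResult(items=items, persons=persons, method="approx",
                           n_iterations=0, converged=True,
                           trace=[(0, float("inf"), ll)])
        elif method == "em":
            fr = fit_em(self.data, conf=conf, tol=tol, max_iter=max_iter)
        else:
            raise ValueError(f"unknown method {method!r}; use 'two_stage' or 'em'")
        return MAFCResults(self, fr)


class MAFCResults:
    """Fitted item/person measures on the d' axis.

    Attributes
    ----------
    items, persons : DataFrame
        Item table (item_id, m, n_correct, n_total, b, ci_low, ci_high,
        degenerate_flag) and person table (person_id, n_items, theta, se,
        degenerate_flag).  b and theta are in d' units; b = 0 is chance for
        the average person, negative b means an easier item.
    trace : list of (iteration, max_abs_change, log_likelihood)
    """

    def __init__(self, model: MAFCModel, fit_result: FitResult):
        self.model = model
        self._fr = fit_result
        self.items = _items_frame(fit_result.items)
        self.persons = _persons_frame(fit_result.persons)

    @property
    def method(self) -> str:
        return self._fr.method

    @property
    def converged(self) -> bool:
        return self._fr.converged

    @property
    def n_iterations(self) -> int:
        return self._fr.n_iterations

    @property
    def trace(self) -> list[tuple[int, float, float]]:
        return self._fr.trace

    @property
    def item_estimates(self) -> list[ItemEstimate]:
        return self._fr.items

    @property
    def person_estimates(self) -> list[PersonEstimate]:
        return self._fr.persons

    @property
    def llf(self) -> float:
        """Log-likelihood of the data at the fitted measures."""
        return self._fr.trace[-1][2]

    def predict(self, person_id: str, item_id: str) -> float:
        """Model probability that ``person_id`` scores ``item_id`` correct."""
        from .psychometric import pc_from_dprime
        theta = self.persons.set_index("person_id").loc[str(person_id), "theta"]
        row = self.items.set_index("item_id").loc[str(item_id)]
        return float(pc_from_dprime(float(theta) - float(row["b"]), int(row["m"])))

    def summary(self) -> str:
        it, pe = self.items, self.persons
        lines = [
            "m-AFC latent-variable SDT fit",
            "=" * 46,
            f"method:          {self.method}",
            f"persons:         {len(pe)}  ({int(pe['degenerate_flag'].sum())} degenerate)",
            f"items:           {len(it)}  ({int(it['degenerate_flag'].sum())} degenerate)",
            f"responses:       {len(self.model.data)}",
            f"log-likelihood:  {self.llf:.4f}",
            f"iterations:      {self.n_iterations}  (converged: {self.converged})",
            "-" * 46,
            f"item b:     mean {it['b'].mean():+.4f}   sd {it['b'].std(ddof=1):.4f}",
            f"person th:  mean {pe['theta'].mean():+.4f}   sd {pe['theta'].std(ddof=1):.4f}",
            f"mean person SE:  {np.nanmean(pe['se']):.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<MAFCResults method={self.method!r} items={len(self.items)} "
                f"persons={len(self.persons)} converged={self.converged}>")
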