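"""Dichotomous Rasch baseline and the SDT-vs-Rasch stratification comparison.

The Rasch model assigns success probability logistic(theta_p - b_i) to every
trial, with no chance floor.  Applied to mixed-m forced-choice data this
misattributes the guessing floor to the item: at equal true sensitivity, an
item with more alternatives (lower chance rate) looks *harder* on the logit
scale... or easier, depending on where the cohort sits relative to chance —
the point of the comparison is that the Rasch difficulties of equally
difficult items separate by m, while the SDT measures, which equate chance
at d' = 0 for every m, do not.  ``compare_sdt_rasch`` quantifies this by
regressing Rasch difficulty on SDT measure within each m stratum and
reporting the per-m intercepts with their standard errors.

Estimation is the same joint-MLE machinery and mean-zero person anchoring as
the SDT model, so the two sets of item measures are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from ._jmle import ModelSpec, jmle_fit, joint_se
from .sdt import ScoreTable, SDTResults

__all__ = ["RaschModel", "RaschResults", "fit_rasch", "compare_sdt_rasch"]


class _LogisticLink:
    def evaluate(self, D: np.ndarray):
        p = expit(D)
        dp = p * (1.0 - p)
        return p, dp, dp * (1.0 - 2.0 * p)


class RaschModel:
    """Joint-MLE dichotomous Rasch model on a score table (logit scale)."""

    link_name = "logistic"

    def __init__(self, scores: ScoreTable, spec: ModelSpec | None = None):
        if scores.frame.empty:
            raise ValueError("empty score table")
        self.scores = scores
        self.spec = spec or ModelSpec()
        self.persons, self.items, self.K, self.N = scores.to_matrices()

    def _default_start(self):
        from scipy.special import logit

        rate_p = np.clip(self.K.sum(axis=1) / self.N.sum(axis=1), 0.01, 0.99)
        rate_i = np.clip(self.K.sum(axis=0) / self.N.sum(axis=0), 0.01, 0.99)
        return logit(rate_p), -logit(rate_i)

    def fit(self, start=None, se_method: str = "block") -> "RaschResults":
        theta0, b0 = self._default_start() if start is None else start
        link = _LogisticLink()
        raw = jmle_fit(self.K, self.N, link, self.spec, theta0, b0)
        if se_method == "joint":
            raw.se_theta, raw.se_b = joint_se(self.K, self.N, link, raw.theta,
                                              raw.b, self.spec.epsilon_clip)
        return RaschResults(self, raw)


class RaschResults(SDTResults):
    """Rasch person/item locations in logits; same layout as SDTResults."""

    scale = "logit"

    def summary(self) -> str:
        head = "Rasch (dichotomous JMLE) fit, logit scale"
        return head + "\n" + "=" * len(head) + "\n" + "\n".join(
            super().summary().splitlines()[2:])


def fit_rasch(scores: ScoreTable, spec: ModelSpec | None = None, **kw) -> RaschResults:
    """Fit the dichotomous Rasch model; see :class:`RaschModel`."""
    return RaschModel(scores, spec).fit(**kw)


@dataclass
class StratificationSummary:
    """Per-m regressions of Rasch item difficulty on SDT item measure."""

    table: pd.DataFrame          # item_id, m, b_sdt, b_rasch
    intercepts: pd.DataFrame     # index m; intercept, se, slope, n_items

    def pairwise_separation(self) -> pd.DataFrame:
        """|intercept difference| / combined SE for each m pair."""
        rows = []
        ms = list(self.intercepts.index)
        for i, m1 in enumerate(ms):
            for m2 in ms[i + 1:]:
                d = abs(self.intercepts.loc[m1, "intercept"]
                        - self.intercepts.loc[m2, "intercept"])
                se = np.hypot(self.intercepts.loc[m1, "se"],
                              self.intercepts.loc[m2, "se"])
                rows.append(dict(m1=m1, m2=m2, difference=d, se=se,
                                 separation=d / se if se > 0 else np.inf))
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Rasch vs SDT item measures, marker per m (the stratification plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for m, marker in zip(sorted(self.table["m"].unique()), "^sD"):
            sub = self.table[self.table["m"] == m]
            ax.scatter(sub["b_sdt"], sub["b_rasch"], marker=marker, label=f"m = {m}")
        ax.set_xlabel("SDT item measure (relative d')")
        ax.set_ylabel("Rasch item difficulty (logits)")
        ax.legend()
        return ax


def compare_sdt_rasch(sdt: SDTResults, rasch: RaschResults,
                      m_of_item: dict) -> StratificationSummary:
    """Quantify m-stratification of Rasch difficulties against SDT measures.

    Both fits must cover the identical item set.  Within each m stratum the
    Rasch difficulty is regressed (OLS) on the SDT measure; the returned
    intercepts separate across m when the Rasch model fails to equate chance.
    """
    items_s, items_r = set(sdt.b.index), set(rasch.b.index)
    if items_s != items_r:
        raise ValueError(f"mismatched item sets: {sorted(items_s ^ items_r)}")
    table = pd.DataFrame(
        {"item_id": sdt.b.index,
         "m": [m_of_item[i] for i in sdt.b.index],
         "b_sdt": sdt.b.to_numpy(),
         "b_rasch": rasch.b.reindex(sdt.b.index).to_numpy()})
    rows = {}
    for m, sub in table.groupby("m"):
        if len(sub) >= 2 and sub["b_sdt"].nunique() > 1:
            ols = sm.OLS(sub["b_rasch"], sm.add_constant(sub["b_sdt"])).fit()
            rows[m] = dict(intercept=ols.params["const"], se=ols.bse["const"],
                           slope=ols.params["b_sdt"], n_items=len(sub))
        else:  # degenerate stratum: intercept is the mean offset
            rows[m] = dict(intercept=sub["b_rasch"].mean(),
                           se=sub["b_rasch"].std(ddof=1) / np.sqrt(len(sub))
                           if len(sub) > 1 else np.nan,
                           slope=np.nan, n_items=len(sub))
    intercepts = pd.DataFrame.from_dict(rows, orient="index").rename_axis("m")
    return StratificationSummary(table=table, intercepts=intercepts)
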