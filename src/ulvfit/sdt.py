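"""Signal-detection latent-variable model for m-alternative forced-choice data.

The central computation of the package.  Each trial of an m-AFC task is
modelled under equal-variance Gaussian signal detection theory: the correct
alternative draws from N(d', 1) and the m-1 foils from N(0, 1), giving the
proportion-correct psychometric function

    Pc(d'; m) = integral phi(x - d') * Phi(x)**(m-1) dx,

with Pc(0; m) = 1/m (chance) and, for m = 2, the closed form Phi(d'/sqrt(2)).
Persons and items are placed jointly on a *relative* d' axis: the success
probability of person p on item i is Pc(theta_p - b_i; m_i), and the origin is
anchored at the sample mean ability, so d' = 0 for an item means chance
performance for the average person, and items with b > 0 are performed below
chance by that average person.

Estimation is joint maximum likelihood (see ``_jmle``); standard errors come
from the observed information, and 95% CIs are estimate +/- 1.96 SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from ._jmle import ModelSpec, jmle_fit, joint_se, loglik_matrix

__all__ = [
    "ModelSpec",
    "ScoreTable",
    "score_responses",
    "pc_mafc",
    "inv_pc_mafc",
    "loglik",
    "SDTModel",
    "SDTResults",
    "fit_sdt",
    "standard_errors",
]


# ----------------------------------------------------------------------
# Psychometric function
# ----------------------------------------------------------------------

@lru_cache(maxsize=8)
def _gh_nodes(order: int):
    t, w = np.polynomial.hermite.hermgauss(order)
    return t, w / np.sqrt(np.pi)


def pc_mafc(dprime, m, order: int = 61):
    """Proportion correct of an m-AFC task at sensitivity ``dprime``.

    Gauss-Hermite quadrature (after the change of variables x = sqrt(2) t + d')
    of the equal-variance Gaussian m-AFC integral.  Accepts scalars or
    broadcastable arrays for both arguments; m may be any integer >= 2.
    Strictly increasing in d', with Pc(0; m) = 1/m and limits 0 and 1.
    """
    m = np.asarray(m)
    if np.any(m < 2):
        raise ValueError("m must be >= 2")
    d = np.asarray(dprime, dtype=float)
    t, w = _gh_nodes(order)
    z = norm.cdf(np.sqrt(2.0) * t.reshape((-1,) + (1,) * d.ndim) + d[None])
    out = np.einsum("q...,q->...", z ** (m - 1), w)
    return float(out) if out.ndim == 0 else out


def inv_pc_mafc(p, m, order: int = 61, tol: float = 1e-10):
    """Sensitivity d' at which an m-AFC task yields proportion correct ``p``.

    Root-finding inverse of :func:`pc_mafc`; ``p`` must lie strictly inside
    (0, 1).  Satisfies pc_mafc(inv_pc_mafc(p, m), m) = p to ~1e-10.
    """
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"p={p} outside the open unit interval")
    return brentq(lambda d: pc_mafc(d, m, order) - p, -12.0, 12.0, xtol=tol)


class _SDTLink:
    """m-AFC link with per-item m, evaluated on the P x I offset matrix."""

    def __init__(self, m_items: np.ndarray, order: int = 61):
        self.m = np.asarray(m_items, dtype=float)[None, :]  # 1 x I
        self.t, self.w = _gh_nodes(order)

    def evaluate(self, D: np.ndarray):
        # One Phi evaluation serves p and both derivatives:
        # p   = sum w_q Phi(z_q)^(m-1)
        # p'  = sum w_q sqrt(2) t_q Phi(z_q)^(m-1)
        # p'' = sum w_q (2 t_q^2 - 1) Phi(z_q)^(m-1)
        z = norm.cdf(np.sqrt(2.0) * self.t[:, None, None] + D[None])
        zm = z ** (self.m - 1.0)
        p = np.einsum("qpi,q->pi", zm, self.w)
        dp = np.einsum("qpi,q->pi", zm, self.w * np.sqrt(2.0) * self.t)
        d2p = np.einsum("qpi,q->pi", zm, self.w * (2.0 * self.t**2 - 1.0))
        return p, dp, d2p


# ----------------------------------------------------------------------
# Scores
# ----------------------------------------------------------------------

@dataclass
class ScoreTable:
    """Per-(person, item) success counts: k successes out of n trials.

    ``frame`` has columns person_id, item_id, k, n.  The matrix view used by
    the fitter is exposed through :meth:`to_matrices`; persons and items keep
    a deterministic (sorted) order.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if ((f["k"] < 0) | (f["k"] > f["n"])).any():
            bad = f[(f["k"] < 0) | (f["k"] > f["n"])].iloc[0]
            raise ValueError(f"score out of range for ({bad.person_id}, {bad.item_id})")

    @property
    def persons(self) -> list[str]:
        return sorted(self.frame["person_id"].unique())

    @property
    def items(self) -> list[str]:
        return sorted(self.frame["item_id"].unique())

    def to_matrices(self):
        persons, items = self.persons, self.items
        K = (
            self.frame.pivot_table(index="person_id", columns="item_id", values="k",
                                   aggfunc="sum", fill_value=0)
            .reindex(index=persons, columns=items, fill_value=0)
            .to_numpy(dtype=float)
        )
        N = (
            self.frame.pivot_table(index="person_id", columns="item_id", values="n",
                                   aggfunc="sum", fill_value=0)
            .reindex(index=persons, columns=items, fill_value=0)
            .to_numpy(dtype=float)
        )
        return persons, items, K, N


def score_responses(records: pd.DataFrame) -> ScoreTable:
    """Sum trial-level binary responses into per-(person, item) scores.

    ``records`` needs columns person_id, item_id, trial, correct (0/1); with
    the standard three trials per item the summed score runs 0-3.  Duplicate
    (person, item, trial) keys are an error.
    """
    df = records
    required = {"person_id", "item_id", "trial", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    if not df["correct"].isin([0, 1]).all():
        raise ValueError("correct must be 0 or 1")
    dup = df.duplicated(subset=["person_id", "item_id", "trial"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate trial key ({first.person_id}, {first.item_id}, {first.trial})"
        )
    g = (
        df.groupby(["person_id", "item_id"], sort=True)["correct"]
        .agg(k="sum", n="count")
        .reset_index()
    )
    return ScoreTable(g)


def loglik(scores: ScoreTable, theta: pd.Series, b: pd.Series,
           m_of_item: dict, spec: ModelSpec | None = None) -> float:
    """Bernoulli log-likelihood of a score table at given measures.

    Invariant under adding the same constant to all person and all item
    measures (only differences theta_p - b_i enter the model).
    """
    spec = spec or ModelSpec()
    persons, items, K, N = scores.to_matrices()
    missing_p = [p for p in persons if p not in theta]
    missing_i = [i for i in items if i not in b or i not in m_of_item]
    if missing_p or missing_i:
        raise KeyError(f"missing parameters for persons {missing_p} / items {missing_i}")
    th = np.array([theta[p] for p in persons], dtype=float)
    bb = np.array([b[i] for i in items], dtype=float)
    link = _SDTLink(np.array([m_of_item[i] for i in items]), spec.quadrature_order)
    return loglik_matrix(K, N, link, th, bb, spec.epsilon_clip)


# ----------------------------------------------------------------------
# Model / Results
# ----------------------------------------------------------------------

class SDTModel:
    """Joint SDT latent-variable model for an m-AFC score table.

    Parameters
    ----------
    scores : ScoreTable
        Success counts per (person, item).
    m_of_item : dict
        item_id -> number of response alternatives.
    spec : ModelSpec, optional
        Numerical settings (quadrature order, tolerance, bounds, clipping).

    Examples
    --------
    >>> table = score_responses(records)
    >>> res = SDTModel(table, bank.m_of_item()).fit()
    >>> res.summary()
    """

    link_name = "gaussian_mafc"

    def __init__(self, scores: ScoreTable, m_of_item: dict, spec: ModelSpec | None = None):
        if scores.frame.empty:
            raise ValueError("empty score table")
        self.scores = scores
        self.m_of_item = dict(m_of_item)
        self.spec = spec or ModelSpec()
        self.persons, self.items, self.K, self.N = scores.to_matrices()
        unknown = [i for i in self.items if i not in self.m_of_item]
        if unknown:
            raise KeyError(f"no m given for items {unknown}")
        self.m_items = np.array([self.m_of_item[i] for i in self.items], dtype=int)

    @classmethod
    def from_records(cls, records: pd.DataFrame, spec: ModelSpec | None = None) -> "SDTModel":
        """Build from a trial-level frame carrying its own ``m`` column."""
        m_map = records.drop_duplicates("item_id").set_index("item_id")["m"].to_dict()
        return cls(score_responses(records), m_map, spec)

    def _link(self):
        return _SDTLink(self.m_items, self.spec.quadrature_order)

    def _default_start(self):
        # person/item success rates mapped through the m=2 closed form
        with np.errstate(invalid="ignore"):
            rate_p = np.clip(self.K.sum(axis=1) / self.N.sum(axis=1), 0.01, 0.99)
            rate_i = np.clip(self.K.sum(axis=0) / self.N.sum(axis=0), 0.01, 0.99)
        theta0 = np.sqrt(2.0) * norm.ppf(rate_p)
        b0 = -np.sqrt(2.0) * norm.ppf(rate_i)
        return theta0, b0

    def fit(self, start=None, se_method: str = "block") -> "SDTResults":
        """Maximize the joint likelihood under the mean-zero person anchor.

        ``se_method`` selects the standard-error computation: ``"block"``
        (default; each block's observed information with the other held
        fixed) or ``"joint"`` (pseudo-inverse of the full joint information).
        """
        theta0, b0 = self._default_start() if start is None else start
        link = self._link()
        raw = jmle_fit(self.K, self.N, link, self.spec, theta0, b0)
        if se_method == "joint":
            se_t, se_b = joint_se(self.K, self.N, link, raw.theta, raw.b,
                                  self.spec.epsilon_clip)
            raw.se_theta, raw.se_b = se_t, se_b
        elif se_method != "block":
            raise ValueError(f"unknown se_method {se_method!r}")
        return SDTResults(self, raw, se_method)


class SDTResults:
    """Fitted person and item measures on the relative d' scale.

    Attributes
    ----------
    theta, b : pandas.Series
        Person abilities / item difficulties, indexed by id; mean(theta) = 0.
    se_theta, se_b : pandas.Series
        Standard errors (NaN where the information was singular).
    ci95_theta, ci95_b : pandas.DataFrame
        Estimate +/- 1.96 SE, columns ``low``/``high``.
    at_bound_theta, at_bound_b : pandas.Series of bool
        True where the parameter hit the +/- param_bound cap (perfect or
        zero scorers); their SEs are flagged unreliable.
    loglik, converged, n_iter
        Fit diagnostics.
    """

    scale = "relative d'"

    def __init__(self, model: SDTModel, raw, se_method: str = "block"):
        self.model = model
        self.se_method = se_method
        self.theta = pd.Series(raw.theta, index=model.persons, name="theta")
        self.b = pd.Series(raw.b, index=model.items, name="b")
        self.se_theta = pd.Series(raw.se_theta, index=model.persons, name="se")
        self.se_b = pd.Series(raw.se_b, index=model.items, name="se")
        self.at_bound_theta = pd.Series(raw.at_bound_theta, index=model.persons)
        self.at_bound_b = pd.Series(raw.at_bound_b, index=model.items)
        self.se_unreliable_theta = pd.Series(raw.se_unreliable_theta, index=model.persons)
        self.se_unreliable_b = pd.Series(raw.se_unreliable_b, index=model.items)
        self.loglik = raw.loglik
        self.converged = raw.converged
        self.n_iter = raw.n_iter

    @property
    def ci95_theta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"low": self.theta - 1.96 * self.se_theta,
             "high": self.theta + 1.96 * self.se_theta})

    @property
    def ci95_b(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"low": self.b - 1.96 * self.se_b, "high": self.b + 1.96 * self.se_b})

    def to_frame(self) -> pd.DataFrame:
        """Long table: id, kind (person|item), measure, se, ci_low, ci_high, at_bound."""
        rows = []
        for ids, est, se, at in (
            (self.theta.index, self.theta, self.se_theta, self.at_bound_theta),
            (self.b.index, self.b, self.se_b, self.at_bound_b),
        ):
            kind = "person" if est is self.theta else "item"
            for i in ids:
                rows.append(dict(id=i, kind=kind, measure=est[i], se=se[i],
                                 ci_low=est[i] - 1.96 * se[i],
                                 ci_high=est[i] + 1.96 * se[i],
                                 at_bound=bool(at[i])))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "SDT latent-variable fit (relative d' scale)",
            "=" * 47,
            f"persons: {len(self.theta)}    items: {len(self.b)}",
            f"log-likelihood: {self.loglik:.4f}   converged: {self.converged} "
            f"({self.n_iter} cycles)   se: {self.se_method}",
            f"person measures: mean {self.theta.mean():+.4f}  "
            f"range [{self.theta.min():.2f}, {self.theta.max():.2f}]",
            f"item measures:   range [{self.b.min():.2f}, {self.b.max():.2f}]"
            f"   below-chance items (b > 0): {(self.b > 0).sum()}",
            f"at-bound parameters: {int(self.at_bound_theta.sum() + self.at_bound_b.sum())}",
        ]
        return "\n".join(lines)

    def plot_measures(self, ax=None):
        """Item measures with 95% CI bars, sorted by difficulty."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 8))
        order = self.b.sort_values().index
        y = np.arange(len(order))
        ax.errorbar(self.b[order], y, xerr=1.96 * self.se_b[order], fmt="o", ms=3)
        ax.axvline(0.0, ls="--", lw=0.8, color="grey")
        ax.set_yticks(y, order, fontsize=6)
        ax.set_xlabel("item measure (relative d')")
        return ax


# ----------------------------------------------------------------------
# Spec-level functional wrappers
# ----------------------------------------------------------------------

def fit_sdt(scores: ScoreTable, m_of_item: dict, spec: ModelSpec | None = None,
            **fit_kw) -> SDTResults:
    """Fit the SDT latent-variable model; see :class:`SDTModel`."""
    return SDTModel(scores, m_of_item, spec).fit(**fit_kw)


def standard_errors(scores: ScoreTable, est: SDTResults, m_of_item: dict,
                    method: str = "block") -> SDTResults:
    """Recompute SEs/CIs for an existing fit with the chosen method."""
    model = SDTModel(scores, m_of_item, est.model.spec)
    link = model._link()
    if method == "joint":
        se_t, se_b = joint_se(model.K, model.N, link, est.theta.to_numpy(),
                              est.b.to_numpy(), model.spec.epsilon_clip)
    elif method == "block":
        from ._jmle import split_block_se

        se_t, se_b, _, _ = split_block_se(model.K, model.N, link,
                                          est.theta.to_numpy(), est.b.to_numpy(),
                                          model.spec.epsilon_clip)
    else:
        raise ValueError(f"unknown method {method!r}")
    est.se_theta = pd.Series(se_t, index=model.persons, name="se")
    est.se_b = pd.Series(se_b, index=model.items, name="se")
    est.se_method = method
    return est
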