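"""End-to-end study analysis: score, fit, summarize, test, regress, compare.

Mirrors the calibration study's Results structure: item and person measure
tables with 95% CIs, a Brown-Forsythe test of equal mean item difficulty
across the three task categories, an OLS regression of BRVT acuity on person
measure (slope p-value, r^2, mean absolute error), and the SDT-vs-Rasch
item-measure comparison stratified by m.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import f as f_dist
from scipy.stats import levene

from ._jmle import ModelSpec
from .item_bank import ItemBank, load_item_bank
from .rasch import StratificationSummary, compare_sdt_rasch, fit_rasch
from .sdt import SDTResults, fit_sdt, score_responses

__all__ = ["brown_forsythe", "acuity_regression", "run_pipeline", "AnalysisReport"]


def brown_forsythe(groups, variant: str = "means"):
    """Brown-Forsythe test for equality of group means (or the median variant).

    The default ``variant="means"`` is the heteroscedasticity-robust one-way
    ANOVA statistic

        F* = sum_j n_j (ybar_j - ybar)^2  /  sum_j (1 - n_j/N) s_j^2

    with Satterthwaite-approximated denominator degrees of freedom; the
    numerator df is k - 1 and p comes from the F distribution.
    ``variant="median"`` instead runs the Levene test with median centering
    (a spread test, included because published df patterns of the form
    (k-1, N-k) often correspond to it).

    Returns
    -------
    (F, df1, df2, p) : tuple
        F is NaN (with p = 1.0) when all groups are constant and equal;
        F = 0, p = 1 when group means coincide with positive spread.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for j, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {j} has fewer than 2 values")
    if variant == "median":
        k = len(groups)
        N = sum(g.size for g in groups)
        stat, p = levene(*groups, center="median")
        return float(stat), k - 1, float(N - k), float(p)
    if variant != "means":
        raise ValueError(f"unknown variant {variant!r}")

    n = np.array([g.size for g in groups], dtype=float)
    N = n.sum()
    means = np.array([g.mean() for g in groups])
    variances = np.array([g.var(ddof=1) for g in groups])
    grand = np.concatenate(groups).mean()
    num = float(np.sum(n * (means - grand) ** 2))
    den_terms = (1.0 - n / N) * variances
    den = float(den_terms.sum())
    df1 = len(groups) - 1
    if den <= 0.0:
        # all groups constant; equal means => no evidence against H0
        return (np.nan, df1, np.nan, 1.0) if num <= 1e-300 else (np.inf, df1, np.nan, 0.0)
    c = den_terms / den
    df2 = float(1.0 / np.sum(c**2 / (n - 1.0)))
    F = num / den
    return float(F), df1, df2, float(f_dist.sf(F, df1, df2))


def acuity_regression(person_table: pd.DataFrame):
    """OLS of logMAR acuity on person measure.

    ``person_table`` needs columns ``measure`` and ``logmar``; rows with a
    missing acuity are dropped.  Returns a dict with slope, intercept, the
    two-sided p-value of the slope, r^2 and the mean absolute residual in
    logMAR.  With a constant predictor the slope is undefined and flagged.
    """
    data = person_table[["measure", "logmar"]].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 persons with both measure and acuity")
    if data["measure"].nunique() == 1:
        return dict(slope=0.0, intercept=float(data["logmar"].mean()),
                    p=np.nan, r2=0.0, mae=float((data["logmar"] - data["logmar"].mean()).abs().mean()),
                    n=len(data), slope_undefined=True)
    ols = sm.OLS(data["logmar"], sm.add_constant(data["measure"])).fit()
    # a constant response has zero total variance; define r2 = 0 there
    with np.errstate(divide="ignore"):
        r2 = float(ols.rsquared) if np.isfinite(ols.rsquared) else 0.0
    return dict(slope=float(ols.params["measure"]),
                intercept=float(ols.params["const"]),
                p=float(ols.pvalues["measure"]),
                r2=r2,
                mae=float(np.abs(ols.resid).mean()),
                n=len(data), slope_undefined=False)


@dataclass
class AnalysisReport:
    """All result tables of one pipeline run."""

    item_table: pd.DataFrame
    person_table: pd.DataFrame
    category_stats: dict
    acuity_stats: dict | None
    rasch_comparison: StratificationSummary
    sdt_results: SDTResults
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        """Write every table; byte-identical across runs with equal inputs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.item_table.to_csv(out / "item_measures.csv", index=False)
        self.person_table.to_csv(out / "person_measures.csv", index=False)
        self.rasch_comparison.table.to_csv(out / "rasch_comparison.csv", index=False)
        with open(out / "category_stats.json", "w", encoding="utf-8") as fh:
            json.dump(self.category_stats, fh, indent=1, sort_keys=True)
        if self.acuity_stats is not None:
            with open(out / "acuity_regression.json", "w", encoding="utf-8") as fh:
                json.dump(self.acuity_stats, fh, indent=1, sort_keys=True)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


def _log(msg: str, quiet: bool) -> None:
    if not quiet:
        print(f"[{time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


def run_pipeline(responses: pd.DataFrame | str | Path,
                 bank: ItemBank | str | Path = "canonical",
                 acuity: pd.DataFrame | str | Path | None = None,
                 spec: ModelSpec | None = None,
                 seed: int = 0,
                 bf_variant: str = "means",
                 quiet: bool = True) -> AnalysisReport:
    """Run the full calibration analysis and return an :class:`AnalysisReport`.

    Deterministic given inputs and seed.  Raises on responses referencing
    items absent from the bank (all offending ids listed); an unconverged fit
    is reported in the manifest but the report is still produced.
    """
    spec = spec or ModelSpec()
    if not isinstance(responses, pd.DataFrame):
        responses = pd.read_csv(responses)
    if not isinstance(bank, ItemBank):
        bank = load_item_bank(bank)
    if acuity is not None and not isinstance(acuity, pd.DataFrame):
        acuity = pd.read_csv(acuity)

    m_of_item = bank.m_of_item()
    unknown = sorted(set(responses["item_id"]) - set(m_of_item))
    if unknown:
        raise ValueError(f"responses reference unknown item ids: {unknown}")

    _log("scoring responses", quiet)
    scores = score_responses(responses)
    _log(f"fitting SDT model ({len(scores.persons)} persons, {len(scores.items)} items)", quiet)
    sdt = fit_sdt(scores, m_of_item, spec)
    _log("fitting Rasch baseline", quiet)
    rasch = fit_rasch(scores, spec)
    comparison = compare_sdt_rasch(sdt, rasch, m_of_item)

    items_meta = bank.items_frame().set_index("item_id")
    item_table = pd.DataFrame(
        {"item_id": sdt.b.index,
         "measure": sdt.b.to_numpy(),
         "se": sdt.se_b.to_numpy(),
         "ci_low": (sdt.b - 1.96 * sdt.se_b).to_numpy(),
         "ci_high": (sdt.b + 1.96 * sdt.se_b).to_numpy(),
         "at_bound": sdt.at_bound_b.to_numpy()})
    for col in ("category", "level", "m", "activity_id"):
        item_table[col] = items_meta.reindex(item_table["item_id"])[col].to_numpy()

    person_table = pd.DataFrame(
        {"person_id": sdt.theta.index,
         "measure": sdt.theta.to_numpy(),
         "se": sdt.se_theta.to_numpy(),
         "ci_low": (sdt.theta - 1.96 * sdt.se_theta).to_numpy(),
         "ci_high": (sdt.theta + 1.96 * sdt.se_theta).to_numpy(),
         "at_bound": sdt.at_bound_theta.to_numpy()})
    if acuity is not None:
        person_table = person_table.merge(
            acuity.rename(columns={"logmar": "logmar"}), on="person_id", how="left")

    _log(f"category test (Brown-Forsythe, {bf_variant})", quiet)
    cats = sorted(item_table["category"].dropna().unique())
    groups = [item_table.loc[item_table["category"] == c, "measure"].to_numpy() for c in cats]
    F, df1, df2, p = brown_forsythe(groups, variant=bf_variant)
    category_stats = {
        "categories": {
            c: {"mean": float(g.mean()), "sd": float(g.std(ddof=1)), "n_items": int(g.size)}
            for c, g in zip(cats, groups)},
        "brown_forsythe": {"F": None if np.isnan(F) else float(F), "df1": int(df1),
                           "df2": None if np.isnan(df2) else float(df2), "p": float(p),
                           "variant": bf_variant}}

    acuity_stats = None
    if acuity is not None and person_table["logmar"].notna().sum() >= 3:
        _log("acuity regression", quiet)
        acuity_stats = acuity_regression(person_table)

    manifest = dict(
        seed=int(seed),
        n_persons=len(scores.persons),
        n_items=len(scores.items),
        sdt_converged=bool(sdt.converged),
        rasch_converged=bool(rasch.converged),
        sdt_loglik=float(sdt.loglik),
        rasch_loglik=float(rasch.loglik),
        bf_variant=bf_variant,
        model_spec=dict(quadrature_order=spec.quadrature_order, max_iter=spec.max_iter,
                        tol=spec.tol, param_bound=spec.param_bound,
                        epsilon_clip=spec.epsilon_clip),
        ulvfit_version=_pkg_version("ulvfit"))

    return AnalysisReport(item_table=item_table, person_table=person_table,
                          category_stats=category_stats, acuity_stats=acuity_stats,
                          rasch_comparison=comparison, sdt_results=sdt,
                          manifest=manifest)
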