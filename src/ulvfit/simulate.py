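"""Synthetic m-AFC response data emulating the calibration study design.

The study's raw responses are not publicly deposited, so every pipeline stage
is exercised on generated data with the same statistical structure: a cohort
of 37 ultra-low-vision participants with abilities spanning roughly -0.74 to
2.2 relative d', the 57-item bank with difficulties spanning roughly -1.09 to
0.39, three Bernoulli trials per person-item cell with success probability
Pc(theta_p - b_i; m_i), and BRVT visual acuities in 2.0-3.5 logMAR weakly
(r^2 ~ 0.2) anti-correlated with ability.

One master seed drives independent substreams for abilities, difficulties,
trial outcomes and acuities, so changing one component leaves the others'
draws untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .item_bank import ItemBank
from .sdt import pc_mafc

__all__ = ["AcuityLink", "SimulationConfig", "SyntheticDataset",
           "simulate_responses", "simulate_acuity"]


@dataclass
class AcuityLink:
    """Linear link from ability (relative d') to BRVT acuity (logMAR).

    acuity = intercept + slope * theta + N(0, noise_sd), clipped to ``clip``.
    Defaults were calibrated once so that with the default ability
    distribution the squared correlation with theta is ~0.2 and the mean
    acuity ~3.2 logMAR (slope negative: better ability -> lower logMAR).
    """

    intercept: float = 3.3
    slope: float = -0.25
    noise_sd: float = 0.40
    clip: tuple[float, float] = (2.0, 3.5)

    def __post_init__(self) -> None:
        if self.clip[0] >= self.clip[1]:
            raise ValueError("acuity clip bounds must be ordered")


@dataclass
class SimulationConfig:
    """Generative settings mirroring the calibration study.

    theta_dist : {"kind": "uniform", "low": .., "high": ..} or
                 {"kind": "normal", "mean": .., "sd": ..}, in relative d'.
    b_values   : explicit per-item difficulty vector (aligned with the bank's
                 item order) or a distribution dict as for theta_dist.
    """

    n_persons: int = 37
    theta_dist: dict = field(default_factory=lambda: dict(kind="uniform", low=-0.74, high=2.2))
    b_values: dict | list | np.ndarray = field(
        default_factory=lambda: dict(kind="uniform", low=-1.09, high=0.39))
    trials_per_item: int = 3
    seed: int = 0
    acuity_link: AcuityLink = field(default_factory=AcuityLink)

    def __post_init__(self) -> None:
        if self.n_persons < 2:
            raise ValueError("n_persons must be >= 2")
        if self.trials_per_item < 1:
            raise ValueError("trials_per_item must be >= 1")
        if isinstance(self.acuity_link, dict):
            self.acuity_link = AcuityLink(**self.acuity_link)


@dataclass
class SyntheticDataset:
    """Generated trial records plus the generating truth."""

    records: pd.DataFrame          # person_id, item_id, m, trial, correct
    theta_true: pd.Series
    b_true: pd.Series
    acuity: pd.Series              # logMAR per person
    config: SimulationConfig

    def truth_frame(self) -> pd.DataFrame:
        """Long truth table: id, kind, true_value."""
        a = pd.DataFrame({"id": self.theta_true.index, "kind": "person",
                          "true_value": self.theta_true.to_numpy()})
        b = pd.DataFrame({"id": self.b_true.index, "kind": "item",
                          "true_value": self.b_true.to_numpy()})
        return pd.concat([a, b], ignore_index=True)


def _draw(rng: np.random.Generator, dist: dict, size: int) -> np.ndarray:
    kind = dist.get("kind", "uniform")
    if kind == "uniform":
        return rng.uniform(dist["low"], dist["high"], size)
    if kind == "normal":
        return rng.normal(dist["mean"], dist["sd"], size)
    raise ValueError(f"unknown distribution kind {kind!r}")


def _substreams(seed: int, n: int = 4):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(int(seed)).spawn(n)]


def simulate_responses(bank: ItemBank, config: SimulationConfig | None = None) -> SyntheticDataset:
    """Draw a full synthetic response set from the generative SDT model.

    Each trial is Bernoulli with success probability
    ``pc_mafc(theta*_p - b*_i, m_i)``; the drawn abilities are re-centered to
    mean zero so the generating scale matches the fitted (anchored) scale.
    Identical (bank, config) including seed reproduce the dataset exactly.
    """
    config = config or SimulationConfig()
    rng_theta, rng_b, rng_trials, rng_acuity = _substreams(config.seed)

    person_ids = [f"P{i + 1:03d}" for i in range(config.n_persons)]
    items = bank.items_frame()
    n_items = len(items)

    theta = _draw(rng_theta, config.theta_dist, config.n_persons)
    theta = theta - theta.mean()
    if isinstance(config.b_values, dict):
        b = _draw(rng_b, config.b_values, n_items)
    else:
        b = np.asarray(config.b_values, dtype=float)
        if b.shape != (n_items,):
            raise ValueError(f"b_values must have length {n_items}")

    m_items = items["m"].to_numpy()
    p_correct = pc_mafc(theta[:, None] - b[None, :], m_items[None, :])
    T = config.trials_per_item
    correct = rng_trials.random((config.n_persons, n_items, T)) < p_correct[:, :, None]

    P, I = np.meshgrid(np.arange(config.n_persons), np.arange(n_items), indexing="ij")
    records = pd.DataFrame(
        {"person_id": np.repeat([person_ids[p] for p in P.ravel()], T),
         "item_id": np.repeat(items["item_id"].to_numpy()[I.ravel()], T),
         "m": np.repeat(m_items[I.ravel()], T),
         "trial": np.tile(np.arange(1, T + 1), config.n_persons * n_items),
         "correct": correct.reshape(-1).astype(int)})

    theta_s = pd.Series(theta, index=person_ids, name="theta_true")
    acuity = simulate_acuity(theta_s, config.acuity_link, rng=rng_acuity)
    return SyntheticDataset(
        records=records,
        theta_true=theta_s,
        b_true=pd.Series(b, index=items["item_id"], name="b_true"),
        acuity=acuity,
        config=config)


def simulate_acuity(theta_true: pd.Series, link: AcuityLink | None = None,
                    seed: int | None = None, rng: np.random.Generator | None = None) -> pd.Series:
    """BRVT-style logMAR acuities linearly linked to ability with noise.

    ``acuity = intercept + slope * theta + N(0, noise_sd)``, clipped to the
    link's logMAR range (default 2.0-3.5).
    """
    link = link or AcuityLink()
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else int(seed))
    theta = np.asarray(theta_true, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta_true must be finite")
    acuity = link.intercept + link.slope * theta
    if link.noise_sd > 0:
        acuity = acuity + rng.normal(0.0, link.noise_sd, theta.shape)
    acuity = np.clip(acuity, *link.clip)
    index = theta_true.index if isinstance(theta_true, pd.Series) else None
    return pd.Series(acuity, index=index, name="logmar")
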