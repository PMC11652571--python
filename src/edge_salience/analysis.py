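"""Signal-detection analysis of yes/no melody-detection responses.

The chain runs: response table → per-cell hit/false-alarm rates →
per-participant d′ → cohort contrasts (presentation-order effect and
edge-minus-middle effect) with participant-bootstrap confidence intervals
→ mixed-effects and binomial-GLM contrasts.

d′ is the equal-variance yes/no sensitivity z(hit rate) − z(false-alarm
rate).  Perfect cells would make it infinite, so a log-linear correction
(0.5 added to each count, 1 to each total) is applied by default; a
1/(2N) rate clamp is available instead.  Cohort means are means of
participant means, and all confidence intervals are percentile bootstrap
intervals resampling participants (not trials) with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .experiment_design import ABSOLUTE_EDGE, CENTER, RELATIVE_EDGE

DEFAULT_B = 10_000


# ---------------------------------------------------------------- rates

def compute_rates(responses: pd.DataFrame,
                  grouping: list[str] = ("participant",)) -> pd.DataFrame:
    """Aggregate a response table to per-cell detection counts.

    Returns one row per cell defined by ``grouping`` with columns
    ``n_present``, ``n_absent``, ``hits``, ``false_alarms``.
    """
    required = {"present", "response"}
    missing = required - set(responses.columns)
    if missing:
        raise KeyError(f"response table lacks columns {sorted(missing)}")
    grouping = list(grouping)
    g = responses.groupby(grouping, sort=True)
    out = g.apply(
        lambda d: pd.Series({
            "n_present": int((d["present"] == 1).sum()),
            "n_absent": int((d["present"] == 0).sum()),
            "hits": int(((d["present"] == 1) & (d["response"] == 1)).sum()),
            "false_alarms": int(((d["present"] == 0) & (d["response"] == 1)).sum()),
        }),
        include_groups=False,
    ).reset_index()
    return out


# ---------------------------------------------------------------- d-prime

def dprime(hits: int, n_present: int, false_alarms: int, n_absent: int,
           correction: str | None = "loglinear") -> float:
    """Equal-variance yes/no sensitivity, z(hit rate) − z(false-alarm rate).

    ``correction='loglinear'`` (default) adds 0.5 to each count and 1 to
    each total, keeping perfect cells finite.  ``correction='clamp'``
    limits rates to [1/(2N), 1 − 1/(2N)].  ``correction=None`` uses the
    raw rates and may return ±inf.
    """
    if n_present <= 0 or n_absent <= 0:
        raise ValueError("d' undefined for a cell with no present or no absent trials")
    if not (0 <= hits <= n_present and 0 <= false_alarms <= n_absent):
        raise ValueError("counts exceed their totals")
    if correction == "loglinear":
        h = (hits + 0.5) / (n_present + 1.0)
        f = (false_alarms + 0.5) / (n_absent + 1.0)
    elif correction == "clamp":
        h = np.clip(hits / n_present, 0.5 / n_present, 1 - 0.5 / n_present)
        f = np.clip(false_alarms / n_absent, 0.5 / n_absent, 1 - 0.5 / n_absent)
    elif correction is None:
        h = hits / n_present
        f = false_alarms / n_absent
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


def dprime_table(responses: pd.DataFrame,
                 grouping: list[str] = ("participant",),
                 correction: str | None = "loglinear") -> pd.DataFrame:
    """Per-cell d′ from a response table (rates → d′ in one step)."""
    rates = compute_rates(responses, grouping)
    rates["dprime"] = [
        dprime(r.hits, r.n_present, r.false_alarms, r.n_absent, correction)
        for r in rates.itertuples()
    ]
    return rates


# ---------------------------------------------------------------- bootstrap

def bootstrap_ci(values, statistic=np.mean, b: int = DEFAULT_B,
                 level: float = 0.95,
                 rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Percentile bootstrap CI, resampling sampling units with replacement.

    ``values`` holds one entry per independent unit (here: participants).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("bootstrap CI needs at least two sampling units")
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, n, size=(b, n))
    reps = np.apply_along_axis(statistic, 1, values[idx]) \
        if statistic is not np.mean else values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(reps, alpha)), float(np.quantile(reps, 1 - alpha)))


# ---------------------------------------------------------------- edge effect

def _edge_mid_bands(responses: pd.DataFrame) -> tuple[set, set]:
    bands = sorted(responses["target_band"].unique())
    return {bands[0], bands[-1]}, set(bands[1:-1])


_RANGE_POOLS = {"low": (1, 2, 3, 4), "high": (3, 4, 5, 6)}


def _has_ranges(responses: pd.DataFrame) -> bool:
    if "range_block" not in responses.columns:
        return False
    vals = set(responses["range_block"].dropna().astype(str))
    return bool(vals & set(_RANGE_POOLS))


def _is_edge_band(responses: pd.DataFrame) -> pd.Series:
    """True where the target band is the extreme band of its trial's range.

    Split-range designs classify per range (first/last of the 4-band
    pool); otherwise the extremes of the whole band set are the edges.
    """
    if _has_ranges(responses):
        return pd.Series(
            [tb in (_RANGE_POOLS[rb][0], _RANGE_POOLS[rb][-1])
             for tb, rb in zip(responses["target_band"],
                               responses["range_block"].astype(str))],
            index=responses.index)
    edge_bands, _ = _edge_mid_bands(responses)
    return responses["target_band"].isin(edge_bands)


@dataclass
class EdgeEffectResult:
    """Per-participant edge-minus-middle d′ contrast and its cohort summary.

    Positive values mean an edge advantage.
    """

    per_participant: pd.Series
    mean: float
    ci: tuple[float, float]
    edge_mean: float
    mid_mean: float


def edge_contrast(edge_mean: float, mid_mean: float) -> float:
    """Edge-minus-middle sensitivity difference (positive = edge advantage)."""
    return edge_mean - mid_mean


def order_contrast(tm_mean: float, mt_mean: float) -> float:
    """Target-Mixture minus Mixture-Target sensitivity difference.

    Positive = advantage of hearing the cue before the mixture.
    """
    return tm_mean - mt_mean


def edge_effect(responses: pd.DataFrame, b: int = DEFAULT_B,
                center_only: bool = True,
                rng: np.random.Generator | None = None) -> EdgeEffectResult:
    """Edge-minus-middle d′ contrast per participant, with a bootstrap CI.

    Edge cells are the first and last frequency band of each trial's
    range; middle cells are the interior bands.  With ``center_only``
    (the default, relevant to split-range designs with muting), interior-
    band present trials are kept only when the target was genuinely
    flanked by active bands on both sides (design-classified ``center``);
    trials where muting promoted the target to a relative edge are
    excluded from the middle cells.
    """
    if len(responses["target_band"].unique()) < 3:
        raise ValueError("need at least three bands to contrast edge vs middle")
    is_edge = _is_edge_band(responses)
    df_edge = responses[is_edge]
    df_mid = responses[~is_edge]
    if center_only and "edge_class" in responses.columns:
        keep = (responses["present"] == 0) \
            | (responses["edge_class"] != RELATIVE_EDGE)
        df_mid = responses[~is_edge & keep]
    per = {}
    for label, df in [("edge", df_edge), ("mid", df_mid)]:
        t = dprime_table(df, ["participant", "target_band"])
        per[label] = t.groupby("participant")["dprime"].mean()
    delta = (per["edge"] - per["mid"]).dropna()
    ci = bootstrap_ci(delta.values, b=b, rng=rng)
    return EdgeEffectResult(
        per_participant=delta,
        mean=float(delta.mean()),
        ci=ci,
        edge_mean=float(per["edge"].mean()),
        mid_mean=float(per["mid"].mean()),
    )


def order_effect(responses: pd.DataFrame, b: int = DEFAULT_B,
                 rng: np.random.Generator | None = None) -> dict:
    """Cohort d′ per presentation order and the TM-minus-MT difference."""
    t = dprime_table(responses, ["participant", "order"])
    means = t.groupby("order")["dprime"].mean()
    wide = t.pivot(index="participant", columns="order", values="dprime")
    diff = (wide["TM"] - wide["MT"]).dropna()
    return {
        "tm_mean": float(means["TM"]),
        "mt_mean": float(means["MT"]),
        "difference": float(diff.mean()),
        "ci": bootstrap_ci(diff.values, b=b, rng=rng),
    }


# ---------------------------------------------------------------- models

@dataclass
class ModelFit:
    """Coefficients and tests from a (generalized) mixed or linear model."""

    formula: str
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    random_intercept_var: float | None = None
    extra: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        """Coefficient by exact name, or by unique substring match."""
        if name in self.params.index:
            return float(self.params[name])
        hits = [n for n in self.params.index if name in n]
        if len(hits) != 1:
            raise KeyError(
                f"{name!r} matches {hits!r} in {list(self.params.index)}")
        return float(self.params[hits[0]])


def _participant_cell_table(responses: pd.DataFrame, center_only: bool = True,
                            correction: str | None = "loglinear") -> pd.DataFrame:
    """Participant × (order, band[, range]) d′ cells with model predictors."""
    cols = ["participant", "order", "target_band"]
    ranged = _has_ranges(responses)
    if ranged:
        cols.append("range_block")
    df = responses
    if center_only and "edge_class" in responses.columns:
        keep = ((responses["present"] == 0)
                | (responses["edge_class"] != RELATIVE_EDGE))
        df = responses[keep]
    cells = dprime_table(df, cols, correction)
    cells["order_tm"] = (cells["order"] == "TM").astype(int)
    cells["edge"] = _is_edge_band(cells).astype(int)
    if ranged:
        cells["range_high"] = (cells["range_block"] == "high").astype(int)
    cells["band"] = cells["target_band"].astype(float)
    for msi in ("msi_training", "msi_perception"):
        if msi in responses.columns:
            per = responses.groupby("participant")[msi].first()
            # standardized so the covariate scale cannot dominate conditioning
            sd = per.std()
            if sd > 0:
                per = (per - per.mean()) / sd
            cells = cells.merge(per.reset_index(), on="participant")
    return cells


def _fit_mixedlm(formula: str, cells: pd.DataFrame, smf):
    """Fit a random-intercept MixedLM, trying a couple of optimizers."""
    last = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return smf.mixedlm(formula, cells,
                                   groups=cells["participant"]).fit(
                    reml=True, method=method)
        except np.linalg.LinAlgError as e:
            last = e
    raise RuntimeError(
        f"singular mixed-model fit for {formula!r}: {last}; check for "
        "collinear or constant predictors")


def fit_mixed_model(responses: pd.DataFrame, center_only: bool = True,
                    include_msi: bool = True,
                    extra_fixed: list[str] | None = None) -> ModelFit:
    """Linear mixed model of participant-cell d′ with random intercepts.

    Fixed effects follow the task's standard analysis: presentation order
    (binary, 1 = Target-Mixture), edge position (binary, 1 = outermost
    band of the range), their interaction, frequency band (numeric), the
    range indicator when the design has one, and musical-sophistication
    scores when present.  Delegates estimation to statsmodels' MixedLM.
    """
    import statsmodels.formula.api as smf

    cells = _participant_cell_table(responses, center_only)
    terms = ["order_tm", "edge", "order_tm:edge", "band"]
    if "range_high" in cells.columns:
        terms.append("range_high")
    if include_msi:
        terms += [m for m in ("msi_training", "msi_perception")
                  if m in cells.columns]
    terms += list(extra_fixed or [])
    formula = "dprime ~ " + " + ".join(terms)
    fit = _fit_mixedlm(formula, cells, smf)
    fe = [p for p in fit.params.index if p != "Group Var"]
    return ModelFit(
        formula=formula,
        params=fit.params[fe],
        tvalues=fit.tvalues[fe],
        pvalues=fit.pvalues[fe],
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        extra={"n_cells": len(cells)},
    )


def hit_rate_edge_analysis(responses: pd.DataFrame, b: int = DEFAULT_B,
                           rng: np.random.Generator | None = None
                           ) -> tuple[ModelFit, pd.DataFrame]:
    """Within-band relative-edge analysis of hit rates (present trials).

    In split-range designs, muting the outermost band sometimes leaves an
    interior-band target as the extreme active band (a "relative edge").
    Because the frequency band is identical across the two classes, a
    relative-edge advantage isolates the scene-relative component of the
    edge effect.  Hit rates are bounded, so the class contrast is fit with
    a binomial (logit) GLM on per-trial hits; class-wise rates come with
    participant-bootstrap CIs.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    present = responses[responses["present"] == 1].copy()
    inner = present[present["edge_class"].isin([RELATIVE_EDGE, CENTER])].copy()
    if inner.empty or inner["edge_class"].nunique() < 2:
        raise ValueError("need both relative-edge and center present trials")
    inner["relative_edge"] = (inner["edge_class"] == RELATIVE_EDGE).astype(int)
    inner["order_tm"] = (inner["order"] == "TM").astype(int)
    formula = "response ~ relative_edge + order_tm + target_band"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.glm(formula, inner, family=sm.families.Binomial()).fit()
    rates = []
    for cls, df in inner.groupby("edge_class"):
        per = df.groupby("participant")["response"].mean()
        ci = bootstrap_ci(per.values, b=b, rng=rng)
        rates.append({"edge_class": cls, "hit_rate": float(per.mean()),
                      "ci_low": ci[0], "ci_high": ci[1],
                      "n_trials": len(df)})
    mf = ModelFit(formula=formula, params=fit.params, tvalues=fit.tvalues,
                  pvalues=fit.pvalues, extra={"n_trials": len(inner)})
    return mf, pd.DataFrame(rates)


def adjacent_muting_contrast(responses: pd.DataFrame) -> ModelFit:
    """Contrast targets whose muted band was adjacent vs non-adjacent.

    Uses present trials that carry a muted band.  Each (participant,
    order, adjacency) cell's hits are paired with the participant-order
    false alarms from absent trials to form d′, then a mixed model with
    random participant intercepts tests the adjacency main effect and its
    interaction with presentation order.  A homogeneous observer yields a
    null contrast.
    """
    import statsmodels.formula.api as smf

    present = responses[(responses["present"] == 1)
                        & (responses["muted_band"] >= 0)].copy()
    if present.empty:
        raise ValueError("no muted-band present trials (needs the fixed-density design)")
    present["adjacent"] = (
        (present["muted_band"] - present["target_band"]).abs() == 1).astype(int)
    hits = present.groupby(["participant", "order", "adjacent"]).agg(
        hits=("response", "sum"), n_present=("response", "size")).reset_index()
    absent = responses[responses["present"] == 0]
    fas = absent.groupby(["participant", "order"]).agg(
        false_alarms=("response", "sum"), n_absent=("response", "size")).reset_index()
    cells = hits.merge(fas, on=["participant", "order"])
    cells["dprime"] = [
        dprime(r.hits, r.n_present, r.false_alarms, r.n_absent)
        for r in cells.itertuples()
    ]
    cells["order_tm"] = (cells["order"] == "TM").astype(int)
    formula = "dprime ~ adjacent + order_tm + adjacent:order_tm"
    fit = _fit_mixedlm(formula, cells, smf)
    fe = [p for p in fit.params.index if p != "Group Var"]
    return ModelFit(formula=formula, params=fit.params[fe],
                    tvalues=fit.tvalues[fe], pvalues=fit.pvalues[fe],
                    random_intercept_var=float(fit.cov_re.iloc[0, 0]),
                    extra={"n_cells": len(cells)})


def covariate_r2(per_participant_dprime, covariate) -> float:
    """Squared Pearson correlation between participant d′ and a covariate."""
    d = np.asarray(per_participant_dprime, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if len(d) != len(c) or len(d) < 3:
        raise ValueError("need >= 3 paired participant values")
    if np.std(c) == 0 or np.std(d) == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    r, _ = stats.pearsonr(d, c)
    return float(r ** 2)
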