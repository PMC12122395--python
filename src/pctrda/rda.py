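"""Sharp regression discontinuity at procalcitonin cut-points.

The estimand is the jump, at a pre-specified PCT cut-point ``c``, in the
probability that an encounter receives a full antibiotic course. Treatment
is sharp — ``T = 1{X >= c}`` with running variable ``X`` the first reported
PCT — and estimation is local to a symmetric bandwidth window ``[c-h, c+h)``
with a uniform kernel.

Model: a logit-link GLM of the binary outcome on ``{1, T, X-c, T*(X-c)}``
(local-linear on each side, so a smooth prescribing gradient is absorbed by
the slope terms and only a genuine discontinuity loads on ``T``). The jump
is the difference of the model-implied probabilities at ``X -> c`` from
above vs below; its CI comes from the delta method. Alongside the model, a
raw 2x2 odds ratio of full-course above vs below the cut-point within the
window is reported with a Wald log-scale CI (Haldane 0.5 correction when a
cell is empty, flagged).

``sensitivity_grid`` runs the full factorial of cut-points x bandwidths x
level-of-care strata; degenerate cells (no observations on a side) are
flagged and never abort the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "RdaSpec",
    "RdaResult",
    "bandwidth_window",
    "fit_rda",
    "sensitivity_grid",
    "primary_specs",
    "DEFAULT_CUTPOINTS",
    "DEFAULT_BANDWIDTHS",
    "DEFAULT_STRATA",
]

#: Early procalcitonin-algorithm decision thresholds, ng/mL.
DEFAULT_CUTPOINTS = (0.1, 0.25, 0.5)
#: Sensitivity-analysis bandwidths, ng/mL.
DEFAULT_BANDWIDTHS = (0.03, 0.05, 0.10)
DEFAULT_STRATA = ("all", "floor", "stepdown", "icu")

#: Primary-analysis bandwidth per cut-point: wider at 0.5 ng/mL, where the
#: assay's relative analytical variability is larger.
PRIMARY_BANDWIDTHS = {0.1: 0.05, 0.25: 0.05, 0.5: 0.10}


@dataclass(frozen=True)
class RdaSpec:
    """One grid cell: cut-point, bandwidth, stratum, significance level."""

    cutpoint: float
    bandwidth: float
    stratum: str = "all"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.cutpoint <= 0:
            raise ValueError("cutpoint must be positive")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class RdaResult:
    """Estimates for one grid cell.

    ``jump`` is the model-based discontinuity in probability at the
    cut-point; ``odds_ratio`` is the raw within-window 2x2 OR (above vs
    below). ``flags`` records fallbacks: ``degenerate`` (a side has no
    observations), ``haldane`` (0.5 added to an empty 2x2 cell),
    ``separation`` (model fallback to the difference in proportions with a
    score CI).
    """

    spec: RdaSpec
    n_below: int = 0
    n_above: int = 0
    k_below: int = 0
    k_above: int = 0
    jump: float = np.nan
    jump_ci: tuple[float, float] = (np.nan, np.nan)
    odds_ratio: float = np.nan
    or_ci: tuple[float, float] = (np.nan, np.nan)
    p_value: float = np.nan
    flags: list[str] = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags

    def to_dict(self) -> dict:
        return {
            "cutpoint": self.spec.cutpoint,
            "bandwidth": self.spec.bandwidth,
            "stratum": self.spec.stratum,
            "n_below": self.n_below,
            "n_above": self.n_above,
            "k_below": self.k_below,
            "k_above": self.k_above,
            "jump": self.jump,
            "jump_ci_low": self.jump_ci[0],
            "jump_ci_high": self.jump_ci[1],
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci[0],
            "or_ci_high": self.or_ci[1],
            "p_value": self.p_value,
            "flags": ";".join(self.flags),
        }


def bandwidth_window(
    cutpoint: float, bandwidth: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Half-open windows ``below=[c-h, c)`` and ``above=[c, c+h)``.

    A value exactly at the cut-point is *above* (the lab reports values at
    or over the threshold as abnormal, and 2-decimal bins like 0.25-0.29
    sit above a 0.25 cut-point). A window reaching below zero is truncated
    at zero with a warning, since concentrations cannot be negative.
    """
    if cutpoint <= 0 or bandwidth <= 0:
        raise ValueError("cutpoint and bandwidth must be positive")
    lo = cutpoint - bandwidth
    if lo < 0:
        warnings.warn(
            f"window [c-h, c) for c={cutpoint}, h={bandwidth} truncated at 0",
            stacklevel=2,
        )
        lo = 0.0
    return (lo, cutpoint), (cutpoint, cutpoint + bandwidth)


def _raw_or(k_b: int, n_b: int, k_a: int, n_a: int, alpha: float):
    """2x2 odds ratio (above vs below) with Wald CI on the log scale."""
    cells = np.array(
        [k_a, n_a - k_a, k_b, n_b - k_b], dtype=float
    )  # a_full, a_not, b_full, b_not
    flags = []
    if (cells == 0).any():
        cells = cells + 0.5
        flags.append("haldane")
    orr = (cells[0] / cells[1]) / (cells[2] / cells[3])
    se = np.sqrt((1.0 / cells).sum())
    z = norm.ppf(1 - alpha / 2)
    ci = (float(np.exp(np.log(orr) - z * se)), float(np.exp(np.log(orr) + z * se)))
    return float(orr), ci, flags


def _score_ci_diff(k_a, n_a, k_b, n_b, alpha):
    from statsmodels.stats.proportion import confint_proportions_2indep

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return confint_proportions_2indep(
            k_a, n_a, k_b, n_b, method="score", compare="diff", alpha=alpha
        )


def fit_rda(cohort: pd.DataFrame, spec: RdaSpec) -> RdaResult:
    """Fit one RDA cell on a cohort with ``pct_value``, ``outcome_full``
    and (for stratified specs) ``loc`` columns.

    Falls back to the difference in proportions with a score CI (flagged
    ``separation``) when the local-linear logit cannot be fit stably, e.g.
    under complete separation. Returns a flagged degenerate result — never
    raises — when a side of the window is empty.
    """
    df = cohort
    if spec.stratum != "all":
        df = df[df["loc"] == spec.stratum]
    (lo, c), (_, hi) = bandwidth_window(spec.cutpoint, spec.bandwidth)
    x = df["pct_value"].to_numpy(dtype=float)
    m = (x >= lo) & (x < hi)
    x = x[m]
    y = df["outcome_full"].to_numpy(dtype=bool)[m].astype(float)
    t = (x >= c).astype(float)

    res = RdaResult(spec=spec)
    res.n_below = int((t == 0).sum())
    res.n_above = int((t == 1).sum())
    res.k_below = int(y[t == 0].sum())
    res.k_above = int(y[t == 1].sum())
    if res.n_below == 0 or res.n_above == 0:
        res.flags.append("degenerate")
        return res

    orr, or_ci, or_flags = _raw_or(
        res.k_below, res.n_below, res.k_above, res.n_above, spec.alpha
    )
    res.odds_ratio, res.or_ci = orr, or_ci
    res.flags.extend(or_flags)

    xc = x - c
    X = np.column_stack([np.ones_like(x), t, xc, t * xc])
    z = norm.ppf(1 - spec.alpha / 2)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        beta, cov = fit.params, fit.cov_params()
        if not (np.all(np.isfinite(fit.bse)) and fit.bse[1] < 50):
            raise RuntimeError("unstable fit (separation)")
        p1 = expit(beta[0] + beta[1])
        p0 = expit(beta[0])
        res.jump = float(p1 - p0)
        grad = np.array([p1 * (1 - p1) - p0 * (1 - p0), p1 * (1 - p1), 0.0, 0.0])
        se_jump = float(np.sqrt(grad @ cov @ grad))
        res.jump_ci = (res.jump - z * se_jump, res.jump + z * se_jump)
        res.p_value = float(2 * norm.sf(abs(beta[1] / fit.bse[1])))
    except Exception:
        res.flags.append("separation")
        p_a = res.k_above / res.n_above
        p_b = res.k_below / res.n_below
        res.jump = float(p_a - p_b)
        try:
            lo_ci, hi_ci = _score_ci_diff(
                res.k_above, res.n_above, res.k_below, res.n_below, spec.alpha
            )
            res.jump_ci = (float(lo_ci), float(hi_ci))
        except Exception:
            res.jump_ci = (np.nan, np.nan)
        se = np.sqrt(
            p_a * (1 - p_a) / res.n_above + p_b * (1 - p_b) / res.n_below
        )
        res.p_value = (
            float(2 * norm.sf(abs(res.jump) / se)) if se > 0 else 1.0
        )
    return res


def primary_specs(
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
    strata: Sequence[str] = DEFAULT_STRATA,
    alpha: float = 0.05,
) -> list[RdaSpec]:
    """Primary-analysis cells: the pre-specified bandwidth for each
    cut-point (0.05 ng/mL at 0.1 and 0.25; 0.10 ng/mL at 0.5), by stratum."""
    return [
        RdaSpec(c, PRIMARY_BANDWIDTHS.get(c, 0.05), s, alpha)
        for c in cutpoints
        for s in strata
    ]


def sensitivity_grid(
    cohort: pd.DataFrame,
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
    bandwidths: Sequence[float] = DEFAULT_BANDWIDTHS,
    strata: Sequence[str] = DEFAULT_STRATA,
    alpha: float = 0.05,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Full factorial cut-point x bandwidth x stratum sensitivity analysis.

    Each cell is fit independently and no multiplicity adjustment is applied
    by default (the study reported unadjusted p-values and discussed the
    multiplicity risk as a limitation); ``bh_adjust=True`` appends a
    Benjamini-Hochberg-adjusted column ``p_bh`` as an optional extra.
    """
    results = [
        fit_rda(cohort, RdaSpec(c, h, s, alpha)).to_dict()
        for c in cutpoints
        for h in bandwidths
        for s in strata
    ]
    out = pd.DataFrame(results)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        p = out["p_value"].to_numpy()
        ok = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if ok.any():
            adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        out["p_bh"] = adj
    return out


def render_table(results: pd.DataFrame) -> str:
    """Human-readable fixed-width rendering of an RDA results table."""
    lines = [
        f"{'cutpoint':>8} {'bw':>5} {'stratum':>8} {'n<':>6} {'n>=':>6} "
        f"{'jump':>7} {'OR':>8} {'OR 95% CI':>17} {'p':>8} flags"
    ]
    for r in results.itertuples(index=False):
        ci = f"[{r.or_ci_low:6.2f},{r.or_ci_high:7.2f}]" if np.isfinite(
            r.odds_ratio
        ) else f"[{'--':>6},{'--':>7}]"
        orr = f"{r.odds_ratio:8.2f}" if np.isfinite(r.odds_ratio) else f"{'--':>8}"
        jmp = f"{r.jump:7.3f}" if np.isfinite(r.jump) else f"{'--':>7}"
        pv = f"{r.p_value:8.4f}" if np.isfinite(r.p_value) else f"{'--':>8}"
        lines.append(
            f"{r.cutpoint:8.2f} {r.bandwidth:5.2f} {r.stratum:>8} "
            f"{r.n_below:6d} {r.n_above:6d} {jmp} {orr} {ci} {pv} {r.flags}"
        )
    return "\n".join(lines)
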