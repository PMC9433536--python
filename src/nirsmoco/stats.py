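"""Group statistics linking kinematics, activation and network metrics.

Factorial ANOVA (Type-II sums of squares, handedness x orientation, plus
phase mode for bilateral designs), paired t tests across subjects for
network metrics, per-channel activation t tests with Benjamini-Hochberg FDR
correction, and Pearson correlations between hemodynamic / network measures
and kinematic performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatReport",
    "anova_factorial",
    "paired_t",
    "one_sample_t",
    "fdr_correct",
    "correlate",
    "channel_activation_tests",
]

logger = logging.getLogger(__name__)


def _log_provenance(test: str, *arrays):
    """Debug-log a hash of each test invocation's inputs for audit trails."""
    import hashlib

    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(np.asarray(a, dtype=float)).tobytes())
    logger.debug("%s inputs sha256=%s", test, h.hexdigest()[:16])


@dataclass(frozen=True)
class StatReport:
    test: str
    statistic: float
    dof: float
    p: float
    n: int
    effect_direction: str | None = None
    p_fdr: float | None = None


def anova_factorial(table: pd.DataFrame, response: str, factors: list[str]) -> pd.DataFrame:
    """Factorial ANOVA with all interactions, Type-II sums of squares.

    ``table`` is long-format with one observation per row.  Returns a tidy
    frame with effect, F, df_num, df_den, p per main effect and interaction.
    """
    if not factors:
        raise ValueError("need at least one factor")
    for f in factors:
        levels = table[f].nunique()
        if levels < 2:
            raise ValueError(f"factor {f!r} has {levels} level(s); need >= 2")
    _log_provenance("anova", table[response].to_numpy())
    formula = f"{response} ~ " + " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=table).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    df_den = float(aov.loc["Residual", "df"])
    constant_response = table[response].nunique() == 1
    rows = []
    for name, row in aov.iterrows():
        if name == "Residual":
            continue
        clean = name.replace("C(", "").replace(")", "").replace(":", " x ")
        f_val = row["F"]
        p_val = row["PR(>F)"]
        # a constant response has zero SS everywhere; the 0/0 ratio is F=0, p=1
        if constant_response or np.isnan(f_val):
            f_val, p_val = 0.0, 1.0
        rows.append(dict(effect=clean, F=float(f_val), df_num=float(row["df"]),
                         df_den=df_den, p=float(p_val)))
    return pd.DataFrame(rows)


def paired_t(x: np.ndarray, y: np.ndarray) -> StatReport:
    """Two-sided paired t test on the differences x - y (dof n-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    _log_provenance("paired_t", x, y)
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return StatReport("paired_t", 0.0, n - 1, 1.0, n, "none")
        logger.warning("zero-variance nonzero-mean differences; reporting p=0")
        return StatReport("paired_t", np.inf * np.sign(d.mean()), n - 1, 0.0, n,
                          "x>y" if d.mean() > 0 else "x<y")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    direction = "x>y" if d.mean() > 0 else ("x<y" if d.mean() < 0 else "none")
    return StatReport("paired_t", float(t), n - 1, float(p), n, direction)


def one_sample_t(x: np.ndarray, popmean: float = 0.0) -> StatReport:
    """Two-sided one-sample t test against ``popmean``."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        if x.mean() == popmean:
            return StatReport("one_sample_t", 0.0, n - 1, 1.0, n, "none")
        return StatReport("one_sample_t", np.inf * np.sign(x.mean() - popmean),
                          n - 1, 0.0, n, "above" if x.mean() > popmean else "below")
    t = (x.mean() - popmean) / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return StatReport("one_sample_t", float(t), n - 1, float(p), n,
                      "above" if x.mean() > popmean else "below")


def fdr_correct(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    _log_provenance("pearson", x, y)
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def channel_activation_tests(
    activation: pd.DataFrame,
    value_col: str = "integral",
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-channel activation inference across subjects, FDR within condition.

    ``activation`` is tidy with columns subject, condition, channel and the
    value column.  For every condition x channel, a one-sample t test across
    subjects against 0, then Benjamini-Hochberg over the channels of that
    condition.  Returns condition, channel, mean, t, p, p_fdr, significant.
    """
    rows = []
    for cond, sub in activation.groupby("condition", sort=False):
        per_channel = []
        for ch, grp in sub.groupby("channel", sort=True):
            vals = grp[value_col].to_numpy()
            rep = one_sample_t(vals)
            per_channel.append(dict(condition=cond, channel=ch,
                                    mean=float(np.mean(vals)), t=rep.statistic, p=rep.p))
        p_adj = fdr_correct(np.array([r["p"] for r in per_channel]))
        for r, pa in zip(per_channel, p_adj):
            r["p_fdr"] = float(pa)
            r["significant"] = bool(pa < q)
            rows.append(r)
    return pd.DataFrame(rows)
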