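"""Efficiency-corrected relative qPCR quantification.

Implements the quantification chain used for the hypoxia/anoxia exposure
study: crossing-point (Cp) calling by the second-derivative-maximum
method, per-reaction amplification-efficiency estimation from the
log-linear window of the raw curve, relative mRNA levels normalized to an
exogenous external standard (mw2060, spiked at a fixed amount per mg of
tissue),

    level = E_std ** Cp_std / E_tar ** Cp_tar,

and control-versus-treatment statistics (one-way ANOVA followed by
Dunnett's many-to-one comparisons with a seeded Monte Carlo null).

The exposure design has six groups — normoxia (control), hypoxia, anoxia
for 1/3/5 days, and reoxygenation — with n = 6-10 fish per group and all
reactions run in duplicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_interp_spline
from scipy.signal import savgol_filter

from .errors import DomainError, NumericalError

__all__ = [
    "GROUPS",
    "CONTROL_GROUP",
    "AmplificationCurve",
    "DunnettResult",
    "call_cp",
    "estimate_efficiency",
    "mean_efficiency",
    "relative_level",
    "relative_levels_table",
    "group_summary",
    "dunnett_vs_control",
    "validate_cp_table",
]

GROUPS = ("normoxia", "hypoxia", "anoxia_1d", "anoxia_3d", "anoxia_5d",
          "reoxygenation")
CONTROL_GROUP = "normoxia"

#: the run is 42 cycles; Cp values must fall inside (0, 42)
MAX_CYCLES = 42


@dataclass
class AmplificationCurve:
    """One well's raw amplification curve."""

    cycle: np.ndarray
    fluorescence: np.ndarray
    well: str = ""
    gene: str = ""
    sample: str = ""

    def __post_init__(self):
        self.cycle = np.asarray(self.cycle, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycle.size != self.fluorescence.size:
            raise DomainError("cycle and fluorescence must have equal length")
        if self.cycle.size < 20:
            raise DomainError("need at least 20 cycles")
        if np.any(self.fluorescence < 0):
            raise DomainError("fluorescence must be non-negative")


# ---------------------------------------------------------------------------
# Cp calling and efficiency estimation
# ---------------------------------------------------------------------------

def call_cp(curve: AmplificationCurve, smooth_window: int = 5,
            smooth_order: int = 4, min_rise: float = 3.0) -> float:
    """Crossing point by the second-derivative-maximum method.

    The curve is Savitzky-Golay smoothed (window 5, order 4; the
    near-interpolating order keeps the asymmetric second-derivative peak
    unshifted, where a low-order kernel biases it by ~0.25 cycles),
    interpolated with a quintic spline, and the sub-cycle position of the
    maximum of the spline's second derivative is returned.  A curve that never rises
    ``min_rise``-fold over its baseline raises :class:`NumericalError`.
    """
    y = curve.fluorescence
    baseline = float(np.median(y[:5]))
    floor = max(baseline, np.max(np.abs(y)) * 1e-9, 1e-12)
    if np.max(y) < min_rise * floor:
        raise NumericalError("no amplification: curve never rises above baseline")
    smoothed = savgol_filter(y, smooth_window, smooth_order)
    spline = make_interp_spline(curve.cycle, smoothed, k=5)
    fine = np.arange(curve.cycle[0], curve.cycle[-1], 0.001)
    d2 = spline.derivative(2)(fine)
    return float(fine[np.argmax(d2)])


def estimate_efficiency(curve: AmplificationCurve, window_sizes=(4, 5, 6),
                        baseline_cycles: int = 5) -> float:
    """Per-reaction amplification efficiency from the log-linear window.

    The baseline (mean of the first cycles) is subtracted and a sliding
    window of 4-6 cycles maximizing the R^2 of the log10-fluorescence
    regression is selected.  The raw window slope underestimates E once
    amplification consumes reagents: for a logistic curve the local
    log-slope is (1 - f) log10 E at plateau fraction f, so the slope is
    divided by (1 - f_bar) with f_bar the window's mean plateau fraction
    before exponentiating.  Values outside (1, 2.1] raise
    :class:`NumericalError` (callers exclude such reactions from means).
    """
    y = curve.fluorescence.astype(float)
    base = float(np.mean(y[:baseline_cycles]))
    corrected = y - base
    amplitude = float(np.max(corrected))
    logy = np.where(corrected > 0, np.log10(np.maximum(corrected, 1e-300)), np.nan)
    n = logy.size
    best = None  # (r2, -start, slope): later windows lose ties deterministically
    for w in window_sizes:
        for start in range(0, n - w + 1):
            seg = logy[start:start + w]
            if np.any(~np.isfinite(seg)):
                continue
            x = curve.cycle[start:start + w]
            slope, intercept, r, _, _ = stats.linregress(x, seg)
            if slope <= 0:
                continue
            key = (r * r, -start, slope)
            if best is None or key > best[0]:
                f_bar = float(np.clip(
                    np.mean(corrected[start:start + w]) / amplitude, 0.0, 0.8))
                best = (key, slope, f_bar)
    if best is None:
        raise NumericalError("no exponential phase found")
    e = 10.0 ** (best[1] / (1.0 - best[2]))
    if not (1.0 < e <= 2.1):
        raise NumericalError(f"efficiency {e:.3f} outside the plausible range (1, 2.1]")
    return float(e)


def mean_efficiency(curves, **kwargs) -> pd.DataFrame:
    """Mean per-reaction efficiency per gene x tissue.

    ``curves`` is an iterable of (gene, tissue, AmplificationCurve).
    Reactions whose efficiency falls outside (1, 2.1] are flagged and
    excluded from the mean.
    """
    rows = []
    for gene, tissue, curve in curves:
        try:
            e = estimate_efficiency(curve, **kwargs)
            rows.append({"gene": gene, "tissue": tissue, "E": e, "flagged": False})
        except NumericalError:
            rows.append({"gene": gene, "tissue": tissue, "E": np.nan, "flagged": True})
    df = pd.DataFrame(rows)
    out = (df[~df.flagged].groupby(["gene", "tissue"], as_index=False)["E"].mean())
    counts = df.groupby(["gene", "tissue"], as_index=False).agg(
        n_reactions=("E", "size"), n_flagged=("flagged", "sum"))
    return out.merge(counts, on=["gene", "tissue"])


# ---------------------------------------------------------------------------
# relative levels
# ---------------------------------------------------------------------------

def relative_level(E_std: float, Cp_std: float, E_tar: float, Cp_tar: float) -> float:
    """Relative mRNA level: E_std^Cp_std / E_tar^Cp_tar."""
    for e in (E_std, E_tar):
        if not (1.0 < e <= 2.1):
            raise DomainError(f"efficiency {e} outside (1, 2.1]")
    return float(E_std ** Cp_std / E_tar ** Cp_tar)


def validate_cp_table(cp_table: pd.DataFrame, max_discordance: float = 1.0) -> pd.DataFrame:
    """Check a Cp table and flag discordant duplicates.

    Expects columns sample_id, group, tissue, gene, cp1, cp2.  Cp values
    must lie in (0, 42).  Duplicates differing by more than one cycle are
    flagged (column ``discordant``), not dropped.
    """
    required = {"sample_id", "group", "tissue", "gene", "cp1", "cp2"}
    missing = required - set(cp_table.columns)
    if missing:
        raise DomainError(f"Cp table missing columns: {sorted(missing)}")
    bad_group = set(cp_table["group"]) - set(GROUPS)
    if bad_group:
        raise DomainError(f"unknown exposure groups: {sorted(bad_group)}")
    cps = cp_table[["cp1", "cp2"]].to_numpy(dtype=float)
    if np.any((cps <= 0) | (cps >= MAX_CYCLES)):
        raise DomainError(f"Cp values must lie in (0, {MAX_CYCLES})")
    out = cp_table.copy()
    out["cp_mean"] = cps.mean(axis=1)
    out["discordant"] = np.abs(cps[:, 0] - cps[:, 1]) >= max_discordance
    return out


def relative_levels_table(cp_table: pd.DataFrame, efficiencies: pd.DataFrame,
                          normalizer: str = "mw2060") -> pd.DataFrame:
    """Per-sample relative levels of every gene against the normalizer.

    ``efficiencies`` has columns gene, tissue, E (tissue-matched, as the
    efficiencies are estimated per tissue).  Duplicate Cp values are
    averaged first.  Returns sample_id, group, tissue, gene, level.
    """
    table = validate_cp_table(cp_table)
    eff = {(r.gene, r.tissue): float(r.E) for r in efficiencies.itertuples()}
    rows = []
    for (sample, tissue), sub in table.groupby(["sample_id", "tissue"]):
        sub = sub.set_index("gene")
        if normalizer not in sub.index:
            raise DomainError(f"normalizer {normalizer!r} missing for sample {sample!r}")
        cp_std = float(sub.loc[normalizer, "cp_mean"])
        e_std = eff.get((normalizer, tissue))
        if e_std is None:
            raise DomainError(f"no efficiency for {normalizer!r} in tissue {tissue!r}")
        for gene, row in sub.iterrows():
            if gene == normalizer:
                continue
            e_tar = eff.get((gene, tissue))
            if e_tar is None:
                raise DomainError(f"no efficiency for {gene!r} in tissue {tissue!r}")
            rows.append({
                "sample_id": sample,
                "group": row["group"],
                "tissue": tissue,
                "gene": gene,
                "level": relative_level(e_std, cp_std, e_tar, float(row["cp_mean"])),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def group_summary(levels: pd.DataFrame, value_col: str = "level",
                  group_col: str = "group") -> pd.DataFrame:
    """Mean +- s.e.m. per group."""
    if levels.empty:
        raise DomainError("no data to summarize")
    counts = levels.groupby(group_col)[value_col].count()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise DomainError(f"groups with fewer than 2 observations: {small}")
    out = levels.groupby(group_col, as_index=False)[value_col].agg(
        mean="mean", sem=lambda x: float(np.std(x, ddof=1) / math.sqrt(len(x))),
        n="count")
    return out


@dataclass
class DunnettResult:
    """Dunnett many-to-one comparison against the control group."""

    table: pd.DataFrame          # group, diff, t, p_adj, significant
    anova_F: float
    anova_p: float
    critical_value: float
    alpha: float
    n_mc: int


def _max_abs_t_null(sizes: np.ndarray, n_mc: int, rng: np.random.Generator) -> np.ndarray:
    """Monte Carlo sample of max |t_i| under the global null.

    Uses the exact decomposition of the homoscedastic one-way layout:
    group means ~ N(0, sigma^2/n_g) independent of the pooled variance
    s^2 ~ sigma^2 chi^2_df / df with df = N - k.
    """
    k = sizes.size
    df = int(sizes.sum()) - k
    means = rng.standard_normal((n_mc, k)) / np.sqrt(sizes)
    s2 = rng.chisquare(df, n_mc) / df
    se = np.sqrt(1.0 / sizes[1:] + 1.0 / sizes[0])
    t = (means[:, 1:] - means[:, [0]]) / (np.sqrt(s2)[:, None] * se[None, :])
    return np.max(np.abs(t), axis=1)


def dunnett_vs_control(levels: pd.DataFrame, value_col: str = "level",
                       group_col: str = "group", control: str = CONTROL_GROUP,
                       alpha: float = 0.05, n_mc: int = 100_000,
                       seed: int = 0) -> DunnettResult:
    """One-way ANOVA followed by Dunnett's post-test against the control.

    Two-sided many-to-one comparisons under the usual homogeneous-variance
    assumption.  The critical value of the max-|t| null (a multivariate t
    with the pooled-variance correlation structure) is obtained by seeded
    Monte Carlo, so results are reproducible and the null is testable.
    Adjusted p-values are Monte Carlo tail probabilities of max |t|.
    """
    groups = [g for g in levels[group_col].unique() if g != control]
    if control not in set(levels[group_col]):
        raise DomainError(f"control group {control!r} absent")
    if not groups:
        raise DomainError("need at least one non-control group")
    samples = {g: levels.loc[levels[group_col] == g, value_col].to_numpy(dtype=float)
               for g in [control] + groups}
    for g, x in samples.items():
        if x.size < 2:
            raise DomainError(f"group {g!r} has fewer than 2 observations")

    arrays = [samples[control]] + [samples[g] for g in groups]
    f_stat, f_p = stats.f_oneway(*arrays)

    sizes = np.array([a.size for a in arrays], dtype=float)
    n_total, k = sizes.sum(), len(arrays)
    df = int(n_total - k)
    pooled_var = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / df
    if pooled_var <= 0:
        raise NumericalError("pooled variance is zero; t statistics undefined")
    mean0 = arrays[0].mean()
    diffs = np.array([a.mean() - mean0 for a in arrays[1:]])
    se = np.sqrt(pooled_var * (1.0 / sizes[1:] + 1.0 / sizes[0]))
    t_obs = diffs / se

    rng = np.random.default_rng(seed)
    null = _max_abs_t_null(sizes, n_mc, rng)
    crit = float(np.quantile(null, 1.0 - alpha))
    p_adj = (1 + np.sum(null[None, :] >= np.abs(t_obs)[:, None], axis=1)) / (n_mc + 1)

    table = pd.DataFrame({
        "group": groups,
        "diff": diffs,
        "t": t_obs,
        "p_adj": p_adj,
        "significant": np.abs(t_obs) > crit,
    })
    return DunnettResult(table=table, anova_F=float(f_stat), anova_p=float(f_p),
                         critical_value=crit, alpha=alpha, n_mc=n_mc)
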