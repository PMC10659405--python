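"""Small derived statistics and report utilities.

Percent change between group means, a two-sided F test for equality of
variances, 10-um binning of fluorescence line profiles, standard
group-comparison columns (Welch t, Mann-Whitney, two-way ANOVA), and the
joint-distribution / stacked-bar figures that summarise bootstrap output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PercentChange",
    "LineProfile",
    "percent_change",
    "variance_ratio",
    "bin_line_profile",
    "group_comparison_table",
    "plot_joint_distribution",
    "plot_stacked_proportions",
]


class PercentChange(NamedTuple):
    raw: float
    rounded: int


def percent_change(ctl_mean: float, cko_mean: float) -> PercentChange:
    """Percent decrease from control: 100 * (ctl - cko) / ctl.

    Returns both the raw value and the nearest-integer rounding used for
    report display.  Negative values indicate an increase.
    """
    if ctl_mean <= 0:
        raise ValueError("control mean must be positive")
    raw = 100.0 * (ctl_mean - cko_mean) / ctl_mean
    return PercentChange(raw=raw, rounded=int(round(raw)))


def variance_ratio(sample_a, sample_b) -> tuple[float, float]:
    """F test for equality of variances; F = larger variance / smaller.

    The two-sided p-value is computed from the F distribution with
    (n_larger - 1, n_smaller - 1) degrees of freedom.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    if va >= vb:
        big_var, small_var, df_big, df_small = va, vb, len(a) - 1, len(b) - 1
    else:
        big_var, small_var, df_big, df_small = vb, va, len(b) - 1, len(a) - 1
    if small_var == 0:
        return np.inf, 0.0
    f = big_var / small_var
    p = 2.0 * stats.f.sf(f, df_big, df_small)
    return float(f), float(min(p, 1.0))


@dataclass
class LineProfile:
    """Fluorescence intensity along a drawn line, binned in 10-um steps."""

    positions_um: np.ndarray
    intensities: np.ndarray
    bin_width_um: float = 10.0

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions_um) != len(self.intensities):
            raise ValueError("positions and intensities must have equal length")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.bin_width_um <= 0:
            raise ValueError("bin_width_um must be positive")


def bin_line_profile(profile: LineProfile) -> tuple[pd.DataFrame, float]:
    """Consecutive bin means along the profile, plus the peak binned value.

    Zero-valued samples (line segments that fell outside the image) are
    removed before averaging.  Bins start at the first sampled position.
    """
    pos = profile.positions_um
    val = profile.intensities
    keep = val != 0
    pos, val = pos[keep], val[keep]
    if len(pos) == 0:
        raise ValueError("profile is empty after removing zero-valued samples")
    idx = np.floor((pos - profile.positions_um[0]) / profile.bin_width_um).astype(int)
    frame = (
        pd.DataFrame({"bin": idx, "intensity": val})
        .groupby("bin")["intensity"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_intensity", "count": "n_samples"})
    )
    frame["bin_start_um"] = profile.positions_um[0] + frame["bin"] * profile.bin_width_um
    peak = float(frame["mean_intensity"].max())
    return frame[["bin", "bin_start_um", "mean_intensity", "n_samples"]], peak


def group_comparison_table(
    frame: pd.DataFrame,
    value_col: str,
    group_col: str = "genotype",
    factor_col: str | None = "layer",
) -> pd.DataFrame:
    """Standard per-cell comparisons between two groups (thin wrappers).

    For each level of ``factor_col`` (or once if None) reports Welch t and
    Mann-Whitney comparisons between the two groups; when a factor is
    given, a two-way ANOVA (group + factor + interaction) is appended as
    attrs['anova'].
    """
    groups = sorted(frame[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups in {group_col!r}, got {groups}")
    cells = (
        [(lvl, frame[frame[factor_col] == lvl]) for lvl in sorted(frame[factor_col].unique())]
        if factor_col
        else [("all", frame)]
    )
    rows = []
    for name, cell in cells:
        a = cell.loc[cell[group_col] == groups[0], value_col].to_numpy()
        b = cell.loc[cell[group_col] == groups[1], value_col].to_numpy()
        welch = stats.ttest_ind(a, b, equal_var=False)
        mwu = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                factor_col or "cell": name,
                f"mean_{groups[0]}": a.mean(),
                f"mean_{groups[1]}": b.mean(),
                "welch_t": welch.statistic,
                "welch_p": welch.pvalue,
                "mwu_u": mwu.statistic,
                "mwu_p": mwu.pvalue,
            }
        )
    table = pd.DataFrame(rows)
    if factor_col:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        data = frame[[value_col, group_col, factor_col]].rename(
            columns={value_col: "value", group_col: "grp", factor_col: "fac"}
        )
        model = smf.ols("value ~ C(grp) * C(fac)", data=data).fit()
        table.attrs["anova"] = sm.stats.anova_lm(model, typ=2)
    return table


def plot_joint_distribution(jd, group_names=("A", "B"), ax=None):
    """Heatmap of a JointDistribution with its P_boot annotated."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = [jd.edges_b[0], jd.edges_b[-1], jd.edges_a[0], jd.edges_a[-1]]
    ax.imshow(jd.hist, origin="lower", extent=extent, aspect="auto", cmap="viridis")
    lo = min(jd.edges_a[0], jd.edges_b[0])
    hi = max(jd.edges_a[-1], jd.edges_b[-1])
    ax.plot([lo, hi], [lo, hi], "w--", lw=1)
    ax.set_xlabel(f"{group_names[1]} resampled median")
    ax.set_ylabel(f"{group_names[0]} resampled median")
    ax.set_title(f"P_boot({group_names[0]} > {group_names[1]}) = {jd.p_boot:.2f}")
    return ax


def plot_stacked_proportions(proportions: Mapping[str, float], ax=None):
    """Stacked bars: per comparison, the share of repetitions each group wins."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = list(proportions)
    upper = np.array([proportions[k] for k in labels])
    ax.bar(labels, upper, label="first group greater")
    ax.bar(labels, 1 - upper, bottom=upper, label="second group greater")
    ax.set_ylabel("proportion of bootstrap repetitions")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
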