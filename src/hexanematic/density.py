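"""Density grouping and group comparisons.

Monolayers are grouped by their mean cell-cell distance R_cc into
contiguous half-open intervals (default width 2.6 μm, six intervals labelled
D1..D6), the R_cc histogram uses 0.2 μm bins, and two-sample comparisons use
the two-sided Wilcoxon rank-sum test with the conventional star labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DensityBinning:
    histogram_bin_width: float = 0.2
    interval_width: float = 2.6
    interval_origin: float = 9.7
    n_intervals: int = 6

    @property
    def labels(self) -> list[str]:
        return [f"D{k + 1}" for k in range(self.n_intervals)]

    @property
    def edges(self) -> np.ndarray:
        return self.interval_origin + self.interval_width * np.arange(
            self.n_intervals + 1
        )

    def assign(self, rcc: float) -> str:
        """Interval label for one R_cc; half-open [left, right) intervals.

        Values outside the configured span land in an overflow bin with a
        warning rather than raising.
        """
        # round before flooring so a value on an interval edge (up to float
        # error) lands in the right-hand interval, per the half-open convention
        k = int(np.floor(round((rcc - self.interval_origin) / self.interval_width, 9)))
        if 0 <= k < self.n_intervals:
            return self.labels[k]
        warnings.warn(
            f"R_cc = {rcc:.2f} μm outside configured span "
            f"[{self.edges[0]:.2f}, {self.edges[-1]:.2f}); assigned to overflow"
        )
        return "overflow"


def binning_from_data(rccs, **kwargs) -> DensityBinning:
    """Binning anchored at the minimum observed R_cc."""
    return DensityBinning(interval_origin=float(np.min(rccs)), **kwargs)


def bin_monolayers(rccs, binning: DensityBinning) -> pd.Series:
    """Interval label per monolayer, indexed like ``rccs``."""
    s = pd.Series(rccs, dtype=float)
    return s.map(binning.assign)


def rcc_histogram(rccs, binning: DensityBinning | None = None) -> pd.DataFrame:
    """Histogram of R_cc with the configured bin width (default 0.2 μm)."""
    binning = binning or DensityBinning()
    rccs = np.asarray(rccs, dtype=float)
    w = binning.histogram_bin_width
    lo = np.floor(rccs.min() / w) * w
    edges = np.arange(lo, rccs.max() + w, w)
    counts, edges = np.histogram(rccs, bins=edges)
    return pd.DataFrame({"left_edge": edges[:-1], "count": counts})


def interval_summary(per_monolayer: pd.DataFrame, binning: DensityBinning) -> pd.DataFrame:
    """Per-interval summary of the per-monolayer analysis table.

    ``per_monolayer`` must contain an ``rcc`` column; recognised optional
    columns are ``n_cells``, ``p0``, ``abs_gamma2``, ``abs_gamma6``,
    ``r_cross_norm`` and ``defect_density_p{2,6}``.  Each numeric column is
    summarised as mean and standard deviation within each density interval.
    """
    df = per_monolayer.copy()
    df["interval"] = bin_monolayers(df["rcc"], binning).values
    if "abs_gamma6" in df and "abs_gamma2" in df:
        df["gamma_diff"] = df["abs_gamma6"] - df["abs_gamma2"]
    rows = []
    for lab in binning.labels + ["overflow"]:
        g = df[df["interval"] == lab]
        if g.empty:
            continue
        row: dict = {"interval": lab, "n_monolayers": len(g)}
        if "n_cells" in g:
            row["n_cells"] = int(g["n_cells"].sum())
        for col in (
            "rcc", "p0", "abs_gamma2", "abs_gamma6", "gamma_diff",
            "r_cross_norm", "defect_density_p2", "defect_density_p6",
        ):
            if col in g:
                vals = g[col].dropna()
                row[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
                row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test between two groups.

    Returns ``(statistic, p_value)``; exact null distribution for small
    tie-free samples, normal approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def significance_label(p_value: float) -> str:
    """Star notation: p <= 0.05 (*), < 0.01 (**), < 0.001 (***),
    < 0.0001 (****), ns otherwise."""
    if p_value > 0.05:
        return "ns"
    if p_value < 0.0001:
        return "****"
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    return "*"
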