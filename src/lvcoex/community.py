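"""Community-level function metrics and summary-statistic tests.

Function here means standing-stock biovolume (or a supplied flux such as
oxygen consumption) of the whole consumer community at steady state.  Also
provides the small statistical utilities the analysis needs: two-sample t
tests computed from printed group summaries (mean, ±error, n — with the
error readable as either SE or SD), classical one-way ANOVA, and the cell
geometry used to convert measurements to volumes: a prolate spheroid
(pi/6 * length * width^2) for ciliates measured under the microscope, and a
sphere (pi/6 * d^3) for particle-counter estimated-spherical-diameter bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .steady_state import DEFAULT_WINDOW, _column_for
from .synthetic import RESOURCE

__all__ = [
    "GroupSummary",
    "summary_ttest",
    "one_way_anova",
    "cell_volume_prolate",
    "cell_volume_esd",
    "spectrum_biovolume",
    "function_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """Published-style group summary: label, mean, ±dispersion, n."""

    label: str
    mean: float
    dispersion: float
    n: int

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2 for any test")

    def sd(self, dispersion_is: str) -> float:
        if dispersion_is == "sd":
            return self.dispersion
        if dispersion_is == "se":
            return self.dispersion * np.sqrt(self.n)
        raise ValueError("dispersion_is must be 'se' or 'sd'")


def summary_ttest(
    g1: GroupSummary,
    g2: GroupSummary,
    mode: str = "welch",
    dispersion_is: str = "se",
) -> tuple[float, float, float]:
    """Two-sample t test from group summaries; returns (t, df, p).

    ``mode='pooled'`` is the equal-variance test, ``'welch'`` the unequal-
    variance test with Welch-Satterthwaite df.  When ``dispersion_is='se'``
    each group's SD is reconstructed as se * sqrt(n) before pooling.  The p
    value is two-sided.  Zero dispersion in both groups with equal means
    leaves t undefined and raises.
    """
    sd1, sd2 = g1.sd(dispersion_is), g2.sd(dispersion_is)
    if sd1 == 0 and sd2 == 0:
        if g1.mean == g2.mean:
            raise ValueError("t is undefined: zero dispersion in both groups and equal means")
        return (np.inf if g1.mean > g2.mean else -np.inf, float(g1.n + g2.n - 2), 0.0)
    if mode not in ("pooled", "welch"):
        raise ValueError("mode must be 'pooled' or 'welch'")
    res = stats.ttest_ind_from_stats(
        g1.mean, sd1, g1.n, g2.mean, sd2, g2.n, equal_var=(mode == "pooled")
    )
    if mode == "pooled":
        df = float(g1.n + g2.n - 2)
    else:
        v1, v2 = sd1**2 / g1.n, sd2**2 / g2.n
        df = float((v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1)))
    return float(res.statistic), df, float(res.pvalue)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float, float, float]:
    """Classical one-way ANOVA on raw values; returns (F, df1, df2, p)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    if all(np.var(a) == 0 for a in arrays):
        means = [a.mean() for a in arrays]
        if np.ptp(means) == 0:
            return 0.0, float(k - 1), float(n_total - k), 1.0
        raise ValueError("zero within-group variance with unequal means: F undefined")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(k - 1), float(n_total - k), float(p)


def cell_volume_prolate(length_um: float, width_um: float) -> float:
    """Prolate-spheroid cell volume, V = (pi/6) * length * width^2 (µm³)."""
    if width_um <= 0 or length_um <= 0:
        raise ValueError("length and width must be strictly positive")
    if length_um < width_um:
        raise ValueError("length must be >= width for a prolate spheroid")
    return np.pi / 6.0 * length_um * width_um**2


def cell_volume_esd(diameter_um: float) -> float:
    """Spherical cell volume from estimated spherical diameter (µm³)."""
    if diameter_um <= 0:
        raise ValueError("diameter must be strictly positive")
    return np.pi / 6.0 * diameter_um**3


def spectrum_biovolume(histogram: pd.Series) -> float:
    """Total biovolume of a binned ESD spectrum (counts or densities indexed
    by diameter); units follow the input (e.g. µm³/mL for densities/mL)."""
    d = histogram.index.to_numpy(dtype=float)
    if np.any(d <= 0):
        raise ValueError("ESD bins must be strictly positive")
    return float(np.sum(histogram.to_numpy(dtype=float) * np.pi / 6.0 * d**3))


def function_table(
    table: pd.DataFrame,
    window: tuple[float, float] = DEFAULT_WINDOW,
    variable: str = "biovolume",
    flux: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Community function per treatment, with pairwise Welch contrasts.

    Consumer species are summed within each microcosm (replicate × day)
    before any averaging, then each replicate is time-averaged over the
    window and treatments are summarized as mean ± SE across replicates.
    The resource-only treatment is excluded (it has no consumer community).
    ``flux`` optionally supplies an extra per-(treatment, replicate)
    function column (e.g. oxygen consumption) passed through to contrasts.

    Returns ``(levels, contrasts)``.
    """
    col = _column_for(variable)
    lo, hi = window
    if hi < lo:
        raise ValueError("window must satisfy day_lo <= day_hi")
    sel = table[
        (table["species"] != RESOURCE)
        & (table["treatment"] != "resource_alone")
        & (table["day"] >= lo)
        & (table["day"] <= hi)
    ]
    if sel.empty:
        raise ValueError("no consumer rows inside the window")
    per_microcosm = (
        sel.groupby(["treatment", "replicate", "day"])[col].sum().reset_index()
    )
    rep_means = per_microcosm.groupby(["treatment", "replicate"])[col].mean()

    levels_rows = []
    rep_arrays: dict[str, np.ndarray] = {}
    for treatment, vals in rep_means.groupby(level="treatment"):
        arr = vals.to_numpy()
        rep_arrays[str(treatment)] = arr
        levels_rows.append(
            {
                "treatment": treatment,
                "variable": variable,
                "mean": float(arr.mean()),
                "se": float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan,
                "n_replicates": int(arr.size),
            }
        )
    levels = pd.DataFrame(levels_rows)

    contrasts = []
    treatments = sorted(rep_arrays)
    for i, ta in enumerate(treatments):
        for tb in treatments[i + 1 :]:
            a, b = rep_arrays[ta], rep_arrays[tb]
            if a.size < 2 or b.size < 2:
                raise ValueError("contrasts need >= 2 replicates per treatment")
            if np.var(a) == 0 and np.var(b) == 0:
                t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
            else:
                t_stat, p = stats.ttest_ind(a, b, equal_var=False)
            contrasts.append(
                {
                    "treatment_a": ta,
                    "treatment_b": tb,
                    "variable": variable,
                    "difference": float(a.mean() - b.mean()),
                    "t": float(t_stat),
                    "p": float(p),
                }
            )
    if flux is not None:
        flux_by_treatment = {
            str(t): g["flux"].to_numpy(dtype=float) for t, g in flux.groupby("treatment")
        }
        names = sorted(flux_by_treatment)
        for i, ta in enumerate(names):
            for tb in names[i + 1 :]:
                a, b = flux_by_treatment[ta], flux_by_treatment[tb]
                t_stat, p = stats.ttest_ind(a, b, equal_var=False)
                contrasts.append(
                    {
                        "treatment_a": ta,
                        "treatment_b": tb,
                        "variable": "flux",
                        "difference": float(a.mean() - b.mean()),
                        "t": float(t_stat),
                        "p": float(p),
                    }
                )
    return levels, pd.DataFrame(contrasts)
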