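"""Steady-state summaries of replicated microcosm time series.

The steady-state mean of a variable is computed replicate-first: each
replicate's observations inside the declared window (default days 8-14 for
biovolume) are averaged over time, and the cross-replicate mean and
standard error (SD of replicate means / sqrt(n)) are reported.  The SE
therefore reflects replicate-level variation, which is what feeds the
parametric bootstrap downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_WINDOW",
    "SteadyStateEstimate",
    "extract_steady_state",
    "r_star_table",
    "steady_state_frame",
]

DEFAULT_WINDOW = (8.0, 14.0)

_VARIABLE_COLUMNS = {"density": "density_per_ml", "biovolume": "biovolume_um3"}


@dataclass(frozen=True)
class SteadyStateEstimate:
    """Mean ± SE of one state variable over a steady-state window."""

    treatment: str
    species: str
    variable: str
    mean: float
    se: float
    n_replicates: int
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @staticmethod
    def exact(mean: float, se: float = 0.0, label: str = "manual") -> "SteadyStateEstimate":
        """Convenience constructor for externally supplied summaries
        (e.g. published tables)."""
        return SteadyStateEstimate(label, label, "biovolume", mean, se, 1, (0.0, 0.0))


def _column_for(variable: str) -> str:
    try:
        return _VARIABLE_COLUMNS[variable]
    except KeyError:
        raise ValueError(f"variable must be one of {sorted(_VARIABLE_COLUMNS)}, got {variable!r}")


def extract_steady_state(
    table: pd.DataFrame,
    treatment: str,
    species: str,
    variable: str = "biovolume",
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> SteadyStateEstimate:
    """Replicate-first steady-state mean ± SE for one treatment/species.

    Raises ``ValueError`` if the selection is empty (wrong labels or no
    sampling day inside the window).  With a single replicate the SE is
    undefined and an error is raised.
    """
    col = _column_for(variable)
    lo, hi = window
    if hi < lo:
        raise ValueError("window must satisfy day_lo <= day_hi")
    sel = table[
        (table["treatment"] == treatment)
        & (table["species"] == species)
        & (table["day"] >= lo)
        & (table["day"] <= hi)
    ]
    if sel.empty:
        raise ValueError(
            f"no rows for treatment={treatment!r}, species={species!r} in window [{lo}, {hi}]"
        )
    rep_means = sel.groupby("replicate")[col].mean()
    n = int(rep_means.size)
    if n < 2:
        raise ValueError("at least 2 replicates are required for a standard error")
    return SteadyStateEstimate(
        treatment=treatment,
        species=species,
        variable=variable,
        mean=float(rep_means.mean()),
        se=float(rep_means.std(ddof=1) / np.sqrt(n)),
        n_replicates=n,
        window=(float(lo), float(hi)),
    )


def r_star_table(
    table: pd.DataFrame,
    window: tuple[float, float] = DEFAULT_WINDOW,
    variable: str = "biovolume",
    resource: str = "bacteria",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Steady-state resource levels per treatment, with pairwise contrasts.

    The resource left standing under each consumer treatment is its R*:
    the lower it is, the better that consumer exploits the resource.
    Returns ``(levels, contrasts)``: per-treatment estimates, and Welch
    t-tests on the replicate means for every treatment pair.  Identical
    replicate means in both groups (zero variance, zero difference) are
    reported as t = 0, p = 1.
    """
    if resource not in set(table["species"]):
        raise ValueError(f"no resource rows (species={resource!r}) in the table")
    treatments = [t for t in table["treatment"].unique() if
                  not table[(table["treatment"] == t) & (table["species"] == resource)].empty]
    estimates = {
        t: extract_steady_state(table, t, resource, variable, window) for t in treatments
    }
    levels = pd.DataFrame(
        [
            {
                "treatment": t,
                "variable": e.variable,
                "mean": e.mean,
                "se": e.se,
                "n_replicates": e.n_replicates,
            }
            for t, e in estimates.items()
        ]
    )
    col = _column_for(variable)
    lo, hi = window
    rep_means = {
        t: table[
            (table["treatment"] == t)
            & (table["species"] == resource)
            & (table["day"] >= lo)
            & (table["day"] <= hi)
        ]
        .groupby("replicate")[col]
        .mean()
        .to_numpy()
        for t in treatments
    }
    contrasts = []
    for i, ta in enumerate(treatments):
        for tb in treatments[i + 1 :]:
            a, b = rep_means[ta], rep_means[tb]
            diff = float(a.mean() - b.mean())
            if np.var(a) == 0 and np.var(b) == 0:
                t_stat, p = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
            else:
                t_stat, p = stats.ttest_ind(a, b, equal_var=False)
            contrasts.append(
                {
                    "treatment_a": ta,
                    "treatment_b": tb,
                    "difference": diff,
                    "t": float(t_stat),
                    "p": float(p),
                }
            )
    return levels, pd.DataFrame(contrasts)


def steady_state_frame(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    variable: str = "biovolume",
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Tabulate :func:`extract_steady_state` over (treatment, species) pairs."""
    rows = []
    for treatment, species in pairs:
        e = extract_steady_state(table, treatment, species, variable, window)
        rows.append(
            {
                "treatment": e.treatment,
                "species": e.species,
                "variable": e.variable,
                "mean": e.mean,
                "se": e.se,
                "n_replicates": e.n_replicates,
                "window_lo": e.window[0],
                "window_hi": e.window[1],
            }
        )
    return pd.DataFrame(rows)
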