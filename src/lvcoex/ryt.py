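"""Relative-yield-total (RYT) geometry and outcome classification.

Each species' coexistence biomass is normalized by its biomass alone
(y_i = coexist_i / alone_i), so both monoculture steady states map to 1 and
the line y1 + y2 = 1 — the RYT line — connects them.  Where the observed
coexistence point falls is diagnostic of the coexistence mechanism:

- on the RYT line: species trade off one-for-one, as under neutral
  (ecologically equivalent) dynamics;
- above it with both y_i <= 1 ("Area A", the overyielding triangle):
  resource partitioning gives the pair access to more resource than either
  species alone;
- below it: some process suppresses function below the trade-off line;
- any y_i > 1: a species does better with a competitor than alone,
  suggesting facilitation or another positive interaction.

The width of the "on the line" band comes from the same parametric
bootstrap used for the competition coefficients: it is the half-width of
the 95% interval of y1 + y2 - 1 implied by the steady-state SEs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .competition import (
    DEFAULT_DIST,
    DEFAULT_N_BOOT,
    _df_of,
    _resample_positive,
    satterthwaite_df,
    welch_expand,
)
from .steady_state import SteadyStateEstimate


def _ratio_components(
    num: SteadyStateEstimate, den: SteadyStateEstimate
) -> list[tuple[float, float]]:
    """Delta-method variance decomposition of num/den."""
    return [
        (num.se**2 / den.mean**2, _df_of(num)),
        (num.mean**2 * den.se**2 / den.mean**4, _df_of(den)),
    ]

__all__ = [
    "REGIONS",
    "RelativeYieldPoint",
    "normalize_state",
    "classify_region",
    "ryt_band",
    "state_space_trajectory",
    "ryt_line",
]

REGIONS = ("below_ryt", "on_ryt", "overyield_area_A", "positive_interaction")


@dataclass(frozen=True)
class RelativeYieldPoint:
    """Normalized coexistence biomasses of the two species.

    ``ci_y1``/``ci_y2`` are 95% bootstrap intervals when the point was built
    from steady-state estimates with SEs; ``None`` for bare literature
    values.  ``region`` is filled in by :func:`classify_region`.
    """

    y1: float
    y2: float
    ci_y1: tuple[float, float] | None = None
    ci_y2: tuple[float, float] | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.y1 < 0 or self.y2 < 0:
            raise ValueError("relative yields must be non-negative")

    @property
    def ryt(self) -> float:
        """Relative yield total, y1 + y2."""
        return self.y1 + self.y2


def normalize_state(
    coexist1: SteadyStateEstimate,
    alone1: SteadyStateEstimate,
    coexist2: SteadyStateEstimate,
    alone2: SteadyStateEstimate,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    dist: str = DEFAULT_DIST,
) -> RelativeYieldPoint:
    """Relative yields y_i = coexist_i / alone_i with bootstrap ratio CIs."""
    if alone1.mean <= 0 or alone2.mean <= 0:
        raise ValueError("alone biomasses must be strictly positive")
    y1 = coexist1.mean / alone1.mean
    y2 = coexist2.mean / alone2.mean
    rng = np.random.default_rng(seed)
    (a1, a2, c1, c2), _ = _resample_positive(
        rng, (alone1, alone2, coexist1, coexist2), positive_idx=(0, 1), n=n_boot, dist=dist
    )
    d1, d2 = c1 / a1, c2 / a2
    if dist == "welch":
        d1 = welch_expand(d1, satterthwaite_df(_ratio_components(coexist1, alone1)))
        d2 = welch_expand(d2, satterthwaite_df(_ratio_components(coexist2, alone2)))
    ci1 = np.percentile(d1, [2.5, 97.5])
    ci2 = np.percentile(d2, [2.5, 97.5])
    return RelativeYieldPoint(
        y1=float(y1),
        y2=float(y2),
        ci_y1=(float(ci1[0]), float(ci1[1])),
        ci_y2=(float(ci2[0]), float(ci2[1])),
    )


def _exceeds_one(y: float, ci: tuple[float, float] | None, ci_aware: bool) -> bool:
    if ci_aware and ci is not None:
        return ci[0] > 1.0
    return y > 1.0


def classify_region(
    point: RelativeYieldPoint,
    band_halfwidth: float = 0.0,
    ci_aware: bool = True,
) -> RelativeYieldPoint:
    """Assign the RYT region label; returns a copy with ``region`` set.

    Positive interaction is tested first: a species counts as doing better
    in coexistence than alone when its yield exceeds 1 — judged by the
    lower 95% CI bound when a CI is available and ``ci_aware`` (the
    conservative rule), by the point estimate otherwise.  Failing that, the
    point is on the RYT line when |ryt - 1| <= band_halfwidth, above it in
    the overyielding triangle, or below it.
    """
    if band_halfwidth < 0:
        raise ValueError("band_halfwidth must be non-negative")
    if _exceeds_one(point.y1, point.ci_y1, ci_aware) or _exceeds_one(
        point.y2, point.ci_y2, ci_aware
    ):
        region = "positive_interaction"
    elif abs(point.ryt - 1.0) <= band_halfwidth:
        region = "on_ryt"
    elif point.ryt > 1.0:
        region = "overyield_area_A"
    else:
        region = "below_ryt"
    return dataclasses.replace(point, region=region)


def ryt_band(
    alone1: SteadyStateEstimate,
    alone2: SteadyStateEstimate,
    coexist1: SteadyStateEstimate,
    coexist2: SteadyStateEstimate,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    dist: str = DEFAULT_DIST,
) -> float:
    """Half-width of the 95% bootstrap interval of (y1 + y2 - 1).

    This is the uncertainty band around the RYT perimeter implied by the
    95% CIs of the four steady states; zero when all SEs are zero.
    """
    if alone1.mean <= 0 or alone2.mean <= 0:
        raise ValueError("alone biomasses must be strictly positive")
    rng = np.random.default_rng(seed)
    (a1, a2, c1, c2), _ = _resample_positive(
        rng, (alone1, alone2, coexist1, coexist2), positive_idx=(0, 1), n=n_boot, dist=dist
    )
    ryt_draws = c1 / a1 + c2 / a2 - 1.0
    if dist == "welch":
        comps = _ratio_components(coexist1, alone1) + _ratio_components(coexist2, alone2)
        ryt_draws = welch_expand(ryt_draws, satterthwaite_df(comps))
    lo, hi = np.percentile(ryt_draws, [2.5, 97.5])
    return float((hi - lo) / 2.0)


def state_space_trajectory(
    table: pd.DataFrame,
    treatment: str = "both",
    variable: str = "biovolume",
) -> pd.DataFrame:
    """Per-day mean ± SE of the two consumer species in state space.

    Returns a day-indexed frame with columns mean1, se1, mean2, se2 (species
    1 on the x axis), suitable for plotting the approach to steady state
    against the RYT perimeter.
    """
    from .steady_state import _column_for
    from .synthetic import SPECIES1, SPECIES2

    col = _column_for(variable)
    sel = table[table["treatment"] == treatment]
    species = set(sel["species"])
    if SPECIES1 not in species or SPECIES2 not in species:
        raise ValueError(f"treatment {treatment!r} lacks one or both consumer species")
    out = {}
    for label, sp in (("1", SPECIES1), ("2", SPECIES2)):
        g = sel[sel["species"] == sp].groupby("day")[col]
        out[f"mean{label}"] = g.mean()
        out[f"se{label}"] = g.std(ddof=1) / np.sqrt(g.count())
    return pd.DataFrame(out).sort_index()


def ryt_line(K1: float = 1.0, K2: float = 1.0, n_points: int = 2) -> pd.DataFrame:
    """The RYT segment from (K1, 0) to (0, K2) (normalized if K's are 1)."""
    s = np.linspace(0.0, 1.0, n_points)
    return pd.DataFrame({"N1": K1 * (1 - s), "N2": K2 * s})
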