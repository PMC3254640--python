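"""Synthetic two-species microcosm experiments.

Generates replicated time series with the statistical structure of a
bactivorous-ciliate competition experiment: *Colpidium striatum* (species 1)
and *Paramecium aurelia* (species 2) grown alone and together in 5 mL
microcosms for 15 days, with 0.2 mL of culture exchanged for fresh
bacterized medium on a Monday/Wednesday/Friday schedule.  Latent consumer
dynamics follow the Lotka-Volterra model of :mod:`lvcoex.lv` in units of
total biovolume per microcosm; observations add density-scaled counting
noise.  Bacterial prey are emitted as a separate observable — a density per
treatment plus a size spectrum whose mean drifts under size-selective
grazing (bacteria left behind by the small ciliate are larger, and vice
versa) — not as a dynamically coupled resource.

The default parameterisation is calibrated so that the Colpidium
monoculture steady state sits at 8.44e7 µm³ per microcosm and the
two-species equilibrium at (3.53e7, 4.09e7) µm³, the biovolume scale of the
motivating experiment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lv import LVParams, State, simulate

__all__ = [
    "SPECIES1",
    "SPECIES2",
    "RESOURCE",
    "TREATMENTS",
    "SAMPLE_COLUMNS",
    "ExperimentDesign",
    "CellSizeParams",
    "PreySpectrumParams",
    "GeneratorParams",
    "default_lv_params",
    "neutral_lv_params",
    "generate_experiment",
    "generate_cell_sizes",
    "generate_prey_spectrum",
    "write_sample_table",
    "read_sample_table",
]

SPECIES1 = "colpidium"
SPECIES2 = "paramecium"
RESOURCE = "bacteria"

TREATMENTS = ("species1_alone", "species2_alone", "both", "resource_alone")

SAMPLE_COLUMNS = ("treatment", "replicate", "day", "species", "density_per_ml", "biovolume_um3")

# Calibration anchors (µm³ biovolume per microcosm / per cell)
K1_BIOVOLUME = 8.44e7          # Colpidium monoculture steady state
C1_COEXIST = 3.53e7            # Colpidium steady state in the two-species culture
C2_COEXIST = 4.0917e7          # Paramecium steady state in the two-species culture
A21_DEFAULT = 0.8              # effect of Colpidium on Paramecium (free; stable with a12=1.2)

CELLVOL_SP1 = (5.04e4, 1.82e3, 81)   # Colpidium: mean µm³, ± error, n cells
CELLVOL_SP2 = (8.56e4, 2.96e3, 86)   # Paramecium

#: manual-count aliquots (mL) keyed by the density (cells/mL) they apply up to;
#: the whole 5 mL dish is scanned at low density, 0.2 mL at medium, 0.1 mL above
COUNT_VOLUME_BREAKS = ((10.0, None), (50.0, 0.2), (np.inf, 0.1))


def default_lv_params(r1: float = 1.5, r2: float = 1.5) -> LVParams:
    """Competition parameters calibrated to the study system.

    a12 = (K1 - C1)/C2 = 1.2 by construction; a21 is not identified by the
    published monoculture numbers and defaults to 0.8, which places a stable
    interior equilibrium exactly at the calibrated coexistence biovolumes
    (K2 = C2 + a21*C1).  Growth rates are free parameters set to reach
    steady state by day 8 from a five-cell inoculum.
    """
    a12 = (K1_BIOVOLUME - C1_COEXIST) / C2_COEXIST
    k2 = C2_COEXIST + A21_DEFAULT * C1_COEXIST
    return LVParams(r1=r1, r2=r2, K1=K1_BIOVOLUME, K2=k2, a12=a12, a21=A21_DEFAULT)


def neutral_lv_params(K: float = K1_BIOVOLUME, r: float = 1.5) -> LVParams:
    """Ecologically equivalent species: a12 = a21 = 1, equal K and r."""
    return LVParams(r1=r, r2=r, K1=K, K2=K, a12=1.0, a21=1.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the microcosm experiment.

    Sampling days default to a Mon/Wed/Fri pattern starting on day 1 of a
    15-day run; medium exchange happens on sampling days.
    """

    n_replicates: int = 6
    duration_days: float = 15.0
    sampling_days: tuple[float, ...] = (1.0, 3.0, 5.0, 8.0, 10.0, 12.0, 15.0)
    microcosm_volume_ml: float = 5.0
    exchange_volume_ml: float = 0.2
    treatments: tuple[str, ...] = TREATMENTS

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 <= self.exchange_volume_ml < self.microcosm_volume_ml:
            raise ValueError("exchange_volume must be non-negative and < microcosm_volume")
        days = np.asarray(self.sampling_days, dtype=float)
        if days.size == 0 or np.any(np.diff(days) <= 0):
            raise ValueError("sampling_days must be non-empty and strictly increasing")
        if days[0] < 0 or days[-1] > self.duration_days:
            raise ValueError("sampling_days must lie within [0, duration_days]")
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatment labels: {sorted(unknown)}")

    @property
    def dilution_factor(self) -> float:
        """Fraction of culture retained at each exchange (0.96 by default)."""
        return 1.0 - self.exchange_volume_ml / self.microcosm_volume_ml


@dataclass(frozen=True)
class CellSizeParams:
    """Per-cell volume summary for one consumer species.

    ``error`` is read as the standard error of the mean at sample size ``n``
    when ``dispersion_is='se'`` (the default in :class:`GeneratorParams`),
    or directly as the population SD when ``'sd'``.
    """

    mean_um3: float
    error_um3: float
    n: int

    def population_sd(self, dispersion_is: str = "se") -> float:
        if dispersion_is == "se":
            return self.error_um3 * np.sqrt(self.n)
        if dispersion_is == "sd":
            return self.error_um3
        raise ValueError("dispersion_is must be 'se' or 'sd'")


@dataclass(frozen=True)
class PreySpectrumParams:
    """Bacterial size-spectrum model over 1-10 µm ESD bins.

    mean ESD(treatment, day) = base + drift_rate[treatment] * max(0, day - drift_lag),
    clipped to the particle-counter range [1, 10] µm.  Drift is positive in
    the Colpidium-alone treatment (the small ciliate removes small cells)
    and negative in the Paramecium-alone treatment; the defaults separate
    the two monocultures by about 1 µm by day 14.
    """

    base_mean_esd: float = 2.5
    drift_rate_by_treatment: Mapping[str, float] = field(
        default_factory=lambda: {
            "species1_alone": 0.055,
            "species2_alone": -0.055,
            "both": 0.0,
            "resource_alone": 0.0,
        }
    )
    drift_lag: float = 5.0
    esd_sd: float = 0.6
    size_bins: tuple[int, ...] = tuple(range(1, 11))
    n_particles: int = 10_000

    def mean_esd(self, treatment: str, day: float) -> float:
        if treatment not in self.drift_rate_by_treatment:
            raise ValueError(f"no drift rate configured for treatment {treatment!r}")
        rate = self.drift_rate_by_treatment[treatment]
        return float(np.clip(self.base_mean_esd + rate * max(0.0, day - self.drift_lag), 1.0, 10.0))


@dataclass(frozen=True)
class GeneratorParams:
    """Everything stochastic about a synthetic experiment.

    Bacterial densities (cells/mL) per treatment are invented at realistic
    magnitudes: grazed treatments sit well below the ungrazed control, with
    the Colpidium monoculture grazing numbers lowest.
    """

    lv: LVParams = field(default_factory=default_lv_params)
    initial_count: int = 5
    obs_noise: bool = True
    cellsize_sp1: CellSizeParams = CellSizeParams(*CELLVOL_SP1)
    cellsize_sp2: CellSizeParams = CellSizeParams(*CELLVOL_SP2)
    dispersion_is: str = "se"
    prey: PreySpectrumParams = field(default_factory=PreySpectrumParams)
    bacteria_density_by_treatment: Mapping[str, float] = field(
        default_factory=lambda: {
            "species1_alone": 1.0e6,
            "species2_alone": 2.0e6,
            "both": 1.05e6,
            "resource_alone": 5.0e6,
        }
    )
    bacteria_density_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_count <= 0:
            raise ValueError("initial_count must be strictly positive")
        if self.dispersion_is not in ("se", "sd"):
            raise ValueError("dispersion_is must be 'se' or 'sd'")
        if any(v <= 0 for v in self.bacteria_density_by_treatment.values()):
            raise ValueError("bacterial densities must be strictly positive")


def _lognormal_mean_sd(rng: np.random.Generator, mean: float, sd: float, size) -> np.ndarray:
    """Lognormal draws with the given *arithmetic* mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return mean if size is None else np.full(size, mean, dtype=float)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def generate_cell_sizes(
    species_params: CellSizeParams,
    n: int,
    seed: int | np.random.Generator,
    dispersion_is: str = "se",
) -> np.ndarray:
    """Draw ``n`` per-cell volumes (µm³) from a lognormal size distribution.

    The lognormal's arithmetic mean equals ``species_params.mean_um3`` and
    its SD equals the population SD implied by the error reading, so the
    standard error of a sample mean at the configured n matches the summary.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = species_params.population_sd(dispersion_is)
    return _lognormal_mean_sd(rng, species_params.mean_um3, sd, n)


def generate_prey_spectrum(
    treatment: str,
    day: float,
    params: PreySpectrumParams,
    seed: int | np.random.Generator,
    duration_days: float = 15.0,
) -> pd.Series:
    """Binned particle counts over integer ESD bins for one sample.

    Particles are multinomial draws from a discretised normal with the
    treatment- and day-dependent mean ESD; counts are indexed by bin centre
    (µm).
    """
    if day < 0 or day > duration_days:
        raise ValueError(f"day {day} outside the experiment duration [0, {duration_days}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = params.mean_esd(treatment, day)
    bins = np.asarray(params.size_bins, dtype=float)
    edges = np.concatenate([bins - 0.5, [bins[-1] + 0.5]])
    if params.esd_sd <= 0:
        probs = np.zeros(bins.size)
        probs[np.argmin(np.abs(bins - mean))] = 1.0
    else:
        from scipy.stats import norm

        cdf = norm.cdf(edges, loc=mean, scale=params.esd_sd)
        probs = np.diff(cdf)
        probs = probs / probs.sum()
    counts = rng.multinomial(params.n_particles, probs)
    return pd.Series(counts, index=params.size_bins, name=f"{treatment}_day{day:g}").rename_axis("esd_um")


def _count_volume(density: float, dish_ml: float) -> float:
    """Aliquot (mL) actually counted at a given density, per the
    density-scaled counting protocol."""
    for upper, vol in COUNT_VOLUME_BREAKS:
        if density <= upper:
            return dish_ml if vol is None else vol
    raise AssertionError("unreachable")


def _treatment_species(treatment: str) -> list[str]:
    return {
        "species1_alone": [SPECIES1],
        "species2_alone": [SPECIES2],
        "both": [SPECIES1, SPECIES2],
        "resource_alone": [],
    }[treatment]


def generate_experiment(design: ExperimentDesign, params: GeneratorParams) -> pd.DataFrame:
    """Simulate one full experiment and return the long-format sample table.

    One row per (treatment, replicate, sampling day, species), consumers and
    bacteria alike, with columns ``treatment, replicate, day, species,
    density_per_ml, biovolume_um3``.  Consumer biovolume is per microcosm;
    density is cells/mL.  The latent trajectory is shared by all replicates
    of a treatment (the model has no process noise); replicates differ by
    observation noise only.  Samples are taken immediately *before* each
    medium exchange.  Fully reproducible from (design, params.seed).
    """
    unknown = set(design.treatments) - set(TREATMENTS)
    if unknown:
        raise ValueError(f"unknown treatment labels: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    dish = design.microcosm_volume_ml
    days = np.asarray(design.sampling_days, dtype=float)
    events = [(d, design.dilution_factor) for d in days]
    t_grid = days if days[0] == 0.0 else np.concatenate([[0.0], days])

    cellsize = {SPECIES1: params.cellsize_sp1, SPECIES2: params.cellsize_sp2}
    init_biovol = {
        SPECIES1: params.initial_count * params.cellsize_sp1.mean_um3,
        SPECIES2: params.initial_count * params.cellsize_sp2.mean_um3,
    }

    rows: list[tuple] = []
    for treatment in design.treatments:
        consumers = _treatment_species(treatment)
        if consumers:
            init = State(
                init_biovol[SPECIES1] if SPECIES1 in consumers else 0.0,
                init_biovol[SPECIES2] if SPECIES2 in consumers else 0.0,
            )
            latent = simulate(
                params.lv, init, t_grid, dilution_events=events, sample_before_events=True
            )
            latent = latent[-days.size :]  # drop the padded t=0 row if present
        for rep in range(1, design.n_replicates + 1):
            for i, day in enumerate(days):
                for sp in consumers:
                    col = 0 if sp == SPECIES1 else 1
                    biovol = latent[i, col]
                    mean_cell = cellsize[sp].mean_um3
                    true_density = biovol / (mean_cell * dish)
                    if params.obs_noise:
                        v = _count_volume(true_density, dish)
                        obs_density = rng.poisson(true_density * v) / v
                        cell_draw = _lognormal_mean_sd(
                            rng,
                            mean_cell,
                            cellsize[sp].population_sd(params.dispersion_is)
                            / np.sqrt(cellsize[sp].n),
                            None,
                        )
                    else:
                        obs_density, cell_draw = true_density, mean_cell
                    rows.append(
                        (treatment, rep, day, sp, float(obs_density), float(obs_density * dish * cell_draw))
                    )
                # bacterial prey: treatment-level density with lognormal noise,
                # biovolume from the drifting size spectrum's mean cell volume
                base_density = params.bacteria_density_by_treatment[treatment]
                esd = params.prey.mean_esd(treatment, day)
                cell_vol = np.pi / 6.0 * esd**3
                if params.obs_noise:
                    bact_density = float(
                        _lognormal_mean_sd(
                            rng, base_density, params.bacteria_density_cv * base_density, None
                        )
                    )
                else:
                    bact_density = base_density
                rows.append(
                    (treatment, rep, day, RESOURCE, bact_density, bact_density * dish * cell_vol)
                )
    return pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))


def write_sample_table(table: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a sample table as CSV, optionally with a ``#`` provenance line."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, index=False)


def read_sample_table(path) -> pd.DataFrame:
    """Read a sample-table CSV (ignoring ``#`` comment lines) and validate
    the schema."""
    df = pd.read_csv(path, comment="#")
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table at {path} is missing columns: {sorted(missing)}")
    return df


def params_with(params: GeneratorParams, **updates) -> GeneratorParams:
    """Functional update helper (frozen dataclass)."""
    return dataclasses.replace(params, **updates)
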