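"""End-to-end pipeline: generate/load -> steady states -> coefficients ->
RYT classification -> community function -> JSON summary.

All randomness flows from one root seed through named substreams (one per
stochastic stage), so a stage can be re-run in isolation and the whole
bundle is reproducible bit-for-bit from (config, seed).  Every output file
carries a header comment with the config hash and root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import community, competition, literature, ryt, steady_state, synthetic
from .lv import LVParams
from .synthetic import ExperimentDesign, GeneratorParams, SPECIES1, SPECIES2

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "assemble_report"]

log = logging.getLogger("lvcoex")

#: named substreams hanging off the root seed
_STAGES = {"generator": 0, "boot_alpha": 1, "boot_ryt": 2, "boot_band": 3}


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2**31)."""
    ss = np.random.SeedSequence(root_seed, spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs; YAML-loadable.

    If ``input_table`` is set the generator is skipped and the sample table
    is read from that CSV; otherwise a synthetic experiment is generated.
    """

    seed: int = 0
    out_dir: str = "lvcoex_out"
    input_table: str | None = None
    literature_table: str | None = None
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"biovolume": (8.0, 14.0), "density": (8.0, 14.0)}
    )
    n_boot: int = competition.DEFAULT_N_BOOT
    dist: str = competition.DEFAULT_DIST
    band_halfwidth: float | None = None  # None -> bootstrap band
    ci_aware: bool = True

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return PipelineConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        design = ExperimentDesign(**_tupled(raw.pop("design", {}), ("sampling_days", "treatments")))
        gen_raw = dict(raw.pop("generator", {}))
        lv = LVParams(**gen_raw.pop("lv")) if "lv" in gen_raw else synthetic.default_lv_params()
        for key in ("cellsize_sp1", "cellsize_sp2"):
            if key in gen_raw:
                gen_raw[key] = synthetic.CellSizeParams(**gen_raw[key])
        if "prey" in gen_raw:
            gen_raw["prey"] = synthetic.PreySpectrumParams(**_tupled(gen_raw["prey"], ("size_bins",)))
        generator = GeneratorParams(lv=lv, **gen_raw)
        windows = {k: tuple(v) for k, v in raw.pop("windows", {}).items()} or None
        cfg = PipelineConfig(
            design=design,
            generator=generator,
            **({"windows": windows} if windows else {}),
            **raw,
        )
        if cfg.input_table is not None and not Path(cfg.input_table).exists():
            raise FileNotFoundError(f"input_table does not exist: {cfg.input_table}")
        if cfg.literature_table is not None and not Path(cfg.literature_table).exists():
            raise FileNotFoundError(f"literature_table does not exist: {cfg.literature_table}")
        return cfg

    def config_hash(self) -> str:
        """Hash of everything that affects results (output location excluded)."""
        d = _as_jsonable(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _tupled(d: Mapping[str, Any], keys: tuple[str, ...]) -> dict:
    d = dict(d)
    for k in keys:
        if k in d:
            d[k] = tuple(d[k])
    return d


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the result bundle to ``out_dir``.

    Returns a dict with the in-memory objects (table, steady states, alpha
    estimate, RYT point, function tables, literature tallies, summary).
    Identical config + seed gives an identical bundle.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"config_hash={config.config_hash()} seed={config.seed}"
    win = tuple(config.windows.get("biovolume", steady_state.DEFAULT_WINDOW))

    # --- stage: input table -------------------------------------------------
    if config.input_table is not None:
        log.info("loading sample table from %s", config.input_table)
        table = synthetic.read_sample_table(config.input_table)
    else:
        gen = dataclasses.replace(config.generator, seed=stage_seed(config.seed, "generator"))
        log.info("generating synthetic experiment (seed %d)", gen.seed)
        table = synthetic.generate_experiment(config.design, gen)
    log.info("sample table: %d rows", len(table))
    _write_csv(table, out / "sample_table.csv", header)

    # --- stage: steady states ----------------------------------------------
    pairs = [
        ("species1_alone", SPECIES1),
        ("species2_alone", SPECIES2),
        ("both", SPECIES1),
        ("both", SPECIES2),
    ]
    ss_frame = steady_state.steady_state_frame(table, pairs, "biovolume", win)
    _write_csv(ss_frame, out / "steady_states.csv", header)
    K1 = steady_state.extract_steady_state(table, "species1_alone", SPECIES1, "biovolume", win)
    K2 = steady_state.extract_steady_state(table, "species2_alone", SPECIES2, "biovolume", win)
    C1 = steady_state.extract_steady_state(table, "both", SPECIES1, "biovolume", win)
    C2 = steady_state.extract_steady_state(table, "both", SPECIES2, "biovolume", win)

    # --- stage: competition coefficients ------------------------------------
    alphas = competition.estimate_alphas(
        K1, K2, C1, C2,
        n_boot=config.n_boot,
        seed=stage_seed(config.seed, "boot_alpha"),
        dist=config.dist,
    )
    log.info("alpha bootstrap: %d/%d draws rejected", alphas.n_rejected, alphas.n_boot)
    neutrality = competition.neutrality_report(alphas)
    alpha_frame = pd.DataFrame(
        [
            {
                "coefficient": "a12",
                "point": alphas.a12_hat,
                "ci_lo": alphas.ci95_12[0],
                "ci_hi": alphas.ci95_12[1],
                "includes_one": alphas.includes_one_12,
                "n_boot": alphas.n_boot,
                "seed": alphas.seed,
            },
            {
                "coefficient": "a21",
                "point": alphas.a21_hat,
                "ci_lo": alphas.ci95_21[0],
                "ci_hi": alphas.ci95_21[1],
                "includes_one": alphas.includes_one_21,
                "n_boot": alphas.n_boot,
                "seed": alphas.seed,
            },
        ]
    )
    _write_csv(alpha_frame, out / "alphas.csv", header)

    # --- stage: RYT ----------------------------------------------------------
    point = ryt.normalize_state(
        C1, K1, C2, K2,
        n_boot=config.n_boot, seed=stage_seed(config.seed, "boot_ryt"), dist=config.dist,
    )
    band = (
        config.band_halfwidth
        if config.band_halfwidth is not None
        else ryt.ryt_band(
            K1, K2, C1, C2,
            n_boot=config.n_boot, seed=stage_seed(config.seed, "boot_band"), dist=config.dist,
        )
    )
    point = ryt.classify_region(point, band_halfwidth=band, ci_aware=config.ci_aware)
    trajectory = ryt.state_space_trajectory(table, "both", "biovolume")
    _write_csv(trajectory.reset_index(), out / "state_space_trajectory.csv", header)
    _write_csv(ryt.ryt_line(K1.mean, K2.mean), out / "ryt_line_biovolume.csv", header)
    _write_csv(ryt.ryt_line(1.0, 1.0), out / "ryt_line_normalized.csv", header)

    # --- stage: community function & resource -------------------------------
    func_levels, func_contrasts = community.function_table(table, win, "biovolume")
    _write_csv(func_levels, out / "function_levels.csv", header)
    _write_csv(func_contrasts, out / "function_contrasts.csv", header)
    rstar_levels, rstar_contrasts = steady_state.r_star_table(table, win, "biovolume")
    _write_csv(rstar_levels, out / "rstar_levels.csv", header)
    _write_csv(rstar_contrasts, out / "rstar_contrasts.csv", header)

    # --- stage: literature ---------------------------------------------------
    lit_path = config.literature_table or literature.packaged_studies_path()
    records = literature.read_study_table(lit_path)
    lit_frame, tallies = literature.classify_studies(records)
    _write_csv(lit_frame, out / "literature_regions.csv", header)

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "window": list(win),
        "steady_states": {
            "K1": {"mean": K1.mean, "se": K1.se},
            "K2": {"mean": K2.mean, "se": K2.se},
            "C1": {"mean": C1.mean, "se": C1.se},
            "C2": {"mean": C2.mean, "se": C2.se},
        },
        "alphas": {
            "a12": {"point": alphas.a12_hat, "ci": list(alphas.ci95_12)},
            "a21": {"point": alphas.a21_hat, "ci": list(alphas.ci95_21)},
            "n_boot": alphas.n_boot,
            "n_rejected": alphas.n_rejected,
        },
        "neutrality": {k: v for k, v in neutrality.items() if k != "text"},
        "ryt": {
            "y1": point.y1,
            "y2": point.y2,
            "ryt": point.ryt,
            "ci_y1": list(point.ci_y1),
            "ci_y2": list(point.ci_y2),
            "band_halfwidth": band,
            "region": point.region,
        },
        "function_contrasts": func_contrasts.to_dict(orient="records"),
        "literature_tallies": tallies,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(_as_jsonable(summary), fh, indent=2)
    log.info("pipeline complete; bundle in %s", out)
    return {
        "table": table,
        "steady_states": {"K1": K1, "K2": K2, "C1": C1, "C2": C2},
        "alphas": alphas,
        "neutrality": neutrality,
        "ryt_point": point,
        "band_halfwidth": band,
        "trajectory": trajectory,
        "function": (func_levels, func_contrasts),
        "rstar": (rstar_levels, rstar_contrasts),
        "literature": (lit_frame, tallies),
        "summary": summary,
    }


def assemble_report(out_dir) -> dict:
    """Re-assemble summary.json from previously written stage outputs.

    Raises a clear error if a required stage output is missing.
    """
    out = Path(out_dir)
    required = ["steady_states.csv", "alphas.csv", "literature_regions.csv"]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing stage outputs in {out}: {missing}; run the generate/estimate/"
            "ryt/literature stages (or the full pipeline) first"
        )
    report = {
        "steady_states": pd.read_csv(out / "steady_states.csv", comment="#").to_dict("records"),
        "alphas": pd.read_csv(out / "alphas.csv", comment="#").to_dict("records"),
        "literature": pd.read_csv(out / "literature_regions.csv", comment="#").to_dict("records"),
    }
    with open(out / "summary_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
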