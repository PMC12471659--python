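"""Orchestration: lifetime design curves, experiment validation, batch runs.

Numbers are the artifact of record: every stage emits tidy long-format CSV
tables; plotting is a convenience that renders only from the exported
table. Years-in-service conversion is fixed at 1.2 × 10⁶ cycles = 5 years
(240,000 cycles/year); design-curve figures sometimes mark this only
approximately, the tables here use the exact conversion.
"""

from __future__ import annotations

import logging
import math
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__, model
from .experiment import (
    OUTCOME_FAILED,
    load_packaged_experiment,
    summarize_group,
    write_specimen_csv,
)
from .params import (
    Band,
    CeramicMaterial,
    FatigueProtocol,
    FoundationStack,
    LoadCase,
    ModelConstants,
    load_presets,
    preset_constants,
    preset_foundation,
    preset_geometry,
    preset_load,
    preset_material,
    preset_protocol,
)
from .simulate import CohortSpec, fit_strength_distribution, simulate_cohort

logger = logging.getLogger("ovfatigue")

__all__ = [
    "ConfigError",
    "ModelConfig",
    "ValidationReport",
    "build_lifetime_curves",
    "validate_against_experiment",
    "run_config",
    "packaged_run_config",
    "plot_lifetime_curves",
]

CURVE_COLUMNS = [
    "material",
    "band",
    "thickness_mm",
    "critical_load_FnR_N",
    "log10_cycles",
    "years_equivalent",
]


class ConfigError(ValueError):
    """A configuration file violates the expected schema; the message names
    the offending key path."""


@dataclass(frozen=True)
class ModelConfig:
    """Resolved model context shared by all pipeline stages."""

    foundation: FoundationStack
    load: LoadCase
    constants: ModelConstants
    protocol: FatigueProtocol
    cusp_incline_theta: float
    lower_strength_policy: str = "mean_minus_sd"

    @classmethod
    def packaged_defaults(cls) -> "ModelConfig":
        presets = load_presets()
        return cls(
            foundation=preset_foundation(presets),
            load=preset_load(presets),
            constants=preset_constants(presets),
            protocol=preset_protocol(presets),
            cusp_incline_theta=presets["geometry"]["cusp_incline_theta"],
        )

    def geometry(self, thickness_d: float):
        from .params import VeneerGeometry

        return VeneerGeometry(
            thickness_d=thickness_d, cusp_incline_theta=self.cusp_incline_theta
        )


@dataclass(frozen=True)
class ValidationReport:
    """Observed vs. predicted outcome for one experimental group."""

    group_id: str
    n_specimens: int
    n_failed: int
    observed_failure_fraction: float
    predicted_lower_log10_cycles: float
    predicted_mean_log10_cycles: float
    n_observed_within_band: int
    geomean_observed_over_lower: float | None  # None when no failures
    predicted_failure_probability_at_censor: float


def build_lifetime_curves(
    materials: list[CeramicMaterial],
    d_grid,
    bands=(Band.lower, Band.mean),
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Predicted critical load and lifetime for every material × band ×
    thickness: the numeric content of the lifetime design chart.

    Thicknesses outside the model's empirical validity domain are skipped
    with a warning rather than aborting the table.
    """
    config = config or ModelConfig.packaged_defaults()
    rows, errors = [], []
    for material in materials:
        for band in bands:
            for d in d_grid:
                try:
                    pred = model.predict_lifetime(
                        material,
                        config.geometry(float(d)),
                        config.foundation,
                        config.load,
                        config.constants,
                        band=band,
                        lower_strength_policy=config.lower_strength_policy,
                    )
                except model.DomainError as err:
                    errors.append(str(err))
                    continue
                rows.append(
                    {
                        "material": material.name,
                        "band": Band(band).value,
                        "thickness_mm": float(d),
                        "critical_load_FnR_N": pred.critical_load_FnR,
                        "log10_cycles": pred.log10_cycles_to_failure,
                        "years_equivalent": 10.0**pred.log10_cycles_to_failure
                        / config.protocol.cycles_per_year
                        if pred.log10_cycles_to_failure < 300
                        else math.inf,
                    }
                )
    for msg in errors:
        logger.warning("curve row skipped: %s", msg)
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def validate_against_experiment(
    table: pd.DataFrame,
    group_id: str,
    materials: dict[str, CeramicMaterial] | None = None,
    config: ModelConfig | None = None,
) -> ValidationReport:
    """Compare one experimental group's observed outcomes with the model's
    lower/mean prediction band.

    Counts how many observed failure cycle counts fall inside
    [lower, mean] (in log₁₀ cycles), forms the geometric-mean ratio of
    observed failures to the lower-band prediction, and evaluates the
    closed-form failure probability at the censoring cycle count using the
    material's mean SCG exponent.
    """
    config = config or ModelConfig.packaged_defaults()
    if materials is None:
        presets = load_presets()
        materials = {
            m.name: m
            for m in (preset_material(k, presets) for k in presets["materials"])
        }
    summary = summarize_group(table, group_id, config.protocol)
    grp = table[table["group_id"] == group_id]
    material_name = grp["material"].iloc[0]
    thickness = float(grp["thickness_mm"].iloc[0])
    try:
        material = materials[material_name]
    except KeyError:
        raise KeyError(
            f"group {group_id!r} references material {material_name!r} with no "
            f"packaged parameters; known: {sorted(materials)}"
        ) from None

    geometry = config.geometry(thickness)
    common = dict(
        foundation=config.foundation,
        load=config.load,
        constants=config.constants,
        lower_strength_policy=config.lower_strength_policy,
    )
    lower = model.predict_lifetime(material, geometry, band=Band.lower, **common)
    mean = model.predict_lifetime(material, geometry, band=Band.mean, **common)

    failed_cycles = grp.loc[grp["outcome"] == OUTCOME_FAILED, "cycles"]
    log10_failed = failed_cycles.map(math.log10)
    within = int(
        (
            (log10_failed >= lower.log10_cycles_to_failure)
            & (log10_failed <= mean.log10_cycles_to_failure)
        ).sum()
    )
    geomean_ratio = (
        10.0 ** (float(log10_failed.mean()) - lower.log10_cycles_to_failure)
        if summary.n_failed
        else None
    )
    p_fail = model.failure_probability_before(
        config.protocol.total_cycles,
        material,
        geometry,
        config.foundation,
        config.load,
        config.constants,
        scg_exponent_N=material.scg_exponent_mean,
    )
    return ValidationReport(
        group_id=group_id,
        n_specimens=summary.n_specimens,
        n_failed=summary.n_failed,
        observed_failure_fraction=summary.failure_fraction,
        predicted_lower_log10_cycles=lower.log10_cycles_to_failure,
        predicted_mean_log10_cycles=mean.log10_cycles_to_failure,
        n_observed_within_band=within,
        geomean_observed_over_lower=geomean_ratio,
        predicted_failure_probability_at_censor=p_fail,
    )


# ---------------------------------------------------------------------------
# Batch runs from a TOML configuration


def _require(cfg: dict, key: str, path: str):
    if key not in cfg:
        raise ConfigError(f"missing required key {path}.{key}")
    return cfg[key]


def packaged_run_config() -> str:
    """Text of the packaged default run configuration (write it to a file
    and pass it to :func:`run_config` or the ``run`` CLI verb)."""
    from importlib import resources

    return resources.files("ovfatigue.data").joinpath("default_run.toml").read_text()


def _load_run_config(config_path) -> dict:
    with open(config_path, "rb") as fh:
        try:
            return tomllib.load(fh)
        except tomllib.TOMLDecodeError as err:
            raise ConfigError(f"unparseable configuration: {err}") from err


def run_config(config_path, output_dir=None, seed: int | None = None) -> dict:
    """Execute the stages named in a TOML run configuration and write CSV
    tables plus a plain-text log to the output directory.

    Re-running an identical configuration reproduces byte-identical
    outputs. Returns {stage name: output path}.
    """
    cfg = _load_run_config(config_path)
    run_cfg = cfg.get("run", {})
    out = Path(output_dir or run_cfg.get("output_dir", "ovfatigue-out"))
    out.mkdir(parents=True, exist_ok=True)
    base_seed = int(seed if seed is not None else run_cfg.get("seed", 0))

    presets = load_presets()
    config = ModelConfig.packaged_defaults()
    if "model" in cfg and "lower_strength_policy" in cfg["model"]:
        from dataclasses import replace

        config = replace(
            config, lower_strength_policy=cfg["model"]["lower_strength_policy"]
        )
    material_by_name = {
        m.name: m for m in (preset_material(k, presets) for k in presets["materials"])
    }

    outputs: dict[str, Path] = {}
    log_lines = [
        f"ovfatigue {__version__}",
        f"config: {Path(config_path).name}",
        f"seed: {base_seed}",
        f"resolved model config: {asdict(config)}",
    ]

    if "curves" in cfg:
        c = cfg["curves"]
        names = _require(c, "materials", "curves")
        for name in names:
            if name not in material_by_name:
                raise ConfigError(
                    f"curves.materials: unknown material {name!r}; "
                    f"packaged: {sorted(material_by_name)}"
                )
        mats = [material_by_name[n] for n in names]
        bands = [Band(b) for b in c.get("bands", ["lower", "mean"])]
        d_min, d_max = c.get("d_min", 0.3), c.get("d_max", 1.5)
        step = c.get("d_step", 0.01)
        n_steps = int(round((d_max - d_min) / step))
        d_grid = [round(d_min + i * step, 10) for i in range(n_steps + 1)]
        curves = build_lifetime_curves(mats, d_grid, bands, config)
        outputs["curves"] = out / "lifetime_curves.csv"
        curves.to_csv(outputs["curves"], index=False)
        log_lines.append(
            f"curves: {len(curves)} rows over d in [{d_min}, {d_max}] mm"
        )

    if "validate" in cfg:
        v = cfg["validate"]
        table = load_packaged_experiment(config.protocol)
        groups = v.get("groups") or sorted(table["group_id"].unique())
        reports = [
            validate_against_experiment(table, g, material_by_name, config)
            for g in groups
        ]
        outputs["validation"] = out / "validation_report.csv"
        pd.DataFrame([asdict(r) for r in reports]).to_csv(
            outputs["validation"], index=False
        )
        outputs["experiment"] = out / "experiment_record.csv"
        write_specimen_csv(table, outputs["experiment"])
        log_lines.append(f"validate: groups {groups}")

    if "simulate" in cfg:
        s = cfg["simulate"]
        name = _require(s, "material", "simulate")
        if name not in material_by_name:
            raise ConfigError(f"simulate.material: unknown material {name!r}")
        spec = CohortSpec(
            material=material_by_name[name],
            geometry=config.geometry(_require(s, "thickness_mm", "simulate")),
            foundation=config.foundation,
            load=config.load,
            constants=config.constants,
            scg_exponent=s.get("scg_exponent"),
            n_specimens=s.get("n_specimens", 12),
            censor_cycles=s.get("censor_cycles", config.protocol.total_cycles),
            seed=base_seed,
        )
        cohort = simulate_cohort(spec)
        outputs["simulation"] = out / "simulated_cohort.csv"
        write_specimen_csv(cohort, outputs["simulation"])
        log_lines.append(
            f"simulate: {spec.n_specimens} specimens of {name} at "
            f"{spec.geometry.thickness_d} mm, seed {base_seed}"
        )
        if s.get("fit", False):
            try:
                fit = fit_strength_distribution(cohort, spec)
            except ValueError as err:
                log_lines.append(f"fit skipped: {err}")
            else:
                outputs["fit"] = out / "strength_fit.csv"
                pd.DataFrame([asdict(fit)]).to_csv(outputs["fit"], index=False)
                log_lines.append(
                    f"fit: mean {fit.strength_mean_hat:.1f} MPa, "
                    f"sd {fit.strength_sd_hat:.1f} MPa"
                )

    log_path = out / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs["log"] = log_path
    return outputs


def plot_lifetime_curves(curves: pd.DataFrame, path) -> None:
    """Render the design chart (log₁₀ cycles vs. thickness, one line per
    material × band) from an exported curve table. Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for (mat, band), sub in curves.groupby(["material", "band"]):
        ax.plot(
            sub["thickness_mm"],
            sub["log10_cycles"],
            linestyle="--" if band == "lower" else "-",
            label=f"{mat} ({band})",
        )
    ax.axhline(math.log10(1_200_000), color="grey", lw=0.8)
    ax.set_xlabel("veneer thickness d (mm)")
    ax.set_ylabel("log10 cycles to radial fracture")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
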