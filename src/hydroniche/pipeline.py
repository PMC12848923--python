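"""End-to-end analysis pipeline.

Orchestrates: data generation (or CSV ingestion) -> meteoric-line fit ->
per-site soil source summaries -> Bayesian mixing per site x group x
species -> site contribution table with herb-to-shrub ratios and stability
classes -> restoration-age trend -> dynamics regime report and bifurcation
scan -> run manifest. A single seed fans out to per-stage sub-streams via
``SeedSequence`` spawn keys, so any stage can be re-run in isolation
reproducibly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import PipelineError
from .isotopes import (
    DEFAULT_DEPTH_GROUPS,
    DELTA_ENVELOPE,
    SAMPLE_COLUMNS,
    fit_meteoric_line,
    read_samples,
    summarize_sources,
)
from .mixing import MixingConfig, aggregate_layers, run_mixing, summarize
from .partition import age_trend, classify_stability, site_contribution
from .synthetic import (
    ChronosequenceDataset,
    GeneratorSettings,
    default_chronosequence,
    generate_chronosequence,
)
from .dynamics import (
    DEFAULT_SITE_RATIOS,
    REPORTED_REGIMES,
    DynParams,
    bifurcation_scan,
    calibrate_regimes,
    site_stability,
)

__all__ = ["PipelineConfig", "ValidationReport", "PipelineResult", "validate_inputs", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    mode: str = "synthetic"  # synthetic | csv
    precipitation_csv: str | None = None
    soil_csv: str | None = None
    xylem_csv: str | None = None
    outdir: str | None = None
    seed: int = 0
    generator: GeneratorSettings = field(default_factory=GeneratorSettings)
    mixing: MixingConfig | None = None  # None -> reduced default plan
    depth_groups: dict = field(default_factory=lambda: dict(DEFAULT_DEPTH_GROUPS))
    stable_max: float = 0.9
    unstable_min: float = 1.4
    dynamics_params: DynParams = field(default_factory=DynParams)
    site_ratios: dict = field(default_factory=lambda: dict(DEFAULT_SITE_RATIOS))
    sites: Sequence[str] | None = None  # restrict to a subset of site ids

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Build a config from a YAML mapping; nested ``generator``,
        ``mixing`` and ``dynamics_params`` mappings populate the
        corresponding settings objects, everything else maps to the
        flat fields."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise PipelineError("config", f"{path} must contain a YAML mapping")
        kwargs = dict(raw)
        if "generator" in kwargs:
            kwargs["generator"] = GeneratorSettings(**kwargs["generator"])
        if "mixing" in kwargs and kwargs["mixing"] is not None:
            mix = dict(kwargs["mixing"])
            if "residual_sd_prior_scale" in mix:
                mix["residual_sd_prior_scale"] = tuple(mix["residual_sd_prior_scale"])
            kwargs["mixing"] = MixingConfig(**mix)
        if "dynamics_params" in kwargs:
            kwargs["dynamics_params"] = DynParams(**kwargs["dynamics_params"])
        unknown = set(kwargs) - {f.name for f in fields(cls)}
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class ValidationReport:
    errors: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class PipelineResult:
    lmwl: object
    contributions: pd.DataFrame
    site_table: pd.DataFrame
    trend: dict
    dynamics_table: pd.DataFrame
    bifurcation: pd.DataFrame
    calibration_summary: str
    manifest: dict


def validate_inputs(samples: pd.DataFrame) -> ValidationReport:
    """Schema and range checks on a combined sample table."""
    errors, warns = [], []
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        errors.append(f"missing columns: {missing}")
        return ValidationReport(errors, warns)
    bad_type = set(samples["sample_type"]) - {"precipitation", "soil", "xylem"}
    if bad_type:
        errors.append(f"unknown sample_type values: {sorted(bad_type)}")
    soil = samples[samples["sample_type"] == "soil"]
    if soil["depth_top_cm"].isna().any() or soil["depth_bottom_cm"].isna().any():
        errors.append("soil rows must carry both depth fields")
    else:
        bad = soil[soil["depth_top_cm"] >= soil["depth_bottom_cm"]]
        for i in bad.index:
            errors.append(
                f"row {i}: depth_top_cm >= depth_bottom_cm "
                f"({bad.loc[i, 'depth_top_cm']} >= {bad.loc[i, 'depth_bottom_cm']})"
            )
    lo, hi = DELTA_ENVELOPE
    for col in ("d2H_permil", "d18O_permil"):
        vals = pd.to_numeric(samples[col], errors="coerce")
        if vals.isna().any():
            errors.append(f"non-numeric values in {col}")
            continue
        out = samples[(vals < lo) | (vals > hi)]
        for i in out.index:
            warns.append(
                f"row {i}: {col} = {samples.loc[i, col]} outside the "
                f"[{lo}, {hi}] permil envelope"
            )
    return ValidationReport(errors, warns)


def _load_csv_mode(config: PipelineConfig) -> ChronosequenceDataset:
    frames = {}
    for name, path in (
        ("precipitation", config.precipitation_csv),
        ("soil", config.soil_csv),
        ("xylem", config.xylem_csv),
    ):
        if path is None or not Path(path).exists():
            raise PipelineError("ingest", f"missing {name} CSV: {path}")
        frames[name] = read_samples(path)
    return ChronosequenceDataset(
        precipitation=frames["precipitation"],
        soil=frames["soil"],
        xylem=frames["xylem"],
        truth=pd.DataFrame(columns=["site_id", "group", "layer", "true_proportion"]),
        sites=pd.DataFrame(),
    )


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis and (optionally) write the report bundle."""
    config = config or PipelineConfig()
    mixing_cfg = config.mixing or MixingConfig(seed=config.seed).reduced()

    # --- stage 1: data ---------------------------------------------------
    if config.mode == "synthetic":
        from dataclasses import replace

        gen = replace(config.generator, seed=config.seed)
        sites_cfg = default_chronosequence()
        if config.sites is not None:
            sites_cfg = [s for s in sites_cfg if s.site_id in set(config.sites)]
            if not sites_cfg:
                raise PipelineError("generate", f"no sites match {config.sites}")
        data = generate_chronosequence(gen, sites_cfg)
    elif config.mode == "csv":
        data = _load_csv_mode(config)
    else:
        raise PipelineError("config", f"unknown mode {config.mode!r}")

    report = validate_inputs(data.samples())
    if not report.ok:
        raise PipelineError("validate", "; ".join(report.errors))

    # --- stage 2: meteoric line ------------------------------------------
    try:
        lmwl = fit_meteoric_line(data.precipitation)
    except Exception as e:  # noqa: BLE001 - annotate with stage
        raise PipelineError("lmwl", str(e)) from e

    # --- stage 3-4: sources + mixing per site/group/species --------------
    site_ids = list(dict.fromkeys(data.soil["site_id"]))
    ages = (
        dict(zip(data.sites["site_id"], data.sites["restoration_age"]))
        if not data.sites.empty
        else {}
    )
    contrib_rows = []
    for s_idx, sid in enumerate(site_ids):
        soil = data.soil[data.soil["site_id"] == sid]
        try:
            sources = summarize_sources(soil)
        except Exception as e:
            raise PipelineError("sources", f"site {sid}: {e}") from e
        xyl_site = data.xylem[data.xylem["site_id"] == sid]
        for g_idx, group in enumerate(dict.fromkeys(xyl_site["group"])):
            for sp_idx, species in enumerate(
                dict.fromkeys(xyl_site[xyl_site["group"] == group]["species"])
            ):
                mix = xyl_site[
                    (xyl_site["group"] == group) & (xyl_site["species"] == species)
                ]
                sub_seed = int(
                    np.random.SeedSequence(
                        config.seed, spawn_key=(5, s_idx, g_idx, sp_idx)
                    ).generate_state(1)[0] % (2**31)
                )
                from dataclasses import replace as _replace

                try:
                    post = run_mixing(mix, sources, _replace(mixing_cfg, seed=sub_seed))
                    agg = aggregate_layers(post, config.depth_groups)
                    summ = summarize(agg)
                except Exception as e:
                    raise PipelineError(
                        "mixing", f"site {sid}, group {group}, species {species}: {e}"
                    ) from e
                for _, row in summ.iterrows():
                    contrib_rows.append(
                        dict(
                            site_id=sid,
                            group=group,
                            species=species,
                            depth_group=row["source"],
                            mean_pct=row["mean_pct"],
                            sd_pct=row["sd_pct"],
                            ci_low_pct=row["ci_low_pct"],
                            ci_high_pct=row["ci_high_pct"],
                        )
                    )
    contributions = pd.DataFrame(contrib_rows)

    # --- stage 5: site ratio table ----------------------------------------
    main_group = {"herb": "0-20 cm", "shrub": "40-100 cm", "semi-shrub": "20-40 cm"}
    site_rows = []
    for sid in site_ids:
        sub = contributions[contributions["site_id"] == sid]
        def _means(group):
            sel = sub[(sub["group"] == group) & (sub["depth_group"] == main_group[group])]
            return list(sel["mean_pct"])
        herb, shrub = _means("herb"), _means("shrub")
        if not herb or not shrub:
            continue
        age = ages.get(sid)
        sc = site_contribution(
            sid, herb, shrub,
            restoration_age=None if sid == "CK" else age,
        )
        cls = classify_stability(sc.R_hs, config.stable_max, config.unstable_min)
        site_rows.append(
            dict(
                site_id=sid,
                restoration_age=sc.restoration_age,
                C_h_pct=sc.C_h,
                C_s_pct=sc.C_s,
                R_hs=sc.R_hs,
                stability_class=cls,
            )
        )
    site_table = pd.DataFrame(site_rows)

    # --- stage 6: age trend (dated sites only) ----------------------------
    trend: dict = {}
    dated = site_table[site_table["restoration_age"].notna()] if not site_table.empty else site_table
    if len(dated) >= 3:
        r, p, n = age_trend(list(zip(dated["restoration_age"], dated["C_s_pct"])))
        trend = {"statistic": "pearson_r", "value": r, "p_value": p, "n_sites": n}

    # --- stage 7: dynamics -------------------------------------------------
    dyn_rows = []
    for sid, ratio in config.site_ratios.items():
        res = site_stability(ratio, config.dynamics_params)
        dyn_rows.append(
            dict(site_id=sid, R_hs=ratio, max_re=res.max_re, regime=res.regime)
        )
    dynamics_table = pd.DataFrame(dyn_rows)
    scan_table, crossings = bifurcation_scan(
        config.dynamics_params, np.round(np.arange(0.5, 2.001, 0.01), 3)
    )
    calib = calibrate_regimes(
        [(config.site_ratios[s], REPORTED_REGIMES[s]) for s in config.site_ratios
         if s in REPORTED_REGIMES],
        config.dynamics_params,
    )

    manifest = {
        "package": "hydroniche",
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "n_sites": len(site_ids),
        "mixing": asdict(mixing_cfg),
        "generator": asdict(config.generator) if config.mode == "synthetic" else None,
        "python": platform.python_version(),
        "bifurcation_candidates": crossings,
    }

    result = PipelineResult(
        lmwl=lmwl,
        contributions=contributions,
        site_table=site_table,
        trend=trend,
        dynamics_table=dynamics_table,
        bifurcation=scan_table,
        calibration_summary=calib.summary(),
        manifest=manifest,
    )

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        if config.mode == "synthetic":
            data.to_csv(out / "data")
        contributions.to_csv(out / "contributions.csv", index=False)
        site_table.to_csv(out / "site_stability.csv", index=False)
        dynamics_table.to_csv(out / "dynamics_regimes.csv", index=False)
        scan_table.to_csv(out / "bifurcation_scan.csv", index=False)
        lm = {
            "slope": lmwl.slope, "intercept": lmwl.intercept,
            "r_squared": lmwl.r_squared, "n": lmwl.n,
            "residual_sd": lmwl.residual_sd,
        }
        (out / "lmwl.json").write_text(json.dumps(lm, indent=2))
        (out / "age_trend.json").write_text(json.dumps(trend, indent=2))
        (out / "calibration.txt").write_text(result.calibration_summary + "\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result
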