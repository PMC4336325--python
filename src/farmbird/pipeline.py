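"""End-to-end scenario-forecasting pipeline.

Orchestrates: synthetic landscape -> SDM consensus + downscaling ->
farmland-cover scenarios -> survey simulation + GLMM fits -> driver
decomposition -> guild summaries. Every stage writes plain CSV artifacts
into the output directory and the run ends with a manifest of SHA-256
hashes; identical config + seed reproduces identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import fit_glmm, overdispersion_ratio, prepare_counts, r2_mixed
from .consensus import ModelProjection, auc, consensus_projection
from .forecast import (
    DEFAULT_COMBOS,
    classify_main_habitat,
    compute_ssig,
    driver_decomposition,
    region_weight,
    tukey_hsd,
    weighted_mean_sd,
    one_sample_t,
)
from .scenarios import ScenarioConfigError, apply_scenario, default_scenario, load_scenario, SCENARIO_NAMES
from .spatial import OverlapMatrix, downscale_to_regions, farmland_proportion
from .synthetic import (
    CROPS,
    generate_grid,
    generate_model_projections,
    generate_overlaps,
    generate_regions,
    generate_species,
    generate_surveys,
    regions_to_frame,
    species_to_frame,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_inputs"]

log = logging.getLogger("farmbird")

STAGES = ("simulate", "scenarios", "fit", "forecast", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible run."""

    out_dir: str = "farmbird_out"
    seed: int = 0
    n_regions: int = 50
    n_farmland: int = 4
    n_generalist: int = 2
    years: list[int] = field(default_factory=lambda: list(range(2001, 2006)))
    n_cells: int = 12
    n_sdm_models: int = 4
    scenarios: list[str] = field(default_factory=lambda: list(SCENARIO_NAMES))
    combos: list[str] = field(default_factory=lambda: [c.name for c in DEFAULT_COMBOS])
    olre: bool = True
    standardize: bool = True
    min_farmland_points: int = 5
    reference_crop: str = "forage_crops"  # dropped from the design (shares sum to 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolve_scenarios(self):
        specs = []
        for s in self.scenarios:
            if s in SCENARIO_NAMES:
                specs.append(default_scenario(s))
            else:
                try:
                    specs.append(load_scenario(s))
                except ScenarioConfigError as e:
                    raise PipelineError("config", str(e)) from e
        return specs

    def resolve_combos(self):
        by_name = {c.name: c for c in DEFAULT_COMBOS}
        unknown = [c for c in self.combos if c not in by_name]
        if unknown:
            raise PipelineError("config", f"unknown driver combinations: {unknown}")
        return [by_name[c] for c in self.combos]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, artifacts: dict) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    artifacts[path.name] = _sha256(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the artifact manifest."""
    # resolve config fully before writing anything, so a bad config leaves
    # no partial outputs behind
    scenario_specs = config.resolve_scenarios()
    combos = config.resolve_combos()
    if config.reference_crop not in CROPS:
        raise PipelineError("config", f"unknown reference crop {config.reference_crop!r}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)
    artifacts: dict[str, str] = {}
    seed = config.seed

    # --- simulate: landscape, community, grid, projections -----------------
    log.info(json.dumps({"stage": "simulate", "seed": seed, "version": __version__}))
    regions = generate_regions(config.n_regions, seed)
    species = generate_species(config.n_farmland, config.n_generalist, seed)
    sp_ids = [p.species_id for p in species]
    grid = generate_grid(config.n_cells, seed, species_ids=sp_ids)
    overlaps = OverlapMatrix(generate_overlaps(regions, config.n_cells, seed))

    # farmland proportions: class fractions -> cell proportion -> region
    for period, attr in (("current", "farmland_prop_current"), ("future", "farmland_prop_future")):
        cell_prop = pd.Series(
            farmland_proportion(
                grid[f"pasture_{period}"], grid[f"cultivated_{period}"], grid[f"mosaic_{period}"]
            ),
            index=grid["cell_id"].to_numpy(),
        )
        reg_prop = downscale_to_regions(cell_prop, overlaps)
        for r in regions:
            setattr(r, attr, float(reg_prop[r.region_id]))

    # consensus suitability per species: rank synthetic model layers by AUC
    # against cell-level presence (suitability above the median), weight, mean
    proj_frames = []
    suit_rows = []
    for sp in sp_ids:
        proj = generate_model_projections(grid, sp, config.n_sdm_models, seed)
        proj_frames.append(proj.assign(species_id=sp))
        latent = grid[f"suit_current_{sp}"].to_numpy()
        presence = (latent > np.median(latent)).astype(int)
        consensus = {}
        for period in ("current", "future"):
            projections = []
            for m, sub in proj[proj["period"] == period].groupby("model_id"):
                layer = pd.Series(sub["value"].to_numpy(), index=sub["cell_id"].to_numpy())
                cur_layer = proj[(proj["period"] == "current") & (proj["model_id"] == m)]
                scores = pd.Series(
                    cur_layer["value"].to_numpy(), index=cur_layer["cell_id"].to_numpy()
                ).reindex(grid["cell_id"]).to_numpy()
                projections.append(
                    ModelProjection(model_id=m, suitability=layer, mean_auc=auc(scores, presence))
                )
            consensus[period] = downscale_to_regions(consensus_projection(projections), overlaps)
        for r in regions:
            suit_rows.append(
                (sp, r.region_id, float(consensus["current"][r.region_id]),
                 float(consensus["future"][r.region_id]))
            )
    suitability = pd.DataFrame(suit_rows, columns=["species_id", "region_id", "current", "future"])

    # surveys driven by the consensus suitabilities
    suit_map = {(s, r): c for s, r, c, _ in suitability.itertuples(index=False)}
    surveys = generate_surveys(regions, species, config.years, seed, suitability=suit_map)

    _write(regions_to_frame(regions), out / "regions.csv", artifacts)
    _write(species_to_frame(species), out / "species.csv", artifacts)
    _write(grid, out / "grid.csv", artifacts)
    _write(overlaps.table, out / "overlaps.csv", artifacts)
    _write(pd.concat(proj_frames, ignore_index=True), out / "projections.csv", artifacts)
    _write(suitability, out / "suitability.csv", artifacts)
    _write(surveys, out / "surveys.csv", artifacts)

    # --- scenarios ----------------------------------------------------------
    log.info(json.dumps({"stage": "scenarios", "seed": seed, "version": __version__}))
    future_shares: dict[str, pd.DataFrame] = {}
    national_frames = []
    for spec in scenario_specs:
        try:
            fut_regions, changes, national = apply_scenario(regions, spec)
        except Exception as e:
            raise PipelineError("scenarios", f"scenario {spec.name!r}: {e}") from e
        shares = pd.DataFrame(
            [dict(zip(CROPS, r.crop_shares), region_id=r.region_id, agroecosystem=r.agroecosystem)
             for r in fut_regions]
        )
        future_shares[spec.name] = shares
        national_frames.append(national.assign(scenario=spec.name))
        _write(shares, out / f"future_shares_{spec.name}.csv", artifacts)
    _write(pd.concat(national_frames, ignore_index=True), out / "national_shares.csv", artifacts)

    # --- fit ---------------------------------------------------------------
    log.info(json.dumps({"stage": "fit", "seed": seed, "version": __version__}))
    abundance = prepare_counts(surveys, species, config.min_farmland_points)
    _write(abundance, out / "abundance.csv", artifacts)

    region_frame = regions_to_frame(regions).set_index("region_id")
    model_crops = [c for c in CROPS if c != config.reference_crop]
    covariates = ["suitability", "farmland_prop", "n_points"] + model_crops
    random_effects = ("region", "year", "obs") if config.olre else ("region", "year")

    fits = {}
    fit_meta = []
    for p in species:
        rows = abundance[abundance["species_id"] == p.species_id].copy()
        rows["suitability"] = [
            suit_map[(p.species_id, r)] for r in rows["region_id"]
        ]
        rows["farmland_prop"] = region_frame.loc[rows["region_id"], "farmland_prop_current"].to_numpy()
        for c in CROPS:
            rows[c] = region_frame.loc[rows["region_id"], c].to_numpy()
        try:
            fit = fit_glmm(rows, covariates, random_effects=random_effects,
                           standardize=config.standardize)
        except ValueError as e:
            raise PipelineError("fit", f"species {p.species_id}: {e}") from e
        fits[p.species_id] = (fit, rows)
        r2m, r2c = r2_mixed(fit)
        meta = {
            "species_id": p.species_id,
            "params": fit.params,
            "se": fit.se,
            "var_region": fit.var_region,
            "var_year": fit.var_year,
            "var_obs": fit.var_obs,
            "loglik": fit.loglik,
            "converged": fit.converged,
            "r2_marginal": r2m,
            "r2_conditional": r2c,
            "overdispersion": overdispersion_ratio(fit),
        }
        path = out / "fits" / f"{p.species_id}.json"
        path.write_text(json.dumps(meta, indent=2, sort_keys=True))
        artifacts[f"fits/{p.species_id}.json"] = _sha256(path)
        fit_meta.append(meta)

    # --- forecast ------------------------------------------------------------
    log.info(json.dumps({"stage": "forecast", "seed": seed, "version": __version__}))
    guilds = {}
    for p in species:
        if p.specialization == "farmland" and p.subhabitat_abundance is not None:
            guilds[p.species_id] = classify_main_habitat(compute_ssig(p.subhabitat_abundance))
        else:
            guilds[p.species_id] = "generalist"
    guild_df = pd.DataFrame(
        {"species_id": list(guilds), "guild": [guilds[s] for s in guilds],
         "specialization": [p.specialization for p in species]}
    )
    _write(guild_df, out / "species_guilds.csv", artifacts)

    effort = abundance.groupby("region_id")["n_points"].mean()
    change_frames = []
    for p in species:
        fit, rows = fits[p.species_id]
        sub = suitability[suitability["species_id"] == p.species_id].set_index("region_id")
        rids = [r.region_id for r in regions if r.region_id in effort.index]
        base = pd.DataFrame({"region_id": rids})
        base["suitability"] = sub.loc[rids, "current"].to_numpy()
        base["farmland_prop"] = region_frame.loc[rids, "farmland_prop_current"].to_numpy()
        base["n_points"] = effort.loc[rids].to_numpy()
        for c in CROPS:
            base[c] = region_frame.loc[rids, c].to_numpy()
        areas = region_frame.loc[rids, "area"].to_numpy()
        w = region_weight(areas, base["n_points"].to_numpy())
        for spec in scenario_specs:
            fut = base.copy()
            fut["suitability"] = sub.loc[rids, "future"].to_numpy()
            fut["farmland_prop"] = region_frame.loc[rids, "farmland_prop_future"].to_numpy()
            shares = future_shares[spec.name].set_index("region_id")
            for c in CROPS:
                fut[c] = shares.loc[rids, c].to_numpy()
            changes, _ = driver_decomposition(fit, base, fut, combos=combos, weights=w)
            change_frames.append(changes.assign(species_id=p.species_id, scenario=spec.name))
    all_changes = pd.concat(change_frames, ignore_index=True)[
        ["species_id", "scenario", "combo", "region_id", "change", "weight"]
    ]
    _write(all_changes, out / "changes.csv", artifacts)

    # --- report ---------------------------------------------------------------
    log.info(json.dumps({"stage": "report", "seed": seed, "version": __version__}))
    all_changes = all_changes.merge(guild_df[["species_id", "guild", "specialization"]], on="species_id")
    summary_rows = []
    for (scenario, combo), sub in all_changes.groupby(["scenario", "combo"]):
        groups = {"all": sub}
        for spec_label, g in sub.groupby("specialization"):
            groups[spec_label] = g
        for guild, g in sub[sub["specialization"] == "farmland"].groupby("guild"):
            groups[guild] = g
        for label, g in groups.items():
            mean, sd = weighted_mean_sd(g["change"], g["weight"])
            if len(g) >= 2 and np.ptp(g["change"].to_numpy()) > 0:
                t, pval = one_sample_t(g["change"], g["weight"])
            else:
                t, pval = np.nan, np.nan
            summary_rows.append((scenario, combo, label, len(g), mean, sd, t, pval))
    summary = pd.DataFrame(
        summary_rows, columns=["scenario", "combo", "group", "n", "mean", "sd", "t", "p"]
    )
    _write(summary, out / "summary.csv", artifacts)

    pairwise_rows = []
    final = all_changes[all_changes["combo"] == combos[-1].name]
    for scenario, sub in final.groupby("scenario"):
        sets = [("specialization", sub.groupby("specialization"))]
        farm = sub[sub["specialization"] == "farmland"]
        if farm["guild"].nunique() >= 2:
            sets.append(("guild", farm.groupby("guild")))
        for label, grouped in sets:
            groups = {k: g["change"].to_numpy() for k, g in grouped if len(g) >= 2}
            if len(groups) < 2:
                continue
            tk = tukey_hsd(groups)
            for rec in tk.itertuples(index=False):
                pairwise_rows.append((scenario, label) + tuple(rec))
    pairwise = pd.DataFrame(
        pairwise_rows,
        columns=["scenario", "grouping", "group1", "group2", "diff", "lower", "upper", "p_adj"],
    )
    _write(pairwise, out / "pairwise.csv", artifacts)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "artifacts": dict(sorted(artifacts.items())),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def validate_inputs(out_dir: str | Path) -> list[dict]:
    """Check artifact tables against the domain invariants.

    Returns a machine-readable list of violations (empty when valid):
    crop shares must sum to 1, proportions and fractions must lie in [0, 1],
    and per-region overlap fractions must sum to 1.
    """
    out = Path(out_dir)
    violations: list[dict] = []

    regions_path = out / "regions.csv"
    if regions_path.exists():
        regions = pd.read_csv(regions_path)
        share_sums = regions[list(CROPS)].sum(axis=1)
        for rid, s in zip(regions["region_id"], share_sums):
            if abs(s - 1.0) > 1e-6:
                violations.append(
                    {"rule": "crop_shares_sum_to_1", "region_id": rid, "value": float(s)}
                )
        for col in ("farmland_prop_current", "farmland_prop_future"):
            if col in regions:
                bad = regions[(regions[col] < 0) | (regions[col] > 1)]
                for rid in bad["region_id"]:
                    violations.append({"rule": f"{col}_in_unit_interval", "region_id": rid})

    overlap_path = out / "overlaps.csv"
    if overlap_path.exists():
        tab = pd.read_csv(overlap_path)
        sums = tab.groupby("region_id")["fraction"].sum()
        for rid, s in sums.items():
            if abs(s - 1.0) > 1e-6:
                violations.append(
                    {"rule": "overlap_fractions_sum_to_1", "region_id": rid, "value": float(s)}
                )
        bad = tab[(tab["fraction"] < 0) | (tab["fraction"] > 1)]
        for rid in bad["region_id"]:
            violations.append({"rule": "overlap_fraction_in_unit_interval", "region_id": rid})

    suit_path = out / "suitability.csv"
    if suit_path.exists():
        suit = pd.read_csv(suit_path)
        for col in ("current", "future"):
            bad = suit[(suit[col] < 0) | (suit[col] > 1)]
            for _, row in bad.iterrows():
                violations.append(
                    {"rule": "suitability_in_unit_interval", "species_id": row["species_id"],
                     "region_id": row["region_id"]}
                )
    return violations
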