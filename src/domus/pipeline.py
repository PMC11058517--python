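"""End-to-end analysis pipeline and report bundle.

Orchestrates: read or generate a society table -> recode EA codes ->
climate summaries -> Box-Cox + varimax composites -> neighbour table and
borrowing fractions -> per-response full mixed model -> Moran residual
diagnostics -> nested-model enumeration -> AICc averaging -> importance and
accuracy summaries -> CSV/JSON report bundle.  Identical config + seed
produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from domus import climate as climate_mod
from domus import io_dplace, spatial
from domus.multimodel import (ModelSpec, average_model, complete_cases,
                              crosstab_percent, effect_profile,
                              enumerate_models, fit_candidates)
from domus.world import RESPONSES, WorldConfig, generate_world

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

#: reference category of each response (fixed, declared)
REFERENCE = {"ground_plan": "rounded", "floor_level": "ground",
             "wall_material": "thick", "roof_shape": "sloped"}

DEFAULT_PREDICTORS = (
    "temperature_harshness", "mountain_dwelling", "xeric_harshness",
    "polygyny", "settlement", "political_complexity",
    "temperature_harshness:political_complexity", "borrowing",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``society_table`` (with optional ``climate_table``) or
    ``synthetic`` must be provided.  Defaults follow the analysis constants:
    10 nearest neighbours, 12 Moran distance classes, 3 varimax components,
    10 Colwell states.
    """

    society_table: Optional[str] = None
    climate_table: Optional[str] = None
    synthetic: Optional[WorldConfig] = None
    seed: int = 0
    output_dir: str = "domus_output"
    n_states: int = 10
    pca_k: int = 3
    k_neighbors: int = 10
    n_moran_classes: int = 12
    moran_permutations: int = 0
    responses: tuple = RESPONSES
    predictors: tuple = DEFAULT_PREDICTORS
    random_effect: bool = True
    var_tol: float = 1e-3
    profile_grid: tuple = (-2.0, 2.0, 25)

    def __post_init__(self):
        has_files = self.society_table is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValueError(
                "exactly one of society_table or synthetic must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        synth = raw.pop("synthetic", None)
        if synth is not None:
            cf = synth.pop("climate_field", None)
            from domus.world import ClimateFieldConfig
            kwargs = dict(synth)
            if cf is not None:
                kwargs["climate_field"] = ClimateFieldConfig(**cf)
            synth = WorldConfig(**kwargs)
        for key in ("responses", "predictors", "profile_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(synthetic=synth, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ResponseResult:
    response: str
    full_fit: object
    averaged: object
    correlograms: dict
    n_used: int


@dataclass
class ResultBundle:
    config: RunConfig
    data: pd.DataFrame
    composites: object
    neighbors: object
    results: dict = field(default_factory=dict)
    crosstab: tuple = None
    output_dir: Optional[Path] = None


def _load_or_generate(cfg: RunConfig):
    if cfg.synthetic is not None:
        world = generate_world(cfg.synthetic, seed=cfg.seed)
        return world.records, world.climate
    df = io_dplace.read_society_table(cfg.society_table,
                                      climate_path=cfg.climate_table)
    return df, df.attrs.get("climate", {})


def assemble_analysis_table(records: pd.DataFrame, climate: dict,
                            cfg: RunConfig):
    """Recode, summarise climate, build composites and borrowing columns."""
    t0 = time.perf_counter()
    data = io_dplace.recode_table(records)
    logger.info("recoded %d societies", len(data))

    rows = []
    for sid, elev, slope in zip(data["society_id"], data["elevation_m"],
                                data["slope_deg"]):
        pair = climate.get(sid)
        rec = type("R", (), {
            "temp_monthly": None if pair is None else pair[0],
            "precip_monthly": None if pair is None else pair[1],
            "elevation_m": elev, "slope_deg": slope})
        s = climate_mod.summarize_climate(rec, n_states=cfg.n_states)
        row = {v: getattr(s, v) for v in climate_mod.DEFAULT_PCA_VARIABLES}
        row["society_id"] = sid
        row["climate_missing"] = s.missing
        rows.append(row)
    summaries = pd.DataFrame(rows).set_index("society_id")

    usable = summaries[~summaries["climate_missing"]].drop(
        columns="climate_missing").dropna()
    comp = climate_mod.environmental_composites(
        usable, k=cfg.pca_k) if len(usable) else None
    data = data.set_index("society_id", drop=False)
    if comp is not None:
        for c in comp.scores.columns:
            data[c] = comp.scores[c]
    logger.info("composites for %d societies (%.2fs)", len(usable),
                time.perf_counter() - t0)

    nbrs = spatial.nearest_neighbors(data, k=cfg.k_neighbors)
    for resp in cfg.responses:
        data[f"borrowing_{resp}"] = spatial.borrowing_fraction(
            data[resp].tolist(), nbrs)
    return data.reset_index(drop=True), summaries, comp, nbrs


def analyse_response(data: pd.DataFrame, response: str, cfg: RunConfig,
                     dist: Optional[np.ndarray] = None) -> ResponseResult:
    """Full fit, residual diagnostics and multimodel average for one response."""
    t0 = time.perf_counter()
    predictors = tuple(p if p != "borrowing" else f"borrowing_{response}"
                       for p in cfg.predictors)
    sub = data.rename(columns={f"borrowing_{response}": "borrowing"})
    predictors = tuple(p if not p.startswith("borrowing_") else "borrowing"
                       for p in predictors)
    full = ModelSpec(response=response, predictors=predictors,
                     random_effect=cfg.random_effect,
                     ref_category=REFERENCE[response])
    cc = complete_cases(sub, full)
    if len(cc) < 30:
        raise RuntimeError(
            f"stage analyse_response[{response}]: only {len(cc)} usable "
            f"societies of {len(sub)}")
    observed = [c for c in _declared_levels(response)
                if (cc[response] == c).any()]
    specs = enumerate_models(full)
    fits = fit_candidates(specs, cc, categories=observed,
                          var_tol=cfg.var_tol)
    full_fit = fits[_full_index(specs, full)]
    if not full_fit.converged:
        conv = [f for f in fits if f.converged]
        logger.warning("%s: full model did not converge; diagnostics use "
                       "the best converged fit", response)
        full_fit = min(conv, key=lambda f: f.aicc)
    avg = average_model(fits, cc, full)
    d = spatial.pairwise_distances_km(cc["lon"].to_numpy(),
                                      cc["lat"].to_numpy())
    corr = spatial.categorical_residual_correlograms(
        cc[response].to_numpy(object), full_fit.fitted_prob,
        full_fit.categories, dist=d, n_classes=cfg.n_moran_classes,
        permutations=cfg.moran_permutations, seed=cfg.seed)
    logger.info("%s: n=%d, %d candidate models, accuracy %.3f (%.2fs)",
                response, len(cc), len(specs), avg.accuracy,
                time.perf_counter() - t0)
    return ResponseResult(response=response, full_fit=full_fit, averaged=avg,
                          correlograms=corr, n_used=len(cc))


def _declared_levels(response: str):
    ref = REFERENCE[response]
    levels = list(io_dplace.HOUSE_LEVELS[response])
    return [ref] + [l for l in levels if l != ref]


def _full_index(specs, full) -> int:
    for i, s in enumerate(specs):
        if set(s.predictors) == set(full.predictors) \
                and s.random_effect == full.random_effect:
            return i
    raise RuntimeError("full model missing from enumeration")


def run_pipeline(cfg: RunConfig, write: bool = True) -> ResultBundle:
    """Execute the whole analysis; optionally write the report bundle."""
    records, climate = _load_or_generate(cfg)
    data, summaries, comp, nbrs = assemble_analysis_table(records, climate,
                                                          cfg)
    bundle = ResultBundle(config=cfg, data=data, composites=comp,
                          neighbors=nbrs)
    for resp in cfg.responses:
        bundle.results[resp] = analyse_response(data, resp, cfg)
    bundle.crosstab = crosstab_percent(
        data["polygyny"], data["ground_plan"],
        a_levels=io_dplace.SOCIAL_LEVELS["polygyny"],
        b_levels=io_dplace.HOUSE_LEVELS["ground_plan"])
    if write:
        write_bundle(bundle, summaries)
    return bundle


def write_bundle(bundle: ResultBundle, summaries: pd.DataFrame) -> Path:
    cfg = bundle.config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _csv(df: pd.DataFrame, name: str, index=False):
        df.to_csv(out / name, index=index, float_format=FLOAT_FMT)

    _csv(bundle.data, "societies.csv")
    _csv(summaries.reset_index(), "climate_summaries.csv")
    if bundle.composites is not None:
        _csv(bundle.composites.loadings.reset_index(names="component"),
             "pca_loadings.csv")
    _csv(bundle.neighbors.to_frame(), "neighbors.csv")

    summary_rows = []
    for resp, res in bundle.results.items():
        fit = res.full_fit
        rows = []
        for c_ix, cat in enumerate(fit.categories[1:]):
            for t_ix, term in enumerate(fit.term_names):
                est = fit.coef[c_ix, t_ix]
                se = fit.se[c_ix, t_ix]
                rows.append({"term": term, "category": cat, "estimate": est,
                             "se": se,
                             "z": est / se if se and np.isfinite(se) else np.nan})
        _csv(pd.DataFrame(rows), f"full_model_{resp}.csv")

        avg = res.averaged
        arows = []
        for cat in avg.avg_coef.index:
            for term in avg.avg_coef.columns:
                arows.append({"term": term, "category": cat,
                              "estimate": avg.avg_coef.loc[cat, term],
                              "uncond_se": avg.uncond_se.loc[cat, term]})
        _csv(pd.DataFrame(arows), f"averaged_model_{resp}.csv")

        mor = []
        for cat, cg in res.correlograms.items():
            f = cg.to_frame()
            f.insert(0, "category", cat)
            mor.append(f)
        _csv(pd.concat(mor, ignore_index=True), f"moran_{resp}.csv")

        row = {"response": resp, "n": res.n_used,
               "chance": avg.chance, "modal": avg.modal,
               "average_model_accuracy": avg.accuracy}
        for term, imp in sorted(avg.importance.items()):
            row[f"importance:{term}"] = imp
        summary_rows.append(row)

        lo, hi, num = cfg.profile_grid
        grid = np.linspace(lo, hi, int(num))
        for comp_name in ("temperature_harshness", "mountain_dwelling",
                          "xeric_harshness"):
            if comp_name not in avg.design_columns:
                continue
            has_inter = any(":" in c and comp_name in c.split(":")
                            for c in avg.design_columns)
            if has_inter and "political_complexity" in avg.design_columns:
                prof = effect_profile(avg, comp_name, grid,
                                      by="political_complexity",
                                      by_levels=(1.0, 5.0))
            else:
                prof = effect_profile(avg, comp_name, grid)
            _csv(prof, f"profile_{resp}_{comp_name}.csv")

    _csv(pd.DataFrame(summary_rows), "summary.csv")
    pct, counts = bundle.crosstab
    _csv(pct.reset_index(names="polygyny"), "crosstab_ground_plan_percent.csv")
    _csv(counts.reset_index(names="polygyny"), "crosstab_ground_plan_counts.csv")

    cfg_dict = cfg.to_dict()
    cfg_dict.pop("output_dir", None)  # bundle location, not analysis config
    manifest = {
        "config": _jsonable(cfg_dict),
        "seed": cfg.seed,
        "package": "domus 0.1.0",
        "versions": _versions(),
        "n_societies": int(len(bundle.data)),
        "responses": {r: int(res.n_used)
                      for r, res in bundle.results.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle.output_dir = out
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _versions() -> dict:
    import scipy
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__}
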