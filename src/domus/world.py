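"""Synthetic worlds with known generative structure.

The generator emulates the statistical structure the analysis assumes:
societies scattered on a sphere with spatially clustered language families,
spatially autocorrelated climate whose mean, seasonality and predictability
are independently tunable, social traits drawn from stated prevalences, and
house features generated by a multinomial-logit model on the environmental
composites and social traits with language-family random intercepts
(vertical transmission) plus an optional neighbour-contagion process
(horizontal transmission).  Every generated world passes the society-table
validation and carries its full ground truth for recovery tests.

All randomness flows from a single integer seed through named substreams
(geography, climate, social, one per house response, contagion, missing),
spawned in that order from one ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from domus import climate as climate_mod
from domus import spatial
from domus.io_dplace import HOUSE_LEVELS, SOCIAL_LEVELS
from domus.multimodel import build_design, design_columns

logger = logging.getLogger(__name__)

#: representative raw EA code for each analysis category (inverse recode)
_CATEGORY_TO_CODE = {
    "ground_plan": {"rounded": 1, "angular": 4},
    "floor_level": {"subterranean": 1, "ground": 2, "elevated": 3},
    "wall_material": {"thick": 1, "wood_bamboo": 5, "fabric_skins": 10,
                      "thatch": 8},
    "roof_shape": {"rounded_domed": 1, "sloped": 6, "flat": 7},
    "polygyny": {"none": 1, "occasional": 2, "frequent": 4},
    "settlement": {"nomadic": 1, "sedentary": 5},
}
_EA_COLUMN = {"ground_plan": "ea079", "floor_level": "ea080",
              "wall_material": "ea081", "roof_shape": "ea082",
              "polygyny": "ea009", "settlement": "ea030"}

RESPONSES = ("ground_plan", "floor_level", "wall_material", "roof_shape")


@dataclass
class ClimateFieldConfig:
    """Tunables of the simulated climate field."""

    gradient_strength: float = 0.55     # deg C lost per degree |latitude|
    spatial_range_km: float = 1500.0    # kernel range of site effects
    seasonal_amplitude: float = 18.0    # deg C peak-to-mean at the poles
    predictability_knob: float = 0.7    # 1 = exactly repeating years
    temp_noise_sd: float = 3.0          # deg C month-to-month noise at knob 0
    precip_noise_sd: float = 0.6        # log-scale noise at knob 0


@dataclass
class HouseTraitModel:
    """Generative model of one house feature.

    ``coef`` maps a design-column name (e.g. ``temperature_harshness`` or
    ``polygyny[frequent]``) to one value per non-reference category, in the
    declared category order.  ``family_sigma`` is the SD of the per-family
    random intercept, shared across categories.
    """

    categories: tuple
    intercepts: tuple
    coef: dict
    family_sigma: float = 1.0
    contagion_eta: float = 0.0
    contagion_rounds: int = 0


@dataclass
class WorldConfig:
    n_societies: int = 1140
    n_families: int = 60
    family_clustering_km: float = 700.0
    climate_field: ClimateFieldConfig = field(default_factory=ClimateFieldConfig)
    n_years: int = 50
    social_prevalences: dict = field(default_factory=lambda: {
        "polygyny": {"none": 0.20, "occasional": 0.35, "frequent": 0.45},
        "settlement": {"sedentary": 0.75, "nomadic": 0.25},
        "political_complexity": {1: 0.45, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.05},
    })
    house_models: dict = None
    missing_rate: float = 0.02
    k_neighbors: int = 10
    n_states: int = 10

    def __post_init__(self):
        if self.n_families > self.n_societies:
            raise ValueError("n_families must be <= n_societies")
        if not (0.0 <= self.climate_field.predictability_knob <= 1.0):
            raise ValueError("predictability_knob must lie in [0, 1]")
        for name, val in (("family_clustering_km", self.family_clustering_km),
                          ("spatial_range_km",
                           self.climate_field.spatial_range_km)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.house_models is None:
            self.house_models = default_house_models()


def default_house_models(family_sigma: float = 1.0,
                         contagion_eta: float = 1.0,
                         contagion_rounds: int = 2) -> dict:
    """Strong-signal generative models echoing the field's expectations.

    Angular ground plans rise with political complexity and sedentism and
    fall with frequent polygyny; elevated floors occur where warm and wet,
    subterranean where cold; thick walls where cold and dry, fabric/skins
    among nomads; sloped roofs where wet, flat where dry.
    """
    return {
        "ground_plan": HouseTraitModel(
            categories=HOUSE_LEVELS["ground_plan"],   # ref rounded
            intercepts=(-1.6,),
            coef={"political_complexity": (0.7,),
                  "settlement[nomadic]": (-1.4,),
                  "polygyny[frequent]": (-1.0,),
                  "temperature_harshness": (-0.6,),
                  "temperature_harshness:political_complexity": (0.25,)},
            family_sigma=family_sigma, contagion_eta=contagion_eta,
            contagion_rounds=contagion_rounds),
        "floor_level": HouseTraitModel(
            categories=HOUSE_LEVELS["floor_level"],   # ref ground
            intercepts=(-2.0, -1.2),                  # subterranean, elevated
            coef={"temperature_harshness": (1.4, -1.2),
                  "xeric_harshness": (0.5, -1.0),
                  "polygyny[frequent]": (0.8, 0.0)},
            family_sigma=family_sigma, contagion_eta=contagion_eta,
            contagion_rounds=contagion_rounds),
        "wall_material": HouseTraitModel(
            categories=HOUSE_LEVELS["wall_material"],  # ref thick
            intercepts=(0.6, 0.2, -0.8),  # wood_bamboo, fabric_skins, thatch
            coef={"temperature_harshness": (-1.0, 0.5, -1.2),
                  "xeric_harshness": (-0.8, 0.3, -1.0),
                  "settlement[nomadic]": (0.0, 1.8, 0.0),
                  "mountain_dwelling": (-0.6, 0.0, -0.4)},
            family_sigma=family_sigma, contagion_eta=contagion_eta,
            contagion_rounds=contagion_rounds),
        "roof_shape": HouseTraitModel(
            categories=HOUSE_LEVELS["roof_shape"],     # ref sloped
            intercepts=(-0.6, -1.6),                   # rounded_domed, flat
            coef={"temperature_harshness": (1.0, 0.4),
                  "xeric_harshness": (0.8, 1.5),
                  "settlement[nomadic]": (1.2, 0.0)},
            family_sigma=family_sigma, contagion_eta=contagion_eta,
            contagion_rounds=contagion_rounds),
    }


@dataclass
class SyntheticWorld:
    records: pd.DataFrame           # canonical society table
    climate: dict                   # society_id -> (temp, precip) matrices
    scores: pd.DataFrame            # composite scores used in generation
    truth: dict                     # config, family intercepts, linear preds
    config: WorldConfig = None


def _spatial_field(dist_km: np.ndarray, range_km: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially correlated field by kernel-weighted mixing."""
    n = dist_km.shape[0]
    z = rng.normal(size=n)
    w = np.exp(-0.5 * (dist_km / range_km) ** 2)
    return (w @ z) / np.sqrt((w ** 2).sum(axis=1))


def _destination(lon: np.ndarray, lat: np.ndarray, bearing: np.ndarray,
                 dist_km: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Great-circle destination points (vectorised spherical trig)."""
    lat1 = np.radians(lat)
    lon1 = np.radians(lon)
    delta = dist_km / spatial.EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta)
                     + np.cos(lat1) * np.sin(delta) * np.cos(bearing))
    lon2 = lon1 + np.arctan2(np.sin(bearing) * np.sin(delta) * np.cos(lat1),
                             np.cos(delta) - np.sin(lat1) * np.sin(lat2))
    lon2 = (np.degrees(lon2) + 180.0) % 360.0 - 180.0
    return lon2, np.degrees(lat2)


def generate_geography(cfg: WorldConfig, rng: np.random.Generator):
    """Family seed points uniform on the sphere; societies clustered round them."""
    n, G = cfg.n_societies, cfg.n_families
    seed_lon = rng.uniform(-180.0, 180.0, G)
    seed_lat = np.degrees(np.arcsin(rng.uniform(-1.0, 1.0, G)))
    fam = np.concatenate([np.arange(G), rng.integers(0, G, n - G)])
    rng.shuffle(fam)
    bearing = rng.uniform(0.0, 2 * np.pi, n)
    disp = np.abs(rng.normal(0.0, cfg.family_clustering_km, n))
    lon, lat = _destination(seed_lon[fam], seed_lat[fam], bearing, disp)
    lat = np.clip(lat, -89.9, 89.9)
    dist = spatial.pairwise_distances_km(lon, lat)
    relief = _spatial_field(dist, cfg.climate_field.spatial_range_km / 2, rng)
    elev = np.exp(6.0 + 0.9 * relief)
    elev = np.clip(elev, 1.0, 6000.0)
    slope = np.clip(np.abs(0.004 * elev + 2.0 * rng.normal(size=n)), 0.05, 45.0)
    labels = np.array([f"fam{f + 1:03d}" for f in fam], dtype=object)
    return lon, lat, labels, elev, slope, dist


def simulate_monthly_climate(cfg: WorldConfig, lon, lat, dist,
                             rng: np.random.Generator) -> dict:
    """Monthly temperature/precipitation per society, one years x 12 pair each.

    Temperature combines a latitudinal gradient, a spatially correlated site
    effect and a seasonal cosine whose amplitude grows with |latitude|
    (phase flipped across hemispheres); precipitation is the exponential of
    an analogous field, hence positive.  Month-to-month noise is scaled by
    (1 - predictability_knob), stronger at higher latitudes, so knob = 1
    yields exactly repeating annual cycles.
    """
    cf = cfg.climate_field
    n = len(lon)
    ny = cfg.n_years
    if ny < 5:
        raise ValueError("n_years must be >= 5")
    months = np.arange(12)
    site_t = 4.0 * _spatial_field(dist, cf.spatial_range_km, rng)
    site_p = 1.0 * _spatial_field(dist, cf.spatial_range_km, rng)
    alat = np.abs(lat)
    mean_t = 27.0 - cf.gradient_strength * alat + site_t
    amp_t = cf.seasonal_amplitude * alat / 90.0 + 0.5
    phase = np.where(lat >= 0, 6.5, 0.5)
    noise_scale = (1.0 - cf.predictability_knob) * (0.3 + 1.4 * alat / 90.0)
    mean_logp = 4.3 + site_p - 1.2 * alat / 90.0
    amp_p = 0.3 + 0.8 * alat / 90.0
    out = {}
    season = np.cos(2 * np.pi * (months[None, :] - phase[:, None]) / 12.0)
    for i in range(n):
        base_t = mean_t[i] + amp_t[i] * season[i]
        noise_t = rng.normal(0.0, 1.0, (ny, 12)) * cf.temp_noise_sd * noise_scale[i]
        temp = base_t[None, :] + noise_t
        base_p = mean_logp[i] + amp_p[i] * season[i]
        noise_p = rng.normal(0.0, 1.0, (ny, 12)) * cf.precip_noise_sd * noise_scale[i]
        precip = np.exp(base_p[None, :] + noise_p)
        out[i] = (temp, precip)
    return out


def _compute_scores(cfg: WorldConfig, clim: dict, elev, slope) -> pd.DataFrame:
    """Environmental composites of the generated climate via the pipeline."""
    rows = []
    for i in sorted(clim):
        temp, precip = clim[i]
        rec = type("R", (), {"temp_monthly": temp, "precip_monthly": precip,
                             "elevation_m": elev[i], "slope_deg": slope[i]})
        s = climate_mod.summarize_climate(rec, n_states=cfg.n_states)
        rows.append({v: getattr(s, v)
                     for v in climate_mod.DEFAULT_PCA_VARIABLES})
    summaries = pd.DataFrame(rows)
    comp = climate_mod.environmental_composites(summaries)
    return comp.scores


def simulate_social_traits(cfg: WorldConfig, n: int,
                           rng: np.random.Generator) -> pd.DataFrame:
    out = {}
    for trait, prev in cfg.social_prevalences.items():
        levels = list(prev.keys())
        p = np.array([prev[l] for l in levels], dtype=float)
        p = p / p.sum()
        out[trait] = rng.choice(np.asarray(levels, dtype=object), size=n, p=p)
    df = pd.DataFrame(out)
    df["political_complexity"] = df["political_complexity"].astype(float)
    return df


def _draw_categories(eta_full: np.ndarray, rng: np.random.Generator,
                     categories: Sequence) -> np.ndarray:
    m = eta_full - eta_full.max(axis=1, keepdims=True)
    p = np.exp(m)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(eta_full.shape[0])
    cum = p.cumsum(axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return np.asarray(categories, dtype=object)[idx]


def simulate_house_traits(cfg: WorldConfig, design_df: pd.DataFrame,
                          families: np.ndarray, nbrs,
                          rng_by_response: dict, contagion_rng) -> tuple:
    """Draw each house feature, then run the contagion passes.

    The initial draw uses linear predictors beta'x + u_family per
    non-reference category; each contagion round redraws every society
    simultaneously with an added eta * (neighbour share of each category)
    term, a finite-round approximation of an autologistic field.
    """
    n = len(design_df)
    fam_levels = pd.unique(families)
    fam_ix = pd.Series(range(len(fam_levels)), index=fam_levels)
    gi = fam_ix[families].to_numpy()
    traits = {}
    truth = {}
    for resp in RESPONSES:
        hm: HouseTraitModel = cfg.house_models[resp]
        rng = rng_by_response[resp]
        cats = list(hm.categories)
        J = len(cats)
        u = rng.normal(0.0, hm.family_sigma, (len(fam_levels), J - 1))
        terms = list(hm.coef.keys())
        eta = np.tile(np.asarray(hm.intercepts, float), (n, 1))
        for t in terms:
            col = _design_column(design_df, t)
            eta += col[:, None] * np.asarray(hm.coef[t], float)[None, :]
        eta = eta + u[gi]
        eta_full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
        y = _draw_categories(eta_full, rng, cats)
        for _ in range(hm.contagion_rounds):
            share = np.zeros((n, J))
            for j, c in enumerate(cats):
                ind = (y == c).astype(float)
                share[:, j] = ind[nbrs.neighbor_index].mean(axis=1)
            y = _draw_categories(eta_full + hm.contagion_eta * share,
                                 contagion_rng, cats)
        traits[resp] = y
        truth[resp] = {"intercepts": np.asarray(hm.intercepts, float),
                       "coef": {t: np.asarray(v, float)
                                for t, v in hm.coef.items()},
                       "family_sigma": hm.family_sigma,
                       "family_intercepts": {f: u[i] for i, f in
                                             enumerate(fam_levels)},
                       "categories": tuple(cats),
                       "eta_initial": eta_full}
    return traits, truth


def _design_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if term in df.columns:
        return df[term].to_numpy(float)
    if ":" in term:
        a, b = term.split(":")
        return _design_column(df, a) * _design_column(df, b)
    if "[" in term:
        base, level = term[:-1].split("[")
        return (df[base].astype(object).to_numpy() == _maybe_num(level)).astype(float)
    raise KeyError(term)


def _maybe_num(s: str):
    try:
        return float(s)
    except ValueError:
        return s


def generate_world(cfg: Optional[WorldConfig] = None,
                   seed: int = 0) -> SyntheticWorld:
    """Generate a full synthetic world; deterministic given config + seed."""
    cfg = cfg or WorldConfig()
    ss = np.random.SeedSequence(seed)
    (ss_geo, ss_clim, ss_soc, ss_gp, ss_fl, ss_wm, ss_rs,
     ss_cont, ss_miss) = ss.spawn(9)
    rng_geo = np.random.default_rng(ss_geo)
    lon, lat, families, elev, slope, dist = generate_geography(cfg, rng_geo)
    n = cfg.n_societies
    clim = simulate_monthly_climate(cfg, lon, lat, dist,
                                    np.random.default_rng(ss_clim))
    scores = _compute_scores(cfg, clim, elev, slope)
    social = simulate_social_traits(cfg, n, np.random.default_rng(ss_soc))
    design_df = pd.concat([scores.reset_index(drop=True),
                           social.reset_index(drop=True)], axis=1)
    nbrs = spatial.nearest_neighbors(
        pd.DataFrame({"society_id": [f"S{i+1:04d}" for i in range(n)],
                      "lon": lon, "lat": lat}),
        k=min(cfg.k_neighbors, n - 1), dist=dist)
    rngs = {"ground_plan": np.random.default_rng(ss_gp),
            "floor_level": np.random.default_rng(ss_fl),
            "wall_material": np.random.default_rng(ss_wm),
            "roof_shape": np.random.default_rng(ss_rs)}
    traits, truth = simulate_house_traits(cfg, design_df, families, nbrs,
                                          rngs, np.random.default_rng(ss_cont))

    rng_miss = np.random.default_rng(ss_miss)
    ids = [f"S{i+1:04d}" for i in range(n)]
    rec = pd.DataFrame({
        "society_id": ids, "lon": lon, "lat": lat,
        "language_family": families,
        "elevation_m": elev, "slope_deg": slope,
    })
    for resp in RESPONSES:
        codes = np.array([_CATEGORY_TO_CODE[resp][c] for c in traits[resp]],
                         dtype=float)
        if cfg.missing_rate > 0:
            mask = rng_miss.random(n) < cfg.missing_rate
            codes[mask] = np.nan
        rec[_EA_COLUMN[resp]] = codes
    for trait in ("polygyny", "settlement"):
        rec[_EA_COLUMN[trait]] = [
            _CATEGORY_TO_CODE[trait][c] for c in social[trait]]
    rec["ea033"] = social["political_complexity"].astype(int)
    rec = rec[["society_id", "lon", "lat", "language_family",
               "ea079", "ea080", "ea081", "ea082", "ea009", "ea030", "ea033",
               "elevation_m", "slope_deg"]]
    climate_by_id = {ids[i]: clim[i] for i in range(n)}
    scores.index = pd.Index(ids)
    truth["config"] = cfg
    truth["seed"] = seed
    return SyntheticWorld(records=rec, climate=climate_by_id, scores=scores,
                          truth=truth, config=cfg)


def fixture_world(seed: int = 20240301) -> SyntheticWorld:
    """The small 120-society world used by the test suite and CLI fixture."""
    cfg = WorldConfig(n_societies=120, n_families=12, n_years=10,
                      missing_rate=0.03)
    return generate_world(cfg, seed=seed)


def recovery_report(world: SyntheticWorld, fits: dict,
                    averaged: Optional[dict] = None) -> pd.DataFrame:
    """Compare fitted models against the world's generative truth.

    ``fits`` maps response -> FittedModel (the full-model fit on that
    world); ``averaged`` optionally maps response -> AveragedModel to pull
    relative importances.  One row per response and coefficient with truth,
    estimate, bias, plus per-response sign agreement and the random-effect
    SD estimate against family_sigma.
    """
    rows = []
    for resp, fit in fits.items():
        t = world.truth.get(resp)
        if t is None:
            raise ValueError(f"world has no truth for response {resp!r}")
        if tuple(fit.categories) != tuple(t["categories"]):
            raise ValueError(f"category order mismatch for {resp!r}")
        names = list(fit.term_names)
        signs = []
        for term, tv in t["coef"].items():
            if term not in names:
                continue
            j = names.index(term)
            for c_ix, cat in enumerate(fit.categories[1:]):
                est = float(fit.coef[c_ix, j])
                tru = float(tv[c_ix])
                rows.append({"response": resp, "term": term, "category": cat,
                             "truth": tru, "estimate": est,
                             "bias": est - tru,
                             "abs_error": abs(est - tru)})
                if tru != 0:
                    signs.append(np.sign(est) == np.sign(tru))
        sig_hat = float(np.sqrt(np.mean(fit.re_var))) \
            if fit.has_random_effect else np.nan
        rows.append({"response": resp, "term": "_family_sigma",
                     "category": "(all)", "truth": t["family_sigma"],
                     "estimate": sig_hat,
                     "bias": sig_hat - t["family_sigma"]
                     if np.isfinite(sig_hat) else np.nan,
                     "abs_error": abs(sig_hat - t["family_sigma"])
                     if np.isfinite(sig_hat) else np.nan})
        rows.append({"response": resp, "term": "_sign_agreement",
                     "category": "(all)", "truth": 1.0,
                     "estimate": float(np.mean(signs)) if signs else np.nan,
                     "bias": np.nan, "abs_error": np.nan})
        if averaged and resp in averaged:
            for term, imp in averaged[resp].importance.items():
                rows.append({"response": resp, "term": f"importance:{term}",
                             "category": "(all)", "truth": np.nan,
                             "estimate": imp, "bias": np.nan,
                             "abs_error": np.nan})
    return pd.DataFrame(rows)
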