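"""Reading, writing and recoding of D-PLACE-style society tables.

A society table has one row per society with its location, language family,
raw Ethnographic Atlas integer codes for house features (EA079 ground plan,
EA080 floor level, EA081 wall material, EA082 roof shape) and social traits
(EA009 polygyny, EA030 settlement pattern, EA033 political complexity),
plus terrain (elevation, slope).  Monthly climate series travel in a
long-format companion table (society_id, year, month, temp_c, precip_mm).

Raw EA codes are recoded into the analysis categories with total maps:
every integer maps to a category, to ``missing`` or — for wall materials
outside the four analysed classes, such as ice and snow — to ``excluded``.
``excluded`` never enters a model; it marks a society whose wall row is
dropped rather than the society itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "missing"
EXCLUDED = "excluded"

#: canonical column names of a society table
MANDATORY_COLUMNS = ("society_id", "lon", "lat")
EA_COLUMNS = ("ea079", "ea080", "ea081", "ea082", "ea009", "ea030", "ea033")
OPTIONAL_COLUMNS = ("language_family", "elevation_m", "slope_deg") + EA_COLUMNS

#: categories of each recoded variable, reference/declared order first
HOUSE_LEVELS = {
    "ground_plan": ("rounded", "angular"),
    "floor_level": ("ground", "subterranean", "elevated"),
    "wall_material": ("thick", "wood_bamboo", "fabric_skins", "thatch"),
    "roof_shape": ("sloped", "rounded_domed", "flat"),
}
SOCIAL_LEVELS = {
    "polygyny": ("none", "occasional", "frequent"),
    "settlement": ("sedentary", "nomadic"),
}

# raw-code -> category maps (total: unmapped ints fall through to a default)
_GROUND_PLAN = {1: "rounded", 2: "rounded", 3: "rounded",
                4: "angular", 5: "angular", 6: "angular"}
_FLOOR_LEVEL = {1: "subterranean", 2: "ground", 3: "elevated", 4: "elevated"}
_WALL = {1: "thick", 2: "thick", 9: "thick",
         5: "wood_bamboo", 6: "wood_bamboo", 7: "wood_bamboo",
         10: "fabric_skins", 8: "thatch"}
_ROOF = {1: "rounded_domed", 2: "rounded_domed", 3: "rounded_domed",
         4: "rounded_domed", 5: "rounded_domed",
         6: "sloped", 8: "sloped", 9: "sloped", 7: "flat"}
_POLYGYNY = {1: "none", 7: "none", 2: "occasional",
             3: "frequent", 4: "frequent", 5: "frequent", 6: "frequent"}
_SETTLEMENT = {1: "nomadic", 2: "nomadic",
               3: "sedentary", 4: "sedentary", 5: "sedentary",
               6: "sedentary", 7: "sedentary", 8: "sedentary"}


@dataclass
class SocietyRecord:
    """One society: location, ancestry label, raw codes, terrain, climate."""

    society_id: str
    lon: float
    lat: float
    language_family: Optional[str] = None
    ea079: Optional[int] = None
    ea080: Optional[int] = None
    ea081: Optional[int] = None
    ea082: Optional[int] = None
    ea009: Optional[int] = None
    ea030: Optional[int] = None
    ea033: Optional[int] = None
    elevation_m: Optional[float] = None
    slope_deg: Optional[float] = None
    #: years x 12 arrays, or None
    temp_monthly: Optional[np.ndarray] = field(default=None, repr=False)
    precip_monthly: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"lon out of bounds: {self.lon}")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat out of bounds: {self.lat}")
        for name in ("temp_monthly", "precip_monthly"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=float)
                if m.ndim != 2 or m.shape[1] != 12:
                    raise ValueError(f"{name} must be a years x 12 matrix")
                setattr(self, name, m)


@dataclass
class RecodedTraits:
    """Analysis categories of one society (missing where unknown)."""

    ground_plan: str = MISSING
    floor_level: str = MISSING
    wall_material: str = MISSING
    roof_shape: str = MISSING
    polygyny: str = MISSING
    settlement: str = MISSING
    political_complexity: Optional[int] = None


def _clean_code(value) -> Optional[int]:
    """Coerce a raw cell to a positive int code, else None."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    try:
        code = int(value)
    except (TypeError, ValueError):
        return None
    return code if code > 0 else None


def _map_code(code: Optional[int], table: Mapping[int, str],
              default: str = MISSING) -> str:
    if code is None:
        return MISSING
    return table.get(code, default)


def recode_house_traits(r: SocietyRecord) -> RecodedTraits:
    """Recode the four raw house codes into analysis categories.

    Total function: any code outside the documented sets yields ``missing``,
    except wall materials where undocumented codes (ice/snow and other rare
    materials) yield ``excluded``.
    """
    return RecodedTraits(
        ground_plan=_map_code(_clean_code(r.ea079), _GROUND_PLAN),
        floor_level=_map_code(_clean_code(r.ea080), _FLOOR_LEVEL),
        wall_material=_map_code(_clean_code(r.ea081), _WALL, default=EXCLUDED),
        roof_shape=_map_code(_clean_code(r.ea082), _ROOF),
    )


def recode_social_traits(r: SocietyRecord) -> RecodedTraits:
    """Recode polygyny, settlement pattern and political complexity.

    Political complexity is the count of jurisdictional levels beyond the
    local community (1 = acephalous ... 5 = large state), kept ordinal.
    """
    pc = _clean_code(r.ea033)
    return RecodedTraits(
        polygyny=_map_code(_clean_code(r.ea009), _POLYGYNY),
        settlement=_map_code(_clean_code(r.ea030), _SETTLEMENT),
        political_complexity=pc if pc is not None and 1 <= pc <= 5 else None,
    )


def _record_from_row(row: pd.Series) -> SocietyRecord:
    def _opt_float(name):
        v = row.get(name)
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    lf = row.get("language_family")
    if isinstance(lf, float) and math.isnan(lf):
        lf = None
    return SocietyRecord(
        society_id=str(row["society_id"]),
        lon=float(row["lon"]),
        lat=float(row["lat"]),
        language_family=None if lf is None else str(lf),
        elevation_m=_opt_float("elevation_m"),
        slope_deg=_opt_float("slope_deg"),
        **{c: _clean_code(row.get(c)) for c in EA_COLUMNS},
    )


def read_society_table(path, column_map: Optional[Mapping[str, str]] = None,
                       climate_path=None) -> pd.DataFrame:
    """Read a society CSV into a canonical-column DataFrame.

    Parameters
    ----------
    path : str or Path
        CSV with header, UTF-8, "." decimal separator.
    column_map : mapping, optional
        ``{file_column: canonical_column}`` renames applied after reading,
        so differently-labelled exports can be ingested without code edits.
    climate_path : str or Path, optional
        Long-format companion CSV (society_id, year, month, temp_c,
        precip_mm); parsed into the DataFrame attribute ``attrs['climate']``
        as ``{society_id: (temp years x 12, precip years x 12)}``.

    Unparseable numeric cells become missing with a logged warning; the row
    count of the file is preserved.  Missing mandatory columns raise a
    ``ValueError`` naming the column.
    """
    df = pd.read_csv(path, dtype={0: str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"society table lacks mandatory column {col!r}")
    df["society_id"] = df["society_id"].astype(str)
    numeric = ["lon", "lat", "elevation_m", "slope_deg", *EA_COLUMNS]
    for col in numeric:
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                logger.warning("column %s: %d unparseable cells set to missing",
                               col, int(bad.sum()))
            df[col] = coerced
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    # validate coordinate bounds via the record constructor
    records = [_record_from_row(row) for _, row in df.iterrows()]
    out = df[[*MANDATORY_COLUMNS, *OPTIONAL_COLUMNS]].copy()
    out.attrs["records"] = records
    if climate_path is not None:
        out.attrs["climate"] = read_climate_table(climate_path)
    return out


def read_climate_table(path) -> dict:
    """Read long-format monthly climate into {society_id: (temp, precip)}."""
    cl = pd.read_csv(path, dtype={"society_id": str})
    needed = {"society_id", "year", "month", "temp_c", "precip_mm"}
    miss = needed - set(cl.columns)
    if miss:
        raise ValueError(f"climate table lacks columns {sorted(miss)}")
    out = {}
    for sid, grp in cl.groupby("society_id", sort=False):
        piv_t = grp.pivot_table(index="year", columns="month",
                                values="temp_c", sort=True)
        piv_p = grp.pivot_table(index="year", columns="month",
                                values="precip_mm", sort=True)
        if piv_t.shape[1] != 12:
            raise ValueError(f"society {sid}: climate lacks 12 months")
        out[str(sid)] = (piv_t.to_numpy(float), piv_p.to_numpy(float))
    return out


def write_society_table(df: pd.DataFrame, path, climate=None,
                        climate_path=None) -> None:
    """Write a canonical society table (and optionally its climate) to CSV.

    Integer EA codes are written without decimal points so that a
    write/read round trip reproduces non-missing fields exactly.
    """
    out = df.copy()
    for col in EA_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False, float_format="%.10g")
    if climate is not None and climate_path is not None:
        rows = []
        for sid in out["society_id"]:
            if sid not in climate:
                continue
            temp, precip = climate[sid]
            ny = temp.shape[0]
            for y in range(ny):
                for m in range(12):
                    rows.append((sid, y + 1, m + 1, temp[y, m], precip[y, m]))
        pd.DataFrame(rows, columns=["society_id", "year", "month",
                                    "temp_c", "precip_mm"]).to_csv(
            climate_path, index=False, float_format="%.10g")


def recode_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append recoded trait columns to a canonical society table."""
    recs = df.attrs.get("records")
    if recs is None:
        recs = [_record_from_row(row) for _, row in df.iterrows()]
    house = [recode_house_traits(r) for r in recs]
    social = [recode_social_traits(r) for r in recs]
    out = df.copy()
    for name in ("ground_plan", "floor_level", "wall_material", "roof_shape"):
        out[name] = [getattr(h, name) for h in house]
    out["polygyny"] = [s.polygyny for s in social]
    out["settlement"] = [s.settlement for s in social]
    out["political_complexity"] = [
        np.nan if s.political_complexity is None else float(s.political_complexity)
        for s in social
    ]
    out.attrs = dict(df.attrs)
    return out
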