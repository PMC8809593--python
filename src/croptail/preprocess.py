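"""Panel ingestion, complete-case filtering, per-country standardization and pooling.

The analysis operates on annual country-level panels of crop yield (hg/ha)
together with growing-season weather aggregates (total precipitation in mm,
mean daily minimum and maximum temperature in degrees C). Countries are pooled
into larger geographical regions; to make series comparable across countries
each variable is standardized within country (subtract the country mean,
divide by the country standard deviation) before pooling. Yield losses and
droughts live in lower tails, so the corresponding variables are reflected
(negated) to bring them into the upper-tail machinery used downstream.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CROPS = ("wheat", "rice", "maize", "soybeans", "barley", "sorghum")
VALUE_COLUMNS = ("yield", "prec", "tmin", "tmax")
WEATHER_VARIABLES = ("prec", "tmin", "tmax")

PANEL_COLUMNS = ("country", "year", "crop") + VALUE_COLUMNS


class ZeroVarianceError(ValueError):
    """A country/variable group has zero standard deviation; standardization is undefined."""


@dataclass
class RegionPanel:
    """Pooled, per-country standardized complete-case panel for one region and crop.

    ``data`` holds one row per retained (country, year) pair with standardized
    columns ``yield``, ``prec``, ``tmin``, ``tmax``; ``dropped`` counts
    incomplete rows removed per country; ``transform`` stores the per-country
    (mean, sd) used, keyed by (country, variable), for back-transformation.
    """

    region: str
    crop: str
    data: pd.DataFrame
    dropped: dict[str, int] = field(default_factory=dict)
    transform: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def countries(self) -> list[str]:
        return sorted(self.data["country"].unique())


@dataclass
class VariablePair:
    """Row-aligned (response, conditioning) variable pair.

    The response is always reflected yield, so large values mean large losses.
    The conditioning variable may itself be reflected (`low_tail`) to target
    its lower tail, e.g. droughts via reflected precipitation.
    """

    response: np.ndarray
    conditioning: np.ndarray
    response_name: str = "yield_refl"
    conditioning_name: str = "prec"
    low_tail: bool = False

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.conditioning = np.asarray(self.conditioning, dtype=float)
        if self.response.shape != self.conditioning.shape:
            raise ValueError("response and conditioning must be row-aligned")

    def __len__(self) -> int:
        return len(self.response)

    @property
    def orientation(self) -> str:
        return "low" if self.low_tail else "high"


def read_panel(path) -> pd.DataFrame:
    """Read a raw panel CSV with header country,year,crop,yield,prec,tmin,tmax.

    Empty cells are treated as missing values.
    """
    df = pd.read_csv(path, dtype={"country": str, "crop": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    return df[list(PANEL_COLUMNS)]


def read_region_map(path=None) -> pd.DataFrame:
    """Read a country->region map; defaults to the packaged region composition."""
    if path is None:
        ref = importlib.resources.files("croptail.data").joinpath("regions.csv")
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def drop_incomplete(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows where any of yield/prec/tmin/tmax is missing.

    Returns the retained rows and a per-country count of dropped rows.
    Countries left with zero rows raise a warning and are absent from the output.
    """
    complete = records[list(VALUE_COLUMNS)].notna().all(axis=1)
    dropped = (
        records.loc[~complete, "country"].value_counts().to_dict()
        if (~complete).any()
        else {}
    )
    kept = records.loc[complete].copy()
    gone = set(records["country"].unique()) - set(kept["country"].unique())
    for country in sorted(gone):
        warnings.warn(f"country {country!r} has no complete records; excluded")
    return kept, dropped


def standardize_by_group(
    records: pd.DataFrame,
    group_key: str = "country",
    columns: tuple[str, ...] = VALUE_COLUMNS,
) -> tuple[pd.DataFrame, dict[tuple[str, str], tuple[float, float]]]:
    """Standardize each variable within each group to mean 0, sd 1 (ddof=1).

    Returns the standardized frame and the (mean, sd) per (group, variable)
    for back-transformation. Zero within-group sd raises ``ZeroVarianceError``.
    """
    out = records.copy()
    params: dict[tuple[str, str], tuple[float, float]] = {}
    for key, grp in records.groupby(group_key, sort=True):
        for col in columns:
            x = grp[col].to_numpy(dtype=float)
            mu = float(np.mean(x))
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            if sd == 0.0 or not np.isfinite(sd):
                raise ZeroVarianceError(
                    f"zero variance for {col!r} in group {key!r}; standardization undefined"
                )
            out.loc[grp.index, col] = (x - mu) / sd
            params[(str(key), col)] = (mu, sd)
    return out, params


def reflect_variable(series: np.ndarray) -> np.ndarray:
    """Reflect a series (elementwise negation) so its lower tail becomes an upper tail."""
    return -np.asarray(series, dtype=float)


def build_region_panel(
    records: pd.DataFrame,
    region_map: pd.DataFrame,
    region: str,
    crop: str,
    min_years: int = 0,
) -> RegionPanel:
    """Assemble the pooled standardized panel for one region and crop.

    Order of operations: filter to region/crop, drop incomplete (country, year)
    rows, optionally drop countries with fewer than ``min_years`` complete
    years, then standardize per country and pool.
    """
    members = set(region_map.loc[region_map["region"] == region, "country"])
    if not members:
        raise ValueError(f"region {region!r} not present in the region map")
    sub = records[(records["crop"] == crop) & (records["country"].isin(members))]
    if sub.empty:
        raise ValueError(f"no records for region {region!r}, crop {crop!r}")
    kept, dropped = drop_incomplete(sub)
    if min_years > 0:
        counts = kept["country"].value_counts()
        short = counts[counts < min_years].index
        kept = kept[~kept["country"].isin(short)]
    if kept.empty:
        raise ValueError(f"no complete records for region {region!r}, crop {crop!r}")
    std, params = standardize_by_group(kept)
    std = std.sort_values(["country", "year"]).reset_index(drop=True)
    return RegionPanel(region=region, crop=crop, data=std, dropped=dropped, transform=params)


def assemble_pair(
    panel: RegionPanel,
    weather_variable: str,
    low_tail: bool = False,
) -> VariablePair:
    """Build the (reflected yield, weather) pair for one panel.

    The response is always reflected yield. The conditioning variable is
    reflected iff ``low_tail`` — meaningful for precipitation (droughts), but
    allowed for the temperatures as well.
    """
    if weather_variable not in WEATHER_VARIABLES:
        raise ValueError(
            f"unknown weather variable {weather_variable!r}; expected one of {WEATHER_VARIABLES}"
        )
    response = reflect_variable(panel.data["yield"].to_numpy())
    conditioning = panel.data[weather_variable].to_numpy(dtype=float)
    if low_tail:
        conditioning = reflect_variable(conditioning)
    return VariablePair(
        response=response,
        conditioning=conditioning,
        response_name="yield_refl",
        conditioning_name=weather_variable + ("_refl" if low_tail else ""),
        low_tail=low_tail,
    )
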