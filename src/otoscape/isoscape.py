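"""Otolith-oxygen isoscape construction from gridded temperature/salinity.

Predicted otolith δ¹⁸O over a regular lat/lon grid is obtained in three
linear steps. Seawater δ¹⁸O (‰ VSMOW) is estimated from salinity via
water-mass-specific mixing lines

    δ¹⁸O_sw = slope · S + intercept

(North Atlantic: 0.55 S − 18.98; Gulf of St. Lawrence: 0.27 S − 10.3,
reflecting the distinct St. Lawrence River freshwater end-member).
Temperature and seawater δ¹⁸O are averaged over the three consecutive
months of the contingent's first growing season (southern: May–July;
northern: June–August), and the species-specific aragonite fractionation
equation converts the seasonal means to otolith δ¹⁸O (‰ VPDB):

    δ¹⁸O_oto = γ·T + β + δ¹⁸O_sw

with chub-mackerel defaults γ = −0.25 ‰/°C, β = 4.46 ‰. The equation mixes
the VSMOW and VPDB scales additively by construction; no further scale
conversion is applied. Because all three steps are linear, averaging before
or after the fractionation equation is equivalent; averaging is done first.

Grids are xarray DataArrays with dims (time, lat, lon), cell-center
coordinates, latitude ascending, longitude in [−180, 180). Masks share the
grid exactly; grid mismatch is an error, never silent interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

# Salinity–δ¹⁸O_seawater mixing-line coefficients (‰ per PSU, ‰ VSMOW)
NORTH_ATLANTIC_LINE = (0.55, -18.98)
GULF_ST_LAWRENCE_LINE = (0.27, -10.3)

# Chub-mackerel (Scomber japonicus) aragonite fractionation coefficients
CHUB_MACKEREL_GAMMA = -0.25  # ‰ per °C
CHUB_MACKEREL_BETA = 4.46    # ‰

#: First month of the three-month first-growing-season window, per contingent.
SEASON_START_MONTH = {"southern": 5, "northern": 6}
SEASON_LENGTH = 3

TEMPERATURE_UNITS = {"degc", "°c", "c", "celsius", "degree_celsius", "degrees_celsius"}
SALINITY_UNITS = {"psu", "1", "", "pss-78", "g/kg", "dimensionless"}


class IsoscapeError(ValueError):
    """Raised on grid/mask inconsistencies or missing data slabs."""


@dataclass
class MixingLine:
    """A linear salinity→seawater-δ¹⁸O relation valid inside a region mask."""

    slope: float
    intercept: float
    region_mask: xr.DataArray  # boolean, dims (lat, lon)
    name: str = ""

    def apply(self, salinity: xr.DataArray) -> xr.DataArray:
        return self.slope * salinity + self.intercept


@dataclass
class FractionationModel:
    """Linear otolith–water fractionation: δ_oto − δ_sw = γ·T + β."""

    gamma: float = CHUB_MACKEREL_GAMMA
    beta: float = CHUB_MACKEREL_BETA
    species: str = "chub mackerel"

    def __post_init__(self):
        if not (np.isfinite(self.gamma) and np.isfinite(self.beta)):
            raise IsoscapeError("fractionation coefficients must be finite")


@dataclass
class Isoscape:
    """Per-year, per-contingent seasonal otolith-δ¹⁸O prediction surface.

    ``values`` holds δ¹⁸O_oto (‰ VPDB) with NaN outside ``domain_mask``
    (contingent region ∩ continental shelf ∩ valid data).
    """

    year: int
    contingent: str
    months: list[int]
    values: xr.DataArray        # dims (lat, lon)
    domain_mask: xr.DataArray   # boolean, dims (lat, lon)
    meta: dict = field(default_factory=dict)

    @property
    def defined_values(self) -> np.ndarray:
        """Flat array of δ¹⁸O at masked-in cells (row-major lat, lon order)."""
        return self.values.values[self.domain_mask.values]

    def n_defined(self) -> int:
        return int(self.domain_mask.values.sum())


def _check_aligned(*fields: xr.DataArray) -> None:
    ref = fields[0]
    for f in fields[1:]:
        if not (np.array_equal(ref["lat"].values, f["lat"].values)
                and np.array_equal(ref["lon"].values, f["lon"].values)):
            raise IsoscapeError("grid mismatch: fields are not on one grid")
        if "time" in ref.dims and "time" in f.dims:
            if ref.sizes["time"] != f.sizes["time"]:
                raise IsoscapeError("grid mismatch: time axes differ")


def seawater_d18o(salinity: xr.DataArray,
                  lines: list[MixingLine]) -> xr.DataArray:
    """Seawater δ¹⁸O (‰ VSMOW) from salinity via region mixing lines.

    The region masks must partition the valid (non-missing) salinity
    domain: a valid cell covered by zero or more than one line is an
    error. Missing salinity stays missing.
    """
    valid = np.isfinite(salinity.isel(time=0).values) if "time" in salinity.dims \
        else np.isfinite(salinity.values)
    cover = np.zeros(valid.shape, dtype=int)
    for line in lines:
        _check_aligned(salinity, line.region_mask)
        cover += line.region_mask.values.astype(int)
    bad = valid & (cover != 1)
    if bad.any():
        ii, jj = np.nonzero(bad)
        cells = list(zip(ii.tolist()[:5], jj.tolist()[:5]))
        raise IsoscapeError(
            f"{bad.sum()} valid cells covered by != 1 mixing line, "
            f"e.g. (lat_idx, lon_idx) = {cells}"
        )
    out = xr.full_like(salinity, np.nan, dtype=float)
    for line in lines:
        est = line.apply(salinity)
        out = xr.where(line.region_mask, est, out,
                       keep_attrs=True).transpose(*salinity.dims)
    out = out.where(np.isfinite(salinity))
    out.attrs = {"variable": "d18o_seawater", "units": "permil VSMOW"}
    out.name = "d18o_seawater"
    return out


def otolith_d18o(temperature: xr.DataArray, d18o_sw: xr.DataArray,
                 frac: FractionationModel) -> xr.DataArray:
    """Otolith δ¹⁸O (‰ VPDB) = γ·T + β + δ¹⁸O_sw on aligned grids."""
    _check_aligned(temperature, d18o_sw)
    out = frac.gamma * temperature + frac.beta + d18o_sw
    out.attrs = {"variable": "d18o_otolith", "units": "permil VPDB"}
    out.name = "d18o_otolith"
    return out


def seasonal_average(fld: xr.DataArray, year: int, start_month: int,
                     n_months: int = SEASON_LENGTH,
                     strict: bool = True) -> xr.DataArray:
    """Mean over ``n_months`` consecutive months of ``year``.

    The time axis must be datetime-like. In strict mode a cell missing in
    any month is missing in the mean; the lenient mode averages whatever
    months are present per cell. A wholly absent month slab is always an
    error.
    """
    t = pd.DatetimeIndex(fld["time"].values)
    months = [start_month + k for k in range(n_months)]
    slabs = []
    for m in months:
        yy, mm = (year + (m - 1) // 12, (m - 1) % 12 + 1)
        sel = (t.year == yy) & (t.month == mm)
        if sel.sum() != 1:
            raise IsoscapeError(f"missing monthly slab {yy}-{mm:02d}")
        slabs.append(fld.isel(time=int(np.nonzero(sel)[0][0])))
    stack = xr.concat(slabs, dim="month")
    out = stack.mean(dim="month", skipna=not strict)
    out.attrs = dict(fld.attrs)
    return out


def build_isoscape(temperature: xr.DataArray, salinity: xr.DataArray,
                   year: int, contingent: str,
                   lines: list[MixingLine],
                   frac: FractionationModel,
                   domain_mask: xr.DataArray,
                   shelf_mask: xr.DataArray,
                   strict: bool = True) -> Isoscape:
    """Build the seasonal otolith-δ¹⁸O isoscape for one year and contingent.

    Seasonal means of T and δ¹⁸O_sw are taken over the contingent's
    three-month first-growing-season window, then the fractionation
    equation is applied once to the means. The final domain is
    contingent region ∩ shelf ∩ valid data; an empty domain is an error.
    """
    if contingent not in SEASON_START_MONTH:
        raise IsoscapeError(f"unknown contingent {contingent!r}")
    _check_aligned(temperature, salinity, domain_mask, shelf_mask)
    start = SEASON_START_MONTH[contingent]
    months = [start + k for k in range(SEASON_LENGTH)]
    d18o_sw = seawater_d18o(salinity, lines)
    t_mean = seasonal_average(temperature, year, start, strict=strict)
    sw_mean = seasonal_average(d18o_sw, year, start, strict=strict)
    oto = otolith_d18o(t_mean, sw_mean, frac)
    mask = (domain_mask.astype(bool) & shelf_mask.astype(bool)
            & xr.DataArray(np.isfinite(oto.values), coords=oto.coords))
    if not bool(mask.values.any()):
        raise IsoscapeError(
            f"empty isoscape domain for {contingent} contingent, year {year}"
        )
    values = oto.where(mask)
    return Isoscape(year=year, contingent=contingent, months=months,
                    values=values, domain_mask=mask,
                    meta={"gamma": frac.gamma, "beta": frac.beta})


# ---------------------------------------------------------------------------
# netCDF-convention I/O (scipy backend, NETCDF3 classic)


def read_ts_fields(path) -> tuple[xr.DataArray, xr.DataArray]:
    """Read monthly temperature/salinity fields with unit checks.

    Expects variables ``temperature`` (°C) and ``salinity`` (PSU) with
    dims (time, lat, lon).
    """
    ds = xr.open_dataset(path, engine="scipy")
    for var in ("temperature", "salinity"):
        if var not in ds:
            raise IsoscapeError(f"variable {var!r} not found in {path}")
    temp, sal = ds["temperature"], ds["salinity"]
    tu = str(temp.attrs.get("units", "degC")).lower()
    su = str(sal.attrs.get("units", "psu")).lower()
    if tu not in TEMPERATURE_UNITS:
        raise IsoscapeError(f"unexpected temperature units {tu!r}")
    if su not in SALINITY_UNITS:
        raise IsoscapeError(f"unexpected salinity units {su!r}")
    for fld in (temp, sal):
        for dim in ("time", "lat", "lon"):
            if dim not in fld.dims:
                raise IsoscapeError(f"field missing dimension {dim!r}")
    lat, lon = ds["lat"].values, ds["lon"].values
    if not (np.all(np.diff(lat) > 0) and np.all(np.diff(lon) > 0)):
        raise IsoscapeError("lat/lon must be ascending")
    return temp.load(), sal.load()


def write_isoscape(iso: Isoscape, path) -> None:
    ds = xr.Dataset(
        {
            "d18o_otolith": iso.values,
            "domain_mask": iso.domain_mask.astype("int8"),
        },
        attrs={
            "year": iso.year,
            "contingent": iso.contingent,
            "months": ",".join(map(str, iso.months)),
            "gamma": iso.meta.get("gamma", np.nan),
            "beta": iso.meta.get("beta", np.nan),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_isoscape(path) -> Isoscape:
    ds = xr.open_dataset(path, engine="scipy").load()
    mask = ds["domain_mask"].astype(bool)
    return Isoscape(
        year=int(ds.attrs["year"]),
        contingent=str(ds.attrs["contingent"]),
        months=[int(m) for m in str(ds.attrs["months"]).split(",")],
        values=ds["d18o_otolith"],
        domain_mask=mask,
        meta={"gamma": float(ds.attrs.get("gamma", np.nan)),
              "beta": float(ds.attrs.get("beta", np.nan))},
    )
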