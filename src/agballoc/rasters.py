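"""Gridded cube container conventions and helpers.

A *cube* is an :class:`xarray.DataArray` with dimensions ``(year, row, col)``
where ``year`` is an explicit integer coordinate (never an implicit index),
rows and columns are 0-based, and NaN marks nodata.  A *grid* is the 2-D
``(row, col)`` analogue.  All higher modules accept and return these.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import xarray as xr

from .exceptions import AlignmentError

CUBE_DIMS = ("year", "row", "col")
GRID_DIMS = ("row", "col")


def make_cube(
    data: np.ndarray,
    years: Sequence[int],
    name: str | None = None,
    units: str | None = None,
) -> xr.DataArray:
    """Wrap a ``(n_years, rows, cols)`` array as a year/row/col cube."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise AlignmentError(f"cube data must be 3-D, got shape {data.shape}")
    if data.shape[0] != len(years):
        raise AlignmentError(
            f"{data.shape[0]} layers but {len(years)} years supplied"
        )
    da = xr.DataArray(
        data,
        dims=CUBE_DIMS,
        coords={"year": np.asarray(list(years), dtype=int)},
        name=name,
    )
    if units is not None:
        da.attrs["units"] = units
    return da


def make_grid(data: np.ndarray, name: str | None = None) -> xr.DataArray:
    data = np.asarray(data)
    if data.ndim != 2:
        raise AlignmentError(f"grid data must be 2-D, got shape {data.shape}")
    return xr.DataArray(data, dims=GRID_DIMS, name=name)


def check_aligned(*arrays: xr.DataArray) -> None:
    """Raise :class:`AlignmentError` unless all cubes/grids share spatial
    shape and (where present) identical year coordinates."""
    if not arrays:
        return
    ref = arrays[0]
    ref_space = ref.sizes["row"], ref.sizes["col"]
    ref_years = ref.coords["year"].values if "year" in ref.dims else None
    for a in arrays[1:]:
        if (a.sizes["row"], a.sizes["col"]) != ref_space:
            raise AlignmentError(
                f"spatial shapes differ: {ref_space} vs "
                f"{(a.sizes['row'], a.sizes['col'])}"
            )
        if "year" in a.dims and ref_years is not None:
            if len(a.coords["year"]) != len(ref_years) or np.any(
                a.coords["year"].values != ref_years
            ):
                raise AlignmentError("year coordinates differ between cubes")


def years_of(cube: xr.DataArray) -> np.ndarray:
    return np.asarray(cube.coords["year"].values, dtype=int)


def valid_mask(*arrays: xr.DataArray) -> np.ndarray:
    """2-D mask of pixels finite in every input (cubes: finite in all years)."""
    check_aligned(*arrays)
    masks = []
    for a in arrays:
        v = np.isfinite(np.asarray(a.values, dtype=float))
        masks.append(v.all(axis=0) if a.ndim == 3 else v)
    return np.logical_and.reduce(masks)


def stack_cubes(cubes: Iterable[xr.DataArray]) -> xr.Dataset:
    ds = xr.Dataset()
    for c in cubes:
        if c.name is None:
            raise ValueError("cube must be named to be stored in a Dataset")
        ds[c.name] = c
    return ds
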