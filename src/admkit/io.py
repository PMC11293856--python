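"""Readers and writers for the package's plain-text and NetCDF formats.

Tables travel as tab-separated text (first column the sample id), grids as
either flat TSV (lat, lon, one column per predictor) or NetCDF (dimensions
``lat``/``lon``, one variable per predictor; read and written through
xarray's scipy backend). Numeric output uses 15 significant digits so
write/read round-trips are value-stable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .adm import EnvTable
from .association import AlphaMatrix, AssociationSet
from .compositional import AbundanceTable
from .projection import GridField, normalize_longitude

__all__ = [
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_env_tsv",
    "write_env_tsv",
    "read_grid",
    "write_grid",
    "write_associations_tsv",
    "read_associations_tsv",
    "write_alpha_tsv",
]

_FLOAT_FMT = "%.15g"


def read_abundance_tsv(path, meta_path=None) -> AbundanceTable:
    """Parse an abundance table (and optional metadata TSV keyed by sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate taxon id {dup!r}")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative abundance at line {i + 2} "
            f"(sample {df.index[i]!r}, taxon {df.columns[j]!r})"
        )
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return AbundanceTable(
        values=values,
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
        sample_meta=meta,
    )


def write_abundance_tsv(table: AbundanceTable, path, meta_path=None) -> None:
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    if meta_path is not None and table.sample_meta is not None:
        table.sample_meta.to_csv(meta_path, sep="\t", float_format=_FLOAT_FMT)


def read_env_tsv(path) -> EnvTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return EnvTable(
        sample_ids=[str(s) for s in df.index],
        features=df.to_numpy(dtype=float),
        feature_names=[str(c) for c in df.columns],
    )


def write_env_tsv(env: EnvTable, path) -> None:
    df = env.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_grid(path, format: str | None = None, feature_names=None, time_label="present") -> GridField:
    """Read a grid from TSV or NetCDF (``format`` inferred from the suffix)."""
    path = Path(path)
    if format is None:
        format = "netcdf" if path.suffix in {".nc", ".nc4", ".cdf"} else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        cols = [c for c in df.columns if c not in {"lat", "lon", "valid"}]
        if feature_names is not None:
            missing = [f for f in feature_names if f not in cols]
            if missing:
                raise ValueError(
                    f"{path}: missing predictor variable(s) {missing}; available: {cols}"
                )
            cols = list(feature_names)
        mask = df["valid"].to_numpy(dtype=bool) if "valid" in df.columns else None
        return GridField(
            lat=df["lat"].to_numpy(dtype=float),
            lon=normalize_longitude(df["lon"].to_numpy(dtype=float)),
            features=df[cols].to_numpy(dtype=float),
            feature_names=cols,
            time_label=time_label,
            valid_mask=mask,
        )
    if format == "netcdf":
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        names = list(feature_names) if feature_names else [
            v for v in ds.data_vars if v != "valid"
        ]
        missing = [f for f in names if f not in ds.data_vars]
        if missing:
            raise ValueError(
                f"{path}: missing predictor variable(s) {missing}; "
                f"available: {list(ds.data_vars)}"
            )
        glat, glon = np.meshgrid(ds["lat"].values, ds["lon"].values, indexing="ij")
        features = np.column_stack([ds[v].values.ravel() for v in names])
        mask = ds["valid"].values.ravel().astype(bool) if "valid" in ds.data_vars else None
        label = str(ds.attrs.get("time_label", time_label))
        ds.close()
        return GridField(
            lat=glat.ravel(), lon=normalize_longitude(glon.ravel()),
            features=features, feature_names=names, time_label=label,
            valid_mask=mask,
        )
    raise ValueError(f"unknown grid format {format!r}")


def write_grid(grid: GridField, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "netcdf" if path.suffix in {".nc", ".nc4", ".cdf"} else "tsv"
    if format == "tsv":
        grid.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        return
    if format == "netcdf":
        import xarray as xr

        lats = np.unique(grid.lat)
        lons = np.unique(grid.lon)
        if lats.size * lons.size != grid.n_cells:
            raise ValueError("grid is not a full lat x lon product; write TSV instead")
        order = np.lexsort((grid.lon, grid.lat))
        shape = (lats.size, lons.size)
        data = {
            name: (("lat", "lon"), grid.features[order, i].reshape(shape))
            for i, name in enumerate(grid.feature_names)
        }
        data["valid"] = (("lat", "lon"), grid.valid_mask[order].reshape(shape).astype(np.int8))
        ds = xr.Dataset(data, coords={"lat": lats, "lon": lons})
        ds.attrs["time_label"] = grid.time_label
        ds.to_netcdf(path, engine="scipy")
        return
    raise ValueError(f"unknown grid format {format!r}")


def write_associations_tsv(assoc: AssociationSet, path) -> None:
    assoc.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_associations_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_alpha_tsv(alpha: AlphaMatrix, path) -> None:
    alpha.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_projection_tsv(result, grid: GridField, path) -> None:
    """Write a per-cell projection map as (lat, lon, value) TSV.

    The value column is the predicted state (cADM) or alpha* (rADM) on the
    valid cells of the grid the projection was made on.
    """
    idx = np.asarray(result.cell_indices, dtype=int)
    values = result.states if result.states is not None else result.alpha_star
    df = pd.DataFrame(
        {"lat": grid.lat[idx], "lon": grid.lon[idx], "value": values}
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
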