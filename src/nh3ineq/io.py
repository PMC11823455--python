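"""Reading and writing the pipeline's file formats.

Everything is plain text: pixel tables, demographics, facilities and
meteorology as CSV; block-group polygons as GeoJSON (see
:meth:`nh3ineq.inequality.BlockGroups.to_geojson`); backgrounds and scene
truth as JSON. Gridded products round-trip through the long-format CSV of
:meth:`OversampledGrid.to_dataframe` (``to_xarray`` is available for NetCDF
export through whatever backend the user has installed).
"""

from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd

from .enhancement import BackgroundSpec
from .oversampling import PIXEL_COLUMNS


def write_pixels_csv(pixels: pd.DataFrame, path) -> None:
    pixels[PIXEL_COLUMNS].to_csv(path, index=False)


def read_pixels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["time"])
    df["sensitivity_ok"] = df["sensitivity_ok"].astype(bool)
    return df[PIXEL_COLUMNS]


def write_met_csv(met: pd.DataFrame, path) -> None:
    met.to_csv(path, index=False)


def read_met_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def write_background_json(background: BackgroundSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(background), fh, indent=2)


def read_background_json(path) -> BackgroundSpec:
    with open(path) as fh:
        return BackgroundSpec(**json.load(fh))


def write_scene_truth_json(scene, path) -> None:
    """Persist the scene's oracle values and generating parameters."""
    from dataclasses import asdict as dc_asdict

    payload = {
        "designed_inequality": scene.designed_inequality,
        "config": dc_asdict(scene.config),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
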