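"""Small-region geodesy helpers.

The study domains are ~1 degree across, so local distances use either the
haversine great-circle formula (point-to-point) or equirectangular scaling
at a reference latitude (footprint-scale offsets, sub-metre error at these
scales). All coordinates are WGS84 decimal degrees.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: kilometres per degree of latitude (spherical earth)
KM_PER_DEG_LAT = np.pi * EARTH_RADIUS_KM / 180.0


def km_per_deg_lon(lat_deg):
    """Kilometres per degree of longitude at the given latitude."""
    return KM_PER_DEG_LAT * np.cos(np.deg2rad(lat_deg))


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = map(np.deg2rad, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def local_offsets_km(lat, lon, ref_lat, ref_lon):
    """East/north offsets in km from a reference point, equirectangular."""
    dx = (np.asarray(lon) - ref_lon) * km_per_deg_lon(ref_lat)
    dy = (np.asarray(lat) - ref_lat) * KM_PER_DEG_LAT
    return dx, dy
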