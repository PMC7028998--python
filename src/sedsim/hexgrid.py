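"""Equal-area icosahedral hexagon grid of the virtual world.

The simulator runs on a discrete global grid of (nearly) equal-area cells:
hexagons plus the 12 pentagons that any icosahedral tessellation carries.
Cells are the vertices of a Class-I geodesic subdivision of the icosahedron
(frequency ``f`` gives ``10 f**2 + 2`` cells); vertex positions are placed
with an equal-area polyhedral projection (Snyder-style) applied per
icosahedron face, so that the dual cells come out equal in area to within a
few tenths of a percent (pentagons are ~5/6 of a hexagon, as in any
icosahedral DGGS).

The default resolution targets a mean cell area of ~23,320 km**2, i.e. the
resolution at which a 131-cell range covers ~3.05 million km**2 and a
180-cell range ~4.20 million km**2.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0
EARTH_AREA_KM2 = 4.0 * math.pi * EARTH_RADIUS_KM**2

#: Default target mean cell area (km^2) back-computed from the printed
#: 131-cell (~3.05e6 km^2) and 180-cell (~4.20e6 km^2) range areas.
DEFAULT_CELL_AREA_KM2 = 23_320.0

#: Longitude (degrees) splitting the Western from the Eastern Hemisphere.
HEMISPHERE_SPLIT_LON = -30.0

_MIN_TARGET_AREA = 10_000.0
_MAX_TARGET_AREA = 100_000.0


class GridConfigurationError(ValueError):
    """Requested grid resolution cannot be built."""


# ---------------------------------------------------------------------------
# Icosahedron and the equal-area face projection
# ---------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Unit-sphere icosahedron vertices (12, 3) and CCW faces (20, 3)."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=int,
    )
    # enforce outward CCW orientation
    for k, (a, b, c) in enumerate(faces):
        n = np.cross(verts[b] - verts[a], verts[c] - verts[a])
        if np.dot(n, verts[a] + verts[b] + verts[c]) < 0:
            faces[k] = (a, c, b)
    return verts, faces


# Spherical distance from a face centre to its vertices (g), the spherical
# half-angle of the face at a vertex (G = 36 deg), and the plane geometry of
# the unfolded face.  R' scales the planar faces so their total area equals
# the sphere's.
def _face_geometry() -> tuple[float, float, float]:
    verts, faces = _icosahedron()
    a, b, c = faces[0]
    centre = verts[a] + verts[b] + verts[c]
    centre /= np.linalg.norm(centre)
    g = math.acos(float(np.clip(np.dot(centre, verts[a]), -1.0, 1.0)))
    big_g = math.pi / 5.0  # 36 deg: half the 72 deg spherical face angle at a vertex
    rprime = math.sqrt(4.0 * math.pi / (15.0 * math.sqrt(3.0) * math.tan(g) ** 2))
    return g, big_g, rprime


_g, _G, _RPRIME = _face_geometry()
_TANG = math.tan(_g)
_COT_THETA = 1.0 / math.tan(math.pi / 6.0)  # vertex-to-edge-midpoint plane angle is 30 deg
_SECTOR = 2.0 * math.pi / 3.0


def _inverse_snyder(azp: np.ndarray, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map planar polar coordinates within one 60-deg sub-sector to the sphere.

    ``azp`` is the planar azimuth from the centre-to-vertex direction, in
    [0, 60 deg]; ``rho`` the planar radius.  Returns the spherical azimuth
    ``az`` (same reference) and spherical distance ``z`` from the face centre
    such that the map preserves area.
    """
    k_const = _RPRIME**2 * _TANG**2
    sin_azp, cos_azp = np.sin(azp), np.cos(azp)
    area_g = k_const * sin_azp / (2.0 * cos_azp + 2.0 * _COT_THETA * sin_azp)
    # Newton solve: az + G + H(az) - pi = area_g
    az = azp.copy()
    sin_g_cos_g = math.sin(_G) * math.cos(_g)
    cos_big_g = math.cos(_G)
    for _ in range(30):
        u = np.sin(az) * sin_g_cos_g - np.cos(az) * cos_big_g
        u = np.clip(u, -1.0, 1.0)
        h = np.arccos(u)
        f_val = az + _G + h - math.pi - area_g
        du = np.cos(az) * sin_g_cos_g + np.sin(az) * cos_big_g
        dh = -du / np.sqrt(np.maximum(1.0 - u * u, 1e-15))
        step = f_val / (1.0 + dh)
        az = az - step
        if np.max(np.abs(step)) < 1e-14:
            break
    az = np.clip(az, 0.0, _SECTOR / 2.0)
    # spherical distance from centre to the face edge along azimuth az
    q = np.arctan2(_TANG, np.cos(az) + _COT_THETA * np.sin(az))
    # planar distance from centre to the face edge along azimuth azp
    dprime = _RPRIME * _TANG / (cos_azp + _COT_THETA * sin_azp)
    f_scale = dprime / (2.0 * _RPRIME * np.sin(q / 2.0))
    z = 2.0 * np.arcsin(np.clip(rho / (2.0 * _RPRIME * f_scale), -1.0, 1.0))
    return az, z


def _face_frame(verts: np.ndarray, face: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Face centre and an orthonormal tangent frame with e1 toward vertex 0."""
    v0, v1, _ = (verts[i] for i in face)
    centre = verts[face].sum(axis=0)
    centre /= np.linalg.norm(centre)
    e1 = v0 - np.dot(v0, centre) * centre
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(centre, e1)
    if np.dot(v1, e2) < 0:  # azimuth must increase from vertex 0 toward vertex 1
        e2 = -e2
    return centre, e1, e2


def _map_face_points(xy: np.ndarray, centre: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    """Inverse-project planar face coordinates (n, 2) to unit vectors (n, 3)."""
    rho = np.hypot(xy[:, 0], xy[:, 1])
    psi = np.mod(np.arctan2(xy[:, 1], xy[:, 0]), 2.0 * math.pi)
    sector = np.floor(psi / _SECTOR)
    az_local = psi - sector * _SECTOR
    reflect = az_local > _SECTOR / 2.0
    azp = np.where(reflect, _SECTOR - az_local, az_local)
    az_s, z = _inverse_snyder(azp, rho)
    az_final = np.where(reflect, _SECTOR - az_s, az_s) + sector * _SECTOR
    tangent = np.cos(az_final)[:, None] * e1 + np.sin(az_final)[:, None] * e2
    pts = np.cos(z)[:, None] * centre + np.sin(z)[:, None] * tangent
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Geodesic subdivision
# ---------------------------------------------------------------------------

def _triangle_solid_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Unsigned solid angle of spherical triangles (vectorised, unit vectors)."""
    num = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)))
    den = 1.0 + np.einsum("ij,ij->i", a, b) + np.einsum("ij,ij->i", b, c) + np.einsum("ij,ij->i", c, a)
    return 2.0 * np.arctan2(num, den)


def _subdivide(freq: int) -> tuple[np.ndarray, np.ndarray]:
    """Vertices (n, 3) and triangles (m, 3) of the frequency-``freq`` grid."""
    verts, faces = _icosahedron()
    plan_l = _RPRIME * _TANG
    plan_v = plan_l * np.array(
        [[math.cos(k * _SECTOR), math.sin(k * _SECTOR)] for k in range(3)]
    )
    points: list[np.ndarray] = [v for v in verts]
    index: dict[tuple, int] = {("v", i): i for i in range(12)}
    triangles: list[tuple[int, int, int]] = []

    for fi, face in enumerate(faces):
        a, b, c = (int(v) for v in face)
        centre, e1, e2 = _face_frame(verts, face)
        local: dict[tuple[int, int], int] = {}
        new_keys: list[tuple] = []
        new_xy: list[np.ndarray] = []
        for i in range(freq + 1):
            for j in range(freq + 1 - i):
                k = freq - i - j
                if k == freq:
                    key: tuple = ("v", a)
                elif i == freq:
                    key = ("v", b)
                elif j == freq:
                    key = ("v", c)
                elif j == 0:  # edge a-b, i steps from a
                    lo, hi = (a, b) if a < b else (b, a)
                    pos = i if a < b else freq - i
                    key = ("e", lo, hi, pos)
                elif i == 0:  # edge a-c, j steps from a
                    lo, hi = (a, c) if a < c else (c, a)
                    pos = j if a < c else freq - j
                    key = ("e", lo, hi, pos)
                elif k == 0:  # edge b-c, j steps from b
                    lo, hi = (b, c) if b < c else (c, b)
                    pos = j if b < c else freq - j
                    key = ("e", lo, hi, pos)
                else:
                    key = ("f", fi, i, j)
                gid = index.get(key)
                if gid is None:
                    gid = len(points) + len(new_xy)
                    index[key] = gid
                    new_keys.append(key)
                    new_xy.append((k * plan_v[0] + i * plan_v[1] + j * plan_v[2]) / freq)
                local[(i, j)] = gid
        if new_xy:
            mapped = _map_face_points(np.asarray(new_xy), centre, e1, e2)
            points.extend(mapped)
        for i in range(freq):
            for j in range(freq - i):
                triangles.append((local[(i, j)], local[(i + 1, j)], local[(i, j + 1)]))
                if j < freq - i - 1:
                    triangles.append((local[(i + 1, j)], local[(i + 1, j + 1)], local[(i, j + 1)]))
    return np.asarray(points), np.asarray(triangles, dtype=int)


# ---------------------------------------------------------------------------
# Public surface
# ---------------------------------------------------------------------------

def great_circle_km(a, b) -> np.ndarray | float:
    """Great-circle distance between (lat, lon) points, in km (haversine)."""
    lat1, lon1 = np.radians(np.asarray(a[0], dtype=float)), np.radians(np.asarray(a[1], dtype=float))
    lat2, lon2 = np.radians(np.asarray(b[0], dtype=float)), np.radians(np.asarray(b[1], dtype=float))
    s = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


@dataclass
class HexGrid:
    """Discrete global grid: cell centroids, areas, adjacency, hemispheres.

    Cells are indexed 0..n_cells-1.  ``neighbors[i]`` is a sorted integer
    array of adjacent cell ids (5 entries for the 12 pentagonal cells, 6
    otherwise).  ``hemisphere`` holds "WH" for cells with centroid longitude
    in [-180, -30) degrees and "EH" otherwise.
    """

    xyz: np.ndarray            # (n, 3) unit vectors
    lat: np.ndarray            # degrees
    lon: np.ndarray            # degrees in (-180, 180]
    area_km2: np.ndarray
    neighbors: list[np.ndarray]
    hemisphere: np.ndarray     # (n,) of "WH"/"EH"
    frequency: int
    triangles: np.ndarray = field(repr=False, default=None)

    @property
    def n_cells(self) -> int:
        return len(self.lat)

    def is_wh(self) -> np.ndarray:
        return self.hemisphere == "WH"

    def centroid(self, cell: int) -> tuple[float, float]:
        return float(self.lat[cell]), float(self.lon[cell])

    def mean_internode_km(self) -> float:
        """Mean centroid distance between adjacent cells."""
        edges = set()
        for i, nbrs in enumerate(self.neighbors):
            for j in nbrs:
                edges.add((min(i, int(j)), max(i, int(j))))
        idx = np.array(sorted(edges))
        d = great_circle_km(
            (self.lat[idx[:, 0]], self.lon[idx[:, 0]]),
            (self.lat[idx[:, 1]], self.lon[idx[:, 1]]),
        )
        return float(np.mean(d))

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cell_id", "lat", "lon", "area_km2", "hemisphere", "neighbors"])
            for i in range(self.n_cells):
                w.writerow(
                    [
                        i,
                        f"{self.lat[i]:.6f}",
                        f"{self.lon[i]:.6f}",
                        f"{self.area_km2[i]:.3f}",
                        self.hemisphere[i],
                        " ".join(str(int(j)) for j in self.neighbors[i]),
                    ]
                )

    def cell_polygons(self) -> list[np.ndarray]:
        """Dual-cell boundary vertices (lat, lon), ordered around each cell."""
        tri = self.triangles
        cent = self.xyz[tri].sum(axis=1)
        cent /= np.linalg.norm(cent, axis=1, keepdims=True)
        incident: list[list[int]] = [[] for _ in range(self.n_cells)]
        for t, (a, b, c) in enumerate(tri):
            incident[a].append(t)
            incident[b].append(t)
            incident[c].append(t)
        polys = []
        for i in range(self.n_cells):
            pts = cent[incident[i]]
            # order by azimuth in the local tangent plane
            n = self.xyz[i]
            ref = np.array([1.0, 0.0, 0.0])
            if abs(n[0]) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e1 = ref - np.dot(ref, n) * n
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(n, e1)
            order = np.argsort(np.arctan2(pts @ e2, pts @ e1))
            pts = pts[order]
            polys.append(
                np.column_stack(
                    [np.degrees(np.arcsin(np.clip(pts[:, 2], -1, 1))),
                     np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))]
                )
            )
        return polys

    def to_geojson(self, path, properties: dict[str, np.ndarray] | None = None) -> None:
        """Write dual-cell polygons as a GeoJSON FeatureCollection."""
        polys = self.cell_polygons()
        feats = []
        for i, poly in enumerate(polys):
            coords = [[float(lon), float(lat)] for lat, lon in poly]
            coords.append(coords[0])
            props = {"cell_id": i, "hemisphere": str(self.hemisphere[i])}
            if properties:
                for k, v in properties.items():
                    props[k] = float(v[i])
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [coords]},
                    "properties": props,
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def assign_hemisphere(lon: np.ndarray) -> np.ndarray:
    """Label cells WH iff centroid longitude lies in [-180, -30) degrees."""
    lon = np.asarray(lon, dtype=float)
    wh = (lon >= -180.0) & (lon < HEMISPHERE_SPLIT_LON)
    return np.where(wh, "WH", "EH")


def build_geodesic_grid(frequency: int) -> HexGrid:
    """Build the grid at an explicit subdivision frequency (10 f^2 + 2 cells)."""
    if frequency < 1:
        raise GridConfigurationError("frequency must be >= 1")
    pts, tri = _subdivide(frequency)
    n = len(pts)
    # adjacency
    nbr_sets: list[set[int]] = [set() for _ in range(n)]
    for a, b, c in tri:
        nbr_sets[a].update((b, c))
        nbr_sets[b].update((a, c))
        nbr_sets[c].update((a, b))
    neighbors = [np.array(sorted(s), dtype=int) for s in nbr_sets]
    # dual-cell areas from the barycentric kite partition (sums to 4 pi)
    va, vb, vc = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
    cent = va + vb + vc
    cent /= np.linalg.norm(cent, axis=1, keepdims=True)

    def _mid(u, v):
        m = u + v
        return m / np.linalg.norm(m, axis=1, keepdims=True)

    m_ab, m_bc, m_ca = _mid(va, vb), _mid(vb, vc), _mid(vc, va)
    area = np.zeros(n)
    for corner, m1, m2 in ((0, m_ca, m_ab), (1, m_ab, m_bc), (2, m_bc, m_ca)):
        v = pts[tri[:, corner]]
        kite = _triangle_solid_angle(v, m1, cent) + _triangle_solid_angle(v, cent, m2)
        np.add.at(area, tri[:, corner], kite)
    area_km2 = area * EARTH_RADIUS_KM**2
    lat = np.degrees(np.arcsin(np.clip(pts[:, 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    lon = np.where(lon <= -180.0, lon + 360.0, lon)
    return HexGrid(
        xyz=pts,
        lat=lat,
        lon=lon,
        area_km2=area_km2,
        neighbors=neighbors,
        hemisphere=assign_hemisphere(lon),
        frequency=frequency,
        triangles=tri,
    )


def build_grid(target_mean_cell_area_km2: float = DEFAULT_CELL_AREA_KM2) -> HexGrid:
    """Build the grid whose mean cell area is closest to the target.

    The achievable cell counts are 10 f^2 + 2 for integer frequency f; the
    frequency minimising |mean area - target| is selected.  Targets outside
    [10,000, 100,000] km^2 raise a configuration error naming the achievable
    band.
    """
    t = float(target_mean_cell_area_km2)
    if not (_MIN_TARGET_AREA <= t <= _MAX_TARGET_AREA):
        raise GridConfigurationError(
            f"target cell area {t:g} km^2 outside the supported band "
            f"[{_MIN_TARGET_AREA:g}, {_MAX_TARGET_AREA:g}] km^2 "
            "(coarser or finer resolutions are out of scope)"
        )
    f0 = math.sqrt(max((EARTH_AREA_KM2 / t - 2.0) / 10.0, 1.0))
    candidates = {max(1, int(math.floor(f0))), int(math.ceil(f0))}
    best = min(candidates, key=lambda f: abs(EARTH_AREA_KM2 / (10 * f * f + 2) - t))
    return build_geodesic_grid(best)
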