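"""Stratification of annual change stacks and footprint co-location.

Derives the analysis strata of the protocol — intact forest (>3,000 m from
the forest/non-forest edge and >120 m from degraded forest), degraded
forest split by driver (fire vs selective logging, with a 300 m fire buffer
guarding the logging attribution), 120 m edge classes split by
post-creation disturbance, and secondary regrowth with 1-based age — plus
Euclidean distance-to-edge rasters binned into the published distance
intervals, and joins quality-filtered LiDAR footprints onto them after a
35 m morphological erosion and temporal masking of disturbances that fall
inside the LiDAR acquisition period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Point
from shapely.prepared import prep
from shapely.strtree import STRtree

from . import codes
from .config import AnalysisThresholds, GridSpec
from .raster_io import GridGeometry
from .synthetic import AnnualChangeStack

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceBandScheme",
    "DEFAULT_BANDS",
    "sieve_forest_mask",
    "sieve_annual_maps",
    "distance_to_edge",
    "derive_strata",
    "colocate_footprints",
    "mask_low_deforestation_cells",
    "StrataRasters",
]

#: the published distance-to-edge intervals (metres)
DEFAULT_BANDS = [
    (0, 60), (60, 120), (120, 240), (240, 420), (420, 720), (720, 1020),
    (1020, 1500), (1500, 2040), (2040, 2580), (2580, 3120), (3120, 4020),
    (4020, 5100), (5100, 6000), (6000, 7200), (7200, 8100), (8100, 9000),
    (9000, 10200),
]


@dataclass(frozen=True)
class DistanceBandScheme:
    """Ordered, contiguous (lower, upper] distance intervals in metres."""

    intervals: tuple = tuple(DEFAULT_BANDS)

    def __post_init__(self):
        lowers = [lo for lo, _ in self.intervals]
        uppers = [hi for _, hi in self.intervals]
        if lowers[0] != 0:
            raise ValueError("first lower bound must be 0")
        if any(hi <= lo for lo, hi in self.intervals):
            raise ValueError("intervals must be strictly increasing")
        if any(u != l for u, l in zip(uppers[:-1], lowers[1:])):
            raise ValueError("intervals must be contiguous")

    @property
    def uppers(self) -> np.ndarray:
        return np.array([hi for _, hi in self.intervals], dtype=float)

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.intervals], dtype=float)

    def band_index(self, distance_m):
        """Band of each distance under the (lower, upper] convention.

        Returns -1 for non-positive distances (non-forest) and for
        distances beyond the last interval.
        """
        d = np.asarray(distance_m, dtype=float)
        idx = np.searchsorted(self.uppers, d, side="left")
        idx = np.where((d <= 0) | (idx >= len(self.intervals)), -1, idx)
        return idx.astype(int)


# ---------------------------------------------------------------------------
# sieve
# ---------------------------------------------------------------------------

def sieve_forest_mask(mask: np.ndarray) -> np.ndarray:
    """Remove isolated pixels from a binary forest mask.

    A pixel is isolated when none of its 4-connected neighbours shares its
    class; isolated pixels are replaced by the modal class of their 5x5
    window (window truncated at borders; ties keep the original value).
    """
    mask = np.asarray(mask, dtype=bool)
    cross = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    # count of in-grid 4-neighbours sharing the pixel's class
    ones = np.ones_like(mask, dtype=float)
    forest_n = ndi.convolve(mask.astype(float), cross, mode="constant", cval=0.0)
    total_n = ndi.convolve(ones, cross, mode="constant", cval=0.0)
    same = np.where(mask, forest_n, total_n - forest_n)
    isolated = same == 0

    k5 = np.ones((5, 5), dtype=float)
    forest5 = ndi.convolve(mask.astype(float), k5, mode="constant", cval=0.0)
    total5 = ndi.convolve(ones, k5, mode="constant", cval=0.0)
    mode_forest = forest5 * 2 > total5
    tie = forest5 * 2 == total5
    out = mask.copy()
    flip = isolated & ~tie
    out[flip] = mode_forest[flip]
    return out


def sieve_annual_maps(stack: AnnualChangeStack) -> AnnualChangeStack:
    """Apply the 5x5 sieve to the binary forest view of every annual map.

    Pixels whose binary class flips take the modal class code of the
    destination side within their 5x5 window.
    """
    data = stack.data.copy()
    for yi in range(data.shape[0]):
        cls = data[yi]
        mask = np.isin(cls, codes.FOREST_CLASSES)
        sieved = sieve_forest_mask(mask)
        flipped = sieved != mask
        if not flipped.any():
            continue
        for r, c in zip(*np.nonzero(flipped)):
            r0, r1 = max(r - 2, 0), min(r + 3, cls.shape[0])
            c0, c1 = max(c - 2, 0), min(c + 3, cls.shape[1])
            window = cls[r0:r1, c0:c1].ravel()
            side = np.isin(window, codes.FOREST_CLASSES) == sieved[r, c]
            vals, counts = np.unique(window[side], return_counts=True)
            data[yi][r, c] = vals[np.argmax(counts)]
    return AnnualChangeStack(stack.years, data, stack.geom)


# ---------------------------------------------------------------------------
# distance transform
# ---------------------------------------------------------------------------

@dataclass
class DistanceResult:
    distance_m: np.ndarray
    band: np.ndarray
    all_forest: bool = False


def distance_to_edge(forest_mask: np.ndarray, scheme: DistanceBandScheme | None = None,
                     pixel_size: float = 30.0) -> DistanceResult:
    """Euclidean distance (pixel centre to nearest non-forest pixel centre)
    for every forest pixel, plus its (lower, upper] distance band.

    Non-forest pixels get distance 0 and band -1.  An all-forest mask is
    flagged and returns +inf distances.
    """
    scheme = scheme or DistanceBandScheme()
    mask = np.asarray(forest_mask, dtype=bool)
    if mask.all():
        logger.warning("all-forest mask: distances undefined (+inf)")
        return DistanceResult(np.full(mask.shape, np.inf),
                              np.full(mask.shape, -1, dtype=int), all_forest=True)
    dist = ndi.distance_transform_edt(mask) * pixel_size
    band = scheme.band_index(dist)
    return DistanceResult(dist, band)


# ---------------------------------------------------------------------------
# strata
# ---------------------------------------------------------------------------

@dataclass
class StrataRasters:
    """Per-pixel stratum assignment and companion rasters at a reference year."""

    reference_year: int
    geom: GridGeometry
    scheme: DistanceBandScheme
    stratum: np.ndarray              # codes.STRATUM_*
    forest: np.ndarray               # forest (undisturbed|degraded) at ref year
    distance_m: np.ndarray
    band: np.ndarray
    distance_degraded_m: np.ndarray
    last_degradation_year: np.ndarray
    degradation_driver: np.ndarray
    edge_creation_year: np.ndarray   # 0 = not an edge pixel
    regrowth_start_year: np.ndarray
    natural_edge: np.ndarray         # nearest non-forest is water/savannah
    undisturbed: np.ndarray          # no degradation history
    far_from_degraded: np.ndarray    # >120 m from degraded forest
    counts: dict = field(default_factory=dict)

    def age_raster(self, kind: str) -> np.ndarray:
        """1-based ages at the reference year (NaN where undefined)."""
        ref = self.reference_year
        if kind == "degradation":
            src = self.last_degradation_year
        elif kind == "edge":
            src = self.edge_creation_year
        elif kind == "regrowth":
            src = self.regrowth_start_year
        else:
            raise ValueError(kind)
        age = np.where(src > 0, ref - src + 1, np.nan)
        return age


def _degradation_history(stack: AnnualChangeStack, reference_year: int):
    """Last year each pixel showed the degraded class, up to the reference year."""
    last = np.zeros(stack.data.shape[1:], dtype=np.int16)
    for yi, year in enumerate(stack.years):
        if year > reference_year:
            break
        degraded = stack.data[yi] == codes.DEGRADED
        last[degraded] = year
    return last


def _attribute_driver(last_degr, fire_year, logging_polygons, geom, pixel_size,
                      fire_buffer_m):
    """Driver per degraded pixel: fire takes precedence; logging is honoured
    only outside the fire buffer."""
    shape = last_degr.shape
    fire_mask = fire_year > 0
    driver = np.zeros(shape, dtype=np.int8)
    driver[fire_mask] = codes.DRIVER_FIRE
    if fire_mask.any():
        dist_fire = ndi.distance_transform_edt(~fire_mask) * pixel_size
    else:
        dist_fire = np.full(shape, np.inf)
    in_buffer = dist_fire <= fire_buffer_m

    logged = np.zeros(shape, dtype=bool)
    if logging_polygons:
        rows, cols = np.nonzero((last_degr > 0) & ~fire_mask)
        if rows.size:
            xs, ys = geom.pixel_center(rows, cols)
            tree = STRtree([poly for _, poly in logging_polygons])
            pts = [Point(x, y) for x, y in zip(xs, ys)]
            for i, pt in enumerate(pts):
                if tree.query(pt, predicate="intersects").size:
                    logged[rows[i], cols[i]] = True
    overlap = logged & fire_mask
    if overlap.any():
        logger.warning("%d pixels have contradictory fire and logging drivers; "
                       "fire takes precedence", int(overlap.sum()))
    driver[logged & ~fire_mask & ~in_buffer] = codes.DRIVER_LOGGING
    # logging inside the fire buffer (but not burned) stays unattributed -> excluded
    return driver, in_buffer


def derive_strata(stack: AnnualChangeStack, fire_year: np.ndarray,
                  logging_polygons, reference_year: int | None = None,
                  scheme: DistanceBandScheme | None = None,
                  thresholds: AnalysisThresholds | None = None,
                  exclusion_mask: np.ndarray | None = None) -> StrataRasters:
    """Assign every forest pixel to exactly one analysis stratum.

    ``logging_polygons`` is a sequence of ``(year, shapely polygon)`` pairs.
    ``exclusion_mask`` (optional) removes pixels a priori (e.g. mangrove or
    bamboo-dominated forest supplied externally).
    """
    thresholds = thresholds or AnalysisThresholds()
    scheme = scheme or DistanceBandScheme()
    if reference_year is None:
        reference_year = int(stack.years[-1])
    px = stack.geom.pixel_size
    ref_cls = stack.classes(reference_year)

    # sieved forest mask at the reference year drives all distances
    forest = sieve_forest_mask(np.isin(ref_cls, codes.FOREST_CLASSES))
    dres = distance_to_edge(forest, scheme, px)
    dist, band = dres.distance_m, dres.band

    # nearest-non-forest class, for natural-edge masking
    natural_edge = np.zeros(forest.shape, dtype=bool)
    if not dres.all_forest:
        _, (ir, ic) = ndi.distance_transform_edt(forest, return_indices=True)
        nearest_cls = ref_cls[ir, ic]
        natural_edge = forest & np.isin(nearest_cls, codes.NATURAL_NONFOREST_CLASSES)

    last_degr = _degradation_history(stack, reference_year)
    driver, fire_buffer = _attribute_driver(last_degr, fire_year, logging_polygons,
                                            stack.geom, px, thresholds.fire_buffer_m)
    degraded_hist = (last_degr > 0) & forest
    if degraded_hist.any():
        dist_degr = ndi.distance_transform_edt(~degraded_hist) * px
    else:
        dist_degr = np.full(forest.shape, np.inf)
    far_from_degraded = dist_degr > thresholds.edge_width_m
    undisturbed = forest & ~degraded_hist

    # edge creation year: first year the pixel sat within the edge width of
    # that year's sieved forest mask (pixels still in the edge zone today)
    edge_zone = forest & (dist <= thresholds.edge_width_m)
    creation = np.zeros(forest.shape, dtype=np.int16)
    for yi, year in enumerate(stack.years):
        if year > reference_year:
            break
        fmask_y = sieve_forest_mask(np.isin(stack.data[yi], codes.FOREST_CLASSES))
        if fmask_y.all():
            continue
        dist_y = ndi.distance_transform_edt(fmask_y) * px
        in_edge_y = fmask_y & (dist_y <= thresholds.edge_width_m)
        newly = edge_zone & in_edge_y & (creation == 0)
        creation[newly] = year

    # regrowth: regrowth class at the reference year with permanent presence
    # over the trailing 3 years
    regrow_now = ref_cls == codes.REGROWTH
    persistent = regrow_now.copy()
    for back in (1, 2):
        y = reference_year - back
        if y >= stack.years[0]:
            persistent &= stack.classes(y) == codes.REGROWTH
    regrowth_start = np.zeros(forest.shape, dtype=np.int16)
    if regrow_now.any():
        # walk back to the first year of the *uninterrupted* current spell
        active = regrow_now.copy()
        start = np.full(forest.shape, reference_year, dtype=np.int16)
        for year in range(reference_year, int(stack.years[0]) - 1, -1):
            still = active & (stack.classes(year) == codes.REGROWTH)
            start[still] = year
            active = still
            if not active.any():
                break
        regrowth_start[regrow_now] = start[regrow_now]

    stratum = np.full(forest.shape, codes.STRATUM_EXCLUDED, dtype=np.int8)

    # regrowth stratum (non-forest in the edge sense, but an analysis class)
    ok_regrow = persistent & (regrowth_start > 0)
    age_re = np.where(ok_regrow, reference_year - regrowth_start + 1, 0)
    ok_regrow &= (age_re >= 1) & (age_re <= 32)
    stratum[ok_regrow] = codes.STRATUM_REGROWTH

    # edge classes within the 120 m edge width (natural edges masked)
    edge_ok = edge_zone & ~natural_edge
    degr_after_edge = degraded_hist & (creation > 0) & (last_degr >= creation)
    stratum[edge_ok & ~degraded_hist] = codes.STRATUM_EDGE_UNDISTURBED
    stratum[edge_ok & degr_after_edge & (driver == codes.DRIVER_FIRE)] = codes.STRATUM_EDGE_BURNED
    stratum[edge_ok & degr_after_edge & (driver == codes.DRIVER_LOGGING)] = codes.STRATUM_EDGE_LOGGED

    # degraded forest beyond the edge zone
    interior_degraded = forest & degraded_hist & ~edge_zone
    stratum[interior_degraded & (driver == codes.DRIVER_FIRE)] = codes.STRATUM_DEGRADED_FIRE
    stratum[interior_degraded & (driver == codes.DRIVER_LOGGING)] = codes.STRATUM_DEGRADED_LOGGING

    # intact: undisturbed, far from the edge and from degraded forest
    intact = (
        undisturbed
        & (dist > thresholds.intact_distance_m)
        & far_from_degraded
        & ~natural_edge
    )
    stratum[intact] = codes.STRATUM_INTACT

    if exclusion_mask is not None:
        stratum[np.asarray(exclusion_mask, dtype=bool)] = codes.STRATUM_EXCLUDED

    counts = {codes.STRATUM_NAMES[k]: int((stratum == k).sum()) for k in codes.STRATUM_NAMES}
    return StrataRasters(
        reference_year=reference_year,
        geom=stack.geom,
        scheme=scheme,
        stratum=stratum,
        forest=forest,
        distance_m=dist,
        band=band,
        distance_degraded_m=dist_degr,
        last_degradation_year=last_degr,
        degradation_driver=driver,
        edge_creation_year=creation,
        regrowth_start_year=regrowth_start,
        natural_edge=natural_edge,
        undisturbed=undisturbed,
        far_from_degraded=far_from_degraded,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# co-location
# ---------------------------------------------------------------------------

def _erosion_selem(radius_m: float, pixel_size: float) -> np.ndarray:
    r_px = radius_m / pixel_size
    k = int(np.floor(r_px))
    yy, xx = np.mgrid[-k : k + 1, -k : k + 1]
    return (yy**2 + xx**2) <= r_px**2


def erode_strata(stratum: np.ndarray, radius_m: float, pixel_size: float) -> np.ndarray:
    """Erode every stratum class by a circular structuring element.

    Pixels whose class does not survive the erosion fall back to
    ``excluded``; this removes single-pixel patches and partial overlaps so
    geolocated footprints cannot straddle a class boundary.
    """
    selem = _erosion_selem(radius_m, pixel_size)
    out = np.full_like(stratum, codes.STRATUM_EXCLUDED)
    for code in np.unique(stratum):
        if code == codes.STRATUM_EXCLUDED:
            continue
        mask = stratum == code
        out[ndi.binary_erosion(mask, structure=selem)] = code
    return out


def colocate_footprints(footprints: pd.DataFrame, strata: StrataRasters,
                        grid_spec: GridSpec | None = None,
                        thresholds: AnalysisThresholds | None = None,
                        acquisition_period: tuple = (2019, 2022),
                        region: str = "synthetic") -> tuple[pd.DataFrame, dict]:
    """Join footprints onto eroded strata; returns (sample table, report).

    Footprints outside the raster extent are excluded (counted); strata
    whose defining event year falls inside the acquisition period are
    dropped (temporal masking); ages are 1-based at the acquisition year.
    """
    thresholds = thresholds or AnalysisThresholds()
    grid_spec = grid_spec or GridSpec()
    geom = strata.geom
    eroded = erode_strata(strata.stratum, thresholds.erosion_radius_m, geom.pixel_size)

    x = footprints["x"].to_numpy()
    y = footprints["y"].to_numpy()
    row, col = geom.rowcol(x, y)
    ny, nx = strata.stratum.shape
    inside = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
    n_outside = int((~inside).sum())
    if n_outside:
        logger.info("%d footprints outside raster extent excluded", n_outside)
    fp = footprints.loc[inside].reset_index(drop=True)
    row, col = row[inside], col[inside]

    stratum_code = eroded[row, col]
    dist = strata.distance_m[row, col]
    band = strata.band[row, col]
    dist_degr = strata.distance_degraded_m[row, col]
    last_degr = strata.last_degradation_year[row, col]
    creation = strata.edge_creation_year[row, col]
    regrow_start = strata.regrowth_start_year[row, col]
    acq_year = fp["acq_year"].to_numpy()

    # event year defining each stratum
    event_year = np.zeros(len(fp), dtype=int)
    deg_strata = np.isin(stratum_code, (codes.STRATUM_DEGRADED_FIRE, codes.STRATUM_DEGRADED_LOGGING,
                                        codes.STRATUM_EDGE_BURNED, codes.STRATUM_EDGE_LOGGED))
    event_year[deg_strata] = last_degr[deg_strata]
    edge_strata = np.isin(stratum_code, (codes.STRATUM_EDGE_UNDISTURBED,))
    event_year[edge_strata] = creation[edge_strata]
    re_strata = stratum_code == codes.STRATUM_REGROWTH
    event_year[re_strata] = regrow_start[re_strata]

    y0, y1 = acquisition_period
    temporal_drop = (event_year >= y0) & (event_year <= y1) & (stratum_code != codes.STRATUM_INTACT)
    n_temporal = int(temporal_drop.sum())

    keep = ~temporal_drop
    fp = fp.loc[keep].reset_index(drop=True)
    row, col = row[keep], col[keep]
    stratum_code = stratum_code[keep]
    dist, band, dist_degr = dist[keep], band[keep], dist_degr[keep]
    last_degr, creation, regrow_start = last_degr[keep], creation[keep], regrow_start[keep]
    acq_year, event_year = acq_year[keep], event_year[keep]

    age = np.where(event_year > 0, acq_year - event_year + 1, np.nan)
    years_since_degr = np.where(last_degr > 0, acq_year - last_degr, np.nan)
    edge_age = np.where(creation > 0, acq_year - creation + 1, np.nan)
    regrowth_age = np.where(regrow_start > 0, acq_year - regrow_start + 1, np.nan)

    sample = fp.copy()
    sample["stratum"] = pd.Categorical(
        [codes.STRATUM_NAMES[c] for c in stratum_code],
        categories=list(codes.STRATUM_NAMES.values()),
    )
    sample["band"] = band
    sample["dist_edge_m"] = dist
    sample["dist_degraded_m"] = dist_degr
    sample["age"] = age
    sample["years_since_degradation"] = years_since_degr
    sample["edge_age"] = edge_age
    sample["regrowth_age"] = regrowth_age
    sample["undisturbed"] = strata.undisturbed[row, col]
    sample["far_from_degraded"] = strata.far_from_degraded[row, col]
    sample["cell_id"] = grid_spec.cell_id(sample["x"].to_numpy(), sample["y"].to_numpy())
    sample["region"] = region

    report = {
        "n_input": int(len(footprints)),
        "n_outside_extent": n_outside,
        "n_temporal_masked": n_temporal,
        "n_output": int(len(sample)),
        "per_stratum": sample["stratum"].value_counts().to_dict(),
    }
    return sample, report


def mask_low_deforestation_cells(stack: AnnualChangeStack,
                                 grid_spec: GridSpec | None = None,
                                 thresholds: AnalysisThresholds | None = None) -> pd.DataFrame:
    """Flag analysis cells whose accumulated deforestation (1991 onwards)
    relative to the initial forest area is <= 2%; such cells are excluded
    from the edge-penetration analysis.

    Returns a frame with cell_id, forest_start, deforested_cum, fraction and
    ``included``.
    """
    thresholds = thresholds or AnalysisThresholds()
    grid_spec = grid_spec or GridSpec()
    first_year = int(stack.years[0])
    forest0 = stack.forest_mask(first_year)
    # pixels that were forest at start and deforested at some later year
    ever_deforested = np.zeros(forest0.shape, dtype=bool)
    for yi, year in enumerate(stack.years):
        if year == first_year:
            continue
        ever_deforested |= stack.data[yi] == codes.DEFORESTED
    cum_def = forest0 & ever_deforested

    rows, cols = np.indices(forest0.shape)
    xs, ys = stack.geom.pixel_center(rows.ravel(), cols.ravel())
    cell = grid_spec.cell_id(xs, ys)
    df = pd.DataFrame({
        "cell_id": cell,
        "forest0": forest0.ravel(),
        "deforested": cum_def.ravel(),
    })
    agg = df.groupby("cell_id", observed=True).agg(
        forest_start=("forest0", "sum"), deforested_cum=("deforested", "sum"))
    agg["fraction"] = np.where(agg["forest_start"] > 0,
                               agg["deforested_cum"] / agg["forest_start"], np.nan)
    agg["included"] = (agg["forest_start"] > 0) & (agg["fraction"] > thresholds.low_deforestation_fraction)
    n_zero = int((agg["forest_start"] == 0).sum())
    if n_zero:
        logger.info("%d cells with zero initial forest excluded", n_zero)
    return agg.reset_index()
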