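"""Intact forest landscape (IFL) mapping.

The edge-aware intact stratum (undisturbed forest farther from the edge
than the locally identified edge-effect scale and >120 m from degraded
forest) is aggregated from 30 m to 1 km and reduced to 4-connected
components of at least 500 pixels (~500 km^2), approximating the standard
IFL minimum-area criterion.  Minimum-width and corridor criteria are
deliberately not applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import block_reduce

from .codes import STRATUM_INTACT
from .strata import StrataRasters

__all__ = ["IFLMask", "intact_input_mask", "aggregate_to_km",
           "connected_patches", "overlap_stats"]

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class IFLMask:
    mask: np.ndarray              # binary 1 km raster after the area filter
    labels: np.ndarray            # component labels (0 = background)
    component_pixels: dict        # label -> pixel count (retained only)
    provenance: dict

    @property
    def n_components(self) -> int:
        return len(self.component_pixels)


def intact_input_mask(strata: StrataRasters, edge_scale_m: float | None = None) -> np.ndarray:
    """30 m intact mask feeding the IFL assessment.

    By default the intact stratum itself; with ``edge_scale_m`` the
    distance criterion is replaced by the locally identified edge-effect
    penetration scale (undisturbed, beyond that distance, >120 m from
    degraded forest).
    """
    if edge_scale_m is None:
        return strata.stratum == STRATUM_INTACT
    return (strata.undisturbed & strata.far_from_degraded
            & (strata.distance_m > edge_scale_m) & ~strata.natural_edge)


def aggregate_to_km(intact_mask_30m: np.ndarray, pixel_size: float = 30.0,
                    target_size: float = 1000.0, min_fraction: float = 0.5) -> np.ndarray:
    """Aggregate a 30 m binary mask to ~1 km cells.

    A coarse cell is intact iff the intact fraction of its fine pixels is
    >= ``min_fraction`` (majority rule by default; the >= convention keeps
    exact-threshold cells).  Trailing rows/columns that do not fill a
    complete block are dropped.
    """
    factor = max(1, int(round(target_size / pixel_size)))
    mask = np.asarray(intact_mask_30m, dtype=float)
    ny = (mask.shape[0] // factor) * factor
    nx = (mask.shape[1] // factor) * factor
    frac = block_reduce(mask[:ny, :nx], (factor, factor), np.mean)
    return frac >= min_fraction


def connected_patches(mask: np.ndarray, min_pixels: int = 500,
                      provenance: dict | None = None) -> IFLMask:
    """4-connected component labelling with a minimum-area filter.

    Components smaller than ``min_pixels`` (500 px ~ 500 km^2 at 1 km
    resolution) are removed; diagonal contact does not join components.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=FOUR_CONNECTED)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = counts[1:] >= min_pixels
    out_mask = keep[labels]
    out_labels = np.where(out_mask, labels, 0)
    comp = {int(l): int(counts[l]) for l in range(1, n + 1) if keep[l]}
    return IFLMask(mask=out_mask, labels=out_labels, component_pixels=comp,
                   provenance=dict(provenance or {}, min_pixels=min_pixels))


def overlap_stats(mask_a: np.ndarray, mask_b: np.ndarray,
                  protected_mask: np.ndarray | None = None) -> dict:
    """Areal overlap percentages between two masks on a common grid."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    area_a = int(a.sum())
    out = {
        "area_a_px": area_a,
        "area_b_px": int(b.sum()),
        "a_in_b_pct": 100.0 * (a & b).sum() / area_a if area_a else float("nan"),
    }
    if protected_mask is not None:
        p = np.asarray(protected_mask, dtype=bool)
        area_p = int(p.sum())
        out["a_in_protected_pct"] = 100.0 * (a & p).sum() / area_a if area_a else float("nan")
        out["protected_in_a_pct"] = 100.0 * (p & a).sum() / area_p if area_p else float("nan")
    return out
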