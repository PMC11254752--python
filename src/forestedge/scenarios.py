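"""Controlled experiment scenarios for parameter-recovery studies.

Each scenario is a :class:`~forestedge.config.SimulationConfig` describing
one study condition:

* ``edge_recovery_config`` isolates the edge-desiccation gradient on an
  otherwise smooth, undisturbed landscape, so the penetration-depth and
  edge-magnitude estimators are tested against their closed-form truth
  without confounding from disturbance history or strong canopy
  heterogeneity;
* ``stationary_world_config`` spreads disturbance and abandonment events
  uniformly through the record with time-invariant rates, which is the
  regime where the space-for-time substitution is exact and trajectories
  can be compared age-by-age against the generator's truth curves.

The scenario parameters are fixed properties of the study design, not
tuning knobs.
"""

from __future__ import annotations

from .config import DEFAULT_CONTAMINATION, SimulationConfig

__all__ = ["clean_contamination", "edge_recovery_config", "stationary_world_config"]


def clean_contamination() -> dict:
    """All metadata contamination rates zero (every footprint passes QC)."""
    return {k: 0.0 for k in DEFAULT_CONTAMINATION}


def qc_fixture_config(seed: int = 0, n_footprints: int = 10000) -> SimulationConfig:
    """Uniform undisturbed forest with default metadata contamination.

    Every quality rule fires at exactly its configured marginal rate: the
    landscape is wall-to-wall tall forest, so no footprints violate the 5 m
    height rule for natural reasons and the only violation source is the
    contamination model itself.
    """
    return SimulationConfig(
        seed=seed,
        n_footprints=n_footprints,
        nonforest_strip_px=0,
        n_water_blobs=0,
        n_savannah_blobs=0,
        deforestation_rate=0.0,
        fire_events_per_year=0.0,
        logging_events_per_year=0.0,
        abandonment_events_per_year=0.0,
        regrowth_prob=0.0,
        steep_patch_fraction=0.0,
    )


def edge_recovery_config(seed: int = 0, edge_magnitude: float = 0.20,
                         edge_depth_d95: float = 400.0,
                         n_footprints: int = 50000) -> SimulationConfig:
    """Smooth undisturbed landscape exposing only the edge gradient.

    Canopy heterogeneity is reduced to a 0.5 m spatial SD (short 2-pixel
    correlation) so that band means estimate the latent multiplier f(d)
    with sampling error well below one band width; no degradation events
    occur, leaving the full forest undisturbed as the distance profile
    requires; contamination is zero ("clean" footprints).
    """
    return SimulationConfig(
        seed=seed,
        grid_size=384,  # 11.5 km extent: hosts the full band scheme to 10.2 km
        edge_magnitude=edge_magnitude,
        edge_depth_d95=edge_depth_d95,
        n_footprints=n_footprints,
        rh98_sd=0.5,
        smoothing_length_px=2.0,
        deforestation_rate=0.35,  # compact front: sieve-invariant edge geometry
        fire_events_per_year=0.0,
        logging_events_per_year=0.0,
        regrowth_prob=0.0,
        steep_patch_fraction=0.0,
        n_water_blobs=0,      # natural features would carve 3 km exclusion
        n_savannah_blobs=0,   # zones out of the intact reference interior
        contamination=clean_contamination(),
    )


def stationary_world_config(seed: int = 0, edge_magnitude: float = 0.0,
                            n_footprints: int = 50000,
                            fire_events_per_year: float = 4.0,
                            logging_events_per_year: float = 4.0) -> SimulationConfig:
    """Stationary disturbance regime for space-for-time validation.

    Event rates are constant through 1991-2022, abandonment to regrowth is
    frequent enough to populate every age step, the edge gradient is off so
    the disturbance trajectories carry only their own signal, and the
    canopy field is smooth (0.5 m SD) so age-step means are dominated by the
    disturbance truth rather than landscape heterogeneity.
    """
    return SimulationConfig(
        seed=seed,
        edge_magnitude=edge_magnitude,
        n_footprints=n_footprints,
        rh98_sd=0.5,
        smoothing_length_px=2.0,
        fire_events_per_year=fire_events_per_year,
        logging_events_per_year=logging_events_per_year,
        event_radius_px=(3, 6),
        driver_zones=True,            # fire north / logging south: exact attribution
        geolocation_sd=0.0,           # exact positions: age assignment is the
                                      # quantity under test, not geolocation
        deforestation_rate=0.05,
        regrowth_prob=0.02,
        abandonment_events_per_year=5.0,
        nonforest_strip_px=40,        # enough converted land to abandon in patches
        steep_patch_fraction=0.0,
        n_water_blobs=0,
        n_savannah_blobs=0,
        contamination=clean_contamination(),
    )
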