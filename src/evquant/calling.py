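"""EV positivity filters and co-labelling subtype classification.

A detected particle is accepted as an EV when its diameter is below 500 nm
and at least one EV-characterisation marker (pan-EV or the tetraspanin trio)
has a label count strictly greater than 5; the cargo marker of interest is
called positive at counts strictly greater than 2.  Retained particles are
partitioned into the six co-labelling subtypes
{panEV-only, TT-only, panEV+TT} x {cargo+, cargo-}.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .clustering import Cluster

MARKER_CLASSES = ("panEV-only", "TT-only", "panEV+TT")
CARGO_STATES = ("cargo+", "cargo-")
SUBTYPES = tuple(f"{m}/{c}" for m in MARKER_CLASSES for c in CARGO_STATES)


@dataclass(frozen=True)
class ParticleFilters:
    """Positivity thresholds; marker/cargo thresholds are strict (count > t)."""

    max_diameter: float = 500.0
    min_marker_count: int = 5
    min_cargo_count: int = 2

    def validate(self) -> None:
        if self.max_diameter < 0 or self.min_marker_count < 0 or self.min_cargo_count < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass(frozen=True)
class ParticleRecord:
    """One measured particle with its per-channel counts and call state."""

    fov: int
    cluster_id: int
    diameter: float
    n_loc: int
    panEV_count: int
    TT_count: int
    cargo_count: int
    degenerate: bool = False
    fallback: bool = False
    condition: str = ""
    capture: str = ""
    permeabilised: bool = False
    panEV_positive: bool | None = None
    TT_positive: bool | None = None
    cargo_positive: bool | None = None

    @property
    def marker_class(self) -> str:
        if self.panEV_positive and self.TT_positive:
            return "panEV+TT"
        if self.panEV_positive:
            return "panEV-only"
        if self.TT_positive:
            return "TT-only"
        raise ValueError("particle has no positive EV marker")

    @property
    def subtype(self) -> str:
        return f"{self.marker_class}/{'cargo+' if self.cargo_positive else 'cargo-'}"


def particles_from_clusters(
    clusters: Iterable[Cluster],
    fov: int,
    *,
    condition: str = "",
    capture: str = "",
    permeabilised: bool = False,
) -> list[ParticleRecord]:
    """Wrap measured clusters as particle records (flags not yet set)."""
    records = []
    for c in clusters:
        records.append(
            ParticleRecord(
                fov=fov,
                cluster_id=c.cluster_id,
                diameter=c.diameter,
                n_loc=c.n_loc,
                panEV_count=c.channel_counts.get("panEV", 0),
                TT_count=c.channel_counts.get("TT", 0),
                cargo_count=c.channel_counts.get("cargo", 0),
                degenerate=c.degenerate,
                fallback=c.fallback,
                condition=condition,
                capture=capture,
                permeabilised=permeabilised,
            )
        )
    return records


def apply_filters(
    particles: Iterable[ParticleRecord],
    filters: ParticleFilters = ParticleFilters(),
    *,
    exclude_degenerate: bool = False,
) -> list[ParticleRecord]:
    """Apply the EV positivity filters and set per-channel flags.

    Retains a particle iff diameter < max_diameter and at least one
    EV-characterisation channel exceeds ``min_marker_count`` (strict).
    Degenerate-diameter particles (d = 0) pass the one-sided diameter filter
    literally; set ``exclude_degenerate`` to drop them.
    """
    filters.validate()
    retained = []
    for p in particles:
        if not p.diameter < filters.max_diameter:
            continue
        if exclude_degenerate and p.degenerate:
            continue
        pan_pos = p.panEV_count > filters.min_marker_count
        tt_pos = p.TT_count > filters.min_marker_count
        if not (pan_pos or tt_pos):
            continue
        retained.append(
            replace(
                p,
                panEV_positive=pan_pos,
                TT_positive=tt_pos,
                cargo_positive=p.cargo_count > filters.min_cargo_count,
            )
        )
    return retained


def classify_subtype(particle: ParticleRecord) -> str:
    """Subtype string for a retained particle; errors if no marker is positive."""
    if particle.panEV_positive is None:
        raise ValueError("particle has not been filtered (flags unset)")
    return particle.subtype  # raises ValueError when no marker is positive


def tabulate_counts(
    particles: Sequence[ParticleRecord],
    fovs: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-FOV subtype contingency with proportions.

    Returns one row per (condition, fov, subtype) cell over the full subtype
    grid, so empty FOVs keep all-zero rows (zero-event cases feed the
    Bayesian stage).  ``fovs`` lists the FOV indices to tabulate; when None,
    the FOVs present among the particles are used.
    """
    rows = []
    conditions: dict[tuple, list[ParticleRecord]] = {}
    for p in particles:
        conditions.setdefault((p.condition, p.capture, p.permeabilised), []).append(p)
    if not conditions:
        conditions = {("", "", False): []}
    for (cond, capture, perm), plist in sorted(conditions.items()):
        fov_list = sorted(set(fovs)) if fovs is not None else sorted({p.fov for p in plist})
        if not fov_list:
            fov_list = [0]
        for fov in fov_list:
            in_fov = [p for p in plist if p.fov == fov]
            total = len(in_fov)
            tally = {s: 0 for s in SUBTYPES}
            for p in in_fov:
                tally[classify_subtype(p)] += 1
            for subtype in SUBTYPES:
                marker, cargo_state = subtype.split("/")
                count = tally[subtype]
                rows.append(
                    {
                        "condition": cond,
                        "capture": capture,
                        "permeabilised": perm,
                        "fov": fov,
                        "subtype": marker,
                        "cargo_state": cargo_state,
                        "count": count,
                        "proportion": count / total if total else 0.0,
                    }
                )
    return pd.DataFrame(rows)


def particles_to_frame(particles: Sequence[ParticleRecord]) -> pd.DataFrame:
    """Particle-level output table (one row per particle)."""
    rows = []
    for p in particles:
        rows.append(
            {
                "condition": p.condition,
                "capture": p.capture,
                "permeabilised": p.permeabilised,
                "fov": p.fov,
                "cluster_id": p.cluster_id,
                "diameter_nm": p.diameter,
                "n_loc": p.n_loc,
                "panEV_count": p.panEV_count,
                "TT_count": p.TT_count,
                "cargo_count": p.cargo_count,
                "degenerate_flag": p.degenerate,
                "fallback_flag": p.fallback,
                "subtype": p.subtype if p.panEV_positive is not None else "",
            }
        )
    return pd.DataFrame(rows)
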