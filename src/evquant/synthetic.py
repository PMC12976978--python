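"""Synthetic dSTORM localisation data with known EV ground truth.

The generator emulates the statistical structure of a chip-based EV imaging
experiment: EVs are discs whose diameters follow a lognormal law (defaults
fitted so the mode is ~137 nm and the SD ~84 nm, matching nanoparticle
tracking of cancer-cell EV preparations), membrane markers (pan-EV, and the
CD9/CD63/CD81 tetraspanin trio "TT") blink on the disc rim, cargo markers
blink in the disc interior, every localisation is jittered by the finite
localisation precision, and uniform background localisations are added per
channel.  Empty-lane negative controls are background-only tables.

Noise convention
----------------
``sigma_loc`` is the total 2-D root-mean-square localisation error: each
coordinate pair receives independent Gaussian jitter with per-axis standard
deviation ``sigma_loc / sqrt(2)``, so the RMS radial displacement of a point
equals ``sigma_loc``.  Under this convention a rim-labelled vesicle of true
radius R has RMS radial spread ``sqrt(R**2 + sigma_loc**2)`` — exactly the
broadening assumed by the observed-diameter model in
:func:`evquant.clustering.predicted_observed_diameter`.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CHANNELS = ("panEV", "TT", "cargo")
CAPTURE_MODES = ("TT", "PS")

#: Lognormal diameter-law defaults, fitted once so that the distribution mode
#: is 137 nm and the standard deviation 84.4 nm.
DIAMETER_LOG_MEAN = 5.112887
DIAMETER_LOG_SD = 0.439211

_COLUMNS = ("x_nm", "y_nm", "frame", "channel")


class LocalisationTableError(ValueError):
    """Base error for malformed localisation tables."""


class MissingColumnError(LocalisationTableError):
    """A required column is absent from a localisation CSV."""


class UnknownChannelError(LocalisationTableError):
    """A channel name outside the fixed three-channel scheme was found."""


class MalformedTableError(LocalisationTableError):
    """The CSV could not be parsed as a localisation table."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic localisation-data generator.

    Lengths are nanometres; ``background_density`` is localisations per
    square micrometre per channel.  ``rate_*`` are the expected numbers of
    localisations per labelled EV in each channel (fluorophores blink
    repeatedly, so tens of localisations per vesicle are typical).
    """

    fov_size: float = 30000.0
    n_fov: int = 6
    mean_evs_per_fov: float = 60.0
    diameter_log_mean: float = DIAMETER_LOG_MEAN
    diameter_log_sd: float = DIAMETER_LOG_SD
    sigma_loc: float = 17.5
    rate_panEV: float = 40.0
    rate_TT: float = 25.0
    rate_cargo: float = 25.0
    p_TT_positive: float = 0.7
    p_cargo_positive: float = 0.3
    p_capture_TT: float = 0.8
    p_capture_PS: float = 0.6
    #: Retention probability of TT-negative EVs under TT capture, as a
    #: fraction of ``p_capture_TT`` (non-specific surface adhesion).
    nonspecific_capture_fraction: float = 0.1
    #: Optional multiplicative attenuation of the TT localisation rate
    #: (epitope masking hook); 1.0 disables it.
    tt_attenuation: float = 1.0
    background_density: float = 0.5
    frames_per_channel: int = 1000
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_TT_positive": self.p_TT_positive,
            "p_cargo_positive": self.p_cargo_positive,
            "p_capture_TT": self.p_capture_TT,
            "p_capture_PS": self.p_capture_PS,
            "nonspecific_capture_fraction": self.nonspecific_capture_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        nonneg = {
            "fov_size": self.fov_size,
            "mean_evs_per_fov": self.mean_evs_per_fov,
            "diameter_log_sd": self.diameter_log_sd,
            "sigma_loc": self.sigma_loc,
            "rate_panEV": self.rate_panEV,
            "rate_TT": self.rate_TT,
            "rate_cargo": self.rate_cargo,
            "tt_attenuation": self.tt_attenuation,
            "background_density": self.background_density,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_fov < 1:
            raise ValueError(f"n_fov must be >= 1, got {self.n_fov}")
        if self.frames_per_channel < 1:
            raise ValueError("frames_per_channel must be >= 1")


@dataclass(frozen=True)
class GroundTruthEV:
    """Truth record for one simulated vesicle (for parameter-recovery tests)."""

    center: tuple[float, float]
    diameter: float
    tt_positive: bool
    cargo_positive: bool
    fov_index: int


@dataclass
class LocalisationTable:
    """Per-field-of-view emitter localisations plus condition metadata.

    ``data`` holds one row per localisation with columns
    ``x_nm, y_nm, frame, channel``.
    """

    data: pd.DataFrame
    fov_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def coordinates(self, channels: Iterable[str] | None = None) -> np.ndarray:
        """Return the (n, 2) coordinate array, optionally channel-filtered."""
        df = self.data
        if channels is not None:
            df = df[df["channel"].isin(list(channels))]
        return df[["x_nm", "y_nm"]].to_numpy(dtype=float)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_nm": pd.Series(dtype=float),
            "y_nm": pd.Series(dtype=float),
            "frame": pd.Series(dtype=int),
            "channel": pd.Series(dtype=str),
        }
    )


def sample_ev_population(
    config: SyntheticConfig,
    capture_mode: str,
    rng: np.random.Generator | None = None,
) -> list[GroundTruthEV]:
    """Draw the ground-truth EV population for all fields of view.

    Per FOV the EV count is Poisson(``mean_evs_per_fov``); diameters are
    i.i.d. lognormal; marker carriage is Bernoulli per EV.  Capture thins the
    population: TT capture retains TT-positive EVs with ``p_capture_TT`` and
    TT-negative ones with ``nonspecific_capture_fraction * p_capture_TT``,
    while PS capture retains every EV with ``p_capture_PS`` independently of
    its tetraspanin status.
    """
    config.validate()
    if capture_mode not in CAPTURE_MODES:
        raise ValueError(f"capture_mode must be one of {CAPTURE_MODES}, got {capture_mode!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    evs: list[GroundTruthEV] = []
    for fov in range(config.n_fov):
        n = rng.poisson(config.mean_evs_per_fov)
        if n == 0:
            continue
        centers = rng.uniform(0.0, config.fov_size, size=(n, 2))
        diameters = rng.lognormal(config.diameter_log_mean, config.diameter_log_sd, size=n)
        tt = rng.random(n) < config.p_TT_positive
        cargo = rng.random(n) < config.p_cargo_positive
        if capture_mode == "TT":
            p_keep = np.where(
                tt,
                config.p_capture_TT,
                config.nonspecific_capture_fraction * config.p_capture_TT,
            )
        else:
            p_keep = np.full(n, config.p_capture_PS)
        keep = rng.random(n) < p_keep
        for i in np.flatnonzero(keep):
            evs.append(
                GroundTruthEV(
                    center=(float(centers[i, 0]), float(centers[i, 1])),
                    diameter=float(diameters[i]),
                    tt_positive=bool(tt[i]),
                    cargo_positive=bool(cargo[i]),
                    fov_index=fov,
                )
            )
    return evs


def _jitter(rng: np.random.Generator, n: int, sigma_loc: float) -> np.ndarray:
    # per-axis sd sigma/sqrt(2) => total 2-D RMS displacement = sigma_loc
    return rng.normal(0.0, sigma_loc / math.sqrt(2.0), size=(n, 2))


def render_localisations(
    evs: Sequence[GroundTruthEV],
    config: SyntheticConfig,
    *,
    fov_index: int = 0,
    metadata: dict | None = None,
    rng: np.random.Generator | None = None,
) -> LocalisationTable:
    """Render one field of view's EVs into a localisation table.

    Membrane markers (pan-EV always; TT iff the EV is TT-positive) are placed
    uniformly on the disc rim; cargo localisations (iff cargo-positive) are
    uniform over the disc interior.  Every point is jittered by the
    localisation-precision Gaussian, and a uniform spatial Poisson background
    is added per channel.  Frame indices are assigned round-robin per channel.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    per_channel: dict[str, list[np.ndarray]] = {ch: [] for ch in CHANNELS}

    for ev in evs:
        if ev.fov_index != fov_index:
            continue
        center = np.asarray(ev.center, dtype=float)
        radius = ev.diameter / 2.0
        rates = {
            "panEV": config.rate_panEV,
            "TT": config.rate_TT * config.tt_attenuation if ev.tt_positive else 0.0,
            "cargo": config.rate_cargo if ev.cargo_positive else 0.0,
        }
        for ch in ("panEV", "TT"):
            k = rng.poisson(rates[ch]) if rates[ch] > 0 else 0
            if k == 0:
                continue
            theta = rng.uniform(0.0, 2.0 * math.pi, k)
            pts = center + radius * np.column_stack([np.cos(theta), np.sin(theta)])
            per_channel[ch].append(pts + _jitter(rng, k, config.sigma_loc))
        if rates["cargo"] > 0:
            k = rng.poisson(rates["cargo"])
            if k:
                theta = rng.uniform(0.0, 2.0 * math.pi, k)
                r = radius * np.sqrt(rng.random(k))
                pts = center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
                per_channel["cargo"].append(pts + _jitter(rng, k, config.sigma_loc))

    area_um2 = (config.fov_size / 1000.0) ** 2
    for ch in CHANNELS:
        mean_bg = config.background_density * area_um2
        k = rng.poisson(mean_bg) if mean_bg > 0 else 0
        if k:
            per_channel[ch].append(rng.uniform(0.0, config.fov_size, size=(k, 2)))

    frames = []
    xs = []
    chs = []
    for ch in CHANNELS:
        if per_channel[ch]:
            pts = np.vstack(per_channel[ch])
            xs.append(pts)
            chs.extend([ch] * len(pts))
            frames.append(np.arange(len(pts)) % config.frames_per_channel)
    if xs:
        coords = np.vstack(xs)
        data = pd.DataFrame(
            {
                "x_nm": coords[:, 0],
                "y_nm": coords[:, 1],
                "frame": np.concatenate(frames).astype(int),
                "channel": chs,
            }
        )
    else:
        data = _empty_frame()
    return LocalisationTable(data=data, fov_index=fov_index, metadata=dict(metadata or {}))


def simulate_condition(
    config: SyntheticConfig,
    capture_mode: str,
    *,
    permeabilised: bool = False,
    cargo_marker: str = "panCit",
    condition: str = "condition",
) -> tuple[list[GroundTruthEV], list[LocalisationTable]]:
    """Simulate one chip lane: ground truth plus one table per FOV.

    Deterministic given ``config`` (all randomness flows from ``config.seed``).
    Permeabilisation is emulated upstream by the ``p_cargo_positive`` value
    supplied in ``config``; this function only records the flag as metadata.
    """
    rng = np.random.default_rng(config.seed)
    evs = sample_ev_population(config, capture_mode, rng=rng)
    meta = {
        "condition": condition,
        "capture_mode": capture_mode,
        "permeabilised": permeabilised,
        "cargo_marker": cargo_marker,
    }
    tables = [
        render_localisations(evs, config, fov_index=fov, metadata=meta, rng=rng)
        for fov in range(config.n_fov)
    ]
    return evs, tables


def simulate_negative_control(
    config: SyntheticConfig,
    *,
    condition: str = "negative_control",
) -> list[LocalisationTable]:
    """Empty-lane control: background localisations only, no EVs."""
    rng = np.random.default_rng(config.seed)
    meta = {"condition": condition, "capture_mode": "none",
            "permeabilised": False, "cargo_marker": "none"}
    return [
        render_localisations([], config, fov_index=fov, metadata=meta, rng=rng)
        for fov in range(config.n_fov)
    ]


def write_localisation_table(table: LocalisationTable, path: str | Path) -> None:
    """Write a table as CSV with `# key: value` metadata header lines.

    Coordinates are written with 0.01 nm resolution so a round trip is
    lossless at that precision.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# fov_index: {table.fov_index}\n")
        fh.write(f"# channels: {','.join(CHANNELS)}\n")
        for key in sorted(table.metadata):
            fh.write(f"# {key}: {table.metadata[key]}\n")
        df = table.data.copy()
        df["x_nm"] = df["x_nm"].map(lambda v: f"{v:.2f}")
        df["y_nm"] = df["y_nm"].map(lambda v: f"{v:.2f}")
        df.to_csv(fh, index=False, columns=list(_COLUMNS))


def read_localisation_table(path: str | Path) -> LocalisationTable:
    """Read a localisation CSV written by :func:`write_localisation_table`.

    Raises :class:`MissingColumnError`, :class:`UnknownChannelError` or
    :class:`MalformedTableError` for the corresponding defects.
    """
    path = Path(path)
    metadata: dict = {}
    fov_index = 0
    body_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    key, value = key.strip(), value.strip()
                    if key == "fov_index":
                        fov_index = int(value)
                    elif key == "channels":
                        pass
                    elif key == "permeabilised":
                        metadata[key] = value == "True"
                    else:
                        metadata[key] = value
            else:
                body_lines.append(line)
    if not body_lines:
        raise MalformedTableError(f"{path}: no CSV header found")
    try:
        data = pd.read_csv(io.StringIO("".join(body_lines)))
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MalformedTableError(f"{path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in data.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing required columns {missing}")
    bad = set(data["channel"].unique()) - set(CHANNELS)
    if bad:
        raise UnknownChannelError(
            f"{path}: unknown channel(s) {sorted(bad)}; expected {CHANNELS}"
        )
    if len(data):
        coords = data[["x_nm", "y_nm"]].to_numpy()
        if not np.all(np.isfinite(coords.astype(float))):
            raise MalformedTableError(f"{path}: non-finite coordinates")
        if (data["frame"] < 0).any():
            raise MalformedTableError(f"{path}: negative frame index")
    else:
        data = _empty_frame()
    data = data[list(_COLUMNS)].astype(
        {"x_nm": float, "y_nm": float, "frame": int, "channel": str}
    )
    return LocalisationTable(data=data, fov_index=fov_index, metadata=metadata)


def config_with(config: SyntheticConfig, **overrides) -> SyntheticConfig:
    """Return a copy of ``config`` with fields replaced (validated)."""
    new = replace(config, **overrides)
    new.validate()
    return new
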