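"""Generator statistics, rendering geometry and table IO round trips."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import gaussian_kde

from evquant import (
    GroundTruthEV,
    SyntheticConfig,
    read_localisation_table,
    render_localisations,
    sample_ev_population,
    simulate_condition,
    write_localisation_table,
)
from evquant.synthetic import (
    MalformedTableError,
    MissingColumnError,
    UnknownChannelError,
)


@pytest.mark.parametrize(
    "field,value",
    [
        ("p_TT_positive", 1.5),
        ("p_cargo_positive", -0.1),
        ("p_capture_TT", 2.0),
        ("rate_panEV", -1.0),
        ("background_density", -0.5),
        ("n_fov", 0),
    ],
)
def test_config_validation_rejects_out_of_range(field, value):
    cfg = dataclasses.replace(SyntheticConfig(), **{field: value})
    with pytest.raises(ValueError):
        cfg.validate()


def test_zero_cargo_probability_gives_no_cargo_positive_evs():
    cfg = SyntheticConfig(n_fov=4, mean_evs_per_fov=100, p_cargo_positive=0.0, seed=1)
    evs = sample_ev_population(cfg, "PS")
    assert len(evs) > 100
    assert not any(ev.cargo_positive for ev in evs)


def test_tt_capture_retention_matches_capture_probability():
    # with every EV TT-positive, TT capture thins by exactly p_capture_TT
    cfg = SyntheticConfig(
        n_fov=25, mean_evs_per_fov=100, p_TT_positive=1.0, p_capture_TT=0.8, seed=2
    )
    evs = sample_ev_population(cfg, "TT")
    expected = 25 * 100 * 0.8
    assert abs(len(evs) - expected) < 4 * math.sqrt(expected)


def test_ps_capture_ignores_tt_status():
    cfg = SyntheticConfig(
        n_fov=25, mean_evs_per_fov=100, p_TT_positive=0.5, p_capture_PS=0.6, seed=3
    )
    evs = sample_ev_population(cfg, "PS")
    frac_tt = np.mean([ev.tt_positive for ev in evs])
    assert abs(frac_tt - 0.5) < 4 * math.sqrt(0.25 / len(evs))


def test_diameter_law_mode_near_137nm():
    # the default lognormal is parameterised for a modal diameter of ~137 nm
    cfg = SyntheticConfig()
    rng = np.random.default_rng(11)
    draws = rng.lognormal(cfg.diameter_log_mean, cfg.diameter_log_sd, 10_000)
    xs = np.linspace(30, 400, 1500)
    mode = xs[np.argmax(gaussian_kde(draws)(xs))]
    assert abs(mode - 137) / 137 < 0.10
    assert abs(draws.std() - 84.4) / 84.4 < 0.10


def _one_ev(diameter, fov=0, cargo=False, tt=False, center=(5000.0, 5000.0)):
    return GroundTruthEV(
        center=center, diameter=diameter, tt_positive=tt, cargo_positive=cargo,
        fov_index=fov,
    )


def test_render_with_zero_rates_and_background_is_empty():
    cfg = SyntheticConfig(
        rate_panEV=0, rate_TT=0, rate_cargo=0, background_density=0, seed=0
    )
    table = render_localisations([_one_ev(100.0)], cfg)
    assert len(table) == 0


def test_rim_points_at_exact_radius_without_noise(rng):
    cfg = SyntheticConfig(
        rate_panEV=1000, rate_TT=0, sigma_loc=0.0, background_density=0, seed=4
    )
    table = render_localisations([_one_ev(100.0)], cfg, rng=rng)
    r = np.linalg.norm(table.coordinates(["panEV"]) - np.array([5000.0, 5000.0]), axis=1)
    assert np.allclose(r, 50.0, atol=1e-9)


def test_rim_rms_radius_matches_closed_form(rng):
    # rim at R plus isotropic noise of total variance sigma^2: RMS = sqrt(R^2+sigma^2)
    cfg = SyntheticConfig(
        rate_panEV=10_000, rate_TT=0, sigma_loc=20.0, background_density=0, seed=5
    )
    table = render_localisations([_one_ev(50.0)], cfg, rng=rng)
    r = np.linalg.norm(table.coordinates(["panEV"]) - np.array([5000.0, 5000.0]), axis=1)
    rms = np.sqrt(np.mean(r**2))
    assert abs(rms - math.sqrt(25**2 + 20**2)) < 0.6  # ~32.0 nm

    # cargo fills the disc interior: with zero noise all points inside radius
    cfg0 = SyntheticConfig(
        rate_panEV=0, rate_TT=0, rate_cargo=2000, sigma_loc=0.0,
        background_density=0, seed=6,
    )
    t2 = render_localisations([_one_ev(100.0, cargo=True)], cfg0)
    r2 = np.linalg.norm(t2.coordinates(["cargo"]) - np.array([5000.0, 5000.0]), axis=1)
    assert np.all(r2 <= 50.0 + 1e-9)


def test_background_count_matches_density():
    cfg = SyntheticConfig(
        fov_size=30000.0, background_density=2.0, rate_panEV=0, rate_TT=0,
        rate_cargo=0, seed=8,
    )
    table = render_localisations([], cfg)
    expected = 2.0 * 30.0**2 * 3  # density * area(um^2) * channels
    assert abs(len(table) - expected) <= 3 * math.sqrt(expected)


def test_pan_ev_counts_are_poisson_dispersed(rng):
    cfg = SyntheticConfig(rate_panEV=20, rate_TT=0, background_density=0, seed=9)
    counts = []
    for i in range(1000):
        t = render_localisations([_one_ev(100.0)], cfg, rng=rng)
        counts.append(len(t))
    counts = np.asarray(counts, dtype=float)
    assert 0.8 <= counts.var() / counts.mean() <= 1.2


def test_seed_determinism_gives_byte_identical_tables(tmp_path, tiny_config):
    paths = []
    for run in range(2):
        _, tables = simulate_condition(tiny_config, "TT", condition="det")
        p = tmp_path / f"run{run}.csv"
        write_localisation_table(tables[0], p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_roundtrip_preserves_rows_and_metadata(tmp_path, tiny_config):
    _, tables = simulate_condition(
        tiny_config, "PS", permeabilised=True, cargo_marker="CitH3", condition="rt"
    )
    table = tables[1]
    path = tmp_path / "rt_fov1.csv"
    write_localisation_table(table, path)
    back = read_localisation_table(path)
    assert back.fov_index == 1
    assert back.metadata["condition"] == "rt"
    assert back.metadata["capture_mode"] == "PS"
    assert back.metadata["permeabilised"] is True
    assert len(back) == len(table)
    # lossless to 0.01 nm
    a = np.sort(table.data[["x_nm", "y_nm"]].to_numpy(), axis=0)
    b = np.sort(back.data[["x_nm", "y_nm"]].to_numpy(), axis=0)
    assert np.allclose(a, b, atol=0.005 + 1e-12)
    assert sorted(back.data["channel"]) == sorted(table.data["channel"])


def test_empty_table_roundtrip(tmp_path):
    cfg = SyntheticConfig(rate_panEV=0, rate_TT=0, rate_cargo=0,
                          background_density=0, seed=0)
    table = render_localisations([], cfg, metadata={"condition": "empty"})
    path = tmp_path / "empty.csv"
    write_localisation_table(table, path)
    back = read_localisation_table(path)
    assert len(back) == 0
    assert back.metadata["condition"] == "empty"


def test_unknown_channel_raises(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("x_nm,y_nm,frame,channel\n1.0,2.0,0,CD9\n")
    with pytest.raises(UnknownChannelError):
        read_localisation_table(path)


def test_missing_column_raises(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("x_nm,frame,channel\n1.0,0,panEV\n")
    with pytest.raises(MissingColumnError):
        read_localisation_table(path)


def test_malformed_file_raises(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("")
    with pytest.raises(MalformedTableError):
        read_localisation_table(path)
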