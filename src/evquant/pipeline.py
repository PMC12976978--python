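"""End-to-end EV quantification runs: generate/load -> cluster -> call ->
gate -> compare -> size-compare, with machine-readable reports.

A run is described by a :class:`RunConfig` (usually from YAML).  Each
condition is one chip lane (capture mode x permeabilisation x cargo marker);
a lane is either synthesised by :mod:`evquant.synthetic` or loaded from
localisation CSVs.  Conditions that fail the detection gate against the
empty-lane negative control are excluded from all comparisons and listed in
the report.  All stochastic stages receive integer seeds derived
deterministically from the run seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .bayes import compare_posteriors, compare_to_null, posterior_from_counts
from .calling import (
    ParticleFilters,
    apply_filters,
    particles_from_clusters,
    particles_to_frame,
    tabulate_counts,
)
from .clustering import detect_particles
from .gate import gate_condition, ks_one_tailed
from .size_stats import compare_sizes, size_summary
from .synthetic import (
    CAPTURE_MODES,
    LocalisationTable,
    SyntheticConfig,
    read_localisation_table,
    simulate_condition,
    simulate_negative_control,
    write_localisation_table,
)


@dataclass(frozen=True)
class ConditionSpec:
    """One chip lane: either a synthetic recipe or a list of CSV paths."""

    name: str
    capture_mode: str = "TT"
    permeabilised: bool = False
    cargo_marker: str = "panCit"
    synthetic: dict | None = None
    paths: tuple[str, ...] | None = None


@dataclass
class RunConfig:
    seed: int
    conditions: dict[str, ConditionSpec]
    negative_control: ConditionSpec | None = None
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    null_tests: list[str] = field(default_factory=list)
    size_comparisons: list[tuple[str, str]] = field(default_factory=list)
    gate_threshold: float = 0.01
    eps: float = 100.0
    min_samples: int = 3
    assign_radius: float = 30.0
    filters: ParticleFilters = field(default_factory=ParticleFilters)
    n_mc: int = 200_000
    n_boot: int = 10_000
    out_dir: str | None = None

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        def cond(name: str, spec: dict) -> ConditionSpec:
            return ConditionSpec(
                name=name,
                capture_mode=spec.get("capture_mode", "TT"),
                permeabilised=bool(spec.get("permeabilised", False)),
                cargo_marker=spec.get("cargo_marker", "panCit"),
                synthetic=spec.get("synthetic"),
                paths=tuple(spec["paths"]) if spec.get("paths") else None,
            )

        clustering = raw.get("clustering", {})
        filt = raw.get("filters", {})
        neg = raw.get("negative_control")
        return RunConfig(
            seed=raw.get("seed"),
            conditions={
                name: cond(name, spec) for name, spec in raw.get("conditions", {}).items()
            },
            negative_control=cond("negative_control", neg) if neg is not None else None,
            comparisons=[tuple(pair) for pair in raw.get("comparisons", [])],
            null_tests=list(raw.get("null_tests", [])),
            size_comparisons=[tuple(p) for p in raw.get("size_comparisons", [])],
            gate_threshold=float(raw.get("gate_threshold", 0.01)),
            eps=float(clustering.get("eps", 100.0)),
            min_samples=int(clustering.get("min_samples", 3)),
            assign_radius=float(clustering.get("assign_radius", 30.0)),
            filters=ParticleFilters(
                max_diameter=float(filt.get("max_diameter", 500.0)),
                min_marker_count=int(filt.get("min_marker_count", 5)),
                min_cargo_count=int(filt.get("min_cargo_count", 2)),
            ),
            n_mc=int(raw.get("n_mc", 200_000)),
            n_boot=int(raw.get("n_boot", 10_000)),
            out_dir=raw.get("out_dir"),
        )


def load_config(path: str | Path) -> RunConfig:
    """Load a run configuration from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return RunConfig.from_dict(raw)


def validate_config(config: RunConfig) -> list[str]:
    """Exhaustive list of configuration issues; empty iff runnable."""
    issues: list[str] = []
    if config.seed is None:
        issues.append("seed is required for the Monte Carlo and bootstrap stages")
    elif not isinstance(config.seed, (int, np.integer)):
        issues.append(f"seed must be an integer, got {config.seed!r}")
    if not config.conditions:
        issues.append("at least one condition is required")
    for name, spec in config.conditions.items():
        if spec.synthetic is None and spec.paths is None:
            issues.append(f"condition {name!r}: needs either 'synthetic' or 'paths'")
        if spec.synthetic is not None and spec.capture_mode not in CAPTURE_MODES:
            issues.append(
                f"condition {name!r}: capture_mode must be one of {CAPTURE_MODES}"
            )
        if spec.synthetic is not None:
            try:
                _synthetic_config(spec, seed=0)
            except (ValueError, TypeError) as exc:
                issues.append(f"condition {name!r}: invalid synthetic config: {exc}")
        if spec.paths is not None:
            for p in spec.paths:
                if not Path(p).exists():
                    issues.append(f"condition {name!r}: missing input file {p}")
    if config.negative_control is None:
        issues.append("negative_control is required for the detection gate")
    elif config.negative_control.synthetic is None and config.negative_control.paths is None:
        issues.append("negative_control: needs either 'synthetic' or 'paths'")
    defined = set(config.conditions)
    for a, b in config.comparisons:
        for name in (a, b):
            if name not in defined:
                issues.append(f"comparison references undefined condition {name!r}")
    for name in config.null_tests:
        if name not in defined:
            issues.append(f"null_test references undefined condition {name!r}")
    for a, b in config.size_comparisons:
        for name in (a, b):
            if name not in defined:
                issues.append(f"size_comparison references undefined condition {name!r}")
    if not 0 < config.gate_threshold <= 1:
        issues.append("gate_threshold must be in (0, 1]")
    if config.eps <= 0:
        issues.append("clustering eps must be > 0")
    if config.min_samples < 1:
        issues.append("clustering min_samples must be >= 1")
    if config.n_mc < 1 or config.n_boot < 1:
        issues.append("n_mc and n_boot must be >= 1")
    return issues


def _derived_seed(base: int, label: str) -> int:
    """Deterministic per-stage integer seed < 2**31."""
    digest = hashlib.sha256(f"{base}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _synthetic_config(spec: ConditionSpec, seed: int) -> SyntheticConfig:
    overrides = dict(spec.synthetic or {})
    overrides["seed"] = seed
    cfg = SyntheticConfig(**overrides)
    cfg.validate()
    return cfg


def _condition_tables(spec: ConditionSpec, seed: int) -> list[LocalisationTable]:
    if spec.paths is not None:
        return [read_localisation_table(p) for p in spec.paths]
    cfg = _synthetic_config(spec, seed)
    if spec.name == "negative_control":
        return simulate_negative_control(cfg)
    _, tables = simulate_condition(
        cfg,
        spec.capture_mode,
        permeabilised=spec.permeabilised,
        cargo_marker=spec.cargo_marker,
        condition=spec.name,
    )
    return tables


def _process_condition(spec: ConditionSpec, config: RunConfig):
    """Cluster, size, filter and classify one lane; returns per-lane results."""
    tables = _condition_tables(spec, _derived_seed(config.seed, f"sim:{spec.name}"))
    retained = []
    counts = []
    for table in tables:
        clusters = detect_particles(
            table,
            eps=config.eps,
            min_samples=config.min_samples,
            assign_radius=config.assign_radius,
        )
        particles = particles_from_clusters(
            clusters,
            table.fov_index,
            condition=spec.name,
            capture=spec.capture_mode if spec.paths is None else
            table.metadata.get("capture_mode", spec.capture_mode),
            permeabilised=spec.permeabilised,
        )
        kept = apply_filters(particles, config.filters)
        retained.extend(kept)
        counts.append(len(kept))
    return {
        "name": spec.name,
        "fovs": [t.fov_index for t in tables],
        "particles": retained,
        "fov_counts": counts,
        "diameters": np.array([p.diameter for p in retained]),
        "cargo_positive": sum(1 for p in retained if p.cargo_positive),
        "cargo_negative": sum(1 for p in retained if not p.cargo_positive),
    }


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    force_gate: bool = False,
) -> dict[str, Any]:
    """Execute a full run and return (and optionally write) the report.

    Conditions failing the detection gate are excluded from comparisons
    unless ``force_gate`` is set.  When ``out_dir`` (or ``config.out_dir``)
    is given, particle tables, subtype tallies, the gate report, comparison
    tables and a reproducibility manifest are written there.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid run config:\n  " + "\n  ".join(issues))

    lanes = {name: _process_condition(spec, config)
             for name, spec in config.conditions.items()}
    control = _process_condition(config.negative_control, config)

    gate_report: dict[str, dict] = {}
    excluded: list[str] = []
    for name, lane in lanes.items():
        res = gate_condition(
            ks_one_tailed(lane["fov_counts"], control["fov_counts"]),
            threshold=config.gate_threshold,
        )
        gate_report[name] = {
            "D_plus": res.ks_statistic,
            "p_value": res.p_value,
            "method": res.method,
            "passed": res.passed,
        }
        if not res.passed:
            excluded.append(name)

    usable = {name for name in lanes if name not in excluded or force_gate}

    comparison_rows = []
    for a, b in config.comparisons:
        if a not in usable or b not in usable:
            continue
        pa = posterior_from_counts(lanes[a]["cargo_positive"], lanes[a]["cargo_negative"])
        pb = posterior_from_counts(lanes[b]["cargo_positive"], lanes[b]["cargo_negative"])
        seed = _derived_seed(config.seed, f"mc:{a}:{b}")
        res = compare_posteriors(pa, pb, n_mc=config.n_mc, seed=seed)
        comparison_rows.append(
            {
                "group1": a, "group2": b,
                "a1": pa.a, "b1": pa.b, "a2": pb.a, "b2": pb.b,
                "mean_diff": res.mean_difference,
                "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                "prob_greater": res.prob_greater, "p_same": res.p_same,
                "n_mc": res.n_mc, "seed": res.seed,
            }
        )

    null_rows = []
    for name in config.null_tests:
        if name not in usable:
            continue
        post = posterior_from_counts(
            lanes[name]["cargo_positive"], lanes[name]["cargo_negative"]
        )
        seed = _derived_seed(config.seed, f"null:{name}")
        res = compare_to_null(
            post, lanes[name]["cargo_negative"], n_mc=config.n_mc, seed=seed
        )
        null_rows.append(
            {
                "group1": name, "group2": "null",
                "a1": post.a, "b1": post.b,
                "a2": 1.0, "b2": lanes[name]["cargo_negative"] + 1.0,
                "mean_diff": res.mean_difference,
                "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                "prob_greater": res.prob_greater, "p_same": res.p_same,
                "n_mc": res.n_mc, "seed": res.seed,
            }
        )

    size_rows = []
    for a, b in config.size_comparisons:
        if a not in usable or b not in usable:
            continue
        da, db = lanes[a]["diameters"], lanes[b]["diameters"]
        if len(da) < 2 or len(db) < 2:
            continue
        seed = _derived_seed(config.seed, f"boot:{a}:{b}")
        res = compare_sizes(da, db, n_boot=config.n_boot, seed=seed)
        size_rows.append(
            {
                "group_a": a, "group_b": b,
                "D": res.ks_statistic, "p": res.ks_p,
                "significant": res.significant,
                "median_diff_nm": res.median_difference,
                "boot_low": res.ci95_boot[0], "boot_high": res.ci95_boot[1],
                "n_boot": res.n_boot, "seed": res.seed,
            }
        )

    summary_rows = []
    for name in sorted(usable):
        d = lanes[name]["diameters"]
        if len(d) == 0:
            continue
        s = size_summary(d)
        summary_rows.append(
            {
                "group": name, "n": s.n, "median_nm": s.median,
                "ci67_low": s.ci67[0], "ci67_high": s.ci67[1],
                "ci95_low": s.ci95[0], "ci95_high": s.ci95[1],
            }
        )

    all_particles = [p for lane in lanes.values() for p in lane["particles"]]
    counts_frames = []
    for name, lane in lanes.items():
        counts_frames.append(tabulate_counts(lane["particles"], fovs=lane["fovs"]))
    counts_table = (
        pd.concat(counts_frames, ignore_index=True) if counts_frames else pd.DataFrame()
    )

    if excluded and len(excluded) == len(lanes):
        status = "all_gated_out"
    elif excluded:
        status = "warning"
    else:
        status = "ok"

    report: dict[str, Any] = {
        "status": status,
        "excluded": excluded,
        "gate": gate_report,
        "fov_counts": {name: lane["fov_counts"] for name, lane in lanes.items()},
        "control_fov_counts": control["fov_counts"],
        "n_retained": {name: len(lane["particles"]) for name, lane in lanes.items()},
        "comparisons": comparison_rows,
        "null_tests": null_rows,
        "size_summaries": summary_rows,
        "size_comparisons": size_rows,
    }

    target_dir = out_dir or config.out_dir
    if target_dir is not None:
        _write_outputs(Path(target_dir), config, report, all_particles, counts_table)
    return report


def _version() -> str:
    from . import __version__

    return __version__


def _config_to_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return enc(config)


def _write_outputs(out_dir: Path, config: RunConfig, report, particles, counts_table):
    out_dir.mkdir(parents=True, exist_ok=True)
    particles_to_frame(particles).to_csv(out_dir / "particles.csv", index=False)
    counts_table.to_csv(out_dir / "subtype_counts.csv", index=False)
    pd.DataFrame(report["comparisons"] + report["null_tests"]).to_csv(
        out_dir / "comparisons.csv", index=False
    )
    pd.DataFrame(report["size_summaries"]).to_csv(
        out_dir / "size_summary.csv", index=False
    )
    pd.DataFrame(report["size_comparisons"]).to_csv(
        out_dir / "size_comparisons.csv", index=False
    )
    with open(out_dir / "gate.json", "w", encoding="utf-8") as fh:
        json.dump(report["gate"], fh, indent=2, sort_keys=True)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    cfg_dict = _config_to_dict(config)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": {
            "evquant": _version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def write_simulated_tables(config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Materialise every synthetic lane as localisation CSVs (one per FOV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    specs = list(config.conditions.values())
    if config.negative_control is not None:
        specs.append(config.negative_control)
    for spec in specs:
        if spec.synthetic is None:
            continue
        tables = _condition_tables(spec, _derived_seed(config.seed, f"sim:{spec.name}"))
        for table in tables:
            path = out_dir / f"{spec.name}_fov{table.fov_index}.csv"
            write_localisation_table(table, path)
            written.append(path)
    return written
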