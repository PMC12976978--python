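"""End-to-end run: two synthetic lanes plus an empty-lane control.

Builds a run configuration in code (the YAML form is identical), executes
simulate -> cluster -> call -> gate -> compare -> size-compare, and prints
the report.  The same run is available from the shell as
`evquant run --config run.yaml --out-dir out/`.
"""

from evquant.pipeline import RunConfig, run_pipeline

raw = {
    "seed": 5,
    "conditions": {
        "perm": {
            "capture_mode": "TT",
            "permeabilised": True,
            "cargo_marker": "panCit",
            "synthetic": {"n_fov": 6, "mean_evs_per_fov": 60, "p_cargo_positive": 0.4},
        },
        "nonperm": {
            "capture_mode": "TT",
            "permeabilised": False,
            "cargo_marker": "panCit",
            "synthetic": {"n_fov": 6, "mean_evs_per_fov": 60, "p_cargo_positive": 0.1},
        },
    },
    "negative_control": {"synthetic": {"n_fov": 6, "mean_evs_per_fov": 0}},
    "comparisons": [["perm", "nonperm"]],
    "null_tests": ["nonperm"],
    "size_comparisons": [["perm", "nonperm"]],
}

report = run_pipeline(RunConfig.from_dict(raw))

print(f"status: {report['status']}  (excluded: {report['excluded'] or 'none'})")
for name, g in report["gate"].items():
    print(f"gate {name}: D+={g['D_plus']:.2f} p={g['p_value']:.2e} -> {'pass' if g['passed'] else 'fail'}")
for c in report["comparisons"]:
    print(
        f"{c['group1']} vs {c['group2']}: diff {c['mean_diff']:+.3f} "
        f"[{c['ci_low']:+.3f}, {c['ci_high']:+.3f}], "
        f"P(p1>p2)={c['prob_greater']:.4f}, p_same={c['p_same']:.2e}"
    )
for n in report["null_tests"]:
    print(f"{n['group1']} vs null: P(p1>null)={n['prob_greater']:.4f}")
for s in report["size_summaries"]:
    print(f"sizes {s['group']}: median {s['median_nm']:.0f} nm, n={s['n']}")
for s in report["size_comparisons"]:
    print(
        f"size diff {s['group_a']}-{s['group_b']}: {s['median_diff_nm']:+.1f} nm "
        f"[{s['boot_low']:+.1f}, {s['boot_high']:+.1f}] (KS p={s['p']:.2f})"
    )
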