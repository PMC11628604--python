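#!/usr/bin/env python
"""The study's statistical analyses on the simulated cohort: per-group
APOE -> Abeta42 dose–response, pooled microglia-count regressions on plaque
load, depletion-arm treatment contrasts adjusted for APOE level, a mixed
model of log-compactness on plaque diameter, and an exact multi-set overlap
test at transcriptome-background scale.

Writes results/statistics.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import gliaquant as gq
from gliaquant.core import child_seed

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    results = {}

    cfg = gq.CohortConfig(groups=gq.default_groups(), mice_per_group=8,
                          rng_seed=child_seed(args.seed, "stats"))
    table = gq.simulate_cohort_table(cfg)
    mice = table.mice

    rows = []
    for name in ("APOE2", "APOE3", "APOE4"):
        sub = mice[mice["group"] == name]
        r = gq.ols_fit(sub["apoe_level"], sub["abeta42"])
        rows.append(dict(group=name, slope=round(r.slope, 4),
                         r_squared=round(r.r_squared, 3),
                         p=float(f"{r.pvalues['x']:.3g}"), n=r.n))
        print(f"{name}: Abeta42 ~ APOE slope {r.slope:.3f}, "
              f"R^2 {r.r_squared:.2f}, p {r.pvalues['x']:.3g}")
    results["dose_response"] = rows

    af = mice["mean_plaque_area_fraction"]
    reg = {}
    for col, key in (("mean_n_pa", "plaque_associated"),
                     ("mean_n_nonpa", "non_plaque_associated"),
                     ("mean_n_microglia", "total")):
        r = gq.ols_fit(af, mice[col])
        reg[key] = dict(slope=round(r.slope, 2),
                        r_squared=round(r.r_squared, 3),
                        p=float(f"{r.pvalues['x']:.3g}"), n=r.n)
        print(f"{key}: count ~ plaque area fraction slope {r.slope:.1f}, "
              f"R^2 {r.r_squared:.2f}")
    results["microglia_vs_plaque_load"] = reg

    contrasts = {}
    for name in ("APOE2", "APOE3", "APOE4"):
        spec = [g for g in gq.default_groups() if g.name == name][0]
        c2 = gq.CohortConfig(groups=[spec, gq.plx_treated(spec)],
                             mice_per_group=8,
                             rng_seed=child_seed(args.seed, f"plx/{name}"))
        m2 = gq.simulate_cohort_table(c2).mice
        r = gq.multiple_regression(
            m2["abeta42"], (m2["treatment"] != "control").astype(float),
            m2["apoe_level"])
        contrasts[name] = dict(beta=round(r.params["treatment"], 1),
                               se=round(r.se["treatment"], 1),
                               p=float(f"{r.pvalues['treatment']:.3g}"),
                               n=r.n)
        print(f"depletion contrast {name}: beta "
              f"{r.params['treatment']:.1f} (SE {r.se['treatment']:.1f}, "
              f"p {r.pvalues['treatment']:.3g})")
    results["depletion_contrast"] = contrasts

    # mixed model: log-ASM on plaque diameter with mouse random intercepts,
    # fitted to image-measured plaques from rendered FOVs (3 mice)
    rng = np.random.default_rng(child_seed(args.seed, "lmm"))
    rows = []
    spec = gq.GroupSpec("asm", plaque_density=40.0)
    for m in range(3):
        fov, gt = gq.generate_fov(spec, child_seed(args.seed, f"lmm/{m}"))
        chan = fov.channel("plaque")
        for pid, d in zip(gt.plaques["plaque_id"],
                          2 * gt.plaques["radius_um"]):
            inst = gt.plaque_labels == pid
            if inst.sum() < 2:
                continue
            asm = gq.compute_asm(gq.compute_glcm(chan, inst))
            rows.append(dict(mouse=m, diameter=float(d), asm=asm))
    df = pd.DataFrame(rows)
    mm = gq.fit_mixed_model(
        gq.MixedModelSpec(response="asm", fixed_effects=["diameter"],
                          group="mouse", log_response=True), df)
    results["asm_mixed_model"] = dict(
        diameter_slope=float(f"{mm.params['diameter']:.4g}"),
        p=float(f"{mm.pvalues['diameter']:.3g}"),
        random_intercept_var=float(f"{mm.random_intercept_var:.3g}"),
        n=len(df))
    print(f"log-ASM ~ diameter LMM: slope {mm.params['diameter']:.4f}, "
          f"p {mm.pvalues['diameter']:.3g} over {len(df)} plaques")

    res = gq.multiset_exact_test(25321, (696, 400, 500), 2)
    results["multiset_overlap_example"] = dict(
        background=25321, set_sizes=[696, 400, 500], k=2,
        tail_p=float(f"{res.tail_p:.4g}"))
    print(f"3-set overlap >= 2 in a 25,321-gene background: "
          f"p = {res.tail_p:.4g}")

    with open(out / "statistics.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    print(f"\nwrote {out / 'statistics.json'}")


if __name__ == "__main__":
    main()
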