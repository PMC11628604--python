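#!/usr/bin/env python
"""Individually label microglia by dual-EDT fusion + seeded watershed,
score the recovery against ground truth, and measure per-cell territory,
process length, clustering and plaque association.

Writes results/microglia_records.csv and results/watershed_recovery.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import gliaquant as gq
from gliaquant.core import child_seed

ROOT = Path(__file__).resolve().parents[1]


def recovery(labels, gt):
    matched, used = 0, set()
    for cid in gt.microglia["cell_id"]:
        g = gt.microglia_labels == cid
        vals, cnts = np.unique(labels[g], return_counts=True)
        sel = vals > 0
        vals, cnts = vals[sel], cnts[sel]
        if len(vals) == 0:
            continue
        best = int(vals[np.argmax(cnts)])
        if best in used:
            continue
        p = labels == best
        if (g & p).sum() / (g | p).sum() >= 0.5:
            used.add(best)
            matched += 1
    return matched


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    cfg = gq.FusionConfig()
    rec_rows, cell_frames = [], []
    spec = gq.GroupSpec("mixed", plaque_density=12.0,
                        microglia_base_density=60.0,
                        pa_recruitment_coeff=900.0)
    for k in range(3):
        fov, gt = gq.generate_fov(spec, child_seed(args.seed, f"mic/{k}"))
        px = fov.pixel_size_um
        mask = gt.microglia_labels > 0
        seeds = np.column_stack([gt.microglia["y_um"] / px,
                                 gt.microglia["x_um"] / px])
        labels, _ = gq.segment_microglia(fov.channel("microglia"), mask, cfg,
                                         px, seeds=seeds)
        body, _ = gq.split_body_process(mask, cfg, px)
        df = gq.measure_microglia(labels, body, gt.plaque_labels > 0, px)
        df.insert(0, "fov", k)
        cell_frames.append(df)
        m = recovery(labels, gt)
        rec_rows.append(dict(fov=k, n_true=gt.n_microglia, n_matched=m,
                             recovery=m / max(gt.n_microglia, 1)))
        print(f"FOV {k}: {m}/{gt.n_microglia} cells recovered 1:1 at IoU>=0.5")

    cells = pd.concat(cell_frames, ignore_index=True)
    cells.to_csv(out / "microglia_records.csv", index=False)
    pd.DataFrame(rec_rows).to_csv(out / "watershed_recovery.csv", index=False)

    pa = cells[cells["plaque_associated"]]
    npa = cells[~cells["plaque_associated"]]
    print(f"\nplaque-associated cells: {len(pa)} "
          f"(mean 3-NN {pa['nn3_mean_dist_um'].mean():.1f} um, "
          f"territory {pa['convex_area_um2'].mean():.0f} um^2)")
    print(f"non-associated cells:    {len(npa)} "
          f"(mean 3-NN {npa['nn3_mean_dist_um'].mean():.1f} um, "
          f"territory {npa['convex_area_um2'].mean():.0f} um^2)")
    print(f"\nwrote {out / 'microglia_records.csv'}")


if __name__ == "__main__":
    main()
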