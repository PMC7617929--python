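#!/usr/bin/env python
"""Swimming-halo dose-response analysis on a synthetic plate study.

Generates halo-diameter tables for wildtype, a che1-like mutant and a
non-motile fliG-like control across glucose/pyruvate/succinate (1-30 mM),
fits four-parameter log-logistic and linear models per strain x carbon
source, selects between them by corrected information criterion, and
estimates the maximum non-motile baseline from the control.

Writes results/halo_fits.json, results/halo_predictions.csv and
results/halo_fits.png.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from rhizotrack.halo import fit_halo_table, predict_four_pl
from rhizotrack.swim_sim import generate_halo_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = generate_halo_table(noise_sd=1.5, replicates=3, seed=args.seed)
    table.to_csv(args.outdir / "halo_table.csv", index=False)
    fits = fit_halo_table(table, control_strain="fliG")
    baseline = fits.pop("baseline_mm")

    payload, pred_rows = {"baseline_mm": baseline}, []
    grid = np.geomspace(1.0, 30.0, 60)
    for (strain, carbon), fr in fits.items():
        sel = fr["selection"]
        fp = fr["fourpl"]
        payload[f"{strain}|{carbon}"] = {
            "model": sel["model"],
            "fourpl": None if not fp.converged else
            {k: round(getattr(fp, k), 4) for k in ("b", "c", "d", "e", "rss")},
            "linear": {"intercept": round(fr["linear"].intercept, 4),
                       "slope": round(fr["linear"].slope, 4),
                       "rss": round(fr["linear"].rss, 4)},
        }
        if sel["model"] == "4PL":
            pred = predict_four_pl(fp, grid)
        else:
            pred = pd.DataFrame({"conc_mM": grid,
                                 "fit_mm": fr["linear"].predict(grid)})
        pred.insert(0, "strain", strain)
        pred.insert(1, "carbon_source", carbon)
        pred_rows.append(pred)

    (args.outdir / "halo_fits.json").write_text(json.dumps(payload, indent=1))
    preds = pd.concat(pred_rows, ignore_index=True)
    preds.to_csv(args.outdir / "halo_predictions.csv", index=False)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    carbons = sorted(table.carbon_source.unique())
    fig, axes = plt.subplots(1, len(carbons), figsize=(4 * len(carbons), 3.2),
                             sharey=True)
    for ax, carbon in zip(np.atleast_1d(axes), carbons):
        for strain, grp in table[table.carbon_source == carbon].groupby("strain"):
            ax.scatter(grp.conc_mM, grp.diameter_mm, s=12, label=strain)
            p = preds[(preds.strain == strain) & (preds.carbon_source == carbon)]
            ax.plot(p.conc_mM, p.fit_mm)
        ax.axhline(baseline, ls="--", c="grey")
        ax.set_xscale("log")
        ax.set_xlabel("concentration (mM)")
        ax.set_title(carbon)
    np.atleast_1d(axes)[0].set_ylabel("halo diameter (mm)")
    np.atleast_1d(axes)[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(args.outdir / "halo_fits.png", dpi=120)

    for key, val in payload.items():
        if key == "baseline_mm":
            print(f"non-motile baseline: {val:.2f} mm")
        else:
            print(f"{key}: {val['model']}")
    print(f"wrote {args.outdir}/halo_fits.json, halo_predictions.csv, halo_fits.png")


if __name__ == "__main__":
    main()
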