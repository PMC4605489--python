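"""Pairwise-Fst ordination of the panel with bootstrap confidence clouds.

Computes the pairwise Fst matrix over all series (globally pooled
within-group covariance), embeds it with Kruskal non-metric MDS, repeats
with 100 within-series bootstraps, and Procrustes-superimposes the
replicate configurations onto the original.  An overview plot goes to
scratch/ (the CSV twins under results/ are the machine-readable record).

Usage: python analysis/06_ordination.py [--seed 1] [--boot 100]
"""

import argparse
import json
from pathlib import Path

from phenostruct import read_table
from phenostruct.pipeline import RunConfig, plot_mds, run_mds_figure


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--boot", type=int, default=100)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()
    outdir = Path(args.results)

    table = read_table(outdir / "synthetic_panel.csv")
    cfg = RunConfig(inputs=[], h2=0.55, seed=args.seed,
                    bootstrap_reps=args.boot, output_dir=str(outdir))
    coords, boot, original, D = run_mds_figure(cfg, table=table, outdir=outdir)

    meta = json.loads((outdir / "mds_meta.json").read_text())
    print(f"NMDS of {len(coords)} series: stress-1 = {original.stress:.4f}, "
          f"{meta['reps'] - meta['dropped']} bootstrap replicates retained")
    print(f"max pairwise Fst = {D.max():.3f}")
    print(f"coords -> {outdir / 'mds_coords.csv'}, "
          f"clouds -> {outdir / 'mds_boot.csv'}")

    scratch = Path("scratch")
    scratch.mkdir(exist_ok=True)
    plot_mds(coords, boot, scratch / "mds_panel.png")
    print(f"plot -> {scratch / 'mds_panel.png'}")


if __name__ == "__main__":
    main()
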