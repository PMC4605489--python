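"""Per-series census of the panel: n, sex counts, percent missing cells.

Reads the panel written by 01_simulate_panel.py and writes the series
summary table (the analogue of a study's sample-description table).

Usage: python analysis/02_summarize_panel.py
"""

import argparse
from pathlib import Path

from phenostruct import read_table, summarize_series
from phenostruct.io_tables import summaries_to_frame


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results")
    args = ap.parse_args()
    outdir = Path(args.results)

    table = read_table(outdir / "synthetic_panel.csv")
    df = summaries_to_frame(summarize_series(table))
    df.to_csv(outdir / "series_summary.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    total = df["missing_cells"].sum()
    print(f"\n{len(df)} series, {df['n'].sum()} individuals, "
          f"{total} missing cells; summary -> {outdir / 'series_summary.csv'}")


if __name__ == "__main__":
    main()
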