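"""End-to-end orchestration of the three analyses from one config file.

A run reads craniometric tables, imputes missing cells, Z-scores against
the pooled sample, and produces machine-readable outputs for the three
standard analyses: matched-n within-group variance distributions, the
regional Fst table, and the pairwise-Fst NMDS with bootstrap clouds.
Every stochastic step is seeded from one master seed through a documented
splitting scheme, and a manifest records enough to reproduce the outputs
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_tables import CraniometricTable, read_table, summaries_to_frame, \
    summarize_series, write_matrix_csv
from .ordination import bootstrap_mds
from .preprocess import apply_standardization, fit_standardization, impute_missing
from .rmatrix import FstConfig, estimate_fst, pairwise_fst
from .within_variance import subsample_trace_distribution, vcv_trace

logger = logging.getLogger(__name__)

# named offsets of the master-seed splitting scheme
_SEED_STREAMS = {"subsample": 1, "bootstrap": 2, "mds": 3, "simulate": 4}


def derive_seed(master: int, stream: str, index: int = 0) -> int:
    """Deterministic child seed for a named stream (stable across runs)."""
    ss = np.random.SeedSequence(master, spawn_key=(_SEED_STREAMS[stream], index))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    inputs: list[str]
    output_dir: str = "results"
    analyses: list[str] = field(default_factory=lambda: ["variance", "fst", "mds"])
    h2: float = 0.55
    weights: str = "sample_size"
    bias_correction: bool = True
    imputation_scope: str = "per_series"
    subsample_reps: int = 1000
    bootstrap_reps: int = 100
    seed: int = 0
    variance_targets: list[str] = field(default_factory=list)
    fst_groupings: dict = field(default_factory=dict)
    region_map: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def fst_config(self) -> FstConfig:
        return FstConfig(h2=self.h2, weights=self.weights,
                         bias_correction=self.bias_correction)


def concat_tables(tables: list[CraniometricTable]) -> CraniometricTable:
    if len(tables) == 1:
        return tables[0]
    vars0 = tables[0].variables
    for t in tables[1:]:
        if t.variables != vars0:
            raise ValueError("tables have different variable sets")
    return CraniometricTable(
        individual_id=np.concatenate([t.individual_id for t in tables]),
        series=np.concatenate([t.series for t in tables]),
        region=np.concatenate([t.region for t in tables]),
        sex=np.concatenate([t.sex for t in tables]),
        values=np.vstack([t.values for t in tables]),
        mask=np.vstack([t.mask for t in tables]),
        variables=vars0,
    )


def _prepare(config: RunConfig, table: CraniometricTable | None):
    if table is None:
        table = concat_tables([read_table(p) for p in config.inputs])
    if config.region_map:
        table = table.copy()
        table.region = np.array(
            [config.region_map.get(s, r) for s, r in zip(table.series, table.region)],
            dtype=object)
    imputed, records = impute_missing(table, scope=config.imputation_scope)
    model = fit_standardization(imputed)
    z, _ = apply_standardization(imputed, model)
    return table, imputed, records, model, z


def run_within_variance_panel(config: RunConfig,
                              table: CraniometricTable | None = None,
                              outdir: Path | None = None) -> dict[str, pd.DataFrame]:
    """Matched-n trace distributions for each target series.

    For each target, every reference series contributes the traces of
    ``subsample_reps`` random subsets drawn at the target's n (clamped to
    the reference's own n when smaller).
    """
    _, imputed, _, _, z = _prepare(config, table)
    series = imputed.series
    labels = imputed.series_labels()
    targets = config.variance_targets or labels
    out: dict[str, pd.DataFrame] = {}
    for ti, target in enumerate(targets):
        if target not in labels:
            raise ValueError(f"unknown target series {target!r}")
        obs = vcv_trace(z, series, target)
        rows = []
        for ri, ref in enumerate(labels):
            if ref == target:
                continue
            dist = subsample_trace_distribution(
                z, series, ref, m=obs.n, reps=config.subsample_reps,
                seed=derive_seed(config.seed, "subsample", ti * 1000 + ri))
            rows.append(pd.DataFrame({
                "reference_series": ref,
                "replicate": np.arange(dist.reps),
                "trace": dist.traces,
                "m": dist.m,
                "clamped": dist.clamped,
            }))
        df = pd.concat(rows, ignore_index=True)
        out[target] = df
        if outdir is not None:
            safe = target.replace(" ", "_")
            df.to_csv(outdir / f"variance_{safe}.csv", index=False)
            with open(outdir / f"variance_{safe}.json", "w") as fh:
                json.dump({"series": target, "observed_trace": obs.trace,
                           "n": obs.n, "reps": config.subsample_reps,
                           "seed": config.seed}, fh, indent=2)
    return out


def _grouping_members(spec, labels: list[str], regions: dict[str, str]) -> list[str]:
    """Resolve a grouping spec: explicit series list or region +/- exclusions."""
    if isinstance(spec, list):
        members = list(spec)
    else:
        spec = dict(spec)
        if "series" in spec:
            members = list(spec["series"])
        elif "region" in spec:
            wanted = spec["region"]
            members = [s for s in labels
                       if wanted == "World" or regions.get(s) == wanted]
        else:
            raise ValueError("grouping needs 'series' or 'region'")
        members = [m for m in members if m not in set(spec.get("without", []))]
    unknown = [m for m in members if m not in labels]
    if unknown:
        raise ValueError(f"unknown series in grouping: {unknown}")
    return members


def run_fst_table(config: RunConfig, table: CraniometricTable | None = None,
                  outdir: Path | None = None) -> pd.DataFrame:
    """One (grouping, Fst, SE) row per configured grouping.

    The pooled within-group covariance is recomputed from each grouping's
    own series (regional scope), matching the per-region estimates.
    """
    _, imputed, _, _, _ = _prepare(config, table)
    labels = imputed.series_labels()
    regions = {s: imputed.region[imputed.series == s][0] for s in labels}
    groupings = config.fst_groupings or {"World": {"region": "World"}}
    rows = []
    for name, spec in groupings.items():
        members = _grouping_members(spec, labels, regions)
        if len(members) < 2:
            logger.warning("grouping %r has < 2 series; skipped", name)
            continue
        groups = {s: imputed.series_values(s) for s in members}
        res = estimate_fst(groups, config=config.fst_config())
        rows.append({"grouping": name, "n_series": len(members),
                     "n_individuals": int(sum(len(g) for g in groups.values())),
                     "fst": res.fst, "se": res.se})
    df = pd.DataFrame(rows)
    if outdir is not None:
        df.to_csv(outdir / "fst_table.csv", index=False)
    return df


def run_mds_figure(config: RunConfig, table: CraniometricTable | None = None,
                   outdir: Path | None = None):
    """Pairwise-Fst NMDS with bootstrap clouds; returns (coords, boot) frames."""
    _, imputed, _, _, _ = _prepare(config, table)
    labels = imputed.series_labels()
    if len(labels) < 3:
        raise ValueError("ordination needs at least 3 series")
    groups = {s: imputed.series_values(s) for s in labels}
    regions = {s: imputed.region[imputed.series == s][0] for s in labels}
    fst_cfg = config.fst_config()
    D, _ = pairwise_fst(groups, config=fst_cfg)
    original, reps, dropped = bootstrap_mds(
        groups, reps=config.bootstrap_reps,
        seed=derive_seed(config.seed, "bootstrap"), fst_config=fst_cfg)
    coords = pd.DataFrame({
        "series": labels,
        "region": [regions[s] for s in labels],
        "x": original.coords[:, 0], "y": original.coords[:, 1],
    })
    boot_rows = []
    for b, rep in enumerate(reps):
        for i, s in enumerate(labels):
            boot_rows.append({"replicate": b, "series": s,
                              "region": regions[s],
                              "x": rep.coords[i, 0], "y": rep.coords[i, 1]})
    boot = pd.DataFrame(boot_rows)
    if outdir is not None:
        write_matrix_csv(D, labels, outdir / "pairwise_fst.csv")
        coords.to_csv(outdir / "mds_coords.csv", index=False)
        boot.to_csv(outdir / "mds_boot.csv", index=False)
        with open(outdir / "mds_meta.json", "w") as fh:
            json.dump({"stress": original.stress, "dropped": dropped,
                       "reps": config.bootstrap_reps}, fh, indent=2)
    return coords, boot, original, D


def run(config: RunConfig, table: CraniometricTable | None = None) -> Path:
    """Execute every configured analysis and write a reproducibility manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, imputed, records, model, z = _prepare(config, table)
    summaries_to_frame(summarize_series(table)).to_csv(
        outdir / "series_summary.csv", index=False)
    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        outdir / "imputation_records.csv", index=False)
    if "variance" in config.analyses:
        run_within_variance_panel(config, table, outdir)
    if "fst" in config.analyses:
        run_fst_table(config, table, outdir)
    if "mds" in config.analyses:
        run_mds_figure(config, table, outdir)
    cfg_dict = {k: v for k, v in config.__dict__.items()}
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"package": "phenostruct", "version": __version__,
                   "inputs": list(config.inputs), "seed": config.seed,
                   "config": cfg_dict, "config_sha256": cfg_hash},
                  fh, indent=2, default=str)
    return outdir


def plot_variance_panel(df: pd.DataFrame, observed: float, path) -> None:
    """Histogram grid of trace distributions, dashed line at the observed trace."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    refs = df["reference_series"].unique()
    ncol = 4
    nrow = int(np.ceil(len(refs) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow),
                             squeeze=False)
    for ax, ref in zip(axes.ravel(), refs):
        ax.hist(df.loc[df["reference_series"] == ref, "trace"],
                bins=30, color="0.6")
        ax.axvline(observed, ls="--", color="k")
        ax.set_title(ref, fontsize=8)
    for ax in axes.ravel()[len(refs):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mds(coords: pd.DataFrame, boot: pd.DataFrame, path) -> None:
    """Scatter of the ordination: solid originals, transparent bootstrap clouds."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, 6))
    regions = sorted(coords["region"].unique())
    cmap = plt.colormaps["tab10"]
    colors = {r: cmap(i % 10) for i, r in enumerate(regions)}
    if len(boot):
        ax.scatter(boot["x"], boot["y"],
                   c=[colors[r] for r in boot["region"]], s=8, alpha=0.12,
                   linewidths=0)
    ax.scatter(coords["x"], coords["y"],
               c=[colors[r] for r in coords["region"]], s=45,
               edgecolors="k", linewidths=0.5, zorder=3)
    for _, row in coords.iterrows():
        ax.annotate(row["series"], (row["x"], row["y"]), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
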