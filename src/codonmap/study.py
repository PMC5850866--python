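"""Driver for the stationary-vs-nonstationary bias study on simulated data.

For each grid cell (theta_root, theta_eq, omega) the driver simulates
replicate alignments, fits the stationary and the nonstationary template,
runs stochastic mapping under each fit, and tabulates omega-hat, dN, dS
and dN/dS per template. The stationary/nonstationary ratio columns
summarize the bias induced by wrongly assuming compositional stationarity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import ModelTemplate, fit_ml
from .mapping import aggregate_dnds, map_tree
from .phylo import RootedTree
from .simulate import gc_drift_scene, mammalian_fixture_tree, simulate


def _derive_seeds(master_seed: int, n: int) -> list:
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_replicate(
    sim_scene,
    templates=("stationary-homogeneous", "nonstationary-homogeneous"),
    scheme: str = "F1X4",
    n_starts: int = 1,
    do_mapping: bool = True,
    fit_seed: int = 0,
):
    """Simulate one alignment and fit/map each requested template.

    Returns {template: {"omega": ..., "loglik": ..., "dN": ..., "dS": ...,
    "ratio": ...}} for the replicate.
    """
    rec = simulate(sim_scene)
    tree = sim_scene.scene.tree
    out = {}
    for kind in templates:
        fit = fit_ml(
            rec.alignment,
            tree,
            ModelTemplate(kind, scheme=scheme),
            n_starts=n_starts,
            seed=fit_seed,
        )
        row = {"omega": fit.omega, "loglik": fit.log_likelihood}
        if do_mapping:
            results = map_tree(fit.scene(), rec.alignment)
            agg = aggregate_dnds(results)
            row.update(dN=agg.dN, dS=agg.dS, ratio=agg.ratio)
        out[kind] = row
    return out


def run_cell(
    theta_root: float,
    theta_eq: float,
    omega: float,
    replicates: int = 10,
    n_codons: int = 1000,
    tree: RootedTree | None = None,
    seed: int = 0,
    templates=("stationary-homogeneous", "nonstationary-homogeneous"),
    scheme: str = "F1X4",
    n_starts: int = 1,
    do_mapping: bool = True,
    heterogeneous: bool = False,
) -> pd.DataFrame:
    """All replicates of one grid cell; one row per replicate and template."""
    tree = tree if tree is not None else mammalian_fixture_tree()
    seeds = _derive_seeds(seed, replicates)
    rows = []
    for rep, s in enumerate(seeds):
        sim = gc_drift_scene(
            theta_root,
            theta_eq,
            omega,
            tree=tree,
            n_codons=n_codons,
            seed=s,
            heterogeneous=heterogeneous,
        )
        res = run_replicate(
            sim,
            templates=templates,
            scheme=scheme,
            n_starts=n_starts,
            do_mapping=do_mapping,
            fit_seed=s,
        )
        for kind, row in res.items():
            rows.append(
                {
                    "theta_root": theta_root,
                    "theta_eq": theta_eq,
                    "omega_true": omega,
                    "replicate": rep,
                    "template": kind,
                    **row,
                }
            )
    return pd.DataFrame(rows)


def summarize_cells(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd per (cell, template) plus stationary/nonstationary ratio
    columns for omega-hat, dN, dS and dN/dS."""
    keys = ["theta_root", "theta_eq", "omega_true"]
    value_cols = [c for c in ("omega", "dN", "dS", "ratio") if c in df.columns]
    summary = (
        df.groupby(keys + ["template"])[value_cols]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = [
        c[0] if not c[1] else f"{c[0]}_{c[1]}" for c in summary.columns
    ]
    wide = summary.pivot(index=keys, columns="template")
    ratios = {}
    stat, nonstat = "stationary-homogeneous", "nonstationary-homogeneous"
    for v in value_cols:
        col = f"{v}_mean"
        if (col, stat) in wide.columns and (col, nonstat) in wide.columns:
            ratios[f"{v}_stat_over_nonstat"] = wide[(col, stat)] / wide[(col, nonstat)]
    out = summary
    if ratios:
        rt = pd.DataFrame(ratios).reset_index()
        out = summary.merge(rt, on=keys, how="left")
    return out


def bias_study(
    theta_root_values=(0.2, 0.8),
    theta_eq_values=(0.2, 0.8),
    omega_values=(0.1,),
    replicates: int = 5,
    n_codons: int = 500,
    tree: RootedTree | None = None,
    seed: int = 0,
    scheme: str = "F1X4",
    n_starts: int = 1,
    do_mapping: bool = True,
    heterogeneous: bool = False,
    progress=None,
):
    """Run the full grid; returns (per-replicate DataFrame, per-cell summary).

    The full study grid (9 x 9 theta values, four omega settings, 100
    replicates of 3000 codons) is reachable through the arguments; the
    defaults run a small corner of it suitable for a desk check.
    """
    frames = []
    cell_seeds = _derive_seeds(
        seed, len(theta_root_values) * len(theta_eq_values) * len(omega_values)
    )
    k = 0
    for tr in theta_root_values:
        for te in theta_eq_values:
            for om in omega_values:
                if progress:
                    progress(f"cell theta_root={tr} theta_eq={te} omega={om}")
                frames.append(
                    run_cell(
                        tr,
                        te,
                        om,
                        replicates=replicates,
                        n_codons=n_codons,
                        tree=tree,
                        seed=cell_seeds[k],
                        scheme=scheme,
                        n_starts=n_starts,
                        do_mapping=do_mapping,
                        heterogeneous=heterogeneous,
                    )
                )
                k += 1
    df = pd.concat(frames, ignore_index=True)
    return df, summarize_cells(df)
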