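"""Read counts as a proxy for species abundance.

Amplicon read counts are not absolute abundances — amplification bias,
body size and primer affinity distort them — but within a site the
*proportion* of reads per species tracks the proportion of individuals.
This module quantifies that relationship (rank correlations, OLS fits)
and the concordance of counts across replicate runs and across genes.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def proportions(counts: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-site proportions of individuals and of reads per species.

    One row per detection opportunity (species with ≥1 individual at the
    site); zero-read species are retained with ``prop_reads = 0``. Reads
    from species not collected at the site (unexpected hits) are excluded
    from the site's read denominator. Sites with zero individuals are
    dropped with a warning.
    """
    reads = counts.groupby(["site", "species"], as_index=False)["reads"].sum()
    present = truth[truth["n_individuals"] >= 1]
    rows = []
    for site, grp in present.groupby("site"):
        n_tot = grp["n_individuals"].sum()
        if n_tot == 0:
            warnings.warn(f"site {site}: zero individuals, excluded")
            continue
        site_reads = reads[reads["site"] == site].set_index("species")["reads"]
        r_tot = sum(site_reads.get(sp, 0) for sp in grp["species"])
        for _, row in grp.iterrows():
            r = int(site_reads.get(row["species"], 0))
            rows.append(
                {
                    "site": site,
                    "species": row["species"],
                    "n_individuals": int(row["n_individuals"]),
                    "reads": r,
                    "prop_individuals": row["n_individuals"] / n_tot,
                    "prop_reads": r / r_tot if r_tot else 0.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["site", "species", "n_individuals", "reads", "prop_individuals", "prop_reads"],
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with midrank ties.

    Raises ValueError on length mismatch or n < 3; a zero-variance rank
    vector yields NaN with a warning (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: Spearman correlation undefined")
        return float("nan")
    r, _ = stats.spearmanr(x, y)
    return float(r)


def fit_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant x: regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def concordance(counts: pd.DataFrame, axis: str = "run") -> dict[tuple[str, str], float]:
    """Spearman correlation of per-species read totals between levels of an axis.

    ``axis`` is 'run' or 'gene'. Species totals are computed over all
    other axes; each pair of levels yields one correlation.
    """
    if axis not in counts.columns:
        raise ValueError(f"counts table has no {axis!r} axis")
    levels = sorted(counts[axis].dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"need at least 2 levels of {axis!r}, got {levels}")
    pivot = (
        counts.groupby(["species", axis])["reads"].sum().unstack(axis, fill_value=0)
    )
    out = {}
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            out[(a, b)] = spearman(pivot[a].to_numpy(), pivot[b].to_numpy())
    return out


def abundance_table(counts: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Proportions plus per-gene read columns when a gene axis is present."""
    table = proportions(counts, truth)
    if "gene" in counts.columns:
        per_gene = (
            counts.groupby(["site", "species", "gene"])["reads"].sum().unstack("gene", fill_value=0)
        )
        per_gene.columns = [f"reads_{g}" for g in per_gene.columns]
        table = table.merge(per_gene.reset_index(), on=["site", "species"], how="left")
        for c in table.columns:
            if c.startswith("reads_"):
                table[c] = table[c].fillna(0).astype(int)
    return table


def plot_abundance(table: pd.DataFrame, path, proportional: bool = True) -> None:
    """Scatter of read share vs individual share per site, with OLS fit."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if proportional:
        x, y = table["prop_individuals"], table["prop_reads"]
        labels = ("proportion of individuals", "proportion of reads")
    else:
        x, y = table["n_individuals"], table["reads"]
        labels = ("individuals", "reads")
    slope, intercept, r2 = fit_r2(x, y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, alpha=0.7)
    xs = np.linspace(float(np.min(x)), float(np.max(x)), 50)
    ax.plot(xs, slope * xs + intercept, color="firebrick", lw=1.2, label=f"$R^2$ = {r2:.3f}")
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
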