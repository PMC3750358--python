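"""Species presence calls, read-count thresholds, and detection audits.

Turns per-(species, site, gene, direction, run) accepted-read counts into
presence/absence calls, compares them against the known community (the
individual identifications), and audits the failure modes that matter in
bulk-sample metabarcoding: species-site occurrences missed below a read
threshold, and "unexpected hits" — reads assigned to a species at a site
where no individual of it was collected (the footprint of mis-tagging or
misassignment).

Thresholds are strict: a species is called present when its combined
reads are *greater than* ``min_reads``. "Missed species" counts
species-site occurrences, not species identities.

The module ships a bundled field-survey dataset: 46 chironomid species
over ten urban wetland/stream sites, with the number of individuals
morphologically/molecularly identified per species per site and the
total pooled-amplicon reads assigned to each.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

AXES = ("gene", "direction", "run")


def load_field_survey() -> pd.DataFrame:
    """The bundled ten-site chironomid survey.

    Columns: species, subfamily, site, n_individuals, reads_total. A row
    exists wherever individuals were collected and/or reads were
    assigned; ``n_individuals == 0`` rows are unexpected hits.
    """
    path = resources.files("bulkbarcode").joinpath("data/field_survey.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def survey_counts_and_truth(survey: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the survey into a counts table and a truth table.

    The bundled survey carries combined read totals only, so the counts
    table has single 'all'/'both' levels on the gene/direction/run axes.
    """
    if survey is None:
        survey = load_field_survey()
    counts = survey.rename(columns={"reads_total": "reads"})[["species", "site", "reads"]].copy()
    counts["gene"] = "all"
    counts["direction"] = "both"
    counts["run"] = "all"
    truth = survey[["species", "site", "n_individuals"]].copy()
    return counts, truth


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    required = {"species", "site", "reads"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if (counts["reads"] < 0).any():
        raise ValueError("read counts must be >= 0")
    return counts


def _scope_filter(counts: pd.DataFrame, scope: Mapping[str, object] | None) -> pd.DataFrame:
    """Restrict a counts table to a scope, e.g. {'gene': 'COI', 'run': ['run1']}."""
    df = counts
    if scope:
        for axis, values in scope.items():
            if axis not in df.columns:
                raise ValueError(f"scope axis {axis!r} not in counts table")
            if isinstance(values, str):
                values = [values]
            df = df[df[axis].isin(values)]
    return df


def combined_reads(counts: pd.DataFrame, scope: Mapping[str, object] | None = None) -> pd.DataFrame:
    """Reads summed over the scoped axes → one row per (site, species)."""
    df = _scope_filter(_validate_counts(counts), scope)
    return df.groupby(["site", "species"], as_index=False)["reads"].sum()


def opportunities(truth: pd.DataFrame) -> int:
    """Number of (species, site) cells where ≥1 individual was collected —
    the chances the sequencing pipeline had to detect a species at a site."""
    return int((truth["n_individuals"] >= 1).sum())


def detect(
    counts: pd.DataFrame,
    min_reads: int = 0,
    scope: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Presence calls per (site, species): present iff reads > min_reads."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    df = combined_reads(counts, scope)
    df["present"] = df["reads"] > min_reads
    return df


def _pct(detected: int, total: int) -> float:
    """Percentage rounded half-up to 2 decimals (96.2616… → 96.26)."""
    if total == 0:
        return float("nan")
    return float(
        (Decimal(100 * detected) / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def success_percent(detected: int, missed: int) -> float:
    """Detection success % from detected/missed occurrence counts."""
    return _pct(detected, detected + missed)


def success_report(
    counts: pd.DataFrame,
    truth: pd.DataFrame,
    scopes: Mapping[str, Mapping[str, object] | None] | None = None,
    min_reads: int = 0,
) -> pd.DataFrame:
    """Detected/missed/success-% per scope (gene × direction × run subset).

    An opportunity counts as detected when the summed reads within the
    scope exceed ``min_reads``. detected + missed = opportunities always.
    """
    if scopes is None:
        scopes = {"all combined": None}
    opp = truth[truth["n_individuals"] >= 1][["site", "species"]]
    rows = []
    for label, scope in scopes.items():
        calls = detect(counts, min_reads, scope)
        merged = opp.merge(calls, on=["site", "species"], how="left")
        detected = int(merged["present"].sum(skipna=True))
        missed = len(opp) - detected
        rows.append(
            {
                "scope": label,
                "detected": detected,
                "missed": missed,
                "success_pct": _pct(detected, len(opp)),
            }
        )
    return pd.DataFrame(rows, columns=["scope", "detected", "missed", "success_pct"])


def unexpected_hits(
    counts: pd.DataFrame,
    truth: pd.DataFrame,
    scope: Mapping[str, object] | None = None,
    min_reads: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Species-site cells with reads but no collected individual.

    Returns (hits, n_sites): hits has columns site, species, reads and a
    ``exceeds_threshold`` flag for hits that would survive the presence
    threshold (undetectable errors); n_sites is the number of distinct
    sites involved.
    """
    reads = combined_reads(counts, scope)
    merged = reads.merge(truth, on=["site", "species"], how="left")
    merged["n_individuals"] = merged["n_individuals"].fillna(0).astype(int)
    hits = merged[(merged["n_individuals"] == 0) & (merged["reads"] >= 1)].copy()
    hits["exceeds_threshold"] = hits["reads"] > min_reads
    hits = hits[["site", "species", "reads", "exceeds_threshold"]].reset_index(drop=True)
    return hits, int(hits["site"].nunique())


def threshold_sweep(
    counts: pd.DataFrame,
    truth: pd.DataFrame,
    thresholds: Sequence[int],
    scope: Mapping[str, object] | None = None,
) -> dict[int, pd.DataFrame]:
    """Per threshold, the (species, site) opportunities with reads ≤ threshold."""
    opp = truth[truth["n_individuals"] >= 1][["site", "species"]]
    reads = combined_reads(counts, scope)
    merged = opp.merge(reads, on=["site", "species"], how="left")
    merged["reads"] = merged["reads"].fillna(0).astype(int)
    out = {}
    for t in thresholds:
        missed = merged[merged["reads"] <= t].reset_index(drop=True)
        out[int(t)] = missed[["site", "species", "reads"]]
    return out


def survey_analytics(survey: pd.DataFrame | None = None, threshold: int = 5) -> dict[str, float | int]:
    """Headline detection analytics of a survey table (bundled one by default)."""
    if survey is None:
        survey = load_field_survey()
    counts, truth = survey_counts_and_truth(survey)
    opp = opportunities(truth)
    report = success_report(counts, truth)
    hits, n_hit_sites = unexpected_hits(counts, truth)
    sweep = threshold_sweep(counts, truth, [0, threshold])
    present = truth[truth["n_individuals"] >= 1]
    site_ind = present.groupby("site")["n_individuals"].sum()
    site_rich = present.groupby("site")["species"].nunique()
    return {
        "opportunities": opp,
        "total_individuals": int(truth["n_individuals"].sum()),
        "n_species": int(truth["species"].nunique()),
        "n_sites": int(truth["site"].nunique()),
        "site_richness_min": int(site_rich.min()),
        "site_richness_max": int(site_rich.max()),
        "site_individuals_min": int(site_ind.min()),
        "site_individuals_max": int(site_ind.max()),
        "zero_read_occurrences": len(sweep[0]),
        f"occurrences_missed_over_{threshold}": len(sweep[threshold]),
        "unexpected_hits": len(hits),
        "unexpected_hit_sites": n_hit_sites,
        "detected": int(report["detected"].iloc[0]),
        "missed": int(report["missed"].iloc[0]),
        "detection_success_pct": float(report["success_pct"].iloc[0]),
    }
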