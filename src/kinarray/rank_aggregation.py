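"""Inclusive percentile ranks and multi-pipeline rank aggregation.

Each upstream-kinase pipeline emits scores on its own scale; to combine
them, every pipeline's per-kinase scores are converted to inclusive
percentile ranks (0-100, endpoints attained, ties share the mean of
their positional percentiles) and the percentiles are averaged per
kinase.  Two combinations are reported: the unweighted average over the
pipelines that report the kinase, and the weighted average, defined as
the sum of reported percentiles divided by the *total* number of
pipelines under consideration — equivalently the unweighted mean scaled
by the fraction of pipelines reporting, which penalizes kinases missed
by some pipelines.  Display values are rounded half-to-even to integer
percent.

Adapters convert the native output of each external tool to an oriented
raw score (larger = stronger evidence): absolute median final score for
the upstream-kinase-analysis tool, the reciprocal of an FDR-scaled
statistic for the enrichment tool (tyrosine kinases only), and the
-log10 of a grand-mean FDR across three substrate databases at three
fold-change cutoffs for the kinase-enrichment web service.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "inclusive_percentile_rank",
    "round_percent",
    "adapter_uka",
    "adapter_ptmsea",
    "adapter_kea3",
    "unweighted_average",
    "weighted_average",
    "combine_pipelines",
    "aggregate_groups",
    "top_k_table",
    "load_printed_table",
]

KEA3_DATABASES = ("ChengKSIN", "PTMsigDB", "PhosDAll")
KEA3_CUTOFFS = (0.2, 0.3, 0.4)


def inclusive_percentile_rank(raw_scores: Mapping[str, float]) -> dict[str, float]:
    """Map raw scores to inclusive percentiles in [0, 100].

    For n values sorted ascending the percentile of ascending rank r is
    ``100 * (r - 1) / (n - 1)``; tied values share the mean of their
    positional percentiles; a single value ranks 100.
    """
    if not raw_scores:
        raise ValueError("need at least one score")
    keys = list(raw_scores)
    vals = np.array([raw_scores[k] for k in keys], dtype=float)
    if not np.isfinite(vals).all():
        # +inf is a legitimate top-sentinel (see the enrichment adapter);
        # NaN is not a score
        if np.isnan(vals).any():
            bad = [k for k, v in zip(keys, vals) if np.isnan(v)]
            raise ValueError(f"non-finite scores for: {bad}")
    n = len(vals)
    if n == 1:
        return {keys[0]: 100.0}
    ranks = rankdata(vals, method="average")  # mean rank for ties
    pct = 100.0 * (ranks - 1.0) / (n - 1.0)
    return dict(zip(keys, pct))


def round_percent(x: float) -> int:
    """Round a percentile to integer percent, halves to even.

    Values an epsilon away from an exact half (from accumulated float
    error in exact-half arithmetic) are snapped to the half first.
    """
    doubled = x * 2.0
    snapped = round(doubled)
    if abs(doubled - snapped) < 1e-9:
        x = snapped / 2.0
    return int(round(x))


# ---------------------------------------------------------------------------
# adapters: native tool outputs -> oriented raw scores


def adapter_uka(
    rows: pd.DataFrame,
    kinase_col: str = "kinase",
    score_col: str = "median_final_score",
) -> pd.DataFrame:
    """Orient an upstream-kinase-analysis output table.

    The raw score is the absolute value of the tool's median final
    score (its sign only encodes direction).
    """
    if score_col not in rows.columns:
        raise ValueError(f"missing score column {score_col!r}")
    return pd.DataFrame(
        {"kinase_id": rows[kinase_col].astype(str), "raw_score": rows[score_col].abs().astype(float)}
    )


def adapter_ptmsea(
    rows: pd.DataFrame,
    kinase_col: str = "kinase",
    value_col: str = "fdr.pvalue.totalGeoMeanLFC",
    tyrosine_col: str = "is_tyrosine_kinase",
    tyrosine_kinases: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Orient an enrichment-analysis output table.

    The raw score is the reciprocal of the FDR-scaled statistic named by
    ``value_col``; rows not representing protein tyrosine kinases are
    dropped (either via a boolean column or an explicit kinase list).  A
    zero statistic yields an infinite score, ranked top, with a warning.
    """
    if value_col not in rows.columns:
        raise ValueError(f"missing value column {value_col!r}")
    sub = rows
    if tyrosine_kinases is not None:
        sub = sub[sub[kinase_col].isin(set(tyrosine_kinases))]
    elif tyrosine_col in sub.columns:
        sub = sub[sub[tyrosine_col].astype(bool)]
    vals = sub[value_col].astype(float)
    if (vals == 0).any():
        warnings.warn("zero-valued statistic; affected kinases ranked top", stacklevel=2)
    with np.errstate(divide="ignore"):
        raw = np.where(vals == 0, np.inf, 1.0 / vals)
    return pd.DataFrame({"kinase_id": sub[kinase_col].astype(str), "raw_score": raw})


def adapter_kea3(
    tables: Mapping[tuple[str, float], pd.DataFrame],
    kinase_col: str = "kinase",
    fdr_col: str = "fdr",
    databases: Sequence[str] = KEA3_DATABASES,
    cutoffs: Sequence[float] = KEA3_CUTOFFS,
) -> pd.DataFrame:
    """Combine per-database FDR tables at several fold-change cutoffs.

    Per database the kinase's FDR is averaged over the cutoff lists;
    the database means are averaged again, and the raw score is
    ``-log10`` of that grand mean.  A kinase absent from a database is
    scored from the remaining databases, with a warning.
    """
    per_db: dict[str, dict[str, float]] = {}
    for db in databases:
        acc: dict[str, list[float]] = {}
        for cut in cutoffs:
            tab = tables.get((db, cut))
            if tab is None:
                raise ValueError(f"missing table for database {db!r} at cutoff {cut}")
            for kin, fdr in zip(tab[kinase_col].astype(str), tab[fdr_col].astype(float)):
                acc.setdefault(kin, []).append(fdr)
        per_db[db] = {k: float(np.mean(v)) for k, v in acc.items()}

    kinases = sorted(set().union(*(set(d) for d in per_db.values())))
    rows = []
    partial: list[str] = []
    for kin in kinases:
        means = [per_db[db][kin] for db in databases if kin in per_db[db]]
        if len(means) < len(databases):
            partial.append(kin)
        grand = float(np.mean(means))
        raw = np.inf if grand == 0 else -np.log10(grand)
        rows.append({"kinase_id": kin, "raw_score": raw})
    if partial:
        warnings.warn(
            f"{len(partial)} kinase(s) absent from some database(s); scored from the rest",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# combination


def unweighted_average(per_pipeline: Mapping[str, float | None]) -> float:
    """Mean percentile over the pipelines that report the kinase."""
    vals = [v for v in per_pipeline.values() if v is not None and not np.isnan(v)]
    if not vals:
        raise ValueError("no reporting pipeline")
    return float(np.mean(vals))


def weighted_average(per_pipeline: Mapping[str, float | None], total_pipelines: int) -> float:
    """Sum of reported percentiles divided by the total pipeline count."""
    if total_pipelines < 1:
        raise ValueError("total_pipelines must be >= 1")
    vals = [v for v in per_pipeline.values() if v is not None and not np.isnan(v)]
    if not vals:
        raise ValueError("no reporting pipeline")
    if len(vals) > total_pipelines:
        raise ValueError("more reporting pipelines than total_pipelines")
    return float(np.sum(vals) / total_pipelines)


def combine_pipelines(
    percentiles: pd.DataFrame,
    total_pipelines: int | None = None,
    families: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Aggregate a long percentile table into per-kinase rankings.

    ``percentiles`` has columns ``pipeline_id, context_id, kinase_id,
    percentile``.  Returns one row per (context, kinase) with one column
    per pipeline plus ``unweighted_avg`` and ``weighted_avg``.
    """
    needed = {"pipeline_id", "context_id", "kinase_id", "percentile"}
    if not needed <= set(percentiles.columns):
        raise ValueError(f"percentile table must have columns {sorted(needed)}")
    pipelines = sorted(percentiles["pipeline_id"].unique())
    total = total_pipelines if total_pipelines is not None else len(pipelines)
    wide = percentiles.pivot_table(
        index=["context_id", "kinase_id"], columns="pipeline_id", values="percentile"
    )
    out = wide.reset_index()
    per_pipe = wide.to_numpy()
    reported = ~np.isnan(per_pipe)
    sums = np.nansum(per_pipe, axis=1)
    counts = reported.sum(axis=1)
    out["unweighted_avg"] = sums / counts
    out["weighted_avg"] = sums / total
    if families is not None:
        out.insert(2, "family_id", out["kinase_id"].map(families))
    return out


def aggregate_groups(
    percentiles: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    total_pipelines: int | None = None,
    families: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Combine cell-line-level percentiles into group-level rankings.

    For each pipeline, a kinase's group percentile is the mean of its
    per-cell-line percentiles over the member cell lines where it is
    reported; the per-pipeline group percentiles are then combined
    exactly as for a single cell line.
    """
    frames = []
    for group_id, members in groups.items():
        if not members:
            raise ValueError(f"group {group_id!r} is empty")
        sub = percentiles[percentiles["context_id"].isin(list(members))]
        pooled = (
            sub.groupby(["pipeline_id", "kinase_id"], sort=True)["percentile"]
            .mean()
            .reset_index()
        )
        pooled["context_id"] = group_id
        frames.append(pooled)
    stacked = pd.concat(frames, ignore_index=True)
    return combine_pipelines(stacked, total_pipelines=total_pipelines, families=families)


def top_k_table(rankings: pd.DataFrame, k: int = 10, sort_key: str = "unweighted_avg") -> pd.DataFrame:
    """Top-k kinases per context, ties broken alphabetically by kinase."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if sort_key not in rankings.columns:
        raise ValueError(f"unknown sort key {sort_key!r}")
    out = []
    for context, sub in rankings.groupby("context_id", sort=True):
        ordered = sub.sort_values(
            [sort_key, "kinase_id"], ascending=[False, True], kind="mergesort"
        ).head(k)
        ordered = ordered.copy()
        ordered.insert(1, "rank", np.arange(1, len(ordered) + 1))
        out.append(ordered)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# printed-table fixtures

_TABLE_FILES = {
    1: "table1_uka_krsa_average.tsv",
    2: "table2_uka_krsa_weighted.tsv",
    3: "table3_all_pipelines_average.tsv",
    4: "table4_all_pipelines_weighted.tsv",
}

#: Which published tables carry a weighted average, and over how many pipelines.
TABLE_META = {
    1: {"weighted": False, "total_pipelines": 2},
    2: {"weighted": True, "total_pipelines": 2},
    3: {"weighted": False, "total_pipelines": 4},
    4: {"weighted": True, "total_pipelines": 4},
}


def load_printed_table(number: int) -> pd.DataFrame:
    """One of the packaged published ranking tables (1-4).

    Columns: context, rank, kinase, family, printed (the published
    average or weighted-average percent) and one integer column per
    pipeline; missing cells are NaN.
    """
    fname = _TABLE_FILES[number]
    with resources.files("kinarray.data.tables").joinpath(fname).open() as fh:
        frame = pd.read_csv(fh, sep="\t", na_values=["-"])
    return frame


def recompute_printed_table(number: int) -> pd.DataFrame:
    """Recompute each printed row's combined percentile from its per-pipeline cells.

    Returns the table with ``recomputed`` (full precision) and
    ``recomputed_pct`` (round-half-even integer percent) columns
    alongside the published ``printed`` value.
    """
    meta = TABLE_META[number]
    frame = load_printed_table(number)
    pipe_cols = [c for c in frame.columns if c not in ("context", "rank", "kinase", "family", "printed")]
    values = []
    for _, row in frame.iterrows():
        per_pipe = {c: (None if pd.isna(row[c]) else float(row[c])) for c in pipe_cols}
        if meta["weighted"]:
            values.append(weighted_average(per_pipe, meta["total_pipelines"]))
        else:
            values.append(unweighted_average(per_pipe))
    out = frame.copy()
    out["recomputed"] = values
    out["recomputed_pct"] = [round_percent(v) for v in values]
    return out
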