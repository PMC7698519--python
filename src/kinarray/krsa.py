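"""Kinome random-sampling upstream-kinase scoring.

Each kinase family is scored by comparing the number of differentially
phosphorylated peptides mapped to it ("observed hits") against a
resampling null: in each of 3000 iterations an equally sized peptide set
is drawn uniformly without replacement from the full list of chip
peptides, and the family's hit count in the draw is recorded.  The
family Z-score is the observed count standardized by the empirical null
mean and SD.  Since draws are uniform without replacement, the null hit
count of a family with k mapped peptides is hypergeometric(N, k, m),
which the empirical moments converge to; the sampling is kept explicit
because it is the procedure being modeled, and the closed form serves
as an independent check.

Directionality comes from the mean log2 fold change of the family's
differential peptides, and families are ranked by inclusive percentile
of |mean log2FC|, the family value being broadcast identically to every
member kinase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinase_mapping import KinasePeptideMap, collapse_to_families
from .rank_aggregation import inclusive_percentile_rank

__all__ = ["KRSAConfig", "observed_hits", "resample_null", "score_families", "krsa_percentiles", "run_krsa"]


@dataclass(frozen=True)
class KRSAConfig:
    """Resampling parameters.

    iterations: number of random draws forming the null (default 3000).
    seed: RNG seed; the whole stage is bit-reproducible given it.
    z_threshold: |Z| cutoff used when flagging significant families.
    include_controls: draw from all chip peptides (the default, matching
        the full 196-peptide list) or only from the filter-surviving set
        supplied by the caller.
    """

    iterations: int = 3000
    seed: int = 0
    z_threshold: float = 2.0
    include_controls: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def observed_hits(
    differential: Iterable[str], family_peptides: Mapping[str, frozenset[str]]
) -> dict[str, int]:
    """Per-family count of differential peptides among its mapped peptides."""
    diff = set(differential)
    return {fam: len(diff & peps) for fam, peps in family_peptides.items()}


def resample_null(
    m: int,
    family_peptides: Mapping[str, frozenset[str]],
    universe: Sequence[str],
    config: KRSAConfig,
) -> pd.DataFrame:
    """Empirical null moments of per-family hit counts.

    Each iteration draws ``m`` peptides uniformly without replacement
    from ``universe``; returns one row per family with the empirical
    mean and SD of its hit count over all iterations.
    """
    universe = list(universe)
    n = len(universe)
    if not 0 <= m <= n:
        raise ValueError(f"m={m} must lie in [0, {n}]")
    fams = sorted(family_peptides)
    uni_index = {p: i for i, p in enumerate(universe)}
    membership = np.zeros((n, len(fams)), dtype=np.float64)
    for j, fam in enumerate(fams):
        for pep in family_peptides[fam]:
            i = uni_index.get(pep)
            if i is not None:
                membership[i, j] = 1.0

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6B5A]))
    if m == 0:
        counts = np.zeros((config.iterations, len(fams)))
    else:
        # rank trick: the m smallest of n iid uniforms index a uniform
        # without-replacement draw of size m
        u = rng.random((config.iterations, n))
        picks = np.argpartition(u, m - 1, axis=1)[:, :m]
        counts = membership[picks].sum(axis=1)
    return pd.DataFrame(
        {
            "family_id": fams,
            "null_mean": counts.mean(axis=0),
            "null_sd": counts.std(axis=0, ddof=1) if config.iterations > 1 else 0.0,
        }
    )


def score_families(
    observed: Mapping[str, int],
    null: pd.DataFrame,
    mean_log2fc: Mapping[str, float],
    config: KRSAConfig,
) -> pd.DataFrame:
    """Z-scores and directionality per family.

    Families with a degenerate null (SD = 0) get Z = 0 when the observed
    count equals the null mean and are otherwise flagged ``degenerate``
    with an undefined Z.  A family with no differential peptide has mean
    log2FC 0 (no directional evidence).
    """
    missing = sorted(set(observed) - set(null["family_id"]))
    if missing:
        raise KeyError(f"families absent from the null: {missing}")
    rows = []
    null_idx = null.set_index("family_id")
    for fam in sorted(observed):
        obs = observed[fam]
        mu = float(null_idx.loc[fam, "null_mean"])
        sd = float(null_idx.loc[fam, "null_sd"])
        degenerate = False
        if sd > 0:
            z = (obs - mu) / sd
        elif obs == mu:
            z = 0.0
        else:
            z = float("nan")
            degenerate = True
        lfc = float(mean_log2fc.get(fam, 0.0))
        rows.append(
            {
                "family_id": fam,
                "observed_hits": obs,
                "null_mean": mu,
                "null_sd": sd,
                "z_score": z,
                "mean_log2fc": lfc,
                "direction": "increased" if lfc > 0 else "decreased",
                "significant": (sd > 0 or not degenerate) and abs(z) >= config.z_threshold,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def krsa_percentiles(results: pd.DataFrame) -> pd.DataFrame:
    """Attach inclusive percentile ranks computed from |mean log2FC|."""
    scores = dict(zip(results["family_id"], results["mean_log2fc"].abs()))
    pct = inclusive_percentile_rank(scores)
    out = results.copy()
    out["percentile"] = out["family_id"].map(pct)
    return out


def family_mean_log2fc(
    differential: Iterable[str],
    log2fc: Mapping[str, float],
    family_peptides: Mapping[str, frozenset[str]],
) -> dict[str, float]:
    """Arithmetic mean log2FC over each family's differential peptides."""
    diff = set(differential)
    out: dict[str, float] = {}
    for fam, peps in family_peptides.items():
        hits = sorted(diff & peps)
        out[fam] = float(np.mean([log2fc[p] for p in hits])) if hits else 0.0
    return out


def run_krsa(
    differential: Iterable[str],
    log2fc: Mapping[str, float],
    kmap: KinasePeptideMap,
    universe: Sequence[str],
    config: KRSAConfig | None = None,
) -> pd.DataFrame:
    """Full family-level scoring of one comparison.

    ``universe`` is the peptide list the null draws from (by default the
    caller passes the full chip catalog, internal controls included).
    """
    config = config or KRSAConfig()
    family_peptides = collapse_to_families(kmap)
    diff = set(differential)
    stray = diff - set(universe)
    if stray:
        raise ValueError(f"differential peptides outside the universe: {sorted(stray)[:5]}")
    obs = observed_hits(diff, family_peptides)
    null = resample_null(len(diff), family_peptides, universe, config)
    lfc = family_mean_log2fc(diff, log2fc, family_peptides)
    return krsa_percentiles(score_families(obs, null, lfc, config))


def broadcast_to_kinases(results: pd.DataFrame, kmap: KinasePeptideMap) -> pd.DataFrame:
    """Per-kinase view: every member kinase inherits its family's scores."""
    fam_col = results.set_index("family_id")
    rows = []
    for kinase, fam in sorted(kmap.families.items()):
        if fam not in fam_col.index:
            continue
        rec = fam_col.loc[fam]
        rows.append(
            {
                "kinase_id": kinase,
                "family_id": fam,
                "z_score": rec["z_score"],
                "mean_log2fc": rec["mean_log2fc"],
                "direction": rec["direction"],
                "percentile": rec["percentile"],
            }
        )
    return pd.DataFrame(rows)
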