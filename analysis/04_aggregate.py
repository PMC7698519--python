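"""Combine four pipelines into per-context and per-group kinase rankings.

The resampling-based family scores come from 03_krsa.py; the other three
pipelines are emulated by the synthetic score generator and converted to
oriented raw scores through their adapters.  All four are mapped to
inclusive percentiles and averaged (unweighted and weighted).
"""

import argparse
from pathlib import Path

import pandas as pd

from kinarray.kinase_mapping import KinasePeptideMap
from kinarray.krsa import broadcast_to_kinases
from kinarray.pipeline import load_config
from kinarray.rank_aggregation import (
    adapter_kea3,
    adapter_ptmsea,
    adapter_uka,
    aggregate_groups,
    combine_pipelines,
    inclusive_percentile_rank,
    round_percent,
    top_k_table,
)
from kinarray.synthetic_data import SyntheticTruth, simulate_pipeline_scores

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--config", default=ROOT / "configs/demo.yaml")
    parser.add_argument("--dir", default=ROOT / "results/analysis")
    args = parser.parse_args()

    config = load_config(args.config)
    base = Path(args.dir)
    kmap = KinasePeptideMap.read_tsv(base / "kinase_map.tsv")

    rows = []
    for i, (context, spiked) in enumerate(sorted(config.contexts.items())):
        krsa_results = pd.read_csv(base / context / "krsa.tsv", sep="\t")
        per_kinase = broadcast_to_kinases(krsa_results, kmap)
        rows.append(pd.DataFrame({
            "pipeline_id": "KRSA", "context_id": context,
            "kinase_id": per_kinase["kinase_id"], "percentile": per_kinase["percentile"],
        }))
        truth = SyntheticTruth(spiked_kinases=tuple(spiked), seed=config.seed * 1000 + i)
        tool = simulate_pipeline_scores(kmap, truth, seed=truth.seed)
        for pipe, scores in (
            ("UKA", adapter_uka(tool["uka"])),
            ("PTMSEA", adapter_ptmsea(tool["ptmsea"])),
            ("KEA3", adapter_kea3(tool["kea3"])),
        ):
            pct = inclusive_percentile_rank(dict(zip(scores["kinase_id"], scores["raw_score"])))
            rows.append(pd.DataFrame({
                "pipeline_id": pipe, "context_id": context,
                "kinase_id": list(pct), "percentile": list(pct.values()),
            }))

    percentiles = pd.concat(rows, ignore_index=True)
    percentiles.to_csv(base / "percentiles.tsv", sep="\t", index=False)
    families = dict(kmap.families)
    rankings = combine_pipelines(percentiles, config.total_pipelines, families=families)
    grouped = aggregate_groups(percentiles, config.groups, config.total_pipelines, families)
    all_ranks = pd.concat([rankings, grouped], ignore_index=True)
    all_ranks.to_csv(base / "rankings.tsv", sep="\t", index=False)
    top = top_k_table(all_ranks, k=config.top_k)
    top.to_csv(base / "top_kinases.tsv", sep="\t", index=False)

    for context, sub in top.groupby("context_id", sort=True):
        lead = sub.iloc[0]
        print(f"{context}: top kinase {lead['kinase_id']} ({lead['family_id']}), "
              f"average {round_percent(lead['unweighted_avg'])}%, "
              f"weighted {round_percent(lead['weighted_avg'])}%")


if __name__ == "__main__":
    main()
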