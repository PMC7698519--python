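"""Score kinase families against the random-sampling null for every
simulated comparison and report the top-scoring families.

Reads the fold-change tables written by 02_preprocess.py and writes a
family-level result table per context.
"""

import argparse
from pathlib import Path

import pandas as pd

from kinarray.kinase_mapping import KinasePeptideMap
from kinarray.krsa import KRSAConfig, run_krsa
from kinarray.pipeline import load_config
from kinarray.synthetic_data import generate_catalog

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--config", default=ROOT / "configs/demo.yaml")
    parser.add_argument("--dir", default=ROOT / "results/analysis")
    args = parser.parse_args()

    config = load_config(args.config)
    catalog = generate_catalog(seed=config.seed)
    base = Path(args.dir)
    kmap = KinasePeptideMap.read_tsv(base / "kinase_map.tsv")
    for i, context in enumerate(sorted(config.contexts)):
        peptides = pd.read_csv(base / context / "peptides.tsv", sep="\t")
        differential = set(peptides.loc[peptides["is_differential"], "peptide_id"])
        log2fc = dict(zip(peptides["peptide_id"], peptides["log2fc"]))
        results = run_krsa(
            differential, log2fc, kmap, catalog.peptide_ids,
            KRSAConfig(iterations=config.iterations, seed=config.seed * 1000 + i,
                       z_threshold=config.z_threshold),
        )
        results.to_csv(base / context / "krsa.tsv", sep="\t", index=False)
        top = results.nlargest(3, "z_score")
        summary = ", ".join(
            f"{r.family_id} (Z={r.z_score:.1f}, {r.direction})" for r in top.itertuples()
        )
        print(f"{context}: m={len(differential)} differential peptides; top families: {summary}")


if __name__ == "__main__":
    main()
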