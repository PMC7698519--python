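"""Fit exposure slopes, apply the R²/detectability filter, and call
differential fold changes for every simulated comparison.

Reads the run tables written by 01_simulate.py and writes a per-peptide
fold-change table per context.
"""

import argparse
from pathlib import Path

from kinarray.pipeline import load_config
from kinarray.signal_processing import preprocess_run
from kinarray.synthetic_data import generate_catalog, read_run

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--config", default=ROOT / "configs/demo.yaml")
    parser.add_argument("--dir", default=ROOT / "results/analysis")
    parser.add_argument("--raw-dir", default=ROOT / "scratch/runs")
    args = parser.parse_args()

    config = load_config(args.config)
    catalog = generate_catalog(seed=config.seed)
    base = Path(args.dir)
    for context in sorted(config.contexts):
        frame = read_run(Path(args.raw_dir) / context / "run.tsv")
        (base / context).mkdir(parents=True, exist_ok=True)
        pre = preprocess_run(
            frame,
            r2_min=config.r2_min,
            fc_up=config.fc_up,
            fc_down=config.fc_down,
            control_ids=catalog.control_ids,
        )
        pre.fold_changes.to_csv(base / context / "peptides.tsv", sep="\t", index=False)
        print(f"{context}: {len(pre.retained)} peptides retained "
              f"(R² >= {config.r2_min}, detectable), "
              f"{len(pre.differential)} differential (FC >= {config.fc_up} or <= {config.fc_down})")


if __name__ == "__main__":
    main()
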