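"""End-to-end pipeline driver: simulate -> preprocess -> score -> aggregate.

The driver wires the library stages together for a configured set of
case-vs-control comparisons ("contexts", i.e. cell lines), producing
per-context and per-group ranking tables plus a manifest recording the
seed and SHA-256 digests of every output, so a rerun with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .kinase_mapping import KinasePeptideMap
from .krsa import KRSAConfig, broadcast_to_kinases, run_krsa
from .rank_aggregation import (
    adapter_kea3,
    adapter_ptmsea,
    adapter_uka,
    aggregate_groups,
    combine_pipelines,
    inclusive_percentile_rank,
    top_k_table,
)
from .signal_processing import preprocess_run
from .synthetic_data import (
    SyntheticTruth,
    generate_catalog,
    generate_map,
    simulate_pipeline_scores,
    simulate_run,
)

log = logging.getLogger("kinarray")

__all__ = ["PipelineConfig", "run_pipeline", "validate_table", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of one end-to-end run."""

    contexts: Mapping[str, Sequence[tuple[str, float]]]  # context -> spiked (kinase, log2fc)
    groups: Mapping[str, Sequence[str]] = field(default_factory=dict)
    r2_min: float = 0.90
    fc_up: float = 1.30
    fc_down: float = 0.70
    intensity_floor: float = 0.0
    iterations: int = 3000
    z_threshold: float = 2.0
    total_pipelines: int = 4
    top_k: int = 10
    n_kinases: int = 60
    noise_sd: float = 10.0
    nonlinear_fraction: float = 0.10
    undetectable_fraction: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.fc_up > 1.0 > self.fc_down > 0.0):
            raise ValueError("thresholds must satisfy fc_up > 1 > fc_down > 0")
        if not 0.0 <= self.r2_min <= 1.0:
            raise ValueError("r2_min must lie in [0, 1]")
        if self.total_pipelines < 1 or self.top_k < 1 or self.iterations < 1:
            raise ValueError("counts must be >= 1")
        if not self.contexts:
            raise ValueError("at least one context is required")
        for group, members in self.groups.items():
            unknown = set(members) - set(self.contexts)
            if unknown:
                raise ValueError(f"group {group!r} references unknown contexts: {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    thresholds = raw.get("thresholds", {})
    krsa = raw.get("krsa", {})
    agg = raw.get("aggregation", {})
    sim = raw.get("simulate", {})
    contexts = {
        name: [(str(k), float(e)) for k, e in spec.get("spiked", [])]
        for name, spec in sim.get("contexts", {}).items()
    }
    return PipelineConfig(
        contexts=contexts,
        groups={g: list(m) for g, m in agg.get("groups", {}).items()},
        r2_min=float(thresholds.get("r2_min", 0.90)),
        fc_up=float(thresholds.get("fc_up", 1.30)),
        fc_down=float(thresholds.get("fc_down", 0.70)),
        intensity_floor=float(thresholds.get("intensity_floor", 0.0)),
        iterations=int(krsa.get("iterations", 3000)),
        z_threshold=float(krsa.get("z_threshold", 2.0)),
        total_pipelines=int(agg.get("total_pipelines", 4)),
        top_k=int(agg.get("top_k", 10)),
        n_kinases=int(sim.get("n_kinases", 60)),
        noise_sd=float(sim.get("noise_sd", 10.0)),
        nonlinear_fraction=float(sim.get("nonlinear_fraction", 0.10)),
        undetectable_fraction=float(sim.get("undetectable_fraction", 0.05)),
        n_replicates=int(sim.get("n_replicates", 3)),
        seed=int(raw.get("seed", 0)),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    catalog = generate_catalog(seed=config.seed)
    kmap = generate_map(catalog, n_kinases=config.n_kinases, seed=config.seed)
    kmap.write_tsv(out / "kinase_map.tsv")

    percentile_rows: list[pd.DataFrame] = []
    for ctx_index, (context, spiked) in enumerate(sorted(config.contexts.items())):
        truth = SyntheticTruth(
            spiked_kinases=tuple(spiked),
            noise_sd=config.noise_sd,
            nonlinear_fraction=config.nonlinear_fraction,
            undetectable_fraction=config.undetectable_fraction,
            seed=config.seed * 1000 + ctx_index,
        )
        run = simulate_run(catalog, kmap, truth, n_replicates=config.n_replicates)
        ctx_dir = out / context
        run.write(ctx_dir)

        pre = preprocess_run(
            run.frame,
            r2_min=config.r2_min,
            fc_up=config.fc_up,
            fc_down=config.fc_down,
            intensity_floor=config.intensity_floor,
            control_ids=catalog.control_ids,
        )
        pre.fold_changes.to_csv(ctx_dir / "peptides.tsv", sep="\t", index=False)
        log.info(
            "%s: %d retained, %d differential of %d peptides",
            context, len(pre.retained), len(pre.differential), len(catalog),
        )

        krsa_cfg = KRSAConfig(
            iterations=config.iterations,
            seed=config.seed * 1000 + ctx_index,
            z_threshold=config.z_threshold,
        )
        results = run_krsa(pre.differential, pre.log2fc, kmap, catalog.peptide_ids, krsa_cfg)
        results.to_csv(ctx_dir / "krsa.tsv", sep="\t", index=False)
        per_kinase = broadcast_to_kinases(results, kmap)

        tool_tables = simulate_pipeline_scores(kmap, truth, seed=truth.seed)
        adapted = {
            "UKA": adapter_uka(tool_tables["uka"]),
            "PTMSEA": adapter_ptmsea(tool_tables["ptmsea"]),
            "KEA3": adapter_kea3(tool_tables["kea3"]),
        }
        frames = [
            pd.DataFrame(
                {
                    "pipeline_id": "KRSA",
                    "context_id": context,
                    "kinase_id": per_kinase["kinase_id"],
                    "percentile": per_kinase["percentile"],
                }
            )
        ]
        for pipe, scores in adapted.items():
            pct = inclusive_percentile_rank(dict(zip(scores["kinase_id"], scores["raw_score"])))
            frames.append(
                pd.DataFrame(
                    {
                        "pipeline_id": pipe,
                        "context_id": context,
                        "kinase_id": list(pct),
                        "percentile": list(pct.values()),
                    }
                )
            )
        percentile_rows.append(pd.concat(frames, ignore_index=True))

    percentiles = pd.concat(percentile_rows, ignore_index=True)
    percentiles.to_csv(out / "percentiles.tsv", sep="\t", index=False)

    families = dict(kmap.families)
    rankings = combine_pipelines(percentiles, config.total_pipelines, families=families)
    rankings.to_csv(out / "rankings_contexts.tsv", sep="\t", index=False)
    tables = [top_k_table(rankings, k=config.top_k)]
    if config.groups:
        grouped = aggregate_groups(percentiles, config.groups, config.total_pipelines, families)
        grouped.to_csv(out / "rankings_groups.tsv", sep="\t", index=False)
        tables.append(top_k_table(grouped, k=config.top_k))
    top = pd.concat(tables, ignore_index=True)
    top.to_csv(out / "top_kinases.tsv", sep="\t", index=False)

    outputs = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_contexts": len(config.contexts),
        "groups": {g: list(m) for g, m in config.groups.items()},
        "digests": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# lightweight tabular validation

_SCHEMAS = {
    "run": ("sample_id", "condition", "replicate", "peptide_id", "exposure_ms", "intensity"),
    "mapping_records": ("source", "kinase_id", "peptide_id"),
    "kinase_map": ("kinase_id", "family_id", "peptide_id", "sources"),
    "scores": ("pipeline_id", "context_id", "kinase_id", "percentile"),
}


def validate_table(path: str | Path, schema_id: str) -> list[str]:
    """Diagnose a TSV against a named schema; returns human-readable findings.

    Never mutates the input; an empty list means the table is well-formed.
    """
    if schema_id not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema_id!r}; known: {sorted(_SCHEMAS)}")
    frame = pd.read_csv(path, sep="\t")
    diags: list[str] = []
    missing = [c for c in _SCHEMAS[schema_id] if c not in frame.columns]
    if missing:
        diags.append(f"missing columns: {missing}")
        return diags
    if schema_id == "run":
        bad = frame.index[frame["exposure_ms"] <= 0]
        diags.extend(f"row {i}: non-positive exposure" for i in bad[:10])
        nonfinite = frame.index[~pd.to_numeric(frame["intensity"], errors="coerce").notna()]
        diags.extend(f"row {i}: non-numeric intensity" for i in nonfinite[:10])
    elif schema_id == "mapping_records":
        gps = frame[frame["source"] == "GPS"]
        if "prediction_threshold" not in frame.columns:
            if not gps.empty:
                diags.append("GPS records present but no prediction_threshold column")
        else:
            bad = gps.index[gps["prediction_threshold"].isna()]
            diags.extend(f"row {i}: GPS record missing prediction_threshold" for i in bad[:10])
    elif schema_id == "kinase_map":
        bad = frame.index[frame["family_id"].isna()]
        diags.extend(f"row {i}: kinase without family (orphan)" for i in bad[:10])
        fam_per_kin = frame.groupby("kinase_id")["family_id"].nunique()
        for kin in fam_per_kin.index[fam_per_kin > 1]:
            diags.append(f"kinase {kin}: multiple family assignments")
    elif schema_id == "scores":
        vals = pd.to_numeric(frame["percentile"], errors="coerce")
        bad = frame.index[vals.isna() | (vals < 0) | (vals > 100)]
        diags.extend(f"row {i}: percentile outside [0, 100]" for i in bad[:10])
    return diags
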