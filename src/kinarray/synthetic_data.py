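"""Synthetic kinome-array runs with known ground truth.

The generator emulates a tyrosine-kinase peptide chip read out at
multiple camera exposure times: each of 196 peptide spots (3 of them
internal controls) yields fluorescence intensities at exposures
{10, 20, 50, 100, 200} ms, for two conditions (case = tumor-like,
control = wild-type-like) assayed in triplicate.  The per-peptide signal
is linear in exposure time, ``intensity(t) = slope * t + intercept``,
with additive homoscedastic Gaussian noise; differential kinase activity
is injected multiplicatively on the slope, so that a kinase spiked with
effect ``e`` (in log2 units) makes the case slopes of its mapped
peptides exactly ``2**e`` times the control slopes.  A designated
fraction of peptides receives a saturating (non-affine) signal
``a * (1 - exp(-t / tau))`` whose linear fit falls below the R² filter,
and another designated fraction receives a non-positive slope
("undetectable").  Both designated sets are drawn disjoint from internal
controls and from peptides mapped to spiked kinases, so the ground-truth
differential set stays exactly recoverable.

Everything is driven by one global seed with per-stage derived
substreams and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinase_mapping import KinasePeptideMap, build_map

__all__ = [
    "DEFAULT_EXPOSURES_MS",
    "PeptideCatalog",
    "SyntheticTruth",
    "SyntheticRun",
    "generate_catalog",
    "generate_map",
    "simulate_run",
    "simulate_pipeline_scores",
]

#: Camera exposure times of the emulated readout, in milliseconds.
DEFAULT_EXPOSURES_MS: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0, 200.0)

#: Chip layout of the emulated tyrosine-kinase array.
N_PEPTIDES = 196
N_CONTROLS = 3

RUN_COLUMNS = ("sample_id", "condition", "replicate", "peptide_id", "exposure_ms", "intensity")


@dataclass(frozen=True)
class PeptideCatalog:
    """The chip layout: peptide identifiers and internal-control flags."""

    entries: tuple[tuple[str, str, bool], ...]  # (peptide_id, substrate_label, is_internal_control)

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("peptide_ids must be unique")

    @property
    def peptide_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def control_ids(self) -> frozenset[str]:
        return frozenset(e[0] for e in self.entries if e[2])

    @property
    def assay_ids(self) -> list[str]:
        """Non-control peptides eligible for kinase mapping."""
        return [e[0] for e in self.entries if not e[2]]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth configuration of one simulated comparison.

    spiked_kinases
        (kinase_id, effect_log2fc) pairs; the case-condition slopes of
        every peptide mapped to a spiked kinase are scaled by
        ``2**effect_log2fc``.
    noise_sd
        SD of the additive Gaussian intensity noise (fluorescence units).
    baseline_slope_range
        Uniform range of baseline slopes (intensity per ms).
    nonlinear_fraction, undetectable_fraction
        Fractions of the chip designated saturating / non-positive-slope.
    """

    spiked_kinases: tuple[tuple[str, float], ...] = ()
    noise_sd: float = 10.0
    baseline_slope_range: tuple[float, float] = (0.5, 3.0)
    nonlinear_fraction: float = 0.0
    undetectable_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for frac in (self.nonlinear_fraction, self.undetectable_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.nonlinear_fraction + self.undetectable_fraction >= 1.0:
            raise ValueError("nonlinear_fraction + undetectable_fraction must sum to < 1")
        lo, hi = self.baseline_slope_range
        if not (0 < lo <= hi):
            raise ValueError("baseline_slope_range must be positive and ordered")


@dataclass(frozen=True)
class SyntheticRun:
    """A simulated comparison: long-format data plus its ground truth."""

    frame: pd.DataFrame  # columns RUN_COLUMNS
    truth: SyntheticTruth
    catalog: PeptideCatalog
    spiked_peptides: frozenset[str]
    nonlinear_peptides: frozenset[str]
    undetectable_peptides: frozenset[str]
    true_slopes: Mapping[str, tuple[float, float]]  # peptide -> (control, case) slope

    def manifest(self) -> dict:
        return {
            "truth": {
                "spiked_kinases": [list(p) for p in self.truth.spiked_kinases],
                "noise_sd": self.truth.noise_sd,
                "baseline_slope_range": list(self.truth.baseline_slope_range),
                "nonlinear_fraction": self.truth.nonlinear_fraction,
                "undetectable_fraction": self.truth.undetectable_fraction,
                "seed": self.truth.seed,
            },
            "spiked_peptides": sorted(self.spiked_peptides),
            "nonlinear_peptides": sorted(self.nonlinear_peptides),
            "undetectable_peptides": sorted(self.undetectable_peptides),
            "control_peptides": sorted(self.catalog.control_ids),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(out / "run.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))


def generate_catalog(
    n_peptides: int = N_PEPTIDES, n_controls: int = N_CONTROLS, seed: int = 0
) -> PeptideCatalog:
    """Generate a chip catalog with ``n_controls`` internal-control spots."""
    if n_peptides <= 0:
        raise ValueError("n_peptides must be positive")
    if n_controls < 0 or n_controls >= n_peptides:
        raise ValueError("n_controls must satisfy 0 <= n_controls < n_peptides")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E0]))
    control_pos = set(rng.choice(n_peptides, size=n_controls, replace=False).tolist())
    entries = []
    for i in range(n_peptides):
        pid = f"PTK{i + 1:03d}"
        if i in control_pos:
            entries.append((pid, f"internal_control_{i + 1}", True))
        else:
            # synthetic phosphosite-style label: substrate protein + Tyr position
            entries.append((pid, f"SUB{i + 1:03d}_Y{int(rng.integers(5, 1200))}", False))
    return PeptideCatalog(entries=tuple(entries))


def generate_map(
    catalog: PeptideCatalog,
    n_kinases: int = 60,
    mean_peptides_per_kinase: float = 8.0,
    mean_family_size: float = 2.5,
    seed: int = 0,
) -> KinasePeptideMap:
    """Generate a synthetic kinase-peptide map over the non-control spots.

    Each kinase draws a Poisson-distributed number of substrate peptides
    (at least 1) uniformly without replacement from the non-control
    peptides, and kinases are partitioned into families of geometric
    size so the family collapse is exercised.
    """
    if n_kinases < 1:
        raise ValueError("n_kinases must be >= 1")
    pool = catalog.assay_ids
    if not pool:
        raise ValueError("catalog has no non-control peptides")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3A9]))

    rows: list[dict] = []
    families: dict[str, str] = {}
    fam_idx = 0
    remaining = n_kinases
    kin_idx = 0
    while remaining > 0:
        fam_idx += 1
        size = min(remaining, 1 + rng.geometric(1.0 / mean_family_size) - 1)
        size = max(1, int(size))
        fam = f"FAM{fam_idx:02d}"
        for _ in range(size):
            kin_idx += 1
            kid = f"KIN{kin_idx:03d}"
            families[kid] = fam
            k = int(min(len(pool), max(1, rng.poisson(mean_peptides_per_kinase))))
            for pep in rng.choice(pool, size=k, replace=False):
                rows.append({"source": "synthetic", "kinase_id": kid, "peptide_id": str(pep)})
        remaining -= size
    selected = pd.DataFrame(rows).drop_duplicates(subset=["kinase_id", "peptide_id"])
    return build_map(selected, families)


def _spiked_effects(kmap: KinasePeptideMap, truth: SyntheticTruth) -> dict[str, float]:
    """Per-peptide summed log2 effect over the spiked kinases mapping to it."""
    known = set(kmap.families)
    effects: dict[str, float] = {}
    for kid, eff in truth.spiked_kinases:
        if kid not in known:
            raise ValueError(f"spiked kinase {kid!r} not present in the map")
        for pep in kmap.peptides_of(kid):
            effects[pep] = effects.get(pep, 0.0) + float(eff)
    return effects


def simulate_run(
    catalog: PeptideCatalog,
    kmap: KinasePeptideMap,
    truth: SyntheticTruth,
    n_replicates: int = 3,
    exposures: Sequence[float] = DEFAULT_EXPOSURES_MS,
) -> SyntheticRun:
    """Simulate one case-vs-control comparison on the chip.

    Returns the long-format intensity table (one row per sample x
    peptide x exposure) together with the ground-truth designations.
    """
    exposures = tuple(float(t) for t in exposures)
    if len(set(exposures)) < 2:
        raise ValueError("need at least 2 distinct exposure times")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    ss = np.random.SeedSequence([truth.seed, 0xA27])
    rng_slopes, rng_assign, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    peptides = catalog.peptide_ids
    n = len(peptides)
    lo, hi = truth.baseline_slope_range
    base_slope = rng_slopes.uniform(lo, hi, size=n)
    intercept = rng_slopes.uniform(0.0, 20.0, size=n)

    effects = _spiked_effects(kmap, truth)
    spiked = frozenset(effects)

    eligible = [p for p in peptides if p not in catalog.control_ids and p not in spiked]
    n_nl = int(round(truth.nonlinear_fraction * n))
    n_ud = int(round(truth.undetectable_fraction * n))
    if n_nl + n_ud > len(eligible):
        raise ValueError("not enough eligible peptides for the designated fractions")
    chosen = rng_assign.choice(len(eligible), size=n_nl + n_ud, replace=False)
    nonlinear = frozenset(eligible[i] for i in chosen[:n_nl])
    undetectable = frozenset(eligible[i] for i in chosen[n_nl:])

    # saturating-curve parameters; tau in [10, 40] ms keeps the linear fit's
    # R^2 well below 0.90 over the 10-200 ms exposure window even noise-free
    tau = rng_assign.uniform(10.0, 40.0, size=n)
    neg_slope = -rng_assign.uniform(0.01, 0.10, size=n)

    idx = {p: i for i, p in enumerate(peptides)}
    t = np.asarray(exposures)

    records: list[pd.DataFrame] = []
    true_slopes: dict[str, tuple[float, float]] = {}
    for p in peptides:
        i = idx[p]
        s_ctrl = base_slope[i]
        s_case = s_ctrl * 2.0 ** effects.get(p, 0.0)
        if p in undetectable:
            s_ctrl = s_case = neg_slope[i]
        true_slopes[p] = (float(s_ctrl), float(s_case))

    for condition in ("control", "case"):
        for rep in range(1, n_replicates + 1):
            sample_id = f"{condition}_{rep}"
            slopes = np.array(
                [true_slopes[p][1] if condition == "case" else true_slopes[p][0] for p in peptides]
            )
            clean = slopes[:, None] * t[None, :] + intercept[:, None]
            nl_rows = np.array([p in nonlinear for p in peptides])
            if nl_rows.any():
                amp = base_slope * 100.0
                sat = amp[:, None] * (1.0 - np.exp(-t[None, :] / tau[:, None]))
                clean[nl_rows] = sat[nl_rows]
            noisy = clean + rng_noise.normal(0.0, truth.noise_sd, size=clean.shape)
            records.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "condition": condition,
                        "replicate": rep,
                        "peptide_id": np.repeat(peptides, len(t)),
                        "exposure_ms": np.tile(t, n),
                        "intensity": noisy.ravel(),
                    }
                )
            )
    frame = pd.concat(records, ignore_index=True)
    return SyntheticRun(
        frame=frame,
        truth=truth,
        catalog=catalog,
        spiked_peptides=spiked,
        nonlinear_peptides=nonlinear,
        undetectable_peptides=undetectable,
        true_slopes=true_slopes,
    )


def read_run(path: str | Path) -> pd.DataFrame:
    """Read a long-format run TSV written by :meth:`SyntheticRun.write`."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in RUN_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"run table missing columns: {missing}")
    return frame


def simulate_pipeline_scores(
    kmap: KinasePeptideMap,
    truth: SyntheticTruth,
    seed: int = 0,
) -> dict:
    """Synthesize native-format score tables for the external pipelines.

    The emulated tools (a median-final-score table, an FDR-based
    enrichment table, and per-database FDR tables at three fold-change
    cutoffs) score kinases noisily around a baseline, with spiked
    kinases shifted toward stronger evidence.  Used by the demo pipeline
    so the aggregation layer has four pipelines to combine.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9C4]))
    kinases = kmap.kinases
    eff = dict(truth.spiked_kinases)
    strength = np.array([abs(eff.get(k, 0.0)) for k in kinases])

    uka = pd.DataFrame(
        {
            "kinase": kinases,
            "median_final_score": rng.normal(0.0, 1.0, len(kinases))
            + strength * 2.5 * rng.choice([-1, 1], len(kinases)),
        }
    )

    # smaller FDR-like statistic = stronger evidence for the enrichment tool
    fdr_stat = 10.0 ** (-(strength * 1.5 + rng.uniform(0.0, 1.0, len(kinases))))
    ptmsea = pd.DataFrame(
        {
            "kinase": kinases,
            "fdr.pvalue.totalGeoMeanLFC": fdr_stat,
            "is_tyrosine_kinase": True,
        }
    )

    kea3: dict[tuple[str, float], pd.DataFrame] = {}
    for db in ("ChengKSIN", "PTMsigDB", "PhosDAll"):
        for cutoff in (0.2, 0.3, 0.4):
            fdr = 10.0 ** (-(strength + rng.uniform(0.0, 0.8, len(kinases))))
            kea3[(db, cutoff)] = pd.DataFrame({"kinase": kinases, "fdr": np.clip(fdr, 1e-12, 1.0)})
    return {"uka": uka, "ptmsea": ptmsea, "kea3": kea3}
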