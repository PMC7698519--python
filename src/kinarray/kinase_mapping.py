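"""Peptide-to-kinase association tables and family-level collapsing.

Upstream-kinase inference needs to know which kinases can phosphorylate
each reporter peptide on the chip.  These associations come from
database-style prediction exports (GPS-style scored predictions,
Kinexus-style ranked predictions, and curated phosphosite resources),
which are filtered with source-specific selection rules and merged into
a single bipartite kinase-peptide map.  Because scoring happens at the
level of kinase *families* (related kinases share substrate peptides and
cannot be distinguished by the array), the map also carries a kinase to
family assignment and can be collapsed to family-level peptide sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "RECORD_COLUMNS",
    "KinasePeptideMap",
    "select_records",
    "build_map",
    "collapse_to_families",
    "load_family_table",
]

#: Schema of a mapping-record table (one row per predicted association).
RECORD_COLUMNS = ("source", "kinase_id", "peptide_id", "score", "prediction_threshold", "rank")

#: Sources kept unconditionally (curated resources, and the synthetic generator).
_UNCONDITIONAL_SOURCES = {"PhosphoELM", "PhosphoSitePlus", "synthetic"}

#: GPS predictions are kept only when score > factor * prediction_threshold.
GPS_SCORE_FACTOR = 2.0

#: Kinexus predictions are kept for ranks 1..KINEXUS_TOP_N per peptide
#: (ties sharing the boundary rank are all kept).
KINEXUS_TOP_N = 5


@dataclass(frozen=True)
class KinasePeptideMap:
    """Deduplicated kinase-peptide associations with source provenance.

    ``entries`` has one row per (kinase_id, peptide_id) pair with columns
    ``kinase_id, family_id, peptide_id, sources`` where ``sources`` is a
    frozenset of contributing database names.  ``families`` maps each
    kinase to its single family.
    """

    entries: pd.DataFrame
    families: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dup = self.entries.duplicated(subset=["kinase_id", "peptide_id"])
        if dup.any():
            raise ValueError("duplicate (kinase_id, peptide_id) pairs in map entries")

    @property
    def kinases(self) -> list[str]:
        return sorted(self.entries["kinase_id"].unique())

    @property
    def peptides(self) -> set[str]:
        return set(self.entries["peptide_id"])

    def peptides_of(self, kinase_id: str) -> frozenset[str]:
        sub = self.entries.loc[self.entries["kinase_id"] == kinase_id, "peptide_id"]
        return frozenset(sub)

    def family_of(self, kinase_id: str) -> str:
        return self.families[kinase_id]

    def members_of(self, family_id: str) -> list[str]:
        return sorted(k for k, f in self.families.items() if f == family_id)

    def to_frame(self) -> pd.DataFrame:
        """Serializable view with semicolon-joined sources."""
        out = self.entries.copy()
        out["sources"] = out["sources"].map(lambda s: ";".join(sorted(s)))
        return out.sort_values(["kinase_id", "peptide_id"]).reset_index(drop=True)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "KinasePeptideMap":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        frame["sources"] = frame["sources"].map(lambda s: frozenset(s.split(";")))
        families = dict(zip(frame["kinase_id"], frame["family_id"]))
        return cls(entries=frame[["kinase_id", "family_id", "peptide_id", "sources"]], families=families)


def select_records(records: pd.DataFrame) -> pd.DataFrame:
    """Apply source-specific selection rules to raw mapping records.

    * GPS-style rows are kept iff ``score > 2 * prediction_threshold``
      (strict); rows missing the threshold are rejected with a warning.
    * Kinexus-style rows are kept iff ``rank <= 5`` within each peptide;
      ties sharing rank 5 are all kept.
    * PhosphoELM / PhosphoSitePlus / synthetic rows are kept as-is.

    Idempotent: re-applying to its own output changes nothing.
    """
    missing = [c for c in ("source", "kinase_id", "peptide_id") if c not in records.columns]
    if missing:
        raise ValueError(f"mapping records missing columns: {missing}")
    rec = records.copy()
    for col in ("score", "prediction_threshold", "rank"):
        if col not in rec.columns:
            rec[col] = pd.NA

    keep = pd.Series(False, index=rec.index)

    is_gps = rec["source"] == "GPS"
    gps_no_thr = is_gps & rec["prediction_threshold"].isna()
    if gps_no_thr.any():
        warnings.warn(
            f"dropping {int(gps_no_thr.sum())} GPS record(s) without a prediction threshold",
            stacklevel=2,
        )
    gps_ok = is_gps & ~gps_no_thr
    score = pd.to_numeric(rec["score"], errors="coerce")
    thr = pd.to_numeric(rec["prediction_threshold"], errors="coerce")
    keep |= gps_ok & (score > GPS_SCORE_FACTOR * thr)

    is_kin = rec["source"] == "Kinexus"
    rank = pd.to_numeric(rec["rank"], errors="coerce")
    keep |= is_kin & (rank <= KINEXUS_TOP_N)

    keep |= rec["source"].isin(_UNCONDITIONAL_SOURCES)

    unknown = ~rec["source"].isin({"GPS", "Kinexus"} | _UNCONDITIONAL_SOURCES)
    if unknown.any():
        names = sorted(rec.loc[unknown, "source"].unique())
        warnings.warn(f"dropping records from unknown source(s): {names}", stacklevel=2)

    return rec.loc[keep].reset_index(drop=True)


def build_map(selected: pd.DataFrame, families: Mapping[str, str]) -> KinasePeptideMap:
    """Union selected records into a deduplicated map with provenance.

    Raises ``KeyError`` naming every kinase that has no family assignment.
    """
    if selected.empty:
        empty = pd.DataFrame(columns=["kinase_id", "family_id", "peptide_id", "sources"])
        return KinasePeptideMap(entries=empty, families={})
    orphans = sorted(set(selected["kinase_id"]) - set(families))
    if orphans:
        raise KeyError(f"kinases without family assignment: {orphans}")
    grouped = (
        selected.groupby(["kinase_id", "peptide_id"], sort=True)["source"]
        .agg(lambda s: frozenset(s))
        .reset_index()
        .rename(columns={"source": "sources"})
    )
    grouped["family_id"] = grouped["kinase_id"].map(families)
    used = {k: families[k] for k in grouped["kinase_id"].unique()}
    entries = grouped[["kinase_id", "family_id", "peptide_id", "sources"]]
    return KinasePeptideMap(entries=entries, families=used)


def collapse_to_families(kmap: KinasePeptideMap) -> dict[str, frozenset[str]]:
    """Family-level peptide sets: union of the member kinases' peptides.

    Family-level scores computed downstream are broadcast identically to
    every member kinase, which is why the collapse preserves total
    peptide coverage (union over families == union over kinases).
    """
    out: dict[str, set[str]] = {}
    for _, row in kmap.entries.iterrows():
        out.setdefault(row["family_id"], set()).add(row["peptide_id"])
    return {fam: frozenset(peps) for fam, peps in out.items()}


def load_family_table() -> dict[str, str]:
    """Packaged kinase -> family assignment table for human tyrosine kinases."""
    with resources.files("kinarray.data").joinpath("kinase_families.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", dtype=str)
    return dict(zip(frame["kinase_id"], frame["family_id"]))


def records_from_tsv(path: str | Path) -> pd.DataFrame:
    """Read a mapping-record TSV (columns of :data:`RECORD_COLUMNS`)."""
    return pd.read_csv(path, sep="\t")


def map_round_trip_equal(a: KinasePeptideMap, b: KinasePeptideMap) -> bool:
    """True when two maps carry identical entries and family assignments."""
    return a.to_frame().equals(b.to_frame()) and dict(a.families) == dict(b.families)
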