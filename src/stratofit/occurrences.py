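"""Fossil occurrence tables: first/last appearance ages and tip areas.

Ages are in Ma (million years ago), larger = older, so every record must
satisfy ``fad >= lad >= 0``.  The optional ``area`` is a continent-level
label used by the ancestral-area module; the optional ``provenance`` field
lets packaged fixtures distinguish values anchored in published statements
("published") from illustrative stand-ins ("illustrative").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .errors import OccurrenceError, ReconcileError
from .tree import Tree, normalize_label

log = logging.getLogger(__name__)

__all__ = ["Occurrence", "OccurrenceTable", "read_occurrence_table", "reconcile"]


@dataclass(frozen=True)
class Occurrence:
    taxon: str
    fad: float                       # first appearance datum, Ma
    lad: float                       # last appearance datum, Ma
    area: Optional[str] = None
    provenance: Optional[str] = None

    def __post_init__(self):
        if self.lad < 0:
            raise OccurrenceError(f"{self.taxon}: negative age (lad={self.lad})")
        if self.fad < self.lad:
            raise OccurrenceError(
                f"{self.taxon}: fad ({self.fad}) < lad ({self.lad}); "
                "ages are in Ma, larger = older")


@dataclass
class OccurrenceTable:
    """Per-taxon stratigraphic ranges, keyed by normalized taxon label."""

    records: dict[str, Occurrence] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[Occurrence]) -> "OccurrenceTable":
        table = cls()
        for rec in records:
            label = normalize_label(rec.taxon)
            if label in table.records:
                raise OccurrenceError(f"duplicate taxon {label!r}")
            table.records[label] = replace(rec, taxon=label)
        return table

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, taxon: str) -> bool:
        return normalize_label(taxon) in self.records

    def __getitem__(self, taxon: str) -> Occurrence:
        return self.records[normalize_label(taxon)]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.records)

    def fad(self, taxon: str) -> float:
        return self[taxon].fad

    def area(self, taxon: str) -> Optional[str]:
        return self[taxon].area

    def fads(self) -> dict[str, float]:
        return {t: r.fad for t, r in self.records.items()}

    def subset(self, taxa: Iterable[str]) -> "OccurrenceTable":
        keep = {normalize_label(t) for t in taxa}
        return OccurrenceTable(
            {t: r for t, r in self.records.items() if t in keep})

    def with_areas(self, areas: dict[str, str]) -> "OccurrenceTable":
        """Return a copy with the given tip->area labels attached."""
        out = {}
        for t, r in self.records.items():
            a = areas.get(t, r.area)
            out[t] = replace(r, area=a)
        return OccurrenceTable(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon": r.taxon, "fad_ma": r.fad, "lad_ma": r.lad,
             "area": r.area, "provenance": r.provenance}
            for r in self.records.values()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        # drop all-empty optional columns for tidy files
        for col in ("area", "provenance"):
            if frame[col].isna().all():
                frame = frame.drop(columns=[col])
        frame.to_csv(path, index=False)


def read_occurrence_table(path) -> OccurrenceTable:
    """Read a CSV/TSV with header ``taxon,fad_ma[,lad_ma][,area]``.

    Separator is sniffed, so both comma- and tab-delimited files work.
    A missing ``lad_ma`` defaults to the FAD (point occurrence); a missing
    ``area`` is left unset.  Errors name the offending row.
    """
    frame = pd.read_csv(path, sep=None, engine="python",
                        skip_blank_lines=True)
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    required = {"taxon", "fad_ma"}
    if not required <= set(frame.columns):
        raise OccurrenceError(
            f"{path}: missing required column(s) "
            f"{sorted(required - set(frame.columns))}; header must contain "
            "'taxon,fad_ma[,lad_ma][,area]'")
    records = []
    for i, row in frame.iterrows():
        taxon = str(row["taxon"]).strip()
        try:
            fad = float(row["fad_ma"])
            lad = float(row["lad_ma"]) if "lad_ma" in frame.columns \
                and pd.notna(row.get("lad_ma")) else fad
        except (TypeError, ValueError) as exc:
            raise OccurrenceError(f"row {i + 2} ({taxon}): bad age: {exc}")
        area = row.get("area")
        area = str(area).strip() if pd.notna(area) and str(area).strip() else None
        prov = row.get("provenance")
        prov = str(prov).strip() if pd.notna(prov) and str(prov).strip() else None
        try:
            records.append(Occurrence(taxon, fad, lad, area, prov))
        except OccurrenceError as exc:
            raise OccurrenceError(f"row {i + 2}: {exc}") from exc
    try:
        return OccurrenceTable.from_records(records)
    except OccurrenceError as exc:
        raise OccurrenceError(f"{path}: {exc}") from exc


def reconcile(tree: Tree, table: OccurrenceTable,
              mode: str = "strict") -> tuple[Tree, OccurrenceTable]:
    """Reconcile a tree's tip set with an occurrence table.

    ``strict`` errors on any tip lacking a record; ``prune`` drops uncovered
    tips (logging each removal) and errors if fewer than 3 tips survive.
    The table is always filtered to the tree's surviving tips.
    """
    tips = tree.tip_labels()
    covered = tips & table.taxa
    if not covered:
        raise ReconcileError("tree and occurrence table share no taxa")
    missing = sorted(tips - table.taxa)
    if mode == "strict":
        if missing:
            raise ReconcileError(
                f"tips without occurrence records: {missing}")
        pruned = tree
    elif mode == "prune":
        if missing:
            if len(covered) < 3:
                raise ReconcileError(
                    f"fewer than 3 tips ({len(covered)}) would survive "
                    f"pruning; uncovered tips: {missing}")
            pruned = tree.prune_to(
                covered,
                on_drop=lambda t: log.info("pruned tip %s (no occurrence record)", t))
        else:
            pruned = tree
    else:
        raise ValueError(f"unknown reconcile mode {mode!r}")
    return pruned, table.subset(pruned.tip_labels())
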