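"""Clinical-annotation merge: chemotherapy response labels.

Two portal dialects are understood:

* Xena-style tables with columns ``submitter_id.samples``,
  ``therapy_type`` and ``measure_of_response``;
* cBioPortal-style tables with columns ``Sample_ID``,
  ``Disease.Free.Status`` and ``Pharmaceutical.Therapy.Indicator``.

A tumor is labeled *responded* (y=0) when a chemotherapy-treated record
shows Complete/Partial response (Xena) or DiseaseFree (cBioPortal), and
*progressive* (y=1) for Radiographic/Clinical progressive disease or
Stable disease (Xena) or Recurred/Progressed (cBioPortal). Everything else
— including responses under non-chemotherapy regimens — stays unlabeled.

Matching is case-insensitive on trimmed, whitespace-collapsed values.
When records for the same tumor disagree, progression wins (the
conservative clinical reading of a mixed record).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

UNLABELED = -1

_XENA_RESPONDED = {"complete response", "partial response"}
_XENA_PROGRESSIVE = {
    "radiographic progressive disease",
    "clinical progressive disease",
    "stable disease",
}
_CBIO_RESPONDED = {"diseasefree", "disease free"}
_CBIO_PROGRESSIVE = {"recurred/progressed", "recurred / progressed"}
_CHEMO = {"chemotherapy"}
_CBIO_CHEMO_YES = {"yes"}

XENA_COLUMNS = ["submitter_id.samples", "therapy_type", "measure_of_response"]
CBIO_COLUMNS = ["Sample_ID", "Disease.Free.Status", "Pharmaceutical.Therapy.Indicator"]


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    source: str                      # "xena" | "cbioportal"
    therapy_type: str | None = None  # Xena therapy / cBio chemo indicator
    response_field: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.source not in ("xena", "cbioportal"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class ResponseLabel:
    sample_id: str
    y: int                           # 0 responded, 1 progressive, -1 unlabeled
    provenance: str = ""


def _norm(value: str | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return re.sub(r"\s+", " ", str(value).strip()).lower()


def _classify(rec: ClinicalRecord) -> int:
    resp = _norm(rec.response_field)
    if not resp:
        return UNLABELED
    if rec.source == "xena":
        if _norm(rec.therapy_type) not in _CHEMO:
            return UNLABELED
        if resp in _XENA_RESPONDED:
            return 0
        if resp in _XENA_PROGRESSIVE:
            return 1
        return UNLABELED
    # cbioportal
    if _norm(rec.therapy_type) not in _CBIO_CHEMO_YES:
        return UNLABELED
    if resp in _CBIO_RESPONDED:
        return 0
    if resp in _CBIO_PROGRESSIVE:
        return 1
    return UNLABELED


def assign_response_labels(records: list[ClinicalRecord]) -> list[ResponseLabel]:
    """Merge records into one label per sample.

    Order-independent: any qualifying record indicating progression sets
    y=1; otherwise any indicating response sets y=0; otherwise unlabeled.
    Output is ordered by first appearance of each sample id.
    """
    seen: dict[str, dict] = {}
    for rec in records:
        entry = seen.setdefault(
            rec.sample_id, {"resp": False, "prog": False, "sources": set()}
        )
        y = _classify(rec)
        if y == 0:
            entry["resp"] = True
            entry["sources"].add(rec.source)
        elif y == 1:
            entry["prog"] = True
            entry["sources"].add(rec.source)
    out = []
    for sid, entry in seen.items():
        if entry["prog"]:
            y, prov = 1, "progressive:" + ",".join(sorted(entry["sources"]))
        elif entry["resp"]:
            y, prov = 0, "responded:" + ",".join(sorted(entry["sources"]))
        else:
            y, prov = UNLABELED, ""
        out.append(ResponseLabel(sid, y, prov))
    return out


def records_from_table(df: pd.DataFrame) -> list[ClinicalRecord]:
    """Parse a clinical table in either dialect (detected by columns)."""
    cols = list(df.columns)
    if set(XENA_COLUMNS).issubset(cols):
        sid, ther, resp = XENA_COLUMNS
        source = "xena"
    elif set(CBIO_COLUMNS).issubset(cols):
        sid, resp, ther = CBIO_COLUMNS
        source = "cbioportal"
    else:
        raise ValueError(
            f"table columns {cols} match neither the Xena nor the "
            "cBioPortal dialect"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(cols, row))
        try:
            records.append(
                ClinicalRecord(
                    sample_id=str(row[sid]),
                    source=source,
                    therapy_type=None if pd.isna(row[ther]) else str(row[ther]),
                    response_field=None if pd.isna(row[resp]) else str(row[resp]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"malformed clinical row {i + 2}: {exc}") from exc
    return records


def read_clinical_tsv(path: str) -> list[ClinicalRecord]:
    return records_from_table(pd.read_csv(path, sep="\t", keep_default_na=False))


def labels_to_array(
    labels: list[ResponseLabel], sample_ids: list[str]
) -> np.ndarray:
    """Dense label vector aligned to ``sample_ids`` (-1 where unlabeled)."""
    by_id = {l.sample_id: l.y for l in labels}
    return np.array([by_id.get(s, UNLABELED) for s in sample_ids], dtype=np.int64)


@dataclass
class BalanceSummary:
    n_total: int
    n_labeled: int
    n_responded: int
    n_progressive: int
    labeled_proportion: float
    balance_ratio: float             # responding / progressive; inf if none progressive


def class_balance_summary(labels) -> BalanceSummary:
    """Cohort counts, labeled proportion and responding/progressive ratio."""
    if isinstance(labels, (list, tuple)) and labels and isinstance(labels[0], ResponseLabel):
        y = np.array([l.y for l in labels])
    else:
        y = np.asarray(labels)
    n_total = len(y)
    n0 = int((y == 0).sum())
    n1 = int((y == 1).sum())
    return BalanceSummary(
        n_total=n_total,
        n_labeled=n0 + n1,
        n_responded=n0,
        n_progressive=n1,
        labeled_proportion=(n0 + n1) / n_total if n_total else 0.0,
        balance_ratio=(n0 / n1) if n1 else math.inf,
    )


def write_labels_tsv(labels: list[ResponseLabel], path: str) -> None:
    pd.DataFrame(
        [(l.sample_id, l.y, l.provenance) for l in labels],
        columns=["sample_id", "y", "provenance"],
    ).to_csv(path, sep="\t", index=False)
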