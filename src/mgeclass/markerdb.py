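"""Marker metadata and the specificity mathematics behind marker selection.

A marker is a protein profile that is informative for deciding whether a
sequence is a chromosome, a plasmid or a virus. Selection works on weighted
hit counts: reference sequences are grouped into reference clusters (RCs)
and weighted so that every RC within a class carries the same total weight
and the three classes carry equal budgets; per-class counts are then scaled
so their medians agree, and each marker's class specificity is summarized
by Pielou's specificity (1 minus normalized Shannon evenness) and by SPM
(the cosine of the count vector against each class axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import CLASSES

HALLMARKS = ("none", "plasmid", "virus")


@dataclass(frozen=True)
class Marker:
    """One classification marker with per-class specificity metadata."""

    id: str
    spm: tuple[float, float, float]
    pielou: float
    hallmark: str = "none"
    is_uscg: bool = False
    is_integrase: bool = False
    lineage: tuple[str, ...] | None = None
    annotation: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.spm, dtype=float)
        if np.linalg.norm(v) > 1 + 1e-9 or v.min() < 0:
            raise ValueError(f"invalid SPM vector {self.spm} for {self.id}")
        if not 0 <= self.pielou <= 1 + 1e-9:
            raise ValueError(f"invalid Pielou specificity {self.pielou}")
        if self.hallmark not in HALLMARKS:
            raise ValueError(f"invalid hallmark {self.hallmark!r}")
        if self.hallmark != "none" and CLASSES[int(np.argmax(v))] != self.hallmark:
            raise ValueError(
                f"hallmark {self.hallmark} marker {self.id} has class argmax "
                f"{CLASSES[int(np.argmax(v))]}"
            )

    @property
    def class_label(self) -> str:
        """Class attribution of the marker (SPM argmax; ties → chromosome)."""
        return CLASSES[int(np.argmax(self.spm))]


class MarkerDB:
    """Collection of markers keyed by id, round-trippable through TSV."""

    def __init__(self, markers: Iterable[Marker]):
        self._by_id: dict[str, Marker] = {}
        for m in markers:
            if m.id in self._by_id:
                raise ValueError(f"duplicate marker id {m.id}")
            self._by_id[m.id] = m

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._by_id

    def __getitem__(self, marker_id: str) -> Marker:
        return self._by_id[marker_id]

    def __iter__(self):
        return iter(self._by_id.values())

    def get(self, marker_id: str) -> Marker | None:
        return self._by_id.get(marker_id)

    def write(self, path: str | Path) -> None:
        rows = []
        for m in self:
            rows.append(
                {
                    "id": m.id,
                    "spm_chromosome": m.spm[0],
                    "spm_plasmid": m.spm[1],
                    "spm_virus": m.spm[2],
                    "pielou": m.pielou,
                    "hallmark": m.hallmark,
                    "is_uscg": int(m.is_uscg),
                    "is_integrase": int(m.is_integrase),
                    "lineage": ";".join(m.lineage) if m.lineage else "",
                    "annotation": m.annotation,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "MarkerDB":
        df = pd.read_csv(path, sep="\t", dtype={"id": str}, keep_default_na=False)
        markers = [
            Marker(
                id=row.id,
                spm=(float(row.spm_chromosome), float(row.spm_plasmid), float(row.spm_virus)),
                pielou=float(row.pielou),
                hallmark=row.hallmark,
                is_uscg=bool(int(row.is_uscg)),
                is_integrase=bool(int(row.is_integrase)),
                lineage=tuple(row.lineage.split(";")) if row.lineage else None,
                annotation=row.annotation,
            )
            for row in df.itertuples(index=False)
        ]
        return cls(markers)


@dataclass(frozen=True)
class WeightedReferenceSet:
    """Labeled reference sequences with RC-balanced weights."""

    seq_ids: tuple[str, ...]
    labels: tuple[str, ...]
    rc_ids: tuple[str, ...]
    weights: tuple[float, ...]

    def weight_of(self, seq_id: str) -> float:
        return self.weights[self.seq_ids.index(seq_id)]


def rc_weights(
    labels: Sequence[str], rc_ids: Sequence[str], class_budget: float = 1.0
) -> np.ndarray:
    """Per-sequence weights equalizing RC totals within each class.

    A class with K reference clusters splits its budget W equally among
    them (W/K per RC), and each RC's share is split equally among its
    member sequences; the three class budgets are identical.
    """
    labels = list(labels)
    rc_ids = list(rc_ids)
    if len(labels) != len(rc_ids):
        raise ValueError("labels and rc_ids length mismatch")
    weights = np.empty(len(labels))
    for cls in CLASSES:
        idx = [i for i, l in enumerate(labels) if l == cls]
        if not idx:
            raise ValueError(f"class {cls!r} has no reference sequences")
        rcs: dict[str, list[int]] = {}
        for i in idx:
            rcs.setdefault(rc_ids[i], []).append(i)
        per_rc = class_budget / len(rcs)
        for members in rcs.values():
            for i in members:
                weights[i] = per_rc / len(members)
    return weights


def build_reference_set(
    seq_ids: Sequence[str], labels: Sequence[str], rc_ids: Sequence[str]
) -> WeightedReferenceSet:
    w = rc_weights(labels, rc_ids)
    return WeightedReferenceSet(tuple(seq_ids), tuple(labels), tuple(rc_ids), tuple(w))


def scaled_class_counts(
    hits: Mapping[str, Iterable[str]], refs: WeightedReferenceSet
) -> dict[str, np.ndarray]:
    """Weighted per-class hit counts, scaled so class medians agree.

    Raw count of marker m for class c is the summed weight of m's hit
    sequences labeled c. Each class column is then multiplied by a scalar
    that brings its median — taken over markers with at least one hit in
    that class — to 1, so the three medians coincide.
    """
    weight = dict(zip(refs.seq_ids, refs.weights))
    label = dict(zip(refs.seq_ids, refs.labels))
    marker_ids = list(hits)
    counts = np.zeros((len(marker_ids), 3))
    for row, mid in enumerate(marker_ids):
        for sid in hits[mid]:
            if sid not in weight:
                raise KeyError(f"hit sequence {sid!r} not in reference set")
            counts[row, CLASSES.index(label[sid])] += weight[sid]
    for c in range(3):
        col = counts[:, c]
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"class {CLASSES[c]!r} has zero hits over all markers")
        counts[:, c] = col / np.median(nonzero)
    return {mid: counts[i] for i, mid in enumerate(marker_ids)}


def pielou_specificity(x: Sequence[float]) -> float:
    """1 − H(p)/ln(n): one minus the normalized Shannon evenness of x."""
    x = np.asarray(x, dtype=float)
    if x.min() < 0:
        raise ValueError("negative component")
    total = x.sum()
    if total <= 0:
        raise ValueError("sum of components must be positive")
    p = x / total
    nz = p[p > 0]
    H = -np.sum(nz * np.log(nz))
    return float(1.0 - H / np.log(x.size))


def spm(x: Sequence[float]) -> np.ndarray:
    """Specificity measure: cosine of x against each class unit vector."""
    x = np.asarray(x, dtype=float)
    if x.min() < 0:
        raise ValueError("negative component")
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("sum of components must be positive")
    return x / norm


def select_markers(
    counts: Mapping[str, Sequence[float]],
    median_total: float | None = None,
    q1_total: float | None = None,
) -> list[str]:
    """Select class-informative markers from scaled class counts.

    A marker is kept when Pielou's specificity ≥ 0.4 or its maximum SPM
    ≥ 0.75, and its total count clears a prevalence bar: chromosome-assigned
    markers must exceed the median of total counts, plasmid/virus-assigned
    markers the first quartile (both strict). The bars default to the
    quantiles of the input distribution; passing them explicitly makes
    re-selection on a subset idempotent.
    """
    ids = list(counts)
    totals = np.array([np.sum(counts[m]) for m in ids])
    if median_total is None:
        median_total = float(np.median(totals))
    if q1_total is None:
        q1_total = float(np.percentile(totals, 25))
    kept = []
    for mid, total in zip(ids, totals):
        vec = np.asarray(counts[mid], dtype=float)
        if not (pielou_specificity(vec) >= 0.4 or spm(vec).max() >= 0.75):
            continue
        assigned = CLASSES[int(np.argmax(vec))]
        bar = median_total if assigned == "chromosome" else q1_total
        if total > bar:
            kept.append(mid)
    return kept
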