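"""Marker assignment to genes and per-sequence evidence summaries.

The search backend is pluggable: the package ships an exact-id lookup
(useful when gene tables already carry ground-truth marker ids, as the
synthetic generator's do) and a best-hit table importer for hits produced
by external profile-search tools. What matters downstream is only the
best marker per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .markerdb import Marker, MarkerDB
from .records import CLASSES, GeneRecord, SequenceRecord


class SearchBackend(Protocol):
    def best_hit(self, gene: GeneRecord) -> str | None:
        """Return the best-hit marker id for a gene, or None."""


class ExactBackend:
    """Backend that trusts the marker_id already present on each gene."""

    def best_hit(self, gene: GeneRecord) -> str | None:
        return gene.marker_id


class TableBackend:
    """Backend backed by a best-hit TSV: gene_key (seq_id:index), marker_id."""

    def __init__(self, mapping: dict[str, str]):
        self._mapping = mapping

    @classmethod
    def read(cls, path: str | Path) -> "TableBackend":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls(dict(zip(df["gene_key"], df["marker_id"])))

    def best_hit(self, gene: GeneRecord) -> str | None:
        return self._mapping.get(f"{gene.seq_id}:{gene.index}") or None


def gene_class(marker: Marker) -> str:
    """Per-gene class attribution: argmax of the marker's SPM (ties → chromosome)."""
    return CLASSES[int(np.argmax(marker.spm))]


@dataclass
class AnnotatedSequence:
    """A sequence with marker-resolved genes and recomputable tallies."""

    record: SequenceRecord
    genes: list[GeneRecord]
    markers: list[Marker | None]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_annotated(self) -> int:
        return sum(m is not None for m in self.markers)

    @property
    def marker_frequency(self) -> float:
        return self.n_annotated / self.n_genes if self.n_genes else 0.0

    def class_counts(self) -> np.ndarray:
        """Number of annotated genes attributed to each class."""
        counts = np.zeros(3)
        for m in self.markers:
            if m is not None:
                counts[CLASSES.index(gene_class(m))] += 1
        return counts


def assign_markers(
    record: SequenceRecord,
    genes: Sequence[GeneRecord],
    db: MarkerDB,
    backend: SearchBackend,
) -> AnnotatedSequence:
    """Resolve each gene's best-hit marker against the database.

    Gene order and indices are preserved. A backend hit whose marker id is
    absent from the database is an error (it indicates a database/search
    mismatch, not a missing annotation).
    """
    resolved_genes: list[GeneRecord] = []
    markers: list[Marker | None] = []
    for gene in genes:
        hit = backend.best_hit(gene)
        if hit is None:
            resolved_genes.append(replace(gene, marker_id=None))
            markers.append(None)
        else:
            if hit not in db:
                raise KeyError(f"backend returned unknown marker id {hit!r}")
            resolved_genes.append(replace(gene, marker_id=hit))
            markers.append(db[hit])
    return AnnotatedSequence(record=record, genes=resolved_genes, markers=markers)


def count_special_genes(ann: AnnotatedSequence) -> tuple[int, int, int, int]:
    """(n_plasmid_hallmarks, n_virus_hallmarks, n_uscg, n_integrases)."""
    n_ph = n_vh = n_uscg = n_int = 0
    for m in ann.markers:
        if m is None:
            continue
        if m.hallmark == "plasmid":
            n_ph += 1
        elif m.hallmark == "virus":
            n_vh += 1
        if m.is_uscg:
            n_uscg += 1
        if m.is_integrase:
            n_int += 1
    return n_ph, n_vh, n_uscg, n_int


def flag_integrases_and_trnas(ann: AnnotatedSequence) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (integrase, tRNA) vectors aligned with gene indices."""
    integrase = np.array(
        [m is not None and m.is_integrase for m in ann.markers], dtype=bool
    )
    trna = np.array([g.is_trna for g in ann.genes], dtype=bool)
    return integrase, trna
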