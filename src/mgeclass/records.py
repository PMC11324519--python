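"""Core record types and readers/writers for FASTA and tab-separated tables.

Coordinates are 0-based half-open everywhere inside the package; every
user-facing file uses 1-based inclusive coordinates. Class order is fixed to
(chromosome, plasmid, virus) and argmax ties are broken in that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

CLASSES = ("chromosome", "plasmid", "virus")
RBS_MOTIFS = ("TATATA", "SD", "NONE", "OTHER")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence over {A,C,G,T,N} with a whitespace-free id."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if any(c.isspace() for c in self.id) or not self.id:
            raise ValueError(f"invalid sequence id {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneRecord:
    """A called or imported gene on a sequence.

    ``start``/``end`` are 0-based half-open; ``strand`` is +1/-1;
    ``rbs_motif`` is one of ``RBS_MOTIFS``; ``marker_id`` is the assigned
    marker (None when unannotated); ``is_trna`` flags tRNA genes supplied by
    the gene table (tRNA detection itself is external).
    """

    seq_id: str
    index: int
    start: int
    end: int
    strand: int
    rbs_motif: str = "NONE"
    marker_id: str | None = None
    is_trna: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError(f"bad strand {self.strand}")
        if self.rbs_motif not in RBS_MOTIFS:
            raise ValueError(f"bad rbs_motif {self.rbs_motif!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ClassScores:
    """A point on the 3-class probability simplex."""

    chromosome: float
    plasmid: float
    virus: float

    def __post_init__(self) -> None:
        total = self.chromosome + self.plasmid + self.virus
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"scores sum to {total}, not 1")
        if min(self.chromosome, self.plasmid, self.virus) < -1e-9:
            raise ValueError("negative class score")

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "ClassScores":
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def to_array(self) -> np.ndarray:
        return np.array([self.chromosome, self.plasmid, self.virus])

    @property
    def label(self) -> str:
        return CLASSES[int(np.argmax(self.to_array()))]


def _normalize_nt(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in _VALID else "N" for c in seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records in file order.

    Lowercase is normalized to uppercase and any character outside
    {A,C,G,T} becomes N. Empty files and duplicate ids are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            rid = title.split()[0]
            if rid in seen:
                raise ValueError(f"duplicate sequence id {rid!r} in {path}")
            seen.add(rid)
            records.append(SequenceRecord(id=rid, seq=_normalize_nt(seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")


_STARTS = {"ATG", "GTG", "TTG"}
_STOPS = {"TAA", "TAG", "TGA"}


def _scan_rbs(upstream: str) -> str:
    """Classify the 20 nt upstream context of a start codon."""
    if "TATATA" in upstream:
        return "TATATA"
    for i in range(len(upstream) - 5):
        window = upstream[i : i + 6]
        if sum(a != b for a, b in zip(window, "AGGAGG")) <= 1:
            return "SD"
    return "NONE"


def _orfs_one_strand(seq: str) -> list[tuple[int, int]]:
    """Maximal start→stop ORF intervals (0-based half-open, stop included)."""
    out = []
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if start is not None:
                    out.append((start, pos + 3))
                start = None
            elif start is None and codon in _STARTS:
                start = pos
    return out


def find_orfs(record: SequenceRecord, min_len: int = 90) -> list[GeneRecord]:
    """Naive six-frame maximal-ORF finder (stand-in for a real gene caller).

    An ORF runs from the first ATG/GTG/TTG after the previous in-frame stop
    to the next stop codon (stop included in the interval). ORFs shorter
    than ``min_len`` are dropped. The RBS motif is read from the 20 nt
    upstream of the start codon in gene orientation.
    """
    if min_len < 60 or min_len % 3:
        raise ValueError("min_len must be >= 60 and divisible by 3")
    seq = record.seq
    n = len(seq)
    intervals: list[tuple[int, int, int]] = []
    for s, e in _orfs_one_strand(seq):
        if e - s >= min_len:
            intervals.append((s, e, 1))
    for s, e in _orfs_one_strand(revcomp(seq)):
        if e - s >= min_len:
            intervals.append((n - e, n - s, -1))
    intervals.sort(key=lambda t: (t[0], t[1], -t[2]))
    genes = []
    for idx, (s, e, strand) in enumerate(intervals):
        if strand == 1:
            upstream = seq[max(0, s - 20) : s]
        else:
            upstream = revcomp(seq[e : e + 20])
        genes.append(
            GeneRecord(record.id, idx, s, e, strand, rbs_motif=_scan_rbs(upstream))
        )
    return genes


# ---------------------------------------------------------------------------
# tab-separated tables

GENE_TABLE_COLUMNS = ["seq_id", "start", "end", "strand", "rbs_motif", "marker_id", "is_trna"]


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write genes as TSV with 1-based inclusive coordinates."""
    rows = [
        {
            "seq_id": g.seq_id,
            "start": g.start + 1,
            "end": g.end,
            "strand": "+" if g.strand == 1 else "-",
            "rbs_motif": g.rbs_motif,
            "marker_id": g.marker_id if g.marker_id is not None else "",
            "is_trna": int(g.is_trna),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> dict[str, list[GeneRecord]]:
    """Read a gene TSV back into per-sequence, index-assigned gene lists."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "marker_id": str}, keep_default_na=False)
    out: dict[str, list[GeneRecord]] = {}
    for seq_id, sub in df.groupby("seq_id", sort=False):
        sub = sub.sort_values(["start", "end"], kind="stable")
        genes = []
        for idx, row in enumerate(sub.itertuples(index=False)):
            genes.append(
                GeneRecord(
                    seq_id=str(seq_id),
                    index=idx,
                    start=int(row.start) - 1,
                    end=int(row.end),
                    strand=1 if row.strand == "+" else -1,
                    rbs_motif=row.rbs_motif,
                    marker_id=row.marker_id or None,
                    is_trna=bool(int(row.is_trna)),
                )
            )
        out[str(seq_id)] = genes
    return out


SCORE_TABLE_COLUMNS = [
    "seq_id",
    "length",
    "n_genes",
    "marker_frequency",
    "chromosome_score",
    "plasmid_score",
    "virus_score",
    "calibrated_chromosome_score",
    "calibrated_plasmid_score",
    "calibrated_virus_score",
    "fdr",
    "n_plasmid_hallmarks",
    "n_virus_hallmarks",
    "n_uscg",
    "taxonomy",
    "label",
]


def score_label(scores: Sequence[float]) -> str:
    """Argmax class label; ties go to the earlier class in CLASSES."""
    return CLASSES[int(np.argmax(np.asarray(scores, dtype=float)))]


def write_score_table(rows: list[dict], path: str | Path) -> None:
    """Write the per-sequence classification summary table.

    Each row dict must carry the simplex scores; the label is recomputed
    from the calibrated scores when present, else from the raw scores.
    Calibrated columns and fdr stay empty for uncalibrated runs.
    """
    out_rows = []
    for row in rows:
        raw = np.array(
            [row["chromosome_score"], row["plasmid_score"], row["virus_score"]], dtype=float
        )
        if abs(raw.sum() - 1.0) > 1e-6 or raw.min() < -1e-9:
            raise ValueError(f"scores off the simplex for {row['seq_id']}: {raw}")
        cal = row.get("calibrated_scores")
        if cal is not None:
            cal = np.asarray(cal, dtype=float)
            if abs(cal.sum() - 1.0) > 1e-6 or cal.min() < -1e-9:
                raise ValueError(f"calibrated scores off the simplex for {row['seq_id']}")
            label = score_label(cal)
        else:
            label = score_label(raw)
        out_rows.append(
            {
                "seq_id": row["seq_id"],
                "length": int(row["length"]),
                "n_genes": int(row["n_genes"]),
                "marker_frequency": row["marker_frequency"],
                "chromosome_score": raw[0],
                "plasmid_score": raw[1],
                "virus_score": raw[2],
                "calibrated_chromosome_score": cal[0] if cal is not None else "",
                "calibrated_plasmid_score": cal[1] if cal is not None else "",
                "calibrated_virus_score": cal[2] if cal is not None else "",
                "fdr": row.get("fdr", "") if row.get("fdr") is not None else "",
                "n_plasmid_hallmarks": int(row.get("n_plasmid_hallmarks", 0)),
                "n_virus_hallmarks": int(row.get("n_virus_hallmarks", 0)),
                "n_uscg": int(row.get("n_uscg", 0)),
                "taxonomy": row.get("taxonomy", "") or "",
                "label": label,
            }
        )
    pd.DataFrame(out_rows, columns=SCORE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"seq_id": str, "taxonomy": str}, keep_default_na=False)
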