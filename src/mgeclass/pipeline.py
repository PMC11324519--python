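"""End-to-end orchestration, post-classification filtering and metrics.

The pipeline runs annotate → features → branch scores → aggregation →
optional composition-aware calibration → viral taxonomy → provirus
demarcation → filtering, and produces the score table, provirus table and
extracted sequences. Filters mirror standard screening practice: a minimum
score, a maximum FDR (only meaningful after calibration), minimum hallmark
counts and a cap on universal single-copy genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import matthews_corrcoef

from .annotate import (
    AnnotatedSequence,
    ExactBackend,
    SearchBackend,
    assign_markers,
    count_special_genes,
)
from .calibrate import CalibratorModel, CommunitySample, fdr_from_scores
from .classify import (
    AggregatorModel,
    MarkerBranchModel,
    SequenceBranchModel,
    score_sequence_branch_batch,
)
from .features import FEATURE_REGISTRY, feature_matrix
from .markerdb import MarkerDB
from .provirus import CRFParams, ProvirusCall, call_proviruses
from .records import CLASSES, GeneRecord, SequenceRecord, find_orfs, score_label
from .taxonomy import conflict_guard


@dataclass(frozen=True)
class FilterPolicy:
    """User-adjustable screen on classified sequences."""

    min_score: float = 0.7
    max_fdr: float | None = None
    min_plasmid_hallmarks: int = 0
    min_virus_hallmarks: int = 0
    max_uscg: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.min_score <= 1:
            raise ValueError("min_score must be in [0, 1]")
        if self.max_fdr is not None and not 0 <= self.max_fdr <= 1:
            raise ValueError("max_fdr must be in [0, 1]")


@dataclass
class PipelineResult:
    rows: list[dict]
    proviruses: list[ProvirusCall]
    retained: list[dict]
    extracted: list[SequenceRecord]
    annotated: list[AnnotatedSequence] = field(repr=False, default_factory=list)


def run_pipeline(
    records: Sequence[SequenceRecord],
    db: MarkerDB,
    marker_model: MarkerBranchModel,
    seq_model: SequenceBranchModel,
    agg_model: AggregatorModel,
    gene_tables: dict[str, list[GeneRecord]] | None = None,
    backend: SearchBackend | None = None,
    calibrator: CalibratorModel | None = None,
    crf_params: CRFParams | None = None,
    policy: FilterPolicy | None = None,
    taxonomy_min_fraction: float = 0.5,
    min_orf_len: int = 90,
) -> PipelineResult:
    """Classify a batch of sequences and demarcate proviruses.

    When no gene table is supplied genes come from the naive ORF finder.
    Provirus demarcation runs only on sequences whose final label is
    chromosome (an integrated virus lives inside a host sequence).
    """
    if marker_model.feature_registry != tuple(FEATURE_REGISTRY):
        raise ValueError("marker model feature registry does not match this build")
    backend = backend or ExactBackend()
    policy = policy or FilterPolicy()

    annotated: list[AnnotatedSequence] = []
    for rec in records:
        genes = (
            gene_tables.get(rec.id)
            if gene_tables is not None
            else find_orfs(rec, min_len=min_orf_len)
        )
        annotated.append(assign_markers(rec, genes or [], db, backend))

    X, _ = feature_matrix(annotated)
    marker_scores = marker_model.predict(X)
    seq_scores = score_sequence_branch_batch(seq_model, list(records))
    freqs = np.array([ann.marker_frequency for ann in annotated])
    agg = agg_model.forward(seq_scores, marker_scores, freqs)

    calibrated = None
    if calibrator is not None:
        if agg.shape[0] >= 10:
            composition = CommunitySample.composition_of(agg)
            calibrated = calibrator.predict(composition, agg)
        else:
            calibrated = agg.copy()

    rows: list[dict] = []
    final = calibrated if calibrated is not None else agg
    labels = [score_label(final[i]) for i in range(len(records))]
    for i, (rec, ann) in enumerate(zip(records, annotated)):
        n_ph, n_vh, n_uscg, _ = count_special_genes(ann)
        taxonomy = ""
        if labels[i] == "virus":
            lineages = [
                m.lineage for m in ann.markers if m is not None and m.lineage
            ]
            consensus = conflict_guard(
                lineages,
                special_parent="Nucleocytoviricota",
                special_conflict="Caudoviricetes",
                min_fraction=taxonomy_min_fraction,
            )
            taxonomy = ";".join(consensus) if consensus else ""
        rows.append(
            {
                "seq_id": rec.id,
                "length": rec.length,
                "n_genes": ann.n_genes,
                "marker_frequency": ann.marker_frequency,
                "chromosome_score": agg[i, 0],
                "plasmid_score": agg[i, 1],
                "virus_score": agg[i, 2],
                "calibrated_scores": calibrated[i] if calibrated is not None else None,
                "fdr": None,
                "n_plasmid_hallmarks": n_ph,
                "n_virus_hallmarks": n_vh,
                "n_uscg": n_uscg,
                "taxonomy": taxonomy,
                "label": labels[i],
            }
        )

    if calibrated is not None:
        # per-sequence FDR: error rate of the acceptance set at the
        # sequence's own calibrated score, within its predicted class
        pred = np.argmax(calibrated, axis=1)
        for c in range(3):
            idx = np.flatnonzero(pred == c)
            if idx.size == 0:
                continue
            class_scores = calibrated[idx, c]
            for i in idx:
                rows[i]["fdr"] = fdr_from_scores(class_scores, float(calibrated[i, c]))

    proviruses: list[ProvirusCall] = []
    if crf_params is not None:
        for i, ann in enumerate(annotated):
            if labels[i] == "chromosome" and ann.n_genes:
                proviruses.extend(call_proviruses(ann, crf_params))

    retained = apply_filters(rows, policy)
    retained_ids = {r["seq_id"] for r in retained}
    extracted = [rec for rec in records if rec.id in retained_ids]
    by_id = {rec.id: rec for rec in records}
    for call in proviruses:
        parent = by_id[call.seq_id]
        extracted.append(
            SequenceRecord(
                id=f"{call.seq_id}|provirus_{call.start + 1}_{call.end}",
                seq=parent.seq[call.start : call.end],
            )
        )
    return PipelineResult(rows, proviruses, retained, extracted, annotated)


def apply_filters(rows: list[dict], policy: FilterPolicy) -> list[dict]:
    """Retain plasmid/virus rows passing every bound of the policy."""
    out = []
    for row in rows:
        label = row["label"]
        if label not in ("plasmid", "virus"):
            continue
        cal = row.get("calibrated_scores")
        if policy.max_fdr is not None and row.get("fdr") is None:
            raise ValueError("max_fdr filter requires calibrated scores")
        scores = cal if cal is not None else np.array(
            [row["chromosome_score"], row["plasmid_score"], row["virus_score"]]
        )
        score = float(np.asarray(scores)[CLASSES.index(label)])
        if score < policy.min_score:
            continue
        if policy.max_fdr is not None and row["fdr"] > policy.max_fdr:
            continue
        if label == "plasmid" and row["n_plasmid_hallmarks"] < policy.min_plasmid_hallmarks:
            continue
        if label == "virus" and row["n_virus_hallmarks"] < policy.min_virus_hallmarks:
            continue
        if row["n_uscg"] > policy.max_uscg:
            continue
        out.append(row)
    return out


def write_provirus_table(calls: Sequence[ProvirusCall], path: str | Path) -> None:
    rows = [
        {
            "seq_id": c.seq_id,
            "start": c.start + 1,
            "end": c.end,
            "n_genes": c.n_genes,
            "virus_spm_sum": c.virus_spm_sum,
            "extended_left": c.extended_left,
            "extended_right": c.extended_right,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "start",
            "end",
            "n_genes",
            "virus_spm_sum",
            "extended_left",
            "extended_right",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# metrics


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient from 2×2 counts (0 on zero denom)."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("negative confusion counts")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def mcc_multiclass(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    return float(matthews_corrcoef(y_true, y_pred))


def binary_mcc_for_class(
    y_true: Sequence[int], y_pred: Sequence[int], cls: int
) -> float:
    """One-vs-rest MCC for a class, via the 2×2 formula."""
    yt = np.asarray(y_true) == cls
    yp = np.asarray(y_pred) == cls
    tp = int(np.sum(yt & yp))
    fp = int(np.sum(~yt & yp))
    fn = int(np.sum(yt & ~yp))
    tn = int(np.sum(~yt & ~yp))
    return mcc(tp, fp, fn, tn)


def calibration_mae(
    scores: Sequence[float], truth: Sequence[int], n_bins: int = 10
) -> float:
    """Mean over nonempty equal-width bins of |mean score − positive rate|."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    errs = []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            errs.append(abs(scores[mask].mean() - truth[mask].mean()))
    return float(np.mean(errs))


def find_threshold_for_fdr(
    scores: Sequence[float], truth: Sequence[int], target_fdr: float = 0.05
) -> float:
    """Smallest threshold whose realized false-discovery proportion <= target."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    best = 1.0
    for t in np.unique(scores)[::-1]:
        accepted = scores >= t
        fdp = float(np.mean(truth[accepted] == 0)) if accepted.any() else 0.0
        if fdp <= target_fdr:
            best = float(t)
    return best
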