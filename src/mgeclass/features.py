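"""The 25 numeric genomic features consumed by the marker branch.

Features summarize gene structure (density, lengths, strand switching),
ribosome-binding-site usage (the TATATA motif is characteristic of phages
with recoded stop codons, Shine–Dalgarno of typical prokaryotic genes) and
marker content (per-class frequencies and specificity of the assigned
markers). The registry order is fixed; trained models record the registry
they were fitted with and refuse mismatched inputs.
"""

from __future__ import annotations

import numpy as np

from .annotate import AnnotatedSequence, gene_class
from .records import CLASSES

STRUCTURE_FEATURES = (
    "gene_density",
    "coding_fraction",
    "mean_gene_length_log10",
    "strand_switch_rate",
    "mean_intergenic_gap",
    "n_genes_log10",
)
RBS_FEATURES = ("freq_TATATA", "freq_SD", "freq_no_RBS", "freq_other")
MARKER_FEATURES = (
    "marker_frequency",
    "chromosome_marker_freq",
    "plasmid_marker_freq",
    "virus_marker_freq",
    "chromosome_mean_spm",
    "plasmid_mean_spm",
    "virus_mean_spm",
    "chromosome_max_spm",
    "plasmid_max_spm",
    "virus_max_spm",
    "virus_hallmark_freq",
    "plasmid_hallmark_freq",
    "uscg_freq",
    "integrase_freq",
    "unannotated_freq",
)

FEATURE_REGISTRY: tuple[str, ...] = STRUCTURE_FEATURES + RBS_FEATURES + MARKER_FEATURES
assert len(FEATURE_REGISTRY) == 25


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
        last_end = max(last_end, e)
    return total


def extract_features(ann: AnnotatedSequence) -> np.ndarray:
    """Compute the 25-feature vector for one annotated sequence.

    With zero genes all gene-derived rates and frequencies are 0 so that
    unannotatable sequences still classify (the sequence branch carries
    them). Frequencies are per-gene fractions in [0, 1]; gene density is
    genes per kb; lengths and counts enter on a log10 scale.
    """
    genes = ann.genes
    n = len(genes)
    length = ann.record.length
    out = np.zeros(len(FEATURE_REGISTRY))
    f = dict.fromkeys(FEATURE_REGISTRY, 0.0)

    if n:
        f["gene_density"] = n / (length / 1000.0)
        f["coding_fraction"] = _union_length([(g.start, g.end) for g in genes]) / length
        f["mean_gene_length_log10"] = np.log10(np.mean([g.length for g in genes]))
        if n >= 2:
            switches = sum(
                genes[i].strand != genes[i + 1].strand for i in range(n - 1)
            )
            f["strand_switch_rate"] = switches / (n - 1)
            gaps = [max(0, genes[i + 1].start - genes[i].end) for i in range(n - 1)]
            f["mean_intergenic_gap"] = float(np.mean(gaps))
    f["n_genes_log10"] = np.log10(1 + n)

    if n:
        rbs = [g.rbs_motif for g in genes]
        f["freq_TATATA"] = rbs.count("TATATA") / n
        f["freq_SD"] = rbs.count("SD") / n
        f["freq_no_RBS"] = rbs.count("NONE") / n
        f["freq_other"] = rbs.count("OTHER") / n

    annotated = [m for m in ann.markers if m is not None]
    if n:
        f["marker_frequency"] = len(annotated) / n
        f["unannotated_freq"] = 1.0 - f["marker_frequency"]
        counts = ann.class_counts()
        for c, cls in enumerate(CLASSES):
            f[f"{cls}_marker_freq"] = counts[c] / n
        if annotated:
            spms = np.array([m.spm for m in annotated])
            for c, cls in enumerate(CLASSES):
                f[f"{cls}_mean_spm"] = float(spms[:, c].mean())
                f[f"{cls}_max_spm"] = float(spms[:, c].max())
        f["virus_hallmark_freq"] = sum(m.hallmark == "virus" for m in annotated) / n
        f["plasmid_hallmark_freq"] = sum(m.hallmark == "plasmid" for m in annotated) / n
        f["uscg_freq"] = sum(m.is_uscg for m in annotated) / n
        f["integrase_freq"] = sum(m.is_integrase for m in annotated) / n

    for i, name in enumerate(FEATURE_REGISTRY):
        out[i] = f[name]
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature value")
    return out


def feature_matrix(batch: list[AnnotatedSequence]) -> tuple[np.ndarray, list[str]]:
    """Stack feature vectors; rows align with input order."""
    ids = [ann.record.id for ann in batch]
    if not batch:
        return np.zeros((0, len(FEATURE_REGISTRY))), ids
    return np.stack([extract_features(ann) for ann in batch]), ids
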