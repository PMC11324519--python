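"""Seeded generator of marker databases, labeled sequences and communities.

The generator emulates the statistical structure the rest of the package
assumes: markers whose SPM vectors concentrate near their class axis;
class-conditional marker emission along gene arrays (with a no-marker mode
so some sequences have marker frequency 0); class-conditional trinucleotide
composition so the alignment-free branch has signal; metagenome-like
fragment lengths drawn from a log-normal truncated at 3 kb; and mock
proviruses — virus gene blocks integrated into chromosome gene arrays with
optional flanking tRNA and edge integrase, the way real integration sites
are organized. Every output is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .markerdb import Marker, MarkerDB
from .records import CLASSES, GeneRecord, SequenceRecord

_NTS = "ACGT"

# toy ICTV-like lineages for virus markers
CAUDO_LINEAGE = ("Duplodnaviria", "Heunggongvirae", "Uroviricota", "Caudoviricetes")
NCLDV_LINEAGE = ("Varidnaviria", "Bamfordvirae", "Nucleocytoviricota", "Megaviricetes")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic world; defaults define the study conditions."""

    n_markers_per_class: int = 50
    spm_concentration: float = 8.0
    hallmark_rate: float = 0.25
    uscg_rate: float = 0.20
    integrase_rate: float = 0.10
    caudo_fraction: float = 0.7
    ncldv_fraction: float = 0.2

    # marker emission per sequence class: P(chromosome, plasmid, virus, none)
    emission: dict = field(
        default_factory=lambda: {
            "chromosome": (0.55, 0.05, 0.05, 0.35),
            "plasmid": (0.10, 0.55, 0.06, 0.29),
            "virus": (0.06, 0.05, 0.56, 0.33),
        }
    )
    no_marker_fraction: float = 0.12

    # gene geometry
    gene_len_log_mean: float = 6.8  # ~900 bp
    gene_len_log_sigma: float = 0.35
    gene_len_min: int = 90
    gap_mean: float = 80.0
    strand_persistence: float = 0.85

    # RBS motif usage per class: P(TATATA, SD, NONE, OTHER)
    rbs_probs: dict = field(
        default_factory=lambda: {
            "chromosome": (0.02, 0.55, 0.38, 0.05),
            "plasmid": (0.03, 0.50, 0.42, 0.05),
            "virus": (0.30, 0.25, 0.40, 0.05),
        }
    )

    # nucleotide composition: class-specific trinucleotide bias
    gc_content: dict = field(
        default_factory=lambda: {"chromosome": 0.52, "plasmid": 0.46, "virus": 0.40}
    )
    composition_bias: float = 0.115
    composition_parent_jitter: float = 0.30
    composition_seed: int = 7

    # fragmenting (metagenome-like length distribution)
    frag_log_mu: float = 8.5
    frag_log_sigma: float = 0.8
    frag_min_len: int = 3000

    # mock proviruses
    host_genes_range: tuple[int, int] = (60, 120)
    provirus_genes_range: tuple[int, int] = (12, 30)
    trna_left_prob: float = 0.6
    trna_right_prob: float = 0.3
    integrase_edge_prob: float = 0.7

    def __post_init__(self) -> None:
        if self.frag_min_len < 3000:
            raise ValueError("fragment minimum length must be >= 3000")
        for probs in list(self.emission.values()) + list(self.rbs_probs.values()):
            p = np.asarray(probs)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"invalid probability vector {probs}")


# ---------------------------------------------------------------------------
# marker database


def make_marker_db(config: GeneratorConfig, seed: int = 0) -> MarkerDB:
    """Draw a non-redundant synthetic marker set.

    SPM vectors come from a Dirichlet concentrated on the marker's own
    class; Pielou's specificity is computed from the same pseudo-counts so
    the two summaries are mutually consistent.
    """
    if config.n_markers_per_class < 10:
        raise ValueError("need at least 10 markers per class")
    rng = np.random.default_rng(seed)
    markers = []
    for c, cls in enumerate(CLASSES):
        alpha = np.ones(3)
        alpha[c] = config.spm_concentration
        for i in range(config.n_markers_per_class):
            is_integrase = cls == "virus" and rng.random() < config.integrase_rate
            # integrases occur across mobile elements, so their profiles are
            # only weakly virus-specific (the CRF may leave them outside an
            # island; boundary extension is what recovers them)
            a = np.full(3, 1.0)
            a[c] = 1.6 if is_integrase else config.spm_concentration
            while True:
                p = rng.dirichlet(a)
                if np.argmax(p) == c:
                    break
            spm_vec = p / np.linalg.norm(p)
            nz = p[p > 0]
            pielou = float(1.0 + np.sum(nz * np.log(nz)) / np.log(3))
            hallmark = "none"
            if (
                cls in ("plasmid", "virus")
                and not is_integrase
                and rng.random() < config.hallmark_rate
            ):
                hallmark = cls
            is_uscg = cls == "chromosome" and rng.random() < config.uscg_rate
            lineage = None
            if cls == "virus":
                u = rng.random()
                if u < config.caudo_fraction:
                    lineage = CAUDO_LINEAGE + (
                        "Caudovirales",
                        f"Caudofam{int(rng.integers(1, 6))}",
                    )
                elif u < config.caudo_fraction + config.ncldv_fraction:
                    lineage = NCLDV_LINEAGE + (
                        "Imitervirales",
                        f"Mimifam{int(rng.integers(1, 4))}",
                    )
            markers.append(
                Marker(
                    id=f"{cls[0].upper()}{i:04d}",
                    spm=tuple(spm_vec),
                    pielou=min(1.0, max(0.0, pielou)),
                    hallmark=hallmark,
                    is_uscg=is_uscg,
                    is_integrase=is_integrase,
                    lineage=lineage,
                )
            )
    return MarkerDB(markers)


# ---------------------------------------------------------------------------
# nucleotide composition


def _class_composition_tables(config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Per-class P(next | previous two nucleotides), shape (16, 4).

    Built from the class GC content perturbed by a fixed class-specific
    trinucleotide bias so classes are separable without markers.
    """
    crng = np.random.default_rng(config.composition_seed)
    tables = {}
    for cls in CLASSES:
        gc = config.gc_content[cls]
        base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        noise = crng.normal(0.0, 1.0, size=(16, 4))
        logits = np.log(base)[None, :] + config.composition_bias * noise
        table = np.exp(logits)
        tables[cls] = table / table.sum(axis=1, keepdims=True)
    return tables


def _jitter_table(
    table: np.ndarray, jitter: float, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Per-sequence transition tables: class table plus taxon-like noise.

    Real classes are compositionally heterogeneous (different taxa have
    different signatures); each generated genome perturbs the class table
    so fragments of unseen genomes cannot be matched by memorized
    composition alone. Returns (n, 16, 4).
    """
    logits = np.log(table)[None, :, :] + jitter * rng.normal(size=(n, 16, 4))
    out = np.exp(logits)
    return out / out.sum(axis=2, keepdims=True)


def _sample_nucleotides(
    lengths: Sequence[int],
    table: np.ndarray,
    rng: np.random.Generator,
    jitter: float = 0.0,
) -> list[np.ndarray]:
    """Batched order-2 Markov sampling of nucleotide arrays (as int codes)."""
    n = len(lengths)
    max_len = max(lengths)
    if jitter > 0:
        tables = _jitter_table(table, jitter, rng, n)
    else:
        tables = np.broadcast_to(table, (n, 16, 4))
    out = np.zeros((n, max_len), dtype=np.int8)
    out[:, 0] = rng.integers(0, 4, size=n)
    out[:, 1] = rng.integers(0, 4, size=n)
    cum = tables.cumsum(axis=2)  # (n, 16, 4)
    rows = np.arange(n)
    for t in range(2, max_len):
        ctx = out[:, t - 2] * 4 + out[:, t - 1]
        u = rng.random(n)
        out[:, t] = (u[:, None] > cum[rows, ctx]).sum(axis=1)
    return [out[i, : lengths[i]] for i in range(n)]


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_NTS[c] for c in codes)


_MOTIF_CODES = {
    "TATATA": np.array([3, 0, 3, 0, 3, 0], dtype=np.int8),
    "AGGAGG": np.array([0, 2, 2, 0, 2, 2], dtype=np.int8),
}
_START_FWD = np.array([0, 3, 2], dtype=np.int8)  # ATG
_STOP_FWD = np.array([3, 0, 0], dtype=np.int8)  # TAA
_START_REV = np.array([1, 0, 3], dtype=np.int8)  # CAT = revcomp(ATG)
_STOP_REV = np.array([3, 3, 0], dtype=np.int8)  # TTA = revcomp(TAA)


def _plant_gene_signals(codes: np.ndarray, genes: list[GeneRecord]) -> None:
    """Overwrite start/stop codons and RBS motifs at gene positions."""
    for g in genes:
        if g.is_trna:
            continue
        if g.strand == 1:
            codes[g.start : g.start + 3] = _START_FWD
            codes[g.end - 3 : g.end] = _STOP_FWD
            if g.rbs_motif in _MOTIF_CODES and g.start >= 14:
                codes[g.start - 12 : g.start - 6] = _MOTIF_CODES[g.rbs_motif]
        else:
            codes[g.start : g.start + 3] = _STOP_REV
            codes[g.end - 3 : g.end] = _START_REV
            if g.rbs_motif in _MOTIF_CODES and g.end + 14 <= len(codes):
                # reverse complement of the motif, downstream on the + strand
                motif = _MOTIF_CODES[g.rbs_motif]
                codes[g.end + 6 : g.end + 12] = (3 - motif)[::-1]


# ---------------------------------------------------------------------------
# gene-array and sequence sampling


def _sample_gene_array(
    config: GeneratorConfig,
    seq_id: str,
    cls: str,
    n_genes: int,
    rng: np.random.Generator,
    marker_pools: dict[str, list[str]],
    silent: bool,
) -> tuple[list[GeneRecord], int]:
    """Sample one gene array; returns genes and the total sequence length."""
    emission = np.asarray(config.emission[cls])
    rbs_p = np.asarray(config.rbs_probs[cls])
    genes: list[GeneRecord] = []
    pos = 25 + int(rng.integers(0, 40))
    strand = 1 if rng.random() < 0.5 else -1
    for i in range(n_genes):
        length = int(
            np.exp(rng.normal(config.gene_len_log_mean, config.gene_len_log_sigma))
        )
        length = max(config.gene_len_min, 3 * (length // 3))
        rbs = ("TATATA", "SD", "NONE", "OTHER")[
            int(rng.choice(4, p=rbs_p))
        ]
        if silent:
            marker_id = None
        else:
            k = int(rng.choice(4, p=emission))
            marker_id = (
                None if k == 3 else str(rng.choice(marker_pools[CLASSES[k]]))
            )
        genes.append(
            GeneRecord(
                seq_id=seq_id,
                index=i,
                start=pos,
                end=pos + length,
                strand=strand,
                rbs_motif=rbs,
                marker_id=marker_id,
            )
        )
        pos += length + 25 + int(rng.geometric(1.0 / config.gap_mean))
        if rng.random() > config.strand_persistence:
            strand = -strand
    return genes, pos + 25


def make_sequences(
    config: GeneratorConfig,
    n_per_class: int,
    seed: int = 0,
    db: MarkerDB | None = None,
    n_genes_range: tuple[int, int] = (5, 15),
) -> tuple[list[SequenceRecord], dict[str, list[GeneRecord]], dict[str, str]]:
    """Sample a labeled corpus: records, gene tables and true class labels."""
    rng = np.random.default_rng(seed)
    db = db if db is not None else make_marker_db(config, seed=seed)
    marker_pools = {
        cls: sorted(m.id for m in db if m.class_label == cls) for cls in CLASSES
    }
    tables = _class_composition_tables(config)
    records: list[SequenceRecord] = []
    gene_tables: dict[str, list[GeneRecord]] = {}
    labels: dict[str, str] = {}
    counter = 0
    for cls in CLASSES:
        specs = []
        for _ in range(n_per_class):
            seq_id = f"s{counter:05d}"
            counter += 1
            n_genes = int(rng.integers(n_genes_range[0], n_genes_range[1] + 1))
            silent = rng.random() < config.no_marker_fraction
            genes, total = _sample_gene_array(
                config, seq_id, cls, n_genes, rng, marker_pools, silent
            )
            specs.append((seq_id, genes, total))
        codes_list = _sample_nucleotides(
            [t for _, _, t in specs], tables[cls], rng,
            jitter=config.composition_parent_jitter,
        )
        for (seq_id, genes, _), codes in zip(specs, codes_list):
            _plant_gene_signals(codes, genes)
            records.append(SequenceRecord(id=seq_id, seq=_codes_to_str(codes)))
            gene_tables[seq_id] = genes
            labels[seq_id] = cls
    return records, gene_tables, labels


# ---------------------------------------------------------------------------
# mock proviruses


def make_mock_proviruses(
    config: GeneratorConfig,
    n: int,
    seed: int = 0,
    db: MarkerDB | None = None,
) -> tuple[
    list[SequenceRecord],
    dict[str, list[GeneRecord]],
    dict[str, tuple[int, int]],
]:
    """Chromosomes with one integrated virus gene block each.

    The integrated element is [optional tRNA] + virus genes (optionally
    ending in an integrase-marker gene) + [optional tRNA]; the truth
    interval spans the whole element, inclusive of flanks, as gene
    indices. Host nucleotide composition is used throughout.
    """
    rng = np.random.default_rng(seed)
    db = db if db is not None else make_marker_db(config, seed=seed)
    marker_pools = {
        cls: sorted(m.id for m in db if m.class_label == cls) for cls in CLASSES
    }
    integrase_pool = sorted(m.id for m in db if m.is_integrase)
    tables = _class_composition_tables(config)
    records, gene_tables, truths = [], {}, {}
    specs = []
    for k in range(n):
        seq_id = f"mock{k:04d}"
        n_host = int(rng.integers(*config.host_genes_range))
        n_virus = int(rng.integers(*config.provirus_genes_range))
        insert_at = int(rng.integers(8, n_host - 8))

        # gene specs as (class_or_special, is_trna)
        plan: list[tuple[str, bool]] = [("chromosome", False)] * insert_at
        element: list[tuple[str, bool]] = []
        if rng.random() < config.trna_left_prob:
            element.append(("trna", True))
        element += [("virus", False)] * n_virus
        use_integrase = integrase_pool and rng.random() < config.integrase_edge_prob
        if use_integrase:
            element[-1] = ("integrase", False)
        if rng.random() < config.trna_right_prob:
            element.append(("trna", True))
        first = insert_at
        last = insert_at + len(element) - 1
        plan += element
        plan += [("chromosome", False)] * (n_host - insert_at)

        genes: list[GeneRecord] = []
        pos = 25 + int(rng.integers(0, 40))
        strand = 1 if rng.random() < 0.5 else -1
        for i, (kind, is_trna) in enumerate(plan):
            if is_trna:
                length = 78
                marker_id = None
                rbs = "NONE"
            else:
                length = int(
                    np.exp(
                        rng.normal(config.gene_len_log_mean, config.gene_len_log_sigma)
                    )
                )
                length = max(config.gene_len_min, 3 * (length // 3))
                if kind == "integrase":
                    marker_id = str(rng.choice(integrase_pool))
                else:
                    emission = np.asarray(config.emission[kind])
                    j = int(rng.choice(4, p=emission))
                    marker_id = (
                        None if j == 3 else str(rng.choice(marker_pools[CLASSES[j]]))
                    )
                rbs_cls = "virus" if kind in ("virus", "integrase") else "chromosome"
                rbs = ("TATATA", "SD", "NONE", "OTHER")[
                    int(rng.choice(4, p=np.asarray(config.rbs_probs[rbs_cls])))
                ]
            genes.append(
                GeneRecord(
                    seq_id=seq_id,
                    index=i,
                    start=pos,
                    end=pos + length,
                    strand=strand,
                    rbs_motif=rbs,
                    marker_id=marker_id,
                    is_trna=is_trna,
                )
            )
            pos += length + 25 + int(rng.geometric(1.0 / config.gap_mean))
            if rng.random() > config.strand_persistence:
                strand = -strand
        specs.append((seq_id, genes, pos + 25, (first, last)))

    codes_list = _sample_nucleotides(
        [t for _, _, t, _ in specs], tables["chromosome"], rng,
        jitter=config.composition_parent_jitter,
    )
    for (seq_id, genes, _, truth), codes in zip(specs, codes_list):
        _plant_gene_signals(codes, genes)
        records.append(SequenceRecord(id=seq_id, seq=_codes_to_str(codes)))
        gene_tables[seq_id] = genes
        truths[seq_id] = truth
    return records, gene_tables, truths


# ---------------------------------------------------------------------------
# fragmenting


def fragment_sequences(
    records: list[SequenceRecord],
    config: GeneratorConfig,
    seed: int = 0,
    gene_tables: dict[str, list[GeneRecord]] | None = None,
) -> tuple[list[SequenceRecord], dict[str, list[GeneRecord]], dict[str, str]]:
    """Cut records into fragments with truncated log-normal lengths.

    Records shorter than the 3 kb minimum pass through untouched. A
    terminal remainder shorter than the minimum is merged into its
    predecessor, so every emitted fragment of a cut record is >= 3 kb and
    the fragments concatenate back to the original sequence. Genes fully
    contained in a fragment are re-coordinated; genes crossing a cut are
    dropped (they are broken open reading frames). Returns fragments,
    per-fragment gene tables, and a fragment → parent id map.
    """
    rng = np.random.default_rng(seed)
    out_records: list[SequenceRecord] = []
    out_genes: dict[str, list[GeneRecord]] = {}
    parents: dict[str, str] = {}

    def draw_length() -> int:
        while True:
            l = int(np.exp(rng.normal(config.frag_log_mu, config.frag_log_sigma)))
            if l >= config.frag_min_len:
                return l

    for rec in records:
        if rec.length < config.frag_min_len:
            out_records.append(rec)
            parents[rec.id] = rec.id
            if gene_tables is not None:
                out_genes[rec.id] = list(gene_tables.get(rec.id, []))
            continue
        bounds = [0]
        while True:
            remaining = rec.length - bounds[-1]
            l = draw_length()
            if remaining - l < config.frag_min_len:
                bounds.append(rec.length)
                break
            bounds.append(bounds[-1] + l)
        for k, (s, e) in enumerate(zip(bounds, bounds[1:])):
            fid = f"{rec.id}_f{k}"
            out_records.append(SequenceRecord(id=fid, seq=rec.seq[s:e]))
            parents[fid] = rec.id
            if gene_tables is not None:
                kept = [
                    g
                    for g in gene_tables.get(rec.id, [])
                    if g.start >= s and g.end <= e
                ]
                out_genes[fid] = [
                    GeneRecord(
                        seq_id=fid,
                        index=i,
                        start=g.start - s,
                        end=g.end - s,
                        strand=g.strand,
                        rbs_motif=g.rbs_motif,
                        marker_id=g.marker_id,
                        is_trna=g.is_trna,
                    )
                    for i, g in enumerate(kept)
                ]
    return out_records, out_genes, parents
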