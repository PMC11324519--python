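"""Desk-scale training and evaluation workflows.

These functions wire the generator, the two branches, the aggregator, the
calibrator and the provirus CRF into a complete, seeded study: a labeled
corpus is split three ways (branch training / calibration pool / held-out
evaluation), fragments of held-out genomes probe end-to-end recovery, and
mock proviruses probe demarcation. The problem sizes are the package's
desk-scale defaults; every quantity is recomputed from scratch for a given
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import calibrate as cal
from . import classify as clf
from . import pipeline as pl
from . import provirus as pv
from . import synthetic as syn
from .annotate import ExactBackend, assign_markers
from .features import FEATURE_REGISTRY, feature_matrix
from .pipeline import calibration_mae, mcc_multiclass
from .records import CLASSES


@dataclass
class DeskScale:
    """Problem sizes for a desk-scale study (single CPU, minutes)."""

    n_parents_per_class: int = 350
    parent_genes: tuple[int, int] = (18, 36)
    window: int = 1500
    channels: int = 24
    n_layers: int = 3
    n_patches: int = 24
    patch_size: int = 4
    dim: int = 48
    proj_dim: int = 24
    contrastive_epochs: int = 8
    classifier_epochs: int = 40
    n_communities: int = 2000
    n_heldout_communities: int = 300
    community_size: tuple[int, int] = (100, 1000)
    calibrator_epochs: int = 40
    n_mock_train: int = 40
    n_mock_eval: int = 200
    n_eval_fragments: int = 1500


@dataclass
class Study:
    config: syn.GeneratorConfig
    scale: DeskScale
    seed: int
    db: object = None
    _cache: dict = field(default_factory=dict)


def build_study(
    seed: int = 1,
    config: syn.GeneratorConfig | None = None,
    scale: DeskScale | None = None,
) -> Study:
    config = config or syn.GeneratorConfig()
    scale = scale or DeskScale()
    study = Study(config=config, scale=scale, seed=seed)
    study.db = syn.make_marker_db(config, seed=seed)
    return study


def _annotate_corpus(study: Study, records, tables):
    return [
        assign_markers(r, tables[r.id], study.db, ExactBackend()) for r in records
    ]


def corpus(study: Study):
    """Fragmented labeled corpus with a deterministic three-way split.

    Long parent genomes are generated and cut into metagenome-like
    fragments (the classifiers both train and evaluate on fragments, the
    regime they are meant for). Fragments of one parent stay within one
    split so evaluation sequences are genuinely unseen.
    """
    if "corpus" in study._cache:
        return study._cache["corpus"]
    parents, ptables, plabels = syn.make_sequences(
        study.config, study.scale.n_parents_per_class, seed=study.seed + 1,
        db=study.db, n_genes_range=study.scale.parent_genes,
    )
    records, tables, parent_of = syn.fragment_sequences(
        parents, study.config, seed=study.seed + 2, gene_tables=ptables
    )
    labels = {r.id: plabels[parent_of[r.id]] for r in records}
    y = np.array([CLASSES.index(labels[r.id]) for r in records])
    anns = _annotate_corpus(study, records, tables)
    X, _ = feature_matrix(anns)
    freqs = np.array([a.marker_frequency for a in anns])
    rng = np.random.default_rng(study.seed + 3)
    parent_ids = [p.id for p in parents]
    order = rng.permutation(len(parent_ids))
    n = len(parent_ids)
    parent_split = {
        "train": {parent_ids[i] for i in order[: int(0.30 * n)]},
        "pool": {parent_ids[i] for i in order[int(0.30 * n) : int(0.60 * n)]},
        "eval": {parent_ids[i] for i in order[int(0.60 * n) :]},
    }
    split = {
        name: np.array(
            [i for i, r in enumerate(records) if parent_of[r.id] in members]
        )
        for name, members in parent_split.items()
    }
    out = dict(
        records=records, tables=tables, y=y, X=X, freqs=freqs, split=split,
    )
    study._cache["corpus"] = out
    return out


def _windows(study: Study, indices) -> np.ndarray:
    """One-hot first-window encodings for a subset of the corpus."""
    c = corpus(study)
    W = study.scale.window
    return np.stack([clf.one_hot(c["records"][i].seq, W) for i in indices])


def models(study: Study):
    """Branches and aggregator trained on the corpus train split.

    All three models are fitted on the same training fold, as in standard
    practice for this kind of two-branch system; the resulting raw scores
    are confident rather than probabilistic, which is precisely what the
    downstream composition-aware calibration stage corrects.
    """
    if "models" in study._cache:
        return study._cache["models"]
    c = corpus(study)
    tr = c["split"]["train"]
    s = study.scale
    mm = clf.train_marker_branch(c["X"][tr], c["y"][tr], FEATURE_REGISTRY, seed=study.seed)
    config = clf.SequenceBranchConfig(
        window=s.window, channels=s.channels, n_layers=s.n_layers,
        n_patches=s.n_patches, patch_size=s.patch_size, dim=s.dim,
        proj_dim=s.proj_dim, contrastive_epochs=s.contrastive_epochs,
        classifier_epochs=s.classifier_epochs,
    )
    sm = clf.train_sequence_branch(_windows(study, tr), c["y"][tr], config, seed=study.seed)
    am = clf.train_aggregator(
        clf.score_sequence_branch_batch(sm, [c["records"][i] for i in tr]),
        mm.predict(c["X"][tr]),
        c["freqs"][tr],
        c["y"][tr],
        seed=study.seed,
    )
    out = dict(marker=mm, sequence=sm, aggregator=am)
    study._cache["models"] = out
    return out


def hybrid_metrics(study: Study) -> dict:
    """Branch and aggregated MCCs on the eval split, plus frequency strata."""
    if "hybrid" in study._cache:
        return study._cache["hybrid"]
    c, m = corpus(study), models(study)
    ev = c["split"]["eval"]
    ms = m["marker"].predict(c["X"][ev])
    ss = clf.score_sequence_branch_batch(m["sequence"], [c["records"][i] for i in ev])
    agg = m["aggregator"].forward(ss, ms, c["freqs"][ev])
    y = c["y"][ev]
    hi = c["freqs"][ev] >= 0.5
    lo = c["freqs"][ev] == 0
    out = {
        "marker_mcc": mcc_multiclass(y, ms.argmax(1)),
        "sequence_mcc": mcc_multiclass(y, ss.argmax(1)),
        "aggregated_mcc": mcc_multiclass(y, agg.argmax(1)),
        "marker_mcc_high_freq": mcc_multiclass(y[hi], ms.argmax(1)[hi]),
        "sequence_mcc_high_freq": mcc_multiclass(y[hi], ss.argmax(1)[hi]),
        "marker_mcc_zero_freq": mcc_multiclass(y[lo], ms.argmax(1)[lo]),
        "sequence_mcc_zero_freq": mcc_multiclass(y[lo], ss.argmax(1)[lo]),
        "n_eval": int(len(ev)),
        "n_zero_freq": int(lo.sum()),
    }
    study._cache["hybrid"] = out
    return out


def pool_scores(study: Study):
    """Aggregated scores of the calibration pool split."""
    if "pool" in study._cache:
        return study._cache["pool"]
    c, m = corpus(study), models(study)
    po = c["split"]["pool"]
    scores = m["aggregator"].forward(
        clf.score_sequence_branch_batch(m["sequence"], [c["records"][i] for i in po]),
        m["marker"].predict(c["X"][po]),
        c["freqs"][po],
    )
    out = (scores, c["y"][po])
    study._cache["pool"] = out
    return out


def community_mae(scores: np.ndarray, labels: np.ndarray, n_bins: int = 5) -> float:
    """Per-community calibration error: mean of the three class-wise MAEs.

    Communities hold 100-1000 members, so per-class reliability curves use
    five equal-width bins; finer binning leaves bins with a handful of
    points whose realized frequencies are dominated by sampling noise.
    """
    return float(
        np.mean(
            [
                calibration_mae(scores[:, k], (labels == k).astype(int), n_bins=n_bins)
                for k in range(3)
            ]
        )
    )


def calibration_metrics(study: Study, fdr_threshold: float = 0.8) -> dict:
    """Calibrator efficacy on held-out communities plus FDR accuracy."""
    if "calibration" in study._cache:
        return study._cache["calibration"]
    scores, y = pool_scores(study)
    s = study.scale
    comms = cal.sample_communities(
        scores, y, s.n_communities + s.n_heldout_communities,
        s.community_size, seed=study.seed + 3,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = cal.train_calibrator(
            comms[: s.n_communities], seed=study.seed, epochs=s.calibrator_epochs
        )
    held = comms[s.n_communities :]
    wins = 0
    pre, post = [], []
    acc_scores, acc_truth = [], []
    for comm in held:
        calibrated = model.predict(comm.composition, comm.scores)
        a = community_mae(comm.scores, comm.labels)
        b = community_mae(calibrated, comm.labels)
        pre.append(a)
        post.append(b)
        wins += b < a
        pred = calibrated.argmax(1)
        for k in range(3):
            mask = pred == k
            if mask.any():
                acc_scores.append(calibrated[mask, k])
                acc_truth.append((comm.labels[mask] == k).astype(int))
    pooled = np.concatenate(acc_scores)
    truth = np.concatenate(acc_truth)
    est = cal.fdr_from_scores(pooled, fdr_threshold)
    accepted = pooled >= fdr_threshold
    realized = float(np.mean(truth[accepted] == 0)) if accepted.any() else 0.0
    out = {
        "mae_improved_fraction": wins / len(held),
        "pre_calibration_mae": float(np.mean(pre)),
        "post_calibration_mae": float(np.mean(post)),
        "fdr_estimated": float(est),
        "fdr_realized": realized,
        "fdr_abs_error": abs(float(est) - realized),
        "n_heldout_communities": len(held),
        "calibrator": model,
    }
    study._cache["calibration"] = out
    return out


def fragment_recovery(study: Study) -> dict:
    """End-to-end 3-class MCC on held-out metagenome-like fragments."""
    if "fragments" in study._cache:
        return study._cache["fragments"]
    c, m = corpus(study), models(study)
    ev = c["split"]["eval"]
    rng = np.random.default_rng(study.seed + 4)
    n_eval = study.scale.n_eval_fragments
    if len(ev) > n_eval:
        ev = np.sort(rng.choice(ev, size=n_eval, replace=False))
    frags = [c["records"][i] for i in ev]
    y = c["y"][ev]
    result = pl.run_pipeline(
        frags, study.db, m["marker"], m["sequence"], m["aggregator"],
        gene_tables=c["tables"],
    )
    pred = np.array([CLASSES.index(r["label"]) for r in result.rows])
    out = {
        "pipeline_mcc": mcc_multiclass(y, pred),
        "pipeline_accuracy": float(np.mean(y == pred)),
        "n_fragments": int(len(frags)),
    }
    study._cache["fragments"] = out
    return out


def provirus_metrics(study: Study) -> dict:
    """CRF trained on mocks; gene-level precision/sensitivity on fresh mocks."""
    if "provirus" in study._cache:
        return study._cache["provirus"]
    s = study.scale
    t_rec, t_tab, t_truth = syn.make_mock_proviruses(
        study.config, s.n_mock_train, seed=study.seed + 7, db=study.db
    )
    chains = []
    for r in t_rec:
        ann = assign_markers(r, t_tab[r.id], study.db, ExactBackend())
        a, b = t_truth[r.id]
        states = np.zeros(ann.n_genes, dtype=int)
        states[a : b + 1] = 1
        chains.append((pv.gene_crf_features(ann), states))
    params = pv.crf_train(chains, seed=study.seed)

    e_rec, e_tab, e_truth = syn.make_mock_proviruses(
        study.config, s.n_mock_eval, seed=study.seed + 8, db=study.db
    )
    precisions, sensitivities = [], []
    for r in e_rec:
        ann = assign_markers(r, e_tab[r.id], study.db, ExactBackend())
        calls = pv.call_proviruses(ann, params)
        (p, sv) = pv.evaluate_provirus_calls(calls, [e_truth[r.id]])[0]
        precisions.append(p)
        sensitivities.append(sv)
    out = {
        "median_precision": float(np.median(precisions)),
        "median_sensitivity": float(np.median(sensitivities)),
        "mean_precision": float(np.mean(precisions)),
        "mean_sensitivity": float(np.mean(sensitivities)),
        "n_mock_proviruses": len(e_rec),
        "crf_params": params,
    }
    study._cache["provirus"] = out
    return out


def crf_oracle_agreement(seed: int = 1, n_instances: int = 1000, max_len: int = 12) -> dict:
    """Fraction of random chains where Viterbi matches exhaustive enumeration."""
    import itertools

    rng = np.random.default_rng(seed + 9)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(1, max_len + 1))
        X = rng.normal(size=(n, 4))
        params = pv.CRFParams(rng.normal(0, 1, (2, 4)), rng.normal(0, 1, (2, 2)))
        path = tuple(pv.crf_decode(params, X))
        psi = X @ params.emission.T
        best, best_score = None, -np.inf
        for cand in itertools.product([0, 1], repeat=n):
            sc = psi[np.arange(n), cand].sum()
            sc += params.transition[cand[:-1], cand[1:]].sum() if n > 1 else 0.0
            if sc > best_score:
                best_score, best = sc, cand
        agree += path == best
    return {"agreement": agree / n_instances, "n_instances": n_instances}
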