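"""Shared fixtures: a small synthetic world and a trained model stack.

The expensive fixtures are session-scoped so the branch models, the CRF
and the calibration pool are trained once and shared across test modules.
Sizes here are deliberately small (they exercise correctness, not
performance); the acceptance tests build their own larger world.
"""

from __future__ import annotations

import numpy as np
import pytest

import mgeclass as mg
from mgeclass import classify as clf
from mgeclass import provirus as pv
from mgeclass import synthetic as syn
from mgeclass.annotate import ExactBackend, assign_markers
from mgeclass.features import FEATURE_REGISTRY, feature_matrix

SMALL_W = 1000


@pytest.fixture(scope="session")
def gen_config() -> syn.GeneratorConfig:
    return syn.GeneratorConfig()


@pytest.fixture(scope="session")
def marker_db(gen_config):
    return syn.make_marker_db(gen_config, seed=11)


@pytest.fixture(scope="session")
def small_corpus(gen_config, marker_db):
    records, tables, labels = syn.make_sequences(
        gen_config, 60, seed=12, db=marker_db
    )
    return records, tables, labels


@pytest.fixture(scope="session")
def annotated_corpus(small_corpus, marker_db):
    records, tables, labels = small_corpus
    anns = [
        assign_markers(r, tables[r.id], marker_db, ExactBackend()) for r in records
    ]
    y = np.array([mg.CLASSES.index(labels[r.id]) for r in records])
    return anns, y


@pytest.fixture(scope="session")
def trained_stack(small_corpus, annotated_corpus, marker_db):
    """Marker branch + tiny sequence branch + aggregator, trained once."""
    records, tables, labels = small_corpus
    anns, y = annotated_corpus
    X, _ = feature_matrix(anns)
    freqs = np.array([a.marker_frequency for a in anns])
    Xs = np.stack([clf.one_hot(r.seq, SMALL_W) for r in records])
    mm = clf.train_marker_branch(X, y, FEATURE_REGISTRY, seed=7)
    config = clf.SequenceBranchConfig(
        window=SMALL_W,
        channels=16,
        n_layers=3,
        n_patches=16,
        patch_size=4,
        dim=32,
        proj_dim=16,
        contrastive_epochs=12,
        classifier_epochs=60,
        batch_size=32,
    )
    sm = clf.train_sequence_branch(Xs, y, config, seed=7)
    am = clf.train_aggregator(
        sm.predict_windows(Xs), mm.predict(X), freqs, y, seed=7
    )
    return {"marker": mm, "sequence": sm, "aggregator": am, "X": X, "y": y, "freqs": freqs}


@pytest.fixture(scope="session")
def crf_fixture(gen_config, marker_db):
    """Mock proviruses and a CRF trained on a third of them."""
    records, tables, truths = syn.make_mock_proviruses(
        gen_config, 45, seed=13, db=marker_db
    )
    anns = [
        assign_markers(r, tables[r.id], marker_db, ExactBackend()) for r in records
    ]
    chains = []
    for r, ann in zip(records, anns):
        a, b = truths[r.id]
        states = np.zeros(ann.n_genes, dtype=int)
        states[a : b + 1] = 1
        chains.append((pv.gene_crf_features(ann), states))
    params = pv.crf_train(chains[:15], seed=7)
    return {
        "records": records,
        "tables": tables,
        "truths": truths,
        "anns": anns,
        "chains": chains,
        "params": params,
    }
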