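"""CRF-based demarcation of integrated viruses (proviruses).

A linear-chain conditional random field with two states (chromosome,
provirus) scores each gene from the chromosome and virus SPM values of its
assigned marker (plus a has-marker indicator and a bias) together with
state-transition weights, so that a gene's state reflects the markers in
its surroundings. Viterbi decoding yields provirus islands, which are then
post-processed: islands separated by short gene arrays are merged, islands
with too little summed virus SPM are dropped, and boundaries are extended
to a nearby tRNA (within 5 kb) or integrase (within 10 kb) when no
chromosome marker lies in between — mirroring how integration sites are
organized in real genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import AnnotatedSequence, gene_class
from .records import GeneRecord

N_STATES = 2  # 0 = chromosome, 1 = provirus
N_FEATURES = 4  # chromosome SPM, virus SPM, has-marker, bias


@dataclass
class CRFParams:
    """Per-state emission weights (2×4) and transition weights (2×2)."""

    emission: np.ndarray
    transition: np.ndarray

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.emission.shape != (N_STATES, N_FEATURES):
            raise ValueError("emission weights must be 2x4")
        if self.transition.shape != (N_STATES, N_STATES):
            raise ValueError("transition weights must be 2x2")
        if not (np.isfinite(self.emission).all() and np.isfinite(self.transition).all()):
            raise ValueError("non-finite CRF parameters")

    def save(self, path: str | Path) -> None:
        payload = {
            "kind": "crf",
            "emission": self.emission.tolist(),
            "transition": self.transition.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CRFParams":
        payload = json.loads(Path(path).read_text())
        if payload.get("kind") != "crf":
            raise ValueError(f"{path} is not a CRF model file")
        return cls(np.array(payload["emission"]), np.array(payload["transition"]))


def gene_crf_features(ann: AnnotatedSequence) -> np.ndarray:
    """Per-gene CRF features; genes without markers contribute zero SPM."""
    X = np.zeros((ann.n_genes, N_FEATURES))
    X[:, 3] = 1.0
    for i, m in enumerate(ann.markers):
        if m is not None:
            X[i, 0] = m.spm[0]
            X[i, 1] = m.spm[2]
            X[i, 2] = 1.0
    return X


def _potentials(params: CRFParams, X: np.ndarray) -> np.ndarray:
    return X @ params.emission.T  # (n, 2)


def crf_loglik_grad(
    params: CRFParams, X: np.ndarray, states: Sequence[int]
) -> tuple[float, np.ndarray, np.ndarray]:
    """Conditional log-likelihood of one chain and its analytic gradient.

    Computed with the forward–backward algorithm: the gradient is observed
    minus expected feature counts under the model's posterior.
    """
    states = np.asarray(states)
    n = X.shape[0]
    psi = _potentials(params, X)
    T = params.transition

    def _lse(m: np.ndarray, axis: int) -> np.ndarray:
        mx = m.max(axis=axis)
        return mx + np.log(np.exp(m - np.expand_dims(mx, axis)).sum(axis=axis))

    # forward/backward in log space (two states: inline logsumexp)
    log_alpha = np.zeros((n, N_STATES))
    log_alpha[0] = psi[0]
    for t in range(1, n):
        log_alpha[t] = psi[t] + _lse(log_alpha[t - 1][:, None] + T, axis=0)
    logZ = float(_lse(log_alpha[-1][None, :], axis=1)[0])
    log_beta = np.zeros((n, N_STATES))
    for t in range(n - 2, -1, -1):
        log_beta[t] = _lse(T + (psi[t + 1] + log_beta[t + 1])[None, :], axis=1)

    score = psi[np.arange(n), states].sum() + T[states[:-1], states[1:]].sum()
    loglik = float(score - logZ)

    # unary posteriors
    post = np.exp(log_alpha + log_beta - logZ)  # (n, 2)
    onehot = np.zeros((n, N_STATES))
    onehot[np.arange(n), states] = 1.0
    d_em = (onehot - post).T @ X

    # pairwise posteriors, vectorized over positions
    d_tr = np.zeros_like(T)
    if n > 1:
        la = log_alpha[:-1, :, None]
        rb = (psi[1:] + log_beta[1:])[:, None, :]
        d_tr = -np.exp(la + T[None, :, :] + rb - logZ).sum(axis=0)
        np.add.at(d_tr, (states[:-1], states[1:]), 1.0)
    return loglik, d_em, d_tr


def crf_train(
    chains: list[tuple[np.ndarray, Sequence[int]]],
    l2: float = 0.01,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-15,
) -> CRFParams:
    """Maximize the L2-penalized conditional log-likelihood.

    The objective is concave, so L-BFGS with the analytic forward–backward
    gradient converges to the global optimum; the seeded random
    initialization only affects the (deterministic) optimization path.
    """
    from scipy.optimize import minimize

    all_states = np.concatenate([np.asarray(s) for _, s in chains])
    if len(np.unique(all_states)) < 2:
        raise ValueError("training data contain a single state only")
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0, 0.01, N_STATES * N_FEATURES + N_STATES * N_STATES)

    def unpack(x: np.ndarray) -> CRFParams:
        em = x[: N_STATES * N_FEATURES].reshape(N_STATES, N_FEATURES)
        tr = x[N_STATES * N_FEATURES :].reshape(N_STATES, N_STATES)
        return CRFParams(em, tr)

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        params = unpack(x)
        total = -l2 * (np.sum(params.emission**2) + np.sum(params.transition**2))
        g_em = -2.0 * l2 * params.emission
        g_tr = -2.0 * l2 * params.transition
        for X, states in chains:
            ll, d_em, d_tr = crf_loglik_grad(params, X, states)
            total += ll
            g_em += d_em
            g_tr += d_tr
        return -total, -np.concatenate([g_em.ravel(), g_tr.ravel()])

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
    )
    return unpack(res.x)


def crf_decode(params: CRFParams, X: np.ndarray) -> np.ndarray:
    """Viterbi decoding; score ties resolve to the chromosome state."""
    n = X.shape[0]
    if n == 0:
        return np.zeros(0, dtype=int)
    psi = _potentials(params, X)
    T = params.transition
    delta = np.zeros((n, N_STATES))
    back = np.zeros((n, N_STATES), dtype=int)
    delta[0] = psi[0]
    for t in range(1, n):
        cand = delta[t - 1][:, None] + T  # (prev, cur)
        back[t] = np.argmax(cand, axis=0)
        delta[t] = psi[t] + cand[back[t], np.arange(N_STATES)]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def islands_from_states(states: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of the provirus state as inclusive gene-index intervals."""
    islands = []
    start = None
    for i, s in enumerate(states):
        if s == 1 and start is None:
            start = i
        elif s == 0 and start is not None:
            islands.append((start, i - 1))
            start = None
    if start is not None:
        islands.append((start, len(states) - 1))
    return islands


def _check_islands(islands: list[tuple[int, int]]) -> None:
    for (a1, b1), (a2, b2) in zip(islands, islands[1:]):
        if a2 <= b1:
            raise ValueError(f"overlapping islands ({a1},{b1}) and ({a2},{b2})")


def merge_islands(
    islands: list[tuple[int, int]], gene_classes: Sequence[str | None]
) -> list[tuple[int, int]]:
    """Merge islands separated by short gene arrays.

    Two adjacent islands merge when the gap between them contains fewer
    than six genes and fewer than two chromosome-class markers; merging is
    applied left to right until closure.
    """
    _check_islands(islands)
    if not islands:
        return []
    merged = [islands[0]]
    for first, last in islands[1:]:
        prev_first, prev_last = merged[-1]
        gap = range(prev_last + 1, first)
        n_gap = len(gap)
        n_chrom = sum(gene_classes[i] == "chromosome" for i in gap)
        if n_gap < 6 and n_chrom < 2:
            merged[-1] = (prev_first, last)
        else:
            merged.append((first, last))
    return merged


def filter_islands(
    islands: list[tuple[int, int]],
    virus_spm: Sequence[float],
    min_virus_spm_sum: float = 1.5,
) -> list[tuple[int, int]]:
    """Drop islands whose summed virus SPM falls below the threshold."""
    return [
        (a, b)
        for a, b in islands
        if sum(virus_spm[a : b + 1]) >= min_virus_spm_sum
    ]


def extend_boundaries(
    islands: list[tuple[int, int]],
    genes: Sequence[GeneRecord],
    trna_flags: Sequence[bool],
    integrase_flags: Sequence[bool],
    gene_classes: Sequence[str | None],
    max_trna_dist: int = 5000,
    max_integrase_dist: int = 10000,
) -> list[tuple[int, int, str, str]]:
    """Extend island edges to nearby tRNA or integrase genes.

    Each edge is treated independently: the nearest tRNA whose near end is
    within 5 kb wins; failing that, the nearest integrase within 10 kb.
    The extension is blocked when any chromosome-class marker lies strictly
    between the original edge gene and the candidate. Extensions never
    cross a neighboring island. Returns (first, last, left_kind,
    right_kind) with kind in {none, trna, integrase}.
    """
    _check_islands(islands)
    out = []
    prev_end = -1
    for k, (first, last) in enumerate(islands):
        lo_bound = prev_end + 1
        hi_bound = islands[k + 1][0] - 1 if k + 1 < len(islands) else len(genes) - 1

        def _scan(edge: int, direction: int, bound: int) -> tuple[int, str]:
            # candidates walking outward from the island edge
            best: tuple[int, str] | None = None
            indices = (
                range(edge - 1, bound - 1, -1)
                if direction < 0
                else range(edge + 1, bound + 1)
            )
            blocked = False
            best_trna = best_int = None
            for j in indices:
                if blocked:
                    break
                if direction < 0:
                    dist = genes[edge].start - genes[j].end
                else:
                    dist = genes[j].start - genes[edge].end
                dist = max(dist, 0)
                if trna_flags[j] and dist <= max_trna_dist and best_trna is None:
                    best_trna = j
                if (
                    integrase_flags[j]
                    and dist <= max_integrase_dist
                    and best_int is None
                ):
                    best_int = j
                if gene_classes[j] == "chromosome":
                    blocked = True  # nothing beyond this marker qualifies
                if dist > max_integrase_dist:
                    break
            if best_trna is not None:
                return best_trna, "trna"
            if best_int is not None:
                return best_int, "integrase"
            return edge, "none"

        new_first, left_kind = _scan(first, -1, lo_bound)
        new_last, right_kind = _scan(last, +1, hi_bound)
        out.append((new_first, new_last, left_kind, right_kind))
        prev_end = new_last
    return out


@dataclass(frozen=True)
class ProvirusCall:
    """A demarcated provirus: gene span, base interval and evidence."""

    seq_id: str
    first_gene: int
    last_gene: int
    start: int  # 0-based half-open internally
    end: int
    virus_spm_sum: float
    extended_left: str = "none"
    extended_right: str = "none"

    @property
    def n_genes(self) -> int:
        return self.last_gene - self.first_gene + 1


def call_proviruses(
    ann: AnnotatedSequence,
    params: CRFParams,
    min_virus_spm_sum: float = 1.5,
) -> list[ProvirusCall]:
    """Full demarcation: decode, merge, filter, extend, emit calls."""
    if ann.n_genes == 0:
        return []
    X = gene_crf_features(ann)
    states = crf_decode(params, X)
    gene_classes = [m and gene_class(m) for m in ann.markers]
    virus_spm = [m.spm[2] if m is not None else 0.0 for m in ann.markers]
    trna, integrase = (
        np.array([g.is_trna for g in ann.genes]),
        np.array([m is not None and m.is_integrase for m in ann.markers]),
    )
    islands = islands_from_states(states)
    islands = merge_islands(islands, gene_classes)
    islands = filter_islands(islands, virus_spm, min_virus_spm_sum)
    extended = extend_boundaries(islands, ann.genes, trna, integrase, gene_classes)
    calls = []
    for first, last, left_kind, right_kind in extended:
        calls.append(
            ProvirusCall(
                seq_id=ann.record.id,
                first_gene=first,
                last_gene=last,
                start=ann.genes[first].start,
                end=ann.genes[last].end,
                virus_spm_sum=float(sum(virus_spm[first : last + 1])),
                extended_left=left_kind,
                extended_right=right_kind,
            )
        )
    return calls


def evaluate_provirus_calls(
    calls: Sequence[ProvirusCall] | Sequence[tuple[int, int]],
    truths: Sequence[tuple[int, int]],
) -> list[tuple[float, float]]:
    """Gene-level precision and sensitivity per truth provirus.

    Each truth interval is matched against the union of overlapping calls:
    precision is the fraction of predicted genes inside the truth interval
    and sensitivity the fraction of truth genes covered. A truth with no
    overlapping call scores (0, 0).
    """
    spans = [
        (c.first_gene, c.last_gene) if isinstance(c, ProvirusCall) else tuple(c)
        for c in calls
    ]
    out = []
    for t_first, t_last in truths:
        truth_genes = set(range(t_first, t_last + 1))
        pred_genes: set[int] = set()
        for a, b in spans:
            if a <= t_last and b >= t_first:
                pred_genes |= set(range(a, b + 1))
        if not pred_genes:
            out.append((0.0, 0.0))
        else:
            inter = len(pred_genes & truth_genes)
            out.append((inter / len(pred_genes), inter / len(truth_genes)))
    return out
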