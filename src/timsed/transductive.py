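"""Transductive information maximization (TIM) over a few-shot episode.

Given a frozen encoder, an episode consists of labeled support embeddings
and unlabeled query embeddings. A linear classifier W in R^{K x d} is
initialized with the class prototypes (support means) and refined by
minimizing

    L(W) = lambda_CE * CE(support) - I(Y_Q; X_Q)

where CE is the mean support cross-entropy and I is the empirical mutual
information between query inputs and their predicted labels,
I = H(marginal) - mean per-query entropy. Posteriors are softmax over raw
inner products <w_k, z_i>; the query marginal is the column mean of the
query posterior. Entropies are in nats. Maximizing I pushes query
posteriors toward confident (low conditional entropy) yet class-balanced
(high marginal entropy) assignments, which sharpens prototypes estimated
from very few shots.

Gradients of L w.r.t. W are closed-form (softmax chain rule); the default
update scope touches only W, with an optional flag that also adapts the
encoder's last convolutional block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import xlogy

from . import _nn

PROB_FLOOR = 1e-12


@dataclass
class Episode:
    """One N-way K-shot task: labeled support + unlabeled query embeddings."""

    support_z: np.ndarray        # [|S|, d]
    support_y: np.ndarray        # [|S|] labels in {0..K-1}
    query_z: np.ndarray          # [|Q|, d]
    n_way: int
    k_shot: int | None = None
    support_patches: np.ndarray | None = None   # raw patches, for encoder updates
    query_patches: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.support_z = np.asarray(self.support_z, dtype=np.float64)
        self.support_y = np.asarray(self.support_y, dtype=np.int64)
        self.query_z = np.asarray(self.query_z, dtype=np.float64)
        if len(self.support_z) != len(self.support_y):
            raise ValueError("support embeddings and labels must align")
        if len(self.query_z) < 1:
            raise ValueError("episode needs at least one query")
        present = np.unique(self.support_y)
        if not np.array_equal(present, np.arange(self.n_way)):
            raise ValueError(
                f"every class 0..{self.n_way - 1} needs support; got {present}")


@dataclass
class ClassifierState:
    """Prototype weight matrix W = [w_1, ..., w_K], one row per class."""

    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if not np.all(np.isfinite(self.W)):
            raise ValueError("classifier weights must be finite")

    @property
    def n_way(self) -> int:
        return self.W.shape[0]


@dataclass
class PosteriorMatrix:
    """Row-stochastic posterior P [n, K] and the marginal (column mean)."""

    P: np.ndarray
    marginal: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        self.marginal = np.asarray(self.marginal, dtype=np.float64)


@dataclass
class TimConfig:
    lambda_ce: float = 1.0
    n_iters: int = 100
    lr: float = 1e-3
    tol: float = 1e-5
    update_scope: Literal["classifier_only", "classifier+last_block"] = "classifier_only"
    l2_normalize: bool = False

    def __post_init__(self) -> None:
        if self.lambda_ce < 0:
            raise ValueError("lambda_ce must be >= 0")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")


def init_prototypes(ep: Episode) -> ClassifierState:
    """w_k = mean of support embeddings with label k."""
    rows = []
    for k in range(ep.n_way):
        members = ep.support_z[ep.support_y == k]
        if len(members) == 0:
            raise ValueError(f"class {k} has no support members")
        rows.append(members.mean(axis=0))
    return ClassifierState(np.stack(rows))


def posterior(cs: ClassifierState, Z: np.ndarray) -> PosteriorMatrix:
    """Softmax posterior p_ik over inner-product logits, with max-subtraction."""
    Z = np.asarray(Z, dtype=np.float64)
    if cs.n_way == 0:
        raise ValueError("classifier has no classes")
    if Z.shape[1] != cs.W.shape[1]:
        raise ValueError("embedding dimension mismatch")
    logits = Z @ cs.W.T
    P = _nn.softmax(logits)
    return PosteriorMatrix(P, P.mean(axis=0))


def mutual_information(pm: PosteriorMatrix) -> float:
    """I(Y_Q; X_Q) = H(marginal) - mean row entropy, in nats; 0 log 0 := 0."""
    P = pm.P
    if P.shape[0] == 0:
        raise ValueError("empty query set")
    marginal = P.mean(axis=0)
    h_marg = -float(xlogy(marginal, marginal).sum())
    h_cond = -float(xlogy(P, P).sum(axis=1).mean())
    return h_marg - h_cond


def support_cross_entropy(cs: ClassifierState, ep: Episode) -> float:
    """Mean negative log-probability of true support labels (floored logs)."""
    pm = posterior(cs, ep.support_z)
    p_true = pm.P[np.arange(len(ep.support_y)), ep.support_y]
    return float(-np.mean(np.log(np.maximum(p_true, PROB_FLOOR))))


def tim_loss(cs: ClassifierState, ep: Episode, cfg: TimConfig | None = None) -> float:
    cfg = cfg or TimConfig()
    pm_q = posterior(cs, ep.query_z)
    return cfg.lambda_ce * support_cross_entropy(cs, ep) - mutual_information(pm_q)


def _tim_grad_logits(cs: ClassifierState, ep: Episode, cfg: TimConfig
                     ) -> tuple[float, np.ndarray, np.ndarray, PosteriorMatrix]:
    """Loss and dL/dlogits for support and query rows (closed form)."""
    ns, nq = len(ep.support_y), len(ep.query_z)
    pm_s = posterior(cs, ep.support_z)
    pm_q = posterior(cs, ep.query_z)
    p_true = pm_s.P[np.arange(ns), ep.support_y]
    ce = float(-np.mean(np.log(np.maximum(p_true, PROB_FLOOR))))
    mi = mutual_information(pm_q)
    loss = cfg.lambda_ce * ce - mi
    # support: d(CE)/dlogits = (p - y)/|S|
    gs = pm_s.P.copy()
    gs[np.arange(ns), ep.support_y] -= 1.0
    gs *= cfg.lambda_ce / ns
    # query: d(-I)/dp_ik = -(log p_ik - log p̂_k)/|Q|, then softmax chain rule
    logp = np.log(np.maximum(pm_q.P, PROB_FLOOR))
    logm = np.log(np.maximum(pm_q.marginal, PROB_FLOOR))
    gp = -(logp - logm[None, :]) / nq
    gq = pm_q.P * (gp - (pm_q.P * gp).sum(axis=1, keepdims=True))
    return loss, gs, gq, pm_q


def tim_gradient(cs: ClassifierState, ep: Episode, cfg: TimConfig | None = None
                 ) -> tuple[float, np.ndarray]:
    """TIM loss and its gradient w.r.t. W."""
    cfg = cfg or TimConfig()
    loss, gs, gq, _ = _tim_grad_logits(cs, ep, cfg)
    dW = gs.T @ ep.support_z + gq.T @ ep.query_z
    return loss, dW


def _maybe_normalize(Z: np.ndarray, on: bool) -> np.ndarray:
    if not on:
        return Z
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    return Z / np.maximum(norms, 1e-12)


def tim_infer(encoder, ep: Episode, cfg: TimConfig | None = None
              ) -> tuple[PosteriorMatrix, ClassifierState, list[float]]:
    """Prototype init + iterative refinement of the transductive classifier.

    ``encoder`` may be None for the default classifier-only scope; the
    "classifier+last_block" scope needs both the encoder and raw patches on
    the episode. Returns the final query posterior, classifier state and the
    per-iteration loss trace. Raises on a non-finite loss, naming the
    iteration.
    """
    cfg = cfg or TimConfig()
    if cfg.update_scope == "classifier+last_block":
        return _tim_infer_with_encoder(encoder, ep, cfg)
    ep = Episode(_maybe_normalize(ep.support_z, cfg.l2_normalize), ep.support_y,
                 _maybe_normalize(ep.query_z, cfg.l2_normalize), ep.n_way, ep.k_shot)
    cs = init_prototypes(ep)
    if ep.n_way == 1:
        pm = posterior(cs, ep.query_z)
        return pm, cs, [tim_loss(cs, ep, cfg)]
    w = _nn.Param(cs.W)
    opt = _nn.Adam([w], lr=cfg.lr)
    trace: list[float] = []
    for it in range(cfg.n_iters):
        cs = ClassifierState(w.value.astype(np.float64))
        loss, dW = tim_gradient(cs, ep, cfg)
        if not np.isfinite(loss):
            raise FloatingPointError(f"TIM loss diverged at iteration {it}")
        trace.append(loss)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < cfg.tol * max(1.0, abs(trace[-2])):
            break
        w.grad[...] = dW.astype(np.float32)
        opt.step()
    cs = ClassifierState(w.value.astype(np.float64))
    return posterior(cs, ep.query_z), cs, trace


def _tim_infer_with_encoder(encoder, ep: Episode, cfg: TimConfig):
    """Joint refinement of W and the encoder's last conv block."""
    if encoder is None or ep.support_patches is None or ep.query_patches is None:
        raise ValueError(
            "classifier+last_block scope needs an encoder and raw patches")
    xs = encoder._prepare(ep.support_patches)
    xq = encoder._prepare(ep.query_patches)
    acts = encoder.forward_until_last(np.concatenate([xs, xq]), train=False)
    ns = len(xs)
    z = encoder.forward_last(acts, train=False)
    ep0 = Episode(z[:ns], ep.support_y, z[ns:], ep.n_way, ep.k_shot)
    cs = init_prototypes(ep0)
    w = _nn.Param(cs.W)
    opt = _nn.Adam([w] + encoder.blocks[-1].params(), lr=cfg.lr)
    trace: list[float] = []
    for it in range(cfg.n_iters):
        z = encoder.forward_last(acts, train=False).astype(np.float64)
        ep_it = Episode(z[:ns], ep.support_y, z[ns:], ep.n_way, ep.k_shot)
        cs = ClassifierState(w.value.astype(np.float64))
        loss, gs, gq, _ = _tim_grad_logits(cs, ep_it, cfg)
        if not np.isfinite(loss):
            raise FloatingPointError(f"TIM loss diverged at iteration {it}")
        trace.append(loss)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < cfg.tol * max(1.0, abs(trace[-2])):
            break
        g = np.concatenate([gs, gq])
        w.grad[...] = (g.T @ z).astype(np.float32)
        encoder.backward_last((g @ w.value.astype(np.float64)).astype(np.float32))
        opt.step()
    z = encoder.forward_last(acts, train=False).astype(np.float64)
    cs = ClassifierState(w.value.astype(np.float64))
    return posterior(cs, z[ns:]), cs, trace


def prototype_posterior(ep: Episode) -> PosteriorMatrix:
    """Prototypical-network posterior: softmax over negative squared
    Euclidean distances to the class prototypes (the baseline classifier)."""
    cs = init_prototypes(ep)
    d2 = ((ep.query_z[:, None, :] - cs.W[None]) ** 2).sum(axis=2)
    P = _nn.softmax(-d2)
    return PosteriorMatrix(P, P.mean(axis=0))


def query_accuracy(pm: PosteriorMatrix, true_labels: np.ndarray) -> float:
    return float(np.mean(pm.P.argmax(axis=1) == np.asarray(true_labels)))


def make_gaussian_episode(n_way: int = 5, k_shot: int = 5, n_query: int = 15,
                          d: int = 8, center_scale: float = 3.0,
                          sigma: float = 0.1,
                          rng: np.random.Generator | int = 0) -> tuple[Episode, np.ndarray]:
    """Synthetic episode: class k is an isotropic Gaussian at center_scale*e_k.

    Returns the episode and the true query labels (balanced over classes).
    A benchmark utility: small ``sigma`` gives linearly separable clusters,
    sigma near the center spacing gives overlapping ones.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    centers = np.zeros((n_way, d))
    for k in range(n_way):
        centers[k, k % d] = center_scale
    sup_z, sup_y, qry_z, qry_y = [], [], [], []
    for k in range(n_way):
        sup_z.append(centers[k] + sigma * rng.standard_normal((k_shot, d)))
        sup_y.append(np.full(k_shot, k))
        qry_z.append(centers[k] + sigma * rng.standard_normal((n_query, d)))
        qry_y.append(np.full(n_query, k))
    ep = Episode(np.concatenate(sup_z), np.concatenate(sup_y),
                 np.concatenate(qry_z), n_way, k_shot)
    return ep, np.concatenate(qry_y)
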