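"""Gated-attention multiple-instance classifier with instance-level
clustering.

Architecture, for a bag of K patch features h_k (D-dimensional):

* Fc stack: two affine+ReLU layers map each h_k to a 512-d embedding.
* Shared attention trunk: a tanh branch (W_attn1) and a sigmoid gate
  (W_attn2), both attn_dim x embed_dim, combined elementwise.
* N parallel attention heads P_a,i (1 x attn_dim) give per-class raw
  scores e_{i,k}; a softmax over the K patches of a branch yields the
  attention distribution a_i on the bag.
* Per-class slide representation h_slide,i = sum_k a_{i,k} h_k, scored by
  per-class linear classifiers W_c,i; slide probabilities are the softmax
  of the N logits.
* Instance-level clustering: within the true class's branch the B
  most-attended patches are labeled positive and the B least-attended
  negative, and a per-branch linear 2-way instance classifier is trained
  on them with a smooth top-1 SVM loss; this sharpens what the branch
  attends to.

Total training loss = c1 * bag cross-entropy + c2 * instance loss.
Everything is plain NumPy with analytic gradients and an Adam optimizer;
bags are processed one at a time (batch size one), which matches how
whole-slide bags of wildly different K are trained in practice.

:class:`GatedAttentionMIL` wraps the pieces as a scikit-learn style
estimator (``fit`` / ``predict_proba`` / ``get_params``) so it composes
with sklearn model selection; the module-level functions expose each
computation on a raw parameter set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "MilConfig",
    "MilParams",
    "AttentionResult",
    "InstanceAssignment",
    "GatedAttentionMIL",
    "init_params",
    "embed",
    "attention_scores",
    "slide_score",
    "forward",
    "select_instances",
    "smooth_top1_svm_loss",
    "instance_cluster_loss",
    "total_loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class MilConfig:
    """Hyperparameters of the classifier.

    ``B`` is the number of top/bottom-attended patches sampled per bag
    for instance clustering; the defaults 8/32/128 track the 10x/40x/100x
    objective magnifications (more patches per slide at higher power).
    ``bag_loss_weight`` (c1) and ``instance_loss_weight`` (c2) mix the
    slide cross-entropy and the clustering loss; ``svm_tau`` is the
    smoothing temperature of the hinge.
    """

    n_classes: int = 5
    input_dim: int = 1024
    embed_dim: int = 512
    attn_dim: int = 384
    dropout_p: float = 0.3
    B: int = 8
    bag_loss_weight: float = 0.7
    instance_loss_weight: float = 0.3
    svm_tau: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.input_dim, self.embed_dim,
               self.attn_dim, self.B) < 1:
            raise ValueError("dims, n_classes and B must be positive")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.bag_loss_weight < 0 or self.instance_loss_weight < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.svm_tau <= 0:
            raise ValueError("svm_tau must be positive")


@dataclass
class MilParams:
    """All weight tensors of the Fc / attention / classifier stack."""

    fc1_w: np.ndarray   # embed x input
    fc1_b: np.ndarray   # embed
    fc2_w: np.ndarray   # embed x embed
    fc2_b: np.ndarray   # embed
    attn1_w: np.ndarray  # attn x embed  (tanh branch, W_attn1)
    attn1_b: np.ndarray  # attn
    attn2_w: np.ndarray  # attn x embed  (sigmoid gate, W_attn2)
    attn2_b: np.ndarray  # attn
    heads_w: np.ndarray  # N x attn      (P_a,i rows)
    heads_b: np.ndarray  # N
    clf_w: np.ndarray    # N x embed     (W_c,i rows)
    clf_b: np.ndarray    # N
    inst_w: np.ndarray   # N x 2 x embed (per-branch instance classifiers)
    inst_b: np.ndarray   # N x 2

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def copy(self) -> "MilParams":
        return MilParams(**{k: v.copy() for k, v in self.arrays().items()})

    def check_finite(self) -> None:
        for k, v in self.arrays().items():
            if not np.isfinite(v).all():
                raise FloatingPointError(f"non-finite values in parameter {k}")


@dataclass
class AttentionResult:
    """Forward-pass outputs for one bag."""

    A: np.ndarray        # N x K attention distributions (rows on simplex)
    H_slide: np.ndarray  # N x embed class-specific slide representations
    logits: np.ndarray   # N
    probs: np.ndarray    # N


@dataclass
class InstanceAssignment:
    """Pseudo-labels for instance clustering in one branch."""

    branch: int
    positive_idx: np.ndarray
    negative_idx: np.ndarray
    targets: np.ndarray  # 1 for each positive then 0 for each negative


def init_params(config: MilConfig, rng: np.random.Generator) -> MilParams:
    """He-style initialization scaled to each layer's fan-in."""
    def mat(rows: int, cols: int) -> np.ndarray:
        return (rng.standard_normal((rows, cols))
                * np.sqrt(2.0 / cols)).astype(np.float64)

    n, d, e, a = (config.n_classes, config.input_dim, config.embed_dim,
                  config.attn_dim)
    return MilParams(
        fc1_w=mat(e, d), fc1_b=np.zeros(e),
        fc2_w=mat(e, e), fc2_b=np.zeros(e),
        attn1_w=mat(a, e), attn1_b=np.zeros(a),
        attn2_w=mat(a, e), attn2_b=np.zeros(a),
        heads_w=mat(n, a), heads_b=np.zeros(n),
        clf_w=mat(n, e), clf_b=np.zeros(n),
        inst_w=np.stack([mat(2, e) for _ in range(n)]),
        inst_b=np.zeros((n, 2)),
    )


# ---------------------------------------------------------------------------
# forward pieces


def _dropout_mask(shape, p: float, rng: np.random.Generator) -> np.ndarray:
    if p <= 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= p) / (1.0 - p)


def embed(
    features: np.ndarray,
    params: MilParams,
    training: bool = False,
    dropout_p: float = 0.0,
    rng: np.random.Generator | None = None,
    _cache: dict | None = None,
) -> np.ndarray:
    """Fc stack: H = relu(fc2(relu(fc1(x)))) rowwise, with inverted
    dropout after each ReLU only in training mode."""
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != params.fc1_w.shape[1]:
        raise ValueError(
            f"features must be K x {params.fc1_w.shape[1]}; got {x.shape}")
    p = dropout_p if training else 0.0
    if p > 0 and rng is None:
        raise ValueError("training-mode dropout needs an rng")
    z1 = x @ params.fc1_w.T + params.fc1_b
    a1 = np.maximum(z1, 0.0)
    m1 = _dropout_mask(a1.shape, p, rng) if p > 0 else 1.0
    d1 = a1 * m1
    z2 = d1 @ params.fc2_w.T + params.fc2_b
    a2 = np.maximum(z2, 0.0)
    m2 = _dropout_mask(a2.shape, p, rng) if p > 0 else 1.0
    h = a2 * m2
    if _cache is not None:
        _cache.update(x=x, z1=z1, m1=m1, d1=d1, z2=z2, m2=m2, h=h)
    return h


def _softmax(v: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = v - v.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def attention_scores(
    H: np.ndarray,
    params: MilParams,
    branch: int | None = None,
    training: bool = False,
    dropout_p: float = 0.0,
    rng: np.random.Generator | None = None,
    _cache: dict | None = None,
) -> np.ndarray:
    """Gated-attention distributions over the K patches.

    Raw score: e_{i,k} = P_a,i (tanh(W_attn1 h_k) * sigmoid(W_attn2 h_k));
    each branch's scores are softmax-normalized over the patches, never
    over the classes.  Returns the N x K matrix (or one branch's row).
    Dropout, in training mode, acts on the shared gated trunk, never on
    the attention distribution itself.
    """
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("H must be a nonempty K x embed matrix")
    u = np.tanh(H @ params.attn1_w.T + params.attn1_b)         # K x attn
    v = 1.0 / (1.0 + np.exp(-(H @ params.attn2_w.T + params.attn2_b)))
    g = u * v
    p = dropout_p if training else 0.0
    m3 = _dropout_mask(g.shape, p, rng) if p > 0 else 1.0
    gd = g * m3
    e = gd @ params.heads_w.T + params.heads_b                 # K x N
    A = _softmax(e.T, axis=1)                                  # N x K
    if _cache is not None:
        _cache.update(u=u, v=v, m3=m3, gd=gd, A=A)
    if branch is not None:
        return A[branch]
    return A


def slide_score(
    H: np.ndarray,
    A: np.ndarray,
    params: MilParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Attention-pooled class representations and slide scores.

    h_slide,i = sum_k a_{i,k} h_k;  s_slide,i = W_c,i h_slide,i + b_i;
    probs = softmax over the N class logits.
    """
    H = np.asarray(H, dtype=np.float64)
    A = np.asarray(A, dtype=np.float64)
    h_slide = A @ H                                            # N x embed
    logits = np.sum(params.clf_w * h_slide, axis=1) + params.clf_b
    probs = _softmax(logits)
    return h_slide, logits, probs


def forward(
    features: np.ndarray,
    params: MilParams,
    config: MilConfig | None = None,
) -> AttentionResult:
    """Deterministic inference-mode forward pass for one bag."""
    H = embed(features, params, training=False)
    A = attention_scores(H, params, training=False)
    h_slide, logits, probs = slide_score(H, A, params)
    return AttentionResult(A=A, H_slide=h_slide, logits=logits, probs=probs)


# ---------------------------------------------------------------------------
# instance clustering


def select_instances(attention: np.ndarray, B: int,
                     branch: int = 0) -> InstanceAssignment:
    """Top-B (positive) and bottom-B (negative) patches of one branch.

    ``B`` is clamped to floor(K/2) so the two sets never overlap.  Ranking
    is by a single stable ascending sort on (score, patch index), i.e.
    ties resolve toward the lower index; the bottom set is read from the
    front of that order and the top set from the back.
    """
    a = np.asarray(attention, dtype=np.float64).ravel()
    k = a.size
    if k < 2:
        raise ValueError("bag too small for clustering")
    b = min(int(B), k // 2)
    # one stable ascending sort defines a total order (score, then patch
    # index); bottom-B from the front, top-B from the back — 2B <= K
    # guarantees the sets are disjoint even under massive score ties
    order = np.argsort(a, kind="stable")
    negative = np.sort(order[:b])
    positive = np.sort(order[k - b:])
    targets = np.concatenate([np.ones(b, dtype=np.int64),
                              np.zeros(b, dtype=np.int64)])
    return InstanceAssignment(branch=branch, positive_idx=positive,
                              negative_idx=negative, targets=targets)


def smooth_top1_svm_loss(scores: np.ndarray, target: int,
                         tau: float = 1.0) -> float:
    """Temperature-smoothed multiclass hinge.

    L = tau * log sum_j exp((s_j + Delta(j, y) - s_y) / tau) with the
    margin Delta(j, y) = 1[j != y]; as tau -> 0 this converges to the
    hinge max(0, 1 + max_{j != y} s_j - s_y).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    s = np.asarray(scores, dtype=np.float64).ravel()
    delta = np.ones_like(s)
    delta[target] = 0.0
    z = (s + delta - s[target]) / tau
    zmax = z.max()
    return float(tau * (zmax + np.log(np.exp(z - zmax).sum())))


def _smooth_svm_loss_grad(scores: np.ndarray, targets: np.ndarray,
                          tau: float) -> tuple[float, np.ndarray]:
    """Mean smooth-SVM loss over rows plus its gradient wrt the scores."""
    s = np.asarray(scores, dtype=np.float64)
    n = s.shape[0]
    delta = np.ones_like(s)
    delta[np.arange(n), targets] = 0.0
    z = (s + delta - s[np.arange(n), targets][:, None]) / tau
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    loss = float(tau * lse.mean())
    p = np.exp(z - zmax)
    p /= p.sum(axis=1, keepdims=True)
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    grad /= n
    return loss, grad


def instance_cluster_loss(
    H: np.ndarray,
    A: np.ndarray,
    bag_label: int,
    params: MilParams,
    B: int,
    tau: float = 1.0,
) -> float:
    """Clustering loss of the in-class branch.

    The branch of the bag's true class selects its top-B and bottom-B
    patches; the branch's 2-way instance classifier is scored on those
    2B embeddings with smooth-SVM loss (positives = 1, negatives = 0),
    averaged.  Out-of-class branches contribute zero.
    """
    assign = select_instances(np.asarray(A)[bag_label], B, branch=bag_label)
    sel = np.concatenate([assign.positive_idx, assign.negative_idx])
    s = np.asarray(H)[sel] @ params.inst_w[bag_label].T + params.inst_b[bag_label]
    loss, _ = _smooth_svm_loss_grad(s, assign.targets, tau)
    return loss


def total_loss(bag_probs: np.ndarray, bag_label: int, instance_loss: float,
               c1: float = 0.7, c2: float = 0.3) -> float:
    """c1 * cross-entropy of the slide prediction + c2 * instance loss."""
    if c1 < 0 or c2 < 0:
        raise ValueError("loss weights must be nonnegative")
    p = float(np.asarray(bag_probs, dtype=np.float64)[bag_label])
    ce = -np.log(max(p, 1e-300))
    return float(c1 * ce + c2 * instance_loss)


# ---------------------------------------------------------------------------
# training forward/backward


def _forward_backward(
    x: np.ndarray,
    y: int,
    params: MilParams,
    config: MilConfig,
    rng: np.random.Generator | None,
    training: bool = True,
) -> tuple[float, dict[str, np.ndarray] | None]:
    """One bag's loss and (in training mode) analytic parameter gradients.

    Backpropagation is written out by hand; the instance-clustering
    selection (which patches are top/bottom-B) is treated as a constant
    of the backward pass, as is standard for hard top-k selection.
    """
    cache_e: dict = {}
    cache_a: dict = {}
    p_drop = config.dropout_p if training else 0.0
    H = embed(x, params, training=training, dropout_p=p_drop, rng=rng,
              _cache=cache_e)
    A = attention_scores(H, params, training=training, dropout_p=p_drop,
                         rng=rng, _cache=cache_a)
    h_slide, logits, probs = slide_score(H, A, params)
    c1, c2 = config.bag_loss_weight, config.instance_loss_weight

    k = x.shape[0]
    inst_loss = 0.0
    assign = sel = s_inst = None
    if c2 > 0 and k >= 2:
        assign = select_instances(A[y], config.B, branch=y)
        sel = np.concatenate([assign.positive_idx, assign.negative_idx])
        s_inst = H[sel] @ params.inst_w[y].T + params.inst_b[y]
        inst_loss, dscore = _smooth_svm_loss_grad(s_inst, assign.targets,
                                                  config.svm_tau)
    loss = total_loss(probs, y, inst_loss, c1, c2)
    if not training:
        return loss, None

    grads = {k_: np.zeros_like(v) for k_, v in params.arrays().items()}

    # bag cross-entropy head
    dlogits = c1 * (probs - np.eye(probs.size)[y])
    grads["clf_w"] += dlogits[:, None] * h_slide
    grads["clf_b"] += dlogits
    dH_slide = dlogits[:, None] * params.clf_w                  # N x E
    dA = dH_slide @ H.T                                         # N x K
    dH = A.T @ dH_slide                                         # K x E

    # instance clustering head (gradient flows through H at the selection)
    if assign is not None:
        dscore *= c2
        grads["inst_w"][y] += dscore.T @ H[sel]
        grads["inst_b"][y] += dscore.sum(axis=0)
        np.add.at(dH, sel, dscore @ params.inst_w[y])

    # softmax over patches, branch by branch
    row_dot = np.sum(A * dA, axis=1, keepdims=True)
    dE = A * (dA - row_dot)                                     # N x K
    gd = cache_a["gd"]
    grads["heads_w"] += dE @ gd                                 # N x attn
    grads["heads_b"] += dE.sum(axis=1)
    dGd = dE.T @ params.heads_w                                 # K x attn
    dG = dGd * cache_a["m3"]
    u, v = cache_a["u"], cache_a["v"]
    dZu = dG * v * (1.0 - u ** 2)
    dZv = dG * u * v * (1.0 - v)
    grads["attn1_w"] += dZu.T @ H
    grads["attn1_b"] += dZu.sum(axis=0)
    grads["attn2_w"] += dZv.T @ H
    grads["attn2_b"] += dZv.sum(axis=0)
    dH += dZu @ params.attn1_w + dZv @ params.attn2_w

    # Fc stack
    dA2 = dH * cache_e["m2"]
    dZ2 = dA2 * (cache_e["z2"] > 0)
    grads["fc2_w"] += dZ2.T @ cache_e["d1"]
    grads["fc2_b"] += dZ2.sum(axis=0)
    dD1 = dZ2 @ params.fc2_w
    dA1 = dD1 * cache_e["m1"]
    dZ1 = dA1 * (cache_e["z1"] > 0)
    grads["fc1_w"] += dZ1.T @ cache_e["x"]
    grads["fc1_b"] += dZ1.sum(axis=0)
    return loss, grads


class _Adam:
    """Standard Adam with bias correction, one slot per parameter."""

    def __init__(self, params: MilParams, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.arrays().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.arrays().items()}

    def step(self, params: MilParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.lr * (self.m[k] / b1t)
                      / (np.sqrt(self.v[k] / b2t) + self.eps))
            getattr(params, k)[...] -= update


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str | Path, params: MilParams,
                    config: MilConfig) -> Path:
    """Single-archive checkpoint: all tensors + the config as JSON."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(config)).encode(), dtype=np.uint8),
        **params.arrays())
    return path


def load_checkpoint(path: str | Path) -> tuple[MilParams, MilConfig]:
    with np.load(path) as data:
        config = MilConfig(**json.loads(bytes(data["__config__"]).decode()))
        params = MilParams(**{k: data[k] for k in MilParams.__dataclass_fields__})
    return params, config


# ---------------------------------------------------------------------------
# estimator


class GatedAttentionMIL(BaseEstimator, ClassifierMixin):
    """Scikit-learn style gated-attention MIL classifier.

    Parameters mirror :class:`MilConfig` plus the training protocol:
    Adam at ``learning_rate`` with batch size one, at most ``max_epochs``
    epochs, early stopping when the validation loss has not improved (by
    at least ``min_improvement``) for ``patience`` consecutive epochs,
    returning the parameters of the best-validation-loss epoch.

    ``X`` in :meth:`fit` / :meth:`predict_proba` is a sequence of bags,
    each a ``(K_i, input_dim)`` array (or a :class:`FeatureBag`).

    Examples
    --------
    >>> from hemamil import SyntheticBagSpec, generate_feature_bags
    >>> spec = SyntheticBagSpec(n_classes=3, feature_dim=32, separation=6.0,
    ...                         bags_per_class=12, seed=0)
    >>> bags = generate_feature_bags(spec)
    >>> X = [b.features for b, _ in bags]
    >>> y = [b.label for b, _ in bags]
    >>> clf = GatedAttentionMIL(n_classes=3, embed_dim=64, attn_dim=48,
    ...                         max_epochs=30, random_state=0).fit(X, y)
    >>> clf.predict_proba(X).shape
    (36, 3)
    """

    def __init__(
        self,
        n_classes: int = 5,
        input_dim: int | None = None,
        embed_dim: int = 512,
        attn_dim: int = 384,
        dropout: float = 0.3,
        B: int = 8,
        bag_loss_weight: float = 0.7,
        instance_loss_weight: float = 0.3,
        svm_tau: float = 1.0,
        learning_rate: float = 2e-4,
        max_epochs: int = 200,
        patience: int = 20,
        min_improvement: float = 1e-6,
        val_fraction: float = 0.2,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.n_classes = n_classes
        self.input_dim = input_dim
        self.embed_dim = embed_dim
        self.attn_dim = attn_dim
        self.dropout = dropout
        self.B = B
        self.bag_loss_weight = bag_loss_weight
        self.instance_loss_weight = instance_loss_weight
        self.svm_tau = svm_tau
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_improvement = min_improvement
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _as_matrix(bag) -> np.ndarray:
        feats = getattr(bag, "features", bag)
        feats = np.asarray(feats, dtype=np.float64)
        if feats.ndim != 2:
            raise ValueError("each bag must be a K x D matrix")
        return feats

    def _mean_loss(self, bags, y, params, config) -> float:
        losses = [
            _forward_backward(b, int(lbl), params, config, rng=None,
                              training=False)[0]
            for b, lbl in zip(bags, y)
        ]
        return float(np.mean(losses))

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y, val_X=None, val_y=None, val_loss_fn=None):
        """Train on bags ``X`` with slide labels ``y``.

        When no validation bags are given, a stratified ``val_fraction``
        of the training bags is held out for early stopping.
        ``val_loss_fn(params, epoch) -> float`` optionally replaces the
        validation-loss evaluation (e.g. to stop on a custom metric).
        """
        bags = [self._as_matrix(b) for b in X]
        y = np.asarray(y, dtype=np.int64)
        if len(bags) != y.size or len(bags) == 0:
            raise ValueError("X and y must be equal-length and nonempty")
        self.classes_ = np.arange(self.n_classes)
        if y.min() < 0 or y.max() >= self.n_classes:
            raise ValueError("labels must lie in [0, n_classes)")
        input_dim = self.input_dim or bags[0].shape[1]
        config = MilConfig(
            n_classes=self.n_classes, input_dim=input_dim,
            embed_dim=self.embed_dim, attn_dim=self.attn_dim,
            dropout_p=self.dropout, B=self.B,
            bag_loss_weight=self.bag_loss_weight,
            instance_loss_weight=self.instance_loss_weight,
            svm_tau=self.svm_tau,
        )
        root = np.random.SeedSequence(self.random_state)
        init_rng, drop_rng, split_rng, shuffle_ss = [
            np.random.default_rng(s) if i < 3 else s
            for i, s in enumerate(root.spawn(4))
        ]

        if val_X is not None:
            train_bags, train_y = bags, y
            vbags = [self._as_matrix(b) for b in val_X]
            vy = np.asarray(val_y, dtype=np.int64)
        elif val_loss_fn is None and self.val_fraction > 0:
            val_idx = []
            for c in np.unique(y):
                members = np.flatnonzero(y == c)
                n_val = max(1, int(round(self.val_fraction * members.size)))
                if n_val >= members.size:
                    n_val = max(members.size - 1, 0)
                val_idx.extend(split_rng.permutation(members)[:n_val])
            val_idx = np.asarray(sorted(val_idx))
            train_idx = np.setdiff1d(np.arange(y.size), val_idx)
            if train_idx.size == 0:
                raise ValueError("no training bags left after validation split")
            train_bags = [bags[i] for i in train_idx]
            train_y = y[train_idx]
            vbags = [bags[i] for i in val_idx]
            vy = y[val_idx]
        else:
            train_bags, train_y = bags, y
            vbags, vy = [], np.empty(0, dtype=np.int64)

        params = init_params(config, init_rng)
        opt = _Adam(params, lr=self.learning_rate)
        best_params = params.copy()
        best_val = np.inf
        best_epoch = 0
        epochs_since_best = 0
        history = {"epoch": [], "train_loss": [], "val_loss": []}

        for epoch in range(1, self.max_epochs + 1):
            # fresh per-epoch order from a derived seed: reproducible
            epoch_rng = np.random.default_rng(
                np.random.SeedSequence([int(shuffle_ss.generate_state(1)[0]
                                            % (2 ** 31)), epoch]))
            order = epoch_rng.permutation(len(train_bags))
            epoch_losses = []
            for i in order:
                loss, grads = _forward_backward(
                    train_bags[i], int(train_y[i]), params, config,
                    rng=drop_rng, training=True)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch "
                        f"{epoch}, bag {i}")
                opt.step(params, grads)
                epoch_losses.append(loss)
            train_loss = float(np.mean(epoch_losses))

            if val_loss_fn is not None:
                val_loss = float(val_loss_fn(params, epoch))
            elif len(vbags):
                val_loss = self._mean_loss(vbags, vy, params, config)
            else:
                val_loss = train_loss
            history["epoch"].append(epoch)
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if self.verbose:
                print(f"epoch {epoch:3d}  train {train_loss:.4f}  "
                      f"val {val_loss:.4f}")

            if val_loss < best_val - self.min_improvement:
                best_val = val_loss
                best_epoch = epoch
                best_params = params.copy()
                epochs_since_best = 0
            else:
                epochs_since_best += 1
                if epochs_since_best >= self.patience:
                    break

        self.config_ = config
        self.params_ = best_params
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_val)
        self.history_ = history
        self.n_features_in_ = input_dim
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")

    def forward(self, bag) -> AttentionResult:
        """Full deterministic forward pass for one bag."""
        self._check_fitted()
        return forward(self._as_matrix(bag), self.params_, self.config_)

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return np.stack([self.forward(b).probs for b in X])

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def attention(self, bag) -> np.ndarray:
        """N x K attention distributions for one bag."""
        return self.forward(bag).A

    def slide_representation(self, bag, branch: int | None = None) -> np.ndarray:
        """Class-specific slide representation(s); by default the
        predicted class's branch (the slide-level feature used for PCA
        visualization)."""
        res = self.forward(bag)
        if branch is None:
            branch = int(np.argmax(res.probs))
        return res.H_slide[branch]

    def save(self, path: str | Path) -> Path:
        self._check_fitted()
        return save_checkpoint(path, self.params_, self.config_)

    @classmethod
    def from_checkpoint(cls, path: str | Path) -> "GatedAttentionMIL":
        params, config = load_checkpoint(path)
        est = cls(n_classes=config.n_classes, input_dim=config.input_dim,
                  embed_dim=config.embed_dim, attn_dim=config.attn_dim,
                  dropout=config.dropout_p, B=config.B,
                  bag_loss_weight=config.bag_loss_weight,
                  instance_loss_weight=config.instance_loss_weight,
                  svm_tau=config.svm_tau)
        est.config_ = config
        est.params_ = params
        est.classes_ = np.arange(config.n_classes)
        est.n_features_in_ = config.input_dim
        return est
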