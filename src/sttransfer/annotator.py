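"""Dual autoencoder / graph-autoencoder annotator with teacher distillation.

The spatial VAE embedding TTI is compressed by a dense autoencoder
(FC-BatchNorm-ELU-Dropout twice) into X, propagated over the spatial graph
by a two-layer graph convolution encoder into S, and fused as Z = X + S.
Three objectives are minimized jointly:

* reconstruction of TTI from X (mean squared error, L_AE);
* reconstruction of the adjacency from Z via the inner-product decoder
  A' = sigmoid(Z Z^T) (binary cross-entropy, L_GAE);
* distillation of the teacher distribution D into the linear-softmax
  student P = softmax(Z W_student + b_student) (cross-entropy normalized
  by n*c, L_SSL).

L_total = w_dae * L_AE + w_gae * L_GAE + w_cls * L_SSL. The final label of
each spatial cell is the argmax of the student probabilities at inference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from ._nn import Adam, BatchNorm1d, Dropout, Linear, Module, Tensor, as_tensor, spmm
from .graph import SpatialGraph, normalize_adjacency
from .teacher import TeacherDistribution
from .vae import LatentEmbedding

logger = logging.getLogger(__name__)

_EPS = 1e-7
# above this many cells the full n^2 adjacency BCE is replaced by the
# positive-edges + sampled-negatives estimator
FULL_BCE_MAX_CELLS = 2000


@dataclass
class AnnotatorConfig:
    k1: int = 128          # AE hidden width
    k: int = 30            # AE latent width; matches the VAE latent so Z = X + S is well-typed
    dropout_p: float = 0.2
    epochs: int = 200
    w_cls: float = 20.0    # W_SSL
    w_dae: float = 1.0     # W_AE
    w_gae: float = 1.0     # W_GAE
    learning_rate: float = 1e-3
    binarize_adjacency: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.w_cls < 0 or self.w_dae < 0 or self.w_gae < 0:
            raise ValueError("loss weights must be non-negative")
        if self.w_cls == 0 and self.w_dae == 0 and self.w_gae == 0:
            raise ValueError("at least one loss weight must be positive")
        if self.k > self.k1:
            raise ValueError("latent width k must not exceed hidden width k1")


class _Net(Module):
    def __init__(self, d: int, n_classes: int, cfg: AnnotatorConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        p = cfg.dropout_p
        # AE encoder: FC -> BN -> ELU -> Dropout, twice
        self.enc1 = Linear(d, cfg.k1, rng)
        self.enc1_bn = BatchNorm1d(cfg.k1)
        self.enc1_drop = Dropout(p, self._dropout_rng)
        self.enc2 = Linear(cfg.k1, cfg.k, rng)
        self.enc2_bn = BatchNorm1d(cfg.k)
        self.enc2_drop = Dropout(p, self._dropout_rng)
        # AE decoder: FC -> BN -> ELU -> Dropout, then a final linear map
        self.dec1 = Linear(cfg.k, cfg.k1, rng)
        self.dec1_bn = BatchNorm1d(cfg.k1)
        self.dec1_drop = Dropout(p, self._dropout_rng)
        self.dec2 = Linear(cfg.k1, d, rng)
        # graph encoder: conv -> ReLU -> Dropout -> conv (no biases)
        self.gc1 = Linear(cfg.k, cfg.k, rng, bias=False)
        self.gc_drop = Dropout(p, self._dropout_rng)
        self.gc2 = Linear(cfg.k, cfg.k, rng, bias=False)
        # student head
        self.student = Linear(cfg.k, n_classes, rng)

    def encode(self, tti: Tensor) -> Tensor:
        h = self.enc1_drop(self.enc1_bn(self.enc1(tti)).elu())
        return self.enc2_drop(self.enc2_bn(self.enc2(h)).elu())

    def decode(self, x: Tensor) -> Tensor:
        h = self.dec1_drop(self.dec1_bn(self.dec1(x)).elu())
        return self.dec2(h)

    def graph_encode(self, x: Tensor, a_norm: sp.csr_matrix) -> Tensor:
        h = spmm(a_norm, self.gc1(x)).relu()
        return spmm(a_norm, self.gc2(self.gc_drop(h)))

    def student_log_probs(self, z: Tensor) -> Tensor:
        return self.student(z).log_softmax(axis=1)


class AnnotatorState:
    """Trained annotator: network weights, class order, config, loss log."""

    def __init__(self, net: _Net, classes: list[str], cfg: AnnotatorConfig, d_in: int):
        self.net = net
        self.classes = list(classes)
        self.cfg = cfg
        self.d_in = d_in
        self.loss_history: list[dict[str, float]] = []
        self.trained = False

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.net.state_arrays())
        manifest = {"classes": self.classes, "config": asdict(self.cfg),
                    "d_in": self.d_in, "trained": self.trained,
                    "loss_history": self.loss_history}
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AnnotatorState":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        cfg = AnnotatorConfig(**manifest["config"])
        net = _Net(manifest["d_in"], len(manifest["classes"]), cfg)
        with np.load(path / "weights.npz") as arrays:
            net.load_state_arrays({k: arrays[k] for k in arrays.files})
        state = cls(net, manifest["classes"], cfg, manifest["d_in"])
        state.trained = manifest["trained"]
        state.loss_history = manifest["loss_history"]
        net.eval()
        return state


# ---------------------------------------------------------------------------
# functional forward pieces (thin wrappers over the network)
# ---------------------------------------------------------------------------

def _as_matrix(tti) -> np.ndarray:
    return tti.values if isinstance(tti, LatentEmbedding) else np.asarray(tti, dtype=float)


def ae_encode(tti, state: AnnotatorState, training: bool = False) -> np.ndarray:
    """X: the dense-autoencoder latent of the spatial embedding."""
    x = _as_matrix(tti)
    if x.shape[1] != state.d_in:
        raise ValueError(f"input has {x.shape[1]} dims, annotator expects {state.d_in}")
    net = state.net.train() if training else state.net.eval()
    return net.encode(Tensor(x)).data


def ae_decode(x, state: AnnotatorState, training: bool = False) -> np.ndarray:
    """TTI': reconstruction of the spatial embedding from X."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] != state.cfg.k:
        raise ValueError(f"latent has {x.shape[1]} dims, expected k={state.cfg.k}")
    net = state.net.train() if training else state.net.eval()
    return net.decode(Tensor(x)).data


def graph_encode(x, g: SpatialGraph, state: AnnotatorState, training: bool = False) -> np.ndarray:
    """S: spatial embedding of X over the normalized adjacency."""
    x = np.asarray(x, dtype=float)
    if g.normalized is None:
        normalize_adjacency(g)
    if g.n_cells != x.shape[0]:
        raise ValueError(f"graph has {g.n_cells} nodes but embedding has {x.shape[0]} rows")
    net = state.net.train() if training else state.net.eval()
    return net.graph_encode(Tensor(x), g.normalized).data


def combine_latent(x, s):
    """Z = X + S, the fusion of expression and spatial latents."""
    x, s = np.asarray(x, dtype=float), np.asarray(s, dtype=float)
    if x.shape != s.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {s.shape}")
    return x + s


def graph_decode(z) -> np.ndarray:
    """A' = sigmoid(Z Z^T), the inner-product adjacency reconstruction."""
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("latent contains non-finite entries")
    return 1.0 / (1.0 + np.exp(-(z @ z.T)))


# ---------------------------------------------------------------------------
# losses (accept numpy arrays or Tensors; return a Tensor)
# ---------------------------------------------------------------------------

def loss_ae(tti, tti_prime) -> Tensor:
    """Mean squared reconstruction error over all n*d entries."""
    tti, tti_prime = as_tensor(tti), as_tensor(tti_prime)
    diff = tti - tti_prime
    return (diff * diff).mean()


def loss_gae(a, a_prime) -> Tensor:
    """Mean binary cross-entropy between adjacency targets in [0,1] and
    reconstructed probabilities, over the evaluated entries."""
    a = as_tensor(a)
    a_prime = as_tensor(a_prime)
    lo, hi = _EPS, 1.0 - _EPS
    if (a_prime.data <= 0).any() or (a_prime.data >= 1).any():
        logger.warning("adjacency reconstruction hit {0,1}; clamping to [%g, %g]", lo, hi)
    clamped = Tensor(np.clip(a_prime.data, lo, hi), parents=(a_prime,),
                     backward=lambda g: a_prime._accum(
                         g * ((a_prime.data > lo) & (a_prime.data < hi))))
    return -(a * clamped.log() + (1.0 - a) * (1.0 - clamped).log()).mean()


def loss_ssl(d, p) -> Tensor:
    """Distillation cross-entropy -1/(n*c) sum_ij D[i,j] log P[i,j].

    Note the 1/(n*c) normalization: the loss is smaller than standard
    cross-entropy by the class count; the weight w_cls absorbs this.
    """
    d_mat = d.probs if isinstance(d, TeacherDistribution) else np.asarray(d, dtype=float)
    p = as_tensor(p)
    if d_mat.shape != p.data.shape:
        raise ValueError(f"shape mismatch: D {d_mat.shape} vs P {p.data.shape}")
    logp = Tensor(np.log(np.clip(p.data, _EPS, None)), parents=(p,),
                  backward=lambda g: p._accum(g / np.clip(p.data, _EPS, None)))
    return -(as_tensor(d_mat) * logp).mean()


def total_loss(l_ae, l_gae, l_ssl, cfg: AnnotatorConfig) -> Tensor:
    """L_total = w_dae * L_AE + w_gae * L_GAE + w_cls * L_SSL."""
    if cfg.w_cls == 0 and cfg.w_dae == 0 and cfg.w_gae == 0:
        raise ValueError("at least one loss weight must be positive")
    return (as_tensor(l_ae) * cfg.w_dae + as_tensor(l_gae) * cfg.w_gae
            + as_tensor(l_ssl) * cfg.w_cls)


# ---------------------------------------------------------------------------
# adjacency-reconstruction targets
# ---------------------------------------------------------------------------

def _bce_from_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable BCE-with-logits, mean over entries."""
    # softplus(x) - t*x  ==  -[t log s(x) + (1-t) log(1-s(x))]
    return (logits.softplus() - as_tensor(targets) * logits).mean()


def _pair_logits(z: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Fused <z_i, z_j> over index pairs: one autograd node with a
    bincount-based scatter backward (much faster than gather + multiply
    + np.add.at for the ~1e5 pairs a training epoch evaluates)."""
    a = z.data[rows]
    b = z.data[cols]
    out = np.einsum("ij,ij->i", a, b)

    def bw(g):
        if not z.requires_grad:
            return
        n, k = z.data.shape
        grad = np.empty_like(z.data)
        ga = g[:, None] * b
        gb = g[:, None] * a
        for j in range(k):
            grad[:, j] = (np.bincount(rows, weights=ga[:, j], minlength=n)
                          + np.bincount(cols, weights=gb[:, j], minlength=n))
        z._accum(grad)

    return Tensor(out, parents=(z,), backward=bw)


def adjacency_bce_exact(z: Tensor, g: SpatialGraph, binarize: bool = True) -> Tensor:
    """Class-balanced adjacency BCE over all n^2 entries (small graphs).

    Positive entries are the graph's edges plus the diagonal (a cell
    trivially reconstructs itself); the loss is the average of the mean BCE
    over positives and the mean BCE over negatives, so edge sparsity does
    not drown the positive class.
    """
    n = g.n_cells
    a = g.binarized() if binarize else g.adjacency
    target = np.asarray(a.todense(), dtype=float)
    np.fill_diagonal(target, 1.0)
    zt = Tensor(z.data.T, parents=(z,), backward=lambda g_: z._accum(g_.T))
    logits = z @ zt
    pos_mask = target > 0
    sp_ = logits.softplus() - as_tensor(target) * logits
    pos_loss = (sp_ * pos_mask).sum() * (1.0 / pos_mask.sum())
    neg_loss = (sp_ * (~pos_mask)).sum() * (1.0 / max((~pos_mask).sum(), 1))
    return (pos_loss + neg_loss) * 0.5


class _EdgeCache:
    """Precomputed positive entries (edges + diagonal) of a graph, reused
    across training epochs."""

    def __init__(self, g: SpatialGraph, binarize: bool):
        n = g.n_cells
        coo = g.adjacency.tocoo()
        self.n = n
        self.rows = np.concatenate([coo.row, np.arange(n)])
        self.cols = np.concatenate([coo.col, np.arange(n)])
        self.targets = (np.ones(len(self.rows)) if binarize
                        else np.concatenate([coo.data, np.ones(n)]))
        self.keys = np.sort(self.rows.astype(np.int64) * n + self.cols)

    def sample_negatives(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        n, n_pos = self.n, len(self.rows)
        neg = np.empty(0, dtype=np.int64)
        while len(neg) < n_pos:
            cand = rng.integers(0, n * n, size=int(1.2 * n_pos), dtype=np.int64)
            cand = cand[~np.isin(cand, self.keys)]
            cand = cand[cand // n != cand % n]
            neg = np.concatenate([neg, cand])
        neg = neg[:n_pos]
        return neg // n, neg % n


def adjacency_bce_sampled(z: Tensor, g: SpatialGraph, rng: np.random.Generator,
                          binarize: bool = True, cache: _EdgeCache | None = None) -> Tensor:
    """Unbiased estimator of the balanced adjacency BCE for large graphs:
    all positive entries (edges + diagonal) plus an equal number of
    uniformly sampled negative pairs."""
    cache = cache or _EdgeCache(g, binarize)
    neg_rows, neg_cols = cache.sample_negatives(rng)
    pos_logits = _pair_logits(z, cache.rows, cache.cols)
    neg_logits = _pair_logits(z, neg_rows, neg_cols)
    pos_loss = (pos_logits.softplus() - as_tensor(cache.targets) * pos_logits).mean()
    neg_loss = neg_logits.softplus().mean()
    return (pos_loss + neg_loss) * 0.5


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def train_annotator(tti: LatentEmbedding, g: SpatialGraph, d: TeacherDistribution,
                    cfg: AnnotatorConfig | None = None) -> AnnotatorState:
    """Full-batch joint training of AE, GAE and student on L_total.

    The teacher distribution D is frozen throughout. Deterministic given
    cfg.seed under single-threaded execution.
    """
    cfg = cfg or AnnotatorConfig()
    x_in = tti.values
    n, d_in = x_in.shape
    if g.n_cells != n or d.probs.shape[0] != n:
        raise ValueError(
            f"size mismatch: embedding {n}, graph {g.n_cells}, teacher {d.probs.shape[0]}")
    if g.normalized is None:
        normalize_adjacency(g)

    net = _Net(d_in, len(d.classes), cfg)
    state = AnnotatorState(net, d.classes, cfg, d_in)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    neg_rng = np.random.default_rng(cfg.seed + 1)
    use_sampled = n > FULL_BCE_MAX_CELLS
    edge_cache = _EdgeCache(g, cfg.binarize_adjacency) if use_sampled else None

    net.train()
    for epoch in range(cfg.epochs):
        x = net.encode(Tensor(x_in))
        losses = {"ae": 0.0, "gae": 0.0, "ssl": 0.0}
        terms = []
        z = x + net.graph_encode(x, g.normalized)
        if cfg.w_dae > 0:
            l_ae = loss_ae(x_in, net.decode(x))
            losses["ae"] = float(l_ae.data)
            terms.append(l_ae * cfg.w_dae)
        if cfg.w_gae > 0:
            if use_sampled:
                l_gae = adjacency_bce_sampled(z, g, neg_rng,
                                              binarize=cfg.binarize_adjacency,
                                              cache=edge_cache)
            else:
                l_gae = adjacency_bce_exact(z, g, binarize=cfg.binarize_adjacency)
            losses["gae"] = float(l_gae.data)
            terms.append(l_gae * cfg.w_gae)
        if cfg.w_cls > 0:
            logp = net.student_log_probs(z)
            l_ssl = -(as_tensor(d.probs) * logp).mean()
            losses["ssl"] = float(l_ssl.data)
            terms.append(l_ssl * cfg.w_cls)
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        if not np.isfinite(total.data):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch} (lr={cfg.learning_rate}); "
                f"sub-losses: {losses}")
        opt.zero_grad()
        total.backward()
        opt.step()
        losses["total"] = float(total.data)
        state.loss_history.append(losses)
        if epoch % 50 == 0 or epoch == cfg.epochs - 1:
            logger.info("annotator epoch %d: total %.4f (ae %.4f gae %.4f ssl %.4f)",
                        epoch, losses["total"], losses["ae"], losses["gae"], losses["ssl"])
    net.eval()
    state.trained = True
    return state


def predict_labels(state: AnnotatorState, tti: LatentEmbedding,
                   g: SpatialGraph) -> tuple[np.ndarray, np.ndarray]:
    """Final labels: argmax of P = softmax(Z W_student + b_student), eval mode."""
    if not state.trained:
        raise ValueError("annotator has not been trained")
    if g.normalized is None:
        normalize_adjacency(g)
    net = state.net.eval()
    x = net.encode(Tensor(tti.values))
    z = x + net.graph_encode(x, g.normalized)
    probs = np.exp(net.student_log_probs(z).data)
    probs /= probs.sum(axis=1, keepdims=True)
    labels = np.asarray(state.classes, dtype=object)[probs.argmax(axis=1)]
    return labels, probs
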