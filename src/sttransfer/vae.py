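"""Batch harmonization of reference and spatial counts with a conditional VAE.

One joint variational autoencoder is trained on the concatenated,
gene-aligned count matrices of both modalities, with the modality ("batch")
as a conditioning covariate for encoder and decoder. The likelihood is a
negative binomial whose mean is the observed library size times a softmax
gene-proportion decoder output, with a free per-gene inverse-dispersion —
the standard count model for this task. The embedding handed downstream is
the posterior mean, so repeated encodings are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._nn import Adam, Linear, Module, Tensor, concat
from .io import ExpressionDataset

logger = logging.getLogger(__name__)

BATCH_CATEGORIES = ("reference", "spatial")


@dataclass
class VAEConfig:
    latent_dim: int = 30
    hidden_dim: int = 128
    decoder_layers: int = 2
    max_epochs: int = 400
    batch_size: int = 256
    learning_rate: float = 1e-3
    kl_weight: float = 1.0
    kl_warmup_epochs: int = 50  # linear KL annealing; guards against posterior collapse
    early_stopping_patience: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim <= 0 or self.hidden_dim <= 0 or self.decoder_layers <= 0:
            raise ValueError("all dimensions must be positive")
        if self.latent_dim >= self.hidden_dim:
            raise ValueError("latent_dim must be smaller than hidden_dim")


@dataclass
class LatentEmbedding:
    """Cells x k real matrix tied to cell ids; ``source`` names the modality."""

    values: np.ndarray
    cell_ids: list[str]
    source: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("embedding must be 2-D")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length does not match embedding rows")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


class VAEModel(Module):
    def __init__(self, n_genes: int, cfg: VAEConfig):
        super().__init__()
        self.cfg = cfg
        self.gene_ids: list[str] = []
        rng = np.random.default_rng(cfg.seed)
        nb = len(BATCH_CATEGORIES)
        self.enc_hidden = Linear(n_genes + nb, cfg.hidden_dim, rng)
        self.enc_mu = Linear(cfg.hidden_dim, cfg.latent_dim, rng)
        self.enc_logvar = Linear(cfg.hidden_dim, cfg.latent_dim, rng)
        dec: list[Linear] = []
        width_in = cfg.latent_dim + nb
        for _ in range(cfg.decoder_layers):
            dec.append(Linear(width_in, cfg.hidden_dim, rng))
            width_in = cfg.hidden_dim
        self.dec_hidden = dec
        self.dec_scale = Linear(cfg.hidden_dim, n_genes, rng)
        self.log_theta = Tensor(np.zeros(n_genes), requires_grad=True)

    # -- forward pieces ----------------------------------------------------
    def encode(self, x_log: np.ndarray, batch_onehot: np.ndarray) -> tuple[Tensor, Tensor]:
        h = concat([Tensor(x_log), Tensor(batch_onehot)], axis=1)
        h = self.enc_hidden(h).relu()
        return self.enc_mu(h), self.enc_logvar(h)

    def decode_scale(self, z: Tensor, batch_onehot: np.ndarray) -> Tensor:
        h = concat([z, Tensor(batch_onehot)], axis=1)
        for layer in self.dec_hidden:
            h = layer(h).relu()
        return self.dec_scale(h).softmax(axis=1)

    def elbo_loss(self, x: np.ndarray, batch_onehot: np.ndarray,
                  rng: np.random.Generator, kl_scale: float = 1.0,
                  lgamma_x1: np.ndarray | None = None) -> Tensor:
        """Negative ELBO, mean per cell (NB reconstruction + KL).

        ``lgamma_x1`` may carry precomputed per-cell sums of log Gamma(x+1)
        (a constant of the data) to avoid recomputing them every step.
        """
        from scipy.special import gammaln

        if lgamma_x1 is None:
            lgamma_x1 = gammaln(x + 1.0).sum(axis=1)
        lib = np.maximum(x.sum(axis=1, keepdims=True), 1.0)
        mu_q, logvar = self.encode(np.log1p(x), batch_onehot)
        eps = rng.standard_normal(mu_q.data.shape)
        z = mu_q + (logvar * 0.5).exp() * eps
        rho = self.decode_scale(z, batch_onehot).clip_min(1e-10)
        mean = rho * lib
        theta = self.log_theta.exp()
        xt = Tensor(x)
        log_theta_mu = (theta + mean).log()
        ll = ((xt + theta).lgamma() - theta.lgamma()
              + theta * (theta.log() - log_theta_mu)
              + xt * (mean.log() - log_theta_mu))
        recon = -(ll.sum(axis=1) - lgamma_x1).mean()
        kl = (-0.5 * (1.0 + logvar - mu_q * mu_q - logvar.exp()).sum(axis=1)).mean()
        return recon + self.cfg.kl_weight * kl_scale * kl

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.state_arrays())
        manifest = {"config": asdict(self.cfg), "gene_ids": self.gene_ids,
                    "n_genes": len(self.gene_ids)}
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "VAEModel":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        model = cls(manifest["n_genes"], VAEConfig(**manifest["config"]))
        model.gene_ids = manifest["gene_ids"]
        with np.load(path / "weights.npz") as arrays:
            state = {k: arrays[k] for k in arrays.files}
        model.load_state_arrays(state)
        model.eval()
        return model


def _batch_onehot(batches: np.ndarray) -> np.ndarray:
    onehot = np.zeros((len(batches), len(BATCH_CATEGORIES)))
    for j, cat in enumerate(BATCH_CATEGORIES):
        onehot[batches == cat, j] = 1.0
    return onehot


def fit_vae(ref: ExpressionDataset, spatial: ExpressionDataset,
            cfg: VAEConfig | None = None) -> VAEModel:
    """Train one joint conditional VAE on both gene-aligned modalities.

    Training is full-shuffle minibatch Adam, seeded from ``cfg.seed``; it
    stops early when the epoch-mean negative ELBO stops improving for
    ``early_stopping_patience`` epochs.
    """
    cfg = cfg or VAEConfig()
    if ref.gene_ids != spatial.gene_ids:
        raise ValueError("datasets must be gene-aligned before VAE training (run align_genes)")
    if ref.batch == spatial.batch:
        raise ValueError("need two distinct batches to harmonize; got one")
    x = np.concatenate([ref.counts, spatial.counts]).astype(np.float64)
    if np.isnan(x).any():
        raise ValueError("counts contain NaNs")
    batches = np.array([ref.batch] * ref.n_cells + [spatial.batch] * spatial.n_cells)
    onehot = _batch_onehot(batches)

    model = VAEModel(x.shape[1], cfg)
    model.gene_ids = list(ref.gene_ids)
    model.train()
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    from scipy.special import gammaln

    n = x.shape[0]
    lgamma_x1 = gammaln(x + 1.0).sum(axis=1)
    best = np.inf
    stale = 0
    for epoch in range(cfg.max_epochs):
        kl_scale = min(1.0, (epoch + 1) / max(cfg.kl_warmup_epochs, 1))
        order = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            loss = model.elbo_loss(x[idx], onehot[idx], rng, kl_scale,
                                   lgamma_x1=lgamma_x1[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        epoch_loss = total / n
        if epoch % 25 == 0 or epoch == cfg.max_epochs - 1:
            logger.info("VAE epoch %d: -ELBO %.4f", epoch, epoch_loss)
        if epoch < cfg.kl_warmup_epochs:
            continue  # the loss scale shifts during annealing; don't early-stop yet
        if not np.isfinite(best) or epoch_loss < best - 1e-3 * abs(best):
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stopping_patience:
                logger.info("VAE early stop at epoch %d (-ELBO %.4f)", epoch, best)
                break
    model.eval()
    return model


def encode_cells(model: VAEModel, data: ExpressionDataset) -> LatentEmbedding:
    """Posterior-mean embedding of a gene-aligned dataset (deterministic)."""
    if model.gene_ids and data.gene_ids != model.gene_ids:
        raise ValueError("dataset gene order does not match the model's training genes")
    onehot = _batch_onehot(np.array([data.batch] * data.n_cells))
    mu, _ = model.encode(np.log1p(data.counts.astype(np.float64)), onehot)
    return LatentEmbedding(values=mu.data, cell_ids=list(data.cell_ids), source=data.batch)


def knn_batch_mixing_entropy(values: np.ndarray, batches: np.ndarray, k: int = 20) -> float:
    """Mean per-cell entropy of batch composition among the k nearest
    neighbors — higher means better mixing of the two modalities."""
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=min(k + 1, len(values))).fit(values)
    _, idx = nn.kneighbors(values)
    idx = idx[:, 1:]  # drop self
    cats = np.unique(batches)
    ent = np.zeros(len(values))
    for cat in cats:
        frac = (batches[idx] == cat).mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(frac > 0, -frac * np.log(frac), 0.0)
        ent += term
    return float(ent.mean())
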