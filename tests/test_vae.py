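"""Integration-stage tests: small, seeded VAE fits on synthetic counts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import silhouette_score
from sklearn.model_selection import cross_val_score

from sttransfer.io import ExpressionDataset
from sttransfer.simulate import SyntheticReferenceSpec, make_synthetic_reference
from sttransfer.vae import (VAEConfig, VAEModel, encode_cells, fit_vae,
                            knn_batch_mixing_entropy)


def make_pair(seed, n_types=2, cells=150, genes=100, shift_sd=0.3):
    """Reference plus a depth/batch-shifted copy as the 'spatial' modality."""
    spec = SyntheticReferenceSpec(n_types=n_types, cells_per_type=cells,
                                  n_genes=genes,
                                  signature_genes_per_type=max(8, genes // 10),
                                  seed=seed)
    ref = make_synthetic_reference(spec)
    keep = np.asarray(ref.labels) != "background"
    ref = ExpressionDataset(ref.counts[keep], ref.gene_ids,
                            list(np.asarray(ref.cell_ids)[keep]),
                            labels=pd.Categorical(np.asarray(ref.labels)[keep]),
                            batch="reference")
    rng = np.random.default_rng(seed + 1000)
    shift = rng.lognormal(0.0, shift_sd, size=ref.n_genes)
    st = ExpressionDataset(np.round(ref.counts * shift).astype(np.int64),
                           ref.gene_ids,
                           [f"s{i}" for i in range(ref.n_cells)],
                           coords=rng.uniform(0, 1, size=(ref.n_cells, 2)),
                           labels=ref.labels, batch="spatial")
    return ref, st


@pytest.fixture(scope="module")
def fitted():
    ref, st = make_pair(seed=1)
    cfg = VAEConfig(max_epochs=120, kl_warmup_epochs=30, seed=2)
    model = fit_vae(ref, st, cfg)
    return ref, st, model


class TestConfig:
    def test_dimension_invariants(self):
        with pytest.raises(ValueError):
            VAEConfig(latent_dim=0)
        with pytest.raises(ValueError):
            VAEConfig(latent_dim=128, hidden_dim=128)


class TestFit:
    def test_single_batch_errors(self):
        ref, _ = make_pair(seed=3, cells=20, genes=60)
        other = ExpressionDataset(ref.counts, ref.gene_ids,
                                  [f"x{i}" for i in range(ref.n_cells)],
                                  labels=ref.labels, batch="reference")
        with pytest.raises(ValueError, match="two distinct batches"):
            fit_vae(ref, other, VAEConfig(max_epochs=1))

    def test_unaligned_genes_error(self):
        ref, st = make_pair(seed=4, cells=20, genes=60)
        st.gene_ids = list(reversed(st.gene_ids))
        with pytest.raises(ValueError, match="gene-aligned"):
            fit_vae(ref, st, VAEConfig(max_epochs=1))

    def test_latent_dim_contract(self, fitted):
        ref, st, model = fitted
        emb = encode_cells(model, ref)
        assert emb.values.shape == (ref.n_cells, 30)


class TestEncode:
    def test_posterior_mean_is_deterministic(self, fitted):
        ref, _, model = fitted
        a = encode_cells(model, ref)
        b = encode_cells(model, ref)
        np.testing.assert_array_equal(a.values, b.values)

    def test_gene_order_mismatch_rejected(self, fitted):
        ref, _, model = fitted
        shuffled = ExpressionDataset(ref.counts[:, ::-1],
                                     list(reversed(ref.gene_ids)),
                                     ref.cell_ids, labels=ref.labels,
                                     batch="reference")
        with pytest.raises(ValueError, match="gene order"):
            encode_cells(model, shuffled)

    def test_types_linearly_separable_in_latent(self, fitted):
        ref, _, model = fitted
        emb = encode_cells(model, ref)
        acc = cross_val_score(LogisticRegression(max_iter=2000), emb.values,
                              np.asarray(ref.labels), cv=3).mean()
        assert acc >= 0.95

    def test_type_silhouette_nonnegative(self, fitted):
        ref, _, model = fitted
        emb = encode_cells(model, ref)
        assert silhouette_score(emb.values, np.asarray(ref.labels)) >= 0.0


def _mixing_embeddings(seed):
    ref, st = make_pair(seed=30 + seed, cells=100, genes=80)
    model = fit_vae(ref, st, VAEConfig(max_epochs=150, kl_warmup_epochs=30,
                                       seed=seed))
    a = encode_cells(model, ref).values
    b = encode_cells(model, st).values
    x = np.concatenate([ref.counts, st.counts]).astype(float)
    x = np.log1p(x / np.maximum(x.sum(1, keepdims=True), 1) * 1e4)
    pca = PCA(n_components=30, random_state=0).fit_transform(x)
    return a, b, pca[:ref.n_cells], pca[ref.n_cells:]


@pytest.fixture(scope="module")
def seeds():
    return [_mixing_embeddings(seed) for seed in range(5)]


class TestBatchMixing:
    """Matched ref/spatial cells differing only by a per-gene batch factor:
    the conditional VAE should mix the modalities better than joint
    log-count PCA (averaged over 5 seeds)."""

    @staticmethod
    def _rel_pair_dist(a, b, rng):
        # matched-pair distance relative to random-pair distance, so the
        # comparison is invariant to the overall scale of each embedding
        matched = np.linalg.norm(a - b, axis=1).mean()
        random = np.linalg.norm(a - b[rng.permutation(len(b))], axis=1).mean()
        return matched / random

    def test_knn_batch_entropy_exceeds_pca(self, seeds):
        gains = []
        for a, b, pa, pb in seeds:
            batches = np.array(["reference"] * len(a) + ["spatial"] * len(b))
            gains.append(
                knn_batch_mixing_entropy(np.concatenate([a, b]), batches)
                - knn_batch_mixing_entropy(np.concatenate([pa, pb]), batches))
        assert np.mean(gains) > 0

    def test_matched_pairs_closer_after_integration(self, seeds):
        ratios_vae, ratios_pca = [], []
        for i, (a, b, pa, pb) in enumerate(seeds):
            rng = np.random.default_rng(i)
            ratios_vae.append(self._rel_pair_dist(a, b, rng))
            ratios_pca.append(self._rel_pair_dist(pa, pb, rng))
        assert np.mean(ratios_vae) < np.mean(ratios_pca)


class TestPersistence:
    def test_model_round_trips_through_disk(self, fitted, tmp_path):
        ref, _, model = fitted
        model.save(tmp_path / "vae")
        back = VAEModel.load(tmp_path / "vae")
        np.testing.assert_allclose(encode_cells(back, ref).values,
                                   encode_cells(model, ref).values, atol=1e-12)
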