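"""Union-of-subspaces synthetic expression data with known structure.

The generator emulates the structural assumptions of the low-rank
representation model: samples from each tumor class lie on a distinct
low-dimensional linear subspace of gene space, observations carry dense
Gaussian noise plus a sparse set of gross corruptions, and a few
designated "salient" genes carry a strong class-independent signature
(ground truth for the gene-ranking front-end).  Cluster sizes may be
unbalanced, mirroring integrated multi-cohort designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .io import ExpressionMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a union-of-subspaces fixture.

    ``subspace_dim`` applies per cluster; ``samples_per_cluster`` may be
    unbalanced.  ``corruption_frac`` of all entries are set to
    +/- ``corruption_scale``, emulating gross errors.  ``n_salient_genes``
    rows receive an added dense signature of per-entry standard deviation
    ``salient_amplitude`` (default 5x the dense noise level).
    """

    n_clusters: int = 3
    subspace_dim: int = 4
    samples_per_cluster: tuple[int, ...] = (60, 60, 60)
    ambient_dim: int = 200
    noise_sigma: float = 0.05
    corruption_frac: float = 0.01
    corruption_scale: float = 1.0
    n_salient_genes: int = 0
    salient_amplitude: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.subspace_dim < 1 or self.ambient_dim < 1:
            raise ValueError("cluster count, subspace dim and ambient dim must be positive")
        if len(self.samples_per_cluster) != self.n_clusters:
            raise ValueError("samples_per_cluster length must equal n_clusters")
        if any(s < 1 for s in self.samples_per_cluster):
            raise ValueError("every cluster needs at least one sample")
        if self.n_clusters * self.subspace_dim > self.ambient_dim:
            raise ValueError("total subspace dimension exceeds ambient dimension")
        if not 0 <= self.corruption_frac < 1:
            raise ValueError("corruption_frac must lie in [0, 1)")
        if self.noise_sigma < 0 or self.corruption_scale <= 0:
            raise ValueError("noise_sigma >= 0 and corruption_scale > 0 required")
        if self.n_salient_genes < 0 or self.n_salient_genes > self.ambient_dim:
            raise ValueError("n_salient_genes outside [0, ambient_dim]")


@dataclass
class SyntheticData:
    X: ExpressionMatrix
    labels: NDArray[np.int64]
    clean: NDArray[np.float64]
    corruption_mask: NDArray[np.bool_]
    salient_genes: NDArray[np.int64]
    spec: SyntheticSpec = field(repr=False, default=None)


def make_subspace_data(spec: SyntheticSpec) -> SyntheticData:
    """Draw one reproducible fixture from the union-of-subspaces model.

    Each cluster gets an orthonormal basis (QR of a Gaussian matrix) and
    i.i.d. standard-normal coefficients, so the clean matrix has rank at
    most ``n_clusters * subspace_dim``.  Noise, corruption and salient
    signatures are then layered on top; everything derives from ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.ambient_dim
    n = int(sum(spec.samples_per_cluster))

    blocks = []
    labels = []
    for c, n_c in enumerate(spec.samples_per_cluster):
        basis, _ = np.linalg.qr(rng.standard_normal((m, spec.subspace_dim)))
        coeffs = rng.standard_normal((spec.subspace_dim, n_c))
        blocks.append(basis @ coeffs)
        labels.extend([c] * n_c)
    clean = np.concatenate(blocks, axis=1)
    labels = np.asarray(labels, dtype=np.int64)

    X = clean.copy()
    salient = rng.choice(m, size=spec.n_salient_genes, replace=False)
    salient.sort()
    if spec.n_salient_genes:
        amp = (
            spec.salient_amplitude
            if spec.salient_amplitude is not None
            else 5.0 * spec.noise_sigma
        )
        X[salient, :] += rng.standard_normal((spec.n_salient_genes, n)) * amp

    if spec.noise_sigma > 0:
        X += rng.normal(0.0, spec.noise_sigma, size=(m, n))

    mask = np.zeros((m, n), dtype=bool)
    n_corrupt = round(spec.corruption_frac * m * n)
    if n_corrupt:
        flat = rng.choice(m * n, size=n_corrupt, replace=False)
        mask.ravel()[flat] = True
        signs = rng.choice([-1.0, 1.0], size=n_corrupt)
        X.ravel()[flat] = signs * spec.corruption_scale

    em = ExpressionMatrix(
        values=X,
        gene_ids=[f"gene_{i}" for i in range(m)],
        sample_ids=[f"sample_{j}" for j in range(n)],
    )
    return SyntheticData(
        X=em,
        labels=labels,
        clean=clean,
        corruption_mask=mask,
        salient_genes=salient,
        spec=spec,
    )


def pca_reduce(X, d: int, center: bool = True) -> ExpressionMatrix:
    """Project the gene dimension onto the top-d principal directions.

    Samples (columns) are the observations; genes are centered by
    default.  Returns a d x n matrix of component scores, the
    variance-optimal rank-d summary of the gene dimension.
    """
    values = np.asarray(getattr(X, "values", X), dtype=float)
    m, n = values.shape
    if not 1 <= d <= m:
        raise ValueError(f"d={d} outside [1, {m}]")
    d = min(d, n)
    Xc = values - values.mean(axis=1, keepdims=True) if center else values
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :d].T @ Xc
    sample_ids = getattr(X, "sample_ids", [f"sample_{j}" for j in range(n)])
    return ExpressionMatrix(
        values=scores,
        gene_ids=[f"pc_{i + 1}" for i in range(d)],
        sample_ids=list(sample_ids),
    )
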