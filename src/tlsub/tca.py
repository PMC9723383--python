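"""Transfer component analysis (TCA) between a source and a target call set.

The source domain (calls at a known clonal proportion, labeled) and the
target domain (calls at an unknown proportion) share a conditional label
distribution but differ in their marginal feature distributions, because the
read-level signals are diluted by the clonal proportion.  TCA learns a
low-dimensional embedding of the pooled points that minimizes the maximum
mean discrepancy (MMD) between the two domains while retaining data
variance.

With the pooled kernel matrix ``K`` (linear kernel, block structure
``[[K_ss, K_st], [K_ts, K_tt]]``), the MMD coefficient matrix ``L``
(``1/n1^2`` on source-source pairs, ``1/n2^2`` on target-target pairs,
``-1/(n1*n2)`` across domains, so that ``trace(K L)`` is the squared
empirical MMD) and the centering matrix ``H = I - (1/n) 1 1'``, the transfer
components are the leading eigenvectors of::

    (K L K + mu I)^{-1} K H K

solved here as the equivalent symmetric generalized eigen-problem
``K H K w = lambda (K L K + mu I) w``.  The embedding of all pooled points
is ``K W``; its first ``n1`` rows embed the source, the rest the target.

The model is transductive: it embeds exactly the points present at fit time
(the pipeline refits per source-target pair), with no out-of-sample
extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from tlsub.errors import ConfigurationError, DimensionError
from tlsub.vcf_features import LabeledDataset

DEFAULT_LATENT_DIM = 15
DEFAULT_MU = 1.0


@dataclass
class GramMatrix:
    """Pooled kernel matrix over source (first ``n1``) and target rows."""

    values: np.ndarray
    n1: int
    n2: int


@dataclass
class Standardization:
    """Pooled per-feature location/scale used before the kernel."""

    mean: np.ndarray
    scale: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.scale


@dataclass
class TCAModel:
    """A fitted transfer-component embedding of one source-target pair."""

    W: np.ndarray
    M: int
    mu: float
    kernel: str
    standardization: Standardization
    cached_points: np.ndarray
    source_embedding: np.ndarray
    target_embedding: np.ndarray
    eigenvalues: np.ndarray
    mmd_input: float
    mmd_latent: float


def standardize(
    source_features: np.ndarray, target_features: np.ndarray
) -> tuple[np.ndarray, np.ndarray, Standardization]:
    """Center/scale both matrices with pooled statistics (zero-variance scale 1)."""
    xs = np.asarray(source_features, dtype=float)
    xt = np.asarray(target_features, dtype=float)
    if xs.ndim != 2 or xt.ndim != 2 or xs.shape[1] != xt.shape[1]:
        raise DimensionError(
            f"source and target must share a column count, got {xs.shape} vs {xt.shape}"
        )
    pooled = np.vstack([xs, xt])
    mean = pooled.mean(axis=0)
    scale = pooled.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    stats = Standardization(mean=mean, scale=scale)
    return stats.apply(xs), stats.apply(xt), stats


def build_mmd_matrix(n1: int, n2: int) -> np.ndarray:
    """The MMD coefficient matrix L: rank-1 PSD, entries summing to zero."""
    if n1 < 1 or n2 < 1:
        raise ConfigurationError("n1 and n2 must be >= 1")
    v = np.concatenate([np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)])
    return np.outer(v, v)


def build_centering(n: int) -> np.ndarray:
    """The centering matrix H = I - (1/n) 1 1' (symmetric, idempotent)."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    return np.eye(n) - np.full((n, n), 1.0 / n)


def build_kernel(points: np.ndarray, n1: int, kernel: str = "linear") -> GramMatrix:
    """Gram matrix over pooled points; only the linear kernel k(x, y) = x'y."""
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ConfigurationError("points must be a non-empty 2-D matrix")
    if kernel != "linear":
        raise ConfigurationError(f"unsupported kernel {kernel!r}")
    values = x @ x.T
    return GramMatrix(values=values, n1=n1, n2=x.shape[0] - n1)


def mmd_distance(K: GramMatrix | np.ndarray, L: np.ndarray) -> float:
    """Squared empirical MMD, trace(K L), clipped at 0 for round-off."""
    k = K.values if isinstance(K, GramMatrix) else np.asarray(K, dtype=float)
    if k.shape != L.shape:
        raise DimensionError(f"K shape {k.shape} does not match L shape {L.shape}")
    return max(float(np.sum(k * L.T)), 0.0)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    # deterministic across LAPACK backends: largest-|entry| component positive
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def fit_tca(
    source: LabeledDataset | np.ndarray,
    target: LabeledDataset | np.ndarray,
    M: int = DEFAULT_LATENT_DIM,
    mu: float = DEFAULT_MU,
    kernel: str = "linear",
) -> TCAModel:
    """Fit TCA on one source-target pair and embed both domains.

    Parameters
    ----------
    source, target
        Feature matrices (or :class:`~tlsub.vcf_features.LabeledDataset`)
        with a common feature count.
    M
        Latent dimension; must satisfy ``2 <= M <= n_features - 1`` and
        ``M <= n1 + n2``. With a linear kernel the pooled Gram matrix has
        rank at most the feature count, so components beyond it carry no
        signal.
    mu
        Trade-off regularizer (> 0) penalizing embedding complexity against
        the MMD objective.
    """
    xs = source.features if isinstance(source, LabeledDataset) else np.asarray(source, float)
    xt = target.features if isinstance(target, LabeledDataset) else np.asarray(target, float)
    n1, n2 = xs.shape[0], xt.shape[0]
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("need at least 2 source and 2 target points")
    d = xs.shape[1]
    if not 2 <= M <= d - 1:
        raise ConfigurationError(
            f"latent dimension M={M} outside the valid range [2, {d - 1}] "
            f"for {d} features"
        )
    if M > n1 + n2:
        raise ConfigurationError(f"M={M} exceeds the pooled sample count {n1 + n2}")
    if mu <= 0:
        raise ConfigurationError("mu must be > 0")

    xs_std, xt_std, stats = standardize(xs, xt)
    points = np.vstack([xs_std, xt_std])
    K = build_kernel(points, n1, kernel)
    L = build_mmd_matrix(n1, n2)
    H = build_centering(n1 + n2)

    KHK = K.values @ H @ K.values
    KLK = K.values @ L @ K.values
    A = (KHK + KHK.T) / 2.0
    B = (KLK + KLK.T) / 2.0 + mu * np.eye(n1 + n2)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(A, B)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - B is PD for mu>0
        raise ConfigurationError(
            f"eigen-problem is singular; try a larger mu than {mu}"
        ) from exc

    order = np.argsort(eigvals)[::-1][:M]
    W = _fix_signs(eigvecs[:, order])
    embedding = K.values @ W

    mmd_in = mmd_distance(K, L)
    mmd_lat = mmd_distance(embedding @ embedding.T, L)
    return TCAModel(
        W=W,
        M=M,
        mu=mu,
        kernel=kernel,
        standardization=stats,
        cached_points=points,
        source_embedding=embedding[:n1],
        target_embedding=embedding[n1:],
        eigenvalues=eigvals[order],
        mmd_input=mmd_in,
        mmd_latent=mmd_lat,
    )
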