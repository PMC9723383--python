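"""Confusion-matrix metrics and feature-proportion correlation diagnostics.

`score` summarises filtered predictions against truth labels.  Metrics with
a zero denominator (e.g. precision when nothing is predicted positive) are
reported as ``None`` together with an ``undefined`` flag rather than as a
silent 0.

`spearman_profile` quantifies how strongly each signal tracks the clonal
proportion across a panel of datasets — the diagnostic that motivates the
transfer stage: raw signals correlate with the proportion nearly perfectly,
while the latent components after domain adaptation should not.  The default
``means`` mode ranks the per-proportion mean signal against the proportion;
``pooled`` mode correlates every row's signal with its dataset proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from tlsub.errors import ConfigurationError, DimensionError
from tlsub.vcf_features import LabeledDataset


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def score(
    predictions: np.ndarray, truth: np.ndarray
) -> tuple[ConfusionCounts, dict[str, float | None]]:
    """Confusion counts plus accuracy / precision / recall / F1.

    Positive class is 1 (true variant kept).  Returns ``(counts, metrics)``
    where undefined metrics are ``None`` and listed in
    ``metrics["undefined"]``.
    """
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(truth, dtype=int)
    if pred.shape != y.shape:
        raise DimensionError(f"predictions {pred.shape} vs truth {y.shape}")
    counts = ConfusionCounts(
        TP=int(np.sum((pred == 1) & (y == 1))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        TN=int(np.sum((pred == 0) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
    )
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    accuracy = ratio(counts.TP + counts.TN, counts.n, "accuracy")
    precision = ratio(counts.TP, counts.TP + counts.FP, "precision")
    recall = ratio(counts.TP, counts.TP + counts.FN, "recall")
    if precision is None or recall is None or precision + recall == 0:
        if "f1" not in undefined:
            undefined.append("f1")
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    metrics: dict[str, float | None] = {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "undefined": undefined,  # type: ignore[dict-item]
    }
    return counts, metrics


def spearman_profile(
    panel: dict[float, np.ndarray], mode: str = "means"
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho between each feature column and the clonal proportion.

    Parameters
    ----------
    panel
        Map from clonal proportion to a feature (or latent) matrix; all
        matrices must share a column count.
    mode
        ``"means"`` ranks the per-proportion column means against the
        proportions (one rank pair per panel member); ``"pooled"``
        correlates all rows, each tagged with its dataset proportion.

    Returns
    -------
    rho, constant
        Per-column correlations and a boolean mask of columns that were
        constant (their rho is reported as 0).
    """
    if len(panel) < 3:
        raise ConfigurationError("need >= 3 distinct proportions for a correlation profile")
    if mode not in ("means", "pooled"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    props = np.array(sorted(panel))
    mats = [np.asarray(panel[p], dtype=float) for p in props]
    d = mats[0].shape[1]
    if any(m.shape[1] != d for m in mats):
        raise DimensionError("panel matrices must share a column count")

    if mode == "means":
        x = props
        y = np.vstack([m.mean(axis=0) for m in mats])
    else:
        x = np.concatenate([np.full(m.shape[0], p) for p, m in zip(props, mats)])
        y = np.vstack(mats)

    rho = np.zeros(d)
    constant = np.zeros(d, dtype=bool)
    for j in range(d):
        col = y[:, j]
        if np.ptp(col) == 0:
            constant[j] = True
            continue
        rho[j] = spearmanr(x, col).statistic
    return rho, constant


def latent_panel_profile(
    panel: dict[float, LabeledDataset],
    M: int = 15,
    mu: float = 1.0,
    mode: str = "means",
) -> tuple[np.ndarray, np.ndarray]:
    """Raw vs latent feature-proportion correlation profiles for a panel.

    Embeds the whole panel jointly with one TCA fit — the highest-proportion
    member as source, the pooled remaining members as target — so all
    panel members share one latent space, then computes Spearman profiles
    on the raw features and on the latent components.

    Returns ``(rho_raw, rho_latent)``.
    """
    from tlsub.tca import fit_tca  # deferred: tca imports vcf_features too

    if len(panel) < 3:
        raise ConfigurationError("need >= 3 panel members")
    props = sorted(panel)
    raw = {p: panel[p].features for p in props}
    rho_raw, _ = spearman_profile(raw, mode=mode)
    source = panel[props[-1]]
    rest = np.vstack([panel[p].features for p in props[:-1]])
    model = fit_tca(source.features, rest, M=M, mu=mu)
    latent: dict[float, np.ndarray] = {}
    offset = 0
    for p in props[:-1]:
        n = panel[p].n
        latent[p] = model.target_embedding[offset : offset + n]
        offset += n
    latent[props[-1]] = model.source_embedding
    rho_latent, _ = spearman_profile(latent, mode=mode)
    return rho_raw, rho_latent


def plot_correlation_profile(
    rho_raw: np.ndarray,
    rho_latent: np.ndarray,
    path: str,
    feature_names: list[str] | None = None,
) -> None:
    """Bar plot of initial (raw) vs final (latent) proportion correlations."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharey=True)
    names = feature_names or [str(i) for i in range(len(rho_raw))]
    ax1.bar(names, rho_raw, color="tab:blue")
    ax1.set_ylabel("initial rho")
    ax1.axhline(0, color="k", lw=0.5)
    ax1.tick_params(axis="x", rotation=90, labelsize=7)
    ax2.bar(range(len(rho_latent)), rho_latent, color="tab:red")
    ax2.set_ylabel("final rho (latent)")
    ax2.set_xlabel("latent component")
    ax2.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
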