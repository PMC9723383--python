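"""End-to-end TLsub run: per-domain transfer, voting, filtered output.

For each labeled source domain the pipeline (i) class-balances the source,
(ii) fits TCA between the balanced source and the unlabeled target, (iii)
trains the extra-trees ensemble on the projected source and predicts the
projected target, then (iv) combines all per-domain predictions with the
strict majority vote.  TCA is refit per source-target pair (the embedding
is transductive), so every domain contributes an independent view of the
target.

Predicted false positives are either dropped from the output VCF or kept
with ``FILTER=TLSUB_FP``; calls with a tied vote are kept with
``FILTER=TLSUB_AMBIGUOUS``.  Given one master seed the whole run is
deterministic, byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from tlsub.classifier import TreeEnsembleConfig, predict, train_classifier
from tlsub.errors import ConfigurationError
from tlsub.evaluation import score
from tlsub.synthetic_data import read_truth_tsv
from tlsub.tca import DEFAULT_LATENT_DIM, DEFAULT_MU, fit_tca
from tlsub.vcf_features import (
    LabeledDataset,
    balance_classes,
    extract_dataset,
    label_by_truth,
    parse_vcf,
)
from tlsub.voting import VoteTable, aggregate

logger = logging.getLogger(__name__)

FILTER_FP = "TLSUB_FP"
FILTER_AMBIGUOUS = "TLSUB_AMBIGUOUS"


@dataclass
class RunConfig:
    """Configuration of one end-to-end run over in-memory datasets."""

    sources: list[LabeledDataset]
    target: LabeledDataset
    latent_dim: int = DEFAULT_LATENT_DIM
    mu: float = DEFAULT_MU
    kernel: str = "linear"
    trees: TreeEnsembleConfig = field(default_factory=TreeEnsembleConfig)
    balance_strategy: str = "undersample"
    reject_policy: str = "flag"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sources) < 1:
            raise ConfigurationError("need at least one source domain")


@dataclass
class DomainResult:
    """Diagnostics of one source-domain transfer."""

    proportion: float | None
    n_source: int
    mmd_input: float
    mmd_latent: float
    votes: np.ndarray
    scores: np.ndarray
    accuracy: float | None


@dataclass
class FilterResult:
    final_labels: np.ndarray
    ambiguous: np.ndarray
    vote_table: VoteTable
    domains: list[DomainResult]
    metrics: dict | None

    def vote_report(self, ids: list[str]) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.vote_table.votes,
            columns=[f"vote_{tag}" for tag in self.vote_table.domain_tags],
        )
        frame.insert(0, "id", ids)
        frame["final_label"] = self.final_labels
        frame["ambiguous"] = self.ambiguous.astype(int)
        return frame


def run_tlsub(config: RunConfig) -> FilterResult:
    """Run the full multi-source transfer pipeline; see the module docstring."""
    target = config.target
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.sources))
    domains: list[DomainResult] = []
    vote_columns: list[np.ndarray] = []
    tags: list[float | str] = []
    for k, (source, child) in enumerate(zip(config.sources, seeds)):
        sub = child.generate_state(2) % (2**31)
        if source.labels is None or len(np.unique(source.labels)) < 2:
            logger.warning("source domain %d lacks both classes; skipped", k)
            continue
        balanced = balance_classes(source, config.balance_strategy, seed=int(sub[0]))
        tca = fit_tca(
            balanced.features,
            target.features,
            M=config.latent_dim,
            mu=config.mu,
            kernel=config.kernel,
        )
        trees = TreeEnsembleConfig(
            n_estimators=config.trees.n_estimators,
            max_features=config.trees.max_features,
            max_depth=config.trees.max_depth,
            min_samples_split=config.trees.min_samples_split,
            min_samples_leaf=config.trees.min_samples_leaf,
            seed=int(sub[1]),
        )
        model = train_classifier(tca.source_embedding, balanced.labels, trees)
        labels_k, scores_k = predict(model, tca.target_embedding)
        acc = None
        if target.labels is not None:
            acc = score(labels_k, target.labels)[1]["accuracy"]
        logger.info(
            "domain %d (proportion %s): MMD %.4g -> %.4g, accuracy %s",
            k, source.proportion, tca.mmd_input, tca.mmd_latent, acc,
        )
        domains.append(
            DomainResult(
                proportion=source.proportion,
                n_source=balanced.n,
                mmd_input=tca.mmd_input,
                mmd_latent=tca.mmd_latent,
                votes=labels_k,
                scores=scores_k,
                accuracy=acc,
            )
        )
        vote_columns.append(labels_k)
        tags.append(source.proportion if source.proportion is not None else f"domain{k}")
    if not vote_columns:
        raise ConfigurationError("all source domains were skipped (single-class labels)")

    table = VoteTable(votes=np.column_stack(vote_columns), domain_tags=tags)
    final_labels, ambiguous = aggregate(table, reject_policy=config.reject_policy)
    metrics = None
    if target.labels is not None:
        counts, m = score(final_labels, target.labels)
        metrics = {"confusion": vars(counts), **m}
    return FilterResult(
        final_labels=final_labels,
        ambiguous=ambiguous,
        vote_table=table,
        domains=domains,
        metrics=metrics,
    )


def load_calls(spec: str, window: int = 200) -> LabeledDataset:
    """Load a call set from a CLI source/target spec.

    Accepted forms: ``features.tsv``, ``features.tsv:PROPORTION``,
    ``calls.vcf``, ``calls.vcf:truth.tsv`` and
    ``calls.vcf:truth.tsv:PROPORTION``.  VCF inputs are feature-extracted;
    a truth table labels them via breakpoint matching within ``window`` bp.
    """
    parts = spec.split(":")
    proportion = None
    if len(parts) > 1:
        try:
            proportion = float(parts[-1])
            parts = parts[:-1]
        except ValueError:
            pass
    path = Path(parts[0])
    if path.suffix in (".tsv", ".txt", ".csv"):
        data = LabeledDataset.read_tsv(path)
        if proportion is not None:
            data.proportion = proportion
        return data
    records = parse_vcf(path)
    labels = None
    if len(parts) > 1:
        labels = label_by_truth(records, read_truth_tsv(parts[1]), window=window)
    return extract_dataset(records, labels=labels, proportion=proportion)


def write_filtered_vcf(
    target_vcf: str | Path,
    out_path: str | Path,
    final_labels: np.ndarray,
    ambiguous: np.ndarray,
    mode: str = "tag",
) -> None:
    """Write the filtered VCF.

    ``tag`` mode preserves every record, annotating predicted false
    positives with ``FILTER=TLSUB_FP`` and tied votes with
    ``FILTER=TLSUB_AMBIGUOUS``; ``drop`` mode omits records whose final
    label is 0.  Record order must match the parse order used to build the
    target dataset.
    """
    if mode not in ("tag", "drop"):
        raise ConfigurationError(f"output mode must be 'tag' or 'drop', got {mode!r}")
    with pysam.VariantFile(str(target_vcf)) as vcf_in:
        header = vcf_in.header
        for name, desc in (
            (FILTER_FP, "Predicted false positive by TLsub majority vote"),
            (FILTER_AMBIGUOUS, "Tied TLsub majority vote"),
        ):
            if name not in header.filters:
                header.filters.add(name, None, None, desc)
        with pysam.VariantFile(str(out_path), "w", header=header) as vcf_out:
            for i, rec in enumerate(vcf_in):
                if mode == "drop" and final_labels[i] == 0:
                    continue
                if ambiguous[i]:
                    rec.filter.clear()
                    rec.filter.add(FILTER_AMBIGUOUS)
                elif final_labels[i] == 0:
                    rec.filter.clear()
                    rec.filter.add(FILTER_FP)
                vcf_out.write(rec)


def write_report(result: FilterResult, config: RunConfig, path: str | Path) -> None:
    """Dump a machine-readable JSON run report (no timestamps: reproducible)."""
    report = {
        "config": {
            "latent_dim": config.latent_dim,
            "mu": config.mu,
            "kernel": config.kernel,
            "n_source_domains": len(config.sources),
            "balance_strategy": config.balance_strategy,
            "reject_policy": config.reject_policy,
            "seed": config.seed,
            "trees": {
                "n_estimators": config.trees.n_estimators,
                "max_features": config.trees.max_features,
                "max_depth": config.trees.max_depth,
                "min_samples_split": config.trees.min_samples_split,
                "min_samples_leaf": config.trees.min_samples_leaf,
            },
        },
        "domains": [
            {
                "proportion": d.proportion,
                "n_source": d.n_source,
                "mmd_input": d.mmd_input,
                "mmd_latent": d.mmd_latent,
                "accuracy": d.accuracy,
            }
            for d in result.domains
        ],
        "n_target": int(len(result.final_labels)),
        "n_kept": int(result.final_labels.sum()),
        "n_filtered": int((result.final_labels == 0).sum()),
        "n_ambiguous": int(result.ambiguous.sum()),
        "metrics": result.metrics,
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
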