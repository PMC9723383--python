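"""VCF parsing and the fixed 26-signal feature vector.

Each variant call is summarised by 26 numeric signals drawn from the INFO,
FORMAT and QUAL columns of a VCF 4.1 record: breakpoint-imprecision flags and
confidence-interval widths (IMPRECISE, CIPOS, CIEND, CIPOS95, CIEND95),
genotype and genotype quality (GT, GQ, GL1-3), evidence counts from
paired-end and split reads (SU, PE, SR, RS, AS, ASC, RP, AP), depth and
allele observations (DP, RO, AO), summed observation qualities (QR, QA), the
site quality (SQ, from the QUAL column), the allele balance
AB = QA / (QR + QA), and the copy number of the segment (CN).

These signals are what downstream domain adaptation operates on: most of
them are diluted roughly in proportion to the clonal proportion of the
mutation, which is exactly the distribution shift the TCA stage removes.

Missing-field conventions (caller dialects differ): absent flags and numeric
fields are imputed as 0; a missing genotype is encoded as the sentinel -1;
confidence intervals are reduced to their width (second value minus first);
only the first sample column and the first ALT allele are considered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from sklearn.neighbors import NearestNeighbors

from tlsub.errors import (
    ConfigurationError,
    DimensionError,
    FeatureExtractionError,
    VCFFormatError,
)

#: The fixed feature order; every feature matrix in the package uses it.
FEATURE_NAMES: tuple[str, ...] = (
    "IMPRECISE", "CIPOS", "CIEND", "CIPOS95", "CIEND95",
    "GT", "SU", "PE", "SR", "GQ", "SQ",
    "GL1", "GL2", "GL3",
    "DP", "RO", "AO", "QR", "QA",
    "RS", "AS", "ASC", "RP", "AP",
    "AB", "CN",
)

N_FEATURES = len(FEATURE_NAMES)

# Preferred column per tag; the other column is used as a fallback so that
# caller dialects which move a tag (e.g. LUMPY keeps SU in both columns)
# still extract. "QR"/"QA" additionally fall back to FORMAT RO/AO (freebayes
# names the summed qualities QR/QA; some tables list them under RO/AO).
_INFO, _FORMAT = "info", "format"
_PREFERRED_COLUMN = {
    "SU": _FORMAT, "PE": _INFO, "SR": _INFO, "GQ": _FORMAT,
    "DP": _INFO, "RO": _INFO, "AO": _INFO,
    "QR": _FORMAT, "QA": _FORMAT,
    "RS": _FORMAT, "AS": _FORMAT, "ASC": _FORMAT, "RP": _FORMAT,
    "CN": _FORMAT,
}


@dataclass
class VariantRecord:
    """One parsed VCF call, with INFO and first-sample FORMAT maps as strings."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None
    filter: str
    info: dict[str, str]
    sample_format: dict[str, str]
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VCFFormatError(f"record {self.id}: pos must be >= 1, got {self.pos}")
        if self.qual is not None and self.qual < 0:
            raise VCFFormatError(f"record {self.id}: negative QUAL {self.qual}")


@dataclass
class LabeledDataset:
    """A feature matrix with optional binary labels and a clonal-proportion tag.

    Parameters
    ----------
    features
        ``(n, 26)`` float matrix in :data:`FEATURE_NAMES` order.
    labels
        ``n`` binary labels (1 = true variant, 0 = false positive), or
        ``None`` for an unlabeled target domain.
    proportion
        Clonal proportion shared by the dataset, in ``[0, 1]``, or ``None``
        when unknown/mixed.
    ids
        ``n`` record identifiers.
    row_proportions
        Optional per-row clonal proportions (mixed cohorts); NaN where not
        applicable.
    meta
        Optional per-row metadata (genomic position, SV type/length) used
        when materialising the dataset as a VCF.
    """

    features: np.ndarray
    labels: np.ndarray | None
    proportion: float | None
    ids: list[str]
    row_proportions: np.ndarray | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != N_FEATURES:
            raise DimensionError(
                f"features must be (n, {N_FEATURES}), got {self.features.shape}"
            )
        n = self.features.shape[0]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise DimensionError("labels length must match feature rows")
        if len(self.ids) != n:
            raise DimensionError("ids length must match feature rows")
        if self.proportion is not None and not 0.0 <= self.proportion <= 1.0:
            raise ConfigurationError(f"proportion must be in [0, 1], got {self.proportion}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=list(FEATURE_NAMES))
        frame.insert(0, "id", self.ids)
        frame.insert(1, "label", self.labels if self.labels is not None else np.nan)
        frame.insert(2, "proportion", np.nan if self.proportion is None else self.proportion)
        return frame

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LabeledDataset":
        frame = pd.read_csv(path, sep="\t")
        missing = [c for c in ("id", "label", "proportion", *FEATURE_NAMES) if c not in frame]
        if missing:
            raise VCFFormatError(f"feature table {path} lacks columns: {missing}")
        labels = None
        if frame["label"].notna().all() and len(frame):
            labels = frame["label"].to_numpy(dtype=int)
        prop = None
        props = frame["proportion"].dropna().unique()
        if len(props) == 1:
            prop = float(props[0])
        return cls(
            features=frame[list(FEATURE_NAMES)].to_numpy(dtype=float),
            labels=labels,
            proportion=prop,
            ids=[str(i) for i in frame["id"]],
        )


def parse_vcf(path: str | Path) -> list[VariantRecord]:
    """Parse a VCF 4.1 file (plain or bgzipped) into :class:`VariantRecord`\\ s.

    INFO flags (keys without ``=``) are stored with the value ``"1"``.
    An empty body yields an empty list; a missing or garbled header raises
    :class:`~tlsub.errors.VCFFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise VCFFormatError(f"no such file: {path}")
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VCFFormatError(f"{path}: not a valid VCF header ({exc})") from exc
    records: list[VariantRecord] = []
    try:
        with vcf:
            for idx, rec in enumerate(vcf):
                records.append(_convert_record(rec, idx))
    except (ValueError, OSError) as exc:
        raise VCFFormatError(f"{path}: malformed record near #{len(records) + 1} ({exc})") from exc
    return records


def _stringify(value: object) -> str:
    if value is True:
        return "1"
    if isinstance(value, (tuple, list)):
        return ",".join("." if v is None else str(v) for v in value)
    return str(value)


def _convert_record(rec: "pysam.VariantRecord", idx: int) -> VariantRecord:
    info = {key: _stringify(val) for key, val in rec.info.items()}
    fmt: dict[str, str] = {}
    if rec.samples:
        sample = rec.samples[0]
        for key in sample.keys():
            if key == "GT":
                alleles = sample.allele_indices or ()
                sep = "|" if sample.phased else "/"
                fmt["GT"] = sep.join("." if a is None else str(a) for a in alleles) or "."
            else:
                fmt[key] = _stringify(sample[key])
    alts = rec.alts or ("",)
    rid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}:{idx}"
    return VariantRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref or "",
        alt=alts[0],
        qual=rec.qual,
        filter=";".join(rec.filter.keys()) or ".",
        info=info,
        sample_format=fmt,
        id=rid,
    )


def _to_float(record: VariantRecord, name: str, raw: str) -> float:
    token = raw.split(",")[0]
    if token in (".", ""):
        return 0.0
    try:
        return float(token)
    except ValueError as exc:
        raise FeatureExtractionError(
            f"record {record.id}: field {name} has non-numeric value {raw!r}"
        ) from exc


def _lookup(record: VariantRecord, key: str) -> str | None:
    order = (
        (record.sample_format, record.info)
        if _PREFERRED_COLUMN.get(key, _INFO) == _FORMAT
        else (record.info, record.sample_format)
    )
    for column in order:
        if key in column:
            return column[key]
    return None


def _interval_width(record: VariantRecord, key: str) -> float:
    raw = record.info.get(key) or record.sample_format.get(key)
    if raw is None:
        return 0.0
    parts = raw.split(",")
    if len(parts) == 1:
        return abs(_to_float(record, key, parts[0]))
    lo = _to_float(record, key, parts[0])
    hi = _to_float(record, key, parts[1])
    return hi - lo


def _encode_gt(gt: str | None) -> float:
    if gt is None:
        return -1.0
    alleles = gt.replace("|", "/").split("/")
    if "." in alleles or gt == ".":
        return -1.0
    try:
        return float(sum(int(a) > 0 for a in alleles))
    except ValueError:
        return -1.0


def extract_features(record: VariantRecord) -> np.ndarray:
    """Compute the 26-signal feature vector of one call, in :data:`FEATURE_NAMES` order."""
    out = np.zeros(N_FEATURES)
    values: dict[str, float] = {}

    values["IMPRECISE"] = 1.0 if "IMPRECISE" in record.info else 0.0
    for key in ("CIPOS", "CIEND", "CIPOS95", "CIEND95"):
        values[key] = _interval_width(record, key)
    values["GT"] = _encode_gt(record.sample_format.get("GT"))
    for key in ("SU", "PE", "SR", "GQ", "DP", "RO", "AO", "RS", "AS", "ASC", "RP", "AP", "CN"):
        raw = _lookup(record, key)
        values[key] = 0.0 if raw is None else _to_float(record, key, raw)
    values["SQ"] = record.qual if record.qual is not None else 0.0

    raw_gl = record.sample_format.get("GL")
    gls = raw_gl.split(",") if raw_gl is not None else []
    for i, key in enumerate(("GL1", "GL2", "GL3")):
        values[key] = _to_float(record, key, gls[i]) if i < len(gls) else 0.0

    for key, fallback in (("QR", "RO"), ("QA", "AO")):
        raw = _lookup(record, key)
        if raw is None:
            raw = record.sample_format.get(fallback)
        values[key] = 0.0 if raw is None else _to_float(record, key, raw)

    qa, qr = values["QA"], values["QR"]
    values["AB"] = qa / (qr + qa) if qr + qa > 0 else 0.0

    for i, key in enumerate(FEATURE_NAMES):
        out[i] = values[key]
    return out


def extract_dataset(
    records: Sequence[VariantRecord],
    labels: np.ndarray | Sequence[int] | None = None,
    proportion: float | None = None,
) -> LabeledDataset:
    """Extract features for a whole call set into a :class:`LabeledDataset`."""
    matrix = (
        np.vstack([extract_features(r) for r in records])
        if records
        else np.empty((0, N_FEATURES))
    )
    return LabeledDataset(
        features=matrix,
        labels=None if labels is None else np.asarray(labels, dtype=int),
        proportion=proportion,
        ids=[r.id for r in records],
    )


def label_by_truth(
    records: Sequence[VariantRecord],
    truth: Iterable[tuple[str, int, int, str]],
    window: int = 200,
) -> np.ndarray:
    """Label each call 1 iff a truth interval on the same chromosome has a
    breakpoint (start or end, 1-based inclusive) within ``window`` bp of the
    call position; otherwise 0.

    SV type matching is intentionally ignored: callers frequently disagree on
    the type of complex events while agreeing on the breakpoint.
    """
    if window < 0:
        raise ConfigurationError("window must be >= 0")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _svtype in truth:
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    breakpoints = {
        chrom: np.array(sorted({p for iv in ivs for p in iv}))
        for chrom, ivs in by_chrom.items()
    }
    labels = np.zeros(len(records), dtype=int)
    for i, rec in enumerate(records):
        points = breakpoints.get(rec.chrom)
        if points is None or len(points) == 0:
            continue
        if np.min(np.abs(points - rec.pos)) <= window:
            labels[i] = 1
    return labels


def balance_classes(
    data: LabeledDataset, strategy: str = "undersample", seed: int = 0
) -> LabeledDataset:
    """Return a 50/50-balanced copy of a labeled dataset.

    ``undersample`` randomly subsamples the majority class to the minority
    count; ``oversample`` adds SMOTE-style synthetic minority rows, each a
    convex combination of a minority sample and one of its k=5 nearest
    minority neighbours. Deterministic given ``seed``.
    """
    if data.labels is None:
        raise ConfigurationError("balance_classes requires labels")
    labels = data.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ConfigurationError(f"need both classes present, got classes {classes.tolist()}")
    rng = np.random.default_rng(seed)
    i_min = int(np.argmin(counts))
    minority = classes[i_min]
    majority = classes[1 - i_min]
    min_idx = np.flatnonzero(labels == minority)
    maj_idx = np.flatnonzero(labels == majority)

    if strategy == "undersample":
        kept = rng.choice(maj_idx, size=len(min_idx), replace=False)
        order = np.sort(np.concatenate([min_idx, kept]))
        return LabeledDataset(
            features=data.features[order],
            labels=labels[order],
            proportion=data.proportion,
            ids=[data.ids[i] for i in order],
        )
    if strategy == "oversample":
        if len(min_idx) < 2:
            raise ConfigurationError("oversample needs >= 2 minority samples to interpolate")
        deficit = len(maj_idx) - len(min_idx)
        minority_x = data.features[min_idx]
        k = min(5, len(min_idx) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(minority_x)
        _, neigh = nn.kneighbors(minority_x)
        synth = np.empty((deficit, data.features.shape[1]))
        for m in range(deficit):
            i = rng.integers(len(min_idx))
            j = neigh[i][1 + rng.integers(k)]  # skip self at position 0
            u = rng.random()
            synth[m] = minority_x[i] + u * (minority_x[j] - minority_x[i])
        features = np.vstack([data.features, synth])
        new_labels = np.concatenate([labels, np.full(deficit, minority, dtype=int)])
        ids = list(data.ids) + [f"smote_{m}" for m in range(deficit)]
        return LabeledDataset(
            features=features, labels=new_labels, proportion=data.proportion, ids=ids
        )
    raise ConfigurationError(f"unknown balancing strategy {strategy!r}")
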