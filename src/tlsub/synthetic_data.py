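"""Synthetic diluted-signal call sets for end-to-end testing.

The generator emulates, directly at the signal level, the feature
distributions a structural-variant caller produces on a tumor sample with a
given clonal proportion:

* **True calls** carry evidence proportional to the clonal proportion ``p``:
  the alternate-allele observation count is ``AO ~ Binomial(DP, p/2 + e)``
  (heterozygous subclone with a small error floor ``e``), ``RO = DP - AO``,
  and the paired-end/split-read evidence counts (PE, SR, SU, RS, AS, ASC,
  RP, AP) are binomial partitions of AO and RO.  Observation quality sums
  (QA, QR) accumulate per-read qualities around Q30, genotype likelihoods
  and GT follow the binomial allele model, breakpoint confidence intervals
  are narrow and IMPRECISE is rare.
* **False-positive calls** carry evidence generated by sequencing error
  alone, ``AO ~ Binomial(DP, k * read_error_rate)``, *independent of the
  clonal proportion*, with wide confidence intervals and IMPRECISE common.

This is exactly the structure the transfer stage exploits: most true-call
signals are monotonically diluted by ``p`` while false-positive signals are
not.  Each simulated dataset plants ``n_variants_per_replicate`` calls per
replicate in a 1 Mb region (pairwise separation > 2 kb), repeats for
``n_replicates`` replicates, and can be materialised as a VCF 4.1 fixture
with a companion truth-interval table.

Float-typed VCF fields (QA, QR, GL, CN) are quantised to a 1/64 grid so
that they are exactly representable in the 32-bit floats VCF toolchains use
internally; the write -> parse -> extract round trip is then an exact
identity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from tlsub.errors import ConfigurationError
from tlsub.vcf_features import FEATURE_NAMES, LabeledDataset, balance_classes

_SLOT_STEP = 2500  # bp between planted variants; keeps breakpoints > 2 kb apart
_SV_TYPES = ("DEL", "INS", "CNV", "DUP")
_SV_TYPE_PROBS = (0.35, 0.3, 0.2, 0.15)
_READ_QUAL_MEAN = 30.0
_READ_QUAL_SD = 3.0
_GL_ERR = 1e-3

DEFAULT_PROPORTIONS: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


def _q64(x: np.ndarray) -> np.ndarray:
    """Quantise to multiples of 1/64 (exact in 32-bit floats)."""
    return np.round(np.asarray(x, dtype=float) * 64.0) / 64.0


@dataclass
class SimulationConfig:
    """One fixed-proportion simulated dataset.

    Defaults mirror the reference simulation design: 200 planted structural
    variants per replicate in a 1 Mb region, 20 replicates (4,000 calls),
    mean coverage 100x, read error rate 0.001, SV lengths normal around
    1,000 bp (sd 100).  ``fp_fraction`` is the pre-balancing fraction of
    false-positive calls and ``fp_error_inflation`` the factor by which
    caller artifacts exceed the raw read error rate.
    """

    proportion: float
    n_variants_per_replicate: int = 200
    n_replicates: int = 20
    region_length: int = 1_000_000
    coverage: float = 100.0
    read_error_rate: float = 0.001
    sv_length_mean: float = 1000.0
    sv_length_sd: float = 100.0
    fp_fraction: float = 0.5
    fp_error_inflation: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ConfigurationError(f"proportion must be in [0, 1], got {self.proportion}")
        for name in ("n_variants_per_replicate", "n_replicates", "region_length"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("read_error_rate", "fp_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be a probability")
        if self.coverage <= 0 or self.sv_length_mean <= 0 or self.sv_length_sd < 0:
            raise ConfigurationError("coverage and SV length parameters must be positive")
        if self.n_variants_per_replicate * _SLOT_STEP > self.region_length:
            raise ConfigurationError(
                "region_length too small to keep planted variants > 2 kb apart"
            )


@dataclass
class MixedCohortConfig:
    """A cohort whose true calls each draw their own clonal proportion.

    Proportions follow a normal distribution with mean 0.70 and sd 0.10,
    truncated to (0, 1]; the number of calls is uniform on [2200, 2400].
    """

    proportion_mean: float = 0.70
    proportion_sd: float = 0.10
    n_mutations_range: tuple[int, int] = (2200, 2400)
    fp_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_mutations_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("n_mutations_range must satisfy 1 <= lo <= hi")
        if self.proportion_sd <= 0 or not 0 < self.proportion_mean <= 1:
            raise ConfigurationError("invalid proportion distribution parameters")


def _simulate_chunk(
    rng: np.random.Generator,
    labels: np.ndarray,
    proportions: np.ndarray,
    cfg: SimulationConfig,
    chrom: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one chromosome's worth of calls (row i at ascending position)."""
    n = len(labels)
    truthy = labels == 1
    err_floor = cfg.fp_error_inflation * cfg.read_error_rate
    p_alt = np.where(truthy, np.clip(proportions / 2.0 + err_floor, 0.0, 1.0), err_floor)

    dp = np.maximum(rng.poisson(cfg.coverage, size=n), 1)
    ao = rng.binomial(dp, p_alt)
    ro = dp - ao
    pe = rng.binomial(ao, 0.5)
    sr = ao - pe
    su = pe + sr
    as_ = rng.binomial(sr, 0.7)
    asc = sr - as_
    ap = pe
    rs = rng.binomial(ro, 0.5)
    rp = ro - rs

    def qual_sum(count: np.ndarray) -> np.ndarray:
        noise = rng.standard_normal(n) * _READ_QUAL_SD * np.sqrt(np.maximum(count, 1))
        total = np.where(count > 0, count * _READ_QUAL_MEAN + noise, 0.0)
        return _q64(np.maximum(total, 0.0))

    qa = qual_sum(ao)
    qr = qual_sum(ro)
    denom = qa + qr
    ab = np.divide(qa, denom, out=np.zeros(n), where=denom > 0)

    # binomial genotype log10-likelihoods for 0/0, 0/1, 1/1, normalised to max 0
    gl = np.empty((n, 3))
    for g, p_g in enumerate((_GL_ERR, 0.5, 1.0 - _GL_ERR)):
        gl[:, g] = ao * np.log10(p_g) + ro * np.log10(1.0 - p_g)
    gl -= gl.max(axis=1, keepdims=True)
    gl = _q64(gl)
    second_best = np.sort(gl, axis=1)[:, 1]
    gq = np.clip(np.round(-10.0 * second_best), 0, 99).astype(int)

    frac = ao / dp
    gt = np.where(frac < 0.2, 0, np.where(frac < 0.8, 1, 2))
    sq = np.round(qa / 10.0)

    imprecise = np.where(truthy, rng.random(n) < 0.05, rng.random(n) < 0.7).astype(int)
    ci_mean = np.where(truthy, 3.0, 30.0)
    ci95_mean = np.where(truthy, 2.0, 20.0)
    cipos = rng.poisson(ci_mean)
    ciend = rng.poisson(ci_mean)
    cipos95 = rng.poisson(ci95_mean)
    ciend95 = rng.poisson(ci95_mean)

    svtype = rng.choice(len(_SV_TYPES), size=n, p=_SV_TYPE_PROBS)
    svtype_names = np.array(_SV_TYPES)[svtype]
    is_cnv = np.isin(svtype_names, ("CNV", "DUP"))
    direction = np.where(svtype_names == "DUP", 1.0, -1.0)
    cn = np.full(n, 2.0)
    cn = np.where(is_cnv & truthy, 2.0 + direction * 2.0 * proportions, cn)
    cn = np.where(
        is_cnv & ~truthy, 2.0 + _q64(rng.standard_normal(n) * 0.05), cn
    )
    cn = _q64(cn)

    svlen = np.round(rng.normal(cfg.sv_length_mean, cfg.sv_length_sd, size=n))
    svlen = np.maximum(svlen, 1).astype(int)
    svlen = np.where(svtype_names == "CNV", 1000, svlen)

    jitter = rng.integers(0, 500, size=n)
    pos = 1000 + np.arange(n) * _SLOT_STEP + jitter

    features = pd.DataFrame(
        {
            "IMPRECISE": imprecise.astype(float),
            "CIPOS": cipos.astype(float),
            "CIEND": ciend.astype(float),
            "CIPOS95": cipos95.astype(float),
            "CIEND95": ciend95.astype(float),
            "GT": gt.astype(float),
            "SU": su.astype(float),
            "PE": pe.astype(float),
            "SR": sr.astype(float),
            "GQ": gq.astype(float),
            "SQ": sq,
            "GL1": gl[:, 0],
            "GL2": gl[:, 1],
            "GL3": gl[:, 2],
            "DP": dp.astype(float),
            "RO": ro.astype(float),
            "AO": ao.astype(float),
            "QR": qr,
            "QA": qa,
            "RS": rs.astype(float),
            "AS": as_.astype(float),
            "ASC": asc.astype(float),
            "RP": rp.astype(float),
            "AP": ap.astype(float),
            "AB": ab,
            "CN": cn,
        }
    )[list(FEATURE_NAMES)]
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "end": pos + svlen,
            "svtype": svtype_names,
            "svlen": svlen,
        }
    )
    return features, meta


def simulate_feature_dataset(config: SimulationConfig) -> LabeledDataset:
    """Simulate a fixed-proportion labeled call set.

    Each of ``n_replicates`` replicates plants ``n_variants_per_replicate``
    calls on its own chromosome; row order is position order within each
    replicate with true and false-positive calls interleaved at random.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants_per_replicate
    n_fp = int(round(n * config.fp_fraction))
    frames, metas, all_labels, ids = [], [], [], []
    counter = 0
    for rep in range(config.n_replicates):
        labels = np.concatenate([np.ones(n - n_fp, dtype=int), np.zeros(n_fp, dtype=int)])
        labels = labels[rng.permutation(n)]
        props = np.full(n, config.proportion)
        feats, meta = _simulate_chunk(rng, labels, props, config, chrom=f"chr{rep + 1}")
        frames.append(feats)
        metas.append(meta)
        all_labels.append(labels)
        ids.extend(f"sv{counter + i:06d}" for i in range(n))
        counter += n
    return LabeledDataset(
        features=pd.concat(frames, ignore_index=True).to_numpy(),
        labels=np.concatenate(all_labels),
        proportion=config.proportion,
        ids=ids,
        meta=pd.concat(metas, ignore_index=True),
    )


def simulate_proportion_panel(
    proportions: tuple[float, ...] | list[float] = DEFAULT_PROPORTIONS,
    config: SimulationConfig | None = None,
) -> dict[float, LabeledDataset]:
    """One class-balanced dataset per clonal proportion.

    Per-proportion seeds are derived from the master seed
    (``config.seed``) via ``numpy.random.SeedSequence`` spawning, so the
    panel members are mutually independent yet fully reproducible.
    """
    if len(proportions) == 0:
        raise ConfigurationError("proportions must be non-empty")
    if len(set(proportions)) != len(proportions):
        raise ConfigurationError("duplicate proportions in panel")
    if config is None:
        config = SimulationConfig(proportion=proportions[0])
    children = np.random.SeedSequence(config.seed).spawn(len(proportions))
    panel: dict[float, LabeledDataset] = {}
    for p, child in zip(proportions, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = dataclasses.replace(config, proportion=p, seed=sub_seed)
        data = simulate_feature_dataset(cfg)
        panel[p] = balance_classes(data, strategy="undersample", seed=sub_seed)
    return panel


def simulate_mixed_cohort(config: MixedCohortConfig | None = None) -> LabeledDataset:
    """Simulate a cohort of subclonal mutations with heterogeneous proportions.

    Each true call draws its own clonal proportion from the truncated
    normal; false positives are proportion-independent.  The returned
    dataset's ``proportion`` is ``None`` (mixed); per-row draws are kept in
    ``row_proportions`` (NaN on false-positive rows).
    """
    config = config or MixedCohortConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.n_mutations_range
    n = int(rng.integers(lo, hi + 1))
    n_fp = int(round(n * config.fp_fraction))
    labels = np.concatenate([np.ones(n - n_fp, dtype=int), np.zeros(n_fp, dtype=int)])
    labels = labels[rng.permutation(n)]

    a = (1e-6 - config.proportion_mean) / config.proportion_sd
    b = (1.0 - config.proportion_mean) / config.proportion_sd
    draws = truncnorm.rvs(
        a, b, loc=config.proportion_mean, scale=config.proportion_sd,
        size=n, random_state=rng,
    )
    row_props = np.where(labels == 1, draws, np.nan)

    sim_cfg = SimulationConfig(proportion=0.5)  # only non-proportion fields used below
    chunk = sim_cfg.n_variants_per_replicate
    frames, metas = [], []
    for rep, start in enumerate(range(0, n, chunk)):
        sl = slice(start, min(start + chunk, n))
        feats, meta = _simulate_chunk(
            rng, labels[sl], np.nan_to_num(row_props[sl]), sim_cfg, chrom=f"chr{rep + 1}"
        )
        frames.append(feats)
        metas.append(meta)
    return LabeledDataset(
        features=pd.concat(frames, ignore_index=True).to_numpy(),
        labels=labels,
        proportion=None,
        ids=[f"mx{i:06d}" for i in range(n)],
        row_proportions=row_props,
        meta=pd.concat(metas, ignore_index=True),
    )


_VCF_HEADER_FIELDS = """\
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise structural variation">
##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">
##INFO=<ID=CIEND,Number=2,Type=Integer,Description="Confidence interval around END">
##INFO=<ID=CIPOS95,Number=2,Type=Integer,Description="95% confidence interval around POS">
##INFO=<ID=CIEND95,Number=2,Type=Integer,Description="95% confidence interval around END">
##INFO=<ID=PE,Number=1,Type=Integer,Description="Paired-end reads supporting the variant">
##INFO=<ID=SR,Number=1,Type=Integer,Description="Split reads supporting the variant">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">
##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate allele observation count">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=SU,Number=1,Type=Integer,Description="Pieces of evidence supporting the variant">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10-scaled genotype likelihoods">
##FORMAT=<ID=QR,Number=1,Type=Float,Description="Sum of reference observation qualities">
##FORMAT=<ID=QA,Number=1,Type=Float,Description="Sum of alternate observation qualities">
##FORMAT=<ID=RS,Number=1,Type=Integer,Description="Reference split-read observations">
##FORMAT=<ID=AS,Number=1,Type=Integer,Description="Alternate split-read observations">
##FORMAT=<ID=ASC,Number=1,Type=Integer,Description="Alternate clipped-read observations">
##FORMAT=<ID=RP,Number=1,Type=Integer,Description="Reference paired-end observations">
##FORMAT=<ID=AP,Number=1,Type=Integer,Description="Alternate paired-end observations">
##FORMAT=<ID=CN,Number=1,Type=Float,Description="Copy number of the segment">
"""


def _fmt(x: float) -> str:
    # 1/64-grid values have at most 6 decimals; strip trailing zeros
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-0") else "0"


def _fmt_pair(width: float) -> str:
    w = int(round(width))
    lo = w // 2
    return f"{-lo},{w - lo}"


_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
_ALT_BY_TYPE = {"DEL": "<DEL>", "INS": "<INS>", "CNV": "<CNV>", "DUP": "<DUP>"}


def write_toy_vcf(data: LabeledDataset, path: str | Path) -> tuple[Path, Path]:
    """Materialise a simulated dataset as a VCF 4.1 file plus truth intervals.

    INFO/FORMAT fields are named exactly as the feature-extraction sources,
    so parsing the file back and extracting features recovers the dataset's
    matrix exactly.  Returns ``(vcf_path, truth_path)``; the truth table
    holds the 1-based inclusive intervals of the true (label 1) calls.
    """
    if data.meta is None:
        raise ConfigurationError("dataset lacks positional metadata; cannot write VCF")
    path = Path(path)
    truth_path = path.with_suffix(".truth.tsv")
    frame = data.to_frame()
    meta = data.meta
    contigs = list(dict.fromkeys(meta["chrom"]))
    region = int(meta["end"].max()) + 10_000

    lines = ["##fileformat=VCFv4.1"]
    lines += [f"##contig=<ID={c},length={region}>" for c in contigs]
    lines.append(_VCF_HEADER_FIELDS.rstrip("\n"))
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE")

    for i in range(data.n):
        row = frame.iloc[i]
        m = meta.iloc[i]
        info = [
            f"SVTYPE={m.svtype}",
            f"END={int(m.end)}",
            f"SVLEN={int(m.svlen)}",
        ]
        if row.IMPRECISE >= 0.5:
            info.append("IMPRECISE")
        info += [
            f"CIPOS={_fmt_pair(row.CIPOS)}",
            f"CIEND={_fmt_pair(row.CIEND)}",
            f"CIPOS95={_fmt_pair(row.CIPOS95)}",
            f"CIEND95={_fmt_pair(row.CIEND95)}",
            f"PE={int(row.PE)}",
            f"SR={int(row.SR)}",
            f"DP={int(row.DP)}",
            f"RO={int(row.RO)}",
            f"AO={int(row.AO)}",
        ]
        sample = ":".join(
            [
                _GT_STRINGS[int(row.GT)],
                str(int(row.SU)),
                str(int(row.GQ)),
                ",".join(_fmt(g) for g in (row.GL1, row.GL2, row.GL3)),
                _fmt(row.QR),
                _fmt(row.QA),
                str(int(row.RS)),
                str(int(row.AS)),
                str(int(row.ASC)),
                str(int(row.RP)),
                str(int(row.AP)),
                _fmt(row.CN),
            ]
        )
        lines.append(
            "\t".join(
                [
                    str(m.chrom),
                    str(int(m.pos)),
                    str(row.id),
                    "N",
                    _ALT_BY_TYPE[str(m.svtype)],
                    str(int(row.SQ)),
                    ".",
                    ";".join(info),
                    "GT:SU:GQ:GL:QR:QA:RS:AS:ASC:RP:AP:CN",
                    sample,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")

    truth_rows = ["chrom\tstart\tend\ttype"]
    if data.labels is not None:
        for i in np.flatnonzero(data.labels == 1):
            m = meta.iloc[i]
            truth_rows.append(f"{m.chrom}\t{int(m.pos)}\t{int(m.end)}\t{m.svtype}")
    truth_path.write_text("\n".join(truth_rows) + "\n")
    return path, truth_path


def read_truth_tsv(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a truth-interval table written by :func:`write_toy_vcf`."""
    frame = pd.read_csv(path, sep="\t")
    return [
        (str(r.chrom), int(r.start), int(r.end), str(r.type))
        for r in frame.itertuples(index=False)
    ]
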