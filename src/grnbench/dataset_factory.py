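"""Measurement noise, study design and dataset I/O.

Per-gene measurement-error variances are drawn once per dataset generation
from a lognormal distribution whose *variate* mean and standard deviation
(0.22 and 0.35 by default, the values estimated from within-group microarray
error variances) are converted to the underlying log-scale parameters via
the exact lognormal moment identities.  Additive Gaussian noise with the
gene's standard deviation is then applied to every cell.

Cohorts are partitioned into replicate benchmark datasets: within each
group-size tier the datasets are class-balanced and use pairwise-disjoint
subjects, so replicate-to-replicate variation reflects sampling alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NoiseModel",
    "StudyDesign",
    "ExpressionDataset",
    "sample_gene_variances",
    "add_noise",
    "partition",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class NoiseModel:
    """Lognormal model of per-gene error variances.

    ``mean`` and ``sd`` describe the variance *variate* itself (not the
    log-scale parameters); ``clip_negative`` optionally truncates noisy
    expression at 0 (off by default: values are left unclipped).
    """

    mean: float = 0.22
    sd: float = 0.35
    clip_negative: bool = False

    def log_params(self) -> tuple[float, float]:
        """Exact (mu, sigma) of the underlying normal from the moments."""
        m, s = self.mean, self.sd
        if m <= 0 or s <= 0:
            raise ValueError("NoiseModel mean and sd must be positive")
        sigma2 = math.log(1.0 + (s * s) / (m * m))
        mu = math.log(m * m / math.sqrt(m * m + s * s))
        return mu, math.sqrt(sigma2)


def sample_gene_variances(
    p: int, model: NoiseModel, seed: int | None = None
) -> np.ndarray:
    """Draw one strictly positive error variance per gene."""
    mu, sigma = model.log_params()
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=mu, sigma=sigma, size=p)


def add_noise(
    matrix: np.ndarray,
    variances: np.ndarray,
    seed: int | None = None,
    clip_negative: bool = False,
) -> np.ndarray:
    """Add gene-wise N(0, sqrt(variance_i)) noise to a features x samples matrix."""
    matrix = np.asarray(matrix, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if variances.shape != (matrix.shape[0],):
        raise ValueError(
            f"got {variances.size} variances for {matrix.shape[0]} features"
        )
    rng = np.random.default_rng(seed)
    noisy = matrix + rng.standard_normal(matrix.shape) * np.sqrt(variances)[:, None]
    if clip_negative:
        noisy = np.maximum(noisy, 0.0)
    return noisy


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Replicate-dataset layout: per tier, n_datasets disjoint balanced sets."""

    group_sizes: tuple[int, ...] = (50, 20, 15, 10)
    datasets_per_size: int = 10
    seed: int | None = None


@dataclass
class ExpressionDataset:
    """A two-class noisy expression matrix with its ground truth."""

    matrix: np.ndarray  # p features x n samples
    labels: list[str]  # per sample: "healthy" | "diseased"
    feature_ids: list[str]
    sample_ids: list[str]
    truth: frozenset[str] = field(default_factory=frozenset)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p, n = self.matrix.shape
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("label/sample count does not match matrix columns")
        if len(self.feature_ids) != p:
            raise ValueError("feature id count does not match matrix rows")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def y(self) -> np.ndarray:
        """Binary label vector: 1 = diseased, 0 = healthy."""
        return np.asarray([1 if l == "diseased" else 0 for l in self.labels])


def partition(
    healthy_ids: np.ndarray,
    diseased_ids: np.ndarray,
    design: StudyDesign,
) -> dict[int, list[tuple[np.ndarray, np.ndarray]]]:
    """Disjoint balanced index sets per group-size tier.

    Returns {group_size: [(healthy_subset, diseased_subset), ...]}, with the
    subject ids drawn without replacement within each tier.
    """
    healthy_ids = np.asarray(healthy_ids)
    diseased_ids = np.asarray(diseased_ids)
    rng = np.random.default_rng(design.seed)
    out: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for size in design.group_sizes:
        need = size * design.datasets_per_size
        for name, pool in (("healthy", healthy_ids), ("diseased", diseased_ids)):
            if need > len(pool):
                raise ValueError(
                    f"size-{size} tier needs {need} {name} subjects, "
                    f"pool has {len(pool)}"
                )
        hperm = rng.permutation(healthy_ids)
        dperm = rng.permutation(diseased_ids)
        out[size] = [
            (
                hperm[k * size : (k + 1) * size],
                dperm[k * size : (k + 1) * size],
            )
            for k in range(design.datasets_per_size)
        ]
    return out


# ---------------------------------------------------------------------------
# I/O: expression TSV + labels TSV + truth file + manifest JSON
# ---------------------------------------------------------------------------

def write_dataset(ds: ExpressionDataset, prefix) -> None:
    """Write <prefix>.expr.tsv, <prefix>.labels.tsv, <prefix>.truth.txt,
    <prefix>.manifest.json."""
    prefix = str(prefix)
    df = pd.DataFrame(ds.matrix, index=ds.feature_ids, columns=ds.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(prefix + ".expr.tsv", sep="\t", float_format="%.12g")
    with open(prefix + ".labels.tsv", "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, lab in zip(ds.sample_ids, ds.labels):
            fh.write(f"{sid}\t{lab}\n")
    with open(prefix + ".truth.txt", "w") as fh:
        for g in sorted(ds.truth):
            fh.write(f"{g}\n")
    with open(prefix + ".manifest.json", "w") as fh:
        json.dump(ds.provenance, fh, indent=1, default=str)


def read_dataset(prefix) -> ExpressionDataset:
    prefix = str(prefix)
    df = pd.read_csv(prefix + ".expr.tsv", sep="\t", index_col="feature_id")
    feature_ids = [str(i) for i in df.index]
    if len(set(feature_ids)) != len(feature_ids):
        dupes = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
        raise ValueError(f"duplicated feature id(s): {dupes[:5]}")
    labels_by_sample: dict[str, str] = {}
    with open(prefix + ".labels.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample_id", "group"]:
            raise ValueError(f"{prefix}.labels.tsv:1: bad header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{prefix}.labels.tsv:{lineno}: expected 2 columns"
                )
            labels_by_sample[parts[0]] = parts[1]
    sample_ids = [str(c) for c in df.columns]
    missing = [s for s in sample_ids if s not in labels_by_sample]
    if missing:
        raise ValueError(f"samples missing a label entry: {missing[:5]}")
    truth: frozenset[str] = frozenset()
    try:
        with open(prefix + ".truth.txt") as fh:
            truth = frozenset(line.strip() for line in fh if line.strip())
    except FileNotFoundError:
        pass
    provenance: dict = {}
    try:
        with open(prefix + ".manifest.json") as fh:
            provenance = json.load(fh)
    except FileNotFoundError:
        pass
    return ExpressionDataset(
        matrix=df.to_numpy(dtype=float),
        labels=[labels_by_sample[s] for s in sample_ids],
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        truth=truth,
        provenance=provenance,
    )
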