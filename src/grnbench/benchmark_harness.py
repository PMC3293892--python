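"""End-to-end benchmark orchestration and statistical method comparison.

Pipeline: simulate a founder network, evolve genotype heterogeneity, apply
the hub knock-out/knock-down disease model, add measurement noise, partition
the cohorts into replicate datasets, run the ranking methods, and score
precision / recall / AUPR / MCC plus core-Canberra list stability per
group-size tier.  The statistical layer reproduces the paired comparisons:
Wilcoxon signed-rank per method vs its bootstrap variant, Friedman across
the bootstrap variants with Bonferroni-corrected post-hoc Wilcoxon
(alpha/6), and SAM against the eight classification pipelines (alpha/8).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import disease_model, evolution, grn_core
from .dataset_factory import (
    NoiseModel,
    StudyDesign,
    add_noise,
    sample_gene_variances,
    partition,
)
from .feature_ranking import (
    BootstrapSchema,
    default_method,
    sam_test,
    single_rank,
    bootstrap_rank,
)
from .list_metrics import RankedList, aupr, precision_recall, stability_indicator

__all__ = [
    "ExperimentConfig",
    "SimulatedStudy",
    "BenchmarkResult",
    "simulate_study",
    "evaluate_tier",
    "run_experiment",
    "compare_methods",
    "summarize",
]

MULTIVARIATE_METHODS = ("LSVM", "GSVM", "SRDA", "IRELIEF")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full parameterization of one benchmark experiment.

    Defaults are the reduced scale used for desk-sized runs: the evolvable
    subnetwork keeps the founder's mean regulatory degree (~1.8 edges/gene)
    and the population is large enough to supply ten disjoint balanced
    datasets of 20 subjects per group from each class pool.
    """

    p: int = 2000
    n_sub: int = 300
    nnz_sub: int | None = None  # default: round(1619/900 * n_sub)
    hub_bias: float = 2.0
    M: int = 400
    generations: int = 30
    mutation_rate: float = 0.025
    survival_percentile: float = 99.5
    theta: float | None = None
    n_hubs: int = 6
    expr_min: float = 0.88
    epsilon: float = 0.01
    noise: NoiseModel = field(default_factory=NoiseModel)
    group_sizes: tuple[int, ...] = (20, 10)
    datasets_per_size: int = 10
    methods: tuple[str, ...] = MULTIVARIATE_METHODS
    modes: tuple[str, ...] = ("single", "bootstrap")
    B: int = 20
    sam_permutations: int = 200
    sam_fdr: float = 0.05
    include_sam: bool = True
    topology_attempts: int = 20
    seed: int = 0

    def resolved_nnz(self) -> int:
        if self.nnz_sub is not None:
            return self.nnz_sub
        return int(round(1619 / 900 * self.n_sub))


@dataclass
class SimulatedStudy:
    """A simulated two-group cohort with known biomarkers."""

    config: ExperimentConfig
    hubs: disease_model.HubSet
    truth: frozenset  # biomarker gene indices
    truth_changes: dict
    matrix: np.ndarray  # p x n noisy expression
    labels: np.ndarray  # 0 healthy / 1 diseased per column
    theta: float
    topology_seed: int
    evolution_log: list
    variances: np.ndarray

    @property
    def healthy_cols(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)

    @property
    def diseased_cols(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)


@dataclass
class BenchmarkResult:
    """Per-(method, mode, tier, dataset) scores plus per-tier stability."""

    table: pd.DataFrame
    stability: pd.DataFrame
    selected_lists: dict  # (method, mode, size) -> list[RankedList]
    config: ExperimentConfig


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_study(config: ExperimentConfig) -> SimulatedStudy:
    """Simulate founder, evolution, disease and noise into one cohort matrix.

    Topology draws that leave fewer than ``n_hubs`` evolvable genes above
    the hub expression threshold are rejected and redrawn with the next
    seed (deterministically), mirroring that hub eligibility is a property
    of the network realization.
    """
    rng = np.random.default_rng(config.seed)
    sub_seeds = rng.integers(2**31, size=8)

    founder = hubs = phenotype = None
    topo_seed = int(sub_seeds[0])
    for attempt in range(config.topology_attempts):
        cand_seed = topo_seed + attempt
        cand = grn_core.generate_topology(
            config.p,
            config.n_sub,
            config.resolved_nnz(),
            hub_bias=config.hub_bias,
            seed=cand_seed,
        )
        st = grn_core.steady_state(cand)
        if not st.converged:
            continue
        try:
            hubs = disease_model.select_hubs(
                cand, st.x, k=config.n_hubs, expr_min=config.expr_min
            )
        except ValueError:
            continue
        founder, phenotype, topo_seed = cand, st.x, cand_seed
        break
    if founder is None:
        raise RuntimeError(
            f"no topology with {config.n_hubs} eligible hubs found in "
            f"{config.topology_attempts} attempts"
        )

    evo = evolution.evolve(
        founder,
        evolution.EvolutionConfig(
            M=config.M,
            generations=config.generations,
            mutation_rate=config.mutation_rate,
            survival_percentile=config.survival_percentile,
            theta=config.theta,
            seed=int(sub_seeds[1]),
        ),
    )

    truth = disease_model.derive_truth(founder, phenotype, hubs, config.epsilon)
    n_d = config.M // 2
    n_h = config.M - n_d
    plan = disease_model.assign_perturbations(n_d, hubs, seed=int(sub_seeds[2]))
    healthy, diseased = disease_model.build_cohorts(
        evo, plan, n_h, n_d, seed=int(sub_seeds[3])
    )

    clean = np.hstack([healthy, diseased])
    labels = np.concatenate([np.zeros(n_h, dtype=int), np.ones(n_d, dtype=int)])
    variances = sample_gene_variances(config.p, config.noise, seed=int(sub_seeds[4]))
    noisy = add_noise(
        clean, variances, seed=int(sub_seeds[5]), clip_negative=config.noise.clip_negative
    )
    return SimulatedStudy(
        config=config,
        hubs=hubs,
        truth=frozenset(truth.gene_ids),
        truth_changes=truth.change,
        matrix=noisy,
        labels=labels,
        theta=evo.theta,
        topology_seed=topo_seed,
        evolution_log=list(evo.log),
        variances=variances,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _dataset_arrays(
    study: SimulatedStudy, h_cols: np.ndarray, d_cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    cols = np.concatenate([h_cols, d_cols])
    X = study.matrix[:, cols].T  # samples x features
    y = np.concatenate([np.zeros(len(h_cols), dtype=int), np.ones(len(d_cols), dtype=int)])
    return X, y


def evaluate_tier(
    study: SimulatedStudy,
    size: int,
    datasets: list[tuple[np.ndarray, np.ndarray]],
    methods: tuple[str, ...],
    modes: tuple[str, ...],
    seed: int,
    include_sam: bool | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run every (method, mode) on each dataset of one group-size tier."""
    config = study.config
    include_sam = config.include_sam if include_sam is None else include_sam
    rows = []
    lists: dict = {}
    rng = np.random.default_rng(seed)
    for d_idx, (h_cols, d_cols) in enumerate(datasets):
        X, y = _dataset_arrays(study, h_cols, d_cols)
        ds_seed = int(rng.integers(2**31))
        for m_idx, name in enumerate(methods):
            spec = default_method(name)
            for mode in modes:
                mode_off = {"single": 0, "bootstrap": 104729}.get(mode, 1)
                run_seed = (ds_seed + 7919 * m_idx + mode_off) % (2**31)
                if mode == "single":
                    run = single_rank(spec, X, y, seed=run_seed)
                elif mode == "bootstrap":
                    run = bootstrap_rank(
                        spec, X, y, BootstrapSchema(B=config.B), seed=run_seed
                    )
                else:
                    raise ValueError(f"unknown mode {mode!r}")
                prec, rec = precision_recall(run.selected, study.truth)
                area = aupr(run.ranking, study.truth)
                rows.append(
                    dict(
                        size=size,
                        dataset=d_idx,
                        method=name,
                        mode=mode,
                        n_star=run.n_star,
                        precision=prec,
                        recall=rec,
                        aupr=area,
                        mcc=run.mcc_value,
                    )
                )
                key = (name, mode, size)
                lists.setdefault(key, []).append(
                    RankedList(run.ranking.ids[: run.n_star], p=config.p)
                )
        if include_sam:
            sam = sam_test(
                X,
                y,
                fdr=config.sam_fdr,
                n_perm=config.sam_permutations,
                seed=ds_seed,
            )
            if sam.selected:
                prec, rec = precision_recall(sam.selected, study.truth)
            else:
                prec, rec = np.nan, 0.0
            sam_ranking = RankedList(tuple(int(g) for g in sam.order), p=config.p)
            rows.append(
                dict(
                    size=size,
                    dataset=d_idx,
                    method="SAM",
                    mode="single",
                    n_star=len(sam.selected),
                    precision=prec,
                    recall=rec,
                    aupr=aupr(sam_ranking, study.truth),
                    mcc=np.nan,
                )
            )
            if sam.selected:
                top = [g for g in sam.order if g in sam.selected]
                lists.setdefault(("SAM", "single", size), []).append(
                    RankedList(tuple(int(g) for g in top), p=config.p)
                )
    return pd.DataFrame(rows), lists


def _stability_frame(lists: dict, p: int) -> pd.DataFrame:
    rows = []
    for (name, mode, size), ls in sorted(lists.items()):
        if len(ls) < 2:
            continue
        rep = stability_indicator(ls, p=p, distance="core")
        rows.append(
            dict(
                size=size,
                method=name,
                mode=mode,
                n_lists=rep.n_lists,
                raw_mean_distance=rep.raw_mean_distance,
                stability=rep.value,
            )
        )
    return pd.DataFrame(rows)


def run_experiment(
    config: ExperimentConfig, study: SimulatedStudy | None = None
) -> BenchmarkResult:
    """Simulate (unless a study is supplied) and evaluate the full roster."""
    if study is None:
        study = simulate_study(config)
    design = StudyDesign(
        group_sizes=config.group_sizes,
        datasets_per_size=config.datasets_per_size,
        seed=config.seed + 1,
    )
    parts = partition(study.healthy_cols, study.diseased_cols, design)
    tables, lists = [], {}
    for t_idx, size in enumerate(config.group_sizes):
        tab, ls = evaluate_tier(
            study,
            size,
            parts[size],
            config.methods,
            config.modes,
            seed=config.seed + 100 + t_idx,
        )
        tables.append(tab)
        lists.update(ls)
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return BenchmarkResult(
        table=table,
        stability=_stability_frame(lists, config.p),
        selected_lists=lists,
        config=config,
    )


# ---------------------------------------------------------------------------
# Statistical comparisons
# ---------------------------------------------------------------------------

def _paired(table: pd.DataFrame, size: int, metric: str, sel: dict) -> np.ndarray:
    sub = table[(table["size"] == size)]
    for k, v in sel.items():
        sub = sub[sub[k] == v]
    return sub.sort_values("dataset")[metric].to_numpy()


def compare_methods(
    table: pd.DataFrame, metric: str = "precision", alpha: float = 0.05
) -> pd.DataFrame:
    """Paired significance tests per group-size tier.

    Per method vs its bootstrap variant: Wilcoxon signed-rank at alpha;
    across the four bootstrap variants: Friedman at alpha with post-hoc
    pairwise Wilcoxon at alpha/6; SAM vs the eight pipelines at alpha/8.
    """
    rows = []
    for size in sorted(table["size"].unique()):
        # method vs bootstrap variant
        for name in MULTIVARIATE_METHODS:
            a = _paired(table, size, metric, {"method": name, "mode": "single"})
            b = _paired(table, size, metric, {"method": name, "mode": "bootstrap"})
            if len(a) and len(a) == len(b):
                pval = _wilcoxon(a, b)
                rows.append(
                    dict(
                        size=size,
                        comparison=f"{name} vs {name}_B",
                        test="wilcoxon",
                        p_value=pval,
                        alpha=alpha,
                        significant=bool(pval < alpha),
                    )
                )
        # Friedman across bootstrap variants
        groups = [
            _paired(table, size, metric, {"method": n, "mode": "bootstrap"})
            for n in MULTIVARIATE_METHODS
        ]
        if all(len(g) == len(groups[0]) and len(g) >= 3 for g in groups):
            if all(np.allclose(g, groups[0]) for g in groups):
                fried_p = 1.0  # identical vectors carry no evidence
            else:
                fried_p = float(stats.friedmanchisquare(*groups).pvalue)
            if np.isnan(fried_p):
                fried_p = 1.0
            rows.append(
                dict(
                    size=size,
                    comparison="bootstrap variants",
                    test="friedman",
                    p_value=fried_p,
                    alpha=alpha,
                    significant=bool(fried_p < alpha),
                )
            )
            if fried_p < alpha:
                post_alpha = alpha / len(list(combinations(MULTIVARIATE_METHODS, 2)))
                for na, nb in combinations(MULTIVARIATE_METHODS, 2):
                    a = _paired(table, size, metric, {"method": na, "mode": "bootstrap"})
                    b = _paired(table, size, metric, {"method": nb, "mode": "bootstrap"})
                    pval = _wilcoxon(a, b)
                    rows.append(
                        dict(
                            size=size,
                            comparison=f"{na}_B vs {nb}_B",
                            test="wilcoxon",
                            p_value=pval,
                            alpha=post_alpha,
                            significant=bool(pval < post_alpha),
                        )
                    )
        # SAM vs the eight pipelines
        sam = _paired(table, size, metric, {"method": "SAM"})
        if len(sam):
            sam_alpha = alpha / 8
            for name in MULTIVARIATE_METHODS:
                for mode in ("single", "bootstrap"):
                    other = _paired(
                        table, size, metric, {"method": name, "mode": mode}
                    )
                    if len(other) == len(sam) and len(sam) >= 3:
                        pval = _wilcoxon(sam, other)
                        label = f"SAM vs {name}" + ("_B" if mode == "bootstrap" else "")
                        rows.append(
                            dict(
                                size=size,
                                comparison=label,
                                test="wilcoxon",
                                p_value=pval,
                                alpha=sam_alpha,
                                significant=bool(pval < sam_alpha),
                            )
                        )
    return pd.DataFrame(rows)


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 3 or np.allclose(a, b):
        return 1.0
    return float(stats.wilcoxon(a, b).pvalue)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def summarize(result: BenchmarkResult, outdir=None) -> dict:
    """Per-size-per-method summary tables (mean with min/max range, boxplot
    quartiles, stability); optionally written as CSV + JSON."""
    table = result.table
    summary: dict = {"mcc_table": [], "boxplots": [], "stability": []}
    for (size, name, mode), grp in table.groupby(["size", "method", "mode"]):
        label = name + ("_B" if mode == "bootstrap" else "")
        m = grp["mcc"].dropna()
        if len(m):
            summary["mcc_table"].append(
                dict(
                    size=int(size),
                    method=label,
                    mean=float(m.mean()),
                    min=float(m.min()),
                    max=float(m.max()),
                    formatted=f"{m.mean():.2f} ({m.min():.2f}, {m.max():.2f})",
                )
            )
        for metric in ("precision", "aupr"):
            v = grp[metric].dropna()
            if len(v):
                q1, q2, q3 = np.percentile(v, [25, 50, 75])
                summary["boxplots"].append(
                    dict(
                        size=int(size),
                        method=label,
                        metric=metric,
                        q1=float(q1),
                        median=float(q2),
                        q3=float(q3),
                        n_selected_iqr=[
                            float(np.percentile(grp["n_star"], 25)),
                            float(np.percentile(grp["n_star"], 75)),
                        ],
                    )
                )
    if len(result.stability):
        summary["stability"] = result.stability.to_dict(orient="records")
    if outdir is not None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "results.csv", index=False)
        result.stability.to_csv(outdir / "stability.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        with open(outdir / "config.json", "w") as fh:
            json.dump(asdict(result.config), fh, indent=1, default=str)
    return summary
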