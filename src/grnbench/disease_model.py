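"""Disease simulation: hub perturbations and the ground-truth biomarker set.

The pathological condition is modelled by knocking out or down a handful of
regulator hubs — genes of the evolvable subnetwork with the highest
out-degree whose founder steady-state expression exceeds a threshold (so the
perturbation has something to suppress).  Knock-out zeroes row *j* of the
weight matrix and clamps the gene's expression at 0; knock-down halves
row *j* and the gene's transcription ceiling.  Each diseased subject carries
its own subset of affected hubs (4, 5 or 6, in equal thirds) with a per-hub
1/3 knock-out : 2/3 knock-down split, so the diseased group is heterogeneous
both in genotype (evolution) and in lesion.

Ground-truth biomarkers are the genes directly or indirectly regulated by at
least one hub whose noise-free steady state actually moves under some
single-hub perturbation, plus the perturbed hubs themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .grn_core import GeneNetwork, steady_state

__all__ = [
    "HubSet",
    "PerturbationPlan",
    "BiomarkerTruth",
    "select_hubs",
    "knock_out",
    "knock_down",
    "assign_perturbations",
    "derive_truth",
    "build_cohorts",
    "perturbed_steady_state",
]

KO, KD = "KO", "KD"


@dataclass(frozen=True)
class HubSet:
    """Perturbation targets, sorted by descending out-degree."""

    gene_ids: tuple[int, ...]
    out_degrees: tuple[int, ...]
    expressions: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class PerturbationPlan:
    """Per diseased subject: which hubs are hit and how.

    ``assignments[s]`` is a dict {hub gene id -> "KO" | "KD"} for diseased
    subject s (indexed 0 .. n_diseased-1 within the diseased group).
    """

    assignments: list[dict[int, str]]

    @property
    def n_subjects(self) -> int:
        return len(self.assignments)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("subject_id\thub_id\ttype\n")
            for s, plan in enumerate(self.assignments):
                for hub, kind in sorted(plan.items()):
                    fh.write(f"{s}\t{hub}\t{kind}\n")


@dataclass(frozen=True)
class BiomarkerTruth:
    """Genes whose noise-free steady state responds to hub perturbation."""

    gene_ids: frozenset[int]
    change: dict[int, float]  # max |steady-state change| per candidate gene
    epsilon: float

    def write(self, ids_path, changes_path=None) -> None:
        with open(ids_path, "w") as fh:
            for g in sorted(self.gene_ids):
                fh.write(f"{g}\n")
        if changes_path is not None:
            with open(changes_path, "w") as fh:
                fh.write("gene_id\tmax_abs_change\n")
                for g in sorted(self.change):
                    fh.write(f"{g}\t{self.change[g]:.12g}\n")


# ---------------------------------------------------------------------------
# Hub selection
# ---------------------------------------------------------------------------

def select_hubs(
    founder: GeneNetwork,
    phenotype: np.ndarray,
    k: int = 6,
    expr_min: float = 0.88,
) -> HubSet:
    """The k highest-out-degree evolvable genes expressed above ``expr_min``.

    Ties in out-degree break toward higher expression, then lower gene index.
    """
    if k == 0:
        return HubSet((), (), ())
    deg = founder.out_degrees()
    eligible = [
        int(g) for g in founder.evolvable_idx if phenotype[g] > expr_min
    ]
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} evolvable genes exceed expression {expr_min}; "
            f"need {k} — lower expr_min or redraw the topology"
        )
    eligible.sort(key=lambda g: (-deg[g], -phenotype[g], g))
    chosen = eligible[:k]
    return HubSet(
        gene_ids=tuple(chosen),
        out_degrees=tuple(int(deg[g]) for g in chosen),
        expressions=tuple(float(phenotype[g]) for g in chosen),
    )


# ---------------------------------------------------------------------------
# Perturbation operators
# ---------------------------------------------------------------------------

def _apply_perturbations(
    net: GeneNetwork, plan: dict[int, str]
) -> tuple[GeneNetwork, np.ndarray, np.ndarray]:
    """Modified network plus the KO clamp mask and KD capacity vector."""
    W = net.W.tolil(copy=True)
    clamp = np.zeros(net.p, dtype=bool)
    cap = np.ones(net.p)
    for j, kind in plan.items():
        if kind == KO:
            W.rows[j] = []
            W.data[j] = []
            clamp[j] = True
        elif kind == KD:
            W.data[j] = [0.5 * v for v in W.data[j]]
            cap[j] = 0.5
        else:
            raise ValueError(f"unknown perturbation type {kind!r}")
    pert = GeneNetwork(
        p=net.p,
        W=W.tocsr(),
        evolvable_idx=net.evolvable_idx,
        alpha=net.alpha,
        beta=net.beta,
        bias=net.bias,
        nnz_evolvable=net.nnz_evolvable,
    )
    return pert, clamp, cap


def perturbed_steady_state(
    net: GeneNetwork, phenotype: np.ndarray, plan: dict[int, str]
) -> tuple[GeneNetwork, np.ndarray]:
    """Recompute the steady state after applying a joint KO/KD plan.

    Integration starts from the unperturbed phenotype with the perturbed
    genes already suppressed (KO genes at 0, KD genes at half value).
    """
    pert, clamp, cap = _apply_perturbations(net, plan)
    x0 = phenotype.copy()
    for j, kind in plan.items():
        x0[j] = 0.0 if kind == KO else 0.5 * x0[j]
    st = steady_state(pert, x0=x0, clamp_zero=clamp, capacity=cap)
    return pert, st.x


def knock_out(
    net: GeneNetwork, phenotype: np.ndarray, j: int
) -> tuple[GeneNetwork, np.ndarray]:
    """Zero row j of W, clamp gene j's expression at 0, re-solve."""
    return perturbed_steady_state(net, phenotype, {int(j): KO})


def knock_down(
    net: GeneNetwork, phenotype: np.ndarray, j: int
) -> tuple[GeneNetwork, np.ndarray]:
    """Halve row j of W and gene j's transcription ceiling, re-solve."""
    return perturbed_steady_state(net, phenotype, {int(j): KD})


# ---------------------------------------------------------------------------
# Per-subject perturbation assignment
# ---------------------------------------------------------------------------

def assign_perturbations(
    n_diseased: int,
    hubs: HubSet,
    seed: int | None = None,
    subset_sizes: tuple[int, ...] = (4, 5, 6),
    ko_fraction: float = 1.0 / 3.0,
) -> PerturbationPlan:
    """Assign each diseased subject an affected hub subset and KO/KD types.

    Subjects split into equal thirds by affected-subset size (remainders to
    the smaller sizes); each subject's subset is drawn uniformly among hub
    subsets of its size; per hub, affected subjects split 1/3 KO : 2/3 KD
    (remainders to KD).
    """
    if n_diseased < 0:
        raise ValueError("n_diseased must be non-negative")
    if len(hubs) < max(subset_sizes, default=0):
        raise ValueError(
            f"{len(hubs)} hubs cannot supply subsets of size {max(subset_sizes)}"
        )
    rng = np.random.default_rng(seed)
    if n_diseased == 0:
        return PerturbationPlan(assignments=[])

    n_groups = len(subset_sizes)
    base, rem = divmod(n_diseased, n_groups)
    counts = [base + (1 if i < rem else 0) for i in range(n_groups)]

    sizes_per_subject: list[int] = []
    for size, cnt in zip(subset_sizes, counts):
        sizes_per_subject.extend([size] * cnt)

    hub_ids = np.asarray(hubs.gene_ids)
    subsets = [
        rng.choice(hub_ids, size=s, replace=False).tolist()
        for s in sizes_per_subject
    ]

    # per hub, split its affected subjects into floor(n/3) KO, rest KD
    assignments: list[dict[int, str]] = [dict() for _ in range(n_diseased)]
    for hub in hub_ids:
        affected = [s for s, sub in enumerate(subsets) if hub in sub]
        perm = rng.permutation(len(affected))
        n_ko = int(len(affected) * ko_fraction)
        for r, pos in enumerate(perm):
            assignments[affected[pos]][int(hub)] = KO if r < n_ko else KD
    return PerturbationPlan(assignments=assignments)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def hub_reachable_genes(net: GeneNetwork, hubs: HubSet) -> set[int]:
    """Genes reachable from any hub in the regulation digraph (j -> i iff
    W[i, j] != 0), hubs included."""
    Wc = net.W.tocsc()
    reach: set[int] = set(hubs.gene_ids)
    frontier = list(hubs.gene_ids)
    while frontier:
        j = frontier.pop()
        s, e = Wc.indptr[j], Wc.indptr[j + 1]
        for i in Wc.indices[s:e]:
            i = int(i)
            if i not in reach:
                reach.add(i)
                frontier.append(i)
    return reach


def derive_truth(
    founder: GeneNetwork,
    phenotype: np.ndarray,
    hubs: HubSet,
    epsilon: float = 0.01,
) -> BiomarkerTruth:
    """Biomarkers: hub-reachable genes whose noise-free steady state moves
    by more than ``epsilon`` under some single-hub KO or KD (hubs included).
    """
    candidates = hub_reachable_genes(founder, hubs)
    change = {g: 0.0 for g in candidates}
    for hub in hubs.gene_ids:
        for kind in (KO, KD):
            _, x = perturbed_steady_state(founder, phenotype, {hub: kind})
            delta = np.abs(x - phenotype)
            for g in candidates:
                if delta[g] > change[g]:
                    change[g] = float(delta[g])
    truth = frozenset(g for g, c in change.items() if c > epsilon)
    return BiomarkerTruth(gene_ids=truth, change=change, epsilon=epsilon)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def build_cohorts(
    population,
    plan: PerturbationPlan,
    n_healthy: int,
    n_diseased: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expression matrices for disjoint healthy/diseased groups.

    Subjects are drawn without replacement from the evolved population:
    healthy columns are unperturbed steady states; each diseased subject's
    steady state is recomputed on its own genotype under its joint plan.
    Returns (healthy p x n_healthy, diseased p x n_diseased).
    """
    if plan.n_subjects != n_diseased:
        raise ValueError("plan size does not match n_diseased")
    if n_healthy + n_diseased > population.size:
        raise ValueError(
            f"population of {population.size} cannot supply "
            f"{n_healthy}+{n_diseased} disjoint subjects"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(population.size)
    healthy_ids = order[:n_healthy]
    diseased_ids = order[n_healthy : n_healthy + n_diseased]

    healthy = np.column_stack(
        [population.individuals[i].phenotype for i in healthy_ids]
    )
    cols = []
    for s, i in enumerate(diseased_ids):
        net = population.network_of(int(i))
        pheno = population.individuals[int(i)].phenotype
        _, x = perturbed_steady_state(net, pheno, plan.assignments[s])
        cols.append(x)
    diseased = np.column_stack(cols) if cols else np.empty((population.founder.p, 0))
    return healthy, diseased
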