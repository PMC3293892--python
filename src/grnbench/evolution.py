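"""Evolve a population of regulatory networks under phenotype-preserving selection.

Starting from a founder genotype shared by every individual, each generation
applies three operators to the evolvable subnetwork only:

* pairing    — each evolvable row of the child's weight matrix is taken whole
               from one of two randomly chosen parents with probability 1/2;
* mutation   — each nonzero evolvable weight is independently replaced by a
               fresh Normal(0, 1) draw with probability rate / nnz, so a
               subject carries >= 1 mutation with probability ~ rate;
* selection  — a candidate survives iff the Euclidean distance between its
               steady-state phenotype and the founder reference profile does
               not exceed the threshold theta.

The population is refilled to its fixed size M every generation.  The result
is a pool of subjects with (numerically) the same phenotype but different
genotypes — the intrinsic biological variability of the benchmark cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .grn_core import GeneNetwork, steady_state, steady_state_batch

__all__ = [
    "Individual",
    "Population",
    "EvolutionConfig",
    "pair_offspring",
    "mutate",
    "mutate_block",
    "select_survivors",
    "calibrate_threshold",
    "evolve",
    "mutation_event_frequency",
]


@dataclass
class Individual:
    """One subject: its evolvable weight block and full phenotype vector."""

    block: sp.csr_matrix
    phenotype: np.ndarray


@dataclass
class Population:
    """A generation of individuals sharing the founder's background genes."""

    founder: GeneNetwork
    individuals: list[Individual]
    founder_profile: np.ndarray
    theta: float
    generation: int = 0
    # per-generation (n_mutated_survivors, n_eliminated) counters
    log: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.individuals)

    def phenotypes(self) -> np.ndarray:
        """(p, M) matrix of subject phenotypes."""
        return np.column_stack([ind.phenotype for ind in self.individuals])

    def network_of(self, i: int) -> GeneNetwork:
        return self.founder.with_evolvable_block(self.individuals[i].block)

    def write_log(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("generation\tn_mutated\tn_eliminated\n")
            for gen, n_mut, n_elim in self.log:
                fh.write(f"{gen}\t{n_mut}\t{n_elim}\n")


@dataclass(frozen=True)
class EvolutionConfig:
    M: int = 1000
    generations: int = 150
    mutation_rate: float = 0.025  # per-subject probability of >= 1 mutation
    survival_percentile: float = 99.5
    theta: float | None = None  # fixed override; None = calibrate per run
    n_probe_mutants: int = 1000
    retry_factor: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must lie in (0, 1)")
        if not 0 < self.survival_percentile <= 100:
            raise ValueError("survival_percentile must lie in (0, 100]")


# ---------------------------------------------------------------------------
# Operators (on evolvable blocks)
# ---------------------------------------------------------------------------

def _mix_rows(
    a: sp.csr_matrix, b: sp.csr_matrix, from_a: np.ndarray
) -> sp.csr_matrix:
    """CSR matrix whose row i is row i of ``a`` where from_a[i] else of ``b``."""
    n = a.shape[0]
    counts = np.where(from_a, np.diff(a.indptr), np.diff(b.indptr))
    indptr = np.zeros(n + 1, dtype=a.indptr.dtype)
    np.cumsum(counts, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=a.indices.dtype)
    data = np.empty(indptr[-1], dtype=a.data.dtype)
    for i in range(n):
        src = a if from_a[i] else b
        s, e = src.indptr[i], src.indptr[i + 1]
        o, q = indptr[i], indptr[i + 1]
        indices[o:q] = src.indices[s:e]
        data[o:q] = src.data[s:e]
    return sp.csr_matrix((data, indices, indptr), shape=a.shape)


def pair_offspring(
    parent_a: "GeneNetwork | sp.spmatrix",
    parent_b: "GeneNetwork | sp.spmatrix",
    seed: int | np.random.Generator | None = None,
) -> "GeneNetwork | sp.csr_matrix":
    """Child: each evolvable row taken whole from parent A or B with prob 1/2.

    Accepts either two :class:`GeneNetwork` parents (background block and
    kinetics inherited from parent A's template — parents are identical
    there by construction) or two bare evolvable blocks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(parent_a, GeneNetwork):
        if not isinstance(parent_b, GeneNetwork) or parent_a.p != parent_b.p or not np.array_equal(
            parent_a.evolvable_idx, parent_b.evolvable_idx
        ):
            raise ValueError("parents are structurally incompatible")
        a = parent_a.evolvable_block()
        b = parent_b.evolvable_block()
        child = _mix_rows(a, b, rng.random(a.shape[0]) < 0.5)
        return parent_a.with_evolvable_block(child)
    a = sp.csr_matrix(parent_a)
    b = sp.csr_matrix(parent_b)
    if a.shape != b.shape:
        raise ValueError(f"incompatible parent blocks {a.shape} vs {b.shape}")
    return _mix_rows(a, b, rng.random(a.shape[0]) < 0.5)


def mutate_block(
    block: sp.spmatrix,
    nnz: int,
    subject_rate: float,
    rng: np.random.Generator,
) -> tuple[sp.csr_matrix, bool]:
    """Replace each nonzero weight with prob ``subject_rate / nnz`` by N(0,1).

    Zero entries never mutate, so the sparsity pattern is immutable.  ``nnz``
    is the founder's recorded nonzero count (the fixed rate denominator).
    """
    out = sp.csr_matrix(block, copy=True)
    if subject_rate == 0 or out.nnz == 0:
        return out, False
    hit = rng.random(out.nnz) < subject_rate / nnz
    n_hit = int(hit.sum())
    if n_hit == 0:
        return out, False
    out.data[hit] = rng.standard_normal(n_hit)
    return out, True


def mutate(
    net: GeneNetwork,
    subject_rate: float = 0.025,
    seed: int | np.random.Generator | None = None,
) -> tuple[GeneNetwork, bool]:
    """Whole-network wrapper around :func:`mutate_block`."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    block, changed = mutate_block(
        net.evolvable_block(), net.nnz_evolvable, subject_rate, rng
    )
    return (net.with_evolvable_block(block) if changed else net), changed


def select_survivors(
    candidates: list[Individual],
    founder_profile: np.ndarray,
    theta: float,
) -> list[Individual]:
    """Candidates whose phenotype lies within ``theta`` of the reference."""
    return [
        ind
        for ind in candidates
        if float(np.linalg.norm(ind.phenotype - founder_profile)) <= theta
    ]


def mutation_event_frequency(
    nnz: int,
    subject_rate: float,
    n_subjects: int,
    seed: int | None = None,
) -> float:
    """Monte Carlo fraction of subjects carrying >= 1 mutated weight.

    Each of ``nnz`` nonzero weights mutates independently with probability
    ``subject_rate / nnz``; the count of hits per subject is Binomial.
    """
    rng = np.random.default_rng(seed)
    hits = rng.binomial(nnz, subject_rate / nnz, size=n_subjects)
    return float(np.mean(hits > 0))


# ---------------------------------------------------------------------------
# Threshold calibration and the main loop
# ---------------------------------------------------------------------------

def _founder_state(founder: GeneNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full founder phenotype plus its evolvable sub-vector and bias."""
    st = steady_state(founder)
    if not st.converged:
        raise RuntimeError("founder steady state did not converge")
    idx = founder.evolvable_idx
    return st.x, st.x[idx], founder.bias[idx]


def _full_phenotype(
    founder_x: np.ndarray, evolvable_idx: np.ndarray, sub_x: np.ndarray
) -> np.ndarray:
    x = founder_x.copy()
    x[evolvable_idx] = sub_x
    return x


def calibrate_threshold(
    founder: GeneNetwork,
    n_probe_mutants: int = 1000,
    percentile: float = 99.5,
    seed: int | None = None,
) -> float:
    """Empirical survival threshold from single-mutation probe subjects.

    Generates ``n_probe_mutants`` copies of the founder, each with exactly
    one randomly chosen nonzero evolvable weight resampled from N(0, 1)
    (the typical mutation load of a mutated subject at the default rate),
    and returns the requested percentile of their phenotype distances from
    the founder profile.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    if n_probe_mutants < 100:
        raise ValueError("need at least 100 probe mutants")
    rng = np.random.default_rng(seed)
    founder_x, sub_x0, bias = _founder_state(founder)
    base = founder.evolvable_block()
    blocks = []
    for _ in range(n_probe_mutants):
        blk = sp.csr_matrix(base, copy=True)
        k = int(rng.integers(blk.nnz))
        blk.data[k] = rng.standard_normal()
        blocks.append(blk)
    X = steady_state_batch(blocks, bias, x0=sub_x0)
    dists = np.linalg.norm(X - sub_x0[:, None], axis=0)
    return float(np.percentile(dists, percentile))


def evolve(founder: GeneNetwork, config: EvolutionConfig) -> Population:
    """Run the pairing / mutation / selection loop for ``config.generations``.

    Each generation assembles exactly M survivors, regenerating offspring
    whose phenotype drifted beyond theta; raises if the retry budget
    (``retry_factor * M`` candidate draws per generation) is exhausted.
    Only evolvable-block steady states are recomputed — background genes are
    untouched by every operator, so their steady state is the founder's.
    """
    rng = np.random.default_rng(config.seed)
    founder_x, sub_x0, bias = _founder_state(founder)
    idx = founder.evolvable_idx

    theta = config.theta
    if theta is None:
        theta = calibrate_threshold(
            founder,
            config.n_probe_mutants,
            config.survival_percentile,
            seed=int(rng.integers(2**31)),
        )

    base_block = founder.evolvable_block()
    pop = Population(
        founder=founder,
        individuals=[
            Individual(block=base_block, phenotype=founder_x.copy())
            for _ in range(config.M)
        ],
        founder_profile=founder_x.copy(),
        theta=theta,
        generation=0,
    )
    ref_sub = founder_x[idx]

    for gen in range(1, config.generations + 1):
        survivors: list[Individual] = []
        n_mut_surv = 0
        n_elim = 0
        budget = config.retry_factor * config.M
        spent = 0
        parents = pop.individuals
        while len(survivors) < config.M:
            batch = min(config.M - len(survivors), config.M)
            if spent + batch > budget:
                raise RuntimeError(
                    f"generation {gen}: could not assemble {config.M} survivors "
                    f"within the retry budget; consider a larger theta"
                )
            spent += batch
            blocks, mut_flags = [], []
            for _ in range(batch):
                ia, ib = rng.integers(len(parents), size=2)
                pa, pb = parents[ia].block, parents[ib].block
                child = _mix_rows(pa, pb, rng.random(pa.shape[0]) < 0.5)
                child, mutated = mutate_block(
                    child, founder.nnz_evolvable, config.mutation_rate, rng
                )
                blocks.append(child)
                mut_flags.append(mutated)
            X = steady_state_batch(blocks, bias, x0=sub_x0)
            dists = np.linalg.norm(X - ref_sub[:, None], axis=0)
            for k in range(batch):
                if dists[k] <= theta:
                    if len(survivors) < config.M:
                        survivors.append(
                            Individual(
                                block=blocks[k],
                                phenotype=_full_phenotype(founder_x, idx, X[:, k]),
                            )
                        )
                        n_mut_surv += int(mut_flags[k])
                else:
                    n_elim += 1
        pop.individuals = survivors
        pop.generation = gen
        pop.log.append((gen, n_mut_surv, n_elim))
    return pop
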