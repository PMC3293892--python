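"""Gene regulatory networks: topology, kinetics and steady-state phenotypes.

A subject is modelled as a sparse signed regulatory network over ``p`` genes.
Entry ``W[i, j]`` is nonzero iff gene product *j* directly regulates the
transcription of gene *i*; the sign encodes activation/repression and the
magnitude the strength of the interaction.  A contiguous "evolvable"
subnetwork is kept disconnected from the remaining background genes so that
evolutionary operators applied to it can never leak into the background.

Normalized expression follows saturating relaxation dynamics

    dx_i/dt = beta_i * (sigma(sum_j W[i, j] x_j + bias_i) - x_i),

with the logistic squash ``sigma``.  The normalized fixed point lies in
[0, 1] and does not depend on the kinetic rates (``alpha_i`` sets the
absolute transcript scale ``alpha_i / beta_i * x_i`` and ``beta_i`` the time
constant); every downstream threshold in the benchmark is applied on the
normalized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GeneNetwork",
    "KineticsPrior",
    "ExpressionState",
    "generate_topology",
    "sample_kinetics",
    "steady_state",
    "steady_state_batch",
    "write_network",
    "read_network",
]

# Solver defaults: damped fixed-point iteration on x <- sigma(Wx + b),
# tolerance on the max-norm residual, iteration cap in damped steps.
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 2_000
DAMPING = 0.5


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class GeneNetwork:
    """Genotype of one subject: wiring plus per-gene kinetic parameters.

    Attributes
    ----------
    p : int
        Total number of genes.
    W : scipy.sparse.csr_matrix
        p x p signed weight matrix; ``W[i, j] != 0`` iff gene j regulates
        gene i.
    evolvable_idx : numpy.ndarray
        Sorted indices of the evolvable subnetwork; no edge crosses the
        boundary between evolvable and background genes.
    alpha, beta : numpy.ndarray
        Per-gene maximal transcription and degradation rates (> 0).
    bias : numpy.ndarray
        Per-gene basal regulatory input (default 0).
    nnz_evolvable : int
        Nonzero count of the evolvable block at creation time; used as the
        fixed denominator of the per-weight mutation rate.
    """

    p: int
    W: sp.csr_matrix
    evolvable_idx: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    bias: np.ndarray = field(default=None)  # type: ignore[assignment]
    nnz_evolvable: int = -1

    def __post_init__(self) -> None:
        if self.bias is None:
            self.bias = np.zeros(self.p)
        self.W = sp.csr_matrix(self.W)
        self.evolvable_idx = np.asarray(self.evolvable_idx, dtype=int)
        if self.W.shape != (self.p, self.p):
            raise ValueError(f"W must be {self.p}x{self.p}, got {self.W.shape}")
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("kinetic rates alpha, beta must be strictly positive")
        if self.nnz_evolvable < 0:
            self.nnz_evolvable = int(self.evolvable_block().nnz)

    # -- block access -------------------------------------------------------

    def evolvable_block(self) -> sp.csr_matrix:
        idx = self.evolvable_idx
        return self.W[np.ix_(idx, idx)].tocsr()

    def background_idx(self) -> np.ndarray:
        mask = np.ones(self.p, dtype=bool)
        mask[self.evolvable_idx] = False
        return np.flatnonzero(mask)

    def validate_block_separation(self) -> bool:
        """True iff no nonzero weight crosses the evolvable/background cut."""
        ev = np.zeros(self.p, dtype=bool)
        ev[self.evolvable_idx] = True
        coo = self.W.tocoo()
        cross = ev[coo.row] != ev[coo.col]
        return not bool(np.any(cross & (coo.data != 0)))

    def with_evolvable_block(self, block: sp.spmatrix) -> "GeneNetwork":
        """Return a copy whose evolvable block is replaced by ``block``."""
        idx = self.evolvable_idx
        n = len(idx)
        if n == self.p:
            return replace(self, W=sp.csr_matrix(block), nnz_evolvable=self.nnz_evolvable)
        if np.array_equal(idx, np.arange(n)):
            # contiguous prefix: rebuild by block composition (cross blocks
            # are structurally zero by the separation invariant)
            bg = self.W[n:, n:]
            W = sp.bmat([[sp.csr_matrix(block), None], [None, bg]], format="csr")
            return replace(self, W=W, nnz_evolvable=self.nnz_evolvable)
        W = self.W.tolil(copy=True)
        W[np.ix_(idx, idx)] = block
        return replace(self, W=W.tocsr(), nnz_evolvable=self.nnz_evolvable)

    def out_degrees(self) -> np.ndarray:
        """Number of direct targets of each gene (nonzeros per column)."""
        return np.asarray((self.W != 0).sum(axis=0)).ravel()


@dataclass(frozen=True)
class KineticsPrior:
    """Hierarchical Gaussian prior for per-gene kinetic rates.

    Subject-level spreads sigma_alpha, sigma_beta are themselves Gaussian
    (resampled once per subject), then gene-level rates are drawn around the
    fixed population means and truncated at a small positive floor.
    """

    mu_alpha: float = 20.0
    mu_beta: float = 0.2
    sigma_alpha_mean: float = 0.5
    sigma_alpha_sd: float = 0.075
    sigma_beta_mean: float = 0.02
    sigma_beta_sd: float = 0.0025
    floor: float = 1e-6


@dataclass(frozen=True)
class ExpressionState:
    """Normalized steady-state expression with convergence diagnostics."""

    x: np.ndarray
    converged: bool
    residual: float


# ---------------------------------------------------------------------------
# Topology generation
# ---------------------------------------------------------------------------

def generate_topology(
    p: int,
    n_sub: int,
    nnz_sub: int,
    hub_bias: float = 2.0,
    bias_sd: float = 2.5,
    seed: int | None = None,
    prior: KineticsPrior | None = None,
) -> GeneNetwork:
    """Draw a random block-separated regulatory network.

    The evolvable block (genes ``0 .. n_sub-1``) receives exactly ``nnz_sub``
    nonzero weights ~ Normal(0, 1).  Out-degrees are drawn from a discrete
    power-law-like distribution (exponent ``hub_bias``) and adjusted to hit
    ``nnz_sub`` exactly, so a few regulator hubs with many targets exist.
    The background block gets the same per-gene mean degree, and no edge
    crosses the block boundary.

    Parameters
    ----------
    p, n_sub, nnz_sub
        Total gene count, evolvable-subnetwork size, and exact nonzero
        count of the evolvable block.
    hub_bias
        Power-law exponent of the out-degree distribution; smaller values
        give heavier tails (more pronounced hubs).
    bias_sd
        Spread of the per-gene basal regulatory input, drawn N(0, bias_sd).
        A nonzero spread places genes across the whole [0, 1] dynamic range
        (as observed expression data are), rather than piling every
        unregulated gene at the symmetric 0.5 baseline; it also guarantees
        a realistic pool of near-saturated genes from which perturbation
        hubs can be drawn.  Set to 0 for the symmetric baseline.
    seed
        Seeds the topology, basal inputs and the founder kinetics draw.
    """
    if not 0 < n_sub <= p:
        raise ValueError(f"need 0 < n_sub <= p, got n_sub={n_sub}, p={p}")
    if not 0 <= nnz_sub <= n_sub * n_sub:
        raise ValueError(
            f"nnz_sub={nnz_sub} exceeds evolvable block capacity {n_sub * n_sub}"
        )
    rng = np.random.default_rng(seed)

    n_bg = p - n_sub
    # background edge count: same mean degree as the evolvable block
    nnz_bg = min(int(round(nnz_sub / n_sub * n_bg)), n_bg * n_bg) if n_sub else 0

    rows, cols, data = [], [], []
    for offset, n_blk, nnz_blk in ((0, n_sub, nnz_sub), (n_sub, n_bg, nnz_bg)):
        if n_blk == 0 or nnz_blk == 0:
            continue
        deg = _skewed_out_degrees(n_blk, nnz_blk, hub_bias, rng)
        for j in range(n_blk):
            if deg[j] == 0:
                continue
            targets = rng.choice(n_blk, size=deg[j], replace=False)
            rows.extend((targets + offset).tolist())
            cols.extend([j + offset] * deg[j])
        data.extend(rng.standard_normal(int(deg.sum())).tolist())

    W = sp.csr_matrix((data, (rows, cols)), shape=(p, p))
    bias = rng.normal(0.0, bias_sd, size=p) if bias_sd > 0 else np.zeros(p)
    prior = prior or KineticsPrior()
    alpha, beta = sample_kinetics(prior, p, rng)
    return GeneNetwork(
        p=p,
        W=W,
        evolvable_idx=np.arange(n_sub),
        alpha=alpha,
        beta=beta,
        bias=bias,
        nnz_evolvable=nnz_sub,
    )


def _skewed_out_degrees(
    n: int, nnz: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Right-skewed integer out-degrees over n genes summing exactly to nnz.

    Degrees follow a zeta-like pmf truncated at 15% of the block size so a
    handful of regulator hubs emerge without a single gene absorbing most
    of the edge budget; the total is then adjusted one unit at a time to
    hit ``nnz`` exactly.
    """
    max_deg = min(n, max(4, int(0.15 * n), (nnz + n - 1) // n))
    support = np.arange(max_deg + 1)
    pmf = 1.0 / np.power(support + 1.0, exponent)
    pmf /= pmf.sum()
    deg = rng.choice(support, size=n, p=pmf)
    diff = int(nnz - deg.sum())
    while diff != 0:
        j = int(rng.integers(n))
        if diff > 0 and deg[j] < max_deg:
            deg[j] += 1
            diff -= 1
        elif diff < 0 and deg[j] > 0:
            deg[j] -= 1
            diff += 1
    return deg.astype(int)


def sample_kinetics(
    prior: KineticsPrior, p: int, seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-gene (alpha, beta) for one subject.

    The subject first draws its own spreads sigma_alpha, sigma_beta from the
    hyperprior, then gene-level rates around the population means; all draws
    are truncated at ``prior.floor`` to stay strictly positive.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    s_a = max(prior.floor, rng.normal(prior.sigma_alpha_mean, prior.sigma_alpha_sd))
    s_b = max(prior.floor, rng.normal(prior.sigma_beta_mean, prior.sigma_beta_sd))
    alpha = np.maximum(prior.floor, rng.normal(prior.mu_alpha, s_a, size=p))
    beta = np.maximum(prior.floor, rng.normal(prior.mu_beta, s_b, size=p))
    return alpha, beta


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------

def steady_state(
    net: GeneNetwork,
    x0: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    clamp_zero: np.ndarray | None = None,
    capacity: np.ndarray | None = None,
) -> ExpressionState:
    """Normalized steady state of the relaxation dynamics.

    Solves ``x = capacity * sigma(W x + bias)`` by damped fixed-point
    iteration (damping 0.5), which is the fixed point of
    ``dx_i/dt = beta_i (capacity_i sigma(.) - x_i)``.

    Parameters
    ----------
    clamp_zero : bool array, optional
        Genes held at expression 0 throughout (knock-out clamp).
    capacity : array, optional
        Per-gene transcription ceiling in (0, 1]; 1 = unperturbed,
        0.5 = knock-down.
    """
    x = np.full(net.p, 0.5) if x0 is None else np.asarray(x0, dtype=float).copy()
    if x.shape != (net.p,):
        raise ValueError("x0 has wrong length")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x0 must lie in [0, 1]")
    cap = np.ones(net.p) if capacity is None else np.asarray(capacity, dtype=float)
    if clamp_zero is not None:
        x[clamp_zero] = 0.0

    W = net.W
    for _ in range(max_iter):
        target = cap * _logistic(W @ x + net.bias)
        if clamp_zero is not None:
            target[clamp_zero] = 0.0
        if not np.all(np.isfinite(target)):
            bad = int(np.flatnonzero(~np.isfinite(target))[0])
            raise FloatingPointError(
                f"non-finite expression encountered at gene index {bad}"
            )
        resid = float(np.max(np.abs(target - x)))
        x = (1.0 - DAMPING) * x + DAMPING * target
        if resid <= tol:
            return ExpressionState(x=np.clip(x, 0.0, 1.0), converged=True, residual=resid)
    return ExpressionState(x=np.clip(x, 0.0, 1.0), converged=False, residual=resid)


def steady_state_batch(
    blocks: list[sp.spmatrix],
    bias: np.ndarray,
    x0: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Steady states of many same-sized subnetworks, solved jointly.

    Stacks the per-subject weight blocks into one block-diagonal sparse
    matrix so each damped iteration is a single sparse matvec; used by the
    evolutionary loop where every offspring carries its own evolvable block.
    Returns an (n_genes, n_subjects) matrix of normalized steady states.
    """
    n_sub = len(blocks)
    n = blocks[0].shape[0]
    big = sp.block_diag(blocks, format="csr")
    b = np.tile(np.asarray(bias, dtype=float), n_sub)
    x = np.full(n * n_sub, 0.5) if x0 is None else np.tile(np.asarray(x0), n_sub)
    for _ in range(max_iter):
        target = _logistic(big @ x + b)
        resid = float(np.max(np.abs(target - x)))
        x = (1.0 - DAMPING) * x + DAMPING * target
        if resid <= tol:
            break
    return np.clip(x, 0.0, 1.0).reshape(n_sub, n).T


# ---------------------------------------------------------------------------
# Serialization: edge-list TSV + per-gene parameter TSV
# ---------------------------------------------------------------------------

def write_network(net: GeneNetwork, edges_path, params_path) -> None:
    coo = net.W.tocoo()
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{j}\t{i}\t{w:.12g}\n")
    ev = set(net.evolvable_idx.tolist())
    with open(params_path, "w") as fh:
        fh.write("gene_id\talpha\tbeta\tbias\tevolvable\n")
        for g in range(net.p):
            fh.write(
                f"{g}\t{net.alpha[g]:.12g}\t{net.beta[g]:.12g}"
                f"\t{net.bias[g]:.12g}\t{int(g in ev)}\n"
            )


def read_network(edges_path, params_path) -> GeneNetwork:
    gene_ids, alpha, beta, bias, evolvable = [], [], [], [], []
    with open(params_path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValueError(f"{params_path}: bad header line")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(f"{params_path}:{lineno}: expected 5 columns")
            gene_ids.append(int(parts[0]))
            alpha.append(float(parts[1]))
            beta.append(float(parts[2]))
            bias.append(float(parts[3]))
            evolvable.append(int(parts[4]))
    p = len(gene_ids)
    rows, cols, data = [], [], []
    with open(edges_path) as fh:
        header = fh.readline()
        if not header.startswith("source"):
            raise ValueError(f"{edges_path}: bad header line")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{edges_path}:{lineno}: expected 3 columns")
            cols.append(int(parts[0]))
            rows.append(int(parts[1]))
            data.append(float(parts[2]))
    W = sp.csr_matrix((data, (rows, cols)), shape=(p, p))
    return GeneNetwork(
        p=p,
        W=W,
        evolvable_idx=np.flatnonzero(np.asarray(evolvable, dtype=bool)),
        alpha=np.asarray(alpha),
        beta=np.asarray(beta),
        bias=np.asarray(bias),
    )
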