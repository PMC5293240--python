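"""Pairwise maximum-entropy (Potts) model of a concatenated MSA and the
residue-level correlated mutation measure (CMM).

The model is the least-biased sequence distribution matching the single and
pairwise column frequencies of the alignment,

    P(A) ∝ exp( -Σ_{i<j} e_ij(A_i, A_j) + Σ_i h_i(A_i) ),

with local fields ``h`` and pair-interaction energies ``e`` (lower ``e`` =
favoured pair).  It is fitted by contrastive divergence (CD-1): short-run
Gibbs chains started from the data rows supply the model-moment term of the
likelihood gradient.  From the fitted couplings, the *direct* pair
distribution

    P^D_ij(a, b) ∝ f_i(a) f_j(b) exp(-e_ij(a, b))

isolates the coupling of a column pair from the rest of the alignment, and
the residue-level CMM

    D(i, j) = Σ_{a,b} P^D_ij(a, b) ln[ P^D_ij(a, b) / (f_i(a) f_j(b)) ]

is its Kullback-Leibler divergence from the independent product — zero iff
the pair is directly uncoupled, and closely related to the direct
information of mean-field DCA.  Couplings are fitted for *all* column pairs
(intra- and inter-protein): intra-protein couplings are required to absorb
indirect correlation chains even though only cross-boundary D values are
scored downstream.

Internally couplings are kept as a flat symmetric ``(N*q, N*q)`` matrix
``J = -e`` with zero diagonal blocks, which turns moment computation and
Gibbs conditionals into sparse/dense matrix products.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.special import logsumexp

from .alignment import Alignment, FrequencyModel

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few alignment rows to fit a model."""


class DivergenceError(RuntimeError):
    """A parameter update became non-finite during training."""


@dataclass
class CDConfig:
    """Hyperparameters of the contrastive-divergence fit.

    Defaults follow common CD-1 practice: one Gibbs sweep per update,
    non-persistent chains restarted from data rows, learning rate 0.5
    decaying as 1/sqrt(t), ridge (L2) regularisation 0.01 on couplings and
    1e-4 on fields.  The initial rate is deliberately aggressive: with the
    1/sqrt(t) decay the cumulative step budget is what limits how far the
    couplings can travel from zero, and smaller rates demonstrably stall
    short of the penalised optimum within the update budget.
    ``batch_size=None`` uses every alignment row as a chain; a smaller
    batch subsamples rows (seeded) for speed.
    """

    seed: int
    gibbs_sweeps_per_update: int = 1
    learning_rate: float = 0.5
    n_updates: int = 2000
    l2_coupling: float = 0.01
    l2_field: float = 1e-4
    convergence_tol: float = 1e-3
    convergence_window: int = 50
    batch_size: int | None = None

    def __post_init__(self) -> None:
        if self.gibbs_sweeps_per_update < 1 or self.n_updates < 1:
            raise ValueError("iteration counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if min(self.l2_coupling, self.l2_field) < 0:
            raise ValueError("L2 strengths must be non-negative")


@dataclass
class PottsModel:
    """Fields and pair couplings of the maximum-entropy model.

    ``fields[i, a]`` is h_i(a); couplings are stored as the flat symmetric
    matrix ``coupling_flat[(i*q+a), (j*q+b)] = e_ij(a, b)`` with
    ``e_ij(a, b) = e_ji(b, a)`` and zero diagonal blocks.
    """

    fields: np.ndarray
    coupling_flat: np.ndarray
    boundary: int
    gauge_note: str = ""

    @property
    def length(self) -> int:
        return int(self.fields.shape[0])

    @property
    def n_states(self) -> int:
        return int(self.fields.shape[1])

    def coupling(self, i: int, j: int) -> np.ndarray:
        """The q x q energy block e_ij(a, b)."""
        q = self.n_states
        return self.coupling_flat[i * q : (i + 1) * q, j * q : (j + 1) * q]

    def max_abs_coupling(self) -> float:
        return float(np.abs(self.coupling_flat).max())

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            fields=self.fields,
            coupling_flat=self.coupling_flat,
            boundary=self.boundary,
            gauge_note=np.array(self.gauge_note),
        )

    @classmethod
    def load_npz(cls, path) -> "PottsModel":
        d = np.load(path, allow_pickle=False)
        return cls(
            fields=d["fields"],
            coupling_flat=d["coupling_flat"],
            boundary=int(d["boundary"]),
            gauge_note=str(d["gauge_note"]),
        )


@dataclass
class CouplingMatrix:
    """Residue-level CMM: symmetric non-negative D(i, j) in nats.

    ``provenance`` records which model/frequency pair produced it.
    """

    D: np.ndarray
    boundary: int
    provenance: str = ""

    @property
    def length(self) -> int:
        return int(self.D.shape[0])

    def cross_boundary(self) -> list[tuple[int, int, float]]:
        """(i, j, D) for all pairs crossing the chain boundary, i < N1 <= j."""
        n1 = self.boundary
        return [
            (i, j, float(self.D[i, j]))
            for i in range(n1)
            for j in range(n1, self.length)
        ]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\tD\n")
            for i in range(self.length):
                for j in range(i + 1, self.length):
                    fh.write(f"{i}\t{j}\t{self.D[i, j]:.10g}\n")


# ---------------------------------------------------------------------------
# Gibbs machinery (shared with the synthetic sampler)
# ---------------------------------------------------------------------------

def _sparse_one_hot(states: np.ndarray, q: int) -> sparse.csr_matrix:
    b, n = states.shape
    cols = (states + q * np.arange(n)[None, :]).ravel()
    rows = np.repeat(np.arange(b), n)
    return sparse.csr_matrix(
        (np.ones(b * n), (rows, cols)), shape=(b, n * q)
    )


def _conditional_logits(states, j_flat, h_flat, q):
    """Full conditional logit table (B, N*q) for the current chain states."""
    x = _sparse_one_hot(states, q)
    return np.asarray(x @ j_flat) + h_flat[None, :]


try:  # numba accelerates the site loop ~5-10x; the numpy path is equivalent
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _gibbs_kernel(states, lam, j_flat, q, u):  # pragma: no cover - jitted
        b, n = states.shape
        n_sweeps = u.shape[0]
        p = np.empty(q)
        for s in range(n_sweeps):
            for i in range(n):
                base = i * q
                for m in range(b):
                    mx = lam[m, base]
                    for a in range(1, q):
                        if lam[m, base + a] > mx:
                            mx = lam[m, base + a]
                    tot = 0.0
                    for a in range(q):
                        p[a] = np.exp(lam[m, base + a] - mx)
                        tot += p[a]
                    r = u[s, i, m] * tot
                    acc = 0.0
                    new = q - 1
                    for a in range(q):
                        acc += p[a]
                        if r < acc:
                            new = a
                            break
                    old = states[m, i]
                    if new != old:
                        for k in range(n * q):
                            lam[m, k] += (
                                j_flat[base + new, k] - j_flat[base + old, k]
                            )
                        states[m, i] = new


def gibbs_sweeps(
    states: np.ndarray,
    j_flat: np.ndarray,
    h_flat: np.ndarray,
    q: int,
    n_sweeps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Run systematic-scan Gibbs sweeps in place on integer chain states.

    ``j_flat`` is the flat symmetric coupling matrix on the *probability*
    scale (J = -e, logit contribution is +J); ``h_flat`` the flat fields.
    The conditional-logit table is maintained incrementally across site
    updates, so each site costs O(B * N * q).  All randomness is drawn
    from ``rng`` up front, so runs are reproducible per seed.
    """
    b, n = states.shape
    lam = _conditional_logits(states, j_flat, h_flat, q)
    if _HAVE_NUMBA:
        u = rng.random((n_sweeps, n, b))
        _gibbs_kernel(states, lam, np.ascontiguousarray(j_flat), q, u)
        return states
    for s in range(n_sweeps):
        u_all = rng.random((n, b))
        for i in range(n):
            sl = slice(i * q, (i + 1) * q)
            logits = lam[:, sl]
            logits = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            u = u_all[i] * p.sum(axis=1)
            new = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
            np.minimum(new, q - 1, out=new)
            old = states[:, i]
            changed = np.nonzero(new != old)[0]
            if changed.size:
                lam[changed] += (
                    j_flat[i * q + new[changed]] - j_flat[i * q + old[changed]]
                )
                states[changed, i] = new[changed]
    return states


# ---------------------------------------------------------------------------
# Contrastive-divergence fit
# ---------------------------------------------------------------------------

def _off_diagonal_block_mask(n: int, q: int) -> np.ndarray:
    mask = np.ones((n * q, n * q), dtype=bool)
    for i in range(n):
        mask[i * q : (i + 1) * q, i * q : (i + 1) * q] = False
    return mask


def fit_potts_cd(
    aln: Alignment, freq: FrequencyModel, cfg: CDConfig
) -> PottsModel:
    """Fit the maximum-entropy model by contrastive divergence.

    Fields are initialised to ln f_i(a) (hence the need for a strictly
    positive pseudocount in ``freq``), couplings to zero.  Each update runs
    ``gibbs_sweeps_per_update`` sweeps from chains restarted at (a batch of)
    data rows, then moves parameters along
    (data moments - sample moments - L2 gradient) * learning rate.
    Training stops early when the max-norm parameter change stays below
    ``convergence_tol`` over the convergence window.  Deterministic given
    the seed.
    """
    m, n = aln.matrix.shape
    q = aln.n_states
    if m < 2:
        raise InsufficientDataError(f"need at least 2 sequences, got {m}")
    if freq.pseudocount <= 0:
        raise ValueError("CD fitting requires a strictly positive pseudocount")
    if freq.length != n or freq.n_states != q:
        raise ValueError("frequency model does not match the alignment")

    rng = np.random.default_rng(cfg.seed)
    h = np.log(freq.single).ravel().copy()
    j = np.zeros((n * q, n * q))
    mask = _off_diagonal_block_mask(n, q)
    f1 = freq.single.ravel()
    f2 = freq.pair_flat

    recent: list[float] = []
    for t in range(1, cfg.n_updates + 1):
        if cfg.batch_size is not None and cfg.batch_size < m:
            idx = rng.choice(m, size=cfg.batch_size, replace=False)
        else:
            idx = np.arange(m)
        chains = aln.matrix[idx].copy()
        gibbs_sweeps(chains, j, h, q, cfg.gibbs_sweeps_per_update, rng)
        cols = chains + q * np.arange(n)[None, :]
        pair_idx = (cols[:, :, None] * (n * q) + cols[:, None, :]).ravel()
        c2 = np.bincount(pair_idx, minlength=(n * q) ** 2).reshape(n * q, n * q)
        c2 = c2 / len(idx)
        c1 = c2.diagonal().copy()

        lr = cfg.learning_rate / math.sqrt(t)
        with np.errstate(over="ignore", invalid="ignore"):
            dj = lr * ((f2 - c2) - cfg.l2_coupling * j)
            dj[~mask] = 0.0
            dh = lr * ((f1 - c1) - cfg.l2_field * h)
        if not (np.isfinite(dj).all() and np.isfinite(dh).all()):
            raise DivergenceError(
                f"non-finite parameter update at iteration {t}; "
                "reduce the learning rate"
            )
        j += dj
        h += dh

        recent.append(max(np.abs(dj).max(), np.abs(dh).max()))
        if len(recent) > cfg.convergence_window:
            recent.pop(0)
            if max(recent) < cfg.convergence_tol:
                logger.info("CD converged after %d updates", t)
                break
    else:
        logger.info(
            "CD stopped at iteration budget %d (max recent step %.2e)",
            cfg.n_updates,
            max(recent) if recent else float("nan"),
        )

    return PottsModel(
        fields=h.reshape(n, q),
        coupling_flat=-j,
        boundary=aln.boundary,
        gauge_note=(
            f"CD-1 fit: lr={cfg.learning_rate}/sqrt(t), updates<={cfg.n_updates}, "
            f"L2(e)={cfg.l2_coupling}, L2(h)={cfg.l2_field}, seed={cfg.seed}"
        ),
    )


# ---------------------------------------------------------------------------
# Direct pair distribution and the CMM
# ---------------------------------------------------------------------------

def direct_pair_distribution(
    model: PottsModel, freq: FrequencyModel, i: int, j: int
) -> np.ndarray:
    """The direct (coupling-only) joint distribution of columns i and j.

    P^D_ij(a, b) ∝ f_i(a) f_j(b) exp(-e_ij(a, b)), normalised to 1.
    """
    if i == j:
        raise ValueError("direct pair distribution requires i != j")
    n = model.length
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"columns must be in 0..{n - 1}")
    w = np.outer(freq.single[i], freq.single[j]) * np.exp(-model.coupling(i, j))
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("direct pair distribution is degenerate")
    return w / total


def pair_divergence(p_direct: np.ndarray, fi: np.ndarray, fj: np.ndarray) -> float:
    """KL divergence of a direct pair table from the independent product."""
    prod = np.outer(fi, fj)
    nz = p_direct > 0
    if np.any(nz & (prod <= 0)):
        raise AssertionError(
            "direct distribution has mass where the product frequency is zero"
        )
    return float((p_direct[nz] * np.log(p_direct[nz] / prod[nz])).sum())


def cmm_matrix(model: PottsModel, freq: FrequencyModel) -> CouplingMatrix:
    """Residue-level CMM D(i, j) for every column pair (symmetric, >= 0)."""
    if model.length != freq.length or model.n_states != freq.n_states:
        raise ValueError("model and frequency dimensions disagree")
    n = model.length
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pd = direct_pair_distribution(model, freq, i, j)
            d[i, j] = d[j, i] = max(
                0.0, pair_divergence(pd, freq.single[i], freq.single[j])
            )
    return CouplingMatrix(
        D=d, boundary=model.boundary, provenance=model.gauge_note
    )


# ---------------------------------------------------------------------------
# Exact-enumeration oracle (tiny instances)
# ---------------------------------------------------------------------------

def _enumerate_states(n: int, q: int) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(q)] * n, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def exact_fit_oracle(
    aln: Alignment,
    freq: FrequencyModel,
    ridge: float = 1e-4,
    max_states: int = 10**6,
    tol: float = 1e-9,
) -> PottsModel:
    """Maximum-likelihood fit with the partition function computed exactly.

    Enumerates all q^N sequences, so it is restricted to tiny instances and
    serves as the independent reference for the CD fit.  Maximises the
    ridge-penalised (couplings only) log-likelihood with L-BFGS; in the
    ridge -> 0 limit the model marginals reproduce ``freq`` exactly.
    """
    from scipy.optimize import minimize

    m, n = aln.matrix.shape
    q = aln.n_states
    if q**n > max_states:
        raise ValueError(f"q^N = {q**n} exceeds the enumeration cap {max_states}")
    states = _enumerate_states(n, q)
    x_all = _sparse_one_hot(states, q)
    x_dense = np.asarray(x_all.todense())
    f1 = freq.single.ravel()
    f2 = freq.pair_flat
    mask = _off_diagonal_block_mask(n, q)
    iu = np.triu_indices(n * q)
    pair_sel = mask[iu]  # upper-triangle entries belonging to i<j blocks

    def unpack(theta):
        h = theta[: n * q]
        jv = theta[n * q :]
        j = np.zeros((n * q, n * q))
        vals = np.zeros(len(iu[0]))
        vals[pair_sel] = jv
        j[iu] = vals
        j = j + j.T
        return h, j

    def negloglik(theta):
        h, j = unpack(theta)
        u = x_dense @ h + 0.5 * np.einsum("sk,sk->s", x_dense @ j, x_dense)
        logz = logsumexp(u)
        p = np.exp(u - logz)
        m1 = x_dense.T @ p
        m2 = (x_dense * p[:, None]).T @ x_dense
        jv = theta[n * q :]
        nll = -(f1 @ h + 0.5 * (f2 * j).sum() - logz) + 0.5 * ridge * (jv @ jv)
        gh = -(f1 - m1)
        gj_full = -(f2 - m2)
        gj_full[~mask] = 0.0
        # each upper i<j entry appears twice in the symmetric J but with the
        # 1/2 in the energy; the two factors cancel.
        gj = gj_full[iu][pair_sel] + ridge * jv
        return nll, np.concatenate([gh, gj])

    theta0 = np.concatenate(
        [np.log(np.clip(freq.single, 1e-12, None)).ravel(), np.zeros(pair_sel.sum())]
    )
    res = minimize(
        negloglik,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": tol},
    )
    h, j = unpack(res.x)
    return PottsModel(
        fields=h.reshape(n, q),
        coupling_flat=-j,
        boundary=aln.boundary,
        gauge_note=f"exact enumeration fit, ridge={ridge}",
    )


def exact_model_marginals(model: PottsModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact single and pairwise marginals of a (tiny) model by enumeration."""
    n, q = model.length, model.n_states
    if q**n > 10**6:
        raise ValueError("model too large for enumeration")
    states = _enumerate_states(n, q)
    x = np.asarray(_sparse_one_hot(states, q).todense())
    j = -model.coupling_flat
    h = model.fields.ravel()
    u = x @ h + 0.5 * np.einsum("sk,sk->s", x @ j, x)
    p = np.exp(u - logsumexp(u))
    m1 = (x.T @ p).reshape(n, q)
    m2 = (x * p[:, None]).T @ x
    return m1, m2
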