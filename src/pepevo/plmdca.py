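"""Potts model fitting by regularized pseudolikelihood maximization (plmDCA).

The model assigns every scaffold-length sequence sigma a score

    S(sigma) = sum_i h_i(sigma_i) + sum_{i<j} J_ij(sigma_i, sigma_j)

with per-position fields ``h`` (conservation) and per-pair couplings ``J``
(residue covariation). The intractable joint likelihood is replaced by the
product of per-site conditionals P(sigma_r | sigma_{\\r}); minimizing the
weighted negative log pseudolikelihood with an L2 penalty is a smooth convex
problem solved here with L-BFGS-B from the zero model, so the fit is
deterministic given data and configuration.

A single shared symmetric J is fitted (the joint pseudolikelihood) rather
than the asymmetric per-site variant with post-hoc averaging: the fitted
tensor doubles as the Monte Carlo energy, and at family sizes of a few dozen
sequences the computational argument for asymmetric fitting is moot.

Usage follows the model/results convention::

    results = PottsPseudolikelihood(msa, lambda_h=0.01, lambda_J=0.01).fit()
    results.model.score("ACDRYECVDCRGRGSVCG")
    results.top_coupled_pairs(k=5)
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .seq_core import MSA, Alphabet, Scaffold

logger = logging.getLogger("pepevo")


# ---------------------------------------------------------------------------
# model container


@dataclass
class PottsModel:
    """Fields ``h`` (L x q) and couplings ``J`` (one q x q block per pair i<j).

    ``J[p]`` is the block for ``pairs[p] = (i, j)`` with i < j (0-based
    internally); symmetry J_ij(a,b) = J_ji(b,a) is implicit in the triangular
    storage. ``gauge`` records whether the zero-sum convention has been
    applied.
    """

    h: np.ndarray
    J: np.ndarray  # (n_pairs, q, q)
    alphabet: Alphabet
    scaffold: Scaffold
    gauge: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if L != self.scaffold.L or q != self.alphabet.q:
            raise ValueError("field tensor shape does not match scaffold/alphabet")
        if self.J.shape != (L * (L - 1) // 2, q, q):
            raise ValueError("coupling tensor has wrong shape")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("model parameters must be finite")
        self._Jfull_cache: np.ndarray | None = None

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """0-based (i, j) with i < j, in lexicographic order."""
        L = self.L
        return [(i, j) for i in range(L) for j in range(i + 1, L)]

    def pair_index(self, i: int, j: int) -> int:
        """Index into J for 0-based positions i < j."""
        if not 0 <= i < j < self.L:
            raise ValueError("need 0 <= i < j < L")
        return i * self.L - i * (i + 1) // 2 + (j - i - 1)

    def coupling_block(self, i: int, j: int) -> np.ndarray:
        """q x q block J_ij for 1-based positions i < j."""
        return self.J[self.pair_index(i - 1, j - 1)]

    def full_coupling_tensor(self) -> np.ndarray:
        """Dense symmetric (L, L, q, q) tensor with zero diagonal blocks."""
        if self._Jfull_cache is None:
            L, q = self.L, self.q
            Jfull = np.zeros((L, L, q, q))
            for p, (i, j) in enumerate(self.pairs):
                Jfull[i, j] = self.J[p]
                Jfull[j, i] = self.J[p].T
            self._Jfull_cache = Jfull
        return self._Jfull_cache

    # -- scoring ------------------------------------------------------------

    def score(self, sequence: str | np.ndarray) -> float:
        """Potts score S(sigma); the MC effective energy is E = -S."""
        sigma = (self.alphabet.encode(sequence)
                 if isinstance(sequence, str) else np.asarray(sequence))
        if sigma.shape != (self.L,):
            raise ValueError(f"sequence length {sigma.shape} != L={self.L}")
        s = float(self.h[np.arange(self.L), sigma].sum())
        for p, (i, j) in enumerate(self.pairs):
            s += self.J[p][sigma[i], sigma[j]]
        return float(s)

    def score_many(self, matrix: np.ndarray) -> np.ndarray:
        """Vectorized scores for an (n, L) index matrix."""
        matrix = np.asarray(matrix)
        n, L = matrix.shape
        s = self.h[np.arange(L), matrix].sum(axis=1)
        Jfull = self.full_coupling_tensor()
        for i in range(L):
            for j in range(i + 1, L):
                s += Jfull[i, j][matrix[:, i], matrix[:, j]]
        return s

    # -- gauge --------------------------------------------------------------

    def to_zero_sum_gauge(self) -> "PottsModel":
        """Reparameterize so every coupling block has zero row/column sums.

        The removed block means are absorbed into the fields, and fields are
        centred per position; score *differences* between any two sequences
        are preserved exactly, so the sampler and all rankings are unchanged.
        Coupling Frobenius norms become comparable across pairs, the
        precondition for ranking covarying positions.
        """
        h = self.h.copy()
        J = np.empty_like(self.J)
        for p, (i, j) in enumerate(self.pairs):
            block = self.J[p]
            row_mean = block.mean(axis=1, keepdims=True)   # over b
            col_mean = block.mean(axis=0, keepdims=True)   # over a
            total = block.mean()
            J[p] = block - row_mean - col_mean + total
            h[i] += row_mean.ravel() - total
            h[j] += col_mean.ravel() - total
        h -= h.mean(axis=1, keepdims=True)
        return PottsModel(h=h, J=J, alphabet=self.alphabet,
                          scaffold=self.scaffold, gauge="zero_sum",
                          meta=dict(self.meta))

    # -- coupling ranking ---------------------------------------------------

    def coupling_norms(self) -> np.ndarray:
        """(L, L) symmetric matrix of Frobenius norms of zero-sum blocks."""
        model = self if self.gauge == "zero_sum" else self.to_zero_sum_gauge()
        L = self.L
        F = np.zeros((L, L))
        for p, (i, j) in enumerate(model.pairs):
            F[i, j] = F[j, i] = np.linalg.norm(model.J[p])
        return F

    def serialize(self, path: str | Path) -> None:
        payload = {"alphabet": self.alphabet.symbols,
                   "scaffold": self.scaffold.to_dict(),
                   "h": self.h.tolist(),
                   "J": self.J.tolist(),
                   "gauge": self.gauge,
                   "meta": self.meta}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PottsModel":
        d = json.loads(Path(path).read_text())
        return cls(h=np.array(d["h"]), J=np.array(d["J"]),
                   alphabet=Alphabet(d["alphabet"]),
                   scaffold=Scaffold.from_dict(d["scaffold"]),
                   gauge=d.get("gauge", "raw"), meta=d.get("meta", {}))

    @classmethod
    def zeros(cls, scaffold: Scaffold, alphabet: Alphabet | None = None,
              **kwargs) -> "PottsModel":
        alphabet = alphabet or Alphabet()
        L, q = scaffold.L, alphabet.q
        return cls(h=np.zeros((L, q)), J=np.zeros((L * (L - 1) // 2, q, q)),
                   alphabet=alphabet, scaffold=scaffold, **kwargs)

    def digest(self) -> str:
        m = hashlib.sha256()
        m.update(np.ascontiguousarray(self.h).tobytes())
        m.update(np.ascontiguousarray(self.J).tobytes())
        return m.hexdigest()[:16]


@dataclass
class SequenceScore:
    """A sequence with its Potts score; energy is the negated score."""

    sequence: str
    score: float

    @property
    def energy(self) -> float:
        return -self.score


@dataclass
class CouplingScore:
    """Ranked covariation signal for one position pair (1-based i < j)."""

    i: int
    j: int
    frobenius: float
    apc: float
    top_pairs: list[tuple[str, str, float]]  # (res_i, res_j, J'_ij) by |value|


# ---------------------------------------------------------------------------
# reweighting


def sequence_weights(msa: MSA, identity_threshold: float = 0.8) -> np.ndarray:
    """Standard DCA redundancy weights: w_m = 1 / #{m': identity >= theta}.

    The count includes the sequence itself, so weights are in (0, 1] and the
    effective family size is Meff = sum_m w_m.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    X = msa.matrix
    identity = (X[:, None, :] == X[None, :, :]).mean(axis=2)
    counts = (identity >= identity_threshold).sum(axis=1)
    return 1.0 / counts


# ---------------------------------------------------------------------------
# objective / gradient on packed parameters

def _pack(h: np.ndarray, J: np.ndarray) -> np.ndarray:
    return np.concatenate([h.ravel(), J.ravel()])


def _unpack(x: np.ndarray, L: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    n_pairs = L * (L - 1) // 2
    return x[:L * q].reshape(L, q), x[L * q:].reshape(n_pairs, q, q)


def _coupling_matrix(J: np.ndarray, pairs, L: int, q: int) -> np.ndarray:
    """(L*q, L*q) block matrix view of the couplings, zero diagonal blocks."""
    Jm = np.zeros((L, q, L, q))
    for p, (i, j) in enumerate(pairs):
        Jm[i, :, j, :] = J[p]
        Jm[j, :, i, :] = J[p].T
    return Jm.reshape(L * q, L * q)


def _objective_and_grad(x, onehot_flat, X, weights, meff, L, q, pairs,
                        lambda_h, lambda_J):
    """Weighted negative log pseudolikelihood + L2 penalty, with gradient.

    The conditional logits for all sites of all sequences come from one GEMM
    against the block coupling matrix; log-normalizers use a max-shifted
    log-sum-exp.
    """
    n = X.shape[0]
    h, J = _unpack(x, L, q)
    Jm = _coupling_matrix(J, pairs, L, q)
    logits = (onehot_flat @ Jm).reshape(n, L, q) + h[None, :, :]
    lse = logsumexp(logits, axis=2)                       # (n, L)
    obs = np.take_along_axis(logits, X[:, :, None], axis=2)[:, :, 0]
    nll = float(weights @ (lse - obs).sum(axis=1)) / meff
    value = nll + lambda_h * float((h ** 2).sum()) + lambda_J * float((J ** 2).sum())

    P = softmax(logits, axis=2)                           # (n, L, q)
    onehot = onehot_flat.reshape(n, L, q)
    D = (P - onehot) * (weights / meff)[:, None, None]
    grad_h = D.sum(axis=0) + 2 * lambda_h * h
    Df = D.reshape(n, L * q)
    G = (Df.T @ onehot_flat).reshape(L, q, L, q)
    grad_J = np.empty_like(J)
    for p, (i, j) in enumerate(pairs):
        # contributions from the conditionals at site i and at site j
        grad_J[p] = G[i, :, j, :] + G[j, :, i, :].T + 2 * lambda_J * J[p]
    return value, _pack(grad_h, grad_J)


def _encode_onehot(X: np.ndarray, q: int) -> np.ndarray:
    n, L = X.shape
    onehot = np.zeros((n, L, q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], X] = 1.0
    return onehot.reshape(n, L * q)


def neg_pseudo_loglik(model: PottsModel, msa: MSA,
                      weights: np.ndarray | None = None,
                      lambda_h: float = 0.0, lambda_J: float = 0.0) -> float:
    """Meff-normalized negative log pseudolikelihood plus L2 penalty (nats)."""
    _check_dims(model, msa)
    w = np.ones(msa.n) if weights is None else np.asarray(weights, dtype=float)
    meff = float(w.sum())
    value, _ = _objective_and_grad(
        _pack(model.h, model.J), _encode_onehot(msa.matrix, model.q),
        msa.matrix, w, meff, model.L, model.q, model.pairs, lambda_h, lambda_J)
    return value


def plm_gradient(model: PottsModel, msa: MSA,
                 weights: np.ndarray | None = None,
                 lambda_h: float = 0.0, lambda_J: float = 0.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of :func:`neg_pseudo_loglik` w.r.t. (h, J)."""
    _check_dims(model, msa)
    w = np.ones(msa.n) if weights is None else np.asarray(weights, dtype=float)
    meff = float(w.sum())
    _, grad = _objective_and_grad(
        _pack(model.h, model.J), _encode_onehot(msa.matrix, model.q),
        msa.matrix, w, meff, model.L, model.q, model.pairs, lambda_h, lambda_J)
    return _unpack(grad, model.L, model.q)


def _check_dims(model: PottsModel, msa: MSA) -> None:
    if model.L != msa.L or model.q != msa.alphabet.q:
        raise ValueError("model dimensions do not match MSA")
    if not (np.isfinite(model.h).all() and np.isfinite(model.J).all()):
        raise ValueError("non-finite model parameters")


# ---------------------------------------------------------------------------
# the model / results pair


class PottsPseudolikelihood:
    """Pseudolikelihood Potts model of a peptide family alignment.

    Parameters
    ----------
    msa : MSA
        Fixed-length, scaffold-conformant alignment.
    lambda_h, lambda_J : float
        Per-parameter L2 strengths on the Meff-normalized objective. The
        defaults (0.01 each) are conventional plmDCA magnitudes; in the
        small-family regime the penalty is what keeps couplings identifiable.
    reweight : bool
        If True, downweight near-duplicate sequences at ``identity_threshold``.
        Off by default: curated phage-display families are intentionally
        similar and silently collapsing Meff would be surprising. The choice
        is logged either way.
    """

    def __init__(self, msa: MSA, lambda_h: float = 0.01, lambda_J: float = 0.01,
                 reweight: bool = False, identity_threshold: float = 0.8):
        if msa.n < 2:
            raise ValueError("need at least 2 sequences to fit")
        if lambda_h < 0 or lambda_J < 0:
            raise ValueError("regularization strengths must be >= 0")
        self.msa = msa
        self.lambda_h = lambda_h
        self.lambda_J = lambda_J
        self.reweight = reweight
        self.identity_threshold = identity_threshold
        if reweight:
            self.weights = sequence_weights(msa, identity_threshold)
        else:
            self.weights = np.ones(msa.n)
        self.meff = float(self.weights.sum())
        logger.info("plmDCA: n=%d, L=%d, q=%d, reweight=%s, Meff=%.2f",
                    msa.n, msa.L, msa.alphabet.q, reweight, self.meff)

    def fit(self, max_iter: int = 500, tol: float = 1e-5) -> "PlmdcaResults":
        """Minimize the regularized objective by L-BFGS-B from the zero model.

        Convergence is declared when the projected-gradient max-norm drops
        below ``tol`` or ``max_iter`` iterations are reached; in the latter
        case the best-so-far model is returned with ``converged=False`` in
        its metadata (and a logged warning), never an exception.
        """
        L, q = self.msa.L, self.msa.alphabet.q
        pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
        onehot_flat = _encode_onehot(self.msa.matrix, q)
        x0 = np.zeros(L * q + len(pairs) * q * q)
        trace: list[float] = []

        def fun(x):
            value, grad = _objective_and_grad(
                x, onehot_flat, self.msa.matrix, self.weights, self.meff,
                L, q, pairs, self.lambda_h, self.lambda_J)
            fun.last = value
            return value, grad

        def callback(_x):
            trace.append(fun.last)

        res = minimize(fun, x0, jac=True, method="L-BFGS-B", callback=callback,
                       options={"maxiter": max_iter, "gtol": tol,
                                "ftol": 1e-14, "maxfun": 10 * max_iter})
        converged = bool(res.success) or "CONVERGENCE" in str(res.message).upper()
        if not res.success:
            logger.warning("plmDCA optimizer stopped early: %s", res.message)
        h, J = _unpack(res.x, L, q)
        meta = {"lambda_h": self.lambda_h, "lambda_J": self.lambda_J,
                "reweight": self.reweight,
                "identity_threshold": self.identity_threshold,
                "meff": self.meff, "n_sequences": self.msa.n,
                "iterations": int(res.nit), "converged": converged,
                "final_objective": float(res.fun),
                "message": str(res.message)}
        model = PottsModel(h=h, J=J, alphabet=self.msa.alphabet,
                           scaffold=self.msa.scaffold, gauge="raw", meta=meta)
        return PlmdcaResults(self, model, objective_trace=trace)


class PlmdcaResults:
    """Fitted Potts model plus fit diagnostics."""

    def __init__(self, model_spec: PottsPseudolikelihood, model: PottsModel,
                 objective_trace: list[float]):
        self.spec = model_spec
        self.model = model
        self.objective_trace = list(objective_trace)

    @property
    def converged(self) -> bool:
        return bool(self.model.meta["converged"])

    @property
    def n_iter(self) -> int:
        return int(self.model.meta["iterations"])

    def score_sequence(self, sequence: str) -> SequenceScore:
        self.model.scaffold.check(sequence)
        return SequenceScore(sequence=sequence, score=self.model.score(sequence))

    def top_coupled_pairs(self, k: int = 10, apc: bool = True,
                          n_residue_pairs: int = 5) -> list[CouplingScore]:
        return top_coupled_pairs(self.model, k=k, apc=apc,
                                 n_residue_pairs=n_residue_pairs)

    def summary(self) -> str:
        m = self.model.meta
        lines = [
            "Potts pseudolikelihood fit",
            "=" * 44,
            f"sequences           {m['n_sequences']:>10}",
            f"Meff                {m['meff']:>10.2f}",
            f"L x q               {self.model.L:>6} x {self.model.q}",
            f"lambda_h / lambda_J {m['lambda_h']:>6g} / {m['lambda_J']:g}",
            f"iterations          {m['iterations']:>10}",
            f"converged           {str(self.converged):>10}",
            f"final objective     {m['final_objective']:>10.4f}",
            "",
            "top coupled position pairs (APC-corrected Frobenius)",
        ]
        for cs in self.top_coupled_pairs(k=5):
            a, b, v = cs.top_pairs[0]
            lines.append(f"  {cs.i:>2}-{cs.j:<2} apc={cs.apc:+.4f} "
                         f"F={cs.frobenius:.4f}  strongest {a}{cs.i}-{b}{cs.j} "
                         f"({v:+.3f})")
        return "\n".join(lines)


def fit_plmdca(msa: MSA, lambda_h: float = 0.01, lambda_J: float = 0.01,
               reweight: bool = False, identity_threshold: float = 0.8,
               max_iter: int = 500, tol: float = 1e-5) -> PottsModel:
    """Functional wrapper: fit and return just the PottsModel."""
    return PottsPseudolikelihood(
        msa, lambda_h=lambda_h, lambda_J=lambda_J, reweight=reweight,
        identity_threshold=identity_threshold).fit(
            max_iter=max_iter, tol=tol).model


def apc_correction(F: np.ndarray) -> np.ndarray:
    """Average-product correction of a symmetric norm matrix.

    ``APC_ij = F_ij - F_i. * F_.j / F_..`` with row/column/total means taken
    over off-diagonal entries. Removes the background tendency of noisy
    positions to couple with everything.
    """
    L = F.shape[0]
    off = ~np.eye(L, dtype=bool)
    row_mean = (F * off).sum(axis=1) / (L - 1)
    total_mean = (F * off).sum() / (L * (L - 1))
    if total_mean == 0:
        return F.copy()
    return F - np.outer(row_mean, row_mean) / total_mean


def top_coupled_pairs(model: PottsModel, k: int = 10, apc: bool = True,
                      n_residue_pairs: int = 5) -> list[CouplingScore]:
    """Rank position pairs by (APC-corrected) coupling strength.

    The model is moved to the zero-sum gauge first if needed. Ties are broken
    by (i, j) lexicographic order; requesting more pairs than exist returns
    all of them. Positions in the result are 1-based.
    """
    zs = model if model.gauge == "zero_sum" else model.to_zero_sum_gauge()
    F = zs.coupling_norms()
    A = apc_correction(F)
    key = A if apc else F
    scored = sorted(((key[i, j], i, j) for (i, j) in zs.pairs),
                    key=lambda t: (-t[0], t[1], t[2]))
    out = []
    symbols = model.alphabet.symbols
    for value, i, j in scored[:min(k, len(scored))]:
        block = zs.J[zs.pair_index(i, j)]
        flat = [(symbols[a], symbols[b], float(block[a, b]))
                for a in range(zs.q) for b in range(zs.q)]
        flat.sort(key=lambda t: -abs(t[2]))
        out.append(CouplingScore(i=i + 1, j=j + 1,
                                 frobenius=float(F[i, j]),
                                 apc=float(A[i, j]),
                                 top_pairs=flat[:n_residue_pairs]))
    return out


def score_sequence(model: PottsModel, sequence: str) -> SequenceScore:
    """Score a scaffold-conformant sequence under the model."""
    model.scaffold.check(sequence)
    return SequenceScore(sequence=sequence, score=model.score(sequence))
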