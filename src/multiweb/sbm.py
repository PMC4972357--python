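"""Multiplex stochastic block model with a 3D-Bernoulli emission.

The model clusters species by their joint connectivity across the three
interaction layers. Species memberships ``Z_i`` are multinomial with
proportions ``a``; conditionally on ``Z_iq = Z_jl = 1`` the 3-bit outcome
of the directed pair ``(i, j)`` — (trophic, positive, negative) presence —
follows a categorical ("3D-Bernoulli") distribution over its 8 joint
outcomes with parameters ``theta[q, l]``. The joint emission captures the
within-pair coupling of interaction types, which three independent
Bernoullis would miss.

Estimation is by variational EM with mean-field responsibilities ``tau``;
initialization is k-means on the Rogers–Tanimoto distance matrix between
species interaction vectors plus random membership perturbations; the
number of clusters is selected with an integrated classification
likelihood (ICL) criterion.

Usage follows the Model/Results convention::

    model = MultiplexSBM(net)
    res = model.fit_best(Q=3, n_restarts=20, seed=0)
    res.membership, res.theta, res.icl
    best = model.select_Q(range(1, 9), n_restarts=10, seed=0)
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .net import LAYER_CODES, MultiplexNet, interaction_vectors, rogers_tanimoto_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "MultiplexSBM", "SBMResults", "emission_logprob", "adjusted_rand",
    "vem_fit", "fit_best", "select_Q", "init_partitions", "icl_score",
    "layer_subset_fit", "robustness_to_removal", "outcome_codes",
]

#: floor applied to mixture weights and emission cells so logs stay finite
DEFAULT_EPS = 1e-10


def outcome_codes(net: MultiplexNet, layers: Sequence[str] = LAYER_CODES) -> np.ndarray:
    """Encode each directed pair's joint outcome as an integer.

    Outcome ``(y1, y2, ..., yL)`` over the chosen layers maps to
    ``y1 + 2*y2 + 4*y3 + ...`` (binary, little-endian in layer order), so
    with the full three layers code 0 means "no interaction of any type"
    and code 7 a pair linked by all three types.
    """
    code = np.zeros((net.n, net.n), dtype=np.int64)
    for bit, layer in enumerate(layers):
        code += (net.layer(layer).astype(np.int64)) << bit
    return code


def emission_logprob(y: Sequence[int], theta_ql: np.ndarray, eps: float = DEFAULT_EPS) -> float:
    """Log-probability of a joint outcome ``y`` (bit tuple) under one
    block-pair emission distribution (cells floored at ``eps``)."""
    theta_ql = np.asarray(theta_ql, dtype=float)
    code = sum(int(b) << k for k, b in enumerate(y))
    p = np.maximum(theta_ql, eps)
    p = p / p.sum()
    return float(np.log(p[code]))


def adjusted_rand(p1: Sequence[int], p2: Sequence[int],
                  ids1: Sequence[str] | None = None,
                  ids2: Sequence[str] | None = None) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    When species id lists are supplied the comparison is restricted to
    their intersection (used by the removal-robustness analysis, where the
    refitted partition covers only surviving species).
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if ids1 is not None or ids2 is not None:
        if ids1 is None or ids2 is None:
            raise ValueError("provide both id lists or neither")
        common = [s for s in ids1 if s in set(ids2)]
        if not common:
            raise ValueError("partitions share no species")
        i1 = {s: k for k, s in enumerate(ids1)}
        i2 = {s: k for k, s in enumerate(ids2)}
        p1 = p1[[i1[s] for s in common]]
        p2 = p2[[i2[s] for s in common]]
    if p1.shape != p2.shape:
        raise ValueError("partitions must cover the same species")
    return float(adjusted_rand_score(p1, p2))


class SBMResults:
    """Fitted multiplex SBM: estimates, bound, ICL and the modal partition.

    Attributes
    ----------
    Q : int
        Number of clusters.
    a : (Q,) ndarray
        Mixture proportions.
    theta : (Q, Q, K) ndarray
        Per ordered block pair, the categorical distribution over the
        ``K = 2^n_layers`` joint outcomes (outcome order little-endian).
    tau : (n, Q) ndarray
        Variational responsibilities, rows sum to one.
    elbo : float
        Final variational lower bound on the log-likelihood.
    icl : float
        Integrated classification likelihood at the modal partition.
    elbo_trace : list of float
        Bound after every VEM iteration (non-decreasing up to damping).
    """

    def __init__(self, model: "MultiplexSBM", Q: int, a: np.ndarray, theta: np.ndarray,
                 tau: np.ndarray, elbo: float, elbo_trace: list[float],
                 converged: bool, n_iter: int):
        self.model = model
        self.Q = int(Q)
        self.a = a
        self.theta = theta
        self.tau = tau
        self.elbo = float(elbo)
        self.elbo_trace = elbo_trace
        self.converged = converged
        self.n_iter = n_iter
        self.icl = model._icl(self)
        self.scan_table: list[dict] | None = None  # filled by select_Q

    @property
    def membership(self) -> np.ndarray:
        """Modal partition: argmax responsibility, ties to the lowest label."""
        return np.argmax(self.tau, axis=1)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return self.model.net.species_ids

    def completed_loglik(self) -> float:
        return self.model._completed_loglik(self)

    def summary(self) -> str:
        lines = [
            "Multiplex stochastic block model (3D-Bernoulli emission)",
            f"  species: {self.model.net.n}    layers: {''.join(self.model.layers)}",
            f"  clusters (Q): {self.Q}",
            f"  ELBO: {self.elbo:.4f}    ICL: {self.icl:.4f}",
            f"  iterations: {self.n_iter}  converged: {self.converged}",
            "  cluster sizes: " + ", ".join(
                f"{q + 1}:{int(c)}" for q, c in enumerate(np.bincount(self.membership, minlength=self.Q))),
        ]
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "Q": self.Q,
            "layers": list(self.model.layers),
            "outcome_order": "little-endian bits (y_T, y_P, y_N) in layer order",
            "a": self.a.tolist(),
            "theta": self.theta.tolist(),
            "tau": self.tau.tolist(),
            "elbo": self.elbo,
            "icl": self.icl,
            "membership": self.membership.tolist(),
            "species_ids": list(self.species_ids),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    def write_partition_csv(self, path: str | Path) -> None:
        """Write species_id,cluster (1-based cluster labels)."""
        rows = ["species_id,cluster"]
        rows += [f"{s},{z + 1}" for s, z in zip(self.species_ids, self.membership)]
        Path(path).write_text("\n".join(rows) + "\n")


class MultiplexSBM:
    """Model object binding a :class:`MultiplexNet` to the block model.

    Parameters
    ----------
    net
        The multiplex network to cluster.
    layers
        Layer subset used for the emission (default all three); the
        emission then has ``2^len(layers)`` cells per block pair, which
        supports the single- and two-layer comparison fits.
    eps
        Probability floor on emission cells and mixture weights.
    """

    def __init__(self, net: MultiplexNet, layers: Sequence[str] = LAYER_CODES,
                 eps: float = DEFAULT_EPS):
        if len(layers) == 0:
            raise ValueError("need at least one layer")
        for code in layers:
            if code not in LAYER_CODES:
                raise KeyError(f"unknown layer code {code!r}")
        self.net = net
        self.layers = tuple(layers)
        self.eps = float(eps)
        self.n_cells = 2 ** len(self.layers)
        self._codes = outcome_codes(net, self.layers)
        n = net.n
        # per-cell indicator matrices with zeroed diagonal (self-pairs are
        # excluded from the likelihood)
        eye = np.eye(n, dtype=bool)
        self._E = np.zeros((self.n_cells, n, n))
        for c in range(self.n_cells):
            self._E[c] = (self._codes == c) & ~eye

    # -- initialization --------------------------------------------------

    def distance_matrix(self) -> np.ndarray:
        """Rogers–Tanimoto distances between species interaction vectors
        (restricted to the model's layers)."""
        vec = interaction_vectors(self.net)
        if self.layers != LAYER_CODES:
            n = self.net.n
            keep = []
            for k, code in enumerate(LAYER_CODES):
                if code in self.layers:
                    keep.extend(range(2 * k * n, 2 * (k + 1) * n))
            vec = vec[:, keep]
        return rogers_tanimoto_matrix(vec)

    def init_partitions(self, Q: int, n_restarts: int = 1, seed: int | None = None,
                        method: str = "kmeans") -> list[np.ndarray]:
        """Starting partitions: unperturbed k-means first, then perturbed copies.

        k-means runs on the rows of the species distance matrix (each
        species represented by its vector of distances to all species);
        each further start switches a uniform 5–15 distinct species to
        uniformly drawn other labels. Deterministic given ``seed``.
        A k-medoids-style variant (``method='medoids'``) picks the species
        minimising within-cluster distance sums instead.
        """
        n = self.net.n
        if not 1 <= Q <= n:
            raise ValueError(f"Q must be in [1, {n}], got {Q}")
        if n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        rng = np.random.default_rng(seed)
        D = self.distance_matrix()
        if Q == n:
            base = np.arange(n)
        elif method == "kmeans":
            km = KMeans(n_clusters=Q, n_init=10,
                        random_state=int(rng.integers(2 ** 31)))
            base = km.fit_predict(D)
        elif method == "medoids":
            base = _kmedoids(D, Q, rng)
        else:
            raise ValueError(f"unknown init method {method!r}")
        parts = [base]
        for _ in range(n_restarts - 1):
            p = base.copy()
            if Q > 1:
                k = int(rng.integers(5, 16))
                k = min(k, n)
                switch = rng.choice(n, size=k, replace=False)
                for i in switch:
                    others = [q for q in range(Q) if q != p[i]]
                    p[i] = rng.choice(others)
            parts.append(p)
        return parts

    # -- variational EM --------------------------------------------------

    def fit(self, Q: int, init: np.ndarray | None = None, max_iter: int = 200,
            tol: float = 1e-6, seed: int | None = None) -> SBMResults:
        """Single VEM run from one starting partition.

        The E-step applies the mean-field fixed point for the
        responsibilities; the M-step has closed forms for ``a`` and
        ``theta``. If an update decreases the bound, the responsibility
        step is damped by 0.5 and retried once before accepting. Stops
        when the bound improves by less than ``tol``.
        """
        n = self.net.n
        if init is None:
            init = self.init_partitions(Q, 1, seed)[0]
        init = np.asarray(init, dtype=int)
        if init.shape != (n,) or init.min() < 0 or init.max() >= Q:
            raise ValueError("init must be a length-n partition with labels in [0, Q)")
        tau = np.full((n, Q), 0.05 / max(Q - 1, 1))
        tau[np.arange(n), init] = 0.95 if Q > 1 else 1.0
        tau /= tau.sum(axis=1, keepdims=True)

        a, log_theta = self._m_step(tau)
        elbo = self._elbo(tau, a, log_theta)
        trace = [elbo]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            tau_new = self._e_step(tau, a, log_theta)
            a_new, log_theta_new = self._m_step(tau_new)
            elbo_new = self._elbo(tau_new, a_new, log_theta_new)
            if elbo_new < elbo - 1e-12:
                # damp the responsibility move once, then accept whatever results
                tau_new = 0.5 * (tau + tau_new)
                tau_new /= tau_new.sum(axis=1, keepdims=True)
                a_new, log_theta_new = self._m_step(tau_new)
                elbo_new = self._elbo(tau_new, a_new, log_theta_new)
                logger.debug("damped E-step at iter %d", it)
            if not np.isfinite(elbo_new):
                raise FloatingPointError(f"non-finite ELBO at iteration {it}")
            tau, a, log_theta = tau_new, a_new, log_theta_new
            improvement = elbo_new - elbo
            elbo = elbo_new
            trace.append(elbo)
            if abs(improvement) < tol:
                converged = True
                break
        theta = np.exp(log_theta)
        theta /= theta.sum(axis=2, keepdims=True)
        return SBMResults(self, Q, a, theta, tau, elbo, trace, converged, it)

    def fit_best(self, Q: int, n_restarts: int = 1000, seed: int | None = None,
                 max_iter: int = 200, tol: float = 1e-6,
                 init_method: str = "kmeans") -> SBMResults:
        """Best-of-restarts fit: VEM from every starting partition, keep the
        run with the maximal bound."""
        inits = self.init_partitions(Q, n_restarts, seed, method=init_method)
        best: SBMResults | None = None
        errors: list[Exception] = []
        for init in inits:
            try:
                res = self.fit(Q, init=init, max_iter=max_iter, tol=tol)
            except FloatingPointError as exc:  # pragma: no cover - defensive
                errors.append(exc)
                continue
            if best is None or res.elbo > best.elbo:
                best = res
        if best is None:
            raise RuntimeError(f"all {n_restarts} restarts failed: {errors[:3]}")
        return best

    def select_Q(self, Q_range: Iterable[int], n_restarts: int = 1000,
                 seed: int | None = None, **fit_kw) -> SBMResults:
        """Fit every Q in the range, return the ICL-maximising fit.

        The returned results carry ``scan_table`` — per Q the bound, the
        completed log-likelihood and the ICL — for inspection/plotting.
        """
        Q_range = list(Q_range)
        if not Q_range:
            raise ValueError("empty Q range")
        rng = np.random.default_rng(seed)
        table = []
        best: SBMResults | None = None
        for Q in Q_range:
            res = self.fit_best(Q, n_restarts=n_restarts,
                                seed=int(rng.integers(2 ** 31)), **fit_kw)
            table.append({"Q": Q, "elbo": res.elbo,
                          "loglik": res.completed_loglik(), "icl": res.icl})
            if best is None or res.icl > best.icl:
                best = res
        best.scan_table = table
        return best

    # -- internals -------------------------------------------------------

    def _m_step(self, tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = tau.mean(axis=0)
        a = np.maximum(a, self.eps)
        a /= a.sum()
        s = tau.sum(axis=0)
        denom = np.outer(s, s) - tau.T @ tau  # sum over ordered pairs i != j
        K = self.n_cells
        num = np.empty((tau.shape[1], tau.shape[1], K))
        for c in range(K):
            num[:, :, c] = tau.T @ self._E[c] @ tau
        dead = denom <= self.eps
        if dead.any():
            warnings.warn("empty cluster pair in M-step; renormalizing with the eps floor",
                          RuntimeWarning, stacklevel=3)
        theta = num / np.maximum(denom[:, :, None], self.eps)
        theta = np.maximum(theta, self.eps)
        theta /= theta.sum(axis=2, keepdims=True)
        return a, np.log(theta)

    def _pair_loglik_fields(self, tau: np.ndarray, log_theta: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
        """S_out[i,q] = sum_{j != i} sum_l tau_jl log f(Y_ij; theta_ql)
        and S_in[i,q] likewise for Y_ji (emission theta_lq)."""
        n, Q = tau.shape
        S_out = np.zeros((n, Q))
        S_in = np.zeros((n, Q))
        for c in range(self.n_cells):
            Lc = log_theta[:, :, c]            # (q, l)
            M = self._E[c] @ tau               # M[i, l]
            S_out += M @ Lc.T
            Mt = self._E[c].T @ tau
            S_in += Mt @ Lc
        return S_out, S_in

    def _e_step(self, tau: np.ndarray, a: np.ndarray, log_theta: np.ndarray,
                n_inner: int = 5, inner_tol: float = 1e-4) -> np.ndarray:
        log_a = np.log(np.maximum(a, self.eps))
        for _ in range(n_inner):
            S_out, S_in = self._pair_loglik_fields(tau, log_theta)
            log_tau = log_a[None, :] + S_out + S_in
            log_tau -= logsumexp(log_tau, axis=1, keepdims=True)
            tau_new = np.exp(log_tau)
            delta = np.abs(tau_new - tau).max()
            tau = tau_new
            if delta < inner_tol:
                break
        return tau

    def _elbo(self, tau: np.ndarray, a: np.ndarray, log_theta: np.ndarray) -> float:
        S_out, _ = self._pair_loglik_fields(tau, log_theta)
        pair_term = float(np.sum(tau * S_out))  # each ordered pair counted once
        log_a = np.log(np.maximum(a, self.eps))
        mix_term = float(np.sum(tau * log_a[None, :]))
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = np.where(tau > 0, tau * np.log(tau), 0.0)
        entropy = -float(ent.sum())
        return pair_term + mix_term + entropy

    def _completed_loglik(self, res: SBMResults) -> float:
        z = res.membership
        log_theta = np.log(np.maximum(res.theta, self.eps))
        codes = self._codes
        n = self.net.n
        ll = float(np.log(np.maximum(res.a, self.eps))[z].sum())
        Zq = z[:, None]
        pair_ll = log_theta[Zq, z[None, :], codes]
        np.fill_diagonal(pair_ll, 0.0)
        return ll + float(pair_ll.sum())

    def _icl(self, res: SBMResults) -> float:
        """ICL = completed log-likelihood minus complexity penalties for the
        mixture ((Q-1)/2 log n) and the emission ((K-1) Q^2 / 2 log n(n-1))."""
        n = self.net.n
        Q = res.Q
        K = self.n_cells
        penalty = (Q - 1) / 2.0 * np.log(n) + (K - 1) * Q * Q / 2.0 * np.log(n * (n - 1))
        return self._completed_loglik(res) - penalty


def _kmedoids(D: np.ndarray, Q: int, rng: np.random.Generator,
              max_iter: int = 50) -> np.ndarray:
    """Plain PAM-style k-medoids on a precomputed distance matrix."""
    n = D.shape[0]
    medoids = rng.choice(n, size=Q, replace=False)
    labels = np.argmin(D[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for q in range(Q):
            members = np.where(labels == q)[0]
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[q] = members[np.argmin(within)]
        new_labels = np.argmin(D[:, new_medoids], axis=1)
        if np.array_equal(new_labels, labels) and np.array_equal(new_medoids, medoids):
            break
        medoids, labels = new_medoids, new_labels
    return labels


# ---------------------------------------------------------------------------
# functional wrappers matching the operation-style surface
# ---------------------------------------------------------------------------

def init_partitions(net: MultiplexNet, Q: int, n_restarts: int = 1,
                    seed: int | None = None, method: str = "kmeans") -> list[np.ndarray]:
    return MultiplexSBM(net).init_partitions(Q, n_restarts, seed, method)


def vem_fit(net: MultiplexNet, Q: int, init: np.ndarray | None = None,
            max_iter: int = 200, tol: float = 1e-6, seed: int | None = None) -> SBMResults:
    return MultiplexSBM(net).fit(Q, init=init, max_iter=max_iter, tol=tol, seed=seed)


def fit_best(net: MultiplexNet, Q: int, n_restarts: int = 1000,
             seed: int | None = None, **kw) -> SBMResults:
    return MultiplexSBM(net).fit_best(Q, n_restarts=n_restarts, seed=seed, **kw)


def select_Q(net: MultiplexNet, Q_min: int, Q_max: int, n_restarts: int = 1000,
             seed: int | None = None, **kw) -> SBMResults:
    return MultiplexSBM(net).select_Q(range(Q_min, Q_max + 1),
                                      n_restarts=n_restarts, seed=seed, **kw)


def icl_score(res: SBMResults) -> float:
    return res.icl


def layer_subset_fit(net: MultiplexNet, layers: Sequence[str], Q: int,
                     n_restarts: int = 1000, seed: int | None = None, **kw) -> SBMResults:
    """Fit using only a subset of layers (emission over 2^|layers| cells);
    used to ask whether any single layer suffices to recover the 3D clusters."""
    return MultiplexSBM(net, layers=layers).fit_best(Q, n_restarts=n_restarts,
                                                     seed=seed, **kw)


def trophic_cascade(net: MultiplexNet, removed: Sequence[int]) -> np.ndarray:
    """Indices surviving after removing ``removed`` plus the topological
    cascade: any species that originally had at least one trophic resource
    but is left with none is iteratively deleted."""
    n = net.n
    alive = np.ones(n, dtype=bool)
    alive[list(removed)] = False
    had_resources = net.layer_T.sum(axis=1) > 0
    while True:
        resources_left = (net.layer_T[:, alive].sum(axis=1) > 0)
        starved = alive & had_resources & ~resources_left
        if not starved.any():
            break
        alive[starved] = False
    return np.where(alive)[0]


def robustness_to_removal(net: MultiplexNet, reference: SBMResults,
                          fractions: Sequence[float], reps: int, seed: int,
                          Q_range: Iterable[int] | None = None,
                          n_restarts: int = 10, **fit_kw):
    """Partition stability under random species removal.

    For each removal fraction, ``reps`` times: remove that share of species
    uniformly at random, apply the trophic cascade, refit (ICL selection
    over ``Q_range``), and score the adjusted Rand index against the
    reference partition restricted to survivors. Returns a DataFrame with
    the mean aRI and mean selected Q per fraction; replicates whose cascade
    empties the network are recorded as degenerate and excluded.
    """
    import pandas as pd

    if Q_range is None:
        Q_range = range(1, reference.Q + 3)
    Q_range = list(Q_range)
    rng = np.random.default_rng(seed)
    ref_ids = list(reference.species_ids)
    rows = []
    for frac in fractions:
        if not 0 < frac <= 0.5:
            raise ValueError("fractions must lie in (0, 0.5]")
        aris, qs, degenerate = [], [], 0
        n_remove = int(round(frac * net.n))
        for _ in range(reps):
            if n_remove == 0:
                aris.append(1.0)
                qs.append(reference.Q)
                continue
            removed = rng.choice(net.n, size=n_remove, replace=False)
            alive = trophic_cascade(net, removed)
            if alive.size < max(Q_range):
                degenerate += 1
                logger.warning("degenerate replicate: cascade left %d species", alive.size)
                continue
            sub = net.subnet(alive)
            res = MultiplexSBM(sub).select_Q(
                Q_range, n_restarts=n_restarts,
                seed=int(rng.integers(2 ** 31)), **fit_kw)
            ref_members = np.asarray(reference.membership)[alive]
            aris.append(adjusted_rand(ref_members, res.membership))
            qs.append(res.Q)
        rows.append({"fraction": frac,
                     "mean_ari": float(np.mean(aris)) if aris else np.nan,
                     "mean_Q": float(np.mean(qs)) if qs else np.nan,
                     "n_degenerate": degenerate,
                     "n_used": len(aris)})
    return pd.DataFrame(rows)
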