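"""Bioenergetic consumer–resource dynamics with non-trophic modifiers.

Simulation units are multiplex clusters (a node stands for a "typical"
species of its cluster), linked by quantitative matrices in [0, 1] whose
entries are between-cluster interaction frequencies. The backbone is a
multi-prey Holling-type consumer–resource model: producers grow
logistically, consumers gain biomass through a saturating functional
response and lose it to metabolism and predation,

    dB_i/dt = r_i (1 - B_i/K_i) B_i + e_i B_i sum_j F_ij TR(i,j)
              - sum_k F_ki B_k TR(k,i) - x_i B_i .

Six non-trophic mechanisms modify the vital rates, all as saturating
functions of the biomass of the interacting species:

* ``COMP`` — space competition multiplies producer growth by
  ``g_i = 1 - sum_k COMP(k,i) c_ki B_k`` (floored at 0);
* ``INT``  — predator interference enters the functional-response
  denominator for predators sharing a prey;
* ``MORT`` — increased mortality raises ``x_i`` toward ``x_max_i``;
* ``REC``  — recruitment facilitation raises producer growth toward
  ``r_i + r_max_i``;
* ``REF``  — refuge provisioning lowers the attack rate toward
  ``b_min_ij``;
* ``FAC``  — survival facilitation lowers ``x_i`` toward ``x_min_i``.

Global multipliers ``intpos`` and ``intneg`` scale the positive
(REC/REF/FAC) and negative (COMP/INT/MORT) interaction strengths.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .net import MultiplexNet

__all__ = [
    "ClusterWeb", "DynParams", "SimResult", "ClusterDynamics",
    "relative_consumption", "refuge_attack", "growth_modifier",
    "recruitment_rate", "mortality_rate", "functional_response", "rhs",
    "rhs_trophic",
    "simulate", "aggregate_layers", "cluster_web_from_sbm", "NTIMapping",
    "removal_experiment", "compare_to_random_nti", "parameter_sweep",
]

NTI_MATRICES = ("COMP", "INT", "MORT", "REC", "REF", "FAC")


@dataclasses.dataclass
class ClusterWeb:
    """Quantitative cluster-level web: one trophic and six mechanism matrices.

    ``TR[i, j] > 0`` means node ``i`` consumes node ``j``; all entries are
    interaction frequencies in [0, 1]. ``producers`` flags the nodes with
    intrinsic growth. ``REF[k, j]`` reads "``k`` provides refuge to prey
    ``j``"; the other matrices read "row affects column".
    """

    labels: tuple[str, ...]
    TR: np.ndarray
    COMP: np.ndarray | None = None
    INT: np.ndarray | None = None
    MORT: np.ndarray | None = None
    REC: np.ndarray | None = None
    REF: np.ndarray | None = None
    FAC: np.ndarray | None = None
    producers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(str(x) for x in self.labels)
        k = len(self.labels)
        self.TR = np.asarray(self.TR, dtype=float)
        if self.TR.shape != (k, k):
            raise ValueError("TR shape mismatch")
        for name in NTI_MATRICES:
            m = getattr(self, name)
            m = np.zeros((k, k)) if m is None else np.asarray(m, dtype=float)
            if m.shape != (k, k):
                raise ValueError(f"{name} shape mismatch")
            if (m < 0).any() or (m > 1).any():
                raise ValueError(f"{name} entries must lie in [0, 1]")
            setattr(self, name, m)
        if (self.TR < 0).any() or (self.TR > 1).any():
            raise ValueError("TR entries must lie in [0, 1]")
        if self.producers is None:
            # producers have no resources
            self.producers = self.TR.sum(axis=1) == 0
        self.producers = np.asarray(self.producers, dtype=bool)

    @property
    def k(self) -> int:
        return len(self.labels)

    def zero_nti(self) -> "ClusterWeb":
        """Copy with all non-trophic matrices emptied (plain food web)."""
        return ClusterWeb(self.labels, self.TR.copy(), producers=self.producers.copy())

    def remove_node(self, node: int) -> "ClusterWeb":
        """Copy with every link of ``node`` voided (node kept in place)."""
        out = ClusterWeb(self.labels, self.TR.copy(),
                         *(getattr(self, nm).copy() for nm in NTI_MATRICES),
                         producers=self.producers.copy())
        for name in ("TR",) + NTI_MATRICES:
            m = getattr(out, name)
            m[node, :] = 0.0
            m[:, node] = 0.0
        return out


@dataclasses.dataclass
class DynParams:
    """All vital-rate parameters of the dynamical model.

    Per node: intrinsic growth ``r`` (1/time; > 0 for producers only),
    carrying capacity ``K``, conversion efficiency ``e``, metabolic rate
    ``x``, handling time ``h``, facilitation bounds ``r_max``, ``x_min``,
    ``x_max``. Per pair: attack rate ``b`` and its refuge floor ``b_min``,
    competition intensity ``c``, interference intensity ``d``. Global:
    Hill coefficient ``q`` (0 = type II response), the NTI strength
    multipliers ``intpos``/``intneg``, and the metabolic constants
    ``x0``/``y`` used to build ``x`` and the handling time.
    """

    r: np.ndarray
    K: np.ndarray
    e: np.ndarray
    x: np.ndarray
    h: np.ndarray
    r_max: np.ndarray
    x_min: np.ndarray
    x_max: np.ndarray
    b: np.ndarray
    b_min: np.ndarray
    c: np.ndarray
    d: np.ndarray
    q: float = 0.0
    intpos: float = 1.0
    intneg: float = 1.0
    x0: float = 0.2227
    y: float = 10.0
    g_floor: bool = True
    strict_refuge: bool = False

    def __post_init__(self) -> None:
        k = self.r.shape[0]
        for name in ("r", "K", "e", "x", "h", "r_max", "x_min", "x_max"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("b", "b_min", "c", "d"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (k, k):
                raise ValueError(f"{name} must be ({k}, {k})")
            setattr(self, name, m)
        if (self.x_min > self.x).any() or (self.x > self.x_max).any():
            raise ValueError("need x_min <= x <= x_max")
        if (self.b_min > self.b).any():
            raise ValueError("need b_min <= b")
        if ((self.e <= 0) | (self.e > 1)).any():
            raise ValueError("conversion efficiency must lie in (0, 1]")

    @classmethod
    def defaults(cls, web: ClusterWeb, *, x0: float = 0.2227, y: float = 10.0,
                 intpos: float = 1.0, intneg: float = 0.2, q: float = 0.0,
                 r0: float = 1.0, K0: float = 1.0, e0: float = 0.85,
                 b0: float = 0.5, b_min_frac: float = 0.2,
                 c0: float = 1.0, d0: float = 1.0, **extra) -> "DynParams":
        """Standard bioenergetic parameterization for a cluster web.

        Producers get growth ``r0`` and no metabolic loss; consumers get
        metabolic rate ``x0`` and a handling time ``1/(y*x0)`` so maximum
        ingestion is ``y`` times metabolism. Facilitation bounds default to
        a doubling of producer growth (``r_max = r``), halved mortality
        (``x_min = x/2``) and a doubled mortality ceiling (``x_max = 2x``,
        or ``x0`` for producers, so negative survival effects can reach
        them too). Refuge can cut attack rates to ``b_min_frac * b``.
        """
        k = web.k
        prod = web.producers
        r = np.where(prod, r0, 0.0)
        x = np.where(prod, 0.0, x0)
        return cls(
            r=r,
            K=np.full(k, K0),
            e=np.full(k, e0),
            x=x,
            h=np.full(k, 1.0 / (y * x0)),
            r_max=r.copy(),
            x_min=0.5 * x,
            x_max=np.where(prod, x0, 2.0 * x),
            b=np.full((k, k), b0),
            b_min=np.full((k, k), b_min_frac * b0),
            c=np.full((k, k), c0),
            d=np.full((k, k), d0),
            q=q, intpos=intpos, intneg=intneg, x0=x0, y=y, **extra)


# ---------------------------------------------------------------------------
# model terms
# ---------------------------------------------------------------------------

def relative_consumption(TR: np.ndarray) -> np.ndarray:
    """``w_i = 1 / (number of resources of i)``; 0 for non-consumers."""
    n_res = (np.asarray(TR) > 0).sum(axis=1)
    with np.errstate(divide="ignore"):
        w = np.where(n_res > 0, 1.0 / np.maximum(n_res, 1), 0.0)
    return w


def refuge_attack(B: np.ndarray, web: ClusterWeb, params: DynParams) -> np.ndarray:
    """Refuge-modified attack rates ``b'`` (matrix over consumer–prey pairs).

    With facilitator load ``S_j = intpos * sum_k REF(k, j) B_k``, the
    default form interpolates from ``b_ij`` (S = 0) down to the floor
    ``b_min_ij`` (S -> inf) — the "minimum consumption reached in the
    presence of facilitators". ``strict_refuge=True`` instead uses the
    additive variant ``b + b_min * S/(1+S)`` whose large-S limit is
    ``b + b_min``.
    """
    S = params.intpos * (web.REF.T @ B)  # per prey j
    sat = S / (1.0 + S)
    if params.strict_refuge:
        return params.b + params.b_min * sat[None, :]
    return params.b - (params.b - params.b_min) * sat[None, :]


def growth_modifier(B: np.ndarray, web: ClusterWeb, params: DynParams) -> np.ndarray:
    """Space-competition growth multiplier ``g_i``, floored at 0 by default."""
    load = params.intneg * ((web.COMP * params.c).T @ B)
    g = 1.0 - load
    return np.maximum(g, 0.0) if params.g_floor else g


def recruitment_rate(B: np.ndarray, web: ClusterWeb, params: DynParams) -> np.ndarray:
    """Facilitated growth rate ``r_i + r_max_i * S/(1+S)``."""
    S = params.intpos * (web.REC.T @ B)
    return params.r + params.r_max * S / (1.0 + S)


def mortality_rate(B: np.ndarray, web: ClusterWeb, params: DynParams) -> np.ndarray:
    """Mortality with survival facilitation (toward ``x_min``) and
    biomass-dependent harm (toward ``x_max``)."""
    S_f = params.intpos * (web.FAC.T @ B)
    S_m = params.intneg * (web.MORT.T @ B)
    return (params.x
            - (params.x - params.x_min) * S_f / (1.0 + S_f)
            + (params.x_max - params.x) * S_m / (1.0 + S_m))


def _response_matrix(B: np.ndarray, web: ClusterWeb, params: DynParams) -> np.ndarray:
    """Full functional-response matrix ``F[i, j]`` (0 where TR[i,j] = 0)."""
    TRpos = web.TR > 0
    w = relative_consumption(web.TR)
    bprime = refuge_attack(B, web, params)
    Bq = np.power(np.maximum(B, 0.0), 1.0 + params.q)
    intake = (web.TR * bprime) @ Bq                        # sum_k TR b' B^{1+q}
    base = 1.0 + w * params.h * intake                     # per consumer i
    # interference: predators l of prey j acting on consumer i
    A = params.intneg * web.INT * params.d * B[:, None]    # A[l, i]
    I = A.T @ TRpos.astype(float)                          # I[i, j]
    denom = base[:, None] + I
    num = (w[:, None] * bprime) * Bq[None, :]
    return np.where(TRpos, num / denom, 0.0)


def functional_response(i: int, j: int, B: np.ndarray, web: ClusterWeb,
                        params: DynParams) -> float:
    """Holling-type response of consumer ``i`` on resource ``j`` including
    interference and refuge effects; requires ``TR[i, j] > 0``."""
    if web.TR[i, j] <= 0:
        raise ValueError(f"node {i} does not consume node {j}")
    return float(_response_matrix(np.asarray(B, dtype=float), web, params)[i, j])


def rhs(t: float, B: np.ndarray, web: ClusterWeb, params: DynParams,
        alive: np.ndarray | None = None) -> np.ndarray:
    """Biomass derivatives of the full model (growth only for producers)."""
    B = np.maximum(np.asarray(B, dtype=float), 0.0)
    if alive is not None:
        B = np.where(alive, B, 0.0)
    F = _response_matrix(B, web, params)
    r_new = recruitment_rate(B, web, params)
    g = growth_modifier(B, web, params)
    x_new = mortality_rate(B, web, params)
    growth = np.where(web.producers, r_new * g * (1.0 - B / params.K) * B, 0.0)
    gain = params.e * B * (F * web.TR).sum(axis=1)
    loss = (F * web.TR * B[:, None]).sum(axis=0)
    dB = growth + gain - loss - x_new * B
    if alive is not None:
        dB = np.where(alive, dB, 0.0)
    return dB


def rhs_trophic(t: float, B: np.ndarray, web: ClusterWeb, params: DynParams,
                alive: np.ndarray | None = None) -> np.ndarray:
    """Plain bioenergetic model (no non-trophic terms): logistic producers
    plus the multi-prey Holling response. With all NTI matrices empty the
    full model reduces to this term for term."""
    B = np.maximum(np.asarray(B, dtype=float), 0.0)
    if alive is not None:
        B = np.where(alive, B, 0.0)
    TRpos = web.TR > 0
    w = relative_consumption(web.TR)
    Bq = np.power(np.maximum(B, 0.0), 1.0 + params.q)
    intake = (web.TR * params.b) @ Bq
    base = 1.0 + w * params.h * intake
    num = (w[:, None] * params.b) * Bq[None, :]
    F = np.where(TRpos, num / base[:, None], 0.0)
    growth = np.where(web.producers, params.r * 1.0 * (1.0 - B / params.K) * B, 0.0)
    gain = params.e * B * (F * web.TR).sum(axis=1)
    loss = (F * web.TR * B[:, None]).sum(axis=0)
    dB = growth + gain - loss - params.x * B
    if alive is not None:
        dB = np.where(alive, dB, 0.0)
    return dB


@dataclasses.dataclass
class SimResult:
    """Trajectories plus end-state summaries of one simulation."""

    times: np.ndarray
    biomass: np.ndarray          # (n_times, k)
    labels: tuple[str, ...]
    ext_threshold: float

    @property
    def final(self) -> np.ndarray:
        return self.biomass[-1]

    @property
    def total_biomass(self) -> float:
        return float(self.final.sum())

    @property
    def extinct(self) -> list[int]:
        return [int(i) for i in np.where(self.final <= self.ext_threshold)[0]]

    @property
    def persistence(self) -> int:
        """Number of nodes alive at the end of the run."""
        return int((self.final > self.ext_threshold).sum())

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.biomass, columns=list(self.labels))
        df.insert(0, "time", self.times)
        return df.melt(id_vars="time", var_name="node", value_name="biomass")


def simulate(web: ClusterWeb, params: DynParams, t_end: float = 2000.0,
             B0: float | np.ndarray = 1.0, ext_threshold: float = 1e-6,
             chunk: float = 1.0, rtol: float = 1e-7, atol: float = 1e-9,
             removed: Sequence[int] = (), rhs_fn: Callable = rhs) -> SimResult:
    """Integrate the model with extinction clamping.

    Integration proceeds in chunks (default unit time, LSODA switching
    between stiff and non-stiff modes); after each chunk any node at or
    below ``ext_threshold`` is clamped to zero for the remainder of the
    run, which keeps the integrator away from the discontinuity. Nodes in
    ``removed`` start extinct.
    """
    k = web.k
    B = np.full(k, B0, dtype=float) if np.isscalar(B0) else np.asarray(B0, dtype=float).copy()
    alive = np.ones(k, dtype=bool)
    for node in removed:
        alive[node] = False
        B[node] = 0.0
    B[B <= ext_threshold] = 0.0
    alive &= B > 0

    n_chunks = int(np.ceil(t_end / chunk))
    times = [0.0]
    traj = [B.copy()]
    fun = lambda t, y: rhs_fn(t, y, web, params, alive)
    t = 0.0
    for _ in range(n_chunks):
        t_next = min(t + chunk, t_end)
        sol = solve_ivp(fun, (t, t_next), B, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={t:.3f}: {sol.message}; state={B}")
        B = np.maximum(sol.y[:, -1], 0.0)
        newly = alive & (B <= ext_threshold)
        if newly.any():
            B[newly] = 0.0
            alive &= ~newly
        B[~alive] = 0.0
        t = t_next
        times.append(t)
        traj.append(B.copy())
    return SimResult(np.asarray(times), np.asarray(traj), web.labels, ext_threshold)


class ClusterDynamics:
    """Model object binding a cluster web to its parameters.

    ``ClusterDynamics(web, params).simulate()`` returns a
    :class:`SimResult`; removal experiments and the randomized-NTI
    comparison hang off the same object.
    """

    def __init__(self, web: ClusterWeb, params: DynParams | None = None):
        self.web = web
        self.params = params if params is not None else DynParams.defaults(web)

    def simulate(self, **kw) -> SimResult:
        return simulate(self.web, self.params, **kw)

    def rhs(self, t: float, B: np.ndarray) -> np.ndarray:
        return rhs(t, B, self.web, self.params)

    def removal_experiment(self, node: int, **sim_kw) -> tuple[int, float]:
        return removal_experiment(self.web, self.params, node, **sim_kw)


# ---------------------------------------------------------------------------
# building cluster webs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NTIMapping:
    """Rule assigning the two non-trophic layers to the six mechanisms.

    The data carries one positive and one negative layer; the model wants
    three mechanisms per sign. Defaults: negative links between two
    sessile nodes become space competition (COMP); negative links between
    consumers sharing at least one prey become interference (INT); the
    rest raise mortality (MORT). Positive links onto producers improve
    recruitment (REC); positive links onto prey provide refuge (REF); the
    rest improve survival (FAC). ``sessile`` defaults to the producer
    flags when not given.
    """

    producers: np.ndarray | None = None
    sessile: np.ndarray | None = None
    link_threshold: float = 0.0

    def split(self, TR: np.ndarray, pos: np.ndarray, neg: np.ndarray
              ) -> dict[str, np.ndarray]:
        k = TR.shape[0]
        thr = self.link_threshold
        producers = (TR.sum(axis=1) <= thr * k) if self.producers is None \
            else np.asarray(self.producers, dtype=bool)
        sessile = producers if self.sessile is None else np.asarray(self.sessile, dtype=bool)
        consumes = TR > thr
        shares_prey = (consumes.astype(float) @ consumes.T.astype(float)) > 0
        is_prey = consumes.any(axis=0)

        out = {name: np.zeros((k, k)) for name in NTI_MATRICES}
        for s in range(k):
            for tgt in range(k):
                if neg[s, tgt] > 0:
                    if sessile[s] and sessile[tgt]:
                        out["COMP"][s, tgt] = neg[s, tgt]
                    elif shares_prey[s, tgt] and not producers[s] and not producers[tgt]:
                        out["INT"][s, tgt] = neg[s, tgt]
                    else:
                        out["MORT"][s, tgt] = neg[s, tgt]
                if pos[s, tgt] > 0:
                    if producers[tgt]:
                        out["REC"][s, tgt] = pos[s, tgt]
                    elif is_prey[tgt]:
                        out["REF"][s, tgt] = pos[s, tgt]
                    else:
                        out["FAC"][s, tgt] = pos[s, tgt]
        return out


def aggregate_layers(net: MultiplexNet, membership: Sequence[int]
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    """Cluster-level interaction frequencies from a species-level net.

    Entry (q, l) is the share of ordered species pairs (i in q, j in l,
    i != j) carrying a link in that layer — quantitative weights in [0, 1].
    """
    z = np.asarray(membership, dtype=int)
    Q = int(z.max()) + 1
    Zind = np.zeros((net.n, Q))
    Zind[np.arange(net.n), z] = 1.0
    sizes = Zind.sum(axis=0)
    denom = np.outer(sizes, sizes) - np.diag(sizes)
    denom = np.maximum(denom, 1.0)
    out = []
    for code in ("T", "P", "N"):
        m = net.layer(code).astype(float).copy()
        np.fill_diagonal(m, 0.0)
        out.append(Zind.T @ m @ Zind / denom)
    labels = tuple(f"C{q + 1}" for q in range(Q))
    return out[0], out[1], out[2], labels


def cluster_web_from_sbm(res_or_marginals, mapping: NTIMapping | None = None,
                         plankton_cluster: int | None = None) -> ClusterWeb:
    """Cluster web from a fitted block model (or explicit layer marginals).

    The trophic matrix is the per-block-pair marginal probability of a
    trophic link under the fitted emission; positive- and negative-layer
    marginals are split into the six mechanism matrices by ``mapping``.
    ``plankton_cluster`` replaces that node by a primary producer (its
    outgoing trophic links are voided and it is flagged as a producer) —
    the substitution used for a plankton cluster that the species web
    cannot resolve.
    """
    if hasattr(res_or_marginals, "theta"):
        theta = np.asarray(res_or_marginals.theta)
        if theta.shape[2] != 8:
            raise ValueError("need a full three-layer fit to build a cluster web")
        codes = np.arange(8)
        TR = theta[:, :, (codes & 1) > 0].sum(axis=2)
        POS = theta[:, :, (codes & 2) > 0].sum(axis=2)
        NEG = theta[:, :, (codes & 4) > 0].sum(axis=2)
    else:
        TR, POS, NEG = (np.asarray(m, dtype=float) for m in res_or_marginals)
    if mapping is None:
        mapping = NTIMapping()
    labels = tuple(f"C{q + 1}" for q in range(TR.shape[0]))
    producers = mapping.producers
    TR = TR.copy()
    if plankton_cluster is not None:
        TR[plankton_cluster, :] = 0.0
        if producers is None:
            producers = TR.sum(axis=1) <= mapping.link_threshold * TR.shape[0]
        producers = np.asarray(producers, dtype=bool).copy()
        producers[plankton_cluster] = True
    mech = NTIMapping(producers=producers, sessile=mapping.sessile,
                      link_threshold=mapping.link_threshold).split(TR, POS, NEG)
    return ClusterWeb(labels, TR, producers=producers, **mech)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def removal_experiment(web: ClusterWeb, params: DynParams, node: int,
                       **sim_kw) -> tuple[int, float]:
    """Secondary extinctions and relative biomass change after removing a node.

    Simulates the intact web, then re-simulates with the node's biomass
    forced to zero and its links voided. Secondary extinctions are nodes
    extinct after the removal but not before (the removed node excluded);
    biomass variation is (after - before) / before on total final biomass.
    """
    if not 0 <= node < web.k:
        raise ValueError(f"node {node} out of range")
    before = simulate(web, params, **sim_kw)
    after = simulate(web.remove_node(node), params, removed=[node], **sim_kw)
    base_extinct = set(before.extinct)
    new_extinct = set(after.extinct) - base_extinct - {node}
    variation = (after.total_biomass - before.total_biomass) / before.total_biomass
    return len(new_extinct), float(variation)


def compare_to_random_nti(net: MultiplexNet, membership: Sequence[int],
                          params_kw: dict | None = None,
                          mapping: NTIMapping | None = None,
                          n_random: int = 500, seed: int | None = None,
                          plankton_cluster: int | None = None,
                          run_removals: bool = False, **sim_kw) -> dict:
    """Observed cluster-web dynamics vs a randomized-NTI null.

    The trophic layer stays fixed; each replicate redraws the positive and
    negative species-level layers from the expected-degree null, then
    re-aggregates with the same (fixed) membership and the same mechanism
    mapping before simulating. The biomass p-value is the fraction of
    replicates whose final total biomass is at least the observed one
    (ties counted half, so a null identical to the data gives p = 0.5).
    ``run_removals=True`` additionally runs single-node removal
    experiments on the observed web and on every null web.
    """
    from .nulls import randomize_multiplex

    params_kw = dict(params_kw or {})
    rng = np.random.default_rng(seed)

    def build(nn: MultiplexNet) -> tuple[ClusterWeb, DynParams]:
        TR, POS, NEG = aggregate_layers(nn, membership)[:3]
        web = cluster_web_from_sbm((TR, POS, NEG), mapping=mapping,
                                   plankton_cluster=plankton_cluster)
        return web, DynParams.defaults(web, **params_kw)

    web_obs, par_obs = build(net)
    obs = simulate(web_obs, par_obs, **sim_kw)

    null_biomass = np.empty(n_random)
    null_persistence = np.empty(n_random, dtype=int)
    null_removals: list[list[int]] = []
    for rep in range(n_random):
        rnet = randomize_multiplex(net, layers=("P", "N"), rng=rng)
        web_r, par_r = build(rnet)
        res = simulate(web_r, par_r, **sim_kw)
        null_biomass[rep] = res.total_biomass
        null_persistence[rep] = res.persistence
        if run_removals:
            null_removals.append(
                [removal_experiment(web_r, par_r, nd, **sim_kw)[0]
                 for nd in range(web_r.k) if not (plankton_cluster == nd)])

    greater = (null_biomass > obs.total_biomass).sum()
    ties = np.isclose(null_biomass, obs.total_biomass).sum()
    p_biomass = float((greater + 0.5 * ties) / n_random)
    report = {
        "observed_biomass": obs.total_biomass,
        "observed_persistence": obs.persistence,
        "null_biomass": null_biomass,
        "null_persistence": null_persistence,
        "p_biomass": p_biomass,
        "n_random": n_random,
        "seed": seed,
    }
    if run_removals:
        report["observed_removals"] = [
            removal_experiment(web_obs, par_obs, nd, **sim_kw)[0]
            for nd in range(web_obs.k) if not (plankton_cluster == nd)]
        report["null_removals"] = null_removals
    return report


def parameter_sweep(net: MultiplexNet, membership: Sequence[int],
                    grid: dict[str, Sequence[float]], n_random: int = 50,
                    seed: int | None = None, **kw):
    """Randomized-NTI comparison over a grid of global parameters.

    ``grid`` maps parameter names (``intpos``, ``intneg``, ``x0``, ``y``,
    or any other :meth:`DynParams.defaults` keyword) to value lists; the
    full Cartesian product is run with a reduced replicate count. Returns
    a tidy DataFrame with the biomass p-value and final richness per cell.
    """
    import itertools

    import pandas as pd

    names = list(grid)
    rows = []
    rng = np.random.default_rng(seed)
    for values in itertools.product(*(grid[nm] for nm in names)):
        params_kw = dict(zip(names, values))
        rep = compare_to_random_nti(net, membership, params_kw=params_kw,
                                    n_random=n_random,
                                    seed=int(rng.integers(2 ** 31)), **kw)
        row = dict(zip(names, values))
        row.update(p_biomass=rep["p_biomass"],
                   observed_biomass=rep["observed_biomass"],
                   observed_persistence=rep["observed_persistence"],
                   null_median_biomass=float(np.median(rep["null_biomass"])))
        rows.append(row)
    return pd.DataFrame(rows)
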