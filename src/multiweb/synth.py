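"""Synthetic fixtures: planted multiplex block models, group-consistent
trait tables and group-clustered cladograms.

Every generator is deterministic under a fixed seed and emits the same
in-memory objects (and, on request, the same file formats) the I/O layer
consumes, so the whole pipeline is testable without any download. The
``chile_like`` preset mirrors the scale of the Chilean rocky-intertidal
web: 106 species, 14 planted blocks and per-layer edge counts calibrated
to 1,362 trophic / 172 positive / 3,089 negative links.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .net import MultiplexNet

__all__ = [
    "planted_multiplex", "planted_traits", "planted_cladogram",
    "separable_theta", "chile_like", "write_fixture",
]


def _check_distributions(a: np.ndarray, theta: np.ndarray) -> None:
    if a.ndim != 1 or not np.isclose(a.sum(), 1.0) or (a < 0).any():
        raise ValueError("a must be a probability vector")
    Q = a.shape[0]
    if theta.shape != (Q, Q, 8):
        raise ValueError(f"theta must have shape {(Q, Q, 8)}")
    if (theta < 0).any() or not np.allclose(theta.sum(axis=2), 1.0):
        raise ValueError("each theta[q, l] must be a distribution over 8 outcomes")


def planted_multiplex(n: int, Q: int, a: Sequence[float], theta: np.ndarray,
                      seed: int | None = None,
                      membership: Sequence[int] | None = None
                      ) -> tuple[MultiplexNet, np.ndarray]:
    """Draw a 3-layer multiplex from a planted block model.

    Memberships come from the mixture ``a`` (or are supplied); each
    ordered pair's 3-bit outcome is drawn from its block pair's 8-cell
    distribution (little-endian bit order T, P, N). The diagonal stays
    empty. Returns the network and the true labels.
    """
    a = np.asarray(a, dtype=float)
    theta = np.asarray(theta, dtype=float)
    _check_distributions(a, theta)
    rng = np.random.default_rng(seed)
    if membership is None:
        z = rng.choice(Q, size=n, p=a)
    else:
        z = np.asarray(membership, dtype=int)
        if z.shape != (n,) or z.min() < 0 or z.max() >= Q:
            raise ValueError("membership must be length n with labels in [0, Q)")
    # cumulative-inverse draw of outcome codes for all ordered pairs at once
    cum = np.cumsum(theta[z[:, None], z[None, :], :], axis=2)
    u = rng.random((n, n))
    codes = (u[:, :, None] > cum).sum(axis=2)
    np.fill_diagonal(codes, 0)
    layers = [((codes >> bit) & 1).astype(np.int8) for bit in range(3)]
    ids = tuple(f"sp{i + 1:03d}" for i in range(n))
    return MultiplexNet(ids, *layers), z


def separable_theta(Q: int, p_in: float = 0.8, p_out: float = 0.05,
                    p_pos_in: float = 0.0, p_neg_in: float = 0.0,
                    p_pos_out: float = 0.0, p_neg_out: float = 0.0) -> np.ndarray:
    """Well-separated planted emission: within-block trophic probability
    ``p_in`` versus ``p_out`` elsewhere, with optional independent
    positive/negative layer probabilities; returns the (Q, Q, 8) joint."""
    theta = np.zeros((Q, Q, 8))
    for qq in range(Q):
        for ll in range(Q):
            pT = p_in if qq == ll else p_out
            pP = p_pos_in if qq == ll else p_pos_out
            pN = p_neg_in if qq == ll else p_neg_out
            for c in range(8):
                y1, y2, y3 = c & 1, (c >> 1) & 1, (c >> 2) & 1
                theta[qq, ll, c] = ((pT if y1 else 1 - pT)
                                    * (pP if y2 else 1 - pP)
                                    * (pN if y3 else 1 - pN))
    return theta


def planted_traits(group_of_species: Sequence[int], trait_rules: dict[int, dict],
                   noise_rate: float = 0.0, seed: int | None = None,
                   species_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Trait table whose profiles follow the group labels.

    ``trait_rules`` maps each group label to a dict with the five trait
    fields (e.g. producers: ``{"trophic_category": "autotroph",
    "mobility": "sessile", ...}``). A fraction ``noise_rate`` of species
    get each trait independently resampled from the pool of rule values,
    degrading the trait–group association toward chance.
    """
    labels = np.asarray(group_of_species, dtype=int)
    missing = sorted(set(labels.tolist()) - set(trait_rules))
    if missing:
        raise ValueError(f"trait_rules missing groups: {missing}")
    rng = np.random.default_rng(seed)
    n = labels.shape[0]
    if species_ids is None:
        species_ids = [f"sp{i + 1:03d}" for i in range(n)]
    cols = ("shore_height", "shore_breadth", "log_body_mass", "mobility",
            "trophic_category")
    pool = {c: [trait_rules[g][c] for g in trait_rules] for c in cols}
    rows = []
    noisy = rng.random(n) < noise_rate
    for i, g in enumerate(labels):
        row = {c: trait_rules[int(g)][c] for c in cols}
        if noisy[i]:
            for c in cols:
                row[c] = pool[c][rng.integers(len(pool[c]))]
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(species_ids, name="species_id"))
    # small jitter keeps continuous traits non-degenerate inside a group
    df["log_body_mass"] = df["log_body_mass"].astype(float) + rng.normal(0, 0.05, n)
    return df


def planted_cladogram(group_of_species: Sequence[int], within_depth: float = 0.1,
                      between_depth: float = 1.0, seed: int | None = None,
                      n_swaps: int = 0, species_ids: Sequence[str] | None = None):
    """Random cladogram whose clades follow the group labels.

    Each group becomes a clade of tips hanging at depth ``within_depth``
    under the group ancestor; ancestors attach to the root at
    ``between_depth``. With ``within_depth == between_depth`` the tree is
    a star and carries no group signal. ``n_swaps`` random tip-label swaps
    inject taxonomic incoherence. Returns a dendropy tree.
    """
    import dendropy

    labels = np.asarray(group_of_species, dtype=int)
    n = labels.shape[0]
    if species_ids is None:
        species_ids = [f"sp{i + 1:03d}" for i in range(n)]
    species_ids = list(species_ids)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    ids = species_ids.copy()
    for _ in range(n_swaps):
        i, j = rng.choice(n, size=2, replace=False)
        ids[i], ids[j] = ids[j], ids[i]
    stem = max(between_depth - within_depth, 0.0)
    clades = []
    for g in groups:
        tips = [f"{ids[i]}:{within_depth}" for i in np.where(labels == g)[0]]
        if len(tips) == 1:
            clades.append(f"{tips[0].split(':')[0]}:{between_depth}")
        else:
            clades.append(f"({','.join(tips)}):{stem}")
    newick = f"({','.join(clades)});"
    return dendropy.Tree.get(data=newick, schema="newick")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def facilitation_scenario(n_per_block: int = 8, seed: int = 0):
    """Synthetic web whose positive links are targeted where they matter.

    Five equal blocks: ``B`` — a producer consumed by ``C``; ``C`` — its
    consumer; ``F`` — an unconsumed, high-biomass facilitator producer;
    ``W`` — a consumer with no resources (it starves, so its outgoing
    facilitation is inert); ``S`` — an unconsumed producer that sits at
    carrying capacity, where extra recruitment changes nothing. Observed
    positive links pair the strong source with the high-leverage target
    (every F species facilitates every B species) and the inert source
    with the inert target (W onto S). A degree-preserving randomization
    mixes sources and targets, diluting the recruitment boost on B — the
    observed web should out-produce the null. A dense negative layer
    among F and S species (space competition between producers at
    equilibrium, dynamically inert) gives the null something to shuffle
    there too.

    Returns ``(net, membership, producer_flags)``; blocks are ordered
    B, C, F, W, S and producer flags mark B, F, S.
    """
    m = n_per_block
    n = 5 * m
    B_idx = np.arange(0, m)
    C_idx = np.arange(m, 2 * m)
    F_idx = np.arange(2 * m, 3 * m)
    W_idx = np.arange(3 * m, 4 * m)
    S_idx = np.arange(4 * m, 5 * m)
    T = np.zeros((n, n), dtype=np.int8)
    P = np.zeros((n, n), dtype=np.int8)
    N = np.zeros((n, n), dtype=np.int8)
    T[np.ix_(C_idx, B_idx)] = 1          # C eats B
    P[np.ix_(F_idx, B_idx)] = 1          # strong facilitation where it counts
    P[np.ix_(W_idx, S_idx)] = 1          # inert source onto inert target
    N[np.ix_(F_idx, S_idx)] = 1          # producer-producer space competition
    N[np.ix_(S_idx, F_idx)] = 1
    ids = tuple(f"sp{i + 1:03d}" for i in range(n))
    net = MultiplexNet(ids, T, P, N)
    membership = np.repeat(np.arange(5), m)
    producers = np.array([True, False, True, False, True])
    return net, membership, producers

def chile_like(seed: int = 0) -> tuple[MultiplexNet, np.ndarray, np.ndarray, np.ndarray]:
    """Chile-scale synthetic multiplex: n=106 species in 14 planted blocks.

    The emission is built so expected per-layer edge counts match the
    field web (1,362 trophic, 172 positive, 3,089 negative links): a
    block-structured trophic layer (some blocks are producers with no
    outgoing trophic links), positive links flowing from two
    "facilitator" blocks, and dense negative links among the sessile
    blocks. Returns (net, membership, a, theta).
    """
    n, Q = 106, 14
    rng = np.random.default_rng(seed)
    sizes = np.array([10, 4, 7, 6, 2, 5, 9, 3, 11, 8, 10, 12, 9, 10])
    assert sizes.sum() == n
    z = np.repeat(np.arange(Q), sizes)
    a = sizes / n

    producers = np.zeros(Q, dtype=bool)
    producers[[2, 5, 9, 10, 11]] = True        # sessile/basal blocks
    facilitators = np.zeros(Q, dtype=bool)
    facilitators[[4, 5]] = True

    pT = np.zeros((Q, Q))
    pP = np.zeros((Q, Q))
    pN = np.zeros((Q, Q))
    for qq in range(Q):
        for ll in range(Q):
            if not producers[qq]:
                # consumers eat producer blocks and some lower consumer blocks
                if producers[ll]:
                    pT[qq, ll] = 0.55 if (qq + ll) % 3 else 0.15
                elif ll < qq:
                    pT[qq, ll] = 0.18 if (qq - ll) % 4 == 1 else 0.02
            if facilitators[qq] and not producers[ll]:
                pP[qq, ll] = 0.08
            if producers[qq] and producers[ll]:
                pN[qq, ll] = 0.75
            elif producers[qq] != producers[ll]:
                pN[qq, ll] = 0.28
            elif qq != ll:
                pN[qq, ll] = 0.18
    # calibrate expected edge counts to the field web's layer sizes
    pairs = np.outer(sizes, sizes) - np.diag(sizes)
    for p, target in ((pT, 1362), (pP, 172), (pN, 3089)):
        expected = float((p * pairs).sum())
        p *= target / expected
        np.clip(p, 0.0, 0.97, out=p)

    theta = np.zeros((Q, Q, 8))
    for c in range(8):
        y1, y2, y3 = c & 1, (c >> 1) & 1, (c >> 2) & 1
        theta[:, :, c] = (np.where(y1, pT, 1 - pT)
                          * np.where(y2, pP, 1 - pP)
                          * np.where(y3, pN, 1 - pN))
    net, z = planted_multiplex(n, Q, a, theta, seed=int(rng.integers(2 ** 31)),
                               membership=z)
    return net, z, a, theta


def write_fixture(outdir: str | Path, net: MultiplexNet, membership: np.ndarray,
                  manifest: dict | None = None) -> None:
    """Write a generated network (edge list + species list + true labels)
    and a manifest JSON recording the generator settings."""
    from .net import write_multiplex

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_multiplex(net, outdir / "edges.tsv", outdir / "species.txt")
    rows = ["species_id,cluster"]
    rows += [f"{s},{int(z) + 1}" for s, z in zip(net.species_ids, membership)]
    (outdir / "true_partition.csv").write_text("\n".join(rows) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(manifest or {}, indent=2))
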