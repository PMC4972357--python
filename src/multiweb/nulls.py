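"""Degree-preserving random multiplexes and the pairwise overlap test.

The null model randomizes each layer independently with a Chung–Lu style
expected-degree construction: directed edge (i, j) appears with
probability ``d_i^out * d_j^in / m`` (capped at 1), which preserves each
species' expected in- and out-degree in that layer. Draws are rejected
until the realized edge count lands within a tolerance band around the
original count, so null replicates match the data in size as well as in
degree structure.

The pairwise test asks whether species pairs engage in fewer or more
simultaneous interaction types than these very constrained random
counterparts allow — the signature of interaction-type specificity.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .net import LAYER_CODES, MultiplexNet

__all__ = [
    "PairTypeCounts", "pair_type_counts", "chung_lu_layer",
    "randomize_multiplex", "pairwise_overlap_test", "OverlapTestReport",
]


@dataclasses.dataclass(frozen=True)
class PairTypeCounts:
    """Unordered distinct species pairs by number of interaction types.

    A type is "present" for a pair when at least one directed link of that
    type exists in either direction; self-pairs are excluded. The four
    counts always sum to ``n(n-1)/2``.
    """

    n0: int
    n1: int
    n2: int
    n3: int

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2 + self.n3

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n0, self.n1, self.n2, self.n3)


def pair_type_counts(net: MultiplexNet) -> PairTypeCounts:
    """Count pairs linked by exactly 0, 1, 2 and 3 interaction types."""
    iu = np.triu_indices(net.n, k=1)
    n_types = np.zeros(len(iu[0]), dtype=int)
    for m in net.layers.values():
        sym = (m | m.T).astype(bool)
        n_types += sym[iu]
    counts = np.bincount(n_types, minlength=4)
    return PairTypeCounts(*(int(c) for c in counts[:4]))


def chung_lu_layer(layer: np.ndarray, seed: int | None = None, tol: float = 0.025,
                   max_tries: int = 1000, rng: np.random.Generator | None = None
                   ) -> np.ndarray:
    """Expected-degree random copy of one directed layer.

    Edge (i, j), i != j, is drawn independently with probability
    ``min(1, d_i_out * d_j_in / m)``; draws are resampled until the edge
    count is within ``±tol*m`` of the original ``m``. The probability cap
    slightly biases hub degrees downward; self-edges are never generated.
    """
    layer = np.asarray(layer)
    m = int(layer.sum())
    if m < 1:
        raise ValueError("layer must contain at least one edge")
    if rng is None:
        rng = np.random.default_rng(seed)
    d_out = layer.sum(axis=1).astype(float)
    d_in = layer.sum(axis=0).astype(float)
    P = np.minimum(1.0, np.outer(d_out, d_in) / m)
    np.fill_diagonal(P, 0.0)
    lo, hi = m - tol * m, m + tol * m
    for _ in range(max_tries):
        draw = (rng.random(P.shape) < P).astype(np.int8)
        realized = int(draw.sum())
        if lo <= realized <= hi:
            return draw
    raise RuntimeError(
        f"no accepted draw in {max_tries} tries (band [{lo:.1f}, {hi:.1f}] around m={m})")


def randomize_multiplex(net: MultiplexNet, layers: Sequence[str] = LAYER_CODES,
                        seed: int | None = None, tol: float = 0.025,
                        rng: np.random.Generator | None = None) -> MultiplexNet:
    """Replace the listed layers by independent Chung–Lu draws; the other
    layers are copied verbatim. Original self-loops are dropped from
    randomized layers (the null never generates them)."""
    if not layers:
        raise ValueError("must randomize at least one layer")
    if rng is None:
        rng = np.random.default_rng(seed)
    new = {}
    for code in LAYER_CODES:
        # a layer with no edges has nothing to randomize; copy it verbatim
        if code in layers and net.layer(code).sum() > 0:
            new[code] = chung_lu_layer(net.layer(code), tol=tol, rng=rng)
        else:
            new[code] = net.layer(code).copy()
    return MultiplexNet(net.species_ids, new["T"], new["P"], new["N"])


@dataclasses.dataclass
class OverlapTestReport:
    """Observed pair-type counts against the random-multiplex ensemble."""

    observed: PairTypeCounts
    n_reps: int
    seed: int | None
    null_counts: np.ndarray  # (n_reps, 4)
    statistics: dict[str, dict]

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "seed": self.seed,
            "observed": dict(zip(("n0", "n1", "n2", "n3"), self.observed.as_tuple())),
            "statistics": self.statistics,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def __str__(self) -> str:
        lines = [f"Pairwise interaction-type overlap test ({self.n_reps} random multiplexes)"]
        for key, st in self.statistics.items():
            lines.append(
                f"  {key}: observed {st['observed']}  null range "
                f"{st['null_min']}-{st['null_max']}  p {st['p_str']} ({st['direction']})")
        return "\n".join(lines)


def pairwise_overlap_test(net: MultiplexNet, n_reps: int = 10000,
                          seed: int | None = None, tol: float = 0.025,
                          plus_one: bool = False) -> OverlapTestReport:
    """Test pair-type counts against fully randomized multiplexes.

    All three layers are randomized in every replicate. For each of the
    one-/two-/three-type counts the report gives the observed value, the
    null min–max range and a one-sided empirical p in the direction of
    deviation, computed as the plain proportion of replicates at least as
    extreme (reported as ``< 1/n_reps`` when no replicate reaches the
    observed value). ``plus_one=True`` switches to the (r+1)/(n+1)
    correction.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    observed = pair_type_counts(net)
    null = np.empty((n_reps, 4), dtype=int)
    for r in range(n_reps):
        rnet = randomize_multiplex(net, LAYER_CODES, tol=tol, rng=rng)
        null[r] = pair_type_counts(rnet).as_tuple()

    stats: dict[str, dict] = {}
    for k, key in enumerate(("n0", "n1", "n2", "n3")):
        obs = observed.as_tuple()[k]
        col = null[:, k]
        med = float(np.median(col))
        direction = "high" if obs >= med else "low"
        if direction == "high":
            extreme = int((col >= obs).sum())
        else:
            extreme = int((col <= obs).sum())
        if plus_one:
            p = (extreme + 1) / (n_reps + 1)
            p_str = f"{p:.6g}"
        else:
            p = extreme / n_reps
            p_str = f"< {1.0 / n_reps:g}" if extreme == 0 else f"{p:.6g}"
        stats[key] = {
            "observed": int(obs),
            "null_min": int(col.min()),
            "null_max": int(col.max()),
            "null_median": med,
            "p": p,
            "p_str": p_str,
            "direction": direction,
        }
    return OverlapTestReport(observed, n_reps, seed, null, stats)
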