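"""Functional groups: Ward aggregation of clusters, trait prediction and
taxonomic coherence.

Clusters whose block-level connectivity parameters are similar — across
all three layers, in and out — collapse into "multiplex functional
groups". Groups are then (i) predicted from simple species traits with a
classification tree and (ii) tested for taxonomic coherence by comparing
within-group patristic distances against label permutations.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .net import MOBILITY_LEVELS, TRAIT_COLUMNS, TROPHIC_LEVELS, patristic_distance_matrix
from .sbm import SBMResults

__all__ = [
    "cluster_param_vector", "ward_groups", "FunctionalGroups",
    "trait_tree", "TraitTreeResult", "taxonomy_test",
]


def cluster_param_vector(res: SBMResults, q: int) -> np.ndarray:
    """Connectivity profile of cluster ``q``: its emission distributions
    toward every cluster (rows ``theta[q, .]``) concatenated with those
    from every cluster (columns ``theta[., q]``); length ``2*Q*K``."""
    if not 0 <= q < res.Q:
        raise IndexError(f"cluster {q} out of range")
    return np.concatenate([res.theta[q, :, :].ravel(), res.theta[:, q, :].ravel()])


@dataclasses.dataclass
class FunctionalGroups:
    """Ward merge tree over clusters plus a chosen cut.

    ``cluster_group[q]`` is the 0-based group of cluster ``q``;
    ``species_group`` maps every species to its cluster's group.
    """

    linkage_matrix: np.ndarray
    cluster_group: np.ndarray
    membership: np.ndarray          # species -> cluster
    species_ids: tuple[str, ...]

    @property
    def n_groups(self) -> int:
        return int(self.cluster_group.max()) + 1

    @property
    def species_group(self) -> np.ndarray:
        return self.cluster_group[self.membership]

    def groups_of_clusters(self) -> list[list[int]]:
        """Cluster ids (1-based, field convention) per group."""
        return [sorted(np.where(self.cluster_group == g)[0] + 1)
                for g in range(self.n_groups)]

    def to_csv(self, path: str | Path) -> None:
        rows = ["species_id,cluster,group"]
        for s, z in zip(self.species_ids, self.membership):
            rows.append(f"{s},{z + 1},{self.cluster_group[z] + 1}")
        Path(path).write_text("\n".join(rows) + "\n")

    def merge_tree_newick(self) -> str:
        """Dendrogram over clusters as a Newick string (cluster ids 1-based)."""
        Q = len(self.cluster_group)
        nodes = {i: f"C{i + 1}" for i in range(Q)}
        for step, (a, b, height, _) in enumerate(self.linkage_matrix):
            nodes[Q + step] = f"({nodes[int(a)]},{nodes[int(b)]}):{height:.4f}"
        last = Q + len(self.linkage_matrix) - 1
        return f"{nodes[last]};" if len(self.linkage_matrix) else f"({nodes[0]});"


def ward_groups(res: SBMResults, n_groups: int) -> FunctionalGroups:
    """Ward agglomeration of clusters on their connectivity profiles.

    Builds the Euclidean distance matrix between
    :func:`cluster_param_vector` profiles, merges by Ward's criterion and
    cuts the tree at ``n_groups``. The full merge tree is kept on the
    result so the cut level can be chosen by inspection.
    """
    if not 1 <= n_groups <= res.Q:
        raise ValueError(f"n_groups must be in [1, {res.Q}]")
    profiles = np.vstack([cluster_param_vector(res, q) for q in range(res.Q)])
    if res.Q == 1:
        return FunctionalGroups(np.empty((0, 4)), np.zeros(1, dtype=int),
                                res.membership, res.species_ids)
    Z = linkage(pdist(profiles, metric="euclidean"), method="ward")
    labels = fcluster(Z, t=n_groups, criterion="maxclust") - 1
    # relabel groups by order of first appearance for determinism
    order, seen = {}, 0
    for lb in labels:
        if lb not in order:
            order[lb] = seen
            seen += 1
    labels = np.array([order[lb] for lb in labels])
    return FunctionalGroups(Z, labels, res.membership, res.species_ids)


# ---------------------------------------------------------------------------
# trait prediction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TraitTreeResult:
    """Fitted classification tree, its deviance-based pseudo-R² and the
    per-leaf group composition."""

    tree: object
    pseudo_r2: float
    feature_names: list[str]
    leaf_table: pd.DataFrame

    def report(self) -> str:
        from sklearn.tree import export_text

        txt = export_text(self.tree, feature_names=self.feature_names)
        return f"pseudo-R2 = {self.pseudo_r2:.3f}\n{txt}"

    def to_json(self, path: str | Path) -> None:
        doc = {"pseudo_r2": self.pseudo_r2,
               "features": self.feature_names,
               "leaves": self.leaf_table.to_dict(orient="records")}
        Path(path).write_text(json.dumps(doc, indent=2))


def _multinomial_deviance(counts: np.ndarray) -> float:
    """-2 log-likelihood of the saturated-null multinomial for one node."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-2.0 * np.sum(counts[counts > 0] * np.log(p)))


def encode_traits(traits: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix from the trait table (ordinal scores kept as
    numbers, mobility and trophic category as integer codes)."""
    X = np.column_stack([
        traits["shore_height"].to_numpy(dtype=float),
        traits["shore_breadth"].to_numpy(dtype=float),
        traits["log_body_mass"].to_numpy(dtype=float),
        traits["mobility"].map({m: i for i, m in enumerate(MOBILITY_LEVELS)}).to_numpy(dtype=float),
        traits["trophic_category"].map({t: i for i, t in enumerate(TROPHIC_LEVELS)}).to_numpy(dtype=float),
    ])
    return X, list(TRAIT_COLUMNS)


def trait_tree(traits: pd.DataFrame, groups: FunctionalGroups,
               min_leaf: int = 5, max_depth: int | None = None,
               seed: int = 0) -> TraitTreeResult:
    """Predict functional-group membership from species traits.

    Fits a CART classification tree (splits chosen by maximal impurity
    decrease) on the five predictors and reports a deviance-based
    pseudo-R² = 1 - deviance(tree) / deviance(root), the natural analogue
    of R² for a categorical response. Missing traits are a hard error.
    """
    from sklearn.tree import DecisionTreeClassifier

    ids = list(groups.species_ids)
    missing = [s for s in ids if s not in traits.index]
    if missing:
        raise ValueError(f"traits missing for species: {missing}")
    sub = traits.loc[ids]
    if sub[list(TRAIT_COLUMNS)].isna().any().any():
        bad = sub.index[sub[list(TRAIT_COLUMNS)].isna().any(axis=1)].tolist()
        raise ValueError(f"missing trait values for species: {bad}")
    X, feat = encode_traits(sub)
    y = groups.species_group

    n_groups = len(np.unique(y))
    if n_groups == 1:
        leaf = pd.DataFrame({"leaf": [0], "count": [len(y)],
                             "majority_group": [int(y[0]) + 1]})
        return TraitTreeResult(None, 0.0, feat, leaf)

    clf = DecisionTreeClassifier(min_samples_leaf=min_leaf, max_depth=max_depth,
                                 random_state=seed)
    clf.fit(X, y)
    leaf_id = clf.apply(X)
    root_dev = _multinomial_deviance(np.bincount(y))
    tree_dev = 0.0
    rows = []
    for leaf in np.unique(leaf_id):
        counts = np.bincount(y[leaf_id == leaf], minlength=y.max() + 1)
        tree_dev += _multinomial_deviance(counts)
        rows.append({"leaf": int(leaf), "count": int(counts.sum()),
                     "majority_group": int(np.argmax(counts)) + 1,
                     "composition": counts.tolist()})
    r2 = 1.0 - tree_dev / root_dev if root_dev > 0 else 0.0
    return TraitTreeResult(clf, float(r2), feat, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def _mean_within_group(D: np.ndarray, labels: np.ndarray,
                       n_groups: int) -> tuple[float, np.ndarray]:
    """Overall and per-group mean within-group patristic distance; groups
    of size < 2 get NaN."""
    per_group = np.full(n_groups, np.nan)
    num_all = den_all = 0.0
    for g in range(n_groups):
        idx = np.where(labels == g)[0]
        if idx.size < 2:
            continue
        sub = D[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        per_group[g] = float(sub[iu].mean())
        num_all += sub[iu].sum()
        den_all += iu[0].size
    overall = num_all / den_all if den_all else np.nan
    return overall, per_group


def taxonomy_test(tree, groups: FunctionalGroups, n_perm: int = 100000,
                  seed: int | None = None) -> dict:
    """Permutation test for taxonomic coherence of the functional groups.

    The statistic is the mean patristic distance between species of the
    same group (overall, and per group); the null permutes group labels
    across species. The p-value is the proportion of permutations with a
    statistic at most the observed one — small p means groups gather
    closely related species. Singleton groups are skipped with a note.
    """
    labels = groups.species_group
    ids = list(groups.species_ids)
    D = patristic_distance_matrix(tree, ids)
    n_groups = groups.n_groups
    obs_all, obs_per = _mean_within_group(D, labels, n_groups)

    rng = np.random.default_rng(seed)
    count_all = 0
    count_per = np.zeros(n_groups)
    valid_per = ~np.isnan(obs_per)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        stat_all, stat_per = _mean_within_group(D, perm, n_groups)
        if stat_all <= obs_all + 1e-12:
            count_all += 1
        hit = valid_per & (stat_per <= obs_per + 1e-12)
        count_per[hit] += 1

    def fmt(count: int) -> tuple[float, str]:
        p = count / n_perm
        return (p, f"< {1.0 / n_perm:g}") if count == 0 else (p, f"{p:.6g}")

    p_all, p_all_str = fmt(count_all)
    per = {}
    for g in range(n_groups):
        if not valid_per[g]:
            per[g + 1] = {"note": "singleton group, statistic undefined"}
            continue
        p, p_str = fmt(int(count_per[g]))
        per[g + 1] = {"statistic": float(obs_per[g]), "p": p, "p_str": p_str}
    return {
        "statistic": float(obs_all),
        "p": p_all,
        "p_str": p_all_str,
        "per_group": per,
        "n_perm": n_perm,
        "seed": seed,
    }
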