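"""Species-level multiplex networks and their file I/O.

A multiplex ecological network holds three directed binary interaction
layers over a single species set: trophic (``T``), positive non-trophic
(``P``, e.g. refuge provisioning, recruitment facilitation) and negative
non-trophic (``N``, e.g. competition for space, predator interference).
The trophic convention is ``layer_T[i, j] = 1`` iff species ``i`` consumes
species ``j``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LAYER_CODES = ("T", "P", "N")

#: header line required at the top of edge-list files; documents the
#: direction convention (source consumes / affects target).
EDGE_LIST_HEADER = ("source", "target", "layer")


@dataclasses.dataclass
class MultiplexNet:
    """Three directed binary interaction layers over one species set.

    Parameters
    ----------
    species_ids
        Ordered unique species labels; defines the row/column ordering of
        all three layers.
    layer_T, layer_P, layer_N
        ``(n, n)`` binary int arrays. ``layer_T[i, j] = 1`` means species
        ``i`` consumes species ``j``; the non-trophic layers read
        "``i`` has an effect on ``j``".
    """

    species_ids: tuple[str, ...]
    layer_T: np.ndarray
    layer_P: np.ndarray
    layer_N: np.ndarray

    def __post_init__(self) -> None:
        self.species_ids = tuple(str(s) for s in self.species_ids)
        if len(self.species_ids) == 0:
            raise ValueError("species_ids must be non-empty")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("species_ids must be unique")
        n = len(self.species_ids)
        for name in ("layer_T", "layer_P", "layer_N"):
            layer = np.asarray(getattr(self, name), dtype=np.int8)
            if layer.shape != (n, n):
                raise ValueError(f"{name} must have shape {(n, n)}, got {layer.shape}")
            if not np.isin(layer, (0, 1)).all():
                raise ValueError(f"{name} entries must be 0/1")
            setattr(self, name, layer)

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of species."""
        return len(self.species_ids)

    @property
    def layers(self) -> dict[str, np.ndarray]:
        return {"T": self.layer_T, "P": self.layer_P, "N": self.layer_N}

    def layer(self, code: str) -> np.ndarray:
        try:
            return self.layers[code]
        except KeyError:
            raise KeyError(f"unknown layer code {code!r}; expected one of {LAYER_CODES}")

    def index_of(self, species: str) -> int:
        return self.species_ids.index(species)

    def edge_counts(self) -> dict[str, int]:
        """Directed edge count per layer."""
        return {c: int(m.sum()) for c, m in self.layers.items()}

    def subnet(self, keep: Sequence[int]) -> "MultiplexNet":
        """Induced sub-network on species positions ``keep`` (order kept)."""
        keep = np.asarray(keep, dtype=int)
        ids = tuple(self.species_ids[i] for i in keep)
        sub = {c: m[np.ix_(keep, keep)] for c, m in self.layers.items()}
        return MultiplexNet(ids, sub["T"], sub["P"], sub["N"])

    def replace_layers(self, **layers: np.ndarray) -> "MultiplexNet":
        """Copy of the network with some layers substituted."""
        mats = dict(self.layers)
        for code, m in layers.items():
            if code not in mats:
                raise KeyError(f"unknown layer code {code!r}")
            mats[code] = m
        return MultiplexNet(self.species_ids, mats["T"], mats["P"], mats["N"])

    def edges(self) -> Iterable[tuple[str, str, str]]:
        """Yield (source, target, layer) triples, layer order T, P, N."""
        for code in LAYER_CODES:
            src, tgt = np.nonzero(self.layer(code))
            for i, j in zip(src.tolist(), tgt.tolist()):
                yield self.species_ids[i], self.species_ids[j], code


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_species_list(path: str | Path) -> tuple[str, ...]:
    """One species id per line; blank lines ignored."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return tuple(ln for ln in lines if ln)


def read_multiplex(edge_list_path: str | Path, species_list_path: str | Path) -> MultiplexNet:
    """Read a multiplex network from an edge-list TSV plus a species list.

    The TSV must carry the header ``source<TAB>target<TAB>layer`` (the header
    documents the direction convention: source consumes / affects target)
    with ``layer`` in ``{T, P, N}``. The species list enumerates every node,
    so species with no interactions are representable. Duplicate edge rows
    collapse to a single link.
    """
    species = read_species_list(species_list_path)
    index = {s: i for i, s in enumerate(species)}
    n = len(species)
    mats = {c: np.zeros((n, n), dtype=np.int8) for c in LAYER_CODES}

    lines = Path(edge_list_path).read_text().splitlines()
    if not lines or tuple(lines[0].rstrip("\n").split("\t")) != EDGE_LIST_HEADER:
        raise ValueError(
            "edge list must start with the header 'source\\ttarget\\tlayer' "
            "(source consumes / affects target)"
        )
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}")
        src, tgt, code = (p.strip() for p in parts)
        if code not in LAYER_CODES:
            raise ValueError(f"line {lineno}: unknown layer code {code!r}")
        for label in (src, tgt):
            if label not in index:
                raise ValueError(f"line {lineno}: species {label!r} not in species list")
        mats[code][index[src], index[tgt]] = 1
    return MultiplexNet(species, mats["T"], mats["P"], mats["N"])


def write_multiplex(net: MultiplexNet, edge_list_path: str | Path,
                    species_list_path: str | Path | None = None) -> None:
    """Write a network back to edge-list TSV (and optionally a species list)."""
    rows = ["\t".join(EDGE_LIST_HEADER)]
    rows += ["\t".join(edge) for edge in net.edges()]
    Path(edge_list_path).write_text("\n".join(rows) + "\n")
    if species_list_path is not None:
        Path(species_list_path).write_text("\n".join(net.species_ids) + "\n")


def read_multiplex_adjacency(path_T: str | Path, path_P: str | Path,
                             path_N: str | Path) -> MultiplexNet:
    """Read one adjacency CSV per layer (species ids as header row/column).

    All three files must present identical species in identical order; this
    dialect produces the same object as :func:`read_multiplex` on the
    corresponding edge list.
    """
    frames = [pd.read_csv(p, index_col=0) for p in (path_T, path_P, path_N)]
    ids = tuple(str(s) for s in frames[0].index)
    for name, df in zip(("T", "P", "N"), frames):
        if tuple(str(s) for s in df.index) != ids or tuple(str(c) for c in df.columns) != ids:
            raise ValueError(f"layer {name}: species ids/order differ between files or rows vs columns")
    mats = [df.to_numpy() for df in frames]
    return MultiplexNet(ids, *mats)


def write_multiplex_adjacency(net: MultiplexNet, path_T: str | Path,
                              path_P: str | Path, path_N: str | Path) -> None:
    for path, code in zip((path_T, path_P, path_N), LAYER_CODES):
        pd.DataFrame(net.layer(code), index=net.species_ids,
                     columns=net.species_ids).to_csv(path)


TRAIT_COLUMNS = ("shore_height", "shore_breadth", "log_body_mass", "mobility",
                 "trophic_category")
MOBILITY_LEVELS = ("mobile", "sessile")
TROPHIC_LEVELS = ("autotroph", "herbivore", "intermediate", "top")


def read_traits(path: str | Path) -> pd.DataFrame:
    """Species trait table: ordinal shore scores, log body mass, mobility and
    trophic category; indexed by species id."""
    df = pd.read_csv(path, index_col=0)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    df.index = df.index.astype(str)
    for col in ("shore_height", "shore_breadth", "log_body_mass"):
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise ValueError(f"non-finite values in trait column {col!r}")
    return df


def read_cladogram(path: str | Path):
    """Load a rooted Newick cladogram (dendropy tree); unit branch lengths
    are substituted where lengths are missing."""
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is None and edge.head_node.parent_node is not None:
            edge.length = 1.0
    return tree


def patristic_distance_matrix(tree, species_ids: Sequence[str]) -> np.ndarray:
    """Symmetric matrix of path-length (patristic) distances between tips.

    Raises if any requested species is absent from the tree.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in species_ids if s not in taxa]
    if missing:
        raise ValueError(f"species absent from cladogram: {missing}")
    n = len(species_ids)
    D = np.zeros((n, n))
    for i, si in enumerate(species_ids):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[si], taxa[species_ids[j]])
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# interaction vectors and their distance
# ---------------------------------------------------------------------------

def interaction_vectors(net: MultiplexNet) -> np.ndarray:
    """Per-species 3D interaction vectors.

    Row ``i`` is the concatenation of species ``i``'s out-row and in-column
    in each layer, order T, P, N — shape ``(n, 6n)``. Summed over species,
    every directed edge contributes exactly two ones (one out-bit, one
    in-bit).
    """
    cols = []
    for code in LAYER_CODES:
        m = net.layer(code)
        cols.append(m)       # out-row
        cols.append(m.T)     # in-column
    return np.concatenate(cols, axis=1)


def rogers_tanimoto(u: np.ndarray, v: np.ndarray) -> float:
    """Rogers–Tanimoto dissimilarity between two binary vectors.

    ``d = 2m / (s + 2m)`` with ``m`` mismatching and ``s`` matching
    positions; 0 iff identical, 1 for fully complementary vectors.
    """
    u = np.asarray(u).ravel()
    v = np.asarray(v).ravel()
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    m = int(np.count_nonzero(u != v))
    if m == 0:
        return 0.0
    s = u.size - m
    return 2.0 * m / (s + 2.0 * m)


def rogers_tanimoto_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise Rogers–Tanimoto distance matrix for binary row-vectors."""
    from scipy.spatial.distance import pdist, squareform

    X = np.asarray(vectors, dtype=bool)
    return squareform(pdist(X, metric="rogerstanimoto"))
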