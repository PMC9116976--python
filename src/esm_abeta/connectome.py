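"""Anatomical connectivity matrices and degree/strength-preserving null models.

The connectome is the substrate of the epidemic spreading model: a weighted,
symmetric, zero-diagonal matrix of anatomical connection probabilities between
grey-matter regions (78 DKT regions in the default atlas).  Null connectomes
are produced by Maslov-Sneppen double-edge swaps on the binary topology
followed by re-assignment of the original edge weights ranked by the product
of the endpoints' original strengths, so that each null matrix keeps the exact
binary degree sequence and edge-weight multiset while closely tracking the
original strength distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "NullEnsemble",
    "load_connectivity",
    "normalize_rows",
    "rewire_null",
    "build_null_ensemble",
    "bilateral_pairs",
]

_ASYMMETRY_TOL = 1e-6


@dataclass
class ConnectivityMatrix:
    """Weighted region-by-region anatomical connection probabilities.

    Parameters
    ----------
    weights
        Nonnegative ``(n, n)`` matrix; symmetric with zero diagonal unless
        ``normalized`` is set (row-normalized matrices are allowed to be
        asymmetric).
    region_labels
        Ordered region names.  Hemisphere is encoded as an ``L_``/``R_``
        prefix; labels without one are treated as ``bilateral-na``.
    atlas_name
        Free-text atlas identifier.
    normalized
        True for row-normalized (transition-like) matrices.
    rewire_warning
        Set by :func:`rewire_null` when the graph admitted no swaps.
    """

    weights: np.ndarray
    region_labels: list[str]
    atlas_name: str = "custom"
    normalized: bool = False
    rewire_warning: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 2:
            raise ValueError("connectivity matrix needs at least 2 regions")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if np.any(w < 0):
            raise ValueError("connectivity matrix contains negative weights")
        if len(self.region_labels) != n:
            raise ValueError(
                f"{len(self.region_labels)} labels for {n}x{n} matrix"
            )
        if len(set(self.region_labels)) != n:
            raise ValueError("region labels must be unique")
        if not self.normalized:
            if np.any(np.abs(np.diag(w)) > 0):
                raise ValueError("connectivity matrix must have a zero diagonal")
            if np.max(np.abs(w - w.T)) > 1e-12:
                raise ValueError("connectivity matrix is not symmetric")
        self.weights = w
        self.region_labels = list(self.region_labels)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def hemispheres(self) -> list[str]:
        """Per-region hemisphere tag: ``L``, ``R`` or ``bilateral-na``."""
        tags = []
        for lab in self.region_labels:
            head = lab.split("_", 1)[0].upper()
            tags.append(head if head in ("L", "R") else "bilateral-na")
        return tags

    def index_of(self, label: str) -> int:
        return self.region_labels.index(label)

    def strengths(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)


@dataclass
class NullEnsemble:
    """Collection of rewired connectomes sharing the source's degree sequence
    and edge-weight multiset."""

    matrices: list[ConnectivityMatrix]
    seeds: list[int]
    source: ConnectivityMatrix = field(repr=False)

    @property
    def n_null(self) -> int:
        return len(self.matrices)


def bilateral_pairs(region_labels: list[str]) -> dict[str, tuple[int, int]]:
    """Map base region name -> (left index, right index) for mirrored labels.

    Only regions present in both hemispheres are returned; label matching is
    case-insensitive on the base name after stripping the hemisphere prefix.
    """
    left: dict[str, int] = {}
    right: dict[str, int] = {}
    for i, lab in enumerate(region_labels):
        head, _, base = lab.partition("_")
        if head.upper() == "L":
            left[base.lower()] = i
        elif head.upper() == "R":
            right[base.lower()] = i
    return {b: (left[b], right[b]) for b in left if b in right}


def load_connectivity(
    path: str,
    labels_path: str | None = None,
    atlas_name: str = "custom",
) -> ConnectivityMatrix:
    """Read a dense CSV/TSV connectivity matrix, validating and symmetrizing.

    The file may carry a single header row of region labels.  Asymmetries up
    to 1e-6 (file-rounding artefacts) are averaged away; larger ones raise.
    A separate ``labels_path`` (one label per line) overrides any header.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    probe = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = probe.iloc[0].apply(
        lambda v: isinstance(v, str) and not _is_number(v)
    ).any()
    if has_header:
        df = pd.read_csv(path, sep=sep)
        labels = [str(c) for c in df.columns]
        w = df.to_numpy(dtype=float)
    else:
        df = pd.read_csv(path, sep=sep, header=None)
        w = df.to_numpy(dtype=float)
        labels = [f"region_{i:02d}" for i in range(w.shape[0])]
    if labels_path is not None:
        with open(labels_path) as fh:
            labels = [ln.strip() for ln in fh if ln.strip()]
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"input matrix is not square: shape {w.shape}")
    if np.any(~np.isfinite(w)):
        raise ValueError("input matrix contains NaN or infinite entries")
    asym = np.max(np.abs(w - w.T))
    if asym > _ASYMMETRY_TOL:
        raise ValueError(
            f"matrix asymmetry {asym:.3g} exceeds tolerance {_ASYMMETRY_TOL:g}"
        )
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, labels, atlas_name=atlas_name)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def normalize_rows(C: ConnectivityMatrix) -> ConnectivityMatrix:
    """Scale each nonzero row to sum to 1 (zero rows stay zero).

    The result is flagged ``normalized`` and may be asymmetric; it is the
    per-region distribution of incoming transmission weights used inside the
    spreading ODE.  Idempotent.
    """
    w = C.weights.copy()
    sums = w.sum(axis=1)
    nz = sums > 0
    w[nz] = w[nz] / sums[nz, None]
    return ConnectivityMatrix(
        w, C.region_labels, atlas_name=C.atlas_name, normalized=True
    )


def rewire_null(
    C: ConnectivityMatrix,
    seed: int,
    n_swaps_per_edge: int = 10,
) -> ConnectivityMatrix:
    """Degree- and strength-preserving rewiring of a weighted connectome.

    Binary topology is scrambled with Maslov-Sneppen double-edge swaps
    (``n_swaps_per_edge`` accepted swaps per edge); the original weights are
    then placed on the new edges in rank order of the product of the
    endpoints' original strengths, which preserves the weight multiset exactly
    and the strength distribution approximately.  Deterministic given
    ``seed``.
    """
    if C.normalized:
        raise ValueError("rewire_null expects an unnormalized symmetric matrix")
    w = C.weights
    iu, ju = np.nonzero(np.triu(w, k=1))
    m = iu.size
    if m < 2:
        out = replace(C, weights=w.copy())
        out.rewire_warning = True
        warnings.warn("graph has fewer than 2 edges; returning an unrewired copy")
        return out
    G = nx.Graph()
    G.add_nodes_from(range(C.n_regions))
    G.add_edges_from(zip(iu.tolist(), ju.tolist()))
    try:
        nx.double_edge_swap(
            G, nswap=n_swaps_per_edge * m, max_tries=100 * n_swaps_per_edge * m,
            seed=int(seed),
        )
    except nx.NetworkXAlgorithmError:
        # dense or constrained graphs may exhaust tries; partial swaps are fine
        pass
    except nx.NetworkXError:
        out = replace(C, weights=w.copy())
        out.rewire_warning = True
        warnings.warn("graph cannot be rewired; returning an unrewired copy")
        return out
    edges = np.array(sorted(tuple(sorted(e)) for e in G.edges()), dtype=int)
    strengths = w.sum(axis=1)
    rank_score = strengths[edges[:, 0]] * strengths[edges[:, 1]]
    order = np.argsort(-rank_score, kind="stable")
    weights_sorted = np.sort(w[iu, ju])[::-1]
    new = np.zeros_like(w)
    ei, ej = edges[order, 0], edges[order, 1]
    new[ei, ej] = weights_sorted
    new[ej, ei] = weights_sorted
    return ConnectivityMatrix(
        new, C.region_labels, atlas_name=C.atlas_name
    )


def build_null_ensemble(
    C: ConnectivityMatrix,
    n_null: int = 100,
    base_seed: int = 0,
    n_swaps_per_edge: int = 10,
) -> NullEnsemble:
    """Build ``n_null`` rewired matrices with seeds ``base_seed .. base_seed+n_null-1``."""
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    seeds = [int(base_seed) + k for k in range(n_null)]
    mats = [rewire_null(C, seed=s, n_swaps_per_edge=n_swaps_per_edge) for s in seeds]
    return NullEnsemble(matrices=mats, seeds=seeds, source=C)
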