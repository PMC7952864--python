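"""Spectral parameterization of a tract volume.

A probabilistic-tractography density map, thresholded at a fraction of
its maximum, yields a voxel set describing the tract.  The voxels are
connected into a neighborhood graph; the Fiedler vector — the
eigenvector of the combinatorial graph Laplacian L = D - A belonging to
the smallest non-zero eigenvalue — varies smoothly and monotonically
along the dominant elongated direction of the shape and serves as the
along-tract coordinate t.  After anatomical orientation (t = 0 at the
frontal end) and min-max normalization, t in [0, 1] is cut into K
equal-width segments.

``TractModel(density).fit()`` runs the whole chain and returns a
:class:`TractParameterization` results object; the individual steps are
also exposed as functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from .volume import ScalarVolume

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelGraph",
    "TractModel",
    "TractParameterization",
    "threshold_density",
    "restrict_core",
    "build_voxel_graph",
    "largest_component",
    "fiedler_vector",
    "orient_and_normalize",
    "segment_labels",
]

def _half_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    if connectivity not in (6, 18, 26):
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                # keep one of each +/- pair
                if (dx, dy, dz) > (0, 0, 0):
                    offs.append((dx, dy, dz))
    return offs


def threshold_density(density: ScalarVolume, fraction: float = 0.10) -> ScalarVolume:
    """Binary mask of voxels with density >= fraction * global maximum.

    The 10%-of-maximum threshold is the usual guard against sparse
    false-positive streamline visitations at the fringe of a
    probabilistic tracking result.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    d = np.asarray(density.data, dtype=float)
    if np.any(d < 0):
        raise ValueError("density map must be non-negative")
    dmax = d.max()
    if dmax == 0:
        raise ValueError("empty tract: density map is all zero")
    return ScalarVolume((d >= fraction * dmax).astype(np.uint8), density.affine)


def restrict_core(
    mask: ScalarVolume,
    y_max: float | None = None,
    z_min: float | None = None,
    units: str = "mm",
) -> ScalarVolume:
    """Restrict a tract mask to its compact white-matter core.

    Removes anterior frontal branching (coordinate y > ``y_max``) and
    inferior temporal branching (z < ``z_min``).  ``units='mm'``
    interprets the limits in the volume's world frame via the affine;
    ``units='voxel'`` compares raw voxel indices.  Either limit may be
    None (no restriction on that side).
    """
    if units not in ("mm", "voxel"):
        raise ValueError(f"units must be 'mm' or 'voxel', got {units}")
    m = mask.data.astype(bool)
    idx = np.argwhere(m)
    if idx.size == 0:
        raise ValueError("mask is empty before core restriction")
    if units == "mm":
        coords = mask.voxel_to_mm(idx)
    else:
        coords = idx.astype(float)
    keep = np.ones(len(idx), dtype=bool)
    if y_max is not None:
        keep &= coords[:, 1] <= y_max
    if z_min is not None:
        keep &= coords[:, 2] >= z_min
    if not keep.any():
        raise ValueError(
            f"core restriction (y_max={y_max}, z_min={z_min}, {units}) removed every voxel"
        )
    out = np.zeros(mask.shape, dtype=np.uint8)
    kept = idx[keep]
    out[kept[:, 0], kept[:, 1], kept[:, 2]] = 1
    return ScalarVolume(out, mask.affine)


@dataclass
class VoxelGraph:
    """Adjacency graph over the in-mask voxels of a 3-D grid."""

    nodes: np.ndarray          # (n, 3) voxel indices
    adjacency: sp.csr_matrix   # symmetric, no self-edges
    shape: tuple[int, int, int]
    connectivity: int
    component_labels: np.ndarray
    n_components: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2


def build_voxel_graph(mask: ScalarVolume, connectivity: int = 26) -> VoxelGraph:
    """Connect in-mask voxels whose index offsets lie in the chosen neighborhood."""
    m = np.asarray(mask.data).astype(bool)
    nodes = np.argwhere(m)
    if len(nodes) == 0:
        raise ValueError("mask is empty")
    node_id = -np.ones(m.shape, dtype=np.int64)
    node_id[m] = np.arange(len(nodes))
    rows, cols = [], []
    for off in _half_offsets(connectivity):
        shifted = nodes + np.asarray(off)
        ok = np.all((shifted >= 0) & (shifted < np.asarray(m.shape)), axis=1)
        j = node_id[shifted[ok, 0], shifted[ok, 1], shifted[ok, 2]]
        present = j >= 0
        i = np.flatnonzero(ok)[present]
        rows.append(i)
        cols.append(j[present])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.empty(0, dtype=np.int64)
    n = len(nodes)
    adj = sp.coo_matrix(
        (np.ones(2 * len(r)), (np.concatenate([r, c]), np.concatenate([c, r]))),
        shape=(n, n),
    ).tocsr()
    n_comp, labels = connected_components(adj, directed=False)
    return VoxelGraph(
        nodes=nodes,
        adjacency=adj,
        shape=m.shape,
        connectivity=connectivity,
        component_labels=labels,
        n_components=n_comp,
    )


def largest_component(graph: VoxelGraph, min_fraction: float = 0.5) -> VoxelGraph:
    """Reduce to the largest connected component.

    Thresholding can leave satellite islands; they are discarded with a
    logged fraction.  If the largest component holds less than
    ``min_fraction`` of the mask the reduction is refused — the mask is
    then not a single tract.
    """
    if graph.n_components == 1:
        return graph
    sizes = np.bincount(graph.component_labels)
    main = int(sizes.argmax())
    frac = sizes[main] / graph.n_nodes
    if frac < min_fraction:
        raise ValueError(
            f"largest connected component holds only {frac:.1%} of the mask "
            f"({graph.n_components} components); refusing to parameterize"
        )
    logger.warning(
        "mask has %d components; keeping largest (%.1f%% of voxels)",
        graph.n_components, 100 * frac,
    )
    keep = graph.component_labels == main
    sub = graph.adjacency[keep][:, keep].tocsr()
    return VoxelGraph(
        nodes=graph.nodes[keep],
        adjacency=sub,
        shape=graph.shape,
        connectivity=graph.connectivity,
        component_labels=np.zeros(int(sizes[main]), dtype=graph.component_labels.dtype),
        n_components=1,
    )

_DENSE_LIMIT = 600
_RESIDUAL_TOL = 1e-8


def fiedler_vector(graph: VoxelGraph) -> tuple[float, np.ndarray]:
    """Eigenpair of the combinatorial Laplacian at the smallest non-zero eigenvalue.

    The constant vector spans the nullspace of L = D - A on a connected
    graph; the next eigenvector (the Fiedler vector) is the smoothest
    non-constant function on the graph and orders the voxels along the
    tract.  Returns ``(eigenvalue, unit eigenvector)`` with a verified
    residual ||L v - lam v|| <= 1e-8.
    """
    if graph.n_components != 1:
        raise ValueError(
            f"graph is disconnected ({graph.n_components} components); "
            "reduce with largest_component first"
        )
    n = graph.n_nodes
    if n < 2:
        raise ValueError("need at least 2 voxels to parameterize")
    adj = graph.adjacency
    lap = sp.csgraph.laplacian(adj, normed=False).tocsc()
    if n <= _DENSE_LIMIT:
        w, v = np.linalg.eigh(lap.toarray())
        lam = float(w[1])
        vec = v[:, 1]
    else:
        try:
            w, v = eigsh(lap, k=2, sigma=-1e-3, which="LM")
        except Exception as exc:  # pragma: no cover - solver diagnostics
            raise RuntimeError(f"Laplacian eigensolver failed: {exc}") from exc
        order = np.argsort(w)
        lam = float(w[order[1]])
        vec = v[:, order[1]]
    vec = vec - vec.mean()  # project out the constant mode
    nrm = np.linalg.norm(vec)
    if nrm == 0:
        raise RuntimeError("degenerate Fiedler vector (constant)")
    vec = vec / nrm
    residual = np.linalg.norm(lap @ vec - lam * vec)
    if residual > _RESIDUAL_TOL * max(1.0, abs(lam)):
        raise RuntimeError(
            f"eigensolver residual {residual:.2e} exceeds tolerance "
            f"{_RESIDUAL_TOL:.0e} (n={n}, lambda={lam:.3e})"
        )
    return lam, vec


def orient_and_normalize(
    raw: np.ndarray,
    nodes: np.ndarray,
    affine: np.ndarray,
    anchor: str = "frontal",
    linearize: bool = True,
) -> np.ndarray:
    """Fix the sign of the spectral coordinate anatomically, rescale to [0, 1].

    With ``anchor='frontal'`` the sign is chosen so the 10% of voxels
    with the smallest coordinate lie more anteriorly (greater mean world
    y) than the 10% with the largest — segment 1 is then the frontal
    end.  ``anchor='temporal'`` flips the convention.  The raw
    eigenvector's arbitrary sign therefore never leaks into results.

    On an elongated domain the Fiedler vector behaves like
    cos(pi s / L) in arc length s, so a plain min-max rescale crowds
    voxels toward t = 0 and t = 1 and "equally spaced" segments would be
    spatially unequal.  With ``linearize=True`` (default) the min-maxed
    coordinate u is passed through arccos(1 - 2u)/pi, which undoes the
    cosine exactly on a path and leaves t approximately proportional to
    arc length; the transform is monotone, so rank-based properties are
    unaffected.
    """
    if anchor not in ("frontal", "temporal"):
        raise ValueError(f"anchor must be 'frontal' or 'temporal', got {anchor}")
    raw = np.asarray(raw, dtype=float)
    if raw.max() == raw.min():
        raise ValueError("constant spectral coordinate: cannot orient or normalize")
    vol = ScalarVolume(np.zeros((1, 1, 1)), affine)  # affine carrier
    y = vol.voxel_to_mm(nodes)[:, 1]
    n_dec = max(1, int(round(0.1 * len(raw))))
    order = np.argsort(raw, kind="stable")
    y_low, y_high = y[order[:n_dec]].mean(), y[order[-n_dec:]].mean()
    if y_low == y_high:
        raise ValueError(
            "sign undecidable: anterior means of the two coordinate extremes are "
            "equal; supply explicit anchor coordinates"
        )
    want_low_anterior = anchor == "frontal"
    if (y_low > y_high) != want_low_anterior:
        raw = -raw
    t = (raw - raw.min()) / (raw.max() - raw.min())
    if linearize:
        t = np.arccos(1.0 - 2.0 * t) / np.pi
    return t


def segment_labels(t: np.ndarray, n_segments: int = 15) -> np.ndarray:
    """Equal-width segment labels 1..K on the normalized coordinate.

    label = floor(t * K) + 1, with t = 1 mapped back to K.  Empty labels
    are legal but logged — they indicate the mask is too small for K.
    """
    if n_segments < 2:
        raise ValueError(f"need at least 2 segments, got {n_segments}")
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("t must lie in [0, 1]")
    labels = np.minimum(np.floor(t * n_segments).astype(np.int32) + 1, n_segments)
    counts = np.bincount(labels, minlength=n_segments + 1)[1:]
    if np.any(counts == 0):
        logger.warning(
            "empty segments %s out of K=%d", list(np.flatnonzero(counts == 0) + 1), n_segments
        )
    return labels


# ------------------------------------------------------------ model facade

class TractModel:
    """Spectral along-tract parameterization of a density volume.

    Parameters
    ----------
    density : ScalarVolume
        Streamline visitation / connectivity map, non-negative.
    fraction : float
        Threshold as a fraction of the map maximum (default 0.10).
    connectivity : {6, 18, 26}
        Voxel neighborhood of the graph (default 26).
    n_segments : int
        Number of equal-width segments K (default 15).
    anchor : {'frontal', 'temporal'}
        Which anatomical end is t = 0.
    y_max, z_min : float, optional
        White-matter-core limits handed to :func:`restrict_core`.
    core_units : {'mm', 'voxel'}
        Interpretation of the core limits.
    """

    def __init__(
        self,
        density: ScalarVolume,
        *,
        fraction: float = 0.10,
        connectivity: int = 26,
        n_segments: int = 15,
        anchor: str = "frontal",
        linearize: bool = True,
        y_max: float | None = None,
        z_min: float | None = None,
        core_units: str = "mm",
    ) -> None:
        self.density = density
        self.fraction = fraction
        self.connectivity = connectivity
        self.n_segments = n_segments
        self.anchor = anchor
        self.linearize = linearize
        self.y_max = y_max
        self.z_min = z_min
        self.core_units = core_units

    def fit(self) -> "TractParameterization":
        mask = threshold_density(self.density, self.fraction)
        if self.y_max is not None or self.z_min is not None:
            mask = restrict_core(mask, self.y_max, self.z_min, self.core_units)
        graph = largest_component(build_voxel_graph(mask, self.connectivity))
        lam, vec = fiedler_vector(graph)
        t = orient_and_normalize(
            vec, graph.nodes, mask.affine, self.anchor, linearize=self.linearize
        )
        labels = segment_labels(t, self.n_segments)
        return TractParameterization(
            model=self,
            mask=mask,
            graph=graph,
            eigenvalue=lam,
            t=t,
            labels=labels,
        )


@dataclass
class TractParameterization:
    """Fitted along-tract coordinate and segment labels."""

    model: TractModel
    mask: ScalarVolume
    graph: VoxelGraph
    eigenvalue: float
    t: np.ndarray        # per graph node, in [0, 1]
    labels: np.ndarray   # per graph node, 1..K

    @property
    def n_segments(self) -> int:
        return self.model.n_segments

    def t_volume(self) -> ScalarVolume:
        out = np.full(self.mask.shape, np.nan)
        n = self.graph.nodes
        out[n[:, 0], n[:, 1], n[:, 2]] = self.t
        return ScalarVolume(out, self.mask.affine)

    def label_volume(self) -> ScalarVolume:
        out = np.zeros(self.mask.shape, dtype=np.uint16)
        n = self.graph.nodes
        out[n[:, 0], n[:, 1], n[:, 2]] = self.labels
        return ScalarVolume(out, self.mask.affine)

    def segment_voxel_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_segments + 1)[1:]

    def summary(self) -> str:
        counts = self.segment_voxel_counts()
        lines = [
            "Spectral tract parameterization",
            "===============================",
            f"voxels in tract:       {self.graph.n_nodes}",
            f"graph edges:           {self.graph.n_edges} ({self.graph.connectivity}-connectivity)",
            f"Fiedler eigenvalue:    {self.eigenvalue:.6g}",
            f"segments (K):          {self.n_segments}",
            f"voxels per segment:    min {counts.min()}, median {int(np.median(counts))}, "
            f"max {counts.max()}",
            f"anchor (t=0):          {self.model.anchor}",
        ]
        return "\n".join(lines)
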