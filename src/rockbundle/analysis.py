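"""Comparative trajectory analyses: correlation networks, bundle-relative
RMSD, and CV ensemble summaries for bound-vs-apo comparisons.

The dynamical network analysis builds a residue-residue correlation matrix
from fluctuations about the mean structure (after superposing every frame on
a fit group — by default the fixed bundle, so rocking motion does not
contaminate the fluctuations), masks it with a contact criterion (pairs
within a distance cutoff in at least an occupancy fraction of frames), and
weights the surviving edges by ``w_ij = -ln|C_ij|``: highly correlated
contacts are "short", so shortest paths trace allosteric communication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .colvars import AtomGroup, CVSpec, apply_transform, evaluate_cv, kabsch_align, rmsd
from .dynamics import Trajectory
from .model import ReferencePair, ToyStructure

__all__ = [
    "CorrelationNetwork",
    "EnsembleSummary",
    "correlation_matrix",
    "contact_mask",
    "build_network",
    "strongest_edges",
    "allosteric_path",
    "interbundle_coupling_score",
    "bundle_relative_rmsd",
    "ensemble_summary",
    "align_frames",
]


def align_frames(frames: np.ndarray, fit_group: AtomGroup) -> np.ndarray:
    """Superpose every frame on the first frame over ``fit_group``."""
    frames = np.asarray(frames, dtype=float)
    out = np.empty_like(frames)
    out[0] = frames[0]
    for t in range(1, frames.shape[0]):
        R, tr = kabsch_align(frames[t], frames[0], fit_group)
        out[t] = apply_transform(frames[t], R, tr)
    return out


def correlation_matrix(traj: Trajectory | np.ndarray, fit_group: AtomGroup) -> np.ndarray:
    """Normalized residue-displacement correlation
    ``C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>)`` with displacements
    taken from the mean structure after alignment on ``fit_group``.

    A node with zero variance outside the fit group is degenerate input and
    raises; fit-group nodes may legitimately be static (they define the
    frame) and get zero off-diagonal correlations instead.
    """
    frames = traj.protein_frames if isinstance(traj, Trajectory) else np.asarray(traj)
    if frames.shape[0] < 10:
        raise ValueError(f"need >= 10 frames for a correlation matrix, got {frames.shape[0]}")
    aligned = align_frames(frames, fit_group)
    mean = aligned.mean(axis=0)
    dr = aligned - mean  # (F, N, 3)
    cov = np.einsum("fia,fja->ij", dr, dr) / dr.shape[0]
    var = np.diag(cov).copy()
    static = var <= 1e-14
    bad = np.flatnonzero(static & ~np.isin(np.arange(len(var)), fit_group.index_array))
    if bad.size:
        raise ValueError(f"zero-variance node(s) {bad.tolist()}: cannot normalize correlations")
    safe_var = np.where(static, 1.0, var)
    C = cov / np.sqrt(np.outer(safe_var, safe_var))
    C[static, :] = 0.0
    C[:, static] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def contact_mask(
    traj: Trajectory | np.ndarray, cutoff: float = 8.0, occupancy: float = 0.75
) -> np.ndarray:
    """Boolean contact matrix: within ``cutoff`` in >= ``occupancy`` of frames."""
    frames = traj.protein_frames if isinstance(traj, Trajectory) else np.asarray(traj)
    if frames.shape[0] < 2:
        raise ValueError("need >= 2 frames for a contact mask")
    n = frames.shape[1]
    count = np.zeros((n, n))
    for f in frames:
        count += cdist(f, f) <= cutoff
    M = count / frames.shape[0] >= occupancy
    np.fill_diagonal(M, False)
    return M


@dataclass
class CorrelationNetwork:
    """Contact-filtered correlation graph with edge weights ``-ln|C_ij|``."""

    C: np.ndarray
    M: np.ndarray
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return int(self.C.shape[0])

    def edge_table(self) -> list[tuple[int, int, float, float]]:
        """(i, j, C_ij, w_ij) rows, i < j, sorted by node pair."""
        rows = []
        for i, j, data in sorted(self.graph.edges(data=True)):
            rows.append((i, j, data["correlation"], data["weight"]))
        return rows


def build_network(C: np.ndarray, M: np.ndarray) -> CorrelationNetwork:
    """Assemble the weighted graph from a correlation matrix and contact mask.

    Edges exist where the mask is true (i != j); anti-correlated pairs couple
    as strongly as correlated ones (|C| enters the weight).  Perfectly
    uncorrelated contacts (C = 0) would have infinite weight and are dropped.
    """
    C = np.asarray(C, dtype=float)
    M = np.asarray(M, dtype=bool)
    if C.shape != M.shape or C.shape[0] != C.shape[1]:
        raise ValueError("C and M must be square matrices of matching shape")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.abs(C).max() > 1 + 1e-9:
        raise ValueError("|C_ij| must be <= 1")
    g = nx.Graph()
    g.add_nodes_from(range(C.shape[0]))
    for i, j in zip(*np.nonzero(np.triu(M, k=1))):
        c = abs(C[i, j])
        if c <= 0.0:
            continue
        w = 0.0 if c >= 1.0 else -float(np.log(c))
        g.add_edge(int(i), int(j), weight=w, correlation=float(C[i, j]))
    return CorrelationNetwork(C=C, M=(M | M.T), graph=g)


def strongest_edges(net: CorrelationNetwork, k: int) -> list[tuple[int, int, float]]:
    """Top-k edges by |C|, descending; ties broken by node pair order."""
    edges = [
        (i, j, data["correlation"]) for i, j, data in net.graph.edges(data=True)
    ]
    edges.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    return edges[: int(k)]


def allosteric_path(net: CorrelationNetwork, source: int, target: int) -> Optional[list[int]]:
    """Deterministic shortest path under ``-ln|C|`` weights.

    Returns None when source and target are disconnected.  Among equal-weight
    shortest paths the lexicographically smallest node sequence is returned.
    """
    g = net.graph
    if source not in g or target not in g:
        raise ValueError(f"nodes ({source}, {target}) not in network")
    try:
        dist = nx.single_source_dijkstra_path_length(g, target)
    except nx.NodeNotFound:  # pragma: no cover
        return None
    if source not in dist:
        return None
    # greedy lexicographic reconstruction along the shortest-path DAG; the
    # visited set guards against ping-ponging over zero-weight edges
    path = [source]
    visited = {source}
    node = source
    tol = 1e-12
    while node != target:
        d_here = dist[node]
        nxt = None
        for nb in sorted(g.neighbors(node)):
            if nb in visited:
                continue
            w = g[node][nb]["weight"]
            if nb in dist and abs(w + dist[nb] - d_here) <= tol + 1e-9 * max(1.0, d_here):
                nxt = nb
                break
        if nxt is None:  # pragma: no cover - numerical safety net
            return nx.dijkstra_path(g, source, target)
        path.append(nxt)
        visited.add(nxt)
        node = nxt
    return path


def interbundle_coupling_score(
    net: CorrelationNetwork, structure: ToyStructure
) -> tuple[float, int]:
    """Mean |C| over contact edges linking the two site-bearing helices across
    the bundle interface; (score, n_edges).  Zero with a warning record when
    no contact edge qualifies."""
    h_b1, h_b2 = structure.site_helices
    set1 = set(structure.helix_atoms(h_b1).tolist())
    set2 = set(structure.helix_atoms(h_b2).tolist())
    vals = [
        abs(data["correlation"])
        for i, j, data in net.graph.edges(data=True)
        if (i in set1 and j in set2) or (i in set2 and j in set1)
    ]
    if not vals:
        import warnings

        warnings.warn("no cross-bundle contact edges between site helices; score = 0")
        return 0.0, 0
    return float(np.mean(vals)), len(vals)


def bundle_relative_rmsd(
    traj: Trajectory | np.ndarray,
    structure: ToyStructure,
    refs: ReferencePair,
    measure_bundle: int,
    fit_bundle: int,
    reference: str = "of",
) -> np.ndarray:
    """Per-frame RMSD of one bundle after superposing on another (or itself).

    The self-fit series reports internal bundle deformation; the other-fit
    series adds the rigid-body motion of the measured bundle relative to the
    fit bundle — the observable that separates "bundles move relative to each
    other" from "bundles fall apart".
    """
    frames = traj.protein_frames if isinstance(traj, Trajectory) else np.asarray(traj)
    ref = refs.of_coords if reference == "of" else refs.if_coords
    measure = structure.bundle_group(measure_bundle)
    fit = structure.bundle_group(fit_bundle)
    return np.array([rmsd(f, ref, measure, fit) for f in frames])


@dataclass
class EnsembleSummary:
    """Per-CV time series, histogram and moments for one condition."""

    condition: str
    names: list[str]
    series: dict[str, np.ndarray]
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # (density, edges)
    means: dict[str, float]
    sds: dict[str, float]
    reference_values: dict[str, float]
    reference_deltas: dict[str, float]  # |mean - reference|


def ensemble_summary(
    traj: Trajectory | np.ndarray,
    cv_specs: Sequence[CVSpec],
    reference_values: Optional[dict[str, float]] = None,
    condition: str = "",
) -> EnsembleSummary:
    """Evaluate CVs on every frame; histogram with the Freedman–Diaconis rule
    (single bin for constant series) normalized to unit mass."""
    frames = traj.protein_frames if isinstance(traj, Trajectory) else np.asarray(traj)
    reference_values = dict(reference_values or {})
    names, series, hists, means, sds, deltas = [], {}, {}, {}, {}, {}
    for idx, spec in enumerate(cv_specs):
        name = spec.name or f"cv{idx}"
        names.append(name)
        vals = np.array([evaluate_cv(spec, f) for f in frames])
        series[name] = vals
        if np.ptp(vals) == 0.0:
            edges = np.array([vals[0] - 0.5, vals[0] + 0.5])
            dens = np.array([1.0])
        else:
            dens, edges = np.histogram(vals, bins="fd", density=True)
            dens = dens * np.diff(edges)  # probability mass per bin
        hists[name] = (dens, edges)
        means[name] = float(vals.mean())
        sds[name] = float(vals.std(ddof=0))
        if name in reference_values:
            deltas[name] = abs(means[name] - reference_values[name])
    return EnsembleSummary(
        condition=condition,
        names=names,
        series=series,
        histograms=hists,
        means=means,
        sds=sds,
        reference_values=reference_values,
        reference_deltas=deltas,
    )
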