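"""Collective variables: distances, radii of gyration, RMSD, orientation quaternions.

All CVs are pure functions of an ``(N, 3)`` coordinate array plus a static
specification (atom groups, reference coordinates).  Angles are reported in
degrees; quaternions follow the scalar-first ``(w, x, y, z)`` convention and
are canonicalized to ``w >= 0`` (``q`` and ``-q`` encode the same rotation).

"Center of mass" on the Cα model means the uniform-weight centroid unless a
group carries explicit weights: the beads have no masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AtomGroup",
    "CVSpec",
    "com",
    "com_distance",
    "com_projection",
    "radius_of_gyration",
    "kabsch_align",
    "apply_transform",
    "rmsd",
    "orientation_quaternion",
    "orientation_angle",
    "evaluate_cv",
    "cv_gradient",
    "pairwise_rmsd_map",
]


class DegenerateGeometryError(ValueError):
    """Raised when a fit/orientation group is collinear or otherwise degenerate."""


@dataclass(frozen=True)
class AtomGroup:
    """Ordered selection of atom indices with optional per-atom weights."""

    indices: tuple[int, ...]
    weights: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(idx) == 0:
            raise ValueError("AtomGroup must be non-empty")
        if len(set(idx)) != len(idx):
            raise ValueError("AtomGroup indices must be unique")
        object.__setattr__(self, "indices", idx)
        if self.weights is not None:
            w = tuple(float(x) for x in self.weights)
            if len(w) != len(idx):
                raise ValueError("weights length must match indices")
            if not all(np.isfinite(w)) or sum(w) <= 0:
                raise ValueError("weights must be finite with positive sum")
            object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def index_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=np.intp)

    @property
    def weight_array(self) -> np.ndarray:
        if self.weights is None:
            return np.full(len(self.indices), 1.0 / len(self.indices))
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()

    def validate(self, n_atoms: int) -> None:
        if min(self.indices) < 0 or max(self.indices) >= n_atoms:
            raise IndexError(
                f"AtomGroup indices out of range for {n_atoms} atoms: {self.indices}"
            )


def _coords(coords, group: AtomGroup) -> np.ndarray:
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"coordinates must be (N, 3), got {x.shape}")
    group.validate(x.shape[0])
    return x[group.index_array]


def com(group: AtomGroup, coords) -> np.ndarray:
    """Weighted centroid of the group (uniform weights by default)."""
    x = _coords(coords, group)
    return group.weight_array @ x


def com_distance(group_a: AtomGroup, group_b: AtomGroup, coords) -> float:
    """Euclidean distance between the two group centroids; symmetric in its groups."""
    return float(np.linalg.norm(com(group_a, coords) - com(group_b, coords)))


def com_projection(group: AtomGroup, coords, axis, origin=(0.0, 0.0, 0.0)) -> float:
    """Displacement of the group centroid along a fixed unit vector.

    The translational analogue of a z-position steering coordinate; its
    equilibrium free energy in a harmonic trap is independent of the trap
    center, which makes it the clean testbed for work bookkeeping.
    """
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("projection axis must be non-zero")
    return float((com(group, coords) - np.asarray(origin, dtype=float)) @ (a / n))


def radius_of_gyration(group: AtomGroup, coords) -> float:
    """Root-mean-square distance of the group atoms from their centroid."""
    x = _coords(coords, group)
    d = x - x.mean(axis=0)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def _check_nondegenerate(x: np.ndarray, what: str) -> None:
    if x.shape[0] < 3:
        raise DegenerateGeometryError(f"{what} needs >= 3 atoms, got {x.shape[0]}")
    c = x - x.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError(f"{what} atoms are (near-)collinear")


def kabsch_align(mobile_coords, ref_coords, fit_group: AtomGroup):
    """Optimal proper rigid transform mapping mobile onto ref over ``fit_group``.

    Returns ``(R, t)`` with ``det(R) = +1`` such that ``mobile @ R.T + t``
    minimizes the fit-group RMSD to ``ref_coords``.
    """
    xm = _coords(mobile_coords, fit_group)
    xr = _coords(ref_coords, fit_group)
    if xm.shape != xr.shape:
        raise ValueError("mobile/ref shape mismatch on fit group")
    _check_nondegenerate(xm, "fit group (mobile)")
    _check_nondegenerate(xr, "fit group (reference)")
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    H = (xm - cm).T @ (xr - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return R, t


def apply_transform(coords, R, t) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(R).T + np.asarray(t)


def rmsd(
    mobile_coords,
    ref_coords,
    measure_group: AtomGroup,
    fit_group: Optional[AtomGroup] = None,
) -> float:
    """RMSD over ``measure_group``, optionally after superposing on ``fit_group``."""
    xm = np.asarray(mobile_coords, dtype=float)
    xr = np.asarray(ref_coords, dtype=float)
    if xm.shape != xr.shape:
        raise ValueError(f"coordinate shape mismatch: {xm.shape} vs {xr.shape}")
    if fit_group is not None:
        R, t = kabsch_align(xm, xr, fit_group)
        xm = apply_transform(xm, R, t)
    a = _coords(xm, measure_group)
    b = _coords(xr, measure_group)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


# Horn's quaternion method: the optimal rotation taking centered reference
# coordinates onto centered current coordinates is the top eigenvector of a
# 4x4 key matrix K(S) built from the 3x3 correlation matrix S.
def _key_matrix(S: np.ndarray) -> np.ndarray:
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    return np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )


# dK/dS as a constant (4,4,3,3) tensor, derived once from the pattern above.
def _build_dK_dS() -> np.ndarray:
    T = np.zeros((4, 4, 3, 3))
    eps = 1e-0
    for r in range(3):
        for c in range(3):
            S = np.zeros((3, 3))
            S[r, c] = eps
            T[:, :, r, c] = _key_matrix(S)
    return T


_DK_DS = _build_dK_dS()
_DK_DS_FLAT = _DK_DS.reshape(16, 9)  # (j*k, rho*sigma) for fast contraction


def _quaternion_from_groups(x: np.ndarray, xref: np.ndarray):
    """Top eigenpair of the key matrix for centered (ref -> current) rotation."""
    a = xref - xref.mean(axis=0)
    b = x - x.mean(axis=0)
    S = a.T @ b
    K = _key_matrix(S)
    lam, vec = np.linalg.eigh(K)
    q = vec[:, -1]
    if q[0] < 0:
        q = -q
    return q, lam, vec, a


def orientation_quaternion(group: AtomGroup, coords, ref_coords) -> np.ndarray:
    """Unit quaternion (w,x,y,z), w >= 0, rotating the reference group onto the
    current group after centroid removal."""
    x = _coords(coords, group)
    xref = _coords(ref_coords, group)
    _check_nondegenerate(xref, "orientation group (reference)")
    _check_nondegenerate(x, "orientation group")
    q, _, _, _ = _quaternion_from_groups(x, xref)
    return q / np.linalg.norm(q)


def orientation_angle(group: AtomGroup, coords, ref_coords) -> float:
    """Rotation angle (degrees, in [0, 180]) of the reference-to-current rotation."""
    q = orientation_quaternion(group, coords, ref_coords)
    w = min(abs(q[0]), 1.0)
    return float(np.degrees(2.0 * np.arccos(w)))


def orientation_angle_and_gradient(
    group: AtomGroup, coords, ref_coords
) -> tuple[float, np.ndarray]:
    """Angle (degrees) and its analytic gradient via first-order perturbation
    of the key-matrix eigenproblem.  The gradient is an (N, 3) array, non-zero
    only on group atoms.

    At angle 0 the CV is non-differentiable (it behaves like a norm); the
    gradient is returned as zero there, which is the correct subgradient for
    a restraint centered at 0.
    """
    xall = np.asarray(coords, dtype=float)
    idx = group.index_array
    x = xall[idx]
    xref = np.asarray(ref_coords, dtype=float)[idx]
    # degeneracy (collinear group) surfaces as a closed eigen gap below;
    # no separate SVD check in this hot path
    a = xref - xref.mean(axis=0)
    b = x - x.mean(axis=0)
    K = _key_matrix(a.T @ b)
    lam, vec = np.linalg.eigh(K)
    q = vec[:, -1]
    if q[0] < 0:
        q = -q
    w = min(abs(q[0]), 1.0)
    angle = float(np.degrees(2.0 * np.arccos(w)))
    grad = np.zeros_like(xall)
    w = q[0]
    if 1.0 - w * w < 1e-12:
        return angle, grad
    # dq0 = sum_{m != top} v_m (v_m^T dK q0) / (lam_top - lam_m); we need only dw.
    gap = lam[-1] - lam[:-1]
    if np.min(np.abs(gap)) < 1e-10:
        raise DegenerateGeometryError("degenerate key-matrix spectrum in orientation CV")
    V = vec[:, :-1]  # (4, 3) non-top eigenvectors
    r = V @ (V[0, :] / gap)  # row vector r with dw = r^T dK q0
    # W[rho, sig] = r^T (dK/dS_{rho,sig}) q0 ; then dS/db_{i,alpha} = a_i e_alpha^T
    W = (np.outer(r, q).reshape(1, 16) @ _DK_DS_FLAT).reshape(3, 3)
    G = a @ W  # (m, 3): d w / d b_{i, alpha}
    pref = -2.0 / np.sqrt(1.0 - w * w) * np.degrees(1.0) * np.sign(w)
    grad[idx] = pref * G
    return angle, grad


def orientation_angle_gradient(group: AtomGroup, coords, ref_coords) -> np.ndarray:
    return orientation_angle_and_gradient(group, coords, ref_coords)[1]


_CV_KINDS = ("rmsd", "orientation_angle", "com_distance", "radius_of_gyration", "com_projection")


@dataclass(frozen=True)
class CVSpec:
    """Declarative description of a collective variable.

    kind-specific fields:
      - ``com_distance``: ``group`` and ``group_b``
      - ``radius_of_gyration``: ``group``
      - ``rmsd``: ``group`` (measured), optional ``fit_group``, ``ref_coords``
      - ``orientation_angle``: ``group``, ``ref_coords``
      - ``com_projection``: ``group``, ``axis`` (unit vector), optional ``origin``
    """

    kind: str
    group: AtomGroup
    group_b: Optional[AtomGroup] = None
    fit_group: Optional[AtomGroup] = None
    ref_coords: Optional[np.ndarray] = None
    axis: Optional[tuple[float, float, float]] = None
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""

    def __post_init__(self):
        if self.kind not in _CV_KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}; expected one of {_CV_KINDS}")
        if self.kind == "com_distance" and self.group_b is None:
            raise ValueError("com_distance requires group_b")
        if self.kind in ("rmsd", "orientation_angle") and self.ref_coords is None:
            raise ValueError(f"{self.kind} requires ref_coords")
        if self.kind == "com_projection" and self.axis is None:
            raise ValueError("com_projection requires axis")
        if self.ref_coords is not None:
            object.__setattr__(
                self, "ref_coords", np.array(self.ref_coords, dtype=float, copy=True)
            )

    # -- serialization (JSON/YAML-friendly) ---------------------------------
    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "name": self.name, "indices": list(self.group.indices)}
        if self.group.weights is not None:
            d["weights"] = list(self.group.weights)
        if self.group_b is not None:
            d["indices_b"] = list(self.group_b.indices)
            if self.group_b.weights is not None:
                d["weights_b"] = list(self.group_b.weights)
        if self.fit_group is not None:
            d["fit_indices"] = list(self.fit_group.indices)
        if self.ref_coords is not None:
            d["ref_coords"] = np.asarray(self.ref_coords).tolist()
        if self.axis is not None:
            d["axis"] = list(self.axis)
            d["origin"] = list(self.origin)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CVSpec":
        group = AtomGroup(tuple(d["indices"]), tuple(d["weights"]) if "weights" in d else None)
        group_b = None
        if "indices_b" in d:
            group_b = AtomGroup(
                tuple(d["indices_b"]), tuple(d["weights_b"]) if "weights_b" in d else None
            )
        fit_group = AtomGroup(tuple(d["fit_indices"])) if "fit_indices" in d else None
        return cls(
            kind=d["kind"],
            group=group,
            group_b=group_b,
            fit_group=fit_group,
            ref_coords=np.asarray(d["ref_coords"], dtype=float) if "ref_coords" in d else None,
            axis=tuple(d["axis"]) if "axis" in d else None,
            origin=tuple(d.get("origin", (0.0, 0.0, 0.0))),
            name=d.get("name", ""),
        )


def evaluate_cv(spec: CVSpec, coords) -> float:
    """Evaluate a CV spec on one coordinate frame (pure function)."""
    if spec.kind == "com_distance":
        return com_distance(spec.group, spec.group_b, coords)
    if spec.kind == "radius_of_gyration":
        return radius_of_gyration(spec.group, coords)
    if spec.kind == "rmsd":
        return rmsd(coords, spec.ref_coords, spec.group, spec.fit_group)
    if spec.kind == "orientation_angle":
        return orientation_angle(spec.group, coords, spec.ref_coords)
    if spec.kind == "com_projection":
        return com_projection(spec.group, coords, spec.axis, spec.origin)
    raise ValueError(f"unknown CV kind {spec.kind!r}")


def _fd_gradient(spec: CVSpec, coords, h: float = 1e-5) -> np.ndarray:
    """Central finite-difference CV gradient, restricted to atoms the CV touches."""
    x = np.array(coords, dtype=float, copy=True)
    grad = np.zeros_like(x)
    touched = set(spec.group.indices)
    if spec.group_b is not None:
        touched |= set(spec.group_b.indices)
    if spec.fit_group is not None:
        touched |= set(spec.fit_group.indices)
    for i in sorted(touched):
        for alpha in range(3):
            x[i, alpha] += h
            up = evaluate_cv(spec, x)
            x[i, alpha] -= 2 * h
            dn = evaluate_cv(spec, x)
            x[i, alpha] += h
            grad[i, alpha] = (up - dn) / (2 * h)
    return grad


def cv_value_and_gradient(spec: CVSpec, coords) -> tuple[float, np.ndarray]:
    """CV value and gradient in one pass (shares the eigenproblem solve for
    orientation CVs)."""
    if spec.kind == "orientation_angle":
        return orientation_angle_and_gradient(spec.group, coords, spec.ref_coords)
    return evaluate_cv(spec, coords), cv_gradient(spec, coords)


def cv_gradient(spec: CVSpec, coords) -> np.ndarray:
    """d(CV)/d(coords) as an (N, 3) array.

    Analytic for com_distance / com_projection / radius_of_gyration and for
    orientation_angle (eigenproblem perturbation); rmsd falls back to central
    finite differences with step 1e-5 over the atoms the CV touches.
    """
    x = np.asarray(coords, dtype=float)
    grad = np.zeros_like(x)
    if spec.kind == "com_distance":
        ca = com(spec.group, x)
        cb = com(spec.group_b, x)
        diff = ca - cb
        d = np.linalg.norm(diff)
        if d < 1e-12:
            return grad
        u = diff / d
        grad[spec.group.index_array] += np.outer(spec.group.weight_array, u)
        grad[spec.group_b.index_array] -= np.outer(spec.group_b.weight_array, u)
        return grad
    if spec.kind == "com_projection":
        a = np.asarray(spec.axis, dtype=float)
        a = a / np.linalg.norm(a)
        grad[spec.group.index_array] = np.outer(spec.group.weight_array, a)
        return grad
    if spec.kind == "radius_of_gyration":
        xs = x[spec.group.index_array]
        d = xs - xs.mean(axis=0)
        rg = np.sqrt((d * d).sum(axis=1).mean())
        if rg < 1e-12:
            return grad
        grad[spec.group.index_array] = d / (rg * len(spec.group))
        return grad
    if spec.kind == "orientation_angle":
        return orientation_angle_gradient(spec.group, x, spec.ref_coords)
    if spec.kind == "rmsd":
        return _fd_gradient(spec, x)
    raise ValueError(f"unknown CV kind {spec.kind!r}")


def pairwise_rmsd_map(
    frames: Sequence[np.ndarray],
    measure_group: AtomGroup,
    fit_group: Optional[AtomGroup] = None,
    stride: int = 1,
) -> np.ndarray:
    """Symmetric frame-vs-frame RMSD matrix (2-D RMSD analysis)."""
    fr = [np.asarray(f, dtype=float) for f in frames][:: max(1, int(stride))]
    if len(fr) < 2:
        raise ValueError("need >= 2 frames after striding")
    n = len(fr)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = rmsd(fr[i], fr[j], measure_group, fit_group)
            out[i, j] = out[j, i] = v
    return out
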