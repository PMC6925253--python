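"""Coarse two-bundle transporter model and its double-basin energy function.

The toy protein is a ring of idealized Cα helices split into two rigid
four-helix-like bundles around a pseudo-two-fold (z) axis.  The outward-facing
(OF) reference is the as-built geometry; the inward-facing (IF) reference is
generated by a rigid-body "rocking" rotation of bundle 1 about an axis through
the bundle interface while bundle 2 stays fixed.  A single ion pseudo-particle
sits at the bundle interface, tied to five tagged site atoms (two on one
bundle, three on the other) by harmonic distance restraints whose rest lengths
are measured in the OF reference — the coarse analogue of restraining a bound
Na+ in the conserved Na2 site.

Energetics: per-basin elastic networks (springs between all atom pairs within
a cutoff of that basin's reference) are combined through exponential
(log-sum-exp) mixing into a smooth double-basin surface, plus a soft excluded
volume term and, when the ion is present, the five site restraints.  All terms
depend only on interparticle distances, so the energy is invariant under
global rigid motion.

Reduced units throughout: kT = 1, lengths are Å-like model units.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .colvars import AtomGroup, radius_of_gyration

__all__ = [
    "ToyStructure",
    "ReferencePair",
    "EnergyModel",
    "build_toy_transporter",
    "build_energy_model",
    "GeometryError",
]

ROLES = ("na_site", "substrate_site", "cyto_gate", "peri_gate", "plain")

# Idealized helix geometry (model units): Cα-like spiral.
_HELIX_RADIUS = 1.0
_HELIX_RISE = 1.5
_HELIX_TWIST_DEG = 100.0
_ADJACENT_AXIS_DIST = 5.0  # spacing between neighbouring helix axes on the ring
_INTERFACE_PULL = 1.0  # site helices lean toward each other (tight interface)
_LOOP_JITTER = 0.3
_SITE_RADIUS_DEFAULT = 3.0


class GeometryError(RuntimeError):
    """Construction produced a geometry unusable for transition detection."""


@dataclass
class ToyStructure:
    """Labeled Cα model: per-atom residue / helix / bundle / role assignments.

    ``bundle_id`` is 1 (the moving bundle), 2 (the fixed bundle) or 0 for loop
    particles.  ``helix_id`` is 1..H for helix atoms, 0 for loops.  Role tags
    follow the gating/site vocabulary: exactly five ``na_site`` atoms spanning
    both bundles and exactly three atoms in each gate.
    """

    residue_id: np.ndarray  # (N,) int
    helix_id: np.ndarray  # (N,) int, 0 = loop
    bundle_id: np.ndarray  # (N,) int, 0 = none
    role: np.ndarray  # (N,) unicode
    coords: np.ndarray  # (N, 3) OF-state build coordinates
    helix_bundle: dict[int, int] = field(default_factory=dict)
    ion_present: bool = False
    ion_position: Optional[np.ndarray] = None  # OF-reference ion position
    site_radius: float = _SITE_RADIUS_DEFAULT

    def __post_init__(self):
        self.validate()

    # -- selections ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_particles(self) -> int:
        """Protein atoms plus the ion when present."""
        return self.n_atoms + (1 if self.ion_present else 0)

    @property
    def ion_index(self) -> Optional[int]:
        return self.n_atoms if self.ion_present else None

    def atoms_with_role(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.role == role)

    def bundle_atoms(self, bundle: int) -> np.ndarray:
        return np.flatnonzero(self.bundle_id == bundle)

    def helix_atoms(self, helix: int) -> np.ndarray:
        return np.flatnonzero(self.helix_id == helix)

    def group(self, indices) -> AtomGroup:
        return AtomGroup(tuple(int(i) for i in indices))

    def bundle_group(self, bundle: int) -> AtomGroup:
        return self.group(self.bundle_atoms(bundle))

    def gate_group(self, which: str) -> AtomGroup:
        if which not in ("cyto_gate", "peri_gate"):
            raise ValueError(which)
        return self.group(self.atoms_with_role(which))

    @property
    def site_helices(self) -> tuple[int, int]:
        """(bundle-1 helix, bundle-2 helix) carrying the ion-site atoms."""
        hs = sorted({int(h) for h in self.helix_id[self.role == "na_site"]})
        b1 = [h for h in hs if self.helix_bundle[h] == 1]
        b2 = [h for h in hs if self.helix_bundle[h] == 2]
        return b1[0], b2[0]

    def validate(self) -> None:
        n = self.coords.shape[0]
        for arr, name in (
            (self.residue_id, "residue_id"),
            (self.helix_id, "helix_id"),
            (self.bundle_id, "bundle_id"),
            (self.role, "role"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} atoms")
        if not set(np.unique(self.role)) <= set(ROLES):
            raise ValueError(f"unknown role tags: {set(np.unique(self.role)) - set(ROLES)}")
        for h in np.unique(self.helix_id):
            if h == 0:
                continue
            b = np.unique(self.bundle_id[self.helix_id == h])
            if len(b) != 1:
                raise ValueError(f"helix {h} maps to multiple bundles {b}")
        for b in (1, 2):
            helices = {int(h) for h in np.unique(self.helix_id[self.bundle_id == b]) if h != 0}
            if len(helices) < 2:
                raise ValueError(f"bundle {b} has {len(helices)} helices; need >= 2")
        site = self.atoms_with_role("na_site")
        if len(site) != 5:
            raise ValueError(f"na_site must tag exactly 5 atoms, got {len(site)}")
        site_bundles = set(self.bundle_id[site].tolist())
        if not {1, 2} <= site_bundles:
            raise ValueError("na_site atoms must span both bundles (interface placement)")
        for gate in ("cyto_gate", "peri_gate"):
            g = self.atoms_with_role(gate)
            if len(g) != 3:
                raise ValueError(f"{gate} must tag exactly 3 atoms, got {len(g)}")
        if self.ion_present and self.ion_position is None:
            raise ValueError("ion_present set but no ion_position")

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.residue_id, self.helix_id, self.bundle_id):
            h.update(np.ascontiguousarray(arr, dtype=np.int64).tobytes())
        h.update("".join(self.role.tolist()).encode())
        h.update(np.ascontiguousarray(self.coords, dtype=np.float64).tobytes())
        if self.ion_present:
            h.update(np.ascontiguousarray(self.ion_position, dtype=np.float64).tobytes())
        return h.hexdigest()[:16]


@dataclass
class ReferencePair:
    """OF and IF reference coordinates plus the rocking transform that links them.

    Bundle 2 superposes exactly between the two references; bundle 1 (and the
    gate/site atoms riding on it) differs by the stated rigid rotation.
    """

    of_coords: np.ndarray
    if_coords: np.ndarray
    rocking_axis: np.ndarray  # unit vector
    rocking_angle_deg: float
    rocking_center: np.ndarray

    def __post_init__(self):
        if self.of_coords.shape != self.if_coords.shape:
            raise ValueError("of/if coordinate shape mismatch")
        self.rocking_axis = np.asarray(self.rocking_axis, dtype=float)
        self.rocking_axis /= np.linalg.norm(self.rocking_axis)


def _minimax_center(pts: np.ndarray) -> np.ndarray:
    """Center of the smallest sphere enclosing ``pts`` (ion optimally coordinated)."""
    from scipy.optimize import minimize

    res = minimize(
        lambda x: np.linalg.norm(pts - x, axis=1).max(),
        pts.mean(axis=0),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
    )
    return res.x


def _rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _rotate_about(coords, axis, angle_deg, center) -> np.ndarray:
    R = _rotation_matrix(axis, angle_deg)
    return (np.asarray(coords) - center) @ R.T + center


def build_toy_transporter(
    n_helices_per_bundle: int = 4,
    residues_per_helix: int = 10,
    rocking_angle_deg: float = 25.0,
    seed: int = 0,
    loop_residues: int = 3,
    site_radius: float = _SITE_RADIUS_DEFAULT,
) -> tuple[ToyStructure, ReferencePair]:
    """Construct the coarse transporter and its OF/IF reference pair.

    Helices alternate bundle membership around a ring (interdigitated bundles);
    the IF reference rotates bundle 1 rigidly about the +y axis through the
    ring center so that the periplasmic (top) lumen closes and the cytoplasmic
    (bottom) lumen opens.  Loop particles (jittered by ``seed``) bridge
    consecutive helices and belong to neither bundle; in the IF reference they
    follow the rocking rotation at half the angle (a smooth interpolation
    between the bundle they leave and the one they enter).

    Raises ``GeometryError`` if the constructed references violate the
    gate-compaction ordering (peri gate tighter in IF, cyto gate tighter in
    OF) — without it, transition completion cannot be detected.
    """
    if n_helices_per_bundle < 2:
        raise ValueError("need >= 2 helices per bundle")
    if residues_per_helix < 6:
        raise ValueError("need >= 6 residues per helix")
    if rocking_angle_deg < 0:
        raise ValueError("rocking angle must be >= 0")
    rng = np.random.default_rng(seed)

    H = 2 * n_helices_per_bundle
    ring_radius = _ADJACENT_AXIS_DIST / (2.0 * np.sin(np.pi / H))
    half_len = (residues_per_helix - 1) * _HELIX_RISE / 2.0

    residue_id, helix_id, bundle_id, role, xyz = [], [], [], [], []
    helix_bundle: dict[int, int] = {}
    res_counter = 0

    def add_atom(pos, hid, bid, r="plain"):
        nonlocal res_counter
        res_counter += 1
        residue_id.append(res_counter)
        helix_id.append(hid)
        bundle_id.append(bid)
        role.append(r)
        xyz.append(np.asarray(pos, dtype=float))

    axes_xy = [
        ring_radius * np.array([np.cos(2 * np.pi * k / H), np.sin(2 * np.pi * k / H)])
        for k in range(H)
    ]
    # the two ion-site helices (1 and 2) lean toward each other: the bundle
    # interface is tighter than the rest of the ring
    mid01 = 0.5 * (axes_xy[0] + axes_xy[1])
    for k in (0, 1):
        u = mid01 - axes_xy[k]
        axes_xy[k] = axes_xy[k] + _INTERFACE_PULL * u / np.linalg.norm(u)

    helix_ends = {}  # helix -> (first atom pos, last atom pos)
    j_mid = (residues_per_helix - 1) / 2.0
    for k in range(H):
        hid = k + 1
        bid = 1 if k % 2 == 0 else 2
        helix_bundle[hid] = bid
        axis_xy = axes_xy[k]
        # spiral phase aimed so mid-helix beads face the partner site helix
        # (helices 1, 2) or the lumen (all others)
        aim = axes_xy[1] if k == 0 else (axes_xy[0] if k == 1 else np.zeros(2))
        aim_ang = np.arctan2(aim[1] - axis_xy[1], aim[0] - axis_xy[0])
        # antiparallel packing: odd helices run top->bottom
        direction = 1 if k % 2 == 0 else -1
        first = None
        for j in range(residues_per_helix):
            z = direction * (-half_len + j * _HELIX_RISE)
            psi = np.radians(_HELIX_TWIST_DEG) * (j - j_mid) + aim_ang
            pos = np.array(
                [
                    axis_xy[0] + _HELIX_RADIUS * np.cos(psi),
                    axis_xy[1] + _HELIX_RADIUS * np.sin(psi),
                    z,
                ]
            )
            add_atom(pos, hid, bid)
            if first is None:
                first = pos
        helix_ends[hid] = (first, pos)

    # loops bridge the end of helix k to the start of helix k+1 (same z side)
    for k in range(H - 1):
        a = helix_ends[k + 1][1]
        b = helix_ends[k + 2][0]
        for j in range(loop_residues):
            f = (j + 1) / (loop_residues + 1)
            pos = (1 - f) * a + f * b + rng.normal(0.0, _LOOP_JITTER, 3)
            add_atom(pos, 0, 0)

    residue_id = np.asarray(residue_id, dtype=int)
    helix_id = np.asarray(helix_id, dtype=int)
    bundle_id = np.asarray(bundle_id, dtype=int)
    role = np.asarray(role, dtype="U16")
    coords = np.vstack(xyz)
    n_atoms = coords.shape[0]

    # --- ion site at the interface between helix 1 (bundle 1) and helix 2
    # (bundle 2): ion at the midpoint of their mid-segments, site atoms are
    # the 2 / 3 nearest beads on each helix (cf. two carbonyl-oxygen donors on
    # one helix, three coordinating oxygens on the other in the real site).
    h1_atoms = np.flatnonzero(helix_id == 1)
    h2_atoms = np.flatnonzero(helix_id == 2)
    mid1 = coords[h1_atoms][np.abs(coords[h1_atoms, 2]).argsort()[:4]].mean(axis=0)
    mid2 = coords[h2_atoms][np.abs(coords[h2_atoms, 2]).argsort()[:4]].mean(axis=0)
    ion_pos = 0.5 * (mid1 + mid2)
    for _ in range(3):  # alternate nearest-bead selection and minimax recentering
        d1 = np.linalg.norm(coords[h1_atoms] - ion_pos, axis=1)
        d2 = np.linalg.norm(coords[h2_atoms] - ion_pos, axis=1)
        site_atoms = np.concatenate(
            [h1_atoms[d1.argsort()[:2]], h2_atoms[d2.argsort()[:3]]]
        )
        ion_pos = _minimax_center(coords[site_atoms])
    site_dists = np.linalg.norm(coords[site_atoms] - ion_pos, axis=1)
    if site_dists.max() > site_radius:
        raise GeometryError(
            f"ion-site construction failed: max rest distance {site_dists.max():.2f} "
            f"exceeds site radius {site_radius}"
        )
    role[site_atoms] = "na_site"

    # --- substrate site: two cross-bundle atom pairs a few residues above the
    # ion site, on the site helices and their ring neighbours.
    def nearest_plain(atoms, target):
        cand = [a for a in atoms if role[a] == "plain"]
        d = np.linalg.norm(coords[cand] - target, axis=1)
        return cand[int(d.argmin())]

    above = ion_pos + np.array([0.0, 0.0, 3.0])
    h3_atoms = np.flatnonzero(helix_id == 3)  # bundle 1 neighbour
    hH_atoms = np.flatnonzero(helix_id == H)  # bundle 2 neighbour
    sub = [
        nearest_plain(h1_atoms, above),
        nearest_plain(h2_atoms, above),
        nearest_plain(h3_atoms, above),
        nearest_plain(hH_atoms, above),
    ]
    role[sub] = "substrate_site"

    # --- gates: a bundle-1 helix across the ring (near 180 deg) plus the two
    # bundle-2 helices flanking the interface; top beads form the periplasmic
    # gate, bottom beads the cytoplasmic gate.
    def helix_near(angle_deg, bundle):
        best, bestd = None, None
        for hid2, bid2 in helix_bundle.items():
            if bid2 != bundle:
                continue
            phi2 = np.degrees(2 * np.pi * (hid2 - 1) / H) % 360
            d = min(abs(phi2 - angle_deg), 360 - abs(phi2 - angle_deg))
            if bestd is None or d < bestd:
                best, bestd = hid2, d
        return best

    gate_helices = [helix_near(180.0, 1), helix_near(45.0, 2), helix_near(315.0, 2)]

    def extreme_atom(hid2, top: bool):
        atoms = np.flatnonzero(helix_id == hid2)
        z = coords[atoms, 2]
        return atoms[int(z.argmax() if top else z.argmin())]

    for hid2 in gate_helices:
        role[extreme_atom(hid2, True)] = "peri_gate"
        role[extreme_atom(hid2, False)] = "cyto_gate"

    # --- IF reference: rigid rocking of bundle 1 about +y through the origin.
    axis = np.array([0.0, 1.0, 0.0])
    center = np.zeros(3)
    if_coords = coords.copy()
    b1 = np.flatnonzero(bundle_id == 1)
    loops = np.flatnonzero(bundle_id == 0)
    if rocking_angle_deg > 0:
        if_coords[b1] = _rotate_about(coords[b1], axis, rocking_angle_deg, center)
        if_coords[loops] = _rotate_about(coords[loops], axis, rocking_angle_deg / 2.0, center)

    structure = ToyStructure(
        residue_id=residue_id,
        helix_id=helix_id,
        bundle_id=bundle_id,
        role=role,
        coords=coords,
        helix_bundle=helix_bundle,
        ion_present=True,
        ion_position=ion_pos,
        site_radius=site_radius,
    )
    refs = ReferencePair(
        of_coords=coords.copy(),
        if_coords=if_coords,
        rocking_axis=axis,
        rocking_angle_deg=float(rocking_angle_deg),
        rocking_center=center,
    )

    if rocking_angle_deg > 0:
        peri = structure.gate_group("peri_gate")
        cyto = structure.gate_group("cyto_gate")
        peri_of = radius_of_gyration(peri, refs.of_coords)
        peri_if = radius_of_gyration(peri, refs.if_coords)
        cyto_of = radius_of_gyration(cyto, refs.of_coords)
        cyto_if = radius_of_gyration(cyto, refs.if_coords)
        if not (peri_if < peri_of and cyto_if > cyto_of):
            raise GeometryError(
                "gate-Rg ordering violated: "
                f"peri OF={peri_of:.3f} IF={peri_if:.3f}, cyto OF={cyto_of:.3f} IF={cyto_if:.3f}"
            )
    return structure, refs


# ---------------------------------------------------------------------------
# Energy model
# ---------------------------------------------------------------------------


@dataclass
class EnergyModel:
    """Double-basin elastic network + excluded volume + optional ion restraints.

    ``V_total(x) = -(1/beta_mix) * ln(exp(-beta_mix*V_OF) + exp(-beta_mix*V_IF))
                   + V_excl(x) + V_ion(x)``

    Each basin term is ``sum over pairs within cutoff of ½ k (|r_ij| - r_ij^ref)²``
    and vanishes at its own reference.  Coordinates passed to :meth:`energy` /
    :meth:`forces` have shape ``(n_atoms + 1, 3)`` when the ion is present
    (ion last) and ``(n_atoms, 3)`` otherwise.
    """

    structure: ToyStructure
    refs: ReferencePair
    of_pairs: np.ndarray  # (P1, 2) int
    of_rest: np.ndarray  # (P1,)
    of_k: np.ndarray  # (P1,) per-pair spring constants
    if_pairs: np.ndarray
    if_rest: np.ndarray
    if_k: np.ndarray
    k_spring: float  # intra-bundle base constant
    k_cross_scale: float  # scale applied to cross-bundle / loop pairs
    beta_mix: float
    ev_radius: float
    ev_k: float
    k_ion: float
    ion_site_atoms: np.ndarray  # (5,) int
    ion_rest: np.ndarray  # (5,)
    ion_present: bool
    # "harmonic": plain restraints (the restrained-ion equilibrium setup);
    # "breakable": harmonic core out to ion_cap, then a smooth taper to a
    # flat plateau at 2*ion_cap — a coordination bond of finite depth
    # k_ion*ion_cap^2 that can rupture during a driven transition
    ion_style: str = "harmonic"
    ion_cap: float = 1.0
    single_basin: Optional[str] = None  # "of"/"if" for diagnostic single-well use
    # pairs closer than ev_radius in either reference are exempt from excluded
    # volume (they are spring-restrained already); keeps references stationary
    ev_excluded: frozenset = frozenset()

    @property
    def n_particles(self) -> int:
        return self.structure.n_atoms + (1 if self.ion_present else 0)

    def start_coords(self, state: str = "of") -> np.ndarray:
        """Initial particle coordinates (protein reference + ion if present)."""
        base = self.refs.of_coords if state == "of" else self.refs.if_coords
        if self.ion_present:
            return np.vstack([base, self.structure.ion_position[None, :]])
        return base.copy()

    def _check_shape(self, x: np.ndarray) -> None:
        if x.shape != (self.n_particles, 3):
            raise ValueError(
                f"expected coordinates ({self.n_particles}, 3), got {x.shape}"
            )

    def _basin_energy_grad(self, x, pairs, rest, k, want_grad):
        # overflow here only signals divergence; the integrator checks for it
        i, j = pairs[:, 0], pairs[:, 1]
        dvec = x[i] - x[j]
        d = np.linalg.norm(dvec, axis=1)
        dd = d - rest
        V = 0.5 * float((k * dd) @ dd)
        if not want_grad:
            return V, None
        f = (k * dd / np.maximum(d, 1e-12))[:, None] * dvec
        n = x.shape[0]
        g = np.empty_like(x)
        for a in range(3):  # bincount accumulation is much faster than add.at
            g[:, a] = np.bincount(i, weights=f[:, a], minlength=n) - np.bincount(
                j, weights=f[:, a], minlength=n
            )
        return V, g

    def _ev_energy_grad(self, x, want_grad):
        d = cdist(x, x)
        np.fill_diagonal(d, np.inf)
        mask = d < self.ev_radius
        iu = np.triu(mask)
        ii, jj = np.nonzero(iu)
        if self.ev_excluded and len(ii):
            keep = np.array(
                [(int(a), int(b)) not in self.ev_excluded for a, b in zip(ii, jj)]
            )
            ii, jj = ii[keep], jj[keep]
        if len(ii) == 0:
            return 0.0, (np.zeros_like(x) if want_grad else None)
        dd = self.ev_radius - d[ii, jj]
        V = 0.5 * self.ev_k * float(dd @ dd)
        if not want_grad:
            return V, None
        dvec = x[ii] - x[jj]
        f = (-self.ev_k * dd / np.maximum(d[ii, jj], 1e-12))[:, None] * dvec
        n = x.shape[0]
        g = np.empty_like(x)
        for a in range(3):
            g[:, a] = np.bincount(ii, weights=f[:, a], minlength=n) - np.bincount(
                jj, weights=f[:, a], minlength=n
            )
        return V, g

    def _ion_energy_grad(self, x, want_grad):
        if not self.ion_present or self.k_ion == 0.0:
            return 0.0, (np.zeros_like(x) if want_grad else None)
        ion = x[-1]
        site = x[self.ion_site_atoms]
        dvec = ion - site
        d = np.linalg.norm(dvec, axis=1)
        dd = d - self.ion_rest
        k, c = self.k_ion, self.ion_cap
        if self.ion_style == "harmonic":
            v_each = 0.5 * k * dd**2
            dv_each = k * dd
        else:  # breakable: harmonic core, smooth taper, flat plateau
            a = np.abs(dd)
            sgn = np.sign(dd)
            core = a <= c
            taper = (a > c) & (a < 2 * c)
            v_each = np.where(
                core,
                0.5 * k * dd**2,
                np.where(
                    taper,
                    0.5 * k * c**2 + k * c * (a - c) - 0.5 * k * (a - c) ** 2,
                    k * c**2,
                ),
            )
            dv_each = np.where(
                core, k * dd, np.where(taper, sgn * k * (2 * c - a), 0.0)
            )
        V = float(v_each.sum())
        if not want_grad:
            return V, None
        g = np.zeros_like(x)
        f = (dv_each / np.maximum(d, 1e-12))[:, None] * dvec
        g[-1] = f.sum(axis=0)
        np.subtract.at(g, self.ion_site_atoms, f)
        return V, g

    def with_ion_style(self, style: str, cap: Optional[float] = None) -> "EnergyModel":
        """Copy of the model with a different ion-bond style."""
        import dataclasses

        if style not in ("harmonic", "breakable"):
            raise ValueError(style)
        return dataclasses.replace(
            self, ion_style=style, ion_cap=self.ion_cap if cap is None else float(cap)
        )

    def energy_terms(self, coords) -> dict[str, float]:
        x = np.asarray(coords, dtype=float)
        self._check_shape(x)
        # overflow in a diverging probe run is handled by the caller
        _err = np.seterr(over="ignore", invalid="ignore")
        v_of, _ = self._basin_energy_grad(x, self.of_pairs, self.of_rest, self.of_k, False)
        v_if, _ = self._basin_energy_grad(x, self.if_pairs, self.if_rest, self.if_k, False)
        if self.single_basin == "of":
            v_mix = v_of
        elif self.single_basin == "if":
            v_mix = v_if
        else:
            b = self.beta_mix
            m = min(v_of, v_if)
            v_mix = m - np.log(np.exp(-b * (v_of - m)) + np.exp(-b * (v_if - m))) / b
        v_ev, _ = self._ev_energy_grad(x, False)
        v_ion, _ = self._ion_energy_grad(x, False)
        np.seterr(**_err)
        return {
            "V_OF": v_of,
            "V_IF": v_if,
            "V_mix": v_mix,
            "V_excl": v_ev,
            "V_ion": v_ion,
            "V_total": v_mix + v_ev + v_ion,
        }

    def energy(self, coords) -> float:
        return self.energy_terms(coords)["V_total"]

    def forces(self, coords) -> np.ndarray:
        """-dV/dx, shape like ``coords``."""
        x = np.asarray(coords, dtype=float)
        self._check_shape(x)
        _err = np.seterr(over="ignore", invalid="ignore")
        v_of, g_of = self._basin_energy_grad(x, self.of_pairs, self.of_rest, self.of_k, True)
        v_if, g_if = self._basin_energy_grad(x, self.if_pairs, self.if_rest, self.if_k, True)
        if self.single_basin == "of":
            g_mix = g_of
        elif self.single_basin == "if":
            g_mix = g_if
        else:
            b = self.beta_mix
            m = min(v_of, v_if)
            w_of = np.exp(-b * (v_of - m))
            w_if = np.exp(-b * (v_if - m))
            s = w_of + w_if
            g_mix = (w_of / s) * g_of + (w_if / s) * g_if
        _, g_ev = self._ev_energy_grad(x, True)
        _, g_ion = self._ion_energy_grad(x, True)
        np.seterr(**_err)
        return -(g_mix + g_ev + g_ion)

    def without_ion(self) -> "EnergyModel":
        """Apo variant: same networks, ion particle absent."""
        return EnergyModel(
            structure=self.structure,
            refs=self.refs,
            of_pairs=self.of_pairs,
            of_rest=self.of_rest,
            of_k=self.of_k,
            if_pairs=self.if_pairs,
            if_rest=self.if_rest,
            if_k=self.if_k,
            k_spring=self.k_spring,
            k_cross_scale=self.k_cross_scale,
            beta_mix=self.beta_mix,
            ev_radius=self.ev_radius,
            ev_k=self.ev_k,
            k_ion=0.0,
            ion_site_atoms=self.ion_site_atoms,
            ion_rest=self.ion_rest,
            ion_present=False,
            ion_style=self.ion_style,
            ion_cap=self.ion_cap,
            single_basin=self.single_basin,
            ev_excluded=self.ev_excluded,
        )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.structure.content_hash().encode())
        for arr in (self.of_pairs, self.if_pairs):
            h.update(np.ascontiguousarray(arr, dtype=np.int64).tobytes())
        for arr in (self.of_rest, self.if_rest, self.ion_rest, self.of_k, self.if_k):
            h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        h.update(
            f"{self.k_spring}:{self.k_cross_scale}:{self.beta_mix}:{self.ev_radius}:{self.ev_k}:"
            f"{self.k_ion}:{self.ion_present}:{self.ion_style}:{self.ion_cap}:"
            f"{self.single_basin}".encode()
        )
        return h.hexdigest()[:16]


def _pairs_within_cutoff(coords: np.ndarray, cutoff: float):
    d = cdist(coords, coords)
    iu = np.triu_indices_from(d, k=1)
    mask = d[iu] <= cutoff
    pairs = np.column_stack([iu[0][mask], iu[1][mask]]).astype(np.intp)
    rest = d[iu][mask]
    return pairs, rest


def _check_bundle_connectivity(structure: ToyStructure, pairs: np.ndarray, which: str):
    n = structure.n_atoms
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    ).tocsr()
    adj = adj + adj.T
    for b in (1, 2):
        atoms = structure.bundle_atoms(b)
        sub = adj[atoms][:, atoms]
        ncomp, _ = connected_components(sub, directed=False)
        if ncomp != 1:
            raise ValueError(
                f"ENM cutoff leaves bundle {b} disconnected in the {which} basin "
                f"({ncomp} components); increase the cutoff"
            )


def build_energy_model(
    structure: ToyStructure,
    refs: ReferencePair,
    enm_cutoff: float = 10.0,
    k_spring: float = 10.0,
    beta_mix: float = 2.0,
    k_ion: float = 200.0,
    ev_radius: float = 1.0,
    ev_k: float = 10.0,
    k_cross_scale: float = 1.0,
    enm_sigma: float = 1.5,
    cross_cutoff: float = 4.5,
    loop_scale: float = 0.3,
    ion_present: Optional[bool] = None,
    ion_style: str = "harmonic",
    ion_cap: float = 1.0,
    single_basin: Optional[str] = None,
) -> EnergyModel:
    """Assemble the double-basin ENM with ion-site restraints.

    Springs between atoms of the same bundle carry ``k_spring``; pairs that
    cross the bundle interface or involve loop particles carry
    ``k_spring * k_cross_scale`` — the rocking-bundle premise (rigid bundles,
    compliant interface) written into the network.  Rest lengths for the five
    ion restraints are the OF-reference distances from the ion position to
    the tagged site atoms.  Raises if the cutoff leaves either bundle's
    network disconnected in either basin.
    """
    if refs.of_coords.shape[0] != structure.n_atoms:
        raise ValueError("reference pair not congruent with structure")
    if enm_cutoff <= 0 or k_spring <= 0 or beta_mix <= 0 or k_ion < 0:
        raise ValueError("enm_cutoff, k_spring, beta_mix must be > 0 and k_ion >= 0")
    if single_basin not in (None, "of", "if"):
        raise ValueError("single_basin must be None, 'of' or 'if'")
    def build_basin(ref):
        pairs, rest = _pairs_within_cutoff(ref, enm_cutoff)
        b = structure.bundle_id
        same = (b[pairs[:, 0]] == b[pairs[:, 1]]) & (b[pairs[:, 0]] != 0)
        loopy = (b[pairs[:, 0]] == 0) | (b[pairs[:, 1]] == 0)
        # inter-bundle pairs are native contacts: short-range only
        keep = same | loopy | (rest <= cross_cutoff)
        pairs, rest, same, loopy = pairs[keep], rest[keep], same[keep], loopy[keep]
        # intra-bundle springs are flat (rigid bundles, the rocking-bundle
        # premise); inter-bundle contacts carry a distance-weighted constant
        # (Gaussian decay, normalized at the Cα virtual-bond length), which
        # concentrates the inter-bundle coupling at the tight ion-site
        # interface; loops are flexible linkers with a damped constant
        decay = np.minimum(np.exp(-(rest**2 - _HELIX_RISE**2) / enm_sigma**2), 1.0)
        k = np.where(
            loopy,
            k_spring * loop_scale * decay,
            np.where(same, k_spring, k_spring * k_cross_scale * decay),
        )
        return pairs, rest, k

    of_pairs, of_rest, of_k = build_basin(refs.of_coords)
    if_pairs, if_rest, if_k = build_basin(refs.if_coords)
    _check_bundle_connectivity(structure, of_pairs, "OF")
    _check_bundle_connectivity(structure, if_pairs, "IF")
    if (of_rest <= 0).any() or (if_rest <= 0).any():
        raise ValueError("coincident atoms give non-positive spring rest lengths")
    site = structure.atoms_with_role("na_site")
    ion_rest = np.linalg.norm(refs.of_coords[site] - structure.ion_position, axis=1)
    present = structure.ion_present if ion_present is None else bool(ion_present)
    excl = set()
    for ref in (refs.of_coords, refs.if_coords):
        d = cdist(ref, ref)
        iu = np.triu_indices_from(d, k=1)
        close = d[iu] < ev_radius
        excl.update(zip(iu[0][close].tolist(), iu[1][close].tolist()))
    if structure.ion_position is not None:
        d_ion = np.linalg.norm(refs.of_coords - structure.ion_position, axis=1)
        for a in np.flatnonzero(d_ion < ev_radius):
            excl.add((int(a), structure.n_atoms))
    return EnergyModel(
        structure=structure,
        refs=refs,
        of_pairs=of_pairs,
        of_rest=of_rest,
        of_k=of_k,
        if_pairs=if_pairs,
        if_rest=if_rest,
        if_k=if_k,
        k_spring=float(k_spring),
        k_cross_scale=float(k_cross_scale),
        beta_mix=float(beta_mix),
        ev_radius=float(ev_radius),
        ev_k=float(ev_k),
        k_ion=float(k_ion),
        ion_site_atoms=site,
        ion_rest=ion_rest,
        ion_present=present,
        ion_style=ion_style,
        ion_cap=float(ion_cap),
        single_basin=single_basin,
        ev_excluded=frozenset(excl),
    )
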