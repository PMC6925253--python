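"""Steering-protocol catalogue for the OF -> IF transition.

The biasing CV vocabulary mirrors the standard catalogue for driven
transporter transitions:

- ``d``  — the ion-site interface distance, represented as two cross-bundle
  Cα–Cα pair distances between site atoms (one pair per bundle-1 site atom).
- ``theta`` — segment orientation angles: each site helix is split into an
  extracellular (top) and intracellular (bottom) half, and each half carries
  an orientation-quaternion angle CV measured against the OF reference; four
  angles in total (the moving-bundle helix rotates by the rocking angle, the
  fixed-bundle helix stays at zero).
- ``rmsd`` — RMSD of the two site helices to the IF reference after
  superposition on bundle 2.

Targets are always the values the CV takes in the IF reference, so a protocol
drags the system from its OF values to its IF values over ``duration`` steps
and then holds the bias fixed for ``hold`` steps (restrained relaxation).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .colvars import AtomGroup, CVSpec, evaluate_cv
from .dynamics import SteeringProtocol
from .model import ReferencePair, ToyStructure

__all__ = [
    "site_distance_specs",
    "segment_orientation_specs",
    "site_helix_rmsd_spec",
    "make_protocol",
    "default_protocol_suite",
]

# Defaults tuned once on the default model so the combined d+theta protocol
# drives a complete transition on test timescales; the same constants are used
# for every condition being compared.  Gentle force constants matter: a stiff
# bias on a small atom group deforms the helices locally instead of steering
# the collective rocking mode.
DEFAULT_DURATION = 16000
DEFAULT_HOLD = 12000
DEFAULT_K_DIST = 35.0
DEFAULT_K_THETA = 3.0
DEFAULT_K_RMSD = 20.0


def _split_halves(structure: ToyStructure, helix: int) -> tuple[AtomGroup, AtomGroup]:
    """Extracellular (top) / intracellular (bottom) halves of a helix.

    Even split by z-sorted residue list; the extra residue of an odd-length
    helix goes to the extracellular half.
    """
    atoms = structure.helix_atoms(helix)
    z = structure.coords[atoms, 2]
    order = atoms[np.argsort(z)]
    n = len(order)
    n_top = (n + 1) // 2
    bottom, top = order[: n - n_top], order[n - n_top :]
    return structure.group(top), structure.group(bottom)


def site_distance_specs(structure: ToyStructure) -> list[CVSpec]:
    """The interface-distance ("d") CV set: separation of the two halves of
    the ion site, plus the distance between mid-segments of the two site
    helices (the toy's TM1-TM8 distance).

    Group centroids rather than single-atom pairs carry the bias so the
    steering force is spread over several beads and cannot rip individual
    atoms out of a helix.
    """
    site = structure.atoms_with_role("na_site")
    b1 = tuple(int(a) for a in site if structure.bundle_id[a] == 1)
    b2 = tuple(int(a) for a in site if structure.bundle_id[a] == 2)
    specs = [
        CVSpec(
            kind="com_distance",
            group=AtomGroup(b1),
            group_b=AtomGroup(b2),
            name="site_separation",
        )
    ]
    h_b1, h_b2 = structure.site_helices
    segs = []
    for h in (h_b1, h_b2):
        atoms = structure.helix_atoms(h)
        z = np.abs(structure.coords[atoms, 2])
        segs.append(tuple(sorted(int(a) for a in atoms[z.argsort()[:4]])))
    specs.append(
        CVSpec(
            kind="com_distance",
            group=AtomGroup(segs[0]),
            group_b=AtomGroup(segs[1]),
            name="tm_mid_distance",
        )
    )
    return specs


def segment_orientation_specs(
    structure: ToyStructure, refs: ReferencePair
) -> list[CVSpec]:
    """Four orientation-angle CVs: top/bottom halves of each site helix,
    measured against the OF reference."""
    h_b1, h_b2 = structure.site_helices
    specs = []
    for helix, label in ((h_b1, "m"), (h_b2, "f")):  # moving / fixed bundle
        top, bottom = _split_halves(structure, helix)
        # measured against the IF reference: steering drives the angle to 0,
        # which pins the full target orientation (axis and magnitude) rather
        # than just a rotation magnitude
        specs.append(
            CVSpec(kind="orientation_angle", group=top, ref_coords=refs.if_coords,
                   name=f"theta_{label}e")
        )
        specs.append(
            CVSpec(kind="orientation_angle", group=bottom, ref_coords=refs.if_coords,
                   name=f"theta_{label}i")
        )
    return specs


def site_helix_rmsd_spec(structure: ToyStructure, refs: ReferencePair) -> CVSpec:
    """RMSD of the two site helices to the IF reference, fit on bundle 2."""
    h_b1, h_b2 = structure.site_helices
    atoms = np.concatenate([structure.helix_atoms(h_b1), structure.helix_atoms(h_b2)])
    return CVSpec(
        kind="rmsd",
        group=structure.group(atoms),
        fit_group=structure.bundle_group(2),
        ref_coords=refs.if_coords,
        name="rmsd_site_helices",
    )


def make_protocol(
    structure: ToyStructure,
    refs: ReferencePair,
    kind: str,
    duration: int = DEFAULT_DURATION,
    hold: int = DEFAULT_HOLD,
    k_dist: float = DEFAULT_K_DIST,
    k_theta: float = DEFAULT_K_THETA,
    k_rmsd: float = DEFAULT_K_RMSD,
) -> SteeringProtocol:
    """Build a named steering protocol: ``"dtheta"``, ``"theta"``, ``"d"``
    or ``"rmsd"``; start values are evaluated on the OF reference and targets
    on the IF reference."""
    terms: list[tuple[CVSpec, float, float, float]] = []

    def add(spec: CVSpec, k: float):
        start = evaluate_cv(spec, refs.of_coords)
        end = evaluate_cv(spec, refs.if_coords)
        terms.append((spec, start, end, k))

    if kind in ("dtheta", "d"):
        for spec in site_distance_specs(structure):
            add(spec, k_dist)
    if kind in ("dtheta", "theta"):
        for spec in segment_orientation_specs(structure, refs):
            add(spec, k_theta)
    if kind == "rmsd":
        add(site_helix_rmsd_spec(structure, refs), k_rmsd)
    if not terms:
        raise ValueError(f"unknown protocol kind {kind!r}")
    return SteeringProtocol(terms=tuple(terms), duration=int(duration), hold=int(hold),
                            name=kind)


def default_protocol_suite(
    structure: ToyStructure,
    refs: ReferencePair,
    duration: int = DEFAULT_DURATION,
    hold: int = DEFAULT_HOLD,
) -> list[SteeringProtocol]:
    """The protocols compared by default: the optimal combined d+theta
    protocol and the orientation-only control."""
    return [
        make_protocol(structure, refs, "dtheta", duration, hold),
        make_protocol(structure, refs, "theta", duration, hold),
    ]
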