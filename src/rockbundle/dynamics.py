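"""Equilibrium and steered overdamped Langevin dynamics with work accounting.

Integrator: first-order (overdamped) Euler–Maruyama,

    x_{t+1} = x_t + (Δt/γ) F(x_t) + sqrt(2 kT Δt / γ) ξ,   ξ ~ N(0, 1)

appropriate for a Cα-bead model with no inertial dynamics of interest.
Steering applies a time-dependent harmonic bias on a set of collective
variables, ``U(x, t) = Σ ½ k_cv (CV(x) − c(t))²`` with centers moving linearly
from start to end over the steering phase and held fixed during an optional
relaxation ("hold") phase.

Nonequilibrium work is accumulated with the force-free bookkeeping identity:
at every center update the increment is ``U(x_t, c_{t+1}) − U(x_t, c_t)``,
which is exact for stepwise schedules (no quadrature error).  The hold phase
adds no work by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .colvars import CVSpec, cv_value_and_gradient, evaluate_cv, radius_of_gyration
from .model import EnergyModel, ReferencePair, ToyStructure

__all__ = [
    "Tethers",
    "scaffold_tethers",
    "Trajectory",
    "SteeringProtocol",
    "WorkProfile",
    "ProtocolResult",
    "run_equilibrium",
    "run_steered",
    "jarzynski_estimate",
    "check_completion",
    "run_protocol_suite",
    "auto_timestep",
    "recompute_work",
    "EnergyDivergenceError",
]

_DIVERGENCE_THRESHOLD = 1e8


@dataclass(frozen=True)
class Tethers:
    """Static scaffold restraints for driven runs: positional tethers on the
    fixed bundle plus a radial confinement wall.

    Models the environment a membrane-embedded protein sits in: the fixed
    bundle cannot translate or tumble (tethers) and no helix can escape
    laterally into the lipid (half-harmonic wall on the cylinder radius
    about the z axis).  Both terms are time-independent, so they perform no
    nonequilibrium work.
    """

    indices: tuple[int, ...]
    k: float
    positions: np.ndarray  # (len(indices), 3)
    wall_radius: float = 0.0  # 0 disables the wall
    wall_k: float = 0.0

    def forces(self, x: np.ndarray) -> np.ndarray:
        f = np.zeros_like(x)
        idx = np.asarray(self.indices, dtype=np.intp)
        if len(idx):
            f[idx] = -self.k * (x[idx] - self.positions)
        if self.wall_radius > 0 and self.wall_k > 0:
            r = np.sqrt(x[:, 0] ** 2 + x[:, 1] ** 2)
            over = r - self.wall_radius
            mask = over > 0
            if mask.any():
                scale = -self.wall_k * over[mask] / np.maximum(r[mask], 1e-12)
                f[mask, 0] += scale * x[mask, 0]
                f[mask, 1] += scale * x[mask, 1]
        return f

    def energy(self, x: np.ndarray) -> float:
        v = 0.0
        idx = np.asarray(self.indices, dtype=np.intp)
        if len(idx):
            d = x[idx] - self.positions
            v += 0.5 * self.k * float((d * d).sum())
        if self.wall_radius > 0 and self.wall_k > 0:
            r = np.sqrt(x[:, 0] ** 2 + x[:, 1] ** 2)
            over = np.maximum(r - self.wall_radius, 0.0)
            v += 0.5 * self.wall_k * float(over @ over)
        return v


def scaffold_tethers(
    structure,
    refs,
    k: float = 50.0,
    wall_margin: float = 1.0,
    wall_k: float = 5.0,
) -> Tethers:
    """Driven-run scaffold: tether every fixed-bundle (bundle 2) atom to its
    reference position and confine all particles inside a radial wall just
    outside the reference envelope."""
    idx = tuple(int(i) for i in structure.bundle_atoms(2))
    r_max = max(
        float(np.sqrt((refs.of_coords[:, :2] ** 2).sum(axis=1)).max()),
        float(np.sqrt((refs.if_coords[:, :2] ** 2).sum(axis=1)).max()),
    )
    return Tethers(
        indices=idx,
        k=float(k),
        positions=refs.of_coords[list(idx)].copy(),
        wall_radius=r_max + float(wall_margin),
        wall_k=float(wall_k),
    )


class EnergyDivergenceError(RuntimeError):
    def __init__(self, step: int, energy: float):
        self.step = step
        self.energy = energy
        super().__init__(
            f"energy diverged at step {step} (V = {energy:.3g}); reduce the time step"
        )


@dataclass
class Trajectory:
    """Ordered frames of particle coordinates with time metadata.

    ``frames`` has shape (F, N, 3) where N includes the ion particle (last
    row) when ``ion_present``.  ``protein_frames`` strips the ion.
    """

    frames: np.ndarray
    dt: float
    stride: int
    seed: int
    ion_present: bool
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be (F >= 1, N, 3)")
        if not np.isfinite(self.frames).all():
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt * self.stride

    @property
    def protein_frames(self) -> np.ndarray:
        return self.frames[:, :-1, :] if self.ion_present else self.frames


@dataclass(frozen=True)
class SteeringProtocol:
    """Time-dependent harmonic bias: linear center schedule per CV, then hold.

    ``terms`` is an ordered list of (CVSpec, start, end, k_cv).
    """

    terms: tuple[tuple[CVSpec, float, float, float], ...]
    duration: int
    hold: int = 0
    name: str = ""

    def __post_init__(self):
        if self.duration < 1:
            raise ValueError("duration must be >= 1 step")
        if self.hold < 0:
            raise ValueError("hold must be >= 0")
        for _, a, b, k in self.terms:
            if not (np.isfinite(a) and np.isfinite(b)):
                raise ValueError("start/end CV values must be finite")
            if k < 0:
                raise ValueError("force constants must be >= 0")

    @property
    def total_steps(self) -> int:
        return self.duration + self.hold

    def centers(self, step: int) -> np.ndarray:
        """Bias centers at integer step (clamped to the end values in the hold)."""
        f = min(max(step, 0), self.duration) / self.duration
        return np.array([a + (b - a) * f for _, a, b, _ in self.terms])

    def bias_energy(self, coords, step: int) -> float:
        c = self.centers(step)
        u = 0.0
        for (spec, _, _, k), ci in zip(self.terms, c):
            if k == 0.0:
                continue
            u += 0.5 * k * (evaluate_cv(spec, coords) - ci) ** 2
        return u


@dataclass
class WorkProfile:
    """Cumulative nonequilibrium work and the CV/center record of a steered run."""

    work: np.ndarray  # (T+1,) cumulative, work[0] = 0
    cv_values: np.ndarray  # (T+1, n_cv)
    centers: np.ndarray  # (T+1, n_cv)
    dt: float

    @property
    def total(self) -> float:
        return float(self.work[-1])


def auto_timestep(
    model: EnergyModel,
    start_coords,
    friction: float = 1.0,
    temperature: float = 1.0,
    candidates: Sequence[float] = (0.02, 0.01, 0.005, 0.002, 0.001, 0.0005),
    probe_steps: int = 1000,
    seed: int = 0,
) -> float:
    """Largest candidate Δt whose short probe run does not diverge in energy.

    The probe accepts a Δt when the final potential energy stays within a
    generous band of the thermal expectation (no blow-up).
    """
    x0 = np.asarray(start_coords, dtype=float)
    v0 = model.energy(x0)
    ndof = 3 * x0.shape[0]
    bound = abs(v0) + 10.0 * ndof * max(temperature, 1e-6) + 100.0
    for dt in candidates:
        try:
            traj = run_equilibrium(
                model, x0, probe_steps, dt, friction, temperature, seed, stride=probe_steps
            )
            if model.energy(traj.frames[-1]) < bound:
                return dt
        except (EnergyDivergenceError, FloatingPointError):
            continue
    raise RuntimeError("no stable time step found; model is too stiff for the ladder")


def _integrate(
    model: EnergyModel,
    x0: np.ndarray,
    n_steps: int,
    dt: float,
    friction: float,
    temperature: float,
    rng: np.random.Generator,
    stride: int,
    extra_force: Optional[Callable[[np.ndarray, int], np.ndarray]] = None,
    frozen: Optional[np.ndarray] = None,
    tethers: Optional["Tethers"] = None,
    noiseless: Optional[np.ndarray] = None,
    callback: Optional[Callable[[int, np.ndarray], None]] = None,
):
    x = np.array(x0, dtype=float, copy=True)
    mob = dt / friction
    noise_amp = np.sqrt(2.0 * temperature * dt / friction)
    frames = [x.copy()]
    for t in range(n_steps):
        if callback is not None:
            callback(t, x)
        f = model.forces(x)
        if tethers is not None:
            f = f + tethers.forces(x)
        if extra_force is not None:
            f = f + extra_force(x, t)
        step = mob * f
        if noise_amp > 0:
            noise = noise_amp * rng.standard_normal(x.shape)
            if noiseless is not None:
                noise[noiseless] = 0.0
            step = step + noise
        if frozen is not None:
            step[frozen] = 0.0
        x += step
        if not np.isfinite(x).all():
            raise EnergyDivergenceError(t, float("inf"))
        if (t + 1) % 200 == 0:
            v = model.energy(x)
            if not np.isfinite(v) or abs(v) > _DIVERGENCE_THRESHOLD:
                raise EnergyDivergenceError(t, v)
        if (t + 1) % stride == 0:
            frames.append(x.copy())
    if callback is not None:
        callback(n_steps, x)
    return np.array(frames), x


def run_equilibrium(
    model: EnergyModel,
    start_coords,
    n_steps: int,
    dt: float = 0.005,
    friction: float = 1.0,
    temperature: float = 1.0,
    seed: int = 0,
    stride: int = 10,
    frozen: Optional[np.ndarray] = None,
    tethers: Optional[Tethers] = None,
    noiseless: Optional[np.ndarray] = None,
) -> Trajectory:
    """Unbiased overdamped Langevin run; deterministic for a given seed.

    ``noiseless`` marks particles integrated without thermal noise (they
    relax deterministically on the potential): used for the ion, whose fast
    solvent-slaved fluctuations are adiabatically eliminated.
    """
    rng = np.random.default_rng(seed)
    frames, _ = _integrate(
        model, start_coords, int(n_steps), dt, friction, temperature, rng, int(stride),
        frozen=frozen, tethers=tethers, noiseless=noiseless,
    )
    return Trajectory(
        frames=frames,
        dt=dt,
        stride=int(stride),
        seed=int(seed),
        ion_present=model.ion_present,
        provenance={"model": model.content_hash(), "protocol": "equilibrium"},
    )


def run_steered(
    model: EnergyModel,
    start_coords,
    protocol: SteeringProtocol,
    dt: float = 0.005,
    friction: float = 1.0,
    temperature: float = 1.0,
    seed: int = 0,
    stride: int = 10,
    frozen: Optional[np.ndarray] = None,
    tethers: Optional[Tethers] = None,
) -> tuple[Trajectory, WorkProfile]:
    """Steered run under ``protocol``; returns the trajectory and work profile.

    Work increments are taken at center updates only, so a static schedule
    (start == end) or a zero force constant accumulates exactly zero work, and
    the hold phase never does work.
    """
    rng = np.random.default_rng(seed)
    T = protocol.total_steps
    n_cv = len(protocol.terms)
    work = np.zeros(T + 1)
    cv_vals = np.zeros((T + 1, n_cv))
    cens = np.zeros((T + 1, n_cv))
    ks = np.array([k for _, _, _, k in protocol.terms])
    # precomputed center schedule: rows t = 0..T
    frac = np.minimum(np.arange(T + 1), protocol.duration) / protocol.duration
    starts = np.array([a for _, a, _, _ in protocol.terms])
    ends = np.array([b for _, _, b, _ in protocol.terms])
    schedule = starts[None, :] + (ends - starts)[None, :] * frac[:, None]

    state = {"w": 0.0, "t": -1, "v": None, "g": None}

    def callback(t: int, x: np.ndarray):
        # invoked with x = x_t before the dynamics step; the center update
        # c(t) -> c(t+1) is applied at this configuration
        ci = schedule[t]
        vg = [cv_value_and_gradient(spec, x) for spec, _, _, _ in protocol.terms]
        v = np.array([val for val, _ in vg])
        state["t"], state["v"] = t, v  # reused by the force evaluation below
        state["g"] = [g for _, g in vg]
        work[t] = state["w"]
        cv_vals[t] = v
        cens[t] = ci
        if t < T:
            c_next = schedule[t + 1]
            du = 0.5 * ks * ((v - c_next) ** 2 - (v - ci) ** 2)
            state["w"] += float(du.sum())

    def extra_force(x: np.ndarray, t: int) -> np.ndarray:
        # bias active at the updated centers c(t+1) between bookkeeping points;
        # CV values and gradients were just computed here by the callback
        ci = schedule[t + 1]
        if state["t"] == t:
            vs, gs = state["v"], state["g"]
        else:  # pragma: no cover - defensive
            vg = [cv_value_and_gradient(spec, x) for spec, _, _, _ in protocol.terms]
            vs = np.array([val for val, _ in vg])
            gs = [g for _, g in vg]
        f = np.zeros_like(x)
        for (spec, _, _, k), c, v, g in zip(protocol.terms, ci, vs, gs):
            if k == 0.0:
                continue
            f -= k * (v - c) * g
        return f

    frames, _ = _integrate(
        model, start_coords, T, dt, friction, temperature, rng, int(stride),
        extra_force=extra_force, frozen=frozen, tethers=tethers, callback=callback,
    )
    traj = Trajectory(
        frames=frames,
        dt=dt,
        stride=int(stride),
        seed=int(seed),
        ion_present=model.ion_present,
        provenance={
            "model": model.content_hash(),
            "protocol": protocol.name or "steered",
            "duration": protocol.duration,
            "hold": protocol.hold,
        },
    )
    profile = WorkProfile(work=work, cv_values=cv_vals, centers=cens, dt=dt)
    return traj, profile


def recompute_work(protocol: SteeringProtocol, frames: np.ndarray) -> float:
    """Post-hoc total work from a stride-1 trajectory and the schedule.

    ``frames[t]`` must be the configuration at which the center update
    ``c(t) -> c(t+1)`` was applied (i.e. the trajectory saved every step).
    """
    frames = np.asarray(frames)
    if frames.shape[0] != protocol.total_steps + 1:
        raise ValueError(
            "post-hoc work needs a stride-1 trajectory with "
            f"{protocol.total_steps + 1} frames, got {frames.shape[0]}"
        )
    w = 0.0
    for t in range(1, protocol.total_steps + 1):
        w += protocol.bias_energy(frames[t - 1], t) - protocol.bias_energy(frames[t - 1], t - 1)
    return w


def jarzynski_estimate(
    works: Sequence[float],
    temperature: float = 1.0,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Free-energy difference from the exponential work average,
    ``ΔF = −kT ln⟨exp(−W/kT)⟩``, with a bootstrap standard error.

    By Jensen's inequality the estimate never exceeds the sample mean work.
    """
    w = np.asarray(list(works), dtype=float)
    if w.size < 2:
        raise ValueError("need >= 2 work values")
    kT = float(temperature)
    est = -kT * (logsumexp(-w / kT) - np.log(w.size))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, w.size, size=(int(n_bootstrap), w.size))
    boots = -kT * (logsumexp(-w[idx] / kT, axis=1) - np.log(w.size))
    return float(est), float(boots.std(ddof=1))


def check_completion(
    traj: Trajectory,
    structure: ToyStructure,
    refs: ReferencePair,
    tol_fraction: float = 0.10,
    hold_frames: Optional[int] = None,
) -> str:
    """Transition verdict from the gate radii of gyration.

    Averaged over the final hold segment (or the last 10% of frames when no
    hold length is given), the run is ``"complete"`` when both gate Rg values
    lie within ``tol_fraction`` of their IF-reference values and the opening
    pattern holds (cytoplasmic gate wider than in OF, periplasmic gate tighter
    than in OF); ``"partial"`` when exactly one gate satisfies its criterion;
    ``"none"`` otherwise.
    """
    peri = structure.gate_group("peri_gate")
    cyto = structure.gate_group("cyto_gate")
    frames = traj.protein_frames
    if hold_frames is None:
        hold_frames = max(1, frames.shape[0] // 10)
    hold_frames = min(hold_frames, frames.shape[0])
    seg = frames[-hold_frames:]
    peri_rg = float(np.mean([radius_of_gyration(peri, f) for f in seg]))
    cyto_rg = float(np.mean([radius_of_gyration(cyto, f) for f in seg]))
    peri_if = radius_of_gyration(peri, refs.if_coords)
    cyto_if = radius_of_gyration(cyto, refs.if_coords)
    peri_of = radius_of_gyration(peri, refs.of_coords)
    cyto_of = radius_of_gyration(cyto, refs.of_coords)
    peri_ok = abs(peri_rg - peri_if) <= tol_fraction * peri_if and peri_rg < peri_of
    cyto_ok = abs(cyto_rg - cyto_if) <= tol_fraction * cyto_if and cyto_rg > cyto_of
    if peri_ok and cyto_ok:
        return "complete"
    if peri_ok or cyto_ok:
        return "partial"
    return "none"


@dataclass
class ProtocolResult:
    """One steered replica: protocol x condition x seed."""

    protocol: str
    condition: str  # "bound" | "apo"
    replica: int
    seed: int
    verdict: str  # "complete" | "partial" | "none" | "failed"
    total_work: float
    error: str = ""


def run_protocol_suite(
    model_bound: EnergyModel,
    model_apo: EnergyModel,
    protocols: Sequence[SteeringProtocol],
    replicas: int | dict[str, int] = 3,
    seed_base: int = 1000,
    dt: float = 0.005,
    dt_bound: Optional[float] = None,
    friction: float = 1.0,
    temperature: float = 1.0,
    tol_fraction: float = 0.10,
    stride: int = 50,
    tethers: Optional[Tethers] = None,
) -> list[ProtocolResult]:
    """Steer every protocol in both conditions with seed-paired replicas.

    Seeds are paired across the bound/apo arms (replica r of protocol p uses
    the same seed in both conditions) for variance reduction in the work
    comparison.  Per-replica failures are recorded as ``verdict="failed"``
    rather than aborting the suite.
    """
    if not protocols:
        raise ValueError("need >= 1 protocol")
    results: list[ProtocolResult] = []
    for p_idx, protocol in enumerate(protocols):
        n_rep = replicas[protocol.name] if isinstance(replicas, dict) else int(replicas)
        for r in range(n_rep):
            seed = int(seed_base + 100 * p_idx + r)
            for condition, model in (("bound", model_bound), ("apo", model_apo)):
                step = dt_bound if (condition == "bound" and dt_bound) else dt
                try:
                    traj, prof = run_steered(
                        model, model.start_coords("of"), protocol,
                        dt=step, friction=friction, temperature=temperature,
                        seed=seed, stride=stride, tethers=tethers,
                    )
                    hold_frames = max(1, protocol.hold // (stride or 1))
                    verdict = check_completion(
                        traj, model.structure, model.refs, tol_fraction, hold_frames
                    )
                    results.append(
                        ProtocolResult(protocol.name, condition, r, seed, verdict, prof.total)
                    )
                except (EnergyDivergenceError, FloatingPointError, ValueError) as exc:
                    results.append(
                        ProtocolResult(
                            protocol.name, condition, r, seed, "failed", float("nan"), str(exc)
                        )
                    )
    return results


def summarize_suite(results: Sequence[ProtocolResult]) -> list[dict]:
    """Per protocol x condition aggregate: copies, verdicts, mean +/- sd work."""
    rows = []
    keys = sorted({(r.protocol, r.condition) for r in results})
    for prot, cond in keys:
        sub = [r for r in results if r.protocol == prot and r.condition == cond]
        ok = [r for r in sub if r.verdict != "failed"]
        w = np.array([r.total_work for r in ok]) if ok else np.array([])
        verdicts = [r.verdict for r in sub]
        if all(v == "complete" for v in verdicts) and verdicts:
            transition = "yes"
        elif any(v == "complete" for v in verdicts):
            transition = "partial"
        else:
            transition = "no"
        rows.append(
            {
                "protocol": prot,
                "state": cond,
                "copies": len(sub),
                "transition": transition,
                "mean_work": float(w.mean()) if w.size else float("nan"),
                "sd_work": float(w.std(ddof=1)) if w.size > 1 else 0.0,
                "verdicts": verdicts,
            }
        )
    return rows
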