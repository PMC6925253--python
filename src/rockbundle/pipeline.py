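"""End-to-end study pipeline: build -> equilibrium (bound/apo) -> steered
protocol suite -> comparative analyses -> report.

The pipeline reproduces the study design at desk scale: equilibrium runs of
the ion-bound and apo transporter probe how the bound ion restrains the
bundles (distance variance, bundle-relative RMSD, correlation networks,
site-distance distributions), and seed-paired steered OF -> IF transitions
under the combined distance+orientation protocol measure how the ion raises
the nonequilibrium work of the transition.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from . import analysis as ana
from .colvars import AtomGroup, CVSpec, evaluate_cv
from .dynamics import (
    ProtocolResult,
    run_equilibrium,
    run_protocol_suite,
    scaffold_tethers,
    summarize_suite,
)
from .model import build_energy_model, build_toy_transporter
from .protocols import make_protocol

__all__ = ["RunConfig", "ComparisonReport", "run_pipeline", "rank_protocols"]


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_helices_per_bundle: int = 4
    residues_per_helix: int = 10
    rocking_angle_deg: float = 25.0
    loop_residues: int = 3


class EnergyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enm_cutoff: float = 10.0
    k_spring: float = 10.0
    beta_mix: float = 2.0
    k_ion: float = 200.0
    k_cross_scale: float = 1.0
    enm_sigma: float = 1.5
    cross_cutoff: float = 4.5
    loop_scale: float = 0.3
    ev_radius: float = 1.0
    ev_k: float = 10.0


class DynamicsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dt: float = 0.002
    friction: float = 1.0
    temperature: float = 0.5
    equil_dt: float = 0.001
    equil_steps: int = 60000
    equil_stride: int = 100
    equil_replicas: int = 4


class SteeringConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    duration: int = 16000
    hold: int = 12000
    k_dist: float = 35.0
    k_theta: float = 3.0
    tether_k: float = 20.0
    wall_k: float = 5.0
    replicas: dict[str, int] = Field(default_factory=lambda: {"dtheta": 10, "theta": 4})
    stride: int = 100
    tol_fraction: float = 0.10
    ion_bond_cap: float = 0.25


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    contact_cutoff: float = 8.0
    contact_occupancy: float = 0.75


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 1
    model: ModelConfig = Field(default_factory=ModelConfig)
    energy: EnergyConfig = Field(default_factory=EnergyConfig)
    dynamics: DynamicsConfig = Field(default_factory=DynamicsConfig)
    steering: SteeringConfig = Field(default_factory=SteeringConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ComparisonReport:
    """Aggregated bound-vs-apo comparison with the headline verdicts.

    Every verdict is traceable to a numeric entry in the same report.
    """

    config_hash: str
    seed: int
    work: dict
    completion: list
    ranking: dict
    of_stability: dict
    site_stability: dict
    coupling: dict
    verdicts: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        lines = [
            "# Bound-vs-apo comparison report",
            "",
            f"- config hash: `{self.config_hash}`, seed {self.seed}",
            "",
            "## Nonequilibrium work (OF -> IF, d+theta protocol)",
            f"- bound: {self.work['bound_mean']:.1f} +/- {self.work['bound_sd']:.1f} "
            f"(n={self.work['n_pairs']})",
            f"- apo:   {self.work['apo_mean']:.1f} +/- {self.work['apo_sd']:.1f}",
            f"- paired one-sided Wilcoxon p = {self.work['p_value']:.4g}",
            "",
            "## Verdicts",
        ]
        for name, v in self.verdicts.items():
            lines.append(f"- {name}: {'PASS' if v else 'FAIL'}")
        lines.append("")
        lines.append("## Completion table")
        for row in self.completion:
            lines.append(
                f"- {row['protocol']} / {row['state']}: {row['transition']} "
                f"(copies {row['copies']}, mean work {row['mean_work']:.1f})"
            )
        return "\n".join(lines)


def _site_pair_specs(structure) -> list[CVSpec]:
    """Substrate-site pair distances (two cross-bundle pairs)."""
    sub = structure.atoms_with_role("substrate_site")
    b1 = [a for a in sub if structure.bundle_id[a] == 1]
    b2 = [a for a in sub if structure.bundle_id[a] == 2]
    pairs = list(zip(b1, b2))
    return [
        CVSpec(
            kind="com_distance",
            group=AtomGroup((int(a),)),
            group_b=AtomGroup((int(b),)),
            name=f"substrate_pair{i + 1}",
        )
        for i, (a, b) in enumerate(pairs)
    ]


def _tm_distance_spec(structure) -> CVSpec:
    """TM1-TM8 analogue: COM distance between 4-residue mid-segments of the
    two site helices."""
    h_b1, h_b2 = structure.site_helices
    segs = []
    for h in (h_b1, h_b2):
        atoms = structure.helix_atoms(h)
        z = np.abs(structure.coords[atoms, 2])
        segs.append(atoms[z.argsort()[:4]])
    return CVSpec(
        kind="com_distance",
        group=structure.group(sorted(int(a) for a in segs[0])),
        group_b=structure.group(sorted(int(a) for a in segs[1])),
        name="tm1_tm8_distance",
    )


def run_pipeline(config: RunConfig, out_dir: Optional[str] = None) -> ComparisonReport:
    """Execute the full study; deterministic for a given config.

    When ``out_dir`` is given, all artifacts (model PDB/JSON, trajectories,
    CSV summaries, network exports, report JSON/Markdown) are written there.
    """
    from . import io as rio

    out = Path(out_dir) if out_dir is not None else None
    seed = int(config.seed)

    # --- build ------------------------------------------------------------
    structure, refs = build_toy_transporter(
        n_helices_per_bundle=config.model.n_helices_per_bundle,
        residues_per_helix=config.model.residues_per_helix,
        rocking_angle_deg=config.model.rocking_angle_deg,
        seed=seed,
        loop_residues=config.model.loop_residues,
    )
    e = config.energy
    model_bound = build_energy_model(
        structure, refs, enm_cutoff=e.enm_cutoff, k_spring=e.k_spring,
        beta_mix=e.beta_mix, k_ion=e.k_ion, k_cross_scale=e.k_cross_scale,
        enm_sigma=e.enm_sigma, cross_cutoff=e.cross_cutoff,
        loop_scale=e.loop_scale, ev_radius=e.ev_radius, ev_k=e.ev_k,
        ion_present=True,
    )
    model_apo = model_bound.without_ion()
    if out is not None:
        rio.write_structure(structure, refs, out / "model")

    # --- equilibrium runs ---------------------------------------------------
    # seed-paired replicas per condition; the bound arm integrates the ion
    # without thermal noise (its fast solvent-slaved fluctuations are
    # adiabatically eliminated; it still transmits site coupling)
    d = config.dynamics
    tm_spec = _tm_distance_spec(structure)
    sub_specs = _site_pair_specs(structure)
    ref_values = {s.name: evaluate_cv(s, refs.of_coords) for s in sub_specs}
    ref_values[tm_spec.name] = evaluate_cv(tm_spec, refs.of_coords)
    fit_b2 = structure.bundle_group(2)
    quiet_ion = np.array([structure.n_atoms])

    summaries, couplings, rmsd_means = {}, {}, {}
    tm_vars, sub_deltas = {}, {}
    for label, model in (("bound", model_bound), ("apo", model_apo)):
        per_var, per_rmsd, per_coup, per_delta = [], [], [], []
        for rep in range(d.equil_replicas):
            traj = run_equilibrium(
                model, model.start_coords("of"), d.equil_steps, dt=d.equil_dt,
                friction=d.friction, temperature=d.temperature,
                seed=seed * 1000 + rep, stride=d.equil_stride,
                noiseless=quiet_ion if model.ion_present else None,
            )
            burn = traj.n_frames // 5
            frames = traj.protein_frames[burn:]
            summ = ana.ensemble_summary(
                frames, [tm_spec] + sub_specs, ref_values, condition=label
            )
            C = ana.correlation_matrix(frames, fit_b2)
            M = ana.contact_mask(
                frames, config.analysis.contact_cutoff,
                config.analysis.contact_occupancy,
            )
            net = ana.build_network(C, M)
            per_coup.append(ana.interbundle_coupling_score(net, structure)[0])
            per_var.append(summ.sds[tm_spec.name] ** 2)
            per_rmsd.append(
                float(ana.bundle_relative_rmsd(frames, structure, refs, 1, 2).mean())
            )
            per_delta.append(
                {sp.name: summ.reference_deltas[sp.name] for sp in sub_specs}
            )
            if rep == 0:
                summaries[label] = summ
                if out is not None:
                    rio.write_trajectory(traj, out / f"equilibrium_{label}.xyz")
                    rio.write_network(net, out / f"network_{label}")
                    import pandas as pd

                    pd.DataFrame(
                        {name: summ.series[name] for name in summ.names}
                    ).to_csv(out / f"cv_series_{label}.csv", index=False)
        couplings[label] = float(np.mean(per_coup))
        tm_vars[label] = float(np.mean(per_var))
        rmsd_means[label] = float(np.mean(per_rmsd))
        sub_deltas[label] = {
            name: float(np.mean([pd_[name] for pd_ in per_delta]))
            for name in per_delta[0]
        }

    # --- steered suite ------------------------------------------------------
    st = config.steering
    protocols = [
        make_protocol(
            structure, refs, kind, duration=st.duration, hold=st.hold,
            k_dist=st.k_dist, k_theta=st.k_theta,
        )
        for kind in st.replicas
    ]
    tethers = scaffold_tethers(structure, refs, k=st.tether_k, wall_k=st.wall_k)
    # during driven transitions the ion is held by a rupturable coordination
    # bond rather than the permanent restraints of the bound equilibrium setup
    results = run_protocol_suite(
        model_bound.with_ion_style("breakable", cap=st.ion_bond_cap),
        model_apo, protocols,
        replicas=dict(st.replicas),
        seed_base=seed * 10000, dt=d.dt, friction=d.friction,
        temperature=d.temperature, tol_fraction=st.tol_fraction,
        stride=st.stride, tethers=tethers,
    )
    completion = summarize_suite(results)
    ranking = rank_protocols(results)

    # --- work comparison (d+theta, seed-paired) -----------------------------
    flagship = "dtheta" if "dtheta" in st.replicas else protocols[0].name
    wb = _works(results, flagship, "bound")
    wa = _works(results, flagship, "apo")
    n_pairs = min(len(wb), len(wa))
    if n_pairs >= 2 and np.ptp(np.array(wb[:n_pairs]) - np.array(wa[:n_pairs])) >= 0:
        diffs = np.array(wb[:n_pairs]) - np.array(wa[:n_pairs])
        if np.allclose(diffs, 0):
            p_value = 1.0
        else:
            p_value = float(
                stats.wilcoxon(wb[:n_pairs], wa[:n_pairs], alternative="greater").pvalue
            )
    else:
        p_value = float("nan")
    work = {
        "bound_mean": float(np.mean(wb)) if wb else float("nan"),
        "bound_sd": float(np.std(wb, ddof=1)) if len(wb) > 1 else 0.0,
        "apo_mean": float(np.mean(wa)) if wa else float("nan"),
        "apo_sd": float(np.std(wa, ddof=1)) if len(wa) > 1 else 0.0,
        "n_pairs": n_pairs,
        "p_value": p_value,
        "bound_works": wb,
        "apo_works": wa,
    }

    # --- assemble verdicts --------------------------------------------------
    of_stability = {
        "tm_distance_var_bound": tm_vars["bound"],
        "tm_distance_var_apo": tm_vars["apo"],
        "bundle1_rmsd_mean_bound": rmsd_means["bound"],
        "bundle1_rmsd_mean_apo": rmsd_means["apo"],
    }
    site_stability = {
        "deltas_bound": dict(sub_deltas["bound"]),
        "deltas_apo": dict(sub_deltas["apo"]),
        "reference_values": {k: float(v) for k, v in ref_values.items()},
    }
    coupling = {"bound": couplings["bound"], "apo": couplings["apo"]}
    sub_names = [s.name for s in sub_specs]
    verdicts = {
        "barrier_work": bool(
            work["bound_mean"] > work["apo_mean"] and work["p_value"] < 0.05
        ),
        "of_stabilization": bool(
            of_stability["tm_distance_var_bound"] < of_stability["tm_distance_var_apo"]
            and of_stability["bundle1_rmsd_mean_bound"]
            < of_stability["bundle1_rmsd_mean_apo"]
        ),
        "site_stabilization": bool(
            np.mean([site_stability["deltas_bound"][n] for n in sub_names])
            < np.mean([site_stability["deltas_apo"][n] for n in sub_names])
        ),
        "coupling": bool(coupling["bound"] > coupling["apo"]),
    }

    report = ComparisonReport(
        config_hash=config.content_hash(),
        seed=seed,
        work=work,
        completion=completion,
        ranking=ranking,
        of_stability=of_stability,
        site_stability=site_stability,
        coupling=coupling,
        verdicts=verdicts,
    )
    if out is not None:
        report.to_json(out / "report.json")
        (out / "report.md").write_text(report.to_markdown())
        (out / "config.json").write_text(json.dumps(config.model_dump(), indent=2))
    return report


def _works(results: list[ProtocolResult], protocol: str, condition: str) -> list[float]:
    return [
        r.total_work
        for r in sorted(results, key=lambda r: r.replica)
        if r.protocol == protocol and r.condition == condition and r.verdict != "failed"
    ]


def rank_protocols(results: list[ProtocolResult]) -> dict:
    """Rank protocols: only those completing in every replica qualify, sorted
    by ascending mean total work; ties broken by fewer CVs (not tracked here:
    by protocol name).  Non-completing protocols are listed with verdicts.

    Mechanistic relevance — the third selection criterion — is a human
    judgment and is deliberately not scored.
    """
    if not results:
        raise ValueError("need >= 1 protocol result")
    by_protocol: dict[str, list[ProtocolResult]] = {}
    for r in results:
        by_protocol.setdefault(r.protocol, []).append(r)
    qualifying, excluded = [], []
    for name in sorted(by_protocol):
        rs = by_protocol[name]
        verdicts = [r.verdict for r in rs]
        if verdicts and all(v == "complete" for v in verdicts):
            mean_w = float(np.mean([r.total_work for r in rs]))
            qualifying.append({"protocol": name, "mean_work": mean_w})
        else:
            excluded.append(
                {
                    "protocol": name,
                    "verdicts": sorted(set(verdicts)),
                    "transition": (
                        "partial" if "complete" in verdicts or "partial" in verdicts
                        else "no"
                    ),
                }
            )
    qualifying.sort(key=lambda q: (q["mean_work"], q["protocol"]))
    for i, q in enumerate(qualifying):
        q["rank"] = i + 1
    out = {"ranking": qualifying, "non_completing": excluded}
    if not qualifying:
        out["notice"] = "no protocol completed in all replicas"
    return out
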