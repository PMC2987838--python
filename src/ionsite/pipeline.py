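"""End-to-end orchestration: ensemble -> sites -> coordination/geometry ->
SASA/interface -> PB complement scan -> conservation.

A run is fully described by a :class:`PipelineConfig` (deserializable from
TOML); re-running an identical config reproduces the report bundle
bit-for-bit. Each stage flushes its partial output into the bundle and a
stage failure marks dependent stages as skipped instead of aborting the
run.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import conservation as cons
from .electrostatics import (
    IonComplement,
    PBParameters,
    charge_reversal_scan,
)
from .geometry import classify_polyhedron
from .sasa import interface_residues, ion_accessibility, region_net_charge
from .site_detection import detect_sites, site_records, site_report
from .solvation_shell import coordination_summary, water_residence
from .structure_io import (
    Ensemble,
    assign_properties,
    ion_species,
    read_ensemble,
    read_structure,
)
from .synthetic_data import PocketSpec, TrajectorySpec, make_pockets_ensemble

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Serializable description of one analysis run."""

    ensemble_path: str | None = None
    simulate: dict[str, Any] | None = None  # pocket/trajectory specs
    charge_scheme: str = "formal"
    cutoff_overrides: dict[str, float] = field(default_factory=dict)
    cluster_eps: float = 2.5
    min_occupancy: float = 20.0
    distortion_threshold: float | None = None
    sasa_probe: float = 1.4
    sasa_points: int = 960
    delta_sasa_threshold: float = 1.0
    interface_free_path: str | None = None
    interface_complex_paths: list[str] = field(default_factory=list)
    interface_chain: str = "A"
    region_residues: list[list] = field(default_factory=list)  # explicit [resid, resname]
    pb: dict[str, Any] = field(default_factory=dict)
    alignment_path: str | None = None
    alignment_format: str = "fasta"
    alignment_reference: str | None = None
    conservation_positions: list[int] = field(default_factory=list)
    window_fraction: float = 0.8
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class ReportBundle:
    """Everything a run produced, with the config that produced it."""

    config: dict[str, Any]
    stages: dict[str, str] = field(default_factory=dict)
    site_table: pd.DataFrame | None = None
    sites: list[dict[str, Any]] = field(default_factory=list)
    geometry: dict[str, dict[str, Any]] = field(default_factory=dict)
    residence: dict[str, dict[str, float]] = field(default_factory=dict)
    ion_sasa: dict[str, float] = field(default_factory=dict)
    interface: dict[str, Any] | None = None
    ep_table: pd.DataFrame | None = None
    reversal_charge: int | None = None
    conservation_rows: list[dict[str, Any]] = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return any(v.startswith("failed") for v in self.stages.values())

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "stages": self.stages,
            "sites": self.sites,
            "site_table": None
            if self.site_table is None
            else self.site_table.to_dict(orient="records"),
            "geometry": self.geometry,
            "residence": self.residence,
            "ion_sasa": self.ion_sasa,
            "interface": self.interface,
            "ep_table": None
            if self.ep_table is None
            else self.ep_table.to_dict(orient="records"),
            "reversal_charge": self.reversal_charge,
            "conservation": self.conservation_rows,
        }
        return json.dumps(payload, sort_keys=True, indent=2, default=_jsonify)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json() + "\n")
        if self.site_table is not None:
            self.site_table.to_csv(outdir / "sites.tsv", sep="\t", index=False)
        if self.ep_table is not None:
            self.ep_table.to_csv(outdir / "ep_scan.tsv", sep="\t", index=False)
        if self.conservation_rows:
            pd.DataFrame(self.conservation_rows).to_csv(
                outdir / "conservation.tsv", sep="\t", index=False
            )


def _jsonify(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _simulated_ensemble(cfg: PipelineConfig) -> Ensemble:
    spec = cfg.simulate or {}
    pockets = []
    centers = []
    for pk in spec.get("pockets", []):
        pockets.append(
            PocketSpec(
                n_protein_donors=int(pk["donors"]),
                donor_resnames=tuple(pk.get("donor_resnames", ["ASP"])),
                n_first_shell_waters=int(pk["waters"]),
                geometry=pk.get("geometry", "octahedral"),
                bond_length=float(pk.get("bond_length", 2.1)),
                ion=ion_species(pk.get("ion", "MG")),
            )
        )
        centers.append(pk.get("center"))
    tr = spec.get("trajectory", {})
    traj = TrajectorySpec(
        n_frames=int(tr.get("n_frames", 100)),
        occupancy_target=float(tr.get("occupancy", 1.0)),
        jitter_sigma=float(tr.get("jitter_sigma", 0.05)),
        unbound_displacement=float(tr.get("unbound_displacement", 8.0)),
        water_exchange_period=tr.get("water_exchange_period"),
        seed=int(tr.get("seed", cfg.seed)),
    )
    if any(c is None for c in centers):
        centers = None
    else:
        centers = [np.asarray(c, dtype=float) for c in centers]
    return make_pockets_ensemble(pockets, traj, centers)


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run all configured stages and return the report bundle.

    Deterministic given the config (all stochastic stages are seeded from
    it).  A stage that cannot run because its input is not configured is
    marked "skipped"; a stage that raises is marked "failed: <reason>" and
    its dependents are skipped.
    """
    bundle = ReportBundle(config=cfg.to_dict())
    ensemble: Ensemble | None = None
    sites = []

    # --- ensemble -----------------------------------------------------
    try:
        if cfg.ensemble_path:
            ensemble = read_ensemble(cfg.ensemble_path)
        elif cfg.simulate:
            ensemble = _simulated_ensemble(cfg)
        else:
            raise ValueError("config provides neither ensemble_path nor simulate")
        ensemble = Ensemble(
            [assign_properties(fr, charge_scheme=cfg.charge_scheme) for fr in ensemble.frames]
        )
        bundle.stages["ensemble"] = "ok"
    except Exception as exc:  # noqa: BLE001 - stage isolation by design
        bundle.stages["ensemble"] = f"failed: {exc}"

    # --- site detection ----------------------------------------------
    if bundle.stages.get("ensemble") == "ok":
        try:
            sites = detect_sites(
                ensemble,
                eps=cfg.cluster_eps,
                min_occupancy=cfg.min_occupancy,
                cutoff_overrides=cfg.cutoff_overrides or None,
            )
            bundle.sites = [
                {
                    "label": s.label,
                    "centroid": [round(float(v), 3) for v in s.centroid],
                    "occupancy_pct": round(s.occupancy, 1),
                    "species": sorted(s.species),
                    "fingerprint": {
                        f"{c}:{rn}{rid}": round(p, 1)
                        for (c, rid, rn), p in s.fingerprint.items()
                    },
                    "double_site": s.double_site,
                }
                for s in sites
            ]
            bundle.stages["sites"] = "ok"
        except Exception as exc:  # noqa: BLE001
            bundle.stages["sites"] = f"failed: {exc}"
    else:
        bundle.stages["sites"] = "skipped"

    # --- coordination, geometry, residence, ion SASA ------------------
    if bundle.stages.get("sites") == "ok" and sites:
        try:
            n = len(ensemble)
            lo = n - max(1, int(round(cfg.window_fraction * n)))
            summaries = {}
            for site in sites:
                recs = site_records(ensemble, site, cutoff_overrides=cfg.cutoff_overrides or None)
                summ = coordination_summary(recs, window=(lo, n), key=site.label)
                summaries[site.label] = summ
                try:
                    res = water_residence(recs)
                    bundle.residence[site.label] = {
                        f"{c}:{rn}{rid}": round(f, 3)
                        for (c, rid, rn), f in res.fractions.items()
                    }
                except ValueError:
                    bundle.residence[site.label] = {}
                bound = [r for r in recs if r.bound]
                if bound:
                    rec = bound[len(bound) // 2]
                    fr = ensemble.frames[rec.frame_index]
                    xyz = fr.coords
                    lig = np.array([xyz[l.atom_index] for l in rec.ligands])
                    try:
                        ga = classify_polyhedron(
                            xyz[rec.ion_index], lig, threshold=cfg.distortion_threshold
                        )
                        bundle.geometry[site.label] = {
                            "class": ga.geometry_class,
                            "distortion": round(ga.distortion, 3)
                            if np.isfinite(ga.distortion)
                            else None,
                            "cn": ga.cn,
                        }
                    except ValueError:
                        bundle.geometry[site.label] = {"class": "other", "cn": rec.cn_total}
                    bundle.ion_sasa[site.label] = round(
                        ion_accessibility(
                            fr,
                            rec.ion_index,
                            probe=cfg.sasa_probe,
                            n_points=cfg.sasa_points,
                        ),
                        2,
                    )
            bundle.site_table = site_report(sites, summaries)
            bundle.stages["coordination"] = "ok"
        except Exception as exc:  # noqa: BLE001
            bundle.stages["coordination"] = f"failed: {exc}"
    else:
        bundle.stages["coordination"] = "skipped"

    # --- SASA interface ------------------------------------------------
    region = None
    if cfg.interface_free_path and cfg.interface_complex_paths:
        try:
            free = assign_properties(read_structure(cfg.interface_free_path))
            cplx = [
                assign_properties(read_structure(p)) for p in cfg.interface_complex_paths
            ]
            region = interface_residues(
                free,
                cplx,
                chain=cfg.interface_chain,
                threshold=cfg.delta_sasa_threshold,
                probe=cfg.sasa_probe,
                n_points=cfg.sasa_points,
            )
            bundle.interface = {
                "chain": region.chain,
                "n_residues": len(region.residue_keys),
                "residues": [f"{rn}{rid}" for rid, rn in region.residue_keys],
                "net_charge": region.net_charge,
            }
            bundle.stages["interface"] = "ok"
        except Exception as exc:  # noqa: BLE001
            bundle.stages["interface"] = f"failed: {exc}"
    elif cfg.region_residues:
        try:
            keys = [(int(rid), str(rn).upper()) for rid, rn in cfg.region_residues]
            frame0 = ensemble.frames[0] if ensemble else None
            net = region_net_charge(frame0, keys) if frame0 is not None else None
            region = keys
            bundle.interface = {
                "chain": cfg.interface_chain,
                "n_residues": len(keys),
                "residues": [f"{rn}{rid}" for rid, rn in keys],
                "net_charge": net,
            }
            bundle.stages["interface"] = "ok"
        except Exception as exc:  # noqa: BLE001
            bundle.stages["interface"] = f"failed: {exc}"
    else:
        bundle.stages["interface"] = "skipped"

    # --- electrostatics -------------------------------------------------
    if (
        bundle.stages.get("interface") == "ok"
        and bundle.stages.get("sites") == "ok"
        and sites
        and region is not None
        and bundle.stages.get("ensemble") == "ok"
    ):
        try:
            p = PBParameters(**cfg.pb)
            frame0 = ensemble.frames[0]
            solute = frame0.subset(
                [i for i, a in enumerate(frame0.atoms) if not a.is_water and not a.is_ion]
            )
            ordered = sorted(sites, key=lambda s: s.label)
            complements = [IonComplement({s.label: None for s in ordered})]
            for k in range(1, len(ordered) + 1):
                placements = {
                    s.label: (sorted(s.species)[0] if i < k else None)
                    for i, s in enumerate(ordered)
                }
                complements.append(IonComplement(placements))
            scan = charge_reversal_scan(
                solute,
                ordered,
                complements,
                region,
                p,
                chain=cfg.interface_chain,
            )
            bundle.ep_table = scan.table
            bundle.reversal_charge = scan.reversal_charge
            bundle.stages["electrostatics"] = "ok"
        except Exception as exc:  # noqa: BLE001
            bundle.stages["electrostatics"] = f"failed: {exc}"
    else:
        bundle.stages["electrostatics"] = "skipped"

    # --- conservation ----------------------------------------------------
    if cfg.alignment_path:
        try:
            aln = cons.read_alignment(
                cfg.alignment_path, cfg.alignment_format, cfg.alignment_reference
            )
            classes = cons.default_substitution_classes()
            positions = cfg.conservation_positions
            cols = cons.map_reference_positions(aln, positions)
            for pos, col in zip(positions, cols):
                row = cons.column_conservation(
                    aln, col, classes=classes, reference_position=pos
                )
                bundle.conservation_rows.append(
                    {
                        "position": pos,
                        "reference_residue": row.reference_residue,
                        "identity_pct": round(row.identity_pct),
                        "top_substitution": None
                        if row.top_substitution is None
                        else f"{row.top_substitution[0]}: {round(row.top_substitution[1])}",
                    }
                )
            bundle.stages["conservation"] = "ok"
        except Exception as exc:  # noqa: BLE001
            bundle.stages["conservation"] = f"failed: {exc}"
    else:
        bundle.stages["conservation"] = "skipped"

    if cfg.output_dir:
        bundle.write(cfg.output_dir)
    return bundle
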