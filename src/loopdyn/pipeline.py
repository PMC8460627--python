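"""End-to-end orchestration: config -> data -> analyses -> report bundle.

A run compares a loop-mobile ("apo") and a loop-closed ("holo") system:
distance-fluctuation matrices and their difference, region-resolved RMSD
series, stable-contact sets and their conservation, inter-protomer
hydrogen-bond occupancies and the residues stabilized between states, and
the static structure comparisons (loop-opening angle, anchoring contacts,
pocket waters, gaps).

Runs are reproducible from (config, seed) alone, and every threshold the
analyses use is echoed into the provenance record — nothing is applied
silently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crystal import (
    anchoring_contacts,
    conserved_waters,
    loop_opening_angle,
    missing_residues,
    pocket_water_census,
)
from .dynamics import (
    compare_contact_sets,
    compare_hbond_occupancy,
    df_compare,
    df_matrix,
    hbond_occupancy,
    rmsd_series,
    stable_contacts,
)
from .structures import (
    LoopdynError,
    Selection,
    Structure,
    Trajectory,
    pool_trajectories,
    read_structure,
    read_trajectory,
    write_structure,
    write_trajectory,
)
from .synthetic import (
    GroundTruth,
    SyntheticSpec,
    make_toy_complex,
    make_two_state_trajectory,
    rotate_loop,
)

__all__ = ["RunConfig", "StageError", "run"]


class StageError(LoopdynError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Fully serializable description of one analysis run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    # synthetic mode
    n_chains: int = 4
    residues_per_chain: int = 50
    loop_range: tuple[int, int] = (11, 31)
    hinge_pair: tuple[int, int] = (10, 32)
    sigma: float = 0.2
    planted_angle: float = 45.7
    apo_open_fraction: float = 0.5
    holo_open_fraction: float = 0.0
    n_frames: int = 300
    n_replicas: int = 2
    pocket_residues: tuple[int, ...] = (40, 41, 42, 43, 44, 45)
    # files mode
    apo_structure: Optional[str] = None
    holo_structure: Optional[str] = None
    apo_trajectory: Optional[str] = None
    holo_trajectory: Optional[str] = None
    vertex_residue: Optional[int] = None
    # thresholds (all echoed in provenance)
    d_cut: float = 6.0
    f_cut: float = 0.30
    hb_cut: float = 3.5
    delta_cut: float = 0.30
    coord_cut: float = 3.5
    min_contacts: int = 3
    match_tol: float = 1.0
    # bookkeeping
    seed: int = 0
    outdir: str = "loopdyn_out"

    def __post_init__(self) -> None:
        self.loop_range = tuple(int(v) for v in self.loop_range)
        self.hinge_pair = tuple(int(v) for v in self.hinge_pair)
        self.pocket_residues = tuple(int(v) for v in self.pocket_residues)
        if self.mode not in ("synthetic", "files"):
            raise LoopdynError("mode must be 'synthetic' or 'files'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise LoopdynError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("loop_range", "hinge_pair", "pocket_residues"):
            out[key] = list(out[key])
        return out


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _df_to_tsv(dfm, path: Path) -> None:
    names = [f"{c}{s}" for c, s, _n in dfm.labels]
    frame = pd.DataFrame(dfm.values, index=names, columns=names)
    frame.to_csv(path, sep="\t", float_format="%.10g")


def _contacts_to_tsv(cs, path: Path) -> None:
    rows = [{"chain_a": r.residue_a[0], "res_a": r.residue_a[1],
             "name_a": r.residue_a[2], "chain_b": r.residue_b[0],
             "res_b": r.residue_b[1], "name_b": r.residue_b[2],
             "fraction": r.fraction} for r in cs.records]
    pd.DataFrame(rows, columns=["chain_a", "res_a", "name_a", "chain_b",
                                "res_b", "name_b", "fraction"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def _hbonds_to_tsv(records, path: Path) -> None:
    rows = [{"donor": "/".join(map(str, r.donor)),
             "acceptor": "/".join(map(str, r.acceptor)),
             "occupancy": r.occupancy,
             "inter_protomer": r.inter_protomer} for r in records]
    pd.DataFrame(rows, columns=["donor", "acceptor", "occupancy",
                                "inter_protomer"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def _build_synthetic(cfg: RunConfig):
    spec = SyntheticSpec(
        n_chains=cfg.n_chains,
        residues_per_chain=cfg.residues_per_chain,
        loop_range=cfg.loop_range,
        hinge_pair=cfg.hinge_pair,
        sigma=cfg.sigma,
        planted_angle=cfg.planted_angle,
        open_fraction=cfg.apo_open_fraction,
        # plant a 4-coordinated water between each consecutive pocket pair
        planted_waters=tuple(
            (r, 4) for r in sorted(cfg.pocket_residues)[:-1]
            if r + 1 <= cfg.residues_per_chain),
        seed=cfg.seed,
    )
    closed, gt = make_toy_complex(spec)
    open_struct = closed
    for cid in closed.chain_ids:
        open_struct = rotate_loop(open_struct, cid, spec.loop_range,
                                  spec.hinge_pair, spec.planted_angle)
    open_struct.source_id = f"{closed.source_id}-open"

    def replicas(p_open: float, tag: int):
        parts, gts = [], []
        for r in range(cfg.n_replicas):
            traj, tgt = make_two_state_trajectory(
                closed, spec.loop_range, spec.hinge_pair, spec.planted_angle,
                p_open, cfg.n_frames, sigma=cfg.sigma,
                seed=cfg.seed * 1000 + tag * 100 + r)
            parts.append(traj)
            gts.append(tgt)
        return pool_trajectories(parts), gts

    apo_traj, apo_gts = replicas(cfg.apo_open_fraction, tag=1)
    holo_traj, holo_gts = replicas(cfg.holo_open_fraction, tag=2)
    return {
        "spec": spec, "ground_truth": gt,
        "apo_structure": open_struct, "holo_structure": closed,
        "apo_trajectory": apo_traj, "holo_trajectory": holo_traj,
        "apo_gts": apo_gts, "holo_gts": holo_gts,
    }


def _load_files(cfg: RunConfig):
    def need(attr):
        value = getattr(cfg, attr)
        if value is None:
            raise LoopdynError(f"files mode requires '{attr}'")
        return Path(value)

    return {
        "spec": None, "ground_truth": None,
        "apo_structure": read_structure(need("apo_structure").read_text(),
                                        source_id="apo"),
        "holo_structure": read_structure(need("holo_structure").read_text(),
                                         source_id="holo"),
        "apo_trajectory": read_trajectory(need("apo_trajectory").read_text()),
        "holo_trajectory": read_trajectory(need("holo_trajectory").read_text()),
        "apo_gts": None, "holo_gts": None,
    }


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict (also written out)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name):
        log.append(name)

    try:
        stage("inputs")
        data = _build_synthetic(cfg) if cfg.mode == "synthetic" else _load_files(cfg)
    except LoopdynError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("inputs", exc) from exc

    apo_s, holo_s = data["apo_structure"], data["holo_structure"]
    apo_t, holo_t = data["apo_trajectory"], data["holo_trajectory"]
    lo, hi = cfg.loop_range
    loop_sel = Selection.make(residue_ranges=[(lo, hi)], atom_names=["CA"])
    core_sel = Selection.make(residue_ranges=[(1, lo - 1),
                                              (hi + 1, 10 ** 6)],
                              atom_names=["CA"])
    all_ca = Selection.make(atom_names=["CA"])
    summary: dict = {"config": cfg.to_dict(), "version": __version__,
                     "stages": log}

    try:
        stage("df")
        df_apo = df_matrix(apo_t)
        df_holo = df_matrix(holo_t)
        comp = df_compare(df_apo, df_holo)
        _df_to_tsv(df_apo, out / "df_apo.tsv")
        _df_to_tsv(df_holo, out / "df_holo.tsv")
        medians = {
            "apo": {f"{a}-{b}": v for (a, b), v in comp.block_medians_a.items()},
            "holo": {f"{a}-{b}": v for (a, b), v in comp.block_medians_b.items()},
            "delta": {f"{a}-{b}": v
                      for (a, b), v in comp.block_medians_delta.items()},
        }
        _json_dump(medians, out / "df_block_medians.json")
        summary["df_block_medians"] = medians
    except Exception as exc:
        raise StageError("df", exc) from exc

    try:
        stage("rmsd")
        series = {}
        for label, traj, ref in (("apo", apo_t, holo_s if cfg.mode == "files"
                                  else data["holo_structure"]),
                                 ("holo", holo_t, holo_s)):
            series[f"{label}_all"] = rmsd_series(traj, ref, all_ca, all_ca)
            series[f"{label}_core"] = rmsd_series(traj, ref, core_sel, core_sel)
            series[f"{label}_loop"] = rmsd_series(traj, ref, core_sel, loop_sel)
        table = pd.DataFrame({k: v.values for k, v in series.items()})
        table.to_csv(out / "rmsd_series.tsv", sep="\t", index_label="frame",
                     float_format="%.10g")
        summary["rmsd_mean"] = {k: v.mean for k, v in series.items()}
    except Exception as exc:
        raise StageError("rmsd", exc) from exc

    try:
        stage("contacts")
        contacts = {}
        for label, traj in (("apo", apo_t), ("holo", holo_t)):
            contacts[label] = stable_contacts(
                traj, loop_sel, all_ca, d_cut=cfg.d_cut, f_cut=cfg.f_cut)
            _contacts_to_tsv(contacts[label], out / f"contacts_{label}.tsv")
        comparison = compare_contact_sets(contacts["holo"].pairs,
                                          contacts["apo"].pairs)
        contact_counts = {
            "n_holo": len(contacts["holo"].pairs),
            "n_apo": len(contacts["apo"].pairs),
            "conserved": comparison.n_conserved,
            "lost": comparison.n_lost,
            "gained": comparison.n_gained,
            "d_cut": cfg.d_cut, "f_cut": cfg.f_cut,
        }
        _json_dump(contact_counts, out / "contact_comparison.json")
        summary["contacts"] = contact_counts
    except Exception as exc:
        raise StageError("contacts", exc) from exc

    try:
        stage("hbonds")
        hb = {}
        for label, traj in (("apo", apo_t), ("holo", holo_t)):
            hb[label] = hbond_occupancy(traj, inter_protomer_only=True,
                                        hb_cut=cfg.hb_cut)
            _hbonds_to_tsv(hb[label], out / f"hbonds_{label}.tsv")
        stabilized = compare_hbond_occupancy(hb["apo"], hb["holo"],
                                             delta_cut=cfg.delta_cut)
        stab = [{"residue": list(map(str, s.residue)), "max_delta": s.max_delta,
                 "domain": s.domain} for s in stabilized]
        _json_dump({"stabilized_residues": stab, "delta_cut": cfg.delta_cut},
                   out / "hbond_comparison.json")
        summary["hbond_stabilized"] = stab
    except Exception as exc:
        raise StageError("hbonds", exc) from exc

    try:
        stage("crystal")
        crystal: dict = {}
        lo_h, hi_h = cfg.hinge_pair
        vertex = cfg.vertex_residue or (lo + hi) // 2
        chain0 = apo_s.chain_ids[0]
        angle = loop_opening_angle(
            apo_s, holo_s, chain0, holo_s.chain_ids[0], cfg.loop_range,
            cfg.hinge_pair, vertex)
        crystal["loop_angle"] = {"chain": chain0, "angle": angle.angle,
                                 "vertex": vertex,
                                 "core_fit_rmsd": angle.core_fit_rmsd}
        anchors = anchoring_contacts(holo_s, chain0, cfg.loop_range,
                                     polar_cut=cfg.hb_cut)
        crystal["anchors"] = [
            {"loop_residue": list(map(str, a.loop_residue)),
             "partner_residue": list(map(str, a.partner_residue)),
             "distance": a.min_polar_distance,
             "role": a.partner_chain_role} for a in anchors]
        census = pocket_water_census(
            holo_s, cfg.pocket_residues, coord_cut=cfg.coord_cut,
            min_contacts=cfg.min_contacts,
            require_all_chains=len(holo_s.chain_ids) > 1,
            equiv_tol=cfg.match_tol)
        crystal["pocket_waters"] = [
            {"water": list(map(str, w.water)),
             "n_polar_contacts": w.n_polar_contacts} for w in census]
        pocket_sel = Selection.make(
            residue_ranges=[(min(cfg.pocket_residues),
                             max(cfg.pocket_residues))],
            atom_names=["CA"], chains=[chain0])
        matches = conserved_waters(apo_s, holo_s, pocket_sel,
                                   match_tol=cfg.match_tol)
        crystal["conserved_waters"] = [
            {"water_a": list(map(str, m.water_a)),
             "water_b": list(map(str, m.water_b)),
             "distance": m.distance} for m in matches]
        crystal["gaps"] = {
            c: missing_residues(apo_s, c, (1, cfg.residues_per_chain))
            for c in apo_s.chain_ids}
        _json_dump(crystal, out / "crystal_comparison.json")
        summary["crystal"] = crystal
    except LoopdynError as exc:
        raise StageError("crystal", exc) from exc

    stage("provenance")
    if data["ground_truth"] is not None:
        _json_dump(data["ground_truth"].to_dict(), out / "ground_truth.json")
    (out / "apo_structure.pdb").write_text(write_structure(apo_s))
    (out / "holo_structure.pdb").write_text(write_structure(holo_s))
    _json_dump({"config": cfg.to_dict(), "version": __version__,
                "seed": cfg.seed, "stages": log}, out / "provenance.json")
    _json_dump({k: v for k, v in summary.items() if k != "stages"},
               out / "summary.json")
    return summary
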