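"""Static crystal-structure comparisons: loop-opening angle, anchoring
contacts, coordinated/conserved pocket waters and missing-residue gaps.

These operations compare conformations of the same protein solved in
different states (ligand-free vs ligand-bound), the way one compares an
open-loop structure against a closed-loop one.  All superpositions are
plain least-squares (Kabsch) fits on C-alpha subsets.

Angle convention: the loop-opening angle is measured at the midpoint of
the two hinge-residue C-alphas in the reference (second) structure's
frame, subtended by the two vertex-residue C-alpha positions (the mobile
structure's vertex after core superposition vs the reference's own
vertex).  The convention is recorded in the result object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structures import (
    LoopdynError,
    Selection,
    Structure,
    resolve_selection,
    superpose,
)

__all__ = [
    "LoopAngleResult",
    "AnchorContact",
    "WaterMatch",
    "CoordinatedWater",
    "loop_opening_angle",
    "anchoring_contacts",
    "pocket_water_census",
    "conserved_waters",
    "missing_residues",
    "companion_of",
]

DEFAULT_CHAIN_PAIRS = (("A", "C"), ("B", "D"))


def companion_of(chain: str,
                 pairs: Sequence[tuple[str, str]] = DEFAULT_CHAIN_PAIRS
                 ) -> Optional[str]:
    """Companion chain of the intimate dimer, per the configured pairing."""
    for a, b in pairs:
        if chain == a:
            return b
        if chain == b:
            return a
    return None


def _ca_map(s: Structure, chain: str) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    for a in s.atoms:
        if (a.model_index == 1 and a.chain_id == chain
                and a.atom_name == "CA" and not a.is_water
                and a.res_seq not in out):
            out[a.res_seq] = np.array(a.coords)
    return out


# ---------------------------------------------------------------------------
# Loop-opening angle
# ---------------------------------------------------------------------------

@dataclass
class LoopAngleResult:
    angle: float  # degrees, in [0, 180]
    vertex_residue: int
    hinge_pair: tuple[int, int]
    core_fit_rmsd: float
    convention: str = ("vertex at hinge-midpoint of the reference chain; arms "
                       "to the two vertex C-alphas after core superposition")


def loop_opening_angle(mobile: Structure, reference: Structure,
                       mobile_chain: str, reference_chain: str,
                       loop: tuple[int, int], hinge_pair: tuple[int, int],
                       vertex_residue: int,
                       core_flank: int = 3,
                       core_sel_residues: Optional[Sequence[int]] = None
                       ) -> LoopAngleResult:
    """Angle between the two loop-vertex positions about the hinge midpoint.

    The mobile chain's core C-alphas (everything outside the loop range
    plus ``core_flank`` residues on each side, unless an explicit residue
    list is given) are superposed onto the reference chain's, isolating
    loop motion from the rigid body.
    """
    ca_m = _ca_map(mobile, mobile_chain)
    ca_r = _ca_map(reference, reference_chain)
    for label, ca in (("mobile", ca_m), ("reference", ca_r)):
        if vertex_residue not in ca:
            raise LoopdynError(
                f"vertex residue {vertex_residue} missing (disordered?) in "
                f"{label} chain")
        for h in hinge_pair:
            if h not in ca:
                raise LoopdynError(f"hinge residue {h} missing in {label} chain")
    lo, hi = loop
    if core_sel_residues is not None:
        core = [r for r in core_sel_residues if r in ca_m and r in ca_r]
    else:
        core = [r for r in ca_m
                if r in ca_r and not (lo - core_flank <= r <= hi + core_flank)]
    core.sort()
    if len(core) < 3:
        raise LoopdynError("fewer than 3 shared core residues for the fit")
    sup = superpose(np.array([ca_m[r] for r in core]),
                    np.array([ca_r[r] for r in core]))
    v_mob = sup.apply(ca_m[vertex_residue][None, :])[0]
    v_ref = ca_r[vertex_residue]
    pivot = 0.5 * (ca_r[hinge_pair[0]] + ca_r[hinge_pair[1]])
    u = v_mob - pivot
    w = v_ref - pivot
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu < 1e-9 or nw < 1e-9:
        raise LoopdynError("vertex coincides with the hinge midpoint")
    cosang = float(np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0))
    return LoopAngleResult(
        angle=math.degrees(math.acos(cosang)),
        vertex_residue=vertex_residue,
        hinge_pair=tuple(hinge_pair),
        core_fit_rmsd=sup.rmsd,
    )


# ---------------------------------------------------------------------------
# Anchoring contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorContact:
    loop_residue: tuple  # (chain, res_seq, res_name)
    partner_residue: tuple
    min_polar_distance: float
    partner_chain_role: str  # "same" | "companion" | "other"


def anchoring_contacts(s: Structure, chain: str, loop: tuple[int, int],
                       polar_cut: float = 3.5,
                       partner_scope: str = "all",
                       chain_pairs: Sequence[tuple[str, str]] = DEFAULT_CHAIN_PAIRS
                       ) -> list[AnchorContact]:
    """Polar contacts pinning the loop to residues outside it.

    Reports every (loop residue, non-loop residue) pair with at least one
    N/O-to-N/O distance <= ``polar_cut``.  ``partner_scope`` restricts the
    partner pool to the ``"same"`` chain, the ``"companion"`` chain of the
    intimate dimer, or ``"all"`` chains.
    """
    if partner_scope not in ("all", "same", "companion"):
        raise ValueError("partner_scope must be all|same|companion")
    lo, hi = loop
    companion = companion_of(chain, chain_pairs)
    loop_atoms = [a for a in s.atoms
                  if a.model_index == 1 and a.chain_id == chain
                  and lo <= a.res_seq <= hi and a.element in ("N", "O")
                  and not a.is_water]
    if not loop_atoms:
        raise LoopdynError(f"loop {loop} resolves to no polar atoms on "
                           f"chain {chain}")
    partner_atoms = []
    for a in s.atoms:
        if a.model_index != 1 or a.is_water or a.element not in ("N", "O"):
            continue
        if a.chain_id == chain and lo <= a.res_seq <= hi:
            continue
        if partner_scope == "same" and a.chain_id != chain:
            continue
        if partner_scope == "companion" and a.chain_id != companion:
            continue
        partner_atoms.append(a)
    if not partner_atoms:
        return []
    lp = np.array([a.coords for a in loop_atoms])
    pp = np.array([a.coords for a in partner_atoms])
    d = np.sqrt(np.sum((lp[:, None, :] - pp[None, :, :]) ** 2, axis=-1))
    best: dict[tuple, tuple[float, AnchorContact]] = {}
    for i, la in enumerate(loop_atoms):
        for j, pa in enumerate(partner_atoms):
            if d[i, j] > polar_cut:
                continue
            key = ((la.chain_id, la.res_seq), (pa.chain_id, pa.res_seq))
            if key not in best or d[i, j] < best[key][0]:
                role = ("same" if pa.chain_id == chain
                        else "companion" if pa.chain_id == companion
                        else "other")
                best[key] = (float(d[i, j]), AnchorContact(
                    loop_residue=(la.chain_id, la.res_seq, la.res_name),
                    partner_residue=(pa.chain_id, pa.res_seq, pa.res_name),
                    min_polar_distance=float(d[i, j]),
                    partner_chain_role=role,
                ))
    return [rec for _d, rec in
            sorted(best.values(), key=lambda t: (t[1].loop_residue,
                                                 t[1].partner_residue))]


# ---------------------------------------------------------------------------
# Pocket waters
# ---------------------------------------------------------------------------

@dataclass
class CoordinatedWater:
    water: tuple  # (chain, res_seq)
    coordinating_residues: list
    n_polar_contacts: int
    present_in_chains: list[str] = field(default_factory=list)


def _waters(s: Structure) -> list:
    seen = {}
    for i, a in enumerate(s.atoms):
        if a.model_index == 1 and a.is_water and a.element == "O":
            seen.setdefault((a.chain_id, a.res_seq, a.insertion_code), i)
    return [(key, s.atoms[i]) for key, i in seen.items()]


def pocket_water_census(s: Structure, pocket_residues: Sequence[int],
                        coord_cut: float = 3.5, min_contacts: int = 3,
                        require_all_chains: bool = False,
                        equiv_tol: float = 1.0,
                        chains: Optional[Sequence[str]] = None
                        ) -> list[CoordinatedWater]:
    """Waters making >= ``min_contacts`` polar contacts to pocket residues.

    ``pocket_residues`` are author residue numbers, applied on every chain.
    With ``require_all_chains`` a water is kept only if, after superposing
    each protomer onto the water's own, a positionally equivalent water
    (within ``equiv_tol``) coordinating the pocket exists in every protomer.
    """
    waters = _waters(s)
    if not waters:
        warnings.warn("structure contains no waters", stacklevel=2)
        return []
    if chains is None:
        chains = [c for c in s.chain_ids
                  if any(not a.is_water and a.chain_id == c for a in s.atoms)]
    pocket_set = set(int(r) for r in pocket_residues)
    polar = [(i, a) for i, a in enumerate(s.atoms)
             if a.model_index == 1 and not a.is_water
             and a.element in ("N", "O") and a.res_seq in pocket_set]
    if not polar:
        raise LoopdynError("pocket selection resolves to no polar atoms")
    ppos = np.array([a.coords for _i, a in polar])

    def census_one(water_atom) -> Optional[CoordinatedWater]:
        w = np.array(water_atom.coords)
        dist = np.linalg.norm(ppos - w, axis=1)
        hits = [k for k in range(len(polar)) if dist[k] <= coord_cut]
        if len(hits) < min_contacts:
            return None
        residues = sorted({(polar[k][1].chain_id, polar[k][1].res_seq)
                           for k in hits})
        return CoordinatedWater(
            water=(water_atom.chain_id, water_atom.res_seq),
            coordinating_residues=residues,
            n_polar_contacts=len(hits),
        )

    coordinated: list[CoordinatedWater] = []
    water_atoms = {}
    for (_key, a) in waters:
        cw = census_one(a)
        if cw is not None:
            coordinated.append(cw)
            water_atoms[cw.water] = a

    if not require_all_chains or len(chains) < 2:
        for cw in coordinated:
            cw.present_in_chains = list(chains)
        return coordinated

    ca_maps = {c: _ca_map(s, c) for c in chains}
    coord_pos = {cw.water: np.array(water_atoms[cw.water].coords)
                 for cw in coordinated}
    kept = []
    for cw in coordinated:
        home = cw.water[0]
        if home not in ca_maps:
            continue
        present = [home]
        for other in chains:
            if other == home:
                continue
            shared = sorted(set(ca_maps[home]) & set(ca_maps[other]))
            if len(shared) < 3:
                continue
            sup = superpose(
                np.array([ca_maps[other][r] for r in shared]),
                np.array([ca_maps[home][r] for r in shared]))
            # map the other protomer's coordinated waters into home frame
            for other_cw in coordinated:
                if other_cw.water[0] != other:
                    continue
                moved = sup.apply(coord_pos[other_cw.water][None, :])[0]
                if np.linalg.norm(moved - coord_pos[cw.water]) <= equiv_tol:
                    present.append(other)
                    break
        if set(present) >= set(chains):
            cw.present_in_chains = sorted(present)
            kept.append(cw)
    return kept


@dataclass(frozen=True)
class WaterMatch:
    water_a: tuple  # (chain, res_seq)
    water_b: tuple
    distance: float


def conserved_waters(a: Structure, b: Structure,
                     pocket_sel: Selection,
                     match_tol: float = 1.0,
                     pocket_radius: float = 8.0) -> list[WaterMatch]:
    """Waters occupying the same pocket position in two superposed structures.

    Structure ``b`` is superposed onto ``a`` on the pocket C-alphas, then
    water oxygens within ``pocket_radius`` of the pocket are matched
    greedily by ascending distance (each water used once, ties broken by
    residue number); only matches within ``match_tol`` are returned.
    """
    ia = resolve_selection(a, pocket_sel, warn=False)
    ib = resolve_selection(b, pocket_sel, warn=False)
    ca_a = [i for i in ia if a.atoms[i].atom_name == "CA"]
    ca_b = [i for i in ib if b.atoms[i].atom_name == "CA"]
    if len(ca_a) != len(ca_b) or len(ca_a) < 3:
        raise LoopdynError("pocket selection does not resolve to matching "
                           "C-alpha sets in both structures")
    xa = a.coords[ca_a]
    xb = b.coords[ca_b]
    sup = superpose(xb, xa)

    def pocket_waters(s: Structure, centre_set: np.ndarray,
                      transform=None) -> list[tuple[tuple, np.ndarray]]:
        out = []
        for (key, atom) in _waters(s):
            p = np.array(atom.coords)
            if transform is not None:
                p = transform.apply(p[None, :])[0]
            if np.min(np.linalg.norm(centre_set - p, axis=1)) <= pocket_radius:
                out.append(((atom.chain_id, atom.res_seq), p))
        return out

    wa = pocket_waters(a, xa)
    wb = pocket_waters(b, xa, transform=sup)
    if not wa or not wb:
        return []
    cand = []
    for ka, pa in wa:
        for kb, pb in wb:
            dist = float(np.linalg.norm(pa - pb))
            if dist <= match_tol:
                cand.append((dist, ka[1], kb[1], ka, kb))
    cand.sort()
    used_a, used_b, matches = set(), set(), []
    for dist, _na, _nb, ka, kb in cand:
        if ka in used_a or kb in used_b:
            continue
        used_a.add(ka)
        used_b.add(kb)
        matches.append(WaterMatch(water_a=ka, water_b=kb, distance=dist))
    matches.sort(key=lambda m: (m.water_a, m.water_b))
    return matches


# ---------------------------------------------------------------------------
# Missing residues
# ---------------------------------------------------------------------------

def missing_residues(s: Structure, chain: str,
                     expected_range: tuple[int, int]) -> list[tuple[int, int]]:
    """Maximal gaps of expected residue numbers with no atoms in the chain."""
    lo, hi = expected_range
    present = {a.res_seq for a in s.atoms
               if a.chain_id == chain and not a.is_water}
    gaps = []
    start = None
    for r in range(lo, hi + 1):
        if r not in present:
            if start is None:
                start = r
        else:
            if start is not None:
                gaps.append((start, r - 1))
                start = None
    if start is not None:
        gaps.append((start, hi))
    return gaps
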