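"""Synthetic toy complexes and trajectories with planted ground truth.

The generator emulates the statistical structure the trajectory and crystal
analyses assume, at desk scale and without a force field:

* a homotetramer of identical chains (A, B, C, D; intimate pairs A-C and
  B-D) laid out as smooth space curves with ~3.8 A C-alpha spacing;
* a flexible loop bulging out of each chain between two hinge residues,
  built as a circular arc that is symmetric about the hinge axis, so a
  rigid rotation of the loop about that axis moves the loop vertex by an
  exactly known angle;
* backbone N/O pseudo-atoms offset +-0.6 A from each C-alpha, acting as
  hydrogen-bond donors/acceptors;
* pocket waters planted next to designated residues with a known number
  of polar contacts, replicated identically in every protomer;
* an inter-protomer anchoring contact: the loop vertex of each chain sits
  3.0 A from a core residue of its companion chain (the toy analogue of a
  closed-loop anchoring point borrowed from the partner protomer), and the
  contact breaks when the loop opens.

Every generator is a pure function of (spec, seed); random sub-streams are
derived per chain so partial regeneration is stable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .structures import (
    AtomRecord,
    LoopdynError,
    Structure,
    Trajectory,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_toy_complex",
    "rotate_loop",
    "make_harmonic_trajectory",
    "make_rigid_trajectory",
    "make_two_state_trajectory",
]

CA_SPACING = 3.8  # A, consecutive C-alpha distance along the chain
PSEUDO_OFFSET = 0.6  # A, N/O pseudo-atom offset from the C-alpha
WATER_OFFSET = 1.5  # A, planted water offset from the backbone midpoint
ANCHOR_DIST = 3.0  # A, planted loop-vertex to companion polar distance
CORE_ARC_RADIUS = 150.0  # A, radius of the arc the core curve follows

CHAIN_ORDER = ["A", "B", "C", "D"]
INTIMATE_PAIRS = (("A", "C"), ("B", "D"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the toy complex; defaults mirror the study system.

    The flexible loop spans residues 11-31 with hinge residues flanking it,
    the planted opening angle defaults to 45.7 degrees (the partially open
    loop orientation), and five pocket waters are planted per protomer.
    """

    n_chains: int = 4
    residues_per_chain: int = 50
    loop_range: tuple[int, int] = (11, 31)
    hinge_pair: tuple[int, int] = (10, 32)
    sigma: float = 0.3  # A, default per-residue isotropic fluctuation
    planted_angle: float = 45.7  # degrees
    open_fraction: float = 0.5
    planted_waters: Optional[tuple[tuple[int, int], ...]] = None
    # default: five 4-coordinated waters on the core shortly after the
    # second hinge (residues 40-44 for the default chain layout)
    anchor_partner: Optional[int] = None  # companion residue anchoring the
    # vertex; defaults to a core residue well past the second hinge
    seed: int = 0

    def __post_init__(self) -> None:
        l1, l2 = self.loop_range
        h1, h2 = self.hinge_pair
        if not (1 <= self.n_chains <= 4):
            raise LoopdynError("n_chains must be between 1 and 4")
        if not (1 < l1 <= l2 < self.residues_per_chain):
            raise LoopdynError("loop_range must lie strictly inside the chain")
        if not (h1 == l1 - 1 and h2 == l2 + 1):
            raise LoopdynError("hinge residues must flank the loop range")
        if not (0.0 <= self.open_fraction <= 1.0):
            raise LoopdynError("open_fraction must be in [0, 1]")
        if self.sigma < 0:
            raise LoopdynError("sigma must be >= 0")
        for res, _count in self.water_sites:
            if self.loop_range[0] <= res <= self.loop_range[1]:
                raise LoopdynError("planted waters must sit on core residues")
            if res + 1 > self.residues_per_chain:
                raise LoopdynError("planted water anchor outside the chain")
        partner = self.partner_residue
        if not (1 <= partner <= self.residues_per_chain) or \
                self.loop_range[0] <= partner <= self.loop_range[1]:
            raise LoopdynError("anchor_partner must be a core residue")

    @property
    def vertex_residue(self) -> int:
        l1, l2 = self.loop_range
        return (l1 + l2) // 2

    @property
    def partner_residue(self) -> int:
        if self.anchor_partner is not None:
            return self.anchor_partner
        return min(self.residues_per_chain - 1, self.hinge_pair[1] + 13)

    @property
    def water_sites(self) -> tuple[tuple[int, int], ...]:
        if self.planted_waters is not None:
            return self.planted_waters
        start = self.hinge_pair[1] + 8
        stop = min(start + 5, self.residues_per_chain)
        return tuple((r, 4) for r in range(start, stop))


@dataclass
class GroundTruth:
    """Planted quantities actually realized in an emitted toy dataset."""

    loop_range: tuple[int, int]
    hinge_pair: tuple[int, int]
    vertex_residue: int
    planted_angle: float
    open_fraction_target: Optional[float] = None
    open_fraction_realized: dict = field(default_factory=dict)
    water_coordination: dict = field(default_factory=dict)
    anchors: list = field(default_factory=list)
    hbond_occupancy: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "loop_range": list(self.loop_range),
            "hinge_pair": list(self.hinge_pair),
            "vertex_residue": self.vertex_residue,
            "planted_angle": self.planted_angle,
            "open_fraction_target": self.open_fraction_target,
            "open_fraction_realized": {str(k): v for k, v in
                                       self.open_fraction_realized.items()},
            "water_coordination": {str(k): v for k, v in
                                   self.water_coordination.items()},
            "anchors": self.anchors,
            "hbond_occupancy": {str(k): v for k, v in
                                self.hbond_occupancy.items()},
        }


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise LoopdynError("zero-length vector in geometry construction")
    return v / n


def _perp_to(v: np.ndarray, prefer: np.ndarray) -> np.ndarray:
    """Unit vector perpendicular to v, as close to `prefer` as possible."""
    w = prefer - np.dot(prefer, v) * v
    if np.linalg.norm(w) < 1e-8:
        w = np.array([1.0, 0.0, 0.0]) - v[0] * v
    if np.linalg.norm(w) < 1e-8:
        w = np.array([0.0, 1.0, 0.0]) - v[1] * v
    return _unit(w)


def _chain_ca_positions(spec: SyntheticSpec) -> np.ndarray:
    """C-alpha positions of one chain: wiggly core + symmetric loop arc."""
    r = spec.residues_per_chain
    h1, h2 = spec.hinge_pair
    pos = np.zeros((r, 3))

    def core_u(i: int) -> float:
        # core abscissa skips the loop: the chain re-enters the rigid body
        # a short hop after the first hinge, keeping the hinges close in
        # space as they are at the base of a real loop
        if i <= h1:
            return float(i - 1)
        return (h1 - 1) + 1.5 + float(i - h2)

    def base(u: float) -> np.ndarray:
        # core follows a large-radius arc (so distant core residues lie
        # well off the hinge axis, as in a folded domain) with a gentle
        # non-planar wiggle; spacing stays ~3.8 A per residue
        theta = 3.7 * u / CORE_ARC_RADIUS
        return np.array([CORE_ARC_RADIUS * math.sin(theta),
                         CORE_ARC_RADIUS * (1.0 - math.cos(theta)),
                         0.8 * math.cos(0.7 * u)])

    for i in range(1, r + 1):
        if i <= h1 or i >= h2:
            pos[i - 1] = base(core_u(i))

    hinge_a = pos[h1 - 1]
    hinge_b = pos[h2 - 1]
    chord = hinge_b - hinge_a
    length = float(np.linalg.norm(chord))
    m = h2 - h1 - 1  # number of loop residues
    arc_len = (m + 1) * CA_SPACING

    def gap(phi: float) -> float:
        return 2.0 * math.sin(phi / 2.0) / phi - length / arc_len

    phi = brentq(gap, 1e-9, 2.0 * math.pi - 1e-9)
    rho = arc_len / phi
    k = math.sqrt(max(rho * rho - (length / 2.0) ** 2, 0.0))
    u_hat = _unit(chord)
    b_hat = _perp_to(u_hat, np.array([0.0, -1.0, 0.0]))
    theta1 = math.atan2(-k, -length / 2.0)
    for j in range(1, m + 1):
        theta = theta1 - phi * j / (m + 1)
        x2 = length / 2.0 + rho * math.cos(theta)
        y2 = k + rho * math.sin(theta)
        pos[h1 - 1 + j] = hinge_a + x2 * u_hat + y2 * b_hat
    return pos


def _frames_along(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-residue orthonormal (tangent, normal, binormal) frames."""
    n = pos.shape[0]
    tangents = np.zeros_like(pos)
    tangents[1:-1] = pos[2:] - pos[:-2]
    tangents[0] = pos[1] - pos[0]
    tangents[-1] = pos[-1] - pos[-2]
    t_hat = np.stack([_unit(t) for t in tangents])
    z = np.array([0.0, 0.0, 1.0])
    n_hat = np.stack([_perp_to(t, z) for t in t_hat])
    m_hat = np.cross(t_hat, n_hat)
    return t_hat, n_hat, m_hat


def _build_chain_atoms(spec: SyntheticSpec) -> tuple[np.ndarray, list[tuple]]:
    """Atom geometry of the template chain (before placement).

    Returns coordinates and a parallel list of
    (res_seq, res_name, atom_name, element) descriptors.
    """
    ca = _chain_ca_positions(spec)
    _t, n_hat, m_hat = _frames_along(ca)
    coords: list[np.ndarray] = []
    meta: list[tuple] = []
    for i in range(spec.residues_per_chain):
        seq = i + 1
        coords.append(ca[i])
        meta.append((seq, "GLY", "CA", "C"))
        coords.append(ca[i] + PSEUDO_OFFSET * n_hat[i])
        meta.append((seq, "GLY", "N", "N"))
        coords.append(ca[i] - PSEUDO_OFFSET * n_hat[i])
        meta.append((seq, "GLY", "O", "O"))
    for w_idx, (res, target) in enumerate(spec.water_sites):
        i = res - 1
        if target >= 3:
            site = 0.5 * (ca[i] + ca[i + 1]) + WATER_OFFSET * m_hat[i]
        else:
            site = ca[i] + 2.6 * m_hat[i]
        coords.append(site)
        meta.append((401 + w_idx, "HOH", "O", "O"))
    return np.stack(coords), meta


def _companion_transform(template: np.ndarray, meta: list[tuple],
                         spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Involutive 180-degree rotation placing the companion chain.

    Chosen so the companion's partner-residue O atom sits ``ANCHOR_DIST``
    from the template's loop-vertex N atom; being an involution, the
    reciprocal vertex-to-partner contact holds automatically, mimicking the
    symmetric anchoring across an intimate dimer.
    """
    def atom_pos(res: int, name: str) -> np.ndarray:
        for p, (seq, _rn, an, _el) in zip(template, meta):
            if seq == res and an == name:
                return p
        raise LoopdynError(f"template atom {name} of residue {res} not found")

    vertex_n = atom_pos(spec.vertex_residue, "N")
    ca = _chain_ca_positions(spec)
    h1, h2 = spec.hinge_pair
    chord = ca[h2 - 1] - ca[h1 - 1]
    out_dir = _perp_to(_unit(chord), np.array([0.0, -1.0, 0.0]))
    target = vertex_n + ANCHOR_DIST * out_dir
    partner_o = atom_pos(spec.partner_residue, "O")
    centre = 0.5 * (partner_o + target)
    w_hat = _unit(partner_o - target)
    axis = _perp_to(w_hat, np.array([0.0, 0.0, 1.0]))
    rot = 2.0 * np.outer(axis, axis) - np.eye(3)
    return rot, centre


def make_toy_complex(spec: SyntheticSpec) -> tuple[Structure, GroundTruth]:
    """Build the closed-conformation toy complex and its ground truth."""
    template, meta = _build_chain_atoms(spec)
    rot, centre = _companion_transform(template, meta, spec)

    def place(chain_idx: int) -> np.ndarray:
        xyz = template.copy()
        if chain_idx % 2 == 1:  # companion of the intimate pair
            xyz = centre + (xyz - centre) @ rot.T
        if chain_idx >= 2:  # second intimate dimer, shifted away
            xyz = xyz + np.array([0.0, 0.0, 40.0])
        return xyz

    # emission order A, B, C, D; placement pairs (A,C) and (B,D)
    placement_index = {"A": 0, "C": 1, "B": 2, "D": 3}
    atoms: list[AtomRecord] = []
    for cid in CHAIN_ORDER[:spec.n_chains]:
        xyz = place(placement_index[cid])
        for p, (seq, rn, an, el) in zip(xyz, meta):
            atoms.append(AtomRecord(
                model_index=1, chain_id=cid, res_seq=seq, insertion_code="",
                res_name=rn, atom_name=an, alt_loc="", element=el,
                coords=(float(p[0]), float(p[1]), float(p[2])),
                occupancy=1.0, b_factor=10.0))
    s = Structure(atoms, source_id=f"toy-{spec.seed}")

    gt = GroundTruth(
        loop_range=spec.loop_range,
        hinge_pair=spec.hinge_pair,
        vertex_residue=spec.vertex_residue,
        planted_angle=spec.planted_angle,
        open_fraction_target=spec.open_fraction,
    )
    _record_water_coordination(s, spec, gt)
    _record_anchors(s, spec, gt)
    return s, gt


def _polar_atoms(s: Structure, exclude_waters: bool = True):
    return [(i, a) for i, a in enumerate(s.atoms)
            if a.element in ("N", "O") and not (exclude_waters and a.is_water)]


def _record_water_coordination(s: Structure, spec: SyntheticSpec,
                               gt: GroundTruth) -> None:
    polar = _polar_atoms(s)
    ppos = np.array([a.coords for _, a in polar])
    for i, a in enumerate(s.atoms):
        if not a.is_water:
            continue
        d = np.linalg.norm(ppos - np.array(a.coords), axis=1)
        same_chain = np.array([b.chain_id == a.chain_id for _, b in polar])
        count = int(np.sum((d <= 3.5) & same_chain))
        gt.water_coordination[(a.chain_id, a.res_seq)] = count


def _record_anchors(s: Structure, spec: SyntheticSpec, gt: GroundTruth) -> None:
    pairs = [p for p in INTIMATE_PAIRS
             if p[0] in s.chain_ids and p[1] in s.chain_ids]
    for ca_id, cb_id in pairs:
        for loop_chain, core_chain in ((ca_id, cb_id), (cb_id, ca_id)):
            vi = s.find_atoms(loop_chain, spec.vertex_residue, "N")
            pj = s.find_atoms(core_chain, spec.partner_residue, "O")
            if not vi or not pj:
                continue
            d = float(np.linalg.norm(
                np.array(s.atoms[vi[0]].coords) - np.array(s.atoms[pj[0]].coords)))
            gt.anchors.append({
                "loop_residue": [loop_chain, spec.vertex_residue],
                "partner_residue": [core_chain, spec.partner_residue],
                "distance": d,
            })


# ---------------------------------------------------------------------------
# Loop rotation
# ---------------------------------------------------------------------------

def rotate_loop(s: Structure, chain: str, loop: tuple[int, int],
                hinge_pair: tuple[int, int], angle: float) -> Structure:
    """Rigidly rotate loop atoms about the axis through the two hinge C-alphas.

    Only atoms of residues inside ``loop`` on ``chain`` move; everything
    else, including the hinge residues themselves, is untouched.
    """
    norm = ((angle + 180.0) % 360.0) - 180.0
    if norm < 0:
        norm = -norm
        warnings.warn(f"rotation angle {angle} normalized to {norm} degrees",
                      stacklevel=2)
    elif not math.isclose(norm, angle):
        warnings.warn(f"rotation angle {angle} normalized to {norm} degrees",
                      stacklevel=2)
    h1, h2 = hinge_pair
    lo, hi = loop
    xyz = s.coords
    out = xyz.copy()
    for midx in s.model_indices:
        a1 = [i for i in s.find_atoms(chain, h1, "CA")
              if s.atoms[i].model_index == midx]
        a2 = [i for i in s.find_atoms(chain, h2, "CA")
              if s.atoms[i].model_index == midx]
        if not a1 or not a2:
            raise LoopdynError(
                f"hinge residues {h1}/{h2} (CA) not found on chain {chain}")
        p1, p2 = xyz[a1[0]], xyz[a2[0]]
        axis = _unit(p2 - p1)
        rot = Rotation.from_rotvec(np.radians(norm) * axis).as_matrix()
        sel = [i for i, a in enumerate(s.atoms)
               if a.model_index == midx and a.chain_id == chain
               and not a.is_water and lo <= a.res_seq <= hi]
        if sel:
            out[sel] = p1 + (xyz[sel] - p1) @ rot.T
    return s.with_coords(out)


# ---------------------------------------------------------------------------
# Trajectory generators
# ---------------------------------------------------------------------------

SigmaLike = Union[float, Mapping[int, float]]


def _sigma_per_residue(s: Structure, sigma_profile: SigmaLike) -> np.ndarray:
    residues = s.residues()
    if isinstance(sigma_profile, Mapping):
        vals = [float(sigma_profile.get(seq, 0.0))
                for _c, seq, _i, _n in residues]
    else:
        vals = [float(sigma_profile)] * len(residues)
    arr = np.array(vals)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise LoopdynError("sigma profile must be finite and non-negative")
    return arr


def _atom_residue_index(s: Structure) -> np.ndarray:
    residues = s.residues()
    lookup = {rid[:3]: k for k, rid in enumerate(residues)}
    return np.array([lookup[a.residue_id] for a in s.atoms], dtype=int)


def make_harmonic_trajectory(s: Structure, sigma_profile: SigmaLike,
                             n_frames: int, seed: int) -> Trajectory:
    """Per-residue isotropic harmonic fluctuation around the input structure.

    Each residue receives, per frame, one Gaussian displacement with its
    own sigma per coordinate, shared by all atoms of the residue (rigid
    residue jitter) and independent across residues and frames.
    """
    if n_frames < 2:
        raise LoopdynError("n_frames must be >= 2 (variance undefined)")
    sigma = _sigma_per_residue(s, sigma_profile)
    res_idx = _atom_residue_index(s)
    residues = s.residues()
    base = s.coords
    # per-chain random sub-streams for stable partial regeneration
    chains = s.chain_ids
    streams = np.random.SeedSequence(seed).spawn(len(chains))
    eps = np.zeros((n_frames, len(residues), 3))
    for cid, stream in zip(chains, streams):
        cols = [k for k, rid in enumerate(residues) if rid[0] == cid]
        rng = np.random.default_rng(stream)
        eps[:, cols, :] = rng.standard_normal((n_frames, len(cols), 3))
    eps *= sigma[None, :, None]
    frames = base[None, :, :] + eps[:, res_idx, :]
    return Trajectory(s, frames)


def make_rigid_trajectory(s: Structure, n_frames: int, seed: int,
                          max_shift: float = 20.0) -> Trajectory:
    """Random rigid-body motion: each frame is a rotated + translated copy."""
    if n_frames < 1:
        raise LoopdynError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    base = s.coords
    centre = base.mean(axis=0)
    quats = rng.standard_normal((n_frames, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    shifts = rng.uniform(-max_shift, max_shift, size=(n_frames, 3))
    frames = np.empty((n_frames, base.shape[0], 3))
    for f in range(n_frames):
        rot = Rotation.from_quat(quats[f]).as_matrix()
        frames[f] = (base - centre) @ rot.T + centre + shifts[f]
    return Trajectory(s, frames)


HBondPlant = tuple[tuple[str, int, str], tuple[str, int, str], float]


def make_two_state_trajectory(
        s: Structure,
        loop: tuple[int, int],
        hinge_pair: tuple[int, int],
        angle: float,
        open_fraction: float,
        n_frames: int,
        sigma: SigmaLike = 0.2,
        seed: int = 0,
        chains: Optional[Sequence[str]] = None,
        planted_hbonds: Optional[Sequence[HBondPlant]] = None,
) -> tuple[Trajectory, GroundTruth]:
    """Open/closed two-state loop mixture with harmonic noise.

    Each frame, independently per chain, the flexible loop is either in
    the input (closed) conformation or rotated by ``angle`` about the hinge
    axis (open) with probability ``open_fraction``.  Planted hydrogen bonds
    are realized with an exact frame count: ``round(occupancy * n_frames)``
    frames keep the bond, the rest displace the acceptor out of range.
    """
    if n_frames < 2:
        raise LoopdynError("n_frames must be >= 2")
    if not 0.0 <= open_fraction <= 1.0:
        raise LoopdynError("open_fraction must be in [0, 1]")
    if chains is None:
        chains = s.chain_ids
    ss = np.random.SeedSequence(seed)
    state_streams = ss.spawn(len(chains) + 2)
    noise_stream, hbond_stream = state_streams[-2], state_streams[-1]

    closed = s.coords
    open_struct = s
    loop_masks = {}
    for cid in chains:
        open_struct = rotate_loop(open_struct, cid, loop, hinge_pair, angle)
        loop_masks[cid] = np.array(
            [a.chain_id == cid and loop[0] <= a.res_seq <= loop[1]
             and not a.is_water for a in s.atoms])
    opened = open_struct.coords

    frames = np.repeat(closed[None, :, :], n_frames, axis=0)
    gt = GroundTruth(
        loop_range=loop, hinge_pair=hinge_pair,
        vertex_residue=(loop[0] + loop[1]) // 2,
        planted_angle=angle, open_fraction_target=open_fraction)
    for cid, stream in zip(chains, state_streams):
        rng = np.random.default_rng(stream)
        states = rng.random(n_frames) < open_fraction
        mask = loop_masks[cid]
        frames[np.ix_(states, mask)] = opened[mask]
        gt.open_fraction_realized[cid] = float(states.mean())
    gt.open_fraction_realized["overall"] = float(
        np.mean([gt.open_fraction_realized[c] for c in chains]))

    # harmonic noise on every residue
    sig = _sigma_per_residue(s, sigma)
    res_idx = _atom_residue_index(s)
    rng = np.random.default_rng(noise_stream)
    eps = rng.standard_normal((n_frames, sig.size, 3)) * sig[None, :, None]
    frames += eps[:, res_idx, :]

    if planted_hbonds:
        rng = np.random.default_rng(hbond_stream)
        for donor, acceptor, occupancy in planted_hbonds:
            di = s.find_atoms(*donor)
            ai = s.find_atoms(*acceptor)
            if not di or not ai:
                raise LoopdynError(f"planted H-bond atoms {donor}/{acceptor} "
                                   "not found")
            di, ai = di[0], ai[0]
            n_on = int(round(occupancy * n_frames))
            order = rng.permutation(n_frames)
            off = order[n_on:]
            direction = _unit(closed[ai] - closed[di])
            frames[off, ai, :] += 4.0 * direction
            gt.hbond_occupancy[(donor, acceptor)] = n_on / n_frames

    return Trajectory(s, frames), gt
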