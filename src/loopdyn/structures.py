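"""Structures, trajectories, atom selections and rigid-body superposition.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
table of :class:`AtomRecord` objects (author residue numbering, insertion
codes honoured), and a :class:`Trajectory` is a fixed atom topology plus an
``(F, A, 3)`` coordinate array.  The interchange format is plain PDB text —
multi-model PDB for trajectories — parsed and written through :mod:`gemmi`.

Conventions applied on reading:

* hydrogens are dropped everywhere (crystal structures carry none, so
  analyses stay comparable between experimental and simulated input);
* alternate locations are collapsed to the highest-occupancy conformer,
  ties broken by the alphabetically first altloc identifier;
* waters are retained as ordinary residues named ``HOH``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Selection",
    "Trajectory",
    "SuperpositionResult",
    "LoopdynError",
    "ParseError",
    "EmptyStructureError",
    "FormattingError",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "resolve_selection",
    "superpose",
    "apply_transform",
    "rmsd",
    "WATER_NAMES",
]

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class LoopdynError(Exception):
    """Base class for user-facing errors raised by this package."""


class ParseError(LoopdynError):
    pass


class EmptyStructureError(LoopdynError):
    pass


class FormattingError(LoopdynError):
    pass


class SelectionError(LoopdynError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one model, in author numbering as printed in the PDB."""

    model_index: int
    chain_id: str
    res_seq: int
    insertion_code: str  # "" when absent
    res_name: str
    atom_name: str
    alt_loc: str  # "" when absent
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES


@dataclass
class Structure:
    """Ordered atom table of one or more models of a complex."""

    atoms: list[AtomRecord]
    source_id: str = ""

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.coords):
                raise ParseError(f"non-finite coordinates on atom {a}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        """Copy of the structure with every atom moved to ``xyz`` (A x 3)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {xyz.shape} does not match "
                             f"{len(self.atoms)} atoms")
        new = [replace(a, coords=tuple(float(v) for v in p))
               for a, p in zip(self.atoms, xyz)]
        return Structure(new, source_id=self.source_id)

    def model(self, model_index: int = 1) -> "Structure":
        sub = [a for a in self.atoms if a.model_index == model_index]
        return Structure(sub, source_id=self.source_id)

    @property
    def model_indices(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.model_index, None)
        return list(seen)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self, chain_id: Optional[str] = None,
                 include_waters: bool = True) -> list[tuple[str, int, str, str]]:
        """Ordered unique residues as (chain, res_seq, icode, res_name)."""
        out: dict[tuple[str, int, str], str] = {}
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if not include_waters and a.is_water:
                continue
            out.setdefault(a.residue_id, a.res_name)
        return [(c, s, i, n) for (c, s, i), n in out.items()]

    def find_atoms(self, chain_id: str, res_seq: int,
                   atom_name: Optional[str] = None) -> list[int]:
        idx = []
        for i, a in enumerate(self.atoms):
            if a.chain_id == chain_id and a.res_seq == res_seq:
                if atom_name is None or a.atom_name == atom_name:
                    idx.append(i)
        return idx


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection; empty criteria match everything.

    ``residue_ranges`` are closed intervals on the author residue number.
    Waters are excluded unless ``include_waters`` is set, so that a default
    ``Selection(atom_names={"CA"})`` means "all protein C-alphas".
    """

    chains: Optional[frozenset[str]] = None
    residue_ranges: Optional[tuple[tuple[int, int], ...]] = None
    atom_names: Optional[frozenset[str]] = None
    include_waters: bool = False

    @classmethod
    def make(cls, chains: Optional[Iterable[str]] = None,
             residue_ranges: Optional[Iterable[Sequence[int]]] = None,
             atom_names: Optional[Iterable[str]] = None,
             include_waters: bool = False) -> "Selection":
        return cls(
            chains=frozenset(chains) if chains is not None else None,
            residue_ranges=tuple((int(lo), int(hi)) for lo, hi in residue_ranges)
            if residue_ranges is not None else None,
            atom_names=frozenset(atom_names) if atom_names is not None else None,
            include_waters=include_waters,
        )

    def matches(self, a: AtomRecord) -> bool:
        if a.is_water and not self.include_waters:
            return False
        if self.chains is not None and a.chain_id not in self.chains:
            return False
        if self.residue_ranges is not None:
            if not any(lo <= a.res_seq <= hi for lo, hi in self.residue_ranges):
                return False
        if self.atom_names is not None and a.atom_name not in self.atom_names:
            return False
        return True


CA_SELECTION = Selection.make(atom_names=["CA"])


@dataclass
class Trajectory:
    """Fixed atom topology plus F frames of coordinates (Angstrom)."""

    topology: Structure
    frames: np.ndarray  # (F, A, 3)
    frame_labels: Optional[list] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, A, 3)")
        if self.frames.shape[1] != len(self.topology.atoms):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {len(self.topology.atoms)}")
        if self.frames.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    def frame_structure(self, f: int) -> Structure:
        return self.topology.with_coords(self.frames[f])


def pool_trajectories(parts: Sequence[Trajectory]) -> Trajectory:
    """Concatenate replicas that share a topology into one frame pool."""
    if not parts:
        raise ValueError("no trajectories to pool")
    top = parts[0].topology
    for t in parts[1:]:
        if [a.atom_name for a in t.topology.atoms] != [a.atom_name for a in top.atoms]:
            raise LoopdynError("cannot pool trajectories with different topologies")
    frames = np.concatenate([t.frames for t in parts], axis=0)
    return Trajectory(top, frames)


# ---------------------------------------------------------------------------
# PDB reading / writing (via gemmi)
# ---------------------------------------------------------------------------

def _validate_coordinate_fields(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"truncated coordinate record at line {lineno}")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi].strip()
                try:
                    float(fld)
                except ValueError:
                    raise ParseError(
                        f"malformed coordinate field {fld!r} at line {lineno}"
                    ) from None


def _dedupe_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom: highest occupancy, ties by altloc id."""
    best: dict[tuple, tuple[int, AtomRecord]] = {}
    order: list[tuple] = []
    for i, a in enumerate(atoms):
        key = (a.model_index, a.chain_id, a.res_seq, a.insertion_code,
               a.res_name, a.atom_name)
        if key not in best:
            best[key] = (i, a)
            order.append(key)
        else:
            _, cur = best[key]
            if (a.occupancy, _altloc_rank(a.alt_loc)) > \
               (cur.occupancy, _altloc_rank(cur.alt_loc)):
                best[key] = (best[key][0], a)
    out = []
    for key in order:
        _, a = best[key]
        if a.alt_loc:
            a = replace(a, alt_loc="")
        out.append(a)
    return out


def _altloc_rank(alt: str) -> float:
    # higher is better; alphabetically earlier altloc wins a tie
    return -ord(alt) if alt else 0.0


def read_structure(pdb_text: str, model_policy: str = "first",
                   source_id: str = "") -> Structure:
    """Parse PDB text into a :class:`Structure`.

    ``model_policy`` is ``"first"`` (default, model 1 only) or ``"all"``
    (every MODEL block, with ``model_index`` running 1..M).
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    _validate_coordinate_fields(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise ParseError(str(exc)) from exc
    atoms: list[AtomRecord] = []
    models = list(st)
    if model_policy == "first":
        models = models[:1]
    for midx, model in enumerate(models, start=1):
        for chain in model:
            for res in chain:
                for at in res:
                    if at.element.name in ("H", "D"):
                        continue
                    alt = at.altloc if at.altloc not in ("", "\x00") else ""
                    atoms.append(AtomRecord(
                        model_index=midx,
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        res_name=res.name,
                        atom_name=at.name,
                        alt_loc=alt,
                        element=at.element.name,
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                        b_factor=at.b_iso,
                    ))
    atoms = _dedupe_altlocs(atoms)
    if not atoms:
        raise EmptyStructureError("no (non-hydrogen) atoms found in input")
    return Structure(atoms, source_id=source_id)


def _to_gemmi(frames: Sequence[Structure], name: str) -> gemmi.Structure:
    # gemmi's add_chain/add_residue copy by value, so assemble bottom-up
    st = gemmi.Structure()
    st.name = name or "loopdyn"
    for midx, frame in enumerate(frames, start=1):
        model = gemmi.Model(midx)
        # group atoms by chain then residue, preserving file order
        by_chain: dict[str, dict[tuple, list[AtomRecord]]] = {}
        for a in frame.atoms:
            if not all(-999.999 <= c <= 9999.999 for c in a.coords):
                raise FormattingError(
                    f"coordinate {a.coords} exceeds fixed-column PDB width")
            rkey = (a.res_seq, a.insertion_code, a.res_name)
            by_chain.setdefault(a.chain_id, {}).setdefault(rkey, []).append(a)
        for chain_id, residues in by_chain.items():
            ch = gemmi.Chain(chain_id)
            for (res_seq, icode, res_name), atoms in residues.items():
                res = gemmi.Residue()
                res.name = res_name
                res.seqid = gemmi.SeqId(res_seq, icode or " ")
                res.het_flag = "H" if res_name in WATER_NAMES else "A"
                for a in atoms:
                    at = gemmi.Atom()
                    at.name = a.atom_name
                    at.element = gemmi.Element(a.element)
                    at.altloc = a.alt_loc or "\x00"
                    at.pos = gemmi.Position(*a.coords)
                    at.occ = a.occupancy
                    at.b_iso = a.b_factor
                    res.add_atom(at)
                ch.add_residue(res)
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure) -> str:
    """Serialize a structure to PDB text (one MODEL block per model index)."""
    if not s.atoms:
        raise EmptyStructureError("refusing to write an empty structure")
    frames = [s.model(m) for m in s.model_indices]
    st = _to_gemmi(frames, s.source_id)
    return st.make_pdb_string()


def write_trajectory(t: Trajectory) -> str:
    """Serialize a trajectory as multi-model PDB, one MODEL block per frame."""
    frames = [t.frame_structure(f) for f in range(t.n_frames)]
    st = _to_gemmi(frames, t.topology.source_id)
    return st.make_pdb_string()


def read_trajectory(pdb_text: str, source_id: str = "") -> Trajectory:
    """Read a multi-model PDB as a trajectory (topology = model 1)."""
    s = read_structure(pdb_text, model_policy="all", source_id=source_id)
    midx = s.model_indices
    models = [s.model(m) for m in midx]
    top = models[0]
    sig = [(a.chain_id, a.res_seq, a.insertion_code, a.atom_name) for a in top.atoms]
    coords = []
    for m in models:
        if [(a.chain_id, a.res_seq, a.insertion_code, a.atom_name)
                for a in m.atoms] != sig:
            raise ParseError("models differ in atom content; not a trajectory")
        coords.append(m.coords)
    return Trajectory(top, np.stack(coords, axis=0))


# ---------------------------------------------------------------------------
# Selection resolution
# ---------------------------------------------------------------------------

def resolve_selection(target, sel: Selection, model_index: int = 1,
                      warn: bool = True) -> np.ndarray:
    """Resolve a :class:`Selection` into a deterministic, ordered index list.

    For a :class:`Trajectory` the indices refer to the topology atom table.
    Indices are ordered by (chain, res_seq, insertion code, file order).
    An empty result is legal and returns an empty array (with a warning).
    """
    if isinstance(target, Trajectory):
        s = target.topology
    else:
        s = target
    hits = [(a.chain_id, a.res_seq, a.insertion_code, i)
            for i, a in enumerate(s.atoms)
            if a.model_index == model_index and sel.matches(a)]
    hits.sort()
    idx = np.array([i for *_key, i in hits], dtype=int)
    if idx.size == 0 and warn:
        import warnings
        warnings.warn("selection matched zero atoms", stacklevel=2)
    return idx


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid fit: x_fit = x_mobile @ rotation.T + translation."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_fitted: int

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Kabsch least-squares superposition of ``mobile`` onto ``reference``.

    Both inputs are (N, 3) with N >= 3 and the reference must not be
    collinear (the rotation is otherwise under-determined).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape:
        raise LoopdynError(
            f"point-count mismatch: mobile {mob.shape} vs reference {ref.shape}")
    if mob.ndim != 2 or mob.shape[1] != 3:
        raise LoopdynError("coordinate sets must be (N, 3)")
    n = mob.shape[0]
    if n < 3:
        raise LoopdynError("superposition needs at least 3 points")
    cm = mob.mean(axis=0)
    cr = ref.mean(axis=0)
    x = mob - cm
    y = ref - cr
    sv = np.linalg.svd(y, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise LoopdynError("degenerate (collinear) reference points")
    h = x.T @ y
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    fitted = mob @ rot.T + trans
    val = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans,
                               rmsd=val, n_fitted=n)


def apply_transform(result: SuperpositionResult, xyz: np.ndarray) -> np.ndarray:
    return result.apply(xyz)


def rmsd(a: np.ndarray, b: np.ndarray, fit: bool = False,
         fit_selection: Optional[np.ndarray] = None) -> float:
    """Root-mean-square deviation between two conformations of the same atoms.

    With ``fit=True`` the optimal superposition is computed on
    ``fit_selection`` (default: all points) and applied to ``a`` before
    measuring over all points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise LoopdynError(f"point-count mismatch: {a.shape} vs {b.shape}")
    if fit:
        if fit_selection is None:
            sup = superpose(a, b)
        else:
            fs = np.asarray(fit_selection, dtype=int)
            sup = superpose(a[fs], b[fs])
        a = sup.apply(a)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
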