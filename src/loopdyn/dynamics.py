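"""Trajectory-level statistics: distance-fluctuation matrices, region RMSD
series, stable C-alpha contacts and hydrogen-bond occupancies.

The central quantity is the distance-fluctuation (DF) matrix: for residues
i and j with time-dependent C-alpha distance d_ij, the entry is the
time-average ``DF_ij = <(d_ij - <d_ij>)^2>``, i.e. the population variance
of the inter-residue distance over the trajectory.  Low DF marks residue
pairs that move in a mechanically coordinated way; the quantity is exactly
invariant under rigid-body motion of each frame.

A "stable contact" is a residue pair whose C-alpha distance is below
``d_cut`` (default 6 A) in strictly more than ``f_cut`` (default 30%) of
the sampled frames; both inequalities are strict, so ties are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structures import (
    CA_SELECTION,
    LoopdynError,
    Selection,
    Structure,
    Trajectory,
    resolve_selection,
    superpose,
)

__all__ = [
    "DFMatrix",
    "RMSDSeries",
    "ContactRecord",
    "StableContactSet",
    "ContactComparison",
    "HBondRecord",
    "df_matrix",
    "df_matrix_bruteforce",
    "df_compare",
    "rmsd_series",
    "stable_contacts",
    "contact_fractions",
    "compare_contact_sets",
    "canonical_pair",
    "hbond_occupancy",
    "compare_hbond_occupancy",
    "load_reference_contacts",
]


# ---------------------------------------------------------------------------
# Residue-level resolution helpers
# ---------------------------------------------------------------------------

def _one_atom_per_residue(t: Trajectory, sel: Selection) -> tuple[list, np.ndarray]:
    """Resolve a selection to exactly one atom per residue.

    Returns residue labels (chain, res_seq, res_name) and atom indices.
    """
    idx = resolve_selection(t, sel, warn=False)
    if idx.size == 0:
        raise LoopdynError("selection matched zero atoms")
    per_res: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    top = t.topology
    for i in idx:
        a = top.atoms[i]
        key = (a.chain_id, a.res_seq, a.insertion_code, a.res_name)
        if key not in per_res:
            per_res[key] = []
            order.append(key)
        per_res[key].append(int(i))
    for key in order:
        if len(per_res[key]) != 1:
            raise LoopdynError(
                f"residue {key[0]}{key[1]} has {len(per_res[key])} selected "
                "atoms; need exactly one per residue")
    labels = [(c, s, n) for (c, s, _i, n) in order]
    atom_idx = np.array([per_res[key][0] for key in order], dtype=int)
    return labels, atom_idx


# ---------------------------------------------------------------------------
# Distance fluctuation
# ---------------------------------------------------------------------------

@dataclass
class DFMatrix:
    """N x N per-residue-pair distance-variance matrix (A^2)."""

    labels: list[tuple[str, int, str]]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("values must be N x N for N labels")
        self.values = v

    def block(self, chain_a: str, chain_b: str) -> np.ndarray:
        ia = [k for k, (c, _s, _n) in enumerate(self.labels) if c == chain_a]
        ib = [k for k, (c, _s, _n) in enumerate(self.labels) if c == chain_b]
        return self.values[np.ix_(ia, ib)]


def df_matrix(t: Trajectory, sel: Optional[Selection] = None,
              chunk_frames: int = 64) -> DFMatrix:
    """Distance-fluctuation matrix over the trajectory.

    Entry (i, j) is the population variance (divide by F) of the Euclidean
    distance between the selected atoms of residues i and j across frames.
    The default selection is one C-alpha per (non-water) residue.
    """
    if t.n_frames < 2:
        raise LoopdynError("DF needs at least 2 frames")
    if sel is None:
        sel = CA_SELECTION
    labels, atom_idx = _one_atom_per_residue(t, sel)
    x = t.frames[:, atom_idx, :]  # (F, N, 3)
    n = len(labels)
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    f_total = t.n_frames
    for start in range(0, f_total, chunk_frames):
        chunk = x[start:start + chunk_frames]
        # distances are translation-invariant; centering each frame keeps
        # the gram-matrix evaluation well conditioned
        chunk = chunk - chunk.mean(axis=1, keepdims=True)
        sq = np.einsum("fni,fni->fn", chunk, chunk)
        gram = np.einsum("fni,fmi->fnm", chunk, chunk)
        d2 = np.maximum(sq[:, :, None] + sq[:, None, :] - 2.0 * gram, 0.0)
        d = np.sqrt(d2)
        s1 += d.sum(axis=0)
        s2 += d2.sum(axis=0)
    mean = s1 / f_total
    var = s2 / f_total - mean * mean
    var = np.maximum(var, 0.0)
    var = 0.5 * (var + var.T)
    np.fill_diagonal(var, 0.0)
    return DFMatrix(labels=labels, values=var)


def df_matrix_bruteforce(t: Trajectory, sel: Optional[Selection] = None) -> DFMatrix:
    """Literal double loop over residue pairs and frames (reference oracle)."""
    if sel is None:
        sel = CA_SELECTION
    labels, atom_idx = _one_atom_per_residue(t, sel)
    n = len(labels)
    f = t.n_frames
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.empty(f)
            for k in range(f):
                d[k] = np.linalg.norm(t.frames[k, atom_idx[i]] -
                                      t.frames[k, atom_idx[j]])
            mu = d.sum() / f
            out[i, j] = out[j, i] = np.sum((d - mu) ** 2) / f
    return DFMatrix(labels=labels, values=out)


@dataclass
class DFComparison:
    """Element-wise delta (b - a) and per-chain-block medians of two DF maps."""

    labels: list
    delta: np.ndarray
    block_medians_a: dict
    block_medians_b: dict
    block_medians_delta: dict


def df_compare(a: DFMatrix, b: DFMatrix) -> DFComparison:
    if a.labels != b.labels:
        raise LoopdynError("DF matrices have different residue labels")
    delta = b.values - a.values
    chains = []
    for c, _s, _n in a.labels:
        if c not in chains:
            chains.append(c)

    def block_medians(values: np.ndarray) -> dict:
        out = {}
        for ca in chains:
            for cb in chains:
                ia = [k for k, (c, _s, _n) in enumerate(a.labels) if c == ca]
                ib = [k for k, (c, _s, _n) in enumerate(a.labels) if c == cb]
                blk = values[np.ix_(ia, ib)]
                if ca == cb:
                    mask = ~np.eye(len(ia), dtype=bool)
                    vals = blk[mask]
                else:
                    vals = blk.ravel()
                out[(ca, cb)] = float(np.median(vals)) if vals.size else float("nan")
        return out

    return DFComparison(
        labels=a.labels,
        delta=delta,
        block_medians_a=block_medians(a.values),
        block_medians_b=block_medians(b.values),
        block_medians_delta=block_medians(delta),
    )


# ---------------------------------------------------------------------------
# RMSD series
# ---------------------------------------------------------------------------

@dataclass
class RMSDSeries:
    values: np.ndarray  # per-frame RMSD, A
    fit_selection: Selection
    measure_selection: Selection
    reference_id: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def rmsd_series(t: Trajectory, reference: Structure,
                fit_sel: Selection, measure_sel: Selection) -> RMSDSeries:
    """Per-frame RMSD to a reference after superposing each frame on fit_sel.

    Selections are resolved on both the trajectory topology and the
    reference structure (they must resolve to the same atom count).
    """
    fit_t = resolve_selection(t, fit_sel, warn=False)
    fit_r = resolve_selection(reference, fit_sel, warn=False)
    mea_t = resolve_selection(t, measure_sel, warn=False)
    mea_r = resolve_selection(reference, measure_sel, warn=False)
    if fit_t.size == 0 or mea_t.size == 0:
        raise LoopdynError("empty selection in rmsd_series")
    if fit_t.size != fit_r.size or mea_t.size != mea_r.size:
        raise LoopdynError("selection resolves to different atom counts on "
                           "trajectory and reference")
    ref_xyz = reference.coords
    ref_fit = ref_xyz[fit_r]
    ref_mea = ref_xyz[mea_r]
    out = np.empty(t.n_frames)
    for f in range(t.n_frames):
        sup = superpose(t.frames[f][fit_t], ref_fit)
        moved = sup.apply(t.frames[f][mea_t])
        out[f] = np.sqrt(np.mean(np.sum((moved - ref_mea) ** 2, axis=1)))
    return RMSDSeries(values=out, fit_selection=fit_sel,
                      measure_selection=measure_sel,
                      reference_id=reference.source_id)


# ---------------------------------------------------------------------------
# Stable contacts
# ---------------------------------------------------------------------------

ResidueKey = tuple  # (chain, res_seq, res_name) or any hashable residue id


def canonical_pair(a: ResidueKey, b: ResidueKey) -> tuple:
    """Unordered residue pair stored canonically (lexicographic order)."""
    return (a, b) if repr(a) <= repr(b) else (b, a)


@dataclass(frozen=True)
class ContactRecord:
    residue_a: ResidueKey
    residue_b: ResidueKey
    fraction: float


@dataclass
class StableContactSet:
    records: list[ContactRecord]
    d_cut: float
    f_cut: float
    n_frames: int

    @property
    def pairs(self) -> set:
        return {canonical_pair(r.residue_a, r.residue_b) for r in self.records}

    def fraction_of(self, res_a: ResidueKey, res_b: ResidueKey) -> Optional[float]:
        key = canonical_pair(res_a, res_b)
        for r in self.records:
            if canonical_pair(r.residue_a, r.residue_b) == key:
                return r.fraction
        return None


def contact_fractions(t: Trajectory, query: Selection, against: Selection,
                      d_cut: float = 6.0,
                      neighbor_exclusion: int = 2) -> dict[tuple, float]:
    """Fraction of frames each residue pair spends below ``d_cut`` (strict).

    Pairs within ``neighbor_exclusion`` sequence positions on the same
    chain (and self pairs) are dropped: they are trivially in contact.
    """
    if t.n_frames == 0:
        raise LoopdynError("trajectory has no frames")
    lab_q, idx_q = _one_atom_per_residue(t, query)
    lab_a, idx_a = _one_atom_per_residue(t, against)
    xq = t.frames[:, idx_q, :]
    xa = t.frames[:, idx_a, :]
    diff = xq[:, :, None, :] - xa[:, None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))  # (F, Nq, Na)
    counts = (d < d_cut).sum(axis=0)
    out: dict[tuple, float] = {}
    for qi, ql in enumerate(lab_q):
        for ai, al in enumerate(lab_a):
            if ql == al:
                continue
            if ql[0] == al[0] and abs(ql[1] - al[1]) <= neighbor_exclusion:
                continue
            pair = canonical_pair(ql, al)
            out[pair] = counts[qi, ai] / t.n_frames
    return out


def stable_contacts(t: Trajectory, query: Selection, against: Selection,
                    d_cut: float = 6.0, f_cut: float = 0.30,
                    neighbor_exclusion: int = 2) -> StableContactSet:
    """Residue pairs whose C-alpha distance is < d_cut in > f_cut of frames."""
    fractions = contact_fractions(t, query, against, d_cut, neighbor_exclusion)
    records = [ContactRecord(pair[0], pair[1], frac)
               for pair, frac in sorted(fractions.items(), key=lambda kv: repr(kv[0]))
               if frac > f_cut]
    return StableContactSet(records=records, d_cut=d_cut, f_cut=f_cut,
                            n_frames=t.n_frames)


@dataclass
class ContactComparison:
    conserved: set
    lost: set
    gained: set

    @property
    def n_conserved(self) -> int:
        return len(self.conserved)

    @property
    def n_lost(self) -> int:
        return len(self.lost)

    @property
    def n_gained(self) -> int:
        return len(self.gained)


def compare_contact_sets(holo: set, apo: set) -> ContactComparison:
    """Partition contact pairs into conserved / lost (holo-only) / gained."""
    holo = set(holo)
    apo = set(apo)
    return ContactComparison(
        conserved=holo & apo,
        lost=holo - apo,
        gained=apo - holo,
    )


def load_reference_contacts() -> dict[str, set]:
    """Packaged transcription of the published APO/HOLO stable-contact table.

    Returns ``{"HOLO": set of canonical pairs, "APO": ...}`` with residues
    keyed as (res_name, res_number_string); companion-chain partners carry
    a prime suffix on the number.
    """
    import importlib.resources as resources

    import pandas as pd

    with (resources.files("loopdyn") / "data" /
          "reference_contacts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    out: dict[str, set] = {"HOLO": set(), "APO": set()}
    for _, row in df.iterrows():
        pair = canonical_pair((row["res_a"], row["num_a"]),
                              (row["res_b"], row["num_b"]))
        out[row["state"]].add(pair)
    return out


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondRecord:
    donor: tuple  # (chain, res_seq, res_name, atom_name)
    acceptor: tuple
    occupancy: float
    inter_protomer: bool


def hbond_occupancy(t: Trajectory, inter_protomer_only: bool = False,
                    hb_cut: float = 3.5, include_waters: bool = False,
                    min_seq_sep: int = 2) -> list[HBondRecord]:
    """Donor(N)/acceptor(O) heavy-atom distance occupancies over frames.

    The geometric criterion is donor-acceptor distance <= ``hb_cut``
    (3.5 A conventional heavy-atom cutoff; no angle term, as crystal
    inputs carry no hydrogens).  Pairs closer than ``min_seq_sep`` in
    sequence on the same chain are skipped as covalently constrained.
    Only pairs with non-zero occupancy are returned.
    """
    top = t.topology
    donors = [(i, a) for i, a in enumerate(top.atoms)
              if a.element == "N" and (include_waters or not a.is_water)]
    acceptors = [(i, a) for i, a in enumerate(top.atoms)
                 if a.element == "O" and (include_waters or not a.is_water)]
    if not donors or not acceptors:
        raise LoopdynError("no polar (N/O) atoms in topology")
    di = np.array([i for i, _ in donors])
    ai = np.array([i for i, _ in acceptors])
    xd = t.frames[:, di, :]
    xa = t.frames[:, ai, :]
    counts = np.zeros((len(donors), len(acceptors)), dtype=int)
    for f in range(t.n_frames):
        diff = xd[f][:, None, :] - xa[f][None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))
        counts += d <= hb_cut
    records = []
    for p, (_, don) in enumerate(donors):
        for q, (_, acc) in enumerate(acceptors):
            if counts[p, q] == 0:
                continue
            same_chain = don.chain_id == acc.chain_id
            if same_chain and abs(don.res_seq - acc.res_seq) < min_seq_sep:
                continue
            if inter_protomer_only and same_chain:
                continue
            records.append(HBondRecord(
                donor=(don.chain_id, don.res_seq, don.res_name, don.atom_name),
                acceptor=(acc.chain_id, acc.res_seq, acc.res_name, acc.atom_name),
                occupancy=counts[p, q] / t.n_frames,
                inter_protomer=not same_chain,
            ))
    records.sort(key=lambda r: (r.donor, r.acceptor))
    return records


@dataclass
class StabilizedResidue:
    residue: tuple  # (chain, res_seq, res_name)
    max_delta: float
    domain: str  # "N" or "C"
    pairs: list


def compare_hbond_occupancy(apo: Sequence[HBondRecord],
                            holo: Sequence[HBondRecord],
                            delta_cut: float = 0.30,
                            domain_split: int = 190) -> list[StabilizedResidue]:
    """Residues whose H-bond occupancy rises by >= delta_cut from apo to holo.

    ``domain_split`` assigns residues below the split to the N-domain and
    the rest to the C-domain, for annotation only.
    """
    key = lambda r: (r.donor, r.acceptor)
    apo_map = {key(r): r.occupancy for r in apo}
    holo_map = {key(r): r.occupancy for r in holo}
    per_res: dict[tuple, list] = {}
    for k, occ_h in holo_map.items():
        delta = occ_h - apo_map.get(k, 0.0)
        if delta >= delta_cut:
            for atom in k:
                res = (atom[0], atom[1], atom[2])
                per_res.setdefault(res, []).append((k, delta))
    out = []
    for res, pairs in sorted(per_res.items()):
        out.append(StabilizedResidue(
            residue=res,
            max_delta=max(d for _k, d in pairs),
            domain="N" if res[1] < domain_split else "C",
            pairs=[k for k, _d in pairs],
        ))
    return out
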