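"""Structure-ensemble quality accounting for NMR model bundles.

Covers the bookkeeping behind a structure-statistics table: classification of
NOE distance restraints by residue separation |i-j|, counting of upper-bound
violations across an ensemble, and mean +/- SD pairwise RMSD after optimal
rigid-body superposition over a named atom selection (backbone or heavy) and
optional residue regions (e.g. secondary-structure elements).

Restraint categories follow the exhaustive convention: intra-residue |i-j|=0,
sequential |i-j|=1, medium-range 2 <= |i-j| <= 4, long-range |i-j| >= 5, so
the four counts always partition the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RestraintRecord",
    "RestraintSummary",
    "StructureEnsemble",
    "RmsdReport",
    "ViolationReport",
    "classify_restraints",
    "count_violations",
    "superpose_pair",
    "kabsch",
    "ensemble_rmsd",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_restraints_csv",
    "read_upl",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
HYDROGEN_PREFIXES = ("H", "1H", "2H", "3H")


@dataclass(frozen=True)
class RestraintRecord:
    """One inter-proton upper-bound distance restraint."""

    res_i: int
    res_j: int
    upper_A: float
    atom_i: str | None = None
    atom_j: str | None = None

    def __post_init__(self) -> None:
        if self.res_i < 1 or self.res_j < 1:
            raise ValueError("residue numbers must be >= 1")
        if self.upper_A <= 0:
            raise ValueError("upper bound must be positive")


@dataclass
class RestraintSummary:
    total: int
    intra: int
    sequential: int
    medium: int
    long: int

    def __post_init__(self) -> None:
        if self.intra + self.sequential + self.medium + self.long != self.total:
            raise ValueError("restraint categories do not partition the total")


def classify_restraints(restraints: Iterable[RestraintRecord]) -> RestraintSummary:
    """Count restraints by sequence separation; the four classes are exhaustive
    and mutually exclusive, so they always sum to the total."""
    intra = seq = med = lng = 0
    total = 0
    for rec in restraints:
        sep = abs(rec.res_i - rec.res_j)
        total += 1
        if sep == 0:
            intra += 1
        elif sep == 1:
            seq += 1
        elif sep <= 4:
            med += 1
        else:
            lng += 1
    return RestraintSummary(total=total, intra=intra, sequential=seq,
                            medium=med, long=lng)


class StructureEnsemble:
    """N conformers sharing one atom roster.

    Parameters
    ----------
    atoms : sequence of ``(atom_name, residue_number)`` defining the roster.
    coords : array of shape ``(n_models, n_atoms, 3)`` in Angstrom.
    ss_regions : optional residue ranges ``[(start, end), ...]`` (inclusive)
        marking secondary-structure elements, used as the default region mask.
    """

    def __init__(self, atoms, coords, ss_regions=None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if coords.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 models")
        if coords.shape[1] != len(atoms):
            raise ValueError("coords second axis must match the atom roster")
        self.atoms = [(str(a), int(r)) for a, r in atoms]
        self.coords = coords
        self.ss_regions = [tuple(map(int, rg)) for rg in (ss_regions or [])]

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def residue_numbers(self) -> set[int]:
        return {r for _, r in self.atoms}

    def selection_mask(self, selection="backbone", regions=None) -> np.ndarray:
        """Boolean mask over the roster for a named selection and regions.

        ``selection``: 'backbone' (N, CA, C, O), 'heavy' (non-hydrogen) or
        'all'.  ``regions``: inclusive residue ranges; ``"ss"`` uses the
        ensemble's stored secondary-structure elements; None keeps everything.
        """
        if selection == "backbone":
            keep = [a in BACKBONE_ATOMS for a, _ in self.atoms]
        elif selection == "heavy":
            keep = [not a.startswith(HYDROGEN_PREFIXES) for a, _ in self.atoms]
        elif selection == "all":
            keep = [True] * len(self.atoms)
        else:
            raise ValueError(f"unknown selection {selection!r}")
        mask = np.array(keep)
        if regions == "ss":
            regions = self.ss_regions or None
        if regions is not None:
            in_region = np.array([
                any(lo <= r <= hi for lo, hi in regions) for _, r in self.atoms
            ])
            mask &= in_region
        return mask

    def atom_indices(self, residue: int, atom: str | None = None) -> np.ndarray:
        """Roster indices for a residue, optionally narrowed to an atom name.
        A trailing ``*`` in the atom name matches as a prefix (pseudo-atoms)."""
        idx = [i for i, (a, r) in enumerate(self.atoms) if r == residue]
        if atom:
            if atom.endswith("*"):
                pre = atom[:-1]
                idx = [i for i in idx if self.atoms[i][0].startswith(pre)]
            else:
                idx = [i for i in idx if self.atoms[i][0] == atom]
        return np.array(idx, dtype=int)


@dataclass
class RmsdReport:
    mean_A: float
    sd_A: float
    n_pairs: int
    selection: str
    regions: str
    pairwise_A: list[float] = field(default_factory=list)


@dataclass
class ViolationReport:
    n_over_threshold: list[int]
    mean: float
    sd: float
    max_violation_A: float
    threshold_A: float


def kabsch(a: np.ndarray, b: np.ndarray):
    """Optimal proper rotation R and translation t minimizing ||R a + t - b||.

    SVD-based; the determinant sign is corrected so no reflection is returned.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cb - rot @ ca
    return rot, trans


def superpose_pair(model_a, model_b, selection_mask=None):
    """Least-squares rigid superposition of model_a onto model_b.

    Returns ``(rotation, translation, rmsd_A)`` over the selected atoms.
    Raises on fewer than 3 selected atoms or a degenerate (collinear)
    selection, where the rotation is not unique.
    """
    a = np.asarray(model_a, float)
    b = np.asarray(model_b, float)
    if selection_mask is not None:
        a = a[selection_mask]
        b = b[selection_mask]
    if len(a) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    centered = a - a.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom selection")
    rot, trans = kabsch(a, b)
    moved = a @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return rot, trans, rmsd


def ensemble_rmsd(
    ensemble: StructureEnsemble,
    selection: str = "backbone",
    regions=None,
) -> RmsdReport:
    """Mean +/- SD of pairwise post-superposition RMSD over all unordered
    model pairs.  SD is the sample SD (ddof=1) over the pair values."""
    mask = ensemble.selection_mask(selection, regions)
    vals = []
    n = ensemble.n_models
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = superpose_pair(
                ensemble.coords[i], ensemble.coords[j], mask
            )
            vals.append(r)
    arr = np.array(vals)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    region_label = "ss" if regions == "ss" else (
        "all" if regions is None else ",".join(f"{a}-{b}" for a, b in regions)
    )
    return RmsdReport(
        mean_A=float(arr.mean()), sd_A=sd, n_pairs=len(arr),
        selection=selection, regions=region_label, pairwise_A=vals,
    )


def count_violations(
    ensemble: StructureEnsemble,
    restraints: Sequence[RestraintRecord],
    threshold_A: float = 0.2,
) -> ViolationReport:
    """Count upper-bound violations per model.

    A restraint's model distance is the minimum over all matching atom pairs
    (standard upper-bound semantics for ambiguous/pseudo-atoms); the violation
    is ``d - upper_A`` where positive.  Counted when the excess exceeds
    ``threshold_A``; the report carries per-model counts, their mean and
    sample SD, and the largest excess seen anywhere.
    """
    pair_idx = []
    for rec in restraints:
        ii = ensemble.atom_indices(rec.res_i, rec.atom_i)
        jj = ensemble.atom_indices(rec.res_j, rec.atom_j)
        if len(ii) == 0 or len(jj) == 0:
            raise ValueError(f"restraint references atoms absent from models: {rec}")
        pair_idx.append((ii, jj, rec.upper_A))
    counts = []
    max_viol = 0.0
    for m in range(ensemble.n_models):
        xyz = ensemble.coords[m]
        n_over = 0
        for ii, jj, upper in pair_idx:
            diff = xyz[ii][:, None, :] - xyz[jj][None, :, :]
            d = float(np.sqrt((diff**2).sum(axis=2)).min())
            excess = d - upper
            if excess > max_viol:
                max_viol = excess
            if excess > threshold_A:
                n_over += 1
        counts.append(n_over)
    arr = np.array(counts, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return ViolationReport(
        n_over_threshold=counts, mean=float(arr.mean()), sd=sd,
        max_violation_A=float(max(max_viol, 0.0)), threshold_A=threshold_A,
    )


# ---------------------------------------------------------------- file I/O

def read_pdb_ensemble(path) -> StructureEnsemble:
    """Read a multi-MODEL PDB file (first chain of each model).

    HELIX/SHEET header records, when present, populate ``ss_regions``.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    rosters = []
    coord_sets = []
    for model in st:
        roster = []
        xyz = []
        for chain in model:
            for res in chain:
                for atom in res:
                    roster.append((atom.name, res.seqid.num))
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
            break  # first chain only
        rosters.append(roster)
        coord_sets.append(xyz)
    if len(coord_sets) < 2:
        raise ValueError("PDB file contains fewer than 2 models")
    if any(r != rosters[0] for r in rosters[1:]):
        raise ValueError("models do not share a common atom roster")
    ss = []
    for helix in st.helices:
        ss.append((helix.start.res_id.seqid.num, helix.end.res_id.seqid.num))
    for sheet in st.sheets:
        for strand in sheet.strands:
            ss.append((strand.start.res_id.seqid.num, strand.end.res_id.seqid.num))
    return StructureEnsemble(rosters[0], np.array(coord_sets), ss_regions=ss)


def write_pdb_ensemble(ensemble: StructureEnsemble, path) -> None:
    """Write a minimal multi-MODEL PDB (single chain A, residue name GLY)."""
    with open(path, "w") as fh:
        for hx, (lo, hi) in enumerate(ensemble.ss_regions, start=1):
            fh.write(
                f"HELIX  {hx:>3} {hx:>3} GLY A {lo:>4}  GLY A {hi:>4}  1"
                f"{'':30}{hi - lo + 1:>6}\n"
            )
        for m in range(ensemble.n_models):
            fh.write(f"MODEL     {m + 1:>4}\n")
            serial = 1
            for (name, resnum), (x, y, z) in zip(
                ensemble.atoms, ensemble.coords[m]
            ):
                pad_name = f" {name:<3}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {serial:>5} {pad_name} GLY A{resnum:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {name[0]:>2}\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_restraints_csv(path) -> list[RestraintRecord]:
    """Read `res_i,atom_i,res_j,atom_j,upper_A`; atom columns may be empty."""
    df = pd.read_csv(path)
    recs = []
    for _, row in df.iterrows():
        ai = row.get("atom_i")
        aj = row.get("atom_j")
        recs.append(RestraintRecord(
            res_i=int(row["res_i"]), res_j=int(row["res_j"]),
            upper_A=float(row["upper_A"]),
            atom_i=None if pd.isna(ai) or ai == "" else str(ai),
            atom_j=None if pd.isna(aj) or aj == "" else str(aj),
        ))
    return recs


def read_upl(path) -> list[RestraintRecord]:
    """Read a CYANA-style .upl file: `res_i name_i atom_i res_j name_j atom_j upper`."""
    recs = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            recs.append(RestraintRecord(
                res_i=int(parts[0]), atom_i=parts[2],
                res_j=int(parts[3]), atom_j=parts[5],
                upper_A=float(parts[6]),
            ))
    return recs
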