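"""Per-residue backbone dihedral time series.

A :class:`DihedralSeries` holds, for one trajectory replicate of one state
(apo or a named ligand-bound state), the per-frame (phi, psi) angles of every
residue.  Angles live on [-180, 180); undefined angles (chain termini,
missing backbone atoms, degenerate geometry) are NaN and the residue is
excluded from scoring downstream.

Series can be extracted from a topology + trajectory readable by MDAnalysis
(PDB, DCD, XTC, NetCDF, in-memory universes) or round-tripped through a plain
CSV dialect with header ``frame,chain,residue,phi,psi`` (plus an optional
``resname`` column), one row per residue per frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import torsion_angles, wrap_angle

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueId",
    "DihedralSeries",
    "extract_dihedrals",
    "read_dihedral_table",
    "write_dihedral_table",
]


@dataclass(frozen=True, order=True)
class ResidueId:
    """Identity of a residue: chain label, author residue number, 3-letter name.

    Insertion codes, when present, are carried in ``icode`` and take part in
    identity.  Comparisons order by (chain, seq_number, icode).
    """

    chain: str
    seq_number: int
    name: str = field(compare=False, default="UNK")
    icode: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValueError("residue name must be non-empty")

    def __str__(self) -> str:
        return f"{self.chain}:{self.name}{self.seq_number}{self.icode}"


@dataclass
class DihedralSeries:
    """(phi, psi) time series for every residue of one replicate of one state.

    ``phi`` and ``psi`` are (n_residues, n_frames) float arrays in degrees on
    [-180, 180), NaN where undefined.  By construction phi is undefined for
    the first residue of each chain and psi for the last.
    """

    state_label: str
    replicate: int
    residues: list[ResidueId]
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        n = len(self.residues)
        if self.phi.shape != self.psi.shape or self.phi.ndim != 2 or self.phi.shape[0] != n:
            raise ValueError("phi/psi must be (n_residues, n_frames) arrays matching residues")
        if self.phi.shape[1] < 1:
            raise ValueError("at least one frame required")
        if self.replicate < 1:
            raise ValueError("replicate index is 1-based")
        for arr in (self.phi, self.psi):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < -180.0 or finite.max() >= 180.0):
                raise ValueError("angles must lie in [-180, 180)")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[1]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def defined_mask(self) -> np.ndarray:
        """Boolean per-residue mask: True where phi and psi are defined in all frames."""
        return np.isfinite(self.phi).all(axis=1) & np.isfinite(self.psi).all(axis=1)

    def residue_index(self) -> dict[ResidueId, int]:
        return {r: i for i, r in enumerate(self.residues)}


def _universe(topology, trajectory):
    import MDAnalysis as mda

    if trajectory is None:
        if isinstance(topology, mda.Universe):
            return topology
        return mda.Universe(str(topology))
    trajs = [str(t) for t in (trajectory if isinstance(trajectory, (list, tuple)) else [trajectory])]
    return mda.Universe(str(topology), *trajs)


def extract_dihedrals(topology, trajectory=None, state_label: str = "apo",
                      replicate: int = 1) -> DihedralSeries:
    """Compute per-residue backbone (phi, psi) series from a trajectory.

    phi(i) is the torsion C(i-1)-N(i)-CA(i)-C(i) and psi(i) is
    N(i)-CA(i)-C(i)-N(i+1); both are computed within a single chain
    (segment), so termini get NaN.  Residues missing any backbone atom are
    flagged undefined with a warning rather than aborting the extraction.

    Parameters
    ----------
    topology
        Path to a structure file (e.g. PDB) or an ``MDAnalysis.Universe``.
    trajectory
        Optional path(s) to coordinate file(s) (DCD/XTC/NetCDF/...).  When
        omitted the topology's own coordinates are used.
    """
    u = _universe(topology, trajectory)
    protein = u.select_atoms("protein") if len(u.select_atoms("protein")) else u.atoms
    residues = list(protein.residues)

    ids: list[ResidueId] = []
    backbone: list[dict] = []
    for res in residues:
        seg = res.segment.segid if res.segment.segid.strip() else getattr(res, "chainID", "A")
        icode = getattr(res, "icode", "") or ""
        ids.append(ResidueId(chain=str(seg).strip() or "A", seq_number=int(res.resid),
                             name=str(res.resname), icode=str(icode).strip()))
        atoms = {}
        for name in ("N", "CA", "C"):
            sel = res.atoms.select_atoms(f"name {name}")
            if len(sel) == 0:
                logger.warning("residue %s missing backbone atom %s; dependent dihedrals"
                               " undefined", ids[-1], name)
                continue
            if len(sel) > 1:
                logger.info("residue %s: multiple %s atoms (altlocs?); first taken", ids[-1], name)
            atoms[name] = sel.indices[0]
        backbone.append(atoms)

    n_res = len(ids)
    n_frames = len(u.trajectory)
    phi = np.full((n_res, n_frames), np.nan)
    psi = np.full((n_res, n_frames), np.nan)

    # quadruple index tables; -1 marks an undefined angle
    phi_idx = np.full((n_res, 4), -1, dtype=int)
    psi_idx = np.full((n_res, 4), -1, dtype=int)
    for i in range(n_res):
        own = backbone[i]
        has_own = all(k in own for k in ("N", "CA", "C"))
        if not has_own:
            continue
        if i > 0 and ids[i - 1].chain == ids[i].chain and "C" in backbone[i - 1]:
            phi_idx[i] = [backbone[i - 1]["C"], own["N"], own["CA"], own["C"]]
        if i + 1 < n_res and ids[i + 1].chain == ids[i].chain and "N" in backbone[i + 1]:
            psi_idx[i] = [own["N"], own["CA"], own["C"], backbone[i + 1]["N"]]

    phi_rows = np.where(phi_idx[:, 0] >= 0)[0]
    psi_rows = np.where(psi_idx[:, 0] >= 0)[0]
    for f, _ in enumerate(u.trajectory):
        pos = u.atoms.positions.astype(float)
        if phi_rows.size:
            q = phi_idx[phi_rows]
            phi[phi_rows, f] = torsion_angles(pos[q[:, 0]], pos[q[:, 1]], pos[q[:, 2]], pos[q[:, 3]])
        if psi_rows.size:
            q = psi_idx[psi_rows]
            psi[psi_rows, f] = torsion_angles(pos[q[:, 0]], pos[q[:, 1]], pos[q[:, 2]], pos[q[:, 3]])

    return DihedralSeries(state_label=state_label, replicate=replicate,
                          residues=ids, phi=phi, psi=psi)


def write_dihedral_table(series: DihedralSeries, path) -> None:
    """Write a series to CSV (``frame,chain,residue,resname,phi,psi``).

    Undefined angles become empty cells; decimal separator is '.'.
    """
    rows = []
    for f in range(series.n_frames):
        for i, rid in enumerate(series.residues):
            rows.append((f + 1, rid.chain, rid.seq_number, rid.name,
                         series.phi[i, f], series.psi[i, f]))
    df = pd.DataFrame(rows, columns=["frame", "chain", "residue", "resname", "phi", "psi"])
    df.to_csv(path, index=False, float_format="%.10g", na_rep="")


def read_dihedral_table(path, state_label: str = "apo", replicate: int = 1) -> DihedralSeries:
    """Read a dihedral CSV back into a :class:`DihedralSeries`.

    Angles outside [-180, 180) are wrapped by +-360; empty cells mean
    undefined.  Every residue must appear in every frame.

    Raises
    ------
    ValueError
        On a non-numeric angle cell (naming the offending row) or on
        inconsistent frame counts across residues.
    """
    df = pd.read_csv(path, dtype={"chain": str})
    required = {"frame", "chain", "residue", "phi", "psi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dihedral table missing columns: {sorted(missing)}")
    if "resname" not in df.columns:
        df["resname"] = "UNK"
    df["resname"] = df["resname"].fillna("UNK")

    for col in ("phi", "psi"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based + header line
            raise ValueError(f"non-numeric {col} value {df[col][bad].iloc[0]!r} at line {row}")
        df[col] = coerced

    frames = np.sort(df["frame"].unique())
    keys = df.groupby(["chain", "residue", "resname"], sort=False).size()
    if keys.nunique() > 1 or keys.iloc[0] != len(frames):
        bad_key = keys.index[keys != len(frames)]
        raise ValueError(f"inconsistent frame counts across residues (e.g. {list(bad_key[:3])})")

    # residue order: chain then residue number, first-appearance name
    first = df.drop_duplicates(subset=["chain", "residue"]).sort_values(["chain", "residue"])
    ids = [ResidueId(chain=str(r.chain), seq_number=int(r.residue), name=str(r.resname))
           for r in first.itertuples()]
    index = {(rid.chain, rid.seq_number): i for i, rid in enumerate(ids)}
    frame_pos = {f: j for j, f in enumerate(frames)}

    phi = np.full((len(ids), len(frames)), np.nan)
    psi = np.full((len(ids), len(frames)), np.nan)
    ri = df.apply(lambda r: index[(str(r["chain"]), int(r["residue"]))], axis=1).to_numpy()
    fi = df["frame"].map(frame_pos).to_numpy()
    phi[ri, fi] = wrap_angle(df["phi"].to_numpy())
    psi[ri, fi] = wrap_angle(df["psi"].to_numpy())
    # wrap_angle maps NaN to NaN under numpy arithmetic; keep as undefined
    return DihedralSeries(state_label=state_label, replicate=replicate,
                          residues=ids, phi=phi, psi=psi)
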