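"""Per-residue scoring of apo vs ligand-bound dihedral ensembles.

Each residue's (phi, psi) distribution over a trajectory is binned into a
180 x 180 Ramachandran matrix (2-degree bins over the full torus).  The raw
difference between the bound (B_L) and apo (B_A) matrices for a residue is

    raw_diff = sum_cells | B_L - B_A |

which, with frequency-normalized matrices, equals twice the total-variation
distance between the two binned distributions and hence lies in [0, 2]:
0 for identical distributions, 2 for disjoint support (a complete microstate
shift).  Within a comparison group (one ligand state, one replicate pairing)
raw differences are divided by the group maximum, giving the normalized
score in [0, 1]; the residue whose distribution changes most scores exactly
1.  Scores are averaged across replicates, binding-site residues are flagged
and excluded from candidate ranking, and mean scores can be projected onto a
PDB structure through the B-factor column for visualization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dihedrals import DihedralSeries, ResidueId

logger = logging.getLogger(__name__)

__all__ = [
    "N_BINS",
    "RamachandranMatrix",
    "ScoreRecord",
    "ScoreTable",
    "build_rama_matrix",
    "raw_difference",
    "fscore2",
    "score_states",
    "aggregate",
    "rank_candidates",
    "project_to_pdb",
]

N_BINS = 180  # 2-degree bins over [-180, 180) in each of phi and psi
_EDGES = np.linspace(-180.0, 180.0, N_BINS + 1)


@dataclass
class RamachandranMatrix:
    """180 x 180 binned (phi, psi) distribution of one residue in one state.

    Bin (i, j) covers phi in [-180 + 2i, -180 + 2(i+1)) and psi likewise.
    With ``normalized=True`` entries are frequencies summing to 1; in count
    mode they are raw frame counts.
    """

    residue: ResidueId
    state_label: str
    replicate: int
    bins: np.ndarray
    frames_used: int
    normalized: bool = True

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (N_BINS, N_BINS):
            raise ValueError(f"expected {N_BINS}x{N_BINS} matrix, got {self.bins.shape}")
        if (self.bins < 0).any():
            raise ValueError("bin frequencies must be non-negative")


def build_rama_matrix(series: DihedralSeries, residue: ResidueId,
                      normalize: bool = True) -> RamachandranMatrix | None:
    """Bin a residue's (phi, psi) trajectory into a Ramachandran matrix.

    Each frame increments exactly one bin, index floor((angle + 180) / 2).
    Returns None when the residue has undefined angles (consumed downstream
    as ``is_defined = False``).
    """
    idx = series.residue_index()
    if residue not in idx:
        raise KeyError(f"residue {residue} not in series")
    i = idx[residue]
    phi = series.phi[i]
    psi = series.psi[i]
    if not (np.isfinite(phi).all() and np.isfinite(psi).all()):
        return None
    counts, _, _ = np.histogram2d(phi, psi, bins=[_EDGES, _EDGES])
    frames = series.n_frames
    bins = counts / frames if normalize else counts
    return RamachandranMatrix(residue=residue, state_label=series.state_label,
                              replicate=series.replicate, bins=bins,
                              frames_used=frames, normalized=normalize)


def raw_difference(bound: RamachandranMatrix, apo: RamachandranMatrix) -> float:
    """Sum of absolute cell-wise differences between bound and apo matrices.

    Symmetric in its arguments; for frequency-normalized matrices the value
    lies in [0, 2].
    """
    if bound.bins.shape != apo.bins.shape:
        raise ValueError("matrix shape mismatch")
    return float(np.abs(bound.bins - apo.bins).sum())


def fscore2(raw_diffs: dict[ResidueId, float]) -> dict[ResidueId, float]:
    """Normalize raw differences of one comparison group to [0, 1].

    Each value is divided by the largest raw difference in the group, so the
    arg-max residue(s) score exactly 1 and the transform is order-preserving.
    If every raw difference is zero (the two states are indistinguishable)
    all scores are 0 and a warning is emitted.
    """
    if not raw_diffs:
        return {}
    top = max(raw_diffs.values())
    if top == 0.0:
        warnings.warn("all raw differences are zero: apo and bound ensembles "
                      "indistinguishable; scores set to 0", stacklevel=2)
        return {r: 0.0 for r in raw_diffs}
    return {r: v / top for r, v in raw_diffs.items()}


@dataclass
class ScoreRecord:
    """One residue's score in one (ligand_state, replicate) comparison."""

    residue: ResidueId
    ligand_state: str
    replicate: int
    raw_diff: float
    fscore2: float
    is_binding_site: bool = False
    is_defined: bool = True


def _merge_series(series_list: list[DihedralSeries]) -> DihedralSeries:
    """Concatenate replicates frame-wise (pooled-apo policy)."""
    base = series_list[0]
    for s in series_list[1:]:
        if s.residues != base.residues:
            raise ValueError("pooled series must share an identical residue list")
    return DihedralSeries(
        state_label=base.state_label, replicate=1, residues=base.residues,
        phi=np.concatenate([s.phi for s in series_list], axis=1),
        psi=np.concatenate([s.psi for s in series_list], axis=1))


def score_states(apo_reps: list[DihedralSeries], bound_reps: list[DihedralSeries],
                 ligand_state: str | None = None, pairing: str = "indexed",
                 binding_site: list[ResidueId] | None = None,
                 normalize_bins: bool = True) -> list[ScoreRecord]:
    """Score every shared residue of an apo/bound ensemble pair.

    Pairing policies:

    - ``"indexed"`` (default): bound replicate i is compared against apo
      replicate i; replicate counts must match.
    - ``"pooled-apo"``: all apo replicates are merged into a single reference
      histogram per residue; each bound replicate is compared against it.
    - ``"all-pairs"``: every (bound, apo) combination yields a record.

    Normalization to the group maximum is applied within each comparison
    group (one bound replicate against its apo counterpart).
    """
    if not apo_reps or not bound_reps:
        raise ValueError("need at least one apo and one bound replicate")
    ligand_state = ligand_state or bound_reps[0].state_label
    site = set(binding_site or [])

    if pairing == "indexed":
        if len(apo_reps) != len(bound_reps):
            raise ValueError(
                f"indexed pairing needs equal replicate counts (got {len(apo_reps)} apo, "
                f"{len(bound_reps)} bound); consider pairing='pooled-apo'")
        pairs = [(a, b, b.replicate) for a, b in zip(apo_reps, bound_reps)]
    elif pairing == "pooled-apo":
        pooled = _merge_series(apo_reps)
        pairs = [(pooled, b, b.replicate) for b in bound_reps]
    elif pairing == "all-pairs":
        pairs = [(a, b, k + 1) for k, (b, a) in
                 enumerate((b, a) for b in bound_reps for a in apo_reps)]
    else:
        raise ValueError(f"unknown pairing policy {pairing!r}")

    shared = [r for r in apo_reps[0].residues
              if all(r in s.residue_index() for s in apo_reps + bound_reps)]
    if not shared:
        raise ValueError("apo and bound series share no residues")

    records: list[ScoreRecord] = []
    for apo, bound, rep in pairs:
        diffs: dict[ResidueId, float] = {}
        undefined: list[ResidueId] = []
        for rid in shared:
            ma = build_rama_matrix(apo, rid, normalize=normalize_bins)
            mb = build_rama_matrix(bound, rid, normalize=normalize_bins)
            if ma is None or mb is None:
                undefined.append(rid)
                continue
            diffs[rid] = raw_difference(mb, ma)
        scores = fscore2(diffs)
        for rid in shared:
            if rid in diffs:
                records.append(ScoreRecord(rid, ligand_state, rep, diffs[rid],
                                           scores[rid], rid in site, True))
            else:
                records.append(ScoreRecord(rid, ligand_state, rep, float("nan"),
                                           float("nan"), rid in site, False))
    return records


@dataclass
class ScoreTable:
    """Score records plus replicate and cross-ligand aggregates.

    ``per_ligand`` has one row per (residue, ligand_state) with the mean and
    standard deviation of the normalized score across replicates; ``summary``
    has one row per residue with the cross-ligand mean and min of those
    per-ligand means.
    """

    records: list[ScoreRecord]
    per_ligand: pd.DataFrame = field(repr=False)
    summary: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.residue.chain, r.residue.seq_number, r.residue.name, r.ligand_state,
              r.replicate, r.raw_diff, r.fscore2, r.is_binding_site, r.is_defined)
             for r in self.records],
            columns=["chain", "residue", "resname", "ligand_state", "replicate",
                     "raw_diff", "fscore2", "is_binding_site", "is_defined"])


def aggregate(records: list[ScoreRecord]) -> ScoreTable:
    """Average normalized scores across replicates and ligand states.

    Per (residue, ligand) mean +- sd over replicates (sd of a single
    replicate is 0), then a per-residue cross-ligand mean and min of the
    per-ligand means.  Undefined residues are excluded from the aggregates.
    """
    if not records:
        raise ValueError("no records to aggregate")
    by_res: dict[ResidueId, dict] = {}
    df = pd.DataFrame(
        [(r.residue, r.ligand_state, r.replicate, r.raw_diff, r.fscore2,
          r.is_binding_site, r.is_defined) for r in records],
        columns=["residue", "ligand_state", "replicate", "raw_diff", "fscore2",
                 "is_binding_site", "is_defined"])
    defined = df[df["is_defined"]]
    g = defined.groupby(["residue", "ligand_state"], sort=False)["fscore2"]
    per_ligand = g.agg(mean="mean", sd=lambda s: float(np.std(s, ddof=1)) if len(s) > 1 else 0.0,
                       n_replicates="size").reset_index()
    raw_means = (defined.groupby(["residue", "ligand_state"], sort=False)["raw_diff"]
                 .mean().reset_index(name="raw_diff_mean"))
    per_ligand = per_ligand.merge(raw_means, on=["residue", "ligand_state"])
    site_flags = {r.residue: r.is_binding_site for r in records}
    s = per_ligand.groupby("residue", sort=False)["mean"]
    summary = s.agg(cross_mean="mean", cross_min="min", n_ligands="size").reset_index()
    summary["is_binding_site"] = summary["residue"].map(site_flags)
    summary = summary.sort_values(
        "residue", key=lambda col: col.map(lambda r: (r.chain, r.seq_number, r.icode))
    ).reset_index(drop=True)
    return ScoreTable(records=records, per_ligand=per_ligand, summary=summary)


def rank_candidates(table: ScoreTable, binding_site: list[ResidueId] | None = None,
                    n: int = 5, by: str = "cross_mean") -> pd.DataFrame:
    """Top-n fluorophore-conjugation candidates.

    Binding-site residues (flagged in the table or passed here) and undefined
    residues are excluded; the rest are sorted by the chosen aggregate
    (``cross_mean`` default, ``cross_min`` for robustness across ligands)
    descending, ties broken by ascending residue number.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if by not in ("cross_mean", "cross_min"):
        raise ValueError("by must be 'cross_mean' or 'cross_min'")
    site = set(binding_site or [])
    df = table.summary.copy()
    df["excluded"] = df["is_binding_site"] | df["residue"].isin(site)
    eligible = df[~df["excluded"]].copy()
    eligible = eligible.sort_values(
        [by, "residue"], ascending=[False, True],
        key=lambda col: col.map(lambda r: (r.chain, r.seq_number, r.icode))
        if col.name == "residue" else col)
    if n > len(eligible):
        logger.warning("requested top %d but only %d eligible residues", n, len(eligible))
        n = len(eligible)
    out = eligible.head(n).drop(columns=["excluded"]).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def project_to_pdb(table: ScoreTable, topology, out, ligand_state: str | None = None) -> None:
    """Write a PDB whose B-factor column carries per-residue mean scores x 100.

    Uses the per-ligand mean for ``ligand_state`` if given, otherwise the
    cross-ligand mean.  Unscored residues get 0.00; residues in the table but
    absent from the structure are skipped with a warning.
    """
    import MDAnalysis as mda

    u = topology if isinstance(topology, mda.Universe) else mda.Universe(str(topology))
    if not hasattr(u.atoms, "tempfactors"):
        u.add_TopologyAttr("tempfactors")
    if ligand_state is not None:
        sub = table.per_ligand[table.per_ligand["ligand_state"] == ligand_state]
        scores = dict(zip(sub["residue"], sub["mean"]))
    else:
        scores = dict(zip(table.summary["residue"], table.summary["cross_mean"]))

    by_key = {(rid.chain, rid.seq_number): v for rid, v in scores.items()}
    u.atoms.tempfactors = 0.0
    matched = set()
    for res in u.residues:
        seg = res.segment.segid if res.segment.segid.strip() else getattr(res, "chainID", "A")
        key = (str(seg).strip() or "A", int(res.resid))
        if key in by_key:
            res.atoms.tempfactors = round(100.0 * by_key[key], 2)
            matched.add(key)
    for key in set(by_key) - matched:
        logger.warning("scored residue %s:%d not found in structure; skipped", *key)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis PDB writer chatters about metadata
        u.atoms.write(str(out))
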