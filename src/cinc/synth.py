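"""Synthetic inputs for the whole pipeline.

Three generators cover everything the scoring and kinetics code consumes, so
no trajectory download or instrument is ever needed:

* **Microstate dihedral ensembles.**  A residue is modeled as a mixture of
  discrete conformational microstates, each a wrapped-normal blob on the
  (phi, psi) torus; the apo and bound states differ only in microstate
  occupancy.  A ligand-induced occupancy shift delta moves a fraction delta
  of the population from one microstate to another, emulating the partial
  and complete microstate shifts seen in apo vs ligand-bound simulations of
  solute-binding proteins.  For modes separated far beyond their spread the
  expected raw histogram difference is 2*delta (the disjoint-support
  total-variation limit), which makes the generator an analytic oracle for
  the scorer.
* **Idealized peptide geometry.**  A backbone builder realizes target
  (phi, psi) values with ideal bond lengths/angles (NeRF construction), used
  to validate dihedral extraction end to end.
* **Noisy exponential time courses.**  Forward evaluation of the one- or
  two-exponential decay with seeded additive Gaussian noise.

All generators are bit-reproducible given their seed arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .dihedrals import DihedralSeries, ResidueId
from .kinetics import TimeCourse, exp_model

__all__ = [
    "Microstate",
    "ResidueMicrostates",
    "MicrostateSpec",
    "KineticSpec",
    "synth_dihedrals",
    "synth_protein_system",
    "synth_toy_peptide",
    "synth_peptide_universe",
    "synth_timecourse",
    "DEFAULT_SPREAD",
    "DEFAULT_MODES",
]

# Default angular spread (degrees, wrapped-normal sd) of a single
# conformational microstate.  Small against the 2-degree bin grid's 360-degree
# span and against the default inter-mode separation, so the disjoint-support
# law E[raw_diff] = 2*delta holds to within the binned estimator's
# finite-sample bias (<3% at 10^4 frames; see docs/methods.md).
DEFAULT_SPREAD = 5.0

# Two well-separated backbone conformers: an alpha-helical-like and a
# left-handed-like basin, 120 degrees apart in both angles.
DEFAULT_MODES = ((-60.0, -45.0), (60.0, 75.0))


@dataclass(frozen=True)
class Microstate:
    """One conformational sub-state: a wrapped-normal blob on the torus."""

    phi_mean: float
    psi_mean: float
    spread: float = DEFAULT_SPREAD

    def __post_init__(self):
        if self.spread <= 0:
            raise ValueError("spread must be positive")


@dataclass
class ResidueMicrostates:
    """Microstate mixture of one residue in both states."""

    residue: ResidueId
    states: list[Microstate]
    apo_occupancy: np.ndarray
    bound_occupancy: np.ndarray

    def __post_init__(self):
        self.apo_occupancy = np.asarray(self.apo_occupancy, dtype=float)
        self.bound_occupancy = np.asarray(self.bound_occupancy, dtype=float)
        for occ in (self.apo_occupancy, self.bound_occupancy):
            if occ.shape != (len(self.states),):
                raise ValueError("occupancy length must match number of microstates")
            if (occ < 0).any() or abs(occ.sum() - 1.0) > 1e-9:
                raise ValueError("occupancies must be non-negative and sum to 1")

    @classmethod
    def shifted(cls, residue: ResidueId, delta: float,
                modes=DEFAULT_MODES, spread: float = DEFAULT_SPREAD) -> "ResidueMicrostates":
        """Two-microstate residue whose occupancy shifts by delta on binding.

        Apo sits fully in mode 0; binding moves a fraction ``delta`` of the
        population to mode 1 (delta = 0: unresponsive, delta = 1: complete
        microstate shift).
        """
        if not 0.0 <= delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        states = [Microstate(m[0], m[1], spread) for m in modes[:2]]
        return cls(residue=residue, states=states,
                   apo_occupancy=np.array([1.0, 0.0]),
                   bound_occupancy=np.array([1.0 - delta, delta]))


@dataclass
class MicrostateSpec:
    """Full specification of a synthetic dihedral ensemble."""

    residues: list[ResidueMicrostates]
    frames: int = 10_000
    dwell: float | None = None  # expected dwell (frames) of the optional Markov chain
    seed: int = 0

    def __post_init__(self):
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if self.dwell is not None and self.dwell < 1:
            raise ValueError("dwell must be >= 1 frame")


_STATE_CODE = {"apo": 0, "bound": 1}


def _microstate_path(rng, occ: np.ndarray, frames: int, dwell: float | None) -> np.ndarray:
    if dwell is None or dwell <= 1.0:
        return rng.choice(len(occ), size=frames, p=occ)
    # Markov chain with stationary distribution occ: stay with prob 1 - 1/dwell,
    # otherwise redraw from occ (possibly landing in the same state).
    stay = 1.0 - 1.0 / dwell
    path = np.empty(frames, dtype=int)
    path[0] = rng.choice(len(occ), p=occ)
    redraws = rng.random(frames - 1) >= stay
    draws = rng.choice(len(occ), size=frames - 1, p=occ)
    for i in range(1, frames):
        path[i] = draws[i - 1] if redraws[i - 1] else path[i - 1]
    return path


def synth_dihedrals(spec: MicrostateSpec, state: str, replicate: int = 1) -> DihedralSeries:
    """Draw one replicate of one state from the microstate mixture model.

    Per frame a microstate is drawn from the state's occupancy vector
    (i.i.d., or with Markov persistence when ``spec.dwell`` is set), then
    (phi, psi) are drawn from the wrapped normal around that microstate's
    means.  Deterministic given (spec.seed, state, replicate).  Chain-end
    conventions are honored: the first residue's phi and the last residue's
    psi are undefined.
    """
    if state not in _STATE_CODE:
        raise ValueError("state must be 'apo' or 'bound'")
    n_res = len(spec.residues)
    phi = np.empty((n_res, spec.frames))
    psi = np.empty((n_res, spec.frames))
    for i, rm in enumerate(spec.residues):
        ss = np.random.SeedSequence((spec.seed, _STATE_CODE[state], replicate, i))
        rng = np.random.default_rng(ss)
        occ = rm.apo_occupancy if state == "apo" else rm.bound_occupancy
        path = _microstate_path(rng, occ, spec.frames, spec.dwell)
        means_phi = np.array([m.phi_mean for m in rm.states])[path]
        means_psi = np.array([m.psi_mean for m in rm.states])[path]
        spreads = np.array([m.spread for m in rm.states])[path]
        phi[i] = geometry.wrap_angle(rng.normal(means_phi, spreads))
        psi[i] = geometry.wrap_angle(rng.normal(means_psi, spreads))
    phi[0, :] = np.nan   # chain N-terminus
    psi[-1, :] = np.nan  # chain C-terminus
    return DihedralSeries(state_label=state, replicate=replicate,
                          residues=[rm.residue for rm in spec.residues],
                          phi=phi, psi=psi)


def synth_protein_system(n_residues: int = 50, signal_residues: dict[int, float] | None = None,
                         seed: int = 0, frames: int = 10_000, n_replicates: int = 3,
                         spread: float = DEFAULT_SPREAD, dwell: float | None = None,
                         binding_site: list[int] | None = None):
    """End-to-end synthetic scoring experiment: paired apo/bound replicates.

    Emulates the design of an apo-vs-bound simulation study (by default 3
    replicates per state).  ``signal_residues`` maps author residue numbers
    (1-based) to occupancy shifts delta in [0, 1]; all other residues keep
    identical apo and bound distributions (delta = 0).  ``binding_site``
    residue numbers are returned as ResidueIds for ranking exclusion.

    Returns ``(apo_reps, bound_reps, site_ids, spec)``.
    """
    signal_residues = signal_residues or {}
    if any(not 0.0 <= d <= 1.0 for d in signal_residues.values()):
        raise ValueError("shifts must lie in [0, 1]")
    if any(not 1 <= r <= n_residues for r in signal_residues):
        raise ValueError("signal residue numbers must lie in 1..n_residues")
    residues = []
    for num in range(1, n_residues + 1):
        rid = ResidueId(chain="A", seq_number=num, name="ALA")
        delta = signal_residues.get(num, 0.0)
        residues.append(ResidueMicrostates.shifted(rid, delta, spread=spread))
    spec = MicrostateSpec(residues=residues, frames=frames, dwell=dwell, seed=seed)
    apo_reps = [synth_dihedrals(spec, "apo", rep) for rep in range(1, n_replicates + 1)]
    bound_reps = [synth_dihedrals(spec, "bound", rep) for rep in range(1, n_replicates + 1)]
    site_ids = [ResidueId(chain="A", seq_number=r, name="ALA")
                for r in (binding_site or [])]
    return apo_reps, bound_reps, site_ids, spec


def synth_toy_peptide(phi_psi_targets, out=None):
    """Idealized polyalanine backbone realizing target (phi, psi) values.

    ``phi_psi_targets`` is a list of (phi, psi) pairs, one per residue; the
    first residue's phi and the last residue's psi are geometrically
    unconstrained and their target values are ignored.  Returns
    ``(names, resids, coords)`` for the N/CA/C backbone and optionally writes
    a PDB.  Only geometry is enforced; steric clashes are not checked.
    """
    targets = [(float(p), float(s)) for p, s in phi_psi_targets]
    if any(not (-180.0 <= p < 180.0 and -180.0 <= s < 180.0) for p, s in targets):
        raise ValueError("targets must lie in [-180, 180)")
    n = len(targets)
    if n < 2:
        raise ValueError("need at least 2 residues")
    g = geometry
    coords = []
    # seed triad: N1 at origin, CA1 on x, C1 in the xy-plane
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([g.BOND_N_CA, 0.0, 0.0])
    ang = np.radians(g.ANGLE_N_CA_C)
    C = CA + g.BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.extend([N, CA, C])
    for i in range(1, n):
        psi_prev = targets[i - 1][1]
        phi_i = targets[i][0]
        N = g.place_atom(coords[-3], coords[-2], coords[-1],
                         g.BOND_C_N, g.ANGLE_CA_C_N, psi_prev)
        CA = g.place_atom(coords[-2], coords[-1], N,
                          g.BOND_N_CA, g.ANGLE_C_N_CA, g.OMEGA_TRANS)
        C = g.place_atom(coords[-1], N, CA, g.BOND_CA_C, g.ANGLE_N_CA_C, phi_i)
        coords.extend([N, CA, C])
    coords = np.asarray(coords)
    names = ["N", "CA", "C"] * n
    resids = np.repeat(np.arange(1, n + 1), 3)
    if out is not None:
        _write_backbone_pdb(names, resids, coords, out)
    return names, resids, coords


def synth_peptide_universe(frame_targets):
    """In-memory MDAnalysis Universe of an ideal peptide trajectory.

    ``frame_targets`` is a list of per-frame target lists (each as accepted
    by :func:`synth_toy_peptide`); all frames must have the same residue
    count.  Useful for validating dihedral extraction without touching disk.
    """
    import MDAnalysis as mda

    frames = [synth_toy_peptide(t) for t in frame_targets]
    names, resids, _ = frames[0]
    n_res = int(resids.max())
    u = mda.Universe.empty(n_atoms=len(names), n_residues=n_res, n_segments=1,
                           atom_resindex=resids - 1,
                           residue_segindex=np.zeros(n_res, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.add_TopologyAttr("resnames", ["ALA"] * n_res)
    u.add_TopologyAttr("segids", ["A"])
    coords = np.stack([c for _, _, c in frames]).astype(np.float32)
    u.load_new(coords, order="fac")
    return u


def _write_backbone_pdb(names, resids, coords, out) -> None:
    import MDAnalysis as mda
    import warnings

    n_res = int(np.max(resids))
    u = mda.Universe.empty(n_atoms=len(names), n_residues=n_res, n_segments=1,
                           atom_resindex=np.asarray(resids) - 1,
                           residue_segindex=np.zeros(n_res, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.add_TopologyAttr("resnames", ["ALA"] * n_res)
    u.add_TopologyAttr("segids", ["A"])
    u.atoms.positions = coords
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(out))


@dataclass
class KineticSpec:
    """Ground truth for a synthetic fluorescence time course."""

    f_inf: float
    amplitudes: tuple
    rates: tuple
    times: np.ndarray = field(default_factory=lambda: np.logspace(-3, 2, 400))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = tuple(float(a) for a in np.atleast_1d(self.amplitudes))
        self.rates = tuple(float(k) for k in np.atleast_1d(self.rates))
        if len(self.amplitudes) != len(self.rates) or len(self.rates) not in (1, 2):
            raise ValueError("need 1 or 2 (amplitude, rate) pairs")
        if any(k <= 0 for k in self.rates):
            raise ValueError("rates must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def synth_timecourse(spec: KineticSpec, label: str = "synthetic") -> TimeCourse:
    """Forward-evaluate the exponential model, plus seeded Gaussian noise."""
    y = exp_model(spec.times, spec.f_inf, spec.amplitudes, spec.rates)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    return TimeCourse(time=spec.times, signal=y, label=label,
                      meta=f"synthetic: {len(spec.rates)}-exponential, noise sd {spec.noise_sd}")
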