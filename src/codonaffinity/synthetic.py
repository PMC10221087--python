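"""Synthetic data with known ground truth.

Three generators stand in for the study's raw data so every downstream
stage can be validated against planted truth:

* :func:`gen_distance_series` — closest-approach distance series from a
  two-state (bound/free) Markov chain, emulating 100 parallel simulations of
  one nucleotide and 10 amino-acid copies in a 40 Å periodic box reduced to
  a per-frame minimum distance. The stationary bound probability (occupancy)
  is the planted truth. Bound-state distances come from a truncated-Gaussian
  mixture at the three observed binding modes (~1.9, 2.5 and 4 Å); free
  distances sit near the ~5.5 Å closest-unbound-neighbour distance.
* :func:`gen_box_trajectory` — random-walk rigid molecules in a periodic
  cube, optionally with a square-well attraction, to exercise minimum-image
  geometry and Monte Carlo volume code on coordinates.
* :func:`gen_titration` — one-site fast-exchange titration curves with
  Gaussian shift noise, for the K_D fitting ensemble.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .titration import TitrationCurve, binding_isotherm

BINDING_THRESHOLD = 5.0  # Å, shared convention with trajectory metrics

__all__ = [
    "TwoStateParams",
    "BoxTrajectoryParams",
    "BoxTrajectory",
    "gen_distance_series",
    "gen_box_trajectory",
    "gen_titration",
    "write_distance_series",
    "read_distance_series",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Parameters of the two-state distance-series generator.

    ``occupancy`` is the stationary probability of the bound state and hence
    the expected fraction of frames below the 5 Å threshold. Dwell times are
    geometric with the given means (frames); ``mean_dwell_free`` defaults to
    the value that makes the chain stationary at ``occupancy``.
    """

    occupancy: float
    mean_dwell_bound: float = 20.0
    mean_dwell_free: float | None = None
    n_frames: int = 10_000
    n_runs: int = 100
    seed: int = 0
    bound_modes: tuple = (1.9, 2.5, 4.0)
    bound_sds: tuple = (0.15, 0.25, 0.35)
    bound_weights: tuple = (0.3, 0.4, 0.3)
    free_mean: float = 5.5
    free_sd: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")
        if self.mean_dwell_bound < 1.0:
            raise ValueError("mean_dwell_bound must be >= 1 frame")
        if self.mean_dwell_free is not None and self.mean_dwell_free < 1.0:
            raise ValueError("mean_dwell_free must be >= 1 frame")
        if self.n_frames < 1 or self.n_runs < 1:
            raise ValueError("n_frames and n_runs must be positive")

    @property
    def dwell_free(self) -> float:
        """Mean free dwell consistent with the target occupancy."""
        if self.mean_dwell_free is not None:
            return self.mean_dwell_free
        if self.occupancy in (0.0, 1.0):
            return self.mean_dwell_bound
        return self.mean_dwell_bound * (1.0 - self.occupancy) / self.occupancy

    @property
    def stationary_occupancy(self) -> float:
        """Bound probability implied by the dwell means actually in force."""
        if self.occupancy in (0.0, 1.0):
            return self.occupancy
        b, f = self.mean_dwell_bound, self.dwell_free
        return b / (b + f)


def _sample_states(rng: np.random.Generator, params: TwoStateParams) -> np.ndarray:
    """Alternating geometric dwells == path of the two-state Markov chain."""
    n = params.n_frames
    if params.occupancy == 0.0:
        return np.zeros(n, dtype=bool)
    if params.occupancy == 1.0:
        return np.ones(n, dtype=bool)
    p_bound = 1.0 / params.mean_dwell_bound
    p_free = 1.0 / params.dwell_free
    states = np.empty(n, dtype=bool)
    state = bool(rng.random() < params.stationary_occupancy)
    pos = 0
    while pos < n:
        dwell = int(rng.geometric(p_bound if state else p_free))
        end = min(pos + dwell, n)
        states[pos:end] = state
        pos = end
        state = not state
    return states


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_distances(rng: np.random.Generator, states: np.ndarray, params: TwoStateParams) -> np.ndarray:
    dist = np.empty(states.size, dtype=float)
    n_bound = int(states.sum())
    if n_bound:
        w = np.asarray(params.bound_weights, dtype=float)
        w = w / w.sum()
        which = rng.choice(len(w), size=n_bound, p=w)
        vals = np.empty(n_bound)
        for i, (m, s) in enumerate(zip(params.bound_modes, params.bound_sds)):
            sel = which == i
            if sel.any():
                vals[sel] = _truncated_normal(rng, m, s, 0.0, BINDING_THRESHOLD, int(sel.sum()))
        dist[states] = vals
    n_free = states.size - n_bound
    if n_free:
        dist[~states] = _truncated_normal(
            rng, params.free_mean, params.free_sd, BINDING_THRESHOLD, np.inf, n_free
        )
    return dist


def gen_distance_series(params: TwoStateParams) -> pd.DataFrame:
    """Closest-approach distance series for ``n_runs`` independent runs.

    Returns a long DataFrame with columns ``run_id``, ``frame``,
    ``distance`` (Å). Runs use independent child seeds spawned from
    ``params.seed``, so the output is reproducible and runs are independent.
    """
    seqs = np.random.SeedSequence(params.seed).spawn(params.n_runs)
    frames = np.arange(params.n_frames)
    parts = []
    for run_id, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        states = _sample_states(rng, params)
        parts.append(
            pd.DataFrame(
                {
                    "run_id": run_id,
                    "frame": frames,
                    "distance": _sample_distances(rng, states, params),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_distance_series(df: pd.DataFrame, path) -> None:
    """Write a distance-series table as TSV (run_id, frame, distance)."""
    df.to_csv(path, sep="\t", index=False)


def read_distance_series(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"run_id", "frame", "distance"} - set(df.columns)
    if missing:
        raise ValueError(f"distance series {path} lacks columns {sorted(missing)}")
    return df


@dataclass(frozen=True)
class BoxTrajectoryParams:
    """Random-walk molecules in a periodic cube.

    One nucleotide group plus ``n_copies`` amino-acid groups, each a rigid
    cluster of atoms random-walking as a unit. ``attraction`` > 0 turns on a
    square-well (depth in kT units, radius ``well_radius``) between the
    nucleotide and each amino-acid centre, sampled by Metropolis steps; zero
    attraction gives the purely geometric null.
    """

    box_edge: float = 40.0
    n_copies: int = 10
    n_atoms_aa: int = 3
    n_atoms_nt: int = 3
    atom_spread: float = 1.0
    step_sd: float = 1.0
    attraction: float = 0.0
    well_radius: float = 5.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.box_edge <= 0:
            raise ValueError(f"box_edge must be positive, got {self.box_edge}")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if self.n_atoms_aa < 1 or self.n_atoms_nt < 1:
            raise ValueError("atom counts must be >= 1")


@dataclass
class BoxTrajectory:
    """Coordinates (n_frames, n_atoms, 3) with per-atom group labels.

    Group labels: ``"nt"`` for the nucleotide, ``"aa<i>"`` for amino-acid
    copy i. Coordinates are wrapped into [0, box_edge).
    """

    coords: np.ndarray
    box_edge: float
    groups: np.ndarray  # shape (n_atoms,), dtype str

    def group_indices(self, prefix_or_name: str) -> np.ndarray:
        exact = np.flatnonzero(self.groups == prefix_or_name)
        if exact.size:
            return exact
        pref = np.flatnonzero(np.char.startswith(self.groups.astype(str), prefix_or_name))
        if not pref.size:
            raise KeyError(f"no atoms in group {prefix_or_name!r}")
        return pref

    def write_xyz(self, path) -> None:
        """Plain-text XYZ trajectory; group labels double as element names."""
        with open(path, "w") as fh:
            for frame in self.coords:
                fh.write(f"{frame.shape[0]}\nbox_edge={self.box_edge}\n")
                for g, (x, y, z) in zip(self.groups, frame):
                    fh.write(f"{g} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> BoxTrajectory:
    """Read a trajectory written by :meth:`BoxTrajectory.write_xyz`."""
    frames, groups = [], None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            edge = float(comment.strip().split("box_edge=")[1])
            labels, coords = [], []
            for _ in range(n):
                g, x, y, z = fh.readline().split()
                labels.append(g)
                coords.append((float(x), float(y), float(z)))
            if groups is None:
                groups = np.array(labels)
            frames.append(coords)
    if groups is None:
        raise ValueError(f"no frames in {path}")
    return BoxTrajectory(coords=np.asarray(frames, float), box_edge=edge, groups=groups)


def _min_image_center_dist(a: np.ndarray, b: np.ndarray, edge: float) -> np.ndarray:
    d = a - b
    d -= edge * np.round(d / edge)
    return np.sqrt((d * d).sum(axis=-1))


def gen_box_trajectory(params: BoxTrajectoryParams) -> BoxTrajectory:
    """Simulate the random-walk box system and return the trajectory.

    With zero attraction every proposed move is accepted, so group centres
    are independent uniform random walks and the closest-approach statistics
    follow the geometric null of uniformly placed rigid molecules.
    """
    rng = np.random.default_rng(params.seed)
    n_groups = params.n_copies + 1
    atoms_per = [params.n_atoms_nt] + [params.n_atoms_aa] * params.n_copies
    labels = np.concatenate(
        [["nt"] * params.n_atoms_nt]
        + [[f"aa{i}"] * params.n_atoms_aa for i in range(params.n_copies)]
    )
    # rigid intra-group geometry: atoms at fixed offsets in a ball
    offsets = [
        np.zeros((m, 3)) if m == 1 else rng.normal(0.0, params.atom_spread, size=(m, 3))
        for m in atoms_per
    ]
    centers = rng.uniform(0.0, params.box_edge, size=(n_groups, 3))

    def energy(c):
        d = _min_image_center_dist(c[1:], c[0], params.box_edge)
        return -params.attraction * np.count_nonzero(d < params.well_radius)

    frames = np.empty((params.n_frames, int(sum(atoms_per)), 3))
    e_cur = energy(centers)
    for t in range(params.n_frames):
        prop = (centers + rng.normal(0.0, params.step_sd, size=centers.shape)) % params.box_edge
        if params.attraction == 0.0:
            centers, e_cur = prop, 0.0
        else:
            e_new = energy(prop)
            if rng.random() < np.exp(min(0.0, -(e_new - e_cur))):
                centers, e_cur = prop, e_new
        pos = np.concatenate([(centers[g] + offsets[g]) % params.box_edge for g in range(n_groups)])
        frames[t] = pos
    return BoxTrajectory(coords=frames, box_edge=params.box_edge, groups=labels)


def gen_titration(
    kd: float,
    dmax: float,
    P_total: float = 0.1,
    L_totals=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    amino_acid: str = "synthetic",
    nucleotide: str = "synthetic",
    probe: str = "H",
) -> TitrationCurve:
    """One-site fast-exchange titration curve with Gaussian shift noise.

    Concentrations in mM, shifts in ppm. Defaults mirror the measurement
    design: receptor (nucleotide) fixed at 0.1 mM, ligand (amino acid)
    titrated over 0.1-100 mM on a log-spaced grid.
    """
    if kd < 0 or dmax < 0:
        raise ValueError("kd and dmax must be non-negative")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    if L_totals is None:
        L_totals = np.geomspace(0.1, 100.0, 10)
    L_totals = np.asarray(L_totals, dtype=float)
    if P_total <= 0 or np.any(L_totals < 0):
        raise ValueError("P_total must be positive and ligand concentrations non-negative")
    shifts = binding_isotherm(P_total, L_totals, kd, dmax)
    if noise_sd > 0:
        shifts = shifts + np.random.default_rng(seed).normal(0.0, noise_sd, size=shifts.shape)
    return TitrationCurve(
        amino_acid=amino_acid,
        nucleotide=nucleotide,
        probe=probe,
        P_total=float(P_total),
        L_totals=L_totals,
        shifts=shifts,
    )
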