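"""Monte Carlo molecular volume fractions and volume adjustment.

Larger molecules spend more time near each other for purely geometric
reasons: under a uniform null, the expected time within a distance threshold
grows linearly with the fraction of the box that lies within the threshold
of the molecule. That fraction is estimated by Monte Carlo — uniform random
points in the periodic box, counted as "in" when within the threshold
(minimum image) of any selected atom — repeated over randomly chosen frames
to absorb conformational flexibility. The raw time-within-threshold measure
is then divided by a volume divisor to make systems of different sizes
comparable.

Divisor modes (the study is ambiguous on whether one combined volume or
both volumes were divided out): ``product`` of the amino-acid and
nucleotide volume fractions (default; best linearizes the geometric null),
``sum``, or ``aa_only``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import BoxTrajectory
from .trajectory import BindingMeasure, min_image_distances

__all__ = ["VolumeFraction", "volume_fraction", "adjust_binding", "DIVISOR_MODES"]

DIVISOR_MODES = ("product", "sum", "aa_only")


@dataclass(frozen=True)
class VolumeFraction:
    """Monte Carlo volume-fraction estimate for one molecule."""

    mean_fraction: float
    range95: tuple
    per_frame: np.ndarray
    threshold: float
    n_points: int
    n_frames: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "mean_fraction": self.mean_fraction,
            "range95": list(self.range95),
            "threshold": self.threshold,
            "n_points": self.n_points,
            "n_frames": self.n_frames,
            "seed": self.seed,
        }


def volume_fraction(
    traj: BoxTrajectory,
    group: str = "nt",
    threshold: float = 5.0,
    n_points: int = 100_000,
    n_frames: int = 150,
    seed: int = 0,
    atom_subset: np.ndarray | None = None,
) -> VolumeFraction:
    """Fraction of the box within ``threshold`` of the molecule's atoms.

    For each of ``n_frames`` randomly chosen trajectory frames, ``n_points``
    uniform points are drawn in the box and the within-threshold fraction
    computed; the estimate is the mean over frames with its central 95%
    range. If the trajectory has fewer frames than requested, frames are
    sampled with replacement (with a warning).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    idx = traj.group_indices(group)
    if atom_subset is not None:
        idx = np.intersect1d(idx, np.asarray(atom_subset, dtype=int))
        if idx.size == 0:
            raise ValueError(f"atom subset leaves no atoms of group {group!r}")
    rng = np.random.default_rng(seed)
    available = traj.coords.shape[0]
    if n_frames > available:
        warnings.warn(
            f"requested {n_frames} frames but trajectory has {available}; "
            "sampling frames with replacement"
        )
        frames = rng.integers(0, available, size=n_frames)
    else:
        frames = rng.choice(available, size=n_frames, replace=False)
    # one point cloud reused across frames: the 95% range over frames then
    # reflects conformational flexibility alone, not Monte Carlo noise
    # (a rigid molecule gets an exactly zero-width range)
    pts = rng.uniform(0.0, traj.box_edge, size=(n_points, 3))
    fracs = np.empty(n_frames)
    for i, t in enumerate(frames):
        dmin = min_image_distances(pts, traj.coords[t, idx], traj.box_edge).min(axis=1)
        fracs[i] = (dmin < threshold).mean()
    lo, hi = np.percentile(fracs, [2.5, 97.5])
    return VolumeFraction(
        mean_fraction=float(fracs.mean()),
        range95=(float(lo), float(hi)),
        per_frame=fracs,
        threshold=float(threshold),
        n_points=int(n_points),
        n_frames=int(n_frames),
        seed=int(seed),
    )


def _mean_fraction(v) -> float:
    return float(v.mean_fraction) if isinstance(v, VolumeFraction) else float(v)


def adjust_binding(measure, v_aa, v_nt, mode: str = "product") -> float:
    """Volume-adjusted binding: raw fraction divided by the volume divisor.

    ``measure`` may be a BindingMeasure or a raw fraction; ``v_aa``/``v_nt``
    VolumeFraction objects or plain fractions. Adjusted values are
    comparable across systems only under one fixed mode.
    """
    raw = measure.raw_fraction if isinstance(measure, BindingMeasure) else float(measure)
    fa, fn = _mean_fraction(v_aa), _mean_fraction(v_nt)
    if fa <= 0 or (mode != "aa_only" and fn <= 0):
        raise ValueError(f"volume fractions must be positive, got aa={fa}, nt={fn}")
    if mode == "product":
        return raw / (fa * fn)
    if mode == "sum":
        return raw / (fa + fn)
    if mode == "aa_only":
        return raw / fa
    raise ValueError(f"unknown divisor mode {mode!r}; expected one of {DIVISOR_MODES}")
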