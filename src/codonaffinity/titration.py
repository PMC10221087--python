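"""NMR chemical-shift-perturbation titration fitting.

Under fast exchange, the observed chemical shift of a receptor proton is a
population-weighted average of its free and bound values, so the observed
shift change at receptor concentration P and ligand concentration L is

    d_obs = d_max * [ (K_D + L + P) - sqrt((K_D + L + P)^2 - 4 P L) ] / (2 P)

the exact one-site binding isotherm (the bracket over 2P is the bound
fraction of the receptor, from the quadratic for complex concentration).

K_D and d_max are inferred by a leave-one-out ensemble of bounded
least-squares fits: each of the (default) 500 fits drops one uniformly
chosen titration point, starts d_max at 0 and K_D uniformly in a start
interval (default 0.5-1.5, concentration units), with both parameters
bounded below at 0 and unbounded above. The reported K_D is the ensemble
mean with the central 95% range as uncertainty. Relative preferences among
nucleotides are compared by repeatedly drawing one K_D per ensemble and
ranking (lowest K_D = strongest binding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TitrationCurve",
    "TitrationFit",
    "binding_isotherm",
    "fit_ensemble",
    "rank_bootstrap",
    "read_titration",
    "write_titration",
]


def binding_isotherm(P_total, L_total, kd, dmax):
    """Predicted shift change (ppm) for one-site fast-exchange binding.

    Concentrations share one unit (mM by convention here); ``kd`` is the
    dissociation constant in the same unit, ``dmax`` the shift change at
    full receptor saturation.
    """
    P = np.asarray(P_total, dtype=float)
    L = np.asarray(L_total, dtype=float)
    kd = float(kd)
    dmax = float(dmax)
    if np.any(P <= 0):
        raise ValueError("P_total must be positive")
    if np.any(L < 0) or kd < 0 or dmax < 0:
        raise ValueError("L_total, kd and dmax must be non-negative")
    s = kd + L + P
    disc = np.maximum(s * s - 4.0 * P * L, 0.0)  # clip roundoff at saturation
    out = dmax * (s - np.sqrt(disc)) / (2.0 * P)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TitrationCurve:
    """Observed shift changes for one amino-acid / nucleotide / probe triple."""

    amino_acid: str
    nucleotide: str
    probe: str
    P_total: float  # mM
    L_totals: np.ndarray  # mM
    shifts: np.ndarray  # ppm, shift change relative to zero ligand

    def __post_init__(self):
        L = np.asarray(self.L_totals, dtype=float)
        d = np.asarray(self.shifts, dtype=float)
        object.__setattr__(self, "L_totals", L)
        object.__setattr__(self, "shifts", d)
        if L.shape != d.shape or L.ndim != 1:
            raise ValueError("L_totals and shifts must be 1-D arrays of equal length")
        if L.size < 3:
            raise ValueError(f"titration needs >= 3 points, got {L.size}")
        if not np.all(np.isfinite(d)):
            raise ValueError("shift changes must be finite")

    @property
    def n_points(self) -> int:
        return int(self.L_totals.size)


@dataclass
class TitrationFit:
    """Leave-one-out fit ensemble for one titration curve."""

    curve: TitrationCurve
    kds: np.ndarray  # converged fits only
    dmaxes: np.ndarray
    kd_mean: float
    kd_range95: tuple
    dmax_mean: float
    n_fits: int
    n_failed: int
    start_kd_interval: tuple
    seed: int

    def summary(self) -> dict:
        return {
            "amino_acid": self.curve.amino_acid,
            "nucleotide": self.curve.nucleotide,
            "probe": self.curve.probe,
            "kd_mean": self.kd_mean,
            "kd_range95": list(self.kd_range95),
            "dmax_mean": self.dmax_mean,
            "n_fits": self.n_fits,
            "n_failed": self.n_failed,
        }


def _fit_once(L, d, P, kd0):
    def resid(theta):
        return binding_isotherm(P, L, theta[0], theta[1]) - d

    res = least_squares(
        resid, x0=[kd0, 0.0], bounds=([0.0, 0.0], [np.inf, np.inf]), method="trf"
    )
    return res


def fit_ensemble(
    curve: TitrationCurve,
    n_fits: int = 500,
    start_kd_interval: tuple = (0.5, 1.5),
    seed: int = 0,
) -> TitrationFit:
    """Fit the binding isotherm ``n_fits`` times, dropping one point per fit.

    Each fit excludes one uniformly chosen titration point, draws the K_D
    starting value uniformly from ``start_kd_interval`` and starts d_max at
    0; both parameters are bounded below by 0. Non-convergent fits are
    excluded and counted in ``n_failed``. Deterministic given the seed.
    """
    if curve.n_points < 4:
        raise ValueError(
            f"need >= 4 titration points for leave-one-out fitting, got {curve.n_points}"
        )
    rng = np.random.default_rng(seed)
    drop = rng.integers(0, curve.n_points, size=n_fits)
    kd0s = rng.uniform(*start_kd_interval, size=n_fits)
    kds, dmaxes, n_failed = [], [], 0
    mask = np.ones(curve.n_points, dtype=bool)
    for j, kd0 in zip(drop, kd0s):
        mask[:] = True
        mask[j] = False
        res = _fit_once(curve.L_totals[mask], curve.shifts[mask], curve.P_total, kd0)
        if res.success and np.all(np.isfinite(res.x)):
            kds.append(res.x[0])
            dmaxes.append(res.x[1])
        else:
            n_failed += 1
    if not kds:
        raise RuntimeError(
            f"all {n_fits} fits failed for "
            f"{curve.amino_acid}/{curve.nucleotide}/{curve.probe}"
        )
    kds = np.asarray(kds)
    dmaxes = np.asarray(dmaxes)
    lo, hi = np.percentile(kds, [2.5, 97.5])
    return TitrationFit(
        curve=curve,
        kds=kds,
        dmaxes=dmaxes,
        kd_mean=float(kds.mean()),
        kd_range95=(float(lo), float(hi)),
        dmax_mean=float(dmaxes.mean()),
        n_fits=n_fits,
        n_failed=n_failed,
        start_kd_interval=tuple(start_kd_interval),
        seed=seed,
    )


def rank_bootstrap(fits: dict, n_draws: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Bootstrap-rank binding partners from their fit ensembles.

    ``fits`` maps partner label (e.g. nucleotide) -> TitrationFit. Per draw,
    one K_D is sampled from each ensemble and partners are ranked ascending
    (lowest K_D = strongest binding = rank 1). Returns a DataFrame indexed
    by partner with columns ``best_fraction``, ``worst_fraction``, the mean
    rank, and ``beats_<other>`` pairwise win fractions.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 partners to rank")
    for name, fit in fits.items():
        if fit.kds.size == 0:
            raise ValueError(f"empty fit ensemble for {name!r}")
    rng = np.random.default_rng(seed)
    names = list(fits)
    draws = np.column_stack(
        [rng.choice(fits[n].kds, size=n_draws, replace=True) for n in names]
    )
    order = np.argsort(draws, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(len(names))[None, :], axis=1)
    out = pd.DataFrame(index=pd.Index(names, name="partner"))
    out["best_fraction"] = (ranks == 0).mean(axis=0)
    out["worst_fraction"] = (ranks == len(names) - 1).mean(axis=0)
    out["mean_rank"] = ranks.mean(axis=0) + 1
    for j, other in enumerate(names):
        out[f"beats_{other}"] = [
            np.nan if i == j else float((draws[:, i] < draws[:, j]).mean())
            for i in range(len(names))
        ]
    return out


def read_titration(path, amino_acid="", nucleotide="", probe="", P_total=None) -> TitrationCurve:
    """Read a titration table (columns L_total, shift; optional metadata columns).

    Metadata may be given as columns (constant per file) or as arguments;
    arguments win. ``P_total`` must come from one of the two.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "l_total" not in cols or "shift" not in cols:
        raise ValueError(f"titration table {path} must have columns L_total, shift")

    def meta(arg, key, default=""):
        if arg:
            return arg
        if key in cols:
            return df[cols[key]].iloc[0]
        return default

    P = P_total if P_total is not None else (
        float(df[cols["p_total"]].iloc[0]) if "p_total" in cols else None
    )
    if P is None:
        raise ValueError(f"P_total not given and no P_total column in {path}")
    return TitrationCurve(
        amino_acid=str(meta(amino_acid, "amino_acid")),
        nucleotide=str(meta(nucleotide, "nucleotide")),
        probe=str(meta(probe, "probe")),
        P_total=float(P),
        L_totals=df[cols["l_total"]].to_numpy(float),
        shifts=df[cols["shift"]].to_numpy(float),
    )


def write_titration(curve: TitrationCurve, path) -> None:
    pd.DataFrame(
        {
            "amino_acid": curve.amino_acid,
            "nucleotide": curve.nucleotide,
            "probe": curve.probe,
            "P_total": curve.P_total,
            "L_total": curve.L_totals,
            "shift": curve.shifts,
        }
    ).to_csv(path, sep="\t", index=False)
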