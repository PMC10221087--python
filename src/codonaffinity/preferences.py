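"""Rank-preference statistics against the genetic code.

Given a matrix of volume-adjusted binding values (rows: amino acids,
columns: nucleotides or dinucleotides), the questions are whether amino
acids bind their cognate bases better than chance:

* enrichment/depletion of cognate *first choices* against an exact binomial
  null of uniform random preference (p = 1/n_columns per allocation);
* a sum-of-ranks score over the expanded allocations (lower = stronger
  collective cognate preference; bounds n_allocations and
  4 * n_allocations for mononucleotides), compared with a randomization
  null of independently uniform ranks (default 200,000 draws). For
  dinucleotide schemes, an amino acid's several cognate dinucleotides can
  be constrained never to receive identical ranks in one draw;
* directionality contrasts between an XY and a YX dinucleotide from the
  underlying per-run trajectories.

Ties receive average ranks; a row has a "first choice" only when a strict
maximum exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, rankdata

from . import genetic_code as gc
from .trajectory import binding_fraction

__all__ = [
    "rank_rows",
    "binomial_preference_test",
    "first_choice_summary",
    "cognate_hit_summary",
    "rank_sum_score",
    "RandomizationNull",
    "randomization_null",
    "directionality_compare",
]


def rank_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Within-row ranks of binding values, 1 = strongest; ties averaged."""
    if matrix.isna().any().any():
        gaps = [
            f"{aa}/{col}"
            for aa in matrix.index
            for col in matrix.columns
            if pd.isna(matrix.loc[aa, col])
        ]
        raise ValueError(f"missing entries in preference matrix: {', '.join(gaps)}")
    ranks = rankdata(-matrix.to_numpy(float), axis=1, method="average")
    return pd.DataFrame(ranks, index=matrix.index, columns=matrix.columns)


def binomial_preference_test(k: int, n: int, p: float, tail: str = "upper") -> float:
    """Exact binomial tail probability: P(X >= k) (upper) or P(X <= k) (lower)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p < 1:
        raise ValueError(f"need 0 < p < 1, got p={p}")
    if tail == "upper":
        return float(binom.sf(k - 1, n, p))
    if tail == "lower":
        return float(binom.cdf(k, n, p))
    raise ValueError(f"unknown tail {tail!r}; expected 'upper' or 'lower'")


def _strict_extreme(row: pd.Series, best: bool):
    """Column label of the strict max (best) or strict min (worst), else None."""
    vals = row.to_numpy(float)
    j = int(np.argmax(vals)) if best else int(np.argmin(vals))
    extreme = vals[j]
    if (vals == extreme).sum() > 1:
        return None
    return row.index[j]


def first_choice_summary(matrix: pd.DataFrame, allocations) -> dict:
    """Count allocations whose strict best (and worst) binder is cognate.

    ``allocations`` come from :func:`codonaffinity.genetic_code.expand_assignments`;
    an allocation scores a cognate-first hit when the amino acid's strictly
    best-binding column is in the allocation's cognate base set, and a
    cognate-last hit when the strictly worst-binding column is.
    """
    best = {aa: _strict_extreme(matrix.loc[aa], best=True) for aa in matrix.index}
    worst = {aa: _strict_extreme(matrix.loc[aa], best=False) for aa in matrix.index}
    per_allocation = []
    k_first = k_last = 0
    for alloc in allocations:
        b, w = best[alloc.amino_acid], worst[alloc.amino_acid]
        hit_first = b is not None and b in alloc.bases
        hit_last = w is not None and w in alloc.bases
        k_first += hit_first
        k_last += hit_last
        per_allocation.append(
            {
                "amino_acid": alloc.amino_acid,
                "family": alloc.family,
                "cognate_bases": sorted(alloc.bases),
                "best": b,
                "cognate_first": hit_first,
                "cognate_last": hit_last,
            }
        )
    return {
        "n_allocations": len(list(allocations)),
        "cognate_first": k_first,
        "cognate_last": k_last,
        "per_allocation": per_allocation,
    }


def cognate_hit_summary(
    matrix: pd.DataFrame,
    table=None,
    convention: str = "revcomp",
) -> dict:
    """Does each amino acid bind best to a base cognate at positions 1-2?

    For each amino acid the strict best binder is checked against the union
    of cognate bases at codon positions 1-2 and anticodon positions 1-2
    (base 3 excluded). Reports per amino acid whether the best binder is
    cognate in the codon set, the anticodon set, both, or neither, plus the
    count with at least one hit (the "bound best to at least 1 cognate
    nucleotide" statistic).
    """
    table = gc.standard_table() if table is None else table
    rows = {}
    n_at_least_one = n_both = n_none = 0
    for aa in matrix.index:
        b = _strict_extreme(matrix.loc[aa], best=True)
        codon_set = gc.cognate_bases(aa, "codon1", table, convention) | gc.cognate_bases(
            aa, "codon2", table, convention
        )
        anti_set = gc.cognate_bases(aa, "anticodon1", table, convention) | gc.cognate_bases(
            aa, "anticodon2", table, convention
        )
        in_codon = b is not None and b in codon_set
        in_anti = b is not None and b in anti_set
        n_both += in_codon and in_anti
        n_at_least_one += in_codon or in_anti
        n_none += not (in_codon or in_anti)
        rows[aa] = {"best": b, "cognate_codon": in_codon, "cognate_anticodon": in_anti}
    return {
        "n_amino_acids": len(matrix.index),
        "best_with_both": n_both,
        "best_with_at_least_one": n_at_least_one,
        "best_with_none": n_none,
        "per_amino_acid": rows,
    }


def _allocation_rank(rank_row: pd.Series, bases) -> float:
    """Rank credited to an allocation: its base's rank, or the best rank
    over the base set when the position is degenerate."""
    return float(min(rank_row[b] for b in bases))


def rank_sum_score(rank_matrix: pd.DataFrame, allocations) -> float:
    """Sum of cognate ranks over allocations (lower = stronger preference).

    With every cognate ranked first this is n_allocations (20 for the
    unexpanded standard table, 23 with hexacodonic expansion); with every
    cognate ranked last it is n_columns * n_allocations.
    """
    return float(
        sum(_allocation_rank(rank_matrix.loc[a.amino_acid], a.bases) for a in allocations)
    )


@dataclass
class RandomizationNull:
    """Null distribution of rank sums under uniform random preferences."""

    sums: np.ndarray
    observed: float | None
    n_allocations: int
    n_columns: int
    n_randomizations: int
    seed: int
    dinucleotide_constraint: bool

    @property
    def mean(self) -> float:
        return float(self.sums.mean())

    @property
    def frac_stronger(self) -> float | None:
        """Fraction of null sums strictly greater than observed.

        Lower sum = stronger preference, so this is "the observed preference
        is stronger than this fraction of random assignments".
        """
        if self.observed is None:
            return None
        return float((self.sums > self.observed).mean())

    @property
    def frac_ge(self) -> float | None:
        if self.observed is None:
            return None
        return float((self.sums >= self.observed).mean())

    @property
    def frac_le(self) -> float | None:
        """One-sided p-value for a low (strong) observed sum."""
        if self.observed is None:
            return None
        return float((self.sums <= self.observed).mean())


def randomization_null(
    allocations,
    n_columns: int = 4,
    n_randomizations: int = 200_000,
    seed: int = 0,
    dinucleotide_constraint: bool = False,
    observed: float | None = None,
) -> RandomizationNull:
    """Null distribution of the rank-sum score under uniform random ranks.

    Each randomization assigns every allocation an independent uniform rank
    from {1..n_columns}. With the dinucleotide constraint on, allocations
    sharing an amino acid draw *distinct* ranks within one randomization
    (an amino acid's several cognate dinucleotides are never ranked
    identically). The constraint is meaningless for mononucleotide schemes
    and is ignored there with a warning (mononucleotide allocations sharing
    an amino acid claim different codon families, not competing columns —
    callers signal the dinucleotide case explicitly).
    """
    allocations = list(allocations)
    n_alloc = len(allocations)
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    is_dinuc = all(len(next(iter(a.bases))) == 2 for a in allocations) if allocations else False
    if dinucleotide_constraint and not is_dinuc:
        warnings.warn(
            "dinucleotide constraint requested for a mononucleotide scheme; ignored"
        )
        dinucleotide_constraint = False
    rng = np.random.default_rng(seed)
    if not dinucleotide_constraint:
        ranks = rng.integers(1, n_columns + 1, size=(n_randomizations, n_alloc))
        sums = ranks.sum(axis=1).astype(float)
    else:
        groups: dict = {}
        for i, a in enumerate(allocations):
            groups.setdefault(a.amino_acid, []).append(i)
        sums = np.zeros(n_randomizations)
        for idxs in groups.values():
            m = len(idxs)
            if m == 1:
                sums += rng.integers(1, n_columns + 1, size=n_randomizations)
            else:
                if m > n_columns:
                    raise ValueError(
                        f"cannot draw {m} distinct ranks from 1..{n_columns}"
                    )
                # m distinct uniform ranks per draw: first m of a permutation
                perm = rng.permuted(
                    np.tile(np.arange(1, n_columns + 1), (n_randomizations, 1)), axis=1
                )
                sums += perm[:, :m].sum(axis=1)
    return RandomizationNull(
        sums=sums,
        observed=observed,
        n_allocations=n_alloc,
        n_columns=n_columns,
        n_randomizations=n_randomizations,
        seed=seed,
        dinucleotide_constraint=dinucleotide_constraint,
    )


def directionality_compare(
    series_xy: pd.DataFrame,
    series_yx: pd.DataFrame,
    threshold: float = 5.0,
    divisor_xy: float = 1.0,
    divisor_yx: float = 1.0,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Adjusted-binding difference between an XY and a YX dinucleotide.

    Both inputs are per-run distance-series tables for the same amino acid
    with the two dinucleotide orientations. Runs of each system are
    bootstrapped independently; the 95% percentile interval of the
    difference (XY minus YX, on the adjusted scale) is reported, with a
    flag when it excludes zero.
    """
    for name, s in (("XY", series_xy), ("YX", series_yx)):
        if s is None or len(s) == 0:
            raise ValueError(f"missing orientation {name}")
    if divisor_xy <= 0 or divisor_yx <= 0:
        raise ValueError("volume divisors must be positive")

    def _boot(series, divisor, rng):
        grp = series.groupby("run_id")["distance"]
        counts = grp.apply(lambda d: int((d.to_numpy() < threshold).sum())).to_numpy()
        sizes = grp.size().to_numpy()
        idx = rng.integers(0, counts.size, size=(n_boot, counts.size))
        return counts[idx].sum(axis=1) / sizes[idx].sum(axis=1) / divisor

    rng = np.random.default_rng(seed)
    bx = _boot(series_xy, divisor_xy, rng)
    by = _boot(series_yx, divisor_yx, rng)
    diff = (
        binding_fraction(series_xy, threshold).raw_fraction / divisor_xy
        - binding_fraction(series_yx, threshold).raw_fraction / divisor_yx
    )
    lo, hi = np.percentile(bx - by, [2.5, 97.5])
    return {
        "difference": float(diff),
        "ci95": (float(lo), float(hi)),
        "excludes_zero": bool(lo > 0 or hi < 0),
        "n_boot": n_boot,
    }
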