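"""Composite hydrophobicity ranking and binding regressions.

Published hydrophobicity scales disagree widely, so a composite is used:
within each scale the 20 amino acids are ranked (1 = most hydrophobic,
ties averaged, orientation flags resolved first), and an amino acid's
composite value is its mean rank across scales. The composite is invariant
to any monotone transformation of an individual scale's values.

Binding is then regressed (ordinary least squares) on hydrophobicity and
the molecular volume fractions of the amino acid and nucleotide, per
nucleotide and charge state; the slope sign and significance of each
covariate are the quantities of interest. A handful of public scales
(Kyte-Doolittle, Hopp-Woods, Eisenberg, Janin) ship as fixtures; the
composite used in the study averaged a larger compilation, which users can
supply as tabular text.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .genetic_code import AA_THREE_LETTER, normalize_amino_acid

__all__ = [
    "HydrophobicityScale",
    "builtin_scales",
    "load_scale_table",
    "composite_rank",
    "regress_binding",
]

AMINO_ACIDS = tuple(AA_THREE_LETTER)  # the 20 standard residues, 1-letter


@dataclass(frozen=True)
class HydrophobicityScale:
    """One amino-acid hydrophobicity scale with its orientation."""

    name: str
    values: dict  # 1-letter amino acid -> scalar
    higher_is_hydrophobic: bool = True

    def __post_init__(self):
        vals = {normalize_amino_acid(k): float(v) for k, v in self.values.items()}
        object.__setattr__(self, "values", vals)
        missing = set(AMINO_ACIDS) - set(vals)
        if missing:
            raise ValueError(
                f"scale {self.name!r} is missing amino acids: {', '.join(sorted(missing))}"
            )

    def ranks(self) -> pd.Series:
        """Within-scale ranks, 1 = most hydrophobic, ties averaged."""
        vals = np.array([self.values[aa] for aa in AMINO_ACIDS])
        if not self.higher_is_hydrophobic:
            vals = -vals
        return pd.Series(rankdata(-vals, method="average"), index=list(AMINO_ACIDS))


def load_scale_table(path) -> list:
    """Load scales from tabular text.

    Long format with columns scale, amino_acid, value and optional
    higher_is_hydrophobic; or two-column (amino_acid, value) for a single
    unnamed scale.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "amino_acid" not in cols or "value" not in cols:
        raise ValueError(f"scale table {path} must have columns amino_acid, value")
    if "scale" not in cols:
        return [
            HydrophobicityScale(
                name=str(path),
                values=dict(zip(df[cols["amino_acid"]], df[cols["value"]])),
            )
        ]
    out = []
    for name, sub in df.groupby(cols["scale"], sort=False):
        hi = True
        if "higher_is_hydrophobic" in cols:
            hi = bool(sub[cols["higher_is_hydrophobic"]].iloc[0])
        out.append(
            HydrophobicityScale(
                name=str(name),
                values=dict(zip(sub[cols["amino_acid"]], sub[cols["value"]])),
                higher_is_hydrophobic=hi,
            )
        )
    return out


def builtin_scales() -> list:
    """The bundled public scales (Kyte-Doolittle, Hopp-Woods, Eisenberg, Janin)."""
    ref = resources.files("codonaffinity.data") / "hydrophobicity_scales.tsv"
    with resources.as_file(ref) as path:
        return load_scale_table(path)


def composite_rank(scales) -> pd.Series:
    """Mean within-scale hydrophobicity rank per amino acid (1 = most hydrophobic)."""
    scales = list(scales)
    if not scales:
        raise ValueError("need at least one hydrophobicity scale")
    return pd.concat([s.ranks() for s in scales], axis=1).mean(axis=1)


def regress_binding(binding: pd.Series, covariates: pd.DataFrame):
    """OLS of adjusted binding on covariates (e.g. hydrophobicity, volumes).

    ``binding`` and ``covariates`` are aligned on amino-acid index; an
    intercept is added. Returns the fitted statsmodels results object
    (``.params``, ``.pvalues``, ``.rsquared``). Collinear covariates are
    rejected with the design-matrix condition number in the message.
    """
    df = covariates.join(binding.rename("_y"), how="inner").dropna()
    n_cov = covariates.shape[1]
    if len(df) < n_cov + 2:
        raise ValueError(
            f"need at least {n_cov + 2} observations for {n_cov} covariates, got {len(df)}"
        )
    X = sm.add_constant(df[covariates.columns].astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        cond = np.linalg.cond(X.to_numpy())
        raise ValueError(
            f"collinear covariates (design matrix rank-deficient, condition number {cond:.3g})"
        )
    return sm.OLS(df["_y"].astype(float), X).fit()
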