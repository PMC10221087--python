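"""The standard genetic code and the cognate-base sets it defines.

Every preference statistic downstream compares binding measurements against
the nucleotides an amino acid "owns" at a given codon or anticodon position.
This module models the code table (built-in standard table, overridable from
tabular text), derives anticodons, and expands the table into per-codon-family
allocations: one allocation per amino acid plus one extra per hexacodonic
amino acid (Leu, Arg, Ser), giving 23 allocations for the standard table.

Anticodon conventions
---------------------
Anticodons are written 5'->3'. Two conventions are supported for mapping
codon positions onto anticodon positions:

``revcomp`` (default)
    The anticodon is the reverse complement of the codon, so anticodon
    base 1 pairs with codon base 3. This is the biological standard.
``aligned``
    Anticodon base i is the complement of codon base i.

Under both conventions the anticodon middle base is the Watson-Crick
complement of the codon middle base.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

RNA_BASES = ("A", "C", "G", "U")
COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

POSITION_SCHEMES = ("codon1", "codon2", "anticodon1", "anticodon2")
CONVENTIONS = ("revcomp", "aligned")

AA_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
_THREE_TO_ONE = {v.upper(): k for k, v in AA_THREE_LETTER.items()}

CodeTable = Mapping[str, frozenset]


def _validate_codon(codon: str) -> str:
    codon = str(codon).strip().upper().replace("T", "U")
    if len(codon) != 3:
        raise ValueError(f"codon {codon!r} is not a triplet")
    for ch in codon:
        if ch not in RNA_BASES:
            raise ValueError(
                f"invalid RNA base {ch!r} in codon {codon!r}; expected one of A, C, G, U"
            )
    return codon


def normalize_amino_acid(aa: str) -> str:
    """Accept 1- or 3-letter amino-acid codes; return the 1-letter code."""
    key = str(aa).strip()
    if len(key) == 1 and key.upper() in AA_THREE_LETTER:
        return key.upper()
    if key.upper() in _THREE_TO_ONE:
        return _THREE_TO_ONE[key.upper()]
    raise KeyError(f"unknown amino acid {aa!r}")


def standard_table() -> dict:
    """The standard genetic code as {1-letter amino acid: frozenset of codons}.

    Stop codons are excluded; 61 sense codons over 20 amino acids.
    """
    fwd = _BioCodonTable.unambiguous_rna_by_id[1].forward_table
    out: dict = {}
    for codon, aa in fwd.items():
        out.setdefault(aa, set()).add(codon)
    return {aa: frozenset(cods) for aa, cods in out.items()}


def load_code_table(path) -> dict:
    """Load a code table from tabular text with columns amino_acid, codon.

    Amino acids may be 1- or 3-letter; codons RNA (or DNA, T mapped to U).
    Used for codon-reassignment experiments; the standard table is built in.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        aa_col, codon_col = cols["amino_acid"], cols["codon"]
    except KeyError as exc:
        raise ValueError(f"code table {path} must have columns amino_acid, codon") from exc
    out: dict = {}
    for aa, codon in zip(df[aa_col], df[codon_col]):
        out.setdefault(normalize_amino_acid(aa), set()).add(_validate_codon(codon))
    seen = list(itertools.chain.from_iterable(out.values()))
    if len(seen) != len(set(seen)):
        raise ValueError(f"code table {path} assigns some codon to more than one amino acid")
    return {aa: frozenset(cods) for aa, cods in out.items()}


def anticodon_of(codon: str, convention: str = "revcomp") -> str:
    """Anticodon (5'->3') of an RNA codon under the given convention."""
    codon = _validate_codon(codon)
    if convention == "revcomp":
        return "".join(COMPLEMENT[b] for b in reversed(codon))
    if convention == "aligned":
        return "".join(COMPLEMENT[b] for b in codon)
    raise ValueError(f"unknown anticodon convention {convention!r}")


def codon_of(anticodon: str, convention: str = "revcomp") -> str:
    """Inverse of :func:`anticodon_of`; both conventions are involutions."""
    return anticodon_of(anticodon, convention)


def codon_families(codons: Iterable[str]) -> dict:
    """Group codons by their first two bases: {'GG': {'GGA', ...}, ...}."""
    fams: dict = {}
    for codon in codons:
        fams.setdefault(_validate_codon(codon)[:2], set()).add(codon)
    return fams


@dataclass(frozen=True)
class CodeAssignment:
    """One amino acid's codons and derived anticodons."""

    amino_acid: str
    amino_acid_3: str
    codons: frozenset
    anticodons: frozenset
    codon_family_middle_bases: frozenset
    convention: str = "revcomp"

    @property
    def hexacodonic(self) -> bool:
        return len(codon_families(self.codons)) > 1


def assignments(table: CodeTable | None = None, convention: str = "revcomp") -> dict:
    """Build a CodeAssignment per amino acid from a code table."""
    table = standard_table() if table is None else table
    out = {}
    for aa, codons in table.items():
        aa = normalize_amino_acid(aa)
        out[aa] = CodeAssignment(
            amino_acid=aa,
            amino_acid_3=AA_THREE_LETTER[aa],
            codons=frozenset(codons),
            anticodons=frozenset(anticodon_of(c, convention) for c in codons),
            codon_family_middle_bases=frozenset(c[1] for c in codons),
            convention=convention,
        )
    return out


def hexacodonic_amino_acids(table: CodeTable | None = None) -> frozenset:
    """Amino acids spanning more than one codon family (standard: Leu, Arg, Ser)."""
    table = standard_table() if table is None else table
    return frozenset(aa for aa, cods in table.items() if len(codon_families(cods)) > 1)


@dataclass(frozen=True)
class Allocation:
    """One codon family's claim on a base (or base set) at a code position.

    ``bases`` is a singleton for codon1, codon2 and anticodon2; it can hold
    several bases for anticodon1 under the revcomp convention, where the
    position pairs with the degenerate codon base 3.
    """

    amino_acid: str
    position_scheme: str
    family: str  # first two codon bases identifying the family
    bases: frozenset

    @property
    def base(self) -> str:
        if len(self.bases) != 1:
            raise ValueError(
                f"allocation {self.amino_acid}/{self.family} at {self.position_scheme} "
                f"has base set {sorted(self.bases)}, not a single base"
            )
        return next(iter(self.bases))


def _family_bases(family: str, codons: set, position: str, convention: str) -> frozenset:
    if position == "codon1":
        return frozenset(family[0])
    if position == "codon2":
        return frozenset(family[1])
    if position == "anticodon2":
        # middle base of the anticodon complements the codon middle base
        # under either convention
        return frozenset(COMPLEMENT[family[1]])
    if position == "anticodon1":
        if convention == "aligned":
            return frozenset(COMPLEMENT[family[0]])
        return frozenset(COMPLEMENT[c[2]] for c in codons)
    raise ValueError(f"unknown position scheme {position!r}; expected one of {POSITION_SCHEMES}")


def expand_assignments(
    table: CodeTable | None = None,
    position: str = "anticodon2",
    convention: str = "revcomp",
) -> list:
    """One Allocation per codon family.

    Standard table: 23 allocations (20 amino acids + 1 extra each for the
    hexacodonic Leu, Arg and Ser, whose codons span two families).
    """
    if position not in POSITION_SCHEMES:
        raise ValueError(f"unknown position scheme {position!r}; expected one of {POSITION_SCHEMES}")
    table = standard_table() if table is None else table
    out = []
    for aa in sorted(table, key=normalize_amino_acid):
        aa1 = normalize_amino_acid(aa)
        for family, codons in sorted(codon_families(table[aa]).items()):
            out.append(
                Allocation(
                    amino_acid=aa1,
                    position_scheme=position,
                    family=family,
                    bases=_family_bases(family, codons, position, convention),
                )
            )
    return out


def cognate_bases(
    amino_acid: str,
    position: str,
    table: CodeTable | None = None,
    convention: str = "revcomp",
) -> frozenset:
    """All bases cognate to an amino acid at one position, across its families."""
    table = standard_table() if table is None else table
    aa = normalize_amino_acid(amino_acid)
    lookup = {normalize_amino_acid(k): v for k, v in table.items()}
    if aa not in lookup:
        raise KeyError(f"amino acid {amino_acid!r} not in code table")
    bases: set = set()
    for family, codons in codon_families(lookup[aa]).items():
        bases |= _family_bases(family, codons, position, convention)
    return frozenset(bases)


def middle_base_usage(table: CodeTable | None = None) -> dict:
    """How many of the 20 amino acids use each base at anticodon position 2.

    Hexacodonic amino acids are counted once per *distinct* middle base, so
    Ser (UCN + AGY families) contributes to two bases and the counts sum to 21
    on the standard table. U leads with 7 of 20 amino acids.
    """
    table = standard_table() if table is None else table
    counts = {b: 0 for b in RNA_BASES}
    for codons in table.values():
        for mid in {COMPLEMENT[c[1]] for c in codons}:
            counts[mid] += 1
    return counts


def cognate_dinucleotides(
    amino_acid: str,
    frame: str = "codonic",
    table: CodeTable | None = None,
    convention: str = "revcomp",
) -> frozenset:
    """Distinct base-1+base-2 pairs of an amino acid's codons or anticodons."""
    if frame not in ("codonic", "anticodonic"):
        raise ValueError(f"unknown frame {frame!r}; expected 'codonic' or 'anticodonic'")
    table = standard_table() if table is None else table
    aa = normalize_amino_acid(amino_acid)
    lookup = {normalize_amino_acid(k): v for k, v in table.items()}
    if aa not in lookup:
        raise KeyError(f"amino acid {amino_acid!r} not in code table")
    triplets = lookup[aa]
    if frame == "anticodonic":
        triplets = {anticodon_of(c, convention) for c in triplets}
    return frozenset(t[:2] for t in triplets)
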