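"""Chemical-shift-index (CSI) secondary-structure classification.

Backbone chemical shifts deviate from their random-coil values in a
structure-dependent way: Cα and C' move downfield in helices and
upfield in extended/sheet conformations, while Hα and Cβ do the
opposite.  The classical CSI turns each secondary shift
Δδ_sec = δ_obs - δ_coil(residue type) into a ternary index (+1/0/-1)
against a per-nucleus cutoff and takes a majority vote across nuclei.

For an intrinsically disordered peptide the expected outcome is a flat,
sub-threshold profile — i.e. no helix or sheet signal — which is exactly
the operative claim this module supports.  Note the classical CSI has no
poly-proline-II class: "no helix/sheet signal" is the strongest
statement it can make, and trained propensity predictors are a separate
kind of tool (deliberately not reimplemented here, so their printed coil
percentages are not comparable numbers).

The bundled random-coil reference is a compilation of the classical
CSI-era random-coil tables (Wishart and co-workers' 1H/13C values for
the 20 standard residues); the table is plain data and swappable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import parse_residue_label
from .io import AssignedShifts

__all__ = [
    "RANDOM_COIL", "DEFAULT_CUTOFFS", "secondary_shifts",
    "CSIResult", "csi_classify",
]

CSI_NUCLEI = ("CA", "CB", "C", "HA")

#: Random-coil reference shifts (ppm) per residue type.  Glycine has no Cβ.
RANDOM_COIL: dict[str, dict[str, float]] = {
    "CA": {"A": 52.8, "C": 56.8, "D": 54.0, "E": 56.3, "F": 58.0,
           "G": 44.9, "H": 55.8, "I": 61.5, "K": 56.4, "L": 55.3,
           "M": 55.8, "N": 53.0, "P": 63.0, "Q": 56.0, "R": 56.5,
           "S": 58.2, "T": 62.0, "V": 62.5, "W": 57.6, "Y": 58.0},
    "CB": {"A": 19.3, "C": 28.6, "D": 41.1, "E": 29.9, "F": 39.1,
           "H": 29.9, "I": 38.9, "K": 32.8, "L": 42.0,
           "M": 32.9, "N": 38.7, "P": 31.8, "Q": 29.3, "R": 30.9,
           "S": 63.8, "T": 69.8, "V": 31.8, "W": 29.8, "Y": 38.8},
    "C":  {"A": 177.6, "C": 174.6, "D": 176.8, "E": 176.6, "F": 175.9,
           "G": 173.6, "H": 175.1, "I": 176.5, "K": 176.5, "L": 176.9,
           "M": 176.3, "N": 175.6, "P": 176.0, "Q": 175.6, "R": 176.3,
           "S": 174.4, "T": 174.8, "V": 176.0, "W": 173.6, "Y": 175.9},
    "HA": {"A": 4.35, "C": 4.65, "D": 4.76, "E": 4.29, "F": 4.66,
           "G": 3.97, "H": 4.63, "I": 3.95, "K": 4.36, "L": 4.17,
           "M": 4.52, "N": 4.75, "P": 4.44, "Q": 4.37, "R": 4.38,
           "S": 4.50, "T": 4.35, "V": 3.95, "W": 4.70, "Y": 4.60},
}

#: Classical per-nucleus cutoffs (ppm) for index assignment.
DEFAULT_CUTOFFS = {"CA": 0.7, "CB": 0.7, "C": 0.7, "HA": 0.1}

# Downfield (positive Δδ_sec) means helix for CA/C', sheet for CB/HA.
_POSITIVE_MEANS = {"CA": "helix", "C": "helix",
                   "CB": "sheet", "HA": "sheet"}
_NEGATIVE_MEANS = {"CA": "sheet", "C": "sheet",
                   "CB": "helix", "HA": "helix"}

CLASSES = ("helix", "sheet", "coil")


def secondary_shifts(shifts: AssignedShifts,
                     reference: dict[str, dict[str, float]] | None = None
                     ) -> dict[str, dict[str, float]]:
    """Per-residue, per-nucleus secondary shifts δ_obs - δ_coil.

    Only CSI nuclei (CA, CB, C', HA) are considered; observations absent
    from the input simply stay absent (Gly contributes no Cβ by
    construction of the reference).  A residue type missing from the
    reference for an observed nucleus is an error.
    """
    reference = reference if reference is not None else RANDOM_COIL
    for nuc in CSI_NUCLEI:
        if nuc not in reference:
            raise ValueError(f"reference table lacks nucleus {nuc!r}")
    out: dict[str, dict[str, float]] = {}
    for label, atoms in shifts.shifts.items():
        aa = parse_residue_label(label)[0]
        sec = {}
        for nuc, obs in atoms.items():
            if nuc not in CSI_NUCLEI:
                continue
            table = reference[nuc]
            if aa not in table:
                if nuc == "CB" and aa == "G":
                    continue  # glycine has no Cβ
                raise ValueError(
                    f"residue type {aa!r} absent from reference for {nuc}")
            sec[nuc] = obs - table[aa]
        if sec:
            out[label] = sec
    return out


@dataclass
class CSIResult:
    """Per-residue indices and consensus classes, plus class fractions."""

    table: pd.DataFrame          # residue, position, per-nucleus cols
    fractions: dict[str, float]  # class -> fraction over classified residues

    @property
    def coil_fraction(self) -> float:
        return self.fractions["coil"]


def _index(value: float, cutoff: float) -> int:
    if value > cutoff:
        return 1
    if value < -cutoff:
        return -1
    return 0


def csi_classify(sec_shifts: dict[str, dict[str, float]],
                 cutoffs: dict[str, float] | None = None) -> CSIResult:
    """Classify residues as helix / sheet(extended) / coil by consensus.

    Each available nucleus votes according to the sign of its index and
    its structural meaning; the consensus is the strict majority over
    votes, ties resolving to coil.  Residues with fewer than two
    available nuclei are left unclassified and excluded from the class
    fractions (which sum to 1 over classified residues).
    """
    cutoffs = dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    if any(c <= 0 for c in cutoffs.values()):
        raise ValueError("cutoffs must be positive")
    rows = []
    counts = {c: 0 for c in CLASSES}
    labels = sorted(sec_shifts, key=lambda lab: parse_residue_label(lab)[1])
    for label in labels:
        sec = sec_shifts[label]
        row = {"residue": label,
               "position": parse_residue_label(label)[1]}
        votes = {c: 0 for c in CLASSES}
        available = 0
        for nuc in CSI_NUCLEI:
            if nuc not in sec:
                row[f"dsec_{nuc}"] = None
                row[f"index_{nuc}"] = None
                continue
            available += 1
            idx = _index(sec[nuc], cutoffs.get(nuc, DEFAULT_CUTOFFS[nuc]))
            row[f"dsec_{nuc}"] = sec[nuc]
            row[f"index_{nuc}"] = idx
            if idx > 0:
                votes[_POSITIVE_MEANS[nuc]] += 1
            elif idx < 0:
                votes[_NEGATIVE_MEANS[nuc]] += 1
            else:
                votes["coil"] += 1
        if available >= 2:
            top = max(votes.values())
            winners = [c for c in CLASSES if votes[c] == top]
            consensus = winners[0] if len(winners) == 1 else "coil"
            counts[consensus] += 1
        else:
            consensus = None
        row["consensus"] = consensus
        rows.append(row)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classifiable residues (need >= 2 nuclei each)")
    fractions = {c: counts[c] / total for c in CLASSES}
    return CSIResult(table=pd.DataFrame(rows), fractions=fractions)
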