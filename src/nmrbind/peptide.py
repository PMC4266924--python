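"""Sequence-derived physicochemical properties of the peptide construct.

Average molecular mass (the quantity MALDI-TOF and ProtParam report),
isoelectric point and net charge via Henderson–Hasselbalch titration of
the ionizable groups, and sample molarity from a weighed mass.  The
default pKa set is Bjellqvist's (the set ProtParam implements), with
EMBOSS as a selectable alternative; both include the free termini, with
residue-specific terminal pKa corrections where the set defines them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio.Data.IUPACData import protein_weights
from scipy.optimize import brentq

from ._util import AA_CODES
from .io import SequenceRecord, read_fasta

__all__ = [
    "PKA_SETS", "average_mass", "net_charge", "integer_net_charge",
    "isoelectric_point", "molarity", "PropertyReport", "characterize",
    "bundled_xa2_sequence",
]

WATER_MASS = 18.01528  # Da

#: Ionization constants.  'bjellqvist' is the ProtParam set, including
#: residue-specific N-terminal pKa values; 'emboss' is the EMBOSS default.
PKA_SETS = {
    "bjellqvist": {
        "positive": {"K": 10.0, "R": 12.0, "H": 5.98},
        "negative": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
        "nterm": 7.5,
        "cterm": 3.55,
        "nterm_by_residue": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
                             "T": 6.82, "V": 7.44, "E": 7.7},
        "cterm_by_residue": {"D": 4.55, "E": 4.75},
    },
    "emboss": {
        "positive": {"K": 10.8, "R": 12.5, "H": 6.5},
        "negative": {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
        "nterm": 8.6,
        "cterm": 3.6,
        "nterm_by_residue": {},
        "cterm_by_residue": {},
    },
}


def _as_sequence(seq) -> SequenceRecord:
    return seq if isinstance(seq, SequenceRecord) else SequenceRecord(str(seq))


def _validate(seq: SequenceRecord) -> str:
    for i, aa in enumerate(seq.sequence):
        if aa not in AA_CODES:
            raise ValueError(
                f"invalid amino-acid code {aa!r} at position "
                f"{seq.start_number + i}")
    return seq.sequence


def average_mass(seq) -> float:
    """Average (not monoisotopic) molecular mass in Da.

    Sum of average residue masses plus one water — the figure a MALDI-TOF
    measurement of the intact peptide reports.  Residue weights come from
    the standard IUPAC average-mass table (free amino acids; one water is
    released per peptide bond), so mass is exactly additive over
    concatenation up to a single water.
    """
    sequence = _validate(_as_sequence(seq))
    free = sum(protein_weights[aa] for aa in sequence)
    return float(free - (len(sequence) - 1) * WATER_MASS)


def _ionizable_groups(sequence: str, pka_set: dict,
                      include_termini: bool = True):
    """Yield (pKa, charge_sign) for every ionizable group."""
    groups = []
    if include_termini:
        groups.append((pka_set["nterm_by_residue"].get(
            sequence[0], pka_set["nterm"]), +1))
        groups.append((pka_set["cterm_by_residue"].get(
            sequence[-1], pka_set["cterm"]), -1))
    for aa in sequence:
        if aa in pka_set["positive"]:
            groups.append((pka_set["positive"][aa], +1))
        elif aa in pka_set["negative"]:
            groups.append((pka_set["negative"][aa], -1))
    return groups


def net_charge(seq, pH: float, pka_set: str = "bjellqvist",
               include_termini: bool = True) -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Sums the protonated fraction of each basic group (K, R, H, N-term)
    and the deprotonated fraction of each acidic group (D, E, C, Y,
    C-term).  Strictly decreasing in pH.
    """
    if not 0 <= pH <= 14:
        raise ValueError("pH must be within [0, 14]")
    sequence = _validate(_as_sequence(seq))
    pkas = PKA_SETS[pka_set]
    charge = 0.0
    for pka, sign in _ionizable_groups(sequence, pkas, include_termini):
        if sign > 0:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return charge


def integer_net_charge(seq) -> int:
    """Formal charge by residue counting: (K + R) - (D + E).

    The back-of-envelope figure often quoted alongside a pI; reported
    next to the Henderson–Hasselbalch value, not instead of it.
    """
    sequence = _validate(_as_sequence(seq))
    return (sum(sequence.count(a) for a in "KR")
            - sum(sequence.count(a) for a in "DE"))


def isoelectric_point(seq, pka_set: str = "bjellqvist",
                      include_termini: bool = True,
                      tol: float = 1e-3) -> float:
    """pH at which the net charge vanishes, by bisection over [0, 14]."""
    sequence = _validate(_as_sequence(seq))
    if not _ionizable_groups(sequence, PKA_SETS[pka_set], include_termini):
        raise ValueError("sequence has no ionizable groups")

    def f(pH):
        return net_charge(sequence, pH, pka_set, include_termini)

    lo, hi = f(0.0), f(14.0)
    if lo <= 0:   # all-acidic edge case
        return 0.0
    if hi >= 0:   # all-basic edge case
        return 14.0
    return float(brentq(f, 0.0, 14.0, xtol=tol))


def molarity(mass_mg: float, molecular_weight_da: float,
             volume_ml: float) -> float:
    """Concentration in mM of ``mass_mg`` dissolved to ``volume_ml``.

    (mass_mg/1000 / MW) mol in (volume_ml/1000) L, expressed in mM.
    """
    if mass_mg <= 0 or molecular_weight_da <= 0 or volume_ml <= 0:
        raise ValueError("mass, molecular weight and volume must be > 0")
    mol = mass_mg / 1000.0 / molecular_weight_da
    litres = volume_ml / 1000.0
    return mol / litres * 1000.0


@dataclass
class PropertyReport:
    """Printed-style characterization of a peptide construct."""

    sequence: str
    start_number: int
    length: int
    average_mass: float       # Da
    pI: float
    net_charge_at_pH7: float  # Henderson–Hasselbalch
    integer_net_charge: int
    pka_set: str

    def __post_init__(self):
        if self.average_mass <= 0:
            raise ValueError("average_mass must be > 0")
        if not 0 < self.pI < 14:
            raise ValueError("pI must lie strictly inside (0, 14)")

    def as_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "start_number": self.start_number,
            "length": self.length,
            "average_mass_da": round(self.average_mass, 2),
            "pI": round(self.pI, 2),
            "net_charge_pH7": round(self.net_charge_at_pH7, 2),
            "integer_net_charge": self.integer_net_charge,
            "pka_set": self.pka_set,
        }


def characterize(seq, pka_set: str = "bjellqvist") -> PropertyReport:
    """Full property report for a sequence or SequenceRecord."""
    record = _as_sequence(seq)
    return PropertyReport(
        sequence=record.sequence,
        start_number=record.start_number,
        length=len(record),
        average_mass=average_mass(record),
        pI=isoelectric_point(record, pka_set=pka_set),
        net_charge_at_pH7=net_charge(record, 7.0, pka_set=pka_set),
        integer_net_charge=integer_net_charge(record),
        pka_set=pka_set,
    )


def bundled_xa2_sequence() -> SequenceRecord:
    """The xα2 peptide: murine 18.5 kDa MBP residues S38–S107.

    Shipped as package data; any other FASTA can be substituted
    throughout the pipeline.
    """
    path = resources.files("nmrbind").joinpath("data/xa2_s38_s107.fasta")
    with resources.as_file(path) as p:
        return read_fasta(p)
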