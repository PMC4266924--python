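"""Shared helpers: residue labels, concentration parsing, warning class."""

from __future__ import annotations

import re

AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")
#: 'X' is accepted in sequences as an unknown residue (e.g. gaps inferred
#: from a sparse chemical-shift table), never in peak assignments.
SEQ_CODES = AA_CODES | {"X"}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_LABEL_RE = re.compile(r"^([A-Z])(\d+)$")


class NmrbindWarning(UserWarning):
    """Non-fatal data-quality or analysis warning emitted by nmrbind."""


def parse_residue_label(label: str) -> tuple[str, int]:
    """Split a residue label like ``"Y65"`` into ``("Y", 65)``.

    Labels carry the protein's own (here: murine 18.5 kDa MBP) 1-based
    numbering verbatim; no renumbering happens anywhere in the package.
    """
    m = _LABEL_RE.match(label)
    if m is None or m.group(1) not in AA_CODES or int(m.group(2)) < 1:
        raise ValueError(
            f"invalid residue label {label!r}: expected one-letter amino-acid "
            "code followed by a positive integer (e.g. 'Y65')"
        )
    return m.group(1), int(m.group(2))


_CONC_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6,
               "μM": 1e-6, "nM": 1e-9}


def parse_concentration(value) -> float:
    """Return a concentration in molar.

    Bare numbers are taken as molar; strings must carry an explicit unit
    tag, e.g. ``"0.8 mM"`` or ``"7.6 uM"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    m = re.match(r"^([-+0-9.eE]+)\s*([A-Za-zµμ]+)$", text)
    if m is None or m.group(2) not in _CONC_UNITS:
        raise ValueError(
            f"cannot parse concentration {value!r}; use e.g. '0.8 mM', '7.6 uM'"
        )
    return float(m.group(1)) * _CONC_UNITS[m.group(2)]
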