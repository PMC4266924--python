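"""Domain types and readers/writers for peak lists, titrations and shifts.

The raw observable of the whole pipeline is a series of 2D 1H-15N HSQC
peak lists collected while a ligand (here an SH3 domain) is titrated into
an isotopically labelled receptor peptide.  This module holds the
containers for those observations and the plain-text formats they travel
in: SPARKY peak lists, CSV peak lists, a minimal NMR-STAR v3 chemical
shift loop, and a YAML run configuration.

Concentrations are molar everywhere inside the package; readers accept
explicit unit tags (``"0.8 mM"``) because titration receptor
concentrations (sub-millimolar) and dissociation constants (micromolar)
would otherwise invite silent unit mistakes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from ._util import (AA3_TO_1, AA_CODES, SEQ_CODES, NmrbindWarning,
                    parse_concentration, parse_residue_label)

__all__ = [
    "Peak", "PeakList", "SequenceRecord", "AssignedShifts",
    "TitrationPoint", "TitrationSeries",
    "read_sparky_peaklist", "write_sparky_peaklist",
    "read_csv_peaklist", "write_csv_peaklist",
    "read_nmrstar_shifts", "read_fasta", "assemble_titration",
    "load_run_config",
]

# Sanity windows for backbone amide shifts; violations warn but never fail,
# since folded-protein outliers and referencing offsets are common.
H_WINDOW = (-2.0, 15.0)
N_WINDOW = (90.0, 140.0)


@dataclass(frozen=True)
class Peak:
    """One amide cross-peak: 1H and 15N positions plus optional height."""

    delta_H: float
    delta_N: float
    residue_label: str | None = None
    height: float | None = None

    def __post_init__(self):
        if self.residue_label is not None:
            parse_residue_label(self.residue_label)  # raises if malformed
        if not (H_WINDOW[0] <= self.delta_H <= H_WINDOW[1]):
            warnings.warn(
                f"delta_H {self.delta_H} ppm outside {H_WINDOW}", NmrbindWarning)
        if not (N_WINDOW[0] <= self.delta_N <= N_WINDOW[1]):
            warnings.warn(
                f"delta_N {self.delta_N} ppm outside {N_WINDOW}", NmrbindWarning)

    @property
    def is_assigned(self) -> bool:
        return self.residue_label is not None

    @property
    def residue_type(self) -> str:
        return parse_residue_label(self.residue_label)[0]

    @property
    def residue_number(self) -> int:
        return parse_residue_label(self.residue_label)[1]


@dataclass(frozen=True)
class PeakList:
    """An ordered collection of peaks from one spectrum.

    Unassigned peaks are retained (they participate in geometric peak
    tracking) but never enter per-residue analyses.  Assigned labels must
    be unique within a list.
    """

    peaks: tuple[Peak, ...]
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "peaks", tuple(self.peaks))
        seen = set()
        for p in self.peaks:
            if p.is_assigned:
                if p.residue_label in seen:
                    raise ValueError(
                        f"duplicate assignment {p.residue_label!r} in peak list")
                seen.add(p.residue_label)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def assigned(self) -> dict[str, Peak]:
        return {p.residue_label: p for p in self.peaks if p.is_assigned}


@dataclass(frozen=True)
class SequenceRecord:
    """A one-letter peptide sequence with its numbering offset.

    ``start_number`` anchors the construct in the parent protein's
    numbering (e.g. 38 for a peptide spanning residues S38-S107), so that
    residue labels such as "Y65" index directly into the sequence.
    """

    sequence: str
    start_number: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        for i, aa in enumerate(self.sequence):
            if aa not in SEQ_CODES:
                raise ValueError(
                    f"invalid amino-acid code {aa!r} at position "
                    f"{self.start_number + i}")
        if self.start_number < 1:
            raise ValueError("start_number must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end_number(self) -> int:
        return self.start_number + len(self.sequence) - 1

    def residue_type(self, position: int) -> str:
        if not self.start_number <= position <= self.end_number:
            raise KeyError(f"position {position} outside "
                           f"[{self.start_number}, {self.end_number}]")
        return self.sequence[position - self.start_number]

    def label(self, position: int) -> str:
        return f"{self.residue_type(position)}{position}"

    def labels(self, include_proline: bool = True) -> list[str]:
        out = []
        for pos in range(self.start_number, self.end_number + 1):
            if not include_proline and self.residue_type(pos) == "P":
                continue
            out.append(self.label(pos))
        return out

    def is_consistent(self, residue_label: str) -> bool:
        aa, pos = parse_residue_label(residue_label)
        if not self.start_number <= pos <= self.end_number:
            return False
        expected = self.residue_type(pos)
        return expected == "X" or expected == aa


# Backbone nuclei tracked in assigned-shift tables.
BACKBONE_NUCLEI = ("HA", "CA", "CB", "C", "N", "HN")


@dataclass
class AssignedShifts:
    """Per-residue assigned backbone chemical shifts (ppm).

    ``shifts`` maps residue label -> nucleus (HA/CA/CB/C/N/HN) -> ppm.
    """

    shifts: dict[str, dict[str, float]]
    sequence: SequenceRecord

    def __post_init__(self):
        for label, atoms in self.shifts.items():
            if not self.sequence.is_consistent(label):
                raise ValueError(
                    f"residue label {label!r} inconsistent with sequence "
                    f"({self.sequence.start_number}-{self.sequence.end_number})")
            for nuc in atoms:
                if nuc not in BACKBONE_NUCLEI:
                    raise ValueError(f"unknown nucleus {nuc!r} for {label}")

    def __len__(self) -> int:
        return sum(len(v) for v in self.shifts.values())


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: a peak list plus total concentrations."""

    peaklist: PeakList
    ligand_total: float   # molar (titrant, e.g. the SH3 domain)
    receptor_total: float  # molar (observed, labelled species)

    def __post_init__(self):
        if self.receptor_total <= 0:
            raise ValueError("receptor_total must be > 0")
        if self.ligand_total < 0:
            raise ValueError("ligand_total must be >= 0")

    @property
    def molar_ratio(self) -> float:
        return self.ligand_total / self.receptor_total


@dataclass(frozen=True)
class TitrationSeries:
    """Ordered titration points; the first must be apo (no ligand).

    The receptor concentration is required to be constant across points:
    dilution correction is deliberately out of scope, matching the
    stated sample preparation (ligand dissolved in the same buffer).
    """

    points: tuple[TitrationPoint, ...]

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))
        if not self.points:
            raise ValueError("titration series needs at least one point")
        if self.points[0].ligand_total != 0:
            raise ValueError("first titration point must be apo "
                             "(ligand_total = 0)")
        ratios = [p.molar_ratio for p in self.points]
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("molar ratios must be strictly increasing")
        p0 = self.points[0].receptor_total
        for p in self.points:
            if abs(p.receptor_total - p0) > 1e-9 * p0:
                raise ValueError("receptor_total must be constant across the "
                                 "titration (no dilution correction)")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def receptor_total(self) -> float:
        return self.points[0].receptor_total

    @property
    def ligand_totals(self) -> list[float]:
        return [p.ligand_total for p in self.points]

    @property
    def molar_ratios(self) -> list[float]:
        return [p.molar_ratio for p in self.points]


# ---------------------------------------------------------------------------
# SPARKY peak lists
# ---------------------------------------------------------------------------

_SPARKY_ASSIGNMENT = re.compile(r"^([A-Z])(\d+)[A-Za-z0-9']*-[A-Za-z0-9']+$")


def _parse_sparky_assignment(token: str) -> str | None:
    if set(token) <= {"?", "-"}:
        return None
    m = _SPARKY_ASSIGNMENT.match(token)
    if m is None or m.group(1) not in AA_CODES:
        raise ValueError(f"unparseable assignment {token!r}")
    return f"{m.group(1)}{m.group(2)}"


def read_sparky_peaklist(path, axis_order: str = "NH",
                         label: str | None = None) -> PeakList:
    """Read a SPARKY text peak list.

    Lines are ``<assignment> <w1> <w2> [height]`` with an optional header
    beginning ``Assignment``.  By default w1 is 15N and w2 is 1H, the
    usual axis order of 15N-HSQC lists exported by SPARKY; pass
    ``axis_order="HN"`` for the transposed convention.  ``"?-?"``
    assignments yield unassigned peaks.
    """
    if axis_order not in ("NH", "HN"):
        raise ValueError("axis_order must be 'NH' (w1=15N) or 'HN' (w1=1H)")
    path = Path(path)
    peaks = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("Assignment"):
            continue
        tokens = line.split()
        if len(tokens) not in (3, 4):
            raise ValueError(f"{path}:{lineno}: expected 3 or 4 columns, "
                             f"got {len(tokens)}: {line!r}")
        try:
            residue = _parse_sparky_assignment(tokens[0])
            w1, w2 = float(tokens[1]), float(tokens[2])
            height = float(tokens[3]) if len(tokens) == 4 else None
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        dN, dH = (w1, w2) if axis_order == "NH" else (w2, w1)
        peaks.append(Peak(delta_H=dH, delta_N=dN,
                          residue_label=residue, height=height))
    if not peaks:
        raise ValueError(f"{path}: no peaks")
    return PeakList(peaks=tuple(peaks), label=label or path.stem)


def write_sparky_peaklist(peaklist: PeakList, path,
                          axis_order: str = "NH") -> None:
    if axis_order not in ("NH", "HN"):
        raise ValueError("axis_order must be 'NH' or 'HN'")
    with_height = any(p.height is not None for p in peaklist)
    lines = ["Assignment w1 w2" + (" Data Height" if with_height else "")]
    for p in peaklist:
        name = f"{p.residue_label}N-HN" if p.is_assigned else "?-?"
        w1, w2 = ((p.delta_N, p.delta_H) if axis_order == "NH"
                  else (p.delta_H, p.delta_N))
        row = f"{name} {w1:.6f} {w2:.6f}"
        if with_height:
            row += f" {p.height if p.height is not None else 0.0:.8g}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV peak lists
# ---------------------------------------------------------------------------

def read_csv_peaklist(path, label: str | None = None) -> PeakList:
    """Read a CSV peak list with columns residue, delta_H, delta_N[, height]."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("residue", "delta_H", "delta_N"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    peaks = []
    for _, row in df.iterrows():
        residue = row["residue"]
        residue = None if (pd.isna(residue) or residue in ("", "?")) \
            else str(residue)
        height = None
        if "height" in df.columns and not pd.isna(row["height"]):
            height = float(row["height"])
        peaks.append(Peak(delta_H=float(row["delta_H"]),
                          delta_N=float(row["delta_N"]),
                          residue_label=residue, height=height))
    if not peaks:
        raise ValueError(f"{path}: no peaks")
    try:
        return PeakList(peaks=tuple(peaks), label=label or path.stem)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_csv_peaklist(peaklist: PeakList, path) -> None:
    df = pd.DataFrame({
        "residue": [p.residue_label or "" for p in peaklist],
        "delta_H": [p.delta_H for p in peaklist],
        "delta_N": [p.delta_N for p in peaklist],
        "height": [p.height for p in peaklist],
    })
    if df["height"].isna().all():
        df = df.drop(columns=["height"])
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# NMR-STAR chemical-shift loop (minimal v3 reader)
# ---------------------------------------------------------------------------

def read_nmrstar_shifts(path) -> AssignedShifts:
    """Read assigned shifts from the Atom_chem_shift loop of an NMR-STAR file.

    Only the columns needed here are consumed (residue index, residue
    type, atom name, shift value); atoms outside the backbone set are
    ignored and "H" is mapped to HN.  Duplicate (residue, atom) rows keep
    the first occurrence with a warning.  The sequence is inferred from
    the residues present, with 'X' filling interior gaps.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    i, n = 0, len(lines)
    tags: list[str] = []
    rows: list[list[str]] = []
    while i < n:
        if lines[i].strip() == "loop_":
            j = i + 1
            loop_tags = []
            while j < n and lines[j].strip().startswith("_"):
                loop_tags.append(lines[j].strip())
                j += 1
            if any(t.startswith("_Atom_chem_shift.") for t in loop_tags):
                tags = loop_tags
                while j < n and lines[j].strip() != "stop_":
                    data = lines[j].strip()
                    if data and not data.startswith("#"):
                        rows.append(data.split())
                    j += 1
                break
            i = j
        else:
            i += 1
    if not tags:
        raise ValueError(f"{path}: no Atom_chem_shift loop found")

    def col(*names):
        for name in names:
            tag = f"_Atom_chem_shift.{name}"
            if tag in tags:
                return tags.index(tag)
        raise ValueError(f"{path}: Atom_chem_shift loop lacks any of {names}")

    c_seq = col("Comp_index_ID", "Seq_ID")
    c_comp = col("Comp_ID")
    c_atom = col("Atom_ID")
    c_val = col("Val")

    shifts: dict[str, dict[str, float]] = {}
    residues: dict[int, str] = {}
    for row in rows:
        if len(row) < len(tags):
            raise ValueError(f"{path}: short data row {row!r}")
        pos = int(row[c_seq])
        aa3 = row[c_comp].upper()
        aa = AA3_TO_1.get(aa3, aa3 if aa3 in AA_CODES else None)
        if aa is None:
            raise ValueError(f"{path}: unknown residue type {row[c_comp]!r}")
        atom = row[c_atom].upper()
        if atom == "H":
            atom = "HN"
        if atom not in BACKBONE_NUCLEI:
            continue
        residues.setdefault(pos, aa)
        label = f"{aa}{pos}"
        atoms = shifts.setdefault(label, {})
        if atom in atoms:
            warnings.warn(f"{path}: duplicate shift for {label} {atom}; "
                          "keeping first", NmrbindWarning)
            continue
        atoms[atom] = float(row[c_val])
    if not shifts:
        raise ValueError(f"{path}: chemical-shift loop contains no usable rows")
    start, end = min(residues), max(residues)
    seq = "".join(residues.get(p, "X") for p in range(start, end + 1))
    return AssignedShifts(shifts=shifts,
                          sequence=SequenceRecord(seq, start_number=start))


# ---------------------------------------------------------------------------
# FASTA sequences
# ---------------------------------------------------------------------------

def read_fasta(path, start_number: int | None = None) -> SequenceRecord:
    """Read the first record of a FASTA file.

    A ``start=<int>`` token in the description sets the numbering offset
    unless ``start_number`` is given explicitly.
    """
    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise ValueError(f"{path}: no FASTA records")
    if start_number is None:
        m = re.search(r"start=(\d+)", record.description)
        start_number = int(m.group(1)) if m else 1
    return SequenceRecord(str(record.seq).upper(), start_number=start_number)


# ---------------------------------------------------------------------------
# Titration assembly and run configuration
# ---------------------------------------------------------------------------

def assemble_titration(peaklists, receptor_total, ratios) -> TitrationSeries:
    """Combine ordered peak lists with a molar-ratio schedule.

    ``ligand_total`` of each point is ``ratio * receptor_total``; the first
    ratio must be 0 (apo) and ratios must increase strictly.
    """
    peaklists = list(peaklists)
    ratios = [float(r) for r in ratios]
    receptor_total = parse_concentration(receptor_total)
    if len(peaklists) != len(ratios):
        raise ValueError(f"{len(peaklists)} peak lists but "
                         f"{len(ratios)} ratios")
    if not ratios or ratios[0] != 0:
        raise ValueError("first molar ratio must be 0 (apo point)")
    if any(b <= a for a, b in zip(ratios, ratios[1:])):
        raise ValueError("molar ratios must be strictly increasing")
    points = [TitrationPoint(peaklist=pl,
                             ligand_total=r * receptor_total,
                             receptor_total=receptor_total)
              for pl, r in zip(peaklists, ratios)]
    return TitrationSeries(points=tuple(points))


def load_run_config(path) -> dict:
    """Load a YAML run configuration (file names, ratios, concentrations)."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return config


def load_titration_from_config(path) -> TitrationSeries:
    """Build a TitrationSeries from a YAML config.

    Expected keys: ``peaklists`` (ordered file list, SPARKY or CSV by
    extension), ``ratios``, ``receptor_total`` (unit-tagged), optional
    ``format`` ('sparky'|'csv') and ``axis_order``.
    """
    config = load_run_config(path)
    base = Path(path).parent
    for key in ("peaklists", "ratios", "receptor_total"):
        if key not in config:
            raise ValueError(f"{path}: missing config key {key!r}")
    fmt = config.get("format")
    axis = config.get("axis_order", "NH")
    lists = []
    for name in config["peaklists"]:
        p = base / name
        use_csv = fmt == "csv" or (fmt is None and p.suffix == ".csv")
        lists.append(read_csv_peaklist(p) if use_csv
                     else read_sparky_peaklist(p, axis_order=axis))
    return assemble_titration(lists, config["receptor_total"],
                              config["ratios"])
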