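"""Text formats: XEASY and Sparky peak lists, prot shift tables, and a
minimal NMR-STAR v3 _Atom_chem_shift loop."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from .consensus import ConsensusAssignment
from .experiments import ObservedPeak, ObservedPeakList
from .sequence import ProteinSequence
from . import topology


# ---------------------------------------------------------------------------
# XEASY peak lists (confidence score appended as final column)

def write_xeasy(peaks: ObservedPeakList, path: str | Path) -> None:
    ndim = len(peaks.peaks[0].positions) if peaks.peaks else 2
    with open(path, "w") as fh:
        fh.write(f"# Number of dimensions {ndim}\n")
        for p in peaks.peaks:
            pos = "".join(f"{x:10.3f}" for x in p.positions)
            fh.write(
                f"{p.id:6d}{pos}  1 U  {p.intensity:12.4e}  0.00e+00 -   0   0"
                f"  {p.confidence:8.4f}\n"
            )


def read_xeasy(path: str | Path, spectrum: str) -> ObservedPeakList:
    lines = Path(path).read_text().splitlines()
    ndim = None
    peaks: list[ObservedPeak] = []
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "dimensions" in line.lower():
                ndim = int(line.split()[-1])
            continue
        parts = line.split()
        if ndim is None:
            raise ValueError("XEASY header '# Number of dimensions N' missing")
        pid = int(parts[0])
        pos = tuple(float(x) for x in parts[1 : 1 + ndim])
        rest = parts[1 + ndim:]
        intensity = 0.0
        for tok in rest:
            try:
                val = float(tok)
            except ValueError:
                continue
            if "e" in tok.lower():
                intensity = val
                break
        # trailing confidence column: plain decimal in [0, 1] (legacy XEASY
        # rows end in a scientific-notation intensity error instead)
        confidence = 1.0
        if rest and "e" not in rest[-1].lower():
            try:
                val = float(rest[-1])
                if 0.0 <= val <= 1.0:
                    confidence = val
            except ValueError:
                pass
        peaks.append(ObservedPeak(pid, pos, confidence, intensity))
    return ObservedPeakList(spectrum, peaks)


# ---------------------------------------------------------------------------
# Sparky list dialect

def write_sparky(peaks: ObservedPeakList, path: str | Path) -> None:
    ndim = len(peaks.peaks[0].positions) if peaks.peaks else 2
    header = " ".join(f"w{i+1}" for i in range(ndim))
    with open(path, "w") as fh:
        fh.write(f"  Assignment  {header}  Height\n")
        for p in peaks.peaks:
            label = "-".join("?" * ndim)
            pos = "".join(f"{x:10.3f}" for x in p.positions)
            fh.write(f"  {label}{pos}  {p.intensity:12.4e}\n")


def read_sparky(path: str | Path, spectrum: str) -> ObservedPeakList:
    peaks: list[ObservedPeak] = []
    next_id = 1
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.lower().startswith("assignment"):
            continue
        parts = line.split()
        if parts[0].lower() == "assignment":
            continue
        try:
            floats = [float(x) for x in parts[1:]]
        except ValueError:
            continue
        if not floats:
            continue
        *pos, height = floats if len(floats) > 1 else (floats[0], 0.0)
        peaks.append(ObservedPeak(next_id, tuple(pos), 1.0, height))
        next_id += 1
    return ObservedPeakList(spectrum, peaks)


# ---------------------------------------------------------------------------
# prot-style shift table: index, shift, sd, atom name, residue number

def write_prot(
    shifts: Mapping[tuple[int, str], float],
    path: str | Path,
    sds: Mapping[tuple[int, str], float] | None = None,
    classes: Mapping[tuple[int, str], str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, ((resnum, name), value) in enumerate(
            sorted(shifts.items(), key=lambda kv: (kv[0][0], kv[0][1])), start=1
        ):
            sd = (sds or {}).get((resnum, name), 0.0)
            line = f"{i:6d} {value:10.3f} {sd:7.3f}  {name:<6s}{resnum:5d}"
            if classes is not None:
                line += f"   # {classes.get((resnum, name), '-')}"
            fh.write(line + "\n")


def read_prot(path: str | Path) -> dict[tuple[int, str], float]:
    shifts: dict[tuple[int, str], float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 5:
            continue
        value = float(parts[1])
        name = topology.normalize_atom_name(parts[3])
        resnum = int(parts[4])
        if abs(value - 999.0) < 1e-6:  # CYANA convention for unknown
            continue
        shifts[(resnum, name)] = value
    return shifts


# ---------------------------------------------------------------------------
# minimal NMR-STAR v3 _Atom_chem_shift loop

_STAR_TAGS = [
    "_Atom_chem_shift.ID",
    "_Atom_chem_shift.Seq_ID",
    "_Atom_chem_shift.Comp_ID",
    "_Atom_chem_shift.Atom_ID",
    "_Atom_chem_shift.Atom_type",
    "_Atom_chem_shift.Val",
    "_Atom_chem_shift.Val_err",
]


def write_star(
    shifts: Mapping[tuple[int, str], float],
    path: str | Path,
    sequence: ProteinSequence | None = None,
    sds: Mapping[tuple[int, str], float] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("data_shifts\n\nsave_assigned_chemical_shifts\n")
        fh.write("   loop_\n")
        for tag in _STAR_TAGS:
            fh.write(f"      {tag}\n")
        fh.write("\n")
        for i, ((resnum, name), value) in enumerate(
            sorted(shifts.items(), key=lambda kv: (kv[0][0], kv[0][1])), start=1
        ):
            comp = sequence.residue_type(resnum) if sequence else "."
            el = topology.element_of(name)
            sd = (sds or {}).get((resnum, name), 0.0)
            fh.write(
                f"      {i:5d} {resnum:4d} {comp:<4s} {name:<6s} {el} "
                f"{value:9.3f} {sd:6.3f}\n"
            )
        fh.write("   stop_\nsave_\n")


def read_star(path: str | Path) -> dict[tuple[int, str], float]:
    """Read _Atom_chem_shift loops; only Seq_ID / Atom_ID / Val are used."""
    text = Path(path).read_text().splitlines()
    shifts: dict[tuple[int, str], float] = {}
    tags: list[str] = []
    in_loop = False
    collecting_tags = False
    for raw in text:
        line = raw.strip()
        if line == "loop_":
            in_loop, collecting_tags, tags = True, True, []
            continue
        if not in_loop:
            continue
        if line.startswith("_"):
            if collecting_tags:
                tags.append(line.split()[0])
            continue
        collecting_tags = False
        if line in ("stop_", "save_") or not line:
            if line == "stop_":
                in_loop = False
            continue
        if not any(t.startswith("_Atom_chem_shift") for t in tags):
            continue
        parts = line.split()
        if len(parts) < len(tags):
            continue
        row = dict(zip(tags, parts))
        try:
            resnum = int(row["_Atom_chem_shift.Seq_ID"])
            name = topology.normalize_atom_name(row["_Atom_chem_shift.Atom_ID"])
            value = float(row["_Atom_chem_shift.Val"])
        except (KeyError, ValueError):
            continue
        shifts[(resnum, name)] = value
    return shifts


# ---------------------------------------------------------------------------
# predicted shifts (CYANA-prot-style table shared with read_prot)

def read_predictions(path: str | Path) -> dict[tuple[int, str], float]:
    """Predicted backbone shifts in the five-column prot format."""
    return read_prot(path)


def write_consensus_table(
    assignment: ConsensusAssignment, path: str | Path
) -> None:
    """Prot-style shift table with a strong/weak class comment column."""
    shifts = {k: v.shift for k, v in assignment.atoms.items() if v.shift is not None}
    classes = {k: v.klass for k, v in assignment.atoms.items()}
    write_prot(shifts, path, classes=classes)
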