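"""Spectrum definitions, magnetization-transfer pathway templates and
observed-peak selection.

Each through-bond experiment is described by a pathway template that is
instantiated at every residue where all constituent atoms exist (prolines
and the chain's first residue drop amide-rooted peaks automatically because
they carry no HN).  Expected peaks carry an a-priori observation
probability taken from an editable per-pathway-class table: 0.95 for
one-bond/strong intra-residue transfers, 0.80 for weaker sequential or
long relay transfers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .sequence import Atom, AtomSet
from . import topology

TOLERANCE_1H = 0.03  # ppm
TOLERANCE_HEAVY = 0.4  # ppm, for 13C and 15N


def default_tolerance(nucleus: str) -> float:
    return TOLERANCE_1H if nucleus == "1H" else TOLERANCE_HEAVY


@dataclass(frozen=True)
class SpectrumDefinition:
    """An experiment type: named dimensions with tolerances."""

    name: str
    dimensions: tuple[tuple[str, str], ...]  # (nucleus, role)
    kind: str  # "through-bond" | "NOESY"
    tolerances: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 2 <= len(self.dimensions) <= 4:
            raise ValueError("spectra must have 2-4 dimensions")
        if not self.tolerances:
            object.__setattr__(
                self,
                "tolerances",
                tuple(default_tolerance(nuc) for nuc, _role in self.dimensions),
            )

    @property
    def ndim(self) -> int:
        return len(self.dimensions)


@dataclass(frozen=True)
class ExpectedPeak:
    """An expected cross peak: one atom per dimension plus observation odds."""

    spectrum: str
    atoms: tuple[Atom, ...]
    probability: float
    origin: str  # through-bond | noesy-short | noesy-medium | noesy-long

    def __post_init__(self) -> None:
        if not 0.0 < self.probability <= 1.0:
            raise ValueError("probability must be in (0, 1]")


@dataclass(frozen=True)
class ObservedPeak:
    id: int
    positions: tuple[float, ...]
    confidence: float = 1.0
    intensity: float = 0.0


@dataclass
class ObservedPeakList:
    spectrum: str
    peaks: list[ObservedPeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise ValueError("observed peak ids must be unique")

    def __len__(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# experiment roster

_DIM_HN = ("1H", "amide-H")
_DIM_N = ("15N", "amide-N")
_DIM_CALI = ("13C", "aliphatic-C")
_DIM_HALI = ("1H", "aliphatic-H")
_DIM_CO = ("13C", "carbonyl-C")
_DIM_H = ("1H", "generic-H")
_DIM_C = ("13C", "generic-C")

_DEFINITIONS: dict[str, tuple[tuple, str]] = {
    "N15HSQC": ((_DIM_HN, _DIM_N), "through-bond"),
    "C13HSQC": ((_DIM_H, _DIM_C), "through-bond"),
    "HNCA": ((_DIM_HN, _DIM_N, _DIM_CALI), "through-bond"),
    "HNCOCA": ((_DIM_HN, _DIM_N, _DIM_CALI), "through-bond"),
    "HNCO": ((_DIM_HN, _DIM_N, _DIM_CO), "through-bond"),
    "HNCACO": ((_DIM_HN, _DIM_N, _DIM_CO), "through-bond"),
    "CBCANH": ((_DIM_HN, _DIM_N, _DIM_CALI), "through-bond"),
    "CBCACONH": ((_DIM_HN, _DIM_N, _DIM_CALI), "through-bond"),
    "HBHACONH": ((_DIM_HN, _DIM_N, _DIM_HALI), "through-bond"),
    "HCCONH": ((_DIM_HN, _DIM_N, _DIM_CALI), "through-bond"),
    "HCCHTOCSY": ((_DIM_HALI, _DIM_CALI, _DIM_HALI), "through-bond"),
    "CCHTOCSY": ((_DIM_CALI, _DIM_CALI, _DIM_HALI), "through-bond"),
    "N15NOESY": ((_DIM_H, _DIM_N, _DIM_HN), "NOESY"),
    "C13NOESY": ((_DIM_H, _DIM_C, _DIM_H), "NOESY"),
}

_ALIASES = {
    "[1H,15N]-HSQC": "N15HSQC", "15NHSQC": "N15HSQC", "HSQC15N": "N15HSQC",
    "[1H,13C]-HSQC": "C13HSQC", "13CHSQC": "C13HSQC", "HSQC13C": "C13HSQC",
    "HNCOCA": "HNCOCA", "HNCACO": "HNCACO",
    "CBCACONH": "CBCACONH", "HBHACONH": "HBHACONH", "HCCONH": "HCCONH",
    "HCCH-TOCSY": "HCCHTOCSY", "CCH-TOCSY": "CCHTOCSY",
    "15N-NOESY": "N15NOESY", "13C-NOESY": "C13NOESY",
    "N15-EDITED-NOESY": "N15NOESY", "C13-EDITED-NOESY": "C13NOESY",
}

#: Default observation probabilities per pathway class (editable).
DEFAULT_PATHWAY_PROBS = {"strong": 0.95, "relay": 0.80}


def canonical_name(name: str) -> str:
    key = name.strip().upper().replace(" ", "")
    key = _ALIASES.get(key, key)
    if key not in _DEFINITIONS:
        raise KeyError(
            f"unknown spectrum type {name!r}; supported: "
            + ", ".join(sorted(_DEFINITIONS))
        )
    return key


def spectrum_definition(name: str) -> SpectrumDefinition:
    key = canonical_name(name)
    dims, kind = _DEFINITIONS[key]
    return SpectrumDefinition(key, tuple(dims), kind)


def supported_spectra() -> list[str]:
    return sorted(_DEFINITIONS)


# ---------------------------------------------------------------------------
# through-bond pathway templates

def _aliphatic_carbons(atom_set: AtomSet, number: int) -> list[Atom]:
    out = []
    for atom in atom_set.residue_atoms(number):
        if atom.nucleus == "13C" and topology.carbon_class(atom.residue_type, atom.atom_name) == "aliphatic":
            out.append(atom)
    return out


def _protons_on(atom_set: AtomSet, carbon: Atom) -> list[Atom]:
    out = []
    for atom in atom_set.residue_atoms(carbon.residue_number):
        if atom.nucleus != "1H":
            continue
        heavy = atom_set.heavy_of(atom)
        if heavy is not None and heavy.key == carbon.key:
            out.append(atom)
    return out


def _carbon_bond_distance(atom_set: AtomSet, a: Atom, b: Atom) -> int | None:
    """BFS distance between two carbons along C-C bonds within one residue."""
    if a.residue_number != b.residue_number:
        return None
    carbons = {c.key: c for c in atom_set.residue_atoms(a.residue_number) if c.nucleus == "13C"}
    adj: dict[tuple[int, str], list[tuple[int, str]]] = {k: [] for k in carbons}
    for bond in atom_set.bonds:
        u, v = tuple(bond)
        if u in carbons and v in carbons:
            adj[u].append(v)
            adj[v].append(u)
    frontier, dist, seen = [a.key], 0, {a.key}
    while frontier:
        if b.key in frontier:
            return dist
        dist += 1
        nxt = []
        for k in frontier:
            for m in adj[k]:
                if m not in seen:
                    seen.add(m)
                    nxt.append(m)
        frontier = nxt
    return None


def expected_peaks_throughbond(
    spectrum: SpectrumDefinition,
    atom_set: AtomSet,
    pathway_probs: Mapping[str, float] | None = None,
) -> list[ExpectedPeak]:
    """Instantiate a through-bond pathway template at every residue.

    A peak is emitted only when all of its constituent atoms exist in the
    atom set, which drops amide-rooted peaks for prolines and the chain's
    first residue, and CB peaks for glycines.
    """
    if spectrum.kind != "through-bond":
        raise ValueError(f"{spectrum.name} is not a through-bond experiment")
    probs = dict(DEFAULT_PATHWAY_PROBS)
    if pathway_probs:
        probs.update(pathway_probs)
    strong, relay = probs["strong"], probs["relay"]
    seq = atom_set.sequence
    name = spectrum.name
    peaks: list[ExpectedPeak] = []

    def emit(atoms: Sequence[Atom | None], p: float) -> None:
        if any(a is None for a in atoms):
            return
        peaks.append(ExpectedPeak(name, tuple(atoms), p, "through-bond"))

    for i in seq.numbers:
        hn = atom_set.get(i, "HN")
        n = atom_set.get(i, "N")
        prev = i - 1 if i - 1 in seq.numbers else None
        if name == "N15HSQC":
            emit((hn, n), strong)
        elif name == "C13HSQC":
            for atom in atom_set.residue_atoms(i):
                if atom.nucleus != "1H":
                    continue
                heavy = atom_set.heavy_of(atom)
                if heavy is not None and heavy.nucleus == "13C":
                    emit((atom, heavy), strong)
        elif name == "HNCA":
            emit((hn, n, atom_set.get(i, "CA")), strong)
            if prev is not None:
                emit((hn, n, atom_set.get(prev, "CA")), relay)
        elif name == "HNCOCA":
            if prev is not None:
                emit((hn, n, atom_set.get(prev, "CA")), strong)
        elif name == "HNCO":
            if prev is not None:
                emit((hn, n, atom_set.get(prev, "C")), strong)
        elif name == "HNCACO":
            emit((hn, n, atom_set.get(i, "C")), strong)
            if prev is not None:
                emit((hn, n, atom_set.get(prev, "C")), relay)
        elif name == "CBCANH":
            emit((hn, n, atom_set.get(i, "CA")), strong)
            emit((hn, n, atom_set.get(i, "CB")), strong)
            if prev is not None:
                emit((hn, n, atom_set.get(prev, "CA")), relay)
                emit((hn, n, atom_set.get(prev, "CB")), relay)
        elif name == "CBCACONH":
            if prev is not None:
                emit((hn, n, atom_set.get(prev, "CA")), strong)
                emit((hn, n, atom_set.get(prev, "CB")), strong)
        elif name == "HBHACONH":
            if prev is not None:
                for stem in ("HA", "HA2", "HA3", "HB", "HB2", "HB3"):
                    emit((hn, n, atom_set.get(prev, stem)), strong)
        elif name == "HCCONH":
            if prev is not None:
                ca = atom_set.get(prev, "CA")
                for carbon in _aliphatic_carbons(atom_set, prev):
                    d = _carbon_bond_distance(atom_set, ca, carbon) if ca else None
                    emit((hn, n, carbon), strong if d is not None and d <= 1 else relay)
        elif name == "HCCHTOCSY":
            carbons = _aliphatic_carbons(atom_set, i)
            hs = [(h, c) for c in carbons for h in _protons_on(atom_set, c)]
            for ha, ca in hs:
                for hb, cb in hs:
                    if ha.key == hb.key:
                        continue
                    d = _carbon_bond_distance(atom_set, ca, cb)
                    if d is None:
                        continue  # e.g. across Met's sulfur: no C-C relay
                    emit((ha, ca, hb), strong if d <= 1 else relay)
        elif name == "CCHTOCSY":
            carbons = _aliphatic_carbons(atom_set, i)
            for ca in carbons:
                for h in _protons_on(atom_set, ca):
                    for cb in carbons:
                        if cb.key == ca.key:
                            continue
                        d = _carbon_bond_distance(atom_set, ca, cb)
                        if d is None:
                            continue
                        emit((cb, ca, h), strong if d <= 1 else relay)
        else:
            raise ValueError(
                f"no through-bond template for {name}; supported: "
                + ", ".join(supported_spectra())
            )
    return peaks


# ---------------------------------------------------------------------------
# observed-peak selection

NOESY_CONFIDENCE_THRESHOLD = 0.1


def select_observed_peaks(
    peaks: ObservedPeakList,
    expected_count: int | None = None,
    kind: str | None = None,
) -> ObservedPeakList:
    """Filter a picked peak list before assignment.

    Through-bond spectra keep the ``expected_count`` highest-confidence
    peaks (ties broken by larger intensity, then smaller id); NOESY spectra
    keep every peak with confidence >= 0.1.  The relative order of retained
    peaks is preserved.
    """
    if kind is None:
        kind = spectrum_definition(peaks.spectrum).kind
    if kind == "through-bond":
        if expected_count is None:
            raise ValueError("expected_count is required for through-bond spectra")
        if expected_count < 0:
            raise ValueError("expected_count must be non-negative")
        ranked = sorted(peaks.peaks, key=lambda p: (-p.confidence, -p.intensity, p.id))
        keep = {p.id for p in ranked[:expected_count]}
        return ObservedPeakList(peaks.spectrum, [p for p in peaks.peaks if p.id in keep])
    return ObservedPeakList(
        peaks.spectrum,
        [p for p in peaks.peaks if p.confidence >= NOESY_CONFIDENCE_THRESHOLD],
    )


# ---------------------------------------------------------------------------
# spectrum library file (name -> dimensions / kind / pathway probabilities)

def write_library(path: str | Path, probs: Mapping[str, float] | None = None) -> None:
    probs = dict(DEFAULT_PATHWAY_PROBS, **(probs or {}))
    with open(path, "w") as fh:
        fh.write("# spectrum library: name  kind  dims(nucleus:role,...)\n")
        for name in supported_spectra():
            sdef = spectrum_definition(name)
            dims = ",".join(f"{nuc}:{role}" for nuc, role in sdef.dimensions)
            fh.write(f"{name}  {sdef.kind}  {dims}\n")
        for cls, p in sorted(probs.items()):
            fh.write(f"prob  {cls}  {p}\n")


def read_library(path: str | Path) -> tuple[dict[str, SpectrumDefinition], dict[str, float]]:
    defs: dict[str, SpectrumDefinition] = {}
    probs: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "prob":
            probs[parts[1]] = float(parts[2])
            continue
        name, kind, dims_str = parts[0], parts[1], parts[2]
        dims = tuple(tuple(d.split(":")) for d in dims_str.split(","))
        defs[name] = SpectrumDefinition(name, dims, kind)
    return defs, probs
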