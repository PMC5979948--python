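"""Coarse-grained lipid topologies with an explicit hydroperoxide bead.

Lipids are described by a compact structure grammar: ``"18:0-18:2:2 PE"`` is a
phosphatidylethanolamine whose first tail has 18 carbons and no double bonds
and whose second tail has 18 carbons, 2 double bonds and 2 hydroperoxide
(-OOH) groups.  A symmetric lipid can be written with a single tail token
(``"18:2 PE"``).  A small library of named species (DSPC ... ox2DHPE) covering
saturated, unsaturated, long-tailed and peroxidized PC/PE lipids is bundled.

The coarse-grained mapping follows the original MARTINI lipid scheme
(~3-4 heavy atoms per bead, 5 beads per 18-carbon tail): a charged head bead
(Q0 choline for PC, Qd ethanolamine for PE), a Qa phosphate, two Na glycerol
linkers, and apolar tail beads that are C3 where the bead houses a C=C double
bond and C1 otherwise.  Each hydroperoxide adds one polar P2 bead bonded to a
C3 bead at 0.33 nm -- shorter than the standard 0.47 nm lipid bond -- with no
angle term, so the peroxide swings freely around its host bead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "TailSpec",
    "LipidSpec",
    "BeadSpec",
    "BondTerm",
    "AngleTerm",
    "LipidTopology",
    "LipidError",
    "parse_abbreviation",
    "build_topology",
    "write_itp",
    "read_itp",
    "lipid_library",
    "write_library_itp",
    "TABLE1_SPECIES",
    "GRO_RESNAMES",
    "GRO_RESNAMES_REVERSE",
]

# Standard MARTINI lipid bond length and the shorter peroxide bond (nm).
STANDARD_BOND_NM = 0.47
PEROXIDE_BOND_NM = 0.33
BOND_FORCE = 1250.0          # kJ/mol/nm^2, all bonds
ANGLE_SATURATED = (180.0, 25.0)   # deg, kJ/mol  (triple centred on C1/linker)
ANGLE_UNSATURATED = (120.0, 45.0)  # triple centred on a C3 double-bond bead

BEAD_CHARGES = {
    "Q0": 1.0,   # choline
    "Qd": 1.0,   # ethanolamine
    "Qa": -1.0,  # phosphate
    "Na": 0.0,   # glycerol
    "C1": 0.0,   # saturated carbon triplet
    "C3": 0.0,   # carbon triplet containing a double bond
    "P2": 0.0,   # hydroperoxide
    "W": 0.0,    # water
}

CARBONS_PER_TAIL_BEADS = {18: 5, 22: 6}


class LipidError(ValueError):
    """Malformed lipid specification or unbuildable topology."""


@dataclass(frozen=True)
class TailSpec:
    """One acyl tail: carbon count, double bonds, hydroperoxide groups."""

    carbons: int
    double_bonds: int
    peroxides: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 4:
            raise LipidError(f"tail needs at least 4 carbons, got {self.carbons}")
        if self.double_bonds < 0 or self.peroxides < 0:
            raise LipidError("double bond and peroxide counts must be non-negative")
        if self.peroxides > self.double_bonds:
            # peroxidation happens at bis-allylic carbons, so each -OOH
            # requires an unsaturation site on the same tail
            raise LipidError(
                f"{self.peroxides} peroxides > {self.double_bonds} double bonds: "
                "a peroxide requires a double-bond site"
            )

    @property
    def n_beads(self) -> int:
        """Tail bead count: 5 for 18 carbons, 6 for 22; else ~3.7 C/bead."""
        try:
            return CARBONS_PER_TAIL_BEADS[self.carbons]
        except KeyError:
            return max(2, round(self.carbons / 3.7))

    def __str__(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        if self.peroxides:
            s += f":{self.peroxides}"
        return s


@dataclass(frozen=True)
class LipidSpec:
    """Parsed lipid identity: head group plus an ordered pair of tails."""

    abbreviation: str
    head: str                      # "PC" or "PE"
    tails: tuple[TailSpec, TailSpec]

    def __post_init__(self) -> None:
        if self.head not in ("PC", "PE"):
            raise LipidError(f"unsupported head group {self.head!r}")
        if len(self.tails) != 2:
            raise LipidError("a glycerophospholipid has exactly two tails")

    @property
    def oxidized(self) -> bool:
        return any(t.peroxides > 0 for t in self.tails)

    @property
    def structure(self) -> str:
        t1, t2 = self.tails
        tails = str(t1) if t1 == t2 else f"{t1}-{t2}"
        return f"{tails} {self.head}"


@dataclass(frozen=True)
class BeadSpec:
    name: str
    martini_type: str
    charge: float = 0.0

    def __post_init__(self) -> None:
        if self.martini_type not in BEAD_CHARGES:
            raise LipidError(f"unknown MARTINI bead type {self.martini_type!r}")


@dataclass(frozen=True)
class BondTerm:
    bead_i: int            # 0-based bead indices
    bead_j: int
    length: float          # nm
    force_constant: float = BOND_FORCE


@dataclass(frozen=True)
class AngleTerm:
    bead_i: int
    bead_j: int
    bead_k: int
    equilibrium: float     # degrees
    force_constant: float  # kJ/mol


@dataclass(frozen=True)
class LipidTopology:
    """Beads, bonds and angles of one coarse-grained lipid."""

    name: str
    beads: tuple[BeadSpec, ...]
    bonds: tuple[BondTerm, ...]
    angles: tuple[AngleTerm, ...]

    @property
    def net_charge(self) -> float:
        return sum(b.charge for b in self.beads)

    def bead_degree(self, i: int) -> int:
        return sum(1 for b in self.bonds if i in (b.bead_i, b.bead_j))


# --- Table of named species ------------------------------------------------

TABLE1_SPECIES: dict[str, str] = {
    "DSPC": "18:0 PC",
    "DOPC": "18:1 PC",
    "DLPC": "18:2 PC",
    "SOPC": "18:0-18:1 PC",
    "SLPC": "18:0-18:2 PC",
    "DSPE": "18:0 PE",
    "DOPE": "18:1 PE",
    "DLPE": "18:2 PE",
    "SLPE": "18:0-18:2 PE",
    "DHPE": "22:6 PE",
    "oxDLPE": "18:2:2 PE",
    "oxSLPE": "18:0-18:2:2 PE",
    "ox1DHPE": "22:6:2 PE",
    "ox2DHPE": "22:6:4 PE",
}

# GRO residue-name field is 5 characters; map longer abbreviations onto
# unique 5-char residue names (identity where the abbreviation already fits).
GRO_RESNAMES: dict[str, str] = {
    name: name if len(name) <= 5 else "" for name in TABLE1_SPECIES
}
GRO_RESNAMES.update({"oxDLPE": "OXDLP", "oxSLPE": "OXSLP",
                     "ox1DHPE": "OX1DH", "ox2DHPE": "OX2DH"})
GRO_RESNAMES_REVERSE = {v: k for k, v in GRO_RESNAMES.items()}

_TAIL_RE = re.compile(r"^(\d+):(\d+)(?::(\d+))?$")


def _parse_tail(token: str) -> TailSpec:
    m = _TAIL_RE.match(token)
    if not m:
        raise LipidError(f"malformed tail token {token!r} (expected C:D or C:D:P)")
    carbons, dbl, per = int(m.group(1)), int(m.group(2)), int(m.group(3) or 0)
    return TailSpec(carbons, dbl, per)


def parse_abbreviation(text: str) -> LipidSpec:
    """Resolve a named species or a structure string to a :class:`LipidSpec`.

    Accepts library abbreviations (``"oxSLPE"``) and structure strings
    (``"18:0-18:2:2 PE"``; en-dash accepted; a single tail token such as
    ``"18:2 PE"`` expands to two identical tails).
    """
    text = text.strip()
    if text in TABLE1_SPECIES:
        spec = _parse_structure(TABLE1_SPECIES[text], abbreviation=text)
        return spec
    if ":" not in text:
        raise LipidError(f"unknown lipid abbreviation {text!r}")
    return _parse_structure(text)


def _parse_structure(text: str, abbreviation: str | None = None) -> LipidSpec:
    norm = text.replace("–", "-").replace("—", "-").strip()
    parts = norm.split()
    if len(parts) != 2:
        raise LipidError(f"malformed lipid structure {text!r} (expected 'TAILS HEAD')")
    tail_part, head = parts
    tokens = tail_part.split("-")
    if len(tokens) == 1:
        tails = (_parse_tail(tokens[0]),) * 2
    elif len(tokens) == 2:
        tails = (_parse_tail(tokens[0]), _parse_tail(tokens[1]))
    else:
        raise LipidError(f"expected one or two tail tokens in {text!r}")
    if abbreviation is None:
        abbreviation = norm.replace(" ", "_")
    return LipidSpec(abbreviation=abbreviation, head=head, tails=tails)


# --- Topology construction -------------------------------------------------

def _tail_c3_positions(tail: TailSpec) -> list[int]:
    """0-based bead indices within the tail that house double bonds.

    Double bonds sit mid-chain (cis-unsaturation in oleoyl/linoleoyl), so C3
    beads are centred: an 18:1 tail has its single C3 at bead 3 of 5, an 18:2
    tail at beads 3 and 4, and a 22:6 tail is all-C3 (capped at bead count).
    """
    n = tail.n_beads
    k = min(tail.double_bonds, n)
    start = (n - k + 1) // 2
    return list(range(start, start + k))


def build_topology(spec: LipidSpec) -> LipidTopology:
    """Emit the coarse-grained topology for one lipid.

    Head: choline/ethanolamine bead, phosphate, two glycerol linkers.  Each
    tail: one bead per ~3.7 carbons (5 for 18 C), C3 where unsaturated else
    C1.  Each peroxide adds a P2 bead bonded to a distinct C3 bead at
    0.33 nm with no angle term; P2 hosts are filled glycerol-proximal-first.
    """
    beads: list[BeadSpec] = []
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []

    head_bead = BeadSpec("NC3", "Q0", 1.0) if spec.head == "PC" else BeadSpec("NH3", "Qd", 1.0)
    beads.append(head_bead)                      # 0
    beads.append(BeadSpec("PO4", "Qa", -1.0))    # 1
    beads.append(BeadSpec("GL1", "Na", 0.0))     # 2
    beads.append(BeadSpec("GL2", "Na", 0.0))     # 3
    bonds.append(BondTerm(0, 1, STANDARD_BOND_NM))
    bonds.append(BondTerm(1, 2, STANDARD_BOND_NM))
    bonds.append(BondTerm(2, 3, STANDARD_BOND_NM))

    for tail, suffix, linker in zip(spec.tails, "AB", (2, 3)):
        c3_set = set(_tail_c3_positions(tail))
        if tail.peroxides > len(c3_set):
            raise LipidError(
                f"tail {tail}: {tail.peroxides} peroxides but only "
                f"{len(c3_set)} double-bond beads available"
            )
        perox_hosts = set(sorted(c3_set)[: tail.peroxides])

        chain = [linker]  # bead path used for angle triples
        prev = linker
        for j in range(tail.n_beads):
            is_c3 = j in c3_set
            name = f"{'D' if is_c3 else 'C'}{j + 1}{suffix}"
            beads.append(BeadSpec(name, "C3" if is_c3 else "C1"))
            idx = len(beads) - 1
            bonds.append(BondTerm(prev, idx, STANDARD_BOND_NM))
            chain.append(idx)
            prev = idx
            if j in perox_hosts:
                beads.append(BeadSpec(f"P{j + 1}{suffix}", "P2"))
                pidx = len(beads) - 1
                # short bond, free rotation: no angle ever references P2
                bonds.append(BondTerm(idx, pidx, PEROXIDE_BOND_NM))

        for a, b, c in zip(chain, chain[1:], chain[2:]):
            eq, k = ANGLE_UNSATURATED if beads[b].martini_type == "C3" else ANGLE_SATURATED
            angles.append(AngleTerm(a, b, c, eq, k))

    topo = LipidTopology(
        name=spec.abbreviation,
        beads=tuple(beads),
        bonds=tuple(bonds),
        angles=tuple(angles),
    )
    assert abs(topo.net_charge) < 1e-12
    return topo


def lipid_library() -> dict[str, LipidTopology]:
    """Topologies for all bundled named species."""
    return {name: build_topology(parse_abbreviation(name)) for name in TABLE1_SPECIES}


# --- ITP dialect -----------------------------------------------------------

def write_itp(topology: LipidTopology) -> str:
    """Serialize one lipid as a GROMACS include-topology ([moleculetype])."""
    lines = [
        "[ moleculetype ]",
        "; molname  nrexcl",
        f"{topology.name}  1",
        "",
        "[ atoms ]",
        ";  id  type  resnr  residue  atom  cgnr  charge",
    ]
    for i, b in enumerate(topology.beads, start=1):
        lines.append(
            f"{i:5d}  {b.martini_type:<4s}  1  {topology.name:<8s}  "
            f"{b.name:<5s}  {i:4d}  {b.charge: .1f}"
        )
    lines += ["", "[ bonds ]", ";  i  j  funct  length  force"]
    for bond in topology.bonds:
        lines.append(
            f"{bond.bead_i + 1:5d}  {bond.bead_j + 1:5d}  1  "
            f"{bond.length:.2f}  {bond.force_constant:.1f}"
        )
    if topology.angles:
        lines += ["", "[ angles ]", ";  i  j  k  funct  angle  force"]
        for ang in topology.angles:
            lines.append(
                f"{ang.bead_i + 1:5d}  {ang.bead_j + 1:5d}  {ang.bead_k + 1:5d}  2  "
                f"{ang.equilibrium:.1f}  {ang.force_constant:.1f}"
            )
    return "\n".join(lines) + "\n"


def write_library_itp(topologies: dict[str, LipidTopology] | None = None) -> str:
    """One ITP file covering every species in the bundled library."""
    if topologies is None:
        topologies = lipid_library()
    return "\n".join(write_itp(t) for t in topologies.values())


def read_itp(text: str) -> LipidTopology:
    """Parse a single-moleculetype ITP written by :func:`write_itp`."""
    section = None
    name = None
    beads: list[BeadSpec] = []
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    for raw in text.splitlines():
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        fields = line.split()
        if section == "moleculetype":
            name = fields[0]
        elif section == "atoms":
            _, btype, _, _, bname, _, charge = fields[:7]
            if btype not in BEAD_CHARGES:
                raise LipidError(f"unknown bead type {btype!r} in ITP")
            beads.append(BeadSpec(bname, btype, float(charge)))
        elif section == "bonds":
            i, j, _funct, length, force = fields[:5]
            bonds.append(BondTerm(int(i) - 1, int(j) - 1, float(length), float(force)))
        elif section == "angles":
            i, j, k, _funct, eq, force = fields[:6]
            angles.append(AngleTerm(int(i) - 1, int(j) - 1, int(k) - 1,
                                    float(eq), float(force)))
    if name is None or not beads:
        raise LipidError("ITP text lacks a moleculetype/atoms section")
    return LipidTopology(name, tuple(beads), tuple(bonds), tuple(angles))
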