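"""RNA structures as coarse-grained charge models.

An :class:`RnaStructure` keeps two views of a molecule:

* the full atom set (element, residue index, position, van der Waals
  radius) — this defines the low-dielectric molecular region and the ion
  exclusion layer for the Poisson-Boltzmann solver and the Born-radius
  integrals;
* the phosphate charge model — one point charge of -1 e at each phosphorus
  position, the standard coarse-grained backbone charge model for nucleic
  acid electrostatics (partial charges are deliberately out of scope).

PDB input follows the usual conventions: first MODEL only, alternate
locations resolved by highest occupancy (first wins a tie), waters and
non-RNA heteroatoms dropped, chains concatenated in file order, and
residues renumbered 1..N so downstream per-nucleotide output is independent
of author numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .config import DEFAULT_RADII

logger = logging.getLogger("tbion")

#: Residue names accepted as standard ribonucleotides.
RNA_RESIDUES = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "RA": "A", "RC": "C", "RG": "G", "RU": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U",
    "A5": "A", "C5": "C", "G5": "G", "U5": "U",
    "A3": "A", "C3": "C", "G3": "G", "U3": "U",
}

#: Elementary charge carried by every phosphate in the charge model.
PHOSPHATE_CHARGE = -1.0


class PdbError(ValueError):
    """Raised when a PDB text cannot be turned into an RNA structure."""


@dataclass
class RnaStructure:
    """Coarse-grained RNA: atoms for geometry, phosphates for charge.

    Attributes
    ----------
    elements : list of str, one per atom.
    atom_nt : (n_atoms,) int array, 1-based nucleotide index per atom.
    atom_xyz : (n_atoms, 3) float array, Angstrom.
    atom_radius : (n_atoms,) float array, Angstrom.
    phos_nt : (n_phos,) int array, nucleotide index of each phosphate.
    phos_xyz : (n_phos, 3) float array, phosphorus positions.
    n_nucleotides : int, N.
    residue_names : list of str, one per nucleotide (single-letter code).
    """

    elements: list
    atom_nt: np.ndarray
    atom_xyz: np.ndarray
    atom_radius: np.ndarray
    phos_nt: np.ndarray
    phos_xyz: np.ndarray
    n_nucleotides: int
    residue_names: list = field(default_factory=list)

    def __post_init__(self):
        self.atom_xyz = np.asarray(self.atom_xyz, dtype=float).reshape(-1, 3)
        self.phos_xyz = np.asarray(self.phos_xyz, dtype=float).reshape(-1, 3)
        self.atom_nt = np.asarray(self.atom_nt, dtype=int)
        self.atom_radius = np.asarray(self.atom_radius, dtype=float)
        self.phos_nt = np.asarray(self.phos_nt, dtype=int)
        if self.n_nucleotides < 1:
            raise ValueError("structure must contain at least one nucleotide")
        if len(self.phos_nt) > self.n_nucleotides:
            raise ValueError("more phosphates than nucleotides")
        if not np.all(np.isfinite(self.atom_xyz)) or not np.all(np.isfinite(self.phos_xyz)):
            raise ValueError("non-finite coordinates")
        if len(self.atom_radius) and np.any(self.atom_radius <= 0):
            raise ValueError("all atomic radii must be positive")
        if not self.residue_names:
            self.residue_names = ["N"] * self.n_nucleotides

    # -- charge model -------------------------------------------------------

    @property
    def n_phosphates(self) -> int:
        return len(self.phos_nt)

    @property
    def phosphate_charges(self) -> np.ndarray:
        return np.full(self.n_phosphates, PHOSPHATE_CHARGE)

    def bounding_box(self, margin: float = 0.0):
        lo = self.atom_xyz.min(axis=0) - margin
        hi = self.atom_xyz.max(axis=0) + margin
        return lo, hi

    # -- serialization ------------------------------------------------------

    def to_pdb(self) -> str:
        """Serialize to minimal standard PDB text (one chain, ATOM records)."""
        lines = []
        serial = 0
        for k in range(len(self.elements)):
            serial += 1
            el = self.elements[k]
            nt = int(self.atom_nt[k])
            name = "P" if el == "P" else f"{el}{k % 99 + 1}"
            res = self.residue_names[nt - 1] if nt - 1 < len(self.residue_names) else "N"
            x, y, z = self.atom_xyz[k]
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{res:>3s} A{nt:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{el:>2s}"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


def _element_of(atom_name: str, element_field: str) -> str:
    el = element_field.strip().upper()
    if el:
        return el
    name = atom_name.strip()
    # strip leading digits (e.g. 1H5')
    name = name.lstrip("0123456789")
    if not name:
        return "*"
    if name[:2].upper() in ("MG", "NA", "CL"):
        return name[:2].upper()
    return name[0].upper()


def parse_pdb(text: str, radii: dict | None = None) -> RnaStructure:
    """Parse PDB-format text into an :class:`RnaStructure`.

    Only standard ribonucleotide residues (A/C/G/U and common aliases) are
    kept; everything else is skipped with a warning.  One phosphate entry is
    created per residue possessing a P atom, carrying charge -1 e at the P
    position.  Residues are renumbered 1..N in chain order.
    """
    radii = radii or DEFAULT_RADII
    records = []          # (chain, resseq, icode, resname, atomname, altloc, occ, xyz, element)
    in_model = 0
    skipped_resnames = set()
    for line in text.splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            in_model += 1
            if in_model > 1:
                break
        elif rec == "ENDMDL":
            break
        elif rec in ("ATOM  ", "HETATM"):
            resname = line[17:20].strip().upper()
            if resname not in RNA_RESIDUES:
                if resname != "HOH":
                    skipped_resnames.add(resname)
                continue
            try:
                x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
            except ValueError:
                continue
            try:
                occ = float(line[54:60])
            except (ValueError, IndexError):
                occ = 1.0
            records.append((
                line[21:22], line[22:26], line[26:27], resname,
                line[12:16], line[16:17].strip(), occ,
                (x, y, z), _element_of(line[12:16], line[76:78] if len(line) >= 78 else ""),
            ))
    if skipped_resnames:
        logger.warning("skipped non-RNA residues: %s", sorted(skipped_resnames))
    if not records:
        raise PdbError("no parseable RNA ATOM records found (empty structure)")

    # resolve altlocs: keep highest occupancy, first on tie, per (chain,res,atom)
    best = {}
    order = []
    for r in records:
        key = (r[0], r[1], r[2], r[4])
        if key not in best:
            best[key] = r
            order.append(key)
        elif r[6] > best[key][6]:
            best[key] = r
    records = [best[k] for k in order]

    # renumber residues contiguously in (chain, file) order
    elements, atom_nt, atom_xyz, atom_radius = [], [], [], []
    phos_nt, phos_xyz, residue_names = [], [], []
    res_index = {}
    for chain, resseq, icode, resname, atomname, _alt, _occ, xyz, el in records:
        rkey = (chain, resseq, icode)
        if rkey not in res_index:
            res_index[rkey] = len(res_index) + 1
            residue_names.append(RNA_RESIDUES[resname])
        nt = res_index[rkey]
        elements.append(el)
        atom_nt.append(nt)
        atom_xyz.append(xyz)
        atom_radius.append(radii.get(el, radii.get("*", 1.7)))
        if atomname.strip() == "P":
            phos_nt.append(nt)
            phos_xyz.append(xyz)

    return RnaStructure(
        elements=elements,
        atom_nt=np.array(atom_nt),
        atom_xyz=np.array(atom_xyz),
        atom_radius=np.array(atom_radius),
        phos_nt=np.array(phos_nt, dtype=int),
        phos_xyz=np.array(phos_xyz, dtype=float).reshape(-1, 3),
        n_nucleotides=len(res_index),
        residue_names=residue_names,
    )


# ---------------------------------------------------------------------------
# Idealized A-form helix fixture
# ---------------------------------------------------------------------------

#: A-form fibre-style helical parameters.
AFORM_RISE = 2.81          # Angstrom per base pair
AFORM_TWIST = 32.7         # degrees per base pair
AFORM_P_RADIUS = 9.4       # phosphate distance from the helical axis

# Coarse per-nucleotide pseudo-atom geometry (radial distance, azimuthal
# offset in degrees, axial offset, vdW radius).  Three spheres per
# nucleotide — phosphate group, ribose, base — fill the duplex interior so
# the dielectric boundary is a solid rod of roughly RNA-duplex girth.
_PSEUDO_ATOMS = (
    ("P", AFORM_P_RADIUS, 0.0, 0.0, 2.1),
    ("C", 8.0, -14.0, -1.0, 2.9),   # ribose centroid
    ("N", 3.5, -4.0, 0.0, 2.9),     # base centroid
)

#: Azimuth (degrees) of each base pair's local dyad axis relative to the
#: strand-1 phosphate; sets the groove phasing of the fixture duplex
#: (phosphate azimuth gap of 2x this value across one groove).
_DYAD_PHASE = 77.5


def generate_aform_helix(n_basepairs: int) -> RnaStructure:
    """Idealized A-form RNA duplex of ``n_basepairs`` base pairs.

    Phosphates sit on two interwound helices (rise 2.81 A/bp, twist
    32.7 deg/bp, radial distance 9.4 A); each nucleotide additionally
    carries ribose and base pseudo-atoms so the molecular volume is
    realistic.  Strand 2 is the image of strand 1 under each base pair's
    local dyad (so local geometry is independent of helix length and the
    full duplex retains an exact dyad); output is deterministic.
    """
    if n_basepairs < 1:
        raise ValueError("n_basepairs must be >= 1")
    n = int(n_basepairs)
    twist = np.deg2rad(AFORM_TWIST)
    phase2 = 2.0 * np.deg2rad(_DYAD_PHASE)

    elements, atom_nt, atom_xyz, atom_radius = [], [], [], []
    phos_nt, phos_xyz = [], []

    def emit(nt, th, z):
        for el, rad, dth, dz, vdw in _PSEUDO_ATOMS:
            a = th + np.deg2rad(dth) if nt <= n else th - np.deg2rad(dth)
            zz = z + dz if nt <= n else z - dz
            p = (rad * np.cos(a), rad * np.sin(a), zz)
            elements.append(el); atom_nt.append(nt)
            atom_xyz.append(p); atom_radius.append(vdw)
            if el == "P":
                phos_nt.append(nt); phos_xyz.append(p)

    for i in range(n):                      # strand 1, 5'->3'
        emit(i + 1, i * twist, i * AFORM_RISE)
    for i in range(n):                      # strand 2: local-dyad image
        emit(n + i + 1, i * twist + phase2, i * AFORM_RISE)

    return RnaStructure(
        elements=elements,
        atom_nt=np.array(atom_nt),
        atom_xyz=np.array(atom_xyz),
        atom_radius=np.array(atom_radius),
        phos_nt=np.array(phos_nt),
        phos_xyz=np.array(phos_xyz),
        n_nucleotides=2 * n,
        residue_names=["A"] * n + ["U"] * n,
    )


def pairwise_phosphate_distances(s: RnaStructure) -> np.ndarray:
    """Symmetric matrix of Euclidean distances between phosphates (A)."""
    if s.n_phosphates < 1:
        raise ValueError("structure has no phosphates")
    return cdist(s.phos_xyz, s.phos_xyz)
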