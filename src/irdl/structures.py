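"""Molecular data model, PDB I/O, protonation, and peptide construction.

The in-memory containers are deliberately small: an ``Atom`` with a name,
element, coordinates and a partial charge; a ``Residue``; a ``Chain``; and a
``MolecularSystem`` holding chains plus a bond graph.  Hydrogens are optional
in the model and all geometric machinery downstream operates on heavy atoms
only.

``PeptideModel`` is the generative half: it converts a peptide sequence plus
a torsion vector (phi/psi/chi/C-terminal carboxyl; omega fixed trans) into
Cartesian coordinates via natural-extension-reference-frame placement over
idealised internal coordinates, and exposes per-torsion rotation axes and
moving-atom sets so poses can be re-torsioned in Cartesian space later.
"""

from __future__ import annotations

import copy as _copy
import io
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio.PDB import PDBIO, PDBParser, StructureBuilder

from . import residues as rt
from .geometry import place_atom
from .residues import UnsupportedResidueError

PSEUDO_RESIDUES = frozenset({"HBD", "HBA", "HPH", "CAG", "RIM",
                             "CHP", "CHN"})
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

_PKA = {"ASP": 3.9, "GLU": 4.1, "HIS": 6.0, "CYS": 8.3, "TYR": 10.1,
        "LYS": 10.8, "ARG": 12.5}
_PKA_NTERM = 9.0
_PKA_CTERM = 2.0


class PDBParseError(ValueError):
    """Malformed PDB record; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class EmptySystemError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    is_backbone: bool = False
    is_hydrogen: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")
        self.element = self.element.upper()
        self.is_hydrogen = self.element == "H"
        self.is_backbone = self.name in rt.BACKBONE_NAMES


@dataclass
class Residue:
    name: str
    seq_index: int
    atoms: list[Atom] = field(default_factory=list)

    @property
    def chi_count(self) -> int:
        return rt.chi_count(self.name)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name}{self.seq_index} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def formal_charge(self) -> int:
        return getattr(self, "_formal_charge", 0)

    @formal_charge.setter
    def formal_charge(self, value: int):
        self._formal_charge = value


@dataclass
class Chain:
    label: str
    residues: list[Residue] = field(default_factory=list)


class MolecularSystem:
    """A receptor or peptide: chains of residues plus a bond graph."""

    def __init__(self, chains: list[Chain], role: str = "peptide"):
        if role not in ("receptor", "peptide"):
            raise ValueError(f"role must be receptor|peptide, got {role!r}")
        self.chains = chains
        self.role = role

    # ---- iteration & arrays -------------------------------------------------
    def residues(self):
        for ch in self.chains:
            yield from ch.residues

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues() for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coords(self) -> np.ndarray:
        ats = self.atoms()
        if not ats:
            return np.zeros((0, 3))
        return np.array([a.coords for a in ats])

    def set_coords(self, coords: np.ndarray):
        ats = self.atoms()
        if len(ats) != len(coords):
            raise ValueError("coordinate count mismatch")
        for a, c in zip(ats, coords):
            a.coords = np.asarray(c, dtype=float)

    def partial_charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms()])

    def atom_labels(self) -> list[tuple[str, int, str]]:
        """(chain label, residue seq_index, atom name) per atom."""
        out = []
        for ch in self.chains:
            for r in ch.residues:
                out.extend((ch.label, r.seq_index, a.name) for a in r.atoms)
        return out

    def copy(self) -> "MolecularSystem":
        return _copy.deepcopy(self)

    @property
    def sequence(self) -> str:
        """One-letter sequence over standard residues (pseudo residues skipped)."""
        return "".join(rt.THREE_TO_ONE[r.name] for r in self.residues()
                       if r.name in rt.STANDARD_RESIDUES)

    # ---- topology -----------------------------------------------------------
    def bond_graph(self) -> nx.Graph:
        """Template-derived bond graph over global atom indices.

        Intra-residue bonds come from the sidechain templates (each atom bonds
        its placement parent) plus backbone and ring-closure bonds;
        inter-residue bonds join consecutive residues' C and N within a chain.
        Pseudo-residues bond their own atoms in listed order.
        """
        g = nx.Graph()
        offset = 0
        for ch in self.chains:
            prev_c = None
            for r in ch.residues:
                idx = {a.name: offset + k for k, a in enumerate(r.atoms)}
                for i in idx.values():
                    g.add_node(i)
                if r.name in rt.STANDARD_RESIDUES:
                    for pair in _residue_bond_pairs(r):
                        if pair[0] in idx and pair[1] in idx:
                            g.add_edge(idx[pair[0]], idx[pair[1]])
                    if prev_c is not None and "N" in idx:
                        g.add_edge(prev_c, idx["N"])
                    prev_c = idx.get("C")
                else:
                    names = [a.name for a in r.atoms]
                    for a, b in zip(names, names[1:]):
                        g.add_edge(idx[a], idx[b])
                    prev_c = None
                offset += len(r.atoms)
        return g

    def validate(self):
        g = self.bond_graph()
        offset = 0
        for r in self.residues():
            names = [a.name for a in r.atoms]
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate atom names in {r.name}{r.seq_index}")
            if r.name in rt.STANDARD_RESIDUES and len(r.atoms) > 1:
                sub = g.subgraph(range(offset, offset + len(r.atoms)))
                if not nx.is_connected(sub):
                    raise ValueError(
                        f"disconnected bond graph in {r.name}{r.seq_index}")
            offset += len(r.atoms)


def _residue_bond_pairs(res: Residue) -> list[tuple[str, str]]:
    # CL: acid-chloride leaving group standing in for the terminal oxygen
    pairs = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT"), ("C", "CL")]
    for entry in rt.SIDECHAIN_TEMPLATES.get(res.name, []):
        pairs.append((entry[0], entry[2]))
    pairs.extend(rt.EXTRA_BONDS.get(res.name, []))
    return pairs


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def read_pdb(path, chain_policy: str = "first-monomer",
             role: str = "receptor") -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem`.

    ``chain_policy`` is ``first-monomer`` (keep only the first chain that
    contains protein or pocket pseudo-residues, mirroring monomer-A selection)
    or ``keep-all``.  Waters and non-peptide HETATM records are always
    dropped; hydrogens are kept if present.
    """
    if chain_policy not in ("first-monomer", "keep-all"):
        raise ValueError(f"unknown chain policy {chain_policy!r}")
    with open(path) as fh:
        text = fh.read()
    _scan_pdb_records(text)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("sys", io.StringIO(text))
    model = next(structure.get_models())
    chains: list[Chain] = []
    for bio_chain in model:
        residues = []
        for bio_res in bio_chain:
            hetflag, resseq, _ = bio_res.id
            resname = bio_res.get_resname().strip()
            if resname in WATER_NAMES:
                continue
            keep = resname in rt.STANDARD_RESIDUES or resname in PSEUDO_RESIDUES
            if hetflag.strip() and resname not in rt.STANDARD_RESIDUES:
                continue  # non-peptide HETATM
            if not keep:
                continue
            res = Residue(name=resname, seq_index=int(resseq))
            for bio_atom in bio_res:
                elem = (bio_atom.element or bio_atom.get_name()[0]).strip()
                res.atoms.append(Atom(name=bio_atom.get_name().strip(),
                                      element=elem,
                                      coords=np.array(bio_atom.get_coord(),
                                                      dtype=float)))
            if res.atoms:
                residues.append(res)
        if residues:
            chains.append(Chain(label=bio_chain.id.strip() or "A",
                                residues=residues))
    if not chains:
        raise EmptySystemError(f"no protein chain found in {path}")
    if chain_policy == "first-monomer":
        chains = chains[:1]
    return MolecularSystem(chains, role=role)


def _scan_pdb_records(text: str):
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(lineno, "truncated coordinate record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise PDBParseError(lineno, "unparsable coordinates") from None


def write_pdb(system: MolecularSystem, path):
    """Write a system as standard ATOM records (1-based residue numbering)."""
    if system.n_atoms == 0:
        raise EmptySystemError("cannot write an empty system")
    sb = StructureBuilder.StructureBuilder()
    sb.init_structure("sys")
    sb.init_model(0)
    for ch in system.chains:
        sb.init_chain(ch.label or "A")
        sb.init_seg("    ")
        for r in ch.residues:
            sb.init_residue(r.name, " ", int(r.seq_index), " ")
            for a in r.atoms:
                sb.init_atom(a.name, a.coords.astype(float), 0.0, 1.0, " ",
                             _pdb_atom_field(a.name), element=a.element)
    pdb_io = PDBIO()
    pdb_io.set_structure(sb.get_structure())
    pdb_io.save(str(path))


def _pdb_atom_field(name: str) -> str:
    # column-alignment: 1-letter element names start in column 14
    return f" {name}" if len(name) < 4 else name


def write_multi_model_pdb(systems: list[MolecularSystem], path):
    """Write several same-topology systems as a multi-MODEL PDB file."""
    if not systems:
        raise EmptySystemError("no systems to write")
    sb = StructureBuilder.StructureBuilder()
    sb.init_structure("poses")
    for m, system in enumerate(systems):
        sb.init_model(m)
        for ch in system.chains:
            sb.init_chain(ch.label or "A")
            sb.init_seg("    ")
            for r in ch.residues:
                sb.init_residue(r.name, " ", int(r.seq_index), " ")
                for a in r.atoms:
                    sb.init_atom(a.name, a.coords.astype(float), 0.0, 1.0,
                                 " ", _pdb_atom_field(a.name),
                                 element=a.element)
    pdb_io = PDBIO()
    pdb_io.set_structure(sb.get_structure())
    pdb_io.save(str(path))


# ---------------------------------------------------------------------------
# Protonation
# ---------------------------------------------------------------------------

def assign_protonation(system: MolecularSystem, pH: float = 7.4
                       ) -> MolecularSystem:
    """Assign formal charges and partial charges at the given pH.

    At pH 7.4: Asp/Glu sidechains -1, Lys/Arg +1, His neutral, free
    N-terminus +1, free C-terminus -1.  Partial charges start from a coarse
    per-element baseline and are shifted uniformly within each residue so the
    residue total equals its formal charge.
    """
    if not (0.0 < pH < 14.0):
        raise ValueError(f"pH must be in (0, 14), got {pH}")
    out = system.copy()
    for ch in out.chains:
        protein = [r for r in ch.residues if r.name in rt.STANDARD_RESIDUES]
        for r in ch.residues:
            if r.name in PSEUDO_RESIDUES:
                _assign_pseudo_charges(r)
                continue
            if r.name not in rt.STANDARD_RESIDUES:
                raise UnsupportedResidueError(r.name)
            q = _sidechain_charge(r.name, pH)
            if protein and r is protein[0]:
                q += 1 if pH < _PKA_NTERM else 0
            if protein and r is protein[-1] and r.has_atom("OXT"):
                q -= 1 if pH > _PKA_CTERM else 0
            r.formal_charge = q
            _assign_partial_charges(r, q)
    return out


def _sidechain_charge(resname: str, pH: float) -> int:
    pka = _PKA.get(resname)
    if pka is None:
        return 0
    if resname in ("ASP", "GLU", "CYS", "TYR"):
        return -1 if pH > pka else 0
    return 1 if pH < pka else 0


def _assign_partial_charges(res: Residue, formal: int):
    heavy = [a for a in res.atoms if not a.is_hydrogen]
    base = [rt.BASELINE_PARTIAL.get(a.element, 0.0) for a in heavy]
    shift = (formal - sum(base)) / max(len(heavy), 1)
    for a, b in zip(heavy, base):
        a.partial_charge = b + shift


def _assign_pseudo_charges(res: Residue):
    table = {"HBD": {"ND": 0.30, "CD": -0.30}, "HBA": {"OA": -0.30},
             "CHP": {"CP": 0.50}, "CHN": {"CP": -0.50}}
    for a in res.atoms:
        a.partial_charge = table.get(res.name, {}).get(a.name, 0.0)


def net_formal_charge(system: MolecularSystem) -> int:
    return sum(r.formal_charge for r in system.residues())


# ---------------------------------------------------------------------------
# Rotatable-bond counting
# ---------------------------------------------------------------------------

def count_rotatable_bonds(peptide) -> int:
    """Rotatable torsions of a free peptide by the package convention.

    phi for residues 2..n (Pro excluded), psi for residues 1..n-1, all
    sidechain chis, plus one C-terminal carboxyl rotation.  Omega amide
    torsions are excluded.  Accepts a one-letter string, a list of 3-letter
    codes, or a :class:`MolecularSystem`.
    """
    seq3 = _as_three_letter(peptide)
    if len(seq3) < 1:
        raise ValueError("empty sequence")
    n = len(seq3)
    phi = sum(1 for r in seq3[1:] if r != "PRO")
    psi = n - 1
    chi = sum(rt.chi_count(r) for r in seq3)
    return phi + psi + chi + 1


def _as_three_letter(peptide) -> list[str]:
    if isinstance(peptide, MolecularSystem):
        return [r.name for r in peptide.residues()
                if r.name in rt.STANDARD_RESIDUES]
    if isinstance(peptide, str):
        out = []
        for c in peptide:
            if c.upper() not in rt.ONE_TO_THREE:
                raise UnsupportedResidueError(c)
            out.append(rt.ONE_TO_THREE[c.upper()])
        return out
    out = []
    for r in peptide:
        if r.upper() not in rt.STANDARD_RESIDUES:
            raise UnsupportedResidueError(r)
        out.append(r.upper())
    return out


# ---------------------------------------------------------------------------
# Generative peptide model
# ---------------------------------------------------------------------------

# idealised backbone internal coordinates
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.330
_B_C_O, _B_C_OXT = 1.231, 1.250
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_CA_C_OXT = 120.5, 117.0
_PRO_PHI = -65.0


@dataclass
class TorsionVar:
    """One sampled torsion: identity, rotation axis and dependent atoms."""
    name: str          # "phi", "psi", "chi1".."chi4", "carboxyl"
    res_index: int     # 0-based residue position
    axis: tuple[int, int] = (0, 0)      # atom indices (proximal, distal)
    moving: np.ndarray = None           # atom indices rotated by this torsion
    default: float = 180.0


class PeptideModel:
    """Sequence -> coordinates generator over idealised internal coordinates.

    The torsion vector layout is, residue by residue N->C: phi (residues
    2..n, non-Pro), psi (residues 1..n-1), chis, and finally the C-terminal
    carboxyl rotation (dihedral N-CA-C-O of the last residue; OXT is placed
    anti to O).  ``coords(values)`` rebuilds all heavy-atom positions.
    """

    def __init__(self, sequence):
        self.seq3 = _as_three_letter(sequence)
        if not self.seq3:
            raise ValueError("empty sequence")
        self.sequence = "".join(rt.THREE_TO_ONE[r] for r in self.seq3)
        self._build_tables()

    # -- construction of the placement program --------------------------------
    def _build_tables(self):
        n = len(self.seq3)
        self.atom_names: list[str] = []
        self.atom_elements: list[str] = []
        self.atom_res: list[int] = []
        self.torsions: list[TorsionVar] = []
        # placement program entries:
        # (atom_idx, parent, angle_ref, dih_ref, bond, angle, kind, payload)
        # kind: "fix" (payload=deg) | "var" (payload=(var_idx, offset))
        self._program: list[tuple] = []
        index: dict[tuple[int, str], int] = {}

        def add_atom(res_i, name, element):
            k = len(self.atom_names)
            self.atom_names.append(name)
            self.atom_elements.append(element)
            self.atom_res.append(res_i)
            index[(res_i, name)] = k
            return k

        def add_var(name, res_i, default):
            self.torsions.append(TorsionVar(name, res_i, default=default))
            return len(self.torsions) - 1

        for i, resname in enumerate(self.seq3):
            ni = add_atom(i, "N", "N")
            cai = add_atom(i, "CA", "C")
            ci = add_atom(i, "C", "C")
            oi = add_atom(i, "O", "O")
            if i == 0:
                self._first = (ni, cai, ci)
            else:
                pn, pca, pc = (index[(i - 1, "N")], index[(i - 1, "CA")],
                               index[(i - 1, "C")])
                # N(i): dihedral N-C(i-1)-CA(i-1)-N(i-1) = psi(i-1)
                psi_v = add_var("psi", i - 1, 140.0)
                self._program.append((ni, pc, pca, pn, _B_C_N, _A_CA_C_N,
                                      "var", (psi_v, 0.0)))
                # CA(i): omega trans, fixed
                self._program.append((cai, ni, pc, pca, _B_N_CA, _A_C_N_CA,
                                      "fix", 180.0))
                # C(i): phi(i) (fixed for Pro)
                if resname == "PRO":
                    self._program.append((ci, cai, ni, pc, _B_CA_C,
                                          _A_N_CA_C, "fix", _PRO_PHI))
                else:
                    phi_v = add_var("phi", i, -120.0)
                    self._program.append((ci, cai, ni, pc, _B_CA_C,
                                          _A_N_CA_C, "var", (phi_v, 0.0)))
            # carbonyl / carboxyl oxygen
            if i < n - 1:
                # O anti to the peptide N of the next residue: psi(i)+180;
                # psi var is created when N(i+1) is added, so defer via name.
                self._program.append((oi, ci, cai, ni, _B_C_O, _A_CA_C_O,
                                      "defer_psi", i))
            else:
                cbx_v = add_var("carboxyl", i, 0.0)
                self._program.append((oi, ci, cai, ni, _B_C_OXT, _A_CA_C_OXT,
                                      "var", (cbx_v, 0.0)))
            # sidechain
            chi_vars: dict[int, int] = {}
            for (name, elem, parent, aref, dref, bond, angle, tau) in \
                    rt.SIDECHAIN_TEMPLATES[resname]:
                ai = add_atom(i, name, elem)
                refs = (index[(i, parent)], index[(i, aref)], index[(i, dref)])
                if tau[0] == "fix":
                    self._program.append((ai, *refs, bond, angle, "fix",
                                          tau[1]))
                else:
                    _, k, offset = tau
                    if k not in chi_vars:
                        chi_vars[k] = add_var(f"chi{k}", i, 180.0)
                    self._program.append((ai, *refs, bond, angle, "var",
                                          (chi_vars[k], offset)))
            if i == n - 1:
                oxt = add_atom(i, "OXT", "O")
                self._program.append((oxt, ci, cai, ni, _B_C_OXT,
                                      _A_CA_C_OXT, "var", (cbx_v, 180.0)))

        # resolve deferred carbonyl-oxygen placements (psi + 180)
        psi_by_res = {t.res_index: v for v, t in enumerate(self.torsions)
                      if t.name == "psi"}
        resolved = []
        for entry in self._program:
            if entry[6] == "defer_psi":
                res_i = entry[7]
                resolved.append(entry[:6] + ("var", (psi_by_res[res_i],
                                                     180.0)))
            else:
                resolved.append(entry)
        self._program = resolved
        self.n_atoms = len(self.atom_names)
        self._index = index
        self._build_bonds()
        self._build_torsion_topology()

    def _build_bonds(self):
        bonds = []
        for i, resname in enumerate(self.seq3):
            res_atoms = {(n2): k for (ri, n2), k in self._index.items()
                         if ri == i}
            for a, b in _residue_bond_pairs(Residue(resname, i + 1)):
                if a in res_atoms and b in res_atoms:
                    bonds.append((res_atoms[a], res_atoms[b]))
            if i > 0:
                bonds.append((self._index[(i - 1, "C")], self._index[(i, "N")]))
        self.bonds = bonds

    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def _build_torsion_topology(self):
        g = self.bond_graph()
        for t in self.torsions:
            i = t.res_index
            if t.name == "phi":
                axis = (self._index[(i, "N")], self._index[(i, "CA")])
            elif t.name == "psi" or t.name == "carboxyl":
                axis = (self._index[(i, "CA")], self._index[(i, "C")])
            else:  # chiK: axis from first program entry using this var
                axis = None
                for entry in self._program:
                    if entry[6] == "var" and entry[7][0] == \
                            self.torsions.index(t) and entry[7][1] == 0.0:
                        axis = (entry[2], entry[1])
                        break
                assert axis is not None
            t.axis = axis
            h = g.copy()
            h.remove_edge(*axis)
            comp = nx.node_connected_component(h, axis[1])
            t.moving = np.array(sorted(comp - {axis[1]}), dtype=int)

    # -- torsion helpers -------------------------------------------------------
    @property
    def n_torsions(self) -> int:
        return len(self.torsions)

    def default_torsions(self) -> np.ndarray:
        return np.array([t.default for t in self.torsions])

    def torsion_index(self, name: str, res_index: int) -> int:
        for v, t in enumerate(self.torsions):
            if t.name == name and t.res_index == res_index:
                return v
        raise KeyError((name, res_index))

    # -- generation ------------------------------------------------------------
    def coords(self, torsion_values: np.ndarray | None = None) -> np.ndarray:
        values = (self.default_torsions() if torsion_values is None
                  else np.asarray(torsion_values, dtype=float))
        if len(values) != self.n_torsions:
            raise ValueError("torsion vector length mismatch")
        x = np.zeros((self.n_atoms, 3))
        ni, cai, ci = self._first
        x[ni] = (0.0, 0.0, 0.0)
        x[cai] = (_B_N_CA, 0.0, 0.0)
        th = np.deg2rad(_A_N_CA_C)
        x[ci] = x[cai] + _B_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])
        for (ai, p, aref, dref, bond, angle, kind, payload) in self._program:
            tau = payload if kind == "fix" else \
                values[payload[0]] + payload[1]
            x[ai] = place_atom(x[dref], x[aref], x[p], bond, angle, tau)
        return x

    # -- conversion ------------------------------------------------------------
    def to_system(self, coords: np.ndarray | None = None,
                  chain_label: str = "P") -> MolecularSystem:
        x = self.coords() if coords is None else np.asarray(coords)
        residues = []
        for i, resname in enumerate(self.seq3):
            res = Residue(name=resname, seq_index=i + 1)
            for k in range(self.n_atoms):
                if self.atom_res[k] == i:
                    res.atoms.append(Atom(name=self.atom_names[k],
                                          element=self.atom_elements[k],
                                          coords=x[k].copy()))
            residues.append(res)
        return MolecularSystem([Chain("P", residues)], role="peptide")

    def heavy_indices(self) -> np.ndarray:
        return np.array([k for k, e in enumerate(self.atom_elements)
                         if e != "H"], dtype=int)

    def backbone_indices(self) -> np.ndarray:
        return np.array([k for k, n2 in enumerate(self.atom_names)
                         if n2 in rt.BACKBONE_NAMES], dtype=int)

    def atom_index(self, res_index: int, name: str) -> int:
        return self._index[(res_index, name)]


def build_peptide(sequence, torsions=None) -> MolecularSystem:
    """Convenience: sequence (+ optional torsion vector) -> MolecularSystem."""
    model = PeptideModel(sequence)
    return model.to_system(model.coords(torsions))


# ---------------------------------------------------------------------------
# Hydrogen-bond donors / acceptors (heavy-atom, implicit-H model)
# ---------------------------------------------------------------------------

def hbond_donors(system: MolecularSystem) -> list[tuple[int, list[int]]]:
    """(donor atom index, antecedent heavy-atom indices) pairs.

    Backbone amide N of every non-Pro residue donates; the free N-terminus
    donates; sidechain donors follow the per-type table.  The donor angle is
    later measured at the donor against its antecedents.
    """
    out = []
    offset = 0
    for ch in system.chains:
        protein = [r for r in ch.residues if r.name in rt.STANDARD_RESIDUES]
        res_offsets = {}
        o = offset
        for r in ch.residues:
            res_offsets[id(r)] = o
            o += len(r.atoms)
        for j, r in enumerate(ch.residues):
            ro = res_offsets[id(r)]
            idx = {a.name: ro + k for k, a in enumerate(r.atoms)}
            if r.name == "HBD" and "ND" in idx:
                out.append((idx["ND"], [idx["CD"]] if "CD" in idx else []))
            if r.name not in rt.STANDARD_RESIDUES:
                continue
            is_nterm = protein and r is protein[0]
            if "N" in idx and (r.name != "PRO" or is_nterm):
                ants = [idx["CA"]] if "CA" in idx else []
                if not is_nterm and j > 0:
                    prev = ch.residues[j - 1]
                    pidx = {a.name: res_offsets[id(prev)] + k
                            for k, a in enumerate(prev.atoms)}
                    if "C" in pidx:
                        ants.append(pidx["C"])
                out.append((idx["N"], ants))
            for name in rt.SIDECHAIN_DONORS.get(r.name, []):
                if name in idx:
                    ant = _donor_antecedent(r.name, name)
                    out.append((idx[name], [idx[ant]] if ant in idx else []))
        offset = o
    return out


def _donor_antecedent(resname: str, donor_name: str) -> str:
    for entry in rt.SIDECHAIN_TEMPLATES[resname]:
        if entry[0] == donor_name:
            return entry[2]
    return "CA"


def hbond_acceptors(system: MolecularSystem) -> list[int]:
    """Acceptor heavy-atom indices (backbone carbonyl O, OXT, sidechain table)."""
    out = []
    offset = 0
    for r in system.residues():
        idx = {a.name: offset + k for k, a in enumerate(r.atoms)}
        if r.name == "HBA" and "OA" in idx:
            out.append(idx["OA"])
        if r.name in rt.STANDARD_RESIDUES:
            if "O" in idx:
                out.append(idx["O"])
            if "OXT" in idx:
                out.append(idx["OXT"])
            for name in rt.SIDECHAIN_ACCEPTORS.get(r.name, []):
                if name in idx:
                    out.append(idx[name])
        offset += len(r.atoms)
    return out
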