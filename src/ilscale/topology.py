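"""Reading, scaling and writing fixed-charge force-field topologies.

The supported dialect is a documented subset of the GROMACS ``.top`` format:
``[ defaults ]``, ``[ atomtypes ]``, ``[ moleculetype ]``, ``[ atoms ]`` and
``[ molecules ]`` are parsed; every other section (bonded terms, ``#include``
blocks, ``[ system ]``, ...) is preserved verbatim as opaque passthrough text.
Output uses canonical fixed-width formatting; the round trip is semantic, not
byte-exact, except for passthrough blocks which are reproduced byte-identically.

Scaling transforms implement the two uniform force-field adjustments used to
tune ionic-liquid force fields against experiment:

* **charge scaling** — every atomic partial charge of the target molecules
  (by default the solvent ions) is multiplied by a factor ``s_q < 1`` to mimic
  polarization and charge-transfer screening;
* **vdW sigma scaling** — the Lennard-Jones collision diameter of every atom
  type used by the target molecules is multiplied by ``s_sigma`` to loosen
  (``> 1``) or tighten (``< 1``) bulk packing.

Solute molecules keep their full charges and radii unless explicitly targeted.
"""

from __future__ import annotations

import copy
import re
import warnings
from dataclasses import dataclass, field

from .errors import SharedAtomTypeError, TopologyParseError

__all__ = [
    "AtomType",
    "Atom",
    "MoleculeDef",
    "ForceFieldTopology",
    "read_topology",
    "write_topology",
    "scale_charges",
    "scale_sigma",
    "net_charge",
    "duplicate_atom_type",
    "infer_role",
]

#: Valid molecule role tags.
ROLES = ("solvent-ion", "solute", "other")

_SECTION_RE = re.compile(r"^\s*\[\s*([A-Za-z_][A-Za-z0-9_]*)\s*\]\s*(?:;.*)?$")
_PTYPES = {"A", "S", "V", "D"}

# Sections that belong to the enclosing [ moleculetype ] block.
_MOLECULE_SUBSECTIONS = {
    "atoms", "bonds", "pairs", "angles", "dihedrals", "exclusions",
    "settles", "constraints", "position_restraints", "virtual_sites2",
    "virtual_sites3", "virtual_sites4",
}


@dataclass
class AtomType:
    """A nonbonded atom type: Lennard-Jones sigma (nm) and epsilon (kJ/mol)."""

    name: str
    sigma: float
    epsilon: float
    at_num: str = ""      # columns between name and mass, preserved as-is
    mass: float = 0.0
    charge: float = 0.0
    ptype: str = "A"

    def __post_init__(self):
        if not self.sigma > 0:
            raise TopologyParseError(f"atom type {self.name!r}: sigma must be > 0")
        if self.epsilon < 0:
            raise TopologyParseError(f"atom type {self.name!r}: epsilon must be >= 0")


@dataclass
class Atom:
    """One atom row of a ``[ atoms ]`` section (charge in e, mass in amu)."""

    index: int
    type_name: str
    resnr: int
    residue: str
    name: str
    cgnr: int
    charge: float
    mass: float


@dataclass
class MoleculeDef:
    """A molecule definition with its atoms, role tag and bonded passthrough."""

    name: str
    nrexcl: int
    atoms: list[Atom] = field(default_factory=list)
    role: str = "other"
    passthrough: list[str] = field(default_factory=list)

    @property
    def net_charge(self) -> float:
        return sum(a.charge for a in self.atoms)

    @property
    def type_names(self) -> set[str]:
        return {a.type_name for a in self.atoms}


@dataclass
class ForceFieldTopology:
    """Parsed topology: atom types, molecules, and verbatim passthrough text."""

    atom_types: dict[str, AtomType] = field(default_factory=dict)
    molecules: list[MoleculeDef] = field(default_factory=list)
    combination_rule: str = "lorentz-berthelot"
    defaults_raw: str | None = None
    leading_raw: list[str] = field(default_factory=list)
    trailing_raw: list[str] = field(default_factory=list)

    def molecule(self, name: str) -> MoleculeDef:
        for mol in self.molecules:
            if mol.name == name:
                return mol
        raise KeyError(f"unknown molecule {name!r}")

    def validate(self) -> None:
        """Check cross-references and per-record invariants."""
        for mol in self.molecules:
            if mol.atoms:
                first = mol.atoms[0].index
                for off, atom in enumerate(mol.atoms):
                    if atom.index != first + off:
                        raise TopologyParseError(
                            f"molecule {mol.name!r}: atom indices not contiguous "
                            f"at atom {atom.index}"
                        )
            for atom in mol.atoms:
                if atom.type_name not in self.atom_types:
                    raise TopologyParseError(
                        f"molecule {mol.name!r}, atom {atom.index} "
                        f"({atom.name}): unresolvable atom type {atom.type_name!r}"
                    )
                if not atom.mass > 0:
                    raise TopologyParseError(
                        f"molecule {mol.name!r}, atom {atom.index}: mass must be > 0"
                    )


def infer_role(mol: MoleculeDef) -> str:
    """Default role heuristic: charged molecules are solvent ions.

    Ionic-liquid ions carry net charges near +-1 e; solutes are neutral.
    """
    return "solvent-ion" if abs(mol.net_charge) > 0.5 else "solute"


def _strip_comment(line: str) -> str:
    return line.split(";", 1)[0].strip()


def _parse_float(tok: str, lineno: int, what: str) -> float:
    try:
        return float(tok)
    except ValueError:
        raise TopologyParseError(
            f"line {lineno}: malformed numeric field {what} ({tok!r})"
        ) from None


def _parse_int(tok: str, lineno: int, what: str) -> int:
    try:
        return int(tok)
    except ValueError:
        raise TopologyParseError(
            f"line {lineno}: malformed integer field {what} ({tok!r})"
        ) from None


def _parse_atomtype(tokens: list[str], lineno: int) -> AtomType:
    # Accepted layouts (GROMACS):
    #   name [bond_type] [at.num] mass charge ptype sigma epsilon
    if len(tokens) < 6 or tokens[-3] not in _PTYPES:
        raise TopologyParseError(
            f"line {lineno}: unsupported [ atomtypes ] record ({' '.join(tokens)!r})"
        )
    return AtomType(
        name=tokens[0],
        at_num=" ".join(tokens[1:-5]),
        mass=_parse_float(tokens[-5], lineno, "mass"),
        charge=_parse_float(tokens[-4], lineno, "charge"),
        ptype=tokens[-3],
        sigma=_parse_float(tokens[-2], lineno, "sigma"),
        epsilon=_parse_float(tokens[-1], lineno, "epsilon"),
    )


def _parse_atom(tokens: list[str], lineno: int) -> Atom:
    if len(tokens) < 8:
        raise TopologyParseError(
            f"line {lineno}: [ atoms ] record needs 8 fields "
            "(nr type resnr residue atom cgnr charge mass)"
        )
    return Atom(
        index=_parse_int(tokens[0], lineno, "nr"),
        type_name=tokens[1],
        resnr=_parse_int(tokens[2], lineno, "resnr"),
        residue=tokens[3],
        name=tokens[4],
        cgnr=_parse_int(tokens[5], lineno, "cgnr"),
        charge=_parse_float(tokens[6], lineno, "charge"),
        mass=_parse_float(tokens[7], lineno, "mass"),
    )


def read_topology(text: str, roles: dict[str, str] | None = None) -> ForceFieldTopology:
    """Parse topology text into a :class:`ForceFieldTopology`.

    Parameters
    ----------
    text:
        Topology in the supported GROMACS-dialect subset.
    roles:
        Optional ``{molecule name: role}`` mapping overriding the default
        net-charge heuristic (charged -> ``solvent-ion``, neutral -> ``solute``).
    """
    top = ForceFieldTopology()
    lines = text.splitlines()

    # Split the file into (section_name, header_line_index, raw_lines) chunks.
    chunks: list[tuple[str | None, int, list[str]]] = []
    current: tuple[str | None, int, list[str]] = (None, 0, [])
    chunks.append(current)
    for i, line in enumerate(lines, start=1):
        m = _SECTION_RE.match(line)
        if m:
            current = (m.group(1).lower(), i, [line])
            chunks.append(current)
        else:
            current[2].append(line)

    current_mol: MoleculeDef | None = None
    seen_tail = False  # once [ system ]/[ molecules ] starts, all goes to trailing

    for name, header_ln, raw in chunks:
        raw_text = "\n".join(raw)
        if name is None:
            if raw_text.strip():
                top.leading_raw.append(raw_text)
            continue
        if seen_tail or name in ("system", "molecules"):
            seen_tail = True
            current_mol = None
            top.trailing_raw.append(raw_text)
            continue

        if name == "defaults":
            top.defaults_raw = raw_text
            for off, line in enumerate(raw[1:], start=header_ln + 1):
                tokens = _strip_comment(line).split()
                if tokens:
                    if len(tokens) >= 2:
                        top.combination_rule = (
                            "geometric" if tokens[1] == "3" else "lorentz-berthelot"
                        )
                    break
            current_mol = None
        elif name == "atomtypes":
            current_mol = None
            for off, line in enumerate(raw[1:], start=header_ln + 1):
                tokens = _strip_comment(line).split()
                if not tokens:
                    continue
                at = _parse_atomtype(tokens, off)
                top.atom_types[at.name] = at
        elif name == "moleculetype":
            body = [
                (off, _strip_comment(line).split())
                for off, line in enumerate(raw[1:], start=header_ln + 1)
                if _strip_comment(line)
            ]
            if not body:
                raise TopologyParseError(
                    f"line {header_ln}: empty [ moleculetype ] section"
                )
            ln, tokens = body[0]
            if len(tokens) < 2:
                raise TopologyParseError(
                    f"line {ln}: [ moleculetype ] needs 'name nrexcl'"
                )
            current_mol = MoleculeDef(
                name=tokens[0], nrexcl=_parse_int(tokens[1], ln, "nrexcl")
            )
            top.molecules.append(current_mol)
        elif name == "atoms":
            if current_mol is None:
                raise TopologyParseError(
                    f"line {header_ln}: [ atoms ] outside of [ moleculetype ]"
                )
            for off, line in enumerate(raw[1:], start=header_ln + 1):
                tokens = _strip_comment(line).split()
                if not tokens:
                    continue
                current_mol.atoms.append(_parse_atom(tokens, off))
        elif name in _MOLECULE_SUBSECTIONS and current_mol is not None:
            current_mol.passthrough.append(raw_text)
        else:
            current_mol = None
            top.trailing_raw.append(raw_text)

    for mol in top.molecules:
        if roles and mol.name in roles:
            role = roles[mol.name]
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
            mol.role = role
        else:
            mol.role = infer_role(mol)

    top.validate()
    return top


def write_topology(top: ForceFieldTopology) -> str:
    """Serialize to canonical topology text.

    Charges are written with 10 decimal places so that molecular net charges
    survive the round trip to well below 1e-6 e; a post-write check warns if
    any molecule's formatted net charge drifts beyond that.
    """
    out: list[str] = []
    out.extend(top.leading_raw)
    if top.defaults_raw is not None:
        out.append(top.defaults_raw)

    if top.atom_types:
        rows = ["[ atomtypes ]",
                "; name    at.num      mass      charge  ptype         sigma       epsilon"]
        for at in top.atom_types.values():
            extra = f" {at.at_num:>6s}" if at.at_num else "       "
            rows.append(
                f"{at.name:<10s}{extra} {at.mass:>10.5f} {at.charge:>12.10f} "
                f"{at.ptype:>3s} {at.sigma:>16.12f} {at.epsilon:>16.12f}"
            )
        out.append("\n".join(rows))

    for mol in top.molecules:
        out.append(f"[ moleculetype ]\n; name  nrexcl\n{mol.name:<10s} {mol.nrexcl}")
        rows = ["[ atoms ]",
                ";  nr  type  resnr residue  atom  cgnr        charge        mass"]
        for a in mol.atoms:
            rows.append(
                f"{a.index:>5d} {a.type_name:<8s} {a.resnr:>5d} {a.residue:<8s} "
                f"{a.name:<6s} {a.cgnr:>5d} {a.charge:>16.10f} {a.mass:>10.5f}"
            )
        out.append("\n".join(rows))
        out.extend(mol.passthrough)

    out.extend(top.trailing_raw)
    text = "\n\n".join(block.strip("\n") for block in out if block.strip()) + "\n"

    # net-charge drift check on the formatted values
    for mol in top.molecules:
        formatted = sum(float(f"{a.charge:.10f}") for a in mol.atoms)
        if abs(formatted - mol.net_charge) > 1e-6:
            warnings.warn(
                f"molecule {mol.name!r}: written net charge drifts by "
                f"{formatted - mol.net_charge:+.2e} e",
                stacklevel=2,
            )
    return text


def _check_targets(targets) -> set[str]:
    targets = set(targets)
    if not targets:
        raise ValueError(
            "empty target set; to express a no-op use a scaling factor of 1.0"
        )
    unknown = targets - set(ROLES)
    if unknown:
        raise ValueError(f"unknown role tag(s): {sorted(unknown)}")
    return targets


def scale_charges(
    top: ForceFieldTopology, s_q: float, targets=("solvent-ion",)
) -> ForceFieldTopology:
    """Multiply every atomic charge of the target molecules by ``s_q``.

    Non-target molecules (by default the solutes, which keep their full
    fitted charges) and all vdW/bonded records are untouched.
    """
    if not 0 < s_q <= 1.5:
        raise ValueError(f"charge-scaling factor {s_q} outside (0, 1.5]")
    targets = _check_targets(targets)
    new = copy.deepcopy(top)
    for mol in new.molecules:
        if mol.role in targets:
            for atom in mol.atoms:
                atom.charge *= s_q
    return new


def _types_by_target(top: ForceFieldTopology, targets: set[str]):
    target_types: set[str] = set()
    other_types: set[str] = set()
    for mol in top.molecules:
        (target_types if mol.role in targets else other_types).update(mol.type_names)
    return target_types, other_types


def scale_sigma(
    top: ForceFieldTopology, s_sigma: float, targets=("solvent-ion",)
) -> ForceFieldTopology:
    """Multiply the LJ sigma of every atom type used by target molecules.

    Epsilon, charges, masses and passthrough text are untouched.  Cross
    interactions with unscaled molecules follow from re-applying the
    combination rule to the scaled per-type sigma.

    Raises
    ------
    SharedAtomTypeError
        If an atom type is used by both a target and a non-target molecule:
        scaling it would silently alter the non-target species.  Duplicate
        the type first with :func:`duplicate_atom_type`.
    """
    if not 0.5 <= s_sigma <= 1.5:
        raise ValueError(f"sigma-scaling factor {s_sigma} outside [0.5, 1.5]")
    targets = _check_targets(targets)
    target_types, other_types = _types_by_target(top, targets)
    shared = target_types & other_types
    if shared:
        raise SharedAtomTypeError(shared)
    new = copy.deepcopy(top)
    for name in target_types:
        new.atom_types[name].sigma *= s_sigma
    return new


def duplicate_atom_type(
    top: ForceFieldTopology,
    type_name: str,
    molecule_names,
    suffix: str = "_s",
) -> ForceFieldTopology:
    """Clone atom type ``type_name`` as ``type_name + suffix`` and rebind it
    in the named molecules, so that the clone can be scaled independently."""
    if type_name not in top.atom_types:
        raise KeyError(f"unknown atom type {type_name!r}")
    new_name = type_name + suffix
    if new_name in top.atom_types:
        raise ValueError(f"atom type {new_name!r} already exists")
    new = copy.deepcopy(top)
    clone = copy.deepcopy(new.atom_types[type_name])
    clone.name = new_name
    new.atom_types[new_name] = clone
    wanted = set(molecule_names)
    for mol in new.molecules:
        if mol.name in wanted:
            for atom in mol.atoms:
                if atom.type_name == type_name:
                    atom.type_name = new_name
    return new


def net_charge(top: ForceFieldTopology, molecule_name: str) -> float:
    """Sum of atomic charges of ``molecule_name`` at full precision (e)."""
    return top.molecule(molecule_name).net_charge
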