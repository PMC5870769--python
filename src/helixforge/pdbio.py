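"""PDB coordinate-format reading and writing (fixed-column v3.3 dialect).

Only the coordinate section is interpreted: ATOM/HETATM/TER/END plus
MODEL/ENDMDL for first-model selection.  Headers and REMARK records are
ignored on read.  Writing emits 80-character lines with occupancy 1.00,
B-factor 0.00, the element column filled, a TER record after each chain
and a final END.
"""

from __future__ import annotations

from typing import TextIO

from .core import Assembly, Atom, Polymer, Residue

__all__ = ["read_pdb", "write_pdb", "read_pdb_file", "write_pdb_file"]

_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HYP", "MSE",
}
_NUCLEIC = {"DA", "DC", "DG", "DT", "A", "C", "G", "U"}


def _polymer_type(mol_codes: set[str]) -> str:
    if mol_codes & _NUCLEIC and not (mol_codes & _AMINO3):
        return "nucleic"
    return "protein"


def read_pdb(text: str | TextIO) -> Assembly:
    """Parse PDB text into an :class:`Assembly`.

    One polymer per chain id, residues and atoms in file order.  Only the
    first model of a multi-MODEL file is read; altloc characters other than
    blank or "A" are dropped.  Raises ``ValueError`` if no ATOM/HETATM
    record is found or a coordinate field fails to parse (with the line
    number).
    """
    if hasattr(text, "read"):
        text = text.read()
    chains: dict[str, list] = {}
    order: list[str] = []
    in_model = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model += 1
            if in_model > 1:
                break
            continue
        if rec == "ENDMDL":
            break
        if rec not in ("ATOM", "HETATM"):
            continue
        altloc = line[16:17]
        if altloc not in (" ", "", "A"):
            continue
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = 0
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21:22]
        res_seq = line[22:27].strip()  # residue number + insertion code
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise ValueError(
                f"line {lineno}: unparseable coordinate field: {line!r}"
            ) from exc
        element = line[76:78].strip() or name[0]
        if chain_id not in chains:
            chains[chain_id] = []
            order.append(chain_id)
        chains[chain_id].append((res_seq, res_name, name, element,
                                 (x, y, z), serial))
    if not chains:
        raise ValueError("no ATOM or HETATM records found")

    assembly = Assembly()
    for chain_id in order:
        records = chains[chain_id]
        mol_codes = {r[1] for r in records}
        polymer = Polymer(id=chain_id, polymer_type=_polymer_type(mol_codes))
        current_key = None
        residue = None
        for res_seq, res_name, name, element, xyz, serial in records:
            key = (res_seq, res_name)
            if key != current_key:
                residue = Residue(res_name, insertion_id=res_seq)
                polymer.add_residue(residue)
                current_key = key
            if name in residue.atoms:  # duplicate label (e.g. stray altloc)
                continue
            residue.add_atom(Atom(name, xyz, element=element, serial=serial))
        assembly.add_polymer(polymer)
    return assembly


def _atom_name_field(name: str, element: str) -> str:
    # Element-aligned justification: 1-2 char elements start in column 13/14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"


def write_pdb(assembly: Assembly) -> str:
    """Serialize an assembly to fixed-column PDB text.

    Raises ``ValueError`` when any coordinate magnitude is >= 10000 Å
    (it would overflow the 8-character coordinate field).
    """
    lines: list[str] = []
    serial = 0
    for chain in assembly:
        last_res = None
        for res in chain:
            for atom in res:
                serial += 1
                x, y, z = atom.coords
                if max(abs(x), abs(y), abs(z)) >= 10000.0:
                    raise ValueError(
                        f"coordinate magnitude >= 10000 Å in atom "
                        f"{atom.label} of residue {res.mol_code} "
                        f"{res.insertion_id}: cannot format")
                try:
                    res_num = int(res.insertion_id)
                    icode = " "
                except ValueError:
                    res_num = int(res.insertion_id[:-1])
                    icode = res.insertion_id[-1]
                line = (
                    f"ATOM  {serial:5d} {_atom_name_field(atom.label, atom.element)}"
                    f" {res.mol_code:>3s} {chain.id}{res_num:4d}{icode}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}  "
                )
                lines.append(line[:80].ljust(80))
            last_res = res
        if last_res is not None:
            serial += 1
            try:
                res_num = int(last_res.insertion_id)
                icode = " "
            except ValueError:
                res_num = int(last_res.insertion_id[:-1])
                icode = last_res.insertion_id[-1]
            ter = (f"TER   {serial:5d}      {last_res.mol_code:>3s} "
                   f"{chain.id}{res_num:4d}{icode}")
            lines.append(ter.ljust(80))
    lines.append("END".ljust(80))
    return "\n".join(lines) + "\n"


def read_pdb_file(path) -> Assembly:
    with open(path) as fh:
        return read_pdb(fh)


def write_pdb_file(assembly: Assembly, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_pdb(assembly))
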