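"""Structure I/O and molecule screening.

Reads SMILES, MOL (V2000) and multi-record SDF input into
:class:`~glycoextract.graph.MolecularGraph` objects, screens out molecules
the algorithm cannot handle (currently: radicals), and writes extracted
fragments back to the standard formats with canonical atom ordering.

Reading follows a batch contract: an unparsable record is collected as a
record-level error and never aborts the remaining records.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import rdmolops
from rdkit.Geometry import Point3D

from .graph import MolecularGraph

FORMATS = ("smiles", "mol", "sdf")


@dataclass
class RecordError:
    record_id: str
    message: str


@dataclass
class ParsedRecord:
    record_id: str
    graph: MolecularGraph


@dataclass
class ReadResult:
    records: list[ParsedRecord] = field(default_factory=list)
    errors: list[RecordError] = field(default_factory=list)


@dataclass(frozen=True)
class ScreeningResult:
    accepted: bool
    reasons: tuple[str, ...] = ()


def _as_text(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    text = str(source)
    if "\n" not in text:
        try:
            p = Path(text)
            if p.is_file():
                return p.read_text()
        except OSError:
            pass
    return text


def read_structures(source: str | Path, fmt: str = "smiles") -> ReadResult:
    """Parse one or more structures from a path or raw text.

    Returns one :class:`ParsedRecord` per successfully parsed record plus a
    list of per-record errors.  Record ids come from the SDF title line (or
    the text after the SMILES on a line) when present, else the 1-based
    record index.
    """
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    text = _as_text(source)
    result = ReadResult()
    if fmt == "smiles":
        lineno = 0
        for raw in text.splitlines():
            line = raw.strip()
            if not line:
                continue
            lineno += 1
            parts = line.split(None, 1)
            smi = parts[0]
            rid = parts[1].strip() if len(parts) > 1 else str(lineno)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                result.errors.append(RecordError(rid, f"unparsable SMILES: {smi!r}"))
            else:
                result.records.append(ParsedRecord(rid, MolecularGraph(mol)))
    elif fmt == "mol":
        if not text.strip():
            return result
        mol = Chem.MolFromMolBlock(text, removeHs=True)
        if mol is None:
            result.errors.append(RecordError("1", "unparsable MOL block"))
        else:
            rid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            result.records.append(ParsedRecord(rid or "1", MolecularGraph(mol)))
    else:  # sdf
        if not text.strip():
            return result
        supplier = Chem.ForwardSDMolSupplier(
            io.BytesIO(text.encode()), removeHs=True, sanitize=True
        )
        for i, mol in enumerate(supplier, start=1):
            if mol is None:
                result.errors.append(RecordError(str(i), "unparsable SDF record"))
                continue
            rid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            result.records.append(ParsedRecord(rid or str(i), MolecularGraph(mol)))
    return result


def screen(graph: MolecularGraph) -> ScreeningResult:
    """Reject molecules the extraction algorithm cannot process.

    Only free radicals are screened out here: exotic elements are handled
    later at the modification level (a modification containing a non-organic
    atom is classified non-glycan), and disconnected counter-ions simply
    yield no backbone.  Screening is idempotent and order-independent.
    """
    reasons: list[str] = []
    if graph.num_heavy_atoms() == 0:
        reasons.append("empty")
    if any(a.GetNumRadicalElectrons() > 0 for a in graph.rdmol.GetAtoms()):
        reasons.append("radical")
    return ScreeningResult(accepted=not reasons, reasons=tuple(reasons))


def _zero_conformer(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    mol.RemoveAllConformers()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(i, Point3D(0.0, 0.0, 0.0))
    mol.AddConformer(conf)
    return mol


def _fragment_mol(frag) -> Chem.Mol:
    # accept a GlycanFragment, a MolecularGraph or a plain RDKit mol
    if hasattr(frag, "graph"):
        return frag.graph.rdmol
    if hasattr(frag, "rdmol"):
        return frag.rdmol
    return frag


def write_fragment(frag, fmt: str = "smiles") -> str:
    """Serialize a fragment canonically.

    The same fragment always yields a byte-identical string regardless of
    the atom order it was assembled in.  MOL/SDF output carries all-zero
    coordinates (the algorithm is purely topological).
    """
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    mol = _fragment_mol(frag)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("cannot write an empty fragment")
    # renumber into canonical order so MOL output is order-independent too
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    order = [i for i, _ in sorted(enumerate(ranks), key=lambda t: t[1])]
    canon = rdmolops.RenumberAtoms(mol, order)
    if fmt == "smiles":
        return Chem.MolToSmiles(canon)
    block = Chem.MolToMolBlock(_zero_conformer(canon), kekulize=True)
    if fmt == "sdf":
        return block + "$$$$\n"
    return block
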