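"""Reading and writing protein structures as per-chain Cα records.

Structure entries are decomposed into their constituent polypeptide
chains.  Each chain carries two sequences: the *deposited* sequence (the
full sequence of the protein as recorded by the depositor — in a FASTA
record or SEQRES) and the *resolved* sequence (residues that actually
have coordinates).  Size-based filtering operates on the deposited
sequence: a chain's "size" is the length of the complete protein, not
its structural coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Map one-letter code -> PDB three-letter residue name, for writing.
AA_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed or holds no usable chain."""


@dataclass
class ChainRecord:
    """One protein chain: identifiers, sequences and resolved Cα coordinates.

    Attributes
    ----------
    entry_id : str
        Structure accession, lower-case canonical (e.g. ``"1p3m"``).
    chain_id : str
        Author chain identifier (e.g. ``"A"``).
    deposited_seq : str
        One-letter amino-acid string of the complete deposited sequence.
    resolved_seq : str
        One-letter string of residues that have Cα coordinates.
    ca_coords : numpy.ndarray
        ``(n, 3)`` float array of Cα positions in Å, one row per resolved
        residue, in chain order.
    author_numbers : list of str
        Author residue numbers (with insertion codes) per resolved residue.
    """

    entry_id: str
    chain_id: str
    deposited_seq: str
    resolved_seq: str
    ca_coords: np.ndarray
    author_numbers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        if not self.author_numbers:
            self.author_numbers = [str(i + 1) for i in range(len(self.resolved_seq))]
        if not (len(self.resolved_seq) == len(self.ca_coords) == len(self.author_numbers)):
            raise ValueError(
                f"{self.key}: resolved_seq ({len(self.resolved_seq)}), ca_coords "
                f"({len(self.ca_coords)}) and author_numbers ({len(self.author_numbers)}) "
                "must have equal length"
            )
        if not self.deposited_seq:
            self.deposited_seq = self.resolved_seq

    @property
    def key(self) -> str:
        """Canonical ``entry_chain`` identifier, e.g. ``"1p3m_A"``."""
        return f"{self.entry_id}_{self.chain_id}"

    @property
    def n_resolved(self) -> int:
        return len(self.resolved_seq)

    def with_coords(self, coords: np.ndarray) -> "ChainRecord":
        """Copy of this record with replacement coordinates."""
        return ChainRecord(
            self.entry_id, self.chain_id, self.deposited_seq,
            self.resolved_seq, np.asarray(coords, dtype=float),
            list(self.author_numbers),
        )


def _one_letter(resname: str) -> str:
    """Map a residue name to its parent one-letter code; unknown -> 'X'."""
    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.strip() and code.isalpha() else "X"


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read deposited sequences keyed by ``entry_chain``.

    Accepts headers of the form ``ENTRYID_CHAIN`` as well as RCSB-style
    headers (``XXXX_1|Chains A, B|description``), in which case every
    listed chain is keyed separately.  Entry ids are lower-cased; chain
    ids keep their case.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        parts = rec.description.split("|")
        token = parts[0].strip()
        if len(parts) >= 2 and parts[1].strip().lower().startswith("chain"):
            entry = token.split("_")[0].lower()
            chain_field = parts[1].split(None, 1)[1] if " " in parts[1].strip() else ""
            for ch in chain_field.replace(",", " ").split():
                ch = ch.strip().split("[")[0]  # strip auth-id annotations
                if ch:
                    out[f"{entry}_{ch}"] = seq
        elif "_" in token:
            entry, ch = token.rsplit("_", 1)
            out[f"{entry.lower()}_{ch}"] = seq
        else:
            out[token.lower()] = seq
    return out


def read_chains(
    path: str | Path,
    fasta: str | Path | Mapping[str, str] | None = None,
) -> list[ChainRecord]:
    """Split a structure file into per-chain Cα records.

    Parameters
    ----------
    path : path
        PDB-format structure file (mmCIF also accepted by the parser).
    fasta : path or mapping, optional
        Deposited sequences keyed by ``entry_chain``.  When given, the
        deposited sequence of each chain is taken from here; otherwise
        SEQRES records are used, and failing that the resolved sequence.

    Returns
    -------
    list of ChainRecord
        One record per distinct polypeptide chain, in file order.  Only
        the first alternate location per atom is used; nonstandard
        residues with known parents are mapped to the parent one-letter
        code and unknowns become ``'X'``.  Only the first model of
        multi-model files is read.  Chains without Cα atoms and
        non-protein chains are skipped with a warning.

    Raises
    ------
    StructureParseError
        If the file cannot be parsed or contains no usable chain.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    entry_id = path.stem.split(".")[0].lower()

    seq_map: Mapping[str, str] | None
    if fasta is None:
        seq_map = None
    elif isinstance(fasta, (str, Path)):
        seq_map = read_fasta_sequences(fasta)
    else:
        seq_map = fasta

    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    model = st[0]

    records: list[ChainRecord] = []
    for chain in model:
        polymer = chain.get_polymer()
        if len(polymer) == 0:
            logger.warning("%s chain %s: no polymer residues, skipped", entry_id, chain.name)
            continue
        ptype = polymer.check_polymer_type()
        if ptype not in (
            gemmi.PolymerType.PeptideL,
            gemmi.PolymerType.PeptideD,
            gemmi.PolymerType.Unknown,
        ):
            logger.warning(
                "%s chain %s: not a protein chain (%s), skipped", entry_id, chain.name, ptype
            )
            continue
        resolved: list[str] = []
        coords: list[tuple[float, float, float]] = []
        numbers: list[str] = []
        for res in polymer:
            ca = res.find_atom("CA", "*")  # '*' -> first altloc present
            if ca is None or ca.element != gemmi.Element("C"):
                continue
            resolved.append(_one_letter(res.name))
            coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
            icode = res.seqid.icode.strip() if res.seqid.icode else ""
            numbers.append(f"{res.seqid.num}{icode}")
        if not coords:
            logger.warning("%s chain %s: no Cα atoms, skipped", entry_id, chain.name)
            continue

        key = f"{entry_id}_{chain.name}"
        deposited = ""
        if seq_map is not None and key in seq_map:
            deposited = seq_map[key]
        else:
            ent = st.get_entity_of(polymer)
            if ent is not None and ent.full_sequence:
                deposited = "".join(
                    _one_letter(gemmi.Entity.first_mon(m)) for m in ent.full_sequence
                )
        records.append(
            ChainRecord(
                entry_id=entry_id,
                chain_id=chain.name,
                deposited_seq=deposited,
                resolved_seq="".join(resolved),
                ca_coords=np.asarray(coords, dtype=float),
                author_numbers=numbers,
            )
        )
    if not records:
        raise StructureParseError(f"{path}: no usable polypeptide chains")
    return records


def chain_size(chain: ChainRecord) -> int:
    """Amino-acid count of the chain's complete deposited sequence.

    This is the number of residues in the deposited sequence record, not
    the number of residues with structural data; the inclusion filter
    operates on this value.
    """
    return len(chain.deposited_seq)


def filter_chains(chains: Sequence[ChainRecord], min_len: int = 50) -> list[ChainRecord]:
    """Keep chains whose deposited size is ``min_len`` or more, in order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [c for c in chains if chain_size(c) >= min_len]


def _validate_rotation(rotation: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(r.T @ r, np.eye(3), atol=tol) or abs(np.linalg.det(r) - 1.0) > tol:
        raise ValueError("rotation must be orthonormal with determinant +1")
    return r


def _next_chain_id(taken: set[str]) -> str:
    for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789":
        if c not in taken:
            return c
    raise ValueError("no free chain identifier")


def _to_gemmi(chains: Iterable[tuple[ChainRecord, str]], name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model(1)
    for rec, cid in chains:
        ch = gemmi.Chain(cid)
        for i, (aa, xyz) in enumerate(zip(rec.resolved_seq, rec.ca_coords)):
            res = gemmi.Residue()
            res.name = AA_THREE.get(aa, "UNK")
            num = rec.author_numbers[i]
            icode = " "
            if num and not num[-1].isdigit():
                icode = num[-1]
                num = num[:-1]
            try:
                seqnum = int(num)
            except ValueError:
                seqnum = i + 1
            res.seqid = gemmi.SeqId(seqnum, icode)
            at = gemmi.Atom()
            at.name = "CA"
            at.element = gemmi.Element("C")
            at.occ = 1.0
            at.b_iso = 20.0
            at.pos = gemmi.Position(*xyz)
            res.add_atom(at)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_chain_pdb(chain: ChainRecord, path: str | Path) -> None:
    """Write a single chain as a Cα-only PDB file."""
    st = _to_gemmi([(chain, chain.chain_id or "A")], chain.key)
    st.write_pdb(str(path))


def write_superposition(
    fixed: ChainRecord,
    moving: ChainRecord,
    transform,
    path: str | Path,
) -> None:
    """Write fixed and rigidly transformed moving chains to one PDB file.

    The fixed chain is written unchanged; the moving chain's coordinates
    are replaced by ``rotation @ x + translation``.  The two chains get
    distinct chain identifiers in the output.

    Parameters
    ----------
    transform : Superposition or (rotation, translation)
        A proper rotation (3×3, det +1) plus translation vector that
        maps the moving chain onto the fixed one.
    """
    if hasattr(transform, "rotation"):
        rotation, translation = transform.rotation, transform.translation
    else:
        rotation, translation = transform
    r = _validate_rotation(rotation)
    t = np.asarray(translation, dtype=float).reshape(3)

    moved = moving.with_coords(moving.ca_coords @ r.T + t)
    fixed_id = fixed.chain_id or "A"
    moving_id = moving.chain_id or "B"
    if moving_id == fixed_id:
        moving_id = _next_chain_id({fixed_id})
    st = _to_gemmi([(fixed, fixed_id), (moved, moving_id)], f"{fixed.key}_on_{moving.key}")
    st.write_pdb(str(path))
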