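"""Drug structure representations: molecular graph, MACCS keys, token sequence.

Each drug enters the classifier through three complementary views of its
SMILES string:

* an undirected heavy-atom graph (nodes carry element, chirality tag,
  formal charge, aromaticity and degree; edges carry bond type and bond
  direction) consumed by the graph isomorphism network;
* the 167-bit MACCS substructure fingerprint (166 catalogued keys plus the
  unused padding bit 0, as emitted by RDKit);
* the written SMILES itself as a token sequence for the Transformer
  encoder, where multi-character units (two-letter elements such as ``Cl``,
  bracket atoms such as ``[C@@H]``, ``%nn`` ring closures) are single tokens.

SMILES are canonicalised before graph construction and fingerprinting so
that different spellings of one molecule give identical features; the token
sequence deliberately encodes the string as written, since that channel is
meant to capture the sequence itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

RDLogger.DisableLog("rdApp.*")  # RDKit parse warnings handled via exceptions

__all__ = [
    "MolecularGraph", "Vocabulary", "TokenSequence", "SmilesParseError",
    "smiles_to_graph", "compute_maccs", "build_vocabulary", "tokenize",
    "detokenize", "canonical_smiles",
]

MACCS_LENGTH = 167

# Stable small catalogue of elements for node features; anything else maps
# to the final "other" slot.
_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se"]
_ELEMENT_INDEX = {sym: i for i, sym in enumerate(_ELEMENTS)}
N_ELEMENT_TYPES = len(_ELEMENTS) + 1
N_CHIRALITY_TAGS = 4   # unspecified, CW, CCW, other
N_BOND_TYPES = 5       # single, double, triple, aromatic, other
N_BOND_DIRS = 3        # none, endupright (/), enddownright (\)


class SmilesParseError(ValueError):
    """Raised when a SMILES string is not a valid molecule."""


def _parse(smiles: str) -> Chem.Mol:
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """RDKit canonical form; two spellings of one molecule map to one string."""
    return Chem.MolToSmiles(_parse(smiles))


# ----------------------------------------------------------------------
# molecular graph
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MolecularGraph:
    """Undirected heavy-atom graph of one molecule.

    ``atoms[i] = (element_id, chirality_id, formal_charge, aromatic, degree)``
    and ``bonds[k] = (i, j, bond_type_id, bond_dir_id)`` with ``i < j``;
    hydrogens are implicit, never nodes.
    """

    atoms: tuple[tuple[int, int, int, int, int], ...]
    bonds: tuple[tuple[int, int, int, int], ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


_CHIRAL_IDS = {
    Chem.ChiralType.CHI_UNSPECIFIED: 0,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: 1,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: 2,
}
_BOND_TYPE_IDS = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}
_BOND_DIR_IDS = {
    Chem.BondDir.NONE: 0,
    Chem.BondDir.ENDUPRIGHT: 1,
    Chem.BondDir.ENDDOWNRIGHT: 2,
}


def smiles_to_graph(smiles: str, canonicalize: bool = True) -> MolecularGraph:
    """Convert a SMILES string to its annotated heavy-atom graph.

    Parameters
    ----------
    smiles
        Any valid SMILES; invalid input raises :class:`SmilesParseError`
        naming the offending string.
    canonicalize
        Re-spell through the canonical form first (default) so graphs of
        the same molecule are identical regardless of atom ordering in the
        input string.
    """
    mol = _parse(smiles)
    if canonicalize:
        mol = _parse(Chem.MolToSmiles(mol))
    atoms = []
    for atom in mol.GetAtoms():
        atoms.append((
            _ELEMENT_INDEX.get(atom.GetSymbol(), len(_ELEMENTS)),
            _CHIRAL_IDS.get(atom.GetChiralTag(), 3),
            atom.GetFormalCharge(),
            int(atom.GetIsAromatic()),
            atom.GetDegree(),
        ))
    bonds = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        bonds.append((
            i, j,
            _BOND_TYPE_IDS.get(bond.GetBondType(), 4),
            _BOND_DIR_IDS.get(bond.GetBondDir(), 0),
        ))
    return MolecularGraph(atoms=tuple(atoms), bonds=tuple(sorted(bonds)))


# ----------------------------------------------------------------------
# MACCS fingerprint
# ----------------------------------------------------------------------

def compute_maccs(smiles: str) -> np.ndarray:
    """167-bit binary MACCS key vector (bit 0 is RDKit's unused padding bit)."""
    mol = _parse(smiles)
    fp = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(MACCS_LENGTH, dtype=np.int8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


# ----------------------------------------------------------------------
# SMILES tokenizer + vocabulary
# ----------------------------------------------------------------------

# Standard SMILES token grammar: bracket atoms, two-letter elements,
# %nn ring closures, then single characters.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|@@|%\d{2}|[BCNOPSFIbcnops]|[0-9]|[=#\-\+\\/\(\)\.~:@\*\$])"
)

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
PAD_ID = 0
UNK_ID = 1


def split_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into grammar tokens; lossless concatenation."""
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise SmilesParseError(f"cannot tokenize SMILES: {smiles!r}")
    return tokens


@dataclass
class Vocabulary:
    """Token-to-id mapping with reserved PAD (0) and UNK (1) entries."""

    token_to_id: dict[str, int]
    max_len: int = 128

    @classmethod
    def from_tokens(cls, tokens: set[str], max_len: int) -> "Vocabulary":
        mapping = {PAD_TOKEN: PAD_ID, UNK_TOKEN: UNK_ID}
        for tok in sorted(tokens):
            mapping[tok] = len(mapping)
        return cls(token_to_id=mapping, max_len=max_len)

    def __len__(self) -> int:
        return len(self.token_to_id)

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    @property
    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    # TSV serialisation: header line records max_len
    def save(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"#max_len\t{self.max_len}\n")
            for tok, i in sorted(self.token_to_id.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{i}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        token_to_id: dict[str, int] = {}
        max_len = 128
        with Path(path).open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                key, val = line.split("\t")
                if key == "#max_len":
                    max_len = int(val)
                else:
                    token_to_id[key] = int(val)
        return cls(token_to_id=token_to_id, max_len=max_len)


@dataclass(frozen=True)
class TokenSequence:
    """Padded/truncated token-id sequence plus its validity mask."""

    ids: tuple[int, ...]
    mask: tuple[int, ...]

    def __post_init__(self):
        assert len(self.ids) == len(self.mask)

    @property
    def n_real(self) -> int:
        return int(sum(self.mask))


def build_vocabulary(corpus: list[str], max_len: int = 128) -> Vocabulary:
    """Collect every token occurring in ``corpus`` into a vocabulary.

    Tokens are inserted in sorted order so the mapping is deterministic
    regardless of corpus ordering.
    """
    if not corpus:
        raise ValueError("vocabulary corpus must be non-empty")
    tokens: set[str] = set()
    for smi in corpus:
        tokens.update(split_smiles(smi))
    return Vocabulary.from_tokens(tokens, max_len=max_len)


def tokenize(smiles: str, vocab: Vocabulary) -> TokenSequence:
    """Encode a SMILES string to a fixed-length id sequence.

    Out-of-vocabulary tokens become UNK; sequences longer than
    ``vocab.max_len`` are truncated from the right, shorter ones padded.
    """
    toks = split_smiles(smiles)[: vocab.max_len]
    ids = [vocab.id_of(t) for t in toks]
    n_pad = vocab.max_len - len(ids)
    return TokenSequence(
        ids=tuple(ids + [PAD_ID] * n_pad),
        mask=tuple([1] * len(ids) + [0] * n_pad),
    )


def detokenize(seq: TokenSequence, vocab: Vocabulary) -> str:
    """Inverse of :func:`tokenize` for in-vocabulary, untruncated input."""
    rev = vocab.id_to_token
    return "".join(rev[i] for i, m in zip(seq.ids, seq.mask) if m)
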