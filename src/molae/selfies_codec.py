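"""A restricted SELFIES-style codec for organic-subset molecules.

SELFIES strings are sequences of bracketed tokens interpreted as derivation
rules rather than literal graph elements: each atom token carries a
requested bond order, and the order actually formed is capped by the
remaining valence of the attachment atom, so *every* token sequence decodes
to a chemically valid molecule. Branches and rings are encoded as a control
token followed by index tokens giving the payload length / ring-closure
distance; because every alphabet token doubles as an index digit, the
robustness guarantee survives arbitrary token shuffling.

This module implements that derivation scheme for a neutral organic subset
(C, N, O, F, S, P; single/double/triple bonds; branches; rings), together
with a graph encoder that emits a SELFIES string for any RDKit molecule
within the subset. The dialect is self-consistent (decode ∘ encode preserves
the molecule) but is not token-compatible with other SELFIES software.
"""

from __future__ import annotations

from rdkit import Chem

from .chemio import _mol_from_smiles, tokenize_selfies

# Valence caps for the supported neutral atoms.
_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "P": 3}

_BOND_ORDER = {"": 1, "=": 2, "#": 3}
_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_RDKIT_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}

# Index alphabet: token -> base-16 digit. Every index token is also an
# ordinary token, so any random string stays decodable.
INDEX_ALPHABET: tuple[str, ...] = (
    "[C]", "[Ring1]", "[Ring2]", "[Branch1]", "[Branch2]",
    "[=C]", "[#C]", "[N]", "[=N]", "[O]",
    "[=O]", "[F]", "[S]", "[P]", "[#N]", "[=S]",
)
_INDEX_OF_TOKEN = {t: i for i, t in enumerate(INDEX_ALPHABET)}

_RING_TOKENS = {
    "[Ring1]": (1, 1), "[Ring2]": (2, 1),
    "[=Ring1]": (1, 2), "[=Ring2]": (2, 2),
}
_BRANCH_TOKENS = {"[Branch1]": 1, "[Branch2]": 2}

#: Tokens safe for the fixture generator: any combination decodes.
ROBUST_ALPHABET: tuple[str, ...] = INDEX_ALPHABET


class SelfiesError(ValueError):
    """Raised on malformed tokens or molecules outside the dialect."""


def _parse_atom_token(token: str) -> tuple[int, str] | None:
    """``[=N]`` -> (2, "N"); None if not an atom token."""
    body = token[1:-1]
    prefix = ""
    if body[:1] in ("=", "#"):
        prefix, body = body[0], body[1:]
    if body in _VALENCE:
        return _BOND_ORDER[prefix], body
    return None


def _digits_to_int(digits: list[str]) -> int:
    value = 0
    for d in digits:
        value = value * len(INDEX_ALPHABET) + _INDEX_OF_TOKEN.get(d, 0)
    return value


def _int_to_digits(value: int, n_digits: int) -> list[str]:
    base = len(INDEX_ALPHABET)
    if value >= base**n_digits:
        raise SelfiesError(f"index {value} exceeds {n_digits}-digit capacity")
    out = []
    for _ in range(n_digits):
        out.append(INDEX_ALPHABET[value % base])
        value //= base
    return out[::-1]


class _Decoder:
    """Sequential derivation state over a token list."""

    def __init__(self) -> None:
        self.mol = Chem.RWMol()
        self.free: dict[int, int] = {}  # atom idx -> remaining valence
        self.n_placed = 0               # atom idx == placement position

    def _add_atom(self, symbol: str, attach: int | None, order: int) -> int:
        cap = _VALENCE[symbol]
        idx = self.mol.AddAtom(Chem.Atom(symbol))
        self.n_placed += 1
        if attach is None:
            self.free[idx] = cap
            return idx
        bond = min(order, self.free[attach], cap)
        self.mol.AddBond(attach, idx, _RDKIT_BOND[bond])
        self.free[attach] -= bond
        self.free[idx] = cap - bond
        return idx

    def derive(self, tokens: list[str], attach: int | None, budget: int | None) -> None:
        """Derive *tokens* growing from *attach*; ``budget`` caps the first
        bond so a branching atom keeps one valence for its main chain."""
        current = attach
        first = True
        i = 0
        while i < len(tokens):
            if current is not None and self.free[current] == 0:
                return  # saturated attachment terminates the derivation
            token = tokens[i]
            i += 1
            atom = _parse_atom_token(token)
            if atom is not None:
                order, symbol = atom
                if first and budget is not None:
                    order = min(order, budget)
                current = self._add_atom(symbol, current, order)
                first = False
                continue
            if token in _BRANCH_TOKENS:
                n_digits = _BRANCH_TOKENS[token]
                digits, i = tokens[i : i + n_digits], i + n_digits
                if len(digits) < n_digits:
                    return
                length = _digits_to_int(digits) + 1
                payload, i = tokens[i : i + length], i + length
                if current is not None and self.free[current] >= 2:
                    self.derive(payload, current, budget=self.free[current] - 1)
                continue
            if token in _RING_TOKENS:
                n_digits, order = _RING_TOKENS[token]
                digits, i = tokens[i : i + n_digits], i + n_digits
                if len(digits) < n_digits:
                    return
                self._close_ring(current, _digits_to_int(digits) + 1, order)
                continue
            raise SelfiesError(f"unknown token {token!r}")

    def _close_ring(self, current: int | None, back: int, order: int) -> None:
        if current is None or current - back < 0:
            return
        target = current - back
        if self.mol.GetBondBetweenAtoms(current, target) is not None:
            return
        bond = min(order, self.free[current], self.free[target])
        if bond >= 1:
            self.mol.AddBond(current, target, _RDKIT_BOND[bond])
            self.free[current] -= bond
            self.free[target] -= bond

    def finish(self) -> str:
        mol = self.mol.GetMol()
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)


def selfies_to_smiles(selfies: str) -> str:
    """Decode a SELFIES string to canonical SMILES.

    Any sequence over the dialect alphabet decodes; an empty derivation
    (e.g. a lone control token) yields the empty string.
    """
    tokens = list(tokenize_selfies(selfies).tokens)
    dec = _Decoder()
    dec.derive(tokens, attach=None, budget=None)
    if dec.mol.GetNumAtoms() == 0:
        return ""
    return dec.finish()


def smiles_to_selfies(smiles: str) -> str:
    """Encode a SMILES string in the dialect.

    The molecule is kekulized and traversed depth-first from atom 0; all but
    the last child of an atom are wrapped in branch tokens, and each ring
    back-edge becomes a ring token on the later of its two atoms.
    """
    mol = Chem.RWMol(_mol_from_smiles(smiles))
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:  # pragma: no cover - rdkit guards
        raise SelfiesError(f"cannot kekulize {smiles!r}: {exc}") from exc
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in _VALENCE or atom.GetFormalCharge() != 0:
            raise SelfiesError(
                f"atom {atom.GetSymbol()}{atom.GetFormalCharge():+d} outside the "
                f"supported subset in {smiles!r}"
            )
        if atom.GetNumRadicalElectrons():
            raise SelfiesError(f"radical atom in {smiles!r}")
        used = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
        if used > _VALENCE[atom.GetSymbol()]:
            raise SelfiesError(
                f"{atom.GetSymbol()} with valence {used} exceeds the dialect cap "
                f"{_VALENCE[atom.GetSymbol()]} in {smiles!r}"
            )
    if mol.GetNumAtoms() == 0:
        raise SelfiesError("empty molecule")

    pos_of: dict[int, int] = {}       # atom idx -> placement position
    ring_done: set[tuple[int, int]] = set()
    visited: set[int] = set()

    def atom_token(idx: int, order: int) -> str:
        return f"[{_BOND_PREFIX[order]}{mol.GetAtomWithIdx(idx).GetSymbol()}]"

    def ring_token(back: int, order: int) -> list[str]:
        if order == 3:
            raise SelfiesError("triple ring-closure bond unsupported")
        prefix = "" if order == 1 else "="
        if back - 1 < len(INDEX_ALPHABET):
            return [f"[{prefix}Ring1]", *_int_to_digits(back - 1, 1)]
        return [f"[{prefix}Ring2]", *_int_to_digits(back - 1, 2)]

    def branch_tokens(payload: list[str]) -> list[str]:
        if len(payload) - 1 < len(INDEX_ALPHABET):
            return ["[Branch1]", *_int_to_digits(len(payload) - 1, 1), *payload]
        return ["[Branch2]", *_int_to_digits(len(payload) - 1, 2), *payload]

    def dfs(idx: int, parent: int | None, order: int) -> list[str]:
        visited.add(idx)
        pos_of[idx] = len(pos_of)
        out = [atom_token(idx, order)]
        # ring closures to already-placed atoms come right after the atom
        # token, where the decoder's attachment point is this atom
        for bond in mol.GetAtomWithIdx(idx).GetBonds():
            nbr = bond.GetOtherAtomIdx(idx)
            pair = (min(idx, nbr), max(idx, nbr))
            if nbr != parent and nbr in visited and pair not in ring_done:
                ring_done.add(pair)
                out.extend(
                    ring_token(pos_of[idx] - pos_of[nbr], int(bond.GetBondTypeAsDouble()))
                )
        subtrees = []
        for bond in mol.GetAtomWithIdx(idx).GetBonds():
            nbr = bond.GetOtherAtomIdx(idx)
            if nbr == parent or nbr in visited:
                continue  # traversed, or closed as a ring in a sibling subtree
            subtrees.append(dfs(nbr, idx, int(bond.GetBondTypeAsDouble())))
        for sub in subtrees[:-1]:
            out.extend(branch_tokens(sub))
        if subtrees:
            out.extend(subtrees[-1])
        return out

    tokens = dfs(0, None, 1)
    if len(visited) != mol.GetNumAtoms():
        raise SelfiesError(f"multi-fragment molecule {smiles!r} unsupported")
    return "".join(tokens)


def heavy_atom_count(smiles: str) -> int:
    return _mol_from_smiles(smiles).GetNumAtoms()
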