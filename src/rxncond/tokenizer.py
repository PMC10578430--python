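"""Regex SMILES tokenization with token↔atom alignment.

The token pattern is the community-standard SMILES regex used by
SMILES-based reaction transformers: bracket atoms ``[...]`` are single
tokens, the two-letter organic-subset halogens Br/Cl are digraph tokens,
``%nn`` ring closures are single tokens, and every other character is its
own token.  Tokenization is lossless: concatenating the non-special
tokens reproduces the input string exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np

from .chem import ReactionCenter, parse_reaction, side_atoms

BOS = "<bos>"
EOS = "<eos>"
PAD = "<pad>"
MASK = "<mask>"
UNK = "<unk>"
SPECIALS = (PAD, UNK, BOS, EOS, MASK)

SMILES_TOKEN_PATTERN = re.compile(
    r"(\[[^\]]+\]|Br|Cl|>>|%\d{2}|[BCNOSPFIbcnosp]|[*]|.)"
)

# tokens denoting an atom: bracket atoms, organic-subset symbols, wildcards
_ATOM_TOKEN = re.compile(r"^(\[[^\]]+\]|Br|Cl|[BCNOSPFIbcnosp]|[*])$")


class LexingError(ValueError):
    pass


@dataclass
class TokenizedReaction:
    """Token sequence of a reaction SMILES with atom alignment.

    ``token_atom[i]`` is ``(side, atom_index)`` when token ``i`` denotes an
    atom (side in {"reactant", "product"}, index 0-based per side), else
    ``None``.  ``center_flags[i]`` marks reaction-center atom tokens.
    """

    tokens: list[str]
    token_atom: list[Optional[tuple[str, int]]]
    center_flags: list[bool]

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def smiles(self) -> str:
        """The original string: concatenation of all non-special tokens."""
        return "".join(t for t in self.tokens if t not in SPECIALS)

    def atom_token_positions(self) -> list[int]:
        return [i for i, ta in enumerate(self.token_atom) if ta is not None]


def is_atom_token(token: str) -> bool:
    return bool(_ATOM_TOKEN.match(token))


def tokenize_smiles(smiles: str) -> list[str]:
    tokens = SMILES_TOKEN_PATTERN.findall(smiles)
    joined = "".join(tokens)
    if joined != smiles:
        pos = len(joined)
        raise LexingError(f"untokenizable character at position {pos} in {smiles!r}")
    return tokens


def tokenize_reaction(rxn_smiles: str, validate: bool = True) -> TokenizedReaction:
    """Tokenize a reaction SMILES, aligning atom tokens with atom indices.

    When ``validate`` is true the SMILES is parsed and the number of atom
    tokens per side is checked against the molecule atom counts.
    """
    if rxn_smiles.count(">>") != 1:
        raise LexingError(f"expected exactly one '>>': {rxn_smiles!r}")
    raw = tokenize_smiles(rxn_smiles)
    tokens = [BOS, *raw, EOS]
    token_atom: list[Optional[tuple[str, int]]] = []
    side, counter = "reactant", 0
    for tok in tokens:
        if tok == ">>":
            side, counter = "product", 0
            token_atom.append(None)
        elif tok not in SPECIALS and is_atom_token(tok):
            token_atom.append((side, counter))
            counter += 1
        else:
            token_atom.append(None)
    if validate:
        reactants, products = parse_reaction(rxn_smiles)
        n_r = len(side_atoms(reactants))
        n_p = len(side_atoms(products))
        got_r = sum(1 for ta in token_atom if ta and ta[0] == "reactant")
        got_p = sum(1 for ta in token_atom if ta and ta[0] == "product")
        if (got_r, got_p) != (n_r, n_p):
            raise LexingError(
                f"atom token counts {(got_r, got_p)} disagree with molecule "
                f"atom counts {(n_r, n_p)} for {rxn_smiles!r}"
            )
    return TokenizedReaction(tokens, token_atom, [False] * len(tokens))


def detokenize(tok: TokenizedReaction) -> str:
    return tok.smiles


def mark_center_tokens(tok: TokenizedReaction, center: ReactionCenter) -> TokenizedReaction:
    """Set ``center_flags`` true exactly on the atom tokens in ``center``."""
    pairs = center.as_pairs()
    n_r = sum(1 for ta in tok.token_atom if ta and ta[0] == "reactant")
    n_p = sum(1 for ta in tok.token_atom if ta and ta[0] == "product")
    for side, idx, n in (("reactant", center.reactant_atoms, n_r),
                         ("product", center.product_atoms, n_p)):
        for i in idx:
            if i < 0 or i >= n:
                raise IndexError(f"{side} center atom index {i} out of range (n={n})")
    flags = [ta is not None and ta in pairs for ta in tok.token_atom]
    return replace(tok, center_flags=flags)


class TokenVocabulary:
    """Token↔id bijection; PAD has id 0 and unknown tokens map to UNK."""

    def __init__(self, tokens: Iterable[str]):
        self.tokens = list(SPECIALS)
        seen = set(self.tokens)
        for tok in tokens:
            if tok not in seen:
                self.tokens.append(tok)
                seen.add(tok)
        self.index = {t: i for i, t in enumerate(self.tokens)}

    pad_id = 0
    unk_id = 1

    @property
    def bos_id(self) -> int:
        return self.index[BOS]

    @property
    def eos_id(self) -> int:
        return self.index[EOS]

    @property
    def mask_id(self) -> int:
        return self.index[MASK]

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @classmethod
    def from_corpus(cls, reactions: Iterable[str]) -> "TokenVocabulary":
        """Build from reaction SMILES strings, min token frequency 1."""
        seen: dict[str, None] = {}
        for rxn in reactions:
            for tok in tokenize_smiles(rxn):
                seen.setdefault(tok)
        return cls(sorted(seen))

    def atom_token_ids(self) -> list[int]:
        return [self.index[t] for t in self.tokens if is_atom_token(t)]

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path) -> "TokenVocabulary":
        with open(path, encoding="utf-8") as fh:
            tokens = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        vocab = cls.__new__(cls)
        vocab.tokens = tokens
        vocab.index = {t: i for i, t in enumerate(tokens)}
        return vocab


def encode(
    tok: TokenizedReaction, vocab: TokenVocabulary, max_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Ids padded right to ``max_len`` plus a 0/1 attention mask."""
    if len(tok) > max_len:
        raise ValueError(f"sequence length {len(tok)} exceeds max_len {max_len}")
    ids = np.full(max_len, vocab.pad_id, dtype=np.int64)
    mask = np.zeros(max_len, dtype=np.int64)
    for i, t in enumerate(tok.tokens):
        ids[i] = vocab.index.get(t, vocab.unk_id)
        mask[i] = 1
    return ids, mask


def decode(ids: np.ndarray, vocab: TokenVocabulary) -> list[str]:
    return [vocab.tokens[int(i)] for i in ids if int(i) != vocab.pad_id]
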