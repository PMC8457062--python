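"""SMILES tokenization and vocabulary handling.

A SMILES string is split into the lexical units a chemical language model
predicts one at a time: bracket atoms (``[nH]``, ``[C@@H]``) and the
two-letter halogens ``Cl``/``Br`` are kept as single tokens, ``%NN``
ring-closure labels are kept whole, and everything else is one character.
The grammar (longest-match, applied left to right) is::

    TOKEN := '[' [^][]+ ']'        bracket atom, verbatim
           | 'Br' | 'Cl'           two-letter organic-subset halogens
           | '%' DIGIT DIGIT       two-digit ring-closure label
           | one of  B C N O P S F I b c n o s p
           | one of  0-9 ( ) = # - + . / \\ : * $ ~ @

Sequences carry explicit begin/end-of-string markers; a padding token exists
for batched training and is never part of a chemical sequence.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: Special (non-chemical) tokens. Chosen so they can never collide with a
#: SMILES lexical unit (bracket atoms never contain '<' or '>').
BEGIN = "<BOS>"
END = "<EOS>"
PAD = "<PAD>"
SPECIAL_TOKENS = (PAD, BEGIN, END)

_ORGANIC_ATOMS = "BCNOPSFIbcnosp"
_PUNCTUATION = "0123456789()=#-+./\\:*$~@"
_SINGLE_CHAR_TOKENS = frozenset(_ORGANIC_ATOMS + _PUNCTUATION)

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]|Br|Cl|%\d{2}|.")


class TokenizationError(ValueError):
    """Raised when a string is not tokenizable SMILES; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class TokenSequence:
    """A tokenized SMILES string with explicit begin/end markers.

    ``tokens`` always starts with :data:`BEGIN`; a *complete* sequence ends
    with :data:`END`. :data:`PAD` never appears between the markers.
    """

    tokens: tuple[str, ...]
    source_smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.tokens or self.tokens[0] != BEGIN:
            raise ValueError("token sequence must start with BEGIN")
        if PAD in self.tokens:
            raise ValueError("PAD may not occur inside a token sequence")

    @property
    def complete(self) -> bool:
        return self.tokens[-1] == END

    @property
    def chemical_tokens(self) -> tuple[str, ...]:
        """Tokens with BEGIN/END stripped."""
        inner = self.tokens[1:]
        if inner and inner[-1] == END:
            inner = inner[:-1]
        return inner

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(smiles: str) -> TokenSequence:
    """Split a SMILES string into a BEGIN...END token sequence.

    Raises
    ------
    TokenizationError
        If a character outside the SMILES alphabet occurs or a bracket atom
        is unterminated; the error names the offending position.
    """
    if not smiles:
        raise TokenizationError("empty SMILES string", 0)
    tokens: list[str] = [BEGIN]
    pos = 0
    for match in _TOKEN_RE.finditer(smiles):
        tok = match.group(0)
        if len(tok) == 1 and tok not in _SINGLE_CHAR_TOKENS:
            if tok == "[":
                raise TokenizationError("unterminated bracket atom", match.start())
            raise TokenizationError(
                f"character {tok!r} outside the SMILES alphabet", match.start()
            )
        tokens.append(tok)
        pos = match.end()
    tokens.append(END)
    return TokenSequence(tokens=tuple(tokens), source_smiles=smiles)


def detokenize(seq: TokenSequence | Sequence[str]) -> str:
    """Concatenate the chemical tokens of a sequence back into a SMILES string.

    Inverse of :func:`tokenize`: ``detokenize(tokenize(s)) == s`` for every
    accepted ``s``.
    """
    if isinstance(seq, TokenSequence):
        return "".join(seq.chemical_tokens)
    tokens = list(seq)
    if tokens and tokens[0] == BEGIN:
        tokens = tokens[1:]
    if tokens and tokens[-1] == END:
        tokens = tokens[:-1]
    if PAD in tokens:
        raise ValueError("PAD may not occur between BEGIN and END")
    if BEGIN in tokens or END in tokens:
        raise ValueError("stray BEGIN/END inside the sequence")
    return "".join(tokens)


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token alphabet of a corpus plus the special tokens.

    Indices are a bijection onto ``0..len-1`` with PAD, BEGIN, END first,
    followed by the corpus tokens in sorted order, so two builds from the
    same corpus are token-for-token identical.
    """

    tokens: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "index", {tok: i for i, tok in enumerate(self.tokens)}
        )
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for special in SPECIAL_TOKENS:
            if special not in self.index:
                raise ValueError(f"vocabulary missing special token {special}")

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def begin_id(self) -> int:
        return self.index[BEGIN]

    @property
    def end_id(self) -> int:
        return self.index[END]

    def encode(self, tokens: Iterable[str]) -> list[int]:
        try:
            return [self.index[t] for t in tokens]
        except KeyError as exc:
            raise KeyError(f"token {exc.args[0]!r} not in vocabulary") from None

    def decode(self, ids: Iterable[int]) -> list[str]:
        return [self.tokens[i] for i in ids]

    @classmethod
    def from_chemical_tokens(cls, chemical_tokens: Iterable[str]) -> "Vocabulary":
        ordered = sorted(set(chemical_tokens) - set(SPECIAL_TOKENS))
        return cls(tokens=SPECIAL_TOKENS + tuple(ordered))

    def to_json(self) -> str:
        return json.dumps({"tokens": list(self.tokens)})

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        return cls(tokens=tuple(json.loads(text)["tokens"]))


def build_vocabulary(corpus: Iterable[str]) -> Vocabulary:
    """Build the deterministic vocabulary of a SMILES corpus.

    Raises
    ------
    TokenizationError
        If any line fails to tokenize; the message carries the 1-based line
        number.
    """
    seen: set[str] = set()
    for lineno, smiles in enumerate(corpus, start=1):
        try:
            seq = tokenize(smiles)
        except TokenizationError as exc:
            raise TokenizationError(
                f"line {lineno}: {smiles!r} is not tokenizable SMILES",
                exc.position,
            ) from exc
        seen.update(seq.chemical_tokens)
    return Vocabulary.from_chemical_tokens(seen)


def read_corpus(path) -> list[str]:
    """Read a one-SMILES-per-line text corpus, ignoring blank lines."""
    with open(path, "r", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]
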