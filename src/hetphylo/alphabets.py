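"""Character alphabets for molecular sequence data.

Four alphabets are supported: nucleotide (``DNA``, c=4), amino acid
(``AA``, c=20), two-state purine/pyrimidine (``BIN``, c=2) and the
six-group Dayhoff reduction of the amino acids (``DAY6``, c=6).

Ambiguity codes (DNA R, Y, N, ...; AA B, Z, X) are legal input.  For
composition counting they are treated as missing data; likelihood
computations expand them to the set of states they denote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Alphabet", "DNA", "AA", "BIN", "DAY6", "get_alphabet"]


@dataclass(frozen=True)
class Alphabet:
    name: str
    states: str
    # char -> string of plain states it may denote (proper ambiguity only)
    ambiguity: dict = field(default_factory=dict)
    missing: frozenset = frozenset({"-", "?"})

    @property
    def size(self) -> int:
        return len(self.states)

    def index(self, char: str) -> int:
        return self.states.index(char)

    def is_missing(self, char: str) -> bool:
        return char in self.missing

    def is_ambiguous(self, char: str) -> bool:
        return char in self.ambiguity

    def is_valid(self, char: str) -> bool:
        return (
            char in self.states or char in self.ambiguity or char in self.missing
        )

    def state_set(self, char: str) -> tuple:
        """Indices of plain states a character may represent.

        Missing characters denote the full state set.
        """
        if char in self.states:
            return (self.index(char),)
        if char in self.ambiguity:
            return tuple(self.index(s) for s in self.ambiguity[char])
        if char in self.missing:
            return tuple(range(self.size))
        raise KeyError(char)


DNA = Alphabet(
    name="DNA",
    states="ACGT",
    ambiguity={
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    },
)

AA = Alphabet(
    name="AA",
    states="ARNDCQEGHILKMFPSTWYV",
    ambiguity={"B": "ND", "Z": "QE", "X": "ARNDCQEGHILKMFPSTWYV"},
)

# two-state purine (R) / pyrimidine (Y) alphabet produced by RY recoding
BIN = Alphabet(name="BIN", states="RY")

# six chemically coherent amino-acid groups (Dayhoff groups):
# 1=AGPST, 2=C, 3=DENQ, 4=FWY, 5=HKR, 6=ILMV
DAY6 = Alphabet(name="DAY6", states="123456")

_REGISTRY = {a.name: a for a in (DNA, AA, BIN, DAY6)}


def get_alphabet(name) -> Alphabet:
    if isinstance(name, Alphabet):
        return name
    try:
        return _REGISTRY[name.upper()]
    except KeyError:
        raise KeyError(f"unknown alphabet {name!r}; choose from {sorted(_REGISTRY)}")
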