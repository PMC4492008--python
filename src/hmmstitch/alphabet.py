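"""Sequence alphabets.

Two molecule types are supported: nucleotide (``dna``) and amino acid
(``amino``).  Each alphabet distinguishes *canonical* symbols, which carry
probability mass in profile-HMM emissions, from *ambiguity* codes (IUPAC
nucleotide codes; B/Z/X/J/U/O for proteins), which are accepted on input and
scored at background frequency (log-odds zero) during HMM evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import SequenceFormatError

GAP = "-"
#: characters accepted as gaps on input; normalised to '-'
GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class Alphabet:
    name: str
    canonical: str
    ambiguous: str

    @property
    def size(self) -> int:
        return len(self.canonical)

    def __post_init__(self):
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.canonical)})
        object.__setattr__(
            self, "_valid", frozenset(self.canonical) | frozenset(self.ambiguous)
        )

    def is_valid(self, ch: str) -> bool:
        return ch in self._valid

    def index(self, ch: str) -> int | None:
        """Canonical index of ``ch``, or None for an ambiguity code."""
        return self._index.get(ch)

    def validate(self, residues: str, seq_id: str) -> None:
        if set(residues) <= self._valid:  # fast path, O(n) in C
            return
        for pos, ch in enumerate(residues):
            if ch not in self._valid:
                raise SequenceFormatError(
                    f"sequence {seq_id!r}: illegal symbol {ch!r} at position "
                    f"{pos + 1} for alphabet {self.name!r}"
                )


DNA = Alphabet("dna", "ACGT", "RYSWKMBDHVN")
AMINO = Alphabet("amino", "ACDEFGHIKLMNPQRSTVWY", "BZXJUO")

_BY_NAME = {"dna": DNA, "nucleotide": DNA, "amino": AMINO, "protein": AMINO}


def get_alphabet(name) -> Alphabet:
    if isinstance(name, Alphabet):
        return name
    try:
        return _BY_NAME[str(name).lower()]
    except KeyError:
        raise SequenceFormatError(
            f"unknown alphabet {name!r}; expected one of {sorted(_BY_NAME)}"
        ) from None
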