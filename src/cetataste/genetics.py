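"""Genetic code, codon indexing and CDS translation.

The standard nuclear genetic code ships as packaged data
(``data/standard_code.tsv``) rather than hard-coded logic.  Sense codons are
indexed lexicographically over the alphabet (A, C, G, T); this ordering
defines row/column indices of every 61x61 codon matrix in the package and
must never change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "BASES",
    "ALL_CODONS",
    "STOP_CODONS",
    "SENSE_CODONS",
    "CODON_INDEX",
    "GAP",
    "MISSING",
    "GeneticCode",
    "translate_cds",
]

BASES = "ACGT"
#: all 64 codons, lexicographic over (A, C, G, T)
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(BASES, repeat=3)
)

#: integer state for a codon column that is an alignment gap in this row
GAP = -2
#: integer state for a codon that is ambiguous (contains N, a stop after
#: repair, or anything else treated as fully unknown in likelihoods)
MISSING = -1


def _load_standard_table() -> dict[str, str]:
    text = (
        resources.files("cetataste.data").joinpath("standard_code.tsv").read_text()
    )
    table: dict[str, str] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        codon, aa = line.split("\t")
        table[codon] = aa
    if len(table) != 64:
        raise ValueError("packaged code table must have 64 codons")
    return table


_STANDARD_TABLE = _load_standard_table()

STOP_CODONS: frozenset[str] = frozenset(
    c for c, aa in _STANDARD_TABLE.items() if aa == "*"
)
#: 61 sense codons in the fixed lexicographic (A,C,G,T) order
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if c not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map plus the derived sense-codon ordering.

    Only the standard nuclear code is packaged; the genes this package
    targets (taste receptors, epithelial sodium channel subunits) are
    nuclear.
    """

    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...] = field(default=SENSE_CODONS)

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls(codon_to_aa=dict(_STANDARD_TABLE))

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon.upper()) == "*"

    def translate_codon(self, codon: str) -> str:
        """One codon -> one symbol; ambiguous/gapped codons give 'X'."""
        codon = codon.upper()
        if len(codon) != 3:
            raise ValueError(f"codon must have length 3, got {codon!r}")
        if any(b not in "ACGT" for b in codon):
            return "X"
        return self.codon_to_aa[codon]


_VALID_CHARS = frozenset("ACGTN-")


def translate_cds(seq: str, frame: int = 1, code: GeneticCode | None = None) -> str:
    """Translate a coding sequence into protein, '*' marking stop codons.

    Parameters
    ----------
    seq:
        Nucleotide sequence over {A, C, G, T, N, -} (case-insensitive).
    frame:
        1-based reading-frame offset, one of 1, 2, 3.
    code:
        Genetic code; defaults to the standard nuclear code.

    Returns one symbol per *complete* codon starting at ``frame``; codons
    containing N or '-' translate to 'X', stop codons to '*'.  A trailing
    incomplete codon is ignored.
    """
    if code is None:
        code = GeneticCode.standard()
    if not seq:
        raise ValueError("cannot translate an empty sequence")
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    up = seq.upper()
    for pos, ch in enumerate(up, start=1):
        if ch not in _VALID_CHARS:
            raise ValueError(
                f"invalid character {ch!r} at position {pos} (1-based)"
            )
    out = []
    for i in range(frame - 1, len(up) - 2, 3):
        out.append(code.translate_codon(up[i : i + 3]))
    return "".join(out)
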