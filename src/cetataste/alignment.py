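"""Codon alignment container and the pseudogene "repair" step.

A :class:`CodonAlignment` is a taxa x codon-column matrix over the 61 sense
codons plus GAP and MISSING states.  Codon substitution models are defined
over sense codons only, so pseudogenized sequences must be *repaired* before
entering a likelihood: frameshift-bearing columns are removed and stop or
ambiguous codons are recoded as MISSING (fully ambiguous).  The repair
recipe is deterministic and returned as a log so every analysis can state
exactly what was removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import CODON_INDEX, GAP, MISSING, SENSE_CODONS, GeneticCode

__all__ = ["CodonAlignment", "RepairLog", "repair_alignment"]


@dataclass
class CodonAlignment:
    """Aligned codon states: integer sense-codon indices, GAP = -2, MISSING = -1."""

    taxa: list[str]
    codes: np.ndarray  # (n_taxa, n_codons) int16
    ref_taxon: str | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be a (n_taxa, n_codons) matrix")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if self.ref_taxon is not None and self.ref_taxon not in self.taxa:
            raise ValueError(f"ref_taxon {self.ref_taxon!r} not among taxa")
        bad = (self.codes >= len(SENSE_CODONS)) | (self.codes < GAP)
        if bad.any():
            raise ValueError("codon state out of range")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return int(self.codes.shape[1])

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.taxa.index(taxon)]

    @classmethod
    def from_nucleotide(
        cls,
        records: dict[str, str],
        ref_taxon: str | None = None,
        code: GeneticCode | None = None,
        stops: str = "error",
    ) -> "CodonAlignment":
        """Build from an in-frame, gapped nucleotide alignment.

        Codons '---' become GAP; codons containing N or a partial gap become
        MISSING; in-frame stop codons raise unless ``stops='missing'``.
        """
        if code is None:
            code = GeneticCode.standard()
        lengths = {len(s) for s in records.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} is not a multiple of 3")
        taxa = list(records)
        n_codons = length // 3
        codes = np.empty((len(taxa), n_codons), dtype=np.int16)
        for i, taxon in enumerate(taxa):
            seq = records[taxon].upper()
            for j in range(n_codons):
                codon = seq[3 * j : 3 * j + 3]
                if codon == "---":
                    codes[i, j] = GAP
                elif "-" in codon or "N" in codon:
                    codes[i, j] = MISSING
                elif code.is_stop(codon):
                    if stops == "missing":
                        codes[i, j] = MISSING
                    else:
                        raise ValueError(
                            f"in-frame stop codon {codon} at codon {j + 1} "
                            f"of {taxon!r}; repair the alignment first"
                        )
                else:
                    codes[i, j] = CODON_INDEX[codon]
        return cls(taxa=taxa, codes=codes, ref_taxon=ref_taxon)

    def to_nucleotide(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for i, taxon in enumerate(self.taxa):
            parts = []
            for state in self.codes[i]:
                if state == GAP:
                    parts.append("---")
                elif state == MISSING:
                    parts.append("NNN")
                else:
                    parts.append(SENSE_CODONS[state])
            out[taxon] = "".join(parts)
        return out

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Collapse identical columns -> (patterns (n_taxa, n_pat), weights)."""
        cols = self.codes.T  # (n_codons, n_taxa)
        uniq, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        return uniq.T.copy(), counts.astype(float)

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(
            taxa=list(taxa),
            codes=self.codes[idx].copy(),
            ref_taxon=self.ref_taxon if self.ref_taxon in taxa else None,
        )


@dataclass
class RepairLog:
    """What the repair step removed/recoded, for the run log."""

    n_columns_in: int = 0
    n_columns_out: int = 0
    dropped_ref_gap_columns: int = 0
    dropped_gap_codons: int = 0
    recoded_stop_codons: int = 0
    recoded_ambiguous_codons: int = 0
    notes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"repair: {self.n_columns_in} nt columns in, kept "
            f"{self.n_columns_out} codon columns; dropped "
            f"{self.dropped_ref_gap_columns} ref-gap nt columns and "
            f"{self.dropped_gap_codons} gapped codon columns; recoded "
            f"{self.recoded_stop_codons} stop and "
            f"{self.recoded_ambiguous_codons} ambiguous codons as MISSING"
        )


def repair_alignment(
    records: dict[str, str],
    ref_taxon: str,
    code: GeneticCode | None = None,
) -> tuple[CodonAlignment, RepairLog]:
    """Prepare a (possibly pseudogene-bearing) nucleotide alignment for
    codon-model likelihoods.

    Recipe, applied in order and logged:

    1. drop every alignment column where the functional reference has a gap
       (insertions relative to the reference reading frame);
    2. group the remaining columns into reference-frame codons;
    3. drop codon columns in which any row has a gap (this removes all
       frameshifting deletion columns and restores a common frame);
    4. recode codons containing a stop or an ambiguous base as MISSING.
    """
    if code is None:
        code = GeneticCode.standard()
    if ref_taxon not in records:
        raise ValueError(f"reference taxon {ref_taxon!r} not in alignment")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    log = RepairLog(n_columns_in=next(iter(lengths)))
    ref = records[ref_taxon].upper()
    keep = [i for i, ch in enumerate(ref) if ch != "-"]
    log.dropped_ref_gap_columns = log.n_columns_in - len(keep)
    stripped = {t: "".join(s.upper()[i] for i in keep) for t, s in records.items()}
    n_full = len(keep) // 3
    if len(keep) % 3 != 0:
        log.notes.append(
            f"trailing {len(keep) % 3} nt beyond the last complete reference codon dropped"
        )
    taxa = list(records)
    columns: list[list[int]] = []
    for j in range(n_full):
        codons = {t: stripped[t][3 * j : 3 * j + 3] for t in taxa}
        if any("-" in c for c in codons.values()):
            log.dropped_gap_codons += 1
            continue
        states = []
        for t in taxa:
            c = codons[t]
            if "N" in c:
                log.recoded_ambiguous_codons += 1
                states.append(MISSING)
            elif code.is_stop(c):
                log.recoded_stop_codons += 1
                states.append(MISSING)
            else:
                states.append(CODON_INDEX[c])
        columns.append(states)
    if not columns:
        raise ValueError("repair removed every codon column")
    codes = np.array(columns, dtype=np.int16).T
    log.n_columns_out = codes.shape[1]
    aln = CodonAlignment(taxa=taxa, codes=codes, ref_taxon=ref_taxon)
    return aln, log
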