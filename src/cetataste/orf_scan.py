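"""Detection of ORF-disrupting mutations relative to a functional reference.

Pseudogene calls rest on two signals: indels whose length is not a multiple
of 3 (frameshifts) and premature stop codons (TAA/TAG/TGA upstream of the
reference terminal stop).  The scanner takes a pairwise alignment of a
functional reference CDS against a query, classifies every gap run as an
insertion or deletion in reference coordinates, tracks the cumulative frame
offset, and translates the query in its *local* frame so that stops created
downstream of a frameshift are still reported (their cause is recorded as
"post-frameshift").

Coordinates are 1-based in the reference reading frame; indel coordinates
are reported at the leftmost-shifted placement, which is the canonical
dialect used throughout the package.  Terminal gap runs (touching either
alignment end) are treated as missing data — incompletely amplified or
sequenced ends — never as disruptions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .genetics import GeneticCode

__all__ = [
    "AlignParams",
    "Disruption",
    "DisruptionReport",
    "InactivationEvent",
    "align_codon_aware",
    "detect_disruptions",
    "find_shared_events",
    "reports_to_table",
]


@dataclass(frozen=True)
class AlignParams:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0


@dataclass(frozen=True)
class Disruption:
    """One ORF-disrupting mutation in reference coordinates."""

    kind: str  # insertion | deletion | premature_stop
    ref_codon_start: int  # 1-based codon index in the reference frame
    ref_nt_start: int  # 1-based nucleotide position in the reference
    length_nt: int  # 0 for premature stops
    frameshifting: bool
    stop_codon: str | None = None  # the trinucleotide, premature_stop only
    cause: str | None = None  # e.g. "post-frameshift"
    note: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion", "premature_stop"):
            raise ValueError(f"unknown disruption kind {self.kind!r}")
        if self.kind == "premature_stop":
            if self.length_nt != 0 or self.frameshifting:
                raise ValueError("premature_stop must have length 0, no frameshift")
        elif self.frameshifting != (self.length_nt % 3 != 0):
            raise ValueError("frameshifting flag inconsistent with length")

    def key(self) -> tuple:
        return (self.kind, self.length_nt, self.stop_codon)


@dataclass
class DisruptionReport:
    taxon: str
    gene: str
    disruptions: list[Disruption]
    ref_protein_length: int
    first_stop_codon: int | None = None
    truncation_fraction: float = 0.0

    @property
    def intact(self) -> bool:
        return not self.disruptions


@dataclass(frozen=True)
class InactivationEvent:
    """A disruption shared (identically placed) by a set of carrier taxa."""

    gene: str
    disruption: Disruption
    carriers: frozenset[str]


# ---------------------------------------------------------------------------
# pairwise alignment


def _leftmost_shift(ref_row: str, query_row: str) -> tuple[str, str]:
    """Canonicalize gap placement: shift each gap run left while the flanking
    character on the gapless row is unchanged (score-preserving moves only)."""

    def shift(gapped: list[str], other: list[str]) -> bool:
        moved = False
        i = 0
        n = len(gapped)
        while i < n:
            if gapped[i] != "-":
                i += 1
                continue
            s = i
            while i < n and gapped[i] == "-":
                i += 1
            e = i
            while s > 0 and gapped[s - 1] != "-" and other[s - 1] != "-" \
                    and other[s - 1] == other[e - 1]:
                gapped[e - 1] = gapped[s - 1]
                gapped[s - 1] = "-"
                s -= 1
                e -= 1
                moved = True
        return moved

    r, q = list(ref_row), list(query_row)
    while shift(q, r) or shift(r, q):
        pass
    return "".join(r), "".join(q)


def align_codon_aware(
    ref_cds: str, query: str, params: AlignParams | None = None
) -> tuple[str, str]:
    """Global affine-gap alignment of a query against an in-frame reference.

    Deterministic for fixed params; gap runs are left-normalized so indel
    coordinates are canonical.  Returns (ref_row, query_row).
    """
    if params is None:
        params = AlignParams()
    ref_cds, query = ref_cds.upper(), query.upper()
    if len(ref_cds) < 3 or len(query) < 3:
        raise ValueError("sequences must contain at least one codon")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    aln = aligner.align(ref_cds, query)[0]
    ref_row, query_row = str(aln[0]), str(aln[1])
    return _leftmost_shift(ref_row, query_row)


# ---------------------------------------------------------------------------
# disruption detection


def _gap_runs(row: str) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(row):
        if row[i] == "-":
            s = i
            while i < len(row) and row[i] == "-":
                i += 1
            runs.append((s, i))
        else:
            i += 1
    return runs


def detect_disruptions(
    alignment: tuple[str, str],
    code: GeneticCode | None = None,
    *,
    taxon: str = "query",
    gene: str = "",
    exon_intervals: Sequence[tuple[int, int]] | None = None,
) -> DisruptionReport:
    """Scan an aligned (reference, query) pair for ORF disruptions.

    The reference row must be in frame and translate without internal stops.
    Exon intervals, if given, are 1-based closed nucleotide intervals in
    reference coordinates; a deletion covering >= 95% of an exon is annotated
    as a whole-exon loss.
    """
    if code is None:
        code = GeneticCode.standard()
    ref_row, query_row = (alignment[0].upper(), alignment[1].upper())
    if len(ref_row) != len(query_row):
        raise ValueError("alignment rows differ in length")
    # drop columns where both rows are gaps (padding invariance)
    cols = [(r, q) for r, q in zip(ref_row, query_row) if not (r == "-" and q == "-")]
    ref_row = "".join(r for r, _ in cols)
    query_row = "".join(q for _, q in cols)

    ref_seq = ref_row.replace("-", "")
    if len(ref_seq) % 3 != 0:
        raise ValueError("reference row is not a whole number of codons")
    ref_protein = ""
    for i in range(0, len(ref_seq) - 2, 3):
        ref_protein += code.translate_codon(ref_seq[i : i + 3])
    has_terminal_stop = ref_protein.endswith("*")
    if "*" in ref_protein.rstrip("*") or ref_protein.count("*") > (
        1 if has_terminal_stop else 0
    ):
        raise ValueError("invalid reference: internal stop codon")
    ref_protein_length = len(ref_protein) - (1 if has_terminal_stop else 0)
    if ref_protein_length < 1:
        raise ValueError("reference shorter than one codon of protein")

    n = len(ref_row)
    # per-column reference nucleotide count *after* consuming the column
    ref_consumed = []
    r = 0
    for ch in ref_row:
        if ch != "-":
            r += 1
        ref_consumed.append(r)

    disruptions: list[Disruption] = []
    # -- indels ----------------------------------------------------------
    indel_runs: list[tuple[str, int, int]] = []  # (kind, start_col, end_col)
    for s, e in _gap_runs(query_row):
        if s == 0 or e == n:
            continue  # terminal gap: missing data, not a deletion
        indel_runs.append(("deletion", s, e))
    for s, e in _gap_runs(ref_row):
        if s == 0 or e == n:
            continue
        indel_runs.append(("insertion", s, e))
    indel_runs.sort(key=lambda t: (t[1], t[0]))

    for kind, s, e in indel_runs:
        length = e - s
        before = ref_consumed[s - 1] if s > 0 else 0
        # deletion: first deleted reference nt; insertion: the reference nt
        # the inserted run precedes
        ref_nt_start = before + 1
        ref_codon_start = (ref_nt_start - 1) // 3 + 1
        note = None
        if kind == "deletion" and exon_intervals:
            del_start, del_end = before + 1, ref_consumed[e - 1]
            for k, (xs, xe) in enumerate(exon_intervals, start=1):
                covered = max(0, min(del_end, xe) - max(del_start, xs) + 1)
                if covered >= 0.95 * (xe - xs + 1):
                    note = f"spans exon {k}"
        disruptions.append(
            Disruption(
                kind=kind,
                ref_codon_start=ref_codon_start,
                ref_nt_start=ref_nt_start,
                length_nt=length,
                frameshifting=length % 3 != 0,
                note=note,
            )
        )

    # -- premature stops (query local frame) -----------------------------
    # map query nucleotide index -> alignment column
    q_cols = [i for i, ch in enumerate(query_row) if ch != "-"]
    query_seq = query_row.replace("-", "")
    # leading terminal gap in query: the query starts mid-reference; keep the
    # reference frame by skipping to the next codon boundary of the reference
    lead = 0
    if query_row and query_row[0] == "-" and q_cols:
        first_col = q_cols[0]
        ref_before = ref_consumed[first_col - 1] if first_col > 0 else 0
        lead = (-ref_before) % 3
    for k in range((len(query_seq) - lead) // 3):
        q_start = lead + 3 * k
        codon = query_seq[q_start : q_start + 3]
        col = q_cols[q_start]
        ref_pos = ref_consumed[col]  # ref nts consumed through this column
        if ref_pos == 0:
            ref_pos = 1
        ref_codon = (ref_pos - 1) // 3 + 1
        if code.is_stop(codon) and ref_codon <= ref_protein_length:
            offset_here = 0
            for kind2, s2, e2 in indel_runs:
                if s2 < col:
                    length2 = e2 - s2
                    offset_here = (
                        offset_here + (length2 if kind2 == "insertion" else -length2)
                    ) % 3
            disruptions.append(
                Disruption(
                    kind="premature_stop",
                    ref_codon_start=ref_codon,
                    ref_nt_start=3 * (ref_codon - 1) + 1,
                    length_nt=0,
                    frameshifting=False,
                    stop_codon=codon,
                    cause="post-frameshift" if offset_here != 0 else None,
                )
            )

    disruptions.sort(key=lambda d: (d.ref_codon_start, d.kind, d.length_nt))
    stops = [d.ref_codon_start for d in disruptions if d.kind == "premature_stop"]
    first_stop = min(stops) if stops else None
    trunc = (
        1.0 - (first_stop - 1) / ref_protein_length if first_stop is not None else 0.0
    )
    return DisruptionReport(
        taxon=taxon,
        gene=gene,
        disruptions=disruptions,
        ref_protein_length=ref_protein_length,
        first_stop_codon=first_stop,
        truncation_fraction=trunc,
    )


# ---------------------------------------------------------------------------
# shared events


def find_shared_events(
    reports: Iterable[DisruptionReport], tolerance: int = 0
) -> list[InactivationEvent]:
    """Group identically placed disruptions across taxa into events.

    Disruptions match when kind, length and stop codon are identical and the
    reference codon coordinates differ by at most ``tolerance`` codons
    (default 0: exact identity, single-linkage within a matching group).
    Singleton disruptions become single-carrier events.
    """
    reports = list(reports)
    if len(reports) < 2:
        raise ValueError("need reports from at least two taxa")
    genes = {r.gene for r in reports}
    if len(genes) != 1:
        raise ValueError(f"reports mix genes: {sorted(genes)}")
    (gene,) = genes

    items: list[tuple[Disruption, str]] = []
    for rep in reports:
        for d in rep.disruptions:
            items.append((d, rep.taxon))

    groups: dict[tuple, list[tuple[Disruption, str]]] = {}
    for d, taxon in items:
        groups.setdefault(d.key(), []).append((d, taxon))

    events: list[InactivationEvent] = []
    for members in groups.values():
        members.sort(key=lambda dt: dt[0].ref_codon_start)
        cluster: list[tuple[Disruption, str]] = []
        for d, taxon in members:
            if cluster and d.ref_codon_start - cluster[-1][0].ref_codon_start > tolerance:
                events.append(_make_event(gene, cluster))
                cluster = []
            if tolerance == 0 and cluster and (
                d.ref_codon_start != cluster[-1][0].ref_codon_start
                or d.ref_nt_start != cluster[-1][0].ref_nt_start
            ):
                events.append(_make_event(gene, cluster))
                cluster = []
            cluster.append((d, taxon))
        if cluster:
            events.append(_make_event(gene, cluster))
    events.sort(key=lambda ev: (ev.disruption.ref_codon_start, ev.disruption.kind))
    return events


def _make_event(gene: str, cluster: list[tuple[Disruption, str]]) -> InactivationEvent:
    # carrier-specific annotations (cause/note) do not belong to the event
    rep = replace(cluster[0][0], cause=None, note=None)
    return InactivationEvent(
        gene=gene,
        disruption=rep,
        carriers=frozenset(t for _, t in cluster),
    )


def reports_to_table(reports: Iterable[DisruptionReport]) -> pd.DataFrame:
    """Flatten reports into the TSV schema used by the CLI."""
    rows = []
    for rep in reports:
        if rep.intact:
            rows.append(
                dict(
                    taxon=rep.taxon,
                    gene=rep.gene,
                    kind="intact",
                    ref_codon_start=pd.NA,
                    length_nt=pd.NA,
                    frameshifting=pd.NA,
                    stop_codon=pd.NA,
                    first_stop_codon=pd.NA,
                    truncation_fraction=0.0,
                )
            )
        for d in rep.disruptions:
            rows.append(
                dict(
                    taxon=rep.taxon,
                    gene=rep.gene,
                    kind=d.kind,
                    ref_codon_start=d.ref_codon_start,
                    length_nt=d.length_nt,
                    frameshifting=d.frameshifting,
                    stop_codon=d.stop_codon or "",
                    first_stop_codon=rep.first_stop_codon,
                    truncation_fraction=round(rep.truncation_fraction, 4),
                )
            )
    return pd.DataFrame(rows)
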