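"""Protein-level conservation scanning and physicochemical-property tests.

Three analyses support the "is this receptor still functional?" question at
the protein level:

* conservation profiling of an amino-acid alignment, with positions reported
  in the numbering of a chosen reference sequence (e.g. rat ENaC alpha) and
  columns classed as completely (100%) or partially (>= 80%) conserved;
* variant scanning of target taxa against the consensus at those conserved
  columns, rendered in the field's ``<gene><consensus><position><observed>``
  style (e.g. gV591I);
* a property-change test in the style of protein-level selection analyses:
  nonsynonymous changes inferred along the tree (Fitch parsimony ancestral
  amino acids) are binned by the magnitude of the change in each of 31
  packaged physicochemical property scales into 8 equal-width categories,
  and a z-score compares observed to expected category counts.  Categories
  1-3 are conservative, 6-8 radical; only significant *positive* z-scores in
  categories 6-8 are flagged as positive-selection signals.  A sliding
  window (width 15 codons) repeats the test regionally; edge windows shorter
  than 15 are skipped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .genetics import SENSE_CODONS, GeneticCode
from .phylo import PhyloTree

__all__ = [
    "ConservationColumn",
    "VariantCall",
    "PropertyReport",
    "load_property_table",
    "conservation_profile",
    "variant_scan",
    "motif_check",
    "property_zscores",
    "fitch_ancestral_states",
    "DEFAULT_MOTIFS",
]

AA20 = "ARNDCQEGHILKMFPSTWYV"

#: motifs essential for epithelial sodium channel function: the C-terminal
#: proline-rich PY motif, the N-terminal HG gating pair, and the post-M1
#: FPxxTxC signature.  X matches any residue.
DEFAULT_MOTIFS = ("PPPXYXXL", "HG", "FPXXTXC")


@dataclass(frozen=True)
class ConservationColumn:
    ref_position: int  # 1-based residue index in the numbering reference
    column_index: int  # 0-based alignment column
    consensus: str
    conservation_level: float
    klass: str  # complete | partial80 | below


@dataclass(frozen=True)
class VariantCall:
    gene: str
    consensus: str
    ref_position: int
    observed: str
    carriers: frozenset[str]

    @property
    def label(self) -> str:
        return f"{self.gene}{self.consensus}{self.ref_position}{self.observed}"


@dataclass
class PropertyReport:
    property_name: str
    observed: np.ndarray  # (8,)
    expected: np.ndarray  # (8,)
    z: np.ndarray  # (8,) NaN where undefined
    significant_positive: np.ndarray  # (8,) bool, only cats 6-8 can be True
    n_changes: int
    windows: pd.DataFrame = field(default_factory=pd.DataFrame)


def load_property_table() -> pd.DataFrame:
    """The packaged 31-property amino-acid scale table (rows: properties)."""
    text = resources.files("cetataste.data").joinpath("aa_properties.tsv").read_text()
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", comment="#", index_col=0)
    if df.shape != (31, 20):
        raise ValueError("packaged property table must be 31 properties x 20 residues")
    return df


# ---------------------------------------------------------------------------
# conservation / variants / motifs


def conservation_profile(
    msa: dict[str, str],
    reference_taxa: set[str],
    numbering_ref: str,
    partial_threshold: float = 0.8,
) -> list[ConservationColumn]:
    """Per-column conservation over ``reference_taxa``, positions numbered by
    the (gap-skipped) coordinates of ``numbering_ref``."""
    if numbering_ref not in msa:
        raise ValueError(f"numbering reference {numbering_ref!r} not in MSA")
    if not reference_taxa:
        raise ValueError("reference_taxa must be non-empty")
    missing = reference_taxa - set(msa)
    if missing:
        raise ValueError(f"reference taxa not in MSA: {sorted(missing)}")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("MSA rows differ in length")
    ref_seq = msa[numbering_ref]
    out: list[ConservationColumn] = []
    pos = 0
    for col in range(len(ref_seq)):
        if ref_seq[col] == "-":
            continue  # position skipped: no coordinate in the numbering ref
        pos += 1
        residues = [
            msa[t][col]
            for t in sorted(reference_taxa)
            if msa[t][col] not in "-X"
        ]
        if not residues:
            continue
        counts = pd.Series(residues).value_counts()
        consensus = counts.index[0]
        level = counts.iloc[0] / len(residues)
        if level == 1.0:
            klass = "complete"
        elif level >= partial_threshold:
            klass = "partial80"
        else:
            klass = "below"
        out.append(ConservationColumn(pos, col, consensus, float(level), klass))
    return out


def variant_scan(
    msa: dict[str, str],
    target_taxa: set[str],
    columns: list[ConservationColumn],
    gene: str = "",
) -> list[VariantCall]:
    """Calls at complete/partial80 columns where target taxa differ from
    the consensus; carriers grouped per observed residue."""
    missing = target_taxa - set(msa)
    if missing:
        raise ValueError(f"target taxa not in MSA: {sorted(missing)}")
    calls: list[VariantCall] = []
    for colinfo in columns:
        if colinfo.klass == "below":
            continue
        by_obs: dict[str, set[str]] = {}
        for t in sorted(target_taxa):
            aa = msa[t][colinfo.column_index]
            if aa in "-X" or aa == colinfo.consensus:
                continue
            by_obs.setdefault(aa, set()).add(t)
        for obs, carriers in sorted(by_obs.items()):
            calls.append(
                VariantCall(
                    gene=gene,
                    consensus=colinfo.consensus,
                    ref_position=colinfo.ref_position,
                    observed=obs,
                    carriers=frozenset(carriers),
                )
            )
    return calls


def motif_check(
    protein: str, patterns: tuple[str, ...] = DEFAULT_MOTIFS
) -> dict[str, list[int]]:
    """1-based match positions of each motif; X is a single-residue wildcard.

    Overlapping occurrences are all reported.
    """
    protein = protein.upper()
    out: dict[str, list[int]] = {}
    for pat in patterns:
        if not all(c in AA20 + "X" for c in pat.upper()):
            raise ValueError(f"motif {pat!r} must be over the 20 residues + X")
        regex = re.compile("(?=(" + pat.upper().replace("X", "[A-Z]") + "))")
        out[pat] = [m.start() + 1 for m in regex.finditer(protein)]
    return out


# ---------------------------------------------------------------------------
# property z-scores


def fitch_ancestral_states(
    tree: PhyloTree, leaf_states: dict[str, str]
) -> dict[int, str]:
    """Fitch parsimony for one site; returns a state per postorder node index.

    Leaves with missing state ('-', 'X') carry the full residue set and never
    force changes.  Ties are broken lexicographically (deterministic).
    """
    sets: dict[int, frozenset[str]] = {}
    order = tree.postorder
    for k, node in enumerate(order):
        if node.is_leaf():
            aa = leaf_states.get(node.taxon.label, "X")
            sets[k] = frozenset(AA20) if aa in "-X" else frozenset(aa)
        else:
            child_idx = [order.index(ch) for ch in node.child_nodes()]
            inter = frozenset.intersection(*(sets[i] for i in child_idx))
            sets[k] = inter if inter else frozenset.union(*(sets[i] for i in child_idx))
    # top-down assignment
    assigned: dict[int, str] = {}
    for k in reversed(range(len(order))):
        node = order[k]
        parent = node.parent_node
        if parent is None:
            assigned[k] = min(sets[k])
        else:
            pstate = assigned[order.index(parent)]
            assigned[k] = pstate if pstate in sets[k] else min(sets[k])
    return assigned


def _expected_change_distribution(
    prop: pd.Series, codon_freqs: np.ndarray, code: GeneticCode, n_bins: int = 8
) -> tuple[np.ndarray, float]:
    """Expected magnitude-category distribution over all single-nucleotide
    nonsynonymous codon exchanges, weighted by observed codon frequencies."""
    mags, weights = [], []
    for i, ci in enumerate(SENSE_CODONS):
        aa_i = code.translate_codon(ci)
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            if sum(a != b for a, b in zip(ci, cj)) != 1:
                continue
            aa_j = code.translate_codon(cj)
            if aa_i == aa_j:
                continue
            mags.append(abs(prop[aa_j] - prop[aa_i]))
            weights.append(codon_freqs[i])
    mags = np.asarray(mags)
    weights = np.asarray(weights, dtype=float)
    max_mag = float(mags.max())
    if max_mag == 0:
        return np.full(n_bins, np.nan), 0.0
    bins = np.minimum((mags / max_mag * n_bins).astype(int), n_bins - 1)
    p = np.bincount(bins, weights=weights, minlength=n_bins)
    return p / p.sum(), max_mag


def property_zscores(
    tree: PhyloTree,
    aln: CodonAlignment,
    property_table: pd.DataFrame | None = None,
    window: int = 15,
    alpha: float = 0.001,
    code: GeneticCode | None = None,
) -> list[PropertyReport]:
    """Property-change magnitude tests over all branches of the tree.

    Observed nonsynonymous changes come from Fitch-parsimony ancestral amino
    acids on the fixed tree; each change's property-magnitude falls in one of
    8 equal-width categories spanning the range attainable by single-
    nucleotide exchanges (larger multi-step changes clamp into category 8).
    z = (obs - N p) / sqrt(N p (1 - p)) per category; a category is flagged
    only if z is positive, category >= 6, and the two-sided normal p-value
    is below ``alpha``.  Sites with zero observed changes yield undefined z,
    reported as not significant.
    """
    if property_table is None:
        property_table = load_property_table()
    if code is None:
        code = GeneticCode.standard()
    if window < 1:
        raise ValueError("window must be >= 1")
    # translate the codon alignment
    aa_rows: dict[str, str] = {}
    for t in aln.taxa:
        states = aln.row(t)
        aa_rows[t] = "".join(
            "X" if s < 0 else code.translate_codon(SENSE_CODONS[s]) for s in states
        )
    # ancestral states per site, then per-branch changes (site, aa_from, aa_to)
    order = tree.postorder
    order_index = {id(n): k for k, n in enumerate(order)}
    changes: list[tuple[int, str, str]] = []
    for site in range(aln.n_codons):
        leaf_states = {t: aa_rows[t][site] for t in aln.taxa}
        assigned = fitch_ancestral_states(tree, leaf_states)
        for k, node in enumerate(order):
            parent = node.parent_node
            if parent is None:
                continue
            a_parent = assigned[order_index[id(parent)]]
            if node.is_leaf():
                a_child = leaf_states.get(node.taxon.label, "X")
                if a_child in "-X":
                    continue
            else:
                a_child = assigned[k]
            if a_parent != a_child:
                changes.append((site, a_parent, a_child))

    # observed codon frequency weights for the expected distribution
    states = aln.codes[aln.codes >= 0]
    codon_freqs = np.bincount(states, minlength=len(SENSE_CODONS)).astype(float)
    codon_freqs = (
        codon_freqs / codon_freqs.sum()
        if codon_freqs.sum() > 0
        else np.full(len(SENSE_CODONS), 1 / len(SENSE_CODONS))
    )

    from scipy.stats import norm

    z_crit = norm.isf(alpha / 2.0)
    reports: list[PropertyReport] = []
    for prop_name, prop in property_table.iterrows():
        p, max_mag = _expected_change_distribution(prop, codon_freqs, code)
        n_bins = 8

        def bin_counts(change_subset) -> np.ndarray:
            counts = np.zeros(n_bins)
            for _, a, b in change_subset:
                mag = abs(prop[b] - prop[a])
                k = min(int(mag / max_mag * n_bins), n_bins - 1) if max_mag else 0
                counts[k] += 1
            return counts

        def zscores(obs: np.ndarray) -> np.ndarray:
            n = obs.sum()
            z = np.full(n_bins, np.nan)
            if n == 0:
                return z
            with np.errstate(divide="ignore", invalid="ignore"):
                denom = np.sqrt(n * p * (1 - p))
                z = np.where(denom > 0, (obs - n * p) / denom, np.nan)
            return z

        obs = bin_counts(changes)
        z = zscores(obs)
        sig = np.zeros(n_bins, dtype=bool)
        for k in range(5, 8):  # categories 6-8 (0-based 5..7)
            if np.isfinite(z[k]) and z[k] > z_crit:
                sig[k] = True

        win_rows = []
        if aln.n_codons >= window:
            by_site: dict[int, list] = {}
            for ch in changes:
                by_site.setdefault(ch[0], []).append(ch)
            for start in range(0, aln.n_codons - window + 1):
                sub = [
                    ch
                    for s in range(start, start + window)
                    for ch in by_site.get(s, [])
                ]
                if not sub:
                    continue
                wobs = bin_counts(sub)
                wz = zscores(wobs)
                flagged = [
                    k + 1
                    for k in range(5, 8)
                    if np.isfinite(wz[k]) and wz[k] > z_crit
                ]
                if flagged:
                    win_rows.append(
                        dict(
                            window_start=start + 1,
                            window_end=start + window,
                            n_changes=int(wobs.sum()),
                            flagged_categories=",".join(map(str, flagged)),
                            max_z=float(np.nanmax(wz[5:8])),
                        )
                    )
        reports.append(
            PropertyReport(
                property_name=str(prop_name),
                observed=obs,
                expected=obs.sum() * p,
                z=z,
                significant_positive=sig,
                n_changes=int(obs.sum()),
                windows=pd.DataFrame(win_rows),
            )
        )
    return reports


def property_report_table(reports: list[PropertyReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for k in range(8):
            rows.append(
                dict(
                    property=rep.property_name,
                    category=k + 1,
                    observed=rep.observed[k],
                    expected=round(float(rep.expected[k]), 3),
                    z=round(float(rep.z[k]), 3) if np.isfinite(rep.z[k]) else "",
                    significant_positive=bool(rep.significant_positive[k]),
                )
            )
    return pd.DataFrame(rows)
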