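"""Simulation of codon alignments with known truth, plus pseudogenizing
mutation injection.

Sequences evolve on a fixed tree under the same GY94 machinery the
estimators use: the root is drawn from pi, and each branch applies
P(t) = exp(Q(kappa, omega_branch) t) site-independently.  ORF-disrupting
events (frameshifting deletions/insertions of, e.g., 5, 17, 4, 1 or 2 nt,
and premature TGA/TAA/TAG stop codons) are injected *after* simulation by
editing the final alignment identically in every taxon descending from the
chosen branch, so the injected truth is exactly recoverable by the scanner.
Disruption shapes mirror those seen in cetacean taste receptors; simulating
indels as evolutionary processes is an explicit non-goal.

All randomness flows from a single integer seed through numpy's PCG64, so
identical seeds give identical datasets on any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import CodonAlignment
from .codon_models import CodonFrequencies, EigenQ, build_generator
from .fastaio import write_fasta
from .genetics import SENSE_CODONS, STOP_CODONS
from .phylo import PhyloTree

__all__ = [
    "SimulationTruth",
    "simulate_alignment",
    "inject_pseudogenization",
    "fixture_suite",
    "CETACEAN_TREE_NEWICK",
    "cetacean_tree",
]

#: 13-taxon fixture topology mirroring the breadth of cetacean sampling in
#: molecular studies of taste receptors: three delphinids, finless porpoise,
#: baiji, a beaked whale, sperm + dwarf sperm whale (toothed whales), two
#: baleen whales, hippo, and two outgroups.  Branch lengths are round
#: plausible values, not estimates.
CETACEAN_TREE_NEWICK = (
    "((((((((Tursiops:0.02,Stenella:0.02):0.01,Lagenorhynchus:0.03):0.02,"
    "Neophocaena:0.05):0.01,Lipotes:0.06):0.01,Mesoplodon:0.07):0.01,"
    "(Physeter:0.05,Kogia:0.05):0.02):0.04,"
    "(Balaenoptera_acutorostrata:0.04,Balaenoptera_physalus:0.04):0.04):0.06,"
    "(Hippopotamus:0.10,(Bos:0.08,Sus:0.09):0.03):0.02);"
)


def cetacean_tree() -> PhyloTree:
    return PhyloTree.from_newick(CETACEAN_TREE_NEWICK)


TOOTHED_WHALES = (
    "Tursiops",
    "Stenella",
    "Lagenorhynchus",
    "Neophocaena",
    "Lipotes",
    "Mesoplodon",
    "Physeter",
    "Kogia",
)
BALEEN_WHALES = ("Balaenoptera_acutorostrata", "Balaenoptera_physalus")
CETACEANS = TOOTHED_WHALES + BALEEN_WHALES


@dataclass
class SimulationTruth:
    """Everything needed to regenerate and to verify a synthetic dataset."""

    newick: str
    branch_omegas: dict[str, float]
    kappa: float
    pi_scheme: str
    n_codons: int
    seed: int
    injected_events: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


def simulate_alignment(
    tree: PhyloTree,
    branch_omegas: dict[str, float] | float,
    kappa: float,
    pi: CodonFrequencies | None = None,
    n_codons: int = 500,
    seed: int = 0,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve a codon alignment on ``tree``.

    ``branch_omegas`` is either one omega for every branch or a mapping from
    branch name to omega (missing branches default to the value under key
    ``"default"``, or 0.3).
    """
    if pi is None:
        pi = CodonFrequencies.equal()
    if isinstance(branch_omegas, (int, float)):
        omega_map = {br.name: float(branch_omegas) for br in tree.branches}
    else:
        default = float(branch_omegas.get("default", 0.3))
        omega_map = {
            br.name: float(branch_omegas.get(br.name, default))
            for br in tree.branches
        }
    rng = np.random.default_rng(seed)
    n_states = len(SENSE_CODONS)
    eig_cache: dict[float, EigenQ] = {}

    def eig(w: float) -> EigenQ:
        if w not in eig_cache:
            eig_cache[w] = EigenQ(build_generator(kappa, w, pi.pi), pi.pi)
        return eig_cache[w]

    root_states = rng.choice(n_states, size=n_codons, p=pi.pi)
    states_of: dict[int, np.ndarray] = {id(tree.root): root_states}
    # preorder: parent before child
    for node in tree.root.preorder_iter():
        if node is tree.root:
            continue
        br = tree.branches[node.branch_index]
        P = eig(omega_map[br.name]).transition_matrix(br.length)
        parent_states = states_of[id(node.parent_node)]
        # vectorized categorical draw per site via inverse CDF
        cdf = np.cumsum(P, axis=1)
        u = rng.random(n_codons)
        child = (u[:, None] > cdf[parent_states]).sum(axis=1)
        states_of[id(node)] = np.minimum(child, n_states - 1).astype(np.int16)
    taxa = list(tree.leaf_labels)
    codes = np.stack(
        [
            states_of[id(lf)]
            for lf in tree.postorder
            if lf.is_leaf()
        ]
    )
    leaf_order = [n.taxon.label for n in tree.postorder if n.is_leaf()]
    reorder = [leaf_order.index(t) for t in taxa]
    aln = CodonAlignment(taxa=taxa, codes=codes[reorder])
    truth = SimulationTruth(
        newick=tree.to_newick(),
        branch_omegas=omega_map,
        kappa=float(kappa),
        pi_scheme=pi.scheme,
        n_codons=int(n_codons),
        seed=int(seed),
    )
    return aln, truth


def inject_pseudogenization(
    records: dict[str, str],
    tree: PhyloTree,
    branch: str,
    event_spec: dict,
    truth: SimulationTruth,
    seed: int = 0,
) -> dict[str, str]:
    """Apply one ORF-disrupting event to every taxon descending from a branch.

    ``records`` is an aligned nucleotide FASTA mapping (modified copies are
    returned).  ``event_spec`` keys: ``kind`` (deletion/insertion/
    premature_stop), ``codon`` (1-based reference codon position), and
    ``length_nt`` for indels or ``stop_codon`` for stops (default TGA).
    Deletions blank carrier nucleotides to gaps; insertions add columns
    (gaps in non-carriers); stops overwrite the codon in carriers.
    """
    rng = np.random.default_rng(seed)
    node = tree.node_of_branch(tree.branch(branch).index)
    carriers = sorted(tree.leaf_set(node))
    kind = event_spec["kind"]
    codon_pos = int(event_spec["codon"])
    nt_start = 3 * (codon_pos - 1)  # 0-based
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise ValueError("records must be aligned")
    (length,) = lengths
    out = dict(records)
    if kind == "deletion":
        L = int(event_spec["length_nt"])
        if nt_start + L > length:
            raise ValueError("deletion runs past the alignment")
        for t in carriers:
            s = out[t]
            out[t] = s[:nt_start] + "-" * L + s[nt_start + L :]
    elif kind == "insertion":
        L = int(event_spec["length_nt"])
        ins = "".join(rng.choice(list("ACGT"), size=L))
        # avoid creating an in-frame stop inside the insertion itself
        while any(ins[i : i + 3] in STOP_CODONS for i in range(0, L - 2, 3)):
            ins = "".join(rng.choice(list("ACGT"), size=L))
        for t in out:
            if t in carriers:
                out[t] = out[t][:nt_start] + ins + out[t][nt_start:]
            else:
                out[t] = out[t][:nt_start] + "-" * L + out[t][nt_start:]
    elif kind == "premature_stop":
        stop = event_spec.get("stop_codon", "TGA")
        if stop not in STOP_CODONS:
            raise ValueError(f"{stop!r} is not a stop codon")
        for t in carriers:
            s = out[t]
            out[t] = s[:nt_start] + stop + s[nt_start + 3 :]
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    truth.injected_events.append(
        dict(
            branch=branch,
            carriers=carriers,
            kind=kind,
            codon=codon_pos,
            length_nt=int(event_spec.get("length_nt", 0)),
            stop_codon=event_spec.get("stop_codon", "TGA")
            if kind == "premature_stop"
            else None,
        )
    )
    return out


def fixture_suite(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write the canonical synthetic datasets used across the test-suite.

    (a) tiny 3- and 4-taxon alignments for exhaustive-enumeration checks,
    (b) a 13-taxon taste-gene scenario with a stem-toothed-whale stop codon
        plus nested frameshifts, with truth manifest,
    (c) relaxation-power datasets (background omega 0.26, foreground 0.68)
        and a matching one-ratio null,
    (d) a conserved protein MSA with planted variants for the conservation
        scanner.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    rng = np.random.default_rng(seed)

    # (a) tiny oracle datasets
    tiny_tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,C:0.15,D:0.3);")
    aln, truth = simulate_alignment(
        tiny_tree, 0.5, kappa=2.0, n_codons=10, seed=int(rng.integers(2**31))
    )
    write_fasta(aln.to_nucleotide(), outdir / "tiny4.fasta")
    tiny_tree.write_newick(outdir / "tiny4.nwk")
    truth.to_json(outdir / "tiny4.truth.json")
    written["tiny4"] = outdir / "tiny4.fasta"

    # (b) 13-taxon taste-gene scenario
    tree = cetacean_tree()
    aln, truth = simulate_alignment(
        tree, 0.25, kappa=3.0, n_codons=300, seed=int(rng.integers(2**31))
    )
    records = aln.to_nucleotide()
    stem_odontoceti = "stem(" + "+".join(sorted(TOOTHED_WHALES)) + ")"
    records = inject_pseudogenization(
        records,
        tree,
        stem_odontoceti,
        dict(kind="deletion", codon=40, length_nt=5),
        truth,
        seed=int(rng.integers(2**31)),
    )
    records = inject_pseudogenization(
        records,
        tree,
        stem_odontoceti,
        dict(kind="premature_stop", codon=120, stop_codon="TGA"),
        truth,
        seed=int(rng.integers(2**31)),
    )
    records = inject_pseudogenization(
        records,
        tree,
        "stem(Balaenoptera_acutorostrata+Balaenoptera_physalus)",
        dict(kind="deletion", codon=80, length_nt=17),
        truth,
        seed=int(rng.integers(2**31)),
    )
    write_fasta(records, outdir / "taste13.fasta")
    tree.write_newick(outdir / "taste13.nwk")
    truth.to_json(outdir / "taste13.truth.json")
    written["taste13"] = outdir / "taste13.fasta"

    # (c) relaxation power + null datasets
    tree_fg = cetacean_tree()
    fg_branches = tree_fg.tag_clade(CETACEANS, 1)
    omegas = {name: 0.68 for name in fg_branches}
    omegas["default"] = 0.26
    aln, truth = simulate_alignment(
        tree_fg, omegas, kappa=2.5, n_codons=500, seed=int(rng.integers(2**31))
    )
    write_fasta(aln.to_nucleotide(), outdir / "relaxed.fasta")
    tree_fg.write_newick(outdir / "relaxed.nwk")
    truth.to_json(outdir / "relaxed.truth.json")
    aln, truth = simulate_alignment(
        tree_fg, 0.26, kappa=2.5, n_codons=500, seed=int(rng.integers(2**31))
    )
    write_fasta(aln.to_nucleotide(), outdir / "null.fasta")
    truth.to_json(outdir / "null.truth.json")
    written["relaxed"] = outdir / "relaxed.fasta"

    # (d) conserved protein MSA with planted variants
    taxa = ["Rat"] + list(CETACEANS)
    L = 60
    base = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=L))
    base = base[:20] + "PPPAYKKL" + base[28:]
    msa = {t: base for t in taxa}
    # planted V->I style change in toothed whales at a conserved column
    col = 40
    planted = dict(msa)
    for t in TOOTHED_WHALES:
        s = planted[t]
        planted[t] = s[:col] + ("I" if s[col] != "I" else "V") + s[col + 1 :]
    write_fasta(planted, outdir / "enac_like_protein.fasta")
    written["protein"] = outdir / "enac_like_protein.fasta"
    (outdir / "enac_like_protein.json").write_text(
        json.dumps(
            dict(
                planted_column_1based=col + 1,
                consensus=base[col],
                observed="I" if base[col] != "I" else "V",
                carriers=sorted(TOOTHED_WHALES),
            ),
            indent=2,
        )
    )
    return written
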