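"""Goldman–Yang codon substitution models and maximum-likelihood fitting.

The instantaneous rate of change between sense codons i and j is zero unless
they differ at exactly one nucleotide, and otherwise proportional to the
target-codon frequency pi_j, multiplied by kappa for transitions (A<->G,
C<->T) and by omega (dN/dS) for nonsynonymous changes.  Each generator is
scaled so the expected substitution rate at stationarity is 1, making branch
lengths expected substitutions per codon.

Model families
--------------
Branch models: one ratio (A), omega fixed at 1 (B), two-ratio
foreground/background (C), two-ratio with foreground omega = 1 (D), and
free-ratio (E, one omega per branch).  Site models: M1a/M2a and M8/M8a
(discretized beta plus an extra class).  Clade models: clade model C (one
site class with a partition-specific omega) and its null M2a_rel.

Free-parameter counts (np) follow the CODEML convention: branch lengths +
kappa + the family's free omega/proportion/shape parameters; codon
frequencies are counted from the data (F3x4) and not included in np.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import betainc, betaincinv, logsumexp

from .alignment import CodonAlignment
from .genetics import BASES, SENSE_CODONS
from .phylo import PhyloTree

__all__ = [
    "CodonFrequencies",
    "ModelSpec",
    "ModelFit",
    "FitOptions",
    "build_generator",
    "stationary_distribution",
    "transition_matrix",
    "EigenQ",
    "estimate_frequencies",
    "beta_category_means",
    "site_classes",
    "log_likelihood",
    "site_log_likelihoods",
    "fit",
    "BRANCH_FAMILIES",
    "SITE_FAMILIES",
    "CLADE_FAMILIES",
]

N_STATES = len(SENSE_CODONS)

# ---------------------------------------------------------------------------
# structural precompute: all single-nucleotide exchanges among sense codons

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _single_nt_pairs() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    from .genetics import GeneticCode

    code = GeneticCode.standard()
    ii, jj, ts, ns = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            ii.append(i)
            jj.append(j)
            ts.append(diffs[0] in _TRANSITIONS)
            ns.append(code.translate_codon(ci) != code.translate_codon(cj))
    return (
        np.array(ii),
        np.array(jj),
        np.array(ts, dtype=bool),
        np.array(ns, dtype=bool),
    )


_PAIR_I, _PAIR_J, _PAIR_TRANSITION, _PAIR_NONSYN = _single_nt_pairs()


# ---------------------------------------------------------------------------
# generator / transition probabilities


@dataclass(frozen=True)
class CodonFrequencies:
    pi: np.ndarray  # (61,)
    scheme: str  # equal | F3x4 | empirical

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (N_STATES,) or (pi < 0).any():
            raise ValueError("pi must be 61 non-negative reals")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")

    @classmethod
    def equal(cls) -> "CodonFrequencies":
        return cls(np.full(N_STATES, 1.0 / N_STATES), "equal")


def build_generator(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """61x61 GY94 rate matrix, scaled to one expected substitution per unit t."""
    if not (np.isfinite(kappa) and np.isfinite(omega)) or kappa <= 0 or omega < 0:
        raise ValueError(f"invalid parameters kappa={kappa}, omega={omega}")
    pi = np.asarray(pi, dtype=float)
    rates = pi[_PAIR_J].copy()
    rates[_PAIR_TRANSITION] *= kappa
    rates[_PAIR_NONSYN] *= omega
    Q = np.zeros((N_STATES, N_STATES))
    Q[_PAIR_I, _PAIR_J] = rates
    Q[np.diag_indices(N_STATES)] = -Q.sum(axis=1)
    scale = -(pi * np.diag(Q)).sum()
    if scale <= 0:
        raise ValueError("degenerate generator (zero expected rate)")
    return Q / scale


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator (left null vector)."""
    w, v = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


class EigenQ:
    """Spectral form of a reversible generator for fast P(t) = exp(Qt).

    Uses the pi-symmetrized similarity transform: with D = diag(sqrt(pi)),
    B = D Q D^-1 is symmetric, so Q = D^-1 U L U' D with real eigenpairs.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)  # symmetrize away rounding
        lam, U = np.linalg.eigh(B)
        self.lam = lam
        self.left = U / d[:, None] * 1.0  # D^-1 U
        self.right = (U * d[:, None]).T  # U' D
        self.pi = pi

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0 or not np.isfinite(t):
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_matrix(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) for a reversible generator (eigendecomposition, clipped at 0)."""
    if pi is None:
        pi = stationary_distribution(Q)
    return EigenQ(Q, pi).transition_matrix(t)


def estimate_frequencies(aln: CodonAlignment, scheme: str = "F3x4") -> CodonFrequencies:
    """Empirical codon frequencies.

    F3x4 multiplies position-specific nucleotide frequencies, removes stop
    codons and renormalizes; ``empirical`` counts codons directly; ``equal``
    is uniform over the 61 sense codons.
    """
    if scheme == "equal":
        return CodonFrequencies.equal()
    states = aln.codes[aln.codes >= 0]
    if states.size == 0:
        raise ValueError("alignment has no unambiguous codons")
    if scheme == "empirical":
        counts = np.bincount(states, minlength=N_STATES).astype(float)
        counts += 1e-8  # guard zero frequencies
        return CodonFrequencies(counts / counts.sum(), "empirical")
    if scheme != "F3x4":
        raise ValueError(f"unknown frequency scheme {scheme!r}")
    pos_freq = np.zeros((3, 4))
    base_index = {b: k for k, b in enumerate(BASES)}
    for s in states:
        codon = SENSE_CODONS[s]
        for p, b in enumerate(codon):
            pos_freq[p, base_index[b]] += 1
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, base_index[c[0]]]
            * pos_freq[1, base_index[c[1]]]
            * pos_freq[2, base_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    pi = np.maximum(pi, 1e-12)
    return CodonFrequencies(pi / pi.sum(), "F3x4")


# ---------------------------------------------------------------------------
# model specifications

BRANCH_FAMILIES = (
    "branch_one_ratio",
    "branch_fixed1",
    "branch_two_ratio",
    "branch_two_ratio_fg1",
    "branch_free",
)
SITE_FAMILIES = ("site_M1a", "site_M2a", "site_M8", "site_M8a")
CLADE_FAMILIES = ("clade_C", "clade_M2a_rel")

#: nested (null, alternative) family pairs accepted by the LRT layer
NESTED_PAIRS = {
    ("branch_fixed1", "branch_one_ratio"),
    ("branch_one_ratio", "branch_two_ratio"),
    ("branch_two_ratio_fg1", "branch_two_ratio"),
    ("branch_two_ratio", "branch_free"),
    ("branch_one_ratio", "branch_free"),
    ("site_M1a", "site_M2a"),
    ("site_M8a", "site_M8"),
    ("clade_M2a_rel", "clade_C"),
}


@dataclass(frozen=True)
class ModelSpec:
    """A codon model family plus its partition usage and hyperparameters."""

    family: str
    foreground: frozenset[int] = frozenset({1})  # partition tags = foreground
    n_beta_categories: int = 10

    def __post_init__(self) -> None:
        if self.family not in BRANCH_FAMILIES + SITE_FAMILIES + CLADE_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        object.__setattr__(self, "foreground", frozenset(self.foreground))

    @property
    def needs_partitions(self) -> bool:
        return self.family in (
            "branch_two_ratio",
            "branch_two_ratio_fg1",
            "clade_C",
        )


# free-parameter layout per family: (name, lower, upper, default init, log?)
_FAMILY_PARAMS: dict[str, list[tuple[str, float, float, float, bool]]] = {
    "branch_one_ratio": [("omega", 1e-4, 20.0, 0.3, True)],
    "branch_fixed1": [],
    "branch_two_ratio": [
        ("omega_bg", 1e-4, 20.0, 0.25, True),
        ("omega_fg", 1e-4, 20.0, 0.6, True),
    ],
    "branch_two_ratio_fg1": [("omega_bg", 1e-4, 20.0, 0.25, True)],
    "branch_free": [],  # expanded per branch at fit time
    "site_M1a": [
        ("p0", 1e-6, 1 - 1e-6, 0.7, False),
        ("omega0", 1e-4, 1.0, 0.1, True),
    ],
    "site_M2a": [
        ("v1", 1e-6, 1 - 1e-6, 0.7, False),
        ("v2", 1e-6, 1 - 1e-6, 0.95, False),
        ("omega0", 1e-4, 1.0, 0.1, True),
        ("omega2", 1.0, 20.0, 2.0, True),
    ],
    "site_M8": [
        ("p0", 1e-6, 1 - 1e-6, 0.9, False),
        ("p", 0.005, 99.0, 0.5, True),
        ("q", 0.005, 99.0, 1.5, True),
        ("omega_s", 1.0, 20.0, 2.0, True),
    ],
    "site_M8a": [
        ("p0", 1e-6, 1 - 1e-6, 0.9, False),
        ("p", 0.005, 99.0, 0.5, True),
        ("q", 0.005, 99.0, 1.5, True),
    ],
    "clade_C": [
        ("v1", 1e-6, 1 - 1e-6, 0.6, False),
        ("v2", 1e-6, 1 - 1e-6, 0.5, False),
        ("omega0", 1e-4, 1.0, 0.1, True),
        ("omega2", 1e-4, 20.0, 0.3, True),
        ("omega3", 1e-4, 20.0, 0.8, True),
    ],
    "clade_M2a_rel": [
        ("v1", 1e-6, 1 - 1e-6, 0.6, False),
        ("v2", 1e-6, 1 - 1e-6, 0.5, False),
        ("omega0", 1e-4, 1.0, 0.1, True),
        ("omega2", 1e-4, 20.0, 0.3, True),
    ],
}


def beta_category_means(p: float, q: float, k: int) -> np.ndarray:
    """Means of k equal-probability categories of a Beta(p, q) density."""
    if p <= 0 or q <= 0 or k < 1:
        raise ValueError("invalid beta discretization")
    edges = betaincinv(p, q, np.linspace(0.0, 1.0, k + 1))
    mass_below = betainc(p + 1.0, q, edges)
    mean = p / (p + q)
    means = k * mean * np.diff(mass_below)
    return np.clip(means, 0.0, 1.0)


def _stick(v1: float, v2: float) -> tuple[float, float, float]:
    p0 = v1
    p1 = (1.0 - v1) * v2
    return p0, p1, 1.0 - p0 - p1


def site_classes(
    spec: ModelSpec, params: dict[str, float]
) -> list[tuple[float, dict[str, float]]]:
    """Expand a spec + parameter values into (proportion, omega-role) classes.

    The omega-role dict maps "background"/"foreground" to the class omega
    (identical for non-clade models).  Proportions always sum to 1.
    """
    fam = spec.family

    def both(w: float) -> dict[str, float]:
        return {"background": w, "foreground": w}

    if fam == "site_M1a":
        p0 = params["p0"]
        out = [(p0, both(params["omega0"])), (1.0 - p0, both(1.0))]
    elif fam == "site_M2a":
        p0, p1, p2 = _stick(params["v1"], params["v2"])
        out = [
            (p0, both(params["omega0"])),
            (p1, both(1.0)),
            (p2, both(params["omega2"])),
        ]
    elif fam in ("site_M8", "site_M8a"):
        p0 = params["p0"]
        k = spec.n_beta_categories
        means = beta_category_means(params["p"], params["q"], k)
        out = [(p0 / k, both(float(m))) for m in means]
        omega_s = params["omega_s"] if fam == "site_M8" else 1.0
        out.append((1.0 - p0, both(omega_s)))
    elif fam in ("clade_C", "clade_M2a_rel"):
        p0, p1, p2 = _stick(params["v1"], params["v2"])
        w3 = params["omega3"] if fam == "clade_C" else params["omega2"]
        out = [
            (p0, both(params["omega0"])),
            (p1, both(1.0)),
            (p2, {"background": params["omega2"], "foreground": w3}),
        ]
    elif fam == "branch_one_ratio":
        out = [(1.0, both(params["omega"]))]
    elif fam == "branch_fixed1":
        out = [(1.0, both(1.0))]
    elif fam == "branch_two_ratio":
        out = [
            (1.0, {"background": params["omega_bg"], "foreground": params["omega_fg"]})
        ]
    elif fam == "branch_two_ratio_fg1":
        out = [(1.0, {"background": params["omega_bg"], "foreground": 1.0})]
    elif fam == "branch_free":
        raise ValueError("branch_free classes are per-branch; use fit()")
    else:  # pragma: no cover
        raise ValueError(fam)
    total = sum(p for p, _ in out)
    if not np.isclose(total, 1.0):
        raise ValueError(f"class proportions sum to {total}, not 1")
    if any(p < -1e-12 for p, _ in out):
        raise ValueError("negative class proportion")
    return out


# ---------------------------------------------------------------------------
# likelihood engine


@dataclass
class _TreeIndex:
    """Flattened postorder traversal of a PhyloTree against alignment rows."""

    ops: list  # (branch_index, leaf_row or None, child_slots or None)
    n_branches: int
    branch_tags: np.ndarray
    branch_names: list[str]
    root_children: list[int]  # slots

    @classmethod
    def build(cls, tree: PhyloTree, taxa: list[str]) -> "_TreeIndex":
        row_of = {t: i for i, t in enumerate(taxa)}
        missing = [lf for lf in tree.leaf_labels if lf not in row_of]
        if missing:
            raise ValueError(f"taxa in tree but not in alignment: {missing}")
        ops = []
        slot_of: dict[int, int] = {}  # id(node) -> op slot
        for node in tree.postorder:
            if node is tree.root:
                continue
            if node.is_leaf():
                ops.append((node.branch_index, row_of[node.taxon.label], None))
            else:
                child_slots = [slot_of[id(ch)] for ch in node.child_nodes()]
                ops.append((node.branch_index, None, child_slots))
            slot_of[id(node)] = len(ops) - 1
        root_children = [slot_of[id(ch)] for ch in tree.root.child_nodes()]
        tags = np.array([br.tag for br in tree.branches])
        names = [br.name for br in tree.branches]
        return cls(ops, tree.n_branches, tags, names, root_children)


def _class_site_loglik(
    patterns: np.ndarray,
    tindex: _TreeIndex,
    P_by_branch: list[np.ndarray],
    pi: np.ndarray,
) -> np.ndarray:
    """Per-pattern log-likelihood for one site class (Felsenstein pruning)."""
    npat = patterns.shape[1]
    messages: list[np.ndarray | None] = [None] * len(tindex.ops)
    logscale = np.zeros(npat)
    for slot, (bidx, leaf_row, child_slots) in enumerate(tindex.ops):
        P = P_by_branch[bidx]
        if leaf_row is not None:
            states = patterns[leaf_row]
            msg = np.ones((N_STATES, npat))
            obs = states >= 0
            msg[:, obs] = P[:, states[obs]]
        else:
            partial = messages[child_slots[0]]
            for cs in child_slots[1:]:
                partial = partial * messages[cs]
            m = partial.max(axis=0)
            m[m == 0] = 1.0
            partial = partial / m
            logscale += np.log(m)
            for cs in child_slots:
                messages[cs] = None
            msg = P @ partial
        messages[slot] = msg
    partial = messages[tindex.root_children[0]]
    for cs in tindex.root_children[1:]:
        partial = partial * messages[cs]
    site_l = pi @ partial
    site_l = np.maximum(site_l, 1e-300)
    return np.log(site_l) + logscale


def _resolve_omegas(
    classes: list[tuple[float, dict[str, float]]],
    tindex: _TreeIndex,
    foreground: frozenset[int],
) -> list[tuple[float, np.ndarray]]:
    """Map role omegas onto per-branch omega vectors via partition tags."""
    fg = np.isin(tindex.branch_tags, list(foreground))
    out = []
    for prop, roles in classes:
        w = np.where(fg, roles["foreground"], roles["background"])
        out.append((prop, w.astype(float)))
    return out


def _mixture_loglik(
    patterns: np.ndarray,
    weights: np.ndarray,
    tindex: _TreeIndex,
    class_omegas: list[tuple[float, np.ndarray]],
    kappa: float,
    pi: np.ndarray,
    branch_lengths: np.ndarray,
) -> float:
    eig_cache: dict[float, EigenQ] = {}

    def eig(w: float) -> EigenQ:
        if w not in eig_cache:
            eig_cache[w] = EigenQ(build_generator(kappa, w, pi), pi)
        return eig_cache[w]

    per_class_log = []
    props = []
    for prop, omegas in class_omegas:
        P_by_branch = [
            eig(float(omegas[b])).transition_matrix(float(branch_lengths[b]))
            for b in range(tindex.n_branches)
        ]
        per_class_log.append(_class_site_loglik(patterns, tindex, P_by_branch, pi))
        props.append(prop)
    props = np.asarray(props)
    if len(per_class_log) == 1:
        site_log = per_class_log[0]
    else:
        keep = props > 0
        stack = np.stack([l for l, k in zip(per_class_log, keep) if k])
        site_log = logsumexp(stack, axis=0, b=props[keep][:, None])
    return float(np.dot(weights, site_log))


def site_log_likelihoods(
    aln: CodonAlignment,
    tree: PhyloTree,
    spec: ModelSpec,
    params: dict[str, float],
    kappa: float,
    pi: np.ndarray | None = None,
    branch_lengths: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site per-class log-likelihood matrix (n_classes, n_sites) and the
    class proportions — the ingredients of NEB site posteriors."""
    if pi is None:
        pi = estimate_frequencies(aln).pi
    tindex = _TreeIndex.build(tree, aln.taxa)
    t = _branch_length_vector(tree, branch_lengths)
    classes = site_classes(spec, params)
    class_omegas = _resolve_omegas(classes, tindex, spec.foreground)
    eig_cache: dict[float, EigenQ] = {}
    rows = []
    for prop, omegas in class_omegas:
        P_by_branch = []
        for b in range(tindex.n_branches):
            w = float(omegas[b])
            if w not in eig_cache:
                eig_cache[w] = EigenQ(build_generator(kappa, w, pi), pi)
            P_by_branch.append(eig_cache[w].transition_matrix(float(t[b])))
        rows.append(_class_site_loglik(aln.codes, tindex, P_by_branch, pi))
    props = np.array([p for p, _ in classes])
    return np.stack(rows), props


def _branch_length_vector(
    tree: PhyloTree, branch_lengths: dict[str, float] | None
) -> np.ndarray:
    t = np.array([br.length for br in tree.branches], dtype=float)
    if branch_lengths:
        for name, val in branch_lengths.items():
            t[tree.branch(name).index] = val
    return t


def log_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    spec: ModelSpec,
    params: dict[str, float],
    kappa: float,
    pi: np.ndarray | None = None,
    branch_lengths: dict[str, float] | None = None,
) -> float:
    """Total log-likelihood of the alignment under the given model.

    MISSING/GAP codon states contribute all-ones partials; per-node
    rescaling keeps the computation in log scale.  A degenerate single-taxon
    alignment on a single-leaf tree reduces to sum of log pi over sites.
    """
    if pi is None:
        pi = estimate_frequencies(aln).pi
    pi = np.asarray(pi, dtype=float)
    if spec.needs_partitions:
        tags = {br.tag for br in tree.branches}
        if not (tags & spec.foreground):
            raise ValueError(
                f"spec {spec.family} needs foreground branches tagged "
                f"{sorted(spec.foreground)}, tree has tags {sorted(tags)}"
            )
    if len(aln.taxa) == 1:
        states = aln.codes[0]
        obs = states[states >= 0]
        return float(np.log(pi[obs]).sum())
    patterns, weights = aln.patterns()
    tindex = _TreeIndex.build(tree, aln.taxa)
    t = _branch_length_vector(tree, branch_lengths)
    if spec.family == "branch_free":
        omega_vec = np.array(
            [params[f"omega_{name}"] for name in tindex.branch_names]
        )
        class_omegas = [(1.0, omega_vec)]
    else:
        classes = site_classes(spec, params)
        class_omegas = _resolve_omegas(classes, tindex, spec.foreground)
    return _mixture_loglik(patterns, weights, tindex, class_omegas, kappa, pi, t)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitOptions:
    n_starts: int = 3
    seed: int = 1234
    maxiter: int = 1000
    ftol: float = 1e-9
    kappa_init: float = 2.0
    branch_length_init: float = 0.1
    use_tree_lengths: bool = True
    warm_start: "ModelFit | None" = None
    t_bounds: tuple[float, float] = (1e-6, 50.0)
    kappa_bounds: tuple[float, float] = (1e-3, 100.0)


@dataclass
class ModelFit:
    spec: ModelSpec
    kappa: float
    params: dict[str, float]
    branch_lengths: dict[str, float]
    lnL: float
    np: int
    converged: bool
    n_evals: int = 0
    pi: np.ndarray | None = None

    def summary(self) -> dict:
        return {
            "family": self.spec.family,
            "lnL": self.lnL,
            "np": self.np,
            "kappa": self.kappa,
            "converged": self.converged,
            **{k: v for k, v in self.params.items()},
        }


def _family_layout(spec: ModelSpec, tree: PhyloTree):
    if spec.family == "branch_free":
        return [
            (f"omega_{br.name}", 1e-4, 20.0, 0.3, True) for br in tree.branches
        ]
    return list(_FAMILY_PARAMS[spec.family])


def n_free_parameters(spec: ModelSpec, tree: PhyloTree) -> int:
    """np under the CODEML convention (branches + kappa + family params)."""
    return tree.n_branches + 1 + len(_family_layout(spec, tree))


def _embed_warm_start(
    warm: ModelFit, spec: ModelSpec, tree: PhyloTree
) -> dict[str, float]:
    """Translate a fitted null model's parameters into a starting point for
    a nesting alternative (guarantees the optimizer starts at >= null lnL)."""
    src = dict(warm.params)
    fam_from, fam_to = warm.spec.family, spec.family
    out: dict[str, float] = {}
    if fam_from == fam_to:
        return src
    if (fam_from, fam_to) == ("branch_fixed1", "branch_one_ratio"):
        out["omega"] = 1.0
    elif (fam_from, fam_to) == ("branch_one_ratio", "branch_two_ratio"):
        out["omega_bg"] = src["omega"]
        out["omega_fg"] = src["omega"]
    elif (fam_from, fam_to) == ("branch_two_ratio_fg1", "branch_two_ratio"):
        out["omega_bg"] = src["omega_bg"]
        out["omega_fg"] = 1.0
    elif (fam_from, fam_to) == ("branch_one_ratio", "branch_two_ratio_fg1"):
        out["omega_bg"] = src["omega"]
    elif fam_to == "branch_free":
        for br in tree.branches:
            if fam_from == "branch_one_ratio":
                out[f"omega_{br.name}"] = src["omega"]
            elif fam_from == "branch_two_ratio":
                out[f"omega_{br.name}"] = (
                    src["omega_fg"]
                    if br.tag in spec.foreground
                    else src["omega_bg"]
                )
    elif (fam_from, fam_to) == ("site_M1a", "site_M2a"):
        out["v1"] = src["p0"]
        out["v2"] = 1 - 1e-4
        out["omega0"] = src["omega0"]
        out["omega2"] = 1.0
    elif (fam_from, fam_to) == ("site_M8a", "site_M8"):
        out = dict(src)
        out["omega_s"] = 1.0
    elif (fam_from, fam_to) == ("clade_M2a_rel", "clade_C"):
        out = dict(src)
        out["omega3"] = src["omega2"]
    return out


def fit(
    aln: CodonAlignment,
    tree: PhyloTree,
    spec: ModelSpec,
    options: FitOptions | None = None,
    pi: np.ndarray | None = None,
) -> ModelFit:
    """Maximum-likelihood fit by bounded quasi-Newton (L-BFGS-B) over log
    branch lengths, log kappa and transformed family parameters.

    Multi-start (seeded) with optional warm start from a nested null fit;
    the converged flag reflects the optimizer outcome honestly.
    """
    if options is None:
        options = FitOptions()
    if pi is None:
        pi = estimate_frequencies(aln).pi
    patterns, weights = aln.patterns()
    tindex = _TreeIndex.build(tree, aln.taxa)
    layout = _family_layout(spec, tree)
    nb = tree.n_branches
    t_lo, t_hi = options.t_bounds
    k_lo, k_hi = options.kappa_bounds

    # free-ratio classes resolved per-branch; others via roles
    branch_free = spec.family == "branch_free"

    def unpack(x: np.ndarray):
        t = np.exp(x[:nb])
        kappa = float(np.exp(x[nb]))
        vals: dict[str, float] = {}
        for k, (name, lo, hi, init, logscale) in enumerate(layout):
            v = x[nb + 1 + k]
            vals[name] = float(np.exp(v)) if logscale else float(v)
        return t, kappa, vals

    n_evals = 0

    def negloglik(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        t, kappa, vals = unpack(x)
        if branch_free:
            omega_vec = np.array([vals[f"omega_{n}"] for n in tindex.branch_names])
            class_omegas = [(1.0, omega_vec)]
        else:
            classes = site_classes(spec, vals)
            class_omegas = _resolve_omegas(classes, tindex, spec.foreground)
        try:
            lnl = _mixture_loglik(
                patterns, weights, tindex, class_omegas, kappa, pi, t
            )
        except (np.linalg.LinAlgError, ValueError):
            return 1e12
        if not np.isfinite(lnl):
            return 1e12
        return -lnl

    # bounds in transformed space
    bounds = [(np.log(t_lo), np.log(t_hi))] * nb + [(np.log(k_lo), np.log(k_hi))]
    for name, lo, hi, init, logscale in layout:
        bounds.append((np.log(lo), np.log(hi)) if logscale else (lo, hi))

    # starting points
    warm = options.warm_start
    t0 = _branch_length_vector(tree, None)
    if warm is not None:
        for name, val in warm.branch_lengths.items():
            t0[tree.branch(name).index] = val
    elif not options.use_tree_lengths or (t0 <= 0).all():
        t0 = np.full(nb, options.branch_length_init)
    t0 = np.clip(t0, t_lo, t_hi)
    kappa0 = warm.kappa if warm is not None else options.kappa_init
    fam0 = {name: init for name, lo, hi, init, _ in layout}
    if warm is not None:
        fam0.update(
            {
                k: v
                for k, v in _embed_warm_start(warm, spec, tree).items()
                if k in fam0
            }
        )

    def pack(t, kappa, vals) -> np.ndarray:
        x = np.empty(nb + 1 + len(layout))
        x[:nb] = np.log(np.clip(t, t_lo, t_hi))
        x[nb] = np.log(np.clip(kappa, k_lo, k_hi))
        for k, (name, lo, hi, init, logscale) in enumerate(layout):
            v = np.clip(vals[name], lo, hi)
            x[nb + 1 + k] = np.log(v) if logscale else v
        return x

    rng = np.random.default_rng(options.seed)
    starts = [pack(t0, kappa0, fam0)]
    for _ in range(max(0, options.n_starts - 1)):
        jitter = {
            name: np.clip(
                fam0[name] * np.exp(rng.normal(0, 0.5)), lo, hi
            )
            if logscale
            else np.clip(fam0[name] + rng.normal(0, 0.15), lo, hi)
            for name, lo, hi, init, logscale in layout
        }
        tj = np.clip(t0 * np.exp(rng.normal(0, 0.5, size=nb)), t_lo, t_hi)
        kj = np.clip(kappa0 * np.exp(rng.normal(0, 0.3)), k_lo, k_hi)
        starts.append(pack(tj, kj, jitter))

    best = None
    for x0 in starts:
        res = minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options=dict(maxiter=options.maxiter, ftol=options.ftol, maxfun=200000),
        )
        if best is None or res.fun < best.fun:
            best = res

    t_hat, kappa_hat, vals_hat = unpack(best.x)
    branch_lengths = {
        br.name: float(t_hat[br.index]) for br in tree.branches
    }
    return ModelFit(
        spec=spec,
        kappa=kappa_hat,
        params=vals_hat,
        branch_lengths=branch_lengths,
        lnL=float(-best.fun),
        np=n_free_parameters(spec, tree),
        converged=bool(best.success),
        n_evals=n_evals,
        pi=pi,
    )
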