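"""Four-cluster likelihood mapping (FcLM) on the quartet simplex.

FcLM probes the phylogenetic signal around one internal branch: taxa are
assigned to four clusters assumed monophyletic, and for every quartet
(one taxon per cluster) the maximum log-likelihoods of the three unrooted
quartet topologies

    T1 = (a,b | c,d)    T2 = (a,c | b,d)    T3 = (a,d | b,c)

are computed under a simple substitution model (Jukes-Cantor for
nucleotides, Poisson for amino acids).  The likelihoods are converted to
posterior weights ``p_i = exp(l_i - logsumexp(l))`` — a point on the
2-simplex — and each quartet is binned into one of seven regions: three
corners (resolved, one topology dominates), three edges (inconclusive
between two topologies) and the centre (star-like, no support).  The
proportion of quartets per region summarises how decisively the data
choose among the three resolutions.

Likelihoods are computed by Felsenstein pruning on the 5-branch quartet
tree, with each branch length optimised by cyclic bounded 1-D search.
Columns with a gap or ambiguity in any of the four taxa are skipped.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

__all__ = [
    "SubstitutionModel",
    "JC69",
    "POISSON",
    "ClusterAssignment",
    "SimplexPoint",
    "QuartetResult",
    "FclmResult",
    "enumerate_quartets",
    "quartet_log_likelihoods",
    "posterior_weights",
    "assign_region",
    "fclm_summary",
    "run_fclm",
]

BL_MIN, BL_MAX, BL_INIT = 1e-8, 10.0, 0.1
REL_TOL = 1e-6
MAX_SWEEPS = 100


@dataclass(frozen=True)
class SubstitutionModel:
    """Equal-rates, equal-frequencies model with k states (JC69 / Poisson)."""

    name: str
    alphabet: str

    @property
    def k(self) -> int:
        return len(self.alphabet)

    def p_same(self, t: float) -> float:
        k = self.k
        return 1.0 / k + (1.0 - 1.0 / k) * np.exp(-k * t / (k - 1))

    def p_diff(self, t: float) -> float:
        k = self.k
        return 1.0 / k * (1.0 - np.exp(-k * t / (k - 1)))

    def encode(self, seq: str) -> np.ndarray:
        """State indices; -1 for gap/ambiguity."""
        lut = {c: i for i, c in enumerate(self.alphabet)}
        return np.array([lut.get(c, -1) for c in seq.upper()], dtype=np.int64)


JC69 = SubstitutionModel("JC69", "ACGT")
POISSON = SubstitutionModel("Poisson", "ACDEFGHIKLMNPQRSTVWY")

CLUSTER_LABELS = ("C1", "C2", "C3", "C4")
REGIONS = ("R1", "R2", "R3", "R12", "R13", "R23", "Rc")

_ATTRACTORS = {
    "R1": (1.0, 0.0, 0.0),
    "R2": (0.0, 1.0, 0.0),
    "R3": (0.0, 0.0, 1.0),
    "R12": (0.5, 0.5, 0.0),
    "R13": (0.5, 0.0, 0.5),
    "R23": (0.0, 0.5, 0.5),
    "Rc": (1 / 3, 1 / 3, 1 / 3),
}
# tie precedence: corners, then edges, then centre; lowest index first
_REGION_ORDER = ("R1", "R2", "R3", "R12", "R13", "R23", "Rc")


@dataclass
class ClusterAssignment:
    """Taxon -> cluster label in {C1..C4, ignore}."""

    assignment: dict[str, str]

    @classmethod
    def from_tsv(cls, path: str) -> "ClusterAssignment":
        assignment = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                taxon, label = line.split("\t")
                label = label.strip().upper()
                if label not in CLUSTER_LABELS and label != "IGNORE":
                    raise ValueError(f"unknown cluster label {label!r} for {taxon}")
                assignment[taxon.strip()] = label if label != "IGNORE" else "ignore"
        return cls(assignment)

    def cluster(self, label: str) -> list[str]:
        return sorted(t for t, c in self.assignment.items() if c == label)


SimplexPoint = tuple[float, float, float]


@dataclass
class QuartetResult:
    quartet: tuple[str, str, str, str]
    log_likelihoods: tuple[float, float, float]
    weights: SimplexPoint
    region: str
    n_sites: int


@dataclass
class FclmResult:
    counts: dict[str, int]
    proportions: dict[str, float]
    n_quartets: int
    n_skipped: int = 0
    quartets: list[QuartetResult] = field(default_factory=list)

    @property
    def resolved(self) -> float:
        return sum(self.proportions[r] for r in ("R1", "R2", "R3"))

    @property
    def partly_resolved(self) -> float:
        return sum(self.proportions[r] for r in ("R12", "R13", "R23"))

    @property
    def unresolved(self) -> float:
        return self.proportions["Rc"]


def enumerate_quartets(
    clusters: ClusterAssignment, alignment_taxa: set[str] | None = None
) -> list[tuple[str, str, str, str]]:
    """Cartesian product C1 x C2 x C3 x C4 in deterministic (sorted) order."""
    groups = []
    for label in CLUSTER_LABELS:
        members = clusters.cluster(label)
        if not members:
            raise ValueError(f"cluster {label} is empty")
        if alignment_taxa is not None:
            missing = sorted(set(members) - alignment_taxa)
            if missing:
                raise ValueError(
                    f"taxa in cluster {label} absent from alignment: {missing}"
                )
        groups.append(members)
    return list(itertools.product(*groups))


def _pattern_counts(
    seqs: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Compress usable columns (all four states valid) to unique patterns.

    Returns (patterns[n,4], counts[n])."""
    mat = np.stack(seqs, axis=1)  # sites x 4
    ok = (mat >= 0).all(axis=1)
    mat = mat[ok]
    if mat.shape[0] == 0:
        return np.empty((0, 4), dtype=np.int64), np.empty(0, dtype=np.int64)
    patterns, counts = np.unique(mat, axis=0, return_counts=True)
    return patterns, counts


def _topology_loglik(
    patterns: np.ndarray,
    counts: np.ndarray,
    bl: np.ndarray,
    pair_order: tuple[int, int, int, int],
    model: SubstitutionModel,
) -> float:
    """Log-likelihood of the quartet tree ((i,j),(k,l)) with branch lengths
    bl = (t_i, t_j, t_k, t_l, t_internal), by pruning.

    States are equal-frequency; transition probabilities depend only on
    whether the two states agree, which lets everything reduce to indicator
    algebra over the k internal states.
    """
    k = model.k
    i, j, kk, ll = pair_order
    # Indicators: I[p, x] = 1 when internal state x equals the tip state.
    states = np.arange(k)
    Ii = (patterns[:, i : i + 1] == states).astype(float)
    Ij = (patterns[:, j : j + 1] == states).astype(float)
    Ik = (patterns[:, kk : kk + 1] == states).astype(float)
    Il = (patterns[:, ll : ll + 1] == states).astype(float)

    def tip(t: float, I: np.ndarray) -> np.ndarray:
        s, d = model.p_same(t), model.p_diff(t)
        return d + (s - d) * I

    Lu = tip(bl[0], Ii) * tip(bl[1], Ij)  # partials at internal node u
    Lv = tip(bl[2], Ik) * tip(bl[3], Il)  # partials at internal node v
    s5, d5 = model.p_same(bl[4]), model.p_diff(bl[4])
    # (P5 @ Lv)[x] = d5 * sum(Lv) + (s5 - d5) * Lv[x]
    Pv = d5 * Lv.sum(axis=1, keepdims=True) + (s5 - d5) * Lv
    site_like = (Lu * Pv).sum(axis=1) / k  # uniform root frequencies
    return float(np.dot(counts, np.log(site_like)))


_PAIR_ORDERS = {
    0: (0, 1, 2, 3),  # T1 = (a,b | c,d)
    1: (0, 2, 1, 3),  # T2 = (a,c | b,d)
    2: (0, 3, 1, 2),  # T3 = (a,d | b,c)
}


def _maximize_topology(
    patterns: np.ndarray,
    counts: np.ndarray,
    pair_order: tuple[int, int, int, int],
    model: SubstitutionModel,
) -> float:
    """Maximise the quartet log-likelihood over its 5 branch lengths by
    cyclic bounded 1-D optimisation (deterministic init 0.1)."""
    bl = np.full(5, BL_INIT)
    prev = _topology_loglik(patterns, counts, bl, pair_order, model)
    for _ in range(MAX_SWEEPS):
        for b in range(5):
            def f(t: float, b: int = b) -> float:
                trial = bl.copy()
                trial[b] = t
                return -_topology_loglik(patterns, counts, trial, pair_order, model)

            res = minimize_scalar(
                f, bounds=(BL_MIN, BL_MAX), method="bounded",
                options={"xatol": 1e-8},
            )
            if -res.fun >= _topology_loglik(patterns, counts, bl, pair_order, model):
                bl[b] = res.x
        cur = _topology_loglik(patterns, counts, bl, pair_order, model)
        if cur - prev <= REL_TOL * max(1.0, abs(cur)):
            break
        prev = cur
    return _topology_loglik(patterns, counts, bl, pair_order, model)


def quartet_log_likelihoods(
    rows: dict[str, str],
    quartet: tuple[str, str, str, str],
    model: SubstitutionModel = JC69,
) -> tuple[float, float, float] | None:
    """Maximised log-likelihoods (l1, l2, l3) of the three topologies.

    Columns with a gap or ambiguous state in any quartet member are
    skipped; returns ``None`` (with a warning) when no usable column
    remains.
    """
    seqs = tuple(model.encode(rows[t]) for t in quartet)
    patterns, counts = _pattern_counts(seqs)
    if counts.sum() == 0:
        warnings.warn(f"quartet {quartet}: no usable columns; skipped")
        return None
    return tuple(
        _maximize_topology(patterns, counts, _PAIR_ORDERS[i], model) for i in range(3)
    )


def posterior_weights(log_likelihoods: tuple[float, float, float]) -> SimplexPoint:
    """Softmax of the three log-likelihoods (numerically stable)."""
    l = np.asarray(log_likelihoods, dtype=float)
    if not np.all(np.isfinite(l)):
        raise ValueError("log-likelihoods must be finite")
    w = np.exp(l - logsumexp(l))
    w = w / w.sum()
    return (float(w[0]), float(w[1]), float(w[2]))


def assign_region(p: SimplexPoint) -> str:
    """Nearest attractor among the three corners, three edge midpoints and
    the centre; ties break toward the more resolved region (corner > edge >
    centre), then the lowest index."""
    arr = np.asarray(p, dtype=float)
    best_region, best_d = None, np.inf
    for region in _REGION_ORDER:
        d = float(np.sum((arr - np.asarray(_ATTRACTORS[region])) ** 2))
        if d < best_d - 1e-15:
            best_region, best_d = region, d
    return best_region


def fclm_summary(results: list[QuartetResult], n_skipped: int = 0) -> FclmResult:
    if not results:
        raise ValueError("no quartet results to summarise")
    counts = Counter(r.region for r in results)
    n = len(results)
    full_counts = {r: counts.get(r, 0) for r in REGIONS}
    proportions = {r: full_counts[r] / n for r in REGIONS}
    return FclmResult(full_counts, proportions, n, n_skipped, results)


def run_fclm(
    rows: dict[str, str],
    clusters: ClusterAssignment,
    model: SubstitutionModel = JC69,
) -> FclmResult:
    """End-to-end FcLM: enumerate quartets, maximise per-topology
    likelihoods, map to the simplex and summarise region occupancy."""
    quartets = enumerate_quartets(clusters, set(rows))
    results: list[QuartetResult] = []
    skipped = 0
    for q in quartets:
        lls = quartet_log_likelihoods(rows, q, model)
        if lls is None:
            skipped += 1
            continue
        w = posterior_weights(lls)
        n_sites = int(
            _pattern_counts(tuple(model.encode(rows[t]) for t in q))[1].sum()
        )
        results.append(QuartetResult(q, lls, w, assign_region(w), n_sites))
    return fclm_summary(results, skipped)
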