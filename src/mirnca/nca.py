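"""Network component analysis (NCA).

NCA decomposes a target-gene expression matrix ``E`` (N genes x M time
points) into a control-strength matrix ``C`` (N x L) and a regulator
activity matrix ``T`` (L x M),

    E = C @ T,        C constrained to a fixed 0/1 support Z0,

by minimizing the Frobenius residual ``||E - C T||`` subject to ``C``
vanishing off the support. The support Z0 encodes which regulator (miRNA
or transcription factor) is allowed to act on which target gene, taken
from curated interaction databases. The decomposition is unique up to a
diagonal rescaling of the regulators provided three structural criteria
hold:

1. the support admits a full-column-rank ``C``;
2. removing any one regulator together with all of its targets leaves a
   support that still admits full column rank;
3. there are at least as many time points as regulators, so ``T`` can
   have full row rank.

This module provides the criteria check, greedy reduction of an
incompatible network to a compatible sub-network, the two-step
alternating least-squares solver, and the canonical post-hoc scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "ConnectivityPattern",
    "CriteriaReport",
    "NCADecomposition",
    "IncompatiblePatternError",
    "NoCompatibleSubnetworkError",
    "check_nca_criteria",
    "reduce_to_compatible",
    "nca_decompose",
    "normalize_decomposition",
]

#: singular values below RANK_TOL * s_max are treated as zero
RANK_TOL = 1e-8


class IncompatiblePatternError(ValueError):
    """Raised when a connectivity pattern violates the NCA criteria."""


class NoCompatibleSubnetworkError(ValueError):
    """Raised when no NCA-compatible sub-network exists."""


@dataclass
class ConnectivityPattern:
    """Bipartite regulator -> target 0/1 support.

    ``support[n, l] == 1`` means regulator ``l`` may control target ``n``.
    """

    regulators: list[str]
    targets: list[str]
    support: np.ndarray  # (N, L) int8

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=np.int8)
        n, l = self.support.shape
        if n != len(self.targets) or l != len(self.regulators):
            raise ValueError(
                f"support shape {self.support.shape} inconsistent with "
                f"{len(self.targets)} targets x {len(self.regulators)} regulators"
            )

    @property
    def n_regulators(self) -> int:
        return len(self.regulators)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def target_sets(self) -> dict[str, frozenset[str]]:
        """Map each regulator to its set of target IDs."""
        t = np.asarray(self.targets, dtype=object)
        return {
            reg: frozenset(t[self.support[:, j] == 1])
            for j, reg in enumerate(self.regulators)
        }

    def to_edges(self) -> list[tuple[str, str]]:
        """Regulator->target edge list in row-major support order."""
        rows, cols = np.nonzero(self.support)
        return [(self.regulators[j], self.targets[i]) for i, j in zip(rows, cols)]

    @classmethod
    def from_edges(cls, edges) -> "ConnectivityPattern":
        """Build from (regulator, target) pairs, first-seen ordering."""
        regulators: list[str] = []
        targets: list[str] = []
        rpos: dict[str, int] = {}
        tpos: dict[str, int] = {}
        pairs = []
        for reg, tg in edges:
            if reg not in rpos:
                rpos[reg] = len(regulators)
                regulators.append(reg)
            if tg not in tpos:
                tpos[tg] = len(targets)
                targets.append(tg)
            pairs.append((tpos[tg], rpos[reg]))
        support = np.zeros((len(targets), len(regulators)), dtype=np.int8)
        for i, j in pairs:
            support[i, j] = 1
        return cls(regulators=regulators, targets=targets, support=support)


@dataclass
class CriteriaReport:
    """Outcome of the three NCA identifiability criteria."""

    criterion1: bool
    criterion2: dict[str, bool]  # per-regulator: reduced network keeps rank
    criterion3: bool
    offending_regulators: list[str] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return self.criterion1 and self.criterion3 and all(self.criterion2.values())


@dataclass
class NCADecomposition:
    """Result of the alternating least-squares decomposition.

    ``C`` is zero off the support; ``residual_trace`` is the Frobenius
    residual recorded after every full iteration and is non-increasing.
    """

    regulators: list[str]
    targets: list[str]
    C: np.ndarray  # (N, L)
    T: np.ndarray  # (L, M)
    residual_trace: list[float]
    converged: bool
    n_iter: int
    seed: int
    zero_activity: list[str] = field(default_factory=list)

    def activities(self, times=None) -> pd.DataFrame:
        cols = times if times is not None else range(self.T.shape[1])
        return pd.DataFrame(self.T, index=self.regulators, columns=list(cols))

    def control_strengths(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=self.targets, columns=self.regulators)


def _numeric_rank(a: np.ndarray) -> int:
    if a.size == 0:
        return 0
    s = np.linalg.svd(a, compute_uv=False)
    return int(np.sum(s > RANK_TOL * s[0])) if s[0] > 0 else 0


def _support_rank(support: np.ndarray, rng: np.random.Generator, n_draws: int = 3) -> int:
    """Generic (structural) rank of matrices carried by a 0/1 support.

    The rank of a random continuous matrix on the support equals the
    maximal rank over the support almost surely; the max over a few
    draws guards against an unlucky realization.
    """
    if support.size == 0 or support.sum() == 0:
        return 0
    best = 0
    for _ in range(n_draws):
        m = support * rng.standard_normal(support.shape)
        best = max(best, _numeric_rank(m))
        if best == min(support.shape):
            break
    return best


def check_nca_criteria(
    Z0: ConnectivityPattern, n_timepoints: int, seed: int = 0
) -> CriteriaReport:
    """Evaluate the three NCA identifiability criteria on a support.

    Criterion 1: the support admits full column rank L. Criterion 2, per
    regulator: deleting that regulator's column and every target row it
    touches leaves a support of rank L-1 (vacuously true for L = 1).
    Criterion 3: ``n_timepoints >= L`` so the activity matrix can have
    full row rank.
    """
    if Z0.n_regulators == 0 or Z0.n_targets == 0:
        raise ValueError("empty connectivity pattern")
    rng = np.random.default_rng(seed)
    L = Z0.n_regulators
    support = Z0.support

    criterion1 = _support_rank(support, rng) == L

    criterion2: dict[str, bool] = {}
    offending: list[str] = []
    for j, reg in enumerate(Z0.regulators):
        keep_rows = support[:, j] == 0
        keep_cols = np.arange(L) != j
        sub = support[np.ix_(keep_rows, keep_cols)]
        ok = _support_rank(sub, rng) == L - 1
        criterion2[reg] = ok
        if not ok:
            offending.append(reg)

    criterion3 = n_timepoints >= L
    return CriteriaReport(
        criterion1=criterion1,
        criterion2=criterion2,
        criterion3=criterion3,
        offending_regulators=offending,
    )


def reduce_to_compatible(
    Z0: ConnectivityPattern, n_timepoints: int, seed: int = 0
) -> tuple[ConnectivityPattern, list[dict]]:
    """Greedily prune a pattern until the NCA criteria hold.

    At each step the offending regulator with the smallest target set is
    removed (ties broken lexicographically by ID); targets left without
    any regulator are pruned, which can in turn empty other regulators.
    When the violation carries no per-regulator attribution (criterion 1
    or 3), every remaining regulator is a removal candidate.

    Returns the reduced pattern and a log of removal records
    ``{"regulator": id, "n_targets": k, "orphaned_targets": [...]}``.
    """
    regulators = list(Z0.regulators)
    targets = list(Z0.targets)
    support = Z0.support.copy()
    log: list[dict] = []

    while True:
        if not regulators or not targets:
            raise NoCompatibleSubnetworkError(
                "no compatible sub-network: reduction emptied the pattern"
            )
        pattern = ConnectivityPattern(regulators, targets, support)
        report = check_nca_criteria(pattern, n_timepoints, seed=seed)
        if report.all_pass:
            return pattern, log

        candidates = report.offending_regulators or list(regulators)
        degrees = support.sum(axis=0)
        j = min(
            (regulators.index(r) for r in candidates),
            key=lambda k: (degrees[k], regulators[k]),
        )
        removed = regulators[j]
        removed_deg = int(degrees[j])

        keep_cols = np.arange(len(regulators)) != j
        support = support[:, keep_cols]
        regulators = [r for k, r in enumerate(regulators) if k != j]

        orphan_mask = support.sum(axis=1) == 0
        orphans = [t for t, o in zip(targets, orphan_mask) if o]
        support = support[~orphan_mask]
        targets = [t for t, o in zip(targets, orphan_mask) if not o]

        # pruning orphans can empty further regulator columns
        empty_cols = support.sum(axis=0) == 0 if support.size else np.array([], bool)
        if empty_cols.any():
            for r, e in zip(list(regulators), empty_cols):
                if e:
                    log.append(
                        {"regulator": r, "n_targets": 0, "orphaned_targets": []}
                    )
            support = support[:, ~empty_cols]
            regulators = [r for r, e in zip(regulators, empty_cols) if not e]

        log.append(
            {
                "regulator": removed,
                "n_targets": removed_deg,
                "orphaned_targets": orphans,
            }
        )


def normalize_decomposition(
    C: np.ndarray, T: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Map (C, T) to the canonical representative of its scaling gauge.

    Any diagonal nonsingular S gives an equivalent solution (C S, S^-1 T).
    The canonical choice scales each activity row to max |value| = 1 and
    fixes its sign so that the matching control-strength column has a
    non-negative sum (positive on a tie). The product C @ T is preserved
    exactly. Zero activity rows are left at scale 1 and their indices
    returned as flags.
    """
    C = np.array(C, dtype=float)
    T = np.array(T, dtype=float)
    if C.shape[1] != T.shape[0]:
        raise ValueError("C columns must match T rows")
    flagged: list[int] = []
    for l in range(T.shape[0]):
        s = np.max(np.abs(T[l]))
        if s == 0.0:
            flagged.append(l)
            continue
        col_sum = C[:, l].sum()
        sigma = -1.0 if col_sum < 0 else 1.0
        T[l] /= sigma * s
        C[:, l] *= sigma * s
    return C, T, flagged


def _solve_C(E, T, row_groups):
    """Step A: support-restricted least squares for each target row.

    Rows sharing a support pattern are solved together through the
    normal equations of the shared sub-matrix of T.
    """
    N = E.shape[0]
    L = T.shape[0]
    C = np.zeros((N, L))
    for idx, rows in row_groups:
        Tsub = T[idx]  # (k, M)
        G = Tsub @ Tsub.T
        B = Tsub @ E[rows].T  # (k, n_rows)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                sol = scipy.linalg.solve(G, B, assume_a="pos")
        except (scipy.linalg.LinAlgError, ValueError):
            sol, *_ = np.linalg.lstsq(Tsub.T, E[rows].T, rcond=None)
        C[np.ix_(rows, idx)] = sol.T
    return C


def nca_decompose(
    E,
    Z0: ConnectivityPattern,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
    seed: int = 0,
) -> NCADecomposition:
    """Estimate C and T by two-step alternating least squares.

    Each iteration solves C given T (per-target, restricted to the
    support) and then T given C (full least squares); both are exact
    least-squares steps, so the Frobenius residual is non-increasing.
    Iteration stops when the relative residual change drops below
    ``tol`` or after ``max_iter`` iterations; the best of ``n_restarts``
    random initializations of T is kept and canonically normalized.

    ``E`` may be an (N, M) array aligned with ``Z0.targets`` or a
    DataFrame indexed by gene ID (reindexed to the targets; missing rows
    are an error).
    """
    if isinstance(E, pd.DataFrame):
        missing = [t for t in Z0.targets if t not in E.index]
        if missing:
            raise ValueError(f"expression matrix missing targets: {missing[:10]}")
        E = E.loc[Z0.targets].to_numpy(dtype=float)
    E = np.asarray(E, dtype=float)
    N, M = E.shape
    L = Z0.n_regulators
    if N != Z0.n_targets:
        raise ValueError(f"E has {N} rows but Z0 has {Z0.n_targets} targets")

    report = check_nca_criteria(Z0, M)
    if not report.all_pass:
        raise IncompatiblePatternError(
            "connectivity pattern violates the NCA criteria "
            f"(offending regulators: {report.offending_regulators}); "
            "apply reduce_to_compatible first"
        )

    # group target rows by identical support pattern for batched solves
    groups: dict[bytes, list[int]] = {}
    for n in range(N):
        groups.setdefault(Z0.support[n].tobytes(), []).append(n)
    row_groups = [
        (np.nonzero(np.frombuffer(key, dtype=np.int8))[0], np.array(rows))
        for key, rows in groups.items()
    ]

    e_norm = np.linalg.norm(E)
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    failures = 0
    for child in children:
        rng = np.random.default_rng(child)
        T = rng.standard_normal((L, M))
        trace: list[float] = []
        converged = False
        prev = np.inf
        for _ in range(max_iter):
            C = _solve_C(E, T, row_groups)
            if _numeric_rank(C) < L:
                failures += 1
                trace = []
                break
            T, *_ = np.linalg.lstsq(C, E, rcond=None)
            resid = float(np.linalg.norm(E - C @ T))
            trace.append(resid)
            if np.isfinite(prev) and prev - resid <= tol * max(prev, 1e-300):
                converged = True
                break
            prev = resid
        if not trace:
            continue
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], C, T, trace, converged)

    if best is None:
        raise RuntimeError(
            f"all {n_restarts} restarts hit rank-deficient intermediate solves"
        )
    _, C, T, trace, converged = best
    # degenerate gauge: a regulator with no true signal can converge to a
    # C column collinear with the others while its activity row absorbs a
    # combination of live activities. Zero any row whose removal leaves
    # the fit unchanged (to RANK_TOL of the data norm).
    base = trace[-1]
    for l in range(L):
        if np.max(np.abs(T[l])) == 0.0:
            continue
        T_try = T.copy()
        T_try[l] = 0.0
        C_try = _solve_C(E, T_try, row_groups)
        resid_try = float(np.linalg.norm(E - C_try @ T_try))
        if resid_try - base <= RANK_TOL * max(e_norm, 1e-300):
            T, C, base = T_try, C_try, resid_try
    C, T, flagged = normalize_decomposition(C, T)
    zero_rows = [Z0.regulators[l] for l in flagged]
    return NCADecomposition(
        regulators=list(Z0.regulators),
        targets=list(Z0.targets),
        C=C,
        T=T,
        residual_trace=trace,
        converged=converged,
        n_iter=len(trace),
        seed=seed,
        zero_activity=zero_rows,
    )
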