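"""Synthetic study generator.

Emulates the shape of the data the pipeline consumes: a curated
regulator->target connectivity pattern, smooth ground-truth regulator
activities over a 17-point / 72-hour time grid, log2 expression built as
``E = C @ T`` plus Gaussian noise, and two-channel raw replicate arrays
(control vs treatment, two replicates) carrying the artifacts the
preprocessing stage is designed to remove: a smooth intensity-dependent
log-ratio bias (exercising loess) and per-column affine distortions
(exercising quantile normalization).

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nca import ConnectivityPattern, check_nca_criteria

__all__ = [
    "TimeGrid",
    "GroundTruth",
    "RawMicroarray",
    "default_grid",
    "generate_connectivity",
    "generate_activities",
    "generate_control_strengths",
    "generate_ground_truth",
    "generate_expression",
    "generate_raw_microarray",
]

#: 17 time points spanning 0-72 h (minutes), denser early as is usual
#: for growth-factor stimulation time courses
DEFAULT_TIMES = (
    0, 10, 15, 30, 60, 120, 180, 240, 360, 480,
    720, 1080, 1440, 2160, 2880, 3600, 4320,
)


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sampling times in minutes."""

    times: tuple[float, ...] = DEFAULT_TIMES

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2:
            raise ValueError("a time grid needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time stamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


def default_grid() -> TimeGrid:
    return TimeGrid()


@dataclass
class GroundTruth:
    """Planted system behind a synthetic expression matrix."""

    Z0: ConnectivityPattern
    C_true: np.ndarray  # (N, L), zero off the support of Z0
    T_true: np.ndarray  # (L, M)
    grid: TimeGrid
    noise_sd: float
    seed: int
    effect_genes: list[str] = field(default_factory=list)


@dataclass
class RawMicroarray:
    """Raw two-channel replicate arrays, genes x time points x replicates."""

    genes: list[str]
    grid: TimeGrid
    control: np.ndarray  # (N, M, R) log2 intensities
    treatment: np.ndarray  # (N, M, R) log2 intensities
    effect_genes: list[str]
    planted_lfc: np.ndarray  # (N, M) log2 fold changes planted on treatment


def generate_connectivity(
    n_regulators: int,
    n_targets: int,
    targets_per_regulator: tuple[int, int] = (3, 8),
    compatible: bool = True,
    seed: int = 0,
) -> ConnectivityPattern:
    """Draw a random miRTarBase-style bipartite 0/1 support.

    With ``compatible=True`` the pattern is regenerated (incrementing a
    seed salt) until it passes all three NCA criteria, so the returned
    support is identifiable by construction. With ``compatible=False``
    the first two regulators are given identical target sets, which
    violates criterion 2.
    """
    if n_regulators < 2 or n_targets <= n_regulators:
        raise ValueError("need n_targets > n_regulators >= 2")
    lo, hi = targets_per_regulator
    if not (1 <= lo <= hi <= n_targets):
        raise ValueError(
            f"targets_per_regulator {targets_per_regulator} infeasible "
            f"for {n_targets} targets"
        )
    regulators = [f"mir-{j + 1:03d}" for j in range(n_regulators)]
    targets = [f"gene-{i + 1:04d}" for i in range(n_targets)]

    for salt in range(100):
        rng = np.random.default_rng((seed, salt))
        support = np.zeros((n_targets, n_regulators), dtype=np.int8)
        for j in range(n_regulators):
            k = int(rng.integers(lo, hi + 1))
            support[rng.choice(n_targets, size=k, replace=False), j] = 1
        if not compatible:
            support[:, 1] = support[:, 0]  # duplicate support: criterion 2 fails
            orphan = support.sum(axis=1) == 0
            support[orphan, 0] = support[orphan, 1] = 1  # keep the duplication
            return ConnectivityPattern(regulators, targets, support)
        # every target must belong to some regulator; single-entry rows
        # cannot lower any criterion rank, so compatibility is unaffected
        orphan = np.nonzero(support.sum(axis=1) == 0)[0]
        support[orphan, rng.integers(0, n_regulators, size=orphan.size)] = 1
        pattern = ConnectivityPattern(regulators, targets, support)
        if check_nca_criteria(pattern, n_timepoints=n_regulators).all_pass:
            return pattern
    raise RuntimeError(
        "could not place a compatible pattern; request more targets or "
        "fewer regulators"
    )


def generate_activities(
    n_regulators: int,
    grid: TimeGrid | None = None,
    n_harmonics: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Smooth random activity profiles, one row per regulator.

    Each row is a low-order Fourier series over the grid span with
    standard-normal coefficients, rescaled to max |value| = 1 — the
    peaked/periodic shapes typical of reconstructed regulator activity.
    The returned matrix has full row rank (redrawn until it does).
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    grid = grid or default_grid()
    # rows live in the (2H+1)-dimensional space spanned by the Fourier
    # basis on the grid; full row rank is impossible beyond that
    if 2 * n_harmonics + 1 < n_regulators:
        raise ValueError(
            f"{n_harmonics} harmonics span only {2 * n_harmonics + 1} dimensions; "
            f"cannot give {n_regulators} full-rank rows"
        )
    if len(grid) < n_regulators:
        raise ValueError("grid shorter than the number of regulators")
    t = grid.array - grid.times[0]
    period = grid.span
    rng = np.random.default_rng(seed)
    for _ in range(100):
        rows = np.empty((n_regulators, len(grid)))
        for l in range(n_regulators):
            y = rng.normal(scale=0.5) * np.ones_like(t)
            for k in range(1, n_harmonics + 1):
                y = (
                    y
                    + rng.standard_normal() * np.cos(2 * np.pi * k * t / period)
                    + rng.standard_normal() * np.sin(2 * np.pi * k * t / period)
                )
            rows[l] = y / np.max(np.abs(y))
        if np.linalg.matrix_rank(rows) == n_regulators:
            return rows
    raise RuntimeError("failed to draw a full-row-rank activity matrix")


def generate_control_strengths(
    Z0: ConnectivityPattern, seed: int = 0, magnitude: tuple[float, float] = (0.2, 2.0)
) -> np.ndarray:
    """Signed control strengths on the support, |value| in [0.2, 2].

    Magnitudes are bounded away from zero so every planted interaction
    is structurally meaningful; signs are symmetric (miRNAs repress,
    TFs activate or repress).
    """
    rng = np.random.default_rng(seed)
    lo, hi = magnitude
    mag = rng.uniform(lo, hi, size=Z0.support.shape)
    sign = rng.choice([-1.0, 1.0], size=Z0.support.shape)
    return Z0.support * mag * sign


def generate_ground_truth(
    n_regulators: int = 10,
    n_targets: int = 120,
    grid: TimeGrid | None = None,
    noise_sd: float = 0.1,
    n_harmonics: int = 3,
    seed: int = 0,
) -> GroundTruth:
    """Bundle a compatible pattern with planted C and T.

    Default scale (L=10 regulators, N=120 genes, M=17 time points) is
    the smallest at which criteria checks and recovery are non-trivial
    while tests stay fast. ``n_harmonics`` is raised when needed so the
    activity matrix can reach full row rank (2H + 1 >= L).
    """
    grid = grid or default_grid()
    n_harmonics = max(n_harmonics, -(-(n_regulators - 1) // 2))
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    Z0 = generate_connectivity(n_regulators, n_targets, compatible=True, seed=s1)
    C = generate_control_strengths(Z0, seed=s2)
    T = generate_activities(n_regulators, grid, n_harmonics=n_harmonics, seed=s3)
    if len(grid) < n_regulators:
        raise ValueError("grid shorter than the number of regulators (criterion 3)")
    return GroundTruth(
        Z0=Z0, C_true=C, T_true=T, grid=grid, noise_sd=noise_sd, seed=seed
    )


def generate_expression(truth: GroundTruth) -> np.ndarray:
    """Noisy log2 expression ``E = C_true @ T_true + N(0, noise_sd)``."""
    if truth.C_true.shape[1] != truth.T_true.shape[0]:
        raise ValueError("C_true / T_true dimension mismatch")
    if truth.T_true.shape[1] != len(truth.grid):
        raise ValueError("T_true does not match the time grid")
    rng = np.random.default_rng((truth.seed, 0xE))
    E = truth.C_true @ truth.T_true
    if truth.noise_sd > 0:
        E = E + rng.normal(scale=truth.noise_sd, size=E.shape)
    return E


def generate_raw_microarray(
    E: np.ndarray,
    genes: list[str],
    grid: TimeGrid,
    n_replicates: int = 2,
    bias_amplitude: float = 0.5,
    effect_genes: list[str] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> RawMicroarray:
    """Raw control/treatment replicate log2 intensities around E.

    ``E`` rows for ``effect_genes`` become planted treatment-vs-control
    log2 fold changes; all other genes carry none. Each replicate column
    adds i.i.d. Gaussian noise; the treatment channel additionally gets
    a smooth bias that depends on mean intensity A (removable by loess),
    and every column an affine distortion (removable by quantile
    normalization). Two replicates per condition mirror the usual
    two-replicate array design.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    E = np.asarray(E, dtype=float)
    N, M = E.shape
    if N != len(genes) or M != len(grid):
        raise ValueError("E shape inconsistent with genes/grid")
    effect_genes = list(effect_genes or [])
    unknown = set(effect_genes) - set(genes)
    if unknown:
        raise ValueError(f"effect genes not in gene list: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)

    base = rng.uniform(6.0, 12.0, size=N)  # per-gene baseline abundance (log2)
    lfc = np.zeros((N, M))
    idx = [genes.index(g) for g in effect_genes]
    lfc[idx] = E[idx]

    R = n_replicates
    control = base[:, None, None] + rng.normal(scale=noise_sd, size=(N, M, R))
    treatment = (
        base[:, None, None]
        + lfc[:, None].transpose(0, 2, 1)
        + rng.normal(scale=noise_sd, size=(N, M, R))
    )
    if bias_amplitude:
        # smooth intensity-dependent dye-bias on the log ratio, applied to
        # the treatment channel as a function of mean intensity A
        A = (control + treatment) / 2.0
        treatment = treatment + bias_amplitude * np.sin(
            np.pi * np.clip((A - 6.0) / 6.0, 0.0, 1.0)
        )
    # per-column affine distortion (scanner gain/offset)
    for arr in (control, treatment):
        gain = rng.uniform(0.95, 1.05, size=(1, M, R))
        offset = rng.uniform(-0.3, 0.3, size=(1, M, R))
        arr *= gain
        arr += offset
    return RawMicroarray(
        genes=list(genes),
        grid=grid,
        control=control,
        treatment=treatment,
        effect_genes=effect_genes,
        planted_lfc=lfc,
    )
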