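"""Block-design GLM pipeline for ROI-averaged BOLD time series.

Builds gamma-HRF regressors for a block schedule, fits an ordinary
least-squares GLM with intercept and linear drift, converts condition
betas to percent signal change (PSC), and derives the crowding and
anisotropy indices:

    C_axis  = PSC(target present) - PSC(target absent)
    A       = (C_radial - C_tangential) / (PSC_absent_radial + PSC_absent_tangential)

Note on the HRF: the parameter triple (delta, tau, alpha) is interpreted
as a shifted gamma-variate *impulse response*,
``h(t) = ((t-delta)/tau)**alpha * exp(-(t-delta)/tau)`` for ``t >= delta``,
the convention of the fMRI analysis toolkits these parameters originate
from.  A literal cumulative distribution function would saturate at 1 and
is not a plausible impulse response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .errors import ConfigError, DomainError, ScheduleError, SingularDesignError

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import BoldRun

AXES = ("radial", "tangential")
TARGETS = ("present", "absent")
#: canonical condition labels, "<axis>_<target>"
CONDITIONS = tuple(f"{a}_{t}" for a in AXES for t in TARGETS)

INTERCEPT = "intercept"
DRIFT = "drift"


@dataclass(frozen=True)
class HRFParams:
    """Shifted gamma-variate hemodynamic response parameters."""

    delta: float = 2.25  # onset delay, s
    tau: float = 1.25  # dispersion, s
    alpha: float = 2.0  # shape exponent

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ConfigError(f"tau must be > 0, got {self.tau}")
        if self.alpha < 0:
            raise ConfigError(f"alpha must be >= 0, got {self.alpha}")
        if self.delta < 0:
            raise ConfigError(f"delta must be >= 0, got {self.delta}")

    @property
    def peak_time(self) -> float:
        """Time of the continuous response maximum, delta + alpha * tau."""
        return self.delta + self.alpha * self.tau


def hrf_kernel(
    params: HRFParams = HRFParams(),
    tr: float = 2.0,
    duration: float = 32.0,
) -> np.ndarray:
    """Sample the HRF at multiples of ``tr`` over ``[0, duration)``.

    The kernel is zero before ``delta`` and normalized to unit peak over
    the sampled grid.

    Raises
    ------
    DomainError
        If ``duration`` does not extend past the onset delay (empty support).
    """
    if tr <= 0:
        raise ConfigError(f"tr must be > 0, got {tr}")
    if duration <= params.delta:
        raise DomainError(
            f"kernel duration {duration}s does not cover onset delay {params.delta}s"
        )
    t = np.arange(0.0, duration, tr)
    s = (t - params.delta) / params.tau
    with np.errstate(invalid="ignore"):
        h = np.where(s > 0, np.power(np.clip(s, 0, None), params.alpha) * np.exp(-np.clip(s, 0, None)), 0.0)
    if params.alpha == 0:
        h = np.where(s >= 0, np.exp(-np.clip(s, 0, None)), 0.0)
    peak = h.max()
    if peak <= 0:
        raise DomainError(
            "HRF kernel has no support on the sampled grid; increase duration or decrease tr"
        )
    return h / peak


@dataclass
class DesignMatrix:
    """GLM design: one HRF-convolved, unit-peak boxcar per condition plus nuisance."""

    matrix: np.ndarray  # (volumes, n_columns)
    labels: list[str]  # column labels, conditions first
    condition_labels: list[str]
    tr: float

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


@dataclass
class GlmFit:
    beta: dict[str, float]
    residual_variance: float
    dof: int
    condition_labels: list[str]


@dataclass
class CrowdingIndicesBold:
    """Per-session condition PSCs and the derived crowding/anisotropy indices.

    ``a_bold`` is NaN when the denominator (sum of target-absent PSCs)
    is zero; the undefined value propagates as missing rather than raising.
    """

    psc: dict[str, float]
    c_bold_rad: float
    c_bold_tan: float
    a_bold: float

    @property
    def a_bold_defined(self) -> bool:
        return not math.isnan(self.a_bold)


def _validate_schedule(
    schedule: Sequence[tuple[int, int, str]], volumes: int
) -> None:
    occupied: list[tuple[int, int, str]] = []
    for onset, dur, label in schedule:
        if dur <= 0:
            raise ScheduleError(f"block {label!r} at volume {onset} has duration {dur}")
        if onset < 0 or onset + dur > volumes:
            raise ScheduleError(
                f"block {label!r} [{onset}, {onset + dur}) falls outside run of {volumes} volumes"
            )
        for o2, d2, l2 in occupied:
            if onset < o2 + d2 and o2 < onset + dur:
                raise ScheduleError(
                    f"blocks {label!r} at {onset} and {l2!r} at {o2} overlap"
                )
        occupied.append((onset, dur, label))


def build_design(
    schedule: Sequence[tuple[int, int, str]],
    kernel: np.ndarray,
    volumes: int,
    tr: float,
) -> DesignMatrix:
    """Build the GLM design for one run.

    Each condition appearing in ``schedule`` contributes one column: a
    boxcar (1 during the condition's blocks) convolved with ``kernel``,
    truncated to the run and rescaled to unit peak.  An intercept and a
    mean-centered linear drift are appended.
    """
    _validate_schedule(schedule, volumes)
    conditions = sorted({label for _, _, label in schedule})
    columns: list[np.ndarray] = []
    for cond in conditions:
        boxcar = np.zeros(volumes)
        for onset, dur, label in schedule:
            if label == cond:
                boxcar[onset : onset + dur] = 1.0
        col = np.convolve(boxcar, kernel)[:volumes]
        peak = col.max()
        if peak > 0:
            col = col / peak
        columns.append(col)
    intercept = np.ones(volumes)
    drift = np.arange(volumes, dtype=float)
    drift -= drift.mean()
    mat = np.column_stack(columns + [intercept, drift])
    labels = conditions + [INTERCEPT, DRIFT]
    return DesignMatrix(matrix=mat, labels=labels, condition_labels=conditions, tr=tr)


def _collinear_columns(x: np.ndarray, labels: Sequence[str]) -> list[str]:
    """Name columns implicated in a rank deficiency (smallest singular direction)."""
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    v = np.abs(vt[-1])
    return [labels[i] for i in np.nonzero(v > 0.1 * v.max())[0]]


def fit_glm(run: "BoldRun | np.ndarray", design: DesignMatrix) -> GlmFit:
    """Ordinary least-squares fit of ``design`` to the run's signal."""
    y = np.asarray(getattr(run, "signal", run), dtype=float)
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise DomainError(
            f"signal length {y.shape[0]} does not match design rows {x.shape[0]}"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        cols = _collinear_columns(x, design.labels)
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {', '.join(cols)}"
        )
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = y.shape[0] - x.shape[1]
    if dof <= 0:
        raise DomainError(f"non-positive degrees of freedom: {dof}")
    rss = float(resid @ resid)
    return GlmFit(
        beta=dict(zip(design.labels, beta.tolist())),
        residual_variance=rss / dof,
        dof=dof,
        condition_labels=list(design.condition_labels),
    )


def percent_signal_change(fit: GlmFit) -> dict[str, float]:
    """PSC per condition: 100 * beta_condition / beta_intercept.

    Valid because condition regressors are unit-peak, so betas are in
    signal units at block plateau.
    """
    baseline = fit.beta[INTERCEPT]
    if baseline <= 0:
        raise DomainError(f"non-positive baseline beta: {baseline}")
    return {c: 100.0 * fit.beta[c] / baseline for c in fit.condition_labels}


def crowding_indices(psc: Mapping[str, float]) -> CrowdingIndicesBold:
    """Crowding index per axis and the BOLD anisotropy index from 4 PSCs."""
    missing = [c for c in CONDITIONS if c not in psc]
    if missing:
        raise ConfigError(f"missing condition PSCs: {', '.join(missing)}")
    c_rad = psc["radial_present"] - psc["radial_absent"]
    c_tan = psc["tangential_present"] - psc["tangential_absent"]
    denom = psc["radial_absent"] + psc["tangential_absent"]
    a_bold = (c_rad - c_tan) / denom if abs(denom) > 1e-12 else math.nan
    return CrowdingIndicesBold(
        psc={c: float(psc[c]) for c in CONDITIONS},
        c_bold_rad=float(c_rad),
        c_bold_tan=float(c_tan),
        a_bold=float(a_bold),
    )


def analyze_session(
    runs: Sequence["BoldRun"],
    hrf: HRFParams = HRFParams(),
    kernel_duration: float = 32.0,
    concatenate: bool = False,
) -> CrowdingIndicesBold:
    """Estimate one session's condition PSCs and crowding indices.

    Default strategy fits one GLM per run and averages betas across runs
    per condition before the PSC conversion.  ``concatenate=True`` instead
    stacks all runs into a single GLM with per-run intercept/drift columns
    and shared condition columns.
    """
    if not runs:
        raise ConfigError("analyze_session needs at least one run")
    if concatenate:
        fit = _fit_concatenated(runs, hrf, kernel_duration)
        psc = percent_signal_change(fit)
        return crowding_indices(psc)

    beta_sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    intercepts: list[float] = []
    for run in runs:
        kernel = hrf_kernel(hrf, run.tr, kernel_duration)
        design = build_design(run.schedule, kernel, len(run.signal), run.tr)
        fit = fit_glm(run, design)
        intercepts.append(fit.beta[INTERCEPT])
        for c in fit.condition_labels:
            beta_sums[c] = beta_sums.get(c, 0.0) + fit.beta[c]
            counts[c] = counts.get(c, 0) + 1
    mean_intercept = float(np.mean(intercepts))
    if mean_intercept <= 0:
        raise DomainError(f"non-positive mean baseline: {mean_intercept}")
    psc = {c: 100.0 * (beta_sums[c] / counts[c]) / mean_intercept for c in beta_sums}
    return crowding_indices(psc)


def _fit_concatenated(
    runs: Sequence["BoldRun"], hrf: HRFParams, kernel_duration: float
) -> GlmFit:
    conditions = sorted({lab for run in runs for _, _, lab in run.schedule})
    cond_blocks: list[np.ndarray] = []
    nuis_blocks: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for i, run in enumerate(runs):
        kernel = hrf_kernel(hrf, run.tr, kernel_duration)
        design = build_design(run.schedule, kernel, len(run.signal), run.tr)
        n = design.n_volumes
        cols = np.zeros((n, len(conditions)))
        for j, c in enumerate(conditions):
            if c in design.condition_labels:
                cols[:, j] = design.column(c)
        cond_blocks.append(cols)
        nuis = np.zeros((n, 2 * len(runs)))
        nuis[:, 2 * i] = 1.0
        drift = np.arange(n, dtype=float)
        nuis[:, 2 * i + 1] = drift - drift.mean()
        nuis_blocks.append(nuis)
        ys.append(np.asarray(run.signal, dtype=float))
    x = np.hstack([np.vstack(cond_blocks), np.vstack(nuis_blocks)])
    labels = conditions + [
        f"{INTERCEPT}_{i}" if k == 0 else f"{DRIFT}_{i}"
        for i in range(len(runs))
        for k in (0, 1)
    ]
    y = np.concatenate(ys)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise SingularDesignError(
            f"concatenated design rank deficient: {', '.join(_collinear_columns(x, labels))}"
        )
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = y.shape[0] - x.shape[1]
    betas = dict(zip(labels, beta.tolist()))
    # PSC baseline: mean of the per-run intercepts
    betas[INTERCEPT] = float(
        np.mean([betas[f"{INTERCEPT}_{i}"] for i in range(len(runs))])
    )
    return GlmFit(
        beta=betas,
        residual_variance=float(resid @ resid) / dof,
        dof=dof,
        condition_labels=conditions,
    )
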