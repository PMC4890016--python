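"""Block paradigm, DCM input functions, GLM regressors and time-series extraction.

The experiment shows faces (F), objects (O) or Fourier-scrambled images (S)
in the left (LVF) or right (RVF) visual hemifield while the subject fixates
centrally.  Stimuli are presented in blocks; every stimulus block is followed
by a fixation block of the same length, and the session is split into runs
interleaved by rest periods.

This module builds that design, derives from it

* the five DCM input functions (``RVF``, ``LVF``, ``faces``, ``faces|RVF``,
  ``faces|LVF``) as boxcars on a microtime grid, and
* the six condition regressors for the region-level GLM, convolved with the
  canonical double-gamma haemodynamic response,

and provides ordinary-least-squares GLM fitting after discrete-cosine
high-pass filtering, plus first-eigenvariate summary-series extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "CONDITIONS",
    "INPUT_LABELS",
    "FACE_CONTRAST",
    "Block",
    "BlockDesign",
    "InputSet",
    "GLMResult",
    "ConfigurationError",
    "build_block_design",
    "build_inputs",
    "canonical_hrf",
    "dct_highpass_basis",
    "fit_glm",
    "first_eigenvariate",
]

#: Stimulus conditions: category (F/O/S) crossed with hemifield (LVF/RVF).
CONDITIONS = ("F_LVF", "F_RVF", "O_LVF", "O_RVF", "S_LVF", "S_RVF")

#: DCM input functions, in canonical order.
INPUT_LABELS = ("RVF", "LVF", "faces", "faces|RVF", "faces|LVF")

#: Face-sensitivity contrast [2*F]-[O+S]: sum of face betas minus half the
#: sum of the four control betas (weights over ``CONDITIONS``).
FACE_CONTRAST = np.array([1.0, 1.0, -0.5, -0.5, -0.5, -0.5])


class ConfigurationError(ValueError):
    """Raised for invalid paradigm / design configuration."""


@dataclass(frozen=True)
class Block:
    onset_s: float
    duration_s: float
    condition: str
    run: int


@dataclass
class BlockDesign:
    """Timed block sequence of one scanning session.

    ``blocks`` holds the stimulus and fixation blocks; the rest periods
    between runs are the gaps described by ``run_boundaries``.
    """

    blocks: list[Block]
    run_boundaries: list[float]
    tr_s: float
    n_scans: int
    seed: int | None = None

    @property
    def stimulus_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.condition in CONDITIONS]

    @property
    def duration_s(self) -> float:
        return self.n_scans * self.tr_s

    def condition_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for b in self.stimulus_blocks:
            counts[b.condition] += 1
        return counts

    def validate(self) -> None:
        last_end = -np.inf
        for b in sorted(self.blocks, key=lambda b: b.onset_s):
            if b.onset_s < last_end - 1e-9:
                raise ConfigurationError(
                    f"overlapping blocks at onset {b.onset_s:.2f} s"
                )
            last_end = b.onset_s + b.duration_s
        if last_end > self.duration_s + 1e-9:
            raise ConfigurationError("blocks extend beyond the scan grid")


def _constrained_shuffle(rng: np.random.Generator, labels: list[str],
                         max_consecutive: int = 2, max_tries: int = 10_000) -> list[str]:
    """Uniform shuffle rejected until no label occurs > max_consecutive in a row."""
    seq = list(labels)
    for _ in range(max_tries):
        rng.shuffle(seq)
        ok = all(
            len(set(seq[i:i + max_consecutive + 1])) > 1
            for i in range(len(seq) - max_consecutive)
        )
        if ok:
            return seq
    raise ConfigurationError("could not satisfy pseudo-randomization constraint")


def build_block_design(
    n_reps: int = 7,
    block_scans: int = 10,
    tr_s: float = 1.45,
    n_runs: int = 3,
    break_scans: int = 42,
    seed: int = 0,
    lead_in_scans: int = 0,
    lead_out_scans: int = 0,
) -> BlockDesign:
    """Build the pseudo-randomized block design.

    Each of the six conditions is presented ``n_reps`` times; every stimulus
    block (``block_scans`` scans of ``tr_s`` seconds) is followed by a
    fixation block of equal duration.  The session is divided into
    ``n_runs`` runs interleaved by ``break_scans`` scans of rest.  The
    pseudo-randomization is a uniform shuffle constrained so that no
    condition occurs three times consecutively.
    """
    if n_reps < 1 or block_scans < 1 or n_runs < 1:
        raise ConfigurationError("n_reps, block_scans and n_runs must be >= 1")
    if tr_s <= 0:
        raise ConfigurationError("tr_s must be positive")
    if break_scans < 0 or lead_in_scans < 0 or lead_out_scans < 0:
        raise ConfigurationError("scan counts must be non-negative")

    n_stim = 6 * n_reps
    if n_stim % n_runs != 0:
        raise ConfigurationError(
            f"{n_stim} stimulus blocks cannot be split evenly over {n_runs} runs"
        )
    per_run = n_stim // n_runs

    rng = np.random.default_rng(seed)
    order = _constrained_shuffle(rng, [c for c in CONDITIONS for _ in range(n_reps)])

    block_dur = block_scans * tr_s
    blocks: list[Block] = []
    run_boundaries: list[float] = []
    t = lead_in_scans * tr_s
    for run in range(n_runs):
        run_boundaries.append(t)
        for cond in order[run * per_run:(run + 1) * per_run]:
            blocks.append(Block(t, block_dur, cond, run))
            t += block_dur
            blocks.append(Block(t, block_dur, "FIXATION", run))
            t += block_dur
        if run < n_runs - 1:
            t += break_scans * tr_s

    n_scans = (
        lead_in_scans
        + 2 * n_stim * block_scans
        + (n_runs - 1) * break_scans
        + lead_out_scans
    )
    design = BlockDesign(blocks, run_boundaries, tr_s, n_scans, seed=seed)
    design.validate()
    return design


@dataclass
class InputSet:
    """DCM inputs on the microtime grid plus convolved GLM regressors.

    ``u`` is (5, n_scans * bins_per_scan) binary; rows follow
    ``INPUT_LABELS``.  ``glm_regressors`` is (6, n_scans), rows follow
    ``CONDITIONS``, each condition boxcar convolved with the canonical HRF
    and sampled at scan onsets.
    """

    microtime_dt_s: float
    u: np.ndarray
    glm_regressors: np.ndarray
    tr_s: float
    n_scans: int
    input_labels: tuple[str, ...] = INPUT_LABELS

    @property
    def bins_per_scan(self) -> int:
        return self.u.shape[1] // self.n_scans


def canonical_hrf(dt: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled every ``dt`` s.

    Peak at 6 s, undershoot at 16 s, peak-to-undershoot ratio 6; scaled to
    unit sum so that convolution preserves the boxcar amplitude.
    """
    t = np.arange(0.0, duration_s, dt)

    def gpdf(x, a, b):
        return np.exp(a * np.log(b) + (a - 1) * np.log(np.maximum(x, 1e-12))
                      - b * x - gammaln(a))

    h = gpdf(t, 6.0, 1.0) - gpdf(t, 16.0, 1.0) / 6.0
    return h / h.sum()


def build_inputs(design: BlockDesign, microtime_dt_s: float | None = None) -> InputSet:
    """Derive the five DCM inputs and six GLM regressors from a design.

    The inputs are boxcars on a microtime grid of ``microtime_dt_s``
    (default TR/16): ``RVF``/``LVF`` are on during any stimulus block in the
    corresponding hemifield, ``faces`` during any face block, and
    ``faces|RVF``/``faces|LVF`` during face blocks in that hemifield.
    """
    design.validate()
    tr = design.tr_s
    if microtime_dt_s is None:
        microtime_dt_s = tr / 16.0
    bins = tr / microtime_dt_s
    bins_per_scan = int(round(bins))
    if bins_per_scan < 1 or abs(bins - bins_per_scan) > 1e-6 * bins:
        raise ConfigurationError("microtime_dt_s must divide tr_s")
    dt = tr / bins_per_scan

    n_bins = design.n_scans * bins_per_scan
    u = np.zeros((5, n_bins))
    cond_box = np.zeros((6, n_bins))
    idx = {lab: i for i, lab in enumerate(INPUT_LABELS)}
    for b in design.stimulus_blocks:
        i0 = int(round(b.onset_s / dt))
        i1 = int(round((b.onset_s + b.duration_s) / dt))
        sl = slice(i0, min(i1, n_bins))
        hemi = b.condition.split("_")[1]
        u[idx[hemi], sl] = 1.0
        if b.condition.startswith("F_"):
            u[idx["faces"], sl] = 1.0
            u[idx[f"faces|{hemi}"], sl] = 1.0
        cond_box[CONDITIONS.index(b.condition), sl] = 1.0

    hrf = canonical_hrf(dt)
    conv = np.array([np.convolve(row, hrf)[:n_bins] for row in cond_box])
    glm_regressors = conv[:, ::bins_per_scan]

    return InputSet(dt, u, glm_regressors, tr, design.n_scans)


def dct_highpass_basis(n_scans: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift basis: components with period above 1/cutoff.

    Returns an (n_scans, k) matrix of the DCT-II components whose frequency
    k / (2 * n_scans * tr_s) lies below ``cutoff_hz``, excluding the
    constant term.  Regressing these out implements the conventional
    high-pass filter.
    """
    n = np.arange(n_scans)
    k_max = int(np.floor(2.0 * n_scans * tr_s * cutoff_hz))
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * n + 1) / (2.0 * n_scans))
        for k in range(1, k_max + 1)
    ]
    if not cols:
        return np.empty((n_scans, 0))
    return np.column_stack(cols)


@dataclass
class GLMResult:
    betas: np.ndarray                  # (n_regressors, n_regions)
    contrast_values: dict[str, np.ndarray] = field(default_factory=dict)
    residual_variance: np.ndarray | None = None
    regressor_names: list[str] = field(default_factory=list)
    region_names: list[str] = field(default_factory=list)


def fit_glm(
    series: np.ndarray,
    inputs: InputSet,
    highpass_cutoff_hz: float = 1.0 / 128.0,
    nuisance: np.ndarray | None = None,
    contrasts: dict[str, np.ndarray] | None = None,
    region_names: list[str] | None = None,
) -> GLMResult:
    """OLS region-level GLM after high-pass filtering of data and design.

    ``series`` is (n_scans, n_regions).  The design holds the six convolved
    condition regressors, optional nuisance columns and an intercept.  Both
    data and task/nuisance regressors are residualized against the
    discrete-cosine drift basis before fitting.  The default contrast is the
    face-sensitivity contrast [2*F]-[O+S] with zero-sum weights.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[0] == 1 and inputs.n_scans != 1:
        series = series.T
    if series.shape[0] != inputs.n_scans:
        raise ValueError(
            f"series has {series.shape[0]} scans, design has {inputs.n_scans}"
        )
    X = inputs.glm_regressors.T.copy()
    names = list(CONDITIONS)
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != inputs.n_scans:
            nuisance = nuisance.T
        X = np.hstack([X, nuisance])
        names += [f"nuisance_{i}" for i in range(nuisance.shape[1])]

    K = dct_highpass_basis(inputs.n_scans, inputs.tr_s, highpass_cutoff_hz)
    if K.shape[1]:
        proj = K @ np.linalg.pinv(K)
        X = X - proj @ X
        series = series - proj @ series
    X = np.hstack([X, np.ones((inputs.n_scans, 1))])
    names.append("constant")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"rank-deficient design; dependent columns: {bad}")

    betas, *_ = np.linalg.lstsq(X, series, rcond=None)
    resid = series - X @ betas
    dof = max(inputs.n_scans - X.shape[1] - K.shape[1], 1)
    resvar = (resid ** 2).sum(axis=0) / dof

    if contrasts is None:
        contrasts = {"[2*F]-[O+S]": FACE_CONTRAST}
    cvals = {}
    for name, w in contrasts.items():
        w = np.asarray(w, dtype=float)
        w_full = np.zeros(X.shape[1])
        w_full[: len(w)] = w
        cvals[name] = w_full @ betas

    return GLMResult(
        betas=betas,
        contrast_values=cvals,
        residual_variance=resvar,
        regressor_names=names,
        region_names=region_names or [],
    )


def first_eigenvariate(voxel_series: np.ndarray) -> np.ndarray:
    """Summary time series of an ROI: scaled first left singular vector.

    The sign is chosen so the eigenvariate correlates positively with the
    mean voxel series; the scale is the data's root-mean-square amplitude
    (singular value / sqrt(n_voxels)), matching common practice.
    """
    Y = np.atleast_2d(np.asarray(voxel_series, dtype=float))
    if Y.ndim != 2 or Y.shape[1] < 1:
        raise ValueError("need a time x voxel matrix with >= 1 voxel")
    if not np.any(Y):
        raise ValueError("all-zero voxel matrix has no eigenvariate")
    U, S, _ = np.linalg.svd(Y, full_matrices=False)
    y = U[:, 0] * S[0] / np.sqrt(Y.shape[1])
    mean_series = Y.mean(axis=1)
    if np.dot(y, mean_series) < 0:
        y = -y
    return y
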