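"""Synthetic right-/left-hander cohorts with the structure the analysis assumes.

Group-level connectivity means and between-subject standard deviations for
the two handedness groups are taken from the published group estimates of
the bilateral face network (endogenous, modulatory and driving parameter
tables).  Each simulated subject draws their connection strengths around
their group's means, a session design is built and integrated through the
generative model at a configurable SNR, pupil traces are synthesized with
condition-dependent block responses, pink noise and blinks, and
suprathreshold voxel sets with configurable hemispheric lateralization are
produced for the LI analysis.

The default generating models are the two winning families: family B
(context S/F) for right-handers and family F (context S/F) for
left-handers, which makes family-recovery experiments meaningful.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .forward import BOLDDataset, DCMParams, DCMSpec, HemodynamicParams, REGIONS, simulate_bold
from .modelspace import DEFAULT_FAMILIES, make_spec
from .paradigm import BlockDesign, InputSet, build_block_design, build_inputs
from .pupil import PupilTrace

__all__ = [
    "ENDOGENOUS_TABLE",
    "MODULATORY_TABLE",
    "DRIVING_TABLE",
    "CohortConfig",
    "Subject",
    "Cohort",
    "generating_spec",
    "sample_subject_params",
    "generate_cohort",
]

# ---------------------------------------------------------------------------
# Group parameter tables: {connection: {"RH": (mean, sd), "LH": (mean, sd)}}
# (Hz; "RH" right-handers, "LH" left-handers).  Non-significant entries keep
# their printed estimates — they are the best available values.
# ---------------------------------------------------------------------------

ENDOGENOUS_TABLE: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("FFA_L", "FFA_R"): {"RH": (0.228, 0.147), "LH": (0.253, 0.087)},
    ("FFA_L", "OFA_L"): {"RH": (0.106, 0.096), "LH": (0.147, 0.095)},
    ("FFA_L", "EVC_L"): {"RH": (-0.111, 0.222), "LH": (-0.141, 0.206)},
    ("FFA_R", "FFA_L"): {"RH": (0.216, 0.133), "LH": (0.235, 0.123)},
    ("FFA_R", "OFA_R"): {"RH": (0.124, 0.147), "LH": (0.197, 0.141)},
    ("FFA_R", "EVC_R"): {"RH": (-0.005, 0.158), "LH": (-0.061, 0.213)},
    ("OFA_L", "OFA_R"): {"RH": (0.214, 0.125), "LH": (0.185, 0.154)},
    ("OFA_L", "FFA_L"): {"RH": (0.155, 0.127), "LH": (0.051, 0.092)},
    ("OFA_L", "EVC_L"): {"RH": (-0.233, 0.140), "LH": (-0.126, 0.272)},
    ("OFA_R", "OFA_L"): {"RH": (0.209, 0.093), "LH": (0.217, 0.165)},
    ("OFA_R", "FFA_R"): {"RH": (0.149, 0.117), "LH": (0.125, 0.084)},
    ("OFA_R", "EVC_R"): {"RH": (-0.177, 0.222), "LH": (-0.099, 0.225)},
    ("EVC_L", "FFA_L"): {"RH": (0.110, 0.078), "LH": (0.155, 0.069)},
    ("EVC_L", "OFA_L"): {"RH": (0.220, 0.119), "LH": (0.213, 0.106)},
    ("EVC_R", "FFA_R"): {"RH": (0.121, 0.073), "LH": (0.180, 0.105)},
    ("EVC_R", "OFA_R"): {"RH": (0.194, 0.069), "LH": (0.182, 0.090)},
}

MODULATORY_TABLE: dict[str, dict[tuple[str, str], dict[str, tuple[float, float]]]] = {
    "RVF": {
        ("FFA_L", "FFA_R"): {"RH": (0.061, 0.104), "LH": (0.180, 0.065)},
        ("OFA_L", "OFA_R"): {"RH": (0.110, 0.176), "LH": (0.016, 0.114)},
        ("OFA_L", "FFA_L"): {"RH": (-0.063, 0.106), "LH": (-0.068, 0.144)},
        ("EVC_L", "FFA_L"): {"RH": (0.018, 0.055), "LH": (0.091, 0.089)},
        ("EVC_L", "OFA_L"): {"RH": (0.119, 0.095), "LH": (0.106, 0.119)},
    },
    "LVF": {
        ("FFA_R", "FFA_L"): {"RH": (0.100, 0.105), "LH": (0.149, 0.101)},
        ("OFA_R", "OFA_L"): {"RH": (0.108, 0.118), "LH": (0.077, 0.133)},
        ("OFA_R", "FFA_R"): {"RH": (-0.116, 0.105), "LH": (-0.068, 0.093)},
        ("EVC_R", "FFA_R"): {"RH": (-0.005, 0.044), "LH": (0.013, 0.101)},
        ("EVC_R", "OFA_R"): {"RH": (0.113, 0.100), "LH": (0.057, 0.144)},
    },
    "faces": {
        ("FFA_L", "FFA_R"): {"RH": (0.169, 0.105), "LH": (0.176, 0.070)},
        ("FFA_R", "FFA_L"): {"RH": (0.060, 0.063), "LH": (0.128, 0.081)},
        ("OFA_L", "OFA_R"): {"RH": (0.154, 0.100), "LH": (0.149, 0.113)},
        ("OFA_L", "FFA_L"): {"RH": (0.094, 0.071), "LH": (0.064, 0.075)},
        ("OFA_R", "OFA_L"): {"RH": (0.087, 0.050), "LH": (0.075, 0.072)},
        ("OFA_R", "FFA_R"): {"RH": (0.120, 0.077), "LH": (0.076, 0.085)},
        ("EVC_L", "FFA_L"): {"RH": (0.070, 0.090), "LH": (0.165, 0.083)},
        ("EVC_L", "OFA_L"): {"RH": (0.137, 0.105), "LH": (0.128, 0.087)},
        ("EVC_R", "FFA_R"): {"RH": (0.065, 0.092), "LH": (0.105, 0.077)},
        ("EVC_R", "OFA_R"): {"RH": (0.129, 0.068), "LH": (0.136, 0.111)},
    },
    "faces|RVF": {
        ("FFA_L", "FFA_R"): {"RH": (0.003, 0.008), "LH": (0.0, 0.0)},
        ("OFA_L", "OFA_R"): {"RH": (0.001, 0.003), "LH": (0.0, 0.0)},
        ("OFA_L", "FFA_L"): {"RH": (-0.000, 0.001), "LH": (-0.000, 0.001)},
        ("EVC_L", "FFA_L"): {"RH": (0.002, 0.005), "LH": (0.001, 0.003)},
        ("EVC_L", "OFA_L"): {"RH": (0.0, 0.0), "LH": (0.000, 0.001)},
    },
    "faces|LVF": {
        ("FFA_R", "FFA_L"): {"RH": (0.001, 0.005), "LH": (0.0, 0.0)},
        ("OFA_R", "OFA_L"): {"RH": (0.002, 0.008), "LH": (0.0, 0.0)},
        ("OFA_R", "FFA_R"): {"RH": (0.000, 0.001), "LH": (0.000, 0.002)},
        ("EVC_R", "FFA_R"): {"RH": (0.002, 0.005), "LH": (0.001, 0.004)},
        ("EVC_R", "OFA_R"): {"RH": (0.0, 0.0), "LH": (0.001, 0.002)},
    },
}

#: Driving inputs: stimuli drive the contralateral early visual cortex.
DRIVING_TABLE: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("RVF", "EVC_L"): {"RH": (0.895, 0.450), "LH": (0.731, 0.334)},
    ("LVF", "EVC_R"): {"RH": (0.794, 0.537), "LH": (0.663, 0.278)},
}

_RIDX = {r: i for i, r in enumerate(REGIONS)}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions of one synthetic cohort.

    Defaults reproduce the published paradigm (7 repetitions per condition,
    10-scan blocks at TR 1.45 s, three runs) with the group tables above as
    generating distributions; ``moment_match`` standardizes each free
    parameter's draws so the generated sample reproduces the group mean and
    s.d. exactly (variance reduction for recovery experiments).
    """

    n_per_group: int = 20
    seed: int = 0
    snr: float = 1.0
    groups: tuple[str, ...] = ("RH", "LH")
    # generating model per group: (family_id, (inter_context, intra_context))
    generating_models: dict = field(default_factory=lambda: {
        "RH": ("B", ("S", "F")), "LH": ("F", ("S", "F")),
    })
    # design
    n_reps: int = 7
    block_scans: int = 10
    tr_s: float = 1.45
    n_runs: int = 3
    break_scans: int = 42
    microtime_bins: int = 16
    # parameter sampling
    a_diag_mean: float = -0.5
    a_diag_sd: float = 0.0
    group_sd_scale: float = 1.0
    moment_match: bool = False
    # pupil generation (amplitudes in a.u. before z-normalization; the
    # group difference is confined to face blocks)
    pupil_fs: float = 500.0
    pupil_amplitudes: dict = field(default_factory=lambda: {
        "RH": {"F": -0.50, "O": -0.35, "S": -0.30},
        "LH": {"F": -0.30, "O": -0.35, "S": -0.30},
    })
    pupil_amplitude_sd: float = 0.10
    pupil_noise_sd: float = 0.30
    pupil_onset_ramp_s: float = 0.5
    blink_rate_hz: float = 0.15
    blink_duration_s: tuple[float, float] = (0.1, 0.3)
    # lateralization-index voxel sets: target LI per region per group
    li_targets: dict = field(default_factory=lambda: {
        "OFA": {"RH": -0.25, "LH": -0.25},
        "FFA": {"RH": -0.35, "LH": -0.04},
    })
    li_subject_sd: float = 0.31
    li_n_voxels: int = 60
    # which artifacts to generate
    include_bold: bool = True
    include_pupil: bool = True
    include_li: bool = True

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class Subject:
    subject_id: str
    group: str
    params: DCMParams
    spec: DCMSpec
    bold: BOLDDataset | None = None
    design: BlockDesign | None = None
    pupil: PupilTrace | None = None
    li_voxels: dict | None = None       # region -> (left_values, right_values)


@dataclass
class Cohort:
    subjects: list[Subject]
    config: CohortConfig
    inputs_by_subject: list[InputSet]
    metadata: dict = field(default_factory=dict)

    def by_group(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

def generating_spec(config: CohortConfig, group: str) -> DCMSpec:
    family_id, combo = config.generating_models[group]
    family = {f.family_id: f for f in DEFAULT_FAMILIES}[family_id]
    return make_spec(family, tuple(combo))


def _table_lookup(kind: str, key, group: str):
    tables = {"a": ENDOGENOUS_TABLE, "c": DRIVING_TABLE}
    if kind == "b":
        inp, conn = key
        table = MODULATORY_TABLE.get(inp, {})
        entry = table.get(conn)
    else:
        entry = tables[kind].get(key)
    if entry is None or group not in entry:
        raise KeyError(f"no group table entry for {kind} parameter {key}")
    return entry[group]


def _free_entries(spec: DCMSpec):
    """(kind, matrix index, table key) for every masked generative parameter."""
    out = []
    n = len(spec.regions)
    for i in range(n):
        for j in range(n):
            if i != j and spec.a_mask[i, j]:
                out.append(("a", (i, j), (spec.regions[j], spec.regions[i])))
    for k, lab in enumerate(spec.input_labels):
        for i in range(n):
            for j in range(n):
                if spec.b_masks[k, i, j]:
                    out.append(("b", (k, i, j),
                                (lab, (spec.regions[j], spec.regions[i]))))
    for i in range(n):
        for k, lab in enumerate(spec.input_labels):
            if spec.c_mask[i, k]:
                out.append(("c", (i, k), (lab, spec.regions[i])))
    return out


def _params_from_draws(spec, draws, diag, hemo):
    A = np.zeros((len(spec.regions),) * 2)
    B = np.zeros_like(spec.b_masks, dtype=float)
    C = np.zeros_like(spec.c_mask, dtype=float)
    np.fill_diagonal(A, diag)
    for (kind, idx, _), val in draws:
        {"a": A, "b": B, "c": C}[kind][idx] = val
    return DCMParams(A, B, C, hemo)


#: Draws whose neural system is not at least this stable are rejected:
#: max Re eig(A) must stay below -STABILITY_MARGIN (real subjects have
#: stable dynamics; Gaussian tails of the table s.d.s occasionally do not).
STABILITY_MARGIN = 0.05


def _is_stable(A: np.ndarray) -> bool:
    return np.linalg.eigvals(A).real.max() < -STABILITY_MARGIN


def _draw_subject(config, group, spec, entries, rng, z_row=None):
    draws = []
    for e_idx, (kind, idx, key) in enumerate(entries):
        m, s = _table_lookup(kind, key, group)
        z = z_row[e_idx] if z_row is not None else rng.standard_normal()
        draws.append(((kind, idx, key), m + config.group_sd_scale * s * z))
    diag = config.a_diag_mean + config.a_diag_sd * rng.standard_normal(
        len(spec.regions))
    for _ in range(100):
        bad = diag >= -0.05
        if not bad.any():
            break
        diag[bad] = (config.a_diag_mean
                     + config.a_diag_sd * rng.standard_normal(int(bad.sum())))
    diag = np.minimum(diag, -0.05)
    return _params_from_draws(spec, draws, diag, HemodynamicParams())


def sample_subject_params(
    config: CohortConfig, group: str, seed=None,
    rng: np.random.Generator | None = None,
) -> DCMParams:
    """Draw one subject's generative parameters around the group means.

    Each structurally present parameter is Gaussian with the group's table
    mean and s.d. (scaled by ``group_sd_scale``); self-connections are
    drawn around ``a_diag_mean`` truncated to stay below -0.05 Hz, and
    whole draws are rejected until the endogenous system is stable.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    spec = generating_spec(config, group)
    entries = _free_entries(spec)
    for _ in range(200):
        params = _draw_subject(config, group, spec, entries, rng)
        if _is_stable(params.A):
            return params
    raise RuntimeError("could not draw a stable subject in 200 attempts")


def _sample_group_params(config, group, rng, n):
    """All subjects of one group at once (enables moment matching).

    Unstable tail draws are replaced at the level of the underlying
    standard-normal deviates and the sample re-standardized, so the
    moment-matched sample keeps the group mean/s.d. exactly while every
    subject's endogenous system is stable.
    """
    spec = generating_spec(config, group)
    entries = _free_entries(spec)
    Z = rng.standard_normal((n, len(entries)))

    def build(Zmat):
        if config.moment_match and n >= 2:
            sd = Zmat.std(axis=0)
            Zmat = (Zmat - Zmat.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        return Zmat, [
            _draw_subject(config, group, spec, entries, rng, z_row=Zmat[i])
            for i in range(n)
        ]

    for _ in range(100):
        Zs, out = build(Z)
        unstable = [i for i, p in enumerate(out) if not _is_stable(p.A)]
        if not unstable:
            return spec, out
        for i in unstable:
            Z[i] = rng.standard_normal(len(entries))
    raise RuntimeError("could not draw a stable moment-matched sample")


# ---------------------------------------------------------------------------
# Pupil and LI generators
# ---------------------------------------------------------------------------

def _pink_noise(rng, n, sd):
    """1/f-amplitude noise of length n with the given standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec = spec / np.sqrt(f)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _synth_pupil(config, design, amplitudes, rng, session_id) -> PupilTrace:
    fs = config.pupil_fs
    n = int(round(design.duration_s * fs))
    box = np.zeros(n)
    onsets = []
    for b in design.stimulus_blocks:
        i0 = int(round(b.onset_s * fs))
        i1 = min(int(round((b.onset_s + b.duration_s) * fs)), n)
        stim = b.condition.split("_")[0]
        box[i0:i1] += amplitudes[stim]
        onsets.append((b.onset_s, b.condition))
    ramp_n = max(1, int(round(config.pupil_onset_ramp_s * fs)))
    kernel = 0.5 * (1.0 - np.cos(np.linspace(0, np.pi, ramp_n)))
    kernel /= kernel.sum()
    signal = np.convolve(box, kernel)[:n]
    x = 5.0 + signal + _pink_noise(rng, n, config.pupil_noise_sd)

    blinks = []
    n_blinks = rng.poisson(config.blink_rate_hz * design.duration_s)
    lo, hi = config.blink_duration_s
    for _ in range(n_blinks):
        start = rng.uniform(0, design.duration_s - hi)
        blinks.append((start, start + rng.uniform(lo, hi)))
    blinks.sort()

    return PupilTrace(samples=x, fs=fs, blink_intervals=blinks,
                      block_onsets=onsets, session_id=session_id)


def _synth_li_voxels(config, group, rng):
    """Suprathreshold voxel-value sets per region with target lateralization."""
    out = {}
    for region, targets in config.li_targets.items():
        li = np.clip(targets[group] + config.li_subject_sd * rng.standard_normal(),
                     -0.9, 0.9)
        mu_left = (1.0 + li) / (1.0 - li)   # right-side mean normalized to 1
        nv = config.li_n_voxels
        left = np.abs(mu_left * (1.0 + 0.25 * rng.standard_normal(nv))) + 0.05
        right = np.abs(1.0 * (1.0 + 0.25 * rng.standard_normal(nv))) + 0.05
        out[region] = (left, right)
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a fully seeded two-group cohort.

    Every subject gets a fresh pseudo-randomized design, generative
    parameters drawn from their group's tables, a BOLD dataset simulated at
    the configured SNR, a pupil trace and LI voxel sets.  Identical config
    and seed give identical output.
    """
    root = np.random.SeedSequence(config.seed)
    subjects: list[Subject] = []
    inputs_list: list[InputSet] = []
    sub_counter = 0
    for g_idx, group in enumerate(config.groups):
        group_rng = np.random.default_rng(root.spawn(1)[0])
        spec, params_list = _sample_group_params(
            config, group, group_rng, config.n_per_group)
        for s_idx in range(config.n_per_group):
            sub_counter += 1
            sid = f"sub-{sub_counter:02d}"
            ss = np.random.SeedSequence([config.seed, g_idx, s_idx])
            rng_design, rng_noise, rng_pupil, rng_li = (
                np.random.default_rng(c) for c in ss.spawn(4))
            design = build_block_design(
                n_reps=config.n_reps, block_scans=config.block_scans,
                tr_s=config.tr_s, n_runs=config.n_runs,
                break_scans=config.break_scans,
                seed=int(rng_design.integers(2 ** 31)),
            )
            inputs = build_inputs(design, config.tr_s / config.microtime_bins)
            params = params_list[s_idx]
            bold = None
            if config.include_bold:
                bold = simulate_bold(
                    spec, params, inputs, snr=config.snr,
                    seed=int(rng_noise.integers(2 ** 31)),
                    subject_id=sid, group=group,
                )
            pupil = None
            if config.include_pupil:
                pupil = _synth_pupil(
                    config, design, config.pupil_amplitudes[group],
                    rng_pupil, session_id=sid)
            li_voxels = _synth_li_voxels(config, group, rng_li) \
                if config.include_li else None
            subjects.append(Subject(sid, group, params, spec, bold, design,
                                    pupil, li_voxels))
            inputs_list.append(inputs)

    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_per_group": config.n_per_group,
        "groups": list(config.groups),
    }
    return Cohort(subjects, config, inputs_list, meta)
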