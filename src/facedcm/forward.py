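"""Generative model: bilinear neural dynamics plus haemodynamic observation.

Neural states z (one per region) evolve as

    dz/dt = (A + sum_j u_j B^j) z + C u

where A (Hz) holds the endogenous coupling, B^j the modulation of that
coupling by experimental input u_j, and C the driving inputs.  Each region's
neural activity feeds a balloon/windkessel model (vasodilatory signal s,
inflow f, venous volume v, deoxyhaemoglobin q) whose states predict the BOLD
signal.  The same integrator serves simulation and model inversion; it is
batched over parameter sets so that finite-difference sensitivities cost one
pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "REGIONS",
    "N_REGIONS",
    "DCMSpec",
    "HemodynamicParams",
    "DCMParams",
    "BOLDDataset",
    "IntegrationError",
    "neural_derivative",
    "hemodynamic_derivative",
    "bold_observation",
    "integrate_batch",
    "simulate_bold",
]

#: The six-region bilateral face network: early visual cortex, occipital
#: face area and fusiform face area, left and right.
REGIONS = ("EVC_L", "EVC_R", "OFA_L", "OFA_R", "FFA_L", "FFA_R")
N_REGIONS = 6


class IntegrationError(RuntimeError):
    """Raised when the forward integration produces non-finite states."""


#: Scaling of the driving term C u in the integrated system.  The model
#: generation whose group estimates parameterize the synthetic cohorts
#: applies a 1/16 factor to driving inputs (a convention tied to the 16
#: microtime bins per scan); under it, driving strengths of ~0.8 Hz produce
#: physiological sub-percent BOLD responses.
DRIVING_SCALE = 1.0 / 16.0


@dataclass
class DCMSpec:
    """Structure of one model: binary masks over connections.

    ``a_mask[i, j]`` marks the endogenous connection from region j to
    region i; ``b_masks[k]`` the connections modulated by input k;
    ``c_mask[i, k]`` the driving influence of input k on region i.
    """

    a_mask: np.ndarray
    b_masks: np.ndarray
    c_mask: np.ndarray
    regions: tuple[str, ...] = REGIONS
    input_labels: tuple[str, ...] = ()
    family_id: str | None = None
    combo: tuple[str, str] | None = None   # (inter_context, intra_context)

    def __post_init__(self):
        self.a_mask = np.asarray(self.a_mask, dtype=int)
        self.b_masks = np.asarray(self.b_masks, dtype=int)
        self.c_mask = np.asarray(self.c_mask, dtype=int)

    @property
    def n_inputs(self) -> int:
        return self.c_mask.shape[1]

    def validate(self) -> None:
        n = len(self.regions)
        if self.a_mask.shape != (n, n):
            raise ValueError("a_mask shape mismatch")
        if not np.all(np.diag(self.a_mask) == 1):
            raise ValueError("self-connections (a_mask diagonal) must be present")
        if np.any(self.b_masks * (1 - self.a_mask)):
            raise ValueError("b_masks must be a subset of a_mask")
        evc_rows = [i for i, r in enumerate(self.regions) if r.startswith("EVC")]
        non_evc = np.ones(n, dtype=bool)
        non_evc[evc_rows] = False
        if np.any(self.c_mask[non_evc]):
            raise ValueError("driving inputs are restricted to EVC")


@dataclass
class HemodynamicParams:
    """Balloon-model constants, optionally per region (scalars broadcast).

    signal_decay kappa (1/s), feedback gamma (1/s), transit_time tau (s),
    vessel stiffness alpha, resting oxygen extraction E0 and resting venous
    volume fraction V0.  Defaults are the classical values; during inversion
    only tau and E0 are free.
    """

    kappa: float | np.ndarray = 0.64
    gamma: float | np.ndarray = 0.32
    tau: float | np.ndarray = 2.0
    alpha: float | np.ndarray = 0.32
    E0: float | np.ndarray = 0.4
    V0: float | np.ndarray = 0.04

    def arrays(self, n: int = N_REGIONS) -> dict[str, np.ndarray]:
        out = {}
        for name in ("kappa", "gamma", "tau", "alpha", "E0", "V0"):
            out[name] = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (n,)
            ).copy()
        return out

    def validate(self) -> None:
        a = self.arrays()
        for name, v in a.items():
            if np.any(v <= 0):
                raise ValueError(f"hemodynamic parameter {name} must be positive")
        if np.any(a["E0"] >= 1) or np.any(a["alpha"] >= 1):
            raise ValueError("E0 and alpha must lie in (0, 1)")


@dataclass
class DCMParams:
    """Connection strengths (Hz) plus haemodynamics for one subject/model."""

    A: np.ndarray
    B: np.ndarray                      # (n_inputs, n, n)
    C: np.ndarray                      # (n, n_inputs)
    hemo: HemodynamicParams = field(default_factory=HemodynamicParams)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)

    def validate(self, spec: DCMSpec | None = None) -> None:
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("A diagonal (self-connections) must be negative")
        if spec is not None:
            if np.any(self.A * (1 - spec.a_mask)):
                raise ValueError("A has entries outside the structural mask")
            if np.any(self.B * (1 - spec.b_masks)):
                raise ValueError("B has entries outside the structural mask")
            if np.any(self.C * (1 - spec.c_mask)):
                raise ValueError("C has entries outside the structural mask")
        self.hemo.validate()

    def copy(self) -> "DCMParams":
        return DCMParams(self.A.copy(), self.B.copy(), self.C.copy(),
                         replace(self.hemo))


@dataclass
class BOLDDataset:
    """Observed or simulated region time series (scans x regions, a.u.)."""

    series: np.ndarray
    tr_s: float
    subject_id: str = ""
    group: str | None = None           # "RH" / "LH"
    noise_sd: np.ndarray | float | None = None
    region_names: tuple[str, ...] = REGIONS

    @property
    def n_scans(self) -> int:
        return self.series.shape[0]


def neural_derivative(z: np.ndarray, u: np.ndarray, params: DCMParams) -> np.ndarray:
    """dz/dt = (A + sum_j u_j B^j) z + C u."""
    z = np.asarray(z, dtype=float)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if z.shape[0] != params.A.shape[0] or u.shape[0] != params.C.shape[1]:
        raise ValueError("state/input dimensions do not match the parameters")
    A_eff = params.A + np.tensordot(u, params.B, axes=(0, 0))
    return A_eff @ z + params.C @ u


def hemodynamic_derivative(
    h: np.ndarray, z: float | np.ndarray, hemo: HemodynamicParams
) -> np.ndarray:
    """Balloon/windkessel state derivative for states h = (s, f, v, q).

    s: vasodilatory signal, f: inflow, v: venous volume, q: deoxyhaemoglobin
    (f, v, q normalized to 1 at rest).
    """
    h = np.asarray(h, dtype=float)
    s, f, v, q = h[..., 0], h[..., 1], h[..., 2], h[..., 3]
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("flow, volume and deoxyhaemoglobin states must be positive")
    a = hemo.arrays(1) if np.isscalar(z) else hemo.arrays(np.shape(z)[-1])
    kappa, gamma, tau = a["kappa"], a["gamma"], a["tau"]
    alpha, E0 = a["alpha"], a["E0"]
    if np.isscalar(z):
        kappa, gamma, tau, alpha, E0 = (x[0] for x in (kappa, gamma, tau, alpha, E0))
    ds = z - kappa * s - gamma * (f - 1.0)
    df = s
    fv = v ** (1.0 / alpha)
    dv = (f - fv) / tau
    dq = (f * (1.0 - (1.0 - E0) ** (1.0 / f)) / E0 - fv * q / v) / tau
    return np.stack([ds, df, dv, dq], axis=-1)


def bold_observation(v: np.ndarray, q: np.ndarray, E0: np.ndarray,
                     V0: np.ndarray) -> np.ndarray:
    """BOLD signal (percent change) from volume and deoxyhaemoglobin states."""
    k1 = 7.0 * E0
    k2 = 2.0
    k3 = 2.0 * E0 - 0.2
    return 100.0 * V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


def _segments(u: np.ndarray) -> list[tuple[int, int, np.ndarray]]:
    """Split the microtime axis into maximal runs of constant input."""
    T = u.shape[1]
    if T == 0:
        return []
    change = np.nonzero(np.any(np.diff(u, axis=1) != 0, axis=0))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [T]])
    return [(int(a), int(b), u[:, a]) for a, b in zip(starts, ends)]


def integrate_batch(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    hemo: dict[str, np.ndarray],
    u: np.ndarray,
    dt: float,
    bins_per_scan: int,
    n_scans: int,
    driving_scale: float = DRIVING_SCALE,
) -> np.ndarray:
    """Integrate P parameter sets jointly; return (P, n_scans, n) BOLD.

    A: (P, n, n); B: (P, m, n, n); C: (P, n, m); hemo entries (P, n);
    u: (m, T) piecewise-constant inputs with T >= n_scans * bins_per_scan.
    The driving term enters as ``driving_scale * C u`` (see
    :data:`DRIVING_SCALE`); modulatory effects use the unscaled inputs.
    Fixed-step 4th-order Runge-Kutta at dt; the BOLD signal is sampled at
    scan onsets (bins 0, bins_per_scan, ...).
    """
    P, n, _ = A.shape
    kappa, gamma = hemo["kappa"], hemo["gamma"]
    tau, alpha, E0, V0 = hemo["tau"], hemo["alpha"], hemo["E0"], hemo["V0"]
    inv_alpha = 1.0 / alpha
    inv_tau = 1.0 / tau
    log1mE0 = np.log(1.0 - E0)

    T_need = n_scans * bins_per_scan
    if u.shape[1] < T_need:
        raise ValueError("input functions shorter than the scan grid")

    from . import _kernels

    if _kernels.HAVE_NUMBA:
        bc = lambda x: np.ascontiguousarray(np.broadcast_to(x, (P, n)), float)
        y = _kernels.rk4_integrate(
            np.ascontiguousarray(A, float), np.ascontiguousarray(B, float),
            np.ascontiguousarray(C, float),
            bc(kappa), bc(gamma), bc(inv_tau), bc(inv_alpha), bc(E0),
            bc(log1mE0), bc(V0),
            np.ascontiguousarray(u[:, :T_need], float),
            float(dt), int(bins_per_scan), int(n_scans),
            float(driving_scale),
        )
        if not np.all(np.isfinite(y)):
            raise IntegrationError("integration produced non-finite output")
        return y

    # The (s, f) flow pair is an exactly linear oscillator and is integrated
    # in linear space; v and q are integrated in log space so the stiff
    # windkessel terms cannot drive them negative.  Flow is rectified at a
    # small floor where it enters the metabolic terms (a hard off-transient
    # can swing the linear flow equation through zero).
    z = np.zeros((P, n))
    s = np.zeros((P, n))
    f = np.ones((P, n))
    lv = np.zeros((P, n))
    lq = np.zeros((P, n))
    y = np.zeros((P, n_scans, n))

    T = n_scans * bins_per_scan
    if u.shape[1] < T:
        raise ValueError("input functions shorter than the scan grid")

    bin_idx = 0
    for a0, b0, u_seg in _segments(u[:, :T]):
        A_eff = A + np.einsum("m,pmij->pij", u_seg, B)
        Cu = driving_scale * (C @ u_seg)

        def rhs(z, s, f, lv, lq, A_eff=A_eff, Cu=Cu):
            # sanitize the stage states: intermediate RK4 stages of an
            # unstable candidate must stay finite
            z = np.clip(z, -50.0, 50.0)
            s = np.clip(s, -100.0, 100.0)
            f = np.clip(f, -100.0, 100.0)
            lv = np.clip(lv, -5.0, 5.0)
            lq = np.clip(lq, -10.0, 5.0)
            dz = np.einsum("pij,pj->pi", A_eff, z) + Cu
            ds = z - kappa * s - gamma * (f - 1.0)
            fr = np.clip(f, 1e-2, None)
            fv = np.exp(lv * inv_alpha)          # v ** (1/alpha)
            dlv = (fr - fv) * inv_tau * np.exp(-lv)
            E = 1.0 - np.exp(log1mE0 / fr)
            dlq = (fr * E / E0 * np.exp(-lq) - fv * np.exp(-lv)) * inv_tau
            return (dz, ds, s,
                    np.clip(dlv, -1e3, 1e3), np.clip(dlq, -1e3, 1e3))

        for _ in range(a0, b0):
            if bin_idx % bins_per_scan == 0:
                y[:, bin_idx // bins_per_scan] = bold_observation(
                    np.exp(lv), np.exp(lq), E0, V0)
            bin_idx += 1

            k1 = rhs(z, s, f, lv, lq)
            k2 = rhs(z + 0.5 * dt * k1[0], s + 0.5 * dt * k1[1],
                     f + 0.5 * dt * k1[2], lv + 0.5 * dt * k1[3],
                     lq + 0.5 * dt * k1[4])
            k3 = rhs(z + 0.5 * dt * k2[0], s + 0.5 * dt * k2[1],
                     f + 0.5 * dt * k2[2], lv + 0.5 * dt * k2[3],
                     lq + 0.5 * dt * k2[4])
            k4 = rhs(z + dt * k3[0], s + dt * k3[1], f + dt * k3[2],
                     lv + dt * k3[3], lq + dt * k3[4])
            z = z + (dt / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            s = s + (dt / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            f = f + (dt / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            lv = lv + (dt / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
            lq = lq + (dt / 6.0) * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
            # saturate far outside the physiological range: an unstable
            # candidate parameter set then yields finite, absurd predictions
            # (which an inversion step simply rejects) instead of overflow
            np.clip(z, -50.0, 50.0, out=z)
            np.clip(s, -100.0, 100.0, out=s)
            np.clip(f, -100.0, 100.0, out=f)
            np.clip(lv, -5.0, 5.0, out=lv)
            np.clip(lq, -10.0, 5.0, out=lq)
        if not (np.all(np.isfinite(z)) and np.all(np.isfinite(lq))):
            raise IntegrationError(
                f"integration diverged at t = {bin_idx * dt:.2f} s"
            )
    return y


def simulate_bold(
    spec: DCMSpec,
    params: DCMParams,
    inputs,
    tr_s: float | None = None,
    n_scans: int | None = None,
    noise_sd: float | np.ndarray = 0.0,
    seed: int | None = None,
    snr: float | None = None,
    subject_id: str = "",
    group: str | None = None,
    driving_scale: float = DRIVING_SCALE,
) -> BOLDDataset:
    """Simulate one subject's BOLD dataset from a parameterized model.

    The joint neural + haemodynamic system is integrated at microtime and
    observed at scan onsets; i.i.d. Gaussian observation noise is added per
    region.  If ``snr`` is given, the per-region noise s.d. is set to that
    region's noiseless signal s.d. divided by ``snr`` (overriding
    ``noise_sd``).  Deterministic for a fixed seed.
    """
    spec.validate()
    params.validate(spec)
    tr = tr_s if tr_s is not None else inputs.tr_s
    n_scans = n_scans if n_scans is not None else inputs.n_scans
    bins_per_scan = inputs.bins_per_scan
    dt = inputs.microtime_dt_s

    hemo = {k: v[None, :] for k, v in params.hemo.arrays().items()}
    y = integrate_batch(
        params.A[None], params.B[None], params.C[None], hemo,
        inputs.u, dt, bins_per_scan, n_scans, driving_scale=driving_scale,
    )[0]

    if snr is not None:
        noise_sd = y.std(axis=0) / snr
    noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (y.shape[1],))
    if np.any(noise_sd > 0):
        rng = np.random.default_rng(seed)
        y = y + rng.standard_normal(y.shape) * noise_sd

    return BOLDDataset(series=y, tr_s=tr, subject_id=subject_id, group=group,
                       noise_sd=noise_sd.copy())
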