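"""Variational-Laplace inversion of a dynamic causal model.

``DCM`` pairs one subject's region time series with a model structure and
Gaussian shrinkage priors; ``fit()`` maximizes the negative free energy

    F = accuracy - complexity
      = E_q[log p(y | theta)] - KL[q(theta) || p(theta)] - (noise penalty)

over a Gaussian posterior q (Laplace approximation) by damped Gauss-Newton
ascent, with per-region noise precisions updated alongside.  F is the
lower-bound approximation to the log model evidence used for model
comparison.

Parameterization: endogenous (A, off-diagonal and diagonal), modulatory (B)
and driving (C) rates in Hz; haemodynamic transit time and resting oxygen
extraction as log-scale deviations from their defaults.  Sensitivities are
obtained by central finite differences, batched through the forward
integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import (
    BOLDDataset,
    DCMParams,
    DCMSpec,
    HemodynamicParams,
    N_REGIONS,
    integrate_batch,
)
from .paradigm import InputSet

__all__ = [
    "Priors",
    "default_priors",
    "DCM",
    "DCMResults",
    "Posterior",
    "variational_laplace",
    "log_evidence",
    "InversionError",
]


class InversionError(RuntimeError):
    """Raised when the free-energy ascent produces non-finite values."""


_HEMO_FREE = ("tau", "E0")


@dataclass
class Priors:
    """Gaussian shrinkage priors over the free parameters of one model.

    ``index`` lists, per free parameter, a tuple identifying it:
    ``("a", i, j)``, ``("b", k, i, j)``, ``("c", i, k)`` or
    ``("hemo", which, region)``.  A zero variance pins the parameter to its
    prior mean.  ``h0``/``var_h`` parameterize the log-normal hyperprior on
    the per-region noise precisions (``h0=None``: set from the data scale).
    """

    mu: np.ndarray
    var: np.ndarray
    index: list[tuple]
    names: list[str]
    hemo_base: HemodynamicParams = field(default_factory=HemodynamicParams)
    h0: float | None = None
    var_h: float = 16.0

    @property
    def n_params(self) -> int:
        return self.mu.size

    def validate(self) -> None:
        if np.any(self.var < 0):
            raise ValueError("prior variances must be >= 0")
        if self.mu.shape != self.var.shape:
            raise ValueError("prior mean/variance shape mismatch")


def default_priors(
    spec: DCMSpec,
    hemo_free: bool = True,
    var_a_off: float = 1.0 / 16.0,
    var_a_diag: float = 1.0 / 256.0,
    var_b: float = 1.0 / 16.0,
    var_c: float = 1.0,
    var_hemo: float = 1.0 / 64.0,
    a_diag_mean: float = -0.5,
    hemo_base: HemodynamicParams | None = None,
    regions: tuple[str, ...] | None = None,
) -> Priors:
    """Tight shrinkage priors for every structurally allowed parameter.

    Zero-mean Gaussians on the masked A off-diagonal, B and C entries; the
    six self-connections have prior mean ``a_diag_mean`` Hz with a very
    tight variance; haemodynamic transit time and E0 enter as zero-mean
    log-scale deviations per region when ``hemo_free``.
    """
    spec.validate()
    regions = regions or spec.regions
    labels = spec.input_labels
    index: list[tuple] = []
    names: list[str] = []
    mu: list[float] = []
    var: list[float] = []

    n = len(regions)
    for i in range(n):
        for j in range(n):
            if i != j and spec.a_mask[i, j]:
                index.append(("a", i, j))
                names.append(f"A: {regions[j]}->{regions[i]}")
                mu.append(0.0)
                var.append(var_a_off)
    for i in range(n):
        index.append(("a", i, i))
        names.append(f"A: {regions[i]} self")
        mu.append(a_diag_mean)
        var.append(var_a_diag)
    for k in range(spec.b_masks.shape[0]):
        for i in range(n):
            for j in range(n):
                if spec.b_masks[k, i, j]:
                    index.append(("b", k, i, j))
                    names.append(f"B[{labels[k]}]: {regions[j]}->{regions[i]}")
                    mu.append(0.0)
                    var.append(var_b)
    for i in range(n):
        for k in range(spec.c_mask.shape[1]):
            if spec.c_mask[i, k]:
                index.append(("c", i, k))
                names.append(f"C: {labels[k]}->{regions[i]}")
                mu.append(0.0)
                var.append(var_c)
    if hemo_free:
        for which in _HEMO_FREE:
            for i in range(n):
                index.append(("hemo", which, i))
                names.append(f"log {which} {regions[i]}")
                mu.append(0.0)
                var.append(var_hemo)

    return Priors(
        mu=np.array(mu), var=np.array(var), index=index, names=names,
        hemo_base=hemo_base or HemodynamicParams(),
    )


class _Packer:
    """Scatter flat parameter vectors into batched (A, B, C, hemo) arrays."""

    def __init__(self, priors: Priors, n_inputs: int, n: int = N_REGIONS):
        self.priors = priors
        self.n = n
        self.n_inputs = n_inputs
        self.ai, self.aj, self.ak = [], [], []
        self.bi = ([], [], [], [])
        self.ci = ([], [], [])
        self.hemo_idx: dict[str, tuple[list, list]] = {w: ([], []) for w in _HEMO_FREE}
        for pos, idx in enumerate(priors.index):
            if idx[0] == "a":
                self.ak.append(pos); self.ai.append(idx[1]); self.aj.append(idx[2])
            elif idx[0] == "b":
                self.bi[0].append(pos); self.bi[1].append(idx[1])
                self.bi[2].append(idx[2]); self.bi[3].append(idx[3])
            elif idx[0] == "c":
                self.ci[0].append(pos); self.ci[1].append(idx[1]); self.ci[2].append(idx[2])
            elif idx[0] == "hemo":
                self.hemo_idx[idx[1]][0].append(pos)
                self.hemo_idx[idx[1]][1].append(idx[2])

    def assemble(self, thetas: np.ndarray):
        thetas = np.atleast_2d(thetas)
        P = thetas.shape[0]
        n, m = self.n, self.n_inputs
        A = np.zeros((P, n, n))
        B = np.zeros((P, m, n, n))
        C = np.zeros((P, n, m))
        A[:, self.ai, self.aj] = thetas[:, self.ak]
        if self.bi[0]:
            B[:, self.bi[1], self.bi[2], self.bi[3]] = thetas[:, self.bi[0]]
        if self.ci[0]:
            C[:, self.ci[1], self.ci[2]] = thetas[:, self.ci[0]]
        base = self.priors.hemo_base.arrays(n)
        hemo = {k: np.broadcast_to(v, (P, n)).copy() for k, v in base.items()}
        for which, (pos, reg) in self.hemo_idx.items():
            if pos:
                hemo[which][:, reg] = hemo[which][:, reg] * np.exp(thetas[:, pos])
        hemo["E0"] = np.clip(hemo["E0"], 1e-3, 0.95)
        return A, B, C, hemo

    def to_params(self, theta: np.ndarray) -> DCMParams:
        A, B, C, hemo = self.assemble(theta)
        hp = HemodynamicParams(**{k: v[0] for k, v in hemo.items()})
        return DCMParams(A[0], B[0], C[0], hp)


class DCM:
    """Dynamic causal model for one subject's region time series.

    Parameters
    ----------
    data : BOLDDataset or (n_scans, n_regions) array
    inputs : InputSet
        Experimental inputs on the microtime grid of the same session.
    spec : DCMSpec
        Structural masks of the model to invert.
    priors : Priors, optional
        Defaults to :func:`default_priors` for the spec.
    center : bool
        Mean-center data and predictions region-wise (the extracted series
        the model is meant for are mean-centered).
    """

    def __init__(
        self,
        data: BOLDDataset | np.ndarray,
        inputs: InputSet,
        spec: DCMSpec,
        priors: Priors | None = None,
        center: bool = True,
        driving_scale: float | None = None,
    ):
        if isinstance(data, BOLDDataset):
            y = np.asarray(data.series, dtype=float)
            self.data = data
        else:
            y = np.asarray(data, dtype=float)
            self.data = BOLDDataset(series=y, tr_s=inputs.tr_s)
        if y.shape[0] != inputs.n_scans:
            raise ValueError("data and inputs are not on the same scan grid")
        spec.validate()
        self.spec = spec
        self.inputs = inputs
        self.priors = priors or default_priors(spec)
        self.priors.validate()
        self.center = center
        self.endog = y - y.mean(axis=0) if center else y
        from .forward import DRIVING_SCALE

        self.driving_scale = (DRIVING_SCALE if driving_scale is None
                              else driving_scale)
        self._packer = _Packer(self.priors, spec.c_mask.shape[1],
                               len(spec.regions))

    # -- forward passes ----------------------------------------------------
    def _predict_batch(self, thetas: np.ndarray) -> np.ndarray:
        A, B, C, hemo = self._packer.assemble(thetas)
        y = integrate_batch(
            A, B, C, hemo, self.inputs.u, self.inputs.microtime_dt_s,
            self.inputs.bins_per_scan, self.inputs.n_scans,
            driving_scale=self.driving_scale,
        )
        if self.center:
            y = y - y.mean(axis=1, keepdims=True)
        return y

    def predict(self, theta: np.ndarray) -> np.ndarray:
        return self._predict_batch(theta[None])[0]

    def _jacobian(self, theta: np.ndarray, fd_step: float):
        """Central finite differences, one batched integrator pass."""
        p = theta.size
        thetas = np.vstack([theta, theta + fd_step * np.eye(p),
                            theta - fd_step * np.eye(p)])
        Y = self._predict_batch(thetas)
        g = Y[0]
        J = (Y[1:p + 1] - Y[p + 1:]) / (2.0 * fd_step)   # (p, N, R)
        return g, np.moveaxis(J, 0, -1)                  # (N, R, p)

    # -- free energy -------------------------------------------------------
    @staticmethod
    def _free_energy(resid, J, h, e, s0_inv, h0, var_h):
        """Negative free energy of q = N(mu, Sigma) with Sigma from J, h.

        resid: (N, R); J: (N, R, p); e = mu - mu0.  Returns (F, Sigma).
        """
        N, R, p = J.shape
        lam = np.exp(h)
        H = np.einsum("nrp,r,nrq->pq", J, lam, J) + np.diag(s0_inv)
        try:
            L = np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            H = H + 1e-8 * np.eye(p)
            L = np.linalg.cholesky(H)
        Sigma = np.linalg.inv(H)
        logdet_Sigma = -2.0 * np.log(np.diag(L)).sum()
        JtJ = np.einsum("nrp,nrq->rpq", J, J)
        trace_r = np.einsum("rpq,qp->r", JtJ, Sigma)
        sse = (resid ** 2).sum(axis=0)
        accuracy = (
            -0.5 * (lam * (sse + trace_r)).sum()
            + 0.5 * N * h.sum()
            - 0.5 * N * R * np.log(2.0 * np.pi)
        )
        with np.errstate(divide="ignore"):
            log_prior_var = np.where(s0_inv > 0, -np.log(s0_inv), 0.0)
        complexity = (
            0.5 * (e ** 2 * s0_inv).sum()
            + 0.5 * np.trace(np.diag(s0_inv) @ Sigma)
            - 0.5 * logdet_Sigma
            + 0.5 * log_prior_var.sum()
            - 0.5 * p
        )
        hyper = ((h - h0) ** 2 / (2.0 * var_h)).sum()
        return accuracy - complexity - hyper, Sigma

    def _update_h(self, resid, J, h, e, s0_inv, h0, var_h, n_cycles=3):
        """Maximize F over the per-region log noise precisions."""
        N = resid.shape[0]
        sse = (resid ** 2).sum(axis=0)
        JtJ = np.einsum("nrp,nrq->rpq", J, J)
        for _ in range(n_cycles):
            lam = np.exp(h)
            H = np.einsum("rpq,r->pq", JtJ, lam) + np.diag(s0_inv)
            Sigma = np.linalg.inv(H + 1e-10 * np.eye(H.shape[0]))
            E_r = sse + np.einsum("rpq,qp->r", JtJ, Sigma)
            for _ in range(8):  # scalar Newton per region, jointly vectorized
                lam = np.exp(h)
                grad = 0.5 * N - 0.5 * lam * E_r - (h - h0) / var_h
                hess = -0.5 * lam * E_r - 1.0 / var_h
                step = np.clip(grad / -hess, -2.0, 2.0)
                h = h + step
                if np.max(np.abs(step)) < 1e-8:
                    break
        return h

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        max_iter: int = 128,
        tol: float = 1e-4,
        fd_step: float = 1e-4,
        verbose: bool = False,
        n_starts: int = 1,
        start_scale: float = 1.0,
        start_seed: int = 0,
    ) -> "DCMResults":
        """Invert the model: damped Gauss-Newton ascent on F.

        Rejected steps are reverted (the retained F never decreases); the
        Levenberg-Marquardt damping shrinks after accepted steps and grows
        after rejections.  Convergence when an accepted step improves F by
        less than ``tol`` nats.

        ``n_starts > 1`` adds seeded restarts from the prior mean perturbed
        by ``start_scale`` prior standard deviations (the free-energy
        landscape of a saturating model can be multimodal); the start with
        the highest final F is returned.
        """
        if n_starts > 1:
            rng = np.random.default_rng(start_seed)
            sd = np.sqrt(self.priors.var)
            results = []
            for k in range(n_starts):
                theta0 = self.priors.mu.copy()
                if k > 0:
                    theta0 = theta0 + start_scale * sd * rng.standard_normal(
                        sd.size)
                results.append(self._fit_single(
                    max_iter, tol, fd_step, verbose, theta0=theta0))
            return max(results, key=lambda r: r.free_energy)
        return self._fit_single(max_iter, tol, fd_step, verbose)

    def _fit_single(self, max_iter, tol, fd_step, verbose, theta0=None):
        y = self.endog
        mu0 = self.priors.mu.copy()
        with np.errstate(divide="ignore"):
            s0_inv = np.where(self.priors.var > 0, 1.0 / self.priors.var, 1e12)
        h0 = self.priors.h0
        if h0 is None:
            # hyperprior centred on the data scale, kept in a sane range
            h0 = float(np.clip(-np.log(max(y.var(axis=0).mean(), 1e-12)),
                               -20.0, 20.0))
        var_h = self.priors.var_h

        theta = theta0.copy() if theta0 is not None else mu0.copy()
        h = np.full(y.shape[1], h0, dtype=float)
        nu = 0.25
        trace: list[float] = []
        best = None
        converged = False
        n_iter = 0
        F_prev = -np.inf

        for n_iter in range(1, max_iter + 1):
            g, J = self._jacobian(theta, fd_step)
            resid = y - g
            e = theta - mu0
            h = self._update_h(resid, J, h, e, s0_inv, h0, var_h)
            F, Sigma = self._free_energy(resid, J, h, e, s0_inv, h0, var_h)
            if not np.isfinite(F):
                raise InversionError(
                    f"non-finite free energy at iteration {n_iter}"
                )
            if best is None or F >= best["F"]:
                best = {"F": F, "theta": theta.copy(), "Sigma": Sigma,
                        "h": h.copy()}
            else:
                # the linearized step over-promised: fall back to the best
                # retained point and search again with heavier damping
                theta = best["theta"].copy()
                h = best["h"].copy()
                nu = min(nu * 64.0, 1e8)
                g, J = self._jacobian(theta, fd_step)
                resid, e = y - g, theta - mu0
                F, Sigma = self._free_energy(resid, J, h, e, s0_inv, h0, var_h)
            trace.append(best["F"])
            improvement = F - F_prev
            F_prev = F
            if verbose:
                print(f"iter {n_iter:3d}  F = {best['F']:.3f}  nu = {nu:.2e}")
            if improvement < tol:
                converged = True
                break

            # damped Gauss-Newton step: evaluate a ladder of damping values
            # in one batched forward pass and move to the best candidate
            lam = np.exp(h)
            Hmat = np.einsum("nrp,r,nrq->pq", J, lam, J) + np.diag(s0_inv)
            grad = np.einsum("nrp,r,nr->p", J, lam, resid) - s0_inv * e
            dH = np.diag(np.diag(Hmat))
            moved = False
            for _ in range(3):
                nus = nu * np.power(8.0, np.arange(-1, 4))
                steps = np.stack([
                    np.linalg.solve(Hmat + nc * dH, grad) for nc in nus
                ])
                cand = theta[None, :] + steps
                Yc = self._predict_batch(cand)
                # candidate score: exact accuracy and prior terms; the
                # Sigma-dependent terms are common to all candidates
                resid_c = y[None] - Yc
                acc_c = -0.5 * (lam[None, :]
                                * (resid_c ** 2).sum(axis=1)).sum(axis=1)
                prior_c = -0.5 * (((cand - mu0) ** 2) * s0_inv).sum(axis=1)
                score_c = acc_c + prior_c
                score_0 = (-0.5 * (lam * (resid ** 2).sum(axis=0)).sum()
                           - 0.5 * (e ** 2 * s0_inv).sum())
                k = int(np.argmax(score_c))
                if score_c[k] > score_0:
                    theta = cand[k]
                    nu = max(nus[k] / 8.0, 1e-8)
                    moved = True
                    break
                nu = min(nu * 8.0 ** 4, 1e8)
            if not moved:
                converged = True   # no ascent direction left at any damping
                break

        return DCMResults(self, best["theta"], best["Sigma"], best["F"],
                          np.array(trace), converged, np.exp(best["h"]),
                          n_iter)


class DCMResults:
    """Posterior over one model's parameters plus its evidence bound.

    Attributes follow the estimates container conventions: ``params`` is
    the posterior mean, ``cov_params()`` the posterior covariance, ``bse``
    posterior standard deviations, ``free_energy`` the negative free energy
    F (nats), ``trace`` the retained-F iteration trace.
    """

    def __init__(self, model: DCM, params, cov, free_energy, trace,
                 converged, noise_precision, n_iter):
        self.model = model
        self.params = params
        self._cov = 0.5 * (cov + cov.T)
        self.free_energy = float(free_energy)
        self.trace = trace
        self.converged = bool(converged)
        self.noise_precision = noise_precision
        self.n_iter = int(n_iter)

    def cov_params(self) -> np.ndarray:
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self._cov), 0.0, None))

    @property
    def param_names(self) -> list[str]:
        return self.model.priors.names

    def to_dcm_params(self) -> DCMParams:
        """Posterior-mean parameters assembled into matrices."""
        return self.model._packer.to_params(self.params)

    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    def get_param(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def summary(self) -> pd.DataFrame:
        pr = self.model.priors
        return pd.DataFrame({
            "prior mean": pr.mu,
            "prior sd": np.sqrt(pr.var),
            "posterior mean": self.params,
            "posterior sd": self.bse,
        }, index=pr.names)

    def __repr__(self):
        flag = "converged" if self.converged else "NOT converged"
        return (f"<DCMResults: F = {self.free_energy:.2f} nats, "
                f"{self.params.size} params, {self.n_iter} iter, {flag}>")


#: Backwards-friendly alias: the posterior object of one inversion.
Posterior = DCMResults


def variational_laplace(
    spec: DCMSpec,
    data: BOLDDataset | np.ndarray,
    inputs: InputSet,
    priors: Priors | None = None,
    max_iter: int = 128,
    **fit_kwargs,
) -> DCMResults:
    """Functional front door: build a :class:`DCM` and fit it."""
    return DCM(data, inputs, spec, priors=priors).fit(max_iter=max_iter,
                                                      **fit_kwargs)


def log_evidence(posterior: DCMResults) -> float:
    """The negative free energy, used as log-evidence approximation."""
    return posterior.free_energy
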