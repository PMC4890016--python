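"""Bayesian model comparison over subjects: RFX BMS, families, BMA.

The random-effects scheme treats each subject's best model as drawn from a
population frequency vector r with a Dirichlet prior; the variational update
over (r, subject model labels) uses each subject's negative free energies as
log evidences.  Family-level inference aggregates model frequencies within
families under a prior that is uniform over families.  Bayesian model
averaging combines per-model posterior means within a subject's Occam's
window, weighted by evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

__all__ = [
    "EvidenceMatrix",
    "BMSResult",
    "BMAResult",
    "rfx_bms",
    "family_bms",
    "compare_group_frequencies",
    "occams_window",
    "bma_subject",
]


@dataclass
class EvidenceMatrix:
    """Per-subject, per-model negative free energies (nats)."""

    F: np.ndarray                       # (n_subjects, n_models)
    model_tags: list[tuple] = field(default_factory=list)
    subjects: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        if not np.all(np.isfinite(self.F)):
            raise ValueError("evidence matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.F.shape[0]

    @property
    def n_models(self) -> int:
        return self.F.shape[1]


@dataclass
class BMSResult:
    """Dirichlet posterior over model (or family) frequencies."""

    alpha: np.ndarray
    expected_prob: np.ndarray
    exceedance_prob: np.ndarray
    labels: list = field(default_factory=list)
    n_samples: int = 0
    seed: int | None = None
    model_attribution: np.ndarray | None = None   # (n_subjects, n_models)
    free_energy: float | None = None              # VB bound of the RFX model

    def summary(self):
        import pandas as pd

        return pd.DataFrame({
            "alpha": self.alpha,
            "expected_prob": self.expected_prob,
            "exceedance_prob": self.exceedance_prob,
        }, index=self.labels or range(len(self.alpha)))


def _vb_dirichlet(F: np.ndarray, alpha0: np.ndarray,
                  max_iter: int = 200, tol: float = 1e-8):
    """Variational posterior Dir(alpha) and attribution q_nk; returns the
    VB lower bound as well (used for group-frequency comparison)."""
    n, K = F.shape
    Fn = F - F.max(axis=1, keepdims=True)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        logu = Fn + digamma(alpha) - digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        q = np.exp(logu)
        q /= q.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + q.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    # VB lower bound on log p(y | RFX model); uses the full (unshifted) F
    Elogr = digamma(alpha) - digamma(alpha.sum())
    qs = np.clip(q, 1e-300, None)
    bound = (
        (q * F).sum()
        + (q * Elogr).sum()
        - (q * np.log(qs)).sum()
    )
    # E[log p(r)] - E[log q(r)] for Dir(alpha0) prior and Dir(alpha) posterior
    bound += (-_log_beta(alpha0) + ((alpha0 - 1) * Elogr).sum())
    bound -= (-_log_beta(alpha) + ((alpha - 1) * Elogr).sum())
    return alpha, q, bound


def _log_beta(alpha: np.ndarray) -> float:
    return float(gammaln(alpha).sum() - gammaln(alpha.sum()))


def _exceedance(alpha: np.ndarray, n_samples: int, seed: int | None,
                partition: list[np.ndarray] | None = None) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet, optionally over
    sums of coordinates (families)."""
    rng = np.random.default_rng(seed)
    r = rng.dirichlet(alpha, size=n_samples)
    if partition is not None:
        r = np.column_stack([r[:, idx].sum(axis=1) for idx in partition])
    winners = np.argmax(r, axis=1)
    counts = np.bincount(winners, minlength=r.shape[1])
    return counts / n_samples


def rfx_bms(
    F: EvidenceMatrix | np.ndarray,
    alpha0: float | np.ndarray = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
) -> BMSResult:
    """Random-effects BMS: Dirichlet posterior over model frequencies.

    Expected probabilities are the Dirichlet mean; exceedance probabilities
    (the probability that a model is the most frequent in the population)
    come from seeded Monte-Carlo sampling.
    """
    em = F if isinstance(F, EvidenceMatrix) else EvidenceMatrix(np.asarray(F))
    if em.n_models < 2:
        raise ValueError("model comparison needs at least two models")
    if em.n_subjects < 1:
        raise ValueError("need at least one subject")
    a0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (em.n_models,)).copy()
    alpha, q, bound = _vb_dirichlet(em.F, a0)
    return BMSResult(
        alpha=alpha,
        expected_prob=alpha / alpha.sum(),
        exceedance_prob=_exceedance(alpha, n_samples, seed),
        labels=list(em.model_tags),
        n_samples=n_samples,
        seed=seed,
        model_attribution=q,
        free_energy=bound,
    )


def family_bms(
    F: EvidenceMatrix | np.ndarray,
    families: dict[str, list[int]],
    n_samples: int = 100_000,
    seed: int = 0,
) -> BMSResult:
    """Family-level RFX BMS.

    ``families`` maps family labels to model column indices and must
    partition the model space.  The per-model Dirichlet prior is 1/(family
    size), i.e. uniform over families, and family frequencies are sums of
    sampled model frequencies within each family.
    """
    em = F if isinstance(F, EvidenceMatrix) else EvidenceMatrix(np.asarray(F))
    all_idx = sorted(i for idx in families.values() for i in idx)
    if all_idx != list(range(em.n_models)):
        raise ValueError("families must partition the model columns exactly")
    a0 = np.empty(em.n_models)
    for idx in families.values():
        a0[list(idx)] = 1.0 / len(idx)
    alpha, q, bound = _vb_dirichlet(em.F, a0)
    labels = list(families)
    partition = [np.asarray(families[lab], dtype=int) for lab in labels]
    fam_alpha = np.array([alpha[idx].sum() for idx in partition])
    return BMSResult(
        alpha=fam_alpha,
        expected_prob=fam_alpha / alpha.sum(),
        exceedance_prob=_exceedance(alpha, n_samples, seed, partition),
        labels=labels,
        n_samples=n_samples,
        seed=seed,
        model_attribution=q,
        free_energy=bound,
    )


def compare_group_frequencies(
    F_g1: EvidenceMatrix | np.ndarray,
    F_g2: EvidenceMatrix | np.ndarray,
    alpha0: float = 1.0,
) -> float:
    """Posterior probability that both groups share one frequency profile.

    Compares, at equal prior odds, a pooled model (one Dirichlet generates
    both groups) against independent per-group Dirichlets, using the VB
    evidence bounds of the random-effects model.
    """
    e1 = F_g1 if isinstance(F_g1, EvidenceMatrix) else EvidenceMatrix(np.asarray(F_g1))
    e2 = F_g2 if isinstance(F_g2, EvidenceMatrix) else EvidenceMatrix(np.asarray(F_g2))
    if e1.n_models != e2.n_models:
        raise ValueError("both groups must share the same model set")
    if e1.n_subjects == 0 or e2.n_subjects == 0:
        raise ValueError("empty group")
    a0 = np.full(e1.n_models, float(alpha0))
    _, _, b_pooled = _vb_dirichlet(np.vstack([e1.F, e2.F]), a0)
    _, _, b1 = _vb_dirichlet(e1.F, a0)
    _, _, b2 = _vb_dirichlet(e2.F, a0)
    log_odds = b_pooled - (b1 + b2)
    return float(1.0 / (1.0 + np.exp(-log_odds)))


def occams_window(F_subject: np.ndarray, odds_threshold: float = 0.05) -> np.ndarray:
    """Indices of models whose evidence ratio to the best exceeds threshold.

    A model i is retained when exp(F_i - F_best) > odds_threshold; the best
    model is always retained.
    """
    F_subject = np.asarray(F_subject, dtype=float)
    if not np.all(np.isfinite(F_subject)):
        raise ValueError("free energies must be finite")
    ratio = np.exp(F_subject - F_subject.max())
    return np.nonzero(ratio > odds_threshold)[0]


@dataclass
class BMAResult:
    """Subject-level Bayesian model average over the retained window."""

    params: dict[str, np.ndarray]
    retained: np.ndarray
    weights: np.ndarray
    odds_threshold: float


def bma_subject(
    posteriors: list,
    F_subject: np.ndarray | None = None,
    odds_threshold: float = 0.05,
) -> BMAResult:
    """Average posterior parameter means across one subject's models.

    ``posteriors`` supply per-model posterior means as full (A, B, C)
    matrices via ``to_dcm_params()`` (or are ``DCMParams``-like directly);
    parameters structurally absent from a model contribute zero with that
    model's weight.  Weights are proportional to exp(F_i - F_best) over the
    models inside the Occam's window.
    """
    if F_subject is None:
        F_subject = np.array([p.free_energy for p in posteriors])
    F_subject = np.asarray(F_subject, dtype=float)
    if len(posteriors) != F_subject.size:
        raise ValueError("one free energy per posterior required")
    keep = occams_window(F_subject, odds_threshold)
    w = np.exp(F_subject[keep] - F_subject[keep].max())
    w = w / w.sum()

    mats = []
    for i in keep:
        p = posteriors[i]
        p = p.to_dcm_params() if hasattr(p, "to_dcm_params") else p
        mats.append((p.A, p.B, p.C))
    out = {
        key: sum(wi * m[j] for wi, m in zip(w, mats))
        for j, key in enumerate(("A", "B", "C"))
    }
    return BMAResult(params=out, retained=keep, weights=w,
                     odds_threshold=odds_threshold)
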