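"""Empirical convergence diagnostics for flux sample chains.

Because ACHR-style samplers carry no asymptotic convergence guarantee,
convergence is assessed empirically with the three classic MCMC
diagnostics, with the decision thresholds conventional in this setting:

* Geweke: per-reaction z-score comparing the means of an early window
  (first 10%) and a late window (last 50%) of a chain, standardised by
  spectral density estimates at frequency zero. Under stationarity z is
  approximately standard normal, so |z| > 1.96 flags non-convergence at
  the 5% level.
* Gelman-Rubin: potential scale reduction factor (PSRF) across >= 2
  independent chains; per-reaction PSRF plus the Brooks-Gelman multivariate
  generalisation. Values below 1.2 are read as converged, closer to 1.0 is
  better.
* Heidelberger-Welch: per-reaction stationarity test based on the
  Cramer-von-Mises statistic of the standardised cumulative sum (Brownian
  bridge), applied to the full chain and after discarding the first 10%,
  20%, ... 50%; a reaction passes (1) at the first stage whose statistic is
  below the critical value, otherwise fails (0).

The three tests frequently disagree; they are reported side by side and
never aggregated into a single verdict.

Spectral densities at frequency zero are estimated from an autoregressive
fit whose order is chosen by AIC (Yule-Walker equations), the standard
approach for these diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

__all__ = [
    "GewekeResult",
    "GelmanRubinResult",
    "HeidelbergerWelchResult",
    "DiagnosticsReport",
    "spectrum0_ar",
    "geweke",
    "gelman_rubin",
    "heidelberger_welch",
    "diagnose",
]

#: Decision thresholds used when summarising the diagnostics.
THRESHOLDS = {"R_crit": 1.2, "z_crit": 1.96, "hw_alpha": 0.05}

#: Upper-tail critical values of the asymptotic Cramer-von-Mises distribution.
_CVM_CRIT = {0.1: 0.34730, 0.05: 0.46136, 0.025: 0.58061, 0.01: 0.74346}

#: Ridge added to the pooled within-chain covariance before the generalised
#: eigenproblem; stoichiometric coupling makes flux covariances singular.
_PSRF_RIDGE = 1e-10


def spectrum0_ar(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density of ``x`` at frequency zero via an AR(p) fit.

    The AR order is selected by AIC among 0..max_order (default
    ``min(20, N // 20)``); coefficients come from the Yule-Walker equations.
    For a white-noise chain this reduces to the sample variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError("chain too short for a spectral estimate")
    x = x - x.mean()
    c0 = float(x @ x) / n
    if c0 <= 0.0:
        return 0.0
    if max_order is None:
        max_order = min(20, n // 20)
    max_order = max(1, min(max_order, n - 2))
    # Autocovariances up to max_order.
    acov = np.array([float(x[: n - k] @ x[k:]) / n for k in range(max_order + 1)])
    best_aic = n * np.log(c0)
    best = (0, c0, np.empty(0))
    for p in range(1, max_order + 1):
        try:
            a = scipy.linalg.solve_toeplitz(acov[:p], acov[1 : p + 1])
        except np.linalg.LinAlgError:
            break
        sigma2 = acov[0] - float(a @ acov[1 : p + 1])
        if sigma2 <= 0.0:
            continue
        aic = n * np.log(sigma2) + 2.0 * p
        if aic < best_aic:
            best_aic = aic
            best = (p, sigma2, a)
    p, sigma2, a = best
    if p == 0:
        return c0
    denom = 1.0 - float(a.sum())
    if abs(denom) < 1e-8:
        denom = 1e-8 if denom >= 0 else -1e-8
    return sigma2 / denom**2


@dataclass
class GewekeResult:
    z: np.ndarray
    degenerate: np.ndarray  # reactions with (numerically) zero variance


def geweke(
    chain: np.ndarray, frac_first: float = 0.1, frac_last: float = 0.5
) -> GewekeResult:
    """Geweke z-scores for every reaction of an N x n chain.

    Zero-variance reactions get z = 0 with their ``degenerate`` flag set
    rather than NaN.
    """
    chain = np.atleast_2d(np.asarray(chain, dtype=float))
    n_samp, n_rxn = chain.shape
    if n_samp < 100:
        raise ValueError("Geweke needs at least 100 samples")
    if frac_first + frac_last > 1.0:
        raise ValueError("window fractions overlap")
    n_a = int(frac_first * n_samp)
    n_b = int(frac_last * n_samp)
    z = np.zeros(n_rxn)
    degenerate = np.zeros(n_rxn, dtype=bool)
    for j in range(n_rxn):
        a = chain[:n_a, j]
        b = chain[n_samp - n_b :, j]
        if np.var(chain[:, j]) <= 1e-300:
            degenerate[j] = True
            continue
        s_a = spectrum0_ar(a)
        s_b = spectrum0_ar(b)
        denom = s_a / n_a + s_b / n_b
        if denom <= 0.0:
            degenerate[j] = True
            continue
        z[j] = (a.mean() - b.mean()) / np.sqrt(denom)
    return GewekeResult(z, degenerate)


@dataclass
class GelmanRubinResult:
    multivariate: float
    per_reaction: np.ndarray
    degenerate: np.ndarray


def gelman_rubin(chains: list[np.ndarray]) -> GelmanRubinResult:
    """Potential scale reduction factors across >= 2 equal-length chains.

    Per reaction: R = sqrt(((N-1)/N * W + B/N) / W) with W the mean
    within-chain variance and B = N * variance of the chain means. The
    multivariate value is the Brooks-Gelman largest-eigenvalue
    generalisation on the within/between covariance matrices, with the
    within-covariance ridge-regularised against rank deficiency.
    """
    if len(chains) < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    mats = [np.atleast_2d(np.asarray(c, dtype=float)) for c in chains]
    n_samp, n_rxn = mats[0].shape
    if n_samp < 10:
        raise ValueError("chains too short")
    for c in mats[1:]:
        if c.shape != (n_samp, n_rxn):
            raise ValueError("chains must share shape")
    m = len(mats)
    means = np.stack([c.mean(axis=0) for c in mats])          # m x n
    within = np.stack([c.var(axis=0, ddof=1) for c in mats]).mean(axis=0)
    between = n_samp * means.var(axis=0, ddof=1)
    degenerate = within <= 1e-300
    w_safe = np.where(degenerate, 1.0, within)
    var_hat = (n_samp - 1) / n_samp * w_safe + between / n_samp
    per = np.sqrt(var_hat / w_safe)
    per[degenerate & (between <= 1e-300)] = 1.0
    # Multivariate PSRF (largest generalised eigenvalue).
    w_cov = np.zeros((n_rxn, n_rxn))
    for c in mats:
        w_cov += np.cov(c, rowvar=False, ddof=1)
    w_cov /= m
    w_cov = np.atleast_2d(w_cov)
    b_cov = np.atleast_2d(np.cov(means, rowvar=False, ddof=1))  # = B/N
    w_reg = w_cov + _PSRF_RIDGE * np.eye(n_rxn)
    lam = scipy.linalg.eigh(b_cov, w_reg, eigvals_only=True)[-1]
    lam = max(float(lam), 0.0)
    multivariate = float(np.sqrt((n_samp - 1) / n_samp + (m + 1) / m * lam))
    return GelmanRubinResult(multivariate, per, degenerate)


@dataclass
class HeidelbergerWelchResult:
    passed: np.ndarray        # 0/1 per reaction
    kept_fraction: np.ndarray # fraction of the chain retained at the passing stage
    degenerate: np.ndarray

    @property
    def pass_fraction(self) -> float:
        return float(self.passed.mean())


def heidelberger_welch(chain: np.ndarray, alpha: float = 0.05) -> HeidelbergerWelchResult:
    """Heidelberger-Welch stationarity test per reaction of an N x n chain.

    The spectral variance is estimated once from the second half of the
    full chain; stages test the full chain, then after discarding the first
    10%, 20%, ... 50%. Supported alpha levels: 0.1, 0.05, 0.025, 0.01.
    """
    if alpha not in _CVM_CRIT:
        raise ValueError(f"alpha must be one of {sorted(_CVM_CRIT)}")
    chain = np.atleast_2d(np.asarray(chain, dtype=float))
    n_samp, n_rxn = chain.shape
    if n_samp < 100:
        raise ValueError("Heidelberger-Welch needs at least 100 samples")
    crit = _CVM_CRIT[alpha]
    passed = np.zeros(n_rxn)
    kept = np.zeros(n_rxn)
    degenerate = np.zeros(n_rxn, dtype=bool)
    for j in range(n_rxn):
        x = chain[:, j]
        if np.var(x) <= 1e-300:
            degenerate[j] = True
            continue
        s0 = spectrum0_ar(x[n_samp // 2 :])
        if s0 <= 0.0:
            degenerate[j] = True
            continue
        for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            xa = x[int(frac * n_samp) :]
            n_a = xa.size
            bridge = np.cumsum(xa) - xa.mean() * np.arange(1, n_a + 1)
            stat = float(bridge @ bridge) / (n_a * n_a * s0)
            if stat < crit:
                passed[j] = 1.0
                kept[j] = 1.0 - frac
                break
    return HeidelbergerWelchResult(passed, kept, degenerate)


@dataclass
class DiagnosticsReport:
    """Side-by-side summary of the three diagnostics over >= 2 runs.

    ``geweke_z`` and ``hw_pass`` are averaged over runs (per reaction);
    ``hw_pass`` entries are therefore in [0, 1] and exactly 0/1 for a
    single run.
    """

    geweke_z: np.ndarray
    gelman_R: float
    gelman_per_reaction: np.ndarray
    hw_pass: np.ndarray
    hw_fraction: float
    reaction_ids: list[str]
    thresholds: dict = field(default_factory=lambda: dict(THRESHOLDS))

    def summary(self) -> str:
        frac_z = float(np.mean(np.abs(self.geweke_z) > self.thresholds["z_crit"]))
        return (
            f"multivariate PSRF R = {self.gelman_R:.4f} "
            f"(converged: {self.gelman_R < self.thresholds['R_crit']})\n"
            f"Geweke |z| > {self.thresholds['z_crit']}: {100 * frac_z:.1f}% of reactions "
            f"(max |z| = {np.max(np.abs(self.geweke_z)):.2f})\n"
            f"Heidelberger-Welch pass fraction: {self.hw_fraction:.3f}"
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gelman_R": self.gelman_R,
            "gelman_per_reaction": dict(
                zip(self.reaction_ids, map(float, self.gelman_per_reaction))
            ),
            "geweke_z": dict(zip(self.reaction_ids, map(float, self.geweke_z))),
            "hw_pass": dict(zip(self.reaction_ids, map(float, self.hw_pass))),
            "hw_fraction": self.hw_fraction,
            "thresholds": self.thresholds,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def diagnose(
    chains: list[np.ndarray],
    reaction_ids: list[str] | None = None,
    hw_alpha: float = 0.05,
) -> DiagnosticsReport:
    """Run all three diagnostics on a set of repeated-run chains."""
    if len(chains) < 2:
        raise ValueError("diagnose needs >= 2 runs (Gelman-Rubin requirement)")
    mats = [np.atleast_2d(np.asarray(c, dtype=float)) for c in chains]
    n_rxn = mats[0].shape[1]
    if reaction_ids is None:
        reaction_ids = [f"R{j + 1}" for j in range(n_rxn)]
    gr = gelman_rubin(mats)
    z = np.mean([geweke(c).z for c in mats], axis=0)
    hw = np.mean([heidelberger_welch(c, hw_alpha).passed for c in mats], axis=0)
    thresholds = dict(THRESHOLDS)
    thresholds["hw_alpha"] = hw_alpha
    return DiagnosticsReport(
        geweke_z=z,
        gelman_R=gr.multivariate,
        gelman_per_reaction=gr.per_reaction,
        hw_pass=hw,
        hw_fraction=float(hw.mean()),
        reaction_ids=list(reaction_ids),
        thresholds=thresholds,
    )
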