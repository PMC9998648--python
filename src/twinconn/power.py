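"""Monte Carlo power analysis for twin intra-pair correlations.

Estimates the power of a twin design to detect heritability by repeated
simulation: in each replicate, twin-pair feature values are drawn from a
bivariate normal with the stated intra-pair correlation, the sample Pearson
correlation is computed across pairs, and a one-sided Fisher-z test is
applied.  Two rejection rules are available, since "power to detect
heritability" can be read either way:

* ``MZ_NONZERO`` — test rMZ > 0 (variance 1/(nMZ - 3));
* ``MZ_GT_DZ``   — test rMZ > rDZ (variance 1/(nMZ - 3) + 1/(nDZ - 3)).

No covariate correction is applied here: the simulated feature has no
age/sex structure.  The Monte Carlo uncertainty on the power estimate is
reported as a 95% Wilson score interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io_model import ValidationError

__all__ = ["PowerResult", "monte_carlo_power"]

_TESTS = ("MZ_NONZERO", "MZ_GT_DZ")


@dataclass(frozen=True)
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_sims: int
    test: str
    alpha: float
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.power <= self.ci_high <= 1.0):
            raise ValidationError("power must lie inside its confidence interval")


def _pair_correlations(
    n_pairs: int, rho: float, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample Pearson correlation across pairs, one value per replicate."""
    shared = rng.standard_normal((n_sims, n_pairs, 1))
    unique = rng.standard_normal((n_sims, n_pairs, 2))
    # negative rho: the shared factor enters the two twins with opposite sign
    signs = np.array([1.0, 1.0]) if rho >= 0 else np.array([1.0, -1.0])
    xy = np.sqrt(abs(rho)) * shared * signs + np.sqrt(1.0 - abs(rho)) * unique
    xc = xy - xy.mean(axis=1, keepdims=True)
    num = (xc[:, :, 0] * xc[:, :, 1]).sum(axis=1)
    den = np.sqrt((xc[:, :, 0] ** 2).sum(axis=1) * (xc[:, :, 1] ** 2).sum(axis=1))
    return np.clip(num / den, -0.999999999, 0.999999999)


def monte_carlo_power(
    n_mz: int,
    n_dz: int = 0,
    r_mz_true: float = 0.6,
    r_dz_true: float = 0.0,
    n_sims: int = 10_000,
    alpha: float = 0.05,
    test: str = "MZ_NONZERO",
    seed: int = 0,
) -> PowerResult:
    """Monte Carlo power of a one-sided Fisher test, with a Wilson 95% CI.

    ``n_dz`` and ``r_dz_true`` are only used by the ``MZ_GT_DZ`` rule.
    Replicates share one seeded generator, so runs at the same seed are
    identical and power comparisons across parameter settings can use
    common random numbers by reusing the seed.
    """
    if test not in _TESTS:
        raise ValidationError(f"test must be one of {_TESTS}")
    if not (abs(r_mz_true) < 1 and abs(r_dz_true) < 1):
        raise ValidationError("true correlations must satisfy |r| < 1")
    if n_mz < 4 or (test == "MZ_GT_DZ" and n_dz < 4):
        raise ValidationError("need at least 4 pairs per group used by the test")
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")

    rng = np.random.default_rng(seed)
    r_mz = _pair_correlations(n_mz, r_mz_true, n_sims, rng)
    if test == "MZ_NONZERO":
        z = np.arctanh(r_mz) * np.sqrt(n_mz - 3)
    else:
        r_dz = _pair_correlations(n_dz, r_dz_true, n_sims, rng)
        z = (np.arctanh(r_mz) - np.arctanh(r_dz)) / np.sqrt(
            1.0 / (n_mz - 3) + 1.0 / (n_dz - 3)
        )
    rejections = int((stats.norm.sf(z) < alpha).sum())
    power = rejections / n_sims
    lo, hi = proportion_confint(rejections, n_sims, alpha=0.05, method="wilson")
    return PowerResult(
        power=power,
        # guard against the interval missing the point estimate by rounding
        ci_low=min(float(lo), power),
        ci_high=max(float(hi), power),
        n_sims=n_sims,
        test=test,
        alpha=alpha,
        seed=seed,
    )
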