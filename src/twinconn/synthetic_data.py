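"""Synthetic twin cohorts with known variance-component structure.

Two generators make the full pipeline testable without any real data:

``simulate_feature_cohort``
    draws one phenotypic feature per subject from the classical biometrical
    model.  Each twin's value is a weighted sum of standard-normal latent
    factors  y = sqrt(a2) A + sqrt(c2) C + sqrt(d2) D + sqrt(e2) E  plus
    linear age/sex covariate effects.  Latent within-pair correlations are
    A: 1 (MZ) / 0.5 (DZ), D: 1 / 0.25, C: 1 / 1, E: 0 / 0, so the implied
    intra-pair correlations are rMZ = a2 + d2 + c2 and
    rDZ = a2/2 + d2/4 + c2.

``simulate_timeseries_cohort``
    draws BOLD-like ROI time series.  Each subject's target correlation
    matrix is a shared base template perturbed per link on the Fisher scale
    by twin-structured noise, mapped back through tanh, projected to the
    nearest positive-definite correlation matrix, and sampled as T
    multivariate-normal time points.

All randomness flows from a single seed through numpy ``SeedSequence``
spawning, so subject-level draws are independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_model import (
    AAL90,
    ParcellationLabels,
    ROITimeSeries,
    TwinPair,
    TwinPairManifest,
    ValidationError,
)

__all__ = [
    "VarianceComponentsSpec",
    "SimulationConfig",
    "simulate_feature_cohort",
    "simulate_timeseries_cohort",
    "block_template",
    "nearest_correlation",
    "toy_graph_fixtures",
]


@dataclass(frozen=True)
class VarianceComponentsSpec:
    """Variance proportions of the four biometrical sources (must sum to 1).

    In a classical same-sex twin design C and D are not jointly
    identifiable; by default at most one of them may be nonzero
    (``allow_cd=True`` lifts the restriction for non-classical simulations).
    """

    a2: float = 0.0
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 1.0
    allow_cd: bool = False

    def __post_init__(self) -> None:
        comps = (self.a2, self.c2, self.d2, self.e2)
        if any(c < 0 for c in comps):
            raise ValidationError(f"variance components must be >= 0, got {comps}")
        if abs(sum(comps) - 1.0) > 1e-12:
            raise ValidationError(
                f"variance components must sum to 1, got {sum(comps)!r}"
            )
        if not self.allow_cd and self.c2 > 0 and self.d2 > 0:
            raise ValidationError(
                "classical design: at most one of c2, d2 may be nonzero "
                "(set allow_cd=True to override)"
            )

    @property
    def r_mz(self) -> float:
        """Implied MZ intra-pair correlation a2 + d2 + c2."""
        return self.a2 + self.d2 + self.c2

    @property
    def r_dz(self) -> float:
        """Implied DZ intra-pair correlation a2/2 + d2/4 + c2."""
        return self.a2 / 2.0 + self.d2 / 4.0 + self.c2


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort dimensions and covariate effects.

    Defaults mirror a small same-sex twin cohort: 18 MZ and 25 DZ pairs,
    ages uniform on 10-30 years, 200 time points over 90 ROIs.
    """

    n_mz: int = 18
    n_dz: int = 25
    t: int = 200
    n_roi: int = 90
    seed: int = 0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    age_range: tuple[float, float] = (10.0, 30.0)

    def __post_init__(self) -> None:
        if self.n_mz < 2 or self.n_dz < 2:
            raise ValidationError("need at least 2 pairs per zygosity group")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise ValidationError(f"invalid age range {self.age_range}")


# latent within-pair correlations of the biometrical sources
_PAIR_CORR = {"MZ": {"A": 1.0, "C": 1.0, "D": 1.0}, "DZ": {"A": 0.5, "C": 1.0, "D": 0.25}}


def _draw_manifest(config: SimulationConfig, rng: np.random.Generator) -> TwinPairManifest:
    pairs = []
    zygosities = ["MZ"] * config.n_mz + ["DZ"] * config.n_dz
    for i, zyg in enumerate(zygosities):
        pid = f"{zyg}{i + 1:03d}"
        pairs.append(
            TwinPair(
                pair_id=pid,
                zygosity=zyg,
                twin1_id=f"{pid}_t1",
                twin2_id=f"{pid}_t2",
                age=float(rng.uniform(*config.age_range)),
                sex="M" if rng.random() < 0.5 else "F",
            )
        )
    return TwinPairManifest(tuple(pairs))


def _pair_factor(rho: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """(size, 2) standard-normal draws with within-row correlation rho."""
    shared = rng.standard_normal((size, 1))
    unique = rng.standard_normal((size, 2))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * unique


def _twin_values(
    spec: VarianceComponentsSpec,
    zygosity: str,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(size, 2) phenotype draws for ``size`` pairs of one zygosity."""
    rho = _PAIR_CORR[zygosity]
    y = np.zeros((size, 2))
    for var, source in ((spec.a2, "A"), (spec.c2, "C"), (spec.d2, "D")):
        if var > 0:
            y += np.sqrt(var) * _pair_factor(rho[source], size, rng)
    if spec.e2 > 0:
        y += np.sqrt(spec.e2) * rng.standard_normal((size, 2))
    return y


def simulate_feature_cohort(
    spec: VarianceComponentsSpec, config: SimulationConfig
) -> tuple[TwinPairManifest, dict[str, float]]:
    """One feature per subject from the biometrical twin model.

    Returns the manifest and a subject_id -> value mapping.  Covariate
    effects enter additively: beta_age * age + beta_sex * [sex == M].
    """
    seq = np.random.SeedSequence(config.seed)
    rng_manifest, rng_mz, rng_dz = (
        np.random.default_rng(s) for s in seq.spawn(3)
    )
    manifest = _draw_manifest(config, rng_manifest)
    values: dict[str, float] = {}
    for zyg, rng in (("MZ", rng_mz), ("DZ", rng_dz)):
        pairs = manifest.by_zygosity(zyg)
        y = _twin_values(spec, zyg, len(pairs), rng)
        for row, p in zip(y, pairs):
            shift = config.beta_age * p.age + config.beta_sex * (p.sex == "M")
            values[p.twin1_id] = float(row[0] + shift)
            values[p.twin2_id] = float(row[1] + shift)
    return manifest, values


# ---------------------------------------------------------------------------
# Time-series cohorts
# ---------------------------------------------------------------------------


def block_template(
    parcellation: ParcellationLabels,
    blocks: tuple[tuple[int, int], ...] = (),
    r_within: float = 0.6,
) -> np.ndarray:
    """Block-diagonal correlation template (RSN-style communities).

    ``blocks`` lists half-open index ranges; within each range all pairwise
    correlations are set to ``r_within``.  Diagonal is 1.
    """
    n = len(parcellation)
    base = np.eye(n)
    for lo, hi in blocks:
        if not (0 <= lo < hi <= n):
            raise ValidationError(f"invalid block range ({lo}, {hi}) for N={n}")
        base[lo:hi, lo:hi] = r_within
    np.fill_diagonal(base, 1.0)
    return base


def nearest_correlation(matrix: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result re-normalized to
    unit diagonal.  This one-shot projection is adequate here because the
    tanh-mapped perturbed templates are already near-PD.
    """
    sym = (matrix + matrix.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.maximum(w, eig_floor)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def simulate_timeseries_cohort(
    config: SimulationConfig,
    base: np.ndarray | None = None,
    link_spec: VarianceComponentsSpec | None = None,
    link_sigma: float = 0.0,
    parcellation: ParcellationLabels | None = None,
) -> tuple[TwinPairManifest, dict[str, ROITimeSeries]]:
    """BOLD-like ROI time series for a twin cohort.

    Each subject's target correlation matrix is ``tanh(atanh(base) + sigma *
    g)`` where g is a per-link twin-structured standard-normal perturbation
    drawn from ``link_spec`` (defaults to pure unique environment), then
    projected to the nearest PD correlation matrix and sampled for
    ``config.t`` multivariate-normal time points.

    With ``link_sigma = 0`` every subject shares the base template exactly.
    """
    if parcellation is None:
        parcellation = (
            AAL90
            if config.n_roi == 90
            else ParcellationLabels(tuple(f"ROI{i + 1:03d}" for i in range(config.n_roi)))
        )
    n = len(parcellation)
    if base is None:
        base = np.eye(n)
    base = np.asarray(base, dtype=float)
    if base.shape != (n, n):
        raise ValidationError(f"base template must be {n} x {n}")
    if not np.allclose(base, base.T):
        raise ValidationError("base template must be symmetric")
    min_eig = np.linalg.eigvalsh((base + base.T) / 2.0).min()
    if min_eig < -1e-6:
        raise ValidationError(
            f"base template is not positive semi-definite (min eigenvalue {min_eig:.3g})"
        )
    if link_spec is None:
        link_spec = VarianceComponentsSpec()  # pure E

    seq = np.random.SeedSequence(config.seed)
    sub_seqs = seq.spawn(3)
    manifest = _draw_manifest(config, np.random.default_rng(sub_seqs[0]))

    iu = np.triu_indices(n, k=1)
    z_base = np.arctanh(np.clip(base[iu], -0.999999, 0.999999))
    n_links = len(z_base)

    series: dict[str, ROITimeSeries] = {}
    rng_pert = {"MZ": np.random.default_rng(sub_seqs[1]),
                "DZ": np.random.default_rng(sub_seqs[2])}
    for zyg in ("MZ", "DZ"):
        pairs = manifest.by_zygosity(zyg)
        rng = rng_pert[zyg]
        for p in pairs:
            if link_sigma > 0:
                pert = _twin_values(link_spec, zyg, n_links, rng)
            else:
                pert = np.zeros((n_links, 2))
            for col, sid in enumerate((p.twin1_id, p.twin2_id)):
                z = z_base + link_sigma * pert[:, col]
                target = np.eye(n)
                target[iu] = np.tanh(z)
                target = target + np.triu(target, k=1).T
                target = nearest_correlation(target)
                chol = np.linalg.cholesky(target)
                data = rng.standard_normal((config.t, n)) @ chol.T
                series[sid] = ROITimeSeries(sid, data, parcellation)
    return manifest, series


# ---------------------------------------------------------------------------
# Toy graphs for metric oracles
# ---------------------------------------------------------------------------


def toy_graph_fixtures() -> dict[str, nx.Graph]:
    """Small named graphs with hand-checkable metric values.

    K3 (triangle), P3 (path), S4 (star with 3 leaves), K4-e (complete on 4
    minus one edge), 2xK3 (two disjoint triangles).
    """
    k4e = nx.complete_graph(4)
    k4e.remove_edge(2, 3)
    two_k3 = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    return {
        "K3": nx.complete_graph(3),
        "P3": nx.path_graph(3),
        "S4": nx.star_graph(3),
        "K4-e": k4e,
        "2xK3": two_k3,
    }
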