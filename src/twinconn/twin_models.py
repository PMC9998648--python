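"""Classical twin-design decomposition of feature variance.

For each feature, the intra-pair partial correlation (net of age and sex) is
computed separately in monozygotic and dizygotic pairs.  The rMZ/rDZ ratio
then gates three scenarios:

* rMZ > 4 rDZ > 0            — epistatic (nonadditive, non-decomposable);
* 0 < 2 rDZ < rMZ <= 4 rDZ   — ADE: A = 4 rDZ - rMZ, D = 2 rMZ - 4 rDZ,
                               E = 1 - rMZ, broad-sense H2 = A + D = rMZ;
* 0 < rDZ < rMZ <= 2 rDZ     — ACE: A = 2 (rMZ - rDZ), C = 2 rDZ - rMZ,
                               E = 1 - rMZ, narrow-sense h2 = A;
* otherwise                  — UNMODELED (rMZ <= 0, rDZ <= 0 or rMZ <= rDZ).

These are Falconer-style closed-form estimators; they assume DZ twins share
half the additive and a quarter of the dominance genetic variance.  Boundary
points rMZ = 2 rDZ and rMZ = 4 rDZ are assigned to ACE (C = 0) and ADE
(A = 0) respectively so estimates are continuous across the gates.

The rMZ-vs-rDZ comparison uses Fisher's z transform with variance
1/(n - 3 - k) per group (k = number of covariates partialled out), a
one-sided upper-tail normal test of rMZ > rDZ, and Bonferroni correction
within (scale x scenario) families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .graph_metrics import feature_scale
from .io_model import RESULTS_COLUMNS, TwinPairManifest, ValidationError

__all__ = [
    "ZygosityCorrelations",
    "VarianceDecomposition",
    "FisherComparison",
    "partial_correlation",
    "zygosity_correlations",
    "fisher_z",
    "compare_correlations",
    "classify_scenario",
    "ade_decompose",
    "ace_decompose",
    "bonferroni_adjust",
    "run_twin_analysis",
]

SCENARIOS = ("EPISTASIS", "ADE", "ACE", "UNMODELED")


@dataclass(frozen=True)
class ZygosityCorrelations:
    """Per-feature intra-pair partial correlations by zygosity."""

    feature_id: str
    r_mz: float
    r_dz: float
    n_mz: int
    n_dz: int
    k: int  # number of covariates partialled out


@dataclass(frozen=True)
class VarianceDecomposition:
    """A/C/D/E variance proportions from Falconer's formulas.

    ``h2`` (narrow-sense, = A) is populated for ACE fits; ``H2``
    (broad-sense, = A + D = rMZ) for ADE fits.
    """

    model: str  # "ADE" | "ACE"
    A: float
    C: float
    D: float
    E: float
    H2: float | None = None
    h2: float | None = None


@dataclass(frozen=True)
class FisherComparison:
    Z: float
    p: float
    p_bonferroni: float | None = None
    significant_unc: bool | None = None
    significant_bonf: bool | None = None


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of the columns of y after least-squares fit on design."""
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValidationError("covariate matrix is rank-deficient")
    return y - design @ coef


def _drop_constant_columns(
    covariates: np.ndarray, names: list[str] | None = None
) -> tuple[np.ndarray, int]:
    """Drop covariate columns with zero variance (warning emitted)."""
    keep = covariates.std(axis=0) > 0
    if not keep.all():
        dropped = (
            [names[i] for i in np.flatnonzero(~keep)]
            if names
            else list(np.flatnonzero(~keep))
        )
        warnings.warn(
            f"dropping constant covariate column(s) {dropped}", stacklevel=3
        )
    return covariates[:, keep], int(keep.sum())


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> float:
    """Pearson correlation of x and y after removing linear covariate effects.

    Both variables are regressed on [intercept, covariates]; the partial
    correlation is the plain correlation of the two residual vectors.  With
    no covariates this reduces to the ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    n = x.size
    design = np.ones((n, 1))
    if covariates is not None:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
        if c.shape[0] != n:
            raise ValidationError("covariates length does not match x")
        design = np.hstack([design, c])
    rx = _residualize(x[:, None], design).ravel()
    ry = _residualize(y[:, None], design).ravel()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0.0:
        raise ValidationError("residual variance is zero; correlation undefined")
    return float(np.clip((rx @ ry) / denom, -1.0, 1.0))


def _columnwise_partial_corr(
    x: np.ndarray, y: np.ndarray, design: np.ndarray
) -> np.ndarray:
    """Partial correlation of paired columns of x and y given a shared design.

    Vectorized over features: x and y are (pairs x features) twin-1 / twin-2
    value matrices.  Columns whose residuals are constant yield NaN.
    """
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    num = np.einsum("ij,ij->j", rx, ry)
    denom = np.sqrt(
        np.einsum("ij,ij->j", rx, rx) * np.einsum("ij,ij->j", ry, ry)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    r[denom == 0.0] = np.nan
    return np.clip(r, -1.0, 1.0)


def zygosity_correlations(
    features: pd.DataFrame,
    manifest: TwinPairManifest,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Intra-pair partial correlations rMZ and rDZ for every feature.

    ``features`` is the subject x feature table; twins are paired as listed
    in the manifest (Twin#1 column vs Twin#2 column).  Age and sex are pair
    covariates (same-sex pairs sharing one age).  Constant covariate columns
    — e.g. sex in a single-sex cohort — are dropped with a warning and the
    covariate count ``k`` reduced accordingly.

    Returns a DataFrame indexed by feature_id with columns
    rMZ, rDZ, nMZ, nDZ, k.
    """
    missing = [
        s for s in manifest.subject_ids if s not in features.index
    ]
    if missing:
        raise ValidationError(f"subjects missing from feature table: {missing}")

    out: dict[str, np.ndarray] = {}
    ns: dict[str, int] = {}
    k_eff: int | None = None
    for zyg in ("MZ", "DZ"):
        pairs = manifest.by_zygosity(zyg)
        n = len(pairs)
        cov = np.array(
            [[p.age, 1.0 if p.sex == "M" else 0.0] for p in pairs]
        )
        cov, k = _drop_constant_columns(cov, ["age", "sex"])
        if n < k + 4:
            raise ValidationError(
                f"need at least k + 4 = {k + 4} {zyg} pairs for a defined "
                f"Fisher variance, got {n}"
            )
        x = features.loc[[p.twin1_id for p in pairs]].to_numpy(dtype=float)
        y = features.loc[[p.twin2_id for p in pairs]].to_numpy(dtype=float)
        design = np.hstack([np.ones((n, 1)), cov])
        out[zyg] = _columnwise_partial_corr(x, y, design)
        ns[zyg] = n
        k_eff = k if k_eff is None else max(k_eff, k)

    return pd.DataFrame(
        {
            "rMZ": out["MZ"],
            "rDZ": out["DZ"],
            "nMZ": ns["MZ"],
            "nDZ": ns["DZ"],
            "k": k_eff,
        },
        index=pd.Index(features.columns, name="feature_id"),
    )


# ---------------------------------------------------------------------------
# Fisher inference
# ---------------------------------------------------------------------------


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform z = atanh(r); requires |r| < 1."""
    r = float(r)
    if not np.isfinite(r) or abs(r) >= 1.0:
        raise ValidationError(f"fisher_z requires |r| < 1, got {r}")
    return float(np.arctanh(r))


def compare_correlations(zc: ZygosityCorrelations) -> FisherComparison:
    """One-sided Fisher test of rMZ > rDZ.

    Z = (atanh rMZ - atanh rDZ) / sqrt(1/(nMZ - 3 - k) + 1/(nDZ - 3 - k));
    p is the upper-tail standard-normal probability.  The k-term accounts
    for the covariates removed by the partial correlation.
    """
    df_mz = zc.n_mz - 3 - zc.k
    df_dz = zc.n_dz - 3 - zc.k
    if df_mz <= 0 or df_dz <= 0:
        raise ValidationError(
            f"Fisher variance undefined: nMZ - 3 - k = {df_mz}, nDZ - 3 - k = {df_dz}"
        )
    z = (fisher_z(zc.r_mz) - fisher_z(zc.r_dz)) / np.sqrt(1.0 / df_mz + 1.0 / df_dz)
    return FisherComparison(Z=float(z), p=float(stats.norm.sf(z)))


def bonferroni_adjust(
    p_values: np.ndarray, n_condition: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Bonferroni correction: p_adj = min(1, N * p), flags at ``alpha``.

    ``n_condition`` is the family size (number of comparisons in the same
    condition) and must cover the supplied list.
    """
    p = np.asarray(p_values, dtype=float)
    if n_condition < 1:
        raise ValidationError("family size must be >= 1")
    if n_condition < p.size:
        raise ValidationError(
            f"family size {n_condition} smaller than number of p-values {p.size}"
        )
    adj = np.minimum(1.0, n_condition * p)
    return pd.DataFrame(
        {
            "p": p,
            "p_bonferroni": adj,
            "significant_unc": p < alpha,
            "significant_bonf": adj < alpha,
        }
    )


# ---------------------------------------------------------------------------
# Scenario gating and Falconer decomposition
# ---------------------------------------------------------------------------


def classify_scenario(r_mz: float, r_dz: float) -> str:
    """Scenario label from the rMZ/rDZ ratio.

    Boundaries: rMZ = 2 rDZ goes to ACE (C = 0) and rMZ = 4 rDZ to ADE
    (A = 0), keeping component estimates continuous across the gates.
    NaN correlations are UNMODELED.
    """
    if not (np.isfinite(r_mz) and np.isfinite(r_dz)):
        return "UNMODELED"
    if r_dz <= 0.0 or r_mz <= r_dz:
        return "UNMODELED"
    if r_mz > 4.0 * r_dz:
        return "EPISTASIS"
    if r_mz > 2.0 * r_dz:
        return "ADE"
    return "ACE"


def ade_decompose(r_mz: float, r_dz: float) -> VarianceDecomposition:
    """Falconer ADE estimates: A = 4 rDZ - rMZ, D = 2 rMZ - 4 rDZ, E = 1 - rMZ.

    Broad-sense heritability H2 = A + D = rMZ.  Valid only inside the ADE
    gate 0 < 2 rDZ < rMZ <= 4 rDZ, where all components are non-negative and
    sum to one by construction.
    """
    if classify_scenario(r_mz, r_dz) != "ADE":
        raise ValidationError(
            f"(rMZ={r_mz}, rDZ={r_dz}) is not in the ADE scenario"
        )
    a = 4.0 * r_dz - r_mz
    d = 2.0 * r_mz - 4.0 * r_dz
    e = 1.0 - r_mz
    return VarianceDecomposition(model="ADE", A=a, C=0.0, D=d, E=e, H2=a + d)


def ace_decompose(r_mz: float, r_dz: float) -> VarianceDecomposition:
    """Falconer ACE estimates: A = 2 (rMZ - rDZ), C = 2 rDZ - rMZ, E = 1 - rMZ.

    Narrow-sense heritability h2 = A.  Valid only inside the ACE gate
    0 < rDZ < rMZ <= 2 rDZ.
    """
    if classify_scenario(r_mz, r_dz) != "ACE":
        raise ValidationError(
            f"(rMZ={r_mz}, rDZ={r_dz}) is not in the ACE scenario"
        )
    a = 2.0 * (r_mz - r_dz)
    c = 2.0 * r_dz - r_mz
    e = 1.0 - r_mz
    return VarianceDecomposition(model="ACE", A=a, C=c, D=0.0, E=e, h2=a)


# ---------------------------------------------------------------------------
# Full per-feature analysis
# ---------------------------------------------------------------------------


def _r_significant(r: float, n: int, k: int, alpha: float) -> bool:
    """One-sided Fisher test of r > 0 with variance 1/(n - 3 - k)."""
    if not np.isfinite(r) or abs(r) >= 1.0:
        return False
    z = np.arctanh(r) * np.sqrt(n - 3 - k)
    return bool(stats.norm.sf(z) < alpha)


def run_twin_analysis(
    features: pd.DataFrame,
    manifest: TwinPairManifest,
    alpha: float = 0.05,
    require_significant_r: bool = False,
    double_entry: bool = False,
) -> pd.DataFrame:
    """Full twin decomposition of every feature column.

    Per feature: zygosity-specific partial correlations, scenario gating,
    the applicable Falconer decomposition, and the one-sided Fisher
    comparison of rMZ vs rDZ with Bonferroni families defined per
    (scale x scenario) condition.

    With ``require_significant_r`` features whose rMZ or rDZ is not itself
    significantly positive are forced to UNMODELED before decomposition.
    ``double_entry`` enters each pair twice in both twin orders (making the
    correlation an intraclass estimate, robust to arbitrary within-pair
    ordering); the effective pair counts used in the Fisher variances remain
    the true ones.
    """
    if double_entry:
        features, manifest = _double_enter(features, manifest)
        zc = zygosity_correlations(features, manifest)
        zc["nMZ"] //= 2
        zc["nDZ"] //= 2
    else:
        zc = zygosity_correlations(features, manifest)

    records = []
    for feature_id, row in zc.iterrows():
        r_mz, r_dz = row["rMZ"], row["rDZ"]
        n_mz, n_dz, k = int(row["nMZ"]), int(row["nDZ"]), int(row["k"])
        scenario = classify_scenario(r_mz, r_dz)
        if require_significant_r and scenario != "UNMODELED":
            if not (
                _r_significant(r_mz, n_mz, k, alpha)
                and _r_significant(r_dz, n_dz, k, alpha)
            ):
                scenario = "UNMODELED"
        comp = {c: np.nan for c in ("A", "C", "D", "E", "H2", "h2")}
        if scenario == "ADE":
            dec = ade_decompose(r_mz, r_dz)
            comp.update(A=dec.A, C=np.nan, D=dec.D, E=dec.E, H2=dec.H2)
        elif scenario == "ACE":
            dec = ace_decompose(r_mz, r_dz)
            comp.update(A=dec.A, C=dec.C, D=np.nan, E=dec.E, h2=dec.h2)
        try:
            fc = compare_correlations(
                ZygosityCorrelations(feature_id, r_mz, r_dz, n_mz, n_dz, k)
            )
            z_stat, p = fc.Z, fc.p
        except ValidationError:
            z_stat, p = np.nan, np.nan
        records.append(
            {
                "feature_id": feature_id,
                "scale": feature_scale(feature_id),
                "rMZ": r_mz,
                "rDZ": r_dz,
                "scenario": scenario,
                **comp,
                "Z": z_stat,
                "p": p,
            }
        )
    results = pd.DataFrame(records)

    # Bonferroni family = (spatial scale x scenario condition)
    results["p_bonferroni"] = np.nan
    results["significant_unc"] = results["p"] < alpha
    results["significant_bonf"] = False
    for (_, _), idx in results.groupby(["scale", "scenario"]).groups.items():
        sub = results.loc[idx]
        valid = sub["p"].notna()
        if valid.any():
            adj = bonferroni_adjust(
                sub.loc[valid, "p"].to_numpy(), n_condition=int(valid.sum()),
                alpha=alpha,
            )
            results.loc[sub.index[valid], "p_bonferroni"] = adj["p_bonferroni"].to_numpy()
            results.loc[sub.index[valid], "significant_bonf"] = adj[
                "significant_bonf"
            ].to_numpy()
    return results[RESULTS_COLUMNS]


def _double_enter(
    features: pd.DataFrame, manifest: TwinPairManifest
) -> tuple[pd.DataFrame, TwinPairManifest]:
    """Duplicate each pair with twins in both orders (ids suffixed)."""
    from .io_model import TwinPair

    new_pairs = []
    frames = []
    for p in manifest.pairs:
        for tag, (t1, t2) in (("a", (p.twin1_id, p.twin2_id)),
                              ("b", (p.twin2_id, p.twin1_id))):
            new_pairs.append(
                TwinPair(
                    pair_id=f"{p.pair_id}_{tag}",
                    zygosity=p.zygosity,
                    twin1_id=f"{t1}_{tag}",
                    twin2_id=f"{t2}_{tag}",
                    age=p.age,
                    sex=p.sex,
                )
            )
            frames.append(
                features.loc[[t1, t2]].set_axis([f"{t1}_{tag}", f"{t2}_{tag}"])
            )
    return pd.concat(frames), TwinPairManifest(tuple(new_pairs))
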