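"""Domain types and file I/O for twin functional-connectivity analyses.

All on-disk formats are tab-separated UTF-8 text with header rows, so every
artifact (manifests, ROI time series, connectivity matrices, results tables)
is diff-friendly and round-trips exactly.  The parcellation label order is
the single source of truth: every ROI-indexed structure in the package is
stored and validated positionally against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParcellationLabels",
    "AAL90",
    "TwinPair",
    "TwinPairManifest",
    "ROITimeSeries",
    "RSNMap",
    "WeightedFCMatrix",
    "BinaryFCMatrix",
    "PValueMatrix",
    "RESULTS_COLUMNS",
    "read_pair_manifest",
    "write_pair_manifest",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "read_rsn_map",
    "write_rsn_map",
    "default_rsn_map",
    "read_matrix",
    "write_matrix",
    "read_results_table",
    "write_results_table",
]


class ValidationError(ValueError):
    """An input file or in-memory object violates a structural invariant."""


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParcellationLabels:
    """Ordered, unique ROI names defining node identity for a whole cohort.

    The default 90-region list covers the AAL cortical and subcortical
    regions (cerebellum and vermis excluded) in standard AAL order.  Any
    label set may be supplied; the pipeline is atlas-agnostic.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValidationError("parcellation needs at least 2 ROIs")
        if len(set(self.labels)) != len(self.labels):
            dupes = {x for x in self.labels if list(self.labels).count(x) > 1}
            raise ValidationError(f"duplicate ROI labels: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown ROI label: {label!r}") from None


# The 90 AAL cortical/subcortical regions in standard atlas order
# (regions 1-90 of the AAL atlas; cerebellar regions 91-116 excluded).
_AAL90_LABELS = (
    "Precentral_L", "Precentral_R",
    "Frontal_Sup_L", "Frontal_Sup_R",
    "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R",
    "Frontal_Mid_L", "Frontal_Mid_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R",
    "Frontal_Inf_Oper_L", "Frontal_Inf_Oper_R",
    "Frontal_Inf_Tri_L", "Frontal_Inf_Tri_R",
    "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R",
    "Rolandic_Oper_L", "Rolandic_Oper_R",
    "Supp_Motor_Area_L", "Supp_Motor_Area_R",
    "Olfactory_L", "Olfactory_R",
    "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
    "Frontal_Med_Orb_L", "Frontal_Med_Orb_R",
    "Rectus_L", "Rectus_R",
    "Insula_L", "Insula_R",
    "Cingulum_Ant_L", "Cingulum_Ant_R",
    "Cingulum_Mid_L", "Cingulum_Mid_R",
    "Cingulum_Post_L", "Cingulum_Post_R",
    "Hippocampus_L", "Hippocampus_R",
    "ParaHippocampal_L", "ParaHippocampal_R",
    "Amygdala_L", "Amygdala_R",
    "Calcarine_L", "Calcarine_R",
    "Cuneus_L", "Cuneus_R",
    "Lingual_L", "Lingual_R",
    "Occipital_Sup_L", "Occipital_Sup_R",
    "Occipital_Mid_L", "Occipital_Mid_R",
    "Occipital_Inf_L", "Occipital_Inf_R",
    "Fusiform_L", "Fusiform_R",
    "Postcentral_L", "Postcentral_R",
    "Parietal_Sup_L", "Parietal_Sup_R",
    "Parietal_Inf_L", "Parietal_Inf_R",
    "SupraMarginal_L", "SupraMarginal_R",
    "Angular_L", "Angular_R",
    "Precuneus_L", "Precuneus_R",
    "Paracentral_Lobule_L", "Paracentral_Lobule_R",
    "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R",
    "Pallidum_L", "Pallidum_R",
    "Thalamus_L", "Thalamus_R",
    "Heschl_L", "Heschl_R",
    "Temporal_Sup_L", "Temporal_Sup_R",
    "Temporal_Pole_Sup_L", "Temporal_Pole_Sup_R",
    "Temporal_Mid_L", "Temporal_Mid_R",
    "Temporal_Pole_Mid_L", "Temporal_Pole_Mid_R",
    "Temporal_Inf_L", "Temporal_Inf_R",
)

#: Default parcellation: 90 AAL cortical/subcortical ROIs.
AAL90 = ParcellationLabels(_AAL90_LABELS)


# ---------------------------------------------------------------------------
# Twin-pair manifest
# ---------------------------------------------------------------------------

VALID_ZYGOSITIES = ("MZ", "DZ")
VALID_SEXES = ("F", "M")


@dataclass(frozen=True)
class TwinPair:
    pair_id: str
    zygosity: str  # "MZ" | "DZ"
    twin1_id: str
    twin2_id: str
    age: float  # years, shared within a pair
    sex: str  # "F" | "M", same-sex pairs only


@dataclass(frozen=True)
class TwinPairManifest:
    """Validated collection of same-sex twin pairs with zygosity and covariates."""

    pairs: tuple[TwinPair, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pairs:
            if p.zygosity not in VALID_ZYGOSITIES:
                raise ValidationError(
                    f"pair {p.pair_id}: zygosity must be MZ or DZ, got {p.zygosity!r}"
                )
            if p.sex not in VALID_SEXES:
                raise ValidationError(
                    f"pair {p.pair_id}: sex must be F or M, got {p.sex!r}"
                )
            if not math.isfinite(p.age) or p.age < 0:
                raise ValidationError(f"pair {p.pair_id}: age must be finite and >= 0")
            for sid in (p.twin1_id, p.twin2_id):
                if sid in seen:
                    raise ValidationError(f"duplicate subject id: {sid!r}")
                seen.add(sid)

    @property
    def n_mz(self) -> int:
        return sum(p.zygosity == "MZ" for p in self.pairs)

    @property
    def n_dz(self) -> int:
        return sum(p.zygosity == "DZ" for p in self.pairs)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for p in self.pairs:
            out.extend((p.twin1_id, p.twin2_id))
        return tuple(out)

    def by_zygosity(self, zygosity: str) -> tuple[TwinPair, ...]:
        if zygosity not in VALID_ZYGOSITIES:
            raise ValidationError(f"unknown zygosity {zygosity!r}")
        return tuple(p for p in self.pairs if p.zygosity == zygosity)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.pair_id, p.zygosity, p.twin1_id, p.twin2_id, p.age, p.sex)
                for p in self.pairs
            ],
            columns=["pair_id", "zygosity", "twin1_id", "twin2_id", "age", "sex"],
        )


_MANIFEST_COLUMNS = ["pair_id", "zygosity", "twin1_id", "twin2_id", "age", "sex"]


def read_pair_manifest(path: str | Path) -> TwinPairManifest:
    """Read a tab-separated twin-pair manifest.

    Expected header: ``pair_id  zygosity  twin1_id  twin2_id  age  sex``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    pairs = []
    for row in df.itertuples(index=False):
        try:
            age = float(row.age)
        except (TypeError, ValueError):
            raise ValidationError(
                f"pair {row.pair_id}: non-numeric age {row.age!r}"
            ) from None
        pairs.append(
            TwinPair(
                pair_id=str(row.pair_id),
                zygosity=str(row.zygosity),
                twin1_id=str(row.twin1_id),
                twin2_id=str(row.twin2_id),
                age=age,
                sex=str(row.sex),
            )
        )
    return TwinPairManifest(tuple(pairs))


def write_pair_manifest(manifest: TwinPairManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ROI time series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROITimeSeries:
    """T x N matrix of ROI-mean BOLD signal for one subject.

    Columns follow the parcellation order exactly.  T >= 4 is required so the
    correlation significance test has at least 2 degrees of freedom.
    """

    subject_id: str
    values: np.ndarray
    parcellation: ParcellationLabels

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValidationError("time series must be a 2-D array")
        if v.shape[1] != len(self.parcellation):
            raise ValidationError(
                f"subject {self.subject_id}: {v.shape[1]} columns but "
                f"parcellation has {len(self.parcellation)} ROIs"
            )
        if v.shape[0] < 4:
            raise ValidationError(
                f"subject {self.subject_id}: need T >= 4 timepoints, got {v.shape[0]}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"subject {self.subject_id}: non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


def read_roi_timeseries(
    path: str | Path, parcellation: ParcellationLabels, subject_id: str | None = None
) -> ROITimeSeries:
    """Read a tab-separated T x N time-series file (header row = ROI labels).

    Columns may appear in any order; they are re-ordered to the parcellation.
    The subject id defaults to the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [lab for lab in parcellation if lab not in df.columns]
    if missing:
        raise ValidationError(f"time series missing ROI columns: {missing}")
    sub = df[list(parcellation.labels)]
    for col in sub.columns:
        if not np.issubdtype(sub[col].dtype, np.number):
            numeric = pd.to_numeric(sub[col], errors="coerce")
            row = int(numeric.index[numeric.isna()][0])
            raise ValidationError(
                f"non-numeric value in column {col!r}, row {row}"
            )
    return ROITimeSeries(
        subject_id=subject_id or path.stem,
        values=sub.to_numpy(dtype=float),
        parcellation=parcellation,
    )


def write_roi_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.values, columns=list(ts.parcellation.labels)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# RSN map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RSNMap:
    """Mapping from resting-state network name to member ROI labels.

    Networks may overlap; each needs at least two member ROIs so that it
    contains at least one within-network link.
    """

    networks: Mapping[str, tuple[str, ...]]
    parcellation: ParcellationLabels

    def __post_init__(self) -> None:
        frozen = {str(k): tuple(v) for k, v in self.networks.items()}
        for name, rois in frozen.items():
            if len(rois) < 2:
                raise ValidationError(f"RSN {name!r} needs >= 2 ROIs, got {len(rois)}")
            if len(set(rois)) != len(rois):
                raise ValidationError(f"RSN {name!r} lists a ROI twice")
            unknown = [r for r in rois if r not in self.parcellation]
            if unknown:
                raise ValidationError(f"RSN {name!r}: unknown ROI labels {unknown}")
        object.__setattr__(self, "networks", frozen)

    def __iter__(self) -> Iterator[str]:
        return iter(self.networks)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.networks[name]

    def items(self):
        return self.networks.items()


def read_rsn_map(path: str | Path, parcellation: ParcellationLabels) -> RSNMap:
    """Read a YAML mapping of RSN name -> list of ROI labels."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError("RSN map must be a mapping of name -> ROI list")
    return RSNMap({k: tuple(v) for k, v in raw.items()}, parcellation)


def write_rsn_map(rsn_map: RSNMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {k: list(v) for k, v in rsn_map.items()}, fh, sort_keys=False
        )


# Placeholder AAL-to-RSN assignment assembled from canonical resting-state
# network descriptions in the general literature.  Intended as an editable
# starting point, not as any study's exact supplementary table.
_DEFAULT_RSN_ASSIGNMENT: dict[str, tuple[str, ...]] = {
    "SAL": (
        "Insula_L", "Insula_R", "Cingulum_Ant_L", "Cingulum_Ant_R",
        "Amygdala_L", "Amygdala_R", "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R",
    ),
    "DMN": (
        "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
        "Frontal_Med_Orb_L", "Frontal_Med_Orb_R",
        "Cingulum_Post_L", "Cingulum_Post_R",
        "Precuneus_L", "Precuneus_R", "Angular_L", "Angular_R",
        "Hippocampus_L", "Hippocampus_R", "Temporal_Mid_L", "Temporal_Mid_R",
    ),
    "CEN": (
        "Frontal_Mid_L", "Frontal_Mid_R",
        "Frontal_Inf_Tri_L", "Frontal_Inf_Tri_R",
        "Parietal_Sup_L", "Parietal_Sup_R",
        "Parietal_Inf_L", "Parietal_Inf_R",
        "SupraMarginal_L", "SupraMarginal_R",
    ),
    "MOT": (
        "Precentral_L", "Precentral_R", "Postcentral_L", "Postcentral_R",
        "Supp_Motor_Area_L", "Supp_Motor_Area_R",
        "Paracentral_Lobule_L", "Paracentral_Lobule_R",
    ),
    "VIS": (
        "Calcarine_L", "Calcarine_R", "Cuneus_L", "Cuneus_R",
        "Lingual_L", "Lingual_R", "Occipital_Sup_L", "Occipital_Sup_R",
        "Occipital_Mid_L", "Occipital_Mid_R",
        "Occipital_Inf_L", "Occipital_Inf_R", "Fusiform_L", "Fusiform_R",
    ),
    "AUD": (
        "Heschl_L", "Heschl_R", "Temporal_Sup_L", "Temporal_Sup_R",
        "Temporal_Pole_Sup_L", "Temporal_Pole_Sup_R",
    ),
    "BG": (
        "Caudate_L", "Caudate_R", "Putamen_L", "Putamen_R",
        "Pallidum_L", "Pallidum_R", "Thalamus_L", "Thalamus_R",
    ),
}


def default_rsn_map(parcellation: ParcellationLabels = AAL90) -> RSNMap:
    """Editable default assignment of AAL ROIs to seven major RSNs."""
    return RSNMap(dict(_DEFAULT_RSN_ASSIGNMENT), parcellation)


# ---------------------------------------------------------------------------
# FC matrices
# ---------------------------------------------------------------------------


def _check_square_symmetric(values: np.ndarray, n: int, what: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.shape != (n, n):
        raise ValidationError(f"{what}: expected shape ({n}, {n}), got {v.shape}")
    if not np.allclose(v, v.T, atol=0.0, rtol=0.0, equal_nan=False):
        raise ValidationError(f"{what}: matrix is not symmetric")
    return v


@dataclass(frozen=True)
class WeightedFCMatrix:
    """Symmetric N x N Pearson-correlation matrix with zero diagonal.

    After significance masking, entries whose correlations were not
    significant are exactly 0; significant entries keep their signed value.
    """

    values: np.ndarray
    parcellation: ParcellationLabels

    def __post_init__(self) -> None:
        v = _check_square_symmetric(self.values, len(self.parcellation), "weighted FC")
        if np.any(np.diag(v) != 0.0):
            raise ValidationError("weighted FC: diagonal must be zero")
        if np.any(np.abs(v) > 1.0 + 1e-12):
            raise ValidationError("weighted FC: entries must lie in [-1, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BinaryFCMatrix:
    """Symmetric N x N adjacency matrix with entries in {0, 1}, zero diagonal."""

    values: np.ndarray
    parcellation: ParcellationLabels

    def __post_init__(self) -> None:
        v = _check_square_symmetric(self.values, len(self.parcellation), "binary FC")
        if not np.all(np.isin(v, (0.0, 1.0))):
            raise ValidationError("binary FC: entries must be 0 or 1")
        if np.any(np.diag(v) != 0.0):
            raise ValidationError("binary FC: diagonal must be zero")
        object.__setattr__(self, "values", v)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.values, k=1).sum())


@dataclass(frozen=True)
class PValueMatrix:
    """Symmetric N x N matrix of two-sided correlation p-values (diagonal = 1)."""

    values: np.ndarray
    parcellation: ParcellationLabels

    def __post_init__(self) -> None:
        v = _check_square_symmetric(self.values, len(self.parcellation), "p-values")
        if np.any((v < 0.0) | (v > 1.0)):
            raise ValidationError("p-values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


_MATRIX_TYPES = {"weighted": WeightedFCMatrix, "binary": BinaryFCMatrix}


def write_matrix(
    matrix: WeightedFCMatrix | BinaryFCMatrix, path: str | Path
) -> None:
    """Write a labelled square matrix as TSV (labels in first row and column).

    Full ``repr`` float precision is used so write -> read is lossless.
    """
    labels = list(matrix.parcellation.labels)
    df = pd.DataFrame(matrix.values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", index_label="ROI", float_format="%.17g")


def read_matrix(
    path: str | Path,
    parcellation: ParcellationLabels,
    kind: str = "weighted",
) -> WeightedFCMatrix | BinaryFCMatrix:
    """Read a labelled square matrix written by :func:`write_matrix`.

    ``kind`` selects the container ("weighted" or "binary"); its invariants
    are re-validated on read.
    """
    if kind not in _MATRIX_TYPES:
        raise ValidationError(f"kind must be one of {sorted(_MATRIX_TYPES)}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = list(parcellation.labels)
    if list(df.index) != labels or list(df.columns) != labels:
        raise ValidationError("matrix labels do not match the parcellation")
    return _MATRIX_TYPES[kind](df.to_numpy(dtype=float), parcellation)


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

#: Long-format results schema: one row per analyzed feature.
RESULTS_COLUMNS = [
    "feature_id",
    "scale",  # link | node | network
    "rMZ",
    "rDZ",
    "scenario",  # EPISTASIS | ADE | ACE | UNMODELED
    "A",
    "C",
    "D",
    "E",
    "H2",
    "h2",
    "Z",
    "p",
    "p_bonferroni",
    "significant_unc",
    "significant_bonf",
]


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format results table as TSV.

    Rows are sorted by (scale, feature_id) so repeated writes of the same
    results are byte-identical.
    """
    missing = [c for c in RESULTS_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"results table missing columns: {missing}")
    out = results[RESULTS_COLUMNS].sort_values(["scale", "feature_id"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"results table missing columns: {missing}")
    return df
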