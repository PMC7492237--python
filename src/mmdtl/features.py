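"""Connectome and clinical feature construction.

Functional connectivity is the temporal Pearson correlation of BOLD signals
between pairs of brain regions of interest (ROIs).  A subject's connectome is
a symmetric n x n correlation matrix (diagonal 1) whose strict upper triangle,
flattened row-major, is the model-ready feature vector (length n*(n-1)/2;
4005 edges for the 90-ROI anatomical parcellation used throughout).

Clinical covariates (mixed continuous / binary / categorical) are encoded to a
numeric vector by a fitted, reusable transform so that held-out data never
contribute to imputation or standardization statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "SubjectRecord",
    "ClinicalDictionary",
    "ClinicalTransform",
    "SiteNormalizer",
    "compute_connectivity",
    "vectorize",
    "devectorize",
    "site_normalize",
    "preprocess_clinical",
    "n_edges",
    "edge_names",
    "rescale_unit",
]

COHORTS = ("source", "intermediate", "target")


def n_edges(n_roi: int) -> int:
    """Number of distinct ROI pairs (strict upper-triangle length)."""
    return n_roi * (n_roi - 1) // 2


def _triangular_roi_count(m: int) -> int:
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"edge-vector length {m} is not n*(n-1)/2 for integer n")
    return n


@dataclass
class TimeSeriesMatrix:
    """Per-subject ROI time series: one column per ROI, one row per frame."""

    subject_id: str
    values: np.ndarray
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a frames x ROIs matrix")
        frames, rois = self.values.shape
        if frames < 3:
            raise ValueError(
                f"subject {self.subject_id}: need >= 3 frames, got {frames}"
            )
        if rois < 2:
            raise ValueError(f"subject {self.subject_id}: need >= 2 ROIs, got {rois}")
        if self.roi_names is None:
            self.roi_names = [f"ROI{i + 1}" for i in range(rois)]
        if len(self.roi_names) != rois:
            raise ValueError("roi_names length does not match column count")

    def constant_rois(self) -> list[str]:
        sd = self.values.std(axis=0)
        return [name for name, s in zip(self.roi_names, sd) if s == 0.0]


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI correlation matrix with unit diagonal."""

    subject_id: str
    values: np.ndarray
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("connectivity matrix is not symmetric (tol 1e-12)")
        if np.any(np.diag(v) != 1.0):
            raise ValueError("connectivity diagonal must be exactly 1")
        if np.min(v) < -1.0 or np.max(v) > 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
        if self.roi_names is None:
            self.roi_names = [f"ROI{i + 1}" for i in range(v.shape[0])]

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


@dataclass
class SubjectRecord:
    """One subject's model-ready features, cohort tag, and optional labels.

    ``connectome`` is the strict-upper-triangle edge vector (row-major);
    ``clinical`` an encoded clinical vector (target cohort); ``labels`` maps
    task name -> {0, 1}.  Source subjects carry exactly one label (the
    pre-training classification task); intermediate subjects carry none.
    """

    subject_id: str
    site: str
    cohort: str
    connectome: np.ndarray
    clinical: np.ndarray | None = None
    labels: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        self.connectome = np.asarray(self.connectome, dtype=float)
        _triangular_roi_count(len(self.connectome))
        if self.labels is not None:
            bad = {k: v for k, v in self.labels.items() if v not in (0, 1)}
            if bad:
                raise ValueError(f"labels must be 0/1, got {bad}")
        if self.cohort == "source" and (self.labels is None or len(self.labels) != 1):
            raise ValueError("source records carry exactly one label")
        if self.cohort == "intermediate" and self.labels:
            raise ValueError("intermediate records are unlabeled")

    @property
    def n_roi(self) -> int:
        return _triangular_roi_count(len(self.connectome))


def compute_connectivity(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation of every ROI pair; diagonal forced to 1.

    Raises if any ROI signal is constant (correlation undefined) naming the
    offending ROI.
    """
    const = ts.constant_rois()
    if const:
        raise ValueError(
            f"subject {ts.subject_id}: constant BOLD signal in ROI(s) "
            f"{', '.join(const)}; correlation undefined"
        )
    r = np.corrcoef(ts.values, rowvar=False)
    r = (r + r.T) / 2.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(ts.subject_id, r, list(ts.roi_names))


def vectorize(cm: ConnectivityMatrix) -> np.ndarray:
    """Strict upper triangle in row-major order: (0,1), (0,2), ..., (n-2,n-1)."""
    v = cm.values
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu].copy()


def devectorize(
    vec: np.ndarray, subject_id: str = "", roi_names: list[str] | None = None
) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize`: rebuild the symmetric unit-diagonal matrix."""
    vec = np.asarray(vec, dtype=float)
    n = _triangular_roi_count(len(vec))
    m = np.eye(n)
    iu = np.triu_indices(n, k=1)
    m[iu] = vec
    m[(iu[1], iu[0])] = vec
    return ConnectivityMatrix(subject_id, m, roi_names)


def edge_names(roi_names: list[str]) -> list[str]:
    """Edge labels 'ROIi__ROIj' in the fixed vectorization order."""
    n = len(roi_names)
    iu = np.triu_indices(n, k=1)
    return [f"{roi_names[i]}__{roi_names[j]}" for i, j in zip(*iu)]


def rescale_unit(x: np.ndarray) -> np.ndarray:
    """Affinely map correlation-valued features from [-1, 1] to [0, 1].

    Applied before every network stage so the autoencoder's per-feature
    cross-entropy reconstruction target is valid; used consistently in the
    supervised stages too.
    """
    return (np.asarray(x, dtype=float) + 1.0) / 2.0


class SiteNormalizer:
    """Per-site, per-feature z-scoring of connectome vectors.

    Multi-site collections carry additive scanner/site offsets; standardizing
    each feature within its site removes first- and second-moment site bias.
    Features constant within a site map to 0.  The fitted statistics are
    stored so held-out subjects can be transformed without refitting.
    """

    method = "per-site z-score"

    def __init__(self) -> None:
        self.site_stats_: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def fit(self, records: list[SubjectRecord]) -> "SiteNormalizer":
        stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        sites: dict[str, list[np.ndarray]] = {}
        for r in records:
            sites.setdefault(r.site, []).append(r.connectome)
        for site, vecs in sites.items():
            if len(vecs) < 2:
                raise ValueError(
                    f"site {site!r} has a single subject; per-site statistics "
                    "are undefined — pool sites or drop the subject"
                )
            x = np.vstack(vecs)
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            stats[site] = (mu, sd)
        self.site_stats_ = stats
        return self

    def transform(self, records: list[SubjectRecord]) -> list[SubjectRecord]:
        if self.site_stats_ is None:
            raise RuntimeError("SiteNormalizer is not fitted")
        out = []
        for r in records:
            if r.site not in self.site_stats_:
                raise ValueError(f"site {r.site!r} was not seen during fitting")
            mu, sd = self.site_stats_[r.site]
            z = np.where(sd > 0, (r.connectome - mu) / np.where(sd > 0, sd, 1.0), 0.0)
            out.append(
                SubjectRecord(r.subject_id, r.site, r.cohort, z, r.clinical, r.labels)
            )
        return out

    @property
    def metadata(self) -> dict:
        return {"method": self.method, "sites": sorted(self.site_stats_ or {})}


def site_normalize(records: list[SubjectRecord]) -> list[SubjectRecord]:
    """Fit-and-apply per-site z-scoring (see :class:`SiteNormalizer`)."""
    return SiteNormalizer().fit(records).transform(records)


@dataclass
class ClinicalDictionary:
    """Declared name, type and domain of every clinical-table column.

    ``entries`` is an ordered list of (name, type, domain) with type in
    {continuous, binary, categorical}; the six overarching domains cover
    maternal demographics through follow-up measurements.
    """

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("clinical dictionary has duplicate feature names")
        for name, typ, _dom in self.entries:
            if typ not in ("continuous", "binary", "categorical"):
                raise ValueError(f"unknown feature type {typ!r} for {name!r}")

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    def type_of(self, name: str) -> str:
        for n, t, _ in self.entries:
            if n == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["name", "type", "domain"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClinicalDictionary":
        return cls([tuple(row) for row in df[["name", "type", "domain"]].to_numpy()])


class ClinicalTransform:
    """Fitted encoder for a mixed-type clinical table.

    Continuous columns: median-imputed then standardized with the fitting
    split's mean/SD (zero-variance columns encode to 0 with a warning).
    Binary columns: mode-imputed, mapped to {0, 1} by sorted level order.
    Categorical columns: mode-imputed, one-hot over the fitted level set.
    All imputation values and statistics are stored so the transform is
    reusable on held-out rows without refitting.
    """

    def __init__(self, dictionary: ClinicalDictionary) -> None:
        self.dictionary = dictionary
        self.columns_: dict[str, dict] | None = None
        self.feature_names_: list[str] | None = None

    def fit(self, table: pd.DataFrame) -> "ClinicalTransform":
        known = set(self.dictionary.names)
        unknown = [c for c in table.columns if c not in known]
        if unknown:
            raise ValueError(f"columns not in clinical dictionary: {unknown}")
        cols: dict[str, dict] = {}
        names: list[str] = []
        for name in self.dictionary.names:
            if name not in table.columns:
                continue
            col = table[name]
            if col.isna().all():
                raise ValueError(f"clinical column {name!r} is entirely missing")
            typ = self.dictionary.type_of(name)
            if typ == "continuous":
                x = pd.to_numeric(col, errors="coerce")
                med = float(x.median())
                filled = x.fillna(med)
                mu, sd = float(filled.mean()), float(filled.std(ddof=0))
                if sd == 0.0:
                    warnings.warn(
                        f"clinical column {name!r} has zero variance; encoded as 0",
                        stacklevel=2,
                    )
                cols[name] = {"type": typ, "impute": med, "mean": mu, "sd": sd}
                names.append(name)
            elif typ == "binary":
                mode = col.mode(dropna=True).iloc[0]
                levels = sorted(col.dropna().unique(), key=str)
                if len(levels) > 2:
                    raise ValueError(f"binary column {name!r} has >2 levels: {levels}")
                cols[name] = {"type": typ, "impute": mode, "levels": levels}
                names.append(name)
            else:  # categorical
                mode = col.mode(dropna=True).iloc[0]
                levels = sorted(col.dropna().unique(), key=str)
                cols[name] = {"type": typ, "impute": mode, "levels": levels}
                names.extend(f"{name}={lv}" for lv in levels)
        self.columns_ = cols
        self.feature_names_ = names
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        if self.columns_ is None:
            raise RuntimeError("ClinicalTransform is not fitted")
        unknown = [c for c in table.columns if c not in set(self.dictionary.names)]
        if unknown:
            raise ValueError(f"columns not in clinical dictionary: {unknown}")
        blocks: list[np.ndarray] = []
        for name, info in self.columns_.items():
            col = table[name]
            if info["type"] == "continuous":
                x = pd.to_numeric(col, errors="coerce").fillna(info["impute"])
                if info["sd"] == 0.0:
                    blocks.append(np.zeros(len(table)))
                else:
                    blocks.append((x.to_numpy(float) - info["mean"]) / info["sd"])
            elif info["type"] == "binary":
                x = col.fillna(info["impute"])
                lv = info["levels"]
                mapping = {lv[0]: 0.0} | ({lv[1]: 1.0} if len(lv) > 1 else {})
                blocks.append(x.map(mapping).fillna(0.0).to_numpy(float))
            else:
                x = col.fillna(info["impute"])
                for level in info["levels"]:
                    blocks.append((x == level).to_numpy(float))
        return np.column_stack(blocks)

    @property
    def width(self) -> int:
        if self.feature_names_ is None:
            raise RuntimeError("ClinicalTransform is not fitted")
        return len(self.feature_names_)


def preprocess_clinical(
    table: pd.DataFrame, dictionary: ClinicalDictionary
) -> tuple[np.ndarray, ClinicalTransform]:
    """Fit a :class:`ClinicalTransform` on ``table`` and encode it."""
    tf = ClinicalTransform(dictionary).fit(table)
    return tf.transform(table), tf
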