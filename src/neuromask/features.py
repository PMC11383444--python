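"""Derivation of connectivity- and ROI-level features on a shared parcellation.

Given per-subject ROI time series (BOLD), raw streamline-count structural
connectivity and per-ROI morphology tables, this module computes everything
the model consumes:

* functional connectivity (FC): Pearson correlation between ROI time series,
  min-max scaled per subject;
* intrinsic neural timescale (INT): repetition-time-scaled area under the
  initial positive phase of the signal autocorrelation, one value per ROI;
* normalized structural connectivity (SC): streamline counts divided by the
  square root of the product of the two regions' gray-matter volumes, then
  min-max scaled;
* structure-function coupling: per-ROI Spearman correlation between the SC
  and FC connectivity profiles of that region;
* the anatomical-statistics (AS) table: nine morphology columns plus INT and
  coupling, log-transformed and min-max scaled column-wise.

All scaling is within-subject by default (cohort-level scaling is available
behind a flag on the pipeline helpers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "AnatomicalTable",
    "GmVolumes",
    "MORPHOLOGY_COLUMNS",
    "compute_fc",
    "compute_int",
    "minmax_scale",
    "minmax_scale_offdiag",
    "normalize_sc",
    "scale_anatomical",
    "compute_coupling",
    "assemble_as",
    "scale_fc",
]

#: FreeSurfer-style names for the nine surface-morphology / volumetric
#: measures, in the canonical column order used throughout the package.
MORPHOLOGY_COLUMNS = (
    "num_vertices",
    "surface_area",
    "gray_matter_volume",
    "thickness_mean",
    "thickness_std",
    "mean_curvature",
    "gaussian_curvature",
    "curvature_index",
    "folding_index",
)

_SYMMETRY_TOL = 1e-10


@dataclass
class RoiTimeSeries:
    """A T x Q matrix of BOLD samples plus the repetition time in seconds."""

    values: np.ndarray
    tr: float
    roi_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 3:
            raise ValueError("time series must be a T x Q matrix with T >= 3")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite entries")
        if self.tr <= 0:
            raise ValueError("repetition time TR must be positive")
        if self.roi_ids is None:
            self.roi_ids = [f"ROI{i:03d}" for i in range(self.values.shape[1])]
        if len(self.roi_ids) != self.values.shape[1]:
            raise ValueError("roi_ids length does not match column count")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Q x Q symmetric connectivity matrix tagged with its modality."""

    values: np.ndarray
    modality: str  # "FC" | "SC"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        q = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != q:
            raise ValueError("connectivity matrix must be square")
        if self.modality not in ("FC", "SC"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if np.max(np.abs(self.values - self.values.T)) > _SYMMETRY_TOL:
            raise ValueError("connectivity matrix is not symmetric")
        if self.modality == "SC":
            if np.any(self.values < 0):
                raise ValueError("SC entries must be nonnegative")
            if np.any(np.diag(self.values) != 0):
                raise ValueError("SC diagonal must be zero")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class AnatomicalTable:
    """Q x d_c table of per-ROI features (morphology, INT, coupling)."""

    values: np.ndarray
    column_names: list[str]
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("anatomical table must be 2-D")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column count does not match column_names")
        if self.scaled and self.values.size and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ValueError("scaled table has entries outside [0, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass
class GmVolumes:
    """Strictly positive gray-matter volume per ROI (mm^3)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("gray-matter volumes must be a vector")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("gray-matter volumes must be finite and strictly positive")


# ---------------------------------------------------------------------------
# Functional connectivity
# ---------------------------------------------------------------------------

def compute_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson-correlation FC matrix of the ROI time series.

    Raises if any ROI column is constant (the correlation is undefined).
    """
    x = ts.values
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance time series for ROI {ts.roi_ids[bad[0]]}")
    fc = np.corrcoef(x, rowvar=False)
    fc = np.clip(fc, -1.0, 1.0)
    fc = (fc + fc.T) / 2.0
    np.fill_diagonal(fc, 1.0)
    return ConnectivityMatrix(fc, modality="FC", normalized=False)


# ---------------------------------------------------------------------------
# Intrinsic neural timescale
# ---------------------------------------------------------------------------

def compute_int(ts: RoiTimeSeries) -> np.ndarray:
    """Intrinsic neural timescale per ROI, in seconds.

    For each ROI the sample autocorrelation function

        r(k) = sum_{t=k+1}^{T} (y_t - ybar)(y_{t-k} - ybar) / sum_t (y_t - ybar)^2

    is accumulated over its initial positive phase: the INT is
    ``TR * sum_{k=1}^{N} r(k)`` where N is the lag immediately preceding the
    first negative autocorrelation.  A signal whose lag-1 autocorrelation is
    already negative has INT exactly 0; if the autocorrelation never turns
    negative the sum runs to the largest retained lag (T - 2).
    """
    x = ts.values
    t, q = x.shape
    xm = x - x.mean(axis=0, keepdims=True)
    denom = np.sum(xm * xm, axis=0)
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        raise ValueError(f"constant time series for ROI {ts.roi_ids[bad[0]]}")

    max_lag = t - 2
    out = np.zeros(q)
    for j in range(q):
        # full raw autocovariance via correlation; lag k sum at index t-1+k
        ac = np.correlate(xm[:, j], xm[:, j], mode="full")[t - 1 :]
        r = ac[1 : max_lag + 1] / denom[j]
        neg = np.flatnonzero(r < 0)
        n = neg[0] if neg.size else max_lag
        out[j] = ts.tr * np.sum(r[:n])
    return out


# ---------------------------------------------------------------------------
# Scaling helpers
# ---------------------------------------------------------------------------

def minmax_scale(m: np.ndarray) -> np.ndarray:
    """Min-max scale an array to [0, 1]; a constant array maps to all zeros."""
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("minmax_scale requires finite input")
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def minmax_scale_offdiag(m: np.ndarray, diag_value: float = 0.0) -> np.ndarray:
    """Min-max scale the off-diagonal entries of a square matrix to [0, 1].

    The diagonal is set to ``diag_value`` and excluded from the min/max.
    """
    m = np.asarray(m, dtype=float)
    q = m.shape[0]
    mask = ~np.eye(q, dtype=bool)
    vals = m[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("minmax_scale_offdiag requires finite input")
    lo, hi = vals.min(), vals.max()
    out = np.zeros_like(m)
    if hi > lo:
        out[mask] = (m[mask] - lo) / (hi - lo)
    np.fill_diagonal(out, diag_value)
    return out


def scale_fc(fc: ConnectivityMatrix) -> ConnectivityMatrix:
    """Min-max scale an FC matrix over its off-diagonal entries.

    The diagonal (self-correlation) is pinned to 1 after scaling.
    """
    if fc.modality != "FC":
        raise ValueError("scale_fc expects an FC matrix")
    scaled = minmax_scale_offdiag(fc.values, diag_value=1.0)
    return ConnectivityMatrix(scaled, modality="FC", normalized=True)


# ---------------------------------------------------------------------------
# Structural connectivity normalization
# ---------------------------------------------------------------------------

def normalize_sc(raw: ConnectivityMatrix, vol: GmVolumes) -> ConnectivityMatrix:
    """Volume-normalize and min-max scale a raw streamline-count SC matrix.

    Entry (i, j) becomes ``raw(i, j) / sqrt(V_i * V_j)`` — correcting for the
    fact that larger regions accumulate more streamlines — followed by
    min-max scaling of the off-diagonal entries to [0, 1].
    """
    if raw.modality != "SC":
        raise ValueError("normalize_sc expects an SC matrix")
    if raw.n_rois != vol.values.size:
        raise ValueError("SC matrix and volume vector disagree on ROI count")
    denom = np.sqrt(np.outer(vol.values, vol.values))
    adj = raw.values / denom
    scaled = minmax_scale_offdiag(adj, diag_value=0.0)
    return ConnectivityMatrix(scaled, modality="SC", normalized=True)


# ---------------------------------------------------------------------------
# Anatomical table scaling and assembly
# ---------------------------------------------------------------------------

def scale_anatomical(raw: AnatomicalTable, log: str = "log1p") -> AnatomicalTable:
    """Variance-stabilize and scale an anatomical table column by column.

    Each column is transformed with ``log1p`` (default; tolerates exact
    zeros) or plain ``log`` (requires strictly positive entries), then
    min-max scaled to [0, 1].  Columns that may be negative (curvatures,
    coupling) are shifted to their minimum before the log so the transform
    is defined; this preserves within-column order, which is all min-max
    scaling retains anyway.
    """
    if log not in ("log1p", "log"):
        raise ValueError("log must be 'log1p' or 'log'")
    x = raw.values
    if not np.all(np.isfinite(x)):
        raise ValueError("anatomical table contains non-finite values")
    out = np.empty_like(x, dtype=float)
    for c in range(x.shape[1]):
        col = x[:, c]
        shifted = col - min(col.min(), 0.0)
        if log == "log":
            if np.any(shifted <= 0):
                raise ValueError(
                    f"column {raw.column_names[c]!r} has non-positive entries; "
                    "plain log requires strictly positive values"
                )
            tr = np.log(shifted)
        else:
            tr = np.log1p(shifted)
        out[:, c] = minmax_scale(tr)
    return AnatomicalTable(out, list(raw.column_names), scaled=True)


def compute_coupling(
    sc: ConnectivityMatrix,
    fc: ConnectivityMatrix,
    min_support: int = 3,
) -> np.ndarray:
    """Per-ROI structure-function coupling.

    For region q the coupling is the Spearman rank correlation between row q
    of the (normalized) SC matrix and row q of the FC matrix, restricted to
    the off-diagonal entries where SC > 0 — the convention that coupling is
    evaluated over a region's existing white-matter connections.  Regions
    with fewer than ``min_support`` nonzero SC entries get coupling 0.
    """
    if sc.n_rois != fc.n_rois:
        raise ValueError("SC and FC disagree on ROI count")
    q = sc.n_rois
    if not np.any(sc.values > 0):
        raise ValueError("all-zero SC matrix: coupling is undefined")
    rho = np.zeros(q)
    offdiag = ~np.eye(q, dtype=bool)
    for i in range(q):
        support = offdiag[i] & (sc.values[i] > 0)
        if support.sum() < min_support:
            continue  # imputed as 0
        s_row = sc.values[i, support]
        f_row = fc.values[i, support]
        if np.all(s_row == s_row[0]) or np.all(f_row == f_row[0]):
            continue
        res = stats.spearmanr(s_row, f_row)
        rho[i] = float(res.statistic)
    return np.clip(rho, -1.0, 1.0)


def assemble_as(
    morphology: AnatomicalTable,
    int_vec: np.ndarray,
    coupling_vec: np.ndarray,
    log: str = "log1p",
) -> AnatomicalTable:
    """Assemble and scale the full AS table: morphology + INT + coupling.

    Column order is fixed: the morphology columns in their given order,
    then ``int_s`` (intrinsic timescale, seconds), then ``coupling``.  The
    result is passed through :func:`scale_anatomical`, so entries lie in
    [0, 1].  An empty morphology table (0 columns) is allowed for
    single-feature ablations.
    """
    int_vec = np.asarray(int_vec, dtype=float)
    coupling_vec = np.asarray(coupling_vec, dtype=float)
    q = morphology.n_rois
    if int_vec.shape != (q,) or coupling_vec.shape != (q,):
        raise ValueError("INT / coupling vectors do not match ROI count")
    values = np.column_stack([morphology.values, int_vec, coupling_vec])
    names = list(morphology.column_names) + ["int_s", "coupling"]
    raw = AnatomicalTable(values, names, scaled=False)
    return scale_anatomical(raw, log=log)


# ---------------------------------------------------------------------------
# Per-subject pipeline helper
# ---------------------------------------------------------------------------

@dataclass
class SubjectFeatures:
    """Fully derived, scaled features for one subject."""

    fc: ConnectivityMatrix  # scaled, diag 1
    sc: ConnectivityMatrix | None  # normalized, diag 0
    as_table: AnatomicalTable | None  # scaled


def derive_features(
    ts: RoiTimeSeries | None,
    sc_raw: ConnectivityMatrix | None,
    gm: GmVolumes | None,
    morphology: AnatomicalTable | None,
) -> SubjectFeatures:
    """Run the full feature-derivation pipeline for one subject.

    FC requires the time series; normalized SC requires raw SC plus volumes;
    the AS table requires the morphology table and whichever of INT/coupling
    are computable (missing ones are zero-filled, matching the convention
    for undefined coupling).
    """
    if ts is None:
        raise ValueError("ROI time series are required to derive FC")
    fc_raw = compute_fc(ts)
    fc = scale_fc(fc_raw)

    sc = None
    if sc_raw is not None:
        if gm is None:
            raise ValueError("gray-matter volumes required to normalize SC")
        sc = normalize_sc(sc_raw, gm)

    as_table = None
    if morphology is not None:
        int_vec = compute_int(ts)
        if sc is not None and np.any(sc.values > 0):
            coupling = compute_coupling(sc, fc_raw)
        else:
            coupling = np.zeros(fc.n_rois)
        as_table = assemble_as(morphology, int_vec, coupling)
    return SubjectFeatures(fc=fc, sc=sc, as_table=as_table)
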