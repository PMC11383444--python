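"""Synthetic multimodal cohorts with planted, recoverable ground truth.

Real multimodal MRI cohorts are access-restricted, so every downstream
stage of this package is exercised on generated subjects that mimic the
statistical structure the method assumes:

1. ROIs are assigned to communities ("blocks"); a base correlation matrix
   has higher within-block than between-block correlation, with per-subject
   jitter projected back to a valid correlation matrix.
2. BOLD-like time series are drawn from a stationary process with that
   cross-sectional correlation; per-ROI AR(1) coefficients spread over
   [0, 0.6] give each region a genuinely different intrinsic timescale.
3. Raw streamline counts are Poisson with a rate that is much larger for
   within-block pairs, so SC is sparse, nonnegative and shares the FC
   community structure.
4. Gray-matter volumes and the nine morphology columns are log-normal at
   parcel-plausible scales.
5. A cognition-like target combines (a) the sum of FC*SC products over a
   planted set of within-block edges and (b) the mean of a few informative
   anatomical columns — both measured on the very features the model will
   ingest — plus Gaussian noise, rescaled to a mean-100 / sd-15 composite
   score.  Binary labels come from a median split (or extreme-group
   quantiles).

The planted edge set and informative columns are returned alongside the
data, so mask recovery and feature attribution can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import (
    MORPHOLOGY_COLUMNS,
    AnatomicalTable,
    ConnectivityMatrix,
    GmVolumes,
    RoiTimeSeries,
    SubjectFeatures,
    derive_features,
)

__all__ = ["SyntheticSpec", "Subject", "SyntheticCohort", "generate_cohort"]


@dataclass
class SyntheticSpec:
    """Generative settings for one synthetic cohort.

    Defaults are the desk-scale study conditions used throughout the
    package's own experiments: 300 subjects on a 40-region parcellation
    with 4 communities, 400 time points at TR = 0.8 s, 5% of within-block
    pairs planted as predictive edges and 3 informative morphology columns,
    with noise leaving roughly 90% of target variance explained.
    """

    n_subjects: int = 300
    q: int = 40
    n_blocks: int = 4
    t: int = 400
    tr: float = 0.8

    rho_in: float = 0.35
    rho_out: float = 0.05
    jitter_sd: float = 0.04
    ar_enabled: bool = True
    ar_low: float = 0.0
    ar_high: float = 0.6

    sc_rate_in: float = 15.0
    sc_rate_out: float = 0.3
    sc_subject_sd: float = 0.2
    sc_edge_sd: float = 0.3
    gm_log_mean: float = 7.3
    gm_log_sd: float = 0.3

    planted_edge_fraction: float = 0.05
    n_informative_as: int = 3
    as_effect_sd: float = 0.6
    beta_edge: float = 1.0
    beta_as: float = 1.0
    noise_sd: float = 0.5

    target_mean: float = 100.0
    target_sd: float = 15.0
    label_mode: str = "median"  # "median" | "extreme"
    extreme_quantiles: tuple[float, float] = (0.15, 0.85)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 2 or self.n_blocks < 1 or self.n_blocks > self.q:
            raise ValueError("need 2 <= q and 1 <= n_blocks <= q")
        if self.t < 3:
            raise ValueError("need at least 3 time points")
        if not (0.0 < self.planted_edge_fraction < 1.0):
            raise ValueError("planted_edge_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (-1 < self.rho_out <= self.rho_in < 1):
            raise ValueError("require rho_out <= rho_in, both valid correlations")
        if self.label_mode not in ("median", "extreme"):
            raise ValueError("label_mode must be 'median' or 'extreme'")
        if self.n_informative_as > len(MORPHOLOGY_COLUMNS):
            raise ValueError("n_informative_as exceeds morphology column count")


@dataclass
class Subject:
    """One generated subject: raw modalities plus derived features."""

    subject_id: str
    ts: RoiTimeSeries
    sc_raw: ConnectivityMatrix
    gm: GmVolumes
    morphology: AnatomicalTable
    y: float = np.nan
    label: int | None = None
    features: SubjectFeatures | None = None
    generating_correlation: np.ndarray | None = None


@dataclass
class SyntheticCohort:
    """Generated subjects plus the planted ground truth."""

    subjects: list[Subject]
    planted_edges: np.ndarray  # (n_edges, 2), i < j
    informative_columns: list[int]  # indices into the morphology columns
    blocks: np.ndarray  # block label per ROI
    coefficients: dict
    spec: SyntheticSpec

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def targets(self) -> np.ndarray:
        return np.array([s.y for s in self.subjects])

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects])


def _nearest_correlation(r: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix by
    eigenvalue clipping and diagonal renormalization."""
    r = (r + r.T) / 2.0
    w, v = np.linalg.eigh(r)
    w = np.maximum(w, floor)
    r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def implied_correlation(r: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Stationary cross-correlation of x_t = phi*x_{t-1} + e_t, cov(e) = R.

    For diagonal AR coefficients the stationary covariance is
    R_ij / (1 - phi_i phi_j); normalizing to unit variance gives
    corr_ij = R_ij sqrt((1-phi_i^2)(1-phi_j^2)) / (1 - phi_i phi_j).
    """
    num = np.sqrt(np.outer(1 - phi**2, 1 - phi**2))
    c = r * num / (1.0 - np.outer(phi, phi))
    np.fill_diagonal(c, 1.0)
    return c


def _simulate_timeseries(r: np.ndarray, phi: np.ndarray, t: int,
                         rng: np.random.Generator, burn: int = 50) -> np.ndarray:
    chol = np.linalg.cholesky(r)
    q = r.shape[0]
    e = rng.standard_normal((t + burn, q)) @ chol.T
    x = np.empty_like(e)
    x[0] = e[0] / np.sqrt(1.0 - phi**2)  # start at stationary marginal scale
    for i in range(1, t + burn):
        x[i] = phi * x[i - 1] + e[i]
    return x[burn:]


def _sample_planted_edges(blocks: np.ndarray, fraction: float,
                          rng: np.random.Generator) -> np.ndarray:
    q = blocks.size
    iu, ju = np.triu_indices(q, k=1)
    within = blocks[iu] == blocks[ju]
    cand = np.flatnonzero(within)
    n_pick = max(1, int(round(fraction * cand.size)))
    pick = rng.choice(cand, size=n_pick, replace=False)
    edges = np.column_stack([iu[pick], ju[pick]])
    return edges[np.lexsort((edges[:, 1], edges[:, 0]))]


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a full multimodal cohort per the documented generative model.

    Deterministic given ``spec`` (all randomness flows from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    q, t = spec.q, spec.t

    # (1) block assignment: contiguous, near-equal blocks
    blocks = np.sort(np.arange(q) % spec.n_blocks)

    # base correlation with community structure
    same = blocks[:, None] == blocks[None, :]
    r0 = np.where(same, spec.rho_in, spec.rho_out).astype(float)
    np.fill_diagonal(r0, 1.0)
    r0 = _nearest_correlation(r0)

    phi = (
        rng.uniform(spec.ar_low, spec.ar_high, size=q)
        if spec.ar_enabled
        else np.zeros(q)
    )

    planted_edges = _sample_planted_edges(blocks, spec.planted_edge_fraction, rng)
    informative_columns = sorted(
        rng.choice(len(MORPHOLOGY_COLUMNS), size=spec.n_informative_as,
                   replace=False).tolist()
    )
    # ROI set through which the informative-column effect is expressed:
    # the first block's regions (a regional, not global, shift — a global
    # shift would be removed by per-subject scaling)
    effect_rois = np.flatnonzero(blocks == 0)

    # log-scale base levels for the nine morphology columns
    morph_log_mean = np.array([6.9, 6.2, 7.3, 0.95, -0.7, -2.0, -1.3, 0.7, 2.3])
    morph_log_sd = np.array([0.4, 0.4, 0.4, 0.08, 0.2, 0.3, 0.3, 0.5, 0.5])

    base_rate = np.where(same, spec.sc_rate_in, spec.sc_rate_out)
    iu, ju = np.triu_indices(q, k=1)

    subjects: list[Subject] = []
    edge_signal = np.empty(spec.n_subjects)
    as_signal = np.empty(spec.n_subjects)
    for s in range(spec.n_subjects):
        # (2) subject-level correlation: jitter + projection
        jit = rng.standard_normal((q, q)) * spec.jitter_sd
        r_s = _nearest_correlation(r0 + (jit + jit.T) / 2.0)

        # (3) time series
        x = _simulate_timeseries(r_s, phi, t, rng)
        ts = RoiTimeSeries(x, tr=spec.tr)

        # (4) raw streamline counts
        subj_factor = np.exp(rng.normal(0.0, spec.sc_subject_sd))
        edge_jit = np.exp(rng.normal(0.0, spec.sc_edge_sd, size=iu.size))
        rates = base_rate[iu, ju] * subj_factor * edge_jit
        counts = rng.poisson(rates)
        sc = np.zeros((q, q))
        sc[iu, ju] = counts
        sc = sc + sc.T
        sc_raw = ConnectivityMatrix(sc.astype(float), modality="SC")

        # (5) gray-matter volumes
        gm = GmVolumes(np.exp(rng.normal(spec.gm_log_mean, spec.gm_log_sd, size=q)))

        # (6) morphology table, with regional subject-level effects on the
        # informative columns
        logvals = morph_log_mean[None, :] + rng.standard_normal((q, 9)) * morph_log_sd
        for c in informative_columns:
            effect = rng.normal(0.0, spec.as_effect_sd)
            logvals[effect_rois, c] += effect
        morphology = AnatomicalTable(np.exp(logvals), list(MORPHOLOGY_COLUMNS))

        feats = derive_features(ts, sc_raw, gm, morphology)
        assert feats.sc is not None and feats.as_table is not None

        # (7) target components, measured on the derived features themselves
        ei, ej = planted_edges[:, 0], planted_edges[:, 1]
        edge_signal[s] = np.sum(feats.fc.values[ei, ej] * feats.sc.values[ei, ej])
        as_signal[s] = np.sum(feats.as_table.values[:, informative_columns].mean(axis=0))

        subjects.append(Subject(
            subject_id=f"sub-{s:04d}", ts=ts, sc_raw=sc_raw, gm=gm,
            morphology=morphology, features=feats,
            generating_correlation=implied_correlation(r_s, phi),
        ))

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    eps = rng.normal(0.0, spec.noise_sd, size=spec.n_subjects)
    y_raw = spec.beta_edge * zscore(edge_signal) + spec.beta_as * zscore(as_signal) + eps
    sd = y_raw.std()
    if sd > 0:
        y = spec.target_mean + spec.target_sd * (y_raw - y_raw.mean()) / sd
    else:
        y = np.full(spec.n_subjects, spec.target_mean)

    if spec.label_mode == "median":
        labels = (y > np.median(y)).astype(int)
    else:
        lo, hi = np.quantile(y, spec.extreme_quantiles)
        labels = np.where(y >= hi, 1, np.where(y <= lo, 0, -1))

    for s, subj in enumerate(subjects):
        subj.y = float(y[s])
        subj.label = int(labels[s])

    return SyntheticCohort(
        subjects=subjects,
        planted_edges=planted_edges,
        informative_columns=informative_columns,
        blocks=blocks,
        coefficients={
            "beta_edge": spec.beta_edge,
            "beta_as": spec.beta_as,
            "noise_sd": spec.noise_sd,
            "phi": phi,
            "base_correlation": r0,
            "effect_rois": effect_rois,
        },
        spec=spec,
    )
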