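"""On-disk artifacts: delimited matrices, cohort manifests, run configuration.

Everything is plain delimited text: one CSV per subject per modality
(atlas-level matrices are at most a few hundred rows, so binary
neuroimaging formats are deliberately avoided), a single manifest CSV with
one row per subject, and a YAML run configuration mirroring
:class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import (
    MORPHOLOGY_COLUMNS,
    AnatomicalTable,
    ConnectivityMatrix,
    GmVolumes,
    RoiTimeSeries,
)
from .synthetic import Subject, SyntheticCohort

__all__ = [
    "RunConfig",
    "CohortManifest",
    "load_config",
    "save_config",
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "load_cohort",
    "load_subjects",
    "write_cohort",
    "get_logger",
    "setup_logging",
]

_LOGGER_NAME = "neuromask"


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def get_logger(name: str | None = None) -> logging.Logger:
    return logging.getLogger(f"{_LOGGER_NAME}.{name}" if name else _LOGGER_NAME)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All knobs of a training/interpretation run.

    Training defaults follow the reference protocol: initial learning rate
    0.005, batch size 32, at most 50 epochs, plateau scheduler with patience
    10, L2 weight decay 1e-6, top-30 graph sparsification above an edge
    threshold of 0.001, and a 70/10/20 train/validation/test split.
    """

    q: int = 40
    k: int = 30
    threshold: float = 0.001
    lambda1: float = 1e-3
    lambda2: float = 1e-3
    lambda3: float = 1e-4
    alpha: float = 1e-5
    manifold_floor: float = 1e-3
    learning_rate: float = 0.005
    batch_size: int = 32
    max_epochs: int = 50
    scheduler_patience: int = 10
    scheduler_factor: float = 0.5
    weight_decay: float = 1e-6
    vis_threshold: float = 0.52
    seed: int = 0
    task: str = "regression"  # "regression" | "classification"
    n_targets: int = 1
    modalities: tuple[str, ...] = ("FC", "SC", "AS")
    d1: int = 64
    d2: int = 64
    hidden: int = 32
    pooling: str = "mean"
    binary_adjacency: bool = False
    split_proportions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    n_bootstrap: int = 10

    def __post_init__(self) -> None:
        self.modalities = tuple(self.modalities)
        self.split_proportions = tuple(self.split_proportions)
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        for name in ("lambda1", "lambda2", "lambda3", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.vis_threshold < 1.0):
            raise ValueError("vis_threshold must lie in (0, 1)")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        unknown = set(self.modalities) - {"FC", "SC", "AS"}
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        if not set(self.modalities) & {"FC", "SC"}:
            raise ValueError("at least one connectivity modality (FC/SC) required")
        if abs(sum(self.split_proportions) - 1.0) > 1e-9:
            raise ValueError("split proportions must sum to 1")


def desk_config(seed: int = 0, **overrides) -> RunConfig:
    """The desk-scale experiment configuration used throughout the
    package's own synthetic studies: Q = 40 regions with top-8 graph
    sparsification (preserving roughly the protocol's *relative* neighbor
    fraction at this parcellation size), all other protocol defaults."""
    overrides.setdefault("q", 40)
    overrides.setdefault("k", 8)
    return RunConfig(seed=seed, **overrides)


def save_config(cfg: RunConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    d["modalities"] = list(cfg.modalities)
    d["split_proportions"] = list(cfg.split_proportions)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    return RunConfig(**d)


# ---------------------------------------------------------------------------
# Delimited matrices and tables
# ---------------------------------------------------------------------------

def _read_frame(path, header: bool) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python",
                       header=0 if header else None)


def _to_numeric(frame: pd.DataFrame, path) -> np.ndarray:
    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_na = frame.isna().to_numpy()
    bad = np.isnan(values) & ~raw_na
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric cell {frame.iloc[r, c]!r} at row {r}, column {c}"
        )
    if raw_na.any():
        r, c = np.argwhere(raw_na)[0]
        raise ValueError(f"{path}: missing cell at row {r}, column {c}")
    return values


def read_matrix(path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a delimited (comma or tab) numeric matrix, no header.

    Shape mismatches and non-numeric cells raise with coordinates.
    """
    values = _to_numeric(_read_frame(path, header=False), path)
    if expected_shape is not None and values.shape != tuple(expected_shape):
        raise ValueError(
            f"{path}: expected shape {tuple(expected_shape)}, got {values.shape}"
        )
    return values


def write_matrix(path, matrix: np.ndarray, precision: int = 12) -> None:
    """Write a numeric matrix as CSV; round-trips with :func:`read_matrix`
    to within 10^-precision."""
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    np.savetxt(path, m, delimiter=",", fmt=f"%.{precision}e")


def read_table(path) -> AnatomicalTable:
    """Read an anatomical table CSV with a header row of column names."""
    frame = _read_frame(path, header=True)
    values = _to_numeric(frame, path)
    return AnatomicalTable(values, [str(c) for c in frame.columns])


def write_table(path, table: AnatomicalTable, precision: int = 12) -> None:
    pd.DataFrame(table.values, columns=table.column_names).to_csv(
        path, index=False, float_format=f"%.{precision}e"
    )


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------

_MANIFEST_PATHS = ("timeseries", "sc", "gm", "morphology")


@dataclass
class CohortManifest:
    """One validated manifest row: file paths, target, availability flags."""

    subject_id: str
    timeseries: Path | None
    sc: Path | None
    gm: Path | None
    morphology: Path | None
    target: float
    label: int | None
    tr: float

    def has_modality(self, modality: str) -> bool:
        if modality == "FC":
            return self.timeseries is not None
        if modality == "SC":
            return self.sc is not None and self.gm is not None
        if modality == "AS":
            return self.morphology is not None and self.timeseries is not None
        raise ValueError(f"unknown modality {modality!r}")


def load_cohort(
    manifest_path,
    required_modalities: tuple[str, ...] = ("FC", "SC", "AS"),
) -> tuple[list[CohortManifest], list[str]]:
    """Load and validate a cohort manifest CSV.

    Subjects missing any required modality are excluded (and logged),
    mirroring task-dependent cohort sizes when modalities are missing.
    Returns (kept entries, excluded subject ids).  Missing files and
    duplicate subject ids raise.
    """
    log = get_logger("io")
    manifest_path = Path(manifest_path)
    frame = pd.read_csv(manifest_path, sep=None, engine="python")
    if "subject_id" not in frame.columns:
        raise ValueError(f"{manifest_path}: manifest needs a subject_id column")
    ids = frame["subject_id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"{manifest_path}: duplicate subject_id {dup.iloc[0]!r}")

    root = manifest_path.parent
    entries: list[CohortManifest] = []
    excluded: list[str] = []
    for _, row in frame.iterrows():
        paths: dict[str, Path | None] = {}
        for kind in _MANIFEST_PATHS:
            cell = row.get(kind)
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell) == "":
                paths[kind] = None
                continue
            p = Path(str(cell))
            if not p.is_absolute():
                p = root / p
            if not p.exists():
                raise FileNotFoundError(
                    f"subject {row['subject_id']}: missing file {p}"
                )
            paths[kind] = p
        entry = CohortManifest(
            subject_id=str(row["subject_id"]),
            timeseries=paths["timeseries"],
            sc=paths["sc"],
            gm=paths["gm"],
            morphology=paths["morphology"],
            target=float(row.get("target", np.nan)),
            label=None if pd.isna(row.get("label")) else int(row.get("label")),
            tr=float(row.get("tr", 1.0)),
        )
        missing = [m for m in required_modalities if not entry.has_modality(m)]
        if not any(entry.has_modality(m) for m in ("FC", "SC", "AS")):
            raise ValueError(
                f"subject {entry.subject_id}: no modality present at all"
            )
        if missing:
            log.info("excluding subject %s: missing %s", entry.subject_id,
                     ",".join(missing))
            excluded.append(entry.subject_id)
            continue
        entries.append(entry)
    return entries, excluded


def load_subjects(entries: list[CohortManifest]) -> list[Subject]:
    """Materialize manifest entries into in-memory subjects."""
    subjects = []
    for e in entries:
        ts = None
        if e.timeseries is not None:
            ts = RoiTimeSeries(read_matrix(e.timeseries), tr=e.tr)
        sc = None
        if e.sc is not None:
            sc = ConnectivityMatrix(read_matrix(e.sc), modality="SC")
        gm = None
        if e.gm is not None:
            gm = GmVolumes(read_matrix(e.gm).ravel())
        morph = None
        if e.morphology is not None:
            morph = read_table(e.morphology)
        subjects.append(Subject(
            subject_id=e.subject_id, ts=ts, sc_raw=sc, gm=gm,
            morphology=morph, y=e.target, label=e.label,
        ))
    return subjects


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write a synthetic cohort to disk (one directory per subject) and
    return the manifest path.  Ground truth goes to separate CSVs so that
    recovery analyses can be scored later."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        sdir = outdir / s.subject_id
        sdir.mkdir(exist_ok=True)
        write_matrix(sdir / "timeseries.csv", s.ts.values, precision=8)
        write_matrix(sdir / "sc_raw.csv", s.sc_raw.values, precision=8)
        write_matrix(sdir / "gm_volumes.csv", s.gm.values[None, :], precision=8)
        write_table(sdir / "morphology.csv", s.morphology, precision=8)
        rows.append({
            "subject_id": s.subject_id,
            "timeseries": f"{s.subject_id}/timeseries.csv",
            "sc": f"{s.subject_id}/sc_raw.csv",
            "gm": f"{s.subject_id}/gm_volumes.csv",
            "morphology": f"{s.subject_id}/morphology.csv",
            "target": s.y,
            "label": s.label,
            "tr": s.ts.tr,
        })
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    pd.DataFrame(cohort.planted_edges, columns=["roi_i", "roi_j"]).to_csv(
        outdir / "planted_edges.csv", index=False
    )
    pd.DataFrame({
        "column_index": cohort.informative_columns,
        "column_name": [MORPHOLOGY_COLUMNS[c] for c in cohort.informative_columns],
    }).to_csv(outdir / "informative_columns.csv", index=False)
    pd.DataFrame({"roi": np.arange(cohort.blocks.size),
                  "block": cohort.blocks}).to_csv(outdir / "blocks.csv", index=False)
    return manifest
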