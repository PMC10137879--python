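"""Structural-connectome containers, cohort manifests, and feature vectorization.

A structural connectome is a symmetric ROI x ROI matrix of white-matter
connectivity strengths (mean fractional anisotropy along reconstructed
tracts, each weight in [0, 1]).  For a parcellation with ``r`` regions the
strictly-upper-triangular weights form the subject's feature vector of
length r(r-1)/2 — 4005 features for the 90-region neonatal AAL atlas.

A cohort manifest records, per subject, an identifier, an optional
continuous motor score (Bayley-III motor composite, normalized scale
40-160, mean 100, SD 15) and an outcome label.  Scores are dichotomized at
one SD below the normative mean (85): score <= 85 is ``positive`` (high
risk of moderate/severe motor abnormality), score > 85 is ``negative``.
Subjects without follow-up are ``unlabeled`` and participate only through
their connectome features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"
AUTO = "auto"
VALID_LABELS = (POSITIVE, NEGATIVE, UNLABELED)

#: Normative motor-score scale: mean, SD and admissible range.
SCORE_MEAN = 100.0
SCORE_SD = 15.0
SCORE_RANGE = (40.0, 160.0)
#: Risk cutoff: one SD below the normative mean; boundary value is positive.
DEFAULT_CUTOFF = SCORE_MEAN - SCORE_SD

#: Relative tolerance for symmetry of matrices read from text files.
SYMMETRY_RTOL = 1e-8


class CohortError(ValueError):
    """Invalid connectome, manifest, or cohort input."""


def _as_matrix(matrix: np.ndarray, subject_id: str) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise CohortError(
            f"connectome {subject_id!r}: matrix must be square, got shape {m.shape}"
        )
    if not np.all(np.isfinite(m)):
        raise CohortError(f"connectome {subject_id!r}: matrix contains non-finite entries")
    if np.any(m < 0):
        i, j = np.argwhere(m < 0)[0]
        raise CohortError(
            f"connectome {subject_id!r}: negative weight at ({i}, {j}): {m[i, j]}"
        )
    scale = max(1.0, float(np.abs(m).max()))
    asym = np.abs(m - m.T)
    if asym.max() > SYMMETRY_RTOL * scale:
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        raise CohortError(
            f"connectome {subject_id!r}: matrix not symmetric at entry pair "
            f"({i}, {j})/({j}, {i}): {m[i, j]} vs {m[j, i]}"
        )
    # text round-trips can break exact symmetry; repair by averaging
    m = 0.5 * (m + m.T)
    if np.abs(np.diag(m)).max() > SYMMETRY_RTOL * scale:
        i = int(np.argmax(np.abs(np.diag(m))))
        raise CohortError(
            f"connectome {subject_id!r}: nonzero diagonal at ({i}, {i}): {m[i, i]}"
        )
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class Connectome:
    """One subject's symmetric connectivity matrix (zero diagonal, weights >= 0)."""

    subject_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = _as_matrix(self.matrix, self.subject_id)

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FeatureVector:
    """Strict upper triangle of a connectome, row-major (i < j, i then j ascending)."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        n = _n_rois_from_length(self.values.size)
        if n is None:
            raise CohortError(
                f"feature vector {self.subject_id!r}: length {self.values.size} is not "
                "r(r-1)/2 for any integer r"
            )

    @property
    def n_rois(self) -> int:
        n = _n_rois_from_length(self.values.size)
        assert n is not None
        return n


def _n_rois_from_length(length: int) -> int | None:
    # solve r(r-1)/2 == length
    r = int((1 + math.isqrt(1 + 8 * length)) // 2)
    return r if r * (r - 1) // 2 == length else None


def n_edge_features(n_rois: int) -> int:
    """Number of unique off-diagonal weights of an ``n_rois`` parcellation."""
    return n_rois * (n_rois - 1) // 2


def vectorize(connectome: Connectome) -> FeatureVector:
    """Extract the canonical strict-upper-triangle feature vector.

    For a 90-ROI connectome this yields the 4005 unique connectivity
    weights, ordered row-major over pairs (i, j) with i < j.
    """
    n = connectome.n_rois
    iu = np.triu_indices(n, k=1)
    return FeatureVector(connectome.subject_id, connectome.matrix[iu].copy())


def matricize(vec: FeatureVector | np.ndarray, n_rois: int, subject_id: str | None = None) -> Connectome:
    """Inverse of :func:`vectorize`: rebuild the symmetric matrix from its triangle."""
    if isinstance(vec, FeatureVector):
        values = vec.values
        subject_id = subject_id if subject_id is not None else vec.subject_id
    else:
        values = np.asarray(vec, dtype=float).ravel()
        subject_id = subject_id if subject_id is not None else "unnamed"
    expected = n_edge_features(n_rois)
    if values.size != expected:
        raise CohortError(
            f"feature vector length mismatch for n_rois={n_rois}: "
            f"expected {expected}, got {values.size}"
        )
    m = np.zeros((n_rois, n_rois), dtype=float)
    iu = np.triu_indices(n_rois, k=1)
    m[iu] = values
    m += m.T
    return Connectome(subject_id, m)


def dichotomize(score: float | None, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Binarize a motor score at ``cutoff``; the boundary value is high risk.

    Returns ``"positive"`` for score <= cutoff, ``"negative"`` above, and
    ``"unlabeled"`` when the score is missing (None or NaN).
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return UNLABELED
    score = float(score)
    lo, hi = SCORE_RANGE
    if not lo <= score <= hi:
        raise CohortError(f"motor score {score} outside the normalized scale [{lo}, {hi}]")
    return POSITIVE if score <= cutoff else NEGATIVE


@dataclass
class CohortManifest:
    """Per-subject records: subject_id, motor_score (NaN if missing), label.

    Labels are ``positive`` / ``negative`` / ``unlabeled``; an input label of
    ``auto`` is resolved from the score via :func:`dichotomize` at the given
    cutoff.  Subject ids must be unique.
    """

    records: pd.DataFrame
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        df = self.records.copy()
        required = ["subject_id", "motor_score", "label"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise CohortError(f"manifest missing columns: {missing}")
        if len(df) == 0:
            raise CohortError("manifest is empty")
        df["subject_id"] = df["subject_id"].astype(str)
        dup = df["subject_id"][df["subject_id"].duplicated()]
        if len(dup):
            raise CohortError(f"duplicated subject_id(s): {sorted(set(dup))}")
        df["motor_score"] = pd.to_numeric(df["motor_score"], errors="coerce")
        labels = df["label"].astype(str).str.strip().str.lower()
        resolved = []
        for sid, score, lab in zip(df["subject_id"], df["motor_score"], labels):
            if lab in ("", "nan", AUTO):
                lab = dichotomize(None if pd.isna(score) else float(score), self.cutoff)
            if lab not in VALID_LABELS:
                raise CohortError(f"subject {sid!r}: invalid label {lab!r}")
            resolved.append(lab)
        df["label"] = resolved
        self.records = df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, rows: Iterable[tuple[str, float | None, str]], cutoff: float = DEFAULT_CUTOFF
    ) -> "CohortManifest":
        df = pd.DataFrame(rows, columns=["subject_id", "motor_score", "label"])
        return cls(df, cutoff=cutoff)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.records["subject_id"])

    @property
    def y(self) -> np.ndarray:
        """Integer labels: positive=1, negative=0, unlabeled=-1."""
        mapping = {POSITIVE: 1, NEGATIVE: 0, UNLABELED: -1}
        return self.records["label"].map(mapping).to_numpy(dtype=int)

    @property
    def is_labeled(self) -> np.ndarray:
        return self.y >= 0

    @property
    def n_labeled(self) -> int:
        return int(self.is_labeled.sum())

    @property
    def n_unlabeled(self) -> int:
        return int((~self.is_labeled).sum())

    def subset(self, index: Sequence[int]) -> "CohortManifest":
        return CohortManifest(self.records.iloc[list(index)].reset_index(drop=True), self.cutoff)


def read_connectome(path: str | Path, subject_id: str | None = None) -> Connectome:
    """Read one connectome from a headerless CSV of n_rois rows x n_rois columns."""
    path = Path(path)
    m = np.loadtxt(path, delimiter=",", ndmin=2)
    return Connectome(subject_id or path.stem, m)


def write_connectome(connectome: Connectome, path: str | Path) -> None:
    np.savetxt(path, connectome.matrix, delimiter=",", fmt="%.10g")


def read_manifest(path: str | Path, cutoff: float = DEFAULT_CUTOFF) -> CohortManifest:
    df = pd.read_csv(path, dtype={"subject_id": str}, na_values=["", "NA"], keep_default_na=True)
    return CohortManifest(df, cutoff=cutoff)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    df = manifest.records[["subject_id", "motor_score", "label"]]
    df.to_csv(path, index=False, na_rep="NA", float_format="%.10g")


def read_cohort(
    manifest_path: str | Path, connectome_dir: str | Path, cutoff: float = DEFAULT_CUTOFF
) -> tuple[list[Connectome], CohortManifest]:
    """Load a cohort: a manifest CSV plus one ``<subject_id>.csv`` matrix per subject.

    Subjects whose matrix file is missing are excluded with a logged warning;
    an empty manifest or duplicated ids raise :class:`CohortError`.
    """
    manifest = read_manifest(manifest_path, cutoff=cutoff)
    connectome_dir = Path(connectome_dir)
    connectomes: list[Connectome] = []
    keep: list[int] = []
    for idx, sid in enumerate(manifest.subject_ids):
        f = connectome_dir / f"{sid}.csv"
        if not f.exists():
            logger.warning("subject %r: connectome file %s missing; subject excluded", sid, f)
            continue
        connectomes.append(read_connectome(f, sid))
        keep.append(idx)
    if not keep:
        raise CohortError(f"no connectome files found in {connectome_dir}")
    n_rois = {c.n_rois for c in connectomes}
    if len(n_rois) > 1:
        raise CohortError(f"inconsistent parcellation sizes across subjects: {sorted(n_rois)}")
    return connectomes, manifest.subset(keep)


def write_cohort(
    connectomes: Sequence[Connectome], manifest: CohortManifest, out_dir: str | Path
) -> Path:
    """Write a cohort in the exact format :func:`read_cohort` consumes."""
    out_dir = Path(out_dir)
    mat_dir = out_dir / "connectomes"
    mat_dir.mkdir(parents=True, exist_ok=True)
    ids = {c.subject_id for c in connectomes}
    if ids != set(manifest.subject_ids):
        raise CohortError("connectome subject ids do not match the manifest")
    for c in connectomes:
        write_connectome(c, mat_dir / f"{c.subject_id}.csv")
    write_manifest(manifest, out_dir / "manifest.csv")
    return out_dir
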