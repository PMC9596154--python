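"""Readers and writers: delimited text tables, RDM files, pattern matrices,
and optional extraction of ROI patterns from NIfTI volumes.

All tables are tab-separated UTF-8 with a header row and "." as the decimal
mark.  Writes are atomic (temp file + rename) so a crashed run never leaves
a half-written table behind.  Every writer/reader pair round-trips
byte-identically.
"""

from __future__ import annotations

import json
import os
import re
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .rdm import RDM, ROIPatternMatrix

_FLOAT_FMT = "%.17g"  # shortest exact round-trip for doubles


def _atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as a TSV file (atomic, exact float round-trip)."""
    text = df.to_csv(sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    _atomic_write_text(Path(path), text)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# ---------------------------------------------------------------------------
# RDM files
# ---------------------------------------------------------------------------


def write_rdm(rdm: RDM, path) -> None:
    """Write an RDM as a labelled square TSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(rdm.matrix, index=rdm.labels, columns=rdm.labels)
    text = df.to_csv(sep="\t", index=True, index_label="trial_id", float_format=_FLOAT_FMT, lineterminator="\n")
    _atomic_write_text(path, text)
    def plain(v):
        return v.item() if isinstance(v, np.generic) else v

    meta = {
        "kind": rdm.kind,
        "condition": rdm.condition,
        "source": rdm.source,
        "subject_id": plain(rdm.subject_id),
    }
    _atomic_write_text(path.with_suffix(path.suffix + ".json"), json.dumps(meta, indent=1) + "\n")


def read_rdm(path) -> RDM:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"RDM file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    labels = df.index.to_numpy()
    return RDM(
        labels=labels,
        matrix=df.to_numpy(dtype=float),
        kind=meta.get("kind", "unknown"),
        condition=meta.get("condition"),
        source=meta.get("source"),
        subject_id=meta.get("subject_id"),
    )


# ---------------------------------------------------------------------------
# pattern matrices
# ---------------------------------------------------------------------------

_PATTERN_RE = re.compile(r"sub-(?P<sub>[^_]+)_roi-(?P<roi>.+)_betas\.tsv$")


def pattern_filename(subject_id, roi_name: str) -> str:
    return f"sub-{subject_id}_roi-{roi_name}_betas.tsv"


def write_patterns(pattern: ROIPatternMatrix, directory) -> Path:
    """Write one trial x voxel matrix as ``sub-<id>_roi-<name>_betas.tsv``.

    First column is the global trial id; remaining columns are voxel ids.
    """
    directory = Path(directory)
    cols = [f"v{i:04d}" for i in range(pattern.n_voxels)]
    df = pd.DataFrame(pattern.matrix, columns=cols)
    df.insert(0, "global_trial_id", pattern.trial_ids)
    path = directory / pattern_filename(pattern.subject_id, pattern.roi_name)
    write_table(df, path)
    return path


def read_patterns(path) -> ROIPatternMatrix:
    path = Path(path)
    m = _PATTERN_RE.search(path.name)
    if not m:
        raise ValidationError(
            f"pattern file name {path.name!r} does not match "
            "'sub-<id>_roi-<name>_betas.tsv'"
        )
    df = read_table(path)
    if "global_trial_id" not in df.columns:
        raise ValidationError(f"{path}: missing global_trial_id column")
    sub = m.group("sub")
    subject_id = int(sub) if sub.isdigit() else sub
    return ROIPatternMatrix(
        subject_id=subject_id,
        roi_name=m.group("roi"),
        trial_ids=df["global_trial_id"].to_numpy(),
        matrix=df.drop(columns="global_trial_id").to_numpy(dtype=float),
    )


def read_all_patterns(directory) -> dict:
    """Load every ``*_betas.tsv`` under a directory, keyed (subject_id, roi)."""
    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob("sub-*_roi-*_betas.tsv")):
        pat = read_patterns(path)
        out[(pat.subject_id, pat.roi_name)] = pat
    if not out:
        raise ValidationError(f"no pattern files found under {directory}")
    return out


# ---------------------------------------------------------------------------
# NIfTI extraction (optional; the tabular path is canonical)
# ---------------------------------------------------------------------------


def extract_roi_patterns(beta_volumes, mask, trial_ids, subject_id=0, roi_name="roi"):
    """Extract a trial x voxel matrix from a 4-D beta image and a 3-D mask.

    ``beta_volumes`` and ``mask`` may be file paths or nibabel images; they
    must share grid dimensions, the mask must be binary and non-empty, and
    the number of 3-D volumes must equal ``len(trial_ids)``.  Columns follow
    ascending linear voxel index in C (row-major) order, so column identity
    is stable across runs; the ordering is recorded nowhere else, which is
    why it is fixed here.
    """
    import nibabel as nib  # local import: imaging support is optional

    img = nib.load(str(beta_volumes)) if isinstance(beta_volumes, (str, Path)) else beta_volumes
    msk = nib.load(str(mask)) if isinstance(mask, (str, Path)) else mask
    data = np.asanyarray(img.dataobj)
    mdata = np.asanyarray(msk.dataobj)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise ValidationError(f"beta image must be 4-D, got {data.ndim}-D")
    if mdata.shape != data.shape[:3]:
        raise ValidationError(
            f"grid mismatch: betas {data.shape[:3]} vs mask {mdata.shape}"
        )
    values = np.unique(mdata)
    if not np.all(np.isin(values, (0, 1))):
        raise ValidationError(f"mask must be binary; found values {values[:5]}")
    flat_mask = mdata.reshape(-1, order="C").astype(bool)
    if not flat_mask.any():
        raise ValidationError("mask is empty (no nonzero voxels)")
    trial_ids = np.asarray(trial_ids)
    if data.shape[3] != len(trial_ids):
        raise ValidationError(
            f"{data.shape[3]} volumes for {len(trial_ids)} trial ids"
        )
    flat = data.reshape(-1, data.shape[3], order="C")
    matrix = flat[flat_mask].T.astype(float)
    return ROIPatternMatrix(
        subject_id=subject_id, roi_name=roi_name, trial_ids=trial_ids, matrix=matrix
    )


# ---------------------------------------------------------------------------
# experiment-level convenience
# ---------------------------------------------------------------------------


def write_experiment(exp, outdir) -> None:
    """Write all tables and pattern matrices of a simulated experiment."""
    outdir = Path(outdir)
    write_table(exp.schedule, outdir / "schedule.tsv")
    write_table(exp.decisions, outdir / "decisions.tsv")
    write_table(exp.outcomes, outdir / "outcomes.tsv")
    write_table(exp.ratings.distress, outdir / "ratings_distress.tsv")
    write_table(exp.ratings.threat, outdir / "ratings_threat.tsv")
    write_table(exp.weights, outdir / "weights.tsv")
    for pattern in exp.patterns.values():
        write_patterns(pattern, outdir / "patterns")
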