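"""File formats: ratings CSV, brain maps (NIfTI or flat container), motion
text, physiology CSV, ground-truth JSON, salience maps.

The flat matrix container is an ``.npz`` archive with named members (data,
mask, ids) accepted everywhere NIfTI is, so desk-scale analyses avoid
volumetric overhead.  Motion files follow the SPM ``rp_*.txt`` convention
(6 whitespace columns: x y z in mm, then pitch roll yaw in rad).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BehaviorMatrix, BrainMatrix
from .features import EMOTION_CATEGORIES, GRID_FEATURE_IDS

__all__ = [
    "read_ratings",
    "write_ratings",
    "read_brain_maps",
    "write_brain_container",
    "read_motion",
    "write_motion",
    "read_physio_csv",
    "write_physio_csv",
    "write_ground_truth",
    "write_salience_maps",
]

RATINGS_META_COLUMNS = (
    "subject_id",
    "session",
    "video_id",
    "event_id",
    "primary_emotion",
    "secondary_emotion",
)


def read_ratings(path, likert_mode: str = "continuous") -> pd.DataFrame:
    """Read and validate a ratings CSV.

    Checks the documented schema (metadata columns + 32 GRID feature
    columns), the emotion-label vocabulary, and — for ``likert_mode=
    'quantized'`` — that feature values are integers in 1..7.  Errors name
    the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in RATINGS_META_COLUMNS if c not in df.columns]
    missing += [c for c in GRID_FEATURE_IDS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    for col in ("primary_emotion", "secondary_emotion"):
        bad = ~df[col].isin(EMOTION_CATEGORIES)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"{path}: unknown emotion label {df.loc[row, col]!r} in row {row + 2}"
            )
    if likert_mode == "quantized":
        for col in GRID_FEATURE_IDS:
            vals = df[col].to_numpy()
            bad = (vals < 1) | (vals > 7) | (vals != np.rint(vals))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{path}: Likert value {vals[row]} out of range 1..7 "
                    f"in row {row + 2}, column {col}"
                )
    return df


def write_ratings(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_brain_maps(source) -> BrainMatrix:
    """Load per-event contrast maps into an M x V matrix.

    ``source`` may be a flat container (``.npz`` with members ``data``,
    ``subject``, ``event_id`` and optional ``mask``/``affine``) or a list of
    3-D NIfTI paths sharing grid and affine, in which case a finite-value
    mask from the first volume is applied.
    """
    if isinstance(source, (str, Path)):
        with np.load(source, allow_pickle=False) as z:
            data = z["data"]
            index = pd.DataFrame(
                {"subject": z["subject"], "event_id": z["event_id"]}
            )
            mask = z["mask"] if "mask" in z else None
            affine = z["affine"] if "affine" in z else None
        return BrainMatrix(values=data, index=index, mask=mask, affine=affine)

    import nibabel as nib

    paths = list(source)
    imgs = [nib.load(str(p)) for p in paths]
    shape, affine = imgs[0].shape, imgs[0].affine
    for p, img in zip(paths, imgs):
        if img.shape != shape or not np.allclose(img.affine, affine):
            raise ValueError(f"{p}: volume grid/affine mismatch")
    vols = [np.asarray(img.dataobj, dtype=float) for img in imgs]
    mask = np.isfinite(vols[0])
    data = np.stack([v[mask] for v in vols])
    index = pd.DataFrame(
        {"subject": np.zeros(len(paths), dtype=int), "event_id": np.arange(len(paths))}
    )
    return BrainMatrix(values=data, index=index, mask=mask, affine=affine)


def write_brain_container(brain: BrainMatrix, path) -> None:
    members = {
        "data": brain.values,
        "subject": brain.index["subject"].to_numpy(),
        "event_id": brain.index["event_id"].to_numpy(),
    }
    if brain.mask is not None:
        members["mask"] = brain.mask
    if brain.affine is not None:
        members["affine"] = brain.affine
    np.savez_compressed(path, **members)


def read_motion(path) -> np.ndarray:
    """Read an SPM-convention 6-column motion parameter text file."""
    motion = np.loadtxt(path)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns of motion parameters")
    return motion


def write_motion(motion: np.ndarray, path) -> None:
    np.savetxt(path, motion, fmt="%.8e")


def read_physio_csv(path):
    """Physiology CSV: '# sample_rate_hz=<f> channel=<name>' header, then
    time_s,value rows.  Returns a PhysioTrace."""
    from .physio import PhysioTrace

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing metadata header line")
    meta = dict(
        item.split("=") for item in header.lstrip("# ").split() if "=" in item
    )
    if "sample_rate_hz" not in meta or "channel" not in meta:
        raise ValueError(f"{path}: header must define sample_rate_hz and channel")
    df = pd.read_csv(path, comment="#", names=["time_s", "value"], header=None)
    return PhysioTrace(
        samples=df["value"].to_numpy(),
        sample_rate=float(meta["sample_rate_hz"]),
        channel=meta["channel"],
        run_id=path.stem,
    )


def write_physio_csv(trace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={trace.sample_rate} channel={trace.channel}\n")
        times = trace.times
        for t, v in zip(times, trace.samples):
            fh.write(f"{t:.6f},{v:.8g}\n")


def write_ground_truth(truth, path) -> None:
    payload = {
        "U_true": truth.U_true.tolist(),
        "W_true": truth.W_true.tolist(),
        "c": truth.c.tolist(),
        "g": truth.g.tolist(),
        "component_membership": truth.component_membership,
        "subject_offsets": truth.subject_offsets.tolist(),
        "event_rates": {
            "hr_bpm": truth.event_rates["hr_bpm"].tolist(),
            "rr_bpm": truth.event_rates["rr_bpm"].tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def write_salience_maps(model, brain: BrainMatrix, out_dir, lv_indices) -> list[Path]:
    """Write voxel-salience maps for selected LVs.

    With volumetric metadata present, maps go out as 3-D NIfTI; otherwise as
    ``.npz`` flat containers.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for k in lv_indices:
        sal = model.W[:, k]
        if brain.mask is not None and brain.affine is not None:
            import nibabel as nib

            vol = np.zeros(brain.mask.shape, dtype=float)
            vol[brain.mask.astype(bool)] = sal
            p = out_dir / f"salience_lv{k + 1}.nii.gz"
            nib.save(nib.Nifti1Image(vol, brain.affine), str(p))
        else:
            p = out_dir / f"salience_lv{k + 1}.npz"
            np.savez(p, salience=sal)
        written.append(p)
    return written
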