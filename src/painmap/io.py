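"""On-disk formats: NIfTI runs/atlases, TSV traces, tables and manifests."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import Atlas, BoldRun, PainTrace, SubjectRecord
from .correlation import ClusterRow
from .occlusion import OcclusionHeatmap

__all__ = ["save_run", "load_run", "save_trace", "load_trace", "save_atlas",
           "load_atlas", "save_cohort", "load_cohort", "cluster_table",
           "heatmap_table"]


def save_run(run: BoldRun, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float32), run.affine)
    img.header["pixdim"][4] = run.tr
    img.to_filename(str(path))
    if run.nuisance is not None:
        pd.DataFrame(run.nuisance,
                     columns=["trans_x", "trans_y", "trans_z",
                              "rot_pitch", "rot_yaw", "rot_roll"]).to_csv(
            str(path).replace(".nii.gz", "").replace(".nii", "") + "_motion.tsv",
            sep="\t", index=False)


def load_run(path: Path, session: str, tr: float | None = None) -> BoldRun:
    img = nib.load(str(path))
    tr = tr or float(img.header["pixdim"][4])
    motion = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_motion.tsv")
    nuis = pd.read_csv(motion, sep="\t").to_numpy() if motion.exists() else None
    return BoldRun(data=np.asarray(img.dataobj), tr=tr, affine=img.affine,
                   session=session, nuisance=nuis)


def save_trace(trace: PainTrace, path: Path) -> None:
    pd.DataFrame({"time_s": trace.times, "rating": trace.ratings}).to_csv(
        path, sep="\t", index=False)


def load_trace(path: Path, subject_id: str = "") -> PainTrace:
    df = pd.read_csv(path, sep="\t")
    return PainTrace(subject_id=subject_id or Path(path).stem,
                     times=df["time_s"].to_numpy(),
                     ratings=df["rating"].to_numpy())


def save_atlas(atlas: Atlas, nii_path: Path, names_path: Path) -> None:
    nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine).to_filename(
        str(nii_path))
    pd.DataFrame(sorted(atlas.names.items()),
                 columns=["code", "name"]).to_csv(names_path, sep="\t", index=False)


def load_atlas(nii_path: Path, names_path: Path) -> Atlas:
    img = nib.load(str(nii_path))
    names = dict(pd.read_csv(names_path, sep="\t").itertuples(index=False, name=None))
    return Atlas(labels=np.asarray(img.dataobj).astype(int),
                 names={int(k): str(v) for k, v in names.items()},
                 affine=img.affine)


def save_cohort(subjects: list[SubjectRecord], atlas: Atlas, out_dir: Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_atlas(atlas, out / "atlas.nii.gz", out / "atlas_names.tsv")
    rows = []
    for s in subjects:
        sdir = out / s.id
        sdir.mkdir(exist_ok=True)
        save_trace(s.trace, sdir / "pain_trace.tsv")
        if s.motion_trace is not None:
            save_trace(s.motion_trace, sdir / "motion_cursor.tsv")
        for run in s.runs:
            save_run(run, sdir / f"{run.session}.nii.gz")
        rows.append({"subject_id": s.id, "sex": s.sex, "surgery": int(s.surgery),
                     "sessions": ",".join(r.session for r in s.runs)})
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)


def load_cohort(out_dir: Path) -> tuple[list[SubjectRecord], Atlas]:
    out = Path(out_dir)
    atlas = load_atlas(out / "atlas.nii.gz", out / "atlas_names.tsv")
    manifest = pd.read_csv(out / "manifest.tsv", sep="\t")
    subjects = []
    for row in manifest.itertuples(index=False):
        sdir = out / row.subject_id
        trace = load_trace(sdir / "pain_trace.tsv", row.subject_id)
        motion_trace = None
        if (sdir / "motion_cursor.tsv").exists():
            motion_trace = load_trace(sdir / "motion_cursor.tsv", row.subject_id)
        runs = [load_run(sdir / f"{sess}.nii.gz", sess)
                for sess in str(row.sessions).split(",")]
        subjects.append(SubjectRecord(id=row.subject_id, sex=row.sex,
                                      surgery=bool(row.surgery), trace=trace,
                                      runs=runs, motion_trace=motion_trace))
    return subjects, atlas


def cluster_table(rows: list[ClusterRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"region": r.region, "x_mm": r.peak_mm[0], "y_mm": r.peak_mm[1],
          "z_mm": r.peak_mm[2], "volume_voxels": r.volume_voxels,
          "volume_mm3": r.volume_mm3, "peak_t": r.peak_t, "sign": r.sign}
         for r in rows])


def heatmap_table(heatmap: OcclusionHeatmap) -> pd.DataFrame:
    rows = []
    for code in heatmap.ranking():
        row = {"code": code, "region": heatmap.names[code],
               "mean_drop": heatmap.mean_drop[code]}
        for i, d in enumerate(heatmap.fold_drops[code]):
            row[f"fold_{i}"] = d
        rows.append(row)
    return pd.DataFrame(rows)
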