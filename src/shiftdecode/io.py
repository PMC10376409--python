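"""Reading and writing sessions, betas and masks in standard formats.

Simulated sessions can be exported as BIDS-style artefacts — one 4-D NIfTI
per run, an events TSV (onset, duration, trial_type) and NIfTI ROI masks —
so that real, already-preprocessed data can be substituted for the
generator at the GLM stage.  A compact ``.npz`` export is provided for
fast round-trips in tests and between CLI stages.
"""

from __future__ import annotations

import json
import pathlib

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import TrialBetaMatrix
from .roi import ROIMask
from .simulate import ExperimentDesign, SimulatedSession

__all__ = [
    "save_session_bids",
    "load_bids_session",
    "save_session_npz",
    "load_session_npz",
    "save_betas",
    "load_betas",
    "save_masks_json",
    "load_masks_json",
]


def _voxel_grid(n_voxels: int) -> tuple[int, int, int]:
    """Smallest near-cubic grid holding ``n_voxels`` voxels."""
    side = int(np.ceil(n_voxels ** (1 / 3)))
    nz = int(np.ceil(n_voxels / side**2))
    return side, side, nz


def save_session_bids(session: SimulatedSession, out_dir) -> dict:
    """Write one NIfTI per run, an events TSV and ROI mask NIfTIs.

    Voxels are packed into a near-cubic 3-D grid in index order (the
    simulation has no spatial structure); the inverse mapping is the same
    flattening, so masks written here align with the 4-D data.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = _voxel_grid(session.n_voxels)
    affine = np.eye(4) * 3.0  # nominal 3 mm isotropic
    affine[3, 3] = 1.0
    paths: dict = {"runs": [], "rois": {}}
    for r, run in enumerate(session.runs):
        vol = np.zeros((nx * ny * nz, run.shape[1]), dtype=np.float32)
        vol[: session.n_voxels] = run
        img = nib.Nifti1Image(vol.reshape(nx, ny, nz, -1), affine)
        img.header.set_zooms((3.0, 3.0, 3.0, session.design.tr_s))
        p = out / f"{session.subject_id}_run-{r + 1:02d}_bold.nii.gz"
        nib.save(img, p)
        paths["runs"].append(str(p))
    ev = session.events.rename(
        columns={"onset_s": "onset", "duration_s": "duration", "condition": "trial_type"}
    )
    ev_path = out / f"{session.subject_id}_events.tsv"
    ev.to_csv(ev_path, sep="\t", index=False)
    paths["events"] = str(ev_path)
    for name, idx in session.rois.items():
        m = np.zeros(nx * ny * nz, dtype=np.uint8)
        m[idx] = 1
        p = out / f"{session.subject_id}_roi-{name}_mask.nii.gz"
        nib.save(nib.Nifti1Image(m.reshape(nx, ny, nz), affine), p)
        paths["rois"][name] = str(p)
    return paths


def load_bids_session(
    run_paths,
    events_path,
    roi_paths: dict | None = None,
    design: ExperimentDesign | None = None,
    n_dummy_already_removed: bool = True,
) -> SimulatedSession:
    """Assemble a session from 4-D NIfTI runs + events TSV (+ masks).

    Intended for real, preprocessed data: only the post-preprocessing
    stages (GLM onward) apply.  Events use BIDS columns onset / duration /
    trial_type and must carry a ``run`` column (0-based) or one TSV per
    run convention (single table covering all runs).
    """
    runs = []
    for p in run_paths:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=float)
        runs.append(data.reshape(-1, data.shape[-1]))
    ev = pd.read_csv(events_path, sep="\t")
    ev = ev.rename(columns={"onset": "onset_s", "duration": "duration_s", "trial_type": "condition"})
    if "run" not in ev.columns:
        raise ValueError("events table needs a 'run' column (0-based run index)")
    rois = {}
    if roi_paths:
        for name, p in roi_paths.items():
            mask = np.asarray(nib.load(str(p)).dataobj).reshape(-1)
            rois[name] = np.flatnonzero(mask > 0)
    if design is None:
        shifts = sorted(
            {
                float(c.partition("_s")[2])
                for c in ev["condition"].unique()
                if c.startswith("im")
            }
        )
        tr = float(nib.load(str(run_paths[0])).header.get_zooms()[-1]) or 1.0
        design = ExperimentDesign(
            shift_levels_deg=tuple(shifts),
            n_runs=len(runs),
            tr_s=tr,
            n_dummy=0 if n_dummy_already_removed else 2,
        )
    return SimulatedSession(
        runs=runs,
        events=ev,
        rois=rois,
        truth={},
        design=design,
        seed=-1,
        subject_id=pathlib.Path(run_paths[0]).name.split("_")[0],
    )


def save_session_npz(session: SimulatedSession, path) -> None:
    """Compact columnar export of a simulated session."""
    ev = session.events
    np.savez_compressed(
        path,
        n_runs=len(session.runs),
        **{f"run{r}": arr for r, arr in enumerate(session.runs)},
        ev_run=ev["run"].to_numpy(),
        ev_onset=ev["onset_s"].to_numpy(),
        ev_duration=ev["duration_s"].to_numpy(),
        ev_condition=np.asarray(ev["condition"], dtype=str),
        roi_names=np.asarray(list(session.rois), dtype=str),
        **{f"roi_{k}": v for k, v in session.rois.items()},
        design=json.dumps(
            {
                "shift_levels_deg": list(session.design.shift_levels_deg),
                "n_runs": session.design.n_runs,
                "sequences_per_run": session.design.sequences_per_run,
                "tr_s": session.design.tr_s,
                "n_dummy": session.design.n_dummy,
            }
        ),
        seed=session.seed,
        subject_id=session.subject_id,
        experiment=session.experiment,
    )


def load_session_npz(path) -> SimulatedSession:
    with np.load(path, allow_pickle=False) as z:
        dd = json.loads(str(z["design"]))
        design = ExperimentDesign(
            shift_levels_deg=tuple(dd["shift_levels_deg"]),
            n_runs=int(dd["n_runs"]),
            sequences_per_run=int(dd["sequences_per_run"]),
            tr_s=float(dd["tr_s"]),
            n_dummy=int(dd["n_dummy"]),
        )
        runs = [z[f"run{r}"] for r in range(int(z["n_runs"]))]
        events = pd.DataFrame(
            {
                "run": z["ev_run"],
                "onset_s": z["ev_onset"],
                "duration_s": z["ev_duration"],
                "condition": z["ev_condition"].astype(str),
            }
        )
        rois = {str(name): z[f"roi_{name}"] for name in z["roi_names"]}
        return SimulatedSession(
            runs=runs,
            events=events,
            rois=rois,
            truth={},
            design=design,
            seed=int(z["seed"]),
            subject_id=str(z["subject_id"]),
            experiment=str(z["experiment"]),
        )


def save_betas(betas: TrialBetaMatrix, stem) -> None:
    """Columnar beta export: ``<stem>.npy`` + ``<stem>_labels.csv`` sidecar."""
    stem = pathlib.Path(stem)
    np.save(stem.with_suffix(".npy"), betas.betas)
    betas.labels.to_csv(stem.parent / f"{stem.name}_labels.csv", index=False)


def load_betas(stem) -> TrialBetaMatrix:
    stem = pathlib.Path(stem)
    mat = np.load(stem.with_suffix(".npy"))
    labels = pd.read_csv(stem.parent / f"{stem.name}_labels.csv")
    return TrialBetaMatrix(mat, labels)


def save_masks_json(masks: dict[str, ROIMask], path) -> None:
    payload = {
        name: {
            "voxel_indices": m.voxel_indices.tolist(),
            "source_contrast": m.source_contrast,
            "threshold": None if np.isnan(m.threshold) else m.threshold,
        }
        for name, m in masks.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_masks_json(path) -> dict[str, ROIMask]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        name: ROIMask(
            np.asarray(d["voxel_indices"], dtype=int),
            d["source_contrast"],
            d["threshold"] if d["threshold"] is not None else float("nan"),
        )
        for name, d in payload.items()
    }
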