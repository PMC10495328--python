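"""End-to-end drivers tying the stages together.

These functions operate either on in-memory synthetic cohorts or on
cohort directories written by :func:`rootsetup.io.write_cohort`; the
numbered analysis scripts and the CLI are thin wrappers around them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import exposure as xp
from . import geometry as geo
from .errors import ValidationError
from .io import Manifest, read_landmarks, read_mesh
from .parallelism import (
    PoolingGate,
    adjacent_differences,
    parallelism_table,
    pool_left_right,
)
from .synthetic import SyntheticCohort


def measure_cohort_angles(cohort: SyntheticCohort) -> pd.DataFrame:
    """Angulation/inclination of every tooth, all setups measured in the
    patient's shared root setup-2 occlusal frame."""
    rows = []
    for patient in cohort.patients:
        frame = patient.frame()
        for (setup, jaw), arch in sorted(patient.arches.items()):
            lms = [arch.landmarks[f] for f in sorted(arch.landmarks)]
            for m in geo.measure_setup(lms, frame, setup):
                rows.append(
                    {
                        "patient_id": patient.patient_id,
                        "jaw": jaw,
                        "setup": setup,
                        "fdi": m.tooth_id,
                        "angulation": m.angulation,
                        "inclination": m.inclination,
                    }
                )
    return pd.DataFrame(rows)


def angles_from_files(data_dir) -> pd.DataFrame:
    """Same as :func:`measure_cohort_angles`, reading a cohort directory."""
    manifest = Manifest.load(Path(data_dir))
    rows = []
    for patient_id, setups in sorted(manifest.entries.items()):
        if "root2" not in setups or "maxilla" not in setups["root2"]:
            raise ValidationError(
                f"patient {patient_id}: missing root setup-2 maxilla "
                "(required for the shared occlusal frame)"
            )
        ref = read_landmarks(manifest.path(setups["root2"]["maxilla"]["landmarks"]))
        frame = ref.occlusal_frame()
        for setup, jaws in sorted(setups.items()):
            for jaw, entry in sorted(jaws.items()):
                ds = read_landmarks(manifest.path(entry["landmarks"]))
                lms = [ds.teeth[f] for f in sorted(ds.teeth)]
                for m in geo.measure_setup(lms, frame, setup):
                    rows.append(
                        {
                            "patient_id": patient_id,
                            "jaw": jaw,
                            "setup": setup,
                            "fdi": m.tooth_id,
                            "angulation": m.angulation,
                            "inclination": m.inclination,
                        }
                    )
    return pd.DataFrame(rows)


def truth_exposure_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-tooth per-side combined exposure from the generator's ground
    truth (the mesh-free path used for cohort-level statistics)."""
    gt = cohort.ground_truth
    rows = []
    for side in xp.SIDES:
        part = gt[["patient_id", "jaw", "setup", "fdi"]].copy()
        part["side"] = side
        part["combined"] = gt[f"true_exposure_{side}"].to_numpy()
        rows.append(part)
    return pd.concat(rows, ignore_index=True)


def measure_arch_exposure(arch, frame, sampling_density: float = 25.0) -> pd.DataFrame:
    """Mesh-based exposure measurement of one arch (both sides of every
    tooth)."""
    if arch.tooth_meshes is None or arch.bone_meshes is None:
        raise ValidationError("arch has no meshes; regenerate with_meshes=True")
    mids = [geo.long_axis(lm)[0] for lm in arch.landmarks.values()]
    rows = []
    for fdi in sorted(arch.landmarks):
        lm = arch.landmarks[fdi]
        lingual = geo.lingual_reference(mids, lm, frame)
        comps = xp.exposed_root_points(
            arch.tooth_meshes[fdi], arch.bone_meshes[fdi], arch.discs[fdi],
            sampling_density,
        )
        comps = xp.assign_side(comps, lm, frame, lingual)
        results = xp.measure_exposure(comps, arch.discs[fdi])
        for side, res in results.items():
            rows.append(
                {
                    "patient_id": arch.patient_id,
                    "jaw": arch.jaw,
                    "setup": arch.setup,
                    "fdi": fdi,
                    "side": side,
                    "dehiscence": res.dehiscence,
                    "fenestration": res.fenestration,
                    "combined": res.combined,
                }
            )
    return pd.DataFrame(rows)


def exposure_from_files(data_dir, sampling_density: float = 25.0) -> pd.DataFrame:
    """Mesh-based exposure for every patient/setup/jaw in a cohort
    directory (setups only; the initial scan carries no bone program)."""
    manifest = Manifest.load(Path(data_dir))
    frames = []
    for patient_id, setups in sorted(manifest.entries.items()):
        ref = read_landmarks(manifest.path(setups["root2"]["maxilla"]["landmarks"]))
        frame = ref.occlusal_frame()
        for setup, jaws in sorted(setups.items()):
            if setup == "initial":
                continue
            for jaw, entry in sorted(jaws.items()):
                if not entry.get("teeth"):
                    raise ValidationError(
                        f"patient {patient_id} {setup}/{jaw}: no tooth meshes"
                    )
                ds = read_landmarks(manifest.path(entry["landmarks"]))
                mids = [geo.long_axis(lm)[0] for lm in ds.teeth.values()]
                for fdi in sorted(ds.teeth):
                    lm = ds.teeth[fdi]
                    lingual = geo.lingual_reference(mids, lm, frame)
                    tooth = read_mesh(manifest.path(entry["teeth"][str(fdi)]))
                    bone = read_mesh(manifest.path(entry["bone"][str(fdi)]))
                    comps = xp.exposed_root_points(
                        tooth, bone, ds.discs[fdi], sampling_density
                    )
                    comps = xp.assign_side(comps, lm, frame, lingual)
                    for side, res in xp.measure_exposure(comps, ds.discs[fdi]).items():
                        frames.append(
                            {
                                "patient_id": patient_id,
                                "jaw": jaw,
                                "setup": setup,
                                "fdi": fdi,
                                "side": side,
                                "dehiscence": res.dehiscence,
                                "fenestration": res.fenestration,
                                "combined": res.combined,
                            }
                        )
    return pd.DataFrame(frames)


def run_parallelism(
    angles: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, PoolingGate | None, pd.DataFrame]:
    """Adjacent-tooth differences, the left/right pooling gate (when an
    initial scan is present), and the per-location comparison table."""
    pairs = adjacent_differences(angles)
    initial = angles[angles["setup"] == "initial"]
    gate = pool_left_right(initial, alpha) if len(initial) else None
    pooled = gate.pooled if gate is not None else True
    table = parallelism_table(
        pairs[pairs["setup"] != "initial"], alpha, pooled=pooled
    )
    return pairs, gate, table


def run_exposure_stats(
    exposure: pd.DataFrame, threshold: float = 2.0, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-exposure and >threshold frequency tables with their tests."""
    return xp.exposure_tables(exposure, threshold, alpha)
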