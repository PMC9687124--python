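"""Palpation-location sweep and surrogate dataset assembly.

Runs one palpation simulation per location of a training grid (plus
held-out test locations), extracts the finger contact force and the
maximum principal stress over the liver-edge ROI at each output time
stamp, and packs everything into flat records suitable for surrogate
training.  Records are stored as CSV with a commented header documenting
the ROI element ids and units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem import FingerPair, PalpationSchedule, ContactParams, simulate_palpation, SimulationError
from .materials import MaterialCards, max_principal_stress_field
from .phantom import HexMesh

__all__ = [
    "SweepPlan",
    "PalpationRecord",
    "make_grid",
    "run_sweep",
    "records_to_frame",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class SweepPlan:
    """Training grid + held-out test locations for the surrogate dataset."""

    nx: int = 5
    ny: int = 5
    bounds: tuple[float, float, float, float] = (18.0, 78.0, 14.0, 46.0)  # xmin, xmax, ymin, ymax
    test_locations: tuple[tuple[float, float], ...] = ((40.5, 26.0), (55.5, 34.0), (25.5, 42.0))
    indentation_depth: float = 15.0
    duration_ms: float = 25.0
    output_stamps: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have nx, ny >= 1")
        grid = {tuple(np.round(p, 9)) for p in make_grid(self.nx, self.ny, self.bounds)}
        for t in self.test_locations:
            if tuple(np.round(t, 9)) in grid:
                raise ValueError(f"test location {t} coincides with a training grid point")

    @property
    def train_locations(self) -> np.ndarray:
        return make_grid(self.nx, self.ny, self.bounds)


@dataclass(frozen=True)
class PalpationRecord:
    """One surrogate sample: plan position, time stamp, force, ROI stresses.

    Force in N, stresses in GPa (sigma3 per ROI element), partition is
    'train' or 'test'.
    """

    x: float
    y: float
    time_ms: float
    force_N: float
    sigma3: np.ndarray
    partition: str = "train"

    def __post_init__(self) -> None:
        if self.force_N < -1e-9:
            raise ValueError("contact force magnitude must be non-negative")


def make_grid(nx: int, ny: int, bounds) -> np.ndarray:
    """Row-major uniform grid over (xmin, xmax, ymin, ymax).

    Ordered top-left to bottom-right: rows sweep y from ymax down, x from
    xmin to xmax within each row (position 1 = top-left, last position =
    bottom-right).  A 1x1 grid is the rectangle centre.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    xmin, xmax, ymin, ymax = map(float, bounds)
    if xmax < xmin or ymax < ymin or (nx > 1 and xmax == xmin) or (ny > 1 and ymax == ymin):
        raise ValueError("degenerate bounds for the requested grid size")
    xs = np.linspace(xmin, xmax, nx) if nx > 1 else np.array([(xmin + xmax) / 2.0])
    ys = np.linspace(ymax, ymin, ny) if ny > 1 else np.array([(ymin + ymax) / 2.0])
    pts = [(x, y) for y in ys for x in xs]
    return np.array(pts)


def run_sweep(
    mesh: HexMesh,
    cards: MaterialCards,
    plan: SweepPlan,
    *,
    contact: ContactParams | None = None,
    fingers_template: FingerPair | None = None,
    progress: bool = False,
    **sim_kwargs,
) -> list[PalpationRecord]:
    """One palpation simulation per plan location; records per time stamp.

    The mesh must carry a tagged liver-edge ROI.  Solver forces are in kN
    and converted to N here, the scale palpation forces are reported in.
    Any simulation abort fails the whole sweep with the offending
    location in the message.
    """
    if len(mesh.roi_elements) == 0:
        raise ValueError("mesh has no tagged ROI elements; run select_roi/tag_roi first")
    schedule = PalpationSchedule(duration_ms=plan.duration_ms, output_stamps=plan.output_stamps)
    template = fingers_template or FingerPair(x=0.0, y=0.0)
    records: list[PalpationRecord] = []
    jobs = [(x, y, "train") for x, y in plan.train_locations]
    jobs += [(x, y, "test") for x, y in plan.test_locations]
    for i, (x, y, part) in enumerate(jobs):
        fingers = FingerPair(
            x=float(x),
            y=float(y),
            tip_radius=template.tip_radius,
            spacing=template.spacing,
            depth=plan.indentation_depth,
            ramp_ms=plan.duration_ms,
            shaft_length=template.shaft_length,
        )
        if progress:
            print(f"[{i + 1}/{len(jobs)}] palpation at ({x:.1f}, {y:.1f}) [{part}]")
        try:
            traj = simulate_palpation(mesh, cards, fingers, schedule, contact=contact, **sim_kwargs)
        except SimulationError as err:
            raise SimulationError(f"sweep failed at location ({x}, {y}): {err}") from err
        for frame in traj.frames:
            s3 = max_principal_stress_field(frame.element_stress[mesh.roi_elements])
            records.append(
                PalpationRecord(
                    x=float(x),
                    y=float(y),
                    time_ms=frame.time,
                    force_N=1e3 * frame.finger_force,
                    sigma3=s3,
                    partition=part,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------


def records_to_frame(records: list[PalpationRecord], roi_ids: np.ndarray) -> pd.DataFrame:
    cols = {
        "partition": [r.partition for r in records],
        "x_mm": [r.x for r in records],
        "y_mm": [r.y for r in records],
        "t_ms": [r.time_ms for r in records],
        "force_N": [r.force_N for r in records],
    }
    s3 = np.array([r.sigma3 for r in records]) if records else np.zeros((0, len(roi_ids)))
    if records and s3.shape[1] != len(roi_ids):
        raise ValueError("record sigma3 length does not match ROI size")
    for j, eid in enumerate(roi_ids):
        cols[f"s3_{int(eid)}"] = s3[:, j] if len(records) else []
    return pd.DataFrame(cols)


def write_dataset(records: list[PalpationRecord], roi_ids: np.ndarray, path) -> None:
    """Write records as CSV; header comments document ROI ids and units."""
    df = records_to_frame(records, roi_ids)
    with open(path, "w") as fh:
        fh.write("# palpsim palpation dataset\n")
        fh.write("# units: x_mm,y_mm [mm]; t_ms [ms]; force_N [N]; s3_* [GPa]\n")
        fh.write(f"# roi_element_ids: {','.join(str(int(e)) for e in roi_ids)}\n")
        df.to_csv(fh, index=False)


def read_dataset(path, expected_roi: np.ndarray | None = None):
    """Read a dataset CSV back into records + ROI element ids.

    Raises if the stored ROI ids disagree with ``expected_roi``.
    """
    roi_ids = None
    with open(path) as fh:
        pos = fh.tell()
        for line in fh:
            if line.startswith("# roi_element_ids:"):
                txt = line.split(":", 1)[1].strip()
                roi_ids = np.array([int(t) for t in txt.split(",")]) if txt else np.array([], dtype=int)
            if not line.startswith("#"):
                break
        fh.seek(0)
        df = pd.read_csv(fh, comment="#")
    if roi_ids is None:
        raise ValueError(f"{path}: missing roi_element_ids header")
    s3_cols = [c for c in df.columns if c.startswith("s3_")]
    stored = np.array([int(c[3:]) for c in s3_cols])
    if not np.array_equal(stored, roi_ids):
        raise ValueError(f"{path}: header ROI ids disagree with stress columns")
    if expected_roi is not None and not np.array_equal(np.asarray(expected_roi), roi_ids):
        raise ValueError(f"{path}: ROI size/ids mismatch with the supplied mesh")
    records = [
        PalpationRecord(
            x=row.x_mm,
            y=row.y_mm,
            time_ms=row.t_ms,
            force_N=row.force_N,
            sigma3=np.array([getattr(row, c) for c in s3_cols]),
            partition=row.partition,
        )
        for row in df.itertuples(index=False)
    ]
    return records, roi_ids
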