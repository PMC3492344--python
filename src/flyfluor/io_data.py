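"""Reading and writing trajectories, image stacks, and identity calls.

Conventions fixed here and used everywhere else in the package:

* trajectories travel as CSV (comma separator, ``.`` decimal, UTF-8, header
  required) with columns ``frame,fly_id,x,y,theta,a,b``;
* ``theta`` is the body-axis orientation in radians, counterclockwise from
  the +x image axis, pointing head-ward, normalized to [-pi, pi);
* ``a``/``b`` are the semi-major/semi-minor body axes in pixels;
* images use the image-coordinate convention: origin at the top-left pixel,
  x rightward, y downward, 0-based indices, pixel centers on the integer
  lattice.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ParseError, UnsupportedFormatError

TRAJECTORY_COLUMNS = ("frame", "fly_id", "x", "y", "theta", "a", "b")

_TWO_PI = 2.0 * math.pi


def normalize_angle(theta: float) -> float:
    """Wrap an angle into [-pi, pi)."""
    wrapped = math.remainder(theta, _TWO_PI)
    if wrapped >= math.pi:  # remainder returns (-pi, pi]; fold the closed end
        wrapped -= _TWO_PI
    return wrapped


class Channel(enum.Enum):
    IR = "IR"
    FLUOR = "FLUOR"


class Label(enum.Enum):
    GFP = "GFP"
    NON_GFP = "non-GFP"


@dataclass(frozen=True)
class TrajectoryRecord:
    """One fly's tracked pose in one frame.

    Positions are centroid pixel coordinates; ``a >= b > 0`` are the fitted
    body-ellipse semi-axes in pixels.
    """

    frame: int
    fly_id: int
    x: float
    y: float
    theta: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.frame < 0 or self.fly_id < 0:
            raise IntegrityError(
                f"frame and fly_id must be non-negative (got frame={self.frame}, "
                f"fly_id={self.fly_id})"
            )
        if not (self.a >= self.b > 0):
            raise IntegrityError(
                f"body semi-axes must satisfy a ≥ b > 0 "
                f"(fly {self.fly_id}, frame {self.frame}: a={self.a}, b={self.b})"
            )
        if not all(math.isfinite(v) for v in (self.x, self.y, self.theta)):
            raise IntegrityError(
                f"non-finite pose for fly {self.fly_id}, frame {self.frame}"
            )
        object.__setattr__(self, "theta", normalize_angle(self.theta))


@dataclass
class ImageStack:
    """An ordered grayscale image sequence from one channel.

    ``frame_indices[k]`` is the trajectory frame number that stack page ``k``
    was acquired at; it defaults to ``0..n-1``.
    """

    frames: np.ndarray  # (n, h, w), uint8 or uint16
    channel: Channel
    frame_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"image stack must be (n, h, w); got shape {self.frames.shape}"
            )
        if self.frames.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
            raise FormatError(
                f"image stack must be 8- or 16-bit unsigned; got {self.frames.dtype}"
            )
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.frames))
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if len(self.frame_indices) != len(self.frames):
            raise IntegrityError("frame_indices length must match frame count")
        if len(self.frame_indices) > 1 and np.any(np.diff(self.frame_indices) <= 0):
            raise IntegrityError("frame_indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class IdentityCall:
    """Per-fly genotype call with its decision score and margin.

    ``margin`` is the distance of the combined score from the decision
    boundary (threshold mode) or from the cut between ranks N and N+1
    (prior-count mode); it is always non-negative.
    """

    fly_id: int
    label: Label
    score: float
    margin: float

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise IntegrityError(f"margin must be >= 0 (fly {self.fly_id})")


# ---------------------------------------------------------------------------
# trajectories


def read_trajectories(path: str | Path, on_invalid: str = "raise") -> list[TrajectoryRecord]:
    """Read trajectory records from the canonical CSV format.

    Parameters
    ----------
    path:
        CSV file with header ``frame,fly_id,x,y,theta,a,b``.
    on_invalid:
        ``"raise"`` (default) aborts on the first row violating a
        TrajectoryRecord invariant; ``"warn"`` drops such rows with an
        explicit warning so no row is ever dropped silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if on_invalid not in ("raise", "warn"):
        raise ValueError("on_invalid must be 'raise' or 'warn'")
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {', '.join(missing)}; "
            f"expected header {','.join(TRAJECTORY_COLUMNS)}"
        )
    for col in TRAJECTORY_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path.name}: non-numeric value {df[col][row]!r} in column "
                f"'{col}' at data row {row + 1}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ParseError(f"{path.name}: empty cell in column '{col}' at data row {row + 1}")
        df[col] = numeric

    dup = df.duplicated(subset=["fly_id", "frame"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["fly_id", "frame"]]
        raise IntegrityError(
            f"{path.name}: duplicate (fly_id, frame) = ({int(pair.fly_id)}, {int(pair.frame)})"
        )

    records: list[TrajectoryRecord] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                TrajectoryRecord(
                    frame=int(row.frame), fly_id=int(row.fly_id),
                    x=float(row.x), y=float(row.y), theta=float(row.theta),
                    a=float(row.a), b=float(row.b),
                )
            )
        except IntegrityError as exc:
            if on_invalid == "raise":
                raise IntegrityError(f"{path.name}, data row {i + 1}: {exc}") from exc
            n_rejected += 1
            warnings.warn(f"{path.name}: rejected data row {i + 1}: {exc}", stacklevel=2)
    if n_rejected:
        warnings.warn(
            f"{path.name}: {n_rejected} of {len(df)} rows rejected", stacklevel=2
        )
    return records


def write_trajectories(records: Iterable[TrajectoryRecord], path: str | Path) -> None:
    """Write records in the canonical CSV format (12 significant digits)."""
    df = pd.DataFrame([vars(r) for r in records], columns=list(TRAJECTORY_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g")


def import_ctrax_export(
    path: str | Path, axis_scale: float = 1.0, flip_orientation: bool = False
) -> list[TrajectoryRecord]:
    """Import a Ctrax-style MAT export into TrajectoryRecords.

    Two container layouts are recognized:

    * *matrix layout*: 2-D arrays ``x_pos, y_pos, angle, maj_ax, min_ax`` of
      shape (n_frames, n_flies); fly ``j`` of frame ``i`` is element (i, j);
    * *flat layout*: 1-D arrays of the same names plus ``identity`` (fly id
      per sample) and ``ntargets`` (flies per frame, defining frame breaks).

    Field mapping: ``x_pos``/``y_pos`` -> centroid pixels; ``angle`` ->
    ``theta`` after normalization to [-pi, pi) (set ``flip_orientation`` to
    add pi to every angle when the tracker's head convention is reversed);
    ``maj_ax``/``min_ax`` are interpreted as semi-axes after multiplication
    by ``axis_scale`` (default 1.0; use 2.0 for trackers exporting
    quarter-axis lengths).
    """
    from scipy.io import loadmat

    try:
        mat = loadmat(str(path))
    except Exception as exc:  # noqa: BLE001 - loadmat raises several types
        raise UnsupportedFormatError(
            f"{path}: not a readable MAT container ({exc}); convert the tracker "
            "output to the trajectory CSV format instead"
        ) from exc

    required = ("x_pos", "y_pos", "angle", "maj_ax", "min_ax")
    missing = [k for k in required if k not in mat]
    if missing:
        raise UnsupportedFormatError(
            f"{path}: container is missing array(s) {', '.join(missing)}; "
            "convert the tracker output to the trajectory CSV format instead"
        )
    flat = "identity" in mat and "ntargets" in mat
    arrays = {
        k: (
            np.asarray(mat[k], dtype=float).ravel()
            if flat
            else np.atleast_2d(np.asarray(mat[k], dtype=float))
        )
        for k in required
    }
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise UnsupportedFormatError(f"{path}: pose arrays have inconsistent shapes")

    records: list[TrajectoryRecord] = []

    def _make(frame: int, fly: int, i) -> TrajectoryRecord:
        theta = float(arrays["angle"][i])
        if flip_orientation:
            theta += math.pi
        return TrajectoryRecord(
            frame=frame, fly_id=fly,
            x=float(arrays["x_pos"][i]), y=float(arrays["y_pos"][i]),
            theta=theta,
            a=float(arrays["maj_ax"][i]) * axis_scale,
            b=float(arrays["min_ax"][i]) * axis_scale,
        )

    if flat:
        identity = np.asarray(mat["identity"], dtype=int).ravel()
        ntargets = np.asarray(mat["ntargets"], dtype=int).ravel()
        if identity.shape != arrays["x_pos"].shape or ntargets.sum() != len(identity):
            raise UnsupportedFormatError(f"{path}: flat layout bookkeeping is inconsistent")
        offset = 0
        for frame, n in enumerate(ntargets):
            for i in range(offset, offset + int(n)):
                records.append(_make(frame, int(identity[i]), i))
            offset += int(n)
    else:
        n_frames, n_flies = arrays["x_pos"].shape
        for frame in range(n_frames):
            for fly in range(n_flies):
                records.append(_make(frame, fly, (frame, fly)))
    return records


# ---------------------------------------------------------------------------
# image stacks

_SEQUENCE_SUFFIXES = (".png", ".tif", ".tiff", ".bmp")


def _check_frame(arr: np.ndarray, name: str) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise FormatError(
            f"{name}: color image; supply single-channel grayscale input"
        )
    if arr.ndim != 2:
        raise FormatError(f"{name}: expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def _read_sidecar_indices(candidates: Sequence[Path], n: int) -> np.ndarray | None:
    for cand in candidates:
        if cand.exists():
            idx = np.loadtxt(cand, dtype=int, ndmin=1)
            if len(idx) != n:
                raise IntegrityError(
                    f"{cand.name}: sidecar lists {len(idx)} indices for {n} frames"
                )
            return idx
    return None


def read_image_stack(path: str | Path, channel: Channel = Channel.FLUOR) -> ImageStack:
    """Read a multi-page TIFF or a numbered grayscale image sequence.

    A directory is read as a lexicographically ordered image sequence. If a
    sidecar index file is present (``<stem>.indices.txt`` next to a TIFF, or
    ``frame_indices.txt`` inside a directory; one integer per line) it
    supplies ``frame_indices``; otherwise they default to ``0..n-1``.
    """
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _SEQUENCE_SUFFIXES
        )
        if not files:
            raise FormatError(f"{path}: no image files found")
        frames = [_check_frame(np.asarray(iio.imread(f)), f.name) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise FormatError(f"{path}: mixed frame shapes {sorted(shapes)}")
        dtypes = {f.dtype for f in frames}
        if len(dtypes) != 1:
            raise FormatError(f"{path}: mixed frame dtypes")
        stack = np.stack(frames)
        sidecar = _read_sidecar_indices([path / "frame_indices.txt"], len(stack))
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        data = np.asarray(tifffile.imread(str(path)))
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            _check_frame(data[0] if data.ndim > 3 else data, path.name)
            raise FormatError(f"{path.name}: unsupported page shape {data.shape}")
        _check_frame(data[0], path.name)
        stack = data
        sidecar = _read_sidecar_indices(
            [path.with_suffix(".indices.txt")], len(stack)
        )
    return ImageStack(frames=stack, channel=channel, frame_indices=sidecar)


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write the stack as a multi-page TIFF, with a sidecar index file when
    frame_indices are not the trivial 0..n-1."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(str(path), stack.frames, photometric="minisblack")
    trivial = np.array_equal(stack.frame_indices, np.arange(len(stack)))
    if not trivial:
        np.savetxt(path.with_suffix(".indices.txt"), stack.frame_indices, fmt="%d")


# ---------------------------------------------------------------------------
# identity calls


def write_identity_calls(calls: Sequence[IdentityCall], path: str | Path) -> None:
    """Write identity calls as CSV with header ``fly_id,label,score,margin``."""
    if not calls:
        raise ValueError("calls must be non-empty")
    ids = [c.fly_id for c in calls]
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate fly_id in identity calls")
    df = pd.DataFrame(
        {
            "fly_id": ids,
            "label": [c.label.value for c in calls],
            "score": [c.score for c in calls],
            "margin": [c.margin for c in calls],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_identity_calls(path: str | Path) -> list[IdentityCall]:
    df = pd.read_csv(path)
    missing = [c for c in ("fly_id", "label", "score", "margin") if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing column(s) {', '.join(missing)}")
    calls = [
        IdentityCall(
            fly_id=int(r.fly_id), label=Label(r.label),
            score=float(r.score), margin=float(r.margin),
        )
        for r in df.itertuples(index=False)
    ]
    if len({c.fly_id for c in calls}) != len(calls):
        raise IntegrityError(f"{Path(path).name}: duplicate fly_id")
    return calls


def read_truth(path: str | Path) -> dict[int, Label]:
    """Read a ground-truth table (columns ``fly_id,label``) into a mapping."""
    df = pd.read_csv(path)
    missing = [c for c in ("fly_id", "label") if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing column(s) {', '.join(missing)}")
    return {int(r.fly_id): Label(r.label) for r in df.itertuples(index=False)}


def write_truth(truth: dict[int, Label], path: str | Path) -> None:
    pd.DataFrame(
        {"fly_id": list(truth), "label": [lab.value for lab in truth.values()]}
    ).to_csv(path, index=False)
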