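"""Slice selection, cropping, normalisation and dataset assembly.

Mirrors the clinical preprocessing chain: within each case the long-time
stack is normalised and the slice with the highest maximum count is taken as
the optimal striatal slice; the five slices centred on it form the analysis
window (the three central ones are kept for reader display).  Each 128 x 128
slice is cropped to its central 64 x 64 pixels, intensities are normalised
per case to [0, 1], and training samples pair a 5-slice short-time input
window with its single long-time target slice.
"""

from __future__ import annotations

import secrets
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from PIL import Image

__all__ = [
    "SliceSelection",
    "SliceSample",
    "select_slices",
    "crop_center",
    "normalize_case",
    "build_samples",
    "split_dataset",
    "export_png8",
    "export_reader_image",
]

WINDOW = 5  # analysis slices per case
READER_WINDOW = 3  # slices shown to readers
CROP = 64


@dataclass(frozen=True)
class SliceSelection:
    case_id: str
    center_index: int
    window_indices: tuple[int, ...]  # 5 contiguous, contains center
    reader_indices: tuple[int, ...]  # 3 contiguous, centred (clamped)

    def __post_init__(self) -> None:
        for name, idx, length in (
            ("window_indices", self.window_indices, WINDOW),
            ("reader_indices", self.reader_indices, READER_WINDOW),
        ):
            if len(idx) != length or list(idx) != list(range(idx[0], idx[0] + length)):
                raise ValueError(f"{name} must be {length} contiguous indices")
        if self.center_index not in self.window_indices:
            raise ValueError("window must contain the center index")


@dataclass
class SliceSample:
    """One training/evaluation unit: 5-slice short-time input, 1 long-time target."""

    case_id: str
    target_index: int
    input_window: np.ndarray  # (5, 64, 64) in [0, 1]
    target: np.ndarray  # (1, 64, 64) in [0, 1]
    partition: str = "train"

    def __post_init__(self) -> None:
        if self.input_window.shape != (WINDOW, CROP, CROP):
            raise ValueError(f"input_window shape must be (5, 64, 64), got {self.input_window.shape}")
        if self.target.shape != (1, CROP, CROP):
            raise ValueError(f"target shape must be (1, 64, 64), got {self.target.shape}")
        for name, arr in (("input_window", self.input_window), ("target", self.target)):
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} intensities must lie in [0, 1]")


def _clamped_window(center: int, length: int, n: int) -> tuple[int, ...]:
    """Contiguous window of ``length`` around ``center``, shifted into [0, n)."""
    start = center - length // 2
    start = max(0, min(start, n - length))
    return tuple(range(start, start + length))


def select_slices(long_stack: np.ndarray, case_id: str = "") -> SliceSelection:
    """Pick the optimal striatal slice and its analysis/reader windows.

    The centre is the slice whose maximum pixel value (after case
    normalisation, which does not change the argmax) is highest; ties break
    to the lowest index.  Windows are clamped to stay in bounds by shifting,
    preserving their length.
    """
    long_stack = np.asarray(long_stack)
    n = long_stack.shape[0]
    if n < WINDOW:
        raise ValueError(f"stack must have >= {WINDOW} slices, got {n}")
    per_slice_max = long_stack.reshape(n, -1).max(axis=1)
    center = int(np.argmax(per_slice_max))  # argmax returns the lowest tied index
    return SliceSelection(
        case_id=case_id,
        center_index=center,
        window_indices=_clamped_window(center, WINDOW, n),
        reader_indices=_clamped_window(center, READER_WINDOW, n),
    )


def crop_center(image: np.ndarray) -> np.ndarray:
    """Central 64 x 64 crop of a 128 x 128 image (rows/cols [32, 96))."""
    image = np.asarray(image)
    if image.shape != (128, 128):
        raise ValueError(f"expected a 128x128 image, got {image.shape}")
    return image[32:96, 32:96]


def normalize_case(stack: np.ndarray) -> np.ndarray:
    """Divide a whole case stack by its global maximum (per case, not per slice)."""
    stack = np.asarray(stack, dtype=np.float64)
    peak = stack.max()
    if peak <= 0:
        raise ValueError("cannot normalise an all-zero (or non-positive) stack")
    return stack / peak


def build_samples(pair, selection: SliceSelection) -> list[SliceSample]:
    """Assemble the 5 per-case samples: cropped, case-normalised, window-padded.

    For each target slice in the analysis window the input is the 5
    short-time slices centred on it; indices falling outside the selected
    window are replicate-padded at the window boundary.
    """
    if pair.case_id != selection.case_id:
        raise ValueError(f"case id mismatch: pair {pair.case_id!r} vs selection {selection.case_id!r}")
    short = normalize_case(pair.short_stack)
    long_ = normalize_case(pair.long_stack)
    lo, hi = selection.window_indices[0], selection.window_indices[-1]
    samples = []
    for target_idx in selection.window_indices:
        channels = []
        for offset in range(-(WINDOW // 2), WINDOW // 2 + 1):
            z = min(max(target_idx + offset, lo), hi)  # replicate-pad at window edge
            channels.append(crop_center(short[z]))
        samples.append(
            SliceSample(
                case_id=pair.case_id,
                target_index=target_idx,
                input_window=np.stack(channels).astype(np.float32),
                target=crop_center(long_[target_idx])[None].astype(np.float32),
            )
        )
    return samples


def split_dataset(case_ids, fractions=(120 / 207, 37 / 207, 50 / 207), seed: int = 0) -> dict[str, str]:
    """Assign whole cases to train/validation/test partitions.

    The split is by case, never by slice, so all 5 samples of a case share a
    partition.  Counts follow floor(train), floor(val), remainder to test.
    """
    case_ids = list(case_ids)
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be 3 non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)!r}")
    n = len(case_ids)
    if n < sum(1 for f in fractions if f > 0):
        raise ValueError("fewer cases than requested partitions")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    order = rng.permutation(n)
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    assignment = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            part = "train"
        elif rank < n_train + n_val:
            part = "validation"
        else:
            part = "test"
        assignment[case_ids[idx]] = part
    return assignment


def export_png8(image: np.ndarray, path) -> Path:
    """Write a [0, 1] image as 8-bit grayscale PNG.

    Quantisation is round(value * 255) half-away-from-zero, so a read-back
    differs from the original by at most 0.5/255.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    quantised = np.floor(image * 255.0 + 0.5).astype(np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(quantised, mode="L").save(path)
    return path


def _cool_colormap(values: np.ndarray) -> np.ndarray:
    """Cyan-to-magenta ('Cool') linear colormap: t -> (t, 1-t, 1)."""
    t = np.clip(values, 0.0, 1.0)
    return np.stack([t, 1.0 - t, np.ones_like(t)], axis=-1)


def export_reader_image(
    selection: SliceSelection,
    stack: np.ndarray,
    path,
    magnify: int = 4,
    blind: bool = False,
    key_file=None,
    case_id: str | None = None,
    method_id: str | None = None,
) -> Path:
    """Emit the 3 reader slices side by side as a 'Cool'-colormapped PNG.

    The full intensity range is used as window/level.  With ``blind=True``
    the file is named by a random token and the (token, case, method) key is
    appended to ``key_file`` so the reading can be un-blinded later.
    """
    stack = normalize_case(np.asarray(stack, dtype=np.float64))
    panels = [np.kron(stack[z], np.ones((magnify, magnify))) for z in selection.reader_indices]
    montage = np.concatenate(panels, axis=1)
    rgb = np.floor(_cool_colormap(montage) * 255.0 + 0.5).astype(np.uint8)
    path = Path(path)
    if blind:
        token = secrets.token_hex(8)
        path = path.parent / f"{token}.png"
        key_file = Path(key_file) if key_file else path.parent / "blinding_key.csv"
        header = not key_file.exists()
        with open(key_file, "a") as fh:
            if header:
                fh.write("token,case_id,method_id\n")
            fh.write(f"{token},{case_id or selection.case_id},{method_id or ''}\n")
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(rgb, mode="RGB").save(path)
    return path
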