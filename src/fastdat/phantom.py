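"""Synthetic striatal SPECT phantom: paired short/long acquisitions with known pattern labels.

Digital stand-in for a clinical 123I-ioflupane cohort.  Each case is a 3-D
activity map holding an elliptical "brain" of diffuse background uptake plus
two comma-shaped striata whose intensity layout realises one of four canonical
visual patterns per hemisphere:

    1 = burst striatum   (whole striatum down at background level)
    2 = egg shape        (putamen lost, caudate preserved)
    3 = eagle wing       (posterior putamen reduced)
    4 = normal           (full comma-shaped caudate + putamen)

Acquisitions are modelled in image domain: the activity is blurred by an
isotropic in-plane Gaussian collimator PSF, scaled to a fixed expected count
total per slice per cycle, and Poisson-sampled independently per cycle.  The
short ("5-min") image is cycle 1 alone; the long ("25-min") reference is the
pixel-wise sum of all five cycles, so noise scales with acquisition time
exactly as count statistics dictate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "PATTERN_NAMES",
    "PhantomSpec",
    "PhantomCase",
    "AcquisitionPair",
    "ScoreTable",
    "make_activity_volume",
    "simulate_cycle",
    "simulate_acquisition_pair",
    "generate_cohort",
    "truth_scores",
    "simulate_reader",
    "write_cohort",
]

#: Four-point visual scale for per-hemisphere striatal uptake.
PATTERN_NAMES = {1: "burst striatum", 2: "egg shape", 3: "eagle wing", 4: "normal"}

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _check_pattern(value: int) -> int:
    if value not in PATTERN_NAMES:
        raise ValueError(
            f"invalid striatal pattern {value!r}: must be one of "
            "1 (burst striatum), 2 (egg shape), 3 (eagle wing), 4 (normal)"
        )
    return int(value)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, activity and counting statistics of the digital phantom.

    Activities are relative concentrations (background = 1 by convention);
    only their ratios matter because each slice is rescaled to
    ``counts_per_cycle`` expected counts before Poisson sampling.
    """

    grid_xy: tuple[int, int] = (128, 128)
    n_slices: int = 15
    pixel_size: float = 3.29  # mm
    background_activity: float = 1.0
    caudate_activity: float = 8.0
    anterior_putamen_activity: float = 8.0
    posterior_putamen_activity: float = 8.0
    psf_fwhm: float = 10.0  # mm, collimator resolution class
    counts_per_cycle: float = 300_000.0  # expected counts per slice per cycle
    n_cycles: int = 5
    # Per-case smooth multiplicative inhomogeneity of the background uptake
    # (relative sd, correlation length in px): emulates anatomical texture
    # that distinguishes learned restoration from plain smoothing.
    background_texture: float = 0.4
    texture_corr_px: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "background_activity",
            "caudate_activity",
            "anterior_putamen_activity",
            "posterior_putamen_activity",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.psf_fwhm <= 0:
            raise ValueError("psf_fwhm must be > 0")
        if self.counts_per_cycle <= 0:
            raise ValueError("counts_per_cycle must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.n_slices < 5:
            raise ValueError("n_slices must be >= 5 (striatum spans 5 slices)")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm * FWHM_TO_SIGMA / self.pixel_size


@dataclass
class PhantomCase:
    """One synthetic patient study: activity volume + ground-truth patterns."""

    case_id: str
    activity: np.ndarray  # (n_slices, rows, cols), float, >= 0
    left_pattern: int
    right_pattern: int
    spec: PhantomSpec
    left_mask: np.ndarray = field(repr=False, default=None)  # 3-D bool striatal mask
    right_mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.left_pattern = _check_pattern(self.left_pattern)
        self.right_pattern = _check_pattern(self.right_pattern)
        expected = (self.spec.n_slices, *self.spec.grid_xy)
        if self.activity.shape != expected:
            raise ValueError(f"activity shape {self.activity.shape} != spec {expected}")
        if not np.all(np.isfinite(self.activity)) or np.any(self.activity < 0):
            raise ValueError("activity must be finite and non-negative")


@dataclass
class AcquisitionPair:
    """Registered short (1-cycle) and long (n-cycle-sum) stacks for one case."""

    case_id: str
    short_stack: np.ndarray
    long_stack: np.ndarray
    noiseless_stack: np.ndarray  # expected single-cycle image x n_cycles

    def __post_init__(self) -> None:
        if not (self.short_stack.shape == self.long_stack.shape == self.noiseless_stack.shape):
            raise ValueError("short, long and noiseless stacks must share dimensions")
        for name in ("short_stack", "long_stack", "noiseless_stack"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} contains negative values")


class ScoreTable:
    """Ordinal pattern scores indexed by (reader, case, hemisphere, method, session)."""

    COLUMNS = ["reader_id", "case_id", "hemisphere", "method_id", "session", "score"]
    KEY = ["reader_id", "case_id", "hemisphere", "method_id", "session"]

    def __init__(self, records) -> None:
        df = pd.DataFrame(records, columns=self.COLUMNS) if not isinstance(records, pd.DataFrame) else records[self.COLUMNS].copy()
        if len(df):
            if not df["score"].isin([1, 2, 3, 4]).all():
                raise ValueError("scores must be integers in 1..4")
            if not df["hemisphere"].isin(["L", "R"]).all():
                raise ValueError("hemisphere must be 'L' or 'R'")
            if not df["session"].isin([1, 2]).all():
                raise ValueError("session must be 1 or 2")
            if df.duplicated(self.KEY).any():
                raise ValueError("duplicate (reader, case, hemisphere, method, session) record")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        a = self.df.sort_values(self.KEY).reset_index(drop=True)
        b = other.df.sort_values(self.KEY).reset_index(drop=True)
        return a.equals(b)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

# Striatal shape parameters, in pixels on the 128 x 128 / 3.29 mm grid and
# scaled for other grids.  These are conventional display-anatomy choices
# (comma shape inside the central 64 x 64 crop), not fitted to any patient.
_AXIAL_TAPER = np.array([0.6, 0.9, 1.0, 0.9, 0.6])


def _hemisphere_masks(spec: PhantomSpec, dx: int = 0, dy: int = 0):
    """2-D sub-region masks (caudate, anterior/posterior putamen) for the
    right-of-midline hemisphere, optionally jittered by (dx, dy) pixels.

    Returned masks are disjoint.  The left hemisphere is the mirror image
    about the mid-sagittal column.
    """
    rows, cols = spec.grid_xy
    scale = min(rows, cols) / 128.0
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    # x measured from the mid-sagittal plane (between cols/2-1 and cols/2)
    x = xx - (cols - 1) / 2.0 - dx
    y = yy - (rows - 1) / 2.0 - dy

    def ellipse(cx, cy, rx, ry, angle=0.0):
        ca, sa = np.cos(angle), np.sin(angle)
        u = (x - cx * scale) * ca + (y - cy * scale) * sa
        v = -(x - cx * scale) * sa + (y - cy * scale) * ca
        return (u / (rx * scale)) ** 2 + (v / (ry * scale)) ** 2 <= 1.0

    # caudate head: round blob, anterior (low y) and medial
    caudate = ellipse(8.0, -10.0, 4.0, 5.5)
    # putamen: elongated lens, lateral, slanting posteriorly; split into
    # anterior/posterior halves along its long axis
    ang = np.deg2rad(55.0)
    putamen = ellipse(15.0, 0.0, 4.0, 10.0, angle=-ang) & ~caudate
    # long-axis coordinate of the putamen ellipse decides ant/post half
    v_axis = -(x - 15.0 * scale) * np.sin(-ang) + (y - 0.0) * np.cos(-ang)
    ant_putamen = putamen & (v_axis <= 0)
    post_putamen = putamen & (v_axis > 0)
    right = x > 0
    return {
        "caudate": caudate & right,
        "anterior_putamen": ant_putamen & right,
        "posterior_putamen": post_putamen & right,
    }


def _brain_mask(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.grid_xy
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    return ((xx - cx) / (0.38 * cols)) ** 2 + ((yy - cy) / (0.44 * rows)) ** 2 <= 1.0


def _pattern_levels(spec: PhantomSpec, pattern: int) -> dict:
    """Sub-region activity excess over background for one visual pattern."""
    bg = spec.background_activity
    full = {
        "caudate": spec.caudate_activity - bg,
        "anterior_putamen": spec.anterior_putamen_activity - bg,
        "posterior_putamen": spec.posterior_putamen_activity - bg,
    }
    if pattern == 4:  # normal: full comma
        return full
    if pattern == 3:  # eagle wing: posterior putamen reduced to 50%
        return {**full, "posterior_putamen": 0.5 * full["posterior_putamen"]}
    if pattern == 2:  # egg shape: putamen at background, caudate preserved
        return {**full, "anterior_putamen": 0.0, "posterior_putamen": 0.0}
    return {k: 0.0 for k in full}  # burst striatum: all at background


def make_activity_volume(
    spec: PhantomSpec,
    left: int,
    right: int,
    seed: int,
    jitter: bool = True,
) -> PhantomCase:
    """Build one phantom case realising the requested pattern per hemisphere.

    Jitter (position <= 1 px, intensity <= 10%) is drawn from per-hemisphere
    random streams derived from ``seed``, so editing the left pattern never
    perturbs the right hemisphere.
    """
    left = _check_pattern(left)
    right = _check_pattern(right)
    nz = spec.n_slices
    brain = _brain_mask(spec)
    volume = np.zeros((nz, *spec.grid_xy), dtype=np.float64)
    volume[:] = spec.background_activity * brain
    if jitter and spec.background_texture > 0:
        # smooth per-case anatomical inhomogeneity of the diffuse uptake;
        # drawn from its own stream so it is independent of the patterns
        rng_tex = np.random.default_rng([int(seed) & 0x7FFFFFFF, 2])
        field = gaussian_filter(
            rng_tex.standard_normal((nz, *spec.grid_xy)),
            (1.0, spec.texture_corr_px, spec.texture_corr_px),
        )
        field /= field.std()
        factor = np.clip(1.0 + spec.background_texture * field, 0.2, None)
        volume *= factor

    z_center = nz // 2
    z_lo = z_center - 2
    masks3d = {}
    for hemi, pattern, stream in (("R", right, 0), ("L", left, 1)):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, stream])
        if jitter:
            dx = int(rng.integers(-1, 2))
            dy = int(rng.integers(-1, 2))
            gain = 1.0 + rng.uniform(-0.1, 0.1)
        else:
            dx = dy = 0
            gain = 1.0
        masks = _hemisphere_masks(spec, dx=dx, dy=dy)
        if hemi == "L":
            masks = {k: m[:, ::-1] for k, m in masks.items()}
        levels = _pattern_levels(spec, pattern)
        union2d = np.zeros(spec.grid_xy, dtype=bool)
        for name, mask in masks.items():
            mask = mask & brain
            union2d |= mask
            for k, w in enumerate(_AXIAL_TAPER):
                volume[z_lo + k][mask] += gain * w * levels[name]
        m3 = np.zeros((nz, *spec.grid_xy), dtype=bool)
        m3[z_lo : z_lo + 5] = union2d
        masks3d[hemi] = m3

    np.maximum(volume, 0.0, out=volume)
    return PhantomCase(
        case_id=f"case_{seed}",
        activity=volume,
        left_pattern=left,
        right_pattern=right,
        spec=spec,
        left_mask=masks3d["L"],
        right_mask=masks3d["R"],
    )


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------


def expected_cycle_image(case: PhantomCase) -> np.ndarray:
    """Noise-free expected counts for a single cycle.

    Activity is blurred slice-by-slice with the in-plane Gaussian PSF, then
    each slice is scaled so its expected total equals ``counts_per_cycle``.
    """
    if not np.all(np.isfinite(case.activity)):
        raise ValueError("activity must be finite")
    sigma = case.spec.psf_sigma_px
    blurred = np.stack([gaussian_filter(sl, sigma, mode="constant") for sl in case.activity])
    expected = np.empty_like(blurred)
    for z, sl in enumerate(blurred):
        total = sl.sum()
        expected[z] = sl * (case.spec.counts_per_cycle / total) if total > 0 else 0.0
    return expected


def simulate_cycle(case: PhantomCase, seed: int) -> np.ndarray:
    """Poisson-sample one acquisition cycle; deterministic given ``seed``."""
    expected = expected_cycle_image(case)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed) & 0x7FFFFFFF))
    return rng.poisson(expected).astype(np.float64)


def simulate_acquisition_pair(case: PhantomCase, seed: int) -> AcquisitionPair:
    """Simulate the paired short (cycle 1) and long (sum of n cycles) study."""
    expected = expected_cycle_image(case)
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    children = ss.spawn(case.spec.n_cycles)
    cycles = [np.random.default_rng(c).poisson(expected).astype(np.float64) for c in children]
    short = cycles[0]
    long_ = np.sum(cycles, axis=0)
    return AcquisitionPair(
        case_id=case.case_id,
        short_stack=short,
        long_stack=long_,
        noiseless_stack=expected * case.spec.n_cycles,
    )


# ---------------------------------------------------------------------------
# Cohorts and simulated readers
# ---------------------------------------------------------------------------


def generate_cohort(
    n_cases: int,
    pattern_prevalence=(0.17, 0.29, 0.28, 0.26),
    spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[tuple[PhantomCase, AcquisitionPair]]:
    """Generate a reproducible cohort of paired acquisitions.

    ``pattern_prevalence`` gives P(score = 1..4) per hemisphere, sampled
    independently for left and right.  Per-case seeds are derived from the
    master seed by case index, so growing the cohort never reshuffles
    earlier cases.
    """
    if n_cases < 0:
        raise ValueError("n_cases must be >= 0")
    prevalence = np.asarray(pattern_prevalence, dtype=float)
    if prevalence.shape != (4,) or np.any(prevalence < 0):
        raise ValueError("pattern_prevalence must be 4 non-negative probabilities")
    if abs(prevalence.sum() - 1.0) > 1e-9:
        raise ValueError(f"pattern_prevalence must sum to 1, got {prevalence.sum()!r}")
    spec = spec or PhantomSpec()

    cohort = []
    master = int(seed) & 0x7FFFFFFF
    for i in range(n_cases):
        ss = np.random.SeedSequence(master, spawn_key=(i,))
        case_seed, acq_seed = (int(s) for s in ss.generate_state(2) % (2**31))
        rng = np.random.default_rng(ss.spawn(1)[0])
        left, right = (int(rng.choice(4, p=prevalence)) + 1 for _ in range(2))
        case = make_activity_volume(spec, left=left, right=right, seed=case_seed)
        case.case_id = f"case_{i:04d}"
        pair = simulate_acquisition_pair(case, seed=acq_seed)
        pair.case_id = case.case_id
        cohort.append((case, pair))
    return cohort


def truth_scores(cases, method_id: str = "truth") -> ScoreTable:
    """Ground-truth pattern labels as a ScoreTable (reader 'truth', session 1)."""
    records = []
    for case in cases:
        records.append(("truth", case.case_id, "L", method_id, 1, case.left_pattern))
        records.append(("truth", case.case_id, "R", method_id, 1, case.right_pattern))
    return ScoreTable(records)


def simulate_reader(
    truth: ScoreTable,
    confusion: np.ndarray,
    seed: int,
    reader_id: str = "sim_reader",
    method_id: str | None = None,
    session: int = 1,
) -> ScoreTable:
    """Replace each true score s by a draw from row s of a 4x4 confusion matrix."""
    confusion = np.asarray(confusion, dtype=float)
    if confusion.shape != (4, 4) or np.any(confusion < 0):
        raise ValueError("confusion must be a non-negative 4x4 matrix")
    if not np.allclose(confusion.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("confusion rows must each sum to 1")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    records = []
    for rec in truth.df.itertuples(index=False):
        drawn = int(rng.choice(4, p=confusion[rec.score - 1])) + 1
        records.append(
            (reader_id, rec.case_id, rec.hemisphere,
             method_id if method_id is not None else rec.method_id, session, drawn)
        )
    return ScoreTable(records)


def write_cohort(cohort, out_dir, seed: int | None = None) -> Path:
    """Write per-case 8-bit PNG slice stacks plus a CSV manifest.

    Layout: ``<case>/short/slice_###.png`` and ``<case>/long/slice_###.png``;
    manifest columns: case_id, hemisphere, truth_score, seed.
    """
    from .preprocess import export_png8, normalize_case

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case, pair in cohort:
        for kind, stack in (("short", pair.short_stack), ("long", pair.long_stack)):
            d = out_dir / case.case_id / kind
            d.mkdir(parents=True, exist_ok=True)
            norm = normalize_case(stack)
            for z in range(norm.shape[0]):
                export_png8(norm[z], d / f"slice_{z:03d}.png")
        for hemi, score in (("L", case.left_pattern), ("R", case.right_pattern)):
            rows.append({"case_id": case.case_id, "hemisphere": hemi,
                         "truth_score": score, "seed": seed})
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["case_id", "hemisphere", "truth_score", "seed"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest
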