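"""Digital phantoms, Rician magnitude noise, and rigid motion corruption.

Two geometries cover the pipeline: a tube grid standing in for a relaxometry
calibration phantom, and a short-axis ring (annular myocardium around a blood
pool) enabling AHA-segment statistics.  All generators are pure functions of
their arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bloch import PrepEfficiency, IDEAL, simulate_acquisition
from .sequence import SaturnProtocol, SignalSeries, TissueParams

#: In vivo myocardial relaxation times at 3 T reported for this sequence
#: family, used as convenient ring-phantom defaults.
DEFAULT_MYOCARDIUM = TissueParams(T1=1573.0, T2=33.2, T2star=25.3)
#: Ventricular blood at 3 T (long T1/T2, moderate T2*).
DEFAULT_BLOOD = TissueParams(T1=1900.0, T2=200.0, T2star=60.0)


@dataclass
class Phantom:
    """Labeled 2-D object with per-compartment tissue parameters.

    Label 0 is background; every nonzero label has an entry in
    ``compartments``.  ``meta`` records geometry (ring center, radii,
    RV-insertion angle) for downstream segmentation.
    """

    label_map: np.ndarray
    compartments: dict[int, TissueParams]
    pixel_size: float = 2.0  # mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(np.unique(self.label_map).tolist()) - {0}
        missing = labels - set(self.compartments)
        if missing:
            raise ValueError(f"labels without tissue parameters: {sorted(missing)}")


def make_tube_phantom(
    n_tubes: int = 9,
    T1_range: tuple[float, float] = (1200.0, 1700.0),
    T2_range: tuple[float, float] = (20.0, 70.0),
    T2star_range: tuple[float, float] = (5.0, 60.0),
    seed: int | None = None,
    shape: tuple[int, int] = (96, 96),
    pixel_size: float = 2.0,
) -> Phantom:
    """Circular tubes on a regular grid with log-uniformly sampled times.

    Default ranges cover the simulation sweep (T1 1200-1700 ms, T2 20-70 ms,
    T2* 5-60 ms).  Tubes never overlap by construction (grid placement); a
    tube count that does not fit the grid raises.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    n_cols = math.ceil(math.sqrt(n_tubes))
    n_rows = math.ceil(n_tubes / n_cols)
    dx, dy = nx / n_cols, ny / n_rows
    radius = 0.35 * min(dx, dy)
    if radius < 2.0:
        raise ValueError("too many tubes for the grid: tubes would overlap or vanish")

    def sample(lo, hi):
        if lo == hi:
            return float(lo)
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    yy, xx = np.mgrid[0:ny, 0:nx]
    labels = np.zeros(shape, int)
    compartments: dict[int, TissueParams] = {}
    for i in range(n_tubes):
        r, c = divmod(i, n_cols)
        cy, cx = (r + 0.5) * dy, (c + 0.5) * dx
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        if np.any(labels[disk] != 0):
            raise ValueError("tube placement overlaps an existing tube")
        labels[disk] = i + 1
        T1 = sample(*T1_range)
        T2 = min(sample(*T2_range), T1)
        compartments[i + 1] = TissueParams(T1=T1, T2=T2, T2star=sample(*T2star_range))

    return Phantom(labels, compartments, pixel_size, meta={"kind": "tubes"})


def make_ring_phantom(
    myocardium: TissueParams = DEFAULT_MYOCARDIUM,
    blood: TissueParams = DEFAULT_BLOOD,
    insertion_angle: float = 90.0,
    shape: tuple[int, int] = (96, 96),
    outer_radius: float = 30.0,
    inner_radius: float = 20.0,
    pixel_size: float = 2.0,
) -> Phantom:
    """Short-axis slice: annular myocardium (label 1) around blood (label 2).

    ``insertion_angle`` (degrees, image convention: 0 = +x, counterclockwise)
    marks the anterior RV insertion and is recorded for AHA segmentation.
    """
    if inner_radius >= outer_radius:
        raise ValueError("inner radius must be smaller than outer radius")
    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    labels = np.zeros(shape, int)
    labels[r2 <= outer_radius**2] = 1
    labels[r2 <= inner_radius**2] = 2
    return Phantom(
        labels,
        {1: myocardium, 2: blood},
        pixel_size,
        meta={
            "kind": "ring",
            "center": (cy, cx),
            "outer_radius": outer_radius,
            "inner_radius": inner_radius,
            "insertion_angle": float(insertion_angle),
        },
    )


def add_rician_noise(
    data: np.ndarray | SignalSeries,
    snr: float,
    reference_signal: float,
    seed: int | None = None,
):
    """Rician magnitude noise: |(S + n1) + i n2| with n ~ N(0, sigma^2).

    ``sigma = reference_signal / snr``; ``snr = inf`` returns an unchanged
    copy.  Accepts an array or a :class:`SignalSeries` (returns the same
    type).  Seed-reproducible.
    """
    if isinstance(data, SignalSeries):
        noisy = add_rician_noise(data.magnitude, snr, reference_signal, seed)
        return SignalSeries(
            contrast_index=data.contrast_index.copy(),
            TS=data.TS.copy(),
            T2p=data.T2p.copy(),
            TE=data.TE.copy(),
            magnitude=noisy,
        )
    arr = np.asarray(data, float)
    if math.isinf(snr):
        return arr.copy()
    if not snr > 0:
        raise ValueError("SNR must be positive or infinite")
    sigma = reference_signal / snr
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, arr.shape)
    n2 = rng.normal(0.0, sigma, arr.shape)
    return np.hypot(arr + n1, n2)


def rigid_source_coords(
    shape: tuple[int, int], dx: float, dy: float, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-mapping source coordinates of a rigid transform.

    The forward transform rotates the image content by ``theta`` degrees
    about the image center and then shifts it by (dx, dy) pixels
    (x = columns, y = rows).  Returns (rows, cols) arrays such that
    ``out = image[rows, cols]`` (interpolated) realizes the transform.
    """
    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    rows, cols = np.mgrid[0:ny, 0:nx].astype(float)
    pr = rows - dy - cy
    pc = cols - dx - cx
    t = math.radians(theta)
    src_r = cy + math.cos(t) * pr + math.sin(t) * pc
    src_c = cx - math.sin(t) * pr + math.cos(t) * pc
    return src_r, src_c


def apply_rigid(image: np.ndarray, dx: float, dy: float, theta: float) -> np.ndarray:
    """Rotate by ``theta`` degrees about the image center, then shift by
    (dx, dy) pixels (x = columns, y = rows); linear interpolation."""
    image = np.asarray(image, float)
    if dx == 0 and dy == 0 and theta == 0:
        return image.copy()
    src_r, src_c = rigid_source_coords(image.shape, dx, dy, theta)
    return ndimage.map_coordinates(
        image, [src_r, src_c], order=1, mode="constant", cval=0.0
    )


def apply_motion(
    image_stack: np.ndarray,
    transforms: list[tuple[float, float, float]] | None = None,
    max_shift: float = 5.0,
    max_rotation: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, list[tuple[float, float, float]]]:
    """Rigidly corrupt each image of a (ny, nx, n) stack.

    Either pass explicit per-image ``transforms`` (dx, dy, theta) or let them
    be drawn uniformly within ``max_shift`` px / ``max_rotation`` deg from
    ``seed``.  Returns the corrupted stack and the ground-truth transforms.
    Shifts that would push the object's bounding box out of frame raise.
    """
    stack = np.asarray(image_stack, float)
    if stack.ndim != 3:
        raise ValueError("image_stack must be (ny, nx, n)")
    ny, nx, n = stack.shape
    if transforms is None:
        rng = np.random.default_rng(seed)
        transforms = [
            (
                float(rng.uniform(-max_shift, max_shift)),
                float(rng.uniform(-max_shift, max_shift)),
                float(rng.uniform(-max_rotation, max_rotation)) if max_rotation else 0.0,
            )
            for _ in range(n)
        ]
    if len(transforms) != n:
        raise ValueError("need one transform per image")

    support = np.any(stack != 0, axis=2)
    if support.any():
        ys, xs = np.nonzero(support)
        margin_x = min(xs.min(), nx - 1 - xs.max())
        margin_y = min(ys.min(), ny - 1 - ys.max())
        for dx, dy, _ in transforms:
            if abs(dx) > margin_x or abs(dy) > margin_y:
                raise ValueError("shift would move the object out of frame")

    out = np.empty_like(stack)
    for i, (dx, dy, th) in enumerate(transforms):
        out[:, :, i] = apply_rigid(stack[:, :, i], dx, dy, th)
    return out, list(transforms)


def simulate_phantom_stack(
    phantom: Phantom,
    protocol: SaturnProtocol,
    eff: PrepEfficiency = IDEAL,
) -> tuple[np.ndarray, SignalSeries]:
    """Noise-free image stack: one Bloch run per compartment, broadcast to
    voxels (the signal depends only on the tissue parameters).

    Returns the (ny, nx, n_samples) stack and the coordinate template series
    (the compartment run of the first label, magnitudes included).
    """
    template: SignalSeries | None = None
    stack = np.zeros(phantom.label_map.shape + (protocol.n_samples,))
    for label, tissue in phantom.compartments.items():
        series = simulate_acquisition(protocol, tissue, eff)
        if template is None:
            template = series
        stack[phantom.label_map == label] = series.magnitude
    if template is None:
        raise ValueError("phantom has no labeled compartments")
    return stack, template


def generate_dataset(
    phantom: Phantom,
    protocol: SaturnProtocol,
    snr: float = math.inf,
    seed: int | None = None,
    eff: PrepEfficiency = IDEAL,
) -> dict:
    """Synthesize a full acquisition over a phantom.

    Returns a dict with the (possibly noisy) image ``stack``, the per-volume
    ``coordinates`` (TS, T2p, TE), ground-truth parameter maps, and the noise
    sigma actually applied.  Noise sigma is referenced to the unprepared
    contrast's first-echo signal of the first compartment.
    """
    stack, template = simulate_phantom_stack(phantom, protocol, eff)
    unprepared = np.isinf(template.TS) & (template.T2p == 0)
    reference = float(template.magnitude[unprepared][0])
    sigma = 0.0
    if not math.isinf(snr):
        sigma = reference / snr
        stack = add_rician_noise(stack, snr, reference, seed)

    shape = phantom.label_map.shape
    truth = {name: np.full(shape, np.nan) for name in ("T1", "T2", "T2star", "M0")}
    for label, tissue in phantom.compartments.items():
        sel = phantom.label_map == label
        truth["T1"][sel] = tissue.T1
        truth["T2"][sel] = tissue.T2
        truth["T2star"][sel] = tissue.T2star
        truth["M0"][sel] = tissue.M0

    return {
        "stack": stack,
        "contrast_index": template.contrast_index,
        "TS": template.TS,
        "T2p": template.T2p,
        "TE": template.TE,
        "truth": truth,
        "noise_sd": sigma,
        "mask": phantom.label_map > 0,
    }
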