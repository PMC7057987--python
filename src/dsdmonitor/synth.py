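"""Synthetic capsule-endoscopy frames and frame streams.

No public capsule-endoscopy corpus exists for the gastric-retention task, so
this module renders two procedurally generated mucosa texture classes that
stand in for the real image categories:

* ``STOMACH_BULB`` — smooth low-frequency mucosa with broad fold-like ridges,
  emulating gastric body/antrum and duodenal-bulb views;
* ``DSD`` — descending-duodenum texture dominated by a dense field of small
  bright villi spots, i.e. markedly more high-spatial-frequency energy.

The classes are deliberately separable (a linear probe on mean intensity plus
band energy exceeds 90 % accuracy at the defaults) so that the classifier,
evaluation and monitoring modules are all testable end to end.  The six
interference kinds (poor focus, laterality/partialness, foam, bile fluid,
fold, debris) and stagnation runs (near-duplicate frames while the capsule is
stationary) reproduce the behavioural confounders of real recordings, not
their appearance.

All randomness flows through ``numpy.random.Generator`` objects derived from
a single stream seed, so equal seeds give byte-identical datasets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "TextureClass",
    "STOMACH_BULB",
    "DSD",
    "InterferenceKind",
    "InterferenceEvent",
    "StreamSpec",
    "FrameStream",
    "generate_frame",
    "generate_stream",
    "generate_labeled_frames",
    "DEFAULT_SHAPE",
    "FAST_SHAPE",
]

#: Native capsule resolution (height, width).
DEFAULT_SHAPE = (240, 256)
#: Reduced resolution for fast desk-scale experiments.
FAST_SHAPE = (64, 64)


@dataclass(frozen=True)
class TextureClass:
    """Parameters of one procedural mucosa texture.

    ``base_intensity`` is the mean grey level on the 0–255 scale,
    ``spatial_frequency`` the dominant number of texture cycles across the
    frame, ``villi_density`` the per-pixel rate of bright villi spots
    (DSD-like) and ``ridge_amplitude`` the grey-level amplitude of smooth
    fold ridges (stomach-like).
    """

    name: str
    base_intensity: float = 140.0
    spatial_frequency: float = 3.0
    villi_density: float = 0.0
    ridge_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.base_intensity < 255.0:
            raise ValueError("base_intensity must lie strictly inside (0, 255)")
        if self.spatial_frequency <= 0:
            raise ValueError("spatial_frequency must be positive")
        if self.villi_density < 0 or self.ridge_amplitude < 0:
            raise ValueError("texture amplitudes must be nonnegative")


STOMACH_BULB = TextureClass(
    name="stomach_bulb",
    base_intensity=150.0,
    spatial_frequency=2.5,
    ridge_amplitude=28.0,
)

DSD = TextureClass(
    name="dsd",
    base_intensity=120.0,
    spatial_frequency=14.0,
    villi_density=0.02,
)


class InterferenceKind(enum.Enum):
    """Image confounders emulated behaviourally."""

    POOR_FOCUS = "poor_focus"
    LATERALITY = "laterality"
    FOAM = "foam"
    BILE = "bile"
    FOLD = "fold"
    DEBRIS = "debris"


@dataclass(frozen=True)
class InterferenceEvent:
    """An interference episode covering ``duration`` consecutive frames."""

    kind: InterferenceKind
    start: int
    duration: int

    def __post_init__(self) -> None:
        if not isinstance(self.kind, InterferenceKind):
            raise ValueError(f"unknown interference kind: {self.kind!r}")
        if self.start < 0:
            raise ValueError("event start must be nonnegative")
        if self.duration < 1:
            raise ValueError("event duration must be >= 1")

    def covers(self, index: int) -> bool:
        return self.start <= index < self.start + self.duration


@dataclass(frozen=True)
class StreamSpec:
    """Recipe for one reproducible synthetic frame stream."""

    total_frames: int
    entry_index: int
    interval_ms: float = 500.0
    events: tuple[InterferenceEvent, ...] = ()
    stagnation: tuple[tuple[int, int], ...] = ()  # (start, duration) runs
    seed: int = 0
    shape: tuple[int, int] = DEFAULT_SHAPE
    stagnation_noise: float = 2.0  # additive grey-level sigma inside a run

    def __post_init__(self) -> None:
        if self.total_frames < 1:
            raise ValueError("total_frames must be >= 1")
        if not 0 < self.entry_index < self.total_frames:
            raise ValueError("entry_index must satisfy 0 < entry < total_frames")
        if self.interval_ms <= 0:
            raise ValueError("interval_ms must be positive")
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(
            self, "stagnation", tuple((int(s), int(d)) for s, d in self.stagnation)
        )
        for s, d in self.stagnation:
            if s < 0 or d < 1:
                raise ValueError("stagnation runs need start >= 0 and duration >= 1")

    # -- flat-file round trip ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "total_frames": self.total_frames,
            "entry_index": self.entry_index,
            "interval_ms": self.interval_ms,
            "events": [
                {"kind": e.kind.value, "start": e.start, "duration": e.duration}
                for e in self.events
            ],
            "stagnation": [list(run) for run in self.stagnation],
            "seed": self.seed,
            "shape": list(self.shape),
            "stagnation_noise": self.stagnation_noise,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StreamSpec":
        return cls(
            total_frames=int(d["total_frames"]),
            entry_index=int(d["entry_index"]),
            interval_ms=float(d.get("interval_ms", 500.0)),
            events=tuple(
                InterferenceEvent(
                    InterferenceKind(e["kind"]), int(e["start"]), int(e["duration"])
                )
                for e in d.get("events", ())
            ),
            stagnation=tuple(tuple(run) for run in d.get("stagnation", ())),
            seed=int(d.get("seed", 0)),
            shape=tuple(d.get("shape", DEFAULT_SHAPE)),
            stagnation_noise=float(d.get("stagnation_noise", 2.0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StreamSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class FrameStream:
    """Ordered frames at a fixed interval with ground truth attached.

    ``frames`` is ``(n, H, W)`` uint8; ``labels`` is ``(n,)`` int8 with
    1 = DSD, 0 = stomach/duodenal bulb; ``entry_index`` is the first
    true-DSD frame.
    """

    frames: np.ndarray
    labels: np.ndarray
    entry_index: int
    interval_ms: float = 500.0
    spec: StreamSpec | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, H, W)")
        if len(self.frames) != len(self.labels):
            raise ValueError("frames and labels must have equal length")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def timestamps_ms(self) -> np.ndarray:
        """Stream time of frame i, with frame 0 at time 0."""
        return np.arange(len(self), dtype=float) * self.interval_ms


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------


def _base_texture(cls: TextureClass, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    # Low-frequency mucosa base: band-passed white noise at the dominant scale.
    sigma = max(min(h, w) / (2.0 * cls.spatial_frequency), 0.6)
    noise = rng.standard_normal((h, w))
    base = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = base.std()
    if sd > 0:
        base = base / sd
    img = cls.base_intensity + 12.0 * base

    if cls.ridge_amplitude > 0:
        # Broad sinusoidal folds with a slowly wandering phase.
        theta = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        coord = (xx * np.cos(theta) + yy * np.sin(theta)) / max(h, w)
        phase = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=sigma)
        img += cls.ridge_amplitude * np.sin(
            2 * np.pi * cls.spatial_frequency * coord + 2.5 * phase + rng.uniform(0, 2 * np.pi)
        )

    if cls.villi_density > 0:
        # Villi: sparse bright impulses smoothed to ~2 px spots.
        spots = (rng.random((h, w)) < cls.villi_density).astype(float)
        spots = ndimage.gaussian_filter(spots, sigma=1.0)
        peak = spots.max()
        if peak > 0:
            img += 90.0 * spots / peak
    return img


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _apply_interference(
    img: np.ndarray, kinds, rng: np.random.Generator
) -> np.ndarray:
    h, w = img.shape
    kinds = set(kinds)
    for kind in kinds:
        if not isinstance(kind, InterferenceKind):
            raise ValueError(f"unknown interference kind: {kind!r}")
    # Overlays first, optics (blur) last, mimicking how the artefacts compose.
    if InterferenceKind.FOLD in kinds:
        theta = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        coord = (xx * np.cos(theta) + yy * np.sin(theta)) / max(h, w)
        img = img + 45.0 * np.sin(2 * np.pi * 2.0 * coord + rng.uniform(0, 2 * np.pi))
    if InterferenceKind.FOAM in kinds:
        for _ in range(rng.integers(4, 9)):
            mask = _disk_mask(
                img.shape,
                rng.uniform(0, h),
                rng.uniform(0, w),
                rng.uniform(0.03, 0.10) * min(h, w),
            )
            img = np.where(mask, 235.0 + rng.normal(0, 4), img)
    if InterferenceKind.DEBRIS in kinds:
        for _ in range(rng.integers(2, 6)):
            mask = _disk_mask(
                img.shape,
                rng.uniform(0, h),
                rng.uniform(0, w),
                rng.uniform(0.02, 0.06) * min(h, w),
            )
            img = np.where(mask, 25.0 + rng.normal(0, 4), img)
    if InterferenceKind.BILE in kinds:
        # Global fluid tint: washed-out contrast plus a brightness lift.
        img = 0.75 * img + 55.0
    if InterferenceKind.LATERALITY in kinds:
        # Partial/lateral wall view: one side of the frame collapses to a
        # dark, nearly featureless wall.
        side = rng.integers(0, 4)
        frac = rng.uniform(0.25, 0.45)
        wall = 60.0 + ndimage.gaussian_filter(rng.standard_normal(img.shape), 6.0) * 5.0
        m = np.zeros(img.shape, dtype=bool)
        if side == 0:
            m[: int(h * frac), :] = True
        elif side == 1:
            m[h - int(h * frac) :, :] = True
        elif side == 2:
            m[:, : int(w * frac)] = True
        else:
            m[:, w - int(w * frac) :] = True
        img = np.where(m, wall, img)
    if InterferenceKind.POOR_FOCUS in kinds:
        img = ndimage.gaussian_filter(img, sigma=0.04 * min(h, w))
    return img


def generate_frame(
    cls: TextureClass,
    kinds=(),
    rng: np.random.Generator | int | None = None,
    shape: tuple[int, int] = DEFAULT_SHAPE,
) -> np.ndarray:
    """Render one 8-bit frame of the given texture class.

    Parameters
    ----------
    cls : TextureClass
        Texture parameters for the frame.
    kinds : iterable of InterferenceKind
        Interference factors active on this frame.
    rng : numpy Generator or int seed
        Source of randomness; equal seeds give byte-identical frames.
    shape : (height, width)

    Returns
    -------
    ndarray of uint8, shape ``shape``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    img = _base_texture(cls, shape, rng)
    img = _apply_interference(img, kinds, rng)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_stream(spec: StreamSpec) -> FrameStream:
    """Render a full labelled stream from its spec.

    Frames before ``entry_index`` are stomach/duodenal-bulb texture, frames at
    and after it are DSD texture.  Stagnation runs freeze the texture at the
    run's first frame and add small pixel noise, so consecutive frames are
    near-duplicates even across the entry boundary — the mechanism by which
    stagnation advances or delays the marked entry time in real recordings.
    """
    n, entry = spec.total_frames, spec.entry_index
    labels = (np.arange(n) >= entry).astype(np.int8)

    # Independent per-frame child seeds: frame i is reproducible on its own.
    children = np.random.SeedSequence(spec.seed).spawn(n + 1)
    stag_rng = np.random.default_rng(children[n])

    in_run = np.full(n, -1, dtype=int)  # index of the run's base frame
    for start, dur in spec.stagnation:
        stop = min(start + dur, n)
        for i in range(max(start, 0), stop):
            if in_run[i] == -1:
                in_run[i] = max(start, 0)

    frames = np.empty((n, *spec.shape), dtype=np.uint8)
    rendered: dict[int, np.ndarray] = {}
    for i in range(n):
        base_idx = in_run[i] if in_run[i] != -1 else i
        if base_idx not in rendered:
            kinds = tuple(e.kind for e in spec.events if e.covers(base_idx))
            cls = DSD if labels[base_idx] else STOMACH_BULB
            rendered[base_idx] = generate_frame(
                cls, kinds, np.random.default_rng(children[base_idx]), spec.shape
            )
        img = rendered[base_idx]
        if base_idx != i:  # near-duplicate within a stagnation run
            noisy = img.astype(float) + stag_rng.normal(0, spec.stagnation_noise, img.shape)
            img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
        frames[i] = img

    return FrameStream(
        frames=frames,
        labels=labels,
        entry_index=entry,
        interval_ms=spec.interval_ms,
        spec=spec,
    )


def stream_with_new_seed(spec: StreamSpec, seed: int) -> StreamSpec:
    """Convenience: same stream recipe, different random draw."""
    return replace(spec, seed=seed)


def generate_labeled_frames(
    n: int, shape: tuple[int, int] = FAST_SHAPE, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced, interleaved two-class training set (frames, labels).

    Each frame gets its own child seed, so subsets are reproducible
    independently of ``n``.
    """
    if n < 2:
        raise ValueError("need at least 2 frames")
    children = np.random.SeedSequence(seed).spawn(n)
    frames = np.empty((n, *shape), dtype=np.uint8)
    labels = (np.arange(n) % 2).astype(np.int8)
    for i in range(n):
        cls = DSD if labels[i] else STOMACH_BULB
        frames[i] = generate_frame(cls, rng=np.random.default_rng(children[i]), shape=shape)
    return frames, labels
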