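"""Synthetic sonomyographic data generator.

No public dataset of residual-limb ultrasound accompanies this analysis, so
the pipeline is exercised on a phenomenological forward model that
reproduces the statistical structure the method depends on, without
attempting acoustic or biomechanical realism:

* **Grasp-specific echotexture.**  Each grasp (rest, tripod via
  wrist-flexion, point via wrist-extension) gets a template built from
  horizontal echogenic bands — a cartoon of muscle bellies and fascial
  planes in a transverse forearm image.  Contraction is modeled as
  displacement and thickening of the deep bands; ``grasp_separation``
  scales how far the three templates sit apart.
* **Arm-position perturbation.**  Moving the arm through the workspace
  shifts and tilts the transducer relative to the tissue.  This is modeled
  as a small affine warp (translation + shear) of the template whose
  magnitude follows a smooth function of a scalar ``arm_state`` in [0, 1]
  parameterizing position along the workspace path, scaled by
  ``position_effect`` and the load condition.
* **Load-condition variability.**  Heavier distal loading (load A) couples
  arm motion into the socket more strongly than the lighter surrogate
  (load B); load A therefore multiplies the warp/jitter noise by a larger
  factor.
* **Speckle.**  Frames are corrupted by multiplicative Rayleigh speckle,
  normalized to unit mean and spatially smoothed to a ~1-pixel grain
  (speckle cell size is set by the imaging point-spread function).  The
  *chance-baseline* images are different by construction: pure i.i.d.
  Rayleigh(sigma) intensity fields, matching how the chance similarity
  floor is defined.
* **Dynamic contrast.**  Classifiers trained on the dynamic strategies
  both classify better and separate same- from different-grasp imagery
  better; the model captures this with a single gain (``dynamic_contrast``)
  on the grasp deformation while the arm is in motion — active movement is
  taken to elicit stronger, more distinct contractions.

Acquisitions run at ~11.5 frames/s, so a 5-s recording holds 57 or 58
frames depending on the (unmodeled) phase of the grabber clock; the frame
count is drawn as ``floor(duration * rate + U[0,1))``.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .frames import FRAME_SHAPE, Frame, quantize8

# ---------------------------------------------------------------------------
# Labels and conditions
# ---------------------------------------------------------------------------


class GraspLabel(enum.IntEnum):
    """The three commanded grasps, in canonical class order."""

    REST = 0
    TRIPOD = 1
    POINT = 2


#: Fixed mapping from the muscle contraction performed to the grasp commanded.
CONTRACTION_TO_GRASP: dict[str, GraspLabel] = {
    "relaxed": GraspLabel.REST,
    "wrist_flexion": GraspLabel.TRIPOD,
    "wrist_extension": GraspLabel.POINT,
}

GRASP_TO_CONTRACTION: dict[GraspLabel, str] = {
    v: k for k, v in CONTRACTION_TO_GRASP.items()
}


class Mode(enum.Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"
    CONTINUOUS_DYNAMIC = "continuous_dynamic"


#: The seven static arm positions, ordered along the workspace path.
STATIC_POSITIONS: tuple[str, ...] = (
    "Ipsilateral Countertop",
    "Midline Countertop",
    "Contralateral Countertop",
    "Ipsilateral Bookshelf",
    "Midline Bookshelf",
    "Contralateral Bookshelf",
    "Drinking Glass",
)

#: The four dynamic movement patterns.
DYNAMIC_PATTERNS: tuple[str, ...] = (
    "Countertop Wipe",
    "Lawnmower",
    "Sliding Glass Door",
    "Drawing Blinds",
)

#: Patterns whose direction is reversed when concatenated into the 20-s
#: continuous-dynamic sweep, so the combined path is continuous.
REVERSED_IN_CONTINUOUS: frozenset[str] = frozenset(
    {"Countertop Wipe", "Sliding Glass Door"}
)

#: Canonical arm_state for each static position: equally spaced in [0, 1].
POSITION_ARM_STATE: dict[str, float] = {
    name: i / (len(STATIC_POSITIONS) - 1) for i, name in enumerate(STATIC_POSITIONS)
}

#: Each dynamic pattern sweeps one quarter of the [0, 1] workspace path.
PATTERN_ARM_SPAN: dict[str, tuple[float, float]] = {
    name: (i / 4, (i + 1) / 4) for i, name in enumerate(DYNAMIC_PATTERNS)
}


@dataclass(frozen=True)
class ArmCondition:
    """How the arm moves (or does not) during an acquisition."""

    mode: Mode
    static_position: str | None = None
    pattern: str | None = None

    def __post_init__(self) -> None:
        if self.mode is Mode.STATIC:
            if self.static_position not in STATIC_POSITIONS:
                raise ValueError(
                    f"STATIC requires a static_position from {STATIC_POSITIONS}"
                )
            if self.pattern is not None:
                raise ValueError("STATIC takes no movement pattern")
        elif self.mode is Mode.DYNAMIC:
            if self.pattern not in DYNAMIC_PATTERNS:
                raise ValueError(f"DYNAMIC requires a pattern from {DYNAMIC_PATTERNS}")
            if self.static_position is not None:
                raise ValueError("DYNAMIC takes no static_position")
        else:
            if self.static_position is not None or self.pattern is not None:
                raise ValueError("CONTINUOUS_DYNAMIC takes neither position nor pattern")

    @property
    def duration_s(self) -> float:
        return 20.0 if self.mode is Mode.CONTINUOUS_DYNAMIC else 5.0

    @property
    def key(self) -> str:
        """Condition label used in tables and manifests."""
        if self.mode is Mode.STATIC:
            return self.static_position  # type: ignore[return-value]
        if self.mode is Mode.DYNAMIC:
            return self.pattern  # type: ignore[return-value]
        return "Continuous Dynamic"


class Load(enum.Enum):
    LOAD_A = "A"
    LOAD_B = "B"


@dataclass(frozen=True)
class LoadCondition:
    """Socket loading during training; A (full distal hardware) couples arm
    motion into the image more strongly than B (light surrogate)."""

    value: Load
    perturbation_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.perturbation_scale < 0:
            raise ValueError("perturbation_scale must be nonnegative")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the forward model, with study-condition defaults.

    ``speckle_sigma`` is the Rayleigh scale of the multiplicative speckle
    (and of the chance-baseline intensity fields) on the [0, 1] intensity
    scale.  ``load_scales`` are the perturbation multipliers for loads A
    and B; A ≥ B.  ``position_effect`` is the maximum transducer-shift
    analog in pixels across the workspace.
    """

    seed: int = 0
    frame_rate_hz: float = 11.5
    grasp_separation: float = 1.0
    position_effect: float = 3.0
    speckle_sigma: float = 0.101
    speckle_grain_px: float = 1.0
    load_scales: tuple[float, float] = (1.5, 1.0)  # (LOAD_A, LOAD_B)
    dynamic_contrast: float = 1.25
    repeat_jitter: float = 0.35
    frame_jitter: float = 0.2

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be nonnegative")
        if self.load_scales[0] < self.load_scales[1]:
            raise ValueError("load A perturbation scale must be >= load B")

    def load_condition(self, load: Load) -> LoadCondition:
        scale = self.load_scales[0] if load is Load.LOAD_A else self.load_scales[1]
        return LoadCondition(load, scale)


@dataclass(frozen=True)
class AcquisitionRecord:
    """One labeled frame sequence (5 s, or 20 s for continuous-dynamic)."""

    frames: tuple[Frame, ...]
    timestamps_s: tuple[float, ...]
    grasp: GraspLabel
    arm_condition: ArmCondition
    load: LoadCondition
    arm_side: str = "RIGHT"
    repeat_index: int = 1

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.timestamps_s):
            raise ValueError("frames and timestamps must align")
        ts = np.asarray(self.timestamps_s)
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.repeat_index not in (1, 2):
            raise ValueError("repeat_index must be 1 or 2")
        if self.arm_side not in ("LEFT", "RIGHT"):
            raise ValueError("arm_side must be LEFT or RIGHT")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def cell(self) -> tuple[GraspLabel, str, Load, int]:
        """(grasp, condition key, load, repeat) identity of this record."""
        return (self.grasp, self.arm_condition.key, self.load.value, self.repeat_index)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def _band_image(
    centers: np.ndarray,
    widths: np.ndarray,
    amps: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Horizontal echogenic bands plus a mild lateral modulation."""
    h, w = FRAME_SHAPE
    depth = np.arange(h)[:, None]
    lateral = np.arange(w)[None, :]
    img = np.full(FRAME_SHAPE, 0.15)
    for c, s, a in zip(centers, widths, amps):
        profile = a * np.exp(-0.5 * ((depth - c) / s) ** 2)
        # gentle lateral undulation so bands are not perfectly flat
        wobble = 1.0 + 0.08 * np.sin(2 * np.pi * lateral / w * rng.uniform(1.0, 3.0))
        img += profile * wobble
    return np.clip(img, 0.0, 1.0)


def make_templates(config: GeneratorConfig) -> dict[GraspLabel, np.ndarray]:
    """Build one base echotexture map per grasp.

    A shared band layout models the resting anatomy; each contraction
    displaces and rescales the deep muscle bands by a grasp-specific
    offset proportional to ``grasp_separation``.  With separation 0 the
    three templates are identical; their pairwise L2 distance grows
    monotonically with separation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n_bands = 6
    centers = np.sort(rng.uniform(8, FRAME_SHAPE[0] - 8, n_bands))
    widths = rng.uniform(2.5, 6.0, n_bands)
    amps = rng.uniform(0.25, 0.6, n_bands)

    # contraction signatures: per-band displacement (pixels of depth) and
    # amplitude change, distinct per grasp; REST is the resting layout
    disp = {
        GraspLabel.REST: np.zeros(n_bands),
        GraspLabel.TRIPOD: rng.uniform(-6, 6, n_bands),
        GraspLabel.POINT: rng.uniform(-6, 6, n_bands),
    }
    damp = {
        GraspLabel.REST: np.zeros(n_bands),
        GraspLabel.TRIPOD: rng.uniform(-0.12, 0.12, n_bands),
        GraspLabel.POINT: rng.uniform(-0.12, 0.12, n_bands),
    }
    templates: dict[GraspLabel, np.ndarray] = {}
    for grasp in GraspLabel:
        band_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
        c = centers + config.grasp_separation * disp[grasp]
        a = np.clip(amps + config.grasp_separation * damp[grasp], 0.05, 0.9)
        templates[grasp] = _band_image(c, widths, a, band_rng)
    return templates


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _warp_params(
    arm_state: float, position_effect: float, load_scale: float
) -> tuple[float, float, float]:
    """(row shift, col shift, shear) of the transducer-motion analog at a
    workspace position; smooth in arm_state and zero at arm_state = 0."""
    m = position_effect * load_scale
    dy = m * 0.5 * (1 - np.cos(np.pi * arm_state))
    dx = m * np.sin(np.pi * arm_state * 0.8)
    shear = m * 0.02 * np.sin(2 * np.pi * arm_state)
    return dy, dx, shear


def _apply_affine(img: np.ndarray, dy: float, dx: float, shear: float) -> np.ndarray:
    if dy == 0.0 and dx == 0.0 and shear == 0.0:
        return img
    matrix = np.array([[1.0, shear], [0.0, 1.0]])
    offset = np.array([dy, dx])
    return ndimage.affine_transform(
        img, matrix, offset=offset, order=1, mode="nearest"
    )


def _speckle_field(
    shape: tuple[int, int], sigma: float, grain_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-mean multiplicative speckle with ~grain_px spatial correlation."""
    if sigma == 0.0:
        return np.ones(shape)
    raw = rng.rayleigh(scale=sigma, size=shape)
    if grain_px > 0:
        raw = ndimage.gaussian_filter(raw, sigma=grain_px, mode="nearest")
    return raw / raw.mean()


def render_frame(
    template: np.ndarray,
    arm_state: float,
    load: LoadCondition,
    config: GeneratorConfig,
    rng: np.random.Generator,
    extra_shift: tuple[float, float] = (0.0, 0.0),
    extra_shear: float = 0.0,
) -> Frame:
    """Render one frame: position warp, speckle, 8-bit quantization.

    ``extra_shift`` adds a constant (row, col) translation and
    ``extra_shear`` a constant shear on top of the position warp (used for
    per-repeat transducer-placement jitter and don/doff perturbations).
    Deterministic given the generator state ``rng``.
    """
    img = np.asarray(template, dtype=float)
    dy, dx, shear = _warp_params(
        float(arm_state), config.position_effect, load.perturbation_scale
    )
    dy += extra_shift[0]
    dx += extra_shift[1]
    shear += extra_shear
    if config.frame_jitter > 0:
        # per-frame transducer micro-motion; heavier distal loading couples
        # more arm motion into the socket, so load A jitters more
        jdy, jdx = rng.normal(0.0, config.frame_jitter * load.perturbation_scale, 2)
        dy += jdy
        dx += jdx
    warped = _apply_affine(img, dy, dx, shear)
    speckled = warped * _speckle_field(
        FRAME_SHAPE, config.speckle_sigma, config.speckle_grain_px, rng
    )
    return quantize8(np.clip(speckled, 0.0, None), in_max=1.0)


def _effective_template(
    templates: dict[GraspLabel, np.ndarray], grasp: GraspLabel, gain: float
) -> np.ndarray:
    """Rest template plus ``gain`` times the grasp's deformation from rest."""
    rest = templates[GraspLabel.REST]
    if grasp is GraspLabel.REST or gain == 1.0:
        return templates[grasp]
    return np.clip(rest + gain * (templates[grasp] - rest), 0.0, 1.0)


def n_frames_for(duration_s: float, frame_rate_hz: float, phase: float) -> int:
    """Frame count for an acquisition: floor(duration * rate + phase).

    The uniform phase reproduces the observed jitter (57 or 58 frames per
    5-s recording at 11.5 Hz) without modeling the grabber clock.
    """
    return int(np.floor(duration_s * frame_rate_hz + phase))


def _arm_state_path(cond: ArmCondition, n: int) -> np.ndarray:
    """arm_state per frame: constant for STATIC, a sweep for the dynamic modes."""
    if cond.mode is Mode.STATIC:
        return np.full(n, POSITION_ARM_STATE[cond.static_position])
    t = np.linspace(0.0, 1.0, n)
    if cond.mode is Mode.DYNAMIC:
        lo, hi = PATTERN_ARM_SPAN[cond.pattern]
        return lo + (hi - lo) * t
    # continuous dynamic: the four pattern spans concatenated, with
    # Countertop Wipe and Sliding Glass Door traversed in reverse so the
    # combined 20-s path is continuous
    segs = []
    per = n // 4
    counts = [per] * 3 + [n - 3 * per]
    for pattern, cnt in zip(DYNAMIC_PATTERNS, counts):
        lo, hi = PATTERN_ARM_SPAN[pattern]
        seg = np.linspace(lo, hi, cnt)
        if pattern in REVERSED_IN_CONTINUOUS:
            seg = seg[::-1]
        segs.append(seg)
    return np.concatenate(segs)


def generate_acquisition(
    grasp: GraspLabel,
    arm_condition: ArmCondition,
    load: Load | LoadCondition,
    config: GeneratorConfig,
    seed: int,
    arm_side: str = "RIGHT",
    repeat_index: int = 1,
    templates: dict[GraspLabel, np.ndarray] | None = None,
    extra_shift: tuple[float, float] = (0.0, 0.0),
) -> AcquisitionRecord:
    """Generate one labeled acquisition under the given condition.

    A per-acquisition transducer-placement jitter (constant within the
    recording, scaled by ``repeat_jitter`` and the load) models imperfect
    repeatability between the two repeats of a condition cell.
    """
    if isinstance(load, Load):
        load = config.load_condition(load)
    if templates is None:
        templates = make_templates(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed]))
    phase = rng.uniform(0.0, 1.0)
    n = n_frames_for(arm_condition.duration_s, config.frame_rate_hz, phase)
    states = _arm_state_path(arm_condition, n)
    gain = (
        config.dynamic_contrast
        if arm_condition.mode in (Mode.DYNAMIC, Mode.CONTINUOUS_DYNAMIC)
        else 1.0
    )
    template = _effective_template(templates, grasp, gain)
    jitter = config.repeat_jitter * load.perturbation_scale
    placement = (
        extra_shift[0] + rng.normal(0.0, jitter),
        extra_shift[1] + rng.normal(0.0, jitter),
    )
    frames = tuple(
        render_frame(template, s, load, config, rng, extra_shift=placement)
        for s in states
    )
    timestamps = tuple(k / config.frame_rate_hz for k in range(n))
    return AcquisitionRecord(
        frames=frames,
        timestamps_s=timestamps,
        grasp=grasp,
        arm_condition=arm_condition,
        load=load,
        arm_side=arm_side,
        repeat_index=repeat_index,
    )


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

def static_protocol(load: Load) -> list[tuple[GraspLabel, ArmCondition, Load]]:
    return [
        (g, ArmCondition(Mode.STATIC, static_position=p), load)
        for g in GraspLabel
        for p in STATIC_POSITIONS
    ]


def dynamic_protocol(load: Load) -> list[tuple[GraspLabel, ArmCondition, Load]]:
    return [
        (g, ArmCondition(Mode.DYNAMIC, pattern=p), load)
        for g in GraspLabel
        for p in DYNAMIC_PATTERNS
    ]


def continuous_dynamic_protocol(load: Load) -> list[tuple[GraspLabel, ArmCondition, Load]]:
    return [(g, ArmCondition(Mode.CONTINUOUS_DYNAMIC), load) for g in GraspLabel]


def generate_session(
    protocol: list[tuple[GraspLabel, ArmCondition, Load]],
    config: GeneratorConfig,
    seed: int,
    repeats: int = 2,
    arm_side: str = "RIGHT",
) -> list[AcquisitionRecord]:
    """Generate ``repeats`` acquisitions per protocol entry, in an order
    randomized by ``seed`` (presentation order was randomized in the study
    protocol this emulates)."""
    if not protocol:
        raise ValueError("protocol must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed, 303]))
    templates = make_templates(config)
    entries = [
        (g, cond, load, rep)
        for (g, cond, load) in protocol
        for rep in range(1, repeats + 1)
    ]
    order = rng.permutation(len(entries))
    records = []
    acq_seeds = rng.integers(0, 2**31 - 1, size=len(entries))
    for pos in order:
        g, cond, load, rep = entries[pos]
        records.append(
            generate_acquisition(
                g,
                cond,
                load,
                config,
                seed=int(acq_seeds[pos]),
                arm_side=arm_side,
                repeat_index=rep,
                templates=templates,
            )
        )
    return records


@dataclass(frozen=True)
class ScriptedSequence:
    """A scripted frame sequence for functional-task emulation.

    Unlike an :class:`AcquisitionRecord`, the commanded grasp changes over
    the sequence; ``true_labels`` carries the grasp demanded at each frame.
    """

    frames: tuple[Frame, ...]
    timestamps_s: tuple[float, ...]
    true_labels: tuple[GraspLabel, ...]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def render_script(
    segments: list[tuple[GraspLabel, float, float, int]],
    load: Load | LoadCondition,
    config: GeneratorConfig,
    seed: int,
    templates: dict[GraspLabel, np.ndarray] | None = None,
    extra_shift: tuple[float, float] = (0.0, 0.0),
    extra_shear: float = 0.0,
    dynamic_gain: bool = True,
) -> ScriptedSequence:
    """Render a grasp-demand script: each segment holds one grasp while the
    arm moves linearly from one arm_state to another over ``n`` frames.

    ``extra_shift``/``extra_shear`` apply a constant transducer-placement
    perturbation to the whole sequence (the don/doff analog).  With
    ``dynamic_gain`` the dynamic-contrast deformation gain applies, as the
    arm is in motion during functional tasks.
    """
    if isinstance(load, Load):
        load = config.load_condition(load)
    if templates is None:
        templates = make_templates(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed, 404]))
    gain = config.dynamic_contrast if dynamic_gain else 1.0
    frames: list[Frame] = []
    labels: list[GraspLabel] = []
    for grasp, s0, s1, n in segments:
        if n < 1:
            raise ValueError("each segment needs at least one frame")
        template = _effective_template(templates, grasp, gain)
        for s in np.linspace(s0, s1, n):
            frames.append(
                render_frame(
                    template,
                    s,
                    load,
                    config,
                    rng,
                    extra_shift=extra_shift,
                    extra_shear=extra_shear,
                )
            )
            labels.append(grasp)
    timestamps = tuple(k / config.frame_rate_hz for k in range(len(frames)))
    return ScriptedSequence(tuple(frames), timestamps, tuple(labels))


def generate_chance_images(
    n: int = 100,
    sigma: float = 0.101,
    shape: tuple[int, int] = FRAME_SHAPE,
    seed: int = 0,
) -> list[Frame]:
    """The chance-baseline image set: ``n`` independent frames of i.i.d.
    Rayleigh(sigma) intensities on [0, 1], quantized to 8 bits.

    These mimic the first- and second-order statistics of ultrasound
    speckle with no shared structure, so their mean pairwise similarity is
    the similarity attributable to chance alone.
    """
    if n < 2:
        raise ValueError("need at least 2 chance images to form a pair")
    rng = np.random.default_rng(seed)
    return [
        quantize8(np.clip(rng.rayleigh(scale=sigma, size=shape), 0.0, 1.0), in_max=1.0)
        for _ in range(n)
    ]
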