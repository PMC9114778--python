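"""Structural Similarity Index (SSIM) and grasp-similarity analysis.

SSIM compares two images by decomposing them into luminance, contrast and
structure components,

    l(A,B) = (2 mu_A mu_B + C1) / (mu_A^2 + mu_B^2 + C1)
    c(A,B) = (2 sig_A sig_B + C2) / (sig_A^2 + sig_B^2 + C2)
    s(A,B) = (sig_AB + C3) / (sig_A sig_B + C3)

with C1 = (K1 L)^2, C2 = (K2 L)^2, C3 = C2 / 2 and exponents
alpha = beta = gamma = 1, giving an index in [-1, 1] (1 for identical
images).  Statistics are either local (Gaussian 11 x 11 window, sd 1.5 —
the canonical choice, averaged over the component-product map) or global
(whole-image moments).

The chance baseline contextualizes an SSIM value: the mean SSIM over all
unordered pairs of independently generated Rayleigh-speckle images is the
similarity two ultrasound-like images share from noise statistics alone.
Same- vs different-grasp comparisons over repeated acquisitions quantify
how consistent imagery of one grasp is, and how distinct imagery of
different grasps is; the two samples are compared with a Welch t-test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .frames import Frame
from .synthgen import AcquisitionRecord, GraspLabel, Load

GAUSSIAN = "gaussian"
GLOBAL = "global"


@dataclass(frozen=True)
class SSIMConfig:
    """SSIM constants and windowing.

    ``L`` is the dynamic range of the images (255 for 8-bit frames; set 1.0
    for [0, 1]-scaled data).  The component exponents default to 1.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    K1: float = 0.01
    K2: float = 0.03
    L: float = 255.0
    window: str = GAUSSIAN
    gaussian_sd: float = 1.5
    window_size: int = 11

    def __post_init__(self) -> None:
        if self.window not in (GAUSSIAN, GLOBAL):
            raise ValueError("window must be 'gaussian' or 'global'")
        if self.K1 <= 0 or self.K2 <= 0 or self.L <= 0:
            raise ValueError("K1, K2, L must be positive")
        if self.window_size % 2 != 1:
            raise ValueError("window_size must be odd")

    @property
    def C1(self) -> float:
        return (self.K1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.L) ** 2

    @property
    def C3(self) -> float:
        return self.C2 / 2.0


@dataclass(frozen=True)
class SSIMResult:
    """SSIM value with its component means."""

    value: float
    luminance: float
    contrast: float
    structure: float
    config: SSIMConfig


def _as_array(img) -> np.ndarray:
    if isinstance(img, Frame):
        return img.pixels.astype(float)
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("SSIM operates on 2-D images")
    return a


def _gaussian_window_stats(a: np.ndarray, cfg: SSIMConfig):
    """Local mean and mean-of-square maps under the truncated Gaussian
    window, cropped to the region where the window fits entirely."""
    radius = (cfg.window_size - 1) // 2
    truncate = radius / cfg.gaussian_sd
    f = lambda x: ndimage.gaussian_filter(x, cfg.gaussian_sd, truncate=truncate)
    ua = f(a)
    uaa = f(a * a)
    return ua, uaa


def _crop(x: np.ndarray, cfg: SSIMConfig) -> np.ndarray:
    pad = (cfg.window_size - 1) // 2
    return x[pad:-pad, pad:-pad]


def _component_maps(a, b, ua, ub, vaa, vbb, vab, cfg: SSIMConfig):
    """Luminance / contrast / structure maps from (co)moment maps."""
    sa = np.sqrt(np.maximum(vaa, 0.0))
    sb = np.sqrt(np.maximum(vbb, 0.0))
    lmap = (2 * ua * ub + cfg.C1) / (ua**2 + ub**2 + cfg.C1)
    cmap = (2 * sa * sb + cfg.C2) / (sa**2 + sb**2 + cfg.C2)
    smap = (vab + cfg.C3) / (sa * sb + cfg.C3)
    return lmap, cmap, smap


def ssim(a, b, config: SSIMConfig | None = None) -> SSIMResult:
    """SSIM between two images (Frames or 2-D arrays of equal shape).

    With the Gaussian window the returned value is the mean of the local
    component-product map over the interior region where the window fits;
    with ``window=GLOBAL`` a single set of whole-image moments is used.
    Symmetric in its arguments.
    """
    A = _as_array(a)
    B = _as_array(b)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if config is None:
        L = a.scale if isinstance(a, Frame) else 255.0
        config = SSIMConfig(L=L)

    if config.window == GLOBAL:
        ua, ub = A.mean(), B.mean()
        vaa = A.var()
        vbb = B.var()
        vab = ((A - ua) * (B - ub)).mean()
        lmap, cmap, smap = _component_maps(A, B, ua, ub, vaa, vbb, vab, config)
        lum, con, stru = float(lmap), float(cmap), float(smap)
        value = lum**config.alpha * con**config.beta * stru**config.gamma
        return SSIMResult(float(value), lum, con, stru, config)

    ua, uaa = _gaussian_window_stats(A, config)
    ub, ubb = _gaussian_window_stats(B, config)
    radius = (config.window_size - 1) // 2
    truncate = radius / config.gaussian_sd
    uab = ndimage.gaussian_filter(A * B, config.gaussian_sd, truncate=truncate)
    vaa = uaa - ua**2
    vbb = ubb - ub**2
    vab = uab - ua * ub
    lmap, cmap, smap = _component_maps(A, B, ua, ub, vaa, vbb, vab, config)
    lmap, cmap, smap = (_crop(m, config) for m in (lmap, cmap, smap))
    prod = lmap**config.alpha * cmap**config.beta * smap**config.gamma
    return SSIMResult(
        float(prod.mean()),
        float(lmap.mean()),
        float(cmap.mean()),
        float(smap.mean()),
        config,
    )


# ---------------------------------------------------------------------------
# Chance baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChanceBaseline:
    mean: float
    sd: float
    n_pairs: int


def chance_baseline(images: list[Frame], config: SSIMConfig | None = None) -> ChanceBaseline:
    """Mean SSIM over all unordered pairs of the chance image set.

    For ``n`` images this enumerates n(n-1)/2 pairs (4,950 for the default
    100).  Per-image window statistics are precomputed so the pairwise pass
    only filters the cross term.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images to form a pair")
    if config is None:
        config = SSIMConfig(L=images[0].scale)
    arrays = [_as_array(im) for im in images]

    if config.window == GLOBAL:
        values = [
            ssim(arrays[i], arrays[j], config).value
            for i, j in itertools.combinations(range(len(arrays)), 2)
        ]
        v = np.array(values)
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        return ChanceBaseline(float(v.mean()), sd, len(v))

    radius = (config.window_size - 1) // 2
    truncate = radius / config.gaussian_sd
    f = lambda x: ndimage.gaussian_filter(x, config.gaussian_sd, truncate=truncate)
    stats_cache = []
    for A in arrays:
        ua = f(A)
        vaa = f(A * A) - ua**2
        stats_cache.append((A, ua, vaa))
    values = []
    for (A, ua, vaa), (B, ub, vbb) in itertools.combinations(stats_cache, 2):
        vab = f(A * B) - ua * ub
        lmap, cmap, smap = _component_maps(A, B, ua, ub, vaa, vbb, vab, config)
        prod = (
            _crop(lmap, config) ** config.alpha
            * _crop(cmap, config) ** config.beta
            * _crop(smap, config) ** config.gamma
        )
        values.append(float(prod.mean()))
    v = np.array(values)
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    return ChanceBaseline(float(v.mean()), sd, len(v))


# ---------------------------------------------------------------------------
# Same- vs different-grasp similarity over a session
# ---------------------------------------------------------------------------

@dataclass
class GraspSimilaritySummary:
    """Per-frame SSIM samples for same- and different-grasp comparisons.

    ``same_trace_sds`` / ``different_trace_sds`` hold, for each individual
    comparison (one pair of acquisitions), the standard deviation of its
    frame-wise SSIM trace — the within-comparison variability that load
    coupling inflates.
    """

    same_grasp_values: np.ndarray
    different_grasp_values: np.ndarray
    t_statistic: float
    p_value: float
    same_trace_sds: np.ndarray = field(default_factory=lambda: np.array([]))
    different_trace_sds: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def same_mean(self) -> float:
        return float(np.mean(self.same_grasp_values))

    @property
    def same_sd(self) -> float:
        return float(np.std(self.same_grasp_values, ddof=1))

    @property
    def different_mean(self) -> float:
        return float(np.mean(self.different_grasp_values))

    @property
    def different_sd(self) -> float:
        return float(np.std(self.different_grasp_values, ddof=1))

    @property
    def gap(self) -> float:
        """mean(same) - mean(different): how much better imagery of one
        grasp matches itself than it matches other grasps."""
        return self.same_mean - self.different_mean


def compare_means(same_values, different_values) -> tuple[float, float]:
    """Welch (unequal-variance) two-sample t-test, two-sided.

    Degenerate inputs (zero variance in both samples with equal means)
    return ``(0.0, 1.0)`` by convention.
    """
    a = np.asarray(same_values, dtype=float)
    b = np.asarray(different_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def grasp_similarity(
    session: list[AcquisitionRecord],
    load: Load,
    mode=None,
    config: SSIMConfig | None = None,
) -> GraspSimilaritySummary:
    """Frame-wise SSIM comparison of repeated and differing-grasp imagery.

    Same-grasp values: frame k of repeat 1 vs frame k of repeat 2 for each
    (grasp, condition) cell, over the first min(n1, n2) frames.
    Different-grasp values: frame k of one grasp vs frame k of another
    grasp, same condition and same repeat, for every unordered grasp pair.
    """
    records = [r for r in session if r.load.value is load]
    if mode is not None:
        records = [r for r in records if r.arm_condition.mode is mode]
    if not records:
        raise ValueError("no records for the requested load/mode")
    if config is None:
        config = SSIMConfig(L=records[0].frames[0].scale)

    by_cell: dict[tuple[str, GraspLabel, int], AcquisitionRecord] = {}
    for r in records:
        key = (r.arm_condition.key, r.grasp, r.repeat_index)
        if key in by_cell:
            raise ValueError(f"duplicate cell {key}")
        by_cell[key] = r

    conditions = sorted({k[0] for k in by_cell})
    grasps = sorted({k[1] for k in by_cell}, key=int)

    same_traces, diff_traces = [], []
    for cond in conditions:
        for g in grasps:
            try:
                r1 = by_cell[(cond, g, 1)]
                r2 = by_cell[(cond, g, 2)]
            except KeyError as e:
                raise ValueError(
                    f"missing repeat for condition {cond!r}, grasp {g.name}"
                ) from e
            m = min(r1.n_frames, r2.n_frames)
            same_traces.append(
                [ssim(r1.frames[k], r2.frames[k], config).value for k in range(m)]
            )
        for ga, gb in itertools.combinations(grasps, 2):
            for rep in (1, 2):
                ra = by_cell[(cond, ga, rep)]
                rb = by_cell[(cond, gb, rep)]
                m = min(ra.n_frames, rb.n_frames)
                diff_traces.append(
                    [ssim(ra.frames[k], rb.frames[k], config).value for k in range(m)]
                )
    same = [v for tr in same_traces for v in tr]
    diff = [v for tr in diff_traces for v in tr]
    t, p = compare_means(same, diff)
    return GraspSimilaritySummary(
        same_grasp_values=np.array(same),
        different_grasp_values=np.array(diff),
        t_statistic=t,
        p_value=p,
        same_trace_sds=np.array([np.std(tr, ddof=1) for tr in same_traces]),
        different_trace_sds=np.array([np.std(tr, ddof=1) for tr in diff_traces]),
    )
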