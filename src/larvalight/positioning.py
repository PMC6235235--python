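"""Image-based specimen fine-positioning from 1D brightfield profiles.

A specimen stopped in the imaging capillary is localized along the flow
axis x by averaging a brightfield image (or a tiled composite of images)
along y to get a 1D intensity profile, then comparing it to a stored
library of average profiles of correctly positioned specimens.  Strong
anatomical features — eyes, swim bladder — produce deep minima that make
the comparison robust.  Two interchangeable offset estimators are provided:

* ``crosscorr`` — normalized cross-correlation over integer-sample shifts,
  scored on the overlapping region only;
* ``minimum`` — difference between the locations of the global intensity
  minima of profile and template.

Offsets are reported in μm; positive means the specimen is displaced
toward +x relative to the template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DataError, ValidationError

MIN_OVERLAP_FRACTION = 0.25
# a lag only competes if its overlap carries real structure: each overlapping
# segment must hold at least this fraction of the full profile's variance
# (featureless baseline tails otherwise produce spurious perfect correlations)
MIN_OVERLAP_VARIANCE_FRACTION = 1e-3


@dataclass
class IntensityProfile:
    """1D axial intensity profile: values at ``origin + i·step`` μm."""

    values: np.ndarray
    step: float
    origin: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError("profile must be 1D with at least 2 samples")
        if self.step <= 0:
            raise ValidationError("profile step must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def positions(self) -> np.ndarray:
        return self.origin + np.arange(self.values.size) * self.step

    def normalized(self) -> "IntensityProfile":
        """Zero-mean, unit-variance copy (constant profiles map to zeros)."""
        v = self.values - self.values.mean()
        sd = v.std()
        if sd > 0:
            v = v / sd
        return IntensityProfile(v, self.step, self.origin)


@dataclass
class TemplateLibrary:
    """Named average profiles of correctly positioned specimens."""

    templates: list[tuple[str, IntensityProfile]]

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValidationError("template library must be non-empty")
        steps = {t.step for _, t in self.templates}
        if len(steps) != 1:
            raise ValidationError(f"all templates must share one step, got {sorted(steps)}")


@dataclass
class OffsetResult:
    """Estimated displacement of a specimen relative to a template."""

    offset: float
    score: float
    method: str
    best_template: str = ""


def profile_from_image(frame: np.ndarray, pixel_size: float = 1.0, origin: float = 0.0) -> IntensityProfile:
    """Average a 2D brightfield frame along y (axis 0) into a 1D profile."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or frame.size == 0:
        raise ValidationError("frame must be a non-empty 2D image")
    return IntensityProfile(frame.mean(axis=0), pixel_size, origin)


def tile_composite(frames: list[np.ndarray], step_um: float, pixel_size: float) -> np.ndarray:
    """Tile brightfield frames captured at regular x steps into one image.

    Frames are placed at nominal positions i·step_um (converted to whole
    pixels); overlapping pixels are averaged.  Frames must share a height;
    the step may not exceed the frame width (gaps are not representable).
    """
    if not frames:
        raise ValidationError("no frames to tile")
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    heights = {f.shape[0] for f in frames}
    if len(heights) != 1:
        raise ValidationError(f"frames must share a height, got {sorted(heights)}")
    if any(f.ndim != 2 for f in frames):
        raise ValidationError("frames must be 2D")
    step_px = int(round(step_um / pixel_size))
    if step_px < 0 or (len(frames) > 1 and step_px > frames[0].shape[1]):
        raise ValidationError("step must be positive and no wider than a frame (no gaps)")
    height = frames[0].shape[0]
    width = step_px * (len(frames) - 1) + frames[-1].shape[1]
    acc = np.zeros((height, width))
    cover = np.zeros((height, width))
    for i, f in enumerate(frames):
        x0 = i * step_px
        acc[:, x0 : x0 + f.shape[1]] += f
        cover[:, x0 : x0 + f.shape[1]] += 1
    return acc / np.maximum(cover, 1)


def build_template(profiles: list[IntensityProfile], normalize: bool = True) -> IntensityProfile:
    """Average member profiles into one library template.

    Profiles are normalized to zero mean / unit variance before averaging
    (set ``normalize=False`` for raw-intensity averaging), which makes the
    template insensitive to illumination differences between specimens.
    """
    if not profiles:
        raise ValidationError("cannot build a template from zero profiles")
    steps = {p.step for p in profiles}
    if len(steps) != 1:
        raise ValidationError(f"profiles must share one step, got {sorted(steps)}")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ValidationError(f"profiles must share one length, got {sorted(lengths)}")
    stack = np.stack([(p.normalized() if normalize else p).values for p in profiles])
    return IntensityProfile(stack.mean(axis=0), profiles[0].step, profiles[0].origin)


def _crosscorr_scores(
    p: np.ndarray, q: np.ndarray, max_lag: int, scoring: str = "pearson"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag correlation of profile p against template q over their overlap,
    for integer lags |k| ≤ max_lag.

    scoring "pearson": Pearson correlation of the overlapping segments
    (bounded by 1, exactly 1 at a perfect alignment; immune to the
    partial-overlap bias of a plain mean product and comparable across
    templates).  scoring "product": Σ p(i)·q(i−k) / overlap length.
    Lags with overlap below MIN_OVERLAP_FRACTION·len(q), or (pearson) with a
    constant segment, are excluded.
    """
    n_p, n_q = p.size, q.size
    min_overlap = max(2, int(np.ceil(MIN_OVERLAP_FRACTION * n_q)))
    var_floor_p = MIN_OVERLAP_VARIANCE_FRACTION * p.var()
    var_floor_q = MIN_OVERLAP_VARIANCE_FRACTION * q.var()
    lags, scores = [], []
    for k in range(-max_lag, max_lag + 1):
        # p(i) aligns with q(i - k): valid i in [max(0, k), min(n_p, n_q + k))
        i0 = max(0, k)
        i1 = min(n_p, n_q + k)
        overlap = i1 - i0
        if overlap < min_overlap:
            continue
        seg_p = p[i0:i1]
        seg_q = q[i0 - k : i1 - k]
        if scoring == "pearson":
            vp = seg_p.var()
            vq = seg_q.var()
            if vp < var_floor_p or vq < var_floor_q or vp == 0 or vq == 0:
                continue
            score = float(np.mean((seg_p - seg_p.mean()) * (seg_q - seg_q.mean())) / np.sqrt(vp * vq))
        else:
            score = float(np.dot(seg_p, seg_q)) / overlap
        lags.append(k)
        scores.append(score)
    if not lags:
        raise DataError("no lag within max_shift leaves sufficient overlap")
    return np.asarray(lags), np.asarray(scores)


def match_offset(
    profile: IntensityProfile,
    template: IntensityProfile,
    method: str = "crosscorr",
    max_shift: float | None = None,
    normalize: bool = True,
    scoring: str = "pearson",
) -> OffsetResult:
    """Estimate the displacement of ``profile`` relative to ``template``.

    crosscorr: the lag maximizing the per-lag correlation score (default:
    Pearson correlation over the overlap; ``scoring="product"`` uses the
    plain overlap-normalized product of the z-scored profiles); ties break
    toward the smaller |offset|.  minimum: the difference of the two
    global-minimum locations.  Offsets are integer multiples of the sample
    step, plus the origin difference.
    """
    if method not in ("crosscorr", "minimum"):
        raise ValidationError(f"unknown matching method {method!r}")
    if profile.step != template.step:
        raise ValidationError("profile and template must share one sample step")
    step = profile.step
    origin_shift = profile.origin - template.origin
    if method == "minimum":
        k = int(np.argmin(profile.values)) - int(np.argmin(template.values))
        offset = k * step + origin_shift
        depth = float(profile.values.mean() - profile.values.min())
        return OffsetResult(offset=offset, score=depth, method=method)
    if max_shift is None:
        max_shift = (len(profile) - 1) * step
    max_lag = int(np.floor(max_shift / step))
    p = (profile.normalized() if normalize else profile).values
    q = (template.normalized() if normalize else template).values
    lags, scores = _crosscorr_scores(p, q, max_lag, scoring)
    best = np.lexsort((lags, np.abs(lags), -scores))[0]  # score desc, then |k|, then k
    offset = lags[best] * step + origin_shift
    return OffsetResult(offset=float(offset), score=float(scores[best]), method="crosscorr")


def match_library(
    profile: IntensityProfile,
    library: TemplateLibrary,
    method: str = "crosscorr",
    max_shift: float | None = None,
    normalize: bool = True,
) -> OffsetResult:
    """Match against every library template; the best score wins."""
    best: OffsetResult | None = None
    for name, template in library.templates:
        r = match_offset(profile, template, method=method, max_shift=max_shift, normalize=normalize)
        r.best_template = name
        if best is None or r.score > best.score:
            best = r
    assert best is not None
    return best


def shift_profile(profile: IntensityProfile, offset_um: float, fill: str = "edge") -> IntensityProfile:
    """Displace a profile by ``offset_um`` via linear interpolation.

    Positive offsets move features toward +x.  Out-of-range samples repeat
    the edge value ("edge") or the profile mean ("mean").
    """
    u = profile.positions
    left = profile.values[0] if fill == "edge" else profile.values.mean()
    right = profile.values[-1] if fill == "edge" else profile.values.mean()
    return IntensityProfile(
        np.interp(u - offset_um, u, profile.values, left=left, right=right),
        profile.step,
        profile.origin,
    )


def simulate_fine_positioning(
    template: IntensityProfile,
    true_offset: float,
    stage_noise_sd: float = 0.0,
    profile_noise_sd: float = 0.0,
    max_iter: int = 5,
    method: str = "crosscorr",
    max_shift: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Closed-loop fine-positioning simulation.

    The specimen starts displaced by ``true_offset`` μm.  Each iteration
    images it (the template shifted by the current residual, plus Gaussian
    profile noise), estimates the offset, and commands the opposite stage
    move, corrupted by Gaussian stage noise.  A zero estimated offset
    commands no move, so an already-converged specimen is not perturbed.
    Returns the residual offset after each iteration (length ``max_iter``).
    """
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    rng = np.random.default_rng(seed)
    residual = float(true_offset)
    trajectory = np.empty(max_iter)
    for i in range(max_iter):
        observed = shift_profile(template, residual)
        if profile_noise_sd > 0:
            observed = IntensityProfile(
                observed.values + rng.normal(0.0, profile_noise_sd, size=len(observed)),
                observed.step,
                observed.origin,
            )
        est = match_offset(observed, template, method=method, max_shift=max_shift).offset
        if est != 0.0:
            residual += -est + (rng.normal(0.0, stage_noise_sd) if stage_noise_sd > 0 else 0.0)
        trajectory[i] = residual
    return trajectory
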