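"""Bottom-up saliency maps, the grid saliency-index simulation, and the
block-reduction image-motion metric.

The saliency model follows the classic center-surround architecture:
intensity, color-opponency (red-green, blue-yellow) and four orientation
channels are extracted over a 9-level Gaussian pyramid; feature maps are
across-scale differences between center levels {2, 3, 4} and surround
levels c + {3, 4}; each map passes through the max-normalization operator
N(.) that promotes maps with one dominant peak; per-channel conspicuity
maps are summed at a common scale and combined with equal weights.

The saliency index of a 3x3 display is the total map activation inside
the target region divided by the mean activation of the eight distractor
regions; the Monte-Carlo simulation repeats this over random target
placements to check that two target types are salience-equated.

Image motion between two frames is the sum of absolute differences of
block-reduced (summed 20x20-pixel blocks) versions of the frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gabor_kernel
from skimage.measure import block_reduce
from skimage.transform import resize

from .stimuli import GridLayout, PatchParams, SyntheticDisplay, generate_display

__all__ = [
    "SaliencyMap",
    "SalienceResult",
    "IttiKochSaliency",
    "compute_saliency_map",
    "saliency_index",
    "run_salience_simulation",
    "image_motion",
]


@dataclass
class SaliencyMap:
    """Final saliency raster (same shape as the input image) plus provenance."""

    values: np.ndarray
    channel_weights: dict[str, float] = field(default_factory=dict)
    conspicuity: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("saliency map must be nonnegative and finite")


@dataclass
class SalienceResult:
    activations: np.ndarray  # per-slot total activation, length 9
    saliency_index: float
    target_slot: int
    emotion: str | None = None
    replicate: int | None = None


def _luma(image: np.ndarray) -> np.ndarray:
    return 0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]


def _local_max_mean(m: np.ndarray) -> float:
    """Mean of local maxima excluding the global maximum (ties included once)."""
    size = max(3, min(m.shape) // 10)
    is_max = (ndimage.maximum_filter(m, size=size, mode="nearest") == m) & (m > 0.01)
    vals = m[is_max]
    if vals.size <= 1:
        return 0.0
    vals = np.sort(vals)[::-1]
    return float(vals[1:].mean())


# small floor keeping the operator from annihilating a map whose local maxima
# are all exactly equal (fully homogeneous displays); ratios are unaffected
_NORM_FLOOR = 1e-4


def _max_normalize(m: np.ndarray) -> np.ndarray:
    """Itti-Koch N(.): rescale to [0, 1] then weight by (1 - mbar)^2."""
    mx = float(m.max())
    if mx <= 0:
        return np.zeros_like(m)
    m = m / mx
    mbar = _local_max_mean(m)
    return m * max((1.0 - mbar) ** 2, _NORM_FLOOR)


class IttiKochSaliency:
    """Center-surround saliency model (sklearn-style transformer).

    Parameters
    ----------
    n_levels : int
        Pyramid depth; the image's short side must be at least
        ``2 ** (n_levels - 1)`` pixels.
    center_levels, surround_deltas : tuples
        Across-scale difference structure.
    orientations : tuple of radians
        Gabor orientations for the orientation channel.
    boundary : str
        Filter boundary mode (scipy convention).  The default "wrap"
        (periodic continuation) treats every cell of a tiled display
        equivalently, so items in corner and center slots are compared
        on equal footing; "reflect" is more natural for single-object
        natural images.
    """

    def __init__(
        self,
        n_levels: int = 9,
        center_levels: tuple[int, ...] = (2, 3, 4),
        surround_deltas: tuple[int, ...] = (3, 4),
        orientations: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4),
        gabor_frequency: float = 0.25,
        boundary: str = "wrap",
    ):
        self.n_levels = n_levels
        self.center_levels = center_levels
        self.surround_deltas = surround_deltas
        self.orientations = orientations
        self.gabor_frequency = gabor_frequency
        self.boundary = boundary

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_levels": self.n_levels,
            "center_levels": self.center_levels,
            "surround_deltas": self.surround_deltas,
            "orientations": self.orientations,
            "gabor_frequency": self.gabor_frequency,
            "boundary": self.boundary,
        }

    def set_params(self, **params) -> "IttiKochSaliency":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- pyramid helpers ----------------------------------------------------

    def _pyramid(self, image: np.ndarray) -> list[np.ndarray]:
        levels = [image]
        for _ in range(self.n_levels - 1):
            sm = ndimage.gaussian_filter(levels[-1], sigma=1.0, mode=self.boundary)
            levels.append(sm[::2, ::2])
        return levels

    def _center_surround(self, pyr: list[np.ndarray]) -> list[np.ndarray]:
        maps = []
        for c in self.center_levels:
            for d in self.surround_deltas:
                s = c + d
                surround = resize(
                    pyr[s], pyr[c].shape, order=1, mode="reflect", anti_aliasing=False
                )
                maps.append(np.abs(pyr[c] - surround))
        return maps

    def _combine(self, maps: list[np.ndarray], out_shape: tuple[int, int]) -> np.ndarray:
        total = np.zeros(out_shape)
        for m in maps:
            total += resize(
                _max_normalize(m), out_shape, order=1, mode="reflect", anti_aliasing=False
            )
        return total

    @property
    def _gabor_kernels(self):
        if not hasattr(self, "_gk_cache"):
            self._gk_cache = [
                gabor_kernel(frequency=self.gabor_frequency, theta=th, sigma_x=2.0, sigma_y=2.0)
                for th in self.orientations
            ]
        return self._gk_cache

    # -- main entry ----------------------------------------------------------

    def transform(self, image: np.ndarray) -> SaliencyMap:
        image = np.asarray(image, dtype=float)
        if np.any(~np.isfinite(image)):
            raise ValueError("image contains NaN or infinite pixels")
        if image.min() < 0 or image.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")
        color = image.ndim == 3
        if color and image.shape[2] != 3:
            raise ValueError("color images must have three channels")
        if image.ndim not in (2, 3):
            raise ValueError("image must be 2-D grayscale or 3-channel")
        min_side = min(image.shape[:2])
        if min_side < 2 ** (self.n_levels - 1):
            raise ValueError(
                f"image short side {min_side} px too small for a "
                f"{self.n_levels}-level pyramid (needs >= {2 ** (self.n_levels - 1)})"
            )

        intensity = _luma(image) if color else image
        # conspicuity scale: the middle center level
        out_level = self.center_levels[len(self.center_levels) // 2]
        pyr_i = self._pyramid(intensity)
        out_shape = pyr_i[out_level].shape

        conspicuity: dict[str, np.ndarray] = {}
        conspicuity["intensity"] = self._combine(self._center_surround(pyr_i), out_shape)

        if color:
            r, g, b = image[..., 0], image[..., 1], image[..., 2]
            denom = np.maximum(intensity, 0.1 * max(float(intensity.max()), 1e-12))
            rn, gn, bn = r / denom, g / denom, b / denom
            rg = rn - gn
            by = bn - (rn + gn) / 2.0
            cmaps = self._center_surround(self._pyramid(rg))
            cmaps += self._center_surround(self._pyramid(by))
            conspicuity["color"] = self._combine(cmaps, out_shape)

        omaps = []
        for kern in self._gabor_kernels:
            opyr = []
            for lev in range(self.n_levels):
                resp = ndimage.convolve(pyr_i[lev], np.real(kern), mode=self.boundary)
                opyr.append(np.abs(resp))
            omaps.extend(self._center_surround(opyr))
        conspicuity["orientation"] = self._combine(omaps, out_shape)

        weights = {k: 1.0 / len(conspicuity) for k in conspicuity}
        final = np.zeros(out_shape)
        for k, cmap in conspicuity.items():
            final += weights[k] * _max_normalize(cmap)
        final = resize(
            final, image.shape[:2], order=1, mode="reflect", anti_aliasing=False
        )
        final = np.maximum(final, 0.0)
        return SaliencyMap(values=final, channel_weights=weights, conspicuity=conspicuity)


def compute_saliency_map(image: np.ndarray, model: IttiKochSaliency | None = None) -> SaliencyMap:
    """Saliency map of ``image`` with default model settings."""
    return (model or IttiKochSaliency()).transform(image)


def saliency_index(smap: SaliencyMap, layout: GridLayout) -> SalienceResult:
    """Target-to-mean-distractor activation ratio over the layout regions."""
    if layout.target_slot is None:
        raise ValueError("layout has no target slot")
    values = smap.values
    h, w = values.shape
    lh, lw = layout.image_size
    if (h, w) != (lh, lw):
        raise ValueError(f"map shape {(h, w)} does not match layout raster {(lh, lw)}")
    activations = np.array(
        [values[t : t + rh, l : l + rw].sum() for (t, l, rh, rw) in layout.rects]
    )
    distractors = np.delete(activations, layout.target_slot)
    mean_d = float(distractors.mean())
    if mean_d <= 0:
        raise ValueError("degenerate display: zero mean distractor activation")
    return SalienceResult(
        activations=activations,
        saliency_index=float(activations[layout.target_slot] / mean_d),
        target_slot=layout.target_slot,
    )


def run_salience_simulation(
    target_patches: dict[str, list[PatchParams]],
    distractor_patches: list[PatchParams],
    n_reps_per_emotion: int = 504,
    rng_seed: int | None = None,
    layout: GridLayout | None = None,
    model: IttiKochSaliency | None = None,
    n_boot: int = 2000,
) -> tuple[pd.DataFrame, dict]:
    """Monte-Carlo check that two target types are salience-equated.

    Each replicate places one target (drawn from that emotion's patch
    set) in a uniformly random slot of the 3x3 grid, fills the remaining
    slots with distractor identities sampled without replacement (with
    replacement if fewer than eight are supplied), renders the display,
    and computes the saliency index.  Returns the replicate table and a
    summary with the mean index difference (first emotion minus second),
    its standard error, and a 95% percentile bootstrap interval.
    """
    if n_reps_per_emotion < 1:
        raise ValueError("n_reps_per_emotion must be >= 1")
    if not target_patches or not distractor_patches:
        raise ValueError("patch sets must be non-empty")
    emotions = list(target_patches)
    rng = np.random.default_rng(rng_seed)
    layout = layout or GridLayout.regular()
    model = model or IttiKochSaliency()

    rows = []
    for emo in emotions:
        pool = target_patches[emo]
        if not pool:
            raise ValueError(f"empty target patch set for {emo!r}")
        for rep in range(n_reps_per_emotion):
            slot = int(rng.integers(9))
            target = pool[int(rng.integers(len(pool)))]
            replace = len(distractor_patches) < 8
            idx = rng.choice(len(distractor_patches), size=8, replace=replace)
            patches: list[PatchParams] = []
            k = 0
            for s in range(9):
                if s == slot:
                    patches.append(target)
                else:
                    patches.append(distractor_patches[int(idx[k])])
                    k += 1
            lay = GridLayout(
                image_size=layout.image_size,
                rects=layout.rects,
                jitter=layout.jitter,
                target_slot=slot,
            )
            try:
                disp = generate_display(lay, patches, rng)
                res = saliency_index(model.transform(disp.image), disp.layout)
            except (ValueError, RuntimeError) as exc:
                raise RuntimeError(
                    f"replicate {rep} ({emo}, slot {slot}) failed: {exc}"
                ) from exc
            rows.append(
                dict(replicate=rep, emotion=emo, target_slot=slot, index=res.saliency_index)
            )
    table = pd.DataFrame(rows)

    summary: dict = {"emotions": emotions, "n_reps_per_emotion": n_reps_per_emotion}
    for emo in emotions:
        vals = table.loc[table.emotion == emo, "index"].to_numpy()
        summary[f"mean_index_{emo}"] = float(vals.mean())
        summary[f"se_index_{emo}"] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    if len(emotions) == 2:
        a = table.loc[table.emotion == emotions[0], "index"].to_numpy()
        b = table.loc[table.emotion == emotions[1], "index"].to_numpy()
        diff = a.mean() - b.mean()
        se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = (
                a[rng.integers(len(a), size=len(a))].mean()
                - b[rng.integers(len(b), size=len(b))].mean()
            )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        summary.update(
            mean_difference=float(diff),
            se_difference=se,
            ci95=[float(lo), float(hi)],
        )
    return table, summary


def image_motion(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    block_size: int = 20,
    normalized: bool = False,
) -> float:
    """Motion between two frames via block-reduced absolute difference.

    Each frame is reduced by summing intensities inside non-overlapping
    ``block_size x block_size`` pixel blocks (frames whose sides are not
    multiples of the block size are zero-padded); the metric is the sum
    of absolute differences of the two reduced images.  ``normalized``
    divides by the number of blocks, giving a per-block mean absolute
    difference that is comparable across frame sizes.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("frames must be 2-D grayscale")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    ra = block_reduce(a, (block_size, block_size), np.sum)
    rb = block_reduce(b, (block_size, block_size), np.sum)
    total = float(np.abs(ra - rb).sum())
    if normalized:
        total /= ra.size
    return total
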