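"""Parametric face-like stimulus patches and 3x3 grid displays.

Real posed-face photographs are license-restricted, so the salience
simulations run on synthetic face-like patches: an elliptical "head"
with eyes, brows and a mouth, rendered on a mid-gray background.  The
patches are parametric — contrast, mouth curvature (smile/frown), brow
angle, and an oriented grating texture — so displays can be built where
the target's low-level salience is controlled relative to the
distractors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PatchParams",
    "GridLayout",
    "SyntheticDisplay",
    "render_face_patch",
    "generate_display",
    "neutral_patch",
    "angry_patch",
    "happy_patch",
]


@dataclass(frozen=True)
class PatchParams:
    """Appearance of one face-like patch.

    contrast scales every deviation from the mid-gray background;
    mouth_curvature in [-1, 1] (negative = frown, positive = smile);
    brow_angle in radians (positive = inner ends lowered, an "angry"
    configuration); texture_amp/texture_freq/texture_angle add an
    oriented grating inside the face region (orientation energy).
    """

    contrast: float = 1.0
    mouth_curvature: float = 0.0
    brow_angle: float = 0.0
    texture_amp: float = 0.0
    texture_freq: float = 6.0
    texture_angle: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def neutral_patch(contrast: float = 1.0, **kw) -> PatchParams:
    return PatchParams(contrast=contrast, mouth_curvature=0.0, brow_angle=0.0, **kw)


def angry_patch(contrast: float = 1.0, **kw) -> PatchParams:
    return PatchParams(contrast=contrast, mouth_curvature=-0.8, brow_angle=0.45, **kw)


def happy_patch(contrast: float = 1.0, **kw) -> PatchParams:
    return PatchParams(contrast=contrast, mouth_curvature=0.8, brow_angle=-0.15, **kw)


def render_face_patch(size: int, params: PatchParams) -> np.ndarray:
    """Render one ``size x size`` patch with intensities in [0, 1].

    Deterministic in its arguments.  The face is left-right symmetric;
    all feature intensities are deviations from 0.5 scaled by contrast.
    """
    if size < 8:
        raise ValueError("patch size must be >= 8 pixels")
    ax = np.linspace(-1.0, 1.0, size)
    x, y = np.meshgrid(ax, ax)  # y grows downward

    dev = np.zeros((size, size))
    face = (x / 0.72) ** 2 + (y / 0.88) ** 2 <= 1.0
    dev[face] += 0.22

    for sx in (-0.28, 0.28):
        eye = (x - sx) ** 2 + (y + 0.22) ** 2 <= 0.10**2
        dev[eye] -= 0.55

    # brows: thin rotated bars above the eyes
    for sx, sgn in ((-0.28, 1.0), (0.28, -1.0)):
        xr = x - sx
        yr = y + 0.42
        ang = sgn * params.brow_angle
        u = xr * np.cos(ang) - yr * np.sin(ang)
        v = xr * np.sin(ang) + yr * np.cos(ang)
        brow = (np.abs(u) <= 0.16) & (np.abs(v) <= 0.035)
        dev[brow] -= 0.45

    # mouth: curved bar, curvature bends the ends up (smile) or down (frown)
    mx = x / 0.30
    curve = y - (0.42 - params.mouth_curvature * 0.12 * (mx**2 - 0.5))
    mouth = (np.abs(mx) <= 1.0) & (np.abs(curve) <= 0.045)
    dev[mouth] -= 0.45

    patch = 0.5 + params.contrast * dev
    if params.texture_amp > 0:
        th = params.texture_angle
        grating = np.sin(
            2 * np.pi * params.texture_freq * (x * np.cos(th) + y * np.sin(th)) / 2.0
        )
        patch = patch + params.contrast * params.texture_amp * grating * face
    return np.clip(patch, 0.0, 1.0)


@dataclass
class GridLayout:
    """Nine row-major slots on a raster.

    ``rects`` are (top, left, height, width) in pixels.  ``jitter`` is
    the maximum absolute displacement applied independently to each
    patch center along each axis.
    """

    image_size: tuple[int, int]
    rects: list[tuple[int, int, int, int]]
    jitter: float = 0.0
    target_slot: int | None = None

    def __post_init__(self) -> None:
        if len(self.rects) != 9:
            raise ValueError("a grid layout needs exactly nine regions")
        h, w = self.image_size
        for t, l, rh, rw in self.rects:
            if t < 0 or l < 0 or t + rh > h or l + rw > w:
                raise ValueError("region outside the raster")
        for i in range(9):
            for j in range(i + 1, 9):
                if _rects_overlap(self.rects[i], self.rects[j]):
                    raise ValueError(f"regions {i} and {j} overlap")
        if self.target_slot is not None and not (0 <= self.target_slot <= 8):
            raise ValueError("target_slot must be in 0..8")

    @classmethod
    def regular(
        cls,
        image_size: int | tuple[int, int] = 288,
        patch_size: int = 64,
        jitter: float = 0.0,
        target_slot: int | None = None,
    ) -> "GridLayout":
        """Evenly spaced 3x3 grid, margins equal to half the spacing."""
        if isinstance(image_size, int):
            image_size = (image_size, image_size)
        h, w = image_size
        rects = []
        for r in range(3):
            for c in range(3):
                cy = int(round((r + 0.5) * h / 3))
                cx = int(round((c + 0.5) * w / 3))
                rects.append((cy - patch_size // 2, cx - patch_size // 2, patch_size, patch_size))
        return cls(image_size=(h, w), rects=rects, jitter=jitter, target_slot=target_slot)

    def to_json(self, path=None) -> str:
        payload = {
            "image_size": list(self.image_size),
            "rects": [list(r) for r in self.rects],
            "jitter": self.jitter,
            "target_slot": self.target_slot,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GridLayout":
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            image_size=tuple(payload["image_size"]),
            rects=[tuple(r) for r in payload["rects"]],
            jitter=payload.get("jitter", 0.0),
            target_slot=payload.get("target_slot"),
        )


def _rects_overlap(a, b) -> bool:
    at, al, ah, aw = a
    bt, bl, bh, bw = b
    return not (at + ah <= bt or bt + bh <= at or al + aw <= bl or bl + bw <= al)


@dataclass
class SyntheticDisplay:
    image: np.ndarray
    layout: GridLayout
    target_slot: int | None = None
    patch_params: list[PatchParams] = field(default_factory=list)


def generate_display(
    layout: GridLayout,
    patch_params: list[PatchParams],
    rng: np.random.Generator | int | None = None,
    max_retries: int = 100,
) -> SyntheticDisplay:
    """Render nine patches at (jittered) grid positions on a 0.5-gray raster.

    Jittered positions that make regions overlap or leave the raster are
    re-drawn up to ``max_retries`` times, then an error is raised.
    Deterministic given the rng seed.
    """
    if len(patch_params) != 9:
        raise ValueError("need exactly nine patch parameter sets")
    rng = np.random.default_rng(rng)
    h, w = layout.image_size

    rects = list(layout.rects)
    if layout.jitter > 0:
        for attempt in range(max_retries + 1):
            cand = []
            ok = True
            for t, l, rh, rw in layout.rects:
                dt = int(round(rng.uniform(-layout.jitter, layout.jitter)))
                dl = int(round(rng.uniform(-layout.jitter, layout.jitter)))
                nt, nl = t + dt, l + dl
                if nt < 0 or nl < 0 or nt + rh > h or nl + rw > w:
                    ok = False
                cand.append((nt, nl, rh, rw))
            if ok:
                for i in range(9):
                    for j in range(i + 1, 9):
                        if _rects_overlap(cand[i], cand[j]):
                            ok = False
            if ok:
                rects = cand
                break
        else:
            raise RuntimeError(
                f"could not place nine non-overlapping jittered regions in {max_retries} tries"
            )

    image = np.full((h, w), 0.5)
    for (t, l, rh, rw), params in zip(rects, patch_params):
        if rh != rw:
            raise ValueError("patch regions must be square")
        image[t : t + rh, l : l + rw] = render_face_patch(rh, params)

    placed = GridLayout(
        image_size=layout.image_size,
        rects=rects,
        jitter=layout.jitter,
        target_slot=layout.target_slot,
    )
    return SyntheticDisplay(
        image=image,
        layout=placed,
        target_slot=layout.target_slot,
        patch_params=list(patch_params),
    )
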