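"""Synthetic stimuli: 1-D hue activation patterns and 2-D word templates.

Hues live on a one-dimensional array of color-tuned input nodes.  Each hue
is a contiguous unit-peak bump; *similar* hues (two hues of the same color
name) overlap by half their support, while different color names occupy
disjoint blocks of the array.  Words are fixed binary glyph masks on a small
grid — recognizability is irrelevant to the model, only pairwise
distinctness matters, so glyphs are derived deterministically (and
seedlessly) from the word label.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "ColorPattern",
    "WordTemplate",
    "COLOR_WORDS",
    "NEUTRAL_WORDS",
    "make_color",
    "overlap",
    "lexicon",
    "hue_layout",
    "write_fixtures",
]

COLOR_WORDS = ("red", "green", "blue", "yellow", "cyan", "magenta")
NEUTRAL_WORDS = ("raw", "great", "best", "yeasty", "cozy", "marital")

#: Word-glyph grid shape (rows, cols).
GLYPH_SHAPE = (5, 7)


@dataclass(frozen=True)
class ColorPattern:
    """Non-negative activation pattern over hue-tuned input nodes."""

    activations: np.ndarray
    hue_label: str

    def __post_init__(self) -> None:
        a = self.activations
        if np.any(a < 0):
            raise ValueError("hue activations must be non-negative")
        if a.max(initial=0.0) > 0 and not np.isclose(a.max(), 1.0):
            raise ValueError("hue patterns are unit-peak")

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.activations > 0)


@dataclass(frozen=True)
class WordTemplate:
    """Binary glyph mask for one lexicon word."""

    grid: np.ndarray
    word_label: str
    role: str  # "color" | "neutral"

    def __post_init__(self) -> None:
        g = self.grid
        if not np.isin(g, (0, 1)).all():
            raise ValueError("word grids are binary")
        if g.sum() < 1:
            raise ValueError("word grids need at least one active cell")

    @property
    def flat(self) -> np.ndarray:
        return self.grid.reshape(-1).astype(float)


def make_color(
    hue_center: int,
    width: int,
    array_size: int,
    shape: str = "boxcar",
    hue_label: str = "",
) -> ColorPattern:
    """Unit-peak bump of ``width`` nodes starting at ``hue_center``.

    ``shape`` is either a flat ``boxcar`` or a ``halfcos`` bump; both have
    the same contiguous support, so overlap arithmetic is shape-independent.
    """
    if hue_center < 0 or hue_center + width > array_size:
        raise ValueError(
            f"hue support [{hue_center}, {hue_center + width}) does not fit "
            f"array of size {array_size}"
        )
    a = np.zeros(array_size)
    if shape == "boxcar":
        a[hue_center : hue_center + width] = 1.0
    elif shape == "halfcos":
        phase = (np.arange(width) + 0.5) / width  # in (0, 1)
        a[hue_center : hue_center + width] = np.sin(np.pi * phase)
        a /= a.max()
    else:
        raise ValueError(f"unknown bump shape {shape!r}")
    return ColorPattern(a, hue_label or f"hue@{hue_center}")


def overlap(p: ColorPattern, q: ColorPattern) -> float:
    """Shared supra-zero support divided by the smaller support size."""
    if p.activations.shape != q.activations.shape:
        raise ValueError("patterns must live on the same hue array")
    sp, sq = set(p.support.tolist()), set(q.support.tolist())
    if not sp or not sq:
        return 0.0
    return len(sp & sq) / min(len(sp), len(sq))


def _glyph(label: str) -> np.ndarray:
    """Deterministic, seed-free binary mask derived from the word label."""
    n = GLYPH_SHAPE[0] * GLYPH_SHAPE[1]
    digest = hashlib.md5(label.encode("ascii")).digest()
    bits = np.unpackbits(np.frombuffer(digest, dtype=np.uint8))[:n]
    grid = bits.reshape(GLYPH_SHAPE).astype(np.int64)
    if grid.sum() == 0:  # pragma: no cover - md5 never yields all-zero here
        grid[0, 0] = 1
    return grid


def lexicon() -> List[WordTemplate]:
    """The twelve-word experiment lexicon: six color words, six neutral words.

    The generator is pure: identical calls yield bit-identical templates,
    and all twelve grids are pairwise distinct (checked at construction).
    """
    entries = [WordTemplate(_glyph(w), w, "color") for w in COLOR_WORDS]
    entries += [WordTemplate(_glyph(w), w, "neutral") for w in NEUTRAL_WORDS]
    seen = {}
    for t in entries:
        key = t.grid.tobytes()
        if key in seen:
            raise RuntimeError(
                f"glyphs for {seen[key]!r} and {t.word_label!r} collide"
            )
        seen[key] = t.word_label
    return entries


def hue_layout(
    width: int = 4,
    fan_out: int = 2,
    sibling_offset: int | None = None,
    gap: int = 2,
    margin: int = 2,
) -> Tuple[int, Dict[str, List[ColorPattern]]]:
    """Hue-array geometry: per color word, ``fan_out`` overlapping hue bumps.

    Sibling hues of one color overlap by half their width by default;
    different colors occupy disjoint blocks separated by ``gap`` silent
    nodes.  Returns ``(array_size, {color: [ColorPattern, ...]})``.
    """
    if sibling_offset is None:
        sibling_offset = max(width // 2, 1)
    block = width + sibling_offset * (fan_out - 1) + gap
    array_size = 2 * margin + len(COLOR_WORDS) * block - gap
    colors: Dict[str, List[ColorPattern]] = {}
    for c, color in enumerate(COLOR_WORDS):
        base = margin + c * block
        colors[color] = [
            make_color(
                base + k * sibling_offset,
                width,
                array_size,
                hue_label=f"{color}{k}",
            )
            for k in range(fan_out)
        ]
    return array_size, colors


def write_fixtures(path) -> None:
    """Serialize the default stimuli (hues + lexicon) to JSON for reuse."""
    array_size, colors = hue_layout()
    payload = {
        "hue_array_size": array_size,
        "hues": {
            color: [
                {"label": p.hue_label, "activations": p.activations.tolist()}
                for p in pats
            ]
            for color, pats in colors.items()
        },
        "lexicon": [
            {"word": t.word_label, "role": t.role, "grid": t.grid.tolist()}
            for t in lexicon()
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
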