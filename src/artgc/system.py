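"""Assembly of the full two-module model from an experiment config.

Builds the color module (hue-tuned input array, one committed category per
hue), the visual-word-form (VWF) module (glyph-grid input, one committed
category per lexicon word) and the associative map grouping the hues of
each color under its color word.  Learning is off: all replication
experiments run on these pre-committed weights.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .assoc import AssociativeMap, build_map
from .circuit import ARTModule, ARTParams, ARTWeights
from .config import ExperimentConfig
from .stimuli import COLOR_WORDS, ColorPattern, WordTemplate, hue_layout, lexicon

__all__ = ["ModelSystem", "build_system"]


def _override(params: ARTParams, overrides: Dict[str, float]) -> ARTParams:
    return dataclasses.replace(params, **overrides) if overrides else params


@dataclass
class ModelSystem:
    """The assembled model: two ART modules, the map, and stimulus lookups."""

    config: ExperimentConfig
    color: ARTModule
    vwf: ARTModule
    amap: AssociativeMap
    hues: Dict[str, List[ColorPattern]]
    words: List[WordTemplate]
    hue_index: Dict[str, int]  # hue label -> color-module F2 index
    word_index: Dict[str, int]  # word label -> VWF F2 index
    n_hue_nodes: int

    def hue_pattern(self, color: str, variant: int = 0) -> ColorPattern:
        """The sensory pattern of one hue of ``color`` (default: first hue)."""
        return self.hues[color][variant]

    def word_template(self, word: str) -> WordTemplate:
        for t in self.words:
            if t.word_label == word:
                return t
        raise KeyError(f"unknown word {word!r}")

    def word_role(self, word: str) -> str:
        return self.word_template(word).role

    def priming_from_word(self, word: str) -> np.ndarray:
        """Expectation drive over color F2 created by one lexicon word."""
        winner = self.word_index[word]
        return self.amap.propagate_word_to_color(
            winner, gain=self.config.priming_gain
        )

    def fresh(self) -> "ModelSystem":
        """A new system with identical configuration and zeroed state."""
        return build_system(self.config)


def build_system(config: Optional[ExperimentConfig] = None) -> ModelSystem:
    config = config or ExperimentConfig()
    s = config.stimuli
    n_hue, hues = hue_layout(
        width=s.hue_width, fan_out=s.fan_out, gap=s.gap, margin=s.margin
    )
    if s.bump_shape != "boxcar":
        from .stimuli import make_color

        hues = {
            color: [
                make_color(
                    int(p.support[0]), s.hue_width, n_hue, s.bump_shape, p.hue_label
                )
                for p in pats
            ]
            for color, pats in hues.items()
        }

    # Color module: one committed category per hue, template = bump support.
    hue_labels: List[str] = []
    color_templates = []
    for color in COLOR_WORDS:
        for p in hues[color]:
            hue_labels.append(p.hue_label)
            color_templates.append((p.activations > 0).astype(float))
    color_weights = ARTWeights.from_templates(np.asarray(color_templates))
    hue_index = {lab: j for j, lab in enumerate(hue_labels)}

    # VWF module: one committed category per lexicon word.
    words = lexicon()
    vwf_templates = np.asarray([t.flat for t in words])
    vwf_weights = ARTWeights.from_templates(vwf_templates)
    word_index = {t.word_label: j for j, t in enumerate(words)}

    taus = config.r_time_constants()
    color_params = _override(
        dataclasses.replace(ARTParams(), vigilance=config.vigilance_color),
        config.color_overrides,
    )
    vwf_params = _override(
        dataclasses.replace(ARTParams(), vigilance=config.vigilance_word),
        config.word_overrides,
    )
    color = ARTModule(
        "color", n_hue, color_weights, color_params, r_time_constants=taus
    )
    # The word module always runs with the slow reset preset: the R-speed
    # manipulation of the task applies to the color module only, and a slow
    # orienting node keeps the many-candidate word race reset-free.
    vwf = ARTModule(
        "vwf",
        vwf_templates.shape[1],
        vwf_weights,
        vwf_params,
        r_preset="slow",
        r_time_constants=taus,
    )

    amap = build_map(
        [
            (
                color_word,
                [hue_index[p.hue_label] for p in hues[color_word]],
                word_index[color_word],
            )
            for color_word in COLOR_WORDS
        ],
        n_color_categories=color_weights.n_categories,
        n_word_categories=vwf_weights.n_categories,
    )
    return ModelSystem(
        config=config,
        color=color,
        vwf=vwf,
        amap=amap,
        hues=hues,
        words=words,
        hue_index=hue_index,
        word_index=word_index,
        n_hue_nodes=n_hue,
    )
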