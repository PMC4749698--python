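"""The inter-ART associative map (F4) linking the word and color modules.

Map nodes are pass-through gates with no intrinsic dynamics: a resonant
word-category node excites its concept node, which in turn excites *all*
hue-category nodes grouped under that color label (different hues of the
same color share one name, so the fan-out is greater than one).  Neutral
words have concept nodes with no color links and therefore no access to the
color module.  The reverse direction maps a resonant hue category onto the
single word naming it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = ["AssociativeMap", "build_map"]


@dataclass(frozen=True)
class AssociativeMap:
    """Bidirectional word-category <-> hue-category association.

    ``color_links[k]`` is the set of color-module F2 indices excited by map
    node ``k``; ``vwf_links[k]`` is the single word-module F2 index bound to
    it.  Words without color semantics simply have no map node.
    """

    labels: Tuple[str, ...]
    color_links: Tuple[Tuple[int, ...], ...]
    vwf_links: Tuple[int, ...]
    n_color_categories: int
    n_word_categories: int

    def __post_init__(self) -> None:
        if len({*self.labels}) != len(self.labels):
            raise ValueError("duplicate word labels in associative map")
        if len(self.vwf_links) != len(set(self.vwf_links)):
            raise ValueError("a word category may bind to at most one map node")
        seen: set = set()
        for links in self.color_links:
            if not links:
                raise ValueError("map nodes must excite at least one hue node")
            if seen & set(links):
                raise ValueError(
                    "hue categories must be disjoint across map nodes "
                    "(a hue names at most one color word)"
                )
            seen |= set(links)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def _word_to_node(self) -> Dict[int, int]:
        return {w: k for k, w in enumerate(self.vwf_links)}

    def _hue_to_node(self) -> Dict[int, int]:
        return {h: k for k, links in enumerate(self.color_links) for h in links}

    def propagate_word_to_color(self, vwf_winner: int, gain: float = 1.0) -> np.ndarray:
        """Expectation drive over color-module F2 given a resonant word node.

        All hues grouped under the word's color receive the same drive; a
        neutral word (no map node) yields the zero vector.
        """
        if not 0 <= vwf_winner < self.n_word_categories:
            raise ValueError(f"unknown word-category index {vwf_winner}")
        drive = np.zeros(self.n_color_categories)
        node = self._word_to_node().get(vwf_winner)
        if node is not None:
            drive[list(self.color_links[node])] = gain
        return drive

    def propagate_color_to_word(self, color_winner: int, gain: float = 1.0) -> np.ndarray:
        """Expectation drive over word-module F2 given a resonant hue node."""
        if not 0 <= color_winner < self.n_color_categories:
            raise ValueError(f"unknown hue-category index {color_winner}")
        drive = np.zeros(self.n_word_categories)
        node = self._hue_to_node().get(color_winner)
        if node is not None:
            drive[self.vwf_links[node]] = gain
        return drive

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "labels": list(self.labels),
                    "color_links": [list(l) for l in self.color_links],
                    "vwf_links": list(self.vwf_links),
                    "n_color_categories": self.n_color_categories,
                    "n_word_categories": self.n_word_categories,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "AssociativeMap":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tuple(d["labels"]),
            tuple(tuple(l) for l in d["color_links"]),
            tuple(d["vwf_links"]),
            d["n_color_categories"],
            d["n_word_categories"],
        )


def build_map(
    assignments: Sequence[Tuple[str, Sequence[int], int]],
    n_color_categories: int,
    n_word_categories: int,
) -> AssociativeMap:
    """Construct a validated map from (label, hue index set, word index) triples.

    Overlapping hue sets or duplicate labels are construction errors; an
    empty assignment list yields an empty map whose propagation is all-zero.
    """
    labels = tuple(a[0] for a in assignments)
    color_links = tuple(tuple(sorted(set(a[1]))) for a in assignments)
    vwf_links = tuple(int(a[2]) for a in assignments)
    for links in color_links:
        for h in links:
            if not 0 <= h < n_color_categories:
                raise ValueError(f"hue index {h} out of range")
    for wi in vwf_links:
        if not 0 <= wi < n_word_categories:
            raise ValueError(f"word index {wi} out of range")
    return AssociativeMap(
        labels, color_links, vwf_links, n_color_categories, n_word_categories
    )
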