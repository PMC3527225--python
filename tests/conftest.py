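"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ishlayer import ExpressionImage


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never share code with the package)


def brute_force_lbp_code(px: np.ndarray, i: int, j: int, radius: float = 2.0) -> int:
    """Per-point LBP oracle: interpolate each of the 8 samples independently."""
    code = 0
    for b in range(8):
        theta = 2.0 * math.pi * b / 8.0
        r = i + round(-radius * math.sin(theta), 8)
        c = j + round(radius * math.cos(theta), 8)
        r0, c0 = math.floor(r), math.floor(c)
        fr, fc = r - r0, c - c0
        # accumulate the four corner contributions explicitly
        val = 0.0
        for dr_, wr in ((0, 1.0 - fr), (1, fr)):
            for dc_, wc in ((0, 1.0 - fc), (1, fc)):
                w = wr * wc
                if w != 0.0:
                    val += w * px[r0 + dr_, c0 + dc_]
        if val >= px[i, j]:
            code |= 1 << b
    return code


def brute_force_lbp_histogram(px: np.ndarray, radius: float = 2.0) -> np.ndarray:
    """Exhaustive per-pixel LBP histogram over interior pixels."""
    m = math.ceil(radius)
    h, w = px.shape
    hist = np.zeros(256, dtype=int)
    for i in range(m, h - m):
        for j in range(m, w - m):
            hist[brute_force_lbp_code(px, i, j, radius)] += 1
    return hist


def brute_force_auc(scores, labels) -> float:
    """All-pairs Mann-Whitney count with half credit for ties."""
    scores = list(scores)
    labels = list(labels)
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture
def random_image():
    """Factory for seeded random intensity images."""

    def make(seed: int, shape=(16, 16), gene="g", image="i") -> ExpressionImage:
        rng = np.random.default_rng(seed)
        return ExpressionImage(gene, image, rng.random(shape))

    return make
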