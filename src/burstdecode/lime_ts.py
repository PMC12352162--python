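"""Local interpretable model-agnostic explanations (LIME) adapted to
multichannel time series.

Each row of a trial tensor (one electrode's high-gamma or beta series) is
tiled into non-overlapping time segments.  Perturbed copies of the tensor
zero out random subsets of (row, segment) cells - zero being the natural
"no burst" baseline of the non-negative convolved series - and a linear
surrogate is fitted by plain least squares to the model probabilities of the
copies.  Cells are ranked by the magnitude of their surrogate coefficient;
the top 20% are flagged influential, and flags are aggregated across trials
into a frequency map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Segmentation", "Explanation", "perturb", "explain", "aggregate",
           "plot_frequency_map"]

INFLUENTIAL_FRACTION = 0.20


@dataclass(frozen=True)
class Segmentation:
    """Non-overlapping tiling of each tensor row into time segments."""

    n_rows: int
    n_samples: int
    n_segments: int = 10

    def __post_init__(self):
        if not 1 <= self.n_segments <= self.n_samples:
            raise ValueError("n_segments must lie in [1, n_samples]")

    @property
    def total(self) -> int:
        return self.n_rows * self.n_segments

    def bounds(self) -> np.ndarray:
        """(n_segments + 1) sample boundaries; the last segment absorbs the
        remainder."""
        return np.linspace(0, self.n_samples, self.n_segments + 1).astype(int)

    def apply_mask(self, tensor: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Zero the cells where ``mask`` (rows x segments) is set."""
        out = tensor.copy()
        b = self.bounds()
        for r, s in zip(*np.nonzero(mask)):
            out[r, b[s]:b[s + 1]] = 0.0
        return out


@dataclass(frozen=True)
class Explanation:
    """Surrogate coefficients per (row, segment) and the influential flags."""

    segmentation: Segmentation
    coefficients: np.ndarray  # (n_rows, n_segments)
    influential: np.ndarray  # bool, same shape

    @property
    def n_influential(self) -> int:
        return int(self.influential.sum())


def perturb(tensor: np.ndarray, segmentation: Segmentation, n_samples: int,
            seed: int, p: float = 0.5):
    """Generate perturbed copies and their binary masks.

    Each copy zeroes an independent Bernoulli(``p``) subset of (row, segment)
    cells, distributed across all rows.  Returns ``(copies, masks)`` with
    ``copies[i] = tensor`` wherever ``masks[i]`` is 0.
    """
    if n_samples < 2 * segmentation.total:
        raise ValueError("n_samples must be >= 2 x total segments for an "
                         "identifiable surrogate")
    rng = np.random.default_rng(seed)
    masks = rng.random((n_samples, segmentation.n_rows,
                        segmentation.n_segments)) < p
    copies = np.stack([segmentation.apply_mask(tensor, m) for m in masks])
    return copies, masks


def explain(model_fn, tensor: np.ndarray, segmentation: Segmentation,
            n_samples: int = 0, seed: int = 0, p: float = 0.5) -> Explanation:
    """Fit the linear surrogate and flag the top-20% segments by |coefficient|.

    ``model_fn`` maps a (n_copies, n_rows, n_samples) stack to predicted
    probabilities.  ``n_samples`` defaults to 4x the number of cells.
    """
    if n_samples <= 0:
        n_samples = 4 * segmentation.total
    copies, masks = perturb(tensor, segmentation, n_samples, seed, p=p)
    probs = np.asarray(model_fn(copies), dtype=np.float64).reshape(-1)
    design = np.column_stack([np.ones(n_samples),
                              masks.reshape(n_samples, -1).astype(np.float64)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError(
            "singular surrogate design; increase n_samples")
    coef, *_ = np.linalg.lstsq(design, probs, rcond=None)
    coefs = coef[1:].reshape(segmentation.n_rows, segmentation.n_segments)
    k = math.ceil(INFLUENTIAL_FRACTION * segmentation.total)
    order = np.argsort(np.abs(coefs), axis=None)[::-1]
    flags = np.zeros(segmentation.total, dtype=bool)
    flags[order[:k]] = True
    return Explanation(segmentation=segmentation, coefficients=coefs,
                       influential=flags.reshape(coefs.shape))


def aggregate(explanations: list[Explanation]) -> np.ndarray:
    """Count, per (row, segment), how many trials flagged it influential."""
    if not explanations:
        raise ValueError("no explanations to aggregate")
    seg = explanations[0].segmentation
    if any(e.segmentation != seg for e in explanations):
        raise ValueError("explanations use different segmentations")
    return np.sum([e.influential for e in explanations], axis=0)


def plot_frequency_map(freq_map: np.ndarray, out_path, row_names=None) -> None:
    """Render the across-trial influence counts as a rows x segments heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, max(2, 0.4 * freq_map.shape[0])))
    im = ax.imshow(freq_map, aspect="auto", cmap="viridis")
    ax.set_xlabel("time segment")
    ax.set_ylabel("electrode / band row")
    if row_names:
        ax.set_yticks(range(len(row_names)), row_names, fontsize=7)
    fig.colorbar(im, ax=ax, label="trials flagged influential")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
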