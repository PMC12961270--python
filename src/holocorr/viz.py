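"""Integrated correlation-map figure: central heatmap, metadata and
cross-layer correlation blocks.

The central omics layer's hub profiles form the middle heatmap (modules x
samples) with its dendrogram; metadata correlations sit to the left, one
correlation block per additional omics layer to the right.  Every block
shares the central layer's hierarchical row order, correlation blocks use a
diverging colour scale fixed to [-1, 1], and significance annotations are
overlaid per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import matplotlib
import numpy as np

matplotlib.use("Agg")  # headless backend; figures are always written to file
import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import pdist

from .correlate import CorrelationResults
from .io import OmicsLayer

logger = logging.getLogger(__name__)


@dataclass
class CentralOrdering:
    """Hierarchical ordering of the central layer's hubs.

    ``merge_tree`` is a scipy-style linkage matrix (or None for a single
    hub); ``leaf_order`` is the resulting permutation of hub ids.
    """

    merge_tree: np.ndarray | None
    leaf_order: list[str]


def order_central_layer(
    hub_layer: OmicsLayer,
    distance: str = "correlation",
    linkage_method: str = "average",
) -> CentralOrdering:
    """Hierarchically cluster the central layer's hubs.

    ``distance="correlation"`` uses 1 - Pearson r between hub profiles, the
    natural metric for co-variation; ``"euclidean"`` is offered for scaled
    data.  Leaf order follows scipy's deterministic tie-break (the cluster
    containing the smaller original index leads at each merge).
    """
    if distance not in ("correlation", "euclidean"):
        raise ValueError(f"unknown distance {distance!r}")
    if linkage_method not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage {linkage_method!r}")
    if hub_layer.has_missing():
        raise ValueError("central ordering requires a complete hub layer")
    n = hub_layer.n_features
    if n < 2:
        logger.warning("only %d hub(s); trivial ordering, no dendrogram", n)
        return CentralOrdering(None, list(hub_layer.feature_ids))
    profiles = hub_layer.values.T  # hubs x samples
    cond = pdist(profiles, metric=distance)
    Z = linkage(cond, method=linkage_method)
    leaves = dendrogram(Z, no_plot=True)["leaves"]
    return CentralOrdering(Z, [hub_layer.feature_ids[i] for i in leaves])


def central_heatmap_matrix(
    hub_layer: OmicsLayer,
    ordering: CentralOrdering | None = None,
    scaling: str = "row-z",
    sample_order: list[str] | None = None,
):
    """Build the central display matrix (modules x samples).

    ``row-z`` (default) standardizes each hub row to mean 0 / sd 1 so
    profiles with different dynamic ranges share one colour scale; a
    zero-variance row renders as zeros with a warning.  Rows follow the
    hierarchical ``ordering`` when given.
    """
    import pandas as pd

    if scaling not in ("row-z", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    frame = hub_layer.to_frame().T  # modules/hubs x samples
    if ordering is not None:
        frame = frame.loc[ordering.leaf_order]
    if sample_order is not None:
        frame = frame[sample_order]
    if scaling == "row-z":
        vals = frame.to_numpy(dtype=float)
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        flat = (sd.ravel() == 0)
        if flat.any():
            logger.warning(
                "zero-variance hub row(s) %s rendered as zeros",
                [frame.index[i] for i in np.flatnonzero(flat)],
            )
        sd[sd == 0] = 1.0
        frame = pd.DataFrame(
            (vals - mu) / sd, index=frame.index, columns=frame.columns
        )
    return frame


@dataclass
class IntegratedFigureSpec:
    """Layout contract for the integrated overview figure.

    ``central`` is the display matrix (modules x samples, rows already in
    dendrogram order); ``left_blocks`` hold metadata correlations and
    ``right_blocks`` one entry per additional omics layer.  Every block's row
    ids must equal the central row order — blocks are never silently
    reindexed.
    """

    central: "object"  # pandas DataFrame, modules x samples
    ordering: CentralOrdering
    left_blocks: list[CorrelationResults] = field(default_factory=list)
    right_blocks: list[CorrelationResults] = field(default_factory=list)
    sample_annotations: dict[str, list[str]] | None = None
    row_label_map: dict[str, str] | None = None

    def validate(self) -> None:
        rows = list(self.central.index)
        if sorted(rows) != sorted(self.ordering.leaf_order) or rows != list(
            self.ordering.leaf_order
        ):
            raise ValueError("central matrix rows do not follow the leaf order")
        for side, blocks in (("left", self.left_blocks), ("right", self.right_blocks)):
            for blk in blocks:
                if list(blk.row_ids) != rows:
                    raise ValueError(
                        f"{side} block {blk.x_id}__{blk.y_id}: row order differs "
                        "from the central ordering (reorder upstream; no silent "
                        "reindexing)"
                    )
        if self.sample_annotations:
            n = self.central.shape[1]
            for name, vals in self.sample_annotations.items():
                if len(vals) != n:
                    raise ValueError(
                        f"sample annotation {name!r} has {len(vals)} values "
                        f"for {n} samples"
                    )


def assemble_integrated_figure(
    spec: IntegratedFigureSpec,
    path,
    fig_format: str = "svg",
    dpi: int = 150,
) -> dict:
    """Render and write the integrated overview figure.

    Layout (columns, left to right): dendrogram, metadata correlation
    block(s), the central heatmap, one correlation block per other omics
    layer.  Correlation blocks share a diverging colormap pinned to [-1, 1];
    annotation strings (stars, p-values or coefficients) are drawn cell by
    cell.  Returns a small manifest dict (path, block and annotation counts).
    """
    spec.validate()
    if fig_format not in ("svg", "pdf", "png"):
        raise ValueError(f"unknown figure format {fig_format!r}")

    central = spec.central
    n_rows, n_samples = central.shape
    blocks = [("left", b) for b in spec.left_blocks] + [
        ("right", b) for b in spec.right_blocks
    ]

    width_ratios = [1.2]  # dendrogram
    for b in spec.left_blocks:
        width_ratios.append(max(0.6, 0.28 * len(b.col_ids)))
    width_ratios.append(max(3.0, 0.28 * n_samples))
    for b in spec.right_blocks:
        width_ratios.append(max(0.6, 0.28 * len(b.col_ids)))

    n_annot = 1 if spec.sample_annotations else 0
    height_ratios = ([0.4] * n_annot) + [max(2.0, 0.3 * n_rows), 0.25]
    fig_w = min(24.0, 1.6 + 0.9 * sum(width_ratios))
    fig_h = min(18.0, 1.2 + 0.9 * sum(height_ratios))
    fig = plt.figure(figsize=(fig_w, fig_h))
    gs = fig.add_gridspec(
        nrows=1 + n_annot + 1,
        ncols=len(width_ratios),
        width_ratios=width_ratios,
        height_ratios=height_ratios,
        hspace=0.08, wspace=0.08,
    )
    main_row = n_annot

    # dendrogram
    ax_d = fig.add_subplot(gs[main_row, 0])
    if spec.ordering.merge_tree is not None:
        dendrogram(
            spec.ordering.merge_tree, ax=ax_d, orientation="left",
            no_labels=True, color_threshold=0, above_threshold_color="0.3",
        )
        ax_d.invert_yaxis()  # match heatmap row direction (top row first)
    ax_d.axis("off")

    col = 1
    n_labels_drawn = 0
    corr_im = None
    for b in spec.left_blocks:
        ax = fig.add_subplot(gs[main_row, col])
        corr_im, drawn = _draw_corr_block(ax, b, spec.row_label_map)
        n_labels_drawn += drawn
        ax.set_title(b.y_id, fontsize=9)
        col += 1

    # central heatmap
    ax_c = fig.add_subplot(gs[main_row, col])
    vals = central.to_numpy(dtype=float)
    vmax = np.nanmax(np.abs(vals)) if vals.size else 1.0
    im_c = ax_c.imshow(
        vals, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
        interpolation="nearest",
    )
    ax_c.set_xticks(range(n_samples))
    ax_c.set_xticklabels(central.columns, rotation=90, fontsize=6)
    labmap = spec.row_label_map or {}
    ax_c.set_yticks(range(n_rows))
    ax_c.set_yticklabels([labmap.get(r, r) for r in central.index], fontsize=7)
    ax_c.set_title("central layer", fontsize=10)
    central_col = col
    col += 1

    for b in spec.right_blocks:
        ax = fig.add_subplot(gs[main_row, col])
        corr_im, drawn = _draw_corr_block(ax, b, spec.row_label_map)
        n_labels_drawn += drawn
        ax.set_yticks([])
        ax.set_title(b.y_id, fontsize=9)
        col += 1

    # sample annotation tracks above the central heatmap
    if spec.sample_annotations:
        ax_a = fig.add_subplot(gs[0, central_col], sharex=ax_c)
        track = np.zeros((len(spec.sample_annotations), n_samples))
        names = []
        for t, (name, values) in enumerate(spec.sample_annotations.items()):
            levels = sorted(set(values))
            track[t] = [levels.index(v) for v in values]
            names.append(name)
        ax_a.imshow(
            track, aspect="auto", interpolation="nearest",
            cmap=ListedColormap(plt.cm.tab10.colors),
        )
        ax_a.set_yticks(range(len(names)))
        ax_a.set_yticklabels(names, fontsize=7)
        ax_a.tick_params(labelbottom=False, bottom=False)

    # colorbars along the bottom
    ax_cb1 = fig.add_subplot(gs[main_row + 1, central_col])
    fig.colorbar(im_c, cax=ax_cb1, orientation="horizontal")
    ax_cb1.set_xlabel("abundance (row z)", fontsize=7)
    if corr_im is not None and len(width_ratios) > 2:
        cb_col = len(width_ratios) - 1 if spec.right_blocks else 1
        ax_cb2 = fig.add_subplot(gs[main_row + 1, cb_col])
        fig.colorbar(corr_im, cax=ax_cb2, orientation="horizontal")
        ax_cb2.set_xlabel("correlation", fontsize=7)

    fig.savefig(str(path), format=fig_format, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return {
        "path": str(path),
        "format": fig_format,
        "n_left_blocks": len(spec.left_blocks),
        "n_right_blocks": len(spec.right_blocks),
        "n_annotation_labels": n_labels_drawn,
    }


def _draw_corr_block(ax, block: CorrelationResults, row_label_map=None):
    """imshow one correlation block with its annotation overlay."""
    vals = block.r
    im = ax.imshow(
        vals, aspect="auto", cmap="RdBu_r", vmin=-1.0, vmax=1.0,
        interpolation="nearest",
    )
    drawn = 0
    for i in range(vals.shape[0]):
        for j in range(vals.shape[1]):
            lab = block.labels[i, j]
            if lab:
                ax.text(
                    j, i, lab, ha="center", va="center", fontsize=6,
                    color="black",
                )
                drawn += 1
    ax.set_xticks(range(len(block.col_ids)))
    ax.set_xticklabels(block.col_ids, rotation=90, fontsize=6)
    labmap = row_label_map or {}
    ax.set_yticks(range(len(block.row_ids)))
    ax.set_yticklabels([labmap.get(r, r) for r in block.row_ids], fontsize=7)
    return im, drawn
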