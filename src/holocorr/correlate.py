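"""All-pairs correlation between two omics layers with significance control.

Hub tables are small (one column per module), so after module reduction an
exhaustive hub x hub correlation scan is statistically affordable: every pair
gets a coefficient (Pearson, Spearman or Kendall tau-b), a two-sided p-value,
and an adjustment over the full matrix treated as one testing family
(Benjamini-Hochberg FDR by default).  Metadata variables join the same
machinery after being encoded into a numeric layer (binary -> 0/1,
categorical -> one-hot indicators).

Missing data is handled by the three conventional policies: ``all.obs``
(refuse), ``complete.obs`` (casewise deletion over both layers, once) and
``pairwise.complete.obs`` (per-pair deletion).  Pairs that retain fewer than
``min_pairs`` samples are reported as missing rather than as noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import OmicsLayer, SampleMetadata

logger = logging.getLogger(__name__)

_ADJUST_METHODS = {"fdr": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}


@dataclass
class CorrelationOptions:
    """Method, missing-data policy, adjustment and annotation settings.

    ``star_thresholds`` are three strictly decreasing p cutoffs applied to the
    *adjusted* p-values: below the first earns "*", below the second "**",
    below the third "***".
    """

    method: str = "pearson"
    use: str = "pairwise.complete.obs"
    adjust: str = "fdr"
    annotation: str = "asterisks"
    star_thresholds: tuple = (0.05, 0.01, 0.001)
    min_pairs: int = 5

    def __post_init__(self) -> None:
        if self.method not in ("pearson", "spearman", "kendall"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.use not in ("all.obs", "complete.obs", "pairwise.complete.obs"):
            raise ValueError(f"unknown missing-data policy {self.use!r}")
        if self.adjust not in ("fdr", "bonferroni", "holm", "none"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")
        if self.annotation not in ("asterisks", "pvalue", "correlation"):
            raise ValueError(f"unknown annotation mode {self.annotation!r}")
        t = tuple(self.star_thresholds)
        if len(t) != 3 or not (0 < t[2] < t[1] < t[0] < 1):
            raise ValueError("star_thresholds must be three descending values in (0,1)")
        self.star_thresholds = t
        if self.min_pairs < 3:
            raise ValueError("min_pairs must be >= 3")


# ---------------------------------------------------------------------------
# single-pair test
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom)


def _kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(len(x), k=1)
    prod = dx[iu] * dy[iu]
    con_minus_dis = prod.sum()
    tx = (dx[iu] != 0).sum()  # pairs untied in x
    ty = (dy[iu] != 0).sum()
    return float(con_minus_dis / np.sqrt(tx * ty))


def _kendall_p_normal(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p for tau-b from the tie-corrected normal approximation."""
    n = len(x)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    s = float((dx[iu] * dy[iu]).sum())

    def tie_counts(v):
        _, counts = np.unique(v, return_counts=True)
        return counts[counts > 1].astype(float)

    t = tie_counts(x)
    u = tie_counts(y)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = (t * (t - 1) * (2 * t + 5)).sum()
    vu = (u * (u - 1) * (2 * u + 5)).sum()
    v1 = (t * (t - 1)).sum() * (u * (u - 1)).sum() / (2.0 * n * (n - 1))
    v2 = (
        (t * (t - 1) * (t - 2)).sum() * (u * (u - 1) * (u - 2)).sum()
        / (9.0 * n * (n - 1) * (n - 2))
    )
    var = (v0 - vt - vu) / 18.0 + v1 + v2
    if var <= 0:
        return np.nan
    z = s / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def _t_pvalue(r: float, n: int) -> float:
    """Two-sided p from t = r*sqrt((n-2)/(1-r^2)) on n-2 df."""
    if abs(r) >= 1.0:
        return 0.0
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def t_tail_pvalue(r: float, n: int) -> float:
    """Independent evaluation of the same tail via the incomplete beta."""
    if abs(r) >= 1.0:
        return 0.0
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(special.betainc(0.5 * df, 0.5, df / (df + t * t)))


def correlation_test(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "pearson",
    min_pairs: int = 5,
) -> tuple[float, float, int]:
    """Correlation coefficient, two-sided p-value and pair count for (x, y).

    Missing entries are pair-deleted first.  Pearson uses the exact t
    reference on n-2 degrees of freedom; Spearman is Pearson on mid-ranks
    with the same t approximation at every n; Kendall is tau-b with the
    tie-corrected normal approximation (exact enumeration for n <= 8 without
    ties).  A perfect |r| = 1 reports p = 0.  Pairs left constant after
    deletion, or shorter than ``min_pairs``, report (nan, nan, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    if n < min_pairs:
        logger.info("pair has only n=%d complete observations (< %d)", n, min_pairs)
        return (np.nan, np.nan, n)
    if x.std() == 0 or y.std() == 0:
        logger.info("constant vector after pair deletion; correlation undefined")
        return (np.nan, np.nan, n)

    if method == "pearson":
        r = _pearson(x, y)
        return (r, _t_pvalue(r, n), n)
    if method == "spearman":
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rho = _pearson(rx, ry)
        return (rho, _t_pvalue(rho, n), n)
    if method == "kendall":
        tau = _kendall_tau_b(x, y)
        has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
        if abs(tau) >= 1.0 - 1e-15:
            p = 0.0
        elif n <= 8 and not has_ties:
            p = float(stats.kendalltau(x, y, method="exact").pvalue)
        else:
            p = _kendall_p_normal(x, y)
        return (tau, p, n)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# p-value adjustment and annotation
# ---------------------------------------------------------------------------

def adjust_pvalues(p: np.ndarray, method: str = "fdr") -> np.ndarray:
    """Adjust a (possibly NaN-holding) p-value array for multiple testing.

    ``fdr`` is Benjamini-Hochberg step-up, ``holm`` the step-down Bonferroni,
    ``bonferroni`` plain min(1, m*p); missing entries stay missing and do not
    count toward the family size m.
    """
    p = np.asarray(p, dtype=float)
    finite = ~np.isnan(p)
    if finite.any() and (p[finite].min() < 0 or p[finite].max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {method!r}")
    out = np.full(p.shape, np.nan)
    flat = p[finite]
    if flat.size:
        out[finite] = multipletests(flat, method=_ADJUST_METHODS[method])[1]
    return out


def significance_labels(
    r: np.ndarray,
    p_adj: np.ndarray,
    annotation: str = "asterisks",
    star_thresholds: tuple = (0.05, 0.01, 0.001),
) -> np.ndarray:
    """Render per-cell annotation strings from coefficients and adjusted p."""
    t1, t2, t3 = star_thresholds
    out = np.empty(np.shape(r), dtype=object)
    it = np.nditer(np.asarray(p_adj, dtype=float), flags=["multi_index"])
    r = np.asarray(r, dtype=float)
    for val in it:
        idx = it.multi_index
        pv = float(val)
        if annotation == "asterisks":
            if np.isnan(pv):
                out[idx] = ""
            elif pv < t3:
                out[idx] = "***"
            elif pv < t2:
                out[idx] = "**"
            elif pv < t1:
                out[idx] = "*"
            else:
                out[idx] = ""
        elif annotation == "pvalue":
            out[idx] = "" if np.isnan(pv) else f"{pv:.3g}"
        else:  # correlation
            rv = r[idx]
            out[idx] = "" if np.isnan(rv) else f"{rv:.2f}"
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class CrossCorrelation:
    """All-pairs correlation model between two aligned layers.

    The two layers must share an identical ordered sample list (enforced).
    ``fit()`` returns a :class:`CorrelationResults` carrying aligned matrices
    of coefficients, raw and adjusted p-values, per-pair sample counts and
    annotation labels.
    """

    def __init__(
        self,
        X: OmicsLayer,
        Y: OmicsLayer,
        options: CorrelationOptions | None = None,
    ):
        if X.sample_ids != Y.sample_ids:
            raise ValueError(
                f"layers {X.layer_id!r} and {Y.layer_id!r} are not aligned on "
                "the same ordered sample list; run align_samples first"
            )
        self.X = X
        self.Y = Y
        self.options = options or CorrelationOptions()

    def fit(self) -> "CorrelationResults":
        opts = self.options
        Xv, Yv = self.X.values, self.Y.values

        if opts.use == "all.obs":
            for layer, vals in ((self.X, Xv), (self.Y, Yv)):
                nan_idx = np.argwhere(np.isnan(vals))
                if nan_idx.size:
                    i, j = nan_idx[0]
                    raise ValueError(
                        f"all.obs: missing value in layer {layer.layer_id!r} at "
                        f"sample {layer.sample_ids[i]!r}, "
                        f"feature {layer.feature_ids[j]!r}"
                    )
        elif opts.use == "complete.obs":
            keep = ~(np.isnan(Xv).any(axis=1) | np.isnan(Yv).any(axis=1))
            if not keep.any():
                raise ValueError("complete.obs leaves no samples")
            Xv, Yv = Xv[keep], Yv[keep]

        nx, ny = Xv.shape[1], Yv.shape[1]
        r = np.full((nx, ny), np.nan)
        p = np.full((nx, ny), np.nan)
        n_pairs = np.zeros((nx, ny), dtype=int)
        for i in range(nx):
            for j in range(ny):
                r[i, j], p[i, j], n_pairs[i, j] = correlation_test(
                    Xv[:, i], Yv[:, j], opts.method, opts.min_pairs
                )
        p_adj = adjust_pvalues(p, opts.adjust)
        labels = significance_labels(
            r, p_adj, opts.annotation, opts.star_thresholds
        )
        return CorrelationResults(
            row_ids=list(self.X.feature_ids),
            col_ids=list(self.Y.feature_ids),
            r=r, p=p, p_adj=p_adj, n_pairs=n_pairs, labels=labels,
            options=opts,
            x_id=self.X.layer_id, y_id=self.Y.layer_id,
        )


@dataclass
class CorrelationResults:
    """Aligned correlation / p-value / annotation matrices for one layer pair."""

    row_ids: list[str]
    col_ids: list[str]
    r: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    n_pairs: np.ndarray
    labels: np.ndarray
    options: CorrelationOptions
    x_id: str = "X"
    y_id: str = "Y"

    def __post_init__(self) -> None:
        shape = (len(self.row_ids), len(self.col_ids))
        for name in ("r", "p", "p_adj", "n_pairs", "labels"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"matrix {name} has shape != {shape}")

    def frame(self, kind: str) -> pd.DataFrame:
        """One matrix as a DataFrame; kind in {r, p, p_adj, n_pairs, labels}."""
        return pd.DataFrame(
            getattr(self, kind), index=self.row_ids, columns=self.col_ids
        )

    def relabel(self, annotation: str, star_thresholds: tuple | None = None) -> None:
        """Re-render annotation labels without re-testing."""
        thresholds = star_thresholds or self.options.star_thresholds
        self.labels = significance_labels(self.r, self.p_adj, annotation, thresholds)
        self.options = replace(
            self.options, annotation=annotation, star_thresholds=thresholds
        )

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Long-format table of pairs with adjusted p below alpha."""
        rows = []
        for i, ri in enumerate(self.row_ids):
            for j, cj in enumerate(self.col_ids):
                if not np.isnan(self.p_adj[i, j]) and self.p_adj[i, j] < alpha:
                    rows.append(
                        (ri, cj, self.r[i, j], self.p[i, j], self.p_adj[i, j],
                         int(self.n_pairs[i, j]))
                    )
        return pd.DataFrame(
            rows, columns=["row", "col", "r", "p", "p_adj", "n"]
        ).sort_values("p_adj", ignore_index=True)

    def summary(self, alpha: float = 0.05) -> str:
        sig = self.significant(alpha)
        lines = [
            f"Cross-correlation: {self.x_id} ({len(self.row_ids)}) x "
            f"{self.y_id} ({len(self.col_ids)})",
            f"  method={self.options.method}, use={self.options.use}, "
            f"adjust={self.options.adjust}",
            f"  significant pairs at adjusted p < {alpha:g}: {len(sig)} of "
            f"{self.r.size}",
        ]
        for _, row in sig.head(10).iterrows():
            lines.append(
                f"    {row['row']} ~ {row['col']}: r={row['r']:+.3f} "
                f"p_adj={row['p_adj']:.2e} (n={row['n']})"
            )
        return "\n".join(lines)

    def write_tsv(self, out_dir, float_format: str = "%.12g") -> list[str]:
        """Write the four matrices as <X>__<Y>.<kind>.tsv; returns paths."""
        import os

        paths = []
        for kind in ("r", "p", "p_adj", "labels"):
            name = f"{self.x_id}__{self.y_id}.{kind}.tsv"
            path = os.path.join(str(out_dir), name)
            frame = self.frame(kind)
            frame.index.name = "id"
            if kind == "labels":
                frame.to_csv(path, sep="\t")
            else:
                frame.to_csv(path, sep="\t", na_rep="NA", float_format=float_format)
            paths.append(path)
        return paths


def calculate_correlations(
    X: OmicsLayer, Y: OmicsLayer, options: CorrelationOptions | None = None
) -> CorrelationResults:
    """Functional wrapper: all-pairs correlation between two aligned layers."""
    return CrossCorrelation(X, Y, options).fit()


def encode_metadata(metadata: SampleMetadata) -> OmicsLayer:
    """Encode typed metadata as a numeric layer for correlation analysis.

    Numeric variables pass through; binary variables become a single 0/1
    feature (level order logged); categorical variables with k > 2 levels
    become k one-hot features named ``var=level``.  Variables with a single
    observed level are dropped with a warning.
    """
    n = len(metadata.sample_ids)
    feature_ids: list[str] = []
    columns: list[np.ndarray] = []
    for var in metadata.variables:
        if var.kind == "numeric":
            col = np.asarray(var.values, dtype=float)
            if len(set(col[~np.isnan(col)])) <= 1:
                logger.warning("metadata variable %r is constant; dropped", var.name)
                continue
            feature_ids.append(var.name)
            columns.append(col)
        else:
            observed = set(v for v in var.values if v is not None)
            if len(observed) < 2:
                logger.warning(
                    "metadata variable %r has a single observed level; dropped",
                    var.name,
                )
                continue
            if var.kind == "binary":
                lo, hi = var.levels
                logger.info(
                    "binary variable %r encoded as 0=%r, 1=%r", var.name, lo, hi
                )
                col = np.array(
                    [np.nan if v is None else float(v == hi) for v in var.values]
                )
                feature_ids.append(var.name)
                columns.append(col)
            else:
                for level in var.levels:
                    col = np.array(
                        [
                            np.nan if v is None else float(v == level)
                            for v in var.values
                        ]
                    )
                    feature_ids.append(f"{var.name}={level}")
                    columns.append(col)
    values = (
        np.column_stack(columns) if columns else np.empty((n, 0))
    )
    return OmicsLayer(
        layer_id="metadata",
        sample_ids=list(metadata.sample_ids),
        feature_ids=feature_ids,
        values=values,
        provenance="metadata",
    )
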