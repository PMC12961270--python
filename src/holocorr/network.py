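"""Weighted correlation-network module detection with hub extraction.

The model follows the weighted co-expression network tradition: a feature x
feature correlation matrix is soft-thresholded into a weighted adjacency
(``|r|^beta`` unsigned, ``((1+r)/2)^beta`` signed), shared-neighbour structure
is folded in through the topological overlap measure (TOM), and modules are
branches of an average-linkage dendrogram of ``1 - TOM`` that clear a minimum
size.  Close modules are merged on eigengene correlation, each feature gets an
intramodular connectivity ``k_within`` (sum of adjacency to its module mates),
and the most connected feature of each module — its *hub* — becomes the
module's representative profile.  The deliverable per layer is a small
samples x hubs table that downstream correlation analysis consumes.

The soft-threshold power beta is chosen by a scale-free-topology scan: the
smallest candidate whose log-log degree-distribution fit reaches the target
R-squared wins; if none qualifies the best-fitting candidate is used with a
warning.

``ModuleNetwork(layer, params).fit()`` is the model entry point; the
functional pieces (``adjacency_from_correlation``, ``tom_similarity``, ...)
are exposed for direct use and testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .io import OmicsLayer

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class NetworkParams:
    """Tuning knobs for the network model.

    power=None triggers the scale-free scan over ``power_grid``; a fixed
    number skips selection.  ``cut_height`` is a fraction of the tallest
    dendrogram merge; branches below it of at least ``min_module_size``
    features become modules.  ``merge_cut_height`` is a dissimilarity: module
    pairs whose eigengenes correlate above ``1 - merge_cut_height`` are fused.
    """

    correlation_method: str = "pearson"
    sign_mode: str = "unsigned"
    power: float | None = None
    power_grid: tuple = tuple(range(1, 21))
    rsq_target: float = 0.8
    cut_height: float = 0.99
    min_module_size: int = 20
    merge_cut_height: float = 0.25
    max_features: int = 20_000

    def __post_init__(self) -> None:
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation_method {self.correlation_method!r}")
        if self.sign_mode not in ("unsigned", "signed"):
            raise ValueError(f"unknown sign_mode {self.sign_mode!r}")
        if self.power is not None and self.power < 1:
            raise ValueError("power must be >= 1")
        if any(b < 1 for b in self.power_grid):
            raise ValueError("power_grid entries must be >= 1")
        if not 0 < self.rsq_target <= 1:
            raise ValueError("rsq_target must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 <= self.merge_cut_height <= 1:
            raise ValueError("merge_cut_height must be in [0, 1]")


@dataclass
class PowerFitRow:
    """One row of the soft-threshold scan diagnostics."""

    power: float
    scale_free_rsq: float
    mean_connectivity: float


@dataclass
class ModuleAssignment:
    """Feature -> module labelling; small branches get the unassigned label."""

    feature_ids: list[str]
    labels: list[str]
    unassigned_label: str = UNASSIGNED

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.labels):
            raise ValueError("one label per feature required")

    @property
    def module_ids(self) -> list[str]:
        """Module labels ordered by decreasing size (ties: first appearance)."""
        counts: dict[str, int] = {}
        for lab in self.labels:
            if lab != self.unassigned_label:
                counts[lab] = counts.get(lab, 0) + 1
        return sorted(counts, key=lambda m: (-counts[m], m))

    def members(self, module_id: str) -> list[str]:
        return [f for f, lab in zip(self.feature_ids, self.labels) if lab == module_id]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.feature_ids, self.labels))


# ---------------------------------------------------------------------------
# elementary network operations
# ---------------------------------------------------------------------------

def correlation_matrix(layer: OmicsLayer, method: str = "pearson") -> np.ndarray:
    """Feature x feature correlation of a complete layer.

    Zero-variance features make correlations undefined and are refused by
    name; missing values are refused outright (network behaviour under
    missingness is not defined here).
    """
    if layer.has_missing():
        raise ValueError(
            f"layer {layer.layer_id!r} has missing values; module detection "
            "requires a complete matrix"
        )
    X = layer.values
    sd = X.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [layer.feature_ids[i] for i in flat[:10]]
        raise ValueError(
            f"layer {layer.layer_id!r}: zero-variance feature(s) {names}; "
            "filter before network construction"
        )
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 0, X)
    R = np.corrcoef(X, rowvar=False)
    return np.clip(R, -1.0, 1.0)


def adjacency_from_correlation(
    R: np.ndarray, power: float, sign_mode: str = "unsigned"
) -> np.ndarray:
    """Soft-threshold a correlation matrix into a weighted adjacency.

    unsigned: ``A_ij = |R_ij|^beta``; signed: ``A_ij = ((1+R_ij)/2)^beta``.
    The diagonal is forced to 1.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if np.abs(R - R.T).max() > 1e-8:
        raise ValueError("correlation matrix is not symmetric (beyond 1e-8)")
    if np.nanmax(np.abs(R)) > 1 + 1e-12:
        raise ValueError("correlation entries must lie in [-1, 1]")
    if sign_mode == "unsigned":
        A = np.abs(R) ** power
    elif sign_mode == "signed":
        A = ((1.0 + R) / 2.0) ** power
    else:
        raise ValueError(f"unknown sign_mode {sign_mode!r}")
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return A


def connectivity(A: np.ndarray) -> np.ndarray:
    """Whole-network node degree ``k_i = sum_{u != i} A_iu``."""
    return A.sum(axis=1) - np.diag(A)


def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of a weighted adjacency.

    ``TOM_ij = (sum_{u != i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij)``
    with ``k_i`` the degree excluding the diagonal; ``TOM_ii = 1``.  Two nodes
    overlap strongly when they are directly connected *and* share neighbours,
    which makes the downstream clustering far less sensitive to single noisy
    correlations than raw adjacency.
    """
    A = np.asarray(A, dtype=float)
    if np.abs(A - A.T).max() > 1e-10 or A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("invalid adjacency: must be symmetric with entries in [0, 1]")
    k = connectivity(A)
    # (A @ A)_ij counts u over everything incl. i and j; with unit diagonal the
    # i and j terms contribute A_ij each, so subtract 2*A_ij then add back A_ij.
    shared = A @ A - 2.0 * A
    numer = shared + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# soft-threshold selection
# ---------------------------------------------------------------------------

def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R-squared of the log-log degree-distribution regression.

    Degrees are binned into up to ``n_bins`` equal-width bins of log10(k);
    log10 of the occupied-bin frequencies is regressed on log10 of the bin
    mean degree.  The R-squared is reported with the sign flipped so that the
    decreasing tail expected of a scale-free network scores positive.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        return 0.0
    logk = np.log10(k)
    lo, hi = logk.min(), logk.max()
    if hi - lo < 1e-12:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(logk, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(np.mean(k[mask])))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    rsq = 1.0 - (resid**2).sum() / ss_tot
    return float(-np.sign(slope) * rsq)


def choose_power(rows: list[PowerFitRow], rsq_target: float) -> float:
    """First candidate power reaching the fit target, else the best fit."""
    for row in rows:
        if row.scale_free_rsq >= rsq_target:
            return row.power
    best = max(rows, key=lambda r: r.scale_free_rsq)
    logger.warning(
        "no candidate power reached scale-free R^2 >= %.2f; using power=%g "
        "(R^2=%.3f)", rsq_target, best.power, best.scale_free_rsq,
    )
    return best.power


def soft_threshold_scan(
    layer: OmicsLayer, params: NetworkParams, R: np.ndarray | None = None
) -> tuple[list[PowerFitRow], float]:
    """Scan candidate soft-threshold powers and pick one.

    For each beta the adjacency is built, node degrees computed, and the
    scale-free fit evaluated; the chosen beta is the smallest one whose fit
    reaches ``params.rsq_target``.
    """
    if layer.n_samples < 8:
        warnings.warn(
            f"layer {layer.layer_id!r}: only {layer.n_samples} samples — "
            "correlation-network inference is unreliable below 8",
            stacklevel=2,
        )
    if layer.n_features < 2:
        raise ValueError("soft_threshold_scan needs at least 2 features")
    if R is None:
        R = correlation_matrix(layer, params.correlation_method)
    rows = _scan_rows(R, params)
    return rows, choose_power(rows, params.rsq_target)


def _scan_rows(R: np.ndarray, params: NetworkParams) -> list[PowerFitRow]:
    rows = []
    for beta in params.power_grid:
        A = adjacency_from_correlation(R, beta, params.sign_mode)
        k = connectivity(A)
        rows.append(
            PowerFitRow(
                power=float(beta),
                scale_free_rsq=scale_free_fit(k),
                mean_connectivity=float(k.mean()),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# dendrogram cutting, eigengenes, merging
# ---------------------------------------------------------------------------

def cut_dendrogram_to_modules(
    tom: np.ndarray, feature_ids: list[str], params: NetworkParams
) -> ModuleAssignment:
    """Cut the TOM dendrogram into modules by static height + minimum size.

    Average-linkage clustering on ``1 - TOM``; the tree is cut at
    ``cut_height`` x (tallest merge); branches of at least
    ``min_module_size`` features become modules labelled "M1", "M2", ... by
    decreasing size, everything else is unassigned.
    """
    n = len(feature_ids)
    if n < params.min_module_size:
        warnings.warn(
            f"{n} features < min_module_size={params.min_module_size}; "
            "everything left unassigned",
            stacklevel=2,
        )
        return ModuleAssignment(list(feature_ids), [UNASSIGNED] * n)
    D = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    max_h = Z[:, 2].max()
    height = params.cut_height * max_h if max_h > 0 else 0.0
    raw = fcluster(Z, t=height, criterion="distance")
    return _labels_from_clusters(raw, feature_ids, params.min_module_size)


def _labels_from_clusters(
    raw: np.ndarray, feature_ids: list[str], min_module_size: int
) -> ModuleAssignment:
    sizes: dict[int, int] = {}
    first_idx: dict[int, int] = {}
    for i, c in enumerate(raw):
        sizes[c] = sizes.get(c, 0) + 1
        first_idx.setdefault(c, i)
    big = [c for c, s in sizes.items() if s >= min_module_size]
    big.sort(key=lambda c: (-sizes[c], first_idx[c]))
    rename = {c: f"M{i + 1}" for i, c in enumerate(big)}
    labels = [rename.get(c, UNASSIGNED) for c in raw]
    return ModuleAssignment(list(feature_ids), labels)


def module_eigengene(layer: OmicsLayer, members: list[str]) -> np.ndarray:
    """First principal component of the standardized member submatrix.

    Returned with unit Euclidean norm; the sign is oriented so the eigengene
    correlates non-negatively with the module's mean standardized profile
    (principal components are otherwise sign-ambiguous).
    """
    if not members:
        raise ValueError("module has no members")
    idx = [layer.feature_ids.index(f) for f in members]
    M = layer.values[:, idx]
    if np.isnan(M).any():
        raise ValueError("missing values among module members")
    sd = M.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"zero-variance member {members[flat[0]]!r}")
    Z = (M - M.mean(axis=0)) / sd
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    eig = U[:, 0]
    mean_profile = Z.mean(axis=1)
    if mean_profile.std() > 1e-12:
        c = np.corrcoef(eig, mean_profile)[0, 1]
    else:
        # degenerate (e.g. members split z / -z): orient on the first member
        c = np.corrcoef(eig, Z[:, 0])[0, 1]
    if c < 0:
        eig = -eig
    return eig


def merge_close_modules(
    layer: OmicsLayer, assignment: ModuleAssignment, merge_cut_height: float
) -> ModuleAssignment:
    """Fuse modules whose eigengenes are closer than ``merge_cut_height``.

    Iteratively merges the most-correlated module pair while its eigengene
    correlation is at least ``1 - merge_cut_height``, then relabels modules by
    size.  ``merge_cut_height = 0`` disables merging.
    """
    if merge_cut_height == 0:
        return assignment
    labels = list(assignment.labels)
    while True:
        mods = _module_list(labels, assignment.unassigned_label)
        if len(mods) < 2:
            break
        eigs = {
            m: module_eigengene(
                layer,
                [f for f, lab in zip(assignment.feature_ids, labels) if lab == m],
            )
            for m in mods
        }
        best_pair, best_r = None, -np.inf
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                r = float(np.corrcoef(eigs[a], eigs[b])[0, 1])
                if r > best_r:
                    best_pair, best_r = (a, b), r
        if best_pair is None or best_r < 1.0 - merge_cut_height:
            break
        a, b = best_pair
        logger.info("merging modules %s and %s (eigengene r=%.3f)", a, b, best_r)
        labels = [a if lab == b else lab for lab in labels]
    # relabel by decreasing size, stable on first appearance
    sizes: dict[str, int] = {}
    first: dict[str, int] = {}
    for i, lab in enumerate(labels):
        if lab == assignment.unassigned_label:
            continue
        sizes[lab] = sizes.get(lab, 0) + 1
        first.setdefault(lab, i)
    ordered = sorted(sizes, key=lambda m: (-sizes[m], first[m]))
    rename = {m: f"M{i + 1}" for i, m in enumerate(ordered)}
    new_labels = [
        rename.get(lab, assignment.unassigned_label) for lab in labels
    ]
    return ModuleAssignment(
        list(assignment.feature_ids), new_labels, assignment.unassigned_label
    )


def _module_list(labels: list[str], unassigned: str) -> list[str]:
    seen: list[str] = []
    for lab in labels:
        if lab != unassigned and lab not in seen:
            seen.append(lab)
    return seen


def intramodular_connectivity(
    A: np.ndarray, assignment: ModuleAssignment
) -> np.ndarray:
    """Per-feature connectivity restricted to its own module.

    ``k_within(i) = sum over module mates j != i of A_ij``; unassigned
    features score 0.
    """
    n = len(assignment.feature_ids)
    if A.shape != (n, n):
        raise ValueError("adjacency and assignment cover different features")
    labels = np.asarray(assignment.labels)
    k_within = np.zeros(n)
    for mod in assignment.module_ids:
        idx = np.flatnonzero(labels == mod)
        sub = A[np.ix_(idx, idx)]
        k_within[idx] = sub.sum(axis=1) - np.diag(sub)
    return k_within


def top_hub_per_module(
    layer: OmicsLayer, assignment: ModuleAssignment, k_within: np.ndarray
) -> tuple[dict[str, str], OmicsLayer]:
    """Pick each module's most intramodularly connected feature as its hub.

    Ties break lexicographically on feature id (logged).  The hub layer is
    the *original* expression columns of the hubs: samples x hubs, one column
    per module, provenance "hubs".
    """
    hubs: dict[str, str] = {}
    labels = np.asarray(assignment.labels)
    for mod in assignment.module_ids:
        idx = np.flatnonzero(labels == mod)
        kw = k_within[idx]
        best = kw.max()
        tied = [assignment.feature_ids[i] for i in idx[np.isclose(kw, best, rtol=0, atol=0)]]
        if len(tied) > 1:
            logger.info(
                "module %s: k_within tie among %s; choosing %s",
                mod, tied, min(tied),
            )
        hubs[mod] = min(tied)
    hub_ids = [hubs[m] for m in assignment.module_ids]
    cols = [layer.feature_ids.index(h) for h in hub_ids]
    hub_layer = OmicsLayer(
        layer_id=layer.layer_id,
        sample_ids=list(layer.sample_ids),
        feature_ids=hub_ids,
        values=layer.values[:, cols],
        provenance="hubs",
    )
    return hubs, hub_layer


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ModuleNetwork:
    """Weighted correlation-network module model for one omics layer.

    Parameters
    ----------
    layer
        Complete (no missing values) samples x features layer, preprocessed.
    params
        NetworkParams; defaults follow community practice for weighted
        co-expression networks (unsigned, Pearson, power grid 1..20,
        scale-free R^2 target 0.8, merge height 0.25).

    Examples
    --------
    >>> result = ModuleNetwork(layer).fit()      # doctest: +SKIP
    >>> result.hub_layer.feature_ids             # doctest: +SKIP
    """

    def __init__(self, layer: OmicsLayer, params: NetworkParams | None = None):
        self.layer = layer
        self.params = params or NetworkParams()
        if layer.n_features > self.params.max_features:
            raise ValueError(
                f"layer {layer.layer_id!r} has {layer.n_features} features, "
                f"above the single-block cap ({self.params.max_features}); "
                "pre-filter or raise max_features"
            )

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, layer_id: str = "layer",
        params: NetworkParams | None = None,
    ) -> "ModuleNetwork":
        return cls(OmicsLayer.from_frame(frame, layer_id), params)

    def fit(self) -> "ModuleNetworkResults":
        """Run scan -> adjacency -> TOM -> cut -> merge -> connectivity -> hubs."""
        params = self.params
        R = correlation_matrix(self.layer, params.correlation_method)
        if params.power is None:
            power_scan, beta = soft_threshold_scan(self.layer, params, R=R)
        else:
            # fixed power: the scan is kept as a diagnostic, no selection
            power_scan = _scan_rows(R, params)
            beta = params.power
        A = adjacency_from_correlation(R, beta, params.sign_mode)
        tom = tom_similarity(A)
        assignment = cut_dendrogram_to_modules(tom, self.layer.feature_ids, params)
        if assignment.module_ids:
            assignment = merge_close_modules(
                self.layer, assignment, params.merge_cut_height
            )
        k_within = intramodular_connectivity(A, assignment)
        eigengenes = {
            m: module_eigengene(self.layer, assignment.members(m))
            for m in assignment.module_ids
        }
        if assignment.module_ids:
            hubs, hub_layer = top_hub_per_module(self.layer, assignment, k_within)
        else:
            hubs, hub_layer = {}, OmicsLayer(
                self.layer.layer_id, list(self.layer.sample_ids), [],
                np.empty((self.layer.n_samples, 0)), provenance="hubs",
            )
        return ModuleNetworkResults(
            model=self,
            assignment=assignment,
            eigengenes=eigengenes,
            k_within=k_within,
            hubs=hubs,
            hub_layer=hub_layer,
            params=replace(params, power=beta),
            power_scan=power_scan,
        )


@dataclass
class ModuleNetworkResults:
    """Fitted module structure of one layer.

    Attributes
    ----------
    assignment : ModuleAssignment
    eigengenes : dict of module id -> unit-norm sample vector
    k_within : per-feature intramodular connectivity (input feature order)
    hubs : module id -> hub feature id
    hub_layer : OmicsLayer, samples x hubs (provenance "hubs")
    params : NetworkParams actually used (power resolved)
    power_scan : soft-threshold diagnostics
    """

    model: ModuleNetwork
    assignment: ModuleAssignment
    eigengenes: dict[str, np.ndarray]
    k_within: np.ndarray
    hubs: dict[str, str]
    hub_layer: OmicsLayer
    params: NetworkParams
    power_scan: list[PowerFitRow] = field(default_factory=list)

    @property
    def module_ids(self) -> list[str]:
        return self.assignment.module_ids

    def module_table(self, label_map: dict[str, str] | None = None) -> pd.DataFrame:
        """Per-feature table: feature_id, module, k_within, is_hub."""
        label_map = label_map or {}
        hubset = set(self.hubs.values())
        return pd.DataFrame(
            {
                "feature_id": self.assignment.feature_ids,
                "module": [
                    label_map.get(lab, lab) for lab in self.assignment.labels
                ],
                "k_within": self.k_within,
                "is_hub": [
                    int(f in hubset) for f in self.assignment.feature_ids
                ],
            }
        )

    def power_scan_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": [r.power for r in self.power_scan],
                "scale_free_rsq": [r.scale_free_rsq for r in self.power_scan],
                "mean_connectivity": [r.mean_connectivity for r in self.power_scan],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Module network: layer={self.model.layer.layer_id!r} "
            f"({self.model.layer.n_samples} samples x "
            f"{self.model.layer.n_features} features)",
            f"  method={self.params.correlation_method}/{self.params.sign_mode}, "
            f"power={self.params.power:g}, min size={self.params.min_module_size}",
            f"  modules: {len(self.module_ids)}  "
            f"(unassigned: {self.assignment.labels.count(self.assignment.unassigned_label)})",
        ]
        for m in self.module_ids:
            lines.append(
                f"    {m}: {len(self.assignment.members(m))} features, "
                f"hub={self.hubs[m]}"
            )
        return "\n".join(lines)


def detect_modules(
    layer: OmicsLayer, params: NetworkParams | None = None
) -> ModuleNetworkResults:
    """Functional wrapper: fit the module network of one layer."""
    return ModuleNetwork(layer, params).fit()
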