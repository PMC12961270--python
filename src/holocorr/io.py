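"""Core table types and input/output for multi-layer omics bundles.

A *layer* is one omics feature table (host transcripts, microbial taxa,
metaproteins, ...) over a shared set of samples.  The canonical in-memory
orientation is samples x features; missing entries are ``NaN``.  Alongside the
layers sits a single sample-metadata table with typed variables (numeric,
binary, categorical).

Preprocessing built into the package is deliberately minimal — low-prevalence
filtering and the centered log-ratio (CLR) transform for compositional layers.
Anything heavier (CSS, VST, batch correction) is expected to happen upstream,
with the results fed in as plain tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens accepted as "missing" when reading tables; "NA" is emitted on write
MISSING_TOKENS = ("NA", "NaN", "nan", "")


class TableFormatError(ValueError):
    """Raised when an input table violates the feature-table contract."""


@dataclass
class OmicsLayer:
    """A named samples x features numeric matrix with optional missing entries.

    Parameters
    ----------
    layer_id
        Short identifier, e.g. ``"host"`` or ``"microbiome"``.
    sample_ids, feature_ids
        Ordered, duplicate-free identifier lists matching the matrix axes.
    values
        Float array of shape ``(n_samples, n_features)``; ``NaN`` marks a
        missing entry, every other entry must be finite.
    provenance
        Free-text note on how the table was produced (``"raw"``, ``"clr"``,
        ``"hubs"``, ...).
    """

    layer_id: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TableFormatError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise TableFormatError(
                f"layer {self.layer_id!r}: {len(self.sample_ids)} sample ids "
                f"for {n} matrix rows"
            )
        if len(self.feature_ids) != p:
            raise TableFormatError(
                f"layer {self.layer_id!r}: {len(self.feature_ids)} feature ids "
                f"for {p} matrix columns"
            )
        for kind, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise TableFormatError(
                    f"layer {self.layer_id!r}: duplicate {kind} ids: {sorted(dupes)}"
                )
        if np.isinf(self.values).any():
            raise TableFormatError(
                f"layer {self.layer_id!r}: non-finite (infinite) entries present"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, layer_id: str, provenance: str = "raw"
    ) -> "OmicsLayer":
        return cls(
            layer_id=layer_id,
            sample_ids=list(frame.index.astype(str)),
            feature_ids=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
            provenance=provenance,
        )

    def subset_samples(self, sample_ids: list[str]) -> "OmicsLayer":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(self, sample_ids=list(sample_ids), values=self.values[idx, :])

    def subset_features(self, feature_ids: list[str]) -> "OmicsLayer":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return replace(self, feature_ids=list(feature_ids), values=self.values[:, idx])


@dataclass
class MetadataVariable:
    """One typed sample-level variable.

    ``kind`` is ``"numeric"``, ``"binary"`` or ``"categorical"``; non-numeric
    kinds carry an explicit, ordered ``levels`` list (exactly two for binary).
    Values are floats for numeric kinds and strings (or None for missing)
    otherwise.
    """

    name: str
    kind: str
    values: list
    levels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "binary", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "numeric":
            self.values = [float("nan") if v is None else float(v) for v in self.values]
            self.levels = None
        else:
            observed = [v for v in self.values if v is not None]
            if self.levels is None:
                self.levels = sorted(set(str(v) for v in observed))
            if self.kind == "binary" and len(self.levels) != 2:
                raise ValueError(
                    f"binary variable {self.name!r} needs exactly 2 levels, "
                    f"got {self.levels}"
                )
            unknown = set(str(v) for v in observed) - set(self.levels)
            if unknown:
                raise ValueError(
                    f"variable {self.name!r}: values outside declared levels: "
                    f"{sorted(unknown)}"
                )


@dataclass
class SampleMetadata:
    """Typed per-sample metadata aligned to an ordered sample-id list."""

    sample_ids: list[str]
    variables: list[MetadataVariable] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise TableFormatError(f"metadata: duplicate sample ids: {sorted(dupes)}")
        for var in self.variables:
            if len(var.values) != len(self.sample_ids):
                raise TableFormatError(
                    f"variable {var.name!r}: {len(var.values)} values for "
                    f"{len(self.sample_ids)} samples"
                )

    def subset_samples(self, sample_ids: list[str]) -> "SampleMetadata":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        variables = [
            MetadataVariable(
                name=v.name,
                kind=v.kind,
                values=[v.values[i] for i in idx],
                levels=None if v.levels is None else list(v.levels),
            )
            for v in self.variables
        ]
        return SampleMetadata(sample_ids=list(sample_ids), variables=variables)


@dataclass
class AlignedBundle:
    """Layers plus metadata restricted to one shared, ordered sample set."""

    layers: list[OmicsLayer]
    metadata: SampleMetadata | None
    common_samples: list[str]

    def __post_init__(self) -> None:
        for layer in self.layers:
            if layer.sample_ids != self.common_samples:
                raise ValueError(
                    f"layer {layer.layer_id!r} sample order differs from "
                    "common_samples"
                )
        if self.metadata is not None and self.metadata.sample_ids != self.common_samples:
            raise ValueError("metadata sample order differs from common_samples")

    def layer(self, layer_id: str) -> OmicsLayer:
        for lyr in self.layers:
            if lyr.layer_id == layer_id:
                return lyr
        raise KeyError(f"no layer {layer_id!r} in bundle")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_feature_table(
    path,
    layer_id: str | None = None,
    orientation: str = "samples-in-rows",
    delimiter: str = "\t",
) -> OmicsLayer:
    """Read a feature table into canonical samples x features orientation.

    The first field of the header is the id column.  ``orientation`` must be
    stated explicitly (``"samples-in-rows"`` or ``"features-in-rows"``) — the
    reader never guesses, because a silently transposed table is one of the
    most common multi-omics corruption modes.  Cells equal to ``NA``, ``NaN``
    or empty become missing entries.
    """
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(
        path, sep=delimiter, index_col=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise TableFormatError(f"{path}: empty table")
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    for axis_name, ids in (("row", raw.index), ("column", raw.columns)):
        dupes = _duplicates(list(ids))
        if dupes:
            raise TableFormatError(f"{path}: duplicate {axis_name} ids: {sorted(dupes)}")

    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col].to_numpy()):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-numeric cell {cell!r} at row {raw.index[i]!r}, "
                    f"column {col!r}"
                ) from None

    if orientation == "features-in-rows":
        values = values.T
        sample_ids, feature_ids = list(raw.columns), list(raw.index)
    else:
        sample_ids, feature_ids = list(raw.index), list(raw.columns)
    if layer_id is None:
        layer_id = _stem(path)
    return OmicsLayer(layer_id, sample_ids, feature_ids, values)


def write_feature_table(layer: OmicsLayer, path, delimiter: str = "\t") -> None:
    """Write a layer as a TSV/CSV with first field ``id`` and ``NA`` missing."""
    frame = layer.to_frame()
    frame.index.name = "id"
    frame.to_csv(path, sep=delimiter, na_rep="NA", float_format="%.12g")


def read_metadata_table(
    path,
    delimiter: str = "\t",
    kinds: dict[str, str] | None = None,
) -> SampleMetadata:
    """Read a sample-metadata table; infer variable kinds unless declared.

    Inference: numeric if every non-missing value parses as a float, binary if
    exactly two distinct string levels, else categorical.  A ``kinds`` mapping
    (name -> kind) overrides inference per variable.
    """
    raw = pd.read_csv(
        path, sep=delimiter, index_col=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    sample_ids = list(raw.index.astype(str))
    kinds = kinds or {}
    variables = []
    for col in raw.columns:
        cells = [c.strip() for c in raw[col].to_numpy()]
        cells = [None if c in MISSING_TOKENS else c for c in cells]
        kind = kinds.get(col)
        if kind is None:
            kind = _infer_kind(cells)
        if kind == "numeric":
            vals = [None if c is None else float(c) for c in cells]
        else:
            vals = cells
        variables.append(MetadataVariable(name=str(col), kind=kind, values=vals))
    return SampleMetadata(sample_ids=sample_ids, variables=variables)


def write_metadata_table(metadata: SampleMetadata, path, delimiter: str = "\t") -> None:
    data = {}
    for var in metadata.variables:
        if var.kind == "numeric":
            data[var.name] = [
                "NA" if (v is None or np.isnan(v)) else f"{v:.12g}" for v in var.values
            ]
        else:
            data[var.name] = ["NA" if v is None else str(v) for v in var.values]
    frame = pd.DataFrame(data, index=metadata.sample_ids)
    frame.index.name = "id"
    frame.to_csv(path, sep=delimiter)


def _infer_kind(cells: list) -> str:
    observed = [c for c in cells if c is not None]
    if not observed:
        return "numeric"
    try:
        for c in observed:
            float(c)
        return "numeric"
    except ValueError:
        pass
    return "binary" if len(set(observed)) == 2 else "categorical"


# ---------------------------------------------------------------------------
# alignment and preprocessing
# ---------------------------------------------------------------------------

def align_samples(
    layers: list[OmicsLayer],
    metadata: SampleMetadata | None = None,
) -> tuple[AlignedBundle, dict[str, list[str]]]:
    """Restrict all layers (and metadata) to their shared samples.

    The shared set is the intersection of every layer's (and the metadata's)
    sample ids, taken in lexicographic order so that no layer is privileged.
    Returns the aligned bundle and a report mapping each table id to the
    sample ids it lost.
    """
    if not layers:
        raise ValueError("align_samples needs at least one layer")
    common = set(layers[0].sample_ids)
    for layer in layers[1:]:
        common &= set(layer.sample_ids)
    if metadata is not None:
        common &= set(metadata.sample_ids)
    if not common:
        counts = ", ".join(
            f"{lyr.layer_id}={lyr.n_samples}" for lyr in layers
        )
        if metadata is not None:
            counts += f", metadata={len(metadata.sample_ids)}"
        raise ValueError(f"no samples shared across all tables (counts: {counts})")
    order = sorted(common)

    report: dict[str, list[str]] = {}
    aligned_layers = []
    for layer in layers:
        dropped = sorted(set(layer.sample_ids) - common)
        report[layer.layer_id] = dropped
        if dropped:
            logger.info(
                "layer=%s dropped=%d ids=%s", layer.layer_id, len(dropped),
                ",".join(dropped),
            )
        aligned_layers.append(layer.subset_samples(order))
    aligned_meta = None
    if metadata is not None:
        dropped = sorted(set(metadata.sample_ids) - common)
        report["metadata"] = dropped
        if dropped:
            logger.info(
                "layer=metadata dropped=%d ids=%s", len(dropped), ",".join(dropped)
            )
        aligned_meta = metadata.subset_samples(order)
    return AlignedBundle(aligned_layers, aligned_meta, order), report


def filter_low_prevalence(
    layer: OmicsLayer,
    min_prevalence: float,
    zero_is_absent: bool = True,
) -> tuple[OmicsLayer, list[str]]:
    """Drop features observed in fewer than ``min_prevalence`` of samples.

    A feature counts as present in a sample when its entry is non-missing
    and, if ``zero_is_absent``, non-zero — the usual semantics for sparse
    amplicon and metaproteomic tables.  Returns the filtered layer and the
    list of removed feature ids; the surviving feature order is preserved.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    if layer.n_features == 0 or layer.n_samples == 0:
        raise ValueError(f"layer {layer.layer_id!r} is empty")
    present = ~np.isnan(layer.values)
    if zero_is_absent:
        present &= layer.values != 0
    prevalence = present.mean(axis=0)
    keep = prevalence >= min_prevalence
    removed = [f for f, k in zip(layer.feature_ids, keep) if not k]
    if not keep.any():
        raise ValueError(
            f"layer {layer.layer_id!r}: min_prevalence={min_prevalence} removes "
            "every feature; lower the threshold"
        )
    kept_layer = replace(
        layer,
        feature_ids=[f for f, k in zip(layer.feature_ids, keep) if k],
        values=layer.values[:, keep],
    )
    if removed:
        logger.info(
            "layer=%s prevalence filter removed %d/%d features",
            layer.layer_id, len(removed), layer.n_features,
        )
    return kept_layer, removed


def clr_transform(layer: OmicsLayer, pseudocount: float | None = None) -> OmicsLayer:
    """Centered log-ratio transform, applied per sample (row).

    Each row is shifted by ``pseudocount``, divided by its geometric mean and
    logged (natural log), so every output row sums to zero.  The default
    pseudocount is half the smallest non-zero entry of the table (only added
    when zeros are present).  CLR is defined on complete non-negative
    compositions: missing or negative entries are refused.
    """
    if np.isnan(layer.values).any():
        raise ValueError(
            f"layer {layer.layer_id!r} has missing entries; CLR needs complete "
            "compositions — filter or impute first"
        )
    if (layer.values < 0).any():
        raise ValueError(f"layer {layer.layer_id!r} has negative entries")
    has_zero = (layer.values == 0).any()
    if pseudocount is None:
        if has_zero:
            nonzero = layer.values[layer.values > 0]
            if nonzero.size == 0:
                raise ValueError(f"layer {layer.layer_id!r} is all zeros")
            pseudocount = 0.5 * nonzero.min()
        else:
            pseudocount = 0.0
    if pseudocount < 0 or (has_zero and pseudocount == 0):
        raise ValueError("pseudocount must be positive when zeros are present")
    shifted = layer.values + pseudocount
    log_vals = np.log(shifted)
    clr = log_vals - log_vals.mean(axis=1, keepdims=True)
    return replace(layer, values=clr, provenance="clr")


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in ids:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
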