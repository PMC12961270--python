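"""End-to-end driver: config in, module tables + correlation maps + figure out.

The YAML run configuration names the input layer tables, designates one
central layer, and carries per-stage options.  The pipeline aligns samples,
applies the built-in preprocessing (prevalence filter, CLR) where requested,
fits the module network of every layer, orders the central layer's hubs,
correlates them against every other layer's hubs and against the encoded
metadata, assembles the integrated figure and writes a run manifest with
input checksums.  Everything downstream of the inputs is deterministic, so a
rerun on identical inputs reproduces the correlation tables byte for byte.

Config schema (YAML)::

    layers:
      - id: host
        path: host.tsv
        orientation: samples-in-rows     # or features-in-rows
        delimiter: "\\t"
        preprocessing:
          min_prevalence: 0.25           # optional
          clr: false                     # optional
        network: { min_module_size: 10, ... }   # per-layer override
    central_layer: host
    metadata:
      path: metadata.tsv
      kinds: { diet: categorical }       # optional per-variable override
    network: { power: auto, rsq_target: 0.8, ... }   # defaults for all layers
    correlation: { method: pearson, use: pairwise.complete.obs, adjust: fdr }
    figure: { format: svg, distance: correlation, linkage: average,
              scaling: row-z, sample_annotation: diet }
    module_labels: { host: { M1: "immune response" } }
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from datetime import datetime, timezone

import yaml

from . import __version__
from .correlate import CorrelationOptions, CrossCorrelation, encode_metadata
from .io import (
    align_samples,
    clr_transform,
    filter_low_prevalence,
    read_feature_table,
    read_metadata_table,
    write_feature_table,
)
from .network import ModuleNetwork, NetworkParams
from .viz import (
    IntegratedFigureSpec,
    assemble_integrated_figure,
    central_heatmap_matrix,
    order_central_layer,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for actionable CLI errors."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _network_params(config: dict, layer_cfg: dict) -> NetworkParams:
    merged = dict(config.get("network") or {})
    merged.update(layer_cfg.get("network") or {})
    power = merged.pop("power", "auto")
    if power in ("auto", None):
        power = None
    else:
        power = float(power)
    known = {
        "correlation_method", "sign_mode", "rsq_target", "cut_height",
        "min_module_size", "merge_cut_height", "max_features", "power_grid",
    }
    unknown = set(merged) - known
    if unknown:
        raise PipelineError("config", f"unknown network option(s): {sorted(unknown)}")
    if "power_grid" in merged:
        merged["power_grid"] = tuple(merged["power_grid"])
    return NetworkParams(power=power, **merged)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config, out_dir: str, seed: int = 0) -> dict:
    """Execute the full workflow described by ``config``.

    ``config`` is a path to a YAML file or an already-parsed dict; relative
    input paths resolve against the config file's directory.  Returns the run
    manifest (also written as ``manifest.json`` in ``out_dir``).  If the
    output directory holds a manifest from an earlier run, that run's files
    are removed first — nothing is silently overwritten in place.
    """
    if isinstance(config, (str, os.PathLike)):
        base = os.path.dirname(os.path.abspath(str(config)))
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
        config_path = str(config)
    else:
        cfg = dict(config)
        base = os.getcwd()
        config_path = None

    if not cfg.get("layers"):
        raise PipelineError("config", "no layers declared")
    central_id = cfg.get("central_layer")
    if not central_id:
        raise PipelineError("config", "central_layer must be designated")
    layer_ids = [lc["id"] for lc in cfg["layers"]]
    if central_id not in layer_ids:
        raise PipelineError(
            "config", f"central_layer {central_id!r} is not among {layer_ids}"
        )

    os.makedirs(out_dir, exist_ok=True)
    _clean_previous_run(out_dir)
    outputs: list[str] = []
    inputs: dict[str, dict] = {}

    def _resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    # ---- read ----------------------------------------------------------
    layers = []
    layer_cfgs: dict[str, dict] = {}
    try:
        for lc in cfg["layers"]:
            path = _resolve(lc["path"])
            layer = read_feature_table(
                path,
                layer_id=lc["id"],
                orientation=lc.get("orientation", "samples-in-rows"),
                delimiter=lc.get("delimiter", "\t"),
            )
            inputs[lc["id"]] = {"path": path, "sha256": _sha256(path)}
            layers.append(layer)
            layer_cfgs[lc["id"]] = lc
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        raise PipelineError("read", str(exc)) from exc

    metadata = None
    meta_cfg = cfg.get("metadata")
    if meta_cfg:
        try:
            path = _resolve(meta_cfg["path"])
            metadata = read_metadata_table(
                path,
                delimiter=meta_cfg.get("delimiter", "\t"),
                kinds=meta_cfg.get("kinds"),
            )
            inputs["metadata"] = {"path": path, "sha256": _sha256(path)}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("read", str(exc)) from exc

    # ---- align + preprocess -------------------------------------------
    try:
        bundle, drop_report = align_samples(layers, metadata)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("align", str(exc)) from exc

    processed = []
    try:
        for layer in bundle.layers:
            pp = layer_cfgs[layer.layer_id].get("preprocessing") or {}
            if pp.get("min_prevalence"):
                layer, _removed = filter_low_prevalence(
                    layer, float(pp["min_prevalence"]),
                    zero_is_absent=bool(pp.get("zero_is_absent", True)),
                )
            if pp.get("clr"):
                layer = clr_transform(layer, pp.get("pseudocount"))
            processed.append(layer)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("preprocess", str(exc)) from exc

    # ---- module detection per layer ------------------------------------
    results = {}
    label_maps = cfg.get("module_labels") or {}
    try:
        for layer in processed:
            params = _network_params(cfg, layer_cfgs[layer.layer_id])
            res = ModuleNetwork(layer, params).fit()
            results[layer.layer_id] = res
            mod_path = os.path.join(out_dir, f"modules_{layer.layer_id}.tsv")
            res.module_table(label_maps.get(layer.layer_id)).to_csv(
                mod_path, sep="\t", index=False, float_format="%.12g"
            )
            outputs.append(mod_path)
            scan_path = os.path.join(out_dir, f"power_scan_{layer.layer_id}.tsv")
            res.power_scan_table().to_csv(
                scan_path, sep="\t", index=False, float_format="%.12g"
            )
            outputs.append(scan_path)
            hub_path = os.path.join(out_dir, f"hubs_{layer.layer_id}.tsv")
            write_feature_table(res.hub_layer, hub_path)
            outputs.append(hub_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("detect", str(exc)) from exc

    # ---- ordering + correlations ---------------------------------------
    central = results[central_id]
    if central.hub_layer.n_features == 0:
        raise PipelineError(
            "order", f"central layer {central_id!r} yielded no modules"
        )
    fig_cfg = cfg.get("figure") or {}
    try:
        ordering = order_central_layer(
            central.hub_layer,
            distance=fig_cfg.get("distance", "correlation"),
            linkage_method=fig_cfg.get("linkage", "average"),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("order", str(exc)) from exc

    corr_opts = CorrelationOptions(**(cfg.get("correlation") or {}))
    central_hubs_ordered = central.hub_layer.subset_features(ordering.leaf_order)

    right_blocks = []
    left_blocks = []
    try:
        for layer_id in layer_ids:
            if layer_id == central_id:
                continue
            other = results[layer_id].hub_layer
            if other.n_features == 0:
                logger.warning("layer %s has no modules; skipped", layer_id)
                continue
            res = CrossCorrelation(central_hubs_ordered, other, corr_opts).fit()
            outputs.extend(res.write_tsv(out_dir))
            right_blocks.append(res)
        if bundle.metadata is not None and bundle.metadata.variables:
            meta_layer = encode_metadata(bundle.metadata)
            if meta_layer.n_features:
                res = CrossCorrelation(
                    central_hubs_ordered, meta_layer, corr_opts
                ).fit()
                outputs.extend(res.write_tsv(out_dir))
                left_blocks.append(res)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("correlate", str(exc)) from exc

    # ---- figure ---------------------------------------------------------
    try:
        sample_annotations = None
        ann_var = fig_cfg.get("sample_annotation")
        if ann_var and bundle.metadata is not None:
            for var in bundle.metadata.variables:
                if var.name == ann_var and var.kind != "numeric":
                    sample_annotations = {
                        ann_var: ["NA" if v is None else str(v) for v in var.values]
                    }
        display = central_heatmap_matrix(
            central.hub_layer, ordering, scaling=fig_cfg.get("scaling", "row-z")
        )
        # group samples by the annotation variable when one is given,
        # otherwise leave input order
        if sample_annotations:
            order = sorted(
                range(display.shape[1]),
                key=lambda i: (sample_annotations[ann_var][i], i),
            )
            display = display.iloc[:, order]
            sample_annotations = {
                ann_var: [sample_annotations[ann_var][i] for i in order]
            }
        hub_label_map = {
            hub: label_maps.get(central_id, {}).get(mod, f"{mod}:{hub}")
            for mod, hub in central.hubs.items()
        }
        spec = IntegratedFigureSpec(
            central=display,
            ordering=ordering,
            left_blocks=left_blocks,
            right_blocks=right_blocks,
            sample_annotations=sample_annotations,
            row_label_map=hub_label_map,
        )
        fig_format = fig_cfg.get("format", "svg")
        fig_path = os.path.join(out_dir, f"integrated_overview.{fig_format}")
        fig_manifest = assemble_integrated_figure(
            spec, fig_path, fig_format=fig_format, dpi=int(fig_cfg.get("dpi", 150))
        )
        outputs.append(fig_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("figure", str(exc)) from exc

    manifest = {
        "tool": "holocorr",
        "version": __version__,
        "config": config_path,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": inputs,
        "dropped_samples": drop_report,
        "central_layer": central_id,
        "modules_per_layer": {
            lid: len(res.module_ids) for lid, res in results.items()
        },
        "figure": fig_manifest,
        "outputs": [os.path.basename(p) for p in outputs],
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("pipeline wrote %d files to %s", len(outputs) + 1, out_dir)
    return manifest


def _clean_previous_run(out_dir: str) -> None:
    manifest_path = os.path.join(out_dir, "manifest.json")
    if not os.path.exists(manifest_path):
        return
    try:
        with open(manifest_path) as fh:
            old = json.load(fh)
        for name in old.get("outputs", []):
            p = os.path.join(out_dir, name)
            if os.path.exists(p):
                os.remove(p)
        os.remove(manifest_path)
        logger.info("removed previous run's outputs from %s", out_dir)
    except (json.JSONDecodeError, OSError) as exc:
        raise PipelineError(
            "setup",
            f"{out_dir} holds an unreadable manifest ({exc}); refusing to "
            "overwrite — clean it manually or pick a fresh directory",
        ) from exc
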