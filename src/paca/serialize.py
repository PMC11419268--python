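"""Model archives: lossless save/load of fitted estimators.

A single ``.npz`` file holds the float64 bases plus a JSON metadata record
(format version, estimator class and parameters, feature ids, centering
and sign conventions). Round trips are bit-exact, so scores produced from
a reloaded model match the in-memory model exactly.
"""

from __future__ import annotations

import json
import zipfile

import numpy as np

from . import __version__
from .estimators import PACA, RandomizedPACA
from .exceptions import ModelArchiveError

__all__ = ["save_model", "load_model"]

FORMAT_VERSION = "1.0"
_CLASSES = {"PACA": PACA, "RandomizedPACA": RandomizedPACA}


def save_model(model, path) -> None:
    """Write a fitted :class:`PACA` or :class:`RandomizedPACA` to ``path``."""
    cls = type(model).__name__
    if cls not in _CLASSES:
        raise ModelArchiveError(f"cannot serialize a {cls}")
    if not hasattr(model, "components_"):
        raise ModelArchiveError("model is not fitted")
    meta = {
        "format_version": FORMAT_VERSION,
        "tool_version": __version__,
        "class": cls,
        "params": {k: v for k, v in model.get_params().items()},
        "centering": ("per_feature_then_per_sample"
                      if getattr(model, "pre_center_features", False)
                      else "per_sample_over_features"),
        "sign_convention": "largest_abs_loading_positive",
        "n_features_in": int(model.n_features_in_),
    }
    arrays = {
        "components": model.components_,
        "explained_variance": model.explained_variance_,
        "meta": np.array(json.dumps(meta)),
    }
    if hasattr(model, "shared_components_"):
        arrays["shared_components"] = model.shared_components_
    if hasattr(model, "canonical_correlations_"):
        arrays["canonical_correlations"] = model.canonical_correlations_
    if hasattr(model, "feature_names_in_"):
        arrays["feature_names"] = np.asarray(model.feature_names_in_, dtype=str)
    if getattr(model, "pre_center_features", False):
        arrays["feature_means"] = model.feature_means_
    np.savez(path, **arrays)


def load_model(path):
    """Reconstruct a fitted estimator from an archive written by
    :func:`save_model`."""
    try:
        with np.load(path, allow_pickle=False) as npz:
            data = {k: npz[k] for k in npz.files}
    except (OSError, zipfile.BadZipFile, ValueError, KeyError) as exc:
        raise ModelArchiveError(f"unreadable model archive {path}: {exc}") from exc
    try:
        meta = json.loads(str(data["meta"]))
    except (KeyError, json.JSONDecodeError) as exc:
        raise ModelArchiveError(f"corrupt metadata in {path}") from exc
    major = str(meta.get("format_version", "?")).split(".")[0]
    if major != FORMAT_VERSION.split(".")[0]:
        raise ModelArchiveError(
            f"archive format version {meta.get('format_version')} is not "
            f"supported by this tool (expects major {FORMAT_VERSION.split('.')[0]})"
        )
    cls = _CLASSES.get(meta.get("class"))
    if cls is None:
        raise ModelArchiveError(f"unknown model class {meta.get('class')!r}")
    params = meta["params"]
    # JSON round-trips tuples as lists; estimator params here are scalars
    model = cls(**params)
    model.components_ = data["components"]
    model.explained_variance_ = data["explained_variance"]
    model.n_features_in_ = int(meta["n_features_in"])
    if "shared_components" in data:
        model.shared_components_ = data["shared_components"]
    if "canonical_correlations" in data:
        model.canonical_correlations_ = data["canonical_correlations"]
    if "feature_names" in data:
        model.feature_names_in_ = data["feature_names"]
    if "feature_means" in data:
        model.feature_means_ = data["feature_means"]
    return model
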