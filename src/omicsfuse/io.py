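"""File formats: delimited-text matrices, label files, the network container.

Text matrices are tab-delimited with features in rows and samples in
columns; the header row holds sample ids and the first column feature ids.
Missing values are empty fields or "NA". Values are written with 12
significant digits so a write/read round trip is lossless at that precision.

The intermediate similarity-network container (consumed repeatedly by the
consensus stage) is a single ``.npz`` array archive holding every layer's A
and W, the sample roster, and the construction config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix
from .simnet import MultiplexNetwork, SimilarityLayer

logger = logging.getLogger(__name__)

__all__ = [
    "read_feature_matrix",
    "write_feature_matrix",
    "read_labels",
    "write_labels",
    "save_network",
    "load_network",
    "write_manifest",
]

_NA = ["NA", "nan", "NaN", ""]
FLOAT_FMT = "%.12g"


def read_feature_matrix(path, layer_name: str | None = None) -> FeatureMatrix:
    """Read a features x samples TSV into the samples x features convention."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = next(h for i, h in enumerate(header) if h in header[:i])
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=_NA, keep_default_na=False
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r} in {path}")
    df.columns = header
    try:
        values = df.to_numpy(dtype=float).T
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
    name = layer_name or str(path)
    return FeatureMatrix(values, list(df.columns), list(df.index), name)


def write_feature_matrix(m: FeatureMatrix, path) -> None:
    df = pd.DataFrame(
        m.values.T, index=m.feature_ids, columns=m.sample_ids
    )
    df.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FMT)


def read_labels(path) -> pd.Series:
    """Two-column TSV (sample_id <tab> label) -> Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    if s.index.has_duplicates:
        raise ValueError(f"duplicate sample id in label file {path}")
    return s


def write_labels(sample_ids, labels, path) -> None:
    pd.DataFrame({"sample": sample_ids, "label": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


def save_network(network: MultiplexNetwork, path, config: dict | None = None) -> None:
    arrays = {
        "sample_ids": np.array(network.sample_ids, dtype=object),
        "t": np.array(network.t),
        "config_json": np.array(json.dumps(config or {})),
    }
    for i, lay in enumerate(network.layers):
        arrays[f"A_{i}"] = lay.A
        arrays[f"W_{i}"] = lay.W
        arrays[f"meta_{i}"] = np.array(
            json.dumps(
                {
                    "n_layer": lay.n_layer,
                    "lambda_weight": lay.lambda_weight,
                    "metric": lay.metric,
                    "name": lay.name,
                }
            )
        )
    np.savez(path, **{k: v for k, v in arrays.items()}, allow_pickle=True)


def load_network(path) -> tuple[MultiplexNetwork, dict]:
    with np.load(path, allow_pickle=True) as z:
        t = int(z["t"])
        sample_ids = [str(s) for s in z["sample_ids"]]
        config = json.loads(str(z["config_json"]))
        layers = []
        for i in range(t):
            meta = json.loads(str(z[f"meta_{i}"]))
            layers.append(
                SimilarityLayer(
                    z[f"A_{i}"],
                    z[f"W_{i}"],
                    int(meta["n_layer"]),
                    float(meta["lambda_weight"]),
                    meta["metric"],
                    meta["name"],
                )
            )
    net = MultiplexNetwork(layers, sample_ids)
    net.validate()
    return net, config


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, inputs: list) -> None:
    """Reproducibility manifest: config echo, input digests, version, time."""
    from . import __version__

    manifest = {
        "tool": "omicsfuse",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "inputs": [
            {"path": str(p), "sha256": sha256_file(p)} for p in inputs
        ],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
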