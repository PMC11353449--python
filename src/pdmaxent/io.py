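"""Delimited-text readers and writers.

Text is the canonical storage format: feature tables are TSV with a
``site`` identifier column and one column per named feature (sites as
rows; the in-memory layout is features-by-sites), distributions are
two-column ``site``/``mass`` tables, and group structures are two-column
``feature``/``group`` tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FeatureMatrix
from .datagen import SyntheticDataset
from .exceptions import InvalidInputError
from .regularizers import GroupStructure

__all__ = [
    "write_features",
    "read_features",
    "write_distribution",
    "read_distribution",
    "read_groups",
    "write_groups",
    "write_dataset",
    "read_dataset",
]

SEP = "\t"


def _site_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"s{j:0{width}d}" for j in range(n)]


def write_features(path, features: FeatureMatrix) -> None:
    df = pd.DataFrame(
        features.values.T,
        index=pd.Index(_site_ids(features.n), name="site"),
        columns=list(features.feature_names()),
    )
    df.to_csv(path, sep=SEP, float_format="%.17g")


def read_features(path) -> FeatureMatrix:
    df = pd.read_csv(path, sep=SEP, index_col="site")
    if df.empty:
        raise InvalidInputError(f"no feature rows in {path}")
    return FeatureMatrix(df.to_numpy(dtype=float).T, names=tuple(df.columns))


def write_distribution(path, p: np.ndarray, column: str = "mass") -> None:
    p = np.asarray(p, dtype=float).ravel()
    df = pd.DataFrame(
        {column: p}, index=pd.Index(_site_ids(p.size), name="site")
    )
    df.to_csv(path, sep=SEP, float_format="%.17g")


def read_distribution(path, column: str | None = None) -> np.ndarray:
    df = pd.read_csv(path, sep=SEP, index_col="site")
    col = column if column is not None else df.columns[0]
    return df[col].to_numpy(dtype=float)


def write_groups(path, groups: GroupStructure, feature_names) -> None:
    df = pd.DataFrame({"feature": list(feature_names), "group": list(groups.labels)})
    df.to_csv(path, sep=SEP, index=False)


def read_groups(path, feature_names=None) -> GroupStructure:
    """Read a feature -> group table; if ``feature_names`` is given, the
    rows are validated against it and reordered to match."""
    df = pd.read_csv(path, sep=SEP)
    if not {"feature", "group"} <= set(df.columns):
        raise InvalidInputError("group table needs 'feature' and 'group' columns")
    if feature_names is not None:
        mapping = dict(zip(df["feature"].astype(str), df["group"]))
        missing = [f for f in feature_names if str(f) not in mapping]
        if missing:
            raise InvalidInputError(f"group table missing features: {missing}")
        labels = [mapping[str(f)] for f in feature_names]
    else:
        labels = df["group"].tolist()
    return GroupStructure(tuple(labels))


def write_dataset(outdir, dataset: SyntheticDataset) -> None:
    """Serialize a synthetic dataset to a directory of TSV files + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_features(outdir / "features.tsv", dataset.features)
    write_distribution(outdir / "prior.tsv", dataset.prior, column="prior")
    write_distribution(outdir / "empirical.tsv", dataset.empirical, column="empirical")
    write_distribution(outdir / "true_p.tsv", dataset.true_p, column="true_p")
    pd.DataFrame(
        {"true_w": dataset.true_w},
        index=pd.Index(list(dataset.features.feature_names()), name="feature"),
    ).to_csv(outdir / "true_w.tsv", sep=SEP, float_format="%.17g")
    pd.DataFrame({"site_index": dataset.samples}).to_csv(
        outdir / "samples.tsv", sep=SEP, index=False
    )
    manifest = {"seed": dataset.seed, "params": dataset.params}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_dataset(outdir) -> SyntheticDataset:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    features = read_features(outdir / "features.tsv")
    true_w = pd.read_csv(outdir / "true_w.tsv", sep=SEP, index_col="feature")[
        "true_w"
    ].to_numpy(dtype=float)
    samples = pd.read_csv(outdir / "samples.tsv", sep=SEP)["site_index"].to_numpy(
        dtype=int
    )
    return SyntheticDataset(
        features=features,
        true_w=true_w,
        prior=read_distribution(outdir / "prior.tsv"),
        true_p=read_distribution(outdir / "true_p.tsv"),
        samples=samples,
        empirical=read_distribution(outdir / "empirical.tsv"),
        seed=int(manifest["seed"]),
        params=manifest["params"],
    )
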