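"""Labeled feature sets and delimited-text feature tables.

A feature table is a delimited text file (comma or tab) with a header row
``sample_id, center, disease, f0 .. f{N-1}``; the ``disease`` column is
optional and may be empty for healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledFeatureSet", "read_feature_table", "write_feature_table"]


class FeatureTableError(ValueError):
    """Raised when a feature table violates the format contract."""


@dataclass
class LabeledFeatureSet:
    """Samples-by-features matrix with a center label track and an optional
    disease label track kept distinct.

    Parameters
    ----------
    features : (P, N) float array
        One row per sample.  No missing values allowed.
    center : (P,) array
        Acquisition-center label per sample (the harmonization class).
    disease : (P,) array, optional
        Diagnosis label per sample; empty string / None marks controls.
    sample_ids : (P,) array, optional
        Unique identifiers; generated as ``s0..s{P-1}`` when omitted.
    """

    features: np.ndarray
    center: np.ndarray
    disease: np.ndarray | None = None
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D samples x features array")
        if self.features.shape[0] < 1 or self.features.shape[1] < 1:
            raise ValueError("features must have at least one sample and one feature")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        self.center = np.asarray(self.center)
        if self.center.shape != (self.n_samples,):
            raise ValueError("center labels must match the number of samples")
        if self.disease is not None:
            self.disease = np.asarray(self.disease)
            if self.disease.shape != (self.n_samples,):
                raise ValueError("disease labels must match the number of samples")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i}" for i in range(self.n_samples)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if len(np.unique(self.sample_ids)) != self.n_samples:
                raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def labels(self, track: str = "center") -> np.ndarray:
        """Return one label track; ``track`` is ``"center"`` or ``"disease"``."""
        if track == "center":
            return self.center
        if track == "disease":
            if self.disease is None:
                raise ValueError("this feature set carries no disease labels")
            return self.disease
        raise ValueError(f"unknown label track {track!r}")

    def subset(self, mask: np.ndarray) -> "LabeledFeatureSet":
        mask = np.asarray(mask)
        return LabeledFeatureSet(
            features=self.features[mask],
            center=self.center[mask],
            disease=None if self.disease is None else self.disease[mask],
            sample_ids=self.sample_ids[mask],
        )

    def controls(self, control_label: str = "") -> "LabeledFeatureSet":
        """Subset of samples whose disease label is empty (healthy controls)."""
        if self.disease is None:
            return self
        lab = np.asarray([str(d) for d in self.disease])
        return self.subset(lab == str(control_label))


def _feature_columns(columns) -> list[str]:
    cols = [c for c in columns if c.startswith("f") and c[1:].isdigit()]
    cols.sort(key=lambda c: int(c[1:]))
    return cols


def read_feature_table(path) -> LabeledFeatureSet:
    """Read a delimited feature table, validating the contract.

    Raises :class:`FeatureTableError` naming the offending rows and columns
    for missing values, non-numeric features or duplicate sample ids.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "center": str},
                     float_precision="round_trip")
    required = {"sample_id", "center"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FeatureTableError(f"missing required columns: {sorted(missing_cols)}")
    fcols = _feature_columns(df.columns)
    if not fcols:
        raise FeatureTableError("no feature columns f0..f{N-1} found")
    expected = [f"f{i}" for i in range(len(fcols))]
    if fcols != expected:
        raise FeatureTableError(f"feature columns are not contiguous f0..f{{N-1}}: got {fcols}")

    problems: list[str] = []
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        problems.append(f"duplicate sample_id values: {sorted(set(dup))}")
    for col in ["sample_id", "center"]:
        bad = df.index[df[col].isna()].tolist()
        if bad:
            problems.append(f"missing values in column {col!r} at rows {bad}")
    feats = df[fcols].apply(pd.to_numeric, errors="coerce")
    bad_cells = np.argwhere(feats.isna().to_numpy())
    for r, c in bad_cells[:20]:
        problems.append(f"missing or non-numeric feature value at row {int(r)}, column {fcols[int(c)]!r}")
    if problems:
        raise FeatureTableError("invalid feature table: " + "; ".join(problems))

    disease = None
    if "disease" in df.columns:
        disease = df["disease"].fillna("").astype(str).to_numpy()
    return LabeledFeatureSet(
        features=feats.to_numpy(dtype=float),
        center=df["center"].to_numpy(),
        disease=disease,
        sample_ids=df["sample_id"].to_numpy(),
    )


def write_feature_table(data: LabeledFeatureSet, path, sep: str = ",") -> None:
    """Write a feature set as delimited text at full float precision."""
    cols: dict[str, object] = {"sample_id": data.sample_ids, "center": data.center}
    cols["disease"] = data.disease if data.disease is not None else [""] * data.n_samples
    for j in range(data.n_features):
        cols[f"f{j}"] = data.features[:, j]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.17g")
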