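"""Assembly of the subjects x features table with stable naming.

Column layout (reference configuration: 90 parcels, 3x3 flexibility
grid, 6 HMM states):

    f1ALFF_parcel1..90, f2ALFF_.., ReHo_.., BDC_.., WDC_..   (450 static)
    NF_g1_o1_parcel1..90 ... NF_g3_o3_parcel1..90            (810)
    FO1..FO6, SR                                             (7)

for 1,267 features in total.  Static-only and dynamic-only tables are
just the corresponding subsets (450 and 817 columns).  Missing subjects
or NaNs are errors by design — there is no imputation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .static import STATIC_METRICS

__all__ = ["FeatureTable", "assemble", "write_feature_table", "read_feature_table"]

LABEL_POSITIVE = "patient"


@dataclass
class FeatureTable:
    """Subjects x named features plus group labels and provenance."""

    features: pd.DataFrame  # index: subject, columns: features
    groups: pd.Series  # subject -> group label
    meta: dict = field(default_factory=dict)

    @property
    def y(self) -> np.ndarray:
        """Binary labels: 1 for patients, 0 otherwise."""
        return (self.groups.loc[self.features.index] == LABEL_POSITIVE).to_numpy(int)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def _flatten_static(block: pd.DataFrame) -> pd.Series:
    parts = []
    for metric in STATIC_METRICS:
        if metric not in block.columns:
            continue
        col = block[metric]
        col.index = [f"{metric}_parcel{p}" for p in block.index]
        parts.append(col)
    return pd.concat(parts)


def _flatten_nf(block: pd.DataFrame) -> pd.Series:
    parts = []
    for cell in block.columns:
        col = block[cell]
        col.index = [f"{cell}_parcel{p}" for p in block.index]
        parts.append(col)
    return pd.concat(parts)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def assemble(
    manifest: pd.DataFrame,
    static_blocks: dict[str, pd.DataFrame] | None = None,
    nf_blocks: dict[str, pd.DataFrame] | None = None,
    hmm_block: pd.DataFrame | None = None,
    meta: dict | None = None,
) -> FeatureTable:
    """Combine per-subject blocks into one ordered feature table.

    ``static_blocks``/``nf_blocks`` map subject -> (parcel x metric/cell)
    frames; ``hmm_block`` is a subjects x (FO1..FOK, SR) frame.  Every
    subject in the manifest must appear in every supplied block; gaps
    and NaNs raise with the offending subject named.
    """
    if static_blocks is None and nf_blocks is None and hmm_block is None:
        raise ValueError("nothing to assemble: all blocks are None")
    subjects = list(manifest["subject"])
    rows = []
    for sub in subjects:
        parts = []
        if static_blocks is not None:
            if sub not in static_blocks:
                raise KeyError(f"subject {sub} missing from the static block")
            parts.append(_flatten_static(static_blocks[sub]))
        if nf_blocks is not None:
            if sub not in nf_blocks:
                raise KeyError(f"subject {sub} missing from the flexibility block")
            parts.append(_flatten_nf(nf_blocks[sub]))
        if hmm_block is not None:
            if sub not in hmm_block.index:
                raise KeyError(f"subject {sub} missing from the HMM block")
            parts.append(hmm_block.loc[sub])
        rows.append(pd.concat(parts))
    features = pd.DataFrame(rows, index=pd.Index(subjects, name="subject"))
    if features.columns.duplicated().any():
        dup = features.columns[features.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names: {dup[:5]}")
    if features.isna().any().any():
        bad = features.index[features.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values for subjects {bad[:5]}")
    groups = manifest.set_index("subject")["group"]
    return FeatureTable(features=features, groups=groups, meta=dict(meta or {}))


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """TSV + JSON sidecar (provenance: config hash, seeds, counts)."""
    path = Path(path)
    out = table.features.copy()
    out.insert(0, "group", table.groups.loc[out.index])
    out.to_csv(path, sep="\t")
    sidecar = dict(table.meta)
    sidecar["n_subjects"] = int(table.features.shape[0])
    sidecar["n_features"] = int(table.features.shape[1])
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="subject", float_precision="round_trip")
    groups = df.pop("group")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return FeatureTable(features=df, groups=groups, meta=meta)
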