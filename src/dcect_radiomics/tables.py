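"""Long-format feature tables and external-CSV ingestion.

The canonical layout is one row per (patient, radiologist, phase, sequence,
feature): columns ``patient_id, radiologist, phase, seq_index, feature,
value``. ``FeatureTable.wide()`` pivots this into one patients x features
frame per (phase, seq_index) for the concordance machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import feature_names, normalize_feature_name

REQUIRED_COLUMNS = ("patient_id", "radiologist", "phase", "seq_index", "feature", "value")


@dataclass
class FeatureTable:
    """Long-format per-(patient, radiologist, sequence) feature records."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        dup = self.df.duplicated(["patient_id", "radiologist", "phase", "seq_index", "feature"])
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate (patient, radiologist, "
                             "sequence, feature) records")

    @classmethod
    def from_records(cls, rows: list[dict]) -> "FeatureTable":
        return cls(pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)))

    @classmethod
    def from_feature_vectors(cls, entries) -> "FeatureTable":
        """entries: iterable of (patient_id, radiologist, phase, seq_index,
        feature_vector dict)."""
        rows = []
        for pid, rad, phase, seq, fv in entries:
            for name, value in fv.items():
                rows.append({"patient_id": pid, "radiologist": rad, "phase": phase,
                             "seq_index": int(seq), "feature": name, "value": float(value)})
        return cls.from_records(rows)

    def radiologist(self, rad: str) -> "FeatureTable":
        return FeatureTable(self.df[self.df.radiologist == rad].reset_index(drop=True))

    def features(self) -> list[str]:
        return sorted(self.df.feature.unique())

    def patients(self) -> list[str]:
        return sorted(self.df.patient_id.unique())

    def wide(self) -> dict[tuple[str, int], pd.DataFrame]:
        """{(phase, seq_index): patients x features DataFrame}."""
        out = {}
        for (phase, seq), g in self.df.groupby(["phase", "seq_index"]):
            out[(str(phase), int(seq))] = g.pivot(index="patient_id",
                                                  columns="feature", values="value")
        return out

    def patient_matrix(self, phase: str | None = None,
                       features: list[str] | None = None) -> pd.DataFrame:
        """Patients x features matrix, feature values averaged over the
        (selected) sequences of ``phase`` (all phases when None)."""
        df = self.df if phase is None else self.df[self.df.phase == phase]
        mat = df.pivot_table(index="patient_id", columns="feature",
                             values="value", aggfunc="mean")
        return mat[features] if features is not None else mat

    def to_csv(self, path) -> None:
        """Wide per-sequence CSV: one row per (patient, radiologist, phase,
        seq_index) with the 127 feature columns in registry order."""
        wide = self.df.pivot_table(
            index=["patient_id", "radiologist", "phase", "seq_index"],
            columns="feature", values="value", aggfunc="first")
        cols = [c for c in feature_names() if c in wide.columns]
        cols += [c for c in wide.columns if c not in cols]
        wide[cols].reset_index().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        wide = pd.read_csv(path)
        id_cols = ["patient_id", "radiologist", "phase", "seq_index"]
        missing = [c for c in id_cols if c not in wide.columns]
        if missing:
            raise ValueError(f"missing identifier columns: {missing}")
        long = wide.melt(id_vars=id_cols, var_name="feature", value_name="value")
        return cls(long.dropna(subset=["value"]).reset_index(drop=True))


DEFAULT_COLUMN_MAPPING = {
    "patient_id": ("patient_id", "patient", "id", "case", "case_id"),
    "radiologist": ("radiologist", "reader", "observer", "rater"),
    "phase": ("phase", "contrast_phase", "enhancement_phase"),
    "seq_index": ("seq_index", "sequence", "seq", "sequence_index", "time_index"),
}


def ingest_external_table(path, mapping: dict[str, str] | None = None) -> FeatureTable:
    """Read an externally produced wide feature CSV into a FeatureTable.

    ``mapping`` maps canonical identifier names to the file's column names;
    unmapped identifier columns are searched among common synonyms. Remaining
    columns are matched against the feature registry, tolerating underscore /
    spacing / trailing-punctuation variants; columns that match nothing are
    reported in a warning and kept under their normalized name.
    """
    raw = pd.read_csv(path)
    if raw.empty:
        raise ValueError(f"{path}: empty table")
    mapping = dict(mapping or {})
    rename = {}
    for canon, synonyms in DEFAULT_COLUMN_MAPPING.items():
        if canon in mapping:
            if mapping[canon] not in raw.columns:
                raise ValueError(
                    f"mapped column {mapping[canon]!r} for {canon!r} not in file; "
                    f"candidates: {list(raw.columns)[:8]}")
            rename[mapping[canon]] = canon
            continue
        hit = [c for c in raw.columns if c.strip().lower() in synonyms]
        if not hit:
            raise ValueError(f"no column found for {canon!r}; "
                             f"candidates: {list(raw.columns)[:8]}")
        rename[hit[0]] = canon
    raw = raw.rename(columns=rename)

    feat_rename, unmatched = {}, []
    for c in raw.columns:
        if c in DEFAULT_COLUMN_MAPPING:
            continue
        hit = normalize_feature_name(str(c))
        if hit is None:
            unmatched.append(str(c))
            feat_rename[c] = " ".join(str(c).replace("_", " ").split())
        else:
            feat_rename[c] = hit
    if unmatched:
        warnings.warn(f"{len(unmatched)} columns did not match the feature "
                      f"registry: {unmatched[:5]}")
    raw = raw.rename(columns=feat_rename)
    id_cols = list(DEFAULT_COLUMN_MAPPING)
    long = raw.melt(id_vars=id_cols, var_name="feature", value_name="value")
    long["seq_index"] = long["seq_index"].astype(int)
    return FeatureTable(long.dropna(subset=["value"]).reset_index(drop=True))
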