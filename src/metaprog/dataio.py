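"""Data model and I/O for longitudinal metabolomics cohorts.

A cohort is stored in long format: one row per (individual, age, metabolite)
with a concentration in µmol/l, plus a per-individual metadata table carrying
the progression group, sex, insulin-autoantibody (IAA) status and end of
follow-up.  Visits are complete profiles: a visit at which any metabolite is
missing is dropped on read (the Gaussian-emission state model downstream
assumes complete profiles), and the number of dropped visits is logged.

Ages are kept in the input's native unit (weeks for mice, years for
children); no unit conversion is attempted, because cross-species comparison
happens in latent state space rather than age space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("metaprog")

DATA_COLUMNS = ["individual", "age", "metabolite", "concentration"]
META_COLUMNS = ["individual", "group", "sex", "iaa_status", "followup_end"]

GROUPS = ("progressor", "non-progressor")
SEXES = ("F", "M")
IAA_STATUSES = ("positive", "negative", "unknown")


class FormatError(ValueError):
    """A file does not have the expected columns or delimiter."""


class ValidationError(ValueError):
    """A dataset violates one of the documented invariants."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs shared across the analysis stages.

    ``bootstrap_n`` is the number of nonparametric bootstrap replicates used
    for confidence bands (the full-study setting is 5000); ``resample_n`` the
    number of resamples for the risk-marker tolerance bound;
    ``marker_threshold`` the decision boundary of the surrogate marker.
    """

    n_states: int = 3
    log_transform: bool = True
    bootstrap_n: int = 5000
    resample_n: int = 1000
    marker_threshold: float = -0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValidationError("n_states must be a positive integer")
        if self.bootstrap_n < 1 or self.resample_n < 1:
            raise ValidationError("bootstrap_n and resample_n must be positive")
        if not np.isfinite(self.marker_threshold):
            raise ValidationError("marker_threshold must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} must be a key: value mapping")
        raw.update(overrides)
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass
class LongitudinalDataset:
    """Long-format records plus per-individual metadata.

    ``records`` has columns individual, age, metabolite, concentration;
    ``meta`` has columns individual, group, sex, iaa_status, followup_end.
    ``metabolite_index`` fixes the column order of every visit matrix.
    """

    records: pd.DataFrame
    meta: pd.DataFrame
    metabolite_index: list[str] = field(default_factory=list)
    #: False once concentrations have been log-transformed (may be negative)
    raw_scale: bool = True

    def __post_init__(self) -> None:
        if not self.metabolite_index:
            self.metabolite_index = sorted(self.records["metabolite"].unique())
        validate(self)

    @property
    def individuals(self) -> list[str]:
        return list(self.meta["individual"])

    def individuals_in_group(self, group: str) -> list[str]:
        return list(self.meta.loc[self.meta["group"] == group, "individual"])

    def subset(self, individuals: Sequence[str]) -> "LongitudinalDataset":
        """Restrict to the given individuals (order and duplicates ignored)."""
        keep = set(individuals)
        rec = self.records[self.records["individual"].isin(keep)].reset_index(drop=True)
        meta = self.meta[self.meta["individual"].isin(keep)].reset_index(drop=True)
        return LongitudinalDataset(rec, meta, list(self.metabolite_index), self.raw_scale)

    def n_visits(self, individual: str) -> int:
        return self.records.loc[self.records["individual"] == individual, "age"].nunique()


def validate(dataset: LongitudinalDataset) -> None:
    """Check every dataset invariant; raise ValidationError naming the first violated one."""
    rec, meta = dataset.records, dataset.meta
    missing = [c for c in DATA_COLUMNS if c not in rec.columns]
    if missing:
        raise FormatError(f"records table missing columns: {missing}")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata table missing columns: {missing}")
    if len(rec):
        if dataset.raw_scale:
            neg = rec.index[rec["concentration"] < 0]
            if len(neg):
                raise ValidationError(
                    f"invariant 'concentration >= 0' violated at row {neg[0]}"
                )
        bad_age = rec.index[rec["age"] <= 0]
        if len(bad_age):
            raise ValidationError(f"invariant 'age > 0' violated at row {bad_age[0]}")
        if rec.duplicated(["individual", "age", "metabolite"]).any():
            raise ValidationError(
                "invariant '(individual, age, metabolite) unique' violated"
            )
    if meta["individual"].duplicated().any():
        raise ValidationError("invariant 'one metadata row per individual' violated")
    unknown_group = set(meta["group"]) - set(GROUPS)
    if unknown_group:
        raise ValidationError(f"invariant 'group in {GROUPS}' violated: {unknown_group}")
    unknown_iaa = set(meta["iaa_status"]) - set(IAA_STATUSES)
    if unknown_iaa:
        raise ValidationError(
            f"invariant 'iaa_status in {IAA_STATUSES}' violated: {unknown_iaa}"
        )
    orphans = set(rec["individual"]) - set(meta["individual"])
    if orphans:
        raise ValidationError(
            f"invariant 'every individual has metadata' violated: {sorted(orphans)[:5]}"
        )
    if len(rec):
        max_age = rec.groupby("individual")["age"].max()
        merged = meta.set_index("individual")["followup_end"].reindex(max_age.index)
        late = max_age.index[max_age > merged]
        if len(late):
            raise ValidationError(
                f"invariant 'followup_end >= last observed age' violated for {late[0]}"
            )
        # complete-profile visits: every visit carries the full metabolite panel
        sizes = rec.groupby(["individual", "age"])["metabolite"].nunique()
        short = sizes[sizes != len(dataset.metabolite_index)]
        if len(short):
            ind, age = short.index[0]
            raise ValidationError(
                "invariant 'complete-profile visits' violated for "
                f"individual {ind} at age {age}"
            )


def _sep_for(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix == ".tsv":
        return "\t"
    raise FormatError(f"unsupported extension {suffix!r}; use .csv or .tsv")


def read_long_table(
    data_path: str | Path,
    meta_path: str | Path,
) -> LongitudinalDataset:
    """Read a long-format concentration table and its metadata companion.

    Visits with a partial metabolite profile are dropped (with a logged
    count) rather than imputed.  Raises FormatError for missing columns and
    ValidationError for invariant violations, naming the offending row.
    """
    rec = pd.read_csv(data_path, sep=_sep_for(data_path))
    missing = [c for c in DATA_COLUMNS if c not in rec.columns]
    if missing:
        raise FormatError(f"{data_path}: missing columns {missing}")
    meta = pd.read_csv(meta_path, sep=_sep_for(meta_path))
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{meta_path}: missing columns {missing}")

    neg = rec.index[rec["concentration"] < 0]
    if len(neg):
        # +2: header line plus 1-based numbering, so the message points at the file
        raise ValidationError(
            f"{data_path}: negative concentration at file line {neg[0] + 2}"
        )

    rec["individual"] = rec["individual"].astype(str)
    meta["individual"] = meta["individual"].astype(str)
    metabolite_index = sorted(rec["metabolite"].unique())
    sizes = rec.groupby(["individual", "age"])["metabolite"].nunique()
    incomplete = sizes[sizes != len(metabolite_index)]
    if len(incomplete):
        logger.warning(
            "dropping %d visit(s) with incomplete metabolite profiles", len(incomplete)
        )
        bad = set(incomplete.index)
        keys = list(zip(rec["individual"], rec["age"]))
        rec = rec[[k not in bad for k in keys]].reset_index(drop=True)

    return LongitudinalDataset(rec, meta, metabolite_index)


def write_long_table(
    dataset: LongitudinalDataset,
    data_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    """Write records (and optionally metadata) as delimited text with stable column order."""
    dataset.records[DATA_COLUMNS].to_csv(data_path, sep=_sep_for(data_path), index=False)
    if meta_path is not None:
        dataset.meta[META_COLUMNS].to_csv(meta_path, sep=_sep_for(meta_path), index=False)


def to_visit_matrix(
    dataset: LongitudinalDataset, individual: str
) -> tuple[np.ndarray, np.ndarray]:
    """Return (ages, matrix) for one individual: visits x metabolites.

    Rows are sorted by ascending age; columns follow ``metabolite_index``.
    """
    rec = dataset.records[dataset.records["individual"] == individual]
    if rec.empty:
        raise KeyError(f"unknown individual {individual!r}")
    wide = rec.pivot(index="age", columns="metabolite", values="concentration")
    wide = wide.sort_index().reindex(columns=dataset.metabolite_index)
    return wide.index.to_numpy(dtype=float), wide.to_numpy(dtype=float)


def log2_transform(
    dataset: LongitudinalDataset, pseudocount: float = 1.0
) -> LongitudinalDataset:
    """Map concentrations to log2(x + pseudocount).

    Lipid concentrations are right-skewed; the diagonal-Gaussian emission
    model downstream wants approximate symmetry.  Invertible via
    :func:`inverse_log2_transform` with the same pseudocount.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    rec = dataset.records.copy()
    rec["concentration"] = np.log2(rec["concentration"] + pseudocount)
    return LongitudinalDataset(rec, dataset.meta, list(dataset.metabolite_index), False)


def inverse_log2_transform(
    dataset: LongitudinalDataset, pseudocount: float = 1.0
) -> LongitudinalDataset:
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    rec = dataset.records.copy()
    values = np.exp2(rec["concentration"]) - pseudocount
    # round-off from exp2(log2(x + p)) - p can dip a few ulp below zero
    tiny = -1e-9 * max(pseudocount, 1.0)
    rec["concentration"] = np.where((values < 0) & (values > tiny), 0.0, values)
    return LongitudinalDataset(rec, dataset.meta, list(dataset.metabolite_index))


def modeling_values(
    dataset: LongitudinalDataset, config: AnalysisConfig
) -> LongitudinalDataset:
    """Dataset on the scale the state model is fitted on (log2(x+1) by default)."""
    return log2_transform(dataset) if config.log_transform else dataset
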