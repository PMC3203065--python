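"""Surrogate diabetes-risk marker from lysoPC concentration and IAA status.

The marker combines two measurements taken at a single early age (8 weeks in
the mouse study design):

1. lysoPC concentration (µmol/l) = PC(16:0/0:0) + PC(18:0/0:0);
2. standardize over the cohort to zero mean, unit variance -> lysoPC_S;
3. Marker = lysoPC_S if IAA-negative, -lysoPC_S if IAA-positive
   (IAA positivity with high lysoPC is protective, hence the sign flip);
4. Marker >= -0.1 -> high risk (predicted progressor), else low risk.

Evaluation: the 2x2 risk-call x outcome table, Pearson chi-square without
continuity correction, the relative risk of progression in the high- vs
low-risk group, and a one-sided lower tolerance bound on the relative risk
from resampling individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import LongitudinalDataset
from .synthetic_data import LYSOPC_COMPONENTS

DEFAULT_THRESHOLD = -0.1
DEFAULT_AGE = 8.0


@dataclass
class ContingencyTable:
    """Counts of risk calls against observed outcomes.

    Layout: rows (high risk, low risk), columns (progressor, non-progressor).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class RiskEstimate:
    relative_risk: float
    lower_tolerance_bound: float
    resample_n: int
    corrected: bool  # True when the observed table needed the 0.5 correction


def compute_lysopc(
    dataset: LongitudinalDataset,
    individual: str,
    at_age: float = DEFAULT_AGE,
    components: tuple[str, str] = LYSOPC_COMPONENTS,
) -> float:
    """Summed lysoPC component concentration at the visit nearest ``at_age``."""
    rec = dataset.records[dataset.records["individual"] == individual]
    if rec.empty:
        raise KeyError(f"unknown individual {individual!r}")
    ages = rec["age"].unique()
    visit_age = ages[np.abs(ages - at_age).argmin()]
    visit = rec[rec["age"] == visit_age]
    values = []
    missing = []
    for comp in components:
        row = visit.loc[visit["metabolite"] == comp, "concentration"]
        if row.empty:
            missing.append(comp)
        else:
            values.append(float(row.iloc[0]))
    if missing:
        raise ValueError(
            f"individual {individual!r}, age {visit_age}: missing lysoPC "
            f"component(s) {missing}"
        )
    return float(sum(values))


def scale_and_classify(
    lysopc: np.ndarray,
    iaa_status: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    population_sd: bool = True,
) -> pd.DataFrame:
    """Apply the marker rule to a cohort of lysoPC values and IAA statuses.

    Returns a frame with columns lysopc, lysopc_s, marker, risk_call.  The
    boundary marker == threshold is a high-risk call.  ``population_sd``
    selects the divisor of the standardization (population SD by default;
    the defining rule says only "zero mean and unit variance").
    """
    lysopc = np.asarray(lysopc, dtype=float)
    iaa = np.asarray(iaa_status)
    if len(lysopc) < 2:
        raise ValueError("need at least 2 individuals to standardize")
    if len(lysopc) != len(iaa):
        raise ValueError("lysopc and iaa_status length mismatch")
    unknown = set(np.unique(iaa)) - {"positive", "negative"}
    if unknown:
        raise ValueError(f"IAA status must be resolved; found {sorted(unknown)}")
    sd = lysopc.std(ddof=0 if population_sd else 1)
    if sd == 0:
        raise ValueError("lysoPC values have zero variance; cannot standardize")
    z = (lysopc - lysopc.mean()) / sd
    marker = np.where(iaa == "negative", z, -z)
    return pd.DataFrame(
        {
            "lysopc": lysopc,
            "lysopc_s": z,
            "marker": marker,
            "risk_call": np.where(marker >= threshold, "high", "low"),
        }
    )


def contingency_table(risk_call: np.ndarray, group: np.ndarray) -> ContingencyTable:
    """Tabulate risk calls against progression outcomes."""
    risk_call = np.asarray(risk_call)
    group = np.asarray(group)
    counts = np.array(
        [
            [
                int(np.sum((risk_call == r) & (group == g)))
                for g in ("progressor", "non-progressor")
            ]
            for r in ("high", "low")
        ]
    )
    return ContingencyTable(counts)


def chi_square_test(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on the 2x2 table."""
    c = table.counts
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise ValueError("degenerate margin in contingency table")
    stat, p, _, _ = stats.chi2_contingency(c, correction=False)
    return float(stat), float(p)


def _rr_from_counts(c: np.ndarray) -> float:
    if np.any(c == 0):
        c = c + 0.5
    p_high = c[0, 0] / c[0].sum()
    p_low = c[1, 0] / c[1].sum()
    return float(p_high / p_low)


def relative_risk(
    risk_call: np.ndarray,
    group: np.ndarray,
    resample_n: int = 1000,
    seed: int = 0,
) -> RiskEstimate:
    """Relative risk of progression (high vs low risk) with a resampled
    one-sided lower tolerance bound.

    The bound is the 5th percentile of the relative risk over ``resample_n``
    bootstrap resamples of individuals.  Any resample (or observed table)
    with a zero cell on the progression column gets 0.5 added to every cell.
    """
    risk_call = np.asarray(risk_call)
    group = np.asarray(group)
    obs = contingency_table(risk_call, group)
    if np.any(obs.counts.sum(axis=1) == 0):
        raise ValueError("a risk group is empty; relative risk undefined")
    corrected = bool(np.any(obs.counts == 0))
    rr = _rr_from_counts(obs.counts)
    rng = np.random.default_rng(seed)
    n = len(risk_call)
    reps = np.empty(resample_n)
    for b in range(resample_n):
        idx = rng.integers(0, n, size=n)
        # zero cells in a resample are handled by the 0.5 correction inside
        reps[b] = _rr_from_counts(contingency_table(risk_call[idx], group[idx]).counts)
    bound = float(np.percentile(reps, 5.0))
    return RiskEstimate(rr, bound, resample_n, bool(corrected))


@dataclass
class MarkerEvaluation:
    per_individual: pd.DataFrame
    table: ContingencyTable
    chi2: float
    p_value: float
    risk: RiskEstimate


def evaluate_marker(
    cohort: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    resample_n: int = 1000,
    seed: int = 0,
) -> MarkerEvaluation:
    """End-to-end marker evaluation on a cohort table.

    ``cohort`` needs the two lysoPC component columns plus iaa_status and
    group (as produced by the marker cohort generator, or assembled from a
    longitudinal dataset via :func:`marker_table_from_dataset`).
    """
    lysopc = cohort[list(LYSOPC_COMPONENTS)].sum(axis=1).to_numpy()
    calls = scale_and_classify(lysopc, cohort["iaa_status"].to_numpy(), threshold)
    calls.insert(0, "individual", cohort["individual"].to_numpy())
    calls["group"] = cohort["group"].to_numpy()
    table = contingency_table(calls["risk_call"].to_numpy(), calls["group"].to_numpy())
    chi2, p = chi_square_test(table)
    risk = relative_risk(
        calls["risk_call"].to_numpy(), calls["group"].to_numpy(), resample_n, seed
    )
    return MarkerEvaluation(calls, table, chi2, p, risk)


def marker_table_from_dataset(
    dataset: LongitudinalDataset,
    at_age: float = DEFAULT_AGE,
    components: tuple[str, str] = LYSOPC_COMPONENTS,
) -> pd.DataFrame:
    """Assemble the marker cohort table from a longitudinal dataset."""
    rows = []
    for _, m in dataset.meta.iterrows():
        total = compute_lysopc(dataset, m["individual"], at_age, components)
        rec = dataset.records[dataset.records["individual"] == m["individual"]]
        ages = rec["age"].unique()
        visit_age = ages[np.abs(ages - at_age).argmin()]
        visit = rec[rec["age"] == visit_age].set_index("metabolite")["concentration"]
        rows.append(
            {
                "individual": m["individual"],
                components[0]: float(visit[components[0]]),
                components[1]: float(visit[components[1]]),
                "lysopc": total,
                "iaa_status": m["iaa_status"],
                "group": m["group"],
            }
        )
    return pd.DataFrame(rows)
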