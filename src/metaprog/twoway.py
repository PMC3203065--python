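"""Bootstrap two-way decomposition of organism x disease effects.

For a matched metabolite measured in two organisms (e.g. human and mouse)
and two disease groups (progressor / non-progressor), the cell means of the
2x2 design are decomposed as

    mean(o, g) = grand_mean + organism(o) + disease(g) + interaction(o, g)

with sum-to-zero effect coding, so "removing the organism effect" is
literally subtracting a single organism mean parameter estimated by least
squares.  Unbalanced cells are handled by weighting each cell equally (least
squares on cell means).  Confidence intervals come from a stratified
nonparametric bootstrap that resamples observations within each cell, which
preserves the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ORGANISMS = ("human", "mouse")
GROUPS = ("progressor", "non-progressor")


@dataclass
class TwoWayDecomposition:
    """Point estimates of the 2x2 cell-means decomposition.

    ``organism_effect`` is the effect of the first organism level (the
    second is its negation); likewise ``disease_effect`` for the first group
    level and ``interaction`` for the (first, first) cell.
    """

    grand_mean: float
    organism_effect: float
    disease_effect: float
    interaction: float
    organisms: tuple[str, str] = ORGANISMS
    groups: tuple[str, str] = GROUPS

    def cell_mean(self, organism: str, group: str) -> float:
        so = 1.0 if organism == self.organisms[0] else -1.0
        sg = 1.0 if group == self.groups[0] else -1.0
        return (
            self.grand_mean
            + so * self.organism_effect
            + sg * self.disease_effect
            + so * sg * self.interaction
        )


def _cell_values(
    values: pd.DataFrame,
    organisms: tuple[str, str],
    groups: tuple[str, str],
) -> dict[tuple[str, str], np.ndarray]:
    cells = {}
    for o in organisms:
        for g in groups:
            v = values.loc[
                (values["organism"] == o) & (values["group"] == g), "value"
            ].to_numpy(dtype=float)
            if len(v) == 0:
                raise ValueError(f"empty design cell ({o}, {g})")
            cells[(o, g)] = v
    return cells


def decompose_effects(
    values: pd.DataFrame,
    organisms: tuple[str, str] = ORGANISMS,
    groups: tuple[str, str] = GROUPS,
) -> TwoWayDecomposition:
    """Least-squares cell-means decomposition with sum-to-zero contrasts.

    ``values`` must have columns organism, group, value with at least one
    observation per cell.  The reconstruction identity
    cell_mean = grand + organism + disease + interaction holds exactly.
    """
    cells = _cell_values(values, organisms, groups)
    m = {k: float(v.mean()) for k, v in cells.items()}
    o0, o1 = organisms
    g0, g1 = groups
    grand = (m[o0, g0] + m[o0, g1] + m[o1, g0] + m[o1, g1]) / 4.0
    org = (m[o0, g0] + m[o0, g1]) / 2.0 - grand
    dis = (m[o0, g0] + m[o1, g0]) / 2.0 - grand
    inter = m[o0, g0] - grand - org - dis
    return TwoWayDecomposition(grand, org, dis, inter, organisms, groups)


def bootstrap_effect_ci(
    values: pd.DataFrame,
    bootstrap_n: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    organisms: tuple[str, str] = ORGANISMS,
    groups: tuple[str, str] = GROUPS,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for all four decomposition components.

    Observations are resampled with replacement within each design cell.
    Returns a frame indexed by effect name with columns estimate, lower,
    upper.  Deterministic given ``seed``.
    """
    if bootstrap_n < 1:
        raise ValueError("bootstrap_n must be >= 1")
    point = decompose_effects(values, organisms, groups)
    cells = _cell_values(values, organisms, groups)
    rng = np.random.default_rng(seed)
    o0, o1 = organisms
    g0, g1 = groups
    # vectorized within-cell resampling: one (bootstrap_n,) mean vector per cell
    means = {}
    for key in ((o0, g0), (o0, g1), (o1, g0), (o1, g1)):
        v = cells[key]
        idx = rng.integers(0, len(v), size=(bootstrap_n, len(v)))
        means[key] = v[idx].mean(axis=1)
    grand = (means[o0, g0] + means[o0, g1] + means[o1, g0] + means[o1, g1]) / 4.0
    org = (means[o0, g0] + means[o0, g1]) / 2.0 - grand
    dis = (means[o0, g0] + means[o1, g0]) / 2.0 - grand
    reps = np.column_stack([grand, org, dis, means[o0, g0] - grand - org - dis])
    lo = np.percentile(reps, 100 * alpha / 2, axis=0)
    hi = np.percentile(reps, 100 * (1 - alpha / 2), axis=0)
    est = [point.grand_mean, point.organism_effect, point.disease_effect, point.interaction]
    return pd.DataFrame(
        {"estimate": est, "lower": lo, "upper": hi},
        index=["grand_mean", "organism_effect", "disease_effect", "interaction"],
    )


def decompose_pairs(
    table: pd.DataFrame,
    bootstrap_n: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the decomposition per matched metabolite pair.

    ``table`` has columns pair, organism, group, value.  Returns one row per
    pair with each effect's estimate and CI.
    """
    out = []
    for i, (pair, sub) in enumerate(table.groupby("pair", sort=True)):
        ci = bootstrap_effect_ci(sub, bootstrap_n, seed + i, alpha)
        row: dict[str, object] = {"pair": pair}
        for name, r in ci.iterrows():
            row[name] = r["estimate"]
            row[f"{name}_lower"] = r["lower"]
            row[f"{name}_upper"] = r["upper"]
        out.append(row)
    return pd.DataFrame(out)
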