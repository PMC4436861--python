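"""Per-family summary tables and headline aggregates.

Assembles the taxonomic verdicts, the phylogenetic metrics and the
null-model p-values into one row per family (the shape of the published
survey table), together with the aggregates used to characterise the
overall mode of trait evolution: the median NoTO, the number of families
with NoTO < 2 (many shallow origins), and the total number of inferred
gains. Kendall tau-b rank correlations check whether the metrics track
sampling artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import DiversityVerdict, FamilyRecord
from .metrics import MetricResult
from .nullmodel import NullResult

__all__ = [
    "FamilySummary",
    "noto_aggregates",
    "summarize",
    "kendall_tau",
    "format_summary_frame",
]


@dataclass(frozen=True)
class FamilySummary:
    family: str
    order: str
    family_size: int
    known_halophytes: int
    taxonomic_pattern: str
    subtree_size: int
    halophytes_in_subtree: int
    pct_species_sampled: float
    pct_halophytes_in_subtree: float
    pct_halophytes_sampled: float
    inferred_origins: int
    noto: float
    sscd: float
    p_noto: float
    p_sscd: float


def noto_aggregates(halophytes: Sequence[int], origins: Sequence[int]) -> dict:
    """NoTO per family plus the headline aggregates.

    ``halophytes[i]`` is the trait-positive tip count of family i's
    subtree and ``origins[i]`` its inferred gain count. The median over an
    even number of families is the midpoint of the two central values;
    it is computed on the full-precision ratios.
    """
    h = np.asarray(halophytes, dtype=float)
    g = np.asarray(origins, dtype=float)
    if h.shape != g.shape or h.ndim != 1 or h.size == 0:
        raise ValueError("halophytes and origins must be equal-length 1-D sequences")
    if (g < 1).any():
        raise ValueError("origin counts must be >= 1")
    noto = h / g
    return {
        "noto": noto,
        "median_noto": float(np.median(noto)),
        "n_families_noto_lt2": int((noto < 2).sum()),
        "total_origins": int(g.sum()),
    }


def summarize(
    records: Mapping[str, FamilyRecord],
    verdicts: Mapping[str, DiversityVerdict],
    metrics: Mapping[str, MetricResult],
    nulls: Mapping[str, NullResult],
    subtree_sizes: Mapping[str, int],
) -> tuple[pd.DataFrame, dict]:
    """One summary row per family plus the headline aggregates.

    All five mappings must be keyed by the same family names.
    """
    keys = set(metrics)
    for name, m in (("records", records), ("verdicts", verdicts),
                    ("nulls", nulls), ("subtree sizes", subtree_sizes)):
        if set(m) != keys:
            raise ValueError(f"family keys of {name} do not match the metrics")
    rows = []
    for fam in sorted(keys):
        rec, ver, met, nul = records[fam], verdicts[fam], metrics[fam], nulls[fam]
        n_sub = int(subtree_sizes[fam])
        rows.append(
            FamilySummary(
                family=fam,
                order=rec.order,
                family_size=rec.n_species,
                known_halophytes=rec.k_halophytes,
                taxonomic_pattern=ver.classification,
                subtree_size=n_sub,
                halophytes_in_subtree=met.n_halophyte_tips,
                pct_species_sampled=100.0 * n_sub / rec.n_species,
                pct_halophytes_in_subtree=100.0 * met.n_halophyte_tips / n_sub,
                pct_halophytes_sampled=(
                    100.0 * met.n_halophyte_tips / rec.k_halophytes
                    if rec.k_halophytes else float("nan")
                ),
                inferred_origins=met.n_gains,
                noto=met.noto,
                sscd=met.sscd,
                p_noto=nul.p_noto,
                p_sscd=nul.p_sscd,
            )
        )
    df = pd.DataFrame([vars(r) for r in rows])
    agg = noto_aggregates(df["halophytes_in_subtree"], df["inferred_origins"])
    aggregates = {
        "n_families": len(rows),
        "median_noto": agg["median_noto"],
        "n_families_noto_lt2": agg["n_families_noto_lt2"],
        "total_origins": agg["total_origins"],
        "n_labile": int(((df["p_noto"] <= 0.05) | (df["p_sscd"] <= 0.05)).sum()),
        "n_conserved_flagged": int(
            ((df["p_noto"] >= 0.95) & (df["p_sscd"] >= 0.95)).sum()
        ),
    }
    return df, aggregates


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall tau-b with its p-value.

    Tau-b corrects for ties, which are guaranteed here (p-values are
    multiples of 1/n_sims, percentages repeat). For n <= 9 with no ties
    the p-value comes from exact enumeration of the permutation null;
    otherwise from the standard normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    has_ties = len(np.unique(x)) < x.size or len(np.unique(y)) < y.size
    method = "exact" if (x.size <= 9 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def format_summary_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Round the summary for display: NoTO and percentages to 1 dp, p to 2 dp."""
    out = df.copy()
    for col in ("noto", "pct_species_sampled", "pct_halophytes_in_subtree",
                "pct_halophytes_sampled"):
        if col in out:
            out[col] = out[col].round(1)
    for col in ("p_noto", "p_sscd"):
        if col in out:
            out[col] = out[col].round(2)
    return out
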