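"""Family-level tests of halophyte over/under-representation.

Families partition angiosperm diversity into defined groups; under the
null, each family's halophyte count k_i is Binomial(n_i, p̂) with n_i the
family's species count and p̂ the global proportion of halophytes across
all families. Two strict one-sided tail tests classify each family:

* "more"   if P(X >= k) < alpha,
* "fewer"  if P(X <= k) < alpha,
* "expected" otherwise (ties at exactly alpha stay "expected").

No multiple-testing correction is applied across families: the verdicts
are descriptive labels for a table of several hundred families, not a
controlled discovery set, and consumers who need FWER/FDR control should
apply it to the reported tail probabilities themselves.

An overall likelihood-ratio G-test of independence on the families ×
{halophyte, non-halophyte} contingency table measures global departure
from the binomial-null fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FamilyRecord",
    "DiversityVerdict",
    "GTestResult",
    "overall_proportion",
    "binomial_tails",
    "classify_family",
    "classify_table",
    "g_test_fit",
    "read_family_table",
    "verdicts_frame",
]


@dataclass(frozen=True)
class FamilyRecord:
    family: str
    n_species: int
    k_halophytes: int
    order: str = ""

    def __post_init__(self):
        if self.n_species <= 0:
            raise ValueError(f"{self.family}: family size must be positive")
        if not 0 <= self.k_halophytes <= self.n_species:
            raise ValueError(
                f"{self.family}: halophyte count {self.k_halophytes} outside "
                f"[0, {self.n_species}]"
            )


@dataclass(frozen=True)
class DiversityVerdict:
    family: str
    expected_k: float
    p_more: float
    p_fewer: float
    classification: str  # "more" | "fewer" | "expected"


@dataclass(frozen=True)
class GTestResult:
    G: float
    df: int
    p_value: float


def read_family_table(path) -> list[FamilyRecord]:
    """Read a TSV with columns family, order, n_species, n_halophytes."""
    df = pd.read_csv(path, sep="\t")
    required = {"family", "n_species", "n_halophytes"}
    if not required.issubset(df.columns):
        raise ValueError(f"family table needs columns {sorted(required)}")
    return [
        FamilyRecord(
            family=str(r.family),
            order=str(getattr(r, "order", "") or ""),
            n_species=int(r.n_species),
            k_halophytes=int(r.n_halophytes),
        )
        for r in df.itertuples(index=False)
    ]


def overall_proportion(records: Sequence[FamilyRecord]) -> float:
    """Global halophyte proportion p̂ = Σk_i / Σn_i over all families."""
    if not records:
        raise ValueError("empty family table")
    total_n = sum(r.n_species for r in records)
    total_k = sum(r.k_halophytes for r in records)
    if total_n <= 0:
        raise ValueError("total species count must be positive")
    return total_k / total_n


def binomial_tails(k: int, n: int, p: float) -> tuple[float, float]:
    """Both one-sided binomial tails: (P(X >= k), P(X <= k)).

    Computed via the regularised incomplete beta function (scipy), which
    sums the exact mass to double precision for any n; no normal
    approximation is involved.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    p_more = float(stats.binom.sf(k - 1, n, p))
    p_fewer = float(stats.binom.cdf(k, n, p))
    return p_more, p_fewer


def classify_family(
    record: FamilyRecord, p_hat: float, alpha: float = 0.05
) -> DiversityVerdict:
    """One family's verdict under Binomial(n, p̂) with strict one-sided rules."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p_more, p_fewer = binomial_tails(record.k_halophytes, record.n_species, p_hat)
    if p_more < alpha and p_fewer < alpha:
        raise RuntimeError(
            f"{record.family}: both tails below alpha={alpha}; "
            "inconsistent tail probabilities"
        )
    if p_more < alpha:
        verdict = "more"
    elif p_fewer < alpha:
        verdict = "fewer"
    else:
        verdict = "expected"
    return DiversityVerdict(
        family=record.family,
        expected_k=record.n_species * p_hat,
        p_more=p_more,
        p_fewer=p_fewer,
        classification=verdict,
    )


def classify_table(
    records: Sequence[FamilyRecord],
    alpha: float = 0.05,
    p_hat: float | None = None,
) -> list[DiversityVerdict]:
    """Classify every family; p̂ defaults to the table's overall proportion."""
    if p_hat is None:
        p_hat = overall_proportion(records)
    return [classify_family(r, p_hat, alpha) for r in records]


def g_test_fit(records: Sequence[FamilyRecord], p_hat: float | None = None) -> GTestResult:
    """Likelihood-ratio G-test on the families × {halophyte, other} table.

    G = 2 Σ O ln(O/E) over cells with O > 0, expecteds from the table
    margins (so the column margin proportion is p̂ by construction),
    df = n_families − 1, p from the chi-square upper tail.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 families")
    k = np.array([r.k_halophytes for r in records], dtype=float)
    n = np.array([r.n_species for r in records], dtype=float)
    if (n <= 0).any():
        raise ValueError("family sizes must all be positive")
    if p_hat is None:
        p_hat = k.sum() / n.sum()
    observed = np.column_stack([k, n - k])
    expected = np.column_stack([n * p_hat, n * (1.0 - p_hat)])
    if (expected <= 0).any():
        raise ValueError("expected cell counts must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(observed > 0, observed * np.log(observed / expected), 0.0)
    G = 2.0 * terms.sum()
    df = len(records) - 1
    return GTestResult(G=float(max(G, 0.0)), df=df, p_value=float(stats.chi2.sf(G, df)))


def verdicts_frame(verdicts: Iterable[DiversityVerdict]) -> pd.DataFrame:
    """Verdicts as a DataFrame ready for TSV output."""
    return pd.DataFrame(
        [
            {
                "family": v.family,
                "expected_k": v.expected_k,
                "p_more": v.p_more,
                "p_fewer": v.p_fewer,
                "classification": v.classification,
            }
            for v in verdicts
        ]
    )
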