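"""Published reference values for the angiosperm salt-tolerance survey.

The package ships the published per-family summary for the 22 angiosperm
families whose subtrees were analysed phylogenetically (family sizes and
halophyte counts, subtree sampling percentages, inferred origin counts,
NoTO, and the Brownian-threshold p-values), plus the headline totals of
the family-level survey (411 families, 276,000 species, 2852 halophyte
species). These printed values are *inputs* for replication: the pipeline
recomputes the derived columns (NoTO, taxonomic pattern, aggregates) from
the raw counts and compares.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_family_survey", "SURVEY_TOTALS"]

#: Headline totals of the published family-level survey.
SURVEY_TOTALS = {
    "n_families": 411,
    "n_families_with_halophytes": 146,
    "n_families_more": 51,
    "n_families_fewer": 68,
    "total_species": 276_000,
    "total_halophyte_species": 2852,
}


def load_family_survey() -> pd.DataFrame:
    """The published 22-family survey table as a DataFrame.

    Columns include raw counts (``family_size``, ``known_halophytes``,
    ``subtree_size``, ``halophytes_in_subtree``, ``inferred_origins``),
    sampling percentages, the published per-family NoTO (1 decimal), the
    taxonomic pattern verdict, and the two null-model p-values.
    """
    with resources.files("saltrait.data").joinpath("family_survey_22.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
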